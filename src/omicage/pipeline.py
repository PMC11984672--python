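"""End-to-end workflow: BioAge scoring -> group comparisons and
correlations -> CR/EX signatures -> overlap test -> pathway enrichment ->
targeted inflammatory enrichment, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .bioage import compute_all_bioages
from .datasets import MultiOmicDataset
from .enrichment import PathwayAnnotation, inflammatory_enrichment, multilayer_enrichment
from .multiblock import (
    BlockData,
    extract_signature,
    fit_multiblock_splsda,
    signature_overlap_test,
    tune_keepx_cv,
)
from .simulate import CohortConfig, simulate_annotations, simulate_cohort
from .stats import correlate_metrics, pairwise_tukey

logger = logging.getLogger(__name__)

ADULT_GROUPS = ("CR", "EX", "WD")


@dataclass
class PipelineConfig:
    """Paths, statistical settings and the master seed for a full run."""

    data_dir: str | None = None          # read dataset here; None -> simulate
    annotation_dir: str | None = None    # read annotations here; None -> simulate
    output_dir: str = "results/pipeline"
    reference_group: str = "yWD"
    covariance_mode: str = "diagonal"
    shrinkage_lambda: float = 0.5
    folds: int = 5
    repeats: int = 100
    tune: bool = False                   # CV-tune keepX (slow) vs fixed keepX
    keepx: dict | None = None            # fixed keepX per block when tune=False
    n_components: int = 1
    permutations: int = 10_000
    alpha: float = 0.05
    q_threshold: float = 0.05
    seed: int = 0
    simulate: CohortConfig = field(default_factory=CohortConfig)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the in-memory results and writes all
    stage tables plus a JSON manifest (seed, config, file hashes)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    written: list[Path] = []
    results: dict = {}

    # --- data -------------------------------------------------------------
    stage = "load_data"
    try:
        if config.data_dir:
            dataset = oio.read_dataset(config.data_dir)
            truth = None
        else:
            sim_cfg = config.simulate
            sim_cfg.seed = seeds[0]
            dataset, truth = simulate_cohort(sim_cfg)
            written += oio.write_dataset(dataset, out / "data")
            oio.write_ground_truth(truth, out / "data" / "ground_truth.json")
            written.append(out / "data" / "ground_truth.json")
        if config.annotation_dir:
            annotation = oio.read_annotation(config.annotation_dir)
        else:
            annotation = simulate_annotations(
                config.simulate, truth=truth, dataset=dataset
            )
            written += oio.write_annotation(annotation, out / "annotations")

        stage = "bioage"
        bioages, models = compute_all_bioages(
            dataset,
            reference_group=config.reference_group,
            mode=config.covariance_mode,
            shrinkage_lambda=config.shrinkage_lambda,
        )
        bioage_path = out / "bioage.tsv"
        bioages.to_csv(bioage_path, sep="\t", index_label="sample_id")
        written.append(bioage_path)
        results["bioage"] = bioages

        stage = "comparisons"
        adults = dataset.metadata["group"].isin(ADULT_GROUPS)
        comp_rows = []
        for col in bioages.columns:
            tab = pairwise_tukey(
                bioages.loc[adults.values, col],
                dataset.metadata.loc[adults.values, "group"],
                alpha=config.alpha,
            )
            tab.insert(0, "metric", col)
            comp_rows.append(tab)
        comparisons = pd.concat(comp_rows, ignore_index=True)
        comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
        written.append(out / "comparisons.tsv")
        results["comparisons"] = comparisons

        stage = "correlations"
        panel = pd.concat(
            [dataset.metadata.loc[adults.values, ["bmi", "body_fat"]],
             bioages.loc[adults.values]],
            axis=1,
        )
        r_mat, p_mat = correlate_metrics(panel)
        r_mat.to_csv(out / "correlations_r.tsv", sep="\t")
        p_mat.to_csv(out / "correlations_p.tsv", sep="\t")
        written += [out / "correlations_r.tsv", out / "correlations_p.tsv"]
        results["correlations"] = (r_mat, p_mat)

        stage = "signatures"
        signatures = {}
        universe_sizes = {b: dataset.layers[b].shape[1] for b in dataset.layers}
        for contrast in (("CR", "WD"), ("EX", "WD")):
            data = BlockData.from_dataset(dataset, contrast=contrast)
            if config.tune:
                cv = tune_keepx_cv(
                    data, folds=config.folds, repeats=config.repeats,
                    seed=seeds[1], n_components=config.n_components,
                )
                keepx = cv.chosen
                pd.DataFrame(cv.grid).assign(ber=cv.ber_mean, se=cv.ber_se).to_csv(
                    out / f"cv_{contrast[0]}_vs_{contrast[1]}.tsv", sep="\t", index=False
                )
                written.append(out / f"cv_{contrast[0]}_vs_{contrast[1]}.tsv")
            else:
                keepx = config.keepx or {
                    b: min(20, m.shape[1]) for b, m in data.blocks.items()
                }
            model = fit_multiblock_splsda(data, keepx, n_components=config.n_components)
            sig = extract_signature(model)
            signatures[contrast[0]] = sig
            rows = []
            for layer, feats in sig.features.items():
                for f in feats:
                    rows.append({
                        "layer": layer, "feature": f,
                        "loading": float(model.loadings[layer].loc[f].abs().max()),
                        "direction": sig.direction[layer][f],
                    })
            sig_path = out / f"signature_{contrast[0]}_vs_{contrast[1]}.tsv"
            pd.DataFrame(rows).to_csv(sig_path, sep="\t", index=False)
            written.append(sig_path)
        results["signatures"] = signatures

        stage = "overlap"
        overlap = signature_overlap_test(
            signatures["CR"], signatures["EX"], universe_sizes
        )
        overlap["per_layer"].to_csv(out / "overlap.tsv", sep="\t", index=False)
        with open(out / "overlap.json", "w") as fh:
            json.dump(
                {"p_combined": overlap["p_combined"], "p_pooled": overlap["p_pooled"]},
                fh,
            )
        written += [out / "overlap.tsv", out / "overlap.json"]
        results["overlap"] = overlap

        stage = "enrichment"
        enrich = {}
        for name, sig in signatures.items():
            tab = multilayer_enrichment(
                sig, annotation, B=min(config.permutations, 2000), seed=seeds[2],
                q_threshold=config.q_threshold,
            )
            tab.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
            written.append(out / f"enrichment_{name}.tsv")
            enrich[name] = tab
        results["enrichment"] = enrich

        stage = "inflammatory"
        inflamm_sets = _candidate_sets(annotation, n=min(17, len(annotation.gene_sets)))
        inflamm = {}
        for name, sig in signatures.items():
            tab = inflammatory_enrichment(
                sig, inflamm_sets, annotation, B=config.permutations, seed=seeds[3]
            )
            tab.to_csv(out / f"inflammatory_{name}.tsv", sep="\t", index=False)
            written.append(out / f"inflammatory_{name}.tsv")
            inflamm[name] = tab
        results["inflammatory"] = inflamm
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), default=str, sort_keys=True).encode()
        ).hexdigest(),
        "bioage_columns": list(results["bioage"].columns),
        "signatures": {k: v.size() for k, v in results["signatures"].items()},
        "outputs": {str(p.relative_to(out)): _hash_file(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    results["manifest"] = manifest
    return results


def _candidate_sets(annotation: PathwayAnnotation, n: int) -> dict[str, set[str]]:
    """First n gene pathways, made disjoint (first-come assignment) so they
    partition the universe for the multivariate-hypergeometric null."""
    names = sorted(annotation.gene_sets)[:n]
    seen: set[str] = set()
    out = {}
    for name in names:
        members = annotation.gene_sets[name] - seen
        if members:
            out[name] = members
            seen |= members
    return out
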