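"""Readers and writers: TSV feature matrices (with orientation
auto-detection), GMT pathway sets, two-column mapping tables, clock
coefficient files, and dataset round-trips."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from .bioage import ClockSpec
from .datasets import MultiOmicDataset
from .enrichment import PathwayAnnotation


def read_feature_matrix(path, metadata_ids=None, sep: str | None = None) -> pd.DataFrame:
    """Read a sample-by-feature matrix (first column = sample IDs).

    If ``metadata_ids`` is given and the column header overlaps it better
    than the row index does, the file is assumed transposed
    (feature-by-sample) and is flipped with a warning.  Duplicate IDs and
    non-numeric cells are rejected with coordinates.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_header = pd.Index(header)
    if dup_header.has_duplicates:
        dup = dup_header[dup_header.duplicated()][0]
        raise ValueError(f"{path}: duplicated feature column {dup!r}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty matrix")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated row ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicated feature column {dup!r}")
    if metadata_ids is not None:
        ids = set(metadata_ids)
        row_hits = len(ids & set(df.index))
        col_hits = len(ids & set(df.columns))
        if col_hits > row_hits:
            warnings.warn(f"{path}: looks transposed (features in rows); transposing")
            df = df.T
    bad = df.apply(pd.to_numeric, errors="coerce")
    nulls = bad.isna() & df.notna()
    if nulls.any().any():
        r = nulls.any(axis=1).idxmax()
        c = nulls.loc[r].idxmax()
        raise ValueError(f"{path}: non-numeric cell at row {r!r}, column {c!r}")
    return bad


def write_feature_matrix(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep=sep, index_label="sample_id")


def read_gmt(path) -> dict[str, set[str]]:
    """Standard GMT: name<TAB>description<TAB>member..., one set per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, _desc, *members = parts
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicated pathway {name!r}")
            uniq = set(members)
            if len(uniq) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicated members in {name!r} deduplicated")
            sets[name] = uniq
    return sets


def write_gmt(sets: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(sets[name])]) + "\n")


def read_mapping(path) -> dict[str, set[str]]:
    """Two-column TSV (source<TAB>target), many-to-many, header optional."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected exactly 2 columns")
            if lineno == 1 and parts[0].lower() in ("source", "cpg", "otu", "feature"):
                continue
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_mapping(mapping: dict[str, set[str]], path, header=("source", "target")) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for src in sorted(mapping):
            for tgt in sorted(mapping[src]):
                fh.write(f"{src}\t{tgt}\n")


def read_clock(path, name: str | None = None) -> ClockSpec:
    """Clock coefficients: two-column TSV whose header's second field holds
    the intercept, e.g. ``feature<TAB>35.5``; data rows are feature, weight."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2:
            raise ValueError(f"{path}: clock header needs 2 fields (feature, intercept)")
        intercept = float(header[1])
        coefs: dict[str, float] = {}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            feat, w = line.split("\t")
            if feat in coefs:
                raise ValueError(f"{path}:{lineno}: duplicated feature {feat!r}")
            coefs[feat] = float(w)
    return ClockSpec(name=name or Path(path).stem, intercept=intercept, coefficients=coefs)


def write_clock(clock: ClockSpec, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"feature\t{clock.intercept!r}\n")
        for feat, w in clock.coefficients.items():
            fh.write(f"{feat}\t{w!r}\n")


# ---------------------------------------------------------------------------
# dataset / annotation round trips
# ---------------------------------------------------------------------------


def write_dataset(dataset: MultiOmicDataset, directory) -> list[Path]:
    """Layers as <layer>.tsv plus metadata.tsv under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    meta_path = directory / "metadata.tsv"
    dataset.metadata.to_csv(meta_path, sep="\t", index_label="sample_id")
    written.append(meta_path)
    for layer, mat in dataset.layers.items():
        p = directory / f"{layer}.tsv"
        write_feature_matrix(mat, p)
        written.append(p)
    return written


def read_dataset(directory, layers=None) -> MultiOmicDataset:
    directory = Path(directory)
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t", index_col="sample_id")
    found = {}
    for p in sorted(directory.glob("*.tsv")):
        if p.stem == "metadata":
            continue
        if layers is not None and p.stem not in layers:
            continue
        found[p.stem] = read_feature_matrix(p, metadata_ids=metadata.index)
    return MultiOmicDataset(layers=found, metadata=metadata)


def write_annotation(annotation: PathwayAnnotation, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_gmt(annotation.gene_sets, directory / "pathways_genes.gmt")
    write_gmt(annotation.metabolite_sets, directory / "pathways_metabolites.gmt")
    write_mapping(annotation.cpg_to_genes, directory / "cpg_to_gene.tsv", ("cpg", "gene"))
    write_mapping(annotation.otu_to_pathways, directory / "otu_to_pathway.tsv", ("otu", "pathway"))
    with open(directory / "universes.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in annotation.universes.items()}, fh)
    return [
        directory / "pathways_genes.gmt",
        directory / "pathways_metabolites.gmt",
        directory / "cpg_to_gene.tsv",
        directory / "otu_to_pathway.tsv",
        directory / "universes.json",
    ]


def read_annotation(directory) -> PathwayAnnotation:
    directory = Path(directory)
    with open(directory / "universes.json") as fh:
        universes = {k: set(v) for k, v in json.load(fh).items()}
    return PathwayAnnotation(
        gene_sets=read_gmt(directory / "pathways_genes.gmt"),
        metabolite_sets=read_gmt(directory / "pathways_metabolites.gmt"),
        cpg_to_genes=read_mapping(directory / "cpg_to_gene.tsv"),
        otu_to_pathways=read_mapping(directory / "otu_to_pathway.tsv"),
        universes=universes,
    )


def write_ground_truth(truth, path) -> None:
    payload = {
        "cr_features": truth.cr_features,
        "ex_features": truth.ex_features,
        "shared_features": truth.shared_features,
        "aging_features": truth.aging_features,
        "bio_age_offset": truth.bio_age_offset.to_dict(),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
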