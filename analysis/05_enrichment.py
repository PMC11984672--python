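"""Pathway enrichment of the CR and EX signatures.

Two analyses per signature: (1) agnostic overrepresentation across the
four annotatable layers (microbiome, metabolome, DNAm via the CpG-bias
resampling test, mRNA), Edgington-combined and BH-FDR corrected; (2) a
targeted permutation enrichment of 17 candidate pathways with a
multivariate-hypergeometric null and min-p family-wise correction.

Reads results/cohort and results/signature_*.tsv; writes
results/enrichment_{CR,EX}.tsv and results/inflammatory_{CR,EX}.tsv.
"""

from pathlib import Path

import pandas as pd

from omicage import io as oio
from omicage.enrichment import inflammatory_enrichment, multilayer_enrichment
from omicage.pipeline import _candidate_sets

OUT = Path("results")
SEED = 22
B_AGNOSTIC = 2000
B_TARGETED = 10_000


def main() -> None:
    annotation = oio.read_annotation(OUT / "cohort" / "annotations")
    candidates = _candidate_sets(annotation, n=17)

    for name in ("CR", "EX"):
        sig_tab = pd.read_csv(OUT / f"signature_{name}_vs_WD.tsv", sep="\t")
        sig = {layer: set(grp["feature"]) for layer, grp in sig_tab.groupby("layer")}

        res = multilayer_enrichment(sig, annotation, B=B_AGNOSTIC, seed=SEED)
        res.to_csv(OUT / f"enrichment_{name}.tsv", sep="\t", index=False)
        hits = res[res["significant"]]
        print(f"{name}: {len(hits)} pathways at q < 0.05 "
              f"(top: {', '.join(hits['pathway'].head(5))})")

        inflam = inflammatory_enrichment(sig, candidates, annotation, B=B_TARGETED, seed=SEED)
        inflam.to_csv(OUT / f"inflammatory_{name}.tsv", sep="\t", index=False)
        best = inflam.nsmallest(3, "p_corrected")[["pathway", "p_combined", "p_corrected"]]
        print(f"{name}: targeted permutation enrichment, most significant candidates:")
        print(best.round(4).to_string(index=False))

    print(f"\nwrote enrichment tables under {OUT}")


if __name__ == "__main__":
    main()
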