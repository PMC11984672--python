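"""Score every sample's BioAge per omic layer and compare the groups.

BioAge = Mahalanobis distance from the young-reference mean profile,
divided by sqrt(feature count).  Group contrasts use pairwise t-tests with
Tukey-Kramer adjustment; a correlation panel relates the six scores to BMI
and body fat.

Reads results/cohort; writes results/bioage.tsv, results/bioage_comparisons.tsv,
results/bioage_correlations_{r,p}.tsv.
"""

from pathlib import Path

import pandas as pd

from omicage import compute_all_bioages
from omicage import io as oio
from omicage.stats import correlate_metrics, pairwise_tukey

OUT = Path("results")


def main() -> None:
    dataset = oio.read_dataset(OUT / "cohort")
    table, models = compute_all_bioages(dataset)
    table.to_csv(OUT / "bioage.tsv", sep="\t", index_label="sample_id")

    groups = dataset.metadata["group"]
    print("mean BioAge per group:")
    print(table.groupby(groups).mean().round(3).to_string())

    adults = groups.isin(["CR", "EX", "WD"])
    rows = []
    for col in table.columns:
        tab = pairwise_tukey(table.loc[adults.values, col], groups[adults])
        tab.insert(0, "metric", col)
        rows.append(tab)
    comparisons = pd.concat(rows, ignore_index=True)
    comparisons.to_csv(OUT / "bioage_comparisons.tsv", sep="\t", index=False)
    sig = comparisons[comparisons["significant"]]
    print(f"\n{len(sig)} of {len(comparisons)} Tukey contrasts significant at 0.05:")
    if len(sig):
        print(sig[["metric", "group_a", "group_b", "diff", "p_tukey"]].round(4).to_string(index=False))

    panel = pd.concat(
        [dataset.metadata.loc[adults.values, ["bmi", "body_fat"]], table.loc[adults.values]],
        axis=1,
    )
    r, p = correlate_metrics(panel)
    r.to_csv(OUT / "bioage_correlations_r.tsv", sep="\t")
    p.to_csv(OUT / "bioage_correlations_p.tsv", sep="\t")
    print(f"\nwrote bioage tables under {OUT}")


if __name__ == "__main__":
    main()
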