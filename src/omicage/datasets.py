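"""Multi-omic dataset container: named layer matrices plus sample metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: canonical layer order used throughout the pipeline
LAYER_ORDER = ("microbiome", "dnam", "mrna", "metabolome", "hormones", "pheno")


@dataclass
class MultiOmicDataset:
    """Named sample-by-feature matrices aligned on a shared sample index.

    Parameters
    ----------
    layers
        Mapping layer name -> DataFrame with samples in rows (index =
        sample IDs) and features in columns.
    metadata
        Per-sample table indexed by sample ID with at least a ``group``
        column; the synthetic generator also provides ``age``, ``sex``,
        ``bmi`` and ``body_fat``.
    """

    layers: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.metadata.index.has_duplicates:
            dups = self.metadata.index[self.metadata.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample IDs in metadata: {dups[:5]}")
        for name, mat in self.layers.items():
            if mat.index.has_duplicates:
                raise ValueError(f"duplicated sample IDs in layer {name!r}")
            missing = mat.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(
                    f"layer {name!r} has samples absent from metadata: {list(missing[:5])}"
                )

    @property
    def sample_ids(self) -> pd.Index:
        return self.metadata.index

    def groups(self) -> pd.Series:
        return self.metadata["group"]

    def samples_in_group(self, group: str) -> list[str]:
        return self.metadata.index[self.metadata["group"] == group].tolist()

    def subset(self, sample_ids) -> "MultiOmicDataset":
        """Restrict all layers and metadata to the given samples (order kept)."""
        ids = pd.Index(sample_ids)
        return MultiOmicDataset(
            layers={k: v.loc[ids.intersection(v.index)] for k, v in self.layers.items()},
            metadata=self.metadata.loc[ids],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        dims = ", ".join(f"{k}: {v.shape[0]}x{v.shape[1]}" for k, v in self.layers.items())
        return f"MultiOmicDataset({len(self.metadata)} samples; {dims})"
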