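"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_META = ("line", "tissue", "replicate")


class InputError(ValueError):
    """Raised when an input table, tree or matrix violates its contract."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class OtuTable:
    """OTU count table (samples x OTUs) with per-sample metadata.

    ``counts`` is indexed by sample id with OTU ids as columns; ``meta`` is
    indexed by the same sample ids and carries ``line``, ``tissue`` and
    ``replicate`` columns.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise InputError("empty OTU table")
        if self.counts.index.duplicated().any():
            raise InputError("duplicate sample ids in count table")
        if self.counts.columns.duplicated().any():
            raise InputError("duplicate OTU ids in count table")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise InputError("non-finite counts")
        if (vals < 0).any():
            raise InputError("negative counts")
        missing = [c for c in REQUIRED_META if c not in self.meta.columns]
        if missing:
            raise InputError(f"metadata missing columns: {missing}")
        if set(self.counts.index) != set(self.meta.index):
            extra = sorted(set(self.counts.index) ^ set(self.meta.index))
            raise InputError(f"sample ids differ between counts and metadata: {extra}")
        # keep metadata aligned with count-table sample order
        self.meta = self.meta.loc[self.counts.index]
        if self.meta[["line", "tissue"]].isna().any().any():
            raise InputError("every sample needs a line and tissue label")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lines(self) -> list[str]:
        return sorted(self.meta["line"].unique())

    def line_labels(self) -> pd.Series:
        return self.meta["line"]

    def subset_samples(self, sample_ids) -> "OtuTable":
        sample_ids = list(sample_ids)
        return OtuTable(self.counts.loc[sample_ids].copy(), self.meta.loc[sample_ids].copy())

    def subset_tissue(self, tissue: str) -> "OtuTable":
        keep = self.meta.index[self.meta["tissue"] == tissue]
        if len(keep) == 0:
            raise InputError(f"no samples with tissue {tissue!r}")
        return self.subset_samples(keep)

    def subset_otus(self, otu_ids) -> "OtuTable":
        otu_ids = list(otu_ids)
        return OtuTable(self.counts[otu_ids].copy(), self.meta.copy())


@dataclass
class ExpressionMatrix:
    """Gene expression in transcripts-per-million, samples x genes."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise InputError("duplicate sample ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate gene ids in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise InputError("negative expression values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)
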