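"""Count-matrix container shared by all pipeline stages.

A :class:`CountMatrix` holds nonnegative integer read counts for features
(rows) by samples (columns), together with a biotype label per feature and a
library size per sample.  The library size is the number of reads that
entered counting, so it may exceed the column sum when some reads were not
assignable to any feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Features x samples integer counts with biotype and library-size metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by feature_id with one column per sample.
    biotype
        Series mapping feature_id -> biotype label, aligned to ``counts.index``.
    library_size
        Series mapping sample_id -> total input reads, aligned to
        ``counts.columns``.  Defaults to the column sums.
    """

    counts: pd.DataFrame
    biotype: pd.Series
    library_size: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.biotype = self.biotype.reindex(self.counts.index)
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()].tolist()[:5]
            raise ValueError(f"missing biotype for features {missing}")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)
        self.library_size = self.library_size.reindex(self.counts.columns)
        colsum = self.counts.sum(axis=0)
        if (self.library_size + 1e-9 < colsum).any():
            raise ValueError("library_size below assigned column sum")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(
            self.counts[sample_ids].copy(),
            self.biotype.copy(),
            self.library_size.loc[sample_ids].copy(),
        )

    def cpm(self, factors: pd.Series | None = None) -> pd.DataFrame:
        """Counts per million on effective library sizes.

        ``factors`` are multiplicative normalization factors (e.g. TMM); the
        effective library size of sample *j* is ``library_size[j] * factors[j]``.
        """
        eff = self.library_size.astype(float)
        if factors is not None:
            eff = eff * pd.Series(factors).reindex(eff.index)
        if (eff <= 0).any():
            raise ValueError("effective library sizes must be positive")
        return self.counts.div(eff, axis=1) * 1e6
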