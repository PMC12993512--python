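"""Filtering and standardisation applied before inference and ordination.

Prevalence/singleton filters operate on count tables; Wisconsin double
standardisation and the centered log-ratio (CLR) transform prepare matrices
for ordination and neighborhood-selection inference respectively. The
fit/transform stages are scikit-learn compatible transformers; thin
module-level functions mirror them for one-shot use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import AbundanceTable


@dataclass
class FilterReport:
    threshold: float
    taxa_before: int
    taxa_after: int
    discarded_ids: list[str]

    def __post_init__(self) -> None:
        assert self.taxa_after + len(self.discarded_ids) == self.taxa_before

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "taxa_before": self.taxa_before,
            "taxa_after": self.taxa_after,
            "discarded_ids": list(self.discarded_ids),
        }


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Drop taxa detected in fewer than ``threshold`` of the samples.

    A taxon is retained when its nonzero-sample fraction is >= threshold;
    strictly-below is discarded (taxa found in "less than" the threshold
    fraction of samples are removed, equality kept). Operates on taxa x
    samples count matrices.
    """

    def __init__(self, threshold: float = 0.05):
        self.threshold = threshold

    def fit(self, X, y=None):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        X = check_array(X, ensure_min_features=1)
        prevalence = (X > 0).mean(axis=1)
        self.prevalence_ = prevalence
        self.support_ = prevalence >= self.threshold
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return X[self.support_, :]


def prevalence_filter(
    table: AbundanceTable, threshold: float = 0.05
) -> tuple[AbundanceTable, FilterReport]:
    f = PrevalenceFilter(threshold).fit(table.counts)
    keep = [t for t, k in zip(table.taxon_ids, f.support_) if k]
    drop = [t for t, k in zip(table.taxon_ids, f.support_) if not k]
    return table.select_taxa(keep), FilterReport(
        threshold, table.n_taxa, len(keep), drop
    )


def singleton_filter(table: AbundanceTable) -> AbundanceTable:
    """Remove singletons (total count 1) and taxa seen in only one sample."""
    if table.n_taxa == 0:
        raise ValueError("empty table")
    total = table.counts.sum(axis=1)
    n_present = (table.counts > 0).sum(axis=1)
    keep = [
        t
        for t, tot, npres in zip(table.taxon_ids, total, n_present)
        if tot > 1 and npres > 1
    ]
    return table.select_taxa(keep)


def relative_abundance(table: AbundanceTable) -> np.ndarray:
    """Per-sample closure to fractions; columns sum to 1."""
    totals = table.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [table.sample_ids[i] for i in zero]
        raise ValueError(f"samples with zero total counts: {bad}")
    return table.counts / totals


class WisconsinScaler(BaseEstimator, TransformerMixin):
    """Wisconsin double standardisation on samples x taxa matrices.

    Species (columns) are first divided by their maxima, then each sample
    (row) by its total, so output rows sum to 1. Stateless: fit records the
    column maxima only for introspection; transform re-derives both steps
    from the input, matching the ecological convention where the
    standardisation is part of the distance computation.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        if np.any(X < 0):
            raise ValueError("matrix must be non-negative")
        self.col_max_ = X.max(axis=0)
        return self

    def transform(self, X):
        X = check_array(X)
        col_max = X.max(axis=0)
        if np.any(col_max <= 0):
            raise ValueError("all-zero taxon column")
        X = X / col_max
        row_tot = X.sum(axis=1, keepdims=True)
        if np.any(row_tot <= 0):
            raise ValueError("all-zero sample row")
        return X / row_tot

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def wisconsin_double_standardize(matrix: np.ndarray) -> np.ndarray:
    """Functional form; input oriented samples x taxa."""
    return WisconsinScaler().fit_transform(np.asarray(matrix, dtype=float))


class CLRTransformer(BaseEstimator, TransformerMixin):
    """Centered log-ratio transform of count rows (samples x taxa).

    Adds ``pseudocount`` to every count, closes each sample, and returns
    log(x / geometric mean); each output row sums to zero.
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        self.n_features_in_ = check_array(X).shape[1]
        return self

    def transform(self, X):
        X = check_array(X) + self.pseudocount
        logx = np.log(X)
        return logx - logx.mean(axis=1, keepdims=True)

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def clr_transform(table: AbundanceTable, pseudocount: float = 1.0) -> np.ndarray:
    """CLR per sample; returns taxa x samples to match the table layout."""
    return CLRTransformer(pseudocount).fit_transform(table.counts.T).T


def aggregate_family(
    table: AbundanceTable, node_subset: list[str]
) -> "pd.DataFrame":
    """Family x sample relative abundances over a node subset.

    Counts of taxa sharing a family label are summed, then each sample
    column is renormalised. Taxa without a parseable family rank fall into
    ``unclassified``.
    """
    import pandas as pd

    if not node_subset:
        raise ValueError("node_subset must be nonempty")
    sub = table.select_taxa([t for t in table.taxon_ids if t in set(node_subset)])
    if sub.n_taxa == 0:
        raise ValueError("no subset taxa present in the table")
    fam = [t.family or "unclassified" for t in sub.taxa]
    df = pd.DataFrame(sub.counts, index=fam, columns=sub.sample_ids)
    agg = df.groupby(level=0).sum()
    totals = agg.sum(axis=0)
    totals = totals.replace(0, np.nan)
    return agg / totals
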