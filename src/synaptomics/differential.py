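"""Differential abundance: normalization, PME/PSE abundance ratios, t-tests, clustering.

The differential contrast is always expressed as PME relative to PSE: the
abundance ratio AR of a feature is the ratio of the arithmetic group means of
its total-amount-normalized abundances, and log2(AR) is the fold-change scale.
Significance is a raw two-sided two-sample t-test at alpha (default 0.05,
matching the a-priori level of the study design); no multiple-testing
correction is applied to the differential tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from synaptomics.abundance import AbundanceMatrix, DataError

TINY_P = 5e-324  # smallest subnormal double: "0-adjacent" p for zero-variance separation


class DesignError(ValueError):
    """Raised when the sample design cannot support the requested test."""


def normalize_total_amount(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Total peptide amount normalization with no scaling.

    Every sample column is rescaled so its sum equals the mean of the input
    column sums; within-column proportions are preserved exactly.
    """
    sums = matrix.values.sum(axis=0)
    if (sums <= 0).any():
        raise DataError("column sums must be positive for total-amount normalization")
    target = sums.mean()
    return matrix.copy_with(matrix.values * (target / sums))


def _ttest_rows(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided two-sample t-test with explicit degenerate handling.

    Rows with zero variance in both groups get p = 1 when the group means are
    equal (t = 0) and a 0-adjacent p with a warning when they differ: the test
    statistic is unbounded there and the direction is still well defined.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        means_equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        eq = degenerate & means_equal
        ne = degenerate & ~means_equal
        t[eq], p[eq] = 0.0, 1.0
        if ne.any():
            warnings.warn(
                f"{int(ne.sum())} feature(s) with zero within-group variance but unequal "
                "means: p set 0-adjacent", stacklevel=3)
            t[ne] = np.sign(a.mean(axis=1)[ne] - b.mean(axis=1)[ne]) * np.inf
            p[ne] = TINY_P
    return t, p


@dataclass
class DifferentialTable:
    """Per-feature differential records plus the significance level used.

    ``records`` columns: feature_id, gene_id, mean_pme, mean_pse, AR, log2_ar,
    t_stat, p_value, significant, direction.
    """

    records: pd.DataFrame
    alpha: float = 0.05
    region: str = ""
    level: str = "protein"

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n_significant, n_up, n_down)."""
        sig = self.records[self.records["significant"]]
        n_up = int((sig["log2_ar"] > 0).sum())
        n_down = int((sig["log2_ar"] < 0).sum())
        return len(sig), n_up, n_down

    def significant_genes(self) -> set[str]:
        sig = self.records[self.records["significant"]]
        return set(sig["gene_id"].dropna())

    def significant_features(self) -> list[str]:
        return list(self.records.loc[self.records["significant"], "feature_id"])

    def write_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, alpha: float = 0.05, region: str = "", level: str = "protein"):
        return cls(pd.read_csv(path, sep="\t"), alpha=alpha, region=region, level=level)

    def volcano_coordinates(self) -> pd.DataFrame:
        """(log2_ar, -log10 p) per feature, for volcano plotting."""
        return pd.DataFrame({
            "feature_id": self.records["feature_id"],
            "log2_ar": self.records["log2_ar"],
            "neg_log10_p": -np.log10(self.records["p_value"]),
        })


def differential_table(
    matrix: AbundanceMatrix,
    alpha: float = 0.05,
    test: str = "student",
    normalize: bool = True,
) -> DifferentialTable:
    """Per-feature PME/PSE abundance ratios and two-sample t-tests.

    Parameters
    ----------
    matrix
        Abundance matrix with exactly two groups, >= 2 samples each.
    alpha
        Raw-p significance level.
    test
        "student" (pooled variance, the default convention for grouped
        reporter abundances) or "welch".
    normalize
        Apply total-amount normalization first (default True).
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    if normalize:
        matrix = normalize_total_amount(matrix)
    pme_cols = matrix.group_columns("PME")
    pse_cols = matrix.group_columns("PSE")
    if len(pme_cols) < 2 or len(pse_cols) < 2:
        raise DesignError("each group needs >= 2 samples for a t-test")
    a = matrix.values[pme_cols].to_numpy(float)
    b = matrix.values[pse_cols].to_numpy(float)
    t, p = _ttest_rows(a, b, equal_var=(test == "student"))
    mean_pme = a.mean(axis=1)
    mean_pse = b.mean(axis=1)
    ar = mean_pme / mean_pse
    log2_ar = np.log2(ar)
    sig = p < alpha
    direction = np.where(log2_ar > 0, "up", "down")
    records = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "gene_id": matrix.gene_ids.values,
        "mean_pme": mean_pme,
        "mean_pse": mean_pse,
        "AR": ar,
        "log2_ar": log2_ar,
        "t_stat": t,
        "p_value": p,
        "significant": sig,
        "direction": direction,
    }).reset_index(drop=True)
    return DifferentialTable(records=records, alpha=alpha, region=matrix.region,
                             level=matrix.level)


def filter_and_count(table: DifferentialTable) -> tuple[pd.DataFrame, int, int]:
    """Significant subset (p < alpha) with up/down counts by sign of log2 AR."""
    subset = table.records[table.records["p_value"] < table.alpha].copy()
    n_up = int((subset["log2_ar"] > 0).sum())
    n_down = int((subset["log2_ar"] < 0).sum())
    return subset, n_up, n_down


def cluster_differential(
    matrix: AbundanceMatrix,
    feature_ids: list[str] | None = None,
    metric: str = "correlation",
) -> dict:
    """Average-linkage hierarchical clustering of differential features and samples.

    Abundances are z-scored per feature across samples, then features (rows)
    and samples (columns) are each clustered with group-average agglomerative
    linkage on the chosen distance (correlation distance by default). Leaf
    orders are deterministic: scipy's linkage breaks ties by observation
    index, and rows are taken in input order.

    Returns a dict with keys ``feature_linkage``, ``sample_linkage``,
    ``feature_order`` and ``sample_order`` (leaf label lists).
    """
    values = matrix.values
    if feature_ids is not None:
        values = values.loc[feature_ids]
    if values.shape[0] < 2:
        raise DesignError("clustering needs >= 2 features")
    x = values.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    feat_link = linkage(pdist(z, metric=metric), method="average")
    samp_link = linkage(pdist(z.T, metric=metric), method="average")
    return {
        "feature_linkage": feat_link,
        "sample_linkage": samp_link,
        "feature_order": [values.index[i] for i in leaves_list(feat_link)],
        "sample_order": [values.columns[i] for i in leaves_list(samp_link)],
    }
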