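"""Paired tumor-normal differential testing, clustering and the DE scan.

Per site and cancer, a two-sided Wilcoxon signed-rank test compares
paired levels. Zero differences are dropped before ranking; the null
distribution is enumerated exactly (via a rank-sum convolution that
handles midranks) up to 25 informative pairs and approximated normally
with tie correction above that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

EXACT_MAX_N = 25


@dataclass
class DifferentialResult:
    site_id: str | None
    cancer_type: str | None
    n_pairs: int
    direction: str | None  # 'tumor-higher' | 'tumor-lower' | None
    p_value: float
    statistic: float

    def nominal_significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha

    def bonferroni_significant(self, alpha: float, m: int) -> bool:
        return self.p_value < bonferroni_threshold(alpha, m)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def signed_rank_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by convolution over sign patterns.

    Handles tied magnitudes via midranks: doubling every rank makes all
    rank contributions integral, so the distribution of W+ under the
    2^n equiprobable sign assignments is a polynomial product evaluated
    by convolution. Returns (W+, p).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks2 = np.rint(2 * stats.rankdata(np.abs(d))).astype(int)
    w2 = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    # pmf over 2*W+ on [0, total]
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    lower = pmf[: w2 + 1].sum()
    upper = pmf[w2:].sum()
    p = min(1.0, 2.0 * min(lower, upper))
    return w2 / 2.0, p


def paired_wilcoxon(
    normal: np.ndarray,
    tumor: np.ndarray,
    site_id: str | None = None,
    cancer_type: str | None = None,
    exact_max_n: int = EXACT_MAX_N,
) -> DifferentialResult:
    """Two-sided paired signed-rank test of tumor vs normal levels.

    Pairs with a missing member must be dropped by the caller; zero
    differences are dropped here. All-zero differences give p = 1 with
    an undefined direction.
    """
    normal = np.asarray(normal, dtype=float)
    tumor = np.asarray(tumor, dtype=float)
    if normal.shape != tumor.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = tumor - normal
    nz = diffs[diffs != 0]
    n_pairs = nz.size
    if n_pairs == 0:
        return DifferentialResult(site_id, cancer_type, len(diffs), None, 1.0, 0.0)
    med = np.median(nz)
    if med > 0:
        direction = "tumor-higher"
    elif med < 0:
        direction = "tumor-lower"
    else:
        direction = "tumor-higher" if nz.mean() > 0 else "tumor-lower"
    if n_pairs <= exact_max_n:
        w, p = signed_rank_exact_p(nz)
    else:
        w, p = stats.wilcoxon(
            nz, alternative="two-sided", method="approx", correction=False
        )
    return DifferentialResult(site_id, cancer_type, n_pairs, direction, float(p), float(w))


def differential_table(
    levels: pd.DataFrame,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
    value_col: str = "level",
) -> pd.DataFrame:
    """Per (site, cancer) paired test table.

    ``levels``: sample_id, site_id, <value_col>; ``pairs``: patient_id,
    cancer_type, normal_sample_id, tumor_sample_id. Bonferroni is applied
    within each cancer over its tested sites. A row is emitted for every
    site x cancer combination, NA-filled when no complete pair exists.
    """
    keyed = levels.set_index(["sample_id", "site_id"])[value_col]
    site_ids = sorted(levels["site_id"].unique())
    cancers = sorted(pairs["cancer_type"].unique())
    rows = []
    for cancer in cancers:
        cpairs = pairs[pairs["cancer_type"] == cancer]
        for site_id in site_ids:
            nvals, tvals = [], []
            for pair in cpairs.itertuples():
                try:
                    ln = keyed[(pair.normal_sample_id, site_id)]
                    lt = keyed[(pair.tumor_sample_id, site_id)]
                except KeyError:
                    continue
                nvals.append(ln)
                tvals.append(lt)
            if nvals:
                res = paired_wilcoxon(np.array(nvals), np.array(tvals), site_id, cancer)
                rows.append(
                    {
                        "site_id": site_id,
                        "cancer_type": cancer,
                        "n_pairs": len(nvals),
                        "direction": res.direction,
                        "p_value": res.p_value,
                    }
                )
            else:
                rows.append(
                    {
                        "site_id": site_id,
                        "cancer_type": cancer,
                        "n_pairs": 0,
                        "direction": None,
                        "p_value": np.nan,
                    }
                )
    out = pd.DataFrame(rows)
    out["nominal_significant"] = out["p_value"] < alpha
    m_per_cancer = out.groupby("cancer_type")["site_id"].transform("size")
    out["bonferroni_significant"] = out["p_value"] < alpha / m_per_cancer
    return out


def cross_cancer_test(
    std_levels: pd.DataFrame, pairs: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """One pooled paired test per site over standardized levels from all cancers."""
    pooled = pairs.copy()
    pooled["cancer_type"] = "ALL"
    return differential_table(std_levels, pooled, alpha=alpha, value_col="std_level")


def cluster_groups(matrix: pd.DataFrame) -> dict:
    """Two-way Ward clustering of a groups x sites mean-level matrix.

    Missing cells are imputed with the column mean (reported). Rows and
    columns cluster independently on Euclidean distance; scipy's linkage
    tie-breaking (lowest original index first) makes leaf orders
    deterministic. Returns linkages, leaf orders and the imputed cells.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    X = matrix.to_numpy(float).copy()
    imputed = []
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        for i, j in zip(*np.nonzero(np.isnan(X))):
            X[i, j] = col_means[j]
            imputed.append((matrix.index[i], matrix.columns[j]))
    row_link = hierarchy.linkage(X, method="ward")
    col_link = hierarchy.linkage(X.T, method="ward")
    return {
        "row_linkage": row_link,
        "col_linkage": col_link,
        "row_order": [matrix.index[i] for i in hierarchy.leaves_list(row_link)],
        "col_order": [matrix.columns[i] for i in hierarchy.leaves_list(col_link)],
        "imputed_cells": imputed,
    }


def de_scan(
    expression: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA of expression by sample type, per gene.

    ``expression`` is genes x samples on the log10 scale; ``labels`` maps
    sample id -> group. Reports F, p, Bonferroni flag and the group mean
    difference converted to log2 units (volcano x-coordinate). Genes with
    zero variance in every group are reported as degenerate, not raised.
    """
    labels = labels.reindex(expression.columns)
    groups = sorted(labels.dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    cols = {g: expression.columns[(labels == g).to_numpy()] for g in groups}
    for g, c in cols.items():
        if len(c) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    rows = []
    log2_per_log10 = 1.0 / np.log10(2.0)
    for gene in expression.index:
        arrays = [expression.loc[gene, cols[g]].to_numpy(float) for g in groups]
        means = [a.mean() for a in arrays]
        degenerate = all(np.ptp(a) == 0 for a in arrays)
        if degenerate:
            f = np.inf if np.ptp(means) > 0 else 0.0
            p = 0.0 if np.ptp(means) > 0 else 1.0
        else:
            f, p = stats.f_oneway(*arrays)
        diff = (means[-1] - means[0]) * log2_per_log10 if len(groups) == 2 else np.nan
        rows.append(
            {
                "gene_id": gene,
                "F": float(f),
                "p_value": float(p),
                "log2_mean_diff": diff,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["bonferroni_significant"] = out["p_value"] < bonferroni_threshold(
        alpha, len(out)
    )
    return out
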