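"""Spearman correlation scans and Fisher-exact gene-set enrichment.

Normal and tumor samples are scanned separately; the Bonferroni
denominator of a scan is the number of attempted tests (NA results from
constant vectors stay in the count, conservatively). p-values use the t
approximation above n = 20 and a seeded Monte-Carlo permutation null at
or below it; within a scan the permutation null is shared per
(state, site) so the whole gene axis vectorises.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

T_APPROX_MIN_N = 21
PERMUTATIONS = 10_000
_EPS = 1e-12


def _rank_center_norm(a: np.ndarray) -> np.ndarray:
    """Midrank, center, scale to unit norm; dot products give rho."""
    r = stats.rankdata(a)
    r = r - r.mean()
    norm = np.sqrt(r @ r)
    return r / norm if norm > 0 else r


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return float(2 * stats.t.sf(abs(t), n - 2))


def spearman_test(
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | None = None,
    n_permutations: int = PERMUTATIONS,
) -> tuple[float, float, int]:
    """Tie-corrected Spearman rho with a sample-size-adaptive p-value.

    Returns (rho, p, n); (nan, nan, n) for constant input or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    rx = _rank_center_norm(x)
    ry = _rank_center_norm(y)
    rho = float(rx @ ry)
    if n >= T_APPROX_MIN_N:
        p = _t_approx_p(rho, n)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        perms = rng.permuted(np.tile(ry, (n_permutations, 1)), axis=1)
        null = perms @ rx
        p = float((np.sum(np.abs(null) >= abs(rho) - _EPS) + 1) / (n_permutations + 1))
    return rho, p, n


def spearman_scan(
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    states: pd.Series,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    n_permutations: int = PERMUTATIONS,
) -> pd.DataFrame:
    """All site x gene rank correlations, per sample state.

    ``methylation``: sites x samples; ``expression``: genes x samples;
    ``states`` maps sample id -> 'normal'|'tumor'. Every attempted test
    is bookkept: the output has len(sites) * len(genes) rows per state
    and the Bonferroni denominator per scan is the number of genes.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    shared = [s for s in methylation.columns if s in set(expression.columns)]
    states = states.reindex(shared)
    genes = list(expression.index)
    m_tests = len(genes)
    thresh = alpha / m_tests if m_tests else np.nan
    rows = []
    for state in ("normal", "tumor"):
        cols = [s for s in shared if states[s] == state]
        E = expression[cols].to_numpy(float)
        for site_id in methylation.index:
            mv = methylation[cols].loc[site_id].to_numpy(float)
            site_mask = ~np.isnan(mv)
            rows.extend(
                _scan_one_site(
                    site_id, state, mv, E, genes, site_mask, thresh, rng, n_permutations
                )
            )
    return pd.DataFrame(
        rows,
        columns=["trait_a", "trait_b", "state", "rho", "p_value", "n", "bonferroni_significant"],
    )


def _scan_one_site(
    site_id, state, mv, E, genes, site_mask, thresh, rng, n_permutations
) -> list[dict]:
    """Vectorised per-site scan over the gene axis.

    Genes with missing values in the site's complete columns fall back
    to the pairwise single-test path.
    """
    out: list[dict] = []
    x = mv[site_mask]
    n = x.size
    Esub = E[:, site_mask]
    gene_ok = ~np.isnan(Esub).any(axis=1)
    degenerate = n < 3 or np.ptp(x) == 0

    rho_vec = np.full(len(genes), np.nan)
    p_vec = np.full(len(genes), np.nan)
    if not degenerate:
        rx = _rank_center_norm(x)
        const = np.ptp(Esub, axis=1) == 0
        vec_idx = np.nonzero(gene_ok & ~const)[0]
        if vec_idx.size:
            R = np.apply_along_axis(_rank_center_norm, 1, Esub[vec_idx])
            rho = R @ rx
            rho_vec[vec_idx] = rho
            if n >= T_APPROX_MIN_N:
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, _EPS))
                p_vec[vec_idx] = 2 * stats.t.sf(np.abs(t), n - 2)
            else:
                perms = rng.permuted(np.tile(rx, (n_permutations, 1)), axis=1)
                null = np.abs(perms @ R.T)  # (P, genes)
                exceed = (null >= np.abs(rho)[None, :] - _EPS).sum(axis=0)
                p_vec[vec_idx] = (exceed + 1) / (n_permutations + 1)
    for gi, gene in enumerate(genes):
        if not gene_ok[gi] and not degenerate:
            # pairwise-complete fallback for genes with their own missingness
            rho_g, p_g, n_g = spearman_test(mv, E[gi][site_mask], rng, n_permutations)
        else:
            rho_g, p_g, n_g = rho_vec[gi], p_vec[gi], n
        out.append(
            {
                "trait_a": site_id,
                "trait_b": gene,
                "state": state,
                "rho": rho_g,
                "p_value": p_g,
                "n": n_g,
                "bonferroni_significant": bool(p_g < thresh) if p_g == p_g else False,
            }
        )
    return out


def methylation_vs_cleavage(
    methylation: pd.DataFrame,
    cleavage: pd.DataFrame,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
    min_individuals: int = 20,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pooled normal+tumor Spearman of methylation vs cleavage and control.

    ``methylation``: sample_id, site_id, level (long); ``cleavage``:
    sample_id, site_id, cleavage_rate, control_rate. Tests run per site x
    cancer on pooled samples, once against the cleavage rate and once
    against the upstream control; the cohort gate requires at least
    ``min_individuals`` complete samples. Bonferroni per metric over
    attempted comparisons.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    sample_cancer = {}
    for p in pairs.itertuples():
        sample_cancer[p.normal_sample_id] = p.cancer_type
        sample_cancer[p.tumor_sample_id] = p.cancer_type
    merged = methylation.merge(cleavage, on=["sample_id", "site_id"])
    merged["cancer_type"] = merged["sample_id"].map(sample_cancer)
    merged = merged.dropna(subset=["cancer_type"])
    rows = []
    for (site_id, cancer), grp in merged.groupby(["site_id", "cancer_type"]):
        for metric in ("cleavage_rate", "control_rate"):
            sub = grp[["level", metric]].dropna()
            if len(sub) < min_individuals:
                continue
            rho, p, n = spearman_test(
                sub["level"].to_numpy(), sub[metric].to_numpy(), rng
            )
            rows.append(
                {
                    "site_id": site_id,
                    "cancer_type": cancer,
                    "metric": metric,
                    "rho": rho,
                    "p_value": p,
                    "n": n,
                }
            )
    out = pd.DataFrame(
        rows, columns=["site_id", "cancer_type", "metric", "rho", "p_value", "n"]
    )
    out["bonferroni_significant"] = False
    for metric in ("cleavage_rate", "control_rate"):
        mask = out["metric"] == metric
        m = int(mask.sum())
        if m:
            out.loc[mask, "bonferroni_significant"] = (
                out.loc[mask, "p_value"] < alpha / m
            ).fillna(False)
    return out


def fisher_enrichment(
    focus_genes: set, gene_set: set, reference_size: int
) -> tuple[float, float]:
    """Right-tailed Fisher exact (hypergeometric upper tail) enrichment.

    Probability of observing at least the seen overlap between the focus
    genes and the gene set when drawing |focus| genes from a reference of
    ``reference_size``. fold = (k/|focus|) / (|set|/reference).
    """
    focus_genes = set(focus_genes)
    gene_set = set(gene_set)
    if not focus_genes or not gene_set:
        raise ValueError("focus genes and gene set must be non-empty")
    if reference_size < len(focus_genes) or reference_size < len(gene_set):
        raise ValueError("reference smaller than focus or gene set")
    k = len(focus_genes & gene_set)
    p = float(
        stats.hypergeom.sf(k - 1, reference_size, len(gene_set), len(focus_genes))
    )
    fold = (k / len(focus_genes)) / (len(gene_set) / reference_size)
    return p, fold
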