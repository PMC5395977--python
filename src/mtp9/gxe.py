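"""Genotype-by-disease-state interaction testing on p9 methylation.

Genotype calls below the quality floor are set missing first; SNPs are
then screened for Hardy-Weinberg equilibrium (exact test, pre-recode
calls), recoded to a dominant carrier indicator, and gated on MAF,
complete individuals and carrier count. The interaction statistic
compares per-state OLS slopes: z = (bT - bN) / sqrt(seT^2 + seN^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1  # sentinel for missing genotype calls in integer arrays


@dataclass
class GxEParams:
    min_quality: float = 0.1
    hwe_p: float = 0.001
    min_maf: float = 0.05
    min_n: int = 40
    min_carriers: int = 5
    alpha: float = 0.05


@dataclass
class GxEResult:
    snp_id: str
    site_id: str
    cancer_type: str | None
    n: int
    beta_normal: float
    se_normal: float
    beta_tumor: float
    se_tumor: float
    z_interaction: float
    p_interaction: float


def apply_quality_filter(
    calls: np.ndarray, qualities: np.ndarray, min_quality: float = 0.1
) -> np.ndarray:
    """Set calls with quality below the floor to missing."""
    out = np.asarray(calls, dtype=float).copy()
    out[np.asarray(qualities, dtype=float) < min_quality] = np.nan
    return out


def hwe_exact_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of configurations no more
    probable than the observed heterozygote count, conditional on allele
    counts)."""
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("all genotype calls missing")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    rare = min(n_minor, n_major)
    # log-probability of each possible het count with the same parity as rare
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.empty(hets.size)
    lg = math.lgamma
    for i, h in enumerate(hets):
        a = (rare - h) // 2  # rare-allele homozygotes
        b = (2 * n - rare - h) // 2  # common homozygotes
        logp[i] = (
            lg(n + 1)
            - lg(a + 1)
            - lg(h + 1)
            - lg(b + 1)
            + h * math.log(2)
            + lg(rare + 1)
            + lg(2 * n - rare + 1)
            - lg(2 * n + 1)
        )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, probs[probs <= obs[0] + 1e-12].sum()))


def hwe_filter(
    n_hom_major: int, n_het: int, n_hom_minor: int, p_threshold: float = 0.001
) -> tuple[bool, float]:
    """Keep iff exact HWE p exceeds the threshold."""
    p = hwe_exact_p(n_hom_major, n_het, n_hom_minor)
    return p > p_threshold, p


def dominant_recode(calls: np.ndarray) -> np.ndarray:
    """Minor-allele homozygotes pooled with heterozygotes (0/1/2 -> 0/1/1)."""
    arr = np.asarray(calls, dtype=float)
    valid = ~np.isnan(arr)
    if valid.any() and not np.isin(arr[valid], (0, 1, 2)).all():
        raise ValueError("calls must be in {0, 1, 2} or missing")
    out = arr.copy()
    out[valid] = np.minimum(arr[valid], 1)
    return out


def minor_allele_frequency(calls: np.ndarray) -> float:
    """MAF from pre-recode calls (copies of minor allele / 2n)."""
    arr = np.asarray(calls, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return np.nan
    return float(arr.sum() / (2 * arr.size))


def snp_eligibility(
    carriers: np.ndarray,
    trait_available: np.ndarray,
    maf: float,
    params: GxEParams | None = None,
) -> tuple[bool, str | None]:
    """Gate one SNP: MAF, complete individuals and carrier count.

    ``carriers`` is the dominant-recoded vector; an individual is
    complete when its call is non-missing and ``trait_available`` is
    true.
    """
    if params is None:
        params = GxEParams()
    complete = (~np.isnan(np.asarray(carriers, dtype=float))) & np.asarray(
        trait_available, dtype=bool
    )
    if maf != maf or maf < params.min_maf:
        return False, "maf"
    if complete.sum() < params.min_n:
        return False, "min_n"
    n_carriers = np.nansum(np.asarray(carriers, dtype=float)[complete])
    if n_carriers < params.min_carriers:
        return False, "carriers"
    return True, None


def _ols_slope(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Slope and its standard error from simple OLS of y on x."""
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations per state")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("zero genotype variance within state")
    beta = float(xc @ y) / sxx
    resid = y - y.mean() - beta * xc
    sigma2 = float(resid @ resid) / (n - 2)
    return beta, math.sqrt(sigma2 / sxx)


def interaction_z(
    beta_normal: float, se_normal: float, beta_tumor: float, se_tumor: float
) -> tuple[float, float]:
    """Interaction z and two-sided p from per-state slopes and SEs."""
    z = (beta_tumor - beta_normal) / math.sqrt(se_tumor**2 + se_normal**2)
    return z, float(2 * stats.norm.sf(abs(z)))


def gxe_test(
    trait_normal: np.ndarray,
    trait_tumor: np.ndarray,
    carriers: np.ndarray,
    snp_id: str = "snp",
    site_id: str = "site",
    cancer_type: str | None = None,
) -> GxEResult:
    """Compare per-state regression slopes of methylation on carrier status.

    Each individual contributes one trait value per state; individuals
    with a missing call or trait are excluded pairwise.
    """
    tn = np.asarray(trait_normal, dtype=float)
    tt = np.asarray(trait_tumor, dtype=float)
    x = np.asarray(carriers, dtype=float)
    mask = ~(np.isnan(tn) | np.isnan(tt) | np.isnan(x))
    tn, tt, x = tn[mask], tt[mask], x[mask]
    beta_n, se_n = _ols_slope(tn, x)
    beta_t, se_t = _ols_slope(tt, x)
    z, p = interaction_z(beta_n, se_n, beta_t, se_t)
    return GxEResult(
        snp_id, site_id, cancer_type, int(mask.sum()), beta_n, se_n, beta_t, se_t, z, p
    )


def prepare_genotypes(
    calls: pd.DataFrame, qualities: pd.DataFrame, params: GxEParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quality-mask and HWE-screen a SNPs x individuals call matrix.

    Returns (recoded carrier matrix restricted to kept SNPs, per-SNP QC
    table with maf/hwe_p/kept). Order of quality, HWE and MAF filtering
    does not matter because all operate on quality-masked calls.
    """
    if params is None:
        params = GxEParams()
    masked = calls.astype(float).where(qualities >= params.min_quality)
    qc_rows = []
    kept_rows = {}
    for snp_id, row in masked.iterrows():
        arr = row.to_numpy(float)
        valid = arr[~np.isnan(arr)]
        if valid.size == 0:
            qc_rows.append({"snp_id": snp_id, "maf": np.nan, "hwe_p": np.nan, "kept": False, "reason": "all_missing"})
            continue
        counts = [(valid == g).sum() for g in (0, 1, 2)]
        keep, hwe_p = hwe_filter(counts[0], counts[1], counts[2], params.hwe_p)
        maf = minor_allele_frequency(arr)
        reason = None if keep else "hwe"
        qc_rows.append({"snp_id": snp_id, "maf": maf, "hwe_p": hwe_p, "kept": keep, "reason": reason})
        if keep:
            kept_rows[snp_id] = dominant_recode(arr)
    carriers = pd.DataFrame.from_dict(kept_rows, orient="index", columns=calls.columns)
    qc = pd.DataFrame(qc_rows, columns=["snp_id", "maf", "hwe_p", "kept", "reason"])
    return carriers, qc


def gxe_scan(
    carriers: pd.DataFrame,
    snp_maf: pd.Series,
    trait_normal: pd.DataFrame,
    trait_tumor: pd.DataFrame,
    cancer_type: str | None = None,
    params: GxEParams | None = None,
) -> pd.DataFrame:
    """All eligible SNP x site interaction tests within one cancer.

    ``carriers``: SNPs x individuals (0/1/NaN); ``trait_*``: sites x
    individuals methylation levels (NaN when unavailable). Sorted by p.
    """
    if params is None:
        params = GxEParams()
    rows = []
    for site_id in trait_normal.index:
        tn = trait_normal.loc[site_id].reindex(carriers.columns).to_numpy(float)
        tt = trait_tumor.loc[site_id].reindex(carriers.columns).to_numpy(float)
        avail = ~(np.isnan(tn) | np.isnan(tt))
        for snp_id, row in carriers.iterrows():
            x = row.to_numpy(float)
            ok, reason = snp_eligibility(x, avail, float(snp_maf.get(snp_id, np.nan)), params)
            if not ok:
                continue
            try:
                res = gxe_test(tn, tt, x, snp_id, site_id, cancer_type)
            except ValueError:
                continue
            rows.append(res.__dict__)
    out = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "site_id", "cancer_type", "n",
            "beta_normal", "se_normal", "beta_tumor", "se_tumor",
            "z_interaction", "p_interaction",
        ],
    )
    return out.sort_values("p_interaction", kind="stable").reset_index(drop=True)


def genome_wide_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def replicate(
    hits: pd.DataFrame,
    scans_by_cancer: dict[str, pd.DataFrame],
    alpha_rep: float = 0.001,
) -> pd.DataFrame:
    """Look up each discovery SNP in every other cancer at any site.

    ``scans_by_cancer`` maps cancer -> full gxe_scan table under the same
    eligibility criteria. Flags p < alpha_rep.
    """
    rows = []
    for hit in hits.itertuples():
        for cancer, scan in scans_by_cancer.items():
            if cancer == hit.cancer_type:
                continue
            sub = scan[scan["snp_id"] == hit.snp_id]
            for r in sub.itertuples():
                rows.append(
                    {
                        "snp_id": hit.snp_id,
                        "discovery_cancer": hit.cancer_type,
                        "discovery_site": hit.site_id,
                        "replication_cancer": cancer,
                        "replication_site": r.site_id,
                        "p_replication": r.p_interaction,
                        "replicated": r.p_interaction < alpha_rep,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "discovery_cancer", "discovery_site",
            "replication_cancer", "replication_site", "p_replication", "replicated",
        ],
    )


def loo_fragility(
    trait_normal: np.ndarray,
    trait_tumor: np.ndarray,
    carriers: np.ndarray,
) -> bool:
    """Automated stand-in for visual outlier inspection of a hit.

    A hit is fragile when removing any single individual more than halves
    its -log10 interaction p.
    """
    full = gxe_test(trait_normal, trait_tumor, carriers)
    base = -math.log10(max(full.p_interaction, 1e-300))
    n = len(carriers)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            res = gxe_test(
                np.asarray(trait_normal, float)[keep],
                np.asarray(trait_tumor, float)[keep],
                np.asarray(carriers, float)[keep],
            )
        except ValueError:
            return True
        if -math.log10(max(res.p_interaction, 1e-300)) < base / 2:
            return True
    return False
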