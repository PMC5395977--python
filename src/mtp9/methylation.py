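"""p9 methylation levels from allele counts.

The methylation level of a site in a sample is the proportion of
non-reference bases among quality-filtered reads, defined only when
depth reaches the coverage floor (default 20x; lower-coverage records
propagate as missing and drop the pair from that site's comparison).
All three alternative bases are pooled.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mtp9.sites import TrnaSite, site_index

DEFAULT_MIN_COVERAGE = 20

_COUNT_COLS = {"A": "count_A", "C": "count_C", "G": "count_G", "T": "count_T"}


def methylation_level(
    record: Mapping, site: TrnaSite, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> dict | None:
    """Non-reference proportion for one allele-count record.

    Returns ``{"sample_id", "site_id", "level", "depth"}`` or ``None``
    when depth is below ``min_coverage`` (excluded, not zero).
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if site.ref_allele not in _COUNT_COLS:
        raise ValueError(f"ref_allele {site.ref_allele!r} not in A/C/G/T")
    depth = int(record["depth"])
    if depth < min_coverage:
        return None
    ref = int(record[_COUNT_COLS[site.ref_allele]])
    return {
        "sample_id": record["sample_id"],
        "site_id": site.site_id,
        "level": (depth - ref) / depth,
        "depth": depth,
    }


def methylation_table(
    counts: pd.DataFrame,
    sites: Sequence[TrnaSite],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Vector of methylation levels for a long allele-count table."""
    idx = site_index(sites)
    rows = []
    for rec in counts.to_dict("records"):
        site = idx.get(rec["site_id"])
        if site is None:
            continue
        out = methylation_level(rec, site, min_coverage=min_coverage)
        if out is not None:
            rows.append(out)
    return pd.DataFrame(rows, columns=["sample_id", "site_id", "level", "depth"])


def resample_matched(
    counts_normal: Mapping, counts_tumor: Mapping, rng: np.random.Generator
) -> tuple[dict, dict]:
    """Downsample the deeper member of a pair to the shallower depth.

    Base composition is drawn hypergeometrically (reads subsampled
    without replacement); the shallower record is returned unchanged.
    """
    dn = int(counts_normal["depth"])
    dt = int(counts_tumor["depth"])
    if dn <= 0 or dt <= 0:
        raise ValueError("cannot resample a record with zero depth")
    target = min(dn, dt)

    def _down(rec: Mapping, depth: int) -> dict:
        out = dict(rec)
        if depth == target:
            return out
        colors = [int(rec[c]) for c in ("count_A", "count_C", "count_G", "count_T")]
        draw = rng.multivariate_hypergeometric(colors, target)
        out.update(
            count_A=int(draw[0]),
            count_C=int(draw[1]),
            count_G=int(draw[2]),
            count_T=int(draw[3]),
            depth=target,
        )
        return out

    return _down(counts_normal, dn), _down(counts_tumor, dt)


def resample_pairs(
    counts: pd.DataFrame, pairs: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Coverage-match every (patient, site) pair in a long count table."""
    rng = np.random.default_rng(seed)
    keyed = {(r["sample_id"], r["site_id"]): r for r in counts.to_dict("records")}
    out = []
    for pair in pairs.itertuples():
        for site_id in sorted({k[1] for k in keyed}):
            rn = keyed.get((pair.normal_sample_id, site_id))
            rt = keyed.get((pair.tumor_sample_id, site_id))
            if rn is None or rt is None:
                continue
            if rn["depth"] <= 0 or rt["depth"] <= 0:
                continue
            rn2, rt2 = resample_matched(rn, rt, rng)
            out.extend([rn2, rt2])
    return pd.DataFrame(out, columns=counts.columns)


def standardize(levels: pd.DataFrame) -> pd.DataFrame:
    """Divide levels by the per-(site, cancer) max over pooled normal+tumor.

    Input needs columns site_id, cancer_type, level; a ``std_level``
    column is added with max exactly 1 in every group. An all-zero group
    has no defined scaling and raises.
    """
    out = levels.copy()
    maxes = out.groupby(["site_id", "cancer_type"])["level"].transform("max")
    if (maxes <= 0).any():
        bad = out.loc[maxes <= 0, ["site_id", "cancer_type"]].drop_duplicates()
        raise ValueError(
            "all-zero methylation in group(s): "
            + ", ".join(f"{r.site_id}/{r.cancer_type}" for r in bad.itertuples())
        )
    out["std_level"] = out["level"] / maxes
    return out


def delta_methylation(levels: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Tumor minus normal level per (patient, site); incomplete pairs drop."""
    keyed = levels.set_index(["sample_id", "site_id"])["level"]
    rows = []
    for pair in pairs.itertuples():
        for site_id in levels["site_id"].unique():
            try:
                ln = keyed[(pair.normal_sample_id, site_id)]
                lt = keyed[(pair.tumor_sample_id, site_id)]
            except KeyError:
                continue
            rows.append(
                {
                    "patient_id": pair.patient_id,
                    "cancer_type": pair.cancer_type,
                    "site_id": site_id,
                    "delta": lt - ln,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "cancer_type", "site_id", "delta"])


def confound_scan(
    deltas: pd.DataFrame, covariates: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman rho of methylation change against candidate confounders.

    ``deltas``: patient_id, cancer_type, site_id, delta.
    ``covariates``: patient_id plus one column per covariate. One row per
    site x cancer x covariate; constant covariates report NA. Bonferroni
    is over the full family of computed comparisons.
    """
    cov_cols = [c for c in covariates.columns if c != "patient_id"]
    merged = deltas.merge(covariates, on="patient_id")
    rows = []
    for (site_id, cancer), grp in merged.groupby(["site_id", "cancer_type"]):
        for cov in cov_cols:
            sub = grp[["delta", cov]].dropna()
            if len(sub) < 3:
                continue
            x = sub["delta"].to_numpy(float)
            y = sub[cov].to_numpy(float)
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x, y)
            rows.append(
                {
                    "site_id": site_id,
                    "cancer_type": cancer,
                    "covariate": cov,
                    "n": len(sub),
                    "rho": rho,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(
        rows, columns=["site_id", "cancer_type", "covariate", "n", "rho", "p_value"]
    )
    m = len(out)
    out["bonferroni_significant"] = out["p_value"] < (alpha / m if m else np.nan)
    return out
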