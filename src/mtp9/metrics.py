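"""Cleavage rates, tRNA expression, mitochondria-normalised TPM and QC.

Cleavage is measured at the tRNA 5' boundary: the position 9 bases
upstream of the p9 site in tRNA orientation. The rate is the fraction of
boundary-adjacent read termini (ends at the upstream base, starts at the
base immediately 3' of it) among reads crossing either side of the
boundary; the control repeats the computation 9 bases further upstream.
All "upstream" arithmetic honours the site's strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from mtp9.sites import TrnaSite

DEFAULT_PSEUDOCOUNT = 1.0


def _boundary_rate(termini: pd.DataFrame, upstream_pos: int, strand: str) -> float | None:
    """Terminus fraction at a boundary in tRNA orientation.

    For a heavy-strand tRNA the boundary sits between genomic positions
    ``upstream_pos`` and ``upstream_pos + 1``; a 5' terminus is a read
    ending at ``upstream_pos`` or starting at ``upstream_pos + 1``. The
    light strand mirrors both roles. The denominator counts reads
    covering either flank so the rate stays within [0, 1].
    """
    step = 1 if strand == "+" else -1
    t = termini.set_index("position")

    def row(pos):
        return t.loc[pos] if pos in t.index else None

    a = row(upstream_pos)
    b = row(upstream_pos + step)
    if a is None or b is None:
        return None
    if strand == "+":
        # 5' terminus: read ends at the upstream base or starts just 3' of it
        n_term = int(a["n_end"]) + int(b["n_start"])
    else:
        n_term = int(a["n_start"]) + int(b["n_end"])
    denom = int(a["n_cover"])
    if denom <= 0:
        return None
    # boundary-adjacent starts need not cover the upstream base; clamp
    return min(1.0, n_term / denom)


def cleavage_rate(termini: pd.DataFrame, site: TrnaSite) -> float | None:
    """5' cleavage rate at the boundary 9 bases upstream of the p9 site."""
    return _boundary_rate(termini, site.cleavage_position, site.strand)


def cleavage_control(termini: pd.DataFrame, site: TrnaSite) -> float | None:
    """Control rate a further 9 bases upstream of the cleavage boundary."""
    return _boundary_rate(termini, site.control_position, site.strand)


def cleavage_table(
    termini: pd.DataFrame, sites: Sequence[TrnaSite]
) -> pd.DataFrame:
    """Cleavage rate + control per sample x site from a long terminus table."""
    rows = []
    for sample_id, grp in termini.groupby("sample_id"):
        for site in sites:
            rows.append(
                {
                    "sample_id": sample_id,
                    "site_id": site.site_id,
                    "cleavage_rate": cleavage_rate(grp, site),
                    "control_rate": cleavage_control(grp, site),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "site_id", "cleavage_rate", "control_rate"])


def trna_expression(
    coverage: Sequence[float], mito_total_reads: float
) -> float:
    """Mean per-position coverage over a tRNA span, scaled by mito library size."""
    cov = np.asarray(coverage, dtype=float)
    if cov.size == 0:
        raise ValueError("empty tRNA span")
    if mito_total_reads <= 0:
        raise ValueError("mito_total_reads must be positive")
    return float(np.mean(cov / mito_total_reads))


@dataclass
class GeneModel:
    gene_id: str
    length: int
    compartment: str  # 'mito' | 'nuclear'

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"gene {self.gene_id}: length must be > 0")
        if self.compartment not in ("mito", "nuclear"):
            raise ValueError(f"gene {self.gene_id}: compartment must be mito|nuclear")


def gene_models_from_frame(df: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(gene_id=str(r.gene_id), length=int(r.length), compartment=str(r.compartment))
        for r in df.itertuples()
    ]


def tpm(
    counts: pd.DataFrame, genes: Sequence[GeneModel], classic: bool = False
) -> pd.DataFrame:
    """Transcripts-per-million with compartment-specific library sizes.

    Mitochondrial genes are normalised by the total fragments mapping to
    mitochondrial genes; nuclear genes by the total library, which keeps
    mito expression independent of nuclear depth. ``classic=True`` instead
    rescales length-normalised rates to sum to 1e6 within each
    compartment.
    """
    order = [g.gene_id for g in genes]
    missing = set(order) - set(counts.index)
    if missing:
        raise ValueError(f"counts missing genes: {sorted(missing)[:5]}")
    counts = counts.loc[order].astype(float)
    lengths = pd.Series({g.gene_id: g.length for g in genes}, dtype=float)
    is_mito = pd.Series({g.gene_id: g.compartment == "mito" for g in genes})

    rate = counts.div(lengths, axis=0)
    out = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for mito in (True, False):
        mask = is_mito == mito
        if not mask.any():
            continue
        if classic:
            denom = rate.loc[mask].sum(axis=0)
        elif mito:
            denom = counts.loc[mask].sum(axis=0)
        else:
            denom = counts.sum(axis=0)
        if (denom <= 0).any():
            bad = denom.index[denom <= 0].tolist()
            raise ValueError(f"zero library size for samples: {bad[:5]}")
        out.loc[mask] = rate.loc[mask].div(denom, axis=1) * 1e6
    return out


def log_median_normalize(
    matrix: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """log10(value + pseudocount), then per-sample median subtraction.

    Post-condition: every sample (column) has median exactly 0. The
    median step is idempotent.
    """
    if (matrix.to_numpy(float) < 0).any():
        raise ValueError("negative values in expression matrix")
    logged = np.log10(matrix.astype(float) + pseudocount)
    return logged.sub(logged.median(axis=0), axis=1)


def pca_outlier_filter(
    matrix: pd.DataFrame,
    pairs: pd.DataFrame,
    n_components: int = 3,
    sd_threshold: float = 3.0,
) -> tuple[list[str], pd.DataFrame]:
    """Drop samples beyond the SD threshold on any leading PC, plus pair-mates.

    ``matrix`` is genes x samples (columns = sample ids); PCA runs on
    centered, unscaled values. Returns (retained sample ids, report of
    removals with reasons).
    """
    samples = list(matrix.columns)
    if len(samples) <= n_components:
        raise ValueError(
            f"need more than {n_components} samples for {n_components}-component PCA"
        )
    X = matrix.T.to_numpy(float)
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(
        X - X.mean(axis=0)
    )
    sds = scores.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    z = scores / sds

    flagged: dict[str, str] = {}
    for i, sample in enumerate(samples):
        for pc in range(n_components):
            if abs(z[i, pc]) > sd_threshold:
                flagged[sample] = f"PC{pc + 1} score {z[i, pc]:.2f} SD"
                break

    mate = {}
    for pair in pairs.itertuples():
        mate[pair.normal_sample_id] = pair.tumor_sample_id
        mate[pair.tumor_sample_id] = pair.normal_sample_id

    removed: dict[str, str] = dict(flagged)
    for sample in list(flagged):
        m = mate.get(sample)
        if m is not None and m not in removed:
            removed[m] = f"paired with outlier {sample}"

    retained = [s for s in samples if s not in removed]
    report = pd.DataFrame(
        [{"sample_id": s, "reason": r} for s, r in sorted(removed.items())],
        columns=["sample_id", "reason"],
    )
    return retained, report
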