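"""Synthetic cohort generator with known ground truth.

Produces every input the pipeline consumes: per-sample SAM alignments
whose p9-site mismatch fractions follow planted methylation rates,
genotypes in Hardy-Weinberg equilibrium with tumor-only planted effects,
expression counts coupled to methylation in normal samples only, and
survival times whose hazard scales with the tumor-normal methylation
change.

One global seed is expanded into independent per-stream substreams
(theta, genotypes, reads, expression, survival, clinical) so adding one
stream never perturbs another; identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from mtp9.sites import MITO_CONTIG, MITO_LENGTH, TrnaSite, default_sites, mito_reference
from mtp9.tsv import write_tsv

_BASES = ("A", "C", "G", "T")
_STREAMS = ("theta", "genotypes", "reads", "expression", "survival", "clinical")


@dataclass
class PlantedGxE:
    """A SNP whose carriers get a tumor-only methylation shift."""

    snp_id: str
    site_id: str
    beta_tumor: float
    cancers: tuple[str, ...] | None = None  # None = all cancers


@dataclass
class SimulationConfig:
    n_patients: int = 40
    cancer_labels: tuple[str, ...] = ("CAN_A", "CAN_B")
    sites: Sequence[TrnaSite] = field(default_factory=default_sites)
    theta_normal: Mapping[str, float] | None = None  # default ramp over sites
    delta_tumor: Mapping[str, float] | None = None
    patient_sd: float = 0.05
    seq_error: float = 0.001
    coverage_mean: float = 600.0
    coverage_dispersion: float = 5.0
    read_length: int = 50
    cleavage_base_rate: float = 0.02
    cleavage_coupling: float = 0.3
    decoy_fraction: float = 0.05  # per decoy class
    n_snps: int = 50
    maf_range: tuple[float, float] = (0.1, 0.4)
    planted_gxe: tuple[PlantedGxE, ...] = ()
    genotype_low_quality_fraction: float = 0.02
    n_genes: int = 120
    n_mito_genes: int = 15
    expr_coupling: Mapping[str, float] | None = None  # gene_id -> rho (normal state)
    expr_site: str = "p9_10413"
    survival_gamma: float = math.log(2)
    baseline_hazard: float = math.log(2) / 24.0  # median ~24 months at delta 0
    censor_months: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sites = list(self.sites)
        ids = [s.site_id for s in self.sites]
        if self.theta_normal is None:
            # ramp of baseline rates across sites, away from 0 and 1
            self.theta_normal = {
                sid: 0.08 + 0.5 * i / max(len(ids) - 1, 1) for i, sid in enumerate(ids)
            }
        if self.delta_tumor is None:
            self.delta_tumor = {sid: 0.10 for sid in ids}
        for sid in ids:
            th = self.theta_normal[sid]
            dt = self.delta_tumor[sid]
            if not 0 <= th <= 1:
                raise ValueError(f"theta_normal[{sid}] outside [0,1]")
            if not 0 <= th + dt <= 1:
                raise ValueError(f"theta_normal + delta_tumor outside [0,1] at {sid}")
        for name, rate in (
            ("seq_error", self.seq_error),
            ("cleavage_base_rate", self.cleavage_base_rate),
            ("decoy_fraction", self.decoy_fraction),
            ("genotype_low_quality_fraction", self.genotype_low_quality_fraction),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.censor_months <= 0:
            raise ValueError("censoring horizon must be positive")
        if self.expr_coupling is None:
            # first 10 nuclear genes track methylation in the normal state
            n_coupled = min(10, self.n_genes - self.n_mito_genes)
            self.expr_coupling = {
                f"gene_{self.n_mito_genes + i:04d}": 0.8 for i in range(n_coupled)
            }

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}

    def site_by_id(self) -> dict[str, TrnaSite]:
        return {s.site_id: s for s in self.sites}


# ---------------------------------------------------------------------------
# cohort truth


def build_manifest(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    per_cancer = config.n_patients // len(config.cancer_labels)
    extra = config.n_patients - per_cancer * len(config.cancer_labels)
    k = 0
    for ci, cancer in enumerate(config.cancer_labels):
        n_here = per_cancer + (1 if ci < extra else 0)
        for _ in range(n_here):
            pid = f"PT{k:04d}"
            rows.append(
                {
                    "patient_id": pid,
                    "cancer_type": cancer,
                    "normal_sample_id": f"{pid}_N",
                    "tumor_sample_id": f"{pid}_T",
                }
            )
            k += 1
    return pd.DataFrame(rows)


def simulate_genotypes(
    config: SimulationConfig, manifest: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """HWE genotypes with per-call qualities.

    Returns (calls SNPs x patients, qualities SNPs x patients, snp meta
    with simulated MAF). Planted-effect SNPs are included with ids from
    ``planted_gxe``; effect application happens in ``build_truth``.
    """
    patients = manifest["patient_id"].tolist()
    lo, hi = config.maf_range
    snp_ids = [f"snp_{i:04d}" for i in range(config.n_snps)]
    planted_ids = [p.snp_id for p in config.planted_gxe]
    for pid in planted_ids:
        if pid not in snp_ids:
            raise ValueError(f"planted SNP {pid} not among simulated SNPs")
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    if (mafs <= 0).any() or (mafs > 0.5).any():
        raise ValueError("MAF outside (0, 0.5]")
    calls = np.empty((config.n_snps, len(patients)), dtype=int)
    for i, q in enumerate(mafs):
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        calls[i] = rng.choice(3, size=len(patients), p=probs)
    quals = rng.uniform(0.3, 1.0, size=calls.shape)
    low = rng.random(calls.shape) < config.genotype_low_quality_fraction
    quals[low] = rng.uniform(0.0, 0.1, size=int(low.sum()))
    meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": "1",
            "position": np.arange(1, config.n_snps + 1) * 1000,
            "maf_true": mafs,
        }
    )
    calls_df = pd.DataFrame(calls, index=snp_ids, columns=patients)
    quals_df = pd.DataFrame(quals, index=snp_ids, columns=patients)
    return calls_df, quals_df, meta


def build_truth(config: SimulationConfig) -> dict:
    """Ground-truth methylation rates per sample x site, plus genotypes.

    theta_normal varies across patients (clipped Gaussian around the
    site baseline); tumor theta adds the site shift and any planted
    carrier effects (dominant: one or two minor alleles shift equally,
    tumor state only, optionally restricted to specific cancers).
    """
    streams = config.streams()
    manifest = build_manifest(config)
    calls, quals, snp_meta = simulate_genotypes(config, manifest, streams["genotypes"])

    rng = streams["theta"]
    rows = []
    planted = list(config.planted_gxe)
    for pt in manifest.itertuples():
        for site in config.sites:
            base = config.theta_normal[site.site_id]
            th_n = float(np.clip(rng.normal(base, config.patient_sd), 0.003, 0.95))
            shift = config.delta_tumor[site.site_id]
            for eff in planted:
                if eff.site_id != site.site_id:
                    continue
                if eff.cancers is not None and pt.cancer_type not in eff.cancers:
                    continue
                if calls.loc[eff.snp_id, pt.patient_id] >= 1:
                    shift += eff.beta_tumor
            th_t = float(np.clip(th_n + shift, 0.003, 0.997))
            rows.append(
                {
                    "patient_id": pt.patient_id,
                    "cancer_type": pt.cancer_type,
                    "site_id": site.site_id,
                    "theta_normal": th_n,
                    "theta_tumor": th_t,
                }
            )
    theta = pd.DataFrame(rows)
    return {
        "manifest": manifest,
        "theta": theta,
        "calls": calls,
        "qualities": quals,
        "snp_meta": snp_meta,
        "streams": streams,
    }


# ---------------------------------------------------------------------------
# reads


@dataclass
class SimRead:
    qname: str
    flag: int
    pos: int  # 1-based leftmost aligned position
    mapq: int
    seq: str
    qual: str  # phred+33

    @property
    def end(self) -> int:
        return self.pos + len(self.seq) - 1


_FLAG_PROPER = 99  # paired, proper pair, mate reverse, first of pair
_FLAG_IMPROPER = 97  # paired but proper-pair bit unset


def _read_sequence(
    ref: str, start: int, length: int, site_pos0: int | None, nonref: bool,
    seq_error: float, rng: np.random.Generator,
) -> str:
    seq = list(ref[start : start + length])
    if seq_error > 0:
        errs = np.nonzero(rng.random(length) < seq_error)[0]
        for i in errs:
            alts = [b for b in _BASES if b != seq[i]]
            seq[i] = alts[rng.integers(3)]
    if site_pos0 is not None:
        offset = site_pos0 - start
        if 0 <= offset < length:
            refb = ref[site_pos0]
            if nonref:
                alts = [b for b in _BASES if b != refb]
                seq[offset] = alts[rng.integers(3)]
            else:
                seq[offset] = refb
    return "".join(seq)


def simulate_sample_reads(
    config: SimulationConfig,
    sample_id: str,
    thetas: Mapping[str, float],
    rng: np.random.Generator,
) -> list[SimRead]:
    """All reads for one sample, across the configured p9 sites.

    Per site: depth ~ NegBin(coverage_mean, dispersion); each read shows
    a non-reference base at the site with probability theta + (1-theta) *
    seq_error; a fraction min(1, base + coupling*theta) of reads starts at
    the base just 3' of the 5' cleavage boundary (in tRNA orientation)
    and a matching set of upstream reads ends at the boundary. Decoy
    reads violating each ingest filter are appended, every one carrying a
    non-reference base so that a filtering failure shows up in counts.
    """
    ref = mito_reference()
    L = config.read_length
    reads: list[SimRead] = []
    hi_q = chr(33 + 40) * L
    lo_q = chr(33 + 2) * L
    serial = 0

    for site in config.sites:
        theta = float(thetas[site.site_id])
        if not 0 <= theta <= 1:
            raise ValueError(f"theta outside [0,1] at {site.site_id}")
        p_mm = theta + (1 - theta) * config.seq_error
        depth = int(rng.negative_binomial(
            config.coverage_dispersion,
            config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean),
        ))
        f_cleave = min(1.0, config.cleavage_base_rate + config.cleavage_coupling * theta)
        pos0 = site.position - 1
        c = site.cleavage_position  # genomic, 1-based

        for _ in range(depth):
            serial += 1
            cleaved = rng.random() < f_cleave
            if site.strand == "+":
                start1 = c + 1 if cleaved else int(rng.integers(site.position - L + 1, site.position + 1))
            else:
                end1 = c - 1 if cleaved else int(rng.integers(site.position, site.position + L))
                start1 = end1 - L + 1
            start1 = max(1, min(start1, MITO_LENGTH - L + 1))
            nonref = rng.random() < p_mm
            seq = _read_sequence(ref, start1 - 1, L, pos0, nonref, config.seq_error, rng)
            reads.append(SimRead(f"{sample_id}:{site.site_id}:{serial}", _FLAG_PROPER, start1, 60, seq, hi_q))
            if cleaved:
                # companion fragment upstream of the boundary, ending at c
                serial += 1
                if site.strand == "+":
                    up_start = max(1, c - L + 1)
                else:
                    up_start = min(c, MITO_LENGTH - L + 1)
                useq = _read_sequence(ref, up_start - 1, L, None, False, config.seq_error, rng)
                reads.append(SimRead(f"{sample_id}:{site.site_id}:{serial}u", _FLAG_PROPER, up_start, 60, useq, hi_q))

        # decoys: always non-reference at the site; must be rejected downstream
        n_decoy = int(round(config.decoy_fraction * depth))
        for cls in ("pair", "mapq", "baseq"):
            for _ in range(n_decoy):
                serial += 1
                start1 = int(rng.integers(max(1, site.position - L + 1), site.position + 1))
                seq = _read_sequence(ref, start1 - 1, L, pos0, True, config.seq_error, rng)
                flag, mapq, qual = _FLAG_PROPER, 60, hi_q
                if cls == "pair":
                    flag = _FLAG_IMPROPER
                elif cls == "mapq":
                    mapq = 5
                else:
                    qual = lo_q
                reads.append(SimRead(f"{sample_id}:{site.site_id}:{serial}d{cls}", flag, start1, mapq, seq, qual))
    return reads


def simulate_reads(
    config: SimulationConfig,
    sample_id: str,
    state: str,
    truth: dict | None = None,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Reads for one manifest sample in the given state.

    With cohort ``truth`` the per-patient planted rates are used;
    otherwise the config's population rates.
    """
    if state not in ("normal", "tumor"):
        raise ValueError(f"invalid state {state!r}; expected 'normal' or 'tumor'")
    if rng is None:
        rng = config.streams()["reads"]
    if truth is not None:
        manifest = truth["manifest"]
        col = f"{state}_sample_id"
        row = manifest[manifest[col] == sample_id]
        if row.empty:
            raise ValueError(f"sample {sample_id} not in manifest for state {state}")
        pid = row.iloc[0]["patient_id"]
        th = truth["theta"][truth["theta"]["patient_id"] == pid]
        key = "theta_normal" if state == "normal" else "theta_tumor"
        thetas = dict(zip(th["site_id"], th[key]))
    else:
        thetas = {
            s.site_id: config.theta_normal[s.site_id]
            + (config.delta_tumor[s.site_id] if state == "tumor" else 0.0)
            for s in config.sites
        }
    return simulate_sample_reads(config, sample_id, thetas, rng)


def sam_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": MITO_CONTIG, "LN": MITO_LENGTH}],
        }
    )


def reads_to_segments(reads: Sequence[SimRead], header: pysam.AlignmentHeader) -> list:
    segments = []
    for r in reads:
        a = pysam.AlignedSegment(header)
        a.query_name = r.qname
        a.flag = r.flag
        a.reference_id = 0
        a.reference_start = r.pos - 1
        a.mapping_quality = r.mapq
        a.cigarstring = f"{len(r.seq)}M"
        a.query_sequence = r.seq
        a.query_qualities = pysam.qualitystring_to_array(r.qual)
        a.next_reference_id = 0
        a.next_reference_start = min(r.pos - 1 + 200, MITO_LENGTH - 1)
        a.template_length = 250
        segments.append(a)
    return segments


def write_sam(reads: Sequence[SimRead], path) -> None:
    header = sam_header()
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for seg in reads_to_segments(reads, header):
            out.write(seg)


# ---------------------------------------------------------------------------
# expression / survival / clinical


def simulate_expression(
    config: SimulationConfig, truth: dict, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts matrix (genes x samples) plus gene models.

    Coupled genes follow rho * z(methylation) + sqrt(1-rho^2) * noise in
    normal samples; the coupling is forced to zero in tumor samples.
    Counts are Poisson around a log-linear mean so TPM and log stages are
    exercised on integer data.
    """
    if rng is None:
        rng = truth["streams"]["expression"]
    manifest = truth["manifest"]
    theta = truth["theta"].set_index(["patient_id", "site_id"])
    gene_ids = [f"gene_{i:04d}" for i in range(config.n_genes)]
    lengths = rng.integers(500, 3000, size=config.n_genes)
    compartment = ["mito"] * config.n_mito_genes + ["nuclear"] * (config.n_genes - config.n_mito_genes)
    models = pd.DataFrame({"gene_id": gene_ids, "length": lengths, "compartment": compartment})

    samples, states, drivers = [], [], []
    for pt in manifest.itertuples():
        for state, sid in (("normal", pt.normal_sample_id), ("tumor", pt.tumor_sample_id)):
            samples.append(sid)
            states.append(state)
            key = "theta_normal" if state == "normal" else "theta_tumor"
            drivers.append(theta.loc[(pt.patient_id, config.expr_site), key])
    drivers = np.asarray(drivers, dtype=float)
    z = (drivers - drivers.mean()) / (drivers.std() or 1.0)
    is_normal = np.array([s == "normal" for s in states])

    base_log = rng.uniform(3.0, 6.0, size=config.n_genes)  # natural-log mean scale
    counts = np.empty((config.n_genes, len(samples)), dtype=int)
    for gi, gene in enumerate(gene_ids):
        rho = float(config.expr_coupling.get(gene, 0.0))
        noise = rng.normal(size=len(samples))
        latent = np.where(
            is_normal, rho * z + math.sqrt(max(0.0, 1 - rho**2)) * noise, noise
        )
        mu = np.exp(base_log[gi] + 0.5 * latent)
        counts[gi] = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    return counts_df, models


def simulate_survival(
    config: SimulationConfig,
    delta_per_patient: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential event times, hazard h0 * exp(gamma * delta), censored."""
    if config.censor_months <= 0:
        raise ValueError("censoring horizon must be positive")
    d = delta_per_patient.astype(float)
    lam = config.baseline_hazard * np.exp(config.survival_gamma * d.to_numpy())
    t = rng.exponential(1.0 / lam)
    event = (t <= config.censor_months).astype(int)
    time = np.minimum(t, config.censor_months)
    return pd.DataFrame(
        {
            "patient_id": d.index,
            "time": time,
            "event": event,
            "delta_methylation": d.to_numpy(),
        }
    ).reset_index(drop=True)


def simulate_clinical(
    config: SimulationConfig, truth: dict, site_id: str | None = None
) -> pd.DataFrame:
    """Clinical table: survival (driven by the planted methylation change
    at one site) plus age/sex/ethnicity covariates."""
    if site_id is None:
        site_id = config.expr_site
    theta = truth["theta"]
    sub = theta[theta["site_id"] == site_id]
    delta = pd.Series(
        (sub["theta_tumor"] - sub["theta_normal"]).to_numpy(),
        index=sub["patient_id"].to_numpy(),
    )
    surv = simulate_survival(config, delta, truth["streams"]["survival"])
    rng = truth["streams"]["clinical"]
    surv["age"] = rng.integers(40, 81, size=len(surv))
    surv["sex"] = rng.choice(["F", "M"], size=len(surv))
    surv["ethnicity"] = rng.choice(["E1", "E2", "E3"], size=len(surv))
    return surv.drop(columns=["delta_methylation"])


# ---------------------------------------------------------------------------
# demo cohort on disk


def generate_cohort(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write a complete synthetic cohort as plain-text inputs.

    Emits manifest, site table, per-sample SAM files, genotype TSVs,
    expression counts + gene models, clinical table and the ground-truth
    methylation rates (for validation only).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samdir = outdir / "sams"
    samdir.mkdir(exist_ok=True)

    truth = build_truth(config)
    manifest = truth["manifest"]
    paths: dict[str, Path] = {}

    from mtp9.sites import write_sites_tsv

    paths["manifest"] = outdir / "manifest.tsv"
    write_tsv(manifest, paths["manifest"])
    paths["sites"] = outdir / "sites.tsv"
    write_sites_tsv(config.sites, paths["sites"])

    rng_reads = truth["streams"]["reads"]
    theta = truth["theta"].set_index(["patient_id", "site_id"])
    for pt in manifest.itertuples():
        for state, sid in (("normal", pt.normal_sample_id), ("tumor", pt.tumor_sample_id)):
            key = "theta_normal" if state == "normal" else "theta_tumor"
            thetas = {
                s.site_id: theta.loc[(pt.patient_id, s.site_id), key]
                for s in config.sites
            }
            reads = simulate_sample_reads(config, sid, thetas, rng_reads)
            write_sam(reads, samdir / f"{sid}.sam")
    paths["sam_dir"] = samdir

    calls_long = truth["calls"].reset_index(names="snp_id").melt(
        id_vars="snp_id", var_name="patient_id", value_name="call"
    )
    quals_long = truth["qualities"].reset_index(names="snp_id").melt(
        id_vars="snp_id", var_name="patient_id", value_name="quality"
    )
    geno = calls_long.merge(quals_long, on=["snp_id", "patient_id"])
    paths["genotypes"] = outdir / "genotypes.tsv"
    write_tsv(geno, paths["genotypes"])
    paths["snp_meta"] = outdir / "snp_meta.tsv"
    write_tsv(truth["snp_meta"], paths["snp_meta"])

    counts, models = simulate_expression(config, truth)
    paths["expression_counts"] = outdir / "expression_counts.tsv"
    write_tsv(counts.reset_index(names="gene_id"), paths["expression_counts"])
    paths["gene_models"] = outdir / "gene_models.tsv"
    write_tsv(models, paths["gene_models"])

    clinical = simulate_clinical(config, truth)
    paths["clinical"] = outdir / "clinical.tsv"
    write_tsv(clinical, paths["clinical"])

    truth_out = truth["theta"]
    paths["truth_theta"] = outdir / "truth_theta.tsv"
    write_tsv(truth_out, paths["truth_theta"])
    return paths
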