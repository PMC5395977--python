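"""Stage orchestration: ingest -> quantify -> metrics -> difftest ->
associate -> gxe -> survival, driven by a single key-value config.

Stages exchange plain TSV files (headers mandatory, UTF-8, '.' decimal,
NA for missing) so each is independently testable; reruns with the same
seed are byte-identical. ``--resume`` skips stages whose outputs exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mtp9 import association, differential, gxe, methylation, metrics, survival
from mtp9.ingest import FilterParams, count_alleles, count_termini, terminus_positions_for_sites
from mtp9.sites import read_sites_tsv
from mtp9.tsv import read_tsv, write_tsv

log = logging.getLogger("mtp9")


@dataclass
class PipelineConfig:
    workdir: str = "."
    sam_dir: str = "sams"
    manifest: str = "manifest.tsv"
    sites: str = "sites.tsv"
    genotypes: str = "genotypes.tsv"
    expression_counts: str = "expression_counts.tsv"
    gene_models: str = "gene_models.tsv"
    clinical: str = "clinical.tsv"
    outdir: str = "out"
    min_mapq: int = 30
    min_baseq: int = 13
    min_coverage: int = 20
    resample: bool = False
    maf: float = 0.05
    hwe_p: float = 0.001
    quality: float = 0.1
    min_n: int = 40
    min_carriers: int = 5
    survival_min_n: int = 50
    survival_min_death_rate: float = 0.25
    censor_months: float = 60.0
    alpha: float = 0.05
    seed: int = 0

    def path(self, name: str) -> Path:
        return Path(self.workdir) / getattr(self, name)

    def out(self, fname: str) -> Path:
        return Path(self.workdir) / self.outdir / fname

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name, lo, hi in (
            ("maf", 0, 0.5),
            ("hwe_p", 0, 1),
            ("quality", 0, 1),
            ("survival_min_death_rate", 0, 1),
            ("alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"config {name}={v} outside [{lo}, {hi}]")
        if self.min_coverage < 1 or self.censor_months <= 0:
            raise ValueError("min_coverage must be >= 1 and censor_months > 0")


def _require(cfg: PipelineConfig, names: list[str]) -> None:
    missing = [str(cfg.path(n)) for n in names if not cfg.path(n).exists()]
    if missing:
        raise FileNotFoundError(f"missing input path(s): {missing}")


def stage_ingest(cfg: PipelineConfig) -> dict[str, Path]:
    _require(cfg, ["manifest", "sites", "sam_dir"])
    sites = read_sites_tsv(cfg.path("sites"))
    manifest = read_tsv(cfg.path("manifest"))
    params = FilterParams(min_mapq=cfg.min_mapq, min_base_quality=cfg.min_baseq)
    positions = terminus_positions_for_sites(sites)
    samdir = cfg.path("sam_dir")
    counts_frames, term_frames = [], []
    sample_ids = pd.concat(
        [manifest["normal_sample_id"], manifest["tumor_sample_id"]]
    ).tolist()
    for sid in sample_ids:
        sam = samdir / f"{sid}.sam"
        if not sam.exists():
            raise FileNotFoundError(f"missing alignment file {sam}")
        counts_frames.append(count_alleles(sam, sites, sample_id=sid, params=params))
        term_frames.append(count_termini(sam, positions, sample_id=sid, params=params))
    out_counts = cfg.out("allele_counts.tsv")
    out_term = cfg.out("termini.tsv")
    write_tsv(pd.concat(counts_frames, ignore_index=True), out_counts)
    write_tsv(pd.concat(term_frames, ignore_index=True), out_term)
    return {"allele_counts": out_counts, "termini": out_term}


def _sample_meta(manifest: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pt in manifest.itertuples():
        rows.append({"sample_id": pt.normal_sample_id, "patient_id": pt.patient_id, "cancer_type": pt.cancer_type, "state": "normal"})
        rows.append({"sample_id": pt.tumor_sample_id, "patient_id": pt.patient_id, "cancer_type": pt.cancer_type, "state": "tumor"})
    return pd.DataFrame(rows)


def stage_quantify(cfg: PipelineConfig) -> dict[str, Path]:
    _require(cfg, ["manifest", "sites"])
    sites = read_sites_tsv(cfg.path("sites"))
    manifest = read_tsv(cfg.path("manifest"))
    counts = read_tsv(cfg.out("allele_counts.tsv"))
    if cfg.resample:
        counts = methylation.resample_pairs(counts, manifest, cfg.seed)
    meth = methylation.methylation_table(counts, sites, min_coverage=cfg.min_coverage)
    meta = _sample_meta(manifest)
    meth = meth.merge(meta, on="sample_id")
    out_meth = cfg.out("methylation.tsv")
    write_tsv(meth, out_meth)
    std = methylation.standardize(meth)
    out_std = cfg.out("methylation_standardized.tsv")
    write_tsv(std, out_std)
    return {"methylation": out_meth, "standardized": out_std}


def stage_metrics(cfg: PipelineConfig) -> dict[str, Path]:
    _require(cfg, ["expression_counts", "gene_models", "manifest", "sites"])
    sites = read_sites_tsv(cfg.path("sites"))
    manifest = read_tsv(cfg.path("manifest"))
    counts = read_tsv(cfg.path("expression_counts")).set_index("gene_id")
    models = metrics.gene_models_from_frame(read_tsv(cfg.path("gene_models")))
    expr = metrics.tpm(counts, models)
    norm = metrics.log_median_normalize(expr)
    retained, qc = metrics.pca_outlier_filter(norm, manifest)
    norm = norm[retained]
    out_expr = cfg.out("expression_matrix.tsv")
    write_tsv(norm.reset_index(names="gene_id"), out_expr)
    out_qc = cfg.out("qc_removed_samples.tsv")
    write_tsv(qc, out_qc)
    termini = read_tsv(cfg.out("termini.tsv"))
    cleav = metrics.cleavage_table(termini, sites)
    out_cleav = cfg.out("cleavage.tsv")
    write_tsv(cleav, out_cleav)
    return {"expression_matrix": out_expr, "qc": out_qc, "cleavage": out_cleav}


def stage_difftest(cfg: PipelineConfig) -> dict[str, Path]:
    manifest = read_tsv(cfg.path("manifest"))
    std = read_tsv(cfg.out("methylation_standardized.tsv"))
    results = differential.differential_table(std, manifest, alpha=cfg.alpha)
    out_res = cfg.out("differential.tsv")
    write_tsv(results, out_res)
    cross = differential.cross_cancer_test(std, manifest, alpha=cfg.alpha)
    out_cross = cfg.out("differential_cross_cancer.tsv")
    write_tsv(cross, out_cross)
    means = (
        std.groupby(["cancer_type", "state", "site_id"])["std_level"].mean().reset_index()
    )
    matrix = means.pivot_table(
        index=["cancer_type", "state"], columns="site_id", values="std_level"
    )
    out_clust = cfg.out("cluster_leaf_orders.tsv")
    if len(matrix) >= 2:
        clust = differential.cluster_groups(matrix)
        rows = [
            {"axis": "row", "order": i, "label": "|".join(map(str, lab)) if isinstance(lab, tuple) else str(lab)}
            for i, lab in enumerate(clust["row_order"])
        ] + [
            {"axis": "col", "order": i, "label": str(lab)}
            for i, lab in enumerate(clust["col_order"])
        ]
        write_tsv(pd.DataFrame(rows), out_clust)
    else:
        write_tsv(pd.DataFrame(columns=["axis", "order", "label"]), out_clust)
    return {"differential": out_res, "cross_cancer": out_cross, "clusters": out_clust}


def stage_associate(cfg: PipelineConfig) -> dict[str, Path]:
    manifest = read_tsv(cfg.path("manifest"))
    meta = _sample_meta(manifest)
    meth = read_tsv(cfg.out("methylation.tsv"))
    expr = read_tsv(cfg.out("expression_matrix.tsv")).set_index("gene_id")
    meth_wide = meth.pivot_table(index="site_id", columns="sample_id", values="level")
    states = meta.set_index("sample_id")["state"]
    rng = np.random.default_rng(cfg.seed)
    scan = association.spearman_scan(
        meth_wide, expr, states, alpha=cfg.alpha, rng=rng
    )
    out_assoc = cfg.out("associations.tsv")
    write_tsv(scan, out_assoc)
    cleav = read_tsv(cfg.out("cleavage.tsv"))
    cl = association.methylation_vs_cleavage(
        meth, cleav, manifest, alpha=cfg.alpha, rng=rng
    )
    out_cl = cfg.out("cleavage_associations.tsv")
    write_tsv(cl, out_cl)
    return {"associations": out_assoc, "cleavage_associations": out_cl}


def stage_gxe(cfg: PipelineConfig) -> dict[str, Path]:
    _require(cfg, ["genotypes", "manifest"])
    manifest = read_tsv(cfg.path("manifest"))
    geno = read_tsv(cfg.path("genotypes"))
    meth = read_tsv(cfg.out("methylation.tsv"))
    params = gxe.GxEParams(
        min_quality=cfg.quality, hwe_p=cfg.hwe_p, min_maf=cfg.maf,
        min_n=cfg.min_n, min_carriers=cfg.min_carriers, alpha=cfg.alpha,
    )
    calls_all = geno.pivot_table(index="snp_id", columns="patient_id", values="call")
    quals_all = geno.pivot_table(index="snp_id", columns="patient_id", values="quality")
    scans: dict[str, pd.DataFrame] = {}
    for cancer, cpairs in manifest.groupby("cancer_type"):
        patients = cpairs["patient_id"].tolist()
        calls = calls_all[[p for p in patients if p in calls_all.columns]]
        quals = quals_all[calls.columns]
        carriers, qc = gxe.prepare_genotypes(calls, quals, params)
        masked = calls.astype(float).where(quals >= params.min_quality)
        maf = masked.apply(lambda r: gxe.minor_allele_frequency(r.to_numpy()), axis=1)
        tn = pd.DataFrame(index=sorted(meth["site_id"].unique()), columns=calls.columns, dtype=float)
        tt = tn.copy()
        keyed = meth.set_index(["patient_id", "site_id", "state"])["level"]
        for pid in calls.columns:
            for site_id in tn.index:
                for state, frame in (("normal", tn), ("tumor", tt)):
                    try:
                        frame.loc[site_id, pid] = keyed[(pid, site_id, state)]
                    except KeyError:
                        pass
        scans[cancer] = gxe.gxe_scan(carriers, maf, tn, tt, cancer, params)
    all_scans = pd.concat(scans.values(), ignore_index=True) if scans else pd.DataFrame()
    out_gxe = cfg.out("gxe.tsv")
    if len(all_scans):
        thresh = gxe.genome_wide_threshold(len(all_scans), cfg.alpha)
        all_scans["genome_wide_significant"] = all_scans["p_interaction"] < thresh
        all_scans = all_scans.sort_values("p_interaction", kind="stable").reset_index(drop=True)
        hits = all_scans[all_scans["genome_wide_significant"]]
        repl = gxe.replicate(hits, scans)
    else:
        repl = pd.DataFrame()
    write_tsv(all_scans, out_gxe)
    out_repl = cfg.out("gxe_replication.tsv")
    write_tsv(repl, out_repl)
    return {"gxe": out_gxe, "replication": out_repl}


def stage_survival(cfg: PipelineConfig) -> dict[str, Path]:
    _require(cfg, ["clinical", "manifest"])
    manifest = read_tsv(cfg.path("manifest"))
    clinical = read_tsv(cfg.path("clinical"))
    meth = read_tsv(cfg.out("methylation.tsv"))
    deltas = methylation.delta_methylation(meth, manifest)
    scan = survival.survival_scan(
        clinical, deltas,
        min_n=cfg.survival_min_n,
        min_death_rate=cfg.survival_min_death_rate,
        censor_months=cfg.censor_months,
        alpha=cfg.alpha,
    )
    out_surv = cfg.out("survival.tsv")
    write_tsv(scan, out_surv)
    km_frames = []
    eligible = scan[scan["eligible"] == True]  # noqa: E712
    if len(eligible):
        top = eligible.sort_values("p_value", kind="stable").iloc[0]
        sub = deltas[
            (deltas["cancer_type"] == top["cancer_type"])
            & (deltas["site_id"] == top["site_id"])
        ]
        rec = sub.rename(columns={"delta": "delta_methylation"}).merge(clinical, on="patient_id")
        binned = survival.cox_binned(rec, cfg.censor_months)
        km = binned["km_curves"]
        km.insert(0, "site_id", top["site_id"])
        km.insert(0, "cancer_type", top["cancer_type"])
        km_frames.append(km)
    out_km = cfg.out("km_curves.tsv")
    write_tsv(
        pd.concat(km_frames, ignore_index=True)
        if km_frames
        else pd.DataFrame(columns=["cancer_type", "site_id", "group", "time", "survival"]),
        out_km,
    )
    return {"survival": out_surv, "km": out_km}


STAGES = [
    ("ingest", stage_ingest),
    ("quantify", stage_quantify),
    ("metrics", stage_metrics),
    ("difftest", stage_difftest),
    ("associate", stage_associate),
    ("gxe", stage_gxe),
    ("survival", stage_survival),
]


def run_all(cfg: PipelineConfig, resume: bool = False) -> pd.DataFrame:
    """Execute every stage in order; returns the run manifest.

    With ``resume``, a stage whose outputs all exist is skipped. A stage
    failure aborts the run with the failing stage named.
    """
    cfg.validate()
    outdir = Path(cfg.workdir) / cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    report_rows = []
    for name, fn in STAGES:
        try:
            if resume:
                probe = _stage_outputs(cfg, name)
                if probe and all(p.exists() for p in probe):
                    log.info("[%s] outputs present, skipping (resume)", name)
                    for p in probe:
                        report_rows.append(_report_row(name, p, skipped=True))
                    continue
            log.info("[%s] running", name)
            outputs = fn(cfg)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        for p in outputs.values():
            report_rows.append(_report_row(name, p, skipped=False))
    report = pd.DataFrame(report_rows, columns=["stage", "output", "rows", "skipped"])
    write_tsv(report, outdir / "run_manifest.tsv")
    return report


_STAGE_FILES = {
    "ingest": ["allele_counts.tsv", "termini.tsv"],
    "quantify": ["methylation.tsv", "methylation_standardized.tsv"],
    "metrics": ["expression_matrix.tsv", "qc_removed_samples.tsv", "cleavage.tsv"],
    "difftest": ["differential.tsv", "differential_cross_cancer.tsv", "cluster_leaf_orders.tsv"],
    "associate": ["associations.tsv", "cleavage_associations.tsv"],
    "gxe": ["gxe.tsv", "gxe_replication.tsv"],
    "survival": ["survival.tsv", "km_curves.tsv"],
}


def _stage_outputs(cfg: PipelineConfig, stage: str) -> list[Path]:
    return [cfg.out(f) for f in _STAGE_FILES.get(stage, [])]


def _report_row(stage: str, path: Path, skipped: bool) -> dict:
    try:
        nrows = max(sum(1 for _ in open(path)) - 1, 0) if path.is_file() else -1
    except OSError:
        nrows = -1
    return {"stage": stage, "output": str(path), "rows": nrows, "skipped": skipped}
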