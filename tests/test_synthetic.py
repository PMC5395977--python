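import numpy as np
import pandas as pd
import pytest

from mtp9.ingest import FilterParams, count_alleles
from mtp9.methylation import methylation_table
from mtp9.sites import default_sites
from mtp9.synthetic import (
    PlantedGxE,
    SimulationConfig,
    build_manifest,
    build_truth,
    generate_cohort,
    reads_to_segments,
    sam_header,
    simulate_expression,
    simulate_genotypes,
    simulate_reads,
    simulate_sample_reads,
    simulate_survival,
)


def _one_site_config(**kw):
    site = default_sites()[7]  # p9_10413
    defaults = dict(
        n_patients=4,
        sites=[site],
        theta_normal={site.site_id: 0.3},
        delta_tumor={site.site_id: 0.1},
        coverage_mean=200.0,
        n_snps=5,
        n_genes=10,
        n_mito_genes=2,
        expr_site=site.site_id,
        seed=5,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# config validation


def test_invalid_rates_rejected():
    site = default_sites()[0]
    with pytest.raises(ValueError, match="outside"):
        SimulationConfig(sites=[site], theta_normal={site.site_id: 1.2})
    with pytest.raises(ValueError, match="outside"):
        SimulationConfig(
            sites=[site],
            theta_normal={site.site_id: 0.95},
            delta_tumor={site.site_id: 0.1},
        )
    with pytest.raises(ValueError, match="maf_range"):
        SimulationConfig(maf_range=(0.0, 0.4))


def test_invalid_state_label():
    cfg = _one_site_config()
    with pytest.raises(ValueError, match="invalid state"):
        simulate_reads(cfg, "x", "metastatic")


# ---------------------------------------------------------------------------
# reads


def _observed_fraction(cfg, theta, rng):
    site = cfg.sites[0]
    reads = simulate_sample_reads(cfg, "s", {site.site_id: theta}, rng)
    segs = reads_to_segments(reads, sam_header())
    counts = count_alleles(segs, cfg.sites)
    row = counts.iloc[0]
    depth = row["depth"]
    ref = row[f"count_{site.ref_allele}"]
    return (depth - ref) / depth, depth


def test_binomial_expectation(rng):
    cfg = _one_site_config(coverage_mean=1000.0, coverage_dispersion=1e6)
    frac, depth = _observed_fraction(cfg, 0.3, rng)
    expected = 0.3 + 0.7 * cfg.seq_error
    se = np.sqrt(expected * (1 - expected) / depth)
    assert abs(frac - expected) < 3 * se + 1e-9


def test_zero_theta_zero_error_exact_zero(rng):
    cfg = _one_site_config(seq_error=0.0, coverage_mean=500.0)
    frac, depth = _observed_fraction(cfg, 0.0, rng)
    assert frac == 0.0
    assert depth > 0


def test_seeded_determinism():
    cfg = _one_site_config()
    truth = build_truth(cfg)
    r1 = simulate_reads(cfg, "PT0000_T", "tumor", truth=truth)
    truth2 = build_truth(cfg)
    r2 = simulate_reads(cfg, "PT0000_T", "tumor", truth=truth2)
    assert r1 == r2


def test_decoys_rejected_by_filters(rng):
    cfg = _one_site_config(decoy_fraction=0.2)
    site = cfg.sites[0]
    reads = simulate_sample_reads(cfg, "s", {site.site_id: 0.1}, rng)
    segs = reads_to_segments(reads, sam_header())
    strict = count_alleles(segs, cfg.sites).iloc[0]
    loose = count_alleles(
        segs,
        cfg.sites,
        params=FilterParams(min_mapq=0, min_base_quality=0, require_proper_pair=False),
    ).iloc[0]
    # decoys always carry a non-reference base: unfiltered depth is larger
    # and unfiltered mismatch fraction strictly higher
    assert loose["depth"] > strict["depth"]
    ref = f"count_{site.ref_allele}"
    frac_strict = (strict["depth"] - strict[ref]) / strict["depth"]
    frac_loose = (loose["depth"] - loose[ref]) / loose["depth"]
    assert frac_loose > frac_strict


def test_reads_pass_ingest_and_recover_theta(rng):
    # the accepted (non-decoy) reads give back the planted rate
    cfg = _one_site_config(coverage_mean=2000.0, coverage_dispersion=1e6)
    site = cfg.sites[0]
    reads = simulate_sample_reads(cfg, "s", {site.site_id: 0.4}, rng)
    segs = reads_to_segments(reads, sam_header())
    meth = methylation_table(count_alleles(segs, cfg.sites), cfg.sites)
    assert meth.iloc[0]["level"] == pytest.approx(0.4, abs=0.05)


# ---------------------------------------------------------------------------
# genotypes


def test_hwe_proportions_large_n():
    cfg = SimulationConfig(n_patients=10000, n_snps=4, maf_range=(0.2, 0.2), seed=3)
    manifest = build_manifest(cfg)
    calls, quals, meta = simulate_genotypes(cfg, manifest, np.random.default_rng(3))
    for snp in calls.index:
        freqs = calls.loc[snp].value_counts(normalize=True)
        for g, expected in ((0, 0.64), (1, 0.32), (2, 0.04)):
            se = np.sqrt(expected * (1 - expected) / 10000)
            assert abs(freqs.get(g, 0) - expected) < 4 * se
    assert ((quals < 0.1).mean().mean()) > 0


def test_maf_zero_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(maf_range=(0, 0.3))


def test_planted_effect_construction():
    site = default_sites()[7]
    cfg = SimulationConfig(
        n_patients=400,
        cancer_labels=("C1",),
        sites=[site],
        theta_normal={site.site_id: 0.3},
        delta_tumor={site.site_id: 0.05},
        patient_sd=0.02,
        n_snps=5,
        n_genes=10,
        n_mito_genes=2,
        expr_site=site.site_id,
        planted_gxe=(PlantedGxE("snp_0000", site.site_id, 0.05),),
        seed=9,
    )
    truth = build_truth(cfg)
    theta = truth["theta"].set_index("patient_id")
    carrier = truth["calls"].loc["snp_0000"] >= 1
    carriers = theta[carrier.reindex(theta.index).to_numpy()]
    non = theta[~carrier.reindex(theta.index).to_numpy()]
    tumor_diff = carriers["theta_tumor"].mean() - non["theta_tumor"].mean()
    normal_diff = carriers["theta_normal"].mean() - non["theta_normal"].mean()
    assert tumor_diff == pytest.approx(0.05, abs=0.015)
    assert abs(normal_diff) < 0.01


# ---------------------------------------------------------------------------
# expression


def _coupling_config(rho, n_patients=200):
    site = default_sites()[7]
    return SimulationConfig(
        n_patients=n_patients,
        cancer_labels=("C1",),
        sites=[site],
        theta_normal={site.site_id: 0.4},
        delta_tumor={site.site_id: 0.1},
        patient_sd=0.1,
        n_snps=5,
        n_genes=12,
        n_mito_genes=2,
        expr_site=site.site_id,
        expr_coupling={"gene_0002": rho},
        seed=21,
    )


def test_expression_coupling_recovered():
    from scipy import stats

    cfg = _coupling_config(0.9)
    truth = build_truth(cfg)
    counts, models = simulate_expression(cfg, truth)
    theta = truth["theta"].set_index("patient_id")["theta_normal"]
    normal_cols = truth["manifest"]["normal_sample_id"]
    meth = theta[truth["manifest"]["patient_id"]].to_numpy()
    expr = counts.loc["gene_0002", normal_cols].to_numpy()
    rho, _ = stats.spearmanr(meth, expr)
    assert rho > 0.6


def test_expression_tumor_decoupled():
    from scipy import stats

    cfg = _coupling_config(0.9)
    truth = build_truth(cfg)
    counts, _ = simulate_expression(cfg, truth)
    theta = truth["theta"].set_index("patient_id")["theta_tumor"]
    tumor_cols = truth["manifest"]["tumor_sample_id"]
    meth = theta[truth["manifest"]["patient_id"]].to_numpy()
    expr = counts.loc["gene_0002", tumor_cols].to_numpy()
    rho, p = stats.spearmanr(meth, expr)
    assert abs(rho) < 0.2


def test_expression_null_gene_uncorrelated():
    from scipy import stats

    cfg = _coupling_config(0.0)
    truth = build_truth(cfg)
    counts, _ = simulate_expression(cfg, truth)
    theta = truth["theta"].set_index("patient_id")["theta_normal"]
    normal_cols = truth["manifest"]["normal_sample_id"]
    meth = theta[truth["manifest"]["patient_id"]].to_numpy()
    expr = counts.loc["gene_0005", normal_cols].to_numpy()
    _, p = stats.spearmanr(meth, expr)
    assert p > 0.05 / 10  # no Bonferroni-level association


# ---------------------------------------------------------------------------
# survival


def test_survival_all_beyond_horizon(rng):
    cfg = _one_site_config(baseline_hazard=1e-9)
    delta = pd.Series(np.zeros(50), index=[f"p{i}" for i in range(50)])
    out = simulate_survival(cfg, delta, rng)
    assert (out["event"] == 0).all()
    assert (out["time"] == cfg.censor_months).all()


def test_survival_hazard_scales_with_delta(rng):
    cfg = _one_site_config(survival_gamma=2.0)
    delta = pd.Series(
        np.r_[np.full(2000, -1.0), np.full(2000, 1.0)],
        index=[f"p{i}" for i in range(4000)],
    )
    out = simulate_survival(cfg, delta, rng)
    low = out.iloc[:2000]["event"].mean()
    high = out.iloc[2000:]["event"].mean()
    assert high > low


# ---------------------------------------------------------------------------
# cohort on disk


def test_generate_cohort_outputs(tmp_path, small_config):
    paths = generate_cohort(small_config, tmp_path / "cohort")
    for key in ("manifest", "sites", "genotypes", "expression_counts", "gene_models", "clinical", "truth_theta"):
        assert paths[key].exists(), key
    sams = list((tmp_path / "cohort" / "sams").glob("*.sam"))
    assert len(sams) == 2 * small_config.n_patients


def test_generate_cohort_byte_identical(tmp_path, small_config):
    p1 = generate_cohort(small_config, tmp_path / "a")
    p2 = generate_cohort(small_config, tmp_path / "b")
    for key in ("manifest", "genotypes", "expression_counts", "clinical", "truth_theta"):
        assert p1[key].read_bytes() == p2[key].read_bytes(), key
    sam1 = sorted((tmp_path / "a" / "sams").glob("*.sam"))
    sam2 = sorted((tmp_path / "b" / "sams").glob("*.sam"))
    for a, b in zip(sam1, sam2):
        assert a.read_bytes() == b.read_bytes()
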