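import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from mtp9.differential import (
    bonferroni_threshold,
    cluster_groups,
    cross_cancer_test,
    de_scan,
    differential_table,
    paired_wilcoxon,
    signed_rank_exact_p,
)

# ---------------------------------------------------------------------------
# signed-rank test


def test_six_pairs_all_positive_exact():
    normal = np.zeros(6)
    tumor = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    res = paired_wilcoxon(normal, tumor)
    assert res.p_value == pytest.approx(2 / 2**6)
    assert res.direction == "tumor-higher"


def test_identical_vectors_p_one():
    v = np.array([0.1, 0.2, 0.3])
    res = paired_wilcoxon(v, v)
    assert res.p_value == 1.0
    assert res.direction is None


def test_exact_matches_scipy_no_ties(rng):
    for _ in range(20):
        d = rng.normal(size=10)
        while len(np.unique(np.abs(d))) < 10 or (d == 0).any():
            d = rng.normal(size=10)
        _, p = signed_rank_exact_p(d)
        p_scipy = stats.wilcoxon(d, method="exact").pvalue
        assert p == pytest.approx(p_scipy, rel=1e-9)


def test_exact_brute_force_enumeration(rng):
    # independent oracle: enumerate all 2^n sign patterns directly
    d = np.array([0.5, 1.1, 2.2, 0.9, 1.7, 3.0, 0.3])
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p_brute = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
    w, p = signed_rank_exact_p(d)
    assert w == pytest.approx(w_obs)
    assert p == pytest.approx(p_brute)


def test_exact_with_ties(rng):
    d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0])
    _, p = signed_rank_exact_p(d)
    assert 0 < p <= 1


def test_zero_differences_dropped():
    normal = np.array([1.0, 1.0, 1.0, 1.0])
    tumor = np.array([1.0, 2.0, 3.0, 4.0])
    res = paired_wilcoxon(normal, tumor)
    assert res.n_pairs == 3


def test_unequal_lengths_raise():
    with pytest.raises(ValueError):
        paired_wilcoxon(np.zeros(3), np.zeros(4))


def test_type_i_error_calibration(rng):
    # exchangeable pairs at n=30 (approximate path); quick version
    n_reps, hits = 2000, 0
    for _ in range(n_reps):
        d = rng.normal(size=30)
        res = paired_wilcoxon(np.zeros(30), d)
        hits += res.p_value < 0.05
    rate = hits / n_reps
    assert abs(rate - 0.05) < 0.017  # 3 SE + discreteness margin


# ---------------------------------------------------------------------------
# Bonferroni


@pytest.mark.parametrize(
    "alpha,m,expected",
    [(0.05, 11, 0.05 / 11), (0.05, 16736, 0.05 / 16736), (0.05, 1, 0.05)],
)
def test_bonferroni_threshold(alpha, m, expected):
    assert bonferroni_threshold(alpha, m) == pytest.approx(expected)


def test_bonferroni_printed_values():
    assert round(bonferroni_threshold(0.05, 11), 4) == 0.0045
    assert bonferroni_threshold(0.05, 16736) == pytest.approx(3e-6, rel=0.005)


def test_bonferroni_zero_m():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


# ---------------------------------------------------------------------------
# result tables


def _cohort(n_sites=11, n_cancers=12, n_pairs=8, delta=0.1, rng=None):
    rng = rng or np.random.default_rng(1)
    pairs_rows, level_rows = [], []
    for c in range(n_cancers):
        cancer = f"C{c:02d}"
        for p in range(n_pairs):
            pid = f"{cancer}p{p}"
            pairs_rows.append(
                {
                    "patient_id": pid,
                    "cancer_type": cancer,
                    "normal_sample_id": f"{pid}_N",
                    "tumor_sample_id": f"{pid}_T",
                }
            )
            for s in range(n_sites):
                base = rng.uniform(0.05, 0.5)
                for state, sid in (("normal", f"{pid}_N"), ("tumor", f"{pid}_T")):
                    level = base + (delta if state == "tumor" else 0) + rng.normal(0, 0.01)
                    level_rows.append(
                        {
                            "sample_id": sid,
                            "site_id": f"s{s:02d}",
                            "cancer_type": cancer,
                            "state": state,
                            "level": max(level, 1e-4),
                        }
                    )
    return pd.DataFrame(level_rows), pd.DataFrame(pairs_rows)


def test_comparison_table_bookkeeping():
    levels, pairs = _cohort()
    out = differential_table(levels, pairs)
    assert len(out) == 132  # 11 sites x 12 cancers


def test_bonferroni_implies_nominal():
    levels, pairs = _cohort()
    out = differential_table(levels, pairs)
    assert (out["bonferroni_significant"] <= out["nominal_significant"]).all()


def test_direction_matches_planted_shift():
    levels, pairs = _cohort(n_cancers=2, n_pairs=15, delta=0.15)
    out = differential_table(levels, pairs)
    assert (out["direction"] == "tumor-higher").all()


def test_cross_cancer_single_cancer_consistency():
    levels, pairs = _cohort(n_cancers=1, n_pairs=10)
    levels["std_level"] = levels["level"]
    per_cancer = differential_table(levels, pairs, value_col="std_level")
    pooled = cross_cancer_test(levels, pairs)
    merged = per_cancer.merge(pooled, on="site_id", suffixes=("_a", "_b"))
    assert np.allclose(merged["p_value_a"], merged["p_value_b"])


# ---------------------------------------------------------------------------
# clustering


def test_identical_rows_merge_first():
    m = pd.DataFrame(
        [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]],
        index=["a", "b", "c"],
    )
    out = cluster_groups(m)
    # first merge joins leaves 0 and 1 at height 0
    assert set(out["row_linkage"][0, :2].astype(int)) == {0, 1}
    assert out["row_linkage"][0, 2] == 0.0


def test_two_cluster_cut_separates_planted_groups(rng):
    normal = rng.normal(0, 0.05, size=(4, 5))
    tumor = rng.normal(3, 0.05, size=(4, 5))
    m = pd.DataFrame(
        np.vstack([normal, tumor]),
        index=[f"n{i}" for i in range(4)] + [f"t{i}" for i in range(4)],
    )
    out = cluster_groups(m)
    cut = hierarchy.fcluster(out["row_linkage"], 2, criterion="maxclust")
    assert len(set(cut[:4])) == 1 and len(set(cut[4:])) == 1
    assert cut[0] != cut[4]


def _brute_force_ward_cophenetic(X):
    """Lance-Williams Ward agglomeration, tracking cophenetic heights."""
    n = X.shape[0]
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))
    members = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(active) > 1:
        (i, j), best = min(
            ((pair, v) for pair, v in d2.items() if pair[0] in active and pair[1] in active),
            key=lambda kv: (kv[1], kv[0]),
        )
        h = np.sqrt(best)
        for a in members[i]:
            for b in members[j]:
                coph[a, b] = coph[b, a] = h
        k = next_id
        next_id += 1
        sizes[k] = sizes[i] + sizes[j]
        members[k] = members[i] + members[j]
        for other in active:
            if other in (i, j):
                continue
            dik = d2[tuple(sorted((i, other)))]
            djk = d2[tuple(sorted((j, other)))]
            dij = best
            ni, nj, nk = sizes[i], sizes[j], sizes[other]
            d2[tuple(sorted((k, other)))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        active = [a for a in active if a not in (i, j)] + [k]
    return coph


def test_cophenetic_matches_brute_force(rng):
    X = rng.normal(size=(5, 3))
    m = pd.DataFrame(X)
    out = cluster_groups(m)
    coph_scipy = squareform(hierarchy.cophenet(out["row_linkage"]))
    coph_brute = _brute_force_ward_cophenetic(X)
    assert np.allclose(coph_scipy, coph_brute)


def test_cluster_imputes_missing():
    m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0], [3.0, 4.0]], index=list("abc"))
    out = cluster_groups(m)
    assert out["imputed_cells"] == [("a", 1)]


def test_cluster_needs_two_rows():
    with pytest.raises(ValueError):
        cluster_groups(pd.DataFrame([[1.0, 2.0]]))


# ---------------------------------------------------------------------------
# DE scan


def _expr_two_groups(shift, n=20, n_genes=5, rng=None):
    rng = rng or np.random.default_rng(3)
    cols = [f"n{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
    X = rng.normal(size=(n_genes, 2 * n))
    X[:, n:] += shift
    labels = pd.Series(["normal"] * n + ["tumor"] * n, index=cols)
    return pd.DataFrame(X, columns=cols, index=[f"g{i}" for i in range(n_genes)]), labels


def test_equal_means_f_near_zero(rng):
    expr, labels = _expr_two_groups(0.0, rng=rng)
    out = de_scan(expr, labels)
    assert (out["p_value"] > 0.001).all()


def test_planted_shift_bonferroni_significant():
    expr, labels = _expr_two_groups(2.0, n=50)
    out = de_scan(expr, labels)
    assert out["bonferroni_significant"].all()


def test_f_equals_t_squared(rng):
    expr, labels = _expr_two_groups(0.5, rng=rng)
    out = de_scan(expr, labels)
    for gene in expr.index:
        a = expr.loc[gene, labels == "normal"]
        b = expr.loc[gene, labels == "tumor"]
        t, _ = stats.ttest_ind(a, b)
        assert out.set_index("gene_id").loc[gene, "F"] == pytest.approx(t**2)


def test_degenerate_gene_reported_not_crashed():
    expr, labels = _expr_two_groups(1.0, n=4, n_genes=1)
    expr.iloc[0] = [1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 2.0]
    out = de_scan(expr, labels)
    assert out.iloc[0]["degenerate"]
    assert out.iloc[0]["p_value"] == 0.0


def test_log2_mean_diff_scale():
    expr, labels = _expr_two_groups(np.log10(2), n=30, n_genes=1, rng=np.random.default_rng(5))
    out = de_scan(expr, labels)
    # a log10 difference of log10(2) is one log2 unit
    assert out.iloc[0]["log2_mean_diff"] == pytest.approx(1.0, abs=0.6)
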