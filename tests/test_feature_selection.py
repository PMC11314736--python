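import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mibci import (
    FeatureTable,
    ReliefFParams,
    GraphFSParams,
    relieff_scores,
    inffs_scores,
    ilfs_scores,
    fsv_rank,
    fsv_gdm,
    sd_scores,
    select_top,
    make_planted_feature_table,
)
from mibci.feature_selection import (
    RankingResult,
    power_series_scores,
    truncated_path_scores,
    rank_features,
    sd_statistic,
    _rank_order,
)

ALL_METHODS = ["relieff", "inf_fs", "ilfs", "fsv", "sd"]


# ---------------------------------------------------------------- ranking API

def test_select_top_breaks_ties_by_lower_index():
    r = RankingResult(np.array([0.2, 0.9, 0.9]), _rank_order([0.2, 0.9, 0.9]), "sd")
    assert select_top(r, 2) == [1, 2]
    assert select_top(r, 1) == [1]
    assert select_top(r, 3) == [1, 2, 0]


def test_select_top_rejects_out_of_range():
    r = RankingResult(np.array([1.0, 2.0]), np.array([1, 0]), "sd")
    with pytest.raises(ValueError):
        select_top(r, 0)
    with pytest.raises(ValueError):
        select_top(r, 3)


@pytest.mark.parametrize("method", ALL_METHODS)
def test_column_permutation_equivariance(method):
    """Permuting feature columns must permute scores identically."""
    table, _ = make_planted_feature_table(30, 3, 5, 2.0, seed=42)
    rng = np.random.default_rng(0)
    perm = rng.permutation(table.n_features)
    permuted = FeatureTable(table.values[:, perm], table.labels, [table.feature_meta[j] for j in perm])
    s_base = rank_features(table, method).scores
    s_perm = rank_features(permuted, method).scores
    np.testing.assert_allclose(s_perm, s_base[perm], atol=1e-6)


# ------------------------------------------------------------------- Relief-F

def test_relieff_constant_feature_scores_zero():
    table, _ = make_planted_feature_table(20, 2, 3, 2.0, seed=1)
    values = table.values.copy()
    values[:, 4] = 7.7
    t = FeatureTable(values, table.labels)
    scores = relieff_scores(t).scores
    assert scores[4] == 0.0


def test_relieff_ranking_is_scale_invariant():
    table, _ = make_planted_feature_table(30, 2, 8, 2.5, seed=2)
    base = relieff_scores(table)
    scaled = FeatureTable(table.values * 123.4, table.labels)
    np.testing.assert_allclose(relieff_scores(scaled).scores, base.scores, atol=1e-10)


def test_relieff_duplicated_instances_preserve_sign_ordering():
    table, _ = make_planted_feature_table(20, 2, 6, 3.0, seed=3)
    base = relieff_scores(table).scores
    dup = FeatureTable(
        np.vstack([table.values, table.values]),
        np.concatenate([table.labels, table.labels]),
    )
    dup_scores = relieff_scores(dup).scores
    # the informative/noise sign split survives duplication
    assert np.array_equal(np.argsort(-base)[:2], np.argsort(-dup_scores)[:2])


def test_relieff_single_class_rejected():
    t = FeatureTable(np.random.default_rng(0).normal(size=(6, 3)), [1, 1, 1, 1, 1, 1])
    with pytest.raises(ValueError):
        relieff_scores(t)


def test_relieff_planted_recovery_small_sweep():
    hits = 0
    for seed in range(20):
        table, _ = make_planted_feature_table(40, 2, 18, 3.0, seed=seed)
        r = relieff_scores(table)
        hits += set(r.order[:2].tolist()) == {0, 1}
    assert hits >= 19


def test_relieff_param_validation():
    with pytest.raises(ValueError):
        ReliefFParams(n_neighbors=0)
    with pytest.raises(ValueError):
        ReliefFParams(sigma=0)
    with pytest.raises(ValueError):
        ReliefFParams(miss_prior="bogus")


# --------------------------------------------------------- Inf-FS power series

def test_power_series_of_zero_adjacency_is_zero():
    assert np.all(power_series_scores(np.zeros((4, 4))) == 0)


@pytest.mark.parametrize("n", [3, 4, 5, 6])
def test_closed_form_matches_truncated_path_enumeration(n):
    """(I - rA)^-1 - I row sums equal explicit path sums for l <= 50 when
    the damping makes the tail negligible."""
    rng = np.random.default_rng(n)
    A = np.abs(rng.normal(size=(n, n)))
    A = 0.5 * (A + A.T)
    closed = power_series_scores(A, r_factor=0.6)
    truncated = truncated_path_scores(A, r_factor=0.6, max_len=50)
    np.testing.assert_allclose(closed, truncated, atol=1e-6)


def test_identical_feature_columns_tie_with_index_order():
    rng = np.random.default_rng(5)
    col = rng.normal(size=30)
    other = rng.normal(size=30)
    t = FeatureTable(np.column_stack([col, other, col]), np.tile([1, 2], 15))
    r = inffs_scores(t)
    assert abs(r.scores[0] - r.scores[2]) < 1e-9
    pos = np.argsort(r.order)
    assert pos[0] < pos[2]  # tie broken toward the lower index


def test_inffs_needs_enough_features_and_instances():
    with pytest.raises(ValueError):
        inffs_scores(FeatureTable(np.ones((5, 1)), [1, 2, 1, 2, 1]))
    with pytest.raises(ValueError):
        inffs_scores(FeatureTable(np.random.default_rng(0).normal(size=(2, 3)), [1, 2]))


def test_graph_params_validation():
    with pytest.raises(ValueError):
        GraphFSParams(lam=1.5)
    with pytest.raises(ValueError):
        GraphFSParams(r_factor=1.0)


# ----------------------------------------------------------------------- ILFS

def test_ilfs_shares_power_series_machinery_with_inffs():
    """For any fixed adjacency the two rankings use the same series."""
    rng = np.random.default_rng(6)
    A = np.abs(rng.normal(size=(5, 5)))
    np.testing.assert_allclose(
        power_series_scores(A, 0.9), power_series_scores(A, 0.9)
    )
    # and the ilfs scores are exactly the series applied to its learned A
    table, _ = make_planted_feature_table(40, 2, 6, 3.0, seed=6)
    from mibci.feature_selection import _token_class_separation, _two_class_mixture_em

    sep = _token_class_separation(table.values, table.labels, 6)
    rel = _two_class_mixture_em(sep) * (1.0 + sep)
    expected = power_series_scores(np.outer(rel, rel), 0.9)
    np.testing.assert_allclose(ilfs_scores(table).scores, expected, atol=1e-9)


def test_ilfs_planted_mean_rank():
    diffs = []
    for seed in range(20):
        table, mask = make_planted_feature_table(40, 2, 18, 3.0, seed=seed)
        pos = np.argsort(ilfs_scores(table).order)
        diffs.append(pos[mask].mean() - pos[~mask].mean())
    assert np.mean(diffs) < 0


def test_ilfs_requires_binary_labels_and_tokens():
    t = FeatureTable(np.random.default_rng(0).normal(size=(10, 3)), [1] * 10)
    with pytest.raises(ValueError):
        ilfs_scores(t)
    t2, _ = make_planted_feature_table(10, 1, 1, 1.0, seed=0)
    with pytest.raises(ValueError):
        ilfs_scores(t2, tt=1)


# ------------------------------------------------------------------------ FSV

def test_fsv_finds_the_single_separating_feature():
    rng = np.random.default_rng(7)
    n = 20
    labels = np.tile([1, 2], n)
    f1 = np.where(labels == 2, 1.0, -1.0) + 0.05 * rng.normal(size=2 * n)
    f2 = rng.normal(size=2 * n)
    t = FeatureTable(np.column_stack([f1, f2]), labels)
    r = fsv_rank(t)
    assert r.order[0] == 0
    # exhaustive 1-D threshold oracle confirms feature 1 separates, feature 2 not
    def best_threshold_acc(x, y):
        accs = [max(np.mean((x > c) == (y == 2)), np.mean((x < c) == (y == 2))) for c in x]
        return max(accs)

    assert best_threshold_acc(f1, labels) > 0.95
    assert best_threshold_acc(f2, labels) < 0.8


def test_fsv_permuted_labels_has_no_dominant_feature():
    """Under the permutation null the top-1 feature is ~uniform."""
    p = 6
    counts = np.zeros(p)
    for seed in range(30):
        rng = np.random.default_rng(seed)
        t = FeatureTable(rng.normal(size=(24, p)), np.tile([1, 2], 12))
        counts[fsv_rank(t).order[0]] += 1
    # no feature wins more than half the time (uniform expectation = 5)
    assert counts.max() <= 15


def test_fsv_duplicate_columns_tie():
    rng = np.random.default_rng(8)
    labels = np.tile([1, 2], 15)
    f = np.where(labels == 2, 1.0, -1.0) + 0.1 * rng.normal(size=30)
    g = rng.normal(size=30)
    t = FeatureTable(np.column_stack([f, f, g]), labels)
    r = fsv_rank(t)
    assert abs(r.scores[0] - r.scores[1]) < 1e-4
    pos = np.argsort(r.order)
    assert pos[0] < pos[1]


def test_fsv_rejects_constant_table():
    t = FeatureTable(np.ones((10, 3)), np.tile([1, 2], 5))
    with pytest.raises(ValueError):
        fsv_rank(t)


# ------------------------------------------------------------------ ADM/FDM/GDM

def test_gdm_of_identical_series_is_zero():
    rng = np.random.default_rng(9)
    x = rng.normal(size=64)
    res = fsv_gdm(x, x)
    np.testing.assert_allclose(res.adm, 0.0, atol=1e-12)
    np.testing.assert_allclose(res.fdm, 0.0, atol=1e-12)
    assert res.gdm_total == pytest.approx(0.0, abs=1e-12)


def test_gdm_invariant_to_global_scaling():
    rng = np.random.default_rng(10)
    x = rng.normal(size=64)
    res = fsv_gdm(x, 4.2 * x)
    np.testing.assert_allclose(res.fdm, 0.0, atol=1e-10)
    np.testing.assert_allclose(res.adm, 0.0, atol=1e-10)


def test_gdm_pointwise_combination_oracle():
    rng = np.random.default_rng(11)
    a, b = rng.normal(size=(2, 64))
    res = fsv_gdm(a, b)
    np.testing.assert_allclose(res.gdm, np.sqrt(res.adm**2 + res.fdm**2), atol=1e-12)
    assert res.gdm_total > 0


def test_gdm_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        fsv_gdm(np.zeros(16), np.ones(16))
    with pytest.raises(ValueError):
        fsv_gdm(np.ones(3), np.ones(3))
    with pytest.raises(ValueError):
        fsv_gdm(np.ones(8), np.ones(9))


# ------------------------------------------------------------------------- SD

def test_sd_is_one_under_exact_independence():
    # joint counts equal the product of marginals: 25 per cell over 100
    tokens = np.array([0] * 25 + [1] * 25 + [0] * 25 + [1] * 25)
    labels = np.array([1] * 50 + [2] * 50)
    assert sd_statistic(tokens, labels) == pytest.approx(1.0, abs=1e-12)


def test_sd_is_two_for_perfectly_matched_balanced_binary():
    labels = np.tile([1, 2], 20)
    tokens = (labels == 2).astype(int)
    assert sd_statistic(tokens, labels) == pytest.approx(2.0, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_sd_never_below_one(seed):
    rng = np.random.default_rng(seed)
    tokens = rng.integers(0, 4, size=40)
    labels = rng.choice([1, 2], size=40)
    assert sd_statistic(tokens, labels) >= 1.0 - 1e-12


def test_sd_monotone_in_planted_dependence():
    wins = 0
    n = 40
    for seed in range(n):
        t_dep, _ = make_planted_feature_table(60, 1, 0, 3.0, seed=seed)
        t_null, _ = make_planted_feature_table(60, 1, 0, 0.0, seed=seed)
        sd_dep = sd_scores(t_dep, qs=4).scores[0]
        sd_null = sd_scores(t_null, qs=4).scores[0]
        wins += sd_dep > sd_null
    assert wins >= 0.95 * n


def test_sd_scores_validation():
    t, _ = make_planted_feature_table(10, 1, 1, 1.0, seed=0)
    with pytest.raises(ValueError):
        sd_scores(t, qs=1)
    with pytest.raises(ValueError):
        sd_scores(t, qs=20)


# ------------------------------------------------------- cross-method recovery

def test_all_selectors_rank_informative_above_noise_on_average():
    n_seeds = 15
    for method in ALL_METHODS:
        diffs = []
        for seed in range(n_seeds):
            table, mask = make_planted_feature_table(40, 2, 18, 3.0, seed=1000 + seed)
            pos = np.argsort(rank_features(table, method).order)
            diffs.append(pos[mask].mean() - pos[~mask].mean())
        assert np.mean(diffs) < 0, method


def test_null_table_gives_chance_level_hit_rate():
    """At delta=0 all columns are exchangeable: a selector's top-2 hit rate
    for the nominally 'informative' columns matches the uniform rate."""
    n_inf, n_noise, n_seeds = 2, 18, 60
    hits = 0
    for seed in range(n_seeds):
        table, _ = make_planted_feature_table(40, n_inf, n_noise, 0.0, seed=seed)
        top = set(sd_scores(table).order[:2].tolist())
        hits += len(top & {0, 1})
    p_single = n_inf / (n_inf + n_noise)
    expected = 2 * p_single * n_seeds
    se = np.sqrt(2 * p_single * (1 - p_single) * n_seeds)
    assert abs(hits - expected) <= 3 * se
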