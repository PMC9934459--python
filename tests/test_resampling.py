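from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronotx.resampling import (
    _draw_valid,
    enumerate_marker_null,
    marker_randomization_test,
    permutation_null,
    permute_labels,
    seasonal_label_permutation,
)


# ------------------------------------------------------- label permutation
def test_permutation_preserves_label_counts():
    labels = np.array(["day"] * 5 + ["night"] * 3 + ["twilight"] * 2)
    perm = permute_labels(labels, seed=0)
    assert Counter(perm) == Counter(labels)


def test_permutation_is_deterministic_per_seed():
    labels = np.array(["a", "a", "b", "b", "c", "c"])
    assert (permute_labels(labels, seed=9) == permute_labels(labels, seed=9)).all()
    assert (permute_labels(labels, seed=9) != permute_labels(labels, seed=10)).any()


def test_permutation_is_uniform_over_arrangements():
    labels = np.array(["a", "a", "b", "b", "c", "c"])
    seen = Counter(tuple(permute_labels(labels, seed=s)) for s in range(2000))
    # 6!/(2!2!2!) = 90 distinct arrangements
    assert len(seen) == 90
    counts = np.array(list(seen.values()))
    chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
    assert stats.chi2.sf(chi2, df=89) > 1e-3


def test_single_label_vector_rejected():
    with pytest.raises(ValueError):
        permute_labels(np.array(["x", "x", "x"]), seed=0)


def test_seasonal_binary_permutation_contract():
    binary = np.array([True] * 4 + [False] * 12)
    perm = seasonal_label_permutation(binary, seed=3)
    assert perm.sum() == 4
    assert (perm == seasonal_label_permutation(binary, seed=3)).all()


# -------------------------------------------------- permutation DE null
@pytest.fixture(scope="module")
def planted_null_report(small_sim_module):
    matrix, meta = small_sim_module
    return permutation_null(matrix, meta, n_perm=15, seed=5, mode="daynight")


@pytest.fixture(scope="module")
def small_sim_module():
    from chronotx.simulate import SimConfig, cohort_to_frame, simulate_tissue

    config = SimConfig(n_donors=160, n_genes=400, seed=33)
    cohort, _, matrix = simulate_tissue(config)
    return matrix, cohort_to_frame(cohort)


def test_planted_signal_exceeds_the_permutation_null(planted_null_report):
    res = planted_null_report
    assert res["observed"] > np.percentile(res["null_counts"], 95)
    assert res["null_median"] < res["observed"]


def test_permutation_null_frequencies_are_probabilities(planted_null_report):
    freq = planted_null_report["per_gene_p05_frequency"]
    assert ((freq >= 0) & (freq <= 1)).all()


def test_null_tissue_observed_count_within_null_range():
    from chronotx.simulate import SimConfig, cohort_to_frame, simulate_tissue

    config = SimConfig(n_donors=160, n_genes=300, frac_daynight=0, frac_seasonal=0,
                       frac_covariate=0, seed=34)
    cohort, _, matrix = simulate_tissue(config)
    res = permutation_null(matrix, cohort_to_frame(cohort), n_perm=15, seed=6, mode="daynight")
    lo, hi = res["null_counts"].min(), res["null_counts"].max()
    assert lo <= res["observed"] <= hi


def test_seasonal_permutation_null_loses_planted_signal(small_sim_module):
    matrix, meta = small_sim_module
    res = permutation_null(matrix, meta, n_perm=10, seed=7, mode="seasonal", season="fall")
    assert res["null_median"] < res["observed"]


def test_permutation_null_rejects_bad_inputs(small_sim_module):
    matrix, meta = small_sim_module
    with pytest.raises(ValueError):
        permutation_null(matrix, meta, n_perm=0)
    with pytest.raises(ValueError):
        permutation_null(matrix, meta, n_perm=2, mode="seasonal")


# ------------------------------------------------- marker randomization
def _toy_table():
    # 2 regions x 2 seasons, one cell type, 2 up + 1 down instances
    return pd.DataFrame(
        {
            "cell_type": ["Astrocyte"] * 2,
            "region": ["r1", "r2"],
            "season": ["fall", "winter"],
            "direction": ["up", "down"],
            "count": [2, 1],
        }
    )


def test_randomization_conserves_signed_totals():
    rng = np.random.default_rng(0)
    up, down = _draw_valid(7, 4, 6, 500, rng)
    assert (up.sum(axis=1) == 7).all()
    assert (down.sum(axis=1) == 4).all()
    assert not ((up > 0) & (down > 0)).any()


def test_cell_sign_scheme_also_respects_the_constraint():
    rng = np.random.default_rng(1)
    up, down = _draw_valid(5, 5, 4, 300, rng, scheme="cell_sign")
    assert (up.sum(axis=1) == 5).all()
    assert not ((up > 0) & (down > 0)).any()


def test_monte_carlo_p_matches_exhaustive_enumeration():
    """Oracle: enumerate every valid assignment on the 2x2 grid."""
    valid = list(enumerate_marker_null(2, 1, 4))
    exact = np.mean([u[0] >= 2 for u, d in valid])
    report = marker_randomization_test(_toy_table(), n_rand=40000, seed=2)
    cell = report.per_cell.query("region == 'r1' and season == 'fall' and direction == 'up'")
    mc = float(cell["p"].iloc[0])
    se = np.sqrt(exact * (1 - exact) / 40000)
    assert abs(mc - exact) < 3 * se + 1e-9


def test_explicit_zero_cells_report_trivial_p():
    table = _toy_table()
    table.loc[len(table)] = ["Astrocyte", "r2", "fall", "up", 0]
    report = marker_randomization_test(table, n_rand=2000, seed=3)
    cell = report.per_cell.query("region == 'r2' and season == 'fall' and direction == 'up'")
    assert float(cell["p"].iloc[0]) == 1.0


def test_mixed_sign_observed_cell_rejected():
    table = _toy_table()
    table.loc[len(table)] = ["Astrocyte", "r1", "fall", "down", 3]
    with pytest.raises(ValueError, match="mixes"):
        marker_randomization_test(table, n_rand=100)


def test_bonferroni_defaults_follow_the_grid():
    report = marker_randomization_test(_toy_table(), n_rand=1000, seed=4)
    assert report.n_tests_cell == 4   # 2 regions x 2 seasons x 1 cell type
    assert report.n_tests_row == 2    # 2 seasons x 1 cell type
    assert (report.per_cell["p_bonferroni"] <= 1.0).all()


def test_p_estimate_stability_across_draw_counts():
    small = marker_randomization_test(_toy_table(), n_rand=10000, seed=5)
    large = marker_randomization_test(_toy_table(), n_rand=50000, seed=6)
    p1 = small.per_cell.query("direction == 'up'")["p"].iloc[0]
    p2 = large.per_cell.query("direction == 'up'")["p"].iloc[0]
    assert abs(p1 - p2) < 3 * np.sqrt(p1 * (1 - p1) / 10000) + 1e-9
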