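import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronotx.diffexp import (
    DEResult,
    build_design,
    estimate_prior,
    fit_moderated,
    norm_factors,
    precision_weights,
    run_daynight,
    run_seasonal,
)
from chronotx.labels import DAY, NIGHT, SEASONS


# ------------------------------------------------------------------- TMM
def test_tmm_identical_samples_give_unit_factors():
    counts = np.tile(np.arange(1, 101)[:, None], (1, 4))
    assert np.allclose(norm_factors(counts), 1.0)


def test_tmm_pure_depth_change_gives_unit_factors():
    rng = np.random.default_rng(0)
    base = rng.integers(1, 500, size=200)
    counts = np.column_stack([base, base * 3])
    assert np.allclose(norm_factors(counts), 1.0)


def test_tmm_factors_have_unit_geometric_mean():
    rng = np.random.default_rng(1)
    counts = rng.negative_binomial(5, 0.05, size=(300, 8))
    f = norm_factors(counts)
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


def test_tmm_zero_total_sample_is_named():
    counts = pd.DataFrame({"good": [5, 5], "empty": [0, 0]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="empty"):
        norm_factors(counts)


def test_tmm_matches_edger(tmp_path):
    """Independent oracle: edgeR::calcNormFactors on the same matrix."""
    rng = np.random.default_rng(42)
    mu = rng.lognormal(4, 1.5, size=250)
    lib = rng.uniform(0.5, 2.0, size=10)
    counts = rng.negative_binomial(10, 10 / (10 + mu[:, None] * lib[None, :]))
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(250)],
                      columns=[f"s{j}" for j in range(10)])
    df.to_csv(tmp_path / "counts.tsv", sep="\t")
    script = f"""
    suppressMessages(library(edgeR))
    x <- as.matrix(read.table("{tmp_path}/counts.tsv", header=TRUE, row.names=1, sep="\\t"))
    nf <- calcNormFactors(DGEList(counts=x))$samples$norm.factors
    cat(nf, sep="\\n")
    """
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
    expected = np.array([float(v) for v in out.stdout.split()])
    assert np.allclose(norm_factors(df), expected, rtol=1e-6)


# ------------------------------------------------------- precision weights
def _homoskedastic_counts(n_genes=2000, n_samples=20, seed=0):
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(6, 12, size=n_genes)
    log2 = baseline[:, None] + rng.normal(0, 0.3, size=(n_genes, n_samples))
    return np.round(np.exp2(log2))


def test_weights_positive_and_flat_for_homoskedastic_data():
    counts = _homoskedastic_counts()
    design = np.column_stack([np.ones(20), np.repeat([0, 1], 10)])
    _, w = precision_weights(counts, np.ones(20), design)
    assert (w > 0).all()
    assert w.std() / w.mean() < 0.2


def test_weight_ordering_invariant_to_doubling_counts():
    # count data with a real mean-variance trend, so the ordering is informative
    rng = np.random.default_rng(5)
    mu = rng.lognormal(3, 1.5, size=400)
    counts = rng.negative_binomial(5, 5 / (5 + mu[:, None] * np.ones(20)))
    design = np.column_stack([np.ones(20), np.repeat([0, 1], 10)])
    _, w1 = precision_weights(counts, np.ones(20), design)
    _, w2 = precision_weights(counts * 2, np.ones(20), design)
    rho = stats.spearmanr(w1.ravel(), w2.ravel()).statistic
    assert rho > 0.99


def test_rank_deficient_design_reports_aliased_columns():
    counts = _homoskedastic_counts(n_genes=50)
    design = np.column_stack([np.ones(20), np.repeat([0, 1], 10), np.repeat([1, 0], 10)])
    with pytest.raises(ValueError, match="aliased"):
        precision_weights(counts, np.ones(20), design)


# --------------------------------------------------------- moderated fit
def _two_group_data(n_genes=200, n_per=50, seed=3):
    rng = np.random.default_rng(seed)
    y = rng.normal(5, 1, size=(n_genes, 2 * n_per))
    y[: n_genes // 4, n_per:] += 0.5
    design = np.column_stack([np.ones(2 * n_per), np.repeat([0, 1], n_per)])
    return y, design


def test_unmoderated_fit_equals_two_sample_t_test():
    """With unit weights and the prior switched off, the moderated machinery
    collapses onto the classical equal-variance two-sample t-test."""
    y, design = _two_group_data()
    res = fit_moderated(y, np.ones_like(y), design, np.array([0.0, 1.0]), prior_df=0)
    t = stats.ttest_ind(y[:, 50:], y[:, :50], axis=1, equal_var=True)
    assert np.allclose(res.table["p"], t.pvalue, rtol=1e-8)
    assert np.allclose(res.table["log2fc"], y[:, 50:].mean(1) - y[:, :50].mean(1), rtol=1e-8)


def test_default_moderation_close_to_t_test_at_large_n():
    y, design = _two_group_data(n_per=100)
    res = fit_moderated(y, np.ones_like(y), design, np.array([0.0, 1.0]))
    t = stats.ttest_ind(y[:, 100:], y[:, :100], axis=1, equal_var=True)
    rel = np.abs(res.table["p"].to_numpy() / t.pvalue - 1)
    assert np.median(rel) < 0.10


def test_infinite_prior_recovers_pooled_variance_closed_form():
    y, design = _two_group_data()
    res = fit_moderated(y, np.ones_like(y), design, np.array([0.0, 1.0]), prior_df=np.inf)
    n, p = y.shape[1], design.shape[1]
    resid = y - (design @ np.linalg.lstsq(design, y.T, rcond=None)[0]).T
    pooled = np.mean((resid ** 2).sum(1) / (n - p))
    lfc = res.table["log2fc"].to_numpy()
    se = np.sqrt(pooled * (1 / 50 + 1 / 50))
    expected = 2 * stats.norm.sf(np.abs(lfc / se))
    assert np.allclose(res.table["p"], expected, rtol=1e-8)


def test_prior_estimation_recovers_known_hyperparameters():
    rng = np.random.default_rng(9)
    d0_true, s02_true, df = 20.0, 2.0, 30
    # s2_g ~ s0^2 * F(df, d0) marginally under the inverse-chi-square prior
    s2 = s02_true * rng.f(df, d0_true, size=20000)
    d0, s02 = estimate_prior(s2, df)
    assert d0 == pytest.approx(d0_true, rel=0.15)
    assert s02 == pytest.approx(s02_true, rel=0.05)


def test_bh_adjustment_is_monotone_and_bounded():
    y, design = _two_group_data()
    res = fit_moderated(y, np.ones_like(y), design, np.array([0.0, 1.0]))
    tab = res.table.sort_values("p")
    assert (tab["fdr"].to_numpy() >= tab["p"].to_numpy() - 1e-12).all()
    assert (np.diff(tab["fdr"].to_numpy()) >= -1e-12).all()


def test_moderated_fit_matches_limma_voom(tmp_path):
    """Independent oracle: the voom/lmFit/eBayes chain run through Rscript."""
    rng = np.random.default_rng(42)
    mu = rng.lognormal(4, 1.5, size=300)
    lib = rng.uniform(0.5, 2.0, size=16)
    counts = rng.negative_binomial(10, 10 / (10 + mu[:, None] * lib[None, :]))
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(300)],
                      columns=[f"s{j}" for j in range(16)])
    df.to_csv(tmp_path / "counts.tsv", sep="\t")
    script = f"""
    suppressMessages({{library(edgeR); library(limma)}})
    x <- as.matrix(read.table("{tmp_path}/counts.tsv", header=TRUE, row.names=1, sep="\\t"))
    nf <- calcNormFactors(DGEList(counts=x))$samples$norm.factors
    design <- model.matrix(~factor(c(rep("a", 8), rep("b", 8))))
    v <- voom(DGEList(counts=x, norm.factors=nf), design)
    fit <- eBayes(lmFit(v, design))
    tt <- topTable(fit, coef=2, number=Inf, sort.by="none")
    write.table(data.frame(gene=rownames(tt), lfc=tt$logFC, p=tt$P.Value),
                "{tmp_path}/limma.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
    """
    subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
    oracle = pd.read_csv(tmp_path / "limma.tsv", sep="\t").set_index("gene")
    design = np.column_stack([np.ones(16), np.repeat([0, 1], 8)])
    factors = norm_factors(df)
    log_cpm, weights = precision_weights(df, factors, design)
    res = fit_moderated(log_cpm, weights, design, np.array([0.0, 1.0]), genes=df.index)
    assert np.allclose(res.table["log2fc"], oracle["lfc"], atol=5e-3)
    assert np.allclose(np.log10(res.table["p"]), np.log10(oracle["p"]), atol=0.02)


# ------------------------------------------------------------- pipelines
def test_daynight_recovers_planted_genes(small_sim):
    res = run_daynight(small_sim["matrix"], small_sim["metadata"])
    truth = small_sim["truth"]
    planted = [g for g in res.table.index if truth[g].effect_class == "daynight"]
    nulls = [g for g in res.table.index if truth[g].effect_class == "null"]
    assert res.table.loc[planted, "call_sensitive"].mean() > 0.8
    assert (res.table.loc[nulls, "p"] <= 0.05).mean() == pytest.approx(0.05, abs=0.03)


def test_daynight_relabeling_flips_every_fold_change(small_sim):
    meta = small_sim["metadata"]
    res = run_daynight(small_sim["matrix"], meta)
    flipped = meta.copy()
    swap = {8 * 60: 22 * 60, 22 * 60: 8 * 60}
    # move every donor to the opposite label, preserving day/night group sizes
    from chronotx.labels import classify_daynight

    labels = meta["time_of_death"].map(classify_daynight)
    flipped["daynight_label"] = labels.map({DAY: NIGHT, NIGHT: DAY, "twilight": "twilight"})
    res_flip = run_daynight(small_sim["matrix"], flipped)
    assert np.allclose(res.table["log2fc"], -res_flip.table["log2fc"], atol=1e-10)
    assert np.allclose(res.table["p"], res_flip.table["p"], atol=1e-12)


def test_daynight_needs_two_samples_per_group(small_sim):
    meta = small_sim["metadata"].copy()
    meta["time_of_death"] = 600  # everyone dies at 10:00
    with pytest.raises(ValueError):
        run_daynight(small_sim["matrix"], meta)


def test_seasonal_recovers_planted_direction(small_sim):
    truth = small_sim["truth"]
    res = {s: run_seasonal(small_sim["matrix"], small_sim["metadata"], season=s) for s in SEASONS}
    hits, total = 0, 0
    for g, t in truth.items():
        if t.effect_class != "seasonal" or g not in res[t.season_target].table.index:
            continue
        total += 1
        row = res[t.season_target].table.loc[g]
        expected_sign = 1 if t.direction == "up" else -1
        if row["call_sensitive"] and np.sign(row["log2fc"]) == expected_sign:
            hits += 1
    assert total > 10 and hits / total > 0.8
    # genes constant across seasons stay below the fold-change cut
    nulls = [g for g, t in truth.items() if t.effect_class == "null" and g in res["fall"].table.index]
    assert (res["fall"].table.loc[nulls, "log2fc"].abs() < 0.1).mean() > 0.85
    assert res["fall"].table.loc[nulls, "call_sensitive"].mean() < 0.1


def test_seasonal_one_vs_rest_estimates_sum_to_zero_when_balanced():
    rng = np.random.default_rng(11)
    n_per = 25
    y = rng.normal(0, 1, size=(100, 4 * n_per))
    groups = np.repeat(np.arange(4), n_per)
    total = np.zeros(100)
    for s in range(4):
        design = np.column_stack([np.ones(4 * n_per), (groups == s).astype(float)])
        res = fit_moderated(y, np.ones_like(y), design, np.array([0.0, 1.0]))
        total += res.table["log2fc"].to_numpy()
    assert np.allclose(total, 0.0, atol=1e-10)


def test_seasonal_rejects_absent_season(small_sim):
    meta = small_sim["metadata"].copy()
    meta["season"] = "winter"
    with pytest.raises(ValueError):
        run_seasonal(small_sim["matrix"], meta, season="summer")


def test_sex_specific_design_drops_sex_column(small_sim):
    meta = small_sim["metadata"]
    sm = meta.copy()
    sm["daynight_label"] = "day"
    group = (np.arange(len(sm)) % 2).astype(float)
    design, names, _ = build_design(sm, group, factor_covariate="season")
    assert "sex[male]" in names
    design2, names2, _ = build_design(sm, group, factor_covariate="season", sex_specific=True)
    assert "sex[male]" not in names2
    assert design.shape[1] == design2.shape[1] + 1
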