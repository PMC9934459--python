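"""Moderated differential expression with covariates.

The model is the standard precision-weighted limma-style chain for RNA-seq
counts: TMM scaling factors correct for library composition, log-CPM values
get inverse-variance precision weights from a smoothed mean-variance trend,
per-gene weighted least squares estimate the design coefficients, and an
empirical-Bayes scaled-inverse-chi-square prior shrinks the residual
variances before the moderated t-test.  All of it is implemented natively
(numpy/scipy/statsmodels); the smoothing span (0.5), the count offset (+0.5)
and the library offset (+1) follow the published defaults of that chain and
are recorded here as configuration constants.

Two contrast schemes are exposed: day vs night (twilight donors excluded,
season as a 4-level covariate) and one season vs the pooled others (all
donors, day/night/twilight as a 3-level covariate).  A positive log2
fold-change always means "up in day" or "up in the target season".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, compute_tpm, filter_expressed
from .labels import DAY, NIGHT, SEASONS, TWILIGHT

#: Sensitive call: raw p <= 0.05 and |log2FC| >= 0.1.
SENSITIVE_P = 0.05
MIN_ABS_LFC = 0.1
#: Strict call: Benjamini-Hochberg FDR <= 0.1.
STRICT_FDR = 0.1

LOWESS_SPAN = 0.5
COUNT_OFFSET = 0.5
LIB_OFFSET = 1.0

NUMERIC_COVARIATES = ("age", "bmi", "postmortem_interval")


@dataclass
class DEResult:
    """Per-gene results for one contrast in one tissue.

    ``table`` is indexed by gene with columns ``log2fc``, ``p``, ``fdr``,
    ``mean_expr``, ``call_sensitive`` and ``call_strict``; both call flags
    are recomputable from the stored columns.
    """

    table: pd.DataFrame
    tissue: str = "tissue"
    contrast: str = ""
    prior_df: float = np.nan
    prior_var: float = np.nan

    @property
    def sensitive_genes(self) -> pd.Index:
        return self.table.index[self.table["call_sensitive"]]

    @property
    def strict_genes(self) -> pd.Index:
        return self.table.index[self.table["call_strict"]]

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index()


# ----------------------------------------------------------------- TMM
def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              log_ratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    mask = (obs > 0) & (ref > 0)
    if mask.sum() == 0:
        return 1.0
    o, r = obs[mask] / n_obs, ref[mask] / n_ref
    m = np.log2(o / r)                       # M-values: composition log-ratios
    a = 0.5 * np.log2(o * r)                 # A-values: average abundance
    w = (n_obs - obs[mask]) / (n_obs * obs[mask]) + (n_ref - ref[mask]) / (n_ref * ref[mask])
    if np.abs(m).max() < 1e-6:
        return 1.0
    n = len(m)
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if keep.sum() == 0 or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def norm_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile of library-scaled
    counts is closest to the mean upper-quartile; 30% of M-values and 5% of
    A-values are trimmed on each side, and the remaining M-values averaged
    with inverse asymptotic-variance weights.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >= 2 samples")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        names = (
            list(counts.columns[lib == 0])
            if isinstance(counts, pd.DataFrame)
            else list(np.flatnonzero(lib == 0))
        )
        raise ValueError(f"sample(s) with zero total counts: {names[:5]}")
    f75 = np.array([np.quantile(y[:, s] / lib[s], 0.75) for s in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [1.0 if s == ref else _tmm_pair(y[:, s], y[:, ref], lib[s], lib[ref]) for s in range(y.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ------------------------------------------------------- precision weights
def _check_full_rank(design: np.ndarray, names: list[str] | None = None) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        aliased: list[str] = []
        cols = [0]
        for j in range(1, design.shape[1]):
            trial = design[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols):
                aliased.append(names[j] if names else str(j))
            else:
                cols.append(j)
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def _ols_batch(y: np.ndarray, design: np.ndarray):
    """OLS of every gene (rows of y) on a shared design. Returns beta, fitted, s."""
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    fitted = (design @ beta).T
    resid = y - fitted
    df = y.shape[1] - design.shape[1]
    s2 = (resid ** 2).sum(axis=1) / df
    return beta.T, fitted, np.sqrt(s2)


def precision_weights(
    counts: pd.DataFrame | np.ndarray,
    factors: np.ndarray,
    design: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-CPM values and inverse-variance precision weights.

    ``log_cpm = log2((count + 0.5) / (lib * factor + 1) * 1e6)``.  The square
    root of the per-gene residual standard deviation is smoothed against mean
    log2 count with lowess (span 0.5); each observation's weight is the trend
    value at its fitted log-count raised to the -4th power, i.e. the inverse
    of the trend variance.
    """
    y = np.asarray(counts, dtype=float)
    n_samples = y.shape[1]
    if design.shape[0] != n_samples:
        raise ValueError("design rows must match sample count")
    if n_samples <= design.shape[1]:
        raise ValueError("need more samples than design coefficients")
    _check_full_rank(design)

    lib = y.sum(axis=0) * np.asarray(factors, dtype=float)
    log_cpm = np.log2((y + COUNT_OFFSET) / (lib + LIB_OFFSET)[None, :] * 1e6)

    _, fitted, sigma = _ols_batch(log_cpm, design)

    # mean log2 count per gene (log-cpm shifted back by the geometric-mean library size)
    mean_log_count = log_cpm.mean(axis=1) + np.mean(np.log2(lib + LIB_OFFSET)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    ok = sigma > 1e-10
    trend = lowess(sy[ok], mean_log_count[ok], frac=LOWESS_SPAN, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    tx, idx = np.unique(tx, return_index=True)
    ty = ty[idx]

    fitted_log_count = fitted + (np.log2(lib + LIB_OFFSET) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_log_count, tx, ty)
    pred = np.maximum(pred, 1e-4)
    weights = pred ** -4.0
    return log_cpm, weights


# ----------------------------------------------------- moderated statistics
def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F distribution to the residual variances.

    Returns (d0, s0^2): prior degrees of freedom (may be inf) and prior
    variance of the inverse-chi-square prior on gene variances.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = len(e)
    emean = e.mean()
    evar = np.sum((e - emean) ** 2) / (n - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s02 = np.exp(emean)
    return float(d0), float(s02)


def fit_moderated(
    log_cpm: np.ndarray,
    weights: np.ndarray,
    design: np.ndarray,
    contrast: np.ndarray,
    genes: pd.Index | None = None,
    tissue: str = "tissue",
    contrast_name: str = "",
    prior_df: float | None = None,
) -> DEResult:
    """Weighted least squares + empirical-Bayes moderated t per gene.

    Parameters
    ----------
    log_cpm, weights
        Gene x sample arrays from :func:`precision_weights`.
    design
        Sample x coefficient matrix (full rank).
    contrast
        Coefficient-space vector whose estimate is reported as log2FC.
    prior_df
        Force the prior degrees of freedom (``np.inf`` recovers the fully
        pooled limit); estimated from the data when None.
    """
    y = np.asarray(log_cpm, dtype=float)
    w = np.asarray(weights, dtype=float)
    x = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    n, p = x.shape
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom; need replication")
    _check_full_rank(x)

    # batched weighted least squares: (X'WX) b = X'Wy per gene
    xtwx = np.einsum("ni,gn,nj->gij", x, w, x)
    xtwy = np.einsum("ni,gn,gn->gi", x, w, y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    resid = y - beta @ x.T
    s2 = np.einsum("gn,gn->g", w, resid ** 2) / df

    # unscaled variance of the contrast estimate: c' (X'WX)^-1 c
    sol = np.linalg.solve(xtwx, np.broadcast_to(c, (y.shape[0], p))[..., None])
    var_unscaled = np.maximum((sol[:, :, 0] * c).sum(axis=1), 1e-300)

    if prior_df is None:
        d0, s02 = estimate_prior(s2, df)
    else:
        d0 = float(prior_df)
        s02 = float(np.mean(s2)) if np.isinf(d0) else estimate_prior(s2, df)[1]

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df

    lfc = beta @ c
    tstat = lfc / np.sqrt(var_unscaled * s2_post)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    pvals = np.clip(pvals, 0.0, 1.0)
    fdr = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": pvals,
            "fdr": fdr,
            "mean_expr": y.mean(axis=1),
        },
        index=genes if genes is not None else pd.RangeIndex(y.shape[0]),
    )
    table.index.name = "gene"
    table["call_sensitive"] = (table["p"] <= SENSITIVE_P) & (table["log2fc"].abs() >= MIN_ABS_LFC)
    table["call_strict"] = table["fdr"] <= STRICT_FDR
    return DEResult(table=table, tissue=tissue, contrast=contrast_name, prior_df=d0, prior_var=s02)


# ----------------------------------------------------------- design builder
def build_design(
    sample_meta: pd.DataFrame,
    group: np.ndarray,
    factor_covariate: str | None,
    sex_specific: bool = False,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix: intercept + group indicator + covariates.

    ``group`` is a 0/1 indicator (1 = day, or 1 = target season) whose
    coefficient is the reported contrast.  Categorical covariates use
    treatment coding with the alphabetically first level as reference; sex is
    dropped for sex-specific tissues.
    """
    n = len(sample_meta)
    cols: list[np.ndarray] = [np.ones(n), np.asarray(group, dtype=float)]
    names = ["intercept", "group"]
    if factor_covariate is not None:
        levels = sorted(sample_meta[factor_covariate].unique())
        for lev in levels[1:]:
            cols.append((sample_meta[factor_covariate] == lev).to_numpy(dtype=float))
            names.append(f"{factor_covariate}[{lev}]")
    if not sex_specific and sample_meta["sex"].nunique() > 1:
        cols.append((sample_meta["sex"] == "male").to_numpy(dtype=float))
        names.append("sex[male]")
    for cov in NUMERIC_COVARIATES:
        cols.append(sample_meta[cov].to_numpy(dtype=float))
        names.append(cov)
    design = np.column_stack(cols)
    _check_full_rank(design, names)
    contrast = np.zeros(design.shape[1])
    contrast[1] = 1.0
    return design, names, contrast


def _sample_metadata(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample covariate table via the sample -> donor map."""
    missing = set(matrix.sample_donor) - set(metadata.index)
    if missing:
        raise ValueError(f"donors missing from metadata: {sorted(missing)[:5]}")
    sm = metadata.loc[matrix.sample_donor.to_numpy()].copy()
    sm.index = matrix.samples
    if "daynight_label" not in sm.columns:
        from .labels import classify_daynight

        sm["daynight_label"] = [classify_daynight(t) for t in sm["time_of_death"]]
    return sm


# -------------------------------------------------------------- pipelines
def run_daynight(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    sex_specific: bool = False,
) -> DEResult:
    """Day vs night contrast for one tissue.

    Twilight samples are excluded, the expression filter (median TPM >= 1) is
    taken over the day+night samples only, and season enters as a 4-level
    covariate.  Positive log2FC = higher during the day (diurnal).
    """
    sm = _sample_metadata(matrix, metadata)
    keep = sm.index[sm["daynight_label"].isin([DAY, NIGHT])]
    sub = matrix.subset_samples(keep)
    sm = sm.loc[keep]
    n_day = int((sm["daynight_label"] == DAY).sum())
    n_night = int((sm["daynight_label"] == NIGHT).sum())
    if n_day < 2 or n_night < 2:
        raise ValueError(f"need >= 2 samples per group, got day={n_day}, night={n_night}")

    genes = filter_expressed(compute_tpm(sub), sub.samples)
    sub = sub.subset_genes(genes)

    factors = norm_factors(sub.counts)
    group = (sm["daynight_label"] == DAY).to_numpy(dtype=float)
    design, _, contrast = build_design(sm, group, factor_covariate="season", sex_specific=sex_specific)
    log_cpm, weights = precision_weights(sub.counts, factors, design)
    return fit_moderated(
        log_cpm, weights, design, contrast,
        genes=genes, tissue=matrix.tissue, contrast_name="day_vs_night",
    )


def run_seasonal(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    season: str,
    sex_specific: bool = False,
) -> DEResult:
    """One season vs the pooled others for one tissue.

    All samples (twilight included) are used; day/night/twilight enters as a
    3-level covariate.  Positive log2FC = up in the target season.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season: {season!r}")
    sm = _sample_metadata(matrix, metadata)
    if (sm["season"] == season).sum() == 0:
        raise ValueError(f"season {season!r} absent from the cohort")

    genes = filter_expressed(compute_tpm(matrix), matrix.samples)
    sub = matrix.subset_genes(genes)

    factors = norm_factors(sub.counts)
    group = (sm["season"] == season).to_numpy(dtype=float)
    design, _, contrast = build_design(sm, group, factor_covariate="daynight_label", sex_specific=sex_specific)
    log_cpm, weights = precision_weights(sub.counts, factors, design)
    return fit_moderated(
        log_cpm, weights, design, contrast,
        genes=genes, tissue=matrix.tissue, contrast_name=f"{season}_vs_rest",
    )
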