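"""Sliding 6-hour window-pair scan defining "circadian-like" genes.

Twelve window pairs [i, i+6) vs [i+12, i+18) hours (mod 24), one per hourly
step i = 0..11, each contrasted with the same moderated model used for the
day-night analysis (times define the groups, so the day/night label drops out
of the covariates while season stays).  Per gene, the 12 nominal p-values are
BH-adjusted; a gene is circadian-like if any pair reaches adjusted p <= 0.05
with |log2FC| >= 0.1.  Pair i and pair i+6 test the same two arcs with the
groups swapped, so only arc-distinct pairs carry independent information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import (
    MIN_ABS_LFC,
    build_design,
    fit_moderated,
    norm_factors,
    precision_weights,
    _sample_metadata,
)
from .expression import ExpressionMatrix, compute_tpm, filter_expressed

N_PAIRS = 12
WINDOW_H = 6
ADJ_P_CUT = 0.05


@dataclass(frozen=True)
class WindowPair:
    """Group A arc [i, i+6) and group B arc [i+12, i+18), hours mod 24."""

    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_PAIRS:
            raise ValueError(f"pair index must be in 0..{N_PAIRS - 1}")

    @property
    def arc_a(self) -> tuple[float, float]:
        return (self.index, self.index + WINDOW_H)

    @property
    def arc_b(self) -> tuple[float, float]:
        return (self.index + 2 * WINDOW_H, self.index + 3 * WINDOW_H)


def _in_arc(times: np.ndarray, start: float, end: float) -> np.ndarray:
    """Half-open arc membership on the 24-h circle."""
    t = np.mod(times, 24.0)
    s, e = np.mod(start, 24.0), np.mod(end, 24.0)
    if s < e:
        return (t >= s) & (t < e)
    return (t >= s) | (t < e)


def assign_window_groups(times_hours: np.ndarray, pair: WindowPair) -> np.ndarray:
    """Label each time A, B or excluded for one window pair."""
    times_hours = np.asarray(times_hours, dtype=float)
    if ((times_hours < 0) | (times_hours >= 24)).any():
        raise ValueError("times must be in [0, 24) hours")
    out = np.full(times_hours.shape, "excluded", dtype=object)
    out[_in_arc(times_hours, *pair.arc_a)] = "A"
    out[_in_arc(times_hours, *pair.arc_b)] = "B"
    return out


def _bh_rows(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up applied independently to every row."""
    g, m = p.shape
    order = np.argsort(p, axis=1)
    ranked = np.take_along_axis(p, order, axis=1)
    adj = ranked * m / np.arange(1, m + 1)[None, :]
    adj = np.minimum.accumulate(adj[:, ::-1], axis=1)[:, ::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty_like(adj)
    np.put_along_axis(out, order, adj, axis=1)
    return out


def circadian_like_scan(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    sex_specific: bool = False,
    return_details: bool = False,
):
    """Run the 12-pair scan for one tissue.

    The expression filter is computed once from the whole tissue (one filter,
    twelve tests).  Pairs with fewer than two samples in either arc are
    skipped and recorded in the per-pair summary.

    Returns
    -------
    per_gene : DataFrame indexed by gene
        ``min_adj_p``, ``best_pair``, ``best_log2fc``, ``n_significant_pairs``
        and the ``circadian_like`` flag.
    per_pair : DataFrame indexed by pair
        group sizes, number of significant genes, and a ``skipped`` flag.
    """
    sm = _sample_metadata(matrix, metadata)
    genes = filter_expressed(compute_tpm(matrix), matrix.samples)
    times = sm["time_of_death"].to_numpy(dtype=float) / 60.0

    pvals = np.full((len(genes), N_PAIRS), np.nan)
    lfcs = np.full((len(genes), N_PAIRS), np.nan)
    pair_rows = []
    for i in range(N_PAIRS):
        pair = WindowPair(i)
        groups = assign_window_groups(times, pair)
        include = groups != "excluded"
        n_a, n_b = int((groups == "A").sum()), int((groups == "B").sum())
        if n_a < 2 or n_b < 2:
            pair_rows.append({"pair": i, "n_a": n_a, "n_b": n_b, "n_significant": 0, "skipped": True})
            continue
        sub = matrix.subset_genes(genes).subset_samples(matrix.samples[include])
        sm_sub = sm.loc[sub.samples]
        factors = norm_factors(sub.counts)
        group = (groups[include] == "A").astype(float)
        design, _, contrast = build_design(sm_sub, group, factor_covariate="season", sex_specific=sex_specific)
        log_cpm, weights = precision_weights(sub.counts, factors, design)
        res = fit_moderated(
            log_cpm, weights, design, contrast,
            genes=genes, tissue=matrix.tissue, contrast_name=f"window_{i}",
        )
        pvals[:, i] = res.table["p"].to_numpy()
        lfcs[:, i] = res.table["log2fc"].to_numpy()
        pair_rows.append({"pair": i, "n_a": n_a, "n_b": n_b, "n_significant": 0, "skipped": False})

    run = ~np.isnan(pvals).all(axis=0)
    adj = np.full_like(pvals, np.nan)
    if run.any():
        adj[:, run] = _bh_rows(pvals[:, run])

    sig = (adj <= ADJ_P_CUT) & (np.abs(lfcs) >= MIN_ABS_LFC)
    per_pair = pd.DataFrame(pair_rows).set_index("pair")
    per_pair["n_significant"] = np.nansum(sig, axis=0).astype(int)

    with np.errstate(invalid="ignore"):
        # rank pairs by adjusted then nominal p so ties break deterministically
        key = np.where(np.isnan(adj), np.inf, adj) + 1e-12 * np.where(np.isnan(pvals), np.inf, pvals)
    best = np.argmin(key, axis=1)
    per_gene = pd.DataFrame(
        {
            "min_adj_p": np.nanmin(np.where(np.isnan(adj), np.inf, adj), axis=1),
            "best_pair": best,
            "best_log2fc": lfcs[np.arange(len(genes)), best],
            "n_significant_pairs": sig.sum(axis=1).astype(int),
        },
        index=genes,
    )
    per_gene["circadian_like"] = per_gene["n_significant_pairs"] > 0
    if return_details:
        details = {
            "p": pd.DataFrame(pvals, index=genes),
            "log2fc": pd.DataFrame(lfcs, index=genes),
            "adj_p": pd.DataFrame(adj, index=genes),
        }
        return per_gene, per_pair, details
    return per_gene, per_pair


def pair_contains_phase(pair_index: int, phase_hours: float, slack_hours: float = 0.0) -> bool:
    """True if either arc of the pair contains the phase, with circular slack."""
    pair = WindowPair(pair_index)
    for start, end in (pair.arc_a, pair.arc_b):
        s, e = start - slack_hours, end + slack_hours
        if _in_arc(np.array([phase_hours]), s, e)[0]:
            return True
    return False
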