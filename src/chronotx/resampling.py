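"""Permutation and constrained-randomization null constructions.

Two bespoke nulls support the pipeline.  First, label permutation: the
day/night/twilight (or one-season-vs-rest) labels are shuffled before any
filtering, preserving the label multiset exactly, and the whole differential
pipeline (twilight removal, median-TPM filter, moderated DE) is re-run per
permutation; the median permuted call count is the reference the observed
count is compared against.  Second, the cell-type-marker randomization:
observed up/down marker instances are redistributed uniformly over the
region x season grid, rejecting assignments that put both signs in one cell
for a cell type (the observed data never mix signs within a cell), and the
empirical tail probability of each cell's count is Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexp import DEResult, run_daynight, run_seasonal
from .expression import ExpressionMatrix
from .labels import DAY, NIGHT, TWILIGHT

#: Default replication counts (tests and examples scale these down).
DEFAULT_N_PERMUTATIONS = 1_000
DEFAULT_N_RANDOMIZATIONS = 1_000_000

#: Marker panel sizes per brain cell type.
DEFAULT_PANEL_SIZES = {
    "Astrocyte": 10,
    "Endothelial": 10,
    "Microglia": 9,
    "Neuron": 11,
    "Oligodendrocyte": 10,
}


def permute_labels(labels: Sequence, seed: int) -> np.ndarray:
    """Uniform random permutation of a label vector; counts preserved."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two distinct labels")
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(len(labels))]


def seasonal_label_permutation(labels_one_vs_rest: Sequence, seed: int) -> np.ndarray:
    """Permute a binarized season-of-interest vs rest labelling."""
    return permute_labels(labels_one_vs_rest, seed)


def permutation_null(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    mode: str = "daynight",
    season: str | None = None,
    sex_specific: bool = False,
) -> dict:
    """Label-permutation null distribution of the sensitive DE-gene count.

    Labels are shuffled *before* any filtering: each permutation reassigns
    the day/night/twilight labels (or the season labels) across donors, then
    twilight removal, the median-TPM filter and the moderated DE run are all
    repeated from scratch.

    Returns a dict with the observed count, the per-permutation counts, their
    median, and the per-gene empirical frequency of a nominal p <= 0.05 over
    the permutations (the permutation empirical CDF input).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("daynight", "seasonal"):
        raise ValueError(f"mode must be daynight or seasonal, got {mode!r}")
    if mode == "seasonal" and season is None:
        raise ValueError("seasonal mode needs a season")

    meta = metadata.copy()
    if "daynight_label" not in meta.columns:
        from .labels import classify_daynight

        meta["daynight_label"] = [classify_daynight(t) for t in meta["time_of_death"]]

    def _run(m: pd.DataFrame) -> DEResult:
        if mode == "daynight":
            return run_daynight(matrix, m, sex_specific=sex_specific)
        return run_seasonal(matrix, m, season=season, sex_specific=sex_specific)

    observed = _run(meta)
    n_observed = int(observed.table["call_sensitive"].sum())

    counts = np.empty(n_perm, dtype=int)
    sig_freq: dict = {}
    for b in range(n_perm):
        perm_meta = meta.copy()
        sub_seed = int(np.random.default_rng([seed, b]).integers(2**31))
        if mode == "daynight":
            perm_meta["daynight_label"] = permute_labels(meta["daynight_label"].to_numpy(), seed=sub_seed)
        else:
            binary = (meta["season"] == season).to_numpy()
            perm = seasonal_label_permutation(binary, seed=sub_seed)
            perm_meta["season"] = np.where(perm, season, "rest")
        res = _run(perm_meta)
        counts[b] = int(res.table["call_sensitive"].sum())
        hit = res.table.index[res.table["p"] <= 0.05]
        for g in hit:
            sig_freq[g] = sig_freq.get(g, 0) + 1

    per_gene = pd.Series(sig_freq, dtype=float) / n_perm
    return {
        "observed": n_observed,
        "null_counts": counts,
        "null_median": float(np.median(counts)),
        "per_gene_p05_frequency": per_gene.sort_index(),
        "observed_result": observed,
    }


# ----------------------------------------------------- marker randomization
def _validate_marker_table(table: pd.DataFrame) -> None:
    required = {"cell_type", "region", "season", "direction", "count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    if not set(table["direction"]) <= {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    wide = table.pivot_table(
        index=["cell_type", "region", "season"], columns="direction", values="count", aggfunc="sum", fill_value=0
    )
    if "up" in wide.columns and "down" in wide.columns:
        mixed = (wide["up"] > 0) & (wide["down"] > 0)
        if mixed.any():
            raise ValueError(
                "observed table mixes up and down instances within a region-season cell: "
                f"{list(wide.index[mixed])[:3]}"
            )


def _draw_valid(
    n_up: int, n_down: int, n_cells: int, n_rand: int, rng: np.random.Generator,
    scheme: str = "instance", max_rounds: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomized (up, down) counts per cell, conditioned on sign exclusivity.

    ``instance`` (default): every instance lands in a uniformly random cell;
    draws with a mixed-sign cell are rejected and redrawn.  ``cell_sign``:
    cells are first assigned a sign uniformly, then each instance lands in a
    uniformly random cell of its sign.
    """
    p = np.full(n_cells, 1.0 / n_cells)
    up = np.empty((n_rand, n_cells), dtype=np.int64)
    down = np.empty((n_rand, n_cells), dtype=np.int64)
    if scheme == "cell_sign":
        for i in range(n_rand):
            sign = rng.random(n_cells) < 0.5  # True = up-eligible
            if not sign.any() or sign.all():
                sign[rng.integers(n_cells)] = not sign[0] if sign.all() else True
            pu = sign / sign.sum()
            pd_ = (~sign) / (~sign).sum()
            up[i] = rng.multinomial(n_up, pu)
            down[i] = rng.multinomial(n_down, pd_)
        return up, down
    if scheme != "instance":
        raise ValueError(f"unknown scheme {scheme!r}")
    pending = np.arange(n_rand)
    rounds = 0
    while len(pending):
        u = rng.multinomial(n_up, p, size=len(pending))
        d = rng.multinomial(n_down, p, size=len(pending))
        valid = ~((u > 0) & (d > 0)).any(axis=1)
        idx = pending[valid]
        up[idx] = u[valid]
        down[idx] = d[valid]
        pending = pending[~valid]
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError("rejection sampling failed to terminate; acceptance probability too low")
    return up, down


@dataclass
class RandomizationReport:
    """Observed statistics, null draws and empirical p-values."""

    per_cell: pd.DataFrame
    per_row: pd.DataFrame
    n_randomizations: int
    n_tests_cell: int
    n_tests_row: int


def marker_randomization_test(
    table: pd.DataFrame,
    n_rand: int = DEFAULT_N_RANDOMIZATIONS,
    seed: int = 0,
    scheme: str = "instance",
    n_tests_cell: int | None = None,
    n_tests_row: int | None = None,
) -> RandomizationReport:
    """Constrained randomization test of marker up/down instances.

    Parameters
    ----------
    table
        Long TSV-style table with columns cell_type, region, season,
        direction (up/down), count.  Within one (cell_type, region, season)
        cell the observed counts must be single-signed.
    n_rand
        Randomization draws (study scale: 1,000,000).
    n_tests_cell, n_tests_row
        Bonferroni factors; default = number of region x season x cell-type
        cells (study: 260) and season x cell-type rows (study: 20).

    The empirical p is the fraction of randomizations with a count >= the
    observed one (no +1 correction), per cell for the observed sign, and per
    all-regions row (summing instances across regions) for each sign.
    """
    _validate_marker_table(table)
    rng = np.random.default_rng(seed)

    regions = sorted(table["region"].unique())
    seasons = sorted(table["season"].unique())
    cells = [(r, s) for r in regions for s in seasons]
    cell_index = {c: i for i, c in enumerate(cells)}
    n_cells = len(cells)

    per_cell_rows = []
    per_row_rows = []
    for cell_type, sub in table.groupby("cell_type"):
        obs_up = np.zeros(n_cells, dtype=int)
        obs_down = np.zeros(n_cells, dtype=int)
        for _, row in sub.iterrows():
            i = cell_index[(row["region"], row["season"])]
            if row["direction"] == "up":
                obs_up[i] += int(row["count"])
            else:
                obs_down[i] += int(row["count"])
        n_up, n_down = int(obs_up.sum()), int(obs_down.sum())
        rand_up, rand_down = _draw_valid(n_up, n_down, n_cells, n_rand, rng, scheme=scheme)

        # explicitly listed zero-count rows still get a (trivial) p of 1
        listed = {(r["region"], r["season"], r["direction"]) for _, r in sub.iterrows()}
        for (region, season), i in cell_index.items():
            for sign, obs, rand in (("up", obs_up[i], rand_up[:, i]), ("down", obs_down[i], rand_down[:, i])):
                if obs == 0 and (region, season, sign) not in listed:
                    continue
                p = 1.0 if obs == 0 else float(np.mean(rand >= obs))
                per_cell_rows.append(
                    {
                        "cell_type": cell_type, "region": region, "season": season,
                        "direction": sign, "observed": int(obs), "p": p,
                    }
                )
        # all-regions rows: sum instances across regions per season
        season_cols = {s: [cell_index[(r, s)] for r in regions] for s in seasons}
        for season, cols in season_cols.items():
            for sign, obs_v, rand_v in (
                ("up", obs_up[cols].sum(), rand_up[:, cols].sum(axis=1)),
                ("down", obs_down[cols].sum(), rand_down[:, cols].sum(axis=1)),
            ):
                if obs_v == 0:
                    continue
                p = float(np.mean(rand_v >= obs_v))
                per_row_rows.append(
                    {"cell_type": cell_type, "season": season, "direction": sign, "observed": int(obs_v), "p": p}
                )

    n_cell_tests = n_tests_cell if n_tests_cell is not None else n_cells * table["cell_type"].nunique()
    n_row_tests = n_tests_row if n_tests_row is not None else len(seasons) * table["cell_type"].nunique()
    per_cell = pd.DataFrame(per_cell_rows, columns=["cell_type", "region", "season", "direction", "observed", "p"])
    per_row = pd.DataFrame(per_row_rows, columns=["cell_type", "season", "direction", "observed", "p"])
    per_cell["p_bonferroni"] = np.minimum(per_cell["p"] * n_cell_tests, 1.0) if len(per_cell) else per_cell.get("p")
    per_row["p_bonferroni"] = np.minimum(per_row["p"] * n_row_tests, 1.0) if len(per_row) else per_row.get("p")
    return RandomizationReport(
        per_cell=per_cell,
        per_row=per_row,
        n_randomizations=n_rand,
        n_tests_cell=n_cell_tests,
        n_tests_row=n_row_tests,
    )


def enumerate_marker_null(n_up: int, n_down: int, n_cells: int):
    """Exhaustive enumeration of valid instance assignments (tiny grids only).

    Yields (up_counts, down_counts) tuples with uniform probability over the
    *accepted* assignments — the exact null the rejection sampler targets.
    """
    from itertools import product

    total = n_cells ** (n_up + n_down)
    if total > 5_000_000:
        raise ValueError("grid too large for enumeration")
    for assign in product(range(n_cells), repeat=n_up + n_down):
        up = np.bincount(assign[:n_up], minlength=n_cells)
        down = np.bincount(assign[n_up:], minlength=n_cells)
        if ((up > 0) & (down > 0)).any():
            continue
        yield up, down
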