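"""Cross-species and cross-set comparison statistics.

Human day/night calls are compared with rhythm evidence from another species
(a direction, or a peak phase in hours mapped through the human day/night
clock intervals); an exact one-sided binomial test asks whether similar or
opposite behavior dominates.  Set overlaps are summarized by the Simpson
(overlap) coefficient and an exact one-sided Fisher/hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .labels import DAY, NIGHT, TWILIGHT, classify_daynight


@dataclass(frozen=True)
class PairClassification:
    status: str            # "similar" / "opposite" / "excluded"
    other_direction: str | None = None
    reason: str | None = None


def phase_to_daynight(phase_hours: float) -> str:
    """Map a peak phase (hours) to day/night/twilight via the clock intervals."""
    return classify_daynight((phase_hours % 24.0) * 60.0)


def classify_pair(human_dir: str, other: float | str) -> PairClassification:
    """Classify one gene-tissue pair as similar or opposite across species.

    ``other`` is either an explicit direction ("day"/"night") or a peak phase
    in hours; twilight phases cannot be binned and exclude the pair (the
    exclusion is recorded so the pair count stays auditable).  Only pairs
    significant in both species should reach this function.
    """
    if human_dir not in (DAY, NIGHT):
        raise ValueError(f"human direction must be day or night, got {human_dir!r}")
    if isinstance(other, str):
        other_dir = other
        if other_dir not in (DAY, NIGHT):
            raise ValueError(f"other-species direction must be day or night, got {other!r}")
    else:
        other_dir = phase_to_daynight(float(other))
        if other_dir == TWILIGHT:
            return PairClassification("excluded", None, "twilight phase")
    return PairClassification(
        "similar" if other_dir == human_dir else "opposite",
        other_dir,
    )


def classify_pairs(table: pd.DataFrame, human_col: str = "human_direction", other_col: str = "other") -> pd.DataFrame:
    """Vector version of :func:`classify_pair` over a pair table."""
    out = table.copy()
    cls = [classify_pair(h, o) for h, o in zip(out[human_col], out[other_col])]
    out["classification"] = [c.status for c in cls]
    out["other_direction"] = [c.other_direction for c in cls]
    return out


def binomial_concordance(n_similar: int, n_opposite: int, direction: str = "excess_similar") -> float:
    """Exact one-sided binomial tail for a concordance count.

    ``P(X >= k)`` with ``X ~ Binomial(n_similar + n_opposite, 0.5)`` and k the
    count in the requested direction.
    """
    n = n_similar + n_opposite
    if n < 1:
        raise ValueError("need at least one classified pair")
    if direction == "excess_similar":
        k = n_similar
    elif direction == "excess_opposite":
        k = n_opposite
    else:
        raise ValueError(f"direction must be excess_similar or excess_opposite, got {direction!r}")
    return float(stats.binom.sf(k - 1, n, 0.5))


def simpson_index(set_a: Iterable, set_b: Iterable) -> float:
    """Overlap coefficient |A n B| / min(|A|, |B|)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("both sets must be non-empty")
    return len(a & b) / min(len(a), len(b))


def simpson_from_sizes(size_a: int, size_b: int, intersection: int) -> float:
    if min(size_a, size_b) < 1:
        raise ValueError("both sets must be non-empty")
    if intersection > min(size_a, size_b):
        raise ValueError("intersection cannot exceed the smaller set")
    return intersection / min(size_a, size_b)


def fisher_overlap(set_a: Iterable, set_b: Iterable, universe: Iterable) -> float:
    """One-sided over-enrichment p for the overlap of two gene sets.

    Exact hypergeometric tail P(|A n B| >= observed) with both sets drawn
    from the stated universe.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both sets must be subsets of the universe")
    return fisher_overlap_from_sizes(len(u), len(a), len(b), len(a & b))


def fisher_overlap_from_sizes(n_universe: int, size_a: int, size_b: int, intersection: int) -> float:
    return float(stats.hypergeom.sf(intersection - 1, n_universe, size_a, size_b))


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Generic two-sided two-sample proportion test (chi-square without
    continuity correction), provided for set-vs-genome rate comparisons."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    return float(stats.chi2_contingency(table, correction=False)[1])
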