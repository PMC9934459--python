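"""Cross-tissue aggregation of per-tissue direction calls.

Each gene's per-tissue calls form a signed direction profile (+1 = day or
season-up, -1 = night or season-down, 0 = not called).  Exact two-sided
binomial tests on the profile — over all tissues, over brain regions only,
and over non-brain tissues only — define the high-confidence gene sets; with
a fair-coin null, full consistency across at least six tissues is needed to
reach p <= 0.05.  A consistency-ratio test checks, per number of called
tissues, whether genes are more often one-sided (day fraction < 0.25 or
> 0.75) than a fair coin allows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import DEResult

SCOPES = ("all", "non_brain", "brain")
HC_ALPHA = 0.05


def default_brain_classifier(tissue: str) -> bool:
    """GTEx-style convention: tissue names beginning with "Brain"."""
    return tissue.startswith("Brain")


def build_profiles(
    de_results: Mapping[str, DEResult],
    brain_tissues: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Signed per-tissue call pattern per gene.

    Parameters
    ----------
    de_results
        Tissue name -> DEResult for one contrast family (day-night, or one
        season).  The sign comes from log2FC of the sensitive calls.
    brain_tissues
        Tissues counted as brain; defaults to names beginning "Brain".

    Returns
    -------
    DataFrame indexed by gene with one signed column per tissue plus
    ``n_called``, ``k_positive`` and the per-scope (k, n) counts.  Genes never
    called anywhere are dropped (they enter no test).
    """
    if not isinstance(de_results, Mapping):
        pairs = list(de_results)
        tissues = [t for t, _ in pairs]
        if len(set(tissues)) != len(tissues):
            raise ValueError("duplicate tissue names")
        de_results = dict(pairs)
    tissues = list(de_results)
    if brain_tissues is None:
        brain = {t for t in tissues if default_brain_classifier(t)}
    else:
        brain = set(brain_tissues)

    signs = {}
    for tissue, res in de_results.items():
        tab = res.table
        s = pd.Series(0, index=tab.index, dtype=int)
        called = tab["call_sensitive"]
        s[called] = np.where(tab.loc[called, "log2fc"] > 0, 1, -1)
        signs[tissue] = s
    prof = pd.DataFrame(signs).fillna(0).astype(int)
    prof = prof[(prof != 0).any(axis=1)]
    prof.index.name = "gene"

    mat = prof.to_numpy()
    is_brain = np.array([t in brain for t in prof.columns])
    prof["n_called"] = (mat != 0).sum(axis=1)
    prof["k_positive"] = (mat > 0).sum(axis=1)
    prof["n_brain"] = (mat[:, is_brain] != 0).sum(axis=1)
    prof["k_brain"] = (mat[:, is_brain] > 0).sum(axis=1)
    prof["n_non_brain"] = prof["n_called"] - prof["n_brain"]
    prof["k_non_brain"] = prof["k_positive"] - prof["k_brain"]
    return prof


def two_sided_binomial(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p: sum of outcomes no more probable than k."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def min_tissues_for_significance(alpha: float = HC_ALPHA) -> int:
    """Smallest n for which full consistency (k = n) reaches p <= alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n = 1
    while two_sided_binomial(n, n) > alpha:
        n += 1
    return n


def high_confidence_calls(profiles: pd.DataFrame, alpha: float = HC_ALPHA) -> pd.DataFrame:
    """Three binomial tests per gene: all tissues, non-brain only, brain only.

    A gene is a member if any scope reaches p <= alpha; the direction per
    scope is the majority sign there, so a gene may legitimately carry
    opposite directions in the brain and non-brain scopes.

    Returns one row per gene and scope with k, n, p, ``direction``
    (positive/negative/tied) and the gene-level ``member`` flag.
    """
    kn = {
        "all": ("k_positive", "n_called"),
        "non_brain": ("k_non_brain", "n_non_brain"),
        "brain": ("k_brain", "n_brain"),
    }
    rows = []
    for gene, row in profiles.iterrows():
        for scope in SCOPES:
            k, n = int(row[kn[scope][0]]), int(row[kn[scope][1]])
            if n == 0:
                continue
            p = two_sided_binomial(k, n)
            direction = "positive" if 2 * k > n else ("negative" if 2 * k < n else "tied")
            rows.append({"gene": gene, "scope": scope, "k": k, "n": n, "p": p, "direction": direction})
    calls = pd.DataFrame(rows, columns=["gene", "scope", "k", "n", "p", "direction"])
    member_genes = set(calls.loc[calls["p"] <= alpha, "gene"])
    calls["member"] = calls["gene"].isin(member_genes)
    return calls


def high_confidence_summary(calls: pd.DataFrame, alpha: float = HC_ALPHA) -> dict:
    """Unique member genes and directional calls (gene x direction pairs).

    Uniqueness is by gene id; a gene significant in opposite directions in
    different scopes contributes two directional calls but one unique gene.
    """
    sig = calls[(calls["p"] <= alpha) & (calls["direction"] != "tied")]
    directional = sig[["gene", "direction"]].drop_duplicates()
    return {
        "n_unique_genes": int(sig["gene"].nunique()),
        "n_directional_calls": int(len(directional)),
        "n_positive": int((directional["direction"] == "positive").sum()),
        "n_negative": int((directional["direction"] == "negative").sum()),
    }


def consistent_ratio_probability(k: int) -> float:
    """P(X/k < 0.25 or X/k > 0.75) for X ~ Binomial(k, 0.5), strict bounds."""
    x = np.arange(k + 1)
    ratio = x / k
    mask = (ratio < 0.25) | (ratio > 0.75)
    return float(stats.binom.pmf(x[mask], k, 0.5).sum())


def consistency_ratio_test(profiles: pd.DataFrame, k_range: range = range(2, 11)) -> pd.DataFrame:
    """Per number of called tissues, test the excess of one-sided genes.

    Genes called in exactly k tissues are "consistent" if their day/up
    fraction is < 0.25 or > 0.75; the observed consistent count among the
    m_k such genes is tested against Binomial(m_k, p_consistent(k)),
    one-sided for enrichment.  Empty k rows are skipped.
    """
    rows = []
    for k in k_range:
        sub = profiles[profiles["n_called"] == k]
        m_k = len(sub)
        if m_k == 0:
            continue
        ratio = sub["k_positive"] / k
        observed = int(((ratio < 0.25) | (ratio > 0.75)).sum())
        p_cons = consistent_ratio_probability(k)
        p = float(stats.binomtest(observed, m_k, p_cons, alternative="greater").pvalue)
        rows.append(
            {
                "n_tissues": k,
                "n_genes": m_k,
                "n_consistent": observed,
                "observed_fraction": observed / m_k,
                "expected_probability": p_cons,
                "p": p,
            }
        )
    return pd.DataFrame(rows, columns=["n_tissues", "n_genes", "n_consistent", "observed_fraction", "expected_probability", "p"])


def strongly_seasonal(de_results: Mapping[tuple[str, str], DEResult], min_abs_lfc: float = 1.0) -> pd.DataFrame:
    """Sensitive seasonal calls with at least a two-fold change.

    ``de_results`` maps (tissue, season) to the one-vs-rest DEResult; the
    returned rows are the call_sensitive entries with |log2FC| >= 1 (the
    boundary is inclusive).
    """
    rows = []
    for (tissue, season), res in de_results.items():
        tab = res.table
        hit = tab["call_sensitive"] & (tab["log2fc"].abs() >= min_abs_lfc)
        for gene in tab.index[hit]:
            rows.append(
                {"gene": gene, "tissue": tissue, "season": season, "log2fc": float(tab.loc[gene, "log2fc"])}
            )
    return pd.DataFrame(rows, columns=["gene", "tissue", "season", "log2fc"])
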