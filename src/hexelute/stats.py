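"""Comparison statistics and set-enrichment tests.

Wraps the standard tests used to compare treatment groups — Pearson
chi-square on protein-type counts, the independent-samples t test
(Welch by default) on Z-scored abundances, and the Mann-Whitney rank-sum
test on sequence features — plus an upper-tail hypergeometric enrichment
test over user-supplied annotation sets with Benjamini-Hochberg FDR,
standing in for web-service enrichment tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

log = logging.getLogger(__name__)

#: Combined sample size at or below which the Mann-Whitney p-value is
#: computed exactly (when there are no ties).
MANN_WHITNEY_EXACT_LIMIT = 12


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float


def chi_square_independence(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2 x k count table.

    No continuity correction; df = k - 1. Zero row or column marginals
    are hard errors, as are non-positive expected counts.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValidationError(f"expected a 2 x k table with k >= 2, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValidationError("zero marginal in contingency table")
    chi2, p, df, expected = sps.chi2_contingency(counts, correction=False)
    if (expected <= 0).any():
        raise ValidationError("expected counts must all be positive")
    return float(chi2), int(df), float(p)


def t_test_independent(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sided independent-samples t test; Welch's unequal-variance form
    by default, pooled-variance Student's with ``equal_var=True``.

    Two constant samples with equal means give t = 0, p = 1 by
    convention; any other zero-variance input is a hard error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs at least two observations")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValidationError("both samples constant with different means: t undefined")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValidationError("zero variance in one sample: t undefined")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for x) with a two-sided p-value.

    Exact by enumeration when the combined sample size is at most
    MANN_WHITNEY_EXACT_LIMIT and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValidationError("each sample needs at least one observation")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= MANN_WHITNEY_EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def hypergeometric_enrichment(
    query: Iterable[str],
    sets: Mapping[str, set[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a query in each annotation set.

    Each set is intersected with the universe before testing; sets that
    vanish after intersection are skipped. p = P(X >= overlap) under
    Hypergeometric(universe_size, set_size, query_size); q is the BH
    adjustment across all tested sets. Results are sorted by p.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValidationError("empty universe")
    if not query:
        raise ValidationError("empty query")
    if not query <= universe:
        extra = sorted(query - universe)[:3]
        raise ValidationError(f"query proteins outside the universe, e.g. {extra}")
    tested = []
    for name, members in sets.items():
        members_in = members & universe
        if not members_in:
            log.info("enrichment: set %r has no members in the universe; skipped", name)
            continue
        overlap = len(query & members_in)
        p = float(sps.hypergeom.sf(overlap - 1, len(universe), len(members_in), len(query)))
        # keep p in (0, 1]: sf underflows to 0 for overwhelming overlaps
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
        tested.append((name, overlap, len(members_in), p))
    q_values = [max(q, np.nextafter(0.0, 1.0)) for q in bh_fdr([p for _, _, _, p in tested])]
    results = [
        EnrichmentResult(
            set_name=name,
            overlap=overlap,
            set_size=set_size,
            query_size=len(query),
            universe_size=len(universe),
            p_value=p,
            q_value=q,
        )
        for (name, overlap, set_size, p), q in zip(tested, q_values)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.set_name))


def quartile_split(values: Mapping[str, float]) -> dict[str, str]:
    """Assign each protein to an abundance quartile Q1 (lowest) .. Q4 (highest).

    Ranks break ties by protein_id lexicographic order so the split is
    deterministic regardless of input order.
    """
    if len(values) < 8:
        raise ValidationError(f"need at least 8 values to split, got {len(values)}")
    ordered = sorted(values.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(ordered)
    return {pid: f"Q{i * 4 // n + 1}" for i, (pid, _) in enumerate(ordered)}
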