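"""Exact and asymptotic contingency-table inference.

2x2 Fisher tests with the probability-mass two-sided criterion,
conditional-maximum-likelihood odds ratios with exact (central) confidence
intervals — both matching R's ``fisher.test`` — a 5x2 omnibus test that
switches to Pearson's chi-squared when every expected count exceeds 40, and
Bonferroni correction driven by a running ledger of performed tests.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .core import FisherResult

log = logging.getLogger(__name__)

#: Expected-count threshold above which the omnibus uses chi-squared.
CHISQ_EXPECTED_MIN = 40.0

#: Largest number of fixed-margin tables the r x c exact test enumerates.
ENUMERATION_MAX_TABLES = 2_000_000

#: Monte Carlo fallback defaults for large sparse tables.
MONTECARLO_RESAMPLES = 1_000_000
MONTECARLO_SEED = 20150615  # fixed for reproducibility

_REL_EPS = 1e-7  # tolerance when comparing table probabilities


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    if (arr < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    return arr


# ---------------------------------------------------------------------------
# 2x2 tests
# ---------------------------------------------------------------------------

def fisher_2x2(table, alternative: str = "two_sided") -> float:
    """Fisher's exact p-value for a 2x2 table.

    One-sided alternatives sum the hypergeometric tail; the two-sided p sums
    the probabilities of all fixed-margin tables no more probable than the
    observed one (the convention of R's ``fisher.test``).
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_2x2 needs a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        log.warning("degenerate margin in 2x2 table %s; p = 1", arr.tolist())
        return 1.0
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    return float(stats.fisher_exact(arr, alternative=alt)[1])


def conditional_mle_or(table) -> float:
    """Conditional maximum-likelihood odds ratio of a 2x2 table.

    The maximizer of Fisher's noncentral hypergeometric likelihood given all
    margins; 0 or infinity when a relevant cell is zero. Matches the estimate
    printed by R's ``fisher.test``.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("conditional_mle_or needs a 2x2 table")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(_odds_ratio(arr, kind="conditional").statistic)


def exact_or_ci(table, level: float = 0.95) -> tuple[float, float]:
    """Exact central confidence interval for the conditional odds ratio.

    Bounds invert the noncentral hypergeometric tail probabilities at
    (1 - level)/2 per side; zero cells yield a one-sided unbounded interval.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must be in (0, 1)")
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("exact_or_ci needs a 2x2 table")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ci = _odds_ratio(arr, kind="conditional").confidence_interval(level)
    return (float(ci.low), float(ci.high))


def fisher_2x2_full(table, alternative: str = "two_sided",
                    level: float = 0.95) -> FisherResult:
    """Convenience bundle: p-value, conditional-MLE OR, and exact CI."""
    lo, hi = exact_or_ci(table, level)
    return FisherResult(
        p_value=fisher_2x2(table, alternative),
        odds_ratio=conditional_mle_or(table),
        ci_low=lo,
        ci_high=hi,
        method="exact",
    )


# ---------------------------------------------------------------------------
# r x c omnibus
# ---------------------------------------------------------------------------

def _exact_rxc_p(arr: np.ndarray) -> float:
    """Full enumeration of all r x 2 tables with the observed margins.

    Sums the probabilities of tables whose probability does not exceed the
    observed table's (up to a relative tolerance), mirroring the two-sided
    probability-mass criterion.
    """
    from scipy.special import gammaln

    if arr.shape[1] != 2:
        raise ValueError("exact enumeration implemented for r x 2 tables")
    if arr.sum(axis=0)[0] > arr.sum(axis=0)[1]:
        arr = arr[:, ::-1]  # enumerate over the smaller column
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    total = arr.sum()
    const = gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum() \
        - gammaln(total + 1.0)
    obs_lp = const - gammaln(arr + 1.0).sum()
    cutoff = obs_lp + math.log1p(_REL_EPS)

    p_sum = 0.0
    r = len(rows)

    def recurse(i: int, c1_left: int, acc: float) -> None:
        nonlocal p_sum
        if i == r - 1:
            x = c1_left
            if 0 <= x <= rows[i]:
                lp = acc - float(gammaln(x + 1.0)) - float(gammaln(rows[i] - x + 1.0))
                if lp <= cutoff:
                    p_sum += math.exp(lp)
            return
        remaining = rows[i + 1:].sum()
        lo = max(0, c1_left - remaining)
        hi = min(rows[i], c1_left)
        for x in range(lo, hi + 1):
            recurse(i + 1, c1_left - x,
                    acc - float(gammaln(x + 1.0)) - float(gammaln(rows[i] - x + 1.0)))

    recurse(0, int(cols[0]), const)
    return min(1.0, p_sum)


def _montecarlo_rxc_p(arr: np.ndarray, resamples: int, seed: int) -> float:
    """Monte Carlo p-value over random fixed-margin tables (as in R's
    ``simulate.p.value``): (1 + #{P(T) <= P(obs)}) / (1 + B)."""
    from scipy.special import gammaln

    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    const = gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum() \
        - gammaln(arr.sum() + 1.0)
    obs_lp = const - gammaln(arr + 1.0).sum()
    rng = np.random.default_rng(seed)
    dist = stats.random_table(rows, cols)
    hits = 0
    chunk = 100_000
    done = 0
    while done < resamples:
        n = min(chunk, resamples - done)
        tables = dist.rvs(n, random_state=rng)
        lps = const - gammaln(tables + 1.0).sum(axis=(1, 2))
        hits += int((lps <= obs_lp + math.log1p(_REL_EPS)).sum())
        done += n
    return (1.0 + hits) / (1.0 + resamples)


def omnibus_rxc(
    table,
    enumeration_max_tables: int = ENUMERATION_MAX_TABLES,
    resamples: int = MONTECARLO_RESAMPLES,
    seed: int = MONTECARLO_SEED,
) -> FisherResult:
    """Omnibus test of homogeneity for an r x 2 (typically 5 x 2) table.

    When every expected count exceeds 40, Pearson's chi-squared (without
    continuity correction) is used; otherwise the exact probability-mass test
    by full enumeration when the fixed-margin table count permits, falling
    back to fixed-seed Monte Carlo.
    """
    arr = _as_table(table)
    if arr.sum() == 0:
        raise ValueError("all-zero contingency table")
    arr = arr[arr.sum(axis=1) > 0]  # drop empty rows (zero-exposure strata)
    if arr.shape[0] < 2 or (arr.sum(axis=0) == 0).any():
        log.warning("degenerate omnibus table; p = 1")
        return FisherResult(p_value=1.0, method="exact")
    expected = stats.contingency.expected_freq(arr)
    if (expected > CHISQ_EXPECTED_MIN).all():
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
        return FisherResult(p_value=float(p), method="chisq")
    # upper bound on the enumeration size: compositions of the smaller
    # column total over the rows
    r = arr.shape[0]
    small = int(arr.sum(axis=0).min())
    n_tables = math.comb(small + r - 1, r - 1)
    if n_tables <= enumeration_max_tables:
        return FisherResult(p_value=_exact_rxc_p(arr), method="exact")
    return FisherResult(p_value=_montecarlo_rxc_p(arr, resamples, seed),
                        method="montecarlo")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


@dataclass
class TestLedger:
    """Running count of performed tests, from which the Bonferroni divisor is
    taken: one omnibus test per non-empty bar, plus the per-population
    follow-up tests actually run when an omnibus is significant."""

    __test__ = False  # statistics ledger, not a pytest collectable

    entries: list[tuple[str, float]] = field(default_factory=list)

    def record(self, label: str, p_value: float) -> None:
        self.entries.append((label, p_value))

    @property
    def m(self) -> int:
        return len(self.entries)

    def threshold(self, alpha: float = 0.05) -> float:
        return bonferroni(alpha, max(1, self.m))


# ---------------------------------------------------------------------------
# Ancestry-skew protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SkewResult:
    """Outcome of the omnibus + follow-up protocol for one bar."""

    omnibus: FisherResult
    followups: tuple[tuple[str, FisherResult], ...]  # (ancestry, result)


def ancestry_skew(
    affected_by_ancestry: dict[str, int],
    cohort_by_ancestry: dict[str, int],
    ledger: Optional[TestLedger] = None,
    alpha: float = 0.05,
    followup_threshold: Optional[float] = None,
    label: str = "",
) -> SkewResult:
    """Test whether indicated-affected individuals deviate from the cohort's
    ancestry composition.

    The omnibus is a two-sided test on the 5 x 2 table of per-ancestry
    (affected count, cohort count); when significant at
    ``followup_threshold`` (default ``alpha``), each ancestry gets a
    one-sided 2 x 2 follow-up of its (affected, cohort) counts against the
    other ancestries pooled, with the conditional odds ratio and exact CI.
    """
    ancestries = sorted(cohort_by_ancestry)
    tab = [[affected_by_ancestry.get(a, 0), cohort_by_ancestry[a]]
           for a in ancestries]
    omnibus = omnibus_rxc(tab)
    if ledger is not None:
        ledger.record(f"{label}:omnibus", omnibus.p_value)
    cut = alpha if followup_threshold is None else followup_threshold
    followups: list[tuple[str, FisherResult]] = []
    if omnibus.p_value < cut:
        total_aff = sum(affected_by_ancestry.get(a, 0) for a in ancestries)
        total_n = sum(cohort_by_ancestry.values())
        for a in ancestries:
            aff = affected_by_ancestry.get(a, 0)
            t = [[aff, total_aff - aff],
                 [cohort_by_ancestry[a], total_n - cohort_by_ancestry[a]]]
            res = FisherResult(
                p_value=fisher_2x2(t, alternative="greater"),
                odds_ratio=conditional_mle_or(t),
                ci_low=exact_or_ci(t)[0],
                ci_high=exact_or_ci(t)[1],
                method="exact",
            )
            followups.append((a, res))
            if ledger is not None:
                ledger.record(f"{label}:{a}", res.p_value)
    return SkewResult(omnibus=omnibus, followups=tuple(followups))
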