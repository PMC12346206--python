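"""Rank-based comparison of outcomes across surgical-intervention groups.

The Kruskal–Wallis H statistic is computed on average ranks with the
standard tie correction (H divided by 1 - sum(t^3 - t)/(N^3 - N) over tie
groups of size t).  P-values come from the chi-square approximation with
k-1 degrees of freedom, from exact enumeration of all labelled group
assignments (small pooled samples), or from a vectorised permutation null —
the latter two serve as distribution-free references when the chi-square
approximation is doubtful (small groups, many ties).

Groups of size 1 are retained in the statistic (their rank is well
defined) but their SD is suppressed in the summary, since a sample SD is
undefined at n=1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cohort import COST_CATEGORIES, INTERVENTIONS, PatientRecord
from .costs import aggregate_patient
from .currency import ConversionTables, packaged_tables
from .errors import ConfigurationError, DataError

_EXACT_MAX_N = 12


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float | None  # None when n == 1
    median: float
    min: float
    max: float


@dataclass(frozen=True)
class GroupComparison:
    """Per-group summaries plus the tie-corrected H statistic and p-value."""

    groups: tuple
    H: float
    p_value: float
    method: str  # chi2_approx | exact | permutation

    def format_table(self, title: str = "") -> str:
        lines = []
        if title:
            lines += [title, "=" * len(title)]
        width = max(len(g.label) for g in self.groups) + 2
        for g in self.groups:
            sd = "—" if g.sd is None else f"{g.sd:,.2f}"
            lines.append(
                f"{g.label:<{width}}{g.n:>3}  {g.mean:,.2f} ± {sd}"
                f"  {g.median:,.2f} ({g.min:,.2f}–{g.max:,.2f})"
            )
        lines.append(f"{'K-W':<{width}}H = {self.H:.3f}, p = {self.p_value:.3f}"
                     f" [{self.method}]")
        return "\n".join(lines) + "\n"


def _tie_correction(ranks: np.ndarray) -> float:
    N = len(ranks)
    _, counts = np.unique(ranks, return_counts=True)
    return 1.0 - ((counts**3 - counts).sum()) / (N**3 - N)


def _h_from_rank_sums(rank_sums, sizes, N, correction):
    h = 12.0 / (N * (N + 1)) * float(
        sum(s * s / m for s, m in zip(rank_sums, sizes))
    ) - 3.0 * (N + 1)
    return h / correction


def _h_statistic(ranks: np.ndarray, sizes: list[int]) -> tuple[float, float]:
    correction = _tie_correction(ranks)
    if correction <= 0.0:  # every pooled value identical
        return 0.0, correction
    bounds = np.cumsum(sizes)
    rank_sums = [
        ranks[start:end].sum()
        for start, end in zip(np.r_[0, bounds[:-1]], bounds)
    ]
    return _h_from_rank_sums(rank_sums, sizes, len(ranks), correction), correction


def _exact_pvalue(ranks, sizes, h_obs) -> float:
    """Enumerate every labelled assignment of the pooled ranks to groups."""
    N = len(ranks)
    correction = _tie_correction(ranks)
    indices = tuple(range(N))
    count = 0
    extreme = 0
    stack = [(indices, list(sizes))]
    # iterative multiset-split enumeration
    def rec(avail: tuple, remaining: list[int], acc: list[float]):
        nonlocal count, extreme
        if len(remaining) == 1:
            rank_sums = acc + [ranks[list(avail)].sum()]
            h = _h_from_rank_sums(rank_sums, sizes, N, correction)
            count += 1
            if h >= h_obs - 1e-12:
                extreme += 1
            return
        m = remaining[0]
        for chosen in itertools.combinations(avail, m):
            rest = tuple(i for i in avail if i not in set(chosen))
            rec(rest, remaining[1:], acc + [ranks[list(chosen)].sum()])

    rec(indices, list(sizes), [])
    return extreme / count


def _permutation_pvalue(ranks, sizes, h_obs, n_resamples, rng) -> float:
    """Monte Carlo permutation null, vectorised over resamples.

    Pooled ranks are invariant under relabelling, so each resample is just
    a permutation of the fixed rank vector split at the group boundaries.
    """
    N = len(ranks)
    correction = _tie_correction(ranks)
    mat = np.tile(ranks.astype(float), (n_resamples, 1))
    mat = rng.permuted(mat, axis=1)
    bounds = np.cumsum(sizes)
    acc = np.zeros(n_resamples)
    start = 0
    for m, end in zip(sizes, bounds):
        s = mat[:, start:end].sum(axis=1)
        acc += s * s / m
        start = end
    h = (12.0 / (N * (N + 1)) * acc - 3.0 * (N + 1)) / correction
    return (1 + int((h >= h_obs - 1e-12).sum())) / (n_resamples + 1)


def kruskal_wallis(
    samples: list,
    labels: list[str] | None = None,
    method: str = "auto",
    n_resamples: int = 9999,
    seed: int = 0,
) -> GroupComparison:
    """Tie-corrected Kruskal–Wallis comparison of two or more groups.

    ``method``: ``chi2`` (k-1 df chi-square approximation), ``exact``
    (full enumeration; pooled n <= 12 unless forced), ``permutation``
    (Monte Carlo null with ``n_resamples`` relabellings), or ``auto`` —
    exact when pooled n <= 12, chi-square otherwise.
    """
    if len(samples) < 2:
        raise DataError("kruskal_wallis needs at least 2 groups")
    groups = [np.asarray(s, dtype=float) for s in samples]
    if any(len(g) == 0 for g in groups):
        raise DataError("every group must be nonempty")
    sizes = [len(g) for g in groups]
    N = sum(sizes)
    if N < 3:
        raise DataError("kruskal_wallis needs at least 3 pooled observations")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]

    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    h, correction = _h_statistic(ranks, sizes)

    if method == "auto":
        method = "exact" if N <= _EXACT_MAX_N else "chi2"
    if correction <= 0.0:
        p = 1.0
        used = "degenerate"
    elif method == "chi2":
        p = float(sps.chi2.sf(h, len(groups) - 1))
        used = "chi2_approx"
    elif method == "exact":
        p = _exact_pvalue(ranks, sizes, h)
        used = "exact"
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        p = _permutation_pvalue(ranks, sizes, h, n_resamples, rng)
        used = "permutation"
    else:
        raise ConfigurationError(f"unknown method {method!r}")

    summaries = tuple(
        GroupSummary(
            label=lab,
            n=len(g),
            mean=float(g.mean()),
            sd=None if len(g) == 1 else float(g.std(ddof=1)),
            median=float(np.median(g)),
            min=float(g.min()),
            max=float(g.max()),
        )
        for lab, g in zip(labels, groups)
    )
    return GroupComparison(groups=summaries, H=float(h), p_value=p, method=used)


def compare_by_intervention(
    cohort: list[PatientRecord],
    value_field: str,
    tables: ConversionTables | None = None,
    method: str = "auto",
    n_resamples: int = 9999,
    seed: int = 0,
) -> GroupComparison:
    """Compare a per-patient value across the surgical-intervention groups.

    ``value_field`` is either a numeric patient field (``outpatient_visits``,
    ``clinic_days``, ...) or a cost category, in which case each patient's
    converted target-period USD total for that category is compared.
    """
    if value_field in COST_CATEGORIES:
        if tables is None:
            tables = packaged_tables()
        values = [aggregate_patient(r, tables)[value_field] for r in cohort]
    elif cohort and hasattr(cohort[0], value_field) and isinstance(
        getattr(cohort[0], value_field), (int, float)
    ):
        values = [float(getattr(r, value_field)) for r in cohort]
    else:
        raise DataError(f"unknown or non-numeric value field {value_field!r}")

    by_group: dict[str, list[float]] = {}
    for rec, v in zip(cohort, values):
        by_group.setdefault(rec.intervention, []).append(v)
    labels = [lab for lab in INTERVENTIONS if lab in by_group]
    return kruskal_wallis(
        [by_group[lab] for lab in labels],
        labels=labels,
        method=method,
        n_resamples=n_resamples,
        seed=seed,
    )
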