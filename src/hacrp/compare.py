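"""Cross-methodology stability of penalty status and relative rankings.

One cohort of hospital performance data is scored under several scoring
methodologies ("retrospective" design: the rules change, the data do
not).  This module quantifies how much the penalized quartile moves:
pairwise percent overlap of penalty sets, the percent of hospitals
penalized under every methodology, and rank-shift summaries (Spearman
correlation of totals, percentile shifts, threshold crossings).

Overlap denominator: the per-methodology penalty-set size, which is
common to all methodologies when total scores are distinct (the top
quartile has a fixed size).  When ties make the sets differ in size,
the larger size is used and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .core import HospitalRecord, MethodologyConfig
from .penalty import ScoredCohort, assign_penalties, score_methodology

__all__ = [
    "RankShiftSummary",
    "ComparisonResult",
    "penalty_overlap",
    "all_years_overlap",
    "rank_shift_summary",
    "compare_all",
]

logger = logging.getLogger("hacrp")


def penalty_overlap(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Percent overlap of two penalty sets: 100*|a ∩ b| / |a| when the
    sets are equal-sized; with unequal sizes (ties in totals) the larger
    size is the denominator and a warning is logged."""
    if not a or not b:
        raise ValueError("penalty sets must be nonempty")
    if len(a) != len(b):
        logger.warning(
            "penalty sets differ in size (%d vs %d, ties in totals); "
            "using max size as overlap denominator", len(a), len(b))
    return 100.0 * len(set(a) & set(b)) / max(len(a), len(b))


def all_years_overlap(sets: Sequence[frozenset[str] | set[str]]) -> float:
    """Percent of hospitals penalized under every methodology, with the
    same denominator convention as :func:`penalty_overlap`."""
    if len(sets) < 2:
        raise ValueError("need at least two penalty sets")
    if any(not s for s in sets):
        raise ValueError("penalty sets must be nonempty")
    sizes = {len(s) for s in sets}
    if len(sizes) > 1:
        logger.warning(
            "penalty sets differ in size (%s); using max size as denominator",
            sorted(sizes))
    common = frozenset.intersection(*map(frozenset, sets))
    return 100.0 * len(common) / max(sizes)


@dataclass(frozen=True)
class RankShiftSummary:
    spearman: float
    mean_abs_percentile_shift: float
    max_abs_percentile_shift: float
    boundary_crossings: int  # hospitals crossing the 75th percentile either way
    n: int


def rank_shift_summary(
    totals_a: Mapping[str, float], totals_b: Mapping[str, float]
) -> RankShiftSummary:
    """How much hospitals move in the ranking between two methodologies
    applied to the same cohort.

    Percentiles are 100*max-rank/n; boundary crossings count hospitals
    penalized under exactly one of the two methodologies.
    """
    if set(totals_a) != set(totals_b):
        diff = sorted(set(totals_a) ^ set(totals_b))
        raise ValueError(f"hospital sets differ; symmetric difference: {diff}")
    ids = sorted(totals_a)
    a = np.asarray([totals_a[h] for h in ids], dtype=float)
    b = np.asarray([totals_b[h] for h in ids], dtype=float)
    n = len(ids)
    pct_a = 100.0 * rankdata(a, method="max") / n
    pct_b = 100.0 * rankdata(b, method="max") / n
    shifts = np.abs(pct_a - pct_b)
    table_a, _ = assign_penalties(dict(zip(ids, a)))
    table_b, _ = assign_penalties(dict(zip(ids, b)))
    pen_a = set(table_a.loc[table_a["penalized"], "hospital_id"])
    pen_b = set(table_b.loc[table_b["penalized"], "hospital_id"])
    rho = spearmanr(a, b).statistic if n > 1 else 1.0
    return RankShiftSummary(
        spearman=float(rho),
        mean_abs_percentile_shift=float(shifts.mean()),
        max_abs_percentile_shift=float(shifts.max()),
        boundary_crossings=len(pen_a ^ pen_b),
        n=n,
    )


@dataclass(frozen=True)
class ComparisonResult:
    methodologies: tuple[str, ...]
    overlap_matrix: pd.DataFrame  # percent, symmetric, labelled
    all_years_pct: float
    pairwise_rank_stats: Mapping[tuple[str, str], RankShiftSummary]
    scored: Mapping[str, ScoredCohort]


def _unique_labels(configs: Sequence[MethodologyConfig]) -> list[str]:
    labels: list[str] = []
    for cfg in configs:
        base = cfg.label
        label, k = base, 1
        while label in labels:
            k += 1
            label = f"{base}({k})"
        labels.append(label)
    return labels


def compare_all(
    records: Sequence[HospitalRecord],
    configs: Sequence[MethodologyConfig],
    mode: str | None = None,
    labels: Sequence[str] | None = None,
) -> ComparisonResult:
    """Score one shared cohort under every config and assemble the
    overlap matrix, all-methodology intersection and pairwise rank-shift
    statistics.  ``mode``, if given, overrides every config's
    missing-Domain-2 treatment."""
    if len(configs) < 2:
        raise ValueError("need at least two methodology configs")
    if mode is not None:
        configs = [replace(c, missing_domain2_mode=mode) for c in configs]
    if labels is None:
        labels = _unique_labels(configs)
    elif len(labels) != len(configs):
        raise ValueError("labels and configs must have equal length")
    labels = list(labels)

    scored: dict[str, ScoredCohort] = {}
    for label, cfg in zip(labels, configs):
        try:
            scored[label] = score_methodology(records, cfg)
        except Exception as err:
            raise RuntimeError(f"scoring failed for config {label}: {err}") from err

    matrix = pd.DataFrame(100.0, index=labels, columns=labels, dtype=float)
    stats: dict[tuple[str, str], RankShiftSummary] = {}
    for la, lb in combinations(labels, 2):
        pct = penalty_overlap(scored[la].penalty_set, scored[lb].penalty_set)
        matrix.loc[la, lb] = matrix.loc[lb, la] = pct
        stats[(la, lb)] = rank_shift_summary(scored[la].totals, scored[lb].totals)
    all_pct = all_years_overlap([scored[lb].penalty_set for lb in labels])
    return ComparisonResult(
        methodologies=tuple(labels),
        overlap_matrix=matrix,
        all_years_pct=all_pct,
        pairwise_rank_stats=stats,
        scored=scored,
    )
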