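"""Total HAC scores and penalty assignment at the 75th percentile.

The total HAC score combines the two domain scores with the fiscal
year's weights.  A hospital with only one domain gets 100% weight on
that domain, except that a hospital with no Domain 2 data and no HAI
exception can instead be assigned the maximum Domain 2 score
(``missing_domain2_mode="max_score"``: 10 points under the decile
method, the cohort's maximum observed Domain 2 z under the winsorized-z
method).  Hospitals with a total score strictly above the cohort's
75th percentile (order statistic at ceil(0.75*n)) are penalized; the
percentile is always computed within the input cohort, never against
external national cutoffs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import HospitalRecord, MethodologyConfig
from .psi90 import SkippedHospital, compute_psi90_cohort
from .scoring import (
    DomainScores,
    WinsorizationBounds,
    score_cohort_winsorized,
    score_domain1_decile,
    score_domain2_decile,
)

__all__ = [
    "ScoredCohort",
    "UnscorableHospitalError",
    "combine_domains",
    "assign_penalties",
    "score_methodology",
]

logger = logging.getLogger("hacrp")

#: columns of ScoredCohort.table, in output order
SCORED_COLUMNS = ("hospital_id", "domain1", "domain2", "domain2_imputed_max",
                  "total", "percentile_rank", "penalized")


class UnscorableHospitalError(ValueError):
    def __init__(self, hospital_id: str):
        self.hospital_id = hospital_id
        super().__init__(f"hospital {hospital_id!r} has no scorable domain")


@dataclass(frozen=True)
class ScoredCohort:
    """Per-hospital domain scores, totals, percentile ranks and penalty
    flags for one methodology, plus the threshold and a skip-list of
    hospitals that could not be scored at all."""

    fiscal_year: int
    missing_domain2_mode: str
    table: pd.DataFrame  # one row per scored hospital, SCORED_COLUMNS
    threshold: float
    skipped: tuple[SkippedHospital, ...] = ()
    winsorization: Mapping[str, WinsorizationBounds] = field(default_factory=dict)

    @property
    def penalty_set(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["penalized"], "hospital_id"])

    @property
    def totals(self) -> dict[str, float]:
        return dict(zip(self.table["hospital_id"], self.table["total"]))


def combine_domains(
    d1: float | None,
    d2: float | None,
    config: MethodologyConfig,
    max_domain2: float,
    hai_exception: bool = False,
) -> tuple[float, bool]:
    """Weighted total for one hospital.

    Returns ``(total, domain2_imputed_max)``.  ``max_domain2`` is the
    value substituted under ``max_score`` mode: 10.0 for the decile
    method, the cohort's maximum observed Domain 2 score for the
    winsorized-z method (the caller computes it before imputation).
    """
    imputed = False
    if d2 is None and config.missing_domain2_mode == "max_score" and not hai_exception:
        d2 = max_domain2
        imputed = True
    if d1 is None and d2 is None:
        raise UnscorableHospitalError("<unknown>")
    if d1 is None:
        return float(d2), imputed
    if d2 is None:
        return float(d1), imputed
    return config.domain1_weight * d1 + config.domain2_weight * d2, imputed


def assign_penalties(totals) -> tuple[pd.DataFrame, float]:
    """Threshold = order statistic at ceil(0.75*n); penalized iff total
    strictly above it; percentile_rank = 100*max-rank/n.

    ``totals`` is a mapping hospital_id -> total or an iterable of pairs.
    Returns (table sorted by hospital_id, threshold).
    """
    if isinstance(totals, Mapping):
        pairs = list(totals.items())
    else:
        pairs = list(totals)
    n = len(pairs)
    if n < 4:
        raise ValueError(f"need at least 4 hospitals to define a quartile, got {n}")
    ids = [h for h, _ in pairs]
    arr = np.asarray([t for _, t in pairs], dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("totals must be finite")
    threshold = float(np.sort(arr)[math.ceil(0.75 * n) - 1])
    ranks = rankdata(arr, method="max")
    table = pd.DataFrame({
        "hospital_id": ids,
        "total": arr,
        "percentile_rank": 100.0 * ranks / n,
        "penalized": arr > threshold,
    })
    return table.sort_values("hospital_id", ignore_index=True), threshold


def score_methodology(
    records: Sequence[HospitalRecord], config: MethodologyConfig
) -> ScoredCohort:
    """Full pipeline for one methodology: PSI-90 composite, domain
    scores under the config's method, missing-Domain-2 treatment,
    weighted combination, penalty assignment.  Deterministic for fixed
    inputs."""
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    ids = [r.hospital_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate hospital_id in cohort")

    psi90, _d1_skipped = compute_psi90_cohort(records, config.psi_weights)
    winsorization: dict[str, WinsorizationBounds] = {}

    if config.scoring_method == "decile":
        d1 = dict(score_domain1_decile(psi90)) if psi90 else {}
        d2 = score_domain2_decile(records, config.domain2_measures)
        max_domain2 = 10.0
    else:
        domain_scores, winsorization = score_cohort_winsorized(
            records, psi90, config.domain2_measures)
        d1 = {s.hospital_id: s.domain1 for s in domain_scores
              if s.domain1 is not None}
        d2 = {s.hospital_id: s.domain2 for s in domain_scores}
        observed = [v for v in d2.values() if v is not None]
        max_domain2 = max(observed) if observed else 0.0

    totals: dict[str, float] = {}
    d1_out: dict[str, float | None] = {}
    d2_out: dict[str, float | None] = {}
    imputed_flags: dict[str, bool] = {}
    d1_skip_reasons = {s.hospital_id: s.reason for s in _d1_skipped}
    skipped: list[SkippedHospital] = []
    for r in records:
        h = r.hospital_id
        try:
            total, imputed = combine_domains(
                d1.get(h), d2.get(h), config, max_domain2,
                hai_exception=r.hai_exception)
        except UnscorableHospitalError:
            reason = d1_skip_reasons.get(h, "no scorable domain")
            skipped.append(SkippedHospital(h, f"no scorable domain ({reason})"))
            continue
        totals[h] = total
        d1_out[h] = d1.get(h)
        d2_out[h] = max_domain2 if imputed else d2.get(h)
        imputed_flags[h] = imputed

    table, threshold = assign_penalties(totals)
    table.insert(1, "domain1", [d1_out[h] for h in table["hospital_id"]])
    table.insert(2, "domain2", [d2_out[h] for h in table["hospital_id"]])
    table.insert(3, "domain2_imputed_max",
                 [imputed_flags[h] for h in table["hospital_id"]])
    logger.info(
        "scored %s mode=%s: n=%d skipped=%d threshold=%.4f penalized=%d",
        config.label, config.missing_domain2_mode, len(table), len(skipped),
        threshold, int(table["penalized"].sum()),
    )
    return ScoredCohort(
        fiscal_year=config.fiscal_year,
        missing_domain2_mode=config.missing_domain2_mode,
        table=table,
        threshold=threshold,
        skipped=tuple(skipped),
        winsorization=winsorization,
    )
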