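"""Domain scoring: decile ranks (FY2015-17) and winsorized z-scores (FY2018).

Both methods convert raw measures into relative performance scores with
the convention higher raw value = worse performance = higher score.

Percentile convention (used package-wide, here and for the penalty
threshold): the p-th percentile of n ascending values is the order
statistic at position ceil(p*n), 1-indexed.  Deciles use max-rank under
ties, so tied hospitals share the worse decile and an all-tied cohort is
well defined (everyone in decile 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import HospitalRecord
from .psi90 import Psi90Result

__all__ = [
    "DomainScores",
    "WinsorizationBounds",
    "DegenerateMeasureError",
    "assign_deciles",
    "score_domain1_decile",
    "score_domain2_decile",
    "fit_winsorization",
    "winsorized_z",
    "score_cohort_winsorized",
]


class DegenerateMeasureError(ValueError):
    """A measure whose eligible values are all identical cannot be
    standardized (zero winsorized SD)."""


@dataclass(frozen=True)
class DomainScores:
    hospital_id: str
    domain1: float | None
    domain2: float | None
    domain2_imputed_max: bool
    method: str


@dataclass(frozen=True)
class WinsorizationBounds:
    """Winsorization caps plus the moments of the winsorized values for
    one measure, fit across the hospitals eligible for that measure."""

    measure_key: str
    p5: float
    p95: float
    mean_w: float
    sd_w: float
    n_eligible: int

    def __post_init__(self) -> None:
        if not self.p5 <= self.p95:
            raise ValueError(f"{self.measure_key}: p5 > p95")
        if not self.sd_w > 0:
            raise DegenerateMeasureError(
                f"{self.measure_key}: winsorized SD is 0 (constant measure)"
            )


def _as_id_value_arrays(values) -> tuple[list[str], np.ndarray]:
    if isinstance(values, Mapping):
        pairs = list(values.items())
    else:
        pairs = list(values)
    ids = [str(h) for h, _ in pairs]
    arr = np.asarray([v for _, v in pairs], dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return ids, arr


def assign_deciles(values) -> dict[str, int]:
    """Decile 1..10 by relative rank: decile = ceil(10 * r / n), where r
    is the max-rank (count of values <= own value).

    ``values`` is a mapping hospital_id -> value or an iterable of
    (hospital_id, value) pairs.
    """
    ids, arr = _as_id_value_arrays(values)
    n = arr.size
    if n == 0:
        raise ValueError("assign_deciles requires at least one value")
    max_ranks = rankdata(arr, method="max").astype(int)
    # ceil(10*r/n) in exact integer arithmetic
    deciles = -((-10 * max_ranks) // n)
    return {h: int(d) for h, d in zip(ids, deciles)}


def score_domain1_decile(psi90: Sequence[Psi90Result]) -> dict[str, int]:
    """Domain 1 score = decile of the PSI-90 composite among scored hospitals."""
    if not psi90:
        raise ValueError("empty PSI-90 result sequence")
    return assign_deciles([(r.hospital_id, r.composite) for r in psi90])


def score_domain2_decile(
    records: Sequence[HospitalRecord], measures: Iterable[str]
) -> dict[str, float | None]:
    """Domain 2 score under the decile method.

    Each measure is deciled among the hospitals reporting it; a hospital's
    score is the unweighted mean of its per-measure decile points over the
    measures it reports.  Hospitals reporting none get ``None`` (the
    missing-data treatment is applied downstream).
    """
    measures = list(measures)
    if not measures:
        raise ValueError("measure set must be nonempty")
    per_measure: dict[str, dict[str, int]] = {}
    for key in measures:
        reported = [(r.hospital_id, r.sir_measures[key])
                    for r in records if key in r.sir_measures]
        if reported:
            per_measure[key] = assign_deciles(reported)
    scores: dict[str, float | None] = {}
    for r in records:
        points = [per_measure[k][r.hospital_id]
                  for k in measures if k in r.sir_measures and k in per_measure]
        scores[r.hospital_id] = float(np.mean(points)) if points else None
    return scores


def _percentile_ceil(sorted_values: np.ndarray, p: float) -> float:
    """Order statistic at position ceil(p*n), 1-indexed."""
    n = sorted_values.size
    idx = max(math.ceil(p * n), 1) - 1
    return float(sorted_values[idx])


def fit_winsorization(values, measure_key: str = "") -> WinsorizationBounds:
    """Fit the 5th/95th-percentile caps and the moments of the winsorized
    values (sample SD, n-1 denominator) for one measure."""
    _, arr = _as_id_value_arrays(values)
    if arr.size < 2:
        raise ValueError("fit_winsorization requires at least 2 values")
    srt = np.sort(arr)
    p5 = _percentile_ceil(srt, 0.05)
    p95 = _percentile_ceil(srt, 0.95)
    w = np.clip(arr, p5, p95)
    sd = float(np.std(w, ddof=1))
    if sd == 0.0:
        raise DegenerateMeasureError(
            f"{measure_key or 'measure'}: winsorized values are constant"
        )
    return WinsorizationBounds(
        measure_key=measure_key, p5=p5, p95=p95,
        mean_w=float(np.mean(w)), sd_w=sd, n_eligible=int(arr.size),
    )


def winsorized_z(value: float, bounds: WinsorizationBounds) -> float:
    """z = (clamp(value, p5, p95) - mean_w) / sd_w."""
    clamped = min(max(value, bounds.p5), bounds.p95)
    return (clamped - bounds.mean_w) / bounds.sd_w


def score_cohort_winsorized(
    records: Sequence[HospitalRecord],
    psi90: Sequence[Psi90Result],
    measures: Iterable[str],
) -> tuple[list[DomainScores], dict[str, WinsorizationBounds]]:
    """Continuous FY2018-style domain scores.

    Domain 1 is the winsorized z of the PSI-90 composite (bounds fit
    across hospitals with a composite); Domain 2 is the unweighted mean of
    per-measure winsorized z-scores, each measure standardized among the
    hospitals reporting it.  Returns the scores plus the fitted bounds per
    measure (key ``"PSI-90"`` for Domain 1) for audit.
    """
    measures = list(measures)
    if not records:
        raise ValueError("empty cohort")
    composites = {r.hospital_id: r.composite for r in psi90}
    bounds: dict[str, WinsorizationBounds] = {}
    d1_z: dict[str, float] = {}
    if composites:
        bounds["PSI-90"] = fit_winsorization(composites, measure_key="PSI-90")
        d1_z = {h: winsorized_z(v, bounds["PSI-90"]) for h, v in composites.items()}

    measure_z: dict[str, dict[str, float]] = {}
    for key in measures:
        reported = {r.hospital_id: r.sir_measures[key]
                    for r in records if key in r.sir_measures}
        if len(reported) >= 2:
            bounds[key] = fit_winsorization(reported, measure_key=key)
            measure_z[key] = {h: winsorized_z(v, bounds[key])
                              for h, v in reported.items()}

    scores: list[DomainScores] = []
    for r in records:
        zs = [measure_z[k][r.hospital_id] for k in measures
              if k in measure_z and r.hospital_id in measure_z[k]]
        scores.append(DomainScores(
            hospital_id=r.hospital_id,
            domain1=d1_z.get(r.hospital_id),
            domain2=float(np.mean(zs)) if zs else None,
            domain2_imputed_max=False,
            method="winsorized_z",
        ))
    return scores, bounds
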