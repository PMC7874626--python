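"""Synthetic hospital cohorts with the structure the scoring pipeline assumes.

The real inputs (HCUP state inpatient discharge data, NHSN standardized
infection ratios) are restricted, so cohorts are simulated instead:

* Each hospital draws a latent quality deviation on the log scale; all of
  its measures load on it, inducing the positive cross-measure
  correlation seen in practice (worse hospitals tend to be worse across
  the board).
* PSI component ratios and SIRs are lognormal around 1 — they are
  observed-to-expected ratios, nonnegative and right-skewed.
* CLABSI/CAUTI exist in two surveillance scopes; the ICU+ward variant is
  the ICU-only value plus independent noise whose SD is on the order of
  the cross-scope prediction error reported for these measures
  (RMSE 0.30-0.40).
* Roughly 65% of hospitals (1105/1704) report at least one Domain 2
  measure; which measures a reporter submits is Bernoulli per measure.
* A fraction of values is rounded to one decimal to induce ties, because
  tie handling is a first-class part of decile scoring.

All randomness flows from the mandatory explicit seed; there is no
global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import MEASURE_KEYS, PSI_CODES, ConfigError, HospitalRecord

__all__ = ["GeneratorConfig", "generate_cohort", "generate_worked_micro_cohort"]

#: Domain 2 base measures; the two CLABSI/CAUTI scope variants derive
#: from the same reporting decision.
_BASE_MEASURES = ("CLABSI", "CAUTI", "SSI", "MRSA", "CDI")

_DEFAULT_REPORTING = {
    "CLABSI": 0.85, "CAUTI": 0.90, "SSI": 0.70, "MRSA": 0.80, "CDI": 0.85,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: 1704 hospitals with scorable
    Domain 1 data, of which 1105 report at least one Domain 2 measure.
    ``latent_quality_sd`` scales the shared log-scale quality deviation
    (0 disables the shared pathway, making measures independent);
    ``measure_noise_sd`` is the idiosyncratic lognormal scale of each
    SIR; ``psi_component_lognormal_params`` gives per-PSI (location,
    scale) on the log scale; ``icu_ward_noise_sd`` is the additive-noise
    SD between the two CLABSI/CAUTI surveillance scopes.
    """

    seed: int
    n_hospitals: int = 1704
    frac_domain2_reporting: float = 1105 / 1704
    reporting_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REPORTING))
    latent_quality_sd: float = 0.3
    measure_noise_sd: float = 0.4
    icu_ward_noise_sd: float = 0.35
    psi_component_lognormal_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {code: (0.0, 0.4) for code in PSI_CODES})
    sir_log_location: float = 0.0
    tie_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an explicit integer")
        if self.n_hospitals < 1:
            raise ConfigError("n_hospitals must be positive")
        if not 0.0 <= self.frac_domain2_reporting <= 1.0:
            raise ConfigError("frac_domain2_reporting must lie in [0,1]")
        if not 0.0 <= self.tie_fraction <= 1.0:
            raise ConfigError("tie_fraction must lie in [0,1]")
        if self.latent_quality_sd < 0:
            raise ConfigError("latent_quality_sd must be >= 0")
        if self.measure_noise_sd <= 0 or self.icu_ward_noise_sd <= 0:
            raise ConfigError("noise SDs must be > 0")
        for m, p in self.reporting_probs.items():
            if m not in _BASE_MEASURES:
                raise ConfigError(f"unknown base measure {m!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"reporting probability for {m} must lie in [0,1]")
        for code, (_, scale) in self.psi_component_lognormal_params.items():
            if code not in PSI_CODES:
                raise ConfigError(f"unknown PSI code {code!r}")
            if scale <= 0:
                raise ConfigError(f"PSI scale for {code} must be > 0")


def generate_cohort(config: GeneratorConfig) -> list[HospitalRecord]:
    """Draw one reproducible cohort of :class:`HospitalRecord`."""
    rng = np.random.default_rng(config.seed)
    n = config.n_hospitals
    width = max(4, len(str(n)))
    ids = [f"H{i:0{width}d}" for i in range(1, n + 1)]

    latent = config.latent_quality_sd * rng.standard_normal(n)

    psi: dict[str, np.ndarray] = {}
    for code in PSI_CODES:
        loc, scale = config.psi_component_lognormal_params[code]
        psi[code] = np.exp(loc + latent + scale * rng.standard_normal(n))

    sir: dict[str, np.ndarray] = {}
    for base in _BASE_MEASURES:
        sir[base] = np.exp(config.sir_log_location + latent
                           + config.measure_noise_sd * rng.standard_normal(n))
    for base in ("CLABSI", "CAUTI"):
        noise = config.icu_ward_noise_sd * rng.standard_normal(n)
        sir[base + "_ICU_WARD"] = np.maximum(sir[base] + noise, 0.0)

    # reporting structure: reporter flag, then per-measure masks
    is_reporter = rng.random(n) < config.frac_domain2_reporting
    masks: dict[str, np.ndarray] = {}
    for base in _BASE_MEASURES:
        p = config.reporting_probs.get(base, 0.0)
        masks[base] = is_reporter & (rng.random(n) < p)
    # a reporter must report at least one measure; fall back to CAUTI
    none_reported = is_reporter.copy()
    for base in _BASE_MEASURES:
        none_reported &= ~masks[base]
    masks["CAUTI"] |= none_reported

    # ties: round a random subset of each measure column to 1 decimal
    def _tie(arr: np.ndarray) -> np.ndarray:
        if config.tie_fraction == 0:
            return arr
        pick = rng.random(n) < config.tie_fraction
        out = arr.copy()
        out[pick] = np.round(out[pick], 1)
        return out

    psi = {code: _tie(v) for code, v in psi.items()}
    sir = {key: _tie(v) for key, v in sir.items()}

    records = []
    for i, hid in enumerate(ids):
        measures: dict[str, float] = {}
        for base in _BASE_MEASURES:
            if masks[base][i]:
                if base in ("CLABSI", "CAUTI"):
                    measures[f"{base}_ICU"] = float(sir[base][i])
                    measures[f"{base}_ICU_WARD"] = float(sir[base + "_ICU_WARD"][i])
                else:
                    measures[base] = float(sir[base][i])
        records.append(HospitalRecord(
            hospital_id=hid,
            psi_components={code: float(psi[code][i]) for code in PSI_CODES},
            sir_measures=measures,
            hai_exception=False,
        ))
    return records


def generate_worked_micro_cohort() -> list[HospitalRecord]:
    """A fixed 12-hospital cohort covering the scoring edge cases.

    Hand-chosen values exercise: missing PSI components (M05), a
    hospital scorable on Domain 1 only under weight sets that include
    PSI-07 (M11), hospitals with no Domain 2 data with (M09) and without
    (M10) the HAI exception, a tie on CAUTI (M02/M03), and an extreme
    outlier hit by the 95th-percentile winsorization cap (M12).  The
    expected domain scores, totals, thresholds and penalty flags under
    all four methodologies are frozen in the test suite's
    ``micro_expected.json`` fixture (synthetic, hand-computed via
    brute-force oracles).
    """
    full = dict(zip(PSI_CODES, [1.0] * len(PSI_CODES)))

    def psis(**overrides: float) -> dict[str, float]:
        out = dict(full)
        out.update({k.replace("_", "-"): v for k, v in overrides.items()})
        return out

    return [
        HospitalRecord("M01", psis(PSI_12=0.5, PSI_15=0.6),
                       {"CLABSI_ICU": 0.4, "CLABSI_ICU_WARD": 0.5,
                        "CAUTI_ICU": 0.7, "CAUTI_ICU_WARD": 0.8,
                        "SSI": 0.6, "MRSA": 0.5, "CDI": 0.9}),
        HospitalRecord("M02", psis(PSI_12=1.1),
                       {"CLABSI_ICU": 1.2, "CLABSI_ICU_WARD": 1.3,
                        "CAUTI_ICU": 1.0, "CAUTI_ICU_WARD": 1.1, "SSI": 1.4}),
        HospitalRecord("M03", psis(PSI_13=1.6),
                       {"CAUTI_ICU": 1.0, "CAUTI_ICU_WARD": 0.9,
                        "MRSA": 1.8, "CDI": 1.1}),
        HospitalRecord("M04", psis(PSI_03=2.0, PSI_11=1.8),
                       {"CLABSI_ICU": 2.2, "CLABSI_ICU_WARD": 2.0,
                        "CAUTI_ICU": 1.9, "CAUTI_ICU_WARD": 2.1,
                        "SSI": 1.7, "MRSA": 2.3, "CDI": 1.6}),
        HospitalRecord("M05", {"PSI-12": 1.3, "PSI-13": 0.9, "PSI-15": 1.2},
                       {"SSI": 1.1, "CDI": 0.8}),
        HospitalRecord("M06", psis(PSI_06=0.7, PSI_15=0.9),
                       {"CLABSI_ICU": 0.9, "CLABSI_ICU_WARD": 1.0,
                        "CAUTI_ICU": 1.1, "CAUTI_ICU_WARD": 1.0, "CDI": 1.2}),
        HospitalRecord("M07", psis(PSI_11=0.6, PSI_12=0.8),
                       {"CAUTI_ICU": 0.5, "CAUTI_ICU_WARD": 0.6,
                        "SSI": 0.9, "MRSA": 0.7}),
        HospitalRecord("M08", psis(PSI_15=1.4),
                       {"CLABSI_ICU": 1.5, "CLABSI_ICU_WARD": 1.6,
                        "SSI": 1.2, "MRSA": 1.1, "CDI": 1.3}),
        HospitalRecord("M09", psis(PSI_12=1.2, PSI_13=1.1), {},
                       hai_exception=True),
        HospitalRecord("M10", psis(PSI_03=1.5, PSI_12=0.9), {}),
        HospitalRecord("M11", {"PSI-07": 1.7},
                       {"CLABSI_ICU": 1.1, "CLABSI_ICU_WARD": 1.2,
                        "CAUTI_ICU": 1.3, "CAUTI_ICU_WARD": 1.4, "SSI": 1.0}),
        HospitalRecord("M12", psis(PSI_15=2.5),
                       {"CLABSI_ICU": 6.0, "CLABSI_ICU_WARD": 6.5,
                        "CAUTI_ICU": 5.0, "CAUTI_ICU_WARD": 5.5,
                        "SSI": 4.0, "MRSA": 4.5, "CDI": 5.0}),
    ]
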