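"""Shared data model and the registry of fiscal-year scoring methodologies.

The Hospital-Acquired Condition Reduction Program (HACRP) scores every
eligible U.S. hospital on two domains — Domain 1, the claims-based AHRQ
PSI-90 patient-safety composite, and Domain 2, the NHSN-reported
standardized infection ratios (SIRs) — and penalizes the worst-performing
quartile 1% of Medicare payments.  Between FY2015 and FY2018 CMS changed
the PSI-90 component weights, the Domain 2 measure set, the domain
weights, and (in FY2018) the scoring method itself.  This module holds the
hospital-level record type and one validated :class:`MethodologyConfig`
per fiscal year capturing exactly those rules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

__all__ = [
    "PSI_CODES",
    "MEASURE_KEYS",
    "PSI_WEIGHT_VERSIONS",
    "HospitalRecord",
    "PsiWeightSet",
    "MethodologyConfig",
    "ConfigError",
    "builtin_psi_weights",
    "builtin_methodologies",
]

#: PSI component codes that may appear in a PSI-90 weight set.
PSI_CODES: tuple[str, ...] = (
    "PSI-03", "PSI-06", "PSI-07", "PSI-08", "PSI-09", "PSI-10",
    "PSI-11", "PSI-12", "PSI-13", "PSI-14", "PSI-15",
)

#: Domain 2 measure keys.  CLABSI and CAUTI exist in two surveillance
#: scopes: ICU-only (FY2015-17 rules) and ICU+ward (FY2018 rules).
MEASURE_KEYS: tuple[str, ...] = (
    "CLABSI_ICU", "CAUTI_ICU", "CLABSI_ICU_WARD", "CAUTI_ICU_WARD",
    "SSI", "MRSA", "CDI",
)

PSI_WEIGHT_VERSIONS: tuple[str, ...] = ("4.5a", "4.5a_POA", "5.0.1", "6.0.2")


class ConfigError(ValueError):
    """Raised when a record, weight set, or methodology config is invalid."""


def _check_nonneg_finite(name: str, mapping: Mapping[str, float]) -> None:
    for key, value in mapping.items():
        if not (math.isfinite(value) and value >= 0):
            raise ConfigError(f"{name}[{key}] must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class HospitalRecord:
    """One hospital's raw measure results.

    ``psi_components`` maps PSI codes to risk-adjusted component ratios
    (higher = worse); ``sir_measures`` maps measure keys to SIRs.  Entries
    are optional — a missing entry means the hospital did not report (or
    was not eligible for) that measure.  ``hai_exception`` marks hospitals
    exempt from Domain 2 scoring: with no reported SIRs they are scored on
    Domain 1 alone instead of receiving the maximum Domain 2 score.
    """

    hospital_id: str
    psi_components: Mapping[str, float] = field(default_factory=dict)
    sir_measures: Mapping[str, float] = field(default_factory=dict)
    hai_exception: bool = False

    def __post_init__(self) -> None:
        if not self.hospital_id:
            raise ConfigError("hospital_id must be a nonempty string")
        unknown = set(self.psi_components) - set(PSI_CODES)
        if unknown:
            raise ConfigError(f"unknown PSI codes {sorted(unknown)}; valid: {PSI_CODES}")
        unknown = set(self.sir_measures) - set(MEASURE_KEYS)
        if unknown:
            raise ConfigError(f"unknown SIR measures {sorted(unknown)}; valid: {MEASURE_KEYS}")
        _check_nonneg_finite("psi_components", self.psi_components)
        _check_nonneg_finite("sir_measures", self.sir_measures)
        object.__setattr__(self, "psi_components", dict(self.psi_components))
        object.__setattr__(self, "sir_measures", dict(self.sir_measures))

    @property
    def reports_domain2(self) -> bool:
        return len(self.sir_measures) > 0


@dataclass(frozen=True)
class PsiWeightSet:
    """One column of PSI-90 component weights (one AHRQ software version)."""

    version_label: str
    weights: Mapping[str, float]

    #: printed weight columns sum to 1.0000 / 0.9994 / 1.0000 / 0.9998
    SUM_TOL = 1e-3

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(PSI_CODES)
        if unknown:
            raise ConfigError(f"unknown PSI codes in weight set: {sorted(unknown)}")
        for code, w in self.weights.items():
            if not (0.0 <= w <= 1.0):
                raise ConfigError(f"weight for {code} must lie in [0,1], got {w}")
        total = sum(self.weights.values())
        if abs(total - 1.0) > self.SUM_TOL:
            raise ConfigError(
                f"weights of {self.version_label!r} sum to {total:.4f}, "
                f"expected 1 within {self.SUM_TOL}"
            )
        object.__setattr__(self, "weights", dict(self.weights))

    @property
    def total_weight(self) -> float:
        return sum(self.weights.values())


# PSI-90 component weights as printed, by AHRQ software version.  The
# "4.5a"/"4.5a_POA" pair are the FY2015-16 columns without/with
# present-on-admission (POA) reporting; 5.0.1 is the FY2017 recalibration;
# 6.0.2 is the FY2018 severity-reweighted column, which drops PSI-07 (so
# CLABSI is not double-counted against Domain 2) and adds PSI-09/10/11.
_PSI_WEIGHT_TABLE: dict[str, dict[str, float]] = {
    "4.5a": {
        "PSI-03": 0.2303, "PSI-06": 0.0545, "PSI-07": 0.0563,
        "PSI-08": 0.0025, "PSI-12": 0.2572, "PSI-13": 0.0603,
        "PSI-14": 0.0097, "PSI-15": 0.3292,
    },
    "4.5a_POA": {
        "PSI-03": 0.0220, "PSI-06": 0.0708, "PSI-07": 0.0652,
        "PSI-08": 0.0011, "PSI-12": 0.2579, "PSI-13": 0.0742,
        "PSI-14": 0.0165, "PSI-15": 0.4917,
    },
    "5.0.1": {
        "PSI-03": 0.0391, "PSI-06": 0.0905, "PSI-07": 0.0301,
        "PSI-08": 0.0025, "PSI-12": 0.3570, "PSI-13": 0.0798,
        "PSI-14": 0.0183, "PSI-15": 0.3827,
    },
    "6.0.2": {
        "PSI-03": 0.0557, "PSI-06": 0.0493, "PSI-08": 0.0093,
        "PSI-09": 0.0820, "PSI-10": 0.0466, "PSI-11": 0.3109,
        "PSI-12": 0.1954, "PSI-13": 0.2318, "PSI-14": 0.0121,
        "PSI-15": 0.0067,
    },
}


def builtin_psi_weights(version_label: str) -> PsiWeightSet:
    """Return the shipped PSI-90 weight column for one software version.

    Weights are stored exactly as published (4 decimal places) and never
    renormalized.
    """
    try:
        column = _PSI_WEIGHT_TABLE[version_label]
    except KeyError:
        raise ConfigError(
            f"unknown PSI weight version {version_label!r}; "
            f"valid labels: {list(PSI_WEIGHT_VERSIONS)}"
        ) from None
    return PsiWeightSet(version_label=version_label, weights=column)


_FY_DOMAIN2_MEASURES: dict[int, tuple[str, ...]] = {
    2015: ("CLABSI_ICU", "CAUTI_ICU"),
    2016: ("CLABSI_ICU", "CAUTI_ICU", "SSI"),
    2017: ("CLABSI_ICU", "CAUTI_ICU", "SSI", "MRSA", "CDI"),
    2018: ("CLABSI_ICU_WARD", "CAUTI_ICU_WARD", "SSI", "MRSA", "CDI"),
}


@dataclass(frozen=True)
class MethodologyConfig:
    """Everything that defines one fiscal year's HACRP scoring rules."""

    fiscal_year: int
    psi_weights: PsiWeightSet
    domain2_measures: tuple[str, ...]
    scoring_method: str  # "decile" or "winsorized_z"
    domain1_weight: float
    domain2_weight: float
    missing_domain2_mode: str = "exception"  # or "max_score"

    def __post_init__(self) -> None:
        if self.fiscal_year not in (2015, 2016, 2017, 2018):
            raise ConfigError(f"fiscal_year must be 2015-2018, got {self.fiscal_year}")
        if self.scoring_method not in ("decile", "winsorized_z"):
            raise ConfigError(f"unknown scoring_method {self.scoring_method!r}")
        # FY2018 is the only winsorized-z year under the FY2015-18 rules
        if (self.scoring_method == "winsorized_z") != (self.fiscal_year == 2018):
            raise ConfigError(
                "scoring_method 'winsorized_z' is used exactly for fiscal_year 2018"
            )
        if self.missing_domain2_mode not in ("exception", "max_score"):
            raise ConfigError(
                f"missing_domain2_mode must be 'exception' or 'max_score', "
                f"got {self.missing_domain2_mode!r}"
            )
        unknown = set(self.domain2_measures) - set(MEASURE_KEYS)
        if unknown:
            raise ConfigError(f"unknown Domain 2 measures: {sorted(unknown)}")
        if not self.domain2_measures:
            raise ConfigError("domain2_measures must be nonempty")
        if self.domain1_weight + self.domain2_weight != 1.0:
            raise ConfigError(
                f"domain weights must sum to 1 exactly, got "
                f"{self.domain1_weight} + {self.domain2_weight}"
            )
        if not (0.0 <= self.domain1_weight <= 1.0):
            raise ConfigError("domain1_weight must lie in [0,1]")
        object.__setattr__(self, "domain2_measures", tuple(self.domain2_measures))

    @property
    def label(self) -> str:
        return f"FY{self.fiscal_year}"

    def with_mode(self, mode: str) -> "MethodologyConfig":
        return replace(self, missing_domain2_mode=mode)

    def with_psi_weights(self, weight_set: PsiWeightSet) -> "MethodologyConfig":
        return replace(self, psi_weights=weight_set)

    # -- plain-text serialization, so hypothetical methodologies can be
    #    defined in a YAML/JSON file ------------------------------------
    def to_dict(self) -> dict:
        return {
            "fiscal_year": self.fiscal_year,
            "psi_weights": {
                "version_label": self.psi_weights.version_label,
                "weights": dict(self.psi_weights.weights),
            },
            "domain2_measures": list(self.domain2_measures),
            "scoring_method": self.scoring_method,
            "domain1_weight": self.domain1_weight,
            "domain2_weight": self.domain2_weight,
            "missing_domain2_mode": self.missing_domain2_mode,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "MethodologyConfig":
        psi = data["psi_weights"]
        if isinstance(psi, str):
            weight_set = builtin_psi_weights(psi)
        else:
            weight_set = PsiWeightSet(psi["version_label"], psi["weights"])
        return cls(
            fiscal_year=int(data["fiscal_year"]),
            psi_weights=weight_set,
            domain2_measures=tuple(data["domain2_measures"]),
            scoring_method=data["scoring_method"],
            domain1_weight=float(data["domain1_weight"]),
            domain2_weight=float(data["domain2_weight"]),
            missing_domain2_mode=data.get("missing_domain2_mode", "exception"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "MethodologyConfig":
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        return cls.from_dict(data)


def builtin_methodologies() -> dict[int, MethodologyConfig]:
    """The four FY2015-FY2018 scoring methodologies, validated.

    Domain weights follow the program's trajectory of increasing Domain 2
    emphasis: 35/65 (FY2015), 25/75 (FY2016), 15/85 (FY2017 and FY2018).
    FY2015-16 default to the POA-adjusted 4.5a weight column (the study
    data had enhanced present-on-admission reporting); the plain "4.5a"
    column remains selectable via :meth:`MethodologyConfig.with_psi_weights`.
    """
    domain_weights = {2015: (0.35, 0.65), 2016: (0.25, 0.75),
                      2017: (0.15, 0.85), 2018: (0.15, 0.85)}
    psi_versions = {2015: "4.5a_POA", 2016: "4.5a_POA", 2017: "5.0.1", 2018: "6.0.2"}
    configs = {}
    for fy in (2015, 2016, 2017, 2018):
        w1, w2 = domain_weights[fy]
        configs[fy] = MethodologyConfig(
            fiscal_year=fy,
            psi_weights=builtin_psi_weights(psi_versions[fy]),
            domain2_measures=_FY_DOMAIN2_MEASURES[fy],
            scoring_method="winsorized_z" if fy == 2018 else "decile",
            domain1_weight=w1,
            domain2_weight=w2,
        )
    return configs
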