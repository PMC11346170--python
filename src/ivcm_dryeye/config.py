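"""Structured cohort configuration, loadable from YAML.

One config drives the whole synthetic study: per-group marginals (mean/SD
and distribution family per variable), grading-subscore targets, planted
Spearman correlations, morphology thresholds and calibration settings.
The packaged default, ``table1_default``, reproduces the published cohort's
group sizes and printed marginals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .scoring import MorphologyThresholds

#: variables that may appear in targets, besides the clinical columns
SCORE_TARGET_NAMES = ("icsc", "ndsc")

CLINICAL_VARS = (
    "age",
    "osdi_symptoms",
    "osdi_vision",
    "osdi_triggers",
    "osdi_total",
    "oxford",
    "schirmer_mm",
    "tbut_s",
    "pain",
    "hla_dr_auf",
)


class ConfigError(ValueError):
    """Invalid or inconsistent cohort configuration."""


@dataclass(frozen=True)
class VariableSpec:
    mean: float
    sd: float
    family: str  # truncnorm | lognorm | ordinal
    lo: float = float("-inf")
    hi: float = float("inf")
    values: tuple[float, ...] | None = None  # ordinal grid

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigError(f"sd must be > 0, got {self.sd}")
        if self.family not in ("truncnorm", "lognorm", "ordinal"):
            raise ConfigError(f"unknown family {self.family!r}")
        if self.family == "ordinal" and not self.values:
            raise ConfigError("ordinal family requires a 'values' grid")


@dataclass(frozen=True)
class ScoreMarginals:
    """Target moments of the grading subscores within one group."""

    icsc_mean: float
    icsc_sd: float
    ndsc_mean: float  # P(decreased nerve density), since NDsc is binary
    nmsc_mean: float  # = P(tortuous) + P(hyper-reflective)

    def __post_init__(self) -> None:
        if not 0 < self.ndsc_mean < 1:
            raise ConfigError("ndsc_mean must be a probability in (0,1)")
        if not 0 < self.nmsc_mean < 2:
            raise ConfigError("nmsc_mean must lie in (0,2)")
        if not 0 <= self.icsc_mean <= 3:
            raise ConfigError("icsc_mean must lie in [0,3]")


@dataclass(frozen=True)
class GroupConfig:
    name: str
    n: int
    female_fraction: float
    clinical: dict[str, VariableSpec]
    scores: ScoreMarginals
    pairwise_targets: tuple[tuple[str, str, float], ...] = ()
    composite_targets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError(f"group size must be >= 0, got {self.n}")
        if not 0 <= self.female_fraction <= 1:
            raise ConfigError("female_fraction must be in [0,1]")
        missing = set(CLINICAL_VARS) - set(self.clinical)
        if missing:
            raise ConfigError(f"group {self.name}: missing clinical variables {sorted(missing)}")
        valid = set(CLINICAL_VARS) | set(SCORE_TARGET_NAMES)
        for a, b, rho in self.pairwise_targets:
            if a not in valid or b not in valid:
                raise ConfigError(f"unknown target variable in pair ({a}, {b})")
            if a == b:
                raise ConfigError(f"self-correlation target on {a}")
            if abs(rho) >= 0.95:
                raise ConfigError(f"|target rho| must be < 0.95, got {rho} for ({a},{b})")
        for key, rho in self.composite_targets.items():
            if key not in ("tivcm_hla", "nmsc_oxford", "nmsc_age"):
                raise ConfigError(f"unknown composite target {key!r}")
            if abs(rho) >= 0.95:
                raise ConfigError(f"|composite target| must be < 0.95, got {rho}")


@dataclass(frozen=True)
class CalibrationConfig:
    n_calib: int = 50_000
    seed: int = 20_817
    tol: float = 0.02

    def __post_init__(self) -> None:
        if self.n_calib < 10_000:
            raise ConfigError("n_calib must be >= 10000")
        if not 0 < self.tol < 0.2:
            raise ConfigError("tol must be in (0, 0.2)")


@dataclass(frozen=True)
class LatentShapes:
    """Shape parameters of the unobserved morphometric marginals."""

    nerve_density_sigma: float = 0.5
    tortuosity_sigma: float = 0.5
    reflectivity_sigma: float = 0.3
    mean_nerve_span_mm: float = 0.4


@dataclass(frozen=True)
class CohortConfig:
    name: str
    groups: tuple[GroupConfig, ...]
    thresholds: MorphologyThresholds = MorphologyThresholds()
    calibration: CalibrationConfig = CalibrationConfig()
    latents: LatentShapes = LatentShapes()

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigError("a cohort config needs at least one group")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate group names: {names}")

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)

    def group(self, name: str) -> GroupConfig:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def cache_key(self) -> str:
        """Content hash used to cache the calibrated copula model."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _parse_variable(name: str, raw: dict) -> VariableSpec:
    values = tuple(raw["values"]) if "values" in raw else None
    return VariableSpec(
        mean=float(raw["mean"]),
        sd=float(raw["sd"]),
        family=str(raw.get("family", "truncnorm")),
        lo=float(raw.get("lo", float("-inf"))),
        hi=float(raw.get("hi", float("inf"))),
        values=values,
    )


def config_from_dict(raw: dict) -> CohortConfig:
    try:
        groups = []
        for gname, graw in raw["groups"].items():
            clinical = {
                vname: _parse_variable(vname, vraw)
                for vname, vraw in graw["clinical"].items()
            }
            scores = ScoreMarginals(**{k: float(v) for k, v in graw["scores"].items()})
            traw = graw.get("targets", {})
            pairwise = tuple(
                (str(a), str(b), float(rho)) for a, b, rho in traw.get("pairwise", [])
            )
            composite = {str(k): float(v) for k, v in traw.get("composite", {}).items()}
            groups.append(
                GroupConfig(
                    name=str(gname),
                    n=int(graw["n"]),
                    female_fraction=float(graw["female_fraction"]),
                    clinical=clinical,
                    scores=scores,
                    pairwise_targets=pairwise,
                    composite_targets=composite,
                )
            )
        thr = raw.get("thresholds", {})
        cal = raw.get("calibration", {})
        lat = raw.get("latents", {})
        return CohortConfig(
            name=str(raw.get("name", "custom")),
            groups=tuple(groups),
            thresholds=MorphologyThresholds(
                tortuosity=float(thr.get("tortuosity", 1.2)),
                reflectivity=float(thr.get("reflectivity", 2.5)),
            ),
            calibration=CalibrationConfig(
                n_calib=int(cal.get("n_calib", 50_000)),
                seed=int(cal.get("seed", 20_817)),
                tol=float(cal.get("tol", 0.02)),
            ),
            latents=LatentShapes(
                nerve_density_sigma=float(lat.get("nerve_density_sigma", 0.5)),
                tortuosity_sigma=float(lat.get("tortuosity_sigma", 0.5)),
                reflectivity_sigma=float(lat.get("reflectivity_sigma", 0.3)),
                mean_nerve_span_mm=float(lat.get("mean_nerve_span_mm", 0.4)),
            ),
        )
    except KeyError as exc:
        raise ConfigError(f"missing required config key: {exc}") from exc


def load_config(path: str | Path) -> CohortConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def default_config() -> CohortConfig:
    """The packaged ``table1_default`` configuration."""
    ref = resources.files("ivcm_dryeye") / "configs" / "table1_default.yaml"
    return config_from_dict(yaml.safe_load(ref.read_text()))
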