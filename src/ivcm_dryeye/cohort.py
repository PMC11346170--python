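"""Synthetic dry-eye cohort generator.

Each eye is one draw from a group-specific Gaussian copula over 14 latent
variables: nine clinical scales, four unobserved morphometric traits
(inflammatory-cell density, nerve density, tortuosity, reflectivity) and
the conjunctival HLA-DR level.  Marginals are moment-matched to the
published group means/SDs (see :mod:`ivcm_dryeye.marginals`); rank
correlations are *induced*, never pasted: the grading subscores are
computed from the sampled morphometric traits by the scoring module, and
the latent correlations are pre-calibrated so that the binned scores
reproduce the published Spearman targets despite discretisation loss.

Because the total score is a deterministic sum of its subscores it cannot
carry an independent planted correlation; its association with HLA-DR is
reached by a joint calibration that adds nerve-morphology/HLA-DR latent
correlation on top of the cell-density/HLA-DR pair.

Calibration depends only on the configuration (it is a deterministic
model-fitting step with its own internal seed) and is cached, so replicate
cohorts at different seeds reuse it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import scoring
from .config import CohortConfig, GroupConfig, default_config
from .copula import (
    calibrate_joint_correlation,
    calibrate_latent_correlation,
    latent_from_spearman_continuous,
    nearest_positive_definite,
)
from .marginals import (
    fit_binned_lognorm,
    fit_lognorm_moments,
    fit_lognorm_quantile,
    fit_ordinal,
    fit_truncnorm,
)
from .morphometry import MorphometrySummary
from .scoring import IVCMScore, score_summary

log = logging.getLogger(__name__)

#: latent variable order in the copula
LATENT_VARS = (
    "age",
    "osdi_symptoms",
    "osdi_vision",
    "osdi_triggers",
    "osdi_total",
    "oxford",
    "schirmer_mm",
    "tbut_s",
    "pain",
    "ic_density",
    "nerve_density",
    "tortuosity",
    "reflectivity",
    "hla_dr_auf",
)

#: score-level target names -> the latent trait they bin
_SCORE_LATENT = {"icsc": "ic_density", "ndsc": "nerve_density"}

#: cohort table column order
COHORT_COLUMNS = (
    "patient_id",
    "group",
    "sex",
    "age",
    "osdi_symptoms",
    "osdi_vision",
    "osdi_triggers",
    "osdi_total",
    "schirmer_mm",
    "tbut_s",
    "oxford",
    "pain",
    "hla_dr_auf",
    "mean_ic_density",
    "mean_nfd",
    "mean_nfl",
    "mean_tortuosity",
    "mean_reflectivity",
    "ic_sub",
    "ic_code",
    "nd_sub",
    "nd_code",
    "nm_sub",
    "nm_code",
    "tivcm",
)


@dataclass(frozen=True)
class PatientRecord:
    """One eye's clinical, morphometric, grading and HLA-DR values."""

    patient_id: str
    group: str
    sex: str
    age: float
    osdi_symptoms: float
    osdi_vision: float
    osdi_triggers: float
    osdi_total: float
    schirmer_mm: float
    tbut_s: float
    oxford: int
    pain: float
    hla_dr_auf: float
    morphometry: MorphometrySummary
    score: IVCMScore

    def __post_init__(self) -> None:
        if self.group not in ("AIDED", "NAIDED"):
            raise ValueError(f"unknown group label {self.group!r}")
        if not 0 <= self.osdi_total <= 100:
            raise ValueError(f"OSDI total {self.osdi_total} outside [0,100]")
        if self.schirmer_mm < 0 or self.tbut_s <= 0:
            raise ValueError("Schirmer must be >= 0 and TBUT > 0")
        if self.oxford not in range(6):
            raise ValueError(f"Oxford grade {self.oxford} outside 0-5")
        if self.hla_dr_auf < 0:
            raise ValueError("HLA-DR AUF must be >= 0")


@dataclass(frozen=True)
class CalibratedGroupModel:
    group: str
    margins: dict
    latent_corr: np.ndarray        # after nearest-PSD repair
    latent_corr_raw: np.ndarray    # as assembled from calibrated targets
    factor: np.ndarray             # lower-triangular sampling factor
    calibrated: dict[tuple[str, str], float]


_MODEL_CACHE: dict[str, tuple[CalibratedGroupModel, ...]] = {}


def _fit_group_margins(group: GroupConfig, config: CohortConfig) -> dict:
    margins = {}
    for name, spec in group.clinical.items():
        if spec.family == "truncnorm":
            margins[name] = fit_truncnorm(spec.mean, spec.sd, spec.lo, spec.hi)
        elif spec.family == "lognorm":
            margins[name] = fit_lognorm_moments(spec.mean, spec.sd)
        else:
            margins[name] = fit_ordinal(spec.mean, spec.sd, spec.values)
    s = group.scores
    lat = config.latents
    thr = config.thresholds
    margins["ic_density"] = fit_binned_lognorm(s.icsc_mean, s.icsc_sd, scoring.IC_BIN_EDGES)
    margins["nerve_density"] = fit_lognorm_quantile(
        scoring.ND_THRESHOLD, p_below=s.ndsc_mean, sigma=lat.nerve_density_sigma
    )
    p_flag = s.nmsc_mean / 2.0  # each morphology flag fires with this rate
    margins["tortuosity"] = fit_lognorm_quantile(
        thr.tortuosity, p_below=1.0 - p_flag, sigma=lat.tortuosity_sigma, shift=1.0
    )
    margins["reflectivity"] = fit_lognorm_quantile(
        thr.reflectivity, p_below=1.0 - p_flag, sigma=lat.reflectivity_sigma
    )
    return margins


def _score_transform(name: str, margins: dict):
    """Latent-z -> observed-scale transform for rank calibration, or None."""
    if name == "icsc":
        return lambda z: scoring.ic_subscore_values(margins["ic_density"].from_z(z))
    if name == "ndsc":
        return lambda z: scoring.nd_subscore_values(margins["nerve_density"].from_z(z))
    margin = margins[name]
    return margin.from_z if margin.discrete else None


def _pair_seed(base: int, a: str, b: str) -> int:
    # process-stable (unlike builtin hash) so calibration is reproducible
    digest = hashlib.sha256(f"{min(a, b)}|{max(a, b)}".encode()).digest()
    return (base + int.from_bytes(digest[:4], "big") % 100_000) % (2**31 - 1)


def calibrate_group(group: GroupConfig, config: CohortConfig) -> CalibratedGroupModel:
    """Fit margins, calibrate all planted latent correlations, repair to PSD."""
    margins = _fit_group_margins(group, config)
    cal = config.calibration
    k = len(LATENT_VARS)
    idx = {v: i for i, v in enumerate(LATENT_VARS)}
    corr = np.eye(k)
    calibrated: dict[tuple[str, str], float] = {}

    for a, b, rho in group.pairwise_targets:
        ta, tb = _score_transform(a, margins), _score_transform(b, margins)
        if ta is None and tb is None:
            latent = latent_from_spearman_continuous(rho)
        else:
            latent = calibrate_latent_correlation(
                rho, ta, tb,
                n_calib=cal.n_calib,
                seed=_pair_seed(cal.seed, a, b),
                tol=cal.tol,
            )
        ia = idx[_SCORE_LATENT.get(a, a)]
        ib = idx[_SCORE_LATENT.get(b, b)]
        corr[ia, ib] = corr[ib, ia] = latent
        calibrated[(a, b)] = latent

    thr = config.thresholds
    tort_m, refl_m = margins["tortuosity"], margins["reflectivity"]

    def nm_from(z_tort, z_refl):
        return (tort_m.from_z(z_tort) > thr.tortuosity).astype(int) + (
            refl_m.from_z(z_refl) > thr.reflectivity
        ).astype(int)

    # nerve-morphology subscore vs a partner: shared latent corr c on both flags
    for key, partner in (("nmsc_oxford", "oxford"), ("nmsc_age", "age")):
        target = group.composite_targets.get(key, 0.0)
        if abs(target) < 1e-12:
            continue
        pm = margins[partner]
        partner_t = pm.from_z if pm.discrete else (lambda z: z)

        def builder(c):
            r = np.eye(3)
            r[0, 2] = r[2, 0] = c
            r[1, 2] = r[2, 1] = c
            return r

        c_val = calibrate_joint_correlation(
            builder,
            lambda z: nm_from(z[:, 0], z[:, 1]),
            lambda z: partner_t(z[:, 2]),
            target,
            n_calib=cal.n_calib,
            seed=_pair_seed(cal.seed, key, partner),
            tol=cal.tol,
        )
        it, ir, ip = idx["tortuosity"], idx["reflectivity"], idx[partner]
        corr[it, ip] = corr[ip, it] = c_val
        corr[ir, ip] = corr[ip, ir] = c_val
        calibrated[(key, partner)] = c_val

    # total score vs HLA-DR: add morphology/HLA-DR correlation on top of the
    # already-calibrated cell-density/HLA-DR latent value
    t_target = group.composite_targets.get("tivcm_hla", 0.0)
    if abs(t_target) > 1e-12:
        a_ic_hla = corr[idx["ic_density"], idx["hla_dr_auf"]]
        ic_m, nd_m = margins["ic_density"], margins["nerve_density"]

        def total_from(z):
            icsc = scoring.ic_subscore_values(ic_m.from_z(z[:, 0]))
            ndsc = scoring.nd_subscore_values(nd_m.from_z(z[:, 1]))
            return icsc + ndsc + nm_from(z[:, 2], z[:, 3])

        def builder_total(b):
            r = np.eye(5)
            r[0, 4] = r[4, 0] = a_ic_hla
            r[2, 4] = r[4, 2] = b
            r[3, 4] = r[4, 3] = b
            return r

        b_val = calibrate_joint_correlation(
            builder_total,
            total_from,
            lambda z: z[:, 4],
            t_target,
            n_calib=cal.n_calib,
            seed=_pair_seed(cal.seed, "tivcm", "hla_dr_auf"),
            tol=cal.tol,
        )
        it, ir, ih = idx["tortuosity"], idx["reflectivity"], idx["hla_dr_auf"]
        corr[it, ih] = corr[ih, it] = b_val
        corr[ir, ih] = corr[ih, ir] = b_val
        calibrated[("tivcm_hla", "hla_dr_auf")] = b_val

    repaired = nearest_positive_definite(corr)
    shift = float(np.max(np.abs(repaired - corr)))
    if shift > 0.05:
        log.warning(
            "group %s: PSD repair moved a planted latent correlation by %.3f",
            group.name, shift,
        )
    w, v = np.linalg.eigh(repaired)
    if w.min() < -1e-8:
        raise ValueError("latent correlation matrix not repairable to PSD")
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    return CalibratedGroupModel(
        group=group.name,
        margins=margins,
        latent_corr=repaired,
        latent_corr_raw=corr,
        factor=factor,
        calibrated=calibrated,
    )


def calibrated_models(config: CohortConfig) -> tuple[CalibratedGroupModel, ...]:
    key = config.cache_key()
    if key not in _MODEL_CACHE:
        log.info("calibrating copula model for config %s", config.name)
        _MODEL_CACHE[key] = tuple(calibrate_group(g, config) for g in config.groups)
    return _MODEL_CACHE[key]


def _records_for_group(
    group: GroupConfig,
    model: CalibratedGroupModel,
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[PatientRecord]:
    n = group.n
    if n == 0:
        return []
    k = len(LATENT_VARS)
    z = rng.standard_normal((n, k)) @ model.factor.T
    cols = {
        name: model.margins[name].from_z(z[:, i]) for i, name in enumerate(LATENT_VARS)
    }
    female = rng.random(n) < group.female_fraction
    span = config.latents.mean_nerve_span_mm

    records = []
    for i in range(n):
        nfd = float(cols["nerve_density"][i])
        tort = float(cols["tortuosity"][i])
        summary = MorphometrySummary(
            eye_id=f"{group.name}-{i + 1:04d}",
            n_images_used=5,
            mean_ic_density=float(cols["ic_density"][i]),
            mean_nfd=nfd,
            mean_nfl=nfd * span * tort,
            mean_tortuosity=tort,
            mean_reflectivity=float(cols["reflectivity"][i]),
        )
        records.append(
            PatientRecord(
                patient_id=summary.eye_id,
                group=group.name,
                sex="F" if female[i] else "M",
                age=float(cols["age"][i]),
                osdi_symptoms=float(cols["osdi_symptoms"][i]),
                osdi_vision=float(cols["osdi_vision"][i]),
                osdi_triggers=float(cols["osdi_triggers"][i]),
                osdi_total=float(cols["osdi_total"][i]),
                schirmer_mm=float(cols["schirmer_mm"][i]),
                tbut_s=float(cols["tbut_s"][i]),
                oxford=int(cols["oxford"][i]),
                pain=float(cols["pain"][i]),
                hla_dr_auf=float(cols["hla_dr_auf"][i]),
                morphometry=summary,
                score=score_summary(summary, config.thresholds),
            )
        )
    return records


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> list[PatientRecord]:
    """Generate one cohort; deterministic given (config, seed)."""
    config = config or default_config()
    models = calibrated_models(config)
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    for group, model in zip(config.groups, models):
        group_records = _records_for_group(group, model, config, rng)
        log.info("group %s: generated %d records", group.name, len(group_records))
        records.extend(group_records)
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "group": r.group,
                "sex": r.sex,
                "age": r.age,
                "osdi_symptoms": r.osdi_symptoms,
                "osdi_vision": r.osdi_vision,
                "osdi_triggers": r.osdi_triggers,
                "osdi_total": r.osdi_total,
                "schirmer_mm": r.schirmer_mm,
                "tbut_s": r.tbut_s,
                "oxford": r.oxford,
                "pain": r.pain,
                "hla_dr_auf": r.hla_dr_auf,
                "mean_ic_density": r.morphometry.mean_ic_density,
                "mean_nfd": r.morphometry.mean_nfd,
                "mean_nfl": r.morphometry.mean_nfl,
                "mean_tortuosity": r.morphometry.mean_tortuosity,
                "mean_reflectivity": r.morphometry.mean_reflectivity,
                "ic_sub": r.score.ic_sub,
                "ic_code": r.score.ic_code,
                "nd_sub": r.score.nd_sub,
                "nd_code": r.score.nd_code,
                "nm_sub": r.score.nm_sub,
                "nm_code": r.score.nm_code,
                "tivcm": r.score.total,
            }
        )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def generate_cohort_frame(
    config: CohortConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    return records_to_frame(generate_cohort(config, seed))


def write_cohort_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
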