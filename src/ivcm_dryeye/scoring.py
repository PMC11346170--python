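"""The IVCM grading score for dry eye disease.

Three subscores summarise a patient's corneal sub-basal plexus:

* **ICsc** (0-3): mean inflammatory/dendritic-cell density, binned at
  10, 50 and 100 cells/mm² (codes IC-0..IC-3).
* **NDsc** (0-1): sub-basal nerve density, normal (>15 nerves/mm², ND-1)
  vs decreased (<=15, ND-2).  Note the *worse* state scores higher.
* **NMsc** (0-2): nerve morphology, one point each for abnormal
  reflectivity (NM1-R) and abnormal tortuosity (NM1-T); both -> NM-2.

The total score T-IVCM = ICsc + NDsc + NMsc ranges 0-6.

The printed density bands leave the gaps (49, 50) and (99, 100) unassigned;
densities are real-valued averages, so the bands are read as half-open bins
[0,10), [10,50), [50,100), [100,inf) -- every nonnegative density is scored
and 100 cells/mm² grades IC-3.  Morphology grading is qualitative in the
clinic; here it is operationalised by configurable thresholds on the
measured tortuosity (arc/chord) and reflectivity indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: half-open IC-density bin edges (cells/mm2); bin index == subscore
IC_BIN_EDGES: tuple[float, ...] = (10.0, 50.0, 100.0)
IC_CODES: tuple[str, ...] = ("IC-0", "IC-1", "IC-2", "IC-3")

#: nerve density at or below this (nerves/mm2) is graded "decreased"
ND_THRESHOLD: float = 15.0
ND_CODES: tuple[str, str] = ("ND-1", "ND-2")

NM_CODES: dict[tuple[bool, bool], tuple[int, str]] = {
    (False, False): (0, "NM-0"),
    (True, False): (1, "NM1-R"),
    (False, True): (1, "NM1-T"),
    (True, True): (2, "NM-2"),
}

TOTAL_MIN, TOTAL_MAX = 0, 6


@dataclass(frozen=True)
class MorphologyThresholds:
    """Cutoffs turning continuous morphology indices into grading flags.

    tortuosity: arc/chord ratio above which a nerve plexus is graded
        tortuous (1.0 = perfectly straight).
    reflectivity: nerve/background intensity ratio above which the plexus
        is graded hyper-reflective.
    """

    tortuosity: float = 1.2
    reflectivity: float = 2.5


@dataclass(frozen=True)
class IVCMScore:
    ic_sub: int
    ic_code: str
    nd_sub: int
    nd_code: str
    nm_sub: int
    nm_code: str
    total: int

    def __post_init__(self) -> None:
        if self.total != self.ic_sub + self.nd_sub + self.nm_sub:
            raise ValueError("total must equal the sum of the subscores")
        if not (TOTAL_MIN <= self.total <= TOTAL_MAX):
            raise ValueError(f"total {self.total} outside [{TOTAL_MIN}, {TOTAL_MAX}]")


def ic_subscore(mean_ic_density: float) -> tuple[int, str]:
    """Grade a mean inflammatory-cell density (cells/mm2) into ICsc 0-3."""
    if mean_ic_density < 0:
        raise ValueError(f"density must be >= 0, got {mean_ic_density}")
    sub = int(np.digitize(mean_ic_density, IC_BIN_EDGES))
    return sub, IC_CODES[sub]


def ic_subscore_values(densities: np.ndarray) -> np.ndarray:
    """Vectorised ICsc for an array of densities."""
    d = np.asarray(densities, dtype=float)
    if np.any(d < 0):
        raise ValueError("densities must be >= 0")
    return np.digitize(d, IC_BIN_EDGES)


def nd_subscore(mean_nfd: float) -> tuple[int, str]:
    """Grade nerve fiber density (nerves/mm2): >15 normal (0), <=15 decreased (1)."""
    if mean_nfd < 0:
        raise ValueError(f"nerve density must be >= 0, got {mean_nfd}")
    sub = int(mean_nfd <= ND_THRESHOLD)
    return sub, ND_CODES[sub]


def nd_subscore_values(nfd: np.ndarray) -> np.ndarray:
    d = np.asarray(nfd, dtype=float)
    if np.any(d < 0):
        raise ValueError("nerve densities must be >= 0")
    return (d <= ND_THRESHOLD).astype(int)


def nm_subscore(
    reflectivity_abnormal: bool, tortuosity_abnormal: bool
) -> tuple[int, str]:
    """Grade nerve morphology from the two abnormality flags."""
    return NM_CODES[(bool(reflectivity_abnormal), bool(tortuosity_abnormal))]


def flag_morphology(
    summary, thresholds: MorphologyThresholds = MorphologyThresholds()
) -> tuple[bool, bool]:
    """(reflectivity_abnormal, tortuosity_abnormal) from a morphometry summary."""
    for field in ("mean_reflectivity", "mean_tortuosity"):
        value = getattr(summary, field, None)
        if value is None:
            raise ValueError(f"morphometry summary is missing '{field}'")
    return (
        summary.mean_reflectivity > thresholds.reflectivity,
        summary.mean_tortuosity > thresholds.tortuosity,
    )


def total_score(ic_sub: int, nd_sub: int, nm_sub: int) -> int:
    if ic_sub not in (0, 1, 2, 3):
        raise ValueError(f"ic_sub out of range: {ic_sub}")
    if nd_sub not in (0, 1):
        raise ValueError(f"nd_sub out of range: {nd_sub}")
    if nm_sub not in (0, 1, 2):
        raise ValueError(f"nm_sub out of range: {nm_sub}")
    return ic_sub + nd_sub + nm_sub


def score_summary(
    summary, thresholds: MorphologyThresholds = MorphologyThresholds()
) -> IVCMScore:
    """Full score for one eye's morphometry summary."""
    ic_sub, ic_code = ic_subscore(summary.mean_ic_density)
    nd_sub, nd_code = nd_subscore(summary.mean_nfd)
    refl_ab, tort_ab = flag_morphology(summary, thresholds)
    nm_sub, nm_code = nm_subscore(refl_ab, tort_ab)
    return IVCMScore(
        ic_sub=ic_sub,
        ic_code=ic_code,
        nd_sub=nd_sub,
        nd_code=nd_code,
        nm_sub=nm_sub,
        nm_code=nm_code,
        total=total_score(ic_sub, nd_sub, nm_sub),
    )


@dataclass(frozen=True)
class EyeExam:
    """Minimal per-eye clinical data needed for worst-eye selection."""

    eye_id: str
    oxford: int
    pain: float | None = None


def select_worst_eye(right: EyeExam, left: EyeExam, seed: int = 0) -> str:
    """Pick the worse eye: higher Oxford, then higher pain, then a seeded coin.

    One eye per patient enters the cohort; the seeded tie-break keeps the
    selection reproducible while remaining uniform across seeds.
    """
    for eye in (right, left):
        if eye.oxford is None:
            raise ValueError(f"eye {eye.eye_id} has no Oxford score")
    if right.oxford != left.oxford:
        return right.eye_id if right.oxford > left.oxford else left.eye_id
    pr = right.pain if right.pain is not None else -np.inf
    pl = left.pain if left.pain is not None else -np.inf
    if pr != pl:
        return right.eye_id if pr > pl else left.eye_id
    rng = np.random.default_rng(seed)
    return right.eye_id if rng.random() < 0.5 else left.eye_id
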