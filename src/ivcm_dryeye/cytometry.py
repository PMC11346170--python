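"""Bead-calibrated quantification of conjunctival HLA-DR fluorescence.

Flow-cytometry mean fluorescence intensities (MFI) are instrument- and
session-specific; quantitative bead kits carry populations of known
antibody-binding capacity (ABC) that are acquired alongside the samples.
Regressing log10(ABC) on log10(MFI) of the beads gives a session
calibration line, and a sample's background-subtracted MFI is converted to
arbitrary units of fluorescence (AUF) through that line:

    AUF = 10 ** (intercept + slope * log10(MFI_sample - MFI_background))

Inputs are pre-gated MFI summaries (listmode parsing is out of scope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class BeadSet:
    """Calibration bead populations: (MFI, assigned ABC) pairs."""

    mfi: tuple[float, ...]
    abc: tuple[float, ...]
    lot_id: str = ""

    def __post_init__(self) -> None:
        if len(self.mfi) != len(self.abc):
            raise ValueError("mfi and abc must have equal length")
        if len(self.mfi) < 3:
            raise ValueError("need at least 3 bead populations")
        if min(self.mfi) <= 0 or min(self.abc) <= 0:
            raise ValueError("bead MFI and ABC must be positive")
        order = np.argsort(self.mfi)
        abc_sorted = np.asarray(self.abc)[order]
        if not (np.all(np.diff(np.asarray(self.mfi)[order]) > 0)
                and np.all(np.diff(abc_sorted) > 0)):
            raise ValueError("beads must be strictly increasing in MFI and ABC")


@dataclass(frozen=True)
class BeadCalibration:
    slope: float
    intercept: float
    r_squared: float
    n_beads: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("calibration coefficients must be finite")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0,1]")


def fit_bead_calibration(beads: BeadSet, r2_warn: float = 0.98) -> BeadCalibration:
    """Ordinary least squares of log10(ABC) on log10(MFI)."""
    x = np.log10(np.asarray(beads.mfi, dtype=float))
    y = np.log10(np.asarray(beads.abc, dtype=float))
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    if r2 < r2_warn:
        warnings.warn(
            f"bead calibration r²={r2:.4f} below {r2_warn}; check the bead acquisition"
        )
    return BeadCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(r2, 1.0),
        n_beads=len(beads.mfi),
    )


def mfi_to_auf(
    cal: BeadCalibration, sample_mfi: float, background_mfi: float = 0.0
) -> tuple[float, bool]:
    """Convert one sample MFI to AUF; returns (auf, below_background_flag).

    A sample at or below the background control converts to 0 AUF and is
    flagged rather than producing a negative or undefined value.
    """
    if cal is None:
        raise ValueError("no bead calibration supplied")
    if background_mfi < 0:
        raise ValueError("background MFI must be >= 0")
    net = sample_mfi - background_mfi
    if net <= 0:
        return 0.0, True
    return float(10.0 ** (cal.intercept + cal.slope * np.log10(net))), False


def auf_to_mfi(cal: BeadCalibration, auf: float, background_mfi: float = 0.0) -> float:
    """Inverse of :func:`mfi_to_auf` for positive AUF (used to synthesise MFIs)."""
    if auf <= 0:
        return background_mfi
    return background_mfi + 10.0 ** ((np.log10(auf) - cal.intercept) / cal.slope)
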