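"""Percent α-helix from circular-dichroism spectra.

The mean residue ellipticity (MRE, deg·cm²·dmol⁻¹) at 222 nm reports
α-helix content: fully helical peptides show a deep negative band there,
random coil a value near the baseline. The helicity estimate is the linear
map

    % α-helix = −(MRE₂₂₂ + 2340) / 303

so that MRE₂₂₂ = −2340 corresponds to 0 % helix and each additional −303
deg·cm²·dmol⁻¹ adds one percentage point (100 % at −32640). The sign is
chosen so helicity grows as the 222 nm band deepens; estimates are clipped
to [0, 100] with a warning, since noisy baselines can overshoot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CDSpectrum", "HelicityModel", "read_spectrum", "mre_at", "helicity_percent"]


@dataclass(frozen=True)
class HelicityModel:
    """Linear MRE₂₂₂ → helicity calibration: baseline b, slope s (per %)."""

    baseline: float = 2340.0  # deg·cm²·dmol⁻¹
    slope: float = 303.0  # deg·cm²·dmol⁻¹ per % helix

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be positive")


@dataclass
class CDSpectrum:
    """Ordered (wavelength nm, MRE) pairs with strictly monotone wavelengths."""

    wavelengths: np.ndarray
    mre: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mre = np.asarray(self.mre, dtype=float)
        if self.wavelengths.shape != self.mre.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and MRE must be equal-length 1-D arrays")
        if self.wavelengths.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        diffs = np.diff(self.wavelengths)
        if not ((diffs > 0).all() or (diffs < 0).all()):
            raise ValueError("wavelengths must be strictly monotone")
        if not (np.isfinite(self.wavelengths).all() and np.isfinite(self.mre).all()):
            raise ValueError("spectrum values must be finite")

    def ascending(self) -> "CDSpectrum":
        if self.wavelengths[0] < self.wavelengths[-1]:
            return self
        return CDSpectrum(self.wavelengths[::-1].copy(), self.mre[::-1].copy())


def read_spectrum(path: str | Path, sep: str | None = None) -> CDSpectrum:
    """Read a two-column wavelength/MRE text table (CSV, TSV or whitespace)."""
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, MRE)")
    return CDSpectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def mre_at(spectrum: CDSpectrum, wavelength: float = 222.0) -> float:
    """MRE at a wavelength: exact sample if present, else linear interpolation.

    Raises for wavelengths outside the sampled range (no extrapolation).
    """
    spec = spectrum.ascending()
    lo, hi = spec.wavelengths[0], spec.wavelengths[-1]
    if not (lo <= wavelength <= hi):
        raise ValueError(
            f"wavelength {wavelength} nm outside the sampled range [{lo}, {hi}]"
        )
    return float(np.interp(wavelength, spec.wavelengths, spec.mre))


def helicity_percent(mre222: float, model: HelicityModel = HelicityModel()) -> float:
    """Percent α-helix from MRE at 222 nm, clipped to [0, 100]."""
    if not np.isfinite(mre222):
        raise ValueError("MRE must be finite")
    raw = -(mre222 + model.baseline) / model.slope
    if raw < 0.0 or raw > 100.0:
        warnings.warn(
            f"helicity estimate {raw:.2f}% outside [0, 100]; clipping",
            UserWarning,
            stacklevel=2,
        )
    return float(np.clip(raw, 0.0, 100.0))
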