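"""Langmuir-monolayer thermodynamics.

A compression record of surface pressure pi (mN/m) against area per
molecule A (nm^2) yields:

* the compression modulus Cs^-1 = -A (dpi/dA), whose maximum classifies the
  film's physical state on the Davies-Rideal scale,
* the mean molecular area A12 at a chosen pressure,
* the excess area A^exc = A12 - (X1 A1 + X2 A2) relative to ideal mixing,
* the excess free energy of mixing dG^exc = N_A * integral_0^pi* A^exc dpi,
  reported in kJ/mol (1 mN/m * nm^2 * N_A = 0.6022 kJ/mol).

Positive dG^exc marks less favourable packing than in the pure films;
literature places the onset of visible phase separation at roughly
0.8-1.2 kJ/mol, quoted here only as an annotation, never as a decision rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

__all__ = [
    "Isotherm",
    "CompressionModulusCurve",
    "MixingAnalysis",
    "compression_modulus",
    "classify_state",
    "area_at_pressure",
    "excess_area",
    "excess_free_energy",
    "mixing_analysis",
    "KJ_PER_MOL_PER_MN_NM",
    "PHASE_SEPARATION_BAND_KJ_MOL",
]

#: 1 mN/m x 1 nm^2 x Avogadro's number, in kJ/mol.
KJ_PER_MOL_PER_MN_NM = 0.6022

#: Literature band above which excess free energy suggests phase separation.
PHASE_SEPARATION_BAND_KJ_MOL = (0.8, 1.2)


@dataclass(frozen=True)
class Isotherm:
    """One pi-A compression record for a film of fixed composition.

    ``x1``/``x2`` are the mole fractions of the two components (x1 + x2 = 1);
    ``pi`` (mN/m) and ``area`` (nm^2/molecule) are ordered along compression,
    i.e. area strictly decreasing.
    """

    pi: np.ndarray
    area: np.ndarray
    x1: float = 1.0
    x2: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        area = np.asarray(self.area, dtype=float)
        if pi.shape != area.shape or pi.ndim != 1:
            raise ValueError("pi and area must be 1-D arrays of equal length")
        if len(pi) < 4:
            raise ValueError("an isotherm needs at least 4 points")
        if np.any(pi < 0):
            raise ValueError("surface pressure must be non-negative")
        if np.any(area <= 0):
            raise ValueError("area per molecule must be positive")
        if abs(self.x1 + self.x2 - 1.0) > 1e-9:
            raise ValueError("mole fractions must sum to 1")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "area", area)

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.area) < 0))

    def cleaned(self) -> "Isotherm":
        """Drop points breaking strict area decrease along compression.

        Collapse plateaus and balance noise produce locally non-decreasing
        area; such points are removed (keeping the first of each run) so
        that interpolation and the Cs^-1 derivative are well defined.
        """
        keep = [0]
        last = self.area[0]
        for i in range(1, len(self.area)):
            if self.area[i] < last:
                keep.append(i)
                last = self.area[i]
        dropped = len(self.area) - len(keep)
        if dropped:
            logger.info("isotherm %s: dropped %d non-monotone points",
                        self.label or "<unnamed>", dropped)
        return Isotherm(self.pi[keep], self.area[keep], self.x1, self.x2, self.label)

    @classmethod
    def from_csv(cls, path, x1: float | None = None, x2: float | None = None,
                 label: str = "") -> "Isotherm":
        """Read ``pi_mN_per_m``, ``area_nm2`` columns; ``# key: value`` header
        comments may carry ``x1``/``x2`` metadata."""
        meta: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        data_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    try:
                        meta[key.strip()] = float(value)
                    except ValueError:
                        pass
                data_start = i + 1
            else:
                break
        from io import StringIO
        df = pd.read_csv(StringIO("".join(lines[data_start:])))
        if x1 is None:
            x1 = meta.get("x1", 1.0)
        if x2 is None:
            x2 = meta.get("x2", 1.0 - x1)
        return cls(df["pi_mN_per_m"].to_numpy(), df["area_nm2"].to_numpy(),
                   x1=float(x1), x2=float(x2), label=label or str(path))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# x1: {self.x1}\n# x2: {self.x2}\n")
            fh.write("pi_mN_per_m,area_nm2\n")
            for p, a in zip(self.pi, self.area):
                fh.write(f"{p:.6f},{a:.8f}\n")


@dataclass(frozen=True)
class CompressionModulusCurve:
    """Cs^-1 as a function of surface pressure, with its maximum."""

    pi: np.ndarray
    cs_inverse: np.ndarray       # mN/m
    max_value: float
    pi_at_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pi_mN_per_m": self.pi, "cs_inv_mN_per_m": self.cs_inverse})


@dataclass(frozen=True)
class MixingAnalysis:
    """Mixing quantities of one composition at the target pressure."""

    pi_star: float
    x1: float
    x2: float
    a12: float                   # nm^2
    ideal_area: float            # nm^2
    excess_area: float           # nm^2
    dg_excess: float             # kJ/mol
    annotation: str = field(default="")


def compression_modulus(iso: Isotherm, window: int = 11,
                        polyorder: int = 2) -> CompressionModulusCurve:
    """Compression modulus Cs^-1 = -A (dpi/dA) along an isotherm.

    The record is cleaned to strict monotonicity, pi is resampled onto a
    uniform area grid and the derivative is taken with a Savitzky-Golay
    filter (quadratic, default 11-point window) — raw balance data are
    noisy and a smoothed stencil keeps the modulus stable.
    """
    iso = iso.cleaned()
    n = len(iso.pi)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if n < window:
        raise ValueError(f"need at least {window} monotone points, got {n}")
    # ascending area for interpolation
    area_asc = iso.area[::-1]
    pi_asc = iso.pi[::-1]
    grid = np.linspace(area_asc[0], area_asc[-1], n)
    pi_grid = np.interp(grid, area_asc, pi_asc)
    dpi_da = savgol_filter(pi_grid, window_length=window, polyorder=polyorder,
                           deriv=1, delta=grid[1] - grid[0])
    cs = -grid * dpi_da
    order = np.argsort(pi_grid)
    pi_sorted = pi_grid[order]
    cs_sorted = cs[order]
    imax = int(np.argmax(cs_sorted))
    return CompressionModulusCurve(pi_sorted, cs_sorted,
                                   float(cs_sorted[imax]), float(pi_sorted[imax]))


_DAVIES_RIDEAL_BANDS = (
    (0.0, 12.5, "gaseous"),
    (12.5, 50.0, "liquid-expanded"),
    (50.0, 100.0, "liquid"),
    (100.0, 250.0, "liquid-condensed"),
    (250.0, np.inf, "solid"),
)


def classify_state(cs_max: float) -> str:
    """Davies-Rideal monolayer state from the maximum compression modulus.

    Bands are closed below and open above, so exactly 50 mN/m reads
    "liquid".
    """
    if cs_max < 0:
        raise ValueError("compression modulus maximum must be non-negative")
    for lo, hi, labelled in _DAVIES_RIDEAL_BANDS:
        if lo <= cs_max < hi:
            return labelled
    return "solid"


def area_at_pressure(iso: Isotherm, pi_star: float) -> float:
    """Mean molecular area at the given pressure by linear interpolation."""
    iso = iso.cleaned()
    lo, hi = float(iso.pi.min()), float(iso.pi.max())
    if not (lo <= pi_star <= hi):
        raise ValueError(f"pi* = {pi_star} mN/m outside the recorded range "
                         f"[{lo}, {hi}] of {iso.label or 'isotherm'}")
    order = np.argsort(iso.pi)
    return float(np.interp(pi_star, iso.pi[order], iso.area[order]))


def excess_area(a12: float, a1: float, a2: float, x1: float, x2: float) -> float:
    """Excess area A^exc = A12 - (X1 A1 + X2 A2), nm^2."""
    if abs(x1 + x2 - 1.0) > 1e-9:
        raise ValueError("mole fractions must sum to 1")
    if min(a12, a1, a2) < 0:
        raise ValueError("areas must be non-negative")
    return a12 - (x1 * a1 + x2 * a2)


def excess_free_energy(mix: Isotherm, pure1: Isotherm, pure2: Isotherm,
                       pi_star: float, n_grid: int = 512,
                       low_pi_tolerance: float = 1.0) -> float:
    """Excess free energy of mixing at pi*, kJ/mol.

    A^exc(pi) is evaluated on a common pressure grid by linear interpolation
    of the three records and integrated by the trapezoidal rule from the
    lowest commonly recorded pressure up to pi*.  Pressures below that
    starting point (never measured on a film balance) contribute zero excess
    provided the gap is at most ``low_pi_tolerance`` mN/m.
    """
    mix, pure1, pure2 = mix.cleaned(), pure1.cleaned(), pure2.cleaned()
    names = ("mixture", "pure component 1", "pure component 2")
    for iso, name in zip((mix, pure1, pure2), names):
        if iso.pi.max() < pi_star:
            raise ValueError(f"{name} isotherm does not reach pi* = {pi_star} mN/m")
    pi_min = max(float(iso.pi.min()) for iso in (mix, pure1, pure2))
    if pi_min > low_pi_tolerance:
        raise ValueError(f"isotherms start at {pi_min} mN/m > {low_pi_tolerance}; "
                         "the zero-pressure limit cannot be approximated")
    grid = np.linspace(pi_min, pi_star, n_grid)

    def area_on(iso: Isotherm) -> np.ndarray:
        order = np.argsort(iso.pi)
        return np.interp(grid, iso.pi[order], iso.area[order])

    a_exc = area_on(mix) - (mix.x1 * area_on(pure1) + mix.x2 * area_on(pure2))
    integral = float(np.trapezoid(a_exc, grid))      # nm^2 * mN/m
    return KJ_PER_MOL_PER_MN_NM * integral


def mixing_analysis(mix: Isotherm, pure1: Isotherm, pure2: Isotherm,
                    pi_star: float = 30.0) -> MixingAnalysis:
    """Full mixing analysis of one composition at pi* (default 30 mN/m)."""
    a12 = area_at_pressure(mix, pi_star)
    a1 = area_at_pressure(pure1, pi_star)
    a2 = area_at_pressure(pure2, pi_star)
    ideal = mix.x1 * a1 + mix.x2 * a2
    a_exc = excess_area(a12, a1, a2, mix.x1, mix.x2)
    dg = excess_free_energy(mix, pure1, pure2, pi_star)
    lo, hi = PHASE_SEPARATION_BAND_KJ_MOL
    if dg > hi:
        note = f"dG_exc above the {lo}-{hi} kJ/mol phase-separation band"
    elif dg > lo:
        note = f"dG_exc within the {lo}-{hi} kJ/mol phase-separation band"
    else:
        note = f"dG_exc below the {lo}-{hi} kJ/mol phase-separation band"
    return MixingAnalysis(pi_star, mix.x1, mix.x2, a12, ideal, a_exc, dg, note)
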