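"""Raw assay readings → the eight cell-surface properties.

Covers the MATH hydrophobicity fraction, potentiometric-titration charge
accounting (net charge vs pH, charge at pH 8, total acidity, point of zero
charge), colorimetric EPS quantitation through linear standard curves, and
assembly of the per-strain property table.  Zeta potential is an instrument
output and passes through unchanged.

Charge accounting: for a suspension titrated from pH 4 to 10, the number of
deprotonated surface sites per 10^8 cells is the acid/base balance of the
sample minus the blank,

    q(pH) = [(C_A − C_B − [H+] + [OH−])_sample − (C_A − C_B − [H+] + [OH−])_blank]
            / (N_bact / 10^8) × 10^−3      [meq / 10^8 cells]

with C_A, C_B cumulative acid/base in mmol/L, [H+] = 10^(3−pH) mmol/L,
[OH−] = 10^(pH−pKw+3) mmol/L, and N_bact the cell count per mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TitrationCurve",
    "ChargeProfile",
    "StandardCurve",
    "PROPERTY_COLUMNS",
    "hydrophobic_partitioning",
    "net_charge_profile",
    "average_charge_profiles",
    "charge_at",
    "total_acidity",
    "point_of_zero_charge",
    "eps_concentration",
    "build_property_table",
]

PKW = 14.0  # room-temperature ion product of water

#: Fixed property vocabulary of the per-strain table.
PROPERTY_COLUMNS = [
    "hydrophobicity",
    "zeta_potential",
    "eps_protein",
    "eps_sugar",
    "eps_ratio",
    "net_charge_ph8",
    "total_acidity",
    "pzc",
]


@dataclass
class TitrationCurve:
    """Cumulative acid/base record of one titration from pH 4 to 10.

    ``role`` distinguishes the cell suspension ("sample") from the
    electrolyte-only "blank"; ``n_bact`` (cells/mL) is required for samples
    and ignored for blanks.
    """

    ph: np.ndarray
    c_acid: np.ndarray  # cumulative acid, mmol/L
    c_base: np.ndarray  # cumulative base, mmol/L
    role: str = "sample"
    n_bact: float | None = None

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.c_acid = np.asarray(self.c_acid, dtype=float)
        self.c_base = np.asarray(self.c_base, dtype=float)
        if self.role not in ("sample", "blank"):
            raise ValueError("role must be 'sample' or 'blank'")
        if self.ph.ndim != 1 or self.c_acid.shape != self.ph.shape or self.c_base.shape != self.ph.shape:
            raise ValueError("ph, c_acid, c_base must be 1-D arrays of equal length")
        if self.ph.size < 2:
            raise ValueError("a titration needs at least two points")
        if np.any(np.diff(self.ph) <= 0):
            raise ValueError("pH must be strictly increasing along the titration")
        if np.any(self.c_acid < 0) or np.any(self.c_base < 0):
            raise ValueError("cumulative acid/base must be non-negative")
        if np.any(np.diff(self.c_base) < -1e-12) or np.any(np.diff(self.c_acid) < -1e-12):
            raise ValueError("cumulative amounts must be non-decreasing along the titration")
        if self.role == "sample":
            if self.n_bact is None or self.n_bact <= 0:
                raise ValueError("sample titrations need n_bact > 0 (cells/mL)")


@dataclass
class ChargeProfile:
    """Net surface charge (meq per 10^8 cells) on an increasing pH grid."""

    ph_grid: np.ndarray
    net_charge: np.ndarray

    def __post_init__(self) -> None:
        self.ph_grid = np.asarray(self.ph_grid, dtype=float)
        self.net_charge = np.asarray(self.net_charge, dtype=float)
        if self.ph_grid.shape != self.net_charge.shape or self.ph_grid.ndim != 1:
            raise ValueError("grid and charge must be 1-D arrays of equal length")
        if np.any(np.diff(self.ph_grid) <= 0):
            raise ValueError("pH grid must be strictly increasing")
        if not np.all(np.isfinite(self.net_charge)):
            raise ValueError("net charge must be finite")


def hydrophobic_partitioning(initial_od: float, aqueous_od: float) -> float:
    """MATH hydrophobicity: fraction of cells leaving the aqueous phase.

    (initial OD546 − aqueous-phase OD546) / initial OD546, clamped to [0, 1]
    (an aqueous OD above the initial reading is measurement noise and clamps
    to 0 with a warning).
    """
    if initial_od <= 0:
        raise ValueError("initial OD must be positive")
    if aqueous_od < 0:
        raise ValueError("aqueous OD must be non-negative")
    frac = (initial_od - aqueous_od) / initial_od
    if frac < 0:
        warnings.warn("aqueous OD exceeds initial OD; hydrophobicity clamped to 0", stacklevel=2)
        return 0.0
    return min(frac, 1.0)


def _proton_hydroxide_mmol(ph: np.ndarray, pkw: float = PKW) -> tuple[np.ndarray, np.ndarray]:
    h = 10.0 ** (3.0 - ph)
    oh = 10.0 ** (ph - pkw + 3.0)
    return h, oh


def net_charge_profile(
    sample: TitrationCurve,
    blank: TitrationCurve,
    ph_grid: np.ndarray | None = None,
    pkw: float = PKW,
    literal_sign: bool = False,
) -> ChargeProfile:
    """Blank-corrected net surface charge vs pH from a pair of titrations.

    Both records are interpolated (piecewise-linear in pH) onto a common
    grid — by default the sample's pH points restricted to the overlap with
    the blank.  ``literal_sign=True`` switches the sample term to
    (C_A − C_B − [H+] − [OH−]); the default uses +[OH−] in both terms so a
    sample identical to the blank gives a profile that is exactly zero.
    """
    if sample.role != "sample" or blank.role != "blank":
        raise ValueError("need one 'sample' curve and one 'blank' curve")
    lo = max(sample.ph[0], blank.ph[0])
    hi = min(sample.ph[-1], blank.ph[-1])
    if lo >= hi:
        raise ValueError("sample and blank titrations do not overlap in pH")
    if ph_grid is None:
        grid = sample.ph[(sample.ph >= lo) & (sample.ph <= hi)]
    else:
        grid = np.asarray(ph_grid, dtype=float)
        if grid.min() < lo or grid.max() > hi:
            raise ValueError("requested grid extends beyond the titrated overlap")
    h, oh = _proton_hydroxide_mmol(grid, pkw)
    ca_s = np.interp(grid, sample.ph, sample.c_acid)
    cb_s = np.interp(grid, sample.ph, sample.c_base)
    ca_b = np.interp(grid, blank.ph, blank.c_acid)
    cb_b = np.interp(grid, blank.ph, blank.c_base)
    oh_sample_sign = -1.0 if literal_sign else 1.0
    term_sample = ca_s - cb_s - h + oh_sample_sign * oh
    term_blank = ca_b - cb_b - h + oh
    per_1e8 = sample.n_bact / 1e8  # type: ignore[operator]
    q = (term_sample - term_blank) / per_1e8 * 1e-3
    return ChargeProfile(grid, q)


def average_charge_profiles(profiles: Sequence[ChargeProfile]) -> ChargeProfile:
    """Mean of replicate charge profiles, interpolated onto the first grid."""
    if not profiles:
        raise ValueError("no profiles to average")
    grid = profiles[0].ph_grid
    stack = [profiles[0].net_charge]
    for p in profiles[1:]:
        if p.ph_grid[0] > grid[0] or p.ph_grid[-1] < grid[-1]:
            raise ValueError("replicate profiles must cover the reference grid")
        stack.append(np.interp(grid, p.ph_grid, p.net_charge))
    return ChargeProfile(grid, np.mean(stack, axis=0))


def charge_at(profile: ChargeProfile, ph: float = 8.0) -> float:
    """Net charge at a pH, linearly interpolated; no extrapolation."""
    if ph < profile.ph_grid[0] or ph > profile.ph_grid[-1]:
        raise ValueError(f"pH {ph} outside the titrated range")
    return float(np.interp(ph, profile.ph_grid, profile.net_charge))


def total_acidity(profile: ChargeProfile) -> float:
    """Titratable acidity: net charge at pH 4 minus net charge at pH 10."""
    return charge_at(profile, 4.0) - charge_at(profile, 10.0)


def point_of_zero_charge(profile: ChargeProfile) -> float | None:
    """pH of the first sign change of the net charge, scanning upward.

    Located by linear interpolation between the bracketing grid points;
    ``None`` when the charge never changes sign over the grid (a strain can
    legitimately stay negative throughout the titrated window).  Additional
    crossings beyond the first are reported as a warning.
    """
    q = profile.net_charge
    sign = np.sign(q)
    crossings = []
    for i in range(len(q) - 1):
        if sign[i] == 0:
            crossings.append(float(profile.ph_grid[i]))
        elif sign[i] * sign[i + 1] < 0:
            p0, p1 = profile.ph_grid[i], profile.ph_grid[i + 1]
            q0, q1 = q[i], q[i + 1]
            crossings.append(float(p0 + (0.0 - q0) * (p1 - p0) / (q1 - q0)))
    if sign[-1] == 0:
        crossings.append(float(profile.ph_grid[-1]))
    if not crossings:
        return None
    if len(crossings) > 1:
        warnings.warn(
            f"multiple zero crossings at pH {crossings}; reporting the first",
            stacklevel=2,
        )
    return crossings[0]


@dataclass
class StandardCurve:
    """Linear calibration line fitted through (concentration, absorbance) standards."""

    concentrations: np.ndarray
    absorbances: np.ndarray
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if c.shape != a.shape or c.ndim != 1:
            raise ValueError("standards must be matched 1-D arrays")
        if np.unique(c).size < 2:
            raise ValueError("need at least two distinct standard concentrations")
        slope, intercept = np.polyfit(c, a, 1)
        if slope == 0:
            raise ValueError("standard curve has zero slope")
        self.concentrations = c
        self.absorbances = a
        self.slope = float(slope)
        self.intercept = float(intercept)

    def invert(self, absorbance: float) -> float:
        return (absorbance - self.intercept) / self.slope


def eps_concentration(absorbance: float, curve: StandardCurve, n_cells: float) -> float:
    """EPS content (μg per 10^8 cells) from a colorimetric reading.

    The standard curve maps total μg in the assayed extract to absorbance;
    ``n_cells`` is the total cell count the extract came from.  Readings
    below the calibration intercept clamp to zero with a warning.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    total = curve.invert(absorbance)
    if total < 0:
        warnings.warn("absorbance below the standard-curve intercept; clamped to 0", stacklevel=2)
        total = 0.0
    return total / (n_cells / 1e8)


def build_property_table(
    records: Iterable,
    blank: TitrationCurve,
    protein_curve: StandardCurve,
    sugar_curve: StandardCurve,
) -> pd.DataFrame:
    """Assemble the strains × 8 properties table from raw per-strain readings.

    ``records`` are StrainRecord-like objects (see :mod:`colisurf.cohort`).
    A strain with no zero-charge crossing gets a missing PZC (NaN), never a
    zero.  Duplicate strain ids are an error.
    """
    rows = []
    ids = []
    for rec in records:
        cp = net_charge_profile(rec.titration, blank)
        pzc = point_of_zero_charge(cp)
        protein = eps_concentration(rec.eps_absorbances[0], protein_curve, rec.eps_n_cells)
        sugar = eps_concentration(rec.eps_absorbances[1], sugar_curve, rec.eps_n_cells)
        rows.append(
            {
                "habitat": rec.habitat,
                "hydrophobicity": hydrophobic_partitioning(*rec.math_reading),
                "zeta_potential": rec.zeta_potential,
                "eps_protein": protein,
                "eps_sugar": sugar,
                "eps_ratio": protein / sugar if sugar > 0 else np.nan,
                "net_charge_ph8": charge_at(cp, 8.0),
                "total_acidity": total_acidity(cp),
                "pzc": np.nan if pzc is None else pzc,
            }
        )
        ids.append(rec.strain_id)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids in cohort")
    table = pd.DataFrame(rows, index=pd.Index(ids, name="strain_id"))
    return table[["habitat"] + PROPERTY_COLUMNS]
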