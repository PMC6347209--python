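"""Exact-mass arithmetic for MALDI imaging: formulas, adducts, lock-mass correction.

Monoisotopic masses come from a frozen in-code table (IUPAC values, 7 decimal
places) so results are reproducible offline.  Adduct m/z values are
electron-corrected: ``[M+H]+ = M + m(H) - m(e)`` and ``[M+Na]+ = M + m(Na) - m(e)``.

The lock-mass correction is the single-point additive recalibration used with
an abundant matrix peak of known mass (here, by default, the sodium adduct of
the CHCA matrix): the most intense peak inside a search window is located and
the whole m/z axis is shifted so that peak lands exactly on the reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Mapping, Tuple, Union

import numpy as np

from .imzml import Spectrum

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "CATION_MASS",
    "MassWindow",
    "LockMassSpec",
    "RecalibrationResult",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "lock_mass_recalibrate",
]

#: Monoisotopic masses of the most abundant isotope, Da (frozen, 7 dp).
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.0078250,
    "C": 12.0000000,
    "N": 14.0030740,
    "O": 15.9949146,
    "Na": 22.9897693,
    "S": 31.9720707,
    "P": 30.9737615,
    "K": 38.9637065,
    "Cl": 34.9688527,
    "F": 18.9984032,
}

ELECTRON_MASS = 0.0005486
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.0072764 Da

#: Cation masses added to the neutral monoisotopic mass for each adduct.
CATION_MASS: Dict[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M+Na]+": MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS,
}

FormulaLike = Union[str, Mapping[str, int]]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-notation molecular formula, e.g. ``"C17H23NO3"``.

    Returns a mapping element symbol → count.  Raises ``ValueError`` on empty
    input, unknown element symbols, or stray characters.
    """
    if not formula or not formula.strip():
        raise ValueError("empty molecular formula")
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        if not match.group(0):
            break
        symbol, digits = match.group(1), match.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {symbol!r} in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = match.end()
        if pos == len(formula):
            break
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    if not counts:
        raise ValueError("empty molecular formula")
    return counts


def _as_counts(formula: FormulaLike) -> Mapping[str, int]:
    if isinstance(formula, str):
        return parse_formula(formula)
    if not formula:
        raise ValueError("empty molecular formula")
    return formula


def monoisotopic_mass(formula: FormulaLike) -> float:
    """Neutral monoisotopic mass in Da of a formula (string or element-count map)."""
    counts = _as_counts(formula)
    total = 0.0
    for symbol, count in counts.items():
        if symbol not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {symbol!r}")
        if count < 1:
            raise ValueError(f"count for {symbol} must be >= 1, got {count}")
        total += count * MONOISOTOPIC_MASS[symbol]
    return total


def adduct_mz(formula: FormulaLike, adduct: str = "[M+H]+") -> float:
    """Theoretical m/z of a singly charged adduct of the neutral molecule.

    Supported adducts: ``[M+H]+`` (protonated) and ``[M+Na]+`` (sodiated).
    """
    if adduct not in CATION_MASS:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(CATION_MASS)}"
        )
    return monoisotopic_mass(formula) + CATION_MASS[adduct]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class MassWindow:
    """A mass window of total width ``full_width`` centred at ``center_mz``.

    Membership is ``|mz - center_mz| <= full_width / 2`` — the 0.0009-Da
    extraction window of the imaging software is a *full* width, i.e.
    ±0.00045 Da around the target.
    """

    center_mz: float
    full_width: float

    def __post_init__(self) -> None:
        if self.full_width <= 0:
            raise ValueError("full_width must be positive")

    @property
    def bounds(self) -> Tuple[float, float]:
        half = self.full_width / 2.0
        return (self.center_mz - half, self.center_mz + half)

    def contains(self, mz: float) -> bool:
        return abs(mz - self.center_mz) <= self.full_width / 2.0


@dataclass(frozen=True)
class LockMassSpec:
    """Lock-mass anchor: theoretical reference m/z plus the search window
    within which the observed anchor peak is located."""

    reference_mz: float
    search_window: MassWindow


@dataclass(frozen=True)
class RecalibrationResult:
    spectrum: Spectrum
    shift_da: float
    anchor_found: bool


def lock_mass_recalibrate(spectrum: Spectrum, lock: LockMassSpec) -> RecalibrationResult:
    """Single-point additive lock-mass correction of one spectrum.

    The most intense peak inside ``lock.search_window`` is taken as the
    observed anchor; every m/z in the spectrum is shifted by
    ``reference_mz - observed`` so the anchor lands exactly on the reference.
    If no peak falls inside the window the spectrum is returned unchanged
    with ``anchor_found=False``.  The operation is idempotent.
    """
    if len(spectrum) == 0:
        return RecalibrationResult(spectrum, 0.0, False)
    lo, hi = lock.search_window.bounds
    i = int(np.searchsorted(spectrum.mz, lo, side="left"))
    j = int(np.searchsorted(spectrum.mz, hi, side="right"))
    if i >= j:
        return RecalibrationResult(spectrum, 0.0, False)
    k = i + int(np.argmax(spectrum.intensity[i:j]))
    shift = lock.reference_mz - float(spectrum.mz[k])
    if shift == 0.0:
        return RecalibrationResult(spectrum, 0.0, True)
    mz = spectrum.mz + shift
    mz[k] = lock.reference_mz  # pin the anchor exactly; makes the op idempotent
    return RecalibrationResult(Spectrum(mz, spectrum.intensity), shift, True)
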