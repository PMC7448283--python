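"""Exact monoisotopic mass arithmetic for elemental formulas and ESI adducts.

Everything downstream (peptide masses, fragment-ion series, adduct grouping)
funnels through the constants and helpers defined here.  Masses are
monoisotopic throughout: each element contributes the mass of its most
abundant isotope.  Positive-mode electrospray species are modelled as a
neutral molecule plus ``n`` protons and/or sodium cations, so the electron
mass enters explicitly — at Orbitrap mass accuracy (~1 ppm) ignoring it is a
0.5 mDa error, which is visible on every printed m/z in this problem domain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Mapping

from pyteomics import mass as _pymass

__all__ = [
    "MassConstantSet",
    "CONSTANTS",
    "ElementalFormula",
    "parse_formula",
    "formula_mz",
    "AdductSpec",
    "NAMED_ADDUCTS",
    "adduct_mz",
    "neutral_from_adduct",
    "ppm_error",
]


class FormulaError(ValueError):
    """Raised when a formula string cannot be interpreted."""


@dataclass(frozen=True)
class MassConstantSet:
    """Monoisotopic atomic masses plus the proton and electron masses (Da).

    The proton mass is *derived* as ``m(H) - m(e)`` so the constant set is
    internally consistent by construction; ``validate`` asserts it.
    """

    atomic: Mapping[str, float]
    electron: float
    proton: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "proton", self.atomic["H"] - self.electron)

    def validate(self) -> None:
        assert abs(self.proton - (self.atomic["H"] - self.electron)) < 1e-12

    def mass_of(self, element: str) -> float:
        try:
            return self.atomic[element]
        except KeyError:
            raise FormulaError(f"unknown element symbol: {element!r}") from None


def _default_constants() -> MassConstantSet:
    atomic = {
        el: data[0][0]
        for el, data in _pymass.nist_mass.items()
        if el != "e*" and data[0][0] > 0
    }
    return MassConstantSet(atomic=atomic, electron=_pymass.nist_mass["e*"][0][0])


#: Module-level default constant set (IUPAC/CODATA values via pyteomics).
CONSTANTS: MassConstantSet = _default_constants()

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map, e.g. ``{"C": 34, "H": 32, "Fe": 1, ...}``."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts or all(c == 0 for c in self.counts.values()):
            raise FormulaError("formula must contain at least one atom")
        for el, c in self.counts.items():
            if c < 0:
                raise FormulaError(f"negative count for element {el}")
            CONSTANTS.mass_of(el)  # reject unknown symbols early

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged: Dict[str, int] = dict(self.counts)
        for el, c in other.counts.items():
            merged[el] = merged.get(el, 0) + c
        return ElementalFormula(merged)

    def scaled(self, k: int) -> "ElementalFormula":
        return ElementalFormula({el: c * k for el, c in self.counts.items()})

    def hill_string(self) -> str:
        """Formula in Hill order (C, H, then alphabetical)."""
        order = sorted(
            self.counts, key=lambda e: (e != "C", e != "H", e)
        )
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}"
            for el in order
            if self.counts[el]
        )


def parse_formula(text: str) -> ElementalFormula:
    """Parse an element-count string such as ``"C34H32FeN4O4"``.

    Element symbols are case-sensitive (``Na`` is sodium; ``NA`` is an
    error).  A trailing charge marker (``+``, ``2+``, ``^+^``) is tolerated
    and ignored; charge is handled by :func:`formula_mz`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    # strip caret-wrapped charge ("^2+^", "^+^") or a bare trailing sign;
    # a bare digit before the sign belongs to the last element count
    body = re.sub(r"\^\s*\d*[+-]\s*\^?$", "", text.strip())
    body = re.sub(r"[+-]$", "", body)
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(body):
        m = _ELEMENT_RE.match(body, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula at {body[pos:]!r}")
        el, num = m.group(1), m.group(2)
        CONSTANTS.mass_of(el)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return ElementalFormula(counts)


def formula_mz(
    f: ElementalFormula, z: int = 0, n_electrons_removed: int = 0
) -> float:
    """m/z of a formula at charge ``z`` with explicit electron bookkeeping.

    ``z = 0`` returns the neutral monoisotopic mass.  For a cation formed by
    electron loss (e.g. heme B as ``[M]+``), pass ``n_electrons_removed``.
    """
    total = sum(CONSTANTS.mass_of(el) * c for el, c in f.counts.items())
    total -= n_electrons_removed * CONSTANTS.electron
    return total / max(z, 1)


@dataclass(frozen=True)
class AdductSpec:
    """Positive-mode ESI adduct: ``[M + nH + mNa]^(n+m)+``."""

    n_protons: int
    n_sodiums: int

    def __post_init__(self) -> None:
        if self.n_protons < 0 or self.n_sodiums < 0:
            raise ValueError("adduct counts must be non-negative")
        if self.charge < 1:
            raise ValueError("adduct charge must be >= 1")

    @property
    def charge(self) -> int:
        return self.n_protons + self.n_sodiums

    @property
    def offset(self) -> float:
        """Total mass added to the neutral molecule (charge carriers)."""
        na_cation = CONSTANTS.mass_of("Na") - CONSTANTS.electron
        return self.n_protons * CONSTANTS.proton + self.n_sodiums * na_cation

    @property
    def name(self) -> str:
        parts = []
        if self.n_protons:
            parts.append("H" if self.n_protons == 1 else f"{self.n_protons}H")
        if self.n_sodiums:
            parts.append("Na" if self.n_sodiums == 1 else f"{self.n_sodiums}Na")
        z = self.charge
        return f"[M+{'+'.join(parts)}]{z if z > 1 else ''}+"


#: The five adduct species observed for britacidin A in positive mode.
NAMED_ADDUCTS: Dict[str, AdductSpec] = {
    "M+H": AdductSpec(1, 0),
    "M+2H": AdductSpec(2, 0),
    "M+H+Na": AdductSpec(1, 1),
    "M+2Na": AdductSpec(0, 2),
    "M+Na": AdductSpec(0, 1),
}


def adduct_mz(M: float, a: AdductSpec) -> float:
    """m/z of adduct ``a`` of a neutral molecule of monoisotopic mass ``M``."""
    if M <= 0:
        raise ValueError("neutral mass must be positive")
    return (M + a.offset) / a.charge


def neutral_from_adduct(mz: float, a: AdductSpec) -> float:
    """Exact algebraic inverse of :func:`adduct_mz`."""
    M = mz * a.charge - a.offset
    if M <= 0:
        raise ValueError(
            f"m/z {mz} is not a physical {a.name} ion (implied M = {M:.4f})"
        )
    return M


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6
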