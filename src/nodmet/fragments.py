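"""Backbone product-ion prediction for linear nonribosomal peptides.

Series conventions (singly charged, extended to z > 1 by adding protons):

* ``b_i``  N-terminal acylium: sum of the first i residues + N-terminal cap
  + one proton.  For a free N-terminus the cap contributes nothing beyond the
  amide hydrogen already counted in the residue/water bookkeeping.
* ``a_i = b_i - CO``.
* ``y_i``  C-terminal fragment with free acid: sum of the last i residues
  + H2O + proton.
* ``Y_i``  y-type fragment retaining the C-terminal ethanolamide cap
  (the capital-Y convention used for gramicidin-family peptides):
  y_i + C2H5N.
* ``x_i = y_i + CO`` (free-acid C-terminal x-type).

All masses route through :mod:`nodmet.masses` so the electron correction is
applied consistently: a 1+ fragment is residues + caps + H minus one
electron, i.e. "+ proton".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

from .masses import CONSTANTS, formula_mz, parse_formula
from .peptide import ETHANOLAMIDE, PeptideSpec, WATER

__all__ = ["FragmentIon", "fragment_ions", "complementarity_check", "CO_MASS"]

CO_MASS = formula_mz(parse_formula("CO"), z=0)  # 27.99491 Da

_SERIES = ("a", "b", "x", "y", "Y")


@dataclass(frozen=True)
class FragmentIon:
    series: str
    index: int          # 1-based residue count from the relevant terminus
    charge: int
    mz: float
    peptide_length: int

    @property
    def label(self) -> str:
        z = self.charge
        return f"{self.series}{self.index}" + (f"({z}+)" if z > 1 else "")


def _prefix_sums(p: PeptideSpec) -> List[float]:
    masses = p.residue_masses()
    out, acc = [], 0.0
    for m in masses:
        acc += m
        out.append(acc)
    return out


def fragment_ions(
    p: PeptideSpec,
    series: Iterable[str] = ("a", "b", "y", "Y"),
    max_charge: int = 1,
) -> List[FragmentIon]:
    """Predict product ions for a linear peptide.

    Indices run 1..len-1 (the full-length "fragment" is the precursor, not a
    product ion).  ``Y`` is only meaningful for ethanolamide-capped peptides
    and raises otherwise; ``y``/``x`` assume a free-acid C-terminus and are
    reported with the actual C-terminal cap of ``p`` included, so for an
    ethanolamide peptide ``y`` is an alias of ``Y``.
    """
    if p.cyclic:
        raise ValueError("cyclic peptides are not supported by fragment_ions")
    series = tuple(series)
    for s in series:
        if s not in _SERIES:
            raise ValueError(f"unknown series {s!r}")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")

    n = len(p)
    prefix = _prefix_sums(p)
    total = prefix[-1]
    proton = CONSTANTS.proton
    nterm = formula_mz(p.n_terminal_formula, 0) if p.n_terminal_formula else 0.0
    cterm = formula_mz(p.c_terminal_formula, 0) if p.c_terminal_formula else 0.0
    water = formula_mz(WATER, 0)
    eth = formula_mz(ETHANOLAMIDE, 0)

    if "Y" in series and p.c_terminal_mod != "ethanolamide":
        raise ValueError("Y series requires a C-terminal ethanolamide cap")

    out: List[FragmentIon] = []
    for i in range(1, n):
        b_neutral = prefix[i - 1] + nterm          # acylium minus the proton
        suffix = total - prefix[i - 1]
        y_neutral = suffix + water + cterm         # includes actual C-term cap
        for z in range(1, max_charge + 1):
            for s in series:
                if s == "b":
                    mz = (b_neutral + z * proton) / z
                elif s == "a":
                    mz = (b_neutral - CO_MASS + z * proton) / z
                elif s == "y":
                    mz = (y_neutral + z * proton) / z
                elif s == "Y":
                    mz = (suffix + water + eth + z * proton) / z
                else:  # x
                    mz = (y_neutral + CO_MASS + z * proton) / z
                idx = i if s in ("a", "b") else n - i
                out.append(FragmentIon(s, idx, z, mz, n))
    out.sort(key=lambda f: (f.series, f.index, f.charge))
    return out


def complementarity_check(
    p: PeptideSpec,
    b_ion: FragmentIon,
    y_ion: FragmentIon,
    tol_da: float = 1e-6,
) -> bool:
    """True iff a singly charged b/y pair sums to [M+H]+ + proton.

    For indices i and n-i of the same peptide the identity
    ``b_i + y_{n-i} = M + 2*proton`` holds exactly; this is the standard
    bookkeeping check for a proposed complementary pair.
    """
    if b_ion.peptide_length != len(p) or y_ion.peptide_length != len(p):
        raise ValueError("fragment ions do not belong to this peptide")
    if b_ion.series != "b" or y_ion.series not in ("y", "Y"):
        raise ValueError("expected a b ion and a y/Y ion")
    if b_ion.charge != 1 or y_ion.charge != 1:
        raise ValueError("complementarity check is defined for 1+ ions")
    if b_ion.index + y_ion.index != len(p):
        raise ValueError("indices must sum to the peptide length")
    from .peptide import peptide_neutral_mass

    target = peptide_neutral_mass(p) + 2 * CONSTANTS.proton
    return abs((b_ion.mz + y_ion.mz) - target) <= max(tol_da, 1e-9 * target)
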