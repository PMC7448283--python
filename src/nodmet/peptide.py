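"""Peptide specifications and neutral-mass arithmetic for nonribosomal peptides.

Nonribosomal peptides (NRPs) routinely carry features ribosomal peptides do
not: D-configured residues, ornithine, N-formyl caps and C-terminal
ethanolamide groups, and macrocyclisation.  The :class:`PeptideSpec` here
models exactly the scaffolds needed for the gramicidin/britacidin family
(linear, formylated, ethanolamide-capped) and the tyrocidines (head-to-tail
cyclic decapeptides):

* linear, free termini:  M = sum(residues) + H2O
* N-formyl:              + CO
* C-terminal ethanolamide (NH-CH2-CH2-OH replacing the acid OH): + C2H5N net
* cyclic:                M = sum(residues) (no terminal water, no mods)

D/L stereochemistry is mass-identical and is carried only as a label in
residue names supplied by the caller (``dPhe`` resolves to ``Phe``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence, Tuple

from .masses import ElementalFormula, FormulaError, formula_mz, parse_formula

__all__ = [
    "ResidueSpec",
    "ResidueTable",
    "RESIDUES",
    "PeptideSpec",
    "peptide_neutral_mass",
    "parse_peptide",
    "AMBIGUITY_CLASSES",
    "WATER",
    "FORMYL",
    "ETHANOLAMIDE",
]

WATER = parse_formula("H2O")
FORMYL = parse_formula("CO")          # N-formyl cap, net addition
ETHANOLAMIDE = parse_formula("C2H5N")  # -OH -> -NH-C2H4-OH, net addition

#: Residue groups this package never resolves on mass alone.  Leu/Ile are
#: exactly isobaric; Gln/Lys are kept together as a conservative class (the
#: classical low-resolution ambiguity).  Collapsing a class requires explicit
#: orthogonal evidence, e.g. a 13C feeding result.
AMBIGUITY_CLASSES: Tuple[frozenset, ...] = (
    frozenset({"Leu", "Ile"}),
    frozenset({"Gln", "Lys"}),
)


@dataclass(frozen=True)
class ResidueSpec:
    name: str
    one_letter: str
    formula: ElementalFormula

    @property
    def mass(self) -> float:
        """Monoisotopic residue (-H2O) mass, always derived from the formula."""
        return formula_mz(self.formula, z=0)


class ResidueTable:
    """Residue lookup by three-letter name, tolerant of D-prefixes."""

    def __init__(self, residues: Sequence[ResidueSpec]):
        self._by_name: Dict[str, ResidueSpec] = {r.name: r for r in residues}

    def __iter__(self):
        return iter(self._by_name.values())

    def __contains__(self, name: str) -> bool:
        try:
            self[name]
            return True
        except KeyError:
            return False

    def __getitem__(self, name: str) -> ResidueSpec:
        key = name.strip()
        for candidate in (key, key.capitalize()):
            if candidate in self._by_name:
                return self._by_name[candidate]
        # D-residue labels: dPhe / D-Phe / dphe are mass-identical to Phe
        stripped = key[1:].lstrip("-") if key[:1] in ("d", "D") else None
        if stripped:
            for candidate in (stripped, stripped.capitalize()):
                if candidate in self._by_name:
                    return self._by_name[candidate]
        raise KeyError(f"unknown residue: {name!r}")

    def names(self) -> List[str]:
        return list(self._by_name)


def _load_builtin_table() -> ResidueTable:
    text = (
        resources.files("nodmet.data").joinpath("residues.tsv").read_text()
    )
    residues = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, one, formula = line.split("\t")
        residues.append(ResidueSpec(name, one, parse_formula(formula)))
    return ResidueTable(residues)


#: Built-in table: 20 proteinogenic residues + ornithine.
RESIDUES: ResidueTable = _load_builtin_table()


@dataclass(frozen=True)
class PeptideSpec:
    """A linear or cyclic peptide with optional terminal caps.

    ``n_terminal_mod`` is one of ``{"free", "formyl"}``;
    ``c_terminal_mod`` one of ``{"free-acid", "ethanolamide"}``.
    Cyclic peptides must have free (absent) termini.
    """

    residues: Tuple[str, ...]
    n_terminal_mod: str = "free"
    c_terminal_mod: str = "free-acid"
    cyclic: bool = False

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide needs at least one residue")
        if self.n_terminal_mod not in ("free", "formyl"):
            raise ValueError(f"unknown N-terminal mod {self.n_terminal_mod!r}")
        if self.c_terminal_mod not in ("free-acid", "ethanolamide"):
            raise ValueError(f"unknown C-terminal mod {self.c_terminal_mod!r}")
        if self.cyclic and (
            self.n_terminal_mod != "free" or self.c_terminal_mod != "free-acid"
        ):
            raise ValueError("cyclic peptides cannot carry terminal mods")
        for r in self.residues:
            RESIDUES[r]  # raises KeyError on unknown residue

    def __len__(self) -> int:
        return len(self.residues)

    def residue_masses(self) -> List[float]:
        return [RESIDUES[r].mass for r in self.residues]

    @property
    def n_terminal_formula(self) -> ElementalFormula | None:
        return FORMYL if self.n_terminal_mod == "formyl" else None

    @property
    def c_terminal_formula(self) -> ElementalFormula | None:
        return ETHANOLAMIDE if self.c_terminal_mod == "ethanolamide" else None

    def formula(self) -> ElementalFormula:
        """Elemental formula of the neutral molecule."""
        total = RESIDUES[self.residues[0]].formula
        for r in self.residues[1:]:
            total = total + RESIDUES[r].formula
        if not self.cyclic:
            total = total + WATER
            if self.n_terminal_formula:
                total = total + self.n_terminal_formula
            if self.c_terminal_formula:
                total = total + self.c_terminal_formula
        return total


def peptide_neutral_mass(p: PeptideSpec) -> float:
    """Monoisotopic neutral mass of a peptide spec (Da)."""
    return formula_mz(p.formula(), z=0)


def parse_peptide(text: str) -> PeptideSpec:
    """Parse a compact peptide string.

    Grammar::

        cyclo[Val,Orn,Leu,dPhe,Pro,Phe,dPhe,Asn,Gln,Tyr]   cyclic peptide
        f-Ile,Gly,...,Trp-Ea                               formyl / ethanolamide
        Ile,Gly,Ala                                        free termini

    ``f-`` marks an N-formyl cap and ``-Ea`` a C-terminal ethanolamide.
    """
    text = text.strip()
    if not text:
        raise FormulaError("empty peptide string")
    if text.lower().startswith("cyclo[") and text.endswith("]"):
        inner = text[text.index("[") + 1 : -1]
        residues = tuple(r.strip() for r in inner.split(",") if r.strip())
        return PeptideSpec(residues, cyclic=True)
    nmod, cmod = "free", "free-acid"
    if text.startswith(("f-", "F-")) and text[2:3].isupper():
        nmod, text = "formyl", text[2:]
    if text.endswith(("-Ea", "-EA", "-ea")):
        cmod, text = "ethanolamide", text[:-3]
    residues = tuple(r.strip() for r in text.split(",") if r.strip())
    return PeptideSpec(residues, n_terminal_mod=nmod, c_terminal_mod=cmod)


#: Britacidin A: the gramicidin-A scaffold with Ile at position 1, inserted
#: Ala/Val at positions 7/8, and Tyr replacing Trp at position 11.
BRITACIDIN_A = PeptideSpec(
    (
        "Ile", "Gly", "Ala", "Leu", "Ala", "Val", "Ala", "Val", "Val",
        "Val", "Tyr", "Leu", "Trp", "Leu", "Trp", "Leu", "Trp",
    ),
    n_terminal_mod="formyl",
    c_terminal_mod="ethanolamide",
)

#: Gramicidin A (Val1 variant), for fragment cross-checks.
GRAMICIDIN_A = PeptideSpec(
    (
        "Val", "Gly", "Ala", "Leu", "Ala", "Val", "Val", "Val", "Trp",
        "Leu", "Trp", "Leu", "Trp", "Leu", "Trp",
    ),
    n_terminal_mod="formyl",
    c_terminal_mod="ethanolamide",
)

#: Tyrocidine A: head-to-tail cyclic decapeptide from B. brevis.
TYROCIDINE_A = PeptideSpec(
    (
        "Val", "Orn", "Leu", "dPhe", "Pro", "Phe", "dPhe", "Asn", "Gln",
        "Tyr",
    ),
    cyclic=True,
)
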