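"""De novo sequence reading by mass-ladder walking.

The sequencer formalises the manual procedure used for gramicidin-family
peptides at low collision energy: successive members of one product-ion
series (b or y) differ by exactly one residue mass, so walking the peak list
and matching consecutive differences against a residue table reads the
sequence out, one residue per step.

Rules of the walk:

* A step is accepted when a peak-to-peak mass difference matches a residue
  mass within tolerance (ppm with an absolute floor for low-mass fragments).
* Mass-degenerate residues are reported as ambiguity classes ({Leu, Ile},
  and conservatively {Gln, Lys}); a class is collapsed only when the caller
  supplies orthogonal evidence — globally (``resolve={"Ile/Leu": "Ile"}``)
  or scoped to positions (``resolve={"Ile/Leu": {1: "Ile"}}``), mirroring
  how a 13C feeding experiment settles position 1 of britacidin A without
  touching the Leu positions downstream.
* When no single-residue step is possible, a two-residue jump is attempted
  and reported as an unresolved gap rather than silently guessed.
* The search is depth-first with deterministic ordering (lowest |ppm| first,
  then alphabetical) and a hard cap on explored branches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

from .masses import CONSTANTS, formula_mz, ppm_error
from .peptide import (
    AMBIGUITY_CLASSES,
    ETHANOLAMIDE,
    FORMYL,
    RESIDUES,
    ResidueTable,
    WATER,
)

__all__ = ["Gap", "SequenceHypothesis", "ladder_sequence"]


@dataclass(frozen=True)
class Gap:
    """An unresolved multi-residue jump in a ladder."""

    mass: float
    span: int = 2
    candidates: Tuple[Tuple[str, ...], ...] = ()

    def __str__(self) -> str:
        return f"gap({self.span}: {self.mass:.4f} Da)"


Position = Union[frozenset, Gap]


@dataclass
class SequenceHypothesis:
    """An ordered residue reading with its per-step mass-error trace."""

    positions: List[Position]
    ppm_trace: List[float]
    complete: bool  # True if the walk closed out against the precursor

    @property
    def score(self) -> float:
        """Cumulative |ppm| across accepted steps (lower is better)."""
        return float(sum(abs(p) for p in self.ppm_trace))

    @property
    def n_residues(self) -> int:
        return sum(p.span if isinstance(p, Gap) else 1 for p in self.positions)

    def as_strings(self) -> List[str]:
        out = []
        for p in self.positions:
            if isinstance(p, Gap):
                out.append(str(p))
            else:
                out.append("/".join(sorted(p)))
        return out


def _class_of(name: str, resolve: Dict[frozenset, object]) -> frozenset:
    for cls in AMBIGUITY_CLASSES:
        if name in cls:
            chosen = resolve.get(cls)
            if isinstance(chosen, str):  # global resolution
                return frozenset({chosen})
            return cls
    return frozenset({name})


def _normalise_resolve(
    resolve: Optional[Dict[str, object]]
) -> Dict[frozenset, object]:
    """Validate evidence flags.

    Values are either a residue name (collapse the class everywhere) or a
    {position: residue} mapping (collapse only at those 1-based positions,
    counted N->C in the returned hypotheses).
    """
    out: Dict[frozenset, object] = {}
    for key, val in (resolve or {}).items():
        cls = frozenset(part.strip() for part in key.split("/"))
        matches = [c for c in AMBIGUITY_CLASSES if cls == c]
        if not matches:
            raise ValueError(f"unknown ambiguity class {key!r}")
        members = val.values() if isinstance(val, dict) else [val]
        for name in members:
            if name not in matches[0]:
                raise ValueError(f"{name!r} is not a member of class {key!r}")
        out[matches[0]] = val
    return out


def _apply_positional_resolution(
    positions: List[Position], resolve: Dict[frozenset, object]
) -> List[Position]:
    """Collapse position-scoped ambiguity classes (N->C, 1-based)."""
    scoped = {c: v for c, v in resolve.items() if isinstance(v, dict)}
    if not scoped:
        return positions
    out: List[Position] = []
    pos = 1
    for item in positions:
        if isinstance(item, Gap):
            out.append(item)
            pos += item.span
            continue
        if item in scoped and pos in scoped[item]:
            out.append(frozenset({scoped[item][pos]}))
        else:
            out.append(item)
        pos += 1
    return out


def ladder_sequence(
    spectrum,
    direction: str = "b",
    residue_table: ResidueTable = RESIDUES,
    tol_ppm: float = 10.0,
    tol_da_floor: float = 0.002,
    n_terminal_mod: str = "free",
    c_terminal_mod: str = "free-acid",
    resolve: Optional[Dict[str, str]] = None,
    max_branches: int = 50,
    allow_gaps: bool = True,
) -> List[SequenceHypothesis]:
    """Read sequence hypotheses from a singly-charged product-ion ladder.

    ``direction="b"`` walks the b series N->C (the first accepted peak is
    interpreted as b1, so the N-terminal cap must be declared);
    ``direction="y"`` walks the y series C->N and returns positions in
    N->C order.  If ``spectrum.precursor_mz`` is set (assumed [M+H]+), the
    walk attempts to close out the final residue against it and marks such
    hypotheses ``complete``.

    Returns hypotheses sorted by (longest, lowest cumulative |ppm|); an
    empty list means no admissible first step.
    """
    if tol_ppm <= 0 or tol_da_floor < 0:
        raise ValueError("tolerances must be positive")
    if direction not in ("b", "y"):
        raise ValueError("direction must be 'b' or 'y'")
    resolve_map = _normalise_resolve(resolve)
    proton = CONSTANTS.proton
    water = formula_mz(WATER, 0)
    nterm = formula_mz(FORMYL, 0) if n_terminal_mod == "formyl" else 0.0
    cterm = (
        formula_mz(ETHANOLAMIDE, 0)
        if c_terminal_mod == "ethanolamide"
        else 0.0
    )

    residues = sorted(residue_table, key=lambda r: r.name)
    mzs = [m for m, _ in spectrum.peaks]

    def tol(at_mz: float) -> float:
        return max(tol_ppm * at_mz * 1e-6, tol_da_floor)

    # mass of the series-1 ion for a given first residue mass
    if direction == "b":
        def first_ion(rm: float) -> float:
            return rm + nterm + proton
        def closing_delta(rm: float) -> float:
            # precursor [M+H]+ minus the last ladder ion
            return rm + water + cterm
    else:
        def first_ion(rm: float) -> float:
            return rm + water + cterm + proton
        def closing_delta(rm: float) -> float:
            return rm + nterm

    # ---- anchors: peaks that look like a series-1 ion --------------------
    anchors: List[Tuple[float, frozenset, float]] = []  # (mz, class, ppm)
    for mz in mzs:
        for r in residues:
            theo = first_ion(r.mass)
            if abs(mz - theo) <= tol(theo):
                anchors.append((mz, _class_of(r.name, resolve_map),
                                ppm_error(mz, theo)))
    # merge identical (mz, class) anchors produced by class members
    seen = {}
    for mz, cls, ppm in anchors:
        key = (mz, cls)
        if key not in seen or abs(ppm) < abs(seen[key]):
            seen[key] = ppm
    anchors = [(mz, cls, ppm) for (mz, cls), ppm in seen.items()]
    anchors.sort(key=lambda a: (abs(a[2]), sorted(a[1])))

    budget = {"branches": max_branches}
    results: List[SequenceHypothesis] = []

    def steps_from(cur_mz: float):
        """Single-residue continuations: (next_mz, class, ppm)."""
        found: Dict[Tuple[float, frozenset], float] = {}
        for nxt in mzs:
            delta = nxt - cur_mz
            if delta <= 0:
                continue
            for r in residues:
                if abs(delta - r.mass) <= tol(nxt):
                    cls = _class_of(r.name, resolve_map)
                    ppm = ppm_error(nxt, cur_mz + r.mass)
                    key = (nxt, cls)
                    if key not in found or abs(ppm) < abs(found[key]):
                        found[key] = ppm
        out = [(mz2, cls, ppm) for (mz2, cls), ppm in found.items()]
        out.sort(key=lambda s: (abs(s[2]), sorted(s[1])))
        return out

    def gap_steps_from(cur_mz: float):
        """Two-residue jumps reported as unresolved gaps."""
        found: Dict[float, Gap] = {}
        for nxt in mzs:
            delta = nxt - cur_mz
            if delta <= 0:
                continue
            pairs = []
            for r1, r2 in itertools.combinations_with_replacement(
                residues, 2
            ):
                if abs(delta - (r1.mass + r2.mass)) <= tol(nxt):
                    pairs.append(tuple(sorted((r1.name, r2.name))))
            if pairs:
                found[nxt] = Gap(mass=delta, span=2,
                                 candidates=tuple(sorted(set(pairs))))
        return sorted(found.items())

    def try_close(cur_mz: float, positions, trace):
        """Attempt the final residue against the precursor [M+H]+."""
        if spectrum.precursor_mz is None:
            return None
        delta = spectrum.precursor_mz - cur_mz
        best = None
        for r in residues:
            theo = closing_delta(r.mass)
            if abs(delta - theo) <= tol(spectrum.precursor_mz):
                ppm = ppm_error(cur_mz + theo, spectrum.precursor_mz)
                cls = _class_of(r.name, resolve_map)
                if best is None or abs(ppm) < abs(best[1]):
                    best = (cls, ppm)
        if best is None:
            return None
        return SequenceHypothesis(
            positions + [best[0]], trace + [best[1]], complete=True
        )

    def walk(cur_mz: float, positions, trace):
        if budget["branches"] <= 0:
            results.append(SequenceHypothesis(positions, trace, False))
            return
        closed = try_close(cur_mz, positions, trace)
        nexts = steps_from(cur_mz)
        if not nexts and allow_gaps and closed is None:
            gaps = gap_steps_from(cur_mz)
            if gaps:
                nxt, gap = gaps[0]
                budget["branches"] -= 1
                walk(nxt, positions + [gap], trace + [0.0])
                return
        if closed is not None:
            results.append(closed)
            if not nexts:
                return
        if not nexts:
            if closed is None:
                results.append(SequenceHypothesis(positions, trace, False))
            return
        for nxt, cls, ppm in nexts:
            if budget["branches"] <= 0:
                break
            budget["branches"] -= 1
            walk(nxt, positions + [cls], trace + [ppm])

    for mz, cls, ppm in anchors:
        if budget["branches"] <= 0:
            break
        budget["branches"] -= 1
        walk(mz, [cls], [ppm])

    if direction == "y":
        for h in results:
            h.positions = h.positions[::-1]
            h.ppm_trace = h.ppm_trace[::-1]
    for h in results:
        h.positions = _apply_positional_resolution(h.positions, resolve_map)
    results.sort(key=lambda h: (-h.n_residues, h.score))

    # drop strict prefixes of better hypotheses (sub-walks of the same path)
    pruned: List[SequenceHypothesis] = []
    for h in results:
        if any(
            g.n_residues >= h.n_residues
            and g.positions[: len(h.positions)] == h.positions
            for g in pruned
        ):
            continue
        pruned.append(h)
    return pruned
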