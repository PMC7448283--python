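"""Spectrum containers, peak-list IO, isotope-spacing charge determination,
and grouping of MS1 ions into neutral-mass hypotheses.

The adduct-grouping step formalises the reasoning used to recognise that a
set of co-eluting MS1 features ([M+2H]2+, [M+H+Na]2+, [M+2Na]2+, [M+H]+,
[M+Na]+) are different adducts of one neutral molecule: each (ion, adduct)
assignment implies a neutral mass; implied masses that agree within a ppm
tolerance are clustered, and clusters with at least two supporting ions
become :class:`NeutralMassHypothesis` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .masses import AdductSpec, NAMED_ADDUCTS, neutral_from_adduct, ppm_error

__all__ = [
    "SpectrumRecord",
    "read_peak_table",
    "read_mzml",
    "charge_from_isotopes",
    "NeutralMassHypothesis",
    "group_adducts",
]

#: Average mass difference between successive isotopologue peaks (Da),
#: dominated by the 13C-12C spacing.
ISOTOPE_SPACING = 1.00335


@dataclass
class SpectrumRecord:
    """A peak list with optional precursor metadata.

    Peaks are kept sorted ascending by m/z; intensities must be >= 0.
    ``collision_energy`` is free-text metadata (e.g. ``"NCE 15"``).
    """

    peaks: List[Tuple[float, float]]
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    collision_energy: Optional[str] = None

    def __post_init__(self) -> None:
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be non-negative")

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def read_peak_table(path: str | Path, **meta) -> SpectrumRecord:
    """Read a two-column (m/z, intensity) delimited text peak list.

    Accepts whitespace-, comma- or tab-delimited rows; lines starting with
    ``#`` are comments.  Extra keyword arguments become spectrum metadata.
    """
    peaks = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").replace("\t", " ").split()
        peaks.append((float(parts[0]), float(parts[1])))
    return SpectrumRecord(peaks, **meta)


def read_mzml(path: str | Path, scan_index: int = 0, **meta) -> SpectrumRecord:
    """Read one scan from an mzML file (scans addressed by 0-based index)."""
    from pyteomics import mzml as _mzml

    with _mzml.MzML(str(path)) as reader:
        for i, scan in enumerate(reader):
            if i == scan_index:
                peaks = list(
                    zip(scan["m/z array"].tolist(),
                        scan["intensity array"].tolist())
                )
                return SpectrumRecord(peaks, **meta)
    raise IndexError(f"scan index {scan_index} not found in {path}")


def charge_from_isotopes(
    envelope_mz: Sequence[float], tol: float = 0.01
) -> Tuple[int, float]:
    """Infer charge state from the spacing of an isotope envelope.

    Returns ``(z, residual)`` where ``z = round(1.00335 / median spacing)``
    and ``residual`` is the absolute difference between the median spacing
    and the ideal spacing at that charge.  Raises if fewer than two peaks are
    given, or if the residual exceeds ``tol`` (ambiguous envelope).
    """
    mzs = sorted(envelope_mz)
    if len(mzs) < 2:
        raise ValueError("need at least two isotope peaks")
    spacings = [b - a for a, b in zip(mzs, mzs[1:])]
    med = median(spacings)
    if med <= 0:
        raise ValueError("non-increasing envelope")
    z = max(1, round(ISOTOPE_SPACING / med))
    residual = abs(med - ISOTOPE_SPACING / z)
    if residual > tol:
        raise ValueError(
            f"ambiguous charge: median spacing {med:.4f} is {residual:.4f} Da "
            f"from the nearest charge hypothesis z={z}"
        )
    return z, residual


@dataclass
class NeutralMassHypothesis:
    """A neutral mass supported by >= 2 adduct-consistent MS1 ions."""

    neutral_mass: float
    supporters: List[Tuple[float, AdductSpec, float]]  # (obs m/z, adduct, ppm)
    score: float = field(init=False)  # mean |ppm| across supporters

    def __post_init__(self) -> None:
        if len(self.supporters) < 2:
            raise ValueError("a hypothesis needs at least two supporting ions")
        self.score = float(np.mean([abs(p) for *_, p in self.supporters]))


def group_adducts(
    ions: Sequence[Tuple[float, int]],
    adducts: Optional[Dict[str, AdductSpec]] = None,
    tol_ppm: float = 5.0,
) -> List[NeutralMassHypothesis]:
    """Group (m/z, charge) ions into neutral-mass hypotheses.

    Every (ion, adduct) pair whose charges agree yields an implied neutral
    mass; implied masses are single-linkage clustered at ``tol_ppm``.
    Clusters supported by >= 2 distinct ions are emitted, best (lowest mean
    |ppm|) first, and each ion may support only the best hypothesis that
    claims it.
    """
    if not ions:
        raise ValueError("empty ion list")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    adducts = adducts or NAMED_ADDUCTS

    # all candidate (ion index, adduct, implied M)
    candidates: List[Tuple[int, AdductSpec, float]] = []
    for idx, (mz, z) in enumerate(ions):
        for a in adducts.values():
            if a.charge != z:
                continue
            try:
                M = neutral_from_adduct(mz, a)
            except ValueError:
                continue
            candidates.append((idx, a, M))
    if not candidates:
        return []

    # single-linkage clustering of implied masses at tol_ppm
    candidates.sort(key=lambda c: c[2])
    clusters: List[List[Tuple[int, AdductSpec, float]]] = [[candidates[0]]]
    for cand in candidates[1:]:
        prev_M = clusters[-1][-1][2]
        if (cand[2] - prev_M) / prev_M * 1e6 <= tol_ppm:
            clusters[-1].append(cand)
        else:
            clusters.append([cand])

    def _build(members: List[Tuple[int, AdductSpec, float]]):
        """Reduce to one adduct assignment per ion; None if < 2 ions."""
        by_ion: Dict[int, Tuple[int, AdductSpec, float]] = {}
        M_est = float(np.mean([m for *_, m in members]))
        for idx, a, M in members:
            err = ppm_error(M, M_est)
            if idx not in by_ion or abs(err) < abs(by_ion[idx][2]):
                by_ion[idx] = (idx, a, err)
        if len(by_ion) < 2:
            return None
        chosen = list(by_ion.values())
        M_final = float(
            np.mean([neutral_from_adduct(ions[i][0], a) for i, a, _ in chosen])
        )
        supporters = [
            (ions[i][0], a,
             ppm_error(neutral_from_adduct(ions[i][0], a), M_final))
            for i, a, _ in chosen
        ]
        hyp = NeutralMassHypothesis(M_final, supporters)
        return hyp, [i for i, *_ in chosen]

    raw = [h for h in (_build(c) for c in clusters) if h is not None]

    # Each ion supports at most one emitted hypothesis.  Claim order prefers
    # hypotheses explaining MORE ions, then lower mean |ppm|: proton/sodium
    # adduct spacings are constant, so a mass-shifted "shadow" hypothesis can
    # explain a subset of the ions with spuriously good internal consistency —
    # supporter count separates the true neutral mass from these shadows.
    # When a shadow explains the same ions exactly (a uniform H<->Na swap
    # across every ion), mass alone cannot discriminate; the conventional
    # protonated-species-first prior breaks the tie (more protons preferred).
    def _claim_key(pair):
        hyp, _ = pair
        protons = sum(a.n_protons for _, a, _ in hyp.supporters)
        return (-len(hyp.supporters), round(hyp.score, 3), -protons,
                hyp.neutral_mass)

    raw.sort(key=_claim_key)
    claimed: set = set()
    out: List[NeutralMassHypothesis] = []
    for hyp, idxs in raw:
        kept = [
            (sup, i) for sup, i in zip(hyp.supporters, idxs)
            if i not in claimed
        ]
        if len(kept) < 2:
            continue
        claimed.update(i for _, i in kept)
        if len(kept) == len(idxs):
            out.append(hyp)
        else:
            rebuilt = _build(
                [(i, a, neutral_from_adduct(mz, a)) for (mz, a, _), i in kept]
            )
            if rebuilt is not None:
                out.append(rebuilt[0])
    out.sort(key=lambda h: (-len(h.supporters), h.score))
    return out
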