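"""Adenylation-domain specificity-code comparison for NRPS clusters.

Within an NRPS adenylation (A) domain, the ten binding-pocket residues — the
Stachelhaus code — largely determine which amino acid the domain activates.
This module compares such codes between clusters and predicts substrates by
nearest-neighbour lookup in a reference code table.  It consumes code
strings produced elsewhere (figure transcription or external annotation);
it never parses genomes or detects domains.

Domain architectures of related clusters are matched by global alignment of
their ordered module lists, scoring each pairing by code identity with a
linear gap penalty, so extra modules in one cluster (e.g. two additional
A domains inserting Ala/Val into a gramicidin-like scaffold) surface as
reported insertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "StachelhausCode",
    "ReferenceCodeTable",
    "code_identity",
    "predict_substrate",
    "DomainAlignment",
    "map_domains",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _check_code(code: str) -> str:
    if len(code) != 10:
        raise ValueError(f"Stachelhaus code must be 10 symbols, got {code!r}")
    bad = set(code.upper()) - _AA - {"-"}
    if bad:
        raise ValueError(f"invalid symbols in code {code!r}: {sorted(bad)}")
    return code.upper()


@dataclass(frozen=True)
class StachelhausCode:
    """One A domain's 10-residue binding-pocket signature."""

    domain_id: str
    cluster_id: str
    module_index: int  # 1-based chemical residue position
    code: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", _check_code(self.code))
        if self.module_index < 1:
            raise ValueError("module_index is 1-based and must be >= 1")


def code_identity(a: str, b: str) -> float:
    """Fraction of matching positions; ``'-'`` (unknown) never matches."""
    a, b = _check_code(a), _check_code(b)
    return sum(
        1 for x, y in zip(a, b) if x == y and x != "-"
    ) / 10.0


@dataclass
class ReferenceCodeTable:
    """Code -> substrate lookup entries, e.g. from characterised domains."""

    entries: List[Tuple[str, str]]  # (code, substrate residue name)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference code table is empty")
        self.entries = [(_check_code(c), s) for c, s in self.entries]


def predict_substrate(
    code: str,
    table: ReferenceCodeTable,
    min_identity: float = 0.8,
) -> Tuple[Optional[List[str]], float]:
    """Nearest-neighbour substrate prediction.

    Returns ``(substrates, identity)`` where ``substrates`` lists every
    substrate tied at the best identity, or ``(None, best)`` (a no-call)
    when the best identity falls below ``min_identity``.
    """
    best = -1.0
    hits: List[str] = []
    for ref_code, substrate in table.entries:
        ident = code_identity(code, ref_code)
        if ident > best + 1e-12:
            best, hits = ident, [substrate]
        elif abs(ident - best) <= 1e-12 and substrate not in hits:
            hits.append(substrate)
    if best < min_identity:
        return None, best
    return sorted(set(hits)), best


@dataclass
class DomainAlignment:
    """Global alignment of two ordered module lists.

    ``pairs`` holds (query module index, reference module index) with
    ``None`` marking a gap; both indices are the 1-based module indices of
    the input codes.  ``insertions`` lists query positions aligned against
    no reference module ("additional domains").
    """

    pairs: List[Tuple[Optional[int], Optional[int]]]
    score: float
    insertions: List[int]
    deletions: List[int]


def map_domains(
    query: Sequence[StachelhausCode],
    reference: Sequence[StachelhausCode],
    gap_penalty: float = 0.4,
) -> DomainAlignment:
    """Needleman-Wunsch alignment of module code lists.

    Match score is :func:`code_identity`; each gapped module costs
    ``gap_penalty`` identity units (linear).  When optima tie — e.g. an
    inserted module duplicates its neighbour, so the gap can sit on either
    copy — query gaps are placed as late (highest module index) as
    possible, matching the convention of numbering inserted chemistry at
    the downstream positions; remaining ties prefer diagonal moves.
    """
    if not query or not reference:
        raise ValueError("clusters must contain at least one module")
    q = sorted(query, key=lambda c: c.module_index)
    r = sorted(reference, key=lambda c: c.module_index)
    nq, nr = len(q), len(r)

    # score in integer tenths of an identity unit so ties are exact
    gap10 = round(gap_penalty * 10)

    def match10(a: StachelhausCode, b: StachelhausCode) -> int:
        return round(code_identity(a.code, b.code) * 10)

    score = np.zeros((nq + 1, nr + 1), dtype=np.int64)
    move = np.zeros((nq + 1, nr + 1), dtype=int)  # 0 diag, 1 up (q gap), 2 left
    for i in range(1, nq + 1):
        score[i, 0] = -gap10 * i
        move[i, 0] = 1
    for j in range(1, nr + 1):
        score[0, j] = -gap10 * j
        move[0, j] = 2
    for i in range(1, nq + 1):
        for j in range(1, nr + 1):
            diag = score[i - 1, j - 1] + match10(q[i - 1], r[j - 1])
            up = score[i - 1, j] - gap10      # query module unmatched
            left = score[i, j - 1] - gap10    # reference module unmatched
            best = max(diag, up, left)
            score[i, j] = best
            # tie order up > diag > left: traceback runs from the high end,
            # so preferring "up" there pushes query gaps rightward
            if best == up:
                move[i, j] = 1
            elif best == diag:
                move[i, j] = 0
            else:
                move[i, j] = 2

    pairs: List[Tuple[Optional[int], Optional[int]]] = []
    i, j = nq, nr
    while i > 0 or j > 0:
        m = move[i, j]
        if i > 0 and j > 0 and m == 0:
            pairs.append((q[i - 1].module_index, r[j - 1].module_index))
            i, j = i - 1, j - 1
        elif i > 0 and (j == 0 or m == 1):
            pairs.append((q[i - 1].module_index, None))
            i -= 1
        else:
            pairs.append((None, r[j - 1].module_index))
            j -= 1
    pairs.reverse()
    insertions = [qi for qi, rj in pairs if rj is None and qi is not None]
    deletions = [rj for qi, rj in pairs if qi is None and rj is not None]
    return DomainAlignment(
        pairs, float(score[nq, nr]) / 10.0, insertions, deletions
    )


def read_code_table(
    path,
) -> Tuple[Dict[str, List[StachelhausCode]], Dict[Tuple[str, int], str]]:
    """Read a delimited code table into per-cluster module lists.

    Columns: cluster_id, gene, module_index, code[, known_substrate];
    ``#`` lines are comments.  Returns ``(clusters, substrates)`` where
    ``substrates`` maps (cluster_id, module_index) to the annotated
    substrate for rows that carry one.
    """
    clusters: Dict[str, List[StachelhausCode]] = {}
    substrates: Dict[Tuple[str, int], str] = {}
    from pathlib import Path

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        cluster, gene, idx, code = parts[0], parts[1], int(parts[2]), parts[3]
        clusters.setdefault(cluster, []).append(
            StachelhausCode(f"{gene}_m{idx}", cluster, idx, code)
        )
        if len(parts) > 4 and parts[4]:
            substrates[(cluster, idx)] = parts[4]
    for modules in clusters.values():
        modules.sort(key=lambda c: c.module_index)
    return clusters, substrates


def reference_from_cluster(path, cluster_id: str) -> ReferenceCodeTable:
    """Build a reference table from the annotated rows of one cluster."""
    clusters, substrates = read_code_table(path)
    entries = [
        (c.code, substrates[(cluster_id, c.module_index)])
        for c in clusters[cluster_id]
        if (cluster_id, c.module_index) in substrates
    ]
    return ReferenceCodeTable(entries)


def synthetic_codes_path():
    """Path of the bundled SYNTHETIC code fixture (see file header)."""
    from importlib import resources

    return resources.files("nodmet.data").joinpath(
        "synthetic_stachelhaus_codes.tsv"
    )
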