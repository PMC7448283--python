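"""Seeded synthetic-data generators for every pipeline stage.

Three generators emulate the statistical structure of the study's inputs so
the whole pipeline runs end-to-end with no external data:

* :func:`gen_feature_tables` — multi-treatment LC-MS feature tables with
  planted microbe-specific features (the nested-Venn design), sub-tolerance
  m/z / RT jitter, optional per-replicate dropout, and a ground-truth
  manifest of every stage's expected membership;
* :func:`gen_ms2_spectrum` — noisy product-ion ladders from a known peptide
  (peak dropout, jitter, off-ladder decoys);
* :func:`gen_nodule_table` — Bernoulli colonization with log-normal CFU
  counts per (treatment, strain).

All randomness flows from one integer seed expanded into independent child
streams by stable hashing of stream names, so adding a new generator never
perturbs existing outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .fragments import fragment_ions
from .masses import adduct_mz, NAMED_ADDUCTS
from .peptide import PeptideSpec, peptide_neutral_mass
from .spectra import SpectrumRecord
from .venn import FeatureTable, TreatmentDesign

__all__ = [
    "child_seed",
    "VennDesignSpec",
    "gen_feature_tables",
    "gen_ms2_spectrum",
    "ColonizationSpec",
    "gen_nodule_table",
    "study_venn_design",
    "study_colonization_spec",
]


def child_seed(base_seed: int, stream: str) -> int:
    """Derive a stable sub-2^31 child seed from a base seed and stream name."""
    digest = hashlib.sha256(f"{base_seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# Venn feature tables
# ---------------------------------------------------------------------------

@dataclass
class VennDesignSpec:
    """Planted ground truth for the nested-Venn pipeline.

    ``unique_counts`` gives each microbe's intended stage-2 count;
    ``shared_counts`` plants features into two microbes' treatment triples
    (they survive stage 1 for both and cancel at stage 2);
    ``baseline_count`` features belong to the plant/medium background and
    appear in every treatment; ``leakage`` maps a microbe to
    {exclusion-community label: k}, planting that microbe's first k unique
    features into the community's samples (they are removed at stage 3).
    Jitters must stay below the downstream matching tolerances.
    """

    microbes: List[str]
    unique_counts: Dict[str, int]
    shared_counts: Dict[Tuple[str, str], int] = field(default_factory=dict)
    baseline_count: int = 25
    leakage: Dict[str, Dict[str, int]] = field(default_factory=dict)
    exclusion_members: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    baseline_label: str = "Sm_only"
    baseline_overrides: Dict[str, str] = field(default_factory=dict)
    extra_control_labels: List[str] = field(default_factory=list)
    mz_range: Tuple[float, float] = (200.0, 2000.0)
    rt_range: Tuple[float, float] = (0.5, 14.0)
    mz_jitter_ppm: float = 5.0
    rt_jitter_min: float = 0.05
    dropout: float = 0.0
    replicates: int = 4
    mz_tol_ppm: float = 10.0
    rt_tol_min: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.microbes:
            self.unique_counts.setdefault(m, 0)
        if any(c < 0 for c in self.unique_counts.values()):
            raise ValueError("unique-feature counts must be non-negative")
        if self.mz_jitter_ppm >= self.mz_tol_ppm:
            raise ValueError(
                "m/z jitter must stay below the matching tolerance "
                f"({self.mz_jitter_ppm} >= {self.mz_tol_ppm} ppm)"
            )
        if self.rt_jitter_min >= self.rt_tol_min:
            raise ValueError("RT jitter must stay below the RT tolerance")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout probability must be in [0, 1)")

    def treatment_design(self) -> TreatmentDesign:
        triples = {
            m: {
                "in_vitro": f"iv_{m}",
                "single": self.baseline_label
                if self.baseline_overrides.get(m)
                else f"single_{m}",
                "full": "full_community",
            }
            for m in self.microbes
        }
        return TreatmentDesign(
            microbes=list(self.microbes),
            triples=triples,
            baseline=self.baseline_label,
            exclusion_communities=dict(self.exclusion_members),
            baseline_overrides=dict(self.baseline_overrides),
        )


def _draw_separated(
    rng: np.random.Generator,
    n: int,
    spec: VennDesignSpec,
    existing: List[Tuple[float, float]],
) -> List[Tuple[float, float]]:
    """Draw n (m/z, RT) pairs kept well clear of all previous features."""
    out = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("cannot place features with safe separation")
        mz = rng.uniform(*spec.mz_range)
        rt = rng.uniform(*spec.rt_range)
        safe = all(
            abs(mz - m0) / m0 * 1e6 > 4 * spec.mz_tol_ppm
            or abs(rt - r0) > 4 * spec.rt_tol_min
            for m0, r0 in existing + out
        )
        if safe:
            out.append((mz, rt))
    return out


def gen_feature_tables(
    spec: VennDesignSpec,
) -> Tuple[List[FeatureTable], TreatmentDesign, Dict]:
    """Generate per-sample feature tables plus a ground-truth manifest.

    Returns ``(tables, design, manifest)``; the manifest records every
    planted feature's true (m/z, RT), its category, the treatments it was
    planted into, and the expected stage-1/2/3 memberships per microbe.
    """
    design = spec.treatment_design()
    rng_place = np.random.default_rng(child_seed(spec.seed, "venn/placement"))

    # ---- decide the treatment list ------------------------------------
    treatments: List[str] = [spec.baseline_label, "full_community"]
    treatments += [lbl for lbl in spec.baseline_overrides.values()
                   if lbl not in treatments]
    for m in spec.microbes:
        treatments.append(f"iv_{m}")
        if not spec.baseline_overrides.get(m):
            treatments.append(f"single_{m}")
    treatments += [lbl for lbl in spec.exclusion_members if lbl not in treatments]
    treatments += [lbl for lbl in spec.extra_control_labels
                   if lbl not in treatments]
    treatments = list(dict.fromkeys(treatments))

    def triple_labels(m: str) -> List[str]:
        t = design.triples[m]
        return [t["in_vitro"], t["single"], t["full"]]

    # ---- plant features ------------------------------------------------
    placed: List[Tuple[float, float]] = []
    features: List[Dict] = []

    def plant(category: str, owner, n: int, labels: Sequence[str]):
        coords = _draw_separated(rng_place, n, spec, placed)
        placed.extend(coords)
        for k, (mz, rt) in enumerate(coords):
            features.append(
                {
                    "truth_id": f"{category}:{owner}:{k}" if owner
                    else f"{category}:{k}",
                    "category": category,
                    "owner": owner,
                    "mz": mz,
                    "rt_min": rt,
                    "treatments": list(dict.fromkeys(labels)),
                }
            )

    plant("baseline", None, spec.baseline_count, treatments)
    for m in spec.microbes:
        labels = triple_labels(m)
        # member microbes' features also show up in exclusion communities
        # that contain them
        labels = labels + [
            lbl for lbl, members in spec.exclusion_members.items()
            if m in members
        ]
        plant("unique", m, spec.unique_counts[m], labels)
    for (a, b), n in sorted(spec.shared_counts.items()):
        plant("shared", f"{a}+{b}", n,
              triple_labels(a) + triple_labels(b))

    # leakage: plant the first k of a microbe's unique features into an
    # exclusion community (nested, so the leaked union is max(k))
    for m, leaks in sorted(spec.leakage.items()):
        uniques = [f for f in features
                   if f["category"] == "unique" and f["owner"] == m]
        for label, k in sorted(leaks.items()):
            if label not in treatments:
                raise ValueError(f"unknown exclusion community {label!r}")
            for f in uniques[:k]:
                if label not in f["treatments"]:
                    f["treatments"].append(label)
                    f.setdefault("leaked_into", []).append(label)

    # ---- emit per-sample tables ----------------------------------------
    tables: List[FeatureTable] = []
    for tr in treatments:
        for rep in range(1, spec.replicates + 1):
            rng = np.random.default_rng(
                child_seed(spec.seed, f"venn/sample/{tr}/r{rep}")
            )
            rows = []
            for f in features:
                if tr not in f["treatments"]:
                    continue
                if spec.dropout and rng.random() < spec.dropout:
                    continue
                mz = f["mz"] * (
                    1 + rng.uniform(-spec.mz_jitter_ppm,
                                    spec.mz_jitter_ppm) * 1e-6
                )
                rt = f["rt_min"] + rng.uniform(-spec.rt_jitter_min,
                                               spec.rt_jitter_min)
                intensity = float(np.exp(rng.normal(12.0, 1.0)))
                rows.append((f["truth_id"], mz, max(rt, 0.0), intensity))
            df = pd.DataFrame(
                rows, columns=["feature_id", "mz", "rt_min", "intensity"]
            )
            tables.append(FeatureTable(tr, f"r{rep}", df))

    # ---- ground-truth manifest -----------------------------------------
    expected_stage1 = {
        m: sorted(
            f["truth_id"] for f in features
            if (f["category"] == "unique" and f["owner"] == m)
            or (f["category"] == "shared" and m in f["owner"].split("+"))
        )
        for m in spec.microbes
    }
    expected_stage2 = {
        m: sorted(
            f["truth_id"] for f in features
            if f["category"] == "unique" and f["owner"] == m
        )
        for m in spec.microbes
    }
    expected_stage3 = {}
    for m in spec.microbes:
        excl_labels = design.exclusions_for(m)
        expected_stage3[m] = sorted(
            tid for tid in expected_stage2[m]
            if not any(
                lbl in next(
                    f for f in features if f["truth_id"] == tid
                )["treatments"]
                for lbl in excl_labels
            )
        )
    manifest = {
        "seed": spec.seed,
        "features": features,
        "treatments": treatments,
        "expected_counts": {
            "stage1": {m: len(v) for m, v in expected_stage1.items()},
            "stage2": {m: len(v) for m, v in expected_stage2.items()},
            "stage3": {m: len(v) for m, v in expected_stage3.items()},
        },
        "expected_stage1": expected_stage1,
        "expected_stage2": expected_stage2,
        "expected_stage3": expected_stage3,
    }
    return tables, design, manifest


def study_venn_design(seed: int = 0, **overrides) -> VennDesignSpec:
    """The five-microbe study design with its published stage counts.

    Stage-2 unique features: 0 (Paenibacillus Ag47), 4 (P. agglomerans
    Ag15), 5 (Pseudomonas Ag54), 16 (B. brevis Ag35), 37 (S. meliloti);
    three of the B. brevis features also occur in the two communities
    lacking B. brevis, leaving 13 after the exclusion filter.  The
    symbiont's baseline is a plant-only control (its own single-inoculation
    treatment is the global baseline and cannot double as its subtraction).
    """
    sm, ag15, ag35, ag47, ag54 = (
        "S_meliloti", "P_agglomerans_Ag15", "B_brevis_Ag35",
        "Paenibacillus_Ag47", "Pseudomonas_Ag54",
    )
    spec = VennDesignSpec(
        microbes=[sm, ag15, ag35, ag47, ag54],
        unique_counts={sm: 37, ag15: 4, ag35: 16, ag47: 0, ag54: 5},
        shared_counts={(ag15, ag54): 3, (ag35, ag47): 2},
        baseline_count=25,
        exclusion_members={
            "excl_all_minus_Bb": frozenset({sm, ag15, ag47, ag54}),
            "excl_trio_Sm_Ag15_Ag47": frozenset({sm, ag15, ag47}),
        },
        leakage={ag35: {"excl_all_minus_Bb": 3,
                        "excl_trio_Sm_Ag15_Ag47": 2}},
        baseline_label="Sm_only",
        baseline_overrides={sm: "plant_only"},
        extra_control_labels=["plant_only"],
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(spec, key, val)
    spec.__post_init__()
    return spec


# ---------------------------------------------------------------------------
# MS2 ladders
# ---------------------------------------------------------------------------

def gen_ms2_spectrum(
    p: PeptideSpec,
    series: str = "b",
    peak_dropout: float = 0.0,
    mz_jitter_ppm: float = 0.0,
    n_decoys: int = 0,
    seed: int = 0,
    tol_ppm: float = 10.0,
    include_precursor: bool = True,
) -> Tuple[SpectrumRecord, Dict]:
    """Simulate one product-ion ladder with dropout, jitter and decoys.

    Decoy peaks are drawn uniformly but rejected within 3x ``tol_ppm`` of
    any true ion, so they can distract but never mimic a ladder step
    end-point.  Returns the spectrum and a truth dict (ion labels, true
    m/z, dropped ions, decoy m/z).
    """
    if p.cyclic:
        raise ValueError("cyclic peptides are not supported")
    rng = np.random.default_rng(child_seed(seed, f"ms2/{series}"))
    ions = fragment_ions(p, series=(series,), max_charge=1)
    precursor = adduct_mz(peptide_neutral_mass(p), NAMED_ADDUCTS["M+H"])

    peaks, truth_ions, dropped = [], [], []
    for ion in ions:
        if peak_dropout and rng.random() < peak_dropout:
            dropped.append(ion.label)
            continue
        mz = ion.mz * (1 + rng.uniform(-mz_jitter_ppm, mz_jitter_ppm) * 1e-6)
        peaks.append((mz, float(np.exp(rng.normal(10.0, 0.8)))))
        truth_ions.append({"label": ion.label, "mz": ion.mz})

    all_true = [i.mz for i in ions] + [precursor]
    decoys = []
    lo, hi = min(all_true) * 0.5, max(all_true) * 1.05
    while len(decoys) < n_decoys:
        mz = rng.uniform(lo, hi)
        if all(abs(mz - t) / t * 1e6 > 3 * tol_ppm for t in all_true):
            decoys.append(mz)
            peaks.append((mz, float(np.exp(rng.normal(8.0, 0.8)))))

    record = SpectrumRecord(
        peaks,
        precursor_mz=precursor if include_precursor else None,
        precursor_charge=1,
        collision_energy="NCE 15",
    )
    truth = {
        "peptide": list(p.residues),
        "series": series,
        "ions": truth_ions,
        "dropped": dropped,
        "decoys": decoys,
        "precursor_mz": precursor,
    }
    return record, truth


# ---------------------------------------------------------------------------
# Nodule colonization tables
# ---------------------------------------------------------------------------

@dataclass
class ColonizationSpec:
    """Bernoulli colonization probabilities and log-normal CFU parameters.

    ``probabilities[treatment][strain]`` is the chance a nodule from that
    treatment carries the strain; ``cfu_lognormal[treatment][strain]`` is
    the (mu, sigma) of the natural-log CFU distribution used when present.
    """

    probabilities: Dict[str, Dict[str, float]]
    cfu_lognormal: Dict[str, Dict[str, Tuple[float, float]]]
    nodules: Dict[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        for tr, strains in self.probabilities.items():
            for s, prob in strains.items():
                if not (0 <= prob <= 1):
                    raise ValueError(f"p({tr},{s}) = {prob} outside [0, 1]")
            if self.nodules.get(tr, 0) < 1:
                raise ValueError(f"treatment {tr!r} needs >= 1 nodule")


def gen_nodule_table(c: ColonizationSpec):
    """Simulate a nodule isolation table from a colonization spec."""
    from .recovery import NoduleTable

    rows = []
    inoculum = {}
    for tr in sorted(c.probabilities):
        strains = c.probabilities[tr]
        inoculum[tr] = frozenset(strains)
        rng = np.random.default_rng(child_seed(c.seed, f"nodules/{tr}"))
        for i in range(1, c.nodules[tr] + 1):
            nodule = f"{tr}_n{i:03d}"
            for strain in sorted(strains):
                present = rng.random() < strains[strain]
                if present:
                    mu, sigma = c.cfu_lognormal[tr][strain]
                    cfu = max(1, int(round(np.exp(rng.normal(mu, sigma)))))
                else:
                    cfu = 0
                rows.append((tr, nodule, strain, cfu))
    df = pd.DataFrame(rows, columns=["treatment", "nodule_id", "strain", "cfu"])
    return NoduleTable(df, inoculum)


def study_colonization_spec(seed: int = 0) -> ColonizationSpec:
    """Colonization probabilities mirroring the reported recovery rates.

    Single-accessory rates: B. brevis 40%, Paenibacillus 64%, Pseudomonas
    0% (0/15 nodules); the Paenibacillus/Pseudomonas pair at 83% each; the
    trio with B. brevis drops the pair to ~17%/~11%.  Mean CFU for
    Paenibacillus: ~280/nodule alone, ~69/nodule with Pseudomonas (the
    ~4-fold drop).  P. agglomerans' single rate is not printed; 0.33 is a
    synthetic choice.
    """
    ag15, ag35, ag47, ag54 = (
        "P_agglomerans_Ag15", "B_brevis_Ag35",
        "Paenibacillus_Ag47", "Pseudomonas_Ag54",
    )
    sigma = 0.8

    def mu_for(mean: float) -> float:
        return float(np.log(mean) - sigma**2 / 2)

    default_cfu = (mu_for(100.0), sigma)
    return ColonizationSpec(
        probabilities={
            f"single_{ag35}": {ag35: 0.40},
            f"single_{ag47}": {ag47: 0.64},
            f"single_{ag54}": {ag54: 0.0},
            f"single_{ag15}": {ag15: 0.33},
            "pair_Ag47_Ag54": {ag47: 0.83, ag54: 0.83},
            "trio_Ag35_Ag47_Ag54": {ag35: 0.30, ag47: 0.17, ag54: 0.11},
        },
        cfu_lognormal={
            f"single_{ag35}": {ag35: default_cfu},
            f"single_{ag47}": {ag47: (mu_for(280.0), sigma)},
            f"single_{ag54}": {ag54: default_cfu},
            f"single_{ag15}": {ag15: default_cfu},
            "pair_Ag47_Ag54": {ag47: (mu_for(69.0), sigma),
                               ag54: (mu_for(65.0), sigma)},
            "trio_Ag35_Ag47_Ag54": {ag35: default_cfu, ag47: default_cfu,
                                    ag54: default_cfu},
        },
        nodules={
            f"single_{ag35}": 15,
            f"single_{ag47}": 14,
            f"single_{ag54}": 15,
            f"single_{ag15}": 12,
            "pair_Ag47_Ag54": 12,
            "trio_Ag35_Ag47_Ag54": 12,
        },
        seed=seed,
    )
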