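"""Nested subtractive Venn attribution of LC-MS features to microbes.

Untargeted metabolomics of a synthetic root-nodule community yields one
feature table (m/z, retention time, intensity) per sample.  Attributing a
feature to one microbe proceeds in three subtractive stages:

1. **stage 1** per microbe: features present in all three of that microbe's
   treatments (grown alone in vitro, inoculated singly onto plants, and the
   full community in planta) but absent from the baseline treatment
   (nodules carrying only the nitrogen-fixing symbiont);
2. **stage 2**: features unique to one microbe, i.e. its stage-1 set minus
   the union of every other microbe's stage-1 set;
3. **stage 3** (focal microbe): stage-2 features also absent from
   "exclusion communities" — inoculation treatments that lack the focal
   microbe — removing features that co-vary with the rest of the community.

Cross-sample feature identity is established first by single-linkage
clustering under joint m/z (ppm) and retention-time tolerances, and a
feature counts as present in a treatment when it is detected in at least a
configurable fraction of that treatment's replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set

import pandas as pd

__all__ = [
    "FeatureTable",
    "TreatmentDesign",
    "AlignedFeatures",
    "match_features",
    "presence_calls",
    "stage1_microbe_features",
    "stage2_unique",
    "stage3_exclusion",
    "venn_report",
]


@dataclass
class FeatureTable:
    """Features of one sample (one treatment replicate)."""

    treatment: str
    replicate: str
    features: pd.DataFrame  # columns: feature_id, mz, rt_min, intensity

    def __post_init__(self) -> None:
        required = {"feature_id", "mz", "rt_min", "intensity"}
        missing = required - set(self.features.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        if (self.features["mz"] <= 0).any():
            raise ValueError("m/z values must be positive")
        if (self.features["rt_min"] < 0).any():
            raise ValueError("retention times must be non-negative")
        if self.features["feature_id"].duplicated().any():
            raise ValueError("feature ids must be unique within a replicate")

    @classmethod
    def read(cls, path, treatment: str, replicate: str) -> "FeatureTable":
        return cls(treatment, replicate, pd.read_csv(path, sep="\t", comment="#"))

    def write(self, path) -> None:
        self.features.to_csv(path, sep="\t", index=False)


@dataclass
class TreatmentDesign:
    """Roles of treatment labels in the nested Venn design.

    ``triples`` maps each microbe to its ``{"in_vitro", "single", "full"}``
    treatment labels.  ``baseline`` is the default subtraction treatment
    (symbiont-only nodules); ``baseline_overrides`` lets a microbe use a
    different baseline — needed for the symbiont itself, whose features
    would otherwise be subtracted away by its own treatment.
    ``exclusion_communities`` maps a treatment label to its member set.
    """

    microbes: List[str]
    triples: Dict[str, Dict[str, str]]
    baseline: str
    exclusion_communities: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    baseline_overrides: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.microbes:
            if m not in self.triples:
                raise ValueError(f"no treatment triple for microbe {m!r}")
            missing = {"in_vitro", "single", "full"} - set(self.triples[m])
            if missing:
                raise ValueError(f"microbe {m!r} triple missing {sorted(missing)}")
        for label, members in self.exclusion_communities.items():
            self.exclusion_communities[label] = frozenset(members)

    def baseline_for(self, microbe: str) -> str:
        return self.baseline_overrides.get(microbe, self.baseline)

    def exclusions_for(self, microbe: str) -> List[str]:
        return [
            label
            for label, members in self.exclusion_communities.items()
            if microbe not in members
        ]


@dataclass
class AlignedFeatures:
    """Result of cross-sample feature matching.

    ``clusters`` has one row per canonical feature (id, consensus m/z and
    RT, n observations, a flag for suspiciously wide clusters); ``presence``
    is a boolean matrix canonical feature x (treatment, replicate).
    """

    clusters: pd.DataFrame
    presence: pd.DataFrame
    mz_tol_ppm: float
    rt_tol_min: float

    def replicates_of(self, treatment: str) -> List[str]:
        cols = [c for c in self.presence.columns if c[0] == treatment]
        if not cols:
            raise KeyError(f"unknown treatment label {treatment!r}")
        return [c[1] for c in cols]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def match_features(
    tables: Sequence[FeatureTable],
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.2,
) -> AlignedFeatures:
    """Single-linkage alignment of features across samples.

    Two observations link when both |Δm/z| <= ``mz_tol_ppm`` (relative to
    their mean m/z) and |ΔRT| <= ``rt_tol_min``; linked components become
    canonical features.  Canonical ids are assigned in (consensus m/z, RT)
    order, so the output is invariant to the input table order.  Clusters
    whose m/z span exceeds twice the tolerance are flagged ``chained`` —
    the known pathology of single-linkage bridging through intermediates.
    """
    if not tables:
        raise ValueError("need at least one feature table")
    if mz_tol_ppm <= 0 or rt_tol_min <= 0:
        raise ValueError("tolerances must be positive")

    rows = []
    for t in tables:
        for _, r in t.features.iterrows():
            rows.append((t.treatment, t.replicate, r["feature_id"],
                         float(r["mz"]), float(r["rt_min"])))
    obs = pd.DataFrame(rows, columns=["treatment", "replicate",
                                      "feature_id", "mz", "rt_min"])
    obs = obs.sort_values(["mz", "rt_min"], kind="mergesort").reset_index(drop=True)

    uf = _UnionFind(len(obs))
    mz = obs["mz"].to_numpy()
    rt = obs["rt_min"].to_numpy()
    for i in range(len(obs)):
        j = i + 1
        while j < len(obs):
            pair_tol = mz_tol_ppm * 1e-6 * 0.5 * (mz[i] + mz[j])
            if mz[j] - mz[i] > pair_tol:
                break
            if abs(rt[j] - rt[i]) <= rt_tol_min:
                uf.union(i, j)
            j += 1

    obs["component"] = [uf.find(i) for i in range(len(obs))]
    groups = obs.groupby("component", sort=False)
    summary = groups.agg(
        mz=("mz", "mean"), rt_min=("rt_min", "mean"),
        mz_min=("mz", "min"), mz_max=("mz", "max"), n_obs=("mz", "size"),
    ).reset_index()
    summary = summary.sort_values(["mz", "rt_min"]).reset_index(drop=True)
    summary["canonical_id"] = [f"F{i:05d}" for i in range(len(summary))]
    span_ppm = (summary["mz_max"] - summary["mz_min"]) / summary["mz"] * 1e6
    summary["chained"] = span_ppm > 2 * mz_tol_ppm
    comp_to_id = dict(zip(summary["component"], summary["canonical_id"]))
    obs["canonical_id"] = obs["component"].map(comp_to_id)

    samples = sorted({(t.treatment, t.replicate) for t in tables})
    presence = pd.DataFrame(
        False,
        index=summary["canonical_id"],
        columns=pd.MultiIndex.from_tuples(samples,
                                          names=["treatment", "replicate"]),
    )
    for (cid, tr, rep), _ in obs.groupby(
        ["canonical_id", "treatment", "replicate"]
    ):
        presence.loc[cid, (tr, rep)] = True

    clusters = summary[
        ["canonical_id", "mz", "rt_min", "n_obs", "chained"]
    ].set_index("canonical_id")
    return AlignedFeatures(clusters, presence, mz_tol_ppm, rt_tol_min)


def presence_calls(
    aligned: AlignedFeatures, min_replicate_fraction: float = 0.5
) -> Dict[str, Set[str]]:
    """Per-treatment presence sets.

    A canonical feature is "present in a treatment" when it was detected in
    at least ``min_replicate_fraction`` of that treatment's replicates
    (inclusive).
    """
    if not (0 < min_replicate_fraction <= 1):
        raise ValueError("min_replicate_fraction must be in (0, 1]")
    out: Dict[str, Set[str]] = {}
    treatments = sorted({c[0] for c in aligned.presence.columns})
    for tr in treatments:
        block = aligned.presence.loc[:, [c for c in aligned.presence.columns
                                         if c[0] == tr]]
        frac = block.sum(axis=1) / block.shape[1]
        out[tr] = set(frac.index[frac >= min_replicate_fraction])
    return out


def _require(presence: Mapping[str, Set[str]], label: str) -> Set[str]:
    if label not in presence:
        raise KeyError(f"treatment {label!r} has no presence calls")
    return presence[label]


def stage1_microbe_features(
    design: TreatmentDesign,
    presence: Mapping[str, Set[str]],
    microbe: str,
) -> Set[str]:
    """Features in all three of a microbe's treatments, absent from baseline."""
    if microbe not in design.microbes:
        raise KeyError(f"unknown microbe {microbe!r}")
    triple = design.triples[microbe]
    iv = _require(presence, triple["in_vitro"])
    si = _require(presence, triple["single"])
    fc = _require(presence, triple["full"])
    base = _require(presence, design.baseline_for(microbe))
    return (iv & si & fc) - base


def stage2_unique(stage1: Mapping[str, Set[str]]) -> Dict[str, Set[str]]:
    """Per-microbe features absent from every other microbe's stage-1 set."""
    if len(stage1) < 2:
        raise ValueError("stage-2 uniqueness needs at least two microbes")
    out = {}
    for m, s in stage1.items():
        others: Set[str] = set()
        for m2, s2 in stage1.items():
            if m2 != m:
                others |= s2
        out[m] = s - others
    return out


def stage3_exclusion(
    unique: Set[str], exclusion_presence: Iterable[Set[str]]
) -> Set[str]:
    """Drop unique features that appear in any exclusion community."""
    excluded: Set[str] = set()
    for s in exclusion_presence:
        excluded |= s
    return unique - excluded


def venn_report(
    design: TreatmentDesign,
    aligned: AlignedFeatures,
    stage1: Mapping[str, Set[str]],
    stage2: Mapping[str, Set[str]],
    stage3: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Per-microbe stage counts plus m/z-ordered feature details."""
    rows = []
    for m in design.microbes:
        rows.append(
            {
                "microbe": m,
                "stage1": len(stage1.get(m, set())),
                "stage2_unique": len(stage2.get(m, set())),
                "stage3_final": len(stage3[m]) if m in stage3 else None,
            }
        )
    return pd.DataFrame(rows).set_index("microbe")


def feature_details(
    aligned: AlignedFeatures, feature_ids: Set[str]
) -> pd.DataFrame:
    """Consensus m/z and RT for a feature set, ordered by m/z."""
    sub = aligned.clusters.loc[sorted(feature_ids)]
    return sub.sort_values("mz")


def run_venn(
    tables: Sequence[FeatureTable],
    design: TreatmentDesign,
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.2,
    min_replicate_fraction: float = 0.5,
):
    """Convenience pipeline: align, call presence, run all three stages.

    Returns ``(aligned, stage1, stage2, stage3, report)``.  The nesting
    invariant stage3 <= stage2 <= stage1 and pairwise disjointness of the
    stage-2 sets are asserted on every run.
    """
    aligned = match_features(tables, mz_tol_ppm, rt_tol_min)
    presence = presence_calls(aligned, min_replicate_fraction)
    stage1 = {
        m: stage1_microbe_features(design, presence, m)
        for m in design.microbes
    }
    stage2 = stage2_unique(stage1)
    stage3 = {}
    for m in design.microbes:
        excl = [presence[label] for label in design.exclusions_for(m)
                if label in presence]
        stage3[m] = stage3_exclusion(stage2[m], excl)

    for m in design.microbes:
        assert stage3[m] <= stage2[m] <= stage1[m], f"nesting violated for {m}"
    ms = list(design.microbes)
    for i, a in enumerate(ms):
        for b in ms[i + 1:]:
            assert not (stage2[a] & stage2[b]), "stage-2 sets must be disjoint"

    report = venn_report(design, aligned, stage1, stage2, stage3)
    return aligned, stage1, stage2, stage3, report
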