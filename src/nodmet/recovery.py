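"""Recovery-rate and CFU statistics for nodule isolation experiments.

Each treatment inoculates a set of accessory bacteria (always together with
the nodulating symbiont) onto gnotobiotic plants; root nodules are later
harvested and each strain re-isolated and counted.  A strain is "recovered"
from a nodule when at least one colony (CFU) is obtained.  The module
computes:

* per-(treatment, strain) recovery rates (% of nodules with >= 1 CFU);
* recovery relative to the strain's single-accessory baseline treatment,
  with a sign classification (negative / zero / positive, zero band ±1
  percentage point by default);
* per-nodule co-occurrence partitions (which exact strain subsets were
  recovered together);
* mean CFU per nodule (zero-count nodules included) and fold changes; and
* cooperation / competition / neutral / mixed calls for strain pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Tuple

import pandas as pd

__all__ = [
    "NoduleTable",
    "recovery_rates",
    "relative_recovery",
    "cooccurrence_counts",
    "cfu_summary",
    "fold_change",
    "classify_interactions",
]


@dataclass
class NoduleTable:
    """Long-format isolation records.

    ``data`` has one row per (nodule, inoculated strain) with columns
    ``treatment, nodule_id, strain, cfu`` — zero-CFU rows are explicit, so
    every assayed nodule appears for every strain in its treatment's
    inoculum.  ``inoculum`` maps each treatment to its accessory member set
    (the symbiont is implicit and not listed).
    """

    data: pd.DataFrame
    inoculum: Dict[str, FrozenSet[str]]

    def __post_init__(self) -> None:
        required = {"treatment", "nodule_id", "strain", "cfu"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"nodule table missing columns: {sorted(missing)}")
        if (self.data["cfu"] < 0).any():
            raise ValueError("CFU counts must be non-negative")
        for tr, grp in self.data.groupby("treatment"):
            if tr not in self.inoculum:
                raise ValueError(f"treatment {tr!r} has no inoculum set")
            extra = set(grp["strain"]) - set(self.inoculum[tr])
            if extra:
                raise ValueError(
                    f"strains {sorted(extra)} recorded for treatment {tr!r} "
                    "but not in its inoculum"
                )
        self.inoculum = {t: frozenset(s) for t, s in self.inoculum.items()}

    @classmethod
    def read(cls, path) -> "NoduleTable":
        """Read a delimited file with columns
        treatment, inoculum ('A+B'), nodule_id, strain, cfu."""
        df = pd.read_csv(path, sep="\t", comment="#")
        inoc = {
            tr: frozenset(str(val).split("+"))
            for tr, val in df.groupby("treatment")["inoculum"].first().items()
        }
        return cls(df.drop(columns=["inoculum"]), inoc)

    def write(self, path) -> None:
        df = self.data.copy()
        df["inoculum"] = df["treatment"].map(
            lambda t: "+".join(sorted(self.inoculum[t]))
        )
        df[["treatment", "inoculum", "nodule_id", "strain", "cfu"]].to_csv(
            path, sep="\t", index=False
        )

    def treatments(self) -> List[str]:
        return sorted(self.inoculum)

    def nodules_of(self, treatment: str) -> List[str]:
        sub = self.data[self.data["treatment"] == treatment]
        return sorted(sub["nodule_id"].unique())


def recovery_rates(t: NoduleTable, threshold: int = 1) -> pd.DataFrame:
    """Per-(treatment, strain) recovery summary.

    ``rate_pct`` = 100 x (nodules with CFU >= threshold) / (nodules
    assayed); ``mean_cfu`` averages over all nodules in the treatment,
    zero counts included.
    """
    if t.data.empty:
        raise ValueError("empty nodule table")
    rows = []
    for tr in t.treatments():
        sub = t.data[t.data["treatment"] == tr]
        n = sub["nodule_id"].nunique()
        if n == 0:
            raise ValueError(f"treatment {tr!r} has no nodules")
        for strain in sorted(t.inoculum[tr]):
            s = sub[sub["strain"] == strain]
            positive = (
                s.groupby("nodule_id")["cfu"].sum() >= threshold
            ).sum()
            mean_cfu = s.groupby("nodule_id")["cfu"].sum().reindex(
                sub["nodule_id"].unique(), fill_value=0
            ).mean()
            rows.append(
                {
                    "treatment": tr,
                    "strain": strain,
                    "rate_pct": 100.0 * positive / n,
                    "n_nodules": n,
                    "mean_cfu": float(mean_cfu),
                }
            )
    return pd.DataFrame(rows).set_index(["treatment", "strain"])


def relative_recovery(
    summary: pd.DataFrame,
    baseline_map: Mapping[str, str],
    zero_band: float = 1.0,
) -> pd.DataFrame:
    """Recovery rates relative to each strain's single-accessory baseline.

    ``baseline_map`` maps strain -> the treatment where it was the sole
    accessory member.  Adds ``delta_pct`` and ``sign`` in
    {negative, zero, positive}; a baseline treatment scores exactly zero
    against itself by construction.
    """
    out = summary.copy()
    deltas, signs = [], []
    for (tr, strain), row in summary.iterrows():
        if strain not in baseline_map:
            raise KeyError(f"no baseline treatment for strain {strain!r}")
        base_tr = baseline_map[strain]
        try:
            base = summary.loc[(base_tr, strain), "rate_pct"]
        except KeyError:
            raise KeyError(
                f"baseline treatment {base_tr!r} missing for {strain!r}"
            ) from None
        d = row["rate_pct"] - base
        deltas.append(d)
        signs.append(
            "zero" if abs(d) <= zero_band
            else ("positive" if d > 0 else "negative")
        )
    out["delta_pct"] = deltas
    out["sign"] = signs
    return out


def cooccurrence_counts(
    t: NoduleTable, treatment: str, threshold: int = 1
) -> Dict[FrozenSet[str], int]:
    """Partition a treatment's nodules by the exact recovered strain set.

    The empty frozenset collects nodules where nothing was recovered;
    counts always sum to the number of nodules assayed.
    """
    if treatment not in t.inoculum:
        raise KeyError(f"unknown treatment {treatment!r}")
    sub = t.data[t.data["treatment"] == treatment]
    counts: Dict[FrozenSet[str], int] = {}
    for nodule, grp in sub.groupby("nodule_id"):
        recovered = frozenset(
            grp.loc[grp["cfu"] >= threshold, "strain"]
        )
        counts[recovered] = counts.get(recovered, 0) + 1
    return counts


def cfu_summary(t: NoduleTable) -> pd.DataFrame:
    """Mean CFU per nodule for every (treatment, strain)."""
    return recovery_rates(t)[["n_nodules", "mean_cfu"]]


def fold_change(
    summary: pd.DataFrame,
    strain: str,
    from_treatment: str,
    to_treatment: str,
) -> Dict[str, object]:
    """Ratio of mean CFU between two treatments for one strain.

    Returns both means and their ratio; a zero denominator yields the
    string ``"undefined"`` rather than an exception.
    """
    a = float(summary.loc[(from_treatment, strain), "mean_cfu"])
    b = float(summary.loc[(to_treatment, strain), "mean_cfu"])
    ratio: object = "undefined" if b == 0 else a / b
    return {"mean_from": a, "mean_to": b, "fold": ratio}


def classify_interactions(
    t: NoduleTable,
    relative: pd.DataFrame,
    zero_band: float = 1.0,
) -> Dict[str, object]:
    """Cooperation / competition calls for accessory strain pairs.

    For every treatment whose inoculum is exactly a pair {A, B}:

    * ``cooperation`` — both members' recovery relative to their single-
      accessory baselines is positive;
    * ``competition`` — either member is negative;
    * ``neutral`` — both within the zero band;
    * ``mixed`` — recovery says cooperation but a member's mean CFU dropped
      below its single-accessory mean (recovery and abundance disagree).

    Additionally, for every trio treatment containing a pair, a
    ``trio_effects`` record notes when a member's recovery in the trio falls
    below its rate in the pair (competition introduced by the third member).
    Missing treatments produce warnings, not errors.
    """
    warnings: List[str] = []
    pair_labels: Dict[Tuple[str, str], Dict[str, object]] = {}
    pair_treatments = {
        tr: members for tr, members in t.inoculum.items() if len(members) == 2
    }
    for tr, members in sorted(pair_treatments.items()):
        a, b = sorted(members)
        try:
            da = relative.loc[(tr, a), "delta_pct"]
            db = relative.loc[(tr, b), "delta_pct"]
        except KeyError:
            warnings.append(f"pair treatment {tr!r} missing recovery rows")
            continue
        if da > zero_band and db > zero_band:
            label = "cooperation"
        elif da < -zero_band or db < -zero_band:
            label = "competition"
        else:
            label = "neutral"
        cfu_conflict = []
        if label == "cooperation":
            for strain in (a, b):
                base_tr = next(
                    (
                        tr2 for tr2, mem in t.inoculum.items()
                        if mem == frozenset({strain})
                    ),
                    None,
                )
                if base_tr is None:
                    continue
                base_cfu = relative.loc[(base_tr, strain), "mean_cfu"]
                pair_cfu = relative.loc[(tr, strain), "mean_cfu"]
                if base_cfu > 0 and pair_cfu < base_cfu:
                    cfu_conflict.append(strain)
            if cfu_conflict:
                label = "mixed"
        pair_labels[(a, b)] = {
            "treatment": tr,
            "label": label,
            "delta": {a: float(da), b: float(db)},
            "cfu_conflict": cfu_conflict,
        }

    trio_effects = []
    for tr, members in sorted(t.inoculum.items()):
        if len(members) != 3:
            continue
        for pair_tr, pair in sorted(pair_treatments.items()):
            if not pair <= members:
                continue
            third = next(iter(members - pair))
            for strain in sorted(pair):
                try:
                    pair_rate = relative.loc[(pair_tr, strain), "rate_pct"]
                    trio_rate = relative.loc[(tr, strain), "rate_pct"]
                except KeyError:
                    warnings.append(
                        f"trio comparison {tr!r}/{pair_tr!r} incomplete"
                    )
                    continue
                drop = pair_rate - trio_rate
                if drop > zero_band:
                    trio_effects.append(
                        {
                            "trio": tr,
                            "pair": pair_tr,
                            "strain": strain,
                            "third_member": third,
                            "drop_pct": float(drop),
                            "label": "competition",
                        }
                    )
    return {
        "pairs": pair_labels,
        "trio_effects": trio_effects,
        "warnings": warnings,
    }
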