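"""Dual-control classification of cold-responsive genes.

Each differentially expressed gene (4C vs 24C at a matched timepoint) is
classified using two controls: the pre-treatment baseline (T0) and the
concurrent ambient sample.  The cold fold-change FC(4vsT0) is tested
first against timepoint-specific cutoffs (induced: >= 1.5 at 30 min,
>= 2 at 3 h; repressed: <= 2/3 at 30 min, <= 1/2 at 3 h, all inclusive).
Genes failing both cold cutoffs are tested on the ambient fold-change
FC(24vsT0) against the same cutoffs: passing means the gene only moved
under ambient conditions -- the signature of a diurnal oscillation frozen
by cold ("cold-static").  Genes passing neither are indeterminate.

Static genes are further split by the direction of the ambient change:
ambient fell while cold stayed flat (gene appears induced relative to
24C, "static_induced") or ambient rose ("static_repressed").
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CUTOFFS",
    "Cutoffs",
    "fold_change",
    "classify_gene",
    "split_static",
    "classify_table",
]


@dataclass(frozen=True)
class Cutoffs:
    induced: float
    repressed: float


#: classifier fold-change cutoffs keyed by timepoint
CUTOFFS: dict[str, Cutoffs] = {
    "30min": Cutoffs(induced=1.5, repressed=2.0 / 3.0),
    "3h": Cutoffs(induced=2.0, repressed=0.5),
}

_TIMEPOINT_ALIASES = {"t0.5": "30min", "30min": "30min", "0.5h": "30min",
                      "t3": "3h", "3h": "3h", "3hr": "3h", "3hrs": "3h"}


def resolve_cutoffs(timepoint, cutoffs: Mapping[str, Cutoffs] | None = None) -> Cutoffs:
    """Cutoffs for a timepoint label or a numeric hour (>= 1 h uses the 3 h set)."""
    table = cutoffs or CUTOFFS
    if isinstance(timepoint, str):
        key = _TIMEPOINT_ALIASES.get(timepoint.lower())
        if key is None or key not in table:
            raise ValueError(f"unknown timepoint: {timepoint!r}")
        return table[key]
    hours = float(timepoint)
    return table["3h"] if hours >= 1.0 else table["30min"]


def fold_change(expr, baseline, pseudocount: float = 0.5) -> float:
    """(mean(expr)+c) / (mean(baseline)+c) on normalized expression values."""
    expr = np.asarray(expr, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if expr.size == 0 or baseline.size == 0:
        raise ValueError("need at least one replicate on each side")
    if (expr < 0).any() or (baseline < 0).any():
        raise ValueError("expression values must be non-negative")
    return float((expr.mean() + pseudocount) / (baseline.mean() + pseudocount))


def classify_gene(fc4: float, fc24: float, timepoint,
                  cutoffs: Mapping[str, Cutoffs] | None = None) -> str:
    """Category of one DEG from its cold and ambient fold-changes vs T0.

    The cold fold-change is checked first; only genes failing both cold
    cutoffs are checked against the ambient control.
    """
    cut = resolve_cutoffs(timepoint, cutoffs)
    if fc4 <= 0 or fc24 <= 0:
        raise ValueError("fold-changes must be positive")
    if fc4 >= cut.induced:
        return "induced"
    if fc4 <= cut.repressed:
        return "repressed"
    if fc24 >= cut.induced or fc24 <= cut.repressed:
        return "static"
    return "indeterminate"


def split_static(category: str, fc24: float, timepoint,
                 cutoffs: Mapping[str, Cutoffs] | None = None) -> str:
    """Subtype of a static gene from the direction of the ambient change."""
    if category != "static":
        raise ValueError("split_static applies only to static genes")
    cut = resolve_cutoffs(timepoint, cutoffs)
    if fc24 <= cut.repressed:
        return "static_induced"   # ambient fell, cold stayed flat
    if fc24 >= cut.induced:
        return "static_repressed"  # ambient rose, cold stayed flat
    raise ValueError("static gene whose FC(24vsT0) passes no cutoff")


def classify_table(
    deg_sets: Mapping[tuple[str, str], set],
    expression: pd.DataFrame,
    design: pd.DataFrame,
    pseudocount: float = 0.5,
    cutoffs: Mapping[str, Cutoffs] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify every DEG in every (organ, timepoint) contrast.

    Parameters
    ----------
    deg_sets:
        Mapping from ``(organ, timepoint)`` to the set of DEG ids of that
        contrast.
    expression:
        TMM-normalized per-million expression, genes x samples.
    design:
        Sample design with organ/condition/timepoint columns; every organ
        needs T0 samples.

    Returns the per-gene classification table and a summary dict with
    per-category counts and pairwise category overlaps across contrasts.
    """
    rows = []
    for (organ, timepoint), genes in deg_sets.items():
        dsub = design[design["organ"] == organ]
        t0_samples = dsub.loc[dsub["timepoint"] == "T0", "sample_id"].tolist()
        if not t0_samples:
            raise ValueError(f"no T0 samples for organ {organ!r}")
        cold_samples = dsub.loc[
            (dsub["timepoint"] == timepoint) & (dsub["condition"] == "cold"),
            "sample_id"].tolist()
        amb_samples = dsub.loc[
            (dsub["timepoint"] == timepoint) & (dsub["condition"] == "ambient"),
            "sample_id"].tolist()
        if not cold_samples or not amb_samples:
            raise ValueError(f"missing samples for contrast ({organ}, {timepoint})")
        for gene in sorted(genes):
            base = expression.loc[gene, t0_samples].to_numpy()
            fc4 = fold_change(expression.loc[gene, cold_samples].to_numpy(), base, pseudocount)
            fc24 = fold_change(expression.loc[gene, amb_samples].to_numpy(), base, pseudocount)
            category = classify_gene(fc4, fc24, timepoint, cutoffs)
            subtype = (split_static(category, fc24, timepoint, cutoffs)
                       if category == "static" else "none")
            rows.append({"gene_id": gene, "organ": organ, "timepoint": timepoint,
                         "FC4": fc4, "FC24": fc24,
                         "category": category, "static_subtype": subtype})
    table = pd.DataFrame(rows, columns=["gene_id", "organ", "timepoint",
                                        "FC4", "FC24", "category", "static_subtype"])

    counts: dict[str, dict[str, int]] = {}
    bins: dict[tuple[str, str, str], set] = {}
    for (organ, timepoint), _ in deg_sets.items():
        sub = table[(table["organ"] == organ) & (table["timepoint"] == timepoint)]
        key = f"{organ}:{timepoint}"
        counts[key] = sub["category"].value_counts().to_dict()
        sub_static = sub[sub["category"] == "static"]
        counts[key].update(sub_static["static_subtype"].value_counts().to_dict())
        for cat in ("induced", "repressed", "static"):
            bins[(organ, timepoint, cat)] = set(sub.loc[sub["category"] == cat, "gene_id"])

    overlaps = {}
    for (k1, s1), (k2, s2) in combinations(sorted(bins.items()), 2):
        if k1[:2] == k2[:2]:
            continue  # same contrast: categories are disjoint by construction
        overlaps["|".join([":".join(k1), ":".join(k2)])] = len(s1 & s2)

    summary = {"category_counts": counts, "overlaps": overlaps,
               "n_classified": int(len(table))}
    return table, summary
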