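"""Hypergeometric gene-set overlap and over-representation analysis.

Covers the two set-based steps of the analysis: testing whether a query
set (e.g. the cold-static genes, translated to a reference species via an
ortholog map) overlaps a rhythmic gene set more than chance, and generic
over-representation of a query against a GMT collection with BH control.
Term sets are treated flat (no ontology-graph propagation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "map_orthologs",
    "rhythmic_set",
    "hypergeometric_overlap",
    "enrich_collections",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT collection (name, description, members per tab-separated line)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    lines = [
        "\t".join([s.name, s.name] + sorted(s.genes)) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ortholog_map(path) -> dict[str, list[str]]:
    """Two-column TSV (source gene, target ortholog) -> source-to-targets dict."""
    mapping: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValueError(f"malformed ortholog map line: {line[:80]!r}")
        mapping.setdefault(parts[0], []).append(parts[1])
    return mapping


def map_orthologs(
    genes: Iterable[str],
    mapping: Mapping[str, Sequence[str]],
    policy: str = "all",
) -> tuple[set[str], int]:
    """Translate gene ids through an ortholog map.

    ``policy`` handles one-to-many sources: ``"all"`` keeps every target,
    ``"first"`` the first listed, ``"drop_ambiguous"`` drops multi-target
    sources.  Returns the deduplicated mapped set and the number of
    unmapped input genes.
    """
    if not mapping:
        raise ValueError("empty ortholog map")
    if policy not in ("all", "first", "drop_ambiguous"):
        raise ValueError(f"unknown policy: {policy!r}")
    mapped: set[str] = set()
    unmapped = 0
    for g in genes:
        targets = mapping.get(g)
        if not targets:
            unmapped += 1
            continue
        if policy == "all":
            mapped.update(targets)
        elif policy == "first":
            mapped.add(targets[0])
        else:
            if len(targets) == 1:
                mapped.add(targets[0])
            else:
                unmapped += 1
    return mapped, unmapped


def rhythmic_set(
    table: pd.DataFrame,
    annotation_col: str = "phase",
    gene_col: str = "gene_id",
    nonrhythmic: str = "n.r",
    case_insensitive: bool = True,
    name: str = "rhythmic",
) -> GeneSet:
    """Genes not flagged non-rhythmic ("n.r") in a diurnal/circadian table.

    Any phase annotation counts as rhythmic, irrespective of peak time.
    """
    for col in (annotation_col, gene_col):
        if col not in table.columns:
            raise ValueError(f"missing column: {col!r}")
    ann = table[annotation_col].astype(str).str.strip()
    flag = nonrhythmic.lower() if case_insensitive else nonrhythmic
    if case_insensitive:
        keep = ann.str.lower() != flag
    else:
        keep = ann != flag
    return GeneSet(name, frozenset(table.loc[keep, gene_col]))


def hypergeometric_overlap(query: GeneSet | set, reference: GeneSet | set,
                           universe_size: int) -> tuple[int, float]:
    """Upper-tail hypergeometric P[X >= k] for the overlap of two sets.

    Returns ``(k, p)`` where ``k`` is the observed overlap.  Both sets
    must fit inside the universe.
    """
    q = query.genes if isinstance(query, GeneSet) else set(query)
    r = reference.genes if isinstance(reference, GeneSet) else set(reference)
    n, big_k = len(q), len(r)
    if n > universe_size or big_k > universe_size:
        raise ValueError("set larger than the universe")
    k = len(q & r)
    # P[X >= k] with X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, universe_size, big_k, n))
    return k, min(p, 1.0)


def enrich_collections(
    query: GeneSet | set,
    collections: Sequence[GeneSet],
    universe: Iterable[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of a query set against a GMT collection.

    Sets are clipped to the universe; one hypergeometric upper-tail test
    per set, BH-adjusted across the collection.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    q = (query.genes if isinstance(query, GeneSet) else set(query)) & universe
    rows = []
    for s in collections:
        members = s.genes & universe
        k, p = hypergeometric_overlap(q, members, len(universe))
        rows.append({"set": s.name, "overlap": k, "query_size": len(q),
                     "set_size": len(members), "universe": len(universe),
                     "pvalue": p})
    out = pd.DataFrame(rows, columns=["set", "overlap", "query_size",
                                      "set_size", "universe", "pvalue"])
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
        out["significant"] = out["fdr"] < fdr
        out = out.sort_values("pvalue", kind="stable").reset_index(drop=True)
    return out
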