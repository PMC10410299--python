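"""Configuration-driven pipeline: simulate -> normalize/DE -> classify -> enrich -> trajectories.

The pipeline either loads a count matrix + design from disk or simulates
one with ground truth, then runs every analysis stage and writes TSV
tables plus a machine-readable JSON summary.  Identical config + seed
produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_table
from .de import call_degs, dispersion_trend, nb_two_group_test
from .enrichment import (GeneSet, enrich_collections, hypergeometric_overlap,
                         map_orthologs, read_gmt, read_ortholog_map)
from .normalize import cpm, tmm_factors
from .profiles import default_clock_panel
from .simulate import (AMPLICON_DEPTH_RANGE, make_design, random_panel,
                       simulate_amplicon, simulate_counts)
from .trajectory import AMPLICON_TIMEPOINTS, compare_trajectories, find_peak, relative_expression

__all__ = ["PipelineConfig", "PipelineError", "ValidationError",
           "validate_inputs", "run_pipeline"]

log = logging.getLogger("coldclock")


class PipelineError(RuntimeError):
    """Internal pipeline failure (exit code 1)."""


class ValidationError(PipelineError):
    """Input schema violation (exit code 2)."""


@dataclass
class SimulationBlock:
    n_genes: int = 1000
    n_replicates: int = 3
    dispersion: float = 0.05
    mean_lib_size: float = 1e6
    lib_cv: float = 0.2
    organs: tuple = ("shoot", "root")
    fractions: dict = field(default_factory=lambda: {
        "induced": 0.1, "repressed": 0.1, "static": 0.25, "none": 0.55})


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    counts_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    ortholog_map_path: str | None = None
    deg_fdr: float = 0.01
    enrich_fdr: float = 0.05
    pseudocount: float = 0.5
    simulation: SimulationBlock = field(default_factory=SimulationBlock)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim = SimulationBlock(**raw.pop("simulation", {}))
        known = {f for f in cls.__dataclass_fields__ if f != "simulation"}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(simulation=sim, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("deg_fdr", "enrich_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if (self.counts_path is None) != (self.design_path is None):
            raise ValidationError("counts_path and design_path must be given together")

    def config_hash(self) -> str:
        # outdir is a location, not an analysis parameter
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_inputs(counts: pd.DataFrame, design: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Check counts/design agreement; raises :class:`ValidationError` naming offenders."""
    dup = counts.index[counts.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate gene ids: {dup[:10]}")
    cols = set(counts.columns)
    ids = set(design["sample_id"])
    extra = sorted(cols - ids)
    missing = sorted(ids - cols)
    if extra or missing:
        raise ValidationError(
            f"sample mismatch between counts and design: extra columns {extra[:10]}, "
            f"missing columns {missing[:10]}")
    arr = counts.to_numpy()
    neg = np.argwhere(arr < 0)
    if neg.size:
        i, j = neg[0]
        raise ValidationError(
            f"negative count for gene {counts.index[i]!r} in sample {counts.columns[j]!r}")
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError("counts must be integers")
    return counts, design


def _contrasts(design: pd.DataFrame) -> list[tuple[str, str]]:
    out = []
    for organ in pd.unique(design["organ"]):
        sub = design[design["organ"] == organ]
        for tp in pd.unique(sub["timepoint"]):
            if tp == "T0":
                continue
            tsub = sub[sub["timepoint"] == tp]
            if {"ambient", "cold"} <= set(tsub["condition"]):
                out.append((str(organ), str(tp)))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the run summary (also written to summary.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config_hash": config.config_hash(), "stages": {}}

    # --- stage 1: data ---------------------------------------------------
    if config.counts_path:
        counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
        design = pd.read_csv(config.design_path)
        truth = None
    else:
        sim = config.simulation
        # one gene panel shared by both organs, as for a real genome
        panel_genes = random_panel(sim.n_genes, sim.fractions,
                                   seed=int(rng.integers(2**31)),
                                   dispersion=sim.dispersion)
        designs, count_frames = [], []
        for organ in sim.organs:
            tps = ("T0", "T0.5", "T3") if organ == "shoot" else ("T0", "T3")
            d = make_design(organ, tps, sim.n_replicates, sim.mean_lib_size,
                            sim.lib_cv, seed=rng)
            c, _ = simulate_counts(panel_genes, d, seed=rng)
            designs.append(d)
            count_frames.append(c)
        design = pd.concat(designs, ignore_index=True)
        counts = pd.concat(count_frames, axis=1)
        from .simulate import truth_table
        truth = truth_table(panel_genes)
        truth.to_csv(outdir / "truth.tsv", sep="\t")
    validate_inputs(counts, design)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    design.to_csv(outdir / "design.csv", index=False)
    summary["stages"]["data"] = {"n_genes": int(counts.shape[0]),
                                 "n_samples": int(counts.shape[1])}
    log.info("data: %d genes x %d samples", *counts.shape)

    # --- stage 2: normalization + DE -------------------------------------
    deg_sets: dict[tuple[str, str], set] = {}
    de_counts = {}
    expr_frames = []
    for organ in pd.unique(design["organ"]):
        dsub = design[design["organ"] == organ]
        csub = counts[dsub["sample_id"]]
        factors = tmm_factors(csub)
        groups = (dsub["timepoint"] + "_" + dsub["condition"]).to_numpy()
        disp = dispersion_trend(csub, groups)
        expr_frames.append(cpm(csub, factors))
        for organ2, tp in [c for c in _contrasts(design) if c[0] == organ]:
            tsub = dsub[dsub["timepoint"] == tp]
            amb = tsub.loc[tsub["condition"] == "ambient", "sample_id"].tolist()
            cold = tsub.loc[tsub["condition"] == "cold", "sample_id"].tolist()
            res = nb_two_group_test(csub, amb, cold, dispersions=disp, factors=factors,
                                    pseudocount=config.pseudocount)
            res.to_csv(outdir / f"de_{organ}_{tp}.tsv", sep="\t")
            degs = call_degs(res, config.deg_fdr)
            deg_sets[(str(organ), str(tp))] = degs
            de_counts[f"{organ}:{tp}"] = len(degs)
    expression = pd.concat(expr_frames, axis=1)
    summary["stages"]["de"] = {"degs": de_counts, "fdr_threshold": config.deg_fdr}
    log.info("DE: %s", de_counts)

    # --- stage 3: dual-control classification ----------------------------
    classified, cls_summary = classify_table(deg_sets, expression, design,
                                             pseudocount=config.pseudocount)
    classified.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    summary["stages"]["classify"] = cls_summary

    # --- stage 4: set enrichment -----------------------------------------
    static_genes = set(classified.loc[classified["category"] == "static", "gene_id"])
    universe = set(counts.index)
    if config.ortholog_map_path:
        omap = read_ortholog_map(config.ortholog_map_path)
        static_mapped, n_unmapped = map_orthologs(static_genes, omap)
        universe_mapped, _ = map_orthologs(universe, omap)
    else:  # identity mapping
        static_mapped, n_unmapped = static_genes, 0
        universe_mapped = universe
    if truth is not None:
        rhythmic = GeneSet("rhythmic_truth", frozenset(
            truth.index[(truth["amplitude"] > 0.5)]) & frozenset(universe_mapped))
    else:
        rhythmic = GeneSet("rhythmic_truth", frozenset())
    enr_summary = {"n_static": len(static_genes), "n_unmapped": n_unmapped}
    if len(rhythmic):
        k, p = hypergeometric_overlap(static_mapped, rhythmic.genes, len(universe_mapped))
        enr_summary["rhythmic_overlap"] = {"k": k, "p": p}
    if config.gmt_path:
        collections = read_gmt(config.gmt_path)
        enr = enrich_collections(static_mapped, collections, universe_mapped,
                                 fdr=config.enrich_fdr)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        enr_summary["n_significant_sets"] = int(enr["significant"].sum()) if len(enr) else 0
    summary["stages"]["enrichment"] = enr_summary

    # --- stage 5: clock trajectories --------------------------------------
    panel = default_clock_panel("shoot")
    zts = [2.5 + h for h in AMPLICON_TIMEPOINTS]
    amp_counts, amp_design = simulate_amplicon(
        panel, zts, ("ambient", "cold"), AMPLICON_DEPTH_RANGE, seed=rng)
    amp_counts.to_csv(outdir / "amplicon_counts.tsv", sep="\t")
    ref = amp_counts.loc["EF1a"].to_numpy()
    records = []
    for gene in amp_counts.index:
        if gene == "EF1a":
            continue
        ratio = relative_expression(amp_counts.loc[gene].to_numpy(), ref)
        for sid, r in zip(amp_counts.columns, ratio):
            row = amp_design[amp_design["sample_id"] == sid].iloc[0]
            records.append({"gene_id": gene, "condition": row["condition"],
                            "time": row["zt"] - 2.5, "ratio": r})
    traj = pd.DataFrame(records)
    comparison = compare_trajectories(traj)
    peaks = {}
    for gene, sub in traj[traj["condition"] == "ambient"].groupby("gene_id"):
        sub = sub.sort_values("time")
        pk = find_peak(sub["time"].to_numpy() + 2.5, sub["ratio"].to_numpy())
        peaks[gene] = pk.time if pk.found else None
    comparison.to_csv(outdir / "trajectory_comparison.tsv", sep="\t")
    summary["stages"]["trajectory"] = {
        "n_genes": int(len(comparison)),
        "n_significant": int((comparison["pvalue"] < 0.01).sum()),
        "ambient_peaks_zt": peaks,
    }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
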