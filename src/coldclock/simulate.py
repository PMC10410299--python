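"""Synthetic diurnal/cold transcriptome generator.

Generates gene-by-sample integer count matrices with known ground truth:
each gene follows a :class:`~coldclock.profiles.ClockGeneProfile`, samples
follow a study design of organs, conditions (4C/24C), ZT timepoints and
replicates, and counts are drawn from a negative-binomial with
library-size-scaled means (Var = mu + alpha*mu^2).  Also simulates the
multiplexed amplicon assay used for clock-gene time series, where a
sample's total depth is drawn uniformly from the observed 11,000-37,000
read range and reads are multinomial across the gene panel.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    DEFAULT_T_TREAT,
    ClockGeneProfile,
    ColdResponseSpec,
    calibrate_amplitude,
    diurnal_mean,
)

__all__ = [
    "TIMEPOINT_ZT",
    "make_design",
    "simulate_counts",
    "simulate_gene_counts",
    "simulate_amplicon",
    "random_panel",
    "truth_table",
]

#: ZT hours of the study's named timepoints (treatment starts at ZT2.5)
TIMEPOINT_ZT = {"T0": 2.5, "T0.5": 3.0, "T3": 5.5}

#: amplicon sequencing depth range (reads per sample)
AMPLICON_DEPTH_RANGE = (11_000, 37_000)


def make_design(
    organ: str = "shoot",
    timepoints: Sequence[str] = ("T0", "T0.5", "T3"),
    n_replicates: int = 3,
    mean_lib_size: float = 1e6,
    lib_cv: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Build a sample design table.

    T0 samples are pre-treatment (one set, labelled ambient); every later
    timepoint appears under both ambient and cold.  Library sizes are
    lognormal with coefficient of variation ``lib_cv`` around
    ``mean_lib_size``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for tp in timepoints:
        zt = TIMEPOINT_ZT.get(tp)
        if zt is None:
            raise ValueError(f"unknown timepoint label: {tp!r}")
        conditions = ("ambient",) if tp == "T0" else ("ambient", "cold")
        for cond in conditions:
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "sample_id": f"{organ}_{tp}_{cond}_r{rep}",
                    "organ": organ,
                    "condition": cond,
                    "zt": zt,
                    "timepoint": tp,
                    "replicate": rep,
                })
    design = pd.DataFrame(rows)
    if lib_cv > 0:
        sigma = math.sqrt(math.log(1.0 + lib_cv**2))
        libs = mean_lib_size * np.exp(rng.normal(-sigma**2 / 2, sigma, len(design)))
    else:
        libs = np.full(len(design), mean_lib_size)
    design["lib_size"] = libs
    return design


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha) -> np.ndarray:
    """Negative-binomial draws with Var = mu + alpha*mu^2 (Poisson at alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 1e-12
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        a = alpha[~pois]
        m = mean[~pois]
        size = 1.0 / a
        p = size / (size + m)
        out[~pois] = rng.negative_binomial(size, p)
    return out


def truth_table(profiles: Iterable[ClockGeneProfile]) -> pd.DataFrame:
    """Ground-truth table: one row per simulated gene."""
    rows = []
    for p in profiles:
        rows.append({
            "gene_id": p.gene_id,
            "category": p.cold.category,
            "fold": p.cold.fold,
            "dampening": p.cold.dampening,
            "phase": p.phase,
            "amplitude": p.amplitude,
            "baseline": p.baseline,
            "dispersion": p.dispersion,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_counts(
    profiles: Sequence[ClockGeneProfile] | Mapping[str, ClockGeneProfile],
    design: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    t_treat: float = DEFAULT_T_TREAT,
    depth_normalize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an integer count matrix (genes x samples) plus its truth table.

    With ``depth_normalize`` the per-sample expected total equals the
    design's library size: mean_ij = s_j * mu_i(t_j) / C with C the average
    across samples of the summed profile means.  Without it the NB mean is
    the raw profile mean (useful for single-gene checks).
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    if len(profiles) == 0:
        raise ValueError("at least one profile required")
    if len(design) == 0:
        raise ValueError("empty design")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    mu = np.empty((len(profiles), len(design)))
    for i, prof in enumerate(profiles):
        for j, row in enumerate(design.itertuples()):
            mu[i, j] = diurnal_mean(prof, row.zt, row.condition, t_treat=t_treat)

    if depth_normalize:
        c = mu.sum(axis=0).mean()
        libs = design["lib_size"].to_numpy() if "lib_size" in design else np.full(len(design), c)
        means = mu * (libs / c)
    else:
        means = mu

    alpha = np.array([p.dispersion for p in profiles])[:, None]
    counts = _nb_draw(rng, means, alpha)
    counts_df = pd.DataFrame(counts, index=[p.gene_id for p in profiles],
                             columns=design["sample_id"].to_numpy())
    counts_df.index.name = "gene_id"
    return counts_df, truth_table(profiles)


def simulate_gene_counts(
    profile: ClockGeneProfile,
    zts: Sequence[float],
    condition: str,
    n_replicates: int = 3,
    dispersion: float | None = None,
    seed: int | np.random.Generator = 0,
    t_treat: float = DEFAULT_T_TREAT,
) -> np.ndarray:
    """NB replicate draws for one gene at given ZT hours (shape: len(zts) x n)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    alpha = profile.dispersion if dispersion is None else dispersion
    mu = np.array([diurnal_mean(profile, t, condition, t_treat=t_treat) for t in zts])
    return _nb_draw(rng, np.repeat(mu[:, None], n_replicates, axis=1), alpha)


def simulate_amplicon(
    profiles: Sequence[ClockGeneProfile] | Mapping[str, ClockGeneProfile],
    zts: Sequence[float],
    conditions: Sequence[str] = ("ambient", "cold"),
    depth_range: tuple[int, int] = AMPLICON_DEPTH_RANGE,
    seed: int | np.random.Generator = 0,
    t_treat: float = DEFAULT_T_TREAT,
    t_release: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the multiplexed amplicon time-series assay.

    One sequencing run per (condition, ZT); total depth uniform over
    ``depth_range`` and reads multinomial across the panel in proportion
    to each gene's expected expression.  Returns (counts genes x samples,
    design table).
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    if len(profiles) == 0:
        raise ValueError("empty amplicon panel")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    cols, col_counts, rows = [], [], []
    for cond in conditions:
        for t in zts:
            mu = np.array([
                diurnal_mean(p, t, cond, t_treat=t_treat, t_release=t_release)
                for p in profiles
            ])
            depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
            reads = rng.multinomial(depth, mu / mu.sum())
            sid = f"{cond}_h{t:g}"
            cols.append(sid)
            col_counts.append(reads)
            rows.append({"sample_id": sid, "condition": cond, "zt": t, "depth": depth})
    counts = pd.DataFrame(
        np.column_stack(col_counts), index=[p.gene_id for p in profiles], columns=cols)
    counts.index.name = "gene_id"
    return counts, pd.DataFrame(rows)


def random_panel(
    n_genes: int = 2000,
    fractions: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    dispersion: float = 0.05,
    t_treat: float = DEFAULT_T_TREAT,
    t_eval: float = 5.5,
) -> list[ClockGeneProfile]:
    """Random gene panel with labelled ground truth for benchmarking.

    Default composition mirrors the structure the analysis assumes: a
    majority of unaffected genes (mildly rhythmic, oscillation unchanged
    by cold), a large block of static genes (strongly diurnal, oscillation
    frozen by cold), and monotone cold-induced/repressed genes.  Effect
    sizes are drawn so that true responders pass the classifier cutoffs by
    a comfortable margin at the 3-hour timepoint.
    """
    fractions = dict(fractions or {"induced": 0.1, "repressed": 0.1,
                                   "static": 0.25, "none": 0.55})
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    counts = {c: int(round(f * n_genes)) for c, f in fractions.items()}
    counts["none"] = n_genes - sum(v for c, v in counts.items() if c != "none")
    profiles: list[ClockGeneProfile] = []
    idx = 0
    for category in ("induced", "repressed", "static", "none"):
        for _ in range(counts.get(category, 0)):
            idx += 1
            gid = f"g{idx:05d}_{category}"
            base = float(np.exp(rng.normal(math.log(200.0), 0.8)))
            if category in ("induced", "repressed"):
                fold = float(np.exp(rng.uniform(math.log(3.0), math.log(10.0))))
                rate = float(rng.uniform(0.5, 2.0))
                profiles.append(ClockGeneProfile(
                    gid, base, dispersion=dispersion,
                    cold=ColdResponseSpec(category=category, fold=fold, rate=rate)))
            elif category == "static":
                # strongly diurnal; amplitude solved so the ambient
                # t_treat -> t_eval fold clears the classifier cutoff, with
                # a cap to rule out pathological near-degenerate phases
                fold = float(np.exp(rng.uniform(math.log(3.0), math.log(8.0))))
                if rng.random() < 0.5:
                    fold = 1.0 / fold
                while True:
                    phase = float(rng.uniform(0.0, 24.0))
                    try:
                        a = calibrate_amplitude(1.0 / fold, t_treat, t_eval, phase)
                    except ValueError:
                        continue
                    if 0 < a <= 6.0:
                        break
                # anchor expected expression at the treatment start
                c0 = math.cos(2.0 * math.pi * (t_treat - phase) / 24.0)
                baseline = base / math.exp(a * c0)
                profiles.append(ClockGeneProfile(
                    gid, baseline, amplitude=a, phase=phase, dispersion=dispersion,
                    cold=ColdResponseSpec(category="static", dampening=0.0)))
            else:
                a = float(rng.uniform(0.0, 0.2))
                phase = float(rng.uniform(0.0, 24.0))
                profiles.append(ClockGeneProfile(
                    gid, base, amplitude=a, phase=phase, dispersion=dispersion,
                    cold=ColdResponseSpec(category="none")))
    return profiles
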