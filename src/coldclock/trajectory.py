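"""Clock-gene time-series analysis from amplicon read counts.

Expression is measured relative to a constant reference gene (read ratio,
invariant to sequencing depth), trajectories are fit with a cubic
regression-spline basis on log1p ratios, and the ambient and cold
trajectories of each gene are compared with an F-test on the block of
condition terms (offset plus condition x basis interactions), with
residual variances moderated across genes when enough genes are assayed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats

from .de import squeeze_var
from .profiles import DEFAULT_T_TREAT, ClockGeneProfile, diurnal_mean

__all__ = [
    "AMPLICON_TIMEPOINTS",
    "relative_expression",
    "spline_basis",
    "fit_spline",
    "TrajectoryFit",
    "compare_trajectories",
    "find_peak",
    "PeakResult",
    "time_to_peak_after_release",
]

#: hours after treatment start at which the amplicon assay samples
AMPLICON_TIMEPOINTS = (0, 1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 24)

#: minimum number of genes for empirical-Bayes variance moderation
MIN_GENES_FOR_MODERATION = 5


def relative_expression(gene_reads, reference_reads) -> np.ndarray:
    """Per-sample ratio of gene reads to reference-gene reads."""
    g = np.asarray(gene_reads, dtype=float)
    r = np.asarray(reference_reads, dtype=float)
    if g.shape != r.shape:
        raise ValueError("gene and reference read vectors differ in length")
    zero = np.flatnonzero(r <= 0)
    if zero.size:
        raise ValueError(f"reference gene has zero reads in sample(s) {zero.tolist()}")
    return g / r


def spline_basis(times, df: int = 4, basis: str = "bs") -> np.ndarray:
    """Cubic spline basis matrix (no intercept column).

    ``basis="bs"`` is a degree-3 B-spline with knots at quantiles of the
    observed times (together with an intercept it spans all cubic
    polynomials); ``"cr"`` is a natural cubic spline.
    """
    t = np.asarray(times, dtype=float)
    if basis == "bs":
        mat = dmatrix(f"bs(x, df={df}, degree=3) - 1", {"x": t})
    elif basis == "cr":
        mat = dmatrix(f"cr(x, df={df}) - 1", {"x": t})
    else:
        raise ValueError(f"unknown basis: {basis!r}")
    return np.asarray(mat)


@dataclass
class TrajectoryFit:
    times: np.ndarray
    coef: np.ndarray
    fitted: np.ndarray        # on the log1p scale
    resid_var: float
    df_resid: int
    df: int
    basis: str

    @property
    def fitted_ratio(self) -> np.ndarray:
        return np.expm1(self.fitted)


def fit_spline(times, values, df: int = 4, basis: str = "bs") -> TrajectoryFit:
    """Least-squares cubic-spline fit of log1p(ratio) against time."""
    t = np.asarray(times, dtype=float)
    y = np.log1p(np.asarray(values, dtype=float))
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be equal-length 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if len(t) < df + 2:
        raise ValueError(f"need at least {df + 2} points for df={df}")
    X = np.column_stack([np.ones(len(t)), spline_basis(t, df=df, basis=basis)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    df_resid = len(t) - X.shape[1]
    rss = float(np.sum((y - fitted) ** 2))
    resid_var = rss / df_resid if df_resid > 0 else np.nan
    return TrajectoryFit(times=t, coef=coef, fitted=fitted,
                         resid_var=resid_var, df_resid=df_resid, df=df, basis=basis)


def compare_trajectories(data: pd.DataFrame, df: int = 4, basis: str = "bs",
                         value_col: str = "ratio") -> pd.DataFrame:
    """Per-gene test for a difference between two condition trajectories.

    ``data`` is long-format with columns ``gene_id``, ``condition``,
    ``time`` and the value column.  For each gene, log1p values are
    regressed on intercept + spline(time) + condition + condition x
    spline(time); the F-test covers the full condition block, so both
    level shifts and shape changes count as differential.  Residual
    variances are shrunk across genes (moderated F) when at least
    ``MIN_GENES_FOR_MODERATION`` genes are present, otherwise the
    ordinary F-test is used.
    """
    required = {"gene_id", "condition", "time", value_col}
    if not required <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    conditions = sorted(data["condition"].unique())
    if len(conditions) != 2:
        raise ValueError("exactly two conditions are required")

    genes, rss0_l, rss1_l, df_res_l, q_l = [], [], [], [], []
    for gene, sub in data.groupby("gene_id", sort=True):
        sub = sub.sort_values(["condition", "time"])
        t = sub["time"].to_numpy(dtype=float)
        y = np.log1p(sub[value_col].to_numpy(dtype=float))
        cond = (sub["condition"] == conditions[1]).to_numpy(dtype=float)
        B = spline_basis(t, df=df, basis=basis)
        X0 = np.column_stack([np.ones(len(t)), B])
        X1 = np.column_stack([X0, cond[:, None], B * cond[:, None]])
        if len(t) <= X1.shape[1]:
            raise ValueError(f"gene {gene!r}: too few observations for df={df}")
        for X, store in ((X0, rss0_l), (X1, rss1_l)):
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            store.append(float(np.sum((y - X @ coef) ** 2)))
        genes.append(gene)
        df_res_l.append(len(t) - X1.shape[1])
        q_l.append(X1.shape[1] - X0.shape[1])

    rss0 = np.array(rss0_l)
    rss1 = np.array(rss1_l)
    df_res = np.array(df_res_l, dtype=float)
    q = np.array(q_l, dtype=float)
    s2 = rss1 / df_res

    if len(genes) >= MIN_GENES_FOR_MODERATION and len(set(df_res)) == 1:
        s2_post, d0, _ = squeeze_var(s2, float(df_res[0]))
        df2 = df_res + (d0 if np.isfinite(d0) else 1e6)
    else:
        s2_post, df2 = s2, df_res

    fstat = ((rss0 - rss1) / q) / np.maximum(s2_post, 1e-300)
    pvals = stats.f.sf(fstat, q, df2)
    return pd.DataFrame({"gene_id": genes, "fstat": fstat, "pvalue": pvals,
                         "df1": q, "df2": df2}).set_index("gene_id")


@dataclass(frozen=True)
class PeakResult:
    found: bool
    time: float | None
    value: float | None


def find_peak(times, values, rel_tol: float = 1e-6) -> PeakResult:
    """Argmax peak of a trajectory on a grid; flat trajectories have no peak.

    Ties break to the earliest time; the trajectory is flagged peakless
    when its relative range is below ``rel_tol``.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        raise ValueError("empty trajectory")
    span = float(v.max() - v.min())
    scale = max(abs(float(v.max())), 1e-300)
    if span < rel_tol * scale:
        return PeakResult(found=False, time=None, value=None)
    i = int(np.argmax(v))  # argmax returns the first (earliest) maximum
    return PeakResult(found=True, time=float(t[i]), value=float(v[i]))


def time_to_peak_after_release(
    profile: ClockGeneProfile,
    cold_duration: float,
    t_treat: float = DEFAULT_T_TREAT,
    grid: float = 0.1,
) -> float:
    """Hours from the end of cold treatment to the first expression peak.

    Simulates the noise-free trajectory through cold and release and runs
    :func:`find_peak` on one post-release period.  A zero duration means
    the plant never experienced cold and the ambient peak is returned.
    """
    if cold_duration < 0:
        raise ValueError("cold duration must be non-negative")
    t_release = t_treat + cold_duration
    times = np.round(np.arange(t_release, t_release + profile.period + grid / 2, grid), 10)
    if cold_duration == 0:
        values = diurnal_mean(profile, times, "ambient", t_treat=t_treat)
    else:
        values = diurnal_mean(profile, times, "cold", t_treat=t_treat, t_release=t_release)
    peak = find_peak(times, values)
    if not peak.found:
        raise ValueError("trajectory has no peak (flat)")
    return float(peak.time - t_release)
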