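"""Between-sample normalization: trimmed mean of M-values (TMM) and CPM.

TMM corrects for library composition: for each sample a weighted mean of
per-gene log2 expression ratios (M-values) against a reference sample is
computed after discarding the most extreme 30% of M-values and 5% of
A-values (average log intensity), with inverse-variance precision
weights.  Factors are rescaled to geometric mean 1 so they are pure
composition corrections on top of library size.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["tmm_factors", "cpm", "effective_lib_sizes"]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference column."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # delta-method variance of M on the count scale (floored: a gene taking
    # a whole library would otherwise get infinite weight)
    w = np.maximum((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r), 1e-12)

    if len(m) == 0:
        return 0.0
    n = len(m)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or not np.isfinite(w[keep2]).all():
        return 0.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    counts: pd.DataFrame,
    reference_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    The reference sample defaults to the column whose upper-quartile
    expression (counts scaled by library size) is closest to the mean
    upper quartile.  Genes with a zero count in either member of a pair
    are excluded from that pair's trim set.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")

    if reference_sample is None:
        f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(reference_sample)

    log_f = np.array([
        0.0 if j == ref_idx else
        _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(x.shape[1])
    ])
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def effective_lib_sizes(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.Series:
    if factors is None:
        factors = tmm_factors(counts)
    return counts.sum(axis=0) * factors


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """TMM-normalized counts per million."""
    eff = effective_lib_sizes(counts, factors)
    return counts.div(eff, axis=1) * 1e6
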