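"""Parametric model of diurnal gene expression and its response to chilling.

The model describes the expected expression of a gene over Zeitgeber time
(ZT, hours since lights-on) under ambient temperature and under a chilling
treatment that starts at ``t_treat`` (default ZT2.5, the treatment start
used throughout the package).

Ambient expression oscillates on the log scale::

    mu(t) = b * exp(a * cos(2*pi*(t - phi)/P))

so that peak/trough ratios are fold-changes independent of the baseline
``b``.  Chilling either freezes the oscillation at its pre-treatment level
(cold-static genes, with a dampening fraction ``d`` of residual amplitude),
or drives a monotone exponential approach to a new level ``F``-fold above
(cold-induced) or below (cold-repressed) the pre-treatment level.  After
the plant is returned to ambient temperature the oscillation resumes with
its phase reset so the next peak falls a fixed number of hours after
release, matching the observed clock-resumption behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CATEGORIES",
    "ColdResponseSpec",
    "ClockGeneProfile",
    "diurnal_mean",
    "calibrate_amplitude",
    "calibrate_dampening",
    "default_clock_panel",
    "DEFAULT_T_TREAT",
]

#: categories a gene's cold response can take
CATEGORIES = ("induced", "repressed", "static", "none")

#: treatment start, hours after lights-on
DEFAULT_T_TREAT = 2.5


@dataclass(frozen=True)
class ColdResponseSpec:
    """How a gene responds to the chilling treatment.

    Parameters
    ----------
    category:
        ``"induced"``/``"repressed"`` for monotone cold responders,
        ``"static"`` for genes whose oscillation is frozen at the
        pre-treatment level, ``"none"`` for genes unaffected by cold.
    fold:
        Fold-change magnitude reached under prolonged cold (>1 for
        induced and repressed; ignored otherwise).
    rate:
        First-order kinetic constant (per hour) of the approach to the
        cold level.
    dampening:
        Fraction ``d`` in [0, 1] of the diurnal amplitude retained under
        cold for static genes; ``d=0`` is a fully flat trajectory.
    resume_peak_delay:
        Hours from the end of cold treatment to the first post-release
        expression peak of an oscillating gene.  The default of 3 h
        reflects the observed clock resumption time, which is independent
        of cold duration and time of day.
    """

    category: str = "none"
    fold: float = 1.0
    rate: float = 1.0
    dampening: float = 0.0
    resume_peak_delay: float = 3.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown cold-response category: {self.category!r}")
        if self.category in ("induced", "repressed") and not self.fold > 1.0:
            raise ValueError("fold must be > 1 for induced/repressed genes")
        if not 0.0 <= self.dampening <= 1.0:
            raise ValueError("dampening must lie in [0, 1]")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass(frozen=True)
class ClockGeneProfile:
    """Ground-truth expression profile of one gene.

    ``baseline`` is in arbitrary mean-count units; ``amplitude`` is the
    dimensionless log-scale oscillation strength; ``phase`` the ZT hour of
    peak expression; ``dispersion`` the negative-binomial dispersion used
    when counts are simulated from the profile.
    """

    gene_id: str
    baseline: float
    amplitude: float = 0.0
    phase: float = 0.0
    period: float = 24.0
    dispersion: float = 0.05
    cold: ColdResponseSpec = field(default_factory=ColdResponseSpec)

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 <= self.phase < self.period:
            raise ValueError("phase must lie in [0, period)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _ambient(profile: ClockGeneProfile, t: np.ndarray) -> np.ndarray:
    theta = 2.0 * math.pi * (t - profile.phase) / profile.period
    return profile.baseline * np.exp(profile.amplitude * np.cos(theta))


def diurnal_mean(
    profile: ClockGeneProfile,
    t,
    condition: str = "ambient",
    t_treat: float = DEFAULT_T_TREAT,
    t_release: float | None = None,
):
    """Expected expression of ``profile`` at ZT hour(s) ``t``.

    ``condition`` is ``"ambient"`` or ``"cold"``; under cold the treatment
    starts at ``t_treat`` and, if ``t_release`` is given, ends there, after
    which the oscillation resumes with its next peak at
    ``t_release + resume_peak_delay``.  Accepts scalar or array ``t``;
    returns the same shape.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if condition not in ("ambient", "cold"):
        raise ValueError(f"unknown condition: {condition!r}")

    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    mu = _ambient(profile, t_arr)

    released = t_release is not None and t_release > t_treat
    if condition == "cold" and profile.cold.category != "none":
        spec = profile.cold
        mu_treat = float(_ambient(profile, np.array([t_treat]))[0])
        in_cold = t_arr >= t_treat
        if released:
            in_cold &= t_arr < t_release
        dt = np.clip(t_arr - t_treat, 0.0, None)
        if spec.category == "static":
            cold_mu = mu_treat + spec.dampening * (mu - mu_treat)
        elif spec.category == "induced":
            cold_mu = mu_treat * (1.0 + (spec.fold - 1.0) * (1.0 - np.exp(-spec.rate * dt)))
        else:  # repressed
            cold_mu = mu_treat * (1.0 + (1.0 / spec.fold - 1.0) * (1.0 - np.exp(-spec.rate * dt)))
        mu = np.where(in_cold, cold_mu, mu)

        if released:
            after = t_arr >= t_release
            if np.any(after):
                if spec.category == "static":
                    # oscillation resumes, phase anchored to the release time
                    peak_t = t_release + spec.resume_peak_delay
                    theta = 2.0 * math.pi * (t_arr - peak_t) / profile.period
                    resumed = profile.baseline * np.exp(profile.amplitude * np.cos(theta))
                else:
                    # monotone responders relax back toward the ambient curve
                    dt_cold = t_release - t_treat
                    if spec.category == "induced":
                        level = mu_treat * (1.0 + (spec.fold - 1.0) * (1.0 - math.exp(-spec.rate * dt_cold)))
                    else:
                        level = mu_treat * (1.0 + (1.0 / spec.fold - 1.0) * (1.0 - math.exp(-spec.rate * dt_cold)))
                    amb = _ambient(profile, t_arr)
                    amb_rel = float(_ambient(profile, np.array([t_release]))[0])
                    resumed = amb + (level - amb_rel) * np.exp(-spec.rate * (t_arr - t_release))
                mu = np.where(after, resumed, mu)

    return float(mu[0]) if scalar else mu


def calibrate_amplitude(fold: float, t0: float, t1: float, phase: float, period: float = 24.0) -> float:
    """Amplitude ``a`` making the ambient trajectory satisfy mu(t0)/mu(t1) = fold.

    Closed-form inversion of the cosine oscillation model::

        a = ln(fold) / (cos(2*pi*(t0-phase)/P) - cos(2*pi*(t1-phase)/P))

    Raises if the two cosines coincide (amplitude unidentifiable).
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    c0 = math.cos(2.0 * math.pi * (t0 - phase) / period)
    c1 = math.cos(2.0 * math.pi * (t1 - phase) / period)
    denom = c0 - c1
    if abs(denom) < 1e-12:
        raise ValueError(
            f"amplitude unidentifiable: cos terms coincide at t0={t0}, t1={t1}, phase={phase}"
        )
    return math.log(fold) / denom


def calibrate_dampening(ambient_fold: float, cold_fold: float) -> float:
    """Dampening ``d`` so a static gene shows ``cold_fold`` where ambient shows ``ambient_fold``.

    Both folds are mu(t1)/mu(t0) with t0 at the treatment start.  For a
    static gene the cold fold is ``1 + d*(ambient_fold - 1)``.
    """
    if ambient_fold == 1.0:
        raise ValueError("ambient fold of 1 leaves dampening unidentifiable")
    d = (cold_fold - 1.0) / (ambient_fold - 1.0)
    return float(min(max(d, 0.0), 1.0))


def _profile_from_fold(
    gene_id: str,
    ambient_fold: float,
    phase: float,
    expr_t0: float,
    cold: ColdResponseSpec,
    t_treat: float = DEFAULT_T_TREAT,
    t1: float = 5.5,
    dispersion: float = 0.05,
) -> ClockGeneProfile:
    """Build a profile whose ambient mu(t1)/mu(t_treat) equals ``ambient_fold``.

    ``expr_t0`` anchors the expected expression at the treatment start.
    When the declared phase cannot produce the declared fold direction
    under a single cosine (the calibrated amplitude comes out negative),
    the amplitude magnitude is kept and the phase wins; the realized fold
    is then the reciprocal of the declared one.
    """
    if ambient_fold == 1.0:
        a = 0.0
    else:
        a = calibrate_amplitude(1.0 / ambient_fold, t_treat, t1, phase)
        a = abs(a)
    c0 = math.cos(2.0 * math.pi * (t_treat - phase) / 24.0)
    baseline = expr_t0 / math.exp(a * c0)
    return ClockGeneProfile(
        gene_id=gene_id, baseline=baseline, amplitude=a, phase=phase,
        dispersion=dispersion, cold=cold,
    )


def default_clock_panel(organ: str = "shoot") -> dict[str, ClockGeneProfile]:
    """The packaged default clock-gene panel.

    Amplitudes are solved from the reported ambient T0-to-T3 (ZT2.5 to
    ZT5.5) fold-changes of the core clock genes; phases are the reported
    diurnal peak times where available, otherwise canonical morning or
    evening phases.  CBF3 is the strong monotone cold-induced control and
    EF1a the constant reference gene used by the amplicon assay.
    """
    static0 = ColdResponseSpec(category="static", dampening=0.0)
    if organ == "shoot":
        panel = {
            # CCA1 falls 10-fold T0->T3 at 24C but only 30% at 4C
            "CCA1": _profile_from_fold(
                "CCA1", 0.1, 2.5, 1000.0,
                ColdResponseSpec(category="static",
                                 dampening=calibrate_dampening(0.1, 0.7))),
            "RVE6": _profile_from_fold("RVE6", 0.5, 2.5, 300.0, static0),
            "RVE8": _profile_from_fold("RVE8", 0.2, 2.5, 500.0, static0),
            "PRR7": _profile_from_fold("PRR7", 2.0, 14.5, 200.0, static0),
            "GI": _profile_from_fold("GI", 8.0, 12.0, 150.0, static0),
            "ELF3": _profile_from_fold("ELF3", 2.5, 18.5, 200.0, static0),
            "PRR9": ClockGeneProfile(
                "PRR9", 150.0,
                cold=ColdResponseSpec(category="induced", fold=2.5, rate=1.0)),
            "CBF3": ClockGeneProfile(
                "CBF3", 20.0,
                cold=ColdResponseSpec(category="induced", fold=400.0, rate=2.0)),
        }
    elif organ == "root":
        panel = {
            "CCA1": _profile_from_fold("CCA1", 0.25, 2.5, 1000.0, static0),
            "RVE8": _profile_from_fold("RVE8", 0.5, 2.5, 500.0, static0),
            "PRR7": _profile_from_fold("PRR7", 1.6, 14.5, 200.0, static0),
            "GI": _profile_from_fold("GI", 1.5, 12.0, 150.0, static0),
            "LUX": _profile_from_fold("LUX", 6.0, 14.0, 100.0, static0),
            "TOC1": _profile_from_fold("TOC1", 2.0, 14.0, 150.0, static0),
            "PRR9": ClockGeneProfile(
                "PRR9", 150.0,
                cold=ColdResponseSpec(category="induced", fold=2.0, rate=1.0)),
            "CBF3": ClockGeneProfile(
                "CBF3", 20.0,
                cold=ColdResponseSpec(category="induced", fold=155.0, rate=2.0)),
        }
    else:
        raise ValueError(f"unknown organ: {organ!r}")
    panel["EF1a"] = ClockGeneProfile("EF1a", 3000.0)  # constant reference gene
    return panel
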