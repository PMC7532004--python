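"""Radioligand binding bookkeeping and curve fits.

Covers the standard filtration-assay workflow: specific binding (total minus
nonspecific counts), single-site saturation isotherms (K_d, B_max), Hill-type
modulator concentration-response curves anchored at 100% of control,
mono-exponential binding time courses, cpm-to-amount conversion, and the
state-affinity-weighted prediction of fractional orthosteric binding from ROD
occupancies.

Fits are unweighted nonlinear least squares (lmfit/Levenberg-Marquardt) on
concentrations normalized internally, with coarse log-grid starting values so
the result is invariant under unit rescaling and robust to local minima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from lmfit import Model

from .model import StateOccupancy

__all__ = [
    "BindingPoint",
    "SpecificBinding",
    "IsothermFit",
    "HillFit",
    "TimeCourseFit",
    "StateAffinities",
    "FitFailure",
    "specific_binding",
    "fit_isotherm",
    "fit_hill_modulation",
    "fit_mono_exponential",
    "predict_fractional_binding",
    "counts_to_amount",
]

#: dpm per Curie
DPM_PER_CI = 2.22e12


class FitFailure(RuntimeError):
    """A nonlinear fit did not converge or gave unphysical parameters."""


@dataclass(frozen=True)
class BindingPoint:
    """One filtration-assay record at a single ligand concentration."""

    ligand_concentration: float  # molar
    total_counts: float  # cpm
    nonspecific_counts: float  # cpm
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.ligand_concentration <= 0:
            raise ValueError("ligand concentration must be positive")
        if self.total_counts < 0 or self.nonspecific_counts < 0:
            raise ValueError("counts must be non-negative")


class SpecificBinding(NamedTuple):
    cpm: float
    negative: bool  # QC flag; negative values are retained, not clipped


@dataclass(frozen=True)
class IsothermFit:
    """Single-site saturation fit B = B_max * x / (K_d + x)."""

    k_d: float  # molar
    b_max: float  # same units as the input binding values
    k_d_stderr: float | None
    b_max_stderr: float | None
    residual_rms: float
    n_points: int

    def predict(self, x):
        return self.b_max * np.asarray(x) / (self.k_d + np.asarray(x))


@dataclass(frozen=True)
class HillFit:
    """Hill modulation fit E(c) = 100 + (E_max - 100) * c^n / (c^n + EC50^n)."""

    ec50: float  # molar
    hill_slope: float
    e_max: float  # percent of control; 100 = no effect
    baseline: float  # fixed at 100 unless a free baseline was requested
    ec50_stderr: float | None
    hill_slope_stderr: float | None
    e_max_stderr: float | None
    residual_rms: float
    no_effect: bool  # degenerate flat-curve report

    def predict(self, c):
        c = np.asarray(c, dtype=float)
        cn = c**self.hill_slope
        return self.baseline + (self.e_max - self.baseline) * cn / (
            cn + self.ec50**self.hill_slope
        )


@dataclass(frozen=True)
class TimeCourseFit:
    """Mono-exponential approach B(t) = B0 + (Binf - B0) * (1 - exp(-t/tau))."""

    tau: float  # minutes
    initial: float  # percent of control at t = 0
    plateau: float  # percent of control at t -> inf
    tau_stderr: float | None
    residual_rms: float

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.initial + (self.plateau - self.initial) * (1 - np.exp(-t / self.tau))


@dataclass(frozen=True)
class StateAffinities:
    """Orthosteric-ligand dissociation constants per ROD state (molar)."""

    resting: float
    open: float
    desensitized: float

    def __post_init__(self) -> None:
        if min(self.resting, self.open, self.desensitized) <= 0:
            raise ValueError("all state K_d values must be positive")
        if self.resting < max(self.open, self.desensitized):
            raise ValueError(
                "resting-state K_d must be >= open/desensitized K_d "
                "(high-affinity assumption)"
            )


#: GABA dissociation constants estimated for resting / open / desensitized
#: alpha-beta-gamma receptors: 78.5 uM, 120 nM, 40 nM.
DEFAULT_STATE_AFFINITIES = StateAffinities(78.5e-6, 120e-9, 40e-9)


def specific_binding(point: BindingPoint) -> SpecificBinding:
    """Total minus nonspecific counts; negative results are flagged, not clipped."""
    value = point.total_counts - point.nonspecific_counts
    return SpecificBinding(cpm=value, negative=value < 0)


def _rms(result) -> float:
    return float(np.sqrt(np.mean(result.residual**2)))


def fit_isotherm(concentrations, binding) -> IsothermFit:
    """Fit a single-site saturation isotherm to specific binding vs concentration.

    Requires >= 4 distinct concentrations.  Concentrations are normalized to
    their geometric mean internally, and K_d starting values are scanned on a
    log grid spanning the data.  A fitted K_d outside
    [min(conc)/100, max(conc)*100] is reported as a failure.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(binding, dtype=float)
    if x.size != y.size:
        raise ValueError("concentration and binding arrays must match")
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    scale = float(np.exp(np.mean(np.log(x))))
    xs = x / scale
    yscale = float(np.max(np.abs(y))) or 1.0
    ys = y / yscale

    def one_site(x, kd, bmax):
        return bmax * x / (kd + x)

    model = Model(one_site)
    best = None
    for kd0 in np.geomspace(xs.min() / 10, xs.max() * 10, 9):
        params = model.make_params(kd=kd0, bmax=max(ys.max(), 1e-6))
        params["kd"].set(min=0)
        res = model.fit(ys, params, x=xs, fit_kws={'xtol': 1e-10, 'ftol': 1e-10})
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitFailure("isotherm fit did not converge from any starting value")
    kd = best.params["kd"].value * scale
    bmax = best.params["bmax"].value * yscale
    if not (x.min() / 100 <= kd <= x.max() * 100) or bmax <= 0:
        raise FitFailure(
            f"isotherm fit unphysical: K_d={kd:.3g} M outside "
            f"[{x.min() / 100:.3g}, {x.max() * 100:.3g}] or B_max={bmax:.3g} <= 0"
        )
    kd_err = best.params["kd"].stderr
    bmax_err = best.params["bmax"].stderr
    return IsothermFit(
        k_d=kd,
        b_max=bmax,
        k_d_stderr=kd_err * scale if kd_err is not None else None,
        b_max_stderr=bmax_err * yscale if bmax_err is not None else None,
        residual_rms=_rms(best) * yscale,
        n_points=int(x.size),
    )


def fit_hill_modulation(
    concentrations, percent_of_control, free_baseline: bool = False
) -> HillFit:
    """Fit a Hill curve to a modulator concentration-response (percent of control).

    The baseline is anchored at exactly 100% of control (the no-modulator
    condition defines 100%) unless ``free_baseline``.  Supports E_max < 100
    (inhibition).  When the fitted effect |E_max - 100| is smaller than twice
    the residual scatter the fit is reported as a degenerate no-effect curve.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(percent_of_control, dtype=float)
    if c.size != y.size:
        raise ValueError("concentration and response arrays must match")
    if np.unique(c).size < 5:
        raise ValueError("need >= 5 distinct modulator concentrations")
    if np.any(c <= 0):
        raise ValueError("modulator concentrations must be positive")
    scale = float(np.exp(np.mean(np.log(c))))
    cs = c / scale

    def hill(c, ec50, n, emax, base):
        cn = c**n
        return base + (emax - base) * cn / (cn + ec50**n)

    model = Model(hill)
    best = None
    emax0 = float(y[np.argmax(c)])
    for ec0 in np.geomspace(cs.min(), cs.max(), 7):
        params = model.make_params(ec50=ec0, n=1.0, emax=emax0, base=100.0)
        params["ec50"].set(min=0)
        params["n"].set(min=0.05, max=10)
        params["emax"].set(min=0)
        params["base"].set(vary=free_baseline)
        res = model.fit(y, params, c=cs, fit_kws={'xtol': 1e-10, 'ftol': 1e-10})
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitFailure("Hill fit did not converge from any starting value")
    emax = best.params["emax"].value
    base = best.params["base"].value
    rms = _rms(best)
    no_effect = abs(emax - base) < 2.0 * max(rms, 1e-9)
    ec50_err = best.params["ec50"].stderr
    return HillFit(
        ec50=best.params["ec50"].value * scale,
        hill_slope=best.params["n"].value,
        e_max=emax,
        baseline=base,
        ec50_stderr=ec50_err * scale if ec50_err is not None else None,
        hill_slope_stderr=best.params["n"].stderr,
        e_max_stderr=best.params["emax"].stderr,
        residual_rms=rms,
        no_effect=bool(no_effect),
    )


def fit_mono_exponential(times, values) -> TimeCourseFit:
    """Fit a mono-exponential time course (times in minutes).

    Requires >= 4 time points including some near the plateau.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("time and value arrays must match")
    if np.unique(t).size < 4:
        raise ValueError("need >= 4 distinct time points")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")

    def mono(t, b0, binf, tau):
        return b0 + (binf - b0) * (1 - np.exp(-t / tau))

    model = Model(mono)
    span = float(t.max() - t.min()) or 1.0
    best = None
    for tau0 in np.geomspace(span / 30, span * 3, 7):
        params = model.make_params(b0=float(y[np.argmin(t)]), binf=float(y[np.argmax(t)]), tau=tau0)
        params["tau"].set(min=1e-9)
        res = model.fit(y, params, t=t, fit_kws={'xtol': 1e-10, 'ftol': 1e-10})
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitFailure("time-course fit did not converge from any starting value")
    tau = best.params["tau"].value
    if not tau > 0:
        raise FitFailure(f"time-course fit unphysical: tau={tau}")
    return TimeCourseFit(
        tau=tau,
        initial=best.params["b0"].value,
        plateau=best.params["binf"].value,
        tau_stderr=best.params["tau"].stderr,
        residual_rms=_rms(best),
    )


def predict_fractional_binding(
    occ: StateOccupancy, x: float, aff: StateAffinities = DEFAULT_STATE_AFFINITIES
) -> float:
    """Occupancy-weighted fractional orthosteric binding at ligand concentration x.

    Sum over states of p_state * x / (x + K_d,state).  With equal open and
    desensitized K_d and x far below every K_d, ratios of this quantity reduce
    to ratios of the high-affinity occupancy (P_open + P_des).
    """
    if x < 0:
        raise ValueError("ligand concentration must be non-negative")
    return (
        occ.p_resting * x / (x + aff.resting)
        + occ.p_open * x / (x + aff.open)
        + occ.p_desensitized * x / (x + aff.desensitized)
    )


def counts_to_amount(
    cpm: float, specific_activity_ci_per_mmol: float, counting_efficiency: float = 1.0
) -> float:
    """Convert scintillation counts (cpm) to femtomoles of ligand.

    dpm = cpm / efficiency; 1 Ci = 2.22e12 dpm; amount = dpm / (SA in dpm/fmol).
    """
    if specific_activity_ci_per_mmol <= 0:
        raise ValueError("specific activity must be positive")
    if not 0 < counting_efficiency <= 1:
        raise ValueError("counting efficiency must be in (0, 1]")
    if cpm < 0:
        raise ValueError("cpm must be non-negative")
    dpm = cpm / counting_efficiency
    dpm_per_fmol = specific_activity_ci_per_mmol * DPM_PER_CI * 1e-12  # mmol -> fmol
    return dpm / dpm_per_fmol
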