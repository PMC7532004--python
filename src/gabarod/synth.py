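"""Synthetic-data generator for the whole analysis pipeline.

Emulates the measurements the pipeline consumes — per-cell peak/steady-state
open probabilities with between-cell scatter, relaxing current traces from a
kinetic three-state scheme, and filtration-assay count tables — from a
parameterized model of state-dependent neurosteroid action at three
transmembrane binding sites (the beta(+)/alpha(-) intersubunit site and the
alpha- and beta-intrasubunit sites).

A ligand is described by a per-site occupancy constant and a per-site
saturating efficacy factor on L (activation) or Q (desensitization).  At
fractional site occupancy ``occ = c / (c + K_site)`` the factor applied to L
or Q is interpolated as ``1 / (1 + occ * (1/e - 1))``, which equals 1 at zero
occupancy and the saturating factor ``e`` at full occupancy, and makes the
low-agonist binding-enhancement effect proportional to site occupancy (so a
fitted Hill EC50 tracks the site's occupancy constant).  Factors combine
multiplicatively across sites.  This quantitative mapping is a generator
choice, not an experimentally derived law.

All randomness flows through an explicit seed: identical seed and
configuration give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.stats import truncnorm

from . import model as rod
from .binding import DEFAULT_STATE_AFFINITIES, StateAffinities, predict_fractional_binding
from .traces import CurrentTrace

__all__ = [
    "SiteAction",
    "LigandEffectProfile",
    "SimulationConfig",
    "apply_ligand",
    "ligand_presets",
    "simulate_responses",
    "simulate_trace",
    "simulate_binding",
    "simulate_hill_curve",
    "simulate_timecourse",
]

SITE_NAMES = ("intersubunit", "alpha_intra", "beta_intra")


@dataclass(frozen=True)
class SiteAction:
    """One binding site's occupancy constant and saturating efficacies.

    ``l_factor``/``q_factor`` are the multiplicative factors applied to L/Q at
    full site occupancy; 1.0 is neutral.  Factors < 1 on L promote channel
    opening (PAM); factors < 1 on Q promote desensitization.
    """

    k_site: float  # molar
    l_factor: float = 1.0
    q_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.k_site <= 0:
            raise ValueError("site occupancy constant must be positive")
        if self.l_factor <= 0 or self.q_factor <= 0:
            raise ValueError("efficacy factors must be positive")


@dataclass(frozen=True)
class LigandEffectProfile:
    """Which sites a ligand occupies and what it does there.

    ``sites`` maps site names (subset of ``SITE_NAMES``) to ``SiteAction``;
    absent sites are not bound.
    """

    name: str
    sites: dict

    def __post_init__(self) -> None:
        unknown = set(self.sites) - set(SITE_NAMES)
        if unknown:
            raise ValueError(f"unknown site names: {sorted(unknown)}")


def _interp_factor(occ: float, saturating: float) -> float:
    # 1 at occ=0, `saturating` at occ=1; harmonic interpolation so the change
    # in 1/L or 1/Q is linear in occupancy
    return 1.0 / (1.0 + occ * (1.0 / saturating - 1.0))


def apply_ligand(
    params: rod.GatingParameters, profile: LigandEffectProfile, ligand_conc: float
) -> rod.GatingParameters:
    """Gating parameters in the presence of an allosteric ligand.

    L and Q are multiplied by the occupancy-weighted efficacy factor of each
    occupied site.  Zero concentration, absent sites, or all-neutral
    efficacies leave the parameters unchanged.
    """
    if ligand_conc < 0:
        raise ValueError("ligand concentration must be non-negative")
    if ligand_conc == 0 or not profile.sites:
        return params
    l_fac = 1.0
    q_fac = 1.0
    for action in profile.sites.values():
        occ = ligand_conc / (ligand_conc + action.k_site)
        l_fac *= _interp_factor(occ, action.l_factor)
        q_fac *= _interp_factor(occ, action.q_factor)
    new_q = params.q * q_fac if math.isfinite(params.q) else params.q
    return replace(params, L=params.L * l_fac, q=new_q)


def ligand_presets() -> dict:
    """Built-in qualitative site/efficacy profiles for the four study ligands.

    * allopregnanolone (3a5aP): binds all three sites; promotes opening via
      the intersubunit and alpha-intrasubunit sites and desensitization via
      the (lower-affinity) beta-intrasubunit site.
    * epi-allopregnanolone (3b5aP): intrasubunit sites only; promotes
      desensitization.  Per-site Q-factor 0.755 reproduces the measured
      Q -> Q* shift (0.1459 -> 0.0864) at 3 uM.
    * KK148: binds all three sites; desensitizing only (the intersubunit
      occupancy is state-independent).
    * KK150: binds all three sites with neutral efficacy everywhere — a
      competitive antagonist by site occlusion.
    """
    return {
        "3a5aP": LigandEffectProfile(
            "3a5aP",
            {
                "intersubunit": SiteAction(0.24e-6, l_factor=0.05),
                "alpha_intra": SiteAction(0.24e-6, l_factor=0.2),
                "beta_intra": SiteAction(2.4e-6, q_factor=0.59),
            },
        ),
        "3b5aP": LigandEffectProfile(
            "3b5aP",
            {
                "alpha_intra": SiteAction(0.25e-6, q_factor=0.755),
                "beta_intra": SiteAction(0.25e-6, q_factor=0.755),
            },
        ),
        "KK148": LigandEffectProfile(
            "KK148",
            {
                "intersubunit": SiteAction(2.4e-6),
                "alpha_intra": SiteAction(2.4e-6, q_factor=0.71),
                "beta_intra": SiteAction(2.4e-6, q_factor=0.71),
            },
        ),
        "KK150": LigandEffectProfile(
            "KK150",
            {
                "intersubunit": SiteAction(2.4e-6),
                "alpha_intra": SiteAction(2.4e-6),
                "beta_intra": SiteAction(2.4e-6),
            },
        ),
    }


@dataclass
class SimulationConfig:
    """Study conditions for the response generator.

    Defaults mirror the benchmark dataset: 1 mM GABA, peak P_open scatter
    SD 0.25 over 16 cells, steady-state scatter SD 0.033 over 7 control cells
    and SD 0.013 over 5 steroid-treated cells.
    """

    params: rod.GatingParameters = field(default_factory=rod.reference_parameters)
    agonist_concentration: float = 1e-3
    profile: LigandEffectProfile | None = None
    ligand_concentration: float = 0.0
    n_peak: int = 16
    n_steady: int = 7
    n_treated: int = 5
    sd_peak: float = 0.25
    sd_steady: float = 0.033
    sd_treated: float = 0.013
    seed: int = 0


def _truncnorm01(mean: float, sd: float, size: int, rng: np.random.Generator):
    if sd == 0:
        return np.full(size, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_responses(config: SimulationConfig) -> pd.DataFrame:
    """Per-cell open-probability table around the closed-form equilibrium values.

    Returns a tidy frame with columns ``cell``, ``condition`` ("control" or
    the ligand name), ``quantity`` ("peak" or "steady_state") and ``p_open``.
    Treated cells carry paired control and treated steady-state rows (each
    experiment serves as its own control).  Zero noise returns the closed-form
    values exactly.
    """
    rng = np.random.default_rng(config.seed)
    p = config.params
    lg = p.lgamma(config.agonist_concentration)
    peak_true = rod.popen_peak(lg)
    ss_true = rod.popen_steady_state(lg, p.q)
    rows = []
    for i, v in enumerate(_truncnorm01(peak_true, config.sd_peak, config.n_peak, rng)):
        rows.append(("peak%02d" % i, "control", "peak", float(v)))
    for i, v in enumerate(_truncnorm01(ss_true, config.sd_steady, config.n_steady, rng)):
        rows.append(("ss%02d" % i, "control", "steady_state", float(v)))
    if config.profile is not None and config.ligand_concentration > 0:
        treated = apply_ligand(p, config.profile, config.ligand_concentration)
        lg_t = treated.lgamma(config.agonist_concentration)
        ss_t_true = rod.popen_steady_state(lg_t, treated.q)
        ratio = ss_t_true / ss_true
        pre = _truncnorm01(ss_true, config.sd_treated, config.n_treated, rng)
        for i, v in enumerate(pre):
            cell = "pair%02d" % i
            rows.append((cell, "control", "steady_state", float(v)))
            rows.append((cell, config.profile.name, "steady_state", float(v * ratio)))
    return pd.DataFrame(rows, columns=["cell", "condition", "quantity", "p_open"])


def _rate_matrix(l_gamma: float, q: float, k_open: float, k_desens: float) -> np.ndarray:
    # states ordered (R, O, D); columns are source states of a linear ODE
    # dp/dt = A p.  Rate pairs are bounded (sums k_open, k_desens) with ratios
    # pinned to the equilibrium constants: R/O = l_gamma, O/D = q.
    k_ro = k_open / (1.0 + l_gamma)
    k_or = k_open - k_ro
    if math.isfinite(q):
        k_od = k_desens / (1.0 + q)
        k_do = k_desens - k_od
    else:
        k_od, k_do = 0.0, k_desens
    return np.array(
        [
            [-k_ro, k_or, 0.0],
            [k_ro, -(k_or + k_od), k_do],
            [0.0, k_od, -k_do],
        ]
    )


def simulate_trace(
    params: rod.GatingParameters,
    schedule,
    k_open: float = 500.0,
    k_desens: float = 0.5,
    dt: float = 1e-3,
    amplitude: float = 1.0,
) -> CurrentTrace:
    """Relaxing current trace from the kinetic three-state scheme.

    ``schedule`` is a list of ``(duration_s, agonist_concentration_M)``
    segments applied in order from a fully resting receptor.  Within each
    segment the occupancy vector is propagated exactly with the matrix
    exponential of the rate matrix, whose equilibrium matches the closed-form
    ROD occupancies at that concentration.  ``k_open``/``k_desens`` set the
    activation and desensitization relaxation rates (1/s); the equilibrium
    analysis is independent of them.  Current is ``amplitude * P_open(t)``
    (nA per unit open probability).

    Raises if ``dt`` is too coarse to resolve the fastest relaxation.
    """
    if k_open <= 0 or k_desens <= 0:
        raise ValueError("rate scales must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 0.5 / max(k_open, k_desens):
        raise ValueError(
            f"dt={dt} s too large to resolve relaxation at rate scale "
            f"{max(k_open, k_desens)} /s"
        )
    state = np.array([1.0, 0.0, 0.0])
    times = [0.0]
    popen = [0.0]
    t0 = 0.0
    for duration, conc in schedule:
        if duration <= 0:
            raise ValueError("segment durations must be positive")
        a = _rate_matrix(params.lgamma(conc), params.q, k_open, k_desens)
        step = expm(a * dt)
        n_steps = max(1, int(round(duration / dt)))
        for i in range(n_steps):
            state = step @ state
            times.append(t0 + (i + 1) * dt)
            popen.append(state[1])
        t0 += n_steps * dt
    return CurrentTrace(
        np.array(times), amplitude * np.array(popen), meta="synthetic ROD trace"
    )


def _steady_occupancy(params: rod.GatingParameters, x: float) -> rod.StateOccupancy:
    lg = params.lgamma(x)
    p_open = rod.popen_steady_state(lg, params.q) if math.isfinite(params.q) else rod.popen_peak(lg)
    p_rest = lg * p_open
    return rod.StateOccupancy(p_rest, p_open, max(1.0 - p_open - p_rest, 0.0))


def simulate_binding(
    kind: str,
    seed: int = 0,
    params: rod.GatingParameters | None = None,
    profile: LigandEffectProfile | None = None,
    affinities: StateAffinities = DEFAULT_STATE_AFFINITIES,
    tracer_concentration: float = 3e-9,
    b_max_cpm: float = 5000.0,
    nonspecific_cpm_per_nm: float = 10.0,
    counting_cv: float = 0.0,
    n_replicates: int = 3,
    # isotherm options
    isotherm_kd: float = 20e-9,
    isotherm_concentrations=None,
    # modulation options
    modulator_concentrations=None,
) -> pd.DataFrame:
    """Filtration-assay tables for the three assay designs.

    ``kind`` is ``"isotherm"`` or ``"modulation"``.

    * isotherm: total/nonspecific cpm over a 0.3 nM - 1 uM tracer grid from a
      single-site curve with apparent ``isotherm_kd`` plus a linear
      nonspecific component.  Zero noise round-trips exactly through
      ``fit_isotherm``.
    * modulation: percent-of-control curves generated mechanistically — the
      modulator profile reshapes L and Q, the ROD equilibrium reshapes state
      occupancies at the tracer concentration, and state-affinity-weighted
      binding gives the expected signal.

    Counting noise is multiplicative normal with CV ``counting_cv``
    (a Poisson-like approximation at the cpm scale used).
    """
    rng = np.random.default_rng(seed)

    def noisy(x):
        x = np.asarray(x, dtype=float)
        if counting_cv == 0:
            return x
        return x * (1.0 + counting_cv * rng.standard_normal(x.shape))

    if kind == "isotherm":
        conc = (
            np.geomspace(0.3e-9, 1e-6, 10)
            if isotherm_concentrations is None
            else np.asarray(isotherm_concentrations, dtype=float)
        )
        rows = []
        for rep in range(n_replicates):
            specific = b_max_cpm * conc / (isotherm_kd + conc)
            nonspecific = nonspecific_cpm_per_nm * conc * 1e9
            total = noisy(specific + nonspecific)
            ns_obs = noisy(nonspecific)
            for x, tot, ns in zip(conc, total, ns_obs):
                rows.append((x * 1e9, float(tot), float(ns), rep))
        return pd.DataFrame(
            rows, columns=["ligand_conc_nM", "total_cpm", "nonspecific_cpm", "replicate"]
        )

    if kind == "modulation":
        if profile is None:
            raise ValueError("modulation simulation needs a ligand profile")
        p = params if params is not None else rod.reference_parameters()
        conc = (
            np.geomspace(3e-9, 30e-6, 9)
            if modulator_concentrations is None
            else np.asarray(modulator_concentrations, dtype=float)
        )
        occ0 = _steady_occupancy(p, tracer_concentration)
        b0 = predict_fractional_binding(occ0, tracer_concentration, affinities)
        rows = []
        for rep in range(n_replicates):
            for c in conc:
                treated = apply_ligand(p, profile, float(c))
                occ = _steady_occupancy(treated, tracer_concentration)
                b = predict_fractional_binding(occ, tracer_concentration, affinities)
                value = noisy(100.0 * b / b0)
                rows.append((c * 1e6, float(value), rep))
        return pd.DataFrame(
            rows, columns=["modulator_conc_uM", "percent_of_control", "replicate"]
        )

    raise ValueError(f"unknown assay kind: {kind!r}")


def simulate_hill_curve(
    ec50: float,
    hill_slope: float,
    e_max: float,
    concentrations=None,
    cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Modulation table drawn directly from a Hill curve (for fit validation).

    Concentrations in molar (default 3 nM - 30 uM log grid); responses in
    percent of control with multiplicative noise of coefficient ``cv``.
    """
    rng = np.random.default_rng(seed)
    conc = (
        np.geomspace(3e-9, 30e-6, 9)
        if concentrations is None
        else np.asarray(concentrations, dtype=float)
    )
    cn = conc**hill_slope
    expected = 100.0 + (e_max - 100.0) * cn / (cn + ec50**hill_slope)
    rows = []
    for rep in range(n_replicates):
        values = expected * (1.0 + cv * rng.standard_normal(conc.shape)) if cv else expected
        for c, v in zip(conc, values):
            rows.append((c * 1e6, float(v), rep))
    return pd.DataFrame(
        rows, columns=["modulator_conc_uM", "percent_of_control", "replicate"]
    )


def simulate_timecourse(
    tau_min: float = 3.97,
    initial: float = 100.0,
    plateau: float = 200.0,
    times_min=(1.0, 3.0, 10.0, 30.0),
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Mono-exponential binding-enhancement time course (percent of control).

    Defaults emulate the slow onset of binding enhancement after adding a
    desensitizing steroid to membranes pre-equilibrated with tracer
    (time constant ~4 min at 4 C).  ``noise_sd`` is additive, in percent
    points, emulating per-point SEM-scale scatter.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times_min, dtype=float)
    expected = initial + (plateau - initial) * (1 - np.exp(-t / tau_min))
    rows = []
    for rep in range(n_replicates):
        values = expected + noise_sd * rng.standard_normal(t.shape) if noise_sd else expected
        for ti, v in zip(t, values):
            rows.append((float(ti), float(v), rep))
    return pd.DataFrame(rows, columns=["time_min", "percent_of_control", "replicate"])
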