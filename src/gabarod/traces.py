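"""Current-trace metrics: peak, steady state, open-probability conversion.

Two-electrode voltage-clamp traces of agonist-evoked currents are reduced to
the quantities the equilibrium analysis consumes: baseline-corrected peak and
steady-state amplitudes, open probabilities (by normalization to a reference
response defined to have P_open = 1), percent desensitization by a modulator,
and potentiation ratios at low agonist.

The interchange format is a two-column CSV (``time_s,current_nA``) plus a
window table (``label,t_start_s,t_end_s``).  Inward currents recorded at
negative holding potentials may be supplied with either sign; the baseline
step can flip the sign so evoked responses are positive magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CurrentTrace",
    "ApplicationWindow",
    "NormalizationReference",
    "baseline_subtract",
    "measure_peak",
    "measure_steady_state",
    "steady_state_window",
    "to_popen",
    "percent_desensitization",
    "potentiation_ratio",
]


@dataclass
class CurrentTrace:
    """Time-stamped current record (seconds, nanoamperes)."""

    time: np.ndarray
    current: np.ndarray
    meta: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.size < 2 or self.time.size != self.current.size:
            raise ValueError("trace needs >= 2 samples with matching time/current")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time base must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "CurrentTrace":
        df = pd.read_csv(path)
        missing = {"time_s", "current_nA"} - set(df.columns)
        if missing:
            raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
        return cls(df["time_s"].to_numpy(), df["current_nA"].to_numpy(), meta=str(path))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "current_nA": self.current}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class ApplicationWindow:
    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"window '{self.label}': t_start must precede t_end")


@dataclass(frozen=True)
class NormalizationReference:
    """Peak amplitude of the maximal reference response, defined as P_open = 1.

    In the benchmark protocol this is the peak response to 1 mM GABA + 50 uM
    propofol.
    """

    reference_peak: float
    label: str = "1 mM GABA + 50 uM propofol"

    def __post_init__(self) -> None:
        if not self.reference_peak > 0:
            raise ValueError("reference peak must be positive")


def read_windows(path) -> list[ApplicationWindow]:
    df = pd.read_csv(path)
    missing = {"label", "t_start_s", "t_end_s"} - set(df.columns)
    if missing:
        raise ValueError(f"window CSV missing columns: {sorted(missing)}")
    return [
        ApplicationWindow(str(r.label), float(r.t_start_s), float(r.t_end_s))
        for r in df.itertuples()
    ]


def _window_mask(trace: CurrentTrace, window: ApplicationWindow) -> np.ndarray:
    mask = (trace.time >= window.t_start) & (trace.time <= window.t_end)
    if not mask.any():
        raise ValueError(
            f"window '{window.label}' [{window.t_start}, {window.t_end}] s "
            "contains no samples"
        )
    return mask


def baseline_subtract(
    trace: CurrentTrace,
    pre_window: ApplicationWindow,
    flip_sign: bool | None = None,
) -> CurrentTrace:
    """Subtract the mean pre-application current; orient the response positive.

    ``flip_sign=None`` flips automatically when the largest post-baseline
    excursion is negative (inward current convention).
    """
    mask = _window_mask(trace, pre_window)
    corrected = trace.current - float(trace.current[mask].mean())
    if flip_sign is None:
        flip_sign = abs(corrected.min()) > abs(corrected.max())
    if flip_sign:
        corrected = -corrected
    return CurrentTrace(trace.time.copy(), corrected, meta=trace.meta)


def measure_peak(
    trace: CurrentTrace, window: ApplicationWindow, smooth_width: float = 0.0
) -> float:
    """Maximum current in the window, after optional moving-average smoothing.

    ``smooth_width`` is in seconds; 0 means the raw maximum.
    """
    mask = _window_mask(trace, window)
    y = trace.current
    if smooth_width > 0:
        dt = float(np.median(np.diff(trace.time)))
        k = max(1, int(round(smooth_width / dt)))
        if k > 1:
            y = np.convolve(y, np.ones(k) / k, mode="same")
    return float(y[mask].max())


def measure_steady_state(trace: CurrentTrace, window: ApplicationWindow) -> float:
    """Mean current over a late window of a sustained application."""
    mask = _window_mask(trace, window)
    return float(trace.current[mask].mean())


def steady_state_window(
    application: ApplicationWindow, fraction: float = 0.1
) -> ApplicationWindow:
    """Default steady-state window: the final ``fraction`` of the application."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    span = application.t_end - application.t_start
    return ApplicationWindow(
        f"{application.label}:steady_state",
        application.t_end - fraction * span,
        application.t_end,
    )


def to_popen(amplitude: float, ref: NormalizationReference) -> float:
    """Convert an amplitude to open probability by reference normalization.

    Amplitudes exceeding the reference by <= 2% (measurement scatter) are
    clipped to 1 with a warning; larger excesses are an error.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    p = amplitude / ref.reference_peak
    if p > 1.02:
        raise ValueError(
            f"amplitude {amplitude} exceeds the reference {ref.reference_peak} "
            "by more than 2%; check the normalization"
        )
    if p > 1.0:
        warnings.warn(
            f"amplitude exceeds reference by {(p - 1) * 100:.2f}%; clipping P_open to 1",
            stacklevel=2,
        )
        p = 1.0
    return p


def percent_desensitization(ss_baseline: float, ss_with_modulator: float) -> float:
    """Percent reduction of the steady-state current by a modulator.

    The baseline steady-state current (e.g. at 1 mM GABA) defines 100%.
    """
    if ss_baseline <= 0:
        raise ValueError("baseline steady-state current must be positive")
    if ss_with_modulator < 0:
        raise ValueError("steady-state current must be non-negative")
    return 100.0 * (1.0 - ss_with_modulator / ss_baseline)


def potentiation_ratio(peak_gaba: float, peak_gaba_plus_modulator: float) -> float:
    """Ratio of peak responses with/without a co-applied modulator.

    Measured at low agonist (P_open ~ 0.05-0.1) where potentiation has dynamic
    range; a ratio near 1 indicates no potentiation.
    """
    if peak_gaba <= 0:
        raise ValueError("peak response to agonist alone must be positive")
    return peak_gaba_plus_modulator / peak_gaba
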