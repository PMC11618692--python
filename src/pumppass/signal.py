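"""Barotrauma-sensor pressure-trace processing.

A barotrauma detection sensor (BDS) is a neutrally buoyant cylinder that logs
total water pressure on three channels at 100 Hz while it passes through a
pump. This module turns one raw three-channel trace into the three
pressure-based barotrauma parameters used to rate decompression risk:

* **nadir** — the minimum total pressure during passage (hPa), reached at the
  impeller;
* **LRP** — log ratio pressure change, ``ln(acclimation / nadir)`` with the
  acclimation pressure taken as 1000 hPa;
* **ROC** — the maximal rate of pressure change (hPa/s) in the immediate
  vicinity of the nadir.

Detection follows a fixed recipe: the injection into the pump inlet is the
first reading above 1005 hPa; the pump-passage nadir is searched 3–75 s after
injection on a Savitzky–Golay smoothed (order 2, window 11) channel average,
keeping only samples whose smoothed pressure changes by more than 20 hPa
within 0.1 s; control (no-pump) drifts take the raw minimum 5–75 s after
injection. Passage profiles are landmark-registered onto a normalized [0, 1]
time axis with the nadir pinned at 0.5 so that deployments of different
duration can be averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import (
    AllChannelsInvalid,
    BadWindow,
    EmptyScenario,
    InvalidMarks,
    NoExit,
    NoInjection,
    NoNadir,
    NonPositivePressure,
    SignalError,
)

__all__ = [
    "DeploymentMeta",
    "PressureTrace",
    "PassageMarks",
    "BarotraumaParams",
    "NormalizedTrace",
    "remove_outlier_channels",
    "mean_pressure",
    "detect_injection",
    "smooth_sg",
    "detect_nadir",
    "detect_exit",
    "compute_lrp",
    "compute_roc",
    "normalize_time",
    "ensemble_stats",
    "PassageModel",
    "PassageResult",
]

#: Channels whose mean pressure reaches this value are dead/railed sensors.
OUTLIER_CHANNEL_HPA = 1.0e5
#: First reading above this pressure marks the injection into the inlet.
INJECTION_THRESHOLD_HPA = 1005.0
#: Minimum absolute smoothed-pressure change that qualifies a nadir candidate.
NADIR_CHANGE_HPA = 20.0
#: Detection horizon for the change criterion (s); lags strictly below this.
NADIR_CHANGE_HORIZON_S = 0.1
#: Nadir search window relative to injection, pump passage (s).
PUMP_NADIR_WINDOW_S = (3.0, 75.0)
#: Nadir search window relative to injection, control drift (s).
CONTROL_NADIR_WINDOW_S = (5.0, 75.0)


@dataclass(frozen=True)
class DeploymentMeta:
    """Deployment-level metadata for one sensor run.

    ``pump`` is ``"FNAFP"`` (the fish-friendly axial flow pump), ``"CAFP"``
    (the conventional axial flow pump) or ``"control"`` (surface drift without
    pump passage). ``rpm`` must be present exactly when the deployment passed
    a pump. ``acclimation_hpa`` is the reference pressure the fish are assumed
    acclimated to (1000 hPa, roughly atmospheric at the surface).
    """

    pump: str = "FNAFP"
    rpm: int | None = 468
    sensor_id: str = "BDS-0"
    water_temp_c: float = 4.5
    acclimation_hpa: float = 1000.0
    fs: float = 100.0
    #: index (0-based) of the center channel, flanked by left/right channels
    center_channel: int = 0
    #: optional manually identified exit time (s), honoured by detect_exit
    manual_exit_s: float | None = None

    def __post_init__(self) -> None:
        if self.pump not in ("FNAFP", "CAFP", "control"):
            raise ValueError(f"unknown pump type {self.pump!r}")
        if self.pump == "control" and self.rpm is not None:
            raise ValueError("control deployments carry no rpm")
        if self.pump != "control" and self.rpm is None:
            raise ValueError("pump deployments require an rpm")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def scenario(self) -> str:
        """Scenario label, e.g. ``FNAFP_468`` or ``control_468``."""
        return self.pump if self.rpm is None else f"{self.pump}_{self.rpm}"


@dataclass
class PressureTrace:
    """Three synchronized pressure channels on a uniform time grid (hPa)."""

    time: np.ndarray
    channels: np.ndarray  # shape (n_channels, n_samples)
    meta: DeploymentMeta = field(default_factory=DeploymentMeta)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.channels.shape[1] != self.time.size:
            raise SignalError("channel length does not match time grid")
        dt = np.diff(self.time)
        if self.time.size > 1 and (
            np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9)
        ):
            raise SignalError("time grid must be strictly increasing and uniform")

    @property
    def fs(self) -> float:
        return self.meta.fs

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class PassageMarks:
    """Landmark times of one passage: injection, nadir and exit (s)."""

    t_injection: float
    t_nadir: float
    t_exit: float
    nadir_pressure: float

    def __post_init__(self) -> None:
        if not (self.t_injection < self.t_nadir < self.t_exit):
            raise InvalidMarks(
                f"marks must satisfy injection < nadir < exit, got "
                f"({self.t_injection}, {self.t_nadir}, {self.t_exit})"
            )


@dataclass(frozen=True)
class BarotraumaParams:
    """Per-deployment barotrauma parameters."""

    nadir: float  # hPa
    lrp: float  # dimensionless, ln(acclimation / nadir)
    roc: float  # hPa/s, >= 0
    marks: PassageMarks


@dataclass(frozen=True)
class NormalizedTrace:
    """Pressure profile on normalized passage time.

    ``u`` runs from 0 (injection) to 1 (exit) with the nadir pinned at 0.5;
    500 equally spaced points between injection and nadir, 500 between nadir
    and exit, plus the injection endpoint: 1001 points in total.
    """

    u: np.ndarray
    p: np.ndarray


def remove_outlier_channels(
    trace: PressureTrace, threshold: float = OUTLIER_CHANNEL_HPA
) -> PressureTrace:
    """Drop railed sensor channels before averaging.

    A channel whose mean pressure equals or exceeds ``threshold`` (1e5 hPa)
    is a failed sensor reporting its rail value and is removed.

    Raises
    ------
    AllChannelsInvalid
        If every channel is an outlier.
    """
    means = trace.channels.mean(axis=1)
    keep = means < threshold
    if not keep.any():
        raise AllChannelsInvalid(
            f"all {trace.n_channels} channels have mean pressure >= {threshold:g} hPa"
        )
    if keep.all():
        return trace
    return replace(trace, channels=trace.channels[keep])


def mean_pressure(trace: PressureTrace) -> np.ndarray:
    """Pointwise mean pressure over the surviving channels (hPa)."""
    return trace.channels.mean(axis=0)


def detect_injection(
    p: np.ndarray, fs: float, threshold: float = INJECTION_THRESHOLD_HPA
) -> float:
    """Time of the first reading exceeding the injection threshold (s).

    Raises :class:`NoInjection` if the trace never exceeds ``threshold``.
    """
    p = np.asarray(p, dtype=float)
    above = np.flatnonzero(p > threshold)
    if above.size == 0:
        raise NoInjection(f"pressure never exceeds {threshold:g} hPa")
    return float(above[0]) / fs


def smooth_sg(p: np.ndarray, order: int = 2, window: int = 11) -> np.ndarray:
    """Savitzky–Golay smoothing (default: 2nd-order polynomial, 11 samples)."""
    p = np.asarray(p, dtype=float)
    if window % 2 == 0 or window <= order:
        raise BadWindow(f"window must be odd and > order, got {window} (order {order})")
    if p.size < window:
        raise BadWindow(f"series of length {p.size} shorter than window {window}")
    return savgol_filter(p, window_length=window, polyorder=order)


def _candidate_mask(sp: np.ndarray, fs: float, change: float, horizon_s: float) -> np.ndarray:
    """Samples whose smoothed pressure changes by > ``change`` within the horizon.

    A sample qualifies when |sp[i] - sp[i - k]| > change for any positive lag
    k with k/fs < horizon_s (lags strictly below the detection horizon).
    """
    mask = np.zeros(sp.size, dtype=bool)
    max_lag = int(np.ceil(horizon_s * fs)) - 1  # k/fs < horizon_s
    for k in range(1, max_lag + 1):
        d = np.abs(sp[k:] - sp[:-k]) > change
        mask[k:] |= d
        mask[:-k] |= d  # the change also qualifies the earlier endpoint
    return mask


def detect_nadir(
    p: np.ndarray,
    t_injection: float,
    fs: float,
    mode: Literal["pump", "control"] = "pump",
    *,
    change_threshold: float = NADIR_CHANGE_HPA,
    horizon_s: float = NADIR_CHANGE_HORIZON_S,
    sg_order: int = 2,
    sg_window: int = 11,
) -> tuple[float, float]:
    """Locate the pressure nadir after injection.

    Pump passage: the smoothed (Savitzky–Golay) channel average is searched
    3–75 s after injection; only samples where the smoothed pressure changes
    by more than 20 hPa within 0.1 s qualify, and the lowest qualifying
    smoothed value is the nadir. Control drifts have no impeller transient:
    the raw minimum 5–75 s after injection is taken, without smoothing.

    Returns ``(t_nadir, nadir_pressure)``.
    """
    p = np.asarray(p, dtype=float)
    if mode == "control":
        lo, hi = CONTROL_NADIR_WINDOW_S
        i0 = int(np.ceil((t_injection + lo) * fs))
        i1 = min(int(np.floor((t_injection + hi) * fs)), p.size - 1)
        if i1 < i0:
            raise NoNadir("control search window is empty")
        seg = p[i0 : i1 + 1]
        j = int(np.argmin(seg))
        return (i0 + j) / fs, float(seg[j])

    sp = smooth_sg(p, order=sg_order, window=sg_window)
    lo, hi = PUMP_NADIR_WINDOW_S
    i0 = int(np.ceil((t_injection + lo) * fs))
    i1 = min(int(np.floor((t_injection + hi) * fs)), p.size - 1)
    if i1 < i0:
        raise NoNadir("pump search window is empty")
    mask = _candidate_mask(sp, fs, change_threshold, horizon_s)
    mask[:i0] = False
    mask[i1 + 1 :] = False
    if not mask.any():
        raise NoNadir(
            f"no sample changes by > {change_threshold:g} hPa within "
            f"{horizon_s:g} s in the search window"
        )
    idx = np.flatnonzero(mask)
    j = idx[int(np.argmin(sp[idx]))]
    return float(j) / fs, float(sp[j])


def detect_exit(
    p: np.ndarray,
    t_nadir: float,
    fs: float,
    *,
    manual_exit_s: float | None = None,
    band_hpa: float = 5.0,
    dwell_s: float = 1.0,
    tail_s: float = 1.0,
    sg_order: int = 2,
    sg_window: int = 11,
) -> float:
    """Exit to the tailwater: first post-nadir settling onto the end plateau.

    The terminal plateau level is the median of the last ``tail_s`` seconds of
    the smoothed series; the exit is the first time after the nadir from which
    the smoothed series stays within ``band_hpa`` of that level for at least
    ``dwell_s`` seconds. A manually identified exit time, when supplied,
    always wins (region-of-interest marking in the field is visual).
    """
    if manual_exit_s is not None:
        return float(manual_exit_s)
    p = np.asarray(p, dtype=float)
    sp = smooth_sg(p, order=sg_order, window=sg_window)
    n = sp.size
    tail = max(int(tail_s * fs), 1)
    plateau = float(np.median(sp[-tail:]))
    dwell = max(int(dwell_s * fs), 1)
    start = int(np.floor(t_nadir * fs)) + 1
    inside = np.abs(sp - plateau) <= band_hpa
    # first index >= start from which `inside` holds for `dwell` samples
    run = 0
    for i in range(start, n):
        run = run + 1 if inside[i] else 0
        if run >= dwell:
            return float(i - dwell + 1) / fs
    if inside[start:].all() and n - start > 0:
        return float(start) / fs
    raise NoExit("no terminal plateau of the required dwell found after the nadir")


def compute_lrp(nadir: float, acclimation: float = 1000.0) -> float:
    """Log ratio pressure change, ``ln(acclimation / nadir)`` (dimensionless).

    Larger LRP means a deeper decompression relative to the acclimation
    pressure and a higher barotrauma risk.
    """
    if nadir <= 0 or acclimation <= 0:
        raise NonPositivePressure(
            f"nadir and acclimation must be positive, got ({nadir}, {acclimation})"
        )
    return float(np.log(acclimation / nadir))


def compute_roc(
    p: np.ndarray,
    marks: PassageMarks,
    fs: float,
    *,
    half_window_s: float = 0.5,
    sg_order: int = 2,
    sg_window: int = 11,
) -> float:
    """Maximal rate of pressure change near the nadir (hPa/s, >= 0).

    The maximum absolute one-sample rate ``|dP|·fs`` of the smoothed series
    within ``nadir ± half_window_s``; the decompression transient at the
    impeller lives in this neighbourhood.
    """
    p = np.asarray(p, dtype=float)
    sp = smooth_sg(p, order=sg_order, window=sg_window) if p.size >= sg_window else p
    i0 = max(int(np.floor((marks.t_nadir - half_window_s) * fs)), 0)
    i1 = min(int(np.ceil((marks.t_nadir + half_window_s) * fs)), p.size - 1)
    seg = sp[i0 : i1 + 1]
    if seg.size < 2:
        return 0.0
    return float(np.max(np.abs(np.diff(seg))) * fs)


def normalize_time(
    p: np.ndarray, marks: PassageMarks, fs: float, n_half: int = 500
) -> NormalizedTrace:
    """Landmark-register a passage onto normalized time [0, 1].

    Linear registration maps injection → 0, nadir → 0.5, exit → 1, with
    ``n_half`` equally spaced points on each half-interval (plus the
    injection endpoint). Pressures are linearly interpolated from the
    original grid, so the profile is invariant to uniform time rescaling.
    """
    p = np.asarray(p, dtype=float)
    t = np.arange(p.size) / fs
    if not (t[0] <= marks.t_injection and marks.t_exit <= t[-1]):
        raise InvalidMarks("marks fall outside the trace")
    t_first = np.linspace(marks.t_injection, marks.t_nadir, n_half + 1)
    t_second = np.linspace(marks.t_nadir, marks.t_exit, n_half + 1)[1:]
    t_grid = np.concatenate([t_first, t_second])
    u = np.concatenate(
        [np.linspace(0.0, 0.5, n_half + 1), np.linspace(0.5, 1.0, n_half + 1)[1:]]
    )
    prof = np.interp(t_grid, t, p)
    # the midpoint is the detected nadir by definition (the detected value can
    # come from the smoothed series, so pin it rather than re-interpolate)
    prof[n_half] = marks.nadir_pressure
    return NormalizedTrace(u=u, p=prof)


def ensemble_stats(
    params: Iterable[BarotraumaParams] | pd.DataFrame,
    scenarios: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-scenario ensemble mean ± SD of nadir, LRP and ROC.

    Accepts either a DataFrame with columns ``scenario, nadir, lrp, roc`` or
    an iterable of :class:`BarotraumaParams` plus a parallel ``scenarios``
    sequence. SD uses the sample convention (ddof=1) and is reported as NaN
    (not 0) for single-deployment scenarios, to avoid implying precision.
    """
    if isinstance(params, pd.DataFrame):
        df = params
    else:
        rows = list(params)
        if scenarios is None or len(rows) != len(scenarios):
            raise ValueError("scenarios must parallel the params list")
        df = pd.DataFrame(
            {
                "scenario": list(scenarios),
                "nadir": [r.nadir for r in rows],
                "lrp": [r.lrp for r in rows],
                "roc": [r.roc for r in rows],
            }
        )
    if df.empty:
        raise EmptyScenario("no deployments supplied")
    g = df.groupby("scenario")[["nadir", "lrp", "roc"]]
    out = g.agg(["mean", "std", "count"])
    out.columns = [f"{a}_{b}" for a, b in out.columns]
    out = out.rename(columns={c: c.replace("_count", "_n") for c in out.columns})
    out["n"] = out.pop("nadir_n").astype(int)
    return out.drop(columns=[c for c in out.columns if c.endswith("_n")])


class PassageModel:
    """End-to-end processing of one deployment trace.

    Statsmodels-flavoured wrapper: construct from a :class:`PressureTrace`
    (or via :meth:`from_dataframe`), call :meth:`fit` to run outlier-channel
    removal, channel averaging, landmark detection and parameter extraction,
    and receive a :class:`PassageResult`.
    """

    def __init__(self, trace: PressureTrace):
        self.trace = trace

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, meta: DeploymentMeta | None = None
    ) -> "PassageModel":
        """Build from a deployment table with columns ``time_s, p1_hPa, ...``."""
        pcols = [c for c in df.columns if c != "time_s"]
        return cls(
            PressureTrace(
                time=df["time_s"].to_numpy(),
                channels=df[pcols].to_numpy().T,
                meta=meta or DeploymentMeta(),
            )
        )

    def fit(self) -> "PassageResult":
        meta = self.trace.meta
        clean = remove_outlier_channels(self.trace)
        p = mean_pressure(clean)
        fs = meta.fs
        t_inj = detect_injection(p, fs)
        mode = "control" if meta.pump == "control" else "pump"
        t_nad, nadir = detect_nadir(p, t_inj, fs, mode=mode)
        t_exit = detect_exit(p, t_nad, fs, manual_exit_s=meta.manual_exit_s)
        marks = PassageMarks(t_inj, t_nad, t_exit, nadir)
        params = BarotraumaParams(
            nadir=nadir,
            lrp=compute_lrp(nadir, meta.acclimation_hpa),
            roc=compute_roc(p, marks, fs),
            marks=marks,
        )
        return PassageResult(
            params=params,
            normalized=normalize_time(p, marks, fs),
            mean_series=p,
            trace=clean,
        )


@dataclass
class PassageResult:
    """Fitted passage: barotrauma parameters, marks and normalized profile."""

    params: BarotraumaParams
    normalized: NormalizedTrace
    mean_series: np.ndarray
    trace: PressureTrace

    def summary(self) -> str:
        m = self.params.marks
        meta = self.trace.meta
        lines = [
            "Passage summary",
            "===============",
            f"scenario       : {meta.scenario} (sensor {meta.sensor_id})",
            f"t_injection    : {m.t_injection:8.2f} s",
            f"t_nadir        : {m.t_nadir:8.2f} s",
            f"t_exit         : {m.t_exit:8.2f} s",
            f"nadir          : {self.params.nadir:8.1f} hPa",
            f"LRP            : {self.params.lrp:8.4f} (-)",
            f"ROC            : {self.params.roc:8.1f} hPa/s",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the normalized passage profile (injection→nadir→exit)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.normalized.u, self.normalized.p)
        ax.axvline(0.5, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("normalized passage time (nadir at 0.5)")
        ax.set_ylabel("pressure (hPa)")
        return ax
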