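"""Single-fiber physiology: indo-1 calibration, force and calcium summaries.

Intact fast-twitch fibers are stimulated with 350-ms tetani while force and
the indo-1 emission ratio R = F405/F495 are recorded.  The ratio converts to
myoplasmic free calcium through the saturation-binding calibration

    [Ca2+]_i = K_D * beta * (R - R_min) / (R_max - R)

with K_D the apparent dissociation constant of the dye, beta the ratio of the
495-nm signals at very low and saturating calcium, and R_min / R_max the
ratios at those two extremes.  Downstream summaries are per-tetanus peak
force (normalized to fiber cross-sectional area as specific force),
plateau tetanic calcium, force/calcium-frequency curves, fatigue series
expressed as percent of the first contraction, and paired caffeine-probe
comparisons of tetanic calcium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationParams",
    "FiberTrace",
    "StimulationProtocol",
    "ratio_to_calcium",
    "calcium_to_ratio",
    "tetanic_peaks",
    "specific_force",
    "frequency_curves",
    "fatigue_summary",
    "caffeine_probe",
    "hill_force",
    "fit_hill",
]

#: 1 mN/um^2 expressed in kN/m^2.
MN_PER_UM2_TO_KN_PER_M2 = 1e6


@dataclass(frozen=True)
class CalibrationParams:
    """Indo-1 calibration constants.

    These are fiber-rig calibration results and must be supplied by the user;
    no defaults are baked in.

    Attributes
    ----------
    kd_um : apparent dissociation constant of the dye, in uM.
    beta : ratio of the 495-nm signals at very low vs saturating calcium.
    r_min, r_max : 405/495 ratios at very low and saturating calcium.
    """

    kd_um: float
    beta: float
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if not (self.kd_um > 0 and self.beta > 0):
            raise ValueError("K_D and beta must be positive")
        if not self.r_min < self.r_max:
            raise ValueError("R_min must be below R_max")


@dataclass(frozen=True)
class StimulationProtocol:
    """Stimulation schedule of a fiber experiment.

    ``frequency_sweep`` delivers one tetanus per frequency (study protocol:
    15-150 Hz, 350-ms tetani, 1-min intervals); ``fatigue`` repeats a single
    frequency (study protocol: 70 Hz, 350-ms tetani, 2-s intervals, 50
    contractions).
    """

    mode: str
    frequencies_hz: tuple[float, ...]
    tetanus_duration_ms: float = 350.0
    interval_s: float = 60.0
    n_contractions: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("frequency_sweep", "fatigue"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.tetanus_duration_ms <= 0:
            raise ValueError("tetanus duration must be positive")
        if self.interval_s * 1000.0 <= self.tetanus_duration_ms:
            raise ValueError("inter-tetanus interval must exceed tetanus duration")
        if not self.frequencies_hz:
            raise ValueError("at least one stimulation frequency required")

    @classmethod
    def frequency_sweep(
        cls,
        frequencies_hz: Sequence[float] = (15, 20, 30, 50, 70, 100, 150),
        tetanus_duration_ms: float = 350.0,
        interval_s: float = 60.0,
    ) -> "StimulationProtocol":
        return cls(
            mode="frequency_sweep",
            frequencies_hz=tuple(float(f) for f in frequencies_hz),
            tetanus_duration_ms=tetanus_duration_ms,
            interval_s=interval_s,
        )

    @classmethod
    def fatigue(
        cls,
        frequency_hz: float = 70.0,
        tetanus_duration_ms: float = 350.0,
        interval_s: float = 2.0,
        n_contractions: int = 50,
    ) -> "StimulationProtocol":
        return cls(
            mode="fatigue",
            frequencies_hz=(float(frequency_hz),),
            tetanus_duration_ms=tetanus_duration_ms,
            interval_s=interval_s,
            n_contractions=n_contractions,
        )

    @property
    def window_frequencies(self) -> tuple[float, ...]:
        if self.mode == "fatigue":
            return self.frequencies_hz * self.n_contractions
        return self.frequencies_hz


@dataclass
class FiberTrace:
    """Recorded fiber signals plus stimulation-window annotations.

    ``windows`` has one row per tetanus with columns ``start_s``, ``end_s``
    and ``frequency_hz``.  ``ratio`` and ``force_mn`` are optional (a trace
    may carry either or both signals).
    """

    fiber_id: str
    time_s: np.ndarray
    ratio: np.ndarray | None = None
    force_mn: np.ndarray | None = None
    csa_um2: float | None = None
    windows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        if t.ndim != 1 or not np.all(np.diff(t) > 0):
            raise ValueError("time must be 1-D and strictly increasing")
        self.time_s = t
        for name in ("ratio", "force_mn"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != t.shape:
                    raise ValueError(f"{name} must match the time vector")
                setattr(self, name, v)
        if self.csa_um2 is not None and self.csa_um2 <= 0:
            raise ValueError("cross-sectional area must be positive")


def ratio_to_calcium(
    r: np.ndarray | float, params: CalibrationParams, clip: bool = False
) -> np.ndarray | float:
    """Convert the 405/495 emission ratio to [Ca2+]_i in uM.

    Applies ``K_D*beta*(R - R_min)/(R_max - R)`` elementwise; strictly
    increasing in R on (R_min, R_max).  Ratios outside the open calibration
    interval raise (a calibration breach should be visible, not hidden);
    ``clip=True`` instead clips R marginally inside the interval.
    """
    arr = np.asarray(r, dtype=float)
    if clip:
        eps = 1e-9 * (params.r_max - params.r_min)
        arr = np.clip(arr, params.r_min + eps, params.r_max - eps)
    elif np.any(arr <= params.r_min) or np.any(arr >= params.r_max):
        raise ValueError("ratio outside the open calibration interval (R_min, R_max)")
    ca = params.kd_um * params.beta * (arr - params.r_min) / (params.r_max - arr)
    return float(ca) if np.isscalar(r) else ca


def calcium_to_ratio(
    ca: np.ndarray | float, params: CalibrationParams
) -> np.ndarray | float:
    """Exact algebraic inverse of :func:`ratio_to_calcium`.

    ``R = (R_min + x*R_max)/(1 + x)`` with ``x = ca/(K_D*beta)``; maps 0 to
    R_min and approaches R_max as calcium saturates.
    """
    arr = np.asarray(ca, dtype=float)
    if np.any(arr < 0):
        raise ValueError("calcium concentration must be non-negative")
    x = arr / (params.kd_um * params.beta)
    r = (params.r_min + x * params.r_max) / (1.0 + x)
    return float(r) if np.isscalar(ca) else r


def _window_slice(trace: FiberTrace, start: float, end: float) -> np.ndarray:
    mask = (trace.time_s >= start) & (trace.time_s <= end)
    if not mask.any():
        raise ValueError(f"stimulation window [{start}, {end}] contains no samples")
    return mask


def tetanic_peaks(
    trace: FiberTrace, params: CalibrationParams | None = None
) -> pd.DataFrame:
    """Per-tetanus peak force and plateau tetanic calcium.

    Peak force is the maximum force inside each annotated window.  Tetanic
    [Ca2+]_i is the mean calibrated signal over the final third of the window,
    a plateau estimate robust to onset kinetics (requires ``params`` and a
    ratio channel).
    """
    if trace.windows.empty:
        raise ValueError("trace has no stimulation windows annotated")
    rows = []
    for i, w in enumerate(trace.windows.itertuples(index=False)):
        mask = _window_slice(trace, w.start_s, w.end_s)
        rec: dict[str, float] = {
            "window": i,
            "frequency_hz": w.frequency_hz,
            "start_s": w.start_s,
            "end_s": w.end_s,
        }
        if trace.force_mn is not None:
            rec["peak_force_mn"] = float(trace.force_mn[mask].max())
        if trace.ratio is not None and params is not None:
            plateau_start = w.end_s - (w.end_s - w.start_s) / 3.0
            pmask = _window_slice(trace, plateau_start, w.end_s)
            ca = ratio_to_calcium(trace.ratio[pmask], params)
            rec["tetanic_ca_um"] = float(np.mean(ca))
        rows.append(rec)
    return pd.DataFrame(rows)


def specific_force(peak_force_mn: float, csa_um2: float) -> float:
    """Peak force normalized to cross-sectional area, in kN/m^2.

    1 mN/um^2 equals 1e6 kN/m^2, so 0.3 mN over 1500 um^2 gives 200 kN/m^2.
    """
    if csa_um2 <= 0:
        raise ValueError("cross-sectional area must be positive")
    return peak_force_mn / csa_um2 * MN_PER_UM2_TO_KN_PER_M2


def hill_force(ca_um: np.ndarray, f_max: float, ca50_um: float, n_h: float) -> np.ndarray:
    """Phenomenological Hill force-calcium relation ``F = Fmax*ca^n/(ca^n + ca50^n)``."""
    ca = np.asarray(ca_um, dtype=float)
    return f_max * ca**n_h / (ca**n_h + ca50_um**n_h)


def fit_hill(
    ca_um: np.ndarray, force: np.ndarray, p0: tuple[float, float, float] | None = None
) -> dict[str, float]:
    """Least-squares fit of the Hill force-calcium relation.

    Returns ``f_max``, ``ca50_um`` (half-activation calcium) and ``n_h``.
    """
    ca = np.asarray(ca_um, dtype=float)
    f = np.asarray(force, dtype=float)
    if p0 is None:
        p0 = (float(f.max()), float(np.median(ca)), 3.0)
    popt, _ = curve_fit(hill_force, ca, f, p0=p0, maxfev=20000)
    return {"f_max": float(popt[0]), "ca50_um": float(popt[1]), "n_h": float(popt[2])}


def frequency_curves(
    traces: Iterable[FiberTrace], params: CalibrationParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Force-frequency and calcium-frequency relations over a fiber collection.

    Per fiber and frequency: peak force, specific force (when CSA is known)
    and plateau tetanic calcium.  The summary table averages fibers per
    frequency with standard errors.  Duplicated frequencies within one fiber
    are an error (the sweep delivers one tetanus per frequency).
    """
    per_fiber_rows = []
    for trace in traces:
        peaks = tetanic_peaks(trace, params)
        if peaks["frequency_hz"].duplicated().any():
            raise ValueError(f"fiber {trace.fiber_id!r}: duplicated frequency labels")
        for rec in peaks.to_dict("records"):
            row = {"fiber_id": trace.fiber_id, "frequency_hz": rec["frequency_hz"]}
            if "peak_force_mn" in rec:
                row["peak_force_mn"] = rec["peak_force_mn"]
                if trace.csa_um2 is not None:
                    row["specific_force_kn_m2"] = specific_force(
                        rec["peak_force_mn"], trace.csa_um2
                    )
            if "tetanic_ca_um" in rec:
                row["tetanic_ca_um"] = rec["tetanic_ca_um"]
            per_fiber_rows.append(row)
    if not per_fiber_rows:
        raise ValueError("no fiber traces supplied")
    per_fiber = pd.DataFrame(per_fiber_rows).sort_values(
        ["fiber_id", "frequency_hz"], kind="mergesort"
    )

    value_cols = [
        c
        for c in ("peak_force_mn", "specific_force_kn_m2", "tetanic_ca_um")
        if c in per_fiber.columns
    ]
    grouped = per_fiber.groupby("frequency_hz")[value_cols]
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem(ddof=1).add_suffix("_sem")
    n = grouped.size().rename("n_fibers")
    summary = pd.concat([mean, sem, n], axis=1).reset_index()
    return per_fiber.reset_index(drop=True), summary


def fatigue_summary(
    trace: FiberTrace,
    protocol: StimulationProtocol,
    params: CalibrationParams | None = None,
) -> pd.DataFrame:
    """Per-contraction force (and calcium) as percent of the first contraction.

    The fatigue protocol delivers ``n_contractions`` identical tetani; the
    summary is ``p_i = 100 * peak_i / peak_1``, so the first contraction is
    100 by construction.  Missing contraction windows are an error — gaps are
    never silently filled.
    """
    if protocol.mode != "fatigue":
        raise ValueError("fatigue_summary requires a fatigue protocol")
    if len(trace.windows) != protocol.n_contractions:
        raise ValueError(
            f"expected {protocol.n_contractions} contraction windows, "
            f"found {len(trace.windows)}"
        )
    peaks = tetanic_peaks(trace, params)
    out = pd.DataFrame({"contraction": np.arange(1, len(peaks) + 1)})
    if "peak_force_mn" in peaks.columns:
        first = peaks["peak_force_mn"].iloc[0]
        if first == 0:
            raise ValueError("zero first-contraction peak force")
        out["peak_force_mn"] = peaks["peak_force_mn"].to_numpy()
        out["pct_force"] = 100.0 * peaks["peak_force_mn"].to_numpy() / first
    if "tetanic_ca_um" in peaks.columns:
        first_ca = peaks["tetanic_ca_um"].iloc[0]
        if first_ca == 0:
            raise ValueError("zero first-contraction tetanic calcium")
        out["tetanic_ca_um"] = peaks["tetanic_ca_um"].to_numpy()
        out["pct_ca"] = 100.0 * peaks["tetanic_ca_um"].to_numpy() / first_ca
    if out.shape[1] == 1:
        raise ValueError("trace carries neither force nor calibrated calcium")
    return out


def caffeine_probe(
    pre: FiberTrace | Sequence[FiberTrace],
    post: FiberTrace | Sequence[FiberTrace],
    params: CalibrationParams,
) -> pd.DataFrame:
    """Paired tetanic-calcium comparison before and after a fatigue run.

    A brief caffeine exposure at high-frequency stimulation probes the
    sarcoplasmic-reticulum calcium store; the comparison is descriptive
    (per-fiber pre, post and difference), with no hypothesis test.
    """
    pres = [pre] if isinstance(pre, FiberTrace) else list(pre)
    posts = [post] if isinstance(post, FiberTrace) else list(post)
    if [t.fiber_id for t in pres] != [t.fiber_id for t in posts]:
        raise ValueError("pre and post traces must pair identical fiber ids")
    rows = []
    for a, b in zip(pres, posts):
        ca_pre = tetanic_peaks(a, params)["tetanic_ca_um"].mean()
        ca_post = tetanic_peaks(b, params)["tetanic_ca_um"].mean()
        rows.append(
            {
                "fiber_id": a.fiber_id,
                "pre_ca_um": float(ca_pre),
                "post_ca_um": float(ca_post),
                "delta_ca_um": float(ca_post - ca_pre),
            }
        )
    return pd.DataFrame(rows)
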