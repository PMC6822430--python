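"""Synthetic peptide-array experiments and fiber recordings with known truth.

No raw array lysate data or fiber recordings are deposited for this kind of
study, so every downstream stage is exercised against generated experiments
whose ground truth is known exactly:

* :func:`generate_array_experiment` emits saturating per-peptide
  phosphorylation kinetics ``S(t) = A*(1 - exp(-k t)) + noise`` across
  control/experimental replicate wells, with a planted activity shift on the
  peptides mapped to chosen kinases, optional visually-damaged wells, and a
  truth record carrying the exact per-peptide and per-well initial
  velocities.
* :func:`generate_fiber_recording` emits indo-1 ratio and force traces under
  the study's stimulation protocols (15-150 Hz frequency sweep with 350-ms
  tetani at 1-min intervals; 70-Hz fatigue runs of 50 tetani at 2-s
  intervals), built by applying the exact algebraic inverse of the
  calibration equation to prescribed calcium waveforms and a Hill-type
  force-calcium relation.

One scenario seed drives a splittable per-component random stream, so a
fixed seed reproduces every output bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fiber import (
    CalibrationParams,
    FiberTrace,
    StimulationProtocol,
    calcium_to_ratio,
    hill_force,
)
from .inference import KinaseMap
from .kinetics import KineticSeries

__all__ = [
    "ArrayScenario",
    "ArrayExperiment",
    "FiberScenario",
    "FiberRecording",
    "generate_array_experiment",
    "generate_fiber_recording",
]

# Kinetic priors for the peptide panel: log-normal spot amplitudes around
# 1000 a.u. and saturation rates around 0.08 /min, so most peptides are still
# rising over a 30-min incubation.  The wide spread keeps the peptide-wise
# velocity profile of a well strongly structured, as on a real array where
# substrate affinities span orders of magnitude.
_AMP_LOG_MEAN = math.log(1000.0)
_AMP_LOG_SD = 0.8
_RATE_LOG_MEAN = math.log(0.08)
_RATE_LOG_SD = 0.5
# Within-series measurement noise, as a fraction of noise_cv; replicate-level
# amplitude variation carries the full noise_cv.  Initial-slope estimation
# amplifies point noise several-fold, so the smaller share keeps the total
# well-level velocity error of the same order as noise_cv.
_POINT_NOISE_FRAC = 0.2


@dataclass(frozen=True)
class ArrayScenario:
    """Design of one synthetic peptide-array experiment.

    ``effect_size`` is the planted standardized shift of the initial velocity
    for peptides whose kinase set intersects ``planted_kinases``: the
    experimental-condition velocity is ``V_ctrl * (1 + effect_size*noise_cv)``,
    i.e. ``effect_size`` replicate-noise standard deviations.  ``noise_cv``
    sets both the between-replicate amplitude variation and (scaled down) the
    within-series point noise.  ``damaged_well_prob`` marks whole wells as
    visually damaged; half of their time points are replaced by independent
    noise, which destroys inter-replicate correlation.
    """

    n_peptides: int = 60
    n_kinases: int = 20
    kinases_per_peptide: int = 8
    n_replicates_per_condition: int = 3
    time_points: tuple[float, ...] = (2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    planted_kinases: tuple[str, ...] = ()
    effect_size: float = 0.0
    noise_cv: float = 0.05
    damaged_well_prob: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_peptides", "n_kinases", "kinases_per_peptide",
                     "n_replicates_per_condition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kinases_per_peptide > self.n_kinases:
            raise ValueError("kinases_per_peptide exceeds n_kinases")
        t = np.asarray(self.time_points, dtype=float)
        if t.size < 3 or not np.all(np.diff(t) > 0) or t[0] <= 0:
            raise ValueError("time_points must be >=3, strictly increasing, starting > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0.0 <= self.damaged_well_prob <= 1.0:
            raise ValueError("damaged_well_prob must be a probability")
        if 1.0 + self.effect_size * self.noise_cv <= 0:
            raise ValueError("planted shift would drive velocities non-positive")
        kin_ids = set(_kinase_ids(self.n_kinases))
        stray = set(self.planted_kinases) - kin_ids
        if stray:
            raise ValueError(f"planted kinases not in panel: {sorted(stray)}")
        object.__setattr__(self, "time_points", tuple(float(x) for x in t))
        object.__setattr__(self, "planted_kinases", tuple(self.planted_kinases))


def _kinase_ids(n: int) -> list[str]:
    return [f"K{i + 1:02d}" for i in range(n)]


def _peptide_ids(n: int) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(n)]


@dataclass
class ArrayTruth:
    """Ground truth of a generated array experiment."""

    planted_kinases: tuple[str, ...]
    peptides: pd.DataFrame  # amplitude, rate, hit, vini_ctrl, vini_exp, std_shift
    vini_wells: pd.DataFrame  # realized per-well true V_ini (peptide x well)
    wells: pd.DataFrame  # condition, replicate, damaged
    damaged_wells: tuple[str, ...]


@dataclass
class ArrayExperiment:
    """Generated kinetic series plus mapping and truth record."""

    series: list[KineticSeries]
    kinase_map: KinaseMap
    truth: ArrayTruth
    scenario: ArrayScenario

    def long_table(self) -> pd.DataFrame:
        """The experiment in the long TSV dialect the analysis CLI reads."""
        rows = []
        for s in self.series:
            for t, y in zip(s.times, s.intensities):
                rows.append((s.peptide_id, s.well_id, s.condition, s.replicate, t, y))
        return pd.DataFrame(
            rows,
            columns=["peptide_id", "well_id", "condition", "replicate",
                     "time_min", "intensity"],
        )

    def map_table(self) -> pd.DataFrame:
        rows = []
        for kinase, peptides in sorted(self.kinase_map.sets.items()):
            for p in sorted(peptides):
                rows.append((p, kinase))
        return pd.DataFrame(rows, columns=["peptide_id", "kinase_id"])


def generate_array_experiment(scenario: ArrayScenario) -> ArrayExperiment:
    """Generate a peptide-array experiment with planted kinase activity.

    Each (peptide, well) series follows the exponential-association model
    with a per-peptide rate and a per-well amplitude; the truth record lists
    the noise-free per-condition initial velocities ``A*k*exp(-k*t1)`` and the
    realized per-well velocities (including replicate variation but not point
    noise).  Deterministic for a fixed ``rng_seed``.
    """
    ss = np.random.SeedSequence(scenario.rng_seed)
    r_map, r_kin, r_rep, r_noise, r_dam = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    n_p = scenario.n_peptides
    peptides = _peptide_ids(n_p)
    kinases = _kinase_ids(scenario.n_kinases)
    t = np.asarray(scenario.time_points)

    # peptide -> top-K kinase assignment, then inverted into kinase sets
    assign = [
        sorted(r_map.choice(scenario.n_kinases, size=scenario.kinases_per_peptide,
                            replace=False))
        for _ in range(n_p)
    ]
    sets: dict[str, set[str]] = {k: set() for k in kinases}
    for p, ks in zip(peptides, assign):
        for j in ks:
            sets[kinases[j]].add(p)
    kmap = KinaseMap(sets={k: frozenset(v) for k, v in sets.items() if v})

    amp = r_kin.lognormal(_AMP_LOG_MEAN, _AMP_LOG_SD, n_p)
    rate = r_kin.lognormal(_RATE_LOG_MEAN, _RATE_LOG_SD, n_p)
    planted = set(scenario.planted_kinases)
    hit = np.array(
        [bool({kinases[j] for j in ks} & planted) for ks in assign], dtype=bool
    )
    shift = 1.0 + scenario.effect_size * scenario.noise_cv
    amp_exp = np.where(hit, amp * shift, amp)

    vini_of = lambda a: a * rate * np.exp(-rate * t[0])
    vini_ctrl = vini_of(amp)
    vini_exp = vini_of(amp_exp)
    with np.errstate(divide="ignore", invalid="ignore"):
        std_shift = np.where(
            scenario.noise_cv > 0,
            (vini_exp - vini_ctrl) / (scenario.noise_cv * vini_ctrl),
            0.0,
        )

    n_rep = scenario.n_replicates_per_condition
    well_ids = [f"ctrl_{i + 1}" for i in range(n_rep)] + [
        f"exp_{i + 1}" for i in range(n_rep)
    ]
    conditions = ["control"] * n_rep + ["experimental"] * n_rep
    replicates = list(range(1, n_rep + 1)) * 2

    eta = r_rep.normal(0.0, scenario.noise_cv, size=(len(well_ids), n_p))
    factors = np.clip(1.0 + eta, 0.05, None)
    damaged_mask = r_dam.random(len(well_ids)) < scenario.damaged_well_prob

    series: list[KineticSeries] = []
    vini_wells = np.empty((n_p, len(well_ids)))
    point_sd = _POINT_NOISE_FRAC * scenario.noise_cv * amp  # per peptide
    n_half = t.size // 2
    for w, (well, cond, rep) in enumerate(zip(well_ids, conditions, replicates)):
        base_amp = amp_exp if cond == "experimental" else amp
        a_pw = base_amp * factors[w]
        vini_wells[:, w] = vini_of(a_pw)
        clean = a_pw[:, None] * (-np.expm1(-rate[:, None] * t[None, :]))
        if scenario.noise_cv > 0:
            y = clean + r_noise.normal(0.0, 1.0, size=clean.shape) * point_sd[:, None]
        else:
            y = clean.copy()
        if damaged_mask[w]:
            for p in range(n_p):
                idx = r_dam.choice(t.size, size=n_half, replace=False)
                y[p, idx] = r_dam.uniform(0.0, 1.5 * amp[p], size=n_half)
        for p, pep in enumerate(peptides):
            series.append(
                KineticSeries(
                    peptide_id=pep,
                    well_id=well,
                    condition=cond,
                    replicate=rep,
                    times=t.copy(),
                    intensities=y[p],
                )
            )

    wells_df = pd.DataFrame(
        {"condition": conditions, "replicate": replicates, "damaged": damaged_mask},
        index=pd.Index(well_ids, name="well_id"),
    )
    truth = ArrayTruth(
        planted_kinases=tuple(sorted(planted)),
        peptides=pd.DataFrame(
            {
                "amplitude": amp,
                "rate": rate,
                "hit": hit,
                "vini_ctrl": vini_ctrl,
                "vini_exp": vini_exp,
                "std_shift": std_shift,
            },
            index=pd.Index(peptides, name="peptide_id"),
        ),
        vini_wells=pd.DataFrame(
            vini_wells, index=pd.Index(peptides, name="peptide_id"), columns=well_ids
        ),
        wells=wells_df,
        damaged_wells=tuple(wells_df.index[damaged_mask]),
    )
    return ArrayExperiment(series=series, kinase_map=kmap, truth=truth,
                           scenario=scenario)


# ---------------------------------------------------------------------------
# Fiber recordings
# ---------------------------------------------------------------------------


def _default_ca_amplitude(frequency_hz: float, ca_max_um: float = 1.8,
                          f50_hz: float = 45.0) -> float:
    """Saturating calcium-frequency relation used for default amplitudes."""
    f2 = frequency_hz**2
    return ca_max_um * f2 / (f2 + f50_hz**2)


@dataclass(frozen=True)
class FiberScenario:
    """Design of one synthetic fiber recording.

    Calcium amplitudes default to a saturating function of stimulation
    frequency; force amplitudes default to the Hill force-calcium relation
    evaluated at those amplitudes (so force-frequency and calcium-frequency
    curves are mutually consistent).  ``fatigue_decline`` applies a geometric
    per-contraction decline to both amplitudes in fatigue mode.
    """

    protocol: StimulationProtocol
    params: CalibrationParams = CalibrationParams(
        kd_um=0.25, beta=3.0, r_min=0.2, r_max=1.0
    )
    ca_amplitudes_um: Mapping[float, float] | None = None
    force_amplitudes_mn: Mapping[float, float] | None = None
    f_max_mn: float = 0.45
    ca50_um: float = 0.6
    hill_n: float = 3.0
    ca_rest_um: float = 0.05
    rise_tau_ms: float = 15.0
    decay_tau_ms: float = 40.0
    fatigue_decline: float = 0.0
    noise_cv: float = 0.0
    sampling_rate_hz: float = 1000.0
    csa_um2: float = 1500.0
    fiber_id: str = "fiber01"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in self.protocol.frequencies_hz:
            if not 15.0 <= f <= 150.0:
                raise ValueError("stimulation frequencies must lie within [15, 150] Hz")
        if not 0.0 <= self.fatigue_decline < 1.0:
            raise ValueError("fatigue_decline must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.ca_rest_um <= 0:
            raise ValueError("resting calcium must be positive")
        for amp in self.resolved_ca_amplitudes().values():
            if not (math.isfinite(amp) and amp > 0):
                raise ValueError("calcium amplitudes must be positive and finite")

    def resolved_ca_amplitudes(self) -> dict[float, float]:
        if self.ca_amplitudes_um is not None:
            out = {float(f): float(a) for f, a in self.ca_amplitudes_um.items()}
            missing = set(self.protocol.frequencies_hz) - set(out)
            if missing:
                raise ValueError(f"missing calcium amplitude for {sorted(missing)} Hz")
            return out
        return {
            f: _default_ca_amplitude(f) for f in self.protocol.frequencies_hz
        }

    def resolved_force_amplitudes(self) -> dict[float, float]:
        ca = self.resolved_ca_amplitudes()
        if self.force_amplitudes_mn is not None:
            out = {float(f): float(a) for f, a in self.force_amplitudes_mn.items()}
            missing = set(self.protocol.frequencies_hz) - set(out)
            if missing:
                raise ValueError(f"missing force amplitude for {sorted(missing)} Hz")
            return out
        return {
            f: float(hill_force(np.array(ca[f]), self.f_max_mn, self.ca50_um,
                                self.hill_n))
            for f in self.protocol.frequencies_hz
        }


@dataclass
class FiberRecording:
    """Generated fiber trace plus the truth record."""

    trace: FiberTrace
    truth: pd.DataFrame  # per window: frequency, start, end, true amplitudes
    scenario: FiberScenario


def generate_fiber_recording(scenario: FiberScenario) -> FiberRecording:
    """Generate indo-1 ratio and force traces under a stimulation protocol.

    The calcium waveform is a square pulse with exponential rise and decay
    kinetics per tetanus; multiplicative noise is applied in the calcium
    domain and the emitted ratio trace is the exact algebraic inverse of the
    calibration equation, so it always lies strictly inside (R_min, R_max).
    The force trace is the Hill transform of the clean calcium waveform,
    rescaled so the within-window peak equals the prescribed force amplitude
    exactly, plus additive noise.  In fatigue mode both amplitudes decline
    geometrically by ``fatigue_decline`` per contraction.
    """
    proto = scenario.protocol
    rng = np.random.default_rng(np.random.SeedSequence(scenario.rng_seed))
    fs = scenario.sampling_rate_hz
    dt = 1.0 / fs
    duration_s = proto.tetanus_duration_ms / 1000.0
    freqs = proto.window_frequencies
    n_win = len(freqs)
    lead_s = 0.5
    total_s = lead_s + n_win * proto.interval_s
    time = np.arange(0.0, total_s, dt)

    ca_amp = scenario.resolved_ca_amplitudes()
    f_amp = scenario.resolved_force_amplitudes()
    rest = scenario.ca_rest_um
    tau_r = scenario.rise_tau_ms / 1000.0
    tau_d = scenario.decay_tau_ms / 1000.0

    ca_clean = np.full_like(time, rest)
    force = np.zeros_like(time)
    force_noise_scale = np.zeros_like(time)
    rows = []
    for i, f in enumerate(freqs):
        decline = (1.0 - scenario.fatigue_decline) ** i if proto.mode == "fatigue" else 1.0
        amp_i = rest + (ca_amp[f] - rest) * decline
        famp_i = f_amp[f] * decline
        start = lead_s + i * proto.interval_s
        end = start + duration_s
        in_win = (time >= start) & (time <= end)
        tw = time[in_win] - start
        ca_clean[in_win] = rest + (amp_i - rest) * (1.0 - np.exp(-tw / tau_r))
        ca_end = ca_clean[in_win][-1] if in_win.any() else rest
        seg_end = lead_s + (i + 1) * proto.interval_s
        after = (time > end) & (time < seg_end)
        ca_clean[after] = rest + (ca_end - rest) * np.exp(-(time[after] - end) / tau_d)

        # force: Hill transform of the clean calcium, unit-peak normalized
        # within the window then scaled to the prescribed amplitude
        seg = (time >= start) & (time < seg_end)
        raw = hill_force(ca_clean[seg], 1.0, scenario.ca50_um, scenario.hill_n)
        raw_win = hill_force(ca_clean[in_win], 1.0, scenario.ca50_um, scenario.hill_n)
        peak_raw = raw_win.max()
        force[seg] = famp_i * raw / peak_raw
        force_noise_scale[seg] = famp_i
        rows.append(
            {
                "window": i,
                "frequency_hz": f,
                "start_s": start,
                "end_s": end,
                "true_ca_amplitude_um": amp_i,
                "true_peak_force_mn": famp_i,
            }
        )

    if scenario.noise_cv > 0:
        ca_noisy = ca_clean * (1.0 + rng.normal(0.0, scenario.noise_cv, time.shape))
        ca_noisy = np.clip(ca_noisy, 1e-4, None)
        # band-limited transducer noise (25-ms boxcar-smoothed, unit sd)
        # scaled to the local tetanic amplitude; as in the array generator,
        # measurement noise carries a 0.2 share of noise_cv so window maxima
        # are not dominated by extreme single samples
        w = max(int(round(0.025 * fs)), 1)
        white = rng.normal(0.0, 1.0, time.size + w - 1)
        smooth = np.convolve(white, np.ones(w) / w, mode="valid") * math.sqrt(w)
        force_noise_scale[force_noise_scale == 0] = (
            f_amp[freqs[0]] if freqs else 0.0
        )
        force = force + _POINT_NOISE_FRAC * scenario.noise_cv * force_noise_scale * smooth
    else:
        ca_noisy = ca_clean
    ratio = calcium_to_ratio(ca_noisy, scenario.params)

    windows = pd.DataFrame(rows)[["start_s", "end_s", "frequency_hz"]]
    trace = FiberTrace(
        fiber_id=scenario.fiber_id,
        time_s=time,
        ratio=ratio,
        force_mn=force,
        csa_um2=scenario.csa_um2,
        windows=windows,
    )
    truth = pd.DataFrame(rows)
    return FiberRecording(trace=trace, truth=truth, scenario=scenario)
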