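"""Initial-velocity estimation and replicate quality control for peptide-array kinetics.

A flow-through peptide array reads out substrate phosphorylation as spot
intensity over repeated pump cycles.  The per-peptide activity measure is the
initial velocity ``V_ini``: the time-derivative of the fitted saturation curve
evaluated at the first kinetic read.  All downstream scoring operates on a
peptide x well matrix of these velocities, after dropping visually damaged
wells and replicates that correlate poorly with the rest of their condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "KineticSeries",
    "ViniTable",
    "fit_vini",
    "fit_vini_table",
    "qc_replicates",
]

QC_KEPT = "kept"
QC_DROPPED_DAMAGED = "dropped_damaged"
QC_DROPPED_CORRELATION = "dropped_correlation"


@dataclass(frozen=True)
class KineticSeries:
    """Spot intensity versus incubation time for one peptide in one well.

    Parameters
    ----------
    peptide_id, well_id
        Identifiers linking the series to the array layout.
    condition
        Experimental-group label of the well (e.g. ``"control"`` /
        ``"experimental"``).
    replicate
        Replicate index of the well within its condition.
    times
        Incubation times in minutes; strictly increasing, at least three.
    intensities
        Fluorescence intensities (arbitrary units), one per time point.
    """

    peptide_id: str
    well_id: str
    condition: str
    replicate: int
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and intensities must be 1-D and equal length")
        if t.size < 3:
            raise ValueError("a kinetic series needs at least 3 time points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise ValueError("times and intensities must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)


@dataclass
class ViniTable:
    """Matrix of initial velocities (peptide x well) with well metadata.

    ``values`` is indexed by peptide id with one column per well id.
    ``wells`` is indexed by well id and carries ``condition``, ``replicate``
    and a ``qc_status`` column (``kept`` until :func:`qc_replicates` runs).
    """

    values: pd.DataFrame
    wells: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.wells.index):
            raise ValueError("values columns and wells index must match")
        if "qc_status" not in self.wells.columns:
            self.wells = self.wells.assign(qc_status=QC_KEPT)

    @property
    def kept_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["qc_status"] == QC_KEPT]

    @property
    def kept_values(self) -> pd.DataFrame:
        return self.values[self.kept_wells.index]

    def condition_labels(self) -> list[str]:
        return sorted(self.wells["condition"].unique())


def _profile_rss(k: float, t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Residual sum of squares of ``y ~ c + A*(1 - exp(-k t))`` at fixed rate.

    The model is linear in ``(c, A)`` once ``k`` is fixed, so the two linear
    coefficients are profiled out in closed form.  Returns ``(rss, A, c)``.
    """
    b = -np.expm1(-k * t)
    bm = b.mean()
    ym = y.mean()
    bc = b - bm
    yc = y - ym
    sbb = float(bc @ bc)
    if sbb <= 0.0:  # basis numerically constant: intercept-only fit
        return float(yc @ yc), 0.0, ym
    sby = float(bc @ yc)
    a = sby / sbb
    rss = float(yc @ yc) - a * sby
    return max(rss, 0.0), a, ym - a * bm


def _fit_exponential(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Profile least squares for the exponential-association model.

    Scans a log-spaced grid of rates, then refines the best rate by bounded
    scalar minimisation.  Returns ``(k, A, c)``.
    """
    k_lo = 1e-4 / t[-1]
    k_hi = 20.0 / t[0]
    grid = np.geomspace(k_lo, k_hi, 80)
    rss = np.array([_profile_rss(k, t, y)[0] for k in grid])
    i = int(np.argmin(rss))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda k: _profile_rss(k, t, y)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": grid[i] * 1e-10},
    )
    k = float(res.x)
    _, a, c = _profile_rss(k, t, y)
    return k, a, c


def fit_vini(series: KineticSeries, model: str = "exponential") -> float:
    """Fit a kinetic model and return the initial velocity at the first read.

    The exponential-association model ``S(t) = c + A*(1 - exp(-k t))`` is fit
    by least squares (rate profiled over a log grid plus bounded refinement);
    ``V_ini`` is its analytic derivative ``A*k*exp(-k*t1)`` at the first time
    point.  ``model="linear"`` returns the ordinary least-squares slope, and
    is also the automatic fallback when the exponential fit does not yield a
    finite result.  The baseline term makes ``V_ini`` invariant to additive
    intensity offsets.
    """
    t, y = series.times, series.intensities
    if model not in ("exponential", "linear"):
        raise ValueError(f"unknown model {model!r}")
    if model == "exponential":
        try:
            k, a, _ = _fit_exponential(t, y)
            v = a * k * math.exp(-k * t[0])
            if math.isfinite(v):
                return v
        except (ValueError, FloatingPointError):
            pass
        # fall through: degenerate exponential fit -> linear slope
    slope = float(np.polyfit(t, y, 1)[0])
    if not math.isfinite(slope):
        raise ValueError(f"unusable series {series.peptide_id}/{series.well_id}")
    return slope


def fit_vini_table(
    series: Iterable[KineticSeries], model: str = "exponential"
) -> ViniTable:
    """Fit every series and assemble the peptide x well ``V_ini`` matrix."""
    records: dict[str, dict[str, float]] = {}
    meta: dict[str, tuple[str, int]] = {}
    for s in series:
        records.setdefault(s.well_id, {})[s.peptide_id] = fit_vini(s, model=model)
        prev = meta.setdefault(s.well_id, (s.condition, s.replicate))
        if prev != (s.condition, s.replicate):
            raise ValueError(f"inconsistent metadata for well {s.well_id}")
    if not records:
        raise ValueError("no kinetic series supplied")
    values = pd.DataFrame(records).sort_index()
    values = values[sorted(values.columns)]
    wells = pd.DataFrame(
        {
            "condition": {w: meta[w][0] for w in values.columns},
            "replicate": {w: meta[w][1] for w in values.columns},
        }
    ).loc[values.columns]
    wells.index.name = "well_id"
    values.index.name = "peptide_id"
    if values.isna().any().any():
        missing = values.columns[values.isna().any()].tolist()
        raise ValueError(f"wells with missing peptides: {missing}")
    return ViniTable(values=values, wells=wells)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(xc @ yc) / denom


def qc_replicates(
    vini: ViniTable,
    min_corr: float = 0.95,
    damaged_wells: Iterable[str] = (),
) -> ViniTable:
    """Drop damaged wells and replicates that disagree with their condition.

    Wells listed in ``damaged_wells`` (visual inspection) are dropped
    unconditionally.  For every remaining well, the Pearson correlation of its
    peptide-wise ``V_ini`` vector against the mean vector of the *other*
    non-damaged replicates of the same condition is computed; wells below
    ``min_corr`` are dropped.  All correlations are evaluated in a single pass
    against the pre-filter reference means (no re-computation after removals).

    Raises
    ------
    ValueError
        If a condition starts with fewer than two replicates, or is left with
        fewer than two kept wells.
    """
    damaged = set(damaged_wells)
    unknown = damaged - set(vini.values.columns)
    if unknown:
        raise ValueError(f"damaged wells not in table: {sorted(unknown)}")
    wells = vini.wells.copy()
    for cond, grp in wells.groupby("condition"):
        if len(grp) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")

    status = pd.Series(QC_KEPT, index=wells.index, dtype=object)
    status[list(damaged)] = QC_DROPPED_DAMAGED

    candidates = [w for w in wells.index if w not in damaged]
    correlations: dict[str, float] = {}
    for w in candidates:
        cond = wells.at[w, "condition"]
        others = [
            o
            for o in wells.index[wells["condition"] == cond]
            if o != w and o not in damaged
        ]
        if not others:
            raise ValueError(
                f"well {w!r}: no non-damaged replicate left in {cond!r} to compare against"
            )
        ref = vini.values[others].mean(axis=1).to_numpy()
        r = _pearson(vini.values[w].to_numpy(), ref)
        correlations[w] = r
        if r < min_corr:
            status[w] = QC_DROPPED_CORRELATION

    wells["qc_status"] = status
    wells["replicate_corr"] = pd.Series(correlations).reindex(wells.index)
    out = ViniTable(values=vini.values.copy(), wells=wells)
    for cond, grp in out.kept_wells.groupby("condition"):
        if len(grp) < 2:
            raise ValueError(
                f"condition {cond!r} left with fewer than 2 kept wells after QC"
            )
    for cond in vini.condition_labels():
        if cond not in set(out.kept_wells["condition"]):
            raise ValueError(f"condition {cond!r} lost all wells during QC")
    return out
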