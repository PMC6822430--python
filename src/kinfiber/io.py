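"""Readers and writers for the plain-text dialects the pipeline exchanges.

Kinetic data travel as long-format TSV (`peptide_id, well_id, condition,
replicate, time_min, intensity`), velocities as a peptide x well TSV plus a
well-metadata TSV, kinase maps as two-or-three column TSV, annotations as
GMT, and fiber traces as CSV with companion window/metadata tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .fiber import FiberTrace
from .inference import KinaseMap
from .kinetics import KineticSeries, ViniTable

__all__ = [
    "read_kinetics_tsv",
    "write_kinetics_tsv",
    "read_vini_table",
    "write_vini_table",
    "read_kinase_map",
    "write_kinase_map",
    "read_fiber_trace",
    "write_fiber_trace",
    "read_damaged_wells",
]

_KINETIC_COLS = ["peptide_id", "well_id", "condition", "replicate", "time_min",
                 "intensity"]


def read_kinetics_tsv(path: str | Path) -> list[KineticSeries]:
    """Read long-format kinetic series, one row per (peptide, well, time)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_KINETIC_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"kinetics TSV missing columns: {sorted(missing)}")
    out = []
    for (pep, well), grp in df.groupby(["peptide_id", "well_id"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            KineticSeries(
                peptide_id=str(pep),
                well_id=str(well),
                condition=str(grp["condition"].iloc[0]),
                replicate=int(grp["replicate"].iloc[0]),
                times=grp["time_min"].to_numpy(dtype=float),
                intensities=grp["intensity"].to_numpy(dtype=float),
            )
        )
    return out


def write_kinetics_tsv(series: Iterable[KineticSeries], path: str | Path) -> None:
    rows = [
        (s.peptide_id, s.well_id, s.condition, s.replicate, t, y)
        for s in series
        for t, y in zip(s.times, s.intensities)
    ]
    pd.DataFrame(rows, columns=_KINETIC_COLS).to_csv(path, sep="\t", index=False)


def write_vini_table(vini: ViniTable, values_path: str | Path,
                     wells_path: str | Path) -> None:
    vini.values.to_csv(values_path, sep="\t")
    vini.wells.to_csv(wells_path, sep="\t")


def read_vini_table(values_path: str | Path, wells_path: str | Path) -> ViniTable:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    wells = pd.read_csv(wells_path, sep="\t", index_col=0)
    return ViniTable(values=values, wells=wells)


def read_kinase_map(path: str | Path, max_per_peptide: int | None = 8) -> KinaseMap:
    """Read a peptide->kinase TSV (``peptide_id, kinase_id[, rank]``)."""
    df = pd.read_csv(path, sep="\t")
    if not {"peptide_id", "kinase_id"} <= set(df.columns):
        raise ValueError("kinase map TSV needs peptide_id and kinase_id columns")
    return KinaseMap.from_long_table(df, max_per_peptide=max_per_peptide)


def write_kinase_map(kmap: KinaseMap, path: str | Path) -> None:
    rows = [
        (p, k)
        for k in kmap.kinases()
        for p in sorted(kmap.sets[k])
    ]
    pd.DataFrame(rows, columns=["peptide_id", "kinase_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_damaged_wells(path: str | Path) -> list[str]:
    """One well id per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_fiber_trace(trace: FiberTrace, trace_path: str | Path,
                      windows_path: str | Path) -> None:
    cols = {"time_s": trace.time_s}
    if trace.ratio is not None:
        cols["ratio"] = trace.ratio
    if trace.force_mn is not None:
        cols["force_mn"] = trace.force_mn
    pd.DataFrame(cols).to_csv(trace_path, index=False)
    w = trace.windows.copy()
    w.insert(0, "fiber_id", trace.fiber_id)
    w.to_csv(windows_path, sep="\t", index=False)


def read_fiber_trace(
    trace_path: str | Path,
    windows_path: str | Path,
    fiber_id: str | None = None,
    csa_um2: float | None = None,
) -> FiberTrace:
    df = pd.read_csv(trace_path)
    if "time_s" not in df.columns:
        raise ValueError("fiber trace CSV needs a time_s column")
    windows = pd.read_csv(windows_path, sep="\t")
    if fiber_id is None:
        if "fiber_id" in windows.columns and len(windows):
            fiber_id = str(windows["fiber_id"].iloc[0])
        else:
            fiber_id = Path(trace_path).stem
    if "fiber_id" in windows.columns:
        windows = windows[windows["fiber_id"].astype(str) == fiber_id]
        windows = windows.drop(columns=["fiber_id"])
    return FiberTrace(
        fiber_id=fiber_id,
        time_s=df["time_s"].to_numpy(dtype=float),
        ratio=df["ratio"].to_numpy(dtype=float) if "ratio" in df.columns else None,
        force_mn=(
            df["force_mn"].to_numpy(dtype=float) if "force_mn" in df.columns else None
        ),
        csa_um2=csa_um2,
        windows=windows.reset_index(drop=True),
    )
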