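"""End-to-end driver for the kinase-inference arm of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .inference import KinaseMap, kinase_scores, peptide_scores, permutation_q, top_kinases
from .kinetics import KineticSeries, ViniTable, fit_vini_table, qc_replicates

__all__ = ["ArrayAnalysis", "analyze_array"]


@dataclass
class ArrayAnalysis:
    """Intermediate and final tables of one array analysis run."""

    vini: ViniTable
    peptide_scores: pd.DataFrame
    results: pd.DataFrame
    top: pd.DataFrame


def analyze_array(
    series: Iterable[KineticSeries],
    kmap: KinaseMap,
    damaged_wells: Iterable[str] = (),
    min_corr: float = 0.95,
    model: str = "exponential",
    M: int = 1000,
    seed: int | None = 0,
    top_k: int = 35,
    two_sided: bool = True,
) -> ArrayAnalysis:
    """Kinetic series -> V_ini -> QC -> scores -> permutation Q -> top-K.

    Runs the full upstream-kinase inference chain: fit initial velocities,
    drop damaged/discordant replicate wells, compute standardized peptide
    scores and set-averaged kinase scores, assign permutation Q significance
    (``M`` global peptide-label permutations) and select the ``top_k``
    kinases by absolute score.
    """
    vini = fit_vini_table(series, model=model)
    vini = qc_replicates(vini, min_corr=min_corr, damaged_wells=damaged_wells)
    pep = peptide_scores(vini)
    results = permutation_q(pep, kmap, M=M, seed=seed, two_sided=two_sided)
    top = top_kinases(results, K=top_k)
    return ArrayAnalysis(vini=vini, peptide_scores=pep, results=results, top=top)
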