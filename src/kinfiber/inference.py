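"""Peptide effect scores, kinase scores, and permutation significance.

Each peptide on the array gets a standardized mean-difference score between
the experimental and control wells.  A peptide->kinase mapping (the top eight
candidate upstream kinases per peptide, inverted into per-kinase peptide
sets) turns peptide scores into kinase scores by set averaging.  Significance
is a permutation Q score on the decibel scale:

    Q = -10 * log10(max(m/M, 1/M))

where ``m`` counts, out of ``M`` random relabelings of the peptide scores,
how often the permuted kinase score exceeds the observed one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .kinetics import ViniTable

__all__ = [
    "KinaseMap",
    "peptide_scores",
    "kinase_scores",
    "permutation_q",
    "top_kinases",
    "q_score",
]


@dataclass(frozen=True)
class KinaseMap:
    """Per-kinase peptide sets, inverted from per-peptide kinase lists."""

    sets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sets", {k: frozenset(v) for k, v in dict(self.sets).items()}
        )

    @classmethod
    def from_long_table(
        cls, table: pd.DataFrame, max_per_peptide: int | None = 8
    ) -> "KinaseMap":
        """Build from a long table with ``peptide_id`` and ``kinase_id`` columns.

        ``max_per_peptide`` enforces the top-K mapping convention (default 8
        kinases per peptide); pass ``None`` to skip the check.
        """
        if max_per_peptide is not None:
            per_pep = table.groupby("peptide_id")["kinase_id"].nunique()
            bad = per_pep[per_pep > max_per_peptide]
            if len(bad):
                raise ValueError(
                    f"peptides mapped to more than {max_per_peptide} kinases: "
                    f"{bad.index.tolist()[:5]}"
                )
        sets = {
            k: frozenset(g["peptide_id"])
            for k, g in table.groupby("kinase_id")
        }
        return cls(sets=sets)

    def peptides(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)

    def kinases(self) -> list[str]:
        return sorted(self.sets)


def peptide_scores(vini: ViniTable, control_label: str = "control") -> pd.DataFrame:
    """Standardized per-peptide difference between the two conditions.

    score = (mean_experimental - mean_control) / pooled SD, where the pooled
    SD combines the within-condition variances over the kept wells.  A peptide
    with zero pooled SD but a nonzero mean difference is degenerate: it is
    flagged and carries a signed infinite sentinel that downstream set
    averaging excludes.

    Returns a frame indexed by peptide with columns ``score``, ``mean_ctrl``,
    ``mean_exp``, ``pooled_sd`` and ``degenerate``.
    """
    wells = vini.kept_wells
    labels = sorted(wells["condition"].unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two conditions, got {labels}")
    if control_label not in labels:
        raise ValueError(f"control label {control_label!r} not among {labels}")
    exp_label = next(l for l in labels if l != control_label)
    ctrl = vini.kept_values[wells.index[wells["condition"] == control_label]]
    exp = vini.kept_values[wells.index[wells["condition"] == exp_label]]
    n1, n2 = ctrl.shape[1], exp.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each condition needs at least two kept wells")

    mean_c = ctrl.mean(axis=1)
    mean_e = exp.mean(axis=1)
    pooled_var = (
        (n1 - 1) * ctrl.var(axis=1, ddof=1) + (n2 - 1) * exp.var(axis=1, ddof=1)
    ) / (n1 + n2 - 2)
    pooled_sd = np.sqrt(pooled_var)
    diff = mean_e - mean_c

    degenerate = (pooled_sd == 0) & (diff != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = diff / pooled_sd
    score = score.where(~((pooled_sd == 0) & (diff == 0)), 0.0)
    score = score.where(~degenerate, np.sign(diff) * np.inf)
    return pd.DataFrame(
        {
            "score": score,
            "mean_ctrl": mean_c,
            "mean_exp": mean_e,
            "pooled_sd": pooled_sd,
            "degenerate": degenerate,
        }
    )


def _usable_scores(scores: pd.Series | pd.DataFrame) -> pd.Series:
    s = scores["score"] if isinstance(scores, pd.DataFrame) else scores
    return s[np.isfinite(s)]


def kinase_scores(scores: pd.Series | pd.DataFrame, kmap: KinaseMap) -> pd.DataFrame:
    """Average the signed peptide scores over each kinase's peptide set.

    Degenerate (non-finite) peptide scores are excluded before averaging; a
    kinase whose set becomes empty is reported with a null (NaN) score and
    ``set_size`` 0.
    """
    if not kmap.sets:
        raise ValueError("empty kinase map")
    s = _usable_scores(scores)
    rows = []
    for kinase in kmap.kinases():
        members = [p for p in kmap.sets[kinase] if p in s.index]
        if members:
            rows.append((kinase, float(s[members].mean()), len(members)))
        else:
            rows.append((kinase, np.nan, 0))
    out = pd.DataFrame(rows, columns=["kinase_id", "score", "set_size"])
    return out.set_index("kinase_id")


def q_score(m: np.ndarray | int, M: int) -> np.ndarray | float:
    """Permutation significance on the decibel scale.

    ``Q = -10*log10(max(m/M, 1/M))``; Q is 0 when every permutation beats the
    observed score and capped at ``10*log10(M)`` when none does.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    m_arr = np.asarray(m, dtype=float)
    q = -10.0 * np.log10(np.maximum(m_arr, 1.0) / M) + 0.0  # avoid -0.0
    return float(q) if np.isscalar(m) or m_arr.ndim == 0 else q


def _membership_matrix(
    kmap: KinaseMap, peptides: pd.Index
) -> tuple[np.ndarray, list[str]]:
    kinases = kmap.kinases()
    B = np.zeros((len(kinases), len(peptides)), dtype=float)
    pos = {p: j for j, p in enumerate(peptides)}
    for i, k in enumerate(kinases):
        for p in kmap.sets[k]:
            if p in pos:
                B[i, pos[p]] = 1.0
    return B, kinases


def permutation_q(
    scores: pd.Series | pd.DataFrame,
    kmap: KinaseMap,
    M: int = 1000,
    seed: int | None = 0,
    two_sided: bool = True,
    method: str = "sample",
) -> pd.DataFrame:
    """Permutation significance of kinase scores under peptide relabeling.

    Each iteration applies one global permutation of the peptide score values
    across peptide labels, shared by all kinases (preserving the inter-kinase
    correlation induced by overlapping sets), and recomputes every kinase's
    set mean.  ``m`` counts permutations whose score strictly exceeds the
    observed one — in absolute value by default (``two_sided``), or signed
    with ``two_sided=False``.

    ``method="exhaustive"`` enumerates all orderings of the peptide score
    vector instead of sampling (``M`` is then the number of orderings);
    feasible only for small peptide panels.

    Returns a frame indexed by kinase with ``score``, ``set_size``, ``m``,
    ``M`` and ``Q`` columns.
    """
    s = _usable_scores(scores)
    if s.empty:
        raise ValueError("no usable peptide scores")
    obs = kinase_scores(s, kmap)
    B, kinases = _membership_matrix(kmap, s.index)
    sizes = B.sum(axis=1)
    values = s.to_numpy()

    if method == "exhaustive":
        if values.size > 8:
            raise ValueError("exhaustive enumeration limited to <= 8 peptides")
        perms = np.array(list(itertools.permutations(values)))
        M = perms.shape[0]
    elif method == "sample":
        if M < 1:
            raise ValueError("M must be >= 1")
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.broadcast_to(values, (M, values.size)).copy(), axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        perm_scores = perms @ B.T / np.where(sizes > 0, sizes, np.nan)  # (M, K)
    obs_vec = obs["score"].to_numpy()
    if two_sided:
        exceed = np.abs(perm_scores) > np.abs(obs_vec)
    else:
        exceed = perm_scores > obs_vec
    m = np.where(np.isfinite(obs_vec), np.nansum(exceed, axis=0), 0).astype(int)

    out = obs.copy()
    out["m"] = m
    out["M"] = M
    q = q_score(m, M)
    out["Q"] = np.where(np.isfinite(obs_vec), q, np.nan)
    return out


def top_kinases(results: pd.DataFrame, K: int = 35) -> pd.DataFrame:
    """Select the top-K kinases by absolute score.

    Sorted by descending ``|score|``; ties broken by higher ``Q`` (when
    present) and then lexical kinase id.  Null-score kinases are excluded.
    Returns the first ``K`` rows (all, if fewer).
    """
    if results.empty:
        raise ValueError("empty results")
    if K <= 0:
        raise ValueError("K must be positive")
    name = results.index.name or "kinase_id"
    df = results[np.isfinite(results["score"])].rename_axis(name).reset_index()
    df["_abs"] = df["score"].abs()
    df["_q"] = df["Q"] if "Q" in df.columns else 0.0
    df = df.sort_values(
        by=["_abs", "_q", name],
        ascending=[False, False, True],
        kind="mergesort",
    ).set_index(name)
    return df.drop(columns=["_abs", "_q"]).head(K)
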