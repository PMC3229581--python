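"""Two-group nonparametric differential expression and the 2^-ddCt utility.

Differential expression between two sample classes (e.g. tumor vs adrenal)
is called per miRNA with the two-sided Wilcoxon rank-sum test on NRQ
values, Bonferroni correction across the retained miRNAs, and a fold-change
gate: a call is Up when the adjusted p is below alpha *and* the group-mean
NRQ ratio exceeds ``fc_min`` (default 2-fold), Down for the mirror case,
otherwise NS.

Two p-value routes are provided.  ``exact`` enumerates the permutation
distribution of the rank sum over all C(N, n1) group assignments, with
ties handled by mid-ranks fixed on the pooled sample; the two-sided p is
P(|W - E[W]| >= |w_obs - E[W]|).  ``approx`` uses the normal approximation
with tie-corrected variance and a 0.5 continuity correction.  ``auto``
picks exact for N <= 12 and approx otherwise.

The module also houses the comparative-Ct (2^-ddCt) utility for single-gene
qPCR: target Ct normalized to a reference (housekeeping) gene and expressed
relative to a calibrator group, whose mean delta-Ct defines the baseline.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .preprocess import NormalizedMatrix

__all__ = [
    "DEResult",
    "DdCtResult",
    "wilcoxon_rank_sum",
    "bonferroni",
    "fold_change",
    "call_differential",
    "ddct_expression",
    "de_results_frame",
]

logger = logging.getLogger(__name__)

Direction = Literal["Up", "Down", "NS"]

_EXACT_MAX_COMBINATIONS = 500_000


@dataclass(frozen=True)
class DEResult:
    """Per-miRNA two-group test outcome.

    ``stat`` is the rank sum of group 1; ``log2fc`` is
    log2(mean NRQ group1 / mean NRQ group2); ``direction`` applies the
    adjusted-alpha and fold-change gates.
    """

    mirna: str
    stat: float
    p_raw: float
    p_adj: float
    log2fc: float
    direction: Direction
    n_group1: int
    n_group2: int


@dataclass(frozen=True)
class DdCtResult:
    """Comparative-Ct outcome for one sample: delta Ct, ddCt and 2**(-ddCt)."""

    sample: str
    delta_ct: float
    ddct: float
    rel_expr: float


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "approx", "auto"] = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of x, p-value).

    Exact mode enumerates every assignment of the pooled values into the
    two group sizes (mid-ranks for ties); approx mode uses the normal
    approximation with tie-corrected variance and continuity correction.
    If all pooled values are identical the test is degenerate and p = 1 is
    returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")

    pooled = np.concatenate([x, y])
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = rankdata(pooled)
    w_obs = float(ranks[:n1].sum())

    if np.ptp(pooled) == 0.0:
        warnings.warn("all values identical across both groups; p set to 1", stacklevel=2)
        return w_obs, 1.0

    if mode == "auto":
        mode = "exact" if n <= 12 else "approx"

    if mode == "exact":
        n_comb = math.comb(n, n1)
        if n_comb > _EXACT_MAX_COMBINATIONS:
            raise ValueError(
                f"exact enumeration of {n_comb} assignments refused; use approx"
            )
        mu = n1 * ranks.mean()
        dev_obs = abs(w_obs - mu)
        hits = 0
        for idx in combinations(range(n), n1):
            if abs(ranks[list(idx)].sum() - mu) >= dev_obs - 1e-9:
                hits += 1
        return w_obs, hits / n_comb

    if mode != "approx":
        raise ValueError(f"unknown mode {mode!r}")

    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        warnings.warn("zero rank variance; p set to 1", stacklevel=2)
        return w_obs, 1.0
    z = max(abs(w_obs - mu) - 0.5, 0.0) / math.sqrt(var)
    return w_obs, min(1.0, 2.0 * float(norm.sf(z)))


def bonferroni(p_raw: float, n_tests: int) -> float:
    """Family-wise Bonferroni adjustment: min(1, p * n_tests)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"p-value {p_raw} outside [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p_raw * n_tests)


def fold_change(nrq_group1: Sequence[float], nrq_group2: Sequence[float]) -> float:
    """log2 ratio of the group arithmetic means of NRQ (group1 over group2)."""
    g1 = np.asarray(nrq_group1, dtype=float)
    g2 = np.asarray(nrq_group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("fold change of an empty group")
    return float(np.log2(g1.mean() / g2.mean()))


def _resolve_groups(
    sample_ids: pd.Index,
    grouping: Mapping[str, str] | pd.Series,
    group1: str | None,
    group2: str | None,
) -> tuple[str, str, list[str], list[str]]:
    labels = pd.Series({s: grouping[s] for s in sample_ids})
    classes = list(dict.fromkeys(labels))
    if group1 is None or group2 is None:
        if len(classes) != 2:
            raise ValueError(
                f"grouping must define exactly two classes, found {classes}"
            )
        group1 = group1 or classes[0]
        group2 = group2 or (classes[1] if classes[1] != group1 else classes[0])
    s1 = [s for s in sample_ids if labels[s] == group1]
    s2 = [s for s in sample_ids if labels[s] == group2]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(
            f"each class needs >= 2 samples (got {group1}: {len(s1)}, {group2}: {len(s2)})"
        )
    return group1, group2, s1, s2


def call_differential(
    n: NormalizedMatrix,
    grouping: Mapping[str, str] | pd.Series,
    *,
    group1: str | None = None,
    group2: str | None = None,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    n_tests: int | None = None,
    mode: Literal["exact", "approx", "auto"] = "auto",
) -> list[DEResult]:
    """Call Up/Down/NS per miRNA from NRQ values under a two-class grouping.

    ``grouping`` maps sample id to class label; ``group1``/``group2`` pin
    which label is the numerator of the fold change (defaults to order of
    appearance).  ``n_tests`` defaults to the number of retained miRNAs.
    The same operation serves any two-class contrast (tumor vs adrenal,
    genotype subgroups, MNA vs non-MNA): only the grouping changes.
    """
    if n.nrq is None:
        raise ValueError("NormalizedMatrix.nrq not computed; run compute_nrq first")
    g1, g2, s1, s2 = _resolve_groups(n.sample_ids, grouping, group1, group2)
    if n_tests is None:
        n_tests = len(n.mirnas)
    log2_gate = math.log2(fc_min)

    results: list[DEResult] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate all-tied rows are expected in nulls
        for mirna, row in n.nrq.iterrows():
            xv, yv = row[s1].to_numpy(), row[s2].to_numpy()
            stat, p_raw = wilcoxon_rank_sum(xv, yv, mode=mode)
            p_adj = bonferroni(p_raw, n_tests)
            lfc = fold_change(xv, yv)
            if p_adj < alpha and lfc >= log2_gate:
                direction: Direction = "Up"
            elif p_adj < alpha and lfc <= -log2_gate:
                direction = "Down"
            else:
                direction = "NS"
            results.append(
                DEResult(str(mirna), stat, p_raw, p_adj, lfc, direction, len(s1), len(s2))
            )
    n_up = sum(r.direction == "Up" for r in results)
    n_down = sum(r.direction == "Down" for r in results)
    logger.info(
        "differential calls (%s vs %s): %d DE (%d up, %d down) of %d tested",
        g1, g2, n_up + n_down, n_up, n_down, len(results),
    )
    return results


def de_results_frame(results: Iterable[DEResult]) -> pd.DataFrame:
    """Tabulate DE results (one row per miRNA) for reporting/serialization."""
    return pd.DataFrame(
        [
            {
                "mirna": r.mirna,
                "stat": r.stat,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "log2fc": r.log2fc,
                "direction": r.direction,
                "n_group1": r.n_group1,
                "n_group2": r.n_group2,
            }
            for r in results
        ]
    ).set_index("mirna")


def ddct_expression(
    ct_target: pd.Series,
    ct_reference: pd.Series,
    calibrator: Sequence[str],
) -> list[DdCtResult]:
    """Comparative-Ct relative expression, 2**(-ddCt), per sample.

    delta_ct = Ct(target) - Ct(reference gene); ddct subtracts the
    arithmetic mean delta_ct of the calibrator samples; rel_expr is
    2**(-ddct), so the calibrator group's geometric mean is 1.
    """
    if len(calibrator) == 0:
        raise ValueError("calibrator sample set is empty")
    samples = list(ct_target.index)
    if set(samples) != set(ct_reference.index):
        raise ValueError("target and reference Ct vectors index different samples")
    missing = [s for s in calibrator if s not in samples]
    if missing:
        raise ValueError(f"calibrator samples absent from data: {missing}")
    if ct_target.isna().any() or ct_reference.isna().any():
        bad = sorted(
            set(ct_target.index[ct_target.isna()]) | set(ct_reference.index[ct_reference.isna()])
        )
        raise ValueError(f"missing Ct for samples: {bad}")

    delta = ct_target - ct_reference.loc[ct_target.index]
    baseline = float(delta.loc[list(calibrator)].mean())
    out = []
    for s in samples:
        ddct = float(delta[s] - baseline)
        out.append(DdCtResult(sample=str(s), delta_ct=float(delta[s]), ddct=ddct,
                              rel_expr=2.0 ** (-ddct)))
    return out
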