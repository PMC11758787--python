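"""Accuracy and coverage metrics, indel-parameter binning, nested subspaces.

The column score (CS) of an inferred alignment against the true one is
the number of shared columns divided by the true alignment's column
count; a column is shared when it pairs the same residues of the same
rows (residue ordinals, not alignment positions).  CS-error = 1 - CS.
Coverage is the fraction of inputs for which the aligner produced any
valid alignment at all; CS is computed on valid alignments only, so the
two metrics are complementary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .simulate import SimulationConfig, violating_range
from .types import Msa

log = logging.getLogger(__name__)

#: ten equal bins per axis, matching the parameter-sweep layout
LENGTH_BIN_EDGES = np.round(np.linspace(1.0, 2.0, 11), 10)
RATE_BIN_EDGES = np.round(np.linspace(0.0, 0.05, 11), 10)


@dataclass
class EvalReport:
    cs: float
    n_shared_columns: int
    n_true_columns: int

    @property
    def cs_error(self) -> float:
        return 1.0 - self.cs


def column_score(inferred: Msa, truth: Msa) -> EvalReport:
    """Fraction of the true alignment's columns reproduced exactly.

    Both alignments must align the same sequences (identical ungapped rows
    per id); anything else is an argument error, not a score of zero.
    """
    iu, tu = inferred.ungapped(), truth.ungapped()
    if iu.ids != tu.ids or iu.seqs != tu.seqs:
        raise ValueError("alignments are not over the same sequence set")
    true_keys = truth.column_keys()
    inferred_keys = set(inferred.column_keys())
    shared = sum(1 for k in true_keys if k in inferred_keys)
    return EvalReport(cs=shared / len(true_keys), n_shared_columns=shared,
                      n_true_columns=len(true_keys))


@dataclass
class CoverageReport:
    n_valid: int
    n_total: int

    @property
    def coverage(self) -> float:
        return self.n_valid / self.n_total


def coverage(results: Sequence) -> CoverageReport:
    """Fraction of alignment outcomes that are valid.

    ``results`` items may be booleans or anything with a ``valid``
    attribute (e.g. AlignResult / SelectionReport failures count as invalid).
    """
    if not results:
        raise ValueError("empty result list")
    flags = [bool(getattr(r, "valid", r) if not hasattr(r, "failed") else not r.failed)
             for r in results]
    return CoverageReport(n_valid=sum(flags), n_total=len(flags))


@dataclass
class ParameterBins:
    """10 x 10 grid of mean scores over an indel-parameter axis pair."""

    axis_pair: tuple[str, str]          # ("AI", "AD") or ("RI", "RD")
    edges: np.ndarray
    mean_score: pd.DataFrame            # rows: first axis bins, cols: second
    count: pd.DataFrame

    @property
    def empty_cells(self) -> list[tuple[int, int]]:
        c = self.count.to_numpy()
        return [(i, j) for i in range(c.shape[0]) for j in range(c.shape[1]) if c[i, j] == 0]


def _bin_index(value: float, edges: np.ndarray) -> int | None:
    """Half-open bins [low, high), last bin closed; None outside all bins."""
    if value < edges[0] or value > edges[-1]:
        return None
    idx = int(np.searchsorted(edges, value, side="right")) - 1
    return min(idx, len(edges) - 2)


def bin_performance(records: Sequence[tuple[dict, float]], axis_pair: tuple[str, str]) -> ParameterBins:
    """Mean score per (axis1, axis2) bin over records of (params, score).

    ``axis_pair`` selects ("AI", "AD") with bins (1.0,1.1)..(1.9,2.0) or
    ("RI", "RD") with bins (0.000,0.005)..(0.045,0.05).  Records outside
    the grid are skipped with a warning.
    """
    if tuple(axis_pair) == ("AI", "AD"):
        edges = LENGTH_BIN_EDGES
    elif tuple(axis_pair) == ("RI", "RD"):
        edges = RATE_BIN_EDGES
    else:
        raise ValueError(f"axis pair must be (AI, AD) or (RI, RD), got {axis_pair!r}")
    n = len(edges) - 1
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for params, score in records:
        i = _bin_index(params[axis_pair[0]], edges)
        j = _bin_index(params[axis_pair[1]], edges)
        if i is None or j is None:
            log.warning("record with %s=%s, %s=%s outside the bin grid; skipped",
                        axis_pair[0], params[axis_pair[0]], axis_pair[1], params[axis_pair[1]])
            continue
        total[i, j] += score
        count[i, j] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(n)]
    return ParameterBins(tuple(axis_pair), edges,
                         pd.DataFrame(mean, index=labels, columns=labels),
                         pd.DataFrame(count, index=labels, columns=labels))


def binned_trend(values: Sequence[float], scores: Sequence[float], n_bins: int = 10,
                 min_per_bin: int = 1) -> tuple[np.ndarray, float]:
    """Bin ``scores`` by equal-width bins of ``values``; Spearman rho of bin means.

    Used to ask whether an error metric trends with a parameter (e.g.
    CS-error against RI+RD): returns the per-bin means (NaN where a bin has
    fewer than ``min_per_bin`` records) and the rank correlation between
    bin order and bin mean over the occupied bins.
    """
    v = np.asarray(values, float)
    s = np.asarray(scores, float)
    edges = np.linspace(v.min(), v.max() + 1e-12, n_bins + 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = (v >= edges[b]) & (v < edges[b + 1])
        if mask.sum() >= min_per_bin:
            means[b] = s[mask].mean()
    ok = ~np.isnan(means)
    rho = float(spearmanr(np.arange(n_bins)[ok], means[ok]).statistic)
    return means, rho


def make_nested_subspaces(general: SimulationConfig, specific: SimulationConfig,
                          ultra: SimulationConfig) -> tuple[SimulationConfig, SimulationConfig, SimulationConfig]:
    """Validate a general ⊇ specific ⊇ ultra-specific configuration triple.

    Every parameter range of each level must be contained in the enclosing
    level's range; the error names the first violating parameter.
    """
    for inner, outer, names in ((specific, general, "specific/general"),
                                (ultra, specific, "ultra/specific")):
        bad = violating_range(inner, outer)
        if bad is not None:
            raise ValueError(f"{names}: range {bad} of the inner config is not "
                             f"contained in the outer config")
    return general, specific, ultra
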