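"""Population-vector (PV) analysis.

A PV is the across-unit vector of smoothed rates at one spatial bin of a
trajectory.  PV correlations (Pearson across units at the same bin) compare
ensembles between sessions (cross-session) or between the two running
directions (cross-trajectory); only bins where at least 5 units are active
enter the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .spatial import RateCurve

__all__ = ["PopulationVectorMatrix", "build_pv", "pv_correlation"]

MIN_ACTIVE_UNITS = 5
BIN_ACTIVE_RATE = 0.5  # Hz: a unit counts as active at a bin above this rate
# (the same 0.5 Hz criterion that defines an active cell, applied per bin)


@dataclass
class PopulationVectorMatrix:
    trajectory: int
    session: str
    bin_edges: np.ndarray
    unit_ids: list[str]
    matrix: np.ndarray  # bins x units, smoothed rates (NaN where invalid)
    active_count: np.ndarray  # per-bin number of active units
    eligible: np.ndarray  # bool per bin

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def build_pv(
    curves: dict[str, RateCurve],
    trajectory: int,
    session: str,
    active_rate: float = BIN_ACTIVE_RATE,
    min_active: int = MIN_ACTIVE_UNITS,
) -> PopulationVectorMatrix:
    """Stack rate curves (column order fixed by unit id) into a bins x units
    matrix and mark bins with at least ``min_active`` units whose rate
    exceeds ``active_rate`` Hz there."""
    if not curves:
        raise ValueError("no curves supplied")
    unit_ids = sorted(curves)
    edges = curves[unit_ids[0]].bin_edges
    cols = []
    for u in unit_ids:
        c = curves[u]
        if not np.array_equal(c.bin_edges, edges):
            raise ValueError("rate curves must share bin edges")
        cols.append(c.rate)
    mat = np.column_stack(cols)
    with np.errstate(invalid="ignore"):
        active = np.nan_to_num(mat) > active_rate
    count = active.sum(axis=1)
    valid_all = np.all(np.isfinite(mat), axis=1)
    eligible = (count >= min_active) & valid_all
    return PopulationVectorMatrix(trajectory, session, edges, unit_ids, mat, count, eligible)


def pv_correlation(
    pv_a: PopulationVectorMatrix, pv_b: PopulationVectorMatrix
) -> tuple[np.ndarray, float]:
    """Per-bin Pearson correlation between matched PVs and its average over
    eligible bins (eligibility joint between the two matrices).  Bins where
    either PV is constant are skipped (NaN)."""
    if pv_a.unit_ids != pv_b.unit_ids:
        raise ValueError("PV matrices must share the same units in the same order")
    if not np.array_equal(pv_a.bin_edges, pv_b.bin_edges):
        raise ValueError("PV matrices must share bin edges")
    nb = pv_a.matrix.shape[0]
    r = np.full(nb, np.nan)
    both = pv_a.eligible & pv_b.eligible
    for i in np.flatnonzero(both):
        a, b = pv_a.matrix[i], pv_b.matrix[i]
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        r[i] = sstats.pearsonr(a, b)[0]
    mean_r = float(np.nanmean(r)) if np.isfinite(r).any() else np.nan
    return r, mean_r
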