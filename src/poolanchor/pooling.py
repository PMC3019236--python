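"""Signal normalisation and positive-pool scoring for three-dimensional BAC pools.

Four scoring methods are implemented, in decreasing order of stringency:

``automated``
    Per probe and per pool axis, a threshold of mean + k x SD (sample SD,
    n-1) is applied; pools strictly above it are positive.  The step is
    repeated twice more with previously detected positives excluded from the
    mean/SD computation (three passes in total); the union of the passes is
    returned.  Default multipliers: plate 2.8, row 2.5, column 3.0.
``boxplot``
    Upper boxplot outliers (value > Q3 + 1.5 x IQR, quartiles by linear
    interpolation) per probe per axis.
``semi_automated``
    Completes probes with exactly five positive pools in a 2/2/1 axis
    pattern by enumerating coordinate combinations and requiring a unique
    pair of wells holding two overlapping BACs.
``manual``
    Completes probes with exactly two positive pools (on two different axes)
    by scanning the missing axis and requiring a unique well holding a BAC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from poolanchor.core_io import AXES, PhysicalMap, Well

DEFAULT_K = {"plate": 2.8, "row": 2.5, "column": 3.0}


class ScoringError(ValueError):
    pass


def plate_pool_id(plate: int) -> str:
    return f"P{plate:02d}"


def row_pool_id(row: str) -> str:
    return f"R{row}"


def column_pool_id(column: int) -> str:
    return f"C{column:02d}"


@dataclass(frozen=True)
class Pool:
    pool_id: str
    axis: str
    coord: int | str
    members: frozenset[str]


class PoolLayout:
    """The plate/row/column pooling geometry.

    Each BAC belongs to exactly one pool per axis; the three axes partition
    the pool set.
    """

    def __init__(self, pools: Sequence[Pool]) -> None:
        self.pools: dict[str, Pool] = {p.pool_id: p for p in pools}
        if len(self.pools) != len(pools):
            raise ScoringError("duplicate pool IDs in layout")
        self._by_axis: dict[str, list[str]] = {axis: [] for axis in AXES}
        for p in pools:
            if p.axis not in AXES:
                raise ScoringError(f"unknown axis {p.axis!r} for pool {p.pool_id}")
            self._by_axis[p.axis].append(p.pool_id)
        membership: dict[str, dict[str, int]] = {}
        for p in pools:
            for bac in p.members:
                counts = membership.setdefault(bac, {axis: 0 for axis in AXES})
                counts[p.axis] += 1
        for bac, counts in membership.items():
            if any(c != 1 for c in counts.values()):
                raise ScoringError(
                    f"BAC {bac} is not in exactly one pool per axis: {counts}"
                )

    @classmethod
    def from_physical_map(cls, pm: PhysicalMap, n_plates: int, n_rows: int, n_cols: int) -> "PoolLayout":
        """Build the 3-D layout implied by the BAC well addresses."""
        from poolanchor.core_io import ROW_LETTERS

        plates: dict[int, set[str]] = {p: set() for p in range(1, n_plates + 1)}
        rows: dict[str, set[str]] = {ROW_LETTERS[r]: set() for r in range(n_rows)}
        cols: dict[int, set[str]] = {c: set() for c in range(1, n_cols + 1)}
        for rec in pm.bacs.values():
            if rec.plate not in plates or rec.row not in rows or rec.column not in cols:
                raise ScoringError(
                    f"BAC {rec.bac_id} well {rec.well} outside the "
                    f"{n_plates}x{n_rows}x{n_cols} geometry"
                )
            plates[rec.plate].add(rec.bac_id)
            rows[rec.row].add(rec.bac_id)
            cols[rec.column].add(rec.bac_id)
        pools = (
            [Pool(plate_pool_id(p), "plate", p, frozenset(m)) for p, m in plates.items()]
            + [Pool(row_pool_id(r), "row", r, frozenset(m)) for r, m in rows.items()]
            + [Pool(column_pool_id(c), "column", c, frozenset(m)) for c, m in cols.items()]
        )
        return cls(pools)

    def pool_ids(self, axis: str | None = None) -> list[str]:
        if axis is None:
            return [pid for ax in AXES for pid in self._by_axis[ax]]
        return list(self._by_axis[axis])

    def axis_of(self, pool_id: str) -> str:
        return self.pools[pool_id].axis

    def coord_of(self, pool_id: str) -> int | str:
        return self.pools[pool_id].coord

    def coords(self, axis: str) -> list[int | str]:
        return [self.pools[pid].coord for pid in self._by_axis[axis]]

    def pool_for_coord(self, axis: str, coord: int | str) -> str:
        for pid in self._by_axis[axis]:
            if self.pools[pid].coord == coord:
                return pid
        raise KeyError((axis, coord))


@dataclass
class SignalMatrix:
    """Probe x pool intensity grid with its normalisation state."""

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ScoringError("signal matrix contains non-finite values")

    @property
    def probes(self) -> list[str]:
        return list(self.data.index)


@dataclass
class ProbeCall:
    probe_id: str
    positives: dict[str, list[str]] = field(default_factory=lambda: {a: [] for a in AXES})
    thresholds: dict[str, list[float]] = field(default_factory=lambda: {a: [] for a in AXES})

    @property
    def n_positive(self) -> int:
        return sum(len(v) for v in self.positives.values())


@dataclass
class ScoringResult:
    """Positive pools per probe for one scoring method.

    ``assigned`` holds direct well assignments produced by the
    semi-automated and manual completion methods (which resolve wells
    rather than pools).
    """

    method: str
    calls: dict[str, ProbeCall] = field(default_factory=dict)
    assigned: dict[str, list[Well]] = field(default_factory=dict)

    def positives_of(self, probe_id: str) -> dict[str, list[str]]:
        call = self.calls.get(probe_id)
        return call.positives if call else {a: [] for a in AXES}


# ---------------------------------------------------------------------------
# normalisation


def normalize(matrix: SignalMatrix, layout: PoolLayout) -> SignalMatrix:
    """Two-step median normalisation.

    Step 1 divides every value by the median of its own pool (making pool
    medians comparable); step 2 divides every value by the median of its own
    probe row.  After both steps every probe-row median is exactly 1.
    """
    if matrix.state != "raw":
        raise ScoringError(f"normalize expects a raw matrix, got state {matrix.state!r}")
    df = matrix.data[layout.pool_ids()].copy()
    pool_medians = df.median(axis=0)
    zero = pool_medians.index[pool_medians == 0]
    if len(zero):
        raise ScoringError(f"zero median in pool {zero[0]}; cannot normalise")
    df = df / pool_medians
    probe_medians = df.median(axis=1)
    zero_probes = probe_medians.index[probe_medians == 0]
    if len(zero_probes):
        raise ScoringError(f"zero median for probe {zero_probes[0]}; cannot normalise")
    df = df.div(probe_medians, axis=0)
    return SignalMatrix(data=df, state="probe_normalised")


# ---------------------------------------------------------------------------
# scoring methods


def _require_normalised(matrix: SignalMatrix) -> None:
    if matrix.state != "probe_normalised":
        raise ScoringError(
            f"scoring expects a probe_normalised matrix, got {matrix.state!r}"
        )


def automated_scoring(
    matrix: SignalMatrix,
    layout: PoolLayout,
    k: Mapping[str, float] | None = None,
    n_passes: int = 3,
) -> ScoringResult:
    """Iterated mean + k x SD outlier scoring (three passes).

    In each pass the mean and sample SD (ddof=1) are computed over the
    pools of one axis excluding positives from earlier passes; pools
    strictly above mean + k x SD become positive.  Ties at the threshold are
    not positive.
    """
    _require_normalised(matrix)
    k = dict(DEFAULT_K if k is None else k)
    for axis in AXES:
        if len(layout.pool_ids(axis)) < 3:
            raise ScoringError(f"axis {axis!r} has fewer than 3 pools")
    result = ScoringResult(method="automated")
    values = matrix.data
    for probe_id in values.index:
        call = ProbeCall(probe_id=probe_id)
        for axis in AXES:
            pool_ids = layout.pool_ids(axis)
            vals = values.loc[probe_id, pool_ids].to_numpy(dtype=float)
            active = np.ones(len(pool_ids), dtype=bool)
            positive = np.zeros(len(pool_ids), dtype=bool)
            for _ in range(n_passes):
                rem = vals[active]
                if len(rem) < 2:
                    break
                mean = rem.mean()
                sd = rem.std(ddof=1)
                threshold = mean + k[axis] * sd
                call.thresholds[axis].append(float(threshold))
                new = active & (vals > threshold)
                if not new.any():
                    break
                positive |= new
                active &= ~new
            call.positives[axis] = [pid for pid, p in zip(pool_ids, positive) if p]
        result.calls[probe_id] = call
    return result


def boxplot_scoring(matrix: SignalMatrix, layout: PoolLayout) -> ScoringResult:
    """Upper boxplot outliers (> Q3 + 1.5 x IQR) per probe per axis.

    Quartiles use linear interpolation.  This method is less stringent than
    the automated one; downstream, its calls are kept only when they resolve
    to two to three overlapping BACs.
    """
    _require_normalised(matrix)
    result = ScoringResult(method="boxplot")
    for probe_id in matrix.data.index:
        call = ProbeCall(probe_id=probe_id)
        for axis in AXES:
            pool_ids = layout.pool_ids(axis)
            vals = matrix.data.loc[probe_id, pool_ids].to_numpy(dtype=float)
            q1, q3 = np.percentile(vals, [25, 75])
            fence = q3 + 1.5 * (q3 - q1)
            call.thresholds[axis].append(float(fence))
            call.positives[axis] = [
                pid for pid, v in zip(pool_ids, vals) if v > fence
            ]
        result.calls[probe_id] = call
    return result


# ---------------------------------------------------------------------------
# completion methods (resolve wells directly from incomplete coordinate sets)


def _positive_coords(call: ProbeCall, layout: PoolLayout) -> dict[str, list[int | str]]:
    return {
        axis: [layout.coord_of(pid) for pid in call.positives[axis]] for axis in AXES
    }


def complete_semi_automated(
    result: ScoringResult, layout: PoolLayout, pm: PhysicalMap
) -> ScoringResult:
    """Resolve probes with five positive pools in a 2/2/1 axis pattern.

    The two complementary pairings of the doubled coordinates are
    enumerated; a probe is resolved only if exactly one pairing names two
    wells that both hold BACs and those BACs overlap on the map.  Ties
    (both pairings valid) and misses are left unresolved.
    """
    out = ScoringResult(method="semi_automated", calls=result.calls)
    for probe_id, call in result.calls.items():
        coords = _positive_coords(call, layout)
        counts = sorted(len(v) for v in coords.values())
        if call.n_positive != 5 or counts != [1, 2, 2]:
            continue
        single_axis = next(a for a in AXES if len(coords[a]) == 1)
        double_axes = [a for a in AXES if len(coords[a]) == 2]
        a1, a2 = coords[double_axes[0]]
        b1, b2 = coords[double_axes[1]]
        c = coords[single_axis][0]
        pairings = [((a1, b1), (a2, b2)), ((a1, b2), (a2, b1))]
        valid: list[tuple[Well, Well]] = []
        for first, second in pairings:
            wells = []
            for a, b in (first, second):
                parts = {double_axes[0]: a, double_axes[1]: b, single_axis: c}
                wells.append((parts["plate"], parts["row"], parts["column"]))
            bacs = [pm.bac_at(w) for w in wells]
            if None in bacs:
                continue
            if pm.overlap(bacs[0], bacs[1]):
                valid.append(tuple(wells))
        if len(valid) == 1:
            out.assigned[probe_id] = list(valid[0])
    return out


def complete_manual(
    result: ScoringResult, layout: PoolLayout, pm: PhysicalMap
) -> ScoringResult:
    """Resolve probes with exactly two positive pools on two different axes.

    Every coordinate of the missing axis is scanned; the probe is resolved
    only if exactly one candidate well holds an MTP BAC.
    """
    out = ScoringResult(method="manual", calls=result.calls)
    for probe_id, call in result.calls.items():
        coords = _positive_coords(call, layout)
        present = [a for a in AXES if len(coords[a]) == 1]
        empty = [a for a in AXES if len(coords[a]) == 0]
        if call.n_positive != 2 or len(present) != 2 or len(empty) != 1:
            continue
        missing_axis = empty[0]
        candidates: list[Well] = []
        for coord in layout.coords(missing_axis):
            parts = {a: coords[a][0] for a in present}
            parts[missing_axis] = coord
            well = (parts["plate"], parts["row"], parts["column"])
            if pm.bac_at(well) is not None:
                candidates.append(well)
        if len(candidates) == 1:
            out.assigned[probe_id] = [candidates[0]]
    return out
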