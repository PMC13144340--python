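"""BOLD containers, nuisance regression, masking and segment extraction.

The containers are deliberately thin: a run is a 4D numpy array with a TR
and an identifier, a masked series is a (voxels x time) matrix whose rows
follow one canonical voxel order so that maps from different stages line up
without bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Shortest usable segment after transient exclusion, in volumes. Pearson
#: correlation over fewer samples is too unstable to average.
MIN_SEGMENT_VOLUMES = 10


class GridMismatchError(ValueError):
    """Mask and run live on different voxel grids."""


class RankDeficientDesignError(ValueError):
    """Nuisance design has linearly dependent columns."""


class SegmentError(ValueError):
    """An event does not yield a valid analysis segment."""


@dataclass
class BoldRun:
    """One participant's 4D time series.

    data is (x, y, z, t); values must be finite, t >= 2, tr_s > 0.
    """

    participant_id: str
    data: np.ndarray
    tr_s: float
    affine: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (x,y,z,t) data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("run must contain at least 2 volumes")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("run contains non-finite values")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class MaskedSeries:
    """Masked voxel time courses in canonical mask order.

    voxel_ids are ascending linear indices into the grid with x varying
    fastest, then y, then z (Fortran raveling); matrix is (voxels x time).
    """

    voxel_ids: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=np.intp)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or len(self.voxel_ids) != self.matrix.shape[0]:
            raise ValueError("matrix must be (len(voxel_ids), time)")

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[1]


def canonical_mask_indices(mask: np.ndarray) -> np.ndarray:
    """Linear indices of mask voxels in canonical (x-fastest) order."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {mask.shape}")
    return np.flatnonzero(mask.ravel(order="F").astype(bool))


def apply_mask(run: BoldRun, mask: np.ndarray) -> MaskedSeries:
    """Vectorize a run over the mask voxels, canonical order, values unchanged."""
    mask = np.asarray(mask)
    if mask.shape != run.grid_dims:
        raise GridMismatchError(
            f"mask grid {mask.shape} does not match run grid {run.grid_dims}"
        )
    ids = canonical_mask_indices(mask)
    if ids.size == 0:
        raise ValueError("mask selects no voxels")
    flat = run.data.reshape(-1, run.n_volumes, order="F")
    return MaskedSeries(voxel_ids=ids, matrix=flat[ids].copy())


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns that add no rank (QR pivot diagnostic)."""
    r = np.linalg.matrix_rank(X)
    kept: list[int] = []
    dependent: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            dependent.append(names[j])
        if len(kept) == r and j >= r:
            dependent.extend(names[j + 1:])
            break
    return dependent


def regress_out_nuisance(run: BoldRun, nuisance: pd.DataFrame | np.ndarray) -> BoldRun:
    """Residualize every voxel against [intercept | nuisance regressors].

    Projection residuals are mean-free per voxel (the intercept is always in
    the design). Idempotent up to numerical precision.
    """
    if isinstance(nuisance, pd.DataFrame):
        names = [str(c) for c in nuisance.columns]
        N = nuisance.to_numpy(dtype=np.float64)
    else:
        N = np.asarray(nuisance, dtype=np.float64)
        if N.ndim == 1:
            N = N[:, None]
        names = [f"nuisance_{j}" for j in range(N.shape[1])]
    T = run.n_volumes
    if N.shape[0] != T:
        raise ValueError(
            f"nuisance has {N.shape[0]} rows but run has {T} volumes"
        )
    X = np.column_stack([np.ones(T), N])
    colnames = ["intercept"] + names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        dep = _dependent_columns(X, colnames)
        raise RankDeficientDesignError(
            f"nuisance design is rank deficient; dependent columns: {dep}"
        )
    flat = run.data.reshape(-1, T, order="F")
    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    resid = flat.T - X @ beta  # (T, voxels)
    out = resid.T.reshape(run.data.shape, order="F")
    prov = dict(run.provenance)
    prov["nuisance_regressed"] = colnames
    return replace(run, data=out, provenance=prov)


def _segment_volumes(onset_s: float, duration_s: float, tr_s: float,
                     n_exclude_volumes: int) -> tuple[int, int]:
    """Inclusive 0-based [first, last] volume range for one event.

    A volume belongs to an event if its acquisition onset lies in
    [onset, onset + duration); the first n_exclude_volumes are then dropped
    to skip the hemodynamic transient.
    """
    first = math.floor(onset_s / tr_s) + n_exclude_volumes
    last = math.floor((onset_s + duration_s) / tr_s) - 1
    return first, last


def extract_segments(
    run: BoldRun,
    events: pd.DataFrame,
    mask: np.ndarray,
    n_exclude_volumes: int = 8,
) -> tuple[pd.DataFrame, dict[str, MaskedSeries]]:
    """Cut a run into per-stimulus masked segments.

    events must carry columns onset, duration, stimulus_id, frame, topic.
    Returns the segment table (stable (stimulus_id, frame) order) and a
    mapping segment_id -> MaskedSeries. Volume indexing follows
    ``_segment_volumes``; segments shorter than MIN_SEGMENT_VOLUMES or
    overlapping raise SegmentError.
    """
    required = {"onset", "duration", "stimulus_id", "frame", "topic"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    if n_exclude_volumes < 0:
        raise ValueError("n_exclude_volumes must be >= 0")

    rows = []
    for _, ev in events.iterrows():
        first, last = _segment_volumes(
            float(ev["onset"]), float(ev["duration"]), run.tr_s, n_exclude_volumes
        )
        seg_id = f"{ev['stimulus_id']}_{ev['frame']}"
        n_vol = last - first + 1
        if last >= run.n_volumes or first < 0:
            raise SegmentError(
                f"segment {seg_id} needs volumes [{first}, {last}] but run "
                f"{run.participant_id} has {run.n_volumes}"
            )
        if n_vol < MIN_SEGMENT_VOLUMES:
            raise SegmentError(
                f"segment {seg_id} retains {n_vol} volumes after excluding "
                f"{n_exclude_volumes}; minimum is {MIN_SEGMENT_VOLUMES}"
            )
        rows.append(
            dict(
                segment_id=seg_id,
                stimulus_id=ev["stimulus_id"],
                frame=ev["frame"],
                topic=ev["topic"],
                onset_s=float(ev["onset"]),
                duration_s=float(ev["duration"]),
                first_volume=first,
                last_volume=last,
            )
        )
    table = pd.DataFrame(rows).sort_values(
        ["stimulus_id", "frame"], kind="stable"
    ).reset_index(drop=True)

    # overlap check on the retained volume ranges (pre-exclusion starts could
    # only overlap if the raw events do)
    intervals = sorted(zip(table["first_volume"], table["last_volume"]))
    for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
        if b0 <= a1:
            raise SegmentError(
                f"segments overlap in volumes: [{a0},{a1}] and [{b0},{b1}]"
            )

    masked = apply_mask(run, mask)
    series = {
        row.segment_id: MaskedSeries(
            voxel_ids=masked.voxel_ids,
            matrix=masked.matrix[:, row.first_volume: row.last_volume + 1].copy(),
        )
        for row in table.itertuples()
    }
    return table, series
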