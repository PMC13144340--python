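"""Pairwise inter-subject correlation maps and baseline correction.

One PairMap = one participant pair's per-voxel Fisher-z correlation for one
scope (a stimulus segment or an averaged condition). The unmatched-segment
baseline captures stimulus-nonspecific synchrony (scanner noise, shared
drift structure) and is subtracted before dyadic regression.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from framesync.preprocess import MaskedSeries

logger = logging.getLogger(__name__)

#: Fisher transform clamp: |r| is capped at 1 - R_CLAMP so z stays finite.
R_CLAMP = 1e-7

#: Unmatched segment combinations per pair beyond which the baseline uses a
#: seeded uniform subsample.
MAX_BASELINE_COMBINATIONS = 200


@dataclass
class PairMap:
    """Per-voxel Fisher-z synchrony map for one participant pair and scope."""

    pair: tuple[str, str]
    scope: str
    values: np.ndarray
    frame: str | None = None
    topic: str | None = None
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        i, j = self.pair
        if not i < j:
            raise ValueError(f"pair must be ordered (i < j), got {self.pair}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pair map contains non-finite values")


def pearson_map(a: MaskedSeries, b: MaskedSeries) -> np.ndarray:
    """Per-voxel Pearson correlation of two masked series over time.

    Voxels with zero temporal variance in either series get r = 0; their
    count is logged rather than propagated as NaN.
    """
    if not np.array_equal(a.voxel_ids, b.voxel_ids):
        raise ValueError("series are defined on different voxel sets")
    if a.n_volumes != b.n_volumes:
        raise ValueError(
            f"series lengths differ: {a.n_volumes} vs {b.n_volumes}"
        )
    if a.n_volumes < 3:
        raise ValueError("need at least 3 time points for a correlation")
    x = a.matrix - a.matrix.mean(axis=1, keepdims=True)
    y = b.matrix - b.matrix.mean(axis=1, keepdims=True)
    sx = np.sqrt((x * x).sum(axis=1))
    sy = np.sqrt((y * y).sum(axis=1))
    bad = (sx == 0) | (sy == 0)
    if bad.any():
        logger.info("pearson_map: %d zero-variance voxels set to r=0", int(bad.sum()))
    denom = np.where(bad, 1.0, sx * sy)
    r = (x * y).sum(axis=1) / denom
    r[bad] = 0.0
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing r -> z = atanh(r), with |r| clamped below 1."""
    arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(arr) > 1.0 + 1e-8):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(arr, -(1.0 - R_CLAMP), 1.0 - R_CLAMP))
    return float(z) if np.isscalar(r) else z


def ordered_pairs(participant_ids: Iterable[str]) -> list[tuple[str, str]]:
    """All unordered participant pairs as sorted (i, j) tuples, i < j."""
    ids = sorted(participant_ids)
    return list(itertools.combinations(ids, 2))


def all_pair_maps(
    series: Mapping[str, Mapping[str, MaskedSeries]],
    segments: pd.DataFrame | None = None,
) -> list[PairMap]:
    """One Fisher-z map per unordered participant pair per segment.

    ``series`` maps participant_id -> segment_id -> MaskedSeries; every
    participant must hold every segment. ``segments`` (optional) supplies
    frame/topic labels per segment_id.
    """
    pids = sorted(series)
    if len(pids) < 2:
        raise ValueError("need at least 2 participants")
    seg_ids = sorted(series[pids[0]])
    for pid in pids:
        missing = set(seg_ids) - set(series[pid])
        extra = set(series[pid]) - set(seg_ids)
        if missing or extra:
            raise ValueError(
                f"participant {pid} segment mismatch; missing={sorted(missing)}"
                f" extra={sorted(extra)}"
            )
    labels: dict[str, tuple[str | None, str | None]] = {}
    if segments is not None:
        labels = {
            row.segment_id: (row.frame, row.topic) for row in segments.itertuples()
        }
    maps = []
    for i, j in ordered_pairs(pids):
        for seg in seg_ids:
            frame, topic = labels.get(seg, (None, None))
            maps.append(
                PairMap(
                    pair=(i, j),
                    scope=seg,
                    values=fisher_z(pearson_map(series[i][seg], series[j][seg])),
                    frame=frame,
                    topic=topic,
                )
            )
    return maps


def average_by_condition(
    maps: Sequence[PairMap], grouping: str = "frame"
) -> list[PairMap]:
    """Arithmetic mean of z-maps within (pair, condition) groups.

    grouping is "frame" or "frame_topic"; every input map must carry the
    labels the grouping needs.
    """
    if grouping not in ("frame", "frame_topic"):
        raise ValueError(f"unknown grouping {grouping!r}")

    def key(m: PairMap) -> tuple:
        if m.frame is None or (grouping == "frame_topic" and m.topic is None):
            raise ValueError(f"map {m.pair}/{m.scope} lacks condition labels")
        return (m.pair, m.frame) if grouping == "frame" else (m.pair, m.frame, m.topic)

    groups: dict[tuple, list[PairMap]] = {}
    for m in maps:
        groups.setdefault(key(m), []).append(m)
    if not groups:
        raise ValueError("no maps to average")
    out = []
    for k in sorted(groups):
        members = groups[k]
        pair, frame = k[0], k[1]
        topic = k[2] if grouping == "frame_topic" else None
        scope = frame if topic is None else f"{frame}_{topic}"
        out.append(
            PairMap(
                pair=pair,
                scope=scope,
                values=np.mean([m.values for m in members], axis=0),
                frame=frame,
                topic=topic,
                baseline_subtracted=all(m.baseline_subtracted for m in members),
            )
        )
    return out


def baseline_map(
    pair: tuple[str, str],
    series_i: Mapping[str, MaskedSeries],
    series_j: Mapping[str, MaskedSeries],
    max_combinations: int = MAX_BASELINE_COMBINATIONS,
    seed: int = 0,
) -> PairMap:
    """Average z-map over unmatched segment pairings of one participant pair.

    Ordered combinations (segment A of i vs segment B of j, A != B) across
    all frame and topic conditions; unequal lengths are truncated to the
    shorter segment. When more than ``max_combinations`` exist, a seeded
    uniform subsample is used.
    """
    seg_ids = sorted(series_i)
    if set(seg_ids) != set(series_j):
        raise ValueError("participants hold different segment sets")
    if len(seg_ids) < 2:
        raise ValueError("baseline needs at least 2 segments per participant")
    combos = [(a, b) for a in seg_ids for b in seg_ids if a != b]
    if len(combos) > max_combinations:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(combos), size=max_combinations, replace=False)
        combos = [combos[k] for k in sorted(idx)]
    acc = None
    for a, b in combos:
        sa, sb = series_i[a], series_j[b]
        t = min(sa.n_volumes, sb.n_volumes)
        za = MaskedSeries(sa.voxel_ids, sa.matrix[:, :t])
        zb = MaskedSeries(sb.voxel_ids, sb.matrix[:, :t])
        z = fisher_z(pearson_map(za, zb))
        acc = z if acc is None else acc + z
    return PairMap(pair=pair, scope="baseline", values=acc / len(combos))


def subtract_baseline(pair_map: PairMap, baseline: PairMap) -> PairMap:
    """Element-wise subtraction of a pair's baseline map from a z-map."""
    if pair_map.pair != baseline.pair:
        raise ValueError(
            f"pair mismatch: {pair_map.pair} vs baseline {baseline.pair}"
        )
    if pair_map.values.shape != baseline.values.shape:
        raise ValueError("voxel sets differ between map and baseline")
    if pair_map.baseline_subtracted:
        raise ValueError("map is already baseline-subtracted")
    return replace(
        pair_map,
        values=pair_map.values - baseline.values,
        baseline_subtracted=True,
    )


def stack_segment_maps(
    maps: Sequence[PairMap], grouping: str = "frame"
) -> tuple[np.ndarray, list[tuple[str, str]], list[str], list[str], np.ndarray]:
    """Stack per-segment maps into a (pairs, stimuli, frames, voxels) array.

    Requires a balanced design: every pair holds one map per
    (stimulus, frame). Returns (Y4, pairs, stimuli, conditions, cond_of)
    where conditions are the grouping labels (frame or frame_topic) and
    cond_of[s, f] is the condition index of stimulus s presented in frame
    slot f — the lookup the within-stimulus permutation scheme relabels.
    """
    if grouping not in ("frame", "frame_topic"):
        raise ValueError(f"unknown grouping {grouping!r}")
    pairs = sorted({m.pair for m in maps})
    frames, stimuli, topics = [], [], {}
    for m in maps:
        stim = m.scope.rsplit("_", 1)[0]
        if m.frame is None:
            raise ValueError(f"map {m.pair}/{m.scope} lacks a frame label")
        if m.frame not in frames:
            frames.append(m.frame)
        if stim not in stimuli:
            stimuli.append(stim)
        topics[stim] = m.topic
    stimuli, frames = sorted(stimuli), sorted(frames)
    lookup = {(m.pair, m.scope.rsplit("_", 1)[0], m.frame): m for m in maps}
    if len(lookup) != len(pairs) * len(stimuli) * len(frames):
        raise ValueError("maps do not form a complete pair x stimulus x frame grid")
    n_vox = maps[0].values.size
    Y4 = np.empty((len(pairs), len(stimuli), len(frames), n_vox))
    for pi, pair in enumerate(pairs):
        for si, stim in enumerate(stimuli):
            for fi, frame in enumerate(frames):
                Y4[pi, si, fi] = lookup[(pair, stim, frame)].values
    if grouping == "frame":
        conditions = list(frames)
        cond_of = np.tile(np.arange(len(frames)), (len(stimuli), 1))
    else:
        conditions = sorted({f"{f}_{topics[s]}" for s in stimuli for f in frames})
        cond_of = np.array(
            [[conditions.index(f"{f}_{topics[s]}") for f in frames] for s in stimuli]
        )
    return Y4, pairs, stimuli, conditions, cond_of


def stack_condition_maps(
    maps: Sequence[PairMap],
) -> tuple[np.ndarray, list[tuple[str, str]], list[str], np.ndarray, np.ndarray]:
    """Stack condition-averaged maps into a samples x voxels matrix.

    Returns (Y, pairs, conditions, block_ids, cond_idx): rows ordered by
    (pair, condition); block_ids give the pair index per row (the
    permutation exchangeability blocks) and cond_idx the condition index.
    """
    pairs = sorted({m.pair for m in maps})
    conditions = sorted({m.scope for m in maps})
    lookup = {(m.pair, m.scope): m for m in maps}
    if len(lookup) != len(pairs) * len(conditions):
        raise ValueError("maps do not form a complete pair x condition grid")
    rows, block_ids, cond_idx = [], [], []
    for bi, pair in enumerate(pairs):
        for ci, cond in enumerate(conditions):
            rows.append(lookup[(pair, cond)].values)
            block_ids.append(bi)
            cond_idx.append(ci)
    return (
        np.vstack(rows),
        pairs,
        conditions,
        np.asarray(block_ids),
        np.asarray(cond_idx),
    )
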