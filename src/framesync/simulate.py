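"""Synthetic BOLD cohort with known ground-truth coupling structure.

The generator emulates a within-subject naturalistic-viewing design in which
every participant watches the same clip set — ``n_stimuli`` unique stimuli,
each presented once per framing condition (neutral / threat / blame), every
clip about one of a small set of political topics.  What the downstream
inter-subject correlation (ISC) analysis should recover is planted directly:

* every clip (stimulus x frame segment) owns two shared latent time courses
  ``s_A``, ``s_B`` (smoothed white noise, standardized per segment);
* participant ``i``'s signal voxels during a clip in frame ``f`` contain
  ``kappa_f * (cos(theta_i) * s_A + sin(theta_i) * s_B)``, where the mixing
  angle ``theta_i`` is an affine function of a political covariate, so pairs
  with similar attitudes share a latent mixture and synchronize more;
* on top of the signal: stationary AR(1) noise of marginal sd ``sigma``,
  a slow per-participant drift, and a linear leak of six motion parameters
  that the nuisance-regression stage can remove exactly.

Under this model the population pairwise correlation at a signal voxel is
``kappa_f^2 * cos(theta_i - theta_j) / (kappa_f^2 + sigma^2)`` (see
:func:`expected_pair_isc`), which the test-suite uses as the analytic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from framesync.preprocess import BoldRun

DEFAULT_FRAMES = ("neutral", "threat", "blame")
DEFAULT_TOPICS = ("immigration", "climate", "healthcare")

#: Default frame -> coupling amplitude. Neutral clips synchronize viewers
#: most; blame clips least — the ordering the analysis is built to detect.
DEFAULT_KAPPA = {"neutral": 0.8, "threat": 0.5, "blame": 0.4}


class ScheduleOverflowError(ValueError):
    """Stimulus schedule does not fit in the run."""


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the study design at desk scale.

    27 participants, 12 stimuli x 3 frames = 36 clips of ~100 s at
    TR 1.5 s, on an 8x8x8 grid standing in for the brain.
    """

    n_participants: int = 27
    grid_dims: tuple[int, int, int] = (8, 8, 8)
    voxel_size_mm: float = 2.5
    tr_s: float = 1.5
    n_stimuli: int = 12
    frames: tuple[str, ...] = DEFAULT_FRAMES
    topics: tuple[str, ...] = DEFAULT_TOPICS
    segment_duration_s: float = 100.0
    #: Inter-stimulus gap; the study does not fix one, so it is a knob.
    gap_s: float = 6.0
    kappa_by_frame: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_KAPPA))
    sigma_noise: float = 1.0
    ar1_phi: float = 0.3
    #: Covariate-mixing strength in [0, 1]: 0 -> identical mixing angles for
    #: everyone (no proximity effect); 1 -> angles span the full quarter turn.
    #: A mapping frame -> gamma plants frame-specific proximity effects.
    gamma_proximity: float | Mapping[str, float] = 0.5
    signal_voxel_fraction: float = 0.1
    drift_amplitude: float = 0.5
    motion_amplitude: float = 0.5
    #: Moving-average width (volumes) of the latent streams; band-limits them
    #: the way sluggish hemodynamics band-limit real BOLD.
    latent_smooth_vols: int = 4
    #: Covariate that drives the mixing angle.
    coupling_covariate: str = "pvv_attitude"
    n_volumes: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not (0 <= self.ar1_phi < 1):
            raise ValueError("ar1_phi must lie in [0, 1)")
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be positive")
        if not (0 < self.signal_voxel_fraction <= 1):
            raise ValueError("signal_voxel_fraction must lie in (0, 1]")
        for f, k in self.kappa_by_frame.items():
            if k < 0:
                raise ValueError(f"kappa for frame {f!r} must be >= 0")
        for g in self._gamma_map().values():
            if not (0 <= g <= 1):
                raise ValueError("gamma_proximity must lie in [0, 1]")
        if self.drift_amplitude < 0 or self.motion_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        missing = [f for f in self.frames if f not in self.kappa_by_frame]
        if missing:
            raise ValueError(f"kappa_by_frame missing frames: {missing}")

    def _gamma_map(self) -> dict[str, float]:
        if isinstance(self.gamma_proximity, Mapping):
            return {f: float(self.gamma_proximity.get(f, 0.0)) for f in self.frames}
        return {f: float(self.gamma_proximity) for f in self.frames}

    @property
    def n_segments(self) -> int:
        return self.n_stimuli * len(self.frames)

    @property
    def segment_volumes(self) -> int:
        """Volumes whose acquisition onset falls inside one segment."""
        return len(_volumes_in(0.0, self.segment_duration_s, self.tr_s, 10**9))

    def required_volumes(self) -> int:
        last_onset = self.gap_s + (self.n_segments - 1) * (self.segment_duration_s + self.gap_s)
        return math.ceil((last_onset + self.segment_duration_s + self.gap_s) / self.tr_s)

    def run_volumes(self) -> int:
        req = self.required_volumes()
        if self.n_volumes is None:
            return req
        if self.n_volumes < req:
            raise ScheduleOverflowError(
                f"schedule needs {req} volumes but only {self.n_volumes} are available"
            )
        return self.n_volumes


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    signal_voxel_ids: np.ndarray
    #: segment_id -> (s_A, s_B), each standardized over the segment volumes.
    latent_streams: dict[str, tuple[np.ndarray, np.ndarray]]
    #: participants x frames mixing angles, radians in [0, pi/2].
    mixing_angles: pd.DataFrame
    covariate_table: pd.DataFrame
    config: SimConfig


def _volumes_in(onset_s: float, duration_s: float, tr_s: float, n_vol: int) -> np.ndarray:
    """0-based volumes whose acquisition onset lies in [onset, onset+duration)."""
    first = math.ceil(onset_s / tr_s - 1e-9)
    last = math.ceil((onset_s + duration_s) / tr_s - 1e-9) - 1
    return np.arange(max(first, 0), min(last, n_vol - 1) + 1)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant stream")
    return x / sd


def _latent_stream(rng: np.random.Generator, n: int, width: int) -> np.ndarray:
    """Smoothed (moving average) standardized white noise."""
    w = rng.standard_normal(n + width - 1)
    kernel = np.ones(max(width, 1)) / max(width, 1)
    return _standardize(np.convolve(w, kernel, mode="valid"))


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) rows with marginal sd sigma (innovation sd scaled)."""
    n_series, n_t = shape
    innov = rng.standard_normal((n_series, n_t)) * (sigma * math.sqrt(1.0 - phi**2))
    innov[:, 0] = rng.standard_normal(n_series) * sigma  # stationary start
    if phi == 0:
        return innov
    return lfilter([1.0], [1.0, -phi], innov, axis=1)


def _signal_blob(grid_dims: tuple[int, int, int], fraction: float) -> np.ndarray:
    """Canonical-order linear indices of a compact central blob of voxels.

    A contiguous cluster (not a random scatter) so that cluster-based spatial
    statistics face a realistic target.
    """
    nx, ny, nz = grid_dims
    n_total = nx * ny * nz
    n_signal = max(1, round(fraction * n_total))
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    center = ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    flat_f = d2.ravel(order="F")
    order = np.argsort(flat_f, kind="stable")
    return np.sort(order[:n_signal])


def build_events(config: SimConfig) -> pd.DataFrame:
    """Deterministic clip schedule shared by all participants.

    Stimuli cycle over topics; each stimulus appears once per frame, frames
    nested within stimulus, separated by ``gap_s``.
    """
    rows = []
    onset = config.gap_s
    for k in range(config.n_stimuli):
        stim = f"stim{k + 1:02d}"
        topic = config.topics[k % len(config.topics)]
        for frame in config.frames:
            rows.append(dict(onset=onset, duration=config.segment_duration_s,
                             stimulus_id=stim, frame=frame, topic=topic))
            onset += config.segment_duration_s + config.gap_s
    return pd.DataFrame(rows)


def _covariates(rng: np.random.Generator, config: SimConfig) -> pd.DataFrame:
    pids = [f"sub-{i + 1:02d}" for i in range(config.n_participants)]
    n = config.n_participants
    return pd.DataFrame(
        dict(
            participant_id=pids,
            # 21-point party-attitude scales, -10 (very unsympathetic) .. +10
            pvv_attitude=np.round(rng.uniform(-10, 10, n), 1),
            gl_attitude=np.round(rng.uniform(-10, 10, n), 1),
            # composite authoritarianism score, 0..20
            authoritarianism=np.round(rng.uniform(0, 20, n), 1),
            age=rng.integers(18, 70, n),
            gender=rng.choice([-0.5, 0.5], n),
            education=rng.integers(1, 8, n),
        )
    ).set_index("participant_id")


def mixing_angles(covariates: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Affine map of the coupling covariate onto [0, gamma_f * pi/2].

    Monotone in the covariate; gamma = 0 collapses everyone onto theta = 0.
    """
    x = covariates[config.coupling_covariate].to_numpy(dtype=float)
    span = x.max() - x.min()
    u = np.zeros_like(x) if span == 0 else (x - x.min()) / span
    gmap = config._gamma_map()
    return pd.DataFrame(
        {f: gmap[f] * (math.pi / 2) * u for f in config.frames},
        index=covariates.index,
    )


def expected_pair_isc(config: SimConfig, theta_i: float, theta_j: float,
                      frame: str) -> float:
    """Population signal-voxel correlation for a participant pair.

    With unit-variance latent streams, equal coupling amplitude ``kappa_f``
    for both participants and independent noise of variance ``sigma^2``:

        r = kappa_f^2 * cos(theta_i - theta_j) / (kappa_f^2 + sigma^2)
    """
    k = float(config.kappa_by_frame[frame])
    s2 = config.sigma_noise**2
    return k * k * math.cos(theta_i - theta_j) / (k * k + s2)


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[BoldRun], pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame,
           np.ndarray, GroundTruth]:
    """Generate runs, events, nuisance tables, covariates, mask and truth.

    Deterministic given the config (including its seed): identical configs
    produce bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n_vol = config.run_volumes()
    nx, ny, nz = config.grid_dims
    n_vox = nx * ny * nz

    mask = np.ones(config.grid_dims, dtype=np.uint8)
    signal_ids = _signal_blob(config.grid_dims, config.signal_voxel_fraction)
    events = build_events(config)
    covariates = _covariates(rng, config)
    thetas = mixing_angles(covariates, config)

    # shared latent streams, one pair per clip
    seg_vols: dict[str, np.ndarray] = {}
    latents: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ev in events.itertuples():
        seg_id = f"{ev.stimulus_id}_{ev.frame}"
        vols = _volumes_in(ev.onset, ev.duration, config.tr_s, n_vol)
        seg_vols[seg_id] = vols
        latents[seg_id] = (
            _latent_stream(rng, len(vols), config.latent_smooth_vols),
            _latent_stream(rng, len(vols), config.latent_smooth_vols),
        )

    t_lin = np.linspace(-0.5, 0.5, n_vol)
    t_cos = np.cos(np.pi * np.arange(n_vol) / n_vol)
    motion_cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]

    runs: list[BoldRun] = []
    nuisance: dict[str, pd.DataFrame] = {}
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    for pid in covariates.index:
        data = _ar1_noise(rng, (n_vox, n_vol), config.ar1_phi, config.sigma_noise)

        for ev in events.itertuples():
            seg_id = f"{ev.stimulus_id}_{ev.frame}"
            th = thetas.loc[pid, ev.frame]
            kappa = float(config.kappa_by_frame[ev.frame])
            s_a, s_b = latents[seg_id]
            sig = kappa * (math.cos(th) * s_a + math.sin(th) * s_b)
            data[np.ix_(signal_ids, seg_vols[seg_id])] += sig

        # slow per-participant drift, global over voxels
        a, b = rng.normal(0.0, config.drift_amplitude, 2)
        data += a * t_lin + b * t_cos

        # six motion parameters leaking linearly into every voxel
        steps = rng.standard_normal((n_vol, 6))
        walk = np.cumsum(steps, axis=0)
        walk -= walk.mean(axis=0)
        sd = walk.std(axis=0)
        sd[sd == 0] = 1.0
        motion = walk / sd
        loadings = rng.standard_normal((6, n_vox)) / math.sqrt(6)
        data += config.motion_amplitude * (motion @ loadings).T

        runs.append(
            BoldRun(
                participant_id=str(pid),
                data=data.reshape((nx, ny, nz, n_vol), order="F"),
                tr_s=config.tr_s,
                affine=affine,
                provenance={"source": "framesync.simulate", "seed": config.seed},
            )
        )
        nuisance[str(pid)] = pd.DataFrame(motion, columns=motion_cols)

    truth = GroundTruth(
        signal_voxel_ids=signal_ids,
        latent_streams=latents,
        mixing_angles=thetas,
        covariate_table=covariates,
        config=config,
    )
    return runs, events, nuisance, covariates.reset_index(), mask, truth


# ---------------------------------------------------------------------------
# behavioral survey generator
# ---------------------------------------------------------------------------

NEG_ITEMS = [f"emo_neg{i}" for i in range(1, 7)]
POS_ITEMS = [f"emo_pos{i}" for i in range(1, 7)]

#: Which negative items feed which emotion composite.
FEAR_ITEMS = ["emo_neg1", "emo_neg2"]
ANGER_ITEMS = ["emo_neg3", "emo_neg4"]
OTHER_NEG_ITEMS = ["emo_neg5", "emo_neg6"]


@dataclass
class SurveyConfig:
    """Synthetic survey emulating the framing experiment's behavioral arm.

    Default effects are the study conditions the behavioral stage is meant
    to detect: framing raises anger strongly (blame > threat), fear weakly,
    and blame depresses sharing. Scales: emotion items 0..20 (21-point
    Likert), sharing a 0..20 button-press count.
    """

    n_participants: int = 1800
    design: str = "between"  # "between" (1 clip each) or "within" (all clips)
    n_stimuli: int = 12
    frames: tuple[str, ...] = DEFAULT_FRAMES
    topics: tuple[str, ...] = DEFAULT_TOPICS
    #: frame assignment probabilities for the between design; threat is
    #: oversampled the way common discourse oversamples it.
    frame_shares: Mapping[str, float] = field(
        default_factory=lambda: {"neutral": 0.25, "threat": 0.5, "blame": 0.25}
    )
    anger_effect: Mapping[str, float] = field(
        default_factory=lambda: {"threat": 1.26, "blame": 2.06}
    )
    fear_effect: Mapping[str, float] = field(
        default_factory=lambda: {"threat": 0.29, "blame": 0.0}
    )
    negaff_effect: Mapping[str, float] = field(
        default_factory=lambda: {"threat": 0.41, "blame": 0.57}
    )
    sharing_effect: Mapping[str, float] = field(
        default_factory=lambda: {"threat": 0.0, "blame": -0.20}
    )
    item_baseline: float = 8.0
    sharing_baseline: float = 6.0
    importance_baseline: float = 12.0
    item_noise_sd: float = 3.0
    participant_sd: float = 1.5
    seed: int = 0


def _frame_assignment(rng: np.random.Generator, cfg: SurveyConfig) -> np.ndarray:
    """Counterbalanced frame labels matching the configured shares exactly."""
    n = cfg.n_participants
    counts = {f: int(round(cfg.frame_shares.get(f, 0) * n)) for f in cfg.frames}
    counts[cfg.frames[0]] += n - sum(counts.values())  # rounding remainder
    labels = np.concatenate([np.repeat(f, c) for f, c in counts.items()])
    return rng.permutation(labels)


def simulate_survey(cfg: SurveyConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a survey table plus the injected ground-truth coefficients.

    Returns (table, truth) where truth["composite_effects"] holds the
    frame -> shift implied for each emotion composite, and truth
    ["sharing_effects"] the frame -> shift of the sharing count.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    pids = [f"resp-{i + 1:04d}" for i in range(n)]

    covs = pd.DataFrame(
        dict(
            participant_id=pids,
            age=rng.integers(18, 80, n),
            gender=rng.choice([-0.5, 0.5], n),
            education=rng.integers(1, 8, n),
            ideology=rng.integers(1, 8, n),
            pvv_attitude=np.round(rng.uniform(-10, 10, n), 1),
            gl_attitude=np.round(rng.uniform(-10, 10, n), 1),
            authoritarianism=np.round(rng.uniform(0, 20, n), 1),
            skepticism=np.round(rng.uniform(0, 20, n), 1),
        )
    )
    intercepts = rng.normal(0.0, cfg.participant_sd, n)

    if cfg.design == "between":
        frames = _frame_assignment(rng, cfg)
        topics = np.array(cfg.topics)[np.arange(n) % len(cfg.topics)]
        rows = pd.DataFrame(dict(participant_id=pids, frame=frames, topic=topics))
        rows = rows.merge(covs, on="participant_id", how="left")
        part_eff = np.repeat(intercepts, 1)
    elif cfg.design == "within":
        clip_frames = np.tile(np.repeat(list(cfg.frames), cfg.n_stimuli), n)
        clip_topics = np.tile(
            np.array(cfg.topics)[np.arange(cfg.n_stimuli) % len(cfg.topics)],
            n * len(cfg.frames),
        )
        n_rows_per = cfg.n_stimuli * len(cfg.frames)
        rows = pd.DataFrame(
            dict(
                participant_id=np.repeat(pids, n_rows_per),
                frame=clip_frames,
                topic=clip_topics,
            )
        ).merge(covs, on="participant_id", how="left")
        part_eff = np.repeat(intercepts, n_rows_per)
    else:
        raise ValueError(f"unknown design {cfg.design!r}")

    def eff(mapping: Mapping[str, float], frames: np.ndarray) -> np.ndarray:
        return np.array([mapping.get(f, 0.0) for f in frames])

    frames_arr = rows["frame"].to_numpy()
    m = len(rows)
    item_effects: dict[str, np.ndarray] = {}
    for item in FEAR_ITEMS:
        item_effects[item] = eff(cfg.fear_effect, frames_arr)
    for item in ANGER_ITEMS:
        item_effects[item] = eff(cfg.anger_effect, frames_arr)
    for item in OTHER_NEG_ITEMS:
        item_effects[item] = eff(cfg.negaff_effect, frames_arr)
    for item in POS_ITEMS:
        item_effects[item] = np.zeros(m)

    for item in NEG_ITEMS + POS_ITEMS:
        raw = (cfg.item_baseline + item_effects[item] + part_eff
               + rng.normal(0.0, cfg.item_noise_sd, m))
        rows[item] = np.clip(raw, 0.0, 20.0)

    rows["issue_importance"] = np.clip(
        cfg.importance_baseline + part_eff + rng.normal(0, cfg.item_noise_sd, m), 0, 20
    )
    sharing_raw = (cfg.sharing_baseline + eff(cfg.sharing_effect, frames_arr)
                   + part_eff + rng.normal(0.0, cfg.item_noise_sd, m))
    rows["sharing"] = np.clip(np.round(sharing_raw), 0, 20)

    def composite_truth(items: Sequence[str]) -> dict[str, float]:
        return {
            f: float(np.mean([
                (cfg.fear_effect if it in FEAR_ITEMS
                 else cfg.anger_effect if it in ANGER_ITEMS
                 else cfg.negaff_effect).get(f, 0.0)
                for it in items
            ]))
            for f in cfg.frames if f != "neutral"
        }

    truth = dict(
        composite_effects=dict(
            fear=composite_truth(FEAR_ITEMS),
            anger=composite_truth(ANGER_ITEMS),
            negative_affect=composite_truth(NEG_ITEMS),
            positive_affect={f: 0.0 for f in cfg.frames if f != "neutral"},
        ),
        sharing_effects={f: cfg.sharing_effect.get(f, 0.0)
                         for f in cfg.frames if f != "neutral"},
        config=cfg,
    )
    return rows, truth
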