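"""End-to-end orchestration: simulate -> preprocess -> ISC -> inference.

``run_pipeline`` drives every stage from one RunConfig with a single seed,
records per-stage parameters and output hashes in a JSON report, and skips
the (expensive) simulation stage when a dataset with a matching manifest
already exists. The numbered scripts under ``analysis/`` are thin drivers
over this module.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from framesync import io as fio
from framesync.behavior import composite_scores, fit_framing_model
from framesync.inference import TFCEParams, permute_and_correct_segments
from framesync.isc import (
    all_pair_maps,
    average_by_condition,
    baseline_map,
    stack_segment_maps,
    subtract_baseline,
)
from framesync.preprocess import extract_segments, regress_out_nuisance
from framesync.proximity import build_proximity_design, isc_proximity_regression
from framesync.simulate import SimConfig, SurveyConfig, simulate_cohort, simulate_survey

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible end-to-end run needs."""

    seed: int
    out_dir: str
    sim: SimConfig | None = None
    dataset_dir: str | None = None
    n_exclude_volumes: int = 8
    grouping: str = "frame"
    baseline: str = "none"  # "none" | "subtract" (contrast path)
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("neutral", "threat"), ("neutral", "blame")]
    )
    n_permutations: int = 1000
    tfce: TFCEParams = field(default_factory=TFCEParams)
    proximity_variables: list[str] = field(
        default_factory=lambda: ["pvv_attitude", "authoritarianism"]
    )
    proximity_conditions: list[str] = field(default_factory=lambda: ["threat", "blame"])
    fwe: str = "within"
    alpha: float = 0.05
    survey: SurveyConfig | None = None
    write_volumes: bool = False

    def __post_init__(self) -> None:
        if self.sim is None and self.dataset_dir is None:
            raise ValueError("config needs either a SimConfig or a dataset_dir")
        if self.baseline not in ("none", "subtract"):
            raise ValueError("baseline must be 'none' or 'subtract'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            for k in ("grid_dims", "frames", "topics"):
                if k in sim:
                    sim[k] = tuple(sim[k])
            raw["sim"] = SimConfig(**sim)
        if "tfce" in raw and raw["tfce"] is not None:
            raw["tfce"] = TFCEParams(**raw["tfce"])
        if "survey" in raw and raw["survey"] is not None:
            raw["survey"] = SurveyConfig(**raw["survey"])
        if "contrasts" in raw:
            raw["contrasts"] = [tuple(c) for c in raw["contrasts"]]
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the scientific configuration (stage-skip key).

        The output directory is a storage choice, not part of the analysis,
        so it does not enter the digest.
        """
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(_jsonable(payload), sort_keys=True).encode()
        ).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def prepare_segments(
    runs,
    events: pd.DataFrame,
    nuisance: dict[str, pd.DataFrame],
    mask: np.ndarray,
    n_exclude_volumes: int = 8,
):
    """Nuisance-regress every run and cut it into masked segments.

    Returns (segment_table, series) with series[participant][segment_id]
    ready for pair-map computation.
    """
    series = {}
    seg_table = None
    for run in runs:
        clean = regress_out_nuisance(run, nuisance[run.participant_id])
        seg_table, segs = extract_segments(
            clean, events, mask, n_exclude_volumes=n_exclude_volumes
        )
        series[run.participant_id] = segs
    return seg_table, series


def pair_baselines(series, seed: int = 0):
    """Unmatched-segment baseline map for every participant pair."""
    import itertools

    pids = sorted(series)
    return {
        (i, j): baseline_map((i, j), series[i], series[j], seed=seed)
        for i, j in itertools.combinations(pids, 2)
    }


def _simulate_stage(config: RunConfig, out: Path):
    """Simulate (or reuse) the cohort; returns in-memory objects."""
    if config.dataset_dir is not None:
        runs, events, nuisance, covariates, mask = fio.read_dataset(config.dataset_dir)
        return runs, events, nuisance, covariates, mask, None, "loaded"
    assert config.sim is not None
    data_dir = out / "dataset"
    stamp = data_dir / "config_digest.txt"
    digest = config.digest()
    if config.write_volumes and stamp.exists() and stamp.read_text() == digest:
        logger.info("simulate: outputs exist with matching digest, skipping")
        runs, events, nuisance, covariates, mask = fio.read_dataset(data_dir)
        return runs, events, nuisance, covariates, mask, None, "skipped"
    runs, events, nuisance, covariates, mask, truth = simulate_cohort(config.sim)
    if config.write_volumes:
        fio.write_dataset(data_dir, runs, events, nuisance, covariates, mask, truth)
        stamp.write_text(digest)
    return runs, events, nuisance, covariates, mask, truth, "ran"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return (and write) the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_digest": config.digest(), "seed": config.seed, "stages": {}}

    # --- simulate / load -------------------------------------------------
    runs, events, nuisance, covariates, mask, truth, status = _simulate_stage(config, out)
    report["stages"]["simulate"] = dict(
        status=status,
        n_participants=len(runs),
        n_events=len(events),
    )

    # --- preprocess ------------------------------------------------------
    seg_table, series = prepare_segments(
        runs, events, nuisance, mask, n_exclude_volumes=config.n_exclude_volumes
    )
    report["stages"]["preprocess"] = dict(
        n_segments=len(seg_table),
        n_exclude_volumes=config.n_exclude_volumes,
    )

    # --- ISC -------------------------------------------------------------
    maps = all_pair_maps(series, seg_table)
    baselines = pair_baselines(series, seed=config.seed)

    contrast_maps = maps
    if config.baseline == "subtract":
        contrast_maps = [subtract_baseline(m, baselines[m.pair]) for m in maps]
    report["stages"]["isc"] = dict(
        n_pair_maps=len(maps), grouping=config.grouping, baseline=config.baseline
    )

    # --- condition contrasts --------------------------------------------
    Y4, pairs, stimuli, conditions, cond_of = stack_segment_maps(
        contrast_maps, grouping=config.grouping
    )
    voxel_ids = np.flatnonzero(np.asarray(mask).ravel(order="F"))
    contrast_spec = [
        (f"{a}>{b}", conditions.index(a), conditions.index(b))
        for a, b in config.contrasts
        if a in conditions and b in conditions
    ]
    results = permute_and_correct_segments(
        Y4,
        cond_of,
        contrast_spec,
        mask.astype(bool),
        voxel_ids,
        params=config.tfce,
        n_perm=config.n_permutations,
        seed=config.seed,
        fwe=config.fwe,
    )
    contrast_summary = []
    for r in results:
        sig = (r.p_fwe <= config.alpha) & mask.astype(bool)
        contrast_summary.append(
            dict(
                contrast=r.contrast,
                n_suprathreshold=int(sig.sum()),
                min_p_fwe=float(r.p_fwe[mask.astype(bool)].min()),
                max_tfce=float(r.observed_tfce.max()),
                n_permutations=r.n_permutations,
            )
        )
        if config.write_volumes:
            fio.save_volume(r.observed_stat, runs[0].affine, out / f"{r.contrast}_t.nii")
            fio.save_volume(1.0 - r.p_fwe, runs[0].affine, out / f"{r.contrast}_1mp.nii")
    report["stages"]["contrast"] = contrast_summary

    # --- proximity regression (baseline-subtracted path) -----------------
    prox_summary = []
    if config.proximity_variables and config.proximity_conditions:
        corrected = [subtract_baseline(m, baselines[m.pair]) for m in maps]
        cond_corrected = average_by_condition(corrected, grouping="frame")
        wanted = [m for m in cond_corrected if m.frame in config.proximity_conditions]
        by_pair: dict[tuple[str, str], list[np.ndarray]] = {}
        for m in wanted:
            by_pair.setdefault(m.pair, []).append(m.values)
        pair_list = sorted(by_pair)
        Yp = np.vstack([np.mean(by_pair[p], axis=0) for p in pair_list])
        design = build_proximity_design(
            covariates, pair_list, config.proximity_variables
        )
        prox = isc_proximity_regression(
            Yp,
            design,
            mask.astype(bool),
            voxel_ids,
            params=config.tfce,
            n_perm=config.n_permutations,
            seed=config.seed,
        )
        for v, r in prox.items():
            sig = (r.p_fwe <= config.alpha) & mask.astype(bool)
            prox_summary.append(
                dict(
                    variable=v,
                    conditions=list(config.proximity_conditions),
                    n_suprathreshold=int(sig.sum()),
                    min_p_fwe=float(r.p_fwe[mask.astype(bool)].min()),
                    max_tfce=float(r.observed_tfce.max()),
                )
            )
    report["stages"]["proximity"] = prox_summary

    # --- behavior ---------------------------------------------------------
    if config.survey is not None:
        table, struth = simulate_survey(config.survey)
        table = composite_scores(table)
        rows = []
        for outcome in ("negative_affect", "anger", "fear", "sharing"):
            fit = fit_framing_model(
                table, outcome, covariates=("age", "gender"),
                within_subject=config.survey.design == "within",
            )
            for frame in ("threat", "blame"):
                co = fit.coef(f"frame[{frame}]")
                rows.append(
                    dict(outcome=outcome, frame=frame,
                         estimate=float(co["estimate"]), se=float(co["se"]),
                         p=float(co["p"]))
                )
        report["stages"]["behavior"] = rows

    report_path = out / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))
    report["report_path"] = str(report_path)
    return report
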