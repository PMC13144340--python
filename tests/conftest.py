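"""Shared fixtures: small synthetic cohorts analyzed end to end."""

from __future__ import annotations

import numpy as np
import pytest

from framesync.isc import all_pair_maps
from framesync.pipeline import prepare_segments
from framesync.simulate import SimConfig, simulate_cohort


def analyze_cohort(config: SimConfig):
    """simulate -> nuisance-regress -> segment: the common test pathway."""
    runs, events, nuisance, covariates, mask, truth = simulate_cohort(config)
    seg_table, series = prepare_segments(runs, events, nuisance, mask)
    return dict(
        runs=runs,
        events=events,
        nuisance=nuisance,
        covariates=covariates,
        mask=mask,
        truth=truth,
        seg_table=seg_table,
        series=series,
    )


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_participants=4,
        grid_dims=(4, 4, 4),
        n_stimuli=2,
        segment_duration_s=60.0,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 participants, 4x4x4 grid, 6 segments; equal coupling, no proximity."""
    cfg = small_config(
        gamma_proximity=0.0,
        kappa_by_frame={"neutral": 1.0, "threat": 1.0, "blame": 1.0},
        seed=42,
    )
    out = analyze_cohort(cfg)
    out["config"] = cfg
    out["maps"] = all_pair_maps(out["series"], out["seg_table"])
    return out


def signal_and_noise_indices(truth, n_vox):
    sig = truth.signal_voxel_ids
    return sig, np.setdiff1d(np.arange(n_vox), sig)
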