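"""Dyadic regression of synchrony on covariate proximity.

Pairs of participants who score similarly on a political covariate should —
if framing polarizes processing — synchronize more. The regressor for a
pair (i, j) is the *proximity* -|x_i - x_j|: zero for identical scores,
increasingly negative with attitude distance. Inference permutes at the
subject level (shuffle the covariate over participants, rebuild all pair
proximities, refit), which respects the dependence between pairs sharing a
participant; other predictors stay in the model as fixed covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from framesync.inference import (
    PermResult,
    TFCEParams,
    _vector_to_map,
    glm_contrast_stat,
    tfce,
)

logger = logging.getLogger(__name__)


@dataclass
class ProximityDesign:
    """Per-pair regressor matrix: intercept + proximity columns.

    Row order matches ``pairs``. ``covariate_table`` holds the (optionally
    standardized) per-participant scores the proximity columns were built
    from, which the subject-level permutation scheme reshuffles.
    """

    pairs: list[tuple[str, str]]
    variables: list[str]
    X: pd.DataFrame
    covariate_table: pd.DataFrame
    standardized_covariates: bool
    standardized_columns: bool

    @property
    def matrix(self) -> np.ndarray:
        return self.X.to_numpy(dtype=np.float64)


def proximity_column(scores: pd.Series, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
    """-|x_i - x_j| per pair; 0 only for identical scores."""
    x = scores.to_dict()
    return np.array([-abs(x[i] - x[j]) for i, j in pairs])


def build_proximity_design(
    covariates: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    variables: Sequence[str],
    standardize_covariates: bool = True,
    standardize_columns: bool = False,
) -> ProximityDesign:
    """Build the dyadic design from a per-participant covariate table.

    ``covariates`` must be indexed by participant_id (or carry that column).
    Covariates are z-scored across participants before proximity
    construction by default, making 21-point attitude scales and composite
    scores commensurable; proximity columns themselves can optionally be
    z-scored afterwards.
    """
    if "participant_id" in covariates.columns:
        covariates = covariates.set_index("participant_id")
    needed = sorted({p for pair in pairs for p in pair})
    missing = [p for p in needed if p not in covariates.index]
    if missing:
        raise ValueError(f"covariate table missing participants: {missing}")
    table = covariates.loc[needed, list(variables)].astype(float).copy()
    for v in variables:
        col = table[v]
        if col.isna().any():
            bad = sorted(col.index[col.isna()])
            raise ValueError(f"covariate {v!r} missing for participants: {bad}")
        if col.std(ddof=0) == 0:
            raise ValueError(
                f"covariate {v!r} has zero variance; proximity column would be all zeros"
            )
        if standardize_covariates:
            table[v] = (col - col.mean()) / col.std(ddof=0)

    X = pd.DataFrame({"intercept": np.ones(len(pairs))})
    for v in variables:
        col = proximity_column(table[v], pairs)
        if standardize_columns:
            col = (col - col.mean()) / col.std(ddof=0)
        X[f"proximity_{v}"] = col
    M = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("proximity design is collinear")
    return ProximityDesign(
        pairs=list(pairs),
        variables=list(variables),
        X=X,
        covariate_table=table,
        standardized_covariates=standardize_covariates,
        standardized_columns=standardize_columns,
    )


def drop_missing_participants(
    covariates: pd.DataFrame, variables: Sequence[str]
) -> pd.DataFrame:
    """Drop participants with any missing selected covariate, logging the count."""
    if "participant_id" in covariates.columns:
        covariates = covariates.set_index("participant_id")
    keep = covariates[list(variables)].notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d participants with missing covariates", n_drop)
    return covariates.loc[keep]


def _regress_variable(
    Y: np.ndarray,
    design: ProximityDesign,
    variable: str,
    mask: np.ndarray,
    voxel_ids: np.ndarray,
    params: TFCEParams,
    n_perm: int,
    seed: int,
) -> PermResult:
    col = f"proximity_{variable}"
    names = list(design.X.columns)
    j = names.index(col)
    X = design.matrix.copy()
    c = np.zeros(X.shape[1])
    c[j] = 1.0

    mask = np.asarray(mask).astype(bool)

    def stat_and_tfce(Xcur: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = glm_contrast_stat(Y, Xcur, c)
        t_map = _vector_to_map(t, voxel_ids, mask.shape)
        return t, tfce(t_map, mask, params)

    t_obs, tfce_obs = stat_and_tfce(X)

    rng = np.random.default_rng(seed)
    scores = design.covariate_table[variable]
    pids = list(scores.index)
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = pd.Series(
            rng.permutation(scores.to_numpy()), index=pids
        )
        col_perm = proximity_column(shuffled, design.pairs)
        if design.standardized_columns:
            col_perm = (col_perm - col_perm.mean()) / col_perm.std()
        Xp = X.copy()
        Xp[:, j] = col_perm
        _, tf = stat_and_tfce(Xp)
        max_null[b] = max(tf[mask].max(), 0.0)

    obs = tfce_obs[mask]
    p_vec = (1.0 + (max_null[None, :] >= obs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    p_map = np.ones(mask.shape)
    p_map[mask] = p_vec
    return PermResult(
        contrast=col,
        observed_stat=_vector_to_map(t_obs, voxel_ids, mask.shape),
        observed_tfce=tfce_obs,
        max_null=max_null,
        p_fwe=p_map,
        n_permutations=n_perm,
        seed=seed,
        fwe_scope="within",
    )


def isc_proximity_regression(
    Y: np.ndarray,
    design: ProximityDesign,
    mask: np.ndarray,
    voxel_ids: np.ndarray,
    params: TFCEParams | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    variables: Sequence[str] | None = None,
) -> dict[str, PermResult]:
    """Voxel-wise regression of baseline-subtracted z-ISC on proximity.

    Y is pairs x voxels, rows in ``design.pairs`` order. Each requested
    variable is tested with the others held as covariates (partial t),
    against a subject-level permutation null with TFCE + FWE as in the
    condition contrasts.
    """
    params = params or TFCEParams()
    if Y.shape[0] != len(design.pairs):
        raise ValueError(
            f"Y has {Y.shape[0]} rows but design lists {len(design.pairs)} pairs"
        )
    variables = list(variables) if variables is not None else design.variables
    return {
        v: _regress_variable(
            Y, design, v, mask, voxel_ids, params, n_perm, seed + k
        )
        for k, v in enumerate(variables)
    }


def condition_moderation(
    Y_by_condition: Mapping[str, np.ndarray],
    cond_a: str,
    cond_b: str,
    design: ProximityDesign,
    mask: np.ndarray,
    voxel_ids: np.ndarray,
    params: TFCEParams | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    variables: Sequence[str] | None = None,
) -> dict[str, PermResult]:
    """Contrast of proximity coefficients between two conditions.

    Regresses the per-pair difference map (cond_a - cond_b) on the same
    dyadic design; a positive proximity effect means attitude distance
    predicts desynchronization more strongly in cond_a than cond_b.
    """
    for c in (cond_a, cond_b):
        if c not in Y_by_condition:
            raise ValueError(f"condition {c!r} missing from Y_by_condition")
    diff = Y_by_condition[cond_a] - Y_by_condition[cond_b]
    out = isc_proximity_regression(
        diff, design, mask, voxel_ids, params, n_perm, seed, variables
    )
    return {
        v: PermResult(
            contrast=f"{r.contrast}:{cond_a}-{cond_b}",
            observed_stat=r.observed_stat,
            observed_tfce=r.observed_tfce,
            max_null=r.max_null,
            p_fwe=r.p_fwe,
            n_permutations=r.n_permutations,
            seed=r.seed,
            fwe_scope=r.fwe_scope,
        )
        for v, r in out.items()
    }
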