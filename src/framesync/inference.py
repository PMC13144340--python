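"""Block-restricted permutation inference with TFCE and FWE control.

The GLM is a voxel-wise repeated-measures design: condition indicators plus
a mean-effect regressor per participant pair; the null distribution is
built by shuffling condition labels only *within* each pair's rows, so the
dyadic dependence structure is never broken. Spatial statistics use
threshold-free cluster enhancement (TFCE), and family-wise error is
controlled with the permutation max-TFCE distribution, either within one
contrast or jointly over a contrast family. An optional generalized-Pareto
tail refinement sharpens small p-values beyond the 1/(n+1) empirical floor.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

#: Guard cap for t statistics in zero-residual degeneracies.
T_CAP = 1e6

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class TFCEParams:
    """TFCE settings: extent exponent E, height exponent H, step dh.

    dh = None means max|stat| / 100, recomputed per map. Connectivity is the
    3D neighbourhood (6 faces, 18 +edges, 26 +corners).
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be one of 6, 18, 26")


@dataclass
class ExchangeabilityScheme:
    """One block per participant pair; permutation only within blocks."""

    block_ids: np.ndarray
    within_block_only: bool = True

    def __post_init__(self) -> None:
        self.block_ids = np.asarray(self.block_ids)
        if self.block_ids.ndim != 1:
            raise ValueError("block_ids must be 1D")


@dataclass
class PermResult:
    """Observed and permutation statistics for one contrast."""

    contrast: str
    observed_stat: np.ndarray
    observed_tfce: np.ndarray
    max_null: np.ndarray
    p_fwe: np.ndarray
    n_permutations: int
    seed: int
    tail_approximated: bool = False
    exhaustive: bool = False
    fwe_scope: str = "within"
    permutation_log: list[np.ndarray] | None = field(default=None, repr=False)


def _tfce_one_sided(vals: np.ndarray, params: TFCEParams, dh: float) -> np.ndarray:
    """TFCE integral over positive thresholds for a non-negative map."""
    out = np.zeros_like(vals)
    vmax = vals.max()
    if vmax <= 0:
        return out
    structure = _STRUCTURES[params.connectivity]
    h = dh
    while h <= vmax + 1e-12:
        above = vals >= h
        labels, n = ndimage.label(above, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        contrib = (sizes.astype(np.float64) ** params.E) * (h**params.H) * dh
        contrib[0] = 0.0
        out += contrib[labels]
        h += dh
    return out


def tfce(stat_map: np.ndarray, mask: np.ndarray, params: TFCEParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed 3D statistic map.

    TFCE(p) = sum over thresholds h (step dh, up to the voxel's height) of
    extent(p, h)^E * h^H * dh, where extent is the size of the connected
    suprathreshold component containing p. Negative values are enhanced on
    the negated map and re-signed.
    """
    params = params or TFCEParams()
    stat_map = np.asarray(stat_map, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if stat_map.shape != mask.shape:
        raise ValueError("stat map and mask shapes differ")
    if not np.all(np.isfinite(stat_map[mask])):
        raise ValueError("stat map must be finite inside the mask")
    vmax = np.abs(stat_map[mask]).max() if mask.any() else 0.0
    if vmax == 0:
        return np.zeros_like(stat_map)
    dh = params.dh if params.dh is not None else vmax / 100.0
    pos = np.where(mask & (stat_map > 0), stat_map, 0.0)
    neg = np.where(mask & (stat_map < 0), -stat_map, 0.0)
    out = _tfce_one_sided(pos, params, dh) - _tfce_one_sided(neg, params, dh)
    out[~mask] = 0.0
    return out


def build_condition_design(
    block_ids: np.ndarray, cond_idx: np.ndarray, n_conditions: int
) -> np.ndarray:
    """Design: one indicator per condition + pair mean-effect regressors.

    Pair regressors (all blocks but the first, to keep full column rank)
    absorb the repeated-measures dependence between a pair's condition maps.
    """
    n = len(block_ids)
    blocks = np.unique(block_ids)
    X = np.zeros((n, n_conditions + len(blocks) - 1))
    X[np.arange(n), cond_idx] = 1.0
    for k, b in enumerate(blocks[1:]):
        X[block_ids == b, n_conditions + k] = 1.0
    return X


def contrast_vector(n_columns: int, cond_a: int, cond_b: int) -> np.ndarray:
    """Contrast c with +1 on condition a, -1 on condition b, zeros elsewhere."""
    c = np.zeros(n_columns)
    c[cond_a] = 1.0
    c[cond_b] = -1.0
    return c


def glm_contrast_stat(
    Y: np.ndarray, X: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Voxel-wise OLS t statistic for contrast c over design X.

    Y is samples x voxels. Zero-residual degeneracies are capped at
    |t| = 1e6 with the sign of the effect.
    """
    Y = np.asarray(Y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(
            f"design is rank deficient (rank {rank} < {p} columns)"
        )
    if n <= rank:
        raise ValueError("no residual degrees of freedom")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - rank
    sigma2 = (resid * resid).sum(axis=0) / dof
    xtx_inv = pinv @ pinv.T
    c_var = float(c @ xtx_inv @ c)
    effect = c @ beta
    se = np.sqrt(sigma2 * c_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    degenerate = se == 0
    t[degenerate] = np.sign(effect[degenerate]) * T_CAP
    return np.clip(t, -T_CAP, T_CAP)


def _count_relabelings(block_ids: np.ndarray) -> float:
    """Number of distinct within-block row permutations (may be huge)."""
    total = 1.0
    for b in np.unique(block_ids):
        total *= math.factorial(int((block_ids == b).sum()))
        if total > 1e18:
            return math.inf
    return total


def _exhaustive_permutations(block_ids: np.ndarray) -> list[np.ndarray]:
    """All distinct within-block permutations as row index arrays."""
    n = len(block_ids)
    per_block = []
    for b in np.unique(block_ids):
        rows = np.flatnonzero(block_ids == b)
        per_block.append([np.asarray(p) for p in itertools.permutations(rows)])
    perms = []
    for combo in itertools.product(*per_block):
        idx = np.empty(n, dtype=np.intp)
        for rows_src, rows_perm in zip(
            (np.flatnonzero(block_ids == b) for b in np.unique(block_ids)), combo
        ):
            idx[rows_src] = rows_perm
        perms.append(idx)
    return perms


def _random_permutation(
    rng: np.random.Generator, block_ids: np.ndarray
) -> np.ndarray:
    idx = np.arange(len(block_ids))
    for b in np.unique(block_ids):
        rows = np.flatnonzero(block_ids == b)
        idx[rows] = rng.permutation(rows)
    return idx


def _vector_to_map(values: np.ndarray, voxel_ids: np.ndarray,
                   grid_dims: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros(int(np.prod(grid_dims)))
    out[voxel_ids] = values
    return out.reshape(grid_dims, order="F")


def permute_and_correct(
    Y: np.ndarray,
    block_ids: np.ndarray,
    cond_idx: np.ndarray,
    contrasts: list[tuple[str, int, int]],
    mask: np.ndarray,
    voxel_ids: np.ndarray,
    params: TFCEParams | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    fwe: str = "within",
    log_permutations: bool = False,
) -> list[PermResult]:
    """Permutation test of condition contrasts with TFCE and FWE correction.

    Y is samples x voxels (rows = pair x condition maps); contrasts are
    (name, condition_index_a, condition_index_b) tested one-sided as a > b.
    Condition labels are shuffled independently within each pair block; the
    unpermuted labeling contributes the "+1" of the exact permutation p:
    p(v) = (1 + #{perm max-TFCE >= observed TFCE(v)}) / (n_perm + 1). With
    fwe="across", the null maximum is taken over the whole contrast family.
    If the relabeling space is smaller than n_perm, it is enumerated
    exhaustively (with a warning) and p = #{>= observed} / N.
    """
    if fwe not in ("within", "across"):
        raise ValueError("fwe must be 'within' or 'across'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    params = params or TFCEParams()
    mask = np.asarray(mask).astype(bool)
    n_cond = int(cond_idx.max()) + 1
    X = build_condition_design(block_ids, cond_idx, n_cond)
    cvecs = {
        name: contrast_vector(X.shape[1], a, b) for name, a, b in contrasts
    }

    mask_flat = mask.ravel(order="F")[voxel_ids]

    def tfce_of(Yp: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for name, c in cvecs.items():
            t = glm_contrast_stat(Yp, X, c)
            t_map = _vector_to_map(t, voxel_ids, mask.shape)
            out[name] = (t, tfce(t_map, mask, params))
        return out

    observed = tfce_of(Y)

    n_distinct = _count_relabelings(block_ids)
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        warnings.warn(
            f"only {int(n_distinct)} distinct within-block relabelings; "
            "enumerating exhaustively",
            stacklevel=2,
        )
        perms = _exhaustive_permutations(block_ids)
    else:
        rng = np.random.default_rng(seed)
        perms = [_random_permutation(rng, block_ids) for _ in range(n_perm)]

    log: list[np.ndarray] = []
    maxima = {name: [] for name in cvecs}
    for idx in perms:
        if log_permutations:
            log.append(idx.copy())
        enhanced = tfce_of(Y[idx])
        for name, (_, tf) in enhanced.items():
            maxima[name].append(max(tf[mask].max(), 0.0))

    max_by_contrast = {name: np.asarray(v) for name, v in maxima.items()}
    if fwe == "across":
        joint = np.max(np.vstack(list(max_by_contrast.values())), axis=0)
        null_for = {name: joint for name in cvecs}
    else:
        null_for = max_by_contrast

    results = []
    for name in cvecs:
        t_vec, tf_map = observed[name]
        obs = tf_map[mask]
        null = null_for[name]
        if exhaustive:
            p_vec = (null[None, :] >= obs[:, None]).sum(axis=1) / len(null)
            p_vec = np.maximum(p_vec, 1.0 / len(null))
        else:
            p_vec = (1.0 + (null[None, :] >= obs[:, None]).sum(axis=1)) / (
                len(null) + 1.0
            )
        p_map = np.ones(mask.shape)
        p_map[mask] = p_vec
        results.append(
            PermResult(
                contrast=name,
                observed_stat=_vector_to_map(t_vec, voxel_ids, mask.shape),
                observed_tfce=tf_map,
                max_null=null_for[name],
                p_fwe=p_map,
                n_permutations=len(perms),
                seed=seed,
                exhaustive=exhaustive,
                fwe_scope=fwe,
                permutation_log=log if log_permutations else None,
            )
        )
    return results


def permute_and_correct_segments(
    Y4: np.ndarray,
    cond_of: np.ndarray,
    contrasts: list[tuple[str, int, int]],
    mask: np.ndarray,
    voxel_ids: np.ndarray,
    params: TFCEParams | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    fwe: str = "within",
    log_permutations: bool = False,
) -> list[PermResult]:
    """Contrast inference with coherent within-stimulus frame relabeling.

    Y4 is (pairs, stimuli, frame-slots, voxels) per-segment z-maps;
    cond_of[s, f] gives the condition index of stimulus s in frame slot f.
    Each permutation draws one frame-slot permutation per stimulus and
    applies it to *every* pair: samples still move only between conditions
    of their own participant pair, but the relabeling is shared across
    pairs, so the dependence between pairs that share a participant (or a
    stimulus set) is preserved under the null. The per-pair condition
    means are then re-averaged and pushed through the same GLM
    (condition indicators + pair mean-effect regressors), TFCE and
    max-statistic FWE machinery as :func:`permute_and_correct`.
    """
    if fwe not in ("within", "across"):
        raise ValueError("fwe must be 'within' or 'across'")
    params = params or TFCEParams()
    mask = np.asarray(mask).astype(bool)
    P, S, F, V = Y4.shape
    cond_of = np.asarray(cond_of)
    if cond_of.shape != (S, F):
        raise ValueError(f"cond_of must be (stimuli, frames) = ({S}, {F})")
    n_cond = int(cond_of.max()) + 1

    block_ids = np.repeat(np.arange(P), n_cond)
    cond_idx = np.tile(np.arange(n_cond), P)
    X = build_condition_design(block_ids, cond_idx, n_cond)
    cvecs = {name: contrast_vector(X.shape[1], a, b) for name, a, b in contrasts}

    sel = cond_of.ravel()
    members = [np.flatnonzero(sel == c) for c in range(n_cond)]
    if any(len(m) == 0 for m in members):
        raise ValueError("every condition needs at least one segment")

    def cond_mean_rows(slot_perm: np.ndarray) -> np.ndarray:
        Yg = np.take_along_axis(Y4, slot_perm[None, :, :, None], axis=2)
        flat = Yg.reshape(P, S * F, V)
        out = np.empty((P, n_cond, V))
        for c in range(n_cond):
            out[:, c] = flat[:, members[c]].mean(axis=1)
        return out.reshape(P * n_cond, V)

    def tfce_of(rows: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for name, c in cvecs.items():
            t = glm_contrast_stat(rows, X, c)
            out[name] = (t, tfce(_vector_to_map(t, voxel_ids, mask.shape), mask, params))
        return out

    identity = np.tile(np.arange(F), (S, 1))
    observed = tfce_of(cond_mean_rows(identity))

    n_distinct = float(math.factorial(F)) ** S
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        warnings.warn(
            f"only {int(n_distinct)} distinct within-stimulus relabelings; "
            "enumerating exhaustively",
            stacklevel=2,
        )
        per_stim = list(itertools.permutations(range(F)))
        slot_perms = [np.array(combo) for combo in itertools.product(per_stim, repeat=S)]
    else:
        rng = np.random.default_rng(seed)
        slot_perms = [
            np.vstack([rng.permutation(F) for _ in range(S)]) for _ in range(n_perm)
        ]

    log: list[np.ndarray] = []
    maxima = {name: [] for name in cvecs}
    for sp in slot_perms:
        if log_permutations:
            # global row-index form over (pair, stimulus, slot)-ordered rows
            base = (np.arange(P * S) * F)[:, None]
            log.append((base + np.tile(sp, (P, 1))).ravel())
        enhanced = tfce_of(cond_mean_rows(sp))
        for name, (_, tf) in enhanced.items():
            maxima[name].append(max(tf[mask].max(), 0.0))

    max_by_contrast = {name: np.asarray(v) for name, v in maxima.items()}
    if fwe == "across":
        joint = np.max(np.vstack(list(max_by_contrast.values())), axis=0)
        null_for = {name: joint for name in cvecs}
    else:
        null_for = max_by_contrast

    results = []
    for name in cvecs:
        t_vec, tf_map = observed[name]
        obs = tf_map[mask]
        null = null_for[name]
        if exhaustive:
            p_vec = (null[None, :] >= obs[:, None]).sum(axis=1) / len(null)
            p_vec = np.maximum(p_vec, 1.0 / len(null))
        else:
            p_vec = (1.0 + (null[None, :] >= obs[:, None]).sum(axis=1)) / (
                len(null) + 1.0
            )
        p_map = np.ones(mask.shape)
        p_map[mask] = p_vec
        results.append(
            PermResult(
                contrast=name,
                observed_stat=_vector_to_map(t_vec, voxel_ids, mask.shape),
                observed_tfce=tf_map,
                max_null=null_for[name],
                p_fwe=p_map,
                n_permutations=len(slot_perms),
                seed=seed,
                exhaustive=exhaustive,
                fwe_scope=fwe,
                permutation_log=log if log_permutations else None,
            )
        )
    return results


def audit_exchangeability(
    permutation_log: list[np.ndarray], block_ids: np.ndarray
) -> int:
    """Count log entries in which any sample left its block (should be 0)."""
    violations = 0
    for idx in permutation_log:
        if not np.array_equal(block_ids[idx], block_ids):
            violations += 1
    return violations


# ---------------------------------------------------------------------------
# generalized Pareto tail approximation
# ---------------------------------------------------------------------------

#: Refine only p-values at or below this empirical threshold.
TAIL_P_THRESHOLD = 0.10
#: Null exceedances are taken above this quantile of the null distribution.
TAIL_QUANTILE = 0.90
#: Anderson-Darling screen: above this statistic the GPD fit is rejected.
AD_CRITICAL = 2.5
MIN_NULL_FOR_TAIL = 60


def _anderson_darling(z_sorted: np.ndarray) -> float:
    """A^2 statistic of sorted probability-integral-transformed values."""
    n = len(z_sorted)
    z = np.clip(z_sorted, 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1]))))


def gpd_tail_pvalue(observed: float, null: np.ndarray) -> float:
    """Refine a permutation p-value with a generalized-Pareto tail fit.

    Empirical p = (1 + #{null >= observed}) / (len(null) + 1). If that is
    above 0.10 it is returned unchanged. Otherwise a GPD is fit by maximum
    likelihood to the null exceedances above the 90th percentile and
    p = P(tail) * GPD-survival(observed - threshold); an Anderson-Darling
    screen (or a degenerate null) falls back to the empirical value.
    """
    null = np.asarray(null, dtype=np.float64)
    emp_p = (1.0 + (null >= observed).sum()) / (len(null) + 1.0)
    if emp_p > TAIL_P_THRESHOLD or len(null) < MIN_NULL_FOR_TAIL:
        return float(emp_p)
    u = np.quantile(null, TAIL_QUANTILE)
    exceed = null[null > u] - u
    if len(exceed) < 10 or np.ptp(exceed) == 0:
        warnings.warn("degenerate permutation tail; using empirical p", stacklevel=2)
        return float(emp_p)
    try:
        shape, loc, scale = stats.genpareto.fit(exceed, floc=0.0)
    except Exception:  # fit failure of any kind -> empirical fallback
        warnings.warn("GPD fit failed; using empirical p", stacklevel=2)
        return float(emp_p)
    cdf = stats.genpareto.cdf(np.sort(exceed), shape, loc=loc, scale=scale)
    if _anderson_darling(cdf) > AD_CRITICAL:
        warnings.warn("GPD fit rejected by AD screen; using empirical p", stacklevel=2)
        return float(emp_p)
    tail_frac = len(exceed) / len(null)
    sf = stats.genpareto.sf(observed - u, shape, loc=loc, scale=scale)
    return float(min(max(tail_frac * sf, 0.0), emp_p))


def apply_tail_approximation(result: PermResult, mask: np.ndarray) -> PermResult:
    """GPD-refine all FWE p-values at or below the 0.10 activation rule."""
    mask = np.asarray(mask).astype(bool)
    p = result.p_fwe.copy()
    refine = mask & (p <= TAIL_P_THRESHOLD)
    for idx in np.argwhere(refine):
        obs = result.observed_tfce[tuple(idx)]
        p[tuple(idx)] = gpd_tail_pvalue(obs, result.max_null)
    result.p_fwe = p
    result.tail_approximated = True
    return result
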