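"""Dyadic proximity regression on baseline-subtracted synchrony.

After subtracting each pair's unmatched-segment baseline, regresses the
average threat+blame synchrony map on the pair's attitude proximity
(-|x_i - x_j|) with subject-level permutation inference, and contrasts the
proximity effect between blame and threat (moderation). The generator's
frame-graded gamma makes attitude distance matter most under blame framing.
"""

import sys
from importlib import import_module
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
sim = import_module("01_simulate_cohort")

from framesync.isc import all_pair_maps, average_by_condition, subtract_baseline  # noqa: E402
from framesync.pipeline import pair_baselines, prepare_segments  # noqa: E402
from framesync.proximity import (  # noqa: E402
    build_proximity_design,
    condition_moderation,
    isc_proximity_regression,
)
from framesync.simulate import simulate_cohort  # noqa: E402

N_PERM = 500
ALPHA = 0.05


def main() -> None:
    cfg = sim.CONFIG
    runs, events, nuisance, covariates, mask, truth = simulate_cohort(cfg)
    seg_table, series = prepare_segments(runs, events, nuisance, mask)
    maps = all_pair_maps(series, seg_table)
    baselines = pair_baselines(series, seed=cfg.seed)
    corrected = [subtract_baseline(m, baselines[m.pair]) for m in maps]
    cond = average_by_condition(corrected, "frame")

    by_frame: dict[str, dict] = {}
    for m in cond:
        by_frame.setdefault(m.frame, {})[m.pair] = m.values
    pair_list = sorted(by_frame["threat"])
    Y_by_cond = {
        f: np.vstack([by_frame[f][p] for p in pair_list]) for f in cfg.frames
    }
    Y_simpl = (Y_by_cond["threat"] + Y_by_cond["blame"]) / 2

    design = build_proximity_design(covariates, pair_list, ["pvv_attitude"])
    n_vox = int(np.prod(cfg.grid_dims))
    args = (design, mask.astype(bool), np.arange(n_vox))

    res = isc_proximity_regression(Y_simpl, *args, n_perm=N_PERM, seed=cfg.seed)
    mod = condition_moderation(
        Y_by_cond, "blame", "threat", *args, n_perm=N_PERM, seed=cfg.seed + 1
    )

    rows = []
    for label, r in [("threat+blame", res["pvv_attitude"]),
                     ("blame-threat moderation", mod["pvv_attitude"])]:
        sig = (r.p_fwe <= ALPHA).ravel(order="F")
        rows.append(
            dict(
                analysis=label,
                regressor="proximity_pvv_attitude",
                n_suprathreshold=int(sig.sum()),
                true_positives=int(sig[truth.signal_voxel_ids].sum()),
                min_p_fwe=round(float(r.p_fwe.min()), 4),
                mean_t_signal=round(
                    float(r.observed_stat.ravel(order="F")[truth.signal_voxel_ids].mean()), 3
                ),
            )
        )
    table = pd.DataFrame(rows)
    sim.RESULTS.mkdir(exist_ok=True)
    table.to_csv(sim.RESULTS / "proximity.csv", index=False)
    print(table.to_string(index=False))
    print("\npositive proximity t: politically closer pairs synchronize more "
          "under simplification framing; the moderation row shows the effect "
          "is stronger under blame than threat.")


if __name__ == "__main__":
    main()
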