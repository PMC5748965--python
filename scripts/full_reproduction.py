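"""Full five-wave history match of the hormonal-crosstalk model.

Runs the reference wave schedule at full scale — 2000 runs and 200
diagnostic runs per emulated wave, cutoffs (wave 1: I_2M<=3.25, I_3M<=3;
wave 2: 3.1/2.8; wave 3: 5/2.9/2.7; wave 4: 3.2/2.8/2.65) — followed by a
simulator-certified sampling pass at I_M<=3.2 that generates acceptable runs
from the final non-implausible region.  Expect several hours on one CPU.

Writes per-wave artifacts under --out, plus summary.json holding the volume
trajectory, the implied expected random-search cost (1 / final volume), and
the distribution of k16a/k16 over the acceptable runs.

Usage:  python scripts/full_reproduction.py --seed 1 --out scratch/full_run \
            [--variant full|k2c_zero] [--n-runs 2000] [--n-mc 100000]
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np

from hmatch import crosstalk as ct
from hmatch.emulator import FitConfig
from hmatch.history_match import (
    WaveConfig,
    WaveState,
    estimate_volume,
    generate_acceptable_runs,
    run_wave,
)
from hmatch.implausibility import CutoffPolicy
from hmatch.persist import persist_wave

SCHEDULE = [
    {"c_2max": 3.25, "c_3max": 3.0},
    {"c_2max": 3.1, "c_3max": 2.8},
    {"c_max": 5.0, "c_2max": 2.9, "c_3max": 2.7},
    {"c_max": 3.2, "c_2max": 2.8, "c_3max": 2.65},
]
CERTIFICATION_CUTOFF = 3.2  # wave 5: sampled runs certified by the simulator


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, required=True)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--variant", choices=["full", "k2c_zero"], default="full")
    parser.add_argument("--n-runs", type=int, default=2000)
    parser.add_argument("--n-mc", type=int, default=100000)
    parser.add_argument("--n-acceptable", type=int, default=200)
    args = parser.parse_args()

    ranges, names = ct.input_ranges(args.variant)
    observations = ct.arabidopsis_observations()
    state = WaveState(ranges=ranges, names=names, observations=observations)
    simulator = ct.make_simulator(args.variant)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, policy in enumerate(SCHEDULE, start=1):
            config = WaveConfig(
                n_runs=args.n_runs,
                n_diagnostic=200,
                policy=policy,
                fit=FitConfig(order=3, theta=0.35, nugget_proportion=0.1),
                n_mc_volume=args.n_mc // 2,
                maximin_candidates=100,
            )
            state = run_wave(state, simulator, config, seed=args.seed + k)
            frac, se = state.volume_history[-1]
            print(f"wave {k}: volume {frac:.4g} (se {se:.2g}), "
                  f"{len(state.waves[-1].q)} outputs, status {state.status}",
                  flush=True)
            persist_wave(state, args.out)
            if state.status == "empty":
                break

        final_frac, final_se = estimate_volume(state, args.n_mc, seed=args.seed)
        runs = generate_acceptable_runs(
            state, simulator, n=args.n_acceptable, max_draws=5_000_000,
            seed=args.seed + 99,
            policy=CutoffPolicy(outputs=tuple(observations),
                                c_max=CERTIFICATION_CUTOFF),
        )

    summary = {
        "variant": args.variant,
        "volume_history": state.volume_history,
        "final_volume": final_frac,
        "final_volume_se": final_se,
        "expected_random_search_cost": (1.0 / final_frac) if final_frac > 0 else None,
        "n_acceptable_runs": int(len(runs)),
    }
    if len(runs) and "k16a/k16" in runs.columns:
        r = np.exp(runs["k16a/k16"].to_numpy())
        summary["k16a_over_k16"] = {
            "median": float(np.median(r)),
            "q25": float(np.percentile(r, 25)),
            "q75": float(np.percentile(r, 75)),
        }
        runs.to_csv(args.out / "acceptable_runs.csv", index=False)
    (args.out / "summary.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
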