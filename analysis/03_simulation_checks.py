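"""Estimator validation on synthetic two-sample summary statistics.

Three experiments against known generative truth, each at the noise scales
of the homocysteine application (12 instruments unless stated):

1. null calibration       — theta = 0, no pleiotropy: IVW type-I error.
2. coverage at the signal — theta = 0.234 (the NAFLD-scale log estimate):
                            95% CI coverage and power.
3. directional pleiotropy — alpha_j ~ N(0.02, 0.005), 100 instruments:
                            IVW bias versus the MR-Egger intercept estimate.

Writes results/simulation_checks.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hcymr.estimators import ivw, mr_egger
from hcymr.synthetic import SyntheticConfig, generate_dataset, recovery_experiment

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    frames = []

    null = recovery_experiment(
        SyntheticConfig(theta=0.0, seed=11), n_reps=500, estimators=("ivw_fixed", "ivw_mre")
    )
    null.insert(0, "experiment", "null_calibration")
    frames.append(null)
    print("null (theta=0): IVW type-I error "
          f"{null.loc[0, 'rejection_rate']:.3f} (nominal 0.05)")

    signal = recovery_experiment(
        SyntheticConfig(theta=0.234, seed=12), n_reps=500, estimators=("ivw_fixed",)
    )
    signal.insert(0, "experiment", "coverage_at_signal")
    frames.append(signal)
    print(f"signal (theta=0.234): coverage {signal.loc[0, 'coverage']:.3f} "
          f"(nominal 0.95), power {signal.loc[0, 'rejection_rate']:.3f}")

    ints, ivws = [], []
    for s in range(200):
        ds = generate_dataset(
            SyntheticConfig(
                n_snps=100, theta=0.234, pleiotropy_mode="directional",
                pleiotropy_mean=0.02, pleiotropy_sd=0.005, sign_random=False, seed=s,
            )
        )
        ints.append(mr_egger(ds).intercept)
        ivws.append(ivw(ds, "fixed").estimate_log)
    pleio = pd.DataFrame(
        [
            {
                "experiment": "directional_pleiotropy",
                "estimator": "egger_intercept",
                "n_reps": 200,
                "theta_true": 0.234,
                "mean_bias": float(np.mean(ints)) - 0.02,
                "empirical_sd": float(np.std(ints, ddof=1)),
            },
            {
                "experiment": "directional_pleiotropy",
                "estimator": "ivw_fixed",
                "n_reps": 200,
                "theta_true": 0.234,
                "mean_bias": float(np.mean(ivws)) - 0.234,
                "empirical_sd": float(np.std(ivws, ddof=1)),
            },
        ]
    )
    frames.append(pleio)
    print(f"directional pleiotropy (mu=0.02): mean Egger intercept {np.mean(ints):.4f}, "
          f"IVW bias {np.mean(ivws) - 0.234:+.3f} — the intercept recovers the injected "
          "pleiotropy while IVW absorbs it as spurious effect")

    OUT.mkdir(exist_ok=True)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(OUT / "simulation_checks.tsv", sep="\t", index=False, float_format="%.5g")
    print(f"wrote {OUT / 'simulation_checks.tsv'}")


if __name__ == "__main__":
    main()
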