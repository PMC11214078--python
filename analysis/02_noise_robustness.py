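"""Noise robustness of the emergent auxin maximum: PMM vs EMM.

Matched ensembles (same replicate seeds) under moderate noise — auxin
resampled at +/-10% or the static CUC field perturbed once at +/-30% — are
scored for retained repolarization + emergent maximum, and for the
predictability (CV) of the maximum's amplitude.  Results land in
results/noise_robustness/.
"""

import argparse
from pathlib import Path

import pandas as pd
import yaml

import leafmargin as lm

OUT = Path(__file__).resolve().parents[1] / "results" / "noise_robustness"

AUXIN_AMPLITUDE = 0.10
CUC_AMPLITUDE = 0.30


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-reps", type=int, default=20)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    wt = lm.make_template("wt")
    rows = []
    for variant in ("pmm", "emm"):
        params = lm.ModelParams(variant=variant)
        for spec in (
            lm.NoiseSpec("auxin", AUXIN_AMPLITUDE, schedule="resample_every",
                         tau=10 * params.dt),
            lm.NoiseSpec("cuc", CUC_AMPLITUDE),
        ):
            res = lm.run_ensemble(wt, params, spec, n_reps=args.n_reps,
                                  seed=args.seed)
            res.replicates.to_csv(
                OUT / f"replicates_{variant}_{spec.target}.csv", index=False
            )
            rows.append({"variant": variant, "noise_target": spec.target,
                         "amplitude": spec.amplitude, **res.summary})
            s = res.summary
            print(f"{variant} / {spec.target} ±{spec.amplitude:.0%}: "
                  f"success={s['success_fraction']:.2f}  "
                  f"peak row {s['position_mean']:.1f}±{s['position_sd']:.2f}  "
                  f"amplitude CV={s['amplitude_cv']:.3f} "
                  f"(profile readout {s['amplitude_cv_mid']:.3f})")

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "summary.csv", index=False)
    mean_cv = table.groupby("variant")["amplitude_cv_mid"].mean()
    checks = {
        "pmm_mean_profile_cv": float(mean_cv["pmm"]),
        "emm_mean_profile_cv": float(mean_cv["emm"]),
        "pmm_amplitude_more_predictable": bool(mean_cv["pmm"] <= mean_cv["emm"]),
    }
    (OUT / "checks.yaml").write_text(yaml.safe_dump(checks, sort_keys=False))
    print("\namplitude more predictable in the PMM:", checks)


if __name__ == "__main__":
    main()
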