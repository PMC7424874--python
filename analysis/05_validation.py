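"""Method validation: recovery, regularization, and test calibration.

Runs the package's validation experiments at reduced scale and reports:
noise-free decoding exactness, the shrinkage-vs-pseudo-inverse benchmark in
the singular-covariance regime, the cluster test's family-wise false-positive
rate on null data, and the injected-template detection rate. Writes
results/validation.json. (The acceptance script runs the same experiments at
their full problem sizes.)
"""

import sys
from pathlib import Path

from cuedmotion import experiments, io
from cuedmotion.pipeline import derive_seed

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1]
(ROOT / "results").mkdir(exist_ok=True)

out = {}
out["noise_free_recovery"] = experiments.noise_free_recovery(seed=derive_seed(SEED, "recovery"))
print(f"noise-free recovery: max error {out['noise_free_recovery']['max_error_deg']:.2f} deg, "
      f"r = {out['noise_free_recovery']['localizer_r']:.4f}")

out["shrinkage"] = experiments.shrinkage_benchmark(n_seeds=10, seed=derive_seed(SEED, "shrink"))
print(f"88 trials x 128 sensors: MAE {out['shrinkage']['mae_shrunk_deg']:.2f} deg shrunk vs "
      f"{out['shrinkage']['mae_pinv_deg']:.2f} deg pseudo-inverse")

out["null_calibration"] = experiments.null_calibration(
    n_experiments=200, seed=derive_seed(SEED, "null"))
print(f"null FWER at alpha=0.05: {out['null_calibration']['fwer']:.3f}")

out["detection"] = experiments.detection_experiment(n_seeds=10, seed=derive_seed(SEED, "detect"))
print(f"template detection rate: {out['detection']['detection_rate']:.0%} "
      f"(single-point d = {out['detection']['mean_d_150ms']:.2f})")

io.write_json(ROOT / "results" / "validation.json", out, seed=SEED)
print("wrote results/validation.json")
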