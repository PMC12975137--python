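"""Coefficient robustness: perturbation Monte Carlo, grid search, power.

On a simulated cohort with graded scores, perturb all seven equation
coefficients by +/-5/10/15/25 % and watch discrimination degrade; then run
the exhaustive +/-20 % grid search over the four risk weights; finally the
Hanley-McNeil sample-size calculation for detecting AUC 0.90 vs 0.50.
"""

from wase.scoring import CoefficientSet
from wase.sensitivity import (
    GridSpec,
    PerturbationSpec,
    auc_sample_size,
    grid_search_coefficients,
    perturbed_auc,
)
from wase.simulate import SessionConfig, simulate_cohort

cfg = SessionConfig.low_intensity().replace(n_athletes=8, n_steps=300)
ds = simulate_cohort(cfg)

print("perturbation ladder (200 iterations each):")
for m in (0.05, 0.10, 0.15, 0.25):
    res = perturbed_auc(ds.frame, spec=PerturbationSpec(
        magnitude=m, n_iterations=200, seed=0))
    print(f"  +/-{m:.0%}: mean AUC {res.mean_auc:.4f} +/- {res.sd_auc:.4f} "
          f"(baseline {res.baseline_auc:.4f})")

grid = GridSpec(levels=3)  # 81 combinations for a quick demo
best, table = grid_search_coefficients(ds.frame, grid)
print(f"\ngrid search over {len(table)} combinations:")
print(f"  best risk weights: a1={best.a1:.2f} a2={best.a2:.2f} "
      f"a3={best.a3:.2f} a4={best.a4:.2f} "
      f"(AUC {table['objective'].max():.4f})")

n = auc_sample_size(0.90, 0.50, alpha=0.05, beta=0.20)
print(f"\nHanley-McNeil: detecting AUC 0.90 vs 0.50 (alpha 0.05, power 80%) "
      f"needs {n} observations (1:1 classes)")
print("\nSmall perturbations barely move the mean AUC; degradation grows")
print("with magnitude, which is the robustness argument for the weights.")
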