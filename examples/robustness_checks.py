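"""Robustness certification of a frozen PRISM score: bootstrap CI, Monte
Carlo measurement-noise perturbation, and repeated-split stability."""

from lrmscore import bootstrap_auroc, generate_cohort, mc_perturbation, paper_like_config, repeated_splits
from lrmscore.cohort import impute_stratified_median
from lrmscore.scoring import FIXED_TEXT_RULE, build_additive_model, score_cohort

cohort = generate_cohort(paper_like_config(seed=42))
full = impute_stratified_median(cohort)
model = build_additive_model(None, "prism", FIXED_TEXT_RULE)
points = score_cohort(model, full)["points"].to_numpy()

boot = bootstrap_auroc(points, full.label, n_boot=1000, seed=1)
print(f"bootstrap (B=1000): mean AUROC {boot.mean:.3f}, "
      f"95% CI [{boot.ci_low:.3f}, {boot.ci_high:.3f}]")

for level in mc_perturbation(full, model, [0.05, 0.10, 0.20], iters=500, seed=2):
    print(f"  +/-{level.epsilon:.0%} noise x{level.iterations}: "
          f"mean AUROC {level.mean:.3f} (sd {level.sd:.3f}, min {level.min:.3f})")

splits = repeated_splits(cohort, n_splits=50, base_seed=3)
s = splits.summary()
print(f"\n50 repeated 80:20 splits (selection redone from scratch per split):")
print(s.round(3))
print("\nselection frequency per marker:")
print(splits.selection_frequency.round(2).to_string())
print("\nStable AUROCs under resampling, bounded noise and re-splitting"
      "\nindicate the score does not hinge on particular patients or exact"
      "\nmeasured values.")
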