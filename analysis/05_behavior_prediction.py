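#!/usr/bin/env python
"""Behavioral relevance and machine-learning prediction stages.

Correlates planted-edge network features with the behavioral scores
(Bonferroni corrected), runs the PLS latent-space association, classifies
the three groups with RCE-SVM on the full feature table, and predicts
symptom scores with cross-validated linear SVR from the planted-chain
features.

Requires results/features.tsv from analysis/03_connectivity_features.py.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ecnet import predict, syndata

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
ap.add_argument("--features", type=Path, default=Path("results/features.tsv"))
ap.add_argument("--reps", type=int, default=5, help="RCE repetitions")
ap.add_argument("--seed", type=int, default=11)
args = ap.parse_args()

cohort = syndata.load_cohort(args.cohort)
feats = pd.read_csv(args.features, sep="\t", index_col=0)
manifest = cohort.manifest.set_index("subject")
behaviors = manifest[["PCL5", "NSI", "NCI"]]

labels = cohort.subjects[0].ts.labels
chain = [f"edge:{labels[i]}>{labels[i + 1]}" for i in range(4)]
chain_cols = [c for c in feats.columns
              if any(c.endswith(e) for e in chain) and c.startswith(("ec.", "spl.", "eb."))]

corr = predict.behavior_correlations(feats[chain_cols], behaviors)
corr.to_csv("results/behavior_correlations.tsv", sep="\t", index=False)
sig = corr[corr.significant]
print(f"behavior correlations: {len(sig)}/{len(corr)} significant after Bonferroni")
print(sig.sort_values("r").head(10).to_string(index=False))

plsr = predict.plsr_assoc(feats[chain_cols].to_numpy(), behaviors.to_numpy(),
                          n_components=2)
print(f"\nPLSR: {plsr.pct_variance_explained:.1f}% behavioral variance explained; "
      f"latent R^2 = {plsr.latent_r2:.2f} (p = {plsr.latent_p:.2e})")

cfg = predict.RCEConfig(clusters_init=40, clusters_final=2, folds=6, reps=args.reps,
                        seed=args.seed)
rce = predict.rce_svm(feats, manifest["group"].to_numpy(), cfg)
steps = pd.DataFrame({
    "clusters": rce.cluster_counts,
    "mean_accuracy": rce.mean_accuracy.round(3),
    "worst_case_accuracy": rce.worst_case_accuracy.round(3),
    "binomial_p": rce.binomial_p(),
})
steps.to_csv("results/rce_steps.tsv", sep="\t", index=False)
print("\nRCE-SVM (three-group, whole feature table):")
print(steps.to_string(index=False))
top = np.argsort(rce.feature_survival)[::-1][:8]
print("top surviving features:", [rce.feature_names[i] for i in top])

print("\nSVR symptom prediction from planted-chain features:")
for score in ("PCL5", "NSI"):
    res = predict.svr_predict(feats[chain_cols], manifest[score].to_numpy(),
                              iterations=100, seed=args.seed)
    print(f"  {score}: R^2 = {res.mean_r2:.2f} +/- {res.sd_r2:.2f}")
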