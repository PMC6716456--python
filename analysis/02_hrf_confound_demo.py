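#!/usr/bin/env python
"""Demonstrate the hemodynamic-lag confound and its blind removal.

Two regions share an identical point-process neural signal but are
observed through HRFs peaking two seconds apart.  The raw BOLD pair
shows strong spurious directed coupling from the early- to the
late-peaking region; blind deconvolution (event detection, FIR HRF
estimation with shape-based time-to-peak, Wiener inverse filtering)
suppresses it.  Writes per-replicate numbers to
results/hrf_confound.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ecnet import deconv, ec, syndata

ap = argparse.ArgumentParser()
ap.add_argument("--replicates", type=int, default=20)
ap.add_argument("--seed", type=int, default=11)
args = ap.parse_args()

rows = []
for rep in range(args.replicates):
    bold, _ = syndata.lagged_hrf_pair(seed=args.seed + rep)
    res = deconv.blind_deconvolve(bold)
    gc_raw = abs(ec.static_gc(ec.fit_mvar(bold)).gc[0, 1])
    gc_dec = abs(ec.static_gc(ec.fit_mvar(res.latent)).gc[0, 1])
    rows.append({
        "replicate": rep,
        "gc_raw": round(gc_raw, 4),
        "gc_deconvolved": round(gc_dec, 4),
        "reduction_factor": round(gc_raw / gc_dec, 2),
        "peak_time_region0": res.hrfs[0].peak_time,
        "peak_time_region1": res.hrfs[1].peak_time,
    })

df = pd.DataFrame(rows)
Path("results").mkdir(exist_ok=True)
df.to_csv("results/hrf_confound.tsv", sep="\t", index=False)

print(df.to_string(index=False))
print(f"\nmedian spurious-GC reduction factor: {df.reduction_factor.median():.1f}x")
print(f"reduction >= 2x in {np.mean(df.reduction_factor >= 2) * 100:.0f}% of replicates")
print("(true HRF peak times are 5 s and 7 s; estimated times are recovered "
      "up to a common offset, their difference is what matters)")
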