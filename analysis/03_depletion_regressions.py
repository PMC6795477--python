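#!/usr/bin/env python
"""Peak-area regressions across depletion/overexpression regimes.

Simulates four conditions against the wild-type reference — an
independent wild-type replicate, uniform competence scaling (×0.7 and
×0.5), weak-origin-biased depletion, and equalized competence — and fits
per-origin peak areas against the reference with residual diagnostics.

Findings this reproduces on known ground truth:
* a replicate and uniformly scaled conditions stay collinear with the
  reference (R² ~0.7) and show no convex residual skew;
* on the absolute (baseline-subtracted) area scale the slope tracks the
  scaling factor;
* biased depletion keeps a correlation but bends it (significant
  positive curvature: weak origins lose disproportionately) and lowers R²;
* equalizing competence erases the correlation (R² ~0.01).

Writes results/area_regressions.csv and results/areas_by_condition.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from orifire.compare import fit_peak_areas, peak_areas
from orifire.scenarios import (
    bias_weak_origins,
    equalize_origins,
    excess_areas,
    make_study_genome,
    reference_origin_set,
    run_ssdna_condition,
    scale_competence,
)
from orifire.simulate import make_probe_positions

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

ss = np.random.SeedSequence(args.seed)
seeds = [int(x) % (2**31 - 1) for x in ss.generate_state(10)]

genome = make_study_genome(np.random.default_rng(seeds[0]))
probes = make_probe_positions(genome, np.random.default_rng(seeds[1]))
smoothed_wt, _, _ = run_ssdna_condition(genome, seeds[2], probe_positions=probes)
origins = reference_origin_set(genome, smoothed_wt)
_, rescaled_ref, _ = run_ssdna_condition(genome, seeds[3], probe_positions=probes)
ref_areas = peak_areas(rescaled_ref, origins)

conditions = [
    ("wt_replicate", genome, seeds[4]),
    ("uniform_x0.7", scale_competence(genome, 0.7), seeds[5]),
    ("uniform_x0.5", scale_competence(genome, 0.5), seeds[6]),
    ("biased_weak", bias_weak_origins(genome, rng=np.random.default_rng(seeds[7])), seeds[8]),
    ("equalized", equalize_origins(genome), seeds[9]),
]

rows = []
area_table = {"origin": [o.id for o in origins], "reference": ref_areas.round(3)}
ex_ref = None
for name, g_cond, seed in conditions:
    smoothed, rescaled, info = run_ssdna_condition(g_cond, seed, probe_positions=probes)
    areas = peak_areas(rescaled, origins)
    ex = excess_areas(smoothed, info, origins)
    if name == "wt_replicate":
        ex_ref = ex
    reg = fit_peak_areas(ref_areas, areas)
    ex_slope = fit_peak_areas(ex_ref, ex).slope if ex_ref is not None else np.nan
    area_table[name] = areas.round(3)
    rows.append(
        {
            "condition": name,
            "n_origins": reg.n,
            "slope": round(reg.slope, 3),
            "intercept": round(reg.intercept, 3),
            "r_squared": round(reg.r_squared, 4),
            "curvature_t": round(reg.curvature_t, 2),
            "curvature_p": round(reg.curvature_p, 4),
            "runs_z": round(reg.runs_z, 2),
            "excess_area_slope_vs_replicate": round(float(ex_slope), 3),
        }
    )

df = pd.DataFrame(rows)
df.to_csv(args.out_dir / "area_regressions.csv", index=False)
pd.DataFrame(area_table).to_csv(args.out_dir / "areas_by_condition.csv", index=False)
print(df.to_string(index=False))
print(
    "\nbiased depletion: convex residual skew "
    f"(t={df.loc[df.condition=='biased_weak','curvature_t'].item():.2f}); "
    "equalized competence: R^2 = "
    f"{df.loc[df.condition=='equalized','r_squared'].item():.3f} vs reference"
)
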