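#!/usr/bin/env python
"""Marker-frequency profiles of the five-origin chromosome: full vs
halved origin competence.

Simulates an asynchronous population, sequences it (Poisson counts),
runs the MFA pipeline (normalize → S/G1 ratio → 50 kb LOESS), and
measures each origin's peak-to-trough amplitude under both conditions.
Finding: halving competence leaves the origin apexes in place but
dampens every amplitude — individual cells fire fewer origins, so
termination is randomized across the population and the peak/valley
distinction fades.

Writes results/mfa_profile_{full,half}.bedgraph and
results/mfa_amplitudes.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from orifire import io
from orifire.genome import make_demo_genome
from orifire.scenarios import peak_trough_amplitudes, run_mfa_study, scale_competence
from orifire.ssdna import _local_maxima

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

genome = make_demo_genome("five_origin")
full = run_mfa_study(genome, seed=args.seed)
half = run_mfa_study(scale_competence(genome, 0.5), seed=args.seed + 100)

hdr = io.provenance_header(args.seed)
io.write_bedgraph(full, args.out_dir / "mfa_profile_full.bedgraph", header=hdr)
io.write_bedgraph(half, args.out_dir / "mfa_profile_half.bedgraph", header=hdr)

pos = [o.position for o in genome.origins]
amps_full = peak_trough_amplitudes(full["chrS"], pos)
amps_half = peak_trough_amplitudes(half["chrS"], pos)
maxima = _local_maxima(full["chrS"])
offsets = [min((m[0] - x for m in maxima), key=abs) for x in pos]

df = pd.DataFrame(
    {
        "origin": [o.id for o in genome.origins],
        "position": pos,
        "t_mean_min": [o.t_mean for o in genome.origins],
        "apex_offset_bp": offsets,
        "amplitude_full": amps_full.round(4),
        "amplitude_half_competence": amps_half.round(4),
        "amplitude_ratio": (amps_half / amps_full).round(4),
    }
)
df.to_csv(args.out_dir / "mfa_amplitudes.csv", index=False)
print(df.to_string(index=False))
print(
    f"\nall apexes within {max(abs(o) for o in offsets)} bp of their origins; "
    f"mean amplitude ratio {float((amps_half / amps_full).mean()):.2f} "
    "(every origin dampened)" if (amps_half < amps_full).all() else "WARNING: dampening not uniform"
)
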