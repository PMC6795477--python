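"""Shared fixtures.

The "study" fixture runs the expensive wild-type ssDNA reference
experiment once per session: simulate the 12 Mb genome, define the
reusable origin set from the wild-type sample, and measure reference
areas on an independent wild-type run.
"""

from __future__ import annotations

import numpy as np
import pytest

from orifire.compare import peak_areas
from orifire.genome import make_demo_genome
from orifire.scenarios import (
    make_study_genome,
    reference_origin_set,
    run_ssdna_condition,
)
from orifire.simulate import make_probe_positions

# fixed once for the whole suite; chosen up front, not per-test
GENOME_SEED = 7
PROBE_SEED = 100
WT_RUN_SEED = 11
REF_RUN_SEED = 99


@pytest.fixture(scope="session")
def study():
    genome = make_study_genome(np.random.default_rng(GENOME_SEED))
    probes = make_probe_positions(genome, np.random.default_rng(PROBE_SEED))
    smoothed_wt, rescaled_wt, info_wt = run_ssdna_condition(
        genome, WT_RUN_SEED, probe_positions=probes
    )
    origins = reference_origin_set(genome, smoothed_wt)
    _, rescaled_ref, _ = run_ssdna_condition(
        genome, REF_RUN_SEED, probe_positions=probes
    )
    return {
        "genome": genome,
        "probes": probes,
        "smoothed_wt": smoothed_wt,
        "rescaled_wt": rescaled_wt,
        "info_wt": info_wt,
        "origins": origins,
        "ref_areas": peak_areas(rescaled_ref, origins),
    }


@pytest.fixture()
def five_origin_genome():
    return make_demo_genome("five_origin")


@pytest.fixture()
def minimal_genome():
    return make_demo_genome("minimal")
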