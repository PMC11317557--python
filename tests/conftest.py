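"""Shared fixtures: small sampled ensembles reused across test modules.

Sampler runs are the expensive part of the suite, so ensembles are
session-scoped and sized to be just long enough for the statistical
assertions that consume them.
"""

from __future__ import annotations

import numpy as np
import pytest

from pepjunction.synthetic_data import (
    Ensemble,
    SamplerConfig,
    TraceGenConfig,
    generate_traces,
    sample_ensemble,
)

#: Reduced-but-sufficient sampler settings for statistical tests:
#: long enough, with the tempering ladder, for chains to equilibrate
#: into and out of the turn basin.
TEST_SAMPLER = SamplerConfig(n_steps=12000, burn_in=4000, thin=10)

STAGES = (6.0, 9.0, 12.0)
SEQUENCES = ("MAAM", "MGGGM")
N_REPLICATES = 4


def _merge(reps: list[Ensemble]) -> Ensemble:
    return Ensemble(
        sequence=reps[0].sequence, stage=reps[0].stage, replicate_seed=-1,
        topology=reps[0].topology,
        frames=np.concatenate([e.frames for e in reps]),
        energies=np.concatenate([e.energies for e in reps]),
        acceptance_rate=float(np.mean([e.acceptance_rate for e in reps])))


@pytest.fixture(scope="session")
def stage_replicates() -> dict:
    """{(sequence, stage): [replicate Ensembles]} for the reference
    tetra- and pentapeptide across all three holding stages."""
    out = {}
    for seq in SEQUENCES:
        for stage in STAGES:
            out[(seq, stage)] = [
                sample_ensemble(seq, stage, TEST_SAMPLER,
                                seed=1000 + 17 * r)
                for r in range(N_REPLICATES)]
    return out


@pytest.fixture(scope="session")
def stage_ensembles(stage_replicates) -> dict:
    """{(sequence, stage): merged Ensemble} (replicates concatenated)."""
    return {key: _merge(reps) for key, reps in stage_replicates.items()}


@pytest.fixture(scope="session")
def default_traces():
    """2,000 generator-default traces (90% molecular), seed 1."""
    return generate_traces(TraceGenConfig(n_traces=2000, seed=1))
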