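import numpy as np
import pytest

from strep_regulome.pipeline import RunConfig, run_all
from strep_regulome.simulate import SimConfig, generate_genome, simulate_tracks


MAIN_SIM = dict(genome_length=100_000, n_genes=80, seed=11)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full pipeline run on the standard synthetic genome, shared by all
    recovery tests (the run is deterministic in the seed)."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = RunConfig(synthetic=SimConfig(**MAIN_SIM), seed=11, outdir=str(outdir))
    return run_all(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """Smaller genome + tracks, for stage-level tests that re-run stages."""
    sim = SimConfig(genome_length=60_000, n_genes=40, seed=7)
    genome, annotation, truth = generate_genome(sim)
    tracks, counts = simulate_tracks(annotation, truth, sim)
    return sim, genome, annotation, truth, tracks, counts


def match_within(positions, target, tol=2):
    """True if any position in ``positions`` is within ``tol`` of target."""
    return any(abs(p - target) <= tol for p in positions)
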