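import pytest

from pirnakit.config import RunConfig, DEFAULT_LIBRARIES
from pirnakit.pipeline import run_pipeline
from pirnakit.synthetic import SimulationParams, build_genome, simulate_libraries

GENOME_SEED = 7
BUNDLE_SEED = 1
BUNDLE_DEPTH = 30000  # primary emission events per library


@pytest.fixture(scope="session")
def toy_genome():
    """Deterministic toy genome + annotation shared across the suite."""
    return build_genome(seed=GENOME_SEED)


@pytest.fixture(scope="session")
def bundle(toy_genome):
    """One full six-library simulation and pipeline run (seeded)."""
    genome, annotations = toy_genome
    reads, truth = simulate_libraries(
        genome, annotations, SimulationParams(),
        per_library_depth={lib: BUNDLE_DEPTH for lib in DEFAULT_LIBRARIES},
        seed=BUNDLE_SEED,
    )
    raw = {lib: [seq for _, seq in rl] for lib, rl in reads.items()}
    result = run_pipeline(RunConfig(), genome, annotations, raw)
    return {"genome": genome, "annotations": annotations, "reads": reads,
            "truth": truth, "result": result}
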