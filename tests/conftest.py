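from __future__ import annotations

import pytest

from smallrna_traj.simulate import (
    SimConfig,
    generate_genome,
    generate_libraries,
    write_references,
)


def small_config(seed: int = 7) -> SimConfig:
    """A reduced study used by unit tests (fast, but structurally complete)."""
    return SimConfig(
        seed=seed,
        scaffold_length=30_000,
        library_size=3_000,
        n_genes=36,
    )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small simulated study: (config, truth, counts, workdir)."""
    workdir = tmp_path_factory.mktemp("smallsim")
    config = small_config()
    truth = generate_genome(config, workdir)
    counts = generate_libraries(config, truth, workdir)
    write_references(config, workdir / "refs", truth)
    return config, truth, counts, workdir
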