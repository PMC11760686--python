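"""Shared fixtures: a small simulated community and one pipeline run over it."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from markergeo import simulate as sim
from markergeo import workflow as wf

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate_dna(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly n substitutions at distinct positions."""
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        chars[pos] = BASES[(BASES.index(chars[pos]) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


SMALL_PARAMS = sim.SimParams(n_taxa=12, samples_per_habitat=3, reads_per_sample=2000)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory) -> tuple[sim.SimTruth, dict[str, Path]]:
    out = tmp_path_factory.mktemp("community")
    return sim.simulate_fixture_set(out, seed=7, params=SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_run(small_fixture, tmp_path_factory):
    """The full pipeline executed once on the small community."""
    truth, paths = small_fixture
    out_dir = tmp_path_factory.mktemp("run")
    cfg = wf.RunConfig(
        genes_nt=paths["genes_nt"],
        genes_aa=paths["genes_aa"],
        hits=paths["hits"],
        roster=paths["roster"],
        reads_dir=paths["reads_dir"],
        taxonomy=paths["taxonomy"],
        out_dir=out_dir,
    )
    manifest = wf.run_all(cfg)
    return truth, cfg, out_dir, manifest
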