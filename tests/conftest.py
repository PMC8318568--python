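"""Shared fixtures: benchmarks are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from gcescan.pipeline import RunConfig, run_scan
from gcescan.synthetic import PlantSpec, generate


@pytest.fixture(scope="session")
def bench_full():
    """The default 200-kb benchmark (all feature classes planted)."""
    return generate(PlantSpec(seed=0))


@pytest.fixture(scope="session")
def scan_full(bench_full):
    """Default-config dual-mode pipeline run on the full benchmark."""
    return run_scan(bench_full.contigs, RunConfig(),
                    references=bench_full.references,
                    annotations=bench_full.annotation)


@pytest.fixture(scope="session")
def bench_small():
    """A 60-kb benchmark for cheaper per-module tests."""
    return generate(PlantSpec(seed=11, genome_length=60_000, n_contigs=1,
                              n_selenoproteins=3, n_pyl=2, n_decoy_uga=2,
                              n_decoy_gbmt=1, n_standard_trna=1))


def random_dna_string(rng: np.random.Generator, n: int, gc: float = 0.41) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
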