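from __future__ import annotations

import numpy as np
import pytest

from mitocomp.data import fixture_genome, load_gene_table
from mitocomp.simulate import MotifSpec, SynthConfig, generate

SENSE_CODONS = sorted(
    set(
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
    )
    - {"TAA", "TAG"}
)


@pytest.fixture(scope="session")
def castaneus_table():
    return load_gene_table("castaneus")


@pytest.fixture(scope="session")
def laterotarsus_table():
    return load_gene_table("laterotarsus")


@pytest.fixture(scope="session")
def castaneus_genome():
    return fixture_genome("castaneus", seed=101)


@pytest.fixture(scope="session")
def laterotarsus_genome():
    return fixture_genome("laterotarsus", seed=102)


@pytest.fixture(scope="session")
def default_synthetic():
    return generate(SynthConfig(seed=11))


def random_feasible_config(rng: np.random.Generator) -> SynthConfig:
    """A random generator configuration drawn from the feasible space."""
    count = int(rng.integers(1, 6))
    gaps = tuple(int(x) for x in rng.integers(1, 40, size=max(count - 1, 0)))
    spec = MotifSpec(count=count, gaps=gaps, lead=int(rng.integers(0, 30)))
    igs = {
        "trnI": int(rng.integers(spec.span, spec.span + 300)),
        "nad2": int(rng.integers(-8, 10)),
        "trnY": int(rng.integers(0, 6)),
    }
    return SynthConfig(
        seed=int(rng.integers(2**31)),
        at_fraction=float(rng.uniform(0.60, 0.80)),
        at_skew_target=float(rng.uniform(-0.15, 0.15)),
        gc_skew_target=float(rng.uniform(-0.35, 0.10)),
        stop_codon_policy=float(rng.uniform(0.0, 1.0)),
        igs_spec=igs,
        motif_spec=spec,
    )
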