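"""Shared fixtures: small genomes, pedigrees and simulated herds."""

from __future__ import annotations

import numpy as np
import pytest

from beefgs import presets
from beefgs.genome import GenomeMap, build_candidate_map, simulate_historical


@pytest.fixture(scope="session")
def micro_cfg():
    return presets.micro()


@pytest.fixture(scope="session")
def micro_pop(micro_cfg):
    """One fully simulated micro herd (shared, read-only)."""
    from beefgs.pipeline import simulate_population

    pop, gmap, arch, log = simulate_population(
        micro_cfg, np.random.SeedSequence(42))
    return {"pop": pop, "gmap": gmap, "arch": arch, "log": log,
            "cfg": micro_cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, 40 evenly placed loci."""
    chrom = np.repeat([0, 1], 20)
    pos = np.tile(np.linspace(2.5, 97.5, 20), 2)
    return GenomeMap(chrom, pos, np.zeros(40, dtype=np.uint8), [100.0, 100.0])


@pytest.fixture(scope="session")
def historical_micro(micro_cfg):
    """Final-generation haplotypes of a small historical phase."""
    rng = np.random.default_rng(7)
    gmap = build_candidate_map(micro_cfg.genome, micro_cfg.history.n_loci_pool,
                               rng)
    haps = simulate_historical(gmap, micro_cfg.history, rng)
    return gmap, haps


def random_pedigree(n, n_founders, rng, n_breeds=1):
    """Random topologically ordered (purebred) pedigree for oracle tests."""
    assert n_founders >= 2 * n_breeds
    sire = [-1] * n_founders
    dam = [-1] * n_founders
    breed = [(i // 2) % n_breeds for i in range(n_founders)]
    sex = [i % 2 for i in range(n_founders)]
    for i in range(n_founders, n):
        b = int(rng.integers(0, n_breeds))
        males = [j for j in range(i) if sex[j] == 0 and breed[j] == b]
        females = [j for j in range(i) if sex[j] == 1 and breed[j] == b]
        sire.append(int(rng.choice(males)))
        dam.append(int(rng.choice(females)))
        breed.append(b)
        sex.append(int(rng.integers(0, 2)))
    return (np.array(sire), np.array(dam), np.array(sex, dtype=np.int8),
            np.array(breed, dtype=np.int8))
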