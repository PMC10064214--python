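"""Selective-genotyping scenarios and phenotyping cases.

A fixed genotyping budget is allocated to strata of the population
(generation-15 selection candidates of one or both sexes, and/or ancestral
parents from generation 7 onward); sampling is uniform at random within
each stratum across the pooled five-breed population, so per-breed counts
are proportional to stratum sizes.  Phenotyping cases record an exact
fraction (100/60/20%) of the animals of the allowed sex(es), drawn without
replacement.

Scenario definitions (shares of the budget B):

* ``RefSc`` — no genotyping (pedigree-only reference).
* ``Sc1``   — B male candidates of the final generation.
* ``Sc2``   — 0.4·B ancestral sires with at least ``min_progeny`` progeny
  plus 0.6·B male candidates.
* ``Sc3``   — B candidates of both sexes (unrestricted random draw,
  so roughly a 50:50 sex split).
* ``Sc4``   — 0.3·B random ancestral sires, 0.3·B random ancestral dams
  (no progeny-count threshold beyond being a parent) and 0.4·B candidates
  of both sexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import FEMALE, MALE, Population
from .presets import DesignConfig


@dataclass(frozen=True)
class PhenotypingCase:
    name: str
    fraction: float
    sexes: str  # "MF", "M" or "F"

    def __post_init__(self) -> None:
        if self.fraction not in (0.2, 0.6, 1.0):
            raise ValueError("fraction must be one of 0.2, 0.6, 1.0")
        if self.sexes not in ("MF", "M", "F"):
            raise ValueError("sexes must be MF, M or F")


CASES: dict[str, PhenotypingCase] = {
    f"{int(frac * 100)}{sx}": PhenotypingCase(f"{int(frac * 100)}{sx}", frac, sx)
    for frac in (1.0, 0.6, 0.2)
    for sx in ("MF", "M", "F")
}


@dataclass(frozen=True)
class Stratum:
    kind: str       # candidate_m | candidate_f | candidate_mf | anc_sire | anc_dam
    count: int
    min_progeny: int = 1


@dataclass(frozen=True)
class GenotypingScenario:
    name: str
    strata: tuple[Stratum, ...]

    @property
    def budget(self) -> int:
        return sum(s.count for s in self.strata)


def _split_budget(budget: int, shares) -> list[int]:
    counts = [int(np.floor(s * budget)) for s in shares]
    rem = budget - sum(counts)
    order = np.argsort([s * budget - c for s, c in zip(shares, counts)])[::-1]
    for i in order[:rem]:
        counts[i] += 1
    return counts


def build_scenarios(design: DesignConfig) -> dict[str, GenotypingScenario]:
    b = design.genotyping_budget
    mp = design.min_progeny_ancestral_sires
    c2 = _split_budget(b, design.sc2_shares)
    c4 = _split_budget(b, design.sc4_shares)
    return {
        "RefSc": GenotypingScenario("RefSc", ()),
        "Sc1": GenotypingScenario("Sc1", (Stratum("candidate_m", b),)),
        "Sc2": GenotypingScenario(
            "Sc2",
            (Stratum("anc_sire", c2[0], min_progeny=mp),
             Stratum("candidate_m", c2[1])),
        ),
        "Sc3": GenotypingScenario("Sc3", (Stratum("candidate_mf", b),)),
        "Sc4": GenotypingScenario(
            "Sc4",
            (Stratum("anc_sire", c4[0]), Stratum("anc_dam", c4[1]),
             Stratum("candidate_mf", c4[2])),
        ),
    }


def _stratum_pool(pop: Population, st: Stratum, design: DesignConfig) -> np.ndarray:
    g_cand = design.candidate_generation
    g_min = design.genotype_from_generation
    if st.kind == "candidate_m":
        mask = (pop.gen == g_cand) & (pop.sex == MALE)
    elif st.kind == "candidate_f":
        mask = (pop.gen == g_cand) & (pop.sex == FEMALE)
    elif st.kind == "candidate_mf":
        mask = pop.gen == g_cand
    elif st.kind == "anc_sire":
        mask = ((pop.gen >= g_min) & (pop.gen < g_cand) & (pop.sex == MALE)
                & (pop.n_progeny >= max(1, st.min_progeny)))
    elif st.kind == "anc_dam":
        mask = ((pop.gen >= g_min) & (pop.gen < g_cand) & (pop.sex == FEMALE)
                & (pop.n_progeny >= max(1, st.min_progeny)))
    else:
        raise ValueError(f"unknown stratum kind {st.kind!r}")
    return np.flatnonzero(mask)


def select_genotyped(pop: Population, scenario: GenotypingScenario,
                     design: DesignConfig, rng: np.random.Generator) -> np.ndarray:
    """Sorted array of genotyped animal rows for one scenario."""
    chosen = []
    for st in scenario.strata:
        pool = _stratum_pool(pop, st, design)
        if pool.size < st.count:
            raise ValueError(
                f"scenario {scenario.name}, stratum {st.kind}: "
                f"{pool.size} eligible animals for a target of {st.count}"
            )
        chosen.append(rng.choice(pool, st.count, replace=False))
    if not chosen:
        return np.empty(0, dtype=np.int64)
    out = np.sort(np.concatenate(chosen))
    if np.unique(out).size != out.size:
        raise RuntimeError(f"scenario {scenario.name}: overlapping strata")
    return out


def select_phenotyped(pop: Population, case: PhenotypingCase,
                      rng: np.random.Generator,
                      min_generation: int = 1) -> np.ndarray:
    """Boolean observed mask: an exact random fraction of the allowed
    sex(es) among animals of generation >= ``min_generation``."""
    eligible = pop.gen >= min_generation
    if case.sexes == "M":
        eligible &= pop.sex == MALE
    elif case.sexes == "F":
        eligible &= pop.sex == FEMALE
    idx = np.flatnonzero(eligible)
    k = int(round(case.fraction * idx.size))
    mask = np.zeros(pop.n, dtype=bool)
    mask[rng.choice(idx, k, replace=False)] = True
    return mask
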