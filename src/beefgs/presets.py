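"""Run configuration: parameter schema, presets and YAML round-trip.

A :class:`RunConfig` fully determines one replicate of the study together
with a seed.  Three presets ship with the package:

``paper``
    The full-scale breeding-program parameterisation (29 chromosomes /
    2,319 cM, 50K markers, 800 QTL, 2,020 historical generations, five
    breeds totalling 740 sires and 5,200 dams, genotyping budget 5,000).
``desk``
    A proportionally scaled preset that finishes a replicate in about a
    minute: breed sizes and the genotyping budget at 1/10 scale, a
    5-chromosome 400 cM genome with 2,000 markers and 200 QTL, and a
    200-generation historical phase.
``micro``
    A very small preset used by the unit-test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class HistoryConfig:
    """Historical (LD-generating) phase: two sub-phases of random mating.

    Population size is constant at ``size_phase1`` during phase 1 and then
    interpolates linearly to ``size_end`` over phase 2.
    """

    n_gen_phase1: int
    size_phase1: int
    n_gen_phase2: int
    size_end: int
    n_loci_pool: int
    mutation_rate: float = 2.5e-5


@dataclass
class GenomeConfig:
    n_chromosomes: int
    chrom_lengths_cM: list[float]
    n_markers: int
    n_qtl: int
    maf_min: float = 0.1
    mutation_rate: float = 2.5e-5

    @property
    def total_length_cM(self) -> float:
        return float(sum(self.chrom_lengths_cM))


@dataclass
class ExpansionConfig:
    """Step 2: expansion generations (random selection and mating)."""

    n_males: int
    n_females: int
    n_generations: int
    offspring_per_dam: int
    # Culling rule: breeding sires/dams per generation are capped at this
    # ceiling (random choice among available animals); all offspring of the
    # final generation are retained as the base pool for breed formation.
    max_breeding_per_sex: int = 500


@dataclass
class BreedFormationConfig:
    """Step 3: formation of reproductively isolated breeds."""

    n_breeds: int
    males_per_breed: int
    females_per_breed: int
    n_generations: int
    offspring_per_dam: int


@dataclass
class BreedSpec:
    """Step 4 per-breed structure: founding counts, replacement and growth.

    ``sire_repl``/``dam_repl`` are the fractions of breeding animals that
    exit each generation (oldest first); ``sire_growth``/``dam_growth`` are
    per-generation proportional growth rates of the breeding counts.
    """

    name: str
    n_males: int
    n_females: int
    sire_repl: float
    sire_growth: float
    dam_repl: float
    dam_growth: float

    def __post_init__(self) -> None:
        if not (0.0 < self.sire_repl <= 1.0 and 0.0 < self.dam_repl <= 1.0):
            raise ValueError(f"breed {self.name}: replacement must be in (0, 1]")
        if self.sire_growth < 0 or self.dam_growth < 0:
            raise ValueError(f"breed {self.name}: growth must be >= 0")
        if self.n_males <= 0 or self.n_females <= 0:
            raise ValueError(f"breed {self.name}: founding counts must be > 0")


@dataclass
class SelectionConfig:
    """Step 4: generations of EBV-based selected breeding."""

    breeds: list[BreedSpec]
    n_generations: int = 15
    offspring_per_dam: int = 1


@dataclass
class TraitConfig:
    h2: float = 0.3
    var_p: float = 1.0
    gamma_shape: float = 0.4
    mu: float = 0.0
    sex_effect: float = 0.25  # +sex_effect for males, -sex_effect for females

    @property
    def var_a(self) -> float:
        return self.h2 * self.var_p

    @property
    def var_e(self) -> float:
        return self.var_p - self.var_a


@dataclass
class DesignConfig:
    """Genotyping/phenotyping design grid applied to the simulated herd."""

    genotyping_budget: int
    genotype_from_generation: int = 7
    candidate_generation: int = 15
    min_progeny_ancestral_sires: int = 10
    # Stratum shares of the budget for the two mixed scenarios
    sc2_shares: tuple[float, float] = (0.4, 0.6)        # ancestral sires, male candidates
    sc4_shares: tuple[float, float, float] = (0.3, 0.3, 0.4)  # anc sires, anc dams, candidates


@dataclass
class RunConfig:
    preset: str
    history: HistoryConfig
    genome: GenomeConfig
    expansion: ExpansionConfig
    breed_formation: BreedFormationConfig
    selection: SelectionConfig
    trait: TraitConfig
    design: DesignConfig
    n_replicates: int = 10
    scenarios: list[str] = field(
        default_factory=lambda: ["RefSc", "Sc1", "Sc2", "Sc3", "Sc4"]
    )
    cases: list[str] = field(
        default_factory=lambda: [
            "100MF", "60MF", "20MF", "100F", "60F", "20F", "100M", "60M", "20M",
        ]
    )

    def validate(self) -> None:
        if self.history.size_phase1 < 2 or self.history.size_end < 2:
            raise ValueError("historical population sizes must be >= 2")
        if self.genome.n_chromosomes != len(self.genome.chrom_lengths_cM):
            raise ValueError("chrom_lengths_cM length must equal n_chromosomes")
        if self.genome.n_markers + self.genome.n_qtl > self.history.n_loci_pool:
            raise ValueError("locus pool smaller than requested markers + QTL")
        if self.design.candidate_generation != self.selection.n_generations:
            raise ValueError("candidate generation must be the final one")
        if not set(self.scenarios) <= {"RefSc", "Sc1", "Sc2", "Sc3", "Sc4"}:
            raise ValueError(f"unknown scenario in {self.scenarios}")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["history"] = HistoryConfig(**d["history"])
        d["genome"] = GenomeConfig(**d["genome"])
        d["expansion"] = ExpansionConfig(**d["expansion"])
        d["breed_formation"] = BreedFormationConfig(**d["breed_formation"])
        sel = dict(d["selection"])
        sel["breeds"] = [BreedSpec(**b) for b in sel["breeds"]]
        d["selection"] = SelectionConfig(**sel)
        d["trait"] = TraitConfig(**d["trait"])
        des = dict(d["design"])
        des["sc2_shares"] = tuple(des["sc2_shares"])
        des["sc4_shares"] = tuple(des["sc4_shares"])
        d["design"] = DesignConfig(**des)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_BREED_TABLE = [
    # name, males, females, sire_repl, sire_growth, dam_repl, dam_growth
    ("A", 220, 1800, 0.5065, 0.072, 0.30, 0.098),
    ("B", 160, 1100, 0.5851, 0.1038, 0.30, 0.1629),
    ("C", 140, 1200, 0.5252, 0.073, 0.30, 0.103),
    ("D", 120, 600, 0.6256, 0.118, 0.30, 0.182),
    ("E", 100, 500, 0.5392, 0.06, 0.30, 0.117),
]


def _breeds(scale: float) -> list[BreedSpec]:
    out = []
    for name, m, f, sr, sg, dr, dg in _BREED_TABLE:
        out.append(
            BreedSpec(
                name=name,
                n_males=max(2, round(m * scale)),
                n_females=max(2, round(f * scale)),
                sire_repl=sr,
                sire_growth=sg,
                dam_repl=dr,
                dam_growth=dg,
            )
        )
    return out


def paper(declining_history: bool = False) -> RunConfig:
    """Full-scale preset.  ``declining_history=True`` selects the variant in
    which phase 2 shrinks to 200 individuals instead of growing to 2,020."""
    return RunConfig(
        preset="paper",
        history=HistoryConfig(
            n_gen_phase1=1000,
            size_phase1=1000,
            n_gen_phase2=1020 if declining_history else 200,
            size_end=200 if declining_history else 2020,
            n_loci_pool=120_000,
        ),
        genome=GenomeConfig(
            n_chromosomes=29,
            chrom_lengths_cM=[2319.0 / 29] * 29,
            n_markers=50_000,
            n_qtl=800,
        ),
        expansion=ExpansionConfig(
            n_males=100, n_females=100, n_generations=8, offspring_per_dam=5
        ),
        breed_formation=BreedFormationConfig(
            n_breeds=5,
            males_per_breed=100,
            females_per_breed=100,
            n_generations=30,
            offspring_per_dam=2,
        ),
        selection=SelectionConfig(breeds=_breeds(1.0)),
        trait=TraitConfig(),
        design=DesignConfig(genotyping_budget=5000),
    )


def desk() -> RunConfig:
    """1/10-scale preset preserving the structure of the full program."""
    return RunConfig(
        preset="desk",
        history=HistoryConfig(
            n_gen_phase1=100,
            size_phase1=100,
            n_gen_phase2=100,
            size_end=50,
            n_loci_pool=10_000,
        ),
        genome=GenomeConfig(
            n_chromosomes=5,
            chrom_lengths_cM=[80.0] * 5,
            n_markers=2000,
            n_qtl=200,
        ),
        expansion=ExpansionConfig(
            n_males=25, n_females=25, n_generations=8, offspring_per_dam=5
        ),
        breed_formation=BreedFormationConfig(
            n_breeds=5,
            males_per_breed=100,
            females_per_breed=100,
            n_generations=30,
            offspring_per_dam=2,
        ),
        selection=SelectionConfig(breeds=_breeds(0.1)),
        trait=TraitConfig(),
        design=DesignConfig(genotyping_budget=500),
    )


def micro() -> RunConfig:
    """Tiny preset for fast unit tests (seconds per replicate)."""
    return RunConfig(
        preset="micro",
        history=HistoryConfig(
            n_gen_phase1=20,
            size_phase1=60,
            n_gen_phase2=20,
            size_end=40,
            n_loci_pool=600,
        ),
        genome=GenomeConfig(
            n_chromosomes=2,
            chrom_lengths_cM=[50.0, 50.0],
            n_markers=120,
            n_qtl=30,
        ),
        expansion=ExpansionConfig(
            n_males=15,
            n_females=15,
            n_generations=4,
            offspring_per_dam=3,
            max_breeding_per_sex=60,
        ),
        breed_formation=BreedFormationConfig(
            n_breeds=5,
            males_per_breed=10,
            females_per_breed=10,
            n_generations=4,
            offspring_per_dam=2,
        ),
        selection=SelectionConfig(breeds=_breeds(0.02), n_generations=6),
        trait=TraitConfig(),
        design=DesignConfig(
            genotyping_budget=40,
            genotype_from_generation=3,
            candidate_generation=6,
            min_progeny_ancestral_sires=2,
        ),
        n_replicates=2,
    )


PRESETS = {"paper": paper, "desk": desk, "micro": micro}


def get_preset(name: str) -> RunConfig:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
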