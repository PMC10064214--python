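"""Population structure: expansion, breed formation and selected breeding.

The breeding program has four stages.  After the historical LD phase
(:mod:`beefgs.genome`), a small founder sample is expanded by random mating
(step 2), five reproductively isolated breeds are formed and randomly mated
(step 3), and each breed is then bred for a number of generations with
truncation selection of replacements on pedigree-BLUP EBVs, age-based
culling, and per-breed replacement and growth rates (step 4).  Only step-4
animals form the evaluated pedigree; their base animals have unknown
parents which are later mapped to one metafounder (or unknown-parent group)
per breed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap, meiosis_batch
from .presets import (
    BreedFormationConfig,
    BreedSpec,
    ExpansionConfig,
    SelectionConfig,
    TraitConfig,
)

MALE, FEMALE = 0, 1


@dataclass
class Population:
    """Columnar pedigree + per-animal state.

    ``sire``/``dam`` are row indices (< position of the child, so the
    pedigree is topologically ordered by construction); -1 means unknown,
    and after :func:`assign_metafounders` unknown parents are recoded as
    ``-(breed+1)`` (metafounder ids).  ``haplo`` has shape (n, 2, L).
    """

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    breed: np.ndarray
    gen: np.ndarray
    haplo: np.ndarray | None = None
    n_progeny: np.ndarray | None = None
    tbv: np.ndarray | None = None
    y: np.ndarray | None = None
    n_metafounders: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny is None:
            self.n_progeny = np.zeros(self.n, dtype=np.int32)

    @property
    def n(self) -> int:
        return int(self.sire.size)

    def pedigree_frame(self) -> pd.DataFrame:
        """Pedigree as a DataFrame (1-based ids; metafounders negative)."""
        def code(p):
            return np.where(p >= 0, p + 1, p)
        return pd.DataFrame(
            {
                "id": np.arange(1, self.n + 1),
                "sire": code(self.sire),
                "dam": code(self.dam),
                "sex": np.where(self.sex == MALE, "M", "F"),
                "breed": np.asarray(self.breed),
                "generation": self.gen,
            }
        )

    def dosage(self, loci_idx: np.ndarray, rows: np.ndarray | None = None) -> np.ndarray:
        h = self.haplo if rows is None else self.haplo[rows]
        return h[:, 0, loci_idx].astype(np.int16) + h[:, 1, loci_idx]


class _Builder:
    """Accumulates cohorts then freezes into a Population."""

    def __init__(self) -> None:
        self.cols: dict[str, list] = {k: [] for k in
                                      ("sire", "dam", "sex", "breed", "gen")}
        self.haps: list[np.ndarray] = []
        self.tbv: list[np.ndarray] = []
        self.y: list[np.ndarray] = []
        self.n = 0

    def add(self, sire, dam, sex, breed, gen, haps, tbv=None, y=None) -> np.ndarray:
        k = len(sex)
        ids = np.arange(self.n, self.n + k)
        self.cols["sire"].append(np.asarray(sire, dtype=np.int64))
        self.cols["dam"].append(np.asarray(dam, dtype=np.int64))
        self.cols["sex"].append(np.asarray(sex, dtype=np.int8))
        self.cols["breed"].append(np.broadcast_to(np.asarray(breed, dtype=np.int8), (k,)))
        self.cols["gen"].append(np.full(k, gen, dtype=np.int16))
        self.haps.append(haps)
        if tbv is not None:
            self.tbv.append(np.asarray(tbv, dtype=np.float64))
            self.y.append(np.asarray(y, dtype=np.float64))
        self.n += k
        return ids

    def freeze(self) -> Population:
        c = {k: np.concatenate(v) for k, v in self.cols.items()}
        return Population(
            sire=c["sire"], dam=c["dam"], sex=c["sex"], breed=c["breed"],
            gen=c["gen"], haplo=np.concatenate(self.haps, axis=0),
            tbv=np.concatenate(self.tbv) if self.tbv else None,
            y=np.concatenate(self.y) if self.y else None,
        )


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of an exactly balanced sex vector (females get the
    extra slot when n is odd: dam replacement demand is the binding side)."""
    sex = np.full(n, FEMALE, dtype=np.int8)
    sex[: n // 2] = MALE
    return rng.permutation(sex)


# ---------------------------------------------------------------------------
# Step 2: expansion
# ---------------------------------------------------------------------------


def expand(founder_haps: np.ndarray, cfg: ExpansionConfig, gmap: GenomeMap,
           rng: np.random.Generator, mutation_rate: float | None = None) -> Population:
    """Random-mating expansion from a founder sample.

    Founders are drawn at random from the historical pool (sexes assigned
    at random, exactly balanced).  Each generation, breeding animals are a
    random sample of at most ``max_breeding_per_sex`` per sex; every
    breeding dam leaves ``offspring_per_dam`` offspring with a random
    breeding sire.
    """
    mu = mutation_rate if mutation_rate is not None else 0.0
    pool_n = founder_haps.shape[0]
    if cfg.n_males + cfg.n_females > pool_n:
        raise ValueError(
            f"founder pool has {pool_n} animals; need "
            f"{cfg.n_males + cfg.n_females}"
        )
    picks = rng.choice(pool_n, cfg.n_males + cfg.n_females, replace=False)
    b = _Builder()
    sex0 = np.concatenate([np.zeros(cfg.n_males, np.int8),
                           np.ones(cfg.n_females, np.int8)])
    ids = b.add(np.full(sex0.size, -1), np.full(sex0.size, -1), sex0, -1, 0,
                founder_haps[picks])
    males = ids[sex0 == MALE]
    females = ids[sex0 == FEMALE]
    all_haps = [founder_haps[picks]]

    for g in range(1, cfg.n_generations + 1):
        n_s = min(males.size, cfg.max_breeding_per_sex)
        n_d = min(females.size, cfg.max_breeding_per_sex)
        sires = rng.choice(males, n_s, replace=False)
        dams = rng.choice(females, n_d, replace=False)
        dam_ids = np.repeat(dams, cfg.offspring_per_dam)
        sire_ids = rng.choice(sires, dam_ids.size, replace=True)
        H = np.concatenate(all_haps, axis=0)
        g1 = meiosis_batch(H[sire_ids], gmap, mu, rng)
        g2 = meiosis_batch(H[dam_ids], gmap, mu, rng)
        haps = np.stack([g1, g2], axis=1)
        sex = _balanced_sexes(dam_ids.size, rng)
        ids = b.add(sire_ids, dam_ids, sex, -1, g, haps)
        all_haps.append(haps)
        males = ids[sex == MALE]
        females = ids[sex == FEMALE]
    return b.freeze()


# ---------------------------------------------------------------------------
# Step 3: breed formation
# ---------------------------------------------------------------------------


def form_breeds(expanded: Population, cfg: BreedFormationConfig, gmap: GenomeMap,
                rng: np.random.Generator, mutation_rate: float = 0.0) -> Population:
    """Five disjoint founder samples, then isolated random mating per breed."""
    last = expanded.gen == expanded.gen.max()
    males = np.flatnonzero(last & (expanded.sex == MALE))
    females = np.flatnonzero(last & (expanded.sex == FEMALE))
    need_m = cfg.n_breeds * cfg.males_per_breed
    need_f = cfg.n_breeds * cfg.females_per_breed
    if males.size < need_m or females.size < need_f:
        raise ValueError(
            f"final expanded generation has {males.size} males / "
            f"{females.size} females; need {need_m}/{need_f}"
        )
    pick_m = rng.choice(males, need_m, replace=False).reshape(cfg.n_breeds, -1)
    pick_f = rng.choice(females, need_f, replace=False).reshape(cfg.n_breeds, -1)

    b = _Builder()
    state = []  # per breed: (male ids, female ids) within new population
    for br in range(cfg.n_breeds):
        src = np.concatenate([pick_m[br], pick_f[br]])
        sex = np.concatenate([
            np.zeros(cfg.males_per_breed, np.int8),
            np.ones(cfg.females_per_breed, np.int8),
        ])
        ids = b.add(np.full(src.size, -1), np.full(src.size, -1), sex, br, 0,
                    expanded.haplo[src])
        state.append((ids[sex == MALE], ids[sex == FEMALE]))

    all_haps = [np.concatenate(b.haps, axis=0)]
    for g in range(1, cfg.n_generations + 1):
        new_state = []
        gen_haps = []
        for br in range(cfg.n_breeds):
            males_b, females_b = state[br]
            dam_ids = np.repeat(females_b, cfg.offspring_per_dam)
            sire_ids = rng.choice(males_b, dam_ids.size, replace=True)
            H = np.concatenate(all_haps, axis=0)
            g1 = meiosis_batch(H[sire_ids], gmap, mutation_rate, rng)
            g2 = meiosis_batch(H[dam_ids], gmap, mutation_rate, rng)
            haps = np.stack([g1, g2], axis=1)
            sex = _balanced_sexes(dam_ids.size, rng)
            ids = b.add(sire_ids, dam_ids, sex, br, g, haps)
            gen_haps.append(haps)
            new_state.append((ids[sex == MALE], ids[sex == FEMALE]))
        all_haps.append(np.concatenate(gen_haps, axis=0))
        state = new_state
    return b.freeze()


def fst_between_breeds(pop: Population, loci_idx: np.ndarray,
                       generation: int | None = None) -> float:
    """Mean Hudson-style FST over loci, averaged across breed pairs."""
    sel = pop.gen == (pop.gen.max() if generation is None else generation)
    breeds = np.unique(pop.breed[sel])
    freqs = []
    for br in breeds:
        rows = np.flatnonzero(sel & (pop.breed == br))
        freqs.append(pop.haplo[rows][:, :, loci_idx].mean(axis=(0, 1)))
    vals = []
    for i in range(len(breeds)):
        for j in range(i + 1, len(breeds)):
            p, q = freqs[i], freqs[j]
            num = (p - q) ** 2
            den = p * (1 - q) + q * (1 - p)
            ok = den > 0
            if ok.any():
                vals.append(np.mean(num[ok] / den[ok]))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Step 4: selected breeding
# ---------------------------------------------------------------------------


@dataclass
class _BreedState:
    spec: BreedSpec
    sires: np.ndarray
    dams: np.ndarray


@dataclass
class BreedingLog:
    """Per-generation bookkeeping of the selection loop."""
    records: list[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def make_base_population(breed_pop: Population, selection: SelectionConfig,
                         gmap: GenomeMap, rng: np.random.Generator,
                         mutation_rate: float = 0.0) -> Population:
    """Step-4 base cohort: offspring of random within-breed matings of the
    final breed-formation generation, sized to each breed's founding counts.

    Base animals enter the evaluated pedigree with unknown parents (they
    are the metafounder children); the bridging matings only supply their
    genotypes.
    """
    last = breed_pop.gen == breed_pop.gen.max()
    b = _Builder()
    for br, spec in enumerate(selection.breeds):
        males = np.flatnonzero(last & (breed_pop.breed == br) & (breed_pop.sex == MALE))
        females = np.flatnonzero(last & (breed_pop.breed == br) & (breed_pop.sex == FEMALE))
        if males.size == 0 or females.size == 0:
            raise ValueError(f"breed {spec.name}: empty formation pool")
        n_tot = spec.n_males + spec.n_females
        sire_src = rng.choice(males, n_tot, replace=True)
        dam_src = rng.choice(females, n_tot, replace=True)
        g1 = meiosis_batch(breed_pop.haplo[sire_src], gmap, mutation_rate, rng)
        g2 = meiosis_batch(breed_pop.haplo[dam_src], gmap, mutation_rate, rng)
        haps = np.stack([g1, g2], axis=1)
        sex = np.concatenate([
            np.zeros(spec.n_males, np.int8), np.ones(spec.n_females, np.int8)
        ])
        b.add(np.full(n_tot, -1), np.full(n_tot, -1), sex, br, 0, haps)
    return b.freeze()


def _update_breeding_set(current: np.ndarray, gen_of: np.ndarray,
                         candidates: np.ndarray, ebv: np.ndarray,
                         repl: float, n_next: int,
                         rng: np.random.Generator, label: str):
    """One generation of replacement: oldest `repl` fraction exits, counts
    move to the target ``n_next``, recruits are the highest-EBV candidates."""
    n = current.size
    n_exit = int(round(repl * n))
    n_keep = min(n - n_exit, n_next)
    # age priority: keep the youngest, random tie-break within a generation
    order = np.lexsort((rng.random(n), -gen_of[current]))
    survivors = current[order[:n_keep]]
    n_recruit = n_next - n_keep
    if n_recruit > candidates.size:
        raise RuntimeError(
            f"{label}: need {n_recruit} replacements, only "
            f"{candidates.size} candidates"
        )
    top = candidates[np.argsort(-ebv[candidates])[:n_recruit]]
    return np.concatenate([survivors, top]), n_recruit


def breed_generation(pop_arrays: dict, states: list[_BreedState], g: int,
                     gmap: GenomeMap, mutation_rate: float,
                     rng: np.random.Generator):
    """Produce generation ``g`` offspring for every breed (random mating,
    ``offspring_per_dam`` = 1): returns cohort arrays to append."""
    sires_all, dams_all, breeds_all = [], [], []
    for br, st in enumerate(states):
        dam_ids = st.dams
        sire_ids = rng.choice(st.sires, dam_ids.size, replace=True)
        sires_all.append(sire_ids)
        dams_all.append(dam_ids)
        breeds_all.append(np.full(dam_ids.size, br, dtype=np.int8))
    sire_ids = np.concatenate(sires_all)
    dam_ids = np.concatenate(dams_all)
    breeds = np.concatenate(breeds_all)
    H = pop_arrays["haplo"]
    g1 = meiosis_batch(H[sire_ids], gmap, mutation_rate, rng)
    g2 = meiosis_batch(H[dam_ids], gmap, mutation_rate, rng)
    haps = np.stack([g1, g2], axis=1)
    # balanced sexes within each breed cohort
    sex = np.empty(dam_ids.size, dtype=np.int8)
    for br in range(len(states)):
        m = breeds == br
        sex[m] = _balanced_sexes(int(m.sum()), rng)
    return sire_ids, dam_ids, sex, breeds, haps


def simulate_breeding(base: Population, selection: SelectionConfig,
                      gmap: GenomeMap, arch, trait_cfg: TraitConfig,
                      rng: np.random.Generator,
                      mutation_rate: float = 0.0,
                      ebv_solver=None,
                      log: BreedingLog | None = None) -> Population:
    """Step 4: ``n_generations`` of EBV selection from the base population.

    ``arch`` is a calibrated :class:`~beefgs.trait.TraitArchitecture`.
    ``ebv_solver(pop, obs_mask, f) -> ebv`` defaults to within-step UPG
    pedigree BLUP at the true variances on all phenotypes recorded so far
    (generations >= 1).  Selection ranks the newest cohort on these EBVs;
    culling is by age.
    """
    from .trait import simulate_phenotypes, true_breeding_values

    if ebv_solver is None:
        from .evaluation import selection_ebv_solver
        ebv_solver = selection_ebv_solver(trait_cfg)

    nb = len(selection.breeds)
    sire = [base.sire.copy()]
    dam = [base.dam.copy()]
    sex = [base.sex.copy()]
    breed = [base.breed.copy()]
    gen = [base.gen.copy()]
    haps = [base.haplo]
    n = base.n

    tbv0 = true_breeding_values(base.haplo, arch)
    y0 = simulate_phenotypes(tbv0, base.sex, trait_cfg, rng)
    tbv = [tbv0]
    y = [y0]
    n_progeny = [np.zeros(n, dtype=np.int32)]

    states = []
    for br, spec in enumerate(selection.breeds):
        rows = np.flatnonzero((base.breed == br))
        states.append(_BreedState(
            spec=spec,
            sires=rows[base.sex[rows] == MALE],
            dams=rows[base.sex[rows] == FEMALE],
        ))
        if states[-1].sires.size != spec.n_males or states[-1].dams.size != spec.n_females:
            raise ValueError(f"breed {spec.name}: base cohort does not match spec")

    f_cache = np.empty(0, dtype=np.float64)
    for g in range(1, selection.n_generations + 1):
        arrs = {
            "haplo": np.concatenate(haps, axis=0),
        }
        s_ids, d_ids, sx, brd, hp = breed_generation(arrs, states, g, gmap,
                                                     mutation_rate, rng)
        cohort_tbv = true_breeding_values(hp, arch)
        cohort_y = simulate_phenotypes(cohort_tbv, sx, trait_cfg, rng)
        ids = np.arange(n, n + sx.size)
        sire.append(s_ids); dam.append(d_ids); sex.append(sx)
        breed.append(brd); gen.append(np.full(sx.size, g, dtype=np.int16))
        haps.append(hp); tbv.append(cohort_tbv); y.append(cohort_y)
        prog = np.zeros(sx.size, dtype=np.int32)
        n_progeny.append(prog)
        np_all = np.concatenate(n_progeny)
        np.add.at(np_all, s_ids, 1)
        np.add.at(np_all, d_ids, 1)
        # write back increments
        off = 0
        for k in range(len(n_progeny)):
            n_progeny[k] = np_all[off:off + n_progeny[k].size]
            off += n_progeny[k].size
        n += sx.size

        if g == selection.n_generations:
            break

        # --- selection of replacements on pedigree-BLUP EBVs -------------
        part = Population(
            sire=np.concatenate(sire), dam=np.concatenate(dam),
            sex=np.concatenate(sex), breed=np.concatenate(breed),
            gen=np.concatenate(gen), haplo=None,
            tbv=np.concatenate(tbv), y=np.concatenate(y),
        )
        from .relationships import inbreeding
        f_cache = inbreeding(part.sire, part.dam, f_cache)
        obs = part.gen >= 1
        ebv = ebv_solver(part, obs, f_cache)
        for br, st in enumerate(states):
            cohort = ids[brd == br]
            spec = st.spec
            # growth is linear in the founding counts: n_t = n_0 (1 + g t),
            # which reproduces the published genotyped/cohort proportions
            st.sires, rec_s = _update_breeding_set(
                st.sires, part.gen, cohort[sx[brd == br] == MALE], ebv,
                spec.sire_repl,
                int(round(spec.n_males * (1.0 + spec.sire_growth * g))), rng,
                f"breed {spec.name} generation {g} sires")
            st.dams, rec_d = _update_breeding_set(
                st.dams, part.gen, cohort[sx[brd == br] == FEMALE], ebv,
                spec.dam_repl,
                int(round(spec.n_females * (1.0 + spec.dam_growth * g))), rng,
                f"breed {spec.name} generation {g} dams")
            if log is not None:
                log.records.append(dict(
                    generation=g, breed=spec.name,
                    n_sires=st.sires.size, n_dams=st.dams.size,
                    recruited_sires=rec_s, recruited_dams=rec_d,
                    cohort=int(cohort.size),
                ))

    pop = Population(
        sire=np.concatenate(sire), dam=np.concatenate(dam),
        sex=np.concatenate(sex), breed=np.concatenate(breed),
        gen=np.concatenate(gen), haplo=np.concatenate(haps, axis=0),
        n_progeny=np.concatenate(n_progeny),
        tbv=np.concatenate(tbv), y=np.concatenate(y),
    )
    return pop


def assign_metafounders(pop: Population) -> Population:
    """Recode unknown parents as per-breed metafounder ids ``-(breed+1)``.

    Animals with known parents are unchanged; exactly one metafounder per
    breed results.
    """
    unknown_s = pop.sire < 0
    unknown_d = pop.dam < 0
    sire = np.where(unknown_s, -(pop.breed.astype(np.int64) + 1), pop.sire)
    dam = np.where(unknown_d, -(pop.breed.astype(np.int64) + 1), pop.dam)
    return Population(
        sire=sire, dam=dam, sex=pop.sex, breed=pop.breed, gen=pop.gen,
        haplo=pop.haplo, n_progeny=pop.n_progeny, tbv=pop.tbv, y=pop.y,
        n_metafounders=int(np.unique(pop.breed[unknown_s | unknown_d]).size),
    )
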