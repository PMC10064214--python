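"""Population structure: expansion, breed formation, selected breeding."""

import numpy as np
import pytest

from beefgs import presets
from beefgs.population import (
    FEMALE,
    MALE,
    Population,
    _update_breeding_set,
    assign_metafounders,
    expand,
    form_breeds,
    fst_between_breeds,
    make_base_population,
    simulate_breeding,
)
from beefgs.relationships import inbreeding


class TestExpansion:
    def test_offspring_count_per_generation(self, historical_micro):
        gmap, haps = historical_micro
        cfg = presets.ExpansionConfig(n_males=10, n_females=10,
                                      n_generations=1, offspring_per_dam=5,
                                      max_breeding_per_sex=50)
        pop = expand(haps, cfg, gmap, np.random.default_rng(0))
        assert (pop.gen == 1).sum() == 50  # 10 dams x 5 offspring

    def test_founder_pool_too_small_raises(self, historical_micro):
        gmap, haps = historical_micro
        cfg = presets.ExpansionConfig(n_males=1000, n_females=1000,
                                      n_generations=1, offspring_per_dam=5)
        with pytest.raises(ValueError, match="founder pool"):
            expand(haps, cfg, gmap, np.random.default_rng(0))

    def test_deterministic_given_seed(self, historical_micro):
        gmap, haps = historical_micro
        cfg = presets.ExpansionConfig(n_males=8, n_females=8,
                                      n_generations=2, offspring_per_dam=3,
                                      max_breeding_per_sex=20)
        p1 = expand(haps, cfg, gmap, np.random.default_rng(5))
        p2 = expand(haps, cfg, gmap, np.random.default_rng(5))
        np.testing.assert_array_equal(p1.sire, p2.sire)
        np.testing.assert_array_equal(p1.dam, p2.dam)
        np.testing.assert_array_equal(p1.haplo, p2.haplo)


@pytest.fixture(scope="module")
def breeds(historical_micro):
    gmap, haps = historical_micro
    ecfg = presets.ExpansionConfig(n_males=15, n_females=15,
                                   n_generations=3, offspring_per_dam=3,
                                   max_breeding_per_sex=60)
    expanded = expand(haps, ecfg, gmap, np.random.default_rng(1))
    bcfg = presets.BreedFormationConfig(n_breeds=3, males_per_breed=8,
                                        females_per_breed=8,
                                        n_generations=4,
                                        offspring_per_dam=2)
    return form_breeds(expanded, bcfg, gmap, np.random.default_rng(2)), bcfg


class TestBreedFormation:
    def test_breeds_are_reproductively_isolated(self, breeds):
        pop, bcfg = breeds
        # pedigree paths never cross breeds after the founding generation
        for i in range(pop.n):
            for p in (pop.sire[i], pop.dam[i]):
                if p >= 0:
                    assert pop.breed[p] == pop.breed[i]

    def test_two_offspring_per_dam_cohort_size(self, breeds):
        pop, bcfg = breeds
        per_breed = [(pop.gen == 1) & (pop.breed == b) for b in range(3)]
        for m in per_breed:
            assert m.sum() == bcfg.females_per_breed * 2

    def test_fst_increases_during_isolation(self, historical_micro):
        """Drift in isolated breeds builds divergence over generations."""
        gmap, haps = historical_micro
        ecfg = presets.ExpansionConfig(n_males=15, n_females=15,
                                       n_generations=2, offspring_per_dam=3,
                                       max_breeding_per_sex=60)
        bcfg = presets.BreedFormationConfig(n_breeds=3, males_per_breed=6,
                                            females_per_breed=6,
                                            n_generations=6,
                                            offspring_per_dam=2)
        loci = np.arange(gmap.n_loci)
        early, late = [], []
        for seed in range(5):
            expanded = expand(haps, ecfg, gmap, np.random.default_rng(seed))
            pop = form_breeds(expanded, bcfg, gmap,
                              np.random.default_rng(100 + seed))
            early.append(fst_between_breeds(pop, loci, generation=1))
            late.append(fst_between_breeds(pop, loci, generation=6))
        assert np.mean(late) > np.mean(early)


class TestReplacement:
    def test_growth_arithmetic_first_generation(self, rng):
        """220 sires at 7.2% growth -> 236 in the next generation."""
        current = np.arange(220)
        gen_of = np.zeros(400, dtype=np.int16)
        candidates = np.arange(220, 400)
        ebv = rng.normal(size=400)
        target = int(round(220 * 1.072))
        updated, n_rec = _update_breeding_set(
            current, gen_of, candidates, ebv, repl=0.5065, n_next=target,
            rng=rng, label="t")
        assert updated.size == 236
        assert n_rec == 236 - (220 - round(0.5065 * 220))

    def test_full_replacement_takes_only_candidates(self, rng):
        current = np.arange(10)
        gen_of = np.concatenate([np.zeros(10, np.int16),
                                 np.ones(30, np.int16)])
        candidates = np.arange(10, 40)
        ebv = rng.normal(size=40)
        updated, _ = _update_breeding_set(current, gen_of, candidates, ebv,
                                          repl=1.0, n_next=10, rng=rng,
                                          label="t")
        assert set(updated) <= set(candidates)

    def test_recruits_are_highest_ebv(self, rng):
        current = np.arange(4)
        gen_of = np.zeros(20, dtype=np.int16)
        gen_of[4:] = 1
        candidates = np.arange(4, 20)
        ebv = np.arange(20.0)  # best candidates are the last ids
        updated, _ = _update_breeding_set(current, gen_of, candidates, ebv,
                                          repl=0.5, n_next=6, rng=rng,
                                          label="t")
        recruits = set(updated) - set(current)
        assert recruits == {16, 17, 18, 19}

    def test_insufficient_candidates_is_an_error(self, rng):
        with pytest.raises(RuntimeError, match="breed X"):
            _update_breeding_set(np.arange(10), np.zeros(12, np.int16),
                                 np.arange(10, 12), np.zeros(12), repl=0.5,
                                 n_next=20, rng=rng, label="breed X")


class TestSelectedBreeding:
    def test_selection_beats_random_selection(self, historical_micro, micro_cfg):
        """EBV-ranked replacement yields more gain than random replacement."""
        from beefgs.pipeline import simulate_population
        from beefgs.trait import make_architecture

        gains_sel, gains_rnd = [], []
        for seed in range(4):
            pop, gmap, arch, _ = simulate_population(
                micro_cfg, np.random.SeedSequence(1000 + seed))
            gains_sel.append(pop.tbv[pop.gen == pop.gen.max()].mean()
                             - pop.tbv[pop.gen == 0].mean())
            # random "EBVs": same machinery, uninformative ranking
            import beefgs.pipeline as pl

            cfg = micro_cfg
            master = np.random.SeedSequence(1000 + seed)
            sim_ss, _ = master.spawn(2)
            s_hist, s_loci, s_exp, s_bf, s_trait, s_breed = sim_ss.spawn(6)
            from beefgs import genome as gn
            from beefgs import population as pp

            rngh = np.random.default_rng(s_hist)
            cand_map = gn.build_candidate_map(cfg.genome,
                                              cfg.history.n_loci_pool, rngh)
            pool = gn.simulate_historical(cand_map, cfg.history, rngh)
            gmap2, fh = gn.select_segregating_loci(
                pool, cand_map, cfg.genome.n_markers, cfg.genome.n_qtl,
                cfg.genome.maf_min, np.random.default_rng(s_loci))
            expanded = pp.expand(fh, cfg.expansion, gmap2,
                                 np.random.default_rng(s_exp),
                                 cfg.genome.mutation_rate)
            breeds = pp.form_breeds(expanded, cfg.breed_formation, gmap2,
                                    np.random.default_rng(s_bf),
                                    cfg.genome.mutation_rate)
            rng_b = np.random.default_rng(s_breed)
            base = pp.make_base_population(breeds, cfg.selection, gmap2,
                                           rng_b, cfg.genome.mutation_rate)
            arch2 = make_architecture(gmap2, base.haplo, cfg.trait,
                                      np.random.default_rng(s_trait))
            noise_rng = np.random.default_rng(999)
            pop_r = pp.simulate_breeding(
                base, cfg.selection, gmap2, arch2, cfg.trait, rng_b,
                mutation_rate=cfg.genome.mutation_rate,
                ebv_solver=lambda p, o, f: noise_rng.normal(size=p.n))
            gains_rnd.append(pop_r.tbv[pop_r.gen == pop_r.gen.max()].mean()
                             - pop_r.tbv[pop_r.gen == 0].mean())
        assert np.mean(gains_sel) > np.mean(gains_rnd)

    def test_pedigree_topologically_ordered(self, micro_pop):
        pop = micro_pop["pop"]
        idx = np.arange(pop.n)
        assert np.all(pop.sire < idx)
        assert np.all(pop.dam < idx)

    def test_sires_male_dams_female(self, micro_pop):
        pop = micro_pop["pop"]
        known_s = pop.sire[pop.sire >= 0]
        known_d = pop.dam[pop.dam >= 0]
        assert np.all(pop.sex[known_s] == MALE)
        assert np.all(pop.sex[known_d] == FEMALE)

    def test_offspring_breed_matches_parents(self, micro_pop):
        pop = micro_pop["pop"]
        m = pop.sire >= 0
        assert np.all(pop.breed[pop.sire[m]] == pop.breed[m])
        assert np.all(pop.breed[pop.dam[m]] == pop.breed[m])

    def test_inbreeding_accumulates(self, micro_pop):
        pop = micro_pop["pop"]
        sire = np.where(pop.sire >= 0, pop.sire, -1)
        dam = np.where(pop.dam >= 0, pop.dam, -1)
        f = inbreeding(sire, dam)
        g_last = pop.gen.max()
        assert f[pop.gen == g_last].mean() > f[pop.gen == 1].mean()

    def test_genetic_gain_is_positive(self, micro_pop):
        pop = micro_pop["pop"]
        assert pop.tbv[pop.gen == pop.gen.max()].mean() > \
            pop.tbv[pop.gen == 0].mean()


class TestMetafounders:
    def test_one_metafounder_per_breed(self, micro_pop):
        pop = assign_metafounders(micro_pop["pop"])
        mf_codes = np.unique(pop.sire[pop.sire < 0])
        assert pop.n_metafounders == 5
        assert mf_codes.size == 5
        # breed-A base animal gets sire = dam = MF_A
        base = np.flatnonzero((pop.gen == 0) & (pop.breed == 0))
        assert np.all(pop.sire[base] == -1)
        assert np.all(pop.dam[base] == -1)

    def test_known_parents_unchanged(self, micro_pop):
        pop0 = micro_pop["pop"]
        pop = assign_metafounders(pop0)
        known = pop0.sire >= 0
        np.testing.assert_array_equal(pop.sire[known], pop0.sire[known])

    def test_no_dangling_parents_after_truncation(self, micro_pop):
        """Every parent reference resolves to a pedigree row or metafounder."""
        pop = assign_metafounders(micro_pop["pop"])
        nb = int(pop.breed.max()) + 1
        for p in (pop.sire, pop.dam):
            assert np.all((p >= 0) | (p >= -nb))
            assert np.all(p < pop.n)
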