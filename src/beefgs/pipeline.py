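"""Orchestration: simulate one herd, evaluate the scenario × case grid,
aggregate replicates.

One replicate simulates the population once and then evaluates every
genotyping scenario × phenotyping case cell on that same population (the
experimental design holds the herd fixed across cells).  Randomness is
split into independent child streams per stage (genome, expansion, breed
formation, trait, breeding, and one stream per design cell) so that, e.g.,
scenario sampling does not perturb the simulated population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import genome as gn
from . import population as pp
from . import relationships as rel
from . import scenarios as sc
from .presets import RunConfig
from .trait import make_architecture

SCENARIOS_ORDER = ["RefSc", "Sc1", "Sc2", "Sc3", "Sc4"]


@dataclass
class ReplicateResult:
    """Accuracy tables of one replicate.

    ``grid``: overall candidate accuracy, cases × scenarios.
    ``by_sex``: long frame (case, scenario, sex, accuracy, n).
    ``no_record``: long frame for unrecorded candidates by sex.
    """

    seed: int
    grid: pd.DataFrame
    by_sex: pd.DataFrame
    no_record: pd.DataFrame
    n_animals: int
    n_candidates: int
    meta: dict = field(default_factory=dict)


def simulate_population(cfg: RunConfig, rng_master: np.random.SeedSequence):
    """Run the four simulation stages; returns (population, gmap, arch)."""
    s_hist, s_loci, s_exp, s_bf, s_trait, s_breed = rng_master.spawn(6)
    rng = np.random.default_rng(s_hist)
    cand_map = gn.build_candidate_map(cfg.genome, cfg.history.n_loci_pool, rng)
    pool = gn.simulate_historical(cand_map, cfg.history, rng)
    gmap, founder_haps = gn.select_segregating_loci(
        pool, cand_map, cfg.genome.n_markers, cfg.genome.n_qtl,
        cfg.genome.maf_min, np.random.default_rng(s_loci))
    mu = cfg.genome.mutation_rate
    expanded = pp.expand(founder_haps, cfg.expansion, gmap,
                         np.random.default_rng(s_exp), mutation_rate=mu)
    breeds = pp.form_breeds(expanded, cfg.breed_formation, gmap,
                            np.random.default_rng(s_bf), mutation_rate=mu)
    rng_b = np.random.default_rng(s_breed)
    base = pp.make_base_population(breeds, cfg.selection, gmap, rng_b,
                                   mutation_rate=mu)
    arch = make_architecture(gmap, base.haplo, cfg.trait,
                             np.random.default_rng(s_trait))
    log = pp.BreedingLog()
    pop = pp.simulate_breeding(base, cfg.selection, gmap, arch, cfg.trait,
                               rng_b, mutation_rate=mu, log=log)
    pop = pp.assign_metafounders(pop)
    return pop, gmap, arch, log


def evaluate_grid(pop: pp.Population, gmap: gn.GenomeMap, cfg: RunConfig,
                  rng_design: np.random.SeedSequence,
                  rtol: float = 1e-8) -> ReplicateResult:
    """Evaluate all requested scenario × case cells on one population."""
    design = cfg.design
    tc = cfg.trait
    g_cand = design.candidate_generation
    cand = pop.gen == g_cand
    scen_defs = sc.build_scenarios(design)

    # shared pedigree machinery
    sire = np.where(pop.sire >= 0, pop.sire, -1)
    dam = np.where(pop.dam >= 0, pop.dam, -1)
    f = rel.inbreeding(sire, dam)

    # metafounder structure from base-generation breed allele frequencies
    base_rows = np.flatnonzero(pop.gen == 0)
    markers = gmap.marker_idx
    P = np.stack([
        pop.haplo[base_rows[pop.breed[base_rows] == b]][:, :, markers]
        .mean(axis=(0, 1))
        for b in range(int(pop.breed.max()) + 1)
    ], axis=1)
    gamma = rel.gamma_from_freqs(P)
    gp = rel.build_a_gamma_inverse(sire, dam, pop.breed, gamma, f=f)

    rng_by_cell = {}
    streams = rng_design.spawn(len(cfg.scenarios) + len(cfg.cases))
    for i, s in enumerate(cfg.scenarios):
        rng_by_cell[("geno", s)] = np.random.default_rng(streams[i])
    for j, c in enumerate(cfg.cases):
        rng_by_cell[("pheno", c)] = np.random.default_rng(
            streams[len(cfg.scenarios) + j])

    # per-case observed masks (shared across scenarios, as in the design)
    obs_masks = {
        c: sc.select_phenotyped(pop, sc.CASES[c], rng_by_cell[("pheno", c)])
        for c in cfg.cases
    }

    grid = pd.DataFrame(index=cfg.cases, columns=cfg.scenarios, dtype=float)
    by_sex_rows, norec_rows = [], []
    for s_name in cfg.scenarios:
        scen = scen_defs[s_name]
        if scen.budget > 0:
            geno_idx = sc.select_genotyped(pop, scen, design,
                                           rng_by_cell[("geno", s_name)])
            dosage = pop.dosage(markers, rows=geno_idx)
            gmat = rel.build_g_gamma(dosage)
            a22 = rel.a_gamma_submatrix(sire, dam, pop.breed, gamma,
                                        geno_idx, f=f)
            h_inv = rel.build_h_gamma_inverse(gp.a_gamma_inv, a22, gmat,
                                              geno_idx)
        x0 = None
        for c_name in cfg.cases:
            obs = obs_masks[c_name]
            if scen.budget == 0:
                solu = ev.solve_blup_upg(pop, obs, tc, f=f, rtol=rtol, x0=x0)
            else:
                solu = ev.solve_ssgblup_mf(pop, obs, h_inv, tc, rtol=rtol,
                                           x0=x0)
            x0 = np.concatenate([solu.beta, solu.u])
            ebv = solu.ebv
            grid.loc[c_name, s_name] = ev.accuracy(pop.tbv, ebv, cand)
            for sex_name, sex_code in (("M", pp.MALE), ("F", pp.FEMALE)):
                sel = cand & (pop.sex == sex_code)
                by_sex_rows.append(dict(
                    case=c_name, scenario=s_name, sex=sex_name,
                    accuracy=ev.accuracy(pop.tbv, ebv, sel),
                    n=int(sel.sum()),
                ))
                sel_nr = sel & ~obs
                norec_rows.append(dict(
                    case=c_name, scenario=s_name, sex=sex_name,
                    accuracy=ev.accuracy(pop.tbv, ebv, sel_nr)
                    if sel_nr.sum() >= 2 else float("nan"),
                    n=int(sel_nr.sum()),
                ))
    return ReplicateResult(
        seed=-1, grid=grid,
        by_sex=pd.DataFrame(by_sex_rows),
        no_record=pd.DataFrame(norec_rows),
        n_animals=pop.n, n_candidates=int(cand.sum()),
    )


def run_replicate(cfg: RunConfig, seed: int, rtol: float = 1e-8) -> ReplicateResult:
    """Simulate one herd and evaluate the full grid; deterministic in
    (config, seed)."""
    cfg.validate()
    master = np.random.SeedSequence(seed)
    sim_ss, design_ss = master.spawn(2)
    pop, gmap, arch, log = simulate_population(cfg, sim_ss)
    res = evaluate_grid(pop, gmap, cfg, design_ss, rtol=rtol)
    res.seed = seed
    res.meta = {"breeding_log": log.frame().to_dict("records")}
    return res


@dataclass
class GridResult:
    """Replicate-aggregated study result."""

    replicates: list[ReplicateResult]

    @property
    def mean_grid(self) -> pd.DataFrame:
        return sum(r.grid for r in self.replicates) / len(self.replicates)

    @property
    def sd_grid(self) -> pd.DataFrame:
        stack = np.stack([r.grid.to_numpy(dtype=float) for r in self.replicates])
        g0 = self.replicates[0].grid
        sd = stack.std(axis=0, ddof=1) if len(self.replicates) > 1 else \
            np.full_like(stack[0], np.nan)
        return pd.DataFrame(sd, index=g0.index, columns=g0.columns)

    def scenario_averages(self) -> pd.Series:
        """Mean accuracy of each scenario across the phenotyping cases."""
        return self.mean_grid.mean(axis=0)

    def mean_by_sex(self) -> pd.DataFrame:
        long = pd.concat([r.by_sex for r in self.replicates])
        return (long.groupby(["case", "scenario", "sex"], sort=False)
                ["accuracy"].mean().reset_index())

    def mean_no_record(self) -> pd.DataFrame:
        long = pd.concat([r.no_record for r in self.replicates])
        g = (long.groupby(["case", "scenario", "sex"], sort=False)
             .agg(accuracy=("accuracy", "mean"), n=("n", "mean"))
             .reset_index())
        return g


def run_grid(cfg: RunConfig, seed: int, n_replicates: int | None = None,
             out_dir: str | Path | None = None,
             progress: bool = False) -> GridResult:
    """Run ``n_replicates`` full replicates (seeds ``seed + i``).

    With ``out_dir``, per-replicate accuracy tables are written as CSV and
    completed replicates are skipped on re-run (resumability).
    """
    n_rep = n_replicates if n_replicates is not None else cfg.n_replicates
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")
    reps = []
    for i in range(n_rep):
        rep_seed = seed + i
        if out is not None:
            gpath = out / f"replicate_{rep_seed}_grid.csv"
            if gpath.exists():
                grid = pd.read_csv(gpath, index_col=0)
                by_sex = pd.read_csv(out / f"replicate_{rep_seed}_by_sex.csv")
                norec = pd.read_csv(out / f"replicate_{rep_seed}_no_record.csv")
                meta = json.loads((out / f"replicate_{rep_seed}_meta.json").read_text())
                reps.append(ReplicateResult(
                    seed=rep_seed, grid=grid, by_sex=by_sex, no_record=norec,
                    n_animals=meta["n_animals"],
                    n_candidates=meta["n_candidates"]))
                continue
        r = run_replicate(cfg, rep_seed)
        reps.append(r)
        if progress:
            print(f"replicate seed={rep_seed}: "
                  f"RefSc/100MF={r.grid.loc['100MF', 'RefSc']:.3f}", flush=True)
        if out is not None:
            r.grid.to_csv(out / f"replicate_{rep_seed}_grid.csv")
            r.by_sex.to_csv(out / f"replicate_{rep_seed}_by_sex.csv", index=False)
            r.no_record.to_csv(out / f"replicate_{rep_seed}_no_record.csv",
                               index=False)
            (out / f"replicate_{rep_seed}_meta.json").write_text(json.dumps(
                {"n_animals": r.n_animals, "n_candidates": r.n_candidates}))
    res = GridResult(reps)
    if out is not None:
        write_summary(res, out)
    return res


def write_summary(res: GridResult, out_dir: str | Path) -> None:
    """Aggregated tables: mean/SD grid with a scenario-average row, plus
    by-sex and no-record breakdowns."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mg = res.mean_grid
    mg.loc["average"] = res.scenario_averages()
    mg.to_csv(out / "accuracy_mean.csv")
    res.sd_grid.to_csv(out / "accuracy_sd.csv")
    res.mean_by_sex().to_csv(out / "accuracy_by_sex.csv", index=False)
    res.mean_no_record().to_csv(out / "accuracy_no_record.csv", index=False)


def summarize_dir(run_dir: str | Path) -> GridResult:
    """Re-aggregate a run directory from its per-replicate CSV files."""
    run_dir = Path(run_dir)
    reps = []
    for gpath in sorted(run_dir.glob("replicate_*_grid.csv")):
        seed = int(gpath.stem.split("_")[1])
        grid = pd.read_csv(gpath, index_col=0)
        by_sex = pd.read_csv(run_dir / f"replicate_{seed}_by_sex.csv")
        norec = pd.read_csv(run_dir / f"replicate_{seed}_no_record.csv")
        meta = json.loads((run_dir / f"replicate_{seed}_meta.json").read_text())
        reps.append(ReplicateResult(seed=seed, grid=grid, by_sex=by_sex,
                                    no_record=norec,
                                    n_animals=meta["n_animals"],
                                    n_candidates=meta["n_candidates"]))
    if not reps:
        raise FileNotFoundError(f"no replicate outputs under {run_dir}")
    return GridResult(reps)
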