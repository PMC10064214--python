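"""Genome simulation: map layout, historical LD-generating phase, meiosis.

The genome is a set of biallelic loci (alleles 0/1) laid out on linkage maps
measured in centimorgans.  A long phase of random mating in a finite
population builds up linkage disequilibrium and drifts allele frequencies;
markers and QTL are then drawn from the loci still segregating with
MAF above a threshold.

Crossovers follow the Haldane model (no interference): the number of
crossovers per chromosome is Poisson with mean equal to the genetic length
in Morgans and positions are uniform.  For batched gamete production the
equivalent Markov formulation is used: the parental phase switches between
adjacent loci with probability r = (1 - exp(-2d))/2 for map distance d
Morgans, which is exactly the marginal law of the Poisson crossover process
at the loci.  Recurrent mutation flips each transmitted allele
independently with the mutation rate (bidirectional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .presets import GenomeConfig, HistoryConfig

ROLE_CANDIDATE = 0
ROLE_MARKER = 1
ROLE_QTL = 2

_ROLE_NAMES = {ROLE_CANDIDATE: "candidate", ROLE_MARKER: "marker", ROLE_QTL: "qtl"}


@dataclass
class GenomeMap:
    """Per-locus layout: chromosome, genetic position and role.

    Positions are strictly increasing within a chromosome.  Marker and QTL
    sets are disjoint by construction (one role per locus).
    """

    chrom: np.ndarray            # (L,) int32, 0-based chromosome index
    pos_cM: np.ndarray           # (L,) float64
    role: np.ndarray             # (L,) uint8
    chrom_lengths_cM: np.ndarray  # (n_chrom,) float64

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.pos_cM = np.asarray(self.pos_cM, dtype=np.float64)
        self.role = np.asarray(self.role, dtype=np.uint8)
        self.chrom_lengths_cM = np.asarray(self.chrom_lengths_cM, dtype=np.float64)
        for c in range(self.n_chromosomes):
            p = self.pos_cM[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_loci(self) -> int:
        return int(self.chrom.size)

    @property
    def n_chromosomes(self) -> int:
        return int(self.chrom_lengths_cM.size)

    @property
    def total_length_cM(self) -> float:
        return float(self.chrom_lengths_cM.sum())

    @property
    def marker_idx(self) -> np.ndarray:
        return np.flatnonzero(self.role == ROLE_MARKER)

    @property
    def qtl_idx(self) -> np.ndarray:
        return np.flatnonzero(self.role == ROLE_QTL)

    @property
    def genome_pos_cM(self) -> np.ndarray:
        """Position on the concatenated genome axis."""
        offsets = np.concatenate([[0.0], np.cumsum(self.chrom_lengths_cM)[:-1]])
        return self.pos_cM + offsets[self.chrom]

    def subset(self, idx: np.ndarray) -> "GenomeMap":
        idx = np.sort(np.asarray(idx))
        return GenomeMap(
            self.chrom[idx], self.pos_cM[idx], self.role[idx], self.chrom_lengths_cM
        )

    # -- flat-file round trip ---------------------------------------------

    def write_map(self, path) -> None:
        """Write a 4-column map file: chromosome, locus id, position cM, role."""
        with open(path, "w") as fh:
            fh.write("#chrom\tlocus\tpos_cM\trole\n")
            for i in range(self.n_loci):
                fh.write(
                    f"{self.chrom[i] + 1}\tL{i}\t{self.pos_cM[i]:.6f}\t"
                    f"{_ROLE_NAMES[int(self.role[i])]}\n"
                )

    @classmethod
    def read_map(cls, path) -> "GenomeMap":
        chrom, pos, role = [], [], []
        names = {v: k for k, v in _ROLE_NAMES.items()}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                c, _, p, r = line.split()
                chrom.append(int(c) - 1)
                pos.append(float(p))
                role.append(names[r])
        chrom = np.array(chrom)
        pos = np.array(pos)
        n_chrom = chrom.max() + 1
        lengths = np.array([pos[chrom == c].max() for c in range(n_chrom)])
        return cls(chrom, pos, np.array(role, dtype=np.uint8), lengths)


def build_candidate_map(genome: GenomeConfig, n_loci: int, rng: np.random.Generator) -> GenomeMap:
    """Uniform-random candidate loci, allocated to chromosomes by length."""
    lengths = np.asarray(genome.chrom_lengths_cM, dtype=float)
    share = lengths / lengths.sum()
    counts = np.floor(share * n_loci).astype(int)
    # largest-remainder top-up
    rem = share * n_loci - counts
    for i in np.argsort(rem)[::-1][: n_loci - counts.sum()]:
        counts[i] += 1
    chrom = np.repeat(np.arange(genome.n_chromosomes, dtype=np.int32), counts)
    pos = np.concatenate(
        [np.sort(rng.uniform(0.0, lengths[c], counts[c])) for c in range(genome.n_chromosomes)]
    )
    return GenomeMap(chrom, pos, np.zeros(n_loci, dtype=np.uint8), lengths)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------


def _interval_recomb(gmap: GenomeMap) -> np.ndarray:
    """Haldane recombination fraction between consecutive loci; 0.5 across
    chromosome boundaries."""
    d_cM = np.diff(gmap.pos_cM)
    r = 0.5 * (1.0 - np.exp(-0.02 * d_cM))
    r[np.diff(gmap.chrom) != 0] = 0.5
    return r


def meiosis(hap_pair: np.ndarray, gmap: GenomeMap, mutation_rate: float,
            rng: np.random.Generator) -> np.ndarray:
    """One gamete from one parent, with explicit Poisson crossovers.

    ``hap_pair`` is a (2, L) 0/1 array (maternal, paternal haplotypes).
    """
    L = gmap.n_loci
    phase = np.empty(L, dtype=np.intp)
    for c in range(gmap.n_chromosomes):
        sel = gmap.chrom == c
        pos = gmap.pos_cM[sel]
        n_x = rng.poisson(gmap.chrom_lengths_cM[c] / 100.0)
        xpos = np.sort(rng.uniform(0.0, gmap.chrom_lengths_cM[c], n_x))
        start = rng.integers(0, 2)
        phase[sel] = (start + np.searchsorted(xpos, pos)) % 2
    gamete = hap_pair[phase, np.arange(L)].astype(np.uint8)
    if mutation_rate > 0:
        gamete ^= (rng.random(L) < mutation_rate).astype(np.uint8)
    return gamete


def meiosis_batch(parent_haps: np.ndarray, gmap: GenomeMap, mutation_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gametes for a batch of parents, (n, 2, L) -> (n, L).

    Uses the interval-switch formulation of the Haldane model, which has the
    same distribution at the loci as explicit Poisson crossovers.
    """
    n, _, L = parent_haps.shape
    phase = np.empty((n, L), dtype=np.uint8)
    phase[:, 0] = 0
    if L > 1:
        r = _interval_recomb(gmap).astype(np.float32)
        switch = (rng.random((n, L - 1), dtype=np.float32) < r).view(np.uint8)
        np.bitwise_xor.accumulate(switch, axis=1, out=phase[:, 1:])
    phase ^= rng.integers(0, 2, size=(n, 1), dtype=np.uint8)
    h0 = parent_haps[:, 0, :]
    diff = parent_haps[:, 0, :] ^ parent_haps[:, 1, :]
    gam = h0 ^ (diff & -phase)
    if mutation_rate > 0:
        if mutation_rate < 0.01:
            # sparse path: draw the Binomial number of mutation events and
            # place them at distinct uniform cells (exact, much cheaper)
            k = rng.binomial(n * L, mutation_rate)
            if k:
                cells = rng.integers(0, n * L, k)
                while np.unique(cells).size < k:
                    cells = np.unique(cells)
                    cells = np.concatenate(
                        [cells, rng.integers(0, n * L, k - cells.size)]
                    )
                gam.reshape(-1)[cells] ^= 1
        else:
            gam = gam ^ (rng.random((n, L), dtype=np.float32) < mutation_rate)
    return np.ascontiguousarray(gam, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Historical phase
# ---------------------------------------------------------------------------


def simulate_historical(gmap: GenomeMap, history: HistoryConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Random-union-of-gametes history; returns final haplotypes (N, 2, L).

    Founders start with independent Bernoulli(0.5) alleles; per-generation
    population size is constant in phase 1 and interpolates linearly to
    ``size_end`` over phase 2.  No selection, no structure.
    """
    if history.size_phase1 < 2 or history.size_end < 2:
        raise ValueError("historical population sizes must be >= 2")
    sizes = [history.size_phase1] * history.n_gen_phase1
    if history.n_gen_phase2 > 0:
        sizes += [
            int(round(s))
            for s in np.linspace(history.size_phase1, history.size_end,
                                 history.n_gen_phase2 + 1)[1:]
        ]
    L = gmap.n_loci
    haps = rng.integers(0, 2, size=(sizes[0] if sizes else 2, 2, L), dtype=np.uint8)
    for n_next in sizes[1:] if sizes else []:
        n_prev = haps.shape[0]
        p1 = rng.integers(0, n_prev, n_next)
        p2 = (p1 + 1 + rng.integers(0, n_prev - 1, n_next)) % n_prev  # no selfing
        g1 = meiosis_batch(haps[p1], gmap, history.mutation_rate, rng)
        g2 = meiosis_batch(haps[p2], gmap, history.mutation_rate, rng)
        haps = np.stack([g1, g2], axis=1)
    p = haps.mean(axis=(0, 1))
    if np.all((p == 0.0) | (p == 1.0)):
        raise RuntimeError(
            "no segregating loci after the historical phase; increase the "
            "mutation rate or initial polymorphism"
        )
    return haps


def allele_freq(haps: np.ndarray) -> np.ndarray:
    """Frequency of allele 1 per locus from (n, 2, L) haplotypes."""
    return haps.mean(axis=(0, 1))


def maf(haps: np.ndarray) -> np.ndarray:
    p = allele_freq(haps)
    return np.minimum(p, 1.0 - p)


def select_segregating_loci(haps: np.ndarray, gmap: GenomeMap, n_markers: int,
                            n_qtl: int, maf_min: float,
                            rng: np.random.Generator):
    """Assign marker/QTL roles among loci segregating with MAF > ``maf_min``.

    Markers are the eligible loci nearest to ``n_markers`` equidistant
    targets on the concatenated genome ("evenly spaced" on a discrete
    eligible set, greedily without reuse); QTL are drawn uniformly at random
    from the remaining eligible loci.

    Returns ``(gmap_subset, haps_subset)`` restricted to the chosen loci.
    """
    eligible = np.flatnonzero(maf(haps) > maf_min)
    if eligible.size < n_markers + n_qtl:
        raise ValueError(
            f"only {eligible.size} loci with MAF > {maf_min}; "
            f"need {n_markers + n_qtl}"
        )
    gpos = gmap.genome_pos_cM
    total = gmap.total_length_cM
    targets = (np.arange(n_markers) + 0.5) * total / n_markers

    elig_pos = gpos[eligible]
    order = np.argsort(elig_pos)
    elig_sorted = eligible[order]
    pos_sorted = elig_pos[order]
    used = np.zeros(elig_sorted.size, dtype=bool)
    marker_loci = np.empty(n_markers, dtype=np.int64)
    for k, t in enumerate(targets):
        j = int(np.searchsorted(pos_sorted, t))
        best, best_d = -1, np.inf
        for jj in (j - 1, j):  # nearest unused: scan outwards from insertion point
            step = -1 if jj == j - 1 else 1
            while 0 <= jj < pos_sorted.size and used[jj]:
                jj += step
            if 0 <= jj < pos_sorted.size:
                d = abs(pos_sorted[jj] - t)
                if d < best_d:
                    best, best_d = jj, d
        used[best] = True
        marker_loci[k] = elig_sorted[best]
    remaining = elig_sorted[~used]
    qtl_loci = rng.choice(remaining, size=n_qtl, replace=False)

    role = np.zeros(gmap.n_loci, dtype=np.uint8)
    role[marker_loci] = ROLE_MARKER
    role[qtl_loci] = ROLE_QTL
    keep = np.sort(np.concatenate([marker_loci, qtl_loci]))
    sub = GenomeMap(gmap.chrom[keep], gmap.pos_cM[keep], role[keep],
                    gmap.chrom_lengths_cM)
    return sub, np.ascontiguousarray(haps[:, :, keep])


# ---------------------------------------------------------------------------
# LD diagnostics (used by tests and reports)
# ---------------------------------------------------------------------------


def pairwise_r2(haps: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Squared gametic correlation r² between pairs of loci (haplotype-based)."""
    H = haps.reshape(-1, haps.shape[-1]).astype(np.float64)
    a = H[:, idx_a]
    b = H[:, idx_b]
    a = a - a.mean(0)
    b = b - b.mean(0)
    num = (a * b).mean(0) ** 2
    den = a.var(0) * b.var(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(den > 0, num / den, np.nan)
    return r2


def mean_r2_by_distance(haps: np.ndarray, gmap: GenomeMap, bins_cM,
                        max_pairs: int = 20000,
                        rng: np.random.Generator | None = None):
    """Mean r² of random segregating locus pairs, binned by map distance."""
    rng = rng or np.random.default_rng(0)
    seg = np.flatnonzero(maf(haps) > 0.05)
    ia = rng.choice(seg, size=max_pairs)
    ib = rng.choice(seg, size=max_pairs)
    same = gmap.chrom[ia] == gmap.chrom[ib]
    dist = np.where(same, np.abs(gmap.pos_cM[ia] - gmap.pos_cM[ib]), np.inf)
    r2 = pairwise_r2(haps, ia, ib)
    out = []
    for lo, hi in bins_cM:
        sel = (dist >= lo) & (dist < hi) & np.isfinite(r2) & (ia != ib)
        out.append(np.nanmean(r2[sel]) if sel.any() else np.nan)
    return np.array(out)
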