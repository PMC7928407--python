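"""Founder genome simulation, QTL effects, true breeding values, meiosis.

The genetic architecture is a single additive polygenic trait on a
cattle-like genome: 10 chromosomes of 10^8 bp, each carrying 1,000 causal
loci and 2,000 marker loci sampled uniformly at random (disjoint sets).
Founder haplotypes come from a coalescent simulation (msprime) with a
two-epoch cattle-like demography, which produces realistic linkage
disequilibrium that decays with physical distance.  Causal effects are
drawn from a normal distribution and rescaled once per replicate so the
variance of founder true breeding values (TBV) defines the additive
genetic unit, sigma2_a = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # founder engine; everything downstream only needs the allele matrices
    import msprime

    _HAVE_MSPRIME = True
except ImportError:  # pragma: no cover
    _HAVE_MSPRIME = False

__all__ = [
    "GenomeSpec",
    "GenomeMap",
    "FounderPopulation",
    "QtlEffects",
    "simulate_founders",
    "sample_qtl_effects",
    "true_breeding_value",
    "meiosis",
    "meiose_batch",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Static description of the simulated genome.

    map_length is in Morgans per chromosome (crossovers are Poisson with
    this mean, no interference).  ne_recent/ne_ancient/t_ancient define the
    two-epoch coalescent demography of the founder simulation.
    """

    n_chromosomes: int = 10
    bp_per_chromosome: float = 1e8
    n_causal_per_chromosome: int = 1000
    n_marker_per_chromosome: int = 2000
    map_length: float = 1.0
    ne_recent: float = 100.0
    ne_ancient: float = 1000.0
    t_ancient: float = 100.0
    mutation_rate: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be positive")
        if self.bp_per_chromosome <= 0:
            raise ValueError("bp_per_chromosome must be positive")
        if self.n_causal_per_chromosome < 1 or self.n_marker_per_chromosome < 1:
            raise ValueError("locus counts must be positive")
        if self.map_length <= 0:
            raise ValueError("map_length must be positive")

    @property
    def loci_per_chromosome(self) -> int:
        return self.n_causal_per_chromosome + self.n_marker_per_chromosome

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    @property
    def n_causal(self) -> int:
        return self.n_chromosomes * self.n_causal_per_chromosome

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.n_marker_per_chromosome


@dataclass
class GenomeMap:
    """Concatenated locus layout: positions per chromosome plus causal mask.

    Loci are stored in one flat axis of length ``n_loci``; ``chrom_bounds``
    gives the half-open [start, stop) slice of each chromosome and
    ``positions`` the strictly increasing bp coordinate within it.
    """

    spec: GenomeSpec
    positions: np.ndarray  # float64, length n_loci, bp within chromosome
    chrom_bounds: np.ndarray  # int, shape (n_chromosomes, 2)
    causal_mask: np.ndarray  # bool, length n_loci

    def __post_init__(self) -> None:
        for lo, hi in self.chrom_bounds:
            p = self.positions[lo:hi]
            if np.any(np.diff(p) <= 0):
                raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def causal_idx(self) -> np.ndarray:
        return np.flatnonzero(self.causal_mask)

    @property
    def marker_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.causal_mask)


@dataclass
class FounderPopulation:
    """Diploid founder genomes: haplotypes[animal, haplotype, locus] in {0,1}."""

    genome_map: GenomeMap
    haplotypes: np.ndarray  # uint8, shape (n_founders, 2, n_loci)

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    def dosages(self, loci: np.ndarray | None = None) -> np.ndarray:
        d = self.haplotypes.sum(axis=1, dtype=np.int16)
        return d if loci is None else d[:, loci]

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


@dataclass
class QtlEffects:
    """Additive causal-locus effects, scaled so var(founder TBV) = sigma2_a = 1.

    ``freqs`` are founder allele frequencies at the causal loci; TBVs are
    centred at 2p so the founder mean is ~0 (the gain-standardisation
    convention).
    """

    causal_idx: np.ndarray  # indices into the flat locus axis
    effects: np.ndarray  # float64, per causal locus, post-scaling
    freqs: np.ndarray  # founder allele frequency per causal locus
    scale: float  # divisor applied to the raw N(0,1) draws


def _simulate_chromosome(
    spec: GenomeSpec, n_founders: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One chromosome of founder haplotypes: (positions, G[site, 2*n])."""
    if not _HAVE_MSPRIME:  # pragma: no cover
        raise RuntimeError("msprime is required for founder simulation")
    demography = msprime.Demography()
    demography.add_population(name="pop", initial_size=spec.ne_recent)
    demography.add_population_parameters_change(
        time=spec.t_ancient, initial_size=spec.ne_ancient, population="pop"
    )
    ts = msprime.sim_ancestry(
        samples=n_founders,
        demography=demography,
        sequence_length=spec.bp_per_chromosome,
        recombination_rate=spec.map_length / spec.bp_per_chromosome,
        random_seed=seed,
    )
    need = spec.loci_per_chromosome
    mu = spec.mutation_rate
    for attempt in range(4):
        mts = msprime.sim_mutations(
            ts, rate=mu, model=msprime.BinaryMutationModel(),
            discrete_genome=False, random_seed=seed + 7919 * (attempt + 1),
        )
        if mts.num_sites >= need:
            break
        mu *= 4.0
    else:
        raise RuntimeError(
            f"coalescent simulation yielded {mts.num_sites} segregating sites; "
            f"{need} required — increase mutation_rate or sequence length"
        )
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(mts.num_sites, size=need, replace=False))
    drop = np.setdiff1d(np.arange(mts.num_sites), keep)
    mts = mts.delete_sites(drop)
    positions = np.array([s.position for s in mts.sites()])
    geno = mts.genotype_matrix().astype(np.uint8)  # (need, 2*n_founders)
    return positions, geno


def simulate_founders(spec: GenomeSpec, n_founders: int, seed: int) -> FounderPopulation:
    """Coalescent founder genomes with LD; raises if >10% of loci are fixed.

    Within each chromosome, `loci_per_chromosome` segregating sites are
    retained at random; causal and marker subsets are then drawn disjointly.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    ss = np.random.SeedSequence(seed)
    chrom_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in ss.spawn(spec.n_chromosomes)]
    rng = np.random.default_rng(ss.spawn(1)[0])

    n_loci = spec.n_loci
    haplos = np.empty((n_founders, 2, n_loci), dtype=np.uint8)
    positions = np.empty(n_loci)
    bounds = np.empty((spec.n_chromosomes, 2), dtype=np.int64)
    causal_mask = np.zeros(n_loci, dtype=bool)
    per = spec.loci_per_chromosome
    for c in range(spec.n_chromosomes):
        pos, geno = _simulate_chromosome(spec, n_founders, chrom_seeds[c])
        lo, hi = c * per, (c + 1) * per
        bounds[c] = (lo, hi)
        positions[lo:hi] = pos
        # geno rows are sites, columns alternate haplotypes of each diploid
        haplos[:, :, lo:hi] = geno.T.reshape(n_founders, 2, per)
        causal_local = rng.choice(per, size=spec.n_causal_per_chromosome, replace=False)
        causal_mask[lo + causal_local] = True

    gmap = GenomeMap(spec=spec, positions=positions, chrom_bounds=bounds, causal_mask=causal_mask)
    pop = FounderPopulation(genome_map=gmap, haplotypes=haplos)
    freqs = pop.allele_frequencies()
    fixed = np.mean((freqs == 0) | (freqs == 1))
    if fixed > 0.10:
        raise RuntimeError(
            f"{fixed:.1%} of loci are monomorphic among founders — degenerate simulation"
        )
    return pop


def sample_qtl_effects(spec: GenomeSpec, founders: FounderPopulation, seed: int) -> QtlEffects:
    """Normal causal effects, rescaled so the founder TBV variance is exactly 1."""
    gmap = founders.genome_map
    causal_idx = gmap.causal_idx
    freqs = founders.haplotypes[:, :, causal_idx].mean(axis=(0, 1))
    if np.all((freqs == 0) | (freqs == 1)):
        raise ValueError("all causal loci are fixed among founders: no genetic variance")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(causal_idx.size)
    dos = founders.dosages(causal_idx).astype(np.float64)
    tbv_raw = (dos - 2.0 * freqs) @ raw
    sd = tbv_raw.std()
    if sd == 0:
        raise ValueError("founder TBVs have zero variance")
    return QtlEffects(causal_idx=causal_idx, effects=raw / sd, freqs=freqs, scale=float(sd))


def true_breeding_value(genotype: np.ndarray, effects: QtlEffects) -> float | np.ndarray:
    """TBV = sum over causal loci of effect * (dosage - 2p).

    ``genotype`` is either a single diploid genome of shape (2, n_loci) or a
    batch of shape (n, 2, n_loci); the flat locus axis must match the map the
    effects were sampled on.
    """
    g = np.asarray(genotype)
    single = g.ndim == 2
    if single:
        g = g[None]
    if g.shape[2] <= int(effects.causal_idx.max()):
        raise ValueError("genotype locus axis does not match the causal-locus map")
    dos = g[:, :, effects.causal_idx].sum(axis=1).astype(np.float64)
    tbv = (dos - 2.0 * effects.freqs) @ effects.effects
    return float(tbv[0]) if single else tbv


def meiosis(parent: np.ndarray, gmap: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid parent.

    Crossovers are Poisson with mean ``map_length`` per chromosome, placed
    uniformly in bp, with a random starting haplotype and no interference.
    """
    parent = np.asarray(parent)
    if parent.ndim != 2 or parent.shape[0] != 2:
        raise ValueError("parent genome must have shape (2, n_loci)")
    gamete = np.empty(parent.shape[1], dtype=np.uint8)
    spec = gmap.spec
    for (lo, hi) in gmap.chrom_bounds:
        pos = gmap.positions[lo:hi]
        n_co = rng.poisson(spec.map_length)
        cuts = np.sort(rng.uniform(0, spec.bp_per_chromosome, size=n_co))
        # haplotype index flips at each crossover
        h = (rng.integers(0, 2) + np.searchsorted(cuts, pos)) % 2
        gamete[lo:hi] = parent[:, lo:hi][h, np.arange(hi - lo)]
    return gamete


def meiose_batch(
    haplotypes: np.ndarray,
    parent_rows: np.ndarray,
    gmap: GenomeMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gametes for many matings at once: one gamete per entry of parent_rows."""
    n = len(parent_rows)
    out = np.empty((n, haplotypes.shape[2]), dtype=np.uint8)
    for i, r in enumerate(parent_rows):
        out[i] = meiosis(haplotypes[r], gmap, rng)
    return out


def export_plink_raw(pop: FounderPopulation, path, ids=None) -> None:
    """Write the marker panel as PLINK .raw-style dosage text (0/1/2).

    One line per animal: FID IID PAT MAT SEX PHENOTYPE then one dosage per
    marker locus; loci are named chr<c>_<bp>.
    """
    gmap = pop.genome_map
    midx = gmap.marker_idx
    names = []
    for c, (lo, hi) in enumerate(gmap.chrom_bounds, start=1):
        for i in midx[(midx >= lo) & (midx < hi)]:
            names.append(f"chr{c}_{int(gmap.positions[i])}")
    dos = pop.dosages(midx)
    ids = range(pop.n_founders) if ids is None else ids
    with open(path, "w") as fh:
        fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(names) + "\n")
        for row, i in zip(dos, ids):
            fh.write(f"0 {i} 0 0 0 -9 " + " ".join(map(str, row)) + "\n")


def adjacent_marker_r2(pop: FounderPopulation, max_pairs: int = 2000,
                       rng: np.random.Generator | None = None) -> float:
    """Mean r^2 between physically adjacent marker pairs (LD diagnostic)."""
    return _pair_r2(pop, lag="adjacent", max_pairs=max_pairs, rng=rng)


def distant_marker_r2(pop: FounderPopulation, distance_bp: float = 1e7,
                      max_pairs: int = 2000, rng: np.random.Generator | None = None) -> float:
    """Mean r^2 between marker pairs separated by >= distance_bp."""
    return _pair_r2(pop, lag=distance_bp, max_pairs=max_pairs, rng=rng)


def _pair_r2(pop, lag, max_pairs, rng):
    rng = rng or np.random.default_rng(0)
    gmap = pop.genome_map
    dos = pop.dosages().astype(np.float64)
    vals = []
    for (lo, hi) in gmap.chrom_bounds:
        midx = np.flatnonzero(~gmap.causal_mask[lo:hi]) + lo
        pos = gmap.positions[midx]
        if lag == "adjacent":
            pairs = list(zip(midx[:-1], midx[1:]))
        else:
            j = np.searchsorted(pos, pos + lag)
            ok = j < len(midx)
            pairs = list(zip(midx[ok], midx[j[ok]]))
        if len(pairs) > max_pairs:
            sel = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[k] for k in sel]
        for a, b in pairs:
            x, y = dos[:, a], dos[:, b]
            if x.std() == 0 or y.std() == 0:
                continue
            vals.append(np.corrcoef(x, y)[0, 1] ** 2)
    return float(np.mean(vals))
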