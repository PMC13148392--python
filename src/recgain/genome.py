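"""Genetic maps, map rescaling, and meiosis under gamma crossover interference.

The meiosis model is a stationary gamma renewal process on the four-strand
bundle: chiasma inter-arrival distances along the chromosome are
Gamma(shape=nu, mean=50 cM), giving a bundle rate of 2 chiasmata per Morgan,
and each chiasma is transmitted to a given gamete with probability 1/2
(thinning, no chromatid interference).  nu = 1 recovers the no-interference
(Haldane/Poisson) limit; nu > 1 suppresses nearby crossovers.  Increased
recombination rates are modelled by multiplying every cM position of the base
map by a constant factor.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import copy_chromosome_gametes

__all__ = [
    "GeneticMap",
    "Individual",
    "Population",
    "MeiosisParams",
    "scale_map",
    "crossover_positions",
    "meiosis_gamete",
    "gametes_batch",
    "make_cross",
    "self_individual",
    "make_dh",
    "cross_batch",
    "self_batch",
    "dh_batch",
]

#: mean chiasma inter-arrival distance on the four-strand bundle, in cM
#: (2 chiasmata per Morgan; thinning by 1/2 gives the map distance).
_BUNDLE_MEAN_CM = 50.0


@dataclass(frozen=True)
class GeneticMap:
    """Ordered cM positions of loci on a set of chromosomes.

    Positions are strictly increasing within each chromosome and satisfy
    0 < position <= length.  ``factor`` records the recombination scaling
    multiplier that has been applied relative to the base map.
    """

    chrom_names: tuple
    chrom_starts: np.ndarray  # (C+1,) int64 flat offsets
    positions: np.ndarray  # (L,) float64 cM
    lengths: np.ndarray  # (C,) float64 cM
    locus_ids: np.ndarray  # (L,) object
    factor: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "chrom_starts", np.asarray(self.chrom_starts, dtype=np.int64))
        object.__setattr__(self, "positions", np.ascontiguousarray(self.positions, dtype=np.float64))
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=np.float64))
        if self.factor <= 0:
            raise ValueError("map factor must be positive")
        if len(self.chrom_names) != len(self.lengths):
            raise ValueError("chrom_names and lengths disagree")
        if self.chrom_starts[0] != 0 or self.chrom_starts[-1] != len(self.positions):
            raise ValueError("chrom_starts must span the position array")
        for c in range(self.n_chrom):
            p = self.chrom_positions(c)
            if p.size == 0:
                raise ValueError(f"chromosome {self.chrom_names[c]} has no loci")
            if p[0] <= 0 or p[-1] > self.lengths[c] * (1 + 1e-12):
                raise ValueError("positions must satisfy 0 < pos <= length")
            if np.any(np.diff(p) <= 0):
                raise ValueError("positions must be strictly increasing")

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_names)

    @property
    def n_loci(self) -> int:
        return int(self.positions.shape[0])

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def chrom_slice(self, c: int) -> slice:
        return slice(int(self.chrom_starts[c]), int(self.chrom_starts[c + 1]))

    def chrom_positions(self, c: int) -> np.ndarray:
        return self.positions[self.chrom_slice(c)]

    def scaled(self, factor: float) -> "GeneticMap":
        """Return this (base) map with all positions and lengths multiplied."""
        return scale_map(self, factor)

    def subset(self, indices: np.ndarray) -> "GeneticMap":
        """Restrict the map to a sorted subset of locus indices.

        Chromosome lengths are preserved, so meiosis on the subset map is
        statistically identical to meiosis on the full map marginalised to
        the retained loci.
        """
        indices = np.asarray(indices, dtype=np.int64)
        if indices.size and np.any(np.diff(indices) <= 0):
            raise ValueError("subset indices must be strictly increasing")
        starts = np.searchsorted(indices, self.chrom_starts)
        return GeneticMap(
            chrom_names=self.chrom_names,
            chrom_starts=starts,
            positions=self.positions[indices],
            lengths=self.lengths.copy(),
            locus_ids=self.locus_ids[indices],
            factor=self.factor,
        )


def scale_map(gmap: GeneticMap, factor: float) -> GeneticMap:
    """Multiply every cM position and chromosome length of a base map.

    Scaling is always applied to the unscaled map (factor 1) so that scaled
    maps remain exact multiples of the base map.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if gmap.factor != 1.0:
        raise ValueError("scale_map must be applied to a base (factor-1) map")
    if factor == 1.0:
        return gmap
    return GeneticMap(
        chrom_names=gmap.chrom_names,
        chrom_starts=gmap.chrom_starts.copy(),
        positions=gmap.positions * factor,
        lengths=gmap.lengths * factor,
        locus_ids=gmap.locus_ids,
        factor=float(factor),
    )


@dataclass(frozen=True)
class MeiosisParams:
    """Gamma-renewal interference parameters.

    interference_nu : gamma shape nu (> 0); 1 = no interference (Poisson),
        2.6 is the conventional default of stochastic gene-dropping
        simulators for plant genomes.
    obligate_crossover : if True, a gamete-retained crossover is forced
        (placed uniformly) on chromosomes where thinning retained none.
    """

    interference_nu: float = 2.6
    obligate_crossover: bool = False

    def __post_init__(self):
        if self.interference_nu <= 0:
            raise ValueError("interference_nu must be positive")


@dataclass
class Individual:
    """A diploid individual: two haplotype vectors over the map loci."""

    haplotypes: np.ndarray  # (2, L) int8
    is_inbred: bool = False

    def __post_init__(self):
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_loci)")
        if self.is_inbred and not np.array_equal(self.haplotypes[0], self.haplotypes[1]):
            raise ValueError("is_inbred individual must be homozygous everywhere")

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0, dtype=np.int8)


@dataclass
class Population:
    """An ordered collection of diploids sharing one genetic map."""

    haplotypes: np.ndarray  # (n, 2, L) int8
    gmap: GeneticMap
    generation: str = ""

    def __post_init__(self):
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if self.haplotypes.shape[2] != self.gmap.n_loci:
            raise ValueError("haplotype length does not match the map")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def individual(self, i: int) -> Individual:
        h = self.haplotypes[i]
        return Individual(h.copy(), is_inbred=bool(np.array_equal(h[0], h[1])))

    def dosages(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Genotype dosage matrix in {0,1,2}, optionally at selected loci."""
        if loci is None:
            return self.haplotypes.sum(axis=1, dtype=np.int8)
        h = self.haplotypes[:, :, np.asarray(loci, dtype=np.int64)]
        return h.sum(axis=1, dtype=np.int8)

    def allele_frequencies(self, loci: np.ndarray | None = None) -> np.ndarray:
        return self.dosages(loci).mean(axis=0, dtype=np.float64) / 2.0


# ---------------------------------------------------------------------------
# crossover sampling


def _sample_crossovers_batch(
    length_cm: float, size: int, params: MeiosisParams, rng: np.random.Generator
):
    """Sample gamete-retained crossover positions for ``size`` meioses.

    Returns (xo, counts): xo is (size, K) float64, sorted ascending per row
    and padded with +inf; counts gives the number of valid entries per row.

    The chiasma process on the bundle is a stationary gamma renewal process:
    the first event distance is U * Gamma(nu+1, scale) (the equilibrium
    forward-recurrence time, via the length-biased interval), subsequent
    inter-arrivals are Gamma(nu, scale) with scale = 50/nu cM.  Each chiasma
    is retained for the gamete independently with probability 1/2.
    """
    if length_cm <= 0:
        raise ValueError("chromosome length must be positive")
    nu = params.interference_nu
    scale = _BUNDLE_MEAN_CM / nu
    mean_events = length_cm / _BUNDLE_MEAN_CM
    sd_events = np.sqrt(mean_events / min(nu, 1.0))
    k = max(4, int(mean_events + 6.0 * sd_events + 5))
    # float32 draws: crossover placement precision ~2e-4 cM, far below any
    # locus spacing of interest, at roughly half the sampling cost
    first = rng.random(size, dtype=np.float32) * rng.standard_gamma(
        nu + 1.0, size=size, dtype=np.float32
    )
    cum = np.empty((size, k), dtype=np.float32)
    cum[:, 0] = first
    cum[:, 1:] = rng.standard_gamma(nu, size=(size, k - 1), dtype=np.float32)
    np.cumsum(cum, axis=1, out=cum)
    cum *= scale
    # rare rows whose k events do not yet cover the chromosome: extend them
    short = np.flatnonzero(cum[:, -1] < length_cm)
    while short.size:
        extra = scale * rng.standard_gamma(nu, size=(short.size, k), dtype=np.float32)
        block = cum[short, -1][:, None] + np.cumsum(extra, axis=1)
        cum = np.concatenate(
            [cum, np.full((size, k), np.inf, dtype=np.float32)], axis=1
        )
        cum[short, -extra.shape[1]:] = block  # appended values continue each row in order
        k = cum.shape[1]
        short = short[cum[short, -1] < length_cm]
    keep = (cum < length_cm) & (rng.random(cum.shape, dtype=np.float32) < 0.5)
    counts = keep.sum(axis=1).astype(np.int64)
    kmax = int(counts.max()) if size else 0
    if params.obligate_crossover:
        kmax = max(kmax, 1)
    xo = np.full((size, max(kmax, 1)), np.inf)
    pos = np.where(keep, cum, np.float32(np.inf))
    pos.sort(axis=1)
    xo[:, :kmax] = pos[:, :kmax] if kmax else 0.0
    if params.obligate_crossover:
        none = counts == 0
        if np.any(none):
            xo[none, 0] = rng.uniform(0.0, length_cm, size=int(none.sum()))
            counts[none] = 1
    return xo, counts


def crossover_positions(
    length_cm: float, params: MeiosisParams, rng: np.random.Generator
) -> np.ndarray:
    """Sorted gamete-retained crossover positions for one meiosis."""
    xo, counts = _sample_crossovers_batch(float(length_cm), 1, params, rng)
    return xo[0, : counts[0]].copy()


# ---------------------------------------------------------------------------
# gamete construction


def gametes_batch(
    haplotypes: np.ndarray,
    parents: np.ndarray,
    gmap: GeneticMap,
    params: MeiosisParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce one gamete per entry of ``parents`` (indices into haplotypes).

    Chromosomes segregate independently; within a chromosome the starting
    strand is a fair coin and strands switch at each retained crossover.
    """
    haplotypes = np.ascontiguousarray(haplotypes, dtype=np.int8)
    parents = np.asarray(parents, dtype=np.int64)
    B = parents.shape[0]
    out = np.empty((B, gmap.n_loci), dtype=np.int8)
    for c in range(gmap.n_chrom):
        xo, counts = _sample_crossovers_batch(float(gmap.lengths[c]), B, params, rng)
        start = rng.integers(0, 2, size=B)
        copy_chromosome_gametes(
            haplotypes,
            parents,
            gmap.chrom_positions(c),
            int(gmap.chrom_starts[c]),
            xo,
            counts,
            start,
            out,
        )
    return out


def meiosis_gamete(
    parent: Individual, gmap: GeneticMap, params: MeiosisParams, rng: np.random.Generator
) -> np.ndarray:
    """One gamete (haplotype vector) from a single parent."""
    hap = parent.haplotypes[None, :, :]
    return gametes_batch(hap, np.zeros(1, dtype=np.int64), gmap, params, rng)[0]


def make_cross(
    mother: Individual,
    father: Individual,
    gmap: GeneticMap,
    params: MeiosisParams,
    rng: np.random.Generator,
) -> Individual:
    """F1 from one gamete of each parent."""
    g_m = meiosis_gamete(mother, gmap, params, rng)
    g_f = meiosis_gamete(father, gmap, params, rng)
    child = np.stack([g_m, g_f])
    return Individual(child, is_inbred=bool(np.array_equal(g_m, g_f)))


def self_individual(
    parent: Individual, gmap: GeneticMap, params: MeiosisParams, rng: np.random.Generator
) -> Individual:
    """Self-pollination: two independent gametes from the same parent."""
    return make_cross(parent, parent, gmap, params, rng)


def make_dh(
    parent: Individual, gmap: GeneticMap, params: MeiosisParams, rng: np.random.Generator
) -> Individual:
    """Doubled haploid: one gamete duplicated into both haplotypes."""
    g = meiosis_gamete(parent, gmap, params, rng)
    return Individual(np.stack([g, g.copy()]), is_inbred=True)


# batch counterparts used by the breeding scheme -----------------------------


def cross_batch(
    pop: Population,
    mothers: np.ndarray,
    fathers: np.ndarray,
    params: MeiosisParams,
    rng: np.random.Generator,
    generation: str = "",
) -> Population:
    g_m = gametes_batch(pop.haplotypes, mothers, pop.gmap, params, rng)
    g_f = gametes_batch(pop.haplotypes, fathers, pop.gmap, params, rng)
    hap = np.stack([g_m, g_f], axis=1)
    return Population(hap, pop.gmap, generation=generation)


def self_batch(
    pop: Population, params: MeiosisParams, rng: np.random.Generator, generation: str = ""
) -> Population:
    idx = np.arange(pop.n, dtype=np.int64)
    return cross_batch(pop, idx, idx, params, rng, generation=generation)


def dh_batch(
    pop: Population,
    parents: np.ndarray,
    params: MeiosisParams,
    rng: np.random.Generator,
    generation: str = "",
) -> Population:
    g = gametes_batch(pop.haplotypes, np.asarray(parents, dtype=np.int64), pop.gmap, params, rng)
    hap = np.stack([g, g], axis=1)
    return Population(hap, pop.gmap, generation=generation)
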