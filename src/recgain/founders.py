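"""Synthetic founder populations and default genetic maps.

The simulator needs a base population of fully homozygous founders with a
realistic, cM-governed pattern of linkage disequilibrium and a U-shaped
allele-frequency spectrum.  Rather than depending on an external coalescent
simulator, founders are produced by a declared stand-in: a small set of
ancestral haplotypes is mixed by random mating for a number of generations
(establishing LD that decays with map distance), after which each founder is
taken as a doubled haploid of a random individual from the mixed population.

The default genetic map uses the ten sorghum chromosome lengths of the study
landscape (total 1545.1 cM) with loci placed uniformly at random.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GeneticMap, MeiosisParams, Population, dh_batch, gametes_batch

__all__ = [
    "SORGHUM_CHROM_LENGTHS_CM",
    "FounderSpec",
    "make_map",
    "make_default_map",
    "sample_founders",
    "export_founders_hdf5",
    "load_founders_hdf5",
]

#: Genetic length (cM) of the 10 sorghum chromosomes under the normal
#: recombination rate; the base map spans 1545.1 cM in total.
SORGHUM_CHROM_LENGTHS_CM: dict[str, float] = {
    "1": 186.3,
    "2": 226.5,
    "3": 168.2,
    "4": 169.4,
    "5": 118.5,
    "6": 165.2,
    "7": 132.6,
    "8": 131.7,
    "9": 134.6,
    "10": 112.1,
}


@dataclass(frozen=True)
class FounderSpec:
    """Parameters of the synthetic founder generator.

    n_founders            : number of fully homozygous founders (3,000 in the
                            simulated breeding programme).
    n_loci_per_chr        : biallelic SNP loci per chromosome (10,000).
    n_ancestral_haplotypes: size of the ancestral haplotype pool mixed to
                            create LD; the default matches the 298-accession
                            diversity panel the study's SNPs derive from.
    mixing_generations    : generations of random mating of the ancestral
                            pool before founders are extracted.
    maf_floor             : lower truncation of the ancestral allele-frequency
                            spectrum (in [0, 0.5)); drift during mixing can
                            still fix loci, and monomorphic loci are retained.
    spectrum              : "neutral" (default) draws derived-allele counts in
                            the ancestral pool from the coalescent site-
                            frequency spectrum (P(k) proportional to 1/k with
                            random allele labelling); "beta" uses a
                            Beta(0.2, 0.2) frequency with Bernoulli draws.
    rng_seed              : seed used when no Generator is supplied.
    """

    n_founders: int = 3000
    n_loci_per_chr: int = 10000
    n_ancestral_haplotypes: int = 298
    mixing_generations: int = 50
    maf_floor: float = 0.01
    spectrum: str = "neutral"
    rng_seed: int = 0

    def __post_init__(self):
        if self.spectrum not in ("neutral", "beta"):
            raise ValueError("spectrum must be 'neutral' or 'beta'")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.n_loci_per_chr < 1:
            raise ValueError("n_loci_per_chr must be >= 1")
        if self.n_ancestral_haplotypes < 2:
            raise ValueError("n_ancestral_haplotypes must be >= 2")
        if self.mixing_generations < 0:
            raise ValueError("mixing_generations must be >= 0")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in [0, 0.5)")


#: default crossover landscape (distal_weight, edge_shape): 97% of the map
#: length follows a U-shaped (Beta(a, a), a = 0.10) density concentrated at
#: the chromosome ends, so ~82% of crossovers fall in the most recombinogenic
#: 25% of the physical genome and the pericentromeric half of the physical
#: genome spans ~11% of the map — the distal/pericentromeric contrast of
#: cereal genomes such as sorghum.
DEFAULT_LANDSCAPE: tuple[float, float] = (0.97, 0.10)


def _physical_to_cm(u: np.ndarray, length: float, landscape) -> np.ndarray:
    """Map relative physical positions u in [0,1] to cM positions.

    ``landscape = (w, a)`` mixes a uniform recombination rate (weight 1-w)
    with a U-shaped Beta(a, a) rate concentrated at the chromosome ends
    (weight w); loci uniform in physical position then pile up, in cM, around
    the centromere.  ``landscape=None`` is the uniform (cM = physical) map.
    """
    if landscape is None:
        return length * u
    w, a = landscape
    from scipy.special import betainc

    return length * ((1.0 - w) * u + w * betainc(a, a, u))


def make_map(
    lengths_cm,
    n_loci_per_chr: int,
    rng: np.random.Generator,
    chrom_names=None,
    landscape: tuple[float, float] | None = DEFAULT_LANDSCAPE,
) -> GeneticMap:
    """Place loci uniformly in physical position on each chromosome.

    Physical positions are translated to cM through the crossover landscape
    (see :func:`_physical_to_cm`); ``landscape=None`` gives uniform cM
    placement.  Positions are sorted and the last locus is pinned to the
    chromosome length (so a 1-locus chromosome has its locus at the full
    length).
    """
    lengths = np.asarray(lengths_cm, dtype=np.float64)
    if chrom_names is None:
        chrom_names = tuple(str(i + 1) for i in range(lengths.size))
    positions = []
    ids = []
    for c, length in enumerate(lengths):
        while True:
            u = np.sort(rng.uniform(0.0, 1.0, size=n_loci_per_chr))
            pos = _physical_to_cm(u, length, landscape)
            pos[-1] = length
            if pos[0] > 0 and np.all(np.diff(pos) > 0):
                break
        positions.append(pos)
        ids.extend(f"snp{chrom_names[c]}_{j}" for j in range(n_loci_per_chr))
    starts = np.arange(lengths.size + 1, dtype=np.int64) * n_loci_per_chr
    return GeneticMap(
        chrom_names=tuple(chrom_names),
        chrom_starts=starts,
        positions=np.concatenate(positions),
        lengths=lengths,
        locus_ids=np.array(ids, dtype=object),
        factor=1.0,
    )


def make_default_map(spec: FounderSpec, rng: np.random.Generator | None = None) -> GeneticMap:
    """The 10-chromosome base map on the sorghum Table-of-lengths landscape."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    return make_map(
        list(SORGHUM_CHROM_LENGTHS_CM.values()),
        spec.n_loci_per_chr,
        rng,
        chrom_names=tuple(SORGHUM_CHROM_LENGTHS_CM.keys()),
    )


def _truncated_beta(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Beta(0.2, 0.2) draws truncated (by rejection) to [lo, hi]."""
    out = rng.beta(0.2, 0.2, size=n)
    bad = np.flatnonzero((out < lo) | (out > hi))
    while bad.size:
        out[bad] = rng.beta(0.2, 0.2, size=bad.size)
        bad = bad[(out[bad] < lo) | (out[bad] > hi)]
    return out


def _ancestral_haplotypes(
    A: int, L: int, maf_floor: float, spectrum: str, rng: np.random.Generator
) -> np.ndarray:
    """Ancestral haplotype pool with the requested frequency spectrum."""
    if spectrum == "beta":
        p_anc = _truncated_beta(rng, L, maf_floor, 1.0 - maf_floor)
        return (rng.random((A, L)) < p_anc).astype(np.int8)
    # neutral coalescent site-frequency spectrum: derived-allele count k in
    # the pool of A haplotypes with P(k) ~ 1/k, alleles relabelled at random
    k_min = max(1, int(np.ceil(maf_floor * A)))
    k_max = A - k_min
    if k_max < k_min:
        raise ValueError("maf_floor too large for the ancestral pool size")
    ks = np.arange(k_min, k_max + 1)
    w = 1.0 / ks
    k = rng.choice(ks, size=L, p=w / w.sum())
    flip = rng.random(L) < 0.5
    k = np.where(flip, A - k, k)
    ranks = rng.random((A, L)).argsort(axis=0).argsort(axis=0)
    return (ranks < k[None, :]).astype(np.int8)


def founders_on_map(
    gmap: GeneticMap,
    n_founders: int,
    n_ancestral_haplotypes: int,
    mixing_generations: int,
    maf_floor: float,
    rng: np.random.Generator,
    params: MeiosisParams | None = None,
    spectrum: str = "neutral",
) -> Population:
    """Generate homozygous founders on an arbitrary (factor-1) map.

    Used directly by the breeding scheme, which tracks only the loci a
    scenario needs; :func:`sample_founders` adds the locus-count check of the
    full-genome interface.
    """
    if gmap.factor != 1.0:
        raise ValueError("founders must be generated on the base (factor-1) map")
    if params is None:
        params = MeiosisParams()
    L = gmap.n_loci
    A = n_ancestral_haplotypes
    anc = _ancestral_haplotypes(A, L, maf_floor, spectrum, rng)
    # pair ancestral haplotypes (with replacement) into A diploids
    hap = anc[rng.integers(0, A, size=(A, 2))]
    pop = Population(np.ascontiguousarray(hap), gmap, generation="ancestral")
    for _ in range(mixing_generations):
        parents = rng.integers(0, A, size=2 * A)  # mothers then fathers
        gam = gametes_batch(pop.haplotypes, parents, gmap, params, rng)
        pop = Population(
            np.stack([gam[:A], gam[A:]], axis=1), gmap, generation="mixing"
        )
    picks = rng.integers(0, A, size=n_founders)
    return dh_batch(pop, picks, params, rng, generation="founders")


def sample_founders(
    spec: FounderSpec, gmap: GeneticMap, rng: np.random.Generator | None = None
) -> Population:
    """Founder population of ``spec.n_founders`` fully homozygous diploids."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    expected = gmap.n_chrom * spec.n_loci_per_chr
    if gmap.n_loci != expected:
        raise ValueError(
            f"map has {gmap.n_loci} loci but spec requires {expected} "
            f"({spec.n_loci_per_chr} per chromosome)"
        )
    return founders_on_map(
        gmap,
        spec.n_founders,
        spec.n_ancestral_haplotypes,
        spec.mixing_generations,
        spec.maf_floor,
        rng,
        spectrum=spec.spectrum,
    )


def export_founders_hdf5(pop: Population, path) -> None:
    """Write founder haplotypes to HDF5, one dataset group per chromosome."""
    import h5py

    gmap = pop.gmap
    with h5py.File(path, "w") as f:
        f.attrs["n_individuals"] = pop.n
        f.attrs["factor"] = gmap.factor
        f.attrs["chrom_order"] = [str(c) for c in gmap.chrom_names]
        for c in range(gmap.n_chrom):
            sl = gmap.chrom_slice(c)
            grp = f.create_group(f"chrom_{gmap.chrom_names[c]}")
            grp.attrs["length_cm"] = gmap.lengths[c]
            grp.create_dataset("haplotypes", data=pop.haplotypes[:, :, sl], compression="gzip")
            grp.create_dataset("positions_cm", data=gmap.positions[sl])
            grp.create_dataset(
                "locus_ids",
                data=np.array([str(x) for x in gmap.locus_ids[sl]], dtype="S"),
            )


def load_founders_hdf5(path) -> Population:
    """Read a population written by :func:`export_founders_hdf5`."""
    import h5py

    with h5py.File(path, "r") as f:
        names = [f"chrom_{c}" for c in f.attrs["chrom_order"]]
        haps, positions, ids, lengths, chroms = [], [], [], [], []
        for k in names:
            grp = f[k]
            haps.append(grp["haplotypes"][...])
            positions.append(grp["positions_cm"][...])
            ids.append([s.decode() for s in grp["locus_ids"][...]])
            lengths.append(float(grp.attrs["length_cm"]))
            chroms.append(k.removeprefix("chrom_"))
        factor = float(f.attrs["factor"])
    counts = [p.size for p in positions]
    starts = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    gmap = GeneticMap(
        chrom_names=tuple(chroms),
        chrom_starts=starts,
        positions=np.concatenate(positions),
        lengths=np.asarray(lengths),
        locus_ids=np.array([i for chunk in ids for i in chunk], dtype=object),
        factor=factor,
    )
    return Population(np.concatenate(haps, axis=2), gmap, generation="founders")
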