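"""Additive trait architectures, phenotypes and variance bookkeeping.

A trait is controlled by biallelic QTL with purely additive effects: the
genetic value of an individual is sum_i a_i * d_i with dosage d_i in {0,1,2}.
Raw effects are N(0,1) draws rescaled by one constant so the founder
population has additive genetic variance exactly 1; the environmental
variance sigma_e^2 = (1 - h^2)/h^2 is then fixed once, at founder
calibration, for the whole breeding programme.

Two variance summaries are tracked per generation: the *genetic* variance
(realised variance of genetic values in the population) and the *genic*
variance (sum_i 2 p_i (1-p_i) a_i^2, the additive variance expected under
Hardy-Weinberg and linkage equilibrium at the current allele frequencies).
Their ratio, after correcting the genic variance for full inbreeding,
quantifies the Bulmer effect.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GeneticMap, Population

__all__ = [
    "TraitArchitecture",
    "SnpChip",
    "DegenerateArchitectureError",
    "sample_qtl",
    "sample_chip",
    "sample_architecture",
    "calibrate_architecture",
    "genetic_values",
    "phenotypes",
    "genic_variance",
    "genetic_variance",
]


class DegenerateArchitectureError(RuntimeError):
    """All sampled QTL were monomorphic in the founders (zero genetic variance)."""


@dataclass
class TraitArchitecture:
    """QTL positions, additive effects and the fixed error variance."""

    qtl_idx: np.ndarray  # (nq,) int64 locus indices into the population map
    effects: np.ndarray  # (nq,) float64 additive effect per allele copy
    sigma_e2: float
    h2_target: float

    def __post_init__(self):
        self.qtl_idx = np.asarray(self.qtl_idx, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=np.float64)
        if self.qtl_idx.shape != self.effects.shape:
            raise ValueError("qtl_idx and effects must align")
        if self.sigma_e2 < 0:
            raise ValueError("sigma_e2 must be >= 0")

    @property
    def n_qtl(self) -> int:
        return int(self.qtl_idx.size)


@dataclass
class SnpChip:
    """Genotyping marker panel; marker loci must exclude all QTL."""

    marker_idx: np.ndarray  # (m,) int64 locus indices into the population map

    def __post_init__(self):
        self.marker_idx = np.asarray(self.marker_idx, dtype=np.int64)
        if np.unique(self.marker_idx).size != self.marker_idx.size:
            raise ValueError("duplicate marker loci")

    @property
    def n_markers(self) -> int:
        return int(self.marker_idx.size)

    def check_disjoint(self, qtl_idx: np.ndarray) -> None:
        if np.intersect1d(self.marker_idx, qtl_idx).size:
            raise ValueError("chip markers overlap QTL loci")


def sample_qtl(gmap: GeneticMap, n_per_chr: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform without-replacement QTL indices, ``n_per_chr`` per chromosome."""
    picks = []
    for c in range(gmap.n_chrom):
        sl = gmap.chrom_slice(c)
        n_avail = sl.stop - sl.start
        if n_per_chr > n_avail:
            raise ValueError("more QTL requested than loci on chromosome")
        picks.append(sl.start + rng.choice(n_avail, size=n_per_chr, replace=False))
    return np.sort(np.concatenate(picks))


def sample_chip(
    gmap: GeneticMap, n_per_chr: int, rng: np.random.Generator, exclude: np.ndarray
) -> SnpChip:
    """Uniform marker panel, ``n_per_chr`` per chromosome, excluding QTL loci.

    No minor-allele-frequency filtering is applied.
    """
    exclude = np.asarray(exclude, dtype=np.int64)
    picks = []
    for c in range(gmap.n_chrom):
        sl = gmap.chrom_slice(c)
        avail = np.setdiff1d(np.arange(sl.start, sl.stop, dtype=np.int64), exclude)
        if n_per_chr > avail.size:
            raise ValueError("not enough non-QTL loci for the chip")
        picks.append(rng.choice(avail, size=n_per_chr, replace=False))
    chip = SnpChip(np.sort(np.concatenate(picks)))
    chip.check_disjoint(exclude)
    return chip


def calibrate_architecture(
    qtl_idx: np.ndarray,
    h2: float,
    founders: Population,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> TraitArchitecture:
    """Draw N(0,1) effects and rescale so founder genetic variance is 1.

    If every sampled effect draw yields zero founder variance (possible only
    when all QTL are monomorphic) the architecture is degenerate.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie in (0, 1)")
    if founders.n == 0:
        raise ValueError("founder population is empty")
    qtl_idx = np.asarray(qtl_idx, dtype=np.int64)
    d = founders.dosages(qtl_idx).astype(np.float64)
    for _ in range(max_retries):
        a = rng.standard_normal(qtl_idx.size)
        g = d @ a
        v = g.var()
        # relative floor guards against float noise on a constant-value vector
        if v > 1e-12 * float(a @ a):
            a /= np.sqrt(v)
            return TraitArchitecture(
                qtl_idx=qtl_idx,
                effects=a,
                sigma_e2=(1.0 - h2) / h2,
                h2_target=h2,
            )
    raise DegenerateArchitectureError(
        "founder genetic variance is zero (all QTL monomorphic)"
    )


def sample_architecture(
    gmap: GeneticMap,
    n_qtl_per_chr: int,
    h2: float,
    founders: Population,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> TraitArchitecture:
    """Sample QTL uniformly per chromosome and calibrate effects on founders.

    On a degenerate draw (all QTL monomorphic in the founders) the QTL set is
    resampled, up to ``max_retries`` times.
    """
    last_err: Exception | None = None
    for _ in range(max_retries):
        qtl = sample_qtl(gmap, n_qtl_per_chr, rng)
        try:
            return calibrate_architecture(qtl, h2, founders, rng, max_retries=max_retries)
        except DegenerateArchitectureError as err:  # resample the QTL set
            last_err = err
    raise DegenerateArchitectureError(str(last_err))


def genetic_values(pop: Population, arch: TraitArchitecture) -> np.ndarray:
    """True genetic value per individual: dosage at QTL times effects."""
    d = pop.dosages(arch.qtl_idx).astype(np.float64)
    return d @ arch.effects


def phenotypes(
    pop: Population,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    genetic: np.ndarray | None = None,
) -> np.ndarray:
    """Genetic values plus i.i.d. N(0, sigma_e^2) environmental noise.

    ``genetic`` may pass pre-computed genetic values to avoid recomputation.
    """
    g = genetic_values(pop, arch) if genetic is None else genetic
    if arch.sigma_e2 == 0:
        return g.copy()
    return g + rng.normal(0.0, np.sqrt(arch.sigma_e2), size=g.size)


def genic_variance(pop: Population, arch: TraitArchitecture) -> float:
    """sum_i 2 p_i (1 - p_i) a_i^2 at the current QTL allele frequencies."""
    p = pop.allele_frequencies(arch.qtl_idx)
    return float(np.sum(2.0 * p * (1.0 - p) * arch.effects**2))


def genetic_variance(pop: Population, arch: TraitArchitecture) -> float:
    """Realised population variance (denominator n) of genetic values."""
    return float(genetic_values(pop, arch).var())
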