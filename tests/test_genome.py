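"""Meiosis engine: map scaling, gamma-interference crossovers, gamete ops."""
import numpy as np
import pytest
from scipy import stats

from recgain.founders import SORGHUM_CHROM_LENGTHS_CM
from recgain.genome import (
    GeneticMap,
    Individual,
    MeiosisParams,
    Population,
    _sample_crossovers_batch,
    cross_batch,
    crossover_positions,
    dh_batch,
    gametes_batch,
    make_cross,
    make_dh,
    meiosis_gamete,
    scale_map,
    self_batch,
    self_individual,
)
from recgain._kernels import copy_chromosome_gametes


# ---------------------------------------------------------------------- maps


def test_scale_map_multiplies_lengths_and_positions(two_chrom_map):
    scaled = scale_map(two_chrom_map, 2.0)
    assert np.allclose(scaled.lengths, two_chrom_map.lengths * 2, rtol=1e-12)
    assert np.allclose(scaled.positions, two_chrom_map.positions * 2, rtol=1e-12)
    assert scaled.factor == 2.0
    assert list(scaled.locus_ids) == list(two_chrom_map.locus_ids)


@pytest.mark.parametrize(
    "chrom,factor,expected",
    [("10", 2.0, 224.2), ("5", 8.0, 948.0)],
)
def test_scale_map_sorghum_lengths(chrom, factor, expected):
    length = SORGHUM_CHROM_LENGTHS_CM[chrom]
    gmap = GeneticMap(
        (chrom,), np.array([0, 1]), np.array([length]), np.array([length]),
        np.array(["x"], dtype=object),
    )
    assert scale_map(gmap, factor).lengths[0] == pytest.approx(expected, abs=1e-9)


def test_scale_map_identity_and_errors(two_chrom_map):
    assert scale_map(two_chrom_map, 1.0) is two_chrom_map
    with pytest.raises(ValueError):
        scale_map(two_chrom_map, 0.0)
    with pytest.raises(ValueError):
        scale_map(scale_map(two_chrom_map, 2.0), 2.0)  # must scale the base map


def test_map_subset_preserves_lengths(two_chrom_map):
    sub = two_chrom_map.subset(np.array([0, 5, 41, 60]))
    assert sub.n_loci == 4
    assert np.array_equal(sub.lengths, two_chrom_map.lengths)
    assert sub.chrom_starts.tolist() == [0, 2, 4]


# ----------------------------------------------------------------- crossovers


def test_poisson_limit_without_interference(rng):
    """At nu=1 the retained-crossover count on 100 cM is Poisson(1)."""
    params = MeiosisParams(interference_nu=1.0)
    _, counts = _sample_crossovers_batch(100.0, 100_000, params, rng)
    observed = np.bincount(counts, minlength=8)
    kmax = 6
    expected = stats.poisson.pmf(np.arange(kmax), 1.0) * counts.size
    obs = np.concatenate([observed[:kmax], [counts.size - observed[:kmax].sum()]])
    exp = np.concatenate([expected, [counts.size - expected.sum()]])
    p = stats.chisquare(obs, exp).pvalue
    assert abs(counts.mean() - 1.0) < 3 * counts.std() / np.sqrt(counts.size)
    assert p > 0.01


def test_crossover_count_scales_with_map_factor(rng):
    """Mean retained-CO count is proportional to the map scaling factor."""
    params = MeiosisParams()
    n = 20_000
    _, c1 = _sample_crossovers_batch(186.3, n, params, rng)
    _, c8 = _sample_crossovers_batch(186.3 * 8, n, params, rng)
    se1 = c1.std() / np.sqrt(n)
    assert abs(c1.mean() - 1.863) < 3 * se1
    ratio = c8.mean() / c1.mean()
    se_ratio = ratio * np.sqrt(
        (c1.std() / c1.mean()) ** 2 / n + (c8.std() / c8.mean()) ** 2 / n
    )
    assert abs(ratio - 8.0) < 3 * se_ratio


def test_interference_reduces_coincidence(rng):
    """With nu=2.6, double crossovers in nearby intervals are suppressed."""
    params = MeiosisParams()  # nu = 2.6
    xo, counts = _sample_crossovers_batch(30.0, 200_000, params, rng)
    valid = np.isfinite(xo)
    in_a = ((xo >= 0) & (xo < 10) & valid).any(axis=1)
    in_b = ((xo >= 20) & (xo < 30) & valid).any(axis=1)
    p_a, p_b, p_ab = in_a.mean(), in_b.mean(), (in_a & in_b).mean()
    coc = p_ab / (p_a * p_b)
    assert coc < 1.0


def test_crossover_positions_sorted_within_range(rng):
    params = MeiosisParams(interference_nu=1.0)
    for _ in range(50):
        pos = crossover_positions(250.0, params, rng)
        assert np.all(np.diff(pos) >= 0)
        assert np.all((pos > 0) & (pos < 250.0))
    with pytest.raises(ValueError):
        crossover_positions(0.0, params, rng)


def test_vanishing_length_gives_no_crossovers(rng):
    assert crossover_positions(1e-12, MeiosisParams(), rng).size == 0


def test_obligate_crossover_flag(rng):
    params = MeiosisParams(interference_nu=2.6, obligate_crossover=True)
    _, counts = _sample_crossovers_batch(1.0, 2000, params, rng)
    assert counts.min() >= 1


# ------------------------------------------------------------------- gametes


def test_crossover_boundary_convention():
    """A crossover at x switches strands only for loci with position > x."""
    hap = np.zeros((1, 2, 3), dtype=np.int8)
    hap[0, 1] = 1  # strand 1 carries allele 1 everywhere
    pos = np.array([10.0, 20.0, 30.0])
    out = np.empty((1, 3), dtype=np.int8)
    xo = np.array([[20.0]])
    copy_chromosome_gametes(
        hap, np.zeros(1, np.int64), pos, 0, xo, np.ones(1, np.int64),
        np.zeros(1, np.int64), out,
    )
    assert out.tolist() == [[0, 0, 1]]  # locus exactly at 20 copied before switch
    xo = np.array([[19.99]])
    copy_chromosome_gametes(
        hap, np.zeros(1, np.int64), pos, 0, xo, np.ones(1, np.int64),
        np.zeros(1, np.int64), out,
    )
    assert out.tolist() == [[0, 1, 1]]


def test_homozygous_parent_gamete_identity(two_chrom_map, rng):
    hap = rng.integers(0, 2, size=(1, two_chrom_map.n_loci), dtype=np.int8)
    parent = Individual(np.vstack([hap, hap]), is_inbred=True)
    g = meiosis_gamete(parent, two_chrom_map, MeiosisParams(), rng)
    assert np.array_equal(g, hap[0])


def test_no_crossover_gamete_is_intact_haplotype(tiny_length_map, rng):
    h0 = np.zeros(tiny_length_map.n_loci, dtype=np.int8)
    h1 = np.ones_like(h0)
    parent = Individual(np.vstack([h0, h1]))
    for _ in range(20):
        g = meiosis_gamete(parent, tiny_length_map, MeiosisParams(), rng)
        assert np.array_equal(g, h0) or np.array_equal(g, h1)


def test_allele_conservation(two_chrom_map, rng):
    """Meiosis never creates alleles absent from the parent at a locus."""
    n = 20
    hap = rng.integers(0, 2, size=(n, 2, two_chrom_map.n_loci), dtype=np.int8)
    gam = gametes_batch(hap, np.arange(n), two_chrom_map, MeiosisParams(), rng)
    ok = (gam == hap[:, 0]) | (gam == hap[:, 1])
    assert ok.all()


def test_make_cross_trivials(two_chrom_map, rng):
    L = two_chrom_map.n_loci
    aa = Individual(np.ones((2, L), dtype=np.int8), is_inbred=True)
    bb = Individual(np.zeros((2, L), dtype=np.int8), is_inbred=True)
    child = make_cross(aa, bb, two_chrom_map, MeiosisParams(), rng)
    assert child.dosage().tolist() == [1] * L  # heterozygous at all segregating loci
    same = make_cross(aa, aa, two_chrom_map, MeiosisParams(), rng)
    assert same.is_inbred and np.all(same.haplotypes == 1)


def test_selfing_mendelian_ratio(single_locus_map, rng):
    """Selfing an Aa F1 gives 1:2:1 genotype proportions at a single locus."""
    hap = np.zeros((1, 2, 1), dtype=np.int8)
    hap[0, 1, 0] = 1
    pop = Population(np.repeat(hap, 10_000, axis=0), single_locus_map)
    off = self_batch(pop, MeiosisParams(), rng)
    dos = off.dosages()[:, 0]
    obs = np.bincount(dos, minlength=3)
    p = stats.chisquare(obs, np.array([0.25, 0.5, 0.25]) * len(dos)).pvalue
    assert p > 0.01


def test_dh_mendelian_ratio_and_homozygosity(single_locus_map, rng):
    hap = np.zeros((1, 2, 1), dtype=np.int8)
    hap[0, 1, 0] = 1
    pop = Population(np.repeat(hap, 10_000, axis=0), single_locus_map)
    dh = dh_batch(pop, np.arange(10_000), MeiosisParams(), rng)
    dos = dh.dosages()[:, 0]
    assert set(np.unique(dos)) <= {0, 2}  # fully homozygous
    frac = (dos == 2).mean()
    assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(10_000)


def test_dh_idempotent_for_inbred_input(two_chrom_map, rng):
    hap = rng.integers(0, 2, size=(1, two_chrom_map.n_loci), dtype=np.int8)
    x = Individual(np.vstack([hap, hap]), is_inbred=True)
    d1 = make_dh(x, two_chrom_map, MeiosisParams(), rng)
    d2 = make_dh(d1, two_chrom_map, MeiosisParams(), rng)
    assert np.array_equal(d1.haplotypes, x.haplotypes)
    assert np.array_equal(d2.haplotypes, d1.haplotypes)


def test_self_of_homozygote_is_clone(two_chrom_map, rng):
    hap = rng.integers(0, 2, size=(1, two_chrom_map.n_loci), dtype=np.int8)
    parent = Individual(np.vstack([hap, hap]), is_inbred=True)
    child = self_individual(parent, two_chrom_map, MeiosisParams(), rng)
    assert np.array_equal(child.haplotypes[0], hap[0])
    assert np.array_equal(child.haplotypes[1], hap[0])


def test_two_locus_recombination_matches_renewal_oracle(rng):
    """Gamete-level recombinant fraction agrees with a direct simulation of
    the stationary thinned gamma renewal process at higher replication."""
    d = 50.0  # cM between the two loci
    gmap = GeneticMap(
        ("1",), np.array([0, 2]), np.array([5.0, 5.0 + d]), np.array([60.0]),
        np.array(["a", "b"], dtype=object),
    )
    params = MeiosisParams()  # nu = 2.6
    n = 100_000
    hap = np.zeros((1, 2, 2), dtype=np.int8)
    hap[0, 1] = 1
    gam = gametes_batch(np.repeat(hap, 1, axis=0), np.zeros(n, np.int64), gmap, params, rng)
    rec_obs = (gam[:, 0] != gam[:, 1]).mean()

    # independent oracle: parity of thinned renewal events in (5, 5+d]
    nu, scale = 2.6, 50.0 / 2.6
    m = 1_000_000
    k = 16
    first = rng.uniform(size=m) * rng.gamma(nu + 1.0, scale, size=m)
    arr = np.cumsum(
        np.column_stack([first, rng.gamma(nu, scale, size=(m, k - 1))]), axis=1
    )
    inside = (arr > 5.0) & (arr <= 5.0 + d) & (rng.random((m, k)) < 0.5)
    rec_exp = (inside.sum(axis=1) % 2 == 1).mean()

    se = np.sqrt(rec_obs * (1 - rec_obs) / n + rec_exp * (1 - rec_exp) / m)
    assert abs(rec_obs - rec_exp) < 3 * se


def test_population_invariants(two_chrom_map, rng):
    hap = rng.integers(0, 2, size=(5, 2, two_chrom_map.n_loci), dtype=np.int8)
    pop = Population(hap, two_chrom_map)
    assert pop.n == 5
    assert pop.dosages().max() <= 2
    with pytest.raises(ValueError):
        Population(hap[:, :, :3], two_chrom_map)
    with pytest.raises(ValueError):
        Individual(np.array([[0, 1], [1, 1]], dtype=np.int8), is_inbred=True)


def test_cross_batch_reproducible(two_chrom_map):
    hap = np.random.default_rng(7).integers(
        0, 2, size=(6, 2, two_chrom_map.n_loci), dtype=np.int8
    )
    pop = Population(hap, two_chrom_map)
    a = cross_batch(pop, np.array([0, 1]), np.array([2, 3]), MeiosisParams(),
                    np.random.default_rng(42))
    b = cross_batch(pop, np.array([0, 1]), np.array([2, 3]), MeiosisParams(),
                    np.random.default_rng(42))
    assert np.array_equal(a.haplotypes, b.haplotypes)
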