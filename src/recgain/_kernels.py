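"""Numba inner loops for gamete construction.

The kernels are integer-only; all randomness is drawn outside with numpy
Generators so that reproducibility is governed by a single seed stream.
"""
from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, nogil=True)
def copy_chromosome_gametes(hap, parents, pos, lo, xo, counts, start, out):
    """Fill gamete alleles for one chromosome of a batch of meioses.

    hap     : (n_ind, 2, L_total) int8 parental haplotypes
    parents : (B,) int64 parent row index per gamete
    pos     : (Lc,) float64 cM positions of this chromosome's loci
    lo      : int, offset of this chromosome's first locus in the flat arrays
    xo      : (B, K) float64 sorted crossover positions (cM), padded with +inf
    counts  : (B,) int64 number of valid crossovers per gamete
    start   : (B,) int64 starting strand (0 or 1)
    out     : (B, L_total) int8 gamete alleles (this chromosome's slice written)

    A crossover at position x switches strands for loci with position > x;
    a locus lying exactly at x is copied before the switch takes effect.
    """
    B = parents.shape[0]
    Lc = pos.shape[0]
    for b in range(B):
        s = start[b]
        k = 0
        m = counts[b]
        p = parents[b]
        for j in range(Lc):
            pj = pos[j]
            while k < m and xo[b, k] < pj:
                s ^= 1
                k += 1
            out[b, lo + j] = hap[p, s, lo + j]
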