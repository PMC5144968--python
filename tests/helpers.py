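"""Shared builders turning coalescent simulations into scan inputs."""

import numpy as np

from drupepop.genomic_io import CallabilityMask, GenotypeMatrix, PopCounts
from drupepop.simulate import simulate_window


def bare_gm(chrom, pos):
    """Positions-only GenotypeMatrix (the scan reads chrom/pos, counts come
    separately)."""
    return GenotypeMatrix.from_arrays(
        chrom=[chrom] * len(pos), pos=np.asarray(pos) + 1,
        ref=["A"] * len(pos), alt=["T"] * len(pos),
        genotypes=np.zeros((len(pos), 1), dtype=np.int8),
        sample_ids=["dummy"], pop_of={"dummy": "p"})


def counts_from_derived(pop, d, n_hap):
    d = np.asarray(d, dtype=np.int64)
    n = np.full(len(d), n_hap, dtype=np.int64)
    return PopCounts(pop=pop, alt=d, n=n, d=d, m=np.minimum(d, n - d))


def single_pop_segments(rng, n_segments, theta, n_hap=26, L=1000, chrom="chr1"):
    """Concatenated independent coalescent segments on one chromosome.

    Returns (gm, counts dict, mask, chrom_length, per-segment derived lists).
    """
    pos_all, d_all = [], []
    for k in range(n_segments):
        w = simulate_window(n_hap, theta, rng, L=L)
        pos_all.append(w.positions + k * L)
        d_all.append(w.haplotypes.sum(axis=0))
    pos = np.concatenate(pos_all)
    d = np.concatenate(d_all)
    order = np.argsort(pos)
    pos, d = pos[order], d[order]
    gm = bare_gm(chrom, pos)
    counts = {"p1": counts_from_derived("p1", d, n_hap)}
    mask = CallabilityMask.from_intervals({chrom: [(0, n_segments * L)]})
    return gm, counts, mask, n_segments * L
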