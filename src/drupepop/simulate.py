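"""Coalescent generator for fully specified synthetic study datasets.

Emulates the study design of a diverged tree-crop species pair: two
populations with strongly contrasting diversity (default ~7:1, an
outcrossing almond-like population against a partially selfing peach-like
one), a distant outgroup lineage for ancestral-allele polarization, a
callability mask, tiled gene annotations, and planted selective-sweep
regions, all with a machine-readable truth table.

The model is the Kingman coalescent with infinite sites and no
intra-window recombination: consecutive segments along a chromosome are
independent coalescent replicates, which matches the window-marginal
statistics the pipeline computes while keeping the generator exact.
Population structure is a clean divergence-in-isolation: lineages coalesce
only within their population until the split time, then in a merged
ancestral population; the outgroup lineage joins deeper in the past.
Partial selfing is modeled as instantaneous identity-by-descent: each
individual's two gene copies are the same haplotype with probability
F = s/(2-s), drawn independently per segment (equilibrium inbreeding at
unlinked loci).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomic_io import CallabilityMask, GenotypeMatrix, write_mask, write_vcf
from .inbreeding import selfing_to_F

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# tree machinery


def _kingman_tree(n: int, rng) -> tuple[np.ndarray, list]:
    """Single-population coalescent tree in coalescent units (pair rate 1).

    Returns (node times, children list); leaves are 0..n-1, internal nodes
    are appended in coalescence order, the root last.
    """
    if n < 2:
        raise ValueError("need at least 2 lineages")
    times = [0.0] * n
    children: list = [None] * n
    active = list(range(n))
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        times.append(t)
        children.append((a, b))
        active = [x for x in active if x not in (a, b)] + [len(times) - 1]
    return np.asarray(times), children


def _split_tree(k1: int, k2: int, N1: float, N2: float, N_anc: float,
                T_split: float, T_out: float, rng):
    """Two-population isolation tree with one outgroup lineage, in generations.

    Leaves 0..k1-1 belong to population 1, k1..k1+k2-1 to population 2 and
    leaf k1+k2 is the outgroup.  Pairwise coalescence rate within a
    population of size N is 1/(2N) per generation.
    """
    n_leaves = k1 + k2 + 1
    times = [0.0] * n_leaves
    children: list = [None] * n_leaves
    groups = {0: list(range(k1)), 1: list(range(k1, k1 + k2)), 2: [k1 + k2]}
    sizes = {0: float(N1), 1: float(N2), 2: float(N_anc)}
    boundaries = [(float(T_split), "merge_pops"), (float(T_out), "join_outgroup")]
    bi = 0
    t = 0.0
    while sum(len(g) for g in groups.values()) > 1:
        rates = {p: len(g) * (len(g) - 1) / 2.0 / (2.0 * sizes[p])
                 for p, g in groups.items() if len(g) >= 2}
        total = sum(rates.values())
        nxt = boundaries[bi][0] if bi < len(boundaries) else np.inf
        dt = rng.exponential(1.0 / total) if total > 0 else np.inf
        if t + dt >= nxt:
            t = nxt
            if boundaries[bi][1] == "merge_pops":
                groups[0] = groups.get(0, []) + groups.pop(1, [])
                sizes[0] = float(N_anc)
            else:
                groups[0] = groups.get(0, []) + groups.pop(2, [])
            bi += 1
            continue
        t += dt
        u = rng.random() * total
        for p, r in rates.items():
            u -= r
            if u <= 0:
                break
        g = groups[p]
        i, j = rng.choice(len(g), size=2, replace=False)
        a, b = g[i], g[j]
        times.append(t)
        children.append((a, b))
        groups[p] = [x for x in g if x not in (a, b)] + [len(times) - 1]
    return np.asarray(times), children


def _leaf_sets(n_leaves: int, children: list) -> list:
    sets = [np.array([i]) for i in range(n_leaves)]
    for node in range(n_leaves, len(children)):
        a, b = children[node]
        sets.append(np.concatenate([sets[a], sets[b]]))
    return sets


def _drop_mutations(times: np.ndarray, children: list, n_leaves: int,
                    rate: float, rng) -> list:
    """Poisson mutations per branch at ``rate`` per unit time.

    Returns the derived-leaf set of every mutation (one entry per
    mutation, in node order).
    """
    parent_time = np.empty(len(times))
    parent_time[:] = np.nan
    for node in range(n_leaves, len(children)):
        a, b = children[node]
        parent_time[a] = times[node]
        parent_time[b] = times[node]
    sets = _leaf_sets(n_leaves, children)
    muts = []
    for node in range(len(times) - 1):  # root (last) has no branch above
        lam = rate * (parent_time[node] - times[node])
        for _ in range(rng.poisson(lam)):
            muts.append(sets[node])
    return muts


def _total_branch_length(times: np.ndarray, children: list, n_leaves: int) -> float:
    tot = 0.0
    for node in range(n_leaves, len(children)):
        a, b = children[node]
        tot += (times[node] - times[a]) + (times[node] - times[b])
    return tot


# ---------------------------------------------------------------------------
# public simulation operations


@dataclass
class WindowSim:
    haplotypes: np.ndarray        # (n, S) 0 ancestral / 1 derived
    positions: np.ndarray         # sorted, in [0, 1) or integer bp
    tmrca: float
    total_branch_length: float


def simulate_window(n: int, theta: float, rng, L: int | None = None) -> WindowSim:
    """One neutral coalescent window for ``n`` haplotypes.

    Mutations are Poisson with mean (theta/2) x total branch length
    (coalescent units), placed uniformly: E[S] = theta * a_n.  With ``L``
    given, positions are distinct integers in [0, L).
    """
    if n < 2 or theta < 0:
        raise ValueError("need n >= 2 and theta >= 0")
    times, children = _kingman_tree(n, rng)
    muts = _drop_mutations(times, children, n, theta / 2.0, rng)
    S = len(muts)
    hap = np.zeros((n, S), dtype=np.int8)
    for j, leaves in enumerate(muts):
        hap[leaves, j] = 1
    pos = _positions(S, L, rng)
    order = np.argsort(pos, kind="stable")
    return WindowSim(haplotypes=hap[:, order], positions=pos[order],
                     tmrca=float(times[-1]),
                     total_branch_length=_total_branch_length(times, children, n))


def _positions(S: int, L: int | None, rng) -> np.ndarray:
    if L is None:
        return rng.random(S)
    if S > L:
        raise ValueError(f"{S} mutations exceed {L} available sites")
    return rng.choice(L, size=S, replace=False)


@dataclass
class SplitSim:
    hap1: np.ndarray
    hap2: np.ndarray
    outgroup: np.ndarray          # (S,) allele of the single outgroup lineage
    positions: np.ndarray
    tmrca: float


def simulate_split(k1: int, k2: int, N1: float, N2: float, T_split: float,
                   T_out: float, mu: float, L: int, rng,
                   N_anc: float | None = None) -> SplitSim:
    """One window under divergence-in-isolation with an outgroup lineage.

    Haplotype counts k1/k2, diploid population sizes N1/N2 (ancestral size
    defaults to their mean), times in generations, mutation rate per bp
    per generation over a window of L bp.  Allele 0 is the true ancestral
    state (the root); outgroup-based polarization can be compared to it.
    """
    if N_anc is None:
        N_anc = (N1 + N2) / 2.0
    times, children = _split_tree(k1, k2, N1, N2, N_anc, T_split, T_out, rng)
    n_leaves = k1 + k2 + 1
    muts = _drop_mutations(times, children, n_leaves, mu * L, rng)
    S = len(muts)
    hap = np.zeros((n_leaves, S), dtype=np.int8)
    for j, leaves in enumerate(muts):
        hap[leaves, j] = 1
    pos = _positions(S, L, rng)
    order = np.argsort(pos, kind="stable")
    hap = hap[:, order]
    return SplitSim(hap1=hap[:k1], hap2=hap[k1:k1 + k2], outgroup=hap[-1],
                    positions=pos[order], tmrca=float(times[-1]))


def apply_selfing(haplotypes: np.ndarray, s: float, rng):
    """Pair haplotypes into diploids under partial selfing.

    With probability F = s/(2-s) an individual's two gene copies are the
    same haplotype (identical by descent); otherwise they are the two
    independent haplotypes assigned to it.  Returns (genotypes, ibd) where
    genotypes is (n_individuals, S) alt dosage and ibd the per-individual
    IBD indicator.  s=1 yields fully homozygous individuals.
    """
    hap = np.asarray(haplotypes)
    if hap.shape[0] % 2:
        raise ValueError("need an even number of haplotypes")
    n_ind = hap.shape[0] // 2
    F = selfing_to_F(s)
    ibd = rng.random(n_ind) < F
    geno = np.empty((n_ind, hap.shape[1]), dtype=np.int8)
    for i in range(n_ind):
        if ibd[i]:
            geno[i] = 2 * hap[2 * i]
        else:
            geno[i] = hap[2 * i] + hap[2 * i + 1]
    return geno, ibd


def sweep_reduction(block: np.ndarray, factor: float, rng) -> None:
    """Reduce within-population diversity to ``factor`` of background.

    Each site polymorphic within the block keeps its variation with
    probability ``factor``; otherwise the block is fixed for its majority
    allele (low-pi sweep signature; fixations raise FST).  In place.
    """
    k = block.shape[0]
    dc = block.sum(axis=0)
    poly = (dc > 0) & (dc < k)
    for j in np.flatnonzero(poly):
        if rng.random() >= factor:
            maj = 1 if dc[j] * 2 > k else (0 if dc[j] * 2 < k else int(block[0, j]))
            block[:, j] = maj


def sweep_skew(block: np.ndarray, rng, prob: float = 0.8,
               direction: str = "high") -> None:
    """Skew the SFS of polymorphic sites, in place.

    direction="high": each site is, with probability ``prob``, resampled to
    derived count k-1 (all haplotypes derived except one) — the hitchhiking
    signature that drives Fay & Wu's H strongly negative (and pushes Zeng's
    E positive, since theta_L then exceeds theta_W).
    direction="low": resampled to derived count 1 (singletons) — the
    post-sweep recovery signature that drives Tajima's D and Zeng's E
    negative.
    """
    k = block.shape[0]
    dc = block.sum(axis=0)
    poly = (dc > 0) & (dc < k)
    for j in np.flatnonzero(poly):
        if rng.random() < prob:
            if direction == "high":
                block[:, j] = 1
                block[rng.integers(k), j] = 0
            elif direction == "low":
                block[:, j] = 0
                block[rng.integers(k), j] = 1
            else:
                raise ValueError(f"unknown skew direction '{direction}'")


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    pop: str
    mode: str = "reduction"      # "reduction" or "skew"
    factor: float = 0.05         # kept-diversity fraction (reduction mode)


def _default_sweeps() -> list:
    return [
        SweepRegion("chr1", 50_000, 60_000, "almond"),
        SweepRegion("chr2", 100_000, 110_000, "peach"),
        SweepRegion("chr3", 50_000, 60_000, "almond", mode="skew"),
        SweepRegion("chr4", 120_000, 130_000, "peach", mode="skew"),
    ]


@dataclass
class SimConfig:
    """Study-design parameters for a synthetic dataset.

    Defaults encode the species contrast the pipeline targets: 13+13
    diploids, per-bp theta 0.0186 vs 0.0027 (about 7:1), an outcrosser
    (s=0) against a partial selfer (s=0.329, equilibrium F~0.197), a split
    800,000 generations ago with the outgroup joining at 2,400,000, and
    planted sweep regions in both species.
    """

    n_diploids: dict = field(default_factory=lambda: {"almond": 13, "peach": 13})
    theta: dict = field(default_factory=lambda: {"almond": 0.0186, "peach": 0.0027})
    selfing: dict = field(default_factory=lambda: {"almond": 0.0, "peach": 0.329})
    mu: float = 1e-8
    split_time: float = 800_000.0
    outgroup_join: float = 2_400_000.0
    N_anc: float | None = None
    chrom_lengths: dict = field(default_factory=lambda: {
        f"chr{i}": 200_000 for i in range(1, 6)})
    segment_bp: int = 1000
    mask_hole: float = 0.0       # fraction of each segment left uncallable
    gene_length: int = 2000
    gene_spacing: int = 5000
    sweeps: list = field(default_factory=_default_sweeps)
    skew_prob: float = 0.8
    ref_pop: str = "peach"
    outgroup_label: str = "outgroup"

    def __post_init__(self):
        if self.split_time >= self.outgroup_join:
            raise ValueError("split_time must precede outgroup_join")
        for pop, s in self.selfing.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"selfing rate for {pop} outside [0, 1]")
        if any(t < 0 for t in self.theta.values()) or self.mu < 0:
            raise ValueError("rates must be non-negative")

    def anc_size(self) -> float:
        """Ancestral N_e; defaults to the mean of the naive 4N mu sizes,
        which makes ancestral diversity equal the mean target diversity and
        the net-divergence dating estimator unbiased."""
        if self.N_anc is not None:
            return float(self.N_anc)
        return float(np.mean([th / (4.0 * self.mu) for th in self.theta.values()]))

    def pop_sizes(self) -> dict:
        """Daughter population sizes solved so realized diversity hits theta.

        Under isolation the expected pairwise coalescence time within a
        daughter population of size N is

            E[T_pair] = 2N (1 - e^(-T/2N)) + e^(-T/2N) * 2 N_anc,

        so realized pi = 2 mu E[T_pair] differs from 4 N mu whenever
        lineages survive past the split.  Each N is solved from the target
        theta by bisection; a target above 2 mu (T + 2 N_anc) is
        infeasible (no population size can exceed the bound set by the
        split and ancestral times) and raises ValueError.
        """
        from scipy.optimize import brentq

        T = float(self.split_time)
        two_n_anc = 2.0 * self.anc_size()
        out = {}
        for pop, th in self.theta.items():
            target = th / (2.0 * self.mu)  # E[T_pair] in generations
            if T <= 0:
                out[pop] = th / (4.0 * self.mu)
                continue
            if target >= T + two_n_anc:
                raise ValueError(
                    f"theta target for {pop} infeasible: needs mean pair time "
                    f"{target:g} >= split + ancestral bound {T + two_n_anc:g}")

            def f(x):
                e = np.exp(-T / x)
                return x * (1.0 - e) + e * two_n_anc - target

            hi = 10.0 * (T + two_n_anc + target)
            out[pop] = brentq(f, 1e-6, hi, xtol=1e-6) / 2.0
        return out


def prunus_preset(**overrides) -> SimConfig:
    """The default two-species contrast configuration."""
    return SimConfig(**overrides)


@dataclass
class SimTruth:
    """Ground truth emitted alongside every generated dataset."""

    seed: int
    split_time: float
    outgroup_join: float
    theta: dict
    F_expected: dict
    ibd_fraction: dict            # realized per-sample IBD segment fraction
    sweeps: list

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"seed\t{self.seed}\n")
            fh.write(f"split_time\t{self.split_time:g}\n")
            fh.write(f"outgroup_join\t{self.outgroup_join:g}\n")
            for pop, th in self.theta.items():
                fh.write(f"theta_{pop}\t{th:g}\n")
            for pop, F in self.F_expected.items():
                fh.write(f"F_expected_{pop}\t{F:.6f}\n")
            for sid, frac in self.ibd_fraction.items():
                fh.write(f"ibd_fraction_{sid}\t{frac:.6f}\n")
            for sw in self.sweeps:
                fh.write(f"sweep\t{sw.chrom}:{sw.start}-{sw.end}\t{sw.pop}"
                         f"\t{sw.mode}\t{sw.factor:g}\n")


def generate_dataset(config: SimConfig, outdir, seed: int):
    """Simulate a full dataset and write VCF, popmap, mask, genes and truth.

    Deterministic given (config, seed).  Returns (SimTruth, paths dict).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    pops = list(config.n_diploids)
    if len(pops) != 2:
        raise ValueError("generate_dataset expects exactly two ingroup populations")
    pop1, pop2 = pops
    k1 = 2 * config.n_diploids[pop1]
    k2 = 2 * config.n_diploids[pop2]
    sizes = config.pop_sizes()
    N_anc = config.anc_size()
    sample_ids = ([f"{pop1}{i:02d}" for i in range(1, config.n_diploids[pop1] + 1)]
                  + [f"{pop2}{i:02d}" for i in range(1, config.n_diploids[pop2] + 1)]
                  + ["outgroup01"])
    pop_of = {s: pop1 for s in sample_ids[:config.n_diploids[pop1]]}
    pop_of.update({s: pop2 for s in
                   sample_ids[config.n_diploids[pop1]:-1]})
    pop_of["outgroup01"] = config.outgroup_label
    ref_block = 0 if config.ref_pop == pop1 else 1

    chrom_l, pos_l, ref_l, alt_l, anc_l, geno_l = [], [], [], [], [], []
    ibd_count = {s: 0 for s in sample_ids[:-1]}
    n_segments = 0
    mask_iv: dict[str, list] = {}

    for chrom, length in config.chrom_lengths.items():
        mask_iv[chrom] = []
        sweeps_here = [sw for sw in config.sweeps if sw.chrom == chrom]
        for seg_start in range(0, int(length), config.segment_bp):
            seg_len = min(config.segment_bp, int(length) - seg_start)
            n_segments += 1
            if config.mask_hole > 0:
                keep = int(round((1.0 - config.mask_hole) * seg_len))
                if keep > 0:
                    mask_iv[chrom].append((seg_start, seg_start + keep))
            else:
                mask_iv[chrom].append((seg_start, seg_start + seg_len))

            sim = simulate_split(k1, k2, sizes[pop1], sizes[pop2],
                                 config.split_time, config.outgroup_join,
                                 config.mu, seg_len, rng, N_anc=N_anc)
            abspos = sim.positions + seg_start  # 0-based
            for sw in sweeps_here:
                cols = np.flatnonzero((abspos >= sw.start) & (abspos < sw.end))
                if not len(cols):
                    continue
                block = sim.hap1 if sw.pop == pop1 else sim.hap2
                view = block[:, cols]
                if sw.mode == "reduction":
                    sweep_reduction(view, sw.factor, rng)
                elif sw.mode in ("skew", "skew_high"):
                    sweep_skew(view, rng, prob=config.skew_prob,
                               direction="high")
                elif sw.mode == "skew_low":
                    sweep_skew(view, rng, prob=config.skew_prob,
                               direction="low")
                else:
                    raise ValueError(f"unknown sweep mode '{sw.mode}'")
                block[:, cols] = view

            g1, ibd1 = apply_selfing(sim.hap1, config.selfing[pop1], rng)
            g2, ibd2 = apply_selfing(sim.hap2, config.selfing[pop2], rng)
            for i, s in enumerate(sample_ids[:config.n_diploids[pop1]]):
                ibd_count[s] += int(ibd1[i])
            for i, s in enumerate(
                    sample_ids[config.n_diploids[pop1]:-1]):
                ibd_count[s] += int(ibd2[i])
            geno = np.vstack([g1, g2, (2 * sim.outgroup)[None, :]])

            # drop sites monomorphic across all samples after sweeps/selfing
            tot = geno.sum(axis=0)
            poly = (tot > 0) & (tot < 2 * geno.shape[0])
            if not poly.any():
                continue
            geno = geno[:, poly]
            abspos = abspos[poly]
            S = geno.shape[1]
            anc_base = _BASES[rng.integers(0, 4, size=S)]
            der_base = np.array([
                _BASES[(np.flatnonzero(_BASES != b))[rng.integers(0, 3)]]
                for b in anc_base])
            # reference allele = first haplotype of the reference population
            ref_hap = (sim.hap1 if ref_block == 0 else sim.hap2)[0][poly]
            ref = np.where(ref_hap == 0, anc_base, der_base)
            alt = np.where(ref_hap == 0, der_base, anc_base)
            anc_code = ref_hap.astype(np.int8)  # 0: ref ancestral, 1: alt ancestral
            dosage = np.where(ref_hap[None, :] == 0, geno, 2 - geno).astype(np.int8)

            chrom_l.extend([chrom] * S)
            pos_l.extend((abspos + 1).tolist())  # VCF is 1-based
            ref_l.extend(ref.tolist())
            alt_l.extend(alt.tolist())
            anc_l.extend(anc_code.tolist())
            geno_l.append(dosage.T)

    genotypes = (np.vstack(geno_l) if geno_l
                 else np.empty((0, len(sample_ids)), dtype=np.int8))
    gm = GenotypeMatrix.from_arrays(chrom_l, pos_l, ref_l, alt_l, genotypes,
                                    sample_ids, pop_of,
                                    ancestral=np.asarray(anc_l, dtype=np.int8))
    paths = {
        "vcf": outdir / "variants.vcf",
        "popmap": outdir / "popmap.tsv",
        "mask": outdir / "callable.bed",
        "features": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(gm, paths["vcf"])
    with open(paths["popmap"], "w") as fh:
        for s in sample_ids:
            fh.write(f"{s}\t{pop_of[s]}\n")
    write_mask(CallabilityMask.from_intervals(mask_iv), paths["mask"])
    _write_genes(config, paths["features"])

    truth = SimTruth(
        seed=int(seed), split_time=config.split_time,
        outgroup_join=config.outgroup_join, theta=dict(config.theta),
        F_expected={p: selfing_to_F(s) for p, s in config.selfing.items()},
        ibd_fraction={s: c / n_segments for s, c in ibd_count.items()},
        sweeps=list(config.sweeps))
    truth.write(paths["truth"])
    log.info("generate_dataset: %d sites, %d segments, seed=%d",
             gm.n_sites, n_segments, seed)
    return truth, paths


def _write_genes(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        g = 0
        for chrom, length in config.chrom_lengths.items():
            start = 0
            while start + config.gene_length <= int(length):
                g += 1
                strand = "+" if g % 2 else "-"
                fh.write(f"{chrom}\tdrupepop\tgene\t{start + 1}\t"
                         f"{start + config.gene_length}\t.\t{strand}\t.\t"
                         f"ID=g{g:05d}\n")
                start += config.gene_spacing


def genes_in_regions(config: SimConfig) -> list:
    """Gene ids whose span lies fully inside a planted sweep region."""
    hits = []
    g = 0
    for chrom, length in config.chrom_lengths.items():
        start = 0
        while start + config.gene_length <= int(length):
            g += 1
            for sw in config.sweeps:
                if (sw.chrom == chrom and start >= sw.start
                        and start + config.gene_length <= sw.end):
                    hits.append((f"g{g:05d}", sw.pop, sw.mode))
            start += config.gene_spacing
    return hits
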