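"""Genomic file I/O and the in-memory genotype/annotation containers.

Reads diploid genotype calls from VCF (via cyvcf2), gene annotations from
BED or GFF3, and callability masks from BED; writes VCF back out.  All
internal coordinates are 0-based half-open; VCF and GFF3 (1-based) are
converted at the boundary.  Ancestral-allele polarization against an
outgroup population lives here too, because it is a property of the
genotype container rather than of any single statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1
_BASES = frozenset("ACGT")

# ---------------------------------------------------------------------------
# interval helpers (0-based half-open, used by masks and genome partitions)


def merge_intervals(intervals) -> np.ndarray:
    """Sort and merge possibly-overlapping intervals into disjoint spans."""
    arr = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
    if arr.size == 0:
        return arr
    if np.any(arr[:, 0] >= arr[:, 1]):
        bad = arr[arr[:, 0] >= arr[:, 1]][0]
        raise ValueError(f"interval with start >= end: {tuple(bad)}")
    arr = arr[np.argsort(arr[:, 0])]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two sorted, merged interval arrays."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def subtract_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b of sorted, merged interval arrays."""
    out = []
    j = 0
    for s, e in np.asarray(a).reshape(-1, 2):
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a set of diploid samples.

    genotypes[i, j] is the alt-allele dosage of sample j at site i
    (0/1/2, or -1 for missing).  ``ancestral`` is 0 where the reference
    allele is ancestral, 1 where the alternate is, and -1 where unknown.
    Positions are 1-based (VCF convention) and strictly increasing within
    each chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    sample_ids: list
    pop_of: dict
    ancestral: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        for s in self.sample_ids:
            if s not in self.pop_of:
                raise ValueError(f"sample '{s}' has no population label")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def populations(self) -> list:
        seen = []
        for s in self.sample_ids:
            p = self.pop_of[s]
            if p not in seen:
                seen.append(p)
        return seen

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.pop_of[s] == pop]
        if not idx:
            raise KeyError(f"no samples with population label '{pop}'")
        return np.asarray(idx, dtype=np.int64)

    @classmethod
    def from_arrays(cls, chrom, pos, ref, alt, genotypes, sample_ids, pop_of,
                    ancestral=None, sort=True):
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        genotypes = np.asarray(genotypes, dtype=np.int8)
        ref = np.asarray(ref, dtype=object)
        alt = np.asarray(alt, dtype=object)
        if ancestral is not None:
            ancestral = np.asarray(ancestral, dtype=np.int8)
        if sort and len(pos):
            order = np.lexsort((pos, chrom.astype(str)))
            chrom, pos, ref, alt = chrom[order], pos[order], ref[order], alt[order]
            genotypes = genotypes[order]
            if ancestral is not None:
                ancestral = ancestral[order]
        return cls(chrom, pos, ref, alt, genotypes, list(sample_ids), dict(pop_of),
                   ancestral)


@dataclass
class CallabilityMask:
    """Per-chromosome sorted, merged, non-overlapping callable intervals."""

    intervals: dict = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, per_chrom: dict) -> "CallabilityMask":
        return cls({c: merge_intervals(iv) for c, iv in per_chrom.items()})

    def callable_in(self, chrom: str, start: int, end: int) -> int:
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return 0
        lo = np.clip(iv[:, 0], start, end)
        hi = np.clip(iv[:, 1], start, end)
        return int(np.sum(hi - lo))

    def total_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))


@dataclass
class PopCounts:
    """Per-site allele counts for one population.

    alt: called alt-allele count; n: called alleles (2 x called diploids);
    d: derived-allele count (-1 where the ancestral state is unknown);
    m: minor-allele count (polarization-invariant).
    """

    pop: str
    alt: np.ndarray
    n: np.ndarray
    d: np.ndarray
    m: np.ndarray


# ---------------------------------------------------------------------------
# readers / writers


def read_popmap(path) -> dict:
    """Two-column TSV (sample_id, population) -> dict."""
    pops = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            pops[parts[0]] = parts[1]
    return pops


def read_vcf(path, pops: dict) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF v4.x into a GenotypeMatrix.

    Multiallelic and non-SNP records are dropped (count logged).  Samples
    are restricted to those in ``pops``; a pops entry absent from the VCF
    is an error, as is an empty intersection.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    inter = [s for s in vcf_samples if s in pops]
    if not inter:
        raise ValueError("no sample shared between VCF and population map")
    missing = [s for s in pops if s not in vcf_samples]
    if missing:
        raise KeyError(
            f"sample '{missing[0]}' from the population map is not in the VCF")
    vcf.set_samples(inter)
    kept_samples = list(vcf.samples)

    chrom, pos, ref, alt, anc, gts = [], [], [], [], [], []
    dropped = 0
    for var in vcf:
        if (len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1
                or var.REF not in _BASES or var.ALT[0] not in _BASES):
            dropped += 1
            continue
        g = var.gt_types.astype(np.int8)  # 0/1/2, 3=missing (gts012)
        g[g == 3] = MISSING
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        gts.append(g)
        aa = var.INFO.get("AA")
        if aa is None:
            anc.append(MISSING)
        elif aa == var.REF:
            anc.append(0)
        elif aa == var.ALT[0]:
            anc.append(1)
        else:
            anc.append(MISSING)
    if dropped:
        log.info("read_vcf: dropped %d multiallelic/non-SNP records", dropped)
    genotypes = (np.vstack(gts) if gts
                 else np.empty((0, len(kept_samples)), dtype=np.int8))
    has_aa = any(a != MISSING for a in anc)
    return GenotypeMatrix.from_arrays(
        chrom, pos, ref, alt, genotypes, kept_samples,
        {s: pops[s] for s in kept_samples},
        ancestral=np.asarray(anc, dtype=np.int8) if has_aa else None)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as VCF v4.2 (GT; AA INFO where known)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for i in range(gm.n_sites):
            if gm.ancestral is not None and gm.ancestral[i] != MISSING:
                info = f"AA={gm.ref[i] if gm.ancestral[i] == 0 else gm.alt[i]}"
            else:
                info = "."
            row = [str(gm.chrom[i]), str(gm.pos[i]), ".", str(gm.ref[i]),
                   str(gm.alt[i]), ".", "PASS", info, "GT"]
            row += [gt_str[int(g)] for g in gm.genotypes[i]]
            fh.write("\t".join(row) + "\n")


def read_features(path, fmt: str | None = None) -> pd.DataFrame:
    """Gene spans from BED (0-based half-open) or GFF3 (1-based inclusive).

    Returns a DataFrame (gene_id, chrom, start, end, strand) with all
    coordinates normalized to 0-based half-open.  Overlapping genes are
    permitted and retained.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    rows = []
    auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if fmt == "bed":
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    gid = f[3] if len(f) > 3 else None
                    strand = f[5] if len(f) > 5 else "."
                else:
                    if len(f) < 9 and len(f) != 8:
                        raise ValueError("short GFF3 line")
                    if f[2].lower() != "gene":
                        continue
                    chrom = f[0]
                    start, end = int(f[3]) - 1, int(f[4])
                    strand = f[6]
                    gid = None
                    attrs = f[8] if len(f) > 8 else ""
                    for kv in attrs.split(";"):
                        if kv.startswith("ID="):
                            gid = kv[3:]
                            break
                        if kv.startswith("Name=") and gid is None:
                            gid = kv[5:]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {fmt} line") from exc
            if gid is None:
                auto += 1
                gid = f"feature_{auto}"
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            rows.append((gid, chrom, start, end, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id '{dup}' in {path}")
    return df


def read_mask(path) -> CallabilityMask:
    """Callability mask from a BED file; intervals are sorted and merged."""
    per_chrom: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: interval start >= end")
            per_chrom.setdefault(chrom, []).append((start, end))
    return CallabilityMask.from_intervals(per_chrom)


def write_mask(mask: CallabilityMask, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.intervals):
            for s, e in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# polarization


def polarize(gm: GenotypeMatrix, outgroup: str = "outgroup") -> dict:
    """Assign ancestral states from the outgroup and build per-population counts.

    The ancestral allele is the one carried by the outgroup where every
    outgroup sample is non-missing and homozygous for the same allele;
    otherwise the ancestral state is unknown (site still usable for the
    polarization-invariant statistics via minor/major counts).

    Returns {population: PopCounts} for all ingroup populations and stores
    the per-site ancestral call on ``gm.ancestral``.
    """
    og_idx = gm.sample_indices(outgroup)  # KeyError if label absent
    og = gm.genotypes[:, og_idx]
    anc = np.full(gm.n_sites, MISSING, dtype=np.int8)
    anc[np.all(og == 0, axis=1)] = 0
    anc[np.all(og == 2, axis=1)] = 1
    gm.ancestral = anc
    n_unknown = int(np.sum(anc == MISSING))
    if n_unknown:
        log.info("polarize: %d of %d sites have unknown ancestral state",
                 n_unknown, gm.n_sites)

    counts = {}
    for pop in gm.populations():
        if pop == outgroup:
            continue
        idx = gm.sample_indices(pop)
        g = gm.genotypes[:, idx]
        called = g != MISSING
        n = 2 * called.sum(axis=1).astype(np.int64)
        a = np.where(called, g, 0).sum(axis=1).astype(np.int64)
        m = np.minimum(a, n - a)
        d = np.where(anc == 0, a, np.where(anc == 1, n - a, -1))
        counts[pop] = PopCounts(pop=pop, alt=a, n=n, d=d, m=m)
    return counts
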