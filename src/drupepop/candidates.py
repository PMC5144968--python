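"""Empirical-quantile outlier scan and permutation overlap tests.

Window statistics are lifted to genes (mean or min over retained windows
overlapping each gene span), genes in the extreme 5% empirical tail of a
statistic are flagged as selection candidates, runs of contiguous
below-threshold windows spanning at least 50 kb become candidate regions,
and the overlap between two candidate gene sets is tested against a
permutation null (random redraws from the scored universe) with an exact
hypergeometric cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

log = logging.getLogger(__name__)

__all__ = ["CandidateSet", "PermutationResult", "gene_statistic",
           "quantile_candidates", "contiguous_regions", "permutation_overlap",
           "hypergeometric_overlap"]


@dataclass(frozen=True)
class CandidateSet:
    statistic: str
    population: str
    tail: str              # "lower" or "upper"
    threshold: float
    flagged: frozenset
    universe: frozenset


@dataclass(frozen=True)
class PermutationResult:
    observed: int
    n_perm: int
    null_mean: float
    null_sd: float
    p_value: float
    seed: int


def gene_statistic(window_table: pd.DataFrame, features: pd.DataFrame,
                   statistic: str, population: str,
                   rule: str = "mean") -> pd.Series:
    """Per-gene value of a window statistic.

    Each gene's value is ``rule`` (mean or min) over the retained windows
    overlapping its span; windows with an undefined (NaN) statistic are
    ignored.  Genes with no contributing window are excluded from the
    returned Series (and hence from the candidate universe).
    """
    if rule not in {"mean", "min"}:
        raise ValueError(f"rule must be 'mean' or 'min', got '{rule}'")
    sub = window_table[window_table["pop"] == population]
    sub = sub[np.isfinite(sub[statistic])]
    values = {}
    for chrom, genes in features.groupby("chrom"):
        w = sub[sub["chrom"] == chrom]
        if not len(w):
            continue
        w = w.sort_values("start")
        starts = w["start"].to_numpy()
        ends = w["end"].to_numpy()
        vals = w[statistic].to_numpy()
        for gid, gs, ge in genes[["gene_id", "start", "end"]].itertuples(index=False):
            # overlap: window.start < gene.end and window.end > gene.start
            lo = np.searchsorted(starts, ge, side="left")
            cand = slice(0, lo)
            m = ends[cand] > gs
            if not m.any():
                continue
            v = vals[cand][m]
            values[gid] = float(v.mean() if rule == "mean" else v.min())
    if not values:
        raise ValueError("no gene overlaps any retained window")
    return pd.Series(values, name=statistic)


def quantile_candidates(values: pd.Series, q: float = 0.05, tail: str = "lower",
                        statistic: str = "", population: str = "") -> CandidateSet:
    """Flag genes at or beyond the empirical q-quantile of ``values``.

    Lower tail: value <= q-quantile; upper tail: value >= (1-q)-quantile.
    Ties at the threshold are included (deterministic, may inflate the set
    slightly beyond q * |universe|).
    """
    if tail not in {"lower", "upper"}:
        raise ValueError(f"tail must be 'lower' or 'upper', got '{tail}'")
    v = values.dropna()
    if not len(v):
        raise ValueError("no finite gene values to rank")
    if tail == "lower":
        thr = float(np.quantile(v.to_numpy(), q))
        flagged = frozenset(v.index[v.to_numpy() <= thr])
    else:
        thr = float(np.quantile(v.to_numpy(), 1.0 - q))
        flagged = frozenset(v.index[v.to_numpy() >= thr])
    if len(flagged) == len(v) and len(v) > 1:
        log.warning("quantile_candidates: all %d genes tied at the threshold",
                    len(v))
    return CandidateSet(statistic=statistic or str(values.name),
                        population=population, tail=tail, threshold=thr,
                        flagged=flagged, universe=frozenset(v.index))


def contiguous_regions(window_table: pd.DataFrame, flag: np.ndarray,
                       min_span: int = 50_000) -> pd.DataFrame:
    """Maximal runs of consecutive flagged windows spanning >= min_span bp.

    ``window_table`` holds the retained windows of one population (sorted
    by position within chromosome) and ``flag`` marks windows beyond the
    threshold.  Runs may bridge windows dropped by the callability filter
    (absent from the table) but break at any retained window that is not
    flagged.
    """
    flag = np.asarray(flag, dtype=bool)
    if len(flag) != len(window_table):
        raise ValueError("flag length does not match window table")
    regions = []
    tab = window_table.reset_index(drop=True)
    for chrom, sub in tab.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        f = flag[sub.index.to_numpy()]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = 0
        while i < len(f):
            if not f[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(f) and f[j + 1]:
                j += 1
            span_start, span_end = int(starts[i]), int(ends[j])
            if span_end - span_start >= min_span:
                regions.append({"chrom": chrom, "start": span_start,
                                "end": span_end, "n_windows": int(j - i + 1)})
            i = j + 1
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows"])


def permutation_overlap(set_a, set_b, universe, n_perm: int = 1000,
                        seed: int = 0) -> PermutationResult:
    """Permutation test for the overlap of two gene sets.

    Each permutation redraws |A| genes uniformly without replacement from
    the universe and records the overlap with B.  The p-value uses the
    add-one estimator p = (1 + #{perm >= observed}) / (1 + n_perm), so the
    smallest reportable value at 1000 permutations is 1/1001.
    """
    universe = list(universe)
    set_a = frozenset(set_a)
    set_b = frozenset(set_b)
    if not set_a <= frozenset(universe) or not set_b <= frozenset(universe):
        raise ValueError("candidate sets must be subsets of the universe")
    if len(set_a) > len(universe):
        raise ValueError("|A| exceeds the universe size")
    observed = len(set_a & set_b)
    rng = np.random.default_rng(seed)
    in_b = np.array([g in set_b for g in universe])
    k = len(set_a)
    N = len(universe)
    null = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, min(n_perm, int(5e6) // max(N, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, N))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k] if k > 0 else \
            np.empty((m, 0), dtype=np.int64)
        null[done:done + m] = in_b[idx].sum(axis=1) if k > 0 else 0
        done += m
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return PermutationResult(observed=observed, n_perm=n_perm,
                             null_mean=float(null.mean()),
                             null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
                             p_value=p, seed=seed)


def hypergeometric_overlap(n_a: int, n_b: int, n_universe: int, observed: int):
    """Exact expectation and upper-tail probability of the overlap.

    Under random draws, overlap ~ Hypergeometric(N, n_b, n_a); returns
    (expected overlap = n_a n_b / N, P(overlap >= observed)).
    """
    if n_a > n_universe or n_b > n_universe:
        raise ValueError("set sizes exceed the universe")
    expected = n_a * n_b / n_universe
    tail = float(hypergeom.sf(observed - 1, n_universe, n_b, n_a))
    return expected, tail
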