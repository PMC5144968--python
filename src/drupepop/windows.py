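"""Sliding-window diversity scan.

Tiles each chromosome into overlapping windows (default 1000 bp with 50 bp
steps, anchored at 0), drops windows with fewer than 150 callable bp, and
computes the full set of SFS statistics per window and population, plus
pairwise Hudson FST where exactly two ingroup populations are present.

Theta estimators are reported per callable bp (window sums divided by the
window's callable length); the neutrality tests D, H and E are unitless.
Undefined statistics (no segregating sites of the relevant kind) are NaN.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import sfs
from .differentiation import fst_site
from .genomic_io import (CallabilityMask, GenotypeMatrix, intersect_intervals,
                         subtract_intervals)

log = logging.getLogger(__name__)

def make_windows(chrom_lengths: dict, size: int = 1000, step: int = 50) -> pd.DataFrame:
    """Overlapping windows anchored at 0; the last windows truncate at the end."""
    if size < step or step < 1:
        raise ValueError(f"need size >= step >= 1, got size={size}, step={step}")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, max(int(length), 0), step, dtype=np.int64)
        ends = np.minimum(starts + size, int(length))
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def window_callable(mask: CallabilityMask, chrom, start, end) -> int:
    """Callable bp of the mask intersecting the window [start, end)."""
    return mask.callable_in(chrom, int(start), int(end))


def _callable_bulk(mask, chrom, starts, ends):
    """Vectorized callable bp for many windows of one chromosome."""
    iv = mask.intervals.get(chrom)
    if iv is None or len(iv) == 0:
        return np.zeros(len(starts), dtype=np.int64)
    bounds = iv.ravel()
    cum = np.concatenate([[0], np.cumsum(iv[:, 1] - iv[:, 0])])

    def cov(x):
        # callable bp in [0, x)
        k = np.searchsorted(bounds, x, side="left")
        inside = k % 2 == 1
        full = cum[(k + 1) // 2 - inside]
        extra = np.where(inside, x - bounds[np.maximum(k - 1, 0)], 0)
        return full + extra

    return cov(np.asarray(ends)) - cov(np.asarray(starts))


def _window_median_n(lo, hi, n_arr):
    """Median called-allele count per window among contributing sites."""
    med = np.zeros(len(lo), dtype=np.int64)
    if len(n_arr) == 0:
        return med
    uniq = np.unique(n_arr[n_arr >= 2])
    if len(uniq) == 1:
        med[:] = uniq[0]
        return med
    for w in range(len(lo)):
        sl = n_arr[lo[w]:hi[w]]
        sl = sl[sl >= 2]
        if len(sl):
            med[w] = int(np.median(sl))
    return med


def scan(gm: GenotypeMatrix, counts: dict, mask: CallabilityMask,
         windows: pd.DataFrame | None = None, chrom_lengths: dict | None = None,
         size: int = 1000, step: int = 50, min_callable: int = 150,
         min_alleles: int = 4) -> pd.DataFrame:
    """Per-window, per-population diversity statistics (long format).

    ``counts`` is the {population: PopCounts} map from
    :func:`drupepop.genomic_io.polarize`.  Windows with fewer than
    ``min_callable`` callable bp are removed (count logged).  Sites where a
    population has fewer than ``min_alleles`` called alleles are dropped
    from that population's statistics.  When ``counts`` holds exactly two
    populations, a per-window Hudson FST column is attached.
    """
    for pop, pc in counts.items():
        if int(np.max(pc.n, initial=0)) < 4:
            raise ValueError(f"population '{pop}' has fewer than 2 diploid samples")
    if windows is None:
        if chrom_lengths is None:
            chrom_lengths = {c: int(gm.pos[gm.chrom == c].max())
                             for c in pd.unique(gm.chrom)}
        windows = make_windows(chrom_lengths, size=size, step=step)

    pops = list(counts)
    fst_pair = pops if len(pops) == 2 else None
    out = []
    n_dropped = 0
    for chrom, wdf in windows.groupby("chrom", sort=False):
        sel = np.flatnonzero(gm.chrom == chrom)
        pos0 = gm.pos[sel] - 1  # 0-based site coordinates
        starts = wdf["start"].to_numpy()
        ends = wdf["end"].to_numpy()
        callable_bp = _callable_bulk(mask, chrom, starts, ends)
        keep = callable_bp >= min_callable
        n_dropped += int((~keep).sum())
        if not keep.any():
            continue
        starts, ends, callable_bp = starts[keep], ends[keep], callable_bp[keep]
        lo = np.searchsorted(pos0, starts)
        hi = np.searchsorted(pos0, ends)

        if fst_pair is not None:
            p1, p2 = (counts[p] for p in fst_pair)
            num, den, ok = fst_site(p1.alt[sel], p1.n[sel], p2.alt[sel], p2.n[sel],
                                    min_alleles=min_alleles)
            cnum = np.concatenate([[0.0], np.cumsum(np.where(ok, num, 0.0))])
            cden = np.concatenate([[0.0], np.cumsum(np.where(ok, den, 0.0))])
            wnum = cnum[hi] - cnum[lo]
            wden = cden[hi] - cden[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                fst_w = np.where(wden > 0, wnum / wden, np.nan)

        for pop in pops:
            pc = counts[pop]
            n = pc.n[sel]
            m = pc.m[sel]
            d = pc.d[sel]
            valid = n >= min_alleles
            pi_site, _, _ = sfs.site_contributions(m, np.where(n > 1, n, 2))
            pi_site = np.where(valid, pi_site, 0.0)
            seg = valid & (m > 0)
            pol = valid & (d >= 0)
            pol_seg = pol & (d > 0) & (d < n)
            _, L_site, H_site = sfs.site_contributions(
                np.where(pol_seg, d, 0), np.where(n > 1, n, 2))
            pi_pol = np.where(pol_seg, pi_site, 0.0)

            def wsum(x):
                c = np.concatenate([[0.0], np.cumsum(x)])
                return c[hi] - c[lo]

            S = wsum(seg)
            S_pol = wsum(pol_seg)
            pi_sum = wsum(pi_site)
            L_sum = wsum(L_site)
            H_sum = wsum(H_site)
            pi_pol_sum = wsum(pi_pol)
            med_n = _window_median_n(lo, hi, np.where(seg | pol_seg, n, 0))
            # fall back to overall median where a window has no seg sites
            all_med = int(np.median(n[valid])) if valid.any() else 0
            med_n = np.where(med_n >= 2, med_n, all_med)

            D = np.full(len(lo), np.nan)
            Hn = np.full(len(lo), np.nan)
            E = np.full(len(lo), np.nan)
            tw = np.full(len(lo), np.nan)
            for nn in np.unique(med_n[med_n >= 2]):
                c = sfs.constants(int(nn))
                i = med_n == nn
                tw[i] = S[i] / c.a_n
                has = i & (S > 0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    D[has] = (pi_sum[has] - S[has] / c.a_n) / np.sqrt(
                        c.e1 * S[has] + c.e2 * S[has] * (S[has] - 1))
                    hasp = i & (S_pol > 0)
                    varh = np.array([sfs._var_fay_wu_h(int(s), c) for s in S_pol[hasp]])
                    Hn[hasp] = (pi_pol_sum[hasp] - L_sum[hasp]) / np.sqrt(varh)
                    vare = np.array([sfs._var_zeng_e(int(s), c) for s in S_pol[hasp]])
                    E[hasp] = (L_sum[hasp] - S_pol[hasp] / c.a_n) / np.sqrt(vare)

            df = pd.DataFrame({
                "chrom": chrom, "start": starts, "end": ends,
                "callable_bp": callable_bp, "pop": pop,
                "S": S.astype(np.int64), "S_pol": S_pol.astype(np.int64),
                "theta_pi": pi_sum / callable_bp,
                "theta_w": tw / callable_bp,
                "theta_L": L_sum / callable_bp,
                "theta_H": H_sum / callable_bp,
                "tajima_d": D, "faywu_h": Hn, "zeng_e": E,
            })
            if fst_pair is not None:
                df["fst"] = fst_w
            out.append(df)
    if n_dropped:
        log.info("scan: dropped %d windows with < %d callable bp",
                 n_dropped, min_callable)
    if not out:
        cols = ["chrom", "start", "end", "callable_bp", "pop", "S", "S_pol",
                "theta_pi", "theta_w", "theta_L", "theta_H",
                "tajima_d", "faywu_h", "zeng_e"]
        return pd.DataFrame(columns=cols)
    table = pd.concat(out, ignore_index=True)
    return table.sort_values(["chrom", "start", "pop"], kind="stable",
                             ignore_index=True)


def normalize_pi(table: pd.DataFrame) -> pd.DataFrame:
    """Add pi_normalized = theta_pi / per-population mean theta_pi.

    The mean of pi_normalized over retained windows of each population is
    exactly 1; doubling every theta_pi leaves the column unchanged.
    """
    table = table.copy()
    means = table.groupby("pop")["theta_pi"].transform("mean")
    with np.errstate(invalid="ignore", divide="ignore"):
        table["pi_normalized"] = table["theta_pi"] / means
    return table


def genome_summary(gm: GenotypeMatrix, counts: dict, mask: CallabilityMask,
                   features: pd.DataFrame | None = None,
                   min_alleles: int = 4) -> pd.DataFrame:
    """Genome / genic / nongenic aggregate statistics per population.

    Length-weighted over callable sites (sums of per-site contributions
    divided by total callable bp of the partition), not means of window
    values.  The genic partition is the mask intersected with gene spans;
    nongenic is its complement within the mask.
    """
    partitions = {"genome": mask.intervals}
    if features is not None and len(features):
        genic = {}
        for chrom, sub in features.groupby("chrom"):
            from .genomic_io import merge_intervals
            spans = merge_intervals(sub[["start", "end"]].to_numpy())
            base = mask.intervals.get(chrom)
            if base is not None:
                genic[chrom] = intersect_intervals(base, spans)
        nongenic = {c: subtract_intervals(iv, genic.get(c, np.empty((0, 2), int)))
                    for c, iv in mask.intervals.items()}
        partitions["genic"] = genic
        partitions["nongenic"] = nongenic

    rows = []
    for part, intervals in partitions.items():
        length = int(sum((iv[:, 1] - iv[:, 0]).sum()
                         for iv in intervals.values() if len(iv)))
        inside = np.zeros(gm.n_sites, dtype=bool)
        for chrom, iv in intervals.items():
            if not len(iv):
                continue
            selc = gm.chrom == chrom
            p0 = gm.pos[selc] - 1
            k = np.searchsorted(iv.ravel(), p0, side="right")
            inside[np.flatnonzero(selc)[k % 2 == 1]] = True
        for pop, pc in counts.items():
            n = pc.n[inside]
            m = pc.m[inside]
            d = pc.d[inside]
            valid = n >= min_alleles
            seg = valid & (m > 0)
            pol_seg = valid & (d > 0) & (d < n)
            pi, _, _ = sfs.site_contributions(m, np.where(n > 1, n, 2))
            pi = np.where(valid, pi, 0.0)
            S = int(seg.sum())
            med = int(np.median(n[seg])) if S else 0
            D = sfs.tajimas_d(m[valid], n[valid]) if S else np.nan
            H = sfs.fay_wu_h(d[valid], n[valid]) if pol_seg.any() else np.nan
            E = sfs.zengs_e(d[valid], n[valid]) if pol_seg.any() else np.nan
            rows.append({
                "partition": part, "pop": pop, "callable_bp": length,
                "S": S, "theta_pi": float(pi.sum()) / length if length else np.nan,
                "tajima_d": D, "faywu_h": H, "zeng_e": E, "median_n": med,
            })
    return pd.DataFrame(rows)
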