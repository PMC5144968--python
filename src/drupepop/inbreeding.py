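"""Inbreeding-coefficient estimation and mating-system conversions.

F is the probability that the two gene copies of an individual are
identical by descent.  Per individual it is estimated by maximum
likelihood over F in [0, 1] from hard genotype calls and population
allele frequencies:

    P(hom ref) = (1-p)^2 + F p (1-p)
    P(het)     = 2 p (1-p) (1-F)
    P(hom alt) = p^2 + F p (1-p)

Allele frequencies are computed from the other samples of the focal
individual's population to avoid self-reference bias.  At equilibrium
under partial self-fertilization with selfing rate s, F = s / (2 - s);
the conversions between the two scales live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

log = logging.getLogger(__name__)

__all__ = ["selfing_to_F", "F_to_selfing", "InbreedingEstimate", "estimate_F",
           "estimate_all"]


def selfing_to_F(s):
    """Equilibrium inbreeding coefficient F = s / (2 - s) for selfing rate s."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("selfing rate must lie in [0, 1]")
    out = s / (2.0 - s)
    return float(out) if out.ndim == 0 else out


def F_to_selfing(F):
    """Selfing rate s = 2F / (1 + F); inverse of :func:`selfing_to_F`."""
    F = np.asarray(F, dtype=float)
    if np.any((F < 0) | (F > 1)):
        raise ValueError("inbreeding coefficient must lie in [0, 1]")
    out = 2.0 * F / (1.0 + F)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class InbreedingEstimate:
    sample_id: str
    F: float
    n_sites: int
    loglik: float


def estimate_F(genotypes, p, sample_id: str = "", min_sites: int = 100) -> InbreedingEstimate:
    """ML inbreeding coefficient for one individual.

    ``genotypes`` are alt-allele dosages (0/1/2, -1 missing) and ``p`` the
    matching per-site alt-allele frequencies.  Sites that are missing or
    monomorphic in the frequency panel are dropped; fewer than
    ``min_sites`` usable sites is an error.  F is constrained to [0, 1]
    (heterozygote excess truncates at 0, as in the standard estimators).
    """
    g = np.asarray(genotypes)
    p = np.asarray(p, dtype=float)
    keep = (g >= 0) & (p > 0) & (p < 1)
    g = g[keep].astype(np.int64)
    p = p[keep]
    n_sites = int(len(g))
    if n_sites < min_sites:
        raise ValueError(
            f"only {n_sites} usable polymorphic sites (< {min_sites}) "
            f"for sample '{sample_id}'")
    q = 1.0 - p
    n0 = g == 0
    n1 = g == 1
    n2 = g == 2
    tiny = 1e-12

    def nll(F):
        pr = np.empty_like(p)
        pq = p * q
        pr[n0] = q[n0] ** 2 + F * pq[n0]
        pr[n1] = 2.0 * pq[n1] * (1.0 - F)
        pr[n2] = p[n2] ** 2 + F * pq[n2]
        return -float(np.sum(np.log(np.maximum(pr, tiny))))

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    # bounded Brent can miss an exact boundary optimum; check both ends
    best_F, best_nll = float(res.x), float(res.fun)
    for Fb in (0.0, 1.0):
        v = nll(Fb)
        if v < best_nll:
            best_F, best_nll = Fb, v
    if best_F == 0.0 and nll(0.0) <= nll(1e-6):
        log.debug("sample %s: heterozygote excess, F truncated at 0", sample_id)
    return InbreedingEstimate(sample_id=sample_id, F=best_F, n_sites=n_sites,
                              loglik=-best_nll)


def estimate_all(gm, outgroup: str = "outgroup", min_sites: int = 100) -> pd.DataFrame:
    """Per-sample F for every ingroup individual of a GenotypeMatrix.

    Frequencies for each focal individual come from the remaining samples
    of its population (leave-one-out).
    """
    rows = []
    for pop in gm.populations():
        if pop == outgroup:
            continue
        idx = gm.sample_indices(pop)
        G = gm.genotypes[:, idx]
        called = G >= 0
        for j, col in enumerate(idx):
            others = np.delete(np.arange(len(idx)), j)
            oc = called[:, others]
            n = 2 * oc.sum(axis=1)
            a = np.where(oc, G[:, others], 0).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(n > 0, a / n, np.nan)
            p = np.where(np.isnan(p), -1.0, p)
            est = estimate_F(G[:, j], np.where(p < 0, 0.0, p),
                             sample_id=gm.sample_ids[col], min_sites=min_sites)
            rows.append({"sample_id": est.sample_id, "pop": pop, "F": est.F,
                         "n_sites": est.n_sites, "loglik": est.loglik})
    return pd.DataFrame(rows)
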