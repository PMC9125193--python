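"""ABC summary statistics and diversity indices for a SNP panel.

All estimators are genotype-based (unphased) with per-site pairwise
deletion of missing calls.  Per-site gene diversity uses the unbiased
small-sample correction ``2n/(2n-1) * 2 p q`` on ``2n`` observed
haplotypes; the panel-total number of pairwise differences is the sum of
these per-site values over all sites.  F-statistics are Weir &
Cockerham (1984) variance-component estimators: theta (Fst) = a/(a+b+c)
and F (Fit) = 1 - c/(a+b+c), with multilocus values formed as ratios of
summed components.

The ABC statistic vector has 17 named entries: species-specific S, pi
and He mean/sd, per-locus global mean/sd of S, pi, Fst and Fit, and the
multilocus interspecific Fst.  Private-allele counts are carried for
diversity reporting but are not ABC statistics.  Additional statistics
can be plugged in through :func:`register_stat`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from cycadiv.genodata import MISSING, GenotypeMatrix

__all__ = [
    "SumStatVector",
    "ABC_STAT_NAMES",
    "seg_sites",
    "pairwise_diff",
    "expected_het",
    "fst",
    "fit",
    "summarize",
    "register_stat",
]

ABC_STAT_NAMES = [
    "S_CR", "S_CT",
    "pi_CR", "pi_CT",
    "He_mean_CR", "He_sd_CR", "He_mean_CT", "He_sd_CT",
    "S_mean_glob", "S_sd_glob",
    "pi_mean_glob", "pi_sd_glob",
    "Fst_mean_glob", "Fst_sd_glob",
    "Fit_mean_glob", "Fit_sd_glob",
    "Fst_inter",
]

#: pluggable registry for extra statistics: name -> callable(GenotypeMatrix) -> float
EXTRA_STATS: dict = {}


def register_stat(name: str, func) -> None:
    """Register an additional summary statistic for :func:`summarize`."""
    EXTRA_STATS[name] = func


@dataclass
class SumStatVector:
    S_CR: float = 0.0
    S_CT: float = 0.0
    pi_CR: float = 0.0
    pi_CT: float = 0.0
    He_mean_CR: float = 0.0
    He_sd_CR: float = 0.0
    He_mean_CT: float = 0.0
    He_sd_CT: float = 0.0
    S_mean_glob: float = 0.0
    S_sd_glob: float = 0.0
    pi_mean_glob: float = 0.0
    pi_sd_glob: float = 0.0
    Fst_mean_glob: float = 0.0
    Fst_sd_glob: float = 0.0
    Fit_mean_glob: float = 0.0
    Fit_sd_glob: float = 0.0
    Fst_inter: float = 0.0
    private_CR: float = 0.0
    private_CT: float = 0.0

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})

    def abc_values(self, names: list[str] | None = None) -> np.ndarray:
        names = names or ABC_STAT_NAMES
        return np.array([getattr(self, n) for n in names], dtype=float)


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def _group_mask(gm: GenotypeMatrix, group) -> np.ndarray:
    if isinstance(group, np.ndarray):
        return group
    sp = gm.labels("species")
    if group in set(sp):
        return sp == group
    pop = gm.labels("population")
    if group in set(pop):
        return pop == group
    raise ValueError(f"group {group!r} matches no species or population label")


def _per_site(calls: np.ndarray):
    """(n diploid observed, alt freq, unbiased per-site gene diversity)
    with NaN diversity where fewer than 1 observed individual."""
    obs = calls != MISSING
    n = obs.sum(axis=0)
    two_n = 2.0 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / two_n
        div = 2.0 * p * (1.0 - p) * two_n / (two_n - 1.0)
    p = np.where(n > 0, p, np.nan)
    div = np.where(n > 1, div, np.nan)
    return n, p, div


def seg_sites(gm: GenotypeMatrix, group) -> int:
    """Number of sites polymorphic among the group's non-missing calls."""
    mask = _group_mask(gm, group)
    if not mask.any():
        raise ValueError("empty group")
    sub = gm.calls[mask]
    obs = sub != MISSING
    alt = np.where(obs, sub, 0).sum(axis=0)
    n = obs.sum(axis=0)
    return int(((alt > 0) & (alt < 2 * n)).sum())


def pairwise_diff(gm: GenotypeMatrix, group) -> float:
    """Mean pairwise allele differences, summed over the panel.

    Per site the unphased estimator is ``2 p (1-p) * 2n/(2n-1)``; sites
    with fewer than two usable individuals are skipped.
    """
    mask = _group_mask(gm, group)
    _, _, div = _per_site(gm.calls[mask])
    return float(np.nansum(div))


def expected_het(gm: GenotypeMatrix, group) -> tuple[float, float]:
    """Mean and population sd over sites of unbiased expected
    heterozygosity ``(2n/(2n-1)) (1 - p^2 - q^2)``."""
    mask = _group_mask(gm, group)
    _, _, div = _per_site(gm.calls[mask])
    ok = ~np.isnan(div)
    if not ok.any():
        return 0.0, 0.0
    return float(np.mean(div[ok])), float(np.std(div[ok]))


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------

def wc_components(calls: np.ndarray, labels: np.ndarray):
    """Per-site W&C (1984) components (a, b, c) for the alt allele.

    Sites where fewer than two groups have data (or where the average
    sample size does not exceed one) get NaN components and are excluded
    from any sum.  With a single group overall, ``a`` is identically 0
    and (b, c) estimate the within-group partition, which supports the
    total-inbreeding coefficient F.
    """
    groups = sorted(set(labels))
    n_sites = calls.shape[1]
    n_i = np.zeros((len(groups), n_sites))
    p_i = np.zeros((len(groups), n_sites))
    h_i = np.zeros((len(groups), n_sites))
    for gi, g in enumerate(groups):
        sub = calls[labels == g]
        obs = sub != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, sub, 0).sum(axis=0) / (2.0 * n)
            h = (sub == 1).sum(axis=0) / n
        n_i[gi] = n
        p_i[gi] = np.where(n > 0, p, np.nan)
        h_i[gi] = np.where(n > 0, h, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        has = n_i > 0
        r = has.sum(axis=0).astype(float)
        n_sum = n_i.sum(axis=0)
        nbar = n_sum / np.where(r > 0, r, np.nan)
        sq = (n_i**2).sum(axis=0)
        pbar = np.nansum(np.where(has, n_i * p_i, 0.0), axis=0) / n_sum
        hbar = np.nansum(np.where(has, n_i * h_i, 0.0), axis=0) / n_sum
        single = r == 1
        # r == 1: no among-group component; use reduced formulas
        rm1 = np.where(r > 1, r - 1.0, np.nan)
        nc = (n_sum - sq / n_sum) / rm1
        s2 = (
            np.nansum(np.where(has, n_i * (p_i - pbar) ** 2, 0.0), axis=0)
            / (rm1 * nbar)
        )
        s2 = np.where(single, 0.0, s2)
        frac = np.where(single, 0.0, (r - 1.0) / r)
        pq = pbar * (1.0 - pbar)
        a = (nbar / np.where(single, np.nan, nc)) * (
            s2 - (pq - frac * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        a = np.where(single, 0.0, a)
        b = (nbar / (nbar - 1.0)) * (
            pq - frac * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    bad = (r < 1) | (nbar <= 1.0) | np.isnan(pbar)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _locus_index(gm: GenotypeMatrix):
    ids, inv = np.unique(gm.loci["locus_id"].to_numpy(), return_inverse=True)
    return ids, inv


def _ratio_by_locus(num: np.ndarray, den: np.ndarray, inv: np.ndarray, n_loci: int):
    ok = ~np.isnan(num) & ~np.isnan(den)
    num_l = np.bincount(inv[ok], weights=num[ok], minlength=n_loci)
    den_l = np.bincount(inv[ok], weights=den[ok], minlength=n_loci)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = num_l / den_l
    return vals[den_l != 0]


def fst(gm: GenotypeMatrix, grouping: str = "population", level: str = "multilocus"):
    """Weir & Cockerham theta.

    ``level='per-locus'`` returns an array of per-locus estimates
    (ratios of per-locus summed components; values may be negative);
    ``'multilocus'`` returns the ratio of panel-wide summed components.
    """
    labels = gm.labels(grouping)
    a, b, c = wc_components(gm.calls, labels)
    tot = a + b + c
    if level == "multilocus":
        ok = ~np.isnan(tot) & (np.abs(tot) > 0)
        denom = tot[ok].sum()
        return float(a[ok].sum() / denom) if denom != 0 else 0.0
    if level == "per-locus":
        ids, inv = _locus_index(gm)
        return _ratio_by_locus(a, tot, inv, len(ids))
    raise ValueError(f"unknown level {level!r}")


def fit(gm: GenotypeMatrix, grouping: str = "population", level: str = "multilocus"):
    """Weir & Cockerham total-inbreeding coefficient F = 1 - c/(a+b+c)."""
    labels = gm.labels(grouping)
    a, b, c = wc_components(gm.calls, labels)
    tot = a + b + c
    if level == "multilocus":
        ok = ~np.isnan(tot) & (np.abs(tot) > 0)
        denom = tot[ok].sum()
        return float(1.0 - c[ok].sum() / denom) if denom != 0 else 0.0
    if level == "per-locus":
        ids, inv = _locus_index(gm)
        vals = _ratio_by_locus(c, tot, inv, len(ids))
        return 1.0 - vals
    raise ValueError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# private alleles & the full vector
# ---------------------------------------------------------------------------

def private_alleles(gm: GenotypeMatrix) -> tuple[int, int]:
    """Count alleles observed in one species and absent in the other."""
    sp = gm.labels("species")
    counts = {}
    for s in ("CR", "CT"):
        sub = gm.calls[sp == s]
        obs = sub != MISSING
        alt = np.where(obs, sub, 0).sum(axis=0)
        n2 = 2 * obs.sum(axis=0)
        counts[s] = (alt, n2)
    alt_cr, n_cr = counts["CR"]
    alt_ct, n_ct = counts["CT"]
    both = (n_cr > 0) & (n_ct > 0)
    priv_cr = ((alt_cr > 0) & (alt_ct == 0) & both).sum() + (
        (alt_cr < n_cr) & (alt_ct == n_ct) & both
    ).sum()
    priv_ct = ((alt_ct > 0) & (alt_cr == 0) & both).sum() + (
        (alt_ct < n_ct) & (alt_cr == n_cr) & both
    ).sum()
    return int(priv_cr), int(priv_ct)


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    x = x[~np.isnan(x)]
    if x.size == 0:
        return 0.0, 0.0
    return float(np.mean(x)), float(np.std(x))


def summarize(gm: GenotypeMatrix, extra: bool = True) -> SumStatVector:
    """Compute the full named statistic vector.

    Per-locus ("global") statistics pool all individuals and aggregate
    over RAD loci; the Fst/Fit grouping is the population label, and the
    interspecific Fst uses the two species as groups.  A panel with no
    segregating sites yields the all-zero vector.
    """
    species = set(gm.labels("species"))
    if not {"CR", "CT"}.issubset(species):
        raise ValueError(f"both species CR and CT required, found {sorted(species)}")

    out = SumStatVector()
    out.S_CR = seg_sites(gm, "CR")
    out.S_CT = seg_sites(gm, "CT")
    out.pi_CR = pairwise_diff(gm, "CR")
    out.pi_CT = pairwise_diff(gm, "CT")
    out.He_mean_CR, out.He_sd_CR = expected_het(gm, "CR")
    out.He_mean_CT, out.He_sd_CT = expected_het(gm, "CT")

    if gm.n_sites > 0:
        ids, inv = _locus_index(gm)
        n_loci = len(ids)
        n, p, div = _per_site(gm.calls)
        poly = ((p > 0) & (p < 1)).astype(float)
        S_loc = np.bincount(inv, weights=np.where(np.isnan(p), 0, poly), minlength=n_loci)
        pi_loc = np.bincount(inv, weights=np.where(np.isnan(div), 0, div), minlength=n_loci)
        out.S_mean_glob, out.S_sd_glob = _mean_sd(S_loc)
        out.pi_mean_glob, out.pi_sd_glob = _mean_sd(pi_loc)
        out.Fst_mean_glob, out.Fst_sd_glob = _mean_sd(fst(gm, "population", "per-locus"))
        out.Fit_mean_glob, out.Fit_sd_glob = _mean_sd(fit(gm, "population", "per-locus"))
        out.Fst_inter = fst(gm, "species", "multilocus")
        out.private_CR, out.private_CT = private_alleles(gm)

    if extra:
        for name, func in EXTRA_STATS.items():
            setattr(out, name, float(func(gm)))
    return out
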