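"""Backward-time two-population coalescent with epochal migration and
bottlenecks.

The demographic scaffold is shared by four speciation scenarios for the
*C. revoluta* (CR) / *C. taitungensis* (CT) pair.  Looking backward from
the present: the species are separate demes with recent sizes
(N_CR2, N_CT2) until ``t1``; at ``t1`` sizes jump to the pre-bottleneck
values (N_CR1, N_CT1); at ``t2`` the demes merge into an ancestral deme
of size N_anc.  A deeper split ``t3`` (the section's stem divergence)
involves only an unsampled ghost lineage and is recorded but does not
affect sampled genealogies.  The four models differ only in which
migration epochs are switched on:

========  ==================  =================
model     recent [0, t1)      older [t1, t2)
========  ==================  =================
CG        m_CT2, m_CR2        m_CT1, m_CR1
PC        off                 m_CT1, m_CR1
SC        m_CT2, m_CR2        off
CI        off                 off
========  ==================  =================

Migration rates are forward-time fractions of the receiving species'
gene pool contributed per generation (m_CT* = CT into CR); backward in
time a lineage sampled in CR therefore jumps to CT at rate m_CT*.

Mutation follows the infinite-sites model at rate ``mu`` per site per
generation on loci of fixed length; each mutation yields one biallelic
SNP.  Genealogies are simulated with exponential waiting times; when a
prior draw puts the migration rate far above the coalescence rate the
simulator switches to the strong-migration (collecting-phase) limit, in
which the two demes behave as a single pool with pair-coalescence rate
``pi0^2/(2 N_0) + pi1^2/(2 N_1)`` at the stationary deme occupancy
``pi`` of the backward migration chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from cycadiv.genodata import GenotypeMatrix

__all__ = [
    "DemographicParams",
    "DerivedSizes",
    "ModelSpec",
    "SimConfig",
    "MODELS",
    "derived_sizes",
    "migration_schedule",
    "simulate_dataset",
    "simulate_loci",
]

#: migration rate ratio above which the strong-migration limit is used
FAST_MIGRATION_RATIO = 50.0

PARAM_NAMES = [
    "N_CR2", "N_CT2", "N_anc_REL", "N_CR_REL", "N_CT_REL",
    "t1", "t2", "t3", "m_CT1", "m_CR1", "m_CT2", "m_CR2", "mu",
]


@dataclass
class DemographicParams:
    """The 13 demographic parameters of the speciation models.

    Sizes are diploid effective sizes; times are generations before
    present; migration rates are per-generation forward fractions; ``mu``
    is the per-site per-generation mutation rate.
    """

    N_CR2: float
    N_CT2: float
    N_anc_REL: float
    N_CR_REL: float
    N_CT_REL: float
    t1: float
    t2: float
    t3: float
    m_CT1: float = 0.0
    m_CR1: float = 0.0
    m_CT2: float = 0.0
    m_CR2: float = 0.0
    mu: float = 1e-7

    def __post_init__(self) -> None:
        if not (0 < self.t1 <= self.t2 <= self.t3):
            raise ValueError(
                f"times must satisfy 0 < t1 <= t2 <= t3, got "
                f"({self.t1}, {self.t2}, {self.t3})"
            )
        for name in ("N_CR2", "N_CT2", "N_anc_REL", "N_CR_REL", "N_CT_REL"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("m_CT1", "m_CR1", "m_CT2", "m_CR2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicParams":
        return cls(**{k: float(d[k]) for k in PARAM_NAMES if k in d})


@dataclass(frozen=True)
class DerivedSizes:
    """Pre-bottleneck and ancestral diploid sizes implied by the relative
    multipliers: N_CR1 = N_CR_REL x N_CR2, N_CT1 = N_CT_REL x N_CT2 and
    N_anc = N_anc_REL x N_CT1."""

    N_CR1: float
    N_CT1: float
    N_anc: float


def derived_sizes(p: DemographicParams) -> DerivedSizes:
    n_cr1 = p.N_CR_REL * p.N_CR2
    n_ct1 = p.N_CT_REL * p.N_CT2
    return DerivedSizes(N_CR1=n_cr1, N_CT1=n_ct1, N_anc=p.N_anc_REL * n_ct1)


@dataclass(frozen=True)
class ModelSpec:
    """Speciation scenario: which migration epochs are active."""

    label: str
    recent_on: bool
    older_on: bool


MODELS: dict[str, ModelSpec] = {
    "CG": ModelSpec("CG", recent_on=True, older_on=True),
    "PC": ModelSpec("PC", recent_on=False, older_on=True),
    "SC": ModelSpec("SC", recent_on=True, older_on=False),
    "CI": ModelSpec("CI", recent_on=False, older_on=False),
}


def migration_schedule(model: ModelSpec | str, p: DemographicParams) -> dict[str, tuple[float, float]]:
    """Epoch table of forward migration rates (m_CT, m_CR) after masking.

    Keys: ``recent`` for [0, t1) and ``older`` for [t1, t2).
    """
    if isinstance(model, str):
        model = MODELS[model]
    return {
        "recent": (p.m_CT2, p.m_CR2) if model.recent_on else (0.0, 0.0),
        "older": (p.m_CT1, p.m_CR1) if model.older_on else (0.0, 0.0),
    }


@dataclass
class SimConfig:
    """Sampling configuration for a simulated SNP dataset."""

    n_CR: int = 209
    n_CT: int = 30
    n_loci: int = 907
    locus_len: int = 238
    seed: int = 0
    generation_years: float = 30.0

    def __post_init__(self) -> None:
        if self.n_CR < 2 or self.n_CT < 2:
            raise ValueError("diploid sample sizes must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


# ---------------------------------------------------------------------------
# Numba kernel: one locus, arbitrary deme schedule
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sim_locus(seed, deme_of_sample, boundaries, sizes, mig, remap, theta, fast_ratio):
    """Simulate one locus genealogy and drop infinite-sites mutations.

    Parameters are flat arrays describing a piecewise-constant demography:
    ``boundaries[e]`` is the end time of epoch ``e`` (last entry inf),
    ``sizes[e, d]`` the diploid size of deme ``d`` (0 = inactive),
    ``mig[e, i, j]`` the backward rate at which a lineage in deme ``i``
    jumps to deme ``j``, and ``remap[e, d]`` the deme that absorbs ``d``
    when epoch ``e`` begins.  Returns a (n_mutations, n_haplotypes)
    uint8 matrix of derived-allele carriers.
    """
    np.random.seed(seed)
    ntot = deme_of_sample.shape[0]
    D = sizes.shape[1]
    maxn = 2 * ntot - 1
    node_time = np.zeros(maxn)
    left = np.full(maxn, -1, np.int32)
    right = np.full(maxn, -1, np.int32)
    act = np.empty(ntot, np.int32)
    deme = np.empty(ntot, np.int32)
    for i in range(ntot):
        act[i] = i
        deme[i] = deme_of_sample[i]
    k = ntot
    nxt = ntot
    t = 0.0
    ep = 0
    was_fast = False
    fast_d0 = 0
    fast_d1 = 0
    fast_pi0 = 0.5
    kcount = np.zeros(D, np.int64)
    coal_d = np.zeros(D)

    while k > 1:
        # active demes this epoch
        nact = 0
        d0 = -1
        d1 = -1
        for d in range(D):
            if sizes[ep, d] > 0.0:
                if nact == 0:
                    d0 = d
                elif nact == 1:
                    d1 = d
                nact += 1
        # strong-migration limit only handled for the two-deme case
        fast = False
        pi0 = 0.5
        if nact == 2:
            m01 = mig[ep, d0, d1]
            m10 = mig[ep, d1, d0]
            if m01 > 0.0 and m10 > 0.0:
                crate = 1.0 / (2.0 * sizes[ep, d0]) + 1.0 / (2.0 * sizes[ep, d1])
                if m01 + m10 > fast_ratio * crate:
                    fast = True
                    pi0 = m10 / (m01 + m10)

        if nact == 1 or fast:
            if nact == 1:
                lam = 1.0 / (2.0 * sizes[ep, d0])
            else:
                lam = (
                    pi0 * pi0 / (2.0 * sizes[ep, d0])
                    + (1.0 - pi0) * (1.0 - pi0) / (2.0 * sizes[ep, d1])
                )
            tot = 0.5 * k * (k - 1) * lam
            migtot = 0.0
        else:
            for d in range(D):
                kcount[d] = 0
            for i in range(k):
                kcount[deme[i]] += 1
            tot = 0.0
            for d in range(D):
                if sizes[ep, d] > 0.0 and kcount[d] > 1:
                    coal_d[d] = kcount[d] * (kcount[d] - 1) / (4.0 * sizes[ep, d])
                else:
                    coal_d[d] = 0.0
                tot += coal_d[d]
            migtot = 0.0
            for i_d in range(D):
                for j_d in range(D):
                    if i_d != j_d:
                        migtot += kcount[i_d] * mig[ep, i_d, j_d]
            tot += migtot

        cross = False
        if tot <= 0.0:
            cross = True
        else:
            dt = np.random.exponential(1.0 / tot)
            if t + dt >= boundaries[ep]:
                cross = True
            else:
                t += dt

        if cross:
            t = boundaries[ep]
            # leaving a fast-regime epoch: lineage demes are stale;
            # redraw from the stationary occupancy before remapping
            if fast:
                for i in range(k):
                    if np.random.random() < pi0:
                        deme[i] = d0
                    else:
                        deme[i] = d1
            ep += 1
            for i in range(k):
                deme[i] = remap[ep, deme[i]]
            continue

        # pick event
        if nact == 1 or fast:
            i = np.random.randint(0, k)
            j = np.random.randint(0, k - 1)
            if j >= i:
                j += 1
            ev_deme = d0
        else:
            u = np.random.random() * tot
            ev_deme = -1
            for d in range(D):
                if u < coal_d[d]:
                    ev_deme = d
                    break
                u -= coal_d[d]
            if ev_deme >= 0:
                # coalescence in ev_deme: pick two distinct lineages there
                r1 = np.random.randint(0, kcount[ev_deme])
                r2 = np.random.randint(0, kcount[ev_deme] - 1)
                if r2 >= r1:
                    r2 += 1
                i = -1
                j = -1
                seen = 0
                for pos in range(k):
                    if deme[pos] == ev_deme:
                        if seen == r1:
                            i = pos
                        if seen == r2:
                            j = pos
                        seen += 1
            else:
                # migration event
                done = False
                for i_d in range(D):
                    for j_d in range(D):
                        if i_d == j_d:
                            continue
                        r = kcount[i_d] * mig[ep, i_d, j_d]
                        if u < r:
                            pick = np.random.randint(0, kcount[i_d])
                            seen = 0
                            for pos in range(k):
                                if deme[pos] == i_d:
                                    if seen == pick:
                                        deme[pos] = j_d
                                        done = True
                                        break
                                    seen += 1
                            break
                        u -= r
                    if done:
                        break
                continue

        # coalescence of positions i, j (i != j)
        if i > j:
            i, j = j, i
        nd = nxt
        nxt += 1
        node_time[nd] = t
        left[nd] = act[i]
        right[nd] = act[j]
        act[i] = nd
        deme[i] = ev_deme
        act[j] = act[k - 1]
        deme[j] = deme[k - 1]
        k -= 1

    # branch lengths (root has length 0)
    elen = np.zeros(nxt)
    for nd in range(ntot, nxt):
        elen[left[nd]] = node_time[nd] - node_time[left[nd]]
        elen[right[nd]] = node_time[nd] - node_time[right[nd]]
    total_len = elen.sum()

    nm = np.random.poisson(theta * total_len) if theta * total_len > 0 else 0
    hap = np.zeros((nm, ntot), np.uint8)
    if nm > 0:
        desc = np.zeros((nxt, ntot), np.uint8)
        for i in range(ntot):
            desc[i, i] = 1
        for nd in range(ntot, nxt):
            for c in range(ntot):
                desc[nd, c] = desc[left[nd], c] | desc[right[nd], c]
        cum = np.cumsum(elen)
        for m in range(nm):
            x = np.random.random() * total_len
            e = np.searchsorted(cum, x)
            if e >= nxt:
                e = nxt - 1
            for c in range(ntot):
                hap[m, c] = desc[e, c]
    return hap


# ---------------------------------------------------------------------------
# Schedule construction and the public simulators
# ---------------------------------------------------------------------------

@dataclass
class DemeSchedule:
    """Piecewise-constant demography in the kernel's array form."""

    boundaries: np.ndarray  # (n_epochs,) end times, last = inf
    sizes: np.ndarray       # (n_epochs, D)
    mig: np.ndarray         # (n_epochs, D, D) backward rates
    remap: np.ndarray       # (n_epochs, D)


def two_population_schedule(p: DemographicParams, model: ModelSpec | str) -> DemeSchedule:
    """Demography arrays for the sampled two-deme system (0=CR, 1=CT)."""
    if isinstance(model, str):
        model = MODELS[model]
    ds = derived_sizes(p)
    sched = migration_schedule(model, p)
    m_ct_recent, m_cr_recent = sched["recent"]
    m_ct_older, m_cr_older = sched["older"]
    boundaries = np.array([p.t1, p.t2, np.inf])
    sizes = np.array([
        [p.N_CR2, p.N_CT2],
        [ds.N_CR1, ds.N_CT1],
        [ds.N_anc, 0.0],
    ])
    mig = np.zeros((3, 2, 2))
    # backward: lineage in CR (deme 0) jumps to CT at the forward CT->CR rate
    mig[0, 0, 1] = m_ct_recent
    mig[0, 1, 0] = m_cr_recent
    mig[1, 0, 1] = m_ct_older
    mig[1, 1, 0] = m_cr_older
    remap = np.array([[0, 1], [0, 1], [0, 0]], dtype=np.int32)
    return DemeSchedule(boundaries=boundaries, sizes=sizes, mig=mig, remap=remap)


def simulate_loci(
    schedule: DemeSchedule,
    deme_of_sample: np.ndarray,
    n_loci: int,
    locus_len: int,
    mu: float,
    seed: int,
) -> list[np.ndarray]:
    """Simulate ``n_loci`` independent loci; returns one
    (n_mutations x n_haplotypes) uint8 matrix per locus.

    Per-locus child seeds are derived deterministically from ``seed``."""
    ss = np.random.SeedSequence(seed)
    locus_seeds = ss.generate_state(n_loci).astype(np.int64)
    theta = mu * locus_len
    deme_of_sample = np.asarray(deme_of_sample, dtype=np.int32)
    out = []
    for j in range(n_loci):
        out.append(
            _sim_locus(
                locus_seeds[j],
                deme_of_sample,
                schedule.boundaries,
                schedule.sizes,
                schedule.mig,
                schedule.remap.astype(np.int32),
                theta,
                FAST_MIGRATION_RATIO,
            )
        )
    return out


def haplotypes_to_matrix(
    locus_haps: list[np.ndarray],
    individuals: list[str],
    pop_of: dict[str, str],
    species_of: dict[str, str],
    locus_len: int,
    seed: int = 0,
) -> GenotypeMatrix:
    """Pair consecutive haplotypes into diploids and assemble a
    GenotypeMatrix.  Haplotype 2i and 2i+1 belong to individual i (the
    coalescent makes haplotypes exchangeable, so the pairing is
    distribution-free).  Site positions within each locus are distinct
    uniform draws."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n_ind = len(individuals)
    blocks = []
    rows = []
    for j, hap in enumerate(locus_haps):
        nm = hap.shape[0]
        if nm == 0:
            continue
        g = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)  # (nm, n_ind)
        if nm <= locus_len:
            pos = np.sort(rng.choice(locus_len, size=nm, replace=False)) + 1
        else:  # pathological theta; keep positions unique anyway
            pos = np.arange(1, nm + 1)
        for s in range(nm):
            rows.append((f"L{j:05d}", int(pos[s]), "A", "T"))
        blocks.append(g.T)
    calls = (
        np.concatenate(blocks, axis=1)
        if blocks
        else np.zeros((n_ind, 0), dtype=np.int8)
    )
    loci = pd.DataFrame(rows, columns=["locus_id", "pos", "ref", "alt"])
    return GenotypeMatrix(
        individuals=individuals,
        loci=loci,
        calls=calls,
        pop_of=pop_of,
        species_of=species_of,
    )


def simulate_dataset(
    p: DemographicParams,
    model: ModelSpec | str,
    cfg: SimConfig,
) -> GenotypeMatrix:
    """Simulate a diploid SNP dataset under one speciation scenario.

    Each of ``cfg.n_loci`` loci is an independent genealogy of the
    structured coalescent described in the module docstring, with
    infinite-sites mutations at rate ``mu x locus_len``.  Output carries
    species labels CR/CT (populations default to the species label).
    """
    ds = derived_sizes(p)
    if 2 * cfg.n_CR > 2 * p.N_CR2 or 2 * cfg.n_CT > 2 * p.N_CT2:
        warnings.warn(
            "sample size exceeds 2N in at least one deme; the continuous "
            "coalescent remains defined but is a poor approximation",
            stacklevel=2,
        )
    del ds
    schedule = two_population_schedule(p, model)
    deme_of_sample = np.repeat(
        np.array([0, 1], dtype=np.int32), [2 * cfg.n_CR, 2 * cfg.n_CT]
    )
    haps = simulate_loci(
        schedule, deme_of_sample, cfg.n_loci, cfg.locus_len, p.mu, cfg.seed
    )
    individuals = [f"CR_{i:03d}" for i in range(cfg.n_CR)] + [
        f"CT_{i:03d}" for i in range(cfg.n_CT)
    ]
    pop_of = {ind: ind.split("_")[0] for ind in individuals}
    species_of = dict(pop_of)
    return haplotypes_to_matrix(
        haps, individuals, pop_of, species_of, cfg.locus_len, seed=cfg.seed + 1
    )
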