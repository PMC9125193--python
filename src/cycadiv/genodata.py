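"""Genotype data model, VCF/TSV IO and SNP-panel filtering.

The central container is :class:`GenotypeMatrix`: unphased diploid
biallelic genotypes coded as alternate-allele counts {0, 1, 2} with
``MISSING = -1``, one column per SNP site, sites grouped into RAD loci.
Filtering follows the fixed rule order used when assembling a ddRAD SNP
panel: depth, site missingness, minor-allele frequency, observed
heterozygosity, individual missingness, and one SNP per RAD locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1

_GT_MAP = {
    "0/0": 0, "0|0": 0,
    "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
    "1/1": 2, "1|1": 2,
    "./.": MISSING, ".|.": MISSING, ".": MISSING,
    "./1": MISSING, "1/.": MISSING, "./0": MISSING, "0/.": MISSING,
}


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes with locus, population and species labels.

    Parameters
    ----------
    individuals
        Ordered sample identifiers.
    loci
        One row per SNP site with columns ``locus_id`` (RAD locus),
        ``pos`` (1-based position within the locus), ``ref`` and ``alt``.
    calls
        ``(n_individuals, n_sites)`` int8 array of alternate-allele
        counts in {0, 1, 2} or ``MISSING``.
    pop_of, species_of
        Maps individual -> population label / species label (CR or CT).
    depth
        Optional ``(n_individuals, n_sites)`` mean read depth.
    """

    individuals: list[str]
    loci: pd.DataFrame
    calls: np.ndarray
    pop_of: dict[str, str]
    species_of: dict[str, str]
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} sites"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype calls outside {{0,1,2,MISSING}}")
        for ind in self.individuals:
            if ind not in self.pop_of:
                raise ValueError(f"individual {ind!r} has no population label")
            if ind not in self.species_of:
                raise ValueError(f"individual {ind!r} has no species label")
        if not self.loci.empty:
            key = list(zip(self.loci["locus_id"], self.loci["pos"]))
            if len(set(key)) != len(key):
                raise ValueError("duplicate (locus_id, pos) site records")
        self.loci = self.loci.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.loci)

    def labels(self, grouping: str) -> np.ndarray:
        """Group label per individual for ``grouping`` in
        {'population', 'species'}."""
        if grouping == "population":
            return np.array([self.pop_of[i] for i in self.individuals])
        if grouping == "species":
            return np.array([self.species_of[i] for i in self.individuals])
        raise ValueError(f"unknown grouping {grouping!r}")

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individuals=list(self.individuals),
            loci=self.loci.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
            pop_of=dict(self.pop_of),
            species_of=dict(self.species_of),
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        inds = [self.individuals[i] for i in np.atleast_1d(idx)]
        return GenotypeMatrix(
            individuals=inds,
            loci=self.loci.copy(),
            calls=self.calls[np.atleast_1d(idx), :],
            pop_of={i: self.pop_of[i] for i in inds},
            species_of={i: self.species_of[i] for i in inds},
            depth=None if self.depth is None else self.depth[np.atleast_1d(idx), :],
        )


@dataclass
class FilterConfig:
    """Thresholds for SNP-panel quality control.

    Defaults reproduce a ddRAD panel-assembly protocol: sites with mean
    allele depth < 5 (when depth is recorded), missing rate > 0.55,
    minor-allele frequency < 0.01 or observed heterozygosity > 0.8 are
    dropped, individuals with > 0.5 missing calls are dropped, and only
    one SNP per RAD locus is kept.
    """

    maf_min: float = 0.01
    max_obs_het: float = 0.8
    site_missing_max: float = 0.55
    indiv_missing_max: float = 0.5
    depth_min: float = 5.0
    one_snp_per_locus: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_obs_het", "site_missing_max", "indiv_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    n_sites_in: int
    n_individuals_in: int
    sites_removed: dict[str, int] = field(default_factory=dict)
    individuals_removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites_out(self) -> int:
        return self.n_sites_in - sum(self.sites_removed.values())

    @property
    def n_individuals_out(self) -> int:
        return self.n_individuals_in - sum(self.individuals_removed.values())

    def to_dict(self) -> dict:
        return {
            "n_sites_in": self.n_sites_in,
            "n_sites_out": self.n_sites_out,
            "n_individuals_in": self.n_individuals_in,
            "n_individuals_out": self.n_individuals_out,
            "sites_removed": dict(self.sites_removed),
            "individuals_removed": dict(self.individuals_removed),
        }


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_labels(labels_path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a TSV with header ``individual<TAB>population<TAB>species``."""
    tab = pd.read_csv(labels_path, sep="\t", dtype=str)
    required = {"individual", "population", "species"}
    if not required.issubset(tab.columns):
        raise ValueError(f"labels file must have columns {sorted(required)}")
    pop_of = dict(zip(tab["individual"], tab["population"]))
    species_of = dict(zip(tab["individual"], tab["species"]))
    return pop_of, species_of


def read_genotypes(vcf_path, labels_path) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF plus a labels TSV into a GenotypeMatrix.

    GT fields ``./.``, ``0/0``, ``0/1``, ``1/1`` (phased equivalents
    accepted) map to MISSING, 0, 1, 2.  Multi-allelic sites are skipped
    with a log message.  A VCF sample absent from the labels file is an
    error naming the sample.
    """
    pop_of, species_of = read_labels(labels_path)
    samples: list[str] = []
    rows: list[tuple] = []
    gts: list[list[int]] = []
    dps: list[list[float]] = []
    has_dp = False
    with open(vcf_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                for s in samples:
                    if s not in pop_of or s not in species_of:
                        raise ValueError(
                            f"sample {s!r} in VCF is absent from the labels file"
                        )
                continue
            parts = line.split("\t")
            chrom, pos, _id, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt or alt in (".", "") or len(ref) != 1 or len(alt) != 1:
                logger.warning("skipping non-biallelic-SNP site %s:%s (ALT=%s)", chrom, pos, alt)
                continue
            fmt = parts[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError:
                raise ValueError(f"site {chrom}:{pos} lacks a GT field")
            dp_i = fmt.index("DP") if "DP" in fmt else None
            row_gt, row_dp = [], []
            for cell in parts[9:]:
                sub = cell.split(":")
                gt = _GT_MAP.get(sub[gt_i])
                if gt is None:
                    raise ValueError(f"unparseable GT {sub[gt_i]!r} at {chrom}:{pos}")
                row_gt.append(gt)
                if dp_i is not None:
                    v = sub[dp_i] if dp_i < len(sub) else "."
                    row_dp.append(float(v) if v not in (".", "") else np.nan)
            rows.append((chrom, int(pos), ref, alt))
            gts.append(row_gt)
            if dp_i is not None:
                has_dp = True
                dps.append(row_dp)
    loci = pd.DataFrame(rows, columns=["locus_id", "pos", "ref", "alt"])
    calls = (
        np.array(gts, dtype=np.int8).T
        if gts
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depth = np.array(dps, dtype=float).T if has_dp and len(dps) == len(rows) else None
    return GenotypeMatrix(
        individuals=samples,
        loci=loci,
        calls=calls,
        pop_of={s: pop_of[s] for s in samples},
        species_of={s: species_of[s] for s in samples},
        depth=depth,
    )


def write_genotypes(gm: GenotypeMatrix, vcf_path, labels_path=None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 (+ labels TSV)."""
    inv_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cycadiv\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.individuals) + "\n")
        fmt = "GT:DP" if gm.depth is not None else "GT"
        for j in range(gm.n_sites):
            rec = gm.loci.iloc[j]
            cells = []
            for i in range(gm.n_individuals):
                cell = inv_gt[int(gm.calls[i, j])]
                if gm.depth is not None:
                    d = gm.depth[i, j]
                    cell += ":." if np.isnan(d) else f":{int(round(d))}"
                cells.append(cell)
            fh.write(
                f"{rec['locus_id']}\t{rec['pos']}\t.\t{rec['ref']}\t{rec['alt']}"
                f"\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )
    if labels_path is not None:
        write_labels(gm, labels_path)


def write_labels(gm: GenotypeMatrix, labels_path) -> None:
    with open(labels_path, "w") as fh:
        fh.write("individual\tpopulation\tspecies\n")
        for ind in gm.individuals:
            fh.write(f"{ind}\t{gm.pop_of[ind]}\t{gm.species_of[ind]}\n")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _site_stats(calls: np.ndarray):
    """Per-site (missing rate, alt frequency, observed het) with NaN for
    sites with zero non-missing calls."""
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        miss = 1.0 - n_obs / calls.shape[0] if calls.shape[0] else np.ones(calls.shape[1])
        alt = np.where(obs, calls, 0).sum(axis=0) / np.where(n_obs > 0, 2 * n_obs, 1)
        alt = np.where(n_obs > 0, alt, np.nan)
        het = (calls == 1).sum(axis=0) / np.where(n_obs > 0, n_obs, 1)
        het = np.where(n_obs > 0, het, np.nan)
    return miss, alt, het


def filter_snps(gm: GenotypeMatrix, cfg: FilterConfig | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the panel QC rules in fixed order and report removals.

    Order within a pass: (1) per-site mean depth (only if depth is
    recorded), (2) site missingness, (3) MAF, (4) observed
    heterozygosity, (5) individual missingness, (6) one SNP per locus
    (highest MAF kept, ties broken by smallest position).  Because the
    site rules are recomputed on the retained individuals and vice
    versa, one pass is not a fixed point; the pass is repeated until
    nothing changes, which makes filtering idempotent.  The report
    accumulates removals per rule across passes.  All sites may
    legitimately be removed; an empty matrix is returned, not an error.
    """
    if cfg is None:
        cfg = FilterConfig()
    if gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    report = FilterReport(n_sites_in=gm.n_sites, n_individuals_in=gm.n_individuals)
    cur = gm
    while True:
        before = (cur.n_sites, cur.n_individuals)
        cur = _filter_pass(cur, cfg, report)
        if (cur.n_sites, cur.n_individuals) == before:
            break
    return cur, report


def _filter_pass(gm: GenotypeMatrix, cfg: FilterConfig, report: FilterReport) -> GenotypeMatrix:
    cur = gm

    def drop_sites(keep: np.ndarray, rule: str) -> None:
        nonlocal cur
        report.sites_removed[rule] = (
            report.sites_removed.get(rule, 0) + int((~keep).sum())
        )
        cur = cur.take_sites(np.flatnonzero(keep))

    # (1) depth
    if cur.depth is not None:
        with np.errstate(invalid="ignore"):
            mean_depth = np.nanmean(
                np.where(cur.calls != MISSING, cur.depth, np.nan), axis=0
            )
            keep = ~(mean_depth < cfg.depth_min)
        drop_sites(keep, "depth")
    else:
        report.sites_removed.setdefault("depth", 0)

    # (2) site missingness
    miss, _, _ = _site_stats(cur.calls)
    drop_sites(miss <= cfg.site_missing_max, "site_missing")

    # (3) MAF
    _, alt, _ = _site_stats(cur.calls)
    maf = np.fmin(alt, 1.0 - alt)
    with np.errstate(invalid="ignore"):
        keep = maf >= cfg.maf_min
    drop_sites(np.where(np.isnan(maf), False, keep), "maf")

    # (4) observed heterozygosity
    _, _, het = _site_stats(cur.calls)
    with np.errstate(invalid="ignore"):
        keep = ~(het > cfg.max_obs_het)
    drop_sites(keep, "max_het")

    # (5) individual missingness
    if cur.n_sites > 0:
        ind_miss = (cur.calls == MISSING).mean(axis=1)
    else:
        ind_miss = np.zeros(cur.n_individuals)
    keep_ind = ind_miss <= cfg.indiv_missing_max
    report.individuals_removed["indiv_missing"] = (
        report.individuals_removed.get("indiv_missing", 0) + int((~keep_ind).sum())
    )
    cur = cur.take_individuals(np.flatnonzero(keep_ind))

    # (6) one SNP per locus
    if cfg.one_snp_per_locus and cur.n_sites > 0:
        _, alt, _ = _site_stats(cur.calls)
        maf = np.fmin(alt, 1.0 - alt)
        maf = np.where(np.isnan(maf), -1.0, maf)
        tab = pd.DataFrame(
            {"locus_id": cur.loci["locus_id"], "pos": cur.loci["pos"], "maf": maf}
        )
        # highest MAF; tie -> smallest position; stable within locus
        tab = tab.sort_values(["maf", "pos"], ascending=[False, True], kind="mergesort")
        keep_idx = tab.drop_duplicates("locus_id", keep="first").index.to_numpy()
        keep = np.zeros(cur.n_sites, dtype=bool)
        keep[keep_idx] = True
        drop_sites(keep, "one_snp_per_locus")
    else:
        report.sites_removed.setdefault("one_snp_per_locus", 0)

    return cur


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_freq(gm: GenotypeMatrix, grouping: str = "population") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alternate-allele frequency and diploid sample size per group x site.

    Frequency = alt-allele count / (2 x non-missing individuals).  A group
    with zero non-missing calls at a site gets NaN (undefined), never 0.

    Returns
    -------
    (freqs, sizes)
        DataFrames indexed by group label, one column per site index.
    """
    labels = gm.labels(grouping)
    groups = sorted(set(labels))
    freq = np.full((len(groups), gm.n_sites), np.nan)
    size = np.zeros((len(groups), gm.n_sites), dtype=int)
    for gi, g in enumerate(groups):
        sub = gm.calls[labels == g, :]
        obs = sub != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(obs, sub, 0).sum(axis=0) / (2.0 * n)
        freq[gi] = np.where(n > 0, f, np.nan)
        size[gi] = n
    cols = pd.RangeIndex(gm.n_sites)
    return (
        pd.DataFrame(freq, index=groups, columns=cols),
        pd.DataFrame(size, index=groups, columns=cols),
    )
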