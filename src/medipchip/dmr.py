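"""Differential methylation region (DMR) calling.

Probe significance is empirical: within each comparative hybridization the
smoothed M values are compared to a normal distribution scaled to their own
mean and standard deviation; a Z-score and two-sided p-value are computed
per probe and probes with p below the threshold (default 1e-5) are
significant.  The analysis is performed in pairs of hybridizations and only
probes significant in all paired comparisons — equivalently, in every
hybridization — are retained.  Retained probes are clustered into regions
by combining consecutive probes within 600 bases of each other with
agreeing sign of mean M, then filtered on mean intensity (A > 9.5) and CpG
density (>= 1 CpG/100 bp).
"""
from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .normalization import MAProfile

logger = logging.getLogger(__name__)

REGION_COLUMNS = ["chrom", "start", "end", "direction", "p_value", "mean_m",
                  "mean_a", "n_probes", "probe_ids"]


class DegenerateDistributionError(RuntimeError):
    """Zero spread in smoothed M; Z-scores undefined."""


def probe_z_scores(profile: MAProfile, threshold: float = 1e-5) -> pd.DataFrame:
    """Empirical per-probe Z-scores and p-values for one hybridization.

    z = (M - mu) / sigma with mu, sigma the mean and standard deviation of
    all valid smoothed M values in this hybridization; p is the two-sided
    normal tail probability.
    """
    profile.require_stage("smoothed")
    df = profile.data
    valid = df["valid"].to_numpy()
    m = df["M"].to_numpy()
    if valid.sum() < 2:
        raise ValueError("need >= 2 valid probes to scale the distribution")
    mu = m[valid].mean()
    sigma = m[valid].std(ddof=0)
    if sigma == 0:
        raise DegenerateDistributionError(
            "all smoothed M values identical; cannot scale Z-scores")
    z = np.where(valid, (m - mu) / sigma, np.nan)
    p = np.where(valid, np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
                 np.nan)
    return pd.DataFrame({
        "M": m, "z": z, "p": p,
        "significant": valid & (p < threshold),
        "valid": valid,
    }, index=df.index)


@dataclasses.dataclass
class PairedSignificance:
    """All-pairs intersection of per-hybridization significant probe sets."""

    pair_counts: dict[tuple[int, int], int]
    retained: pd.Index
    n_hybridizations: int

    def min_pair_count(self) -> int:
        return min(self.pair_counts.values())


def paired_intersection(sig_frames: list[pd.DataFrame]) -> PairedSignificance:
    """Intersect significance over all unordered hybridization pairs.

    A probe is pair-significant iff significant in both members of a pair;
    the retained set is the intersection over all pairs, which equals the
    set of probes significant in every hybridization.  Pairwise set sizes
    are reported (the per-pair "sites" counts).
    """
    if len(sig_frames) < 2:
        raise ValueError("paired intersection requires >= 2 hybridizations")
    idx0 = sig_frames[0].index
    for f in sig_frames[1:]:
        if not f.index.equals(idx0):
            raise ValueError("significance frames must share a probe universe")
    sig = np.column_stack([f["significant"].to_numpy() for f in sig_frames])
    pair_counts = {}
    for i, j in itertools.combinations(range(sig.shape[1]), 2):
        pair_counts[(i + 1, j + 1)] = int((sig[:, i] & sig[:, j]).sum())
    retained_mask = sig.all(axis=1)
    for (i, j), cnt in pair_counts.items():
        logger.info("pair (%d,%d) gave %d sites", i, j, cnt)
    return PairedSignificance(pair_counts, idx0[retained_mask], len(sig_frames))


def cluster_probes_to_regions(probes: pd.DataFrame,
                              gap_bp: int = 600) -> pd.DataFrame:
    """Cluster retained probes into candidate regions.

    ``probes`` must be sorted by (chrom, start) and carry columns chrom,
    start, end, mean_m (mean smoothed M over hybridizations), mean_a and
    p_value (the probe's least favorable p over hybridizations).  Probes
    are combined into maximal runs where consecutive midpoint gaps are
    <= ``gap_bp`` and mean-M signs agree; the region interval spans the
    first probe's start to the last probe's end, the region p-value is the
    maximum member p (most conservative), and the direction is the shared
    sign (+1 hyper / -1 hypo).  An exact-zero mean M breaks toward +1 and
    is logged.
    """
    if probes.empty:
        return pd.DataFrame(columns=REGION_COLUMNS)
    rows = []
    cur: list[tuple] = []

    def flush():
        if not cur:
            return
        chroms, starts, ends, mids, ms, as_, ps, pids, signs = zip(*cur)
        rows.append({
            "chrom": chroms[0],
            "start": int(min(starts)),
            "end": int(max(ends)),
            "direction": int(signs[0]),
            "p_value": float(max(ps)),
            "mean_m": float(np.mean(ms)),
            "mean_a": float(np.mean(as_)),
            "n_probes": len(cur),
            "probe_ids": ",".join(pids),
        })

    prev_mid = None
    prev_chrom = None
    prev_sign = None
    for pid, row in probes.iterrows():
        mid = (int(row["start"]) + int(row["end"])) // 2
        mm = float(row["mean_m"])
        if mm == 0.0:
            logger.warning("probe %s has mean M exactly 0; sign tie-broken "
                           "to +1", pid)
        sign = 1 if mm >= 0 else -1
        if (prev_chrom != row["chrom"] or prev_mid is None
                or mid - prev_mid > gap_bp or sign != prev_sign):
            flush()
            cur = []
        cur.append((row["chrom"], int(row["start"]), int(row["end"]), mid,
                    mm, float(row["mean_a"]), float(row["p_value"]),
                    str(pid), sign))
        prev_mid, prev_chrom, prev_sign = mid, row["chrom"], sign
    flush()
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def annotate_regions(regions: pd.DataFrame,
                     annotation: GenomeAnnotation) -> pd.DataFrame:
    """Annotate regions with promoter gene, CpG count and density.

    The gene is the promoter with the largest overlap (ties to the
    lexicographically smaller gene id); a region overlapping no promoter
    gets gene NA and is flagged.  cpg_density = 100 * n_cpg / (end-start).
    """
    regions = regions.copy()
    genes, ncpg, dens, flagged = [], [], [], []
    for _, r in regions.iterrows():
        gene, overlap = annotation.promoter_for_interval(
            r["chrom"], int(r["start"]), int(r["end"]))
        if gene is None:
            logger.warning("region %s:%d-%d overlaps no promoter",
                           r["chrom"], r["start"], r["end"])
        genes.append(gene)
        n = annotation.count_cpg(r["chrom"], int(r["start"]), int(r["end"]))
        ncpg.append(n)
        width = int(r["end"]) - int(r["start"])
        dens.append(100.0 * n / width if width > 0 else 0.0)
        flagged.append(gene is None)
    regions["gene_id"] = genes
    regions["n_cpg"] = ncpg
    regions["cpg_density"] = dens
    regions["no_promoter"] = flagged
    return regions


def filter_regions(regions: pd.DataFrame,
                   min_mean_a: float = 9.5,
                   min_cpg_density: float = 1.0
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intensity and CpG-density filters.

    A region is kept iff mean A strictly exceeds ``min_mean_a`` AND
    cpg_density >= ``min_cpg_density`` (boundary inclusive).  Returns
    (kept, removed) with the failing criterion recorded on removed rows.
    """
    if regions.empty:
        removed = regions.copy()
        removed["failed"] = pd.Series(dtype=str)
        return regions.copy(), removed
    pass_a = regions["mean_a"] > min_mean_a
    pass_d = regions["cpg_density"] >= min_cpg_density
    kept = regions[pass_a & pass_d].copy()
    removed = regions[~(pass_a & pass_d)].copy()
    reasons = []
    for ok_a, ok_d in zip(pass_a[~(pass_a & pass_d)], pass_d[~(pass_a & pass_d)]):
        fails = []
        if not ok_a:
            fails.append(f"mean_a<={min_mean_a}")
        if not ok_d:
            fails.append(f"cpg_density<{min_cpg_density}")
        reasons.append(";".join(fails))
    removed["failed"] = reasons
    for _, r in removed.iterrows():
        logger.info("region %s:%d-%d removed (%s)", r["chrom"], r["start"],
                    r["end"], r["failed"])
    return kept, removed


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """BED6+ view: name=gene, score=-log10 region p, strand=direction."""
    return pd.DataFrame({
        "chrom": regions["chrom"],
        "start": regions["start"],
        "end": regions["end"],
        "name": regions.get("gene_id", pd.Series(["."] * len(regions))).fillna("."),
        "score": (-np.log10(regions["p_value"].clip(lower=1e-300))).round(3),
        "strand": np.where(regions["direction"] > 0, "+", "-"),
    })
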