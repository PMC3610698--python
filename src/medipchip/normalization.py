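"""Two-channel tiling-array normalization.

Signals are converted to MA values (M = Cy5 - Cy3, A = (Cy5 + Cy3)/2 on
the log2 scale) and pushed through three stages in fixed order:

1. ``gc_group_loess`` — within each array, probes are split into GC-content
   groups and each group receives its own loess normalization curve of M on
   A, which is subtracted from M (removes intensity- and GC-dependent dye
   bias).
2. ``aquantile_across_arrays`` — the distribution of A values is forced to
   be identical across arrays (rank-mean quantile normalization of A only);
   each probe's M is preserved.
3. ``window_median_smooth`` — each probe's M (and likewise A) is replaced
   by the median over all probes whose midpoints fall within a 600 bp
   window centered on the probe; if fewer than 3 distinct probe positions
   contribute, no value is assigned and the probe is flagged invalid.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .annotation import check_probe_order

STAGES = ("raw", "loess", "aquantile", "smoothed")


class StageError(RuntimeError):
    """Normalization stages applied out of order."""


class AlignmentError(RuntimeError):
    """Probe universes differ between arrays."""


@dataclasses.dataclass
class MAProfile:
    """Per-hybridization MA profile.

    ``data`` is indexed by probe_id with columns chrom, start, end,
    gc_fraction, M, A, valid; ``stage`` is one of ``STAGES``.
    """

    data: pd.DataFrame
    stage: str
    hyb: int = 1

    def copy(self) -> "MAProfile":
        return MAProfile(self.data.copy(), self.stage, self.hyb)

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.data["start"].to_numpy()
                 + self.data["end"].to_numpy()) // 2)

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"operation requires stage={stage!r}, profile is at "
                f"{self.stage!r} (stages run in order {'->'.join(STAGES)})")


def compute_ma(cy5, cy3):
    """MA transform of log2 channel signals: M = Cy5 - Cy3, A = (Cy5+Cy3)/2.

    Non-finite inputs propagate to non-finite outputs (flagged invalid by
    callers).
    """
    cy5 = np.asarray(cy5, dtype=float)
    cy3 = np.asarray(cy3, dtype=float)
    m = cy5 - cy3
    a = (cy5 + cy3) / 2.0
    if m.ndim == 0:
        return float(m), float(a)
    return m, a


def ma_from_hybridizations(hybset) -> list[MAProfile]:
    """Raw MA profiles, one per comparative hybridization."""
    profiles = []
    base = hybset.probes.set_index("probe_id")[
        ["chrom", "start", "end", "gc_fraction"]]
    for h in range(1, hybset.n_pairs + 1):
        m, a = compute_ma(hybset.channel("cy5", h), hybset.channel("cy3", h))
        df = base.copy()
        df["M"] = m
        df["A"] = a
        df["valid"] = np.isfinite(m) & np.isfinite(a)
        profiles.append(MAProfile(df, "raw", hyb=h))
    return profiles


def _loess_curve(a: np.ndarray, m: np.ndarray, span: float):
    """Fit a loess curve of M on A; return an interpolator."""
    delta = 0.005 * (a.max() - a.min())
    fit = sm.nonparametric.lowess(m, a, frac=span, it=2, delta=delta,
                                  return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]

    def predict(x: np.ndarray) -> np.ndarray:
        return np.interp(x, xs, ys)

    return predict


def gc_group_loess(profile: MAProfile, n_groups: int = 10, span: float = 0.4,
                   min_group_size: int = 50) -> MAProfile:
    """Within-array GC-grouped loess normalization.

    Probes are split into ``n_groups`` quantile groups of GC fraction and
    each group receives a loess normalization curve of M on A specific to
    that group, which is subtracted from M.  Groups smaller than
    ``min_group_size`` fall back to the pooled (all-probe) curve; a group
    whose A values are all identical falls back to subtracting its median
    M.  A is unchanged.
    """
    profile.require_stage("raw")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    out = profile.copy()
    df = out.data
    valid = df["valid"].to_numpy()
    a = df["A"].to_numpy(copy=True)
    m = df["M"].to_numpy(copy=True)
    gc = df["gc_fraction"].to_numpy()

    av, mv = a[valid], m[valid]
    if len(av) == 0:
        out.stage = "loess"
        return out
    if np.ptp(av) < 1e-9:
        med = float(np.median(mv))
        def pooled(x):
            return np.full(np.shape(x), med)
    else:
        pooled = _loess_curve(av, mv, span)
    correction = np.zeros(len(df))
    if n_groups == 1:
        groups = np.zeros(len(df), dtype=int)
    else:
        groups = pd.qcut(gc, n_groups, labels=False, duplicates="drop")
        groups = np.asarray(groups, dtype=int)
    for g in np.unique(groups):
        idx = valid & (groups == g)
        ag, mg = a[idx], m[idx]
        if idx.sum() < min_group_size:
            correction[idx] = pooled(ag)
        elif np.ptp(ag) < 1e-9:
            correction[idx] = np.median(mg)
        else:
            correction[idx] = _loess_curve(ag, mg, span)(ag)
    m = m - correction
    df["M"] = m
    out.stage = "loess"
    return out


def aquantile_across_arrays(profiles: list[MAProfile]) -> list[MAProfile]:
    """A-only quantile normalization across arrays.

    Each probe's A is replaced by the mean of the A values at its rank
    across arrays, so the multiset of A values becomes identical on every
    array; each probe's M is preserved.
    """
    if not profiles:
        return []
    for p in profiles:
        p.require_stage("loess")
    idx0 = profiles[0].data.index
    for p in profiles[1:]:
        if not p.data.index.equals(idx0):
            missing = idx0.symmetric_difference(p.data.index)
            raise AlignmentError(
                f"probe sets differ between arrays; unmatched probes include "
                f"{list(missing[:5])}")
    amat = np.column_stack([p.data["A"].to_numpy() for p in profiles])
    orders = np.argsort(amat, axis=0, kind="stable")
    mean_sorted = np.take_along_axis(amat, orders, axis=0).mean(axis=1)
    out = []
    for j, p in enumerate(profiles):
        new = p.copy()
        new_a = np.empty(len(amat))
        new_a[orders[:, j]] = mean_sorted
        new.data["A"] = new_a
        new.stage = "aquantile"
        out.append(new)
    return out


def window_median_smooth(profiles: list[MAProfile],
                         window_bp: int = 600,
                         min_probes: int = 3,
                         pool_arrays: bool = True) -> list[MAProfile]:
    """Windowed median smoothing of M (and likewise A).

    For each probe, the M values of all probes whose midpoints lie within
    ``window_bp/2`` of its midpoint on the same chromosome are collected —
    across all arrays when ``pool_arrays`` is on, within the probe's own
    array otherwise — and the probe's M is replaced by their median; the
    same procedure is applied to A.  If the window holds fewer than
    ``min_probes`` distinct probe positions, no value is assigned and the
    probe is flagged invalid (pooling arrays cannot rescue an isolated
    probe since positions, not replicated measurements, are counted).
    """
    if not profiles:
        return []
    for p in profiles:
        p.require_stage("aquantile")
    df0 = profiles[0].data
    if not check_probe_order(df0.reset_index()):
        raise ValueError("probes must be sorted by (chromosome, start)")
    half = window_bp / 2.0
    mids = ((df0["start"].to_numpy() + df0["end"].to_numpy()) // 2)
    chrom = df0["chrom"].to_numpy()
    mmat = np.column_stack([p.data["M"].to_numpy() for p in profiles])
    amat = np.column_stack([p.data["A"].to_numpy() for p in profiles])
    valid_in = np.column_stack([p.data["valid"].to_numpy() for p in profiles])
    n, k = mmat.shape
    new_m = np.full((n, k), np.nan)
    new_a = np.full((n, k), np.nan)
    new_valid = np.zeros((n, k), dtype=bool)

    # chromosome blocks are contiguous after the sort check
    start_idx = 0
    for c in pd.unique(chrom):
        block = np.flatnonzero(chrom == c)
        b0, b1 = block[0], block[-1] + 1
        cm = mids[b0:b1].astype(float)
        lo = np.searchsorted(cm, cm - half, side="left")
        hi = np.searchsorted(cm, cm + half, side="right")
        for i in range(b1 - b0):
            l, h = lo[i], hi[i]
            seg_mids = cm[l:h]
            n_positions = len(np.unique(seg_mids))
            if n_positions < min_probes:
                continue
            mseg = mmat[b0 + l:b0 + h, :]
            aseg = amat[b0 + l:b0 + h, :]
            vseg = valid_in[b0 + l:b0 + h, :]
            if pool_arrays:
                mv = mseg[vseg]
                av = aseg[vseg]
                if mv.size == 0:
                    continue
                med_m = np.median(mv)
                med_a = np.median(av)
                new_m[b0 + i, :] = med_m
                new_a[b0 + i, :] = med_a
                new_valid[b0 + i, :] = True
            else:
                for j in range(k):
                    vj = vseg[:, j]
                    if not vj.any():
                        continue
                    new_m[b0 + i, j] = np.median(mseg[vj, j])
                    new_a[b0 + i, j] = np.median(aseg[vj, j])
                    new_valid[b0 + i, j] = True
        start_idx = b1

    out = []
    for j, p in enumerate(profiles):
        new = p.copy()
        new.data["M"] = new_m[:, j]
        new.data["A"] = new_a[:, j]
        new.data["valid"] = new_valid[:, j] & p.data["valid"].to_numpy()
        new.stage = "smoothed"
        out.append(new)
    return out
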