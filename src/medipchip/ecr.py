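"""Epigenetic control region (ECR) detection.

Candidate coordinate-regulation regions are found by sliding a 2 Mb
window at 50 kb steps across each chromosome, testing each window for
over-representation of differentially expressed genes with a one-sided
one-proportion Z-test against the genome-wide DE fraction (p < 0.05),
and merging consecutive over-represented windows into clusters.  Called
DMRs are then associated with clusters within a gap distance (default
2 Mb), and DMR-expression correlations are tabulated as direct pairs
(the DMR's promoter gene is itself DE) and distal pairs (DMR within 2 Mb
of a DE gene body).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation

WINDOW_COLUMNS = ["chrom", "start", "end", "n_genes", "n_de_genes",
                  "truncated"]


def make_windows(annotation: GenomeAnnotation,
                 de_gene_ids=(),
                 window_bp: int = 2_000_000,
                 step_bp: int = 50_000) -> pd.DataFrame:
    """Sliding windows with per-window gene and DE-gene counts.

    A gene belongs to a window when its gene-body midpoint lies in
    [start, end).  A chromosome shorter than the window yields a single
    truncated window, flagged.
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    de_set = set(de_gene_ids)
    mids = annotation.gene_midpoints()
    rows = []
    for chrom, length in annotation.chromosomes.items():
        gm = mids[mids["chrom"] == chrom].sort_values("midpoint")
        pos = gm["midpoint"].to_numpy()
        is_de = gm["gene_id"].isin(de_set).to_numpy()
        de_pos = pos[is_de]
        if length < window_bp:
            starts = np.array([0])
            ends = np.array([length])
            truncated = True
        else:
            starts = np.arange(0, length - window_bp + 1, step_bp)
            ends = starts + window_bp
            truncated = False
        n_genes = (np.searchsorted(pos, ends, side="left")
                   - np.searchsorted(pos, starts, side="left"))
        n_de = (np.searchsorted(de_pos, ends, side="left")
                - np.searchsorted(de_pos, starts, side="left"))
        for s, e, ng, nd in zip(starts, ends, n_genes, n_de):
            rows.append((chrom, int(s), int(e), int(ng), int(nd), truncated))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def window_overrep_test(windows: pd.DataFrame, genome_de_fraction: float,
                        alpha: float = 0.05) -> pd.DataFrame:
    """One-sided one-proportion Z-test for DE over-representation.

    z = (n_de/n_genes - pi0) / sqrt(pi0 (1-pi0) / n_genes) with pi0 the
    genome-wide DE fraction; upper-tail p; a window is over-represented
    when p < alpha.  Windows with no genes are untestable and flagged.
    """
    if not 0.0 < genome_de_fraction < 1.0:
        raise ValueError("genome_de_fraction must be in (0, 1)")
    out = windows.copy()
    n = out["n_genes"].to_numpy(dtype=float)
    x = out["n_de_genes"].to_numpy(dtype=float)
    testable = n >= 1
    se = np.sqrt(genome_de_fraction * (1 - genome_de_fraction)
                 / np.where(testable, n, np.nan))
    with np.errstate(invalid="ignore"):
        z = (x / n - genome_de_fraction) / se
    p = stats.norm.sf(z)
    out["testable"] = testable
    out["z"] = z
    out["p_value"] = p
    out["over_represented"] = testable & (p < alpha)
    return out


def merge_windows(windows: pd.DataFrame, step_bp: int = 50_000,
                  annotation: GenomeAnnotation | None = None,
                  de_gene_ids=()) -> pd.DataFrame:
    """Merge consecutive over-represented windows into ECR clusters.

    Windows are consecutive when they sit on the same chromosome one
    stride apart; the cluster interval is the union of member windows and
    member DE genes are those with midpoints inside the cluster (when an
    annotation is provided).
    """
    over = windows[windows["over_represented"]].sort_values(["chrom", "start"])
    rows = []
    cur: list[pd.Series] = []

    de_mids = None
    if annotation is not None:
        mids = annotation.gene_midpoints()
        de_mids = mids[mids["gene_id"].isin(set(de_gene_ids))]

    def flush():
        if not cur:
            return
        start = int(cur[0]["start"])
        end = int(cur[-1]["end"])
        chrom = cur[0]["chrom"]
        genes = []
        if de_mids is not None:
            sel = de_mids[(de_mids["chrom"] == chrom)
                          & (de_mids["midpoint"] >= start)
                          & (de_mids["midpoint"] < end)]
            genes = sorted(sel["gene_id"])
        rows.append({"chrom": chrom, "start": start, "end": end,
                     "n_windows": len(cur), "span_bp": end - start,
                     "n_de_genes": len(genes),
                     "de_genes": ",".join(genes)})

    prev = None
    for _, w in over.iterrows():
        if (prev is None or w["chrom"] != prev["chrom"]
                or w["start"] - prev["start"] != step_bp):
            flush()
            cur = []
        cur.append(w)
        prev = w
    flush()
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows",
                                       "span_bp", "n_de_genes", "de_genes"])


def _gap_distance(start_a, end_a, start_b, end_b) -> int:
    return max(0, max(start_a, start_b) - min(end_a, end_b))


def associate_dmrs(clusters: pd.DataFrame, dmrs: pd.DataFrame,
                   max_distance_bp: int = 2_000_000) -> pd.DataFrame:
    """Attach DMRs within ``max_distance_bp`` gap distance of each cluster.

    Many-to-many: a DMR can associate with several clusters and vice
    versa.  Adds associated_dmrs (comma-joined indices) and n_dmrs.
    """
    out = clusters.copy()
    assoc, counts = [], []
    for _, cl in out.iterrows():
        hits = []
        for di, d in dmrs.iterrows():
            if d["chrom"] != cl["chrom"]:
                continue
            gap = _gap_distance(int(cl["start"]), int(cl["end"]),
                                int(d["start"]), int(d["end"]))
            if gap <= max_distance_bp:
                hits.append(str(di))
        assoc.append(",".join(hits))
        counts.append(len(hits))
    out["associated_dmrs"] = assoc
    out["n_dmrs"] = counts
    return out


def correlate_dmr_expression(dmrs: pd.DataFrame, de_genes: pd.DataFrame,
                             annotation: GenomeAnnotation,
                             max_distance_bp: int = 2_000_000) -> dict:
    """Direct and distal DMR-expression pairings.

    Direct pair: the DMR's promoter gene is itself a selected DE gene.
    Distal pair: the DMR interval lies within ``max_distance_bp`` gap
    distance of a DE gene's body (direct pairs excluded).  DE genes
    missing from the annotation are excluded with a warning.
    """
    import warnings

    gb = annotation.gene_bodies.set_index("gene_id")
    de_ids = []
    for gid in de_genes["gene_id"]:
        if gid in gb.index:
            de_ids.append(gid)
        else:
            warnings.warn(f"DE gene {gid!r} missing from annotation; "
                          "excluded from correlation", stacklevel=2)
    direct_rows, distal_rows = [], []
    de_set = set(de_ids)
    for di, d in dmrs.iterrows():
        pg = d.get("gene_id")
        if pg in de_set:
            direct_rows.append({"dmr_index": di, "gene_id": pg})
        for gid in de_ids:
            body = gb.loc[gid]
            if body["chrom"] != d["chrom"]:
                continue
            gap = _gap_distance(int(d["start"]), int(d["end"]),
                                int(body["start"]), int(body["end"]))
            if gap <= max_distance_bp and not (pg == gid and pg in de_set):
                distal_rows.append({"dmr_index": di, "gene_id": gid,
                                    "gap_bp": gap})
    direct = pd.DataFrame(direct_rows, columns=["dmr_index", "gene_id"])
    distal = pd.DataFrame(distal_rows, columns=["dmr_index", "gene_id",
                                                "gap_bp"])
    return {
        "direct": direct,
        "distal": distal,
        "n_direct_pairs": len(direct),
        "n_distal_pairs": len(distal),
        "n_distal_dmrs": distal["dmr_index"].nunique(),
        "n_distal_genes": distal["gene_id"].nunique(),
        "n_direct_dmrs": direct["dmr_index"].nunique(),
        "n_direct_genes": direct["gene_id"].nunique(),
    }
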