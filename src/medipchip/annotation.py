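"""Genome annotation container for promoter tiling-array analysis.

Coordinates are 0-based half-open throughout.  A promoter spans
``[TSS - 3880, TSS + 970)`` on the + strand (strand-reflected on -),
the span scanned by the NimbleGen 3x720K promoter array design the
synthetic geometry emulates.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

UPSTREAM_SPAN = 3880
DOWNSTREAM_SPAN = 970
PROMOTER_SPAN = UPSTREAM_SPAN + DOWNSTREAM_SPAN

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "gc_fraction", "gene_id"]


@dataclasses.dataclass
class GenomeAnnotation:
    """Promoter-array genome annotation.

    Attributes
    ----------
    chromosomes : mapping of chromosome name -> length (bp)
    promoters : DataFrame with columns
        gene_id, chrom, tss, strand, start, end, cpg_class
    gene_bodies : DataFrame with columns gene_id, chrom, start, end
    cpg_positions : mapping of chromosome -> sorted int array of CpG positions
    probes : DataFrame with PROBE_COLUMNS, sorted by (chrom, start)
    """

    chromosomes: dict[str, int]
    promoters: pd.DataFrame
    gene_bodies: pd.DataFrame
    cpg_positions: dict[str, np.ndarray]
    probes: pd.DataFrame

    # ------------------------------------------------------------------ CpG
    def count_cpg(self, chrom: str, start: int, end: int) -> int:
        """Number of annotated CpG positions in [start, end)."""
        pos = self.cpg_positions.get(chrom)
        if pos is None or len(pos) == 0:
            return 0
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return int(hi - lo)

    def cpg_density(self, chrom: str, start: int, end: int) -> float:
        """CpG per 100 bp over [start, end)."""
        if end <= start:
            return 0.0
        return 100.0 * self.count_cpg(chrom, start, end) / (end - start)

    # ------------------------------------------------------------- promoters
    def promoter_for_interval(self, chrom: str, start: int, end: int):
        """Promoter gene overlapping [start, end); largest overlap wins,
        ties break to the lexicographically smaller gene id.

        Returns (gene_id or None, overlap_bp).
        """
        prom = self.promoters
        cand = prom[(prom["chrom"] == chrom)
                    & (prom["start"] < end) & (prom["end"] > start)]
        if cand.empty:
            return None, 0
        overlap = (np.minimum(cand["end"], end)
                   - np.maximum(cand["start"], start)).astype(int)
        best = overlap.max()
        winners = sorted(cand.loc[overlap == best, "gene_id"])
        return winners[0], int(best)

    def gene_midpoints(self) -> pd.DataFrame:
        gb = self.gene_bodies
        return pd.DataFrame({
            "gene_id": gb["gene_id"].to_numpy(),
            "chrom": gb["chrom"].to_numpy(),
            "midpoint": ((gb["start"] + gb["end"]) // 2).to_numpy(),
        })

    # --------------------------------------------------------------------- IO
    def write(self, outdir: str | Path) -> None:
        """Write BED (promoters, gene bodies) + TSV (probes, CpGs, sizes)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prom = self.promoters
        bed = pd.DataFrame({
            "chrom": prom["chrom"], "start": prom["start"], "end": prom["end"],
            "name": prom["gene_id"], "score": 0, "strand": prom["strand"],
        })
        bed.to_csv(outdir / "promoters.bed", sep="\t", header=False, index=False)
        gb = self.gene_bodies
        pd.DataFrame({
            "chrom": gb["chrom"], "start": gb["start"], "end": gb["end"],
            "name": gb["gene_id"], "score": 0, "strand": ".",
        }).to_csv(outdir / "gene_bodies.bed", sep="\t", header=False, index=False)
        self.probes.to_csv(outdir / "probes.tsv", sep="\t", index=False)
        rows = [(c, int(p)) for c, pos in sorted(self.cpg_positions.items())
                for p in pos]
        pd.DataFrame(rows, columns=["chrom", "position"]).to_csv(
            outdir / "cpg_positions.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(self.chromosomes.items()),
                     columns=["chrom", "length"]).to_csv(
            outdir / "chromosomes.tsv", sep="\t", index=False)
        # promoter metadata not expressible in BED6
        prom[["gene_id", "tss", "cpg_class"]].to_csv(
            outdir / "promoter_meta.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "GenomeAnnotation":
        indir = Path(indir)
        chroms = pd.read_csv(indir / "chromosomes.tsv", sep="\t")
        chromosomes = dict(zip(chroms["chrom"], chroms["length"].astype(int)))
        bed = pd.read_csv(indir / "promoters.bed", sep="\t", header=None,
                          names=["chrom", "start", "end", "name", "score", "strand"])
        meta = pd.read_csv(indir / "promoter_meta.tsv", sep="\t")
        promoters = pd.DataFrame({
            "gene_id": bed["name"], "chrom": bed["chrom"],
            "start": bed["start"], "end": bed["end"], "strand": bed["strand"],
        }).merge(meta, left_on="gene_id", right_on="gene_id")
        gbed = pd.read_csv(indir / "gene_bodies.bed", sep="\t", header=None,
                           names=["chrom", "start", "end", "name", "score", "strand"])
        gene_bodies = pd.DataFrame({
            "gene_id": gbed["name"], "chrom": gbed["chrom"],
            "start": gbed["start"], "end": gbed["end"],
        })
        probes = pd.read_csv(indir / "probes.tsv", sep="\t")
        cpg = pd.read_csv(indir / "cpg_positions.tsv", sep="\t")
        cpg_positions = {
            str(c): g["position"].to_numpy(dtype=np.int64)
            for c, g in cpg.groupby("chrom")
        }
        for c in chromosomes:
            cpg_positions.setdefault(c, np.empty(0, dtype=np.int64))
        return cls(chromosomes, promoters, gene_bodies, cpg_positions, probes)


def check_probe_order(probes: pd.DataFrame) -> bool:
    """True when probes are sorted by (chrom, start) with contiguous
    chromosome blocks."""
    chrom = probes["chrom"].to_numpy()
    start = probes["start"].to_numpy()
    seen: set[str] = set()
    prev_chrom = None
    prev_start = -1
    for c, s in zip(chrom, start):
        if c != prev_chrom:
            if c in seen:
                return False
            seen.add(c)
            prev_chrom, prev_start = c, s
        elif s < prev_start:
            return False
        else:
            prev_start = s
    return True
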