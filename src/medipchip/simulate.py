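"""Synthetic MeDIP-Chip study generator.

Generates the four inputs the analysis consumes — genome annotation,
two-channel comparative hybridizations, expression matrices, promoter
sequences — with planted ground truth (DMRs, DE genes, DE gene clusters,
motif occurrences) recorded in a :class:`SyntheticTruth` sidecar, so that
every downstream stage can be scored by parameter recovery.

The default geometry is a desk-scale reduction of the real platform
(NimbleGen 3x720K promoter array: 50-75 mer probes at ~100 bp median
spacing tiling promoters from 3,880 bp upstream to 970 bp downstream of
each TSS; three comparative two-channel hybridizations): 2 chromosomes x
10 Mb, 400 promoters, ~19,000 probes, 3 hybridization pairs.

All generators are pure functions of (parameters, seed).  Signals are
generated and stored on the log2 scale; the expression table stores
un-logged signals because the downstream mean-difference filter operates
on the un-logged scale.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import (DOWNSTREAM_SPAN, PROMOTER_SPAN, UPSTREAM_SPAN,
                         GenomeAnnotation)

#: CpG/100 bp class mix: mostly 1-2 CpG/100 bp with a thin high-density
#: tail, the "CpG desert" composition promoter DMRs sit in.
DEFAULT_CPG_MIX: dict[float, float] = {1: 0.35, 2: 0.35, 3: 0.15, 5: 0.10, 8: 0.05}

IUPAC_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


# --------------------------------------------------------------------- truth
@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic study.

    planted_dmrs : DataFrame(chrom, start, end, delta_m, sign, gene_id)
    planted_de_genes : DataFrame(gene_id, direction, multiplier)
    planted_cluster_intervals : DataFrame(chrom, start, end)
    planted_motif_sites : mapping sequence id -> list of forward offsets
    """

    planted_dmrs: pd.DataFrame
    planted_de_genes: pd.DataFrame
    planted_cluster_intervals: pd.DataFrame
    planted_motif_sites: dict[str, list[int]]
    seed: int

    @classmethod
    def empty(cls, seed: int = 0) -> "SyntheticTruth":
        return cls(
            planted_dmrs=pd.DataFrame(
                columns=["chrom", "start", "end", "delta_m", "sign", "gene_id"]),
            planted_de_genes=pd.DataFrame(
                columns=["gene_id", "direction", "multiplier"]),
            planted_cluster_intervals=pd.DataFrame(columns=["chrom", "start", "end"]),
            planted_motif_sites={},
            seed=seed,
        )

    def validate(self, annotation: GenomeAnnotation) -> None:
        dmrs = self.planted_dmrs.sort_values(["chrom", "start"])
        for _, grp in dmrs.groupby("chrom"):
            ends = grp["end"].to_numpy()
            starts = grp["start"].to_numpy()
            if len(grp) > 1 and (starts[1:] < ends[:-1]).any():
                raise ValueError("planted DMR intervals overlap")
        known = set(annotation.gene_bodies["gene_id"])
        missing = set(self.planted_de_genes["gene_id"]) - known
        if missing:
            raise ValueError(f"planted DE genes absent from annotation: {sorted(missing)[:5]}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": int(self.seed),
            "planted_dmrs": self.planted_dmrs.to_dict(orient="records"),
            "planted_de_genes": self.planted_de_genes.to_dict(orient="records"),
            "planted_cluster_intervals":
                self.planted_cluster_intervals.to_dict(orient="records"),
            "planted_motif_sites": {k: list(map(int, v))
                                    for k, v in self.planted_motif_sites.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        empty = cls.empty(d["seed"])
        return cls(
            planted_dmrs=pd.DataFrame(d["planted_dmrs"],
                                      columns=empty.planted_dmrs.columns),
            planted_de_genes=pd.DataFrame(d["planted_de_genes"],
                                          columns=empty.planted_de_genes.columns),
            planted_cluster_intervals=pd.DataFrame(
                d["planted_cluster_intervals"],
                columns=empty.planted_cluster_intervals.columns),
            planted_motif_sites={k: list(v)
                                 for k, v in d["planted_motif_sites"].items()},
            seed=d["seed"],
        )


# ------------------------------------------------------------------- genome
def generate_genome(n_chromosomes: int = 2,
                    chrom_length_bp: int = 10_000_000,
                    n_promoters: int = 400,
                    cpg_density_mix: Mapping[float, float] | None = None,
                    seed: int = 0,
                    probe_spacing_bp: int = 100,
                    probe_length_range: tuple[int, int] = (50, 75),
                    intergenic_cpg_per_100bp: float = 0.3) -> GenomeAnnotation:
    """Generate a promoter-array genome annotation.

    Promoters (span ``UPSTREAM_SPAN + DOWNSTREAM_SPAN`` = 4,850 bp) are
    placed non-overlapping, one per evenly sized slot with random jitter;
    each is tiled with 50-75 mer probes at ``probe_spacing_bp`` midpoint
    spacing and assigned a CpG/100 bp density class drawn from
    ``cpg_density_mix``.
    """
    if cpg_density_mix is None:
        cpg_density_mix = DEFAULT_CPG_MIX
    rng = np.random.default_rng(seed)
    classes = np.array(list(cpg_density_mix.keys()), dtype=float)
    weights = np.array(list(cpg_density_mix.values()), dtype=float)
    weights = weights / weights.sum()

    chromosomes = {f"chr{i + 1}": int(chrom_length_bp)
                   for i in range(n_chromosomes)}
    # round-robin split of promoters over chromosomes
    per_chrom = {c: 0 for c in chromosomes}
    for i in range(n_promoters):
        per_chrom[f"chr{i % n_chromosomes + 1}"] += 1

    prom_rows, gene_rows, probe_rows = [], [], []
    cpg_positions: dict[str, np.ndarray] = {}
    gene_idx = 0
    lo_len, hi_len = probe_length_range
    for chrom, length in chromosomes.items():
        k = per_chrom[chrom]
        chrom_cpgs: list[np.ndarray] = []
        if k > 0:
            slot = length // k
            if slot < PROMOTER_SPAN + 2:
                raise ValueError(
                    f"{k} promoters of span {PROMOTER_SPAN} bp do not fit in "
                    f"{chrom} ({length} bp)")
            for j in range(k):
                start = j * slot + int(rng.integers(0, slot - PROMOTER_SPAN + 1))
                end = start + PROMOTER_SPAN
                strand = "+" if rng.random() < 0.5 else "-"
                tss = start + (UPSTREAM_SPAN if strand == "+" else DOWNSTREAM_SPAN)
                gene_id = f"gene{gene_idx:05d}"
                gene_idx += 1
                cls_ = float(rng.choice(classes, p=weights))
                prom_rows.append((gene_id, chrom, tss, strand, start, end, cls_))
                # gene body: from TSS downstream along the strand
                glen = int(rng.integers(5_000, 50_000))
                if strand == "+":
                    gstart, gend = tss, min(tss + glen, length)
                else:
                    gstart, gend = max(tss - glen, 0), tss
                gene_rows.append((gene_id, chrom, gstart, gend))
                # promoter CpGs at the drawn density class
                n_cpg = int(round(cls_ * PROMOTER_SPAN / 100.0))
                if n_cpg > 0:
                    pos = rng.choice(np.arange(start, end - 1), size=n_cpg,
                                     replace=False)
                    chrom_cpgs.append(np.sort(pos))
                # probes tiling the promoter at ~probe_spacing_bp midpoints
                mids = np.arange(start + hi_len // 2 + 1,
                                 end - hi_len // 2, probe_spacing_bp)
                lens = rng.integers(lo_len, hi_len + 1, size=len(mids))
                for mid, plen in zip(mids, lens):
                    pstart = int(mid) - int(plen) // 2
                    pend = pstart + int(plen)
                    probe_rows.append((chrom, pstart, pend,
                                       0.0, gene_id, cls_))
        # sparse intergenic CpG background
        n_bg = int(length * intergenic_cpg_per_100bp / 100.0)
        if n_bg > 0:
            bg = np.sort(rng.integers(0, length - 1, size=n_bg))
            if k > 0:
                starts = np.array([r[4] for r in prom_rows if r[1] == chrom])
                ends = np.array([r[5] for r in prom_rows if r[1] == chrom])
                inside = np.zeros(len(bg), dtype=bool)
                idx = np.searchsorted(starts, bg, side="right") - 1
                ok = idx >= 0
                inside[ok] = bg[ok] < ends[idx[ok]]
                bg = bg[~inside]
            chrom_cpgs.append(bg)
        allpos = (np.unique(np.concatenate(chrom_cpgs))
                  if chrom_cpgs else np.empty(0, dtype=np.int64))
        cpg_positions[chrom] = allpos.astype(np.int64)

    promoters = pd.DataFrame(
        prom_rows,
        columns=["gene_id", "chrom", "tss", "strand", "start", "end", "cpg_class"])
    gene_bodies = pd.DataFrame(gene_rows,
                               columns=["gene_id", "chrom", "start", "end"])
    probes = pd.DataFrame(
        probe_rows,
        columns=["chrom", "start", "end", "gc_fraction", "gene_id", "cpg_class"])
    if len(probes):
        probes = probes.sort_values(["chrom", "start"], kind="stable",
                                    ignore_index=True)
        # GC fraction mildly tracks CpG density (drives GC-grouped loess)
        gc = rng.normal(0.45 + 0.015 * probes["cpg_class"].to_numpy(), 0.07)
        probes["gc_fraction"] = np.clip(gc, 0.2, 0.85)
        probes.insert(0, "probe_id",
                      [f"probe{i:06d}" for i in range(len(probes))])
    else:
        probes = pd.DataFrame(columns=["probe_id", "chrom", "start", "end",
                                       "gc_fraction", "gene_id", "cpg_class"])
    return GenomeAnnotation(chromosomes, promoters, gene_bodies,
                            cpg_positions, probes)


# -------------------------------------------------------------------- truth
def plant_truth(annotation: GenomeAnnotation,
                n_dmrs: int = 20,
                dmr_delta_m: float = 1.2,
                dmr_probe_range: tuple[int, int] = (6, 10),
                dmr_min_cpg_density: float = 1.2,
                de_background_fraction: float = 0.05,
                cluster_de_fraction: float = 0.5,
                n_clusters: int = 1,
                cluster_span_bp: int = 1_000_000,
                de_multiplier: float = 2.0,
                motif_fraction: float = 0.0,
                motif_length: int = 20,
                seed: int = 0) -> SyntheticTruth:
    """Plant DMRs, DE genes, DE-gene clusters and motif sites.

    DMRs occupy runs of 6-10 consecutive probes inside distinct promoters
    whose realized CpG density over the run interval passes
    ``dmr_min_cpg_density``.  The default sits a little above the
    downstream density filter (1 CpG/100 bp) so that planted regions are
    not censored by boundary jitter: a called region's interval is trimmed
    to its significant probes, and truth planted exactly on the filter
    boundary would fail the filter about half the time by measurement
    noise rather than by detection.  Cluster intervals receive DE genes
    at ``cluster_de_fraction`` (default 10x the 0.05 background).
    """
    rng = np.random.default_rng(seed)
    prom = annotation.promoters
    probes = annotation.probes

    # ---- clusters
    cluster_rows = []
    chrom_names = list(annotation.chromosomes)
    attempts = 0
    while len(cluster_rows) < n_clusters and attempts < 1000:
        attempts += 1
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        length = annotation.chromosomes[chrom]
        margin = min(1_000_000, max(0, (length - cluster_span_bp) // 4))
        if length < cluster_span_bp + 2 * margin:
            continue
        start = int(rng.integers(margin, length - cluster_span_bp - margin + 1))
        end = start + cluster_span_bp
        if any(c == chrom and s < end and start < e
               for c, s, e in cluster_rows):
            continue
        cluster_rows.append((chrom, start, end))
    clusters = pd.DataFrame(cluster_rows, columns=["chrom", "start", "end"])

    # ---- DE genes
    mids = annotation.gene_midpoints()
    in_cluster = np.zeros(len(mids), dtype=bool)
    for _, row in clusters.iterrows():
        in_cluster |= ((mids["chrom"] == row["chrom"])
                       & (mids["midpoint"] >= row["start"])
                       & (mids["midpoint"] < row["end"])).to_numpy()
    p_de = np.where(in_cluster, cluster_de_fraction, de_background_fraction)
    is_de = rng.random(len(mids)) < p_de
    de_rows = []
    for gid in mids.loc[is_de, "gene_id"]:
        direction = "up" if rng.random() < 0.5 else "down"
        de_rows.append((gid, direction, de_multiplier))
    de_genes = pd.DataFrame(de_rows, columns=["gene_id", "direction", "multiplier"])

    # ---- DMRs
    dmr_rows = []
    order = rng.permutation(prom.index.to_numpy()) if len(prom) else []
    lo_run, hi_run = dmr_probe_range
    for idx in order:
        if len(dmr_rows) >= n_dmrs:
            break
        row = prom.loc[idx]
        pp = probes[probes["gene_id"] == row["gene_id"]]
        if len(pp) < hi_run:
            continue
        run = int(rng.integers(lo_run, hi_run + 1))
        i0 = int(rng.integers(0, len(pp) - run + 1))
        seg = pp.iloc[i0:i0 + run]
        start, end = int(seg["start"].iloc[0]), int(seg["end"].iloc[-1])
        if annotation.cpg_density(row["chrom"], start, end) < dmr_min_cpg_density:
            continue
        sign = 1 if rng.random() < 0.5 else -1
        dmr_rows.append((row["chrom"], start, end, float(dmr_delta_m),
                         sign, row["gene_id"]))
    if len(dmr_rows) < n_dmrs:
        raise ValueError(
            f"could only plant {len(dmr_rows)} of {n_dmrs} requested DMRs "
            "meeting the CpG-density condition")
    dmrs = pd.DataFrame(
        dmr_rows, columns=["chrom", "start", "end", "delta_m", "sign", "gene_id"])

    # ---- motif sites
    motif_sites: dict[str, list[int]] = {}
    n_motif = int(round(motif_fraction * len(prom)))
    if n_motif > 0:
        chosen = rng.choice(prom["gene_id"].to_numpy(), size=n_motif,
                            replace=False)
        for gid in chosen:
            off = int(rng.integers(0, PROMOTER_SPAN - motif_length + 1))
            motif_sites[str(gid)] = [off]

    truth = SyntheticTruth(dmrs, de_genes, clusters, motif_sites, seed)
    truth.validate(annotation)
    return truth


# ----------------------------------------------------------- hybridizations
@dataclasses.dataclass
class HybridizationSet:
    """Per-probe two-channel log2 signals for n comparative hybridizations.

    ``signals`` is indexed by probe_id with columns ``cy3_<h>``/``cy5_<h>``
    for h in 1..n_pairs.  Experimental (treatment-lineage) samples carry
    the Cy3 label, controls Cy5, so M = Cy5 - Cy3 is control minus
    treatment on the log2 scale.
    """

    probes: pd.DataFrame
    signals: pd.DataFrame
    n_pairs: int
    treatment_channel: str = "cy3"

    def channel(self, channel: str, h: int) -> np.ndarray:
        return self.signals[f"{channel}_{h}"].to_numpy()

    def write(self, path: str | Path, header_extra: str = "") -> None:
        """Pair-table TSV: probe meta columns then cy3_h/cy5_h pairs."""
        df = self.probes[["probe_id", "chrom", "start", "end",
                          "gc_fraction"]].copy()
        df = df.rename(columns={"gc_fraction": "gc"})
        for h in range(1, self.n_pairs + 1):
            df[f"cy3_{h}"] = self.signals[f"cy3_{h}"].to_numpy()
            df[f"cy5_{h}"] = self.signals[f"cy5_{h}"].to_numpy()
        with open(path, "w") as fh:
            fh.write(f"# medipchip pair-table n_pairs={self.n_pairs} "
                     f"treatment_channel={self.treatment_channel}"
                     f"{' ' + header_extra if header_extra else ''}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read(cls, path: str | Path,
             probes: pd.DataFrame | None = None) -> "HybridizationSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        n_pairs = sum(1 for c in df.columns if c.startswith("cy3_"))
        meta = df[["probe_id", "chrom", "start", "end", "gc"]].rename(
            columns={"gc": "gc_fraction"})
        if probes is not None:
            meta = probes
        signals = df.set_index("probe_id")[
            [f"{ch}_{h}" for h in range(1, n_pairs + 1)
             for ch in ("cy3", "cy5")]]
        return cls(meta.reset_index(drop=True), signals, n_pairs)


def simulate_hybridizations(annotation: GenomeAnnotation,
                            truth: SyntheticTruth,
                            noise_sd: float = 0.3,
                            dye_bias_amplitude: float = 0.0,
                            n_pairs: int = 3,
                            seed: int = 0) -> HybridizationSet:
    """Simulate two-channel comparative hybridizations.

    Each probe carries a shared abundance term (its A baseline); the M
    dimension receives the planted DMR shift (consistent sign across
    hybridizations), a smooth low-order dye bias in A and GC of the
    requested amplitude, and independent Gaussian noise per probe per
    hybridization.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    probes = annotation.probes.reset_index(drop=True)
    n = len(probes)
    mid = ((probes["start"] + probes["end"]) // 2).to_numpy()

    # shared per-probe abundance: promoter-level + probe-level components
    genes = probes["gene_id"].to_numpy()
    uniq = pd.unique(genes)
    gene_eff = dict(zip(uniq, rng.normal(0.0, 0.3, size=len(uniq))))
    abundance = (10.5 + np.array([gene_eff[g] for g in genes])
                 + rng.normal(0.0, 0.3, size=n))

    true_m = np.zeros(n)
    for _, d in truth.planted_dmrs.iterrows():
        mask = ((probes["chrom"] == d["chrom"]).to_numpy()
                & (mid >= d["start"]) & (mid < d["end"]))
        if not mask.any():
            warnings.warn(
                f"planted DMR {d['chrom']}:{d['start']}-{d['end']} overlaps "
                "no probe and cannot be recovered", stacklevel=2)
            continue
        true_m[mask] = float(d["delta_m"]) * int(d["sign"])

    gc = probes["gc_fraction"].to_numpy()
    cols = {}
    for h in range(1, n_pairs + 1):
        a = abundance + rng.normal(0.0, 0.1, size=n)
        a_c = (a - a.mean()) / max(a.std(), 1e-12)
        # minimal smooth intensity-and-GC dye bias: an intensity trend whose
        # slope scales with GC plus an additive GC offset, so every GC group
        # needs its own normalization curve
        bias = dye_bias_amplitude * (
            0.3 * a_c * (0.5 + gc) + 0.8 * (gc - gc.mean()))
        m = true_m + bias + rng.normal(0.0, noise_sd, size=n)
        cols[f"cy5_{h}"] = a + m / 2.0
        cols[f"cy3_{h}"] = a - m / 2.0
    signals = pd.DataFrame(cols, index=probes["probe_id"].to_numpy())
    signals.index.name = "probe_id"
    signals = signals[[f"{ch}_{h}" for h in range(1, n_pairs + 1)
                       for ch in ("cy3", "cy5")]]
    return HybridizationSet(probes, signals, n_pairs)


# -------------------------------------------------------------- expression
def simulate_expression(annotation: GenomeAnnotation,
                        truth: SyntheticTruth,
                        n_per_group: int = 3,
                        batch_effect_sd: float = 0.25,
                        noise_sd: float = 0.2,
                        seed: int = 0
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an un-logged expression matrix (genes x samples).

    Samples come in replicate pairs (one control + one treated per
    batch), mirroring paired biological replicate pools; planted DE genes
    have treated/control group-mean ratio equal to their multiplier.

    Returns (signals, sample_sheet) where signals are positive un-logged
    values and the sample sheet has columns sample, treatment, batch.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 to test a treatment effect")
    rng = np.random.default_rng(seed)
    genes = annotation.gene_bodies["gene_id"].to_numpy()
    g = len(genes)

    samples = []
    for i in range(n_per_group):
        samples.append((f"control_{i + 1}", "control", f"batch{i + 1}"))
        samples.append((f"treated_{i + 1}", "treated", f"batch{i + 1}"))
    sheet = pd.DataFrame(samples, columns=["sample", "treatment", "batch"])

    base = rng.normal(7.0, 1.0, size=g)
    effect = np.zeros(g)
    de = truth.planted_de_genes.set_index("gene_id")
    for i, gid in enumerate(genes):
        if gid in de.index:
            mult = float(de.loc[gid, "multiplier"])
            effect[i] = (np.log2(mult) if de.loc[gid, "direction"] == "up"
                         else -np.log2(mult))
    batch_eff = rng.normal(0.0, batch_effect_sd, size=(g, n_per_group))

    log2sig = np.empty((g, len(sheet)))
    for j, (_, row) in enumerate(sheet.iterrows()):
        b = int(row["batch"][5:]) - 1
        mu = base + batch_eff[:, b]
        if row["treatment"] == "treated":
            mu = mu + effect
        log2sig[:, j] = mu + rng.normal(0.0, noise_sd, size=g)
    signals = pd.DataFrame(np.exp2(log2sig), index=genes,
                           columns=sheet["sample"].to_numpy())
    signals.index.name = "gene_id"
    return signals, sheet


# ---------------------------------------------------------------- sequences
def _concretize_iupac(consensus: str, rng: np.random.Generator) -> str:
    out = []
    for ch in consensus.upper():
        bases = IUPAC_BASES.get(ch)
        if bases is None:
            raise ValueError(f"non-IUPAC character {ch!r} in motif consensus")
        out.append(bases[int(rng.integers(len(bases)))])
    return "".join(out)


def simulate_promoter_sequences(annotation: GenomeAnnotation,
                                truth: SyntheticTruth,
                                motif_consensus: str,
                                background_rate: float = 0.0,
                                seed: int = 0) -> dict[str, str]:
    """Generate one sequence per promoter with planted motif occurrences.

    Background sequence is sampled avoiding spontaneous CpG dinucleotides,
    then the annotated CpG positions of the promoter are written in, so
    realized CpG density tracks the annotation.  The motif (concretized
    from its IUPAC consensus) is planted at the truth-specified offsets,
    plus with probability ``background_rate`` in each remaining sequence.
    """
    if not 0.0 <= background_rate <= 1.0:
        raise ValueError("background_rate must be in [0, 1]")
    prom = annotation.promoters
    if len(prom) == 0:
        return {}
    if len(motif_consensus) > PROMOTER_SPAN:
        raise ValueError("motif longer than the shortest promoter")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    for _, row in prom.iterrows():
        span = int(row["end"] - row["start"])
        raw = bases[rng.integers(0, 4, size=span)]
        # suppress spontaneous CG dinucleotides
        for i in range(1, span):
            if raw[i - 1] == "C" and raw[i] == "G":
                raw[i] = "ACT"[int(rng.integers(3))]
        cpg = annotation.cpg_positions[row["chrom"]]
        lo = np.searchsorted(cpg, row["start"], side="left")
        hi = np.searchsorted(cpg, row["end"] - 1, side="left")
        for pos in cpg[lo:hi]:
            off = int(pos - row["start"])
            raw[off] = "C"
            raw[off + 1] = "G"
        seq = raw
        gid = str(row["gene_id"])
        offsets = list(truth.planted_motif_sites.get(gid, []))
        if not offsets and background_rate > 0 and rng.random() < background_rate:
            offsets = [int(rng.integers(0, span - len(motif_consensus) + 1))]
        for off in offsets:
            inst = _concretize_iupac(motif_consensus, rng)
            seq[off:off + len(inst)] = list(inst)
        seqs[gid] = "".join(seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
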