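"""Pipeline orchestration: config, stage runners, run report, plots.

All randomness flows from one root seed through named substreams (one per
stage), so a whole run is a pure function of its config.  Every output
file carries a header naming the producing stage, the parameters and the
code version; re-running with the same config reproduces byte-identical
outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import GenomeAnnotation
from .features import (MotifModel, compare_incidence, cpg_density_histogram,
                       random_promoter_regions, scan_motif)
from .models import (DifferentialExpressionModel, DifferentialMethylationModel,
                     ECRModel)
from .simulate import (HybridizationSet, SyntheticTruth, generate_genome,
                       plant_truth, read_fasta, simulate_expression,
                       simulate_hybridizations, simulate_promoter_sequences,
                       write_fasta)

logger = logging.getLogger(__name__)

#: Placeholder demo motif — a synthetic 20-mer IUPAC consensus standing in
#: for a real environmentally-responsive methylation motif, whose sequence
#: is not distributed with this package.  Always configurable.
SYNTHETIC_DEMO_MOTIF = "TGCWGGRTCAMGTKCCAATY"


def rng_for(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    return int((seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31))


@dataclasses.dataclass
class RunConfig:
    """Structured run configuration; defaults equal the published values."""

    outdir: str = "medipchip_run"
    seed: int = 0
    # synthetic study geometry
    n_chromosomes: int = 2
    chrom_length_bp: int = 10_000_000
    n_promoters: int = 400
    n_pairs: int = 3
    noise_sd: float = 0.3
    dye_bias_amplitude: float = 1.0
    n_dmrs: int = 20
    dmr_delta_m_sds: float = 4.0          # planted effect in units of noise_sd
    de_background_fraction: float = 0.05
    cluster_de_fraction: float = 0.5
    n_clusters: int = 1
    cluster_span_bp: int = 1_000_000
    de_multiplier: float = 2.0
    n_per_group: int = 3
    batch_effect_sd: float = 0.25
    expression_noise_sd: float = 0.2
    motif_fraction: float = 0.1
    motif_consensus: str = SYNTHETIC_DEMO_MOTIF
    motif_background_rate: float = 0.15
    # normalization
    gc_groups: int = 10
    loess_span: float = 0.4
    window_bp: int = 600
    min_probes: int = 3
    pool_arrays: bool = False
    # DMR calling
    z_threshold: float = 1e-5
    gap_bp: int = 600
    min_mean_a: float = 9.5
    min_cpg_density: float = 1.0
    # DE selection
    p_max: float = 0.05
    fold_min: float = 1.2
    mean_diff_min: float = 10.0
    # ECR
    ecr_window_bp: int = 2_000_000
    ecr_step_bp: int = 50_000
    ecr_alpha: float = 0.05
    assoc_distance_bp: int = 2_000_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _header(stage: str, config: RunConfig, **params) -> str:
    ptxt = " ".join(f"{k}={v}" for k, v in params.items())
    return (f"# medipchip v{__version__} stage={stage} seed={config.seed}"
            + (f" {ptxt}" if ptxt else ""))


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, config: RunConfig,
               **params) -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, config, **params) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


# ------------------------------------------------------------------- stages
def stage_simulate(config: RunConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = generate_genome(config.n_chromosomes, config.chrom_length_bp,
                                 config.n_promoters,
                                 seed=rng_for(config.seed, "genome"))
    truth = plant_truth(
        annotation,
        n_dmrs=config.n_dmrs,
        dmr_delta_m=config.dmr_delta_m_sds * config.noise_sd,
        de_background_fraction=config.de_background_fraction,
        cluster_de_fraction=config.cluster_de_fraction,
        n_clusters=config.n_clusters,
        cluster_span_bp=config.cluster_span_bp,
        de_multiplier=config.de_multiplier,
        motif_fraction=config.motif_fraction,
        motif_length=len(config.motif_consensus),
        seed=rng_for(config.seed, "truth"),
    )
    hybs = simulate_hybridizations(annotation, truth,
                                   noise_sd=config.noise_sd,
                                   dye_bias_amplitude=config.dye_bias_amplitude,
                                   n_pairs=config.n_pairs,
                                   seed=rng_for(config.seed, "hybridizations"))
    signals, sheet = simulate_expression(
        annotation, truth, n_per_group=config.n_per_group,
        batch_effect_sd=config.batch_effect_sd,
        noise_sd=config.expression_noise_sd,
        seed=rng_for(config.seed, "expression"))
    seqs = simulate_promoter_sequences(
        annotation, truth, config.motif_consensus,
        background_rate=config.motif_background_rate,
        seed=rng_for(config.seed, "sequences"))

    annotation.write(out / "annotation")
    truth.to_json(out / "truth.json")
    truth.planted_dmrs[["chrom", "start", "end"]].assign(
        name=truth.planted_dmrs["gene_id"]).to_csv(
        out / "annotation" / "planted_dmrs.bed", sep="\t", header=False,
        index=False)
    hybs.write(out / "hybridizations.tsv",
               header_extra=f"medipchip v{__version__} stage=simulate")
    _write_tsv(signals.reset_index(), out / "expression.tsv", "simulate",
               config)
    _write_tsv(sheet, out / "samples.tsv", "simulate", config)
    write_fasta(seqs, out / "promoter_sequences.fasta")
    return {"annotation": annotation, "truth": truth, "hybridizations": hybs,
            "expression": signals, "samples": sheet, "sequences": seqs}


def stage_call_dmrs(config: RunConfig, annotation: GenomeAnnotation,
                    hybs: HybridizationSet):
    model = DifferentialMethylationModel(
        hybs, annotation, gc_groups=config.gc_groups,
        loess_span=config.loess_span, window_bp=config.window_bp,
        min_probes=config.min_probes, pool_arrays=config.pool_arrays,
        z_threshold=config.z_threshold, gap_bp=config.gap_bp,
        min_mean_a=config.min_mean_a, min_cpg_density=config.min_cpg_density)
    res = model.fit()
    out = Path(config.outdir)
    res.to_bed(out / "dmrs.bed")
    _write_tsv(res.regions, out / "dmrs.tsv", "call-dmrs", config,
               z_threshold=config.z_threshold, gap_bp=config.gap_bp,
               min_mean_a=config.min_mean_a,
               min_cpg_density=config.min_cpg_density)
    return res


def stage_de(config: RunConfig, signals: pd.DataFrame, sheet: pd.DataFrame):
    res = DifferentialExpressionModel(signals, sheet, p_max=config.p_max,
                                      fold_min=config.fold_min,
                                      mean_diff_min=config.mean_diff_min).fit()
    _write_tsv(res.table, Path(config.outdir) / "de_genes.tsv", "de", config,
               p_max=config.p_max, fold_min=config.fold_min,
               mean_diff_min=config.mean_diff_min)
    return res


def stage_ecr(config: RunConfig, annotation: GenomeAnnotation, de_results):
    res = ECRModel(annotation, de_results.selected["gene_id"],
                   window_bp=config.ecr_window_bp, step_bp=config.ecr_step_bp,
                   alpha=config.ecr_alpha).fit()
    out = Path(config.outdir)
    _write_tsv(res.windows, out / "ecr_windows.tsv", "ecr", config,
               window_bp=config.ecr_window_bp, step_bp=config.ecr_step_bp)
    return res


def stage_features(config: RunConfig, annotation: GenomeAnnotation,
                   dmr_results, sequences: dict[str, str]) -> dict:
    out = Path(config.outdir)
    hist = cpg_density_histogram(dmr_results.regions)
    _write_tsv(hist.rename_axis("cpg_density_bin").reset_index(),
               out / "cpg_density_histogram.tsv", "features", config)
    motif = MotifModel(consensus=config.motif_consensus)
    dmr_genes = [g for g in dmr_results.regions.get("gene_id", []) if g]
    dmr_seqs = {g: sequences[g] for g in dmr_genes if g in sequences}
    result = {"histogram": hist, "incidence": None}
    if dmr_seqs:
        rng_seed = rng_for(config.seed, "background-regions")
        rng = np.random.default_rng(rng_seed)
        bg_ids = rng.choice([g for g in sequences if g not in dmr_seqs],
                            size=min(len(sequences) - len(dmr_seqs),
                                     max(len(dmr_seqs), 20)),
                            replace=False)
        bg_seqs = {g: sequences[g] for g in bg_ids}
        hits_dmr = scan_motif(dmr_seqs, motif)
        hits_bg = scan_motif(bg_seqs, motif)
        cmp = compare_incidence(hits_dmr["hit"], hits_bg["hit"],
                                labels=("dmr", "background"))
        result["incidence"] = cmp
        _write_tsv(pd.DataFrame([dataclasses.asdict(cmp)]),
                   out / "motif_incidence.tsv", "features", config)
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Full run: simulate -> normalize+call DMRs -> features -> DE -> ECR ->
    correlations.  Returns the run report (per-stage counts + config echo)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = stage_simulate(config)
    dmr_res = stage_call_dmrs(config, sim["annotation"], sim["hybridizations"])
    feats = stage_features(config, sim["annotation"], dmr_res,
                           sim["sequences"])
    de_res = stage_de(config, sim["expression"], sim["samples"])
    ecr_res = stage_ecr(config, sim["annotation"], de_res)
    clusters = ecr_res.associate_dmrs(dmr_res.regions,
                                      max_distance_bp=config.assoc_distance_bp)
    _write_tsv(clusters, out / "ecr_clusters.tsv", "ecr", config)
    if not clusters.empty:
        pd.DataFrame({
            "chrom": clusters["chrom"], "start": clusters["start"],
            "end": clusters["end"],
            "name": [f"ECR{i + 1}" for i in range(len(clusters))],
        }).to_csv(out / "ecr_clusters.bed", sep="\t", header=False,
                  index=False)
    corr = ecr_res.correlate(dmr_res.regions, de_res.selected,
                             max_distance_bp=config.assoc_distance_bp)
    _write_tsv(corr["direct"], out / "direct_pairs.tsv", "correlate", config)
    _write_tsv(corr["distal"], out / "distal_pairs.tsv", "correlate", config)

    report = {
        "config": config.to_dict(),
        "version": __version__,
        "n_probes": len(sim["annotation"].probes),
        "n_valid_probes_after_smoothing": dmr_res.n_valid_probes,
        "pairwise_site_counts": {f"{i}-{j}": c for (i, j), c
                                 in dmr_res.pairwise_site_counts.items()},
        "n_probes_all_pairs": len(dmr_res.paired.retained),
        "n_regions_prefilter": len(dmr_res.prefilter_regions),
        "n_regions_removed": len(dmr_res.removed_regions),
        "n_dmrs": len(dmr_res.regions),
        "n_de_selected": len(de_res.selected),
        "n_de_up": len(de_res.up),
        "n_de_down": len(de_res.down),
        "n_windows_testable": int(ecr_res.windows["testable"].sum()),
        "n_windows_over_represented":
            int(ecr_res.windows["over_represented"].sum()),
        "n_clusters": len(clusters),
        "n_dmr_bearing_clusters": int((clusters["n_dmrs"] > 0).sum())
            if "n_dmrs" in clusters else 0,
        "n_direct_pairs": corr["n_direct_pairs"],
        "n_distal_pairs": corr["n_distal_pairs"],
        "n_distal_dmrs": corr["n_distal_dmrs"],
        "n_distal_genes": corr["n_distal_genes"],
    }
    if feats["incidence"] is not None:
        report["motif_incidence_dmr"] = feats["incidence"].incidence_a
        report["motif_incidence_background"] = feats["incidence"].incidence_b
        report["motif_incidence_p"] = feats["incidence"].p_value
    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                sort_keys=True))
    for stage_name, count_key in [("DMR calling", "n_dmrs"),
                                  ("DE selection", "n_de_selected"),
                                  ("ECR clusters", "n_clusters")]:
        logger.info("%s: %s", stage_name, report[count_key])
    report["_objects"] = {"annotation": sim["annotation"],
                          "truth": sim["truth"], "dmr": dmr_res,
                          "de": de_res, "ecr": ecr_res, "clusters": clusters}
    return report


# -------------------------------------------------------------------- plots
def plot_summaries(report: dict, outdir: str | Path | None = None) -> dict:
    """Chromosome track plot (DMRs, DE genes, ECR clusters) + CpG-density
    histogram.  Returns the plotted coordinates and written file paths so
    tests can assert on data, not pixels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    objs = report["_objects"]
    annotation: GenomeAnnotation = objs["annotation"]
    dmr_res = objs["dmr"]
    de_res = objs["de"]
    clusters = objs["clusters"]
    outdir = Path(outdir or report["config"]["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    chroms = list(annotation.chromosomes)
    fig, axes = plt.subplots(len(chroms), 1,
                             figsize=(10, 1.8 * max(len(chroms), 1)),
                             squeeze=False)
    coords: dict[str, dict] = {}
    mids = annotation.gene_midpoints()
    de_set = set(de_res.selected["gene_id"])
    for ax, chrom in zip(axes[:, 0], chroms):
        length = annotation.chromosomes[chrom]
        ax.set_xlim(0, length)
        ax.set_ylim(0, 3)
        ax.set_yticks([0.5, 1.5, 2.5],
                      labels=["clusters", "DE genes", "DMRs"])
        ax.set_title(chrom, fontsize=9)
        d = dmr_res.regions[dmr_res.regions["chrom"] == chrom]
        dmr_x = ((d["start"] + d["end"]) / 2).tolist()
        ax.plot(dmr_x, [2.5] * len(dmr_x), "v", color="crimson", ms=6)
        gm = mids[(mids["chrom"] == chrom) & mids["gene_id"].isin(de_set)]
        ax.plot(gm["midpoint"], [1.5] * len(gm), "|", color="navy", ms=10)
        spans = []
        cl = clusters[clusters["chrom"] == chrom] if not clusters.empty \
            else clusters
        if not cl.empty:
            for _, row in cl.iterrows():
                ax.axvspan(row["start"], row["end"], ymin=0.05, ymax=0.3,
                           color="seagreen", alpha=0.4)
                spans.append((int(row["start"]), int(row["end"])))
        coords[chrom] = {"dmr_midpoints": dmr_x,
                         "de_midpoints": gm["midpoint"].tolist(),
                         "cluster_spans": spans}
    fig.tight_layout()
    tracks_path = outdir / "tracks.png"
    fig.savefig(tracks_path, dpi=110)
    plt.close(fig)

    hist = cpg_density_histogram(dmr_res.regions)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(range(len(hist)), hist.to_numpy(), color="gray")
    ax.set_xticks(range(len(hist)), labels=hist.index, rotation=45,
                  fontsize=7)
    ax.set_xlabel("CpG density (CpG/100 bp)")
    ax.set_ylabel("number of DMRs")
    fig.tight_layout()
    hist_path = outdir / "cpg_density_histogram.png"
    fig.savefig(hist_path, dpi=110)
    plt.close(fig)
    return {"tracks": str(tracks_path), "histogram": str(hist_path),
            "coords": coords, "histogram_counts": hist}
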