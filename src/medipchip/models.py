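"""Model/Results front-ends for the three analyses.

Each model is built from data, exposes the stage parameters as keyword
arguments with defaults equal to the published pipeline values, and its
``fit()`` returns a Results object carrying estimates, diagnostics and a
``summary()`` table.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import dmr as dmr_mod
from . import ecr as ecr_mod
from . import expression as expr_mod
from . import normalization as norm_mod
from .annotation import GenomeAnnotation
from .simulate import HybridizationSet


def _fmt_table(title: str, rows: list[tuple[str, object]]) -> str:
    width = max(len(k) for k, _ in rows) + 2
    lines = [title, "=" * len(title)]
    lines += [f"{k:<{width}}{v}" for k, v in rows]
    return "\n".join(lines)


# ------------------------------------------------------------- methylation
class DifferentialMethylationModel:
    """Probe-level two-channel MeDIP-Chip model for DMR calling.

    Runs MA conversion -> GC-grouped within-array loess -> across-array
    A-quantile -> 600 bp windowed median smoothing -> empirical per-probe
    Z-scores (p < 1e-5) per hybridization -> all-pairs intersection ->
    600 b sign-consistent clustering -> intensity (mean A > 9.5) and CpG
    density (>= 1/100 bp) filters.

    By default smoothing is per-array (``pool_arrays=False``) so the
    per-hybridization Z-scores and the paired intersection are
    non-degenerate; pass ``pool_arrays=True`` for the pooled reading of
    the smoothing step.
    """

    def __init__(self, hybridizations: HybridizationSet,
                 annotation: GenomeAnnotation, *,
                 gc_groups: int = 10, loess_span: float = 0.4,
                 window_bp: int = 600, min_probes: int = 3,
                 pool_arrays: bool = False, z_threshold: float = 1e-5,
                 gap_bp: int = 600, min_mean_a: float = 9.5,
                 min_cpg_density: float = 1.0):
        self.hybridizations = hybridizations
        self.annotation = annotation
        self.params = dict(gc_groups=gc_groups, loess_span=loess_span,
                           window_bp=window_bp, min_probes=min_probes,
                           pool_arrays=pool_arrays, z_threshold=z_threshold,
                           gap_bp=gap_bp, min_mean_a=min_mean_a,
                           min_cpg_density=min_cpg_density)

    def fit(self) -> "DMRResults":
        p = self.params
        profiles = norm_mod.ma_from_hybridizations(self.hybridizations)
        profiles = [norm_mod.gc_group_loess(pr, n_groups=p["gc_groups"],
                                            span=p["loess_span"])
                    for pr in profiles]
        profiles = norm_mod.aquantile_across_arrays(profiles)
        profiles = norm_mod.window_median_smooth(
            profiles, window_bp=p["window_bp"], min_probes=p["min_probes"],
            pool_arrays=p["pool_arrays"])
        sig = [dmr_mod.probe_z_scores(pr, threshold=p["z_threshold"])
               for pr in profiles]
        paired = dmr_mod.paired_intersection(sig)

        base = profiles[0].data
        mmat = np.column_stack([pr.data["M"].to_numpy() for pr in profiles])
        amat = np.column_stack([pr.data["A"].to_numpy() for pr in profiles])
        pmat = np.column_stack([s["p"].to_numpy() for s in sig])
        retained = pd.DataFrame({
            "chrom": base["chrom"], "start": base["start"], "end": base["end"],
            "mean_m": np.nanmean(mmat, axis=1),
            "mean_a": np.nanmean(amat, axis=1),
            "p_value": np.nanmax(pmat, axis=1),
        }, index=base.index).loc[paired.retained]

        regions = dmr_mod.cluster_probes_to_regions(retained,
                                                    gap_bp=p["gap_bp"])
        regions = dmr_mod.annotate_regions(regions, self.annotation)
        kept, removed = dmr_mod.filter_regions(
            regions, min_mean_a=p["min_mean_a"],
            min_cpg_density=p["min_cpg_density"])
        n_valid = int(profiles[0].data["valid"].to_numpy().sum()) \
            if not p["pool_arrays"] else int(profiles[0].data["valid"].sum())
        return DMRResults(self, profiles, sig, paired, regions, kept,
                          removed, n_valid)


class DMRResults:
    """Fitted DMR-calling results.

    Attributes: ``regions`` (final filtered DMRs), ``prefilter_regions``,
    ``removed_regions``, ``pairwise_site_counts``, ``significance`` (per
    hybridization), ``profiles`` (smoothed), ``n_valid_probes``.
    """

    def __init__(self, model, profiles, significance, paired,
                 prefilter_regions, regions, removed_regions, n_valid):
        self.model = model
        self.profiles = profiles
        self.significance = significance
        self.paired = paired
        self.prefilter_regions = prefilter_regions
        self.regions = regions.reset_index(drop=True)
        self.removed_regions = removed_regions.reset_index(drop=True)
        self.n_valid_probes = n_valid

    @property
    def pairwise_site_counts(self) -> dict:
        return self.paired.pair_counts

    def to_bed(self, path) -> None:
        dmr_mod.regions_to_bed(self.regions).to_csv(
            path, sep="\t", header=False, index=False)

    def to_tsv(self, path) -> None:
        self.regions.to_csv(path, sep="\t", index=False,
                            float_format="%.6g")

    def summary(self) -> str:
        rows = [
            ("n probes", len(self.profiles[0].data)),
            ("n valid after smoothing", self.n_valid_probes),
            ("n hybridizations", len(self.profiles)),
        ]
        for (i, j), c in self.pairwise_site_counts.items():
            rows.append((f"pair ({i},{j}) sites", c))
        rows += [
            ("probes in all-pair intersection", len(self.paired.retained)),
            ("regions before filters", len(self.prefilter_regions)),
            ("regions removed by filters", len(self.removed_regions)),
            ("final DMRs", len(self.regions)),
            ("hyper / hypo", f"{int((self.regions['direction'] > 0).sum())}"
                             f" / {int((self.regions['direction'] < 0).sum())}"),
        ]
        return _fmt_table("Differential methylation (DMR calling)", rows)


# ------------------------------------------------------------- expression
class DifferentialExpressionModel:
    """Two-factor (treatment + batch) per-gene DE model with three gates."""

    def __init__(self, signals: pd.DataFrame, samples: pd.DataFrame, *,
                 p_max: float = 0.05, fold_min: float = 1.2,
                 mean_diff_min: float = 10.0):
        self.signals = signals
        self.samples = samples
        self.params = dict(p_max=p_max, fold_min=fold_min,
                           mean_diff_min=mean_diff_min)

    @classmethod
    def from_dataframe(cls, signals: pd.DataFrame, samples: pd.DataFrame,
                       **kwargs) -> "DifferentialExpressionModel":
        return cls(signals, samples, **kwargs)

    def fit(self) -> "DEResults":
        table = expr_mod.de_table(self.signals, self.samples, **self.params)
        return DEResults(self, table)


class DEResults:
    def __init__(self, model, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    @property
    def up(self) -> pd.DataFrame:
        sel = self.selected
        return sel[sel["direction"] == "up"]

    @property
    def down(self) -> pd.DataFrame:
        sel = self.selected
        return sel[sel["direction"] == "down"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        p = self.model.params
        return _fmt_table("Differential expression (three-gate selection)", [
            ("genes tested", len(self.table)),
            ("gates", f"p<{p['p_max']}, fold>{p['fold_min']}, "
                      f"un-logged mean diff>{p['mean_diff_min']}"),
            ("selected", len(self.selected)),
            ("up-regulated", len(self.up)),
            ("down-regulated", len(self.down)),
        ])


# -------------------------------------------------------------------- ECR
class ECRModel:
    """Sliding-window DE-gene cluster (ECR) model."""

    def __init__(self, annotation: GenomeAnnotation, de_gene_ids, *,
                 window_bp: int = 2_000_000, step_bp: int = 50_000,
                 alpha: float = 0.05, reference: str = "genome"):
        self.annotation = annotation
        self.de_gene_ids = list(de_gene_ids)
        self.params = dict(window_bp=window_bp, step_bp=step_bp, alpha=alpha,
                           reference=reference)

    def fit(self) -> "ECRResults":
        p = self.params
        windows = ecr_mod.make_windows(self.annotation, self.de_gene_ids,
                                       window_bp=p["window_bp"],
                                       step_bp=p["step_bp"])
        n_genes_total = len(self.annotation.gene_bodies)
        pi0 = len(set(self.de_gene_ids)) / n_genes_total
        if p["reference"] == "genome":
            windows = ecr_mod.window_overrep_test(windows, pi0,
                                                  alpha=p["alpha"])
        elif p["reference"] == "chromosome":
            parts = []
            mids = self.annotation.gene_midpoints()
            de_set = set(self.de_gene_ids)
            for chrom, grp in windows.groupby("chrom", sort=False):
                gm = mids[mids["chrom"] == chrom]
                frac = gm["gene_id"].isin(de_set).mean()
                frac = min(max(frac, 1e-9), 1 - 1e-9)
                parts.append(ecr_mod.window_overrep_test(grp, frac,
                                                         alpha=p["alpha"]))
            windows = pd.concat(parts, ignore_index=True)
        else:
            raise ValueError("reference must be 'genome' or 'chromosome'")
        clusters = ecr_mod.merge_windows(windows, step_bp=p["step_bp"],
                                         annotation=self.annotation,
                                         de_gene_ids=self.de_gene_ids)
        return ECRResults(self, windows, clusters, pi0)


class ECRResults:
    def __init__(self, model, windows, clusters, genome_de_fraction):
        self.model = model
        self.windows = windows
        self.clusters = clusters
        self.genome_de_fraction = genome_de_fraction

    def associate_dmrs(self, dmrs: pd.DataFrame,
                       max_distance_bp: int = 2_000_000) -> pd.DataFrame:
        self.clusters = ecr_mod.associate_dmrs(self.clusters, dmrs,
                                               max_distance_bp)
        return self.clusters

    def correlate(self, dmrs: pd.DataFrame, de_genes: pd.DataFrame,
                  max_distance_bp: int = 2_000_000) -> dict:
        return ecr_mod.correlate_dmr_expression(
            dmrs, de_genes, self.model.annotation, max_distance_bp)

    def summary(self) -> str:
        testable = self.windows[self.windows["testable"]]
        return _fmt_table("Epigenetic control regions (sliding window)", [
            ("windows tested", len(testable)),
            ("genome DE fraction", f"{self.genome_de_fraction:.4f}"),
            ("over-represented windows",
             int(self.windows["over_represented"].sum())),
            ("clusters", len(self.clusters)),
            ("cluster spans (Mb)",
             ", ".join(f"{s / 1e6:.2f}"
                       for s in self.clusters.get("span_bp", []))),
        ])
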