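"""Differential-expression selection.

Per gene, an additive two-factor fixed-effects linear model (treatment +
batch) is fitted on log2 signals and the treatment effect tested by an
F-test; with a single batch the model degrades to a one-way comparison.
A gene is selected iff it passes all three gates:

* treatment p-value < 0.05,
* fold change > 1.2 (the larger of the treated/control un-logged
  group-mean ratio and its reciprocal),
* absolute difference of the un-logged group means > 10.

The F-test is computed with closed-form projection algebra shared across
genes (the design is the same for every gene), which makes the per-gene
loop a handful of matrix products.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene_id", "p_value", "fold_change", "direction",
              "mean_difference", "selected"]


class ModelRankError(RuntimeError):
    """No residual degrees of freedom left for the per-gene model."""


def _design_matrices(samples: pd.DataFrame
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full and reduced (no-treatment) design matrices plus treated mask."""
    treatment = samples["treatment"].to_numpy()
    if set(treatment) != {"control", "treated"}:
        raise ValueError("treatment labels must be exactly "
                         "{'control','treated'}")
    treated = (treatment == "treated").astype(float)
    batches = pd.Categorical(samples["batch"])
    cols = [np.ones(len(samples))]
    # drop-first batch dummies; single batch degrades to one-way
    for lev in batches.categories[1:]:
        cols.append((batches == lev).astype(float))
    x_reduced = np.column_stack(cols)
    x_full = np.column_stack(cols + [treated])
    return x_full, x_reduced, treated.astype(bool)


def _residual_projector(x: np.ndarray) -> tuple[np.ndarray, int]:
    """M = I - X(X'X)^-X' and the rank of X."""
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    q = q[:, :rank]
    m = np.eye(x.shape[0]) - q @ q.T
    return m, rank


def de_table(signals: pd.DataFrame, samples: pd.DataFrame,
             p_max: float = 0.05, fold_min: float = 1.2,
             mean_diff_min: float = 10.0) -> pd.DataFrame:
    """Three-gate DE statistics for every gene.

    ``signals`` is an un-logged genes x samples matrix (positive); tests
    run on the log2 scale, the fold and mean-difference gates on the
    un-logged group means.
    """
    samples = samples.set_index("sample").loc[signals.columns].reset_index()
    x_full, x_reduced, treated = _design_matrices(samples)
    n = x_full.shape[0]
    m_full, rank_full = _residual_projector(x_full)
    m_red, rank_red = _residual_projector(x_reduced)
    df_num = rank_full - rank_red
    df_den = n - rank_full
    if df_den <= 0 or df_num <= 0:
        raise ModelRankError(
            f"no residual degrees of freedom (n={n}, rank={rank_full}); "
            "add replicate samples")

    vals = signals.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("un-logged signals must be positive")
    y = np.log2(vals)
    rss_full = np.einsum("gs,st,gt->g", y, m_full, y)
    rss_red = np.einsum("gs,st,gt->g", y, m_red, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    f = np.where(rss_full <= 0, np.inf, f)
    p = np.clip(stats.f.sf(f, df_num, df_den), 1e-300, 1.0)

    mean_t = vals[:, treated].mean(axis=1)
    mean_c = vals[:, ~treated].mean(axis=1)
    ratio = mean_t / mean_c
    fold = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(ratio > 1.0, "up", "down")
    mean_diff = np.abs(mean_t - mean_c)
    selected = (p < p_max) & (fold > fold_min) & (mean_diff > mean_diff_min)
    return pd.DataFrame({
        "gene_id": signals.index.to_numpy(),
        "p_value": p,
        "fold_change": fold,
        "direction": direction,
        "mean_difference": mean_diff,
        "selected": selected,
    }, columns=DE_COLUMNS)


def de_test(gene_id: str, values: pd.Series | np.ndarray,
            samples: pd.DataFrame, **gates) -> pd.Series:
    """Single-gene DE test; same machinery as :func:`de_table`."""
    sig = pd.DataFrame([np.asarray(values, dtype=float)],
                       index=[gene_id], columns=samples["sample"])
    try:
        return de_table(sig, samples, **gates).iloc[0]
    except ModelRankError as err:
        raise ModelRankError(f"gene {gene_id}: {err}") from err


def select_de_genes(signals: pd.DataFrame, samples: pd.DataFrame,
                    p_max: float = 0.05, fold_min: float = 1.2,
                    mean_diff_min: float = 10.0) -> pd.DataFrame:
    """DE table restricted to selected genes, with up/down partition logged."""
    table = de_table(signals, samples, p_max=p_max, fold_min=fold_min,
                     mean_diff_min=mean_diff_min)
    sel = table[table["selected"]]
    n_up = int((sel["direction"] == "up").sum())
    n_down = int((sel["direction"] == "down").sum())
    logger.info("selected %d DE genes (%d up, %d down) of %d tested",
                len(sel), n_up, n_down, len(table))
    return table
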