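"""Genomic-feature characterization of DMR sets.

CpG-density histograms, motif incidence in sequence sets (exact IUPAC or
PWM log-odds matching on both strands, replacing an external motif-scan
service with an explicit matcher), two-proportion incidence comparison
against a background set, and cross-set DMR interval overlap.
"""
from __future__ import annotations

import dataclasses
import re

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .annotation import GenomeAnnotation
from .simulate import IUPAC_BASES

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def cpg_density_histogram(regions: pd.DataFrame, bin_width: float = 1.0,
                          max_bin: float = 11.0) -> pd.Series:
    """Counts of regions per CpG-density bin [k, k+bin_width).

    Densities >= ``max_bin`` pool into a final open bin; the counts always
    sum to the number of input regions.
    """
    edges = np.arange(0.0, max_bin + bin_width / 2, bin_width)
    labels = [f"[{lo:g},{lo + bin_width:g})" for lo in edges[:-1]]
    labels.append(f"[{max_bin:g},inf)")
    if regions.empty:
        return pd.Series(0, index=labels, name="n_regions")
    d = regions["cpg_density"].to_numpy(dtype=float)
    counts, _ = np.histogram(d, bins=np.append(edges, np.inf))
    return pd.Series(counts, index=labels, name="n_regions")


# -------------------------------------------------------------------- motifs
@dataclasses.dataclass
class MotifModel:
    """IUPAC consensus (exact degenerate match) or PWM (log-odds >= threshold).

    PWM rows are positions, columns A/C/G/T probabilities summing to 1;
    scores are log2 odds against a uniform background.
    """

    consensus: str | None = None
    pwm: np.ndarray | None = None
    score_threshold: float | None = None

    def __post_init__(self):
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("provide exactly one of consensus or pwm")
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC_BASES)
            if bad:
                raise ValueError(f"non-IUPAC characters in consensus: {bad}")
            if len(self.consensus) < 4:
                raise ValueError("consensus must be at least 4 bp")
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ValueError("PWM must be L x 4 (A,C,G,T)")
            if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("PWM rows must each sum to 1")
            if self.score_threshold is None:
                raise ValueError("PWM matching requires score_threshold")

    def __len__(self) -> int:
        return (len(self.consensus) if self.consensus is not None
                else self.pwm.shape[0])

    @classmethod
    def from_pwm_file(cls, path, score_threshold: float) -> "MotifModel":
        """Minimal tab-delimited matrix: one row per position, 4 columns."""
        mat = pd.read_csv(path, sep="\t", header=None, comment="#").to_numpy()
        return cls(pwm=mat, score_threshold=score_threshold)

    # ---- matching primitives
    def _regex(self) -> re.Pattern:
        # N in the consensus matches anything including N; a sequence N never
        # matches a non-N consensus position.
        parts = []
        for ch in self.consensus.upper():
            bases = IUPAC_BASES[ch]
            parts.append("[" + bases + ("N" if ch == "N" else "") + "]")
        return re.compile("(?=(" + "".join(parts) + "))")

    def _forward_offsets(self, seq: str) -> list[int]:
        if self.consensus is not None:
            return [m.start() for m in self._regex().finditer(seq)]
        L = len(self)
        idx = np.full(len(seq), -1, dtype=np.int64)
        for i, b in enumerate("ACGT"):
            idx[np.frombuffer(seq.encode(), dtype=np.uint8)
                == ord(b)] = i
        logodds = np.log2(np.clip(self.pwm, 1e-9, None) / 0.25)
        hits = []
        for off in range(len(seq) - L + 1):
            window = idx[off:off + L]
            if (window < 0).any():
                continue  # N never matches
            score = logodds[np.arange(L), window].sum()
            if score >= self.score_threshold:
                hits.append(off)
        return hits


def scan_motif(sequences: dict[str, str], motif: MotifModel) -> pd.DataFrame:
    """Scan sequences on both strands for motif occurrences.

    Returns a per-sequence frame with a hit flag and forward-coordinate
    offsets (reverse-strand hits are mapped back to the forward system).
    """
    rows = []
    L = len(motif)
    for sid, seq in sequences.items():
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence {sid!r} has non-nucleotide "
                             f"characters: {sorted(bad)}")
        if L > len(seq):
            raise ValueError(f"motif ({L} bp) longer than sequence {sid!r}")
        fwd = motif._forward_offsets(seq)
        rc = seq.translate(_COMPLEMENT)[::-1]
        rev = [len(seq) - o - L for o in motif._forward_offsets(rc)]
        offsets = sorted(set(fwd) | set(rev))
        strands = ["+" if o in fwd else "-" for o in offsets]
        rows.append({"seq_id": sid, "hit": bool(offsets),
                     "n_hits": len(offsets), "offsets": offsets,
                     "strands": strands})
    return pd.DataFrame(rows, columns=["seq_id", "hit", "n_hits",
                                       "offsets", "strands"])


# --------------------------------------------------------------- incidence
@dataclasses.dataclass
class IncidenceComparison:
    label_a: str
    label_b: str
    n_a: int
    n_with_motif_a: int
    n_b: int
    n_with_motif_b: int
    p_value: float
    method: str

    @property
    def incidence_a(self) -> float:
        return self.n_with_motif_a / self.n_a

    @property
    def incidence_b(self) -> float:
        return self.n_with_motif_b / self.n_b


def compare_incidence(set_a_flags, set_b_flags,
                      labels: tuple[str, str] = ("a", "b")
                      ) -> IncidenceComparison:
    """Two-proportion comparison of motif incidence between sequence sets.

    Uses a two-sided two-proportion z-test, with a Fisher exact fallback
    whenever any expected cell count under the pooled proportion is < 5.
    """
    a = np.asarray(set_a_flags, dtype=bool)
    b = np.asarray(set_b_flags, dtype=bool)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both sequence sets must be non-empty")
    xa, xb = int(a.sum()), int(b.sum())
    na, nb = len(a), len(b)
    pooled = (xa + xb) / (na + nb)
    expected = np.array([na * pooled, na * (1 - pooled),
                         nb * pooled, nb * (1 - pooled)])
    if (expected < 5).any():
        _, p = stats.fisher_exact([[xa, na - xa], [xb, nb - xb]],
                                  alternative="two-sided")
        method = "fisher"
    else:
        _, p = proportions_ztest([xa, xb], [na, nb], alternative="two-sided")
        method = "ztest"
    return IncidenceComparison(labels[0], labels[1], na, xa, nb, xb,
                               float(p), method)


# ------------------------------------------------------------------ overlap
def overlap_dmr_sets(set_a: pd.DataFrame, set_b: pd.DataFrame,
                     min_overlap_bp: int = 1) -> pd.DataFrame:
    """All region pairs with interval overlap >= ``min_overlap_bp``.

    Both sets need chrom/start/end columns on the same coordinate
    convention; if the two sets share no chromosome name at all, a naming
    error is raised listing the unshared chromosomes.
    """
    if set_a.empty or set_b.empty:
        return pd.DataFrame(columns=["a_index", "b_index", "chrom",
                                     "overlap_bp"])
    chroms_a, chroms_b = set(set_a["chrom"]), set(set_b["chrom"])
    if not chroms_a & chroms_b:
        raise ValueError(
            "no shared chromosome names between sets; unshared: "
            f"{sorted(chroms_a ^ chroms_b)}")
    rows = []
    for c in sorted(chroms_a & chroms_b):
        aa = set_a[set_a["chrom"] == c]
        bb = set_b[set_b["chrom"] == c]
        for ia, ra in aa.iterrows():
            ov = (np.minimum(bb["end"], ra["end"])
                  - np.maximum(bb["start"], ra["start"]))
            hit = bb[ov >= min_overlap_bp]
            for ib, amount in zip(hit.index, ov[ov >= min_overlap_bp]):
                rows.append({"a_index": ia, "b_index": ib, "chrom": c,
                             "overlap_bp": int(amount)})
    return pd.DataFrame(rows, columns=["a_index", "b_index", "chrom",
                                       "overlap_bp"])


def random_promoter_regions(annotation: GenomeAnnotation,
                            lengths, seed: int = 0) -> pd.DataFrame:
    """Sample size-matched random regions from promoters (background set)."""
    rng = np.random.default_rng(seed)
    prom = annotation.promoters
    rows = []
    for L in lengths:
        row = prom.iloc[int(rng.integers(len(prom)))]
        span = int(row["end"] - row["start"])
        L = min(int(L), span)
        off = int(rng.integers(0, span - L + 1))
        rows.append({"chrom": row["chrom"], "start": int(row["start"]) + off,
                     "end": int(row["start"]) + off + L,
                     "gene_id": row["gene_id"]})
    return pd.DataFrame(rows)
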