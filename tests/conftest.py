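import numpy as np
import pandas as pd
import pytest

from medipchip import generate_genome
from medipchip.normalization import MAProfile


@pytest.fixture(scope="session")
def small_annotation():
    """1 chromosome x 2 Mb, 40 promoters (~1,900 probes)."""
    return generate_genome(1, 2_000_000, 40, seed=11)


@pytest.fixture(scope="session")
def medium_annotation():
    """2 chromosomes x 10 Mb, 400 promoters (~19,200 probes)."""
    return generate_genome(2, 10_000_000, 400, seed=3)


def make_profile(mids, m, a=None, stage="aquantile", chrom="chr1", hyb=1,
                 valid=None, probe_len=50, gc=None):
    """Hand-built MAProfile for unit tests (midpoint-centered probes)."""
    mids = np.asarray(mids)
    m = np.asarray(m, dtype=float)
    a = np.full(len(mids), 10.0) if a is None else np.asarray(a, dtype=float)
    valid = np.ones(len(mids), dtype=bool) if valid is None else np.asarray(valid)
    gc = np.full(len(mids), 0.5) if gc is None else np.asarray(gc, dtype=float)
    df = pd.DataFrame({
        "chrom": chrom,
        "start": mids - probe_len // 2,
        "end": mids + probe_len // 2,
        "gc_fraction": gc,
        "M": m, "A": a, "valid": valid,
    }, index=pd.Index([f"p{i:04d}" for i in range(len(mids))],
                      name="probe_id"))
    return MAProfile(df, stage, hyb=hyb)


def reciprocal_overlap_matches(called: pd.DataFrame, planted: pd.DataFrame,
                               frac: float = 0.5) -> int:
    """Number of planted intervals matched by a called region with
    reciprocal overlap >= frac (each called region used at most once)."""
    used = set()
    tp = 0
    for _, p in planted.iterrows():
        for i, c in called.iterrows():
            if i in used or c["chrom"] != p["chrom"]:
                continue
            ov = min(c["end"], p["end"]) - max(c["start"], p["start"])
            if (ov > 0 and ov >= frac * (p["end"] - p["start"])
                    and ov >= frac * (c["end"] - c["start"])):
                tp += 1
                used.add(i)
                break
    return tp
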