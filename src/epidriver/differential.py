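"""Differentially methylated fragment (DMF) calling.

For each fragment analysable in both samples of a comparison, the pooled
methylated/unmethylated read counts form a 2x2 table tested with a
two-sided Fisher's exact test.  P-values are Bonferroni-corrected over the
fragments tested in that comparison, and a fragment is a DMF when the
adjusted p-value falls below alpha *and* the absolute difference of the
pooled methylation fractions is at least ``delta_min`` (0.25 by default,
inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import DataError

#: relative tolerance when comparing hypergeometric probabilities, so that
#: floating-point ties on symmetric tables are counted as ties
FISHER_TIE_TOL = 1e-7


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(np.subtract(n, k) + 1)


def fisher_exact_two_sided(
    meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int
) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[ma, ua], [mb, ub]].

    The p-value sums the hypergeometric probabilities, over all tables
    with the observed margins, of every table whose probability does not
    exceed that of the observed table (up to a small relative tolerance
    for floating-point ties).
    """
    if min(meth_a, unmeth_a, meth_b, unmeth_b) < 0:
        raise DataError("negative count in 2x2 table")
    ra = meth_a + unmeth_a
    rb = meth_b + unmeth_b
    if ra == 0 or rb == 0:
        raise DataError("zero row margin in 2x2 table")
    c1 = meth_a + meth_b
    lo = max(0, c1 - rb)
    hi = min(c1, ra)
    support = np.arange(lo, hi + 1)
    logp = (
        _log_comb(ra, support)
        + _log_comb(rb, c1 - support)
        - _log_comb(ra + rb, c1)
    )
    pmf = np.exp(logp - logp.max())
    pmf /= pmf.sum()
    observed = pmf[meth_a - lo]
    p = float(pmf[pmf <= observed * (1.0 + FISHER_TIE_TOL)].sum())
    return min(p, 1.0)


def fisher_exact_many(
    meth_a: np.ndarray,
    unmeth_a: np.ndarray,
    meth_b: np.ndarray,
    unmeth_b: np.ndarray,
) -> np.ndarray:
    """Vectorised driver for fisher_exact_two_sided over aligned arrays."""
    meth_a = np.asarray(meth_a, dtype=np.int64)
    unmeth_a = np.asarray(unmeth_a, dtype=np.int64)
    meth_b = np.asarray(meth_b, dtype=np.int64)
    unmeth_b = np.asarray(unmeth_b, dtype=np.int64)
    out = np.empty(len(meth_a))
    for i in range(len(meth_a)):
        out[i] = fisher_exact_two_sided(
            int(meth_a[i]), int(unmeth_a[i]), int(meth_b[i]), int(unmeth_b[i])
        )
    return out


def bonferroni(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Bonferroni adjustment: min(1, p * m) for m tests."""
    if m < 1:
        raise DataError("number of tests m must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m) if np.ndim(p) else min(
        1.0, float(p) * m
    )


def call_dmfs(
    frag_table_a: pd.DataFrame,
    frag_table_b: pd.DataFrame,
    pair_id: str,
    comparison: str = "primary_vs_metastatic",
    alpha: float = 0.05,
    delta_min: float = 0.25,
) -> pd.DataFrame:
    """Test every fragment analysable in both samples of a comparison.

    Returns one row per tested fragment (not only significant ones) with
    columns: fragment_id, chrom, start, end, pair_id, comparison, level_a,
    level_b, delta, p, p_adj, direction, significant; ordered by
    (chrom, start).  Bonferroni m is the number of fragments tested in
    this comparison.
    """
    cols = ["fragment_id", "chrom", "start", "end", "pooled_meth", "pooled_unmeth", "level"]
    merged = frag_table_a[cols].merge(
        frag_table_b[cols],
        on=["fragment_id", "chrom", "start", "end"],
        suffixes=("_a", "_b"),
    )
    if merged.empty:
        raise DataError(
            f"no fragments analysable in both samples ({pair_id}, {comparison})"
        )
    m = len(merged)
    p = fisher_exact_many(
        merged["pooled_meth_a"].to_numpy(),
        merged["pooled_unmeth_a"].to_numpy(),
        merged["pooled_meth_b"].to_numpy(),
        merged["pooled_unmeth_b"].to_numpy(),
    )
    delta = (merged["level_b"] - merged["level_a"]).to_numpy()
    p_adj = np.minimum(1.0, p * m)
    out = pd.DataFrame(
        {
            "fragment_id": merged["fragment_id"],
            "chrom": merged["chrom"],
            "start": merged["start"],
            "end": merged["end"],
            "pair_id": pair_id,
            "comparison": comparison,
            "level_a": merged["level_a"],
            "level_b": merged["level_b"],
            "delta": delta,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(delta > 0, "hyper", "hypo"),
            "significant": (p_adj < alpha) & (np.abs(delta) >= delta_min),
        }
    )
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def summarize_direction(dmfs: pd.DataFrame) -> tuple[int, int]:
    """(n_hyper, n_hypo) among significant records."""
    sig = dmfs[dmfs["significant"].astype(bool)]
    n_hyper = int((sig["direction"] == "hyper").sum())
    return n_hyper, len(sig) - n_hyper
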