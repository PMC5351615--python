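"""Cross-platform and cohort validation statistics.

Covers per-CpG and per-amplicon Pearson concordance between two
measurement platforms, Bland-Altman limits of agreement, cohort validation
of DMFs against array-style beta values (probe matching within a window,
Mann-Whitney rank test, direction concordance), a Shapiro-Wilk normality
gate, and methylation-expression Spearman correlation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .regions import Fragment


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement between two platforms."""

    bias: float
    sd_bias: float
    limit_low: float
    limit_high: float
    n: int


def per_cpg_concordance(pairs: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson r (and two-tailed p) over matched per-CpG fractions.

    ``pairs`` needs columns frac1, frac2 with one row per matched CpG.
    """
    if len(pairs) < 3:
        raise DataError(f"need >= 3 matched CpGs, got {len(pairs)}")
    res = stats.pearsonr(pairs["frac1"], pairs["frac2"])
    return float(res.statistic), float(res.pvalue), len(pairs)


def per_amplicon_concordance(pairs: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson r over per-amplicon mean fractions.

    Averaging independent per-CpG noise within an amplicon shrinks the
    noise variance, so this r is expected to exceed the per-CpG r.
    Requires an amplicon_id column and >= 3 amplicons.
    """
    means = pairs.groupby("amplicon_id")[["frac1", "frac2"]].mean()
    if len(means) < 3:
        raise DataError(f"need >= 3 amplicons, got {len(means)}")
    res = stats.pearsonr(means["frac1"], means["frac2"])
    return float(res.statistic), float(res.pvalue), len(means)


def bland_altman(pairs: pd.DataFrame) -> AgreementResult:
    """Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 sd).

    Differences are platform2 - platform1; the SD uses n-1 denominators.
    """
    if len(pairs) < 2:
        raise DataError("Bland-Altman needs >= 2 paired observations")
    diff = (pairs["frac2"] - pairs["frac1"]).to_numpy(dtype=float)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementResult(
        bias=bias,
        sd_bias=sd,
        limit_low=bias - 1.96 * sd,
        limit_high=bias + 1.96 * sd,
        n=len(diff),
    )


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, otherwise the normal approximation with
    tie correction.  Returns (U of x, p, 'exact'|'asymptotic').
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided",
            method="exact" if method == "exact" else "asymptotic",
        )
    return float(res.statistic), float(min(res.pvalue, 1.0)), method


def shapiro_gate(values: Sequence[float], alpha: float = 0.05) -> tuple[bool, float]:
    """Shapiro-Wilk normality gate: (looks_normal, p).

    Annotates whether a t-test would have been defensible; the rank test
    is computed regardless downstream.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise DataError("Shapiro-Wilk needs >= 3 values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.shapiro(values).pvalue)
    return p >= alpha, p


def spearman_meth_expr(
    beta: Sequence[float], expression: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation between methylation and expression.

    For n <= 9 the p-value is exact, from full enumeration of rank
    permutations; beyond that the t approximation is used.
    """
    beta = np.asarray(beta, dtype=float)
    expression = np.asarray(expression, dtype=float)
    n = len(beta)
    if n != len(expression) or n < 4:
        raise DataError("need paired vectors with n >= 4")
    rho = float(stats.spearmanr(beta, expression).statistic)
    if n <= 9:
        rx = stats.rankdata(beta)
        ry = stats.rankdata(expression)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        norm = np.linalg.norm(rxc) * np.linalg.norm(ryc)
        perms = np.array(list(itertools.permutations(ryc)))
        rho_perm = perms @ rxc / norm
        obs = abs(rho)
        p = float(np.mean(np.abs(rho_perm) >= obs - 1e-12))
    else:
        p = float(stats.spearmanr(beta, expression).pvalue)
    return rho, p


def match_probes_to_dmfs(
    probes: pd.DataFrame,
    fragments: Sequence[Fragment],
    window: int = 500,
) -> pd.DataFrame:
    """Assign each probe to at most one DMF within ``window`` bases.

    A probe matches a fragment when its single-base coordinate lies inside
    the fragment or within ``window`` bases of either edge; a probe in
    range of several fragments goes to the nearest (midpoint distance).
    Returns probe rows with matched fragment_id and distance columns.
    """
    rows = []
    for _, pr in probes.iterrows():
        best = None
        best_key = None
        for frag in fragments:
            if frag.chrom != pr["chrom"]:
                continue
            d = frag.interval.distance_to(int(pr["pos"]))
            if d <= window:
                mid_d = abs(int(pr["pos"]) - frag.interval.midpoint)
                key = (mid_d, frag.id)
                if best_key is None or key < best_key:
                    best, best_key = frag, key
        if best is not None:
            rows.append(
                {
                    "probe_id": pr["probe_id"],
                    "chrom": pr["chrom"],
                    "pos": int(pr["pos"]),
                    "fragment_id": best.id,
                    "distance": best.interval.distance_to(int(pr["pos"])),
                }
            )
    return pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "fragment_id", "distance"]
    )


def cohort_validate(
    dmf_directions: pd.Series,
    fragments: Sequence[Fragment],
    probes: pd.DataFrame,
    betas: pd.DataFrame,
    groups: pd.DataFrame,
    window: int = 500,
) -> pd.DataFrame:
    """Validate shared DMFs in an array-style cohort.

    ``dmf_directions`` maps fragment_id -> RRBS consensus direction
    ('hyper'/'hypo').  Probes are matched to DMF fragments within
    ``window`` bases; every matched probe gets a Mann-Whitney test of
    metastatic vs primary betas and a direction-concordance flag (sign of
    the metastatic-minus-primary median difference equals the RRBS
    direction).  A Bonferroni column over matched probes is emitted for
    transparency but does not drive any flag.
    """
    frag_set = [f for f in fragments if f.id in set(dmf_directions.index)]
    matched = match_probes_to_dmfs(probes, frag_set, window=window)
    if matched.empty:
        warnings.warn("no probes matched any DMF within the window")
        return pd.DataFrame(
            columns=[
                "probe_id", "fragment_id", "distance", "median_primary",
                "median_metastatic", "U", "p", "method", "p_bonferroni",
                "direction_concordant",
            ]
        )
    grp = groups.set_index("sample_id")["group"]
    primary_ids = grp.index[grp == "primary"]
    met_ids = grp.index[grp == "metastatic"]
    rows = []
    for _, pr in matched.iterrows():
        beta = betas.loc[pr["probe_id"]]
        x = beta.loc[met_ids].to_numpy(dtype=float)
        y = beta.loc[primary_ids].to_numpy(dtype=float)
        u, p, method = mann_whitney_u(x, y)
        med_p = float(np.median(y))
        med_m = float(np.median(x))
        rrbs_dir = dmf_directions.loc[pr["fragment_id"]]
        observed_dir = "hyper" if med_m > med_p else "hypo"
        rows.append(
            {
                "probe_id": pr["probe_id"],
                "fragment_id": pr["fragment_id"],
                "distance": pr["distance"],
                "median_primary": med_p,
                "median_metastatic": med_m,
                "U": u,
                "p": p,
                "method": method,
                "direction_concordant": (med_m != med_p) and observed_dir == rrbs_dir,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    return out
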