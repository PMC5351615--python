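"""Per-CpG methylomes and fragment-level summaries.

A sample methylome is the per-CpG table of methylated/unmethylated read
counts for one library (or for combined replicate libraries).  Fragment
methylation applies the coverage gate — a fragment is analysable in a
sample only if at least ``min_cpgs`` of its CpGs carry ``cov_min`` or more
reads — and then pools reads over all covered CpGs of the fragment, so the
fragment level is the pooled-read fraction rather than a mean of per-CpG
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .errors import DataError
from .regions import FragmentCatalog, GeneModel


@dataclass
class SampleMethylome:
    """Per-CpG counts for one sample.

    ``counts`` columns: chrom, pos (0-based C offset), meth, unmeth; one
    row per CpG position.
    """

    sample_id: str
    role: str  # normal | primary | metastatic
    counts: pd.DataFrame
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("normal", "primary", "metastatic"):
            raise DataError(f"{self.sample_id}: unknown role {self.role!r}")
        dup = self.counts.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise DataError(f"{self.sample_id}: duplicate CpG positions")

    @property
    def coverage(self) -> pd.Series:
        return self.counts["meth"] + self.counts["unmeth"]

    def fractions(self, cov_min: int = 1) -> pd.DataFrame:
        """CpGs with coverage >= cov_min and their methylation fraction."""
        cov = self.coverage
        sub = self.counts[cov >= cov_min].copy()
        sub["fraction"] = sub["meth"] / (sub["meth"] + sub["unmeth"])
        return sub


def read_coverage_file(
    path: str | Path,
    sample_id: str,
    role: str,
    pair_id: str | None = None,
    percent_tol: float = 0.1,
) -> SampleMethylome:
    """Read a Bismark-style coverage file (1-based inclusive coordinates).

    Columns: chrom, start, end, percent methylation, count methylated,
    count unmethylated.  Rows whose percent column disagrees with the
    counts by more than ``percent_tol`` are rejected as corrupt; duplicate
    positions (e.g. from strand-split output) are merged by summing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "pct", "meth", "unmeth"],
            dtype={"chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataError(f"{path}: malformed coverage file: {exc}") from exc
    for col in ("start", "end", "meth", "unmeth"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise DataError(f"{path}: non-numeric {col} at line {bad[0] + 1}")
    if (df[["meth", "unmeth"]] < 0).any().any():
        line = int((df[["meth", "unmeth"]] < 0).any(axis=1).idxmax()) + 1
        raise DataError(f"{path}: negative count at line {line}")
    cov = df["meth"] + df["unmeth"]
    if (cov == 0).any():
        line = int((cov == 0).idxmax()) + 1
        raise DataError(f"{path}: zero-coverage row at line {line}")
    expected = 100.0 * df["meth"] / cov
    off = (df["pct"] - expected).abs() > percent_tol
    if off.any():
        line = int(off.idxmax()) + 1
        raise DataError(
            f"{path}: percent column disagrees with counts at line {line}"
        )
    counts = (
        df.assign(pos=df["start"] - 1)[["chrom", "pos", "meth", "unmeth"]]
        .groupby(["chrom", "pos"], as_index=False)
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SampleMethylome(sample_id=sample_id, role=role, pair_id=pair_id, counts=counts)


def merge_replicates(a: SampleMethylome, b: SampleMethylome) -> SampleMethylome:
    """Combine replicate libraries by summing counts per CpG position."""
    if (a.role, a.pair_id) != (b.role, b.pair_id):
        raise DataError(
            f"cannot merge replicates with different metadata: "
            f"{a.sample_id}({a.role}) vs {b.sample_id}({b.role})"
        )
    counts = (
        pd.concat([a.counts, b.counts], ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False)[["meth", "unmeth"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SampleMethylome(a.sample_id, a.role, counts, a.pair_id)


def replicate_correlation(
    a: SampleMethylome, b: SampleMethylome, cov_min: int = 10
) -> tuple[float, int]:
    """Pearson r of per-CpG fractions at positions covered >= cov_min in both."""
    fa = a.fractions(cov_min).set_index(["chrom", "pos"])["fraction"]
    fb = b.fractions(cov_min).set_index(["chrom", "pos"])["fraction"]
    common = fa.index.intersection(fb.index)
    if len(common) < 3:
        raise DataError(
            f"only {len(common)} common CpGs with coverage >= {cov_min}; need >= 3"
        )
    r = float(pearsonr(fa.loc[common], fb.loc[common]).statistic)
    return r, len(common)


def fragment_methylation(
    sample: SampleMethylome,
    catalog: FragmentCatalog,
    cov_min: int = 10,
    min_cpgs: int = 2,
) -> pd.DataFrame:
    """Fragment-level pooled methylation for one sample.

    A fragment enters the table iff at least ``min_cpgs`` of its CpGs have
    coverage >= ``cov_min``; its pooled counts then sum over every CpG of
    the fragment with any coverage, and its level is the pooled fraction.

    Returns columns: fragment_id, chrom, start, end, pooled_meth,
    pooled_unmeth, n_cpgs_covered, level; ordered by (chrom, start).
    """
    index = catalog.cpg_index()
    merged = index.merge(sample.counts, on=["chrom", "pos"], how="inner")
    if merged.empty:
        return pd.DataFrame(
            columns=[
                "fragment_id", "chrom", "start", "end",
                "pooled_meth", "pooled_unmeth", "n_cpgs_covered", "level",
            ]
        )
    merged["covered"] = (merged["meth"] + merged["unmeth"]) >= cov_min
    table = merged.groupby("fragment_id", sort=False).agg(
        pooled_meth=("meth", "sum"),
        pooled_unmeth=("unmeth", "sum"),
        n_cpgs_covered=("covered", "sum"),
    )
    table = table[table["n_cpgs_covered"] >= min_cpgs]
    table["n_cpgs_covered"] = table["n_cpgs_covered"].astype(int)
    table["level"] = table["pooled_meth"] / (
        table["pooled_meth"] + table["pooled_unmeth"]
    )
    coords = catalog.to_frame().set_index("fragment_id")[["chrom", "start", "end"]]
    table = table.join(coords).reset_index()
    table = table.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return table[
        [
            "fragment_id", "chrom", "start", "end",
            "pooled_meth", "pooled_unmeth", "n_cpgs_covered", "level",
        ]
    ]


def global_mean_methylation(sample: SampleMethylome, cov_min: int = 10) -> float:
    """Unweighted mean of per-CpG methylation fractions, in percent."""
    frac = sample.fractions(cov_min)["fraction"]
    if frac.empty:
        raise DataError(
            f"{sample.sample_id}: no CpGs with coverage >= {cov_min}"
        )
    return float(100.0 * frac.mean())


def methylation_histogram(
    fragment_table: pd.DataFrame, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of fragment methylation levels over [0, 1].

    Bins are half-open with the last bin closed (numpy convention), so the
    counts always sum to the number of analysable fragments.
    """
    if fragment_table.empty:
        raise DataError("no analysable fragments to histogram")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(fragment_table["level"].to_numpy(), bins=edges)
    return counts, edges


def cluster_samples(
    samples: Sequence[SampleMethylome], cov_min: int = 10
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering on 1 - Pearson r of common-CpG profiles.

    Only CpGs with coverage >= cov_min in *all* samples enter the profile.
    Samples are ordered by id before linkage so ties resolve
    deterministically.  Returns (scipy linkage matrix, sample ids).
    """
    if len(samples) < 2:
        raise DataError("clustering needs >= 2 samples")
    ordered = sorted(samples, key=lambda s: s.sample_id)
    fracs = []
    common: pd.Index | None = None
    for s in ordered:
        f = s.fractions(cov_min).set_index(["chrom", "pos"])["fraction"]
        fracs.append(f)
        common = f.index if common is None else common.intersection(f.index)
    if common is None or len(common) < 3:
        raise DataError("fewer than 3 CpGs covered in all samples")
    mat = np.vstack([f.loc[common].to_numpy() for f in fracs])
    flat = np.flatnonzero(mat.std(axis=1) == 0)
    if len(flat):
        raise DataError(
            f"constant methylation profile (no correlation defined): "
            f"{ordered[flat[0]].sample_id}"
        )
    r = np.corrcoef(mat)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # exact symmetry for squareform
    link = hierarchy.average(squareform(dist, checks=False))
    return link, [s.sample_id for s in ordered]


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        ll = max(node.dist - left.dist, 0.0)
        rl = max(node.dist - right.dist, 0.0)
        return f"({walk(left)}:{ll:.6g},{walk(right)}:{rl:.6g})"

    return walk(tree) + ";"


def element_distribution(
    sample: SampleMethylome,
    genes: Sequence[GeneModel],
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
    cov_min: int = 10,
) -> pd.DataFrame:
    """Mean methylation per genomic element class.

    Each CpG receives exactly one class with precedence
    promoter > gene body > intergenic; promoters are strand-aware windows
    around the TSS.  Returns columns: element, n_cpgs, mean_level.
    """
    prom_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    for g in genes:
        p = g.promoter(promoter_upstream, promoter_downstream)
        prom_trees.setdefault(g.chrom, IntervalTree()).addi(p.start, p.end)
        body_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)

    frac = sample.fractions(cov_min)
    if frac.empty:
        raise DataError(f"{sample.sample_id}: no CpGs pass coverage >= {cov_min}")

    def classify(chrom: str, pos: int) -> str:
        if chrom in prom_trees and prom_trees[chrom].overlaps(pos):
            return "promoter"
        if chrom in body_trees and body_trees[chrom].overlaps(pos):
            return "gene_body"
        return "intergenic"

    frac = frac.assign(
        element=[classify(c, p) for c, p in zip(frac["chrom"], frac["pos"])]
    )
    out = (
        frac.groupby("element")["fraction"]
        .agg(n_cpgs="count", mean_level="mean")
        .reindex(["promoter", "gene_body", "intergenic"])
        .dropna(how="all")
        .reset_index()
    )
    out["n_cpgs"] = out["n_cpgs"].astype(int)
    return out


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet (sample_id, role, pair_id, replicate_of, path)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "role", "pair_id", "replicate_of", "path"}
    missing = required - set(sheet.columns)
    if missing:
        raise DataError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def load_samples(sheet: pd.DataFrame, base_dir: str | Path | None = None) -> dict[str, SampleMethylome]:
    """Load every library in the sheet and combine replicate libraries."""
    base = Path(base_dir) if base_dir is not None else None
    loaded: dict[str, SampleMethylome] = {}
    order: list[str] = []
    for _, row in sheet.iterrows():
        target = row["replicate_of"] or row["sample_id"]
        path = Path(row["path"])
        if base is not None and not path.is_absolute():
            path = base / path
        m = read_coverage_file(
            path, target, row["role"], row["pair_id"] or None
        )
        if target in loaded:
            loaded[target] = merge_replicates(loaded[target], m)
        else:
            loaded[target] = m
            order.append(target)
    return {k: loaded[k] for k in order}
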