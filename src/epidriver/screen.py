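"""Epigenetic driver screen over per-pair DMF calls.

A candidate "epi-driver" is a fragment called differentially methylated in
every primary/metastatic pair with the same direction of change — a shared,
direction-consistent event is more plausibly causal than a passenger
private to one pair.  This module intersects per-pair DMF sets, partitions
the shared set by direction, classifies two-step (normal->primary->
metastatic) progression patterns, and annotates fragments against gene
models, CpG island/shore tracks and arbitrary user-supplied feature
tracks.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError
from .regions import Fragment, FragmentCatalog, GeneModel


def _significant_index(dmfs: pd.DataFrame) -> pd.DataFrame:
    return dmfs[dmfs["significant"]].set_index("fragment_id")


def intersect_dmfs(
    dmf_sets: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-pair intersection of significant DMFs.

    Returns (shared, pairwise):

    * ``shared`` — one row per fragment significant in every pair, with
      per-pair deltas/directions, ``direction_consistent`` and
      ``consensus_direction`` ('hyper'/'hypo'/'mixed').
    * ``pairwise`` — for every pair of pairs: overlap percentage
      ``100 * |A & B| / min(|A|, |B|)`` and the percentage of shared
      fragments changing in the same direction.
    """
    if len(dmf_sets) < 2:
        raise DataError("intersection needs >= 2 pair DMF sets")
    sig = {p: _significant_index(df) for p, df in sorted(dmf_sets.items())}
    pair_ids = list(sig)

    rows = []
    for a, b in combinations(pair_ids, 2):
        sa, sb = set(sig[a].index), set(sig[b].index)
        inter = sa & sb
        denom = min(len(sa), len(sb))
        overlap_pct = 100.0 * len(inter) / denom if denom else 0.0
        if inter:
            ids = sorted(inter)
            same = (
                sig[a].loc[ids, "direction"].to_numpy()
                == sig[b].loc[ids, "direction"].to_numpy()
            )
            consistency_pct = 100.0 * float(same.mean())
        else:
            consistency_pct = float("nan")
        rows.append((a, b, len(inter), overlap_pct, consistency_pct))
    pairwise = pd.DataFrame(
        rows,
        columns=["pair_a", "pair_b", "n_shared", "overlap_pct", "same_direction_pct"],
    )

    shared_ids = set(sig[pair_ids[0]].index)
    for p in pair_ids[1:]:
        shared_ids &= set(sig[p].index)
    shared_rows = []
    for fid in sorted(shared_ids):
        directions = [sig[p].loc[fid, "direction"] for p in pair_ids]
        consistent = len(set(directions)) == 1
        first = sig[pair_ids[0]].loc[fid]
        row = {
            "fragment_id": fid,
            "chrom": first["chrom"],
            "start": first["start"],
            "end": first["end"],
            "n_pairs_significant": len(pair_ids),
            "direction_consistent": consistent,
            "consensus_direction": directions[0] if consistent else "mixed",
        }
        for p in pair_ids:
            row[f"delta_{p}"] = sig[p].loc[fid, "delta"]
            row[f"direction_{p}"] = sig[p].loc[fid, "direction"]
        shared_rows.append(row)
    shared = pd.DataFrame(shared_rows)
    if not shared.empty:
        shared = shared.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )
    return shared, pairwise


def common_direction_dmfs(shared: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Split direction-consistent shared DMFs into hyper- and hypo-in-all sets."""
    if shared.empty:
        return set(), set()
    consistent = shared[shared["direction_consistent"]]
    hyper = set(consistent.loc[consistent["consensus_direction"] == "hyper", "fragment_id"])
    hypo = set(consistent.loc[consistent["consensus_direction"] == "hypo", "fragment_id"])
    return hyper, hypo


def classify_progression_pattern(
    dmfs_normal_primary: pd.DataFrame,
    dmfs_primary_metastatic: pd.DataFrame,
) -> pd.DataFrame:
    """Two-step methylation-change patterns for one pair.

    Fragments significant in both the normal->primary and the
    primary->metastatic comparison receive a pattern label
    '<step1>-<step2>' from the two directions (hyper-hyper, hyper-hypo,
    hypo-hyper, hypo-hypo); fragments significant in only one step are
    excluded.
    """
    s1 = _significant_index(dmfs_normal_primary)
    s2 = _significant_index(dmfs_primary_metastatic)
    both = sorted(set(s1.index) & set(s2.index))
    rows = []
    for fid in both:
        d1 = s1.loc[fid, "direction"]
        d2 = s2.loc[fid, "direction"]
        rows.append(
            {
                "fragment_id": fid,
                "chrom": s2.loc[fid, "chrom"],
                "start": s2.loc[fid, "start"],
                "end": s2.loc[fid, "end"],
                "pair_id": s2.loc[fid, "pair_id"],
                "step1_direction": d1,
                "step2_direction": d2,
                "pattern": f"{d1}-{d2}",
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "fragment_id", "chrom", "start", "end", "pair_id",
            "step1_direction", "step2_direction", "pattern",
        ],
    )
    if not out.empty:
        out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# annotation


def _tree_of(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals[["chrom", "start", "end"]].itertuples(index=False):
        trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


def _overlaps(trees: Mapping[str, IntervalTree], frag: Fragment) -> bool:
    t = trees.get(frag.chrom)
    return bool(t and t.overlap(frag.start, frag.end))


def annotate_dmfs(
    fragments: Sequence[Fragment],
    genes: Sequence[GeneModel],
    cgi_track: pd.DataFrame | None = None,
    shore_width: int = 2000,
    repeat_track: pd.DataFrame | None = None,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> pd.DataFrame:
    """Annotate fragments with gene, CpG-island and repeat context.

    Gene context follows the precedence promoter > exon > intron >
    intergenic using any-overlap of the fragment interval; the distance to
    the TSS is the signed, strand-aware offset of the fragment midpoint
    (negative = upstream of the TSS).  CGI context is 'island_core' when
    the fragment overlaps an island, 'shore' when within ``shore_width``
    bases of one without overlapping, else 'open_sea'.  Repeat context
    lists every overlapped repeat class (comma-joined), from the name
    column of the repeat track.
    """
    gene_list = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    prom_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    for g in gene_list:
        if g.start >= g.end:
            raise DataError(f"gene {g.gene_id}: empty/inverted extent")
        p = g.promoter(promoter_upstream, promoter_downstream)
        prom_trees.setdefault(g.chrom, IntervalTree()).addi(p.start, p.end, g)
        body_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
        for s, e in g.exons:
            exon_trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g)

    cgi_trees = _tree_of(cgi_track) if cgi_track is not None else {}
    shore_trees: dict[str, IntervalTree] = {}
    if cgi_track is not None:
        for chrom, start, end in cgi_track[["chrom", "start", "end"]].itertuples(index=False):
            shore_trees.setdefault(chrom, IntervalTree()).addi(
                max(0, int(start) - shore_width), int(end) + shore_width
            )
    repeat_trees: dict[str, IntervalTree] = {}
    if repeat_track is not None:
        for chrom, start, end, name in repeat_track[
            ["chrom", "start", "end", "name"]
        ].itertuples(index=False):
            repeat_trees.setdefault(chrom, IntervalTree()).addi(
                int(start), int(end), str(name)
            )

    def tss_distance(frag: Fragment, g: GeneModel) -> int:
        mid = frag.interval.midpoint
        return mid - g.tss if g.strand == "+" else g.tss - mid

    rows = []
    for frag in fragments:
        hits_prom = (
            sorted(prom_trees[frag.chrom].overlap(frag.start, frag.end),
                   key=lambda iv: iv.data.gene_id)
            if frag.chrom in prom_trees
            else []
        )
        hits_exon = (
            sorted(exon_trees[frag.chrom].overlap(frag.start, frag.end),
                   key=lambda iv: iv.data.gene_id)
            if frag.chrom in exon_trees
            else []
        )
        hits_body = (
            sorted(body_trees[frag.chrom].overlap(frag.start, frag.end),
                   key=lambda iv: iv.data.gene_id)
            if frag.chrom in body_trees
            else []
        )
        if hits_prom:
            context, gene = "promoter", hits_prom[0].data
        elif hits_exon:
            context, gene = "exon", hits_exon[0].data
        elif hits_body:
            context, gene = "intron", hits_body[0].data
        else:
            context, gene = "intergenic", None
        if gene is None:
            # nearest gene by TSS distance for intergenic fragments
            nearest, best = None, None
            for g in gene_list:
                if g.chrom != frag.chrom:
                    continue
                d = abs(tss_distance(frag, g))
                if best is None or d < best:
                    nearest, best = g, d
            gene = nearest

        if _overlaps(cgi_trees, frag):
            cgi = "island_core"
        elif _overlaps(shore_trees, frag):
            cgi = "shore"
        else:
            cgi = "open_sea"

        repeats: list[str] = []
        t = repeat_trees.get(frag.chrom)
        if t:
            repeats = sorted({iv.data for iv in t.overlap(frag.start, frag.end)})

        rows.append(
            {
                "fragment_id": frag.id,
                "chrom": frag.chrom,
                "start": frag.start,
                "end": frag.end,
                "gene_context": context,
                "nearest_gene": gene.gene_id if gene else "",
                "tss_distance": tss_distance(frag, gene) if gene else np.nan,
                "cgi_context": cgi,
                "repeat_classes": ",".join(repeats),
            }
        )
    return pd.DataFrame(rows)


def feature_overlap_fractions(
    fragments: Sequence[Fragment],
    tracks: Mapping[str, pd.DataFrame],
) -> pd.Series:
    """Fraction of fragments overlapping >= 1 interval of each named track."""
    if not fragments:
        raise DataError("empty fragment set")
    out = {}
    for name, track in tracks.items():
        trees = _tree_of(track)
        n_hit = sum(_overlaps(trees, f) for f in fragments)
        out[name] = n_hit / len(fragments)
    return pd.Series(out, name="overlap_fraction")


def associate_genes(
    annotation: pd.DataFrame,
    shared: pd.DataFrame | None = None,
    distance_cap: int = 50_000,
) -> pd.DataFrame:
    """Gene-level rollup of annotated DMFs.

    DMFs inside or near a gene (|TSS distance| <= ``distance_cap``) are
    grouped under it; intergenic DMFs beyond the cap are reported under
    the pseudo-gene ''.  When a shared table is given, each gene also
    gets the consensus direction of its DMFs ('mixed' on disagreement).
    """
    ann = annotation.copy()
    near = (ann["gene_context"] != "intergenic") | (
        ann["tss_distance"].abs() <= distance_cap
    )
    ann["assigned_gene"] = np.where(near & (ann["nearest_gene"] != ""), ann["nearest_gene"], "")
    directions = None
    if shared is not None and not shared.empty:
        directions = shared.set_index("fragment_id")["consensus_direction"]
    rows = []
    for gene, grp in ann.groupby("assigned_gene", sort=True):
        contexts = ",".join(sorted(grp["gene_context"].unique()))
        if directions is not None:
            ds = {directions.get(f, "") for f in grp["fragment_id"]} - {""}
            consensus = ds.pop() if len(ds) == 1 else ("mixed" if ds else "")
        else:
            consensus = ""
        rows.append(
            {
                "gene_id": gene,
                "n_dmfs": len(grp),
                "contexts": contexts,
                "consensus_direction": consensus,
                "fragment_ids": ",".join(sorted(grp["fragment_id"])),
            }
        )
    return pd.DataFrame(rows)
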