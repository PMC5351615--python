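"""Genomic interval primitives, fragment catalogs and annotation track I/O.

All coordinates are 0-based half-open internally.  Readers for 1-based
formats (Bismark coverage, GTF) convert on input; writers convert back.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance_to(self, pos: int) -> int:
        """0 if ``pos`` lies inside, else gap to the nearest contained base."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


@dataclass
class Fragment:
    """An in-silico MspI restriction fragment, the unit of analysis.

    ``cpg_positions`` holds the absolute offsets of the C of every CpG
    dinucleotide inside the fragment (forward strand).
    """

    id: str
    interval: GenomicInterval
    cpg_positions: list[int] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass
class FragmentCatalog:
    """Ordered, non-overlapping fragments for one genome."""

    fragments: list[Fragment]
    genome_id: str = "genome"
    size_min: int | None = None
    size_max: int | None = None

    def __post_init__(self) -> None:
        ids = [f.id for f in self.fragments]
        if len(set(ids)) != len(ids):
            raise ValueError("fragment ids must be unique")
        prev: Fragment | None = None
        for frag in self.fragments:
            if prev is not None and prev.chrom == frag.chrom:
                if frag.start < prev.end:
                    raise ValueError(
                        f"fragments overlap or are unsorted: {prev.id}, {frag.id}"
                    )
            prev = frag

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def by_id(self) -> dict[str, Fragment]:
        return {f.id: f for f in self.fragments}

    def cpg_index(self) -> pd.DataFrame:
        """Long table mapping every assigned CpG to its fragment.

        Columns: chrom, pos, fragment_id.
        """
        rows = [
            (f.chrom, p, f.id) for f in self.fragments for p in f.cpg_positions
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "fragment_id"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [f.chrom for f in self.fragments],
                "start": [f.start for f in self.fragments],
                "end": [f.end for f in self.fragments],
                "fragment_id": [f.id for f in self.fragments],
                "length": [f.length for f in self.fragments],
                "n_cpgs": [f.n_cpgs for f in self.fragments],
            }
        )


def write_catalog_bed(catalog: FragmentCatalog, path: str | Path) -> None:
    """Write the fragment catalog as BED6 (score column = fragment length)."""
    with open(path, "w") as fh:
        for f in catalog:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t{f.length}\t+\n")


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED6 track into a frame (chrom, start, end, name).

    Rows missing a name column get names derived from the file stem.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{i}: BED row needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise DataError(f"{path}:{i}: empty/inverted interval")
            name = parts[3] if len(parts) > 3 else f"{path.stem}_{i}"
            rows.append((chrom, start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


@dataclass
class GeneModel:
    """A gene with its exon structure, for element annotation."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """TSS base position (the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, upstream: int = 2000, downstream: int = 500) -> GenomicInterval:
        """Strand-aware promoter window around the TSS.

        ``upstream``/``downstream`` are in bases relative to transcription
        direction; defaults give TSS-2000..TSS+500.
        """
        if self.strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream
        else:
            lo, hi = self.tss - downstream + 1, self.tss + upstream + 1
        return GenomicInterval(self.chrom, max(0, lo), max(1, hi))


_GTF_ATTR = re.compile(r'gene_id "([^"]+)"')


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF file (gene extents + exon features)."""
    path = Path(path)
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise DataError(f"{path}:{i}: GTF row needs 9 columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            m = _GTF_ATTR.search(attrs)
            if m is None:
                raise DataError(f"{path}:{i}: missing gene_id attribute")
            gid = m.group(1)
            s, e = int(start) - 1, int(end)  # GTF is 1-based inclusive
            if s >= e:
                raise DataError(f"{path}:{i}: empty/inverted feature ({gid})")
            g = genes.get(gid)
            if g is None:
                g = genes[gid] = GeneModel(gid, chrom, s, e, strand)
            else:
                if g.chrom != chrom:
                    raise DataError(f"{path}:{i}: gene {gid} spans chromosomes")
                g.start = min(g.start, s)
                g.end = max(g.end, e)
            if feature == "exon":
                g.exons.append((s, e))
    for g in genes.values():
        g.exons.sort()
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def read_bed12_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (blocks become exons)."""
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise DataError(f"{path}:{i}: BED12 row needs 12 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(name, chrom, start, end, strand, exons))
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Dispatch on extension: .gtf/.gff -> GTF reader, .bed -> BED12."""
    suffix = Path(path).suffix.lower()
    if suffix in {".gtf", ".gff"}:
        return read_gtf_genes(path)
    if suffix == ".bed":
        return read_bed12_genes(path)
    raise DataError(f"unrecognised gene-model format: {path}")
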