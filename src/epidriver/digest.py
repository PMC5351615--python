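"""In-silico MspI digestion and CpG indexing.

MspI recognises CCGG and cuts between the first and second base (C^CGG).
On the forward strand a CCGG at offset ``i`` therefore induces a cut at
coordinate ``i + 1``, which keeps the CG of each recognition site attached
to the downstream fragment.  Fragments are the intervals between two
consecutive cuts on a chromosome; the chromosome-terminal pieces, which
have only one enzymatic end, are excluded from the catalog.

RRBS size selection happens at the library level; the analysis unit is the
40-220 bp cut-to-cut fragment, applied here as an inclusive size filter.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import DataError
from .regions import Fragment, FragmentCatalog, GenomicInterval

_CCGG = re.compile("CCGG")
_CG = re.compile("CG")
_VALID = re.compile(r"^[ACGTN]*$")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record, possibly wrapped) FASTA into upper-case strings."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise DataError(f"no sequences found in {path}")
    return genome


def _check_sequence(chrom: str, seq: str) -> str:
    seq = seq.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise DataError(f"sequence {chrom} contains invalid characters: {bad}")
    return seq


def digest_genome(genome: Mapping[str, str], genome_id: str = "genome") -> FragmentCatalog:
    """Digest sequences with MspI into an unfiltered fragment catalog.

    A chromosome without any CCGG site contributes zero fragments.  N bases
    never match the recognition site.
    """
    if not genome:
        raise DataError("empty sequence set")
    fragments: list[Fragment] = []
    for chrom in genome:
        seq = _check_sequence(chrom, genome[chrom])
        cuts = [m.start() + 1 for m in _CCGG.finditer(seq)]
        for i in range(len(cuts) - 1):
            start, end = cuts[i], cuts[i + 1]
            fragments.append(
                Fragment(
                    id=f"{chrom}:{start}-{end}",
                    interval=GenomicInterval(chrom, start, end),
                )
            )
    return FragmentCatalog(fragments, genome_id=genome_id)


def filter_fragments_by_size(
    catalog: FragmentCatalog, min_len: int = 40, max_len: int = 220
) -> FragmentCatalog:
    """Retain fragments with min_len <= length <= max_len (both inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [f for f in catalog if min_len <= f.length <= max_len]
    return FragmentCatalog(
        kept, genome_id=catalog.genome_id, size_min=min_len, size_max=max_len
    )


def locate_cpgs(genome: Mapping[str, str]) -> dict[str, list[int]]:
    """Per-chromosome ordered offsets of the C of every forward-strand CpG.

    Reads mapping to the G on the reverse strand are collapsed onto this C
    position at count-reading time.
    """
    out: dict[str, list[int]] = {}
    for chrom in genome:
        seq = _check_sequence(chrom, genome[chrom])
        out[chrom] = [m.start() for m in _CG.finditer(seq)]
    return out


def assign_cpgs_to_fragments(
    cpgs: Mapping[str, Iterable[int]], catalog: FragmentCatalog
) -> FragmentCatalog:
    """Populate each fragment's cpg_positions from the genome-wide CpG scan.

    Each CpG lands in the unique fragment whose half-open interval contains
    its C offset; CpGs outside every fragment stay unassigned.
    """
    by_chrom: dict[str, list[Fragment]] = {}
    for frag in catalog:
        frag.cpg_positions = []
        by_chrom.setdefault(frag.chrom, []).append(frag)

    for chrom, frags in by_chrom.items():
        positions = sorted(cpgs.get(chrom, []))
        fi = 0
        for pos in positions:
            while fi < len(frags) and frags[fi].end <= pos:
                fi += 1
            if fi < len(frags) and frags[fi].start <= pos < frags[fi].end:
                frags[fi].cpg_positions.append(pos)
    return catalog


def digest_and_index(
    genome: Mapping[str, str],
    min_len: int = 40,
    max_len: int = 220,
    genome_id: str = "genome",
) -> FragmentCatalog:
    """Convenience: digest, size-filter, and assign CpGs in one call."""
    catalog = filter_fragments_by_size(
        digest_genome(genome, genome_id=genome_id), min_len, max_len
    )
    return assign_cpgs_to_fragments(locate_cpgs(genome), catalog)
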