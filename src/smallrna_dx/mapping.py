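"""Exact short-tag genome mapping and mapping-rate summaries.

Tags are located in the genome by exact match (zero mismatches) on both
strands via a per-length substring hash index.  The summary separates the
two conventional mapping rates: the fraction of *unique* tag sequences with
at least one genomic hit, and the fraction of *total* reads (count-weighted
tags) mapped.  Per-chromosome sense/antisense tallies count every locus of
a multi-mapping tag, weighted by its read count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

from ._util import check_alphabet, normalize_seq, revcomp, round_half_up


@dataclass(frozen=True)
class GenomeHit:
    """One exact occurrence of a tag: 0-based half-open start, '+' = sense."""

    tag: str
    chromosome: str
    start: int
    strand: str  # '+' sense / '-' antisense


@dataclass
class MappingSummary:
    library_id: str
    unique_total: int
    unique_mapped: int
    reads_total: int
    reads_mapped: int
    per_chromosome: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    @property
    def pct_unique(self) -> float:
        return 100.0 * self.unique_mapped / self.unique_total if self.unique_total else 0.0

    @property
    def pct_reads(self) -> float:
        return 100.0 * self.reads_mapped / self.reads_total if self.reads_total else 0.0


def mapping_percentage(mapped: int, total: int) -> float:
    """100 x mapped/total, exact; report rendering rounds half-up to 1 dp."""
    if total < 0 or mapped < 0 or mapped > total:
        raise ValueError("need 0 <= mapped <= total")
    return 100.0 * mapped / total if total else 0.0


class GenomeIndex:
    """Per-length exact substring index over a genome, built lazily.

    For a query length L the index maps every L-mer of every chromosome to
    its sense positions; an antisense hit of a tag is a sense occurrence of
    its reverse complement.
    """

    def __init__(self, genome: Mapping[str, str]):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("genome is empty")
        self.genome = {name: normalize_seq(seq) for name, seq in genome.items()}
        self._by_length: Dict[int, Dict[str, List[Tuple[str, int]]]] = {}

    def _index_length(self, length: int) -> Dict[str, List[Tuple[str, int]]]:
        if length not in self._by_length:
            table: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
            for chrom in sorted(self.genome):
                seq = self.genome[chrom]
                for start in range(len(seq) - length + 1):
                    table[seq[start : start + length]].append((chrom, start))
            self._by_length[length] = dict(table)
        return self._by_length[length]


def build_index(genome: Mapping[str, str]) -> GenomeIndex:
    return GenomeIndex(genome)


def map_tag(tag: str, index: GenomeIndex) -> List[GenomeHit]:
    """All exact occurrences of ``tag`` on both strands, deterministically sorted."""
    seq = normalize_seq(tag)
    check_alphabet(seq, context=f"tag {tag!r}")
    table = index._index_length(len(seq))
    hits = [
        GenomeHit(tag=seq, chromosome=c, start=s, strand="+")
        for c, s in table.get(seq, [])
    ]
    rc = revcomp(seq)
    hits += [
        GenomeHit(tag=seq, chromosome=c, start=s, strand="-")
        for c, s in table.get(rc, [])
    ]
    # a palindromic tag (seq == revcomp) legitimately hits both strands at
    # every occurrence; the two comprehensions already produce both records
    return sorted(hits, key=lambda h: (h.chromosome, h.start, h.strand))


def map_library(library_tags: Mapping[str, int], index: GenomeIndex) -> Dict[str, List[GenomeHit]]:
    return {tag: map_tag(tag, index) for tag in library_tags}


def mapping_summary(
    library_id: str,
    tags: Mapping[str, int],
    hits_per_tag: Mapping[str, List[GenomeHit]],
    total_reads: int | None = None,
) -> MappingSummary:
    """Unique/total mapped fractions plus per-chromosome strand tallies.

    A multi-mapping tag counts once toward mapped status but contributes its
    read count at every locus in the per-chromosome table.
    """
    missing = set(tags) - set(hits_per_tag)
    if missing:
        raise ValueError(f"hits not computed for {len(missing)} tags")
    unique_total = len(tags)
    reads_total = total_reads if total_reads is not None else sum(tags.values())
    unique_mapped = 0
    reads_mapped = 0
    per_chrom: Dict[str, List[int]] = defaultdict(lambda: [0, 0])
    for tag, count in tags.items():
        hits = hits_per_tag[tag]
        if hits:
            unique_mapped += 1
            reads_mapped += count
        for hit in hits:
            per_chrom[hit.chromosome][0 if hit.strand == "+" else 1] += count
    return MappingSummary(
        library_id=library_id,
        unique_total=unique_total,
        unique_mapped=unique_mapped,
        reads_total=reads_total,
        reads_mapped=reads_mapped,
        per_chromosome={c: (v[0], v[1]) for c, v in sorted(per_chrom.items())},
    )


# ---------------------------------------------------------------------------
# I/O

def write_hits_tsv(
    hits_per_tag: Mapping[str, List[GenomeHit]],
    tags: Mapping[str, int],
    path: str | Path,
) -> None:
    """BED-like TSV: chrom, start (1-based incl.), end, tag, count, strand."""
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\ttag\tcount\tstrand\n")
        for tag in sorted(hits_per_tag):
            for h in hits_per_tag[tag]:
                fh.write(
                    f"{h.chromosome}\t{h.start + 1}\t{h.start + len(tag)}\t"
                    f"{tag}\t{tags.get(tag, 0)}\t{h.strand}\n"
                )


def summary_dict(summary: MappingSummary) -> dict:
    return {
        "library_id": summary.library_id,
        "unique_total": summary.unique_total,
        "unique_mapped": summary.unique_mapped,
        "reads_total": summary.reads_total,
        "reads_mapped": summary.reads_mapped,
        "pct_unique": round_half_up(summary.pct_unique, 1),
        "pct_reads": round_half_up(summary.pct_reads, 1),
        "per_chromosome": {
            c: {"sense": s, "antisense": a}
            for c, (s, a) in summary.per_chromosome.items()
        },
    }


def read_fasta(path: str | Path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
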