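"""Raw-read cleaning and tag collapsing.

Mirrors the standard small-RNA data-cleansing flow: quality filtering on
mean Phred score and N content, 3' adaptor trimming to recover the insert,
removal of 5' adaptor-ligation contaminants, and collapsing of identical
tags into a (sequence, count) library with its total clean-read count N —
the denominator of all later per-million normalization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from ._util import normalize_seq

Read = Tuple[str, str, str]  # (id, sequence, Phred+33 quality string)

#: default mean-Phred threshold for keeping a read
DEFAULT_MIN_MEAN_QUALITY = 20.0
#: default maximum tolerated fraction of N calls
DEFAULT_MAX_N_FRACTION = 0.10
#: default insert-length window (typical mature miRNA range)
DEFAULT_MIN_INSERT = 18
DEFAULT_MAX_INSERT = 30
#: adaptor match seed length (exact match, leftmost occurrence)
ADAPTOR_SEED_LENGTH = 8


@dataclass
class TagLibrary:
    """Collapsed clean tags of one library.

    ``total_clean`` is the library's N — the read-count denominator used by
    per-million normalization and the Audic-Claverie statistic.
    """

    library_id: str
    tags: Dict[str, int] = field(default_factory=dict)
    total_clean: int = 0

    @property
    def length_histogram(self) -> Dict[int, int]:
        hist: Counter[int] = Counter()
        for seq, count in self.tags.items():
            hist[len(seq)] += count
        return dict(sorted(hist.items()))

    @property
    def n_unique(self) -> int:
        return len(self.tags)

    def validate(self) -> None:
        if self.total_clean != sum(self.tags.values()):
            raise ValueError("total_clean does not equal the sum of tag counts")


@dataclass
class CleaningReport:
    """Read-conservation accounting: input = retained + Σ removed-by-reason."""

    library_id: str
    n_input: int = 0
    removed: Dict[str, int] = field(default_factory=dict)
    n_clean: int = 0

    def check_conservation(self) -> None:
        if self.n_input != self.n_clean + sum(self.removed.values()):
            raise ValueError(
                f"{self.library_id}: reads in ({self.n_input}) != clean "
                f"({self.n_clean}) + removed ({sum(self.removed.values())})"
            )


def mean_phred(quality: str) -> float:
    return sum(ord(c) - 33 for c in quality) / len(quality)


def filter_low_quality(
    reads: Iterable[Read],
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
    removed_counter: Optional[Dict[str, int]] = None,
) -> Iterator[Read]:
    """Yield reads with mean Phred >= threshold and N fraction <= maximum.

    Raises ValueError naming the record index for malformed records
    (empty sequence or quality length mismatch).
    """
    for idx, (rid, seq, qual) in enumerate(reads):
        if not seq or len(qual) != len(seq):
            raise ValueError(
                f"malformed read record at index {idx} (id={rid!r}): "
                "quality/sequence length mismatch or empty sequence"
            )
        n_frac = seq.upper().count("N") / len(seq)
        if mean_phred(qual) < min_mean_quality or n_frac > max_n_fraction:
            if removed_counter is not None:
                removed_counter["low_quality"] = removed_counter.get("low_quality", 0) + 1
            continue
        yield rid, seq, qual


def trim_adaptor_3p(
    sequence: str,
    adaptor_3p: str,
    min_insert: int = DEFAULT_MIN_INSERT,
    max_insert: int = DEFAULT_MAX_INSERT,
    seed_length: int = ADAPTOR_SEED_LENGTH,
) -> Tuple[Optional[str], Optional[str]]:
    """Cut the insert preceding the leftmost exact 3' adaptor seed match.

    Returns ``(tag, None)`` on success or ``(None, reason)`` with reason one
    of ``no-adaptor``, ``too-short``, ``too-long``.
    """
    if len(adaptor_3p) < seed_length:
        raise ValueError(
            f"adaptor ({len(adaptor_3p)} nt) shorter than match seed ({seed_length} nt)"
        )
    pos = sequence.upper().find(adaptor_3p[:seed_length].upper())
    if pos < 0:
        return None, "no-adaptor"
    if pos < min_insert:
        return None, "too-short"
    if pos > max_insert:
        return None, "too-long"
    return sequence[:pos], None


def remove_5p_contaminants(
    tags: Iterable[str],
    adaptor_5p: Optional[str],
    seed_length: int = ADAPTOR_SEED_LENGTH,
    removed_counter: Optional[Dict[str, int]] = None,
) -> Iterator[str]:
    """Drop tags beginning with the 5' adaptor seed (ligation artifacts)."""
    prefix = adaptor_5p[:seed_length].upper() if adaptor_5p else None
    for tag in tags:
        if prefix and tag.upper().startswith(prefix):
            if removed_counter is not None:
                removed_counter["5p_contaminant"] = removed_counter.get("5p_contaminant", 0) + 1
            continue
        yield tag


def collapse_unique(tags: Iterable[str], library_id: str) -> TagLibrary:
    """De-duplicate exact tag sequences into a TagLibrary (counts summed).

    Sequences are normalized to uppercase DNA (U -> T) so the identity is
    alphabet-independent.  Collapsing an already-collapsed stream of unique
    sequences is the identity.
    """
    counts: Counter[str] = Counter()
    total = 0
    for tag in tags:
        counts[normalize_seq(tag)] += 1
        total += 1
    lib = TagLibrary(library_id=library_id, tags=dict(counts), total_clean=total)
    lib.validate()
    return lib


def clean_reads(
    reads: Iterable[Read],
    library_id: str,
    adaptor_3p: str,
    adaptor_5p: Optional[str] = None,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
    min_insert: int = DEFAULT_MIN_INSERT,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> Tuple[TagLibrary, CleaningReport]:
    """Full cleaning flow: quality filter -> 3' trim -> 5' removal -> collapse."""
    report = CleaningReport(library_id=library_id)
    reads = list(reads)
    report.n_input = len(reads)
    kept = filter_low_quality(
        reads, min_mean_quality, max_n_fraction, removed_counter=report.removed
    )
    tags: List[str] = []
    for _rid, seq, _qual in kept:
        tag, reason = trim_adaptor_3p(seq, adaptor_3p, min_insert, max_insert)
        if tag is None:
            report.removed[reason] = report.removed.get(reason, 0) + 1
        else:
            tags.append(tag)
    tags = list(remove_5p_contaminants(tags, adaptor_5p, removed_counter=report.removed))
    library = collapse_unique(tags, library_id)
    report.n_clean = library.total_clean
    report.check_conservation()
    return library, report


# ---------------------------------------------------------------------------
# I/O

def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream (id, sequence, quality) from a Sanger/Phred+33 FASTQ file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq), qual


def write_tags_tsv(library: TagLibrary, path: str | Path) -> None:
    """Collapsed tags as ``sequence<TAB>count``, most abundant first."""
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for seq, count in sorted(library.tags.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{seq}\t{count}\n")


def read_tags_tsv(path: str | Path, library_id: str) -> TagLibrary:
    tags: Dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError(f"{path}: expected 'sequence\\tcount' header")
        for line in fh:
            seq, count = line.rstrip("\n").split("\t")
            tags[normalize_seq(seq)] = tags.get(normalize_seq(seq), 0) + int(count)
    lib = TagLibrary(library_id=library_id, tags=tags, total_clean=sum(tags.values()))
    lib.validate()
    return lib


def cleaning_report_dict(report: CleaningReport, library: TagLibrary) -> dict:
    return {
        "library_id": report.library_id,
        "n_input": report.n_input,
        "removed_by_reason": dict(sorted(report.removed.items())),
        "n_clean": report.n_clean,
        "n_unique": library.n_unique,
        "length_histogram": {str(k): v for k, v in library.length_histogram.items()},
    }
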