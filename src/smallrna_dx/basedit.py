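"""Seed-region base-edit detection and MN/NC edit-ratio classification.

Mature-miRNA positions 2-8 (1-based) form the seed region, the main
determinant of target recognition.  A candidate base edit is an unannotated
tag that matches a mature sequence of the same length at every position
except exactly one, with that single mismatch inside the seed.  Per miRNA
and group, the edit percentage is 100 * edited/(edited + exact) read
counts; the MN/NC ratio of these percentages, rounded to 2 decimals, puts
each miRNA into the >1 / =1 / <1 class (edits more common in disease,
equal, or more common in control).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._util import normalize_seq, round_half_up
from .profiling import MatureMiRNA

SEED_START = 2  # 1-based, inclusive
SEED_END = 8  # 1-based, inclusive


@dataclass(frozen=True)
class SeedEditHit:
    tag: str
    mirna: str
    edit_position: int  # 1-based on the mature sequence, in 2..8
    ref_base: str
    obs_base: str
    multi: bool = False  # tag assigned to >1 miRNA


@dataclass
class EditSummary:
    mirna: str
    pct_mn: float
    pct_nc: float
    ratio: Optional[float]  # rounded to 2 decimals; None when pct_nc == 0
    edit_class: Optional[str]  # gt1 / eq1 / lt1; None when ratio undefined


def find_seed_edits(
    tag: str, reference: Sequence[MatureMiRNA]
) -> List[SeedEditHit]:
    """All miRNAs matching ``tag`` with exactly one mismatch at seed positions 2-8.

    Only equal-length comparisons are made (substitutions, no indels).  A
    tag hitting several miRNAs is reported against each, flagged ``multi``.
    """
    if not reference:
        raise ValueError("mature reference is empty")
    seq = normalize_seq(tag)
    hits: List[SeedEditHit] = []
    for m in reference:
        ref = normalize_seq(m.sequence)
        if len(ref) != len(seq):
            continue
        mismatches = [i for i in range(len(ref)) if ref[i] != seq[i]]
        if len(mismatches) != 1:
            continue
        pos = mismatches[0] + 1  # 1-based
        if SEED_START <= pos <= SEED_END:
            hits.append(
                SeedEditHit(
                    tag=seq,
                    mirna=m.name,
                    edit_position=pos,
                    ref_base=ref[pos - 1],
                    obs_base=seq[pos - 1],
                )
            )
    if len(hits) > 1:
        hits = [
            SeedEditHit(h.tag, h.mirna, h.edit_position, h.ref_base, h.obs_base, True)
            for h in hits
        ]
    return hits


def tally_seed_edits(
    unannotated: Mapping[str, int], reference: Sequence[MatureMiRNA]
) -> Tuple[Dict[str, int], List[SeedEditHit]]:
    """Read-count-weighted edited tallies per miRNA over an unannotated pool.

    Tags that exactly match some mature sequence must be excluded upstream
    (exactness trumps edit); here every tag is single-mismatch aligned.
    """
    edited: Dict[str, int] = defaultdict(int)
    all_hits: List[SeedEditHit] = []
    for tag in sorted(unannotated):
        hits = find_seed_edits(tag, reference)
        for h in hits:
            edited[h.mirna] += unannotated[tag]
        all_hits.extend(hits)
    return dict(edited), all_hits


def edit_percentage(edited_reads: int, exact_reads: int) -> float:
    """100 * edited/(edited + exact); caller must ensure a non-zero denominator."""
    if edited_reads < 0 or exact_reads < 0:
        raise ValueError("read counts must be non-negative")
    denom = edited_reads + exact_reads
    if denom == 0:
        raise ZeroDivisionError("no observed reads (edited + exact = 0)")
    return 100.0 * edited_reads / denom


def edit_ratio(pct_mn: float, pct_nc: float) -> Tuple[Optional[float], Optional[str]]:
    """MN/NC percentage ratio rounded to 2 decimals, classified vs 1.00.

    pct_nc == 0 leaves the ratio undefined; such miRNAs are excluded from
    the three-class partition.
    """
    if pct_nc == 0:
        return None, None
    ratio = round_half_up(pct_mn / pct_nc, 2)
    if ratio > 1.0:
        cls = "gt1"
    elif ratio < 1.0:
        cls = "lt1"
    else:
        cls = "eq1"
    return ratio, cls


def edit_partition(summaries: Sequence[EditSummary]) -> Tuple[int, int, int]:
    """(n_gt1, n_eq1, n_lt1) over the ratio-defined miRNAs."""
    n = {"gt1": 0, "eq1": 0, "lt1": 0}
    for s in summaries:
        if s.edit_class is not None:
            n[s.edit_class] += 1
    return n["gt1"], n["eq1"], n["lt1"]


def summarize_edits(
    exact_mn: Mapping[str, int],
    edited_mn: Mapping[str, int],
    exact_nc: Mapping[str, int],
    edited_nc: Mapping[str, int],
) -> Tuple[List[EditSummary], List[str]]:
    """Per-miRNA edit summaries for miRNAs observed in both groups.

    Returns the summaries plus the names skipped for a zero denominator in
    either group (no observed reads at all).
    """
    names = sorted(set(exact_mn) | set(edited_mn) | set(exact_nc) | set(edited_nc))
    summaries: List[EditSummary] = []
    skipped: List[str] = []
    for name in names:
        denom_mn = edited_mn.get(name, 0) + exact_mn.get(name, 0)
        denom_nc = edited_nc.get(name, 0) + exact_nc.get(name, 0)
        if denom_mn == 0 or denom_nc == 0:
            skipped.append(name)
            continue
        pct_mn = edit_percentage(edited_mn.get(name, 0), exact_mn.get(name, 0))
        pct_nc = edit_percentage(edited_nc.get(name, 0), exact_nc.get(name, 0))
        ratio, cls = edit_ratio(pct_mn, pct_nc)
        summaries.append(
            EditSummary(
                mirna=name,
                pct_mn=round_half_up(pct_mn, 2),
                pct_nc=round_half_up(pct_nc, 2),
                ratio=ratio,
                edit_class=cls,
            )
        )
    return summaries, skipped


# ---------------------------------------------------------------------------
# I/O

def write_edit_summary(summaries: Sequence[EditSummary], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "mirna": [s.mirna for s in summaries],
            "pct_MN": [f"{s.pct_mn:.2f}" for s in summaries],
            "pct_NC": [f"{s.pct_nc:.2f}" for s in summaries],
            "ratio": ["NA" if s.ratio is None else f"{s.ratio:.2f}" for s in summaries],
            "class": [s.edit_class or "undefined" for s in summaries],
        }
    ).set_index("mirna")
    df.to_csv(path, sep="\t")


def write_edit_hits(hits: Sequence[SeedEditHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tmirna\tposition\tref\tobs\tmulti\n")
        for h in hits:
            fh.write(
                f"{h.tag}\t{h.mirna}\t{h.edit_position}\t{h.ref_base}\t"
                f"{h.obs_base}\t{int(h.multi)}\n"
            )
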