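"""Known-miRNA counting and per-position base composition.

A clean tag is assigned to a mature miRNA if and only if it equals the
mature sequence exactly (after alphabet normalization, U == T); everything
else stays in the unannotated pool, which later feeds seed-edit detection.
The base-composition matrix gives, for each position p along the tags, the
count-weighted percentage of A/U/C/G among tags of length >= p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from ._util import normalize_seq, round_half_up, to_rna

#: Table-style composition spans positions 1..24 by default
DEFAULT_MAX_POSITION = 24

#: fixed tie-break order for the dominant base
BASE_ORDER = ("A", "U", "C", "G")


@dataclass(frozen=True)
class MatureMiRNA:
    name: str
    sequence: str  # stored in DNA alphabet internally

    @property
    def rna(self) -> str:
        return to_rna(self.sequence)


@dataclass
class CountTable:
    """Per-miRNA counts for the two libraries plus their clean totals.

    ``totals`` carries (N1, N2) = clean-read totals of (NC, MN) — the
    denominators of per-million normalization and the Audic-Claverie
    statistic, not the sums of the miRNA counts.
    """

    counts: pd.DataFrame  # index: miRNA name; columns: NC, MN
    totals: Tuple[int, int]  # (N1 = NC, N2 = MN)

    def validate(self) -> None:
        if (self.counts < 0).any().any():
            raise ValueError("negative miRNA counts")
        if any(t <= 0 for t in self.totals):
            raise ValueError("library totals must be positive")


@dataclass
class BaseComposition:
    group: str
    matrix: pd.DataFrame  # index: position (1-based); columns A, U, C, G (%)

    def validate(self, tol: float = 0.01) -> None:
        sums = self.matrix.sum(axis=1)
        bad = sums[(sums - 100.0).abs() > tol]
        if not bad.empty:
            raise ValueError(f"composition rows do not sum to 100: {bad.to_dict()}")


def load_mature_reference(path: str | Path) -> List[MatureMiRNA]:
    from Bio import SeqIO

    ref = [
        MatureMiRNA(name=rec.id, sequence=normalize_seq(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    names = [m.name for m in ref]
    if len(set(names)) != len(names):
        raise ValueError("duplicate miRNA names in mature reference")
    return ref


def count_known(
    tags: Mapping[str, int], reference: Sequence[MatureMiRNA]
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Assign tags to mature miRNAs by exact full-length identity.

    Returns ``(counts_by_mirna, unannotated_tags)``.  Duplicate mature
    sequences would make assignment ambiguous and raise, listing the
    colliding names.
    """
    if not reference:
        raise ValueError("mature reference is empty")
    by_seq: Dict[str, str] = {}
    collisions: Dict[str, List[str]] = {}
    for m in reference:
        seq = normalize_seq(m.sequence)
        if seq in by_seq:
            collisions.setdefault(seq, [by_seq[seq]]).append(m.name)
        by_seq[seq] = m.name
    if collisions:
        pairs = "; ".join(", ".join(names) for names in collisions.values())
        raise ValueError(f"duplicate mature sequences for: {pairs}")
    counts = {m.name: 0 for m in reference}
    unannotated: Dict[str, int] = {}
    for tag, count in tags.items():
        seq = normalize_seq(tag)
        name = by_seq.get(seq)
        if name is None:
            unannotated[seq] = unannotated.get(seq, 0) + count
        else:
            counts[name] += count
    return counts, unannotated


def build_count_table(
    counts_nc: Mapping[str, int],
    counts_mn: Mapping[str, int],
    n1: int,
    n2: int,
) -> CountTable:
    names = sorted(set(counts_nc) | set(counts_mn))
    df = pd.DataFrame(
        {
            "NC": [int(counts_nc.get(n, 0)) for n in names],
            "MN": [int(counts_mn.get(n, 0)) for n in names],
        },
        index=pd.Index(names, name="mirna"),
    )
    table = CountTable(counts=df, totals=(int(n1), int(n2)))
    table.validate()
    return table


def base_composition(
    tags: Mapping[str, int],
    group: str,
    max_position: int = DEFAULT_MAX_POSITION,
) -> BaseComposition:
    """Count-weighted per-position A/U/C/G percentages over the given tags.

    Position p (1-based) is computed over tags of length >= p only, so each
    row sums to 100; positions with zero coverage are omitted.
    """
    if max_position < 1:
        raise ValueError("max_position must be >= 1")
    rows = {}
    for p in range(1, max_position + 1):
        tallies = {b: 0 for b in BASE_ORDER}
        covered = 0
        for seq, count in tags.items():
            s = normalize_seq(seq)
            if len(s) >= p:
                base = "U" if s[p - 1] == "T" else s[p - 1]
                if base in tallies:
                    tallies[base] += count
                    covered += count
        if covered:
            rows[p] = {b: 100.0 * tallies[b] / covered for b in BASE_ORDER}
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(BASE_ORDER))
    matrix.index.name = "position"
    comp = BaseComposition(group=group, matrix=matrix)
    if not matrix.empty:
        comp.validate()
    return comp


def dominant_base(
    composition: BaseComposition, position: int
) -> Tuple[str, float, bool]:
    """Arg-max base at a position; ties broken A < U < C < G with a flag."""
    if position not in composition.matrix.index:
        raise ValueError(f"position {position} not covered in group {composition.group}")
    row = composition.matrix.loc[position]
    best = max(BASE_ORDER, key=lambda b: (row[b], -BASE_ORDER.index(b)))
    tie = sum(1 for b in BASE_ORDER if row[b] == row[best]) > 1
    return best, float(row[best]), tie


# ---------------------------------------------------------------------------
# I/O

def write_count_table(table: CountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t")


def write_composition(comp: BaseComposition, path: str | Path) -> None:
    rounded = comp.matrix.map(lambda v: round_half_up(v, 2))
    rounded.to_csv(path, sep="\t", float_format="%.2f")
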