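"""Seeded synthetic data: toy genomes, planted miRNAs, and paired read libraries.

The generator stands in for an undeposited patient data set.  It emits two
FASTQ libraries — a disease library (MN) and a control library (NC) — whose
reads are mature-miRNA tags padded with a 3' adaptor to a fixed raw read
length, plus a configurable fraction of contaminants.  Per-miRNA abundances
in the MN library are scaled by 2**log2_effect relative to NC, so planted
fold changes are analytic and recoverable.  A GroundTruth record carries the
planted coordinates, per-library true counts, seed-edit counts and effects
so every downstream stage can be validated exactly.

All randomness flows from one ``numpy.random.Generator`` seeded in the
config; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from ._util import revcomp

BASES = np.array(list("ACGT"))

#: classic small-RNA 3' adaptor prefix; any >=6 nt string is accepted
DEFAULT_ADAPTOR_3P = "TCGTATGCCGTCT"

#: raw read length of the sequencing tags being emulated
DEFAULT_READ_LENGTH = 50

#: FASTQ read: (identifier, sequence, Sanger/Phred+33 quality string)
Read = Tuple[str, str, str]


@dataclass
class SimulationConfig:
    """Parameters of one paired-library simulation.

    Parameters
    ----------
    n_chromosomes, chrom_length
        Shape of the toy genome (nt).
    n_mirnas
        Number of mature miRNAs planted in the genome.
    mirna_length_range
        Inclusive mature-length bounds, default 18-24 nt.
    library_depths
        Exact raw read counts emitted for (NC, MN).
    log2_effects
        Planted log2 MN/NC abundance ratio per miRNA name; missing names
        default to 0 (null).
    seed_edit_rate
        Per-read probability that a miRNA read carries one substitution at
        a uniformly chosen seed position (2-8, 1-based on the mature).
    contamination_rate
        Fraction of reads that are contaminants (low-quality, adaptor
        dimer, or adaptor-free random sequence, in equal parts).
    adaptor_3p
        3' adaptor appended after the insert, padded to ``read_length``.
    read_length
        Raw tag length in nt.
    rng_seed
        Seed of the single random generator driving everything.
    """

    n_chromosomes: int = 3
    chrom_length: int = 10_000
    n_mirnas: int = 50
    mirna_length_range: Tuple[int, int] = (18, 24)
    library_depths: Tuple[int, int] = (100_000, 100_000)
    log2_effects: Mapping[str, float] = field(default_factory=dict)
    seed_edit_rate: float = 0.0
    contamination_rate: float = 0.0
    adaptor_3p: str = DEFAULT_ADAPTOR_3P
    read_length: int = DEFAULT_READ_LENGTH
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mirna_length_range
        if not (0.0 <= self.seed_edit_rate <= 1.0):
            raise ValueError("seed_edit_rate must lie in [0, 1]")
        if not (0.0 <= self.contamination_rate <= 1.0):
            raise ValueError("contamination_rate must lie in [0, 1]")
        if any(d <= 0 for d in self.library_depths):
            raise ValueError("library depths must be positive")
        if lo > hi or lo < 16 or hi > self.read_length:
            raise ValueError(
                f"miRNA lengths must satisfy 16 <= {lo} <= {hi} <= "
                f"read_length={self.read_length}"
            )
        if len(self.adaptor_3p) < 6:
            raise ValueError("3' adaptor must be at least 6 nt")


@dataclass
class GroundTruth:
    """Planted truth of one simulation (coordinates, counts, effects)."""

    #: miRNA -> (chromosome, 0-based start, '+'/'-')
    mirna_positions: Dict[str, Tuple[str, int, str]] = field(default_factory=dict)
    #: (miRNA, library_id) -> emitted read count
    true_counts: Dict[Tuple[str, str], int] = field(default_factory=dict)
    #: (miRNA, library_id) -> emitted seed-edited read count
    true_edit_counts: Dict[Tuple[str, str], int] = field(default_factory=dict)
    #: miRNA -> planted log2 MN/NC ratio
    planted_effects: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for key, n_edit in self.true_edit_counts.items():
            if n_edit > self.true_counts.get(key, 0):
                raise ValueError(f"edited count exceeds total for {key}")
        for (mirna, _lib) in self.true_counts:
            if mirna not in self.mirna_positions:
                raise ValueError(f"{mirna} counted but never planted")


def generate_genome(
    n_chromosomes: int, chrom_length: int, rng_seed: int
) -> Dict[str, str]:
    """Uniform-random toy chromosomes over {A,C,G,T}, deterministic per seed."""
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if chrom_length < 100:
        raise ValueError("chrom_length must be >= 100")
    rng = np.random.default_rng(rng_seed)
    return {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=chrom_length))
        for i in range(n_chromosomes)
    }


def plant_mirnas(
    genome: Mapping[str, str], config: SimulationConfig
) -> Tuple[List[Tuple[str, str]], GroundTruth]:
    """Pick non-overlapping genomic sites and read mature sequences off them.

    Returns the mature reference as ``[(name, DNA sequence), ...]`` and a
    GroundTruth with coordinates.  A '-' strand miRNA is the reverse
    complement of the genomic window, so mapping it back yields an
    antisense hit at the recorded locus.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    lo, hi = config.mirna_length_range
    chrom_names = sorted(genome)
    capacity = sum(max(0, len(genome[c]) - hi) for c in chrom_names)
    # non-overlap bookkeeping: claimed [start, end) intervals per chromosome
    if config.n_mirnas * hi > capacity:
        raise ValueError(
            f"genome too small to host {config.n_mirnas} non-overlapping "
            f"miRNAs of up to {hi} nt"
        )
    claimed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_names}
    reference: List[Tuple[str, str]] = []
    truth = GroundTruth()
    seen_seqs = set()
    attempts = 0
    while len(reference) < config.n_mirnas:
        attempts += 1
        if attempts > 1000 * max(1, config.n_mirnas):
            raise ValueError("could not place non-overlapping miRNAs; genome too crowded")
        chrom = chrom_names[rng.integers(len(chrom_names))]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(genome[chrom]) - length + 1))
        end = start + length
        if any(s < end and start < e for s, e in claimed[chrom]):
            continue
        window = genome[chrom][start:end]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = window if strand == "+" else revcomp(window)
        if seq in seen_seqs or revcomp(seq) in seen_seqs:
            continue  # keep exact-match assignment unambiguous
        seen_seqs.add(seq)
        claimed[chrom].append((start, end))
        name = f"syn-mir-{len(reference) + 1:03d}"
        reference.append((name, seq))
        truth.mirna_positions[name] = (chrom, start, strand)
    for name in config.log2_effects:
        if name not in truth.mirna_positions and config.n_mirnas > 0:
            raise ValueError(f"log2_effects names unknown miRNA {name!r}")
    truth.planted_effects = {
        name: float(config.log2_effects.get(name, 0.0))
        for name, _ in reference
    }
    return reference, truth


def _random_quality(rng: np.random.Generator, length: int, lo: int, hi: int) -> str:
    return "".join(chr(33 + q) for q in rng.integers(lo, hi + 1, size=length))


def _pad_to_length(insert: str, adaptor: str, rng: np.random.Generator, read_length: int) -> str:
    read = insert + adaptor
    if len(read) < read_length:
        read += "".join(rng.choice(BASES, size=read_length - len(read)))
    return read[:read_length]


def simulate_libraries(
    mirna_ref: Sequence[Tuple[str, str]],
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> Tuple[List[Read], List[Read], GroundTruth]:
    """Emit the NC and MN raw read lists and fill GroundTruth counts.

    Per library, the contaminant read count is Binomial(depth, rate) and the
    remainder is split multinomially across miRNAs with uniform base weights,
    scaled by 2**log2_effect in MN — so the expected MN/NC count ratio of a
    miRNA is exactly 2**effect (up to total-weight renormalization).
    Emitted reads per library equal the configured depth exactly.
    """
    if truth is None:
        truth = GroundTruth(
            mirna_positions={name: ("chrUn", 0, "+") for name, _ in mirna_ref},
            planted_effects={
                name: float(config.log2_effects.get(name, 0.0))
                for name, _ in mirna_ref
            },
        )
    for name in config.log2_effects:
        if name not in dict(mirna_ref):
            raise ValueError(f"log2_effects names unknown miRNA {name!r}")
    rng = np.random.default_rng(config.rng_seed + 2)
    names = [name for name, _ in mirna_ref]
    seqs = {name: seq for name, seq in mirna_ref}
    effects = np.array([truth.planted_effects.get(n, 0.0) for n in names])
    libraries: Dict[str, List[Read]] = {}
    for lib_id, depth, scale in (
        ("NC", config.library_depths[0], np.zeros_like(effects)),
        ("MN", config.library_depths[1], effects),
    ):
        reads: List[Read] = []
        n_contam = int(rng.binomial(depth, config.contamination_rate))
        n_real = depth - n_contam
        if names:
            weights = np.exp2(scale)
            weights = weights / weights.sum()
            counts = rng.multinomial(n_real, weights)
        else:
            counts = np.array([], dtype=int)
            n_contam = depth
            n_real = 0
        for name, count in zip(names, counts):
            mature = seqs[name]
            truth.true_counts[(name, lib_id)] = int(count)
            n_edit = int(rng.binomial(count, config.seed_edit_rate))
            truth.true_edit_counts[(name, lib_id)] = n_edit
            for i in range(count):
                insert = mature
                if i < n_edit:
                    pos = int(rng.integers(2, 9))  # 1-based seed position 2..8
                    old = insert[pos - 1]
                    new = str(rng.choice([b for b in "ACGT" if b != old]))
                    insert = insert[: pos - 1] + new + insert[pos:]
                seq = _pad_to_length(insert, config.adaptor_3p, rng, config.read_length)
                qual = _random_quality(rng, config.read_length, 30, 40)
                reads.append((f"{lib_id}:{name}:{i}", seq, qual))
        for j in range(n_contam):
            kind = j % 3
            if kind == 0:  # low quality (fails mean-Phred and N-fraction rules)
                seq = "".join(rng.choice(BASES, size=config.read_length))
                n_pos = rng.choice(config.read_length, size=config.read_length // 5, replace=False)
                seq = "".join("N" if k in set(n_pos) else b for k, b in enumerate(seq))
                qual = _random_quality(rng, config.read_length, 2, 10)
            elif kind == 1:  # adaptor dimer: adaptor at position 0, empty insert
                seq = _pad_to_length("", config.adaptor_3p, rng, config.read_length)
                qual = _random_quality(rng, config.read_length, 30, 40)
            else:  # random sequence without the adaptor
                while True:
                    seq = "".join(rng.choice(BASES, size=config.read_length))
                    if config.adaptor_3p[:8] not in seq:
                        break
                qual = _random_quality(rng, config.read_length, 30, 40)
            reads.append((f"{lib_id}:contam:{j}", seq, qual))
        order = rng.permutation(len(reads))
        libraries[lib_id] = [reads[k] for k in order]
    truth.validate()
    return libraries["NC"], libraries["MN"], truth


# ---------------------------------------------------------------------------
# writers

def write_fasta(records: Sequence[Tuple[str, str]], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    """GroundTruth as positions TSV + counts TSV + effects JSON."""
    outdir = Path(outdir)
    with open(outdir / "truth_positions.tsv", "w") as fh:
        fh.write("mirna\tchromosome\tstart\tstrand\n")
        for name, (chrom, start, strand) in sorted(truth.mirna_positions.items()):
            fh.write(f"{name}\t{chrom}\t{start}\t{strand}\n")
    with open(outdir / "truth_counts.tsv", "w") as fh:
        fh.write("mirna\tlibrary\tcount\tedited\n")
        for (name, lib), count in sorted(truth.true_counts.items()):
            edited = truth.true_edit_counts.get((name, lib), 0)
            fh.write(f"{name}\t{lib}\t{count}\t{edited}\n")
    with open(outdir / "truth_effects.json", "w") as fh:
        json.dump(truth.planted_effects, fh, indent=1, sort_keys=True)


def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Run the full generator and write FASTA/FASTQ/truth files to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config.n_chromosomes, config.chrom_length, config.rng_seed)
    reference, truth = plant_mirnas(genome, config)
    reads_nc, reads_mn, truth = simulate_libraries(reference, config, truth)
    write_fasta(sorted(genome.items()), outdir / "genome.fa")
    write_fasta(reference, outdir / "mirnas.fa")
    write_fastq(reads_nc, outdir / "reads_NC.fastq")
    write_fastq(reads_mn, outdir / "reads_MN.fastq")
    write_ground_truth(truth, outdir)
    return truth
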