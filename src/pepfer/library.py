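"""Library designs, raw-read processing, and count-table I/O.

A :class:`LibraryDesign` describes a displayed random-peptide library: the
variable-region length, fixed residues (e.g. the central tyrosine of the
``x5yx5`` design), the constant DNA anchors that bracket the variable region
in a sequencing read, the constant peptide flanks of the display scaffold,
and the degenerate codon pattern used to encode the library.

Raw reads are converted to per-round :class:`CountTable` objects through a
fixed pipeline: locate the variable region between the DNA anchors, apply a
per-base quality filter to the cropped region, check the region against the
codon design, and translate.  Reads discarded at each stage are tallied in a
:class:`ProcessingReport`.
"""

from __future__ import annotations

import csv
import gzip
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Seq import Seq

from .errors import (
    ConfigurationError,
    EmptyTableError,
    FormatError,
    MalformedInputError,
)

#: Canonical amino-acid ordering used for every coefficient matrix.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Placeholder residue used to pad windows that run past a protein terminus.
PAD_CHAR = "X"
PAD_INDEX = len(ALPHABET)

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC degenerate-base expansions (used to interpret codon patterns).
IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LibraryDesign:
    """Description of a displayed random-peptide library."""

    name: str
    length: int
    fixed_positions: Mapping[int, str] = field(default_factory=dict)
    dna_left_anchor: str = "GTAGCTGGCCAGTCTGGCCAG"
    dna_right_anchor: str = "GGAGGGCAGTCTGGGCAGTC"
    protein_flank_left: str = "GQSGQ"
    protein_flank_right: str = "GGQSG"
    codon_pattern: str = "NNS"
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        if self.alphabet != ALPHABET:
            raise ConfigurationError(
                f"alphabet must be {ALPHABET!r} in this fixed order"
            )
        if self.length < 1:
            raise ConfigurationError("length must be >= 1")
        if len(self.codon_pattern) != 3 or any(
            b not in IUPAC_DNA for b in self.codon_pattern
        ):
            raise ConfigurationError(
                f"codon_pattern must be a 3-letter IUPAC string, got "
                f"{self.codon_pattern!r}"
            )
        for pos, res in self.fixed_positions.items():
            if not 1 <= pos <= self.length:
                raise ConfigurationError(
                    f"fixed position {pos} outside 1..{self.length}"
                )
            if res not in self.alphabet:
                raise ConfigurationError(f"fixed residue {res!r} not in alphabet")
        for flank in (self.protein_flank_left, self.protein_flank_right):
            bad = set(flank) - set(self.alphabet)
            if bad:
                raise ConfigurationError(
                    f"protein flank contains non-alphabet letters: {sorted(bad)}"
                )
        for anchor in (self.dna_left_anchor, self.dna_right_anchor):
            if set(anchor) - set("ACGT"):
                raise ConfigurationError("DNA anchors must be plain ACGT strings")

    @property
    def variable_dna_length(self) -> int:
        """Expected length in nt of the variable region (3 per residue)."""
        return 3 * self.length

    def central_position(self) -> int:
        """1-based index of the central residue (length must be odd)."""
        if self.length % 2 == 0:
            raise ConfigurationError("design length must be odd to have a center")
        return (self.length + 1) // 2

    def check_peptide(self, peptide: str) -> None:
        if len(peptide) != self.length:
            raise MalformedInputError(
                f"peptide {peptide!r} has length {len(peptide)}, "
                f"expected {self.length}"
            )
        bad = set(peptide) - set(self.alphabet)
        if bad:
            raise MalformedInputError(
                f"peptide {peptide!r} contains letters outside alphabet: {sorted(bad)}"
            )
        for pos, res in self.fixed_positions.items():
            if peptide[pos - 1] != res:
                raise MalformedInputError(
                    f"peptide {peptide!r} violates fixed position {pos}={res}"
                )


def x5yx5_design() -> LibraryDesign:
    """Eleven residues with a fixed central tyrosine (X5YX5)."""
    return LibraryDesign(name="x5yx5", length=11, fixed_positions={6: "Y"})


def x11_design() -> LibraryDesign:
    """Eleven fully random residues (X11)."""
    return LibraryDesign(name="x11", length=11, fixed_positions={})


_BUILTIN_DESIGNS = {"x5yx5": x5yx5_design, "x11": x11_design}


def get_design(spec: str) -> LibraryDesign:
    """Resolve a design name (``x5yx5``, ``x11``) or a YAML file path."""
    if spec in _BUILTIN_DESIGNS:
        return _BUILTIN_DESIGNS[spec]()
    path = Path(spec)
    if not path.exists():
        raise ConfigurationError(
            f"unknown design {spec!r}; expected one of "
            f"{sorted(_BUILTIN_DESIGNS)} or a YAML file path"
        )
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: design YAML must be a mapping")
    fixed = {int(k): str(v) for k, v in (raw.get("fixed_positions") or {}).items()}
    kwargs = {
        k: raw[k]
        for k in (
            "name",
            "length",
            "dna_left_anchor",
            "dna_right_anchor",
            "protein_flank_left",
            "protein_flank_right",
            "codon_pattern",
        )
        if k in raw
    }
    return LibraryDesign(fixed_positions=fixed, **kwargs)


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read with per-base PHRED quality scores."""

    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise MalformedInputError(
                f"sequence length {len(self.sequence)} != quality length "
                f"{len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTQ file (gzip transparently supported)."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(
                sequence=str(rec.seq),
                quality=tuple(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, rec in enumerate(records):
            qual = "".join(chr(q + 33) for q in rec.quality)
            fh.write(f"@read{i}\n{rec.sequence}\n+\n{qual}\n")


def merge_pairs(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = 10,
    min_identity: float = 0.9,
) -> ReadRecord | None:
    """Join a read pair by its best-scoring ungapped overlap.

    ``r2`` is reverse-complemented and slid along ``r1``; the placement with
    the most matching bases among those with identity >= ``min_identity`` and
    overlap >= ``min_overlap`` wins (ties broken leftmost).  At disagreeing
    positions the higher-quality base is taken.  Returns ``None`` when no
    qualifying overlap exists.
    """
    if not len(r1) or not len(r2):
        raise MalformedInputError("cannot merge empty reads")
    if min_overlap < 1:
        raise ConfigurationError("min_overlap must be >= 1")
    rc_seq = reverse_complement(r2.sequence)
    rc_qual = r2.quality[::-1]
    n1, n2 = len(r1), len(rc_seq)

    best_matches = -1
    best_p = None
    for p in range(0, n1 - min_overlap + 1):
        ov = min(n1 - p, n2)
        if ov < min_overlap:
            break
        matches = sum(
            a == b for a, b in zip(r1.sequence[p : p + ov], rc_seq[:ov])
        )
        if matches / ov >= min_identity and matches > best_matches:
            best_matches = matches
            best_p = p
    if best_p is None:
        return None

    p = best_p
    ov = min(n1 - p, n2)
    seq_chars: list[str] = list(r1.sequence[:p])
    qual: list[int] = list(r1.quality[:p])
    for k in range(ov):
        a, qa = r1.sequence[p + k], r1.quality[p + k]
        b, qb = rc_seq[k], rc_qual[k]
        if a == b:
            seq_chars.append(a)
            qual.append(max(qa, qb))
        elif qb > qa:
            seq_chars.append(b)
            qual.append(qb)
        else:
            seq_chars.append(a)
            qual.append(qa)
    seq_chars.extend(rc_seq[ov:])
    qual.extend(rc_qual[ov:])
    return ReadRecord(sequence="".join(seq_chars), quality=tuple(qual))


def _mismatch_profile(read_arr: np.ndarray, anchor: str) -> np.ndarray:
    """Hamming distance of ``anchor`` against every offset of ``read_arr``."""
    m = len(anchor)
    n = len(read_arr)
    if n < m:
        return np.empty(0, dtype=np.int64)
    anchor_arr = np.frombuffer(anchor.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(read_arr, m)
    return (windows != anchor_arr).sum(axis=1)


def _locate_region_start(
    read: str, design: LibraryDesign, max_mismatches: int
) -> int | None:
    """Start index of the variable region within ``read``, or None."""
    la, ra = design.dna_left_anchor, design.dna_right_anchor
    span = len(la) + design.variable_dna_length + len(ra)
    if len(read) < span:
        return None
    arr = np.frombuffer(read.encode(), dtype=np.uint8)
    left_mm = _mismatch_profile(arr, la)
    right_mm = _mismatch_profile(arr, ra)
    offset = len(la) + design.variable_dna_length
    n_pos = len(read) - span + 1
    total = left_mm[:n_pos] + right_mm[offset : offset + n_pos]
    ok = (left_mm[:n_pos] <= max_mismatches) & (
        right_mm[offset : offset + n_pos] <= max_mismatches
    )
    if not ok.any():
        return None
    masked = np.where(ok, total, np.iinfo(np.int64).max)
    i = int(masked.argmin())  # argmin takes the leftmost minimum
    return i + len(la)


def locate_variable_region(
    read: str, design: LibraryDesign, max_mismatches: int = 5
) -> str | None:
    """Find the variable region bracketed by the design's DNA anchors.

    Anchors are matched without indels; each anchor may carry up to
    ``max_mismatches`` substitutions.  Among qualifying placements, the one
    with the fewest total anchor mismatches wins, ties broken leftmost.
    """
    start = _locate_region_start(read, design, max_mismatches)
    if start is None:
        return None
    return read[start : start + design.variable_dna_length]


def quality_pass(region_quality: Iterable[int], min_phred: int = 20) -> bool:
    """True iff every position of the cropped region has PHRED >= min_phred."""
    scores = tuple(region_quality)
    if not scores:
        raise MalformedInputError("empty quality region")
    return min(scores) >= min_phred


def _codon_allows(codon: str, pattern: str) -> bool:
    return all(base in IUPAC_DNA[p] for base, p in zip(codon, pattern))


def match_and_translate(region: str, design: LibraryDesign) -> str | None:
    """Translate a located variable region, rejecting design violations.

    Returns ``None`` if any codon violates the degenerate codon pattern, if
    any codon is a stop, or if a fixed position translates to the wrong
    residue.  Fixed residues are accepted under any codon encoding them.
    """
    if len(region) % 3 != 0:
        raise MalformedInputError(
            f"region length {len(region)} is not a multiple of 3"
        )
    if len(region) != design.variable_dna_length:
        raise MalformedInputError(
            f"region length {len(region)} != expected "
            f"{design.variable_dna_length}"
        )
    for i in range(0, len(region), 3):
        if not _codon_allows(region[i : i + 3], design.codon_pattern):
            return None
    peptide = str(Seq(region).translate())
    if "*" in peptide:
        return None
    for pos, res in design.fixed_positions.items():
        if peptide[pos - 1] != res:
            return None
    return peptide


@dataclass
class ColumnReport:
    """Per-column read bookkeeping; kept + all discards == total."""

    total: int = 0
    no_region: int = 0
    low_quality: int = 0
    design_mismatch: int = 0
    kept: int = 0

    def check_conservation(self) -> bool:
        return (
            self.no_region + self.low_quality + self.design_mismatch + self.kept
            == self.total
        )


@dataclass
class ProcessingReport:
    input: ColumnReport = field(default_factory=ColumnReport)
    bound: ColumnReport = field(default_factory=ColumnReport)

    def to_text(self) -> str:
        lines = []
        for name, col in (("input", self.input), ("bound", self.bound)):
            lines.append(f"[{name}]")
            lines.append(f"total_reads\t{col.total}")
            lines.append(f"discarded_no_region\t{col.no_region}")
            lines.append(f"discarded_low_quality\t{col.low_quality}")
            lines.append(f"discarded_design_mismatch\t{col.design_mismatch}")
            lines.append(f"kept\t{col.kept}")
        return "\n".join(lines) + "\n"


class CountTable:
    """One selection round's peptide -> (input count, bound count) map."""

    def __init__(
        self,
        round_id: int,
        design: LibraryDesign,
        sequences: Iterable[str],
        counts_input: Iterable[int],
        counts_bound: Iterable[int],
    ) -> None:
        if round_id < 1:
            raise ConfigurationError("round_id must be >= 1")
        self.round_id = int(round_id)
        self.design = design
        self.sequences = tuple(sequences)
        self.counts_input = np.asarray(counts_input, dtype=np.int64)
        self.counts_bound = np.asarray(counts_bound, dtype=np.int64)
        self._validate()

    def _validate(self) -> None:
        n = len(self.sequences)
        if self.counts_input.shape != (n,) or self.counts_bound.shape != (n,):
            raise MalformedInputError("count arrays misaligned with sequences")
        if (self.counts_input < 0).any() or (self.counts_bound < 0).any():
            raise MalformedInputError("counts must be >= 0")
        if ((self.counts_input == 0) & (self.counts_bound == 0)).any():
            raise MalformedInputError("row with both counts zero")
        if len(set(self.sequences)) != n:
            raise MalformedInputError("duplicate sequences in count table")
        for seq in self.sequences:
            self.design.check_peptide(seq)
        if self.k_total <= 0:
            raise EmptyTableError("count table has no reads")

    @property
    def k_total(self) -> int:
        """Total reads in the table (input + bound columns)."""
        return int(self.counts_input.sum() + self.counts_bound.sum())

    @property
    def n_unique(self) -> int:
        return len(self.sequences)

    def rows(self) -> dict[str, tuple[int, int]]:
        return {
            s: (int(ki), int(kb))
            for s, ki, kb in zip(self.sequences, self.counts_input, self.counts_bound)
        }

    @classmethod
    def from_rows(
        cls,
        rows: Mapping[str, tuple[int, int]],
        design: LibraryDesign,
        round_id: int = 1,
    ) -> "CountTable":
        seqs = list(rows)
        return cls(
            round_id=round_id,
            design=design,
            sequences=seqs,
            counts_input=[rows[s][0] for s in seqs],
            counts_bound=[rows[s][1] for s in seqs],
        )


def _process_stream(
    reads: Iterable[ReadRecord],
    design: LibraryDesign,
    max_mismatches: int,
    min_phred: int,
    report: ColumnReport,
    counts: dict[str, int],
) -> None:
    for read in reads:
        report.total += 1
        start = _locate_region_start(read.sequence, design, max_mismatches)
        if start is None:
            report.no_region += 1
            continue
        region = read.sequence[start : start + design.variable_dna_length]
        region_quality = read.quality[start : start + len(region)]
        if not quality_pass(region_quality, min_phred):
            report.low_quality += 1
            continue
        peptide = match_and_translate(region, design)
        if peptide is None:
            report.design_mismatch += 1
            continue
        report.kept += 1
        counts[peptide] = counts.get(peptide, 0) + 1


def build_count_table(
    input_reads: Iterable[ReadRecord],
    bound_reads: Iterable[ReadRecord],
    design: LibraryDesign,
    round_id: int,
    max_mismatches: int = 5,
    min_phred: int = 20,
) -> tuple[CountTable, ProcessingReport]:
    """Run the locate -> quality -> design-match -> translate pipeline.

    Aggregates surviving peptides into a :class:`CountTable`; the report
    records how many reads each stage discarded, per column.
    """
    report = ProcessingReport()
    in_counts: dict[str, int] = {}
    bd_counts: dict[str, int] = {}
    _process_stream(
        input_reads, design, max_mismatches, min_phred, report.input, in_counts
    )
    _process_stream(
        bound_reads, design, max_mismatches, min_phred, report.bound, bd_counts
    )
    if report.input.kept == 0:
        raise EmptyTableError("no input reads survived processing")
    if report.bound.kept == 0:
        raise EmptyTableError("no bound reads survived processing")
    peptides = sorted(set(in_counts) | set(bd_counts))
    table = CountTable(
        round_id=round_id,
        design=design,
        sequences=peptides,
        counts_input=[in_counts.get(p, 0) for p in peptides],
        counts_bound=[bd_counts.get(p, 0) for p in peptides],
    )
    return table, report


_TSV_HEADER = ["sequence", "count_input", "count_bound"]


def write_count_table(table: CountTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_HEADER)
        for seq, ki, kb in zip(
            table.sequences, table.counts_input, table.counts_bound
        ):
            writer.writerow([seq, int(ki), int(kb)])


def read_count_table(
    path: str | Path, design: LibraryDesign, round_id: int = 1
) -> CountTable:
    """Read a count-table TSV, validating every row (errors name the line)."""
    seqs: list[str] = []
    k_in: list[int] = []
    k_bd: list[int] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if header != _TSV_HEADER:
            raise FormatError(
                f"{path}: line 1: expected header {_TSV_HEADER}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            seq = row[0]
            try:
                ki, kb = int(row[1]), int(row[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer count"
                ) from None
            if ki < 0 or kb < 0:
                raise FormatError(f"{path}: line {lineno}: negative count")
            if seq in seen:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate sequence {seq!r}"
                )
            try:
                design.check_peptide(seq)
            except MalformedInputError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            seen.add(seq)
            seqs.append(seq)
            k_in.append(ki)
            k_bd.append(kb)
    if not seqs:
        raise FormatError(f"{path}: no data rows")
    return CountTable(
        round_id=round_id,
        design=design,
        sequences=seqs,
        counts_input=k_in,
        counts_bound=k_bd,
    )
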