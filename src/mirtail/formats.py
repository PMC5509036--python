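"""Readers, writers and core record types for the formats the pipeline touches.

Conventions
-----------
* Internal sequences use the uppercase DNA alphabet ``A/C/G/T/N``; RNA input
  (``U``) is converted to ``T`` on read.  Report columns render 3' tail
  nucleotides back in the RNA alphabet (``U``) for display.
* All coordinates are 0-based half-open.  1-based values only ever appear in
  report columns whose name carries the ``_1based`` suffix.
* Collapsed-FASTA ids may carry the common ``_xN`` read-count suffix
  (``>seq1_x532``); :func:`read_collapsed_fasta` honours it.
"""

from __future__ import annotations

import gzip
import io
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA_ALPHABET = frozenset("ACGTN")
#: IUPAC ambiguity codes mapped to N under the permissive policy.
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")

_COUNT_SUFFIX = re.compile(r"_x(\d+)$")


class FormatError(ValueError):
    """Base class for all parse/validation failures in this module."""


class FastaParseError(FormatError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class FastqParseError(FormatError):
    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


class AnnotationError(FormatError):
    """Raised with one message per offending annotation row."""

    def __init__(self, problems: Sequence[str]):
        super().__init__("invalid annotation rows:\n" + "\n".join(problems))
        self.problems = list(problems)


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinRecord:
    """A pre-miRNA hairpin used as the mapping reference."""

    hairpin_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"hairpin {self.hairpin_id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"hairpin {self.hairpin_id!r}: disallowed characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MatureAnnotation:
    """Location of one mature product on its hairpin (0-based half-open)."""

    mature_id: str
    hairpin_id: str
    start: int
    end: int
    is_guide: bool | None = None

    def validate(self, hairpin: HairpinRecord) -> list[str]:
        problems = []
        if not (0 <= self.start < self.end <= len(hairpin)):
            problems.append(
                f"{self.mature_id}: coordinates [{self.start},{self.end}) "
                f"invalid on hairpin of length {len(hairpin)}"
            )
        elif not (16 <= self.end - self.start <= 28):
            problems.append(
                f"{self.mature_id}: mature length {self.end - self.start} "
                "outside plausible 16-28 nt range"
            )
        return problems


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence and how many raw reads shared it."""

    read_id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise FormatError(f"read {self.read_id!r}: count must be >= 1")
        if not self.sequence:
            raise FormatError(f"read {self.read_id!r}: empty sequence")


@dataclass
class SpikeInSet:
    """Exogenous spike-in sequences plus the running exact-match tally."""

    records: list[tuple[str, str]] = field(default_factory=list)
    matched_count: int = 0

    def __post_init__(self) -> None:
        seqs = [s for _, s in self.records]
        if len(set(seqs)) != len(seqs):
            raise FormatError("spike-in sequences must be pairwise distinct")

    def sequence_index(self) -> dict[str, str]:
        return {seq: sid for sid, seq in self.records}


# ---------------------------------------------------------------------------
# Sequence normalisation
# ---------------------------------------------------------------------------

def normalize_sequence(seq: str, alphabet_policy: str = "strict") -> str:
    """Uppercase, convert U->T, and apply the alphabet policy.

    ``strict`` rejects anything outside A/C/G/T/N; ``permissive`` maps IUPAC
    ambiguity codes to N.  Characters outside the IUPAC alphabet are rejected
    under both policies.  Raises ``ValueError`` naming the first bad
    character (callers attach file/line context).
    """
    out = seq.upper().replace("U", "T")
    bad = set(out) - DNA_ALPHABET
    if not bad:
        return out
    if alphabet_policy == "permissive" and bad <= IUPAC_AMBIGUITY:
        return out.translate(str.maketrans({c: "N" for c in IUPAC_AMBIGUITY}))
    offender = sorted(bad - (IUPAC_AMBIGUITY if alphabet_policy == "permissive" else set()))
    raise ValueError(f"disallowed character(s) {offender} in sequence")


def to_rna(seq: str) -> str:
    """Render a DNA-alphabet sequence in the RNA display alphabet (T->U)."""
    return seq.replace("T", "U")


class _DeterministicGzipWriter(io.TextIOWrapper):
    """Text writer over gzip with fixed mtime/name: byte-identical output."""

    def __init__(self, path: Path):
        self._raw = open(path, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=self._raw, mtime=0)
        super().__init__(gz)

    def close(self) -> None:
        if not self.closed:
            super().close()
            self._raw.close()


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        if "r" in mode:
            return gzip.open(path, mode)  # type: ignore[return-value]
        return _DeterministicGzipWriter(path)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path, alphabet_policy: str = "strict"
) -> list[tuple[str, str]]:
    """Parse FASTA into ``(id, sequence)`` pairs in file order.

    Sequences may wrap over multiple lines.  Errors carry the 1-based line
    number of the offending input.  A hand-written reader is used so that
    alphabet violations and structural problems can be reported with exact
    line positions.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(at_line: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        if not chunks:
            raise FastaParseError(f"record {header!r} has no sequence", header_line)
        records.append((header, "".join(chunks)))
        header, chunks = None, []

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise FastaParseError("empty FASTA header", lineno)
                header_line = lineno
            else:
                if header is None:
                    raise FastaParseError(
                        f"sequence data before any header: {line[:20]!r}", lineno
                    )
                try:
                    chunks.append(normalize_sequence(line, alphabet_policy))
                except ValueError as exc:
                    raise FastaParseError(str(exc), lineno) from None
        flush(-1)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_hairpins(path: str | Path, alphabet_policy: str = "strict") -> dict[str, HairpinRecord]:
    """Load a hairpin reference set, enforcing unique ids."""
    out: dict[str, HairpinRecord] = {}
    for rid, seq in read_fasta(path, alphabet_policy):
        if rid in out:
            raise FormatError(f"duplicate hairpin id {rid!r}")
        out[rid] = HairpinRecord(rid, seq)
    return out


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    """Read pre-collapsed FASTA honouring the ``>id_xCOUNT`` convention."""
    reads = []
    for rid, seq in read_fasta(path):
        m = _COUNT_SUFFIX.search(rid)
        reads.append(CollapsedRead(rid, seq, int(m.group(1)) if m else 1))
    return reads


def read_spike_fasta(path: str | Path) -> SpikeInSet:
    return SpikeInSet(records=[(rid, seq) for rid, seq in read_fasta(path)])


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream ``(id, sequence, quality)`` from plain or gzipped FASTQ.

    Sequences are normalised to the internal DNA alphabet.  Structural
    problems (truncated record, |seq| != |qual|) raise
    :class:`FastqParseError` carrying the 1-based record index.
    """
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            index += 1
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(str(exc), index) from None
            try:
                seq = normalize_sequence(seq, "permissive")
            except ValueError as exc:
                raise FastqParseError(str(exc), index) from None
            yield title.split()[0], seq, qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Collapsing
# ---------------------------------------------------------------------------

def collapse_reads(sequences: Iterable[str]) -> list[CollapsedRead]:
    """Collapse identical sequences into counted unique reads.

    Output order is deterministic: descending count, then lexicographic
    sequence.  Counts sum to the input cardinality.
    """
    counts = Counter(sequences)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CollapsedRead(f"seq{i}_x{n}", seq, n)
        for i, (seq, n) in enumerate(ordered, start=1)
    ]


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["mature_id", "hairpin_id", "start", "end"]


def read_annotation_tsv(
    path: str | Path, hairpins: Mapping[str, HairpinRecord]
) -> list[MatureAnnotation]:
    """Load mature annotations and validate them against the hairpin set.

    All offending rows are collected and reported together in a single
    :class:`AnnotationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mature_id": str, "hairpin_id": str})
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise AnnotationError(
            [f"header must be {ANNOTATION_COLUMNS}, got {list(df.columns)}"]
        )
    problems: list[str] = []
    seen: set[str] = set()
    annotations: list[MatureAnnotation] = []
    for row in df.itertuples(index=False):
        ann = MatureAnnotation(row.mature_id, row.hairpin_id, int(row.start), int(row.end))
        if ann.mature_id in seen:
            problems.append(f"{ann.mature_id}: duplicate mature_id")
            continue
        seen.add(ann.mature_id)
        if ann.start >= ann.end:
            problems.append(f"{ann.mature_id}: start >= end ({ann.start} >= {ann.end})")
            continue
        hp = hairpins.get(ann.hairpin_id)
        if hp is None:
            problems.append(f"{ann.mature_id}: unknown hairpin_id {ann.hairpin_id!r}")
            continue
        problems.extend(ann.validate(hp))
        annotations.append(ann)
    if problems:
        raise AnnotationError(problems)
    return annotations


def write_annotation_tsv(annotations: Iterable[MatureAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.mature_id, a.hairpin_id, a.start, a.end) for a in annotations],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def write_count_table(matrix: pd.DataFrame, path: str | Path) -> None:
    """Serialise a labelled matrix to TSV (row label first, floats %.6g).

    Output is bit-exact across runs on identical input, so tables can be
    diffed between pipeline runs.
    """
    matrix.to_csv(path, sep="\t", float_format="%.6g", index_label=matrix.index.name or "id")


def read_count_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df
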