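"""Hairpin-anchored read classification: templated isoforms vs 3' tails.

Each read is compared, without indels, against its annotated mature window on
the hairpin at every 5' start within a small anchor window.  The best
placement (fewest mismatches, then smallest |5' offset|, then leftmost start)
is classified into exactly one category:

``TEMPLATED``
    zero mismatches — the read is a literal hairpin substring, i.e. a
    templated length isoform (including templated 3' extensions).
``NTA``
    all mismatches form a contiguous run ending at the read's last position,
    of length at most ``tail_max`` — a 3' nontemplated addition.  A terminal
    nucleotide that matches the next hairpin base is templated by definition
    and never called a tail.
``INTERNAL_MM``
    at most ``max_mismatches`` mismatches, at least one of them internal —
    the sequencing-error/editing background the terminal-vs-internal fold
    statistic is measured against.
``SPIKEIN`` / ``UNASSIGNED``
    exact spike-in matches, and reads exceeding the mismatch budget at every
    admissible placement.

Positions extending past the hairpin 3' end have nothing to match and count
as mismatches (they are nontemplated by construction).  ``N`` never matches
any base.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .formats import (
    CollapsedRead,
    FormatError,
    HairpinRecord,
    MatureAnnotation,
    SpikeInSet,
)

CATEGORIES = ("TEMPLATED", "NTA", "INTERNAL_MM", "SPIKEIN", "UNASSIGNED")


@dataclass
class MapConfig:
    max_mismatches: int = 2
    anchor_window: int = 3
    min_len: int = 18
    max_len: int = 24
    tail_max: int = 2

    def __post_init__(self) -> None:
        if min(self.max_mismatches, self.anchor_window, self.tail_max) < 0:
            raise ValueError("MapConfig fields must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


@dataclass
class ReadCall:
    """Classification of one read against one (hairpin, mature) pair."""

    read_id: str
    count: int
    hairpin_id: str
    mature_id: str
    category: str
    offset5: int = 0
    read_length: int = 0
    templated_prefix_len: int = 0
    tail_seq: str = ""
    mismatch_positions_1based: tuple[int, ...] = ()
    multimap_n: int = 1


def _mismatch_positions(read: str, hairpin_seq: str, start: int, cap: int) -> list[int] | None:
    """1-based read positions mismatching the hairpin at placement ``start``.

    Returns None as soon as more than ``cap`` mismatches accumulate.
    Overhang past the hairpin end and any N (either side) count as mismatches.
    """
    H = len(hairpin_seq)
    mm: list[int] = []
    for i, base in enumerate(read):
        p = start + i
        if p < 0 or p >= H or base == "N" or hairpin_seq[p] == "N" or base != hairpin_seq[p]:
            mm.append(i + 1)
            if len(mm) > cap:
                return None
    return mm


def _classify(read: str, mm: Sequence[int], cfg: MapConfig) -> tuple[str, str, int]:
    """(category, tail_seq, templated_prefix_len) from a mismatch pattern."""
    L = len(read)
    k = len(mm)
    if k == 0:
        return "TEMPLATED", "", L
    if mm[-1] == L and k <= cfg.tail_max and list(mm) == list(range(L - k + 1, L + 1)):
        return "NTA", read[L - k:], L - k
    return "INTERNAL_MM", "", 0


def align_anchored(
    read: str,
    hairpin: HairpinRecord,
    mature: MatureAnnotation,
    cfg: MapConfig,
) -> ReadCall:
    """Best anchored placement of ``read`` near ``mature`` on ``hairpin``.

    Candidate starts s satisfy |s - mature.start| <= anchor_window (and
    s >= 0); ties are broken by (mismatch count, |offset5|, s).  A read whose
    every candidate placement exceeds ``max_mismatches`` is UNASSIGNED.
    """
    best: tuple[tuple[int, int, int], list[int]] | None = None
    lo = max(0, mature.start - cfg.anchor_window)
    hi = mature.start + cfg.anchor_window
    for s in range(lo, hi + 1):
        mm = _mismatch_positions(read, hairpin.sequence, s, cfg.max_mismatches)
        if mm is None:
            continue
        key = (len(mm), abs(s - mature.start), s)
        if best is None or key < best[0]:
            best = (key, mm)
    if best is None:
        return ReadCall(
            read_id="", count=1, hairpin_id=hairpin.hairpin_id,
            mature_id=mature.mature_id, category="UNASSIGNED",
            read_length=len(read),
        )
    (n_mm, _, s), mm = best[0], best[1]
    category, tail, prefix = _classify(read, mm, cfg)
    return ReadCall(
        read_id="", count=1,
        hairpin_id=hairpin.hairpin_id, mature_id=mature.mature_id,
        category=category, offset5=s - mature.start, read_length=len(read),
        templated_prefix_len=prefix, tail_seq=tail,
        mismatch_positions_1based=tuple(mm),
    )


def brute_force_oracle(
    read: str,
    hairpin: HairpinRecord,
    mature: MatureAnnotation,
    cfg: MapConfig,
    restrict_window: bool = True,
) -> ReadCall:
    """Exhaustive reference aligner used to certify :func:`align_anchored`.

    Literally enumerates every start on the hairpin (or only the anchor
    window when ``restrict_window``), recounts mismatches position by
    position with no shortcuts, and applies the classification rules
    independently of the production code path.
    """
    candidates: list[tuple[tuple[int, int, int], int, list[int]]] = []
    if restrict_window:
        starts = range(max(0, mature.start - cfg.anchor_window),
                       mature.start + cfg.anchor_window + 1)
    else:
        starts = range(0, len(hairpin.sequence))
    for s in starts:
        mm = []
        for i in range(len(read)):
            p = s + i
            inside = 0 <= p < len(hairpin.sequence)
            if not inside:
                mm.append(i + 1)
            elif read[i] == "N" or hairpin.sequence[p] == "N":
                mm.append(i + 1)
            elif read[i] != hairpin.sequence[p]:
                mm.append(i + 1)
        candidates.append(((len(mm), abs(s - mature.start), s), s, mm))
    candidates = [c for c in candidates if c[0][0] <= cfg.max_mismatches]
    if not candidates:
        return ReadCall("", 1, hairpin.hairpin_id, mature.mature_id,
                        "UNASSIGNED", read_length=len(read))
    key, s, mm = min(candidates, key=lambda c: c[0])
    L = len(read)
    # independent restatement of the category rules
    if not mm:
        category, tail, prefix = "TEMPLATED", "", L
    else:
        suffix_run = 0
        for pos in range(L, 0, -1):
            if pos in mm:
                suffix_run += 1
            else:
                break
        if suffix_run == len(mm) and suffix_run >= 1 and suffix_run <= cfg.tail_max and L in mm:
            category, tail, prefix = "NTA", read[L - suffix_run:], L - suffix_run
        else:
            category, tail, prefix = "INTERNAL_MM", "", 0
    return ReadCall("", 1, hairpin.hairpin_id, mature.mature_id, category,
                    offset5=s - mature.start, read_length=L,
                    templated_prefix_len=prefix, tail_seq=tail,
                    mismatch_positions_1based=tuple(mm))


def classify_library(
    reads: Sequence[CollapsedRead],
    hairpins: Mapping[str, HairpinRecord],
    annotations: Sequence[MatureAnnotation],
    spikes: SpikeInSet | None,
    cfg: MapConfig,
) -> list[ReadCall]:
    """Classify every read against every (hairpin, mature) pair.

    Spike-in sequences are intercepted first (exact match; the spike set's
    ``matched_count`` is incremented by read count).  A read assigned to k>1
    matures receives k calls, each flagged ``multimap_n=k``; a read matching
    nothing receives a single UNASSIGNED call.  Deterministic for
    deterministic inputs.
    """
    ids = [a.mature_id for a in annotations]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate mature_ids in annotation set")
    spike_index = spikes.sequence_index() if spikes is not None else {}
    pairs = [(hairpins[a.hairpin_id], a) for a in annotations]

    cache: dict[str, list[ReadCall]] = {}
    out: list[ReadCall] = []
    for read in reads:
        if read.sequence in spike_index:
            assert spikes is not None
            spikes.matched_count += read.count
            out.append(ReadCall(read.read_id, read.count, "",
                                spike_index[read.sequence], "SPIKEIN",
                                read_length=len(read.sequence)))
            continue
        template = cache.get(read.sequence)
        if template is None:
            hits = []
            for hp, ann in pairs:
                call = align_anchored(read.sequence, hp, ann, cfg)
                if call.category != "UNASSIGNED":
                    hits.append(call)
            if hits:
                for h in hits:
                    h.multimap_n = len(hits)
                template = hits
            else:
                template = [ReadCall("", 1, "", "", "UNASSIGNED",
                                     read_length=len(read.sequence))]
            cache[read.sequence] = template
        for call in template:
            out.append(replace(call, read_id=read.read_id, count=read.count))
    return out


def validate_calls(
    calls: Iterable[ReadCall],
    hairpins: Mapping[str, HairpinRecord],
    cfg: MapConfig,
    sequences: Mapping[str, str] | None = None,
) -> None:
    """Assert the per-category invariants on a call set (raises on violation).

    TEMPLATED calls must be literal hairpin substrings (checked when a
    ``read_id -> sequence`` mapping is supplied); NTA mismatches must form a
    contiguous terminal suffix equal to the tail; INTERNAL_MM must have an
    internal mismatch within budget.  Every read must receive at least one
    call and each call exactly one category from the closed set.
    """
    seen_reads: set[str] = set()
    for c in calls:
        seen_reads.add(c.read_id)
        if c.category not in CATEGORIES:
            raise AssertionError(f"unknown category {c.category!r}")
        seq = sequences.get(c.read_id) if sequences is not None else None
        mm = c.mismatch_positions_1based
        if c.category == "TEMPLATED":
            if mm or c.tail_seq or c.templated_prefix_len != c.read_length:
                raise AssertionError(f"TEMPLATED invariant violated: {c}")
            if seq is not None and seq not in hairpins[c.hairpin_id].sequence:
                raise AssertionError(f"TEMPLATED read not a hairpin substring: {c}")
        elif c.category == "NTA":
            k = len(c.tail_seq)
            if not (1 <= k <= cfg.tail_max):
                raise AssertionError(f"NTA tail length invalid: {c}")
            if list(mm) != list(range(c.read_length - k + 1, c.read_length + 1)):
                raise AssertionError(f"NTA mismatches not a terminal suffix: {c}")
            if c.templated_prefix_len != c.read_length - k:
                raise AssertionError(f"NTA prefix length inconsistent: {c}")
            if seq is not None and not seq.endswith(c.tail_seq):
                raise AssertionError(f"NTA tail is not the read suffix: {c}")
        elif c.category == "INTERNAL_MM":
            if not mm or len(mm) > cfg.max_mismatches or min(mm) >= c.read_length:
                raise AssertionError(f"INTERNAL_MM invariant violated: {c}")
    if sequences is not None and set(sequences) - seen_reads:
        missing = sorted(set(sequences) - seen_reads)[:5]
        raise AssertionError(f"reads without any call, e.g. {missing}")
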