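"""3' adapter trimming and minimum-length filtering of raw small-RNA reads.

The trimmer reproduces the classic 3'-adapter semantics of small-RNA
preprocessing: the leftmost position at which a prefix of the adapter aligns
to the read suffix (within an error budget proportional to the overlap) marks
the insert end; everything from that position on is removed.  Reads shorter
than ``min_length`` after trimming are discarded, with length exactly
``min_length`` kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, TypeVar

T = TypeVar("T")


@dataclass
class TrimConfig:
    adapter: str = ""
    max_adapter_mismatch_rate: float = 0.1
    min_overlap: int = 5
    min_length: int = 18

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_adapter_mismatch_rate <= 1.0:
            raise ValueError("max_adapter_mismatch_rate must be in [0, 1]")
        if self.min_overlap < 3:
            raise ValueError("min_overlap must be >= 3")


def trim_adapter(read_seq: str, cfg: TrimConfig) -> str:
    """Remove a 3' adapter occurrence from ``read_seq``.

    Scans candidate cut positions left to right; at position ``i`` the
    overlap is ``min(len(read) - i, len(adapter))`` and up to
    ``floor(rate * overlap)`` mismatches are tolerated.  The first admissible
    position wins (leftmost match), and the returned value is always a prefix
    of the input — possibly empty, possibly the unchanged read when no
    admissible position exists.  Trimming is idempotent because the removed
    suffix can only be found once.
    """
    adapter = cfg.adapter
    if not adapter:
        return read_seq
    n = len(read_seq)
    for i in range(0, n - cfg.min_overlap + 1):
        overlap = min(n - i, len(adapter))
        if overlap < cfg.min_overlap:
            break
        allowed = int(cfg.max_adapter_mismatch_rate * overlap)
        mismatches = 0
        hit = True
        for j in range(overlap):
            if read_seq[i + j] != adapter[j]:
                mismatches += 1
                if mismatches > allowed:
                    hit = False
                    break
        if hit:
            return read_seq[:i]
    return read_seq


def length_filter(
    items: Iterable[T],
    min_length: int,
    seq_of: Callable[[T], str] = lambda x: x,  # type: ignore[assignment,return-value]
) -> tuple[list[T], int]:
    """Keep items whose sequence is at least ``min_length`` nt.

    Returns ``(kept, n_discarded)``; kept + discarded equals the input
    cardinality.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept: list[T] = []
    discarded = 0
    for item in items:
        if len(seq_of(item)) >= min_length:
            kept.append(item)
        else:
            discarded += 1
    return kept, discarded
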