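"""Summary statistics over read calls: isoform spectra, tail composition,
guide selection, spike-in normalization and the terminal-vs-internal fold.

The quantities here mirror the standard isomiR reporting conventions:
per-miRNA fractions of templated read lengths (18-24 nt), per-position
percentages of mono nontemplated additions (positions 21-24, nucleotides
rendered as U/A/C/G), and a fold statistic contrasting terminal-addition
read counts with the mean single-mismatch count at internal positions —
large folds indicate genuine enzymatic tailing rather than sequencing error,
which would spread mismatches evenly across the read.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import MatureAnnotation, SpikeInSet, to_rna
from .mapper import MapConfig, ReadCall

NTA_NUCLEOTIDES = ("U", "A", "C", "G")
DEFAULT_NTA_POSITIONS = (21, 22, 23, 24)


@dataclass
class GuideFilter:
    min_guide_count: int = 50

    def __post_init__(self) -> None:
        if self.min_guide_count < 0:
            raise ValueError("min_guide_count must be >= 0")


@dataclass
class IsoformSpectrum:
    mature_id: str
    counts: dict[int, float]
    fractions: dict[int, float]

    @property
    def total(self) -> float:
        return sum(self.counts.values())


@dataclass
class NtaProfile:
    mature_id: str
    counts: dict[tuple[int, str], float]
    percentages: dict[tuple[int, str], float]


@dataclass
class FoldReport:
    mature_id: str
    terminal_count: float
    internal_mean: float
    fold: float  # NaN when internal_mean == 0


def _usable(call: ReadCall, unique_only: bool) -> bool:
    return not unique_only or call.multimap_n == 1


def templated_counts(
    calls: Iterable[ReadCall], unique_only: bool = False
) -> Counter:
    """Summed TEMPLATED read count per mature_id."""
    out: Counter = Counter()
    for c in calls:
        if c.category == "TEMPLATED" and _usable(c, unique_only):
            out[c.mature_id] += c.count
    return out


def select_guides(
    calls: Sequence[ReadCall],
    annotations: Sequence[MatureAnnotation],
    filt: GuideFilter,
    unique_only: bool = False,
) -> set[str]:
    """Pick the guide arm per hairpin and apply the read-count cutoff.

    Per hairpin the mature with the larger templated count is the guide
    (ties broken toward the 5' arm, i.e. smaller start); guides are retained
    only with templated count strictly above ``min_guide_count``.  Hairpins
    with zero mapped reads yield no guide.
    """
    counts = templated_counts(calls, unique_only)
    by_hairpin: dict[str, list[MatureAnnotation]] = defaultdict(list)
    for ann in annotations:
        by_hairpin[ann.hairpin_id].append(ann)
    guides: set[str] = set()
    for anns in by_hairpin.values():
        best = max(anns, key=lambda a: (counts.get(a.mature_id, 0), -a.start))
        n = counts.get(best.mature_id, 0)
        if n > filt.min_guide_count:
            guides.add(best.mature_id)
    return guides


def isoform_spectrum(
    calls: Iterable[ReadCall],
    mature_id: str,
    cfg: MapConfig,
    unique_only: bool = False,
) -> IsoformSpectrum:
    """Length spectrum of mismatch-free reads for one mature miRNA.

    Only TEMPLATED calls within [min_len, max_len] are tabulated; fractions
    sum to 1 whenever any read is counted.
    """
    counts: dict[int, float] = {L: 0.0 for L in range(cfg.min_len, cfg.max_len + 1)}
    for c in calls:
        if (
            c.category == "TEMPLATED"
            and c.mature_id == mature_id
            and cfg.min_len <= c.read_length <= cfg.max_len
            and _usable(c, unique_only)
        ):
            counts[c.read_length] += c.count
    total = sum(counts.values())
    fractions = {L: (n / total if total > 0 else math.nan) for L, n in counts.items()}
    return IsoformSpectrum(mature_id, counts, fractions)


def _tabulate_nta(
    calls: Iterable[ReadCall],
    mature_ids: set[str] | None,
    positions: Sequence[int],
    unique_only: bool,
) -> dict[tuple[int, str], float]:
    counts = {(p, nt): 0.0 for p in positions for nt in NTA_NUCLEOTIDES}
    for c in calls:
        if c.category != "NTA" or len(c.tail_seq) != 1:
            continue
        if mature_ids is not None and c.mature_id not in mature_ids:
            continue
        if c.read_length not in positions or not _usable(c, unique_only):
            continue
        counts[(c.read_length, to_rna(c.tail_seq))] += c.count
    return counts


def _percentages(counts: Mapping[tuple[int, str], float], positions: Sequence[int]):
    pct: dict[tuple[int, str], float] = {}
    for p in positions:
        total = sum(counts[(p, nt)] for nt in NTA_NUCLEOTIDES)
        for nt in NTA_NUCLEOTIDES:
            pct[(p, nt)] = 100.0 * counts[(p, nt)] / total if total > 0 else math.nan
    return pct


def nta_profile(
    calls: Iterable[ReadCall],
    mature_id: str,
    positions: Sequence[int] = DEFAULT_NTA_POSITIONS,
    unique_only: bool = False,
) -> NtaProfile:
    """Mono-addition tail composition by terminal position for one miRNA.

    The position is the 1-based read position of the added base (= read
    length for a mono tail); per-position percentages sum to 100 where any
    tail was observed.
    """
    counts = _tabulate_nta(calls, {mature_id}, positions, unique_only)
    return NtaProfile(mature_id, counts, _percentages(counts, positions))


def pooled_nta_profile(
    calls: Iterable[ReadCall],
    mature_ids: Iterable[str],
    positions: Sequence[int] = DEFAULT_NTA_POSITIONS,
    unique_only: bool = False,
) -> NtaProfile:
    """Tail composition pooled over a set of miRNAs (counts summed before
    percentages are taken)."""
    counts = _tabulate_nta(calls, set(mature_ids), positions, unique_only)
    return NtaProfile("(pooled)", counts, _percentages(counts, positions))


def normalize(
    counts: Mapping[str, float],
    spikes: SpikeInSet | None,
    fallback_total: float,
) -> dict[str, float]:
    """Scale counts to per-million units anchored on spike-in reads.

    The factor is 1e6 / spike matched count; libraries without spike matches
    fall back to 1e6 / total classified non-spike reads.  Scaling never
    changes any fraction or percentage.
    """
    matched = spikes.matched_count if spikes is not None else 0
    denom = matched if matched > 0 else fallback_total
    if denom <= 0:
        raise ValueError("nothing to normalize by: no spike matches and zero fallback total")
    factor = 1e6 / denom
    return {k: v * factor for k, v in counts.items()}


def terminal_internal_fold(
    calls: Iterable[ReadCall],
    mature_ids: str | Iterable[str],
    focal_position: int = 23,
    exclude_positions: Sequence[int] = (),
    unique_only: bool = False,
) -> FoldReport:
    """Fold excess of terminal mono-additions over internal single mismatches.

    ``terminal_count`` sums mono-NTA calls whose added base sits at
    ``focal_position`` (read length == focal position).  ``internal_mean``
    averages, over read positions 1..focal_position-1 (minus any excluded),
    the summed counts of INTERNAL_MM calls carrying exactly one mismatch at
    that position.  The fold is their ratio, NaN when no internal mismatch
    was seen.  Pass a collection of mature ids to pool across guide miRNAs.
    """
    ids = {mature_ids} if isinstance(mature_ids, str) else set(mature_ids)
    label = mature_ids if isinstance(mature_ids, str) else "(pooled)"
    internal_positions = [
        p for p in range(1, focal_position) if p not in exclude_positions
    ]
    terminal = 0.0
    per_position = {p: 0.0 for p in internal_positions}
    for c in calls:
        if c.mature_id not in ids or not _usable(c, unique_only):
            continue
        if c.category == "NTA" and len(c.tail_seq) == 1 and c.read_length == focal_position:
            terminal += c.count
        elif c.category == "INTERNAL_MM" and len(c.mismatch_positions_1based) == 1:
            p = c.mismatch_positions_1based[0]
            if p in per_position:
                per_position[p] += c.count
    internal_mean = (
        sum(per_position.values()) / len(internal_positions) if internal_positions else 0.0
    )
    fold = terminal / internal_mean if internal_mean > 0 else math.nan
    return FoldReport(label, terminal, internal_mean, fold)


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------

def spectra_frame(spectra: Sequence[IsoformSpectrum], cfg: MapConfig) -> pd.DataFrame:
    lengths = list(range(cfg.min_len, cfg.max_len + 1))
    rows = {
        s.mature_id: [s.fractions.get(L, math.nan) for L in lengths] for s in spectra
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"len{L}" for L in lengths])
    df.index.name = "mature_id"
    return df


def nta_frame(profiles: Sequence[NtaProfile], positions=DEFAULT_NTA_POSITIONS) -> pd.DataFrame:
    cols = [f"pos{p}_{nt}" for p in positions for nt in NTA_NUCLEOTIDES]
    rows = {
        prof.mature_id: [prof.percentages[(p, nt)] for p in positions for nt in NTA_NUCLEOTIDES]
        for prof in profiles
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "mature_id"
    return df


def fold_frame(reports: Sequence[FoldReport]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.mature_id, r.terminal_count, r.internal_mean, r.fold) for r in reports],
        columns=["mature_id", "terminal_count", "internal_mean", "fold"],
    ).set_index("mature_id")
    return df


def heatmap_matrix(
    spectra_by_sample: Mapping[str, Sequence[IsoformSpectrum]],
    lengths: Sequence[int] = tuple(range(18, 25)),
) -> pd.DataFrame:
    """Fraction matrix rows=miRNA, columns=(sample x length) for heat maps.

    Rows are ordered by descending total templated count across samples
    (then lexicographically); miRNAs absent from a sample keep their row
    with NaN cells.  Rendering to an image is a thin convenience on top of
    this matrix.
    """
    totals: Counter = Counter()
    cells: dict[str, dict[str, float]] = defaultdict(dict)
    for sample, spectra in spectra_by_sample.items():
        for s in spectra:
            totals[s.mature_id] += s.total
            for L in lengths:
                cells[s.mature_id][f"{sample}|len{L}"] = s.fractions.get(L, math.nan)
    order = sorted(cells, key=lambda m: (-totals[m], m))
    columns = [f"{sample}|len{L}" for sample in spectra_by_sample for L in lengths]
    df = pd.DataFrame(
        [[cells[m].get(col, math.nan) for col in columns] for m in order],
        index=order, columns=columns,
    )
    df.index.name = "mature_id"
    return df


def calls_frame(calls: Sequence[ReadCall]) -> pd.DataFrame:
    """Per-read call table with tails rendered in the RNA alphabet."""
    df = pd.DataFrame(
        [
            (
                c.read_id, c.count, c.hairpin_id, c.mature_id, c.category,
                c.offset5, c.read_length, c.templated_prefix_len,
                to_rna(c.tail_seq),
                ",".join(map(str, c.mismatch_positions_1based)),
                c.multimap_n,
            )
            for c in calls
        ],
        columns=[
            "read_id", "count", "hairpin_id", "mature_id", "category",
            "offset5", "read_length", "templated_prefix_len", "tail_seq",
            "mismatch_positions_1based", "multimap_n",
        ],
    ).set_index("read_id")
    return df


def conservation_check(total_input: int, calls: Sequence[ReadCall]) -> None:
    """Every input read must be accounted for exactly once across categories.

    Multimapped calls share one read, so counts are deduplicated by read_id
    before summing.  Raises AssertionError on leakage.
    """
    seen: dict[str, int] = {}
    for c in calls:
        prev = seen.setdefault(c.read_id, c.count)
        if prev != c.count:
            raise AssertionError(f"inconsistent counts for read {c.read_id}")
    total = sum(seen.values())
    if total != total_input:
        raise AssertionError(
            f"read-count conservation violated: {total} classified vs {total_input} input"
        )
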