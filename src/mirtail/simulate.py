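"""Synthetic small-RNA library generator with full per-read ground truth.

The generator emulates the statistical structure of hairpin-derived small-RNA
sequencing libraries: reads are drawn from annotated mature arms with a
length distribution over 18-24 nt, small 5' start offsets, optional mono/di
3' nontemplated tails with a configurable U/A/C/G mix, uniform per-base
sequencing error, a ligated 3' adapter, and a configurable fraction of
spike-in reads.  Every emitted read carries a truth record, which is the
acceptance surface for parameter-recovery testing.

A tail nucleotide that happens to equal the templated hairpin base at its
position is genuinely indistinguishable from a templated extension under the
genome-mismatch definition of a nontemplated addition; such reads are
truth-flagged ``tail_indistinguishable`` rather than forbidden, so recall can
be measured on the well-defined subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (
    HairpinRecord,
    MatureAnnotation,
    SpikeInSet,
    to_rna,
    write_annotation_tsv,
    write_fasta,
    write_fastq,
)

NUCLEOTIDES = ("A", "C", "G", "T")

#: Widely used small-RNA 3' sequencing adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _default_length_weights() -> dict[int, float]:
    return {20: 0.05, 21: 0.10, 22: 0.70, 23: 0.10, 24: 0.05}


def _default_offset_weights() -> dict[int, float]:
    return {-2: 0.025, -1: 0.075, 0: 0.8, 1: 0.075, 2: 0.025}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions.

    ``tail_nt_weights`` accepts RNA (U) or DNA (T) keys; internally DNA.
    """

    seed: int
    n_hairpins: int = 20
    hairpin_len: tuple[int, int] = (60, 90)
    n_reads: int = 50_000
    length_weights: dict[int, float] = field(default_factory=_default_length_weights)
    offset5_weights: dict[int, float] = field(default_factory=_default_offset_weights)
    tail_rate: float = 0.07
    tail_len_weights: dict[int, float] = field(default_factory=lambda: {1: 0.9, 2: 0.1})
    tail_nt_weights: dict[str, float] = field(
        default_factory=lambda: {"T": 0.55, "A": 0.30, "C": 0.10, "G": 0.05}
    )
    error_rate: float = 0.001
    adapter: str | None = DEFAULT_ADAPTER
    spike_fraction: float = 0.02
    n_spikes: int = 4
    spike_len: int = 22
    guide_star_ratio: float = 9.0
    mature_len: int = 22

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.tail_nt_weights = {
            k.upper().replace("U", "T"): v for k, v in self.tail_nt_weights.items()
        }
        for name in ("length_weights", "offset5_weights", "tail_len_weights", "tail_nt_weights"):
            weights = getattr(self, name)
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
        for name in ("tail_rate", "error_rate", "spike_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        # room for a mature on each arm plus the widest offset+length window
        max_len = max(self.length_weights)
        max_off = max(self.offset5_weights)
        min_required = 2 * self.mature_len + (max_off + max_len - self.mature_len) + 12
        if self.hairpin_len[0] < min_required:
            raise ValueError(
                f"hairpin_len lower bound {self.hairpin_len[0]} cannot host two "
                f"mature arms (need >= {min_required})"
            )


@dataclass
class Reference:
    hairpins: dict[str, HairpinRecord]
    annotations: list[MatureAnnotation]
    spikes: SpikeInSet
    guide_arm: dict[str, str]  # hairpin_id -> guide mature_id


TRUTH_COLUMNS = [
    "read_id", "is_spike", "mature_id", "templated_len", "offset5",
    "tail_seq", "tail_indistinguishable", "error_positions_1based",
]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def make_reference(cfg: SimConfig) -> Reference:
    """Random hairpin set with one 5'-arm and one 3'-arm mature each.

    Matures are placed so that every sampled (offset, length) window stays on
    the hairpin: the 5' arm starts at position 4 and the 3' arm ends 6 nt
    from the hairpin end.  The guide arm is drawn at random per hairpin.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(cfg.seed)
    hairpins: dict[str, HairpinRecord] = {}
    annotations: list[MatureAnnotation] = []
    guide_arm: dict[str, str] = {}
    for i in range(cfg.n_hairpins):
        hid = f"hp{i + 1:03d}"
        length = int(rng.integers(cfg.hairpin_len[0], cfg.hairpin_len[1] + 1))
        hairpins[hid] = HairpinRecord(hid, _random_seq(rng, length))
        m5 = MatureAnnotation(f"{hid}-5p", hid, 4, 4 + cfg.mature_len)
        start3 = length - 6 - cfg.mature_len
        m3 = MatureAnnotation(f"{hid}-3p", hid, start3, start3 + cfg.mature_len)
        annotations.extend([m5, m3])
        guide_arm[hid] = m5.mature_id if rng.random() < 0.5 else m3.mature_id
    spikes = SpikeInSet(
        records=[(f"spike{j + 1}", _random_seq(rng, cfg.spike_len)) for j in range(cfg.n_spikes)]
    )
    return Reference(hairpins, annotations, spikes, guide_arm)


def write_reference(reference: Reference, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        [(h.hairpin_id, h.sequence) for h in reference.hairpins.values()],
        outdir / "hairpins.fa",
    )
    write_annotation_tsv(reference.annotations, outdir / "mature.tsv")
    write_fasta(reference.spikes.records, outdir / "spikes.fa")


def generate_library(
    cfg: SimConfig,
    reference: Reference,
    outdir: str | Path | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Emit reads and their truth table; optionally write files.

    Each non-spike read is a templated hairpin window (sampled arm, length
    and 5' offset) plus an optional 3' tail, followed by the adapter;
    uniform substitution errors are then applied across the full emitted
    read (adapter included).  Quality strings are constant — the pipeline
    ignores them.  Byte-identical outputs for a fixed seed.

    When ``outdir`` is given, writes ``hairpins.fa``, ``mature.tsv``,
    ``spikes.fa``, ``reads.fastq.gz`` and ``truth.tsv`` there.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from make_reference
    ann_by_id = {a.mature_id: a for a in reference.annotations}
    n = cfg.n_reads

    lengths = np.array(sorted(cfg.length_weights))
    length_p = np.array([cfg.length_weights[L] for L in lengths])
    offsets = np.array(sorted(cfg.offset5_weights))
    offset_p = np.array([cfg.offset5_weights[o] for o in offsets])
    tail_lens = np.array(sorted(cfg.tail_len_weights))
    tail_len_p = np.array([cfg.tail_len_weights[k] for k in tail_lens])
    tail_nts = np.array(sorted(cfg.tail_nt_weights))
    tail_nt_p = np.array([cfg.tail_nt_weights[nt] for nt in tail_nts])
    hairpin_ids = sorted(reference.hairpins)
    p_guide = cfg.guide_star_ratio / (1.0 + cfg.guide_star_ratio)
    star_arm = {
        hid: next(
            a.mature_id
            for a in reference.annotations
            if a.hairpin_id == hid and a.mature_id != reference.guide_arm[hid]
        )
        for hid in hairpin_ids
    }

    is_spike = rng.random(n) < cfg.spike_fraction
    spike_idx = rng.integers(0, max(1, len(reference.spikes.records)), size=n)
    hp_idx = rng.integers(0, len(hairpin_ids), size=n)
    from_guide = rng.random(n) < p_guide
    length_draw = rng.choice(lengths, size=n, p=length_p)
    offset_draw = rng.choice(offsets, size=n, p=offset_p)
    tailed = rng.random(n) < cfg.tail_rate
    tail_len_draw = rng.choice(tail_lens, size=n, p=tail_len_p)
    tail_base_draw = rng.choice(tail_nts, size=(n, int(tail_lens.max())), p=tail_nt_p)

    reads: list[tuple[str, str, str]] = []
    truth_rows: list[tuple] = []
    adapter = cfg.adapter or ""
    for i in range(n):
        rid = f"r{i:06d}"
        if is_spike[i] and reference.spikes.records:
            sid, insert = reference.spikes.records[spike_idx[i]]
            mature_id, templated_len, off = "", len(insert), 0
            tail, indist = "", False
        else:
            hid = hairpin_ids[hp_idx[i]]
            mature_id = reference.guide_arm[hid] if from_guide[i] else star_arm[hid]
            ann = ann_by_id[mature_id]
            hp_seq = reference.hairpins[hid].sequence
            templated_len = int(length_draw[i])
            off = int(offset_draw[i])
            start = ann.start + off
            end = start + templated_len
            insert = hp_seq[start:end]
            tail, indist = "", False
            if tailed[i]:
                k = int(tail_len_draw[i])
                tail = "".join(tail_base_draw[i, :k])
                for j, base in enumerate(tail):
                    if end + j < len(hp_seq) and hp_seq[end + j] == base:
                        indist = True
                insert = insert + tail
        emitted = insert + adapter
        errs = np.flatnonzero(rng.random(len(emitted)) < cfg.error_rate)
        if errs.size:
            chars = list(emitted)
            for p in errs:
                alternatives = [b for b in NUCLEOTIDES if b != chars[p]]
                chars[p] = alternatives[int(rng.integers(0, 3))]
            emitted = "".join(chars)
        reads.append((rid, emitted, "I" * len(emitted)))
        truth_rows.append(
            (
                rid, bool(is_spike[i] and reference.spikes.records), mature_id,
                templated_len, off, to_rna(tail), indist,
                ",".join(str(p + 1) for p in errs),
            )
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_reference(reference, outdir)
        write_fastq(reads, outdir / "reads.fastq.gz")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return reads, truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def classify_simulated(
    reads: Sequence[tuple[str, str, str]],
    reference: Reference,
    trim_config=None,
    map_config=None,
):
    """Trim, filter and classify simulated reads one by one, keeping ids.

    Identical sequences share cached trim/alignment results, so per-read
    bookkeeping costs little more than collapsed classification.  Reads
    falling below the length floor after trimming receive an UNASSIGNED call
    so that every truth record has a matching call (score_recovery requires
    id parity).
    """
    from .formats import CollapsedRead
    from .mapper import MapConfig, ReadCall, classify_library
    from .preprocess import TrimConfig, trim_adapter

    trim_config = trim_config or TrimConfig(adapter=DEFAULT_ADAPTER)
    map_config = map_config or MapConfig()
    trim_cache: dict[str, str] = {}
    kept: list[CollapsedRead] = []
    dropped: list[ReadCall] = []
    for rid, seq, _ in reads:
        cut = trim_cache.get(seq)
        if cut is None:
            cut = trim_adapter(seq, trim_config) if trim_config.adapter else seq
            trim_cache[seq] = cut
        if len(cut) >= trim_config.min_length:
            kept.append(CollapsedRead(rid, cut))
        else:
            dropped.append(ReadCall(rid, 1, "", "", "UNASSIGNED", read_length=len(cut)))
    calls = classify_library(
        kept, reference.hairpins, reference.annotations, reference.spikes, map_config
    )
    return calls + dropped


def _best_call_per_read(calls, truth_mature: Mapping[str, str]):
    by_read: dict[str, object] = {}
    for c in calls:
        cur = by_read.get(c.read_id)
        if cur is None:
            by_read[c.read_id] = c
        elif c.mature_id == truth_mature.get(c.read_id, ""):
            by_read[c.read_id] = c
    return by_read


def score_recovery(truth: pd.DataFrame, calls: Sequence) -> dict:
    """Compare per-read classifications against the generator's truth.

    ``calls`` must be per-read (one classified unit per original read id;
    multimapped calls are resolved toward the truth mature).  Reads flagged
    ``tail_indistinguishable`` are excluded from NTA precision/recall and
    from the parameter estimates, since their tails are templated under the
    genome-mismatch definition and carry no recoverable signal.

    Returns a dict with a category confusion table, NTA precision/recall on
    distinguishable tails, and estimated vs truth-empirical length weights,
    tail rate and tail nucleotide mix (each with its sample size).
    """
    truth = truth.set_index("read_id", drop=False)
    call_ids = {c.read_id for c in calls}
    missing = set(truth.index) - call_ids
    extra = call_ids - set(truth.index)
    if missing or extra:
        raise ValueError(
            f"read id mismatch between truth and calls "
            f"({len(missing)} missing, {len(extra)} unexpected)"
        )
    if truth.empty:
        return {
            "confusion": {}, "n_reads": 0,
            "nta_precision": float("nan"), "nta_recall": float("nan"),
        }
    best = _best_call_per_read(calls, truth["mature_id"].to_dict())

    confusion: dict[tuple[str, str], int] = {}
    tp = fp = fn = 0
    length_est: dict[int, int] = {}
    length_true: dict[int, int] = {}
    n_eligible = n_called_nta = n_true_tailed = 0
    mix_est: dict[str, int] = {}
    mix_true: dict[str, int] = {}
    for row in truth.itertuples(index=False):
        call = best[row.read_id]
        truth_cat = (
            "SPIKEIN" if row.is_spike
            else "TAIL_COINCIDENT" if row.tail_indistinguishable
            else "TAILED" if row.tail_seq
            else "UNTAILED"
        )
        key = (truth_cat, call.category)
        confusion[key] = confusion.get(key, 0) + 1
        if row.is_spike or row.tail_indistinguishable:
            continue
        n_eligible += 1
        called_nta = call.category == "NTA"
        truly_tailed = bool(row.tail_seq)
        n_called_nta += called_nta
        n_true_tailed += truly_tailed
        tp += called_nta and truly_tailed
        fp += called_nta and not truly_tailed
        fn += (not called_nta) and truly_tailed
        if call.category == "TEMPLATED":
            length_est[call.read_length] = length_est.get(call.read_length, 0) + 1
        if not truly_tailed:
            length_true[row.templated_len] = length_true.get(row.templated_len, 0) + 1
        if called_nta and len(call.tail_seq) == 1:
            nt = to_rna(call.tail_seq)
            mix_est[nt] = mix_est.get(nt, 0) + 1
        if truly_tailed and len(row.tail_seq) == 1:
            mix_true[row.tail_seq] = mix_true.get(row.tail_seq, 0) + 1

    def _normed(d: Mapping, keys) -> dict:
        total = sum(d.values())
        return {k: (d.get(k, 0) / total if total else float("nan")) for k in keys}

    lengths = sorted(set(length_est) | set(length_true))
    nts = sorted(set(mix_est) | set(mix_true))
    return {
        "confusion": {f"{t}->{c}": n for (t, c), n in sorted(confusion.items())},
        "n_reads": int(len(truth)),
        "n_eligible": n_eligible,
        "nta_precision": tp / (tp + fp) if (tp + fp) else float("nan"),
        "nta_recall": tp / (tp + fn) if (tp + fn) else float("nan"),
        "est_length_weights": _normed(length_est, lengths),
        "true_length_weights": _normed(length_true, lengths),
        "n_templated_est": sum(length_est.values()),
        "est_tail_rate": n_called_nta / n_eligible if n_eligible else float("nan"),
        "true_tail_rate": n_true_tailed / n_eligible if n_eligible else float("nan"),
        "est_tail_nt_weights": _normed(mix_est, nts),
        "true_tail_nt_weights": _normed(mix_true, nts),
        "n_mono_tails_est": sum(mix_est.values()),
    }


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["hairpin_len"] = list(cfg.hairpin_len)
    return d
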