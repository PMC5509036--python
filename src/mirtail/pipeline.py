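"""End-to-end orchestration: preprocess -> classify -> statistics.

``run_pipeline`` composes the library modules into the standard analysis
order, enforcing read-count conservation between every pair of adjacent
stages and recording configuration, input checksums and stage tallies in a
``run_manifest.json``.  The manifest is deterministic so that two runs on
identical inputs produce byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from collections import Counter

from .formats import (
    CollapsedRead,
    SpikeInSet,
    read_collapsed_fasta,
    read_fastq,
    read_hairpins,
    read_annotation_tsv,
    read_spike_fasta,
    write_count_table,
)
from .mapper import MapConfig, classify_library
from .preprocess import TrimConfig, length_filter, trim_adapter
from .stats import (
    GuideFilter,
    calls_frame,
    fold_frame,
    heatmap_matrix,
    isoform_spectrum,
    nta_frame,
    nta_profile,
    normalize,
    pooled_nta_profile,
    select_guides,
    spectra_frame,
    templated_counts,
    terminal_internal_fold,
)

log = logging.getLogger("mirtail")

OUTPUT_FILES = (
    "read_calls.tsv",
    "isoform_spectrum.tsv",
    "nta_profile.tsv",
    "nta_pooled.tsv",
    "fold_report.tsv",
    "heatmap_matrix.tsv",
    "run_manifest.json",
)


@dataclass
class RunConfig:
    reads: Path
    hairpins: Path
    annotation: Path
    outdir: Path
    spikes: Path | None = None
    trim: TrimConfig = field(default_factory=TrimConfig)
    map: MapConfig = field(default_factory=MapConfig)
    guide: GuideFilter = field(default_factory=GuideFilter)
    focal_position: int = 23
    unique_only: bool = False
    sample_name: str = "sample"

    def __post_init__(self) -> None:
        for name in ("reads", "hairpins", "annotation", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.spikes is not None:
            self.spikes = Path(self.spikes)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(cfg: RunConfig) -> list[str]:
    """Dry-run cross-check of the input files; returns a list of problems."""
    problems: list[str] = []
    for name in ("reads", "hairpins", "annotation"):
        path = getattr(cfg, name)
        if not Path(path).exists():
            problems.append(f"missing {name} file: {path}")
    if cfg.spikes is not None and not cfg.spikes.exists():
        problems.append(f"missing spikes file: {cfg.spikes}")
    if problems:
        return problems
    try:
        hairpins = read_hairpins(cfg.hairpins)
        read_annotation_tsv(cfg.annotation, hairpins)
        if cfg.spikes is not None:
            read_spike_fasta(cfg.spikes)
    except Exception as exc:  # surfaced as report entries, not a crash
        problems.append(str(exc))
    return problems


def _load_reads(path: Path) -> list[tuple[str, str, int]]:
    """(id, sequence, count) triples; FASTQ reads count 1 each, collapsed
    FASTA honours the `_xN` id convention."""
    suffixes = [s for s in path.suffixes if s != ".gz"]
    ext = suffixes[-1] if suffixes else ""
    if ext in (".fa", ".fasta"):
        return [(r.read_id, r.sequence, r.count) for r in read_collapsed_fasta(path)]
    return [(rid, seq, 1) for rid, seq, _ in read_fastq(path)]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run preprocess -> classify -> stats, writing all output tables.

    Returns the manifest dict.  Raises on any validation failure; read-count
    conservation is asserted at every stage boundary.
    """
    problems = validate_inputs(cfg)
    if problems:
        raise FileNotFoundError("; ".join(problems))
    cfg.outdir.mkdir(parents=True, exist_ok=True)

    hairpins = read_hairpins(cfg.hairpins)
    annotations = read_annotation_tsv(cfg.annotation, hairpins)
    spikes = read_spike_fasta(cfg.spikes) if cfg.spikes is not None else SpikeInSet()

    raw = _load_reads(cfg.reads)
    n_raw = sum(n for _, _, n in raw)
    log.info("loaded %d raw reads (%d records)", n_raw, len(raw))

    if cfg.trim.adapter:
        trim_cache: dict[str, str] = {}
        trimmed = []
        for rid, seq, n in raw:
            cut = trim_cache.get(seq)
            if cut is None:
                cut = trim_adapter(seq, cfg.trim)
                trim_cache[seq] = cut
            trimmed.append((rid, cut, n))
    else:
        trimmed = raw
    kept, _ = length_filter(trimmed, cfg.trim.min_length, seq_of=lambda t: t[1])
    n_kept = sum(n for _, _, n in kept)
    n_discarded = n_raw - n_kept
    log.info("kept %d reads (%d discarded < %d nt)", n_kept, n_discarded, cfg.trim.min_length)

    weighted: Counter = Counter()
    for _, seq, n in kept:
        weighted[seq] += n
    collapsed = [
        CollapsedRead(f"seq{i}_x{n}", seq, n)
        for i, (seq, n) in enumerate(
            sorted(weighted.items(), key=lambda kv: (-kv[1], kv[0])), start=1
        )
    ]
    assert sum(r.count for r in collapsed) == n_kept, "collapse stage lost reads"

    calls = classify_library(collapsed, hairpins, annotations, spikes, cfg.map)
    seen = {}
    for c in calls:
        seen[c.read_id] = c.count
    assert sum(seen.values()) == n_kept, "classification stage lost reads"

    n_spike = spikes.matched_count
    fallback_total = n_kept - n_spike

    guides = select_guides(calls, annotations, cfg.guide, cfg.unique_only)
    guide_order = sorted(guides)
    spectra = [isoform_spectrum(calls, m, cfg.map, cfg.unique_only) for m in guide_order]
    profiles = [nta_profile(calls, m, unique_only=cfg.unique_only) for m in guide_order]
    pooled = pooled_nta_profile(calls, guides, unique_only=cfg.unique_only)
    folds = [
        terminal_internal_fold(calls, m, cfg.focal_position, unique_only=cfg.unique_only)
        for m in guide_order
    ]
    folds.append(
        terminal_internal_fold(calls, guides, cfg.focal_position, unique_only=cfg.unique_only)
    )
    norm_counts = (
        normalize(templated_counts(calls, cfg.unique_only), spikes, fallback_total)
        if fallback_total > 0 or n_spike > 0
        else {}
    )

    write_count_table(calls_frame(calls), cfg.outdir / "read_calls.tsv")
    spec_df = spectra_frame(spectra, cfg.map)
    spec_df["templated_count"] = [s.total for s in spectra]
    spec_df["normalized_per_million"] = [
        norm_counts.get(m, float("nan")) for m in guide_order
    ]
    write_count_table(spec_df, cfg.outdir / "isoform_spectrum.tsv")
    write_count_table(nta_frame(profiles), cfg.outdir / "nta_profile.tsv")
    write_count_table(nta_frame([pooled]), cfg.outdir / "nta_pooled.tsv")
    write_count_table(fold_frame(folds), cfg.outdir / "fold_report.tsv")
    write_count_table(
        heatmap_matrix({cfg.sample_name: spectra}), cfg.outdir / "heatmap_matrix.tsv"
    )

    manifest = {
        "package_version": __version__,
        "config": {
            "reads": str(cfg.reads),
            "hairpins": str(cfg.hairpins),
            "annotation": str(cfg.annotation),
            "spikes": str(cfg.spikes) if cfg.spikes else None,
            "trim": asdict(cfg.trim),
            "map": asdict(cfg.map),
            "guide": asdict(cfg.guide),
            "focal_position": cfg.focal_position,
            "unique_only": cfg.unique_only,
            "sample_name": cfg.sample_name,
        },
        "input_sha256": {
            name: _sha256(getattr(cfg, name))
            for name in ("reads", "hairpins", "annotation")
        }
        | ({"spikes": _sha256(cfg.spikes)} if cfg.spikes else {}),
        "counts": {
            "raw_reads": n_raw,
            "discarded_short": n_discarded,
            "kept_reads": n_kept,
            "unique_sequences": len(collapsed),
            "spike_reads": n_spike,
            "classified_reads": sum(seen.values()),
            "n_guides": len(guides),
        },
    }
    with open(cfg.outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
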