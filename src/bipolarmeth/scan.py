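"""Genome-wide scan: filters, per-segment detection and region merging.

The scan consumes an epiread file, drops segments below the coverage floor,
removes segments overlapping known allele-specific-methylation (ASM)
intervals, runs the two-step bipolar detector on the rest and merges runs of
consecutive bipolar segments into bipolar methylated regions.  Stage counts
are conserved (input = tested + low_coverage + asm_overlap) and the whole
scan is deterministic given the seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import false_discovery_control

from .detect import detect_bipolar
from .dpm import DpmConfig
from .io import SegmentReadMatrix, SegmentRecord, read_epireads

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "BipolarRegion",
    "read_bed_intervals",
    "filter_asm",
    "run_genome_scan",
    "merge_bipolar_regions",
    "compare_with_paired_dm",
]


@dataclass(frozen=True)
class ScanConfig:
    """Settings of a genome scan (defaults are the recommended analysis)."""

    n: int = 4
    min_coverage: int = 10
    delta: float = 0.35
    tau: float = 0.32
    alpha_level: float = 0.05
    permutations: int = 999
    asm_bed: str | None = None
    mtc: str = "none"  # "none" | "bh"
    seed: int = 0
    fallback_min_reads: int = 10
    dpm: DpmConfig = field(default_factory=DpmConfig)

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.mtc not in ("none", "bh"):
            raise ValueError("mtc must be 'none' or 'bh'")


@dataclass
class BipolarRegion:
    """Maximal run of consecutive bipolar segments merged into one region."""

    chrom: str
    start: int
    end: int
    segment_ids: list[str]
    min_p_value: float
    n_segments: int


def read_bed_intervals(path) -> dict[str, IntervalTree]:
    """Load BED intervals (first three columns) into per-chromosome trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                continue
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def filter_asm(
    segments: list[SegmentReadMatrix], asm_bed
) -> tuple[list[SegmentReadMatrix], list[SegmentReadMatrix]]:
    """Split segments into (kept, removed) by ASM-interval overlap.

    A segment is removed iff any of its CpG positions falls inside any ASM
    interval (half-open, point query on the position of the C).  A missing or
    None BED path is a no-op with a warning.
    """
    if asm_bed is None:
        return list(segments), []
    try:
        trees = read_bed_intervals(asm_bed)
    except FileNotFoundError:
        warnings.warn(f"ASM BED {asm_bed!r} not found; no filtering", stacklevel=2)
        return list(segments), []
    kept, removed = [], []
    for seg in segments:
        tree = trees.get(seg.chrom)
        hit = tree is not None and any(tree[int(p)] for p in seg.cpg_positions)
        (removed if hit else kept).append(seg)
    return kept, removed


def run_genome_scan(
    epireads, config: ScanConfig | None = None
) -> tuple[list[SegmentRecord], list[BipolarRegion]]:
    """Full pipeline: coverage filter, ASM filter, detection, merging.

    ``epireads`` is an epiread TSV path or a pre-built list of
    :class:`SegmentReadMatrix`.  Returns the per-segment records (sorted by
    chrom, start) and the merged bipolar regions.  With ``config.mtc='bh'``
    calls are made on Benjamini-Hochberg-adjusted p-values across all tested
    segments instead of raw ones.
    """
    config = config or ScanConfig()
    if isinstance(epireads, (str, bytes)) or hasattr(epireads, "__fspath__"):
        segments = read_epireads(epireads)
    else:
        segments = sorted(epireads, key=lambda s: (s.chrom, s.start))

    kept, asm_removed = filter_asm(segments, config.asm_bed)
    asm_ids = {id(s) for s in asm_removed}

    records: list[SegmentRecord] = []
    tested: list[tuple[int, float]] = []  # (record index, p)
    # one independent, deterministic RNG stream per input segment
    children = np.random.SeedSequence(config.seed).spawn(max(len(segments), 1))
    n_low = 0
    for seg, child in zip(segments, children):
        base = dict(
            chrom=seg.chrom,
            start=seg.start,
            end=seg.end,
            coverage=seg.m,
            cpg_positions=tuple(int(p) for p in seg.cpg_positions),
        )
        if id(seg) in asm_ids:
            records.append(
                SegmentRecord(status="untested", filtered_reason="asm_overlap", **base)
            )
            continue
        if seg.m < config.min_coverage:
            n_low += 1
            records.append(
                SegmentRecord(status="untested", filtered_reason="low_coverage", **base)
            )
            continue
        result = detect_bipolar(
            seg,
            delta=config.delta,
            tau=config.tau,
            permutations=config.permutations,
            dpm_config=config.dpm,
            fallback_min_reads=config.fallback_min_reads,
            significance_level=config.alpha_level,
            rng=np.random.default_rng(child),
        )
        status = "bipolar" if result.call else "non_bipolar"
        records.append(SegmentRecord(status=status, p_value=result.p_value, **base))
        tested.append((len(records) - 1, result.p_value))

    if config.mtc == "bh" and tested:
        qs = false_discovery_control([p for _, p in tested], method="bh")
        for (idx, _), q in zip(tested, qs):
            records[idx].status = (
                "bipolar" if q <= config.alpha_level else "non_bipolar"
            )

    logger.info(
        "scan: %d segments -> %d tested, %d low_coverage, %d asm_overlap",
        len(segments),
        len(tested),
        n_low,
        len(asm_removed),
    )
    regions = merge_bipolar_regions(records)
    return records, regions


def merge_bipolar_regions(records: list[SegmentRecord]) -> list[BipolarRegion]:
    """Merge runs of consecutive bipolar segments into regions.

    Consecutive means adjacent in (chrom, start) order with no *tested*
    non-bipolar segment in between; untested (filtered) segments neither
    break a run nor extend a region's coordinates.  Idempotent in the sense
    that the produced regions cover exactly the bipolar segments.
    """
    regions: list[BipolarRegion] = []
    current: list[SegmentRecord] = []

    def flush() -> None:
        if current:
            regions.append(
                BipolarRegion(
                    chrom=current[0].chrom,
                    start=min(r.start for r in current),
                    end=max(r.end for r in current),
                    segment_ids=[r.segment_id for r in current],
                    min_p_value=min(r.p_value for r in current),
                    n_segments=len(current),
                )
            )
            current.clear()

    prev_chrom = None
    for rec in sorted(records, key=lambda r: (r.chrom, r.start)):
        if rec.chrom != prev_chrom:
            flush()
            prev_chrom = rec.chrom
        if rec.status == "bipolar":
            current.append(rec)
        elif rec.status == "non_bipolar":
            flush()
        # untested: neither breaks nor extends
    flush()
    return regions


def compare_with_paired_dm(
    pooled_calls: set,
    dm_calls: set,
    per_sample_calls: dict[str, set] | None = None,
    universe: set | None = None,
) -> dict:
    """Overlap summary between pooled bipolar calls and paired-sample DM calls.

    All call sets are segment-id sets on a common universe; when ``universe``
    is given, sets exceeding it are restricted to it with a warning.  Returns
    counts of each set, the pooled/DM intersection, the DM-recovery fraction
    (the headline consistency number) and, per extra sample set, its overlap
    with the pooled calls.
    """
    pooled = set(pooled_calls)
    dm = set(dm_calls)
    per_sample = {k: set(v) for k, v in (per_sample_calls or {}).items()}
    if universe is not None:
        universe = set(universe)
        allsets = {"pooled": pooled, "dm": dm, **per_sample}
        for name, s in allsets.items():
            extra = s - universe
            if extra:
                warnings.warn(
                    f"{name}: {len(extra)} calls outside universe dropped",
                    stacklevel=2,
                )
        pooled &= universe
        dm &= universe
        per_sample = {k: v & universe for k, v in per_sample.items()}
    out = {
        "n_pooled": len(pooled),
        "n_dm": len(dm),
        "n_overlap": len(pooled & dm),
        "dm_recovery": (len(pooled & dm) / len(dm)) if dm else float("nan"),
    }
    for name, calls in per_sample.items():
        out[f"n_{name}"] = len(calls)
        out[f"{name}_in_pooled"] = (
            len(calls & pooled) / len(calls) if calls else float("nan")
        )
    return out
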