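"""Domain types and plain-text I/O for read-level methylation data.

The central container is :class:`SegmentReadMatrix`: the binary m x n matrix of
methylation states for the m sequence reads that fully cover a genomic segment
of n CpG sites.  Segments, per-read "epiread" records and BED output all use
0-based half-open genomic coordinates.

Epiread TSV format (no header, ``#`` comment lines allowed)::

    chrom <TAB> cpg_positions(comma-joined ints) <TAB> read_id <TAB> pattern

where ``pattern`` is a string over ``{0, 1, .}`` with one character per CpG
position; ``.`` marks a site not covered by the read.  Reads with any ``.``
inside a segment are dropped from that segment's matrix (the model requires
full coverage), and the number of dropped reads is logged.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentReadMatrix",
    "SegmentRecord",
    "OriginModel",
    "EpireadFormatError",
    "read_epireads",
    "write_epireads",
    "extract_segments",
    "write_segment_bed",
    "read_segment_bed",
]


class EpireadFormatError(ValueError):
    """A malformed record in an epiread TSV (carries the 1-based line number)."""


@dataclass
class SegmentReadMatrix:
    """Binary methylation states of ``m`` reads over ``n`` CpG sites.

    Parameters
    ----------
    chrom
        Chromosome name.
    cpg_positions
        Strictly increasing genomic coordinates (0-based) of the n CpG sites
        (position of the C on the plus strand).
    reads
        ``(m, n)`` array with entries in {0, 1}; row i is the methylation
        pattern of read i (1 = methylated).
    read_ids
        ``m`` opaque read identifiers.
    """

    chrom: str
    cpg_positions: np.ndarray
    reads: np.ndarray
    read_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.cpg_positions = np.asarray(self.cpg_positions, dtype=np.int64)
        self.reads = np.asarray(self.reads, dtype=np.int8)
        if self.reads.ndim != 2:
            raise ValueError("reads must be a 2-D matrix")
        if self.cpg_positions.ndim != 1 or self.cpg_positions.size < 1:
            raise ValueError("need at least one CpG position")
        if self.reads.shape[1] != self.cpg_positions.size:
            raise ValueError("reads and cpg_positions disagree on n")
        if np.any(np.diff(self.cpg_positions) <= 0):
            raise ValueError("cpg_positions must be strictly increasing")
        if not np.isin(self.reads, (0, 1)).all():
            raise ValueError("methylation states must be 0/1")
        if self.read_ids is None:
            self.read_ids = [f"r{i}" for i in range(self.reads.shape[0])]
        if len(self.read_ids) != self.reads.shape[0]:
            raise ValueError("read_ids length must equal m")

    @property
    def m(self) -> int:
        return self.reads.shape[0]

    @property
    def n(self) -> int:
        return self.reads.shape[1]

    @property
    def start(self) -> int:
        return int(self.cpg_positions[0])

    @property
    def end(self) -> int:
        # half-open end covering the last CpG dinucleotide (C and G)
        return int(self.cpg_positions[-1]) + 2

    @property
    def segment_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def pattern_strings(self) -> list[str]:
        return ["".join("1" if x else "0" for x in row) for row in self.reads]


@dataclass
class SegmentRecord:
    """Outcome of testing (or filtering) one segment in a genome scan."""

    chrom: str
    start: int
    end: int
    coverage: int
    status: str  # "bipolar" | "non_bipolar" | "untested"
    p_value: float | None = None
    filtered_reason: str = "none"  # "none" | "low_coverage" | "asm_overlap"
    cpg_positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.status not in ("bipolar", "non_bipolar", "untested"):
            raise ValueError(f"bad status {self.status!r}")
        if self.filtered_reason not in ("none", "low_coverage", "asm_overlap"):
            raise ValueError(f"bad filtered_reason {self.filtered_reason!r}")
        if self.status == "untested":
            if self.p_value is not None:
                raise ValueError("untested segments carry no p-value")
        else:
            if self.p_value is None or not (0.0 < self.p_value <= 1.0):
                raise ValueError("tested segments need p_value in (0, 1]")

    @property
    def segment_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class OriginModel:
    """Hierarchical origin model for the reads of one segment.

    Reads derive from ``k`` genomic origins (alleles or cell types); origin l
    has a per-site methylation-probability vector ``P[:, l]`` and reads pick
    their origin independently with proportions ``q``.  Given its origin, a
    read's sites are independent Bernoulli draws.  Bipolar methylation is the
    k=2 special case with one hyper- and one hypo-methylated origin.
    """

    P: np.ndarray  # (n, k) per-site methylation probabilities
    q: np.ndarray  # (k,) origin proportions

    def __post_init__(self) -> None:
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        self.q = np.asarray(self.q, dtype=float)
        if self.P.ndim != 2:
            raise ValueError("P must be n x k")
        if self.q.shape != (self.P.shape[1],):
            raise ValueError("q length must equal number of origins")
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise ValueError("methylation probabilities must lie in [0, 1]")
        if np.any(self.q < 0) or not math.isclose(self.q.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("q must be a probability vector")

    @property
    def k(self) -> int:
        return self.P.shape[1]

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def sample(self, m: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``m`` reads; returns ``(reads, origins)``.

        ``origins[i]`` is the index of the origin read i was drawn from
        (the arg of the multinomial origin indicator).
        """
        origins = rng.choice(self.k, size=m, p=self.q)
        theta = self.P.T[origins]  # (m, n)
        reads = (rng.random(theta.shape) < theta).astype(np.int8)
        return reads, origins


# ---------------------------------------------------------------------------
# epiread TSV
# ---------------------------------------------------------------------------

def read_epireads(path) -> list[SegmentReadMatrix]:
    """Parse an epiread TSV into one :class:`SegmentReadMatrix` per segment.

    Records are grouped by ``(chrom, cpg_positions)``; reads whose pattern
    contains ``.`` at any of the segment's sites are dropped (and counted in a
    log message).  Matrices are returned sorted by ``(chrom, start)``.
    """
    groups: dict[tuple[str, tuple[int, ...]], list[tuple[str, str]]] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise EpireadFormatError(
                    f"line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_str, read_id, pattern = fields
            try:
                positions = tuple(int(p) for p in pos_str.split(","))
            except ValueError as exc:
                raise EpireadFormatError(f"line {lineno}: bad positions {pos_str!r}") from exc
            if set(pattern) - set("01."):
                raise EpireadFormatError(f"line {lineno}: bad pattern {pattern!r}")
            if len(pattern) != len(positions):
                raise EpireadFormatError(
                    f"line {lineno}: pattern length {len(pattern)} != "
                    f"{len(positions)} positions"
                )
            if "." in pattern:
                n_dropped += 1
                continue
            groups.setdefault((chrom, positions), []).append((read_id, pattern))
    if n_dropped:
        logger.info("read_epireads: dropped %d reads with uncovered sites", n_dropped)

    out = []
    for (chrom, positions), recs in groups.items():
        reads = np.array([[int(c) for c in pat] for _, pat in recs], dtype=np.int8)
        out.append(
            SegmentReadMatrix(
                chrom=chrom,
                cpg_positions=np.array(positions),
                reads=reads,
                read_ids=[rid for rid, _ in recs],
            )
        )
    out.sort(key=lambda s: (s.chrom, s.start))
    return out


def write_epireads(segments: list[SegmentReadMatrix], path) -> None:
    """Write segments back to epiread TSV (inverse of :func:`read_epireads`)."""
    with open(path, "w") as fh:
        for seg in segments:
            pos_str = ",".join(str(int(p)) for p in seg.cpg_positions)
            for rid, pat in zip(seg.read_ids, seg.pattern_strings()):
                fh.write(f"{seg.chrom}\t{pos_str}\t{rid}\t{pat}\n")


# ---------------------------------------------------------------------------
# segment extraction from per-CpG calls
# ---------------------------------------------------------------------------

def extract_segments(
    per_read_calls: pd.DataFrame,
    n: int = 4,
    mode: str = "tiling",
) -> list[SegmentReadMatrix]:
    """Window per-CpG methylation calls into n-CpG segment matrices.

    Parameters
    ----------
    per_read_calls
        DataFrame with columns ``read_id``, ``chrom``, ``cpg_pos``, ``state``
        (0/1).  CpG calls are assumed already collapsed onto the plus-strand C.
    n
        Segment length in CpG sites (>= 2); every n neighboring CpGs on a
        chromosome form one segment.
    mode
        ``"tiling"`` (non-overlapping, default) or ``"sliding"`` (step 1).

    Only reads covering *all* n sites of a window contribute to that window's
    matrix; windows left with no fully-covering read are omitted.
    """
    if n < 2:
        raise ValueError("segment length n must be >= 2")
    if mode not in ("tiling", "sliding"):
        raise ValueError("mode must be 'tiling' or 'sliding'")
    required = {"read_id", "chrom", "cpg_pos", "state"}
    if not required.issubset(per_read_calls.columns):
        raise ValueError(f"per_read_calls needs columns {sorted(required)}")

    out: list[SegmentReadMatrix] = []
    for chrom, sub in per_read_calls.groupby("chrom", sort=True):
        positions = np.sort(sub["cpg_pos"].unique())
        if positions.size < n:
            warnings.warn(
                f"chromosome {chrom}: only {positions.size} CpGs (< n={n}); no segments",
                stacklevel=2,
            )
            continue
        pivot = sub.pivot_table(
            index="read_id", columns="cpg_pos", values="state", aggfunc="first"
        )
        pivot = pivot.reindex(columns=positions)
        if mode == "tiling":
            starts = range(0, (positions.size // n) * n, n)
        else:
            starts = range(0, positions.size - n + 1)
        for s in starts:
            win = positions[s : s + n]
            block = pivot[win]
            full = block.notna().all(axis=1)
            if not full.any():
                continue
            block = block.loc[full]
            out.append(
                SegmentReadMatrix(
                    chrom=str(chrom),
                    cpg_positions=win,
                    reads=block.to_numpy(dtype=np.int8),
                    read_ids=[str(r) for r in block.index],
                )
            )
    out.sort(key=lambda s: (s.chrom, s.start))
    return out


# ---------------------------------------------------------------------------
# BED output
# ---------------------------------------------------------------------------

def _bed_score(p: float | None) -> int:
    if p is None or p >= 1.0:
        return 0
    return min(1000, int(round(-10.0 * math.log10(p))))


def write_segment_bed(records: list[SegmentRecord], path) -> None:
    """Write segment records as BED6+ (sorted by chrom, start).

    Columns: chrom, start, end, name, score (-10*log10 p, capped at 1000),
    strand '.', then p_value, status, coverage, filtered_reason and the
    comma-joined CpG positions.
    """
    recs = sorted(records, key=lambda r: (r.chrom, r.start))
    with open(path, "w") as fh:
        for r in recs:
            p_str = "NA" if r.p_value is None else f"{r.p_value:.6g}"
            pos_str = (
                "NA"
                if r.cpg_positions is None
                else ",".join(str(p) for p in r.cpg_positions)
            )
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.segment_id,
                        str(_bed_score(r.p_value)),
                        ".",
                        p_str,
                        r.status,
                        str(r.coverage),
                        r.filtered_reason,
                        pos_str,
                    ]
                )
                + "\n"
            )


def read_segment_bed(path) -> list[SegmentRecord]:
    """Parse a BED file written by :func:`write_segment_bed`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                SegmentRecord(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    p_value=None if f[6] == "NA" else float(f[6]),
                    status=f[7],
                    coverage=int(f[8]),
                    filtered_reason=f[9],
                    cpg_positions=(
                        None
                        if f[10] == "NA"
                        else tuple(int(p) for p in f[10].split(","))
                    ),
                )
            )
    return out
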