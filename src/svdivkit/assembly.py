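"""Assembly summary statistics, N-gap closure, and non-reference-sequence
(NRS) classification.

An assembled genome is evaluated three ways: contiguity (Nx statistics and
gap content), its ability to span and thereby close N-gaps in a reference
genome, and the archaic-hominin sharing status of its non-reference
segments, judged from the coverage of archaic reads mapped onto them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .compare import DEFAULT_INS_MIN_LEN_RATIO, DEFAULT_INS_WINDOW
from .core import GenomicElement
from .errors import ValidationError

MIN_GAP_RUN = 10
MIN_FLANK = 50


# ---------------------------------------------------------------------------
# Contiguity
# ---------------------------------------------------------------------------

def nx(lengths: Sequence[int], x: int = 50) -> int:
    """Nx statistic: smallest length L such that sequences >= L hold x% of
    the total assembly span (N50 at x=50)."""
    if not lengths:
        raise ValidationError("Nx of an empty length list is undefined")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if np.any(arr <= 0):
        raise ValidationError("sequence lengths must be positive")
    target = arr.sum() * x / 100.0
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, target, side="left"))
    return int(arr[min(idx, arr.size - 1)])


@dataclass
class AssemblyStats:
    n_scaffolds: int
    n_contigs: int
    total_bases: int
    non_n_bases: int
    gap_count: int
    gap_length: int
    scaffold_n50: int
    contig_n50: int
    scaffold_lengths: list[int] = field(default_factory=list)
    contig_lengths: list[int] = field(default_factory=list)


def _n_runs(seq: str) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of N in an upper-cased sequence."""
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def assembly_stats(
    sequences: Mapping[str, str], min_gap_run: int = MIN_GAP_RUN
) -> AssemblyStats:
    """Scaffold/contig statistics from sequences.

    A reported gap is a maximal N run of at least ``min_gap_run`` bases;
    shorter N runs are treated as local ambiguity.  Contigs are obtained by
    splitting scaffolds at every N run, so the sum of contig lengths equals
    the non-N base count exactly.  Non-nucleotide characters are counted as
    N with a warning.
    """
    if not sequences:
        raise ValidationError("assembly_stats needs at least one sequence")
    scaffold_lengths: list[int] = []
    contig_lengths: list[int] = []
    gap_count = 0
    gap_length = 0
    non_n = 0
    total = 0
    for name, seq in sequences.items():
        s = seq.upper()
        bad = sum(1 for ch in s if ch not in "ACGTN")
        if bad:
            warnings.warn(
                f"{name}: {bad} non-nucleotide characters counted as N",
                stacklevel=2,
            )
            s = "".join(ch if ch in "ACGTN" else "N" for ch in s)
        total += len(s)
        runs = _n_runs(s)
        for rs, re in runs:
            if re - rs >= min_gap_run:
                gap_count += 1
                gap_length += re - rs
        # split at every N run: conserves non-N bases exactly
        prev = 0
        for rs, re in runs:
            if rs > prev:
                contig_lengths.append(rs - prev)
            prev = re
        if len(s) > prev:
            contig_lengths.append(len(s) - prev)
        non_n += len(s) - sum(re - rs for rs, re in runs)
        scaffold_lengths.append(len(s))
    return AssemblyStats(
        n_scaffolds=len(scaffold_lengths),
        n_contigs=len(contig_lengths),
        total_bases=total,
        non_n_bases=non_n,
        gap_count=gap_count,
        gap_length=gap_length,
        scaffold_n50=nx(scaffold_lengths, 50),
        contig_n50=nx(contig_lengths, 50) if contig_lengths else 0,
        scaffold_lengths=scaffold_lengths,
        contig_lengths=contig_lengths,
    )


def assembly_stats_from_fasta(path: str | Path,
                              min_gap_run: int = MIN_GAP_RUN) -> AssemblyStats:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return assembly_stats(seqs, min_gap_run=min_gap_run)


# ---------------------------------------------------------------------------
# Gap closure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentBlock:
    """One assembly-to-reference alignment block (PAF-like)."""

    query_id: str
    query_start: int
    query_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    identity: float = 1.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.query_end < self.query_start or self.ref_end < self.ref_start:
            raise ValidationError(f"{self.query_id}: invalid block interval")
        if not 0.0 <= self.identity <= 1.0:
            raise ValidationError(f"{self.query_id}: identity outside [0,1]")
        if self.strand not in "+-":
            raise ValidationError(f"{self.query_id}: strand must be + or -")


def read_alignment_blocks(path: str | Path) -> list[AlignmentBlock]:
    """PAF-like TSV: query, qstart, qend, strand, ref, rstart, rend, identity."""
    out = []
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            q, qs, qe, strand, r, rs, re_, ident = raw.split("\t")[:8]
            out.append(
                AlignmentBlock(
                    query_id=q, query_start=int(qs), query_end=int(qe),
                    strand=strand, ref_chrom=r, ref_start=int(rs),
                    ref_end=int(re_), identity=float(ident),
                )
            )
    return out


def write_alignment_blocks(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"{b.query_id}\t{b.query_start}\t{b.query_end}\t{b.strand}\t"
                f"{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t{b.identity}\n"
            )


def find_gap_closures(
    ref_gaps: Sequence[GenomicElement],
    blocks: Sequence[AlignmentBlock],
    min_flank: int = MIN_FLANK,
) -> tuple[list[GenomicElement], int]:
    """Reference N-gaps completely filled by the assembly.

    A gap counts as closed iff a single alignment block spans it with at
    least ``min_flank`` anchored bases on each side; two adjacent blocks
    that each cover one flank do not close the gap.  Returns the closed
    gaps and the total closed gap length.
    """
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.ref_chrom, []).append(b)
    closed = []
    for gap in ref_gaps:
        for b in by_chrom.get(gap.chrom, ()):
            if (b.ref_start <= gap.start - min_flank
                    and b.ref_end >= gap.end + min_flank):
                closed.append(gap)
                break
    return closed, sum(g.end - g.start for g in closed)


# ---------------------------------------------------------------------------
# Non-reference sequences
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Per-base read depth over one NRS segment."""

    segment_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if np.any(self.depth < 0):
            raise ValidationError(f"{self.segment_id}: negative depth")


def classify_nrs_sharing(
    segment_length: int,
    coverage: CoverageProfile,
    min_frac: float = 0.8,
    min_depth: int = 1,
) -> str:
    """``shared`` iff >= ``min_frac`` of the segment has depth >= ``min_depth``.

    Sharing with an archaic genome is evidenced by that genome's
    reference-unmapped reads piling up along the segment.
    """
    if coverage.depth.size != segment_length:
        raise ValidationError(
            f"{coverage.segment_id}: coverage length {coverage.depth.size} "
            f"!= segment length {segment_length}"
        )
    frac = float(np.mean(coverage.depth >= min_depth))
    return "shared" if frac >= min_frac else "unshared"


def call_insertion_model(
    flank_left: AlignmentBlock | None,
    flank_right: AlignmentBlock | None,
    max_ref_gap: int = 100,
) -> bool | None:
    """Decide whether an NRS sits at a clean insertion point.

    True iff both flanks anchor to the same reference chromosome, in the
    same orientation, with |reference gap| <= ``max_ref_gap`` (a small
    negative gap tolerates breakpoint micro-homology).  An unaligned flank
    makes the call indeterminate (None), not negative.
    """
    if flank_left is None or flank_right is None:
        return None
    if flank_left.ref_chrom != flank_right.ref_chrom:
        return False
    if flank_left.strand != flank_right.strand:
        return False
    left, right = sorted((flank_left, flank_right), key=lambda b: b.ref_start)
    gap = right.ref_start - left.ref_end
    return abs(gap) <= max_ref_gap


@dataclass(frozen=True)
class NRSEvent:
    """One insertion-model NRS anchored on the reference."""

    id: str
    chrom: str
    position: int  # reference breakpoint, 0-based
    length: int
    archaic_sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"{self.id}: NRS length must be >= 1")


def _ins_match(a: NRSEvent, b: NRSEvent, window: int, min_len_ratio: float) -> bool:
    if a.chrom != b.chrom or abs(a.position - b.position) > window:
        return False
    lo, hi = sorted((a.length, b.length))
    return lo / hi >= min_len_ratio


def specific_nrs_events(
    target: Sequence[NRSEvent],
    other_sets: Sequence[Sequence[NRSEvent]],
    window: int = DEFAULT_INS_WINDOW,
    min_len_ratio: float = DEFAULT_INS_MIN_LEN_RATIO,
) -> tuple[list[NRSEvent], dict[str, int]]:
    """Target NRS events absent from every other event set.

    Matching uses the insertion rule (breakpoint window + length ratio).
    Returns the retained events and per-archaic-source counts among them.
    """
    retained = []
    for ev in target:
        found = any(
            _ins_match(ev, other, window, min_len_ratio)
            for others in other_sets
            for other in others
        )
        if not found:
            retained.append(ev)
    counts: dict[str, int] = {}
    for ev in retained:
        for src in ev.archaic_sources:
            counts[src] = counts.get(src, 0) + 1
    return retained, counts


def read_coverage_profiles(path: str | Path) -> dict[str, CoverageProfile]:
    """TSV of ``segment_id<TAB>position<TAB>depth`` rows, positions 0-based
    and contiguous per segment."""
    depths: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            seg, pos, d = raw.split("\t")[:3]
            depths.setdefault(seg, []).append((int(pos), int(d)))
    out = {}
    for seg, rows in depths.items():
        rows.sort()
        arr = np.zeros(rows[-1][0] + 1, dtype=np.int64)
        for pos, d in rows:
            arr[pos] = d
        out[seg] = CoverageProfile(segment_id=seg, depth=arr)
    return out


def write_coverage_profiles(profiles: Iterable[CoverageProfile],
                            path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            for pos, d in enumerate(p.depth):
                fh.write(f"{p.segment_id}\t{pos}\t{d}\n")
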