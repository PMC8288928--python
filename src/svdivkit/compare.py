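"""Reciprocal-overlap SV matching across call sets.

Two deletions/duplications/inversions match when each covers at least a
threshold fraction (default 50%) of the other — the standard reciprocal
overlap rule used when merging SV call sets from different genomes.
Insertions are breakpoints with no footprint, so they match by breakpoint
proximity plus a length-ratio test instead.

Matching between two call sets is 1-to-1: candidate pairs are generated by
a per-chromosome sweep line, then greedily accepted in decreasing order of
the pair score min(frac_a, frac_b), with deterministic tie-breaking.  The
greedy order makes the matched-pair set a prefix of the candidate ranking,
so raising the threshold can only shrink it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import CallSet, SVRecord, SVType
from .errors import ValidationError

DEFAULT_THRESHOLD = 0.5
DEFAULT_INS_WINDOW = 1000
DEFAULT_INS_MIN_LEN_RATIO = 0.5


def reciprocal_overlap(a: SVRecord, b: SVRecord) -> tuple[float, float]:
    """Fraction of each record's footprint covered by the other.

    Records on different chromosomes overlap nothing: (0, 0).  Insertions
    have no footprint and must go through :func:`match_insertions`.
    """
    if a.svtype is SVType.INS or b.svtype is SVType.INS:
        raise ValidationError(
            "reciprocal_overlap is undefined for insertions; use match_insertions"
        )
    if a.chrom != b.chrom:
        return (0.0, 0.0)
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    return (inter / a.length, inter / b.length)


def match_insertions(
    a: SVRecord,
    b: SVRecord,
    window: int = DEFAULT_INS_WINDOW,
    min_len_ratio: float = DEFAULT_INS_MIN_LEN_RATIO,
) -> bool:
    """Breakpoints within ``window`` bp and length ratio >= ``min_len_ratio``."""
    if a.svtype is not SVType.INS or b.svtype is not SVType.INS:
        raise ValidationError("match_insertions requires two INS records")
    if a.chrom != b.chrom:
        return False
    if abs(a.start - b.start) > window:
        return False
    lo, hi = sorted((a.length, b.length))
    return lo / hi >= min_len_ratio


@dataclass(frozen=True)
class MatchPair:
    id_a: str
    id_b: str
    frac_a: float
    frac_b: float

    @property
    def score(self) -> float:
        return min(self.frac_a, self.frac_b)


@dataclass
class MatchResult:
    pairs: list[MatchPair]
    unmatched_a: list[str]
    unmatched_b: list[str]

    def pair_set(self) -> set[tuple[str, str]]:
        return {(p.id_a, p.id_b) for p in self.pairs}


def _candidate_pairs_footprint(
    recs_a: list[SVRecord], recs_b: list[SVRecord], threshold: float
) -> list[tuple[SVRecord, SVRecord, float, float]]:
    """Sweep line over two start-sorted record lists of one (chrom, svtype)."""
    out = []
    recs_b = sorted(recs_b, key=lambda r: r.start)
    starts_b = [r.start for r in recs_b]
    import bisect

    for a in sorted(recs_a, key=lambda r: r.start):
        # b can only overlap a if b.start < a.end; scan backwards is bounded
        # because a match needs b to cover >= threshold of itself.
        hi = bisect.bisect_left(starts_b, a.end)
        for b in recs_b[:hi]:
            if b.end <= a.start:
                continue
            inter = min(a.end, b.end) - max(a.start, b.start)
            fa, fb = inter / a.length, inter / b.length
            if fa >= threshold and fb >= threshold:
                out.append((a, b, fa, fb))
    return out


def _candidate_pairs_ins(
    recs_a: list[SVRecord],
    recs_b: list[SVRecord],
    window: int,
    min_len_ratio: float,
) -> list[tuple[SVRecord, SVRecord, float, float]]:
    out = []
    recs_b = sorted(recs_b, key=lambda r: r.start)
    starts_b = [r.start for r in recs_b]
    import bisect

    for a in sorted(recs_a, key=lambda r: r.start):
        lo = bisect.bisect_left(starts_b, a.start - window)
        hi = bisect.bisect_right(starts_b, a.start + window)
        for b in recs_b[lo:hi]:
            small, big = sorted((a.length, b.length))
            ratio = small / big
            if ratio >= min_len_ratio:
                out.append((a, b, ratio, ratio))
    return out


def intersect_callsets(
    A: CallSet,
    B: CallSet,
    threshold: float = DEFAULT_THRESHOLD,
    ins_window: int = DEFAULT_INS_WINDOW,
    ins_min_len_ratio: float = DEFAULT_INS_MIN_LEN_RATIO,
) -> MatchResult:
    """Greedy 1-to-1 matching of two call sets, per chromosome and SV class.

    DEL/DUP/INV/CPX match within their own class by reciprocal overlap;
    INS by breakpoint window + length ratio.  Candidates are accepted in
    decreasing order of min(frac_a, frac_b); ties break on the smaller
    start coordinate and then on record ids, so the result is deterministic
    and symmetric in its pair set.
    """
    groups_a: dict[tuple[str, SVType], list[SVRecord]] = {}
    for r in A.records:
        groups_a.setdefault((r.chrom, r.svtype), []).append(r)
    groups_b: dict[tuple[str, SVType], list[SVRecord]] = {}
    for r in B.records:
        groups_b.setdefault((r.chrom, r.svtype), []).append(r)

    candidates: list[tuple[SVRecord, SVRecord, float, float]] = []
    for key, recs_a in groups_a.items():
        recs_b = groups_b.get(key)
        if not recs_b:
            continue
        if key[1] is SVType.INS:
            candidates.extend(
                _candidate_pairs_ins(recs_a, recs_b, ins_window, ins_min_len_ratio)
            )
        else:
            candidates.extend(_candidate_pairs_footprint(recs_a, recs_b, threshold))

    candidates.sort(
        key=lambda c: (
            -min(c[2], c[3]),
            min(c[0].start, c[1].start),
            min(c[0].id, c[1].id),
            max(c[0].id, c[1].id),
        )
    )
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    pairs: list[MatchPair] = []
    for a, b, fa, fb in candidates:
        if a.id in matched_a or b.id in matched_b:
            continue
        matched_a.add(a.id)
        matched_b.add(b.id)
        pairs.append(MatchPair(id_a=a.id, id_b=b.id, frac_a=fa, frac_b=fb))
    unmatched_a = [r.id for r in A.records if r.id not in matched_a]
    unmatched_b = [r.id for r in B.records if r.id not in matched_b]
    return MatchResult(pairs=pairs, unmatched_a=unmatched_a, unmatched_b=unmatched_b)


@dataclass
class SpecificityResult:
    """Partition of a target call set into genome-specific vs shared records."""

    specific_ids: set[str]
    shared_ids: set[str]
    # per svtype: frozenset of other-genome ids sharing the record -> count;
    # the empty frozenset bin counts the target-specific records.
    venn: dict[str, dict[frozenset, int]] = field(default_factory=dict)

    def venn_counts(self, svtype: str) -> dict[frozenset, int]:
        return self.venn.get(svtype, {})


def classify_specific(
    target: CallSet,
    others: list[CallSet],
    threshold: float = DEFAULT_THRESHOLD,
    ins_window: int = DEFAULT_INS_WINDOW,
    ins_min_len_ratio: float = DEFAULT_INS_MIN_LEN_RATIO,
) -> SpecificityResult:
    """Mark target records found in none of the other call sets as specific.

    Each other genome is intersected with the target independently (the
    1-to-1 matching runs per pair of call sets); the Venn tally records,
    per SV class, which subset of other genomes shares each target record.
    """
    if not others:
        raise ValidationError("classify_specific needs at least one other call set")
    shared_by: dict[str, set[str]] = {r.id: set() for r in target.records}
    for other in others:
        res = intersect_callsets(
            target, other, threshold=threshold, ins_window=ins_window,
            ins_min_len_ratio=ins_min_len_ratio,
        )
        for p in res.pairs:
            shared_by[p.id_a].add(other.genome_id)

    specific = {rid for rid, s in shared_by.items() if not s}
    shared = set(shared_by) - specific
    venn: dict[str, dict[frozenset, int]] = {}
    for r in target.records:
        bins = venn.setdefault(r.svtype.value, {})
        key = frozenset(shared_by[r.id])
        bins[key] = bins.get(key, 0) + 1
    return SpecificityResult(specific_ids=specific, shared_ids=shared, venn=venn)
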