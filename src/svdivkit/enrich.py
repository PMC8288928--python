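"""SV-to-gene assignment and permutation enrichment of genomic elements.

The permutation scheme is the standard region-shuffling convention: each
SV is re-placed uniformly at random on its own chromosome, preserving its
length (insertions are re-placed as breakpoints), and the number of SVs
touching at least one element is recounted.  Depletion or enrichment is
judged against that null with the +1 empirical-p correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import GenomicElement, SVRecord, SVType
from .errors import ValidationError

GENE_WINDOW = 5_000


def assign_genes(
    svs: Sequence[SVRecord],
    genes: Sequence[GenomicElement],
    window: int = GENE_WINDOW,
) -> dict[str, set[str]]:
    """Map each SV to the genes lying strictly within ``window`` bp.

    Distance is the gap between the SV footprint and the gene interval
    (overlap counts as 0); the boundary is strict, so a gap of exactly
    ``window`` bp does not qualify.  An SV assigned to at least one gene
    is, in the original study's vocabulary, the seed of a ZSAG
    (specific-SV-associated gene) set.
    """
    trees: dict[str, IntervalTree] = {}
    for i, gene in enumerate(genes):
        key = gene.name or f"gene_{i}"
        trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start, gene.end, key)
    out: dict[str, set[str]] = {}
    for sv in svs:
        tree = trees.get(sv.chrom)
        hits: set[str] = set()
        if tree is not None:
            s, e = sv.footprint
            # intervaltree query is half-open: [s-window, e+window) intersects
            # exactly the genes at distance < window
            for iv in tree.overlap(s - window, e + window):
                hits.add(iv.data)
            if s == e:  # zero-length insertion footprint
                for iv in tree.overlap(s - window, s + window):
                    hits.add(iv.data)
        out[sv.id] = hits
    return out


@dataclass
class EnrichmentResult:
    observed: int
    null_values: np.ndarray
    fold: float
    empirical_p: float
    alternative: str
    params: dict


def _merged_intervals(elements: Iterable[GenomicElement]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for e in elements:
        by_chrom.setdefault(e.chrom, []).append((e.start, e.end))
    out = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        merged = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def _overlaps_any(starts: np.ndarray, ends: np.ndarray,
                  s: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Whether each interval [s, e) hits any merged element interval."""
    idx = np.searchsorted(ends, s, side="right")
    hit = idx < starts.size
    hit[hit] &= starts[idx[hit]] < e[hit]
    return hit


def permutation_enrichment(
    svs: Sequence[SVRecord],
    elements: Sequence[GenomicElement],
    chrom_lengths: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "depletion",
) -> EnrichmentResult:
    """Permutation test of SV / element co-location.

    Observed = number of SVs overlapping >= 1 element (per SV, not per bp;
    insertions count through their 1-bp breakpoint interval).  Each
    permutation re-places every SV uniformly on its own chromosome keeping
    its length.  ``alternative`` selects the tail: depletion (null <=
    observed), enrichment (null >= observed) or two_sided.
    """
    if n_perm < 100:
        raise ValidationError("permutation test needs n_perm >= 100")
    if alternative not in ("depletion", "enrichment", "two_sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    merged = _merged_intervals(elements) if elements else {}
    rng = np.random.default_rng(seed)

    observed = 0
    null = np.zeros(n_perm, dtype=int)
    for sv in svs:
        L = chrom_lengths.get(sv.chrom)
        if L is None:
            raise ValidationError(f"{sv.id}: no length for chromosome {sv.chrom}")
        span = 1 if sv.svtype is SVType.INS else sv.length
        if span > L:
            raise ValidationError(f"{sv.id}: SV longer than chromosome {sv.chrom}")
        chrom_elems = merged.get(sv.chrom)
        s0, e0 = sv.footprint
        if sv.svtype is SVType.INS:
            e0 = s0 + 1
        if chrom_elems is not None:
            starts, ends = chrom_elems
            observed += int(
                _overlaps_any(starts, ends, np.array([s0]), np.array([e0]))[0]
            )
            place = rng.integers(0, L - span + 1, size=n_perm)
            null += _overlaps_any(starts, ends, place, place + span)
        else:
            rng.integers(0, L - span + 1, size=n_perm)  # keep the stream aligned

    mean_null = float(null.mean())
    if mean_null == 0.0:
        fold = 1.0 if observed == 0 else float("inf")
    else:
        fold = observed / mean_null
    p_dep = float((1 + np.sum(null <= observed)) / (1 + n_perm))
    p_enr = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    if alternative == "depletion":
        p = p_dep
    elif alternative == "enrichment":
        p = p_enr
    else:
        p = min(1.0, 2 * min(p_dep, p_enr))
    return EnrichmentResult(
        observed=observed, null_values=null, fold=fold, empirical_p=p,
        alternative=alternative,
        params={
            "n_perm": n_perm, "seed": seed,
            "scheme": "uniform re-placement on own chromosome, length preserved",
        },
    )


@dataclass
class OverlapTestResult:
    odds_ratio: float
    chi2_p: float
    table: np.ndarray  # [[a, b], [c, d]]
    haldane_corrected: bool


def gene_set_overlap_test(
    setA: Iterable[str], setB: Iterable[str], universe: Iterable[str]
) -> OverlapTestResult:
    """2x2 overlap test of two gene sets within a finite universe.

    Cells: a = in both, b = A only, c = B only, d = neither.  The odds
    ratio is ad/bc with the Haldane 0.5 correction applied to every cell
    iff any cell is 0; the p-value is a Pearson chi-squared test without
    continuity correction.
    """
    U = set(universe)
    if not U:
        raise ValidationError("gene universe must be non-empty")
    A = set(setA) & U
    B = set(setB) & U
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(U - A - B)
    table = np.array([[a, b], [c, d]], dtype=float)
    corrected = 0 in (a, b, c, d)
    t = table + 0.5 if corrected else table
    odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return OverlapTestResult(odds_ratio=odds, chi2_p=float(p), table=table,
                             haldane_corrected=corrected)
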