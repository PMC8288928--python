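"""Between-population SV divergence and a Wright-Fisher drift null.

The core statistic is V_ST, a 0–1 analogue of F_ST for copy-number or
dosage data:

    V_ST = (V_T - V_S) / V_T

where V_T is the variance of all values pooled and V_S is the
sample-size-weighted mean of the within-population variances.  Population
variances use denominator n.  The same computation applied to insertion
dosage genotypes (0/1/2 copies of the inserted allele) is exposed under
the name mV_ST.  Negative estimates — which arise by sampling noise when
the true divergence is 0 — are clamped to 0; the raw value is retained.

The drift null asks whether an observed divergence is expected under
neutral demography: two populations split T generations ago from a common
ancestral frequency p0 drift independently by binomial Wright-Fisher
sampling, diploid samples of the study sizes are drawn under HWE, and the
statistic is recomputed.  The empirical p-value uses the +1 correction so
it is never exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import GenotypeMatrix
from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError

DEFAULT_NE = 10_000
DEFAULT_T_SPLIT = 1_200
REPEAT_MAX = 0.70
TOP_QUANTILE = 0.05


# ---------------------------------------------------------------------------
# Allele frequencies and divergence
# ---------------------------------------------------------------------------

def allele_frequency(g: GenotypeMatrix, locus: str, population: str) -> float:
    """(sum of dosages) / (2 x number of non-missing samples)."""
    vals = g.dosages(locus, population)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise UndefinedStatisticError(
            f"no non-missing genotypes for locus {locus!r} in {population!r}"
        )
    return float(vals.sum() / (2 * vals.size))


def allelic_divergence(p1: float, p2: float) -> float:
    """Absolute allele-frequency difference between two populations."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"allele frequency {p} outside [0,1]")
    return abs(p1 - p2)


def vst_components(
    values: Sequence[float] | np.ndarray, labels: Sequence[str] | np.ndarray
) -> tuple[float, float, float]:
    """Return (V_T, V_S, raw V_ST) before clamping.

    Missing values (NaN) are dropped per sample.  Every population must
    retain at least two values and there must be at least two populations.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    pops = np.unique(labels)
    if pops.size < 2:
        raise InsufficientDataError("V_ST needs at least two populations")
    ns, vs = [], []
    for pop in pops:
        x = values[labels == pop]
        if x.size < 2:
            raise InsufficientDataError(
                f"population {pop!r} has {x.size} values; need >= 2"
            )
        ns.append(x.size)
        vs.append(float(np.var(x)))  # denominator n
    ns_arr = np.array(ns, dtype=float)
    v_t = float(np.var(values))
    v_s = float(np.dot(ns_arr, vs) / ns_arr.sum())
    raw = 0.0 if v_t == 0.0 else (v_t - v_s) / v_t
    return v_t, v_s, raw


def vst(
    values: Sequence[float] | np.ndarray, labels: Sequence[str] | np.ndarray
) -> float:
    """V_ST clamped to [0, 1]; returns 0 when the pooled variance is 0."""
    _, _, raw = vst_components(values, labels)
    return max(0.0, raw)


def hwe_expected_vst(p1: float, n1: int, p2: float, n2: int) -> float:
    """V_ST of the HWE-expected dosage distributions, no sampling.

    Under HWE a diploid dosage has mean 2p and variance 2p(1-p); the pooled
    variance decomposes into the weighted within variance plus the weighted
    between-mean variance with weights n_i / (n1 + n2).
    """
    w1, w2 = n1 / (n1 + n2), n2 / (n1 + n2)
    m1, m2 = 2 * p1, 2 * p2
    v1, v2 = 2 * p1 * (1 - p1), 2 * p2 * (1 - p2)
    v_s = w1 * v1 + w2 * v2
    m = w1 * m1 + w2 * m2
    v_t = v_s + w1 * (m1 - m) ** 2 + w2 * (m2 - m) ** 2
    if v_t == 0.0:
        return 0.0
    return max(0.0, (v_t - v_s) / v_t)


# ---------------------------------------------------------------------------
# Candidate ranking
# ---------------------------------------------------------------------------

@dataclass
class DivergenceResult:
    """Divergence of one locus, ready for ranking."""

    locus_id: str
    statistic_name: str  # VST, mVST or allelic_divergence
    value: float
    p1: float | None = None
    p2: float | None = None
    repeat_fraction: float = 0.0
    raw_value: float | None = None
    rank_quantile: float | None = None
    passes_repeat_filter: bool = True
    is_top: bool = False


@dataclass
class RankedCandidates:
    results: list[DivergenceResult]  # kept loci, sorted by value descending
    excluded: list[DivergenceResult]  # removed by the repeat filter
    cutoff: float
    q: float

    @property
    def top(self) -> list[DivergenceResult]:
        return [r for r in self.results if r.is_top]


def rank_candidates(
    results: Sequence[DivergenceResult],
    q: float = TOP_QUANTILE,
    repeat_max: float = REPEAT_MAX,
) -> RankedCandidates:
    """Repeat-filter, then flag the top q fraction of loci by divergence.

    Loci whose repeat_fraction is >= ``repeat_max`` are excluded before the
    cutoff is computed (only SVs with <70% repeat content are trusted from
    short-read genotyping by default).  The cutoff is the empirical (1-q)
    quantile with linear interpolation; loci at or above it are flagged.
    """
    if not results:
        raise InsufficientDataError("rank_candidates needs at least one locus")
    kept, excluded = [], []
    for r in results:
        (excluded if r.repeat_fraction >= repeat_max else kept).append(r)
        r.passes_repeat_filter = r.repeat_fraction < repeat_max
    if not kept:
        raise InsufficientDataError("all loci removed by the repeat filter")
    values = np.array([r.value for r in kept])
    cutoff = float(np.quantile(values, 1.0 - q, method="linear"))
    order = values.argsort(kind="stable")
    ranks = np.empty(len(kept))
    ranks[order] = np.arange(1, len(kept) + 1)
    for r, rk in zip(kept, ranks):
        r.rank_quantile = float(rk / len(kept))
        r.is_top = r.value >= cutoff
    for r in excluded:
        r.is_top = False
        r.rank_quantile = None
    kept_sorted = sorted(kept, key=lambda r: (-r.value, r.locus_id))
    return RankedCandidates(results=kept_sorted, excluded=excluded,
                            cutoff=cutoff, q=q)


def divergence_scan(
    g: GenotypeMatrix,
    statistic_name: str = "VST",
    repeat_fractions: dict[str, float] | None = None,
    populations: tuple[str, str] | None = None,
) -> list[DivergenceResult]:
    """V_ST (or mV_ST) plus allele frequencies for every locus in a matrix."""
    pops = list(populations) if populations else g.populations
    if len(pops) < 2:
        raise InsufficientDataError("divergence scan needs two populations")
    labels = g.population_vector()
    out = []
    for locus in g.locus_ids:
        vals = g.dosages(locus)
        v_t, v_s, raw = vst_components(vals, labels)
        p1 = allele_frequency(g, locus, pops[0])
        p2 = allele_frequency(g, locus, pops[1])
        out.append(
            DivergenceResult(
                locus_id=locus, statistic_name=statistic_name,
                value=max(0.0, raw), raw_value=raw, p1=p1, p2=p2,
                repeat_fraction=(repeat_fractions or {}).get(locus, 0.0),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Watterson's theta
# ---------------------------------------------------------------------------

def watterson_theta(S: int, n_haploid: int) -> float:
    """Watterson's estimator: S over the (n-1)-th harmonic number."""
    if n_haploid < 2:
        raise ValidationError("watterson_theta needs n_haploid >= 2")
    if S < 0:
        raise ValidationError("segregating-site count cannot be negative")
    a = np.sum(1.0 / np.arange(1, n_haploid))
    return float(S / a)


def mutation_rate(theta: float, Ne: int = DEFAULT_NE) -> float:
    """Per-generation per-haploid-genome rate mu = theta / (4 Ne)."""
    return theta / (4 * Ne)


# ---------------------------------------------------------------------------
# Wright-Fisher drift null
# ---------------------------------------------------------------------------

P0Model = float | tuple | Callable[[np.random.Generator, int], np.ndarray]


@dataclass
class DriftNull:
    observed: float | None
    null_values: np.ndarray
    quantile_95: float
    empirical_p: float | None
    params: dict = field(default_factory=dict)
    n_degenerate: int = 0  # reps where the statistic was undefined (V_T = 0)


def _draw_p0(p0_model: P0Model, rng: np.random.Generator, reps: int) -> np.ndarray:
    if callable(p0_model):
        p0 = np.asarray(p0_model(rng, reps), dtype=float)
    elif isinstance(p0_model, tuple):
        kind = p0_model[0]
        if kind == "uniform":
            lo, hi = p0_model[1], p0_model[2]
            p0 = rng.uniform(lo, hi, reps)
        elif kind == "spectrum":
            freqs = np.asarray(p0_model[1], dtype=float)
            weights = np.asarray(p0_model[2], dtype=float)
            p0 = rng.choice(freqs, size=reps, p=weights / weights.sum())
        else:
            raise ValidationError(f"unknown p0 model {kind!r}")
    else:
        p0 = np.full(reps, float(p0_model))
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValidationError("ancestral frequencies must lie in [0,1]")
    return p0


def _vst_two_pops(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised V_ST over reps; returns (vst, degenerate mask)."""
    n1, n2 = g1.shape[1], g2.shape[1]
    v1 = g1.var(axis=1)
    v2 = g2.var(axis=1)
    m1 = g1.mean(axis=1)
    m2 = g2.mean(axis=1)
    w1, w2 = n1 / (n1 + n2), n2 / (n1 + n2)
    v_s = w1 * v1 + w2 * v2
    m = w1 * m1 + w2 * m2
    v_t = v_s + w1 * (m1 - m) ** 2 + w2 * (m2 - m) ** 2
    degenerate = v_t == 0.0
    out = np.zeros_like(v_t)
    ok = ~degenerate
    out[ok] = np.clip((v_t[ok] - v_s[ok]) / v_t[ok], 0.0, 1.0)
    return out, degenerate


def drift_null_vst(
    p0_model: P0Model,
    N1: int = DEFAULT_NE,
    N2: int = DEFAULT_NE,
    T: int = DEFAULT_T_SPLIT,
    n1: int = 38,
    n2: int = 39,
    reps: int = 10_000,
    seed: int = 0,
    statistic: str = "vst",
    observed: float | None = None,
) -> DriftNull:
    """Null distribution of a divergence statistic under pure drift.

    Per replicate: draw an ancestral frequency p0, evolve the two
    descendant populations independently for T generations of binomial
    sampling of 2N gametes, then draw n1/n2 diploid genotypes as
    Binomial(2, p) dosages (HWE) and compute the statistic.

    ``statistic`` is ``"vst"`` or ``"allelic_divergence"``.  Replicates
    where the statistic is undefined (pooled variance 0, i.e. the allele
    fixed or lost everywhere) score 0 and are counted in ``n_degenerate``.
    """
    if reps < 100:
        raise ValidationError("drift null needs reps >= 100")
    if N1 < n1 or N2 < n2:
        raise ValidationError("population size must be >= sample size")
    rng = np.random.default_rng(seed)
    p0 = _draw_p0(p0_model, rng, reps)

    p1 = p0.copy()
    p2 = p0.copy()
    for _ in range(T):
        p1 = rng.binomial(2 * N1, p1) / (2 * N1)
        p2 = rng.binomial(2 * N2, p2) / (2 * N2)

    if statistic == "vst":
        g1 = rng.binomial(2, p1[:, None], size=(reps, n1)).astype(float)
        g2 = rng.binomial(2, p2[:, None], size=(reps, n2)).astype(float)
        null, degenerate = _vst_two_pops(g1, g2)
    elif statistic == "allelic_divergence":
        c1 = rng.binomial(2 * n1, p1)
        c2 = rng.binomial(2 * n2, p2)
        null = np.abs(c1 / (2 * n1) - c2 / (2 * n2))
        degenerate = np.zeros(reps, dtype=bool)
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")

    q95 = float(np.quantile(null, 0.95, method="linear"))
    emp_p = None
    if observed is not None:
        emp_p = float((1 + np.sum(null >= observed)) / (1 + reps))
    return DriftNull(
        observed=observed, null_values=null, quantile_95=q95, empirical_p=emp_p,
        params={
            "N1": N1, "N2": N2, "T": T, "n1": n1, "n2": n2, "reps": reps,
            "seed": seed, "statistic": statistic,
            "p0_model": repr(p0_model),
            "note": "default demography is a placeholder single-split model",
        },
        n_degenerate=int(degenerate.sum()),
    )
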