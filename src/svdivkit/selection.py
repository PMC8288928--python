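"""Extended haplotype homozygosity and genotype-phenotype association.

EHH at a site x, for the carriers of a focal allele, is the probability
that two carrier haplotypes drawn at random are identical over the stretch
from the core site out to x:

    EHH(x) = sum_h C(e_h, 2) / C(c, 2)

with e_h the number of carriers sharing extended haplotype h and c the
carrier count.  EHH is 1 at the core and can only decrease outward,
because growing the stretch refines the haplotype partition.

Association uses an additive model: ordinary least squares of the trait on
allele dosage (0/1/2), optional covariates, listwise deletion of missing
values, and a two-sided t-test on the dosage coefficient.  Multiple
testing is controlled with Benjamini-Hochberg step-up FDR, either per
trait or across the full traits x loci grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import GenotypeMatrix, PhenotypeTable
from .errors import (
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)

MIN_SAMPLES = 10


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes around a focal site.

    ``haplotypes`` is a (2n x m) 0/1 matrix; ``positions`` are strictly
    increasing bp coordinates; ``focal_index`` marks the core site and
    ``focal_allele`` the allele whose carriers are followed.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    focal_index: int
    focal_allele: int = 1

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValidationError("haplotypes must be a 2-D matrix")
        if self.positions.size != self.haplotypes.shape[1]:
            raise ValidationError("positions do not match haplotype columns")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if not 0 <= self.focal_index < self.positions.size:
            raise ValidationError("focal index out of range")

    @property
    def focal_position(self) -> int:
        return int(self.positions[self.focal_index])

    def carriers(self, allele: int | None = None) -> np.ndarray:
        allele = self.focal_allele if allele is None else allele
        return self.haplotypes[self.haplotypes[:, self.focal_index] == allele]


def _ehh_of_stretch(stretch: np.ndarray) -> float:
    c = stretch.shape[0]
    _, counts = np.unique(stretch, axis=0, return_counts=True)
    pairs_same = np.sum(counts * (counts - 1) // 2)
    return float(pairs_same / (c * (c - 1) // 2))


def ehh(panel: HaplotypePanel, position: int, allele: int | None = None) -> float:
    """EHH at the site with coordinate ``position`` (must be a panel site)."""
    idx = np.searchsorted(panel.positions, position)
    if idx >= panel.positions.size or panel.positions[idx] != position:
        raise ValidationError(f"position {position} is not a site in the panel")
    carr = panel.carriers(allele)
    if carr.shape[0] < 2:
        raise InsufficientDataError("EHH needs >= 2 carrier haplotypes")
    lo, hi = sorted((idx, panel.focal_index))
    return _ehh_of_stretch(carr[:, lo:hi + 1])


def ehh_curve(
    panel: HaplotypePanel,
    direction: str = "both",
    alleles: Sequence[int] = (0, 1),
) -> dict[int, list[tuple[int, float]]]:
    """EHH at every site moving outward from the core, per allele class.

    ``direction`` selects sites left of, right of, or on both sides of the
    core (the core itself is always included, with EHH 1).  Allele classes
    with fewer than two carriers are omitted.
    """
    f = panel.focal_index
    if direction == "left":
        site_idx = np.arange(0, f + 1)
    elif direction == "right":
        site_idx = np.arange(f, panel.positions.size)
    elif direction == "both":
        site_idx = np.arange(panel.positions.size)
    else:
        raise ValidationError(f"unknown direction {direction!r}")

    out: dict[int, list[tuple[int, float]]] = {}
    for allele in alleles:
        carr = panel.carriers(allele)
        if carr.shape[0] < 2:
            continue
        curve = []
        for idx in site_idx:
            lo, hi = sorted((int(idx), f))
            curve.append(
                (int(panel.positions[idx]), _ehh_of_stretch(carr[:, lo:hi + 1]))
            )
        out[allele] = curve
    if not out:
        raise InsufficientDataError("no allele class has >= 2 carriers")
    return out


def write_haplotypes(panel: HaplotypePanel, path) -> None:
    """TSV: a header row of site positions (first cell marks the focal site
    as ``pos*``), then one 0/1 row per haplotype."""
    with open(path, "w") as fh:
        cells = [str(p) + ("*" if i == panel.focal_index else "")
                 for i, p in enumerate(panel.positions)]
        fh.write("\t".join(cells) + "\n")
        for row in panel.haplotypes:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_haplotypes(path, focal_allele: int = 1) -> HaplotypePanel:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        focal_index = next(
            (i for i, c in enumerate(header) if c.endswith("*")), None
        )
        if focal_index is None:
            raise ValidationError("haplotype file header marks no focal site (*)")
        positions = [int(c.rstrip("*")) for c in header]
        rows = [[int(v) for v in line.strip().split("\t")]
                for line in fh if line.strip()]
    return HaplotypePanel(
        haplotypes=np.array(rows, dtype=np.int8),
        positions=np.array(positions), focal_index=focal_index,
        focal_allele=focal_allele,
    )


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    locus_id: str
    trait: str
    beta: float
    se: float
    p_value: float
    fdr_bh: float
    n_used: int
    direction: int  # sign of beta


def _fit_additive(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None,
    locus_id: str,
    trait: str,
) -> AssociationResult:
    mask = ~np.isnan(y) & ~np.isnan(dosage)
    if covariates is not None:
        mask &= ~np.isnan(covariates).any(axis=1)
    y, dosage = y[mask], dosage[mask]
    n = int(mask.sum())
    if n < MIN_SAMPLES:
        raise InsufficientDataError(
            f"{locus_id}/{trait}: only {n} complete samples (need {MIN_SAMPLES})"
        )
    if np.ptp(dosage) == 0:
        raise UndefinedStatisticError(f"{locus_id}/{trait}: dosage is constant")
    X = np.column_stack([np.ones(n), dosage])
    if covariates is not None:
        X = np.column_stack([X, covariates[mask]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"{locus_id}/{trait}: collinear covariates")
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params[1])
    return AssociationResult(
        locus_id=locus_id, trait=trait, beta=beta, se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]), fdr_bh=float(fit.pvalues[1]),
        n_used=n, direction=int(np.sign(beta)),
    )


def _align_samples(
    g: GenotypeMatrix, traits: PhenotypeTable
) -> tuple[list[str], np.ndarray, np.ndarray]:
    common = [s for s in g.sample_ids if s in set(traits.sample_ids)]
    if not common:
        raise InsufficientDataError("no samples shared between genotypes and traits")
    gi = [g.sample_ids.index(s) for s in common]
    ti = [traits.sample_ids.index(s) for s in common]
    return common, g.values[gi, :], traits.values[ti, :]


def associate(
    g: GenotypeMatrix,
    locus: str,
    traits: PhenotypeTable,
    trait_names: Sequence[str] | None = None,
    covariates: np.ndarray | None = None,
) -> list[AssociationResult]:
    """Additive-model OLS of each trait on the dosage at one locus.

    ``covariates``, when given, is an array aligned with the shared-sample
    order (rows = samples common to both tables in genotype order).  The
    returned ``fdr_bh`` equals the raw p until a scan applies correction.
    """
    _, gvals, tvals = _align_samples(g, traits)
    dosage = gvals[:, g.locus_index(locus)]
    names = list(trait_names) if trait_names else traits.traits
    out = []
    for trait in names:
        j = traits.traits.index(trait)
        out.append(_fit_additive(tvals[:, j], dosage, covariates, locus, trait))
    return out


def joint_association(
    g: GenotypeMatrix,
    locusA: str,
    locusB: str,
    traits: PhenotypeTable,
    trait_names: Sequence[str] | None = None,
    covariates: np.ndarray | None = None,
) -> list[AssociationResult]:
    """Joint additive model: the predictor is dosageA + dosageB.

    Combining two loci into one additive score tests whether the two SVs
    act in the same direction on the trait; with one locus constant this
    degenerates to the single-locus model (up to a dosage offset, which
    the intercept absorbs).
    """
    _, gvals, tvals = _align_samples(g, traits)
    combined = gvals[:, g.locus_index(locusA)] + gvals[:, g.locus_index(locusB)]
    names = list(trait_names) if trait_names else traits.traits
    out = []
    for trait in names:
        j = traits.traits.index(trait)
        res = _fit_additive(tvals[:, j], combined, covariates,
                            f"{locusA}+{locusB}", trait)
        out.append(res)
    return out


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def association_scan(
    g: GenotypeMatrix,
    loci: Sequence[str],
    traits: PhenotypeTable,
    correction_scope: str = "traits_x_loci",
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """All (locus, trait) associations with FDR control.

    ``correction_scope`` is ``"per_trait"`` (BH across loci within each
    trait) or ``"traits_x_loci"`` (BH across the flattened grid — the most
    rigorous adjustment).  Per-cell failures are recorded in the ``error``
    column rather than aborting the scan.  Sorted by FDR then raw p.
    """
    if correction_scope not in ("per_trait", "traits_x_loci"):
        raise ValidationError(f"unknown correction scope {correction_scope!r}")
    rows = []
    for locus in loci:
        for trait in traits.traits:
            try:
                res = associate(g, locus, traits, trait_names=[trait],
                                covariates=covariates)[0]
                rows.append({
                    "locus": locus, "trait": trait, "beta": res.beta,
                    "se": res.se, "p_value": res.p_value, "n_used": res.n_used,
                    "direction": res.direction, "error": "",
                })
            except (InsufficientDataError, UndefinedStatisticError,
                    ValidationError) as exc:
                rows.append({
                    "locus": locus, "trait": trait, "beta": np.nan,
                    "se": np.nan, "p_value": np.nan, "n_used": 0,
                    "direction": 0, "error": str(exc),
                })
    df = pd.DataFrame(rows)
    df["fdr_bh"] = np.nan
    ok = df["p_value"].notna()
    if correction_scope == "traits_x_loci":
        if ok.any():
            df.loc[ok, "fdr_bh"] = bh_fdr(df.loc[ok, "p_value"].to_numpy())
    else:
        for trait in traits.traits:
            sel = ok & (df["trait"] == trait)
            if sel.any():
                df.loc[sel, "fdr_bh"] = bh_fdr(df.loc[sel, "p_value"].to_numpy())
    return df.sort_values(["fdr_bh", "p_value"],
                          na_position="last").reset_index(drop=True)
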