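"""Synthetic-data generators with recorded ground truth.

Every input the analysis chain consumes can be generated here: two-population
SV genotypes under HWE, three-genome SV call sets with a known
shared/specific partition, quantitative traits with additive SV effects,
haplotype panels with or without an extended shared haplotype, and a toy
reference/assembly pair with N-gaps and non-reference insertions carrying
archaic read coverage.  Each generator is deterministic given its seed and
returns truth sufficient to score the downstream stage exactly.

The default two-population preset emulates the study design the package
targets: 38 + 39 diploid samples, one strongly diverged deletion locus
(allele frequencies 0.544 vs 0.317), one moderately diverged insertion
locus (0.240 vs 0.130), and null loci with equal frequencies in both
populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .assembly import AlignmentBlock, CoverageProfile
from .core import CallSet, GenomicElement, GenotypeMatrix, PhenotypeTable, SVRecord, SVType
from .errors import ValidationError
from .selection import HaplotypePanel

# study-design constants for the default preset
DEFAULT_N_TBN = 38
DEFAULT_N_HAN = 39
MKL1_LIKE = ("MKL1_del", 0.544, 0.317)
SCUBE2_LIKE = ("SCUBE2_ins", 0.240, 0.130)

TRAIT_PARAMS: dict[str, tuple[float, float]] = {
    # trait: (baseline mean, residual SD) in conventional clinical units
    "PAP": (30.0, 5.0),    # systolic pulmonary arterial pressure, mmHg
    "HB": (160.0, 15.0),   # hemoglobin, g/L
    "HCT": (48.0, 5.0),    # hematocrit, %
    "RBC": (5.2, 0.5),     # red cells, 10^12/L
    "PLT": (220.0, 50.0),  # platelets, 10^9/L
    "SBP": (120.0, 12.0),  # systolic blood pressure, mmHg
    "DBP": (75.0, 9.0),    # diastolic blood pressure, mmHg
    "MVV": (100.0, 20.0),  # maximum ventilatory volume, L/min
    "FVC": (4.2, 0.7),     # forced vital capacity, L
    "FEV1": (3.4, 0.6),    # forced expiratory volume in 1 s, L
    "FFR": (82.0, 6.0),    # FEV1/FVC ratio, %
    "HR": (72.0, 10.0),    # heart rate, bpm
    "SPO2": (90.0, 3.0),   # oxygen saturation, %
    "WBC": (6.5, 1.5),     # white cells, 10^9/L
    "MCV": (90.0, 5.0),    # mean corpuscular volume, fL
    "MCH": (30.0, 2.0),    # mean corpuscular hemoglobin, pg
    "MCHC": (340.0, 10.0), # mean corpuscular Hb concentration, g/L
    "RDW": (13.0, 1.0),    # red-cell distribution width, %
    "BMI": (23.0, 3.0),    # body mass index, kg/m^2
}

DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    # per-allele additive effects: the deletion lowers pulmonary pressure,
    # the insertion improves the FEV1/FVC ratio
    "MKL1_del": {"PAP": -3.0},
    "SCUBE2_ins": {"FFR": 2.0},
}


# ---------------------------------------------------------------------------
# Two-population genotypes
# ---------------------------------------------------------------------------

@dataclass
class PopulationSVTruth:
    freqs: dict[str, tuple[float, float]]  # locus -> (p pop1, p pop2)
    pop_names: tuple[str, str]
    n1: int
    n2: int


def default_freq_spec(n_loci: int, seed: int) -> dict[str, tuple[float, float]]:
    """Null loci with equal frequencies plus the two planted diverged loci."""
    rng = np.random.default_rng(seed)
    spec: dict[str, tuple[float, float]] = {
        MKL1_LIKE[0]: (MKL1_LIKE[1], MKL1_LIKE[2]),
        SCUBE2_LIKE[0]: (SCUBE2_LIKE[1], SCUBE2_LIKE[2]),
    }
    n_null = max(0, n_loci - len(spec))
    p_null = rng.uniform(0.05, 0.95, n_null)
    for k, p in enumerate(p_null):
        spec[f"null_{k:04d}"] = (float(p), float(p))
    return spec


def simulate_population_svs(
    n1: int = DEFAULT_N_TBN,
    n2: int = DEFAULT_N_HAN,
    n_loci: int = 200,
    freq_spec: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    pop_names: tuple[str, str] = ("TBN", "HAN"),
) -> tuple[GenotypeMatrix, PopulationSVTruth]:
    """HWE dosage genotypes for two populations with known frequencies.

    Each sample's dosage at a locus is Binomial(2, p) with p the
    population's allele frequency for that locus.
    """
    if freq_spec is None:
        freq_spec = default_freq_spec(n_loci, seed)
    for locus, (p1, p2) in freq_spec.items():
        if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
            raise ValidationError(f"{locus}: frequencies must lie in [0,1]")
    rng = np.random.default_rng(seed)
    loci = list(freq_spec)
    p1s = np.array([freq_spec[l][0] for l in loci])
    p2s = np.array([freq_spec[l][1] for l in loci])
    g1 = rng.binomial(2, p1s[None, :], size=(n1, len(loci)))
    g2 = rng.binomial(2, p2s[None, :], size=(n2, len(loci)))
    samples = [f"{pop_names[0]}_{i:04d}" for i in range(n1)] + [
        f"{pop_names[1]}_{i:04d}" for i in range(n2)
    ]
    labels = {s: (pop_names[0] if i < n1 else pop_names[1])
              for i, s in enumerate(samples)}
    g = GenotypeMatrix(
        sample_ids=samples, locus_ids=loci,
        values=np.vstack([g1, g2]).astype(float), pop_labels=labels,
    )
    truth = PopulationSVTruth(
        freqs={l: (float(a), float(b)) for l, a, b in zip(loci, p1s, p2s)},
        pop_names=pop_names, n1=n1, n2=n2,
    )
    return g, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    g: GenotypeMatrix,
    effects: Mapping[str, Mapping[str, float]] | None = None,
    trait_params: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> PhenotypeTable:
    """Traits = baseline + sum of per-allele effects x dosage + Gaussian noise.

    ``effects`` maps locus -> {trait: beta per allele copy}; the default
    plants a negative PAP effect on the deletion locus and a positive FFR
    effect on the insertion locus.  Residual SDs come from
    ``trait_params`` (clinical-scale defaults).
    """
    effects = effects if effects is not None else DEFAULT_EFFECTS
    trait_params = dict(trait_params or TRAIT_PARAMS)
    rng = np.random.default_rng(seed)
    n = len(g.sample_ids)
    traits = list(trait_params)
    values = np.empty((n, len(traits)))
    for j, trait in enumerate(traits):
        mean, sd = trait_params[trait]
        y = np.full(n, mean, dtype=float)
        for locus, trait_betas in effects.items():
            beta = trait_betas.get(trait)
            if beta and locus in g.locus_ids:
                dosage = g.values[:, g.locus_index(locus)]
                y = y + beta * np.nan_to_num(dosage)
        y = y + rng.normal(0.0, sd, n)
        values[:, j] = y
    return PhenotypeTable(sample_ids=g.sample_ids, traits=traits, values=values)


# ---------------------------------------------------------------------------
# Three-genome call sets
# ---------------------------------------------------------------------------

@dataclass
class CallSetTruth:
    # event id -> frozenset of genome ids carrying it
    membership: dict[str, frozenset]
    # genome id -> {event id -> record id in that genome's call set}
    record_ids: dict[str, dict[str, str]] = field(default_factory=dict)


DEFAULT_CHROM_LENGTHS = {"chr1": 2_000_000, "chr2": 1_500_000}


def simulate_callsets(
    genome_ids: Sequence[str] = ("genomeA", "genomeB", "genomeC"),
    n_shared_all: int = 20,
    n_shared_pair: int = 10,
    n_specific: int = 15,
    chrom_lengths: Mapping[str, int] | None = None,
    svtypes: Sequence[str] = ("DEL", "INS", "DUP"),
    size_range: tuple[int, int] = (100, 2000),
    jitter: int = 20,
    seed: int = 0,
) -> tuple[dict[str, CallSet], CallSetTruth]:
    """Three call sets with a planted shared/specific partition.

    ``n_shared_all`` events appear in every genome, ``n_shared_pair`` in
    each of the three genome pairs, and ``n_specific`` in each single
    genome.  Breakpoints of shared events are jittered by up to ``jitter``
    bp per copy — small relative to the minimum event size, so shared
    events still satisfy the 50% reciprocal-overlap rule (and insertion
    copies stay within the breakpoint window).
    """
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    if jitter * 4 >= size_range[0]:
        raise ValidationError("jitter too large for the minimum event size")
    rng = np.random.default_rng(seed)
    genome_ids = list(genome_ids)
    memberships: list[frozenset] = []
    memberships += [frozenset(genome_ids)] * n_shared_all
    for i in range(len(genome_ids)):
        for j in range(i + 1, len(genome_ids)):
            memberships += [frozenset({genome_ids[i], genome_ids[j]})] * n_shared_pair
    for gid in genome_ids:
        memberships += [frozenset({gid})] * n_specific

    chroms = list(chrom_lengths)
    records: dict[str, list[SVRecord]] = {gid: [] for gid in genome_ids}
    truth = CallSetTruth(membership={}, record_ids={gid: {} for gid in genome_ids})
    # lay events on a coarse grid so distinct events can never cross-match
    spacing = size_range[1] + 10_000
    per_chrom_slots = {c: (chrom_lengths[c] - size_range[1]) // spacing for c in chroms}
    slots = [(c, k) for c in chroms for k in range(per_chrom_slots[c])]
    if len(memberships) > len(slots):
        raise ValidationError("too many events for the given chromosome lengths")
    rng.shuffle(slots)

    for e, member in enumerate(memberships):
        chrom, slot = slots[e]
        base = slot * spacing + 1000
        svtype = SVType(svtypes[int(rng.integers(0, len(svtypes)))])
        length = int(rng.integers(size_range[0], size_range[1] + 1))
        event_id = f"ev{e:04d}"
        truth.membership[event_id] = member
        for gid in genome_ids:
            if gid not in member:
                continue
            shift = int(rng.integers(-jitter, jitter + 1)) if len(member) > 1 else 0
            start = base + shift
            rid = f"{event_id}_{gid}"
            if svtype is SVType.INS:
                rec = SVRecord(id=rid, chrom=chrom, start=start, end=start,
                               svtype=svtype, length=length)
            else:
                rec = SVRecord(id=rid, chrom=chrom, start=start,
                               end=start + length, svtype=svtype, length=length)
            records[gid].append(rec)
            truth.record_ids[gid][event_id] = rid

    callsets = {
        gid: CallSet(genome_id=gid, records=records[gid],
                     chrom_lengths=chrom_lengths)
        for gid in genome_ids
    }
    return callsets, truth


# ---------------------------------------------------------------------------
# Haplotype panels
# ---------------------------------------------------------------------------

def simulate_haplotypes(
    n_haps: int = 120,
    n_sites: int = 41,
    sweep: bool = True,
    sweep_span: int = 500_000,
    region_span: int = 1_000_000,
    focal_freq: float = 0.5,
    mutation_prob: float = 0.02,
    seed: int = 0,
) -> HaplotypePanel:
    """Biallelic haplotypes around a central focal site.

    Neutral mode draws every site independently (per-site frequencies
    uniform on [0.1, 0.9]).  Sweep mode additionally copies one founder
    haplotype across all carriers of the focal allele at sites within
    ``sweep_span``/2 of the core, with a small per-site mutation
    probability — an extended shared haplotype, the footprint a recent
    partial sweep leaves.
    """
    rng = np.random.default_rng(seed)
    positions = np.linspace(0, region_span, n_sites).astype(np.int64)
    positions = np.unique(positions)
    n_sites = positions.size
    focal_index = n_sites // 2
    site_freqs = rng.uniform(0.1, 0.9, n_sites)
    haps = (rng.random((n_haps, n_sites)) < site_freqs).astype(np.int8)
    haps[:, focal_index] = (rng.random(n_haps) < focal_freq).astype(np.int8)
    if sweep:
        founder = (rng.random(n_sites) < site_freqs).astype(np.int8)
        near = np.abs(positions - positions[focal_index]) <= sweep_span / 2
        carriers = np.where(haps[:, focal_index] == 1)[0]
        for h in carriers:
            copy = founder.copy()
            mut = rng.random(n_sites) < mutation_prob
            copy[mut] = 1 - copy[mut]
            haps[h, near] = copy[near]
        haps[:, focal_index] = 0
        haps[carriers, focal_index] = 1
    return HaplotypePanel(haplotypes=haps, positions=positions,
                          focal_index=int(focal_index), focal_allele=1)


# ---------------------------------------------------------------------------
# Toy reference + assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAssembly:
    reference: dict[str, str]          # chrom -> sequence with N-gaps
    assembly: dict[str, str]           # scaffold -> sequence
    ref_gaps: list[GenomicElement]
    blocks: list[AlignmentBlock]
    nrs_lengths: dict[str, int]
    coverage: dict[str, CoverageProfile]
    truth: dict


def simulate_assembly(
    chrom_length: int = 60_000,
    n_gaps: int = 8,
    n_closed: int = 3,
    gap_size_range: tuple[int, int] = (100, 400),
    n_nrs: int = 6,
    n_shared: int = 3,
    nrs_size_range: tuple[int, int] = (200, 800),
    shared_cover_frac: float = 0.95,
    unshared_cover_frac: float = 0.30,
    min_flank: int = 200,
    seed: int = 0,
) -> SimulatedAssembly:
    """A toy reference with N-gaps plus an assembly that closes some of them.

    The first ``n_closed`` gaps get a single spanning alignment block with
    ``min_flank`` anchored bases on each side; the remaining gaps get a
    block that stops inside the gap (not closable).  ``n_nrs`` non-reference
    segments are generated with archaic read coverage over approximately
    ``shared_cover_frac`` (first ``n_shared`` segments) or
    ``unshared_cover_frac`` of their bases.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    seq = rng.choice(bases, size=chrom_length)
    spacing = chrom_length // (n_gaps + 1)
    gaps: list[GenomicElement] = []
    for k in range(n_gaps):
        size = int(rng.integers(*gap_size_range))
        start = (k + 1) * spacing
        seq[start:start + size] = "N"
        gaps.append(GenomicElement(chrom="ref1", start=start, end=start + size,
                                   element_class="gap", name=f"gap{k}"))
    reference = {"ref1": "".join(seq)}

    blocks: list[AlignmentBlock] = []
    closed_ids = []
    for k, gap in enumerate(gaps):
        if k < n_closed:
            blocks.append(AlignmentBlock(
                query_id=f"scf{k}", query_start=0,
                query_end=(gap.end - gap.start) + 2 * min_flank,
                ref_chrom="ref1", ref_start=gap.start - min_flank,
                ref_end=gap.end + min_flank, identity=0.999,
            ))
            closed_ids.append(gap.name)
        else:
            # block enters the gap from the left but never reaches the far side
            blocks.append(AlignmentBlock(
                query_id=f"scf{k}", query_start=0, query_end=min_flank + 10,
                ref_chrom="ref1", ref_start=gap.start - min_flank,
                ref_end=gap.start + 10, identity=0.999,
            ))

    assembly = {
        b.query_id: "".join(rng.choice(bases, size=b.query_end - b.query_start))
        for b in blocks
    }

    nrs_lengths: dict[str, int] = {}
    coverage: dict[str, CoverageProfile] = {}
    shared_ids = []
    for k in range(n_nrs):
        seg = f"nrs{k}"
        L = int(rng.integers(*nrs_size_range))
        nrs_lengths[seg] = L
        frac = shared_cover_frac if k < n_shared else unshared_cover_frac
        covered = rng.random(L) < frac
        depth = np.where(covered, rng.integers(1, 6, L), 0)
        coverage[seg] = CoverageProfile(segment_id=seg, depth=depth)
        if k < n_shared:
            shared_ids.append(seg)

    return SimulatedAssembly(
        reference=reference, assembly=assembly, ref_gaps=gaps, blocks=blocks,
        nrs_lengths=nrs_lengths, coverage=coverage,
        truth={
            "closed_gaps": closed_ids,
            "closed_length": sum(g.end - g.start for g in gaps
                                 if g.name in closed_ids),
            "shared_nrs": shared_ids,
            "gap_count": n_gaps,
            "gap_length": sum(g.end - g.start for g in gaps),
        },
    )


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
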