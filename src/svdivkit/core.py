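"""Domain types, file I/O, and descriptive structural-variant summaries.

Coordinates are 0-based half-open everywhere inside the package; VCF and
other 1-based formats are converted at the I/O boundary.  An insertion is a
breakpoint: its interval is ``[start, start)`` and its size lives in
``length``; for every other class ``length == end - start``.

Structural variants are taken seriously in the 50 bp – 2 Mb window; records
outside that window are retained but flagged ``out_of_range`` so downstream
divergence statistics can skip them without destroying the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .errors import (
    InputFormatError,
    InsufficientDataError,
    ValidationError,
)

SV_SIZE_MIN = 50
SV_SIZE_MAX = 2_000_000

MISSING = "NA"


class SVType(str, Enum):
    """Structural-variant class.  CPX is an opaque catch-all."""

    DEL = "DEL"
    INS = "INS"
    DUP = "DUP"
    INV = "INV"
    CPX = "CPX"

    @classmethod
    def coerce(cls, value: "str | SVType") -> "SVType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            warnings.warn(
                f"unknown SVTYPE {value!r} mapped to CPX", stacklevel=2
            )
            return cls.CPX


@dataclass(frozen=True)
class SVRecord:
    """One structural variant on the internal 0-based half-open system."""

    id: str
    chrom: str
    start: int
    end: int
    svtype: SVType
    length: int
    inserted_seq: str | None = None
    repeat_fraction: float = 0.0
    support: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "svtype", SVType.coerce(self.svtype))
        object.__setattr__(self, "support", frozenset(self.support))
        if self.end < self.start:
            raise ValidationError(f"{self.id}: end < start")
        if self.length < 1:
            raise ValidationError(f"{self.id}: length must be >= 1")
        if self.svtype is not SVType.INS and self.length != self.end - self.start:
            raise ValidationError(
                f"{self.id}: non-INS length {self.length} != end-start "
                f"{self.end - self.start}"
            )
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValidationError(f"{self.id}: repeat_fraction outside [0,1]")

    @property
    def out_of_range(self) -> bool:
        """True when the variant falls outside the 50 bp – 2 Mb window."""
        return not (SV_SIZE_MIN <= self.length <= SV_SIZE_MAX)

    @property
    def footprint(self) -> tuple[int, int]:
        """Genomic interval occupied on the reference (a point for INS)."""
        return (self.start, self.end)


@dataclass
class CallSet:
    """All SV records of one assembled genome."""

    genome_id: str
    records: list[SVRecord]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"{self.genome_id}: duplicate record ids")
        for r in self.records:
            L = self.chrom_lengths.get(r.chrom)
            if L is not None and r.end > L:
                raise ValidationError(
                    f"{r.id}: end {r.end} beyond {r.chrom} length {L}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def sorted_records(self) -> list[SVRecord]:
        return sorted(self.records, key=lambda r: (r.chrom, r.start, r.id))

    def by_type(self) -> dict[SVType, list[SVRecord]]:
        out: dict[SVType, list[SVRecord]] = {}
        for r in self.records:
            out.setdefault(r.svtype, []).append(r)
        return out


@dataclass(frozen=True)
class GenomicElement:
    """A functional genomic interval (CDS, UTR, exon, gene, UCE, ...)."""

    chrom: str
    start: int
    end: int
    element_class: str = "other"
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"element {self.name or self.element_class}: end <= start"
            )


class GenotypeMatrix:
    """Samples x loci dosage (0/1/2) or copy-number matrix with populations.

    Missing entries are NaN.  ``pop_labels`` maps each sample to a
    population name; divergence statistics require at least two populations.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        locus_ids: Sequence[str],
        values: np.ndarray,
        pop_labels: Mapping[str, str],
    ):
        self.sample_ids = list(sample_ids)
        self.locus_ids = list(locus_ids)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValidationError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        missing = set(self.sample_ids) - set(pop_labels)
        if missing:
            raise ValidationError(f"samples without population label: {sorted(missing)[:5]}")
        self.pop_labels = {s: pop_labels[s] for s in self.sample_ids}

    # -- access -----------------------------------------------------------
    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_labels[s], None)
        return list(seen)

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_ids.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def dosages(self, locus: str, population: str | None = None) -> np.ndarray:
        """Per-sample values at a locus, optionally restricted to one population."""
        col = self.values[:, self.locus_index(locus)]
        if population is None:
            return col.copy()
        mask = np.array([self.pop_labels[s] == population for s in self.sample_ids])
        return col[mask]

    def population_vector(self) -> np.ndarray:
        return np.array([self.pop_labels[s] for s in self.sample_ids])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.locus_ids)


class PhenotypeTable:
    """Samples x quantitative traits; NaN marks missing measurements."""

    def __init__(
        self,
        sample_ids: Sequence[str],
        traits: Sequence[str],
        values: np.ndarray,
        units: Mapping[str, str] | None = None,
    ):
        self.sample_ids = list(sample_ids)
        self.traits = list(traits)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.traits)):
            raise ValidationError("phenotype table shape mismatch")
        self.units = dict(units or {})

    def trait_values(self, trait: str) -> np.ndarray:
        try:
            j = self.traits.index(trait)
        except ValueError:
            raise KeyError(f"unknown trait {trait!r}") from None
        return self.values[:, j].copy()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.traits)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_VCF_INFO_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length in bp">',
    '##INFO=<ID=REPFRAC,Number=1,Type=Float,Description="Fraction of the SV covered by repeats">',
    '##INFO=<ID=SUPPORT,Number=.,Type=String,Description="Supporting platforms">',
    '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Inserted sequence">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=DUP,Description="Duplication">',
    '##ALT=<ID=INV,Description="Inversion">',
    '##ALT=<ID=CPX,Description="Complex SV">',
]


def read_sv_vcf(path: str | Path, chrom_lengths: Mapping[str, int] | None = None,
                genome_id: str | None = None) -> CallSet:
    """Read a structural-variant VCF into a :class:`CallSet`.

    VCF 1-based inclusive coordinates become 0-based half-open.  Insertion
    length comes from SVLEN or, failing that, the inserted allele sequence.
    Records outside 50 bp – 2 Mb are kept; :attr:`SVRecord.out_of_range`
    flags them.  A record without SVTYPE raises :class:`InputFormatError`
    with its line number; an unrecognised SVTYPE becomes CPX with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        header_lines = sum(1 for line in fh if line.startswith("#"))
    with pysam.VariantFile(str(path)) as vf:
        records: list[SVRecord] = []
        contig_lengths: dict[str, int] = {}
        for name, contig in vf.header.contigs.items():
            if contig.length:
                contig_lengths[name] = contig.length
        def info_get(rec, key, default=None):
            # pysam raises on keys absent from the header definition
            try:
                return rec.info.get(key, default)
            except (KeyError, ValueError):
                return default

        for i, rec in enumerate(vf):
            line_no = header_lines + i + 1
            svtype_raw = info_get(rec, "SVTYPE")
            if svtype_raw is None:
                raise InputFormatError("record is missing SVTYPE", line=line_no)
            svtype = SVType.coerce(svtype_raw)
            start = rec.start  # pysam: 0-based
            svlen = info_get(rec, "SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            inserted_seq = info_get(rec, "INSSEQ")
            if svtype is SVType.INS:
                end = start
                if svlen is not None:
                    length = abs(int(svlen))
                elif inserted_seq:
                    length = len(inserted_seq)
                elif rec.alts and not rec.alts[0].startswith("<"):
                    # sequence-resolved insertion: ALT carries ref base + insert
                    length = max(len(rec.alts[0]) - len(rec.ref), 1)
                    inserted_seq = rec.alts[0][len(rec.ref):]
                else:
                    raise InputFormatError(
                        "INS record without SVLEN or sequence", line=line_no
                    )
            else:
                end = rec.stop  # END (converted to 0-based exclusive == 1-based value)
                length = end - start
            repfrac = float(info_get(rec, "REPFRAC", 0.0))
            support = info_get(rec, "SUPPORT", ())
            if isinstance(support, str):
                support = (support,)
            rid = rec.id or f"{path.stem}_{i}"
            records.append(
                SVRecord(
                    id=rid, chrom=rec.chrom, start=start, end=end,
                    svtype=svtype, length=length, inserted_seq=inserted_seq,
                    repeat_fraction=repfrac, support=frozenset(support),
                )
            )
    lengths = dict(chrom_lengths) if chrom_lengths else contig_lengths
    return CallSet(genome_id=genome_id or path.stem, records=records,
                   chrom_lengths=lengths)


def write_sv_vcf(callset: CallSet, path: str | Path) -> None:
    """Write a CallSet as VCF 4.2 with symbolic ALT alleles."""
    header = pysam.VariantHeader()
    for line in _VCF_INFO_LINES:
        header.add_line(line)
    for chrom, L in callset.chrom_lengths.items():
        header.contigs.add(chrom, length=L)
    # contigs present in records but not in chrom_lengths still need declaring
    for r in callset.records:
        if r.chrom not in header.contigs:
            header.contigs.add(r.chrom)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in callset.sorted_records():
            stop = r.end if r.svtype is not SVType.INS else r.start + 1
            rec = vf.new_record(
                contig=r.chrom, start=r.start, stop=max(stop, r.start + 1),
                alleles=("N", f"<{r.svtype.value}>"), id=r.id,
            )
            rec.info["SVTYPE"] = r.svtype.value
            # htslib force-derives END from SVLEN for symbolic alleles
            # (VCF 4.4 semantics), which clashes with the END convention
            # used here; SVLEN is therefore only written where it is the
            # sole length carrier (insertions).
            if r.svtype is SVType.INS:
                rec.info["SVLEN"] = r.length
            if r.repeat_fraction:
                rec.info["REPFRAC"] = r.repeat_fraction
            if r.support:
                rec.info["SUPPORT"] = tuple(sorted(r.support))
            if r.inserted_seq:
                rec.info["INSSEQ"] = r.inserted_seq
            vf.write(rec)


def read_bed(path: str | Path, element_class: str | None = None) -> list[GenomicElement]:
    """Read BED3/BED6 into elements; column 4 (name) doubles as the class
    when no explicit class is given."""
    out: list[GenomicElement] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                raise InputFormatError("BED line has fewer than 3 columns", line=ln)
            name = parts[3] if len(parts) > 3 else ""
            out.append(
                GenomicElement(
                    chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                    element_class=element_class or name or "other", name=name,
                )
            )
    return out


def write_bed(elements: Iterable[GenomicElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.name or e.element_class}\n")


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     comment="#", dtype={"chrom": str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, L in lengths.items():
            fh.write(f"{chrom}\t{L}\n")


def read_genotype_matrix(path: str | Path, pops_path: str | Path) -> GenotypeMatrix:
    """Tab-delimited matrix (rows = samples, columns = loci, ``NA`` missing)
    plus a two-column sample→population table."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])
    pops = pd.read_csv(pops_path, sep="\t", header=None, names=["sample", "pop"],
                       dtype=str)
    labels = dict(zip(pops["sample"], pops["pop"]))
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        locus_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        pop_labels=labels,
    )


def write_genotype_matrix(g: GenotypeMatrix, path: str | Path,
                          pops_path: str | Path | None = None) -> None:
    g.to_dataframe().to_csv(path, sep="\t", na_rep=MISSING, index_label="sample")
    if pops_path is not None:
        with open(pops_path, "w") as fh:
            for s in g.sample_ids:
                fh.write(f"{s}\t{g.pop_labels[s]}\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])
    return PhenotypeTable(
        sample_ids=[str(s) for s in df.index],
        traits=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_phenotypes(t: PhenotypeTable, path: str | Path) -> None:
    t.to_dataframe().to_csv(path, sep="\t", na_rep=MISSING, index_label="sample")


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

@dataclass
class SVSummary:
    total: int
    counts: dict[str, int]
    median_length: dict[str, float]
    fraction_below_1kb: float
    affected_bp: int
    fraction_with_repeats: float


def sv_summary(callset: CallSet) -> SVSummary:
    """Per-class counts and sizes, the sub-1-kb fraction, the total affected
    footprint (union of non-INS intervals plus inserted lengths), and the
    fraction of records containing any repeat sequence."""
    if not callset.records:
        raise InsufficientDataError("cannot summarise an empty call set")
    counts: dict[str, int] = {}
    lengths: dict[str, list[int]] = {}
    for r in callset.records:
        counts[r.svtype.value] = counts.get(r.svtype.value, 0) + 1
        lengths.setdefault(r.svtype.value, []).append(r.length)
    medians = {k: float(np.median(v)) for k, v in lengths.items()}
    all_lengths = np.array([r.length for r in callset.records])
    frac_small = float(np.mean(all_lengths < 1000))

    # union of non-INS footprints per chromosome
    affected = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in callset.records:
        if r.svtype is SVType.INS:
            affected += r.length
        else:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for ivals in by_chrom.values():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                affected += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        affected += cur_e - cur_s

    frac_rep = float(np.mean([r.repeat_fraction > 0 for r in callset.records]))
    return SVSummary(
        total=len(callset.records), counts=counts, median_length=medians,
        fraction_below_1kb=frac_small, affected_bp=affected,
        fraction_with_repeats=frac_rep,
    )


def sv_chrom_correlation(callset: CallSet) -> tuple[float, float, pd.DataFrame]:
    """OLS of per-chromosome SV count on chromosome length.

    Returns (R², two-sided p for the slope, per-chromosome table).  Needs
    at least three chromosomes with known lengths.
    """
    counts: dict[str, int] = {c: 0 for c in callset.chrom_lengths}
    for r in callset.records:
        if r.chrom in counts:
            counts[r.chrom] += 1
    table = pd.DataFrame(
        {
            "chrom": list(counts),
            "length": [callset.chrom_lengths[c] for c in counts],
            "n_svs": [counts[c] for c in counts],
        }
    )
    if len(table) < 3:
        raise InsufficientDataError(
            f"need >= 3 chromosomes with lengths, got {len(table)}"
        )
    res = stats.linregress(table["length"], table["n_svs"])
    r2 = float(res.rvalue**2)
    if np.ptp(table["n_svs"].to_numpy()) == 0:  # constant counts: R2 is 0
        r2, p = 0.0, 1.0
    else:
        p = float(res.pvalue)
    return r2, p, table
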