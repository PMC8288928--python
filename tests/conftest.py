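import numpy as np
import pytest

from svdivkit.core import CallSet, SVRecord, SVType


def make_sv(id, chrom="chr1", start=1000, end=None, svtype="DEL", length=None,
            **kw):
    svtype = SVType(svtype)
    if svtype is SVType.INS:
        end = start
        length = length or 100
    else:
        end = end if end is not None else start + (length or 100)
        length = end - start
    return SVRecord(id=id, chrom=chrom, start=start, end=end, svtype=svtype,
                    length=length, **kw)


def random_callset(genome_id, n_records, seed, chrom_lengths=None,
                   svtypes=("DEL", "DUP", "INS"), region=50_000):
    """Dense random call set (many incidental overlaps) for oracle tests."""
    rng = np.random.default_rng(seed)
    chrom_lengths = chrom_lengths or {"chr1": 100_000, "chr2": 100_000}
    chroms = list(chrom_lengths)
    records = []
    for i in range(n_records):
        chrom = chroms[int(rng.integers(len(chroms)))]
        svtype = SVType(svtypes[int(rng.integers(len(svtypes)))])
        start = int(rng.integers(0, region))
        length = int(rng.integers(50, 500))
        if svtype is SVType.INS:
            rec = SVRecord(id=f"{genome_id}_{i}", chrom=chrom, start=start,
                           end=start, svtype=svtype, length=length)
        else:
            rec = SVRecord(id=f"{genome_id}_{i}", chrom=chrom, start=start,
                           end=start + length, svtype=svtype, length=length)
        records.append(rec)
    return CallSet(genome_id=genome_id, records=records,
                   chrom_lengths=chrom_lengths)


@pytest.fixture
def tiny_callset():
    records = [
        make_sv("del1", start=1000, end=1200),
        make_sv("del2", start=5000, end=5100),
        make_sv("ins1", start=3000, svtype="INS", length=300),
    ]
    return CallSet(genome_id="tiny", records=records,
                   chrom_lengths={"chr1": 100_000})
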