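import numpy as np
import pytest

from gsikit.loci import (
    DIPLOID,
    HAPLOID_COMPOSITE,
    BaselineSet,
    GenotypeRecord,
    LocusDefinition,
)


@pytest.fixture
def snp_loci():
    return [
        LocusDefinition("L1", DIPLOID, ("A", "C")),
        LocusDefinition("L2", DIPLOID, ("G", "T")),
        LocusDefinition("L3", DIPLOID, ("A", "G")),
    ]


@pytest.fixture
def mixed_loci(snp_loci):
    return snp_loci + [LocusDefinition("mt", HAPLOID_COMPOSITE, ("H1", "H2", "H3"))]


def make_baseline(counts_by_pop, loci, group_map, groups):
    """Counts-only baseline from {pop: {locus: [counts...]}}."""
    pops = list(counts_by_pop)
    counts = {
        pop: {n: np.asarray(v, dtype=np.int64) for n, v in per.items()}
        for pop, per in counts_by_pop.items()
    }
    return BaselineSet(
        loci=list(loci),
        populations=pops,
        group_map=dict(group_map),
        groups=tuple(groups),
        counts=counts,
    )


@pytest.fixture
def two_pop_one_locus_baseline():
    """Two populations, one biallelic SNP, frequencies 0.7/0.3 and 0.3/0.7.

    With the flat-total prior (0.5 pseudocounts per allele) the baseline
    posterior-mean frequencies are exactly (3 + 0.5)/5 = 0.7 etc., so the
    sampler's fixed frequencies match the values used by enumeration oracles.
    """
    loci = [LocusDefinition("L1", DIPLOID, ("A", "C"))]
    return make_baseline(
        {"p1": {"L1": [3, 1]}, "p2": {"L1": [1, 3]}},
        loci,
        {"p1": "G1", "p2": "G2"},
        ("G1", "G2"),
    )


def make_record(rid, calls, **kw):
    return GenotypeRecord(individual_id=rid, calls=calls, **kw)
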