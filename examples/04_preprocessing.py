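"""SNP panel cleanup: monomorphic/LD/failed-assay drops and composites.

Builds a small individual-level baseline containing a monomorphic locus, a
linkage-disequilibrium pair, three mitochondrial SNPs, and an MHC locus
pair, then applies the standard preprocessing: the monomorphic locus and
the designated LD member are dropped, the mtDNA SNPs merge into one haploid
haplotype locus, and the MHC pair becomes one joint-genotype "phenotype"
locus.  Fish missing too many calls are excluded afterwards.
"""

import numpy as np

from gsikit import (
    BaselineSet,
    CompositeSpec,
    GenotypeRecord,
    LocusDefinition,
    PreprocessConfig,
    filter_missing,
    preprocess_loci,
)
from gsikit.loci import DIPLOID, HAPLOID_COMPOSITE, PHENOTYPE_COMPOSITE

rng = np.random.default_rng(5)
loci = [
    LocusDefinition("mono-1", DIPLOID, ("A", "C")),
    LocusDefinition("ld-a", DIPLOID, ("A", "G")),
    LocusDefinition("ld-b", DIPLOID, ("A", "G")),
    LocusDefinition("mt1", HAPLOID_COMPOSITE, ("A", "G")),
    LocusDefinition("mt2", HAPLOID_COMPOSITE, ("C", "T")),
    LocusDefinition("mt3", HAPLOID_COMPOSITE, ("A", "G")),
    LocusDefinition("mhc1", DIPLOID, ("A", "T")),
    LocusDefinition("mhc2", DIPLOID, ("C", "G")),
]


def random_fish(rid):
    def pair(symbols):
        return tuple(sorted(str(a) for a in rng.choice(symbols, 2)))

    calls = {"mono-1": ("A", "A")}  # same allele everywhere: monomorphic
    calls["ld-a"] = pair(["A", "G"])
    calls["ld-b"] = pair(["A", "G"])
    for name, alphabet in (("mt1", "AG"), ("mt2", "CT"), ("mt3", "AG")):
        calls[name] = str(rng.choice(list(alphabet)))
    calls["mhc1"] = pair(["A", "T"])
    calls["mhc2"] = pair(["C", "G"])
    return GenotypeRecord(rid, calls)


baseline = BaselineSet.from_individuals(
    loci,
    {"p1": [random_fish(f"p1_{i}") for i in range(12)],
     "p2": [random_fish(f"p2_{i}") for i in range(12)]},
    {"p1": "Black Lake", "p2": "Chignik Lake"},
    ("Black Lake", "Chignik Lake"),
)
mixture = [random_fish(f"mix_{i}") for i in range(5)]
# one fish missing most of its genotype
mixture.append(GenotypeRecord("mix_sparse", {loc.name: None for loc in loci}))

config = PreprocessConfig(
    ld_pairs=[("ld-a", "ld-b")],
    composites=(
        CompositeSpec("mtDNA", HAPLOID_COMPOSITE, ("mt1", "mt2", "mt3")),
        CompositeSpec("MHC", PHENOTYPE_COMPOSITE, ("mhc1", "mhc2")),
    ),
)
new_baseline, new_mixture, report = preprocess_loci(baseline, mixture, config)
retained, excluded = filter_missing(new_mixture, new_baseline.loci, 0.15)

print("dropped monomorphic :", report.loci_dropped_monomorphic)
print("dropped LD member   :", report.loci_dropped_ld)
print("composites created  :", report.composites_created)
print("final locus set     :", new_baseline.locus_names)
print("mtDNA haplotypes    :", list(new_baseline.locus("mtDNA").alleles))
print("example fish calls  :", new_mixture[0].calls)
print(f"missing-data filter : {len(retained)} retained, {len(excluded)} excluded "
      "(>= 15% of loci missing)")
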