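"""Core data model: marker definitions, genotype records, and baselines.

Genetic stock identification (GSI) works with three kinds of markers:

* diploid nuclear SNPs, observed as unordered allele pairs;
* composite haploid loci (e.g. several mitochondrial SNPs inherited as one
  haplotype), observed as a single category;
* composite "phenotype" loci (e.g. a pair of tightly linked MHC loci scored
  jointly), also observed as a single category with empirical frequencies.

A missing call is represented by ``None`` (:data:`MISSING`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "MISSING",
    "DIPLOID",
    "HAPLOID_COMPOSITE",
    "PHENOTYPE_COMPOSITE",
    "LocusDefinition",
    "GenotypeRecord",
    "BaselineSet",
    "PreprocessReport",
    "canonical_diploid_call",
]

MISSING = None

DIPLOID = "diploid_nuclear"
HAPLOID_COMPOSITE = "haploid_composite"
PHENOTYPE_COMPOSITE = "phenotype_composite"

_MODES = (DIPLOID, HAPLOID_COMPOSITE, PHENOTYPE_COMPOSITE)

#: a call is an unordered allele pair (diploid), a category string
#: (composite), or ``None`` for missing
Call = Union[tuple, str, type(None)]


def canonical_diploid_call(a: str, b: str) -> tuple:
    """Return the lexicographically sorted allele pair, so ``A/C == C/A``."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class LocusDefinition:
    """One marker with its mode and allele (or category) alphabet."""

    name: str
    mode: str
    alleles: tuple

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"unknown locus mode {self.mode!r} for {self.name}")
        alleles = tuple(self.alleles)
        if not alleles:
            raise ValueError(f"locus {self.name} has an empty allele alphabet")
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"locus {self.name} has duplicate alleles")
        object.__setattr__(self, "alleles", alleles)

    @property
    def is_diploid(self) -> bool:
        return self.mode == DIPLOID

    def allele_index(self) -> dict:
        return {a: i for i, a in enumerate(self.alleles)}

    def validate_call(self, call: Call) -> None:
        """Raise ``ValueError`` if *call* is not expressible at this locus."""
        if call is MISSING:
            return
        if self.is_diploid:
            if not (isinstance(call, tuple) and len(call) == 2):
                raise ValueError(
                    f"diploid locus {self.name} expects an allele pair, got {call!r}"
                )
            for a in call:
                if a not in self.alleles:
                    raise ValueError(f"allele {a!r} not in alphabet of {self.name}")
        else:
            if call not in self.alleles:
                raise ValueError(f"category {call!r} not in alphabet of {self.name}")


@dataclass
class GenotypeRecord:
    """One individual's calls plus optional morphometrics and metadata."""

    individual_id: str
    calls: dict  # locus name -> Call
    length_mm: Optional[float] = None
    mass_g: Optional[float] = None
    capture_site: Optional[str] = None
    year: Optional[int] = None
    population: Optional[str] = None

    def __post_init__(self):
        if self.length_mm is not None and not self.length_mm > 0:
            raise ValueError(
                f"{self.individual_id}: length_mm must be > 0, got {self.length_mm}"
            )
        if self.mass_g is not None and not self.mass_g > 0:
            raise ValueError(
                f"{self.individual_id}: mass_g must be > 0, got {self.mass_g}"
            )

    def missing_fraction(self, loci: Sequence[LocusDefinition]) -> float:
        if not loci:
            raise ValueError("empty locus set")
        n_missing = sum(1 for loc in loci if self.calls.get(loc.name) is MISSING)
        return n_missing / len(loci)

    def subset(self, locus_names: Iterable[str]) -> "GenotypeRecord":
        names = list(locus_names)
        return replace(self, calls={n: self.calls.get(n, MISSING) for n in names})


def _count_calls(loci, records):
    """Per-locus allele/category count vectors accumulated over *records*."""
    counts = {}
    for loc in loci:
        idx = loc.allele_index()
        vec = np.zeros(len(loc.alleles), dtype=np.int64)
        for rec in records:
            call = rec.calls.get(loc.name)
            if call is MISSING:
                continue
            if loc.is_diploid:
                vec[idx[call[0]]] += 1
                vec[idx[call[1]]] += 1
            else:
                vec[idx[call]] += 1
        counts[loc.name] = vec
    return counts


@dataclass
class BaselineSet:
    """Reference populations with per-locus allele counts and a group map.

    ``counts[pop][locus_name]`` is an integer vector aligned with the
    locus's allele alphabet.  When the baseline was built from (or ships
    with) individual genotypes, ``individuals[pop]`` holds them; this is
    required for holdout calibration, which removes whole fish.
    """

    loci: list  # of LocusDefinition
    populations: list  # of population ids, ordered
    group_map: dict  # population id -> stock group
    groups: tuple  # ordered stock-group labels
    counts: dict  # pop -> {locus name -> np.ndarray of counts}
    individuals: Optional[dict] = None  # pop -> list[GenotypeRecord]

    def __post_init__(self):
        for pop in self.populations:
            if pop not in self.group_map:
                raise ValueError(f"population {pop!r} missing from group_map")
            if self.group_map[pop] not in self.groups:
                raise ValueError(
                    f"group {self.group_map[pop]!r} of {pop!r} not in {self.groups}"
                )
        for pop in self.populations:
            for loc in self.loci:
                vec = np.asarray(self.counts[pop][loc.name])
                if vec.shape != (len(loc.alleles),):
                    raise ValueError(
                        f"count vector for {pop}/{loc.name} has wrong length"
                    )
                if (vec < 0).any():
                    raise ValueError(f"negative count at {pop}/{loc.name}")

    @property
    def locus_names(self) -> list:
        return [loc.name for loc in self.loci]

    def locus(self, name: str) -> LocusDefinition:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    @classmethod
    def from_individuals(
        cls,
        loci: Sequence[LocusDefinition],
        individuals: Mapping[str, Sequence[GenotypeRecord]],
        group_map: Mapping[str, str],
        groups: Sequence[str],
    ) -> "BaselineSet":
        loci = list(loci)
        pops = list(individuals)
        counts = {pop: _count_calls(loci, individuals[pop]) for pop in pops}
        return cls(
            loci=loci,
            populations=pops,
            group_map=dict(group_map),
            groups=tuple(groups),
            counts=counts,
            individuals={pop: list(individuals[pop]) for pop in pops},
        )

    def subset_loci(self, locus_names: Iterable[str]) -> "BaselineSet":
        keep = list(locus_names)
        loci = [self.locus(n) for n in keep]
        counts = {
            pop: {n: np.array(self.counts[pop][n]) for n in keep}
            for pop in self.populations
        }
        individuals = None
        if self.individuals is not None:
            individuals = {
                pop: [rec.subset(keep) for rec in recs]
                for pop, recs in self.individuals.items()
            }
        return BaselineSet(
            loci=loci,
            populations=list(self.populations),
            group_map=dict(self.group_map),
            groups=self.groups,
            counts=counts,
            individuals=individuals,
        )

    def count_matrix(self, locus: LocusDefinition) -> np.ndarray:
        """Counts for one locus as a (n_populations, n_alleles) array."""
        return np.stack([self.counts[pop][locus.name] for pop in self.populations])

    def group_indicator(self) -> np.ndarray:
        """(n_populations, n_groups) 0/1 matrix mapping populations to groups."""
        g_index = {g: j for j, g in enumerate(self.groups)}
        mat = np.zeros((len(self.populations), len(self.groups)))
        for i, pop in enumerate(self.populations):
            mat[i, g_index[self.group_map[pop]]] = 1.0
        return mat

    def without_individuals(self, held_out: Mapping[str, Sequence[GenotypeRecord]]):
        """Rebuild counts after removing *held_out* fish (per population).

        Count conservation holds exactly: rebuilt counts plus the held-out
        fish's own allele counts equal the original counts.
        """
        if self.individuals is None:
            raise ValueError("baseline has no individual genotypes to hold out")
        kept = {}
        for pop in self.populations:
            out_ids = {rec.individual_id for rec in held_out.get(pop, ())}
            kept[pop] = [
                rec for rec in self.individuals[pop] if rec.individual_id not in out_ids
            ]
            if len(kept[pop]) != len(self.individuals[pop]) - len(out_ids):
                raise ValueError(f"held-out ids not all present in population {pop}")
        return BaselineSet.from_individuals(
            self.loci, kept, self.group_map, self.groups
        )


@dataclass
class PreprocessReport:
    """What preprocessing did: dropped loci, built composites, excluded fish."""

    loci_dropped_monomorphic: list = field(default_factory=list)
    loci_dropped_ld: list = field(default_factory=list)
    loci_dropped_failed_assay: list = field(default_factory=list)
    composites_created: list = field(default_factory=list)
    individuals_excluded_missing: list = field(default_factory=list)  # (id, fraction)

    @property
    def empty(self) -> bool:
        return not (
            self.loci_dropped_monomorphic
            or self.loci_dropped_ld
            or self.loci_dropped_failed_assay
            or self.composites_created
            or self.individuals_excluded_missing
        )
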