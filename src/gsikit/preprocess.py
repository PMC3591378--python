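"""Baseline/mixture preprocessing: locus filtering and composite building.

The cleaning rules applied before stock-identification inference are:

* drop loci whose assay failed outright;
* drop loci that are monomorphic across the baseline populations
  (monomorphism is judged on the baseline only — variation present only in
  the mixture does not rescue a locus);
* for each linkage-disequilibrium pair, drop the designated member;
* replace groups of jointly inherited markers with one composite locus —
  e.g. several mitochondrial SNPs become a single haploid haplotype locus,
  and a tightly linked pair of MHC loci becomes a single "phenotype" locus
  whose categories are the observed joint two-locus genotype classes.

A composite call is MISSING whenever any member call is MISSING.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .loci import (
    DIPLOID,
    HAPLOID_COMPOSITE,
    MISSING,
    PHENOTYPE_COMPOSITE,
    BaselineSet,
    GenotypeRecord,
    LocusDefinition,
    PreprocessReport,
)

__all__ = [
    "CompositeSpec",
    "PreprocessConfig",
    "preprocess_loci",
    "filter_missing",
]


@dataclass(frozen=True)
class CompositeSpec:
    """A composite locus to build from jointly inherited member loci."""

    name: str
    mode: str  # HAPLOID_COMPOSITE or PHENOTYPE_COMPOSITE
    members: tuple

    def __post_init__(self):
        if self.mode not in (HAPLOID_COMPOSITE, PHENOTYPE_COMPOSITE):
            raise ValueError(f"composite {self.name}: invalid mode {self.mode!r}")
        object.__setattr__(self, "members", tuple(self.members))


@dataclass
class PreprocessConfig:
    failed_assay_loci: tuple = ()
    ld_pairs: tuple = ()  # of (locus to drop, locus to keep)
    composites: tuple = ()  # of CompositeSpec
    max_missing_fraction: float = 0.15

    def __post_init__(self):
        self.failed_assay_loci = tuple(self.failed_assay_loci)
        self.ld_pairs = tuple(tuple(p) for p in self.ld_pairs)
        self.composites = tuple(self.composites)


class ConfigurationError(ValueError):
    """Inconsistent preprocessing configuration."""


def _monomorphic_loci(baseline: BaselineSet) -> list:
    """Loci with at most one allele observed across all baseline populations."""
    out = []
    for loc in baseline.loci:
        observed = (baseline.count_matrix(loc).sum(axis=0) > 0).sum()
        if observed <= 1:
            out.append(loc.name)
    return out


def _joint_call(rec: GenotypeRecord, members, member_loci):
    parts = []
    for loc in member_loci:
        call = rec.calls.get(loc.name)
        if call is MISSING:
            return MISSING
        parts.append("/".join(call) if loc.is_diploid else str(call))
    sep = "|" if any(loc.is_diploid for loc in member_loci) else "-"
    return sep.join(parts)


def preprocess_loci(
    baseline: BaselineSet,
    mixtures: Sequence[GenotypeRecord],
    config: PreprocessConfig,
):
    """Apply the locus-handling rules; returns ``(baseline, mixtures, report)``.

    Idempotent: a second application returns identical data and an empty
    report.  The output baseline and every output record share the same
    locus set.
    """
    report = PreprocessReport()
    present = set(baseline.locus_names)
    dropped = set()

    for name in config.failed_assay_loci:
        if name in present:
            dropped.add(name)
            report.loci_dropped_failed_assay.append(name)

    mono = [
        n for n in _monomorphic_loci(baseline)
        if n not in dropped
    ]
    dropped.update(mono)
    report.loci_dropped_monomorphic.extend(mono)

    for drop_name, _keep_name in config.ld_pairs:
        if drop_name in present and drop_name not in dropped:
            dropped.add(drop_name)
            report.loci_dropped_ld.append(drop_name)

    keep = [n for n in baseline.locus_names if n not in dropped]

    # composites: replace member loci with one joint locus
    composite_plans = []
    for spec in config.composites:
        members_present = [m for m in spec.members if m in keep]
        members_dropped = [m for m in spec.members if m in dropped]
        if members_dropped:
            raise ConfigurationError(
                f"composite {spec.name} references dropped loci {members_dropped}"
            )
        if not members_present:
            if spec.name in keep:
                continue  # already built on a previous pass
            raise ConfigurationError(
                f"composite {spec.name}: no member loci present"
            )
        if len(members_present) != len(spec.members):
            raise ConfigurationError(
                f"composite {spec.name}: members {set(spec.members) - set(members_present)} "
                f"absent from the baseline"
            )
        composite_plans.append(spec)

    if composite_plans and baseline.individuals is None:
        raise ConfigurationError(
            "building composite loci requires individual-level baseline genotypes "
            "(joint haplotype counts cannot be derived from marginal allele counts)"
        )

    member_names = {m for spec in composite_plans for m in spec.members}
    keep = [n for n in keep if n not in member_names]

    new_loci = [baseline.locus(n) for n in keep]
    new_mixture = [rec.subset(keep) for rec in mixtures]
    if baseline.individuals is not None:
        new_base_inds = {
            pop: [rec.subset(keep) for rec in recs]
            for pop, recs in baseline.individuals.items()
        }
    else:
        new_base_inds = None

    for spec in composite_plans:
        member_loci = [baseline.locus(m) for m in spec.members]
        categories = set()
        pools = [new_mixture]
        if new_base_inds is not None:
            pools.extend(new_base_inds.values())
        joint_calls = {}  # id(record) is unstable; key on (pool idx, rec idx)
        for rec, orig in _paired_records(
            new_mixture, mixtures, new_base_inds, baseline.individuals
        ):
            call = _joint_call(orig, spec.members, member_loci)
            joint_calls[id(rec)] = call
            if call is not MISSING:
                categories.add(call)
        if not categories:
            raise ConfigurationError(
                f"composite {spec.name}: every individual is missing a member call"
            )
        comp_locus = LocusDefinition(spec.name, spec.mode, tuple(sorted(categories)))
        new_loci.append(comp_locus)
        for rec, _ in _paired_records(
            new_mixture, mixtures, new_base_inds, baseline.individuals
        ):
            rec.calls[spec.name] = joint_calls[id(rec)]
        report.composites_created.append(spec.name)

    if new_base_inds is not None:
        new_baseline = BaselineSet.from_individuals(
            new_loci, new_base_inds, baseline.group_map, baseline.groups
        )
    else:
        new_baseline = baseline.subset_loci([loc.name for loc in new_loci])

    # a composite can itself come out monomorphic; it is then unusable
    late_mono = _monomorphic_loci(new_baseline)
    if late_mono:
        report.loci_dropped_monomorphic.extend(late_mono)
        report.composites_created = [
            n for n in report.composites_created if n not in late_mono
        ]
        keep2 = [n for n in new_baseline.locus_names if n not in late_mono]
        new_baseline = new_baseline.subset_loci(keep2)
        new_mixture = [rec.subset(keep2) for rec in new_mixture]

    return new_baseline, new_mixture, report


def _paired_records(new_mixture, old_mixture, new_base_inds, old_base_inds):
    yield from zip(new_mixture, old_mixture)
    if new_base_inds is not None:
        for pop in new_base_inds:
            yield from zip(new_base_inds[pop], old_base_inds[pop])


def filter_missing(
    records: Sequence[GenotypeRecord],
    loci: Sequence[LocusDefinition],
    max_missing_fraction: float = 0.15,
):
    """Partition records into (retained, excluded) by missing-call fraction.

    An individual is excluded iff its fraction of MISSING calls over the
    fixed locus set is **at least** ``max_missing_fraction`` (inclusive, so
    the default 0.15 excludes fish missing 15% or more of the loci).
    """
    if not 0 < max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in (0, 1]")
    if not loci:
        raise ValueError("empty locus set")
    retained, excluded = [], []
    for rec in records:
        if rec.missing_fraction(loci) >= max_missing_fraction:
            excluded.append(rec)
        else:
            retained.append(rec)
    return retained, excluded
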