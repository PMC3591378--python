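"""Synthetic baselines, mixtures, and length–mass data.

The generator emulates the structure of a sockeye salmon mixed-stock study
in the Chignik watershed: 13 baseline populations partitioned into three
stock groups (5 Black Lake, 7 Chignik Lake, 1 Chignik River), ~92 diploid
nuclear SNPs plus one composite haploid mitochondrial locus and one
composite MHC "phenotype" locus, mixture samples of a few hundred fish with
group proportions near 25%/75%/0%, and group-specific allometric
length–mass relationships with multiplicative (log-normal) noise.

Population allele frequencies follow the Balding–Nichols model: at each
locus an ancestral frequency is drawn, and each population's frequency is
drawn from a Beta (Dirichlet, for multi-category loci) distribution centred
on the ancestral value with concentration (1 - F)/F, so the
``differentiation`` parameter F plays the role of a fixation index.
Genotypes are then Hardy–Weinberg draws from the population frequencies.

All generators are pure functions of their design (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .condition import ConditionDataset
from .loci import (
    DIPLOID,
    HAPLOID_COMPOSITE,
    MISSING,
    PHENOTYPE_COMPOSITE,
    BaselineSet,
    GenotypeRecord,
    LocusDefinition,
    canonical_diploid_call,
)

__all__ = [
    "DEFAULT_GROUPS",
    "SimulationDesign",
    "ConditionDesign",
    "GroupConditionParams",
    "simulate_baseline",
    "simulate_mixture",
    "simulate_condition",
]

DEFAULT_GROUPS = ("Black Lake", "Chignik Lake", "Chignik River")


@dataclass
class SimulationDesign:
    """Shape and differentiation of a synthetic baseline."""

    n_populations: int = 13
    group_sizes: tuple = (5, 7, 1)
    group_names: tuple = DEFAULT_GROUPS
    n_diploid_loci: int = 92
    include_composites: bool = True
    n_haploid_categories: int = 5
    n_phenotype_categories: int = 6
    differentiation: float = 0.05
    baseline_n_per_pop: int = 100
    seed: int = 0

    def __post_init__(self):
        if sum(self.group_sizes) != self.n_populations:
            raise ValueError("group_sizes must sum to n_populations")
        if len(self.group_sizes) != len(self.group_names):
            raise ValueError("one name per group required")
        if not 0.0 < self.differentiation < 1.0:
            raise ValueError("differentiation must lie in (0, 1)")

    @property
    def populations(self) -> list:
        return [f"pop_{i + 1:02d}" for i in range(self.n_populations)]

    @property
    def group_map(self) -> dict:
        out = {}
        i = 0
        for name, size in zip(self.group_names, self.group_sizes):
            for _ in range(size):
                out[self.populations[i]] = name
                i += 1
        return out


def _make_loci(design: SimulationDesign) -> list:
    loci = [
        LocusDefinition(f"SNP_{i + 1:03d}", DIPLOID, ("A", "B"))
        for i in range(design.n_diploid_loci)
    ]
    if design.include_composites:
        loci.append(
            LocusDefinition(
                "mtDNA_composite",
                HAPLOID_COMPOSITE,
                tuple(f"H{i + 1}" for i in range(design.n_haploid_categories)),
            )
        )
        loci.append(
            LocusDefinition(
                "MHC_composite",
                PHENOTYPE_COMPOSITE,
                tuple(f"P{i + 1}" for i in range(design.n_phenotype_categories)),
            )
        )
    return loci


def _population_freqs(design: SimulationDesign, loci, rng):
    """True per-population frequencies under the Balding–Nichols model."""
    F = design.differentiation
    conc = (1.0 - F) / F
    freqs = {}  # locus name -> (K, A) array
    for loc in loci:
        A = len(loc.alleles)
        if loc.is_diploid:
            anc = rng.uniform(0.05, 0.95)
            ancestral = np.array([anc, 1.0 - anc])
        else:
            ancestral = rng.dirichlet(np.ones(A))
        # clip so Beta/Dirichlet parameters stay positive
        ancestral = np.clip(ancestral, 1e-3, None)
        ancestral /= ancestral.sum()
        freqs[loc.name] = rng.dirichlet(conc * ancestral, size=design.n_populations)
    return freqs


def _draw_indices(p: np.ndarray, size, rng) -> np.ndarray:
    """Vectorized categorical draws by inverse CDF."""
    u = rng.random(size)
    cum = np.cumsum(p)
    return np.minimum(np.searchsorted(cum, u, side="right"), len(p) - 1)


def _locus_calls(loc: LocusDefinition, p: np.ndarray, n: int, rng) -> list:
    """n Hardy–Weinberg calls at one locus from frequency vector p."""
    if loc.is_diploid:
        idx = _draw_indices(p, (n, 2), rng)
        return [
            canonical_diploid_call(loc.alleles[i], loc.alleles[j])
            for i, j in idx
        ]
    idx = _draw_indices(p, n, rng)
    return [loc.alleles[i] for i in idx]


def simulate_baseline(design: SimulationDesign):
    """Simulate a baseline with individual genotypes.

    Returns ``(BaselineSet, true_freqs)`` where ``true_freqs`` maps locus
    name to a (n_populations, n_alleles) matrix of generating frequencies.
    """
    rng = np.random.default_rng([design.seed, 1])
    loci = _make_loci(design)
    true_freqs = _population_freqs(design, loci, rng)
    n = design.baseline_n_per_pop
    individuals = {}
    for k, pop in enumerate(design.populations):
        calls_by_locus = {
            loc.name: _locus_calls(loc, true_freqs[loc.name][k], n, rng)
            for loc in loci
        }
        individuals[pop] = [
            GenotypeRecord(
                individual_id=f"{pop}_f{i + 1:04d}",
                calls={loc.name: calls_by_locus[loc.name][i] for loc in loci},
                population=pop,
            )
            for i in range(n)
        ]
    baseline = BaselineSet.from_individuals(
        loci, individuals, design.group_map, design.group_names
    )
    return baseline, true_freqs


def simulate_mixture(
    baseline: BaselineSet,
    true_freqs: dict,
    group_proportions: dict,
    n: int = 200,
    missing_rate: float = 0.0,
    seed: int = 0,
):
    """Simulate a mixture sample of known origin.

    Each fish draws a stock group from ``group_proportions``, a population
    uniformly within the group, and a multilocus genotype from that
    population's true frequencies under Hardy–Weinberg.  Calls are set
    MISSING independently with probability ``missing_rate``.  Returns
    ``(records, truth)`` with ``truth`` a list of (individual_id,
    population, group).
    """
    if abs(sum(group_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("group proportions must sum to 1")
    rng = np.random.default_rng([seed, 2])
    groups = list(baseline.groups)
    probs = np.array([group_proportions.get(g, 0.0) for g in groups])
    pops_by_group = {
        g: [p for p in baseline.populations if baseline.group_map[p] == g]
        for g in groups
    }
    pop_index = {p: i for i, p in enumerate(baseline.populations)}
    g_idx = _draw_indices(probs, n, rng)
    origins = []
    for gi in g_idx:
        g = groups[gi]
        pop = pops_by_group[g][rng.integers(len(pops_by_group[g]))]
        origins.append((pop, g))
    pop_rows = np.array([pop_index[pop] for pop, _ in origins])

    calls_by_locus = {}
    for loc in baseline.loci:
        freq_rows = np.asarray(true_freqs[loc.name])[pop_rows]  # (n, A)
        cum = np.cumsum(freq_rows, axis=1)
        if loc.is_diploid:
            u = rng.random((n, 2))
            idx = np.minimum(
                (cum[:, :, None] < u[:, None, :]).sum(axis=1), cum.shape[1] - 1
            )
            calls = [
                canonical_diploid_call(loc.alleles[i], loc.alleles[j])
                for i, j in idx
            ]
        else:
            u = rng.random(n)
            idx = np.minimum((cum < u[:, None]).sum(axis=1), cum.shape[1] - 1)
            calls = [loc.alleles[i] for i in idx]
        if missing_rate > 0:
            drop = rng.random(n) < missing_rate
            calls = [MISSING if d else c for c, d in zip(calls, drop)]
        calls_by_locus[loc.name] = calls

    records, truth = [], []
    for i, (pop, g) in enumerate(origins):
        rid = f"mix_f{i + 1:04d}"
        records.append(
            GenotypeRecord(
                individual_id=rid,
                calls={loc.name: calls_by_locus[loc.name][i]
                       for loc in baseline.loci},
            )
        )
        truth.append((rid, pop, g))
    return records, truth


@dataclass
class GroupConditionParams:
    """One group's allometry and length distribution.

    ``intercept`` and ``slope`` are on the log10 scale (log10 mass in g
    against log10 length in mm); ``resid_sd`` is the SD of the log10-mass
    residual, i.e. multiplicative noise on the natural scale.  Defaults give
    a typical juvenile sockeye allometry: a 65 mm fish weighs about 2.7 g.
    """

    intercept: float = -5.10
    slope: float = 3.04
    resid_sd: float = 0.04
    length_mean: float = 67.0
    length_sd: float = 6.0
    n: int = 200


@dataclass
class ConditionDesign:
    groups: dict = field(default_factory=dict)  # label -> GroupConditionParams
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            # emulate two rearing-lake groups with distinct allometries
            self.groups = {
                "Black Lake residents": GroupConditionParams(
                    intercept=-5.00, slope=3.02, resid_sd=0.035,
                    length_mean=69.7, length_sd=5.4, n=200,
                ),
                "Chignik Lake residents": GroupConditionParams(
                    intercept=-5.20, slope=3.06, resid_sd=0.045,
                    length_mean=65.1, length_sd=7.9, n=200,
                ),
            }
        for label, par in self.groups.items():
            if par.resid_sd < 0:
                raise ValueError(f"group {label!r}: resid_sd must be >= 0")


def simulate_condition(design: ConditionDesign) -> ConditionDataset:
    """Simulate per-fish lengths and masses under group-specific allometries.

    Lengths are normal, truncated to be positive (redraw); log10 mass is
    linear in log10 length plus normal noise.
    """
    rng = np.random.default_rng([design.seed, 3])
    groups, lengths, masses = [], [], []
    for label, par in design.groups.items():
        ln = rng.normal(par.length_mean, par.length_sd, size=par.n)
        while (ln <= 0).any():  # truncate at zero by redrawing
            bad = ln <= 0
            ln[bad] = rng.normal(par.length_mean, par.length_sd, size=bad.sum())
        log_mass = (
            par.intercept
            + par.slope * np.log10(ln)
            + rng.normal(0.0, par.resid_sd, size=par.n)
        )
        groups.extend([label] * par.n)
        lengths.append(ln)
        masses.append(10.0 ** log_mass)
    return ConditionDataset(
        group=np.array(groups),
        length_mm=np.concatenate(lengths),
        mass_g=np.concatenate(masses),
    )
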