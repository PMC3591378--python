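"""Threshold-based individual assignment and holdout error-rate calibration.

A fish is assigned to the stock group whose posterior origin probability
(the sum of its population-level posterior frequencies over the group's
member populations) meets the probability threshold; otherwise it is left
NOT_ASSIGNED.  Thresholds above 0.5 guarantee at most one qualifying group.

Assignment quality is calibrated with known-origin test mixtures: fish are
drawn from the baseline itself, the baseline is rebuilt without them, the
full mixture analysis is rerun, and per-group error rates (1 - precision:
the share of fish assigned to a group whose true origin is elsewhere) are
averaged over replicates across a grid of thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .loci import BaselineSet, GenotypeRecord
from .mcmc import ChainConfig, PosteriorDraws, PriorSpec, run_chains

__all__ = [
    "NOT_ASSIGNED",
    "IndividualPosterior",
    "AssignmentResult",
    "CalibrationReport",
    "individual_posteriors",
    "assign_individuals",
    "summarize_assignments",
    "holdout_calibration",
    "choose_threshold",
    "largest_remainder",
]

NOT_ASSIGNED = "NOT_ASSIGNED"

DEFAULT_THRESHOLD_GRID = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class IndividualPosterior:
    individual_id: str
    group_probs: dict  # stock group -> posterior probability

    def __post_init__(self):
        total = sum(self.group_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.individual_id}: group probabilities sum to {total}, not 1"
            )


@dataclass
class AssignmentResult:
    individual_id: str
    assigned_group: str  # a stock group or NOT_ASSIGNED
    threshold: float
    top_prob: float


def individual_posteriors(draws: PosteriorDraws) -> list:
    """Stock-group posterior probabilities per fish, from pooled z tallies."""
    probs = draws.group_z_probs()
    return [
        IndividualPosterior(ind_id, dict(zip(draws.groups, row)))
        for ind_id, row in zip(draws.individual_ids, probs)
    ]


def assign_individuals(
    posteriors: Sequence[IndividualPosterior], threshold: float
) -> list:
    """Assign each fish to the group meeting the threshold, else NOT_ASSIGNED.

    The comparison is inclusive: a posterior probability exactly equal to
    the threshold assigns.  Thresholds below 0.5 are rejected (two groups
    could qualify); at exactly 0.5 the maximal-probability group is taken,
    so at most one group is ever assigned.
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0.5, 1]")
    out = []
    for post in posteriors:
        group, top = max(post.group_probs.items(), key=lambda kv: kv[1])
        assigned = group if top >= threshold else NOT_ASSIGNED
        out.append(
            AssignmentResult(
                individual_id=post.individual_id,
                assigned_group=assigned,
                threshold=threshold,
                top_prob=float(top),
            )
        )
    return out


def summarize_assignments(
    results: Sequence[AssignmentResult], groups: Sequence[str]
) -> dict:
    """Proportion of the whole sample per group, plus NOT_ASSIGNED; sums to 1."""
    if not results:
        raise ValueError("no assignment results to summarize")
    n = len(results)
    out = {g: 0 for g in list(groups) + [NOT_ASSIGNED]}
    for res in results:
        out[res.assigned_group] += 1
    return {g: c / n for g, c in out.items()}


def assignments_to_frame(results: Sequence[AssignmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in results],
            "group": [r.assigned_group for r in results],
            "top_prob": [r.top_prob for r in results],
            "threshold": [r.threshold for r in results],
        }
    )


@dataclass
class CalibrationReport:
    """Per-(threshold, group) holdout error rates over replicates.

    ``summary`` columns: threshold, group, mean_error, sd_error,
    mean_assigned_fraction, n_replicates_defined.  ``detail`` holds the
    replicate-level counts behind them.  A replicate in which no fish was
    assigned to a group has an undefined error rate there; such replicates
    are excluded from that group's mean/SD and counted out of
    ``n_replicates_defined``.
    """

    thresholds: tuple
    groups: tuple
    summary: pd.DataFrame
    detail: pd.DataFrame
    chain_config: Optional[ChainConfig] = None

    def mean_error(self, threshold: float, group: str) -> float:
        sel = self.summary[
            (self.summary.threshold == threshold) & (self.summary.group == group)
        ]
        return float(sel.mean_error.iloc[0])

    def overall_error(self, threshold: float) -> float:
        """Pooled error over groups: wrong assignments / all assignments."""
        det = self.detail[self.detail.threshold == threshold]
        assigned = det.n_assigned.sum()
        return float((det.n_assigned - det.n_correct).sum() / assigned) if assigned else np.nan

    def assigned_fraction(self, threshold: float) -> float:
        det = self.detail[self.detail.threshold == threshold]
        reps = det.replicate.nunique()
        return float(det.n_assigned.sum() / (reps * det.mixture_size.iloc[0]))


def largest_remainder(total: int, proportions: np.ndarray) -> np.ndarray:
    """Integer quotas summing to *total*, proportional to *proportions*.

    Floor quotas first, then hand out the remaining units by descending
    fractional part (ties broken by index order, deterministically).
    """
    proportions = np.asarray(proportions, dtype=float)
    if total < 0 or (proportions < 0).any():
        raise ValueError("total and proportions must be non-negative")
    p = proportions / proportions.sum()
    raw = total * p
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.lexsort((np.arange(len(p)), -(raw - base)))
    base[order[:short]] += 1
    return base


def _draw_holdout(
    baseline: BaselineSet,
    mixture_size: int,
    group_proportions: dict,
    rng: np.random.Generator,
):
    """Pick known-origin fish: group quotas by largest remainder, populations
    within a group proportional to their baseline sample sizes."""
    group_quota = largest_remainder(
        mixture_size, np.array([group_proportions.get(g, 0.0) for g in baseline.groups])
    )
    held = {pop: [] for pop in baseline.populations}
    truth = []
    for g, quota in zip(baseline.groups, group_quota):
        if quota == 0:
            continue
        pops = [p for p in baseline.populations if baseline.group_map[p] == g]
        sizes = np.array([len(baseline.individuals[p]) for p in pops], dtype=float)
        pop_quota = largest_remainder(int(quota), sizes)
        for pop, nq in zip(pops, pop_quota):
            avail = baseline.individuals[pop]
            if nq > len(avail):
                raise ValueError(
                    f"holdout draw exhausts population {pop} "
                    f"({nq} requested, {len(avail)} available); use a larger "
                    "baseline or a smaller test mixture"
                )
            picks = rng.choice(len(avail), size=int(nq), replace=False)
            for j in picks:
                held[pop].append(avail[j])
                truth.append((avail[j].individual_id, pop, g))
    return held, truth


def holdout_calibration(
    baseline: BaselineSet,
    mixture_size: int,
    group_proportions: dict,
    n_replicates: int,
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    prior: Optional[PriorSpec] = None,
    config: Optional[ChainConfig] = None,
    seed: int = 0,
) -> CalibrationReport:
    """Known-mixture holdout calibration of assignment error rates.

    Per replicate: draw ``mixture_size`` fish from the baseline so that
    group totals match ``group_proportions``; rebuild the baseline counts
    without them; rerun the mixture MCMC and individual assignment; score a
    confusion count at every threshold.  Reports mean and SD of the
    per-group error rate and the mean assigned fraction across replicates.

    The chains may deliberately be shorter than production runs; the
    configuration used is recorded on the report.
    """
    if baseline.individuals is None:
        raise ValueError("holdout calibration needs individual-level baseline data")
    total_p = sum(group_proportions.values())
    if abs(total_p - 1.0) > 1e-9:
        raise ValueError(f"group proportions sum to {total_p}, not 1")
    thresholds = tuple(sorted(thresholds))
    prior = prior or PriorSpec()
    config = config or ChainConfig(
        n_chains=1, iterations=10_000, thin=2, burn_in=1_000, update_allele_freqs=False
    )
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, 7919, rep])
        held, truth = _draw_holdout(baseline, mixture_size, group_proportions, rng)
        reduced = baseline.without_individuals(held)
        test_mixture = [rec for pop in baseline.populations for rec in held[pop]]
        true_group = {ind_id: g for ind_id, _, g in truth}
        rep_config = ChainConfig(
            n_chains=config.n_chains,
            iterations=config.iterations,
            thin=config.thin,
            burn_in=config.burn_in,
            seed=int(np.random.default_rng([seed, 104729, rep]).integers(2**31)),
            start_scheme=config.start_scheme,
            update_allele_freqs=config.update_allele_freqs,
            gr_threshold=config.gr_threshold,
        )
        draws = run_chains(reduced, test_mixture, prior, rep_config)
        posteriors = individual_posteriors(draws)
        for thr in thresholds:
            results = assign_individuals(posteriors, thr)
            for g in baseline.groups:
                to_g = [r for r in results if r.assigned_group == g]
                correct = sum(
                    1 for r in to_g if true_group[r.individual_id] == g
                )
                rows.append(
                    {
                        "replicate": rep,
                        "threshold": thr,
                        "group": g,
                        "n_assigned": len(to_g),
                        "n_correct": correct,
                        "mixture_size": mixture_size,
                        "error_rate": (
                            (len(to_g) - correct) / len(to_g) if to_g else np.nan
                        ),
                    }
                )
    detail = pd.DataFrame(rows)
    summary_rows = []
    for thr in thresholds:
        for g in baseline.groups:
            sel = detail[(detail.threshold == thr) & (detail.group == g)]
            defined = sel.error_rate.dropna()
            if defined.empty:
                warnings.warn(
                    f"no fish assigned to {g} at threshold {thr} in any replicate; "
                    "error rate undefined"
                )
            summary_rows.append(
                {
                    "threshold": thr,
                    "group": g,
                    "mean_error": defined.mean() if not defined.empty else np.nan,
                    "sd_error": (
                        defined.std(ddof=1) if len(defined) > 1 else
                        (0.0 if len(defined) == 1 else np.nan)
                    ),
                    "mean_assigned_fraction": float(
                        sel.n_assigned.mean() / mixture_size
                    ),
                    "n_replicates_defined": int(len(defined)),
                }
            )
    return CalibrationReport(
        thresholds=thresholds,
        groups=baseline.groups,
        summary=pd.DataFrame(summary_rows),
        detail=detail,
        chain_config=config,
    )


def choose_threshold(report: CalibrationReport, error_ceiling: float = 0.15) -> float:
    """Smallest threshold keeping every group's mean error below the ceiling.

    The rule operationalizes "assign as many fish as possible while keeping
    incorrect assignment rare": lower thresholds assign more fish, so the
    lowest acceptable one wins.  Groups with an undefined error rate (no
    fish ever assigned there) do not disqualify a threshold.  If no
    threshold qualifies, the highest is returned with a warning.
    """
    if len(report.thresholds) < 2:
        raise ValueError("calibration report must cover at least 2 thresholds")
    for thr in report.thresholds:
        errs = report.summary[report.summary.threshold == thr].mean_error
        if errs.dropna().lt(error_ceiling).all():
            return float(thr)
    warnings.warn(
        f"no threshold achieved mean error < {error_ceiling} for every group; "
        "returning the most conservative one"
    )
    return float(report.thresholds[-1])
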