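"""Configuration-driven orchestration of the full GSI analysis.

A run proceeds: (simulate or load inputs) -> preprocess -> mixture MCMC ->
group summaries -> individual assignment -> optional holdout calibration ->
optional body-condition comparison.  Every artifact lands in the output
directory and is listed, with a content checksum, in ``manifest.json``.
Reruns with an identical configuration and seed reproduce the numerical
outputs byte for byte (the manifest's wall-clock timings excepted).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .assignment import (
    DEFAULT_THRESHOLD_GRID,
    assign_individuals,
    assignments_to_frame,
    holdout_calibration,
    individual_posteriors,
    summarize_assignments,
)
from .condition import ConditionDataset, compare_condition, comparison_table
from .io import write_baseline_counts, write_genotypes
from .loci import MISSING
from .mcmc import ChainConfig, PriorSpec, export_draws, run_chains, summarize_groups
from .preprocess import PreprocessConfig, filter_missing, preprocess_loci
from .synthetic import ConditionDesign, SimulationDesign, simulate_baseline, simulate_mixture

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("gsikit")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    With ``simulate`` set, inputs are generated by the synthetic module;
    otherwise baseline/mixture input paths must be supplied by the caller
    through a pre-built BaselineSet and record list (the CLI wires file
    loading).  ``thresholds`` is the assignment grid; ``report_thresholds``
    are the levels at which assignment (and condition) outputs are written,
    the conventional report level being 0.80.
    """

    out_dir: str = "gsi_run"
    seed: int = 0
    simulate: Optional[dict] = None  # SimulationDesign overrides
    mixture_n: int = 200
    mixture_proportions: Optional[dict] = None
    missing_rate: float = 0.02
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    chains: ChainConfig = field(default_factory=ChainConfig)
    thresholds: tuple = DEFAULT_THRESHOLD_GRID
    report_thresholds: tuple = (0.8,)
    calibrate: bool = False
    calibration_size: int = 200
    calibration_replicates: int = 10
    calibration_chains: Optional[ChainConfig] = None
    condition: bool = False
    condition_design: Optional[ConditionDesign] = None
    condition_transform: str = "log10"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "preprocessing" in kwargs:
            kwargs["preprocessing"] = PreprocessConfig(**kwargs["preprocessing"])
        if "prior" in kwargs:
            kwargs["prior"] = PriorSpec(**kwargs["prior"])
        if "chains" in kwargs:
            kwargs["chains"] = ChainConfig(**kwargs["chains"])
        if "calibration_chains" in kwargs and kwargs["calibration_chains"]:
            kwargs["calibration_chains"] = ChainConfig(**kwargs["calibration_chains"])
        for key in ("thresholds", "report_thresholds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def canonical(self) -> str:
        def _default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if hasattr(obj, "__dict__"):
                return vars(obj)
            return str(obj)

        blob = {k: v for k, v in asdict(self).items()}
        return json.dumps(blob, sort_keys=True, default=_default)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, baseline=None, mixture=None) -> dict:
    """Execute the configured stages; returns the run manifest.

    ``baseline``/``mixture`` may be passed directly (pre-loaded data); when
    ``config.simulate`` is set they are generated instead.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "stages": [],
        "outputs": {},
    }
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:
                failed_marker.write_text(f"{name}: {exc}\n")
                _finalize(out, manifest)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)}
            )
            log.info("stage %s: done", name)
            return result

        return deco

    truth = None
    true_freqs = None
    if config.simulate is not None:

        @stage("simulate")
        def _simulated():
            design = SimulationDesign(seed=config.seed, **config.simulate)
            base, freqs = simulate_baseline(design)
            props = config.mixture_proportions or {
                design.group_names[0]: 0.25,
                design.group_names[1]: 0.75,
            }
            mix, tr = simulate_mixture(
                base, freqs, props, n=config.mixture_n,
                missing_rate=config.missing_rate, seed=config.seed,
            )
            write_baseline_counts(out / "baseline_counts.csv", base)
            write_genotypes(out / "mixture_genotypes.csv", mix, base.loci)
            with open(out / "truth.tsv", "w") as fh:
                fh.write("individual_id\tpopulation\tgroup\n")
                for rid, pop, grp in tr:
                    fh.write(f"{rid}\t{pop}\t{grp}\n")
            return base, mix, tr, freqs

        baseline, mixture, truth, true_freqs = _simulated
    if baseline is None or mixture is None:
        raise PipelineError("stage 'inputs' failed: no baseline/mixture provided")

    @stage("preprocess")
    def _preprocessed():
        base, mix, report = preprocess_loci(baseline, mixture, config.preprocessing)
        retained, excluded = filter_missing(
            mix, base.loci, config.preprocessing.max_missing_fraction
        )
        for rec, frac in (
            (r, r.missing_fraction(base.loci)) for r in excluded
        ):
            report.individuals_excluded_missing.append((rec.individual_id, frac))
        _write_json(
            out / "preprocess_report.json",
            {
                "loci_dropped_monomorphic": report.loci_dropped_monomorphic,
                "loci_dropped_ld": report.loci_dropped_ld,
                "loci_dropped_failed_assay": report.loci_dropped_failed_assay,
                "composites_created": report.composites_created,
                "individuals_excluded_missing": report.individuals_excluded_missing,
            },
        )
        return base, retained

    base, mix = _preprocessed

    @stage("fit-mixture")
    def _draws():
        cfg = config.chains
        if cfg.seed != config.seed:
            cfg = ChainConfig(**{**vars(cfg), "seed": config.seed})
        draws = run_chains(base, mix, config.prior, cfg)
        export_draws(draws, out / "theta_draws.tsv", out / "group_draws.tsv")
        summary = summarize_groups(draws, gr_threshold=config.chains.gr_threshold)
        _write_json(out / "mixture_summary.json", summary.to_dict())
        return draws

    draws = _draws

    @stage("assign")
    def _assignments():
        posteriors = individual_posteriors(draws)
        per_threshold = {}
        for thr in config.report_thresholds:
            results = assign_individuals(posteriors, thr)
            tag = f"{int(round(thr * 100)):02d}"
            assignments_to_frame(results).to_csv(
                out / f"assignments_thr{tag}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            props = summarize_assignments(results, base.groups)
            _write_json(out / f"assignment_proportions_thr{tag}.json", props)
            per_threshold[thr] = results
        return per_threshold

    assignments = _assignments

    if config.calibrate:

        @stage("calibrate")
        def _calibration():
            report = holdout_calibration(
                base,
                mixture_size=config.calibration_size,
                group_proportions=config.mixture_proportions
                or {base.groups[0]: 0.25, base.groups[1]: 0.75},
                n_replicates=config.calibration_replicates,
                thresholds=config.thresholds,
                prior=config.prior,
                config=config.calibration_chains,
                seed=config.seed,
            )
            report.summary.to_csv(
                out / "calibration_summary.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            report.detail.to_csv(
                out / "calibration_detail.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            return report

        _ = _calibration

    if config.condition:

        @stage("condition")
        def _condition():
            for thr, results in assignments.items():
                data = _condition_data(config, mix, results, truth)
                if data is None:
                    continue
                fits = compare_condition(data, transform=config.condition_transform)
                tag = f"{int(round(thr * 100)):02d}"
                comparison_table(fits).to_csv(
                    out / f"condition_models_thr{tag}.tsv", sep="\t", index=False,
                    float_format="%.6g",
                )
                _write_json(
                    out / f"condition_coefficients_thr{tag}.json",
                    {f.model_id: f.coefficients for f in fits},
                )

        _ = _condition

    _finalize(out, manifest)
    return manifest


def _condition_data(config, mix, results, truth):
    """Join lengths/masses to assigned groups; None if unavailable."""
    if config.condition_design is not None:
        from .synthetic import simulate_condition

        return simulate_condition(config.condition_design)
    by_id = {rec.individual_id: rec for rec in mix}
    groups, lengths, masses = [], [], []
    for res in results:
        rec = by_id.get(res.individual_id)
        if rec is None or rec.length_mm is None or rec.mass_g is None:
            continue
        if res.assigned_group == "NOT_ASSIGNED":
            continue
        groups.append(res.assigned_group)
        lengths.append(rec.length_mm)
        masses.append(rec.mass_g)
    if len(set(groups)) != 2:
        log.warning("condition stage skipped: need exactly 2 assigned groups "
                    "with length/mass data")
        return None
    return ConditionDataset(
        group=np.array(groups),
        length_mm=np.array(lengths),
        mass_g=np.array(masses),
    )


def _finalize(out: Path, manifest: dict) -> None:
    for path in sorted(out.iterdir()):
        if path.name in ("manifest.json", "FAILED") or path.is_dir():
            continue
        manifest["outputs"][path.name] = _sha256(path)
    _write_json(out / "manifest.json", manifest)
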