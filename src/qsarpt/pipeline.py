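"""End-to-end orchestration: load -> scale -> select -> enumerate -> fit ->
prune -> rank -> leave-many-out validation.

The pipeline is a pure function of its inputs and configuration: repeated
runs with the same config produce identical reports.  Stage progress is
logged as machine-parseable ``key=value`` lines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fixtures
from .errors import CollinearityError, PipelineStageError
from .io import (
    ClearanceTable,
    DescriptorMatrix,
    build_chrom_schema,
    build_molecular_schema,
    concat_matrices,
    load_clearance_table,
    load_descriptor_matrix,
)
from .mlr import (
    MLRModel,
    fit_wls,
    flag_high_leverage,
    forward_aic,
    prune_model,
    rank_models,
)
from .peaks import read_manifest, traces_to_matrix
from .selection import AnnConfig, ann_weights, enumerate_uncorrelated, scale_matrix
from .validation import ValidationReport, cross_validate, lmo_validate, make_split_plan

log = logging.getLogger("qsarpt.pipeline")

MODES = ("molecular", "chromatographic", "both")


@dataclass
class PipelineConfig:
    mode: str = "chromatographic"
    # input paths (unused when an in-memory bundle is supplied)
    molecular_csv: str | None = None
    chromatographic_csv: str | None = None
    clearance_csv: str | None = None
    traces_manifest: str | None = None
    reference_compound: str | None = None
    # selection
    ann_restarts: int = 5
    ann_stepmax: int = 100_000
    ann_threshold: float = 0.005
    r2_threshold: float = 0.5
    # modelling
    weighting: str = "1/Y"  # auto | 1 | 1/Y | 1/Y2
    max_combinations: int = 500  # resource guard for the combination search
    max_model_size: int = 8  # largest descriptor set fitted (11-compound
    # training sets saturate above this; replicate rows add no rank)
    r2_min: float = 0.7
    alpha: float = 0.05
    stepwise_trigger: int = 3
    leverage_rule: float | None = None
    # validation
    split: str = "random"  # random | fixture
    n_sets: int = 3
    test_size: int = 4
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def load_pipeline_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    report: ValidationReport
    final_model: MLRModel
    selection: object
    combinations: object
    ranked: list
    plan: object
    pinned: tuple[str, ...]
    stage_counts: dict = field(default_factory=dict)


def _load_inputs(config: PipelineConfig, bundle):
    if bundle is not None:
        mol, chrom, y = bundle.molecular, bundle.chromatographic, bundle.clearance
    else:
        mol = chrom = None
        if config.mode in ("molecular", "both"):
            if not config.molecular_csv:
                raise ValueError("molecular_csv required for this mode")
            mol = load_descriptor_matrix(config.molecular_csv, build_molecular_schema())
        if config.mode in ("chromatographic", "both"):
            if config.chromatographic_csv:
                chrom = load_descriptor_matrix(
                    config.chromatographic_csv, build_chrom_schema()
                )
            elif config.traces_manifest:
                traces = read_manifest(config.traces_manifest)
                chrom = traces_to_matrix(
                    traces, config.reference_compound, build_chrom_schema()
                )
            else:
                raise ValueError("chromatographic_csv or traces_manifest required")
        if not config.clearance_csv:
            raise ValueError("clearance_csv required")
        y = load_clearance_table(config.clearance_csv)
    if config.mode == "molecular":
        X = mol
    elif config.mode == "chromatographic":
        X = chrom
    else:
        X = concat_matrices(mol, chrom)
    return X, y


def run_pipeline(config: PipelineConfig, bundle=None) -> PipelineResult:
    """Run the full modelling workflow and validate the winning model.

    ``bundle`` may be a :class:`~qsarpt.synthetic.StudyBundle`; otherwise the
    CSV paths in ``config`` are read.  Raises
    :class:`~qsarpt.errors.PipelineStageError` naming the failing stage, with
    a replayable partial-state dump when an output directory is set.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {"config": dataclasses.asdict(config)}
    counts: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            path = None
            if outdir:
                path = outdir / "partial_state.json"
                with open(path, "w") as fh:
                    json.dump(state, fh, indent=2, default=str)
            raise PipelineStageError(name, str(exc), state_path=path) from exc

    X, y = stage("load", lambda: _load_inputs(config, bundle))
    counts["n_compounds"] = len(X.compound_ids)
    counts["n_descriptor_slots"] = len(X.schema)
    counts["n_observations"] = len(y)
    log.info(
        "stage=load mode=%s compounds=%d slots=%d observations=%d",
        config.mode, counts["n_compounds"], counts["n_descriptor_slots"], counts["n_observations"],
    )

    Xs = stage("scale", lambda: scale_matrix(X))
    counts["n_scaled"] = len(Xs.codes)
    counts["n_dropped_zero_variance"] = len(Xs.dropped)
    log.info("stage=scale kept=%d dropped=%d", counts["n_scaled"], counts["n_dropped_zero_variance"])

    ann_cfg = AnnConfig(
        restarts=config.ann_restarts,
        seed=config.seed,
        stepmax=config.ann_stepmax,
        threshold=config.ann_threshold,
    )
    selection = stage("ann_selection", lambda: ann_weights(Xs, y, ann_cfg))
    state["selected"] = list(selection.selected)
    counts["n_selected"] = len(selection.selected)
    log.info(
        "stage=ann_selection selected=%d median_weight=%.6g threshold=%.6g",
        counts["n_selected"], selection.median_weight, selection.threshold,
    )

    combos = stage(
        "enumerate_uncorrelated",
        lambda: enumerate_uncorrelated(Xs, selection.selected, config.r2_threshold),
    )
    counts["n_combinations"] = len(combos)
    log.info("stage=enumerate_uncorrelated combinations=%d", counts["n_combinations"])
    combo_sets = list(combos.sets)
    if len(combo_sets) > config.max_combinations:
        # resource guard: prefer combinations carrying the most ANN weight
        wmap = dict(zip(selection.codes, selection.weights))
        combo_sets.sort(key=lambda s: -sum(wmap.get(c, 0.0) for c in s))
        combo_sets = combo_sets[: config.max_combinations]
        counts["n_combinations_fitted"] = len(combo_sets)
        log.info("stage=enumerate_uncorrelated capped=%d", len(combo_sets))
    state["combinations"] = [sorted(s) for s in combo_sets]

    weightings = ("1", "1/Y", "1/Y2") if config.weighting == "auto" else (config.weighting,)

    def fit_all():
        fitted = []
        skipped = 0
        # replicate rows add no rank: a fit needs at least two more distinct
        # compounds than descriptors, and CV folds one more again
        fit_cap = len(X.compound_ids) - 2
        for w in weightings:
            for combo in combo_sets:
                if len(combo) > fit_cap:
                    skipped += 1
                    continue
                try:
                    m = fit_wls(Xs, y, tuple(sorted(combo)), w)
                    fitted.append(
                        prune_model(Xs, y, m, config.alpha, config.stepwise_trigger)
                    )
                except CollinearityError:
                    skipped += 1
        if skipped:
            log.info("stage=mlr skipped_collinear=%d", skipped)
        return fitted

    models = stage("mlr", fit_all)
    counts["n_models_fitted"] = len(models)
    log.info("stage=mlr fitted=%d", counts["n_models_fitted"])
    # parsimony guard: interpretable final models only
    models = [m for m in models if m.n_descriptors <= config.max_model_size]
    if not models:
        # every combination was too large or pruned past the size guard:
        # build candidates by forward stepwise-AIC over the selected codes
        def fallback():
            fitted = []
            for w in weightings:
                m = forward_aic(
                    Xs, y, selection.selected, w, config.max_model_size
                )
                fitted.append(prune_model(Xs, y, m, config.alpha, config.stepwise_trigger))
            return fitted

        models = stage("mlr_fallback", fallback)
        counts["mlr_fallback"] = 1
        log.info("stage=mlr_fallback fitted=%d", len(models))

    ranked = stage("rank", lambda: rank_models(models, config.r2_min, config.alpha))
    counts["n_models_passing"] = len(ranked)
    log.info("stage=rank passing_r2_gt_%.2f=%d", config.r2_min, counts["n_models_passing"])
    if not ranked:
        # fall back to the best-BIC fully-significant model (then best BIC
        # overall) so a weak study still yields a validated report
        ranked = rank_models(models, r2_min=-np.inf, alpha=config.alpha)
        if not ranked:
            ranked = sorted(
                (m for m in models if m.n_descriptors > 0), key=lambda m: m.bic
            )
        counts["rank_fallback"] = 1
        log.info("stage=rank fallback=best_bic survivors=%d", len(ranked))
    if not ranked:
        def _no_survivor():
            raise ValueError("no candidate model could be fitted")
        stage("rank", _no_survivor)

    if config.weighting == "auto" and len(weightings) > 1:
        # among each weighting's best survivor, keep the smallest RMSECV
        def pick():
            best, best_rmsecv = None, np.inf
            for w in weightings:
                cand = [m for m in ranked if m.weighting == w]
                if not cand:
                    continue
                _, rmsecv, _ = cross_validate(Xs, y, cand[0].codes, w)
                log.info("stage=weighting choice=%s rmsecv=%.5f", w, rmsecv)
                if rmsecv < best_rmsecv:
                    best, best_rmsecv = cand[0], rmsecv
            return best
        final = stage("weighting", pick)
    else:
        final = ranked[0]
    state["final_model"] = final.to_report()
    log.info(
        "stage=final descriptors=%d codes=%s bic=%.3f",
        final.n_descriptors, ",".join(final.codes), final.bic,
    )

    flags = stage("leverage", lambda: flag_high_leverage(final, config.leverage_rule))
    lev = final.leverage_by_compound()
    flagged = sorted((c for c, f in flags.items() if f), key=lambda c: -lev[c])
    # pin as many flagged compounds as the split arithmetic allows
    eligible_needed = config.n_sets * config.test_size
    max_pinned = len(X.compound_ids) - eligible_needed
    pinned = tuple(flagged[:max_pinned])
    counts["n_flagged_high_leverage"] = len(flagged)
    log.info("stage=leverage flagged=%d pinned=%s", len(flagged), ",".join(pinned) or "-")

    def build_plan():
        if config.split == "fixture":
            return fixtures.split_plan_fixture(
                "molecular" if config.mode == "molecular" else "chromatographic"
            )
        return make_split_plan(
            X.compound_ids, pinned, config.n_sets, config.test_size, seed=config.seed
        )

    plan = stage("split", build_plan)
    report = stage(
        "lmo_validation",
        lambda: lmo_validate(Xs, y, final.codes, plan, final.weighting),
    )
    log.info(
        "stage=lmo_validation r2=%.3f q2=%.3f qlmo2=%.3f ccc=%.3f",
        report.aggregate["r2"], report.aggregate["q2"],
        report.aggregate["qlmo2"], report.aggregate["ccc"],
    )

    if outdir:
        _write_artifacts(outdir, config, selection, combos, final, report, counts)
    return PipelineResult(
        report=report,
        final_model=final,
        selection=selection,
        combinations=combos,
        ranked=ranked,
        plan=plan,
        pinned=pinned,
        stage_counts=counts,
    )


def _write_artifacts(outdir, config, selection, combos, final, report, counts):
    with open(outdir / "selection_report.json", "w") as fh:
        json.dump(
            {
                "weights": dict(zip(selection.codes, map(float, selection.weights))),
                "median_weight": selection.median_weight,
                "threshold": selection.threshold,
                "selected": list(selection.selected),
                "combinations": [sorted(s) for s in combos.sets],
                "seed": config.seed,
            },
            fh,
            indent=2,
        )
    with open(outdir / "model_report.json", "w") as fh:
        json.dump(final.to_report(), fh, indent=2)
    with open(outdir / "validation_report.json", "w") as fh:
        json.dump(
            {
                "per_set": report.per_set,
                "aggregate": report.aggregate,
                "verdicts": report.verdicts,
                "thresholds": report.thresholds,
                "unreliable": list(report.unreliable),
                "stage_counts": counts,
                "seed": config.seed,
            },
            fh,
            indent=2,
            default=float,
        )
    report.pooled.to_csv(outdir / "lmo_pooled.csv", index=False)
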