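"""End-to-end screening workflow.

Stage order is fixed and logged: select wavelengths (from the reference
standard's record) -> crop to the fingerprint window -> COW alignment per
channel -> unfold -> optional pretreatment -> duplex split -> 10-fold CV
for the factor count -> PLS-DA fit -> external test-set validation.
Screening new samples reuses every piece of train-time state (channel
targets, warp spec, scaling state, model); nothing is refitted.

Row-wise pretreatments (SNV, derivatives) are stateless and run before the
split; autoscaling is fitted on the calibration rows only, after the
split, so validation statistics never leak into the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chromsim import SimConfig, simulate_dad_record, simulate_study
from .cowarp import (
    ChannelAlignment,
    WarpSpec,
    align_cube,
    select_target_profile,
    warp_to_stored_target,
)
from .cube import DataCube, FingerprintMatrix, crop_time_window, unfold_cube
from .plsda import (
    CVResult,
    PLSDAModel,
    ClassificationReport,
    cross_validate_lv,
    evaluate,
    fit_plsda,
    predict_classes,
)
from .pretreat import PretreatConfig, ScalingState, apply_scaling, apply_stateless, autoscale
from .split import SplitAssignment, duplex_split
from .wavesel import channel_correlation_map, select_orthogonal_wavelengths

__all__ = [
    "PipelineConfig",
    "StudyResult",
    "ScreeningBundle",
    "ScreeningReport",
    "select_study_wavelengths",
    "process_study",
    "model_study",
    "run_study",
    "train_screening_models",
    "screen_samples",
    "compare_channel_strategies",
    "compare_simulated_binary",
    "run_simulated_binary_study",
    "simulate_reference_record",
    "study_result_to_dict",
    "study_result_from_dict",
]

STAGE_ORDER = (
    "select_wavelengths",
    "crop",
    "align",
    "unfold",
    "pretreat",
    "split",
    "cross_validate",
    "fit",
    "external_validation",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Hyperparameters of the screening workflow.

    Defaults mirror the study conditions: 1.5-6.6 min fingerprint window,
    0.95 correlation cutoff with at most 5 channels, COW at segment 35 /
    slack 3 (grids 10..50 / 1..5 when optimizing), duplex at a 25 % test
    fraction, 10-fold CV over up to 30 latent variables, no pretreatment.
    """

    window: tuple[float, float] = (1.5, 6.6)
    correlation_cutoff: float = 0.95
    max_wavelengths: int = 5
    warp: WarpSpec = WarpSpec(35, 3)
    optimize_warp: bool = False
    per_channel_warp: bool = False
    segment_grid: tuple[int, ...] | None = None
    slack_grid: tuple[int, ...] | None = None
    pretreat: PretreatConfig = PretreatConfig()
    test_fraction: float = 0.25
    cv_folds: int = 10
    max_factors: int = 30
    seed: int = 0


@dataclass
class StudyResult:
    """Everything one trained model needs for reporting and screening."""

    name: str
    coding: str
    wavelengths: np.ndarray
    align_logs: list[ChannelAlignment]
    target_traces: np.ndarray  # (n_channels, n_times) train-time COW targets
    aligned_traces: np.ndarray | None  # (n_samples, n_channels, n_times)
    times: np.ndarray
    split: SplitAssignment
    cv: CVResult
    model: PLSDAModel
    scaling: ScalingState | None
    train_report: ClassificationReport
    test_report: ClassificationReport
    stage_log: list[str] = field(default_factory=list)


@dataclass
class ScreeningBundle:
    binary: dict[str, StudyResult]
    multiclass: StudyResult | None
    config: PipelineConfig


@dataclass
class ScreeningReport:
    """Per-sample verdicts: one binary verdict per plant model plus exactly
    one multiclass verdict, with full provenance."""

    sample_ids: list[str]
    binary_verdicts: dict[str, np.ndarray]  # plant -> bool array
    multiclass_verdicts: np.ndarray | None  # class labels
    provenance: dict

    def to_frame(self) -> pd.DataFrame:
        data = {f"binary:{plant}": v for plant, v in self.binary_verdicts.items()}
        if self.multiclass_verdicts is not None:
            data["multiclass"] = self.multiclass_verdicts
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"))


def simulate_reference_record(library, plant_name: str, sim_config: SimConfig):
    """Pure reference-standard injection on the full wavelength grid."""
    plant = next(p for p in library if p.name == plant_name and p.kind == "plant")
    seed = int(np.random.SeedSequence([sim_config.seed, 0x5EF]).generate_state(1)[0] % 2**31)
    return simulate_dad_record([(plant, 1.0)], sim_config, jitter=0.0, seed=seed)


def select_study_wavelengths(
    record: np.ndarray,
    wavelengths: np.ndarray,
    times: np.ndarray,
    config: PipelineConfig,
) -> np.ndarray:
    """Orthogonal channel set from a reference record's fingerprint window."""
    times = np.asarray(times, dtype=float)
    lo, hi = config.window
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    cmap = channel_correlation_map(np.asarray(record)[:, mask], wavelengths)
    return select_orthogonal_wavelengths(
        cmap, cutoff=config.correlation_cutoff, max_k=config.max_wavelengths
    )


@dataclass
class ProcessedStudy:
    cube: DataCube  # cropped + aligned
    matrix: FingerprintMatrix  # unfolded (+ stateless pretreatments)
    align_logs: list[ChannelAlignment]
    target_traces: np.ndarray
    split: SplitAssignment
    stage_log: list[str]


def process_study(cube: DataCube, config: PipelineConfig) -> ProcessedStudy:
    """crop -> align -> unfold -> stateless pretreat -> duplex split."""
    log = ["crop"]
    cropped = crop_time_window(cube, *config.window)
    targets = np.stack(
        [
            cropped.values[select_target_profile(cropped.values[:, j, :]), j, :]
            for j in range(cropped.n_wavelengths)
        ]
    )
    aligned, align_logs = align_cube(
        cropped,
        config.warp,
        optimize=config.optimize_warp,
        per_channel=config.per_channel_warp,
        segment_grid=config.segment_grid,
        slack_grid=config.slack_grid,
    )
    log.append("align")
    matrix = apply_stateless(unfold_cube(aligned), config.pretreat)
    log.extend(["unfold", "pretreat"])
    split = duplex_split(matrix, config.test_fraction)
    log.append("split")
    return ProcessedStudy(
        cube=aligned,
        matrix=matrix,
        align_logs=align_logs,
        target_traces=targets,
        split=split,
        stage_log=log,
    )


def model_study(
    ps: ProcessedStudy, coding: str, config: PipelineConfig, name: str
) -> StudyResult:
    """CV factor selection, final fit and external validation on a processed study."""
    if ps.matrix.labels is None:
        raise ValueError("study matrix carries no class labels")
    cal = ps.matrix.take_ids(ps.split.calibration_ids)
    val = ps.matrix.take_ids(ps.split.validation_ids)
    scaling = None
    if config.pretreat.autoscale:
        cal, scaling = autoscale(cal)
        val = apply_scaling(scaling, val)
    cv = cross_validate_lv(
        cal, cal.labels, coding,
        folds=config.cv_folds, max_factors=config.max_factors, seed=config.seed,
    )
    model = fit_plsda(cal, cal.labels, cv.n_factors, coding)
    train_report = evaluate(
        cal.labels, predict_classes(model, cal), cal.sample_ids, model.classes
    )
    test_report = evaluate(
        val.labels, predict_classes(model, val), val.sample_ids, model.classes
    )
    return StudyResult(
        name=name,
        coding=coding,
        wavelengths=ps.cube.wavelengths.copy(),
        align_logs=ps.align_logs,
        target_traces=ps.target_traces,
        aligned_traces=ps.cube.values,
        times=ps.cube.times.copy(),
        split=ps.split,
        cv=cv,
        model=model,
        scaling=scaling,
        train_report=train_report,
        test_report=test_report,
        stage_log=list(STAGE_ORDER),
    )


def _find_reference_id(cube: DataCube) -> str:
    # multiclass studies carry one reference per plant; default to the
    # first (a multiclass model is built on one plant's wavelength set)
    refs = sorted(s for s in cube.sample_ids if s.endswith("-ref"))
    if not refs:
        raise ValueError(
            "no reference record (id ending '-ref') found; pass reference_id"
        )
    return refs[0]


def run_study(
    cube: DataCube,
    coding: str,
    config: PipelineConfig,
    name: str = "study",
    reference_id: str | None = None,
) -> StudyResult:
    """Full workflow on a labelled study cube.

    If the cube holds more channels than ``config.max_wavelengths``, the
    orthogonal set is first selected from the reference record (id ending
    in ``-ref`` unless given); otherwise all channels are used as-is.
    """
    if cube.labels is None:
        raise ValueError("study cube carries no class labels")
    work = cube
    if cube.n_wavelengths > config.max_wavelengths:
        ref = reference_id or _find_reference_id(cube)
        selection = select_study_wavelengths(
            cube.record(ref), cube.wavelengths, cube.times, config
        )
        work = cube.select_wavelengths(selection)
    ps = process_study(work, config)
    return model_study(ps, coding, config, name)


def run_simulated_binary_study(
    library,
    target_plant: str,
    sim_config: SimConfig,
    config: PipelineConfig,
    extra_wavelengths=(),
) -> StudyResult:
    """Simulate and model one binary study without materializing the full
    201-channel cube: wavelengths are selected from a separately simulated
    reference injection, and the study is generated on that channel subset."""
    record = simulate_reference_record(library, target_plant, sim_config)
    selection = select_study_wavelengths(
        record, sim_config.wavelength_grid, sim_config.time_grid, config
    )
    keep = np.unique(np.concatenate([selection, np.asarray(extra_wavelengths, dtype=float)]))
    cube, _ = simulate_study(
        library, target_plant, "binary", sim_config, keep_wavelengths=keep
    )
    work = cube.select_wavelengths(selection)
    ps = process_study(work, config)
    return model_study(ps, "binary", config, name=target_plant)


def train_screening_models(
    binary_studies: dict[str, DataCube],
    multiclass_study: DataCube | None,
    config: PipelineConfig,
) -> ScreeningBundle:
    """Train one binary model per plant and optionally a multiclass model."""
    binary = {
        plant: run_study(cube, "binary", config, name=plant)
        for plant, cube in binary_studies.items()
    }
    multi = None
    if multiclass_study is not None:
        multi = run_study(multiclass_study, "multiclass", config, name="multiclass")
    return ScreeningBundle(binary=binary, multiclass=multi, config=config)


def _apply_model_to_cube(result: StudyResult, samples: DataCube, config: PipelineConfig,
                         joint_warp: bool = False) -> np.ndarray:
    sub = samples.select_wavelengths(result.wavelengths)
    cropped = crop_time_window(sub, *config.window)
    if cropped.n_times != result.times.size:
        raise ValueError("sample time grid does not match the trained model")
    warped = np.empty_like(cropped.values)
    for j in range(cropped.n_wavelengths):
        target = result.target_traces[j]
        if joint_warp and result.aligned_traces is not None:
            pool = np.vstack([result.aligned_traces[:, j, :], cropped.values[:, j, :]])
            target = pool[select_target_profile(pool)]
        warped[:, j, :] = warp_to_stored_target(
            cropped.values[:, j, :], target, result.align_logs[j].spec
        )
    matrix = apply_stateless(
        unfold_cube(replace(cropped, values=warped)), config.pretreat
    )
    if result.scaling is not None:
        matrix = apply_scaling(result.scaling, matrix)
    return predict_classes(result.model, matrix)


def screen_samples(
    bundle: ScreeningBundle, samples: DataCube, joint_warp: bool = False
) -> ScreeningReport:
    """Classify unknown samples with every trained model.

    Samples are warped against the stored train-time channel targets (or,
    with ``joint_warp``, against a target re-selected from the pooled
    aligned-training + sample traces), then cropped, unfolded, pretreated
    with stored state and classified.  A sample may screen positive for
    several plants under the binary models; the multiclass model yields
    exactly one verdict.
    """
    config = bundle.config
    binary_verdicts = {}
    for plant, result in bundle.binary.items():
        pred = _apply_model_to_cube(result, samples, config, joint_warp)
        binary_verdicts[plant] = pred == 1
    multi = None
    if bundle.multiclass is not None:
        multi = _apply_model_to_cube(bundle.multiclass, samples, config, joint_warp)
    provenance = {
        "stage_order": STAGE_ORDER,
        "models": {
            plant: {
                "wavelengths_nm": r.wavelengths.tolist(),
                "n_factors": r.model.n_factors,
                "warp": {
                    "targets": [log.target_id for log in r.align_logs],
                    "spec": [(log.spec.segment_length, log.spec.slack) for log in r.align_logs],
                },
            }
            for plant, r in bundle.binary.items()
        },
        "joint_warp": joint_warp,
    }
    return ScreeningReport(
        sample_ids=list(samples.sample_ids),
        binary_verdicts=binary_verdicts,
        multiclass_verdicts=multi,
        provenance=provenance,
    )


@dataclass
class ChannelComparison:
    """Twin binary models on the selected channel set vs a single channel."""

    multi: StudyResult
    single: StudyResult
    single_wavelength: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, r in (("multiwavelength", self.multi), ("single", self.single)):
            rows.append(
                {
                    "arm": arm,
                    "wavelengths_nm": r.wavelengths.tolist(),
                    "n_features": r.model.x_means.size,
                    "n_factors": r.model.n_factors,
                    "train_ccr": r.train_report.ccr,
                    "test_ccr": r.test_report.ccr,
                }
            )
        return pd.DataFrame(rows)


def compare_channel_strategies(
    cube: DataCube,
    config: PipelineConfig,
    reference_id: str | None = None,
    single_wavelength: float = 254.0,
) -> ChannelComparison:
    """Train twin binary models on (a) the selected orthogonal channel set
    and (b) one conventional channel (254 nm by default), with identical
    duplex splits and seeds.

    The duplex assignment is computed once, on the multiwavelength matrix,
    and reused verbatim for the single-channel arm: duplex is data-driven,
    so recomputing it per arm would confound the comparison.
    """
    if cube.labels is None:
        raise ValueError("study cube carries no class labels")
    ref = reference_id or _find_reference_id(cube)
    if cube.n_wavelengths > config.max_wavelengths:
        selection = select_study_wavelengths(
            cube.record(ref), cube.wavelengths, cube.times, config
        )
    else:
        selection = cube.wavelengths[np.abs(cube.wavelengths - single_wavelength) > 1e-9]
    multi_ps = process_study(cube.select_wavelengths(selection), config)
    multi = model_study(multi_ps, "binary", config, name="multiwavelength")

    single_ps = process_study(cube.select_wavelengths([single_wavelength]), config)
    single_ps.split = multi_ps.split  # shared assignment, by design
    single = model_study(single_ps, "binary", config, name=f"{single_wavelength:g}nm")
    return ChannelComparison(multi=multi, single=single, single_wavelength=single_wavelength)


def study_result_to_dict(result: StudyResult, config: PipelineConfig) -> dict:
    """JSON-serializable form of a trained model with all state needed for
    screening (train-time warp targets, specs, scaling, coefficients).
    The aligned training traces are not stored; deserialized models screen
    with stored targets only."""
    m = result.model
    return {
        "name": result.name,
        "coding": result.coding,
        "wavelengths_nm": result.wavelengths.tolist(),
        "times_min": result.times.tolist(),
        "target_traces": result.target_traces.tolist(),
        "align": [
            {
                "wavelength": log.wavelength,
                "target_id": log.target_id,
                "segment_length": log.spec.segment_length,
                "slack": log.spec.slack,
                "mean_corr_before": log.mean_corr_before,
                "mean_corr_after": log.mean_corr_after,
            }
            for log in result.align_logs
        ],
        "split": {
            "calibration_ids": result.split.calibration_ids,
            "validation_ids": result.split.validation_ids,
        },
        "cv": {"n_factors": result.cv.n_factors, "ccr_by_factor": result.cv.ccr_by_factor.tolist()},
        "model": {
            "x_means": m.x_means.tolist(),
            "y_means": m.y_means.tolist(),
            "weights": m.weights.tolist(),
            "x_loadings": m.x_loadings.tolist(),
            "y_loadings": m.y_loadings.tolist(),
            "n_factors": m.n_factors,
            "coding": m.coding,
            "classes": m.classes.tolist(),
            "regression_coefficients": m.regression_coefficients.tolist(),
        },
        "scaling": None
        if result.scaling is None
        else {
            "column_means": result.scaling.column_means.tolist(),
            "column_sds": result.scaling.column_sds.tolist(),
            "flagged": result.scaling.flagged.tolist(),
            "fitted_on": result.scaling.fitted_on,
        },
        "reports": {
            "train_ccr": result.train_report.ccr,
            "test_ccr": result.test_report.ccr,
        },
        "config": {
            "window": list(config.window),
            "correlation_cutoff": config.correlation_cutoff,
            "max_wavelengths": config.max_wavelengths,
            "test_fraction": config.test_fraction,
            "cv_folds": config.cv_folds,
            "max_factors": config.max_factors,
            "seed": config.seed,
            "pretreat": {
                "snv": config.pretreat.snv,
                "derivative": config.pretreat.derivative,
                "autoscale": config.pretreat.autoscale,
            },
        },
    }


def study_result_from_dict(payload: dict) -> tuple[StudyResult, PipelineConfig]:
    """Inverse of :func:`study_result_to_dict` (reports are restored as
    ccr-only stubs)."""
    m = payload["model"]
    model = PLSDAModel(
        x_means=np.asarray(m["x_means"]),
        y_means=np.asarray(m["y_means"]),
        weights=np.asarray(m["weights"]),
        x_loadings=np.asarray(m["x_loadings"]),
        y_loadings=np.asarray(m["y_loadings"]),
        n_factors=int(m["n_factors"]),
        coding=m["coding"],
        classes=np.asarray(m["classes"], dtype=int),
        regression_coefficients=np.asarray(m["regression_coefficients"]),
    )
    logs = [
        ChannelAlignment(
            wavelength=a["wavelength"],
            target_id=a["target_id"],
            target_index=-1,
            spec=WarpSpec(a["segment_length"], a["slack"]),
            mean_corr_before=a["mean_corr_before"],
            mean_corr_after=a["mean_corr_after"],
            scores=np.empty(0),
            n_segments=0,
        )
        for a in payload["align"]
    ]
    scaling = None
    if payload["scaling"] is not None:
        s = payload["scaling"]
        scaling = ScalingState(
            column_means=np.asarray(s["column_means"]),
            column_sds=np.asarray(s["column_sds"]),
            flagged=np.asarray(s["flagged"], dtype=bool),
            fitted_on=int(s["fitted_on"]),
        )
    c = payload["config"]
    pre = c["pretreat"]
    config = PipelineConfig(
        window=tuple(c["window"]),
        correlation_cutoff=c["correlation_cutoff"],
        max_wavelengths=c["max_wavelengths"],
        test_fraction=c["test_fraction"],
        cv_folds=c["cv_folds"],
        max_factors=c["max_factors"],
        seed=c["seed"],
        pretreat=PretreatConfig(
            snv=pre["snv"],
            derivative=None if pre["derivative"] is None else tuple(pre["derivative"]),
            autoscale=pre["autoscale"],
        ),
    )
    classes = model.classes
    stub = ClassificationReport(
        confusion=np.zeros((classes.size, classes.size), dtype=int),
        classes=classes,
        ccr=float("nan"),
        misclassified_ids=[],
    )
    train_stub = replace(stub, ccr=payload["reports"]["train_ccr"])
    test_stub = replace(stub, ccr=payload["reports"]["test_ccr"])
    result = StudyResult(
        name=payload["name"],
        coding=payload["coding"],
        wavelengths=np.asarray(payload["wavelengths_nm"]),
        align_logs=logs,
        target_traces=np.asarray(payload["target_traces"]),
        aligned_traces=None,
        times=np.asarray(payload["times_min"]),
        split=SplitAssignment(
            calibration_ids=list(payload["split"]["calibration_ids"]),
            validation_ids=list(payload["split"]["validation_ids"]),
        ),
        cv=CVResult(
            n_factors=int(payload["cv"]["n_factors"]),
            ccr_by_factor=np.asarray(payload["cv"]["ccr_by_factor"]),
            folds=[],
        ),
        model=model,
        scaling=scaling,
        train_report=train_stub,
        test_report=test_stub,
        stage_log=list(STAGE_ORDER),
    )
    return result, config


def compare_simulated_binary(
    library,
    target_plant: str,
    sim_config: SimConfig,
    config: PipelineConfig,
    single_wavelength: float = 254.0,
) -> ChannelComparison:
    """Simulate one binary study and run :func:`compare_channel_strategies`
    on it, generating only the selected channels plus the single comparison
    channel instead of the full wavelength grid."""
    record = simulate_reference_record(library, target_plant, sim_config)
    selection = select_study_wavelengths(
        record, sim_config.wavelength_grid, sim_config.time_grid, config
    )
    keep = np.unique(np.append(selection, single_wavelength))
    cube, _ = simulate_study(
        library, target_plant, "binary", sim_config, keep_wavelengths=keep
    )
    multi_ps = process_study(cube.select_wavelengths(selection), config)
    multi = model_study(multi_ps, "binary", config, name="multiwavelength")
    single_ps = process_study(cube.select_wavelengths([single_wavelength]), config)
    single_ps.split = multi_ps.split
    single = model_study(single_ps, "binary", config, name=f"{single_wavelength:g}nm")
    return ChannelComparison(multi=multi, single=single, single_wavelength=single_wavelength)
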