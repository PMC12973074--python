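"""End-to-end experiment driver: configure, run, report.

``run_experiment`` chains the whole pipeline — simulate (or load) a
session, condition and align the signals, build run-level folds, train the
deep model and the ridge baseline on identical folds, evaluate every fold
(held-out r, surrogate p, native-rate control, win/loss betas, control-ROI
correlations), run the group-level paired tests, extract the top-branch
spatio-spectral profiles, and write the report bundle.

One global seed derives every stage seed through a fixed
``SeedSequence([global_seed, stage_tag])`` scheme, so a config plus seed
reproduces the bundle.  The reduced desk-scale profile (fewer channels,
branches and shorter runs) exercises the identical code path at laptop
cost.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baseline import BaselineFold, train_fold_linear
from .datatypes import EegRecording, RoiBoldSeries, TaskEvent
from .evaluation import (
    FoldResult,
    GroupReport,
    downsample_check,
    event_regressor,
    functional_validity,
    group_tests,
    pearson_r,
    permutation_pvalue,
    specificity_report,
)
from .interpret import BranchProfile, top_branches_report
from .model import ModelConfig, save_checkpoint
from .preprocess import AlignedPair, align_pair, zscore
from .synth import (
    CONTROL_ROIS,
    TARGET_ROI,
    SessionTruth,
    SourceSpec,
    SyntheticConfig,
    EegNoiseSpec,
    load_session,
    simulate_session,
    smooth_pattern,
)
from .training import (
    LossConfig,
    TrainConfig,
    TrainedFold,
    make_folds,
    train_fold,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EvalSettings",
    "InterpretSettings",
    "ExperimentConfig",
    "ExperimentResult",
    "desk_scale_config",
    "validate_config",
    "prepare_session",
    "evaluate_fold",
    "run_experiment",
    "run_recovery",
    "ten_fold_config",
    "config_to_yaml",
    "config_from_yaml",
]

# stage tags for the one-seed-derives-all scheme
_STAGE_SYNTH, _STAGE_FOLDS, _STAGE_TRAIN, _STAGE_EVAL = 0, 1, 2, 3


@dataclass(frozen=True)
class EvalSettings:
    n_surrogates: int = 1000
    alpha: float = 0.05
    rois: tuple[str, ...] = CONTROL_ROIS

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class InterpretSettings:
    k_top: int = 3


@dataclass
class ExperimentConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    evaluation: EvalSettings = field(default_factory=EvalSettings)
    interpret: InterpretSettings = field(default_factory=InterpretSettings)
    n_folds: int = 4
    output_dir: str | None = None
    global_seed: int = 0
    session_dir: str | None = None  # load a stored container instead of simulating


@dataclass
class SessionData:
    """A prepared session: aligned pairs plus the raw context evaluation needs."""

    runs: list[EegRecording]
    bolds: dict[str, list[RoiBoldSeries]]
    events: list[TaskEvent]
    truth: SessionTruth | None
    pairs: dict[str, AlignedPair]
    control_aligned: dict[str, dict[str, np.ndarray]]
    fs_hz: float
    delay_s: float
    tr_s: float


@dataclass
class ExperimentResult:
    report: GroupReport
    dl_folds: list[TrainedFold]
    linear_folds: list[BaselineFold]
    dl_results: list[FoldResult]
    linear_results: list[FoldResult]
    profiles: list[BranchProfile]
    session: SessionData
    output_dir: Path | None


def desk_scale_config(global_seed: int = 0, output_dir: str | None = None,
                      n_runs: int = 6, n_folds: int = 4) -> ExperimentConfig:
    """Reduced profile: 16 channels, 4 branches, encoder 32, short runs.

    Runs the identical pipeline at laptop cost: 16-channel EEG, 18 trials
    per 200 s run (a 6-run session lasts 20 min), 40 s training windows.
    Runs are kept at 200 s so a held-out run supports a stable correlation
    estimate despite hemodynamic autocorrelation.  The planted source keeps
    the full-scale coupling defaults (10 Hz, squared envelope, BOLD noise
    at the ~0.71 ceiling).
    """
    n_channels = 16
    synthetic = SyntheticConfig(
        n_channels=n_channels,
        n_runs=n_runs,
        trials_per_run=18,
        volumes_per_run=100,
        sources=[SourceSpec(spatial_pattern=smooth_pattern(n_channels),
                            baseline_amp=3.0)],
        seed=global_seed,
    )
    # instance norm: immune to the train/eval statistics gap that batch norm
    # shows at small batch counts
    model = ModelConfig(n_channels=n_channels, n_branches=4, encoder_channels=32,
                        norm="instance")
    train = TrainConfig(
        learning_rate=1e-3,
        batch_size=16,
        windows_per_epoch=64,
        window_s=40.0,
        max_epochs=24,
        scheduler_t_max_epochs=24,
        early_stop_patience_epochs=7,
        augment_noise_sd=0.5,
        seed=global_seed,
    )
    return ExperimentConfig(
        synthetic=synthetic, model=model, train=train,
        evaluation=EvalSettings(n_surrogates=200),
        n_folds=n_folds, output_dir=output_dir, global_seed=global_seed,
    )


def validate_config(cfg: ExperimentConfig) -> list[str]:
    """Blocking errors ("error: ...") and warnings ("warning: ...")."""
    findings: list[str] = []
    syn, tr = cfg.synthetic, cfg.train
    run_len_s = syn.run_duration_s - syn.hrf_delay_s
    if tr.window_s > run_len_s:
        findings.append(
            f"error: window ({tr.window_s} s) longer than the aligned run "
            f"({run_len_s} s)"
        )
    if cfg.model.n_channels != syn.n_channels:
        findings.append("error: model n_channels does not match the generator")
    if round(tr.window_s * syn.fs_hz) < cfg.model.min_length:
        findings.append(
            f"error: window shorter than the model's receptive minimum "
            f"({cfg.model.min_length} samples)"
        )
    if cfg.n_folds > syn.n_runs:
        findings.append("error: n_folds exceeds the number of runs")
    elif syn.n_runs < 3:
        findings.append("error: need at least 3 runs for train/validation/test folds")
    if cfg.evaluation.n_surrogates < 100:
        findings.append("warning: fewer than 100 surrogates gives a coarse p-value")
    return findings


def _stage_seed(global_seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([global_seed, tag]).generate_state(1)[0] % (2 ** 31))


def prepare_session(cfg: ExperimentConfig) -> SessionData:
    """Simulate or load the session and build the aligned training pairs.

    Conditioning follows the pipeline contract: per-run z-scoring of both
    modalities, EEG and BOLD brought to the common 100 Hz rate, EEG
    advanced by the hemodynamic delay.
    """
    syn = replace(cfg.synthetic, seed=_stage_seed(cfg.global_seed, _STAGE_SYNTH))
    if cfg.session_dir is not None:
        runs, bolds, events = load_session(cfg.session_dir)
        truth = None
    else:
        runs, bolds, events, truth = simulate_session(syn)
    delay = syn.hrf_delay_s
    fs = syn.fs_hz
    pairs: dict[str, AlignedPair] = {}
    control_aligned: dict[str, dict[str, np.ndarray]] = {roi: {} for roi in bolds
                                                         if roi != TARGET_ROI}
    for k, rec in enumerate(runs):
        eeg = EegRecording(zscore(rec.data), rec.channel_labels, rec.fs_hz, rec.run_id)
        target = bolds[TARGET_ROI][k]
        target = RoiBoldSeries(zscore(target.values), target.fs_hz,
                               target.roi_label, target.role, target.run_id)
        pairs[rec.run_id] = align_pair(eeg, target, fs_common=fs, delay_s=delay)
        for roi in control_aligned:
            ctrl = bolds[roi][k]
            ctrl = RoiBoldSeries(zscore(ctrl.values), ctrl.fs_hz, roi, "control",
                                 ctrl.run_id)
            control_aligned[roi][rec.run_id] = align_pair(
                eeg, ctrl, fs_common=fs, delay_s=delay
            ).bold.values
    return SessionData(runs=runs, bolds=bolds, events=events, truth=truth,
                       pairs=pairs, control_aligned=control_aligned,
                       fs_hz=fs, delay_s=delay, tr_s=syn.tr_s)


def evaluate_fold(fold_id: int, run_id: str, y_true: np.ndarray,
                  y_pred: np.ndarray, session: SessionData,
                  settings: EvalSettings, seed: int,
                  model_label: str = "dl") -> FoldResult:
    """Fill the full metric record for one fold's held-out prediction."""
    fs = session.fs_hz
    r = pearson_r(y_pred, y_true)
    p, _ = permutation_pvalue(y_pred, y_true, settings.n_surrogates,
                              seed=seed)
    run_events = [ev for ev in session.events if ev.run_id == run_id]
    beta_win, beta_loss = functional_validity(y_pred, run_events, fs,
                                              offset_s=session.delay_s)

    shift_vols = round(session.delay_s / session.tr_s)
    native = session.bolds[TARGET_ROI][_run_index(session, run_id)].values
    r_down = downsample_check(y_pred, zscore(native)[shift_vols:], fs,
                              session.tr_s)

    n = y_pred.size
    shift = round(session.delay_s * fs)
    total = n + shift
    nuisance = np.column_stack([
        event_regressor(run_events, "win", fs, total)[shift:],
        event_regressor(run_events, "loss", fs, total)[shift:],
    ])
    rois = {roi: session.control_aligned[roi][run_id]
            for roi in settings.rois if roi in session.control_aligned}
    spec = specificity_report(y_pred, rois, nuisance=nuisance)
    return FoldResult(fold_id=fold_id, y_true=y_true, y_pred=y_pred, fs_hz=fs,
                      r=r, permutation_p=p,
                      roi_r={roi: v[0] for roi, v in spec.items()},
                      beta_win=beta_win, beta_loss=beta_loss,
                      r_downsampled=r_down, model=model_label)


def _run_index(session: SessionData, run_id: str) -> int:
    for k, rec in enumerate(session.runs):
        if rec.run_id == run_id:
            return k
    raise KeyError(run_id)


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Execute the full pipeline; write the bundle if output_dir is set."""
    findings = [f for f in validate_config(cfg) if f.startswith("error")]
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))

    logger.info("stage: session")
    session = prepare_session(cfg)
    run_ids = [rec.run_id for rec in session.runs]

    logger.info("stage: folds")
    folds = make_folds(run_ids, cfg.n_folds, _stage_seed(cfg.global_seed, _STAGE_FOLDS))

    train_cfg = replace(cfg.train, seed=_stage_seed(cfg.global_seed, _STAGE_TRAIN))
    eval_seed = _stage_seed(cfg.global_seed, _STAGE_EVAL)

    dl_folds: list[TrainedFold] = []
    linear_folds: list[BaselineFold] = []
    dl_results: list[FoldResult] = []
    linear_results: list[FoldResult] = []
    for fold in folds:
        logger.info("stage: train fold %d (test %s)", fold.fold_id, fold.test_run)
        try:
            trained = train_fold(session.pairs, fold, cfg.model, train_cfg, cfg.loss)
            base = train_fold_linear(session.pairs, fold)
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(
                f"stage train failed at fold {fold.fold_id}: {exc}"
            ) from exc
        dl_folds.append(trained)
        linear_folds.append(base)
        dl_results.append(evaluate_fold(
            fold.fold_id, fold.test_run, trained.y_true, trained.y_pred,
            session, cfg.evaluation, seed=eval_seed + fold.fold_id, model_label="dl",
        ))
        linear_results.append(evaluate_fold(
            fold.fold_id, fold.test_run, base.y_true, base.y_pred,
            session, cfg.evaluation, seed=eval_seed + fold.fold_id,
            model_label="linear",
        ))

    logger.info("stage: group tests")
    report = group_tests(dl_results, linear_results)

    logger.info("stage: interpretability")
    profiles = top_branches_report(
        [t.model for t in dl_folds],
        [session.pairs[t.fold.test_run] for t in dl_folds],
        cfg.train.window_s,
        k=min(cfg.interpret.k_top, cfg.model.n_branches),
    )

    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir is not None:
        _write_bundle(out_dir, cfg, session, dl_folds, linear_folds,
                      dl_results, linear_results, report, profiles)
    return ExperimentResult(report=report, dl_folds=dl_folds,
                            linear_folds=linear_folds, dl_results=dl_results,
                            linear_results=linear_results, profiles=profiles,
                            session=session, output_dir=out_dir)


def ten_fold_config(global_seed: int, output_dir: str | None = None) -> ExperimentConfig:
    """Desk-scale 10-run / 10-fold study for the deep-vs-linear comparison.

    Same generator coupling and model profile as :func:`desk_scale_config`;
    the session is longer (10 runs) so ten distinct held-out runs exist,
    and the per-fold epoch budget is trimmed to keep the whole study a
    single-CPU computation.
    """
    cfg = desk_scale_config(global_seed, output_dir=output_dir,
                            n_runs=10, n_folds=10)
    cfg.train = replace(cfg.train, max_epochs=15, scheduler_t_max_epochs=15,
                        early_stop_patience_epochs=5)
    return cfg


def run_recovery(seed: int, n_surrogates: int = 200) -> dict:
    """Single-fold synthetic-recovery probe on a fresh desk-scale session.

    Simulates a 20-minute session at the ~0.71 noise ceiling, trains one
    fold, and returns the held-out r, its phase-randomization p-value and
    the oracle ceiling of the test run.
    """
    from .evaluation import pearson_r, permutation_pvalue
    from .synth import oracle_envelope_r

    cfg = desk_scale_config(seed)
    session = prepare_session(cfg)
    fold = make_folds([r.run_id for r in session.runs], 1, seed)[0]
    trained = train_fold(session.pairs, fold, cfg.model, cfg.train, cfg.loss)
    r = pearson_r(trained.y_pred, trained.y_true)
    p, _ = permutation_pvalue(trained.y_pred, trained.y_true, n_surrogates,
                              seed=seed)
    test_idx = [rec.run_id for rec in session.runs].index(fold.test_run)
    ceiling = oracle_envelope_r(session.truth, session.bolds[TARGET_ROI][test_idx])
    return {"seed": seed, "test_run": fold.test_run, "r": r, "p": p,
            "oracle_ceiling": ceiling, "epochs": len(trained.train_losses),
            "stop_reason": trained.stop_reason}


# ---------------------------------------------------------------------------
# bundle output and config (de)serialisation


def _write_bundle(out_dir: Path, cfg: ExperimentConfig, session: SessionData,
                  dl_folds: list[TrainedFold], linear_folds: list[BaselineFold],
                  dl_results: list[FoldResult], linear_results: list[FoldResult],
                  report: GroupReport, profiles: list[BranchProfile]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(config_to_yaml(cfg))
    report.per_fold.to_csv(out_dir / "per_fold.tsv", sep="\t", index=False)
    (out_dir / "group_report.json").write_text(
        json.dumps(report.to_json_dict(), indent=2)
    )
    for trained, result in zip(dl_folds, dl_results):
        fid = trained.fold.fold_id
        save_checkpoint(trained.model, out_dir / f"fold{fid}_model.npz")
        pd.DataFrame({
            "time_s": np.arange(result.y_true.size) / result.fs_hz,
            "y_true": result.y_true,
            "y_pred": result.y_pred,
        }).to_csv(out_dir / f"fold{fid}_dl_traces.tsv", sep="\t", index=False)
        (out_dir / f"fold{fid}_dl_metrics.json").write_text(json.dumps({
            "fold_id": fid, "model": "dl", "r": result.r,
            "permutation_p": result.permutation_p,
            "r_downsampled": result.r_downsampled,
            "beta_win": result.beta_win, "beta_loss": result.beta_loss,
            "roi_r": result.roi_r, "stop_reason": trained.stop_reason,
            "train_losses": trained.train_losses,
            "val_losses": trained.val_losses,
        }, indent=2))
    interp = [{
        "rank": i + 1,
        "importance": p.importance,
        "spatial_pattern": p.spatial_pattern.tolist(),
        "freq_grid_hz": p.freq_grid_hz.tolist(),
        "freq_profile": p.freq_profile.tolist(),
        "peak_freq_hz": p.peak_freq_hz,
    } for i, p in enumerate(profiles)]
    (out_dir / "top_branches.json").write_text(json.dumps(interp, indent=2))
    _write_figures(out_dir, dl_results, linear_results, profiles,
                   session.runs[0].channel_labels)


def _write_figures(out_dir: Path, dl_results: list[FoldResult],
                   linear_results: list[FoldResult],
                   profiles: list[BranchProfile], channel_labels: list[str]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    data = [[f.r for f in dl_results], [f.r for f in linear_results]]
    labels = ["DL", "linear"]
    rois = sorted(dl_results[0].roi_r)
    for roi in rois:
        data.append([f.roi_r[roi] for f in dl_results])
        labels.append(roi)
    axes[0].boxplot(data, tick_labels=labels)
    axes[0].set_ylabel("held-out Pearson r")
    best = max(dl_results, key=lambda f: f.r)
    t = np.arange(best.y_true.size) / best.fs_hz
    axes[1].plot(t, best.y_true, label="true", lw=0.8)
    axes[1].plot(t, best.y_pred, label=f"predicted (r={best.r:.2f})", lw=0.8)
    axes[1].set_xlabel("time (s)")
    axes[1].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_dir / "performance.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(len(profiles), 2, figsize=(10, 2.6 * len(profiles)),
                             squeeze=False)
    for i, prof in enumerate(profiles):
        axes[i][0].bar(range(prof.spatial_pattern.size), prof.spatial_pattern)
        axes[i][0].set_ylabel(f"rank {i + 1}\npattern")
        axes[i][0].set_xticks(range(len(channel_labels)))
        axes[i][0].set_xticklabels(channel_labels, rotation=90, fontsize=5)
        axes[i][1].plot(prof.freq_grid_hz, prof.freq_profile)
        axes[i][1].set_xlabel("frequency (Hz)")
    fig.tight_layout()
    fig.savefig(out_dir / "top_branches.png", dpi=120)
    plt.close(fig)


def _cfg_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        out = {}
        for f in dataclasses.fields(obj):
            out[f.name] = _cfg_dict(getattr(obj, f.name))
        return out
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_cfg_dict(x) for x in obj]
    return obj


def config_to_yaml(cfg: ExperimentConfig) -> str:
    return yaml.safe_dump(_cfg_dict(cfg), sort_keys=False)


def config_from_yaml(text: str) -> ExperimentConfig:
    """Parse an experiment config; raises yaml.YAMLError with line info."""
    raw = yaml.safe_load(text)
    syn_raw = dict(raw.get("synthetic", {}))
    sources = [SourceSpec(spatial_pattern=np.asarray(s.pop("spatial_pattern")), **s)
               for s in syn_raw.pop("sources", [])] or None
    noise = syn_raw.pop("eeg_noise", None)
    syn_kwargs = dict(syn_raw)
    if sources is not None:
        syn_kwargs["sources"] = sources
    if noise is not None:
        syn_kwargs["eeg_noise"] = EegNoiseSpec(**noise)
    eval_raw = dict(raw.get("evaluation", {}))
    if "rois" in eval_raw:
        eval_raw["rois"] = tuple(eval_raw["rois"])
    return ExperimentConfig(
        synthetic=SyntheticConfig(**syn_kwargs),
        model=ModelConfig(**raw.get("model", {})),
        train=TrainConfig(**raw.get("train", {})),
        loss=LossConfig(**raw.get("loss", {})),
        evaluation=EvalSettings(**eval_raw),
        interpret=InterpretSettings(**raw.get("interpret", {})),
        n_folds=raw.get("n_folds", 4),
        output_dir=raw.get("output_dir"),
        global_seed=raw.get("global_seed", 0),
        session_dir=raw.get("session_dir"),
    )
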