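"""Statistical validation of the decoded BOLD series.

Covers the full validity battery: held-out Pearson performance, a
phase-randomization surrogate null for significance, a native-rate
downsampling control against interpolation-inflated correlations, win/loss
event-regressor GLMs for functional (reward) validity, control-ROI
correlations for regional specificity, and group-level paired t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import TaskEvent
from .hrf import canonical_hrf

__all__ = [
    "FoldResult",
    "GroupReport",
    "pearson_r",
    "phase_randomize",
    "permutation_pvalue",
    "downsample_check",
    "event_regressor",
    "functional_validity",
    "specificity_report",
    "group_tests",
]


@dataclass
class FoldResult:
    """Per-fold evaluation record for one model (deep or linear)."""

    fold_id: int
    y_true: np.ndarray
    y_pred: np.ndarray
    fs_hz: float
    r: float = np.nan
    permutation_p: float = np.nan
    roi_r: dict[str, float] = field(default_factory=dict)
    beta_win: float = np.nan
    beta_loss: float = np.nan
    r_downsampled: float = np.nan
    model: str = "dl"

    def __post_init__(self) -> None:
        if self.y_true.size != self.y_pred.size:
            raise ValueError("y_true and y_pred must have equal lengths")


@dataclass
class GroupReport:
    """Group-level summary: per-fold table, summaries and paired tests."""

    per_fold: pd.DataFrame
    summary: dict[str, dict[str, float]]
    paired_tests: dict[str, dict[str, float]]
    n_folds: int

    def to_json_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "summary": self.summary,
            "paired_tests": self.paired_tests,
            "per_fold": self.per_fold.to_dict(orient="records"),
        }


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation; zero-variance input gives 0 with a warning."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("inputs must have equal lengths")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance input; returning r = 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def phase_randomize(y: np.ndarray, seed: int) -> np.ndarray:
    """Fourier surrogate: same amplitude spectrum, seeded random phases.

    DC and (for even length) Nyquist bins are left untouched; Hermitian
    symmetry is implicit in the rfft representation, so the output is real.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 4:
        raise ValueError("need at least 4 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("input must be finite")
    spec = np.fft.rfft(y)
    rng = np.random.default_rng(seed)
    hi = spec.size - 1 if y.size % 2 == 0 else spec.size
    phases = rng.uniform(0, 2 * np.pi, size=max(hi - 1, 0))
    spec[1:hi] = np.abs(spec[1:hi]) * np.exp(1j * phases)
    return np.fft.irfft(spec, n=y.size)


def permutation_pvalue(y_pred: np.ndarray, y_true: np.ndarray,
                       n_surrogates: int = 1000, seed: int = 0
                       ) -> tuple[float, np.ndarray]:
    """One-sided surrogate p-value for the observed positive correlation.

    The target is phase-randomized ``n_surrogates`` times; with the add-one
    correction p = (1 + #{null r >= observed r}) / (1 + n_surrogates).
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    observed = pearson_r(y_pred, y_true)
    ss = np.random.SeedSequence([seed, 23])
    child_seeds = ss.generate_state(n_surrogates)
    null_rs = np.empty(n_surrogates)
    yp = np.asarray(y_pred, dtype=float).ravel()
    yp_c = yp - yp.mean()
    denom_p = np.linalg.norm(yp_c)
    for i in range(n_surrogates):
        surr = phase_randomize(y_true, int(child_seeds[i]))
        sc = surr - surr.mean()
        denom = denom_p * np.linalg.norm(sc)
        null_rs[i] = 0.0 if denom == 0 else float(yp_c @ sc / denom)
    p = (1 + int((null_rs >= observed).sum())) / (1 + n_surrogates)
    return p, null_rs


def downsample_check(y_pred: np.ndarray, y_true_native: np.ndarray,
                     fs_pred_hz: float = 100.0, tr_s: float = 2.0) -> float:
    """Correlation at the native volume rate.

    The prediction is decimated by averaging each TR-long bin and then
    correlated with the native-rate target, guarding against correlation
    inflation from interpolated targets.
    """
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    y_true_native = np.asarray(y_true_native, dtype=float).ravel()
    step = round(tr_s * fs_pred_hz)
    n_bins = y_pred.size // step
    if abs(n_bins - y_true_native.size) * tr_s > tr_s:
        raise ValueError("prediction and native series durations differ by > 1 TR")
    n = min(n_bins, y_true_native.size)
    binned = y_pred[: n * step].reshape(n, step).mean(axis=1)
    return pearson_r(binned, y_true_native[:n])


def event_regressor(events: list[TaskEvent], outcome: str, fs_hz: float,
                    n_samples: int) -> np.ndarray:
    """HRF-convolved impulse regressor for one outcome type."""
    reg = np.zeros(n_samples)
    for ev in events:
        if ev.outcome != outcome:
            continue
        idx = round(ev.onset_s * fs_hz)
        if not 0 <= idx < n_samples:
            raise ValueError(f"event onset {ev.onset_s} s outside the run")
        reg[idx] += 1.0
    kernel = canonical_hrf(fs_hz)
    return np.convolve(reg, kernel)[:n_samples]


def _ols(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(design)
    if cond > 1e8:
        raise np.linalg.LinAlgError(
            f"degenerate design (condition number {cond:.2e})"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta


def functional_validity(y_pred: np.ndarray, events: list[TaskEvent],
                        fs_hz: float, offset_s: float = 0.0
                        ) -> tuple[float, float]:
    """Win and loss event betas from an OLS of the decoded series.

    ``offset_s`` shifts event onsets into the timeline of ``y_pred`` when
    the series starts after run onset (the hemodynamic alignment trim).
    """
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    n = y_pred.size
    shift = round(offset_s * fs_hz)
    total = n + shift
    win = event_regressor(events, "win", fs_hz, total)[shift:]
    loss = event_regressor(events, "loss", fs_hz, total)[shift:]
    design = np.column_stack([np.ones(n), win, loss])
    beta = _ols(y_pred, design)
    return float(beta[1]), float(beta[2])


def specificity_report(y_pred: np.ndarray, roi_bolds: dict[str, np.ndarray],
                       nuisance: np.ndarray | None = None
                       ) -> dict[str, tuple[float, float]]:
    """Per-ROI correlation and GLM beta of the decoded series.

    For each ROI series (aligned to the prediction's rate and length) the
    report holds the Pearson r with the prediction and the prediction's
    coefficient from an OLS of the ROI series on [intercept, prediction,
    nuisance regressors] - the ROI-level analogue of a whole-brain
    regression on the decoded signal.
    """
    if len(set(roi_bolds)) != len(roi_bolds):
        raise ValueError("duplicate ROI labels")
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    n = y_pred.size
    cols = [np.ones(n), y_pred]
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] == n:
            nuisance = nuisance.T
        cols += list(nuisance)
    design = np.column_stack(cols)
    out: dict[str, tuple[float, float]] = {}
    for label, series in roi_bolds.items():
        series = np.asarray(series, dtype=float).ravel()
        if series.size != n:
            raise ValueError(f"ROI {label!r} length {series.size} != {n}")
        beta = _ols(series, design)
        out[label] = (pearson_r(y_pred, series), float(beta[1]))
    return out


def _paired_t(a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
              ) -> dict[str, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff = a - b
    if np.allclose(diff, 0):
        return {"t": 0.0, "p": 1.0, "df": float(a.size - 1),
                "mean_diff": 0.0, "degenerate": 1.0}
    res = stats.ttest_rel(a, b, alternative=alternative)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "df": float(a.size - 1), "mean_diff": float(diff.mean()),
            "degenerate": 0.0}


def _summary(values: np.ndarray) -> dict[str, float]:
    return {"mean": float(np.mean(values)), "sd": float(np.std(values, ddof=1)),
            "min": float(np.min(values)), "max": float(np.max(values))}


def group_tests(per_fold: list[FoldResult],
                linear_per_fold: list[FoldResult] | None = None) -> GroupReport:
    """Assemble the group report with paired t-tests (df = n_folds - 1).

    Tests: DL vs linear held-out r (one-sided, DL greater), target vs each
    control ROI r (one-sided, target greater, Bonferroni-adjusted p also
    reported), and win vs loss betas (one-sided, win greater).
    """
    if linear_per_fold is not None:
        if len(linear_per_fold) != len(per_fold):
            raise ValueError("fold counts must match")
        if [f.fold_id for f in per_fold] != [f.fold_id for f in linear_per_fold]:
            raise ValueError("fold ids must match pairwise")

    rows = []
    for f in per_fold:
        row = {"fold_id": f.fold_id, "model": f.model, "r": f.r,
               "permutation_p": f.permutation_p, "r_downsampled": f.r_downsampled,
               "beta_win": f.beta_win, "beta_loss": f.beta_loss}
        for roi, r in f.roi_r.items():
            row[f"r_{roi}"] = r
        rows.append(row)
    if linear_per_fold is not None:
        for f in linear_per_fold:
            rows.append({"fold_id": f.fold_id, "model": f.model, "r": f.r,
                         "permutation_p": f.permutation_p,
                         "r_downsampled": f.r_downsampled,
                         "beta_win": f.beta_win, "beta_loss": f.beta_loss})
    table = pd.DataFrame(rows)

    dl_r = np.array([f.r for f in per_fold])
    summary = {"dl_r": _summary(dl_r)}
    tests: dict[str, dict[str, float]] = {}

    if linear_per_fold is not None:
        lin_r = np.array([f.r for f in linear_per_fold])
        summary["linear_r"] = _summary(lin_r)
        tests["dl_vs_linear_r"] = _paired_t(dl_r, lin_r, alternative="greater")

    roi_labels = sorted({roi for f in per_fold for roi in f.roi_r})
    control_labels = [lab for lab in roi_labels]
    for roi in control_labels:
        roi_r = np.array([f.roi_r[roi] for f in per_fold])
        summary[f"r_{roi}"] = _summary(roi_r)
        test = _paired_t(dl_r, roi_r, alternative="greater")
        test["p_bonferroni"] = min(test["p"] * len(control_labels), 1.0)
        tests[f"target_vs_{roi}_r"] = test

    betas_w = np.array([f.beta_win for f in per_fold])
    betas_l = np.array([f.beta_loss for f in per_fold])
    if np.all(np.isfinite(betas_w)) and np.all(np.isfinite(betas_l)):
        summary["beta_win"] = _summary(betas_w)
        summary["beta_loss"] = _summary(betas_l)
        tests["beta_win_vs_loss"] = _paired_t(betas_w, betas_l,
                                              alternative="greater")

    if np.all(np.isfinite([f.r_downsampled for f in per_fold])):
        summary["dl_r_downsampled"] = _summary(
            np.array([f.r_downsampled for f in per_fold])
        )
    return GroupReport(per_fold=table, summary=summary, paired_tests=tests,
                       n_folds=len(per_fold))
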