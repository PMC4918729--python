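"""Desk-scale model-based neural analysis.

Trial-wise model quantities (Q of the chosen option at cue onsets, the
prediction error delta at outcome onsets) become parametric fMRI regressors:
delta functions at event onsets, scaled by the mean-centered modulator,
convolved with a canonical double-gamma haemodynamic response function on a
microtime grid and downsampled to the TR.  Ordinary least squares per ROI
yields subject-level betas; treatment effects are paired contrasts across
the crossover, and a BIC comparison asks whether outcome-phase activity is
better explained by the prediction error or by the objective outcome value.

Sign conventions follow the field: reward prediction error correlates
positively with the ventral-striatum signal; punishment prediction error
correlates negatively with the insula signal, so "stronger pPE encoding"
means a more negative signed beta.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from sklearn.base import BaseEstimator

from .stats import PairedTResult, paired_t

ROI_NAMES = ("ventral_striatum", "anterior_insula")


class RoiError(ValueError):
    """Raised for unknown ROIs or malformed ROI data."""


@dataclass(frozen=True)
class HrfSpec:
    """Canonical double-gamma HRF and sampling grid.

    Response gamma peaks near 5-6 s, undershoot near 16 s, undershoot ratio
    1/6, kernel length 32 s; events are placed on a microtime grid of
    ``microtime`` bins per TR (default TR 3.3 s, 16 bins).
    """

    tr: float = 3.3
    microtime: int = 16
    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("TR must be > 0")
        if self.microtime < 1:
            raise ValueError("microtime must be >= 1")

    @property
    def dt(self) -> float:
        return self.tr / self.microtime


def hrf_kernel(spec: HrfSpec = HrfSpec()) -> np.ndarray:
    """Double-gamma HRF sampled at microtime resolution, normalized to peak 1."""
    t = np.arange(0.0, spec.length + spec.dt / 2, spec.dt)
    h = gamma_dist.pdf(
        t, a=spec.response_delay / spec.response_dispersion, scale=spec.response_dispersion
    ) - spec.undershoot_ratio * gamma_dist.pdf(
        t, a=spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    return h / h.max()


def build_regressor(
    onsets: np.ndarray,
    modulators: np.ndarray | float,
    spec: HrfSpec,
    scan_length: float,
    mean_center: bool = True,
) -> np.ndarray:
    """HRF-convolved parametric regressor sampled on the TR grid.

    Delta functions of height ``modulator`` (mean-centered by default, as is
    standard for parametric modulation; pass ``mean_center=False`` and
    ``modulators=1`` for a plain event regressor) are placed at the nearest
    microtime bin of each onset and convolved with the canonical kernel.
    The construction is linear in the modulators.
    """
    onsets = np.asarray(onsets, dtype=float)
    mods = np.broadcast_to(np.asarray(modulators, dtype=float), onsets.shape).copy()
    if onsets.size and (onsets.min() < 0 or onsets.max() >= scan_length):
        raise RoiError("onset outside scan")
    if np.any(np.diff(onsets) < 0):
        raise RoiError("onsets must be sorted")
    if mean_center and mods.size:
        mods = mods - mods.mean()
    n_micro = int(np.ceil(scan_length / spec.dt))
    u = np.zeros(n_micro)
    idx = np.round(onsets / spec.dt).astype(int)
    np.add.at(u, np.clip(idx, 0, n_micro - 1), mods)
    conv = np.convolve(u, hrf_kernel(spec))[:n_micro]
    n_tr = int(np.floor(scan_length / spec.tr))
    return conv[np.arange(n_tr) * spec.microtime]


# ---------------------------------------------------------------------------
# event timing and design matrices
# ---------------------------------------------------------------------------

#: cue -> outcome delay in seconds (outcome displayed after a 4 s delay)
OUTCOME_DELAY = 4.0
#: cue -> cue inter-trial interval, seconds (convention; not reported)
DEFAULT_ITI = 8.0
#: lead-in before the first cue, seconds
T0 = 10.0


def events_from_series(
    cell_series: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    iti: float = DEFAULT_ITI,
    t0: float = T0,
) -> pd.DataFrame:
    """Interleave per-condition series into a single event table.

    ``cell_series`` maps condition -> (q_series, delta_series,
    outcome_values), each in the cell's canonical trial order (outcome
    values are the objective ±1/0 outcomes, needed by the outcome-value
    candidate model).  Conditions are interleaved trial by trial (the
    scanner session presents pairs in shuffled order; a fixed round-robin
    interleaving is an adequate desk-scale timing model).  Returns one row
    per trial with cue and outcome times.
    """
    conds = sorted(cell_series)
    frames = []
    for c in conds:
        q, d, ov = cell_series[c]
        if not (len(q) == len(d) == len(ov)):
            raise RoiError("q, delta and outcome series misaligned")
        frames.append(pd.DataFrame({
            "condition": c, "idx": np.arange(len(q)), "q": np.asarray(q, float),
            "delta": np.asarray(d, float),
            "outcome_value": np.asarray(ov, float),
        }))
    ev = pd.concat(frames).sort_values(["idx", "condition"], ignore_index=True)
    ev["t_cue"] = t0 + np.arange(len(ev)) * iti
    ev["t_outcome"] = ev["t_cue"] + OUTCOME_DELAY
    return ev


def scan_length_for(events: pd.DataFrame, spec: HrfSpec, pad: float = 20.0) -> float:
    n_tr = int(np.ceil((events["t_outcome"].max() + pad) / spec.tr))
    return n_tr * spec.tr


def session_design(
    events: pd.DataFrame,
    spec: HrfSpec,
    scan_length: float,
    outcome_modulator: str = "delta",
    include_cue_q: bool = True,
    drop_degenerate: bool = True,
) -> pd.DataFrame:
    """Analysis design matrix for one subject x treatment scan.

    Columns: intercept, linear drift, unmodulated outcome-onset regressor,
    condition-specific outcome-phase modulators (delta by default — the
    reward PE regressor on gain trials and punishment PE regressor on loss
    trials — or the objective outcome value), and optionally the Q-modulated
    cue regressor pooled over conditions.  A modulator that is identically
    zero (e.g. the delta series of a no-learning fit) carries no signal and
    is dropped when ``drop_degenerate`` is set; its beta is reported as 0
    downstream.
    """
    n_tr = int(np.floor(scan_length / spec.tr))
    cols = {
        "intercept": np.ones(n_tr),
        "drift": np.linspace(-0.5, 0.5, n_tr),
        "outcome_onset": build_regressor(
            events["t_outcome"].to_numpy(), 1.0, spec, scan_length, mean_center=False
        ),
    }
    for cond, sub in events.groupby("condition"):
        if cond == "gain":
            name = "rpe" if outcome_modulator == "delta" else "gain_outcome"
        elif cond == "loss":
            name = "ppe" if outcome_modulator == "delta" else "loss_outcome"
        else:
            continue
        if outcome_modulator == "delta":
            mod = sub["delta"].to_numpy()
        elif outcome_modulator == "outcome":
            mod = sub["outcome_value"].to_numpy()
        else:
            raise ValueError(f"unknown outcome modulator {outcome_modulator!r}")
        cols[name] = build_regressor(sub["t_outcome"].to_numpy(), mod, spec, scan_length)
    if include_cue_q:
        cols["cue_q"] = build_regressor(
            events["t_cue"].to_numpy(), events["q"].to_numpy(), spec, scan_length
        )
    X = pd.DataFrame(cols)
    if drop_degenerate:
        keep = ["intercept", "drift", "outcome_onset"] + [
            c for c in X.columns
            if c not in ("intercept", "drift", "outcome_onset")
            and not np.allclose(X[c], 0.0)
        ]
        X = X[keep]
    return X


# ---------------------------------------------------------------------------
# ROI simulation
# ---------------------------------------------------------------------------

@dataclass
class RoiDataset:
    """TR-sampled ROI signal plus the event metadata needed for its GLM."""

    roi: str
    signal: np.ndarray
    events: pd.DataFrame
    tr: float
    scan_length: float

    def __post_init__(self):
        if self.roi not in ROI_NAMES:
            raise RoiError(f"unknown roi {self.roi!r}; expected one of {ROI_NAMES}")
        if len(self.events) and self.events["t_outcome"].max() >= self.scan_length:
            raise RoiError("onsets extend beyond the scan")


@dataclass(frozen=True)
class RoiWeights:
    """Planted encoding weights of one ROI for one subject x treatment."""

    w_outcome_onset: float = 1.0
    w_rpe: float = 0.0
    w_ppe: float = 0.0
    w_cue: float = 0.0


def simulate_roi(
    roi: str,
    events: pd.DataFrame,
    weights: RoiWeights,
    spec: HrfSpec,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
    drift_amplitude: float = 1.0,
    encode: str = "pe",
    design: pd.DataFrame | None = None,
) -> RoiDataset:
    """Synthesize one ROI time series with planted prediction-error encoding.

    ``signal = w_onset * onset + w_rpe * rPE + w_ppe * pPE + w_cue * cueQ +
    drift + N(0, noise_sd)``.  With ``encode='outcome'`` the modulated
    regressors carry the objective outcome value instead of delta, providing
    the alternative generative family for model-comparison harnesses.
    ``design`` lets callers reuse a precomputed session design (it must
    match ``events`` and ``encode``).
    """
    if roi not in ROI_NAMES:
        raise RoiError(f"unknown roi {roi!r}; expected one of {ROI_NAMES}")
    scan_length = scan_length_for(events, spec)
    modulator = "delta" if encode == "pe" else "outcome"
    X = design if design is not None else session_design(
        events, spec, scan_length, outcome_modulator=modulator
    )
    n_tr = len(X)
    y = weights.w_outcome_onset * X["outcome_onset"].to_numpy()
    gain_col = "rpe" if encode == "pe" else "gain_outcome"
    loss_col = "ppe" if encode == "pe" else "loss_outcome"
    if gain_col in X:
        y = y + weights.w_rpe * X[gain_col].to_numpy()
    if loss_col in X:
        y = y + weights.w_ppe * X[loss_col].to_numpy()
    if "cue_q" in X:
        y = y + weights.w_cue * X["cue_q"].to_numpy()
    y = y + drift_amplitude * np.linspace(-0.5, 0.5, n_tr)
    y = y + rng.normal(0.0, noise_sd, n_tr)
    return RoiDataset(roi=roi, signal=y, events=events, tr=spec.tr, scan_length=scan_length)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

class RoiGlm(BaseEstimator):
    """Ordinary least squares GLM for one ROI time series.

    After ``fit(X, y)``: ``betas_`` (Series indexed by design column),
    ``residual_var_`` (MLE), ``loglik_`` (Gaussian), ``bic_`` with
    ``k = n_regressors + 1`` (the +1 for the noise variance).
    """

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "RoiGlm":
        A = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if A.ndim != 2 or A.shape[0] != y.size:
            raise RoiError("design/signal shape mismatch")
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            # name the collinear columns for the caller
            keep, bad = [], []
            for j, name in enumerate(X.columns):
                if np.linalg.matrix_rank(A[:, keep + [j]]) > len(keep):
                    keep.append(j)
                else:
                    bad.append(str(name))
            raise RoiError(f"rank-deficient design; collinear columns: {bad}")
        beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        n = y.size
        sigma2 = float(resid @ resid) / n
        if sigma2 <= 0:
            sigma2 = np.finfo(float).tiny
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        k = A.shape[1] + 1
        self.betas_ = pd.Series(beta, index=list(X.columns))
        self.residual_var_ = sigma2
        self.loglik_ = float(loglik)
        self.bic_ = float(k * np.log(n) - 2 * loglik)
        self.n_obs_ = n
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.betas_.to_numpy()


@dataclass(frozen=True)
class GlmResult:
    betas: pd.Series
    residual_var: float
    loglik: float
    bic: float


def fit_glm(dataset: RoiDataset, design: pd.DataFrame) -> GlmResult:
    """OLS fit of a design matrix to one ROI dataset."""
    est = RoiGlm().fit(design, dataset.signal)
    return GlmResult(est.betas_, est.residual_var_, est.loglik_, est.bic_)


def fit_session_glm(dataset: RoiDataset, spec: HrfSpec) -> GlmResult:
    """Fit the standard analysis design (delta modulators) to one scan."""
    X = session_design(dataset.events, spec, dataset.scan_length)
    return fit_glm(dataset, X)


# ---------------------------------------------------------------------------
# group-level comparisons
# ---------------------------------------------------------------------------

def treatment_contrast(
    betas: pd.DataFrame,
    roi: str,
    regressor: str,
    treatments: tuple = ("placebo", "vaccine"),
) -> PairedTResult:
    """Paired t of one regressor's betas across treatments within one ROI.

    Reported as second-listed treatment minus first (vaccine - placebo by
    default): a negative mean difference means vaccine < placebo on the
    signed beta — reduced rPE encoding in striatum, or a larger-magnitude
    negative pPE weight in insula.
    """
    sub = betas[(betas["roi"] == roi) & (betas["regressor"] == regressor)]
    if len(sub) == 0:
        raise RoiError(f"no betas for roi={roi!r}, regressor={regressor!r}")
    wide = sub.pivot_table(index="subject_id", columns="treatment", values="beta")
    if any(t not in wide.columns for t in treatments) or wide[list(treatments)].isna().any().any():
        raise RoiError("unpaired subjects across treatments")
    return paired_t(wide[treatments[1]], wide[treatments[0]])


def compare_pe_vs_outcome(
    datasets: dict[str, RoiDataset],
    spec: HrfSpec,
    designs: dict[str, tuple[pd.DataFrame, pd.DataFrame]] | None = None,
) -> dict:
    """BIC comparison: prediction-error vs outcome-value outcome modulators.

    ``datasets`` maps subject_id -> RoiDataset (one ROI, one treatment or
    concatenated).  Both candidate designs share every column except the
    outcome-phase modulators (delta vs objective outcome value), so equal
    complexity; the group fixed-effects log Bayes factor is
    ``0.5 * sum(BIC_outcome - BIC_PE)`` — positive favours the PE model.
    """
    rows = []
    for subject, ds in sorted(datasets.items()):
        if designs is not None and subject in designs:
            X_pe, X_out = designs[subject]
        else:
            X_pe = session_design(ds.events, spec, ds.scan_length, outcome_modulator="delta")
            X_out = session_design(ds.events, spec, ds.scan_length, outcome_modulator="outcome")
        # keep the candidate designs at equal complexity: if one family's
        # modulator was degenerate (dropped), drop its counterpart too
        for pe_c, out_c in (("rpe", "gain_outcome"), ("ppe", "loss_outcome")):
            if (pe_c in X_pe.columns) != (out_c in X_out.columns):
                X_pe = X_pe.drop(columns=[pe_c], errors="ignore")
                X_out = X_out.drop(columns=[out_c], errors="ignore")
        bic_pe = fit_glm(ds, X_pe).bic
        bic_out = fit_glm(ds, X_out).bic
        rows.append({
            "subject_id": subject,
            "bic_pe": bic_pe,
            "bic_outcome": bic_out,
            "delta_bic": bic_out - bic_pe,
        })
    table = pd.DataFrame(rows)
    log_bf = 0.5 * float(table["delta_bic"].sum())
    return {
        "per_subject": table,
        "group_log_bayes_factor": log_bf,
        "favours_pe": log_bf > 0,
        "prop_subjects_pe": float((table["delta_bic"] > 0).mean()),
    }
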