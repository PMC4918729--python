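"""Maximum-likelihood fitting of (alpha, beta, R) to observed choices.

One *cell* is the trial set of a single subject x treatment x valence
condition, pooled over the runs' pairs with Q values reset to zero at each
new pair (fresh stimuli carry no learned value).  The likelihood is the
product of softmax choice probabilities along the observed choice/outcome
sequence, with values updated by the delta rule and R treated as a free,
optionally sign-constrained, subjective outcome magnitude.

A structural fact drives the optimizer design: because the value recursion
is homogeneous of degree one in R (Q values start at zero and every update
is linear in R) and choices depend on the values only through Q / beta, the
likelihood is *exactly* invariant under ``(R, beta) -> (c R, c beta)``.
Only the learning rate alpha and the sensitivity ratio ``rho = R / beta``
are identified by choices.  Naive three-parameter maximum likelihood
therefore drifts arbitrarily along this ridge.  We instead maximize the
likelihood over the identified coordinates ``(logit alpha, ln |rho|)`` with
box bounds and multiple seeded L-BFGS-B restarts, then place the solution
on the ridge deterministically by a weak quadratic anchor on
``(ln beta, ln |R|)`` — a minimal-information tie-break that leaves alpha,
rho and the likelihood untouched while keeping the reported beta and R on
interpretable scales.

The estimator follows the scikit-learn protocol
(:class:`RescorlaWagnerML`); :func:`fit_cell` / :func:`fit_study` are thin
functional wrappers.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from . import _likelihood
from .agent import AgentParams


class DataError(ValueError):
    """Raised for malformed or misaligned trial data."""


@dataclass(frozen=True)
class FitSpec:
    """Optimizer configuration for one cell fit.

    Bounds follow the transformed parameterization: alpha in [0, 1] via a
    clipped logit, beta in [1e-3, 1e2] on the log scale, |R| <= 10, and the
    identified ratio |R|/beta in [1e-4, 1e4] on the log scale.  With
    ``sign_constraint`` on (default), R >= 0 for gain cells and R <= 0 for
    loss cells.  ``beta_anchor`` / ``r_anchor`` and their weights define the
    ridge tie-break (see module docstring).
    """

    alpha_logit_bounds: tuple = (-12.0, 12.0)
    log_beta_bounds: tuple = (float(np.log(1e-3)), float(np.log(1e2)))
    r_abs_max: float = 10.0
    log_rho_bounds: tuple = (float(np.log(1e-4)), float(np.log(1e4)))
    sign_constraint: bool = True
    n_restarts: int = 10
    beta_anchor: float = 0.3
    r_anchor: float = 1.0
    beta_anchor_weight: float = 9.0
    r_anchor_weight: float = 1.0
    alpha_prior: tuple | None = (0.35, 1.0)
    rho_prior: tuple | None = (3.0, 1.0)
    tol: float = 1e-9
    seed: int | None = None

    def __post_init__(self):
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        for lo, hi in (self.alpha_logit_bounds, self.log_beta_bounds, self.log_rho_bounds):
            if not lo < hi:
                raise ValueError("bounds must be well-ordered")


@dataclass
class FitResult:
    """Outcome of one cell fit."""

    params: AgentParams
    neg_log_likelihood: float
    n_trials: int
    n_pairs: int
    mean_log_likelihood_per_pair: float
    converged: bool
    n_restarts_used: int
    degenerate_choices: bool
    q_series: np.ndarray
    delta_series: np.ndarray


def cell_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Canonical (choices, nonnil, pair_start, n_pairs) arrays of one cell.

    Trials are ordered pair by pair (pairs in run order, trials by
    within-pair index); ``pair_start`` marks the Q-reset at each new pair.
    """
    if len(trials) == 0:
        raise DataError("empty trial list")
    bad = set(trials["choice"].unique()) - {"A", "B"}
    if bad:
        raise DataError(f"choice codes outside {{'A','B'}}: {sorted(bad)}")
    df = trials.sort_values(["run", "pair_id", "trial"], kind="mergesort")
    choices = (df["choice"].to_numpy() == "B").astype(np.int8)
    nonnil = (df["outcome"].to_numpy() != 0).astype(np.float64)
    pair_id = df["pair_id"].to_numpy()
    pair_start = np.zeros(len(df), dtype=np.bool_)
    pair_start[0] = True
    pair_start[1:] = pair_id[1:] != pair_id[:-1]
    return choices, nonnil, pair_start, int(pair_start.sum())


def negative_log_likelihood(params: AgentParams, trials: pd.DataFrame) -> float:
    """NLL (nats) of the observed choices of one cell under ``params``."""
    choices, nonnil, pair_start, _ = cell_arrays(trials)
    return float(
        _likelihood.nll_core(params.alpha, params.beta, params.r, choices, nonnil, pair_start)
    )


class RescorlaWagnerML(BaseEstimator):
    """Maximum-likelihood Rescorla-Wagner + softmax estimator for one cell.

    Parameters
    ----------
    sign : {'auto', 'free', 'positive', 'negative'}
        Sign constraint on R.  'auto' reads the cell's condition
        (gain -> positive, loss -> negative); 'free' removes the constraint.
    n_restarts : int
        Seeded random restarts of the bounded optimizer.
    r_abs_max : float
        Bound on |R| (currency units).
    random_state : int or None
        Seed for the restart initial points.

    Attributes (after :meth:`fit`)
    ------------------------------
    alpha_, beta_, r_ : fitted parameters
    nll_ : negative log-likelihood at the optimum (nats)
    mean_ll_per_pair_ : total log-likelihood / number of pairs
    q_series_, delta_series_ : trial-wise values along the observed sequence
    converged_, n_restarts_used_, degenerate_ : diagnostics
    """

    def __init__(
        self,
        sign: str = "auto",
        n_restarts: int = 10,
        alpha_logit_bounds: tuple = (-12.0, 12.0),
        log_beta_bounds: tuple = (float(np.log(1e-3)), float(np.log(1e2))),
        r_abs_max: float = 10.0,
        log_rho_bounds: tuple = (float(np.log(1e-4)), float(np.log(1e4))),
        beta_anchor: float = 0.3,
        r_anchor: float = 1.0,
        beta_anchor_weight: float = 9.0,
        r_anchor_weight: float = 1.0,
        alpha_prior: tuple | None = (0.35, 1.0),
        rho_prior: tuple | None = (3.0, 1.0),
        tol: float = 1e-9,
        random_state: int | None = None,
    ):
        self.sign = sign
        self.n_restarts = n_restarts
        self.alpha_logit_bounds = alpha_logit_bounds
        self.log_beta_bounds = log_beta_bounds
        self.r_abs_max = r_abs_max
        self.log_rho_bounds = log_rho_bounds
        self.beta_anchor = beta_anchor
        self.r_anchor = r_anchor
        self.beta_anchor_weight = beta_anchor_weight
        self.r_anchor_weight = r_anchor_weight
        self.alpha_prior = alpha_prior
        self.rho_prior = rho_prior
        self.tol = tol
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _resolve_sign(self, trials: pd.DataFrame) -> str:
        if self.sign != "auto":
            return self.sign
        conds = set(trials["condition"].unique())
        if conds == {"gain"}:
            return "positive"
        if conds == {"loss"}:
            return "negative"
        if "neutral" in conds:
            raise DataError("neutral trials carry no learnable outcome; exclude them")
        raise DataError(
            f"cell mixes conditions {sorted(conds)}; fit one valence at a time "
            "or set sign explicitly"
        )

    def _r_bounds(self, sign: str) -> tuple[float, float]:
        if sign == "positive":
            return (0.0, self.r_abs_max)
        if sign == "negative":
            return (-self.r_abs_max, 0.0)
        if sign == "free":
            return (-self.r_abs_max, self.r_abs_max)
        raise ValueError(f"unknown sign constraint {sign!r}")

    def _allocate_ridge(self, rho_mag: float, r_sign: float) -> tuple[float, float]:
        """Deterministic (beta, R) on the ridge R = sign * rho_mag * beta.

        Minimizes ``w_b (ln beta - ln beta_anchor)^2 +
        w_r (ln |R| - ln r_anchor)^2`` subject to the fitted ratio — a
        closed-form tie-break along the exactly likelihood-flat direction.
        """
        b_lo, b_hi = np.exp(self.log_beta_bounds)
        if rho_mag <= np.exp(self.log_rho_bounds[0]) * (1 + 1e-9):
            # no choice preference to scale against: report the anchor
            return float(self.beta_anchor), float(r_sign * self.beta_anchor * rho_mag)
        w_b, w_r = self.beta_anchor_weight, self.r_anchor_weight
        log_beta = (
            w_b * np.log(self.beta_anchor)
            + w_r * (np.log(self.r_anchor) - np.log(rho_mag))
        ) / (w_b + w_r)
        beta = float(np.clip(np.exp(log_beta), b_lo, b_hi))
        r_mag = beta * rho_mag
        if r_mag > self.r_abs_max:  # keep the identified ratio, shrink beta
            r_mag = self.r_abs_max
            beta = float(np.clip(r_mag / rho_mag, b_lo, b_hi))
            r_mag = beta * rho_mag
        return beta, float(r_sign * r_mag)

    def fit(self, trials: pd.DataFrame, y=None) -> "RescorlaWagnerML":
        choices, nonnil, pair_start, n_pairs = cell_arrays(trials)
        sign = self._resolve_sign(trials)
        bounds = [self.alpha_logit_bounds, self.log_rho_bounds]
        signs = (1.0, -1.0) if sign == "free" else ((1.0,) if sign == "positive" else (-1.0,))

        rng = np.random.default_rng(self.random_state)
        starts = [np.array([float(logit(0.3)), float(np.log(1.0 / 0.3))])]
        for _ in range(self.n_restarts - 1):
            a0 = rng.uniform(0.02, 0.98)
            lr0 = rng.uniform(np.log(0.1), np.log(30.0))
            starts.append(np.array([float(logit(a0)), lr0]))

        # weak MAP penalties stabilize the alpha-rho trade-off (see docstring)
        if self.alpha_prior is not None:
            mu_a, sd_a = float(logit(self.alpha_prior[0])), self.alpha_prior[1]
        if self.rho_prior is not None:
            mu_r, sd_r = float(np.log(self.rho_prior[0])), self.rho_prior[1]

        def penalty(u):
            pen = 0.0
            if self.alpha_prior is not None:
                pen += 0.5 * ((u[0] - mu_a) / sd_a) ** 2
            if self.rho_prior is not None:
                pen += 0.5 * ((u[1] - mu_r) / sd_r) ** 2
            return pen

        best = None
        best_sign = signs[0]
        any_success = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for r_sign in signs:

                def objective(u, _s=r_sign):
                    a = expit(u[0])
                    rho = _s * np.exp(u[1])
                    # likelihood depends on (alpha, R/beta) only; fix beta=1
                    return (
                        _likelihood.nll_core(a, 1.0, rho, choices, nonnil, pair_start)
                        + penalty(u)
                    )

                for x0 in starts:
                    res = minimize(
                        objective, x0, method="L-BFGS-B", bounds=bounds, tol=self.tol
                    )
                    any_success = any_success or bool(res.success)
                    if best is None or res.fun < best.fun:
                        best = res
                        best_sign = r_sign

        u = best.x
        self.alpha_ = float(expit(u[0]))
        self.rho_ = float(best_sign * np.exp(u[1]))
        self.beta_, self.r_ = self._allocate_ridge(float(np.exp(u[1])), best_sign)
        # report the data term (the NLL proper) at the optimum
        self.nll_ = float(
            _likelihood.nll_core(
                self.alpha_, 1.0, self.rho_, choices, nonnil, pair_start
            )
        )
        # a fit may never be worse than the random-choice model (alpha = 0);
        # if the regularized optimum is, the data carry no learning signal and
        # the no-learning boundary solution is reported instead
        chance_nll = choices.size * np.log(2.0)
        if self.nll_ > chance_nll:
            self.alpha_ = 0.0
            self.rho_ = 0.0
            self.beta_ = float(self.beta_anchor)
            self.r_ = 0.0
            self.nll_ = float(chance_nll)
        self.n_trials_ = int(choices.size)
        self.n_pairs_ = n_pairs
        self.mean_ll_per_pair_ = -self.nll_ / n_pairs
        self.converged_ = any_success
        self.n_restarts_used_ = len(starts) * len(signs)
        self.degenerate_ = bool(len(np.unique(choices)) == 1)
        if self.degenerate_:
            warnings.warn("all choices identical; parameters lie at a boundary", stacklevel=2)
        q, d = _likelihood.series_core(
            self.alpha_, self.beta_, self.r_, choices, nonnil, pair_start
        )
        self.q_series_ = np.asarray(q)
        self.delta_series_ = np.asarray(d)
        return self

    def result_(self) -> FitResult:
        return FitResult(
            params=AgentParams(self.alpha_, self.beta_, self.r_),
            neg_log_likelihood=self.nll_,
            n_trials=self.n_trials_,
            n_pairs=self.n_pairs_,
            mean_log_likelihood_per_pair=self.mean_ll_per_pair_,
            converged=self.converged_,
            n_restarts_used=self.n_restarts_used_,
            degenerate_choices=self.degenerate_,
            q_series=self.q_series_,
            delta_series=self.delta_series_,
        )


def fit_cell(trials: pd.DataFrame, spec: FitSpec = FitSpec()) -> FitResult:
    """Fit one subject x treatment x valence cell; best of seeded restarts."""
    sign = "auto" if spec.sign_constraint else "free"
    est = RescorlaWagnerML(
        sign=sign,
        n_restarts=spec.n_restarts,
        alpha_logit_bounds=spec.alpha_logit_bounds,
        log_beta_bounds=spec.log_beta_bounds,
        r_abs_max=spec.r_abs_max,
        log_rho_bounds=spec.log_rho_bounds,
        beta_anchor=spec.beta_anchor,
        r_anchor=spec.r_anchor,
        beta_anchor_weight=spec.beta_anchor_weight,
        r_anchor_weight=spec.r_anchor_weight,
        alpha_prior=spec.alpha_prior,
        rho_prior=spec.rho_prior,
        tol=spec.tol,
        random_state=spec.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(trials)
    return est.result_()


def fit_study(
    trials: pd.DataFrame,
    spec: FitSpec = FitSpec(),
    conditions: tuple = ("gain", "loss"),
) -> tuple[pd.DataFrame, dict]:
    """Fit every subject x treatment x condition cell of a trial log.

    Neutral trials are excluded by default (nothing monetary to learn).
    Returns a tidy frame (one row per cell) and a dict of
    ``(subject_id, treatment, condition) -> FitResult``.  Per-cell restart
    seeds derive deterministically from ``spec.seed``.
    """
    cells = []
    keys = sorted(
        (s, t, c)
        for (s, t) in trials.groupby(["subject_id", "treatment"]).groups
        for c in conditions
    )
    ss = np.random.SeedSequence(spec.seed if spec.seed is not None else 0)
    children = ss.spawn(len(keys))
    results = {}
    for key, child in zip(keys, children):
        s, t, c = key
        sub = trials[
            (trials["subject_id"] == s)
            & (trials["treatment"] == t)
            & (trials["condition"] == c)
        ]
        if len(sub) == 0:
            raise DataError(f"no trials for cell {key}")
        cell_seed = int(child.generate_state(1)[0] % (2**31))
        cell_spec = dataclasses.replace(spec, seed=cell_seed)
        fr = fit_cell(sub, cell_spec)
        results[key] = fr
        row = {
            "subject_id": s,
            "treatment": t,
            "condition": c,
            "alpha": fr.params.alpha,
            "beta": fr.params.beta,
            "r": fr.params.r,
            "nll": fr.neg_log_likelihood,
            "n_trials": fr.n_trials,
            "mean_ll_per_pair": fr.mean_log_likelihood_per_pair,
            "converged": fr.converged,
        }
        if "session_order" in sub.columns:
            row["session_order"] = int(sub["session_order"].iloc[0])
        cells.append(row)
    return pd.DataFrame(cells), results


def extract_modulators(fit: FitResult, trials: pd.DataFrame | None = None):
    """Onset-aligned parametric modulators: Q(chosen) at cues, delta at outcomes.

    Both series are mean-centered, the standard convention for parametric
    modulation.  If ``trials`` is given its length is validated against the
    fit's series.
    """
    if trials is not None and len(trials) != len(fit.delta_series):
        raise DataError(
            f"fit covers {len(fit.delta_series)} trials but log has {len(trials)}"
        )
    cue = fit.q_series - fit.q_series.mean()
    outcome = fit.delta_series - fit.delta_series.mean()
    return cue, outcome
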