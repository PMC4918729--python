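"""Validation harnesses: parameter recovery, planted-effect detection, power.

These functions define the package's own evidence that the pipeline works:
simulate under known conditions, run the full estimation path, and score the
result.  They are used by the test suite and by the acceptance script, and
are exposed so users can rerun them at other settings.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .agent import AgentParams, simulate_session
from .cohort import CohortSpec, behavioral_pipeline, generate_study, roi_pipeline
from .fitting import FitSpec, fit_cell, fit_study
from .stats import rm_anova_2x2
from .task import TaskConfig, make_schedule


def draw_prior_cells(spec: CohortSpec, n_cells: int, rng: np.random.Generator):
    """Independent (alpha, beta, R, condition) draws from the cohort priors."""
    cells = []
    for i in range(n_cells):
        cond = "gain" if i % 2 == 0 else "loss"
        a = float(rng.beta(*spec.alpha_beta_shape))
        b = float(np.exp(rng.normal(spec.beta_log_mu, spec.beta_log_sigma)))
        mag = -1.0
        while mag < spec.r_abs_min:
            mag = float(rng.normal(abs(spec.r_gain_mean), spec.r_gain_sd))
        cells.append((a, b, mag if cond == "gain" else -mag, cond))
    return cells


def simulate_prior_cell(alpha, beta, r, condition, trials_per_pair, seed):
    cfg = TaskConfig(trials_per_pair=trials_per_pair, conditions=(condition,))
    schedule = make_schedule(cfg, seed)
    rng = np.random.default_rng(seed + 1)
    return simulate_session({condition: AgentParams(alpha, beta, r)}, schedule, rng)


def recovery_study(
    n_cells: int = 200,
    trials_per_pair: int = 30,
    seed: int = 0,
    spec: CohortSpec | None = None,
    fit_spec: FitSpec | None = None,
) -> dict:
    """Simulate ``n_cells`` independent cells and score parameter recovery.

    Returns Spearman correlations (alpha, beta, signed R pooled over
    valences, and the identified ratio R/beta) plus the median absolute
    error of alpha.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    cells = draw_prior_cells(spec, n_cells, rng)
    rows = []
    base = (seed + 1) * 100_000
    for i, (a, b, r, cond) in enumerate(cells):
        log = simulate_prior_cell(a, b, r, cond, trials_per_pair, base + i)
        fs = dataclasses.replace(fit_spec or FitSpec(), seed=i)
        fr = fit_cell(log, fs)
        rows.append((a, b, r, fr.params.alpha, fr.params.beta, fr.params.r))
    arr = np.array(rows)
    sp = lambda x, y: float(sps.spearmanr(x, y).statistic)
    return {
        "n_cells": n_cells,
        "trials_per_pair": trials_per_pair,
        "spearman_alpha": sp(arr[:, 0], arr[:, 3]),
        "spearman_beta": sp(arr[:, 1], arr[:, 4]),
        "spearman_r": sp(arr[:, 2], arr[:, 5]),
        "spearman_ratio": sp(arr[:, 2] / arr[:, 1], arr[:, 5] / arr[:, 4]),
        "alpha_median_abs_error": float(np.median(np.abs(arr[:, 3] - arr[:, 0]))),
    }


def interaction_detection_rate(
    n_cohorts: int = 100,
    seed: int = 0,
    null: bool = False,
    spec: CohortSpec | None = None,
) -> dict:
    """End-to-end planted-effect detection: generate -> fit -> 2x2 ANOVA on R.

    Counts cohorts whose treatment x valence interaction on the
    valence-aligned subjective value reaches p < .05.
    """
    spec = spec or CohortSpec()
    if null:
        spec = spec.null()
    base = 1_000_000 if not null else 5_000_000
    ps = []
    for i in range(n_cohorts):
        study = generate_study(spec, base + seed * 10_000 + i, include_roi=False)
        res = behavioral_pipeline(study, FitSpec(seed=seed * 10_000 + i))
        ps.append(res["anovas"]["r_magnitude"]["interaction"].p)
    ps = np.asarray(ps)
    return {
        "n_cohorts": n_cohorts,
        "rate": float((ps < 0.05).mean()),
        "median_p": float(np.median(ps)),
    }


def neural_dissociation_rate(
    n_cohorts: int = 30,
    seed: int = 0,
    spec: CohortSpec | None = None,
) -> dict:
    """Full neural loop: fit scanned subjects, simulate ROI data from the
    fitted series with planted treatment-dependent weights, fit GLMs, and
    test the double dissociation plus the PE-vs-outcome BIC comparison."""
    spec = spec or CohortSpec()
    rpe_hits = ppe_hits = both = bic_hits = 0
    for i in range(n_cohorts):
        cohort_seed = 2_000_000 + seed * 10_000 + i
        study = generate_study(spec, cohort_seed, include_roi=False)
        scanned_trials = study.trials[study.trials["subject_id"].isin(study.scanned)]
        fits, results = fit_study(scanned_trials, FitSpec(seed=cohort_seed))
        out = roi_pipeline(study, results, seed=cohort_seed)
        rpe = out["contrasts"]["striatum_rpe"]
        ppe = out["contrasts"]["insula_ppe"]
        ok_rpe = rpe.p < 0.05 and rpe.t < 0          # vaccine < placebo
        ok_ppe = ppe.p < 0.05 and ppe.t < 0          # vaccine more negative
        rpe_hits += ok_rpe
        ppe_hits += ok_ppe
        both += ok_rpe and ok_ppe
        bic_hits += out["pe_vs_outcome"]["group_log_bayes_factor"] > 0
    return {
        "n_cohorts": n_cohorts,
        "striatum_rpe_rate": rpe_hits / n_cohorts,
        "insula_ppe_rate": ppe_hits / n_cohorts,
        "double_dissociation_rate": both / n_cohorts,
        "bic_pe_selection_rate": bic_hits / n_cohorts,
    }


def anova_identity_max_error(n_tables: int = 1000, seed: int = 0, n_subjects: int = 12) -> float:
    """Max |F_interaction - t^2| over fuzzed complete 2x2 tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        rows = []
        for i in range(n_subjects):
            for t in ("placebo", "vaccine"):
                for c in ("gain", "loss"):
                    rows.append({"subject_id": f"s{i}", "treatment": t,
                                 "condition": c, "y": rng.normal()})
        table = pd.DataFrame(rows)
        wide = table.pivot_table(index="subject_id",
                                 columns=["treatment", "condition"], values="y")
        dod = (wide[("vaccine", "gain")] - wide[("placebo", "gain")]) - (
            wide[("vaccine", "loss")] - wide[("placebo", "loss")]
        )
        t_stat = float(sps.ttest_1samp(dod, 0.0).statistic)
        F = rm_anova_2x2(table, "y")["interaction"].F
        worst = max(worst, abs(F - t_stat**2))
    return worst


def il6_summary(n_cohorts: int = 50, seed: int = 0, spec: CohortSpec | None = None) -> dict:
    """IL-6 generator check: post-vaccine group mean and interaction power."""
    from .cohort import generate_il6

    spec = spec or CohortSpec()
    subjects = [f"s{i + 1:02d}" for i in range(spec.n_subjects)]
    means, hits = [], 0
    for i in range(n_cohorts):
        il6 = generate_il6(spec, subjects, np.random.default_rng(3_000_000 + seed * 10_000 + i))
        post = il6[(il6["treatment"] == "vaccine") & (il6["sample"] == "post")]
        means.append(post["value"].mean())
        res = rm_anova_2x2(il6, "value", a_col="treatment", b_col="sample")
        hits += res["interaction"].p < 0.05
    return {
        "n_cohorts": n_cohorts,
        "vaccine_post_mean": float(np.mean(means)),
        "interaction_rate": hits / n_cohorts,
    }
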