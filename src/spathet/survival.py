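"""Survival association, stratification, and cross-validated permutation tests.

Per-sample spatial scores are related to overall survival by

* univariate Cox proportional-hazards fits (scores z-scored, so hazard
  ratios are per standard deviation);
* a multiple Cox model with forced clinical base covariates, candidate
  scores entered by forward-backward stepwise search on AIC, and a
  likelihood-ratio test of the final model against the base model;
* quantile-cutoff stratification (25/50/75% score quantiles) compared by
  the logrank test, including bivariate grouping against average expression;
* an n-times repeated k-fold cross-validation scheme in which the cutoff is
  optimized on training folds only, test folds are pooled into one
  cross-validated logrank statistic, and significance comes from an
  empirical permutation null (the entire CV procedure re-run on m
  permutations of the (time, event) pairs).

The logrank statistic used inside the CV/permutation loop is a vectorized
implementation of the standard two-group test (verified against lifelines);
a single permutation analysis evaluates it tens of thousands of times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy.stats import chi2, spearmanr

__all__ = [
    "logrank_statistic",
    "UnivariateCoxResult",
    "univariate_cox",
    "StepwiseCoxResult",
    "multiple_cox_stepwise",
    "StratificationResult",
    "quantile_stratify",
    "CvPermutationResult",
    "repeated_cv_permutation",
    "bivariate_group",
    "km_curves",
]

DEFAULT_QUANTILES = (0.25, 0.5, 0.75)


# ---------------------------------------------------------------------------
# logrank


def _logrank_oev_numpy(t: np.ndarray, e: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """(observed, expected, variance) for group 1; inputs sorted by time."""
    n = len(t)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    at_risk = n - starts
    g_cum = np.r_[0.0, np.cumsum(g)]
    e_cum = np.r_[0.0, np.cumsum(e)]
    eg_cum = np.r_[0.0, np.cumsum(e * g)]
    ends = np.r_[starts[1:], n]
    n1 = g_cum[-1] - g_cum[starts]  # group-1 members still at risk
    d = e_cum[ends] - e_cum[starts]  # events at this time
    d1 = eg_cum[ends] - eg_cum[starts]
    mask = d > 0
    N, N1, D, D1 = at_risk[mask], n1[mask], d[mask], d1[mask]
    observed = float(D1.sum())
    expected = float((D * N1 / N).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = D * (N1 / N) * (1 - N1 / N) * (N - D) / (N - 1)
    variance = float(np.sum(np.where(N > 1, var_terms, 0.0)))
    return observed, expected, variance


try:  # numba kernel: the CV permutation loop calls this tens of thousands of times
    from numba import njit

    @njit(cache=False)
    def _logrank_oev(t, e, g):  # pragma: no cover - exercised via wrapper
        n = len(t)
        observed = 0.0
        expected = 0.0
        variance = 0.0
        n_risk = float(n)
        n1_risk = 0.0
        for i in range(n):
            n1_risk += g[i]
        i = 0
        while i < n:
            j = i
            d = 0.0
            d1 = 0.0
            while j < n and t[j] == t[i]:
                d += e[j]
                d1 += e[j] * g[j]
                j += 1
            if d > 0.0:
                frac = n1_risk / n_risk
                observed += d1
                expected += d * frac
                if n_risk > 1.0:
                    variance += d * frac * (1.0 - frac) * (n_risk - d) / (n_risk - 1.0)
            for k in range(i, j):
                n1_risk -= g[k]
            n_risk -= j - i
            i = j
        return observed, expected, variance

except ImportError:  # pragma: no cover
    _logrank_oev = _logrank_oev_numpy


def _logrank_stat_sorted(t: np.ndarray, e: np.ndarray, g: np.ndarray) -> float:
    """Chi-square logrank statistic; inputs sorted by time, g float 0/1."""
    observed, expected, variance = _logrank_oev(t, e, g)
    if variance <= 0:
        return 0.0
    return (observed - expected) ** 2 / variance


def logrank_statistic(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group logrank test; returns (chi-square statistic, p-value).

    ``group`` is boolean (True = high group).  Uses the standard
    hypergeometric variance with ties.  Degenerate inputs (one group empty,
    no events, zero variance) return (0.0, 1.0).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any() or event.sum() == 0:
        return 0.0, 1.0
    order = np.argsort(time, kind="stable")
    stat = _logrank_stat_sorted(time[order], event[order], group[order].astype(float))
    return float(stat), float(chi2.sf(stat, 1)) if stat > 0 else 1.0


# ---------------------------------------------------------------------------
# Cox regression


@dataclass(frozen=True)
class UnivariateCoxResult:
    """Hazard ratio per SD of the score, with Wald p and 95% CI."""

    hr: float
    p: float
    ci_low: float
    ci_high: float
    ok: bool = True
    message: str = ""


def univariate_cox(
    score: np.ndarray, time: np.ndarray, event: np.ndarray
) -> UnivariateCoxResult:
    """Univariate Cox PH fit of survival on one z-scored score.

    Non-identifiable or non-convergent fits are returned flagged
    (``ok=False``) rather than raising.
    """
    score = np.asarray(score, dtype=float)
    if np.sum(event) < 2:
        return UnivariateCoxResult(np.nan, np.nan, np.nan, np.nan, False, "fewer than 2 events")
    sd = np.std(score)
    if not np.isfinite(sd) or sd == 0:
        return UnivariateCoxResult(np.nan, np.nan, np.nan, np.nan, False, "constant or non-finite score")
    z = (score - np.mean(score)) / sd
    df = pd.DataFrame({"z": z, "time": time, "event": event})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        return UnivariateCoxResult(np.nan, np.nan, np.nan, np.nan, False, f"fit failed: {exc}")
    s = cph.summary.loc["z"]
    return UnivariateCoxResult(
        hr=float(s["exp(coef)"]),
        p=float(s["p"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
    )


def _build_design(
    survival: pd.DataFrame, base_covariates: tuple[str, ...]
) -> pd.DataFrame:
    """Numeric design matrix for the base model (categoricals dummy-coded)."""
    cols = [c for c in base_covariates if c in survival.columns]
    design = pd.get_dummies(survival[cols], drop_first=True, dtype=float)
    # drop constant columns (non-identifiable)
    keep = [c for c in design.columns if design[c].nunique() > 1]
    return design[keep]


def _fit_cox(df: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="os_time", event_col="os_event")
    return cph


@dataclass(frozen=True)
class StepwiseCoxResult:
    base_covariates: tuple[str, ...]
    selected_scores: tuple[str, ...]
    screened_out: tuple[str, ...]  #: candidates dropped by the Spearman screen
    base_loglik: float
    final_loglik: float
    final_aic: float
    lr_stat: float
    lr_df: int
    lr_p: float
    audit: tuple[str, ...] = ()


def multiple_cox_stepwise(
    scores: pd.DataFrame,
    survival: pd.DataFrame,
    base_covariates: tuple[str, ...] = (
        "age", "gender", "grade", "pathologist_score", "avg_expression",
    ),
    spearman_max: float = 0.9,
    max_steps: int = 50,
) -> StepwiseCoxResult:
    """Multiple Cox model: forced base covariates plus stepwise-selected scores.

    Candidates with |Spearman rho| >= ``spearman_max`` against average
    expression are screened out (multicollinearity guard).  The remaining
    candidates enter/leave by forward-backward search minimizing AIC; base
    covariates are never removed.  The final model is compared to the base
    model by a likelihood-ratio test (chi-square, df = number of added
    scores).  ``scores`` and ``survival`` must be row-aligned by sample_id.
    """
    scores = scores.set_index("sample_id") if "sample_id" in scores.columns else scores
    surv = survival.set_index("sample_id") if "sample_id" in survival.columns else survival
    scores = scores.loc[surv.index]
    audit: list[str] = []

    screened = []
    candidates = []
    avg = surv["avg_expression"].to_numpy(dtype=float)
    for name in scores.columns:
        col = scores[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)) or np.std(col) == 0:
            screened.append(name)
            audit.append(f"{name}: dropped (missing or constant)")
            continue
        rho = spearmanr(col, avg).statistic
        if np.isfinite(rho) and abs(rho) >= spearman_max:
            screened.append(name)
            audit.append(f"{name}: screened out (|Spearman|={abs(rho):.3f} vs avg_expression)")
        else:
            candidates.append(name)

    design = _build_design(surv.reset_index(), base_covariates)
    design.index = surv.index
    base_df = pd.concat([design, surv[["os_time", "os_event"]]], axis=1)
    base_fit = _fit_cox(base_df)
    base_ll = float(base_fit.log_likelihood_)
    base_aic = float(base_fit.AIC_partial_)

    def fit_with(selected: list[str]) -> tuple[float, float] | None:
        df = pd.concat(
            [design, scores[selected].astype(float), surv[["os_time", "os_event"]]],
            axis=1,
        )
        try:
            fit = _fit_cox(df)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            audit.append(f"fit {selected}: skipped ({type(exc).__name__})")
            return None
        return float(fit.log_likelihood_), float(fit.AIC_partial_)

    selected: list[str] = []
    current_aic = base_aic
    current_ll = base_ll
    for _ in range(max_steps):
        best: tuple[float, float, list[str]] | None = None
        for cand in candidates:
            if cand in selected:
                continue
            res = fit_with(selected + [cand])
            if res and res[1] < (best[0] if best else current_aic) - 1e-9:
                best = (res[1], res[0], selected + [cand])
        for cand in selected:
            trial = [c for c in selected if c != cand]
            res = fit_with(trial) if trial else (base_ll, base_aic)
            if res and res[1] < (best[0] if best else current_aic) - 1e-9:
                best = (res[1], res[0], trial)
        if best is None:
            break
        current_aic, current_ll, selected = best[0], best[1], best[2]
    lr_df = len(selected)
    lr_stat = max(0.0, 2.0 * (current_ll - base_ll))
    lr_p = float(chi2.sf(lr_stat, lr_df)) if lr_df > 0 else 1.0
    return StepwiseCoxResult(
        base_covariates=tuple(design.columns),
        selected_scores=tuple(selected),
        screened_out=tuple(screened),
        base_loglik=base_ll,
        final_loglik=current_ll,
        final_aic=current_aic,
        lr_stat=lr_stat,
        lr_df=lr_df,
        lr_p=lr_p,
        audit=tuple(audit),
    )


# ---------------------------------------------------------------------------
# quantile stratification


@dataclass(frozen=True)
class StratificationResult:
    """Quantile-cutoff stratification of one score against survival."""

    cutoffs: pd.DataFrame  #: per candidate cutoff: quantile, value, stat, p, n_high
    best_cutoff: float
    best_quantile: float
    best_p: float
    labels: np.ndarray  #: True = score >= best cutoff ("high")
    median_survival: dict[str, float]

    @property
    def ok(self) -> bool:
        return np.isfinite(self.best_cutoff)


def quantile_stratify(
    score: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
) -> StratificationResult:
    """Test each score quantile as a high/low cutoff; keep the best logrank p.

    Cutoffs that leave one group empty are skipped.  When no cutoff is
    valid (e.g. a constant score), the result is flagged with NaN cutoff.
    """
    score = np.asarray(score, dtype=float)
    rows = []
    for q in quantiles:
        cut = float(np.quantile(score, q))
        high = score >= cut
        if high.all() or not high.any():
            continue
        stat, p = logrank_statistic(time, event, high)
        rows.append({"quantile": q, "cutoff": cut, "statistic": stat,
                     "p": p, "n_high": int(high.sum())})
    table = pd.DataFrame(rows, columns=["quantile", "cutoff", "statistic", "p", "n_high"])
    if table.empty:
        return StratificationResult(
            cutoffs=table, best_cutoff=float("nan"), best_quantile=float("nan"),
            best_p=float("nan"), labels=np.zeros(len(score), dtype=bool),
            median_survival={},
        )
    ibest = int(table["p"].idxmin())
    best_cut = float(table.loc[ibest, "cutoff"])
    labels = score >= best_cut
    medians = {}
    for name, mask in (("high", labels), ("low", ~labels)):
        km = KaplanMeierFitter()
        km.fit(time[mask], event[mask])
        medians[name] = float(km.median_survival_time_)
    return StratificationResult(
        cutoffs=table,
        best_cutoff=best_cut,
        best_quantile=float(table.loc[ibest, "quantile"]),
        best_p=float(table.loc[ibest, "p"]),
        labels=labels,
        median_survival=medians,
    )


# ---------------------------------------------------------------------------
# repeated cross-validation with permutation null


@dataclass(frozen=True)
class CvPermutationResult:
    n_repeats: int
    k: int
    m: int
    statistics: np.ndarray  #: per-repeat pooled logrank statistic
    p_values: np.ndarray  #: per-repeat empirical p, each in [1/(m+1), 1]

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))


def _make_folds(
    n: int, k: int, event: np.ndarray, rng: np.random.Generator, max_retries: int = 100
) -> list[np.ndarray]:
    """Random k-fold partition; redrawn until every training set has events."""
    for _ in range(max_retries):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        ok = all(
            event[np.concatenate([f for j, f in enumerate(folds) if j != i])].sum() >= 2
            and len(folds[i]) >= 1
            for i in range(k)
        )
        if ok:
            return folds
    raise RuntimeError("could not draw a fold partition with events in every training set")


@dataclass(frozen=True)
class _FoldPlan:
    """Permutation-invariant per-fold precomputation for the CV statistic.

    Candidate cutoffs are quantiles of the training-fold scores, so they —
    and the induced train/test group labels — do not depend on the survival
    data and can be shared across all permutations of (time, event).
    """

    train_idx: np.ndarray
    test_idx: np.ndarray
    train_groups: list[np.ndarray]  #: float 0/1 per candidate cutoff
    test_labels: list[np.ndarray]  #: bool per candidate cutoff


def _plan_folds(
    score: np.ndarray, folds: list[np.ndarray], quantiles: tuple[float, ...]
) -> list[_FoldPlan]:
    plans = []
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        s_train, s_test = score[train_idx], score[test_idx]
        groups, labels = [], []
        for q in quantiles:
            cut = float(np.quantile(s_train, q))
            high = s_train >= cut
            if high.all() or not high.any():
                continue
            groups.append(high.astype(float))
            labels.append(s_test >= cut)
        if not groups:  # no quantile splits the training scores: fall back to median
            cut = float(np.quantile(s_train, 0.5))
            groups.append((s_train >= cut).astype(float))
            labels.append(s_test >= cut)
        plans.append(_FoldPlan(train_idx, test_idx, groups, labels))
    return plans


def _cv_statistic(
    time: np.ndarray, event: np.ndarray, plans: list[_FoldPlan]
) -> float:
    """Pooled test-fold logrank statistic with train-fold cutoff optimization.

    Per fold, the candidate with the best (largest chi-square, equivalently
    smallest p) training logrank labels the held-out samples.
    """
    n = len(time)
    labels = np.zeros(n, dtype=bool)
    for plan in plans:
        t_train, e_train = time[plan.train_idx], event[plan.train_idx]
        order = np.argsort(t_train, kind="stable")
        ts, es = t_train[order], e_train[order]
        best_stat, best = -1.0, 0
        for c, group in enumerate(plan.train_groups):
            stat = _logrank_stat_sorted(ts, es, group[order])
            if stat > best_stat:
                best_stat, best = stat, c
        labels[plan.test_idx] = plan.test_labels[best]
    stat, _ = logrank_statistic(time, event, labels)
    return stat


def repeated_cv_permutation(
    score: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_repeats: int = 20,
    k: int = 10,
    m: int = 1000,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
    seed: int = 0,
) -> CvPermutationResult:
    """Repeated k-fold CV stratification with a permutation-based empirical p.

    Per repeat: a random k-fold partition; for each fold the cutoff with the
    best training-fold logrank p (among the score quantiles recomputed on
    training data) labels the held-out samples high/low; pooled labels give
    one logrank statistic.  The identical procedure applied to ``m`` joint
    permutations of (time, event) forms the null distribution, and

        empirical p = (1 + #{null >= observed}) / (m + 1),

    so p is never 0.  All randomness flows from ``seed``.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n = len(score)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_repeats)
    pvals = np.empty(n_repeats)
    for rep in range(n_repeats):
        folds = _make_folds(n, k, event, rng)
        plans = _plan_folds(score, folds, quantiles)
        obs = _cv_statistic(time, event, plans)
        null = np.empty(m)
        for j in range(m):
            perm = rng.permutation(n)
            null[j] = _cv_statistic(time[perm], event[perm], plans)
        stats[rep] = obs
        pvals[rep] = (1.0 + np.sum(null >= obs)) / (m + 1.0)
    return CvPermutationResult(
        n_repeats=n_repeats, k=k, m=m, statistics=stats, p_values=pvals
    )


# ---------------------------------------------------------------------------
# bivariate grouping and KM export


def bivariate_group(
    score: np.ndarray,
    avg_expression: np.ndarray,
    score_cutoff: float,
    avg_cutoff: float,
    time: np.ndarray,
    event: np.ndarray,
) -> pd.DataFrame:
    """Four groups from high/low score x high/low average expression.

    Returns one row per group (including empty ones) with size and
    Kaplan-Meier median survival.  "High" means value >= cutoff.
    """
    score = np.asarray(score, dtype=float)
    avg = np.asarray(avg_expression, dtype=float)
    s_high = score >= score_cutoff
    a_high = avg >= avg_cutoff
    if s_high.all() or not s_high.any() or a_high.all() or not a_high.any():
        warnings.warn("one feature does not split: fewer than 4 nonempty groups",
                      stacklevel=2)
    rows = []
    for s_lab, s_mask in (("low", ~s_high), ("high", s_high)):
        for a_lab, a_mask in (("low", ~a_high), ("high", a_high)):
            mask = s_mask & a_mask
            if mask.sum() == 0:
                rows.append({"score": s_lab, "avg_expression": a_lab,
                             "n": 0, "median_survival": float("nan")})
                continue
            km = KaplanMeierFitter()
            km.fit(time[mask], event[mask])
            rows.append({"score": s_lab, "avg_expression": a_lab,
                         "n": int(mask.sum()),
                         "median_survival": float(km.median_survival_time_)})
    return pd.DataFrame(rows)


def km_curves(
    time: np.ndarray, event: np.ndarray, labels: np.ndarray,
    names: tuple[str, str] = ("low", "high"),
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier survival curves for a binary grouping (label True = high)."""
    labels = np.asarray(labels, dtype=bool)
    out = {}
    for name, mask in ((names[0], ~labels), (names[1], labels)):
        if mask.sum() == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(time[mask], event[mask], label=name)
        sf = km.survival_function_
        out[name] = pd.DataFrame({"time": sf.index.to_numpy(),
                                  "survival": sf[name].to_numpy()})
    return out
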