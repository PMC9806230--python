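"""Score-battery reduction: correlation pruning and Cox-lasso stability selection.

The full battery (16 co-occurrence + 37 tessellation scores) is highly
redundant.  Two stages reduce it:

1. *Correlation pruning* — scores are ranked by their univariate Cox p-value
   against overall survival and accepted greedily; a candidate is rejected
   when its absolute Pearson correlation with an already-accepted score
   exceeds 0.9.  Within a correlated set this keeps exactly the score with
   the best survival association.

2. *Stability selection* — B subsamples (without replacement, half the
   cohort each) are fitted with an L1-penalized Cox model over a fixed
   penalty path; a score counts as selected in a subsample if it is active
   anywhere on the path before more than q features have entered (the
   per-family error control of stability selection).  Scores selected in at
   least ``freq_min`` (default 20%) of subsamples are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .survival import univariate_cox

__all__ = [
    "PruneResult",
    "SelectionResult",
    "clean_score_table",
    "prune_correlated",
    "stability_select",
    "select_scores",
]


@dataclass(frozen=True)
class PruneResult:
    kept: tuple[str, ...]
    cox_p: pd.Series  #: univariate Cox p per score (input order)
    displaced_by: dict[str, str]  #: rejected score -> accepted score that displaced it
    dropped: tuple[str, ...]  #: constant / unusable columns


@dataclass(frozen=True)
class SelectionResult:
    kept: tuple[str, ...]
    frequency: pd.Series  #: selection frequency in [0, 1] per score
    cox_p: pd.Series
    freq_min: float
    audit: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"frequency": self.frequency, "cox_p": self.cox_p})
        df["kept"] = df.index.isin(self.kept)
        return df


def clean_score_table(
    scores: pd.DataFrame, max_missing: float = 0.2
) -> tuple[pd.DataFrame, list[str]]:
    """Drop over-missing columns, median-impute the rest; returns audit log."""
    audit = []
    out = {}
    for name in scores.columns:
        col = scores[name].to_numpy(dtype=float)
        n_missing = int(np.sum(~np.isfinite(col)))
        if n_missing > max_missing * len(col):
            audit.append(f"{name}: dropped ({n_missing}/{len(col)} missing)")
            continue
        if n_missing:
            med = np.nanmedian(np.where(np.isfinite(col), col, np.nan))
            col = np.where(np.isfinite(col), col, med)
            audit.append(f"{name}: median-imputed {n_missing} values")
        out[name] = col
    return pd.DataFrame(out, index=scores.index), audit


def prune_correlated(
    scores: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    r_max: float = 0.9,
) -> PruneResult:
    """Greedy correlation pruning keeping the best survival association.

    Scores are ordered by (univariate Cox p, name) — the name tiebreak makes
    the kept set independent of column order — and accepted unless their
    absolute Pearson correlation with an accepted score exceeds ``r_max``.
    Constant columns are excluded with a warning (correlation undefined).
    """
    pvals = {}
    dropped = []
    for name in scores.columns:
        col = scores[name].to_numpy(dtype=float)
        if np.std(col) == 0 or not np.all(np.isfinite(col)):
            dropped.append(name)
            warnings.warn(f"score {name}: constant or non-finite, excluded from pruning",
                          stacklevel=2)
            continue
        res = univariate_cox(col, time, event)
        pvals[name] = res.p if res.ok else 1.0
    order = sorted(pvals, key=lambda name: (pvals[name], name))
    kept: list[str] = []
    displaced: dict[str, str] = {}
    for name in order:
        col = scores[name].to_numpy(dtype=float)
        blocker = None
        for acc in kept:
            r = np.corrcoef(col, scores[acc].to_numpy(dtype=float))[0, 1]
            if abs(r) > r_max:
                blocker = acc
                break
        if blocker is None:
            kept.append(name)
        else:
            displaced[name] = blocker
    return PruneResult(
        kept=tuple(kept),
        cox_p=pd.Series(pvals).reindex(scores.columns),
        displaced_by=displaced,
        dropped=tuple(dropped),
    )


def _path_selection(coefs: np.ndarray, q: int) -> np.ndarray:
    """Features active on the penalty path before more than q have entered.

    ``coefs`` is (p, n_alphas) with alphas in decreasing order of penalty.
    """
    active = np.abs(coefs) > 0
    counts = active.sum(axis=0)
    within = counts <= q
    if not within.any():
        return active[:, 0]
    # union of active sets over the admissible (least-penalized last) prefix
    last = int(np.max(np.flatnonzero(within)))
    return active[:, : last + 1].any(axis=1)


def stability_select(
    scores: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    freq_min: float = 0.20,
    B: int = 100,
    fraction: float = 0.5,
    n_alphas: int = 25,
    q: int | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Cox-lasso stability selection over B half-cohort subsamples.

    Keeps scores whose selection frequency is at least ``freq_min``.  The
    active-set cap ``q`` defaults to ceil(sqrt(p)).  Subsamples with fewer
    than 2 events are redrawn (bounded retries).  Reproducible via ``seed``.
    """
    names = list(scores.columns)
    X = scores.to_numpy(dtype=float)
    n, p = X.shape
    if p == 0:
        raise ValueError("no scores to select from")
    q = q if q is not None else int(np.ceil(np.sqrt(p)))
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    y_full = Surv.from_arrays(event=event, time=time)
    base = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=0.01)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base.fit(Xz, y_full)
    alphas = base.alphas_
    audit = [f"penalty path: {len(alphas)} alphas in [{alphas.min():.4g}, {alphas.max():.4g}]",
             f"active-set cap q={q}"]
    rng = np.random.default_rng(seed)
    size = int(np.ceil(fraction * n))
    counts = np.zeros(p)
    n_done = 0
    for _ in range(B):
        for _retry in range(50):
            idx = rng.choice(n, size=size, replace=False)
            if event[idx].sum() >= 2:
                break
        else:
            audit.append("subsample skipped: could not draw >= 2 events")
            continue
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xz[idx], Surv.from_arrays(event=event[idx], time=time[idx]))
        except (ValueError, ArithmeticError) as exc:
            audit.append(f"subsample fit failed: {exc}")
            continue
        counts += _path_selection(model.coef_, q)
        n_done += 1
    if n_done == 0:
        raise RuntimeError("all stability-selection subsample fits failed")
    freq = pd.Series(counts / n_done, index=names)
    pvals = pd.Series(
        {name: univariate_cox(scores[name].to_numpy(dtype=float), time, event).p
         for name in names}
    )
    kept = tuple(freq.index[freq >= freq_min])
    return SelectionResult(kept=kept, frequency=freq, cox_p=pvals,
                           freq_min=freq_min, audit=tuple(audit))


def select_scores(
    scores: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    r_max: float = 0.9,
    freq_min: float = 0.20,
    B: int = 100,
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[PruneResult, SelectionResult]:
    """Full reduction: clean, prune correlated, then stability-select."""
    cleaned, audit = clean_score_table(scores)
    prune = prune_correlated(cleaned, time, event, r_max=r_max)
    sel = stability_select(
        cleaned[list(prune.kept)], time, event,
        freq_min=freq_min, B=B, fraction=fraction, seed=seed,
    )
    return prune, SelectionResult(
        kept=sel.kept, frequency=sel.frequency, cox_p=sel.cox_p,
        freq_min=sel.freq_min, audit=tuple(audit) + sel.audit,
    )
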