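"""End-to-end driver: cohort manifest -> score table -> selection -> survival.

The pipeline ties the scoring modules together for whole-cohort runs.  Its
defaults are the study parameters: neighborhood radii 10/25/50/75 µm, 250 µm
tiles shifted by 25 µm, at least 5 cells per tile, OD thresholds
8/10/15/20/25, entropy threshold 0.61, stability-selection frequency 0.20,
and a 20 x 10 repeated cross-validation with 1000 permutations.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cooccurrence, tessellation
from .data import CellTable, read_cell_table, read_manifest, validate_survival_table
from .selection import PruneResult, SelectionResult, select_scores
from .survival import (
    CvPermutationResult,
    StepwiseCoxResult,
    StratificationResult,
    bivariate_group,
    km_curves,
    multiple_cox_stepwise,
    quantile_stratify,
    repeated_cv_permutation,
    univariate_cox,
)

__all__ = ["RunConfig", "compute_sample_scores", "run_scores", "run_survival",
           "SurvivalReport"]

logger = logging.getLogger("spathet")

N_COOCCURRENCE_SCORES = 16
N_TESSELLATION_SCORES = 37


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters; defaults are the study values."""

    radii: tuple[float, ...] = cooccurrence.DEFAULT_RADII
    tile_size: float = tessellation.DEFAULT_TILE_SIZE
    shift: float = tessellation.DEFAULT_SHIFT
    min_cells: int = tessellation.DEFAULT_MIN_CELLS
    od_thresholds: tuple[float, ...] = tessellation.DEFAULT_OD_THRESHOLDS
    entropy_threshold: float = tessellation.ENTROPY_THRESHOLD
    r_max: float = 0.9
    freq_min: float = 0.20
    stability_B: int = 100
    stability_fraction: float = 0.5
    cv_n: int = 20
    cv_k: int = 10
    cv_m: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for key in ("radii", "od_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["radii"] = list(data["radii"])
        data["od_thresholds"] = list(data["od_thresholds"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def compute_sample_scores(cells: CellTable, config: RunConfig = RunConfig()) -> dict[str, float]:
    """The full 53-score battery (16 co-occurrence + 37 tessellation) for one sample."""
    scores = cooccurrence.cooccurrence_scores(cells, radii=config.radii)
    scores.update(
        tessellation.tessellation_scores(
            cells,
            od_thresholds=config.od_thresholds,
            tile_size=config.tile_size,
            shift=config.shift,
            min_cells=config.min_cells,
            entropy_threshold=config.entropy_threshold,
            seed=config.seed,
        )
    )
    return scores


def run_scores(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Score every sample of a cohort manifest; failures yield NaN rows.

    ``manifest`` maps sample_id -> cell-table path (or is a path to such a
    CSV).  A failing sample is logged and reported as a row of NaN; it never
    aborts the cohort.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    rows = {}
    columns: list[str] | None = None
    for _, rec in manifest.iterrows():
        sid = str(rec["sample_id"])
        try:
            cells = read_cell_table(rec["path"], sample_id=sid)
            rows[sid] = compute_sample_scores(cells, config)
            columns = columns or list(rows[sid])
            logger.info("scored sample %s (%d cells)", sid, cells.n_cells)
        except Exception as exc:  # isolate per-sample failures
            logger.error("sample %s failed: %s", sid, exc)
            rows[sid] = {}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(index=list(rows))  # failed samples become NaN rows
    if columns:
        table = table.reindex(columns=columns)
    table.index.name = "sample_id"
    return table


@dataclass(frozen=True)
class SurvivalReport:
    """Bundle of every survival-analysis output for one cohort."""

    prune: PruneResult
    selection: SelectionResult
    univariate: pd.DataFrame  #: per kept score: HR per SD, p, CI
    stepwise: StepwiseCoxResult | None
    stratification: dict[str, StratificationResult]
    cv: dict[str, CvPermutationResult]
    bivariate: dict[str, pd.DataFrame]


def run_survival(
    scores: pd.DataFrame,
    survival: pd.DataFrame,
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
    run_cv: bool = True,
) -> SurvivalReport:
    """Selection, Cox analysis, stratification and CV-permutation for a cohort.

    ``scores`` is samples x scores (index or column sample_id); ``survival``
    the clinical table.  Rows are joined on sample_id; unjoinable ids raise.
    Writes CSV reports and Kaplan-Meier plots when ``outdir`` is given.
    """
    if "sample_id" in scores.columns:
        scores = scores.set_index("sample_id")
    survival = validate_survival_table(survival).set_index("sample_id")
    missing = sorted(set(scores.index) ^ set(survival.index))
    if missing:
        raise ValueError(f"sample ids not present in both tables: {missing}")
    survival = survival.loc[scores.index]
    time = survival["os_time"].to_numpy(dtype=float)
    event = survival["os_event"].to_numpy(dtype=float)

    prune, selection = select_scores(
        scores, time, event,
        r_max=config.r_max, freq_min=config.freq_min,
        B=config.stability_B, fraction=config.stability_fraction,
        seed=config.seed,
    )
    kept = list(selection.kept)

    uni_rows = []
    for name in kept:
        res = univariate_cox(scores[name].to_numpy(dtype=float), time, event)
        uni_rows.append({"score": name, "hr_per_sd": res.hr, "p": res.p,
                         "ci_low": res.ci_low, "ci_high": res.ci_high, "ok": res.ok})
    univariate = pd.DataFrame(uni_rows)

    stepwise = None
    if kept and "avg_expression" in survival.columns:
        stepwise = multiple_cox_stepwise(scores[kept].reset_index(),
                                         survival.reset_index())

    stratification: dict[str, StratificationResult] = {}
    cv: dict[str, CvPermutationResult] = {}
    bivar: dict[str, pd.DataFrame] = {}
    for name in kept:
        vals = scores[name].to_numpy(dtype=float)
        strat = quantile_stratify(vals, time, event)
        stratification[name] = strat
        if run_cv:
            cv[name] = repeated_cv_permutation(
                vals, time, event,
                n_repeats=config.cv_n, k=config.cv_k, m=config.cv_m,
                seed=config.seed,
            )
        if strat.ok and "avg_expression" in survival.columns:
            avg = survival["avg_expression"].to_numpy(dtype=float)
            avg_strat = quantile_stratify(avg, time, event)
            if avg_strat.ok:
                bivar[name] = bivariate_group(
                    vals, avg, strat.best_cutoff, avg_strat.best_cutoff, time, event
                )

    report = SurvivalReport(
        prune=prune, selection=selection, univariate=univariate,
        stepwise=stepwise, stratification=stratification, cv=cv, bivariate=bivar,
    )
    if outdir is not None:
        _write_report(report, survival, scores, config, Path(outdir))
    return report


def _write_report(report: SurvivalReport, survival: pd.DataFrame,
                  scores: pd.DataFrame, config: RunConfig, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report.selection.to_frame().to_csv(outdir / "selection.csv")
    report.univariate.to_csv(outdir / "univariate_cox.csv", index=False)
    time = survival["os_time"].to_numpy(dtype=float)
    event = survival["os_event"].to_numpy(dtype=float)
    strat_rows = []
    for name, strat in report.stratification.items():
        if not strat.ok:
            continue
        strat_rows.append({"score": name, "cutoff": strat.best_cutoff,
                           "quantile": strat.best_quantile, "logrank_p": strat.best_p})
        curves = km_curves(time, event, strat.labels)
        fig, ax = plt.subplots(figsize=(5, 4))
        for label, curve in curves.items():
            ax.step(curve["time"], curve["survival"], where="post", label=label)
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
        ax.set_title(f"{name} (cutoff {strat.best_cutoff:.3g}, p={strat.best_p:.3g})")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / f"km_{name}.png", dpi=120)
        plt.close(fig)
    pd.DataFrame(strat_rows).to_csv(outdir / "stratification.csv", index=False)
    if report.cv:
        pd.DataFrame(
            [{"score": k, "median_p": v.median_p,
              **{f"p_rep{i}": p for i, p in enumerate(v.p_values)}}
             for k, v in report.cv.items()]
        ).to_csv(outdir / "cv_permutation.csv", index=False)
    if report.stepwise is not None:
        pd.Series({
            "selected_scores": ";".join(report.stepwise.selected_scores),
            "lr_stat": report.stepwise.lr_stat,
            "lr_df": report.stepwise.lr_df,
            "lr_p": report.stepwise.lr_p,
        }).to_csv(outdir / "stepwise_lr.csv", header=False)
    for name, table in report.bivariate.items():
        table.to_csv(outdir / f"bivariate_{name}.csv", index=False)
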