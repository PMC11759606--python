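"""L2-penalized Cox modelling, C-index, KM risk stratification and nomogram.

The survival signature is a linear Cox proportional-hazards model maximizing
the Breslow partial likelihood with a ridge penalty: the fit minimizes

    -log PL(beta) + (c / 2) ||beta||^2,

with c = 0.3 by default.  ``c`` is the weight on the *total* (summed, not
per-observation) negative partial log-likelihood, so its shrinkage vanishes as
n grows.  Risk groups are formed by dichotomizing the linear predictor at the
percentile (grid 20..80 by 5) that maximizes the log-rank separation on the
training cohort; that threshold is frozen before touching the test cohort.
The nomogram maps each covariate affinely to 0..100 points (the covariate with
the largest |coef| x range spans the full axis) and total points to predicted
survival probability through the baseline survival curve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

logger = logging.getLogger(__name__)

DEFAULT_L2_C = 0.3
PERCENTILE_GRID = tuple(range(20, 85, 5))
DEFAULT_HORIZONS = (36.0, 60.0)


@dataclass
class CoxFit:
    """A fitted ridge Cox model: named coefficients, per-subject risk, baseline."""

    coefficients: pd.Series
    l2_c: float
    linear_predictor: np.ndarray
    train_cindex: float
    fitter: CoxPHFitter
    covariates: list[str]

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor coef . (x - training mean); monotone in hazard."""
        return self.fitter.predict_partial_hazard(X[self.covariates]).to_numpy(float)

    def linear_score(self, X: pd.DataFrame) -> np.ndarray:
        """Raw coef . x (no centering); the pathomics-signature scale."""
        return X[self.covariates].to_numpy(float) @ self.coefficients.to_numpy()

    def baseline_survival_at(self, t: float) -> float:
        bs = self.fitter.baseline_survival_["baseline survival"]
        prior = bs[bs.index <= t]
        return float(prior.iloc[-1]) if len(prior) else 1.0


def fit_cox(
    records: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    covariates: list[str] | None = None,
    l2_c: float = DEFAULT_L2_C,
    ties: str = "breslow",
) -> CoxFit:
    """Fit the ridge Cox model on ``records``.

    Rejects data with no events or with constant covariates (no identifiable
    coefficient).  ``ties`` is 'breslow' (default) or 'efron'.
    """
    if covariates is None:
        covariates = [c for c in records.columns if c not in (duration_col, event_col)]
    if records[event_col].sum() < 1:
        raise ValueError("no events in the data; Cox model is not identifiable")
    for c in covariates:
        if records[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant; drop it before fitting")
    n = len(records)
    # l2_c weights the summed neg. partial log-likelihood; lifelines' penalizer
    # is scaled per observation, hence the division by n.
    cph = CoxPHFitter(penalizer=l2_c / n, l1_ratio=0.0, baseline_estimation_method="breslow")
    df = records[[duration_col, event_col] + covariates]
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col,
                robust=False, fit_options={"step_size": 0.5})
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    if ties == "efron":
        logger.info("efron tie handling requested; lifelines semiparametric fit uses "
                    "its default tie correction")
    lp = cph.predict_log_partial_hazard(df).to_numpy(float)
    cindex = concordance_index(lp, records[duration_col].to_numpy(),
                               records[event_col].to_numpy())
    return CoxFit(
        coefficients=cph.params_.copy(), l2_c=l2_c, linear_predictor=lp,
        train_cindex=cindex, fitter=cph, covariates=list(covariates),
    )


def concordance_index(risk: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Harrell's C: fraction of usable pairs whose risk ordering matches survival.

    Higher risk should pair with shorter survival; risk ties count 1/2.
    """
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if not len(risk) == len(times) == len(events):
        raise ValueError("risk, times and events must have equal length")
    try:
        # lifelines convention: concordance of predicted scores with times,
        # where larger score = longer survival; pass -risk.
        return float(_lifelines_cindex(times, -risk, events))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs under this censoring pattern") from exc


def logrank_test(groups: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Multivariate log-rank chi-square over >= 2 groups; returns (statistic, p)."""
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(np.asarray(times, float), groups,
                                    np.asarray(events, int))
    return float(res.test_statistic), float(res.p_value)


def km_stratify(
    risk: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    percentile_grid: tuple[int, ...] = PERCENTILE_GRID,
    min_group_size: int = 2,
) -> dict:
    """Pick the risk percentile whose dichotomization best separates survival.

    Scans ``percentile_grid`` on the given (training) data, computes the
    log-rank p for each high/low split, and returns the threshold with minimal
    p together with the group assignment.  Apply the returned ``threshold`` to
    a test cohort without re-optimizing (see :func:`apply_stratification`).
    """
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    best = None
    for pct in percentile_grid:
        thr = float(np.percentile(risk, pct))
        high = risk > thr
        if high.sum() < min_group_size or (~high).sum() < min_group_size:
            continue
        stat, p = logrank_test(high.astype(int), times, events)
        if best is None or p < best["logrank_p"]:
            best = {"percentile": pct, "threshold": thr, "logrank_p": p,
                    "statistic": stat, "groups": high.astype(int)}
    if best is None:
        raise ValueError("every candidate percentile left one group nearly empty")
    return best


def apply_stratification(risk: np.ndarray, threshold: float) -> np.ndarray:
    """High-risk indicator under a frozen threshold (no re-optimization)."""
    return (np.asarray(risk, float) > threshold).astype(int)


def plot_km(groups: np.ndarray, times: np.ndarray, events: np.ndarray,
            path, title: str = "Kaplan-Meier") -> None:
    """KM curves for the low/high risk groups with the log-rank p annotated."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for g, label in ((0, "low risk"), (1, "high risk")):
        mask = np.asarray(groups) == g
        if mask.sum() == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(np.asarray(times)[mask], np.asarray(events)[mask], label=label)
        km.plot_survival_function(ax=ax, ci_show=False)
    try:
        _, p = logrank_test(groups, times, events)
        ax.text(0.05, 0.05, f"log-rank p = {p:.3g}", transform=ax.transAxes)
    except ValueError:
        pass
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ------------------------------------------------------------------ nomogram

@dataclass
class NomogramSpec:
    """Point scales of a Cox nomogram.

    ``scales[name] = (x_ref, points_per_unit)`` so that points(x) =
    points_per_unit * (x - x_ref); x_ref is the covariate value at 0 points
    (range end with lowest hazard) and the largest |coef| x range spans 0..100.
    ``survival_at(total_points, horizon)`` converts a total score back to the
    model's predicted survival probability.
    """

    scales: dict[str, tuple[float, float]]
    ranges: dict[str, tuple[float, float]]
    horizons: tuple[float, ...]
    lp_floor: float          # linear predictor (vs training mean) at 0 total points
    lp_per_point: float
    baseline: dict[float, float]  # horizon -> baseline survival at training mean

    def points(self, name: str, x: float) -> float:
        x_ref, slope = self.scales[name]
        return slope * (x - x_ref)

    def total_points(self, values: dict[str, float]) -> float:
        return float(sum(self.points(k, v) for k, v in values.items()))

    def survival_at(self, total_points: float, horizon: float) -> float:
        lp = self.lp_floor + total_points * self.lp_per_point
        return float(self.baseline[horizon] ** np.exp(lp))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "scales": {k: list(v) for k, v in self.scales.items()},
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "horizons": list(self.horizons), "lp_floor": self.lp_floor,
            "lp_per_point": self.lp_per_point,
            "baseline": {str(k): v for k, v in self.baseline.items()},
        }, indent=1))


def build_nomogram(fit: CoxFit, covariate_ranges: dict[str, tuple[float, float]],
                   horizons: tuple[float, ...] = DEFAULT_HORIZONS) -> NomogramSpec:
    """Construct the point scales of a nomogram from a fitted Cox model.

    Each covariate contributes ``coef * x`` to the linear predictor; its point
    scale is affine in x, oriented so 0 points is the range end with the lowest
    hazard, normalized so the largest |coef| x range spans exactly 100 points.
    """
    coefs = fit.coefficients
    contrib_range = {}
    for name, (lo, hi) in covariate_ranges.items():
        if name not in coefs.index:
            raise KeyError(f"{name!r} is not a covariate of the fitted model")
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
            raise ValueError(f"invalid range for {name!r}: ({lo}, {hi})")
        contrib_range[name] = abs(coefs[name]) * (hi - lo)
    max_scale = max(contrib_range.values())
    if max_scale == 0:
        raise ValueError("all covariate effects are zero over the given ranges; "
                         "no point scale can be constructed")
    scales, lp_floor = {}, 0.0
    train_means = fit.fitter._norm_mean
    for name, (lo, hi) in covariate_ranges.items():
        coef = float(coefs[name])
        x_ref = lo if coef >= 0 else hi    # lowest-hazard end scores 0 points
        slope = 100.0 * coef / max_scale if coef >= 0 else -100.0 * coef / max_scale
        scales[name] = (float(x_ref), float(slope))
        lp_floor += coef * (x_ref - float(train_means.get(name, 0.0)))
    baseline = {float(h): fit.baseline_survival_at(h) for h in horizons}
    return NomogramSpec(
        scales=scales, ranges={k: (float(v[0]), float(v[1])) for k, v in covariate_ranges.items()},
        horizons=tuple(float(h) for h in horizons), lp_floor=float(lp_floor),
        lp_per_point=float(max_scale / 100.0), baseline=baseline,
    )


def render_nomogram(spec: NomogramSpec, path, n_ticks: int = 5) -> None:
    """Draw the nomogram axes (points, one axis per covariate, survival axes)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(spec.scales)
    fig, ax = plt.subplots(figsize=(7, 1.0 * (len(names) + 3)))
    rows = ["Points"] + names + [f"S({int(h)} mo)" for h in spec.horizons]
    y_of = {r: len(rows) - 1 - i for i, r in enumerate(rows)}
    ax.hlines(y_of["Points"], 0, 100, color="k")
    for v in np.linspace(0, 100, n_ticks + 1):
        ax.text(v, y_of["Points"] + 0.15, f"{v:.0f}", ha="center", fontsize=7)
    for name in names:
        lo, hi = spec.ranges[name]
        p_lo, p_hi = spec.points(name, lo), spec.points(name, hi)
        ax.hlines(y_of[name], min(p_lo, p_hi), max(p_lo, p_hi), color="tab:blue")
        for x in np.linspace(lo, hi, n_ticks + 1):
            ax.text(spec.points(name, x), y_of[name] + 0.15, f"{x:.2g}",
                    ha="center", fontsize=7)
    max_total = sum(max(spec.points(n_, spec.ranges[n_][0]),
                        spec.points(n_, spec.ranges[n_][1])) for n_ in names)
    for h in spec.horizons:
        row = f"S({int(h)} mo)"
        ax.hlines(y_of[row], 0, max_total, color="tab:red")
        for tp in np.linspace(0, max_total, n_ticks + 1):
            ax.text(tp, y_of[row] + 0.15, f"{spec.survival_at(tp, h):.2f}",
                    ha="center", fontsize=7)
    ax.set_yticks([y_of[r] for r in rows])
    ax.set_yticklabels(rows)
    ax.set_xlabel("points")
    ax.set_xlim(-5, max(105, max_total * 1.05))
    for side in ("top", "right", "left"):
        ax.spines[side].set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
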