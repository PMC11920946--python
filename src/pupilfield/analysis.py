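"""Covert-attention statistics on fitted regional weights.

Reads the three drivers of covert attention out of per-participant,
per-condition model fits:

* bottom-up (exogenous): correlation of right-minus-left weight
  differences with right-minus-left saliency (count and magnitude of
  supra-threshold luminance changes);
* top-down (endogenous): attended-minus-unattended side weight contrast
  in the attend-left/attend-right conditions;
* pseudoneglect: the grand right-minus-left weight difference, negative
  when attention is biased leftward.

Also implements behavioural scoring of grating-stop detection, the
gaze-position control analyses, a driver regression with AIC/BIC backward
selection, and the event-related analysis of the model-residual pupil
trace (stop-locked epochs, miss vs correct-rejection contrast).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .model import ConditionExclusionError, PupilResponseResults, fit_condition
from .preprocess import TrialRecord, preprocess_trial
from .regions import EventMatrix, RegionMap, SaliencySummary, summarize_saliency
from .synth import Cohort, ResponseLog, StopSchedule, attended_sides

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeTable",
    "StatResult",
    "TimecourseResult",
    "EpochSet",
    "RegressionResult",
    "classify_stops",
    "score_behavior",
    "side_weights",
    "summarize_cohort",
    "bottom_up_test",
    "top_down_test",
    "pseudoneglect_test",
    "gaze_controls",
    "driver_regression",
    "residualize",
    "residualize_trials",
    "build_epochs",
    "compare_miss_cr",
    "erp_analysis",
    "analyze_cohort",
    "CohortStats",
]


# ---------------------------------------------------------------------------
# Behavioural scoring


@dataclass(frozen=True)
class OutcomeTable:
    """Detection outcomes of one trial (or pooled trials)."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def hit_rate(self) -> float:
        """Hits among all possible responses: hits / (hits + misses + FA)."""
        denom = self.hits + self.misses + self.false_alarms
        return self.hits / denom if denom else np.nan

    def __add__(self, other: "OutcomeTable") -> "OutcomeTable":
        return OutcomeTable(self.hits + other.hits, self.misses + other.misses,
                           self.false_alarms + other.false_alarms,
                           self.correct_rejections + other.correct_rejections)


def classify_stops(
    stops: StopSchedule,
    responses: ResponseLog,
    condition: str,
    window: float = 1.5,
) -> tuple[list[tuple], int]:
    """Assign an outcome to every stop and count false alarms.

    A press within (0, window] seconds of a to-be-attended stop onset is a
    hit; the first press consumes the stop.  Presses matching no attended
    stop are false alarms.  An attended stop without a press is a miss; an
    unattended-side stop is a correct rejection unless some press fell in
    its window (then it carries no usable outcome).

    Returns ``([(stop, outcome), ...], n_false_alarms)`` with outcomes in
    {"hit", "miss", "correct_rejection", "invalid_rejection"}.
    """
    att = attended_sides(condition)
    ordered = sorted(stops.stops, key=lambda s: s.onset)
    consumed = {}
    n_fa = 0
    for press in responses.presses:
        matched = None
        for i, s in enumerate(ordered):
            if (s.side in att and i not in consumed
                    and s.onset < press <= s.onset + window):
                matched = i
                break
        if matched is None:
            n_fa += 1
        else:
            consumed[matched] = press
    out = []
    presses = np.asarray(responses.presses, dtype=float)
    for i, s in enumerate(ordered):
        if s.side in att:
            out.append((s, "hit" if i in consumed else "miss"))
        else:
            in_window = np.any((presses > s.onset) & (presses <= s.onset + window))
            out.append((s, "invalid_rejection" if in_window
                        else "correct_rejection"))
    return out, n_fa


def score_behavior(
    stops: StopSchedule,
    responses: ResponseLog,
    condition: str,
    window: float = 1.5,
) -> OutcomeTable:
    """Score one trial's presses against its stop schedule."""
    if condition == "none":
        if responses.presses:
            logger.warning("presses recorded in passive-viewing trial %s; "
                           "scoring as zeros", stops.trial)
        return OutcomeTable(0, 0, 0, 0)
    outcomes, n_fa = classify_stops(stops, responses, condition, window=window)
    labels = [o for _, o in outcomes]
    return OutcomeTable(hits=labels.count("hit"), misses=labels.count("miss"),
                        false_alarms=n_fa,
                        correct_rejections=labels.count("correct_rejection"))


# ---------------------------------------------------------------------------
# Side summaries


@dataclass(frozen=True)
class StatResult:
    """A scalar test result (one-sample t, paired t or Pearson r)."""

    name: str
    estimate: float
    stat: float
    df: float
    p: float
    n: int
    cohen_d: Optional[float] = None

    def __str__(self) -> str:
        d = f", d = {self.cohen_d:.2f}" if self.cohen_d is not None else ""
        return (f"{self.name}: estimate = {self.estimate:.4g}, "
                f"stat = {self.stat:.3f}, df = {self.df:g}, p = {self.p:.4g}{d}")


def side_weights(fit: PupilResponseResults, region_map: RegionMap) -> dict:
    """Per-side mean weights and their right-minus-left difference."""
    left, right = fit.side_means(region_map)
    if np.isnan(left) or np.isnan(right):
        raise ValueError("region map has no lateral regions")
    return {"weight_left": left, "weight_right": right, "dw": right - left}


def _pool_saliency(trials: Sequence[TrialRecord], region_map: RegionMap,
                   threshold: float) -> SaliencySummary:
    mats = [t.events for t in trials if t.events is not None]
    if not mats:
        raise ValueError("no trial carries an EventMatrix")
    values = np.vstack([m.values for m in mats])
    missing = np.concatenate([m.missing for m in mats])
    pooled = EventMatrix(times=np.arange(values.shape[0], dtype=float),
                         values=values, region_ids=mats[0].region_ids,
                         missing=missing, rate=mats[0].rate)
    return summarize_saliency(pooled, region_map, threshold=threshold)


def summarize_cohort(
    cohort: Cohort,
    preprocess: bool = True,
    saliency_threshold: float = 5.0,
    train_frac: float = 0.7,
) -> pd.DataFrame:
    """One row per participant x condition: side weights, saliency and gaze.

    Trials go through the standard preprocessing pipeline (a no-op
    resample for movie-rate simulations), one weight vector is fitted per
    cell, and the row records the side-mean weights, their difference
    ``dw = right - left``, the right-minus-left saliency differences, the
    mean horizontal gaze, the held-out fit quality, and the pooled
    behavioural outcome of the cell.  Cells with fewer than two surviving
    trials are skipped with a log entry.
    """
    kernels = cohort.kernels()
    rows = []
    for part, cell in cohort.cells():
        trials = cell.trials
        if preprocess:
            trials = [preprocess_trial(t) for t in trials]
            trials = [t for t in trials if t.keep]
        try:
            fit = fit_condition(trials, kernels=kernels, train_frac=train_frac)
        except (ConditionExclusionError, ValueError) as exc:
            logger.info("cell %s/%s excluded: %s", part.participant,
                        cell.condition, exc)
            continue
        row = {"participant": part.participant, "condition": cell.condition,
               "mirrored": part.mirrored, "r2": fit.r2, "rmse": fit.rmse,
               "n_trials": len(trials)}
        row.update(side_weights(fit, cohort.region_map))
        sal = _pool_saliency(trials, cohort.region_map, saliency_threshold)
        row["n_diff"] = sal.n_diff
        row["amp_diff"] = sal.amp_diff
        gx = np.concatenate([t.samples.gaze_x[t.samples.valid] for t in trials])
        row["gaze_x_mean"] = float(gx.mean())
        table = OutcomeTable(0, 0, 0, 0)
        for t in trials:
            if t.stops is not None and t.responses is not None:
                table = table + score_behavior(t.stops, t.responses, t.condition)
        row["hits"] = table.hits
        row["misses"] = table.misses
        row["false_alarms"] = table.false_alarms
        row["correct_rejections"] = table.correct_rejections
        row["hit_rate"] = table.hit_rate
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Driver tests


def _one_sample(name: str, x: np.ndarray) -> StatResult:
    x = np.asarray(x, dtype=float)
    t, p = stats.ttest_1samp(x, 0.0)
    sd = x.std(ddof=1)
    d = float(x.mean() / sd) if sd > 0 else 0.0
    if sd == 0:
        t, p = 0.0, 1.0
    return StatResult(name=name, estimate=float(x.mean()), stat=float(t),
                      df=x.size - 1, p=float(p), n=x.size, cohen_d=d)


def _pearson(name: str, x: np.ndarray, y: np.ndarray) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError(f"{name}: zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return StatResult(name=name, estimate=float(r), stat=float(r),
                      df=x.size - 2, p=float(p), n=x.size)


def bottom_up_test(
    summaries: pd.DataFrame,
    aggregate: str = "participant",
) -> tuple[StatResult, StatResult]:
    """Correlate weight asymmetry with saliency asymmetry.

    Returns Pearson results for the amplitude difference and the count
    difference.  With ``aggregate="participant"`` (default, matching how
    the per-participant scatter is usually drawn) cells are first averaged
    within participant; ``aggregate="cell"`` pools participant x condition
    cells.
    """
    df = summaries
    if aggregate == "participant":
        df = df.groupby("participant", as_index=False)[
            ["dw", "amp_diff", "n_diff"]].mean()
    elif aggregate != "cell":
        raise ValueError("aggregate must be 'participant' or 'cell'")
    if len(df) < 3:
        raise ValueError("need at least 3 participants")
    amp = _pearson("bottom-up r (amplitude of luminance changes)",
                   df["amp_diff"], df["dw"])
    num = _pearson("bottom-up r (number of luminance changes)",
                   df["n_diff"], df["dw"])
    return amp, num


def top_down_test(summaries: pd.DataFrame) -> StatResult:
    """Attended-minus-unattended side weight contrast, one-sample t vs 0.

    Per participant the contrast averages the attend-left and attend-right
    conditions; participants missing either condition are dropped with a
    log entry.
    """
    contrasts = []
    for pid, g in summaries.groupby("participant"):
        g = g.set_index("condition")
        if not {"left", "right"}.issubset(g.index):
            logger.info("participant %s dropped from top-down test "
                        "(missing condition)", pid)
            continue
        c_left = g.loc["left", "weight_left"] - g.loc["left", "weight_right"]
        c_right = g.loc["right", "weight_right"] - g.loc["right", "weight_left"]
        contrasts.append(0.5 * (c_left + c_right))
    return _one_sample("top-down contrast (attended - unattended weight)",
                       np.asarray(contrasts))


def pseudoneglect_test(summaries: pd.DataFrame) -> StatResult:
    """Grand right-minus-left weight difference; negative = leftward bias."""
    dw = summaries.groupby("participant")["dw"].mean().to_numpy()
    if dw.size < 3:
        raise ValueError("need at least 3 participants")
    return _one_sample("pseudoneglect (right - left weight)", dw)


def gaze_controls(summaries: pd.DataFrame) -> tuple[StatResult, StatResult]:
    """Check that weight asymmetries are not explained by gaze position.

    (a) one-sample t of weight(more-gazed side) - weight(less-gazed side)
    across participant x condition cells (cells with exactly centred gaze
    excluded); (b) Pearson r between dw and mean horizontal gaze.
    """
    df = summaries[summaries["gaze_x_mean"] != 0.0]
    more = np.where(df["gaze_x_mean"] > 0, df["weight_right"], df["weight_left"])
    less = np.where(df["gaze_x_mean"] > 0, df["weight_left"], df["weight_right"])
    t_res = _one_sample("gaze control (more-gazed - less-gazed weight)",
                        more - less)
    r_res = _pearson("gaze control r (dw vs horizontal gaze)",
                     summaries["gaze_x_mean"], summaries["dw"])
    return t_res, r_res


# ---------------------------------------------------------------------------
# Driver regression with backward selection


@dataclass
class RegressionResult:
    """OLS driver regression after (optional) backward elimination."""

    formula: str
    params: pd.Series
    pvalues: pd.Series
    selected_terms: list
    criterion: str
    criterion_trace: list          # (formula, aic, bic) per step
    results: object = field(repr=False, default=None)

    @property
    def interaction_terms(self) -> list:
        return [t for t in self.selected_terms if ":" in t]


_COND = "C(condition, Treatment('left'))"


def _contained_in(term: str, other: str) -> bool:
    a, b = set(term.split(":")), set(other.split(":"))
    return a != b and a.issubset(b)


def driver_regression(
    summaries: pd.DataFrame,
    select: str = "aic",
    interactions: bool = False,
    include_gaze: bool = True,
) -> RegressionResult:
    """Regress dw on the three attention drivers (plus gaze as control).

    The design is ``dw ~ condition + luminance-change composite
    [+ gaze]``, condition dummy-coded with "left" as baseline; the
    composite averages the standardised count and amplitude saliency
    differences (they are strongly correlated, so a single predictor
    avoids multicollinearity).  ``interactions=True`` starts from all
    two-way interactions.  Backward elimination removes whole terms
    (respecting marginality) while the chosen information criterion
    improves; ``select="none"`` keeps the full model.
    """
    if select not in ("aic", "bic", "none"):
        raise ValueError("select must be 'aic', 'bic' or 'none'")
    df = summaries.copy()
    for col in ("n_diff", "amp_diff"):
        sd = df[col].std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero variance in {col}")
        df[col + "_z"] = (df[col] - df[col].mean()) / sd
    df["composite"] = (df["n_diff_z"] + df["amp_diff_z"]) / 2.0
    df["gaze"] = df["gaze_x_mean"]

    terms = [_COND, "composite"] + (["gaze"] if include_gaze else [])
    if interactions:
        base = list(terms)
        terms += [f"{a}:{b}" for i, a in enumerate(base)
                  for b in base[i + 1:]]

    def fit(term_list):
        f = "dw ~ " + (" + ".join(term_list) if term_list else "1")
        res = smf.ols(f, data=df).fit()
        if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
            raise ValueError(f"collinear design in terms: {term_list}")
        return f, res

    formula, res = fit(terms)
    trace = [(formula, res.aic, res.bic)]
    if select != "none":
        crit = (lambda r: r.aic) if select == "aic" else (lambda r: r.bic)
        current = list(terms)
        while current:
            droppable = [t for t in current
                         if not any(_contained_in(t, o) for o in current)]
            best = None
            for t in droppable:
                f_try, r_try = fit([x for x in current if x != t])
                if crit(r_try) < crit(res) and (
                        best is None or crit(r_try) < crit(best[2])):
                    best = (t, f_try, r_try)
            if best is None:
                break
            current.remove(best[0])
            formula, res = best[1], best[2]
            trace.append((formula, res.aic, res.bic))
        terms = current
    return RegressionResult(formula=formula, params=res.params,
                            pvalues=res.pvalues, selected_terms=list(terms),
                            criterion=select, criterion_trace=trace,
                            results=res)


# ---------------------------------------------------------------------------
# Event-related residual-pupil analysis


def residualize(observed: np.ndarray, predicted_change: np.ndarray) -> np.ndarray:
    """Pupil trace left unexplained by the luminance model.

    ``observed`` is the (z-scored) pupil level of one trial,
    ``predicted_change`` the model's per-frame change.  Both are
    re-referenced to the trial start: residual[k] = (observed[k] -
    observed[0]) - sum_{j<=k} predicted_change[j] (with the undefined
    first change taken as 0).  A perfect model leaves zeros.
    """
    observed = np.asarray(observed, dtype=float)
    predicted_change = np.asarray(predicted_change, dtype=float)
    if observed.size != predicted_change.size:
        raise ValueError("observed and predicted lengths differ")
    pred = predicted_change.copy()
    if pred.size:
        pred[0] = 0.0
    return (observed - observed[0]) - np.cumsum(pred)


def residualize_trials(fit: PupilResponseResults,
                       trials: Sequence[TrialRecord]) -> list[np.ndarray]:
    """Per-trial residual traces from a condition-level fit."""
    bounds = fit.model.trial_bounds
    if len(bounds) != len(trials):
        raise ValueError("fit was not computed on these trials")
    out = []
    for (a, b), trial in zip(bounds, trials):
        n = b - a
        out.append(residualize(trial.samples.pupil[:n], fit.predicted[a:b]))
    return out


@dataclass
class EpochSet:
    """Stop-locked 3-s residual-pupil epochs of one participant."""

    epochs: np.ndarray              # (n_epochs, n_samples)
    categories: list                # per epoch: hit/miss/correct_rejection
    rate: float
    baseline_corrected: bool
    norm_sd: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.epochs.shape[1]) / self.rate

    def mean_trace(self, category: str) -> Optional[np.ndarray]:
        sel = [i for i, c in enumerate(self.categories) if c == category]
        return self.epochs[sel].mean(axis=0) if sel else None


def build_epochs(
    residuals: Sequence[np.ndarray],
    stop_outcomes: Sequence[Sequence[tuple]],
    rate: float = 25.0,
    length: float = 3.0,
    baseline: float = 0.25,
) -> EpochSet:
    """Cut stop-locked epochs from residual traces and normalise them.

    ``residuals`` and ``stop_outcomes`` are parallel per-trial sequences;
    each outcome list holds (stop, outcome) pairs from
    :func:`classify_stops`.  Epochs of ``length`` seconds start at stop
    onset; each epoch is baseline-corrected by subtracting its mean over
    the closed [0, baseline]-second window, then all epochs are divided
    by one pooled standard deviation.  False alarms have no stop to lock
    to; stops whose epoch would run past the trial end are dropped with a
    log entry.
    """
    n_samp = int(round(length * rate))
    n_base = int(np.floor(baseline * rate)) + 1  # closed window
    epochs, cats = [], []
    for resid, outcomes in zip(residuals, stop_outcomes):
        for stop, outcome in outcomes:
            if outcome not in ("hit", "miss", "correct_rejection"):
                continue
            i0 = int(round(stop.onset * rate))
            if i0 + n_samp > resid.size:
                logger.info("epoch at %.2f s dropped (extends past trial end)",
                            stop.onset)
                continue
            ep = resid[i0:i0 + n_samp].astype(float).copy()
            ep -= ep[:n_base].mean()
            epochs.append(ep)
            cats.append(outcome)
    if not epochs:
        return EpochSet(epochs=np.empty((0, n_samp)), categories=[],
                        rate=rate, baseline_corrected=True, norm_sd=np.nan)
    arr = np.asarray(epochs)
    sd = float(arr.std())
    if sd > 0:
        arr = arr / sd
    return EpochSet(epochs=arr, categories=cats, rate=rate,
                    baseline_corrected=True, norm_sd=sd)


@dataclass
class TimecourseResult:
    """Per-timepoint paired contrast between two epoch categories."""

    times: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n: int
    alpha: float
    windows: list                   # (start_s, end_s) of contiguous p < alpha

    def __str__(self) -> str:
        w = ", ".join(f"[{a:.2f}, {b:.2f}] s" for a, b in self.windows)
        return (f"miss vs correct rejection: n = {self.n} participants, "
                f"significant windows: {w or 'none'}")


def compare_miss_cr(epoch_sets: dict, alpha: float = 0.05) -> TimecourseResult:
    """Paired t-test of miss vs correct-rejection traces at each timepoint.

    ``epoch_sets`` maps participant id -> :class:`EpochSet`.  Each
    participant contributes one mean trace per category; participants
    missing a category are dropped.  Contiguous runs of p < alpha are
    reported as significant windows (uncorrected, by convention).
    """
    miss, cr, rate = [], [], None
    for pid, es in epoch_sets.items():
        m = es.mean_trace("miss")
        c = es.mean_trace("correct_rejection")
        if m is None or c is None:
            logger.info("participant %s dropped from miss-vs-CR (missing "
                        "category)", pid)
            continue
        miss.append(m)
        cr.append(c)
        rate = es.rate
    if len(miss) < 2:
        raise ValueError("need >= 2 participants with both categories")
    miss = np.asarray(miss)
    cr = np.asarray(cr)
    t, p = stats.ttest_rel(miss, cr, axis=0)
    times = np.arange(miss.shape[1]) / rate
    sig = p < alpha
    windows = []
    i = 0
    while i < sig.size:
        if sig[i]:
            j = i
            while j + 1 < sig.size and sig[j + 1]:
                j += 1
            windows.append((times[i], times[j]))
            i = j + 1
        else:
            i += 1
    return TimecourseResult(times=times, t=t, p=p, n=miss.shape[0],
                            alpha=alpha, windows=windows)


def erp_analysis(
    cohort: Cohort,
    conditions: tuple[str, ...] = ("left", "right"),
    preprocess: bool = True,
    train_frac: float = 0.7,
) -> tuple[dict, TimecourseResult]:
    """Full event-related pipeline on a synthetic cohort.

    For each participant the attend-left/attend-right cells are fitted,
    trials residualised, stop-locked epochs built (pooled per
    participant) and finally misses are contrasted with correct
    rejections across participants.  Returns (epoch sets by participant,
    timecourse result).
    """
    kernels = cohort.kernels()
    epoch_sets = {}
    for part in cohort.participants:
        residuals, outcomes = [], []
        for condition in conditions:
            cell = part.cells.get(condition)
            if cell is None:
                continue
            trials = cell.trials
            if preprocess:
                trials = [preprocess_trial(t) for t in trials]
                trials = [t for t in trials if t.keep]
            try:
                fit = fit_condition(trials, kernels=kernels,
                                    train_frac=train_frac)
            except (ConditionExclusionError, ValueError) as exc:
                logger.info("ERP cell %s/%s excluded: %s", part.participant,
                            condition, exc)
                continue
            residuals.extend(residualize_trials(fit, trials))
            for t in trials:
                outcomes.append(classify_stops(t.stops, t.responses,
                                               condition)[0])
        if residuals:
            epoch_sets[part.participant] = build_epochs(
                residuals, outcomes, rate=cohort.params.rate)
    return epoch_sets, compare_miss_cr(epoch_sets)


# ---------------------------------------------------------------------------
# Cohort-level wrapper


@dataclass
class CohortStats:
    """All driver statistics of one (synthetic) cohort."""

    summaries: pd.DataFrame
    bottom_up_amp: StatResult
    bottom_up_n: StatResult
    top_down: StatResult
    pseudoneglect: StatResult
    gaze_diff: StatResult
    gaze_corr: StatResult
    regression: RegressionResult
    regression_interactions: RegressionResult

    def report(self) -> str:
        lines = [
            "Covert-attention drivers",
            "=" * 48,
            str(self.bottom_up_amp),
            str(self.bottom_up_n),
            str(self.top_down),
            str(self.pseudoneglect),
            str(self.gaze_diff),
            str(self.gaze_corr),
            f"driver regression ({self.regression.criterion.upper()}-selected): "
            f"{self.regression.formula}",
            f"  selected interactions: "
            f"{self.regression_interactions.interaction_terms or 'none'}",
            f"  mean held-out R^2 of pupil model: "
            f"{self.summaries['r2'].mean():.3f}",
        ]
        return "\n".join(lines)


def analyze_cohort(cohort: Cohort, preprocess: bool = True) -> CohortStats:
    """Summarise a cohort and run every driver statistic."""
    summaries = summarize_cohort(cohort, preprocess=preprocess)
    amp, num = bottom_up_test(summaries)
    gaze_t, gaze_r = gaze_controls(summaries)
    try:
        reg_int = driver_regression(summaries, select="bic",
                                    interactions=True)
    except ValueError as exc:
        # tiny cohorts cannot support the full two-way interaction design
        logger.info("interaction regression skipped: %s", exc)
        reg_int = driver_regression(summaries, select="bic")
    return CohortStats(
        summaries=summaries,
        bottom_up_amp=amp,
        bottom_up_n=num,
        top_down=top_down_test(summaries),
        pseudoneglect=pseudoneglect_test(summaries),
        gaze_diff=gaze_t,
        gaze_corr=gaze_r,
        regression=driver_regression(summaries, select="aic"),
        regression_interactions=reg_int,
    )
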