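"""Forward model and inverse fit of luminance-driven pupil responses.

The pupillary light response is modelled as a linear time-invariant system:
each region's signed luminance-change stream is convolved with a pupil
response kernel (separate kernels for luminance increments, which constrict,
and decrements, which dilate), and the observed per-frame pupil-size change
is a non-negatively weighted sum of these regional regressors,

    d_pupil[k] = sum_r  w_r * x_r[k] + eps[k],   w_r >= 0.

The fitted regional weights w_r are the covert-attention readout: a region
whose luminance changes influence the pupil more than their physical
magnitude warrants is a region receiving more attention.

The API follows the statsmodels convention: build a
:class:`PupilResponseModel` from data, call :meth:`~PupilResponseModel.fit`,
get a :class:`PupilResponseResults` carrying weights, goodness of fit and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import nnls

from .kernels import ResponseKernel, default_kernels
from .regions import EventMatrix, RegionMap

__all__ = [
    "PupilResponseModel",
    "PupilResponseResults",
    "ConditionExclusionError",
    "convolve_events",
    "observed_change",
    "score",
    "fit_condition",
]


class ConditionExclusionError(ValueError):
    """Fewer than the minimum number of surviving trials in a condition."""


def convolve_events(
    events: EventMatrix,
    kernel_light: ResponseKernel,
    kernel_dark: ResponseKernel,
) -> np.ndarray:
    """Turn per-region luminance changes into pupil-change regressors.

    Luminance increments are convolved with the (negative-signed) light
    kernel, decrements with the (positive-signed) dark kernel; the
    convolution is causal with no look-ahead, truncated to the event
    series length.  Returns an array (n_times, n_regions).
    """
    for k in (kernel_light, kernel_dark):
        if abs(k.rate - events.rate) > 1e-9:
            raise ValueError(f"kernel rate {k.rate} != event rate {events.rate}")
    if kernel_light.sign >= 0 or kernel_dark.sign <= 0:
        raise ValueError("expected a light (constriction) and a dark (dilation) kernel")
    e = events.values
    pos = np.clip(e, 0.0, None)
    neg = np.clip(-e, 0.0, None)
    T = e.shape[0]
    hl = kernel_light.values[:, None]
    hd = kernel_dark.values[:, None]
    reg = (signal.fftconvolve(pos, hl, axes=0)[:T]
           + signal.fftconvolve(neg, hd, axes=0)[:T])
    return reg


def observed_change(pupil_z: np.ndarray) -> np.ndarray:
    """Per-frame pupil change from a z-scored pupil trace.

    First difference; the leading sample (no predecessor) is zero and
    should be masked by the caller."""
    pupil_z = np.asarray(pupil_z, dtype=float)
    out = np.zeros_like(pupil_z)
    out[1:] = np.diff(pupil_z)
    return out


def score(predicted: np.ndarray, observed: np.ndarray,
          idx: np.ndarray) -> tuple[float, float]:
    """R^2 and RMSE between predicted and observed over an index set.

    R^2 = 1 - SS_res / SS_tot with SS_tot about the observed mean on the
    same index set; RMSE is the root mean squared residual."""
    idx = np.asarray(idx)
    if idx.size == 0:
        raise ValueError("empty index set")
    p = np.asarray(predicted, dtype=float)[idx]
    o = np.asarray(observed, dtype=float)[idx]
    res = o - p
    ss_res = float(res @ res)
    dev = o - o.mean()
    ss_tot = float(dev @ dev)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rmse = float(np.sqrt(np.mean(res**2)))
    return r2, rmse


@dataclass
class PupilResponseResults:
    """Fit results: non-negative regional weights plus goodness of fit.

    ``r2`` and ``rmse`` are computed on the held-out (test) samples;
    ``predicted`` is the full predicted per-frame change series.
    """

    model: "PupilResponseModel"
    weights: pd.Series
    r2: float
    rmse: float
    r2_train: float
    rmse_train: float
    train_idx: np.ndarray
    test_idx: np.ndarray
    predicted: np.ndarray

    @property
    def params(self) -> pd.Series:  # statsmodels-flavoured alias
        return self.weights

    def predict(self, regressors: Optional[np.ndarray] = None) -> np.ndarray:
        X = self.model.regressors if regressors is None else np.asarray(regressors)
        return X @ self.weights.to_numpy()

    def side_means(self, region_map: RegionMap) -> tuple[float, float]:
        """(left, right) unweighted mean weight per side; midline excluded."""
        w = self.weights
        left = float(w.loc[region_map.side_ids("left")].mean())
        right = float(w.loc[region_map.side_ids("right")].mean())
        return left, right

    def weight_table(self, region_map: Optional[RegionMap] = None) -> pd.DataFrame:
        tab = self.weights.rename("weight").to_frame()
        tab.index.name = "region"
        if region_map is not None:
            tab = region_map.region_table().join(tab)
        return tab

    def summary(self, region_map: Optional[RegionMap] = None) -> str:
        lines = [
            "Pupil response model (non-negative regional weights)",
            "=" * 56,
            f"n samples (train/test):  {self.train_idx.size} / {self.test_idx.size}",
            f"held-out R^2:            {self.r2:.4f}",
            f"held-out RMSE:           {self.rmse:.4f}",
            f"training R^2:            {self.r2_train:.4f}",
            f"active regions (w > 0):  {int((self.weights > 0).sum())} "
            f"of {self.weights.size}",
            "-" * 56,
        ]
        lines.append(self.weight_table(region_map).to_string())
        return "\n".join(lines)

    def plot_weights(self, region_map: RegionMap, ax=None, ppd: float = 10.0,
                     shape: tuple[int, int] = (360, 610)):
        """Render the fitted weights as a visual-field map."""
        import matplotlib.pyplot as plt

        labels = region_map.label_image(shape, ppd)
        img = np.full(labels.shape, np.nan)
        w = self.weights.to_numpy()
        inside = labels >= 0
        img[inside] = w[labels[inside]]
        if ax is None:
            _, ax = plt.subplots()
        m = ax.imshow(img, origin="upper", cmap="viridis")
        ax.set_title("regional weights (visual field)")
        ax.figure.colorbar(m, ax=ax, label="weight")
        return ax


class PupilResponseModel:
    """Non-negative linear model of per-frame pupil change.

    Parameters
    ----------
    endog : array
        Observed per-frame pupil change (z-units/frame), already
        differenced (see :func:`observed_change`).
    regressors : array (n_samples, n_regions)
        Kernel-convolved regional luminance-change streams.
    mask : boolean array, optional
        Samples excluded from the loss and the scores (blinks, gaze
        purge, trial-leading samples).  Regressors are still computed
        through them: the stimulus continues during a blink.
    trial_bounds : sequence of (start, stop), optional
        Half-open sample ranges of the concatenated trials; the
        train/test split is laid out within each trial.
    region_ids : sequence, optional
        Labels for the weight vector index.
    train_frac : float
        Fraction of each trial's samples (the first, contiguous part)
        used for training; the remainder is held out.  Contiguity avoids
        leakage through kernel overlap.
    """

    def __init__(
        self,
        endog: np.ndarray,
        regressors: np.ndarray,
        mask: Optional[np.ndarray] = None,
        trial_bounds: Optional[Sequence[tuple[int, int]]] = None,
        region_ids: Optional[Sequence] = None,
        train_frac: float = 0.7,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.regressors = np.asarray(regressors, dtype=float)
        if self.regressors.ndim != 2 or self.regressors.shape[0] != self.endog.size:
            raise ValueError("regressors must be (n_samples, n_regions) aligned "
                             "with endog")
        n, p = self.regressors.shape
        self.mask = (np.zeros(n, dtype=bool) if mask is None
                     else np.asarray(mask, dtype=bool))
        if self.mask.size != n:
            raise ValueError("mask length differs from endog")
        self.trial_bounds = ([(0, n)] if trial_bounds is None
                             else [(int(a), int(b)) for a, b in trial_bounds])
        if not 0 < train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        self.train_frac = train_frac
        self.region_ids = (np.arange(p) if region_ids is None
                           else np.asarray(region_ids))
        if self.region_ids.size != p:
            raise ValueError("region_ids length differs from regressor count")

    @classmethod
    def from_trials(
        cls,
        trials: Sequence,
        kernels: Optional[tuple[ResponseKernel, ResponseKernel]] = None,
        train_frac: float = 0.7,
    ) -> "PupilResponseModel":
        """Build the per-condition model from preprocessed trials.

        Each trial must carry 25 Hz z-scored samples and an attached
        :class:`~pupilfield.regions.EventMatrix`.  Trials are concatenated;
        regressors are convolved per trial so an event near the end of one
        trial cannot bleed into the next, and each trial's first sample
        (undefined change) is masked.
        """
        if kernels is None:
            kernels = default_kernels()
        kl, kd = kernels
        endog_parts, reg_parts, mask_parts, bounds = [], [], [], []
        offset = 0
        region_ids = None
        for trial in trials:
            ev: EventMatrix = trial.events
            if ev is None:
                raise ValueError("trial has no attached EventMatrix")
            if region_ids is None:
                region_ids = ev.region_ids
            elif not np.array_equal(region_ids, ev.region_ids):
                raise ValueError("trials disagree on the region set")
            X = convolve_events(ev, kl, kd)
            pupil = trial.samples.pupil
            n = min(X.shape[0], pupil.size)
            y = observed_change(pupil)[:n]
            X = X[:n]
            m = np.zeros(n, dtype=bool)
            m[0] = True  # change undefined at the trial's first sample
            if trial.model_mask is not None:
                mm = np.asarray(trial.model_mask, dtype=bool)[:n]
                # change at k uses pupil samples k-1 and k
                m[:mm.size] |= mm
                m[1:mm.size] |= mm[:-1]
            m |= ev.missing[:n]
            endog_parts.append(y)
            reg_parts.append(X)
            mask_parts.append(m)
            bounds.append((offset, offset + n))
            offset += n
        return cls(
            endog=np.concatenate(endog_parts),
            regressors=np.vstack(reg_parts),
            mask=np.concatenate(mask_parts),
            trial_bounds=bounds,
            region_ids=region_ids,
            train_frac=train_frac,
        )

    # -- fitting -----------------------------------------------------------
    def split_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Unmasked (train, test) sample indices: within each trial the
        first ``train_frac`` of samples train, the rest test."""
        train, test = [], []
        for a, b in self.trial_bounds:
            cut = a + int(round(self.train_frac * (b - a)))
            idx = np.arange(a, b)
            ok = ~self.mask[a:b]
            train.append(idx[(idx < cut) & ok])
            test.append(idx[(idx >= cut) & ok])
        return np.concatenate(train), np.concatenate(test)

    def fit(self) -> PupilResponseResults:
        """Fit the non-negative weights by bound-constrained least squares.

        The problem is convex; the active-set NNLS solver reaches the
        global optimum deterministically.  For speed the training system
        is first reduced by a thin QR factorisation (equivalent normal
        reduction, exact up to numerical precision).
        """
        train_idx, test_idx = self.split_indices()
        p = self.regressors.shape[1]
        if train_idx.size < 10 * p:
            raise ValueError(
                f"too few unmasked training samples ({train_idx.size}) for "
                f"{p} regions; need at least {10 * p}")
        A = self.regressors[train_idx]
        b = self.endog[train_idx]
        if A.shape[0] > A.shape[1]:
            Q, R = np.linalg.qr(A)
            rhs = Q.T @ b
        else:
            R, rhs = A, b
        if np.linalg.matrix_rank(R) < p:
            warnings.warn("rank-deficient regressors; weights are a "
                          "minimum-norm non-negative solution", RuntimeWarning)
        w, _ = nnls(R, rhs)
        predicted = self.regressors @ w
        r2, rmse = score(predicted, self.endog, test_idx)
        r2_tr, rmse_tr = score(predicted, self.endog, train_idx)
        return PupilResponseResults(
            model=self,
            weights=pd.Series(w, index=pd.Index(self.region_ids, name="region")),
            r2=r2, rmse=rmse, r2_train=r2_tr, rmse_train=rmse_tr,
            train_idx=train_idx, test_idx=test_idx, predicted=predicted,
        )


def fit_condition(
    trials: Sequence,
    kernels: Optional[tuple[ResponseKernel, ResponseKernel]] = None,
    train_frac: float = 0.7,
    min_trials: int = 2,
) -> PupilResponseResults:
    """Fit one weight vector for all surviving trials of a participant x
    condition cell.  Raises :class:`ConditionExclusionError` when fewer
    than ``min_trials`` trials survive preprocessing."""
    kept = [t for t in trials if getattr(t, "keep", True) in (True, None)]
    if len(kept) < min_trials:
        raise ConditionExclusionError(
            f"only {len(kept)} surviving trial(s); need >= {min_trials}")
    return PupilResponseModel.from_trials(kept, kernels=kernels,
                                          train_frac=train_frac).fit()
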