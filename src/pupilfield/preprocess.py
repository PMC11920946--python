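"""Preprocessing of eye-tracking sample series.

Fixed pipeline, applied per trial in this order:

1. blink detection by the pupil change-velocity rule (|velocity| beyond
   k standard deviations, default k = 3) and removal,
2. linear interpolation across removed samples,
3. down-sampling from the tracker rate (500 Hz) to the movie rate (25 Hz)
   by bin means,
4. z-scoring of pupil size (the model explains pupil size *changes*, so
   only standardised changes matter),
5. purging of samples whose gaze deviates more than 2.5 deg from the
   movie centre, together with the following 2 s (purged samples are
   excluded from model fitting, not interpolated),
6. trial-level exclusion: more than 30% missing after blink removal, or
   more than 50% after the gaze purge, drops the trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SampleSeries",
    "TrialRecord",
    "UnrecoverableTrialError",
    "detect_blinks",
    "interpolate_gaps",
    "resample_to_movie_rate",
    "zscore_pupil",
    "purge_gaze_deviation",
    "assess_trial",
    "preprocess_trial",
]


class UnrecoverableTrialError(ValueError):
    """Raised when a trial cannot be salvaged (fully masked, zero variance...)."""


@dataclass
class SampleSeries:
    """Time-indexed gaze/pupil record for one trial.

    ``t`` in seconds (strictly increasing), gaze in degrees relative to the
    movie centre, pupil in raw tracker units before z-scoring (z-units
    after), ``valid`` flags tracker-reported sample validity.
    """

    t: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        for name in ("gaze_x", "gaze_y", "pupil", "valid"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name} length differs from t")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def rate(self) -> float:
        if len(self) < 2:
            raise ValueError("need >= 2 samples to infer a rate")
        return 1.0 / float(np.median(np.diff(self.t)))

    def copy(self) -> "SampleSeries":
        return SampleSeries(self.t.copy(), self.gaze_x.copy(), self.gaze_y.copy(),
                            self.pupil.copy(), self.valid.copy())


@dataclass
class TrialRecord:
    """One trial: samples plus task metadata and bookkeeping."""

    participant: str
    condition: str
    samples: SampleSeries
    movie: str = ""
    mirrored: bool = False
    stops: object = None          # StopSchedule
    responses: object = None      # ResponseLog
    events: object = None         # EventMatrix (attached when simulated)
    model_mask: Optional[np.ndarray] = None  # samples excluded from fitting
    missing_frac_postblink: float = np.nan
    missing_frac_postgaze: float = np.nan
    keep: Optional[bool] = None
    extra: dict = field(default_factory=dict)

    VALID_CONDITIONS = ("left", "right", "both", "none")

    def __post_init__(self) -> None:
        if self.condition not in self.VALID_CONDITIONS:
            raise ValueError(f"invalid condition {self.condition!r}")


# ---------------------------------------------------------------------------
# Operations


def detect_blinks(pupil: np.ndarray, t: np.ndarray | None = None,
                  k: float = 3.0) -> np.ndarray:
    """Flag blink samples by the change-velocity rule.

    Velocity is the first difference divided by the sampling interval; a
    difference whose absolute velocity strictly exceeds ``k`` standard
    deviations (SD over the trial's finite velocities) flags both samples
    it connects.  A constant series yields an empty mask.
    """
    pupil = np.asarray(pupil, dtype=float)
    if pupil.size < 3:
        raise ValueError("need at least 3 samples")
    if t is None:
        vel = np.diff(pupil)
    else:
        vel = np.diff(pupil) / np.diff(np.asarray(t, dtype=float))
    finite = np.isfinite(vel)
    mask = np.zeros(pupil.size, dtype=bool)
    if not finite.any():
        return mask
    sd = float(np.std(vel[finite]))
    if sd == 0.0:
        return mask
    hit = finite & (np.abs(vel) > k * sd)
    mask[:-1] |= hit
    mask[1:] |= hit
    return mask


def interpolate_gaps(series: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked samples by linear interpolation between valid neighbours.

    Leading/trailing masked runs take the nearest valid value.  Raises
    :class:`UnrecoverableTrialError` when everything is masked.
    """
    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.size != series.size:
        raise ValueError("mask and series lengths differ")
    good = ~mask & np.isfinite(series)
    if not good.any():
        raise UnrecoverableTrialError("entire trial masked; nothing to interpolate from")
    idx = np.arange(series.size)
    out = series.copy()
    out[~good] = np.interp(idx[~good], idx[good], series[good])
    return out


def resample_to_movie_rate(series: SampleSeries, target: float = 25.0) -> SampleSeries:
    """Down-sample by non-overlapping bin means to the movie rate.

    The input rate must be an integer multiple of ``target`` (500/25 = 20).
    Output timestamps sit at bin centres; an output sample is valid when
    more than half of its bin's input samples were valid.  A trailing
    partial bin is dropped.
    """
    rate = series.rate
    ratio = rate / target
    if abs(ratio - round(ratio)) > 1e-6 or round(ratio) < 1:
        raise ValueError(f"input rate {rate:.3f} Hz is not an integer multiple "
                         f"of target {target} Hz")
    f = int(round(ratio))
    n_out = len(series) // f
    if n_out == 0:
        raise ValueError("series shorter than one output bin")
    sl = slice(0, n_out * f)

    def binmean(x):
        return np.asarray(x, dtype=float)[sl].reshape(n_out, f).mean(axis=1)

    valid_frac = series.valid[sl].reshape(n_out, f).mean(axis=1)
    return SampleSeries(
        t=binmean(series.t),
        gaze_x=binmean(series.gaze_x),
        gaze_y=binmean(series.gaze_y),
        pupil=binmean(series.pupil),
        valid=valid_frac > 0.5,
    )


def zscore_pupil(series: SampleSeries) -> SampleSeries:
    """Standardise the pupil channel to mean 0, SD 1 over valid samples."""
    out = series.copy()
    ref = out.pupil[out.valid & np.isfinite(out.pupil)]
    if ref.size == 0:
        raise UnrecoverableTrialError("no valid pupil samples to standardise")
    sd = float(np.std(ref))
    if sd == 0.0:
        raise UnrecoverableTrialError("zero pupil variance; cannot z-score")
    out.pupil = (out.pupil - float(np.mean(ref))) / sd
    return out


def purge_gaze_deviation(series: SampleSeries, radius: float = 2.5,
                         purge_after: float = 2.0) -> np.ndarray:
    """Mask samples with gaze eccentricity strictly beyond ``radius`` deg,
    plus every sample within ``purge_after`` seconds after each of them
    (window closed on both ends)."""
    ecc = np.hypot(series.gaze_x, series.gaze_y)
    deviant = ecc > radius
    mask = np.zeros(len(series), dtype=bool)
    if not deviant.any():
        return mask
    n_after = int(round(purge_after * series.rate))
    for i in np.flatnonzero(deviant):
        mask[i:i + n_after + 1] = True
    return mask


def assess_trial(trial: TrialRecord, max_postblink: float = 0.30,
                 max_postgaze: float = 0.50) -> TrialRecord:
    """Apply the trial-exclusion rule from recorded missing fractions.

    Drop when post-blink missingness exceeds ``max_postblink`` (strictly)
    or post-gaze missingness exceeds ``max_postgaze``.
    """
    fb = trial.missing_frac_postblink
    fg = trial.missing_frac_postgaze
    if not (np.isfinite(fb) and np.isfinite(fg)):
        raise ValueError("missing fractions not computed; run preprocess_trial first")
    keep = not (fb > max_postblink or fg > max_postgaze)
    trial.keep = keep
    if not keep:
        logger.info("trial dropped (participant=%s condition=%s movie=%s): "
                    "missing post-blink %.1f%%, post-gaze %.1f%%",
                    trial.participant, trial.condition, trial.movie,
                    100 * fb, 100 * fg)
    return trial


def preprocess_trial(
    trial: TrialRecord,
    blink_k: float = 3.0,
    target_rate: float = 25.0,
    gaze_radius: float = 2.5,
    purge_after: float = 2.0,
    max_postblink: float = 0.30,
    max_postgaze: float = 0.50,
) -> TrialRecord:
    """Run the full preprocessing pipeline on one trial.

    Returns a new :class:`TrialRecord` whose samples are at the movie rate
    and z-scored, with ``model_mask`` marking samples excluded from model
    fitting (gaze purge and mostly-invalid bins) and the two missing
    fractions and the keep/drop decision recorded.
    """
    raw = trial.samples
    blink_mask = detect_blinks(raw.pupil, raw.t, k=blink_k) | ~raw.valid
    frac_postblink = float(blink_mask.mean())

    clean = raw.copy()
    clean.pupil = interpolate_gaps(raw.pupil, blink_mask)
    clean.gaze_x = interpolate_gaps(raw.gaze_x, blink_mask)
    clean.gaze_y = interpolate_gaps(raw.gaze_y, blink_mask)
    clean.valid = ~blink_mask

    if abs(clean.rate - target_rate) > 1e-6:
        low = resample_to_movie_rate(clean, target=target_rate)
    else:
        low = clean
    low = zscore_pupil(low)

    gaze_mask = purge_gaze_deviation(low, radius=gaze_radius, purge_after=purge_after)
    model_mask = gaze_mask | ~low.valid
    frac_postgaze = float((gaze_mask | ~low.valid).mean())

    out = TrialRecord(
        participant=trial.participant, condition=trial.condition,
        samples=low, movie=trial.movie, mirrored=trial.mirrored,
        stops=trial.stops, responses=trial.responses, events=trial.events,
        model_mask=model_mask,
        missing_frac_postblink=frac_postblink,
        missing_frac_postgaze=frac_postgaze,
        extra=dict(trial.extra),
    )
    return assess_trial(out, max_postblink=max_postblink, max_postgaze=max_postgaze)
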