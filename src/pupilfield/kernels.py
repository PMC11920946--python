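"""Pupil response kernels.

The pupillary light response to a discrete luminance change is well
approximated by an Erlang-style gamma function

    h(t) = (t / t_max)^n * exp(n * (1 - t / t_max)),

which is zero at t = 0, rises to a single peak of 1 at t = t_max and decays
smoothly afterwards.  Two kernels are used throughout: a "light" kernel for
luminance increments (pupil constriction, negative-signed output) and a
"dark" kernel for decrements (dilation, positive-signed output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ResponseKernel", "make_kernel", "erp_kernel"]

_POLARITY_SIGN = {"light": -1.0, "dark": 1.0}


@dataclass(frozen=True)
class ResponseKernel:
    """Sampled pupil response function.

    Parameters
    ----------
    n : float
        Shape parameter; larger values give a narrower, more symmetric peak.
    t_max : float
        Latency to peak in seconds.
    gain : float
        Multiplicative gain applied after peak normalisation.
    polarity : {"light", "dark"}
        "light" responses are constrictions (negative pupil change),
        "dark" responses dilations (positive).
    duration : float
        Length of the finite support in seconds.
    rate : float
        Sampling rate in Hz (the movie/model rate, 25 Hz by default).
    """

    n: float = 10.1
    t_max: float = 0.93
    gain: float = 1.0
    polarity: str = "light"
    duration: float = 4.0
    rate: float = 25.0
    _values: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.n <= 0 or self.t_max <= 0:
            raise ValueError("kernel shape n and latency t_max must be positive")
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("kernel duration and rate must be positive")
        if self.polarity not in _POLARITY_SIGN:
            raise ValueError(f"polarity must be 'light' or 'dark', got {self.polarity!r}")
        t = self.times
        with np.errstate(divide="ignore"):
            h = (t / self.t_max) ** self.n * np.exp(self.n * (1.0 - t / self.t_max))
        h[0] = 0.0
        sign = _POLARITY_SIGN[self.polarity]
        object.__setattr__(self, "_values", sign * self.gain * h)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, 0 .. duration inclusive."""
        n_samp = int(round(self.duration * self.rate)) + 1
        return np.arange(n_samp) / self.rate

    @property
    def values(self) -> np.ndarray:
        """Kernel samples, peak magnitude ``gain``, signed by polarity."""
        return self._values

    @property
    def sign(self) -> float:
        return _POLARITY_SIGN[self.polarity]


def make_kernel(
    n: float = 10.1,
    t_max: float = 0.93,
    gain: float = 1.0,
    polarity: str = "light",
    duration: float = 4.0,
    rate: float = 25.0,
) -> ResponseKernel:
    """Build a :class:`ResponseKernel`; see the class for parameter meaning."""
    return ResponseKernel(n=n, t_max=t_max, gain=gain, polarity=polarity,
                          duration=duration, rate=rate)


def default_kernels(
    light_gain: float = 1.0,
    dark_gain: float = 0.5,
    n: float = 10.1,
    t_max: float = 0.93,
    duration: float = 4.0,
    rate: float = 25.0,
) -> tuple[ResponseKernel, ResponseKernel]:
    """Default (light, dark) kernel pair; dark gain is half the light gain,
    reflecting the weaker dilation response to luminance decrements."""
    light = make_kernel(n=n, t_max=t_max, gain=light_gain, polarity="light",
                        duration=duration, rate=rate)
    dark = make_kernel(n=n, t_max=t_max, gain=dark_gain, polarity="dark",
                       duration=duration, rate=rate)
    return light, dark


def erp_kernel(
    t_max: float = 1.2,
    n: float = 3.0,
    amplitude: float = 1.0,
    duration: float = 3.0,
    rate: float = 25.0,
) -> np.ndarray:
    """Smooth unimodal dilation transient for task-relevant events.

    Effort-linked pupil dilation to attended events peaks roughly 1.2 s
    after the event.  Same gamma family as the light-response kernel but
    broader and positive (dilation)."""
    k = make_kernel(n=n, t_max=t_max, gain=amplitude, polarity="dark",
                    duration=duration, rate=rate)
    return k.values
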