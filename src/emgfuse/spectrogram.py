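"""Short-time Fourier spectrogram features for multichannel trials.

A trial's signal is cut into overlapping frames (window 200 ms, hop 50 ms by
default), each frame is tapered and transformed with an ``n_fft``-point DFT
(1024 by default), and the one-sided spectrum of ``n_fft/2 + 1`` bins per
channel per frame becomes the feature representation.  Frame ``t`` covers
samples ``[t*H, t*H + W)`` (half-open, frames indexed from 0) and the frame
count is ``floor((L - W)/H) + 1``.

The ``power`` scale is normalized so that, with a rectangular window, the
one-sided bin powers of a frame sum to the frame energy divided by the window
length (a Parseval-consistent density per sample); ``log-power`` is the
natural log of that with a 1e-12 floor, which keeps autoencoder inputs on a
stable scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps

from .containers import FeatureTable, LabeledSignalSet
from .tensorize import FeatureTensor

__all__ = ["SpectrogramSpec", "spectrogram_features", "dataset_features"]

_EPS = 1e-12
_SCALES = ("magnitude", "power", "log-power")


@dataclass(frozen=True)
class SpectrogramSpec:
    window_ms: float = 200.0
    increment_ms: float = 50.0
    n_fft: int = 1024
    window_shape: str = "hamming"
    scale: str = "log-power"

    def __post_init__(self) -> None:
        if not (self.window_ms > self.increment_ms > 0):
            raise ValueError("require window_ms > increment_ms > 0")
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def hop_samples(self, fs: float) -> int:
        return int(round(self.increment_ms * fs / 1000.0))


def _frame(x: np.ndarray, W: int, H: int) -> np.ndarray:
    """(n_frames, W) view of a 1-D signal; frame t covers [t*H, t*H+W)."""
    L = x.shape[-1]
    n_frames = (L - W) // H + 1
    idx = np.arange(W)[None, :] + H * np.arange(n_frames)[:, None]
    return x[idx]


def spectrogram_features(
    trial_signal: np.ndarray,
    sampling_rate: float,
    spec: SpectrogramSpec = SpectrogramSpec(),
) -> FeatureTensor:
    """Spectrogram of a channels x samples matrix as a (channel, frequency,
    time) tensor; flatten it (row-major) for one feature row per trial."""
    x = np.atleast_2d(np.asarray(trial_signal, dtype=float))
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    W = spec.window_samples(sampling_rate)
    H = spec.hop_samples(sampling_rate)
    if x.shape[1] < W:
        raise ValueError(f"trial has {x.shape[1]} samples, shorter than one {W}-sample window")
    if spec.n_fft < W:
        raise ValueError(f"n_fft={spec.n_fft} smaller than window length {W}")

    if spec.window_shape == "rectangular":
        taper = np.ones(W)
    else:
        taper = sps.get_window(spec.window_shape, W, fftbins=True)

    n_bins = spec.n_fft // 2 + 1
    n_frames = (x.shape[1] - W) // H + 1
    out = np.empty((x.shape[0], n_bins, n_frames))
    # one-sided doubling weights: DC and Nyquist counted once
    dbl = np.full(n_bins, 2.0)
    dbl[0] = 1.0
    if spec.n_fft % 2 == 0:
        dbl[-1] = 1.0
    for ch in range(x.shape[0]):
        frames = _frame(x[ch], W, H) * taper
        spec_c = sfft.rfft(frames, n=spec.n_fft, axis=1)
        mag = np.abs(spec_c)
        if spec.scale == "magnitude":
            vals = mag
        else:
            power = dbl[None, :] * mag**2 / (spec.n_fft * W)
            vals = power if spec.scale == "power" else np.log(power + _EPS)
        out[ch] = vals.T  # (frequency, time)
    return FeatureTensor(out, axis_names=("channel", "frequency", "time"))


def dataset_features(
    dataset: LabeledSignalSet,
    spec: SpectrogramSpec = SpectrogramSpec(),
) -> FeatureTable:
    """One feature row per trial: the flattened (channel, frequency, time)
    spectrogram tensor, with subject/trial annotations preserved."""
    rows, ys, subs, tids = [], [], [], []
    names: list[str] | None = None
    for t in dataset:
        tens = spectrogram_features(t.signal, t.sampling_rate, spec)
        rows.append(tens.data.reshape(-1))
        ys.append(t.class_label)
        subs.append(t.subject_id)
        tids.append(t.trial_id)
        if names is None:
            ch, fr, ti = tens.shape
            names = [
                f"ch{c}_f{f}_t{tt}"
                for c in range(ch)
                for f in range(fr)
                for tt in range(ti)
            ]
    return FeatureTable(
        X=np.vstack(rows),
        y=np.array(ys),
        feature_names=names or [],
        subject_id=np.array(subs),
        trial_id=np.array(tids),
    )
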