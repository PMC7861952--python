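"""Synthetic surface-EMG recordings and toy feature tables.

Real sEMG corpora for gesture decoding are rarely redistributable, so the
package ships a statistical stand-in: each gesture class is a band-emphasized
stochastic process (white noise through a second-order resonant filter centred
on a class-specific frequency), scaled per channel and per subject, with
additive sensor noise and a hardware-style amplification factor.  The defaults
mirror a typical able-bodied protocol — 2 recording channels, 10 gesture
classes, 9 subjects, 6 repetitions, 2000 Hz, 5 s of activity followed by 5 s
of rest — and an amputee-style variant with 8 channels, 6 gestures and three
force levels is a parameter choice away.

The signals are not physiological (no motor-unit action potentials, no
fatigue); they exist so that spectral placement, class structure and the full
pipeline are testable end to end with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import FeatureTable, LabeledSignalSet, Trial

__all__ = ["EmgSimSpec", "simulate_emg_dataset", "make_toy_multiclass"]


def _default_band_centers(n_classes: int) -> np.ndarray:
    # conventional sEMG energy band is roughly 20-450 Hz; spread class
    # signatures over its informative middle
    return np.linspace(60.0, 400.0, n_classes)


def _default_channel_gains(n_classes: int, n_channels: int) -> np.ndarray:
    # deterministic, strictly positive class x channel pattern so channel
    # amplitude ratios carry class information beyond the band centre
    c = np.arange(n_classes)[:, None]
    ch = np.arange(n_channels)[None, :]
    return 1.0 + 0.5 * np.sin(2.0 * np.pi * (c * (ch + 1) + 1) / max(n_classes, 2))


@dataclass
class EmgSimSpec:
    """Parameters of the simulated recording session.

    ``class_band_centers`` (Hz, one per class) set where each gesture's
    spectral energy sits; ``class_channel_gains`` (class x channel, strictly
    positive) set the per-channel amplitude signature; ``subject_gain_sd``
    scales a per-subject multiplicative log-normal gain; ``force_levels``
    multiplies per-trial amplitude (amputee-style force variation) while the
    label stays the gesture.
    """

    n_subjects: int = 9
    n_classes: int = 10
    n_channels: int = 2
    n_repetitions: int = 6
    sampling_rate: float = 2000.0
    trial_duration: float = 5.0
    rest_duration: float = 5.0
    class_band_centers: np.ndarray | None = None
    class_channel_gains: np.ndarray | None = None
    subject_gain_sd: float = 0.1
    noise_sd: float = 0.05
    amplification: float = 1000.0
    force_levels: tuple[float, ...] = (1.0,)
    include_rest: bool = False
    resonance_q: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_band_centers is None:
            self.class_band_centers = _default_band_centers(self.n_classes)
        self.class_band_centers = np.asarray(self.class_band_centers, dtype=float)
        if self.class_channel_gains is None:
            self.class_channel_gains = _default_channel_gains(self.n_classes, self.n_channels)
        self.class_channel_gains = np.asarray(self.class_channel_gains, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("invariant violated: n_classes >= 2")
        for name in ("n_subjects", "n_channels", "n_repetitions"):
            if getattr(self, name) < 1:
                raise ValueError(f"invariant violated: {name} >= 1")
        if self.trial_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("invariant violated: all durations > 0")
        if self.class_band_centers.shape != (self.n_classes,):
            raise ValueError("invariant violated: one band centre per class")
        if self.sampling_rate <= 2.0 * float(np.max(self.class_band_centers)):
            raise ValueError("invariant violated: sampling_rate > 2*max(class_band_centers)")
        if self.class_channel_gains.shape != (self.n_classes, self.n_channels):
            raise ValueError("invariant violated: class_channel_gains is class x channel")
        if np.any(self.class_channel_gains < 0):
            # zero gains are accepted as an explicit degenerate (silent) channel
            raise ValueError("invariant violated: class_channel_gains nonnegative")


def _band_noise(rng: np.random.Generator, n: int, f0: float, fs: float, q: float) -> np.ndarray:
    """White noise shaped by a second-order resonator centred on f0."""
    white = rng.standard_normal(n)
    b, a = sps.iirpeak(f0 / (fs / 2.0), q)
    shaped = sps.lfilter(b, a, white)
    shaped -= shaped.mean()
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def simulate_emg_dataset(spec: EmgSimSpec) -> LabeledSignalSet:
    """Generate one labeled trial per (subject, class, repetition, force level).

    Active segments are zero-mean band-emphasized noise per channel, scaled by
    the class/channel gain, a subject gain and the trial's force factor, plus
    additive white sensor noise, all multiplied by ``spec.amplification``.
    Rest segments are sensor noise only and are appended as class label ``-1``
    when ``include_rest`` is set.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n_active = int(round(spec.trial_duration * fs))
    n_rest = int(round(spec.rest_duration * fs))
    subject_gains = np.exp(spec.subject_gain_sd * rng.standard_normal(spec.n_subjects))

    trials: list[Trial] = []
    for s in range(spec.n_subjects):
        for c in range(spec.n_classes):
            for r in range(spec.n_repetitions):
                for fi, force in enumerate(spec.force_levels):
                    sig = np.empty((spec.n_channels, n_active))
                    for ch in range(spec.n_channels):
                        gain = spec.class_channel_gains[c, ch] * subject_gains[s] * force
                        if gain > 0:
                            base = gain * _band_noise(
                                rng, n_active, spec.class_band_centers[c], fs, spec.resonance_q
                            )
                        else:
                            base = np.zeros(n_active)
                        noise = spec.noise_sd * rng.standard_normal(n_active)
                        sig[ch] = spec.amplification * (base + noise)
                    trials.append(
                        Trial(
                            signal=sig,
                            subject_id=s,
                            class_label=c,
                            repetition=r,
                            force_level=fi,
                            sampling_rate=fs,
                        )
                    )
                    if spec.include_rest:
                        rest = spec.amplification * spec.noise_sd * rng.standard_normal(
                            (spec.n_channels, n_rest)
                        )
                        trials.append(
                            Trial(
                                signal=rest,
                                subject_id=s,
                                class_label=-1,
                                repetition=r,
                                force_level=fi,
                                sampling_rate=fs,
                            )
                        )
    return LabeledSignalSet(trials)


def make_toy_multiclass(
    n_per_class: int,
    n_classes: int,
    n_features: int,
    separation: float,
    discrete_cols: set[int] | None = None,
    seed: int = 0,
) -> FeatureTable:
    """Balanced Gaussian blobs with class means ``separation`` apart.

    Continuous columns are unit-variance Gaussians around orthonormal class
    directions scaled by ``separation``; columns in ``discrete_cols`` carry an
    integer code constant within each class.  With large separation any linear
    classifier reaches perfect training accuracy; with separation 0 the class
    conditionals coincide.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    discrete_cols = set(discrete_cols or ())
    if not discrete_cols <= set(range(n_features)):
        raise ValueError("discrete_cols must be a subset of the feature columns")

    rng = np.random.default_rng(seed)
    cont_cols = sorted(set(range(n_features)) - discrete_cols)
    d_cont = len(cont_cols)

    # orthonormal class directions (QR of a random matrix) guarantee pairwise
    # mean distance separation*sqrt(2)
    if d_cont > 0:
        raw = rng.standard_normal((d_cont, n_classes))
        q, _ = np.linalg.qr(raw if d_cont >= n_classes else raw.T)
        dirs = q[:, :n_classes] if d_cont >= n_classes else q[:n_classes, :].T
        if dirs.shape != (d_cont, n_classes):  # fewer features than classes
            dirs = rng.standard_normal((d_cont, n_classes))
            dirs /= np.linalg.norm(dirs, axis=0, keepdims=True)
        means = separation * dirs.T  # (classes, d_cont)
    else:
        means = np.zeros((n_classes, 0))

    n = n_per_class * n_classes
    X = np.zeros((n, n_features))
    y = np.repeat(np.arange(n_classes), n_per_class)
    for c in range(n_classes):
        rows = slice(c * n_per_class, (c + 1) * n_per_class)
        for k, j in enumerate(cont_cols):
            X[rows, j] = means[c, k] + rng.standard_normal(n_per_class)
        for j in discrete_cols:
            X[rows, j] = float(c + 10 * j)  # integer code, constant within class

    discrete = np.array([j in discrete_cols for j in range(n_features)])
    return FeatureTable(X=X, y=y, discrete=discrete, trial_id=np.arange(n), subject_id=np.zeros(n, dtype=int))
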