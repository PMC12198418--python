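"""Band-limited amplitude envelopes from parcel time series.

The envelope of a parcel signal at a center frequency f is the magnitude of
its complex Morlet-wavelet transform (5 cycles by default), downsampled to
5*f so that each oscillatory cycle is represented by five samples. Edge
windows contaminated by the wavelet support are trimmed from both ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from mne.time_frequency import tfr_array_morlet
from scipy import signal

__all__ = ["EnvelopeArray", "morlet_envelope", "normalize_envelopes"]


@dataclass
class EnvelopeArray:
    """Amplitude envelopes per (subject, trial, parcel, time).

    values has shape (n_subjects, n_trials, n_parcels, n_times) and is
    nonnegative unless the array has been normalized (z-scored), in which
    case ``normalized`` is True.
    """

    values: np.ndarray
    center_frequency: float
    sampling_rate: float
    edge_trimmed: bool = False
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be (subjects, trials, parcels, time)")
        if not self.normalized and np.any(self.values < -1e-12):
            raise ValueError("amplitude envelopes must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[2]

    @property
    def n_times(self) -> int:
        return self.values.shape[3]


def morlet_envelope(series: np.ndarray, sampling_rate: float,
                    center_frequency: float, n_cycles: float = 5,
                    trim: float | None = None) -> EnvelopeArray:
    """Complex Morlet envelope of parcel time series, downsampled to 5*f.

    Parameters
    ----------
    series
        Array of shape (..., n_parcels, n_times); leading axes (subject,
        trial) are preserved. Sampling rate must exceed twice the center
        frequency.
    trim
        Seconds removed from each end of the trial after filtering; defaults
        to half the wavelet support (n_cycles / (2 f)).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim < 2:
        raise ValueError("series must have (parcels, time) as trailing axes")
    if sampling_rate <= 2 * center_frequency:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz undersamples a {center_frequency} Hz "
            "carrier (need > 2x)")
    n_times = series.shape[-1]
    support = n_cycles / center_frequency  # wavelet length in s
    if n_times / sampling_rate < support:
        raise ValueError("series shorter than the wavelet support")
    if trim is None:
        trim = support / 2
    if trim < support / 2 - 1e-12:
        warnings.warn("trim shorter than half the wavelet support; edges may "
                      "carry filter transients", stacklevel=2)

    lead_shape = series.shape[:-2]
    flat = series.reshape((-1,) + series.shape[-2:])  # (epochs, parcels, time)
    tfr = tfr_array_morlet(flat, sfreq=sampling_rate,
                           freqs=[center_frequency], n_cycles=n_cycles,
                           output="complex", zero_mean=False)
    env = np.abs(tfr[:, :, 0, :])  # drop singleton frequency axis

    target_rate = 5 * center_frequency
    step = sampling_rate / target_rate
    if abs(step - round(step)) < 1e-9:
        # integer decimation: the wavelet already band-limited the signal
        env = env[..., :: int(round(step))]
        out_rate = sampling_rate / int(round(step))
    else:
        from fractions import Fraction

        frac = Fraction(target_rate / sampling_rate).limit_denominator(1000)
        env = signal.resample_poly(env, frac.numerator, frac.denominator,
                                   axis=-1)
        env = np.clip(env, 0, None)   # polyphase ripple can dip below zero
        out_rate = sampling_rate * frac.numerator / frac.denominator
    n_trim = int(round(trim * out_rate))
    if 2 * n_trim >= env.shape[-1]:
        raise ValueError("trim removes the entire trial")
    if n_trim:
        env = env[..., n_trim:-n_trim]
    env = env.reshape(lead_shape + env.shape[-2:])
    while env.ndim < 4:
        env = env[None]
    return EnvelopeArray(values=env, center_frequency=center_frequency,
                         sampling_rate=out_rate, edge_trimmed=n_trim > 0)


def normalize_envelopes(env: EnvelopeArray,
                        groups: np.ndarray | None = None) -> EnvelopeArray:
    """Z-score envelopes pooled over parcels and time within each group.

    ``groups`` assigns a label to every (subject, trial) pair, shape
    (n_subjects, n_trials); trials sharing a label (same frequency, session,
    subject and task) are pooled and z-scored together. The default groups
    by subject. Pooled scoring preserves relative parcel loadings within a
    group, which the downstream spatial ICA relies on.
    """
    vals = env.values
    if groups is None:
        groups = np.arange(env.n_subjects)[:, None] * np.ones(
            (1, env.n_trials), dtype=int)
    groups = np.asarray(groups)
    if groups.shape != vals.shape[:2]:
        raise ValueError("groups must label every (subject, trial) pair")
    out = np.empty_like(vals)
    for label in np.unique(groups):
        mask = groups == label
        block = vals[mask]
        sd = block.std()
        if sd == 0:
            raise ValueError(f"group {label!r} has zero variance; cannot normalize")
        out[mask] = (block - block.mean()) / sd
    return replace(env, values=out, normalized=True)
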