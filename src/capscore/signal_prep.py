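"""Raw EEG conditioning: resampling to 100 Hz, normalization, epoching, flatline flags.

The scoring unit of sleep microstructure is the one-second epoch.  All
classifiers downstream consume a matrix with one row per epoch and exactly
100 columns (one second at the canonical 100 Hz rate), so every recording is
first brought to 100 Hz by anti-aliased decimation, z-scored over its whole
duration, and segmented into contiguous non-overlapping one-second windows.

Movement artifacts are deliberately left in the signal: transient activity
is precisely what distinguishes an A phase from quiescent background, so
artifact rejection would remove part of the class signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, EmptyTensorError, UnsupportedRateError

logger = logging.getLogger(__name__)

#: Canonical sampling rate of the pipeline (Hz).
TARGET_FS = 100.0

#: Number of samples per one-second epoch at the canonical rate.
EPOCH_SAMPLES = 100

#: Length, in epochs, of one flatline scanning block (one minute).
FLATLINE_BLOCK_EPOCHS = 60


@dataclass
class RawRecording:
    """A single subject's EEG series from one monopolar derivation.

    Parameters
    ----------
    samples : ndarray
        Amplitude series, arbitrary units (typically microvolt).
    fs : float
        Sampling rate in Hz, strictly positive.
    derivation : str
        Channel label, e.g. ``"C4-A1"`` or ``"C3-A2"``.
    subject_id : str
        Identifier used to enforce subject independence in evaluation.
    start_time : datetime, optional
        Wall-clock start of the recording, used for scoring-file timestamps.
    """

    samples: np.ndarray
    fs: float
    derivation: str = "C4-A1"
    subject_id: str = "unknown"
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D series")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.derivation:
            raise ValueError("derivation label must be non-empty")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class EpochTensor:
    """Matrix of one-second epochs: ``n_epochs x 100`` normalized samples."""

    values: np.ndarray
    subject_id: str = "unknown"
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != EPOCH_SAMPLES:
            raise ValueError(
                f"epoch tensor must have exactly {EPOCH_SAMPLES} columns, "
                f"got shape {self.values.shape}"
            )

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


@dataclass
class ErrorFlags:
    """Per-epoch boolean flags, true where the epoch is unusable."""

    flags: np.ndarray = field()

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1:
            raise ValueError("flags must be 1-D")


def _chebyshev_antialias(r: int) -> np.ndarray:
    """Order-8 Chebyshev type I lowpass: 0.05 dB ripple, cutoff 0.8/r (Nyquist units).

    Returned as second-order sections: the transfer-function form is
    numerically ill-conditioned at the very low relative cutoffs produced
    by large rational upsampling factors.
    """
    return sps.cheby1(8, 0.05, 0.8 / r, output="sos")


def resample_to_100hz(recording: RawRecording, zero_phase: bool = False) -> RawRecording:
    """Resample a recording to the canonical 100 Hz rate by decimation.

    An order-8 Chebyshev type I lowpass (0.05 dB passband ripple, normalized
    cutoff 0.8/r for rate-reduction factor r) guards against aliasing before
    every r-th sample is kept.  Rates that are not integer multiples of
    100 Hz are handled by rational resampling: zero-stuff by L, filter with
    the same Chebyshev design at cutoff 0.8/max(L, M), keep every M-th
    sample, where fs/100 = M/L in lowest terms.

    Parameters
    ----------
    recording : RawRecording
        Input at any rate >= 100 Hz.
    zero_phase : bool
        Apply the anti-aliasing filter forward-backward instead of forward
        only.  Off by default: plain forward filtering is the standard
        decimation routine.

    Returns
    -------
    RawRecording
        The same recording at fs = 100 Hz.
    """
    if not np.all(np.isfinite(recording.samples)):
        raise ValueError("recording contains non-finite samples")
    if recording.fs < TARGET_FS:
        raise UnsupportedRateError(
            f"fs = {recording.fs} Hz < {TARGET_FS} Hz; upsampling unsupported"
        )
    if math.isclose(recording.fs, TARGET_FS):
        return replace(recording, samples=recording.samples.copy(), fs=TARGET_FS)

    ratio = Fraction(recording.fs / TARGET_FS).limit_denominator(1000)
    m, l = ratio.numerator, ratio.denominator  # fs * l / m = 100
    sos = _chebyshev_antialias(max(l, m))
    if l == 1:
        x = recording.samples
    else:
        x = np.zeros(recording.samples.size * l)
        x[::l] = recording.samples * l  # compensate zero-stuffing energy loss
    y = sps.sosfiltfilt(sos, x) if zero_phase else sps.sosfilt(sos, x)
    out = y[::m]
    logger.info(
        "resampled %s: %.6g Hz -> 100 Hz (L=%d, M=%d)",
        recording.subject_id, recording.fs, l, m,
    )
    return replace(recording, samples=out, fs=TARGET_FS)


def zscore_normalize(recording: RawRecording) -> RawRecording:
    """Subtract the mean and divide by the population standard deviation.

    Normalization is computed over the whole recording, before epoching, so
    relative amplitude differences between epochs are preserved.

    Raises
    ------
    DegenerateSignalError
        If the signal is constant (zero standard deviation).
    """
    mu = recording.samples.mean()
    sd = recording.samples.std()  # population convention (divide by n)
    if sd == 0:
        raise DegenerateSignalError("constant signal cannot be z-scored")
    return replace(recording, samples=(recording.samples - mu) / sd)


def segment_epochs(recording: RawRecording) -> EpochTensor:
    """Cut a 100 Hz recording into contiguous, non-overlapping one-second epochs.

    A trailing remainder shorter than one second is dropped, never padded.

    Raises
    ------
    EmptyTensorError
        If the recording holds fewer than 100 samples.
    """
    if not math.isclose(recording.fs, TARGET_FS):
        raise ValueError(f"segment_epochs requires fs = 100 Hz, got {recording.fs}")
    n = recording.samples.size // EPOCH_SAMPLES
    if n == 0:
        raise EmptyTensorError("recording shorter than one epoch")
    values = recording.samples[: n * EPOCH_SAMPLES].reshape(n, EPOCH_SAMPLES)
    return EpochTensor(values=values.copy(), subject_id=recording.subject_id,
                       start_time=recording.start_time)


def flag_flatline_blocks(tensor: EpochTensor, amplitude_eps: float = 1e-3) -> ErrorFlags:
    """Flag one-minute blocks whose signal never leaves the near-zero band.

    A stretch of near-zero signal is read as electrode detachment.  The
    epoch axis is scanned in consecutive, non-overlapping sixty-epoch
    blocks; a block in which every sample satisfies ``|value| <
    amplitude_eps`` is flagged erroneous in full, and scanning restarts at
    the next block.  A trailing partial block can never complete sixty
    consecutive flat epochs and is left unflagged.

    Parameters
    ----------
    tensor : EpochTensor
        Epoch matrix in normalized units.
    amplitude_eps : float
        Near-zero amplitude threshold (normalized units).  The rule itself
        does not quantify "close to zero"; 1e-3 of a unit-variance signal
        is far below physiological EEG background.
    """
    if not amplitude_eps > 0:
        raise ValueError("amplitude_eps must be positive")
    n = tensor.n_epochs
    flags = np.zeros(n, dtype=bool)
    epoch_flat = np.all(np.abs(tensor.values) < amplitude_eps, axis=1)
    for start in range(0, n - FLATLINE_BLOCK_EPOCHS + 1, FLATLINE_BLOCK_EPOCHS):
        block = slice(start, start + FLATLINE_BLOCK_EPOCHS)
        if epoch_flat[block].all():
            flags[block] = True
    return ErrorFlags(flags=flags)


def preprocess_recording(recording: RawRecording,
                         amplitude_eps: float = 1e-3,
                         zero_phase: bool = False) -> tuple[EpochTensor, ErrorFlags]:
    """Full conditioning chain: resample -> z-score -> epoch -> flatline flags."""
    rec = resample_to_100hz(recording, zero_phase=zero_phase)
    rec = zscore_normalize(rec)
    tensor = segment_epochs(rec)
    flags = flag_flatline_blocks(tensor, amplitude_eps=amplitude_eps)
    return tensor, flags
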