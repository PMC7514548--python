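"""Synthetic CAP-structured EEG with ground-truth annotations.

The generator is an honest stand-in for real polysomnography, not a claim
about EEG physiology: it reproduces the *population statistics* of CAP
(phase durations of 2-60 s, a mean cycle duration near 26.9 s, sequences
of on average 5.6 cycles separated by long quiescent stretches) on top of
a 1/f colored-noise background, with A phases carrying a band-limited
burst whose amplitude is a difficulty knob.  Every recording ships with
its true per-second phase labels and the CAP cycle vector obtained by
running the rule-based scorer on those labels, so generator and scorer are
consistent by construction.

Phase-track layout: each CAP sequence is emitted as ``n`` cycles (pairs of
valid A and B runs) followed by one terminal valid A run and an
inter-sequence B gap longer than 60 s.  The terminal A run closes no cycle
— the gap's B run is too long to be a valid phase — so the scorer flags
exactly ``n`` cycles per sequence and the long gap cleanly separates
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .cap_cycles import CAPCyclesVector, score_cap_cycles
from .evaluation import SubjectData
from .signal_prep import (
    EpochTensor, ErrorFlags, RawRecording, flag_flatline_blocks,
    segment_epochs, zscore_normalize,
)


@dataclass(frozen=True)
class SimParams:
    """Knobs of the synthetic corpus.

    Duration laws are uniform on ``[2, 2*mean - 2]`` seconds, i.e. uniform
    with lower bound at the minimum valid phase duration and upper bound
    set by the target mean; cycles per sequence are ``2 + Poisson(mean - 2)``
    so the minimum CAP-sequence requirement is always met.
    """

    duration_s: int = 600
    fs: float = 100.0
    a_mean_s: float = 8.0            # mean A-phase duration
    b_mean_s: float = 18.9           # mean in-sequence B-phase duration
    cycles_per_sequence_mean: float = 5.6
    gap_range_s: tuple[float, float] = (65.0, 120.0)  # inter-sequence B gap
    snr: float = 4.0                 # A-burst amplitude ratio (difficulty knob)
    noise_exponent: float = 1.0      # background 1/f^beta spectral slope
    burst_band_hz: tuple[float, float] = (0.5, 4.0)
    fast_band_hz: tuple[float, float] = (8.0, 12.0)
    fast_weight: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for mean in (self.a_mean_s, self.b_mean_s):
            if not 2.0 <= mean <= 60.0:
                raise ValueError("phase duration means must lie in [2, 60] s")
        if self.cycles_per_sequence_mean < 2:
            raise ValueError("cycles per sequence mean must be >= 2")
        if self.gap_range_s[0] <= 60.0:
            raise ValueError("inter-sequence gaps must exceed 60 s")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")

    @property
    def cycle_mean_s(self) -> float:
        """Configured mean CAP cycle (A + B) duration."""
        return self.a_mean_s + self.b_mean_s


@dataclass
class SyntheticRecording:
    """A generated recording with its ground truth."""

    recording: RawRecording
    phase_labels: np.ndarray          # per-second, 1 = A
    cycle_vector: CAPCyclesVector     # scorer output on the true labels
    params: SimParams
    cycles_per_sequence: list[int] = field(default_factory=list)


def _draw_duration(rng: np.random.Generator, mean_s: float) -> int:
    """Integer phase duration from the uniform-[2, 2*mean-2] law."""
    hi = max(2.0, 2.0 * mean_s - 2.0)
    return int(np.clip(np.rint(rng.uniform(2.0, hi)), 2, 60))


def simulate_phase_track(params: SimParams,
                         rng: np.random.Generator | None = None,
                         return_meta: bool = False):
    """Per-second A/B label track with CAP-sequence structure.

    Deterministic given ``params.seed`` (or the supplied generator).  With
    ``return_meta=True`` also returns the list of cycle counts of the
    fully emitted sequences.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    pieces: list[np.ndarray] = []
    meta: list[int] = []
    total = 0

    def emit(label: int, dur: int) -> None:
        nonlocal total
        pieces.append(np.full(dur, label, dtype=np.int8))
        total += dur

    emit(0, int(rng.uniform(*params.gap_range_s)))
    while total < params.duration_s:
        n_cycles = 2 + int(rng.poisson(params.cycles_per_sequence_mean - 2.0))
        for _ in range(n_cycles):
            emit(1, _draw_duration(rng, params.a_mean_s))
            emit(0, _draw_duration(rng, params.b_mean_s))
        emit(1, _draw_duration(rng, params.a_mean_s))  # terminal A, closes no cycle
        emit(0, int(rng.uniform(*params.gap_range_s)))
        if total <= params.duration_s + 1:  # sequence fully inside the record
            meta.append(n_cycles)
    labels = np.concatenate(pieces)[: params.duration_s]
    return (labels, meta) if return_meta else labels


def _unit_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^beta colored Gaussian noise with unit variance."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    colored = np.fft.irfft(spec * scale, n)
    return colored / colored.std()


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Band-limited Gaussian noise with unit variance."""
    nyq = fs / 2.0
    b, a = sps.butter(4, [band[0] / nyq, band[1] / nyq], btype="bandpass")
    x = sps.lfilter(b, a, rng.standard_normal(n))
    return x / x.std()


def _burst_envelope(labels: np.ndarray, fs: float, ramp_s: float = 0.25) -> np.ndarray:
    """Per-sample A-phase mask with raised-cosine onset/offset ramps."""
    mask = np.repeat(labels.astype(np.float64), int(fs))
    ramp = int(ramp_s * fs)
    if ramp > 1:
        kernel = np.hanning(2 * ramp + 1)
        kernel /= kernel.sum()
        mask = np.convolve(mask, kernel, mode="same")
    return mask


def synthesize_eeg(labels: np.ndarray, params: SimParams,
                   rng: np.random.Generator | None = None,
                   subject_id: str = "synthetic") -> RawRecording:
    """EEG-like series for a label track: colored background plus A bursts.

    The burst is band-limited noise (slow band plus a weaker fast
    component) with RMS ``params.snr`` relative to the unit-variance
    background, gated by the A-phase envelope.  ``snr=0`` produces a pure
    null recording in which A and B epochs are statistically identical.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    labels = np.asarray(labels).astype(np.int8).ravel()
    n = labels.size * int(params.fs)
    background = _unit_noise(rng, n, params.noise_exponent)
    if params.snr > 0:
        slow = _band_noise(rng, n, params.fs, params.burst_band_hz)
        fast = _band_noise(rng, n, params.fs, params.fast_band_hz)
        burst = slow + params.fast_weight * fast
        burst *= params.snr / burst.std()
        signal = background + _burst_envelope(labels, params.fs) * burst
    else:
        signal = background
    return RawRecording(samples=signal, fs=params.fs, derivation="C4-A1",
                        subject_id=subject_id)


def make_recording(params: SimParams, subject_id: str = "synthetic",
                   rng: np.random.Generator | None = None) -> SyntheticRecording:
    """One synthetic subject: signal, phase truth and scored cycle truth."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    labels, meta = simulate_phase_track(params, rng=rng, return_meta=True)
    recording = synthesize_eeg(labels, params, rng=rng, subject_id=subject_id)
    cycles = score_cap_cycles(labels)
    return SyntheticRecording(recording=recording, phase_labels=labels,
                              cycle_vector=cycles, params=params,
                              cycles_per_sequence=meta)


def make_dataset(n_subjects: int, per_subject_duration_s: int | None = None,
                 params: SimParams | None = None,
                 seed: int = 0) -> list[SyntheticRecording]:
    """A corpus of independent synthetic subjects from one master seed.

    The master seed fans out to per-subject seeds through a fixed
    ``SeedSequence`` split, so regenerating with the same seed reproduces
    the corpus exactly and different subjects are pairwise independent.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = params or SimParams()
    if per_subject_duration_s is not None:
        params = replace(params, duration_s=per_subject_duration_s)
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        make_recording(params, subject_id=f"synthetic-{i:02d}",
                       rng=np.random.default_rng(child))
        for i, child in enumerate(children)
    ]


def to_subject_data(synth: SyntheticRecording,
                    amplitude_eps: float = 1e-3) -> SubjectData:
    """Preprocess a synthetic recording into evaluation-ready epochs."""
    rec = zscore_normalize(synth.recording)
    tensor: EpochTensor = segment_epochs(rec)
    flags: ErrorFlags = flag_flatline_blocks(tensor, amplitude_eps=amplitude_eps)
    n = tensor.n_epochs
    return SubjectData(
        subject_id=synth.recording.subject_id,
        epochs=tensor.values,
        phase_labels=synth.phase_labels[:n],
        cycle_truth=(synth.cycle_vector.flags[:n] == 1).astype(np.int8),
        error_flags=flags.flags,
    )
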