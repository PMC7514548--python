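"""Rule-based scoring of CAP cycles from a per-second A/B phase sequence.

Terzano's scoring rules, in the form applied here:

* a phase (A or B) is *valid* when it lasts between 2 and 60 seconds;
* a *CAP cycle* is a valid A phase immediately followed by a valid B phase;
* a *CAP sequence* is a chain of two or more consecutive CAP cycles (each
  cycle's B phase immediately followed by the next cycle's A phase).

The scorer walks the run-length decomposition of the label sequence as a
small finite state machine: all epochs start as non-CAP, candidate cycles
are identified, and every maximal chain of at least ``min_cycles_per_sequence``
consecutive candidates has all of its epochs promoted to CAP.  A trailing
valid A run with no valid B after it closes no cycle.  Epochs flagged
erroneous (flatline blocks) break chains: a cycle overlapping an erroneous
stretch is discarded, and erroneous epochs are marked as such in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Output codes of the per-epoch CAP vector.
NON_CAP = 0
CAP = 1
ERRONEOUS = 2

#: Valid phase duration bounds (seconds).
MIN_PHASE_S = 2
MAX_PHASE_S = 60

#: Label codes of the phase sequence.
B_PHASE = 0
A_PHASE = 1


@dataclass(frozen=True)
class PhaseRun:
    """One maximal homogeneous run of the label sequence."""

    label: int          # 1 = A, 0 = B
    start_epoch: int
    duration_s: int

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("run duration must be positive")
        if self.label not in (A_PHASE, B_PHASE):
            raise ValueError("run label must be 0 (B) or 1 (A)")

    @property
    def end_epoch(self) -> int:
        """Exclusive end index."""
        return self.start_epoch + self.duration_s


@dataclass
class CAPCyclesVector:
    """Per-epoch flags: NON_CAP (0), CAP (1) or ERRONEOUS (2)."""

    flags: np.ndarray

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=np.int8)
        if self.flags.ndim != 1:
            raise ValueError("flags must be 1-D")

    @property
    def cap_mask(self) -> np.ndarray:
        return self.flags == CAP


def runs_from_labels(labels: np.ndarray) -> list[PhaseRun]:
    """Run-length decomposition of a binary label sequence, in order.

    The runs tile the sequence: durations sum to its length, and expanding
    them reproduces the labels exactly.
    """
    labels = np.asarray(labels).astype(np.int8).ravel()
    if labels.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [labels.size]])
    return [PhaseRun(int(labels[s]), int(s), int(e - s))
            for s, e in zip(starts, ends)]


def is_valid_phase(run: PhaseRun) -> bool:
    """True when the run's duration lies within the 2-60 s scoring bounds."""
    return MIN_PHASE_S <= run.duration_s <= MAX_PHASE_S


def score_cap_cycles(labels: np.ndarray,
                     min_cycles_per_sequence: int = 2,
                     error_flags: np.ndarray | None = None) -> CAPCyclesVector:
    """Convert a per-second A/B sequence into the per-second CAP vector.

    Parameters
    ----------
    labels : ndarray
        Per-second labels in {0, 1} (1 = A).
    min_cycles_per_sequence : int
        Number of consecutive cycles a chain needs before its epochs are
        flagged CAP.  The normative CAP-sequence definition requires 2;
        setting 1 flags every valid isolated cycle.
    error_flags : ndarray of bool, optional
        Per-epoch erroneous markers (flatline blocks).  Erroneous epochs
        are reported as ERRONEOUS and any cycle touching them is discarded.

    Returns
    -------
    CAPCyclesVector
    """
    labels = np.asarray(labels).astype(np.int8).ravel()
    if min_cycles_per_sequence < 1:
        raise ValueError("min_cycles_per_sequence must be >= 1")
    n = labels.size
    flags = np.full(n, NON_CAP, dtype=np.int8)
    if error_flags is not None:
        error_flags = np.asarray(error_flags, dtype=bool).ravel()
        if error_flags.size != n:
            raise ValueError("error_flags must align with labels")
    runs = runs_from_labels(labels)

    def run_clean(run: PhaseRun) -> bool:
        if error_flags is None:
            return True
        return not error_flags[run.start_epoch:run.end_epoch].any()

    # Candidate cycle at run index i: valid clean A run followed by a valid
    # clean B run.
    candidate = [
        i + 1 < len(runs)
        and runs[i].label == A_PHASE and runs[i + 1].label == B_PHASE
        and is_valid_phase(runs[i]) and is_valid_phase(runs[i + 1])
        and run_clean(runs[i]) and run_clean(runs[i + 1])
        for i in range(len(runs))
    ]

    # Maximal chains of consecutive candidates: cycle at run i chains with
    # the cycle at run i + 2 (its B run is immediately followed by that
    # cycle's A run, since runs alternate).
    i = 0
    while i < len(runs):
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j + 2 < len(runs) and candidate[j + 2]:
            j += 2
        n_cycles = (j - i) // 2 + 1
        if n_cycles >= min_cycles_per_sequence:
            flags[runs[i].start_epoch:runs[j + 1].end_epoch] = CAP
        i = j + 2

    if error_flags is not None:
        flags[error_flags] = ERRONEOUS
    return CAPCyclesVector(flags=flags)
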