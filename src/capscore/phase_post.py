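"""Isolated-phase correction of a hard A/B label sequence.

Most classifier mistakes are single short blips: a one- or two-second run
of one phase sandwiched between two valid runs of the opposite phase.
Since the minimum valid CAP phase lasts two seconds, such a blip can never
stand as a phase of its own and is flipped to match its surroundings.

Labels are integer arrays with 1 = A phase and 0 = B phase (the package
convention, see :mod:`capscore.cap_cycles` for run utilities).
"""

from __future__ import annotations

import numpy as np

from .cap_cycles import runs_from_labels

#: Minimum duration (s) of a run that can flank — and absorb — a blip.
MIN_VALID_FLANK_S = 2


def correct_isolated_phases(labels: np.ndarray,
                            exactly_two: bool = False) -> np.ndarray:
    """Flip isolated short runs into the surrounding phase.

    A maximal run of duration at most two seconds whose two neighbouring
    runs both last at least two seconds is considered a misclassification
    and converted to the opposite phase.  All flips are decided on the
    original run decomposition and applied simultaneously — a single
    left-to-right pass with no cascading re-evaluation, so the result does
    not depend on processing order.  Runs at the sequence boundaries have
    only one flank and are never flipped.

    Parameters
    ----------
    labels : ndarray
        Per-second labels in {0, 1} (1 = A).
    exactly_two : bool
        If true, only runs of exactly two seconds are treated as isolated
        (a stricter reading); by default one-second runs count as well,
        since a shorter run is even further below the minimum valid phase
        duration.

    Returns
    -------
    ndarray
        Corrected labels, same length and dtype family as the input.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a non-empty 1-D sequence")
    runs = runs_from_labels(labels)
    out = labels.copy()
    for k in range(1, len(runs) - 1):
        run = runs[k]
        isolated = (run.duration_s == 2 if exactly_two
                    else run.duration_s <= 2)
        if not isolated:
            continue
        left, right = runs[k - 1], runs[k + 1]
        if (left.duration_s >= MIN_VALID_FLANK_S
                and right.duration_s >= MIN_VALID_FLANK_S):
            sl = slice(run.start_epoch, run.start_epoch + run.duration_s)
            out[sl] = 1 - run.label
    return out
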