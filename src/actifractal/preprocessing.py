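"""Raw 30 Hz acceleration → epoch activity counts, and count rebinning.

Per sample the Euclidean magnitude of the tri-axial acceleration is computed,
gravity (1 g) is subtracted from the magnitude (scalar correction, not vector
filtering), the result is binarized at strictly greater than 0.1 g, and the
binary values are summed over non-overlapping blocks of τ = ν·δ samples.  A
trailing partial block is discarded, so counts are integers in [0, τ].
"""

from __future__ import annotations

import numpy as np

from .exceptions import InputError, ParameterError
from .series import (
    ActivityCountSeries,
    RawAccelerationSeries,
    RESOLUTION_LABELS,
    VALID_DELTAS,
)

#: Activity threshold on the gravity-corrected magnitude, in g.
DEFAULT_THRESHOLD_G = 0.1


def accel_to_counts(
    raw: RawAccelerationSeries, delta: int, threshold: float = DEFAULT_THRESHOLD_G
) -> ActivityCountSeries:
    """Threshold-crossing counts per epoch of ``delta`` seconds.

    The comparison is strict: a sample at exactly ``threshold`` above gravity
    contributes 0.  Epochs are aligned to the first sample; ``start_time``
    carries any clock offset.
    """
    if delta not in VALID_DELTAS:
        raise ParameterError(f"delta must be one of {VALID_DELTAS}, got {delta}")
    tau = int(round(raw.nu * delta))
    n = len(raw)
    if n == 0:
        raise InputError("empty acceleration record")
    if n < tau:
        raise InputError(
            f"record of {n} samples is shorter than one epoch (τ = {tau} samples)"
        )
    bad = ~np.isfinite(raw.samples)
    if bad.any():
        idx = int(np.argwhere(bad.any(axis=1))[0][0])
        raise InputError(f"non-finite acceleration sample at index {idx}")
    magnitude = np.linalg.norm(raw.samples, axis=1) - 1.0  # gravity-corrected, in g
    binary = magnitude > threshold
    n_epochs = n // tau
    counts = binary[: n_epochs * tau].reshape(n_epochs, tau).sum(axis=1)
    return ActivityCountSeries(
        counts=counts.astype(np.int64),
        delta=delta,
        start_time=raw.start_time,
        label=RESOLUTION_LABELS[delta],
    )


def rebin_counts(counts: ActivityCountSeries, delta_target: int) -> ActivityCountSeries:
    """Sum blocks of ``delta_target/delta`` epochs; trailing partial block dropped."""
    if delta_target == counts.delta:
        return ActivityCountSeries(
            counts.counts.copy(), counts.delta, counts.start_time, counts.label
        )
    if delta_target % counts.delta:
        raise ParameterError(
            f"target epoch {delta_target}s is not a multiple of {counts.delta}s"
        )
    k = delta_target // counts.delta
    n = len(counts) // k
    summed = counts.counts[: n * k].reshape(n, k).sum(axis=1)
    return ActivityCountSeries(
        counts=summed,
        delta=delta_target,
        start_time=counts.start_time,
        label=RESOLUTION_LABELS.get(delta_target),
    )
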