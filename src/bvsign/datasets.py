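"""Built-in example datasets.

Currently one fixture: eye-refraction deviations for ten adult sons and
their fathers (northern-Finland birth cohort of 1966).  Positive
refraction values indicate long-sightedness, negative values
near-sightedness.  The analysed bivariate sample is the pair of
son-minus-father deviations (right eye, left eye); the raw four
refraction columns are stored alongside, and the deviations are
re-derived from them on access as a transcription guard.
"""

from __future__ import annotations

import numpy as np

from .scores import BivariateSample

__all__ = ["builtin_dataset", "available_datasets"]

# columns: son right, son left, father right, father left
_REFRACTION_RAW = np.array(
    [
        [+0.50, +0.50, -0.62, -1.25],
        [-2.75, -3.37, -1.00, -1.00],
        [+0.25, +0.00, +2.75, +2.75],
        [-0.50, -0.25, -2.00, -1.50],
        [+0.75, +0.50, +0.50, +0.63],
        [-2.50, -2.75, +0.50, +0.50],
        [+0.50, +0.25, +2.00, +2.50],
        [-1.00, -3.12, -2.50, -2.62],
        [-3.37, -2.37, -1.75, -1.75],
        [+0.50, +0.50, +1.50, +2.25],
    ]
)

# son-minus-father deviation per eye: x1 = right, x2 = left
_REFRACTION_DEVIATIONS = np.array(
    [
        [+1.12, +1.75],
        [-1.75, -2.37],
        [-2.50, -2.75],
        [+1.50, +1.25],
        [+0.25, -0.13],
        [-3.00, -3.25],
        [-1.50, -2.25],
        [+1.50, -0.50],
        [-1.62, -0.62],
        [-1.00, -1.75],
    ]
)


def _refraction() -> BivariateSample:
    derived = _REFRACTION_RAW[:, :2] - _REFRACTION_RAW[:, 2:]
    if not np.allclose(derived, _REFRACTION_DEVIATIONS, atol=5e-3):
        raise AssertionError(
            "refraction fixture self-check failed: stored deviations do not "
            "match son-minus-father differences of the raw columns"
        )
    return BivariateSample(points=_REFRACTION_DEVIATIONS.copy())


_DATASETS = {"refraction": _refraction}


def available_datasets() -> tuple[str, ...]:
    return tuple(sorted(_DATASETS))


def builtin_dataset(name: str) -> BivariateSample:
    """Return a built-in dataset by name (currently ``"refraction"``)."""
    try:
        builder = _DATASETS[name]
    except KeyError:
        raise KeyError(
            f"unknown dataset {name!r}; available fixtures: {', '.join(available_datasets())}"
        ) from None
    return builder()
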