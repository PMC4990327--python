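"""Mean-centering and three-level discretization of expression matrices.

The method's first stage turns a cohort's normalized log2 expression matrix
into per-sample ternary profiles: for every probe the cohort mean is
subtracted, and each deviation is coded +1 (above), -1 (below) or 0 (near
the mean) depending on where it falls relative to +/- ``t * sigma_g``, where
``sigma_g`` is the probe's standard deviation and ``t`` defaults to 0.43.
That cut is the standard-normal tercile: under Gaussian deviations each of
the three codes occurs with probability ~1/3, which is exactly why 0.43 was
chosen.  Because both the mean and sigma are per-probe, the codes are
invariant under per-probe shifts and positive rescalings of the input —
the property that makes profiles comparable across tissues and platforms.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .containers import (
    DeviationMatrix,
    DiscretizationParams,
    ExpressionMatrix,
    TernaryMatrix,
)

__all__ = [
    "equal_tercile_threshold",
    "compute_deviations",
    "discretize",
    "discretize_matrix",
]


def equal_tercile_threshold() -> float:
    """The threshold factor that makes the three codes equally likely.

    Returns the z* with ``P(-z* < Z < z*) = 1/3`` for a standard normal Z,
    i.e. the inverse normal CDF at 2/3 (~0.4307, quoted as 0.43).
    """
    return float(norm.ppf(2.0 / 3.0))


def compute_deviations(
    x: ExpressionMatrix, params: DiscretizationParams | None = None
) -> DeviationMatrix:
    """Subtract each probe's cohort mean and record the per-probe sigma.

    Parameters
    ----------
    x
        Expression matrix with at least two samples (a one-sample cohort has
        no meaningful mean or spread to deviate from).
    params
        Supplies ``std_mode`` — whether sigma uses the sample (n-1, default)
        or population (n) denominator.

    Returns
    -------
    DeviationMatrix
        Same shape and identifiers as ``x``; every probe's deviations sum
        to zero.
    """
    params = params or DiscretizationParams()
    if x.n_samples < 2:
        raise ValueError(
            f"need at least 2 samples to compute cohort deviations, got {x.n_samples}"
        )
    mean = x.values.mean(axis=1, keepdims=True)
    dev = x.values - mean
    sigma = dev.std(axis=1, ddof=params.ddof)
    return DeviationMatrix(x.probe_ids, x.sample_ids, dev, sigma, std_mode=params.std_mode)


def discretize(d: DeviationMatrix, params: DiscretizationParams | None = None) -> TernaryMatrix:
    """Code deviations as -1 / 0 / +1 relative to ``threshold_factor * sigma``.

    A deviation strictly above ``+t*sigma_g`` codes +1, strictly below
    ``-t*sigma_g`` codes -1, and anything in between — including values
    exactly on a boundary — codes 0.  Probes with zero spread produce
    all-zero codes (they carry no cohort information).
    """
    params = params or DiscretizationParams()
    thresh = params.threshold_factor * d.probe_sigma[:, None]
    codes = np.zeros(d.deviations.shape, dtype=np.int8)
    codes[d.deviations > thresh] = 1
    codes[d.deviations < -thresh] = -1
    codes[d.probe_sigma == 0, :] = 0
    return TernaryMatrix(d.probe_ids, d.sample_ids, codes)


def discretize_matrix(
    x: ExpressionMatrix, params: DiscretizationParams | None = None
) -> TernaryMatrix:
    """Full first stage: mean-center then discretize in one call."""
    params = params or DiscretizationParams()
    return discretize(compute_deviations(x, params), params)
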