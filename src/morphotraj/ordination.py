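"""PCA of Procrustes coordinates and broken-stick component selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .superimposition import AlignedSample


@dataclass
class PcaResult:
    eigenvalues: np.ndarray         # descending, nonnegative
    variance_fractions: np.ndarray  # over nonzero components, sums to 1
    scores: np.ndarray              # (n, m)
    loadings: np.ndarray            # (2k, m), orthonormal columns
    mean: np.ndarray                # (2k,)
    n_significant: int              # broken stick

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


_NULL_EIGENVALUE_RTOL = 1e-12  # relative to the largest eigenvalue


def pca(sample: AlignedSample | np.ndarray) -> PcaResult:
    """Eigendecomposition of the sample covariance (divisor n-1) of the
    Procrustes coordinates.

    A GPA leaves ~4 near-null dimensions (two translations, rotation,
    size) in a 2D data set; eigenvalues below ``1e-12`` of the largest are
    treated as null and excluded both from the variance fractions and from
    the broken-stick pool.  Column signs follow a deterministic convention
    (largest-magnitude loading positive) so stored results are stable.
    """
    data = sample.procrustes_coords if isinstance(sample, AlignedSample) else np.asarray(sample)
    n = data.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    mean = data.mean(axis=0)
    centered = data - mean
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    if evals[0] <= 0:
        raise ValueError("rank-0 data: no shape variation")
    nonzero = evals > _NULL_EIGENVALUE_RTOL * evals[0]
    evals, evecs = evals[nonzero], evecs[:, nonzero]
    # deterministic sign: largest-|loading| entry positive in each column
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
    fractions = evals / evals.sum()
    return PcaResult(
        eigenvalues=evals,
        variance_fractions=fractions,
        scores=centered @ evecs,
        loadings=evecs,
        mean=mean,
        n_significant=broken_stick_significant(evals),
    )


def broken_stick_expected(p: int) -> np.ndarray:
    """Broken-stick expected fractions b_i = (1/p) * sum_{j=i..p} 1/j."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick_significant(eigenvalues: np.ndarray) -> int:
    """Number of leading components whose observed variance fraction
    exceeds the broken-stick expectation.

    Retention stops at the first component that fails, even if a later
    one would pass (the initial-run rule).
    """
    evals = np.asarray(eigenvalues, dtype=float)
    if evals.size == 0 or evals[0] <= 0:
        raise ValueError("need at least one positive eigenvalue")
    if np.any(np.diff(evals) > 1e-12 * evals[0]):
        raise ValueError("eigenvalues must be in descending order")
    p = evals.size
    fractions = evals / evals.sum()
    expected = broken_stick_expected(p)
    count = 0
    for obs, exp in zip(fractions, expected):
        if obs > exp:
            count += 1
        else:
            break
    return count
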