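"""Allometric regression of shape on size and scalar shape variables.

The multivariate regression of Procrustes coordinates on log centroid
size yields (i) the allometric coefficient vector, (ii) the percentage of
shape variation it predicts, with a permutation test, and (iii) the
*regression score* — the projection of each shape onto the unit-length
coefficient vector — which serves as a univariate shape variable for the
heterochrony comparisons.  The *Euclidean distance* variable (Procrustes
distance to a designated smallest specimen) is the independent second
shape variable used to cross-check regression-score results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .superimposition import AlignedSample, procrustes_distance


@dataclass
class RegressionResult:
    coefficient_vector: np.ndarray       # (2k,) shape change per unit log CS
    percent_predicted: float             # in [0, 100]
    permutation_p: Optional[float]
    regression_scores: np.ndarray        # (n,)
    pooled: bool
    grand_mean: np.ndarray               # (2k,)
    n_permutations: int = 0
    group_means: Optional[dict] = None

    @property
    def unit_axis(self) -> np.ndarray:
        norm = np.linalg.norm(self.coefficient_vector)
        if norm == 0:
            raise ValueError("zero coefficient vector: no allometric axis")
        return self.coefficient_vector / norm


@dataclass
class ShapeVariableSeries:
    variable: str                        # "regression_score" | "euclidean_distance"
    values: np.ndarray
    specimen_ids: list[str]
    reference_id: Optional[str] = None

    def value_of(self, specimen_id: str) -> float:
        return float(self.values[self.specimen_ids.index(specimen_id)])


def _within_group_center(arr: np.ndarray, groups: Sequence) -> np.ndarray:
    out = np.array(arr, dtype=float)
    for g in set(groups):
        idx = [i for i, gi in enumerate(groups) if gi == g]
        out[idx] = out[idx] - out[idx].mean(axis=0)
    return out


def regress_shape_on_size(sample: AlignedSample, groups: Optional[Sequence] = None,
                          n_perm: int = 10000, seed: int = 0) -> RegressionResult:
    """Multivariate regression of Procrustes coordinates on log centroid
    size; optionally pooled within groups.

    The pooled variant centers both shape and log CS within each group
    before fitting one common slope (each group then needs >= 2
    specimens).  The permutation test shuffles the size values against
    the shapes (within groups when pooled) and reports
    p = (b + 1) / (n_perm + 1), b counting permutations whose predicted
    sum of squares reaches the observed one.
    """
    Y = sample.procrustes_coords
    x = sample.log_cs
    n = Y.shape[0]
    if n < 3:
        raise ValueError("regression needs at least 3 specimens")
    pooled = groups is not None
    group_means = None
    if pooled:
        groups = list(groups)
        if len(groups) != n:
            raise ValueError("one group label per specimen required")
        counts = {g: groups.count(g) for g in set(groups)}
        small = [g for g, c in counts.items() if c < 2]
        if small:
            raise ValueError(f"pooled regression requires >= 2 specimens per group; bad: {small}")
        Yc = _within_group_center(Y, groups)
        xc = _within_group_center(x, groups)
        group_means = {
            g: {
                "shape": Y[[i for i, gi in enumerate(groups) if gi == g]].mean(axis=0),
                "log_cs": float(np.mean([x[i] for i, gi in enumerate(groups) if gi == g])),
            }
            for g in set(groups)
        }
    else:
        Yc = Y - Y.mean(axis=0)
        xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("zero size variance: regression on log CS undefined")
    coef = (xc @ Yc) / sxx                       # (2k,)
    ss_tot = float((Yc ** 2).sum())
    ss_pred = sxx * float(coef @ coef)
    percent = 100.0 * ss_pred / ss_tot

    p_value = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        yty = Yc.T  # cached transpose
        hits = 0
        for _ in range(n_perm):
            if pooled:
                xp = np.array(xc)
                for g in set(groups):
                    idx = np.array([i for i, gi in enumerate(groups) if gi == g])
                    xp[idx] = rng.permutation(xp[idx])
            else:
                xp = rng.permutation(xc)
            bp = (yty @ xp) / float(xp @ xp)
            if float(xp @ xp) * float(bp @ bp) >= ss_pred - 1e-12 * ss_tot:
                hits += 1
        p_value = (hits + 1) / (n_perm + 1)

    result = RegressionResult(
        coefficient_vector=coef,
        percent_predicted=percent,
        permutation_p=p_value,
        regression_scores=np.zeros(n),
        pooled=pooled,
        grand_mean=Y.mean(axis=0),
        n_permutations=int(n_perm or 0),
        group_means=group_means,
    )
    result.regression_scores = regression_score(Y, result)
    return result


def regression_score(shapes: np.ndarray, result: RegressionResult) -> np.ndarray:
    """Project shapes (rows, from the same GPA as the fit) onto the
    unit-normalized allometric axis, after subtracting the grand mean.
    The score is therefore in Procrustes units."""
    shapes = np.atleast_2d(np.asarray(shapes, dtype=float))
    return (shapes - result.grand_mean) @ result.unit_axis


def euclidean_distance_variable(sample: AlignedSample, reference_id: str
                                ) -> ShapeVariableSeries:
    """Per-specimen Procrustes (Euclidean) distance to a reference
    specimen, whose own value is exactly zero.  The reference is
    conventionally the smallest specimen in the sample, anchoring the
    distance axis at the bottom of the size range."""
    ref = sample.shape_of(reference_id)
    values = np.array([procrustes_distance(row, ref) for row in sample.procrustes_coords])
    return ShapeVariableSeries(
        variable="euclidean_distance",
        values=values,
        specimen_ids=list(sample.specimen_ids),
        reference_id=reference_id,
    )


def euclidean_distances_to(shapes: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Distance variable for arbitrary shape rows against a reference
    shape vector (used to score reconstructed ancestors)."""
    shapes = np.atleast_2d(np.asarray(shapes, dtype=float))
    return np.linalg.norm(shapes - np.asarray(reference, dtype=float), axis=1)


def trajectory_slope(juvenile: tuple[float, float], adult: tuple[float, float]) -> float:
    """Slope of a two-stage trajectory in (log CS, shape variable) space:
    change of the shape variable per unit log centroid size."""
    (x0, y0), (x1, y1) = juvenile, adult
    if x1 == x0:
        raise ZeroDivisionError("juvenile and adult log CS are equal: slope undefined")
    return (y1 - y0) / (x1 - x0)
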