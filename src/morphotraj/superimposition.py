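"""Generalized Procrustes analysis (GPA) for 2D landmark configurations.

GPA removes the non-shape differences between configurations: each is
centered, scaled and rotated so only shape variation remains.  Rotations
are restricted to proper rotations (det +1) by default — all specimens
must be digitized in the same orientation, and mirrored input is a data
error rather than something the fit should absorb.  Semilandmarks receive
full weight and are never slid.

The aligned coordinates are returned at unit centroid size and, by
default, orthogonally projected onto the tangent space at the consensus
so that ordinary Euclidean statistics on the coordinates approximate
Procrustes shape distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import LandmarkConfiguration, check_common_k


class GpaError(RuntimeError):
    pass


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the
    centroid.  Invariant to translation and rotation; scales linearly with
    uniform scaling."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config)
    if coords.shape[0] < 3:
        raise ValueError("centroid size needs at least 3 landmarks")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def optimal_rotation(source: np.ndarray, target: np.ndarray,
                     allow_reflection: bool = False) -> np.ndarray:
    """Orthogonal Procrustes rotation of ``source`` onto ``target``
    (both k x 2, centered).  det +1 enforced unless reflections allowed."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


@dataclass
class AlignedSample:
    """Procrustes-fitted sample: n x 2k aligned coordinates, original
    centroid sizes, (natural) log sizes, consensus shape, fit diagnostics.

    ``procrustes_coords`` rows have centroid at the origin and unit
    centroid size before tangent projection; ``consensus`` is the mean
    shape at unit centroid size.
    """

    procrustes_coords: np.ndarray          # (n, 2k)
    centroid_sizes: np.ndarray             # (n,)
    consensus: np.ndarray                  # (2k,)
    specimen_ids: list[str]
    taxa: list[str]
    stages: list[Optional[str]]
    iterations: int
    converged: bool
    tangent_projected: bool
    is_semilandmark: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.procrustes_coords.shape[0]

    @property
    def k(self) -> int:
        return self.procrustes_coords.shape[1] // 2

    @property
    def log_cs(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    def shape_of(self, specimen_id: str) -> np.ndarray:
        return self.procrustes_coords[self.index_of(specimen_id)]

    def index_of(self, specimen_id: str) -> int:
        try:
            return self.specimen_ids.index(specimen_id)
        except ValueError:
            raise KeyError(f"specimen {specimen_id!r} not in sample") from None

    def subset(self, ids: Sequence[str]) -> "AlignedSample":
        """Row subset by specimen id (no re-superimposition)."""
        idx = [self.index_of(i) for i in ids]
        return AlignedSample(
            procrustes_coords=self.procrustes_coords[idx],
            centroid_sizes=self.centroid_sizes[idx],
            consensus=self.consensus,
            specimen_ids=[self.specimen_ids[i] for i in idx],
            taxa=[self.taxa[i] for i in idx],
            stages=[self.stages[i] for i in idx],
            iterations=self.iterations,
            converged=self.converged,
            tangent_projected=self.tangent_projected,
            is_semilandmark=self.is_semilandmark,
        )


def gpa(configs: Sequence[LandmarkConfiguration], *, allow_reflection: bool = False,
        tangent_project: bool = True, full_fit: bool = True, tol: float = 1e-10,
        max_iter: int = 200, apply_scale: Optional[bool] = None) -> AlignedSample:
    """Generalized Procrustes analysis.

    Iteratively aligns every configuration to the evolving consensus until
    the consensus displacement falls below ``tol`` (max ``max_iter``
    sweeps).  With ``full_fit`` (default) each sweep also applies the
    optimal per-specimen scale toward the consensus (full Procrustes fit);
    the final coordinates are renormalized to unit centroid size so the
    aligned sample always satisfies the unit-size contract.

    TPS SCALE factors are applied to the raw coordinates before the fit
    only when present for *every* specimen (``apply_scale=None`` policy);
    set ``apply_scale`` explicitly to force either behaviour.
    """
    if len(configs) < 2:
        raise GpaError("GPA needs at least 2 configurations")
    k = check_common_k(configs)
    scales = [c.scale for c in configs]
    if apply_scale is None:
        apply_scale = all(s is not None for s in scales)
        if any(s is not None for s in scales) and not apply_scale:
            import logging
            logging.getLogger("morphotraj").warning(
                "SCALE present for some but not all specimens; ignoring all SCALE records")
    raw = []
    for c in configs:
        xy = c.coords.astype(float)
        if apply_scale and c.scale is not None:
            xy = xy * c.scale
        raw.append(xy)

    sizes = np.array([centroid_size(x) for x in raw])
    shapes = np.stack([(x - x.mean(axis=0)) / s for x, s in zip(raw, sizes)])  # (n,k,2)

    consensus = shapes[0].copy()
    consensus /= np.sqrt((consensus ** 2).sum())
    converged = False
    iterations = 0
    last_change = np.inf
    for iterations in range(1, max_iter + 1):
        for i in range(shapes.shape[0]):
            r = optimal_rotation(shapes[i], consensus, allow_reflection)
            shapes[i] = shapes[i] @ r
            if full_fit:
                beta = float((shapes[i] * consensus).sum() / (shapes[i] ** 2).sum())
                shapes[i] *= beta
        new_consensus = shapes.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus ** 2).sum())
        last_change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if last_change < tol:
            converged = True
            break
    if not converged:
        raise GpaError(
            f"GPA did not converge in {max_iter} iterations (last consensus change "
            f"{last_change:.3e})")

    # canonical orientation: principal axes of the consensus define the
    # frame, so the fit is invariant to a common rotation of the inputs
    cov = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(cov)
    rot = evecs[:, ::-1]  # major axis -> x
    if np.linalg.det(rot) < 0:
        rot[:, 1] *= -1  # proper rotation only, never a reflection
    consensus = consensus @ rot
    shapes = shapes @ rot
    # resolve the remaining 180-degree ambiguity deterministically
    j = int(np.argmax(np.abs(consensus[:, 0])))
    if consensus[j, 0] < 0:
        consensus = -consensus
        shapes = -shapes

    # unit-size contract, then optional tangent projection
    norms = np.sqrt((shapes ** 2).sum(axis=(1, 2)))
    shapes /= norms[:, None, None]
    flat = shapes.reshape(shapes.shape[0], -1)
    c = consensus.reshape(-1)
    if tangent_project:
        # orthogonal projection onto the hyperplane {z : z . c = 1}
        flat = flat + (1.0 - flat @ c)[:, None] * c[None, :]

    masks = [c_.is_semilandmark for c_ in configs if c_.is_semilandmark is not None]
    return AlignedSample(
        procrustes_coords=flat,
        centroid_sizes=sizes,
        consensus=c,
        specimen_ids=[c_.specimen_id for c_ in configs],
        taxa=[c_.taxon for c_ in configs],
        stages=[c_.stage for c_ in configs],
        iterations=iterations,
        converged=converged,
        tangent_projected=tangent_project,
        is_semilandmark=masks[0] if masks else None,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of a - b between two aligned shape vectors from a
    common GPA (the tangent-space approximation to Procrustes distance)."""
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape vectors differ in dimension: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))
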