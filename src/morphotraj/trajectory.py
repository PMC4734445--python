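"""Two-stage ontogenetic trajectories and heterochrony classification.

A trajectory is the juvenile-to-adult pair of one taxon (or of one
reconstructed hypothetical ancestor) in size-and-shape space.  Change
vectors point from juvenile to adult; angles between trajectories come
from the normalized dot product.  An ancestor-descendant change in the
adult shape variables (regression score and Euclidean distance) counts as
significant when it reaches 1.5x a confidence-interval threshold derived
from the branch-wise differences across the whole adult tree; agreement
of both variables in sign yields a paedomorphosis (both significantly
lower) or peramorphosis (both significantly higher) call, anything else
stays undetermined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .phylo import AncestralReconstruction

PAEDOMORPHOSIS = "paedomorphosis"
PERAMORPHOSIS = "peramorphosis"
UNDETERMINED = "undetermined"


@dataclass
class OntogeneticTrajectory:
    label: str
    juvenile_shape: np.ndarray
    adult_shape: np.ndarray
    juvenile_log_cs: float
    adult_log_cs: float
    is_ancestral: bool = False
    # optional scalar shape variables, keyed "regression_score"/"euclidean_distance"
    juvenile_vars: dict = field(default_factory=dict)
    adult_vars: dict = field(default_factory=dict)


@dataclass
class HeterochronyCall:
    ancestor: str
    descendant: str
    delta_rs: float
    delta_ed: float
    ci_rs: float
    ci_ed: float
    rs_significant: bool
    ed_significant: bool
    classification: str


def change_vector(traj: OntogeneticTrajectory,
                  traits: Optional[Sequence[int]] = None,
                  scores: Optional[Mapping[str, np.ndarray]] = None) -> np.ndarray:
    """Adult-minus-juvenile change vector of a trajectory.

    Without arguments the full-shape difference is returned.  With
    ``traits`` (axis indices) and ``scores`` (stage label -> score
    vectors, e.g. PCA scores), the difference is taken on those axes,
    which is how the PC1-PC2 / PC1-PC3 plane vectors are built.
    """
    if scores is not None:
        juv, adu = np.asarray(scores["juvenile"], float), np.asarray(scores["adult"], float)
    else:
        juv, adu = traj.juvenile_shape, traj.adult_shape
    if juv is None or adu is None:
        raise ValueError(f"trajectory {traj.label!r}: missing stage")
    diff = np.asarray(adu, float) - np.asarray(juv, float)
    if traits is not None:
        diff = diff[list(traits)]
    return diff


def trajectory_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two change vectors, in degrees within [0, 180]."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for a zero-length change vector")
    ua, ub = a / na, b / nb
    # 2*atan2 form is numerically exact near 0 and 180 degrees, where
    # the arccos of the dot product loses precision
    return math.degrees(2.0 * math.atan2(np.linalg.norm(ua - ub),
                                         np.linalg.norm(ua + ub)))


def trajectory_length(v: np.ndarray) -> float:
    """Euclidean norm of a change vector."""
    return float(np.linalg.norm(np.asarray(v, float)))


def ancestral_trajectories(adult_recon: AncestralReconstruction,
                           juvenile_recon: AncestralReconstruction,
                           clades: Mapping[str, Sequence[str]],
                           adult_size_recon: AncestralReconstruction,
                           juvenile_size_recon: AncestralReconstruction,
                           ) -> list[OntogeneticTrajectory]:
    """Pair reconstructed juvenile and adult states into hypothetical
    ancestral trajectories.

    ``adult_recon`` lives on the full adult tree, ``juvenile_recon`` on
    the tree pruned to the taxa with juveniles (original calibration
    retained); the size reconstructions carry log centroid sizes on the
    same trees.  ``clades`` maps a clade name to the tip labels whose
    MRCA defines it; every clade must resolve in both trees.
    """
    out = []
    for name, members in clades.items():
        try:
            a_node = adult_recon.tree.mrca(members)
            j_node = juvenile_recon.tree.mrca(members)
        except KeyError as exc:
            raise KeyError(f"clade {name!r} cannot be placed: {exc}") from exc
        out.append(OntogeneticTrajectory(
            label=name,
            juvenile_shape=juvenile_recon.state_of(j_node),
            adult_shape=adult_recon.state_of(a_node),
            juvenile_log_cs=float(juvenile_size_recon.state_of(j_node)[0]),
            adult_log_cs=float(adult_size_recon.state_of(a_node)[0]),
            is_ancestral=True,
        ))
    return out


def branch_differences(recon: AncestralReconstruction, values: np.ndarray) -> np.ndarray:
    """Child-minus-parent differences of a scalar variable over every
    branch of the reconstruction's tree (2n-2 values).

    ``values`` holds the scalar per node, indexed like
    ``recon.node_states`` rows.
    """
    tree = recon.tree
    return np.array([values[v] - values[tree.parent[v]]
                     for v in range(tree.n_nodes) if v != tree.root])


def ci_threshold(differences: np.ndarray, level: float = 0.95,
                 method: str = "t") -> float:
    """Confidence-interval half-width of branch-wise differences.

    ``method='t'`` (default): half-width of the two-sided t interval for
    the mean difference.  ``method='quantile'``: half-width of the
    empirical (1-level)/2 .. (1+level)/2 interval of the differences
    themselves — a broader, distribution-based alternative.
    """
    d = np.asarray(differences, float)
    if d.size < 2:
        raise ValueError("need at least 2 branch differences")
    if method == "t":
        half = stats.t.ppf(0.5 + level / 2, d.size - 1) * d.std(ddof=1) / math.sqrt(d.size)
        return float(half)
    if method == "quantile":
        lo, hi = np.quantile(d, [(1 - level) / 2, (1 + level) / 2])
        return float((hi - lo) / 2)
    raise ValueError(f"unknown CI method {method!r}")


def classify_heterochrony(ancestor: OntogeneticTrajectory,
                          descendant: OntogeneticTrajectory,
                          ci_rs: float, ci_ed: float,
                          factor: float = 1.5) -> HeterochronyCall:
    """Compare adult shape variables of descendant vs ancestor.

    Each delta (descendant adult minus ancestor adult) is significant
    when |delta| >= factor * CI.  Both significant and negative ->
    paedomorphosis; both significant and positive -> peramorphosis;
    anything else -> undetermined.
    """
    for traj in (ancestor, descendant):
        for key in ("regression_score", "euclidean_distance"):
            if key not in traj.adult_vars:
                raise ValueError(f"trajectory {traj.label!r} lacks adult {key}")
    d_rs = descendant.adult_vars["regression_score"] - ancestor.adult_vars["regression_score"]
    d_ed = descendant.adult_vars["euclidean_distance"] - ancestor.adult_vars["euclidean_distance"]
    rs_sig = abs(d_rs) >= factor * ci_rs
    ed_sig = abs(d_ed) >= factor * ci_ed
    if rs_sig and ed_sig and d_rs < 0 and d_ed < 0:
        cls = PAEDOMORPHOSIS
    elif rs_sig and ed_sig and d_rs > 0 and d_ed > 0:
        cls = PERAMORPHOSIS
    else:
        cls = UNDETERMINED
    return HeterochronyCall(
        ancestor=ancestor.label,
        descendant=descendant.label,
        delta_rs=float(d_rs),
        delta_ed=float(d_ed),
        ci_rs=float(ci_rs),
        ci_ed=float(ci_ed),
        rs_significant=bool(rs_sig),
        ed_significant=bool(ed_sig),
        classification=cls,
    )
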