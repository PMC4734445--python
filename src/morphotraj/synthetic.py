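"""Synthetic landmark data with known ontogenetic and phylogenetic truth.

The generator emulates the structure the pipeline assumes: each taxon has
a juvenile and an adult related by a common allometric growth vector,
adult mean shapes evolve by Brownian motion on a time-calibrated tree,
designated branches carry heterochronic shifts of known sign along the
allometric axis, and every emitted specimen is perturbed by landmark
digitization noise and an arbitrary similarity transform (which the
Procrustes fit must undo).

The base configuration is a schematic lateral archosaur skull — snout
and outline plus naris, antorbital fenestra, orbit and infratemporal
fenestra — with 20 fixed landmarks and 51 semilandmarks by default,
mirroring the lateral-view digitizing scheme standard for dinosaur
crania.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import LandmarkConfiguration
from .superimposition import centroid_size
from .tree import TimeTree
from .phylo import calibrate_branch_lengths


# ---------------------------------------------------------------------------
# base skull geometry
# ---------------------------------------------------------------------------

# landmark budget of the default 71-point scheme
_DEFAULT_FIXED = 20
_DEFAULT_SEMI = {"outline": 23, "naris": 6, "antorbital_fenestra": 8,
                 "orbit": 8, "infratemporal_fenestra": 6}


def _ellipse(center, rx, ry, n, t0=0.0):
    t = t0 + np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([center[0] + rx * np.cos(t), center[1] + ry * np.sin(t)])


def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """n points equidistant along a polyline (semilandmark placement)."""
    seg = np.sqrt(((np.diff(points, axis=0)) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0, s[-1], n)
    out = np.empty((n, 2))
    for i, t in enumerate(targets):
        j = min(np.searchsorted(s, t, side="right") - 1, len(seg) - 1)
        frac = 0.0 if seg[j] == 0 else (t - s[j]) / seg[j]
        out[i] = points[j] * (1 - frac) + points[j + 1] * frac
    return out


def skull_region_sizes(k: int) -> dict[str, int]:
    """Partition k landmarks into fixed points and semilandmark curves,
    proportional to the default 20 + 51 scheme."""
    if k < 10:
        raise ValueError("need at least 10 landmarks for a skull schematic")
    n_fixed = max(5, round(k * _DEFAULT_FIXED / 71))
    remaining = k - n_fixed
    names = list(_DEFAULT_SEMI)
    total = sum(_DEFAULT_SEMI.values())
    sizes = {"fixed": n_fixed}
    assigned = 0
    for i, name in enumerate(names):
        if i == len(names) - 1:
            sizes[name] = remaining - assigned
        else:
            sizes[name] = max(1, round(remaining * _DEFAULT_SEMI[name] / total))
            assigned += sizes[name]
    return sizes


def skull_regions(k: int = 71) -> dict[str, np.ndarray]:
    """0-based landmark indices per region; regions partition 0..k-1."""
    sizes = skull_region_sizes(k)
    out, start = {}, 0
    for name, n in sizes.items():
        out[name] = np.arange(start, start + n)
        start += n
    return out


def make_base_skull(k_landmarks: int = 71) -> LandmarkConfiguration:
    """Deterministic schematic lateral skull (snout to the left, y up).

    Fixed landmarks sit on sutural/extremal loci of the outline and
    openings; semilandmarks run equidistantly along the outline and the
    margins of the naris, antorbital fenestra, orbit and infratemporal
    fenestra.  Two calls return identical output.
    """
    sizes = skull_region_sizes(k_landmarks)
    # outline polygon, anterior (snout) at x=0, posterior at x=10
    outline = np.array([
        [0.0, 1.1],   # snout tip
        [0.6, 1.9], [1.6, 2.5], [3.0, 2.9], [4.6, 3.2], [6.2, 3.5],
        [7.6, 3.6], [9.0, 3.5], [10.0, 3.2],   # dorsal margin
        [10.2, 2.2], [10.0, 1.2], [9.4, 0.8],  # posterior margin / quadrate
        [8.0, 0.7], [6.4, 0.6], [4.8, 0.5], [3.2, 0.4], [1.6, 0.3],
        [0.4, 0.5], [0.0, 1.1],                # ventral margin back to tip
    ])
    fixed = np.array([
        [0.0, 1.1],    # anterior tip of premaxilla
        [0.9, 0.35],   # premaxilla-maxilla alveolar contact
        [3.4, 0.42],   # maxilla-jugal ventral contact
        [5.6, 0.52],   # jugal midpoint below orbit
        [7.6, 0.64],   # jugal-quadratojugal contact
        [9.4, 0.8],    # jaw joint (quadrate condyle)
        [10.0, 3.2],   # posterodorsal corner (squamosal)
        [7.6, 3.6],    # postorbital-frontal contact
        [6.2, 3.5],    # frontal midpoint
        [4.6, 3.2],    # nasal-lacrimal contact
        [1.6, 2.5],    # premaxilla-nasal contact
        [1.0, 2.2],    # anterior naris corner
        [2.1, 2.25],   # posterior naris corner
        [3.3, 2.0],    # anterior corner antorbital fossa
        [5.1, 2.05],   # posterior corner antorbital fenestra
        [5.5, 2.9],    # lacrimal dorsal end
        [6.1, 2.3],    # anterior orbit margin
        [7.5, 2.3],    # posterior orbit margin (postorbital bar)
        [8.1, 1.8],    # anterior infratemporal corner
        [9.2, 1.9],    # posterior infratemporal corner
    ])
    n_fixed = sizes["fixed"]
    if n_fixed <= 20:
        fixed_pts = fixed[:n_fixed]
    else:  # pad along the outline
        fixed_pts = np.vstack([fixed, _resample_polyline(outline, n_fixed - 20 + 2)[1:-1]])
    parts = [fixed_pts, _resample_polyline(outline, sizes["outline"])]
    parts.append(_ellipse((1.55, 2.0), 0.55, 0.35, sizes["naris"]))
    parts.append(_ellipse((4.2, 1.9), 0.95, 0.65, sizes["antorbital_fenestra"]))
    parts.append(_ellipse((6.8, 2.2), 0.72, 0.78, sizes["orbit"]))
    parts.append(_ellipse((8.6, 1.6), 0.55, 0.85, sizes["infratemporal_fenestra"]))
    coords = np.vstack(parts)
    assert coords.shape == (k_landmarks, 2)
    mask = np.ones(k_landmarks, dtype=bool)
    mask[:n_fixed] = False
    return LandmarkConfiguration(
        specimen_id="base_skull", taxon="synthetic", stage="adult",
        coords=coords, is_semilandmark=mask,
    )


# ---------------------------------------------------------------------------
# truth parameters
# ---------------------------------------------------------------------------


def _unit_shape(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    return (c / np.sqrt((c ** 2).sum())).reshape(-1)


def similarity_null_basis(shape_flat: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity directions (x/y translation,
    scaling, rotation) at a unit-size shape; columns are 2k vectors."""
    k = shape_flat.size // 2
    xy = shape_flat.reshape(k, 2)
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    sc = shape_flat.copy()
    rot = np.column_stack([-xy[:, 1], xy[:, 0]]).reshape(-1)
    basis, cols = [], [tx, ty, sc, rot]
    for v in cols:
        w = v.astype(float)
        for b in basis:
            w = w - (w @ b) * b
        n = np.linalg.norm(w)
        if n > 1e-12:
            basis.append(w / n)
    return np.column_stack(basis)


def project_to_shape_space(v: np.ndarray, base_flat: np.ndarray) -> np.ndarray:
    """Remove the similarity components of a perturbation vector."""
    B = similarity_null_basis(base_flat)
    return v - B @ (B.T @ v)


def default_allometric_vector(base: LandmarkConfiguration) -> np.ndarray:
    """Deterministic growth field: snout elongation and deepening with
    relative orbit reduction — the general saurischian ontogenetic
    pattern — orthogonalized against the similarity directions."""
    u = _unit_shape(base.coords)
    xy = u.reshape(-1, 2)
    x, y = xy[:, 0], xy[:, 1]
    x0 = x - x.min()
    span = x0.max()
    dx = -0.8 * np.maximum(0.0, 0.45 - x0 / span)          # stretch snout forward
    dy = 0.5 * np.sign(y - y.mean()) * np.maximum(0.0, 0.6 - x0 / span) * np.abs(y - y.mean())
    regions = skull_regions(base.k)
    orbit = regions["orbit"]
    center = xy[orbit].mean(axis=0)
    d = np.zeros_like(xy)
    d[:, 0], d[:, 1] = dx, dy
    d[orbit] -= 0.35 * (xy[orbit] - center)                 # shrink the orbit
    v = project_to_shape_space(d.reshape(-1), u)
    return v / np.linalg.norm(v)


def bm_direction_basis(base: LandmarkConfiguration, allometric_vector: np.ndarray,
                       m: int = 8) -> np.ndarray:
    """Orthonormal low-rank basis for interspecific Brownian variation.

    Real cranial shape variation is concentrated on a handful of axes (a
    few PCs carry most interspecific variance), so the Brownian process
    acts on ``m`` smooth low-order polynomial deformation fields of the
    skull rather than isotropically on all 2k coordinates.  The basis is
    orthogonalized against the similarity directions *and against the
    allometric axis*: under the simulated no-heterochrony null, lineages
    drift in non-allometric shape space, while displacement along the
    allometric (ontogenetic) axis is produced exclusively by injected
    heterochronic shifts.  That separation is what makes the injected
    shifts an unambiguous ground truth for the recovery experiments.
    """
    u = _unit_shape(base.coords)
    xy = u.reshape(-1, 2)
    x = (xy[:, 0] - xy[:, 0].mean()) / xy[:, 0].std()
    y = (xy[:, 1] - xy[:, 1].mean()) / xy[:, 1].std()
    zero = np.zeros_like(x)
    fields = [
        np.column_stack([x ** 2, zero]).reshape(-1),
        np.column_stack([zero, x * y]).reshape(-1),
        np.column_stack([y, zero]).reshape(-1),
        np.column_stack([zero, x ** 2]).reshape(-1),
        np.column_stack([x * y, zero]).reshape(-1),
        np.column_stack([zero, y ** 2]).reshape(-1),
        np.column_stack([x ** 3, zero]).reshape(-1),
        np.column_stack([zero, x ** 3]).reshape(-1),
    ]
    v = allometric_vector / np.linalg.norm(allometric_vector)
    basis: list[np.ndarray] = []
    for f in fields:
        w = project_to_shape_space(np.asarray(f, float), u)
        w = w - (w @ v) * v
        for b in basis:
            w = w - (w @ b) * b
        n = np.linalg.norm(w)
        if n > 1e-10:
            basis.append(w / n)
        if len(basis) == m:
            break
    return np.column_stack(basis)


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a simulated clade.

    Units: shapes are unit-centroid-size Procrustes-scale vectors;
    ``allometric_slope`` is Procrustes units of shape change per unit of
    natural-log centroid size.  ``bm_rate`` is the total interspecific
    shape variance accrued per Myr, spread over the low-rank direction
    basis with geometrically decaying weights (``bm_decay``); a small
    isotropic floor ``bm_iso_rate`` (per coordinate per Myr) keeps the
    process full-rank.  ``noise_sd`` is the per-landmark digitization
    displacement (0.005 = 0.5% of centroid size, the order of published
    digitizing error for this kind of data).  Sizes evolve by Brownian
    motion on the natural-log scale.
    """

    base_shape: np.ndarray
    allometric_vector: np.ndarray
    bm_directions: np.ndarray = None  # (2k, m) orthonormal, set by make_truth
    allometric_slope: float = 0.1
    bm_rate: float = 2e-6
    bm_decay: float = 0.5
    bm_iso_rate: float = 2e-8
    size_bm_rate: float = 5e-4
    noise_sd: float = 0.005
    ontogeny_span: float = 1.5            # adult logCS - juvenile logCS
    log_cs_root: float = 5.7              # ~300 mm adult skull at the root
    heterochrony_shifts: dict = field(default_factory=dict)  # clade key -> shift
    seed: int = 0

    @property
    def k(self) -> int:
        return self.base_shape.size // 2

    @property
    def bm_direction_rates(self) -> np.ndarray:
        m = self.bm_directions.shape[1]
        w = self.bm_decay ** np.arange(m)
        return self.bm_rate * w / w.sum()


def make_truth(seed: int = 0, k_landmarks: int = 71, **overrides) -> SyntheticTruth:
    base = make_base_skull(k_landmarks)
    v = default_allometric_vector(base)
    truth = SyntheticTruth(
        base_shape=_unit_shape(base.coords),
        allometric_vector=v,
        bm_directions=bm_direction_basis(base, v),
        seed=seed,
    )
    return replace(truth, **overrides) if overrides else truth


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _emit(truth: SyntheticTruth, shape_flat: np.ndarray, log_cs: float,
          specimen_id: str, taxon: str, stage: str, rng,
          jitter_pose: bool = True, mask=None) -> LandmarkConfiguration:
    # noise_sd is the per-landmark displacement sd; isotropic in 2D, so
    # each coordinate gets noise_sd / sqrt(2)
    shape = shape_flat + rng.normal(0.0, truth.noise_sd / math.sqrt(2.0),
                                    size=shape_flat.shape)
    xy = shape.reshape(-1, 2)
    xy = xy - xy.mean(axis=0)
    xy = xy / centroid_size(xy) * math.exp(log_cs)
    if jitter_pose:
        theta = rng.uniform(-0.26, 0.26)   # ~15 degrees of digitizing tilt
        c, s = math.cos(theta), math.sin(theta)
        xy = xy @ np.array([[c, s], [-s, c]])
        xy = xy + rng.uniform(-50, 50, size=2)
    return LandmarkConfiguration(specimen_id=specimen_id, taxon=taxon, stage=stage,
                                 coords=xy, is_semilandmark=mask)


def simulate_ontogeny(base: LandmarkConfiguration, truth: SyntheticTruth,
                      log_cs_juvenile: float, log_cs_adult: float,
                      rng: Optional[np.random.Generator] = None,
                      taxon: str = "synthetic") -> tuple[LandmarkConfiguration,
                                                         LandmarkConfiguration]:
    """One juvenile/adult pair along the allometric growth axis.

    Stage shape is ``base + slope * (logCS - logCS_adult) * v`` plus
    noise, emitted at its stage centroid size with a random pose.
    """
    if log_cs_adult <= log_cs_juvenile:
        raise ValueError("adult log CS must exceed juvenile log CS")
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    u = _unit_shape(base.coords)
    mask = base.is_semilandmark
    out = []
    for stage, lcs in (("juvenile", log_cs_juvenile), ("adult", log_cs_adult)):
        shape = u + truth.allometric_slope * (lcs - log_cs_adult) * truth.allometric_vector
        out.append(_emit(truth, shape, lcs, f"{taxon}_{stage}", taxon, stage, rng, mask=mask))
    return out[0], out[1]


def _resolve_shift_node(tree: TimeTree, key) -> int:
    if isinstance(key, str):
        node = tree.node_by_name(key)
        if node is None:
            node = tree.tip_index(key)
        return node
    return tree.mrca(list(key))


def simulate_clade(tree: TimeTree, truth: SyntheticTruth,
                   juvenile_taxa: Sequence[str] = (),
                   rng: Optional[np.random.Generator] = None,
                   ) -> tuple[list[LandmarkConfiguration], dict]:
    """Evolve adult mean shapes by Brownian motion over ``tree`` and emit
    noisy specimens.

    Every tip yields an adult; taxa in ``juvenile_taxa`` also yield a
    juvenile whose mean reverses the lineage's ontogeny
    (``span * slope`` back along the allometric axis).  Branches listed
    in ``truth.heterochrony_shifts`` (key: tip label, clade-name, or tuple
    of tip labels for an MRCA) add a signed shift along the allometric
    axis to the child node's state, inherited by all its descendants.
    Brownian steps are projected into shape space (similarity directions
    removed) so the truth states stay comparable after Procrustes fitting.

    Returns the specimen list and an info dict with the true node means
    and sizes keyed by tree node index.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    shift_nodes = {_resolve_shift_node(tree, k): v
                   for k, v in truth.heterochrony_shifts.items()}
    d = truth.base_shape.size
    states = np.zeros((tree.n_nodes, d))
    log_sizes = np.zeros(tree.n_nodes)
    for v in tree.preorder():
        if v == tree.root:
            states[v] = truth.base_shape
            log_sizes[v] = truth.log_cs_root
        else:
            p = tree.parent[v]
            l = tree.length[v]
            z = rng.normal(size=truth.bm_directions.shape[1])
            step = truth.bm_directions @ (np.sqrt(truth.bm_direction_rates * l) * z)
            iso = rng.normal(0.0, math.sqrt(truth.bm_iso_rate * l), size=d)
            states[v] = states[p] + step + project_to_shape_space(iso, truth.base_shape)
            log_sizes[v] = log_sizes[p] + rng.normal(
                0.0, math.sqrt(truth.size_bm_rate * l))
        if v in shift_nodes:
            states[v] = states[v] + shift_nodes[v] * truth.allometric_vector
    base = make_base_skull(truth.k)
    mask = base.is_semilandmark
    configs = []
    for t in tree.tips:
        taxon = tree.labels[t]
        lcs_a = log_sizes[t]
        configs.append(_emit(truth, states[t], lcs_a, f"{taxon}_adult", taxon,
                             "adult", rng, mask=mask))
        if taxon in set(juvenile_taxa):
            juv_shape = states[t] - truth.allometric_slope * truth.ontogeny_span \
                * truth.allometric_vector
            configs.append(_emit(truth, juv_shape, lcs_a - truth.ontogeny_span,
                                 f"{taxon}_juvenile", taxon, "juvenile", rng, mask=mask))
    info = {"node_states": states, "node_log_sizes": log_sizes,
            "shift_nodes": shift_nodes}
    return configs, info


# ---------------------------------------------------------------------------
# the miniature study design
# ---------------------------------------------------------------------------

FIXTURE_TIP_AGES = {
    "T01": 205.0, "T02": 190.0,                      # sauropodomorph-like pair
    "T03": 195.0, "T04": 185.0,                      # basal theropod-like pair
    "T05": 160.0, "T06": 150.0,                      # megalosaur-like pair
    "T07": 125.0, "T08": 118.0,
    "T09": 112.0, "T10": 108.0,                      # allosaur-like pair
    "T11": 75.0, "T12": 70.0,                        # tyrannosaur-like pair
}

FIXTURE_TOPOLOGY = ("((T01,T02),((T03,T04),((T05,T06),((T07,T08),"
                    "((T09,T10),(T11,T12))))));")

FIXTURE_JUVENILE_TAXA = ["T01", "T03", "T05", "T09", "T11"]

# members list enough tips to pin the clade's MRCA on the full adult tree
# and, after dropping taxa without juveniles, on the pruned juvenile tree
FIXTURE_CLADES = {
    "CladeA": ["T01", "T03", "T11"],   # root: whole clade (Saurischia analogue)
    "CladeB": ["T03", "T05", "T11"],   # Neotheropoda analogue
    "CladeC": ["T05", "T09", "T11"],   # Orionides analogue
    "CladeD": ["T07", "T09", "T11"],   # Avetheropoda analogue
}

FIXTURE_PAIRS = [
    ("CladeA", "T01"), ("CladeA", "CladeB"),
    ("CladeB", "T03"), ("CladeB", "CladeC"),
    ("CladeC", "T05"), ("CladeC", "CladeD"),
    ("CladeD", "T09"), ("CladeD", "T11"),
]

# internal ancestor-descendant branch used in the recovery experiments
FIXTURE_FOCAL_PAIR = ("CladeC", "CladeD")

# ground-truth heterochrony of the showcase study: a paedomorphic shift
# on the stem of CladeD and a peramorphic shift in the terminal T03,
# both along the allometric axis (Procrustes units)
FIXTURE_SHIFTS = {
    ("T07", "T09", "T11"): -0.02,    # CladeD stem: paedomorphosis
    "T03": +0.02,                    # terminal branch: peramorphosis
}


def fixture_tree() -> TimeTree:
    """The 12-taxon time-calibrated tree of the miniature study."""
    topo = TimeTree.from_newick(FIXTURE_TOPOLOGY)
    return calibrate_branch_lengths(topo, FIXTURE_TIP_AGES)


# ---------------------------------------------------------------------------
# the recovery-experiment design
# ---------------------------------------------------------------------------
#
# Classification power depends on how well the ancestral nodes are
# supported: single-specimen digitization noise barely averages out on a
# small tree, so the controlled recovery experiments use a 32-taxon
# ladder clade in which every taxon has a juvenile/adult pair, the two
# groups flanking the focal divergence are sampled densely (the focal
# ancestor and descendant nodes then average digitizing noise over many
# specimens), and a long mid-ladder branch decouples the focal pair from
# each other's reconstruction.

RECOVERY_GROUP_SIZES = (2, 2, 3, 9, 9, 3, 2, 2)


def make_recovery_design():
    """Tree, juvenile list, clade map, pairs and focal pair for the
    shift-recovery experiments."""
    sizes = RECOVERY_GROUP_SIZES
    G = len(sizes)
    mid = G // 2
    names = [[f"S{j}{chr(97 + i)}" for i in range(sizes[j])] for j in range(G)]
    ages = {}
    for j, grp in enumerate(names):
        top = 205.0 - 15.0 * j if j < mid else 205.0 - 15.0 * (mid - 1) - 45.0 \
            - 15.0 * (j - mid)
        for i, nm in enumerate(grp):
            ages[nm] = top - 10.0 * i / max(1, len(grp) - 1)

    def group_newick(grp):
        s = f"({grp[0]},{grp[1]})"
        for nm in grp[2:]:
            s = f"({s},{nm})"
        return s

    def ladder(j):
        if j == G - 2:
            return f"({group_newick(names[j])},{group_newick(names[j + 1])})"
        return f"({group_newick(names[j])},{ladder(j + 1)})"

    tree = calibrate_branch_lengths(TimeTree.from_newick(ladder(0) + ";"), ages)
    juveniles = [n for grp in names for n in grp]
    clades = {
        "Ancestor": [names[mid - 1][0], names[-1][0]],
        "Descendant": [names[mid][0], names[-1][0]],
    }
    focal = ("Ancestor", "Descendant")
    return tree, juveniles, clades, [focal], focal
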