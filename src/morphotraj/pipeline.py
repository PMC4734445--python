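"""End-to-end analysis: GPA -> PCA -> allometry -> phylogenetic signal ->
ancestral reconstruction -> trajectories -> heterochrony calls.

:func:`analyze` is the library entry point working on in-memory objects;
:func:`run_full_analysis` wraps it with file I/O, a JSON run
configuration and provenance logging for the command line.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .allometry import (RegressionResult, euclidean_distances_to,
                        regress_shape_on_size, regression_score, trajectory_slope)
from .ordination import PcaResult, pca
from .phylo import (AncestralReconstruction, SignalTestResult, ancestral_states_scp,
                    calibrate_branch_lengths, k_mult, permutation_signal_test)
from .superimposition import AlignedSample, gpa
from .trajectory import (HeterochronyCall, OntogeneticTrajectory, ancestral_trajectories,
                         branch_differences, change_vector, ci_threshold,
                         classify_heterochrony, trajectory_angle, trajectory_length)
from .tree import TimeTree


@dataclass
class StudyResult:
    aligned: AlignedSample
    main_pca: PcaResult
    main_regression: RegressionResult
    adult_shape_recon: AncestralReconstruction
    adult_size_recon: AncestralReconstruction
    juvenile_shape_recon: AncestralReconstruction
    juvenile_size_recon: AncestralReconstruction
    trajectories: dict[str, OntogeneticTrajectory]
    trajectory_regression: RegressionResult
    trajectory_pca: PcaResult
    trajectory_table: pd.DataFrame
    calls: list[HeterochronyCall]
    ci_rs: float
    ci_ed: float
    branch_diff_rs: np.ndarray
    branch_diff_ed: np.ndarray
    reference_specimen: str
    shape_signal: Optional[SignalTestResult] = None
    size_signal: Optional[SignalTestResult] = None
    shape_k: Optional[SignalTestResult] = None
    size_k: Optional[SignalTestResult] = None

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ancestor": c.ancestor, "descendant": c.descendant,
                    "delta_rs": c.delta_rs, "delta_ed": c.delta_ed,
                    "rs_significant": c.rs_significant, "ed_significant": c.ed_significant,
                    "classification": c.classification,
                }
                for c in self.calls
            ]
        )


def _adult_specimen_of(aligned: AlignedSample, taxon: str) -> int:
    hits = [i for i in range(aligned.n)
            if aligned.taxa[i] == taxon and aligned.stages[i] != "juvenile"]
    if len(hits) != 1:
        raise ValueError(f"taxon {taxon!r}: expected exactly 1 adult specimen, got {len(hits)}")
    return hits[0]


def _juvenile_specimen_of(aligned: AlignedSample, taxon: str) -> int:
    hits = [i for i in range(aligned.n)
            if aligned.taxa[i] == taxon and aligned.stages[i] == "juvenile"]
    if len(hits) != 1:
        raise ValueError(f"taxon {taxon!r}: expected exactly 1 juvenile specimen, "
                         f"got {len(hits)}")
    return hits[0]


def analyze(configs: Sequence[mio.LandmarkConfiguration], tree: TimeTree,
            clades: Mapping[str, Sequence[str]], pairs: Sequence[tuple[str, str]],
            *, reference_specimen: Optional[str] = None, n_perm_regression: int = 10000,
            n_perm_signal: int = 10000, seed: int = 0, ci_method: str = "t",
            gpa_kwargs: Optional[dict] = None) -> StudyResult:
    """Run the whole comparative-heterochrony analysis.

    ``configs`` holds every specimen (adults of all tree tips, juveniles
    of the taxa with ontogenetic series); ``tree`` is the calibrated
    adult supertree; ``clades`` names the hypothetical ancestors (clade
    name -> member tip labels, resolved by MRCA); ``pairs`` lists the
    ancestor-descendant comparisons to classify (labels are clade names
    or terminal taxa).  Signal tests are skipped when
    ``n_perm_signal == 0``.
    """
    aligned = gpa(configs, **(gpa_kwargs or {}))
    juvenile_taxa = sorted({aligned.taxa[i] for i in range(aligned.n)
                            if aligned.stages[i] == "juvenile"})

    main_pca = pca(aligned)
    main_reg = regress_shape_on_size(aligned, n_perm=n_perm_regression, seed=seed)

    # ancestral reconstruction of adult shapes and sizes on the supertree
    adult_idx = [_adult_specimen_of(aligned, t) for t in tree.tip_labels]
    adult_shapes = aligned.procrustes_coords[adult_idx]
    adult_logcs = aligned.log_cs[adult_idx][:, None]
    adult_shape_recon = ancestral_states_scp(tree, adult_shapes)
    adult_size_recon = ancestral_states_scp(tree, adult_logcs)

    shape_signal = size_signal = shape_k = size_k = None
    if n_perm_signal:
        shape_signal = permutation_signal_test(tree, adult_shapes, n_perm_signal, seed)
        size_signal = permutation_signal_test(tree, adult_logcs, n_perm_signal, seed + 1)
        shape_k = k_mult(tree, adult_shapes, n_perm_signal, seed + 2)
        size_k = k_mult(tree, adult_logcs, n_perm_signal, seed + 3)

    # juvenile reconstruction on the pruned tree, original calibration kept
    juv_tree = tree.prune_to(juvenile_taxa)
    juv_idx = [_juvenile_specimen_of(aligned, t) for t in juv_tree.tip_labels]
    juv_shape_recon = ancestral_states_scp(juv_tree, aligned.procrustes_coords[juv_idx])
    juv_size_recon = ancestral_states_scp(juv_tree, aligned.log_cs[juv_idx][:, None])

    # trajectories: terminal ontogenetic series + hypothetical ancestors
    trajectories: dict[str, OntogeneticTrajectory] = {}
    for taxon in juvenile_taxa:
        j, a = _juvenile_specimen_of(aligned, taxon), _adult_specimen_of(aligned, taxon)
        trajectories[taxon] = OntogeneticTrajectory(
            label=taxon,
            juvenile_shape=aligned.procrustes_coords[j],
            adult_shape=aligned.procrustes_coords[a],
            juvenile_log_cs=float(aligned.log_cs[j]),
            adult_log_cs=float(aligned.log_cs[a]),
        )
    for traj in ancestral_trajectories(adult_shape_recon, juv_shape_recon, clades,
                                       adult_size_recon, juv_size_recon):
        trajectories[traj.label] = traj

    labels = list(trajectories)
    stage_rows, stage_sizes, stage_ids, groups = [], [], [], []
    for lab in labels:
        t = trajectories[lab]
        for stage, shp, lcs in (("juvenile", t.juvenile_shape, t.juvenile_log_cs),
                                ("adult", t.adult_shape, t.adult_log_cs)):
            stage_rows.append(shp)
            stage_sizes.append(lcs)
            stage_ids.append(f"{lab}/{stage}")
            groups.append(lab)
    traj_sample = AlignedSample(
        procrustes_coords=np.array(stage_rows),
        centroid_sizes=np.exp(stage_sizes),
        consensus=aligned.consensus,
        specimen_ids=stage_ids,
        taxa=groups,
        stages=[s.split("/")[1] for s in stage_ids],
        iterations=aligned.iterations,
        converged=aligned.converged,
        tangent_projected=aligned.tangent_projected,
    )
    traj_reg = regress_shape_on_size(traj_sample, groups=groups,
                                     n_perm=n_perm_regression, seed=seed + 4)

    # shape variables: regression score and Euclidean distance to the
    # smallest specimen of the trajectory data set
    if reference_specimen is None:
        reference_specimen = stage_ids[int(np.argmin(stage_sizes))]
    ref_shape = traj_sample.shape_of(reference_specimen)
    rs_vals = traj_reg.regression_scores
    ed_vals = euclidean_distances_to(traj_sample.procrustes_coords, ref_shape)
    for i, sid in enumerate(stage_ids):
        lab, stage = sid.split("/")
        t = trajectories[lab]
        target = t.juvenile_vars if stage == "juvenile" else t.adult_vars
        target["regression_score"] = float(rs_vals[i])
        target["euclidean_distance"] = float(ed_vals[i])

    traj_pca = pca(traj_sample)

    # CI thresholds from branch-wise differences over the adult supertree
    node_rs = regression_score(adult_shape_recon.node_states, traj_reg)
    node_ed = euclidean_distances_to(adult_shape_recon.node_states, ref_shape)
    diff_rs = branch_differences(adult_shape_recon, node_rs)
    diff_ed = branch_differences(adult_shape_recon, node_ed)
    ci_rs = ci_threshold(diff_rs, method=ci_method)
    ci_ed = ci_threshold(diff_ed, method=ci_method)

    calls = []
    for anc, desc in pairs:
        if anc not in trajectories or desc not in trajectories:
            missing = [x for x in (anc, desc) if x not in trajectories]
            raise KeyError(f"pair ({anc}, {desc}): no trajectory for {missing}")
        calls.append(classify_heterochrony(trajectories[anc], trajectories[desc],
                                           ci_rs, ci_ed))

    table = _trajectory_table(trajectories, traj_pca, stage_ids)

    return StudyResult(
        aligned=aligned, main_pca=main_pca, main_regression=main_reg,
        adult_shape_recon=adult_shape_recon, adult_size_recon=adult_size_recon,
        juvenile_shape_recon=juv_shape_recon, juvenile_size_recon=juv_size_recon,
        trajectories=trajectories, trajectory_regression=traj_reg,
        trajectory_pca=traj_pca, trajectory_table=table, calls=calls,
        ci_rs=float(ci_rs), ci_ed=float(ci_ed),
        branch_diff_rs=diff_rs, branch_diff_ed=diff_ed,
        reference_specimen=reference_specimen,
        shape_signal=shape_signal, size_signal=size_signal,
        shape_k=shape_k, size_k=size_k,
    )


def _trajectory_table(trajectories, traj_pca: PcaResult, stage_ids) -> pd.DataFrame:
    """Per-trajectory descriptors in the trajectory-PCA morphospace:
    angle against PC1, length on the leading plane, and the allometric
    slopes of both scalar shape variables."""
    n_axes = min(traj_pca.n_components, max(2, traj_pca.n_significant))
    scores = {sid: traj_pca.scores[i, :n_axes] for i, sid in enumerate(stage_ids)}
    rows = []
    for lab, t in trajectories.items():
        vec = scores[f"{lab}/adult"] - scores[f"{lab}/juvenile"]
        pc1_axis = np.zeros(len(vec))
        pc1_axis[0] = 1.0
        row = {
            "trajectory": lab,
            "is_ancestral": t.is_ancestral,
            "angle_vs_pc1_deg": trajectory_angle(vec, pc1_axis),
            "length_pc_plane": trajectory_length(vec[:2]),
            "delta_log_cs": t.adult_log_cs - t.juvenile_log_cs,
        }
        for var in ("regression_score", "euclidean_distance"):
            if var in t.adult_vars and var in t.juvenile_vars:
                row[f"slope_{var}"] = trajectory_slope(
                    (t.juvenile_log_cs, t.juvenile_vars[var]),
                    (t.adult_log_cs, t.adult_vars[var]))
                row[f"length_{var}"] = math.hypot(
                    t.adult_log_cs - t.juvenile_log_cs,
                    t.adult_vars[var] - t.juvenile_vars[var])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configured file-based runs
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


_CONFIG_DEFAULTS = {"n_perm_regression": 10000, "n_perm_signal": 10000,
                    "seed": 0, "ci_method": "t"}


def load_config(path) -> dict:
    return {**_CONFIG_DEFAULTS, **json.loads(Path(path).read_text())}


def run_full_analysis(config: dict | str | Path, output_dir: Optional[Path] = None
                      ) -> StudyResult:
    """Execute the configured pipeline and write CSV/JSON results.

    The JSON configuration names the landmark file (``landmarks``, TPS or
    CSV by extension), the tree (``tree``, NEXUS/Newick), an optional
    ``tip_ages`` CSV (taxon,age_ma) triggering time calibration, the
    ``clades`` map, the ``pairs`` list, permutation counts and the master
    ``seed``.  All referenced files are checked before any computation,
    and a provenance record (input hashes, seeds, versions) accompanies
    the outputs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = {**_CONFIG_DEFAULTS, **config}
    paths = {key: Path(config[key]) for key in ("landmarks", "tree") if key in config}
    if "tip_ages" in config and config["tip_ages"]:
        paths["tip_ages"] = Path(config["tip_ages"])
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    if "landmarks" not in paths or "tree" not in paths:
        raise KeyError("config must name 'landmarks' and 'tree' files")

    lm_path = paths["landmarks"]
    if lm_path.suffix.lower() == ".tps":
        configs = mio.read_tps(lm_path)
        stages = config.get("stages", {})
        taxa = config.get("taxa", {})
        for c in configs:
            c.stage = stages.get(c.specimen_id, c.stage)
            c.taxon = taxa.get(c.specimen_id, c.taxon or c.specimen_id)
    else:
        configs = mio.read_landmark_csv(lm_path, mask=config.get("semilandmarks"))

    from .tree import read_nexus_tree
    tree = read_nexus_tree(paths["tree"])
    if "tip_ages" in paths:
        ages = pd.read_csv(paths["tip_ages"])
        tree = calibrate_branch_lengths(
            tree, dict(zip(ages.iloc[:, 0].astype(str), ages.iloc[:, 1])),
            root_extension=float(config.get("root_extension", 1.0)))

    result = analyze(
        configs, tree,
        clades=config["clades"], pairs=[tuple(p) for p in config["pairs"]],
        reference_specimen=config.get("reference_specimen"),
        n_perm_regression=int(config["n_perm_regression"]),
        n_perm_signal=int(config["n_perm_signal"]),
        seed=int(config["seed"]), ci_method=config["ci_method"],
        gpa_kwargs=config.get("gpa", {}),
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_outputs(result, out, config, paths)
    return result


def _write_outputs(result: StudyResult, out: Path, config: dict, paths: dict) -> None:
    aligned = result.aligned
    coords = pd.DataFrame(aligned.procrustes_coords,
                          index=pd.Index(aligned.specimen_ids, name="specimen"))
    coords.insert(0, "centroid_size", aligned.centroid_sizes)
    coords.to_csv(out / "procrustes_coordinates.csv")
    pd.DataFrame({
        "eigenvalue": result.main_pca.eigenvalues,
        "variance_fraction": result.main_pca.variance_fractions,
    }).to_csv(out / "pca_eigenvalues.csv", index_label="component")
    pd.DataFrame(result.main_pca.scores[:, :10],
                 index=pd.Index(aligned.specimen_ids, name="specimen"),
                 columns=[f"PC{i + 1}" for i in range(min(10, result.main_pca.n_components))]
                 ).to_csv(out / "pca_scores.csv")
    result.trajectory_table.to_csv(out / "trajectory_table.csv", index=False)
    result.calls_frame().to_csv(out / "heterochrony_calls.csv", index=False)

    summary = {
        "n_specimens": aligned.n,
        "n_landmarks": aligned.k,
        "gpa_iterations": aligned.iterations,
        "pc_variance_pct": [round(100 * f, 4) for f in
                            result.main_pca.variance_fractions[:5].tolist()],
        "n_significant_pcs": result.main_pca.n_significant,
        "regression_percent_predicted": result.main_regression.percent_predicted,
        "regression_p": result.main_regression.permutation_p,
        "trajectory_pca_pc_pct": [round(100 * f, 4) for f in
                                  result.trajectory_pca.variance_fractions[:3].tolist()],
        "trajectory_pca_n_significant": result.trajectory_pca.n_significant,
        "ci_rs": result.ci_rs, "ci_ed": result.ci_ed,
        "reference_specimen": result.reference_specimen,
        "adult_tree_length_shape": result.adult_shape_recon.tree_length,
        "adult_tree_length_size": result.adult_size_recon.tree_length,
    }
    for name, res in (("shape_signal", result.shape_signal),
                      ("size_signal", result.size_signal),
                      ("shape_kmult", result.shape_k), ("size_kmult", result.size_k)):
        if res is not None:
            summary[name] = {"statistic": res.statistic, "p": res.p_value,
                             "n_perm": res.n_permutations}
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    provenance = {
        "seed": config.get("seed"),
        "n_perm_regression": config.get("n_perm_regression"),
        "n_perm_signal": config.get("n_perm_signal"),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in paths.items()},
        "versions": _versions(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")

    # ancestral states keyed by clade name where named, else node index
    recon = result.adult_shape_recon
    names = [recon.tree.labels[v] or f"node_{v}" for v in range(recon.tree.n_nodes)]
    pd.DataFrame(recon.node_states, index=pd.Index(names, name="node")
                 ).to_csv(out / "ancestral_shapes.csv")


def _versions() -> dict:
    import numpy, scipy, pandas, dendropy
    from importlib.metadata import version
    return {
        "morphotraj": version("morphotraj"),
        "numpy": numpy.__version__, "scipy": scipy.__version__,
        "pandas": pandas.__version__, "dendropy": dendropy.__version__,
    }


# ---------------------------------------------------------------------------
# fixture study + recovery experiment
# ---------------------------------------------------------------------------


def simulate_fixture_study(seed: int = 0, shifts: Optional[dict] = None, **truth_overrides):
    """Simulate the miniature 12-taxon study (5 ontogenetic series).

    By default the study carries the showcase ground truth
    (``synthetic.FIXTURE_SHIFTS``): a paedomorphic stem shift and a
    peramorphic terminal shift.  Pass ``shifts={}`` for a
    heterochrony-free clade.  Returns (configs, tree, truth, info)."""
    from . import synthetic as syn
    if shifts is None:
        shifts = dict(syn.FIXTURE_SHIFTS)
    tree = syn.fixture_tree()
    truth = syn.make_truth(seed=seed, heterochrony_shifts=shifts, **truth_overrides)
    configs, info = syn.simulate_clade(tree, truth, juvenile_taxa=syn.FIXTURE_JUVENILE_TAXA)
    return configs, tree, truth, info


def analyze_fixture_study(configs, tree, *, n_perm_regression=10000, n_perm_signal=10000,
                          seed=0) -> StudyResult:
    from . import synthetic as syn
    return analyze(configs, tree, clades=syn.FIXTURE_CLADES, pairs=syn.FIXTURE_PAIRS,
                   n_perm_regression=n_perm_regression, n_perm_signal=n_perm_signal,
                   seed=seed)


def heterochrony_recovery_trial(seed: int, shift_multiple: float = 3.0,
                                direction: int = -1) -> dict:
    """One recovery experiment: classify a focal internal branch with and
    without an injected heterochronic shift.

    Pass 1 simulates the recovery clade (24 fully sampled taxa) with no
    shift and measures the spread (SD) of branch-wise differences of the
    two shape variables — the noise floor of the study; the larger of
    the two spreads is the conservative effect-size unit.  Pass 2
    re-simulates the *same* seed with a shift of
    ``direction * shift_multiple * spread`` on the focal branch and
    classifies it.  Returns the null call, the shifted call and the
    expected label.
    """
    from . import synthetic as syn
    from .trajectory import PAEDOMORPHOSIS, PERAMORPHOSIS
    tree, juveniles, clades, pairs, focal = syn.make_recovery_design()

    def run(shifts):
        truth = syn.make_truth(seed=seed, heterochrony_shifts=shifts)
        configs, _ = syn.simulate_clade(tree, truth, juvenile_taxa=juveniles)
        return analyze(configs, tree, clades=clades, pairs=pairs,
                       n_perm_regression=0, n_perm_signal=0, seed=seed)

    null_res = run({})
    spread = max(float(null_res.branch_diff_rs.std(ddof=1)),
                 float(null_res.branch_diff_ed.std(ddof=1)))
    null_call = next(c for c in null_res.calls
                     if (c.ancestor, c.descendant) == focal)

    shift = direction * shift_multiple * spread
    res = run({tuple(clades[focal[1]]): shift})
    call = next(c for c in res.calls if (c.ancestor, c.descendant) == focal)
    expected = PAEDOMORPHOSIS if direction < 0 else PERAMORPHOSIS
    return {"null_call": null_call, "shifted_call": call, "expected": expected,
            "spread": spread, "shift": shift}


# ---------------------------------------------------------------------------
# fixture bundle on disk
# ---------------------------------------------------------------------------


def write_fixture_bundle(out_dir, seed: int = 0) -> dict:
    """Write a complete miniature study (landmarks, tree, ages, config)
    as plain-text files and return the config dict."""
    from . import synthetic as syn
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs, tree, truth, _ = simulate_fixture_study(seed=seed)
    mio.write_landmark_csv(out / "landmarks.csv", configs)
    mio.write_tps(out / "landmarks.tps", configs)
    (out / "tree.nex").write_text(
        "#NEXUS\nBEGIN TREES;\n  TREE study = " + tree.to_newick(names=False)
        + "\nEND;\n")
    pd.DataFrame(sorted(syn.FIXTURE_TIP_AGES.items()),
                 columns=["taxon", "age_ma"]).to_csv(out / "tip_ages.csv", index=False)
    cfg = {
        "landmarks": str(out / "landmarks.csv"),
        "tree": str(out / "tree.nex"),
        "clades": {k: list(v) for k, v in syn.FIXTURE_CLADES.items()},
        "pairs": [list(p) for p in syn.FIXTURE_PAIRS],
        "n_perm_regression": 1000,
        "n_perm_signal": 1000,
        "seed": seed,
    }
    (out / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    return cfg
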