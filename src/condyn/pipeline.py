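"""Configuration-driven orchestration of the full analysis pipeline.

A single YAML config drives generation/ingest -> fluctuation analysis ->
PCA -> MSM (ITS, PCCA+, CK, TPT, representatives) -> residue network ->
(optionally) interaction fingerprints, writing plain-text artifacts plus a
run manifest with the config echo, package version, seed and SHA-256
checksum of every artifact.  Reruns with the same config and seed produce
byte-identical numeric outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import dimred, fluct, msm, network, trajgen
from .interactions import InteractionCriteria, fingerprint_summary
from .traj_io import read_topology, read_trajectory, select_atoms

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "condyn_out",
    "input": {                       # either trajectory files or a generator spec
        "topology": None,            # PDB path
        "trajectory": None,          # plain-matrix or multi-model PDB path
        "trajectory_format": "plain-matrix",
        "generate": None,            # {"kind": "receptor-demo", ...}
    },
    "selections": {
        "analysis": "name CA",
        "ligand": None,
        "receptor": None,
    },
    "fluct": {
        "reference": "mean",
        "dccm_min_abs": 0.3,
        "equilibration_fraction": 0.2,
    },
    "pca": {
        "mass_weighted": True,
        "n_components": None,        # None -> smallest set explaining variance_fraction
        "variance_fraction": 0.8,
        "max_components": 10,
    },
    "msm": {
        "k": 100,
        "lag": 60,                   # frames; 60 frames at 1 ns/frame mirrors a 60 ns lag
        "max_kmeans_iter": 100,
        "reversible": True,
        "n_macrostates": 3,
        "its_lags": [1, 5, 10, 20, 40, 60, 80],
        "ck_factors": [1, 2, 3],
        "representative_pool": 100,  # frames subsampled per macrostate for Eq-style scoring
        "tpt_source": 0,
        "tpt_sink": None,            # default: last macrostate
    },
    "network": {
        "cutoff": 4.5,
        "occupancy_threshold": 0.75,
        "contact_mode": "heavy-atom-min",
        "exclude_neighbors": 1,
        "max_frames": 2000,
        "min_community_size": 3,
    },
    "interactions": {
        "enabled": False,
        "hbond_distance_max": 3.5,
        "hbond_angle_min": 120.0,
        "weak_hbond_distance_range": [3.5, 4.0],
        "hydrophobic_distance_max": 4.5,
        "persistence_min": 0.5,
    },
}

DEMO_GENERATE = {
    "kind": "receptor-demo",
    "n_frames": 20000,
    "n_residues": 48,
    "weights": [0.36, 0.36, 0.28],
    "exchange_rate": 0.02,
    "block_size": 12,
    "displacement": 6.0,
    "fluct_sigma": 0.8,
    "intra_corr": 0.6,
}


class ConfigError(ValueError):
    pass


def _merge_defaults(user: dict, defaults: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key {here!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge_defaults(value, defaults[key], here)
        else:
            out[key] = value
    # log filled defaults at this level
    for key in defaults:
        if key not in user and not isinstance(defaults[key], dict):
            log.debug("config default filled: %s.%s = %r", path, key, defaults[key])
    return out


def validate_config(config: dict | str | Path) -> dict:
    """Fill defaults, reject unknown keys and out-of-range values."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge_defaults(config, DEFAULT_CONFIG)
    inp = cfg["input"]
    if inp["generate"] is None and (inp["topology"] is None or inp["trajectory"] is None):
        raise ConfigError("config needs either input.generate or input.topology + input.trajectory")
    for key in ("topology", "trajectory"):
        if inp[key] is not None and not Path(inp[key]).exists():
            raise ConfigError(f"input.{key} does not exist: {inp[key]}")
    if not 0 <= cfg["network"]["occupancy_threshold"] <= 1:
        raise ConfigError(f"network.occupancy_threshold must be in [0, 1], "
                          f"got {cfg['network']['occupancy_threshold']}")
    if cfg["msm"]["lag"] < 1 or cfg["msm"]["k"] < 2:
        raise ConfigError("msm.lag must be >= 1 and msm.k >= 2")
    if not 0 < cfg["pca"]["variance_fraction"] <= 1:
        raise ConfigError("pca.variance_fraction must be in (0, 1]")
    if cfg["interactions"]["enabled"] and (
            cfg["selections"]["ligand"] is None or cfg["selections"]["receptor"] is None):
        raise ConfigError("interactions.enabled requires selections.ligand and selections.receptor")
    return cfg


def _save_matrix(path: Path, M: np.ndarray, header: str = "") -> None:
    np.savetxt(path, np.atleast_2d(M), fmt="%.10g", delimiter=",", header=header)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_or_generate(cfg: dict):
    inp = cfg["input"]
    if inp["generate"] is not None:
        gen = dict(inp["generate"])
        kind = gen.pop("kind", "receptor-demo")
        if kind != "receptor-demo":
            raise ConfigError(f"unknown generator kind {kind!r}")
        n_frames = int(gen.pop("n_frames", 20000))
        spec = trajgen.default_receptor_spec(
            n_residues=int(gen.pop("n_residues", 48)),
            weights=tuple(gen.pop("weights", (0.36, 0.36, 0.28))),
            exchange_rate=float(gen.pop("exchange_rate", 0.02)),
            block_size=int(gen.pop("block_size", 12)),
            displacement=float(gen.pop("displacement", 6.0)),
            fluct_sigma=float(gen.pop("fluct_sigma", 0.8)),
            intra_corr=float(gen.pop("intra_corr", 0.6)),
        )
        if gen:
            raise ConfigError(f"unknown generator keys {sorted(gen)}")
        traj, labels = trajgen.generate_receptor_trajectory(spec, n_frames, cfg["seed"])
        return traj, spec, labels
    top, _ = read_topology(inp["topology"])
    traj = read_trajectory(inp["trajectory"], top, fmt=inp["trajectory_format"])
    return traj, None, None


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    cfg = validate_config(config)
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "condyn", "version": __version__, "seed": cfg["seed"],
                "config": cfg, "stages": {}, "checksums": {}}
    t0 = time.time()

    def stage(name):
        log.info("[%7.2fs] stage: %s", time.time() - t0, name)
        manifest["stages"][name] = round(time.time() - t0, 3)

    try:
        stage("input")
        traj, spec, hidden = _load_or_generate(cfg)
        sel = select_atoms(traj.topology, cfg["selections"]["analysis"])

        stage("fluct")
        fl = cfg["fluct"]
        series, summary = fluct.rmsd_series(
            traj, sel, equilibration_fraction=fl["equilibration_fraction"])
        _save_matrix(out / "rmsd.csv", series[:, None],
                     f"per-frame RMSD (A); equilibrated mean={summary['mean']:.4f} "
                     f"sd={summary['sd']:.4f}")
        rmsf_vals = fluct.rmsf(traj, sel, reference=fl["reference"])
        _save_matrix(out / "rmsf.csv", rmsf_vals[:, None], "per-residue RMSF (A)")
        corr = fluct.dccm(traj, sel, min_abs=fl["dccm_min_abs"], reference=fl["reference"])
        _save_matrix(out / "dccm.csv", corr.values, "DCCM C_ij")

        stage("pca")
        pc = cfg["pca"]
        model = dimred.fit_pca(traj, sel, mass_weighted=pc["mass_weighted"],
                               reference=fl["reference"])
        n_comp = pc["n_components"] or model.n_components_for_variance(
            pc["variance_fraction"], pc["max_components"])
        log.info("using %d principal components", n_comp)
        scores = dimred.project(traj, sel, model, n_components=n_comp,
                                reference=fl["reference"])
        _save_matrix(out / "pca_eigenvalues.csv", model.eigenvalues[:20][:, None],
                     "leading eigenvalues")
        _save_matrix(out / "projections.csv", scores, "per-frame PC scores")
        _save_matrix(out / "porcupine_pc1.tsv",
                     dimred.porcupine_vectors(model, 0, scale=1.0),
                     "atom anchor_xyz arrow_xyz")

        stage("msm")
        mc = cfg["msm"]
        assign = msm.cluster_microstates(scores, k=min(mc["k"], scores.shape[0] // 10),
                                         max_iter=mc["max_kmeans_iter"], seed=cfg["seed"])
        its = msm.implied_timescales(assign.labels, mc["its_lags"],
                                     reversible=mc["reversible"],
                                     frame_spacing=traj.frame_spacing)
        _save_matrix(out / "its.csv",
                     np.column_stack([its.lags, its.timescales]),
                     "lag_frames, timescales (frames)")
        counts = msm.count_transitions(assign.labels, mc["lag"])
        mod = msm.estimate_transition_matrix(counts, reversible=mc["reversible"],
                                             lag=mc["lag"],
                                             frame_spacing=traj.frame_spacing)
        _save_matrix(out / "transition_matrix.csv", mod.transition_matrix)
        _save_matrix(out / "stationary.csv", mod.stationary_distribution[:, None])
        decomp = msm.pcca_plus(mod, mc["n_macrostates"])
        _save_matrix(out / "macrostate_probabilities.csv",
                     decomp.macrostate_probabilities[:, None],
                     "stationary probability per macrostate")
        _save_matrix(out / "memberships.csv", decomp.memberships, "PCCA+ memberships chi")
        ck = msm.ck_test(assign.labels, mc["lag"], mc["n_macrostates"],
                         factors=mc["ck_factors"], reversible=mc["reversible"])
        _save_matrix(out / "ck.csv",
                     np.column_stack([ck.factors, ck.predicted, ck.estimated]),
                     f"factor, predicted self-transitions, estimated; "
                     f"max_dev={ck.max_deviation:.4g} passed={ck.passed}")
        sink = mc["tpt_sink"] if mc["tpt_sink"] is not None else mc["n_macrostates"] - 1
        tpt = msm.tpt_analysis(mod, mc["tpt_source"], sink, decomposition=decomp)
        _save_matrix(out / "committor.csv", tpt.forward_committor[:, None],
                     f"forward committor; MFPT={tpt.mfpt:.4f} lag units "
                     f"({tpt.mfpt_ns:.2f} ns)")
        # representative conformation per macrostate
        micro_of_frame = np.full(traj.n_frames, -1, dtype=int)
        pos = {s: i for i, s in enumerate(mod.active_set)}
        frame_labels = assign.labels if isinstance(assign.labels, np.ndarray) \
            else np.concatenate(assign.labels)
        rep_rows = []
        for a in range(decomp.n_macrostates):
            members = mod.active_set[decomp.macrostate_of == a]
            pool = np.where(np.isin(frame_labels, members))[0]
            if pool.size < 2:
                log.warning("macrostate %d has <2 frames; skipping representative", a)
                continue
            if pool.size > mc["representative_pool"]:
                pool = pool[np.linspace(0, pool.size - 1,
                                        mc["representative_pool"]).round().astype(int)]
            rep = msm.select_representative(traj.coordinates[pool][:, sel.indices, :])
            rep_rows.append([a, int(pool[rep.frame_index]), rep.score, rep.d_scale])
        _save_matrix(out / "representatives.csv", np.array(rep_rows),
                     "macrostate, frame, score, d_scale(A)")

        stage("network")
        nc = cfg["network"]
        occ = network.contact_occupancy(traj, cutoff=nc["cutoff"],
                                        mode=nc["contact_mode"],
                                        exclude_neighbors=nc["exclude_neighbors"],
                                        max_frames=nc["max_frames"])
        net = network.build_network(occ, corr, nc["occupancy_threshold"])
        eb = network.edge_betweenness(net)
        with open(out / "network_edges.tsv", "w") as fh:
            fh.write("node_i\tnode_j\toccupancy\tC\tweight\tbetweenness\n")
            for (u, v), e in sorted(net.edges.items()):
                fh.write(f"{u}\t{v}\t{e.occupancy:.6g}\t{e.correlation:.6g}\t"
                         f"{e.weight:.6g}\t{eb[(u, v)]:.6g}\n")
        part = network.girvan_newman(net, min_community_size=nc["min_community_size"])
        with open(out / "communities.csv", "w") as fh:
            fh.write(f"# modularity,{part.modularity:.6g}\n")
            for ci, comm in enumerate(part.communities):
                fh.write(f"{ci}," + ";".join(map(str, comm)) + "\n")
            for comm in part.discarded:
                fh.write("discarded," + ";".join(map(str, comm)) + "\n")
        _save_matrix(out / "connectivity.csv", part.intercommunity_connectivity,
                     "inter-community betweenness totals")

        if cfg["interactions"]["enabled"]:
            stage("interactions")
            ic = cfg["interactions"]
            crit = InteractionCriteria(
                hbond_distance_max=ic["hbond_distance_max"],
                hbond_angle_min=ic["hbond_angle_min"],
                weak_hbond_distance_range=tuple(ic["weak_hbond_distance_range"]),
                hydrophobic_distance_max=ic["hydrophobic_distance_max"],
                persistence_min=ic["persistence_min"])
            fp = fingerprint_summary(
                traj,
                select_atoms(traj.topology, cfg["selections"]["ligand"]),
                select_atoms(traj.topology, cfg["selections"]["receptor"]),
                crit)
            with open(out / "fingerprint.csv", "w") as fh:
                fh.write(f"# criteria,{json.dumps(crit.__dict__)}\n")
                fh.write("type,atom_i,atom_j,residue_j,occupancy\n")
                for kind, contacts in (("hbond", fp.hbonds), ("weak_hbond", fp.weak_hbonds),
                                       ("hydrophobic", fp.hydrophobic_contacts)):
                    for c in contacts:
                        fh.write(f"{kind},{c.atom_i},{c.atom_j},{c.residue_j},"
                                 f"{c.occupancy:.6g}\n")
        else:
            log.info("interactions stage skipped (no ligand configured)")
    except Exception as err:
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "input"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {err}") from err

    stage("finalize")
    for artifact in sorted(out.iterdir()):
        if artifact.name != "manifest.json" and artifact.is_file():
            manifest["checksums"][artifact.name] = _sha256(artifact)
    if hidden is not None and spec is not None:
        manifest["ground_truth"] = {
            "stationary_weights": [float(w) for w in spec.stationary_weights],
            "slowest_timescale_frames": trajgen.analytic_slowest_timescale(spec),
            "label_frequencies": [float(f) for f in
                                  np.bincount(hidden, minlength=spec.n_states) / hidden.size],
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def demo_config(output_dir: str = "condyn_demo", seed: int = 0,
                n_frames: int | None = None) -> dict:
    """The bundled synthetic-receptor demo configuration."""
    gen = dict(DEMO_GENERATE)
    if n_frames is not None:
        gen["n_frames"] = int(n_frames)
    return {
        "seed": seed,
        "output_dir": output_dir,
        "input": {"generate": gen},
        "pca": {"mass_weighted": False, "n_components": 2},
        "msm": {"k": 50, "lag": 20, "its_lags": [1, 5, 10, 20, 40],
                "ck_factors": [1, 2, 3]},
        "network": {"contact_mode": "calpha", "max_frames": 1000},
    }
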