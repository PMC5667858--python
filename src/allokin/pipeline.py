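"""End-to-end orchestration: simulate -> dynamics -> PRS -> networks -> rigidity.

A :class:`PipelineConfig` carries every stage parameter (defaults are
the standard values: DMD r_c = 8 A with sigma = 0.05/0.1, GNM r_c =
7.0 A, H-bond cutoff -1.0 kcal/mol, hydrophobic slack 0.25 A, community
stability 0.75, MSA coverage 0.5) plus a seed; ``run_pipeline`` produces
a deterministic bundle of TSV/JSON tables and a manifest sufficient to
reproduce every number bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

import allokin
from allokin import structures as sio
from allokin import synthetic
from allokin.coupling import column_mi, dynamic_rmi, filter_msa, kl_conservation
from allokin.dmd import build_go_model, run_dmd
from allokin.gnm import (
    build_kirchhoff,
    gnm_modes,
    identify_hinges,
    mobility_profile,
    pca_ensemble,
)
from allokin.network import (
    build_rin,
    community_stability,
    edge_betweenness,
    girvan_newman,
    node_betweenness,
    shortest_paths,
)
from allokin.prs import effector_profile, prs_scan, sensor_profile
from allokin.rigidity import (
    build_constraint_network,
    detect_hbonds,
    detect_hydrophobic,
    hb_dilution,
    weak_spot_frequency,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

ALL_STAGES = ("simulate", "enm", "prs", "conserve", "network", "rigidity")


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 7
    stages: tuple[str, ...] = ALL_STAGES
    # input: a synthetic spec, or paths
    synthetic: str | None = "two_lobe"
    pdb: str | None = None
    chain: str | None = None
    msa: str | None = None
    # synthetic two-lobe sizes
    lobe1: int = 20
    lobe2: int = 20
    # DMD stage
    dmd_events: int = 200_000
    temperature: float = 1.0
    nu: float = 1.0
    snapshot_every: int = 1000
    r_c_dmd: float = 8.0
    sigma_bond: float = 0.05
    sigma_native: float = 0.1
    d_hc: float = 4.0
    # GNM / PCA
    r_c_gnm: float = 7.0
    n_modes: int = 10
    # conservation / coupling (synthetic MSA spec when no file given)
    coverage_min: float = 0.5
    msa_n_seq: int = 500
    msa_n_col: int = 40
    msa_conserved: tuple[int, ...] = (5, 15)
    msa_covarying: tuple[tuple[int, int], ...] = ((10, 25),)
    # network stage
    ca_cutoff: float = 7.5
    occupancy_min: float = 0.5
    i_min: float = 3.0
    atom_cutoff: float = 4.5
    stability_min: float = 0.75
    match_jaccard: float = 0.6
    stability_frames: int = 8
    # rigidity stage (synthetic all-atom helix conformers)
    e_cut_hb: float = -1.0
    d_cut_hp: float = 0.25
    rigidity_n_res: int = 12
    rigidity_conformers: int = 5
    rigidity_jitter: float = 0.04  # A, coordinate noise per conformer

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat YAML key/value file into a config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config key(s): {sorted(bad)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    if "msa_conserved" in raw:
        raw["msa_conserved"] = tuple(raw["msa_conserved"])
    if "msa_covarying" in raw:
        raw["msa_covarying"] = tuple(tuple(p) for p in raw["msa_covarying"])
    return PipelineConfig(**raw)


def _get_trace(cfg: PipelineConfig) -> sio.CaTrace:
    if cfg.pdb is not None:
        models = sio.read_pdb(Path(cfg.pdb).read_text())
        return sio.extract_ca_trace(models[0], cfg.chain)
    if cfg.synthetic == "two_lobe":
        return synthetic.make_two_lobe_toy(cfg.lobe1, cfg.lobe2, seed=cfg.seed)
    raise ValueError("no input: set pdb or synthetic='two_lobe'")


def _write(outdir: Path, name: str, text: str) -> None:
    (outdir / name).write_text(text)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Returns a dict with the in-memory results of each stage; every file
    in ``cfg.outdir`` is a deterministic function of the config.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    try:
        trace = _get_trace(cfg)
        results["trace"] = trace
        ensemble = None

        if "simulate" in cfg.stages:
            stage = "simulate"
            model = build_go_model(
                trace, r_c=cfg.r_c_dmd, sigma_bond=cfg.sigma_bond,
                sigma_native=cfg.sigma_native, d_hc=cfg.d_hc,
            )
            ensemble = run_dmd(
                model, trace, n_events=cfg.dmd_events,
                temperature=cfg.temperature, nu=cfg.nu,
                snapshot_every=cfg.snapshot_every, seed=cfg.seed,
            )
            results["ensemble"] = ensemble
            _write(outdir, "trajectory.xyz", sio.write_trajectory(ensemble, "xyz"))
            bf = sio.compute_bfactors(ensemble)
            results["bfactors"] = bf
            _write(outdir, "bfactors.tsv", bf.to_tsv())

        if "enm" in cfg.stages:
            stage = "enm"
            km = build_kirchhoff(trace, r_c=cfg.r_c_gnm)
            modes = gnm_modes(km)
            m = min(cfg.n_modes, len(modes.nonzero_values))
            mob = mobility_profile(modes, m)
            hinges = identify_hinges(mob)
            results["mobility"] = mob
            results["hinges"] = hinges
            prof = sio.ResidueProfile(
                residue_ids=list(trace.residue_ids), values=mob.values,
                name="mobility", units="",
            )
            _write(outdir, "mobility.tsv", prof.to_tsv())
            flags = np.zeros(trace.n_residues)
            flags[sorted(hinges)] = 1.0
            _write(
                outdir, "hinges.tsv",
                sio.ResidueProfile(list(trace.residue_ids), flags, "hinge").to_tsv(),
            )
            if ensemble is not None and ensemble.n_frames >= 10:
                pca = pca_ensemble(ensemble)
                results["pca"] = pca
                _write(
                    outdir, "pca_displacement.tsv",
                    sio.ResidueProfile(
                        list(trace.residue_ids), pca.residue_displacement,
                        "pca_displacement",
                    ).to_tsv(),
                )

        if "prs" in cfg.stages:
            stage = "prs"
            km = build_kirchhoff(trace, r_c=cfg.r_c_gnm)
            s = prs_scan(km)
            eff = effector_profile(s)
            sen = sensor_profile(s)
            results["effector"] = eff
            _write(
                outdir, "effector.tsv",
                sio.ResidueProfile(list(trace.residue_ids), eff.values, "effector").to_tsv(),
            )
            _write(
                outdir, "sensor.tsv",
                sio.ResidueProfile(list(trace.residue_ids), sen.values, "sensor").to_tsv(),
            )
            np.savetxt(outdir / "prs_matrix.tsv", s.values, delimiter="\t", fmt="%.6g")

        if "conserve" in cfg.stages:
            stage = "conserve"
            if cfg.msa is not None:
                from allokin.coupling import read_msa

                msa = read_msa(Path(cfg.msa).read_text())
            else:
                msa = synthetic.make_synthetic_msa(
                    cfg.msa_n_seq, cfg.msa_n_col,
                    conserved_cols=set(cfg.msa_conserved),
                    covarying_pairs=list(cfg.msa_covarying),
                    seed=cfg.seed + 1,
                )
            msa = filter_msa(msa, min_coverage=cfg.coverage_min)
            kl = kl_conservation(msa)
            mi = column_mi(msa)
            results["kl"] = kl
            results["mi"] = mi
            lines = ["column\tkl_nats"]
            lines += [f"{c}\t{v:.6g}" for c, v in enumerate(kl.scores)]
            _write(outdir, "kl_conservation.tsv", "\n".join(lines) + "\n")
            lines = ["i\tj\tmi_nats"]
            n = mi.values.shape[0]
            for i in range(n):
                for j in range(i + 1, n):
                    if np.isfinite(mi.values[i, j]):
                        lines.append(f"{i}\t{j}\t{mi.values[i, j]:.6g}")
            _write(outdir, "mi_pairs.tsv", "\n".join(lines) + "\n")

        if "network" in cfg.stages:
            stage = "network"
            if ensemble is None:
                raise RuntimeError("network stage requires the simulate stage")
            coupling = dynamic_rmi(ensemble)
            graph = build_rin(
                ensemble, coupling, mode="ca_contact",
                ca_cutoff=cfg.ca_cutoff, occupancy_min=cfg.occupancy_min,
            )
            results["graph"] = graph
            _write(outdir, "edges.tsv", graph.to_tsv())
            paths = shortest_paths(graph)
            nb = node_betweenness(graph, paths)
            eb = edge_betweenness(graph, paths)
            results["betweenness"] = nb
            _write(
                outdir, "betweenness.tsv",
                sio.ResidueProfile(
                    list(ensemble.residue_ids), nb.node_values, "betweenness"
                ).to_tsv(),
            )
            lines = ["i\tj\tedge_betweenness"]
            lines += [f"{i}\t{j}\t{v:.6g}" for (i, j), v in sorted(eb.items())]
            _write(outdir, "edge_betweenness.tsv", "\n".join(lines) + "\n")
            comms = girvan_newman(graph)
            results["communities"] = comms
            # per-frame partitions on a frame subsample for the stability rule
            n_sub = min(cfg.stability_frames, ensemble.n_frames)
            pick = np.linspace(0, ensemble.n_frames - 1, n_sub).astype(int)
            frame_parts = []
            for f in pick:
                sub = sio.Ensemble(
                    frames=ensemble.frames[f : f + 1],
                    times=ensemble.times[f : f + 1],
                    residue_ids=list(ensemble.residue_ids),
                )
                gsub = build_rin(
                    sub, coupling, mode="ca_contact",
                    ca_cutoff=cfg.ca_cutoff, occupancy_min=cfg.occupancy_min,
                )
                frame_parts.append(girvan_newman(gsub))
            stable = community_stability(
                frame_parts, stability_min=cfg.stability_min,
                match_jaccard=cfg.match_jaccard,
            )
            results["stable_communities"] = stable
            payload = {
                "modularity": comms.modularity,
                "consensus": [sorted(c) for c in comms.communities],
                "stable": [
                    {"members": sorted(c), "frequency": f}
                    for c, f in zip(stable.communities, stable.stability or [])
                ],
            }
            _write(outdir, "communities.json", json.dumps(payload, indent=1))

        if "rigidity" in cfg.stages:
            stage = "rigidity"
            conformers = _rigidity_conformers(cfg)
            if not conformers:
                raise RuntimeError(
                    "rigidity stage requires an all-atom input: provide a PDB "
                    "with hydrogens or enable the synthetic helix fixture"
                )
            dils = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for s in conformers:
                    net = build_constraint_network(
                        s, hbonds=detect_hbonds(s),
                        tethers=detect_hydrophobic(s, d_cut=cfg.d_cut_hp),
                        e_cut=cfg.e_cut_hb,
                    )
                    dils.append(hb_dilution(net))
            ws = weak_spot_frequency(dils)
            results["weak_spots"] = ws
            _write(outdir, "weak_spots.tsv", ws.to_tsv())
            lines = ["conformer\tstep\tremoved_energy\tgiant_size"]
            for c, d in enumerate(dils):
                for s_, (e, gsz) in enumerate(
                    zip([float("nan")] + d.removal_energies, d.giant_sizes)
                ):
                    lines.append(f"{c}\t{s_}\t{e:.4g}\t{gsz}")
            _write(outdir, "dilution.tsv", "\n".join(lines) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": allokin.__version__,
        "config": _config_dict(cfg),
    }
    _write(outdir, "manifest.json", json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d.pop("outdir")  # location-independent manifest
    d["stages"] = list(cfg.stages)
    d["msa_conserved"] = list(cfg.msa_conserved)
    d["msa_covarying"] = [list(p) for p in cfg.msa_covarying]
    return d


def _rigidity_conformers(cfg: PipelineConfig):
    if cfg.pdb is not None:
        models = sio.read_pdb(Path(cfg.pdb).read_text())
        if not any(e == "H" for e in models[0].elements):
            return []
        return models
    base = synthetic.make_allatom_helix(cfg.rigidity_n_res)
    rng = np.random.default_rng(cfg.seed + 2)
    out = []
    for _ in range(cfg.rigidity_conformers):
        s = synthetic.make_allatom_helix(cfg.rigidity_n_res)
        s.coords = base.coords + rng.normal(0.0, cfg.rigidity_jitter, base.coords.shape)
        out.append(s)
    return out
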