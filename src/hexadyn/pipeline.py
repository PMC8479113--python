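"""Orchestrate the full open/closed two-state comparison.

A single :class:`RunConfig` drives all stages in dependency order — global
metrics (RMSD, core alignment, RMSF, Rg), cross-correlation, essential
dynamics with subspace comparison, SASA/IASA, cavity volumes, tunnels and
CVAE state discrimination — over a pair of trajectories (by default the
bundled synthetic open/closed fixtures).  Every stage writes its tables
under the output directory; failures are recorded and dependent stages
skipped, but a report is always produced.  The global seed propagates to
every stochastic stage and the configuration is echoed into the run
metadata, so a rerun with the same config and seed is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align, cvae, dccm, essential, pockets, surface, synthetic, tunnels
from .synthetic import closed_state_spec, open_state_spec
from .trajio import FrameSelection, Trajectory, read_trajectory, select, write_pdb

TOP = {"A", "B", "C"}
BOTTOM = {"D", "E", "F"}


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "results/run"
    n_frames: int = 60
    # input trajectories; when None, synthetic fixtures are generated
    open_trajectory: str | None = None
    closed_trajectory: str | None = None
    # stage toggles
    run_global_metrics: bool = True
    run_dccm: bool = True
    run_pca: bool = True
    run_surface: bool = True
    run_pockets: bool = True
    run_tunnels: bool = True
    run_cvae: bool = True
    # stage parameters
    core_fraction: float = 0.7
    pca_modes: int = 10
    sasa_points: int = 240
    pocket_spacing: float = 1.0
    pocket_frames: int = 2
    tunnel_spacing: float = 0.8
    tunnel_frames: int = 1
    cvae_latent_dim: int = 7
    cvae_epochs: int = 30
    cvae_frames_per_state: int = 150

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ComparisonReport:
    sections: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    output_dir: str = ""

    def to_json(self, path: str) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        with open(path, "w") as fh:
            json.dump(_clean({"sections": self.sections, "errors": self.errors,
                              "skipped": self.skipped}), fh, indent=2)


def _load_states(c: RunConfig) -> dict[str, tuple[Trajectory, synthetic.SyntheticSpec]]:
    states = {}
    # distinct seeds per state: a shared seed would reuse the same thermal
    # noise realization in both states and correlate their fluctuations
    for name, path, spec_fn, seed in (
        ("open", c.open_trajectory, open_state_spec, c.seed),
        ("closed", c.closed_trajectory, closed_state_spec, c.seed + 1),
    ):
        spec = spec_fn(seed=seed, n_frames=c.n_frames)
        if path is not None:
            traj = read_trajectory(path)
        else:
            traj = synthetic.generate_hexamer_trajectory(spec)
        states[name] = (traj, spec)
    return states


def run_pipeline(c: RunConfig) -> ComparisonReport:
    out = Path(c.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = ComparisonReport(output_dir=str(out))
    t_start = time.time()
    states = _load_states(c)

    def stage(name, enabled, fn):
        if not enabled:
            report.skipped.append(name)
            return
        try:
            report.sections[name] = fn()
        except Exception as exc:  # recorded, dependent stages skipped
            report.errors[name] = f"{type(exc).__name__}: {exc}"

    def global_metrics():
        rows = []
        for name, (traj, _) in states.items():
            ca = traj.topology.mask(name="CA")
            rmsd = align.conventional_rmsd(traj, mask=ca)
            core = align.core_align(traj, c.core_fraction, mask=ca)
            prof = align.rmsf(traj, mask=ca)
            rg = align.radius_of_gyration(traj, mask=ca)
            pd.DataFrame({"frame": np.arange(traj.n_frames), "rmsd_A": rmsd,
                          "core_rmsd_A": core.core_rmsd, "rg_A": rg}).to_csv(
                out / f"global_{name}.csv", index=False)
            pd.DataFrame({"atom": np.arange(prof.rmsf.size),
                          "rmsf_A": prof.rmsf}).to_csv(
                out / f"rmsf_{name}.csv", index=False)
            rows.append({
                "state": name,
                "mean_rmsd_A": float(rmsd.mean()),
                "mean_core_rmsd_A": float(core.core_rmsd.mean()),
                "core_fraction": c.core_fraction,
                "mean_rg_A": float(rg.mean()),
                "mean_rmsf_A": float(prof.rmsf.mean()),
            })
        return rows

    def dccm_stage():
        summary = {}
        for name, (traj, _) in states.items():
            ca = traj.topology.mask(name="CA")
            m = dccm.compute_dccm(traj, mask=ca)
            np.savetxt(out / f"dccm_{name}.csv", m.values, delimiter=",", fmt="%.5f")
            n_per = 60
            blocks = dccm.dccm_block_summary(
                m, {ch: (n_per * i, n_per * (i + 1))
                    for i, ch in enumerate("ABCDEF")})
            summary[name] = {f"{a}-{b}": v for (a, b), v in blocks.items()}
        return summary

    def pca_stage():
        ca_masks = {n: t.topology.mask(name="CA") for n, (t, _) in states.items()}
        modes = {
            n: essential.fit_pca(t, mask=ca_masks[n])
            for n, (t, _) in states.items()
        }
        for n, em in modes.items():
            pd.DataFrame({"mode": np.arange(em.eigenvalues.size),
                          "eigenvalue_A2": em.eigenvalues}).to_csv(
                out / f"pca_spectrum_{n}.csv", index=False)
        comp = essential.compare_subspaces(modes["open"], modes["closed"],
                                           k=c.pca_modes)
        np.savetxt(out / "pca_dot_matrix.csv", comp.dot_product_matrix,
                   delimiter=",", fmt="%.5f")
        return {
            "rmsip": comp.rmsip,
            "subspace_overlap_percent": comp.subspace_overlap_percent,
            "average_max_dot": comp.average_max_dot,
            "k": comp.k,
            "ev1_share": {
                n: float(m.eigenvalues[0] / m.eigenvalues.sum())
                for n, m in modes.items()
            },
        }

    def surface_stage():
        summary = {}
        for name, (traj, _) in states.items():
            total, per_chain = surface.sasa_series(
                traj.__class__(topology=traj.topology,
                               coordinates=traj.coordinates[:4]),
                n_points=c.sasa_points)
            res = surface.iasa(
                traj.__class__(topology=traj.topology,
                               coordinates=traj.coordinates[:4]),
                group_a=TOP, group_b=BOTTOM, n_points=c.sasa_points)
            pd.DataFrame({"frame": np.arange(total.size), "sasa_A2": total,
                          "iasa_A2": res.iasa}).to_csv(
                out / f"surface_{name}.csv", index=False)
            summary[name] = {
                "mean_sasa_A2": float(total.mean()),
                "mean_subunit_sasa_A2": float(
                    np.mean([v.mean() for v in per_chain.values()])),
                "mean_iasa_A2": float(res.iasa.mean()),
            }
        return summary

    def pockets_stage():
        summary = {}
        for name, (traj, _) in states.items():
            frames = np.arange(min(c.pocket_frames, traj.n_frames))
            total_union = 0.0
            per_sub = {}
            for ch in sorted(TOP | BOTTOM):
                g = pockets.detect_pockets(
                    traj, mask=traj.topology.mask(chain=ch),
                    spacing=c.pocket_spacing, frames=frames)
                per_sub[ch] = g.cumulative_volume_union
                total_union += g.cumulative_volume_union
            summary[name] = {"cumulative_volume_A3": total_union,
                             "per_subunit_A3": per_sub}
        pd.DataFrame(summary).to_csv(out / "pocket_volumes.csv")
        return summary

    def tunnels_stage():
        summary = {}
        for name, (traj, spec) in states.items():
            paths = []
            for fr in range(min(c.tunnel_frames, traj.n_frames)):
                for ch in ("A",):
                    start = synthetic.tunnel_start_point(traj, ch, spec, frame=fr)
                    paths += tunnels.find_tunnels(
                        traj.coordinates[fr], topology=traj.topology,
                        start_point=start, probe_radius=1.0,
                        spacing=c.tunnel_spacing, frame_index=fr)
            if paths:
                clusters = tunnels.cluster_tunnels(paths)
                table = tunnels.tunnel_summary(clusters)
                table.to_csv(out / f"tunnels_{name}.csv", index=False)
                summary[name] = {
                    "n_clusters": len(clusters),
                    "max_bottleneck_A": float(
                        max(cl.max_bottleneck for cl in clusters)),
                    "average_throughput": float(
                        np.mean([cl.average_throughput for cl in clusters])),
                }
            else:
                summary[name] = {"n_clusters": 0, "max_bottleneck_A": 0.0,
                                 "average_throughput": 0.0}
        return summary

    def cvae_stage():
        d = synthetic.generate_site_distance_dataset(
            open_state_spec(seed=c.seed),
            closed_state_spec(seed=c.seed + 1),
            frames_per_state=c.cvae_frames_per_state,
            split_seed=c.seed,
        )
        model = cvae.train_cvae(d, latent_dim=c.cvae_latent_dim,
                                epochs=c.cvae_epochs, seed=c.seed)
        emb = cvae.embed(model, d, method="linear")
        from sklearn.metrics import silhouette_score

        sil = float(silhouette_score(emb.latent, d.labels))
        table = pd.DataFrame({
            "frame": np.arange(d.n_frames),
            "label": d.labels,
            **{f"z{i}": emb.latent[:, i] for i in range(emb.latent.shape[1])},
        })
        table.to_csv(out / "cvae_embedding.csv", index=False)
        return {
            "latent_dim": c.cvae_latent_dim,
            "val_loss_first": float(model.val_loss[0]),
            "val_loss_last": float(model.val_loss[-1]),
            "latent_silhouette": sil,
        }

    stage("global_metrics", c.run_global_metrics, global_metrics)
    stage("dccm", c.run_dccm, dccm_stage)
    stage("pca", c.run_pca, pca_stage)
    stage("surface", c.run_surface, surface_stage)
    stage("pockets", c.run_pockets, pockets_stage)
    stage("tunnels", c.run_tunnels, tunnels_stage)
    stage("cvae", c.run_cvae, cvae_stage)

    meta = {"config": c.to_dict(), "wall_time_s": time.time() - t_start}
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    report.to_json(str(out / "report.json"))
    return report


def make_fixtures(seed: int = 0, output_dir: str = "results/fixtures") -> dict:
    """Write the default synthetic open/closed fixtures and toy geometries.

    Returns a manifest mapping each file to its sha256 checksum;
    regeneration with the same seed reproduces the checksums.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, spec_fn in (("open", open_state_spec), ("closed", closed_state_spec)):
        traj = synthetic.generate_hexamer_trajectory(spec_fn(seed=seed, n_frames=20))
        path = out / f"hexamer_{name}.pdb"
        write_pdb(traj, str(path))
        files[path.name] = path
    for kind, params in (
        ("sphere", {"radius": 1.7}),
        ("shell_cavity", {"cavity_side": 6.0}),
        ("channel", {"radius": 2.0, "length": 10.0}),
    ):
        geom = synthetic.generate_toy_geometry(kind, **params)
        path = out / f"toy_{kind}.pdb"
        write_pdb(geom.as_trajectory(), str(path))
        truth = out / f"toy_{kind}.json"
        with open(truth, "w") as fh:
            json.dump({"kind": kind, **{k: float(v) for k, v in
                                        geom.ground_truth.items()}}, fh)
        files[path.name] = path
        files[truth.name] = truth
    manifest = {}
    for name, path in files.items():
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
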