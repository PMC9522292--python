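"""Trajectory persistence and run summaries.

Trajectories are written as HDF5 (frames as datasets, the event log as a
table, the full configuration as a JSON attribute) with a CSV fallback for
the frame tables.  A run directory holds per-replicate trajectory files,
ensemble summary CSVs, and a machine-readable manifest (config hash +
seeds) sufficient to reproduce the run exactly.  Writes go through a
temporary file and an atomic rename, so interrupted runs never leave
half-written artifacts and can be resumed.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import List, Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from . import observables
from .config_io import config_hash, config_to_dict, load_config
from .engine import RunControl
from .state import SimulationConfig, Trajectory

__all__ = [
    "save_trajectory",
    "save_frames_csv",
    "load_trajectory",
    "save_ensemble",
    "ensemble_summary",
    "write_manifest",
]


def _atomic(path: Path):
    return path.with_name(path.name + ".tmp")


def save_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write one trajectory as HDF5 (atomic rename on completion)."""
    path = Path(path)
    tmp = _atomic(path)
    cfg: SimulationConfig = traj.metadata["config"]
    with h5py.File(tmp, "w") as h5:
        h5.attrs["config_json"] = json.dumps(config_to_dict(cfg))
        h5.attrs["seed"] = int(traj.metadata["seed"])
        h5.attrs["engine"] = traj.metadata.get("engine", "unknown")
        h5.attrs["record_dt"] = float(traj.metadata["record_dt"])
        h5.attrs["t_end"] = float(traj.metadata["t_end"])
        h5.create_dataset("times", data=traj.times)
        h5.create_dataset("mrna", data=traj.mrna)
        h5.create_dataset("loop_state", data=traj.loop_state.astype(np.int8))
        if traj.turn is not None:
            h5.create_dataset("turn", data=traj.turn, compression="gzip")
        # ragged per-frame RNAP snapshots flattened with a frame column
        rows = []
        for f, arr in enumerate(traj.rnap_frames):
            for r in arr:
                rows.append((f, r[0], r[1], r[2], r[3]))
        h5.create_dataset(
            "rnap", data=np.array(rows, dtype=np.int64).reshape(len(rows), 5)
        )
        ev = traj.events
        g = h5.create_group("events")
        g.create_dataset("t", data=ev["t"])
        g.create_dataset("kind", data=np.array([k.encode() for k in ev["kind"]]))
        g.create_dataset("gene", data=ev["gene"])
        g.create_dataset("rnap_id", data=ev["rnap_id"])
        g.create_dataset("value", data=ev["value"])
        if traj.region_means:
            rg = h5.create_group("region_means")
            for name, v in traj.region_means.items():
                rg.create_dataset(name, data=v)
        if traj.final_counters:
            h5.attrs["final_counters_json"] = json.dumps(
                {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in traj.final_counters.items()
                }
            )
    os.replace(tmp, path)


def load_trajectory(path: Union[str, Path]) -> Trajectory:
    """Read a trajectory back; the embedded configuration is revalidated."""
    import tempfile

    path = Path(path)
    with h5py.File(path, "r") as h5:
        cfg_doc = json.loads(h5.attrs["config_json"])
        with tempfile.NamedTemporaryFile("w", suffix=".json", delete=False) as fh:
            json.dump(cfg_doc, fh)
            tmp_name = fh.name
        try:
            cfg, _ = load_config(tmp_name)
        finally:
            os.unlink(tmp_name)
        times = h5["times"][:]
        n_frames = len(times)
        rnap_rows = h5["rnap"][:]
        rnap_frames: List[np.ndarray] = [
            np.empty((0, 4), np.int64) for _ in range(n_frames)
        ]
        if len(rnap_rows):
            for f in np.unique(rnap_rows[:, 0]):
                sel = rnap_rows[rnap_rows[:, 0] == f]
                rnap_frames[int(f)] = sel[:, 1:5]
        ev = h5["events"]
        events = np.array(
            [
                (t, k.decode(), g, r, v)
                for t, k, g, r, v in zip(
                    ev["t"][:], ev["kind"][:], ev["gene"][:], ev["rnap_id"][:], ev["value"][:]
                )
            ],
            dtype=Trajectory.EVENT_DTYPE,
        )
        region_means = None
        if "region_means" in h5:
            region_means = {k: h5["region_means"][k][:] for k in h5["region_means"]}
        final_counters = None
        if "final_counters_json" in h5.attrs:
            final_counters = json.loads(h5.attrs["final_counters_json"])
        return Trajectory(
            times=times,
            mrna=h5["mrna"][:],
            rnap_frames=rnap_frames,
            loop_state=h5["loop_state"][:].astype(bool),
            events=events,
            metadata={
                "config": cfg,
                "seed": int(h5.attrs["seed"]),
                "engine": str(h5.attrs["engine"]),
                "record_dt": float(h5.attrs["record_dt"]),
                "t_end": float(h5.attrs["t_end"]),
            },
            turn=h5["turn"][:] if "turn" in h5 else None,
            region_means=region_means,
            final_counters=final_counters,
        )


def save_frames_csv(traj: Trajectory, path: Union[str, Path]) -> None:
    """CSV fallback for the per-frame tables: one row per frame with mRNA
    counts, loop state, RNAP count and (optionally) region densities."""
    path = Path(path)
    cfg: SimulationConfig = traj.metadata["config"]
    data = {"t_s": traj.times}
    for g, gene in enumerate(cfg.genes):
        data[f"mrna_{gene.name}"] = traj.mrna[:, g]
    for b in range(traj.loop_state.shape[1]):
        data[f"looped_{b}"] = traj.loop_state[:, b].astype(int)
    data["n_rnap"] = [len(a) for a in traj.rnap_frames]
    if traj.region_means:
        for name, v in traj.region_means.items():
            data[f"sigma_{name}"] = v
    tmp = _atomic(path)
    pd.DataFrame(data).to_csv(tmp, index=False)
    os.replace(tmp, path)


def ensemble_summary(
    trajs: Sequence[Trajectory], window: Optional[tuple] = None
) -> pd.DataFrame:
    """One row per replicate: seed, event counts, final mRNA, realized rates."""
    rows = []
    for tr in trajs:
        cfg: SimulationConfig = tr.metadata["config"]
        t_end = float(tr.metadata["t_end"])
        w = window or (0.0, t_end)
        for g, gene in enumerate(cfg.genes):
            ini = tr.events_of("initiation")
            ini = ini[ini["gene"] == g]
            n_init = int(((ini["t"] >= w[0]) & (ini["t"] <= w[1])).sum())
            rates = observables.transcript_rates([tr], w, gene=g)
            rows.append(
                {
                    "seed": tr.metadata["seed"],
                    "gene": gene.name,
                    "window_start_s": w[0],
                    "window_end_s": w[1],
                    "initiations": n_init,
                    "empirical_initiation_rate_per_s": n_init / (w[1] - w[0]),
                    "mean_elongation_rate_bp_per_s": rates.mean() if rates.size else np.nan,
                    "n_transcripts": int(rates.size),
                    "mrna_final": int(tr.mrna[-1, g]),
                }
            )
    return pd.DataFrame(rows)


def write_manifest(
    out_dir: Union[str, Path],
    cfg: SimulationConfig,
    run: RunControl,
    trajectory_files: Sequence[str],
) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "config_hash": config_hash(cfg, run),
        "base_seed": int(run.seed),
        "n_replicates": int(run.n_replicates),
        "replicate_seeds": [run.replicate_seed(i) for i in range(run.n_replicates)],
        "trajectories": list(trajectory_files),
    }
    path = out_dir / "manifest.json"
    tmp = _atomic(path)
    tmp.write_text(json.dumps(manifest, indent=2))
    os.replace(tmp, path)
    return path


def save_ensemble(
    trajs: Sequence[Trajectory],
    out_dir: Union[str, Path],
    run: RunControl,
    window: Optional[tuple] = None,
    save_h5: bool = True,
) -> Path:
    """Persist an ensemble: per-replicate HDF5 files, a summary CSV, the
    resolved config, and the manifest.  Returns the run directory."""
    from .config_io import dump_config

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg: SimulationConfig = trajs[0].metadata["config"]
    files = []
    if save_h5:
        for tr in trajs:
            name = f"trajectory_seed{tr.metadata['seed']}.h5"
            save_trajectory(tr, out_dir / name)
            files.append(name)
    summary = ensemble_summary(trajs, window=window)
    tmp = _atomic(out_dir / "summary.csv")
    summary.to_csv(tmp, index=False)
    os.replace(tmp, out_dir / "summary.csv")
    dump_config(cfg, out_dir / "config.yaml", run=run)
    write_manifest(out_dir, cfg, run, files)
    return out_dir
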