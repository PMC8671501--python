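"""File formats, run configuration and the pipeline orchestrator.

TA maps round-trip to a delimited text matrix (header row = probe
energies in eV, first column = delays in fs) with a JSON metadata
sidecar -- the same layout used to ingest deposited experimental maps.
Trajectory ensembles round-trip to an HDF5 container.  A pipeline run
executes sample -> propagate -> spectra -> fits -> oscillations ->
channels and writes a manifest with seeds, config hash and output
hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import analysis, channels as channels_mod, spectroscopy
from .fssh import Ensemble, HopEvent, Trajectory, diabatic_rehop, run_ensemble
from .initial import excitation_window, sample_for_model
from .models import ElectronicModel, make_pucker_model, model_from_config, model_to_config
from .spectroscopy import TAMap


# ---------------------------------------------------------------------------
# TA map text format
# ---------------------------------------------------------------------------

def write_tamap(tamap: TAMap, path: str | Path) -> Path:
    """Write a map as a delimited text matrix plus a JSON sidecar."""
    path = Path(path)
    n_d, n_e = tamap.delta_a.shape
    out = np.zeros((n_d + 1, n_e + 1))
    out[0, 0] = np.nan
    out[0, 1:] = tamap.probe_energies_ev
    out[1:, 0] = tamap.delays_fs
    out[1:, 1:] = tamap.delta_a
    header = "\t".join(
        ["delay_fs\\probe_eV"] + [f"{e:.9g}" for e in tamap.probe_energies_ev]
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(n_d):
            row = [f"{tamap.delays_fs[i]:.9g}"] + [
                f"{v:.9e}" for v in tamap.delta_a[i]
            ]
            fh.write("\t".join(row) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(_jsonable(tamap.metadata), fh, indent=1)
    return path


def read_tamap(path: str | Path, column_map: dict | None = None) -> TAMap:
    """Read the text-matrix TA map format.

    Raises a parse error naming the offending line for ragged rows or
    non-monotone axes.  ``column_map`` allows header-name variants when
    ingesting externally deposited matrices.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    try:
        energies = np.array([float(x) for x in header[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}:1: cannot parse probe energies: {exc}") from exc
    delays, rows = [], []
    n_cols = len(header)
    for k, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_cols:
            raise ValueError(
                f"{path}:{k}: ragged row ({len(parts)} fields, expected {n_cols})"
            )
        try:
            delays.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{k}: {exc}") from exc
    delays = np.array(delays)
    if np.any(np.diff(delays) <= 0):
        bad = int(np.argmax(np.diff(delays) <= 0)) + 3
        raise ValueError(f"{path}:{bad}: delay axis is not strictly increasing")
    if np.any(np.diff(energies) <= 0):
        raise ValueError(f"{path}:1: probe-energy axis is not strictly increasing")
    metadata = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    return TAMap(
        delays_fs=delays,
        probe_energies_ev=energies,
        delta_a=np.array(rows),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# trajectory store (HDF5)
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: Ensemble, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["base_seed"] = ensemble.base_seed
        fh.attrs["metadata"] = json.dumps(_jsonable(ensemble.metadata))
        if ensemble.model is not None:
            fh.attrs["model_config"] = yaml.safe_dump(model_to_config(ensemble.model))
        for i, tr in enumerate(ensemble.trajectories):
            g = fh.create_group(f"trajectory_{i:04d}")
            g.create_dataset("time_fs", data=tr.t_fs)
            g.create_dataset("q", data=tr.q)
            g.create_dataset("p", data=tr.p)
            g.create_dataset("active", data=tr.active)
            g.create_dataset("amplitudes_re", data=tr.amplitudes.real)
            g.create_dataset("amplitudes_im", data=tr.amplitudes.imag)
            g.create_dataset("energies", data=tr.energies)
            g.create_dataset("dipoles", data=tr.dipoles)
            g.attrs["seed"] = tr.seed
            g.attrs["valid"] = tr.valid
            g.attrs["energy_drift"] = tr.energy_drift
            g.attrs["hop_to_gs_fs"] = tr.hop_to_gs_fs
            g.attrs["start_state"] = tr.start_state
            ev = np.array(
                [
                    (e.t_hop_fs, e.from_state, e.to_state, int(e.accepted), e.kinetic_deficit_ev)
                    for e in tr.events
                ]
            )
            g.create_dataset("events", data=ev if ev.size else np.zeros((0, 5)))
            g.create_dataset(
                "event_q", data=np.array([e.q_at_hop for e in tr.events])
                if tr.events
                else np.zeros((0, tr.q.shape[1])),
            )
    return path


def load_ensemble(path: str | Path) -> Ensemble:
    path = Path(path)
    trajectories = []
    with h5py.File(path, "r") as fh:
        model = None
        if "model_config" in fh.attrs:
            model = model_from_config(yaml.safe_load(fh.attrs["model_config"]))
        keys = sorted(k for k in fh.keys() if k.startswith("trajectory_"))
        for k in keys:
            g = fh[k]
            events = []
            ev = np.asarray(g["events"])
            evq = np.asarray(g["event_q"])
            for row, qh in zip(ev, evq):
                events.append(
                    HopEvent(
                        t_hop_fs=row[0],
                        from_state=int(row[1]),
                        to_state=int(row[2]),
                        accepted=bool(row[3]),
                        q_at_hop=qh,
                        kinetic_deficit_ev=row[4],
                    )
                )
            trajectories.append(
                Trajectory(
                    t_fs=np.asarray(g["time_fs"]),
                    q=np.asarray(g["q"]),
                    p=np.asarray(g["p"]),
                    active=np.asarray(g["active"]),
                    amplitudes=np.asarray(g["amplitudes_re"])
                    + 1j * np.asarray(g["amplitudes_im"]),
                    energies=np.asarray(g["energies"]),
                    dipoles=np.asarray(g["dipoles"]),
                    events=events,
                    seed=int(g.attrs["seed"]),
                    valid=bool(g.attrs["valid"]),
                    energy_drift=float(g.attrs["energy_drift"]),
                    hop_to_gs_fs=float(g.attrs["hop_to_gs_fs"]),
                    start_state=int(g.attrs["start_state"]),
                )
            )
        base_seed = int(fh.attrs["base_seed"])
        metadata = json.loads(fh.attrs["metadata"])
    return Ensemble(trajectories=trajectories, model=model, base_seed=base_seed, metadata=metadata)


def populations_to_csv(ensemble: Ensemble, path: str | Path) -> Path:
    t, P = ensemble.populations()
    labels = (
        list(ensemble.model.labels)
        if ensemble.model is not None
        else [f"state_{i}" for i in range(P.shape[1])]
    )
    cols = {"time_fs": t}
    name_map = {"S0": "P_S0", "pipi*": "P_bright", "npi*": "P_dark"}
    for i, lab in enumerate(labels):
        cols[name_map.get(lab, f"P_{lab}")] = P[:, i]
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.6f")
    return Path(path)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

PRESETS = {
    "urd-like": {
        "model": {
            "kind": "pucker",
            "params": {
                "pucker_mass_amu": 1.0,
                "solvent_coupling_eV": 0.0,
                "barrier_eV": 0.0,
                "dark_offset_eV": 0.15,
            },
        },
        "sampling": {"n": 500, "n_select": 57, "window_eV": [4.43, 4.75]},
        "dynamics": {"dt_fs": 0.08, "t_max_fs": 500.0},
        "rehop": {"dark_coupling_eV": 0.04},
    },
    "5murd-like": {
        "model": {
            "kind": "pucker",
            "params": {
                "pucker_mass_amu": 15.0,
                "solvent_coupling_eV": 0.15,
                "solvent_tau_fs": 85.0,
                "barrier_eV": 0.0,
                "dark_offset_eV": 0.6,
            },
        },
        "sampling": {"n": 500, "n_select": 57, "window_eV": [4.43, 4.75]},
        "dynamics": {"dt_fs": 0.2, "t_max_fs": 1000.0},
        "rehop": {"dark_coupling_eV": 0.015},
    },
}


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    model: dict = field(default_factory=lambda: {"kind": "pucker", "params": {}})
    sampling: dict = field(
        default_factory=lambda: {"n": 500, "n_select": 57, "window_eV": [4.43, 4.75]}
    )
    dynamics: dict = field(
        default_factory=lambda: {
            "dt_fs": 0.25,
            "t_max_fs": 500.0,
            "decoherence_C": 0.1,
            "frustrated_reversal": False,
            "gs_continuation_fs": 200.0,
        }
    )
    spectroscopy: dict = field(
        default_factory=lambda: {
            "sigma_e_ev": 0.15,
            "irf_fwhm_fs": 30.0,
            "probe_min_ev": 1.8,
            "probe_max_ev": 4.8,
            "probe_step_ev": 0.02,
        }
    )
    analysis: dict = field(
        default_factory=lambda: {
            "n_exp": 2,
            "passband_cm": [300.0, 1200.0],
            "t_start_fs": 50.0,
            "window_fn": "hann",
            "zero_pad_factor": 4,
        }
    )
    seed: int = 1
    output_dir: str = "run_output"

    @classmethod
    def from_preset(cls, name: str, seed: int = 1, output_dir: str | None = None) -> "RunConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        cfg = cls(seed=seed)
        preset = PRESETS[name]
        cfg.model = json.loads(json.dumps(preset["model"]))
        cfg.sampling.update(preset.get("sampling", {}))
        cfg.dynamics.update(preset.get("dynamics", {}))
        cfg.output_dir = output_dir or f"run_{name}"
        return cfg

    def validate(self) -> None:
        if self.dynamics.get("dt_fs", 0) <= 0:
            raise ValueError("dynamics.dt_fs must be positive")
        if self.dynamics.get("t_max_fs", 0) <= 0:
            raise ValueError("dynamics.t_max_fs must be positive")
        if self.sampling.get("n", 0) < 1:
            raise ValueError("sampling.n must be >= 1")

    def to_yaml(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls()
        for k, v in data.items():
            setattr(cfg, k, v)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_model(model_cfg: dict) -> ElectronicModel:
    kind = model_cfg.get("kind", "pucker")
    params = model_cfg.get("params", {})
    if kind == "pucker":
        return make_pucker_model(params)
    return model_from_config(model_cfg)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full chain and write all artifacts plus a manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "files": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    config.to_yaml(out / "config.yaml")
    try:
        model = build_model(config.model)

        t0 = time.time()
        samples = sample_for_model(model, config.sampling["n"], seed=config.seed)
        window = tuple(config.sampling.get("window_eV", (0.0, np.inf)))
        filtered = excitation_window(samples, model, window)
        n_sel = config.sampling.get("n_select")
        chosen = filtered.samples
        if n_sel and len(chosen) > n_sel:  # uniform thinning
            idx = np.linspace(0, len(chosen) - 1, n_sel).round().astype(int)
            chosen = [chosen[i] for i in idx]
        manifest["stages"]["sample"] = {
            "n_raw": len(samples),
            "n_window": len(filtered.samples),
            "acceptance_ratio": filtered.acceptance_ratio,
            "n_selected": len(chosen),
            "seconds": round(time.time() - t0, 2),
        }

        t0 = time.time()
        dyn = config.dynamics
        ensemble = run_ensemble(
            model,
            chosen,
            base_seed=config.seed,
            dt_fs=dyn.get("dt_fs", 0.25),
            t_max_fs=dyn.get("t_max_fs", 500.0),
            decoherence_C=dyn.get("decoherence_C", 0.1),
            frustrated_reversal=dyn.get("frustrated_reversal", False),
            gs_continuation_fs=dyn.get("gs_continuation_fs", 200.0),
        )
        save_ensemble(ensemble, out / "trajectories.h5")
        populations_to_csv(ensemble, out / "populations.csv")
        n_invalid = sum(1 for tr in ensemble.trajectories if not tr.valid)
        manifest["stages"]["propagate"] = {
            "n_trajectories": len(ensemble.trajectories),
            "n_invalid": n_invalid,
            "seconds": round(time.time() - t0, 2),
        }

        # population lifetime
        t_grid, P = ensemble.populations()
        bright = list(model.labels).index("pipi*")
        tau, err = analysis.fit_population_lifetime(t_grid, P[:, bright], plateau=False)
        manifest["stages"]["lifetime"] = {"tau_fs": tau, "stderr_fs": err}

        t0 = time.time()
        spec = config.spectroscopy
        probe = np.arange(
            spec["probe_min_ev"], spec["probe_max_ev"] + 1e-9, spec["probe_step_ev"]
        )
        tamap = spectroscopy.ensemble_ta_map(
            ensemble,
            sigma_e_ev=spec["sigma_e_ev"],
            irf_fwhm_fs=spec["irf_fwhm_fs"],
            probe_energies_ev=probe,
        )
        write_tamap(tamap, out / "ta_map.tsv")
        manifest["stages"]["spectra"] = {"seconds": round(time.time() - t0, 2)}

        ana = config.analysis
        fit = analysis.global_fit(tamap, n_exp=ana["n_exp"], irf_fwhm_fs=spec["irf_fwhm_fs"])
        (out / "global_fit.json").write_text(
            json.dumps(
                _jsonable(
                    {
                        "taus_fs": fit.taus_fs,
                        "tau_stderr_fs": fit.tau_stderr_fs,
                        "residual_rms": fit.residual_rms,
                        "t0_fs": fit.t0_fs,
                    }
                ),
                indent=1,
            )
        )

        resid = analysis.extract_oscillations(
            tamap, passband_cm=tuple(ana["passband_cm"]), t_start_fs=ana["t_start_fs"]
        )
        oscmap = analysis.ftmap_2d(
            resid, window_fn=ana["window_fn"], zero_pad_factor=ana["zero_pad_factor"]
        )
        # dominant wavenumber inside the passband and its node analysis
        band = (oscmap.wavenumbers_cm >= ana["passband_cm"][0]) & (
            oscmap.wavenumbers_cm <= ana["passband_cm"][1]
        )
        mean_amp = oscmap.amplitude[:, band].mean(axis=0)
        nu_star = float(oscmap.wavenumbers_cm[band][np.argmax(mean_amp)])
        node = analysis.node_phase_analysis(oscmap, nu_star)
        (out / "oscillations.json").write_text(
            json.dumps(
                _jsonable(
                    {
                        "dominant_wavenumber_cm": nu_star,
                        "dominant_period_fs": analysis.wavenumber_to_period(nu_star),
                        "node_found": node.found,
                        "node_energy_ev": node.node_energy_ev,
                        "phase_jump_rad": node.phase_jump_rad,
                    }
                ),
                indent=1,
            )
        )

        report = channels_mod.channel_yields(ensemble)
        pd.DataFrame(
            {"trajectory": range(len(report.labels)), "channel": report.labels}
        ).to_csv(out / "channel_labels.csv", index=False)
        surv_t = min(dyn.get("t_max_fs", 500.0), 1000.0)
        try:
            surv, surv_ci = channels_mod.survival_fraction(ensemble, surv_t)
        except ValueError:
            surv, surv_ci = np.nan, (np.nan, np.nan)
        (out / "channels.json").write_text(
            json.dumps(
                _jsonable(
                    {
                        "counts": report.counts,
                        "fractions": report.fractions,
                        "intervals": report.intervals,
                        "n_decayed": report.n_decayed,
                        "n_total": report.n_total,
                        "survival_t_fs": surv_t,
                        "survival_fraction": surv,
                        "survival_ci95": surv_ci,
                    }
                ),
                indent=1,
            )
        )
        manifest["stages"]["analysis"] = {"completed": True}
        status = "complete"
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        status = "partial"
    manifest["status"] = status
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
    if status != "complete":
        raise RuntimeError(f"pipeline failed: {manifest['error']}")
    return out
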