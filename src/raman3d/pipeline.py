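"""End-to-end experiment orchestration.

One config drives six stages — phantom generation → Poisson-Gaussian
corruption → train/val/test split → network training → denoising (network
plus tuned classical baselines) → evaluation — mirroring a full synthetic
denoising study at desk scale.  Every stage is seeded from the single
experiment seed, artifacts land under ``out_dir`` in the package's HDF5
cube layout, and a JSON manifest records config, seeds, stage wall times
and artifact paths.  A completed stage is skipped on ``resume=True``.

Cubes are min-max normalized per cube (one global min/max pair) before
entering the network, and all metrics are computed on normalized data with
dynamic range 1 — the convention is recorded in each report.
"""

from __future__ import annotations

import json
import os
import subprocess
import sys
import time
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from raman3d import __version__
from raman3d.cube import HyperspectralCube, min_max_denormalize, min_max_normalize, read_cube, write_cube
from raman3d.baselines import pca_denoise, sg_denoise, tune_pca, tune_sg
from raman3d.errors import ConfigError
from raman3d.metrics import evaluate
from raman3d.noise import NoiseModelParams, corrupt
from raman3d.nn.model import NetworkSpec, build_network, denoise_cube_array
from raman3d.phantom import PhantomSpec
from raman3d.training import (
    AugmentFlags,
    TrainConfig,
    load_checkpoint,
    save_checkpoint,
    split_dataset,
    train,
)

STAGES = ("phantom", "corrupt", "split", "train", "denoise", "evaluate")


# ---------------------------------------------------------------------------
# config handling
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "runs/experiment",
    "n_cubes": 12,
    "phantom": {},  # PhantomSpec field overrides
    "noise": {"alpha": 1.0, "sigma": 2.5},
    "split": {"fractions": [0.8, 0.1, 0.1]},
    "network": {"n_levels": 2, "base_channels": 8},
    "train": {"epochs": 30, "lr_drop_epoch": 18},
    "evaluate": {"tune_baselines": True, "window": "gaussian"},
}

_KNOWN_KEYS = set(_DEFAULT_CONFIG)


def load_config(source: dict | str | os.PathLike) -> dict:
    """Parse and validate an experiment config (YAML path or dict)."""
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    config = json.loads(json.dumps(_DEFAULT_CONFIG))  # deep copy
    for key, value in raw.items():
        if isinstance(value, dict):
            config[key].update(value)
        else:
            config[key] = value
    if int(config["n_cubes"]) < 3:
        raise ConfigError("n_cubes must be >= 3 to allow a 3-way split")
    return config


def _phantom_spec(config: dict, seed: int) -> PhantomSpec:
    # desk-scale default geometry; a config's phantom section overrides it
    defaults = dict(height=32, width=32, n_bands=64, wn_start=500.0, wn_end=1800.0,
                    n_cells=2, cell_radius_range=(5.0, 9.0))
    defaults.update(config.get("phantom", {}))
    if "cell_radius_range" in defaults:
        defaults["cell_radius_range"] = tuple(defaults["cell_radius_range"])
    return PhantomSpec(seed=seed, **defaults)


def _git_describe() -> str:
    try:
        out = subprocess.run(
            ["git", "describe", "--always", "--dirty"],
            capture_output=True, text=True, timeout=10,
            cwd=os.path.dirname(os.path.abspath(__file__)),
        )
        if out.returncode == 0:
            return out.stdout.strip()
    except Exception:
        pass
    return "unknown"


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------


class ExperimentRunner:
    """Executes the six pipeline stages and maintains the run manifest."""

    def __init__(self, config: dict | str | os.PathLike, resume: bool = False):
        self.config = load_config(config)
        self.resume = resume
        self.out_dir = Path(self.config["out_dir"])
        self.cube_dir = self.out_dir / "cubes"
        self.report_dir = self.out_dir / "reports"
        self.manifest_path = self.out_dir / "manifest.json"
        self.checkpoint_path = self.out_dir / "checkpoint.npz"
        self.manifest: dict = {
            "config": self.config,
            "seed": self.config["seed"],
            "package_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "git_describe": _git_describe(),
            "stages": {},
            "artifacts": {},
        }
        if resume and self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                previous = json.load(fh)
            if previous.get("config") == self.config:
                self.manifest = previous

    # -- plumbing ---------------------------------------------------------
    def _save_manifest(self) -> None:
        self.out_dir.mkdir(parents=True, exist_ok=True)
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)

    def _stage_done(self, stage: str) -> bool:
        return self.resume and self.manifest["stages"].get(stage, {}).get("status") == "done"

    def _run_stage(self, stage: str, fn) -> None:
        if self._stage_done(stage):
            print(f"[{stage}] skipped (resume)", file=sys.stderr)
            return
        t0 = time.time()
        print(f"[{stage}] start", file=sys.stderr)
        try:
            fn()
        except Exception as exc:
            self.manifest["stages"][stage] = {"status": "failed", "error": repr(exc)}
            self._save_manifest()
            raise
        self.manifest["stages"][stage] = {
            "status": "done",
            "wall_time_s": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self._save_manifest()
        print(f"[{stage}] done in {time.time() - t0:.1f}s", file=sys.stderr)

    def _clean_path(self, i: int) -> Path:
        return self.cube_dir / f"cube_{i:03d}.clean.h5"

    def _noisy_path(self, i: int) -> Path:
        return self.cube_dir / f"cube_{i:03d}.noisy.h5"

    # -- stages -----------------------------------------------------------
    def stage_phantom(self) -> None:
        self.cube_dir.mkdir(parents=True, exist_ok=True)
        n = int(self.config["n_cubes"])
        base_seed = int(self.config["seed"])
        for i in range(n):
            spec = _phantom_spec(self.config, seed=base_seed + i)
            from raman3d.phantom import render_phantom

            cube, _maps = render_phantom(spec)
            write_cube(cube, self._clean_path(i), overwrite=True)
        self.manifest["artifacts"]["clean_cubes"] = [str(self._clean_path(i)) for i in range(n)]

    def stage_corrupt(self) -> None:
        n = int(self.config["n_cubes"])
        noise_cfg = self.config["noise"]
        base_seed = int(self.config["seed"]) + 10_000
        for i in range(n):
            clean = read_cube(self._clean_path(i))
            params = NoiseModelParams(
                alpha=float(noise_cfg["alpha"]), sigma=float(noise_cfg["sigma"]), seed=base_seed + i
            )
            write_cube(corrupt(clean, params), self._noisy_path(i), overwrite=True)
        self.manifest["artifacts"]["noisy_cubes"] = [str(self._noisy_path(i)) for i in range(n)]

    def stage_split(self) -> None:
        n = int(self.config["n_cubes"])
        fractions = tuple(self.config["split"]["fractions"])
        split = split_dataset(n, fractions, seed=int(self.config["seed"]))
        self.manifest["split"] = {
            "train": list(split.train_idx),
            "val": list(split.val_idx),
            "test": list(split.test_idx),
            "sizes": list(split.sizes),
        }

    def _normalized_pairs(self, indices) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for i in indices:
            noisy, _ = min_max_normalize(read_cube(self._noisy_path(i)))
            clean, _ = min_max_normalize(read_cube(self._clean_path(i)))
            pairs.append((noisy.data, clean.data))
        return pairs

    def stage_train(self) -> None:
        split = self.manifest["split"]
        train_pairs = self._normalized_pairs(split["train"])
        val_pairs = self._normalized_pairs(split["val"])
        net_cfg = dict(self.config["network"])
        spec = NetworkSpec(seed=int(self.config["seed"]), **net_cfg)
        model = build_network(spec)
        train_cfg_fields = dict(self.config["train"])
        augment = AugmentFlags(**train_cfg_fields.pop("augment", {}))
        if "patch" in train_cfg_fields:
            train_cfg_fields["patch"] = tuple(train_cfg_fields["patch"])
        config = TrainConfig(seed=int(self.config["seed"]), augment=augment, **train_cfg_fields)
        model, history = train(model, train_pairs, val_pairs, config)
        save_checkpoint(model, self.checkpoint_path, meta={"history_tail": history[-1]})
        history_df = pd.DataFrame(history)
        self.report_dir.mkdir(parents=True, exist_ok=True)
        history_df.to_csv(self.report_dir / "history.csv", index=False)
        self.manifest["artifacts"]["checkpoint"] = str(self.checkpoint_path)
        self.manifest["artifacts"]["history"] = str(self.report_dir / "history.csv")
        self.manifest["train"] = {
            "n_params": model.n_params,
            "final_train_loss": history[-1]["train_loss"],
            "final_val_loss": history[-1]["val_loss"],
        }

    def stage_denoise(self) -> None:
        split = self.manifest["split"]
        model, _ = load_checkpoint(self.checkpoint_path)
        eval_cfg = self.config["evaluate"]
        val_pairs = self._normalized_pairs(split["val"])
        if eval_cfg.get("tune_baselines", True):
            sg_window, sg_order = tune_sg(val_pairs)
            pca_k = tune_pca(val_pairs)
        else:
            sg_window, sg_order = int(eval_cfg.get("sg_window", 9)), int(eval_cfg.get("sg_polyorder", 3))
            pca_k = int(eval_cfg.get("pca_k", 4))
        self.manifest["baselines"] = {"sg_window": sg_window, "sg_polyorder": sg_order, "pca_k": pca_k}
        predictions: dict[str, list[np.ndarray]] = {"input": [], "sg": [], "pca": [], "network": []}
        references: list[np.ndarray] = []
        for noisy, clean in self._normalized_pairs(split["test"]):
            references.append(clean)
            predictions["input"].append(noisy)
            predictions["sg"].append(sg_denoise(noisy, sg_window, sg_order))
            predictions["pca"].append(pca_denoise(noisy, pca_k))
            predictions["network"].append(denoise_cube_array(model, noisy))
        self._predictions = predictions
        self._references = references

    def stage_evaluate(self) -> None:
        window = self.config["evaluate"].get("window", "gaussian")
        reports = {
            method: evaluate(preds, self._references, dynamic_range=1.0, window=window)
            for method, preds in self._predictions.items()
        }
        self.report_dir.mkdir(parents=True, exist_ok=True)
        report_payload = {method: report.to_dict() for method, report in reports.items()}
        with open(self.report_dir / "report.json", "w") as fh:
            json.dump(report_payload, fh, indent=2)
        table = pd.DataFrame(
            {
                method: {
                    "SSIM": report.mean_ssim,
                    "PSNR_dB": report.mean_psnr_db,
                    "MSE": report.mean_mse,
                    "SNR_dB": report.mean_snr_db,
                }
                for method, report in reports.items()
            }
        )
        table.to_csv(self.report_dir / "report.csv")
        self.manifest["artifacts"]["report_json"] = str(self.report_dir / "report.json")
        self.manifest["artifacts"]["report_csv"] = str(self.report_dir / "report.csv")
        self.manifest["metrics"] = report_payload

    def run(self) -> dict:
        # denoise/evaluate share in-memory predictions, so resuming past a
        # completed denoise stage must re-run it unless evaluate is also done
        if self._stage_done("denoise") and not self._stage_done("evaluate"):
            self.manifest["stages"].pop("denoise", None)
        stage_fns = {
            "phantom": self.stage_phantom,
            "corrupt": self.stage_corrupt,
            "split": self.stage_split,
            "train": self.stage_train,
            "denoise": self.stage_denoise,
            "evaluate": self.stage_evaluate,
        }
        for stage in STAGES:
            if stage in ("denoise", "evaluate") and self._stage_done("evaluate"):
                print(f"[{stage}] skipped (resume)", file=sys.stderr)
                continue
            self._run_stage(stage, stage_fns[stage])
        return self.manifest


def run_experiment(config: dict | str | os.PathLike, resume: bool = False) -> dict:
    """Run all six stages; returns the manifest (also written to out_dir)."""
    return ExperimentRunner(config, resume=resume).run()


def denoise_file(
    checkpoint_path: str | os.PathLike,
    noisy_path: str | os.PathLike,
    out_path: Optional[str | os.PathLike] = None,
) -> HyperspectralCube:
    """Denoise one cube file with a trained checkpoint.

    The cube is min-max normalized, passed through the network (with
    pad-and-crop for extents not divisible by the downsampling factor), and
    rescaled back to the input's intensity range.  Deterministic given the
    checkpoint.
    """
    model, _ = load_checkpoint(checkpoint_path)
    noisy = read_cube(noisy_path)
    normalized, record = min_max_normalize(noisy)
    denoised = denoise_cube_array(model, normalized.data)
    out_cube = min_max_denormalize(normalized.with_data(denoised), record)
    out_cube = replace(out_cube, provenance=f"{noisy.provenance}+denoised")
    if out_path is not None:
        write_cube(out_cube, out_path, overwrite=True)
    return out_cube
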