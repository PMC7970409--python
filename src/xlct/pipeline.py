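"""End-to-end experiment pipeline: dataset generation, training, validation.

All randomness derives from one root seed through numpy SeedSequence
spawning, so a re-run with the same config reproduces every phantom,
sinogram and training curve. Two built-in profiles: ``desk`` (100 phantoms
on a 64×64 slice grid, reduced epochs — fits a single-CPU desk budget) and
``paper`` (400 phantoms, 0.25 mm voxels, 200 epochs — the full protocol).
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .forward import BeamSpec, DetectorSet, NoiseModel, Sinogram, write_sinogram, read_sinogram
from .network import (NetConfig, TrainedModel, TrainingPair, load_model,
                      save_model, synthesize_full_view, train)
from .phantoms import (Phantom, PhantomConfig, random_phantom,
                       rasterize_concentration, save_phantom)
from .recon import build_weight_matrix, psnr, reconstruct_tv, ssim

__all__ = [
    "ExperimentConfig", "generate_dataset", "train_from_manifest",
    "validate", "validation_phantom", "load_config", "PROFILES",
    "run_headline_experiment", "simulate_pair",
]

log = logging.getLogger("xlct")

FEW_VIEWS = 15
FULL_VIEWS = 30


@dataclass(frozen=True)
class ExperimentConfig:
    """Root configuration of one experiment, seeded from a single integer."""

    seed: int = 0
    n_phantoms: int = 100
    n_validation: int = 5
    voxel_size: float = 25.0 / 64    # mm; 64×64 grid over the 25 mm diameter
    epochs: int = 12
    batch_size: int = 4
    learning_rate: float = 1e-3
    loss_alpha: float = 0.8
    noise_level: float = 0.01        # shot-noise level; 0 disables
    recon_max_iter: int = 300
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def __post_init__(self) -> None:
        object.__setattr__(self, "phantom",
                           PhantomConfig(**{**asdict(self.phantom),
                                            "voxel_size": self.voxel_size})
                           if not isinstance(self.phantom, PhantomConfig)
                           or self.phantom.voxel_size != self.voxel_size
                           else self.phantom)

    def beam(self, n_views: int = FEW_VIEWS) -> BeamSpec:
        return BeamSpec(n_views=n_views)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


PROFILES: dict[str, dict] = {
    "desk": {"n_phantoms": 100, "voxel_size": 25.0 / 64, "epochs": 12,
             "recon_max_iter": 300},
    "paper": {"n_phantoms": 400, "voxel_size": 0.25, "epochs": 200,
              "recon_max_iter": 500},
}


def load_config(path=None, profile: str = "desk", seed: int = 0,
                **overrides) -> ExperimentConfig:
    """Build a config from a profile, an optional YAML file and overrides."""
    base = dict(PROFILES[profile])
    if path is not None:
        with open(path) as fh:
            base.update(yaml.safe_load(fh) or {})
    base.update(overrides)
    base["seed"] = seed
    pc = base.pop("phantom", {})
    if isinstance(pc, dict):
        pc = PhantomConfig(**{**pc, "voxel_size": base.get("voxel_size",
                                                           25.0 / 64)})
    return ExperimentConfig(phantom=pc, **base)


def _child_seeds(root: int, n: int, tag: int) -> np.ndarray:
    """n reproducible sub-seeds < 2**31 derived from (root, tag)."""
    return np.random.SeedSequence([root, tag]).generate_state(n) % (2 ** 31)


def simulate_pair(phantom: Phantom, cfg: ExperimentConfig,
                  noise_seed: int | None = None
                  ) -> tuple[Sinogram, Sinogram]:
    """(few-view, full-view) sinograms of one phantom.

    Computed through the weight matrix (identical to the per-operation
    forward simulation; the two codings are pinned together by tests); the
    few-view sinogram is the even-view subset of the full-view scan.
    """
    beam_full = cfg.beam(FULL_VIEWS)
    detectors = DetectorSet()
    A = build_weight_matrix(phantom, beam_full, detectors)
    rho = rasterize_concentration(phantom)
    full_vals = A.project(rho.values)
    if cfg.noise_level > 0 and noise_seed is not None:
        noise = NoiseModel(level=cfg.noise_level, seed=int(noise_seed))
        full_vals = noise.apply(full_vals)
        meta = noise.metadata()
    else:
        meta = {}
    full = Sinogram(values=full_vals, angles=beam_full.angles,
                    offsets=beam_full.offsets,
                    detector_offsets=tuple(detectors.angular_offsets),
                    noise=meta)
    few = Sinogram(values=full_vals[0::2], angles=beam_full.angles[0::2],
                   offsets=beam_full.offsets,
                   detector_offsets=tuple(detectors.angular_offsets),
                   noise=meta)
    return few, full


def _phantom_checksum(phantom: Phantom) -> str:
    desc = {
        "radius": phantom.radius, "height": phantom.height,
        "voxel_size": phantom.voxel_size, "seed": phantom.seed,
        "mu_a": phantom.background.mu_a,
        "mu_s_prime": phantom.background.mu_s_prime,
        "targets": [[*t.center, t.radius, t.concentration]
                    for t in phantom.targets],
    }
    return hashlib.sha256(
        yaml.safe_dump(desc, sort_keys=True).encode()).hexdigest()


def generate_dataset(cfg: ExperimentConfig, outdir) -> Path:
    """Generate the training dataset: N phantoms with paired 15-/30-view
    sinograms, plus a manifest of artifacts, seeds and checksums.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(cfg.seed, cfg.n_phantoms, tag=1)
    noise_seeds = _child_seeds(cfg.seed, cfg.n_phantoms, tag=2)
    entries = []
    t0 = time.time()
    for i, s in enumerate(seeds):
        phantom = random_phantom(int(s), cfg.phantom)
        few, full = simulate_pair(phantom, cfg, noise_seeds[i])
        stem = f"phantom_{i:04d}"
        save_phantom(phantom, outdir / f"{stem}.h5")
        write_sinogram(few, outdir / f"{stem}_few.h5")
        write_sinogram(full, outdir / f"{stem}_full.h5")
        entries.append({
            "index": i, "seed": int(s),
            "phantom": f"{stem}.h5", "few": f"{stem}_few.h5",
            "full": f"{stem}_full.h5",
            "checksum": _phantom_checksum(phantom),
        })
        if (i + 1) % 25 == 0:
            log.info("generated %d/%d phantoms (%.1f s)", i + 1,
                     cfg.n_phantoms, time.time() - t0)
    manifest = {
        "format": "xlct-dataset-v1",
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "few_angles_deg": [float(a) for a in cfg.beam(FEW_VIEWS).angles],
        "full_angles_deg": [float(a) for a in cfg.beam(FULL_VIEWS).angles],
        "entries": entries,
    }
    path = outdir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    log.info("dataset of %d pairs written to %s", cfg.n_phantoms, outdir)
    return path


def _load_pairs(manifest_path) -> tuple[list[TrainingPair], dict]:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"dataset manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("format") != "xlct-dataset-v1":
        raise ValueError(f"{manifest_path}: not an xlct dataset manifest")
    root = manifest_path.parent
    pairs = [TrainingPair(few=read_sinogram(root / e["few"]),
                          full=read_sinogram(root / e["full"]))
             for e in manifest["entries"]]
    return pairs, manifest


def train_from_manifest(cfg: ExperimentConfig, manifest_path,
                        checkpoint_path, verbose: bool = False) -> TrainedModel:
    """Train the view-synthesis network on a generated dataset and write a
    checkpoint plus a per-epoch loss table."""
    pairs, _ = _load_pairs(manifest_path)
    model = train(pairs, NetConfig(loss_alpha=cfg.loss_alpha, seed=cfg.seed),
                  epochs=cfg.epochs, lr=cfg.learning_rate,
                  batch_size=cfg.batch_size, seed=cfg.seed, verbose=verbose)
    checkpoint_path = Path(checkpoint_path)
    checkpoint_path.parent.mkdir(parents=True, exist_ok=True)
    save_model(model, checkpoint_path)
    with open(checkpoint_path.with_suffix(".history.csv"), "w") as fh:
        fh.write("epoch,train_loss,val_loss\n")
        for e, tl in enumerate(model.history["train"]):
            vl = model.history["val"][e] if e < len(model.history["val"]) else ""
            fh.write(f"{e},{tl},{vl}\n")
    return model


def validation_phantom(seed: int, cfg: ExperimentConfig) -> Phantom:
    """Four-target validation phantom at the nominal optical parameters
    (μa = 0.5, μs′ = 15 cm⁻¹, no perturbation), targets on the scan plane."""
    pc = cfg.phantom
    vc = PhantomConfig(radius=pc.radius, height=pc.height,
                       voxel_size=pc.voxel_size, n_targets=(4, 4),
                       target_radius=pc.target_radius,
                       concentration=pc.concentration,
                       optical_perturbation=0.0, in_plane=True)
    return random_phantom(seed, vc)


def _evaluate_phantom(phantom: Phantom, model: TrainedModel,
                      cfg: ExperimentConfig, noise_seed: int | None = None
                      ) -> dict:
    """Reconstruct one phantom from (a) few-view, (b) synthesized, and
    (c) true full-view sinograms; score each against the ground truth."""
    few, full = simulate_pair(phantom, cfg, noise_seed)
    synth = synthesize_full_view(model, few)
    truth = rasterize_concentration(phantom).values
    detectors = DetectorSet()
    A_few = build_weight_matrix(phantom, cfg.beam(FEW_VIEWS), detectors)
    A_full = build_weight_matrix(phantom, cfg.beam(FULL_VIEWS), detectors)
    out: dict = {}
    for name, sino, A in (("few", few, A_few), ("synth", synth, A_full),
                          ("full", full, A_full)):
        res = reconstruct_tv(sino, A, max_iter=cfg.recon_max_iter)
        rec = res.map.values
        out[name] = {
            "psnr": psnr(truth, rec, data_range=float(truth.max())),
            "ssim": ssim(truth, rec, data_range=float(truth.max())),
            "iterations": res.iterations_run,
        }
        out[f"_recon_{name}"] = rec
        out[f"_result_{name}"] = res
    out["_truth"] = truth
    return out


def validate(cfg: ExperimentConfig, checkpoint_path, outdir,
             save_images: bool = True) -> dict:
    """Reproduce the validation experiment on held-out phantoms.

    Evaluates ``cfg.n_validation`` seeded four-target phantoms under the
    three conditions (few-view / synthesized / true full-view) and writes a
    machine-readable report plus a delimited metric table. Returns the
    report dict.
    """
    model = load_model(checkpoint_path) if not isinstance(
        checkpoint_path, TrainedModel) else checkpoint_path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(cfg.seed, cfg.n_validation, tag=3)
    noise_seeds = _child_seeds(cfg.seed, cfg.n_validation, tag=4)
    per_phantom = []
    for i, s in enumerate(seeds):
        phantom = validation_phantom(int(s), cfg)
        r = _evaluate_phantom(phantom, model, cfg, noise_seeds[i])
        if save_images and i == 0:
            _save_slice_images(r, outdir)
        per_phantom.append({
            "seed": int(s),
            **{cond: {k: float(v) for k, v in r[cond].items()}
               for cond in ("few", "synth", "full")},
        })
        log.info("validation phantom %d/%d: few %.2f dB, synth %.2f dB, "
                 "full %.2f dB", i + 1, len(seeds), r["few"]["psnr"],
                 r["synth"]["psnr"], r["full"]["psnr"])
    report = {
        "format": "xlct-report-v1",
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "per_phantom": per_phantom,
        "mean": {cond: {m: float(np.mean([p[cond][m] for p in per_phantom]))
                        for m in ("psnr", "ssim")}
                 for cond in ("few", "synth", "full")},
    }
    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    with open(outdir / "report.csv", "w") as fh:
        fh.write("phantom_seed,condition,psnr_db,ssim\n")
        for p in per_phantom:
            for cond in ("few", "synth", "full"):
                fh.write(f"{p['seed']},{cond},{p[cond]['psnr']},"
                         f"{p[cond]['ssim']}\n")
    return report


def run_headline_experiment(seed: int, profile: str = "desk",
                            verbose: bool = False) -> dict:
    """Full in-memory reproduction of the validation experiment.

    Generates the training set, trains the view-synthesis network, and
    scores TV reconstructions of held-out four-target phantoms from
    (a) raw 15-view, (b) network-synthesized 30-view and (c) true 30-view
    sinograms. Returns per-phantom and mean PSNR/SSIM plus the metrics of
    the first held-out phantom under ``"first"``.
    """
    cfg = load_config(profile=profile, seed=seed)
    t0 = time.time()
    seeds = _child_seeds(cfg.seed, cfg.n_phantoms, tag=1)
    noise_seeds = _child_seeds(cfg.seed, cfg.n_phantoms, tag=2)
    pairs = [TrainingPair(*simulate_pair(random_phantom(int(s), cfg.phantom),
                                         cfg, int(ns)))
             for s, ns in zip(seeds, noise_seeds)]
    log.info("simulated %d training pairs (%.0f s)", len(pairs),
             time.time() - t0)
    model = train(pairs, NetConfig(loss_alpha=cfg.loss_alpha, seed=cfg.seed),
                  epochs=cfg.epochs, lr=cfg.learning_rate,
                  batch_size=cfg.batch_size, seed=cfg.seed, verbose=verbose)
    log.info("trained %d epochs (%.0f s total)", cfg.epochs, time.time() - t0)
    vseeds = _child_seeds(cfg.seed, cfg.n_validation, tag=3)
    vnoise = _child_seeds(cfg.seed, cfg.n_validation, tag=4)
    per_phantom = []
    for i, s in enumerate(vseeds):
        phantom = validation_phantom(int(s), cfg)
        r = _evaluate_phantom(phantom, model, cfg, int(vnoise[i]))
        per_phantom.append({cond: {k: float(v) for k, v in r[cond].items()}
                            for cond in ("few", "synth", "full")})
        log.info("held-out phantom %d/%d: few %.2f dB / synth %.2f dB / "
                 "full %.2f dB", i + 1, len(vseeds), r["few"]["psnr"],
                 r["synth"]["psnr"], r["full"]["psnr"])
    mean = {cond: {m: float(np.mean([p[cond][m] for p in per_phantom]))
                   for m in ("psnr", "ssim")}
            for cond in ("few", "synth", "full")}
    return {"per_phantom": per_phantom, "mean": mean,
            "first": per_phantom[0],
            "final_train_loss": model.history["train"][-1],
            "runtime_s": time.time() - t0}


def _save_slice_images(result: dict, outdir: Path) -> None:
    import imageio.v3 as iio

    from .recon import export_diagnostics_csv
    for name in ("truth", "recon_few", "recon_synth", "recon_full"):
        img = result["_truth"] if name == "truth" else result[f"_{name}"]
        peak = img.max()
        u8 = np.zeros_like(img, dtype=np.uint8) if peak <= 0 else \
            np.clip(img / peak * 255, 0, 255).astype(np.uint8)
        iio.imwrite(outdir / f"{name}.png", u8.T[::-1])
        np.savetxt(outdir / f"{name}.csv", img, delimiter=",")
    for cond in ("few", "synth", "full"):
        export_diagnostics_csv(result[f"_result_{cond}"],
                               outdir / f"diagnostics_{cond}.csv")
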