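"""Configuration-driven runs, artifact writers, and run summaries.

A run is described by one TOML file with ``[instrument]``, ``[spectrum]``,
``[scene]``, ``[solver]``, ``[scan]`` and ``[output]`` tables (all units SI).
``run_from_config`` resolves and validates the config, executes the B-scan,
and writes into the output directory:

* ``tomogram.npy`` (float image, depth x lateral) + ``tomogram.json`` axes,
* ``tomogram.csv`` (depth, y, value) and optional PNG/TIFF renderings,
* ``interferograms.csv`` per scan position (omega, Re/Im alpha_sca/ref),
* ``scene.json``, ``resolved_config.json`` and ``run.log``.

Identical config + seed produce bit-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np

from .optics import FiberMode, OpticalSystem, Polarisation
from .scenes import (
    PhantomSpec,
    Scene,
    make_cylinder_cluster,
    make_dentin_slab,
    make_single_cylinder,
    make_ziggurat,
)
from .spectral import (
    SolverConfig,
    SourceSpectrum,
    Tomogram,
    build_spectrum,
    max_visible_depth,
    run_bscan,
)

__all__ = ["RunConfig", "load_config", "run_from_config", "summarize",
           "write_tomogram", "read_tomogram"]


class ConfigError(ValueError):
    """Schema violation in a run configuration, with the offending field path."""


_DEFAULTS = {
    "instrument": {"f1": 25e-3, "f2": 36e-3, "h": 3.5e-3, "w0": 4.6e-6,
                   "E0": 1.0, "n_med": 1.35, "n_debye": 1.0, "mirror_r": 1.0},
    "spectrum": {"lambda0": 1.3e-6, "delta_lambda": 170e-9,
                 "epsilon": 1e-3, "N": 160},
    "solver": {"type": "analytic", "scheme": "convergent_born",
               "tolerance": 1e-6, "max_iterations": 10000,
               "dx_over_lambda0": 1 / 24, "subsampling": 10,
               "boundary_width": 10e-6, "n_nodes": 201},
    "scan": {"polarisation": "perpendicular", "y_min": 0.0, "y_max": 0.0,
             "n_positions": 1, "weighting": "power"},
    "output": {"scale": "log", "formats": ["npy", "csv"]},
}


class RunConfig:
    """Resolved, validated run configuration."""

    def __init__(self, raw: dict, source_path: str | None = None):
        self.raw = raw
        self.source_path = source_path
        merged = {}
        for section, defaults in _DEFAULTS.items():
            merged[section] = dict(defaults)
            user = raw.get(section, {})
            if not isinstance(user, dict):
                raise ConfigError(f"{section}: must be a table")
            unknown = (set(user) - set(defaults)) if section != "scene" else set()
            if unknown:
                raise ConfigError(f"{section}.{sorted(unknown)[0]}: unknown key")
            merged[section].update(user)
        if "scene" not in raw:
            raise ConfigError("scene: section is required")
        merged["scene"] = raw["scene"]
        self.data = merged
        self._validate()

    def _validate(self) -> None:
        sp = self.data["spectrum"]
        if sp["N"] < 4 or sp["N"] % 2:
            raise ConfigError(
                "spectrum.N: must be even (the reconstruction uses the "
                "-N/2..N/2-1 DFT index convention) and at least 4")
        if not (0 < sp["epsilon"] < 1):
            raise ConfigError("spectrum.epsilon: must lie in (0, 1)")
        inst = self.data["instrument"]
        for key in ("f1", "f2", "h", "w0"):
            if inst[key] <= 0:
                raise ConfigError(f"instrument.{key}: must be positive")
        sc = self.data["scan"]
        if sc["polarisation"] not in ("perpendicular", "parallel"):
            raise ConfigError("scan.polarisation: must be "
                              "'perpendicular' or 'parallel'")
        if sc["n_positions"] < 1:
            raise ConfigError("scan.n_positions: must be >= 1")
        if self.data["solver"]["type"] not in ("analytic", "grid"):
            raise ConfigError("solver.type: must be 'analytic' or 'grid'")
        if "type" not in self.data["scene"]:
            raise ConfigError("scene.type: is required")

    # ---- constructed objects -------------------------------------------
    def optical_system(self) -> OpticalSystem:
        i = self.data["instrument"]
        return OpticalSystem(i["f1"], i["f2"], i["h"], i["n_med"], i["n_debye"])

    def fiber_mode(self) -> FiberMode:
        i = self.data["instrument"]
        return FiberMode(i["w0"], i["E0"])

    def spectrum(self) -> SourceSpectrum:
        s = self.data["spectrum"]
        return build_spectrum(s["lambda0"], s["delta_lambda"], s["epsilon"],
                              int(s["N"]))

    def scene(self) -> Scene:
        sc = dict(self.data["scene"])
        kind = sc.pop("type")
        seed = int(sc.pop("seed", 0))
        if kind == "single_cylinder":
            return make_single_cylinder(sc["radius"], sc["n_cyl"],
                                        self.data["instrument"]["n_med"],
                                        tuple(sc.get("center", (0.0, 0.0))))
        if kind == "cluster":
            spec = PhantomSpec(
                int(sc["count"]), tuple(sc["region"]), sc["radius"],
                sc["index"], seed, bool(sc.get("allow_overlap", True)),
                tuple(sc["jitter"]) if "jitter" in sc else None,
                sc.get("arrangement", "lattice"))
            scene = make_cylinder_cluster(spec)
            scene.n_med = self.data["instrument"]["n_med"]
            return scene
        if kind == "ziggurat":
            return make_ziggurat(sc["plateau_widths"], sc["step_height"],
                                 sc["index"], self.data["instrument"]["n_med"],
                                 sc.get("x_top", 0.0))
        if kind == "dentin_slab":
            spec = PhantomSpec(int(sc["count"]), tuple(sc["region"]),
                               sc.get("radius", 1e-6), sc.get("n_tubule", 1.33),
                               seed, bool(sc.get("allow_overlap", True)))
            return make_dentin_slab(spec, sc.get("n_dentin", 1.52),
                                    sc.get("n_tubule", 1.33))
        if kind == "empty":
            half = sc.get("half_extent", 20e-6)
            return Scene([], self.data["instrument"]["n_med"],
                         ((-half, half), (-half, half)))
        raise ConfigError(f"scene.type: unknown scene type '{kind}'")

    def solver_config(self) -> SolverConfig:
        s = self.data["solver"]
        return SolverConfig(s["tolerance"], int(s["max_iterations"]), s["scheme"])

    def y_positions(self) -> np.ndarray:
        s = self.data["scan"]
        return np.linspace(s["y_min"], s["y_max"], int(s["n_positions"]))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return RunConfig(raw, str(path))


def write_tomogram(tomo: Tomogram, outdir: Path, scale: str = "log",
                   formats=("npy", "csv")) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img = tomo.image
    np.save(outdir / "tomogram.npy", img)
    meta = {
        "depth_m": [float(v) for v in tomo.depth],
        "y_positions_m": [float(v) for v in tomo.y_positions],
        "normalization": tomo.normalization,
        "scale": scale,
    }
    (outdir / "tomogram.json").write_text(json.dumps(meta, indent=1))
    if "csv" in formats:
        with open(outdir / "tomogram.csv", "w") as fh:
            fh.write("depth_m,y_m,value\n")
            for i, d in enumerate(tomo.depth):
                for j, y in enumerate(tomo.y_positions):
                    fh.write(f"{d!r},{y!r},{img[i, j]!r}\n")
    if "png" in formats:
        import imageio.v3 as iio

        disp = np.log10(np.maximum(img, 1e-12)) if scale == "log" else img
        lo, hi = disp.min(), disp.max()
        u16 = np.zeros_like(disp) if hi == lo else (disp - lo) / (hi - lo)
        iio.imwrite(outdir / "tomogram.png",
                    (u16 * 65535).astype(np.uint16))
    if "tiff" in formats:
        import tifffile

        tifffile.imwrite(outdir / "tomogram.tiff", img.astype(np.float32))


def read_tomogram(outdir: Path) -> tuple[np.ndarray, dict]:
    outdir = Path(outdir)
    img = np.load(outdir / "tomogram.npy")
    meta = json.loads((outdir / "tomogram.json").read_text())
    return img, meta


def run_from_config(path: str, outdir: str | Path | None = None) -> Path:
    """Execute a configured run and write all artifacts; returns the out dir."""
    cfg = load_config(path)
    outdir = Path(outdir) if outdir is not None else Path(path).with_suffix(".out")
    outdir.mkdir(parents=True, exist_ok=True)
    sysm = cfg.optical_system()
    mode = cfg.fiber_mode()
    spectrum = cfg.spectrum()
    scene = cfg.scene()
    sol = cfg.data["solver"]
    log_lines = [f"config digest {cfg.digest()}",
                 f"seed {cfg.data['scene'].get('seed', 0)}"]
    import numpy as _np
    import scipy as _scipy
    log_lines.append(f"numpy {_np.__version__} scipy {_scipy.__version__}")
    tomo = run_bscan(
        scene, sysm, mode, spectrum,
        Polarisation(cfg.data["scan"]["polarisation"]),
        cfg.y_positions(), sol["type"], cfg.solver_config(),
        cfg.data["instrument"]["mirror_r"], cfg.data["scan"]["weighting"],
        int(sol["n_nodes"]),
        sol["dx_over_lambda0"] * cfg.data["spectrum"]["lambda0"],
        int(sol["subsampling"]), sol["boundary_width"],
        progress=lambda j, n: log_lines.append(f"wavenumber {j + 1}/{n} done"),
    )
    write_tomogram(tomo, outdir, cfg.data["output"]["scale"],
                   cfg.data["output"]["formats"])
    if tomo.couplings:
        (outdir / "interferograms.csv").write_text(tomo.couplings[0].to_csv())
    (outdir / "scene.json").write_text(scene.to_json())
    (outdir / "resolved_config.json").write_text(
        json.dumps(cfg.data, indent=1, sort_keys=True, default=str))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


def summarize(outdir: str | Path, threshold: float = 1e-6) -> dict:
    """Peak report for a written tomogram artifact.

    Reports, per A-scan, the depth of every local intensity maximum above
    ``threshold`` (relative to the global maximum), plus the global maximum,
    the stored normalization and the aliasing-free depth for the run's
    spectral parameters.
    """
    img, meta = read_tomogram(outdir)
    resolved = json.loads((Path(outdir) / "resolved_config.json").read_text())
    depth = np.array(meta["depth_m"])
    peaks = []
    gmax = float(img.max())
    for j, y in enumerate(meta["y_positions_m"]):
        col = img[:, j]
        loc = [i for i in range(1, len(col) - 1)
               if col[i] >= col[i - 1] and col[i] >= col[i + 1]
               and col[i] > threshold * gmax]
        peaks.append({"y_m": y,
                      "peak_depths_m": [float(depth[i]) for i in loc],
                      "peak_values": [float(col[i]) for i in loc]})
    sp = resolved["spectrum"]
    from .spectral import build_spectrum as _bs

    spec = _bs(sp["lambda0"], sp["delta_lambda"], sp["epsilon"], int(sp["N"]))
    return {
        "global_max": gmax,
        "normalization": meta["normalization"],
        "max_visible_depth_m": max_visible_depth(
            int(sp["N"]), spec.b, sp["epsilon"],
            resolved["instrument"]["n_med"]),
        "ascans": peaks,
    }
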