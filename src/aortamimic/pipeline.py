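"""End-to-end pipeline: synthesise -> analyse -> compare -> report.

A single config object (loadable from YAML) drives the whole run; all
randomness flows from its seed, so repeated runs produce identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import compare as cmp
from . import lattice as lat
from . import synth
from .tensile import WINDOW, analyze_batch

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("aortamimic")


@dataclass
class PipelineConfig:
    """Configuration for one full run; defaults mirror the study conditions."""

    seed: int = 0
    # synthetic batches: name -> material model key in synth.DEFAULT_MODELS
    models: dict = field(
        default_factory=lambda: {
            "Synth_Polymer": "polymer",
            "Synth_Tissue": "tissue",
            "Synth_Composite": "composite",
        }
    )
    n_samples: int = 6
    inter_sample_cov: float = 0.05
    load_noise_sd_n: float = 0.005
    window: tuple = WINDOW
    assumed_n: int = cmp.DEFAULT_ASSUMED_N
    build_lattices: bool = False  # STL builds are the slow stage; opt in
    lattice_kinds: tuple = tuple(lat.PUBLISHED_DESIGNS)
    make_figure: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.window = tuple(cfg.window)
        return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the configured stages and write artifacts into ``outdir``.

    Returns a manifest with per-stage timings and artifact paths; the same
    config and seed always produce identical summary output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "artifacts": {}}
    if not config.models and not config.build_lattices:
        log.warning("pipeline config enables no stages; nothing to do")
        return manifest

    noise = synth.NoiseModel(
        load_noise_sd_n=config.load_noise_sd_n,
        inter_sample_cov=config.inter_sample_cov,
    )

    summaries, curves = [], {}
    if config.models:
        t0 = time.perf_counter()
        for i, (name, key) in enumerate(sorted(config.models.items())):
            model = synth.DEFAULT_MODELS[key]
            records = synth.generate_batch(
                model,
                n=config.n_samples,
                noise=noise,
                seed=config.seed + i,
                model_id=name,
            )
            summary, avg, einc = analyze_batch(records, name, window=config.window)
            summaries.append(summary)
            curves[name] = (avg, einc)
        manifest["stages"]["synth+analyze"] = time.perf_counter() - t0
        log.info("analysed %d synthetic models", len(summaries))

        t0 = time.perf_counter()
        comparisons = cmp.compare_all(summaries, assumed_n=config.assumed_n)
        manifest["stages"]["compare"] = time.perf_counter() - t0

    vfs = {}
    if config.build_lattices:
        t0 = time.perf_counter()
        slab = lat.MatrixSlab()
        for kind in config.lattice_kinds:
            lattice = lat.build_design(kind, slab)
            vfs[kind] = 100.0 * lat.volume_fraction(lattice, slab)
            stl = outdir / f"{kind}.stl"
            lat.export_stl(lattice.mesh, stl)
            manifest["artifacts"][f"stl_{kind}"] = str(stl)
        manifest["stages"]["lattice"] = time.perf_counter() - t0

    if config.models:
        t0 = time.perf_counter()
        paths = cmp.render_report(
            summaries,
            comparisons,
            volume_fractions=vfs,
            outdir=outdir,
            make_figure=config.make_figure,
        )
        manifest["artifacts"].update({k: str(p) for k, p in paths.items()})
        for name, (avg, einc) in curves.items():
            cpath = outdir / f"curve_{name}.csv"
            import pandas as pd

            pd.DataFrame(
                {"strain": avg.strain, "stress_mpa": avg.stress}
            ).to_csv(cpath, index=False)
            epath = outdir / f"einc_{name}.csv"
            pd.DataFrame(
                {"strain": einc.strain, "einc_mpa": einc.modulus}
            ).to_csv(epath, index=False)
            manifest["artifacts"][f"curve_{name}"] = str(cpath)
            manifest["artifacts"][f"einc_{name}"] = str(epath)
        manifest["stages"]["report"] = time.perf_counter() - t0

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    for stage, dt in manifest["stages"].items():
        log.info("stage %-14s %.2f s", stage, dt)
    return manifest
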