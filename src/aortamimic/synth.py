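"""Synthetic uniaxial tensile records with tissue/polymer/composite mechanics.

The experimental raw data behind the printed-sample characterisation is
available only on request, so this generator emulates the test conditions --
10 mm/min constant-rate stretch to rupture, 100 Hz sampling, 0.02 MPa
preload and three 0-1 N conditioning cycles -- for three material classes:

* ``polymer_softening``:  sigma = a*eps / (1 + b*eps), a creep-like response
  whose incremental modulus a/(1+b*eps)^2 decreases monotonically, like the
  printed photopolymer controls;
* ``tissue_stiffening``:  sigma = A*(exp(B*eps) - 1), a one-dimensional proxy
  for the exponential strain-stiffening of the collagenous aortic wall
  (the Holzapfel-Gasser-Ogden response reduces to this shape uniaxially);
* ``composite_rupture``:  a rule-of-mixtures blend of a matrix and a lattice
  model whose matrix ruptures first, dropping the stress over a strain band
  before the lattice finally fails -- the behaviour seen when a rigid chain
  reinforcement outlives its soft matrix.

Noise is additive Gaussian on the load channel, and batches jitter the
stress-scale parameters multiplicatively to emulate inter-sample spread.
All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .tensile import (
    SpecimenGeometry,
    TensileRecord,
    TestProtocol,
    write_tensile_csv,
)

__all__ = [
    "MaterialModel",
    "polymer_model",
    "tissue_model",
    "composite_model",
    "NoiseModel",
    "stress_at",
    "incremental_modulus_true",
    "generate_record",
    "generate_batch",
    "write_batch",
    "DEFAULT_GEOMETRY",
    "DEFAULT_MODELS",
]

MATERIAL_KINDS = ("polymer_softening", "tissue_stiffening", "composite_rupture")

#: Specimen geometry template matching the printed slab samples
#: (width x thickness from the matrix slab; ASTM D638-V scale gauge).
DEFAULT_GEOMETRY = SpecimenGeometry(
    width=10.13,
    thickness_measurements=(2.60,) * 5,
    gauge_length=10.0,
)


@dataclass(frozen=True)
class MaterialModel:
    """Closed-form engineering stress-strain law sigma(eps) in MPa."""

    kind: str
    a: float = 1.0  # polymer scale (MPa)
    b: float = 1.0  # polymer softening rate
    A: float = 0.05  # tissue scale (MPa)
    B: float = 3.0  # tissue exponential rate
    rupture_strain: float = 1.0
    # composite fields
    matrix: "MaterialModel | None" = None
    lattice: "MaterialModel | None" = None
    lattice_fraction: float = 0.15
    matrix_rupture_strain: float = 0.70
    post_rupture_drop: float = 0.4
    drop_band: float = 0.10  # strain width over which the drop develops

    def __post_init__(self):
        if self.kind not in MATERIAL_KINDS:
            raise ValueError(f"unknown material kind {self.kind!r}")
        if self.a <= 0 or self.A <= 0 or self.B <= 0 or self.b < 0:
            raise ValueError("material scales must be positive (b >= 0)")
        if self.rupture_strain <= 0:
            raise ValueError("rupture strain must be positive")
        if self.kind == "composite_rupture":
            if self.matrix is None or self.lattice is None:
                raise ValueError("composite model needs matrix and lattice models")
            if not 0.0 <= self.lattice_fraction <= 1.0:
                raise ValueError("lattice fraction must lie in [0, 1]")
            if not self.matrix_rupture_strain < self.rupture_strain:
                raise ValueError("matrix must rupture before the final rupture")
            if not 0.0 <= self.post_rupture_drop < 1.0:
                raise ValueError("post_rupture_drop must lie in [0, 1)")


def polymer_model(a: float = 1.2, b: float = 1.5, rupture_strain: float = 1.4) -> MaterialModel:
    return MaterialModel(kind="polymer_softening", a=a, b=b, rupture_strain=rupture_strain)


def tissue_model(A: float = 0.05, B: float = 3.0, rupture_strain: float = 1.0) -> MaterialModel:
    return MaterialModel(kind="tissue_stiffening", A=A, B=B, rupture_strain=rupture_strain)


def composite_model(
    matrix: MaterialModel | None = None,
    lattice: MaterialModel | None = None,
    lattice_fraction: float = 0.15,
    matrix_rupture_strain: float = 0.70,
    post_rupture_drop: float = 0.4,
    drop_band: float = 0.10,
    rupture_strain: float = 1.05,
) -> MaterialModel:
    """Composite emulating a rigid chain lattice in a soft matrix.

    Defaults approximate the published chain-in-soft-matrix sample whose
    stress peaks near 0.9 MPa around 70% strain, drops until 80% strain as
    the matrix ruptures, and finally fails above 100% strain.
    """
    matrix = matrix or polymer_model(a=2.8, b=1.5, rupture_strain=rupture_strain)
    lattice = lattice or polymer_model(a=1.0, b=0.0, rupture_strain=rupture_strain)
    return MaterialModel(
        kind="composite_rupture",
        matrix=matrix,
        lattice=lattice,
        lattice_fraction=lattice_fraction,
        matrix_rupture_strain=matrix_rupture_strain,
        post_rupture_drop=post_rupture_drop,
        drop_band=drop_band,
        rupture_strain=rupture_strain,
    )


#: Named default material models used by the end-to-end pipeline.
DEFAULT_MODELS = {
    "polymer": polymer_model(),
    "tissue": tissue_model(),
    "composite": composite_model(),
}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement and inter-sample variability."""

    load_noise_sd_n: float = 0.005
    inter_sample_cov: float = 0.05

    def __post_init__(self):
        if self.load_noise_sd_n < 0 or self.inter_sample_cov < 0:
            raise ValueError("noise levels must be non-negative")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def stress_at(model: MaterialModel, strain) -> np.ndarray | float:
    """Closed-form engineering stress sigma(eps) in MPa (eps >= 0)."""
    eps = np.asarray(strain, dtype=float)
    if np.any(eps < 0):
        raise ValueError("strain must be non-negative")
    if model.kind == "polymer_softening":
        sig = model.a * eps / (1.0 + model.b * eps)
    elif model.kind == "tissue_stiffening":
        sig = model.A * np.expm1(model.B * eps)
    else:
        f = model.lattice_fraction
        sig = (1.0 - f) * stress_at(model.matrix, eps) + f * stress_at(
            model.lattice, eps
        )
        # Matrix rupture: the stress falls by post_rupture_drop over the
        # drop band, then the (mostly lattice-borne) load continues.
        ramp = _smoothstep((eps - model.matrix_rupture_strain) / model.drop_band)
        sig = sig * (1.0 - model.post_rupture_drop * ramp)
    sig = np.where(eps > model.rupture_strain, np.nan, sig)
    return float(sig) if np.isscalar(strain) else sig


def incremental_modulus_true(model: MaterialModel, strain) -> np.ndarray | float:
    """Analytic d sigma / d eps for the smooth (non-composite) models."""
    eps = np.asarray(strain, dtype=float)
    if model.kind == "polymer_softening":
        out = model.a / (1.0 + model.b * eps) ** 2
    elif model.kind == "tissue_stiffening":
        out = model.A * model.B * np.exp(model.B * eps)
    else:
        raise ValueError("composite model has no closed-form modulus")
    return float(out) if np.isscalar(strain) else out


def _displacement_at_load(
    model: MaterialModel, area: float, gauge: float, target_n: float
) -> float:
    """Clamp displacement at which the load reaches ``target_n``."""

    def f(eps):
        return stress_at(model, eps) * area - target_n

    hi = model.rupture_strain
    if f(hi) < 0:  # sample never reaches the conditioning load; use 30% of range
        return 0.3 * hi * gauge
    eps = brentq(f, 0.0, hi)
    return eps * gauge


def generate_record(
    model: MaterialModel,
    protocol: TestProtocol | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    geometry: SpecimenGeometry = DEFAULT_GEOMETRY,
    model_id: str = "synthetic",
    conditioning: bool = True,
) -> TensileRecord:
    """One synthetic tensile record: conditioning cycles then ramp to rupture."""
    protocol = protocol or TestProtocol()
    noise = noise or NoiseModel()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    fs = protocol.sampling_hz
    rate = protocol.strain_rate_mm_per_min / 60.0  # mm/s
    gauge = geometry.gauge_length
    duration = model.rupture_strain * gauge / rate
    n = int(np.floor(duration * fs))
    t_ramp = np.arange(n) / fs
    disp_ramp = rate * t_ramp
    segments = []
    if conditioning and protocol.conditioning_cycles > 0:
        d1 = _displacement_at_load(
            model, geometry.area, gauge, protocol.cycle_load_max_n
        )
        n_half = max(2, int(round(d1 / rate * fs)))
        up = np.linspace(0.0, d1, n_half, endpoint=False)
        down = np.linspace(d1, 0.0, n_half, endpoint=False)
        for _ in range(protocol.conditioning_cycles):
            segments.extend([up, down])
    segments.append(disp_ramp)
    disp = np.concatenate(segments)
    time = np.arange(len(disp)) / fs
    strain = np.clip(disp / gauge, 0.0, model.rupture_strain)
    load = stress_at(model, strain) * geometry.area
    if noise.load_noise_sd_n > 0:
        load = load + rng.normal(0.0, noise.load_noise_sd_n, size=load.shape)
    return TensileRecord(
        time=time,
        load=load,
        displacement=disp,
        geometry=geometry,
        model_id=model_id,
        protocol=protocol,
    )


def _jitter(model: MaterialModel, factor: float) -> MaterialModel:
    """Scale the stress magnitude of a model multiplicatively."""
    if model.kind == "composite_rupture":
        return replace(
            model,
            matrix=_jitter(model.matrix, factor),
            lattice=_jitter(model.lattice, factor),
        )
    return replace(model, a=model.a * factor, A=model.A * factor)


def generate_batch(
    model: MaterialModel,
    n: int = 6,
    protocol: TestProtocol | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    geometry: SpecimenGeometry = DEFAULT_GEOMETRY,
    model_id: str = "synthetic",
    conditioning: bool = True,
) -> list[TensileRecord]:
    """A printed-model batch: ``n`` samples with jittered stress scales.

    Each sample draws a multiplicative factor ~ Normal(1, inter_sample_cov)
    applied to the model's stress scale, then its own measurement noise, all
    from per-sample sub-seeds spawned from ``seed``.
    """
    if n < 1:
        raise ValueError("batch size must be >= 1")
    noise = noise or NoiseModel()
    root = np.random.SeedSequence(seed)
    subs = root.spawn(n)
    records = []
    for i, ss in enumerate(subs):
        rng = np.random.default_rng(ss)
        factor = 1.0
        if noise.inter_sample_cov > 0:
            factor = max(0.1, rng.normal(1.0, noise.inter_sample_cov))
        rec = generate_record(
            _jitter(model, factor),
            protocol=protocol,
            noise=noise,
            seed=ss.spawn(1)[0],
            geometry=geometry,
            model_id=f"{model_id}",
            conditioning=conditioning,
        )
        records.append(rec)
    return records


def write_batch(records: Sequence[TensileRecord], outdir) -> list[Path]:
    """Write one analysis-ready CSV per record into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rec in enumerate(records):
        paths.append(write_tensile_csv(rec, outdir / f"{rec.model_id}_{i:02d}.csv"))
    return paths
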