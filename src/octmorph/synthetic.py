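"""Synthetic segmented-OCT cohort generator.

Generates eyes whose whole-macula layer means (and foveal-pit parameters)
follow known forward models of age, sex, and scan focus, so the downstream
mapping / sectorization / regression stages can be validated by parameter
recovery.  Two generation modes exist:

* ``template`` mode — each of the five layers is a fixed radial template
  scaled so its whole-macula mean equals the forward model for that eye;
  total retinal thickness (TRT) is the layer sum.
* ``pit`` mode — TRT is a parametric foveal-pit surface whose per-eye central
  foveal thickness (CFT), rim height and rim radius follow their own forward
  models; layers are radial shares of TRT so additivity still holds.

Eyes are sampled either on the device raster (scattered A-scan positions,
25x512 or 97x1024 over a 6x6 mm field, with a random fixation offset and
left eyes mirrored) or directly on the regular analysis grid ("grid mode",
used for large cohorts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

import numpy as np

from .config import (
    LAYERS,
    TRT,
    REFERENCE_AGE,
    ConfigurationError,
    EffectModel,
    GeneratorConfig,
)

PROTOCOL_RASTERS = {"standard": (25, 512), "highres": (97, 1024)}
RASTER_HALF_WIDTH_MM = 3.0


# ---------------------------------------------------------------------------
# Subjects

@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: float
    sex: str  # "F" or "M"
    scan_focus: float  # diopters
    subject_intercept: float  # um, on the TRT scale
    z_intercept: float = 0.0  # standard-normal subject draw behind the intercept

    @property
    def is_male(self) -> bool:
        return self.sex == "M"


def sample_demographics(config: GeneratorConfig, seed: int | None = None,
                        rng: np.random.Generator | None = None) -> list[SubjectRecord]:
    """Draw the subject table: ages from weighted uniform buckets, sex as a
    Bernoulli(female_fraction), scan focus ~ N(0, scan_focus_sd), and a
    subject-level random intercept ~ N(0, random_intercept_sd)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = config.n_subjects
    edges = np.asarray(config.age_bucket_edges)
    weights = np.asarray(config.age_bucket_weights)
    buckets = rng.choice(len(weights), size=n, p=weights / weights.sum())
    ages = rng.uniform(edges[buckets], edges[buckets + 1])
    female = rng.random(n) < config.female_fraction
    focus = rng.normal(0.0, config.scan_focus_sd, size=n)
    z = rng.standard_normal(n)
    width = len(str(max(n, 1)))
    return [
        SubjectRecord(
            subject_id=f"S{i:0{width}d}",
            age=float(ages[i]),
            sex="F" if female[i] else "M",
            scan_focus=float(focus[i]),
            subject_intercept=float(z[i] * config.random_intercept_sd),
            z_intercept=float(z[i]),
        )
        for i in range(n)
    ]


def layer_mean_model(subject: SubjectRecord, layer: str,
                     config: GeneratorConfig) -> float:
    """Target whole-macula mean (um) for one subject and layer.

    mu_layer + b1*(age-40) + b2*(age-40)^2 + b_sex*isMale + b_sf*scanFocus
    plus the subject intercept scaled by mu_layer / mu_TRT (the intercept is
    calibrated on the TRT scale and applied proportionally to each layer).
    """
    try:
        model = config.layer_models[layer]
    except KeyError:
        raise KeyError(f"unknown layer {layer!r}") from None
    mu_trt = config.layer_models[TRT].mu
    intercept = subject.subject_intercept * model.mu / mu_trt
    return model.mean(subject.age, subject.is_male, subject.scan_focus) + intercept


# ---------------------------------------------------------------------------
# Parametric pit surface

def _pit_bump(u: np.ndarray | float, a: float) -> np.ndarray | float:
    """g(u) = u^a exp(a(1-u)): g(0)=0, g(1)=1, unique max at u=1."""
    u = np.asarray(u, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(u > 0, np.exp(a * (np.log(np.maximum(u, 1e-300)) + 1.0 - u)), 0.0)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class PitGeometry:
    """Per-eye pit parameters (before angular modulation)."""
    cft: float  # um
    rim_height: float  # um
    rim_radius_mm: float
    shape: float = 2.0
    rim_radius_cos2: float = 0.0
    rim_height_cos2: float = 0.0

    def rim_height_at(self, theta: np.ndarray | float) -> np.ndarray | float:
        return self.rim_height * (1.0 + self.rim_height_cos2 * np.cos(2.0 * np.asarray(theta)))

    def rim_radius_at(self, theta: np.ndarray | float) -> np.ndarray | float:
        return self.rim_radius_mm * (1.0 + self.rim_radius_cos2 * np.cos(2.0 * np.asarray(theta)))


def pit_surface(r_mm: np.ndarray | float, theta: np.ndarray | float,
                pit: PitGeometry) -> np.ndarray | float:
    """TRT (um) of the parametric pit at polar position (r, theta).

    T(r, theta) = CFT + (RimHeight(theta) - CFT) * g(r / RimRadius(theta)).
    """
    if pit.shape <= 0:
        raise ConfigurationError("pit shape exponent must be > 0")
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    rim_h = pit.rim_height_at(theta)
    rim_r = pit.rim_radius_at(theta)
    out = pit.cft + (rim_h - pit.cft) * _pit_bump(r / rim_r, pit.shape)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Radial layer templates
#
# Fixed synthetic shapes with the qualitative anatomy of the macula: inner
# layers (RNFL, GCIPL, INL) essentially absent centrally (< 1 um inside
# r < 0.3 mm after scaling) with an annular maximum, ONPL centrally peaked,
# ELM-BM near-flat.  Each template is normalized to mean 1 over the 3 mm disc.

def _sigmoid_rise(r: np.ndarray, r0: float, p: float) -> np.ndarray:
    rp = r ** p
    return rp / (rp + r0 ** p)


_TEMPLATE_SHAPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "RNFL": lambda r: _sigmoid_rise(r, 0.70, 8.0) * (1.0 + 0.15 * r),
    "GCIPL": lambda r: _sigmoid_rise(r, 0.55, 12.0) * np.exp(-r / 4.0),
    "INL": lambda r: _sigmoid_rise(r, 0.60, 12.0) * np.exp(-r / 3.5),
    # flat-topped central peak: its decay inside the foveola stays below the
    # inner-layer rise so the template TRT has its minimum at the center
    "ONPL": lambda r: 1.0 + 0.8 * np.exp(-((r / 1.15) ** 6)),
    "ELM_BM": lambda r: 1.0 - 0.03 * (r / 3.0) ** 2,
}


def _disc_mean_exact(f: Callable[[np.ndarray], np.ndarray], radius: float = 3.0,
                     n: int = 20000) -> float:
    """Mean of a radial function over the disc r <= radius (area-weighted
    midpoint quadrature; accurate to ~1e-8 for these smooth shapes)."""
    r = (np.arange(n) + 0.5) * (radius / n)
    dr = radius / n
    return float(np.sum(f(r) * 2.0 * np.pi * r * dr) / (np.pi * radius**2))


def layer_template(layer: str, r_mm: np.ndarray,
                   normalization: float | None = None) -> np.ndarray:
    """Evaluate a layer's radial template, normalized to disc mean 1.

    ``normalization`` overrides the continuum disc mean (grid mode passes the
    discrete node mean of the template over the analysis disc so that sector
    means recover targets exactly in the noiseless limit).
    """
    shape = _TEMPLATE_SHAPES[layer]
    if normalization is None:
        normalization = template_disc_mean(layer)
    return shape(np.asarray(r_mm, dtype=float)) / normalization


_TEMPLATE_MEANS: dict[str, float] = {}


def template_disc_mean(layer: str) -> float:
    if layer not in _TEMPLATE_MEANS:
        _TEMPLATE_MEANS[layer] = _disc_mean_exact(_TEMPLATE_SHAPES[layer])
    return _TEMPLATE_MEANS[layer]


def layer_shares(r_mm: np.ndarray, config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Radial share of each layer in the template TRT (sums to 1 at every r)."""
    mu_fields = {
        layer: config.layer_models[layer].mu * layer_template(layer, r_mm)
        for layer in LAYERS
    }
    total = sum(mu_fields.values())
    return {layer: f / total for layer, f in mu_fields.items()}


# ---------------------------------------------------------------------------
# Eye-level truth

@dataclass(frozen=True)
class EyeTruth:
    """The noise-free surface of one eye plus its acquisition geometry.

    ``layer_targets`` are the eye's whole-macula layer means (template mode);
    ``pit`` holds the eye's pit geometry (pit mode).  The fixation offset is
    the device-frame position of the fovea, identical across repeat scans of
    the same eye.
    """

    subject: SubjectRecord
    eye: str  # "OD" | "OS"
    mode: str
    offset: tuple[float, float]
    layer_targets: dict[str, float] = field(default_factory=dict)
    pit: PitGeometry | None = None

    def evaluate(self, u: np.ndarray, v: np.ndarray,
                 config: GeneratorConfig,
                 template_norms: dict[str, float] | None = None,
                 thickness_shift: float = 0.0) -> dict[str, np.ndarray]:
        """Layer fields (um) at fovea-centered anatomical positions (u, v).

        ``thickness_shift`` adds a constant to TRT (pit-mode measurement
        noise), distributed over the layers through their radial shares.
        """
        r = np.hypot(u, v)
        fields: dict[str, np.ndarray] = {}
        if self.mode == "template":
            for layer in LAYERS:
                norm = template_norms.get(layer) if template_norms else None
                target = max(self.layer_targets[layer] + thickness_shift
                             * config.layer_models[layer].mu
                             / config.layer_models[TRT].mu, 0.0)
                fields[layer] = target * layer_template(layer, r, norm)
        else:
            theta = np.arctan2(v, u)
            trt = pit_surface(r, theta, self.pit) + thickness_shift
            shares = layer_shares(r, config)
            for layer in LAYERS:
                fields[layer] = shares[layer] * trt
        fields[TRT] = sum(fields[layer] for layer in LAYERS)
        return fields


def _sample_offset(config: GeneratorConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Uniform draw from the fixation-offset disc."""
    rmax = config.fixation_offset_max_mm
    if rmax == 0:
        return (0.0, 0.0)
    r = rmax * math.sqrt(rng.random())
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return (r * math.cos(phi), r * math.sin(phi))


def pit_eye_params(subject: SubjectRecord, config: GeneratorConfig,
                   rng: np.random.Generator | None = None,
                   residuals: tuple[float, float, float] | None = None) -> PitGeometry:
    """Draw one eye's pit geometry from the pit forward models.

    The subject-level component reuses the subject's standard-normal
    intercept draw (scaled by each parameter's calibrated SD), so CFT and rim
    height co-vary within a subject as retinal thickness does; the per-eye
    residuals are independent across parameters.
    """
    if residuals is None:
        if rng is None:
            raise ValueError("need rng or explicit residuals")
        residuals = tuple(rng.standard_normal(3))
    values = {}
    for (name, e) in zip(("cft_um", "rim_height_um", "rim_radius_um"), residuals):
        m = config.pit_models[name]
        val = (m.mean(subject.age, subject.is_male, subject.scan_focus)
               + subject.z_intercept * m.subject_sd * config.intercept_scale
               + e * m.residual_sd * config.residual_scale)
        values[name] = val
    cft = values["cft_um"]
    rim_h = max(values["rim_height_um"], cft + 20.0)  # keep a rim above the pit
    rim_r = min(max(values["rim_radius_um"], 200.0), 2000.0) / 1000.0
    ps = config.pit_shape
    return PitGeometry(cft=cft, rim_height=rim_h, rim_radius_mm=rim_r,
                       shape=ps.shape, rim_radius_cos2=ps.rim_radius_cos2,
                       rim_height_cos2=ps.rim_height_cos2)


def make_eye_truth(subject: SubjectRecord, eye: str, config: GeneratorConfig,
                   rng: np.random.Generator) -> EyeTruth:
    """Sample the noise-free truth of one eye (offset + targets/pit)."""
    offset = _sample_offset(config, rng)
    if config.mode == "template":
        targets = {layer: layer_mean_model(subject, layer, config) for layer in LAYERS}
        return EyeTruth(subject=subject, eye=eye, mode="template",
                        offset=offset, layer_targets=targets)
    pit = pit_eye_params(subject, config, rng)
    return EyeTruth(subject=subject, eye=eye, mode="pit", offset=offset, pit=pit)


def draw_measurement_noise(truth: EyeTruth, config: GeneratorConfig,
                           rng: np.random.Generator) -> float:
    """Eye-level measurement noise on the TRT scale (um), drawn independently
    per acquisition of the same eye."""
    return float(rng.standard_normal() * config.residual_sd)


# ---------------------------------------------------------------------------
# Raster sampling

@dataclass
class SegmentedScan:
    """Scattered thickness samples of one eye in the device frame."""

    subject_id: str
    eye: str
    protocol: str
    x: np.ndarray  # mm, device frame
    y: np.ndarray
    layers: dict[str, np.ndarray]  # um per sample, keys: 5 layers + TRT

    @property
    def n_samples(self) -> int:
        return self.x.size


def raster_positions(protocol: str) -> tuple[np.ndarray, np.ndarray]:
    """Device-frame sample positions of a raster protocol (flattened)."""
    try:
        n_bscans, n_ascans = PROTOCOL_RASTERS[protocol]
    except KeyError:
        raise ConfigurationError(f"unknown protocol {protocol!r}") from None
    h = RASTER_HALF_WIDTH_MM
    ys = np.linspace(-h, h, n_bscans)
    xs = np.linspace(-h, h, n_ascans)
    X, Y = np.meshgrid(xs, ys)
    return X.ravel(), Y.ravel()


def evaluate_truth_on_raster(truth: EyeTruth, protocol: str,
                             config: GeneratorConfig,
                             thickness_shift: float = 0.0,
                             layer_shifts: dict[str, float] | None = None) -> SegmentedScan:
    """Evaluate an eye's surface on a raster protocol.

    Device -> anatomical mapping: u = +-(x - x0), v = y - y0 with the sign
    flipped for left (OS) eyes, so a nasally-peaked field appears on the
    temporal side of the device image of an OS eye, as on a real scanner.
    """
    x, y = raster_positions(protocol)
    x0, y0 = truth.offset
    u = (x - x0) if truth.eye == "OD" else -(x - x0)
    v = y - y0
    if layer_shifts:
        shifted = replace(truth, layer_targets={
            k: truth.layer_targets[k] + layer_shifts.get(k, 0.0) for k in truth.layer_targets
        })
    else:
        shifted = truth
    fields = shifted.evaluate(u, v, config, thickness_shift=thickness_shift)
    fields = {k: np.maximum(f, 0.0) for k, f in fields.items()}
    fields[TRT] = sum(fields[layer] for layer in LAYERS)
    return SegmentedScan(subject_id=truth.subject.subject_id, eye=truth.eye,
                         protocol=protocol, x=x, y=y, layers=fields)


def _layer_residual_shifts(config: GeneratorConfig,
                           rng: np.random.Generator) -> dict[str, float]:
    """Template-mode residual: one TRT-scale draw applied proportionally."""
    e = rng.standard_normal() * config.residual_sd
    mu_trt = config.layer_models[TRT].mu
    return {layer: e * config.layer_models[layer].mu / mu_trt for layer in LAYERS}


def sample_eye(subject: SubjectRecord, eye: str, config: GeneratorConfig,
               seed: int | None = None,
               rng: np.random.Generator | None = None) -> SegmentedScan:
    """Sample one eye of a subject on the configured raster protocol."""
    if rng is None:
        rng = np.random.default_rng(seed)
    truth = make_eye_truth(subject, eye, config, rng)
    if config.mode == "template":
        shifts = _layer_residual_shifts(config, rng)
        return evaluate_truth_on_raster(truth, config.protocol, config,
                                        layer_shifts=shifts)
    shift = draw_measurement_noise(truth, config, rng)
    return evaluate_truth_on_raster(truth, config.protocol, config,
                                    thickness_shift=shift)


# ---------------------------------------------------------------------------
# Cohort assembly

def assign_eyes(config: GeneratorConfig, rng: np.random.Generator,
                subjects: list[SubjectRecord]) -> list[tuple[SubjectRecord, str]]:
    """Each subject contributes both eyes with probability both_eyes_prob,
    otherwise one eye (laterality chosen at random)."""
    pairs: list[tuple[SubjectRecord, str]] = []
    for s in subjects:
        if rng.random() < config.both_eyes_prob:
            pairs.extend([(s, "OD"), (s, "OS")])
        else:
            pairs.append((s, "OD" if rng.random() < 0.5 else "OS"))
    return pairs


def simulate_cohort(config: GeneratorConfig, seed: int | None = None
                    ) -> Iterator[tuple[SubjectRecord, str, SegmentedScan]]:
    """Stream raster scans for a whole cohort (deterministic given seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    subjects = sample_demographics(config, rng=rng)
    for subject, eye in assign_eyes(config, rng, subjects):
        yield subject, eye, sample_eye(subject, eye, config, rng=rng)


def generate_cohort(config: GeneratorConfig, out_dir, seed: int | None = None):
    """Write a raster cohort to disk: metadata.csv, one scan CSV per eye,
    and the ground-truth generator configuration (YAML).

    Deterministic given (config, seed): regenerating produces byte-identical
    files.  Returns the output directory path.
    """
    from pathlib import Path

    from .config import save_config
    from .io import ensure_dir, write_metadata, write_scan

    out = ensure_dir(out_dir)
    scans_dir = ensure_dir(Path(out) / "scans")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    subjects = sample_demographics(config, rng=rng)
    meta_rows = []
    try:
        for subject, eye in assign_eyes(config, rng, subjects):
            scan = sample_eye(subject, eye, config, rng=rng)
            write_scan(scan, scans_dir / f"{subject.subject_id}_{eye}.csv")
            meta_rows.append((subject, eye, config.protocol))
        write_metadata(meta_rows, Path(out) / "metadata.csv")
        save_config(config, Path(out) / "generator_config.yaml")
    except OSError as err:
        raise OSError(f"failed writing cohort under {out}: {err}") from err
    return out


def true_parameter_table(config: GeneratorConfig, seed: int | None = None):
    """Noise-free per-eye parameter values straight from the forward models.

    This bypasses imaging entirely: layer means come from layer_mean_model
    and pit parameters from their effect models (with the subject intercept
    but no residual, offset, or discretization), which is the reference for
    exact coefficient recovery by the effects stage.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed if seed is None else seed)
    subjects = sample_demographics(config, rng=rng)
    rows = []
    for subject, eye in assign_eyes(config, rng, subjects):
        base = {
            "subject_id": subject.subject_id, "eye": eye, "age": subject.age,
            "sex": subject.sex, "scan_focus": subject.scan_focus,
        }
        for layer in LAYERS + (TRT,):
            rows.append({**base, "parameter": layer,
                         "value": layer_mean_model(subject, layer, config)})
        for name in ("cft_um", "rim_height_um", "rim_radius_um"):
            m = config.pit_models[name]
            val = (m.mean(subject.age, subject.is_male, subject.scan_focus)
                   + subject.z_intercept * m.subject_sd * config.intercept_scale)
            rows.append({**base, "parameter": name, "value": val})
    return pd.DataFrame(rows)
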