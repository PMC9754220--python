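"""Generator and run configuration.

The default :class:`GeneratorConfig` encodes the demographic structure and
effect sizes of a normative macular OCT study cohort: 444 subjects (855 eyes
expected), ages 21-88 concentrated in the 40-80 range, 63% female, and
per-layer age/sex effects on the whole-macula thickness means.  Reference
means are derived as the ratio of the absolute to the percent effect for each
layer (the percent normalization is relative to the young-group mean, so
absolute / percent * 100 recovers that mean).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

#: The five anatomical layers; their sum is the total retinal thickness (TRT).
LAYERS = ("RNFL", "GCIPL", "INL", "ONPL", "ELM_BM")
TRT = "TRT"
ALL_LAYERS = LAYERS + (TRT,)

#: Foveal pit parameter names used in tables.
PIT_PARAMS = ("cft_um", "rim_height_um", "rim_radius_mm", "mean_slope_deg")

REFERENCE_AGE = 40.0  # years; effect models are centered here


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class EffectModel:
    """Forward model of one parameter's whole-macula mean.

    mean(age, sex, focus) = mu + b1*(age-40) + b2*(age-40)^2
                            + sex_effect*isMale + focus_effect*scanFocus

    ``age_per_decade`` is the combined mean yearly change between ages 40 and
    80, times ten.  For quadratic parameters the curvature is fixed at 10% of
    the combined effect: the yearly slope varies +-10% around the combined
    value across ages 40-80, i.e. b2 = c/400 and b1 = 0.9*c with
    c = age_per_decade/10.
    """

    mu: float
    age_per_decade: float
    quadratic: bool
    sex_effect: float
    focus_effect: float = 0.0

    @property
    def age_linear(self) -> float:
        c = self.age_per_decade / 10.0
        return 0.9 * c if self.quadratic else c

    @property
    def age_quadratic(self) -> float:
        c = self.age_per_decade / 10.0
        return c / 400.0 if self.quadratic else 0.0

    def mean(self, age: float, is_male: bool, scan_focus: float) -> float:
        a = age - REFERENCE_AGE
        return (
            self.mu
            + self.age_linear * a
            + self.age_quadratic * a * a
            + self.sex_effect * float(is_male)
            + self.focus_effect * scan_focus
        )


@dataclass(frozen=True)
class PitParamModel(EffectModel):
    """Effect model for one foveal-pit parameter plus its noise calibration.

    ``subject_sd``/``residual_sd`` are the between-subject and per-eye SDs at
    the default global noise level; they are scaled by the global
    ``random_intercept_sd``/``residual_sd`` knobs of the generator (relative
    to their defaults of 14 and 6 um) so that a zero-noise configuration
    silences them as well.
    """

    subject_sd: float = 0.0
    residual_sd: float = 0.0


def _default_layer_models() -> dict[str, EffectModel]:
    # Reference means as abs/percent coefficient ratios; the five layers are
    # then renormalized so that they sum exactly to the TRT reference mean.
    raw_mu = {
        "RNFL": 0.22 / 0.69 * 100.0,
        "GCIPL": 1.77 / 2.41 * 100.0,
        "INL": 0.45 / 1.31 * 100.0,
        "ONPL": 0.66 / 0.73 * 100.0,
        "ELM_BM": 0.45 / 0.56 * 100.0,
    }
    mu_trt = 3.25 / 1.05 * 100.0
    scale = mu_trt / sum(raw_mu.values())
    # (age per decade, quadratic, sex effect) for each layer
    effects = {
        "RNFL": (0.22, False, -0.03),
        "GCIPL": (-1.77, True, 0.57),
        "INL": (-0.45, True, 0.87),
        "ONPL": (-0.66, False, 1.80),
        "ELM_BM": (-0.45, True, 0.93),
    }
    models = {}
    for name, (age10, quad, sex) in effects.items():
        mu = raw_mu[name] * scale
        models[name] = EffectModel(
            mu=mu, age_per_decade=age10, quadratic=quad, sex_effect=sex,
            focus_effect=1.0 * mu / mu_trt,
        )
    # TRT carries the printed whole-retina coefficients; note that generated
    # TRT effects are the *sums* of the per-layer effects (additivity), which
    # agree with these to within table rounding.
    models[TRT] = EffectModel(
        mu=mu_trt, age_per_decade=-3.25, quadratic=True, sex_effect=4.14,
        focus_effect=1.0,
    )
    return models


def _default_pit_models() -> dict[str, PitParamModel]:
    return {
        "cft_um": PitParamModel(
            mu=7.99 / 3.47 * 100.0, age_per_decade=-1.44, quadratic=True,
            sex_effect=7.99, focus_effect=1.0, subject_sd=18.0, residual_sd=9.0,
        ),
        "rim_height_um": PitParamModel(
            mu=8.63 / 2.46 * 100.0, age_per_decade=-3.42, quadratic=True,
            sex_effect=8.63, focus_effect=1.0, subject_sd=15.0, residual_sd=7.4,
        ),
        # rim radius is modelled in um (as printed); the pipeline reports mm
        "rim_radius_um": PitParamModel(
            mu=59.4 / 5.24 * 100.0, age_per_decade=-7.66,
            quadratic=False, sex_effect=-59.4, focus_effect=1.0,
            subject_sd=90.0, residual_sd=42.0,
        ),
    }


@dataclass(frozen=True)
class PitShape:
    """Parametric radial pit profile T(r, theta).

    T = CFT + (RimHeight(theta) - CFT) * g(r / RimRadius(theta)) with
    g(u) = u**a * exp(a*(1-u)); g(0)=0, g(1)=1, unique maximum at u=1.
    Rim radius and rim height carry a cos(2*theta) modulation so the pit is
    broader horizontally than vertically.
    """

    shape: float = 2.0
    rim_radius_cos2: float = 0.10
    rim_height_cos2: float = 0.02


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 444
    #: [21,40), [40,60), [60,80), [80,88] year buckets; proportions follow
    #: the reported per-bucket subject counts (51 : 212 : 161 : 8)
    age_bucket_weights: tuple[float, ...] = (51 / 432, 212 / 432, 161 / 432, 8 / 432)
    age_bucket_edges: tuple[float, ...] = (21.0, 40.0, 60.0, 80.0, 88.0)
    female_fraction: float = 281 / 444
    both_eyes_prob: float = 411 / 444
    scan_focus_sd: float = 1.5
    random_intercept_sd: float = 14.0
    residual_sd: float = 6.0
    fixation_offset_max_mm: float = 0.3
    protocol: str = "standard"
    mode: str = "template"  # or "pit"
    layer_models: Mapping[str, EffectModel] = field(default_factory=_default_layer_models)
    pit_models: Mapping[str, PitParamModel] = field(default_factory=_default_pit_models)
    pit_shape: PitShape = field(default_factory=PitShape)
    seed: int = 0

    # default calibration anchors for scaling per-parameter noise terms
    _BASE_INTERCEPT_SD = 14.0
    _BASE_RESIDUAL_SD = 6.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        w = self.age_bucket_weights
        if any(x < 0 for x in w):
            raise ConfigurationError("age bucket weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ConfigurationError("age bucket weights must sum to 1")
        if len(self.age_bucket_edges) != len(w) + 1:
            raise ConfigurationError("need one more bucket edge than weight")
        for p, name in ((self.female_fraction, "female_fraction"),
                        (self.both_eyes_prob, "both_eyes_prob")):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for sd in (self.random_intercept_sd, self.residual_sd, self.scan_focus_sd):
            if sd < 0:
                raise ConfigurationError("noise SDs must be >= 0")
        for name, m in self.layer_models.items():
            if m.mu <= 0:
                raise ConfigurationError(f"reference mean for {name} must be > 0")
        pit = self.pit_models
        if pit["rim_height_um"].mu <= pit["cft_um"].mu:
            raise ConfigurationError("rim height reference must exceed CFT")
        if not 0.0 < pit["rim_radius_um"].mu <= 2000.0:
            raise ConfigurationError("rim radius reference must be in (0, 2] mm")
        if self.pit_shape.shape <= 0:
            raise ConfigurationError("pit shape exponent must be > 0")
        if self.mode not in ("template", "pit"):
            raise ConfigurationError(f"unknown generator mode {self.mode!r}")
        if self.protocol not in ("standard", "highres"):
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")

    @property
    def intercept_scale(self) -> float:
        """Global scaling of subject-level noise relative to the calibration."""
        return self.random_intercept_sd / self._BASE_INTERCEPT_SD

    @property
    def residual_scale(self) -> float:
        return self.residual_sd / self._BASE_RESIDUAL_SD

    def noiseless(self) -> "GeneratorConfig":
        """Copy of this config with every noise term set to zero."""
        return dataclasses.replace(
            self, random_intercept_sd=0.0, residual_sd=0.0,
            fixation_offset_max_mm=0.0,
        )


# ---------------------------------------------------------------------------
# YAML round-trip (flat representation of the knobs a user typically edits)

def config_to_dict(config: GeneratorConfig) -> dict:
    d = {
        "n_subjects": config.n_subjects,
        "age_bucket_weights": list(config.age_bucket_weights),
        "age_bucket_edges": list(config.age_bucket_edges),
        "female_fraction": config.female_fraction,
        "both_eyes_prob": config.both_eyes_prob,
        "scan_focus_sd": config.scan_focus_sd,
        "random_intercept_sd": config.random_intercept_sd,
        "residual_sd": config.residual_sd,
        "fixation_offset_max_mm": config.fixation_offset_max_mm,
        "protocol": config.protocol,
        "mode": config.mode,
        "seed": config.seed,
        "layer_models": {
            k: dataclasses.asdict(v) for k, v in config.layer_models.items()
        },
        "pit_models": {
            k: dataclasses.asdict(v) for k, v in config.pit_models.items()
        },
        "pit_shape": dataclasses.asdict(config.pit_shape),
    }
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "layer_models" in d:
        d["layer_models"] = {k: EffectModel(**v) for k, v in d["layer_models"].items()}
    if "pit_models" in d:
        d["pit_models"] = {k: PitParamModel(**v) for k, v in d["pit_models"].items()}
    if "pit_shape" in d:
        d["pit_shape"] = PitShape(**d["pit_shape"])
    for key in ("age_bucket_weights", "age_bucket_edges"):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)


def save_config(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config(path) -> GeneratorConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
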