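"""Synthetic indentation studies with known ground truth.

The generator inverts the analysis pipeline's statistical model: aggregate
compliance for a subject at a site is assembled as

    A/k = t_m / E_m + t_f / E_f + u_subject + v_location + eps

with layer thicknesses drawn per site from truncated normals, crossed
zero-mean normal random intercepts for subject and location, and a normal
residual.  From that compliance the generator emits the raw channels the
preprocessing stage consumes: a linear force-displacement trace (with
optional force noise) and tissue-boundary depth traces whose fat and
muscle layers thin with the applied force so that the layer deformations
at maximum force equal the serial-spring predictions

    dt_m = t_m/E_m * F_max/A,    dt_f = t_f/E_f * F_max/A

plus a per-trial deformation-noise draw.  Probe-face offset and skin
thickness are held constant: the skin layer is not modelled.

Everything is deterministic given the seed; per-trial RNG substreams are
derived from (seed, subject index, site index) so a study is reproducible
trial by trial.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from springlayer.errors import ConfigurationError, GenerationError
from springlayer.sites import SITE_CODES, validate_site

# Per-site (mean, SD) in mm for fat and muscle thickness.  Values span the
# ranges seen across extremity sites: thin fat / moderate muscle on the
# forearm and shank, thicker fat and much thicker muscle on the thigh, with
# muscle thickness clustering by site more strongly than fat.  Together
# with the default inverse moduli these give site-mean compliances of
# roughly 200 (lower arm anterior) to 500 (upper leg posterior) mm^3/N;
# the default noise SDs below are sized so the additive-Gaussian model
# keeps every site's compliance distribution effectively positive
# (P(compliance <= 0) < 1e-4 at the thinnest site), which the generative
# model requires for self-consistency.
DEFAULT_THICKNESS_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "LA_A": {"fat": (6.0, 1.5), "muscle": (24.0, 5.0)},
    "LA_P": {"fat": (8.0, 2.0), "muscle": (20.0, 4.0)},
    "LL_A": {"fat": (6.0, 1.5), "muscle": (28.0, 6.0)},
    "LL_P": {"fat": (9.0, 2.5), "muscle": (34.0, 7.0)},
    "UA_A": {"fat": (10.0, 3.0), "muscle": (25.0, 6.0)},
    "UA_P": {"fat": (12.0, 3.5), "muscle": (20.0, 5.0)},
    "UL_A": {"fat": (12.0, 3.5), "muscle": (40.0, 8.0)},
    "UL_P": {"fat": (18.0, 5.0), "muscle": (45.0, 9.0)},
}

# Constant probe-face offset to the superficial skin boundary and constant
# skin thickness (mm); the skin layer carries no mechanics here.
_SKIN_SURFACE_MM = 0.5
_SKIN_THICKNESS_MM = 1.5

_MAX_RESAMPLE = 100

# No layer is driven past this fraction of its thickness; the generator
# shortens the indentation depth of very compliant trials accordingly.
_MAX_LAYER_STRAIN = 0.6


@dataclass(frozen=True)
class GeneratorConfig:
    """All parameters of a synthetic indentation study.

    Units: inverse moduli mm^2/N, random-effect and residual SDs mm^3/N,
    thicknesses and displacement mm, probe area mm^2, force noise N.
    """

    n_subjects: int = 100
    sites: tuple[str, ...] = SITE_CODES
    inv_E_m: float = 3.77
    inv_E_f: float = 18.10
    sigma_subject: float = 30.0
    sigma_location: float = 20.0
    sigma_resid: float = 30.0
    thickness_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_THICKNESS_PARAMS
    )
    probe_area: float = 500.0
    max_displacement: float = 5.0
    n_trace_points: int = 100
    trace_noise_sd: float = 0.1
    deformation_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not self.sites:
            raise ConfigurationError("sites must be non-empty")
        for s in self.sites:
            try:
                validate_site(s)
            except ValueError as exc:
                raise ConfigurationError(str(exc)) from exc
        if self.inv_E_m <= 0 or self.inv_E_f <= 0:
            raise ConfigurationError("inverse moduli must be > 0")
        for name in ("sigma_subject", "sigma_location", "sigma_resid",
                     "trace_noise_sd", "deformation_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.probe_area <= 0:
            raise ConfigurationError("probe_area must be > 0")
        if self.max_displacement <= 0:
            raise ConfigurationError("max_displacement must be > 0")
        if self.n_trace_points < 2:
            raise ConfigurationError("n_trace_points must be >= 2")
        for s in self.sites:
            if s not in self.thickness_params:
                raise ConfigurationError(f"thickness_params missing site {s!r}")
            for layer in ("fat", "muscle"):
                mean, sd = self.thickness_params[s][layer]
                if mean <= 0:
                    raise ConfigurationError(
                        f"{layer} thickness mean for {s} must be > 0"
                    )
                if sd < 0:
                    raise ConfigurationError(
                        f"{layer} thickness SD for {s} must be >= 0"
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sites"] = list(self.sites)
        d["thickness_params"] = {
            s: {layer: list(v) for layer, v in layers.items()}
            for s, layers in self.thickness_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "sites" in d:
            d["sites"] = tuple(d["sites"])
        if "thickness_params" in d:
            d["thickness_params"] = {
                s: {layer: tuple(v) for layer, v in layers.items()}
                for s, layers in d["thickness_params"].items()
            }
        return cls(**d)


@dataclass
class IndentationTrial:
    """One manual-indentation trial of a subject at a site.

    ``displacement`` is the bulk tissue thickness change (mm, monotone from
    0); ``force`` the baselined indentation force (N).  Boundary depths are
    measured from the probe face at each sample, in the fixed anatomical
    order superficial skin < skin/fat < fat/muscle < muscle/bone.
    """

    subject_id: str
    site: str
    force: np.ndarray
    displacement: np.ndarray
    probe_area: float
    skin: np.ndarray
    skinfat: np.ndarray
    fatmuscle: np.ndarray
    musclebone: np.ndarray

    def validate(self) -> None:
        n = len(self.force)
        traces = (self.displacement, self.skin, self.skinfat,
                  self.fatmuscle, self.musclebone)
        if any(len(t) != n for t in traces):
            raise ValueError(f"trial {self.subject_id}/{self.site}: unequal trace lengths")
        if self.displacement[0] != 0:
            raise ValueError(f"trial {self.subject_id}/{self.site}: displacement[0] != 0")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError(f"trial {self.subject_id}/{self.site}: displacement not monotone")
        pairs = (("skin", "skinfat"), ("skinfat", "fatmuscle"),
                 ("fatmuscle", "musclebone"))
        for lo, hi in pairs:
            if not np.all(getattr(self, lo) < getattr(self, hi)):
                raise ValueError(
                    f"trial {self.subject_id}/{self.site}: boundary ordering "
                    f"violated between {lo} and {hi}"
                )


@dataclass
class GroundTruth:
    """True parameter values a recovery analysis is judged against.

    ``trials`` has one row per generated trial with the drawn thicknesses,
    the residual draw, the exact assembled compliance and the true layer
    deformations at maximum force (before extraction).
    """

    inv_E_m: float
    inv_E_f: float
    subject_effects: dict[str, float]
    location_effects: dict[str, float]
    trials: pd.DataFrame


def generate_trace(
    compliance: float,
    probe_area: float,
    max_displacement: float,
    n_trace_points: int,
    trace_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Force (N) and probe-displacement (mm) arrays for one linear trial.

    Noiseless pressure is displacement / compliance; force is pressure times
    probe area plus optional gaussian noise, with the zero-displacement
    sample forced to exactly zero force.
    """
    if compliance <= 0:
        raise ValueError(f"compliance must be > 0, got {compliance}")
    displacement = np.linspace(0.0, max_displacement, n_trace_points)
    force = displacement / compliance * probe_area
    if trace_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        force = force + rng.normal(0.0, trace_noise_sd, size=n_trace_points)
    force[0] = 0.0
    return force, displacement


def _trial_rng(seed: int, subj_idx: int, site_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1, subj_idx, site_idx]))


def _draw_thickness(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return mean
    a = (0.0 - mean) / sd  # truncate at zero
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def generate_study(config: GeneratorConfig) -> tuple[list[IndentationTrial], GroundTruth]:
    """Generate one trial per subject x site plus the generating truth.

    Residual draws that would produce non-positive compliance, or a layer
    deformation exceeding the layer's thickness, are resampled (up to 100
    attempts) so the emitted study satisfies every trial invariant.
    """
    effects_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    subjects = [f"S{i + 1:03d}" for i in range(config.n_subjects)]
    subject_effects = {
        s: float(e)
        for s, e in zip(
            subjects, effects_rng.normal(0.0, config.sigma_subject, config.n_subjects)
        )
    }
    location_effects = {
        l: float(e)
        for l, e in zip(
            config.sites, effects_rng.normal(0.0, config.sigma_location, len(config.sites))
        )
    }

    trials: list[IndentationTrial] = []
    rows = []
    for si, subject in enumerate(subjects):
        for li, site in enumerate(config.sites):
            rng = _trial_rng(config.seed, si, li)
            fat_mean, fat_sd = config.thickness_params[site]["fat"]
            mus_mean, mus_sd = config.thickness_params[site]["muscle"]
            # resample thickness + residual + deformation noise until the
            # trial is physical (positive compliance, deformations within
            # their layers even under worst-case force noise)
            for _ in range(_MAX_RESAMPLE):
                t_f = _draw_thickness(fat_mean, fat_sd, rng)
                t_m = _draw_thickness(mus_mean, mus_sd, rng)
                resid = rng.normal(0.0, config.sigma_resid) if config.sigma_resid else 0.0
                compliance = (
                    config.inv_E_m * t_m
                    + config.inv_E_f * t_f
                    + subject_effects[subject]
                    + location_effects[site]
                    + resid
                )
                if compliance <= 0:
                    continue
                e_f = (
                    rng.normal(0.0, config.deformation_noise_sd)
                    if config.deformation_noise_sd
                    else 0.0
                )
                e_m = (
                    rng.normal(0.0, config.deformation_noise_sd)
                    if config.deformation_noise_sd
                    else 0.0
                )
                # Indentation depth is capped per trial so that no layer is
                # compressed past ~60% of its thickness (an operator stops
                # pressing before bottoming a layer out); d_layer/t_layer =
                # inv_E_layer * depth / compliance under the serial-spring
                # split, so the cap depends only on compliance.
                depth = min(
                    config.max_displacement,
                    _MAX_LAYER_STRAIN * compliance / max(config.inv_E_f, config.inv_E_m),
                )
                # worst-case peak pressure over the trace (+4 SD force-noise headroom)
                p_max = depth / compliance + 4.0 * config.trace_noise_sd / config.probe_area
                # slightly negative apparent deformations are allowed (the
                # extraction stage clamps them as annotation noise); only a
                # deformation exceeding its layer's thickness is unphysical
                d_f_max = config.inv_E_f * t_f * p_max + e_f
                d_m_max = config.inv_E_m * t_m * p_max + e_m
                if d_f_max < t_f and d_m_max < t_m:
                    break
            else:
                raise GenerationError(
                    f"trial {subject}/{site}: no physical draw after "
                    f"{_MAX_RESAMPLE} attempts (site {site}, fat mean {fat_mean}, "
                    f"muscle mean {mus_mean})"
                )

            force, displacement = generate_trace(
                compliance,
                config.probe_area,
                depth,
                config.n_trace_points,
                config.trace_noise_sd,
                rng,
            )
            f_max = float(np.max(force))
            # layer deformations track the (noisy) force channel; at the
            # max-force sample they equal the serial-spring value + noise draw
            scale = force / f_max if f_max > 0 else np.zeros_like(force)
            d_f = (config.inv_E_f * t_f / config.probe_area) * force + e_f * scale
            d_m = (config.inv_E_m * t_m / config.probe_area) * force + e_m * scale

            skin = np.full_like(force, _SKIN_SURFACE_MM)
            skinfat = skin + _SKIN_THICKNESS_MM
            fatmuscle = skinfat + t_f - d_f
            musclebone = fatmuscle + t_m - d_m
            trial = IndentationTrial(
                subject_id=subject,
                site=site,
                force=force,
                displacement=displacement,
                probe_area=config.probe_area,
                skin=skin,
                skinfat=skinfat,
                fatmuscle=fatmuscle,
                musclebone=musclebone,
            )
            trial.validate()
            trials.append(trial)
            i_max = int(np.argmax(force))
            rows.append(
                {
                    "subject_id": subject,
                    "site": site,
                    "t_fat_mm": t_f,
                    "t_muscle_mm": t_m,
                    "residual_mm3_per_N": resid,
                    "compliance_mm3_per_N": compliance,
                    "f_max_N": f_max,
                    "dfat_true_mm": float(d_f[i_max]),
                    "dmuscle_true_mm": float(d_m[i_max]),
                }
            )

    truth = GroundTruth(
        inv_E_m=config.inv_E_m,
        inv_E_f=config.inv_E_f,
        subject_effects=subject_effects,
        location_effects=location_effects,
        trials=pd.DataFrame(rows),
    )
    return trials, truth


# ---------------------------------------------------------------------------
# disk round trip

TRACE_COLUMNS = ["sample", "force_N", "displacement_mm", "skin_mm",
                 "skinfat_mm", "fatmuscle_mm", "musclebone_mm"]


def write_study(
    trials: Sequence[IndentationTrial],
    truth: GroundTruth,
    config: GeneratorConfig,
    outdir: str | Path,
) -> Path:
    """Write trace CSVs, a manifest, ground truth and a config echo."""
    outdir = Path(outdir)
    traces = outdir / "traces"
    traces.mkdir(parents=True, exist_ok=True)
    manifest = []
    for trial in trials:
        fname = f"{trial.subject_id}_{trial.site}.csv"
        df = pd.DataFrame(
            {
                "sample": np.arange(len(trial.force)),
                "force_N": trial.force,
                "displacement_mm": trial.displacement,
                "skin_mm": trial.skin,
                "skinfat_mm": trial.skinfat,
                "fatmuscle_mm": trial.fatmuscle,
                "musclebone_mm": trial.musclebone,
            }
        )
        df.to_csv(traces / fname, index=False)
        manifest.append(
            {
                "subject_id": trial.subject_id,
                "site": trial.site,
                "probe_area_mm2": trial.probe_area,
                "trace_file": f"traces/{fname}",
            }
        )
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
    truth.trials.to_csv(outdir / "ground_truth_trials.csv", index=False)
    pd.DataFrame(
        {
            "effect": ["subject"] * len(truth.subject_effects)
            + ["location"] * len(truth.location_effects),
            "level": list(truth.subject_effects) + list(truth.location_effects),
            "value_mm3_per_N": list(truth.subject_effects.values())
            + list(truth.location_effects.values()),
        }
    ).to_csv(outdir / "ground_truth_effects.csv", index=False)
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return outdir


def read_study(indir: str | Path) -> list[IndentationTrial]:
    """Load trials written by :func:`write_study` (or any same-schema data)."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    trials = []
    for rec in manifest.itertuples(index=False):
        df = pd.read_csv(indir / rec.trace_file)
        trials.append(
            IndentationTrial(
                subject_id=str(rec.subject_id),
                site=str(rec.site),
                force=df["force_N"].to_numpy(),
                displacement=df["displacement_mm"].to_numpy(),
                probe_area=float(rec.probe_area_mm2),
                skin=df["skin_mm"].to_numpy(),
                skinfat=df["skinfat_mm"].to_numpy(),
                fatmuscle=df["fatmuscle_mm"].to_numpy(),
                musclebone=df["musclebone_mm"].to_numpy(),
            )
        )
    return trials
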