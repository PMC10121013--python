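"""From raw indentation trials to the per-trial feature table.

Each trial contributes one row: initial fat and muscle thicknesses from
the first-sample boundary depths, aggregate compliance as the inverse of
the through-origin slope of pressure vs. probe displacement, the maximum
baselined force, and the experimental fat/muscle deformations read at the
max-force sample.  Trials with a non-positive fitted slope are excluded
(logged), not errored, mirroring routine data-quality exclusions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from springlayer.errors import PipelineError
from springlayer.synthetic import IndentationTrial

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "subject_id",
    "site",
    "t_fat_mm",
    "t_muscle_mm",
    "compliance_mm3_per_N",
    "f_max_N",
    "probe_area_mm2",
    "dfat_exp_mm",
    "dmuscle_exp_mm",
]


def zero_force_baseline(force: np.ndarray, displacement: np.ndarray) -> np.ndarray:
    """Shift the force channel so it reads exactly zero at zero displacement."""
    force = np.asarray(force, dtype=float)
    displacement = np.asarray(displacement, dtype=float)
    if force.shape != displacement.shape or force.size < 2:
        raise ValueError("force and displacement must be equal-length arrays of >= 2 samples")
    zero_idx = np.flatnonzero(displacement == 0)
    if zero_idx.size == 0:
        raise ValueError("no zero-displacement sample to baseline against")
    return force - force[zero_idx[0]]


def fit_stiffness_through_origin(displacement: np.ndarray, pressure: np.ndarray) -> float:
    """Least-squares slope of pressure on displacement constrained through (0, 0).

    The closed-form solution is sum(d*p) / sum(d^2) (N/mm^3 when pressure is
    N/mm^2 and displacement mm).  A non-positive slope is returned as-is;
    callers flag such trials invalid rather than erroring.
    """
    displacement = np.asarray(displacement, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    if displacement.size < 2 or displacement.shape != pressure.shape:
        raise ValueError("need >= 2 paired samples")
    denom = float(np.dot(displacement, displacement))
    if denom == 0.0:
        raise ValueError("all displacements are zero; slope undefined")
    return float(np.dot(displacement, pressure) / denom)


def compliance_from_slope(slope: float) -> float:
    """Aggregate tissue compliance (mm^3/N) as the inverse of surface stiffness."""
    if slope <= 0:
        raise ValueError(f"stiffness slope must be > 0, got {slope}")
    return 1.0 / slope


def extract_thicknesses(
    skin: float, skinfat: float, fatmuscle: float, musclebone: float
) -> tuple[float, float]:
    """Initial fat and muscle thicknesses (mm) from first-sample boundary depths."""
    if not skin < skinfat:
        raise ValueError("boundary ordering violated: skin >= skin/fat")
    if not skinfat < fatmuscle:
        raise ValueError("boundary ordering violated: skin/fat >= fat/muscle (zero fat thickness)")
    if not fatmuscle < musclebone:
        raise ValueError("boundary ordering violated: fat/muscle >= muscle/bone (zero muscle thickness)")
    return float(fatmuscle - skinfat), float(musclebone - fatmuscle)


def extract_layer_deformations(trial: IndentationTrial) -> tuple[float, float, float]:
    """Fat and muscle deformations (mm) at the max-force sample, plus F_max (N).

    Deformation is the initial layer thickness minus the thickness at the
    sample of maximum baselined force; small negatives (annotation noise)
    are clamped to zero with a warning.
    """
    for name in ("skin", "skinfat", "fatmuscle", "musclebone"):
        if not np.all(np.isfinite(getattr(trial, name))):
            raise ValueError(
                f"trial {trial.subject_id}/{trial.site}: non-finite {name} boundary values"
            )
    force = zero_force_baseline(trial.force, trial.displacement)
    i_max = int(np.argmax(force))
    f_max = float(force[i_max])
    t_fat = trial.fatmuscle - trial.skinfat
    t_mus = trial.musclebone - trial.fatmuscle
    dfat = float(t_fat[0] - t_fat[i_max])
    dmus = float(t_mus[0] - t_mus[i_max])
    if dfat < 0 or dmus < 0:
        logger.warning(
            "trial %s/%s: negative extracted deformation (fat %.3g, muscle %.3g) clamped to 0",
            trial.subject_id, trial.site, dfat, dmus,
        )
        dfat = max(dfat, 0.0)
        dmus = max(dmus, 0.0)
    return dfat, dmus, f_max


def trial_features(trial: IndentationTrial) -> dict:
    """Feature row for one trial; raises on invalid geometry or slope."""
    t_f, t_m = extract_thicknesses(
        trial.skin[0], trial.skinfat[0], trial.fatmuscle[0], trial.musclebone[0]
    )
    force = zero_force_baseline(trial.force, trial.displacement)
    pressure = force / trial.probe_area
    slope = fit_stiffness_through_origin(trial.displacement, pressure)
    if slope <= 0:
        raise ValueError(f"non-positive fitted stiffness slope ({slope:.3g} N/mm^3)")
    dfat, dmus, f_max = extract_layer_deformations(trial)
    if f_max <= 0:
        raise ValueError("non-positive maximum force")
    return {
        "subject_id": trial.subject_id,
        "site": trial.site,
        "t_fat_mm": t_f,
        "t_muscle_mm": t_m,
        "stiffness_slope_N_per_mm3": slope,  # exact reciprocal of compliance
        "compliance_mm3_per_N": compliance_from_slope(slope),
        "f_max_N": f_max,
        "probe_area_mm2": trial.probe_area,
        "dfat_exp_mm": dfat,
        "dmuscle_exp_mm": dmus,
    }


def build_feature_table(trials: Iterable[IndentationTrial]) -> pd.DataFrame:
    """One feature row per valid trial; invalid trials are excluded and logged.

    The returned frame carries the exclusion count in ``df.attrs["n_excluded"]``
    so that rows_out + exclusions always equals trials_in.
    """
    rows = []
    excluded = 0
    n_in = 0
    for trial in trials:
        n_in += 1
        try:
            rows.append(trial_features(trial))
        except ValueError as exc:
            excluded += 1
            logger.info("excluding trial %s/%s: %s", trial.subject_id, trial.site, exc)
    if n_in == 0:
        raise PipelineError("no trials supplied")
    if not rows:
        raise PipelineError(f"all {n_in} trials were excluded; nothing to analyse")
    if excluded:
        logger.info("excluded %d of %d trials", excluded, n_in)
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.attrs["n_excluded"] = excluded
    df.attrs["n_input"] = n_in
    return df
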