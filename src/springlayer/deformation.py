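"""Layer deformation predictions from fitted inverse moduli.

A physics-family fit gives inverse moduli 1/E_m and 1/E_f; under the
serial-spring idealization the deformation of each layer at maximum
applied force is

    dt_m = 1/E_m * t_m * F_max / A,    dt_f = 1/E_f * t_f * F_max / A

When the source fit is the combined mixed model, only the fixed-effect
coefficients enter: the random intercepts are compliance offsets with no
per-layer attribution.
"""

from __future__ import annotations

import pandas as pd

from springlayer.errors import PipelineError, UsageError
from springlayer.models import SpringFit

DEFORMATION_COLUMNS = [
    "subject_id",
    "site",
    "dfat_pred_mm",
    "dmuscle_pred_mm",
    "dfat_exp_mm",
    "dmuscle_exp_mm",
    "f_max_N",
    "probe_area_mm2",
    "coefficient_source",
]


def predict_layer_deformations(fit: SpringFit, row: pd.Series | dict) -> dict:
    """Predicted fat and muscle deformations (mm) for one feature row."""
    if fit.spec.family != "physics":
        raise UsageError(
            "layer deformations require a physics (zero-intercept) fit; "
            "an intercept has no serial-spring interpretation"
        )
    area = float(row["probe_area_mm2"])
    if area <= 0:
        raise ValueError(f"probe area must be > 0, got {area}")
    f_max = float(row["f_max_N"])
    pressure = f_max / area
    return {
        "subject_id": row["subject_id"],
        "site": row["site"],
        "dfat_pred_mm": fit.coef["fat"] * float(row["t_fat_mm"]) * pressure,
        "dmuscle_pred_mm": fit.coef["muscle"] * float(row["t_muscle_mm"]) * pressure,
        "dfat_exp_mm": float(row["dfat_exp_mm"]),
        "dmuscle_exp_mm": float(row["dmuscle_exp_mm"]),
        "f_max_N": f_max,
        "probe_area_mm2": area,
        "coefficient_source": "combined" if fit.spec.is_combined else "location_specific",
    }


def deformation_table(fit: SpringFit, features: pd.DataFrame) -> pd.DataFrame:
    """One prediction row per trial, paired with the experimental values."""
    if len(features) == 0:
        raise PipelineError("empty feature table")
    rows = []
    for _, row in features.iterrows():
        try:
            rows.append(predict_layer_deformations(fit, row))
        except ValueError as exc:
            raise ValueError(
                f"trial {row['subject_id']}/{row['site']}: {exc}"
            ) from exc
    return pd.DataFrame(rows, columns=DEFORMATION_COLUMNS)
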