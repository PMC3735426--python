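"""Outcome and covariate coding, and assembly of the model design tables.

The binary outcome is psychological distress: a GHQ-30 score at or above the
standard cut-point of 5.  Exposures are coded as in the analysis plan:

* land-use mix -> tertiles (low tertile is the reference);
* the four street-syntax variables, slope variability and NDVI -> z-scores;
* dwelling type (reference: detached) and plot exposure (reference: one
  exposed face) -> factors;
* age (years) and alcohol (ml/week) -> continuous;
* social class -> the six Registrar-General groups collapsed to three levels
  (I/II/III-non-manual as reference, III-manual, IV/V);
* education -> three levels (none/apprenticeship as reference);
* chronic vascular morbidity -> any of six condition flags;
* area deprivation -> six domain scores (0-100) carried through as-is; the
  'access to services' domain is rejected outright because of its
  collinearity with the street-accessibility measures.

Three design tables are defined: Model 1 (built-environment block +
individual covariates), Model 2 (natural environment + deprivation +
individual covariates) and Model 3 (the union).  Rows with any missing value
are dropped before z-scoring, and every assembly emits a machine-readable
coding manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import geo_morphometrics as gm


class CodingError(ValueError):
    pass


GHQ_CASE_CUTPOINT = 5

CHRONIC_FLAGS = ("mi", "angina", "high_bp", "high_chol", "diabetes", "stroke")

SOCIAL_CLASS_RAW = ("I", "II", "III_nonmanual", "III_manual", "IV", "V")
SOCIAL_CLASS_COLLAPSE = {
    "I": "I_II_IIInm",
    "II": "I_II_IIInm",
    "III_nonmanual": "I_II_IIInm",
    "III_manual": "III_manual",
    "IV": "IV_V",
    "V": "IV_V",
}
SOCIAL_CLASS_LEVELS = ("I_II_IIInm", "III_manual", "IV_V")  # first = reference

EDUCATION_LEVELS = (
    "none_apprenticeship",      # reference
    "school_certificate",
    "professional_degree",
)

WIMD_DOMAINS = (
    "wimd_income",
    "wimd_employment",
    "wimd_health",
    "wimd_education",
    "wimd_housing",
    "wimd_physical",
)
WIMD_EXCLUDED = "wimd_access_services"

TERTILE_LABELS = ("T1", "T2", "T3")


def ghq_case(score: int) -> int:
    """Dichotomise a GHQ-30 score at the standard cut-point (>= 5 is a case)."""
    if not 0 <= score <= 30:
        raise CodingError(f"GHQ-30 score {score} out of range [0, 30]")
    return int(score >= GHQ_CASE_CUTPOINT)


def derive_morbidity(flags: Sequence[int]) -> int:
    """1 if any of the six chronic-condition flags is set, else 0."""
    if len(flags) != 6:
        raise CodingError(f"expected six chronic-condition flags, got {len(flags)}")
    return int(any(int(f) == 1 for f in flags))


def tertile_encode(values: Sequence[float]) -> List[str]:
    """Label values T1/T2/T3 by the empirical 1/3 and 2/3 quantiles.

    Ties at a boundary fall into the lower tertile.  Requires at least three
    distinct values.
    """
    arr = np.asarray(values, dtype=float)
    if np.unique(arr).size < 3:
        raise CodingError("tertile encoding needs >= 3 distinct values")
    q1, q2 = np.quantile(arr, [1.0 / 3.0, 2.0 / 3.0])
    return ["T1" if x <= q1 else ("T2" if x <= q2 else "T3") for x in arr]


def standardize(values: Sequence[float]) -> np.ndarray:
    """z-scores (x - mean) / sd with the sample (n-1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    sd = arr.std(ddof=1)
    if not sd > 0:
        raise CodingError("cannot standardize a constant vector (sd = 0)")
    return (arr - arr.mean()) / sd


# ---------------------------------------------------------------------------
# Design assembly


@dataclass
class ExposureTable:
    """Per-respondent analysis table plus the covariate list and manifest."""

    df: pd.DataFrame               # columns: case, area_id, <covariates>
    covariates: List[str]
    manifest: Dict[str, Dict[str, str]]
    n_dropped: int = 0

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def write_manifest(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _dummies(
    series: pd.Series, levels: Sequence[str], reference: str, prefix: str,
    manifest: Dict[str, Dict[str, str]],
) -> pd.DataFrame:
    observed = set(series.dropna().unique())
    unknown = observed - set(levels)
    if unknown:
        raise CodingError(f"{prefix}: unknown levels {sorted(unknown)}")
    if reference not in observed:
        raise CodingError(
            f"{prefix}: reference level {reference!r} absent from the data"
        )
    out = {}
    for lev in levels:
        if lev == reference or lev not in observed:
            # unobserved levels would give an all-zero (singular) column
            continue
        col = f"{prefix}_{lev}".replace("+", "plus")
        out[col] = (series == lev).astype(float)
        manifest[col] = {
            "transform": "indicator", "level": lev, "reference": reference,
            "source": prefix,
        }
    return pd.DataFrame(out, index=series.index)


_SYNTAX_Z = {
    gm.COL_MP1200: "mp_r1200_z",
    gm.COL_MP3000: "mp_r3000_z",
    gm.COL_MPGLOBAL: "mp_rglobal_z",
    gm.COL_CONNECTIVITY: "connectivity_z",
}
_DENSITY_COLS = {
    gm.COL_DENSITY["bus_stops"]: "dens_bus_stops",
    gm.COL_DENSITY["retail"]: "dens_retail",
    gm.COL_DENSITY["community_services"]: "dens_community_services",
    gm.COL_DENSITY["recreation_leisure"]: "dens_recreation_leisure",
    gm.COL_DENSITY["business_offices"]: "dens_business_offices",
}

INDIVIDUAL_COVARIATES = (
    "age", "alcohol",
    "social_class_III_manual", "social_class_IV_V",
    "education_school_certificate", "education_professional_degree",
    "morbidity",
)


def assemble_design(
    respondents: pd.DataFrame,
    morphometrics: pd.DataFrame,
    model_id: int,
    include_lum: bool = True,
    include_individual: bool = True,
) -> ExposureTable:
    """Join respondents to their dwelling morphometrics and build the design
    table for Model 1, 2 or 3.

    Rows with any missing value among the model's inputs are dropped
    (listwise deletion) before tertile and z-score transforms, so every
    z-scored column has mean 0 and sd 1 over the analysis sample.  The
    returned manifest documents the transform and reference level of every
    output column.
    """
    if model_id not in (1, 2, 3):
        raise CodingError(f"unknown model_id {model_id!r}; expected 1, 2 or 3")
    if WIMD_EXCLUDED in respondents.columns:
        raise CodingError(
            f"column {WIMD_EXCLUDED!r} must not be supplied: the 'access to "
            "services' deprivation domain is excluded (collinear with the "
            "street-accessibility measures)"
        )

    resp = respondents.copy()
    morph = morphometrics
    orphans = sorted(set(resp["dwelling_id"]) - set(morph.index))
    if orphans:
        raise CodingError(f"respondents reference unknown dwelling ids: {orphans[:10]}")
    merged = resp.join(morph, on="dwelling_id")

    needed: List[str] = ["ghq30", "area_id", "dwelling_id"]
    if include_individual:
        needed += ["age", "alcohol", "social_class", "education", *CHRONIC_FLAGS]
    built = model_id in (1, 3)
    area = model_id in (2, 3)
    if built:
        needed += list(gm.BUILT_ENV_COLUMNS) if include_lum else [
            c for c in gm.BUILT_ENV_COLUMNS if c != gm.COL_LUM
        ]
    if area:
        needed += [gm.COL_SLOPE_SD, gm.COL_NDVI, *WIMD_DOMAINS]
    missing_cols = [c for c in needed if c not in merged.columns]
    if missing_cols:
        raise CodingError(f"missing input columns: {missing_cols}")

    n0 = len(merged)
    data = merged.dropna(subset=list(dict.fromkeys(needed))).copy()
    n_dropped = n0 - len(data)

    manifest: Dict[str, Dict[str, str]] = {}
    out = pd.DataFrame(index=data.index)
    out["case"] = [ghq_case(int(s)) for s in data["ghq30"]]
    manifest["case"] = {"transform": "ghq30 >= 5", "source": "ghq30"}
    out["area_id"] = data["area_id"].values
    covariates: List[str] = []

    def add_z(src: str, name: str):
        out[name] = standardize(data[src].astype(float).values)
        manifest[name] = {"transform": "z-score (sample sd)", "source": src}
        covariates.append(name)

    def add_raw(src: str, name: str, unit: str = ""):
        out[name] = data[src].astype(float).values
        manifest[name] = {"transform": "identity", "source": src, "units": unit}
        covariates.append(name)

    if built:
        add_raw(gm.COL_DWELLING_DENSITY, "dwelling_density", "count within 30 m")
        for block, levels, ref, prefix in (
            (gm.COL_DWELLING_TYPE, ("detached", "semi_detached", "terraced", "flat"),
             "detached", "dwelling_type"),
            (gm.COL_PLOT_EXPOSURE, ("0", "1", "2+"), "1", "plot_exposure"),
        ):
            # CSV round-trips can parse "0"/"1" exposure levels as integers
            dm = _dummies(data[block].astype(str), levels, ref, prefix, manifest)
            for c in dm.columns:
                out[c] = dm[c]
                covariates.append(c)
        if include_lum:
            tert = tertile_encode(data[gm.COL_LUM].astype(float).values)
            for lab in ("T2", "T3"):
                col = f"lum_{lab}"
                out[col] = [1.0 if t == lab else 0.0 for t in tert]
                manifest[col] = {
                    "transform": "tertile indicator", "level": lab,
                    "reference": "T1", "source": gm.COL_LUM,
                }
                covariates.append(col)
        for src, name in _DENSITY_COLS.items():
            add_raw(src, name, "count per km^2")
        for src, name in _SYNTAX_Z.items():
            add_z(src, name)
    if area:
        add_z(gm.COL_SLOPE_SD, "slope_sd_z")
        add_z(gm.COL_NDVI, "ndvi_z")
        for dom in WIMD_DOMAINS:
            add_raw(dom, dom, "domain score 0-100")

    if include_individual:
        add_raw("age", "age", "years")
        add_raw("alcohol", "alcohol", "ml/week")
        sc = data["social_class"].map(SOCIAL_CLASS_COLLAPSE)
        bad = data.loc[sc.isna(), "social_class"].unique()
        if len(bad):
            raise CodingError(f"social_class: unknown groups {sorted(bad)}")
        dm = _dummies(sc, SOCIAL_CLASS_LEVELS, SOCIAL_CLASS_LEVELS[0],
                      "social_class", manifest)
        for c in dm.columns:
            out[c] = dm[c]
            covariates.append(c)
        dm = _dummies(data["education"], EDUCATION_LEVELS, EDUCATION_LEVELS[0],
                      "education", manifest)
        for c in dm.columns:
            out[c] = dm[c]
            covariates.append(c)
        out["morbidity"] = [
            derive_morbidity([row[f] for f in CHRONIC_FLAGS])
            for _, row in data.iterrows()
        ]
        manifest["morbidity"] = {
            "transform": "any of " + ", ".join(CHRONIC_FLAGS), "source": "chronic flags"
        }
        covariates.append("morbidity")

    out = out.reset_index(drop=True)
    return ExposureTable(
        df=out, covariates=covariates, manifest=manifest, n_dropped=n_dropped
    )


def model_covariates(model_id: int, include_lum: bool = True) -> List[str]:
    """The fixed covariate list of each model (predictor blocks only)."""
    built = [
        "dwelling_density",
        "dwelling_type_semi_detached", "dwelling_type_terraced", "dwelling_type_flat",
        "plot_exposure_0", "plot_exposure_2plus",
        *(["lum_T2", "lum_T3"] if include_lum else []),
        "dens_bus_stops", "dens_retail", "dens_community_services",
        "dens_recreation_leisure", "dens_business_offices",
        "mp_r1200_z", "mp_r3000_z", "mp_rglobal_z", "connectivity_z",
    ]
    areal = ["slope_sd_z", "ndvi_z", *WIMD_DOMAINS]
    if model_id == 1:
        return built
    if model_id == 2:
        return areal
    if model_id == 3:
        return built + areal
    raise CodingError(f"unknown model_id {model_id!r}")
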