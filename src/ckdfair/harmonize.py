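"""Cohort harmonization and fold-safe preprocessing.

Turns raw cohort rows into model-ready feature matrices: kidney function is
recomputed from serum creatinine with the race-free CKD-EPI 2021 equation,
UACR (and plasma biomarkers, when used) are log-transformed, implausible lab
values are winsorized to fixed physiologic bounds, missing continuous values
are mean-imputed, and continuous features are centered and scaled.  Scaling,
imputation and all other statistics are fit within (source cohort x training
fold) only, so nothing computed from a test fold can leak into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EgfrParams",
    "PreprocessorState",
    "ckd_epi_2021",
    "fit_preprocessor",
    "apply_preprocessor",
    "CLINICAL_FEATURES",
    "BIOMARKER_FEATURES",
    "BINARY_FEATURES",
    "DEFAULT_WINSOR_BOUNDS",
]

# The 15-feature clinical set.  Race is never a feature.  Total cholesterol is
# kept in the data model but not in the default feature list (it is nearly
# collinear with LDL/HDL/triglycerides).
CLINICAL_FEATURES = [
    "age", "sex", "egfr_baseline", "log_uacr", "sbp", "dbp",
    "diabetes", "hypertension", "cvd", "hba1c", "glucose",
    "ldl", "hdl", "triglycerides", "hemoglobin",
]
BIOMARKER_FEATURES = CLINICAL_FEATURES + ["log_tnfr1", "log_tnfr2", "log_kim1"]

# Binary indicators pass through untouched (sex coded 1=Female, 0=Male;
# missing comorbidity = absent).
BINARY_FEATURES = frozenset({"sex", "diabetes", "hypertension", "cvd"})

# Fixed physiologic plausibility bounds applied to raw labs before any
# transform; values outside are brought to the nearest boundary.
DEFAULT_WINSOR_BOUNDS = {
    "age": (18.0, 110.0),
    "serum_creatinine": (0.2, 15.0),
    "uacr": (1.0, 10000.0),
    "sbp": (70.0, 250.0),
    "dbp": (30.0, 150.0),
    "hba1c": (3.0, 20.0),
    "glucose": (40.0, 600.0),
    "ldl": (20.0, 400.0),
    "hdl": (10.0, 150.0),
    "triglycerides": (20.0, 1500.0),
    "total_cholesterol": (50.0, 500.0),
    "hemoglobin": (4.0, 22.0),
    "tnfr1": (100.0, 50000.0),
    "tnfr2": (200.0, 100000.0),
    "kim1": (10.0, 20000.0),
}


@dataclass
class EgfrParams:
    """Coefficients of the race-free CKD-EPI 2021 creatinine equation."""

    kappa: dict = field(default_factory=lambda: {"Female": 0.7, "Male": 0.9})
    alpha: dict = field(default_factory=lambda: {"Female": -0.241, "Male": -0.302})
    age_factor: float = 0.9938
    sex_factor: float = 1.012  # multiplier for women
    scale: float = 142.0

    def validate(self) -> None:
        if any(k <= 0 for k in self.kappa.values()) or self.scale <= 0:
            raise ValueError("kappa and scale must be positive")


DEFAULT_EGFR_PARAMS = EgfrParams()


def ckd_epi_2021(scr, age, sex, params: EgfrParams = DEFAULT_EGFR_PARAMS):
    """Estimated GFR (ml/min/1.73m2) from the 2021 race-free CKD-EPI equation.

    ``scr`` in mg/dL, ``age`` in years, ``sex`` as "Male"/"Female" (scalar or
    arrays).  Strictly decreasing in both creatinine and age.
    """
    params.validate()
    scr_arr = np.asarray(scr, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    sex_arr = np.asarray(sex)
    if np.any(scr_arr <= 0):
        raise ValueError("serum creatinine must be positive")
    female = sex_arr == "Female"
    kappa = np.where(female, params.kappa["Female"], params.kappa["Male"])
    alpha = np.where(female, params.alpha["Female"], params.alpha["Male"])
    ratio = scr_arr / kappa
    egfr = (
        params.scale
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.200
        * params.age_factor ** age_arr
        * np.where(female, params.sex_factor, 1.0)
    )
    if np.isscalar(scr) and np.isscalar(age):
        return float(egfr)
    return egfr


@dataclass
class PreprocessorState:
    """Frozen preprocessing statistics, fit on training rows only.

    Per source cohort: imputation means, centering means and scaling SDs for
    each continuous feature.  Binary features pass through.  The state is a
    pure function of the training rows -- applying it never updates it.
    """

    feature_names: list
    winsor_bounds: dict
    impute_values: dict  # source_cohort -> {feature -> mean}
    means: dict          # source_cohort -> {feature -> mean}
    sds: dict            # source_cohort -> {feature -> sd}
    egfr_params: EgfrParams = field(default_factory=EgfrParams)

    @property
    def continuous_features(self) -> list:
        return [f for f in self.feature_names if f not in BINARY_FEATURES]


def _derive_features(rows: pd.DataFrame, feature_names, winsor_bounds,
                     egfr_params) -> pd.DataFrame:
    """Winsorize raw labs, recompute eGFR, log-transform, encode binaries.

    This is the deterministic, state-free part of the pipeline shared by fit
    and apply; the row order of the input is preserved.
    """
    needed_raw = {"serum_creatinine", "age", "sex", "uacr", "source_cohort"}
    for f in feature_names:
        if f == "egfr_baseline":
            continue
        if f.startswith("log_"):
            needed_raw.add(f[4:])
        else:
            needed_raw.add(f)
    missing = sorted(needed_raw - set(rows.columns))
    if missing:
        raise KeyError(f"rows are missing required columns: {missing}")

    raw = rows.copy()
    for col, (lo, hi) in winsor_bounds.items():
        if col in raw.columns:
            raw[col] = raw[col].clip(lo, hi)

    out = pd.DataFrame(index=raw.index)
    for f in feature_names:
        if f == "sex":
            out[f] = (raw["sex"] == "Female").astype(float)
        elif f in BINARY_FEATURES:
            out[f] = raw[f].fillna(0).astype(float)
        elif f == "egfr_baseline":
            out[f] = ckd_epi_2021(
                raw["serum_creatinine"].to_numpy(),
                raw["age"].to_numpy(),
                raw["sex"].to_numpy(),
                egfr_params,
            )
        elif f.startswith("log_"):
            out[f] = np.log(raw[f[4:]].astype(float))
        else:
            out[f] = raw[f].astype(float)
    out["source_cohort"] = raw["source_cohort"]
    return out


def fit_preprocessor(
    training_rows: pd.DataFrame,
    feature_names=CLINICAL_FEATURES,
    winsor_bounds=None,
    egfr_params: EgfrParams = DEFAULT_EGFR_PARAMS,
) -> PreprocessorState:
    """Fit imputation/centering/scaling statistics on training rows only.

    Statistics are computed per source cohort.  A continuous feature with no
    observed value in some training source cohort is an error (named in the
    message); a constant feature is centered but left unscaled (SD 1).
    """
    if len(training_rows) == 0:
        raise ValueError("training rows must be non-empty")
    bounds = dict(DEFAULT_WINSOR_BOUNDS if winsor_bounds is None else winsor_bounds)
    derived = _derive_features(training_rows, feature_names, bounds, egfr_params)

    impute, means, sds = {}, {}, {}
    for source, grp in derived.groupby("source_cohort", sort=True):
        impute[source], means[source], sds[source] = {}, {}, {}
        for f in feature_names:
            if f in BINARY_FEATURES:
                continue
            vals = grp[f].to_numpy(dtype=float)
            observed = vals[~np.isnan(vals)]
            if observed.size == 0:
                raise ValueError(
                    f"feature {f!r} has no observed value in training rows "
                    f"of source cohort {source!r}"
                )
            m = float(observed.mean())
            filled = np.where(np.isnan(vals), m, vals)
            sd = float(filled.std())  # population SD: fit rows scale to SD 1
            if sd <= 0:
                sd = 1.0  # constant feature: center only (sklearn convention)
            impute[source][f] = m
            means[source][f] = float(filled.mean())
            sds[source][f] = sd
    return PreprocessorState(
        feature_names=list(feature_names),
        winsor_bounds=bounds,
        impute_values=impute,
        means=means,
        sds=sds,
        egfr_params=egfr_params,
    )


def apply_preprocessor(state: PreprocessorState, rows: pd.DataFrame) -> pd.DataFrame:
    """Transform rows with frozen training statistics.

    Pipeline order: winsorize -> recompute eGFR -> log transforms -> impute ->
    center/scale.  The output is a numeric feature matrix (indexed by patient
    id when present) with no missing values; ``state`` is never modified.
    """
    derived = _derive_features(
        rows, state.feature_names, state.winsor_bounds, state.egfr_params
    )
    unknown = sorted(set(derived["source_cohort"]) - set(state.means))
    if unknown:
        raise ValueError(
            f"source cohorts {unknown} were not present in the training rows"
        )
    out = derived[state.feature_names].copy()
    for source, grp_idx in derived.groupby("source_cohort", sort=True).groups.items():
        for f in state.continuous_features:
            col = out.loc[grp_idx, f]
            col = col.fillna(state.impute_values[source][f])
            out.loc[grp_idx, f] = (
                (col - state.means[source][f]) / state.sds[source][f]
            )
    if "id" in rows.columns:
        out.index = pd.Index(rows["id"], name="id")
    out = out.astype(float)
    assert not out.isna().any().any()
    return out
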