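"""Synthetic high-grade prostate-cancer cohorts and 3D imaging phantoms.

Real cohorts of this kind (pre-operative clinical variables, one lymph-
node-invasion label, five right-censored time-to-event outcomes whose
typical onset follows the natural history LNI -> BCR -> metastasis ->
dADT -> CRPC -> death) are not publicly depositable, so every other
module in the package is exercised against cohorts drawn from the
generative model implemented here:

* six clinical features: age, PSA, primary/secondary/global Gleason
  (global = primary + secondary, constrained >= 8: the cohort is
  high-grade by construction), and ordinal clinical stage;
* a latent "aggressiveness" z, linear in standardized features plus
  Gaussian noise, that correlates all outcomes;
* LNI drawn from a logistic model on z;
* progression times built cumulatively along the natural history: the
  first survival time (BCR) and each subsequent inter-event gap are
  drawn from Weibull proportional-hazards models whose linear
  predictors combine observed features, z, and an early-event
  indicator of the preceding task (inter-task coupling), so each
  patient's event times are ordered as the disease progresses;
* administrative censoring uniform over a follow-up window.

The generator returns the ground-truth parameters alongside the cohort
so that estimation code can be tested by parameter recovery.  Note that
the global Gleason score is an exact linear combination of the primary
and secondary scores, so per-feature hazard coefficients are only
identifiable on a non-collinear feature subset; the ground-truth record
names that subset (``recovery_features``) and the marginal
coefficients a Cox fit on it estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskEffect", "CohortConfig", "PhantomConfig", "CLINICAL_FEATURES",
    "SURVIVAL_TASKS", "TASKS", "generate_cohort", "generate_phantom",
    "mask_missing", "impute_missing", "standardize_clinical",
]

CLINICAL_FEATURES = ["age", "psa", "gleason_primary", "gleason_secondary",
                     "gleason_global", "clinical_stage"]
#: non-collinear subset on which hazard coefficients are identifiable
RECOVERY_FEATURES = ["age", "psa", "gleason_global", "clinical_stage"]
SURVIVAL_TASKS = ["bcr", "mfs", "dadt", "crpc", "pcss"]
TASKS = ["lni"] + SURVIVAL_TASKS

# high-grade Gleason pairs (primary, secondary) with global >= 8
_GLEASON_PAIRS = [(3, 5), (4, 4), (4, 5), (5, 3), (5, 4), (5, 5)]
_GLEASON_PROBS = [0.15, 0.30, 0.20, 0.10, 0.15, 0.10]
_STAGE_PROBS = [0.35, 0.35, 0.20, 0.10]     # cT1..cT4 ordinal 1..4


@dataclass(frozen=True)
class TaskEffect:
    """Log-hazard (or log-odds) coefficients of one task's linear predictor."""

    features: tuple = (0.0,) * 6   # on the six standardized clinical features
    latent: float = 0.8            # on the latent aggressiveness z
    prev: float = 0.8              # on the previous task's early-event indicator

    def scaled(self, c: float) -> "TaskEffect":
        return TaskEffect(tuple(c * f for f in self.features),
                          c * self.latent, c * self.prev)


def _default_effects() -> dict:
    eff = {t: TaskEffect() for t in SURVIVAL_TASKS}
    # BCR has no causal link from the LNI label beyond the shared latent
    eff["bcr"] = TaskEffect(prev=0.0)
    return eff


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the synthetic cohort."""

    n_patients: int = 250
    seed: int = 0
    #: Weibull time scales (months): the first survival time (BCR), then
    #: one inter-event gap per subsequent task along the natural history
    base_rates: tuple = (36.0, 30.0, 40.0, 50.0, 60.0)
    weibull_shape: float = 1.2
    censor_window: tuple = (24.0, 120.0)
    effects: dict = field(default_factory=_default_effects)
    #: latent z = latent_weights . x_std(recovery features) + noise
    latent_weights: tuple = (0.6, 0.9, 0.75, 0.6)
    latent_noise_sd: float = 0.3
    lni_intercept: float = -1.2
    lni_slope: float = 1.5

    def __post_init__(self):
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if any(b <= 0 for b in self.base_rates):
            raise ValueError("event-time scales must be positive")
        if len(self.base_rates) != len(SURVIVAL_TASKS):
            raise ValueError("one base rate per survival task")
        for t, e in self.effects.items():
            if len(e.features) != len(CLINICAL_FEATURES):
                raise ValueError(f"effect vector for {t} has wrong length")

    def with_zero_effects(self) -> "CohortConfig":
        """All outcome-model coefficients zeroed: outcomes independent of z."""
        zero = {t: e.scaled(0.0) for t, e in self.effects.items()}
        return replace(self, effects=zero, lni_slope=0.0)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "effects" in raw:
            raw["effects"] = {t: TaskEffect(**v) for t, v in raw["effects"].items()}
        for key in ("base_rates", "censor_window", "latent_weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def standardize_clinical(df: pd.DataFrame, ref: pd.DataFrame | None = None,
                         features=CLINICAL_FEATURES) -> np.ndarray:
    """Z-normalize clinical features (ordinal ones included, after encoding)."""
    ref = df if ref is None else ref
    x = df[list(features)].to_numpy(float)
    mu = ref[list(features)].to_numpy(float).mean(axis=0)
    sd = ref[list(features)].to_numpy(float).std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def generate_cohort(config: CohortConfig):
    """Draw a cohort table plus the ground-truth parameter record.

    Returns ``(cohort, truth)`` where `cohort` has one row per patient
    (features, ``lni_label`` and per-survival-task ``<task>_event`` /
    ``<task>_time`` columns in months) and `truth` records z, the
    generator coefficients and the identifiable marginal coefficients.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    age = rng.normal(66.0, 7.0, n)
    psa = np.exp(rng.normal(np.log(15.0), 0.6, n))
    pairs = rng.choice(len(_GLEASON_PAIRS), size=n, p=_GLEASON_PROBS)
    gp = np.array([_GLEASON_PAIRS[k][0] for k in pairs], float)
    gs = np.array([_GLEASON_PAIRS[k][1] for k in pairs], float)
    stage = rng.choice([1, 2, 3, 4], size=n, p=_STAGE_PROBS).astype(float)
    df = pd.DataFrame({
        "id": [f"P{i:05d}" for i in range(n)],
        "age": age, "psa": psa, "gleason_primary": gp,
        "gleason_secondary": gs, "gleason_global": gp + gs,
        "clinical_stage": stage,
    })

    x_rec = standardize_clinical(df, features=RECOVERY_FEATURES)
    w = np.asarray(config.latent_weights, float)
    noise = rng.normal(0.0, 1.0, n)
    z = x_rec @ w + config.latent_noise_sd * noise

    lni_p = _sigmoid(config.lni_intercept + config.lni_slope * z)
    lni = (rng.uniform(size=n) < lni_p).astype(int)
    df["lni_label"] = lni

    x_all = standardize_clinical(df, features=CLINICAL_FEATURES)
    shape = config.weibull_shape
    censor = rng.uniform(*config.censor_window, size=n)
    prev_early = lni.astype(float)
    true_times = {}
    t_cum = np.zeros(n)
    cum_scale = 0.0
    for task, scale in zip(SURVIVAL_TASKS, config.base_rates):
        eff = config.effects[task]
        eta = (x_all @ np.asarray(eff.features, float)
               + eff.latent * z + eff.prev * prev_early)
        e_std = rng.exponential(size=n)
        gap = scale * (e_std / np.exp(eta)) ** (1.0 / shape)
        t_true = t_cum + gap          # progression: events occur in sequence
        true_times[task] = t_true
        event = t_true <= censor
        df[f"{task}_event"] = event.astype(int)
        df[f"{task}_time"] = np.maximum(np.where(event, t_true, censor), 1e-3)
        # early-event indicator feeding the next task's hazard
        cum_scale += scale
        prev_early = (t_true < 0.5 * cum_scale).astype(float)
        t_cum = t_true

    marginal = {}
    for task in SURVIVAL_TASKS:
        eff = config.effects[task]
        b = np.asarray(eff.features, float)
        # map the 6-feature direct effects onto the recovery subset; defaults use 0
        b_rec = np.array([b[CLINICAL_FEATURES.index(f)] for f in RECOVERY_FEATURES])
        marginal[task] = dict(zip(RECOVERY_FEATURES, b_rec + eff.latent * w))

    truth = {
        "z": z, "latent_weights": w, "latent_noise_sd": config.latent_noise_sd,
        "effects": config.effects, "true_times": true_times,
        "recovery_features": list(RECOVERY_FEATURES),
        "marginal_coefficients": marginal,
        "censoring_times": censor,
    }
    return df, truth


# -- missingness and imputation ---------------------------------------------

def mask_missing(cohort: pd.DataFrame, columns, fraction: float,
                 seed: int = 0) -> pd.DataFrame:
    """Blank a random `fraction` of entries in the given feature columns."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for col in columns:
        mask = rng.uniform(size=len(out)) < fraction
        out.loc[mask, col] = np.nan
    return out


_ORDINAL_VALUES = {
    "gleason_primary": [3, 4, 5],
    "gleason_secondary": [3, 4, 5],
    "gleason_global": [8, 9, 10],
    "clinical_stage": [1, 2, 3, 4],
}


def impute_missing(cohort: pd.DataFrame, seed: int = 0,
                   n_sweeps: int = 10) -> pd.DataFrame:
    """Round-robin iterative imputation with a random-forest regressor.

    Each incomplete feature column is regressed on the others over a
    fixed column order for `n_sweeps` sweeps; observed entries are left
    untouched and ordinal columns are snapped back onto their valid
    value sets.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.impute import IterativeImputer

    cols = [c for c in CLINICAL_FEATURES if c in cohort.columns]
    block = cohort[cols]
    for c in cols:
        if block[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing")
    if not block.isna().any().any():
        return cohort.copy()
    imputer = IterativeImputer(
        estimator=RandomForestRegressor(n_estimators=25, random_state=seed),
        max_iter=n_sweeps, imputation_order="roman", random_state=seed,
        sample_posterior=False, tol=0.0,
    )
    filled = imputer.fit_transform(block.to_numpy(float))
    out = cohort.copy()
    out[cols] = filled
    for c, valid in _ORDINAL_VALUES.items():
        if c in out.columns:
            valid = np.asarray(valid, float)
            vals = out[c].to_numpy(float)
            out[c] = valid[np.abs(vals[:, None] - valid[None, :]).argmin(axis=1)]
    # observed entries are authoritative
    observed = block.notna().to_numpy()
    restored = np.where(observed, block.to_numpy(float), out[cols].to_numpy(float))
    out[cols] = restored
    return out


# -- 3D phantoms -------------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """An ellipsoidal organ in a noisy CT/PET-like grid."""

    grid_shape: tuple = (32, 32, 32)
    voxel_size_mm: float = 2.0
    center_mm: tuple | None = None          # defaults to the grid center
    semi_axes_mm: tuple = (14.0, 11.0, 9.0)
    ct_inside: tuple = (45.0, 15.0)         # mean, sd in HU
    ct_outside: tuple = (0.0, 20.0)
    pet_inside: tuple = (2.0, 0.2)          # mean, sd in activity units
    pet_outside: tuple = (1.0, 0.2)
    lesion_uptake: float = 2.0              # PET hot-spot amplitude per unit z
    aggressiveness: float = 0.0             # the patient's latent z
    seed: int = 0


def generate_phantom(config: PhantomConfig):
    """Rasterize the phantom; returns (ct, pet, mask) float/uint8 arrays.

    The PET mean inside the organ is raised by ``lesion_uptake * z`` so
    that image intensity carries the prognostic signal the imaging arm
    is meant to learn.  The mask rasterization is deterministic; only
    the additive noise depends on the seed.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    vs = config.voxel_size_mm
    extent = np.array(shape, float) * vs
    center = (np.asarray(config.center_mm, float) if config.center_mm is not None
              else extent / 2.0)
    axes = np.asarray(config.semi_axes_mm, float)
    if np.any(center - axes < 0) or np.any(center + axes > extent):
        raise ValueError("organ extends outside the grid")

    coords = np.stack(np.meshgrid(*[(np.arange(s) + 0.5) * vs for s in shape],
                                  indexing="ij"))
    dist2 = sum(((coords[i] - center[i]) / axes[i]) ** 2 for i in range(3))
    mask = (dist2 <= 1.0).astype(np.uint8)

    inside = mask.astype(bool)
    ct = rng.normal(*config.ct_outside, size=shape)
    ct[inside] = rng.normal(*config.ct_inside, size=int(inside.sum()))
    pet = rng.normal(*config.pet_outside, size=shape)
    pet_mu = config.pet_inside[0] + config.lesion_uptake * config.aggressiveness
    pet[inside] = rng.normal(pet_mu, config.pet_inside[1], size=int(inside.sum()))
    return ct, pet, mask
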