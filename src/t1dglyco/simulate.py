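"""Synthetic sibling-pair cohort generator.

Emulates a family-based case-control glycomics cohort: each family has one
affected proband and one to five unaffected siblings, samples are spread
over multiwell plates (batches), and peak areas follow a multiplicative
model on the raw scale, i.e. an additive model on log-areas::

    log area[i, j] = baseline[j] + u[family(i)] + g[batch(i), j]
                     + sex_effect[j] * male(i) + age_slope[j] * age(i)
                     + disease_effect[j] * status(i) + eps[i, j]

with family random intercept u ~ N(0, family_intercept_sd^2), per
batch-and-peak location shift g ~ N(0, batch_shift_sd^2) and Gaussian
residual eps.  Because batch effects are additive on the log scale, the
empirical-Bayes batch correction downstream is operating under exactly the
model it assumes, which keeps its tests sharp.

Autoantibody levels for affected children are log-normal, right-censored at
an upper limit of quantification (LOQ): the recorded level is
``min(c, LOQ)`` and the indicator ``I`` is 1 when the latent level c is
below the LOQ.  A designated peak's log-area receives ``+ b1 * c`` when
c < LOQ and ``+ b2`` otherwise, which is the inverse of the censored
regression model the association stage fits, so that (b0, b1, b2) are
recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import PeakTable, SampleMetadata

__all__ = [
    "AutoantibodyParams",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_autoantibodies",
    "plasma_disease_effect",
]

#: Default distribution of the number of unaffected siblings per family
#: (1..5).  Mean ~1.30, so 188 families yield ~244 unaffected siblings,
#: matching a registry in which most probands have a single sampled sibling.
DEFAULT_SIBLING_PROBS = (0.76, 0.18, 0.04, 0.015, 0.005)


@dataclass
class AutoantibodyParams:
    """Generative parameters for one autoantibody assay.

    ``log_mean``/``log_sd`` parameterize the latent log-normal level,
    ``loq`` is the upper limit of quantification, ``b1`` is the slope
    linking a below-LOQ level to the designated peak's log-area and ``b2``
    the constant offset applied when the level is at or above the LOQ.
    """

    name: str = "ZnT8R"
    log_mean: float = 0.5
    log_sd: float = 0.8
    loq: float = 2.5
    b1: float = 0.0
    b2: float = 0.0
    target_peak: str = "GP1"

    def __post_init__(self) -> None:
        if self.loq <= 0:
            raise ValueError(f"LOQ must be positive, got {self.loq}")
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")


@dataclass
class SimulationConfig:
    """Configuration of the synthetic cohort generator.

    All effect vectors are on the log-area scale and must have length
    ``n_peaks``; ``None`` means a zero vector.
    """

    n_families: int = 188
    sibling_probs: tuple = DEFAULT_SIBLING_PROBS
    n_peaks: int = 39
    n_batches: int = 5
    batch_shift_sd: float = 0.2
    family_intercept_sd: float = 0.3
    residual_sd: float = 0.25
    disease_effect: np.ndarray | None = None
    sex_effect: np.ndarray | None = None
    age_slope: np.ndarray | None = None
    baseline: np.ndarray | None = None
    age_range: tuple = (0.6, 19.1)
    autoantibody_params: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 2:
            raise ValueError("n_peaks must be >= 2")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("batch_shift_sd", "family_intercept_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        probs = np.asarray(self.sibling_probs, dtype=float)
        if probs.ndim != 1 or len(probs) < 1 or np.any(probs < 0):
            raise ValueError("sibling_probs must be nonnegative")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("sibling_probs must sum to 1")
        for name in ("disease_effect", "sex_effect", "age_slope", "baseline"):
            vec = getattr(self, name)
            if vec is None:
                continue
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.n_peaks,):
                raise ValueError(
                    f"{name} must have length n_peaks={self.n_peaks}, "
                    f"got shape {vec.shape}"
                )
            setattr(self, name, vec)

    @property
    def peak_ids(self) -> list:
        return [f"GP{j + 1}" for j in range(self.n_peaks)]

    def effective_baseline(self) -> np.ndarray:
        """Baseline log-areas; default is a smooth geometric decay.

        Chosen so that on the percent scale the largest peaks carry roughly
        ten times the share of the smallest, as in a real chromatogram where
        a few major peaks dominate.
        """
        if self.baseline is not None:
            return self.baseline
        j = np.arange(self.n_peaks)
        return 3.0 - 2.3 * j / max(self.n_peaks - 1, 1)


@dataclass
class SyntheticCohort:
    """A simulated cohort: raw peak areas, metadata and the ground truth."""

    peak_table: PeakTable
    metadata: SampleMetadata
    truth: dict

    def __post_init__(self) -> None:
        meta = self.metadata.table
        by_family = meta.groupby("family_id")["status"]
        if not (by_family.max() == 1).all():
            raise ValueError("every family must contain >= 1 affected member")
        if np.any(self.peak_table.values.to_numpy() <= 0):
            raise ValueError("raw areas must be strictly positive")


def _vector(v: np.ndarray | None, n: int) -> np.ndarray:
    return np.zeros(n) if v is None else np.asarray(v, dtype=float)


def plasma_disease_effect(magnitude: float = 0.2) -> np.ndarray:
    """A disease-onset effect profile for the 39-peak plasma panel.

    Log-scale shifts on the peaks that change at type 1 diabetes onset:
    increases in the bisected (GP2, GP17, GP23), high-mannose (GP7, GP12)
    and sialylated (GP21, GP22, GP25, GP29) peaks, decreases in the
    monogalactosylated (GP4, GP5) and digalactosylated neutral (GP10)
    peaks.  ``magnitude`` sets the common absolute shift; the default 0.2
    log-units against a residual + family SD of ~0.4 gives per-peak
    standardized effects of ~0.5 SD, the order of magnitude implied by
    per-SD odds ratios between roughly 0.6 and 2.
    """
    effect = np.zeros(39)
    up = [2, 7, 12, 17, 21, 22, 23, 25, 29]
    down = [4, 5, 10]
    for gp in up:
        effect[gp - 1] = magnitude
    for gp in down:
        effect[gp - 1] = -magnitude
    return effect


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a family-based cohort of raw glycan peak areas.

    Deterministic given ``config.seed``.  Each family consists of one
    affected proband plus a random number of unaffected siblings; ages are
    uniform over ``config.age_range``, sexes Bernoulli(0.5), batches
    assigned round-robin over plates in sample order.
    """
    rng = np.random.default_rng(config.seed)
    n_sibs = rng.choice(
        np.arange(1, len(config.sibling_probs) + 1),
        size=config.n_families,
        p=np.asarray(config.sibling_probs, dtype=float),
    )

    rows = []
    for f in range(config.n_families):
        rows.append((f"FAM{f:04d}", 1))
        for _ in range(n_sibs[f]):
            rows.append((f"FAM{f:04d}", 0))
    n = len(rows)
    family = np.array([r[0] for r in rows])
    status = np.array([r[1] for r in rows], dtype=int)
    sample_id = np.array([f"S{i:05d}" for i in range(n)])
    age = rng.uniform(*config.age_range, size=n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    male = (sex == "M").astype(float)
    batch = np.array([f"plate{i % config.n_batches + 1}" for i in range(n)])

    p = config.n_peaks
    fam_codes, fam_index = np.unique(family, return_inverse=True)
    u = rng.normal(0.0, config.family_intercept_sd, size=len(fam_codes))
    g = rng.normal(0.0, config.batch_shift_sd, size=(config.n_batches, p))
    batch_index = np.arange(n) % config.n_batches

    log_area = (
        config.effective_baseline()[None, :]
        + u[fam_index, None]
        + g[batch_index, :]
        + male[:, None] * _vector(config.sex_effect, p)[None, :]
        + age[:, None] * _vector(config.age_slope, p)[None, :]
        + status[:, None] * _vector(config.disease_effect, p)[None, :]
        + rng.normal(0.0, config.residual_sd, size=(n, p))
    )

    peaks = PeakTable(
        values=pd.DataFrame(np.exp(log_area), index=sample_id, columns=config.peak_ids),
        state="raw",
    )
    peaks.values.index.name = "sample_id"
    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_id,
                "family_id": family,
                "sex": sex,
                "age": age,
                "status": status,
                "batch": batch,
            }
        )
    )
    truth = {
        "seed": config.seed,
        "n_families": config.n_families,
        "n_samples": n,
        "family_intercept_sd": config.family_intercept_sd,
        "batch_shift_sd": config.batch_shift_sd,
        "residual_sd": config.residual_sd,
        "disease_effect": _vector(config.disease_effect, p).tolist(),
        "sex_effect": _vector(config.sex_effect, p).tolist(),
        "age_slope": _vector(config.age_slope, p).tolist(),
        "baseline": config.effective_baseline().tolist(),
        "batch_shifts": g.tolist(),
    }
    return SyntheticCohort(peak_table=peaks, metadata=metadata, truth=truth)


def simulate_autoantibodies(
    metadata: SampleMetadata,
    peak_table: PeakTable,
    config: SimulationConfig,
) -> tuple[SampleMetadata, PeakTable]:
    """Add right-censored autoantibody levels for affected samples.

    For every assay in ``config.autoantibody_params`` the latent level c is
    log-normal; the recorded level is ``min(c, LOQ)`` with indicator column
    ``<assay>_below_loq`` = 1 iff c < LOQ.  The designated peak's raw area
    is multiplied by ``exp(b1 * c)`` when c < LOQ and by ``exp(b2)``
    otherwise, i.e. its log-area follows the censored regression model.

    Returns updated copies of both the metadata and the peak table (the
    peak table changes because the designated glycan responds to the
    level).  Only affected samples receive levels; unaffected siblings get
    missing values, as autoantibody panels are run on diagnosed children.
    """
    peak_table.require_state("raw")
    if not config.autoantibody_params:
        raise ValueError("config.autoantibody_params is empty")
    meta = metadata.table.copy()
    values = peak_table.values.copy()
    affected = meta["status"].to_numpy() == 1
    if not affected.any():
        raise ValueError("no affected samples present")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xAB]))

    for params in config.autoantibody_params:
        if params.target_peak not in values.columns:
            raise ValueError(f"designated peak {params.target_peak!r} not in table")
        n_aff = int(affected.sum())
        latent = rng.lognormal(params.log_mean, params.log_sd, size=n_aff)
        below = latent < params.loq
        recorded = np.minimum(latent, params.loq)

        level = np.full(len(meta), np.nan)
        level[affected] = recorded
        flag = np.full(len(meta), np.nan)
        flag[affected] = below.astype(float)
        meta[f"{params.name}_level"] = level
        meta[f"{params.name}_below_loq"] = flag
        meta[f"{params.name}_loq"] = params.loq

        shift = np.where(below, params.b1 * latent, params.b2)
        col = values.columns.get_loc(params.target_peak)
        values.iloc[np.flatnonzero(affected), col] *= np.exp(shift)

    return SampleMetadata(meta), PeakTable(values=values, state="raw")
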