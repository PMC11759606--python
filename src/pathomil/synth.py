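"""Synthetic cohort generator for the weakly supervised pathomics pipeline.

Emulates, at configurable desk scale, the statistical structure the pipeline
assumes about a breast-cancer slide cohort:

* each slide has a binary ER (luminal) status label;
* each tile carries a latent class likelihood drawn from a Beta distribution
  whose shape depends on the slide label, and the tile image is painted so that
  simple image statistics (dark nucleus-like blob density, an eosin-like hue
  shift) are monotone in that latent likelihood — so both a trivial intensity
  feature and a small trainable network can recover it;
* the metastasis label follows a logistic model on slide-level summaries of
  the latent likelihoods;
* right-censored survival times follow an exponential (optionally Weibull)
  hazard with a linear predictor over (planted risk score, age, Ki-67), with
  independent censoring calibrated to a target rate.

All randomness flows from the single ``seed`` in :class:`CohortConfig`;
identical (config, seed) pairs are bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

# Painted palette (frozen design, see docs/methods.md): pink stroma base,
# purple nucleus blobs. Blob count ~ Poisson(2 + 55 p) with radius U(3, 6) px.
_BASE_RGB = np.array([232.0, 186.0, 212.0])
_BLOB_RGB = np.array([90.0, 60.0, 130.0])
_HUE_SHIFT = np.array([25.0, 35.0, 0.0])  # subtracted, scaled by latent p
_BASE_NOISE_SD = 6.0
_BLOB_NOISE_SD = 8.0
_BLOB_COUNT_BASE = 2.0
_BLOB_COUNT_SLOPE = 55.0


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``metastasis_logit_coefs`` applies to (1, mean latent likelihood, sd of
    latent likelihood) per slide; ``hazard_coefs`` applies to (planted risk
    score, standardized age, Ki-67 fraction).  ``baseline_median_months`` sets
    the baseline (linear predictor 0) median survival time.
    """

    n_patients: int = 120
    tiles_per_slide: int = 100
    er_prevalence: float = 0.5
    likelihood_beta_pos: tuple[float, float] = (8.0, 2.0)
    likelihood_beta_neg: tuple[float, float] = (2.0, 8.0)
    metastasis_logit_coefs: tuple[float, ...] = (-4.0, 8.0, 0.0)
    censoring_rate: float = 0.3
    hazard_coefs: tuple[float, float, float] = (1.0, 0.3, 0.5)
    seed: int = 0
    tile_size: int = 512
    weibull_shape: float = 1.0
    baseline_median_months: float = 60.0
    train_fraction: float = 0.7

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        if self.tiles_per_slide <= 0:
            raise ValueError(f"tiles_per_slide must be positive, got {self.tiles_per_slide}")
        if self.tile_size < 16:
            raise ValueError("tile_size must be >= 16")
        if not 0.0 <= self.er_prevalence <= 1.0:
            raise ValueError("er_prevalence must be a probability")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        for pair in (self.likelihood_beta_pos, self.likelihood_beta_neg):
            a, b = pair
            if not (0 < a < math.inf and 0 < b < math.inf):
                raise ValueError(f"Beta shapes must be finite and positive, got {pair}")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def null_config(base: CohortConfig | None = None, **overrides) -> CohortConfig:
    """The no-signal cohort: equal Beta shapes for both ER classes AND zero
    slide-feature weight in the metastasis model (labels are fair coin flips).

    Equalizing only the Beta shapes is not a full null for the metastasis
    task — the label would still lean on the slide's mean latent likelihood —
    so the null condition zeroes that dependence explicitly.
    """
    base = base or CohortConfig()
    return dataclasses.replace(
        base,
        likelihood_beta_pos=(2.0, 2.0),
        likelihood_beta_neg=(2.0, 2.0),
        metastasis_logit_coefs=(0.0, 0.0, 0.0),
        **overrides,
    )


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort: manifest, tile images, latent truth, survival."""

    config: CohortConfig
    manifest: pd.DataFrame           # slide_id, patient_id, er_label, metastasis_label, split
    tiles: dict[str, np.ndarray]     # slide_id -> (n_tiles, ts, ts, 3) uint8
    tile_coords: dict[str, np.ndarray]  # slide_id -> (n_tiles, 2) int (row, col)
    patch_truth: pd.DataFrame        # slide_id, row, col, latent_likelihood
    survival: pd.DataFrame           # patient_id, time_months, event, age, ki67, risk_score


def _paint_tile(p: float, rng: np.random.Generator, ts: int) -> np.ndarray:
    """Paint one tile whose blob density and hue shift are monotone in ``p``."""
    img = _BASE_RGB + rng.normal(0.0, _BASE_NOISE_SD, (ts, ts, 3))
    img -= _HUE_SHIFT * p
    n_blobs = rng.poisson(_BLOB_COUNT_BASE + _BLOB_COUNT_SLOPE * p)
    # blob density is defined per 64x64 px; scale with tile area
    n_blobs = int(round(n_blobs * (ts / 64) ** 2))
    yy, xx = np.mgrid[0:ts, 0:ts]
    for _ in range(n_blobs):
        cy = rng.uniform(2, ts - 2)
        cx = rng.uniform(2, ts - 2)
        r = rng.uniform(3.0, 6.0)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 < r**2
        img[mask] = _BLOB_RGB + rng.normal(0.0, _BLOB_NOISE_SD, 3)
    return np.clip(img, 0, 255).astype(np.uint8)


def _grid_shape(n_tiles: int) -> tuple[int, int]:
    n_cols = int(math.ceil(math.sqrt(n_tiles)))
    n_rows = int(math.ceil(n_tiles / n_cols))
    return n_rows, n_cols


def _calibrate_censoring(event_times: np.ndarray, censor_u: np.ndarray, target: float) -> np.ndarray:
    """Censoring times C = -ln(u)/mu with mu bisected so P(C < T) hits ``target``.

    Censoring is independent of covariates (u drawn independently); only the
    overall rate is calibrated against the realized event-time sample.
    """
    if target <= 0:
        return np.full_like(event_times, np.inf)
    log_u = -np.log(censor_u)

    def realized(mu: float) -> float:
        return float(np.mean(log_u / mu < event_times))

    lo, hi = 1e-8, 1.0
    while realized(hi) < target and hi < 1e6:
        hi *= 10.0
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    return log_u / math.sqrt(lo * hi)


def simulate_survival(
    n: int,
    hazard_coefs: tuple[float, float, float] = (1.0, 0.3, 0.5),
    censoring_rate: float = 0.3,
    weibull_shape: float = 1.0,
    baseline_median_months: float = 60.0,
    risk: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Standalone survival simulator (used by the cohort generator and by tests).

    ``risk`` defaults to N(0, 1) draws; age is reported in years but enters the
    hazard standardized ((age - 52.6)/10.4); Ki-67 is a fraction in [0.01, 0.9].
    """
    rng = np.random.default_rng(seed)
    if risk is None:
        risk = rng.standard_normal(n)
    risk = np.asarray(risk, dtype=float)
    age = np.clip(rng.normal(52.6, 10.4, n), 27.0, 89.0)
    ki67 = 0.01 + 0.89 * rng.beta(1.2, 3.0, n)
    lp = (
        hazard_coefs[0] * risk
        + hazard_coefs[1] * (age - 52.6) / 10.4
        + hazard_coefs[2] * ki67
    )
    k = weibull_shape
    lam0 = math.log(2.0) / baseline_median_months  # exponential-scale baseline rate
    u = rng.uniform(size=n)
    # inverse-CDF draw from S(t) = exp(-(lam0 t)^k exp(lp))
    event_t = (-np.log(u) / np.exp(lp)) ** (1.0 / k) / lam0
    censor_t = _calibrate_censoring(event_t, rng.uniform(size=n), censoring_rate)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    time = np.maximum(time, 1e-3)  # observed time strictly positive
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "time_months": time,
            "event": event,
            "age": age,
            "ki67": ki67,
            "risk_score": risk,
        }
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from one root seed.

    Slide ER labels are Bernoulli(er_prevalence); each tile's latent class
    likelihood is a Beta draw whose shape pair follows the slide label, and the
    tile image is painted from it.  Metastasis labels follow a logistic model
    on (1, mean, sd) of the slide's latent likelihoods.  Survival times follow
    the configured hazard with the planted risk score equal to the slide's
    standardized mean latent likelihood.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_patients
    er = rng.binomial(1, config.er_prevalence, n)
    slide_ids = [f"S{i:04d}" for i in range(n)]
    patient_ids = [f"P{i:04d}" for i in range(n)]
    n_rows, n_cols = _grid_shape(config.tiles_per_slide)

    tiles: dict[str, np.ndarray] = {}
    tile_coords: dict[str, np.ndarray] = {}
    truth_rows = []
    mean_latent = np.empty(n)
    sd_latent = np.empty(n)
    for i, sid in enumerate(slide_ids):
        a, b = config.likelihood_beta_pos if er[i] == 1 else config.likelihood_beta_neg
        latent = rng.beta(a, b, config.tiles_per_slide)
        mean_latent[i] = latent.mean()
        sd_latent[i] = latent.std()
        imgs = np.empty(
            (config.tiles_per_slide, config.tile_size, config.tile_size, 3), np.uint8
        )
        coords = np.empty((config.tiles_per_slide, 2), int)
        for t in range(config.tiles_per_slide):
            imgs[t] = _paint_tile(float(latent[t]), rng, config.tile_size)
            coords[t] = divmod(t, n_cols)
            truth_rows.append(
                {"slide_id": sid, "row": coords[t, 0], "col": coords[t, 1],
                 "latent_likelihood": latent[t]}
            )
        tiles[sid] = imgs
        tile_coords[sid] = coords

    coefs = np.asarray(config.metastasis_logit_coefs, dtype=float)
    summaries = np.column_stack([np.ones(n), mean_latent, sd_latent])[:, : len(coefs)]
    met_p = 1.0 / (1.0 + np.exp(-summaries @ coefs))
    metastasis = rng.binomial(1, met_p)

    sd_pop = mean_latent.std()
    risk = (mean_latent - mean_latent.mean()) / (sd_pop if sd_pop > 0 else 1.0)
    survival = simulate_survival(
        n,
        hazard_coefs=config.hazard_coefs,
        censoring_rate=config.censoring_rate,
        weibull_shape=config.weibull_shape,
        baseline_median_months=config.baseline_median_months,
        risk=risk,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    # reproducible split: shuffle by the root-seeded rng, first floor(f*n) train
    order = rng.permutation(n)
    n_train = int(math.floor(config.train_fraction * n))
    split = np.array(["test"] * n, dtype=object)
    split[order[:n_train]] = "train"

    manifest = pd.DataFrame(
        {
            "slide_id": slide_ids,
            "patient_id": patient_ids,
            "er_label": er,
            "metastasis_label": metastasis,
            "split": split,
        }
    )
    patch_truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(config, manifest, tiles, tile_coords, patch_truth, survival)


def write_cohort(
    cohort: SyntheticCohort, directory: str | Path, overwrite: bool = False
) -> Path:
    """Write the cohort to disk; returns the manifest path.

    Layout: ``slides/<slide_id>/tile_rRRR_cCCC.png`` for every tile, plus a
    composed ``slides/<slide_id>/slide.png`` grid image (white filler in unused
    grid cells) that the tiling stage can re-partition; ``manifest.csv`` (with
    an ``image_path`` column pointing at the composed slide) and
    ``survival.csv`` at the root; the latent tile truth under ``truth/`` —
    oracle data for tests, never an input to the pipeline.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} exists and is not empty; pass overwrite=True to replace"
        )
    slides_dir = directory / "slides"
    slides_dir.mkdir(parents=True, exist_ok=True)
    ts = cohort.config.tile_size
    n_rows, n_cols = _grid_shape(cohort.config.tiles_per_slide)

    image_paths = []
    for sid in cohort.manifest["slide_id"]:
        slide_dir = slides_dir / sid
        slide_dir.mkdir(exist_ok=True)
        composite = np.full((n_rows * ts, n_cols * ts, 3), 255, np.uint8)
        for img, (r, c) in zip(cohort.tiles[sid], cohort.tile_coords[sid]):
            Image.fromarray(img).save(slide_dir / f"tile_r{r:03d}_c{c:03d}.png")
            composite[r * ts:(r + 1) * ts, c * ts:(c + 1) * ts] = img
        slide_path = slide_dir / "slide.png"
        Image.fromarray(composite).save(slide_path)
        image_paths.append(str(slide_path))

    manifest = cohort.manifest.copy()
    manifest.insert(1, "image_path", image_paths)
    manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    cohort.survival.to_csv(directory / "survival.csv", index=False)
    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    cohort.patch_truth.to_csv(truth_dir / "patch_truth.csv", index=False)
    return manifest_path
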