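"""Synthetic QLF-like images and case-control cohorts with known truth.

Two generators make the whole pipeline testable without the (undeposited)
study data:

* :func:`simulate_tooth_image` draws an elliptical tooth whose enamel is
  green-dominant (red/green ratio < 1) with a contiguous plaque band of
  controllable areal fraction ``f`` along the gingival (lower) edge, where
  plaque actually accrues. In *disclosed* mode the band is red-dominant
  (ratio > 1), emulating a disclosing agent; in *undisclosed* mode the
  band's ratio is elevated by a configurable dR% over enamel. Optional
  Gaussian channel noise and an interlacing brightness artifact emulate
  the video capture chain. The exact plaque mask is returned as ground
  truth.

* :func:`simulate_cohort` draws subjects whose covariates (age, BMI,
  smoking), plaque coverage, red fluorescence and delivery outcome follow
  a known generative model, in one of two modes:

  - ``stratified``: fixed group sizes with per-group coverage moments —
    produces cohorts whose descriptive table mirrors a published
    case/control summary;
  - ``logistic``: covariates drawn from pooled distributions and case
    status assigned by a Bernoulli draw through a logistic link with
    configured coefficients — the mode used for parameter-recovery and
    type-I-error calibration.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .cohort import SMOKING_LEVELS, SubjectRecord
from .errors import ConfigError
from .image_model import BinaryMask, EllipseROI, FluorescenceImage, PolygonROI
from .plaque_segmentation import CoverageResult
from .red_fluorescence import DeltaRResult

__all__ = [
    "ImageSimConfig",
    "CohortSimConfig",
    "simulate_tooth_image",
    "simulate_cohort",
    "simulate_cohort_frame",
    "calibrate_delta_r_link",
    "realized_coverage_moments",
    "study_accounting_cohort",
]


# ---------------------------------------------------------------------------
# Image generator


@dataclass
class ImageSimConfig:
    """Parameters of one synthetic tooth frame.

    ``plaque_fraction`` is the areal fraction of the tooth covered by the
    plaque band (0-1). ``r_enamel`` must stay below 1 and ``r_plaque``
    above 1 so that integer red/green division separates the classes in
    disclosed mode. ``delta_r_pct`` sets the band's ratio elevation over
    enamel in undisclosed mode (where the band's absolute ratio may well
    stay below 1 — undisclosed plaque is not red-dominant).
    """

    height: int = 256
    width: int = 256
    tooth_center: tuple[float, float] = (128.0, 128.0)  # (x, y)
    tooth_semi_axes: tuple[float, float] = (80.0, 110.0)  # (a_x, a_y)
    enamel_green: int = 150
    r_enamel: float = 0.55
    plaque_fraction: float = 0.25
    r_plaque: float = 1.6
    delta_r_pct: float = 70.0
    disclosed: bool = True
    scattered: bool = False  # speckle mode instead of a gingival band
    noise_sd: float = 0.0
    interlace_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plaque_fraction <= 1.0:
            raise ConfigError(f"plaque_fraction must be in [0, 1], got {self.plaque_fraction}")
        if not self.r_enamel < 1.0 < self.r_plaque:
            raise ConfigError(
                f"need r_enamel < 1 < r_plaque, got {self.r_enamel}, {self.r_plaque}"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.enamel_green <= 0 or self.enamel_green > 255:
            raise ConfigError("enamel_green must be in (0, 255]")


def _tooth_mask(cfg: ImageSimConfig) -> np.ndarray:
    cx, cy = cfg.tooth_center
    a, b = cfg.tooth_semi_axes
    xs = np.arange(cfg.width) + 0.5
    ys = np.arange(cfg.height) + 0.5
    dx = (xs[None, :] - cx) / a
    dy = (ys[:, None] - cy) / b
    return dx**2 + dy**2 <= 1.0


def _band_mask(tooth: np.ndarray, fraction: float) -> np.ndarray:
    """Contiguous band of exactly ceil(f * area) tooth pixels, grown row by
    row from the bottom (gingival) edge; the partial top row fills from
    the left."""
    n_target = math.ceil(fraction * tooth.sum())
    mask = np.zeros_like(tooth)
    if n_target == 0:
        return mask
    remaining = n_target
    for i in range(tooth.shape[0] - 1, -1, -1):
        cols = np.flatnonzero(tooth[i])
        if cols.size == 0:
            continue
        if cols.size <= remaining:
            mask[i, cols] = True
            remaining -= cols.size
        else:
            mask[i, cols[:remaining]] = True
            remaining = 0
        if remaining == 0:
            break
    return mask


def _speckle_mask(tooth: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    n_target = math.ceil(fraction * tooth.sum())
    idx = np.flatnonzero(tooth)
    chosen = rng.choice(idx, size=n_target, replace=False)
    mask = np.zeros(tooth.size, dtype=bool)
    mask[chosen] = True
    return mask.reshape(tooth.shape)


def simulate_tooth_image(
    cfg: ImageSimConfig,
) -> tuple[FluorescenceImage, PolygonROI, EllipseROI, BinaryMask]:
    """Render one synthetic tooth frame.

    Returns the frame, a 72-gon tooth-boundary ROI, a plaque-free
    reference ellipse in the upper enamel zone, and the exact plaque mask.
    """
    rng = np.random.default_rng(cfg.seed)
    tooth = _tooth_mask(cfg)
    if not tooth.any():
        raise ConfigError("tooth ellipse rasterizes to an empty region")
    plaque = (
        _speckle_mask(tooth, cfg.plaque_fraction, rng)
        if cfg.scattered
        else _band_mask(tooth, cfg.plaque_fraction)
    )

    g_level = float(cfg.enamel_green)
    if cfg.disclosed:
        r_band = cfg.r_plaque
    else:
        r_band = cfg.r_enamel * (1.0 + cfg.delta_r_pct / 100.0)
    if round(r_band * g_level) > 255:
        raise ConfigError("plaque red level exceeds 8-bit range; lower enamel_green")

    red = np.zeros(tooth.shape, dtype=float)
    green = np.zeros(tooth.shape, dtype=float)
    blue = np.zeros(tooth.shape, dtype=float)
    green[tooth] = g_level
    red[tooth & ~plaque] = cfg.r_enamel * g_level
    red[plaque] = r_band * g_level
    blue[tooth] = 24.0

    if cfg.interlace_amplitude > 0:
        rows = np.arange(cfg.height)
        offset = np.where(rows % 2 == 1, cfg.interlace_amplitude, 0.0)[:, None]
        red += offset * tooth
        green += offset * tooth
    if cfg.noise_sd > 0:
        red += rng.normal(0, cfg.noise_sd, red.shape)
        green += rng.normal(0, cfg.noise_sd, green.shape)
        blue += rng.normal(0, cfg.noise_sd, blue.shape)

    pixels = np.clip(
        np.rint(np.stack([red, green, blue], axis=-1)), 0, 255
    ).astype(np.uint8)
    image_id = f"sim-{cfg.seed}"
    img = FluorescenceImage(pixels, image_id=image_id)

    cx, cy = cfg.tooth_center
    a, b = cfg.tooth_semi_axes
    angles = np.linspace(0.0, 2.0 * np.pi, 72, endpoint=False)
    verts = [(cx + a * np.cos(t), cy + b * np.sin(t)) for t in angles]
    roi = PolygonROI(verts, tooth_id="11")

    ref = EllipseROI(
        center=(cx, cy - 0.55 * b),
        semi_axes=(max(2.0, 0.30 * a), max(2.0, 0.14 * b)),
        rotation=0.0,
    )
    # reference must sit on clean enamel; a very tall band would swallow it
    ys = np.arange(cfg.height) + 0.5
    xs = np.arange(cfg.width) + 0.5
    du = (xs[None, :] - ref.center[0]) / ref.semi_axes[0]
    dv = (ys[:, None] - ref.center[1]) / ref.semi_axes[1]
    ref_mask = du**2 + dv**2 <= 1.0
    if not cfg.disclosed and (ref_mask & plaque).any():
        # only fatal when the frame is meant for dR%: the reference must
        # be plaque-free there, whereas coverage never reads it
        raise ConfigError(
            f"plaque_fraction {cfg.plaque_fraction} reaches the reference zone; "
            "use a smaller fraction or scattered=False"
        )
    return img, roi, ref, BinaryMask(plaque, origin_image_id=image_id)


# ---------------------------------------------------------------------------
# Cohort generator


@dataclass
class CohortSimConfig:
    """Generative model of a case-control cohort.

    Defaults are calibrated to the descriptive moments of an antenatal
    case-control sample of 91 (51 cases / 40 controls): coverage ~25.5%
    (sd 17.5) in cases vs ~20.6% (sd 14.4) in controls, dR% in the high
    60s, age ~29-31 y, BMI ~26 kg/m^2, and mostly nonsmoking mothers.

    ``mode="stratified"`` draws exactly the configured group sizes with
    per-group coverage moments. ``mode="logistic"`` draws covariates from
    the pooled distributions and assigns case status by a Bernoulli draw
    with probability ``expit(intercept + beta . x)``; group sizes are then
    random.
    """

    n_case: int = 51
    n_control: int = 40
    mode: Literal["stratified", "logistic"] = "stratified"
    # covariates (pooled; per-group means only used for age in stratified mode)
    age_mean: tuple[float, float] = (28.69, 30.78)  # (case, control)
    age_sd: tuple[float, float] = (5.91, 6.41)
    bmi_mean: tuple[float, float] = (26.05, 26.21)
    bmi_sd: tuple[float, float] = (5.29, 5.32)
    smoking_probs: tuple[tuple[float, ...], tuple[float, ...]] = (
        (31 / 51, 5 / 51, 15 / 51),
        (30 / 40, 4 / 40, 6 / 40),
    )
    coverage_mean: tuple[float, float] = (25.50, 20.58)
    coverage_sd: tuple[float, float] = (17.45, 14.39)
    # dR% linear link to coverage, calibrated (via calibrate_delta_r_link
    # with the truncation-aware coverage sd) to a population Pearson r of
    # 0.55 with dR% mean ~66.6 and sd ~16.5
    dr_slope: float = 0.6331
    dr_intercept: float = 50.29
    dr_noise_sd: float = 13.78
    # logistic-mode coefficients on (coverage, delta_r, smoking code, bmi, age)
    beta_coverage: float = -0.042
    beta_delta_r: float = 0.036
    beta_smoking: float = -0.822
    beta_bmi: float = 0.005
    beta_age: float = 0.030
    intercept: float = -1.75
    # preterm-outcome model: P(delivery < 37 wk) = expit(a + b * coverage)
    preterm_intercept: float = -2.75
    preterm_slope: float = 0.05
    # per-tooth scatter around the subject mean
    tooth_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ConfigError("group sizes must be positive")
        for sd in (*self.age_sd, *self.bmi_sd, *self.coverage_sd, self.dr_noise_sd, self.tooth_sd):
            if sd < 0:
                raise ConfigError(f"negative standard deviation {sd}")
        for probs in self.smoking_probs:
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ConfigError(f"smoking probabilities invalid: {probs}")

    @property
    def n_subjects(self) -> int:
        return self.n_case + self.n_control


def realized_coverage_moments(cfg: CohortSimConfig) -> tuple[float, float]:
    """Mean and sd of the coverage marginal the generator actually draws:
    the case/control mixture of normals truncated to [0, 100]. Truncation
    pulls the mean up and the sd down relative to the configured parent
    moments; calibrations against the generated data should use these."""
    from scipy import stats as sps

    w = cfg.n_case / cfg.n_subjects
    moments = []
    for m, s in zip(cfg.coverage_mean, cfg.coverage_sd):
        a, b = (0.0 - m) / s, (100.0 - m) / s
        d = sps.truncnorm(a, b, loc=m, scale=s)
        moments.append((d.mean(), d.std()))
    (m1, s1), (m2, s2) = moments
    mean = w * m1 + (1 - w) * m2
    var = w * (s1**2 + m1**2) + (1 - w) * (s2**2 + m2**2) - mean**2
    return float(mean), float(math.sqrt(var))


def calibrate_delta_r_link(
    target_r: float,
    coverage_sd: float,
    delta_r_sd: float,
    coverage_mean: float,
    delta_r_mean: float,
) -> tuple[float, float, float]:
    """Choose (slope, intercept, noise sd) of the linear dR%-on-coverage
    link so the population correlation equals ``target_r`` and the dR%
    marginal has the requested mean and sd."""
    if not 0 < abs(target_r) < 1:
        raise ConfigError("target correlation must be in (0, 1) in magnitude")
    slope = target_r * delta_r_sd / coverage_sd
    intercept = delta_r_mean - slope * coverage_mean
    noise_sd = delta_r_sd * math.sqrt(1.0 - target_r**2)
    return slope, intercept, noise_sd


def _pooled(cfg: CohortSimConfig, pair: tuple[float, float]) -> float:
    w = cfg.n_case / cfg.n_subjects
    return w * pair[0] + (1 - w) * pair[1]


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_cohort_frame(cfg: CohortSimConfig) -> pd.DataFrame:
    """Vectorized subject-level cohort draw (no per-tooth objects).

    Columns: subject_id, group, maternal_age, bmi, smoking, smoking_code,
    mean_coverage_pct, mean_delta_r_pct, n_teeth, delivery_weeks,
    natural_anterior_teeth, antibiotics_recent, visit_index.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    def trunc_normal(mean, sd, lo, hi, size):
        out = rng.normal(mean, sd, size)
        bad = (out < lo) | (out > hi)
        while bad.any():
            out[bad] = rng.normal(
                np.broadcast_to(mean, out.shape)[bad] if np.ndim(mean) else mean,
                np.broadcast_to(sd, out.shape)[bad] if np.ndim(sd) else sd,
                bad.sum(),
            )
            bad = (out < lo) | (out > hi)
        return out

    if cfg.mode == "stratified":
        grp = np.array(["case"] * cfg.n_case + ["control"] * cfg.n_control)
        is_case = grp == "case"
        mean_v = np.where(is_case, cfg.coverage_mean[0], cfg.coverage_mean[1])
        sd_v = np.where(is_case, cfg.coverage_sd[0], cfg.coverage_sd[1])
        coverage = trunc_normal(mean_v, sd_v, 0.0, 100.0, n)
        age = trunc_normal(
            np.where(is_case, cfg.age_mean[0], cfg.age_mean[1]),
            np.where(is_case, cfg.age_sd[0], cfg.age_sd[1]),
            16.0, 50.0, n,
        )
        bmi = trunc_normal(
            np.where(is_case, cfg.bmi_mean[0], cfg.bmi_mean[1]),
            np.where(is_case, cfg.bmi_sd[0], cfg.bmi_sd[1]),
            14.0, 55.0, n,
        )
        smoke_code = np.empty(n, dtype=int)
        for gi, probs in zip((True, False), cfg.smoking_probs):
            sel = is_case == gi
            smoke_code[sel] = rng.choice(3, size=sel.sum(), p=probs)
        delta = cfg.dr_intercept + cfg.dr_slope * coverage + rng.normal(0, cfg.dr_noise_sd, n)
        delta = np.clip(delta, 0.0, None)
    elif cfg.mode == "logistic":
        coverage = trunc_normal(
            _pooled(cfg, cfg.coverage_mean), _pooled(cfg, cfg.coverage_sd), 0.0, 100.0, n
        )
        age = trunc_normal(_pooled(cfg, cfg.age_mean), _pooled(cfg, cfg.age_sd), 16.0, 50.0, n)
        bmi = trunc_normal(_pooled(cfg, cfg.bmi_mean), _pooled(cfg, cfg.bmi_sd), 14.0, 55.0, n)
        w = cfg.n_case / cfg.n_subjects
        pooled_probs = tuple(
            w * a + (1 - w) * b for a, b in zip(*cfg.smoking_probs)
        )
        smoke_code = rng.choice(3, size=n, p=pooled_probs)
        delta = cfg.dr_intercept + cfg.dr_slope * coverage + rng.normal(0, cfg.dr_noise_sd, n)
        delta = np.clip(delta, 0.0, None)
        lp = (
            cfg.intercept
            + cfg.beta_coverage * coverage
            + cfg.beta_delta_r * delta
            + cfg.beta_smoking * smoke_code
            + cfg.beta_bmi * bmi
            + cfg.beta_age * age
        )
        is_case = rng.random(n) < _expit(lp)
        grp = np.where(is_case, "case", "control")
    else:
        raise ConfigError(f"unknown mode {cfg.mode!r}")

    p_pre = _expit(cfg.preterm_intercept + cfg.preterm_slope * coverage)
    preterm = rng.random(n) < p_pre
    weeks = np.where(
        preterm,
        trunc_normal(34.0, 2.4, 24.0, 36.9, n),
        trunc_normal(39.5, 1.2, 37.0, 42.5, n),
    )
    n_teeth = rng.integers(10, 13, size=n)

    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "group": grp,
            "maternal_age": age,
            "bmi": bmi,
            "smoking": [SMOKING_LEVELS[c] for c in smoke_code],
            "smoking_code": smoke_code,
            "mean_coverage_pct": coverage,
            "mean_delta_r_pct": delta,
            "n_teeth": n_teeth,
            "delivery_weeks": weeks,
            "natural_anterior_teeth": n_teeth,
            "antibiotics_recent": 0,
            "visit_index": 1,
        }
    )


def _tooth_measurements(
    rng: np.random.Generator, mean_cov: float, mean_dr: float, n_teeth: int, tooth_sd: float
) -> list[tuple[CoverageResult, DeltaRResult]]:
    tooth_ids = ["13", "12", "11", "21", "22", "23", "33", "32", "31", "41", "42", "43"]
    roi_px = 12000
    out = []
    covs = np.clip(rng.normal(mean_cov, tooth_sd, n_teeth), 0.0, 100.0)
    drs = np.clip(rng.normal(mean_dr, tooth_sd, n_teeth), 0.0, None)
    for t in range(n_teeth):
        plaque_px = int(round(covs[t] / 100.0 * roi_px))
        out.append(
            (
                CoverageResult(
                    tooth_id=tooth_ids[t],
                    roi_pixels=roi_px,
                    plaque_pixels=plaque_px,
                    coverage_pct=100.0 * plaque_px / roi_px,
                ),
                DeltaRResult(
                    tooth_id=tooth_ids[t],
                    reference_ratio=0.55,
                    delta_r_pct=float(drs[t]),
                    detected_pixels=plaque_px,
                ),
            )
        )
    return out


def simulate_cohort(cfg: CohortSimConfig) -> list[SubjectRecord]:
    """Full cohort draw: subject records with per-tooth measurements.

    Per-tooth coverage and dR% scatter normally (sd ``tooth_sd``) around
    the subject mean, clipped to their valid ranges, over 10-12 anterior
    teeth.
    """
    frame = simulate_cohort_frame(cfg)
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                group=row.group,
                maternal_age=float(row.maternal_age),
                bmi=float(row.bmi),
                smoking=row.smoking,
                natural_anterior_teeth=int(row.natural_anterior_teeth),
                antibiotics_recent=bool(row.antibiotics_recent),
                visit_index=int(row.visit_index),
                delivery_weeks=float(row.delivery_weeks),
                tooth_measurements=_tooth_measurements(
                    rng,
                    float(row.mean_coverage_pct),
                    float(row.mean_delta_r_pct),
                    int(row.n_teeth),
                    cfg.tooth_sd,
                ),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Study-accounting fixture


def study_accounting_cohort(
    seed: int = 0, include_repeat_visits: bool = False
) -> list[SubjectRecord]:
    """A 109-subject recruitment fixture mirroring the study's accounting.

    Composition: 91 analyzable subjects (51 cases, 40 controls), 7 with
    fewer than 10 natural anterior teeth, 5 with recent antibiotic use,
    4 with missing BMI/smoking data, and 2 who withdrew during imaging
    (no tooth measurements). Among the 91, delivery outcomes are 2
    extreme (<28 wk), 4 moderate (28-<34), 11 mild (34-<37) and 73 term,
    with one control outcome missing — 17 preterm (<37 wk) of which 6
    before 34 weeks. With ``include_repeat_visits`` three retained
    subjects carry an extra visit-2 row that the filter must drop.
    """
    cfg = CohortSimConfig(n_case=51, n_control=40, mode="stratified", seed=seed)
    base = simulate_cohort(cfg)
    rng = np.random.default_rng(seed + 1)

    # overwrite delivery outcomes with the fixed accounting
    case_recs = [r for r in base if r.group == "case"]
    ctrl_recs = [r for r in base if r.group == "control"]
    weeks_case = (
        [26.0, 27.5]  # extreme
        + [29.0, 31.0, 33.5]  # moderate
        + [34.5, 35.0, 35.5, 36.0, 36.2, 36.4, 36.6, 36.8, 36.9, 36.9]  # mild
        + [None] * 0
    )
    weeks_case += list(rng.uniform(37.0, 42.0, len(case_recs) - len(weeks_case)))
    weeks_ctrl = [32.0] + [36.5] + list(rng.uniform(37.0, 42.0, len(ctrl_recs) - 3)) + [None]
    for rec, w in zip(case_recs, weeks_case):
        rec.delivery_weeks = None if w is None else round(float(w), 1)
    for rec, w in zip(ctrl_recs, weeks_ctrl):
        rec.delivery_weeks = None if w is None else round(float(w), 1)

    extras: list[SubjectRecord] = []

    def blank_record(i: int, **kw) -> SubjectRecord:
        grp = "case" if i % 2 == 0 else "control"
        defaults = dict(
            subject_id=f"X{i:03d}",
            group=grp,
            maternal_age=float(rng.uniform(20, 40)),
            bmi=float(rng.uniform(19, 33)),
            smoking="nonsmoker",
            natural_anterior_teeth=12,
            antibiotics_recent=False,
            visit_index=1,
            delivery_weeks=None,
            tooth_measurements=_tooth_measurements(rng, 20.0, 60.0, 10, 5.0),
        )
        defaults.update(kw)
        return SubjectRecord(**defaults)  # type: ignore[arg-type]

    for i in range(7):  # fewer than 10 natural anterior teeth
        extras.append(blank_record(i, natural_anterior_teeth=int(rng.integers(4, 10))))
    for i in range(7, 12):  # recent antibiotics
        extras.append(blank_record(i, antibiotics_recent=True))
    for i in range(12, 16):  # missing BMI or smoking status
        if i % 2 == 0:
            extras.append(blank_record(i, bmi=None))
        else:
            extras.append(blank_record(i, smoking=None))
    for i in range(16, 18):  # withdrew during imaging
        extras.append(blank_record(i, tooth_measurements=[]))

    repeats = [
        SubjectRecord(
            subject_id=base[k].subject_id,
            group=base[k].group,
            maternal_age=base[k].maternal_age,
            bmi=base[k].bmi,
            smoking=base[k].smoking,
            natural_anterior_teeth=base[k].natural_anterior_teeth,
            antibiotics_recent=False,
            visit_index=2,
            delivery_weeks=base[k].delivery_weeks,
            tooth_measurements=_tooth_measurements(rng, 18.0, 60.0, 11, 5.0),
        )
        for k in (0, 5, 9)
    ]
    out = base + extras
    if include_repeat_visits:
        out = out + repeats
    return out
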