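"""Synthetic dual-time DCE phantoms and cohorts with known ground truth.

Every downstream stage (signal conversion, Patlak fitting, histogram noise
correction, cohort regression) is exercised against phantoms generated
here, so the generator mirrors the acquisition it emulates: a fast
sequence (3.2 s interval, 29 volumes) covering the bolus first pass and a
slow sequence (30.5 s interval, 30 volumes) covering the leakage phase,
both saturation-recovery weighted, with per-region leakage rates at the
1e-7..1e-6 min^-1 level typical of an intact or mildly disrupted BBB.

The phantom's "true" plasma curve is defined as the piecewise-linear
interpolant of a parametric population input function (gamma-variate
rise, biexponential washout) on the merged acquisition grid.  Trapezoid
integration of that curve is then exact, so a noiseless phantom is
recovered by the analysis pipeline to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

import pandas as pd

from .protocol import AcquisitionProtocol
from .conversion import (CalibrationCurve, DEFAULT_HEMATOCRIT, DynamicSeries)
from .summarize import ROIMaskSet, ROI_ORDER
from .stats import KI_COLUMNS

__all__ = [
    "PhantomSpec", "CohortSpec", "GroundTruth", "SimulatedSubject",
    "REGION_LABELS", "TABLE_KI_MEDIANS", "TABLE_KI_QUARTILES",
    "TABLE_AGE_BETAS", "population_aif", "forward_patlak",
    "concentration_to_signal", "simulate_subject", "simulate_cohort",
    "default_calibration_curve",
]

#: Integer codes of the phantom label map.
REGION_LABELS = {
    "background": 0, "sinus": 1, "white_matter": 2, "gray_matter": 3,
    "primary": 4, "secondary": 5, "tertiary": 6,
}

#: Default per-ROI leakage-rate medians (min^-1); the reference cohort's
#: reported values, printed there as x 1e-7 min^-1.
TABLE_KI_MEDIANS = {
    "white_matter": 11.4e-7, "gray_matter": 9.5e-7,
    "primary": 4.4e-7, "secondary": 3.4e-7, "tertiary": 9.2e-7,
}

#: Default per-ROI (p25, p75) leakage-rate quartiles (min^-1).
TABLE_KI_QUARTILES = {
    "white_matter": (5.1e-7, 20.4e-7), "gray_matter": (3.9e-7, 17.3e-7),
    "primary": (1.0e-7, 10.8e-7), "secondary": (0.4e-7, 7.1e-7),
    "tertiary": (1.1e-7, 25.1e-7),
}

#: Default programmed standardized age effect per ROI.
TABLE_AGE_BETAS = {
    "white_matter": 0.306, "gray_matter": 0.286,
    "primary": 0.145, "secondary": 0.098, "tertiary": 0.307,
}


def population_aif(
    times_s: np.ndarray,
    bolus_arrival_s: float,
    peak_mM: float,
    decay_rates: tuple[float, float] = (1.0 / 30.0, 1.7e-3),
    rise_time_s: float = 8.0,
    rise_shape: float = 2.0,
    fast_fraction: float = 0.7,
) -> np.ndarray:
    """Parametric whole-blood input function (mM).

    Zero before ``bolus_arrival_s``; a gamma-variate rise that reaches
    exactly ``peak_mM`` at ``bolus_arrival_s + rise_time_s``; then a
    biexponential washout mixing the two ``decay_rates`` (s^-1) with
    weight ``fast_fraction`` on the first.  A parsimonious single-peaked
    stand-in for a measured sinus curve.
    """
    times_s = np.asarray(times_s, dtype=float)
    d = np.diff(times_s)
    if np.any(d < 0):
        i = int(np.argmax(d < 0)) + 1
        raise ValueError(f"times must be non-decreasing; decrease at index {i}")
    if peak_mM <= 0:
        raise ValueError(f"peak concentration must be positive, got {peak_mM}")
    k1, k2 = decay_rates
    if k1 <= 0 or k2 <= 0:
        raise ValueError(f"decay rates must be positive, got {decay_rates}")
    if rise_time_s <= 0 or rise_shape <= 0 or not (0 <= fast_fraction <= 1):
        raise ValueError("invalid rise/washout shape parameters")
    tau = times_s - bolus_arrival_s
    out = np.zeros_like(times_s)
    rising = (tau > 0) & (tau <= rise_time_s)
    x = tau[rising] / rise_time_s
    out[rising] = peak_mM * x**rise_shape * np.exp(rise_shape * (1.0 - x))
    washing = tau > rise_time_s
    w = tau[washing] - rise_time_s
    out[washing] = peak_mM * (fast_fraction * np.exp(-k1 * w)
                              + (1.0 - fast_fraction) * np.exp(-k2 * w))
    return out


def forward_patlak(
    ki_per_min: float,
    vp: float,
    cp_mM: np.ndarray,
    times_s: np.ndarray,
) -> np.ndarray:
    """Tissue concentration from the Patlak model (mM).

    ``Ct(t) = Ki * integral Cp dtau + vp * Cp(t)`` with the integral taken
    by the trapezoid rule on the provided sampling grid and converted to
    minutes, so Ki is in min^-1.  Linear in (Ki, vp) by construction.
    """
    cp_mM = np.asarray(cp_mM, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if cp_mM.shape != times_s.shape:
        raise ValueError(
            f"cp length {cp_mM.size} != times length {times_s.size}")
    if np.any(np.diff(times_s) < 0):
        raise ValueError("times must be non-decreasing")
    integral_min = np.concatenate(
        [[0.0], cumulative_trapezoid(cp_mM, times_s)]) / 60.0
    return ki_per_min * integral_min + vp * cp_mM


def concentration_to_signal(
    conc_mM: np.ndarray,
    t10_ms: float | np.ndarray,
    protocol: AcquisitionProtocol,
    s0: float = 1.0,
) -> np.ndarray:
    """Saturation-recovery signal for a given concentration curve.

    ``S = s0 * (1 - exp(-TD * (R10 + r1 * C)))`` — the exact inverse of
    the tissue conversion, so noiseless round trips are identities.  At
    C = 0 the baseline ``s0 * (1 - exp(-TD * R10))`` is returned; as
    C -> inf the signal saturates at ``s0``.
    """
    t10_ms = np.asarray(t10_ms, dtype=float)
    if np.any(t10_ms <= 0):
        raise ValueError("T10 must be strictly positive")
    r1 = 1000.0 / t10_ms + protocol.r1_relaxivity * np.asarray(conc_mM, float)
    if np.any(r1 <= 0):
        raise ValueError("concentration drives R1 non-positive; "
                         "outside the model's validity")
    return s0 * (1.0 - np.exp(-protocol.td_s * r1))


_DEFAULT_KI = dict(TABLE_KI_MEDIANS)
_DEFAULT_VP = {"white_matter": 0.008, "gray_matter": 0.015,
               "primary": 0.015, "secondary": 0.015, "tertiary": 0.015}
_DEFAULT_T10 = {"background": 1000.0, "white_matter": 1100.0,
                "gray_matter": 1800.0, "primary": 1800.0,
                "secondary": 1800.0, "tertiary": 1800.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics and noise of a single phantom subject.

    Regions are axis-aligned boxes on a small 3D grid (default 32x32x16)
    sized so each analysis ROI holds >= 500 voxels.  Per-region Ki
    (min^-1), vp (fraction in [0, 1)) and T10 (ms) default to values at
    the reported cohort's level.  ``noise_sigma_rel`` scales the noise
    standard deviation relative to each voxel's baseline signal; the
    default is low enough that per-voxel Ki noise sits at a few percent
    of the programmed rates (see the methods note).
    """

    shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    ki: dict = field(default_factory=lambda: dict(_DEFAULT_KI))
    vp: dict = field(default_factory=lambda: dict(_DEFAULT_VP))
    t10_ms: dict = field(default_factory=lambda: dict(_DEFAULT_T10))
    blood_t10_ms: float = 1650.0
    noise_sigma_rel: float = 2e-5
    noise_model: str = "rician"
    aif_peak_mM: float = 6.0
    aif_rise_time_s: float = 8.0
    aif_rise_shape: float = 2.0
    aif_decay_rates: tuple[float, float] = (1.0 / 30.0, 1.7e-3)
    aif_fast_fraction: float = 0.7
    hematocrit: float = DEFAULT_HEMATOCRIT
    s0: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        required = set(ROI_ORDER)
        if not required <= set(self.ki) or not required <= set(self.vp):
            raise ValueError(f"ki and vp must cover regions {sorted(required)}")
        if not (required | {"background"}) <= set(self.t10_ms):
            raise ValueError("t10_ms must cover all regions and background")
        for r, v in self.vp.items():
            if not (0 <= v < 1):
                raise ValueError(f"vp[{r!r}] must lie in [0, 1), got {v}")
        for r, v in self.t10_ms.items():
            if v <= 0:
                raise ValueError(f"t10_ms[{r!r}] must be positive, got {v}")
        if self.blood_t10_ms <= 0:
            raise ValueError("blood_t10_ms must be positive")
        if self.noise_sigma_rel < 0:
            raise ValueError("noise_sigma_rel must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(
                f"noise_model must be 'gaussian' or 'rician', "
                f"got {self.noise_model!r}")
        if not (0 <= self.hematocrit < 1):
            raise ValueError("hematocrit must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Known kinetics of a simulated subject.

    ``cp_times_s`` / ``cp_mM`` hold the noiseless *plasma* curve defined
    piecewise-linearly on the merged acquisition grid; ``cb_mM`` is the
    corresponding whole-blood curve seen by the sinus voxels.
    """

    ki_map: np.ndarray
    vp_map: np.ndarray
    labels: np.ndarray
    cp_times_s: np.ndarray
    cp_mM: np.ndarray
    cb_mM: np.ndarray
    bolus_arrival_s: float


@dataclass
class SimulatedSubject:
    """Bundle returned by :func:`simulate_subject`."""

    fast: DynamicSeries
    slow: DynamicSeries
    t10_ms: np.ndarray
    masks: ROIMaskSet
    sinus_mask: np.ndarray
    brain_mask: np.ndarray
    truth: GroundTruth
    calibration: CalibrationCurve
    protocol: AcquisitionProtocol
    hematocrit: float


def default_calibration_curve(
    phantom: PhantomSpec, protocol: AcquisitionProtocol
) -> CalibrationCurve:
    """Calibration table consistent with the phantom's blood relaxometry.

    Tabulated densely (2.5e-3 mM steps from -1 to 40 mM) so that monotone
    cubic inversion reproduces the forward map to numerical precision;
    the small negative branch lets noisy pre-bolus enhancement ratios
    below one map to (retained) negative concentrations.
    """
    conc = np.arange(-400, 16001) * 0.0025
    return CalibrationCurve.from_saturation_recovery(
        phantom.blood_t10_ms, protocol.td_ms, protocol.r1_relaxivity,
        concentrations_mM=conc)


def _box(shape, xf, yf, zf) -> tuple[slice, slice, slice]:
    """Axis-aligned box from fractional coordinates of the grid."""
    def sl(n, lo, hi):
        return slice(int(round(lo * n)), int(round(hi * n)))
    return (sl(shape[0], *xf), sl(shape[1], *yf), sl(shape[2], *zf))


def build_label_map(shape: tuple[int, int, int]) -> np.ndarray:
    """Box-shaped phantom regions on the given grid.

    White matter and gray matter occupy two slabs; the primary, secondary
    and tertiary cortical classes are disjoint sub-boxes of the gray
    matter slab; a small separate box is the sagittal sinus.
    """
    labels = np.zeros(shape, dtype=np.int16)
    z = (2 / 16, 14 / 16)
    labels[_box(shape, (2 / 32, 12 / 32), (2 / 32, 30 / 32), z)] = \
        REGION_LABELS["white_matter"]
    gmx = (16 / 32, 30 / 32)
    labels[_box(shape, gmx, (26 / 32, 30 / 32), z)] = REGION_LABELS["gray_matter"]
    labels[_box(shape, gmx, (2 / 32, 10 / 32), z)] = REGION_LABELS["primary"]
    labels[_box(shape, gmx, (10 / 32, 18 / 32), z)] = REGION_LABELS["secondary"]
    labels[_box(shape, gmx, (18 / 32, 26 / 32), z)] = REGION_LABELS["tertiary"]
    labels[_box(shape, (12 / 32, 16 / 32), (2 / 32, 6 / 32), z)] = \
        REGION_LABELS["sinus"]
    return labels


def acquisition_times(protocol: AcquisitionProtocol
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Fast/slow time stamps on a common clock and the bolus arrival.

    The slow sequence's pre-contrast volumes open the session; the fast
    sequence then runs back-to-back through the bolus (injected after its
    own pre-contrast volumes); the slow sequence resumes afterwards for
    the leakage phase.
    """
    p = protocol
    slow_pre = np.arange(p.n_precontrast_slow) * p.slow_interval_s
    fast_start = p.n_precontrast_slow * p.slow_interval_s
    fast = fast_start + np.arange(p.n_fast) * p.fast_interval_s
    bolus_arrival = fast_start + p.n_precontrast_fast * p.fast_interval_s
    n_slow_post = p.n_slow - p.n_precontrast_slow
    slow_post = fast[-1] + (np.arange(n_slow_post) + 1) * p.slow_interval_s
    slow = np.concatenate([slow_pre, slow_post])
    return fast, slow, bolus_arrival


def simulate_subject(
    phantom: PhantomSpec | None = None,
    protocol: AcquisitionProtocol | None = None,
    seed: int | None = None,
) -> SimulatedSubject:
    """Simulate one subject's dual-time DCE acquisition.

    Tissue voxels carry the forward Patlak curve of their region's
    (Ki, vp); sinus voxels carry the whole-blood input function; both are
    rendered through the saturation-recovery signal equation with the
    region's T10, and noise (Rician by default) is added at
    ``noise_sigma_rel`` times each voxel's baseline signal.  Identical
    seeds give bit-identical output.
    """
    phantom = phantom or PhantomSpec()
    protocol = protocol or AcquisitionProtocol()
    rng = np.random.default_rng(phantom.seed if seed is None else seed)

    labels = build_label_map(phantom.shape)
    inv = {v: k for k, v in REGION_LABELS.items()}
    fast_t, slow_t, t0 = acquisition_times(protocol)
    merged_t = np.unique(np.concatenate([fast_t, slow_t]))

    # Ground-truth curves: the parametric input function sampled on the
    # merged grid *defines* the (piecewise-linear) truth.
    cb = population_aif(merged_t, t0, phantom.aif_peak_mM,
                        phantom.aif_decay_rates, phantom.aif_rise_time_s,
                        phantom.aif_rise_shape, phantom.aif_fast_fraction)
    cp = cb / (1.0 - phantom.hematocrit)
    cp_int_min = np.concatenate(
        [[0.0], cumulative_trapezoid(cp, merged_t)]) / 60.0

    # Per-region maps.
    ki_map = np.zeros(phantom.shape)
    vp_map = np.zeros(phantom.shape)
    t10_map = np.full(phantom.shape, phantom.t10_ms["background"])
    for name in ROI_ORDER:
        m = labels == REGION_LABELS[name]
        ki_map[m] = phantom.ki[name]
        vp_map[m] = phantom.vp[name]
        t10_map[m] = phantom.t10_ms[name]
    sinus_mask = labels == REGION_LABELS["sinus"]
    t10_map[sinus_mask] = phantom.blood_t10_ms

    def series_signal(times: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(merged_t, times)
        ct = (ki_map[..., None] * cp_int_min[idx]
              + vp_map[..., None] * cp[idx])
        ct[sinus_mask, :] = cb[idx]
        return concentration_to_signal(ct, t10_map[..., None], protocol,
                                       phantom.s0)

    def add_noise(sig: np.ndarray) -> np.ndarray:
        if phantom.noise_sigma_rel == 0:
            return sig
        base = concentration_to_signal(
            np.zeros(phantom.shape), t10_map, protocol, phantom.s0)
        sigma = phantom.noise_sigma_rel * base[..., None]
        e1 = rng.normal(0.0, 1.0, sig.shape) * sigma
        if phantom.noise_model == "gaussian":
            return sig + e1
        e2 = rng.normal(0.0, 1.0, sig.shape) * sigma
        return np.sqrt((sig + e1) ** 2 + e2**2)

    fast = DynamicSeries(add_noise(series_signal(fast_t)), fast_t, "fast",
                         protocol.n_precontrast_fast)
    slow = DynamicSeries(add_noise(series_signal(slow_t)), slow_t, "slow",
                         protocol.n_precontrast_slow)

    masks = ROIMaskSet(
        white_matter=labels == REGION_LABELS["white_matter"],
        gray_matter=np.isin(labels, [REGION_LABELS["gray_matter"],
                                     REGION_LABELS["primary"],
                                     REGION_LABELS["secondary"],
                                     REGION_LABELS["tertiary"]]),
        primary=labels == REGION_LABELS["primary"],
        secondary=labels == REGION_LABELS["secondary"],
        tertiary=labels == REGION_LABELS["tertiary"],
    )
    brain_mask = masks.white_matter | masks.gray_matter
    truth = GroundTruth(ki_map, vp_map, labels, merged_t, cp, cb, t0)
    calibration = default_calibration_curve(phantom, protocol)
    return SimulatedSubject(fast, slow, t10_map, masks, sinus_mask,
                            brain_mask, truth, calibration, protocol,
                            phantom.hematocrit)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Generative model of a cohort's covariates and per-ROI mean Ki.

    Per-ROI mean Ki is generated on the cube-root scale, where the
    reference analyses are linear: ``y = c + s * u`` with
    ``u = beta * z_age + beta_sex * z_sex + sqrt(1 - beta^2 - beta_sex^2) * eps``,
    ``c`` the cube root of the programmed median and ``s`` matched to the
    programmed interquartile range.  Back-transforming ``y**3`` yields Ki
    with the programmed median and a refittable standardized age effect.

    When ``mediator`` names an integrity measure the age path runs
    entirely through that measure (full mediation): the measure keeps its
    own age slope and Ki loads on the measure instead of on age, with the
    loading chosen so the *marginal* age effect equals ``beta_age``.
    """

    n_subjects: int = 57
    age_range: tuple[float, float] = (47.0, 91.0)
    age_mean: float = 65.8
    age_sd: float = 10.2
    male_fraction: float = 0.526
    beta_age: dict = field(default_factory=lambda: dict(TABLE_AGE_BETAS))
    beta_sex: float = 0.0
    ki_median: dict = field(default_factory=lambda: dict(TABLE_KI_MEDIANS))
    ki_quartiles: dict = field(
        default_factory=lambda: dict(TABLE_KI_QUARTILES))
    ki_noise_scale: float = 1.0
    sbp_mean: float = 141.3
    sbp_sd: float = 17.2
    sbp_age_slope: float = 0.5
    bmi_mean: float = 27.7
    bmi_sd: float = 4.5
    diabetes_prevalence: float = 0.175
    smoker_prevalence: float = 0.14
    wmh_log_mean: float = 1.1
    wmh_log_sd: float = 0.9
    wmh_age_beta: float = 0.55
    thickness_mean: float = 2.45
    thickness_sd: float = 0.10
    thickness_age_beta: float = -0.5
    hippocampus_mean: float = 6.5
    hippocampus_sd: float = 0.7
    hippocampus_age_beta: float = -0.3
    mediator: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError(f"n_subjects must be >= 3, got {self.n_subjects}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        for roi, b in self.beta_age.items():
            if not (-1 < b < 1):
                raise ValueError(
                    f"beta_age[{roi!r}] must lie in (-1, 1), got {b}")
        if not (-1 < self.beta_sex < 1):
            raise ValueError("beta_sex must lie in (-1, 1)")
        if self.mediator is not None and self.mediator not in (
                "wmh_volume", "cortical_thickness", "hippocampal_volume"):
            raise ValueError(f"unknown mediator {self.mediator!r}")


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def simulate_cohort(
    spec: CohortSpec | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort table with known per-ROI age effects.

    Returns the table (one row per subject: covariates and per-ROI mean
    Ki in min^-1) and a dictionary of the generative parameters actually
    used.  Seed-deterministic.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects

    lo, hi = spec.age_range
    age = np.empty(n)
    have = 0
    while have < n:             # truncated normal by rejection
        draw = rng.normal(spec.age_mean, spec.age_sd, 2 * (n - have))
        draw = draw[(draw >= lo) & (draw <= hi)][: n - have]
        age[have:have + draw.size] = draw
        have += draw.size
    sex = (rng.random(n) < spec.male_fraction).astype(int)
    z_age = _zscore(age)
    z_sex = _zscore(sex) if sex.std() > 0 else np.zeros(n)

    sbp = (spec.sbp_mean + spec.sbp_age_slope * (age - spec.age_mean)
           + rng.normal(0, spec.sbp_sd, n))
    bmi = spec.bmi_mean + rng.normal(0, spec.bmi_sd, n)
    diabetes = (rng.random(n) < spec.diabetes_prevalence).astype(int)
    smoker = (rng.random(n) < spec.smoker_prevalence).astype(int)

    def age_linked(mean, sd, b):
        u = b * z_age + np.sqrt(max(0.0, 1 - b**2)) * rng.normal(0, 1, n)
        return mean + sd * u, u

    log_wmh, u_wmh = age_linked(spec.wmh_log_mean, spec.wmh_log_sd,
                                spec.wmh_age_beta)
    wmh = np.exp(log_wmh)
    thickness, u_thick = age_linked(spec.thickness_mean, spec.thickness_sd,
                                    spec.thickness_age_beta)
    hippo, u_hippo = age_linked(spec.hippocampus_mean, spec.hippocampus_sd,
                                spec.hippocampus_age_beta)

    mediator_u = {"wmh_volume": (u_wmh, spec.wmh_age_beta),
                  "cortical_thickness": (u_thick, spec.thickness_age_beta),
                  "hippocampal_volume": (u_hippo, spec.hippocampus_age_beta)}

    table = pd.DataFrame({
        "subject_id": [f"sub-{i:03d}" for i in range(n)],
        "age": age, "sex": sex, "sbp": sbp, "bmi": bmi,
        "diabetes": diabetes, "smoker": smoker,
        "wmh_volume": wmh, "cortical_thickness": thickness,
        "hippocampal_volume": hippo,
    })

    truth: dict = {"beta_age": {}, "cbrt_center": {}, "cbrt_scale": {},
                   "mediator": spec.mediator}
    for roi in KI_COLUMNS:
        beta = spec.beta_age[roi]
        c = np.cbrt(spec.ki_median[roi])
        p25, p75 = spec.ki_quartiles[roi]
        s = (np.cbrt(p75) - np.cbrt(p25)) / 1.349 * spec.ki_noise_scale
        eps = rng.normal(0, 1, n)
        if spec.mediator is None:
            resid = max(0.0, 1 - beta**2 - spec.beta_sex**2)
            u = (beta * z_age + spec.beta_sex * z_sex
                 + np.sqrt(resid) * eps)
        else:
            u_m, a = mediator_u[spec.mediator]
            bm = beta / a
            if not (-1 < bm < 1):
                raise ValueError(
                    f"mediated loading beta/a = {bm:.3f} outside (-1, 1); "
                    "increase the mediator's age slope")
            u = bm * _zscore(u_m) + np.sqrt(1 - bm**2) * eps
        y = c + s * u
        table[KI_COLUMNS[roi]] = y**3
        truth["beta_age"][roi] = beta
        truth["cbrt_center"][roi] = c
        truth["cbrt_scale"][roi] = s
    return table, truth
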