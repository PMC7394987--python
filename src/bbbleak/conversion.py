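"""Signal-to-concentration conversion and dual-time series merging.

Dynamic signal is converted to gadolinium concentration in two different
ways, mirroring how tissue and blood are handled in practice:

* **Tissue** — the saturation-recovery signal equation is inverted
  analytically.  With a saturation delay TD and pre-contrast relaxation
  rate ``R10 = 1/T10``, the signal is ``S = S0 (1 - exp(-TD R1))``, so

  ``R1 = -ln(1 - (S/S_base) (1 - exp(-TD R10))) / TD``

  and the concentration follows the linear relaxivity relation
  ``C = (R1 - R10) / r1``.

* **Blood** — the sinus signal-enhancement ratio is mapped to blood
  concentration through a monotone in-vitro calibration curve and then
  converted from whole blood to plasma with a hematocrit correction
  ``Cp = Cb / (1 - Hct)``.

The fast and slow sequences are finally merged into one strictly
time-ordered concentration series: fast samples cover the bolus passage,
slow samples the leakage phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "DynamicSeries",
    "CalibrationCurve",
    "VascularInputFunction",
    "ConcentrationSeries",
    "DEFAULT_HEMATOCRIT",
    "signal_to_r1",
    "r1_to_concentration",
    "extract_vif",
    "convert_series",
    "tissue_concentration",
    "merge_dual_time",
]

#: Default hematocrit used for the blood-to-plasma conversion.
DEFAULT_HEMATOCRIT = 0.45


@dataclass
class DynamicSeries:
    """A 4D dynamic signal series (x, y, z, t) with acquisition times.

    ``times_s`` are seconds on the subject's common clock (t = 0 at the
    first acquired volume of the whole session).  ``role`` is ``"fast"`` or
    ``"slow"``; ``n_precontrast`` volumes at the start of the series were
    acquired before contrast arrival and define the baseline.
    """

    data: np.ndarray
    times_s: np.ndarray
    role: str
    n_precontrast: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D, got ndim={self.data.ndim}")
        if self.data.shape[-1] != self.times_s.size:
            raise ValueError(
                f"time axis length {self.data.shape[-1]} != "
                f"{self.times_s.size} time stamps")
        if np.any(np.diff(self.times_s) <= 0):
            i = int(np.argmax(np.diff(self.times_s) <= 0))
            raise ValueError(
                f"time stamps must be strictly increasing; violation at "
                f"index {i + 1}")
        if self.role not in ("fast", "slow"):
            raise ValueError(f"role must be 'fast' or 'slow', got {self.role!r}")
        if not (1 <= self.n_precontrast < self.times_s.size):
            raise ValueError(
                f"n_precontrast must be in [1, {self.times_s.size - 1}], "
                f"got {self.n_precontrast}")

    @property
    def n_volumes(self) -> int:
        return self.times_s.size

    def baseline(self) -> np.ndarray:
        """Per-voxel mean of the pre-contrast volumes."""
        return self.data[..., : self.n_precontrast].mean(axis=-1)


@dataclass
class CalibrationCurve:
    """In-vitro mapping from signal-enhancement ratio to blood concentration.

    The curve pairs a dimensionless enhancement ratio ``S/S_pre`` with a
    whole-blood gadolinium concentration (mM).  It must be strictly monotone
    increasing and include the zero-concentration point (ratio 1 at 0 mM).
    Inversion uses monotone piecewise-cubic (PCHIP) interpolation.
    """

    concentrations_mM: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations_mM = np.asarray(self.concentrations_mM, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.concentrations_mM.shape != self.ratios.shape:
            raise ValueError("concentration and ratio arrays differ in shape")
        order = np.argsort(self.concentrations_mM)
        self.concentrations_mM = self.concentrations_mM[order]
        self.ratios = self.ratios[order]
        if np.any(np.diff(self.concentrations_mM) <= 0):
            raise ValueError("calibration concentrations must be distinct")
        if np.any(np.diff(self.ratios) <= 0):
            raise ValueError("calibration curve must be strictly monotone "
                             "increasing in concentration")
        if self.concentrations_mM[0] > 0:
            raise ValueError("calibration curve must include the "
                             "zero-concentration point")

    @classmethod
    def from_saturation_recovery(
        cls,
        blood_t10_ms: float,
        td_ms: float,
        relaxivity: float,
        concentrations_mM: np.ndarray | None = None,
    ) -> "CalibrationCurve":
        """Build a calibration table from the saturation-recovery law.

        Emulates an in-vitro phantom whose baseline T1 matches blood: the
        ratio at concentration C is
        ``(1 - exp(-TD (R10 + r1 C))) / (1 - exp(-TD R10))``.
        """
        if concentrations_mM is None:
            concentrations_mM = np.concatenate(
                [[0.0], np.geomspace(0.05, 40.0, 60)])
        c = np.asarray(concentrations_mM, dtype=float)
        td_s = td_ms / 1000.0
        r10 = 1000.0 / blood_t10_ms
        ratio = (1.0 - np.exp(-td_s * (r10 + relaxivity * c))) / (
            1.0 - np.exp(-td_s * r10))
        return cls(c, ratio)

    def ratio_to_concentration(
        self, ratio: np.ndarray, extrapolate: bool = False
    ) -> np.ndarray:
        """Invert the curve: enhancement ratio -> blood concentration (mM).

        Ratios outside the calibrated range are refused unless
        ``extrapolate`` is set, in which case linear extrapolation from the
        nearest segment is used.
        """
        ratio = np.asarray(ratio, dtype=float)
        lo, hi = self.ratios[0], self.ratios[-1]
        out_of_range = (ratio < lo) | (ratio > hi)
        if np.any(out_of_range) and not extrapolate:
            bad = float(ratio[out_of_range].flat[0])
            raise ValueError(
                f"enhancement ratio {bad:.4g} outside calibration range "
                f"[{lo:.4g}, {hi:.4g}]; pass extrapolate=True to allow "
                "linear extrapolation")
        # PCHIP on (ratio -> concentration); monotone because the forward
        # curve is strictly monotone.
        interp = PchipInterpolator(self.ratios, self.concentrations_mM,
                                   extrapolate=False)
        conc = interp(np.clip(ratio, lo, hi))
        if extrapolate and np.any(out_of_range):
            slope_lo = ((self.concentrations_mM[1] - self.concentrations_mM[0])
                        / (self.ratios[1] - self.ratios[0]))
            slope_hi = ((self.concentrations_mM[-1] - self.concentrations_mM[-2])
                        / (self.ratios[-1] - self.ratios[-2]))
            conc = np.where(ratio < lo,
                            self.concentrations_mM[0] + slope_lo * (ratio - lo),
                            conc)
            conc = np.where(ratio > hi,
                            self.concentrations_mM[-1] + slope_hi * (ratio - hi),
                            conc)
        return conc


@dataclass
class VascularInputFunction:
    """Plasma contrast concentration over time in a draining vessel.

    ``cp_mM`` is plasma (not whole-blood) concentration; ``n_voxels`` is the
    number of sinus voxels averaged to form the curve.
    """

    times_s: np.ndarray
    cp_mM: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.cp_mM = np.asarray(self.cp_mM, dtype=float)
        if self.times_s.shape != self.cp_mM.shape:
            raise ValueError("times and cp arrays differ in shape")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("VIF time stamps must be strictly increasing")
        if not np.all(np.isfinite(self.cp_mM)):
            raise ValueError("VIF concentrations must be finite")


@dataclass
class ConcentrationSeries:
    """4D tissue concentration (mM) with merged time stamps and provenance.

    ``provenance`` holds the originating sequence role per time point
    (``"fast"`` or ``"slow"``).  Voxels outside the brain mask are NaN.
    """

    data: np.ndarray
    times_s: np.ndarray
    provenance: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.provenance = np.asarray(self.provenance)
        if self.data.ndim != 4:
            raise ValueError("concentration data must be 4D")
        if self.data.shape[-1] != self.times_s.size:
            raise ValueError("time axis length mismatch")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("merged time stamps must be strictly increasing")
        if self.provenance.shape != self.times_s.shape:
            raise ValueError("provenance must have one flag per time point")


def signal_to_r1(
    signal: np.ndarray,
    baseline_signal: np.ndarray,
    r10: np.ndarray | float,
    td_ms: float,
    ceiling: float = 0.999,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the saturation-recovery signal equation to R1 (s^-1).

    Parameters
    ----------
    signal
        Measured signal, any shape broadcastable with ``baseline_signal``.
    baseline_signal
        Pre-contrast signal of the same voxel(s); must be positive.
    r10
        Pre-contrast longitudinal relaxation rate (s^-1).
    td_ms
        Saturation delay (ms).
    ceiling
        Noise can push the measured signal above the saturation-recovery
        ceiling, where the log argument would be non-positive.  Such points
        have their saturation argument clamped to ``ceiling`` (< 1) and are
        flagged; no non-finite value is ever produced.

    Returns
    -------
    r1 : ndarray
        Longitudinal relaxation rate (s^-1); equals ``r10`` where the
        signal equals the baseline.
    clamped : ndarray of bool
        Mask of points that hit the saturation ceiling.
    """
    if td_ms <= 0:
        raise ValueError(f"td_ms must be positive, got {td_ms}")
    if not (0 < ceiling < 1):
        raise ValueError(f"ceiling must lie in (0, 1), got {ceiling}")
    baseline_signal = np.asarray(baseline_signal, dtype=float)
    if np.any(baseline_signal <= 0):
        raise ValueError("baseline signal must be strictly positive")
    td_s = td_ms / 1000.0
    r10 = np.asarray(r10, dtype=float)
    sat0 = 1.0 - np.exp(-td_s * r10)  # pre-contrast saturation factor
    arg = (np.asarray(signal, dtype=float) / baseline_signal) * sat0
    clamped = arg >= ceiling
    arg = np.where(clamped, ceiling, arg)
    r1 = -np.log1p(-arg) / td_s
    return r1, clamped


def r1_to_concentration(
    r1: np.ndarray, r10: np.ndarray | float, relaxivity: float
) -> np.ndarray:
    """Linear relaxivity relation ``C = (R1 - R10) / r1_relaxivity`` (mM).

    Negative concentrations are deliberately retained: they encode noise
    and are required by the downstream histogram noise correction.
    """
    if relaxivity <= 0:
        raise ValueError(f"relaxivity must be positive, got {relaxivity}")
    return (np.asarray(r1, dtype=float) - np.asarray(r10, dtype=float)) / relaxivity


def _series_vif_curve(
    series: DynamicSeries,
    sinus_mask: np.ndarray,
    calibration: CalibrationCurve,
    hematocrit: float,
    extrapolate: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean sinus curve of one series, mapped to plasma concentration."""
    sig = series.data[sinus_mask, :]            # (n_voxels, t)
    mean_sig = sig.mean(axis=0)
    base = mean_sig[: series.n_precontrast].mean()
    if base <= 0:
        raise ValueError("non-positive pre-contrast sinus signal")
    ratio = mean_sig / base
    cb = calibration.ratio_to_concentration(ratio, extrapolate=extrapolate)
    cp = cb / (1.0 - hematocrit)
    return series.times_s.copy(), cp


def extract_vif(
    fast_series: DynamicSeries,
    sinus_mask: np.ndarray,
    calibration: CalibrationCurve,
    min_voxels: int = 20,
    slow_series: DynamicSeries | None = None,
    hematocrit: float = DEFAULT_HEMATOCRIT,
    extrapolate: bool = False,
) -> VascularInputFunction:
    """Extract the vascular input function from sagittal-sinus voxels.

    The signal of the masked voxels is averaged per time point, expressed
    as an enhancement ratio relative to the pre-contrast mean, mapped to
    whole-blood concentration through the monotone calibration curve, and
    divided by ``1 - hematocrit`` to yield plasma concentration.

    When ``slow_series`` is given its sinus curve (own baseline) extends
    the VIF beyond the fast sequence, so the Patlak design can cover the
    whole leakage phase without extrapolation.
    """
    sinus_mask = np.asarray(sinus_mask, dtype=bool)
    n = int(sinus_mask.sum())
    if n < min_voxels:
        raise ValueError(
            f"sinus mask has too few voxels: {n} < {min_voxels}")
    if not (0 <= hematocrit < 1):
        raise ValueError(f"hematocrit must lie in [0, 1), got {hematocrit}")
    times, cp = _series_vif_curve(
        fast_series, sinus_mask, calibration, hematocrit, extrapolate)
    if slow_series is not None:
        t_s, cp_s = _series_vif_curve(
            slow_series, sinus_mask, calibration, hematocrit, extrapolate)
        keep = (t_s < times[0]) | (t_s > times[-1])
        times = np.concatenate([times, t_s[keep]])
        cp = np.concatenate([cp, cp_s[keep]])
        order = np.argsort(times, kind="stable")
        times, cp = times[order], cp[order]
    return VascularInputFunction(times, cp, n)


def convert_series(
    series: DynamicSeries,
    t10_ms: np.ndarray,
    relaxivity: float,
    brain_mask: np.ndarray,
    td_ms: float,
    ceiling: float = 0.999,
) -> tuple[np.ndarray, int]:
    """Voxel-wise signal -> concentration for one dynamic series.

    Returns the 4D concentration array (NaN outside the mask) and the
    number of clamped voxel-time points.
    """
    t10_ms = np.asarray(t10_ms, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if t10_ms.shape != series.data.shape[:3] or brain_mask.shape != t10_ms.shape:
        raise ValueError(
            f"grid mismatch: series {series.data.shape[:3]}, "
            f"t10 {t10_ms.shape}, mask {brain_mask.shape}")
    out = np.full(series.data.shape, np.nan)
    if not brain_mask.any():
        warnings.warn("empty brain mask: no voxels converted", stacklevel=2)
        return out, 0
    if np.any(t10_ms[brain_mask] <= 0):
        raise ValueError("T10 must be positive inside the brain mask")
    sig = series.data[brain_mask, :]
    base = sig[:, : series.n_precontrast].mean(axis=1)
    r10 = 1000.0 / t10_ms[brain_mask]
    r1, clamped = signal_to_r1(sig, base[:, None], r10[:, None], td_ms,
                               ceiling=ceiling)
    conc = r1_to_concentration(r1, r10[:, None], relaxivity)
    out[brain_mask, :] = conc
    n_clamped = int(clamped.sum())
    if n_clamped:
        warnings.warn(f"{n_clamped} voxel-time points clamped at the "
                      "saturation ceiling", stacklevel=2)
    return out, n_clamped


def tissue_concentration(
    fast: DynamicSeries,
    slow: DynamicSeries,
    t10_ms: np.ndarray,
    relaxivity: float,
    brain_mask: np.ndarray,
    td_ms: float,
    ceiling: float = 0.999,
) -> ConcentrationSeries:
    """Convert both sequences to concentration and merge them in time.

    Each sequence uses its own pre-contrast baseline.  Voxels outside
    ``brain_mask`` are NaN in the output.
    """
    fast_conc, ncf = convert_series(fast, t10_ms, relaxivity, brain_mask,
                                    td_ms, ceiling)
    slow_conc, ncs = convert_series(slow, t10_ms, relaxivity, brain_mask,
                                    td_ms, ceiling)
    fast_cs = ConcentrationSeries(
        fast_conc, fast.times_s, np.full(fast.times_s.size, "fast"),
        n_clamped=ncf)
    slow_cs = ConcentrationSeries(
        slow_conc, slow.times_s, np.full(slow.times_s.size, "slow"),
        n_clamped=ncs)
    return merge_dual_time(fast_cs, slow_cs)


def merge_dual_time(
    fast_conc: ConcentrationSeries, slow_conc: ConcentrationSeries
) -> ConcentrationSeries:
    """Merge fast and slow concentration series into one ordered series.

    Fast points are kept in full; slow points are kept only outside the
    fast sequence's time window (before its first or after its last
    volume).  Slow points whose time stamp coincides exactly with a fast
    point are dropped with a warning.  The result is strictly increasing
    in time with per-point provenance flags.
    """
    if slow_conc.times_s.size == 0:
        return fast_conc
    if fast_conc.times_s.size == 0:
        return slow_conc
    if fast_conc.data.shape[:3] != slow_conc.data.shape[:3]:
        raise ValueError(
            f"grid mismatch: fast {fast_conc.data.shape[:3]} vs "
            f"slow {slow_conc.data.shape[:3]}")
    t_fast = fast_conc.times_s
    dup = np.isin(slow_conc.times_s, t_fast)
    if dup.any():
        warnings.warn(f"dropping {int(dup.sum())} slow time points that "
                      "coincide with fast time stamps", stacklevel=2)
    keep = (~dup) & ((slow_conc.times_s < t_fast[0])
                     | (slow_conc.times_s > t_fast[-1]))
    times = np.concatenate([t_fast, slow_conc.times_s[keep]])
    data = np.concatenate([fast_conc.data, slow_conc.data[..., keep]], axis=-1)
    prov = np.concatenate([fast_conc.provenance, slow_conc.provenance[keep]])
    order = np.argsort(times, kind="stable")
    return ConcentrationSeries(
        data[..., order], times[order], prov[order],
        n_clamped=fast_conc.n_clamped + slow_conc.n_clamped)
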