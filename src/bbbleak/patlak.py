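"""Voxel-wise Patlak estimation of the BBB leakage rate Ki.

The Patlak model describes irreversible tracer uptake with no reflux from
tissue back to blood:

    Ct(t) = Ki * integral_0^t Cp(tau) dtau  +  vp * Cp(t)

with Ct and Cp in mM, Ki in min^-1 and vp a dimensionless plasma volume
fraction.  Estimation uses the bilinear ordinary-least-squares form (Ct
regressed on the running plasma integral and on Cp directly) rather than
the classical graphical ratio plot; the two are algebraically equivalent
but the bilinear form is numerically stable when Cp is small.

Negative Ki estimates are retained by contract: the downstream histogram
noise correction requires the noise distribution around zero intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .conversion import ConcentrationSeries, VascularInputFunction

__all__ = ["PatlakDesign", "LeakageMap", "build_design",
           "fit_patlak_voxel", "fit_patlak_map"]

#: Sentinel marking voxels whose design was rank-deficient or whose data
#: were unusable; excluded from all downstream summaries.
SENTINEL = np.nan


@dataclass
class PatlakDesign:
    """Regressors of the Patlak model at the tissue sampling times.

    ``cp_mM`` is plasma concentration resampled to the tissue times,
    ``cp_integral_mM_min`` its running trapezoid integral in mM*min, and
    ``usable`` masks the post-bolus points that enter the fit.
    """

    times_s: np.ndarray
    cp_mM: np.ndarray
    cp_integral_mM_min: np.ndarray
    usable: np.ndarray

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def matrix(self) -> np.ndarray:
        """The (n_usable, 2) design matrix [integral, Cp]."""
        return np.column_stack([self.cp_integral_mM_min[self.usable],
                                self.cp_mM[self.usable]])


@dataclass
class LeakageMap:
    """Voxel-wise Patlak estimates with fit diagnostics.

    ``ki`` (min^-1, negative values permitted), ``vp`` (fraction) and
    ``resid_sd`` (mM) are NaN outside the fitted mask and at flagged
    voxels.  ``dof`` is the residual degrees of freedom of each fit.
    """

    ki: np.ndarray
    vp: np.ndarray
    resid_sd: np.ndarray
    dof: int
    n_fitted: int = 0
    n_flagged: int = 0


def detect_bolus_arrival(cp: np.ndarray, frac_of_peak: float = 0.05) -> int:
    """Index of the first sample where Cp exceeds ``frac_of_peak`` * peak."""
    cp = np.asarray(cp, dtype=float)
    peak = cp.max()
    if peak <= 0:
        return cp.size  # no bolus anywhere
    above = np.nonzero(cp > frac_of_peak * peak)[0]
    return int(above[0]) if above.size else cp.size


def build_design(
    vif: VascularInputFunction,
    tissue_times_s: np.ndarray,
    cp_floor_mM: float = 0.0,
    bolus_frac: float = 0.05,
    time_unit: str = "s",
) -> PatlakDesign:
    """Resample the VIF to the tissue times and build Patlak regressors.

    Cp is linearly interpolated inside the VIF's coverage (extrapolation
    beyond it is refused), the running integral uses the trapezoid rule
    converted to mM*min, and the usable mask keeps points from the
    detected bolus arrival onward (first sample with
    ``Cp > max(cp_floor_mM, bolus_frac * peak)``).

    ``time_unit`` declares the unit of ``tissue_times_s`` and of the VIF
    time stamps ("s" or "min"); Ki downstream is in min^-1 either way.
    """
    scale = {"s": 1.0 / 60.0, "min": 1.0}.get(time_unit)
    if scale is None:
        raise ValueError(f"time_unit must be 's' or 'min', got {time_unit!r}")
    t = np.asarray(tissue_times_s, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("tissue times must be strictly increasing")
    if t[0] < vif.times_s[0] - 1e-9 or t[-1] > vif.times_s[-1] + 1e-9:
        raise ValueError(
            f"tissue times [{t[0]:.3g}, {t[-1]:.3g}] exceed VIF coverage "
            f"[{vif.times_s[0]:.3g}, {vif.times_s[-1]:.3g}]; "
            "extrapolation is not permitted")
    cp = np.interp(t, vif.times_s, vif.cp_mM)
    integral = np.concatenate(
        [[0.0], cumulative_trapezoid(cp, t)]) * scale
    floor = max(cp_floor_mM, bolus_frac * cp.max()) if cp.max() > 0 else np.inf
    usable = np.zeros(t.size, dtype=bool)
    first = np.nonzero(cp > floor)[0]
    if first.size:
        usable[int(first[0]):] = True
    return PatlakDesign(t, cp, integral, usable)


def fit_patlak_voxel(
    ct_mM: np.ndarray, design: PatlakDesign
) -> tuple[float, float, float]:
    """OLS Patlak fit for a single voxel's concentration curve.

    Returns ``(ki_per_min, vp, resid_sd_mM)``.  Rank-deficient designs
    (Cp proportional to its own integral over the usable points) yield
    NaN sentinels.  Requires at least 3 usable time points.
    """
    ct = np.asarray(ct_mM, dtype=float)
    if ct.size != design.times_s.size:
        raise ValueError(
            f"ct length {ct.size} != design length {design.times_s.size}")
    if design.n_usable < 3:
        raise ValueError(
            f"need >= 3 usable time points, have {design.n_usable}")
    X = design.matrix()
    y = ct[design.usable]
    if not np.all(np.isfinite(y)):
        return SENTINEL, SENTINEL, SENTINEL
    sol, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        return SENTINEL, SENTINEL, SENTINEL
    resid = y - X @ sol
    resid_sd = float(np.sqrt(resid @ resid / (y.size - 2)))
    return float(sol[0]), float(sol[1]), resid_sd


def fit_patlak_map(
    conc: ConcentrationSeries,
    vif: VascularInputFunction,
    brain_mask: np.ndarray,
    cp_floor_mM: float = 0.0,
    bolus_frac: float = 0.05,
) -> LeakageMap:
    """Fit the Patlak model in every voxel of ``brain_mask``.

    All voxels share the same design (the VIF does not vary spatially),
    so the fit is a single least-squares solve over the voxel matrix.
    Voxels with non-finite concentrations are flagged with NaN sentinels
    and counted.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != conc.data.shape[:3]:
        raise ValueError(
            f"grid mismatch: mask {brain_mask.shape} vs "
            f"series {conc.data.shape[:3]}")
    if not brain_mask.any():
        raise ValueError("empty brain mask")
    design = build_design(vif, conc.times_s, cp_floor_mM, bolus_frac)
    if design.n_usable < 3:
        raise ValueError(
            f"need >= 3 usable time points, have {design.n_usable}")
    X = design.matrix()
    Y = conc.data[brain_mask][:, design.usable]      # (n_voxels, n_usable)
    finite = np.all(np.isfinite(Y), axis=1)
    shape = brain_mask.shape
    ki = np.full(shape, np.nan)
    vp = np.full(shape, np.nan)
    resid_sd = np.full(shape, np.nan)
    sol, _, rank, _ = np.linalg.lstsq(X, Y[finite].T, rcond=None)
    if rank < 2:
        raise ValueError("rank-deficient Patlak design: Cp is proportional "
                         "to its running integral over the usable points")
    resid = Y[finite].T - X @ sol
    rsd = np.sqrt(np.sum(resid**2, axis=0) / (design.n_usable - 2))
    ki_v = np.full(finite.size, np.nan)
    vp_v = np.full(finite.size, np.nan)
    sd_v = np.full(finite.size, np.nan)
    ki_v[finite], vp_v[finite], sd_v[finite] = sol[0], sol[1], rsd
    ki[brain_mask] = ki_v
    vp[brain_mask] = vp_v
    resid_sd[brain_mask] = sd_v
    n_flagged = int((~finite).sum())
    if n_flagged:
        warnings.warn(f"{n_flagged} voxels flagged (non-finite "
                      "concentrations) and excluded from the fit",
                      stacklevel=2)
    return LeakageMap(ki, vp, resid_sd, dof=design.n_usable - 2,
                      n_fitted=int(finite.sum()), n_flagged=n_flagged)
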