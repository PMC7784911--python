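"""Patlak (uptake) model estimation of Ktrans and vp.

Assuming unidirectional transport of the tracer from blood plasma to the
extravascular extracellular space, tissue concentration follows

    C_t(t) = vp * C_p(t) + Ktrans * integral_0^t C_p(tau) dtau.

Both parameters are estimated per voxel by a no-intercept ordinary least
squares fit in concentration space with regressors C_p(t) and its running
integral — equivalent to the classic graphical (divided) Patlak form on
noiseless data, but without the noise amplification of dividing by C_p.
Estimates are never clipped; physiological plausibility is handled by the
subject-level QC rule, not by constraining the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .kinetics import ConcentrationSeries, VIFCurve

__all__ = [
    "PatlakRegressors",
    "PatlakResult",
    "PKMaps",
    "QCVerdict",
    "build_regressors",
    "patlak_fit_voxel",
    "fit_volume",
    "subject_qc",
]


@dataclass
class PatlakRegressors:
    """Design of the uptake-model fit: C_p(t) and its running integral.

    ``cp`` is zeroed before the bolus dynamic (the model sees no tracer before
    injection); ``cp_integral`` is the cumulative trapezoid of that curve.
    ``fit_window`` holds the 0-based frame indices entering the fit.
    """

    times: np.ndarray          # minutes
    cp: np.ndarray             # mM, pre-bolus frames zeroed
    cp_integral: np.ndarray    # mM * min
    fit_window: np.ndarray     # 0-based indices

    def __post_init__(self) -> None:
        if not (self.times.size == self.cp.size == self.cp_integral.size):
            raise ValueError("times, cp and cp_integral must have equal length")
        if self.fit_window.size < 3:
            raise ValueError("fit window must contain at least 3 frames")

    @property
    def design(self) -> np.ndarray:
        """(n_window, 2) design matrix: columns [cp, cp_integral]."""
        return np.stack(
            [self.cp[self.fit_window], self.cp_integral[self.fit_window]], axis=1
        )


@dataclass
class PatlakResult:
    """Single-voxel uptake-model estimates."""

    ktrans: float              # min^-1
    vp: float                  # fraction
    r_squared: float
    n_points: int
    reason: str | None = None  # set when the fit is missing/degenerate


@dataclass
class QCVerdict:
    """Subject-level physiological plausibility verdict for a PK map set."""

    passed: bool
    reasons: list[str] = field(default_factory=list)
    median_vp: float = float("nan")
    frac_vp_gt1: float = float("nan")
    n_voxels: int = 0


@dataclass
class PKMaps:
    """Voxelwise Ktrans (min^-1) and vp (fraction) fields with fit quality.

    Values are NaN outside the brain mask and at unfitted voxels; unfitted
    voxels are tallied by reason in ``reason_counts``.
    """

    ktrans: np.ndarray
    vp: np.ndarray
    r_squared: np.ndarray
    mask: np.ndarray
    reason_counts: dict[str, int] = field(default_factory=dict)
    qc: QCVerdict | None = None


def build_regressors(vif: VIFCurve, fit_window: np.ndarray | None = None) -> PatlakRegressors:
    """Build the uptake-model regressors from a plasma input function.

    Pre-bolus frames of ``cp`` are set to zero before integrating (no tracer
    is present before injection; pre-bolus samples are measurement noise).
    The default fit window runs from the bolus dynamic to the series end.
    """
    cp = np.asarray(vif.cp, dtype=float).copy()
    cp[: vif.bolus_dynamic - 1] = 0.0
    integral = cumulative_trapezoid(cp, vif.times, initial=0.0)
    if fit_window is None:
        fit_window = np.arange(vif.bolus_dynamic - 1, vif.times.size)
    fit_window = np.asarray(fit_window, dtype=int)
    if fit_window.size and (
        fit_window.min() < vif.bolus_dynamic - 1 or fit_window.max() >= vif.times.size
    ):
        raise ValueError(
            "fit window must start at or after the bolus dynamic and stay in range"
        )
    return PatlakRegressors(
        times=np.asarray(vif.times, dtype=float),
        cp=cp,
        cp_integral=integral,
        fit_window=fit_window,
    )


def patlak_fit_voxel(ct: np.ndarray, reg: PatlakRegressors) -> PatlakResult:
    """No-intercept OLS fit of one tissue curve to the uptake model.

    Returns estimates with ``reason`` set (and NaN values) when the design is
    degenerate (C_p identically zero over the window) or the curve contains
    non-invertible (NaN) frames in the window.
    """
    ct = np.asarray(ct, dtype=float)
    if ct.size != reg.times.size:
        raise ValueError("tissue curve length must match regressors")
    y = ct[reg.fit_window]
    x = reg.design
    n = int(reg.fit_window.size)
    if not np.all(np.isfinite(y)):
        return PatlakResult(np.nan, np.nan, np.nan, n, reason="non_invertible_frames")
    if not np.any(x[:, 0] != 0.0):
        return PatlakResult(np.nan, np.nan, np.nan, n, reason="degenerate_design")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float((resid**2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    return PatlakResult(ktrans=float(beta[1]), vp=float(beta[0]), r_squared=r2, n_points=n)


def fit_volume(
    conc: ConcentrationSeries,
    vif: VIFCurve,
    mask: np.ndarray,
    fit_window: np.ndarray | None = None,
) -> PKMaps:
    """Voxelwise uptake-model fit over a brain mask.

    Every masked voxel with a valid T1 fit and fully invertible window frames
    is fitted (vectorised normal-equations solve; voxels are independent, so
    ordering is immaterial). Unfitted voxels stay NaN and are counted by
    reason. Masked-out voxels carry NaN, never zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != conc.grid_shape:
        raise ValueError(
            f"grid mismatch: concentration {conc.grid_shape} vs mask {mask.shape}"
        )
    if not mask.any():
        raise ValueError("brain mask is empty")
    reg = build_regressors(vif, fit_window)
    x = reg.design
    if not np.any(x[:, 0] != 0.0):
        raise ValueError("degenerate design: cp is identically zero over the fit window")

    grid = conc.grid_shape
    ktrans = np.full(grid, np.nan)
    vp = np.full(grid, np.nan)
    r2 = np.full(grid, np.nan)
    reasons: dict[str, int] = {}

    fit_mask = mask & conc.valid
    reasons["invalid_t1"] = int((mask & ~conc.valid).sum())

    y_all = conc.concentration[fit_mask, :][:, reg.fit_window]     # (n_vox, n_w)
    finite = np.all(np.isfinite(y_all), axis=1)
    reasons["non_invertible_frames"] = int((~finite).sum())

    if finite.any():
        y = y_all[finite].T                                        # (n_w, n_vox)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        sse = (resid**2).sum(axis=0)
        sst = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_flat = np.where(sst > 0, 1.0 - sse / sst, np.where(sse == 0, 1.0, -np.inf))
        idx = np.zeros(int(fit_mask.sum()), dtype=bool)
        idx[finite] = True
        sel = np.zeros(grid, dtype=bool)
        sel[fit_mask] = idx
        vp[sel] = beta[0]
        ktrans[sel] = beta[1]
        r2[sel] = r2_flat

    return PKMaps(ktrans=ktrans, vp=vp, r_squared=r2, mask=mask, reason_counts=reasons)


def subject_qc(
    maps: PKMaps,
    mask: np.ndarray | None = None,
    median_vp_range: tuple[float, float] = (0.0, 0.1),
    max_frac_vp_gt1: float = 0.10,
) -> QCVerdict:
    """Physiological plausibility check on a subject's plasma-volume map.

    Fails when the masked median vp falls outside ``median_vp_range``
    (open below, closed above) or when more than ``max_frac_vp_gt1`` of masked
    voxels have vp > 1 (a volume fraction cannot exceed unity). Thresholds are
    declared here and overridable; the verdict is attached to the maps.
    """
    if mask is None:
        mask = maps.mask
    vals = maps.vp[np.asarray(mask, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    verdict = QCVerdict(passed=True, n_voxels=int(vals.size))
    if vals.size == 0:
        verdict.passed = False
        verdict.reasons.append("no fitted voxels")
        maps.qc = verdict
        return verdict
    verdict.median_vp = float(np.median(vals))
    verdict.frac_vp_gt1 = float(np.mean(vals > 1.0))
    lo, hi = median_vp_range
    if not (lo < verdict.median_vp <= hi):
        verdict.passed = False
        verdict.reasons.append(
            f"median vp {verdict.median_vp:.4g} outside ({lo}, {hi}]"
        )
    if verdict.frac_vp_gt1 > max_frac_vp_gt1:
        verdict.passed = False
        verdict.reasons.append(
            f"vp>1 fraction {verdict.frac_vp_gt1:.3f} exceeds {max_frac_vp_gt1}"
        )
    maps.qc = verdict
    return verdict
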