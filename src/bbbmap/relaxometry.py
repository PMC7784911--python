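"""Spoiled gradient-echo (SPGR / T1-FFE) signal model and variable-flip-angle T1 mapping.

The steady-state SPGR signal at flip angle :math:`\\alpha` and repetition time TR is

.. math::

    S = M_0 \\sin(\\theta) \\frac{1 - E_1}{1 - \\cos(\\theta) E_1},
    \\qquad E_1 = e^{-TR/T_1}, \\quad \\theta = b_1 \\alpha,

where :math:`b_1` is the transmit-field scale (actual/nominal flip-angle ratio).
Pre-contrast T1 and M0 are estimated voxelwise from images acquired at two or
more flip angles by the linearised (DESPOT1-style) fit of
:math:`y = S/\\sin\\theta` against :math:`x = S/\\tan\\theta`, whose slope is
:math:`E_1` and intercept :math:`M_0 (1 - E_1)`.

Units: T1 in seconds, TR in milliseconds, flip angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VFAStack",
    "B1Map",
    "T1M0Maps",
    "spgr_signal",
    "effective_flip",
    "fit_vfa_t1",
]


@dataclass
class VFAStack:
    """Pre-contrast SPGR images acquired at multiple nominal flip angles.

    Parameters
    ----------
    signals : ndarray, shape (n_angles, nx, ny, nz)
        One 3D magnitude image per flip angle, in acquisition order matching
        ``flip_angles``.
    flip_angles : ndarray, shape (n_angles,)
        Nominal flip angles in degrees.
    repetition_time : float
        TR in milliseconds.
    """

    signals: np.ndarray
    flip_angles: np.ndarray
    repetition_time: float

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.flip_angles = np.asarray(self.flip_angles, dtype=float)
        if self.signals.ndim != 4:
            raise ValueError("signals must be 4D: (n_angles, nx, ny, nz)")
        if self.signals.shape[0] != self.flip_angles.size:
            raise ValueError("number of signal volumes must match number of flip angles")
        if np.unique(self.flip_angles).size < 2:
            raise ValueError("at least 2 distinct flip angles are required")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be positive")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.signals.shape[1:]


@dataclass
class B1Map:
    """Transmit-field scale map: actual/nominal flip-angle ratio (1.0 = nominal)."""

    scale: np.ndarray

    def __post_init__(self) -> None:
        self.scale = np.asarray(self.scale, dtype=float)


@dataclass
class T1M0Maps:
    """Voxelwise pre-contrast T1 (s) and equilibrium signal M0, with validity flags.

    ``valid`` is False wherever the VFA fit was degenerate (slope outside (0, 1),
    zero signal, or outside the mask); ``t1`` and ``m0`` are NaN there.
    """

    t1: np.ndarray
    m0: np.ndarray
    valid: np.ndarray
    repetition_time: float = field(default=float("nan"))

    @property
    def r1_0(self) -> np.ndarray:
        """Pre-contrast longitudinal relaxation rate 1/T1 (s^-1)."""
        return 1.0 / self.t1


def effective_flip(alpha_nominal, b1):
    """Actual flip angle in degrees: nominal angle scaled by the B1 ratio."""
    b1 = np.asarray(b1, dtype=float)
    if np.any(b1 <= 0):
        raise ValueError("b1 scale must be strictly positive")
    return np.asarray(alpha_nominal, dtype=float) * b1


def spgr_signal(m0, t1, tr, alpha, b1=1.0):
    """Steady-state spoiled gradient-echo signal.

    Parameters
    ----------
    m0 : array_like
        Equilibrium signal (arbitrary units).
    t1 : array_like
        Longitudinal relaxation time in seconds; must be positive.
    tr : float
        Repetition time in milliseconds; must be positive.
    alpha : array_like
        Nominal flip angle in degrees.
    b1 : array_like, optional
        Transmit-field scale; the effective flip is ``b1 * alpha``.

    Returns
    -------
    ndarray or float
        Signal in the units of ``m0``.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be strictly positive")
    if np.any(np.asarray(tr) <= 0):
        raise ValueError("tr must be strictly positive")
    theta = np.deg2rad(effective_flip(alpha, b1))
    e1 = np.exp(-(tr / 1000.0) / t1)
    return np.asarray(m0) * np.sin(theta) * (1.0 - e1) / (1.0 - np.cos(theta) * e1)


def fit_vfa_t1(stack: VFAStack, b1: B1Map, mask: np.ndarray | None = None) -> T1M0Maps:
    """Voxelwise linearised VFA fit of T1 and M0 with B1 correction.

    Per voxel, ordinary least squares of ``y = S/sin(theta)`` on
    ``x = S/tan(theta)`` over flip angles, with ``theta`` the B1-corrected flip.
    The slope estimates E1 = exp(-TR/T1); voxels with slope outside (0, 1) or
    without signal are flagged invalid (NaN maps), never clamped.

    Parameters
    ----------
    stack : VFAStack
    b1 : B1Map
        On the same grid as ``stack``.
    mask : ndarray of bool, optional
        Voxels to fit; defaults to all voxels.
    """
    grid = stack.grid_shape
    if b1.scale.shape != grid:
        raise ValueError(
            f"grid mismatch: VFA stack {grid} vs B1 map {b1.scale.shape}"
        )
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    elif mask.shape != grid:
        raise ValueError(f"grid mismatch: VFA stack {grid} vs mask {mask.shape}")

    s = stack.signals[:, mask]                     # (n_angles, n_vox)
    theta = np.deg2rad(
        effective_flip(stack.flip_angles[:, None], b1.scale[mask][None, :])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        y = s / np.sin(theta)
        x = s / np.tan(theta)

        n = s.shape[0]
        sx, sy = x.sum(0), y.sum(0)
        sxx, sxy = (x * x).sum(0), (x * y).sum(0)
        denom = n * sxx - sx * sx
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n

    ok = (
        np.isfinite(slope)
        & np.isfinite(intercept)
        & (slope > 0.0)
        & (slope < 1.0)
        & (s > 0).any(axis=0)
    )
    tr_s = stack.repetition_time / 1000.0
    t1_flat = np.full(s.shape[1], np.nan)
    m0_flat = np.full(s.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1_flat[ok] = -tr_s / np.log(slope[ok])
        m0_flat[ok] = intercept[ok] / (1.0 - slope[ok])

    t1_map = np.full(grid, np.nan)
    m0_map = np.full(grid, np.nan)
    valid = np.zeros(grid, dtype=bool)
    t1_map[mask] = t1_flat
    m0_map[mask] = m0_flat
    valid[mask] = ok
    return T1M0Maps(t1=t1_map, m0=m0_map, valid=valid, repetition_time=stack.repetition_time)
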