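"""Signal-to-concentration conversion and vascular input function extraction.

The dynamic T1-weighted signal is converted to gadolinium concentration through
the SPGR relaxometric model: the pre-contrast T1 map anchors an effective M0 so
that the model reproduces the measured baseline signal at R1 = 1/T1_pre; each
post-contrast frame is then inverted for R1(t), and

    C(t) = (R1(t) - R1_pre) / r1

with r1 the longitudinal relaxivity of the agent (s^-1 mM^-1). The vascular
input function is taken from a sagittal-sinus ROI: each ROI voxel is converted
to blood concentration, averaged over the ROI per frame, and divided by
(1 - Hct) to give plasma concentration.

Kinetic quantities use minutes; acquisition metadata (frame times, TR) are
stored in seconds/milliseconds and converted at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relaxometry import B1Map, T1M0Maps

__all__ = [
    "DynamicSeries",
    "KineticsConfig",
    "ConcentrationSeries",
    "VIFCurve",
    "baseline_signal",
    "signal_to_concentration",
    "extract_vif",
]


@dataclass
class DynamicSeries:
    """4D dynamic contrast-enhanced series.

    Parameters
    ----------
    signal : ndarray, shape (nx, ny, nz, n_dynamics)
    times : ndarray, shape (n_dynamics,)
        Frame times in seconds from series start; strictly increasing and
        uniformly spaced to within 1%.
    bolus_dynamic : int
        1-based index of the dynamic on which the contrast bolus is injected
        (frames 1 .. bolus_dynamic-1 are pre-contrast baseline).
    flip_angle : float
        Nominal flip angle of the dynamic acquisition, degrees.
    repetition_time : float
        TR in milliseconds.
    """

    signal: np.ndarray
    times: np.ndarray
    bolus_dynamic: int
    flip_angle: float
    repetition_time: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D: (nx, ny, nz, n_dynamics)")
        if self.signal.shape[-1] != self.times.size:
            raise ValueError("time axis length must match times")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if dt.size and (dt.max() - dt.min()) > 0.01 * dt.mean():
            raise ValueError("frame spacing must be uniform to within 1%")
        if not (2 <= self.bolus_dynamic <= self.times.size):
            raise ValueError("bolus_dynamic must satisfy 2 <= bolus_dynamic <= n_dynamics")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.signal.shape[:3]

    @property
    def n_dynamics(self) -> int:
        return self.signal.shape[-1]


@dataclass
class KineticsConfig:
    """Parameters of the relaxometric conversion.

    r1 : longitudinal relaxivity of the contrast agent, s^-1 mM^-1
        (default 3.5, typical of gadoterate at 3 T).
    hematocrit : fraction of whole blood occupied by cells (default 0.42);
        plasma concentration = blood concentration / (1 - hematocrit).
    baseline_window : 0-based dynamic indices averaged for the pre-contrast
        baseline; None means all frames before the bolus dynamic.
    """

    r1: float = 3.5
    hematocrit: float = 0.42
    baseline_window: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise ValueError("relaxivity r1 must be positive")
        if not (0.0 < self.hematocrit < 1.0):
            raise ValueError("hematocrit must lie in (0, 1)")


@dataclass
class ConcentrationSeries:
    """Voxelwise tissue concentration (mM) on a time grid in minutes."""

    concentration: np.ndarray          # (nx, ny, nz, n_dynamics), NaN where non-invertible
    times: np.ndarray                  # minutes from series start
    bolus_time: float                  # minutes
    bolus_dynamic: int                 # 1-based
    valid: np.ndarray                  # 3D bool: voxel had a valid T1 fit
    non_invertible: np.ndarray         # 3D int: frames per voxel exceeding saturation
    negative_frames: np.ndarray | None = None  # 3D int: frames below baseline (flag only)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.concentration.shape[:3]


@dataclass
class VIFCurve:
    """Plasma contrast-concentration time course from a venous ROI."""

    cp: np.ndarray                     # mM
    times: np.ndarray                  # minutes
    bolus_time: float                  # minutes
    bolus_dynamic: int                 # 1-based
    n_roi_voxels: int
    hematocrit_used: float

    def __post_init__(self) -> None:
        self.cp = np.asarray(self.cp, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.cp.size != self.times.size:
            raise ValueError("cp and times must have equal length")
        if self.n_roi_voxels <= 0:
            raise ValueError("n_roi_voxels must be positive")


def baseline_signal(series: DynamicSeries, window: np.ndarray | None = None) -> np.ndarray:
    """Voxelwise mean signal over the pre-contrast window.

    ``window`` holds 0-based dynamic indices; default is every frame before the
    bolus dynamic. Any index at or past the bolus frame is an error.
    """
    if window is None:
        window = np.arange(series.bolus_dynamic - 1)
    window = np.asarray(window, dtype=int)
    if window.size == 0:
        raise ValueError("baseline window is empty")
    if window.max() >= series.bolus_dynamic - 1 or window.min() < 0:
        raise ValueError(
            "baseline window must contain only pre-bolus frames "
            f"(0..{series.bolus_dynamic - 2})"
        )
    return series.signal[..., window].mean(axis=-1)


def signal_to_concentration(
    series: DynamicSeries,
    t1m0: T1M0Maps,
    b1: B1Map,
    cfg: KineticsConfig,
    mask: np.ndarray | None = None,
) -> ConcentrationSeries:
    """Convert a dynamic SPGR series to gadolinium concentration.

    The SPGR equation is inverted frame by frame for E1 = exp(-TR * R1(t)),
    with M0 anchored so the model reproduces the voxel's measured baseline
    signal at R1 = 1/T1_pre. Frames whose signal meets or exceeds the SPGR
    saturation ceiling (M0 sin(theta), the T1 -> 0 limit) are non-invertible
    and set to NaN, with per-voxel counts recorded. Signal below baseline
    yields negative concentration, retained (not clipped) and counted.
    """
    grid = series.grid_shape
    for name, shape in (("T1/M0 maps", t1m0.t1.shape), ("B1 map", b1.scale.shape)):
        if shape != grid:
            raise ValueError(f"grid mismatch: dynamic series {grid} vs {name} {shape}")
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    voxels = mask & t1m0.valid

    s0 = baseline_signal(series, cfg.baseline_window)
    theta = np.deg2rad(series.flip_angle * b1.scale[voxels])     # (n_vox,)
    tr_s = series.repetition_time / 1000.0
    t1 = t1m0.t1[voxels]
    e1_pre = np.exp(-tr_s / t1)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    # effective M0 anchored to the measured baseline at R1 = 1/T1_pre
    m0_eff = s0[voxels] * (1.0 - cos_t * e1_pre) / (sin_t * (1.0 - e1_pre))

    s = series.signal[voxels, :]                                 # (n_vox, n_t)
    ceiling = (m0_eff * sin_t)[:, None]
    denom = s * cos_t[:, None] - ceiling
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (s - ceiling) / denom
    invertible = (e1 > 0.0) & (e1 < 1.0) & (s < ceiling)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1t = -np.log(np.where(invertible, e1, 0.5)) / tr_s
    conc_flat = (r1t - (1.0 / t1)[:, None]) / cfg.r1
    conc_flat[~invertible] = np.nan

    conc = np.full(series.signal.shape, np.nan)
    conc[voxels, :] = conc_flat
    non_inv = np.zeros(grid, dtype=int)
    non_inv[voxels] = (~invertible).sum(axis=1)
    negative = np.zeros(grid, dtype=int)
    negative[voxels] = np.nansum(conc_flat < 0, axis=1)

    times_min = series.times / 60.0
    return ConcentrationSeries(
        concentration=conc,
        times=times_min,
        bolus_time=float(times_min[series.bolus_dynamic - 1]),
        bolus_dynamic=series.bolus_dynamic,
        valid=voxels,
        non_invertible=non_inv,
        negative_frames=negative,
    )


def extract_vif(
    conc: ConcentrationSeries,
    sinus_mask: np.ndarray,
    cfg: KineticsConfig,
) -> VIFCurve:
    """Haematocrit-corrected plasma input function from a venous (sagittal sinus) ROI.

    Each ROI voxel's blood concentration curve is averaged per frame
    (NaN frames excluded), then divided by (1 - Hct). Voxels non-invertible in
    more than half of the frames are an error: the ROI is unusable.
    """
    sinus_mask = np.asarray(sinus_mask, dtype=bool)
    if sinus_mask.shape != conc.grid_shape:
        raise ValueError(
            f"grid mismatch: concentration {conc.grid_shape} vs sinus mask {sinus_mask.shape}"
        )
    n_roi = int(sinus_mask.sum())
    if n_roi == 0:
        raise ValueError("sinus mask is empty")
    n_frames = conc.times.size
    bad = conc.non_invertible[sinus_mask] > 0.5 * n_frames
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} sinus-ROI voxel(s) non-invertible in >50% of frames"
        )
    curves = conc.concentration[sinus_mask, :]
    cb = np.nanmean(curves, axis=0)
    cp = cb / (1.0 - cfg.hematocrit)
    return VIFCurve(
        cp=cp,
        times=conc.times,
        bolus_time=conc.bolus_time,
        bolus_dynamic=conc.bolus_dynamic,
        n_roi_voxels=n_roi,
        hematocrit_used=cfg.hematocrit,
    )
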