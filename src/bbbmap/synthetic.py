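"""Digital DCE-MRI phantoms and synthetic cohorts.

The phantom generator produces everything a subject-level analysis consumes —
a variable-flip-angle stack, a B1 map, a 4D dynamic series, tissue labels and
ground-truth T1/Ktrans/vp maps — by running the same physics the analysis
inverts: an exponential-sum plasma input function, the discrete-time uptake
(Patlak) model for tissue concentration, and the spoiled-gradient-echo signal
equation. The cohort generator emulates the statistical structure of a
three-group (CN / CP / PD) study: subject-by-region parameter means with
between- and within-subject variability, plus demographic and clinical
covariates.

Default acquisition geometry and timing follow a 3 T brain DCE protocol:
160 dynamics at 7.6 s, bolus on the 8th dynamic, VFA flips 2/5/10 degrees,
1.5 x 1.5 x 4 mm voxels, contrast dose 0.1 mmol/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .kinetics import DynamicSeries, KineticsConfig
from .relaxometry import B1Map, VFAStack, spgr_signal

__all__ = [
    "AIFParams",
    "TissueParams",
    "PhantomSpec",
    "PhantomDataset",
    "CohortDesign",
    "population_aif",
    "generate_phantom",
    "generate_cohort",
    "CANONICAL_REGIONS",
]

CANONICAL_REGIONS = ("SN", "CA", "PU", "P", "WML", "NAWM", "FC", "PC")


# --------------------------------------------------------------------------
# population input function
# --------------------------------------------------------------------------

@dataclass
class AIFParams:
    """Exponential-sum model of the whole-blood concentration curve.

    C_b(t) = dose * sum_i amplitudes[i] * exp(-decay_rates[i] * (t - onset))
    for t >= onset_time, zero before. Amplitudes are in mM per (mmol/kg) of
    injected dose; decay rates in 1/min; onset_time in minutes.

    The default is a three-term curve: a fast first-pass term giving a
    realistic ~5 mM plasma peak after a 0.1 mmol/kg bolus, plus Weinmann-type
    distribution and washout terms (3.99 and 4.78 kg/L at 0.144 and
    0.0111 /min).
    """

    onset_time: float = 0.0
    amplitudes: tuple[float, ...] = (21.0, 3.99, 4.78)
    decay_rates: tuple[float, ...] = (1.5, 0.144, 0.0111)
    dose: float = 0.1
    functional_form: str = "exponential-sum-after-onset"

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        m = np.asarray(self.decay_rates, dtype=float)
        if a.size != m.size or a.size == 0:
            raise ValueError("amplitudes and decay_rates must be non-empty, equal length")
        if np.any(m <= 0):
            raise ValueError("decay_rates must be strictly positive")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")


def population_aif(time_grid: np.ndarray, params: AIFParams) -> np.ndarray:
    """Evaluate the blood concentration curve (mM) on a time grid in minutes."""
    t = np.asarray(time_grid, dtype=float)
    if t.size == 0:
        raise ValueError("time grid is empty")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    a = np.asarray(params.amplitudes, dtype=float)
    m = np.asarray(params.decay_rates, dtype=float)
    tt = t - params.onset_time
    curve = params.dose * np.sum(
        a[:, None] * np.exp(-m[:, None] * np.clip(tt, 0.0, None)[None, :]), axis=0
    )
    return np.where(tt >= 0.0, curve, 0.0)


# --------------------------------------------------------------------------
# digital phantom
# --------------------------------------------------------------------------

@dataclass
class TissueParams:
    """Ground-truth parameters of one phantom tissue class."""

    name: str
    t1: float          # s
    ktrans: float      # min^-1
    vp: float          # fraction

    def __post_init__(self) -> None:
        if not (0.0 <= self.vp <= 1.0):
            raise ValueError(f"tissue {self.name!r}: vp must lie in [0, 1]")
        if self.t1 <= 0:
            raise ValueError(f"tissue {self.name!r}: t1 must be positive")


def _default_tissues() -> dict[int, TissueParams]:
    return {
        1: TissueParams("white_matter", t1=0.9, ktrans=1.5e-3, vp=0.010),
        2: TissueParams("grey_matter", t1=1.4, ktrans=2.5e-3, vp=0.030),
        3: TissueParams("lesion", t1=1.2, ktrans=4.0e-3, vp=0.020),
    }


@dataclass
class PhantomSpec:
    """Full specification of a digital DCE phantom.

    ``tissues`` maps integer labels to ground-truth parameters; the label
    ``vif_roi_label`` is a pure-blood compartment (T1 ``blood_t1``) carrying
    the whole-blood input-function signal. ``b1`` may be a scalar or a 3D
    field of transmit-scale values. Noise (``gaussian`` or ``rician``) is
    applied to magnitude signals with per-voxel sigma = baseline signal / SNR.
    """

    grid_shape: tuple[int, int, int] = (20, 20, 8)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 4.0)
    n_dynamics: int = 160
    dt: float = 7.6                      # s
    bolus_dynamic: int = 8               # 1-based
    flip_angles: tuple[float, ...] = (2.0, 5.0, 10.0)
    dynamic_flip: float = 18.0           # deg
    repetition_time: float = 5.0         # ms
    m0: float = 1000.0
    tissues: dict[int, TissueParams] = field(default_factory=_default_tissues)
    vif_roi_label: int = 4
    blood_t1: float = 1.65               # s
    b1: float | np.ndarray = 1.0
    noise_model: str = "none"            # none | gaussian | rician
    snr: float = 20.0
    seed: int = 0
    label_map: np.ndarray | None = None
    aif: AIFParams | None = None
    r1: float = 3.5                      # s^-1 mM^-1
    hematocrit: float = 0.42

    def __post_init__(self) -> None:
        if not (2 <= self.bolus_dynamic <= self.n_dynamics):
            raise ValueError("need n_dynamics >= bolus_dynamic >= 2")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError("noise_model must be none, gaussian or rician")
        if self.noise_model != "none" and self.snr <= 0:
            raise ValueError("SNR must be positive when noise is enabled")
        if self.vif_roi_label in self.tissues:
            raise ValueError("vif_roi_label must not collide with a tissue label")


def _default_label_map(spec: PhantomSpec) -> np.ndarray:
    """Simple geometric layout: a blood slab plus nested tissue blocks."""
    nx, ny, nz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=int)
    tissue_labels = sorted(spec.tissues)
    # blood slab along the first axis (at least one plane, ~10% of x extent)
    n_blood = max(1, nx // 10)
    labels[:n_blood] = spec.vif_roi_label
    # split the remaining x extent evenly among tissue labels
    rest = np.array_split(np.arange(n_blood, nx), len(tissue_labels))
    for lab, idx in zip(tissue_labels, rest):
        if idx.size:
            labels[idx] = lab
    return labels


@dataclass
class PhantomDataset:
    """A generated phantom: acquired-like data plus ground truth."""

    vfa_stack: dict[float, np.ndarray]   # flip angle (deg) -> 3D signal
    b1_map: np.ndarray
    dynamic_series: np.ndarray           # (nx, ny, nz, n_dynamics)
    times: np.ndarray                    # s
    truth_ktrans: np.ndarray
    truth_vp: np.ndarray
    truth_t1: np.ndarray
    label_map: np.ndarray
    manifest: dict

    @property
    def vif_mask(self) -> np.ndarray:
        return self.label_map == self.manifest["vif_roi_label"]

    @property
    def brain_mask(self) -> np.ndarray:
        return (self.label_map > 0) & ~self.vif_mask

    def as_vfa_stack(self) -> VFAStack:
        angles = sorted(self.vfa_stack)
        return VFAStack(
            signals=np.stack([self.vfa_stack[a] for a in angles]),
            flip_angles=np.array(angles),
            repetition_time=self.manifest["repetition_time"],
        )

    def as_b1_map(self) -> B1Map:
        return B1Map(scale=self.b1_map)

    def as_dynamic_series(self) -> DynamicSeries:
        return DynamicSeries(
            signal=self.dynamic_series,
            times=self.times,
            bolus_dynamic=self.manifest["bolus_dynamic"],
            flip_angle=self.manifest["dynamic_flip"],
            repetition_time=self.manifest["repetition_time"],
        )

    def kinetics_config(self) -> KineticsConfig:
        return KineticsConfig(
            r1=self.manifest["r1"], hematocrit=self.manifest["hematocrit"]
        )


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Generate a digital DCE phantom from its specification.

    Tissue concentration follows the discrete-time uptake model
    C_t = vp * C_p + Ktrans * cumtrapz(C_p) on the acquisition time grid,
    with C_p the haematocrit-corrected plasma curve of the blood input
    function; the VIF label carries pure whole-blood signal. All signals go
    through the SPGR forward model with the spec's B1 field. Reproducible
    under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    times_s = np.arange(spec.n_dynamics) * spec.dt
    t_min = times_s / 60.0

    labels = spec.label_map if spec.label_map is not None else _default_label_map(spec)
    labels = np.asarray(labels)
    if labels.shape != tuple(spec.grid_shape):
        raise ValueError("label_map shape must match grid_shape")
    present = set(np.unique(labels).tolist())
    missing = [lab for lab in spec.tissues if lab not in present]
    if missing:
        raise ValueError(f"tissue labels {missing} absent from label_map")

    aif = spec.aif or AIFParams(onset_time=float(t_min[spec.bolus_dynamic - 1]))
    cb = population_aif(t_min, aif)
    cp = cb / (1.0 - spec.hematocrit)
    icp = cumulative_trapezoid(cp, t_min, initial=0.0)

    b1 = np.broadcast_to(np.asarray(spec.b1, dtype=float), spec.grid_shape).copy()

    truth_t1 = np.full(spec.grid_shape, np.nan)
    truth_kt = np.full(spec.grid_shape, np.nan)
    truth_vp = np.full(spec.grid_shape, np.nan)
    dyn = np.zeros(spec.grid_shape + (spec.n_dynamics,))

    # per-class concentration curves -> R1(t) -> SPGR signal
    curves: dict[int, tuple[float, np.ndarray]] = {}
    for lab, tis in spec.tissues.items():
        ct = tis.vp * cp + tis.ktrans * icp
        curves[lab] = (tis.t1, ct)
    if spec.vif_roi_label in present:
        curves[spec.vif_roi_label] = (spec.blood_t1, cb)

    for lab, (t1, conc) in curves.items():
        sel = labels == lab
        if not sel.any():
            continue
        r1t = 1.0 / t1 + spec.r1 * conc                       # (n_t,)
        sig = spgr_signal(
            spec.m0, 1.0 / r1t[None, :], spec.repetition_time,
            spec.dynamic_flip, b1[sel][:, None],
        )
        dyn[sel, :] = sig
        truth_t1[sel] = t1
        if lab in spec.tissues:
            truth_kt[sel] = spec.tissues[lab].ktrans
            truth_vp[sel] = spec.tissues[lab].vp

    vfa: dict[float, np.ndarray] = {}
    for angle in spec.flip_angles:
        vol = np.zeros(spec.grid_shape)
        for lab, (t1, _) in curves.items():
            sel = labels == lab
            vol[sel] = spgr_signal(spec.m0, t1, spec.repetition_time, angle, b1[sel])
        vfa[float(angle)] = vol

    if spec.noise_model != "none":
        sigma = dyn[..., 0] / spec.snr                        # baseline signal / SNR
        def add_noise(img, sig):
            if spec.noise_model == "gaussian":
                return img + rng.normal(0.0, 1.0, img.shape) * sig
            re = img + rng.normal(0.0, 1.0, img.shape) * sig
            im = rng.normal(0.0, 1.0, img.shape) * sig
            return np.sqrt(re**2 + im**2)
        dyn = add_noise(dyn, sigma[..., None])
        vfa = {a: add_noise(v, sigma) for a, v in vfa.items()}

    manifest = {
        "grid_shape": tuple(spec.grid_shape),
        "voxel_size": tuple(spec.voxel_size),
        "n_dynamics": spec.n_dynamics,
        "dt": spec.dt,
        "bolus_dynamic": spec.bolus_dynamic,
        "flip_angles": tuple(float(a) for a in spec.flip_angles),
        "dynamic_flip": spec.dynamic_flip,
        "repetition_time": spec.repetition_time,
        "m0": spec.m0,
        "vif_roi_label": spec.vif_roi_label,
        "blood_t1": spec.blood_t1,
        "noise_model": spec.noise_model,
        "snr": spec.snr if spec.noise_model != "none" else None,
        "seed": spec.seed,
        "r1": spec.r1,
        "hematocrit": spec.hematocrit,
        "aif": {
            "onset_time": aif.onset_time,
            "amplitudes": tuple(aif.amplitudes),
            "decay_rates": tuple(aif.decay_rates),
            "dose": aif.dose,
            "functional_form": aif.functional_form,
        },
        "tissues": {
            lab: {"name": t.name, "t1": t.t1, "ktrans": t.ktrans, "vp": t.vp}
            for lab, t in spec.tissues.items()
        },
    }
    return PhantomDataset(
        vfa_stack=vfa,
        b1_map=b1,
        dynamic_series=dyn,
        times=times_s,
        truth_ktrans=truth_kt,
        truth_vp=truth_vp,
        truth_t1=truth_t1,
        label_map=labels,
        manifest=manifest,
    )


# --------------------------------------------------------------------------
# synthetic cohort
# --------------------------------------------------------------------------

def _default_mean_table() -> dict[str, dict[str, dict[str, float]]]:
    """Regional Ktrans (min^-1) and vp means per group.

    Base profiles sit in the published low-leakage range (Ktrans of order
    1e-3 /min, vp of order 0.01); PD elevates Ktrans mainly in SN, NAWM, WML
    and posterior cortex, CP elevates white-matter Ktrans and runs slightly
    lower vp, mirroring the qualitative group structure of a BBB study.
    """
    base_kt = {"SN": 2.2e-3, "CA": 1.3e-3, "PU": 1.4e-3, "P": 1.6e-3,
               "WML": 3.0e-3, "NAWM": 1.1e-3, "FC": 1.7e-3, "PC": 1.9e-3}
    base_vp = {"SN": 0.012, "CA": 0.015, "PU": 0.016, "P": 0.013,
               "WML": 0.007, "NAWM": 0.008, "FC": 0.018, "PC": 0.020}
    pd_boost = {"SN": 1.25, "NAWM": 1.25, "WML": 1.20, "PC": 1.25}
    cp_boost = {"WML": 1.20, "NAWM": 1.15}
    kt = {
        "CN": dict(base_kt),
        "CP": {r: v * cp_boost.get(r, 1.05) for r, v in base_kt.items()},
        "PD": {r: v * pd_boost.get(r, 1.10) for r, v in base_kt.items()},
    }
    vp = {
        "CN": dict(base_vp),
        "CP": {r: 0.85 * v for r, v in base_vp.items()},
        "PD": dict(base_vp),
    }
    return {"ktrans": kt, "vp": vp}


_TABLE1 = {
    # group -> (MoCA mean, sd), (cube-root WML mean, sd), male fraction, age (mean, sd)
    "CN": {"moca": (27.9, 2.3), "wml_cbrt": (1.26, 0.83), "male": 0.45, "age": (66.0, 7.0)},
    "CP": {"moca": (26.1, 2.9), "wml_cbrt": (2.11, 0.72), "male": 0.70, "age": (67.0, 7.0)},
    "PD": {"moca": (25.2, 3.9), "wml_cbrt": (1.80, 0.95), "male": 0.68, "age": (67.0, 7.0)},
}
_PD_CLINICAL = {"ledd": (583.5, 399.6), "updrs": (29.2, 12.7)}


@dataclass
class CohortDesign:
    """Statistical design of a synthetic three-group cohort.

    Regional means are ``means[metric][group][region]``; each subject draws a
    random between-subject offset per metric (SD ``between_subject_sd``) and
    independent within-subject region-level noise (SD ``within_subject_sd``).
    Covariates follow group-specific distributions (MoCA, LEDD, UPDRS and
    cube-root WML volume centred on the study's printed summary statistics).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"CN": 31, "CP": 15, "PD": 49}
    )
    region_names: tuple[str, ...] = CANONICAL_REGIONS
    means: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=_default_mean_table
    )
    between_subject_sd: dict[str, float] = field(
        default_factory=lambda: {"ktrans": 4.0e-4, "vp": 3.0e-3}
    )
    within_subject_sd: dict[str, float] = field(
        default_factory=lambda: {"ktrans": 3.0e-4, "vp": 2.5e-3}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.region_names) == 0:
            raise ValueError("region list is empty")
        for table in (self.between_subject_sd, self.within_subject_sd):
            if any(v < 0 for v in table.values()):
                raise ValueError("standard deviations must be >= 0")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("each group needs at least 2 subjects")

    def null(self) -> "CohortDesign":
        """Same design with every group sharing the CN means (no group effect)."""
        means = {
            metric: {g: dict(tab["CN"]) for g in tab}
            for metric, tab in self.means.items()
        }
        return replace(self, means=means)

    def with_group_shift(self, metric: str, group: str, n_sd: float) -> "CohortDesign":
        """Add ``n_sd`` between-subject SDs to one group's means, all regions."""
        shift = n_sd * self.between_subject_sd[metric]
        means = {m: {g: dict(t) for g, t in tab.items()} for m, tab in self.means.items()}
        means[metric][group] = {r: v + shift for r, v in means[metric][group].items()}
        return replace(self, means=means)


def generate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Simulate a cohort table: one row per subject x region x metric.

    Columns: subject, group, age, gender, wml_volume (cube of the cube-root
    draw), wml_cuberoot, moca, ledd, updrs, region, metric, value.
    Deterministic under the design's seed.
    """
    rng = np.random.default_rng(design.seed)
    metrics = sorted(design.means)
    rows = []
    for group in sorted(design.group_sizes):
        info = _TABLE1[group]
        for i in range(design.group_sizes[group]):
            sid = f"{group}{i + 1:03d}"
            age = float(np.clip(rng.normal(*info["age"]), 40, 92))
            gender = "M" if rng.random() < info["male"] else "F"
            moca = float(np.clip(np.round(rng.normal(*info["moca"])), 0, 30))
            wml_cbrt = float(max(rng.normal(*info["wml_cbrt"]), 0.05))
            ledd = updrs = np.nan
            if group == "PD":
                ledd = float(max(rng.normal(*_PD_CLINICAL["ledd"]), 0.0))
                updrs = float(max(rng.normal(*_PD_CLINICAL["updrs"]), 1.0))
            offsets = {m: rng.normal(0.0, design.between_subject_sd[m]) for m in metrics}
            for region in design.region_names:
                for metric in metrics:
                    value = (
                        design.means[metric][group][region]
                        + offsets[metric]
                        + rng.normal(0.0, design.within_subject_sd[metric])
                    )
                    rows.append(
                        (sid, group, age, gender, wml_cbrt**3, wml_cbrt,
                         moca, ledd, updrs, region, metric, value)
                    )
    return pd.DataFrame(
        rows,
        columns=["subject", "group", "age", "gender", "wml_volume", "wml_cuberoot",
                 "moca", "ledd", "updrs", "region", "metric", "value"],
    )
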