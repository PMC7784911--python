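"""End-to-end subject and group runs.

``run_subject_arrays`` chains the subject-level analysis in memory
(VFA T1 fit -> concentration -> VIF -> Patlak -> QC -> regional means);
``run_subject`` wraps it with file I/O and provenance sidecars, and
``run_group`` performs the cohort analysis (exclusions, demographics,
repeated-measures ANOVA with and without covariates, post hocs, clinical
mixed model, and optional voxelwise cluster statistics).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .kinetics import (
    DynamicSeries,
    KineticsConfig,
    extract_vif,
    signal_to_concentration,
)
from .patlak import fit_volume, subject_qc
from .regions import ROISet, regional_means
from .relaxometry import B1Map, VFAStack, fit_vfa_t1
from .stats import (
    apply_exclusions,
    clinical_lmm,
    demographic_tests,
    gaussian_smooth,
    permutation_cluster_fwe,
    posthoc_pairwise,
    rm_anova,
)

__all__ = [
    "PipelineConfig",
    "SubjectRecord",
    "run_subject_arrays",
    "run_subject",
    "run_group",
    "ValidationError",
    "QCFailure",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Invalid configuration or missing input (CLI exit code 2)."""


class QCFailure(RuntimeError):
    """Subject failed physiological QC (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """All tunable values of the science path; no hidden defaults downstream."""

    r1: float = 3.5                      # s^-1 mM^-1
    hematocrit: float = 0.42
    fit_window: list[int] | None = None  # 0-based frames; None = bolus..end
    qc_median_vp_range: tuple[float, float] = (0.0, 0.1)
    qc_max_frac_vp_gt1: float = 0.10
    lesion_threshold: float = 0.3
    smooth_fwhm: float = 8.0             # mm, voxelwise analysis
    voxel_p: float = 0.001
    min_extent: int = 50
    n_perm: int = 199
    covariates: tuple[str, ...] = ("age", "gender", "wml_cuberoot")
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.qc_median_vp_range, list):
            cfg.qc_median_vp_range = tuple(cfg.qc_median_vp_range)
        if isinstance(cfg.covariates, list):
            cfg.covariates = tuple(cfg.covariates)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc_median_vp_range"] = list(self.qc_median_vp_range)
        d["covariates"] = list(self.covariates)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def kinetics(self) -> KineticsConfig:
        return KineticsConfig(r1=self.r1, hematocrit=self.hematocrit)

    def write_template(self, path) -> Path:
        """Write this configuration as a YAML template (all values explicit)."""
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


@dataclass
class SubjectRecord:
    """Paths and metadata of one subject's inputs.

    ``vfa_paths`` maps flip angle (deg) to a NIfTI path; ``meta`` must hold
    ``times`` (s), ``bolus_dynamic`` (1-based), ``flip_angle`` (deg) and
    ``repetition_time`` (ms) for the dynamic series.
    """

    subject: str
    group: str
    vfa_paths: dict[float, str] = field(default_factory=dict)
    b1_path: str = ""
    dynamic_path: str = ""
    meta_path: str = ""
    brain_mask_path: str = ""
    sinus_mask_path: str = ""
    roi_paths: dict[str, str] = field(default_factory=dict)
    demographics: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def validate(self) -> None:
        required = {
            "b1_path": self.b1_path,
            "dynamic_path": self.dynamic_path,
            "meta_path": self.meta_path,
            "brain_mask_path": self.brain_mask_path,
            "sinus_mask_path": self.sinus_mask_path,
        }
        for angle, p in self.vfa_paths.items():
            required[f"vfa_paths[{angle}]"] = p
        if not self.vfa_paths:
            raise ValidationError("vfa_paths is empty")
        missing = [name for name, p in required.items() if not p or not Path(p).exists()]
        if missing:
            raise ValidationError(f"missing input file(s) for: {missing}")
        for name, p in self.roi_paths.items():
            if not Path(p).exists():
                raise ValidationError(f"missing input file(s) for: ['roi_paths[{name}]']")


def run_subject_arrays(
    vfa: VFAStack,
    b1: B1Map,
    dynamic: DynamicSeries,
    brain_mask: np.ndarray,
    sinus_mask: np.ndarray,
    config: PipelineConfig,
    rois: ROISet | None = None,
) -> dict:
    """Subject-level analysis chain on in-memory arrays."""
    _io.check_same_grid(
        vfa=vfa.grid_shape,
        b1=b1.scale.shape,
        dynamic=dynamic.grid_shape,
        brain_mask=brain_mask.shape,
        sinus_mask=sinus_mask.shape,
    )
    kcfg = config.kinetics()
    fit_mask = brain_mask | sinus_mask
    t1m0 = fit_vfa_t1(vfa, b1, mask=fit_mask)
    conc = signal_to_concentration(dynamic, t1m0, b1, kcfg, mask=fit_mask)
    vif = extract_vif(conc, sinus_mask, kcfg)
    window = np.asarray(config.fit_window) if config.fit_window is not None else None
    maps = fit_volume(conc, vif, brain_mask, fit_window=window)
    qc = subject_qc(
        maps,
        median_vp_range=config.qc_median_vp_range,
        max_frac_vp_gt1=config.qc_max_frac_vp_gt1,
    )
    out = {"t1m0": t1m0, "conc": conc, "vif": vif, "maps": maps, "qc": qc}
    if rois is not None:
        out["regional_means"] = regional_means(maps, rois)
    return out


def run_subject(record: SubjectRecord, config: PipelineConfig) -> dict:
    """Run one subject from files and write all outputs with provenance.

    A failed QC still writes every output (plus the fail verdict); it never
    silently omits results.
    """
    record.validate()
    meta = _io.load_json(record.meta_path)
    angles = sorted(record.vfa_paths)
    vols, voxel_size = [], None
    for a in angles:
        v, voxel_size = _io.load_nifti(record.vfa_paths[a])
        vols.append(v)
    vfa = VFAStack(
        signals=np.stack(vols),
        flip_angles=np.array(angles, dtype=float),
        repetition_time=float(meta["repetition_time"]),
    )
    b1 = B1Map(scale=_io.load_nifti(record.b1_path)[0])
    dyn_data, _ = _io.load_nifti(record.dynamic_path)
    dynamic = DynamicSeries(
        signal=dyn_data,
        times=np.asarray(meta["times"], dtype=float),
        bolus_dynamic=int(meta["bolus_dynamic"]),
        flip_angle=float(meta["flip_angle"]),
        repetition_time=float(meta["repetition_time"]),
    )
    brain_mask = _io.load_nifti(record.brain_mask_path)[0] > 0.5
    sinus_mask = _io.load_nifti(record.sinus_mask_path)[0] > 0.5
    rois = None
    if record.roi_paths:
        rois = ROISet(
            masks={n: _io.load_nifti(p)[0] > 0.5 for n, p in record.roi_paths.items()}
        )

    res = run_subject_arrays(vfa, b1, dynamic, brain_mask, sinus_mask, config, rois)

    out_dir = Path(config.out_dir) / record.subject
    out_dir.mkdir(parents=True, exist_ok=True)
    vs = voxel_size or (1.0, 1.0, 1.0)
    _io.save_nifti(out_dir / "t1.nii.gz", res["t1m0"].t1, vs)
    _io.save_nifti(out_dir / "m0.nii.gz", res["t1m0"].m0, vs)
    _io.save_nifti(out_dir / "t1_valid.nii.gz", res["t1m0"].valid.astype(np.uint8), vs)
    _io.save_nifti(out_dir / "ktrans.nii.gz", res["maps"].ktrans, vs)
    _io.save_nifti(out_dir / "vp.nii.gz", res["maps"].vp, vs)
    _io.save_nifti(out_dir / "r_squared.nii.gz", res["maps"].r_squared, vs)
    vif = res["vif"]
    pd.DataFrame({"time_min": vif.times, "cp_mM": vif.cp}).to_csv(
        out_dir / "vif.csv", index=False
    )
    _io.save_json(
        out_dir / "vif.json",
        {
            "n_roi_voxels": vif.n_roi_voxels,
            "hematocrit_used": vif.hematocrit_used,
            "r1": config.r1,
        },
    )
    qc = res["qc"]
    _io.save_json(
        out_dir / "qc.json",
        {
            "passed": qc.passed,
            "reasons": qc.reasons,
            "median_vp": qc.median_vp,
            "frac_vp_gt1": qc.frac_vp_gt1,
            "unfitted_reason_counts": res["maps"].reason_counts,
        },
    )
    if "regional_means" in res:
        res["regional_means"].to_csv(out_dir / "regional_means.csv", index=False)
    _io.save_json(
        out_dir / "provenance.json",
        {
            "subject": record.subject,
            "group": record.group,
            "inputs": {
                "vfa": {str(a): str(p) for a, p in record.vfa_paths.items()},
                "b1": record.b1_path,
                "dynamic": record.dynamic_path,
                "meta": record.meta_path,
                "brain_mask": record.brain_mask_path,
                "sinus_mask": record.sinus_mask_path,
            },
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "seed": config.seed,
        },
    )
    logger.info(
        "subject %s: r1=%g Hct=%g window=%s QC=%s",
        record.subject, config.r1, config.hematocrit,
        config.fit_window or "bolus..end", "pass" if qc.passed else "fail",
    )
    res["out_dir"] = out_dir
    return res


def run_group(
    cohort: pd.DataFrame,
    config: PipelineConfig,
    manifest: pd.DataFrame | None = None,
    maps_by_group: dict[str, np.ndarray] | None = None,
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 4.0),
) -> dict:
    """Cohort-level statistics, preceded by the exclusion report.

    ``cohort`` is the long subject x region x metric table. ``manifest``
    (subject-level QC flags) defaults to the unique subjects of ``cohort``
    with no flags. ``maps_by_group`` optionally supplies per-group stacks of
    subject parameter maps for the voxelwise cluster analysis.
    """
    if cohort.empty:
        raise ValidationError("empty cohort table")
    if manifest is None:
        manifest = cohort[["subject", "group"]].drop_duplicates("subject")
    manifest, report = apply_exclusions(manifest)
    kept = set(manifest["subject"])
    cohort = cohort[cohort["subject"].isin(kept)]
    groups_left = cohort["group"].nunique()
    if groups_left < 2:
        raise ValidationError(
            f"fewer than 2 groups remain after exclusions; report: {report}"
        )

    out: dict = {"exclusions": report}
    out["demographics"] = demographic_tests(cohort)
    for dv in sorted(cohort["metric"].unique()):
        out[f"anova_{dv}"] = rm_anova(cohort, dv)
        out[f"anova_{dv}_covariates"] = rm_anova(cohort, dv, covariates=config.covariates)
        out[f"posthoc_{dv}"] = posthoc_pairwise(cohort, dv)
        if (cohort["group"] == "PD").any() and cohort["ledd"].notna().any():
            try:
                out[f"clinical_lmm_{dv}"] = clinical_lmm(cohort, dv)
            except ValueError as exc:
                logger.warning("clinical mixed model skipped for %s: %s", dv, exc)

    if maps_by_group:
        clusters = {}
        for a, b in (("PD", "CN"), ("PD", "CP"), ("CP", "CN")):
            if a not in maps_by_group or b not in maps_by_group:
                continue
            sm_a = np.stack(
                [gaussian_smooth(m, config.smooth_fwhm, voxel_size) for m in maps_by_group[a]]
            )
            sm_b = np.stack(
                [gaussian_smooth(m, config.smooth_fwhm, voxel_size) for m in maps_by_group[b]]
            )
            for name, (x, y) in {
                f"{a}>{b}": (sm_a, sm_b),
                f"{b}>{a}": (sm_b, sm_a),
            }.items():
                clusters[name] = permutation_cluster_fwe(
                    x, y,
                    voxel_p=config.voxel_p,
                    min_extent=config.min_extent,
                    n_perm=config.n_perm,
                    seed=config.seed,
                )
        out["clusters"] = clusters

    n_per_group = cohort.drop_duplicates("subject")["group"].value_counts().to_dict()
    out["n_per_group"] = n_per_group
    return out


def write_group_outputs(out: dict, config: PipelineConfig) -> Path:
    """Write cohort-analysis tables and a plain-text report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["Group analysis report", "=" * 40]
    rep = out["exclusions"]
    lines += [
        f"recruited: {rep.n_recruited}",
        f"excluded: {rep.n_excluded} {rep.by_reason}",
        f"analysable: {rep.n_analysable} {rep.remaining_by_group}",
        f"n per group: {out['n_per_group']}",
        f"config hash: {config.hash()}  seed: {config.seed}",
    ]
    for key, val in out.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out_dir / f"{key}.csv", index=False)
            lines += ["", key, val.to_string(index=False)]
    if "clusters" in out:
        for name, res in out["clusters"].items():
            lines.append(
                f"{name}: {len(res.clusters)} cluster(s) "
                + ", ".join(
                    f"size={c.size} peak_t={c.peak_t:.2f} p_fwe={c.corrected_p}"
                    for c in res.clusters
                )
            )
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return out_dir
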