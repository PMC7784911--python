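"""Cohort statistics: exclusions, demographics, ANOVA, mixed models and
voxelwise group comparison with cluster-level permutation FWE.

The regional analysis is a split-plot (repeated-measures) design: group is a
between-subject factor, region a within-subject factor, subject a random
effect. The between-subject stratum (group, plus optional age / gender /
cube-root WML volume covariates) is tested on subject means against the
subject-within-group mean square; region and the group-by-region interaction
are tested against the subject-by-region residual. For complete-data
random-intercept designs these are exactly the F tests a linear mixed model
with Satterthwaite denominator degrees of freedom yields.

Voxelwise comparisons use Welch's unequal-variance two-sample t per voxel,
one-sided supra-threshold clustering at p < 0.001 with a 50-voxel minimum
extent (26-neighbour connectivity), and family-wise error control by
permutation of group labels: the null distribution of the maximum
supra-threshold cluster extent.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "ExclusionReport",
    "Cluster",
    "ClusterResults",
    "apply_exclusions",
    "demographic_tests",
    "rm_anova",
    "posthoc_pairwise",
    "clinical_lmm",
    "gaussian_smooth",
    "voxelwise_ttest",
    "cluster_threshold",
    "permutation_cluster_fwe",
]

logger = logging.getLogger(__name__)

GROUP_PAIRS = (("CN", "PD"), ("CP", "PD"), ("CN", "CP"))

EXCLUSION_FLAGS = ("incomplete_scan", "injection_failure", "nonphysiological_vp")


# --------------------------------------------------------------------------
# participant QC exclusions
# --------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    n_recruited: int
    n_excluded: int
    n_analysable: int
    by_reason: dict[str, int]
    by_group: dict[str, int]            # excluded per group
    remaining_by_group: dict[str, int]


def apply_exclusions(manifest: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop subjects with any QC flag set; report counts per reason and group.

    ``manifest`` needs columns ``subject``, ``group`` and the boolean flags
    ``incomplete_scan``, ``injection_failure``, ``nonphysiological_vp``
    (missing flag columns are treated as all-False).
    """
    if manifest["subject"].duplicated().any():
        dupes = manifest.loc[manifest["subject"].duplicated(), "subject"].tolist()
        raise ValueError(f"duplicate subject ids in manifest: {dupes}")
    flags = pd.DataFrame(index=manifest.index)
    for name in EXCLUSION_FLAGS:
        flags[name] = (
            manifest[name].fillna(False).astype(bool)
            if name in manifest
            else False
        )
    excluded = flags.any(axis=1)
    report = ExclusionReport(
        n_recruited=len(manifest),
        n_excluded=int(excluded.sum()),
        n_analysable=int((~excluded).sum()),
        by_reason={name: int(flags[name].sum()) for name in EXCLUSION_FLAGS},
        by_group=manifest.loc[excluded, "group"].value_counts().to_dict(),
        remaining_by_group=manifest.loc[~excluded, "group"].value_counts().to_dict(),
    )
    return manifest.loc[~excluded].reset_index(drop=True), report


# --------------------------------------------------------------------------
# demographics
# --------------------------------------------------------------------------

def _subject_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long cohort table to one row per subject."""
    cols = [c for c in cohort.columns if c not in ("region", "metric", "value")]
    return cohort[cols].drop_duplicates("subject").reset_index(drop=True)


def demographic_tests(
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "moca", "wml_cuberoot"),
    categorical: tuple[str, ...] = ("gender",),
) -> pd.DataFrame:
    """Pairwise group comparisons of demographic and clinical variables.

    Continuous variables use an unpaired Welch t-test, categorical variables
    a two-sided Fisher exact test on the 2x2 level-by-group table. All three
    group pairs are reported. A continuous variable with zero variance in
    both groups yields an undefined t, reported as NaN.
    """
    subj = _subject_table(cohort)
    rows = []
    for a, b in GROUP_PAIRS:
        ga = subj[subj["group"] == a]
        gb = subj[subj["group"] == b]
        for var in continuous:
            xa = ga[var].dropna().to_numpy(float)
            xb = gb[var].dropna().to_numpy(float)
            if min(xa.size, xb.size) < 2:
                continue
            if xa.var(ddof=1) == 0.0 and xb.var(ddof=1) == 0.0:
                t_stat, p = (0.0, 1.0) if xa.mean() == xb.mean() else (np.nan, np.nan)
            else:
                t_stat, p = sps.ttest_ind(xa, xb, equal_var=False)
            rows.append((var, f"{a} vs {b}", "welch_t", float(t_stat), float(p)))
        for var in categorical:
            levels = sorted(subj[var].dropna().unique())
            if len(levels) != 2:
                raise ValueError(f"categorical variable {var!r} must have 2 levels")
            table = [
                [int((ga[var] == lv).sum()), int((gb[var] == lv).sum())]
                for lv in levels
            ]
            _, p = sps.fisher_exact(table, alternative="two-sided")
            rows.append((var, f"{a} vs {b}", "fisher_exact", np.nan, float(p)))
    return pd.DataFrame(rows, columns=["variable", "pair", "test", "stat", "p"])


# --------------------------------------------------------------------------
# repeated-measures ANOVA
# --------------------------------------------------------------------------

def _ols_rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and design rank of an OLS fit."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def _dummies(values: pd.Series) -> np.ndarray:
    """Full-rank treatment coding (drop first level)."""
    levels = sorted(values.unique())
    return np.column_stack([(values == lv).to_numpy(float) for lv in levels[1:]])


def rm_anova(
    cohort: pd.DataFrame,
    dv: str,
    covariates: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Repeated-measures ANOVA of a regional metric with group and region.

    Split-plot decomposition with subject as the random blocking factor:

    * between-subject stratum — OLS on subject means with group and the
      optional covariates (``age``, ``gender``, ``wml_cuberoot``); each term's
      F is a drop-one model comparison against the subject-level residual
      (the subject-within-group mean square).
    * within-subject stratum — region and group:region tested by model
      comparison against the subject-by-region residual.

    Returns a table with columns term, df_num, df_den, F, p.
    """
    df = cohort[cohort["metric"] == dv]
    if df.empty:
        raise ValueError(f"no rows with metric {dv!r}")
    if df["region"].nunique() < 2 or df["group"].nunique() < 2:
        raise ValueError("need at least 2 regions and 2 groups")
    covariates = tuple(covariates or ())

    # ---- between-subject stratum: subject means
    subj = (
        df.groupby("subject", sort=True)
        .agg(value=("value", "mean"), **{c: (c, "first") for c in ("group", *covariates)})
        .reset_index()
    )
    y = subj["value"].to_numpy(float)
    n_subj = len(subj)
    blocks: dict[str, np.ndarray] = {"group": _dummies(subj["group"])}
    for cov in covariates:
        col = subj[cov]
        if col.dtype == object or str(col.dtype) == "category":
            blocks[cov] = _dummies(col)
        else:
            blocks[cov] = col.to_numpy(float)[:, None]
    intercept = np.ones((n_subj, 1))
    x_full = np.hstack([intercept, *blocks.values()])
    rss_full, rank_full = _ols_rss(x_full, y)
    df_den_between = n_subj - rank_full
    if df_den_between <= 0:
        raise ValueError("between-subject stratum has no residual degrees of freedom")
    mse_between = rss_full / df_den_between

    rows = []
    for term, block in blocks.items():
        x_red = np.hstack([intercept, *(b for t, b in blocks.items() if t != term)])
        rss_red, rank_red = _ols_rss(x_red, y)
        df_num = rank_full - rank_red
        if df_num == 0:
            logger.warning("term %r is confounded with the rest of the design", term)
            rows.append((term, 0, df_den_between, np.nan, np.nan))
            continue
        f_val = (rss_red - rss_full) / df_num / mse_between
        p = float(sps.f.sf(f_val, df_num, df_den_between))
        rows.append((term, df_num, df_den_between, float(f_val), p))

    # ---- within-subject stratum: region, group:region
    yw = df["value"].to_numpy(float)
    subj_d = _dummies(df["subject"])
    reg_d = _dummies(df["region"])
    groups = sorted(df["group"].unique())
    regions = sorted(df["region"].unique())
    inter = np.column_stack(
        [
            ((df["group"] == g) & (df["region"] == r)).to_numpy(float)
            for g in groups[1:]
            for r in regions[1:]
        ]
    )
    one = np.ones((len(df), 1))
    x_s = np.hstack([one, subj_d])
    x_sr = np.hstack([one, subj_d, reg_d])
    x_srg = np.hstack([one, subj_d, reg_d, inter])
    rss_s, rank_s = _ols_rss(x_s, yw)
    rss_sr, rank_sr = _ols_rss(x_sr, yw)
    rss_srg, rank_srg = _ols_rss(x_srg, yw)
    df_err = len(df) - rank_srg
    if df_err <= 0:
        raise ValueError("within-subject stratum has no residual degrees of freedom")
    mse_within = rss_srg / df_err
    for term, (rss_hi, rank_hi, rss_lo, rank_lo) in {
        "region": (rss_sr, rank_sr, rss_s, rank_s),
        "group:region": (rss_srg, rank_srg, rss_sr, rank_sr),
    }.items():
        df_num = rank_hi - rank_lo
        f_val = (rss_lo - rss_hi) / df_num / mse_within
        rows.append(
            (term, df_num, df_err, float(f_val), float(sps.f.sf(f_val, df_num, df_err)))
        )
    return pd.DataFrame(rows, columns=["term", "df_num", "df_den", "F", "p"])


def posthoc_pairwise(cohort: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Pairwise group comparisons of a regional metric after rm_anova.

    Overall rows (region == "overall") compare subject means (averaged over
    regions) with Welch t-tests and Bonferroni correction over the three
    group pairs (p_corrected = min(1, 3 * p_raw)). Per-region rows report
    uncorrected Welch t-tests for each group pair.
    """
    df = cohort[cohort["metric"] == dv]
    if df.empty:
        raise ValueError(f"no rows with metric {dv!r}")
    subj = df.groupby(["subject", "group"], sort=True)["value"].mean().reset_index()
    rows = []
    for a, b in GROUP_PAIRS:
        xa = subj.loc[subj["group"] == a, "value"].to_numpy(float)
        xb = subj.loc[subj["group"] == b, "value"].to_numpy(float)
        if np.var(xa, ddof=1) == 0.0 and np.var(xb, ddof=1) == 0.0 and xa.mean() == xb.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = sps.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            ("overall", f"{a} vs {b}", float(t_stat), float(p), min(1.0, 3.0 * float(p)))
        )
    for region in sorted(df["region"].unique()):
        sub = df[df["region"] == region]
        for a, b in GROUP_PAIRS:
            xa = sub.loc[sub["group"] == a, "value"].to_numpy(float)
            xb = sub.loc[sub["group"] == b, "value"].to_numpy(float)
            if np.var(xa, ddof=1) == 0.0 and np.var(xb, ddof=1) == 0.0 and xa.mean() == xb.mean():
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = sps.ttest_ind(xa, xb, equal_var=False)
            rows.append((region, f"{a} vs {b}", float(t_stat), float(p), np.nan))
    return pd.DataFrame(
        rows, columns=["region", "pair", "t", "p_raw", "p_bonferroni"]
    )


# --------------------------------------------------------------------------
# clinical mixed model (PD group)
# --------------------------------------------------------------------------

def clinical_lmm(
    cohort: pd.DataFrame,
    dv: str,
    scores: tuple[str, ...] = ("moca", "ledd", "updrs"),
) -> pd.DataFrame:
    """Mixed-effects association of regional parameters with clinical scores.

    Restricted to the PD group. Fixed effects: region (factor), each clinical
    score (continuous, mean-centred), and score-by-region interactions;
    random intercept per subject (fitted by REML via statsmodels MixedLM).
    Per-term Wald F tests use between-within denominator degrees of freedom
    (scores, which are constant within subject, are tested against the
    between-subject residual df; region terms against the within-subject
    residual df) — the containment approximation to Satterthwaite, exact for
    balanced random-intercept designs. Rows with missing scores are dropped
    (count logged); a constant score is dropped from the model with a warning.
    """
    import statsmodels.api as sm

    df = cohort[(cohort["group"] == "PD") & (cohort["metric"] == dv)].copy()
    if df.empty:
        raise ValueError(f"no PD rows with metric {dv!r}")
    n0 = len(df)
    df = df.dropna(subset=list(scores))
    if n0 - len(df):
        logger.info("clinical_lmm: dropped %d rows with missing scores", n0 - len(df))
    if df["value"].nunique() <= 1:
        raise ValueError("response has zero variance")

    kept = []
    for s in scores:
        if df[s].nunique() <= 1:
            logger.warning("score %r is constant; term dropped", s)
        else:
            kept.append(s)
    regions = sorted(df["region"].unique())
    n_reg = len(regions)

    # design: intercept | region dummies | centred scores | score x region
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    reg_dummies = {r: (df["region"] == r).to_numpy(float) for r in regions[1:]}
    for r, d in reg_dummies.items():
        cols.append(d)
        names.append(f"region[{r}]")
    centred = {}
    for s in kept:
        z = df[s].to_numpy(float)
        centred[s] = z - z.mean()
        cols.append(centred[s])
        names.append(s)
    for s in kept:
        for r, d in reg_dummies.items():
            cols.append(centred[s] * d)
            names.append(f"region[{r}]:{s}")
    x = np.column_stack(cols)

    model = sm.MixedLM(
        endog=df["value"].to_numpy(float),
        exog=x,
        groups=df["subject"].to_numpy(),
    )
    import warnings

    k = x.shape[1]
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs")
            fe = np.asarray(res.fe_params)
            cov = np.asarray(res.cov_params())[:k, :k]
            if not np.all(np.isfinite(cov)):
                raise np.linalg.LinAlgError("non-finite covariance")
        except (np.linalg.LinAlgError, ValueError):
            # boundary fit (subject variance ~ 0): the model degenerates to
            # ordinary least squares, whose covariance is the correct limit
            logger.warning("singular mixed-model fit; using fixed-effects covariance")
            xtx_inv = np.linalg.pinv(x.T @ x)
            fe = xtx_inv @ x.T @ df["value"].to_numpy(float)
            resid = df["value"].to_numpy(float) - x @ fe
            sigma2 = float(resid @ resid) / (len(df) - np.linalg.matrix_rank(x))
            cov = sigma2 * xtx_inv

    n_subj = df["subject"].nunique()
    nobs = len(df)
    df_between = n_subj - (1 + len(kept))
    df_within = nobs - n_subj - (n_reg - 1) * (1 + len(kept))

    terms: dict[str, tuple[list[int], int]] = {}
    reg_idx = [i for i, nm in enumerate(names) if nm.startswith("region[") and ":" not in nm]
    terms["region"] = (reg_idx, df_within)
    for s in kept:
        terms[s] = ([names.index(s)], df_between)
        inter_idx = [i for i, nm in enumerate(names) if nm.endswith(f":{s}")]
        terms[f"region:{s}"] = (inter_idx, df_within)

    rows = []
    for term, (idx, df_den) in terms.items():
        contrast = np.zeros((len(idx), k))
        for j, i in enumerate(idx):
            contrast[j, i] = 1.0
        lb = contrast @ fe
        lvl = contrast @ cov @ contrast.T
        f_val = float(lb @ np.linalg.pinv(lvl) @ lb) / len(idx)
        p = float(sps.f.sf(f_val, len(idx), df_den))
        rows.append((term, len(idx), df_den, f_val, p))
    return pd.DataFrame(rows, columns=["term", "df_num", "df_den", "F", "p"])


# --------------------------------------------------------------------------
# voxelwise comparison
# --------------------------------------------------------------------------

def gaussian_smooth(
    image: np.ndarray,
    fwhm: float | tuple[float, float, float],
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Separable Gaussian smoothing with FWHM given in millimetres.

    sigma per axis = FWHM / (2 sqrt(2 ln 2)) converted to voxel units.
    Reflective boundaries keep a constant field constant; an interior delta
    integrates to one (mass preservation). FWHM 0 is the identity.
    """
    fwhm_arr = np.broadcast_to(np.asarray(fwhm, dtype=float), (3,))
    if np.any(fwhm_arr < 0):
        raise ValueError("fwhm must be >= 0")
    sigma_vox = fwhm_arr / (2.0 * math.sqrt(2.0 * math.log(2.0))) / np.asarray(voxel_size)
    return ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma=sigma_vox, mode="reflect")


def voxelwise_ttest(
    maps_a: np.ndarray, maps_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Welch's unequal-variance two-sample t-test per voxel (A minus B).

    Inputs are stacks of subject maps, shape (n_subjects, nx, ny, nz); NaN
    voxels are excluded per subject (per-voxel sample sizes). Returns the t
    field and the Welch-Satterthwaite degrees-of-freedom field; voxels with
    zero variance in both groups (or fewer than two subjects) are NaN.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError(f"grid mismatch: {a.shape[1:]} vs {b.shape[1:]}")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")

    def moments(x):
        n = np.sum(np.isfinite(x), axis=0).astype(float)
        with np.errstate(all="ignore"):
            m = np.nanmean(x, axis=0)
            v = np.nanvar(x, axis=0, ddof=1)
        return n, m, v

    na, ma, va = moments(a)
    nb, mb, vb = moments(b)
    with np.errstate(all="ignore"):
        sea2 = va / na
        seb2 = vb / nb
        se2 = sea2 + seb2
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sea2**2 / (na - 1) + seb2**2 / (nb - 1))
    bad = (na < 2) | (nb < 2) | ~(se2 > 0)
    t = np.where(bad, np.nan, t)
    df = np.where(bad, np.nan, df)
    return t, df


@dataclass
class Cluster:
    size: int
    peak_t: float
    peak_index: tuple[int, int, int]
    corrected_p: float | None = None


@dataclass
class ClusterResults:
    clusters: list[Cluster]
    label_map: np.ndarray
    voxel_p: float
    min_extent: int
    n_permutations: int | None = None
    exhaustive: bool = False
    null_max_extent: np.ndarray | None = None


_CONN26 = np.ones((3, 3, 3), dtype=int)


def _supra_components(t: np.ndarray, df: np.ndarray, voxel_p: float):
    """Label one-sided (positive t) supra-threshold voxels, 26-connectivity."""
    with np.errstate(invalid="ignore"):
        t_crit = sps.t.isf(voxel_p, df)
        supra = np.nan_to_num(t, nan=-np.inf) > t_crit
    labels, n = ndimage.label(supra, structure=_CONN26)
    return labels, n


def cluster_threshold(
    t: np.ndarray,
    df: np.ndarray,
    voxel_p: float = 0.001,
    min_extent: int = 50,
) -> ClusterResults:
    """One-sided supra-threshold clustering of a t field.

    Voxels with t above the one-sided critical value of p < ``voxel_p``
    (using each voxel's df) are labelled with 26-neighbour connectivity
    (components touching only at a corner are one cluster); components
    smaller than ``min_extent`` voxels are discarded. Negative-direction
    effects are obtained by negating the t field.
    """
    if voxel_p <= 0 or min_extent <= 0:
        raise ValueError("voxel_p and min_extent must be positive")
    labels, n = _supra_components(t, df, voxel_p)
    clusters = []
    out_labels = np.zeros_like(labels)
    next_id = 0
    for comp in range(1, n + 1):
        sel = labels == comp
        size = int(sel.sum())
        if size < min_extent:
            continue
        next_id += 1
        out_labels[sel] = next_id
        masked_t = np.where(sel, t, -np.inf)
        peak_flat = int(np.argmax(masked_t))
        peak = tuple(int(v) for v in np.unravel_index(peak_flat, t.shape))
        clusters.append(Cluster(size=size, peak_t=float(t[peak]), peak_index=peak))
    clusters.sort(key=lambda c: -c.size)
    return ClusterResults(
        clusters=clusters, label_map=out_labels, voxel_p=voxel_p, min_extent=min_extent
    )


def _perm_max_extents(
    pooled: np.ndarray,
    masks_a: np.ndarray,
    voxel_p: float,
    grid: tuple[int, int, int],
) -> np.ndarray:
    """Maximum supra-threshold cluster extent per permutation (vectorised t)."""
    n = pooled.shape[0]
    x = pooled.reshape(n, -1)
    x2 = x * x
    sel = masks_a.astype(float)                      # (n_perm, n)
    na = sel.sum(1, keepdims=True)
    nb = n - na
    sa, sb = sel @ x, (1.0 - sel) @ x
    sa2, sb2 = sel @ x2, (1.0 - sel) @ x2
    ma, mb = sa / na, sb / nb
    va = (sa2 - na * ma**2) / (na - 1)
    vb = (sb2 - nb * mb**2) / (nb - 1)
    with np.errstate(all="ignore"):
        sea2, seb2 = va / na, vb / nb
        se2 = sea2 + seb2
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sea2**2 / (na - 1) + seb2**2 / (nb - 1))
        t_crit = sps.t.isf(voxel_p, df)
        supra = np.nan_to_num(t, nan=-np.inf) > t_crit
    out = np.zeros(masks_a.shape[0], dtype=int)
    for i in range(masks_a.shape[0]):
        labels, nlab = ndimage.label(supra[i].reshape(grid), structure=_CONN26)
        if nlab:
            out[i] = int(np.bincount(labels.ravel())[1:].max())
    return out


def permutation_cluster_fwe(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    voxel_p: float = 0.001,
    min_extent: int = 50,
    n_perm: int = 199,
    seed: int = 0,
) -> ClusterResults:
    """Cluster-extent FWE-corrected group comparison by label permutation.

    The observed clusters (A > B, one-sided) are assessed against the null
    distribution of the maximum supra-threshold cluster extent obtained by
    permuting group labels. Corrected p per cluster is
    (1 + #{permutation max extent >= observed extent}) / (n_perm + 1); when
    fewer distinct label assignments than ``n_perm`` exist they are
    enumerated exactly and the p value is the exact proportion.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    t, df = voxelwise_ttest(a, b)
    observed = cluster_threshold(t, df, voxel_p, min_extent)

    na, nb = a.shape[0], b.shape[0]
    n = na + nb
    pooled = np.concatenate([a, b], axis=0)
    n_distinct = math.comb(n, na)
    if n_distinct <= n_perm:
        combos = list(itertools.combinations(range(n), na))
        masks = np.zeros((len(combos), n), dtype=bool)
        for i, c in enumerate(combos):
            masks[i, list(c)] = True
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            masks[i, rng.choice(n, na, replace=False)] = True
        exhaustive = False

    null_max = _perm_max_extents(pooled, masks, voxel_p, t.shape)
    for cl in observed.clusters:
        hits = int((null_max >= cl.size).sum())
        if exhaustive:
            cl.corrected_p = max(hits, 1) / len(null_max)
        else:
            cl.corrected_p = (1 + hits) / (n_perm + 1)
    observed.n_permutations = len(null_max)
    observed.exhaustive = exhaustive
    observed.null_max_extent = null_max
    return observed
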