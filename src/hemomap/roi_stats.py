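"""ROI aggregation, CMRO2, paired tests and mixed-effects associations.

Regional subject-level values are collected into a table of per-condition
means/SDs, compared with two-sided paired t-tests under Bonferroni control,
and related to perfusion with random-intercept linear mixed models (subject
and region intercepts, REML by default).  The derived summary block reduces
the table to the headline group statistics: mean baseline OEF, average
regional relative CBF increase and OEF decrease, and per-region absolute
OEF changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANONICAL_ROIS",
    "MetabolicConstants",
    "RoiStatsTable",
    "LmmResult",
    "roi_means",
    "cmro2",
    "paired_t",
    "paired_tests",
    "lmm_association",
    "summary_changes",
    "table_from_spec",
]

#: The nine cortical regions reported on: six default-mode-network regions
#: plus three non-DMN reference regions.
CANONICAL_ROIS = ("AG", "MFG", "aCG", "pCG", "PCun", "SG", "OP", "MTG", "ITG")

PARAMS = ("cbf", "oef", "r2p", "dbv", "cmro2")


@dataclass(frozen=True)
class MetabolicConstants:
    """Constants converting CBF x OEF into an oxygen metabolic rate.

    hbt : hemoglobin concentration in tissue blood, umol/mL.
    ya : arterial oxygen saturation (fraction).
    hba : oxygenated hemoglobin concentration in the arteriole, umol/mL —
        always exactly ``hbt * ya``.
    """

    hbt: float = 8.441
    ya: float = 0.98

    def __post_init__(self):
        if self.hbt <= 0:
            raise ValueError("hbt must be positive")
        if not 0 < self.ya <= 1:
            raise ValueError("ya must be a fraction in (0, 1]")

    @property
    def hba(self) -> float:
        return self.hbt * self.ya


@dataclass
class RoiStatsTable:
    """Per-region, per-condition group statistics plus paired-test cells.

    ``means`` / ``sds`` are DataFrames indexed by region with column
    MultiIndex (parameter, condition); ``tests`` (optional) is indexed by
    (region, parameter) with columns t, p, p_threshold, significant,
    undefined.  OEF and DBV are in percent at this reporting level.
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    n_subjects: int
    tests: pd.DataFrame | None = None

    @classmethod
    def from_subject_values(cls, values: dict, *, n_comparisons: int | None = None,
                            compute_tests: bool = True) -> "RoiStatsTable":
        """Build the table from per-subject regional values.

        ``values[param][condition]`` is a DataFrame indexed by region with
        one column per subject.  Tests compare pre vs post per region for
        each parameter present in both conditions.
        """
        mean_cols, sd_cols = {}, {}
        n_subj = None
        for param, conds in values.items():
            for cond, df in conds.items():
                n_subj = df.shape[1] if n_subj is None else n_subj
                mean_cols[(param, cond)] = df.mean(axis=1)
                sd_cols[(param, cond)] = df.std(axis=1, ddof=1)
        means = pd.DataFrame(mean_cols)
        sds = pd.DataFrame(sd_cols)
        tests = None
        if compute_tests and (n_subj or 0) >= 2:
            frames = []
            for param, conds in values.items():
                if "pre" in conds and "post" in conds:
                    m = n_comparisons if n_comparisons is not None else len(conds["pre"])
                    t = paired_tests(conds["pre"], conds["post"], m)
                    t.insert(0, "param", param)
                    frames.append(t.reset_index(names="roi"))
            if frames:
                tests = pd.concat(frames, ignore_index=True).set_index(["roi", "param"])
        return cls(means=means, sds=sds, n_subjects=int(n_subj or 0), tests=tests)


@dataclass
class LmmResult:
    """Slope of a random-intercepts mixed model of a parameter on CBF."""

    beta: float
    se: float
    tstat: float
    pvalue: float
    var_subject: float
    var_region: float
    var_residual: float
    converged: bool


def roi_means(volume: np.ndarray, atlas: np.ndarray,
              valid_mask: np.ndarray | None = None,
              labels: dict | None = None) -> pd.DataFrame:
    """Mean/SD/voxel-count of a map over each atlas region, honoring validity.

    ``labels`` optionally maps region names to integer labels; atlas labels
    absent from it are ignored with a warning.  Regions with no valid voxel
    are reported with NaN statistics and ``n_voxels = 0``.
    """
    volume = np.asarray(volume, dtype=float)
    atlas = np.asarray(atlas)
    if volume.shape != atlas.shape:
        raise ValueError("volume and atlas shapes differ")
    valid = np.isfinite(volume)
    if valid_mask is not None:
        if valid_mask.shape != volume.shape:
            raise ValueError("valid_mask shape differs from volume")
        valid &= np.asarray(valid_mask, dtype=bool)

    present = [int(lab) for lab in np.unique(atlas) if lab > 0]
    if labels is not None:
        known = {int(v): k for k, v in labels.items()}
        unknown = [lab for lab in present if lab not in known]
        if unknown:
            warnings.warn(f"ignoring unknown atlas labels {unknown}", stacklevel=2)
        rows = [(name, lab) for lab, name in known.items() if lab in present]
    else:
        rows = [(str(lab), lab) for lab in present]

    records = []
    for name, lab in rows:
        sel = (atlas == lab) & valid
        vals = volume[sel]
        records.append({
            "roi": name,
            "label": lab,
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else (0.0 if vals.size == 1 else np.nan),
            "n_voxels": int(vals.size),
        })
    return pd.DataFrame.from_records(records).set_index("roi")


def cmro2(cbf, oef, const: MetabolicConstants | None = None):
    """Oxygen metabolic rate (umol/100 g/min) = CBF x OEF x Hba.

    ``cbf`` in mL/100 g/min, ``oef`` as a fraction; bilinear in both.
    """
    const = const or MetabolicConstants()
    cbf_arr = np.asarray(cbf, dtype=float)
    oef_arr = np.asarray(oef, dtype=float)
    if np.any(cbf_arr < 0) or np.any(oef_arr < 0):
        raise ValueError("cbf and oef must be non-negative")
    out = cbf_arr * oef_arr * const.hba
    return float(out) if out.ndim == 0 else out


def paired_t(pre, post):
    """Two-sided paired t statistic and p-value (textbook formulation).

    Zero-variance differences are flagged: identical samples give
    (t=0, p=1, defined); a constant non-zero shift gives NaNs with
    ``defined=False`` rather than a silently misleading zero p.
    Returns ``(t, p, defined)``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D arrays")
    if pre.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0, True
        return np.nan, np.nan, False
    t, p = stats.ttest_rel(post, pre)
    return float(t), float(p), True


def paired_tests(pre: pd.DataFrame, post: pd.DataFrame, n_comparisons: int,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Per-region paired tests with a Bonferroni-corrected threshold.

    ``pre`` / ``post`` are region x subject DataFrames with matching shape.
    The significance flag compares the raw p against ``alpha / n_comparisons``
    (0.05 / 9 ~= 0.0056 for the canonical nine-region family).
    """
    if list(pre.index) != list(post.index) or pre.shape != post.shape:
        raise ValueError("pre and post tables must share regions and subjects")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    threshold = alpha / n_comparisons
    records = []
    for roi in pre.index:
        t, p, defined = paired_t(pre.loc[roi].to_numpy(), post.loc[roi].to_numpy())
        records.append({
            "roi": roi, "t": t, "p": p, "p_threshold": threshold,
            "significant": bool(defined and p < threshold),
            "undefined": not defined,
        })
    return pd.DataFrame.from_records(records).set_index("roi")


def lmm_association(dependent, cbf, subject_ids, region_ids, *,
                    reml: bool = True) -> LmmResult:
    """Random-intercepts mixed model: dependent ~ CBF + (1|subject) + (1|region).

    Crossed random intercepts are expressed as variance components over a
    single all-inclusive group.  Requires at least 2 subjects and 2 regions;
    conditions are pooled by the caller.  A non-converged or singular fit is
    reported through the ``converged`` flag, not an exception.
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": np.asarray(dependent, dtype=float),
        "cbf": np.asarray(cbf, dtype=float),
        "subject": pd.Categorical(subject_ids),
        "region": pd.Categorical(region_ids),
    })
    if df["subject"].nunique() < 2 or df["region"].nunique() < 2:
        raise ValueError("need at least 2 subjects and 2 regions")
    df["group"] = 1
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "y ~ cbf", data=df, groups="group",
            vc_formula={"subject": "0 + C(subject)", "region": "0 + C(region)"},
        )
        try:
            fit = model.fit(reml=reml)
            converged = bool(fit.converged)
        except Exception:
            fit = model.fit(reml=reml, method="powell")
            converged = False
    beta = float(fit.fe_params["cbf"])
    se = float(fit.bse_fe["cbf"])
    vcomp = dict(zip(model.exog_vc.names, np.atleast_1d(fit.vcomp)))
    return LmmResult(
        beta=beta,
        se=se,
        tstat=beta / se if se > 0 else np.nan,
        pvalue=float(fit.pvalues["cbf"]),
        var_subject=float(vcomp.get("subject", np.nan)),
        var_region=float(vcomp.get("region", np.nan)),
        var_residual=float(fit.scale),
        converged=converged,
    )


def summary_changes(table: RoiStatsTable) -> dict:
    """Headline group summaries derived from the regional table.

    Returns a dict with:

    - ``mean_baseline_oef_pct``: mean of the nine pre-condition OEF region
      means (percent).
    - ``mean_cbf_change_pct``: mean over regions of the per-region relative
      CBF change, 100 * (post - pre) / pre.
    - ``mean_oef_decrease_pct``: mean over regions of the per-region relative
      OEF decrease, 100 * (pre - post) / pre.
    - ``oef_change_points``: per-region absolute OEF change pre - post, in
      percentage points.

    All nine canonical regions must be present; a missing one raises with its
    name.
    """
    missing = [r for r in CANONICAL_ROIS if r not in table.means.index]
    if missing:
        raise ValueError(f"missing ROI(s) in table: {', '.join(missing)}")
    for col in (("oef", "pre"), ("oef", "post"), ("cbf", "pre"), ("cbf", "post")):
        if col not in table.means.columns:
            raise ValueError(f"table lacks required column {col}")
    rois = list(CANONICAL_ROIS)
    oef_pre = table.means.loc[rois, ("oef", "pre")]
    oef_post = table.means.loc[rois, ("oef", "post")]
    cbf_pre = table.means.loc[rois, ("cbf", "pre")]
    cbf_post = table.means.loc[rois, ("cbf", "post")]
    return {
        "mean_baseline_oef_pct": float(oef_pre.mean()),
        "mean_cbf_change_pct": float((100.0 * (cbf_post - cbf_pre) / cbf_pre).mean()),
        "mean_oef_decrease_pct": float((100.0 * (oef_pre - oef_post) / oef_pre).mean()),
        "oef_change_points": {r: float(oef_pre[r] - oef_post[r]) for r in rois},
    }


def table_from_spec(spec) -> RoiStatsTable:
    """Regional table built directly from a phantom spec's published means/SDs."""
    mean_cols, sd_cols = {}, {}
    for param in PARAMS:
        for cond in ("pre", "post"):
            mean_cols[(param, cond)] = {}
            sd_cols[(param, cond)] = {}
    for name, roi in spec.roi_table.items():
        for cond in ("pre", "post"):
            p = roi.condition(cond)
            for param in PARAMS:
                mean_cols[(param, cond)][name] = getattr(p, f"{param}_mean")
                sd_cols[(param, cond)][name] = getattr(p, f"{param}_sd")
    means = pd.DataFrame(mean_cols)
    sds = pd.DataFrame(sd_cols)
    return RoiStatsTable(means=means, sds=sds, n_subjects=spec.n_subjects)
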