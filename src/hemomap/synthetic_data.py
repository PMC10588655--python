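"""Digital phantom: aligned ASE + ASL datasets with ground truth.

Nine cortical regions of interest are laid out as disjoint blocks on a small
3-D grid.  Per-subject regional parameter values (CBF, OEF, DBV) are drawn
from Gaussians with the published per-region means and between-subject SDs
for two physiological conditions (pre / post vasodilation); R2' is derived
from OEF and DBV through the dephasing relation so the truth volumes are
internally consistent.  Signal volumes are generated with the closed-form
forward models plus seeded Gaussian thermal noise, so every pipeline stage
is testable without acquired data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forward_model import AseProtocol, TissueConstants, ase_signal_stack, delta_omega
from .asl_quant import AslProtocol, CBF_UNIT_FACTOR, _dm_core
from .roi_stats import CANONICAL_ROIS

__all__ = [
    "ConditionParams",
    "RoiSpec",
    "PhantomSpec",
    "PhantomTruth",
    "default_table1_spec",
    "build_phantom",
    "simulate_ase_study",
    "simulate_asl_study",
]

CONDITIONS = ("pre", "post")


@dataclass(frozen=True)
class ConditionParams:
    """Regional means / between-subject SDs for one condition.

    CBF in mL/100 g/min; OEF and DBV in percent (reporting units — converted
    to fractions when a phantom is built); R2' in s^-1.  The R2' and CMRO2
    columns are carried for report validation only: phantom generation
    derives R2' from (OEF, DBV).
    """

    cbf_mean: float
    cbf_sd: float
    oef_mean: float
    oef_sd: float
    r2p_mean: float
    r2p_sd: float
    dbv_mean: float
    dbv_sd: float
    cmro2_mean: float
    cmro2_sd: float


@dataclass(frozen=True)
class RoiSpec:
    label: int
    name: str
    pre: ConditionParams
    post: ConditionParams

    def condition(self, cond: str) -> ConditionParams:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
        return self.pre if cond == "pre" else self.post


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; ``seed`` is mandatory for reproducibility."""

    seed: int
    roi_table: dict = field(default_factory=dict)
    grid_shape: tuple = (24, 24, 24)
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    n_subjects: int = 8
    snr_ase: float = math.inf
    snr_asl: float = math.inf
    att_s: float = 1.3
    within_roi_jitter: float = 0.0

    def __post_init__(self):
        labels = [r.label for r in self.roi_table.values()]
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")
        if any(lab <= 0 for lab in labels):
            raise ValueError("ROI labels must be positive (0 is background)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def roi(self) -> dict:
        return self.roi_table


@dataclass
class PhantomTruth:
    """Ground-truth volumes: atlas labels plus per-subject/condition maps.

    ``maps[(subject, condition)]`` is a dict with keys ``oef``, ``dbv``
    (fractions), ``r2p`` (s^-1), ``cbf`` (mL/100 g/min), ``att`` (s), ``s0``
    and ``m0`` (arbitrary units), each a 3-D array on the atlas grid.
    ``roi_values[(subject, condition)]`` holds the drawn scalar per ROI name.
    """

    atlas: np.ndarray
    maps: dict
    roi_values: dict
    spec: PhantomSpec
    conditions: tuple = CONDITIONS

    @property
    def brain_mask(self) -> np.ndarray:
        return self.atlas > 0


# Published regional means +/- between-subject SDs, both conditions.
# Order per row: CBF, OEF(%), R2'(s^-1), DBV(%), CMRO2 — mean/sd pairs.
_TABLE1 = {
    #            CBF pre        CBF post        OEF pre      OEF post      R2' pre     R2' post     DBV pre      DBV post     CMRO2 pre      CMRO2 post
    "AG":   ((60.7, 15.6), (81.8, 22.4), (44.4, 4.1), (38.2, 3.8), (4.8, 1.0), (4.3, 0.8), (3.1, 0.7), (3.5, 0.7), (223.0, 58.2), (260.8, 80.1)),
    "MFG":  ((43.2, 10.6), (74.8, 23.2), (32.4, 10.9), (30.3, 11.6), (9.1, 2.6), (9.0, 2.1), (11.0, 6.1), (12.2, 6.0), (117.1, 47.7), (173.5, 40.6)),
    "aCG":  ((68.6, 14.5), (93.3, 21.3), (35.9, 4.7), (30.7, 6.5), (3.8, 0.4), (3.9, 0.7), (3.2, 0.4), (4.3, 1.4), (206.3, 57.1), (238.4, 82.3)),
    "pCG":  ((76.3, 14.8), (104.4, 17.8), (34.5, 4.8), (25.7, 4.7), (3.7, 0.3), (3.7, 0.5), (3.4, 0.8), (4.5, 1.3), (216.9, 51.8), (221.5, 51.1)),
    "PCun": ((61.6, 11.1), (87.6, 18.1), (39.6, 4.2), (30.9, 4.1), (4.0, 0.7), (3.6, 0.7), (3.2, 0.7), (3.7, 0.7), (201.7, 43.8), (223.1, 54.0)),
    "SG":   ((54.9, 14.1), (76.4, 22.2), (43.2, 5.2), (39.1, 2.5), (5.1, 0.5), (4.7, 0.6), (3.1, 0.9), (3.4, 0.9), (194.9, 51.3), (246.7, 70.6)),
    "OP":   ((40.0, 9.7), (58.4, 8.8), (30.7, 8.3), (27.2, 7.2), (7.1, 1.6), (6.5, 0.7), (7.8, 2.2), (8.2, 2.1), (103.2, 38.9), (130.4, 35.8)),
    "MTG":  ((54.5, 13.7), (76.1, 20.7), (25.9, 3.0), (25.1, 3.0), (7.8, 1.0), (7.1, 0.8), (11.5, 2.8), (10.7, 2.5), (115.6, 28.8), (154.9, 33.5)),
    "ITG":  ((40.2, 10.7), (57.6, 13.5), (29.3, 3.1), (27.1, 2.3), (11.1, 1.2), (10.4, 1.9), (17.6, 3.1), (16.1, 3.6), (100.3, 28.1), (130.3, 35.8)),
}


def default_table1_spec(seed: int = 0, *, n_subjects: int = 8, sd_scale: float = 1.0,
                        **overrides) -> PhantomSpec:
    """The nine-region reference phantom spec with published means and SDs.

    ``sd_scale`` rescales every between-subject SD (0 gives a deterministic
    phantom whose regional truths equal the spec means exactly).  Additional
    :class:`PhantomSpec` fields can be overridden by keyword.
    """
    table = {}
    for i, name in enumerate(CANONICAL_ROIS, start=1):
        row = _TABLE1[name]
        conds = []
        for c in (0, 1):  # pre, post
            conds.append(ConditionParams(
                cbf_mean=row[0 + c][0], cbf_sd=sd_scale * row[0 + c][1],
                oef_mean=row[2 + c][0], oef_sd=sd_scale * row[2 + c][1],
                r2p_mean=row[4 + c][0], r2p_sd=sd_scale * row[4 + c][1],
                dbv_mean=row[6 + c][0], dbv_sd=sd_scale * row[6 + c][1],
                cmro2_mean=row[8 + c][0], cmro2_sd=sd_scale * row[8 + c][1],
            ))
        table[name] = RoiSpec(label=i, name=name, pre=conds[0], post=conds[1])
    return PhantomSpec(seed=seed, roi_table=table, n_subjects=n_subjects, **overrides)


def _layout_blocks(grid_shape, labels):
    """Place up to 9 ROIs as disjoint blocks in a 3x3 in-plane arrangement."""
    nx, ny, nz = grid_shape
    if min(nx, ny) < 9 or nz < 3:
        raise ValueError("grid too small for the 3x3 block layout")
    atlas = np.zeros(grid_shape, dtype=np.int32)
    tile_x, tile_y = nx // 3, ny // 3
    z0, z1 = nz // 3, max(nz // 3 + 1, 2 * nz // 3)
    for k, label in enumerate(labels):
        if k >= 9:
            raise ValueError("block layout supports at most 9 ROIs")
        ix, iy = divmod(k, 3)
        x0, y0 = ix * tile_x + 1, iy * tile_y + 1
        x1, y1 = (ix + 1) * tile_x - 1, (iy + 1) * tile_y - 1
        if x1 <= x0 or y1 <= y0:
            raise ValueError("grid too small for non-empty ROI blocks")
        block = atlas[x0:x1, y0:y1, z0:z1]
        if np.any(block != 0):
            raise ValueError("overlapping ROI blocks")
        block[...] = label
    return atlas


def build_phantom(spec: PhantomSpec, const: TissueConstants | None = None,
                  b0: float = 3.0) -> PhantomTruth:
    """Build ground-truth volumes for every subject and condition.

    Regional values are drawn from the spec Gaussians with a seeded RNG;
    OEF and DBV are clipped to physiological fractions and R2' is derived as
    ``DBV * delta_omega(OEF)`` so the truth satisfies the dephasing relation
    exactly.  ATT is constant, S0 = M0 = 1.
    """
    const = const or TissueConstants()
    labels = {name: r.label for name, r in spec.roi_table.items()}
    atlas = _layout_blocks(spec.grid_shape, list(labels.values()))
    rng = np.random.default_rng(spec.seed)

    maps = {}
    roi_values = {}
    for subject in range(spec.n_subjects):
        for cond in CONDITIONS:
            oef = np.zeros(spec.grid_shape)
            dbv = np.zeros(spec.grid_shape)
            cbf = np.zeros(spec.grid_shape)
            drawn = {}
            for name, roi in spec.roi_table.items():
                p = roi.condition(cond)
                cbf_v = max(rng.normal(p.cbf_mean, p.cbf_sd), 0.0)
                oef_v = float(np.clip(rng.normal(p.oef_mean, p.oef_sd) / 100.0, 1e-3, 0.99))
                dbv_v = float(np.clip(rng.normal(p.dbv_mean, p.dbv_sd) / 100.0, 1e-3, 0.5))
                sel = atlas == roi.label
                oef[sel], dbv[sel], cbf[sel] = oef_v, dbv_v, cbf_v
                if spec.within_roi_jitter > 0:
                    n = int(sel.sum())
                    oef[sel] = np.clip(oef_v * (1 + spec.within_roi_jitter * rng.standard_normal(n)), 1e-3, 0.99)
                    dbv[sel] = np.clip(dbv_v * (1 + spec.within_roi_jitter * rng.standard_normal(n)), 1e-3, 0.5)
                drawn[name] = {"cbf": cbf_v, "oef": oef_v, "dbv": dbv_v}
            r2p = dbv * delta_omega(oef, const, b0)
            for name in drawn:
                drawn[name]["r2p"] = drawn[name]["dbv"] * delta_omega(drawn[name]["oef"], const, b0)
            maps[(subject, cond)] = {
                "oef": oef,
                "dbv": dbv,
                "r2p": r2p,
                "cbf": cbf,
                "att": np.full(spec.grid_shape, spec.att_s),
                "s0": np.ones(spec.grid_shape),
                "m0": np.ones(spec.grid_shape),
            }
            roi_values[(subject, cond)] = drawn
    return PhantomTruth(atlas=atlas, maps=maps, roi_values=roi_values, spec=spec)


def _spawned_rngs(seed, truth: PhantomTruth):
    seq = np.random.SeedSequence(seed)
    keys = sorted(truth.maps.keys())
    children = seq.spawn(len(keys))
    return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


def simulate_ase_study(truth: PhantomTruth, proto: AseProtocol, snr: float, seed: int,
                       const: TissueConstants | None = None) -> dict:
    """Simulate tau-stacked ASE volumes for every subject and condition.

    Noise is i.i.d. Gaussian with SD equal to the brain-average tau = 0
    signal divided by ``snr`` (``snr = inf`` is noise-free); realizations
    differ across subjects/conditions but are reproducible under ``seed``.
    Returns ``{(subject, condition): 4-D array}`` with tau last.
    """
    const = const or TissueConstants()
    rngs = _spawned_rngs(seed, truth)
    brain = truth.brain_mask
    out = {}
    for key, m in truth.maps.items():
        stack = ase_signal_stack(m["s0"], m["oef"], m["dbv"], const, proto)
        stack[~brain] = 0.0
        if np.isfinite(snr):
            se_mean = float(stack[..., 0][brain].mean()) if brain.any() else 1.0
            stack = stack + rngs[key].normal(0.0, se_mean / snr, size=stack.shape)
        out[key] = stack
    return out


def simulate_asl_study(truth: PhantomTruth, proto: AslProtocol, snr: float, seed: int) -> dict:
    """Simulate multi-PLD dM series plus an M0 volume per subject/condition.

    Noise SD is the brain-average M0 divided by ``snr``.  Returns
    ``{(subject, condition): (dm_4d, m0_volume)}`` with PLD last.
    """
    rngs = _spawned_rngs(seed, truth)
    brain = truth.brain_mask
    t = proto.label_duration + proto.pld_array
    out = {}
    for key, m in truth.maps.items():
        f = m["cbf"] / CBF_UNIT_FACTOR
        dm = np.empty(truth.atlas.shape + (len(proto.plds),))
        for k in range(len(proto.plds)):
            dm[..., k] = _dm_core(f, m["att"], m["m0"], proto, t[k])
        dm[~brain] = 0.0
        m0 = np.where(brain, m["m0"], 0.0)
        if np.isfinite(snr):
            m0_mean = float(m["m0"][brain].mean()) if brain.any() else 1.0
            rng = rngs[key]
            dm = dm + rng.normal(0.0, m0_mean / snr, size=dm.shape)
            m0 = m0 + rng.normal(0.0, m0_mean / snr, size=m0.shape)
        out[key] = (dm, m0)
    return out
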