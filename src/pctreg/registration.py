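"""Adaptive-template registration: joint optimization of the spatial
transform and the template appearance weight w.

The cascade follows the template-matching design for amyloid PET:

1. multiresolution 12-parameter affine registration, maximizing normalized
   mutual information (NMI) over the whole volume, with w as a 13th
   optimization coordinate — at every objective evaluation the template is
   re-synthesized as I_PC1 + w I_PC2 for the current w;
2. masked refinement over a brain mask without ventricles, continuing the
   affine and adding a second-order polynomial deformation (NMI, 43
   coordinates including w);
3. hand-off to the reference-region rigid refinement (normalized cross
   correlation; see :mod:`pctreg.refinement`).

Powell's direction-set method is used throughout; it needs no gradients,
which suits the histogram-based NMI objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import yaml
from scipy import optimize

from .pca import PrincipalComponentModel, PCAError
from .transforms import (
    AffineTransform,
    PolynomialTransform,
    TransformChain,
    N_POLY_TERMS,
)
from .volume import Volume, build_pyramid, sample_at_world

__all__ = [
    "RegistrationConfig",
    "RegistrationError",
    "NonFiniteObjectiveError",
    "normalized_mutual_information",
    "normalized_cross_correlation",
    "powell_minimize",
    "register_adaptive",
]


class RegistrationError(Exception):
    pass


class NonFiniteObjectiveError(RegistrationError):
    """Raised when the objective turns non-finite during a Powell search."""

    def __init__(self, x: np.ndarray, value: float):
        self.x = np.asarray(x)
        self.value = value
        super().__init__(f"objective became {value} at parameters {self.x.tolist()}")


# ---------------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------------

def _as_samples(a, mask=None) -> np.ndarray:
    arr = a.data if isinstance(a, Volume) else np.asarray(a)
    arr = np.asarray(arr, dtype=np.float64)
    if mask is not None:
        arr = arr[np.asarray(mask, dtype=bool)] if arr.ndim == 3 else arr
    else:
        arr = arr.ravel()
    return arr


def nmi_from_samples(av: np.ndarray, bv: np.ndarray, bins: int = 64) -> float:
    """NMI = (H(A) + H(B)) / H(A, B) from a joint histogram of paired samples."""
    a_lo, a_hi = float(av.min()), float(av.max())
    b_lo, b_hi = float(bv.min()), float(bv.max())
    if a_hi <= a_lo or b_hi <= b_lo:
        warnings.warn("constant image in NMI computation; returning 1.0", stacklevel=2)
        return 1.0
    # joint histogram via bincount (equivalent to np.histogram2d on the
    # [min, max] range, values at the top edge landing in the last bin)
    ia = np.clip(((av - a_lo) * (bins / (a_hi - a_lo))).astype(np.intp), 0, bins - 1)
    ib = np.clip(((bv - b_lo) * (bins / (b_hi - b_lo))).astype(np.intp), 0, bins - 1)
    h = np.bincount(ia * bins + ib, minlength=bins * bins).astype(float).reshape(bins, bins)
    p = h / h.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hab = ent(p.ravel())
    if hab <= 0:
        warnings.warn("zero joint entropy in NMI computation; returning 1.0", stacklevel=2)
        return 1.0
    return (ent(pa) + ent(pb)) / hab


def normalized_mutual_information(a, b, mask=None, bins: int = 64) -> float:
    """Normalized mutual information of two images over an optional mask.

    Values lie in [1, 2]; 2 means the discrete joint histogram is a
    bijection (identical images), 1 means independence.
    """
    if bins < 8:
        raise RegistrationError("NMI needs at least 8 bins")
    av = _as_samples(a, mask)
    bv = _as_samples(b, mask)
    if av.shape != bv.shape:
        raise RegistrationError("images (or masked samples) differ in size")
    if av.size < 100:
        raise RegistrationError(f"NMI needs >= 100 voxels, got {av.size}")
    return nmi_from_samples(av, bv, bins)


def normalized_cross_correlation(a, b, mask=None) -> float:
    """Pearson correlation of paired voxel intensities within a mask."""
    av = _as_samples(a, mask)
    bv = _as_samples(b, mask)
    if av.size == 0:
        raise RegistrationError("empty mask in NCC")
    sa, sb = av.std(), bv.std()
    if sa == 0 or sb == 0:
        raise RegistrationError("constant input within mask; NCC undefined")
    return float(np.corrcoef(av, bv)[0, 1])


# ---------------------------------------------------------------------------
# Powell wrapper
# ---------------------------------------------------------------------------

def powell_minimize(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: Optional[Sequence[tuple[float, float]]] = None,
    xtol: float = 1e-3,
    ftol: float = 1e-5,
    max_iter: int = 20,
) -> tuple[np.ndarray, float, int]:
    """Direction-set minimization without gradients (Powell's method).

    Returns (x*, f*, n_eval).  Deterministic given identical inputs; a
    non-finite objective value anywhere in the search aborts with
    :class:`NonFiniteObjectiveError` naming the offending parameter vector.
    """
    x0 = np.asarray(x0, dtype=float)
    f0 = objective(x0)
    if not np.isfinite(f0):
        raise NonFiniteObjectiveError(x0, f0)

    def checked(x: np.ndarray) -> float:
        v = objective(x)
        if not np.isfinite(v):
            raise NonFiniteObjectiveError(x, v)
        return v

    res = optimize.minimize(
        checked,
        x0,
        method="Powell",
        bounds=bounds,
        options={
            "xtol": xtol,
            "ftol": ftol,
            "maxiter": max_iter,
            "maxfev": 200_000,
        },
    )
    return np.asarray(res.x, dtype=float), float(res.fun), int(res.nfev)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationConfig:
    """Settings for the staged adaptive registration.

    Parameter scaling makes one Powell step commensurate across parameter
    types: rotations move in units of 0.01 rad, translations in mm, scales
    and shears in units of 0.01, polynomial coefficients in units of a tenth
    of a voxel, and w in units of 0.1.
    """

    schema_version: int = 1
    n_levels: int = 2
    pyramid_fwhm_voxels: float = 2.0
    nmi_bins: int = 64
    xtol: float = 0.005
    ftol: float = 1e-4
    max_iter: int = 20
    template_presmooth_voxels: float = 0.5
    w_init: float = 0.0
    w_bounds: tuple[float, float] = (-1.0, 1.0)
    sampling_stride: int = 2
    max_restarts: int = 3
    enable_polynomial_stage: bool = True
    freeze_w: Optional[float] = None
    # reference refinement settings (used by pctreg.refinement); the rigid
    # step is a local correction, so its search is box-bounded
    reference_fraction: float = 0.85
    reference_sigma_mm: float = 3.0
    reference_max_trans_mm: float = 8.0
    reference_max_rot_deg: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.xtol <= 0 or self.ftol <= 0:
            raise RegistrationError("tolerances must be positive")
        lo, hi = self.w_bounds
        if lo < -1.0 or hi > 1.0 or lo >= hi:
            raise RegistrationError("w bounds must be a sub-interval of [-1, 1]")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["w_bounds"] = list(self.w_bounds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegistrationConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "w_bounds" in d:
            d["w_bounds"] = tuple(d["w_bounds"])
        return cls(**d)


# ---------------------------------------------------------------------------
# adaptive registration
# ---------------------------------------------------------------------------

_AFFINE_SCALES = np.array([1.0, 1.0, 1.0, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01])
_W_SCALE = 0.1
_MIN_SCALE = 0.1  # hard floor on affine scale factors inside the objective


def _clamp_physical(p12: np.ndarray) -> np.ndarray:
    p12 = p12.copy()
    p12[6:9] = np.maximum(p12[6:9], _MIN_SCALE)
    return p12


def _grid_points_and_values(level: Volume, stride: int) -> tuple[np.ndarray, tuple]:
    """Voxel-centre world points of a level grid (optionally strided)."""
    sl = (slice(None, None, stride),) * 3
    idx = np.indices(level.shape, dtype=float)[(slice(None),) + sl]
    pts = level.voxel_to_world(idx.reshape(3, -1).T)
    return pts, sl


def register_adaptive(
    subject: Volume,
    model: PrincipalComponentModel,
    config: Optional[RegistrationConfig] = None,
    brain_mask_noventricles: Optional[np.ndarray] = None,
) -> TransformChain:
    """Register a subject scan to template space with an adaptive template.

    Stage 1 optimizes the 12 affine parameters plus w coarse-to-fine with NMI
    over the whole volume; stage 2 continues the affine, adds a 30-coefficient
    second-order polynomial deformation and keeps optimizing w, with NMI
    restricted to ``brain_mask_noventricles``.  The template is re-synthesized
    for the current w at every objective evaluation.  The returned chain has
    ``local_rigid`` unset; the reference-region refinement fills it in.
    """
    if config is None:
        config = RegistrationConfig()
    if model.n_components < 2:
        raise PCAError("adaptive registration needs a model with >= 2 components")

    pc1 = model.components[0]
    pc2 = model.components[1]
    template_grid = pc1
    center = 0.5 * (np.add(*template_grid.world_bounds()))
    w_lo, w_hi = config.w_bounds

    # Both images are pre-smoothed by a small common kernel before the NMI
    # stages: trilinear interpolation low-pass filters the moving image by a
    # comparable amount at every evaluation, and matching the two marginals
    # of the joint histogram removes a bias in the w estimate at the finest
    # level.
    metric_subject = subject
    if config.template_presmooth_voxels > 0:
        from scipy import ndimage as _ndi

        s = config.template_presmooth_voxels
        pc1 = pc1.like(_ndi.gaussian_filter(np.asarray(pc1.data, float), s))
        pc2 = pc2.like(_ndi.gaussian_filter(np.asarray(pc2.data, float), s))
        metric_subject = subject.like(
            _ndi.gaussian_filter(np.asarray(subject.data, float), s)
        )

    pyr1 = build_pyramid(pc1, config.n_levels, config.pyramid_fwhm_voxels)
    pyr2 = build_pyramid(pc2, config.n_levels, config.pyramid_fwhm_voxels)
    pyr_subj = build_pyramid(metric_subject, config.n_levels, config.pyramid_fwhm_voxels)

    freeze_w = config.freeze_w
    w_cur = float(np.clip(config.w_init, w_lo, w_hi)) if freeze_w is None else float(freeze_w)

    warnings_log: list[str] = []
    stage_metrics: list[dict] = []

    def make_stage1_objective(level_i: int):
        lvl1, lvl2 = pyr1[level_i], pyr2[level_i]
        subj_lvl = pyr_subj[level_i]
        stride = config.sampling_stride if level_i == config.n_levels - 1 else 1
        pts, sl = _grid_points_and_values(lvl1, stride)
        t1 = np.asarray(lvl1.data[sl], dtype=np.float64).ravel()
        t2 = np.asarray(lvl2.data[sl], dtype=np.float64).ravel()

        def objective(u: np.ndarray) -> float:
            p12 = _clamp_physical(u[:12] * _AFFINE_SCALES)
            w = (
                freeze_w
                if freeze_w is not None
                else float(np.clip(u[12] * _W_SCALE, w_lo, w_hi))
            )
            aff = AffineTransform(p12, center)
            sv = sample_at_world(subj_lvl, aff.map_points(pts))
            tv = t1 + w * t2
            return -nmi_from_samples(tv, sv, config.nmi_bins)

        return objective

    # ---- stage 1: multiresolution global affine (+ w) -------------------
    # with freeze_w set, w is not an optimization coordinate at all
    n_w = 0 if freeze_w is not None else 1
    u = np.zeros(12 + n_w)
    u[:12] = AffineTransform.identity().parameters / _AFFINE_SCALES
    if n_w:
        u[12] = w_cur / _W_SCALE

    # initialization: align intensity centroids, then scan a small grid of
    # rotation and appearance-weight candidates at the coarsest level to
    # pick the starting basin before the joint optimization
    lvl0_t, lvl0_s = pyr1[0], pyr_subj[0]

    def _centroid(vol: Volume) -> np.ndarray:
        wgt = np.abs(np.asarray(vol.data, dtype=float)).ravel()
        tot = wgt.sum()
        if tot <= 0:
            return 0.5 * np.add(*vol.world_bounds())
        pts0 = vol.grid_world_coordinates()
        return (pts0 * wgt[:, None]).sum(axis=0) / tot

    u[:3] = _centroid(lvl0_s) - _centroid(lvl0_t)
    obj0 = make_stage1_objective(0)
    rot_step = np.deg2rad(8.0) / _AFFINE_SCALES[3]
    w_cands = np.linspace(w_lo, w_hi, 5) if n_w else [None]
    best_init, best_u = np.inf, u.copy()
    for rx in (-rot_step, 0.0, rot_step):
        for ry in (-rot_step, 0.0, rot_step):
            for rz in (-rot_step, 0.0, rot_step):
                for wc in w_cands:
                    uc = u.copy()
                    uc[3:6] = [rx, ry, rz]
                    if wc is not None:
                        uc[12] = wc / _W_SCALE
                    f = obj0(uc)
                    if f < best_init:
                        best_init, best_u = f, uc
    u = best_u
    prev_best = None
    for level_i in range(config.n_levels):
        obj = make_stage1_objective(level_i)
        if n_w:
            # cheap re-scan of the appearance weight with the current affine:
            # w and the transform are coupled, and the joint line searches can
            # leave w in a shallow side valley
            cands = np.linspace(w_lo, w_hi, 9)
            scores = []
            for wc in cands:
                uc = u.copy()
                uc[12] = wc / _W_SCALE
                scores.append(obj(uc))
            u[12] = cands[int(np.argmin(scores))] / _W_SCALE
        start = obj(u)
        if prev_best is not None and start > prev_best + 0.05:
            warnings_log.append(
                f"objective worsened moving to pyramid level {level_i}: "
                f"{prev_best:.5f} -> {start:.5f}"
            )
        # Powell with direction-set restarts: re-initializing the directions
        # after convergence escapes the degenerate direction sets that
        # direction-set methods accumulate on coupled objectives
        best = start
        nfev = 0
        for _ in range(max(1, config.max_restarts)):
            u_new, f_new, ne = powell_minimize(
                obj, u, xtol=config.xtol, ftol=config.ftol, max_iter=config.max_iter
            )
            nfev += ne
            if f_new < best - abs(config.ftol) * max(1.0, abs(best)):
                u, best = u_new, f_new
            else:
                if f_new < best:
                    u, best = u_new, f_new
                break
        if best > start + 1e-12:
            warnings_log.append(f"divergence at level {level_i}; keeping starting point")
            best = start
        prev_best = best
        stage_metrics.append(
            {
                "stage": "affine",
                "level": level_i,
                "nmi": -best,
                "nmi_start": -start,
                "n_eval": nfev,
            }
        )

    affine_params = _clamp_physical(u[:12] * _AFFINE_SCALES)
    w_cur = freeze_w if n_w == 0 else float(np.clip(u[12] * _W_SCALE, w_lo, w_hi))
    stage1_u = u.copy()

    # ---- stage 2: masked affine + polynomial refinement ------------------
    polynomial = None
    if config.enable_polynomial_stage:
        if brain_mask_noventricles is None:
            warnings_log.append("no brain mask supplied; polynomial stage skipped")
        else:
            mask = np.asarray(brain_mask_noventricles, dtype=bool)
            if mask.shape != template_grid.shape:
                raise RegistrationError("brain mask shape does not match the template grid")
            stride = config.sampling_stride
            sub = np.zeros_like(mask)
            sub[::stride, ::stride, ::stride] = True
            sel = mask & sub
            ii = np.argwhere(sel).astype(float)
            pts = template_grid.voxel_to_world(ii)
            t1 = np.asarray(pc1.data[sel], dtype=np.float64)
            t2 = np.asarray(pc2.data[sel], dtype=np.float64)
            bounds = template_grid.world_bounds()
            basis = PolynomialTransform.zero(bounds).basis(
                PolynomialTransform.zero(bounds)._normalize(pts)
            )
            voxel_mm = float(template_grid.voxel_sizes.mean())
            poly_scale = 0.1 * voxel_mm

            def objective2(u2: np.ndarray) -> float:
                p12 = _clamp_physical(u2[:12] * _AFFINE_SCALES)
                coeffs = (u2[12:42] * poly_scale).reshape(3, N_POLY_TERMS)
                w = (
                    freeze_w
                    if freeze_w is not None
                    else float(np.clip(u2[42] * _W_SCALE, w_lo, w_hi))
                )
                aff = AffineTransform(p12, center)
                mpts = aff.map_points(pts) + basis @ coeffs.T
                sv = sample_at_world(metric_subject, mpts)
                tv = t1 + w * t2
                return -nmi_from_samples(tv, sv, config.nmi_bins)

            u2 = np.zeros(42 + n_w)
            u2[:12] = stage1_u[:12]
            if n_w:
                u2[42] = stage1_u[12]
            start2 = objective2(u2)
            u2, best2, nfev2 = powell_minimize(
                objective2, u2, xtol=config.xtol, ftol=config.ftol, max_iter=config.max_iter
            )
            if best2 > start2 + 1e-12:
                warnings_log.append("masked refinement worsened NMI; keeping affine stage")
            else:
                affine_params = _clamp_physical(u2[:12] * _AFFINE_SCALES)
                coeffs = (u2[12:42] * poly_scale).reshape(3, N_POLY_TERMS)
                polynomial = PolynomialTransform(coeffs, bounds)
                if n_w:
                    w_cur = float(np.clip(u2[42] * _W_SCALE, w_lo, w_hi))
            stage_metrics.append(
                {
                    "stage": "masked_poly",
                    "level": config.n_levels - 1,
                    "nmi": -min(best2, start2),
                    "nmi_start": -start2,
                    "n_eval": nfev2,
                }
            )

    if freeze_w is None and (
        abs(w_cur - w_lo) < 1e-9 or abs(w_cur - w_hi) < 1e-9
    ):
        warnings_log.append(f"template weight pinned at bound w={w_cur:+.2f}")

    chain = TransformChain(
        affine=AffineTransform(affine_params, center),
        polynomial=polynomial,
        local_rigid=None,
        weight=w_cur,
        metadata={
            "stages": stage_metrics,
            "warnings": warnings_log,
            "config": {**asdict(config), "w_bounds": list(config.w_bounds)},
        },
    )
    return chain
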