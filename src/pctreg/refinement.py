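"""Rigid refinement of the cerebellum / brain-stem (reference region) fit.

Quantification leans on the reference region, so after the global stages a
6-parameter rigid registration is run for the cerebellum and brain stem
alone.  Only the characteristic high-uptake voxels of the synthetic template
within a binary cerebellum+brain-stem mask drive the fit (voxels at or above
the 85th percentile of the within-mask intensity histogram), scored with
normalized cross correlation.  The rigid increment is then blended into the
global transform through a Gaussian-smoothed copy of the mask, weighting the
mapped coordinates so the composite displacement field stays continuous:
voxels with smoothed weight 1 get the full rigid correction, voxels outside
the mask none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .pca import SyntheticTemplate
from .registration import (
    RegistrationConfig,
    RegistrationError,
    powell_minimize,
)
from .transforms import RigidTransform, TransformChain
from .volume import Volume, sample_at_world

__all__ = [
    "ReferenceMask",
    "RefinementError",
    "subsample_high_uptake",
    "make_smoothed_mask",
    "rigid_refine",
    "blend_local_transform",
    "refine_reference_region",
]


class RefinementError(Exception):
    pass


@dataclass
class ReferenceMask:
    """Binary cerebellum+brain-stem mask with its smoothed and subsampled forms."""

    binary: np.ndarray
    smoothed: Volume
    subsampled: np.ndarray

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary, dtype=bool)
        self.subsampled = np.asarray(self.subsampled, dtype=bool)
        if not self.subsampled.any():
            raise RefinementError("subsampled reference mask is empty")
        if (self.subsampled & ~self.binary).any():
            raise RefinementError("subsampled voxels must lie inside the binary mask")


def subsample_high_uptake(
    template: SyntheticTemplate | Volume,
    binary_mask: np.ndarray,
    fraction: float = 0.85,
) -> np.ndarray:
    """High-uptake voxels of the template within the mask.

    The threshold is the ``fraction`` quantile (linear-interpolation
    convention) of the within-mask intensity distribution; voxels with
    intensity >= threshold survive, i.e. roughly the top (1 - fraction) of
    the mask.
    """
    if not 0.0 < fraction < 1.0:
        raise RefinementError("fraction must lie strictly between 0 and 1")
    vol = template.volume if isinstance(template, SyntheticTemplate) else template
    mask = np.asarray(binary_mask, dtype=bool)
    if not mask.any():
        raise RefinementError("empty reference mask")
    vals = np.asarray(vol.data, dtype=float)[mask]
    if vals.max() <= vals.min():
        raise RefinementError("constant template within the reference mask")
    thr = float(np.quantile(vals, fraction))
    out = mask & (np.asarray(vol.data, dtype=float) >= thr)
    if not out.any():
        raise RefinementError(f"no voxels at or above threshold {thr}")
    return out


def make_smoothed_mask(binary: np.ndarray, sigma_mm: float, grid: Volume) -> Volume:
    """Gaussian-blurred 0/1 mask on the template grid, clipped to [0, 1]."""
    if sigma_mm <= 0:
        raise RefinementError("sigma must be positive")
    mask = np.asarray(binary, dtype=float)
    if not mask.any():
        raise RefinementError("empty binary mask")
    sigma_vox = sigma_mm / grid.voxel_sizes
    sm = ndimage.gaussian_filter(mask, sigma=sigma_vox)
    return grid.like(np.clip(sm, 0.0, 1.0))


def rigid_refine(
    subject: Volume,
    template: SyntheticTemplate,
    chain: TransformChain,
    subsampled: np.ndarray,
    config: Optional[RegistrationConfig] = None,
) -> RigidTransform:
    """Optimize the 6 rigid parameters over the subsampled template voxels.

    The fixed grid is template space restricted to the subsampled voxels; the
    subject is sampled through global-after-rigid, scored with NCC, starting
    from identity.  w stays frozen at the value the global stage accepted.
    """
    if config is None:
        config = RegistrationConfig()
    sub = np.asarray(subsampled, dtype=bool)
    if not sub.any():
        raise RefinementError("subsampled reference mask is empty")
    grid = template.volume
    pts = grid.voxel_to_world(np.argwhere(sub).astype(float))
    # both arms of the correlation are pre-smoothed by the same small kernel
    # (the subject passes through trilinear interpolation, which low-pass
    # filters it; matching the template removes a sub-voxel bias)
    sm = config.template_presmooth_voxels
    if sm > 0:
        tdat = ndimage.gaussian_filter(np.asarray(grid.data, dtype=float), sm)
        subject = subject.like(
            ndimage.gaussian_filter(np.asarray(subject.data, dtype=float), sm)
        )
    else:
        tdat = np.asarray(grid.data, dtype=float)
    tv = tdat[sub]
    if tv.std() == 0:
        raise RegistrationError("constant template over the subsampled voxels")
    center = pts.mean(axis=0)
    scales = np.array([1.0, 1.0, 1.0, 0.01, 0.01, 0.01])
    # an already-refined chain contributes its rigid part, so a repeated
    # refinement estimates an increment on top of it (fixed point: identity)
    pre_rigid = chain.local_rigid[0] if chain.local_rigid is not None else None

    def objective(u: np.ndarray) -> float:
        rigid = RigidTransform(u * scales, center)
        q = rigid.map_points(pts)
        if pre_rigid is not None:
            q = pre_rigid.map_points(q)
        mpts = chain.map_points_global(q)
        sv = sample_at_world(subject, mpts)
        if sv.std() == 0:
            raise RegistrationError("constant subject under the reference mask")
        c = np.corrcoef(tv, sv)[0, 1]
        return -float(c)

    u0 = np.zeros(6)
    f0 = objective(u0)
    tmax = config.reference_max_trans_mm
    rmax = np.deg2rad(config.reference_max_rot_deg) / 0.01
    bounds = [(-tmax, tmax)] * 3 + [(-rmax, rmax)] * 3
    u, f, _ = powell_minimize(
        objective, u0, bounds=bounds,
        xtol=config.xtol, ftol=config.ftol, max_iter=config.max_iter
    )
    if f > f0:  # never accept a worse NCC than the identity increment
        u, f = u0, f0
    return RigidTransform(u * scales, center)


def blend_local_transform(
    chain: TransformChain, rigid: RigidTransform, smoothed: Volume
) -> TransformChain:
    """Attach the rigid increment, blended through the smoothed mask.

    The final mapping at template point x is
    ``(1 - s(x)) G(x) + s(x) G(R(x))`` — linear interpolation between the two
    mapped coordinates, which keeps the displacement field continuous.
    """
    s = np.asarray(smoothed.data, dtype=float)
    if s.min() < -1e-9 or s.max() > 1.0 + 1e-9:
        raise RefinementError("smoothed mask values must lie in [0, 1]")
    return TransformChain(
        affine=chain.affine,
        polynomial=chain.polynomial,
        local_rigid=(rigid, smoothed),
        weight=chain.weight,
        metadata={
            **chain.metadata,
            "stages": list(chain.metadata.get("stages", [])),
        },
    )


def refine_reference_region(
    subject: Volume,
    template: SyntheticTemplate,
    chain: TransformChain,
    binary_mask: np.ndarray,
    config: Optional[RegistrationConfig] = None,
) -> tuple[TransformChain, ReferenceMask]:
    """Full reference-region step: subsample, rigid fit, blend.  Returns the
    completed chain and the masks used."""
    if config is None:
        config = RegistrationConfig()
    sub = subsample_high_uptake(template, binary_mask, config.reference_fraction)
    smoothed = make_smoothed_mask(binary_mask, config.reference_sigma_mm, template.volume)
    rigid = rigid_refine(subject, template, chain, sub, config)
    out = blend_local_transform(chain, rigid, smoothed)
    out.metadata.setdefault("stages", []).append(
        {
            "stage": "reference_rigid",
            "n_subsampled": int(sub.sum()),
            "rigid_parameters": rigid.parameters.tolist(),
        }
    )
    return out, ReferenceMask(binary=binary_mask, smoothed=smoothed, subsampled=sub)
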