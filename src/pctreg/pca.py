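"""Principal-component template model for amyloid-PET appearance.

Given n spatially- and intensity-normalized images with p voxels each, form
X (p x n), centre it with the mean image mu to get D = X - mu 1', and
eigendecompose the n x n Gram-form sample covariance

    C = D'D / (n - 1) = V Lambda V'.

Eigenimages are obtained by projecting the centred stack onto the
eigenvectors, I_PCi = D q_i, so the p x p voxel covariance is never
materialized.  Eigenimages keep the intensity-like scale this projection
gives them (||I_PCi|| = sqrt((n-1) lambda_i)); the adaptive template is the
literal two-component combination

    I_synthetic = I_PC1 + w I_PC2,   w in [-1, 1],

whose appearance sweeps the negative-to-positive amyloid continuum of the
training cohort as w moves from -1 to +1.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .volume import Volume, load_volume, save_volume

__all__ = [
    "ImageStack",
    "PrincipalComponentModel",
    "SyntheticTemplate",
    "PCAError",
    "compute_mean",
    "fit_pc_model",
    "explained_variance_fraction",
    "synthesize_template",
    "fix_component_signs",
    "save_model",
    "load_model",
]


class PCAError(Exception):
    pass


@dataclass
class ImageStack:
    """n volumes on a common grid plus subject identifiers."""

    volumes: list[Volume]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.volumes) < 2:
            raise PCAError("an image stack needs at least 2 volumes")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if not ref.same_grid(v):
                raise PCAError("stack volumes are on mismatched grids")
        if not self.ids:
            self.ids = [f"img{i:03d}" for i in range(len(self.volumes))]
        if len(self.ids) != len(self.volumes):
            raise PCAError("ids/volumes length mismatch")

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def grid(self) -> Volume:
        return self.volumes[0]

    def as_matrix(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Stack voxels as a (p, n) float64 matrix, optionally mask-restricted."""
        if mask is None:
            cols = [np.asarray(v.data, dtype=np.float64).ravel() for v in self.volumes]
        else:
            m = np.asarray(mask, dtype=bool)
            cols = [np.asarray(v.data, dtype=np.float64)[m] for v in self.volumes]
        return np.stack(cols, axis=1)


@dataclass
class PrincipalComponentModel:
    """Mean image, ordered eigenimages, and the full eigenvalue spectrum.

    ``eigenvalues`` always holds all n-1 possible values (descending) even
    when fewer eigenimages are retained, so explained-variance fractions are
    exact.  ``mask`` is the template-space brain mask the decomposition was
    restricted to (components are zero outside it).
    """

    mean_image: Volume
    components: list[Volume]
    eigenvalues: np.ndarray
    n_train: int
    mask: Optional[np.ndarray] = None
    sign_flips: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-9 * max(1.0, self.eigenvalues.max(initial=0.0))):
            raise PCAError("eigenvalues must be sorted non-increasing")
        if not self.sign_flips:
            self.sign_flips = [1] * len(self.components)

    @property
    def grid(self) -> Volume:
        return self.mean_image

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class SyntheticTemplate:
    """An appearance-adaptive registration target at a given weight."""

    volume: Volume
    weight: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.weight <= 1.0:
            raise PCAError("template weight must lie in [-1, 1]")


def compute_mean(stack: ImageStack) -> Volume:
    """Voxel-wise arithmetic mean image of the stack."""
    acc = np.zeros(stack.grid.shape, dtype=np.float64)
    for v in stack.volumes:
        acc += np.asarray(v.data, dtype=np.float64)
    return Volume(acc / len(stack), stack.grid.affine.copy())


def fit_pc_model(
    stack: ImageStack,
    k: Optional[int] = None,
    mask: Optional[np.ndarray] = None,
) -> PrincipalComponentModel:
    """Fit the Gram-form PCA model to a stack.

    Parameters
    ----------
    stack : ImageStack
        n >= 2 volumes on a common grid.
    k : int, optional
        Number of eigenimages to retain (default n - 1).  All n - 1
        eigenvalues are stored regardless.
    mask : bool array, optional
        Template-space brain mask; voxels outside it are excluded from the
        decomposition and eigenimages are zero there.
    """
    n = len(stack)
    if k is None:
        k = n - 1
    if not 1 <= k <= n - 1:
        raise PCAError(f"k must be in [1, n-1] = [1, {n - 1}], got {k}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.grid.shape:
            raise PCAError("mask shape does not match the stack grid")

    X = stack.as_matrix(mask)  # (p, n)
    mu = X.mean(axis=1)
    D = X - mu[:, None]
    C = (D.T @ D) / (n - 1)  # n x n Gram-form covariance
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)[: n - 1]
    evecs = evecs[:, order]

    grid = stack.grid

    def embed(flat: np.ndarray) -> Volume:
        if mask is None:
            return Volume(flat.reshape(grid.shape), grid.affine.copy())
        full = np.zeros(grid.shape, dtype=np.float64)
        full[mask] = flat
        return Volume(full, grid.affine.copy())

    mean_full = compute_mean(stack) if mask is not None else embed(mu)
    components = [embed(D @ evecs[:, i]) for i in range(k)]
    return PrincipalComponentModel(
        mean_image=mean_full,
        components=components,
        eigenvalues=evals,
        n_train=n,
        mask=mask,
    )


def explained_variance_fraction(model: PrincipalComponentModel, m: int) -> float:
    """Fraction of total variance carried by the first m components."""
    if m < 1:
        raise PCAError("m must be >= 1")
    ev = model.eigenvalues
    if m > ev.size:
        raise PCAError(f"m={m} exceeds the {ev.size} stored eigenvalues")
    total = ev.sum()
    if total <= 0:
        # zero-variance stack: everything (nothing) is explained
        return 1.0
    return float(ev[:m].sum() / total)


def synthesize_template(model: PrincipalComponentModel, w: float) -> SyntheticTemplate:
    """Adaptive template I_PC1 + w * I_PC2; w outside [-1, 1] is clamped."""
    if model.n_components < 2:
        raise PCAError("synthesizing a template requires at least 2 components")
    wc = float(np.clip(w, -1.0, 1.0))
    if wc != w:
        warnings.warn(f"template weight {w} clamped to {wc}", stacklevel=2)
    data = model.components[0].data + wc * model.components[1].data
    return SyntheticTemplate(Volume(data, model.grid.affine.copy()), wc)


def fix_component_signs(
    model: PrincipalComponentModel,
    brain_mask: np.ndarray,
    ctx_mask: Optional[np.ndarray] = None,
) -> PrincipalComponentModel:
    """Resolve the arbitrary eigenvector signs by an anatomical convention.

    I_PC1 is flipped to have positive mean within the brain mask and I_PC2 to
    have positive mean within the cortical mask, so that w = +1 corresponds to
    the amyloid-positive end of the appearance continuum.  Idempotent.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise PCAError("empty brain mask")
    if ctx_mask is None:
        ctx_mask = brain_mask
    else:
        ctx_mask = np.asarray(ctx_mask, dtype=bool)
        if not ctx_mask.any():
            raise PCAError("empty cortical mask")
    masks = [brain_mask, ctx_mask]
    flips = list(model.sign_flips)
    comps = []
    for i, comp in enumerate(model.components):
        m = masks[min(i, 1)]
        if comp.data[m].mean() < 0:
            comps.append(comp.like(-comp.data))
            flips[i] = -flips[i]
        else:
            comps.append(comp)
    return PrincipalComponentModel(
        mean_image=model.mean_image,
        components=comps,
        eigenvalues=model.eigenvalues.copy(),
        n_train=model.n_train,
        mask=model.mask,
        sign_flips=flips,
    )


def save_model(model: PrincipalComponentModel, path: str | Path) -> None:
    """Persist a model as a directory of NIfTI images plus model.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    save_volume(model.mean_image, path / "mean.nii.gz")
    for i, comp in enumerate(model.components, start=1):
        save_volume(comp, path / f"pc{i:02d}.nii.gz")
    mask_hash = None
    if model.mask is not None:
        m = np.asarray(model.mask, dtype=np.uint8)
        save_volume(Volume(m, model.grid.affine.copy()), path / "mask.nii.gz")
        mask_hash = hashlib.sha256(m.tobytes()).hexdigest()
    meta = {
        "eigenvalues": model.eigenvalues.tolist(),
        "n_train": model.n_train,
        "n_components": model.n_components,
        "sign_flips": model.sign_flips,
        "mask_sha256": mask_hash,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> PrincipalComponentModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    mean = load_volume(path / "mean.nii.gz")
    comps = [
        load_volume(path / f"pc{i:02d}.nii.gz")
        for i in range(1, meta["n_components"] + 1)
    ]
    mask = None
    if (path / "mask.nii.gz").exists():
        mask = load_volume(path / "mask.nii.gz").data > 0.5
    return PrincipalComponentModel(
        mean_image=mean,
        components=comps,
        eigenvalues=np.asarray(meta["eigenvalues"]),
        n_train=meta["n_train"],
        mask=mask,
        sign_flips=meta["sign_flips"],
    )
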