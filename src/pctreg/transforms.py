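"""Spatial transform types: affine, second-order polynomial, rigid, chain.

Transforms act on world coordinates (mm) and map template space into subject
space.  The full cascade is

    y(x) = (1 - s(x)) * G(x) + s(x) * G(R(x)),

where G is the global transform (12-parameter affine plus an optional
additive second-order polynomial displacement), R is a local rigid
refinement of the cerebellum / brain-stem fit, and s is a Gaussian-smoothed
mask in [0, 1] that blends the refined mapping into the global one so the
composite displacement field stays continuous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .volume import Volume, sample_at_world, save_volume, load_volume

__all__ = [
    "AffineTransform",
    "PolynomialTransform",
    "RigidTransform",
    "TransformChain",
    "TransformError",
]

# polynomial basis on normalized coordinates: {1, x, y, z, x^2, y^2, z^2, xy, xz, yz}
N_POLY_TERMS = 10


class TransformError(Exception):
    pass


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """R = Rz @ Ry @ Rx (intrinsic x-then-y-then-z rotation)."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class AffineTransform:
    """12-parameter affine: 3 translations (mm), 3 rotations (rad), 3 scales, 3 shears.

    Composition order is T . R . Sh . Sc, with the linear part applied about
    ``center`` (world mm), i.e. y = t + c + R Sh Sc (x - c).
    """

    parameters: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.parameters = np.asarray(self.parameters, dtype=float)
        if self.parameters.shape != (12,):
            raise TransformError("affine needs 12 parameters")
        self.center = np.asarray(self.center, dtype=float)
        if np.any(self.parameters[6:9] <= 0):
            raise TransformError("scales must be strictly positive")

    @classmethod
    def identity(cls, center=None) -> "AffineTransform":
        p = np.zeros(12)
        p[6:9] = 1.0
        return cls(p, np.zeros(3) if center is None else np.asarray(center, float))

    @property
    def linear(self) -> np.ndarray:
        t = self.parameters
        R = _rotation_matrix(*t[3:6])
        Sc = np.diag(t[6:9])
        Sh = np.eye(3)
        Sh[0, 1], Sh[0, 2], Sh[1, 2] = t[9], t[10], t[11]
        return R @ Sh @ Sc

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world->world matrix."""
        L = self.linear
        m = np.eye(4)
        m[:3, :3] = L
        m[:3, 3] = self.parameters[:3] + self.center - L @ self.center
        return m

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        m = self.matrix
        return np.atleast_2d(pts) @ m[:3, :3].T + m[:3, 3]

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_dict(self) -> dict:
        return {"parameters": self.parameters.tolist(), "center": self.center.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["parameters"]), np.asarray(d["center"]))


@dataclass
class PolynomialTransform:
    """Second-order polynomial displacement on [-1, 1]-normalized coordinates.

    ``coefficients`` is (3, 10): for each output axis the coefficients of
    {1, x, y, z, x^2, y^2, z^2, xy, xz, yz}.  The displacement (mm) is added
    on top of the affine-mapped coordinates; zero coefficients mean zero
    displacement everywhere.  ``bounds`` is the world bounding box used for
    coordinate normalization.
    """

    coefficients: np.ndarray
    bounds: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (3, N_POLY_TERMS):
            raise TransformError("polynomial needs (3, 10) coefficients")
        lo, hi = self.bounds
        self.bounds = (np.asarray(lo, dtype=float), np.asarray(hi, dtype=float))

    @classmethod
    def zero(cls, bounds) -> "PolynomialTransform":
        return cls(np.zeros((3, N_POLY_TERMS)), bounds)

    def _normalize(self, pts: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds
        return 2.0 * (pts - lo) / (hi - lo) - 1.0

    @staticmethod
    def basis(npts: np.ndarray) -> np.ndarray:
        x, y, z = npts[:, 0], npts[:, 1], npts[:, 2]
        return np.stack(
            [np.ones_like(x), x, y, z, x * x, y * y, z * z, x * y, x * z, y * z],
            axis=1,
        )

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        npts = self._normalize(np.atleast_2d(pts))
        return self.basis(npts) @ self.coefficients.T

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "bounds": [self.bounds[0].tolist(), self.bounds[1].tolist()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialTransform":
        lo, hi = d["bounds"]
        return cls(np.asarray(d["coefficients"]), (np.asarray(lo), np.asarray(hi)))


@dataclass
class RigidTransform:
    """6-parameter rigid: 3 translations (mm), 3 rotations (rad), about ``center``."""

    parameters: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.parameters = np.asarray(self.parameters, dtype=float)
        if self.parameters.shape != (6,):
            raise TransformError("rigid needs 6 parameters")
        self.center = np.asarray(self.center, dtype=float)

    @classmethod
    def identity(cls, center=None) -> "RigidTransform":
        return cls(np.zeros(6), np.zeros(3) if center is None else np.asarray(center, float))

    @property
    def matrix(self) -> np.ndarray:
        R = _rotation_matrix(*self.parameters[3:6])
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.parameters[:3] + self.center - R @ self.center
        return m

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        m = self.matrix
        return np.atleast_2d(pts) @ m[:3, :3].T + m[:3, 3]

    def to_dict(self) -> dict:
        return {"parameters": self.parameters.tolist(), "center": self.center.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["parameters"]), np.asarray(d["center"]))


@dataclass
class TransformChain:
    """Template-to-subject mapping: global affine (+ polynomial) with an
    optional locally-blended rigid refinement.

    ``local_rigid`` is a pair (RigidTransform, blend-weight Volume in template
    space with values in [0, 1]).  ``weight`` records the accepted template
    appearance weight w.
    """

    affine: AffineTransform
    polynomial: Optional[PolynomialTransform] = None
    local_rigid: Optional[tuple[RigidTransform, Volume]] = None
    weight: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def map_points_global(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        out = self.affine.map_points(pts)
        if self.polynomial is not None:
            out = out + self.polynomial.displacement(pts)
        return out

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        g = self.map_points_global(pts)
        if self.local_rigid is None:
            return g
        rigid, blend = self.local_rigid
        s = sample_at_world(blend, pts, "trilinear")
        inside = s > 0
        if not inside.any():
            return g
        gr = self.map_points_global(rigid.map_points(pts[inside]))
        si = s[inside][:, None]
        g[inside] = (1.0 - si) * g[inside] + si * gr
        return g

    def save(self, path: str | Path, blend_path: str | Path | None = None) -> None:
        path = Path(path)
        d: dict = {
            "affine": self.affine.to_dict(),
            "polynomial": self.polynomial.to_dict() if self.polynomial else None,
            "weight": self.weight,
            "metadata": self.metadata,
            "local_rigid": None,
        }
        if self.local_rigid is not None:
            rigid, blend = self.local_rigid
            if blend_path is None:
                blend_path = path.with_name(path.stem.split(".")[0] + "_blend.nii.gz")
            save_volume(blend, blend_path)
            d["local_rigid"] = {
                "rigid": rigid.to_dict(),
                "blend_path": str(Path(blend_path).name),
            }
        path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TransformChain":
        path = Path(path)
        d = json.loads(path.read_text())
        affine = AffineTransform.from_dict(d["affine"])
        poly = (
            PolynomialTransform.from_dict(d["polynomial"]) if d.get("polynomial") else None
        )
        local = None
        if d.get("local_rigid"):
            rigid = RigidTransform.from_dict(d["local_rigid"]["rigid"])
            blend = load_volume(path.parent / d["local_rigid"]["blend_path"])
            local = (rigid, blend)
        return cls(
            affine=affine,
            polynomial=poly,
            local_rigid=local,
            weight=d.get("weight"),
            metadata=d.get("metadata", {}),
        )
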