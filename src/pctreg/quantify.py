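"""Intensity normalization, VOI atlas, ThPons construction and SUVR.

SUVR (standardized uptake value ratio) is mean tracer uptake in a target
region divided by mean uptake in a reference region.  The atlas carries the
reference set used for amyloid quantification — cerebellar gray (CG), whole
cerebellum (WC), WC plus brain stem, pons, and the high-uptake-thresholded
pons subset (ThPons) — together with the global cortical target CTX.
Regions are encoded as sets of integer labels over one label volume, which
lets nested regions (CG within WC within WC+brain stem, ThPons within pons)
coexist without duplicate volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .pca import PrincipalComponentModel
from .transforms import TransformChain
from .volume import Volume, load_volume, resample, save_volume

__all__ = [
    "VOIAtlas",
    "SUVRReport",
    "QuantifyError",
    "REFERENCE_REGIONS",
    "intensity_normalize",
    "make_thpons",
    "compute_suvr",
    "quantify_subject",
    "correlation_r2",
]

REFERENCE_REGIONS = ("CG", "WC", "WC_brainstem", "pons", "ThPons")


class QuantifyError(Exception):
    pass


@dataclass
class VOIAtlas:
    """Integer-coded label volume plus region name -> label-set table."""

    labels: Volume
    regions: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        self.regions = {k: frozenset(v) for k, v in self.regions.items()}

    def region_mask(self, name: str) -> np.ndarray:
        if name not in self.regions:
            raise QuantifyError(f"unknown region {name!r}")
        lab = np.asarray(self.labels.data)
        return np.isin(lab, sorted(self.regions[name]))

    def region_mean(self, image: Volume, name: str) -> float:
        m = self.region_mask(name)
        if not m.any():
            raise QuantifyError(f"region {name!r} is empty")
        return float(np.asarray(image.data, dtype=float)[m].mean())

    def validate_nesting(self) -> None:
        """Check the anatomical containment the reference set relies on."""
        pairs = [("CG", "WC"), ("WC", "WC_brainstem"), ("pons", "WC_brainstem")]
        if "ThPons" in self.regions:
            pairs.append(("ThPons", "pons"))
        for inner, outer in pairs:
            if not self.regions[inner] <= self.regions[outer]:
                raise QuantifyError(f"{inner} must be contained in {outer}")
        cbbs = self.regions["WC_brainstem"]
        if self.regions["CTX"] & cbbs:
            raise QuantifyError("CTX overlaps the cerebellum/brain-stem regions")

    def save(self, labels_path: str | Path, table_path: str | Path) -> None:
        save_volume(self.labels, labels_path)
        table = {k: sorted(v) for k, v in self.regions.items()}
        Path(table_path).write_text(json.dumps(table, indent=2))

    @classmethod
    def load(cls, labels_path: str | Path, table_path: str | Path) -> "VOIAtlas":
        vol = load_volume(labels_path)
        vol = Volume(np.rint(vol.data).astype(np.int32), vol.affine)
        table = json.loads(Path(table_path).read_text())
        return cls(vol, {k: frozenset(v) for k, v in table.items()})


@dataclass
class SUVRReport:
    """Per-subject quantification: SUVR of CTX against each reference region."""

    subject_id: str
    weight: Optional[float]
    suvr: dict[str, float]
    region_means: dict[str, float]
    voxel_counts: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, v in self.suvr.items():
            if not v > 0:
                raise QuantifyError(f"non-positive SUVR for {name}: {v}")
        for name, c in self.voxel_counts.items():
            if c <= 0:
                raise QuantifyError(f"empty region {name}")

    def to_dict(self) -> dict:
        return {
            "id": self.subject_id,
            "w": self.weight,
            "suvr": self.suvr,
            "region_means": self.region_means,
            "voxel_counts": self.voxel_counts,
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_frame(self) -> pd.DataFrame:
        row = {
            "id": self.subject_id,
            "w": self.weight,
            "suvr_cg": self.suvr.get("CG"),
            "suvr_wc": self.suvr.get("WC"),
            "suvr_wc_bs": self.suvr.get("WC_brainstem"),
            "suvr_pons": self.suvr.get("pons"),
            "suvr_thpons": self.suvr.get("ThPons"),
            "warnings": ";".join(self.warnings),
        }
        return pd.DataFrame([row])


def intensity_normalize(v: Volume, atlas: VOIAtlas, reference: str = "pons") -> Volume:
    """Divide the image by its mean intensity within the reference region."""
    ref_mean = atlas.region_mean(v, reference)
    if ref_mean <= 0:
        raise QuantifyError(f"non-positive {reference} mean: {ref_mean}")
    return v.like(np.asarray(v.data, dtype=float) / ref_mean)


def make_thpons(
    pons_mask: np.ndarray, reference_image: Volume, fraction: float = 0.85
) -> np.ndarray:
    """High-uptake pons subset: voxels at or above the within-pons
    ``fraction`` quantile of ``reference_image`` (normally the training mean
    image, so the VOI is fixed per template rather than per subject)."""
    if not 0.0 < fraction < 1.0:
        raise QuantifyError("fraction must lie strictly between 0 and 1")
    mask = np.asarray(pons_mask, dtype=bool)
    if not mask.any():
        raise QuantifyError("empty pons mask")
    vals = np.asarray(reference_image.data, dtype=float)[mask]
    thr = float(np.quantile(vals, fraction))
    out = mask & (np.asarray(reference_image.data, dtype=float) >= thr)
    if not out.any():
        raise QuantifyError("ThPons selection is empty")
    return out


def compute_suvr(
    normalized: Volume, atlas: VOIAtlas, target: str = "CTX", reference: str = "pons"
) -> float:
    """Mean intensity over the target divided by mean over the reference."""
    t = atlas.region_mean(normalized, target)
    r = atlas.region_mean(normalized, reference)
    if r == 0:
        raise QuantifyError(f"zero mean in reference region {reference!r}")
    return t / r


def quantify_subject(
    subject: Volume,
    chain: TransformChain,
    atlas: VOIAtlas,
    model: Optional[PrincipalComponentModel] = None,
    subject_id: str = "subject",
) -> SUVRReport:
    """Resample through the chain, normalize by pons, report all SUVRs."""
    grid = model.grid if model is not None else atlas.labels
    warped = resample(subject, chain, grid, "trilinear")
    normalized = intensity_normalize(warped, atlas, "pons")
    refs = [r for r in REFERENCE_REGIONS if r in atlas.regions]
    suvr = {r: compute_suvr(normalized, atlas, "CTX", r) for r in refs}
    means = {r: atlas.region_mean(normalized, r) for r in refs + ["CTX"]}
    counts = {r: int(atlas.region_mask(r).sum()) for r in refs + ["CTX"]}
    warn = list(chain.metadata.get("warnings", []))
    return SUVRReport(
        subject_id=subject_id,
        weight=chain.weight,
        suvr=suvr,
        region_means=means,
        voxel_counts=counts,
        warnings=warn,
    )


def correlation_r2(x, y) -> float:
    """Squared Pearson correlation between two SUVR series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise QuantifyError("need equal-length series with at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise QuantifyError("constant input; correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
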