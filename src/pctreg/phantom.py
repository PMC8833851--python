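"""Digital amyloid-PET phantom: template-space cohorts and warped subject
scans with full ground truth.

The phantom emulates the appearance continuum of amyloid tracer uptake on a
simple geometric brain (ellipsoidal cortical ribbon over white matter with
ventricles, an inferior cerebellum with its own gray shell, and a
brain-stem/pons cylinder).  Two latent factors generate cohort variability:

* ``burden`` a in [0, 1] — cortical gray-matter uptake rises linearly with
  amyloid burden (0.8 + 1.6 a) while white matter, pons and cerebellar gray
  stay burden-independent, reproducing the negative-to-positive pattern of
  amyloid PET;
* ``amplitude`` — a per-subject global uptake multiplier on all brain
  tissue except the pons, emulating inter-subject and inter-scanner
  variability in tracer delivery and nonspecific retention relative to the
  pons (the empirical stability of the pons is exactly why it serves as
  reference region).

With both factors active the leading principal component of a cohort is the
global, mean-like appearance mode and the second component the
amyloid-specific cortical pattern, so the adaptive-template weight w tracks
amyloid positivity by construction.

Every random draw flows from one seed through a named generator; identical
truth records give bit-identical images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .pca import ImageStack
from .quantify import VOIAtlas, intensity_normalize, make_thpons
from .transforms import AffineTransform, PolynomialTransform, RigidTransform
from .volume import Volume, FWHM_TO_SIGMA, load_volume, save_volume

__all__ = [
    "LABELS",
    "PhantomAnatomy",
    "PhantomTruth",
    "PhantomError",
    "make_anatomy",
    "render_uptake",
    "generate_subject",
    "generate_cohort",
    "make_atlas",
    "sample_affine_truth",
    "Cohort",
]

LABELS = {
    "background": 0,
    "cortical_gm": 1,
    "white_matter": 2,
    "ventricles": 3,
    "cerebellar_gm": 4,
    "cerebellar_wm": 5,
    "brain_stem": 6,
    "pons": 7,
}

# fixture intensity conventions (arbitrary units, pre-normalization)
_INTENSITY = {
    "background": 0.0,
    "cortical_gm_base": 0.8,
    "cortical_gm_slope": 1.6,
    "white_matter": 2.0,
    "ventricles": 0.1,
    "cerebellar_gm": 0.8,
    "cerebellar_wm": 2.0,
    "brain_stem": 2.2,
    "pons": 2.2,
}

DEFAULT_SHAPE = (64, 64, 54)
DEFAULT_VOXEL_MM = 2.0
DEFAULT_PSF_FWHM_MM = 4.0
DEFAULT_AMPLITUDE_SIGMA = 0.25
DEFAULT_TEXTURE_AMP = 0.15


class PhantomError(Exception):
    pass


@dataclass
class PhantomAnatomy:
    """Mutually exclusive tissue labels on the template grid."""

    labels: Volume
    names: dict[str, int] = field(default_factory=lambda: dict(LABELS))

    def mask(self, *names: str) -> np.ndarray:
        ids = [self.names[n] for n in names]
        return np.isin(np.asarray(self.labels.data), ids)

    @property
    def brain_mask(self) -> np.ndarray:
        """All tissue incl. ventricles (everything that is not background)."""
        return np.asarray(self.labels.data) != 0

    @property
    def brain_mask_noventricles(self) -> np.ndarray:
        return self.brain_mask & ~self.mask("ventricles")

    @property
    def cerebral_mask_noventricles(self) -> np.ndarray:
        """Cerebrum tissue without ventricles — the masked-refinement mask.

        The masked NMI stage refines the cortical fit; the cerebellum and
        brain stem are deliberately left out because the reference region
        gets its own rigid refinement afterwards (letting the polynomial
        chase the reference region would defeat that step).
        """
        return self.mask("cortical_gm", "white_matter")

    @property
    def cerebellum_brainstem_mask(self) -> np.ndarray:
        return self.mask("cerebellar_gm", "cerebellar_wm", "brain_stem", "pons")

    @property
    def grid(self) -> Volume:
        return self.labels


@dataclass
class PhantomTruth:
    """Generating parameters of one synthetic subject — the test oracle."""

    burden: float
    affine_true: Optional[AffineTransform] = None
    poly_true: Optional[PolynomialTransform] = None
    local_shift_true: Optional[RigidTransform] = None
    noise_sigma: float = 0.0
    seed: int = 0
    amplitude: float = 1.0
    subject_id: str = "phantom"

    def to_dict(self) -> dict:
        return {
            "burden": self.burden,
            "affine_true": self.affine_true.to_dict() if self.affine_true else None,
            "poly_true": self.poly_true.to_dict() if self.poly_true else None,
            "local_shift_true": (
                self.local_shift_true.to_dict() if self.local_shift_true else None
            ),
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "amplitude": self.amplitude,
            "subject_id": self.subject_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        return cls(
            burden=d["burden"],
            affine_true=AffineTransform.from_dict(d["affine_true"]) if d.get("affine_true") else None,
            poly_true=PolynomialTransform.from_dict(d["poly_true"]) if d.get("poly_true") else None,
            local_shift_true=RigidTransform.from_dict(d["local_shift_true"]) if d.get("local_shift_true") else None,
            noise_sigma=d.get("noise_sigma", 0.0),
            seed=d.get("seed", 0),
            amplitude=d.get("amplitude", 1.0),
            subject_id=d.get("subject_id", "phantom"),
        )


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    acc = np.zeros(shape, dtype=float)
    for g, c, s in zip(grids, center, semi):
        acc += ((g - c) / s) ** 2
    return acc <= 1.0


def make_anatomy(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_mm: float = DEFAULT_VOXEL_MM,
) -> PhantomAnatomy:
    """Deterministic geometric anatomy with all eight labels present."""
    if min(shape) < 32:
        raise PhantomError("grid must have at least 32 voxels per axis")
    nx, ny, nz = shape
    sx, sy, sz = (nx - 1) / 63.0, (ny - 1) / 63.0, (nz - 1) / 53.0
    lab = np.zeros(shape, dtype=np.int32)

    # cerebrum: outer ellipsoid = brain envelope; inner 0.82 ratio = WM
    c_cer = (31.5 * sx, 36.0 * sy, 33.0 * sz)
    a_cer = (25.0 * sx, 23.0 * sy, 18.0 * sz)
    outer = _ellipsoid(shape, c_cer, a_cer)
    inner = _ellipsoid(shape, c_cer, tuple(0.82 * a for a in a_cer))
    lab[outer] = LABELS["cortical_gm"]
    lab[inner] = LABELS["white_matter"]

    # lateral ventricles inside WM
    for dx in (-6.5, 6.5):
        v = _ellipsoid(shape, ((31.5 + dx) * sx, 36.0 * sy, 33.0 * sz),
                       (3.5 * sx, 7.0 * sy, 4.0 * sz))
        lab[v & inner] = LABELS["ventricles"]

    # cerebellum: inferior-posterior ellipsoid, GM shell over WM core
    c_cb = (31.5 * sx, 17.0 * sy, 13.0 * sz)
    a_cb = (13.0 * sx, 9.0 * sy, 8.0 * sz)
    cb_outer = _ellipsoid(shape, c_cb, a_cb)
    cb_inner = _ellipsoid(shape, c_cb, tuple(0.6 * a for a in a_cb))
    free = lab == 0
    lab[cb_outer & free] = LABELS["cerebellar_gm"]
    lab[cb_inner & free] = LABELS["cerebellar_wm"]

    # brain stem: vertical cylinder anterior to the cerebellum; pons segment
    gx, gy, gz = np.indices(shape, dtype=float)
    r2 = ((gx - 31.5 * sx) / (4.5 * sx)) ** 2 + ((gy - 30.0 * sy) / (4.5 * sy)) ** 2
    stem = (r2 <= 1.0) & (gz >= 4 * sz) & (gz <= 26 * sz)
    lab[stem] = LABELS["brain_stem"]
    pons = stem & (gz >= 12 * sz) & (gz <= 18 * sz)
    lab[pons] = LABELS["pons"]

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    anatomy = PhantomAnatomy(Volume(lab, affine))
    for name, lid in LABELS.items():
        if lid and not (lab == lid).any():
            raise PhantomError(f"anatomy label {name} came out empty")
    return anatomy


def texture_field(grid: Volume, amplitude: float, wavelength_mm: float = 20.0) -> np.ndarray:
    """Deterministic smooth within-tissue heterogeneity pattern.

    Real tracer images have spatial structure inside each tissue class
    (folia, tracts, perfusion gradients); this multiplicative field — a
    product of phase-shifted sinusoids, identical for every subject — stands
    in for it, and is what gives the correlation-driven reference-region
    refinement something to lock onto.
    """
    if amplitude == 0.0:
        return np.ones(grid.shape)
    pts = grid.grid_world_coordinates().reshape(grid.shape + (3,))
    k = 2.0 * np.pi / wavelength_mm
    t = (
        np.sin(k * pts[..., 0] + 0.7)
        * np.sin(k * pts[..., 1] + 1.3)
        * np.sin(k * pts[..., 2] + 2.1)
    )
    return 1.0 + amplitude * t


def render_uptake(
    anatomy: PhantomAnatomy,
    burden: float,
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM_MM,
    amplitude: float = 1.0,
    texture_amp: float = 0.0,
) -> Volume:
    """Noise-free uptake image at a given amyloid burden.

    Piecewise-constant tissue intensities (cortical GM = 0.8 + 1.6 burden)
    blurred by the scanner point-spread function.  ``amplitude`` scales
    every brain tissue except the pons — the per-subject global uptake level
    relative to the reference tissue.  ``psf_fwhm_mm = 0`` skips the blur;
    ``texture_amp > 0`` modulates the tissue intensities by the fixed
    :func:`texture_field` before blurring.
    """
    if not 0.0 <= burden <= 1.0:
        raise PhantomError(f"burden must lie in [0, 1], got {burden}")
    lab = np.asarray(anatomy.labels.data)
    img = np.zeros(lab.shape, dtype=np.float64)
    I = _INTENSITY
    values = {
        LABELS["background"]: I["background"],
        LABELS["cortical_gm"]: (I["cortical_gm_base"] + I["cortical_gm_slope"] * burden)
        * amplitude,
        LABELS["white_matter"]: I["white_matter"] * amplitude,
        LABELS["ventricles"]: I["ventricles"],
        LABELS["cerebellar_gm"]: I["cerebellar_gm"] * amplitude,
        LABELS["cerebellar_wm"]: I["cerebellar_wm"] * amplitude,
        LABELS["brain_stem"]: I["brain_stem"] * amplitude,
        # the pons proper is the stable reference tissue and does not share
        # the global amplitude mode
        LABELS["pons"]: I["pons"],
    }
    for lid, val in values.items():
        if val != 0.0:
            img[lab == lid] = val
    if texture_amp != 0.0:
        img *= texture_field(anatomy.grid, texture_amp)
    if psf_fwhm_mm > 0:
        sigma_vox = psf_fwhm_mm * FWHM_TO_SIGMA / anatomy.grid.voxel_sizes
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    return anatomy.grid.like(img)


def _shift_reference_block(anatomy: PhantomAnatomy, shift: RigidTransform) -> PhantomAnatomy:
    """Move the cerebellum+brain-stem labels rigidly; vacated voxels -> background."""
    lab = np.asarray(anatomy.labels.data)
    cbbs_ids = [LABELS[k] for k in ("cerebellar_gm", "cerebellar_wm", "brain_stem", "pons")]
    block = np.where(np.isin(lab, cbbs_ids), lab, 0).astype(np.int32)
    grid = anatomy.grid
    # content moved by `shift` means sampling the original at shift^{-1}(y)
    pts = grid.grid_world_coordinates()
    inv = np.linalg.inv(shift.matrix)
    mpts = pts @ inv[:3, :3].T + inv[:3, 3]
    idx = grid.world_to_voxel(mpts)
    moved = ndimage.map_coordinates(
        block, idx.T, order=0, mode="grid-constant", cval=0
    ).reshape(lab.shape)
    out = lab.copy()
    out[np.isin(lab, cbbs_ids)] = 0
    out[moved > 0] = moved[moved > 0]
    return PhantomAnatomy(Volume(out, grid.affine.copy()), dict(anatomy.names))


def _invert_global(truth: PhantomTruth, pts: np.ndarray, n_iter: int = 8) -> np.ndarray:
    """x = G^{-1}(y) for G = affine (+ polynomial), by fixed-point iteration."""
    A_inv = truth.affine_true.inverse_matrix()

    def ainv(p):
        return p @ A_inv[:3, :3].T + A_inv[:3, 3]

    if truth.poly_true is None:
        return ainv(pts)
    x = ainv(pts)
    for _ in range(n_iter):
        x = ainv(pts - truth.poly_true.displacement(x))
    return x


def generate_subject(
    anatomy: PhantomAnatomy,
    truth: PhantomTruth,
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM_MM,
    texture_amp: float = DEFAULT_TEXTURE_AMP,
) -> tuple[Volume, PhantomTruth]:
    """Render, locally shift, warp and add noise according to the truth record.

    The subject grid reuses the template grid (same field of view); the true
    transform maps template world coordinates to subject world coordinates,
    so a perfect registration recovers exactly ``truth.affine_true`` (plus
    the polynomial, if set).
    """
    anat = anatomy
    if truth.local_shift_true is not None:
        anat = _shift_reference_block(anatomy, truth.local_shift_true)
    template_img = render_uptake(anat, truth.burden, psf_fwhm_mm, truth.amplitude, texture_amp)

    grid = anatomy.grid
    if truth.affine_true is None:
        img = np.asarray(template_img.data, dtype=float).copy()
    else:
        pts = grid.grid_world_coordinates()
        src = _invert_global(truth, pts)
        idx = grid.world_to_voxel(src)
        img = ndimage.map_coordinates(
            template_img.data, idx.T, order=1, mode="grid-constant", cval=0.0,
            prefilter=False,
        ).reshape(grid.shape)

    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        brain = _warped_brain_mask(anatomy, truth)
        brain_mean = img[brain].mean() if brain.any() else img.mean()
        img = img + rng.standard_normal(img.shape) * (truth.noise_sigma * brain_mean)
    return Volume(img, grid.affine.copy()), truth


def _warped_brain_mask(anatomy: PhantomAnatomy, truth: PhantomTruth) -> np.ndarray:
    """Subject-space brain mask under the true transform (nearest sampling)."""
    grid = anatomy.grid
    mask = anatomy.brain_mask.astype(np.float32)
    if truth.affine_true is None:
        return mask > 0.5
    pts = grid.grid_world_coordinates()
    src = _invert_global(truth, pts)
    idx = grid.world_to_voxel(src)
    out = ndimage.map_coordinates(
        mask, idx.T, order=0, mode="grid-constant", cval=0.0
    ).reshape(grid.shape)
    return out > 0.5


def warp_labels_to_subject(anatomy: PhantomAnatomy, truth: PhantomTruth) -> Volume:
    """Subject-space copy of the anatomy labels under the true transform."""
    grid = anatomy.grid
    if truth.affine_true is None:
        return anatomy.labels.copy()
    pts = grid.grid_world_coordinates()
    src = _invert_global(truth, pts)
    idx = grid.world_to_voxel(src)
    out = ndimage.map_coordinates(
        np.asarray(anatomy.labels.data), idx.T, order=0, mode="grid-constant", cval=0
    ).reshape(grid.shape)
    return Volume(out.astype(np.int32), grid.affine.copy())


def sample_affine_truth(
    rng: np.random.Generator,
    center: np.ndarray,
    max_rot_deg: float = 10.0,
    max_trans_mm: float = 8.0,
    scale_range: tuple[float, float] = (0.95, 1.05),
    max_shear: float = 0.02,
) -> AffineTransform:
    """Small random affine in the ranges typical of head-position variation."""
    p = np.zeros(12)
    p[:3] = rng.uniform(-max_trans_mm, max_trans_mm, 3)
    p[3:6] = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg, 3))
    p[6:9] = rng.uniform(*scale_range, 3)
    p[9:12] = rng.uniform(-max_shear, max_shear, 3)
    return AffineTransform(p, np.asarray(center, dtype=float))


@dataclass
class Cohort:
    """Template-space training stack plus optional warped subject scans."""

    stack: ImageStack
    truths: list[PhantomTruth]
    subjects: list[Volume] = field(default_factory=list)
    subject_truths: list[PhantomTruth] = field(default_factory=list)


def generate_cohort(
    anatomy: PhantomAnatomy,
    n: int,
    warp: bool = False,
    seed: int = 0,
    noise_sigma: float = 0.05,
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM_MM,
    amplitude_sigma: float = DEFAULT_AMPLITUDE_SIGMA,
    texture_amp: float = DEFAULT_TEXTURE_AMP,
    atlas: Optional[VOIAtlas] = None,
) -> Cohort:
    """Stratified burden cohort for template building (and, with ``warp``,
    matching subject-space scans for registration experiments).

    Burdens are a stratified grid covering [0, 1]; template-space images are
    rendered on the template grid, given additive Gaussian noise at
    ``noise_sigma`` of the brain mean, and pons-intensity-normalized.  With
    ``warp`` set, each subject additionally gets a scan warped by a random
    small affine (new noise realization).
    """
    if n < 4:
        raise PhantomError("a cohort needs n >= 4")
    rng = np.random.default_rng(seed)
    burdens = np.linspace(0.0, 1.0, n)
    if burdens.std() == 0:
        import warnings as _w

        _w.warn("degenerate burden sampler: all burdens equal")
    amplitudes = np.clip(rng.normal(1.0, amplitude_sigma, n), 0.4, 1.8)
    if atlas is None:
        atlas = make_atlas(anatomy)

    center = 0.5 * (np.add(*anatomy.grid.world_bounds()))
    volumes, truths = [], []
    subjects, subject_truths = [], []
    for i in range(n):
        t = PhantomTruth(
            burden=float(burdens[i]),
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
            amplitude=float(amplitudes[i]),
            subject_id=f"sub{i:03d}",
        )
        img, _ = generate_subject(anatomy, t, psf_fwhm_mm, texture_amp)
        volumes.append(intensity_normalize(img, atlas, "pons"))
        truths.append(t)
        if warp:
            ts = PhantomTruth(
                burden=t.burden,
                affine_true=sample_affine_truth(rng, center),
                noise_sigma=noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
                amplitude=t.amplitude,
                subject_id=t.subject_id,
            )
            s_img, _ = generate_subject(anatomy, ts, psf_fwhm_mm, texture_amp)
            subjects.append(s_img)
            subject_truths.append(ts)

    stack = ImageStack(volumes, ids=[t.subject_id for t in truths])
    return Cohort(stack=stack, truths=truths, subjects=subjects, subject_truths=subject_truths)


def save_cohort(
    cohort: Cohort,
    anatomy: PhantomAnatomy,
    out_dir: str | Path,
    atlas: Optional[VOIAtlas] = None,
) -> None:
    """Write a cohort as plain NIfTI + JSON files.

    Layout: train_###.nii.gz (template-space normalized images),
    sub_###.nii.gz (warped subject scans, when present), anatomy.nii.gz,
    atlas.nii.gz + atlas.json, truths.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, v in enumerate(cohort.stack.volumes):
        save_volume(v, out / f"train_{i:03d}.nii.gz")
    for i, v in enumerate(cohort.subjects):
        save_volume(v, out / f"sub_{i:03d}.nii.gz")
    save_volume(anatomy.labels, out / "anatomy.nii.gz")
    if atlas is not None:
        atlas.save(out / "atlas.nii.gz", out / "atlas.json")
    (out / "truths.json").write_text(
        json.dumps(
            {
                "train": [t.to_dict() for t in cohort.truths],
                "subjects": [t.to_dict() for t in cohort.subject_truths],
            },
            indent=2,
        )
    )


def load_cohort(in_dir: str | Path) -> tuple[Cohort, PhantomAnatomy, Optional[VOIAtlas]]:
    """Read back a cohort written by :func:`save_cohort`."""
    d = Path(in_dir)
    meta = json.loads((d / "truths.json").read_text())
    truths = [PhantomTruth.from_dict(t) for t in meta["train"]]
    subject_truths = [PhantomTruth.from_dict(t) for t in meta["subjects"]]
    volumes = [load_volume(d / f"train_{i:03d}.nii.gz") for i in range(len(truths))]
    subjects = [load_volume(d / f"sub_{i:03d}.nii.gz") for i in range(len(subject_truths))]
    lab = load_volume(d / "anatomy.nii.gz")
    anatomy = PhantomAnatomy(Volume(np.rint(lab.data).astype(np.int32), lab.affine))
    atlas = None
    if (d / "atlas.nii.gz").exists():
        atlas = VOIAtlas.load(d / "atlas.nii.gz", d / "atlas.json")
    stack = ImageStack(volumes, ids=[t.subject_id for t in truths])
    return (
        Cohort(stack=stack, truths=truths, subjects=subjects, subject_truths=subject_truths),
        anatomy,
        atlas,
    )


def make_atlas(
    anatomy: PhantomAnatomy,
    reference_image: Optional[Volume] = None,
    thpons_fraction: float = 0.85,
) -> VOIAtlas:
    """VOI atlas over the phantom labels.

    CG = cerebellar gray, WC = whole cerebellum, WC_brainstem adds the brain
    stem and pons, CTX = the cortical ribbon.  When a reference image
    (normally the training mean) is supplied, the high-uptake pons voxels are
    re-coded with their own label so ThPons nests inside pons.
    """
    lab = np.asarray(anatomy.labels.data).copy()
    regions = {
        "CG": {LABELS["cerebellar_gm"]},
        "WC": {LABELS["cerebellar_gm"], LABELS["cerebellar_wm"]},
        "WC_brainstem": {
            LABELS["cerebellar_gm"],
            LABELS["cerebellar_wm"],
            LABELS["brain_stem"],
            LABELS["pons"],
        },
        "pons": {LABELS["pons"]},
        "CTX": {LABELS["cortical_gm"]},
    }
    if reference_image is not None:
        th = make_thpons(lab == LABELS["pons"], reference_image, thpons_fraction)
        thpons_id = max(LABELS.values()) + 1
        lab[th] = thpons_id
        regions["pons"] = {LABELS["pons"], thpons_id}
        regions["WC_brainstem"] = regions["WC_brainstem"] | {thpons_id}
        regions["ThPons"] = {thpons_id}
    atlas = VOIAtlas(
        Volume(lab, anatomy.grid.affine.copy()),
        {k: frozenset(v) for k, v in regions.items()},
    )
    atlas.validate_nesting()
    return atlas
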