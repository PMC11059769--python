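"""Synthetic midsagittal corpus-callosum phantom generator.

Marchiafava-Bignami disease (MBD) attacks the corpus callosum: the band
thins, T2-bright / T1-dark lesions appear, diffusion drops (lower ADC),
cysts and necrotic patches form, gadolinium enhancement and signal
non-uniformity emerge.  This module renders seeded 2-D grayscale slices of
a stylised midsagittal callosum for both phenotypes, with pixel-accurate
lesion masks, so every downstream stage (feature extraction, training,
detection, segmentation metrics) can be exercised end to end with known
ground truth.

Morphometric sampling ranges follow the published normal intervals (genu
thickness 8-12 mm, body 3-5 mm, splenium 4-6 mm, length 60-70 mm, widths
13-18 / 10-15 / 15-20 mm, ADC 0.6-1.2) and, for the disease class, the
spans observed across ten tabulated MBD case instances (shipped verbatim
as ``data/table2_instances.csv``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "PhantomImage",
    "PhantomDataset",
    "sample_spec",
    "render",
    "generate_dataset",
    "lesion_free",
    "load_table2_specs",
    "NORMAL_RANGES",
    "MBD_RANGES",
    "DegenerateGeometryError",
]

INTENSITY_CLASSES = ("T2_hyper", "T1_hypo", "mixed", "normal")
ENHANCEMENTS = ("none", "mild", "moderate", "strong", "variable")
UNIFORMITIES = ("uniform", "non_uniform")
CYSTS = ("none", "small", "medium", "large")
DEGENERATIONS = ("none", "necrosis", "atrophy")

#: Normal morphometric intervals (mm; ADC dimensionless stand-in).
NORMAL_RANGES = {
    "thickness_genu_mm": (8.0, 12.0),
    "thickness_body_mm": (3.0, 5.0),
    "thickness_splenium_mm": (4.0, 6.0),
    "length_mm": (60.0, 70.0),
    "width_genu_mm": (13.0, 18.0),
    "width_body_mm": (10.0, 15.0),
    "width_splenium_mm": (15.0, 20.0),
    "adc_contrast": (0.6, 1.2),
}

#: Disease-class sampling intervals; spans of the tabulated case instances.
MBD_RANGES = {
    "thickness_genu_mm": (5.0, 8.0),
    "thickness_body_mm": (1.5, 3.1),
    "thickness_splenium_mm": (2.5, 4.2),
    "length_mm": (50.0, 65.0),
    "width_genu_mm": (10.0, 14.0),
    "width_body_mm": (7.0, 12.0),
    "width_splenium_mm": (11.0, 17.0),
    "adc_contrast": (0.4, 0.9),
}

_BACKGROUND = 0.12
_BAND_INTENSITY = 0.72
_NOISE_SIGMA = 0.02  # additive Gaussian noise, [0,1] intensity units
_MIN_IMAGE_SIZE = 32


class DegenerateGeometryError(ValueError):
    """Raised when the image raster is too coarse to hold the phantom."""


@dataclass
class PhantomSpec:
    """Morphometric and lesion parameters for one synthetic slice."""

    image_size: int = 64
    thickness_genu_mm: float = 10.0
    thickness_body_mm: float = 4.0
    thickness_splenium_mm: float = 5.0
    length_mm: float = 65.0
    width_genu_mm: float = 15.5
    width_body_mm: float = 12.5
    width_splenium_mm: float = 17.5
    adc_contrast: float = 0.9
    intensity_class: str = "normal"
    enhancement: str = "none"
    uniformity: str = "uniform"
    cysts: str = "none"
    degeneration: str = "none"
    mm_per_pixel: float = 2.0
    label: str = "normal"

    def validate(self) -> None:
        if self.image_size < 1:
            raise ValueError("image_size must be positive")
        for name in (
            "thickness_genu_mm",
            "thickness_body_mm",
            "thickness_splenium_mm",
            "length_mm",
            "width_genu_mm",
            "width_body_mm",
            "width_splenium_mm",
            "mm_per_pixel",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.adc_contrast <= 2.0:
            raise ValueError("adc_contrast must lie in [0, 2]")
        for name, allowed in (
            ("intensity_class", INTENSITY_CLASSES),
            ("enhancement", ENHANCEMENTS),
            ("uniformity", UNIFORMITIES),
            ("cysts", CYSTS),
            ("degeneration", DEGENERATIONS),
            ("label", ("normal", "MBD")),
        ):
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {allowed}")
        if self.label == "MBD":
            thinned = any(
                getattr(self, k) < NORMAL_RANGES[k][0]
                for k in ("thickness_genu_mm", "thickness_body_mm", "thickness_splenium_mm")
            )
            if not (
                thinned
                or self.intensity_class != "normal"
                or self.cysts != "none"
                or self.degeneration != "none"
            ):
                raise ValueError("MBD spec must carry at least one abnormality")


@dataclass
class PhantomImage:
    """Rendered slice, its ground-truth lesion mask, and provenance."""

    pixels: np.ndarray
    lesion_mask: np.ndarray
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if self.pixels.shape != self.lesion_mask.shape:
            raise ValueError("pixels and lesion_mask must share a shape")


def sample_spec(label: str, rng_seed: int, image_size: int = 64) -> PhantomSpec:
    """Draw a morphometric specification for one phantom.

    Normal specs sample each dimension uniformly inside its normal
    interval with all lesion attributes absent.  MBD specs sample the
    disease-class intervals (significant thinning, reduced ADC) and
    categorical lesion attributes covering every state seen across the
    tabulated case instances.
    """
    if label not in ("normal", "MBD"):
        raise ValueError("label must be 'normal' or 'MBD'")
    rng = np.random.default_rng(np.random.SeedSequence([0x5EC, int(rng_seed)]))
    ranges = NORMAL_RANGES if label == "normal" else MBD_RANGES
    dims = {k: float(rng.uniform(*v)) for k, v in ranges.items()}
    spec = PhantomSpec(
        image_size=image_size,
        mm_per_pixel=2.0 * 64.0 / image_size,
        label=label,
        **dims,
    )
    if label == "MBD":
        spec.intensity_class = str(rng.choice(["T2_hyper", "T1_hypo", "mixed"]))
        spec.cysts = str(rng.choice(CYSTS))
        spec.degeneration = str(rng.choice(["necrosis", "atrophy"]))
        spec.enhancement = str(rng.choice(ENHANCEMENTS))
        spec.uniformity = "non_uniform" if rng.uniform() < 0.8 else "uniform"
    spec.validate()
    return spec


def lesion_free(spec: PhantomSpec) -> PhantomSpec:
    """Counterfactual twin of ``spec`` with all lesion attributes removed.

    Geometry (including any thinning) and ADC are preserved, so comparing a
    render against its counterfactual isolates exactly the lesion pixels.
    """
    return replace(
        spec,
        intensity_class="normal",
        enhancement="none",
        uniformity="uniform",
        cysts="none",
        degeneration="none",
    )


def _quadratic_profile(t: np.ndarray, v0: float, v1: float, v2: float) -> np.ndarray:
    """Quadratic through (0, v0), (0.5, v1), (1, v2)."""
    return (
        v0 * (2 * t - 1) * (t - 1)
        - v1 * 4 * t * (t - 1)
        + v2 * t * (2 * t - 1)
    )


def _soft_ellipse(yy, xx, cy, cx, ry, rx, angle, edge=0.75):
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    r = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    scale = max(edge / max(min(rx, ry), 1e-6), 1e-6)
    return np.clip((1.0 - r) / scale + 1.0, 0.0, 1.0)


def _render_fields(spec: PhantomSpec, seed: int, with_lesions: bool):
    """Noise-free intensity field; lesion randomness drawn from a child
    stream independent of the anatomy/noise stream so the counterfactual
    shares every non-lesion pixel bit for bit."""
    n = spec.image_size
    mpp = spec.mm_per_pixel
    ss = np.random.SeedSequence([0xBD, int(seed)])
    anat_seed, lesion_seed = ss.spawn(2)
    anat_rng = np.random.default_rng(anat_seed)
    lesion_rng = np.random.default_rng(lesion_seed)

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cx = cy = (n - 1) / 2.0

    # centreline: arch spanning the callosal length, genu on the left
    m = 400
    t = np.linspace(0.0, 1.0, m)
    half_len_px = spec.length_mm / (2 * mpp)
    arch_px = 10.0 / mpp
    line_x = cx + (2 * t - 1) * half_len_px
    line_y = cy + 2.0 / mpp - arch_px * np.sin(np.pi * t)

    # distance from every pixel to the centreline, and the arc position of
    # the nearest centreline point
    px = np.stack([yy.ravel(), xx.ravel()], axis=1)
    pts = np.stack([line_y, line_x], axis=1)
    d2 = ((px[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    nearest = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(px.shape[0]), nearest]).reshape(n, n)
    t_near = t[nearest].reshape(n, n)

    half_th_px = _quadratic_profile(
        t_near, spec.thickness_genu_mm, spec.thickness_body_mm, spec.thickness_splenium_mm
    ) / (2 * mpp)
    if np.max(half_th_px) < 0.5:
        raise DegenerateGeometryError(
            "raster too coarse: callosal band thinner than one pixel"
        )
    band_alpha = np.clip(half_th_px - dist + 1.0, 0.0, 1.0)

    # segment brightness: partial-volume surrogate for the (out-of-plane)
    # widths, plus the ADC-dependent contrast modulation
    width = _quadratic_profile(
        t_near, spec.width_genu_mm, spec.width_body_mm, spec.width_splenium_mm
    )
    width_ref = _quadratic_profile(t_near, 15.5, 12.5, 17.5)
    band_val = _BAND_INTENSITY * (1.0 + 0.10 * (width / width_ref - 1.0))
    band_val = band_val * (1.0 + 0.12 * (0.9 - spec.adc_contrast))

    texture = gaussian_filter(anat_rng.normal(size=(n, n)), sigma=3.0)
    background = _BACKGROUND + 0.03 * texture
    clean = background * (1 - band_alpha) + band_val * band_alpha

    if not with_lesions:
        return clean, clean

    img = clean.copy()
    in_band = band_alpha > 0.5
    blob_centers = []

    def _point_on_band(lo=0.1, hi=0.9):
        tt = lesion_rng.uniform(lo, hi)
        i = int(tt * (m - 1))
        off = lesion_rng.uniform(-0.4, 0.4)
        hw = np.interp(
            tt,
            [0, 0.5, 1],
            [spec.thickness_genu_mm, spec.thickness_body_mm, spec.thickness_splenium_mm],
        ) / (2 * mpp)
        return line_y[i] + off * hw, line_x[i]

    # focal hyper-/hypo-intense demyelination blobs
    if spec.intensity_class != "normal":
        for _ in range(int(lesion_rng.integers(1, 4))):
            by, bx = _point_on_band()
            ry = lesion_rng.uniform(1.5, 3.5) / mpp
            rx = lesion_rng.uniform(2.0, 5.0) / mpp
            ang = lesion_rng.uniform(0, np.pi)
            a = _soft_ellipse(yy, xx, by, bx, max(ry, 0.8), max(rx, 0.8), ang)
            if spec.intensity_class == "T2_hyper":
                delta = 0.22
            elif spec.intensity_class == "T1_hypo":
                delta = -0.22
            else:  # mixed: sign drawn per blob
                delta = 0.22 * (1 if lesion_rng.uniform() < 0.5 else -1)
            img += delta * a * band_alpha
            blob_centers.append((by, bx, ry, rx, ang))

    # cystic degeneration: fluid-filled ellipses, CSF-bright in the
    # phantom's T2-like intensity convention, free to bulge past the band
    if spec.cysts != "none":
        rmm = {"small": (1.0, 2.0), "medium": (2.0, 4.0), "large": (4.0, 7.0)}[spec.cysts]
        for _ in range(int(lesion_rng.integers(1, 3))):
            by, bx = _point_on_band()
            ry = lesion_rng.uniform(*rmm) / mpp
            rx = lesion_rng.uniform(*rmm) / mpp
            a = _soft_ellipse(yy, xx, by, bx, max(ry, 0.8), max(rx, 0.8), 0.0)
            img = img * (1 - a) + 0.95 * a
            blob_centers.append((by, bx, ry, rx, 0.0))

    # necrosis: one ragged dark patch; atrophy: focal loss of the outer band
    if spec.degeneration == "necrosis":
        by, bx = _point_on_band(0.2, 0.8)
        ry = lesion_rng.uniform(1.5, 3.0) / mpp
        rx = lesion_rng.uniform(3.0, 6.0) / mpp
        a = _soft_ellipse(yy, xx, by, bx, max(ry, 0.8), max(rx, 0.8), 0.0)
        ragged = gaussian_filter(lesion_rng.normal(size=(n, n)), sigma=1.0)
        a = np.clip(a + 0.3 * ragged * (a > 0), 0.0, 1.0)
        img -= 0.30 * a * band_alpha
    elif spec.degeneration == "atrophy":
        t0 = lesion_rng.uniform(0.15, 0.6)
        seg = (t_near >= t0) & (t_near <= t0 + 0.25)
        carved = dist > 0.6 * half_th_px
        img = np.where(seg & carved & in_band, background, img)

    # gadolinium enhancement: bright rim around each focal lesion
    if spec.enhancement != "none" and blob_centers:
        level = {"mild": 0.08, "moderate": 0.15, "strong": 0.25}.get(spec.enhancement)
        for by, bx, ry, rx, ang in blob_centers:
            lv = lesion_rng.uniform(0.05, 0.30) if level is None else level
            inner = _soft_ellipse(yy, xx, by, bx, ry, rx, ang)
            outer = _soft_ellipse(yy, xx, by, bx, ry + 1.2 / mpp, rx + 1.2 / mpp, ang)
            img += lv * np.clip(outer - inner, 0.0, 1.0)

    # signal non-uniformity: multiplicative low-frequency ripple on the band
    if spec.uniformity == "non_uniform":
        f = lesion_rng.uniform(0.03, 0.08)
        phase = lesion_rng.uniform(0, 2 * np.pi)
        theta = lesion_rng.uniform(0, np.pi)
        ripple = 1.0 + 0.08 * np.sin(
            2 * np.pi * f * (np.cos(theta) * xx + np.sin(theta) * yy) + phase
        )
        img = np.where(in_band, img * ripple, img)

    return img, clean


def render(spec: PhantomSpec, rng_seed: int) -> PhantomImage:
    """Render one phantom slice; deterministic in ``(spec, rng_seed)``.

    The lesion mask marks exactly the pixels whose noise-free intensity
    differs from the lesion-free counterfactual rendered with the same
    seed; for normal specs it is identically zero.
    """
    spec.validate()
    if spec.image_size < _MIN_IMAGE_SIZE:
        raise DegenerateGeometryError(
            f"image_size must be >= {_MIN_IMAGE_SIZE}, got {spec.image_size}"
        )
    has_lesions = spec.label == "MBD" and (
        spec.intensity_class != "normal"
        or spec.cysts != "none"
        or spec.degeneration != "none"
        or spec.uniformity == "non_uniform"
    )
    if has_lesions:
        lesioned, clean = _render_fields(spec, rng_seed, with_lesions=True)
        mask = (np.abs(lesioned - clean) > 1e-9).astype(np.uint8)
        field_img = lesioned
    else:
        clean, _ = _render_fields(spec, rng_seed, with_lesions=False)
        mask = np.zeros_like(clean, dtype=np.uint8)
        field_img = clean

    # the noise stream is a pure function of the seed, shared with the
    # counterfactual, so out-of-mask pixels match bit for bit
    noise_rng = np.random.default_rng(np.random.SeedSequence([0x4015E, int(rng_seed)]))
    noisy = np.clip(field_img + _NOISE_SIGMA * noise_rng.normal(size=field_img.shape), 0.0, 1.0)
    return PhantomImage(pixels=noisy, lesion_mask=mask, spec=spec)


@dataclass
class PhantomDataset:
    """Labelled phantom collection with simple array/file exports."""

    images: list[PhantomImage] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> np.ndarray:
        return np.array([im.spec.label for im in self.images])

    def pixel_stack(self) -> np.ndarray:
        return np.stack([im.pixels for im in self.images])

    def mask_stack(self) -> np.ndarray:
        return np.stack([im.lesion_mask for im in self.images])

    def spec_frame(self):
        import pandas as pd
        from dataclasses import asdict

        rows = [asdict(im.spec) for im in self.images]
        frame = pd.DataFrame(rows)
        frame.insert(0, "image_id", [f"img_{i:05d}" for i in range(len(rows))])
        return frame

    def write_dir(self, path, fmt: str = "png") -> None:
        """Write slices (PNG or single-slice NIfTI), masks and CSV tables."""
        from pathlib import Path

        from . import io as mio

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, im in enumerate(self.images):
            stem = f"img_{i:05d}"
            if fmt == "png":
                mio.write_png(path / f"{stem}.png", im.pixels)
            elif fmt == "nifti":
                mio.write_nifti(path / f"{stem}.nii", im.pixels, im.spec.mm_per_pixel)
            else:
                raise ValueError(f"unknown format {fmt!r}")
            mio.write_png(path / f"{stem}_mask.png", im.lesion_mask.astype(float))
        frame = self.spec_frame()
        frame.to_csv(path / "specs.csv", index=False)
        frame[["image_id", "label"]].to_csv(path / "labels.csv", index=False)


def generate_dataset(
    n_normal: int,
    n_mbd: int,
    image_size: int = 64,
    rng_seed: int = 0,
) -> PhantomDataset:
    """Generate ``n_normal`` normal and ``n_mbd`` MBD phantoms.

    Per-image spec and render seeds are derived deterministically from the
    master seed, so the whole dataset is a pure function of its arguments.
    """
    if n_normal < 0 or n_mbd < 0:
        raise ValueError("counts must be non-negative")
    if n_normal + n_mbd < 1:
        raise ValueError("dataset must contain at least one image")
    rng = np.random.default_rng(np.random.SeedSequence([0xDA7A, int(rng_seed)]))
    seeds = rng.integers(0, 2**31 - 1, size=2 * (n_normal + n_mbd))
    images = []
    for i, label in enumerate(["normal"] * n_normal + ["MBD"] * n_mbd):
        spec = sample_spec(label, int(seeds[2 * i]), image_size=image_size)
        images.append(render(spec, int(seeds[2 * i + 1])))
    return PhantomDataset(images=images)


_TABLE2_APPEARANCE = {
    "T2 Hyperintense": "T2_hyper",
    "T1 Hypointense": "T1_hypo",
    "Mixed": "mixed",
}
_TABLE2_ENHANCEMENT = {
    "No Enhancement": "none",
    "Mild Enhancement": "mild",
    "Moderate Enhancement": "moderate",
    "Strong Enhancement": "strong",
    "Variable Enhancement": "variable",
}
_TABLE2_CYSTS = {
    "No cysts": "none",
    "Small cysts present": "small",
    "Medium cysts present": "medium",
    "Large cysts present": "large",
}
_TABLE2_DEGEN = {
    "Necrosis present": "necrosis",
    "Atrophy present": "atrophy",
}


def load_table2_specs(image_size: int = 64) -> list[PhantomSpec]:
    """Load the ten packaged MBD case instances as renderable specs."""
    import pandas as pd

    ref = importlib.resources.files("mbdetect") / "data" / "table2_instances.csv"
    with importlib.resources.as_file(ref) as p:
        frame = pd.read_csv(p)
    specs = []
    for _, row in frame.iterrows():
        spec = PhantomSpec(
            image_size=image_size,
            mm_per_pixel=2.0 * 64.0 / image_size,
            thickness_genu_mm=float(row["Thickness Genu (mm)"]),
            thickness_body_mm=float(row["Thickness Body (mm)"]),
            thickness_splenium_mm=float(row["Thickness Splenium (mm)"]),
            length_mm=float(row["Length (mm)"]),
            width_genu_mm=float(row["Width Genu (mm)"]),
            width_body_mm=float(row["Width Body (mm)"]),
            width_splenium_mm=float(row["Width Splenium (mm)"]),
            adc_contrast=float(row["ADC (x10^-3 mm^2/s)"]),
            intensity_class=_TABLE2_APPEARANCE[row["MRI Appearance"]],
            enhancement=_TABLE2_ENHANCEMENT[row["Gadolinium Enhancement"]],
            uniformity="non_uniform" if row["Signal Uniformity"] == "Non-uniform" else "uniform",
            cysts=_TABLE2_CYSTS[row["Cystic Degeneration"]],
            degeneration=_TABLE2_DEGEN[row["Necrosis or Atrophy"]],
            label="MBD",
        )
        spec.validate()
        specs.append(spec)
    return specs
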