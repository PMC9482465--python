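"""Forward detector model and radial reduction.

A 1-D intensity curve is mapped onto a flat 2-D detector assuming isotropic
scattering: each pixel sees the curve value at its scattering vector
s = (4 pi / lambda) sin(theta / 2), theta = arctan(r / L) with r the radial
distance from the beam centre and L the camera length.  Poisson counting
noise is optional.  ``radial_average`` inverts the mapping by annular
binning; ``find_center`` refines the beam centre by annular-variance
sharpness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scattering import DiffractionCurve, electron_wavelength

__all__ = [
    "DetectorGeometry",
    "DetectorImage",
    "RadialProfile",
    "s_of_pixel",
    "render_image",
    "radial_average",
    "find_center",
    "write_image",
    "read_image",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector: pixel pitch and camera length in mm, voltage in kV.

    The defaults (1024x1024 pixels, 0.06 mm pitch, 500 mm camera length,
    100 kV) put s ≈ 10.4 Å⁻¹ at the edge of the image, covering the default
    simulation grid.
    """

    pixel_pitch: float = 0.06
    camera_length: float = 500.0
    n_pixels: tuple[int, int] = (1024, 1024)
    accel_voltage: float = 100.0
    beam_center: tuple[float, float] = (511.5, 511.5)

    def __post_init__(self):
        if min(self.pixel_pitch, self.camera_length, self.accel_voltage) <= 0:
            raise ValueError("pitch, camera length and voltage must be positive")
        rows, cols = self.n_pixels
        r0, c0 = self.beam_center
        if not (0 <= r0 <= rows - 1 and 0 <= c0 <= cols - 1):
            raise ValueError("beam centre must lie inside the image")

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.accel_voltage)

    def s_map(self, beam_center: tuple[float, float] | None = None) -> np.ndarray:
        """Per-pixel scattering vector magnitude, Å⁻¹."""
        rows, cols = self.n_pixels
        r0, c0 = beam_center if beam_center is not None else self.beam_center
        yy = (np.arange(rows) - r0)[:, None]
        xx = (np.arange(cols) - c0)[None, :]
        radius_mm = np.sqrt(yy * yy + xx * xx) * self.pixel_pitch
        theta = np.arctan(radius_mm / self.camera_length)
        return (4.0 * np.pi / self.wavelength) * np.sin(theta / 2.0)


@dataclass
class DetectorImage:
    """2-D counts (or expected values) with geometry and validity mask."""

    counts: np.ndarray
    geometry: DetectorGeometry
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != tuple(self.geometry.n_pixels):
            raise ValueError("counts shape does not match detector geometry")
        if self.mask is None:
            self.mask = np.ones(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape does not match counts")
        if np.any(self.counts[self.mask] < 0):
            raise ValueError("negative counts inside the usable mask")


def s_of_pixel(geometry: DetectorGeometry, pixel) -> float | np.ndarray:
    """Scattering vector at a (row, col) pixel position; fractional allowed."""
    pix = np.asarray(pixel, dtype=float)
    row, col = pix[..., 0], pix[..., 1]
    r0, c0 = geometry.beam_center
    radius_mm = np.hypot(row - r0, col - c0) * geometry.pixel_pitch
    theta = np.arctan(radius_mm / geometry.camera_length)
    s = (4.0 * np.pi / geometry.wavelength) * np.sin(theta / 2.0)
    return float(s) if s.ndim == 0 else s


def render_image(
    curve: DiffractionCurve,
    geometry: DetectorGeometry | None = None,
    total_counts: float = 1e7,
    seed: int | None = None,
    mask: np.ndarray | None = None,
    beamstop_radius_px: float = 0.0,
) -> DetectorImage:
    """Render an isotropic detector image from a 1-D curve.

    The expected value at each pixel is the linearly interpolated curve at the
    pixel's s, normalized so the expectations over the usable mask sum to
    ``total_counts``.  With a seed, each pixel is drawn from a Poisson law at
    its expectation; ``seed=None`` returns the noiseless expectation image.
    A central circular beam stop of ``beamstop_radius_px`` pixels can be
    masked out (off by default).
    """
    if geometry is None:
        geometry = DetectorGeometry()
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    s_map = geometry.s_map()
    if s_map.max() > curve.s[-1] + 1e-9 or curve.s[0] > 1e-9:
        raise ValueError(
            f"curve range [{curve.s[0]:.3f}, {curve.s[-1]:.3f}] Å⁻¹ does not cover "
            f"the detector range [0, {s_map.max():.3f}] Å⁻¹"
        )
    if mask is None:
        mask = np.ones(s_map.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool).copy()
    if beamstop_radius_px > 0:
        rows, cols = geometry.n_pixels
        r0, c0 = geometry.beam_center
        rr = np.hypot(
            (np.arange(rows) - r0)[:, None], (np.arange(cols) - c0)[None, :]
        )
        mask &= rr > beamstop_radius_px

    expected = np.interp(s_map, curve.s, curve.intensity)
    expected = np.clip(expected, 0.0, None)
    norm = expected[mask].sum()
    if norm > 0:
        expected = expected * (total_counts / norm)
    expected[~mask] = 0.0

    meta = {"total_counts": total_counts, "seed": seed}
    if seed is None:
        return DetectorImage(expected, geometry, mask, meta)
    rng = np.random.default_rng(seed)
    sampled = rng.poisson(expected).astype(np.int64)
    sampled[~mask] = 0
    return DetectorImage(sampled, geometry, mask, meta)


@dataclass
class RadialProfile:
    """Annular-bin reduction of a detector image.

    ``s`` holds nominal bin centres on a uniform grid; ``s_mean`` the mean
    pixel s within each bin (a better abscissa for fitting); ``mean`` the mean
    counts per pixel; ``n_pixels`` and ``sem`` the per-bin statistics.  Bins
    with no usable pixel are flagged in ``empty`` and carry NaN means.
    """

    s: np.ndarray
    s_mean: np.ndarray
    mean: np.ndarray
    n_pixels: np.ndarray
    sem: np.ndarray

    @property
    def empty(self) -> np.ndarray:
        return self.n_pixels == 0

    def to_curve(self, role: str = "total", drop_empty: bool = True) -> DiffractionCurve:
        """Curve on the mean-s abscissa (empty bins dropped by default)."""
        keep = ~self.empty if drop_empty else slice(None)
        return DiffractionCurve(self.s_mean[keep], self.mean[keep], role=role)


def radial_average(
    image: DetectorImage,
    bin_width: float = 0.02,
    beam_center: tuple[float, float] | None = None,
) -> RadialProfile:
    """Mean counts per pixel in annular s-bins around the beam centre."""
    if not image.mask.any():
        raise ValueError("image is fully masked")
    s_map = image.geometry.s_map(beam_center)
    s_pix = s_map[image.mask]
    values = np.asarray(image.counts, dtype=float)[image.mask]
    n_bins = int(np.ceil(s_pix.max() / bin_width)) + 1
    idx = np.minimum((s_pix / bin_width).astype(np.int64), n_bins - 1)
    npix = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    sums_s = np.bincount(idx, weights=s_pix, minlength=n_bins)
    sums_sq = np.bincount(idx, weights=values * values, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(npix > 0, sums / npix, np.nan)
        s_mean = np.where(npix > 0, sums_s / npix, np.nan)
        var = np.where(npix > 1, (sums_sq - sums**2 / np.maximum(npix, 1))
                       / np.maximum(npix - 1, 1), np.nan)
        sem = np.where(npix > 1, np.sqrt(np.maximum(var, 0.0) / np.maximum(npix, 1)),
                       np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return RadialProfile(centers, s_mean, mean, npix, sem)


def _annular_variance(image: DetectorImage, center, bin_width: float) -> float:
    """Mean within-bin variance of counts; sharp rings minimize it."""
    s_map = image.geometry.s_map(center)
    s_pix = s_map[image.mask]
    values = np.asarray(image.counts, dtype=float)[image.mask]
    n_bins = int(np.ceil(s_pix.max() / bin_width)) + 1
    idx = np.minimum((s_pix / bin_width).astype(np.int64), n_bins - 1)
    npix = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    sums_sq = np.bincount(idx, weights=values * values, minlength=n_bins)
    good = npix > 1
    if not good.any():
        return float("inf")
    within = (sums_sq[good] - sums[good] ** 2 / npix[good])
    return float(within.sum() / npix[good].sum())


def find_center(
    image: DetectorImage,
    initial: tuple[float, float] | None = None,
    search_radius_px: float = 4.0,
    bin_width: float = 0.02,
):
    """Refine the beam centre by minimizing annular within-bin variance.

    Coarse-to-fine deterministic grid search around ``initial`` (default: the
    geometry's beam centre): 1 px steps over ±``search_radius_px``, then
    0.25 px steps over ±1 px.  Returns ``(center, refined)``; a flat image
    yields ``refined=False`` with the initial centre unchanged.
    """
    if initial is None:
        initial = image.geometry.beam_center
    vals = np.asarray(image.counts, dtype=float)[image.mask]
    if np.ptp(vals) == 0:
        return tuple(initial), False

    def metric(center):
        return _annular_variance(image, center, bin_width)

    best = tuple(initial)
    best_val = metric(best)
    steps = np.arange(-search_radius_px, search_radius_px + 0.5, 1.0)
    for dr in steps:
        for dc in steps:
            cand = (initial[0] + dr, initial[1] + dc)
            val = metric(cand)
            if val < best_val:
                best, best_val = cand, val
    fine = np.arange(-1.0, 1.001, 0.25)
    coarse_best = best
    for dr in fine:
        for dc in fine:
            cand = (coarse_best[0] + dr, coarse_best[1] + dc)
            val = metric(cand)
            if val < best_val:
                best, best_val = cand, val
    if not np.isfinite(best_val):
        return tuple(initial), False
    return best, True


# ---------------------------------------------------------------------------
# image i/o: TIFF counts plus plain-text metadata sidecar; text matrix fallback
# ---------------------------------------------------------------------------

def write_image(image: DetectorImage, path) -> None:
    """Write counts as TIFF (with .txt metadata sidecar) or as a text matrix.

    Integer count images are stored as uint16 when they fit, otherwise
    float32.  Paths not ending in .tif/.tiff get a plain-text matrix.
    """
    path = str(path)
    geom = image.geometry
    meta_lines = [
        f"pixel_pitch_mm = {geom.pixel_pitch}",
        f"camera_length_mm = {geom.camera_length}",
        f"n_pixels = {geom.n_pixels[0]} {geom.n_pixels[1]}",
        f"accel_voltage_kv = {geom.accel_voltage}",
        f"beam_center = {geom.beam_center[0]} {geom.beam_center[1]}",
    ]
    for key, val in image.meta.items():
        meta_lines.append(f"{key} = {val}")
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        data = image.counts
        if np.issubdtype(data.dtype, np.integer) and data.max(initial=0) < 2**16:
            data = data.astype(np.uint16)
        else:
            data = data.astype(np.float32)
        tifffile.imwrite(path, data)
        with open(path + ".meta", "w") as fh:
            fh.write("\n".join(meta_lines) + "\n")
    else:
        np.savetxt(path, image.counts, header="\n".join(meta_lines), fmt="%.8g")


def read_image(path) -> DetectorImage:
    """Read a TIFF (+ sidecar) or text-matrix detector image."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        counts = tifffile.imread(path)
        meta_path = path + ".meta"
        meta_text = open(meta_path).read().splitlines()
    else:
        counts = np.loadtxt(path)
        meta_text = []
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                meta_text.append(line[1:].strip())
    fields = {}
    for line in meta_text:
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip()] = val.strip()
    rows, cols = counts.shape
    geom = DetectorGeometry(
        pixel_pitch=float(fields.get("pixel_pitch_mm", 0.06)),
        camera_length=float(fields.get("camera_length_mm", 500.0)),
        n_pixels=(rows, cols),
        accel_voltage=float(fields.get("accel_voltage_kv", 100.0)),
        beam_center=tuple(
            float(v) for v in fields.get(
                "beam_center", f"{(rows - 1) / 2} {(cols - 1) / 2}"
            ).split()
        ),
    )
    return DetectorImage(counts, geom)
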