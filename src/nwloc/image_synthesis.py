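"""Synthetic fluorescence and bright-field frame rendering.

Image formation follows the photon-sampling scheme used for validating the
localization pipeline: each molecule emits an expected number of photons
(base rate × exposure × axial enhancement factor for waveguide-coupled
molecules), the realized photon count is Poisson, and the photons are
sampled multinomially onto camera pixels from a discretized point-spread
function.  Waveguide-coupled emission appears as an in-focus Gaussian at
the wire's lateral position (the objective is focused at the wire tips);
substrate-bound and defective-wire molecules appear with a z-defocused
Gaussian PSF at their own position and no enhancement.  The final frame is
the sum of the nanowire component, the substrate component, a uniform
autofluorescence background, dark-current offset, and read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .array_model import GroundTruth, NanowireLayout

__all__ = [
    "OpticalModel",
    "CameraModel",
    "SyntheticFrame",
    "sample_photons",
    "render_fluorescence",
    "render_brightfield",
    "enhancement_at",
    "default_enhancement_profile",
]


def default_enhancement_profile(
    wire_length_um: float = 2.5,
    step_um: float = 0.05,
    base: float = 2.0,
    tip: float = 18.0,
) -> np.ndarray:
    """Default combined-enhancement profile σ_enh(z) on the 50 nm grid.

    Waveguide coupling, excitation enhancement and quantum-yield modification
    all favor positions toward the wire tip; the default is a linear ramp
    from ``base`` at z = 0 to ``tip`` at z = L with mean 10 — an
    order-of-magnitude average enhancement.  Returns an array of shape
    (n, 2): columns are z (µm) and the combined factor.
    """
    z = np.arange(int(round(wire_length_um / step_um)) + 1) * step_um
    f = base + (tip - base) * z / wire_length_um
    return np.column_stack([z, f])


@dataclass
class OpticalModel:
    """Optics: emission PSF widths, defocus law, and the enhancement profile.

    ``psf_sigma_um`` is the in-focus Gaussian sd; its default is the
    diffraction-limited 0.21·λ/NA.  Defocus follows
    ``sd(Δz) = sd0·sqrt(1 + (Δz/z_R)²)`` with Rayleigh-type range ``z_R``.
    ``enhancement_profile`` tabulates (z µm, combined factor σ_enh) on the
    axial binding grid; emission from non-coupled molecules is unenhanced.
    ``background_photon_rate`` is a uniform autofluorescence photon rate per
    pixel per ms.
    """

    wavelength_em_nm: float = 670.0
    wavelength_ex_nm: float = 640.0
    na: float = 1.2
    psf_sigma_um: float | None = None
    rayleigh_range_um: float = 1.1
    enhancement_profile: np.ndarray = field(default_factory=default_enhancement_profile)
    background_photon_rate: float = 0.12  # photons / px / ms

    def __post_init__(self) -> None:
        if self.psf_sigma_um is None:
            self.psf_sigma_um = 0.21 * self.wavelength_em_nm / 1000.0 / self.na
        prof = np.asarray(self.enhancement_profile, float)
        if prof.ndim != 2 or prof.shape[1] != 2:
            raise ValueError("enhancement_profile must be an (n, 2) table of (z, factor)")
        if np.any(prof[:, 1] <= 0):
            raise ValueError("enhancement factors must be positive")
        if np.any(np.diff(prof[:, 0]) <= 0):
            raise ValueError("enhancement profile z values must be strictly increasing")
        self.enhancement_profile = prof
        # sanity: in-focus width should be diffraction-limited within 50 %
        diff_lim = 0.21 * self.wavelength_em_nm / 1000.0 / self.na
        if not (0.5 * diff_lim <= self.psf_sigma_um <= 1.5 * diff_lim):
            raise ValueError(
                f"psf_sigma_um={self.psf_sigma_um} inconsistent with the "
                f"diffraction limit {diff_lim:.3f} um"
            )

    def mean_enhancement(self) -> float:
        """<σ_enh>: the profile averaged over axial binding positions."""
        return float(np.mean(self.enhancement_profile[:, 1]))

    def defocus_sigma_um(self, dz_um: float | np.ndarray) -> np.ndarray | float:
        return self.psf_sigma_um * np.sqrt(1.0 + (np.asarray(dz_um) / self.rayleigh_range_um) ** 2)


def enhancement_at(optics: OpticalModel, z_um: float) -> float:
    """Combined enhancement factor at axial position ``z`` (µm).

    Linear interpolation on the profile table; exact at table nodes; raises
    for z outside the tabulated range.
    """
    prof = optics.enhancement_profile
    z0, z1 = prof[0, 0], prof[-1, 0]
    if not (z0 - 1e-12 <= z_um <= z1 + 1e-12):
        raise ValueError(f"z={z_um} um outside enhancement profile range [{z0}, {z1}]")
    return float(np.interp(z_um, prof[:, 0], prof[:, 1]))


@dataclass
class CameraModel:
    """Camera geometry, photon budget, and noise parameters.

    ``pixel_size_um`` is the object-space pixel pitch (6.5 µm physical pixels
    behind a 60× objective → 108.3 nm).  ``base_photon_rate`` is the expected
    photon emission rate of one unenhanced molecule in photons/ms; the
    expected photon count of a molecule is
    ``base_photon_rate × exposure_ms × σ_enh(z)`` (σ_enh = 1 when the
    molecule does not couple to a waveguide).
    """

    pixel_size_um: float = 0.1083
    shape: tuple[int, int] = (201, 201)  # (rows, cols)
    dark_offset: float = 100.0           # counts
    read_noise: float = 2.0              # counts, rms
    gain: float = 1.0                    # counts per photon
    exposure_ms: float = 100.0
    base_photon_rate: float = 4.5        # photons / ms / molecule (unenhanced)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.dark_offset < 0:
            raise ValueError("dark_offset must be non-negative")

    @classmethod
    def for_layout(cls, layout: NanowireLayout, **kw) -> "CameraModel":
        """Camera whose frame covers the layout's field exactly."""
        cam = cls(**kw)
        w, h = layout.field_size_um
        cam.shape = (
            int(np.ceil(h / cam.pixel_size_um)),
            int(np.ceil(w / cam.pixel_size_um)),
        )
        return cam

    # ------------------------------------------------------------ coordinates
    def um_to_px(self, xy_um: np.ndarray) -> np.ndarray:
        """µm → pixel-index coordinates (integer values are pixel centers)."""
        return np.asarray(xy_um, float) / self.pixel_size_um - 0.5

    def px_to_um(self, xy_px: np.ndarray) -> np.ndarray:
        return (np.asarray(xy_px, float) + 0.5) * self.pixel_size_um


@dataclass
class SyntheticFrame:
    """A rendered frame plus the pieces needed for diagnostics.

    ``image`` holds camera counts (float; quantize via :meth:`as_uint16`).
    ``expected_nw`` / ``expected_sub`` are the noiseless expected photon
    images of the nanowire and substrate/defect components, so that
    ``expected_nw + expected_sub + background + dark_offset`` is the
    noiseless expectation of ``image`` (in counts when gain = 1).
    """

    image: np.ndarray
    brightfield: np.ndarray | None
    ground_truth: GroundTruth
    expected_nw: np.ndarray
    expected_sub: np.ndarray
    background_photons: float
    camera: CameraModel
    optics: OpticalModel

    def expected_image(self) -> np.ndarray:
        """Noiseless expectation of the frame in counts."""
        return (
            (self.expected_nw + self.expected_sub + self.background_photons)
            * self.camera.gain
            + self.camera.dark_offset
        )

    def as_uint16(self) -> np.ndarray:
        return np.clip(np.rint(self.image), 0, 65535).astype(np.uint16)


def sample_photons(
    psf: np.ndarray, n_photons: int, seed_or_rng: int | np.random.Generator | None = None
) -> np.ndarray:
    """Sample ``n_photons`` onto pixels multinomially, proportional to ``psf``.

    Returns integer counts of the same shape as ``psf`` summing exactly to
    ``n_photons``.
    """
    psf = np.asarray(psf, float)
    if n_photons < 0:
        raise ValueError("n_photons must be non-negative")
    if np.any(psf < 0):
        raise ValueError("psf must be non-negative")
    total = psf.sum()
    if n_photons == 0:
        return np.zeros(psf.shape, dtype=np.int64)
    if total <= 0:
        raise ValueError("psf sums to zero but n_photons > 0")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    counts = rng.multinomial(int(n_photons), (psf / total).ravel())
    return counts.reshape(psf.shape)


def _integrated_gaussian_window(
    cx_px: float, cy_px: float, sigma_px: float, shape: tuple[int, int], half: int
):
    """Pixel-integrated Gaussian on a local window; returns (window, (r0, c0)).

    The window is clipped at the frame edges.  Pixel (r, c) covers
    [c−0.5, c+0.5] × [r−0.5, r+0.5] in pixel-index coordinates.
    """
    r0 = max(int(np.floor(cy_px)) - half, 0)
    r1 = min(int(np.floor(cy_px)) + half + 1, shape[0] - 1)
    c0 = max(int(np.floor(cx_px)) - half, 0)
    c1 = min(int(np.floor(cx_px)) + half + 1, shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return None, (0, 0)
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    s = sigma_px * np.sqrt(2.0)
    ey = 0.5 * (erf((rows + 0.5 - cy_px) / s) - erf((rows - 0.5 - cy_px) / s))
    ex = 0.5 * (erf((cols + 0.5 - cx_px) / s) - erf((cols - 0.5 - cx_px) / s))
    return np.outer(ey, ex), (r0, c0)


def render_fluorescence(
    gt: GroundTruth,
    layout: NanowireLayout,
    optics: OpticalModel,
    camera: CameraModel,
    seed: int | None = None,
    *,
    shot_noise: bool = True,
) -> SyntheticFrame:
    """Render a fluorescence frame from ground truth.

    Per molecule the realized photon count is Poisson around its expectation
    and photons are placed multinomially under the molecule's PSF, so the
    per-pixel signal is Poisson (photon shot noise).  With
    ``shot_noise=False`` the expected (noiseless) photon images are used and
    no noise of any kind is applied — useful for oracle tests.

    Also fills ``gt.molecules['expected_photons']`` in place.
    """
    rng = np.random.default_rng(seed)
    shape = camera.shape
    nw = np.zeros(shape)
    sub = np.zeros(shape)
    nw_exp = np.zeros(shape)
    sub_exp = np.zeros(shape)
    sigma0_px = optics.psf_sigma_um / camera.pixel_size_um
    L = layout.wire_length_um

    mol = gt.molecules
    expected = np.empty(len(mol))
    for i, row in enumerate(mol.itertuples(index=False)):
        if row.target == "wire" and row.wire_index >= 0:
            if layout.status[int(row.wire_index)] == "missing":
                raise ValueError(
                    f"molecule {i} references missing wire {int(row.wire_index)}; "
                    "placement must re-target molecules on missing wires"
                )
        if row.enhanced:
            factor = enhancement_at(optics, float(row.z_um))
            sigma_px = sigma0_px
        else:
            factor = 1.0
            # focal plane at the wire tips: defocus is the distance below it
            sigma_px = optics.defocus_sigma_um(L - float(row.z_um)) / camera.pixel_size_um
        e_photons = camera.base_photon_rate * camera.exposure_ms * factor
        expected[i] = e_photons

        cxy = camera.um_to_px(np.array([row.x_um, row.y_um]))
        half = max(int(np.ceil(4.0 * sigma_px)), 3)
        win, (r0, c0) = _integrated_gaussian_window(
            cxy[0], cxy[1], sigma_px, shape, half
        )
        if win is None:
            continue
        tgt_exp = nw_exp if row.enhanced else sub_exp
        tgt_exp[r0 : r0 + win.shape[0], c0 : c0 + win.shape[1]] += e_photons * win
        if shot_noise:
            n = int(rng.poisson(e_photons))
            if n and win.sum() > 0:
                counts = sample_photons(win, n, rng)
                tgt = nw if row.enhanced else sub
                tgt[r0 : r0 + win.shape[0], c0 : c0 + win.shape[1]] += counts

    mol["expected_photons"] = expected

    bg = optics.background_photon_rate * camera.exposure_ms
    if shot_noise:
        photons = nw + sub + rng.poisson(bg, size=shape)
        img = photons * camera.gain
        if camera.read_noise > 0:
            img = img + rng.normal(0.0, camera.read_noise, size=shape)
        img = img + camera.dark_offset
        np.clip(img, 0.0, None, out=img)
    else:
        img = (nw_exp + sub_exp + bg) * camera.gain + camera.dark_offset

    return SyntheticFrame(
        image=img,
        brightfield=None,
        ground_truth=gt,
        expected_nw=nw_exp,
        expected_sub=sub_exp,
        background_photons=bg,
        camera=camera,
        optics=optics,
    )


def render_brightfield(
    layout: NanowireLayout,
    camera: CameraModel,
    contrast: float = -0.3,
    seed: int | None = None,
    *,
    base_level: float = 1000.0,
    blob_sigma_um: float = 0.15,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Render a co-registered bright-field frame of the array.

    Every non-missing site appears as a Gaussian blob of relative amplitude
    ``contrast`` (negative = wires darker than background, as observed in
    transmission) on a uniform background, on the same pixel grid as the
    fluorescence frame.
    """
    if abs(contrast) > 1:
        raise ValueError("contrast must satisfy |contrast| <= 1")
    img = np.full(camera.shape, float(base_level))
    sigma_px = blob_sigma_um / camera.pixel_size_um
    half = max(int(np.ceil(4 * sigma_px)), 3)
    for i in range(layout.n_sites):
        if layout.status[i] == "missing":
            continue
        cxy = camera.um_to_px(layout.positions_um[i])
        win, (r0, c0) = _integrated_gaussian_window(
            cxy[0], cxy[1], sigma_px, camera.shape, half
        )
        if win is None:
            continue
        amp = contrast * base_level / win.max() if win.max() > 0 else 0.0
        img[r0 : r0 + win.shape[0], c0 : c0 + win.shape[1]] += amp * win
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd * base_level, size=img.shape)
    return img
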