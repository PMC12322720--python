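"""End-to-end composition: fusion → localization → Voronoi exclusion.

The three stages are individually optional; the bright-field-dependent
stages (fusion preprocessing and tip-colocalization postprocessing) degrade
gracefully to pass-through when no bright-field frame or no credible
lattice is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fusion as _fusion
from . import postprocess as _post
from .image_synthesis import CameraModel
from .localization import LocalizationParams, estimate_noise_sigma0, localize_frame

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("nwloc")


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run on one frame."""

    detections: pd.DataFrame            # final (kept) detections
    raw_detections: pd.DataFrame        # before postprocessing
    excluded: pd.DataFrame | None
    lattice: _fusion.LatticeEstimate | None
    fused_image: np.ndarray | None
    reference_points_um: np.ndarray | None


def run_pipeline(
    fluorescence: np.ndarray,
    brightfield: np.ndarray | None,
    camera: CameraModel,
    *,
    fusion_on: bool = True,
    fusion_strength: float = 0.9,
    postprocess_on: bool = True,
    one_per_wire: bool = True,
    nominal_spacing_um: float = 0.99,
    r_max_um: float | None = None,
    loc_params: LocalizationParams | None = None,
    psf_sigma_um: float = 0.117,
) -> PipelineResult:
    """Run the localization pipeline on one frame.

    With ``fusion_on`` the fluorescence frame is preprocessed using the
    lattice estimated from the bright-field frame; with ``postprocess_on``
    detections not colocalized with a bright-field tip are excluded
    (``r_max`` defaults to spacing/3) and at most one detection per wire is
    kept.  ``fusion_on=False, postprocess_on=False`` is the
    localization-only baseline.
    """
    loc_params = loc_params or LocalizationParams()
    lattice = None
    fused = None
    work = np.asarray(fluorescence, float)
    noise_sigma0 = None

    if fusion_on and brightfield is not None:
        try:
            lattice = _fusion.estimate_lattice(
                brightfield, nominal_spacing_um, camera.pixel_size_um
            )
            fused = _fusion.fuse(
                work, lattice, fusion_strength, camera.pixel_size_um,
                psf_sigma_um=psf_sigma_um,
            )
            # anchor the detection threshold to the raw-frame noise floor:
            # fusion suppresses off-lattice noise, which would otherwise
            # deflate the threshold and admit on-lattice noise peaks
            noise_sigma0 = estimate_noise_sigma0(
                np.asarray(fluorescence, float), loc_params.n_levels
            )
            work = fused
        except _fusion.LatticeEstimationError as err:
            log.warning("fusion skipped: %s", err)
            lattice = None

    detections = localize_frame(work, camera, loc_params, noise_sigma0=noise_sigma0)
    raw = detections

    excluded = None
    reference = None
    if postprocess_on and brightfield is not None and len(detections):
        reference = _post.detect_tips(
            brightfield, camera.pixel_size_um, nominal_spacing_um
        )
        if len(reference) >= 4:
            grid = _post.build_reference(
                reference, r_max_um, spacing_um=nominal_spacing_um
            )
            detections, excluded = _post.voronoi_exclude(
                detections, grid, one_per_wire=one_per_wire
            )
        else:
            log.warning("postprocessing skipped: too few reference tips")

    return PipelineResult(
        detections=detections,
        raw_detections=raw,
        excluded=excluded,
        lattice=lattice,
        fused_image=fused,
        reference_points_um=reference,
    )
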