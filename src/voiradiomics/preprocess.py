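"""Intensity standardization applied before feature extraction.

Two methods are provided:

``zscore``
    ``(x - mean) / sd`` computed over a body mask (or the whole volume).
    Idempotent up to floating point.

``landmark``
    A simplified single-image variant of piecewise-linear histogram
    standardization: the image's {p1, p10, 20, ..., p90, p99} percentiles are
    mapped onto a fixed reference scale [0, 100].  Training-set landmark
    averaging across a cohort (as done for multi-scanner harmonization) is
    deliberately out of scope; this variant is invariant to affine intensity
    transforms of the input, which is the property the pipeline relies on.

Bias-field correction is assumed to have been applied upstream; images from
the synthetic generator are bias-free.
"""

from __future__ import annotations

import numpy as np

from .volume import ImageVolume, VoiMask

#: Percentile landmarks: 1st, deciles, 99th.
LANDMARK_PERCENTILES = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)
#: Reference scale the landmarks are mapped onto.
REFERENCE_SCALE = (0.0, 100.0)


def normalize_intensity(
    image: ImageVolume,
    method: str = "zscore",
    body_mask: VoiMask | None = None,
) -> ImageVolume:
    """Standardize image intensities; spacing and origin are unchanged.

    Parameters
    ----------
    image : ImageVolume
    method : {"zscore", "landmark"}
    body_mask : VoiMask, optional
        Restrict the statistics (zscore) or percentile landmarks (landmark)
        to this region; the mapping is still applied to the whole volume.

    Raises
    ------
    ValueError
        If the (masked) intensity distribution is degenerate (sd == 0, or
        all landmark percentiles coincide), or the body mask is empty.
    """
    vox = image.voxels
    if body_mask is not None:
        body_mask.check_aligned(image)
        if body_mask.is_empty:
            raise ValueError("body_mask is empty")
        sample = vox[body_mask.voxels]
    else:
        sample = vox.reshape(-1)

    if method == "zscore":
        mu = sample.mean()
        sd = sample.std()
        if sd <= 0:
            raise ValueError("degenerate intensity distribution (zero variance)")
        return image.with_voxels((vox - mu) / sd)

    if method == "landmark":
        pct = np.percentile(sample, LANDMARK_PERCENTILES)
        if pct[-1] <= pct[0]:
            raise ValueError("degenerate intensity distribution (flat percentiles)")
        ref = np.linspace(REFERENCE_SCALE[0], REFERENCE_SCALE[1], len(pct))
        # monotone piecewise-linear map; linear extrapolation with edge slopes
        out = np.interp(vox, pct, ref)
        below = vox < pct[0]
        above = vox > pct[-1]
        if below.any():
            slope = (ref[1] - ref[0]) / max(pct[1] - pct[0], 1e-12)
            out[below] = ref[0] + slope * (vox[below] - pct[0])
        if above.any():
            slope = (ref[-1] - ref[-2]) / max(pct[-1] - pct[-2], 1e-12)
            out[above] = ref[-1] + slope * (vox[above] - pct[-1])
        return image.with_voxels(out)

    raise ValueError(f"unknown normalization method {method!r}")
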