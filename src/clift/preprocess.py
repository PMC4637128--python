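"""Image preprocessing: channel registration, focus scoring, artefact
detection and cell segmentation.

Everything structural happens in the red channel: the Evans-blue
counterstain renders every cell visible regardless of antibody status, so
sharpness control and segmentation there can never mistake an anti-dsDNA
negative (green-dark) biochip for a defocused or empty one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.registration import phase_cross_correlation

from .io import ChannelPair, RunConfig

__all__ = [
    "ImageQC",
    "SegmentationResult",
    "register_pair",
    "score_focus",
    "detect_artefacts",
    "segment_cells",
]


@dataclass
class ImageQC:
    """Image-level quality record."""

    focus_score: float = 0.0
    in_focus: bool = False
    artefact_mask: np.ndarray | None = None
    artefact_area_fraction: float = 0.0
    registration_shift: tuple = (0, 0)
    registration_failed: bool = False


@dataclass
class SegmentationResult:
    """Connected-component cell masks from the red channel."""

    label_image: np.ndarray
    n_components: int
    bounding_boxes: list = field(default_factory=list)  # (rmin, cmin, rmax, cmax)
    pixel_counts: list = field(default_factory=list)


def _is_featureless(image: np.ndarray) -> bool:
    """True when the image carries no structure beyond noise (e.g. a green
    channel of an all-negative biochip)."""
    p50, p999 = np.percentile(image, [50.0, 99.9])
    return bool(p999 - p50 < 0.05)


def register_pair(pair: ChannelPair, cfg: RunConfig | None = None):
    """Align green onto red by the integer-pixel translation maximizing
    cross-correlation.

    Returns ``(registered_pair, (d_row, d_col), failed)``.  The shift is the
    displacement applied to the green channel.  Registration is flagged
    failed when the required shift exceeds 5% of the image width or the
    aligned channels are uncorrelated despite the green channel carrying
    structure (likely an unpaired image).  A featureless green channel
    (no antibody signal anywhere) registers trivially at (0, 0).
    """
    cfg = cfg or RunConfig()
    red, green = pair.red, pair.green
    if _is_featureless(green):
        return pair, (0, 0), False
    shift, _, _ = phase_cross_correlation(
        red, green, upsample_factor=1, normalization=None
    )
    d = (int(round(shift[0])), int(round(shift[1])))
    max_shift = cfg.registration_max_shift_fraction * red.shape[1]
    failed = abs(d[0]) > max_shift or abs(d[1]) > max_shift
    aligned = ndimage.shift(green, d, order=0, mode="nearest")
    gc = aligned - aligned.mean()
    rc = red - red.mean()
    denom = np.sqrt((gc**2).sum() * (rc**2).sum())
    corr = float((gc * rc).sum() / denom) if denom > 0 else 0.0
    # sparse green signal (e.g. only faint basal bodies) correlates weakly
    # with the counterstain, so only near-zero correlation marks an
    # unpaired image
    if corr < 0.05:
        failed = True
    out = ChannelPair(
        green=aligned,
        red=red,
        bit_depth=pair.bit_depth,
        biochip_id=pair.biochip_id,
        sample_id=pair.sample_id,
        dilution_factor=pair.dilution_factor,
        source_paths=pair.source_paths,
    )
    return out, d, failed


def score_focus(red_image: np.ndarray) -> float:
    """Sharpness score of the red (counterstain) channel.

    Variance of the 3x3 Laplacian response after light Gaussian denoising
    (sigma 1), normalized by the squared mean intensity so the score is
    invariant to overall staining brightness.  The pre-smoothing keeps read
    noise from swamping the edge response, so the score strictly decreases
    as defocus blur increases; a constant image scores 0.
    """
    red = np.asarray(red_image, dtype=np.float64)
    if red.size == 0:
        raise ValueError("empty image")
    lap = ndimage.laplace(ndimage.gaussian_filter(red, 1.0))
    mean = red.mean()
    if mean <= 0:
        return 0.0
    return float(lap.var() / (mean**2))


def detect_artefacts(red_image, green_image, cfg: RunConfig | None = None):
    """Mask incubation artefacts: saturated patches and bright connected
    components far larger than any plausible cell.

    Returns ``(artefact_mask, artefact_area_fraction)``.
    """
    cfg = cfg or RunConfig()
    red = np.asarray(red_image, dtype=np.float64)
    green = np.asarray(green_image, dtype=np.float64)
    saturated = (red >= 0.995) | (green >= 0.995)
    # global threshold: robust background estimate + fixed offset; adaptive
    # thresholds plateau inside large blobs, which is exactly what must be
    # caught here
    bright = (red > np.median(red) + 0.10) | (green > np.median(green) + 0.10)

    def _big_components(binary, min_area):
        labels = measure.label(binary, connectivity=2)
        if labels.max() == 0:
            return np.zeros_like(binary)
        counts = np.bincount(labels.ravel())
        big = np.flatnonzero(counts > min_area)
        big = big[big != 0]
        return np.isin(labels, big) if big.size else np.zeros_like(binary)

    mask = _big_components(bright | saturated, cfg.artefact_max_component_area_px)
    # extended saturated patches only: a strongly stained kinetoplast may
    # legitimately saturate a few dozen pixels and must not be masked
    mask |= _big_components(saturated, cfg.artefact_saturation_min_area_px)
    fraction = float(mask.mean())
    return mask, fraction


def segment_cells(red_image, artefact_mask, cfg: RunConfig | None = None) -> SegmentationResult:
    """Segment every cell in the red channel by adaptive thresholding and
    8-connected components.

    Threshold: local mean over a window of about twice the expected cell
    length, offset by ``seg_k_sd`` local standard deviations (with a noise
    floor ``seg_min_offset``) — robust to the Evans-blue background varying
    across biochips.  Components touching the artefact mask or below the
    minimum area are removed; touching-cell clumps are not split, they fail
    downstream shape QC instead.
    """
    cfg = cfg or RunConfig()
    red = np.asarray(red_image, dtype=np.float64)
    w = cfg.seg_window_px
    local_mean = ndimage.uniform_filter(red, size=w, mode="reflect")
    local_sq = ndimage.uniform_filter(red**2, size=w, mode="reflect")
    local_sd = np.sqrt(np.clip(local_sq - local_mean**2, 0.0, None))
    threshold = local_mean + np.maximum(cfg.seg_k_sd * local_sd, cfg.seg_min_offset)
    fg = red > threshold
    fg = ndimage.binary_opening(fg, structure=morphology.disk(1).astype(bool))
    labels = measure.label(fg, connectivity=2)
    if artefact_mask is None:
        artefact_mask = np.zeros(red.shape, dtype=bool)

    keep = []
    if labels.max() > 0:
        counts = np.bincount(labels.ravel())
        touching = np.unique(labels[artefact_mask])
        touching = set(int(t) for t in touching if t != 0)
        for lab in range(1, labels.max() + 1):
            if counts[lab] < cfg.min_component_area_px:
                continue
            if lab in touching:
                continue
            keep.append(lab)

    out = np.zeros_like(labels)
    boxes, pixel_counts = [], []
    for new_id, lab in enumerate(keep, start=1):
        sel = labels == lab
        out[sel] = new_id
        rows, cols = np.nonzero(sel)
        boxes.append((int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1))
        pixel_counts.append(int(sel.sum()))
    return SegmentationResult(
        label_image=out,
        n_components=len(keep),
        bounding_boxes=boxes,
        pixel_counts=pixel_counts,
    )
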