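"""Synthetic dual-channel *Crithidia luciliae* image generator.

Emulates what a CLIFT biochip looks like through the microscope's two
cameras: the red channel carries the Evans-blue counterstain (every cell
body visible regardless of antibody status), the green channel carries the
FITC-specific signal of whichever organelles actually bound antibody.

Each cell is an elongated, tapered body with three organelles in fixed
anterior-to-posterior order along the main axis: basal body, kinetoplast,
nucleus.  Anti-dsDNA positivity of a cell is *defined* by green kinetoplast
fluorescence; nuclei and basal bodies may fluoresce independently of it,
which produces the six diagnostic archetypes (negative with bright nucleus
and/or basal body; positive with either accompaniment).

Every image comes with full per-cell ground truth so segmentation, QC,
orientation, profile extraction and classification can all be scored
without real data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SimConfig",
    "CellTruth",
    "GroundTruth",
    "simulate_image",
    "simulate_dilution_series",
    "simulate_artefact",
    "ORGANELLE_AXIS_POSITIONS",
    "ORGANELLE_SIGMA_PX",
]

# Fractional positions of the organelles along the main axis, measured from
# the basal (anterior, tapered) end.  Order is fixed by the biology:
# basal body < kinetoplast < nucleus.
ORGANELLE_AXIS_POSITIONS = {"basal_body": 0.10, "kinetoplast": 0.25, "nucleus": 0.60}

# Gaussian spot widths (px) at the reference cell length of 40 px; scaled
# linearly with actual cell length.  The nucleus is the largest structure,
# the basal body the smallest.
ORGANELLE_SIGMA_PX = {"basal_body": 1.5, "kinetoplast": 2.6, "nucleus": 4.0}

_REFERENCE_LENGTH_PX = 40.0

ARTEFACT_KINDS = ("bright_blob", "fiber", "saturation_patch")


def _default_organelle_intensity():
    # amplitudes calibrated so a lone kinetoplast keeps even the largest
    # cells clearly above the whole-cell darkness threshold
    return {
        "kinetoplast": (0.8, 0.12),
        "nucleus": (0.55, 0.1),
        "basal_body": (0.45, 0.08),
    }


@dataclass
class SimConfig:
    """Parameters of one synthetic biochip image.

    Defaults describe the test-scale frame: 612x512 px (one quarter of the
    full 2448x2048 acquisition) holding ~30 cells, matching the cell density
    of a 400x magnification field.  Intensities are on the normalized [0, 1]
    scale used throughout the pipeline.
    """

    image_width: int = 612
    image_height: int = 512
    n_cells: int = 30
    positive_fraction: float = 0.5
    organelle_intensity: dict = field(default_factory=_default_organelle_intensity)
    cell_length_px: tuple = (40.0, 4.0)
    cell_aspect: tuple = (3.5, 0.4)
    background_level: float = 0.05
    noise_sd: float = 0.01
    blur_sigma: float = 0.8
    artefact_count: int = 0
    rng_seed: int = 0
    # probability that a cell's nucleus / basal body fluoresce in green,
    # independently of anti-dsDNA status; together with positive_fraction
    # these generate all six diagnostic archetypes
    nucleus_fluor_prob: float = 0.5
    basal_fluor_prob: float = 0.5
    red_cell_intensity: tuple = (0.45, 0.05)
    # rejection-sampling placement
    overlap_margin_px: int = 5
    max_place_attempts: int = 100

    def validate(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        for name, (mean, sd) in self.organelle_intensity.items():
            if mean < 0 or sd < 0:
                raise ValueError(f"organelle_intensity[{name}] must be >= 0")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be >= 0")


@dataclass
class CellTruth:
    """Ground truth for one placed cell."""

    cell_index: int
    centroid_rc: tuple  # (row, col), 0-based, mask centroid
    orientation_deg: float  # main-axis angle, CCW from +col axis, mod 180
    length_px: float
    aspect: float
    organelle_positions: dict  # organelle -> fractional axis position
    is_positive: bool  # kinetoplast fluorescent in green
    nucleus_fluorescent: bool
    basal_body_fluorescent: bool
    organelle_amplitude: dict  # organelle -> drawn green amplitude (0 if dark)
    organelle_centers_rc: dict = field(default_factory=dict)  # organelle -> (row, col)
    true_titer_level: int = -1  # index into a dilution series; -1 = negative


@dataclass
class GroundTruth:
    """Per-image ground truth: every placed cell, artefact pixels, skips."""

    cells: list
    artefact_mask: np.ndarray
    n_skipped: int = 0
    true_titer_level: int = -1

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def fraction_positive(self) -> float:
        if not self.cells:
            return 0.0
        return sum(c.is_positive for c in self.cells) / len(self.cells)

    def cell_occupancy(self) -> np.ndarray:
        """Boolean map of all ground-truth cell bodies (from stored masks)."""
        return self._occupancy.copy()

    def to_json(self, path) -> None:
        payload = {
            "n_skipped": self.n_skipped,
            "true_titer_level": self.true_titer_level,
            "n_artefact_pixels": int(self.artefact_mask.sum()),
            "cells": [
                {
                    **dataclasses.asdict(c),
                    "centroid_rc": list(c.centroid_rc),
                }
                for c in self.cells
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for c in self.cells:
            rows.append(
                {
                    "cell_index": c.cell_index,
                    "centroid_row": c.centroid_rc[0],
                    "centroid_col": c.centroid_rc[1],
                    "orientation_deg": c.orientation_deg,
                    "length_px": c.length_px,
                    "aspect": c.aspect,
                    "is_positive": c.is_positive,
                    "nucleus_fluorescent": c.nucleus_fluorescent,
                    "basal_body_fluorescent": c.basal_body_fluorescent,
                    "kinetoplast_amplitude": c.organelle_amplitude["kinetoplast"],
                    "nucleus_amplitude": c.organelle_amplitude["nucleus"],
                    "basal_body_amplitude": c.organelle_amplitude["basal_body"],
                    "true_titer_level": c.true_titer_level,
                }
            )
        return pd.DataFrame(rows)


def _cell_geometry(center_rc, angle_deg, length, aspect, shape):
    """Rasterize one cell body.

    The body is a filled ellipse of semi-axes (0.6*length, width/2) centred
    at fractional axis position 0.6 and clipped at the posterior end, which
    yields a convex teardrop: pointed at the basal (anterior) end, widest
    around the nucleus.  Returns (rows, cols, axis_t) of interior pixels,
    with axis_t in [0, 1] measured from the basal end.
    """
    half_w = length / (2.0 * aspect)
    theta = np.deg2rad(angle_deg)
    ct, st = np.cos(theta), np.sin(theta)
    r0, c0 = center_rc
    reach = length / 2.0 + half_w + 2.0
    rmin = max(int(np.floor(r0 - reach)), 0)
    rmax = min(int(np.ceil(r0 + reach)) + 1, shape[0])
    cmin = max(int(np.floor(c0 - reach)), 0)
    cmax = min(int(np.ceil(c0 + reach)) + 1, shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    dr = rr - r0
    dc = cc - c0
    t = dc * ct + dr * st  # along axis, px, 0 at centre
    s = -dc * st + dr * ct  # across axis, px
    u = (t + length / 2.0) / length  # fractional position from basal end
    body = ((u - 0.6) / 0.6) ** 2 + (s / half_w) ** 2 <= 1.0
    inside = body & (u <= 1.0) & (u >= 0.0)
    return rr[inside], cc[inside], u[inside]


def _draw_spot(img, center_rc, amplitude, sigma):
    """Add an isotropic Gaussian spot to ``img`` in place."""
    r0, c0 = center_rc
    reach = int(np.ceil(4 * sigma)) + 1
    rmin = max(int(r0) - reach, 0)
    rmax = min(int(r0) + reach + 1, img.shape[0])
    cmin = max(int(c0) - reach, 0)
    cmax = min(int(c0) + reach + 1, img.shape[1])
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    img[rmin:rmax, cmin:cmax] += amplitude * np.exp(-d2 / (2.0 * sigma**2))


def _organelle_center(center_rc, angle_deg, length, frac):
    theta = np.deg2rad(angle_deg)
    t = (frac - 0.5) * length
    return (center_rc[0] + t * np.sin(theta), center_rc[1] + t * np.cos(theta))


def _place_cells(cfg: SimConfig, rng, amplitude_scale=1.0):
    """Rejection-sample non-overlapping cells; returns (cells, rendering info).

    Cells that cannot be placed within ``max_place_attempts`` are counted in
    ``n_skipped`` (reported, never silently dropped).
    """
    shape = (cfg.image_height, cfg.image_width)
    occupancy = np.zeros(shape, dtype=bool)
    cells = []
    placements = []
    n_skipped = 0
    struct = ndimage.generate_binary_structure(2, 2)
    for i in range(cfg.n_cells):
        length = max(rng.normal(*cfg.cell_length_px), 10.0)
        aspect = max(rng.normal(*cfg.cell_aspect), 1.5)
        angle = rng.uniform(0.0, 180.0)
        is_positive = bool(rng.random() < cfg.positive_fraction)
        nucleus_on = bool(rng.random() < cfg.nucleus_fluor_prob)
        basal_on = bool(rng.random() < cfg.basal_fluor_prob)
        red_level = float(np.clip(rng.normal(*cfg.red_cell_intensity), 0.1, 0.9))
        amplitudes = {}
        for org, on in (
            ("kinetoplast", is_positive),
            ("nucleus", nucleus_on),
            ("basal_body", basal_on),
        ):
            mean, sd = cfg.organelle_intensity[org]
            mean = mean * amplitude_scale
            sd = sd * amplitude_scale
            amplitudes[org] = float(max(rng.normal(mean, sd), 0.0)) if on else 0.0

        margin = length / 2.0 + 6.0
        placed = False
        for _ in range(cfg.max_place_attempts):
            r0 = rng.uniform(margin, shape[0] - margin)
            c0 = rng.uniform(margin, shape[1] - margin)
            rows, cols, axis_u = _cell_geometry((r0, c0), angle, length, aspect, shape)
            if rows.size < 5:
                continue
            cand = np.zeros(shape, dtype=bool)
            cand[rows, cols] = True
            grown = ndimage.binary_dilation(
                cand, structure=struct, iterations=cfg.overlap_margin_px
            )
            if np.any(grown & occupancy):
                continue
            occupancy |= cand
            centroid = (float(rows.mean()), float(cols.mean()))
            # organelle positions are fractions of the *rasterized* body
            # extent, the same coordinate the axis profile uses
            u_min, u_max = float(axis_u.min()), float(axis_u.max())
            centers = {}
            for org, frac in ORGANELLE_AXIS_POSITIONS.items():
                frac_eff = u_min + frac * (u_max - u_min)
                centers[org] = _organelle_center((r0, c0), angle, length, frac_eff)
            cells.append(
                CellTruth(
                    cell_index=len(cells),
                    centroid_rc=centroid,
                    orientation_deg=angle % 180.0,
                    length_px=length,
                    aspect=aspect,
                    organelle_positions=dict(ORGANELLE_AXIS_POSITIONS),
                    is_positive=is_positive,
                    nucleus_fluorescent=nucleus_on,
                    basal_body_fluorescent=basal_on,
                    organelle_amplitude=amplitudes,
                    organelle_centers_rc=centers,
                )
            )
            placements.append(
                {
                    "rows": rows,
                    "cols": cols,
                    "center": (r0, c0),
                    "angle": angle,
                    "length": length,
                    "red_level": red_level,
                    "u_range": (u_min, u_max),
                }
            )
            placed = True
            break
        if not placed:
            n_skipped += 1
    return cells, placements, occupancy, n_skipped


def _render(cfg: SimConfig, cells, placements, rng, amplitude_scale=1.0):
    """Render green/red channels for an already-placed scene."""
    shape = (cfg.image_height, cfg.image_width)
    red = np.full(shape, cfg.background_level, dtype=np.float64)
    green = np.full(shape, cfg.background_level, dtype=np.float64)
    for cell, plc in zip(cells, placements):
        red[plc["rows"], plc["cols"]] += plc["red_level"]
        sigma_scale = plc["length"] / _REFERENCE_LENGTH_PX
        u_min, u_max = plc["u_range"]
        for org, frac in cell.organelle_positions.items():
            amp = cell.organelle_amplitude[org] * amplitude_scale
            if amp <= 0:
                continue
            frac_eff = u_min + frac * (u_max - u_min)
            center = _organelle_center(
                plc["center"], plc["angle"], plc["length"], frac_eff
            )
            _draw_spot(green, center, amp, ORGANELLE_SIGMA_PX[org] * sigma_scale)
    return green, red


def _finalize(cfg: SimConfig, green, red, rng):
    if cfg.blur_sigma > 0:
        green = ndimage.gaussian_filter(green, cfg.blur_sigma)
        red = ndimage.gaussian_filter(red, cfg.blur_sigma)
    if cfg.noise_sd > 0:
        green = green + rng.normal(0.0, cfg.noise_sd, green.shape)
        red = red + rng.normal(0.0, cfg.noise_sd, red.shape)
    return np.clip(green, 0.0, 1.0), np.clip(red, 0.0, 1.0)


def simulate_image(cfg: SimConfig):
    """Simulate one registered green/red image pair.

    Returns ``(green, red, GroundTruth)`` with float images in [0, 1].
    The red channel shows every cell body (counterstain); the green channel
    shows only the organelles drawn fluorescent.  Deterministic for a fixed
    config including ``rng_seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    cells, placements, occupancy, n_skipped = _place_cells(cfg, rng)
    green, red = _render(cfg, cells, placements, rng)
    artefact_mask = np.zeros(green.shape, dtype=bool)
    for _ in range(cfg.artefact_count):
        kind = ARTEFACT_KINDS[rng.integers(0, len(ARTEFACT_KINDS))]
        green, red, m = _apply_artefact(green, red, kind, rng)
        artefact_mask |= m
    green, red = _finalize(cfg, green, red, rng)
    gt = GroundTruth(cells=cells, artefact_mask=artefact_mask, n_skipped=n_skipped)
    gt._occupancy = occupancy
    return green, red, gt


def _apply_artefact(green, red, kind, rng, **params):
    shape = green.shape
    mask = np.zeros(shape, dtype=bool)
    if kind == "bright_blob":
        area = float(params.get("area", 3000.0))
        radius = np.sqrt(area / np.pi)
        r0 = rng.uniform(radius + 2, shape[0] - radius - 2)
        c0 = rng.uniform(radius + 2, shape[1] - radius - 2)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        green = green + 0.85 * mask
        red = red + 0.85 * mask
    elif kind == "fiber":
        length = float(params.get("length", 150.0))
        width = float(params.get("width", 3.0))
        angle = rng.uniform(0, np.pi)
        r0 = rng.uniform(0.2 * shape[0], 0.8 * shape[0])
        c0 = rng.uniform(0.2 * shape[1], 0.8 * shape[1])
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        dr, dc = rr - r0, cc - c0
        t = dc * np.cos(angle) + dr * np.sin(angle)
        s = -dc * np.sin(angle) + dr * np.cos(angle)
        mask = (np.abs(t) <= length / 2) & (np.abs(s) <= width / 2)
        green = green + 0.7 * mask
        red = red + 0.7 * mask
    elif kind == "saturation_patch":
        h = int(params.get("height", 60))
        w = int(params.get("width", 80))
        r0 = int(rng.integers(0, max(shape[0] - h, 1)))
        c0 = int(rng.integers(0, max(shape[1] - w, 1)))
        mask[r0 : r0 + h, c0 : c0 + w] = True
        green = np.where(mask, 1.0, green)
        red = np.where(mask, 1.0, red)
    else:
        raise ValueError(f"unknown artefact kind: {kind!r}")
    return np.clip(green, 0, None), np.clip(red, 0, None), mask


def simulate_artefact(image, kind, rng, **params):
    """Inject one incubation artefact into a single-channel image.

    Returns ``(image, artefact_mask)``.  ``kind`` is one of
    ``bright_blob`` (circular debris; ``area`` param in px),
    ``fiber`` (elongated lint; ``length``/``width`` params),
    ``saturation_patch`` (rectangle forced to the dtype maximum).
    """
    out, _, mask = _apply_artefact(image.astype(np.float64), image.astype(np.float64), kind, rng, **params)
    if kind == "saturation_patch":
        out = np.where(mask, 1.0, image)
    return out, mask


def simulate_dilution_series(
    cfg: SimConfig,
    dilution_factors,
    positivity_threshold: float = 0.32,
):
    """Simulate one sample imaged at several dilutions of the same serum.

    The scene (cell placement and base amplitudes) is drawn once; each
    dilution is rendered with every green amplitude scaled by ``1/factor``,
    emulating antibody depletion.  The ground-truth titer level is the index
    of the last dilution whose mean kinetoplast amplitude still reaches
    ``positivity_threshold`` (the amplitude at which a cell's mean green
    fluorescence rises detectably above background for the default
    geometry), or -1 if none does.

    Returns ``(pairs, ground_truths)`` where ``pairs`` is a list of
    ``(green, red)`` tuples, one per dilution.
    """
    cfg.validate()
    factors = list(dilution_factors)
    if not factors:
        raise ValueError("dilution_factors must be non-empty")
    if any(f <= 0 for f in factors):
        raise ValueError("dilution_factors must be positive")
    if any(b >= a for b, a in zip(factors, factors[1:])):
        raise ValueError("dilution_factors must be strictly increasing")

    rng = np.random.default_rng(cfg.rng_seed)
    cells, placements, occupancy, n_skipped = _place_cells(cfg, rng)

    base_kineto = cfg.organelle_intensity["kinetoplast"][0]
    level = -1
    for j, f in enumerate(factors):
        if base_kineto / f >= positivity_threshold and any(
            c.is_positive for c in cells
        ):
            level = j
    for c in cells:
        c.true_titer_level = level

    pairs = []
    gts = []
    for f in factors:
        g, r = _render(cfg, cells, placements, rng, amplitude_scale=1.0 / f)
        g, r = _finalize(cfg, g, r, rng)
        gt = GroundTruth(
            cells=cells,
            artefact_mask=np.zeros(g.shape, dtype=bool),
            n_skipped=n_skipped,
            true_titer_level=level,
        )
        gt._occupancy = occupancy
        pairs.append((g, r))
        gts.append(gt)
    return pairs, gts
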