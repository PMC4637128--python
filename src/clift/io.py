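"""Image-pair and configuration I/O.

Reads the two single-channel fluorescence images of a biochip (green =
FITC-specific signal, red = Evans-blue counterstain), discovers slide
layouts on disk, and loads/saves the run configuration.

Conventions: 0-based (row, col) coordinates, origin top-left, half-open
crop intervals.  Intensities are normalized to [0, 1] by the *dtype*
maximum (not per-image min/max) so absolute brightness comparisons across
dilutions of the same sample remain meaningful for titer estimation.
"""

from __future__ import annotations

import dataclasses
import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = [
    "ChannelPair",
    "RunConfig",
    "ConfigError",
    "load_channel_pair",
    "save_image",
    "discover_slide",
    "load_config",
    "save_config",
    "DEFAULT_NAMING_PATTERN",
]


class ConfigError(ValueError):
    """Invalid run configuration or slide layout."""


@dataclass
class ChannelPair:
    """Registered green/red image pair for one biochip."""

    green: np.ndarray
    red: np.ndarray
    bit_depth: int
    biochip_id: str = ""
    sample_id: str = ""
    dilution_factor: float = 1.0
    source_paths: tuple = ("", "")

    def __post_init__(self):
        if self.green.shape != self.red.shape:
            raise ValueError(
                f"channel dimension mismatch: green {self.green.shape} "
                f"vs red {self.red.shape}"
            )
        if self.dilution_factor < 1.0:
            raise ValueError("dilution_factor must be >= 1")


def _default_qc_limits():
    # area limits are relative to the per-image median cell area; the other
    # features are absolute
    return {
        "area": [0.3, 3.0],
        "aspect_ratio": [2.0, 12.0],
        "solidity": [0.85, 1.0],
    }


# Breakpoints map median kinetoplast brightness (background-subtracted,
# un-normalized green intensity in the kinetoplast band) onto titer steps.
# Calibrated once on the simulator's default geometry: one titer step
# corresponds to a sqrt(10) brightness factor, anchored at the detection
# limit of the dark-cell rule.  See docs/methods.md.
_DEFAULT_BREAKPOINTS = [0.144, 0.454, 1.437, 4.543, 14.367]


@dataclass
class RunConfig:
    """All tunable thresholds of the classification pipeline."""

    positive_cell_cutoff: float = 0.5
    titer_steps: list = field(
        default_factory=lambda: ["1:10", "1:32", "1:100", "1:320", "1:1000"]
    )
    brightness_to_titer_breakpoints: list = field(
        default_factory=lambda: list(_DEFAULT_BREAKPOINTS)
    )
    cell_qc_limits: dict = field(default_factory=_default_qc_limits)
    dark_cell_k: float = 3.0
    focus_threshold: float = 0.008
    artefact_area_fraction_max: float = 0.25
    profile_bins: int = 32
    classifier_path: str | None = None
    rng_seed: int = 0
    # segmentation parameters (red channel, adaptive threshold)
    seg_window_px: int = 81
    seg_k_sd: float = 2.0
    seg_min_offset: float = 0.05
    min_component_area_px: int = 50
    artefact_max_component_area_px: int = 2000
    artefact_saturation_min_area_px: int = 400
    # axis band covering the kinetoplast, as fractions of the canonical axis
    kinetoplast_band: list = field(default_factory=lambda: [0.15, 0.35])
    min_aspect_for_orientation: float = 1.3
    registration_max_shift_fraction: float = 0.05

    def validate(self) -> None:
        if not 0.0 <= self.positive_cell_cutoff <= 1.0:
            raise ConfigError("positive_cell_cutoff must be in [0, 1]")
        if not self.titer_steps:
            raise ConfigError("titer_steps must be non-empty")
        bp = self.brightness_to_titer_breakpoints
        if len(bp) != len(self.titer_steps):
            raise ConfigError(
                "brightness_to_titer_breakpoints must match titer_steps length"
            )
        if any(b >= a for b, a in zip(bp, bp[1:])):
            raise ConfigError(
                "brightness_to_titer_breakpoints must be strictly increasing"
            )
        if self.profile_bins < 8:
            raise ConfigError("profile_bins must be >= 8")
        for name, (lo, hi) in self.cell_qc_limits.items():
            if lo > hi:
                raise ConfigError(f"cell_qc_limits[{name}] min exceeds max")
        if self.dark_cell_k < 0:
            raise ConfigError("dark_cell_k must be >= 0")
        if not 0.0 <= self.artefact_area_fraction_max <= 1.0:
            raise ConfigError("artefact_area_fraction_max must be in [0, 1]")
        if self.seg_window_px < 3 or self.seg_window_px % 2 == 0:
            raise ConfigError("seg_window_px must be an odd integer >= 3")
        lo, hi = self.kinetoplast_band
        if not 0.0 <= lo < hi <= 1.0:
            raise ConfigError("kinetoplast_band must be an increasing pair in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON (same schema); fills defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    cfg.validate()
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _read_gray(path) -> tuple[np.ndarray, int]:
    """Read a single-channel image; returns (float array in [0,1], bit depth)."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: RGB/multichannel input; extract the fluorescence channel "
            "to a single-channel grayscale image first"
        )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        bit_depth = arr.dtype.itemsize * 8
        scale = float(np.iinfo(arr.dtype).max)
        return arr.astype(np.float64) / scale, bit_depth
    arr = arr.astype(np.float64)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError(f"{path}: float images must already be scaled to [0, 1]")
    return arr, 32


def load_channel_pair(green_path, red_path, metadata=None) -> ChannelPair:
    """Load a registered-size green/red pair from disk.

    Arrays are float-normalized to [0, 1] by dtype max, preserving relative
    intensity.  ``metadata`` may carry biochip_id, sample_id and
    dilution_factor.
    """
    green, bits_g = _read_gray(green_path)
    red, bits_r = _read_gray(red_path)
    meta = dict(metadata or {})
    return ChannelPair(
        green=green,
        red=red,
        bit_depth=max(bits_g, bits_r),
        biochip_id=str(meta.get("biochip_id", "")),
        sample_id=str(meta.get("sample_id", "")),
        dilution_factor=float(meta.get("dilution_factor", 1.0)),
        source_paths=(str(green_path), str(red_path)),
    )


def save_image(image: np.ndarray, path) -> None:
    """Write a float [0,1] image as 16-bit grayscale TIFF or PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    data = np.round(arr * 65535.0).astype(np.uint16)
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


# default file naming: {sample}_{biochip}_{dilution}_{channel}.tif
DEFAULT_NAMING_PATTERN = (
    r"(?P<sample>[^_]+)_(?P<biochip>[^_]+)_(?P<dilution>[0-9.]+)"
    r"_(?P<channel>green|red)\.(?:tif|tiff|png)$"
)


@dataclass
class PairDescriptor:
    """Paths and metadata of one discovered biochip image pair."""

    sample_id: str
    biochip_id: str
    dilution_factor: float
    green_path: str
    red_path: str

    def load(self) -> ChannelPair:
        return load_channel_pair(
            self.green_path,
            self.red_path,
            {
                "sample_id": self.sample_id,
                "biochip_id": self.biochip_id,
                "dilution_factor": self.dilution_factor,
            },
        )


def discover_slide(dir_path, naming_pattern: str = DEFAULT_NAMING_PATTERN):
    """Discover image pairs in a directory, grouped by sample and dilution.

    Returns ``(descriptors, skipped)``: descriptors sorted by
    (sample, dilution ascending, biochip) — stable across file-system
    enumeration orders — and a list of skip records for unpaired files.
    """
    rx = re.compile(naming_pattern)
    groups: dict[tuple, dict] = {}
    skipped = []
    for name in sorted(os.listdir(dir_path)):
        m = rx.search(name)
        if not m:
            continue
        key = (m.group("sample"), m.group("biochip"), m.group("dilution"))
        groups.setdefault(key, {})[m.group("channel")] = os.path.join(dir_path, name)
    descriptors = []
    for (sample, biochip, dilution), channels in groups.items():
        if "green" in channels and "red" in channels:
            descriptors.append(
                PairDescriptor(
                    sample_id=sample,
                    biochip_id=biochip,
                    dilution_factor=float(dilution),
                    green_path=channels["green"],
                    red_path=channels["red"],
                )
            )
        else:
            missing = "red" if "green" in channels else "green"
            present = next(iter(channels.values()))
            skipped.append(
                {
                    "sample_id": sample,
                    "biochip_id": biochip,
                    "dilution": dilution,
                    "file": present,
                    "reason": f"missing_{missing}_channel",
                }
            )
    descriptors.sort(key=lambda d: (d.sample_id, d.dilution_factor, d.biochip_id))
    skipped.sort(key=lambda s: (s["sample_id"], s["dilution"], s["biochip_id"]))
    return descriptors, skipped
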