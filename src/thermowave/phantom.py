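"""Synthetic 2D neck phantom: tissue raster, ROIs, temperatures, randomization.

The phantom is a square imaging domain Omega (default 24 x 24 cm, 128 x 128
cells) containing an elliptical neck cross-section Sigma built from
concentric layers (skin, fat, muscle) plus posterior vertebra and spinal
cord, anterior thyroid lobes, and a small circular tumor (default radius
4.5 mm) embedded in one thyroid lobe.  Everything outside the neck is the
coupling (background) medium, a lossy water mixture.

Coordinate convention (used everywhere in the package): the label raster is
indexed ``labels[ix, iy]`` with the physical pixel-center coordinates

    x = (ix + 0.5) * cell_size - L / 2,   y = (iy + 0.5) * cell_size - L / 2,

so the domain is centred at the origin; +y is anterior (towards the
thyroid/tumor), -y posterior (towards the spine).

Two regions of interest are tracked: the tumor window Omega_1 (5 x 5 pixels)
and the spinal-cord window Omega_2 (6 x 6 pixels), each a square crop
centred on its structure.  Temperatures are imposed per ROI (no bio-heat
modelling): tumor in [37, 46] degC, cord in [37, 40] degC; all other tissues
stay at 37 degC.  Per-sample measurement-scenario variability is emulated by
adding, independently per tissue, Gaussian offsets (sd 0.1) to the real and
imaginary parts of the frequency-evaluated complex permittivity, constant
across the band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dielectric import (
    EPS0,
    TissueEntry,
    cole_cole,
    load_tissue_table,
    params_at_temperature,
)

__all__ = [
    "BACKGROUND",
    "PhantomConfig",
    "RoiSpec",
    "Phantom",
    "build_neck_phantom",
    "randomize_tissues",
    "set_roi_temperatures",
    "permittivity_map",
]

#: Label value of the background (coupling medium); tissues get 1..N.
BACKGROUND = 0

TUMOR_T_RANGE = (37.0, 46.0)
CORD_T_RANGE = (37.0, 40.0)


class ConfigError(ValueError):
    """Raised when a phantom/layout configuration is geometrically invalid."""


@dataclass(frozen=True)
class RoiSpec:
    """A square pixel window enclosing one anatomical structure.

    ``rows``/``cols`` are half-open index ranges on the phantom grid.
    """

    name: str
    row0: int
    col0: int
    size: int

    @property
    def rows(self) -> slice:
        return slice(self.row0, self.row0 + self.size)

    @property
    def cols(self) -> slice:
        return slice(self.col0, self.col0 + self.size)

    def contains(self, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        return (
            (ix >= self.row0)
            & (ix < self.row0 + self.size)
            & (iy >= self.col0)
            & (iy < self.col0 + self.size)
        )


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and material configuration of the synthetic neck phantom.

    All lengths in meters.  The default grid (128 cells over 24 cm, i.e.
    1.875 mm cells) keeps the 4.5 mm-radius tumor inside a 5 x 5 crop and
    the 5 mm-radius spinal cord inside a 6 x 6 crop.
    """

    grid_n: int = 128
    domain_size: float = 0.24
    neck_semi_axes: tuple[float, float] = (0.055, 0.050)
    skin_thickness: float = 0.002
    fat_thickness: float = 0.003
    vertebra_center: tuple[float, float] = (0.0, -0.020)
    vertebra_radius: float = 0.018
    cord_radius: float = 0.005
    thyroid_centers: tuple[tuple[float, float], ...] = ((-0.013, 0.032), (0.013, 0.032))
    thyroid_radius: float = 0.009
    tumor_center: tuple[float, float] = (0.013, 0.032)
    tumor_radius: float = 0.0045
    tumor_crop: int = 5
    cord_crop: int = 6
    # Coupling medium ("water mixture"): configurable stand-in values.
    background_eps_real: float = 23.0
    background_sigma: float = 1.0
    # Per-sample Gaussian randomization of tissue permittivities.
    perturb_sd: float = 0.1
    perturb_clip: float | None = None
    # Temperature model: perturb Cole-Cole parameters (table coefficients)
    # of tumor and spinal cord only.
    temperature_window: tuple[float, float] = (37.0, 46.0)

    @property
    def cell_size(self) -> float:
        return self.domain_size / self.grid_n

    def background_eps(self, f: float) -> complex:
        """Relative complex permittivity of the coupling medium at f [Hz]."""
        w = 2.0 * math.pi * f
        return self.background_eps_real - 1j * self.background_sigma / (w * EPS0)


#: Canonical tissue painting order; later entries overwrite earlier ones.
_TISSUE_ORDER = ("skin", "fat", "muscle", "bone", "spinal_cord", "thyroid", "tumor")


@dataclass(frozen=True)
class Phantom:
    """A tissue-label raster plus material state (offsets, ROI temperatures)."""

    labels: np.ndarray  # int array (grid_n, grid_n); 0 = background
    config: PhantomConfig
    tissue_ids: dict[str, int]  # tissue name -> label value
    tissue_table: dict[str, TissueEntry]
    tumor_roi: RoiSpec
    cord_roi: RoiSpec
    offsets: dict[str, complex] = field(default_factory=dict)
    T_tumor: float = 37.0
    T_cord: float = 37.0

    @property
    def cell_size(self) -> float:
        return self.config.cell_size

    @property
    def inside_neck(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of every pixel center, as 2D arrays."""
        n, h, L = self.config.grid_n, self.cell_size, self.config.domain_size
        c = (np.arange(n) + 0.5) * h - L / 2.0
        return np.meshgrid(c, c, indexing="ij")


def _grid_coords(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    n, h, L = config.grid_n, config.cell_size, config.domain_size
    c = (np.arange(n) + 0.5) * h - L / 2.0
    return np.meshgrid(c, c, indexing="ij")


def _enclosing_window(labels: np.ndarray, tid: int, size: int, name: str) -> RoiSpec:
    """Square window of the given pixel size centred on the structure's bbox."""
    ix, iy = np.nonzero(labels == tid)
    n = labels.shape[0]
    r_lo, r_hi = int(ix.min()), int(ix.max())
    c_lo, c_hi = int(iy.min()), int(iy.max())
    if r_hi - r_lo + 1 > size or c_hi - c_lo + 1 > size:
        raise ConfigError(f"{name!r} spans more than {size} pixels; enlarge the crop or coarsen")
    r0 = np.clip((r_lo + r_hi + 1 - size) // 2, 0, n - size)
    c0 = np.clip((c_lo + c_hi + 1 - size) // 2, 0, n - size)
    r0 = int(np.clip(r0, r_hi + 1 - size, r_lo))  # keep the structure enclosed
    c0 = int(np.clip(c0, c_hi + 1 - size, c_lo))
    if r0 < 0 or c0 < 0 or r0 + size > n or c0 + size > n:
        raise ConfigError(f"ROI window for {name!r} does not fit the grid")
    return RoiSpec(name=name, row0=r0, col0=c0, size=size)


def build_neck_phantom(
    config: PhantomConfig | None = None,
    tissue_table: dict[str, TissueEntry] | None = None,
) -> Phantom:
    """Rasterize the synthetic neck anatomy; deterministic given the config.

    Returns a phantom at uniform 37 degC with no per-sample offsets.
    Raises :class:`ConfigError` when a structure does not fit the grid or the
    tumor rasterizes to zero pixels.
    """
    config = config or PhantomConfig()
    tissue_table = tissue_table or load_tissue_table()
    missing = [t for t in _TISSUE_ORDER if t not in tissue_table]
    if missing:
        raise ConfigError(f"tissue table lacks entries for {missing}")
    if config.tumor_radius <= 0:
        raise ConfigError("tumor radius must be positive (empty tumor ROI)")

    x, y = _grid_coords(config)
    a, b = config.neck_semi_axes
    labels = np.zeros((config.grid_n, config.grid_n), dtype=np.int8)
    ids = {name: i + 1 for i, name in enumerate(_TISSUE_ORDER)}

    def ellipse(ax: float, ay: float) -> np.ndarray:
        return (x / ax) ** 2 + (y / ay) ** 2 <= 1.0

    def disc(cx: float, cy: float, r: float) -> np.ndarray:
        return (x - cx) ** 2 + (y - cy) ** 2 <= r * r

    t_sk, t_fa = config.skin_thickness, config.fat_thickness
    if a - t_sk - t_fa <= 0 or b - t_sk - t_fa <= 0:
        raise ConfigError("skin/fat layers thicker than the neck semi-axes")
    labels[ellipse(a, b)] = ids["skin"]
    labels[ellipse(a - t_sk, b - t_sk)] = ids["fat"]
    labels[ellipse(a - t_sk - t_fa, b - t_sk - t_fa)] = ids["muscle"]
    labels[disc(*config.vertebra_center, config.vertebra_radius)] = ids["bone"]
    labels[disc(*config.vertebra_center, config.cord_radius)] = ids["spinal_cord"]
    for cx, cy in config.thyroid_centers:
        labels[disc(cx, cy, config.thyroid_radius)] = ids["thyroid"]
    labels[disc(*config.tumor_center, config.tumor_radius)] = ids["tumor"]

    if not (labels == ids["tumor"]).any():
        raise ConfigError("tumor rasterized to zero pixels; refine the grid")
    if not (labels == ids["spinal_cord"]).any():
        raise ConfigError("spinal cord rasterized to zero pixels; refine the grid")

    tumor_roi = _enclosing_window(labels, ids["tumor"], config.tumor_crop, "tumor")
    cord_roi = _enclosing_window(labels, ids["spinal_cord"], config.cord_crop, "spinal_cord")
    t_rows = set(range(tumor_roi.row0, tumor_roi.row0 + tumor_roi.size))
    t_cols = set(range(tumor_roi.col0, tumor_roi.col0 + tumor_roi.size))
    c_rows = set(range(cord_roi.row0, cord_roi.row0 + cord_roi.size))
    c_cols = set(range(cord_roi.col0, cord_roi.col0 + cord_roi.size))
    if (t_rows & c_rows) and (t_cols & c_cols):
        raise ConfigError("tumor and cord ROI windows overlap")

    return Phantom(
        labels=labels,
        config=config,
        tissue_ids=ids,
        tissue_table=tissue_table,
        tumor_roi=tumor_roi,
        cord_roi=cord_roi,
    )


def randomize_tissues(phantom: Phantom, seed: int | np.random.Generator) -> Phantom:
    """Draw one complex permittivity offset per tissue (reproducible).

    For each tissue present in the raster, independent Gaussian offsets with
    sd ``config.perturb_sd`` are added to the real part eps' and to the loss
    part eps'' of its complex permittivity (constant across the frequency
    band).  Optionally clipped to ``+/- config.perturb_clip``.  Labels are
    never modified.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = phantom.config.perturb_sd
    clip = phantom.config.perturb_clip
    offsets: dict[str, complex] = {}
    for name in _TISSUE_ORDER:  # fixed order => reproducible draws
        if phantom.tissue_ids[name] not in phantom.labels:
            continue
        d_re, d_im = rng.normal(0.0, sd, size=2) if sd > 0 else (0.0, 0.0)
        if clip is not None:
            d_re = float(np.clip(d_re, -clip, clip))
            d_im = float(np.clip(d_im, -clip, clip))
        # eps = eps' - j eps'': a positive loss offset lowers the imag part.
        offsets[name] = complex(d_re, -d_im)
    return replace(phantom, offsets=offsets)


def set_roi_temperatures(phantom: Phantom, T_tumor: float, T_cord: float) -> Phantom:
    """Impose treatment temperatures on the two ROIs (other tissues stay 37 degC)."""
    if not TUMOR_T_RANGE[0] <= T_tumor <= TUMOR_T_RANGE[1]:
        raise ValueError(f"T_tumor {T_tumor} outside {TUMOR_T_RANGE}")
    if not CORD_T_RANGE[0] <= T_cord <= CORD_T_RANGE[1]:
        raise ValueError(f"T_cord {T_cord} outside {CORD_T_RANGE}")
    return replace(phantom, T_tumor=float(T_tumor), T_cord=float(T_cord))


def save_phantom(path, phantom: Phantom) -> None:
    """Export the raster plus a JSON metadata sidecar into one .npz container."""
    import dataclasses
    import json

    meta = {
        "config": dataclasses.asdict(phantom.config),
        "tissue_ids": phantom.tissue_ids,
        "offsets": {k: [v.real, v.imag] for k, v in phantom.offsets.items()},
        "T_tumor": phantom.T_tumor,
        "T_cord": phantom.T_cord,
        "tumor_roi": dataclasses.asdict(phantom.tumor_roi),
        "cord_roi": dataclasses.asdict(phantom.cord_roi),
    }
    np.savez(path, labels=phantom.labels, meta=json.dumps(meta))


def load_phantom(path, tissue_table: dict[str, TissueEntry] | None = None) -> Phantom:
    """Load a phantom written by :func:`save_phantom` (labels are trusted as-is)."""
    import json

    with np.load(path, allow_pickle=False) as blob:
        labels = blob["labels"]
        meta = json.loads(str(blob["meta"]))
    cfg_raw = meta["config"]
    for key in ("neck_semi_axes", "vertebra_center", "tumor_center", "temperature_window"):
        cfg_raw[key] = tuple(cfg_raw[key])
    cfg_raw["thyroid_centers"] = tuple(tuple(c) for c in cfg_raw["thyroid_centers"])
    return Phantom(
        labels=labels,
        config=PhantomConfig(**cfg_raw),
        tissue_ids=meta["tissue_ids"],
        tissue_table=tissue_table or load_tissue_table(),
        tumor_roi=RoiSpec(**meta["tumor_roi"]),
        cord_roi=RoiSpec(**meta["cord_roi"]),
        offsets={k: complex(v[0], v[1]) for k, v in meta["offsets"].items()},
        T_tumor=meta["T_tumor"],
        T_cord=meta["T_cord"],
    )


_TEMPERATURE_BEARING = {"tumor": "T_tumor", "spinal_cord": "T_cord"}


def permittivity_map(phantom: Phantom, f: float) -> np.ndarray:
    """Per-pixel relative complex permittivity at frequency ``f`` [Hz].

    Pure function of the phantom state: tissue label -> Cole-Cole at the
    tissue's imposed temperature, plus the per-sample complex offset;
    background pixels get the coupling-medium permittivity.
    """
    cfg = phantom.config
    eps_map = np.full(phantom.labels.shape, cfg.background_eps(f), dtype=np.complex128)
    present = set(np.unique(phantom.labels))
    for name, tid in phantom.tissue_ids.items():
        if tid not in present:
            continue
        entry = phantom.tissue_table[name]
        params = entry.params
        attr = _TEMPERATURE_BEARING.get(name)
        if attr is not None:
            T = getattr(phantom, attr)
            params = params_at_temperature(params, entry.coeffs, T, cfg.temperature_window)
        eps = cole_cole(params, f).to_complex() + phantom.offsets.get(name, 0.0)
        eps_map[phantom.labels == tid] = eps
    return eps_map
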