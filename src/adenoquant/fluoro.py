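"""Compartment-wise PGR immunofluorescence quantification.

The workflow mirrors a manual-ROI uterine immunofluorescence analysis:
a trichrome image (PGR in red, αSMA in green, DAPI in blue) is
decomposed into luminal epithelium, glands and stroma from hand-drawn
polygons; the red and blue channels are binarised independently with an
automatic (Otsu) threshold computed once per image over the studied
region; and per compartment the PGR signal is expressed as the ratio of
red foreground area to blue (nuclear) foreground area. The green
channel delineates the myometrium visually and is carried through but
never enters the quantification.

Conventions (fixed so results are reproducible across runs):

* polygon coordinates are 0-based pixel coordinates (x = column,
  y = row, origin top-left); a pixel belongs to a polygon when its
  center lies strictly inside (even-odd fill);
* the Otsu threshold is the lowest maximiser of the between-class
  variance over the 256-bin histogram; foreground is strictly greater
  than the threshold;
* areas are pixel counts (ratios are scale-free); µm² areas are derived
  only when a pixel size is supplied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from . import stats as _stats

COMPARTMENTS = ("epithelium", "glands", "stroma")


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class TrichromeImage:
    """Three co-registered 8-bit channels of one stained section."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        for name in ("red", "green", "blue"):
            arr = np.asarray(getattr(self, name))
            if arr.ndim != 2:
                raise ValueError(f"{name} channel must be 2-D")
            if arr.dtype != np.uint8:
                if arr.min() < 0 or arr.max() > 255:
                    raise ValueError(f"{name} channel outside 8-bit range")
                arr = arr.astype(np.uint8)
            setattr(self, name, arr)
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def to_array(self) -> np.ndarray:
        """(H, W, 3) RGB stack."""
        return np.stack([self.red, self.green, self.blue], axis=-1)


@dataclass
class CompartmentROIs:
    """Manually drawn polygons: the studied region, the luminal epithelium
    (one or more polygons) and the glands."""

    total_region: list[tuple[float, float]]
    luminal_epithelium: list[list[tuple[float, float]]] = field(default_factory=list)
    glands: list[list[tuple[float, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for poly in self._all_polygons():
            if len(poly) < 3:
                raise ValueError("polygons need at least 3 vertices")
        total = Polygon(self.total_region)
        if not total.is_valid:
            raise ValueError("total_region polygon is invalid")
        for name, polys in (
            ("luminal_epithelium", self.luminal_epithelium),
            ("glands", self.glands),
        ):
            for poly in polys:
                if not Polygon(poly).covered_by(total):
                    raise ValueError(f"a {name} polygon lies outside total_region")

    def _all_polygons(self) -> Iterable[Sequence[tuple[float, float]]]:
        yield self.total_region
        yield from self.luminal_epithelium
        yield from self.glands

    def to_json(self, path: str | Path) -> None:
        payload = {
            "total_region": [list(p) for p in self.total_region],
            "luminal_epithelium": [[list(p) for p in poly]
                                   for poly in self.luminal_epithelium],
            "glands": [[list(p) for p in poly] for poly in self.glands],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CompartmentROIs":
        payload = json.loads(Path(path).read_text())
        return cls(
            total_region=[tuple(p) for p in payload["total_region"]],
            luminal_epithelium=[[tuple(p) for p in poly]
                                for poly in payload.get("luminal_epithelium", [])],
            glands=[[tuple(p) for p in poly] for poly in payload.get("glands", [])],
        )


@dataclass
class CompartmentMasks:
    """Disjoint boolean rasters whose union is the studied region."""

    epithelium: np.ndarray
    glands: np.ndarray
    stroma: np.ndarray
    studied_region: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.epithelium, self.glands,
                                    self.stroma, self.studied_region)}
        if len(shapes) != 1:
            raise ValueError("masks must share one shape")
        overlap = (
            (self.epithelium & self.glands)
            | (self.epithelium & self.stroma)
            | (self.glands & self.stroma)
        )
        if overlap.any():
            raise ValueError("compartment masks must be pairwise disjoint")
        union = self.epithelium | self.glands | self.stroma
        if not np.array_equal(union, self.studied_region):
            raise ValueError("compartments must tile the studied region")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "epithelium": self.epithelium,
            "glands": self.glands,
            "stroma": self.stroma,
        }


@dataclass
class CompartmentQuant:
    area_red: int
    area_blue: int

    @property
    def ratio(self) -> float:
        """Red area over blue area; NaN when the compartment has no blue."""
        if self.area_blue == 0:
            return math.nan
        return self.area_red / self.area_blue

    @property
    def ratio_defined(self) -> bool:
        return self.area_blue > 0


@dataclass
class PGRQuant:
    compartments: dict[str, CompartmentQuant]
    threshold_red: int
    threshold_blue: int


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_trichrome(
    path: str | Path,
    channel_order: str = "RGB",
    pixel_size_um: float | None = None,
) -> TrichromeImage:
    """Read a 3-channel 8-bit raster (TIFF or PNG) and map its planes to
    PGR (red) / αSMA (green) / DAPI (blue) per ``channel_order``."""
    path = Path(path)
    order = channel_order.upper()
    if sorted(order) != ["B", "G", "R"]:
        raise ValueError(f"channel_order must be a permutation of RGB, got {channel_order!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(
            f"{path.name}: expected a 3-channel raster, got shape {arr.shape}"
        )
    planes = {ch: arr[..., i] for i, ch in enumerate(order)}
    return TrichromeImage(
        red=planes["R"], green=planes["G"], blue=planes["B"],
        pixel_size_um=pixel_size_um,
    )


def write_trichrome(image: TrichromeImage, path: str | Path) -> None:
    """Write the RGB stack as 8-bit TIFF or PNG by extension."""
    path = Path(path)
    stack = image.to_array()
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, stack, photometric="rgb")
    else:
        from PIL import Image

        Image.fromarray(stack, mode="RGB").save(path)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def rasterize_polygons(
    polygons: Sequence[Sequence[tuple[float, float]]], shape: tuple[int, int]
) -> np.ndarray:
    """Boolean mask of pixels whose centers fall strictly inside the union
    of the polygons (overlaps counted once).

    Pixel (row r, col c) has its center at coordinates (x=c, y=r).
    """
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    for coords in polygons:
        poly = Polygon(coords)
        if not poly.is_valid:
            poly = poly.buffer(0)
        minx, miny, maxx, maxy = poly.bounds
        if minx < -0.5 or miny < -0.5 or maxx > W - 0.5 or maxy > H - 0.5:
            raise ValueError("polygon extends outside the image bounds")
        c0, c1 = max(0, math.floor(minx)), min(W - 1, math.ceil(maxx))
        r0, r1 = max(0, math.floor(miny)), min(H - 1, math.ceil(maxy))
        if c1 < c0 or r1 < r0:
            continue
        cols = np.arange(c0, c1 + 1)
        rows = np.arange(r0, r1 + 1)
        cc, rr = np.meshgrid(cols, rows)
        inside = shapely.contains_xy(poly, cc.ravel().astype(float),
                                     rr.ravel().astype(float))
        mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask


def decompose_compartments(
    image: TrichromeImage, rois: CompartmentROIs
) -> CompartmentMasks:
    """Split the studied region into epithelium, glands and stroma.

    Epithelium wins over glands where the polygons overlap; stroma is
    the remainder of the studied region, so the three masks are disjoint
    and tile it exactly.
    """
    shape = image.shape
    studied = rasterize_polygons([rois.total_region], shape)
    epithelium = (
        rasterize_polygons(rois.luminal_epithelium, shape)
        if rois.luminal_epithelium else np.zeros(shape, dtype=bool)
    )
    glands = (
        rasterize_polygons(rois.glands, shape)
        if rois.glands else np.zeros(shape, dtype=bool)
    )
    epithelium &= studied
    glands &= studied
    glands &= ~epithelium
    stroma = studied & ~epithelium & ~glands
    return CompartmentMasks(
        epithelium=epithelium, glands=glands, stroma=stroma, studied_region=studied
    )


# ---------------------------------------------------------------------------
# Thresholding and quantification
# ---------------------------------------------------------------------------


class DegenerateHistogramError(ValueError):
    """Raised when the masked region holds a single intensity value."""


def otsu_threshold(channel: np.ndarray, within: np.ndarray | None = None) -> int:
    """Otsu's automatic threshold on the 256-bin histogram of the masked
    pixels: the value t maximising the between-class variance of the
    split (<= t) vs (> t), lowest t on ties."""
    channel = np.asarray(channel)
    values = channel[within] if within is not None else channel.ravel()
    if values.size == 0:
        raise DegenerateHistogramError("empty mask")
    hist = np.bincount(values.astype(np.uint8).ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("constant region: no threshold separates it")
    total = hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)  # class 0 = values <= t
    sum0 = np.cumsum(hist * levels)
    w1 = total - w0
    grand = sum0[-1]
    # between-class variance for t = 0..254; both classes must be non-empty
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (grand - sum0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = sigma_b[:255]
    sigma_b[np.isnan(sigma_b)] = -np.inf
    valid = (w0[:255] > 0) & (w1[:255] > 0)
    sigma_b[~valid] = -np.inf
    return int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximiser


def quantify_pgr(image: TrichromeImage, masks: CompartmentMasks) -> PGRQuant:
    """Per-compartment red/blue area ratio.

    One threshold per channel per image, computed over the whole studied
    region and applied to every compartment (keeping compartments
    comparable); areas are counts of strictly-above-threshold pixels.
    """
    if masks.studied_region.shape != image.shape:
        raise ValueError("masks do not match the image shape")
    t_red = otsu_threshold(image.red, masks.studied_region)
    t_blue = otsu_threshold(image.blue, masks.studied_region)
    red_fg = image.red > t_red
    blue_fg = image.blue > t_blue
    out: dict[str, CompartmentQuant] = {}
    for name, mask in masks.as_dict().items():
        out[name] = CompartmentQuant(
            area_red=int(np.count_nonzero(red_fg & mask)),
            area_blue=int(np.count_nonzero(blue_fg & mask)),
        )
    out["studied_region"] = CompartmentQuant(
        area_red=int(np.count_nonzero(red_fg & masks.studied_region)),
        area_blue=int(np.count_nonzero(blue_fg & masks.studied_region)),
    )
    return PGRQuant(compartments=out, threshold_red=t_red, threshold_blue=t_blue)


def compare_groups_pgr(
    quants: Sequence[PGRQuant], groups: Sequence[str]
) -> dict[str, _stats.TestResult]:
    """Two-sided Mann-Whitney on per-compartment ratios between two groups."""
    if len(quants) != len(groups):
        raise ValueError("one group label per quantification")
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    out: dict[str, _stats.TestResult] = {}
    for comp in COMPARTMENTS:
        x = [q.compartments[comp].ratio for q, g in zip(quants, groups)
             if g == labels[0] and q.compartments[comp].ratio_defined]
        y = [q.compartments[comp].ratio for q, g in zip(quants, groups)
             if g == labels[1] and q.compartments[comp].ratio_defined]
        if not x or not y:
            raise ValueError(f"compartment {comp!r}: a group has no defined ratios")
        out[comp] = _stats.mann_whitney(x, y)
    return out


def quant_to_row(image_id: str, quant: PGRQuant) -> list[dict]:
    """Flatten one quantification into CSV rows."""
    rows = []
    for comp, cq in quant.compartments.items():
        rows.append(
            {
                "image_id": image_id,
                "compartment": comp,
                "area_red": cq.area_red,
                "area_blue": cq.area_blue,
                "ratio": cq.ratio,
                "threshold_red": quant.threshold_red,
                "threshold_blue": quant.threshold_blue,
            }
        )
    return rows
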