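"""Reading and writing fixation tables, AOI definitions, and heat-map images.

Conventions used throughout the package:

* pixel coordinates are 0-based, row-major, origin at the top-left corner;
  ``x`` indexes columns, ``y`` indexes rows;
* fixation times are milliseconds since stimulus onset;
* heat-map images use a three-level ordinal color scheme (high / medium /
  low attention) over a transparent background.
"""

from __future__ import annotations

import io
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

DEFAULT_VIEWING_MS = 7000.0


class Group(str, Enum):
    """Participant group: trained geneticist clinicians vs. lay controls."""

    CLINICIAN = "clinician"
    NON_CLINICIAN = "non_clinician"


class MapKind(str, Enum):
    GAZE = "gaze"
    SALIENCY = "saliency"
    DIFFERENCE = "difference"


class FormatError(ValueError):
    """Raised when an input stream violates the documented file contract."""


@dataclass(frozen=True)
class Fixation:
    """A single fixation event: where the gaze rested, when, and for how long."""

    x_px: float
    y_px: float
    onset_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError(f"fixation duration must be positive, got {self.duration_ms}")
        if self.onset_ms < 0:
            raise ValueError(f"fixation onset must be >= 0, got {self.onset_ms}")


@dataclass
class FixationSequence:
    """Time-ordered fixations of one participant on one stimulus."""

    participant_id: str
    group: Group
    stimulus_id: str
    fixations: list[Fixation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.fixations = sorted(self.fixations, key=lambda f: f.onset_ms)

    def total_duration_ms(self) -> float:
        return float(sum(f.duration_ms for f in self.fixations))

    def __len__(self) -> int:
        return len(self.fixations)


@dataclass
class AttentionMap:
    """Dense nonnegative scalar field over stimulus pixels.

    The single container for gaze heat maps, classifier saliency maps and
    common-attention-subtracted residuals. ``values[y, x]`` follows the raster
    convention (row = y, column = x).
    """

    values: np.ndarray
    kind: MapKind = MapKind.GAZE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.kind = MapKind(self.kind)
        if self.values.ndim != 2:
            raise ValueError("AttentionMap values must be a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("AttentionMap values must be finite")
        if self.kind is not MapKind.DIFFERENCE and np.any(self.values < 0):
            raise ValueError(f"{self.kind.value} map must be nonnegative")

    @property
    def height_px(self) -> int:
        return self.values.shape[0]

    @property
    def width_px(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def total_mass(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class ColorScheme:
    """Ordinal three-color heat-map palette rendered over transparency.

    Defaults are the homogeneous dark-red ramp used for quantitative heat-map
    export (high #943126, medium #B03A2E, low #CB4335).
    """

    high_hex: str = "#943126"
    medium_hex: str = "#B03A2E"
    low_hex: str = "#CB4335"

    def __post_init__(self) -> None:
        codes = [self.high_hex, self.medium_hex, self.low_hex]
        if len(set(c.upper() for c in codes)) != 3:
            raise ValueError("color scheme requires three distinct hex codes")

    def rgb_levels(self) -> dict[int, tuple[int, int, int]]:
        """Level -> RGB triple; level 3 = high, 2 = medium, 1 = low."""
        return {
            3: _hex_to_rgb(self.high_hex),
            2: _hex_to_rgb(self.medium_hex),
            1: _hex_to_rgb(self.low_hex),
        }


def _hex_to_rgb(code: str) -> tuple[int, int, int]:
    code = code.lstrip("#")
    if len(code) != 6:
        raise ValueError(f"bad hex color {code!r}")
    return tuple(int(code[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


@dataclass
class AOISet:
    """Named analyst-drawn polygons over one stimulus (areas of interest)."""

    stimulus_id: str
    aois: list[tuple[str, Polygon]] = field(default_factory=list)

    def names(self) -> list[str]:
        return [name for name, _ in self.aois]

    def __len__(self) -> int:
        return len(self.aois)


# ---------------------------------------------------------------------------
# Fixation tables
# ---------------------------------------------------------------------------

_FIXATION_COLUMNS = [
    "participant_id",
    "group",
    "stimulus_id",
    "x_px",
    "y_px",
    "onset_ms",
    "duration_ms",
]


def read_fixation_table(
    source: str | IO[str],
    bounds: tuple[int, int] | None = None,
) -> list[FixationSequence]:
    """Parse a fixation-level TSV export into one sequence per trial.

    Parameters
    ----------
    source
        Path or text stream. Tab-separated, UTF-8, '#' comment lines ignored.
        Required columns: participant_id, group, stimulus_id, x_px, y_px,
        onset_ms, duration_ms.
    bounds
        Optional ``(width_px, height_px)``. Fixations landing outside are
        clipped to the image boundary (partially off-screen gaze still carries
        signal); the clipped count is logged.

    Returns
    -------
    One :class:`FixationSequence` per (participant, stimulus) pair present in
    the table, fixations sorted by onset. Rows with missing coordinates are
    dropped (count logged). Participant × stimulus coverage may be unbalanced:
    trials with no recorded data simply yield no sequence.
    """
    try:
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"fixation table missing required column(s): {', '.join(missing)}")
    if df.empty:
        return []

    numeric_cols = ["x_px", "y_px", "onset_ms", "duration_ms"]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise FormatError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column {col} (line {line})"
            )
        df[col] = converted

    n_before = len(df)
    df = df.dropna(subset=["x_px", "y_px"])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d fixation rows with missing coordinates", n_dropped)

    n_clipped = 0
    if bounds is not None:
        w, h = bounds
        outside = (df["x_px"] < 0) | (df["x_px"] > w - 1) | (df["y_px"] < 0) | (df["y_px"] > h - 1)
        n_clipped = int(outside.sum())
        df["x_px"] = df["x_px"].clip(0, w - 1)
        df["y_px"] = df["y_px"].clip(0, h - 1)
        if n_clipped:
            logger.info("clipped %d off-image fixations to the boundary", n_clipped)

    sequences: list[FixationSequence] = []
    for (pid, grp, sid), sub in df.groupby(
        ["participant_id", "group", "stimulus_id"], sort=True
    ):
        fixes = [
            Fixation(float(r.x_px), float(r.y_px), float(r.onset_ms), float(r.duration_ms))
            for r in sub.itertuples()
        ]
        sequences.append(FixationSequence(str(pid), Group(grp), str(sid), fixes))
    return sequences


def write_fixation_table(sequences: Iterable[FixationSequence], dest: str | IO[str]) -> None:
    """Serialize sequences back to the TSV contract (round-trips with reader)."""
    rows = []
    for seq in sequences:
        for f in seq.fixations:
            rows.append(
                (seq.participant_id, seq.group.value, seq.stimulus_id,
                 f.x_px, f.y_px, f.onset_ms, f.duration_ms)
            )
    df = pd.DataFrame(rows, columns=_FIXATION_COLUMNS)
    df.to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Heat-map images (3-level ordinal color scheme over transparency)
# ---------------------------------------------------------------------------

#: Euclidean RGB distance below which a pixel is taken to match a scheme code
#: exactly; anti-aliased edge pixels beyond it are snapped to the nearest code
#: with a warning.
COLOR_TOLERANCE = 16.0


def decode_heatmap_image(
    image: np.ndarray | Image.Image, scheme: ColorScheme | None = None
) -> AttentionMap:
    """Recover the ordinal attention levels from a rendered heat-map image.

    Fully transparent pixels map to 0; opaque pixels map to the nearest scheme
    code (high → 3, medium → 2, low → 1). Pixels farther than
    :data:`COLOR_TOLERANCE` from every code are still snapped to the nearest
    one, but their fraction is reported via a warning.
    """
    scheme = scheme or ColorScheme()
    if isinstance(image, Image.Image):
        image = np.asarray(image.convert("RGBA"))
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] not in (3, 4):
        raise ValueError("expected an RGB(A) pixel grid")
    rgb = image[..., :3].astype(np.float64)
    if image.shape[2] == 4:
        opaque = image[..., 3] > 0
    else:
        opaque = np.ones(image.shape[:2], dtype=bool)

    levels = scheme.rgb_levels()
    codes = np.array([levels[3], levels[2], levels[1]], dtype=np.float64)
    # distance of every pixel to each of the three codes
    dist = np.linalg.norm(rgb[..., None, :] - codes[None, None, :, :], axis=-1)
    nearest = dist.argmin(axis=-1)  # 0 -> high, 1 -> medium, 2 -> low
    level_of_nearest = np.array([3, 2, 1])[nearest]

    out = np.where(opaque, level_of_nearest, 0)
    min_dist = dist.min(axis=-1)
    off = opaque & (min_dist > COLOR_TOLERANCE)
    if off.any():
        frac = off.mean()
        warnings.warn(
            f"{frac:.1%} of opaque pixels matched no scheme code within "
            f"tolerance {COLOR_TOLERANCE}; snapped to nearest code",
            stacklevel=2,
        )
    return AttentionMap(out.astype(np.float64), kind=MapKind.GAZE)


def encode_heatmap_image(amap: AttentionMap, scheme: ColorScheme | None = None) -> np.ndarray:
    """Render an attention map as an RGBA pixel grid in the ordinal scheme.

    Maps already on levels {0,1,2,3} are rendered directly; continuous maps
    are first quantized by terciles of their nonzero values (so the top third
    of attended pixels renders as "high", etc.). Level 0 renders fully
    transparent. Negative values are rejected — clip difference maps first.
    """
    scheme = scheme or ColorScheme()
    vals = amap.values
    if np.any(vals < 0):
        raise ValueError("cannot encode a map with negative values; clip first")
    levels = quantize_levels(vals)
    rgb_of = scheme.rgb_levels()
    out = np.zeros((*vals.shape, 4), dtype=np.uint8)
    for lvl, rgb in rgb_of.items():
        m = levels == lvl
        out[m, :3] = rgb
        out[m, 3] = 255
    return out


def quantize_levels(values: np.ndarray) -> np.ndarray:
    """Quantize a nonnegative map onto ordinal levels {0, 1, 2, 3}.

    Zero stays 0; nonzero values split at the terciles of the nonzero
    distribution. A map already on {0,1,2,3} is returned unchanged.
    """
    values = np.asarray(values, dtype=np.float64)
    unique = np.unique(values)
    if np.all(np.isin(unique, [0.0, 1.0, 2.0, 3.0])):
        return values.astype(np.int64)
    out = np.zeros(values.shape, dtype=np.int64)
    nz = values > 0
    if not nz.any():
        return out
    t1, t2 = np.quantile(values[nz], [1 / 3, 2 / 3])
    out[nz] = 1
    out[nz & (values > t1)] = 2
    out[nz & (values > t2)] = 3
    return out


# ---------------------------------------------------------------------------
# Continuous attention-map persistence: 16-bit grayscale PNG + JSON sidecar
# ---------------------------------------------------------------------------

def save_attention_map(amap: AttentionMap, png_path: str) -> None:
    """Persist a continuous map losslessly-enough as 16-bit gray + scale sidecar."""
    vals = amap.values
    if np.any(vals < 0):
        raise ValueError("cannot persist negative values; clip first")
    vmax = float(vals.max())
    scale = vmax / 65535.0 if vmax > 0 else 1.0
    gray = np.round(vals / scale).astype(np.uint16) if vmax > 0 else vals.astype(np.uint16)
    Image.fromarray(gray).save(png_path)
    with open(_sidecar_path(png_path), "w", encoding="utf-8") as fh:
        json.dump({"scale": scale, "kind": amap.kind.value}, fh)


def load_attention_map(png_path: str) -> AttentionMap:
    gray = np.asarray(Image.open(png_path), dtype=np.float64)
    with open(_sidecar_path(png_path), encoding="utf-8") as fh:
        meta = json.load(fh)
    return AttentionMap(gray * float(meta["scale"]), kind=MapKind(meta.get("kind", "gaze")))


def _sidecar_path(png_path: str) -> str:
    return png_path + ".json" if not png_path.endswith(".png") else png_path[:-4] + ".json"


# ---------------------------------------------------------------------------
# AOI definitions
# ---------------------------------------------------------------------------

def read_aoi_set(
    source: str | IO[str] | dict, bounds: tuple[int, int] | None = None
) -> AOISet:
    """Load and validate an AOI set from JSON.

    Contract: ``{"stimulus_id": str, "aois": [{"name": str,
    "polygon": [[x, y], ...]}]}``. Each polygon must be simple
    (non-self-intersecting), have at least 3 vertices, carry a unique name,
    and — when ``bounds = (width, height)`` is given — lie inside the image.
    """
    if isinstance(source, dict):
        data = source
    elif isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            data = json.load(fh)
    else:
        data = json.load(source)

    stimulus_id = str(data["stimulus_id"])
    aois: list[tuple[str, Polygon]] = []
    seen: set[str] = set()
    for entry in data.get("aois", []):
        name = str(entry["name"])
        if name in seen:
            raise FormatError(f"duplicate AOI name {name!r} for stimulus {stimulus_id}")
        seen.add(name)
        verts = entry["polygon"]
        if len(verts) < 3:
            raise FormatError(f"AOI {name!r}: polygon needs >= 3 vertices, got {len(verts)}")
        poly = Polygon([(float(x), float(y)) for x, y in verts])
        if not poly.is_valid or poly.area == 0:
            raise FormatError(f"AOI {name!r}: polygon is self-intersecting or degenerate")
        if bounds is not None:
            w, h = bounds
            minx, miny, maxx, maxy = poly.bounds
            if minx < 0 or miny < 0 or maxx > w - 1 or maxy > h - 1:
                raise FormatError(f"AOI {name!r}: polygon extends outside image bounds")
        aois.append((name, poly))
    return AOISet(stimulus_id=stimulus_id, aois=aois)


def write_aoi_set(aoi_set: AOISet, dest: str | IO[str]) -> None:
    data = {
        "stimulus_id": aoi_set.stimulus_id,
        "aois": [
            {"name": name, "polygon": [[float(x), float(y)] for x, y in poly.exterior.coords[:-1]]}
            for name, poly in aoi_set.aois
        ],
    }
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1)
    else:
        json.dump(data, dest, indent=1)
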