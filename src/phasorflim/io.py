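"""Data model and file I/O for TCSPC decay cubes, masks, ROIs and result tables.

A decay cube is the raw object of FLIM analysis: a per-pixel photon-count
histogram ``F(x, y, t)`` together with the acquisition metadata needed to
interpret the time axis.  Cubes are stored as multi-page unsigned-integer
TIFF files (one page per time bin) with a JSON metadata sidecar, which keeps
them portable and readable by any scientific TIFF stack.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "AcquisitionMeta",
    "DecayCube",
    "MaskSet",
    "RoiPolygon",
    "FieldResultTable",
    "LABEL_BACKGROUND",
    "LABEL_CYTOPLASM",
    "LABEL_NUCLEUS",
    "read_decay_cube",
    "write_decay_cube",
    "rasterize_rois",
    "write_results",
    "read_results",
]

LABEL_BACKGROUND = 0
LABEL_CYTOPLASM = 1
LABEL_NUCLEUS = 2

RESULT_COLUMNS = [
    "field_id",
    "compartment",
    "treatment",
    "mean_lifetime",
    "bound_fraction",
    "raw_intensity",
    "corrected_intensity",
    "normalized_intensity",
    "concentration_proxy",
    "n_pixels",
]


class MetadataError(ValueError):
    """Sidecar metadata missing or inconsistent."""


class FormatError(ValueError):
    """File contents violate the cube format contract."""


class ShapeError(ValueError):
    """Array dimensions inconsistent with metadata."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters of one TCSPC field.

    Times are SI seconds internally; convenience properties expose the
    nanosecond values used throughout the analysis layer.  The default
    geometry is a 10-ns measurement window (one period of a 100-MHz
    excitation laser) divided into 256 time bins.
    """

    n_bins: int = 256
    bin_width: float = 10e-9 / 256
    period: float = 10e-9
    rep_frequency: float = 1e8
    n_frames: int = 1
    pixel_size: float = 1e-6
    field_id: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise ValueError(f"n_bins must be >= 8, got {self.n_bins}")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not math.isclose(self.n_bins * self.bin_width, self.period, rel_tol=1e-9):
            raise ValueError(
                f"n_bins * bin_width = {self.n_bins * self.bin_width!r} "
                f"does not equal period = {self.period!r}"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def bin_width_ns(self) -> float:
        return self.bin_width * 1e9

    @property
    def period_ns(self) -> float:
        return self.period * 1e9

    def bin_centers_ns(self) -> np.ndarray:
        """Bin-center times in ns; bin k spans [k*dt, (k+1)*dt)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns

    def matches_period_convention(self, rel_tol: float = 1e-6) -> bool:
        """True when the window equals one full laser period T = 1/f_rep."""
        return math.isclose(self.period, 1.0 / self.rep_frequency, rel_tol=rel_tol)

    def to_json_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "bin_width_ps": self.bin_width * 1e12,
            "period_ns": self.period * 1e9,
            "rep_frequency_MHz": self.rep_frequency / 1e6,
            "n_frames": self.n_frames,
            "pixel_size_um": self.pixel_size * 1e6,
            "field_id": self.field_id,
            "treatment": self.treatment,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "AcquisitionMeta":
        try:
            return cls(
                n_bins=int(d["n_bins"]),
                bin_width=float(d["bin_width_ps"]) * 1e-12,
                period=float(d["period_ns"]) * 1e-9,
                rep_frequency=float(d["rep_frequency_MHz"]) * 1e6,
                n_frames=int(d.get("n_frames", 1)),
                pixel_size=float(d.get("pixel_size_um", 1.0)) * 1e-6,
                field_id=str(d.get("field_id", "")),
                treatment=str(d.get("treatment", "")),
            )
        except KeyError as exc:  # pragma: no cover - message only
            raise MetadataError(f"missing metadata key {exc}") from exc


@dataclass
class DecayCube:
    """Per-pixel photon-count decay histograms with acquisition metadata.

    ``counts[row, col, bin]`` holds non-negative integer photon counts.
    ``frame_intensity`` optionally records the mean intensity of each of the
    accumulated frames, used downstream for photobleaching correction.
    """

    counts: np.ndarray
    meta: AcquisitionMeta
    frame_intensity: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ShapeError(f"counts must be 3-D (row, col, bin), got {counts.ndim}-D")
        if counts.shape[2] != self.meta.n_bins:
            raise ShapeError(
                f"cube has {counts.shape[2]} time bins but metadata says "
                f"{self.meta.n_bins}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.array_equal(counts, np.round(counts)):
                raise FormatError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise FormatError("counts must be non-negative")
        self.counts = counts
        if self.frame_intensity is not None:
            fi = [float(v) for v in self.frame_intensity]
            if len(fi) != self.meta.n_frames:
                raise ShapeError(
                    f"frame_intensity has {len(fi)} entries for "
                    f"{self.meta.n_frames} frames"
                )
            self.frame_intensity = fi

    @property
    def shape(self) -> tuple:
        return self.counts.shape[:2]

    def total_photons(self) -> int:
        return int(self.counts.sum())

    def intensity_image(self) -> np.ndarray:
        """Total photons per pixel (summed over time bins)."""
        return self.counts.sum(axis=2)

    def with_counts(self, counts: np.ndarray) -> "DecayCube":
        return DecayCube(counts=counts, meta=self.meta,
                         frame_intensity=self.frame_intensity)


@dataclass
class MaskSet:
    """Compartment label image: 0 background, 1 cytoplasm, 2 nucleus."""

    labels: np.ndarray
    provenance: str = "manual"

    _ALLOWED_PROVENANCE = ("manual", "synthetic-truth", "threshold")

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ShapeError("labels must be a 2-D image")
        if not np.isin(labels, [0, 1, 2]).all():
            raise ValueError("labels must be in {0, 1, 2}")
        self.labels = labels.astype(np.uint8)
        if self.provenance not in self._ALLOWED_PROVENANCE:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def pixels(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class RoiPolygon:
    """A hand-drawn region polygon in 0-based (row, col) pixel coordinates."""

    vertices: tuple
    label: int = LABEL_NUCLEUS

    def __post_init__(self) -> None:
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = _ShapelyPolygon([(c, r) for r, c in verts])  # shapely is (x, y)
        if not poly.is_valid or poly.area == 0:
            raise ValueError("polygon is self-intersecting or degenerate")
        object.__setattr__(self, "vertices", verts)

    def as_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon([(c, r) for r, c in self.vertices])


@dataclass
class FieldResultTable:
    """Per-(field, compartment) aggregate results as a tidy table."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESULT_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"result table missing columns: {missing}")
        self.df = self.df[RESULT_COLUMNS + [c for c in self.df.columns
                                            if c not in RESULT_COLUMNS]]
        if len(self.df):
            dup = self.df.duplicated(subset=["field_id", "compartment"])
            if dup.any():
                raise ValueError("duplicate (field_id, compartment) rows")
            if (self.df["n_pixels"] <= 0).any():
                raise ValueError("n_pixels must be positive")


# ---------------------------------------------------------------------------
# cube I/O


def write_decay_cube(cube: DecayCube, path: str | Path) -> tuple:
    """Write a cube as multi-page TIFF + JSON sidecar; returns both paths.

    Page k of the TIFF is the image of time bin k.  Counts are stored as
    uint16 (raw single-field TCSPC counts fit comfortably); larger values
    raise rather than overflow silently.
    """
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        path = path.with_suffix(".tif")
    cmax = cube.counts.max() if cube.counts.size else 0
    if cmax > np.iinfo(np.uint16).max:
        raise FormatError(f"count {cmax} exceeds uint16 range")
    pages = np.ascontiguousarray(cube.counts.transpose(2, 0, 1).astype(np.uint16))
    tifffile.imwrite(path, pages)
    sidecar = path.with_suffix(".json")
    payload = cube.meta.to_json_dict()
    if cube.frame_intensity is not None:
        payload["frame_intensity"] = list(cube.frame_intensity)
    sidecar.write_text(json.dumps(payload, indent=1))
    return path, sidecar


def read_decay_cube(path: str | Path, format: str = "tiff+json") -> DecayCube:
    """Read a cube written by :func:`write_decay_cube`.

    The ``sdt`` vendor format is an optional adapter and is only available
    when the ``sdtfile`` package is installed.
    """
    path = Path(path)
    if format == "sdt":
        return _read_sdt(path)
    if format != "tiff+json":
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise MetadataError(f"no metadata sidecar for {path}")
    payload = json.loads(sidecar.read_text())
    meta = AcquisitionMeta.from_json_dict(payload)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != meta.n_bins:
        raise ShapeError(
            f"TIFF has {pages.shape[0]} pages but metadata says {meta.n_bins} bins"
        )
    if not np.issubdtype(pages.dtype, np.integer):
        raise FormatError(f"expected integer pixel type, got {pages.dtype}")
    counts = pages.transpose(1, 2, 0).astype(np.int64)
    return DecayCube(counts=counts, meta=meta,
                     frame_intensity=payload.get("frame_intensity"))


def _read_sdt(path: Path) -> DecayCube:  # pragma: no cover - optional adapter
    try:
        import sdtfile
    except ImportError as exc:
        raise ImportError("reading .sdt requires the optional sdtfile package") from exc
    sdt = sdtfile.SdtFile(str(path))
    data = np.asarray(sdt.data[0])
    times = np.asarray(sdt.times[0])
    dt = float(times[1] - times[0])
    n_bins = data.shape[-1]
    meta = AcquisitionMeta(n_bins=n_bins, bin_width=dt, period=n_bins * dt,
                           field_id=path.stem)
    return DecayCube(counts=data.astype(np.int64), meta=meta)


# ---------------------------------------------------------------------------
# ROI rasterization


def rasterize_rois(
    rois: Sequence[RoiPolygon],
    shape: tuple,
    background_mask: Optional[np.ndarray] = None,
) -> MaskSet:
    """Convert nuclear ROI polygons plus a background mask into labels.

    Membership is a pixel-center-in-polygon test with boundary pixels
    included.  The background threshold is applied first, so background
    always wins over an overlapping nuclear ROI; all remaining non-background
    pixels outside every nuclear polygon become cytoplasm.
    """
    rows, cols = shape
    if background_mask is None:
        background_mask = np.zeros(shape, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != tuple(shape):
        raise ShapeError("background_mask shape differs from image shape")

    labels = np.full(shape, LABEL_CYTOPLASM, dtype=np.uint8)
    if rois:
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        nuclear = np.zeros(shape, dtype=bool)
        for roi in rois:
            if roi.label != LABEL_NUCLEUS:
                raise ValueError("only nuclear (label 2) ROIs are rasterized")
            poly = roi.as_shapely()
            # shapely points are (x=col, y=row); intersects includes boundary
            inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel())
            nuclear |= inside.reshape(shape)
        labels[nuclear] = LABEL_NUCLEUS
    labels[background_mask] = LABEL_BACKGROUND
    return MaskSet(labels=labels, provenance="manual")


def read_rois(path: str | Path) -> list:
    """Read ROI polygons from the JSON list-of-objects format."""
    payload = json.loads(Path(path).read_text())
    return [RoiPolygon(vertices=[tuple(v) for v in item["vertices"]],
                       label=int(item.get("label", LABEL_NUCLEUS)))
            for item in payload]


def write_rois(rois: Sequence[RoiPolygon], path: str | Path) -> None:
    payload = [{"label": r.label, "vertices": [list(v) for v in r.vertices]}
               for r in rois]
    Path(path).write_text(json.dumps(payload))


def write_mask(mask: MaskSet, path: str | Path) -> None:
    tifffile.imwrite(Path(path), mask.labels.astype(np.uint8))


def read_mask(path: str | Path, provenance: str = "manual") -> MaskSet:
    return MaskSet(labels=tifffile.imread(Path(path)), provenance=provenance)


# ---------------------------------------------------------------------------
# result tables


def write_results(table: FieldResultTable, path: str | Path) -> Path:
    """Write the per-(field, compartment) table as CSV with a stable header."""
    path = Path(path)
    df = table.df
    numeric = df[RESULT_COLUMNS].select_dtypes(include=[np.number])
    if len(df) and not np.isfinite(numeric.to_numpy(dtype=float)).all():
        raise ValueError("refusing to write non-finite values")
    df.to_csv(path, index=False)
    return path


def read_results(path: str | Path) -> FieldResultTable:
    return FieldResultTable(df=pd.read_csv(path))
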