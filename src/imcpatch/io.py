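"""Cohort inputs and outputs.

Images are multipage TIFF stacks, one page per marker channel, in panel order.
Panels and cohort metadata are plain UTF-8 CSV files with a header row:

* panel:    ``channel,marker``
* metadata: ``sample_id,file,grade,is_case``

Physical pixel size (micrometres per pixel) is read from image metadata when
present — either this package's own JSON image description or an OME-XML
``PhysicalSizeX`` attribute — and otherwise must be supplied by the caller.
Hyperion-class IMC instruments ablate on a 1 um spot pitch, so cohort readers
default to 1.0 um/px when the table does not say otherwise.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._errors import ConfigurationError, FormatError

log = logging.getLogger(__name__)

GRADES = ("G0", "G1", "G2", "G3")
#: Grade labels accepted in cohort metadata. "control" is treated as the
#: unfibrotic stratum alongside G0.
ALLOWED_GRADES = GRADES + ("control",)
REQUIRED_MARKERS = ("DNA", "Shh", "TGFb")

# Both "SHH"/"Shh" and several TGF-beta spellings occur in practice.
_MARKER_ALIASES = {
    "dna": "DNA",
    "shh": "Shh",
    "tgfb": "TGFb",
    "tgf-b": "TGFb",
    "tgf-beta": "TGFb",
    "tgfbeta": "TGFb",
    "tgf-β": "TGFb",
    "tgfβ": "TGFb",
}


def canonical_marker(name: str) -> str:
    """Resolve a marker name to its canonical form (case-insensitive aliases)."""
    key = str(name).strip().lower()
    return _MARKER_ALIASES.get(key, str(name).strip())


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered mapping from TIFF page index to marker name."""

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        idx = [int(i) for i, _ in self.entries]
        if sorted(idx) != list(range(len(idx))):
            raise FormatError(
                f"panel channel indices must be unique and contiguous from 0, got {idx}"
            )
        names = [canonical_marker(m) for _, m in self.entries]
        if len(set(names)) != len(names):
            raise FormatError(f"duplicate marker names in panel: {names}")

    @classmethod
    def from_markers(cls, markers) -> "MarkerPanel":
        return cls(tuple(enumerate(markers)))

    @property
    def markers(self) -> tuple[str, ...]:
        """Canonical marker names in channel order."""
        ordered = sorted(self.entries, key=lambda e: e[0])
        return tuple(canonical_marker(m) for _, m in ordered)

    def __len__(self) -> int:
        return len(self.entries)

    def channel_of(self, marker: str) -> int:
        target = canonical_marker(marker)
        for i, name in enumerate(self.markers):
            if name == target:
                return i
        raise KeyError(f"marker {marker!r} not in panel {self.markers}")

    def require(self, markers=REQUIRED_MARKERS) -> None:
        missing = [m for m in markers if canonical_marker(m) not in self.markers]
        if missing:
            raise FormatError(f"panel lacks required markers {missing}; has {self.markers}")

    @classmethod
    def from_csv(cls, path) -> "MarkerPanel":
        df = pd.read_csv(path)
        for col in ("channel", "marker"):
            if col not in df.columns:
                raise FormatError(f"panel CSV {path} lacks column {col!r}")
        return cls(tuple(zip(df["channel"].astype(int), df["marker"].astype(str))))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"channel": [i for i, _ in self.entries], "marker": self.markers}
        ).to_csv(path, index=False)


@dataclass
class MarkerImage:
    """One sample's multichannel intensity raster (channel x row x col)."""

    pixels: np.ndarray
    panel: MarkerPanel
    pixel_size_um: float = 1.0
    sample_id: str = "sample"
    grade: str = "control"
    is_case: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise FormatError(f"pixels must be 3-D (channel,row,col), got {self.pixels.ndim}-D")
        if self.pixels.shape[0] != len(self.panel):
            raise FormatError(
                f"channel count mismatch: panel has {len(self.panel)} markers, "
                f"image has {self.pixels.shape[0]} channels"
            )
        if self.pixels.size == 0:
            raise FormatError("image has zero-sized pixel array")
        if not np.isfinite(self.pixels).all() or (self.pixels < 0).any():
            raise FormatError("intensities must be finite and non-negative")
        if not self.pixel_size_um > 0:
            raise ConfigurationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.grade not in ALLOWED_GRADES:
            raise FormatError(f"grade {self.grade!r} not in allowed labels {ALLOWED_GRADES}")

    @property
    def shape(self):
        return self.pixels.shape

    def channel(self, marker: str) -> np.ndarray:
        """2-D view of one marker's channel."""
        return self.pixels[self.panel.channel_of(marker)]


@dataclass
class Cohort:
    images: list
    metadata_source: str = ""

    def __post_init__(self) -> None:
        ids = [im.sample_id for im in self.images]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample_id in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)


# ---------------------------------------------------------------------------
# image stacks


def write_image_stack(image: MarkerImage, path) -> None:
    """Write a MarkerImage as a multipage TIFF, one page per channel.

    Sample metadata and the pixel size travel in the TIFF image description
    as JSON, so write/read round-trips are lossless. Integer-valued data are
    stored as uint16 when they fit, keeping round-trips bit-exact.
    """
    path = Path(path)
    px = image.pixels
    if np.all(px == np.round(px)) and px.max(initial=0) < 2**16:
        data = px.astype(np.uint16)
    else:
        data = px.astype(np.float32)
    desc = json.dumps(
        {
            "pixel_size_um": image.pixel_size_um,
            "sample_id": image.sample_id,
            "grade": image.grade,
            "is_case": bool(image.is_case),
            "markers": list(image.panel.markers),
        }
    )
    try:
        tifffile.imwrite(path, data, photometric="minisblack", description=desc, metadata=None)
    except OSError as exc:  # pragma: no cover - disk-dependent
        raise OSError(f"failed writing image stack to {path}: {exc}") from exc


def _pixel_size_from_ome(xml_text: str):
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None
    for elem in root.iter():
        size = elem.attrib.get("PhysicalSizeX")
        if size is not None:
            return float(size)
    return None


def read_image_stack(
    path,
    panel: MarkerPanel,
    pixel_size_um: float | None = None,
    sample_id: str | None = None,
    grade: str | None = None,
    is_case: bool | None = None,
) -> MarkerImage:
    """Read a multipage TIFF into a MarkerImage, channels ordered per panel.

    Metadata precedence: values embedded in the file (JSON description or
    OME ``PhysicalSizeX``) win over the keyword arguments, which in turn are
    required when the file carries nothing.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = len(tif.pages)
        if pages != len(panel):
            raise FormatError(
                f"{path}: expected {len(panel)} channels (panel) but found {pages} pages"
            )
        arr = tif.asarray()
        meta = {}
        desc = tif.pages[0].description
        if desc:
            try:
                parsed = json.loads(desc)
                if isinstance(parsed, dict):
                    meta = parsed
            except json.JSONDecodeError:
                pass
        if "pixel_size_um" not in meta and tif.ome_metadata:
            size = _pixel_size_from_ome(tif.ome_metadata)
            if size is not None:
                meta["pixel_size_um"] = size
    if arr.ndim == 2:
        arr = arr[None, ...]
    size = meta.get("pixel_size_um", pixel_size_um)
    if size is None:
        raise ConfigurationError(
            f"{path}: no pixel size in image metadata; pass pixel_size_um explicitly"
        )
    # The sidecar cohort table is authoritative for labels; embedded values
    # only fill gaps. Pixel size goes the other way (file metadata wins).
    if sample_id is None:
        sample_id = meta.get("sample_id", path.stem)
    if grade is None:
        grade = meta.get("grade", "control")
    if is_case is None:
        is_case = bool(meta.get("is_case", False))
    return MarkerImage(
        pixels=np.asarray(arr, dtype=np.float64),
        panel=panel,
        pixel_size_um=float(size),
        sample_id=str(sample_id),
        grade=str(grade),
        is_case=bool(is_case),
    )


# ---------------------------------------------------------------------------
# cohorts


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise FormatError(f"cannot parse boolean from {value!r}")


def read_cohort(image_dir, panel_path, metadata_path, pixel_size_um: float = 1.0) -> Cohort:
    """Load a labeled cohort from an image directory plus panel/metadata CSVs."""
    image_dir = Path(image_dir)
    panel = MarkerPanel.from_csv(panel_path)
    panel.require()
    meta = pd.read_csv(metadata_path)
    required = {"sample_id", "file", "grade", "is_case"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"metadata {metadata_path} lacks columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"].unique())
        raise FormatError(f"duplicate sample_id in metadata: {dupes}")
    bad = sorted(set(meta["grade"].astype(str)) - set(ALLOWED_GRADES))
    if bad:
        raise FormatError(f"unknown grade labels {bad}; allowed: {list(ALLOWED_GRADES)}")
    images = []
    for row in meta.itertuples(index=False):
        fpath = image_dir / str(row.file)
        if not fpath.exists():
            raise FormatError(f"image file listed in metadata not found: {fpath}")
        images.append(
            read_image_stack(
                fpath,
                panel,
                pixel_size_um=pixel_size_um,
                sample_id=str(row.sample_id),
                grade=str(row.grade),
                is_case=_parse_bool(row.is_case),
            )
        )
    return Cohort(images=images, metadata_source=str(metadata_path))


def write_cohort(cohort: Cohort, out_dir) -> pd.DataFrame:
    """Write every image plus panel.csv / metadata.csv; returns the metadata table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for image in cohort:
        fname = f"{image.sample_id}.tiff"
        write_image_stack(image, out_dir / fname)
        rows.append(
            {
                "sample_id": image.sample_id,
                "file": fname,
                "grade": image.grade,
                "is_case": bool(image.is_case),
            }
        )
    meta = pd.DataFrame(rows)
    meta.to_csv(out_dir / "metadata.csv", index=False)
    if len(cohort.images) > 0:
        cohort.images[0].panel.to_csv(out_dir / "panel.csv")
    return meta
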