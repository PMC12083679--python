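"""Patch extraction, percentile scaling, and QC flagging.

Instead of segmenting cells, marker intensity is quantified on a fixed grid
of square tissue tiles ("patches", 50 um by default) — the appropriate unit
for secreted, extracellular proteins like Shh and TGF-β. Per sample and per
marker, patch means are then divided by the 99th percentile of that sample's
patch means, so intensities are comparable across channels and acquisitions.
Patches that exceed their own reference (hot-pixel artifacts) or that carry
essentially no DNA signal (no tissue) are flagged and excluded from analysis.

Coordinate conventions: row-major, origin top-left, 0-based grid indices,
half-open tile intervals; incomplete edge tiles are dropped so every patch
covers the same area. Percentiles use numpy's default linear interpolation
between order statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, StateError
from .io import Cohort, MarkerImage, REQUIRED_MARKERS, canonical_marker

log = logging.getLogger(__name__)

FLAG_OUTLIER = "outlier"
FLAG_LOW_SIGNAL = "low_signal"


@dataclass
class PatchTable:
    """Per-patch, per-marker intensities for one or more samples.

    ``df`` columns: sample_id, grade, is_case, patch_row, patch_col,
    ``raw_<marker>`` for every marker, ``scaled_<marker>`` once scaled,
    ``qc_flags`` (semicolon-joined), and ``group`` once split.
    """

    df: pd.DataFrame
    patch_size_um: float
    markers: tuple[str, ...]
    percentile: float | None = None
    scaling_refs: pd.DataFrame | None = None  # sample_id, marker, reference

    @property
    def is_scaled(self) -> bool:
        return self.percentile is not None

    def __len__(self) -> int:
        return len(self.df)

    def raw(self, marker: str) -> pd.Series:
        return self.df[f"raw_{canonical_marker(marker)}"]

    def scaled(self, marker: str) -> pd.Series:
        if not self.is_scaled:
            raise StateError("table has no scaled values; call scale_patches first")
        return self.df[f"scaled_{canonical_marker(marker)}"]

    def to_csv(self, path, refs_path=None) -> None:
        self.df.to_csv(path, index=False)
        if refs_path is not None and self.scaling_refs is not None:
            self.scaling_refs.to_csv(refs_path, index=False)

    @classmethod
    def from_csv(cls, path, patch_size_um: float, refs_path=None) -> "PatchTable":
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
        markers = tuple(c[len("raw_"):] for c in df.columns if c.startswith("raw_"))
        refs = pd.read_csv(refs_path) if refs_path is not None else None
        percentile = None
        if any(c.startswith("scaled_") for c in df.columns):
            percentile = 99.0 if refs is None or "percentile" not in refs else float(refs["percentile"].iloc[0])
        df["qc_flags"] = df.get("qc_flags", "").astype(str)
        return cls(df=df, patch_size_um=patch_size_um, markers=markers,
                   percentile=percentile, scaling_refs=refs)


def _empty_df(markers) -> pd.DataFrame:
    cols = ["sample_id", "grade", "is_case", "patch_row", "patch_col"]
    cols += [f"raw_{m}" for m in markers] + ["qc_flags"]
    return pd.DataFrame({c: [] for c in cols})


def extract_patches(image: MarkerImage, patch_size_um: float = 50.0) -> PatchTable:
    """Tile one image into non-overlapping square patches of raw channel means.

    The patch side in pixels is ``round(patch_size_um / pixel_size_um)``; the
    grid is anchored at (0,0) and incomplete edge tiles are dropped, so the
    patch count is ``floor(rows/p) * floor(cols/p)``.
    """
    p = int(round(patch_size_um / image.pixel_size_um))
    if p < 1:
        raise ConfigurationError(
            f"patch_size_um={patch_size_um} is below one pixel at "
            f"{image.pixel_size_um} um/px"
        )
    markers = image.panel.markers
    n_ch, rows, cols = image.pixels.shape
    n_r, n_c = rows // p, cols // p
    if n_r == 0 or n_c == 0:
        log.warning(
            "patch side %d px exceeds image %s (%dx%d); returning empty table",
            p, image.sample_id, rows, cols,
        )
        return PatchTable(df=_empty_df(markers), patch_size_um=patch_size_um, markers=markers)
    tiles = image.pixels[:, : n_r * p, : n_c * p].reshape(n_ch, n_r, p, n_c, p)
    means = tiles.mean(axis=(2, 4))  # (channel, patch_row, patch_col)
    grid_r, grid_c = np.meshgrid(np.arange(n_r), np.arange(n_c), indexing="ij")
    data = {
        "sample_id": image.sample_id,
        "grade": image.grade,
        "is_case": bool(image.is_case),
        "patch_row": grid_r.ravel(),
        "patch_col": grid_c.ravel(),
    }
    for i, m in enumerate(markers):
        data[f"raw_{m}"] = means[i].ravel()
    df = pd.DataFrame(data)
    df["qc_flags"] = ""
    return PatchTable(df=df, patch_size_um=patch_size_um, markers=markers)


def extract_cohort_patches(cohort: Cohort, patch_size_um: float = 50.0) -> PatchTable:
    """Concatenate per-image patch tables over a cohort."""
    tables = [extract_patches(im, patch_size_um) for im in cohort]
    markers = tables[0].markers
    df = pd.concat([t.df for t in tables], ignore_index=True)
    return PatchTable(df=df, patch_size_um=patch_size_um, markers=markers)


def scale_patches(
    table: PatchTable,
    markers=REQUIRED_MARKERS,
    percentile: float = 99.0,
    pooled: bool = False,
) -> PatchTable:
    """Divide each marker's patch means by a percentile reference.

    The reference is the ``percentile``-th percentile (linear interpolation)
    of the patch raw means, computed per sample per marker by default —
    correcting acquisition/staining intensity differences between samples —
    or over the pooled cohort when ``pooled=True``. A zero reference maps the
    whole (sample, marker) to 0 with a logged warning.
    """
    if not 0 < percentile <= 100:
        raise ConfigurationError(f"percentile must be in (0, 100], got {percentile}")
    markers = [canonical_marker(m) for m in markers]
    unknown = [m for m in markers if m not in table.markers]
    if unknown:
        raise ConfigurationError(f"unknown markers {unknown}; table has {table.markers}")
    df = table.df.copy()
    refs = []
    for m in markers:
        raw = df[f"raw_{m}"].to_numpy(dtype=float)
        scaled = np.zeros_like(raw)
        if pooled:
            groups = {"__cohort__": np.ones(len(df), dtype=bool)}
        else:
            groups = {s: (df["sample_id"] == s).to_numpy() for s in df["sample_id"].unique()}
        for sample, sel in groups.items():
            ref = float(np.percentile(raw[sel], percentile)) if sel.any() else 0.0
            if ref == 0.0:
                log.warning("zero %gth-percentile reference for sample=%s marker=%s; "
                            "scaled values set to 0", percentile, sample, m)
                scaled[sel] = 0.0
            else:
                scaled[sel] = raw[sel] / ref
            refs.append({"sample_id": sample, "marker": m, "reference": ref,
                         "percentile": percentile})
        df[f"scaled_{m}"] = scaled
    return PatchTable(
        df=df,
        patch_size_um=table.patch_size_um,
        markers=table.markers,
        percentile=percentile,
        scaling_refs=pd.DataFrame(refs),
    )


def _add_flag(df: pd.DataFrame, where, flag: str) -> None:
    def merge(existing: str) -> str:
        parts = set(filter(None, existing.split(";")))
        parts.add(flag)
        return ";".join(sorted(parts))

    df.loc[where, "qc_flags"] = df.loc[where, "qc_flags"].map(merge)


def flag_outliers(table: PatchTable, markers=None) -> PatchTable:
    """Flag patches whose scaled value exceeds 1.0 in any named marker.

    A scaled value above 1 means the patch exceeded its own sample's
    percentile reference — by construction roughly the top 1% per marker at
    the default 99th percentile, which is where hot-pixel patches land.
    The boundary (scaled == 1.0) is not flagged.
    """
    if not table.is_scaled:
        raise StateError("flag_outliers requires a scaled table")
    markers = [canonical_marker(m) for m in (markers or table.markers)]
    df = table.df.copy()
    exceeds = np.zeros(len(df), dtype=bool)
    for m in markers:
        exceeds |= (df[f"scaled_{m}"] > 1.0).to_numpy()
    _add_flag(df, exceeds, FLAG_OUTLIER)
    return replace(table, df=df)


def flag_low_signal(table: PatchTable, dna_threshold: float = 0.05) -> PatchTable:
    """Flag patches with scaled DNA below ``dna_threshold`` (no tissue)."""
    if not 0.0 <= dna_threshold <= 1.0:
        raise ConfigurationError(f"dna_threshold must be in [0,1], got {dna_threshold}")
    if not table.is_scaled:
        raise StateError("flag_low_signal requires a scaled table")
    df = table.df.copy()
    low = (df["scaled_DNA"] < dna_threshold).to_numpy()
    _add_flag(df, low, FLAG_LOW_SIGNAL)
    return replace(table, df=df)


def analysis_view(table: PatchTable):
    """QC-passing records only; returns ``(view, removed_counts)``.

    ``removed_counts`` maps each flag to the number of records carrying it
    (a record with both flags counts under both) plus ``"total_removed"``.
    """
    flags = table.df["qc_flags"].astype(str)
    keep = flags == ""
    counts = {
        FLAG_OUTLIER: int(flags.str.contains(FLAG_OUTLIER).sum()),
        FLAG_LOW_SIGNAL: int(flags.str.contains(FLAG_LOW_SIGNAL).sum()),
        "total_removed": int((~keep).sum()),
    }
    if counts["total_removed"]:
        log.info("QC removed %d/%d patches (%s)", counts["total_removed"], len(table.df),
                 {k: v for k, v in counts.items() if k != "total_removed"})
    if keep.sum() == 0:
        log.warning("all %d patches removed by QC", len(table.df))
    view = replace(table, df=table.df.loc[keep].reset_index(drop=True))
    return view, counts
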