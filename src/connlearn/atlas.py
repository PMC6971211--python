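"""ROI atlas tables used to label connectome nodes.

Two parcellations are shipped as plain-text resources: the Harvard-Oxford
FSL-derived table restricted to 106 forebrain regions (cerebellum and vermis
excluded) and the Brainnetome (BN) table with 246 regions.  Each entry carries
the region name, its abbreviation and the MNI-space centroid in millimetres.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Tuple

import pandas as pd

ATLAS_SIZES = {"FSL": 106, "BN": 246}

_FILES = {"FSL": "fsl_atlas.tsv", "BN": "bn_atlas.tsv"}


class UnsupportedAtlasError(ValueError):
    """Raised when an unknown atlas name is requested."""


class ROINotFoundError(KeyError):
    """Raised when a label id is absent from an atlas."""


@dataclass(frozen=True)
class AtlasEntry:
    """One atlas region: integer label, names and MNI centroid."""

    label_id: int
    name: str
    abbreviation: str
    hemisphere: str  # "left" | "right" | "midline"
    mni_xyz: Tuple[int, int, int]


@dataclass(frozen=True)
class AtlasTable:
    """An ordered atlas: `entries` sorted by label_id, 1..n without gaps."""

    atlas_name: str
    entries: tuple

    @property
    def n_rois(self) -> int:
        return len(self.entries)

    def lookup(self, label_id: int) -> AtlasEntry:
        return roi_lookup(self, label_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label_id": [e.label_id for e in self.entries],
                "name": [e.name for e in self.entries],
                "abbreviation": [e.abbreviation for e in self.entries],
                "hemisphere": [e.hemisphere for e in self.entries],
                "x": [e.mni_xyz[0] for e in self.entries],
                "y": [e.mni_xyz[1] for e in self.entries],
                "z": [e.mni_xyz[2] for e in self.entries],
            }
        )


def _hemisphere(name: str, abbreviation: str) -> str:
    # Hemisphere is encoded only in the labels: "... Right"/"... Left" in the
    # name, "r"/"l" suffix in the abbreviation; everything else is midline.
    if name.endswith("Right") or abbreviation.endswith(" r"):
        return "right"
    if name.endswith("Left") or abbreviation.endswith(" l"):
        return "left"
    return "midline"


def load_atlas(atlas_name: str) -> AtlasTable:
    """Load a packaged atlas table ("FSL" or "BN").

    Returns the full table with one entry per ROI, ordered by label id.
    Raises :class:`UnsupportedAtlasError` for any other name.
    """
    if atlas_name not in _FILES:
        raise UnsupportedAtlasError(
            f"unsupported atlas {atlas_name!r}; choose one of {sorted(_FILES)}"
        )
    resource = importlib.resources.files("connlearn.data") / _FILES[atlas_name]
    with importlib.resources.as_file(resource) as path:
        df = _read_table(path)
    entries = tuple(
        AtlasEntry(
            label_id=int(row.label_id),
            name=row.name_,
            abbreviation=row.abbreviation,
            hemisphere=_hemisphere(row.name_, row.abbreviation),
            mni_xyz=(int(row.x), int(row.y), int(row.z)),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    )
    table = AtlasTable(atlas_name=atlas_name, entries=entries)
    expected = ATLAS_SIZES[atlas_name]
    if table.n_rois != expected:
        raise RuntimeError(
            f"packaged {atlas_name} table has {table.n_rois} rows, expected {expected}"
        )
    return table


def _read_table(path) -> pd.DataFrame:
    # Resources are TSV; external tables may be comma-delimited instead.
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 1:
        df = pd.read_csv(path, sep=",")
    required = {"label_id", "name", "abbreviation", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"atlas table missing columns: {sorted(missing)}")
    return df.sort_values("label_id").reset_index(drop=True)


def roi_lookup(atlas: AtlasTable, label_id: int) -> AtlasEntry:
    """Return the entry with the given label id, or raise :class:`ROINotFoundError`."""
    idx = label_id - 1
    if 0 <= idx < len(atlas.entries) and atlas.entries[idx].label_id == label_id:
        return atlas.entries[idx]
    for entry in atlas.entries:  # pragma: no cover - non-contiguous fallback
        if entry.label_id == label_id:
            return entry
    raise ROINotFoundError(f"label_id {label_id} not in atlas {atlas.atlas_name}")
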