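"""Dataset manifests: the ordered table of image records driving training.

A manifest row carries the image path, its mask path, the emitted (possibly
noisy) class label, the ground-truth label, patient and acquisition-site
identifiers, and an ``active`` flag that the pruning loop clears as samples
are removed.  Manifests are stored as plain CSV with paths relative to the
manifest's own directory.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import pandas as pd

from .errors import ManifestError

LABEL_NODULE = "nodule"
LABEL_NORMAL = "non-nodule"
VALID_LABELS = (LABEL_NODULE, LABEL_NORMAL)

#: columns written by generate_dataset and required by read_manifest
MANIFEST_COLUMNS = [
    "image_id",
    "image_path",
    "mask_path",
    "emitted_label",
    "true_label",
    "patient_id",
    "site_id",
    "mislabeled",
]


@dataclass
class Manifest:
    """Ordered table of image records plus an optional fold assignment."""

    df: pd.DataFrame
    root: Optional[Path] = None
    fold_assignment: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing required columns: {missing}")
        dupes = df["image_id"][df["image_id"].duplicated()]
        if len(dupes):
            raise ManifestError(
                f"duplicate image_id in manifest: {sorted(set(dupes))}"
            )
        bad = df.loc[~df["emitted_label"].isin(VALID_LABELS), "emitted_label"]
        if len(bad):
            raise ManifestError(f"invalid labels: {sorted(set(bad))}")
        if "active" not in df.columns:
            df["active"] = True
        df["active"] = df["active"].astype(bool)
        df["mislabeled"] = df["mislabeled"].astype(bool)
        df = df.reset_index(drop=True)
        self.df = df

    # -- accessors -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def image_ids(self) -> List[str]:
        return list(self.df["image_id"])

    def active_df(self) -> pd.DataFrame:
        return self.df[self.df["active"]]

    def labels(self) -> Dict[str, str]:
        return dict(zip(self.df["image_id"], self.df["emitted_label"]))

    def class_counts(self, active_only: bool = True) -> Dict[str, int]:
        df = self.active_df() if active_only else self.df
        counts = df["emitted_label"].value_counts().to_dict()
        return {lab: int(counts.get(lab, 0)) for lab in VALID_LABELS}

    def active_ids(self, label: Optional[str] = None) -> List[str]:
        df = self.active_df()
        if label is not None:
            df = df[df["emitted_label"] == label]
        return list(df["image_id"])

    def resolve_path(self, rel: str) -> Path:
        p = Path(rel)
        if self.root is not None and not p.is_absolute():
            p = Path(self.root) / p
        return p

    # -- mutation --------------------------------------------------------
    def deactivate(self, image_id: str) -> None:
        idx = self.df.index[self.df["image_id"] == image_id]
        if len(idx) == 0:
            raise ManifestError(f"unknown image_id: {image_id}")
        self.df.loc[idx, "active"] = False

    def drop_ids(self, ids: Iterable[str]) -> None:
        ids = set(ids)
        self.df = self.df[~self.df["image_id"].isin(ids)].reset_index(drop=True)

    def copy(self) -> "Manifest":
        return Manifest(
            self.df.copy(),
            root=self.root,
            fold_assignment=dict(self.fold_assignment)
            if self.fold_assignment
            else None,
        )

    # -- I/O -------------------------------------------------------------
    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.df[MANIFEST_COLUMNS].to_csv(path, index=False)
        return path


def read_manifest(path, check_files: bool = True) -> Manifest:
    """Read and validate a CSV manifest.

    Paths in the manifest are interpreted relative to the manifest's own
    directory.  Raises :class:`ManifestError` on missing columns, duplicate
    image ids, or (when ``check_files`` is true) missing image files.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"image_id": str, "patient_id": str})
    manifest = Manifest(df, root=path.parent)
    if check_files:
        missing = [
            str(rel)
            for rel in manifest.df["image_path"]
            if rel and not manifest.resolve_path(rel).exists()
        ]
        if missing:
            raise ManifestError(f"missing image files: {missing[:5]}")
    return manifest
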