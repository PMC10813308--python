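"""Dataset manifest I/O: CSV with header
``id,path,concentration_ng_per_ml,split,seed``."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .speckle_sim import SPLIT_NAMES

__all__ = ["read_manifest", "write_manifest", "validate_manifest", "ManifestError"]

MANIFEST_COLUMNS = ["id", "path", "concentration_ng_per_ml", "split", "seed"]


class ManifestError(ValueError):
    pass


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest missing columns {missing}")
    bad = set(manifest["split"]) - set(SPLIT_NAMES)
    if bad:
        raise ManifestError(
            f"unknown split tag(s) {sorted(bad)}; expected one of {SPLIT_NAMES}"
        )
    if manifest["id"].duplicated().any():
        dupes = manifest.loc[manifest["id"].duplicated(), "id"].tolist()
        raise ManifestError(f"duplicate identifiers {dupes[:5]}")
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "path": str, "split": str})
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(manifest)
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS)
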