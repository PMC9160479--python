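"""Delimited-text readers/writers, configs and run manifests.

Everything on disk is plain text: feature blocks and outcome tables as TSV
(first column = substance id, header = feature names; delimiter sniffed
from the extension), raw scatter events as ``fsc,ssc`` CSV, configuration
and manifests as YAML.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import BLOCK_NAMES, FeatureBlock

__all__ = [
    "read_block",
    "write_block",
    "read_table",
    "write_table",
    "read_events",
    "write_events",
    "read_config",
    "write_config",
    "RunManifest",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path) -> pd.DataFrame:
    """Substances x columns table; first column is the substance id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate substance ids {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        raise ValueError(f"{path}: missing values present")
    return numeric


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "substance") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index_label=index_label)


def read_block(path: str | Path, name: str | None = None) -> FeatureBlock:
    """Load and validate one feature block from TSV/CSV."""
    path = Path(path)
    if name is None:
        stem = path.stem
        name = stem if stem in BLOCK_NAMES else None
        if name is None:
            raise ValueError(
                f"cannot infer block name from {path.name!r}; pass name= one of {BLOCK_NAMES}"
            )
    return FeatureBlock(name=name, data=read_table(path))


def write_block(block: FeatureBlock, path: str | Path) -> None:
    write_table(block.data, path)


def read_events(path: str | Path) -> pd.DataFrame:
    """Raw scatter events: CSV with ``fsc`` and ``ssc`` columns."""
    df = pd.read_csv(path)
    if not {"fsc", "ssc"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns fsc,ssc; got {list(df.columns)}")
    return df[["fsc", "ssc"]].astype(float)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events[["fsc", "ssc"]].to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline stage bit-identically."""

    version: str = __version__
    seed: int | None = None
    hyperparameters: dict = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def record_input(self, path: str | Path) -> None:
        path = Path(path)
        self.input_digests[path.name] = _digest(path)

    def write(self, path: str | Path) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        write_config(asdict(self), path)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        data = read_config(path)
        return cls(
            version=data.get("version", __version__),
            seed=data.get("seed"),
            hyperparameters=data.get("hyperparameters", {}),
            input_digests=data.get("input_digests", {}),
            timestamp=data.get("timestamp", ""),
        )
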