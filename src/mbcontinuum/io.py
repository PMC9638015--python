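"""Readers/writers, pipeline configuration and seed derivation.

Dense matrices travel as TSV/CSV (first column = feature id, header row
= sample ids, "NA" for missing); sparse single-cell counts as Matrix
Market MTX with sibling ``features.tsv`` / ``barcodes.tsv`` files; BED
regions are 0-based half-open.  Every table written by the pipeline
carries the configuration hash in a leading ``#`` comment line.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import yaml

from .core import LabeledMatrix, MatrixKind

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_mtx",
    "write_mtx",
    "read_bed",
    "read_table",
    "write_table",
    "PipelineConfig",
    "stage_seed",
    "get_logger",
]

log = logging.getLogger("mbcontinuum")


def get_logger(level: str = "INFO") -> logging.Logger:
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(level.upper())
    return log


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage substream seed (< 2^31) from the master seed.

    The stage name is hashed so adding a stage never shifts the streams
    of the others.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# dense matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, kind: str | MatrixKind = "expression") -> LabeledMatrix:
    """Read a matrix, auto-detecting the format from the extension.

    ``.tsv``/``.csv`` are dense (feature ids in the first column);
    ``.mtx`` is sparse with sibling ``features.tsv``/``barcodes.tsv``.
    Validation errors report the offending row/column ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".mtx":
        return read_mtx(path, kind=kind)
    sep = "\t" if path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#", na_values=["NA"])
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate feature ids: {dups[:10]}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValueError(f"duplicate sample ids: {dups[:10]}")
    bad_cols = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad_cols:
        col = bad_cols[0]
        bad_row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric cell at row {bad_row!r}, column {col!r}")
    values = df.to_numpy(dtype=float)
    kind = MatrixKind(kind)
    if kind is MatrixKind.beta:
        bad = np.argwhere((values < 0) | (values > 1) | ~np.isfinite(values))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"beta value {values[i, j]!r} outside [0,1] at "
                f"CpG {df.index[i]!r}, sample {df.columns[j]!r}"
            )
    return LabeledMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)), kind)


def write_matrix(
    m: LabeledMatrix, path: str | Path, config_hash: str | None = None
) -> None:
    """Write a dense matrix as TSV with an optional config-hash header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if config_hash:
            fh.write(f"# config={config_hash}\n")
        m.to_frame().to_csv(fh, sep="\t", na_rep="NA", lineterminator="\n")


# ---------------------------------------------------------------------------
# sparse matrices (MTX + features/barcodes)
# ---------------------------------------------------------------------------

def read_mtx(
    path: str | Path,
    features: str | Path | None = None,
    barcodes: str | Path | None = None,
    kind: str | MatrixKind = "counts",
) -> LabeledMatrix:
    path = Path(path)
    features = Path(features) if features else path.with_name("features.tsv")
    barcodes = Path(barcodes) if barcodes else path.with_name("barcodes.tsv")
    for p in (path, features, barcodes):
        if not p.exists():
            raise FileNotFoundError(p)
    values = sio.mmread(path).tocsr()
    row_ids = features.read_text().split()
    col_ids = barcodes.read_text().split()
    return LabeledMatrix(values, row_ids, col_ids, MatrixKind(kind))


def write_mtx(m: LabeledMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = m.values if sp.issparse(m.values) else sp.csr_matrix(m.values)
    sio.mmwrite(str(path), values)
    path.with_name("features.tsv").write_text("\n".join(m.row_ids) + "\n")
    path.with_name("barcodes.tsv").write_text("\n".join(m.col_ids) + "\n")


# ---------------------------------------------------------------------------
# annotation tables, BED
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix != ".csv" else ","
    return pd.read_csv(path, sep=sep, comment="#", na_values=["NA"])


def write_table(
    df: pd.DataFrame, path: str | Path, config_hash: str | None = None, index: bool = False
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if config_hash:
            fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index=index, lineterminator="\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3+1-column BED file (0-based half-open intervals)."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
        name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
        rows.append(
            {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2]), "name": name}
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

_KNOWN_STAGES = (
    "simulate", "classify", "score", "methyl", "switchpoints", "sc", "associate",
)
_KNOWN_TOP = {"seed", "out_dir", "log_level", "stages"} | set(_KNOWN_STAGES)


@dataclass
class PipelineConfig:
    """Validated YAML pipeline configuration.

    Top-level keys: ``seed`` (master seed), ``out_dir``, ``log_level``,
    ``stages`` (ordered list of enabled stage names) and one optional
    mapping per stage with that stage's parameters.  Unknown keys are
    rejected.  ``config_hash`` (first 12 hex digits of the SHA-256 of
    the canonical YAML dump) is stamped into every output file.
    """

    seed: int = 0
    out_dir: str = "mbcontinuum_out"
    log_level: str = "INFO"
    stages: list[str] = field(default_factory=lambda: list(_KNOWN_STAGES))
    stage_params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        unknown = [s for s in self.stage_params if s not in _KNOWN_STAGES]
        if unknown:
            raise ValueError(f"parameters for unknown stages: {unknown}")

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        unknown = sorted(set(data) - _KNOWN_TOP)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        stage_params = {s: dict(data[s]) for s in _KNOWN_STAGES if s in data}
        return cls(
            seed=int(data.get("seed", 0)),
            out_dir=str(data.get("out_dir", "mbcontinuum_out")),
            log_level=str(data.get("log_level", "INFO")),
            stages=list(data.get("stages", list(_KNOWN_STAGES))),
            stage_params=stage_params,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("pipeline config must be a mapping")
        return cls.from_mapping(data)

    def to_mapping(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "stages": list(self.stages),
        }
        for s, params in sorted(self.stage_params.items()):
            out[s] = params
        return out

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (seed, stages, stage params).

        Paths and log level are excluded so reruns into different
        directories stamp identical hashes.
        """
        mapping = self.to_mapping()
        mapping.pop("out_dir", None)
        mapping.pop("log_level", None)
        buf = _io.StringIO()
        yaml.safe_dump(mapping, buf, sort_keys=True)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:12]
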