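"""File formats and configuration.

Everything on disk is plain text: atlas annotation and result tables are
tab-separated with a header row, ROI time series are headerless numeric TSV
(rows = time points, columns = ROIs in atlas order), connectivity matrices
round-trip as TSV with a ``roi_id`` header row/column plus a JSON sidecar
carrying the processing stage, and gene sets use the GMT convention
(set name, description, then gene symbols, tab-separated, one set per line).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical functional community labels: the seven Yeo networks plus a
#: subcortical catch-all for cerebellar/striatal/thalamic ROIs.
COMMUNITIES = ("Vis", "SM", "DA", "VA", "Lim", "FP", "DMN", "Subcortical")

HEMISPHERES = ("L", "R", "NA")

ATLAS_COLUMNS = ("roi_id", "roi_name", "community", "hemisphere", "x", "y", "z")


@dataclass(frozen=True)
class Atlas:
    """ROI annotation table: the frame every regional map lives on.

    ``table`` rows are the canonical ROI order for every matrix and
    embedding in the pipeline; ``roi_id`` is 1-based and contiguous.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ATLAS_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"atlas table is missing columns: {missing}")
        if len(t) < 3:
            raise ValueError(f"atlas needs at least 3 ROIs, got {len(t)}")
        ids = t["roi_id"].to_numpy()
        dup = pd.Series(ids)[pd.Series(ids).duplicated()]
        if len(dup):
            raise ValueError(f"duplicate roi_id values: {sorted(set(dup))}")
        if not np.array_equal(np.sort(ids), np.arange(1, len(t) + 1)):
            raise ValueError("roi_id must be contiguous 1..N")
        bad = t.loc[~t["community"].isin(COMMUNITIES)]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"unknown community {row['community']!r} at roi_id {row['roi_id']}; "
                f"allowed labels: {list(COMMUNITIES)}"
            )
        bad_h = t.loc[~t["hemisphere"].isin(HEMISPHERES)]
        if len(bad_h):
            raise ValueError(
                f"unknown hemisphere {bad_h.iloc[0]['hemisphere']!r}; allowed: {list(HEMISPHERES)}"
            )

    @property
    def n_roi(self) -> int:
        return len(self.table)

    @property
    def roi_ids(self) -> np.ndarray:
        return self.table["roi_id"].to_numpy()

    @property
    def communities(self) -> np.ndarray:
        return self.table["community"].to_numpy()

    def index_of(self, roi_id: int) -> int:
        """0-based row index of a roi_id."""
        idx = np.flatnonzero(self.roi_ids == roi_id)
        if idx.size == 0:
            raise KeyError(f"roi_id {roi_id} not in atlas")
        return int(idx[0])


def read_atlas(path: str | Path) -> Atlas:
    """Load and validate an ROI annotation table (TSV or CSV, header row).

    Row order is preserved and becomes the ROI order of all downstream
    matrices. Duplicated roi_id or an unrecognised community label is a
    hard error naming the offending row.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep)
    table.columns = [str(c).strip() for c in table.columns]
    atlas = Atlas(table.reset_index(drop=True))
    # roi order = file row order; verify ids are sorted so the two agree
    if not np.array_equal(atlas.roi_ids, np.arange(1, atlas.n_roi + 1)):
        raise ValueError("atlas rows must be sorted by roi_id (1..N)")
    return atlas


def write_atlas(atlas: Atlas, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path, atlas: Atlas) -> np.ndarray:
    """Load a T×N ROI time-series matrix (headerless numeric TSV).

    Columns must match the atlas ROI count and order; any non-numeric or
    missing cell is an error citing its row and column.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] != atlas.n_roi:
        raise ValueError(
            f"time series has {df.shape[1]} columns but atlas has {atlas.n_roi} ROIs"
        )
    if df.shape[0] < 8:
        raise ValueError(f"time series has only {df.shape[0]} time points (need >= 8)")
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric or missing value at row {r + 1}, column {c + 1} of {path}"
        )
    return arr


def write_timeseries(ts: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(ts, dtype=float), delimiter="\t", fmt="%.10g")


def write_matrix(values: np.ndarray, atlas: Atlas, path: str | Path,
                 meta: dict | None = None) -> None:
    """Write an N×N matrix as TSV with roi_id header row/column.

    ``meta`` (stage tag, threshold fraction, ...) goes to a ``.json``
    sidecar next to the matrix.
    """
    path = Path(path)
    df = pd.DataFrame(values, index=atlas.roi_ids, columns=atlas.roi_ids)
    df.to_csv(path, sep="\t", index_label="roi_id")
    if meta is not None:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_matrix(path: str | Path, atlas: Atlas | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if atlas is not None and values.shape != (atlas.n_roi, atlas.n_roi):
        raise ValueError(f"matrix shape {values.shape} does not match atlas N={atlas.n_roi}")
    return values


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(path: str | Path, atlas: Atlas | None = None) -> pd.DataFrame:
    """Genes × ROI expression TSV; first column = gene symbol."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if atlas is not None and df.shape[1] != atlas.n_roi:
        raise ValueError(
            f"expression has {df.shape[1]} ROI columns but atlas has {atlas.n_roi}"
        )
    return df


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with the defaults used throughout.

    threshold_fraction
        Row-wise proportion of strongest connections kept before the
        affinity step (0.10 = "top 10%" convention; robustness range
        0.10-0.20).
    n_components
        Number of gradient components computed and aligned; primary
        analyses use ``primary_dims`` (1-based) of these.
    fdr_alpha
        Benjamini-Hochberg significance level for all regional families.
    alpha_enter / alpha_remove
        Partial-F entry/removal p thresholds of the stepwise regression.
    n_permutations
        Permutation count for PLS significance and gene-set enrichment.
    """

    threshold_fraction: float = 0.10
    n_components: int = 10
    primary_dims: tuple[int, int] = (1, 2)
    fdr_alpha: float = 0.05
    alpha_enter: float = 0.05
    alpha_remove: float = 0.05
    n_permutations: int = 1000
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.threshold_fraction <= 1):
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        self.primary_dims = tuple(self.primary_dims)  # type: ignore[assignment]
        if len(self.primary_dims) != 2 or not all(
            1 <= d <= self.n_components for d in self.primary_dims
        ):
            raise ValueError("primary_dims must be a pair within 1..n_components")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        for name in ("fdr_alpha", "alpha_enter", "alpha_remove"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["primary_dims"] = list(self.primary_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text) or {}
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        if "primary_dims" in d:
            d["primary_dims"] = tuple(d["primary_dims"])
        return cls.from_dict(d)

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration; stamped onto
        every output so tables from different configs cannot be mixed
        silently."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
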