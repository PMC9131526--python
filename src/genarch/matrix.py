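"""The windows × features matrix: merging tracks, min-max scaling, window
coarsening and TSV/bedgraph interchange.

Scaling maps every feature column to [0, 1] with min-max scaling (the
convention the clustering step expects); constant columns map to all-0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .seqfeats import FeatureTrack
from .windows import WindowGrid


@dataclass
class FeatureMatrix:
    """Windows × features table with raw and min-max-scaled views."""

    grid: WindowGrid
    raw: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if len(self.raw) != len(self.grid):
            raise ValueError(
                f"matrix has {len(self.raw)} rows but grid has "
                f"{len(self.grid)} windows"
            )
        if self.raw.columns.duplicated().any():
            dupes = self.raw.columns[self.raw.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        if not np.all(np.isfinite(self.raw.to_numpy())):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def scaled(self) -> pd.DataFrame:
        """Min-max-scaled view in [0,1]; constant columns become all-0."""
        scaler = MinMaxScaler()
        vals = scaler.fit_transform(self.raw.to_numpy())
        vals = np.clip(vals, 0.0, 1.0)  # guard 1 + 2e-16 rounding artefacts
        return pd.DataFrame(vals, columns=self.raw.columns, index=self.raw.index)

    def select(
        self,
        include: Sequence[str] | None = None,
        exclude: Sequence[str] | None = None,
    ) -> "FeatureMatrix":
        """Restrict to an explicit feature list (include before exclude)."""
        cols = list(self.raw.columns)
        if include is not None:
            missing = set(include) - set(cols)
            if missing:
                raise KeyError(f"unknown features: {sorted(missing)}")
            cols = [c for c in cols if c in set(include)]
        if exclude is not None:
            cols = [c for c in cols if c not in set(exclude)]
        return FeatureMatrix(self.grid, self.raw[cols].copy())

    # -- interchange --------------------------------------------------------

    def to_tsv(self, path, header_comments: Sequence[str] = ()) -> None:
        """Write scaffold/start/end plus raw feature columns, full precision."""
        df = self.grid.to_dataframe()
        out = pd.concat([df, self.raw.reset_index(drop=True)], axis=1)
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            out.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        try:
            df = pd.read_csv(
                path, sep="\t", comment="#", dtype={"scaffold": str},
                float_precision="round_trip",
            )
        except Exception as exc:  # pragma: no cover - pandas names the line
            raise ValueError(f"{path}: malformed TSV ({exc})") from exc
        for col in ("scaffold", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        if df.isna().any().any():
            bad = int(df.isna().any(axis=1).idxmax()) + 2
            raise ValueError(f"{path}: malformed row near line {bad}")
        grid = _grid_from_intervals(df)
        raw = df.drop(columns=["scaffold", "start", "end"])
        return cls(grid, raw)

    def write_bedgraphs(self, outdir) -> list[str]:
        """One bedgraph per feature, window order, 0-based half-open."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        coords = self.grid.to_dataframe()
        paths = []
        for name in self.raw.columns:
            p = outdir / f"{name}.bedgraph"
            with open(p, "w") as fh:
                fh.write(f'track type=bedGraph name="{name}"\n')
                block = coords.copy()
                block["value"] = self.raw[name].to_numpy()
                block.to_csv(fh, sep="\t", index=False, header=False,
                             float_format="%.17g")
            paths.append(str(p))
        return paths


def _grid_from_intervals(df: pd.DataFrame) -> WindowGrid:
    """Rebuild a WindowGrid from scaffold/start/end rows in window order."""
    window_size = int((df["end"] - df["start"]).max())
    ids: list[str] = []
    lengths: dict[str, int] = {}
    for scaf, sub in df.groupby("scaffold", sort=False):
        ids.append(scaf)
        lengths[scaf] = int(sub["end"].max())
    sindex = {s: i for i, s in enumerate(ids)}
    return WindowGrid(
        window_size=window_size,
        scaffold_ids=ids,
        scaffold_lengths=lengths,
        scaffold=df["scaffold"].map(sindex).to_numpy(dtype=np.int64),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
    )


def merge_tracks(tracks: Sequence[FeatureTrack], grid: WindowGrid) -> FeatureMatrix:
    """Assemble named per-window tracks into a FeatureMatrix (input order)."""
    names = [t.name for t in tracks]
    if len(set(names)) != len(names):
        raise ValueError("duplicate track names")
    for t in tracks:
        if len(t.values) != len(grid):
            raise ValueError(
                f"track {t.name!r} has {len(t.values)} values for "
                f"{len(grid)} windows"
            )
    raw = pd.DataFrame({t.name: t.values for t in tracks})
    return FeatureMatrix(grid, raw)


def merge_windows(matrix: FeatureMatrix, factor: int) -> FeatureMatrix:
    """Merge consecutive same-scaffold windows in runs of ``factor``.

    Raw values are averaged with window-length weights (trailing short
    groups kept), which conserves length-weighted sums of additive
    features; the scaled view is recomputed on the coarse grid.
    """
    if factor < 2:
        raise ValueError(f"merge factor must be >= 2, got {factor}")
    grid = matrix.grid
    coarse = _coarse_grid(grid, factor)
    vals = matrix.raw.to_numpy()
    w = grid.lengths.astype(float)
    group = _group_index(grid, factor)
    nz = np.zeros((len(coarse), vals.shape[1]))
    wsum = np.zeros(len(coarse))
    np.add.at(nz, group, vals * w[:, None])
    np.add.at(wsum, group, w)
    out = nz / wsum[:, None]
    return FeatureMatrix(coarse, pd.DataFrame(out, columns=matrix.raw.columns))


def _group_index(grid: WindowGrid, factor: int) -> np.ndarray:
    group = np.empty(len(grid), dtype=np.int64)
    g = -1
    prev_scaf = None
    pos = 0
    for i in range(len(grid)):
        scaf = grid.scaffold[i]
        if scaf != prev_scaf:
            prev_scaf = scaf
            pos = 0
        if pos % factor == 0:
            g += 1
        group[i] = g
        pos += 1
    return group


def _coarse_grid(grid: WindowGrid, factor: int) -> WindowGrid:
    new_size = grid.window_size * factor
    scaffold_idx, starts, ends = [], [], []
    for i, sid in enumerate(grid.scaffold_ids):
        length = grid.scaffold_lengths[sid]
        s = np.arange(0, length, new_size, dtype=np.int64)
        e = np.minimum(s + new_size, length)
        scaffold_idx.append(np.full(len(s), i, dtype=np.int64))
        starts.append(s)
        ends.append(e)
    return WindowGrid(
        window_size=new_size,
        scaffold_ids=list(grid.scaffold_ids),
        scaffold_lengths=dict(grid.scaffold_lengths),
        scaffold=np.concatenate(scaffold_idx),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
    )
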