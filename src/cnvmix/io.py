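"""Track and results file formats plus run configuration.

Input tracks are tab-delimited text with a ``chrom  position  snp_id
log2ratio`` header, one row per SNP, 1-based positions.  Outputs are an
annotated track (calls plus the averaged class probabilities) and a
BED-like segment file (0-based half-open genomic coordinates).  Run
configuration files are flat ``key = value`` text.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import ChainResult, segment_calls

__all__ = [
    "TrackFormatError",
    "LogRatioTrack",
    "RunConfig",
    "read_track",
    "read_tracks",
    "write_track",
    "write_calls",
    "read_calls",
    "write_truth",
    "read_truth",
    "read_config",
    "write_config",
    "segments_path",
]

TRACK_COLUMNS = ("chrom", "position", "snp_id", "log2ratio")


class TrackFormatError(ValueError):
    """Malformed track file (missing columns, bad values, duplicates)."""


@dataclass
class LogRatioTrack:
    """Ordered per-chromosome log2-ratio track."""

    chrom: str
    positions: np.ndarray
    snp_ids: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        if not len(self.positions) == len(self.snp_ids) == len(self.y):
            raise TrackFormatError("track columns have unequal lengths")
        if not np.all(np.isfinite(self.y)):
            raise TrackFormatError("log2-ratios must be finite")
        if np.any(np.diff(self.positions) <= 0):
            raise TrackFormatError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom,
            "position": self.positions,
            "snp_id": self.snp_ids,
            "log2ratio": self.y,
        })


def _parse_track_frame(df: pd.DataFrame, path) -> list[LogRatioTrack]:
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    pos = pd.to_numeric(df["position"], errors="coerce")
    ratio = pd.to_numeric(df["log2ratio"], errors="coerce")
    for name, col in (("position", pos), ("log2ratio", ratio)):
        bad = col.index[col.isna() | ~np.isfinite(col.fillna(np.inf))]
        if len(bad):
            # +2: header line plus 1-based numbering.
            raise TrackFormatError(
                f"{path}: non-numeric {name} at line {int(bad[0]) + 2}")
    df = df.assign(position=pos.astype(np.int64), log2ratio=ratio.astype(float))
    tracks = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("position", kind="stable")
        dup = sub["position"].duplicated()
        if dup.any():
            line = int(sub.index[dup][0]) + 2
            raise TrackFormatError(f"{path}: duplicate position at line {line}")
        tracks.append(LogRatioTrack(
            chrom=str(chrom),
            positions=sub["position"].to_numpy(),
            snp_ids=sub["snp_id"].astype(str).to_numpy(),
            y=sub["log2ratio"].to_numpy(),
        ))
    if not tracks:
        raise TrackFormatError(f"{path}: empty track file")
    return tracks


def read_tracks(path) -> list[LogRatioTrack]:
    """Read a track file, splitting by chromosome; rows are sorted by
    position within each chromosome."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return _parse_track_frame(df, path)


def read_track(path) -> LogRatioTrack:
    """Read a single-chromosome track file."""
    tracks = read_tracks(path)
    if len(tracks) != 1:
        raise TrackFormatError(
            f"{path}: expected one chromosome, found {len(tracks)}; "
            "use read_tracks for multi-chromosome input")
    return tracks[0]


def write_track(path, track: LogRatioTrack) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False)


def segments_path(path) -> Path:
    """Companion segment-file path for a calls file."""
    p = Path(path)
    return p.with_name(p.stem + ".segments.bed")


def calls_frame(track: LogRatioTrack, result: ChainResult) -> pd.DataFrame:
    """Annotated track: calls (integer label; 6 stands for the ">5" class)
    plus one averaged probability column per class."""
    df = track.to_frame()
    df["cn_call"] = result.calls
    for j, cls in enumerate(result.classes):
        df[f"prob_cn{cls.label.replace('>', 'gt')}"] = result.omega_bar[:, j]
    return df


def segments_frame(track: LogRatioTrack, result: ChainResult) -> pd.DataFrame:
    """BED-like constant-call segments, 0-based half-open coordinates."""
    segs = segment_calls(result.calls, track.positions)
    return pd.DataFrame({
        "chrom": track.chrom,
        "start": [s.start_pos - 1 for s in segs],
        "end": [s.end_pos for s in segs],
        "cn_label": [s.cn_label for s in segs],
        "n_snps": [s.n_snps for s in segs],
    })


def write_calls(path, track: LogRatioTrack, result: ChainResult) -> None:
    """Write the annotated call track and its BED-like segment companion."""
    calls_frame(track, result).to_csv(path, sep="\t", index=False,
                                      float_format="%.6g")
    segments_frame(track, result).to_csv(segments_path(path), sep="\t",
                                         index=False, header=False)


def read_calls(path) -> tuple[LogRatioTrack, np.ndarray, pd.DataFrame]:
    """Read an annotated call track back: (track, calls, probability
    columns)."""
    df = pd.read_csv(path, sep="\t")
    tracks = _parse_track_frame(df[list(TRACK_COLUMNS)], path)
    if len(tracks) != 1:
        raise TrackFormatError(f"{path}: expected one chromosome")
    if "cn_call" not in df.columns:
        raise TrackFormatError(f"{path}: missing cn_call column")
    calls = df["cn_call"].to_numpy(dtype=np.int64)
    probs = df[[c for c in df.columns if c.startswith("prob_")]]
    return tracks[0], calls, probs


def write_truth(path, track: LogRatioTrack, truth: np.ndarray) -> None:
    pd.DataFrame({
        "chrom": track.chrom,
        "position": track.positions,
        "snp_id": track.snp_ids,
        "cn": np.asarray(truth, dtype=np.int64),
    }).to_csv(path, sep="\t", index=False)


def read_truth(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if "cn" not in df.columns:
        raise TrackFormatError(f"{path}: missing cn column")
    return df.sort_values("position", kind="stable")["cn"].to_numpy(dtype=np.int64)


@dataclass
class RunConfig:
    """Sampler run settings; every random draw descends from ``seed``."""

    n_burnin: int = 5000
    n_samples: int = 5000
    seed: int = 0
    phi: float = 0.01
    nb: int = 4
    k_max: int = 7
    poisson_mean: float = 2.0
    ig_shape: float = 2.1
    ig_scale: float = 0.22
    h_max: float = 1_000_000.0
    sigma_h0: float = 10.0
    adapt_every: int = 100
    contamination: float = 0.0
    background: float = 1.47

    def __post_init__(self) -> None:
        if self.n_burnin < 0 or self.n_samples < 1:
            raise ValueError("need n_burnin >= 0 and n_samples >= 1")


def read_config(path) -> RunConfig:
    """Parse a flat key = value configuration file (``#`` comments and
    blank lines ignored); values are typed from the RunConfig field types."""
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    types = {f.name: type(getattr(RunConfig(), f.name)) for f in dataclasses.fields(RunConfig)}
    values = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown setting {key!r}")
            try:
                values[key] = types[key](val.strip())
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: cannot parse {val.strip()!r} as "
                    f"{types[key].__name__} for {key}")
    return RunConfig(**values)


def write_config(path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(RunConfig):
            fh.write(f"{f.name} = {getattr(cfg, f.name)}\n")
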