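"""Transcript-space coordinate model and table I/O.

All coordinates are 0-based, half-open intervals in transcript space
(position 0 is the transcript 5' end).  A transcript model is its length and
CDS interval, which partitions it into UTR5 = [0, cds_start), CDS =
[cds_start, cds_end) and UTR3 = [cds_end, length).  A probe mapping places a
probe interval on one transcript and carries a relative location in [0, 1]
(0 = 5' end, 1 = 3' end) computed from the probe midpoint, plus that location
binned at step 0.02.

Tables are tab-separated UTF-8 with a header row; lines starting with '#'
are comments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

UTR5 = "UTR5"
CDS = "CDS"
UTR3 = "UTR3"
REGIONS = (UTR5, CDS, UTR3)

GROUP_EXOSOME = "exosome"
GROUP_CELL = "cell"
GROUPS = (GROUP_EXOSOME, GROUP_CELL)

LOCATION_STEP = 0.02
N_LOCATION_BINS = 50

TRANSCRIPT_COLUMNS = ("transcript_id", "length", "cds_start", "cds_end")
PROBE_COLUMNS = ("probe_id", "transcript_id", "start", "end")
MAPPING_COLUMNS = PROBE_COLUMNS + ("relative_location", "binned_location", "region")

_READ_KWARGS = dict(sep="\t", comment="#", dtype={"transcript_id": str, "probe_id": str})


def _read_tsv(path: str | Path, required: Iterable[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"{what} file not found: {path}")
    df = pd.read_csv(path, **_READ_KWARGS)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} table {path} is missing required column {col!r}")
    return df


def validate_transcripts(df: pd.DataFrame) -> pd.DataFrame:
    """Check transcript-model invariants; return the frame unchanged."""
    dup = df["transcript_id"][df["transcript_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate transcript_id {dup.iloc[0]!r}")
    for _, row in df.iterrows():
        tid = row["transcript_id"]
        if row["length"] < 100:
            raise ValidationError(f"transcript {tid}: length {row['length']} < 100 nt")
        if not (0 <= row["cds_start"] < row["cds_end"] <= row["length"]):
            raise ValidationError(
                f"transcript {tid}: CDS [{row['cds_start']}, {row['cds_end']}) "
                f"violates 0 <= cds_start < cds_end <= length ({row['length']})"
            )
    return df


def read_transcript_models(path: str | Path) -> pd.DataFrame:
    """Read a transcripts.tsv table (transcript_id, length, cds_start, cds_end)."""
    df = _read_tsv(path, TRANSCRIPT_COLUMNS, "transcript")
    df = df.loc[:, list(TRANSCRIPT_COLUMNS)].reset_index(drop=True)
    for col in ("length", "cds_start", "cds_end"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    return validate_transcripts(df)


def write_transcript_models(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(TRANSCRIPT_COLUMNS)].to_csv(path, sep="\t", index=False)


def relative_location(start: float, end: float, length: float) -> float:
    """Relative location of a probe: midpoint scaled by transcript length."""
    return ((start + end) / 2.0) / length


def bin_location(rel: float) -> float:
    """Round a relative location down to the 0.02 grid; 1.0 joins the top bin (0.98)."""
    idx = min(int(np.floor(rel / LOCATION_STEP + 1e-9)), N_LOCATION_BINS - 1)
    return round(idx * LOCATION_STEP, 2)


def location_bin_index(rel: np.ndarray | float, step: float = LOCATION_STEP) -> np.ndarray:
    """Vectorised bin index: floor(rel / step), capped at the top bin."""
    n_bins = int(round(1.0 / step))
    idx = np.floor(np.asarray(rel, dtype=float) / step + 1e-9).astype(int)
    return np.minimum(idx, n_bins - 1)


def assign_region(midpoint: float, cds_start: int, cds_end: int) -> str:
    """Region containing a position; a boundary position belongs 3'-ward."""
    if midpoint >= cds_end:
        return UTR3
    if midpoint >= cds_start:
        return CDS
    return UTR5


def annotate_probes(probes: pd.DataFrame, transcripts: pd.DataFrame) -> pd.DataFrame:
    """Attach relative_location, binned_location and region to raw probe intervals.

    Validates that every probe interval is well-formed and lies within its
    (resolvable) transcript, and that (probe_id, transcript_id) pairs are
    unique.
    """
    tx = transcripts.set_index("transcript_id")
    out = probes.loc[:, list(PROBE_COLUMNS)].copy().reset_index(drop=True)
    out["start"] = pd.to_numeric(out["start"], errors="raise").astype(np.int64)
    out["end"] = pd.to_numeric(out["end"], errors="raise").astype(np.int64)

    unknown = ~out["transcript_id"].isin(tx.index)
    if unknown.any():
        bad = out.loc[unknown, "transcript_id"].iloc[0]
        raise ValidationError(f"probe table references unknown transcript {bad!r}")
    dup = out.duplicated(subset=["probe_id", "transcript_id"])
    if dup.any():
        pid, tid = out.loc[dup, ["probe_id", "transcript_id"]].iloc[0]
        raise ValidationError(f"duplicate probe mapping ({pid!r}, {tid!r})")

    lengths = tx.loc[out["transcript_id"], "length"].to_numpy()
    cds_start = tx.loc[out["transcript_id"], "cds_start"].to_numpy()
    cds_end = tx.loc[out["transcript_id"], "cds_end"].to_numpy()

    bad = (out["start"] < 0) | (out["start"] >= out["end"]) | (out["end"] > lengths)
    if bad.any():
        row = out.loc[bad.to_numpy()].iloc[0]
        raise ValidationError(
            f"probe {row['probe_id']!r} on {row['transcript_id']!r}: interval "
            f"[{row['start']}, {row['end']}) violates 0 <= start < end <= length"
        )

    mid = (out["start"].to_numpy() + out["end"].to_numpy()) / 2.0
    rel = mid / lengths
    out["relative_location"] = rel
    out["binned_location"] = np.round(location_bin_index(rel) * LOCATION_STEP, 2)
    region = np.where(mid >= cds_end, UTR3, np.where(mid >= cds_start, CDS, UTR5))
    out["region"] = region
    return out


def read_probe_table(path: str | Path, transcripts: pd.DataFrame) -> pd.DataFrame:
    """Read probes.tsv (probe_id, transcript_id, start, end) and annotate it."""
    df = _read_tsv(path, PROBE_COLUMNS, "probe")
    return annotate_probes(df, transcripts)


def write_probe_table(mappings: pd.DataFrame, path: str | Path) -> None:
    mappings.loc[:, list(PROBE_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_probe_bed(mappings: pd.DataFrame, path: str | Path) -> None:
    """BED-like export of probe intervals in transcript space (0-based half-open)."""
    bed = mappings.loc[:, ["transcript_id", "start", "end", "probe_id"]]
    bed.to_csv(path, sep="\t", index=False, header=False)


def filter_min_probes(mappings: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Keep only mappings whose transcript carries at least k distinct probes."""
    if k < 1:
        raise ConfigurationError(f"minimum probe count must be >= 1, got {k}")
    n = mappings.groupby("transcript_id")["probe_id"].transform("nunique")
    return mappings.loc[n >= k].reset_index(drop=True)


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix with a group label per sample.

    values: DataFrame indexed by probe_id, one column per sample, linear-scale
    nonnegative intensities.  groups: Series mapping sample_id to
    'exosome' | 'cell'.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.astype(str)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ConfigurationError(f"sample {missing[0]!r} has no group label")
        self.groups = self.groups.loc[list(self.values.columns)]
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ConfigurationError(
                f"unknown group label {sorted(bad)[0]!r}; expected one of {GROUPS}"
            )
        for g in GROUPS:
            if not (self.groups == g).any():
                raise ValidationError(f"expression matrix has no {g!r} samples")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id {dup!r} in expression matrix")
        arr = self.values.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite intensity at probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative intensity at probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    @property
    def exosome_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == GROUP_EXOSOME])

    @property
    def cell_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == GROUP_CELL])


def read_groups(path: str | Path) -> pd.Series:
    """Read groups.tsv (sample_id, group) into a Series."""
    df = _read_tsv(path, ("sample_id", "group"), "group")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"].astype(str))


def read_expression_table(
    path: str | Path, groups: str | Path | pd.Series | Mapping[str, str]
) -> ExpressionMatrix:
    """Read expression.tsv (probe_id, then one numeric column per sample).

    groups may be a groups.tsv path or an in-memory sample -> group mapping.
    """
    if isinstance(groups, (str, Path)):
        groups = read_groups(groups)
    elif isinstance(groups, Mapping):
        groups = pd.Series(groups)
    df = _read_tsv(path, ("probe_id",), "expression")
    df = df.set_index(df["probe_id"].astype(str)).drop(columns="probe_id")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() != df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric value {df.iat[i, j]!r} at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"missing value at probe {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(values=numeric.astype(float), groups=groups)


def write_expression_table(
    matrix: ExpressionMatrix, expression_path: str | Path, groups_path: str | Path
) -> None:
    out = matrix.values.copy()
    out.insert(0, "probe_id", out.index)
    out.to_csv(expression_path, sep="\t", index=False)
    pd.DataFrame({"sample_id": matrix.groups.index, "group": matrix.groups.to_numpy()}).to_csv(
        groups_path, sep="\t", index=False
    )
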