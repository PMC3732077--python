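"""Exosome-to-cell enrichment ratios (ECER) and secretion calls.

For every probe the ECER is the arithmetic mean of its linear-scale
intensity over exosome samples divided by its mean over cell samples, with a
small floor on the cell mean so the ratio stays finite.  A probe is called
secreted when its ECER reaches the active cutoff (default 3; the "strong"
preset is 10); the boundary is inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .probemap import ExpressionMatrix

DEFAULT_CUTOFF = 3.0
STRONG_CUTOFF = 10.0

SECRETION_COLUMNS = (
    "probe_id",
    "transcript_id",
    "mean_exosome",
    "mean_cell",
    "ecer",
    "secreted",
    "cutoff",
)


def group_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-probe arithmetic means within each sample group.

    Returns a DataFrame with columns probe_id, mean_exosome, mean_cell, one
    row per probe in matrix order.
    """
    return pd.DataFrame(
        {
            "probe_id": matrix.values.index,
            "mean_exosome": matrix.values[matrix.exosome_samples].mean(axis=1).to_numpy(),
            "mean_cell": matrix.values[matrix.cell_samples].mean(axis=1).to_numpy(),
        }
    )


def auto_epsilon(values) -> float:
    """Cell-mean floor policy: half the smallest strictly positive intensity.

    Accepts an ExpressionMatrix, a DataFrame of intensities/means, or an
    array.  Raises if no positive value exists (an all-zero matrix has no
    natural scale).
    """
    if isinstance(values, ExpressionMatrix):
        arr = values.values.to_numpy(dtype=float)
    elif isinstance(values, pd.DataFrame):
        arr = values.select_dtypes("number").to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
    pos = arr[arr > 0]
    if pos.size == 0:
        raise ConfigurationError("cannot derive epsilon: no strictly positive intensity")
    return float(pos.min() / 2.0)


def compute_ecer(
    means: pd.DataFrame,
    epsilon: float | str = "auto",
    mappings: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """ECER per probe: mean_exosome / max(mean_cell, epsilon).

    ``epsilon="auto"`` derives the floor from the means table (half the
    smallest positive value); pass the value from :func:`auto_epsilon` on the
    full matrix to use the matrix-wide policy.  If ``mappings`` is given the
    per-probe ratios are expanded to one record per (probe, transcript)
    mapping, so a probe shared by several transcripts contributes to each.
    """
    if epsilon == "auto":
        epsilon = auto_epsilon(means[["mean_exosome", "mean_cell"]])
    epsilon = float(epsilon)
    if epsilon <= 0:
        raise ConfigurationError(f"epsilon must be > 0, got {epsilon}")
    out = means.loc[:, ["probe_id", "mean_exosome", "mean_cell"]].copy()
    out["ecer"] = out["mean_exosome"].to_numpy() / np.maximum(
        out["mean_cell"].to_numpy(), epsilon
    )
    if mappings is not None:
        out = mappings.loc[:, ["probe_id", "transcript_id"]].merge(
            out, on="probe_id", how="inner"
        )
    else:
        out.insert(1, "transcript_id", pd.NA)
    return out.reset_index(drop=True)


def call_secretion(records: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Flag records as secreted where ecer >= cutoff (inclusive boundary)."""
    if cutoff <= 0:
        raise ConfigurationError(f"secretion cutoff must be > 0, got {cutoff}")
    out = records.copy()
    out["secreted"] = out["ecer"].to_numpy() >= cutoff
    out["cutoff"] = float(cutoff)
    return out


def probe_secretion(
    matrix: ExpressionMatrix,
    mappings: pd.DataFrame,
    epsilon: float | str = "auto",
    cutoff: float | None = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Convenience composition: group means -> ECER per mapping -> secretion calls."""
    if epsilon == "auto":
        epsilon = auto_epsilon(matrix)
    records = compute_ecer(group_means(matrix), epsilon=epsilon, mappings=mappings)
    if cutoff is not None:
        records = call_secretion(records, cutoff)
    return records
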