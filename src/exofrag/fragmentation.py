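"""Transcript fragmentation classes, cutoff-sweep curves and fragment-length bounds.

A transcript with >= 2 probes is classified at a given ECER cutoff by how
many of its probes are secreted: all of them (intact secretion), exactly
half, more than half, less than half, or none.  The three partial classes
are the fragmented ones; their share of secreted transcripts, and how that
share moves as the cutoff rises, is the analysis' central readout.

The fragment-length estimator bounds the extent of a secreted 3'-terminal
region using the only landmarks available on an array: probe positions and
region borders.  Within a 3' UTR carrying enough probes, the bound runs from
the transcript 3' end to the 3'-most non-secreted UTR probe (its interval
end), or to the UTR 5' border when every UTR probe is secreted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ecer import call_secretion
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    UndefinedResultError,
    ValidationError,
)
from .kendall import CorrelationResult, kendall_tau_b
from .probemap import UTR3

ALL_SECRETED = "all_secreted"
HALF = "half"
MAJORITY = "majority"
MINORITY = "minority"
NOT_SECRETED = "not_secreted"

CLASSES = (ALL_SECRETED, HALF, MAJORITY, MINORITY, NOT_SECRETED)
SECRETED_CLASSES = (ALL_SECRETED, HALF, MAJORITY, MINORITY)
FRAGMENTED_CLASSES = (HALF, MAJORITY, MINORITY)

DEFAULT_CUTOFF_GRID = tuple(range(1, 33))


def classify_transcript(n_secreted: int, n_probes: int) -> str:
    """Fragmentation class from secreted/total probe counts.

    all_secreted: every probe secreted; half: exactly half; majority /
    minority: more / fewer than half (but at least one); not_secreted: none.
    """
    if n_probes < 2:
        raise ValidationError(f"classification requires >= 2 probes, got {n_probes}")
    if not 0 <= n_secreted <= n_probes:
        raise ValidationError(
            f"n_secreted = {n_secreted} outside [0, n_probes = {n_probes}]"
        )
    if n_secreted == 0:
        return NOT_SECRETED
    if n_secreted == n_probes:
        return ALL_SECRETED
    if 2 * n_secreted == n_probes:
        return HALF
    return MAJORITY if 2 * n_secreted > n_probes else MINORITY


def classify_all(
    records: pd.DataFrame, cutoff: float | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every transcript in a secretion table.

    records needs columns transcript_id, probe_id, ecer and (if cutoff is
    None) secreted + cutoff from a prior :func:`exofrag.ecer.call_secretion`;
    passing ``cutoff`` re-calls secretion at that value first.

    Returns (classes, counts): one row per transcript with columns
    transcript_id, n_probes, n_secreted, klass, cutoff; and per-class counts
    as a Series over all five classes.
    """
    if cutoff is not None:
        records = call_secretion(records, cutoff)
    elif "secreted" not in records.columns:
        raise ConfigurationError("records carry no secretion flags; pass a cutoff")
    active = float(records["cutoff"].iloc[0]) if len(records) else float("nan")

    grouped = records.groupby("transcript_id", sort=True)
    classes = grouped.agg(
        n_probes=("probe_id", "nunique"), n_secreted=("secreted", "sum")
    ).reset_index()
    if len(classes) and (classes["n_probes"] < 2).any():
        bad = classes.loc[classes["n_probes"] < 2, "transcript_id"].iloc[0]
        raise ValidationError(
            f"transcript {bad!r} has < 2 probes; apply filter_min_probes first"
        )
    classes["n_secreted"] = classes["n_secreted"].astype(int)
    classes["klass"] = [
        classify_transcript(s, n)
        for s, n in zip(classes["n_secreted"], classes["n_probes"])
    ]
    classes["cutoff"] = active
    counts = classes["klass"].value_counts().reindex(CLASSES, fill_value=0)
    counts.name = "count"
    return classes, counts


def half_class_breakdown(classes: pd.DataFrame) -> pd.Series:
    """Counts of half-class transcripts by their n_secreted (1, 2, 3, ...)."""
    half = classes.loc[classes["klass"] == HALF]
    return half["n_secreted"].value_counts().sort_index()


def fragmented_fraction(counts: Mapping[str, int] | pd.Series) -> float:
    """Percentage of secreted transcripts that are only partially secreted.

    Denominator: transcripts with at least one secreted probe (the four
    secreted classes); numerator: the three fragmented classes.
    """
    secreted = sum(int(counts[k]) for k in SECRETED_CLASSES if k in counts)
    if secreted == 0:
        raise UndefinedResultError("fragmented fraction undefined: no secreted transcripts")
    fragmented = sum(int(counts[k]) for k in FRAGMENTED_CLASSES if k in counts)
    return 100.0 * fragmented / secreted


@dataclass
class ClassFractionCurve:
    """Per-cutoff class composition of the secreted transcript set.

    fractions: index cutoff, one column per secreted class, each row summing
    to 1 where any transcript is secreted (NaN rows mark empty cutoffs).
    counts: index cutoff, per-class transcript counts plus the secreted total.
    """

    cutoffs: tuple[float, ...]
    fractions: pd.DataFrame
    counts: pd.DataFrame


def class_fraction_curve(
    records: pd.DataFrame, cutoffs: Iterable[float] = DEFAULT_CUTOFF_GRID
) -> ClassFractionCurve:
    """Sweep ECER cutoffs, re-calling secretion and re-classifying at each.

    At every cutoff the fraction of secreted transcripts in each secreted
    class is recorded; cutoffs where nothing is secreted get NaN fractions
    (with a warning) so downstream trend statistics can drop them.
    """
    cutoffs = tuple(float(c) for c in cutoffs)
    if any(c <= 0 for c in cutoffs):
        raise ConfigurationError("all cutoffs must be > 0")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ConfigurationError("cutoffs must be strictly increasing")

    frac_rows, count_rows = [], []
    for c in cutoffs:
        _, counts = classify_all(records, cutoff=c)
        n_secreted = int(counts[list(SECRETED_CLASSES)].sum())
        row = counts.to_dict()
        row["n_secreted_transcripts"] = n_secreted
        count_rows.append(row)
        if n_secreted == 0:
            warnings.warn(f"no secreted transcripts at cutoff {c}; fractions missing")
            frac_rows.append({k: np.nan for k in SECRETED_CLASSES})
        else:
            frac_rows.append({k: counts[k] / n_secreted for k in SECRETED_CLASSES})

    index = pd.Index(cutoffs, name="cutoff")
    return ClassFractionCurve(
        cutoffs=cutoffs,
        fractions=pd.DataFrame(frac_rows, index=index),
        counts=pd.DataFrame(count_rows, index=index),
    )


def curve_trend(curve: ClassFractionCurve, klass: str) -> CorrelationResult:
    """Kendall tau-b between the cutoff grid and one class's fraction curve."""
    if klass not in SECRETED_CLASSES:
        raise ConfigurationError(f"unknown secreted class {klass!r}; one of {SECRETED_CLASSES}")
    series = curve.fractions[klass].dropna()
    if len(series) < 3:
        raise InsufficientDataError(
            f"trend for {klass!r} needs >= 3 non-missing cutoffs, have {len(series)}"
        )
    return kendall_tau_b(series.index.to_numpy(), series.to_numpy(), stratum=f"trend:{klass}")


@dataclass
class FragmentLengthSummary:
    """Upper bounds on secreted 3'-terminal fragment lengths at one cutoff."""

    cutoff: float
    n_transcripts: int
    median_length: float
    iqr_length: float
    bounds: pd.DataFrame = field(repr=False)


def fragment_length_bounds(
    records: pd.DataFrame,
    mappings: pd.DataFrame,
    transcripts: pd.DataFrame,
    cutoff: float,
    min_probes_per_utr: int = 3,
    max_utr_length: int | None = None,
    limit_border: str = "utr",
) -> FragmentLengthSummary:
    """Per-transcript upper bounds on the secreted 3'-terminal fragment length.

    Only transcripts whose 3' UTR carries at least ``min_probes_per_utr``
    probes (and, if ``max_utr_length`` is set, whose UTR is no longer than
    that) are informative enough to bound.  The bound for a transcript is
    the distance from its 3' end to the interval end of the 3'-most
    non-secreted UTR probe; when every UTR probe is secreted the limit falls
    back to the UTR 5' border (``limit_border="utr"``, the default) or the
    transcript 5' end (``"gene"``).  Transcripts with no secreted UTR probe,
    or with a non-secreted probe flush against the 3' end (a degenerate zero
    bound), carry no fragment evidence and are excluded.
    """
    if limit_border not in ("utr", "gene"):
        raise ConfigurationError(f"limit_border must be 'utr' or 'gene', got {limit_border!r}")
    flagged = call_secretion(records, cutoff)
    utr = mappings.loc[mappings["region"] == UTR3, ["probe_id", "transcript_id", "end"]]
    merged = utr.merge(
        flagged[["probe_id", "transcript_id", "secreted"]],
        on=["probe_id", "transcript_id"],
        how="inner",
    ).merge(transcripts[["transcript_id", "length", "cds_end"]], on="transcript_id")

    rows = []
    for tid, grp in merged.groupby("transcript_id", sort=True):
        if len(grp) < min_probes_per_utr:
            continue
        length = int(grp["length"].iloc[0])
        utr3_len = length - int(grp["cds_end"].iloc[0])
        if max_utr_length is not None and utr3_len > max_utr_length:
            continue
        n_sec = int(grp["secreted"].sum())
        if n_sec == 0:
            continue
        if n_sec == len(grp):
            bound = utr3_len if limit_border == "utr" else length
        else:
            bound = length - int(grp.loc[~grp["secreted"], "end"].max())
        if bound <= 0:
            continue
        rows.append(
            {
                "transcript_id": tid,
                "utr3_length": utr3_len,
                "n_utr_probes": len(grp),
                "n_secreted_utr": n_sec,
                "bound": bound,
            }
        )

    bounds = pd.DataFrame(
        rows, columns=["transcript_id", "utr3_length", "n_utr_probes", "n_secreted_utr", "bound"]
    )
    if len(bounds) == 0:
        warnings.warn(f"no transcript qualifies for fragment-length bounds at cutoff {cutoff}")
        return FragmentLengthSummary(float(cutoff), 0, float("nan"), float("nan"), bounds)
    q25, q50, q75 = np.percentile(bounds["bound"].to_numpy(), [25, 50, 75])
    return FragmentLengthSummary(
        cutoff=float(cutoff),
        n_transcripts=len(bounds),
        median_length=float(q50),
        iqr_length=float(q75 - q25),
        bounds=bounds,
    )
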