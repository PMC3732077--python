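"""Location-versus-secretion statistics.

Everything here asks one question in different stratifications: do probes
closer to the transcript 3' end carry more of the exosomal signal?  The
workhorse is Kendall tau-b between a probe's relative location (0 = 5' end,
1 = 3' end) and its ECER, computed over all probe records or within strata
defined by region (UTR vs CDS), by transcript fragmentation class, or by
secretion strength.  Alongside it: a binned expression landscape over
(location, ECER), per-transcript representative probe pairs with their
3'/5' expression ratios, and a probe-design control correlating raw
expression with location.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ecer import STRONG_CUTOFF
from .errors import ConfigurationError, InsufficientDataError, UndefinedResultError
from .fragmentation import DEFAULT_CUTOFF_GRID, MAJORITY, classify_all
from .kendall import CorrelationResult, kendall_tau_b
from .probemap import CDS, LOCATION_STEP, UTR3, UTR5, location_bin_index

__all__ = [
    "CorrelationResult",
    "kendall_tau_b",
    "Landscape",
    "expression_location_landscape",
    "select_representative_pair",
    "pair_table",
    "location_secretion_correlation",
    "region_stratified_correlations",
    "probe_design_bias_check",
]

DEFAULT_ECER_EDGES = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)

_REGION_SETS = {
    "utr": (UTR5, UTR3),
    "cds": (CDS,),
    "utr3": (UTR3,),
    "utr5": (UTR5,),
}


def _merged(records: pd.DataFrame, mappings: pd.DataFrame) -> pd.DataFrame:
    """Join secretion records with their probe mappings on (probe, transcript)."""
    cols = ["probe_id", "transcript_id", "relative_location", "binned_location", "region"]
    out = records.merge(mappings.loc[:, cols], on=["probe_id", "transcript_id"], how="inner")
    if len(out) < len(records):
        raise ConfigurationError(
            f"{len(records) - len(out)} secretion records have no probe mapping"
        )
    return out


@dataclass
class Landscape:
    """Mean exosomal expression binned by (relative location, ECER).

    mean_expression and counts share the layout: one row per ECER bin, one
    column per location bin (left edge).  Empty cells are NaN in
    mean_expression and 0 in counts — missing, not zero expression.
    """

    location_step: float
    location_bins: tuple[float, ...]
    ecer_edges: tuple[float, ...]
    mean_expression: pd.DataFrame
    counts: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        long = (
            self.mean_expression.stack(future_stack=True)
            .rename("mean_expression")
            .reset_index()
        )
        long.columns = ["ecer_bin", "location_bin", "mean_expression"]
        long["count"] = self.counts.stack(future_stack=True).to_numpy()
        return long


def expression_location_landscape(
    records: pd.DataFrame,
    mappings: pd.DataFrame,
    ecer_edges: Sequence[float] = DEFAULT_ECER_EDGES,
    location_step: float = LOCATION_STEP,
) -> Landscape:
    """Bin probe records into a (location x ECER) grid of mean exosomal expression.

    Location bins have width ``location_step`` (default the 0.02 precision
    grid); ECER bins are [0, e1), [e1, e2), ..., [e_last, inf) from the given
    edges (default log2-spaced 1..32 with an open top bin).
    """
    edges = tuple(float(e) for e in ecer_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])) or any(e <= 0 for e in edges):
        raise ConfigurationError("ecer_edges must be strictly increasing and positive")
    df = _merged(records, mappings)
    n_loc = int(round(1.0 / location_step))
    loc_bins = tuple(round(i * location_step, 6) for i in range(n_loc))
    loc_idx = location_bin_index(df["relative_location"].to_numpy(), location_step)
    ecer_idx = np.digitize(df["ecer"].to_numpy(), edges)  # 0 => below first edge
    labels = (
        [f"[0,{edges[0]:g})"]
        + [f"[{a:g},{b:g})" for a, b in zip(edges, edges[1:])]
        + [f">={edges[-1]:g}"]
    )

    sums = np.zeros((len(labels), n_loc))
    counts = np.zeros((len(labels), n_loc), dtype=int)
    np.add.at(sums, (ecer_idx, loc_idx), df["mean_exosome"].to_numpy())
    np.add.at(counts, (ecer_idx, loc_idx), 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    index = pd.Index(labels, name="ecer_bin")
    columns = pd.Index(loc_bins, name="location_bin")
    return Landscape(
        location_step=float(location_step),
        location_bins=loc_bins,
        ecer_edges=edges,
        mean_expression=pd.DataFrame(means, index=index, columns=columns),
        counts=pd.DataFrame(counts, index=index, columns=columns),
    )


def select_representative_pair(transcript_records: pd.DataFrame) -> pd.Series:
    """The (max-ECER, min-ECER) probe pair of one transcript.

    Ties on ECER break toward the more 3'-located probe, then lexicographic
    probe_id.  The 3'/5' ratio divides the exosomal mean of whichever pair
    member sits closer to the 3' end by that of the other member.
    """
    df = transcript_records
    if df["probe_id"].nunique() < 2:
        raise InsufficientDataError(
            f"representative pair needs >= 2 probes, transcript "
            f"{df['transcript_id'].iloc[0]!r} has {df['probe_id'].nunique()}"
        )
    hi_order = df.sort_values(
        ["ecer", "relative_location", "probe_id"], ascending=[False, False, True]
    )
    lo_order = df.sort_values(
        ["ecer", "relative_location", "probe_id"], ascending=[True, True, True]
    )
    hi = hi_order.iloc[0]
    lo = lo_order.iloc[0]
    if lo.name == hi.name:  # fully tied two-row frame collapses to one record
        lo = lo_order.iloc[1]

    hi_is_3prime = hi["relative_location"] >= lo["relative_location"]
    three, five = (hi, lo) if hi_is_3prime else (lo, hi)
    denom = five["mean_exosome"]
    ratio = float(three["mean_exosome"] / denom) if denom > 0 else float("inf")
    return pd.Series(
        {
            "transcript_id": df["transcript_id"].iloc[0],
            "hi_probe": hi["probe_id"],
            "lo_probe": lo["probe_id"],
            "hi_ecer": float(hi["ecer"]),
            "lo_ecer": float(lo["ecer"]),
            "hi_location": float(hi["relative_location"]),
            "lo_location": float(lo["relative_location"]),
            "ratio_3p_5p": ratio,
            "hi_is_3prime": bool(hi_is_3prime),
            "delta_location": float(hi["relative_location"] - lo["relative_location"]),
        }
    )


def pair_table(
    records: pd.DataFrame,
    mappings: pd.DataFrame,
    min_strength: float | None = None,
) -> pd.DataFrame:
    """Representative pairs for every transcript (optionally only strong secretors).

    ``min_strength`` keeps transcripts whose maximal probe ECER reaches the
    threshold (e.g. 10 for strongly secreted transcripts).
    """
    df = _merged(records, mappings)
    if min_strength is not None:
        strong = df.groupby("transcript_id")["ecer"].transform("max") >= min_strength
        df = df.loc[strong]
    rows = [
        select_representative_pair(grp)
        for _, grp in df.groupby("transcript_id", sort=True)
        if grp["probe_id"].nunique() >= 2
    ]
    columns = [
        "transcript_id", "hi_probe", "lo_probe", "hi_ecer", "lo_ecer",
        "hi_location", "lo_location", "ratio_3p_5p", "hi_is_3prime", "delta_location",
    ]
    return pd.DataFrame(rows, columns=columns).reset_index(drop=True)


def location_secretion_correlation(
    records: pd.DataFrame,
    mappings: pd.DataFrame,
    region: str | None = None,
    min_strength: float | None = None,
    strength_mode: str = "any",
    transcript_ids: Iterable[str] | None = None,
    stratum: str | None = None,
) -> CorrelationResult:
    """Kendall tau-b between probe relative location and ECER within a stratum.

    Parameters
    ----------
    region
        None for all probes, or 'utr' (UTR5 + UTR3), 'cds', 'utr3', 'utr5'.
    min_strength, strength_mode
        Keep only transcripts whose probe ECERs reach ``min_strength`` —
        under mode 'any' the maximal probe suffices (the default reading of
        a strongly secreted transcript), under 'all' every probe must.
    transcript_ids
        Optional explicit transcript subset (e.g. one fragmentation class).
    """
    df = _merged(records, mappings)
    labels = []
    if region is not None:
        key = region.lower()
        if key not in _REGION_SETS:
            raise ConfigurationError(f"unknown region {region!r}; one of {sorted(_REGION_SETS)}")
        df = df.loc[df["region"].isin(_REGION_SETS[key])]
        labels.append(key.upper())
    if transcript_ids is not None:
        df = df.loc[df["transcript_id"].isin(set(transcript_ids))]
        labels.append("subset")
    if min_strength is not None:
        if strength_mode not in ("any", "all"):
            raise ConfigurationError(f"strength_mode must be 'any' or 'all', got {strength_mode!r}")
        agg = "max" if strength_mode == "any" else "min"
        keep = df.groupby("transcript_id")["ecer"].transform(agg) >= min_strength
        df = df.loc[keep]
        labels.append(f"ECER>={min_strength:g}")
    if stratum is None:
        stratum = ", ".join(labels) if labels else "all probes"
    if len(df) < 3:
        raise InsufficientDataError(
            f"stratum {stratum!r} has {len(df)} probe records; need >= 3"
        )
    return kendall_tau_b(
        df["relative_location"].to_numpy(), df["ecer"].to_numpy(), stratum=stratum
    )


def region_stratified_correlations(
    records: pd.DataFrame,
    mappings: pd.DataFrame,
    cutoffs: Iterable[float] = DEFAULT_CUTOFF_GRID,
    strength_threshold: float = STRONG_CUTOFF,
) -> pd.DataFrame:
    """Location-vs-ECER correlations per region, per selection, across cutoffs.

    For every cutoff and region (UTR = both untranslated regions, CDS), two
    transcript selections are correlated: transcripts whose majority of
    probes is secreted at that cutoff, and strongly secreted transcripts
    (max probe ECER >= ``strength_threshold``).  Strata too small for a
    correlation are kept as rows with NaN statistics so the table stays
    complete.
    """
    rows = []
    for c in cutoffs:
        classes, _ = classify_all(records, cutoff=float(c))
        majority_ids = set(classes.loc[classes["klass"] == MAJORITY, "transcript_id"])
        for region in ("utr", "cds"):
            selections = {
                "majority_class": dict(transcript_ids=majority_ids),
                "strong": dict(min_strength=strength_threshold),
            }
            for name, kw in selections.items():
                label = f"{region.upper()}, {name}, cutoff={c:g}"
                try:
                    res = location_secretion_correlation(
                        records, mappings, region=region, stratum=label, **kw
                    )
                    tau, p, n = res.tau, res.p_value, res.n
                except (InsufficientDataError, UndefinedResultError):
                    tau, p, n = np.nan, np.nan, 0
                rows.append(
                    {
                        "cutoff": float(c),
                        "region": region.upper(),
                        "selection": name,
                        "tau": tau,
                        "p_value": p,
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


def probe_design_bias_check(
    records: pd.DataFrame,
    mappings: pd.DataFrame,
    split_cutoff: float = 3.0,
) -> dict[str, CorrelationResult | None]:
    """Control for array design bias: expression vs location in two ECER strata.

    Correlates each probe's exosomal mean expression with its relative
    location separately for weakly secreted (ECER < split_cutoff) and
    secreted (ECER >= split_cutoff) records.  Near-zero tau in both strata
    says probe placement does not itself predict signal, so the positional
    secretion statistics are not design artefacts.  A stratum too small to
    test is returned as None.
    """
    df = _merged(records, mappings)
    out: dict[str, CorrelationResult | None] = {}
    strata = {
        f"ECER<{split_cutoff:g}": df.loc[df["ecer"] < split_cutoff],
        f"ECER>={split_cutoff:g}": df.loc[df["ecer"] >= split_cutoff],
    }
    for label, sub in strata.items():
        if len(sub) < 3:
            out[label] = None
            continue
        try:
            out[label] = kendall_tau_b(
                sub["mean_exosome"].to_numpy(),
                sub["relative_location"].to_numpy(),
                stratum=f"design bias, {label}",
            )
        except UndefinedResultError:
            out[label] = None
    return out
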