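"""End-to-end orchestration and the qPCR helper arithmetic.

run_pipeline composes the analysis in its natural order — read and validate
tables, drop transcripts with fewer than two probes, compute ECER, call
secretion, classify transcripts, sweep the cutoff grid, run the positional
statistics and the fragment-length bounds — and writes per-stage TSVs plus
a summary in two equivalent forms (report.txt and report.json).
"""

from __future__ import annotations

import json
import logging
import math
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import ecer as ecer_mod
from . import fragmentation as frag_mod
from . import positional as pos_mod
from . import probemap
from .errors import ConfigurationError, ExofragError, InsufficientDataError, ValidationError

log = logging.getLogger("exofrag")


@dataclass
class RunConfig:
    """Inputs, cutoffs and output location for one pipeline run."""

    transcripts: str | Path
    probes: str | Path
    expression: str | Path
    groups: str | Path
    out_dir: str | Path
    cutoff: float = ecer_mod.DEFAULT_CUTOFF
    strong_cutoff: float = ecer_mod.STRONG_CUTOFF
    cutoff_grid: tuple[float, ...] = frag_mod.DEFAULT_CUTOFF_GRID
    epsilon: float | str = "auto"
    min_probes: int = 2
    min_probes_per_utr: int = 3
    max_utr_length: int | None = None

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.strong_cutoff <= 0:
            raise ConfigurationError("cutoffs must be > 0")
        grid = tuple(float(c) for c in self.cutoff_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigurationError("cutoff_grid must be strictly increasing")
        self.cutoff_grid = grid
        for name in ("transcripts", "probes", "expression", "groups"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigurationError(f"{name} file not found: {p}")
            setattr(self, name, p)
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown run-config key {sorted(unknown)[0]!r}")
        return cls(**raw)


@dataclass
class PipelineReport:
    """In-memory results of a run plus the paths of everything written."""

    summary: dict[str, Any]
    secretion: pd.DataFrame
    classes: pd.DataFrame
    curve: frag_mod.ClassFractionCurve
    correlations: pd.DataFrame
    pairs: pd.DataFrame
    fraglen: frag_mod.FragmentLengthSummary
    paths: dict[str, Path] = field(default_factory=dict)


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        yield
    except ExofragError as exc:
        raise type(exc)(f"stage {name!r}: {exc}") from exc
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _corr_dict(res: pos_mod.CorrelationResult | None) -> dict[str, Any] | None:
    if res is None:
        return None
    return {"tau": res.tau, "p_value": res.p_value, "n": res.n, "stratum": res.stratum}


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute every stage and write the report bundle into config.out_dir.

    Any stage failure removes the partially written outputs and re-raises
    the error with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    try:
        with _stage("read"):
            transcripts = probemap.read_transcript_models(config.transcripts)
            mappings = probemap.read_probe_table(config.probes, transcripts)
            matrix = probemap.read_expression_table(config.expression, config.groups)

        with _stage("filter"):
            mappings = probemap.filter_min_probes(mappings, config.min_probes)
            if len(mappings) == 0:
                raise ValidationError("no transcript passes the minimum-probe filter")

        with _stage("ecer"):
            epsilon = (
                ecer_mod.auto_epsilon(matrix) if config.epsilon == "auto" else float(config.epsilon)
            )
            secretion = ecer_mod.probe_secretion(
                matrix, mappings, epsilon=epsilon, cutoff=config.cutoff
            )
            _write("ecer.tsv", lambda p: secretion.to_csv(p, sep="\t", index=False))

        with _stage("classify"):
            classes, counts = frag_mod.classify_all(secretion)
            frac = frag_mod.fragmented_fraction(counts)
            half_breakdown = frag_mod.half_class_breakdown(classes)
            _write("classes.tsv", lambda p: classes.to_csv(p, sep="\t", index=False))

        with _stage("curve"):
            curve = frag_mod.class_fraction_curve(secretion, config.cutoff_grid)
            trends = {}
            for klass in (frag_mod.HALF, frag_mod.ALL_SECRETED):
                try:
                    trends[klass] = _corr_dict(frag_mod.curve_trend(curve, klass))
                except InsufficientDataError:
                    trends[klass] = None
            _write("curve.tsv", lambda p: curve.fractions.join(
                curve.counts, rsuffix="_count").to_csv(p, sep="\t"))

        with _stage("positional"):
            overall = pos_mod.location_secretion_correlation(secretion, mappings)
            stratified = pos_mod.region_stratified_correlations(
                secretion, mappings, config.cutoff_grid, config.strong_cutoff
            )
            bias = pos_mod.probe_design_bias_check(secretion, mappings, config.cutoff)
            pairs = pos_mod.pair_table(secretion, mappings, min_strength=config.strong_cutoff)
            landscape = pos_mod.expression_location_landscape(secretion, mappings)
            _write("correlations.tsv", lambda p: stratified.to_csv(p, sep="\t", index=False))
            _write("pairs.tsv", lambda p: pairs.to_csv(p, sep="\t", index=False))
            _write("landscape.tsv", lambda p: landscape.to_long().to_csv(p, sep="\t", index=False))

        with _stage("fraglen"):
            fraglen = frag_mod.fragment_length_bounds(
                secretion,
                mappings,
                transcripts,
                cutoff=config.cutoff,
                min_probes_per_utr=config.min_probes_per_utr,
                max_utr_length=config.max_utr_length,
            )
            _write("fraglen.tsv", lambda p: fraglen.bounds.to_csv(p, sep="\t", index=False))

        summary = _jsonable(
            {
                "n_transcripts": int(classes["transcript_id"].nunique()),
                "n_probe_records": int(len(secretion)),
                "cutoff": config.cutoff,
                "epsilon": epsilon,
                "class_counts": counts.to_dict(),
                "half_breakdown_by_n_secreted": {str(int(k)): int(v) for k, v in half_breakdown.items()},
                "fragmented_fraction_pct": frac,
                "curve_trends": trends,
                "location_secretion": _corr_dict(overall),
                "design_bias": {k: _corr_dict(v) for k, v in bias.items()},
                "fragment_length": {
                    "cutoff": fraglen.cutoff,
                    "n_transcripts": fraglen.n_transcripts,
                    "median_nt": fraglen.median_length,
                    "iqr_nt": fraglen.iqr_length,
                },
            }
        )

        with _stage("report"):
            _write("report.json", lambda p: p.write_text(json.dumps(summary, indent=2) + "\n"))
            _write("report.txt", lambda p: p.write_text(_render_report(summary, curve)))
    except ExofragError:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    paths = {p.name: p for p in written}
    return PipelineReport(
        summary=summary,
        secretion=secretion,
        classes=classes,
        curve=curve,
        correlations=stratified,
        pairs=pairs,
        fraglen=fraglen,
        paths=paths,
    )


def _render_report(summary: dict[str, Any], curve: frag_mod.ClassFractionCurve) -> str:
    lines = ["exofrag pipeline report", "=" * 23, ""]
    lines.append(f"transcripts classified : {summary['n_transcripts']}")
    lines.append(f"probe records          : {summary['n_probe_records']}")
    lines.append(f"ECER cutoff            : {summary['cutoff']} (epsilon {summary['epsilon']:.4g})")
    lines.append("")
    lines.append("fragmentation classes at the main cutoff:")
    for klass, n in summary["class_counts"].items():
        lines.append(f"  {klass:<14} {n}")
    frac = summary["fragmented_fraction_pct"]
    lines.append(f"fragmented fraction of secreted transcripts: {frac:.1f}%")
    hb = summary["half_breakdown_by_n_secreted"]
    if hb:
        parts = ", ".join(
            f"{v} with {k}" for k, v in sorted(hb.items(), key=lambda kv: int(kv[0]))
        )
        lines.append(f"half-class breakdown by n_secreted: {parts}")
    lines.append("")
    for klass, trend in summary["curve_trends"].items():
        if trend is None:
            lines.append(f"trend tau({klass}) vs cutoff: not estimable")
        else:
            lines.append(
                f"trend tau({klass}) vs cutoff: {trend['tau']:+.3f} (p = {trend['p_value']:.3g})"
            )
    loc = summary["location_secretion"]
    lines.append(
        f"location vs ECER, all probes: tau = {loc['tau']:+.3f} "
        f"(p = {loc['p_value']:.3g}, n = {loc['n']})"
    )
    for label, res in summary["design_bias"].items():
        if res is None:
            lines.append(f"design-bias control [{label}]: stratum empty")
        else:
            lines.append(
                f"design-bias control [{label}]: tau = {res['tau']:+.3f} (p = {res['p_value']:.3g})"
            )
    fl = summary["fragment_length"]
    lines.append("")
    if fl["n_transcripts"]:
        lines.append(
            f"fragment-length bounds (cutoff {fl['cutoff']:g}, n = {fl['n_transcripts']}): "
            f"median {fl['median_nt']:.1f} nt, IQR {fl['iqr_nt']:.1f} nt"
        )
    else:
        lines.append("fragment-length bounds: no qualifying transcripts")
    lines.append("")
    lines.append("class-fraction curve (fraction of secreted transcripts):")
    lines.append(curve.fractions.round(4).to_string())
    lines.append("")
    return "\n".join(lines)


def qpcr_relative_abundance(ct_gene: float, ct_spike: float) -> float:
    """Relative abundance 2^-(CT_gene - CT_spike) against a spike-in control.

    Assumes the idealised amplification efficiency of 2 per cycle.
    """
    if not (math.isfinite(ct_gene) and math.isfinite(ct_spike)):
        raise ValidationError(f"CT values must be finite, got {ct_gene} and {ct_spike}")
    return 2.0 ** (-(ct_gene - ct_spike))


def qpcr_ratio_3p_5p(ct_3p: float, ct_5p: float, ct_spike: float) -> float:
    """3'/5' amplicon ratio: quotient of the two spike-normalised abundances."""
    return qpcr_relative_abundance(ct_3p, ct_spike) / qpcr_relative_abundance(ct_5p, ct_spike)
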