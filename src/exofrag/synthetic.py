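"""Synthetic two-compartment microarray data with planted 3'-terminal secretion.

The generator emulates the kind of dataset the pipeline analyses: a
transcriptome of mRNAs 400-12,000 nt long centred near 2,100 nt, each
carrying a handful of 60-mer probes whose placement brackets the transcript
ends, and a probe x sample intensity matrix for exosome and cell
compartments with multiplicative lognormal noise.

The planted biology: a configurable fraction of transcripts is "fragmented"
— a 3'-terminal piece starting at a breakpoint drawn with 3'-ward bias is
exported into exosomes with a gain, while the rest of the molecule only
leaks.  Unfragmented transcripts are either secreted intact (gain on every
probe) or retained (leak on every probe).  A ground-truth table records
every planted label so recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, GenerationError
from .probemap import (
    ExpressionMatrix,
    GROUP_CELL,
    GROUP_EXOSOME,
    annotate_probes,
    write_expression_table,
    write_probe_table,
    write_transcript_models,
)

STATUS_FRAGMENTED = "fragmented"
STATUS_INTACT = "intact_secreted"
STATUS_RETAINED = "not_secreted"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset.

    Transcript lengths are lognormal (natural-log mean/sd) truncated to
    [length_min, length_max] nt; CDS borders come from the UTR fractions.
    Each transcript gets probes_min..probes_max non-overlapping 60-mers;
    with anchor_terminal_probe set (the default) one probe sits flush
    against each terminus and the rest pack uniformly between, so the probe
    set brackets the full transcript and any interior breakpoint falls
    between two probes.
    frag_prob transcripts are fragmented at a breakpoint drawn as
    lo + (hi - lo) * Beta(1 + bias_beta, 1) on relative coordinates — density
    increasingly 3'-ward as bias_beta grows, uniform at bias_beta = 0 — with
    hi capped so the exported fragment is at least min_fragment_nt long (a
    shorter piece would not be a detectable mRNA fragment) and lo raised to
    the 3'-UTR start when breakpoint_region = "utr3".

    Probes 3' of the breakpoint carry their transcript's export efficiency
    into exosome samples — secretion_gain with a lognormal spread of
    gain_log_sd, damped by intact_gain_factor for intact-secreted molecules
    — while all other probes of the transcript carry leak.  Replicate noise
    is multiplicative lognormal with total sd noise_sd on the natural-log
    scale per measurement, split into a transcript-level component shared
    by a transcript's probes within a sample and an independent probe-level
    residual (noise_probe_frac of the variance).
    """

    seed: int = 0
    n_transcripts: int = 1000
    length_log_mean: float = math.log(2100.0)
    length_log_sd: float = 0.65
    length_min: int = 400
    length_max: int = 12000
    utr5_frac: float = 0.10
    utr3_frac: float = 0.35
    probes_min: int = 2
    probes_max: int = 6
    probe_count_decay: float = 0.25
    probe_length: int = 60
    anchor_terminal_probe: bool = True
    n_exosome_samples: int = 3
    n_cell_samples: int = 3
    frag_prob: float = 0.7
    bias_beta: float = 5.0
    secretion_gain: float = 8.0
    gain_log_sd: float = 0.5
    intact_gain_factor: float = 0.6
    leak: float = 0.05
    noise_sd: float = 0.2
    noise_probe_frac: float = 0.35
    intact_secretion_prob: float = 0.6
    min_fragment_nt: int = 100
    breakpoint_region: str = "any"
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 1.0
    probe_eff_log_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ConfigurationError("n_transcripts must be >= 1")
        if not (0 < self.utr5_frac and 0 < self.utr3_frac
                and self.utr5_frac + self.utr3_frac < 1):
            raise ConfigurationError("UTR fractions must be in (0,1) and sum below 1")
        if self.probes_min < 2 or self.probes_max < self.probes_min:
            raise ConfigurationError("need probes_max >= probes_min >= 2")
        if not 0 < self.probe_count_decay <= 1:
            raise ConfigurationError("probe_count_decay must be in (0, 1]")
        if self.n_exosome_samples < 1 or self.n_cell_samples < 1:
            raise ConfigurationError("need >= 1 sample per compartment")
        if not 0 <= self.frag_prob <= 1:
            raise ConfigurationError("frag_prob must be in [0, 1]")
        if self.bias_beta < 0 or self.noise_sd < 0:
            raise ConfigurationError("bias_beta and noise_sd must be >= 0")
        if not 0 <= self.noise_probe_frac <= 1:
            raise ConfigurationError("noise_probe_frac must be in [0, 1]")
        if self.secretion_gain <= 1:
            raise ConfigurationError("secretion_gain must be > 1")
        if self.gain_log_sd < 0:
            raise ConfigurationError("gain_log_sd must be >= 0")
        if not 0 < self.intact_gain_factor <= 1:
            raise ConfigurationError("intact_gain_factor must be in (0, 1]")
        if not 0 <= self.leak < 1:
            raise ConfigurationError("leak must be in [0, 1)")
        if not 0 <= self.intact_secretion_prob <= 1:
            raise ConfigurationError("intact_secretion_prob must be in [0, 1]")
        if self.breakpoint_region not in ("any", "utr3"):
            raise ConfigurationError("breakpoint_region must be 'any' or 'utr3'")
        if not (100 <= self.length_min < self.length_max):
            raise ConfigurationError("need 100 <= length_min < length_max")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown simulation key {sorted(unknown)[0]!r}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


class GroundTruth(NamedTuple):
    """Planted labels: one row per transcript and one per probe."""

    transcripts: pd.DataFrame  # transcript_id, status, fragmented, breakpoint
    probes: pd.DataFrame  # probe_id, transcript_id, in_fragment


class SimBundle(NamedTuple):
    transcripts: pd.DataFrame
    mappings: pd.DataFrame
    matrix: ExpressionMatrix
    truth: GroundTruth
    config: SimConfig


def _truncated_lognormal(rng, n, log_mean, log_sd, lo, hi) -> np.ndarray:
    out = np.empty(n)
    remaining = np.arange(n)
    for _ in range(1000):
        draw = rng.lognormal(log_mean, log_sd, size=len(remaining))
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
        if len(remaining) == 0:
            return out
    raise GenerationError("length truncation bounds reject nearly every draw")


def simulate_transcriptome(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw transcript models and non-overlapping probe placements.

    Returns (transcripts, mappings) in the same annotated form the readers
    produce.  Probe placement is uniform given non-overlap (a stars-and-bars
    draw), with the optional anchored terminal probe occupying the last
    probe_length nt.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    n = config.n_transcripts
    lengths = np.round(
        _truncated_lognormal(
            rng, n, config.length_log_mean, config.length_log_sd,
            config.length_min, config.length_max,
        )
    ).astype(np.int64)
    cds_start = np.maximum(1, np.round(config.utr5_frac * lengths)).astype(np.int64)
    cds_end = np.minimum(
        lengths - 1, np.round((1.0 - config.utr3_frac) * lengths)
    ).astype(np.int64)

    width = int(np.ceil(np.log10(max(n, 10))))
    tids = [f"TX{i:0{width}d}" for i in range(1, n + 1)]
    transcripts = pd.DataFrame(
        {"transcript_id": tids, "length": lengths, "cds_start": cds_start, "cds_end": cds_end}
    )

    w = config.probe_length
    # Probe counts decay geometrically from probes_min (decay 1 = uniform):
    # low-probe transcripts dominate expression arrays filtered to >= 2 probes.
    ks = np.arange(config.probes_min, config.probes_max + 1)
    weights = config.probe_count_decay ** (ks - config.probes_min)
    k_all = rng.choice(ks, size=n, p=weights / weights.sum())
    rows = []
    for tid, length, k in zip(tids, lengths, k_all):
        k = int(k)
        anchored = config.anchor_terminal_probe
        m = k - 2 if anchored else k  # probes packed between the two anchors
        span = int(length) - (2 * w if anchored else 0)
        free = span - m * w
        if free < 0:
            raise GenerationError(
                f"transcript {tid}: cannot place {k} probes of {w} nt on {length} nt"
            )
        offsets = np.sort(rng.uniform(0.0, free, size=m)) if m else np.empty(0)
        base = w if anchored else 0
        starts = base + np.floor(offsets).astype(np.int64) + w * np.arange(m)
        if anchored:
            starts = np.concatenate([[0], starts, [int(length) - w]])
        for j, s in enumerate(starts, start=1):
            rows.append((f"{tid}:P{j}", tid, int(s), int(s) + w))
    probes = pd.DataFrame(rows, columns=["probe_id", "transcript_id", "start", "end"])
    return transcripts, annotate_probes(probes, transcripts)


def simulate_expression(
    transcripts: pd.DataFrame, mappings: pd.DataFrame, config: SimConfig
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw intensities for both compartments plus the planted ground truth."""
    rng = np.random.default_rng([int(config.seed), 1])
    tids = transcripts["transcript_id"].to_numpy()
    n = len(tids)
    lengths = transcripts["length"].to_numpy(dtype=float)
    cds_end = transcripts["cds_end"].to_numpy(dtype=float)

    u = rng.random(n)
    fragmented = u < config.frag_prob
    intact = (~fragmented) & (rng.random(n) < config.intact_secretion_prob)
    status = np.where(
        fragmented, STATUS_FRAGMENTED, np.where(intact, STATUS_INTACT, STATUS_RETAINED)
    )

    hi = 1.0 - config.min_fragment_nt / lengths
    lo = np.where(config.breakpoint_region == "utr3", cds_end / lengths, 0.0)
    if np.any(hi[fragmented] <= lo[fragmented]):
        bad = tids[fragmented][(hi <= lo)[fragmented]][0]
        raise GenerationError(
            f"transcript {bad}: no room for a >= {config.min_fragment_nt} nt fragment "
            f"inside the {config.breakpoint_region!r} breakpoint region"
        )
    beta = rng.beta(1.0 + config.bias_beta, 1.0, size=n)
    breakpoint_rel = np.where(fragmented, lo + (hi - lo) * beta, 0.0)

    # Per-transcript export efficiency: lognormal spread around the nominal
    # gain, damped for intact molecules (whole-mRNA secretion is weaker than
    # 3'-fragment export, which is what makes strong enrichment fragment-rich).
    gain = (
        config.secretion_gain
        * rng.lognormal(0.0, config.gain_log_sd, size=n)
        * np.where(intact, config.intact_gain_factor, 1.0)
    )
    gain_applied = np.where(fragmented | intact, gain, 0.0)

    tx_index = pd.Index(tids)
    probe_tx = tx_index.get_indexer(mappings["transcript_id"])
    rel = mappings["relative_location"].to_numpy()
    in_fragment = np.where(
        fragmented[probe_tx],
        rel >= breakpoint_rel[probe_tx],
        intact[probe_tx],
    )
    factor = np.where(in_fragment, gain[probe_tx], config.leak)

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    efficiency = rng.lognormal(0.0, config.probe_eff_log_sd, size=len(mappings))
    base = baseline[probe_tx] * efficiency

    n_exo, n_cell = config.n_exosome_samples, config.n_cell_samples
    # Replicate noise (total log-sd noise_sd) decomposes into a
    # transcript-level component shared by all probes of a transcript within
    # one sample (biological/loading variation of that RNA species) and an
    # independent probe-level hybridisation residual.
    sd_probe = config.noise_sd * math.sqrt(config.noise_probe_frac)
    sd_shared = config.noise_sd * math.sqrt(1.0 - config.noise_probe_frac)
    probe_noise = lambda cols: np.exp(rng.normal(0.0, sd_probe, (len(base), cols)))
    tx_noise = lambda cols: np.exp(rng.normal(0.0, sd_shared, (n, cols)))[probe_tx]
    cell = base[:, None] * tx_noise(n_cell) * probe_noise(n_cell)
    exo = (base * factor)[:, None] * tx_noise(n_exo) * probe_noise(n_exo)

    exo_names = [f"Exo{i + 1}" for i in range(n_exo)]
    cell_names = [f"Cell{i + 1}" for i in range(n_cell)]
    values = pd.DataFrame(
        np.hstack([exo, cell]),
        index=pd.Index(mappings["probe_id"], name="probe_id"),
        columns=exo_names + cell_names,
    )
    groups = pd.Series(
        [GROUP_EXOSOME] * n_exo + [GROUP_CELL] * n_cell, index=exo_names + cell_names
    )
    truth = GroundTruth(
        transcripts=pd.DataFrame(
            {
                "transcript_id": tids,
                "status": status,
                "fragmented": fragmented,
                "breakpoint": breakpoint_rel,
                "secretion_gain_applied": gain_applied,
            }
        ),
        probes=pd.DataFrame(
            {
                "probe_id": mappings["probe_id"].to_numpy(),
                "transcript_id": mappings["transcript_id"].to_numpy(),
                "in_fragment": in_fragment,
            }
        ),
    )
    return ExpressionMatrix(values=values, groups=groups), truth


def simulate_bundle(config: SimConfig) -> SimBundle:
    """One-call generation of transcriptome, expression and ground truth."""
    transcripts, mappings = simulate_transcriptome(config)
    matrix, truth = simulate_expression(transcripts, mappings, config)
    return SimBundle(transcripts, mappings, matrix, truth, config)


def write_fixture_bundle(bundle: SimBundle, directory: str | Path) -> dict[str, Path]:
    """Write transcripts/probes/expression/groups/truth TSVs readable by the pipeline."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / f"{name}.tsv"
             for name in ("transcripts", "probes", "expression", "groups", "truth")}
    try:
        write_transcript_models(bundle.transcripts, paths["transcripts"])
        write_probe_table(bundle.mappings, paths["probes"])
        write_expression_table(bundle.matrix, paths["expression"], paths["groups"])
        long = bundle.truth.probes.merge(bundle.truth.transcripts, on="transcript_id")
        long.loc[:, ["transcript_id", "fragmented", "breakpoint", "probe_id", "in_fragment"]
                 ].to_csv(paths["truth"], sep="\t", index=False)
    except OSError as exc:
        raise GenerationError(f"cannot write fixture bundle under {directory}: {exc}") from exc
    return paths
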