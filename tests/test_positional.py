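"""Positional statistics: landscape, pairs, stratified correlations, bias control."""

import numpy as np
import pandas as pd
import pytest

import exofrag as xf
from exofrag.errors import ConfigurationError, InsufficientDataError


def _records_with_mappings(rows):
    """rows: (probe, transcript, rel_loc, region, ecer, exo_mean)."""
    records = pd.DataFrame(
        [
            {
                "probe_id": p,
                "transcript_id": t,
                "mean_exosome": e,
                "mean_cell": 1.0,
                "ecer": c,
            }
            for p, t, _, _, c, e in rows
        ]
    )
    mappings = pd.DataFrame(
        [
            {
                "probe_id": p,
                "transcript_id": t,
                "start": 0,
                "end": 60,
                "relative_location": loc,
                "binned_location": xf.bin_location(loc),
                "region": reg,
            }
            for p, t, loc, reg, _, _ in rows
        ]
    )
    return records, mappings


class TestLandscape:
    def test_singleton_occupies_one_cell(self):
        records, mappings = _records_with_mappings([("P", "T", 0.5, "CDS", 3.0, 42.0)])
        ls = xf.expression_location_landscape(records, mappings)
        assert int(ls.counts.to_numpy().sum()) == 1
        assert ls.mean_expression.loc["[2,4)", 0.5] == 42.0

    def test_two_probes_in_one_cell_average(self):
        records, mappings = _records_with_mappings(
            [("P1", "T", 0.501, "CDS", 3.0, 10.0), ("P2", "T", 0.503, "CDS", 3.5, 20.0)]
        )
        ls = xf.expression_location_landscape(records, mappings)
        assert ls.mean_expression.loc["[2,4)", 0.5] == 15.0

    def test_empty_cells_are_missing_not_zero(self):
        records, mappings = _records_with_mappings([("P", "T", 0.5, "CDS", 3.0, 42.0)])
        ls = xf.expression_location_landscape(records, mappings)
        assert np.isnan(ls.mean_expression.loc["[1,2)", 0.5])

    def test_counts_total_and_fine_rebinning(self, sim_bundle, sim_secretion):
        ls = xf.expression_location_landscape(sim_secretion, sim_bundle.mappings)
        assert int(ls.counts.to_numpy().sum()) == len(sim_secretion)
        fine = xf.expression_location_landscape(
            sim_secretion, sim_bundle.mappings, location_step=0.01
        )
        merged = fine.counts.to_numpy().reshape(len(fine.counts), 50, 2).sum(axis=2)
        np.testing.assert_array_equal(merged, ls.counts.to_numpy())

    def test_planted_bias_concentrates_signal_at_3prime(self, sim_bundle, sim_secretion):
        ls = xf.expression_location_landscape(sim_secretion, sim_bundle.mappings)
        cols = ls.mean_expression.columns.to_numpy(dtype=float)
        strong = ls.mean_expression.loc[["[4,8)", "[8,16)"]]
        counts = ls.counts.loc[["[4,8)", "[8,16)"]]
        hi = (strong.loc[:, cols > 0.8] * counts.loc[:, cols > 0.8]).sum().sum()
        hi /= counts.loc[:, cols > 0.8].sum().sum()
        n_lo = counts.loc[:, cols < 0.2].sum().sum()
        if n_lo:
            lo = (strong.loc[:, cols < 0.2] * counts.loc[:, cols < 0.2]).sum().sum() / n_lo
            assert hi > lo
        # secreted signal lives overwhelmingly in the 3'-ward half
        assert counts.loc[:, cols > 0.5].sum().sum() > 5 * counts.loc[:, cols < 0.5].sum().sum()


class TestRepresentativePair:
    def test_direct_application(self):
        records, mappings = _records_with_mappings(
            [("P1", "T", 0.9, "UTR3", 8.0, 30.0), ("P2", "T", 0.1, "UTR5", 1.0, 10.0)]
        )
        pairs = xf.pair_table(records, mappings)
        row = pairs.iloc[0]
        assert row["hi_probe"] == "P1" and row["lo_probe"] == "P2"
        assert row["hi_is_3prime"] and row["ratio_3p_5p"] == pytest.approx(3.0)
        assert row["delta_location"] == pytest.approx(0.8)

    def test_equal_ecer_tie_breaks_to_more_3prime(self):
        records, mappings = _records_with_mappings(
            [("P1", "T", 0.2, "CDS", 4.0, 10.0), ("P2", "T", 0.7, "CDS", 4.0, 20.0)]
        )
        pairs = xf.pair_table(records, mappings)
        assert pairs.iloc[0]["hi_probe"] == "P2"

    def test_deterministic_under_input_permutation(self, sim_bundle, sim_secretion):
        a = xf.pair_table(sim_secretion, sim_bundle.mappings)
        shuffled = sim_secretion.sample(frac=1.0, random_state=0)
        b = xf.pair_table(shuffled, sim_bundle.mappings)
        pd.testing.assert_frame_equal(a, b)

    def test_min_strength_filters_transcripts(self, sim_bundle, sim_secretion):
        strong = xf.pair_table(sim_secretion, sim_bundle.mappings, min_strength=10.0)
        maxima = sim_secretion.groupby("transcript_id")["ecer"].max()
        assert set(strong["transcript_id"]) == set(maxima.index[maxima >= 10.0]) & set(
            strong["transcript_id"]
        )
        assert len(strong) < len(xf.pair_table(sim_secretion, sim_bundle.mappings))

    def test_single_probe_transcript_rejected(self):
        records, mappings = _records_with_mappings([("P", "T", 0.5, "CDS", 3.0, 1.0)])
        with pytest.raises(InsufficientDataError):
            xf.select_representative_pair(records.merge(mappings))


class TestLocationSecretionCorrelation:
    def test_monotone_relation_gives_tau_one(self):
        rows = [(f"P{i}", f"T{i % 3}", 0.1 * i, "CDS", float(i), 1.0) for i in range(1, 9)]
        records, mappings = _records_with_mappings(rows)
        assert xf.location_secretion_correlation(records, mappings).tau == pytest.approx(1.0)

    def test_planted_bias_gives_significant_positive_tau(self, sim_bundle, sim_secretion):
        res = xf.location_secretion_correlation(sim_secretion, sim_bundle.mappings)
        assert res.tau > 0.2 and res.p_value < 1e-3

    def test_unknown_region_rejected(self, sim_bundle, sim_secretion):
        with pytest.raises(ConfigurationError):
            xf.location_secretion_correlation(sim_secretion, sim_bundle.mappings, region="exon")

    def test_insufficient_records_after_filter(self):
        records, mappings = _records_with_mappings(
            [("P1", "T", 0.9, "UTR3", 8.0, 1.0), ("P2", "T", 0.1, "UTR5", 1.0, 1.0)]
        )
        with pytest.raises(InsufficientDataError):
            xf.location_secretion_correlation(records, mappings, region="cds")


class TestRegionStratified:
    def test_utr_restricted_bias_orders_taus(self):
        cfg = xf.SimConfig(seed=5, n_transcripts=2000, breakpoint_region="utr3")
        b = xf.simulate_bundle(cfg)
        sec = xf.probe_secretion(b.matrix, b.mappings, cutoff=None)
        utr = xf.location_secretion_correlation(sec, b.mappings, region="utr")
        cds = xf.location_secretion_correlation(sec, b.mappings, region="cds")
        assert utr.tau > cds.tau
        assert utr.tau > 0.2 and abs(cds.tau) < 0.1

    def test_uniform_bias_gives_comparable_taus(self):
        # breakpoints anywhere: both strata carry the positional signal
        b = xf.simulate_bundle(xf.SimConfig(seed=6, n_transcripts=2000))
        sec = xf.probe_secretion(b.matrix, b.mappings, cutoff=None)
        utr = xf.location_secretion_correlation(sec, b.mappings, region="utr")
        cds = xf.location_secretion_correlation(sec, b.mappings, region="cds")
        assert utr.tau > 0 and cds.tau > 0

    def test_table_complete_with_missing_strata_labelled(self):
        records, mappings = _records_with_mappings(
            [
                ("P1", "T", 0.9, "UTR3", 8.0, 1.0),
                ("P2", "T", 0.1, "UTR5", 1.0, 1.0),
                ("P3", "U", 0.8, "UTR3", 6.0, 1.0),
                ("P4", "U", 0.2, "UTR5", 2.0, 1.0),
            ]
        )
        table = xf.region_stratified_correlations(records, mappings, cutoffs=[3.0])
        assert set(table["region"]) == {"UTR", "CDS"}
        cds_rows = table.loc[table["region"] == "CDS"]
        assert cds_rows["tau"].isna().all() and (cds_rows["n"] == 0).all()


class TestDesignBiasCheck:
    def test_null_simulation_shows_no_bias(self):
        cfg = xf.SimConfig(
            seed=21, n_transcripts=900, frag_prob=0.0, bias_beta=0.0,
            anchor_terminal_probe=False,
        )
        b = xf.simulate_bundle(cfg)
        sec = xf.probe_secretion(b.matrix, b.mappings, cutoff=None)
        out = xf.probe_design_bias_check(sec, b.mappings)
        for res in out.values():
            assert res is not None and abs(res.tau) <= 0.05

    def test_planted_positional_expression_is_detected(self, sim_bundle):
        # positive control: force expression proportional to location
        sec = xf.probe_secretion(sim_bundle.matrix, sim_bundle.mappings, cutoff=None)
        rigged = sec.merge(
            sim_bundle.mappings[["probe_id", "transcript_id", "relative_location"]],
            on=["probe_id", "transcript_id"],
        )
        rigged["mean_exosome"] = 1.0 + rigged.pop("relative_location")
        out = xf.probe_design_bias_check(rigged, sim_bundle.mappings)
        assert any(res is not None and res.tau > 0.5 for res in out.values())

    def test_empty_stratum_reported_missing(self):
        records, mappings = _records_with_mappings(
            [(f"P{i}", "T", 0.1 * i, "CDS", 5.0 + i, float(i)) for i in range(1, 6)]
        )
        out = xf.probe_design_bias_check(records, mappings, split_cutoff=3.0)
        assert out["ECER<3"] is None and out["ECER>=3"] is not None
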