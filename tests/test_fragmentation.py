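"""Fragmentation classes, cutoff sweeps and fragment-length bounds."""

import numpy as np
import pandas as pd
import pytest

import exofrag as xf
from exofrag.errors import InsufficientDataError, UndefinedResultError, ValidationError


class TestClassify:
    @pytest.mark.parametrize(
        "n_secreted,n_probes,klass",
        [
            (1, 2, xf.HALF),
            (2, 3, xf.MAJORITY),
            (1, 3, xf.MINORITY),
            (0, 5, xf.NOT_SECRETED),
            (5, 5, xf.ALL_SECRETED),
        ],
    )
    def test_examples(self, n_secreted, n_probes, klass):
        assert xf.classify_transcript(n_secreted, n_probes) == klass

    def test_exhaustive_agreement_with_majority_comparison(self):
        for n in range(2, 9):
            for s in range(n + 1):
                klass = xf.classify_transcript(s, n)
                if s == 0:
                    expected = xf.NOT_SECRETED
                elif s == n:
                    expected = xf.ALL_SECRETED
                elif 2 * s == n:
                    expected = xf.HALF
                elif 2 * s > n:
                    expected = xf.MAJORITY
                else:
                    expected = xf.MINORITY
                assert klass == expected

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            xf.classify_transcript(1, 1)
        with pytest.raises(ValidationError):
            xf.classify_transcript(4, 3)


def _records(spec):
    """spec: {transcript: [ecer per probe]} -> secretion table."""
    rows = []
    for tid, ecers in spec.items():
        for i, e in enumerate(ecers):
            rows.append(
                {
                    "probe_id": f"{tid}_p{i}",
                    "transcript_id": tid,
                    "mean_exosome": e,
                    "mean_cell": 1.0,
                    "ecer": float(e),
                }
            )
    return pd.DataFrame(rows)


class TestClassifyAll:
    def test_toy_counts(self):
        rec = _records({"A": [5, 4], "B": [5, 1], "C": [1, 1, 1]})
        _, counts = xf.classify_all(rec, cutoff=3.0)
        assert counts[xf.ALL_SECRETED] == 1
        assert counts[xf.HALF] == 1
        assert counts[xf.NOT_SECRETED] == 1

    def test_everything_below_cutoff(self):
        rec = _records({"A": [1, 2], "B": [0.5, 0.1, 2.0]})
        classes, counts = xf.classify_all(rec, cutoff=3.0)
        assert (classes["klass"] == xf.NOT_SECRETED).all()
        assert counts.sum() == 2

    def test_partition_counts_sum(self, sim_secretion):
        classes, counts = xf.classify_all(sim_secretion)
        assert counts.sum() == classes["transcript_id"].nunique()

    def test_half_breakdown(self):
        rec = _records({"A": [5, 1], "B": [5, 1], "C": [5, 5, 1, 1]})
        classes, _ = xf.classify_all(rec, cutoff=3.0)
        breakdown = xf.half_class_breakdown(classes)
        assert breakdown.to_dict() == {1: 2, 2: 1}

    def test_single_probe_transcript_rejected(self):
        rec = _records({"A": [5]})
        with pytest.raises(ValidationError, match="filter_min_probes"):
            xf.classify_all(rec, cutoff=3.0)


class TestFragmentedFraction:
    def test_intact_only_is_zero(self):
        assert xf.fragmented_fraction({xf.ALL_SECRETED: 10}) == 0.0

    def test_fragmented_only_is_hundred(self):
        assert xf.fragmented_fraction({xf.ALL_SECRETED: 0, xf.HALF: 5}) == 100.0

    def test_not_secreted_excluded_from_denominator(self):
        counts = {xf.ALL_SECRETED: 1, xf.HALF: 1, xf.NOT_SECRETED: 98}
        assert xf.fragmented_fraction(counts) == 50.0

    def test_zero_secreted_undefined(self):
        with pytest.raises(UndefinedResultError):
            xf.fragmented_fraction({xf.NOT_SECRETED: 5})

    def test_invariant_to_integer_scaling(self):
        counts = {xf.ALL_SECRETED: 3, xf.HALF: 4, xf.MAJORITY: 2, xf.MINORITY: 1}
        scaled = {k: 7 * v for k, v in counts.items()}
        assert xf.fragmented_fraction(counts) == pytest.approx(
            xf.fragmented_fraction(scaled)
        )


class TestCurve:
    def test_single_cutoff_matches_classify_all(self, sim_secretion):
        curve = xf.class_fraction_curve(sim_secretion, [3.0])
        _, counts = xf.classify_all(sim_secretion, cutoff=3.0)
        n_sec = counts[list(xf.SECRETED_CLASSES)].sum()
        for k in xf.SECRETED_CLASSES:
            assert curve.fractions.loc[3.0, k] == pytest.approx(counts[k] / n_sec)

    def test_fractions_sum_to_one_and_secreted_nonincreasing(self, sim_secretion):
        curve = xf.class_fraction_curve(sim_secretion, range(1, 17))
        sums = curve.fractions.dropna().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)
        n = curve.counts["n_secreted_transcripts"].to_numpy()
        assert (np.diff(n) <= 0).all()

    def test_cutoff_beyond_max_ecer_is_missing_with_warning(self, sim_secretion):
        huge = float(sim_secretion["ecer"].max() * 2)
        with pytest.warns(UserWarning, match="no secreted"):
            curve = xf.class_fraction_curve(sim_secretion, [1.0, 2.0, huge])
        assert curve.fractions.loc[huge].isna().all()

    def test_invalid_grids_rejected(self, sim_secretion):
        from exofrag.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            xf.class_fraction_curve(sim_secretion, [3.0, 2.0])
        with pytest.raises(ConfigurationError):
            xf.class_fraction_curve(sim_secretion, [0.0, 1.0])


class TestCurveTrend:
    def _curve_from(self, fractions):
        idx = pd.Index([float(i) for i in range(1, len(fractions) + 1)], name="cutoff")
        df = pd.DataFrame({k: fractions for k in xf.SECRETED_CLASSES}, index=idx)
        return xf.ClassFractionCurve(tuple(idx), df, df)

    def test_strictly_increasing_gives_tau_one(self):
        curve = self._curve_from(np.linspace(0.1, 0.9, 10))
        assert xf.curve_trend(curve, xf.HALF).tau == pytest.approx(1.0)

    def test_strictly_decreasing_gives_tau_minus_one(self):
        curve = self._curve_from(np.linspace(0.9, 0.1, 10))
        assert xf.curve_trend(curve, xf.ALL_SECRETED).tau == pytest.approx(-1.0)

    def test_too_few_points_rejected(self):
        curve = self._curve_from([0.1, 0.2])
        with pytest.raises(InsufficientDataError):
            xf.curve_trend(curve, xf.HALF)


class TestFragmentLengthBounds:
    """Constructed 2000 nt transcript, UTR3 = [1400, 2000), probes ending at
    1500 / 1700 / 1900 with ECER 1 / 5 / 20."""

    @pytest.fixture
    def toy(self):
        transcripts = pd.DataFrame(
            {"transcript_id": ["T"], "length": [2000], "cds_start": [200], "cds_end": [1400]}
        )
        probes = pd.DataFrame(
            {
                "probe_id": ["u1", "u2", "u3"],
                "transcript_id": "T",
                "start": [1440, 1640, 1840],
                "end": [1500, 1700, 1900],
            }
        )
        mappings = xf.annotate_probes(probes, transcripts)
        records = pd.DataFrame(
            {
                "probe_id": ["u1", "u2", "u3"],
                "transcript_id": "T",
                "mean_exosome": [1.0, 5.0, 20.0],
                "mean_cell": [1.0, 1.0, 1.0],
                "ecer": [1.0, 5.0, 20.0],
            }
        )
        return records, mappings, transcripts

    def test_bound_limited_by_most_3prime_nonsecreted_probe(self, toy):
        summary = xf.fragment_length_bounds(*toy, cutoff=3.0)
        assert summary.bounds.loc[0, "bound"] == 500  # 2000 - 1500

    def test_bound_shrinks_when_cutoff_drops_middle_probe(self, toy):
        summary = xf.fragment_length_bounds(*toy, cutoff=10.0)
        assert summary.bounds.loc[0, "bound"] == 300  # 2000 - 1700

    def test_all_secreted_limit_is_utr_border(self, toy):
        summary = xf.fragment_length_bounds(*toy, cutoff=0.5)
        assert summary.bounds.loc[0, "bound"] == 600  # full UTR3

    def test_gene_border_flag_extends_limit(self, toy):
        summary = xf.fragment_length_bounds(*toy, cutoff=0.5, limit_border="gene")
        assert summary.bounds.loc[0, "bound"] == 2000

    def test_zero_secreted_utr_probes_excluded(self, toy):
        records, mappings, transcripts = toy
        with pytest.warns(UserWarning):
            summary = xf.fragment_length_bounds(
                records, mappings, transcripts, cutoff=50.0
            )
        assert summary.n_transcripts == 0 and np.isnan(summary.median_length)

    def test_min_probe_and_utr_length_filters(self, toy):
        records, mappings, transcripts = toy
        with pytest.warns(UserWarning):
            assert (
                xf.fragment_length_bounds(
                    records, mappings, transcripts, cutoff=3.0, min_probes_per_utr=4
                ).n_transcripts
                == 0
            )
        with pytest.warns(UserWarning):
            assert (
                xf.fragment_length_bounds(
                    records, mappings, transcripts, cutoff=3.0, max_utr_length=500
                ).n_transcripts
                == 0
            )

    def test_bounds_within_utr_and_nonincreasing_in_cutoff(self, sim_bundle, sim_secretion):
        prev = None
        for cutoff in (1.0, 2.0, 4.0, 8.0):
            s = xf.fragment_length_bounds(
                sim_secretion, sim_bundle.mappings, sim_bundle.transcripts, cutoff=cutoff
            )
            merged = s.bounds.merge(sim_bundle.transcripts, on="transcript_id")
            assert (s.bounds["bound"] > 0).all()
            assert (
                s.bounds["bound"] <= merged["length"] - merged["cds_end"]
            ).all()
            if prev is not None:
                joined = prev.merge(s.bounds, on="transcript_id", suffixes=("_lo", "_hi"))
                assert (joined["bound_hi"] <= joined["bound_lo"]).all()
            prev = s.bounds
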