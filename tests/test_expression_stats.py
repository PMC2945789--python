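"""qPCR ratios, nCounter normalization, regulation calls, discordance, correlation."""

import io

import numpy as np
import pandas as pd
import pytest

from asu import (
    ExpressionTable,
    ProbeClass,
    QpcrMeasurement,
    Regulation,
    RegulationCall,
    call_regulation,
    count_discordant_pairs,
    ncounter_normalize,
    qpcr_log_ratio,
    read_expression_table,
    sense_antisense_correlation,
    write_expression_table,
)


def meas(target, orient, primer, rep, cond, q):
    return QpcrMeasurement(target, orient, primer, rep, cond, q)


class TestQpcrLogRatio:
    def test_fourfold_induction_is_log2_2(self):
        rows = [
            meas("T", "sense", "p1", "r1", "ESP", 400),
            meas("T", "sense", "p1", "r1", "ML", 100),
            meas("PDA1", "control", "p1", "r1", "ESP", 100),
            meas("PDA1", "control", "p1", "r1", "ML", 100),
        ]
        mean, sd = qpcr_log_ratio(rows, "T", "ESP", "ML")
        assert mean == pytest.approx(2.0) and sd == 0.0

    def test_no_change_is_zero(self):
        rows = [
            meas("T", "sense", "p1", "r1", "ESP", 250),
            meas("T", "sense", "p1", "r1", "ML", 250),
            meas("PDA1", "control", "p1", "r1", "ESP", 100),
            meas("PDA1", "control", "p1", "r1", "ML", 100),
        ]
        mean, _ = qpcr_log_ratio(rows, "T", "ESP", "ML")
        assert mean == 0.0

    def test_mean_and_sd_across_strata(self):
        rows = []
        for primer, fold in (("p1", 4), ("p2", 2)):
            rows += [
                meas("T", "sense", primer, "r1", "ESP", 100 * fold),
                meas("T", "sense", primer, "r1", "ML", 100),
                meas("PDA1", "control", primer, "r1", "ESP", 100),
                meas("PDA1", "control", primer, "r1", "ML", 100),
            ]
        mean, sd = qpcr_log_ratio(rows, "T", "ESP", "ML")
        assert mean == pytest.approx(1.5)
        assert sd == pytest.approx(np.std([2.0, 1.0], ddof=1))

    def test_missing_control_names_the_stratum(self):
        rows = [
            meas("T", "sense", "p1", "r1", "ESP", 400),
            meas("T", "sense", "p1", "r1", "ML", 100),
            meas("PDA1", "control", "p1", "r1", "ESP", 100),
        ]
        with pytest.raises(ValueError, match="p1"):
            qpcr_log_ratio(rows, "T", "ESP", "ML")


def toy_table():
    counts = pd.DataFrame(
        {
            "S1": {"T1": 100.0, "Spike1": 1000.0, "Ctrl1": 500.0},
            "S2": {"T1": 90.0, "Spike1": 2000.0, "Ctrl1": 600.0},
        }
    )
    classes = {
        "T1": ProbeClass.TARGET_SENSE,
        "Spike1": ProbeClass.POSITIVE_SPIKE,
        "Ctrl1": ProbeClass.CONTROL_GENE,
    }
    return ExpressionTable(counts, classes)


class TestNcounterNormalize:
    def test_two_factor_hand_computation(self):
        # S2: spike step scales by 1000/2000 = 0.5 -> controls 600*0.5 = 300;
        # control step scales mRNA probes by 500/300 -> target 90*0.5*(500/300) = 75
        norm = ncounter_normalize(toy_table())
        assert norm.counts.loc["T1", "S2"] == pytest.approx(75.0)
        assert norm.counts.loc["T1", "S1"] == pytest.approx(100.0)  # ref untouched

    def test_identical_samples_unchanged(self):
        counts = pd.DataFrame({"S1": {"T1": 10.0, "Spike1": 5.0, "Ctrl1": 7.0}})
        counts["S2"] = counts["S1"]
        classes = {
            "T1": ProbeClass.TARGET_SENSE,
            "Spike1": ProbeClass.POSITIVE_SPIKE,
            "Ctrl1": ProbeClass.CONTROL_GENE,
        }
        norm = ncounter_normalize(ExpressionTable(counts, classes))
        pd.testing.assert_frame_equal(norm.counts, counts)

    def test_spike_sums_and_control_geomeans_equalized(self):
        norm = ncounter_normalize(toy_table())
        spikes = norm.counts.loc[norm.probes_of(ProbeClass.POSITIVE_SPIKE)].sum()
        ctrls = norm.counts.loc[norm.probes_of(ProbeClass.CONTROL_GENE)]
        geo = np.exp(np.log(ctrls).mean())
        assert spikes["S1"] == pytest.approx(spikes["S2"], rel=1e-12)
        assert geo["S1"] == pytest.approx(geo["S2"], rel=1e-12)

    def test_idempotent(self):
        once = ncounter_normalize(toy_table())
        twice = ncounter_normalize(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_zero_spike_sum_is_an_error(self):
        table = toy_table()
        table.counts.loc["Spike1", "S2"] = 0.0
        with pytest.raises(ValueError, match="spike"):
            ncounter_normalize(table)

    def test_table_requires_spike_and_control(self):
        counts = pd.DataFrame({"S1": {"T1": 1.0}})
        with pytest.raises(ValueError):
            ExpressionTable(counts, {"T1": ProbeClass.TARGET_SENSE})


class TestCallRegulation:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(1.5, Regulation.INDUCED), (-1.5, Regulation.REPRESSED), (0.2, Regulation.NO_CHANGE),
         (1.0, Regulation.INDUCED), (-1.0, Regulation.REPRESSED)],
    )
    def test_threshold_calls(self, ratio, expected):
        assert call_regulation(ratio) == expected

    def test_antisymmetry(self):
        mirror = {
            Regulation.INDUCED: Regulation.REPRESSED,
            Regulation.REPRESSED: Regulation.INDUCED,
            Regulation.NO_CHANGE: Regulation.NO_CHANGE,
        }
        for x in np.linspace(-3, 3, 25):
            assert call_regulation(-x) == mirror[call_regulation(float(x))]


def _call(target, orient, cond, reg):
    value = {"induced": 2.0, "repressed": -2.0, "no_change": 0.0}[reg]
    return RegulationCall(target, orient, cond, value, Regulation(reg))


class TestDiscordance:
    def test_direct_counts(self):
        calls = [
            _call("t1", "sense", "ESP", "induced"), _call("t1", "antisense", "ESP", "repressed"),
            _call("t2", "sense", "ESP", "induced"), _call("t2", "antisense", "ESP", "repressed"),
            _call("t3", "sense", "ESP", "repressed"), _call("t3", "antisense", "ESP", "induced"),
        ]
        counts = count_discordant_pairs(calls)
        assert counts.sense_up_as_down["ESP"] == 2
        assert counts.sense_down_as_up["ESP"] == 1

    def test_all_no_change(self):
        calls = [
            _call("t1", "sense", "ESP", "no_change"),
            _call("t1", "antisense", "ESP", "no_change"),
        ]
        counts = count_discordant_pairs(calls)
        assert counts.sense_up_as_down == {"ESP": 0, "either": 0, "both": 0}

    def test_union_and_intersection_semantics(self):
        calls = []
        # t1 discordant in both conditions, t2 only in HS
        for cond in ("ESP", "HS"):
            calls += [_call("t1", "sense", cond, "induced"),
                      _call("t1", "antisense", cond, "repressed")]
        calls += [_call("t2", "sense", "ESP", "no_change"),
                  _call("t2", "antisense", "ESP", "no_change"),
                  _call("t2", "sense", "HS", "induced"),
                  _call("t2", "antisense", "HS", "repressed")]
        counts = count_discordant_pairs(calls)
        ud = counts.sense_up_as_down
        assert (ud["ESP"], ud["HS"], ud["either"], ud["both"]) == (1, 2, 2, 1)
        assert ud["either"] <= ud["ESP"] + ud["HS"]
        assert ud["both"] <= min(ud["ESP"], ud["HS"])

    def test_unpaired_target_is_an_error(self):
        with pytest.raises(ValueError, match="t9"):
            count_discordant_pairs([_call("t9", "sense", "ESP", "induced")])


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        pairs = [(1, -1), (2, -2), (3, -3)]
        assert sense_antisense_correlation(pairs) == pytest.approx(-1.0)

    def test_null_simulation_is_near_zero(self):
        rng = np.random.default_rng(4)
        pairs = list(zip(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)))
        assert abs(sense_antisense_correlation(pairs)) < 0.1

    def test_spearman_flag(self):
        pairs = [(1, -1), (2, -4), (3, -9), (4, -16)]
        assert sense_antisense_correlation(pairs, method="spearman") == pytest.approx(-1.0)


def test_expression_table_tsv_round_trip(tmp_path):
    table = toy_table()
    path = tmp_path / "t.tsv"
    write_expression_table(table, path)
    back = read_expression_table(path)
    pd.testing.assert_frame_equal(back.counts, table.counts)
    assert list(back.probe_class) == list(table.probe_class)
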