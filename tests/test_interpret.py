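"""Local/traded classification, Fisher's exact test, qualitative dates."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from codprov.affinity import AffinityResult
from codprov.interpret import (
    LOCAL,
    TRADED,
    UNCLASSIFIED,
    ContingencyTable2x2,
    DateInterval,
    DateParseError,
    TradeClassification,
    classify_trade_status,
    fisher_exact_2x2,
    parse_qualitative_date,
    test_element_origin_association as element_origin_association,
)

from conftest import fisher_enumeration_oracle


def _affinity(haplogroup, origin, sid="S"):
    return AffinityResult(
        specimen_id=sid,
        raw={},
        normalized={},
        merged={},
        haplogroup=haplogroup,
        putative_origin=origin,
        loci_used=["LG1", "LG2", "LG7", "LG12"],
    )


class TestClassifyTradeStatus:
    def test_confident_north_central_north_sea_is_local(self):
        aff = _affinity({"north_central": 0.90, "northernmost": 0.10}, ["North Sea"])
        assert classify_trade_status(aff, "eastern_atlantic").status == LOCAL

    def test_confident_northernmost_iceland_is_traded(self):
        aff = _affinity({"northernmost": 0.85, "north_central": 0.15}, ["Iceland"])
        assert classify_trade_status(aff, "eastern_atlantic").status == TRADED

    def test_weak_group_share_is_unclassified(self):
        aff = _affinity({"north_central": 0.60, "northernmost": 0.40}, ["North Sea"])
        c = classify_trade_status(aff, "eastern_atlantic")
        assert c.status == UNCLASSIFIED
        assert "below" in c.basis

    def test_western_assignment_is_traded_without_affinity(self):
        assert classify_trade_status(None, "western_atlantic").status == TRADED

    def test_norwegian_coast_member_of_north_central_is_traded(self):
        """Within the north-central group, a remote member population
        (Norwegian Coast) still classifies as traded: the member, not the
        group, drives the local/traded sets."""
        aff = _affinity(
            {"north_central": 0.90, "northernmost": 0.10}, ["Norwegian Coast Lofoten"]
        )
        assert classify_trade_status(aff, "eastern_atlantic").status == TRADED

    def test_origin_spanning_both_sets_is_unclassified(self):
        aff = _affinity(
            {"north_central": 0.90, "northernmost": 0.10},
            ["North Sea", "Norwegian Coast Lofoten"],
        )
        assert classify_trade_status(aff, "eastern_atlantic").status == UNCLASSIFIED

    def test_missing_haplogroups_unclassified_with_reason(self):
        aff = _affinity({}, [])
        c = classify_trade_status(aff, "eastern_atlantic")
        assert c.status == UNCLASSIFIED and "haplogroup" in c.basis


class TestFisherExact:
    def test_uniform_table_has_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_diagonal_two_by_two(self):
        # margins (2,2)/(2,2): P(x=0) = P(x=2) = 1/6, so p = 1/3
        assert fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 2)) == pytest.approx(1 / 3, abs=1e-12)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            ContingencyTable2x2(0, 0, 0, 0)

    def test_matches_enumeration_oracle_for_all_small_tables(self):
        """Every 2x2 table with N <= 20 agrees with the independent
        hypergeometric full-enumeration oracle."""
        for n in range(1, 21):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        got = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
                        want = fisher_enumeration_oracle(a, b, c, d)
                        assert got == pytest.approx(want, abs=1e-9), (a, b, c, d)

    def test_symmetry_under_row_column_swap_and_transpose(self):
        for a, b, c, d in [(3, 1, 2, 5), (0, 4, 6, 1), (2, 2, 3, 3)]:
            p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert fisher_exact_2x2(ContingencyTable2x2(c, d, a, b)) == pytest.approx(p)
            assert fisher_exact_2x2(ContingencyTable2x2(b, a, d, c)) == pytest.approx(p)
            assert fisher_exact_2x2(ContingencyTable2x2(a, c, b, d)) == pytest.approx(p)


class TestElementOriginAssociation:
    def test_perfect_association_rejects(self):
        records = [("cranial", TradeClassification(f"c{i}", LOCAL, "")) for i in range(6)]
        records += [("postcranial", TradeClassification(f"p{i}", TRADED, "")) for i in range(6)]
        table, p = element_origin_association(records)
        assert table.as_list() == [[6, 0], [0, 6]]
        assert p < 0.01

    def test_unclassified_records_excluded(self):
        records = [
            ("cranial", TradeClassification("a", LOCAL, "")),
            ("cranial", TradeClassification("b", TRADED, "")),
            ("postcranial", TradeClassification("c", TRADED, "")),
            ("postcranial", TradeClassification("d", LOCAL, "")),
            ("postcranial", TradeClassification("e", UNCLASSIFIED, "")),
        ]
        table, _ = element_origin_association(records)
        assert sum(itertools.chain(*table.as_list())) == 4

    def test_degenerate_table_rejected(self):
        records = [("cranial", TradeClassification("a", LOCAL, ""))] * 3
        with pytest.raises(ValueError, match="degenerate"):
            element_origin_association(records)

    def test_type_i_error_controlled_under_independence(self):
        """Statuses assigned independently of element: the exact test is
        conservative, so rejection rates stay at or below nominal levels
        (small-sample p-values are discrete and stochastically larger than
        uniform)."""
        rng = np.random.default_rng(0)
        pvals = []
        while len(pvals) < 1000:
            elements = rng.random(22) < 0.5
            statuses = rng.random(22) < 0.5
            a = int(np.sum(elements & statuses))
            b = int(np.sum(elements & ~statuses))
            c = int(np.sum(~elements & statuses))
            d = int(np.sum(~elements & ~statuses))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            pvals.append(fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)))
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.10, 0.25):
            assert np.mean(pvals <= alpha) <= alpha + 0.02


class TestParseQualitativeDate:
    @pytest.mark.parametrize(
        "text, start, end",
        [
            ("early eleventh century", 1000, 1050),
            ("mid thirteenth century", 1225, 1275),
            ("late fifteenth–early sixteenth centuries", 1450, 1550),
            ("late fourteenth century", 1350, 1400),
            ("seventeenth century", 1600, 1700),
            ("seventeenth–eighteenth centuries", 1600, 1800),
            ("ca seventeenth century", 1600, 1700),
            ("eleventh to twelfth centuries", 1000, 1200),
            ("Early Eleventh Century", 1000, 1050),
        ],
    )
    def test_grammar(self, text, start, end):
        iv = parse_qualitative_date(text)
        assert (iv.start_year, iv.end_year) == (start, end)

    @pytest.mark.parametrize("text", ["", "sometime old", "eleventy century", "early century"])
    def test_unparseable_text_rejected(self, text):
        with pytest.raises(DateParseError):
            parse_qualitative_date(text)

    def test_interval_must_be_nonempty(self):
        with pytest.raises(ValueError):
            DateInterval(1500, 1500)

    @given(
        q1=st.sampled_from(["", "early ", "mid ", "late "]),
        q2=st.sampled_from(["", "early ", "mid ", "late "]),
        c1=st.integers(1, 20),
        c2=st.integers(1, 20),
    )
    def test_total_on_grammar_with_nonempty_intervals(self, q1, q2, c1, c2):
        ordinals = [
            "first", "second", "third", "fourth", "fifth", "sixth", "seventh",
            "eighth", "ninth", "tenth", "eleventh", "twelfth", "thirteenth",
            "fourteenth", "fifteenth", "sixteenth", "seventeenth", "eighteenth",
            "nineteenth", "twentieth",
        ]
        text = f"{q1}{ordinals[c1 - 1]}–{q2}{ordinals[c2 - 1]} centuries"
        iv = parse_qualitative_date(text)
        assert iv.start_year < iv.end_year
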