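"""Consensus voting, outcome classification, summaries, and outliers."""

import io
import itertools

import pandas as pd
import pytest

from qsconsensus.annotations import (
    QSAnnotation,
    Source,
    Status,
    Stoichiometry,
    parse_stoichiometry,
    parse_symmetry,
)
from qsconsensus.consensus import (
    BenchmarkEntry,
    agreement_analysis,
    benchmark_summary,
    classify_outcome,
    collect_votes,
    consensus_predict,
    flag_outliers,
    read_wide_table,
    write_wide_table,
)


def ann(stoich=None, sym=None, source="PDB", order_only=False):
    return QSAnnotation(
        stoichiometry=parse_stoichiometry(stoich) if stoich else None,
        symmetry=parse_symmetry(sym) if sym else None,
        source=Source(source),
        order_only=order_only,
    )


def tm_order(n):
    return QSAnnotation(
        stoichiometry=Stoichiometry({"A": n}), source=Source.TM, order_only=True
    )


def entry(pdb_id, reference, methods, archive=None):
    return BenchmarkEntry(
        pdb_id=pdb_id,
        reference=reference,
        method_results=methods,
        pdb_annotation=archive,
    )


class TestCollectVotes:
    def test_not_available_dropped(self):
        e = entry(
            "1abc",
            ann("A2", "C2"),
            {
                "SC": QSAnnotation.not_available("SC"),
                "TM": tm_order(2),
                "PISA": ann("A2", "C2", "PISA"),
                "EPPIC": ann("A2", "C2", "EPPIC"),
            },
        )
        assert len(collect_votes(e)) == 3

    def test_all_na_empty(self):
        e = entry(
            "1abc",
            ann("A2", "C2"),
            {m: QSAnnotation.not_available(m) for m in ("SC", "TM", "PISA", "EPPIC")},
        )
        assert collect_votes(e) == []

    def test_inconclusive_excluded_by_default_retained_on_request(self):
        e = entry(
            "1abc",
            ann("A2", "C2"),
            {
                "PISA": QSAnnotation.inconclusive("PISA"),
                "SC": ann("A2", "C2", "SC"),
                "EPPIC": ann("A2", "C2", "EPPIC"),
                "TM": tm_order(2),
            },
        )
        assert len(collect_votes(e)) == 3
        assert len(collect_votes(e, count_abstentions=True)) == 4

    def test_method_subset(self):
        e = entry(
            "1abc",
            ann("A2", "C2"),
            {m: ann("A2", "C2", m) if m != "TM" else tm_order(2)
             for m in ("SC", "TM", "PISA", "EPPIC")},
        )
        assert len(collect_votes(e, methods=("SC", "PISA", "EPPIC"))) == 3


class TestConsensusPredict:
    def test_deposition_error_case(self):
        # archive says monomer; all four methods say dimer -> consensus dimer C2
        votes = [
            ann("A2", "C2", "SC"),
            ann("A2", "C2", "PISA"),
            ann("A2", "C2", "EPPIC"),
            tm_order(2),
        ]
        consensus = consensus_predict(votes)
        assert consensus.status is Status.PREDICTED
        assert str(consensus.stoichiometry) == "A2"
        assert str(consensus.symmetry) == "C2"

    def test_two_two_split_inconclusive(self):
        votes = [
            ann("A2", "C2", "SC"),
            ann("A2", "C2", "PISA"),
            ann("A4", "D2", "EPPIC"),
            tm_order(4),
        ]
        consensus = consensus_predict(votes)
        # stoichiometry 2-2 (A2 vs A4+order-4), symmetry 2-1 C2 wins
        assert consensus.stoichiometry is None
        assert str(consensus.symmetry) == "C2"

    def test_singleton_vote(self):
        consensus = consensus_predict([ann("A2", "C2", "EPPIC")])
        assert str(consensus.stoichiometry) == "A2" and str(consensus.symmetry) == "C2"

    def test_empty_votes_not_available(self):
        assert consensus_predict([]).status is Status.NOT_AVAILABLE

    def test_order_only_vote_supports_matching_formula(self):
        # PISA+EPPIC say A2B2; TM's "tetramer" supports it; SC says A2
        votes = [
            ann("A2B2", "D2", "PISA"),
            ann("A2B2", "D2", "EPPIC"),
            tm_order(4),
            ann("A2", "C2", "SC"),
        ]
        consensus = consensus_predict(votes)
        assert str(consensus.stoichiometry) == "A2B2"
        assert not consensus.order_only

    def test_order_only_winner_flagged(self):
        consensus = consensus_predict([tm_order(2), tm_order(2), ann("A4", "D2", "SC")])
        assert consensus.order_only
        assert consensus.stoichiometry.total_subunits == 2

    def test_shared_order_support_tie_is_inconclusive(self):
        # A4 and A2B2 each get one full vote; TM order-4 lifts both to 2 of 3
        votes = [ann("A4", "D2", "PISA"), ann("A2B2", "D2", "EPPIC"), tm_order(4)]
        consensus = consensus_predict(votes)
        assert consensus.stoichiometry is None
        assert str(consensus.symmetry) == "D2"

    def test_vote_order_invariance(self):
        votes = [
            ann("A2", "C2", "SC"),
            ann("A4", "D2", "PISA"),
            ann("A2", "C2", "EPPIC"),
            tm_order(2),
        ]
        results = set()
        for perm in itertools.permutations(votes):
            c = consensus_predict(list(perm))
            results.add((str(c.stoichiometry), str(c.symmetry), c.status.value))
        assert len(results) == 1

    def test_removing_dissenting_vote_preserves_winner(self):
        votes = [
            ann("A2", "C2", "SC"),
            ann("A2", "C2", "PISA"),
            ann("A2", "C2", "EPPIC"),
            ann("A4", "D2", "PISA"),
        ]
        with_dissent = consensus_predict(votes)
        without = consensus_predict(votes[:3])
        assert str(with_dissent.stoichiometry) == str(without.stoichiometry) == "A2"


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "prediction, reference, outcome",
        [
            (ann("A2", "C2"), ann("A2", "C2"), "correct"),
            (ann("A2", "C1"), ann("A2", "C2"), "inconclusive"),  # half right
            (ann("A", "C1"), ann("A2", "C2"), "incorrect"),
            (tm_order(2), ann("A2", "C2"), "correct"),  # order-only comparison
            (tm_order(3), ann("A2", "C2"), "incorrect"),
            (QSAnnotation.inconclusive("PISA"), ann("A2", "C2"), "inconclusive"),
            (QSAnnotation.not_available("SC"), ann("A2", "C2"), "not_available"),
        ],
    )
    def test_examples(self, prediction, reference, outcome):
        assert classify_outcome(prediction, reference).outcome == outcome

    def test_reference_must_carry_stoichiometry(self):
        with pytest.raises(ValueError):
            classify_outcome(ann("A2", "C2"), QSAnnotation(symmetry=parse_symmetry("C2")))


def all_correct_entries(n=4):
    return [
        entry(
            f"e{i}",
            ann("A2", "C2"),
            {
                "SC": ann("A2", "C2", "SC"),
                "TM": tm_order(2),
                "PISA": ann("A2", "C2", "PISA"),
                "EPPIC": ann("A2", "C2", "EPPIC"),
            },
            archive=ann("A2", "C2"),
        )
        for i in range(n)
    ]


class TestBenchmarkSummary:
    def test_all_correct_fixture(self):
        summary = benchmark_summary(all_correct_entries())
        assert summary.loc["CONSENSUS", "pct_correct"] == 100.0
        for method in ("SC", "TM", "PISA", "EPPIC"):
            assert summary.loc[method, "pct_correct"] == 100.0

    def test_rows_sum_to_100(self):
        entries = all_correct_entries() + [
            entry(
                "mix",
                ann("A2", "C2"),
                {
                    "SC": QSAnnotation.not_available("SC"),
                    "TM": QSAnnotation.inconclusive("TM"),
                    "PISA": ann("A", "C1", "PISA"),
                    "EPPIC": ann("A2", "C2", "EPPIC"),
                },
            )
        ]
        summary = benchmark_summary(entries)
        assert (summary.sum(axis=1).round(9) == 100.0).all()

    def test_single_entry_rates_degenerate(self):
        summary = benchmark_summary(all_correct_entries(1))
        assert set(summary.values.ravel()) <= {0.0, 100.0}

    def test_empty_benchmark_rejected(self):
        with pytest.raises(ValueError):
            benchmark_summary([])

    def test_three_method_consensus_excludes_tm(self):
        # TM is the lone dissenter; excluding it must not change the winner
        entries = [
            entry(
                "x",
                ann("A2", "C2"),
                {
                    "SC": ann("A2", "C2", "SC"),
                    "TM": tm_order(6),
                    "PISA": ann("A2", "C2", "PISA"),
                    "EPPIC": ann("A2", "C2", "EPPIC"),
                },
            )
        ]
        four = benchmark_summary(entries)
        three = benchmark_summary(entries, methods=("SC", "PISA", "EPPIC"))
        assert four.loc["CONSENSUS", "pct_correct"] == 100.0
        assert three.loc["CONSENSUS", "pct_correct"] == 100.0
        assert "TM" not in three.index


class TestAgreementAnalysis:
    def test_exact_subset_attribution(self):
        entries = [
            # all four correct -> counted once under the full 4-set
            all_correct_entries(1)[0],
            # only PISA and EPPIC wrong
            entry(
                "w",
                ann("A2", "C2"),
                {
                    "SC": ann("A2", "C2", "SC"),
                    "TM": tm_order(2),
                    "PISA": ann("A", "C1", "PISA"),
                    "EPPIC": ann("A", "C1", "EPPIC"),
                },
            ),
        ]
        table = agreement_analysis(entries)
        assert table["correct"][frozenset({"SC", "TM", "PISA", "EPPIC"})] == 1
        assert table["correct"][frozenset({"SC", "TM"})] == 1
        assert table["incorrect"][frozenset({"PISA", "EPPIC"})] == 1
        # disjoint subsets within a category sum to entries having it
        assert sum(table["correct"].values()) == 2

    def test_empty_benchmark(self):
        table = agreement_analysis([])
        assert all(not v for v in table.values())


class TestFlagOutliers:
    def test_consensus_contradicting_archive_is_outlier(self):
        # archive deposited monomer, methods agree on dimer
        e = entry(
            "1z77",
            ann("A2", "C2"),
            {
                "SC": ann("A2", "C2", "SC"),
                "PISA": ann("A2", "C2", "PISA"),
                "EPPIC": ann("A2", "C2", "EPPIC"),
                "TM": tm_order(2),
            },
            archive=ann("A", "C1"),
        )
        flags, fraction = flag_outliers([e])
        assert flags["1z77"] is True and fraction == 1.0

    def test_agreement_is_not_outlier(self):
        flags, fraction = flag_outliers(all_correct_entries(2))
        assert not any(flags.values()) and fraction == 0.0

    def test_inconclusive_consensus_not_outlier(self):
        e = entry(
            "tie",
            ann("A2", "C2"),
            {"SC": ann("A2", "C2", "SC"), "PISA": ann("A4", "D2", "PISA")},
            archive=ann("A", "C1"),
        )
        flags, fraction = flag_outliers([e])
        assert flags["tie"] is False and fraction == 0.0


class TestWideTable:
    def test_round_trip(self):
        entries = all_correct_entries(3)
        entries[1].method_results["PISA"] = QSAnnotation.inconclusive("PISA")
        entries[2].method_results["SC"] = QSAnnotation.not_available("SC")
        frame = write_wide_table(entries)
        back = read_wide_table(
            pd.read_csv(io.StringIO(frame.to_csv(index=False)))
        )
        assert len(back) == 3
        for original, restored in zip(entries, back):
            assert original.pdb_id == restored.pdb_id
            for m in ("SC", "TM", "PISA", "EPPIC"):
                o, r = original.method_results[m], restored.method_results[m]
                assert o.status == r.status
                assert str(o.stoichiometry) == str(r.stoichiometry)
            assert restored.method_results["TM"].order_only
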