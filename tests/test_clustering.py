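"""Identity clustering, consistency scoring, and the representative rule."""

import itertools

import numpy as np
import pytest

from qsconsensus.annotations import (
    QSAnnotation,
    Source,
    Status,
    parse_stoichiometry,
    parse_symmetry,
)
from qsconsensus.clustering import (
    Cluster,
    ClusterProfile,
    SeqRecord,
    SequenceIdentityClusterer,
    build_clusters,
    cluster_profile,
    cluster_size_sweep,
    consistency_score,
    pairwise_identity,
    representative_state,
)
from qsconsensus.fixtures import ClusterSpec, make_cluster_fixture


def ann(stoich, sym):
    return QSAnnotation(
        stoichiometry=parse_stoichiometry(stoich), symmetry=parse_symmetry(sym)
    )


def records_from_fasta(fasta: str) -> list[SeqRecord]:
    lines = fasta.strip().split("\n")
    return [SeqRecord(lines[i][1:], lines[i + 1]) for i in range(0, len(lines), 2)]


class TestPairwiseIdentity:
    def test_self_match(self):
        r = SeqRecord("a", "MKLVAGHTWE")
        assert pairwise_identity(r, r) == (1.0, 1.0, 1.0)

    def test_no_identical_columns(self):
        ident, *_ = pairwise_identity(SeqRecord("a", "AAAA"), SeqRecord("b", "CCCC"))
        assert ident == 0.0

    def test_hand_alignment(self):
        # gapless alignment, 4 of 5 columns identical
        ident, cov_a, cov_b = pairwise_identity(
            SeqRecord("a", "MKLVA"), SeqRecord("b", "MKIVA")
        )
        assert ident == pytest.approx(0.8)
        assert cov_a == cov_b == 1.0

    def test_terminal_gaps_excluded_from_identity(self):
        # identical core, one side has a terminal extension: identity over the
        # shared span stays 1, coverage of the longer side drops
        core = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        ident, cov_short, cov_long = pairwise_identity(
            SeqRecord("a", core), SeqRecord("b", core + "AAAAAAA")
        )
        assert ident == pytest.approx(1.0)
        assert cov_short == pytest.approx(1.0)
        assert cov_long < 1.0


def union_find_components(records, k, min_coverage=0.9):
    """Oracle: exhaustive pairwise testing + union-find over the edge list."""
    parent = {r.id: r.id for r in records}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in itertools.combinations(records, 2):
        ident, ca, cb = pairwise_identity(a, b)
        if ident >= k / 100 and ca >= min_coverage and cb >= min_coverage:
            parent[find(a.id)] = find(b.id)
    components = {}
    for r in records:
        components.setdefault(find(r.id), set()).add(r.id)
    return {frozenset(c) for c in components.values()}


class TestBuildClusters:
    def test_identical_sequences_one_cluster(self):
        recs = [SeqRecord(f"s{i}", "MKTAYIAKQRQISFVKSHFSRQ") for i in range(3)]
        clusters = build_clusters(recs, 90)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_dissimilar_sequences_are_singletons(self):
        recs = [
            SeqRecord("a", "MKTAYIAKQRQISFVKSHFSRQ"),
            SeqRecord("b", "GGGGGGGGGGPPPPPPPPPPWW"),
            SeqRecord("c", "CCCCHHHHEEEEDDDDNNNNYY"),
        ]
        clusters = build_clusters(recs, 70)
        assert sorted(c.size for c in clusters) == [1, 1, 1]

    def test_single_linkage_transitivity(self):
        # A~B and B~C above threshold, A~C below: one cluster of three
        base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQV"
        mid = "WWTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQV"
        far = "WWWWYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQV"
        recs = [SeqRecord("a", base), SeqRecord("b", mid), SeqRecord("c", far)]
        ia, *_ = pairwise_identity(recs[0], recs[2])
        assert ia < 0.95  # A-C alone would not pass at 95%
        clusters = build_clusters(recs, 95)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_partition_and_oracle_equivalence(self):
        fasta, _, _ = make_cluster_fixture(
            [ClusterSpec(size=5), ClusterSpec(size=4), ClusterSpec(size=3),
             ClusterSpec(size=2), ClusterSpec(size=1)],
            seed=5,
        )
        recs = records_from_fasta(fasta)
        assert len(recs) <= 20
        clusters = build_clusters(recs, 70)
        got = {frozenset(c.member_ids) for c in clusters}
        assert got == union_find_components(recs, 70)
        # partition: every record in exactly one cluster
        all_ids = [m for c in clusters for m in c.member_ids]
        assert sorted(all_ids) == sorted(r.id for r in recs)


class TestConsistencyScore:
    def make_cluster(self, annotations, k=70):
        c = Cluster(threshold_k=k)
        for i, a in enumerate(annotations):
            c.members.append((f"m{i}", a))
        return c

    def test_degenerate_profile(self):
        c = self.make_cluster([ann("A2", "C2")] * 4)
        profile = cluster_profile(c)
        assert profile.p_stoich[parse_stoichiometry("A2")] == 1.0
        assert consistency_score(
            profile, parse_stoichiometry("A2"), parse_symmetry("C2")
        ) == 1.0

    def test_two_thirds_profile(self):
        c = self.make_cluster([ann("A2", "C2"), ann("A2", "C2"), ann("A", "C1")])
        profile = cluster_profile(c)
        assert profile.p_stoich[parse_stoichiometry("A2")] == pytest.approx(2 / 3)
        score = consistency_score(profile, parse_stoichiometry("A2"), parse_symmetry("C2"))
        assert score == pytest.approx(4 / 9)

    def test_absent_pair_scores_zero(self):
        c = self.make_cluster([ann("A2", "C2"), ann("A2", "C2")])
        profile = cluster_profile(c)
        assert consistency_score(
            profile, parse_stoichiometry("A6"), parse_symmetry("C2")
        ) == 0.0

    def test_uniform_two_point(self):
        c = self.make_cluster([ann("A2", "C2"), ann("A4", "D2")])
        profile = cluster_profile(c)
        for p in profile.p_stoich.values():
            assert p == 0.5

    def test_partial_annotations_renormalized(self):
        members = [ann("A2", "C2"), ann("A2", "C2")]
        members.append(QSAnnotation(stoichiometry=parse_stoichiometry("A4")))
        c = self.make_cluster(members)
        profile = cluster_profile(c)
        # symmetry marginal excludes the symmetry-less member
        assert profile.p_sym[parse_symmetry("C2")] == 1.0
        assert profile.p_stoich[parse_stoichiometry("A2")] == pytest.approx(2 / 3)

    def test_unannotated_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_profile(self.make_cluster([None, None]))

    def test_adding_modal_member_never_decreases_max_score(self):
        rng = np.random.default_rng(2)
        states = [("A", "C1"), ("A2", "C2"), ("A4", "D2")]
        for _ in range(50):
            members = [
                ann(*states[int(rng.integers(3))])
                for _ in range(int(rng.integers(2, 8)))
            ]
            c = self.make_cluster(members)
            profile = cluster_profile(c)
            scores = {
                (s, y): consistency_score(profile, parse_stoichiometry(s), parse_symmetry(y))
                for s, y in states
            }
            (s_max, y_max), best = max(scores.items(), key=lambda kv: kv[1])
            grown = self.make_cluster(members + [ann(s_max, y_max)])
            new_best = max(
                consistency_score(
                    cluster_profile(grown), parse_stoichiometry(s), parse_symmetry(y)
                )
                for s, y in states
            )
            assert new_best >= best - 1e-12


class TestRepresentativeState:
    def make_cluster(self, annotations, k=70):
        c = Cluster(threshold_k=k)
        for i, a in enumerate(annotations):
            c.members.append((f"m{i}", a))
        return c

    def test_small_cluster_not_available(self):
        c = self.make_cluster([ann("A2", "C2")] * 2)  # min size 3 at k=70
        assert representative_state(c).status is Status.NOT_AVAILABLE

    def test_unanimous_cluster_at_40_percent_minimum(self):
        c = self.make_cluster([ann("A2", "C2")] * 5, k=40)  # min size 5 at k=40
        rep = representative_state(c)
        assert rep.status is Status.PREDICTED
        assert str(rep.stoichiometry) == "A2" and str(rep.symmetry) == "C2"
        four = self.make_cluster([ann("A2", "C2")] * 4, k=40)
        assert representative_state(four).status is Status.NOT_AVAILABLE

    def test_majority_rule_is_strict(self):
        # marginals 2/3 give max score 4/9 <= 0.5: inconclusive
        c = self.make_cluster([ann("A2", "C2"), ann("A2", "C2"), ann("A", "C1")])
        assert representative_state(c).status is Status.INCONCLUSIVE

    def test_exact_half_is_inconclusive(self):
        # one marginal degenerate, the other exactly 1/2: max score 0.5 is
        # not strictly greater than 0.5
        members = [ann("A2", "C2"), ann("A2", "C2"), ann("A2", "C1"), ann("A2", "C1")]
        c = self.make_cluster(members + [])
        # p(A2)=1, p(C2)=p(C1)=0.5 -> max score exactly 0.5
        assert representative_state(c).status is Status.INCONCLUSIVE


class TestClusterSizeSweep:
    def test_trade_off_on_constructed_fixture(self):
        # one clean big cluster, one noisy 3-cluster whose prediction is wrong
        clean = Cluster(threshold_k=70)
        for i in range(6):
            clean.members.append((f"a{i}", ann("A2", "C2")))
        noisy = Cluster(threshold_k=70)
        for i in range(4):
            noisy.members.append((f"b{i}", ann("A4", "D2")))
        entries = [(ann("A2", "C2"), clean)] + [(ann("A", "C1"), noisy)]
        rows = cluster_size_sweep(entries, sizes=range(1, 9))
        by_size = {r.min_size: r for r in rows}
        # noisy cluster (size 4) predicts A4/D2 against reference A/C1 ->
        # incorrect until min size excludes it at 5
        assert by_size[4].pct_incorrect == 50.0
        assert by_size[5].pct_incorrect == 0.0
        assert by_size[5].pct_na == 50.0
        # monotone trade-off on this fixture
        for lo, hi in zip(rows, rows[1:]):
            assert hi.pct_incorrect <= lo.pct_incorrect
            assert hi.pct_na >= lo.pct_na
        # percentages sum to 100
        for r in rows:
            total = r.pct_correct + r.pct_incorrect + r.pct_inconclusive + r.pct_na
            assert total == pytest.approx(100.0)

    def test_empty_benchmark(self):
        assert cluster_size_sweep([]) == []


class TestSklearnSurface:
    def test_params_roundtrip_and_labels(self):
        est = SequenceIdentityClusterer(identity=90, min_coverage=0.8)
        assert est.get_params() == {"identity": 90, "min_coverage": 0.8}
        est.set_params(identity=70)
        recs = [
            SeqRecord("a", "MKTAYIAKQRQISFVKSHFSRQ"),
            SeqRecord("b", "MKTAYIAKQRQISFVKSHFSRQ"),
            SeqRecord("c", "GGGGGGGGGGPPPPPPPPPPWW"),
        ]
        labels = est.fit_predict(recs)
        assert labels[0] == labels[1] != labels[2]
        assert len(est.clusters_) == 2
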