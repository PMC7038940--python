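"""Flanking introns, Alu overlap, complexity/predominant comparisons, CSI."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circabs import events as ev
from circabs import features as ft
from circabs import pcu as pc
from circabs.io import GeneModel


@pytest.fixture
def plus_gene():
    # 5 exons of 100 bp separated by introns of 100/200/300/400 bp
    exons = ((0, 100), (200, 300), (500, 600), (900, 1000), (1400, 1500))
    return GeneModel("gplus", "chr1", "+", exons)


@pytest.fixture
def minus_gene():
    exons = ((0, 100), (200, 300), (500, 600), (900, 1000), (1400, 1500))
    return GeneModel("gminus", "chr1", "-", exons)


class TestAssignFlankingIntrons:
    def test_plus_strand_exons_2_to_3(self, plus_gene):
        key = ("chr1", "+", 200, 600)  # spans exons 2-3
        asn = ft.assign_flanking_introns([key], [plus_gene])[key]
        assert asn.ok
        assert asn.upstream == (100, 200)  # intron 1
        assert asn.downstream == (600, 900)  # intron 3

    def test_minus_strand_swaps_sides(self, minus_gene):
        key = ("chr1", "-", 200, 600)
        asn = ft.assign_flanking_introns([key], [minus_gene])[key]
        assert asn.upstream == (600, 900)
        assert asn.downstream == (100, 200)

    def test_first_and_last_exon_edges(self, plus_gene):
        first = ("chr1", "+", 0, 300)
        last = ("chr1", "+", 900, 1500)
        asns = ft.assign_flanking_introns([first, last], [plus_gene])
        assert asns[first].upstream is None and asns[first].downstream == (300, 500)
        assert asns[last].downstream is None and asns[last].upstream == (600, 900)

    def test_shared_upstream_distinct_downstream(self, plus_gene):
        # two A5BS members sharing the acceptor at exon 2
        k1 = ("chr1", "+", 200, 600)
        k2 = ("chr1", "+", 200, 1000)
        asns = ft.assign_flanking_introns([k1, k2], [plus_gene])
        assert asns[k1].upstream == asns[k2].upstream == (100, 200)
        assert asns[k1].downstream != asns[k2].downstream

    def test_unannotated_and_ambiguous(self, plus_gene):
        other = GeneModel("gother", "chr1", "+", ((0, 100), (200, 300), (500, 600)))
        off = ("chr1", "+", 250, 600)  # 250 is not an exon start
        amb = ("chr1", "+", 200, 300)  # matches both genes
        asns = ft.assign_flanking_introns([off, amb], [plus_gene, other])
        assert asns[off].status == "unannotated"
        assert asns[amb].status == "ambiguous"

    def test_isoform_with_most_exons_wins(self, plus_gene):
        short = GeneModel("gplus", "chr1", "+", ((200, 300), (500, 600)), name="txS")
        key = ("chr1", "+", 200, 600)
        asn = ft.assign_flanking_introns([key], [short, plus_gene])[key]
        assert asn.transcript != "txS"
        assert asn.upstream == (100, 200)


class TestCountAlu:
    def repeats(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "family"])

    def test_overlap_arithmetic(self):
        alu = ft.build_alu_index(
            self.repeats(
                [("chr1", 150, 180, "+", "AluY"), ("chr1", 195, 260, "-", "AluSx")]
            )
        )
        total, plus, minus = ft.count_alu("chr1", 100, 200, alu)
        assert (total, plus, minus) == (2, 1, 1)
        assert ft.count_alu("chr1", 300, 400, alu) == (0, 0, 0)
        assert ft.count_alu("chr9", 0, 100, alu) == (0, 0, 0)

    def test_boundary_is_half_open(self):
        alu = ft.build_alu_index(self.repeats([("chr1", 200, 260, "+", "AluY")]))
        assert ft.count_alu("chr1", 100, 200, alu)[0] == 0  # abutting, no overlap
        assert ft.count_alu("chr1", 100, 201, alu)[0] == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alus = [
            ("chr1", int(s), int(s + rng.integers(50, 400)),
             "+" if rng.random() < 0.5 else "-", "AluY")
            for s in rng.integers(0, 100_000, size=500)
        ]
        index = ft.build_alu_index(self.repeats(alus))
        for _ in range(100):
            s = int(rng.integers(0, 100_000))
            e = s + int(rng.integers(10, 5_000))
            want = sum(1 for _, a, b, _, _ in alus if a < e and b > s)
            assert ft.count_alu("chr1", s, e, index)[0] == want


class TestControlIntrons:
    def test_support_excludes_flanking_and_is_deterministic(self, plus_gene):
        key = ("chr1", "+", 200, 600)
        asn = ft.assign_flanking_introns([key], [plus_gene])
        draws = set()
        for _ in range(200):
            controls, excl = ft.sample_control_introns(asn, [plus_gene], 7)
            draws.add(controls[key])
        # flanking introns 1 and 3 never drawn; seed fixed => single draw
        assert len(draws) == 1
        support = set()
        for s in range(50):
            controls, _ = ft.sample_control_introns(asn, [plus_gene], s)
            support.add(controls[key])
        assert support <= {(300, 500), (1000, 1400)}
        assert len(support) == 2

    def test_gene_without_spare_intron_excluded(self):
        # both introns flank the single circularized exon: nothing to draw
        g = GeneModel("g2", "chr1", "+", ((0, 100), (200, 300), (400, 500)))
        key = ("chr1", "+", 200, 300)
        asn = ft.assign_flanking_introns([key], [g])
        controls, excluded = ft.sample_control_introns(asn, [g], 0)
        assert controls == {} and excluded == [key]

    def test_internal_intron_is_a_valid_control(self):
        g = GeneModel("g3", "chr1", "+", ((0, 100), (200, 300), (400, 500), (600, 700)))
        key = ("chr1", "+", 0, 500)  # spans exons 1-3; downstream intron 3 flanks
        asn = ft.assign_flanking_introns([key], [g])
        support = {ft.sample_control_introns(asn, [g], s)[0][key] for s in range(40)}
        assert support == {(100, 200), (300, 400)}  # internal introns allowed


class TestRankTests:
    def test_rank_sum_matches_exact_enumeration(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 6)
        y = rng.normal(1, 1, 6)
        stat, p = ft.rank_sum_test(x, y)
        # oracle: enumerate all 6-subsets of the pooled ranks
        pooled = np.argsort(np.argsort(np.r_[x, y])) + 1
        u_obs = pooled[:6].sum() - 6 * 7 / 2
        count = total = 0
        for comb in itertools.combinations(range(12), 6):
            u = sum(pooled[list(comb)]) - 6 * 7 / 2
            total += 1
            if abs(u - 18) >= abs(u_obs - 18) - 1e-9:  # 18 = n1*n2/2
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_identical_distributions_near_null(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 1, 200)
        _, p = ft.rank_sum_test(x, y)
        assert p > 0.05
        assert abs(np.median(x) - np.median(y)) < 0.3

    def test_signed_rank_small_sample_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = x - np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        _, p = ft.signed_rank_test(x, y)
        assert p == pytest.approx(2 / 64)  # all six differences positive


class TestCompareByComplexity:
    def make_table(self, rng, n=40, up_shift=0.0):
        rows = []
        classes = {}
        for i in range(n):
            key = ("chr1", "+", 100 * i, 100 * i + 50)
            cls = ["high", "low", ev.CONSTITUTIVE][i % 3]
            classes[key] = cls
            bump = up_shift if cls == "high" else 0.0
            for side, length in (("upstream", 1000 + bump + rng.normal(0, 10)),
                                 ("downstream", 1000 + rng.normal(0, 10))):
                rows.append(
                    {"key": key, "gene_id": f"g{i}", "side": side, "start": 0,
                     "end": 1, "length": length, "alu_count": 1,
                     "alu_same": 1, "alu_opposite": 0}
                )
        return pd.DataFrame(rows), classes

    def test_planted_upstream_shift_detected_downstream_null(self):
        rng = np.random.default_rng(6)
        table, classes = self.make_table(rng, up_shift=100.0)
        out = ft.compare_by_complexity(table, classes, feature="length")
        up = out[(out.side == "upstream") & (out.class_a == "high") & (out.class_b == "low")]
        down = out[(out.side == "downstream") & (out.class_a == "high") & (out.class_b == "low")]
        assert up["pvalue"].iloc[0] < 1e-4
        assert down["pvalue"].iloc[0] > 0.05
        assert up["median_a"].iloc[0] - up["median_b"].iloc[0] == pytest.approx(100, abs=20)

    def test_small_groups_skipped(self):
        rng = np.random.default_rng(7)
        table, classes = self.make_table(rng, n=4)
        out = ft.compare_by_complexity(table, classes, min_group=3)
        assert set(out["class_a"]) | set(out["class_b"]) <= {"high", "low", ev.CONSTITUTIVE}


class TestPredominantVsOther:
    def make_events(self, n, lengths):
        events, rows, pred = [], [], {}
        for i in range(n):
            keys = [("chr1", "+", 10_000 * i, 10_000 * i + 400 * (j + 1)) for j in range(2)]
            e = ev.ABSEvent(ev.A5BS, "chr1", "+", 10_000 * i, tuple(keys), tuple(keys))
            events.append(e)
            pred[e.event_id] = keys[0]
            for k, L in zip(keys, lengths(i)):
                for side in ("upstream", "downstream"):
                    rows.append(
                        {"key": k, "gene_id": f"g{i}", "side": side, "start": 0,
                         "end": 1, "length": L, "alu_count": 0, "alu_same": 0,
                         "alu_opposite": 0}
                    )
        return events, pd.DataFrame(rows), pred

    def test_all_equal_pairs_sit_at_null(self):
        events, table, pred = self.make_events(10, lambda i: (500.0, 500.0))
        out = ft.compare_predominant_vs_other(events, pred, table)
        assert out[ev.A5BS].pvalue == 1.0

    def test_planted_longer_predominant_rejected(self):
        rng = np.random.default_rng(8)
        events, table, pred = self.make_events(
            60, lambda i: (2000 + rng.normal(0, 50), 1000 + rng.normal(0, 50))
        )
        out = ft.compare_predominant_vs_other(events, pred, table)
        assert out[ev.A5BS].pvalue < 1e-6
        assert out[ev.A5BS].side == "downstream"

    def test_single_event_insufficient(self):
        events, table, pred = self.make_events(1, lambda i: (500.0, 400.0))
        with pytest.raises(ValueError, match="insufficient pairs"):
            ft.compare_predominant_vs_other(events, pred, table)

    def test_cumulative_frequency_monotone(self):
        out = ft.cumulative_frequency([3.0, 1.0, 2.0])
        assert out["value"].tolist() == [1.0, 2.0, 3.0]
        assert out["cumulative_frequency"].tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])


class TestCSI:
    def setup_pair(self, useq, dseq, u_strand="+", d_strand="-"):
        """One upstream Alu and one downstream Alu with given genomic sequences."""
        seq = "T" * 100 + useq + "T" * 100 + dseq + "T" * 100
        u = (100, 100 + len(useq))
        d = (200 + len(useq), 200 + len(useq) + len(dseq))
        repeats = pd.DataFrame(
            [("chr1", *u, u_strand, "AluY"), ("chr1", *d, d_strand, "AluY")],
            columns=["chrom", "start", "end", "strand", "family"],
        )
        index = ft.build_alu_index(repeats)
        upstream = (90, u[1] + 10)
        downstream = (d[0] - 10, d[1] + 10)
        return upstream, downstream, index, {"chr1": seq}

    def test_single_perfect_inverted_pair_scores_its_length(self):
        rng = np.random.default_rng(9)
        u = "".join(rng.choice(list("ACGT"), 60))
        d = ft.reverse_complement(u)
        up, down, index, seqs = self.setup_pair(u, d)
        score = ft.compute_csi("chr1", up, down, index, seqs)
        # perfect complementarity, equal lengths, no competitors: CSI = S = |u|
        assert score.csi == pytest.approx(60.0)
        assert score.symmetry == pytest.approx(1.0)

    def test_same_orientation_pairs_are_ignored(self):
        rng = np.random.default_rng(10)
        u = "".join(rng.choice(list("ACGT"), 60))
        up, down, index, seqs = self.setup_pair(u, ft.reverse_complement(u), "+", "+")
        assert ft.compute_csi("chr1", up, down, index, seqs).csi == 0.0

    def test_no_alu_gives_zero(self):
        up, down, index, seqs = self.setup_pair("ACGT" * 10, "ACGT" * 10)
        assert ft.compute_csi("chr1", (0, 50), (900, 950), index, seqs).csi == 0.0

    def test_symmetric_under_intron_exchange(self):
        rng = np.random.default_rng(11)
        u = "".join(rng.choice(list("ACGT"), 80))
        d = "".join(rng.choice(list("ACGT"), 50))
        up, down, index, seqs = self.setup_pair(u, d)
        a = ft.compute_csi("chr1", up, down, index, seqs)
        b = ft.compute_csi("chr1", down, up, index, seqs)
        assert a.csi == pytest.approx(b.csi)

    def test_planted_predominant_pair_beats_others(self):
        """Closed loop on sequence-emitting simulation: stronger inverted-Alu
        pairs planted for predominant members give them higher CSI."""
        from circabs.simulate import SimConfig, simulate

        sim = simulate(SimConfig(seed=9, n_loci=120, emit_fasta=True, dual_fraction=0.0))
        alu = ft.build_alu_index(sim.annotation.repeats)
        asn = ft.assign_flanking_introns(list(sim.truth.circ.index), sim.annotation.genes)
        truth = sim.truth
        vp, vo = [], []
        for eid, row in truth.events.iterrows():
            members = truth.circ.index[truth.circ["gene_id"] == row["gene_id"]]
            vals = {}
            for k in members:
                a = asn[tuple(k)]
                if not (a.ok and a.upstream and a.downstream):
                    continue
                vals[tuple(k)] = ft.compute_csi(
                    k[0], a.upstream, a.downstream, alu, sim.annotation.sequences
                ).csi
            p = tuple(row["predominant_key"])
            others = [v for kk, v in vals.items() if kk != p]
            if p in vals and others:
                vp.append(vals[p])
                vo.append(float(np.mean(others)))
        assert len(vp) >= 25
        assert np.median(vp) > np.median(vo)
        assert stats.wilcoxon(vp, vo, alternative="greater").pvalue < 0.01
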