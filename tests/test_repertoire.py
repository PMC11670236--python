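import numpy as np
import pandas as pd
import pytest

from clonal_surveil import repertoire as rep
from clonal_surveil.io_formats import GermlineSegment
from clonal_surveil.synthetic_data import load_packaged_germlines

from conftest import make_rearrangement


# ---------------------------------------------------------------------------
# brute-force clonotyping oracle: all-pairs union-find
# ---------------------------------------------------------------------------

def clonotype_oracle(records, threshold):
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if a.v_call != b.v_call or a.j_call != b.j_call:
                continue
            if len(a.cdr3_aa) != len(b.cdr3_aa):
                continue
            same = sum(x == y for x, y in zip(a.cdr3_aa, b.cdr3_aa))
            if same / len(a.cdr3_aa) >= threshold - 1e-12:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def partition_of(cloneset):
    return {frozenset(c.member_indices) for c in cloneset.clones}


def random_records(rng, n, n_v=3, n_j=2, lengths=(8, 10)):
    recs = []
    for i in range(n):
        L = int(rng.choice(lengths))
        cdr3 = "".join(rng.choice(list("ACDE"), size=L))  # tiny alphabet forces clusters
        recs.append(make_rearrangement(
            cell_id=f"c{i}",
            v_call=f"VH{int(rng.integers(n_v))}-1",
            j_call=f"JH{int(rng.integers(n_j))}",
            cdr3_aa=cdr3,
        ))
    return recs


class TestClonotyping:
    def test_boundary_identity_is_inclusive(self):
        # length 10, 2 mismatches -> identity exactly 0.80 -> same clone
        a = make_rearrangement(cell_id="a", cdr3_aa="AAAAAAAAAA")
        b = make_rearrangement(cell_id="b", cdr3_aa="AAAAAAAACC")
        cs = rep.assign_clonotypes([a, b], identity_threshold=0.80)
        assert len(cs.clones) == 1

    def test_identical_records_share_a_clone(self):
        recs = [make_rearrangement(cell_id=f"c{i}") for i in range(4)]
        cs = rep.assign_clonotypes(recs)
        assert len(cs.clones) == 1 and cs.clones[0].size == 4

    def test_different_lengths_never_merge(self):
        a = make_rearrangement(cell_id="a", cdr3_aa="AAAAAAAA")
        b = make_rearrangement(cell_id="b", cdr3_aa="AAAAAAAAA")
        cs = rep.assign_clonotypes([a, b])
        assert len(cs.clones) == 2

    def test_matches_union_find_oracle_on_random_repertoires(self, rng):
        for _ in range(30):
            recs = random_records(rng, int(rng.integers(5, 31)))
            cs = rep.assign_clonotypes(recs, identity_threshold=0.80)
            assert partition_of(cs) == clonotype_oracle(recs, 0.80)

    def test_threshold_one_equals_exact_grouping_dictionary(self, rng):
        recs = random_records(rng, 60)
        cs = rep.assign_clonotypes(recs, identity_threshold=1.0)
        exact = {}
        for i, r in enumerate(recs):
            exact.setdefault((r.v_call, r.j_call, r.cdr3_aa), set()).add(i)
        assert partition_of(cs) == {frozenset(v) for v in exact.values()}

    def test_partition_invariant_to_record_order(self, rng):
        recs = random_records(rng, 40)
        cs1 = rep.assign_clonotypes(recs)
        perm = rng.permutation(len(recs))
        shuffled = [recs[i] for i in perm]
        cs2 = rep.assign_clonotypes(shuffled)
        remapped = {frozenset(int(perm[i]) for i in grp) for grp in partition_of(cs2)}
        assert partition_of(cs1) == remapped

    def test_sizes_conserve_record_count(self, rng):
        recs = random_records(rng, 50)
        cs = rep.assign_clonotypes(recs)
        assert cs.sizes().sum() == 50
        assert (cs.assignments >= 0).all()

    def test_empty_input_gives_empty_cloneset(self):
        cs = rep.assign_clonotypes([])
        assert cs.clones == [] and cs.n_records == 0


class TestMutationStats:
    def test_germline_identical_is_zero(self):
        r = make_rearrangement()
        assert rep.vh_mutation_stats(r) == (0, 0.0)

    def test_six_of_three_hundred_is_exactly_two_percent(self):
        germ = "A" * 300
        seq = "C" * 6 + "A" * 294
        r = make_rearrangement(v_seq=seq, germ=germ)
        count, freq = rep.vh_mutation_stats(r)
        assert (count, freq) == (6, 2.0)
        # 2.0 is the boundary case: "above 2%" must exclude it
        assert not freq > 2.0

    def test_matches_positionwise_oracle(self, rng):
        germ = "".join(rng.choice(list("ACGT"), size=120))
        seq = list(germ)
        mut = rng.choice(120, size=15, replace=False)
        for p in mut:
            seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        # sprinkle gaps which must not count
        gaps = rng.choice(np.setdiff1d(np.arange(120), mut), size=5, replace=False)
        for p in gaps:
            seq[p] = "-"
        r = make_rearrangement(v_seq="".join(seq), germ=germ)
        count, freq = rep.vh_mutation_stats(r)
        assert count == 15
        assert freq == pytest.approx(100 * 15 / 115)

    def test_length_mismatch_raises(self):
        r = make_rearrangement(v_seq="ACGT", germ="ACG")
        with pytest.raises(ValueError):
            rep.vh_mutation_stats(r)


def _cloneset_with(sizes_freqs):
    clones = []
    n = 0
    for i, (size, freq) in enumerate(sizes_freqs):
        clones.append(rep.Clone(
            clone_id=i, member_indices=list(range(n, n + size)),
            v_call="VH1-1", j_call="JH1", ancestor_cdr3="CAR",
            size=size, mean_vh_mutation_freq=freq))
        n += size
    return rep.CloneSet(clones=clones, assignments=np.zeros(n, dtype=int), n_records=n)


class TestMutatedClonotypeFrequency:
    def test_all_unmutated_is_zero(self):
        cs = _cloneset_with([(12, 0.0), (15, 0.0)])
        assert rep.mutated_clonotype_frequency(cs, denominator="qualifying_clones") == 0.0

    def test_hand_example_two_of_three_clones(self):
        # sizes (12, 11, 5), freqs (3%, 1%, 9%): size-5 clone excluded,
        # 1 mutated of 2 qualifying -> 0.5
        cs = _cloneset_with([(12, 3.0), (11, 1.0), (5, 9.0)])
        out = rep.mutated_clonotype_frequency(cs, denominator="qualifying_clones")
        assert out == 0.5

    def test_boundaries_are_strict(self):
        # size exactly 10 and freq exactly 2.0 both fail the strict filters
        cs = _cloneset_with([(10, 5.0), (12, 2.0)])
        assert rep.mutated_clonotype_frequency(cs, denominator="qualifying_clones") == 0.0

    def test_no_qualifying_clones_reports_missing(self):
        cs = _cloneset_with([(3, 5.0)])
        assert rep.mutated_clonotype_frequency(cs, denominator="qualifying_clones") is None

    def test_sequence_denominator_counts_members(self):
        cs = _cloneset_with([(20, 5.0), (15, 1.0), (65, 0.0)])
        out = rep.mutated_clonotype_frequency(cs, denominator="sequences")
        assert out == pytest.approx(20 / 100)


class TestSpectra:
    def test_all_igm_frequency_one(self):
        recs = [make_rearrangement(cell_id=f"c{i}", c_call="IGHM") for i in range(5)]
        freqs, unknown = rep.isotype_frequencies(recs)
        assert freqs.loc["all", "IgM"] == 1.0
        assert freqs.loc["all"].sum() == pytest.approx(1.0)

    def test_frequencies_match_brute_force_counting(self, rng):
        calls = ["IGHM", "IGHG1", "IGHG2B", "IGHA", "junk"]
        recs = [make_rearrangement(cell_id=f"c{i}",
                                   c_call=str(rng.choice(calls)),
                                   sample_id=str(rng.choice(["s1", "s2"])))
                for i in range(200)]
        freqs, unknown = rep.isotype_frequencies(recs)
        for s in ("s1", "s2"):
            sub = [r for r in recs if r.sample_id == s]
            known = [r.isotype for r in sub if r.isotype != "unknown"]
            for iso in ("IgM", "IgG1", "IgG2b", "IgA"):
                assert freqs.loc[s, iso] == pytest.approx(
                    known.count(iso) / len(known))
            assert unknown[s] == sum(1 for r in sub if r.isotype == "unknown")
            assert freqs.loc[s].sum() == pytest.approx(1.0)

    def test_single_record_vj_matrix(self):
        recs = [make_rearrangement(v_call="VH1-72", j_call="JH2")]
        fam, vj = rep.vfamily_and_vj_matrix(recs)
        assert vj.loc["VH1-72", "JH2"] == 1
        assert vj.to_numpy().sum() == 1
        assert fam["VH1"] == 1.0

    def test_vj_marginals_equal_usage_counts(self, rng):
        recs = random_records(rng, 80)
        _, vj = rep.vfamily_and_vj_matrix(recs)
        from collections import Counter

        v_counts = Counter(r.v_call for r in recs)
        j_counts = Counter(r.j_call for r in recs)
        for v, cnt in v_counts.items():
            assert vj.loc[v].sum() == cnt
        for j, cnt in j_counts.items():
            assert vj[j].sum() == cnt

    def test_clone_collapsed_counts_each_clone_once(self, rng):
        recs = [make_rearrangement(cell_id=f"c{i}", cdr3_aa="CARDYWWW")
                for i in range(10)]
        cs = rep.assign_clonotypes(recs)
        _, vj = rep.vfamily_and_vj_matrix(recs, clones=cs)
        assert vj.to_numpy().sum() == len(cs.clones) == 1


class TestCdr3Lengths:
    def test_single_length_all_mass_at_mode(self):
        recs = [make_rearrangement(cell_id=f"c{i}", cdr3_aa="A" * 8) for i in range(6)]
        d = rep.cdr3_length_distribution(recs)
        assert d["modal_length"] == 8
        assert d["frequencies"][8] == 1.0

    def test_uniform_lengths_trapezoid_auc(self):
        recs = [make_rearrangement(cell_id=f"c{i}", cdr3_aa="A" * L)
                for i, L in enumerate([7, 8, 9, 10])]
        d = rep.cdr3_length_distribution(recs)
        assert d["auc"] == pytest.approx(0.75)

    def test_frequencies_sum_to_one(self, rng):
        recs = random_records(rng, 50, lengths=(7, 8, 9, 12))
        d = rep.cdr3_length_distribution(recs)
        assert d["frequencies"].sum() == pytest.approx(1.0)


def _canonical_segment():
    germs, _ = load_packaged_germlines()
    return germs


class TestVh172:
    def test_germline_record_has_w_not_w33l(self):
        germs = _canonical_segment()
        g = germs["VH1-72"]
        rec = make_rearrangement(v_call="VH1-72", v_seq=g.seq, germ=g.seq,
                                 sample_id="s1")
        out = rep.vh1_72_analysis([rec], germs)
        assert out["w33l_counts"].loc["s1", "W"] == 1
        assert out["w33l_counts"].loc["s1", "L"] == 0

    def test_leucine_at_window_position_8_flags_w33l(self):
        germs = _canonical_segment()
        g = germs["VH1-72"]
        start = (g.cdr1_aa_start + 8 - 2) * 3
        seq = g.seq[:start] + "CTG" + g.seq[start + 3:]
        rec = make_rearrangement(v_call="VH1-72", v_seq=seq, germ=g.seq,
                                 sample_id="s1")
        out = rep.vh1_72_analysis([rec], germs)
        assert out["w33l_counts"].loc["s1", "L"] == 1

    def test_usage_fraction_and_short_records_flagged(self):
        germs = _canonical_segment()
        g = germs["VH1-72"]
        recs = [
            make_rearrangement(cell_id="a", v_call="VH1-72", v_seq=g.seq,
                               germ=g.seq, sample_id="s1"),
            make_rearrangement(cell_id="b", v_call="VH2-2",
                               v_seq=germs["VH2-2"].seq,
                               germ=germs["VH2-2"].seq, sample_id="s1"),
            make_rearrangement(cell_id="c", v_call="VH1-72", v_seq="ACG",
                               germ="ACG", sample_id="s1"),  # window past end
        ]
        out = rep.vh1_72_analysis(recs, germs)
        assert out["usage"]["s1"] == pytest.approx(2 / 3)
        assert out["n_flagged"] == 1
        assert out["w33l_counts"].loc["s1"].sum() == 1  # short record excluded


class TestCloneSizes:
    def test_log10_values(self):
        cs = _cloneset_with([(1, 0.0), (10, 0.0), (100, 0.0)])
        df, _ = rep.clone_size_stats({"g": cs}, min_size=1)
        assert sorted(df["log10_size"]) == [0.0, 1.0, 2.0]

    def test_depleted_group_has_lower_log_sizes(self):
        big = _cloneset_with([(100, 0.0)] * 5)
        small = _cloneset_with([(10, 0.0)] * 5)
        df, report = rep.clone_size_stats({"treated": small, "untreated": big})
        means = df.groupby("group")["log10_size"].mean()
        assert means["untreated"] - means["treated"] == pytest.approx(1.0)


class TestKlLogo:
    def test_background_equal_observed_gives_zero_logo(self):
        # windows realizing exactly the uniform background at every position
        aas = rep.AMINO_ACIDS
        windows = [a + a for a in aas]  # 20 windows of length 2, each AA once
        logo = rep.kl_logo(windows, pseudocount=0.0)
        assert np.allclose(logo.weights.to_numpy(), 0.0, atol=1e-12)

    def test_single_residue_column_signs(self):
        windows = ["AA"] * 10
        logo = rep.kl_logo(windows, pseudocount=1.0)
        w = logo.weights
        assert (w.loc[:, "A"] > 0).all()
        others = [a for a in rep.AMINO_ACIDS if a != "A"]
        assert (w.loc[:, others].to_numpy() <= 0).all()

    def test_weights_match_direct_formula(self, rng):
        windows = ["".join(rng.choice(list("AWLG"), size=5)) for _ in range(30)]
        q = 1 / 20
        logo = rep.kl_logo(windows, pseudocount=1.0)
        for i in range(5):
            for a in rep.AMINO_ACIDS:
                c = sum(1 for w in windows if w[i] == a)
                p = (c + 1.0 * q) / (30 + 1.0)
                assert logo.weights.loc[i + 1, a] == pytest.approx(
                    p * np.log2(p / q), abs=1e-12)

    def test_enrichment_sign_convention(self):
        # depleted letters sit below zero, enriched above
        windows = ["W" * 3] * 9 + ["L" * 3]
        logo = rep.kl_logo(windows)
        assert (logo.weights["W"] > 0).all()
        assert (logo.weights["C"] < 0).all()  # absent letter is depleted

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            rep.kl_logo(["AAA", "AA"])
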