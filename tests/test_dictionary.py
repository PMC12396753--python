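from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rloopgram as rg
from rloopgram.dictionary import (
    RegionKmerCollection,
    RegionWeightTable,
    WeightRow,
    entropy_curve,
    genome_multiplicity,
    region_windows,
)


class TestRegionWindows:
    def test_window_geometry(self):
        win = region_windows(i=20, j=39, k=4, p=2)
        assert win["r1"] == [16, 15, 14]
        assert win["r2"] == [20, 21, 22]
        assert win["r3"] == [36, 35, 34]
        assert win["r4"] == [40, 41, 42]

    def test_window_count_with_padding(self, tiny_plasmid):
        # an interior footprint yields p + 1 windows in every region
        ds = rg.Dataset([rg.RLoopRecord("tiny", "linear", 13, 16)], "tiny", "linear")
        colls = rg.extract_region_kmers(ds, tiny_plasmid, k=3, p=1)
        assert all(colls[r].total() == 2 for r in ("r1", "r2", "r3", "r4"))

    def test_p_zero_single_window(self, tiny_plasmid):
        ds = rg.Dataset([rg.RLoopRecord("tiny", "linear", 13, 16)], "tiny", "linear")
        colls = rg.extract_region_kmers(ds, tiny_plasmid, k=4, p=0)
        assert all(colls[r].total() == 1 for r in ("r1", "r2", "r3", "r4"))
        assert list(colls["r2"].counts) == [tiny_plasmid.kmer_at(13, 4)]
        assert list(colls["r4"].counts) == [tiny_plasmid.kmer_at(17, 4)]

    def test_boundary_windows_discarded(self, tiny_plasmid):
        # footprint starting at b leaves no room for any r1 window
        b = tiny_plasmid.b
        ds = rg.Dataset([rg.RLoopRecord("tiny", "linear", b, b + 3)], "tiny", "linear")
        colls = rg.extract_region_kmers(ds, tiny_plasmid, k=4, p=2)
        assert colls["r1"].total() == 0
        assert colls["r2"].total() == 3


class TestWeights:
    def test_weight_formula(self):
        # one occurrence in the region, one in the genome, N=28 -> 1/28
        pl = rg.PlasmidSequence("p", "TTTTCAATTTTT", gene_region=(1, 12))
        coll = RegionKmerCollection("r4", 4, 0, Counter({"CAAT": 1}))
        table = rg.compute_weights(coll, pl, n_rloops=28)
        assert table.rows[0].weight == Fraction(1, 28)
        assert float(table.rows[0].weight) == pytest.approx(0.03571, abs=5e-6)

    def test_multiplicity_counts_overlaps(self):
        pl = rg.PlasmidSequence("p", "AAAAA", gene_region=(1, 5))
        assert genome_multiplicity(pl, 2)["AA"] == 4

    def test_equal_weights_grouped_in_one_rank(self):
        pl = rg.PlasmidSequence("p", "ACGTACGTTTTT", gene_region=(1, 12))
        coll = RegionKmerCollection("r1", 4, 0, Counter({"ACGT": 2, "CGTA": 1}))
        table = rg.compute_weights(coll, pl, n_rloops=10)
        # ACGT: 2/(10*2) = 1/10; CGTA: 1/(10*1) = 1/10 -> same rank group
        assert len(table.rows) == 1
        assert table.rows[0].kmers == ("ACGT", "CGTA")

    def test_missing_from_genome_is_error(self):
        pl = rg.PlasmidSequence("p", "AAAAAAAA", gene_region=(1, 8))
        coll = RegionKmerCollection("r1", 4, 0, Counter({"CCCC": 1}))
        with pytest.raises(ValueError, match="absent"):
            rg.compute_weights(coll, pl, n_rloops=5)


def brute_force_cutoff(weights):
    """Independent recomputation: argmax over running averages of H."""
    import math

    top = weights[0]
    H = []
    for w in weights:
        wp = w / top
        H.append(0.0 if wp == 1 else -wp * math.log10(wp))
    best_n, best_h = 1, -1.0
    for n in range(1, len(H) + 1):
        h = sum(H[:n]) / n
        if h > best_h:
            best_n, best_h = n, h
    return best_n


class TestEntropyThreshold:
    def test_published_weight_table_exact(self):
        # exact rational weights underlying a published r4 region table
        # (hyper-negatively supercoiled condition): the rescaled weights,
        # entropies and running averages match the printed 5-decimal values
        rescaled, H, h = entropy_curve(
            [Fraction(1, 28), Fraction(9, 280), Fraction(5, 168), Fraction(1, 112)]
        )
        assert rescaled[0] == 1.0 and H[0] == 0.0 and h[0] == 0.0
        for got, printed in [
            (rescaled[1], 0.90000), (H[1], 0.04118), (h[1], 0.02059),
            (rescaled[2], 0.83333), (H[2], 0.06598), (h[2], 0.03572),
            (rescaled[3], 0.25000), (H[3], 0.15051),
        ]:
            assert got == pytest.approx(printed, abs=5e-6)

    def test_printed_weight_inputs_within_rounding(self):
        # feeding the rounded printed weights reproduces the same columns
        # within the input-rounding tolerance
        _, H, h = entropy_curve([0.03571, 0.03214, 0.02976])
        assert H[1] == pytest.approx(0.04118, abs=5e-5)
        assert h[1] == pytest.approx(0.02059, abs=5e-5)
        assert H[2] == pytest.approx(0.06598, abs=5e-5)
        assert h[2] == pytest.approx(0.03572, abs=5e-5)

    def test_rank29_entropy_from_rescaled_quarter_weight(self):
        _, H, _ = entropy_curve([0.03571, 0.00893])
        assert H[1] == pytest.approx(0.15051, abs=5e-5)

    def test_exact_quarter_weight(self):
        _, H, _ = entropy_curve([Fraction(1, 4) * Fraction(1, 7), Fraction(1, 28) / 4])
        # w' = 1/4 exactly: H = -(1/4) log10(1/4)
        assert H[1] == pytest.approx(0.1505149978, abs=1e-9)

    def test_degenerate_all_equal(self):
        table = RegionWeightTable(
            "r1", [WeightRow(1, ("AAAA", "CCCC"), Fraction(1, 10))], n_rloops=10
        )
        out = rg.entropy_threshold(table)
        assert out.cutoff_rank == 1
        assert set(out.highly_weighted()) == {"AAAA", "CCCC"}

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=1, max_value=10_000), min_size=1, max_size=60,
            unique=True,
        )
    )
    def test_cutoff_matches_brute_force(self, counts):
        weights = sorted((Fraction(c, 10_000) for c in counts), reverse=True)
        rows = [
            WeightRow(rank, (f"K{rank}",), w) for rank, w in enumerate(weights, 1)
        ]
        table = rg.entropy_threshold(RegionWeightTable("r1", rows, n_rloops=1))
        assert table.cutoff_rank == brute_force_cutoff([float(w) for w in weights])

    def test_one_h_entry_per_rank_group(self):
        # four tied k-mers contribute a single rank and single h entry
        pl = rg.PlasmidSequence("p", "ACGTTGCAAATTCGCG", gene_region=(1, 16))
        counts = Counter({"ACGT": 4, "TGCA": 1, "AATT": 1, "CGCG": 1})
        table = rg.compute_weights(
            RegionKmerCollection("r1", 4, 0, counts), pl, n_rloops=10
        )
        assert [len(r.kmers) for r in table.rows] == [1, 3]


class TestAssignSymbols:
    def _table(self, region, entries, n=10):
        rows = [
            WeightRow(rank, (s,), w) for rank, (s, w) in enumerate(entries, 1)
        ]
        t = RegionWeightTable(region, rows, n_rloops=n)
        t.cutoff_rank = len(rows)
        return t

    def _tables(self, **kwargs):
        out = {}
        for region in ("r1", "r2", "r3", "r4"):
            out[region] = self._table(region, kwargs.get(region, []))
        return out

    def test_start_region_max_gives_sig_tauH(self):
        tables = self._tables(r2=[("AA", Fraction(1, 2))])
        dic = rg.assign_symbols(tables, k=2, p=0)
        assert dic.outside["AA"] == "sig" and dic.inside["AA"] == "tauH"

    def test_end_region_max_gives_sigH_tau(self):
        tables = self._tables(r4=[("AA", Fraction(1, 2))])
        dic = rg.assign_symbols(tables, k=2, p=0)
        assert dic.outside["AA"] == "sigH" and dic.inside["AA"] == "tau"

    def test_start_end_tie_gives_delta_beta(self):
        tables = self._tables(
            r1=[("AA", Fraction(1, 2))], r4=[("AA", Fraction(1, 2))]
        )
        dic = rg.assign_symbols(tables, k=2, p=0)
        assert dic.outside["AA"] == "delta" and dic.inside["AA"] == "beta"

    def test_unlisted_kmer_is_indeterminate(self):
        dic = rg.assign_symbols(self._tables(), k=2, p=0)
        assert dic.outside["GG"] == "gamma" and dic.inside["GG"] == "rho"

    def test_map_is_total(self):
        dic = rg.assign_symbols(self._tables(r2=[("AC", Fraction(1, 3))]), k=2, p=0)
        assert len(dic.outside) == 16 and len(dic.inside) == 16

    def test_start_beats_lower_end_weight(self):
        tables = self._tables(
            r1=[("AA", Fraction(1, 2))], r3=[("AA", Fraction(1, 3))]
        )
        dic = rg.assign_symbols(tables, k=2, p=0)
        assert dic.outside["AA"] == "sig"


class TestMergeUnion:
    def _dict(self, k, mapping_out, mapping_in):
        import itertools

        kmers = ["".join(t) for t in itertools.product("ACGT", repeat=k)]
        outside = {s: mapping_out.get(s, "gamma") for s in kmers}
        inside = {s: mapping_in.get(s, "rho") for s in kmers}
        return rg.SymbolDictionary(k=k, p=0, outside=outside, inside=inside)

    def test_agreement_copied(self):
        d1 = self._dict(2, {"AA": "sig"}, {"AA": "tauH"})
        d2 = self._dict(2, {"AA": "sig"}, {"AA": "tauH"})
        merged = rg.merge_union_dictionary(d1, d2, mode="deterministic")
        assert merged.outside["AA"] == "sig" and merged.inside["AA"] == "tauH"

    def test_determinate_conflict_becomes_ambiguous(self):
        d1 = self._dict(2, {"AA": "sig"}, {"AA": "tauH"})
        d2 = self._dict(2, {"AA": "sigH"}, {"AA": "tau"})
        merged = rg.merge_union_dictionary(d1, d2, mode="deterministic")
        assert merged.outside["AA"] == "delta" and merged.inside["AA"] == "beta"

    def test_determinate_beats_indeterminate(self):
        d1 = self._dict(2, {"AA": "sig"}, {"AA": "tauH"})
        d2 = self._dict(2, {}, {})  # AA indeterminate
        merged = rg.merge_union_dictionary(d1, d2, mode="deterministic")
        assert merged.outside["AA"] == "sig" and merged.inside["AA"] == "tauH"

    def test_stochastic_seeded_reproducible(self):
        d1 = self._dict(2, {"AA": "sig", "AC": "sigH"}, {"AA": "tauH"})
        d2 = self._dict(2, {"AA": "sigH", "AC": "sig"}, {"AA": "tau"})
        m1 = rg.merge_union_dictionary(d1, d2, mode="stochastic", seed=11)
        m2 = rg.merge_union_dictionary(d1, d2, mode="stochastic", seed=11)
        assert m1.outside == m2.outside and m1.inside == m2.inside
        # a stochastic pick always comes from one of the two parents
        assert m1.outside["AA"] in ("sig", "sigH")

    def test_kp_mismatch_errors(self):
        d1 = self._dict(2, {}, {})
        d3 = rg.SymbolDictionary(
            k=1, p=0,
            outside={s: "gamma" for s in "ACGT"},
            inside={s: "rho" for s in "ACGT"},
        )
        with pytest.raises(ValueError, match="merge"):
            rg.merge_union_dictionary(d1, d3)


def test_dictionary_tsv_round_trip(tmp_path, small_model):
    _, dic, _ = small_model
    path = tmp_path / "dict.tsv"
    dic.to_tsv(path)
    back = rg.SymbolDictionary.from_tsv(path)
    assert back.k == dic.k and back.p == dic.p
    assert back.outside == dic.outside and back.inside == dic.inside


def test_k3_dictionary_saturates_all_3mers(small_sample):
    """With k=3 a few hundred footprints exhaust all 64 3-mers."""
    spec, plasmid, ds = small_sample
    clean = rg.preprocess(ds, plasmid, 3)
    dic = rg.build_dictionary(clean, plasmid, 3, 7)
    assert dic.determinate_fraction() > 0.9
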