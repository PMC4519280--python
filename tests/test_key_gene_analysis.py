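import random

import pytest

import motifkey as mk
from motifkey.key_gene_analysis import KeyGeneRecord

from conftest import random_digraph


def _instances(motif, member_tuples):
    return [mk.MotifInstance(motif, tuple(m)) for m in member_tuples]


class TestGeneFrequencies:
    def test_single_instance_counts_each_gene_once(self):
        motif = mk.bifan_motif()
        freq = mk.gene_frequencies(_instances(motif, [("a", "b", "c", "d")]))
        assert dict(freq) == {"a": 1, "b": 1, "c": 1, "d": 1}

    def test_shared_gene_accumulates(self):
        motif = mk.bifan_motif()
        freq = mk.gene_frequencies(
            _instances(motif, [("a", "b", "c", "d"), ("a", "x", "y", "z")])
        )
        assert freq["a"] == 2
        assert all(freq[g] == 1 for g in "bcdxyz")

    def test_mixed_classes_rejected(self):
        i1 = _instances(mk.bifan_motif(), [("a", "b", "c", "d")])
        i2 = _instances(mk.chain_motif(4), [("a", "b", "c", "d")])
        with pytest.raises(ValueError):
            mk.gene_frequencies(i1 + i2)

    def test_recurrent_genes_in_overlapping_pattern(self):
        """Genes recurring across overlapping instances of one class show
        frequencies > 1, the structural signature behind recurrent
        regulators like kras/araf/pik3r5 in real pathways."""
        motif = mk.chain_motif(4).canonical()
        graph, instances = mk.plant_motifs(
            mk.DirectedGraph(nodes=[f"g{i:04d}" for i in range(1, 41)]),
            motif, copies=5, overlap_fraction=1.0, seed=0,
            gene_names=("kras", "araf", "pik3r5", "ralgds", "akt3"),
        )
        res = mk.enumerate_subgraphs(graph, 4)
        own = [i for i in res.instances if i.motif == motif]
        freq = mk.gene_frequencies(own)
        assert max(freq.values()) > 1
        assert set(freq) & {"kras", "araf", "pik3r5", "ralgds", "akt3"}


class TestKeyGeneRecord:
    @pytest.mark.parametrize(
        "fn, ftn, display",
        [(25, 76, 0.329), (12, 70, 0.171), (9, 16, 0.563), (13, 29, 0.448)],
    )
    def test_ft_display_rounding(self, fn, ftn, display):
        rec = KeyGeneRecord(motif=mk.bifan_motif(), fn=fn, ftn=ftn)
        assert rec.ft_display == display

    def test_all_unique_genes_give_ft_one(self):
        motif = mk.bifan_motif()
        insts = _instances(motif, [("a", "b", "c", "d"), ("e", "f", "g", "h")])
        rec = mk.compute_key_gene_record(insts)
        assert rec.ft == 1.0 and rec.fn == rec.ftn == 8

    def test_ftn_is_k_times_instances_on_enumerated_graphs(self):
        rng = random.Random(21)
        for _ in range(10):
            g = random_digraph(rng.randint(6, 10), rng.uniform(0.15, 0.35), rng)
            res = mk.enumerate_subgraphs(g, 4)
            by_class = {}
            for inst in res.instances:
                by_class.setdefault(inst.motif, []).append(inst)
            for motif, insts in by_class.items():
                rec = mk.compute_key_gene_record(insts)
                assert rec.ftn == 4 * len(insts)
                assert rec.fn <= rec.ftn
                assert 0 < rec.ft <= 1

    def test_overlapping_instance_strictly_lowers_ft(self):
        motif = mk.bifan_motif()
        base = _instances(motif, [("a", "b", "c", "d")])
        rec0 = mk.compute_key_gene_record(base)
        overlapping = base + _instances(motif, [("a", "b", "c", "e")])
        rec1 = mk.compute_key_gene_record(overlapping)
        assert rec1.ft < rec0.ft
        disjoint = base + _instances(motif, [("w", "x", "y", "z")])
        rec2 = mk.compute_key_gene_record(disjoint)
        assert rec2.ft <= rec0.ft

    def test_empty_instance_list_rejected(self):
        with pytest.raises(ValueError):
            mk.compute_key_gene_record([])


class TestSelectKeyMotif:
    def test_reference_table_selects_7n(self):
        records = mk.reference_records()
        key = mk.select_key_motif(records)
        assert key.ft_display == 0.171
        assert key.fn == 12 and key.ftn == 70

    def test_single_record_returned(self):
        rec = KeyGeneRecord(motif=mk.bifan_motif(), fn=4, ftn=8)
        assert mk.select_key_motif([rec]) is rec

    def test_tie_broken_by_larger_ftn(self):
        a = KeyGeneRecord(motif=mk.bifan_motif(), fn=35, ftn=70)
        b = KeyGeneRecord(motif=mk.chain_motif(4).canonical(), fn=25, ftn=50)
        assert mk.select_key_motif([a, b]) is a

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mk.select_key_motif([])


class TestRankKeyGenes:
    def test_frequency_then_alphabetical(self):
        rec = KeyGeneRecord(
            motif=mk.bifan_motif(),
            gene_freq={"kras": 10, "araf": 10, "pik3r5": 10, "ralgds": 10,
                       "akt3": 8, "rhoa": 6},
        )
        ranked = mk.rank_key_genes(rec, top=6)
        assert [g for g, _ in ranked[:4]] == ["araf", "kras", "pik3r5", "ralgds"]
        assert ranked[4] == ("akt3", 8)
        assert ranked[5] == ("rhoa", 6)

    def test_all_equal_frequencies_alphabetical(self):
        rec = KeyGeneRecord(motif=mk.bifan_motif(),
                            gene_freq={"c": 2, "a": 2, "b": 2})
        assert [g for g, _ in mk.rank_key_genes(rec, top=3)] == ["a", "b", "c"]

    def test_truncation(self):
        rec = KeyGeneRecord(motif=mk.bifan_motif(), gene_freq={"a": 3, "b": 1})
        assert mk.rank_key_genes(rec, top=1) == [("a", 3)]


class TestTFImportance:
    def test_identity_weight_and_zero_frequency(self):
        assert mk.tf_importance(0.42, 1.0) == 0.42
        assert mk.tf_importance(0.0, 7.5) == 0.0

    def test_recovers_published_importance_from_frequency(self):
        # an importance/frequency pair published for a recurrent CRC TF:
        # frequency 31.80%, importance 0.31802 -> weight by division
        frequency = 0.3180
        weight = 0.31802 / frequency
        assert mk.tf_importance(frequency, weight) == pytest.approx(0.31802)

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            mk.tf_importance(1.2, 1.0)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.5625, 0.563), (0.4485, 0.449), (0.171428, 0.171), (1.0, 1.0)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert mk.round_half_away(value, 3) == expected
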