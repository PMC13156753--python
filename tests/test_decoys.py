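"""Decoy generation: mapping, enumeration, overlap and affinity filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhcassign.decoys import (
    enumerate_candidates,
    filter_hard_negatives,
    filter_overlaps,
    generate_decoys,
    map_ligands_to_proteins,
    sample_decoys,
)
from mhcassign.io import Proteome


def brute_force_count(length):
    """Independent enumeration: count substrings of lengths 8..11 directly."""
    return sum(
        1
        for k in range(8, 12)
        for start in range(length)
        if start + k <= length
    )


class FixedAffinity:
    """Affinity predictor backed by a lookup with a default."""

    def __init__(self, table=None, default=1000.0):
        self.table = table or {}
        self.default = default

    def predict(self, peptide, allele):
        return self.table.get((peptide, allele), self.default)


@pytest.fixture
def toy_proteome():
    return Proteome(
        entries={
            "P1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
            "P2": "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL",
            "P3": "MKTAYIAKQRQISF",  # shares a prefix with P1
        }
    )


class TestMapping:
    def test_unique_multi_and_unmapped(self, toy_proteome):
        mapping = map_ligands_to_proteins(
            ["KQRQISFV", "MKTAYIAK", "WWWWWWWW"], toy_proteome
        )
        assert mapping.unique == {"KQRQISFV": "P1"}
        assert set(mapping.multi_mapping) == {"MKTAYIAK"}
        assert mapping.unmapped == ["WWWWWWWW"]

    def test_empty_proteome_raises(self):
        with pytest.raises(ValueError):
            map_ligands_to_proteins(["ACDEFGHI"], Proteome(entries={}))


class TestEnumerate:
    @pytest.mark.parametrize("length, expected", [(12, 14), (8, 1), (7, 0), (11, 10)])
    def test_count_closed_form(self, length, expected):
        cands = enumerate_candidates("P", "A" * length)
        assert len(cands) == expected

    @given(st.integers(0, 100))
    @settings(max_examples=60, deadline=None)
    def test_count_matches_brute_force(self, length):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 6
        cands = enumerate_candidates("P", seq[:length])
        assert len(cands) == brute_force_count(length)
        for c in cands:
            assert c.sequence == seq[c.start : c.start + c.length]


class TestOverlapFilter:
    def test_sequence_identity_removed(self):
        cands = enumerate_candidates("P", "ACDEFGHIKLMN")
        positives = ["ACDEFGHI"]
        kept = filter_overlaps(cands, positives)
        assert all(c.sequence != "ACDEFGHI" for c in kept)
        assert len(kept) == len(cands) - 1

    def test_interval_mode_removes_partial_overlap(self):
        cands = enumerate_candidates("P", "ACDEFGHIKLMN")
        # positive occupies [0, 8); a candidate sharing 7 residues overlaps
        kept = filter_overlaps(
            cands, ["ACDEFGHI"], mode="interval",
            positive_intervals={"P": [(0, 8)]},
        )
        for c in kept:
            assert c.start >= 8 or c.start + c.length <= 0
        # brute-force interval check as oracle
        oracle = [c for c in cands if not (c.start < 8 and 0 < c.start + c.length)]
        assert kept == oracle

    def test_protein_without_positives_kept_in_sequence_mode(self):
        cands = enumerate_candidates("Q", "LMNPQRSTVWYA")
        assert filter_overlaps(cands, ["ACDEFGHI"]) == cands


class TestHardNegativeFilter:
    @pytest.mark.parametrize(
        "nm, kept", [(1500.0, True), (2000.0, True), (2500.0, False)]
    )
    def test_threshold_boundary_inclusive(self, nm, kept):
        cands = enumerate_candidates("P", "ACDEFGHI")
        predictor = FixedAffinity(default=nm)
        out = filter_hard_negatives(cands, "HLA-A*02:01", predictor)
        assert (len(out) == 1) is kept

    def test_exclusive_mode(self):
        cands = enumerate_candidates("P", "ACDEFGHI")
        out = filter_hard_negatives(
            cands, "HLA-A*02:01", FixedAffinity(default=2000.0), inclusive=False
        )
        assert out == []

    def test_predictor_failure_names_allele(self):
        class Broken:
            def predict(self, peptide, allele):
                raise KeyError(allele)

        cands = enumerate_candidates("P", "ACDEFGHI")
        with pytest.raises(RuntimeError, match="HLA-B\\*08:01"):
            filter_hard_negatives(cands, "HLA-B*08:01", Broken())


class TestSampling:
    def _pool(self, n):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        cands = enumerate_candidates("P", seq[: n + 7])[:n]
        return [(c, "HLA-A*02:01") for c in cands]

    def test_count_contract(self):
        out = sample_decoys(self._pool(10), n_positives=2, ratio=3, seed=0)
        assert len(out) == 6

    def test_exhaustion_returns_all(self):
        out = sample_decoys(self._pool(50), n_positives=3, ratio=1000, seed=0)
        assert len(out) == 50

    def test_deterministic(self):
        a = sample_decoys(self._pool(30), 2, 5, seed=42)
        b = sample_decoys(self._pool(30), 2, 5, seed=42)
        assert a.pairs == b.pairs

    def test_exchangeable_under_input_permutation(self):
        pool = self._pool(30)
        rng = np.random.default_rng(0)
        shuffled = [pool[i] for i in rng.permutation(len(pool))]
        a = sample_decoys(pool, 2, 5, seed=7)
        b = sample_decoys(shuffled, 2, 5, seed=7)
        assert a.pairs == b.pairs


class TestPipeline:
    def test_disjointness_and_affinity_invariants(self):
        rng = np.random.default_rng(123)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        background = "".join(rng.choice(aas, size=200))
        positives = ["ACDEFGHIK", "LMNPQRSTV"]
        seq = positives[0] + background[:80] + positives[1] + background[80:]
        proteome = Proteome(entries={"P1": seq})
        predictor = FixedAffinity(default=500.0)
        decoy_set = generate_decoys(
            positives, proteome, ["HLA-A*02:01"], predictor, ratio=10, seed=3
        )
        assert decoy_set.sequences().isdisjoint(positives)
        for frag, allele in decoy_set.pairs:
            assert predictor.predict(frag.sequence, allele) <= 2000.0
        rerun = generate_decoys(
            positives, proteome, ["HLA-A*02:01"], predictor, ratio=10, seed=3
        )
        assert rerun.pairs == decoy_set.pairs
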