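"""Data pathway: filtering, stratified sampling, randomization,
tokenization, batching, chirality enrichment."""

import numpy as np
import pytest
from scipy import stats

from chemtrace.corpus import (Vocabulary, canonicalize,
                              chirality_enriched_resample, filter_molecules,
                              make_batches, make_pairs, padding_fraction,
                              randomize_smiles, split_tokens,
                              stratified_sample, train_test_split)
from chemtrace.synthetic import MoleculeRecord


class TestFilter:
    def test_heavy_atom_window(self):
        assert filter_molecules(["CC", "CCO"]) == ["CCO"]

    def test_salt_stripping_keeps_largest_fragment(self):
        assert filter_molecules(["CCO.[Na+]"]) == ["CCO"]

    def test_foreign_element_rejected(self):
        assert filter_molecules(["[Si](C)(C)C"]) == []

    def test_invalid_lines_dropped(self):
        assert filter_molecules(["notasmiles", "C1CC"]) == []

    def test_upper_bound(self):
        big = "C" * 51
        assert filter_molecules([big]) == []
        assert filter_molecules(["C" * 50]) == ["C" * 50]


class TestStratifiedSample:
    def test_cap_rule(self, rng):
        pool = ["C" * 5] * 10 + ["C" * 7] * 3  # lengths 5 and 7
        out = stratified_sample(pool, per_length_cap=5, rng=rng)
        lengths = [len(s) for s in out]
        assert lengths.count(5) == 5 and lengths.count(7) == 3

    def test_identity_when_cap_exceeds_pool(self, rng):
        pool = [f"{'C' * k}O" for k in range(1, 6)]
        out = stratified_sample(pool, per_length_cap=100, rng=rng)
        assert sorted(out) == sorted(pool)

    def test_group_counts_match_histogram_oracle(self, small_corpus, rng):
        pool = [r.canonical_smiles for r in small_corpus] * 3
        cap = 7
        out = stratified_sample(pool, cap, rng)
        from collections import Counter
        pool_hist = Counter(len(s) for s in pool)
        out_hist = Counter(len(s) for s in out)
        for length, n in pool_hist.items():
            assert out_hist[length] == min(n, cap)


class TestRandomize:
    def test_round_trip(self, rng):
        assert canonicalize(randomize_smiles("OCC", rng)) == canonicalize("OCC")

    def test_single_atom_is_fixed_point(self, rng):
        assert randomize_smiles("C", rng) == "C"

    def test_renumbering_produces_diversity(self, rng):
        smi = canonicalize("CC(C)CC(N)C(=O)OCC1CCCO1")  # 20 heavy atoms
        variants = {randomize_smiles(smi, rng) for _ in range(1000)}
        assert len(variants) > 1

    def test_unparseable_raises(self, rng):
        with pytest.raises(ValueError):
            randomize_smiles("C1CC", rng)


class TestTokenizer:
    def test_parity_and_two_letter_tokens_are_units(self):
        assert split_tokens("C[C@@H](N)O") == \
            ["C", "[", "C", "@@", "H", "]", "(", "N", ")", "O"]
        assert split_tokens("CCl") == ["C", "Cl"]
        assert split_tokens("C%12CC%12") == ["C", "%12", "C", "C", "%12"]

    def test_round_trip_over_corpus(self, small_corpus, small_vocab, rng):
        strings = [r.canonical_smiles for r in small_corpus]
        strings += [randomize_smiles(s, rng) for s in strings]
        for s in strings:
            assert small_vocab.decode(small_vocab.encode(s)) == s

    def test_encode_decode_structure(self, small_vocab):
        ids = small_vocab.encode("CCO")
        assert ids[0] == small_vocab.start_id and ids[-1] == small_vocab.end_id

    def test_unknown_token_handling(self, small_vocab):
        assert small_vocab.unk_id in small_vocab.encode("CZ")
        with pytest.raises(KeyError):
            small_vocab.encode("CZ", on_unknown="raise")

    def test_serialization_round_trip(self, small_vocab, tmp_path):
        path = tmp_path / "vocab.json"
        small_vocab.to_json(path)
        loaded = Vocabulary.from_json(path)
        assert loaded.tokens == small_vocab.tokens


class TestBatching:
    def _pairs(self, small_corpus, small_vocab, rng):
        return make_pairs(small_corpus, small_vocab, small_vocab, rng)

    def test_budget_respected_and_each_pair_once(self, small_corpus, small_vocab, rng):
        pairs = self._pairs(small_corpus, small_vocab, rng)
        budget = 200
        batches = make_batches(pairs, budget, bucketing=True, rng=rng,
                               pad_id=small_vocab.pad_id)
        seen = []
        for b in batches:
            assert b.source.shape[0] * b.source.shape[1] <= budget
            seen.extend(b.molecule_indices.tolist())
        assert sorted(seen) == sorted(p.molecule_index for p in pairs)

    def test_equal_lengths_pack_exactly(self, small_vocab):
        ids = small_vocab.encode("CCO")
        pairs = [type("P", (), {"source": ids, "target": ids,
                                "molecule_index": i})() for i in range(10)]
        batches = make_batches(pairs, token_budget=5 * len(ids),
                               bucketing=False,
                               rng=np.random.default_rng(0),
                               pad_id=small_vocab.pad_id)
        assert sorted(b.source.shape[0] for b in batches) == [5, 5]

    def test_bucketing_reduces_padding(self, small_corpus, small_vocab):
        pairs = make_pairs(small_corpus, small_vocab, small_vocab,
                           np.random.default_rng(1))
        on = make_batches(pairs, 300, True, np.random.default_rng(2),
                          small_vocab.pad_id)
        off = make_batches(pairs, 300, False, np.random.default_rng(2),
                           small_vocab.pad_id)
        assert padding_fraction(on, small_vocab.pad_id) <= \
            padding_fraction(off, small_vocab.pad_id)

    def test_reproducible_given_seed(self, small_corpus, small_vocab):
        pairs = make_pairs(small_corpus, small_vocab, small_vocab,
                           np.random.default_rng(1))
        a = make_batches(pairs, 300, True, np.random.default_rng(5),
                         small_vocab.pad_id)
        b = make_batches(pairs, 300, True, np.random.default_rng(5),
                         small_vocab.pad_id)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.source, y.source)
            assert np.array_equal(x.target, y.target)

    def test_oversized_pair_raises(self, small_corpus, small_vocab, rng):
        pairs = self._pairs(small_corpus, small_vocab, rng)
        with pytest.raises(ValueError):
            make_batches(pairs, 2, bucketing=False, rng=rng,
                         pad_id=small_vocab.pad_id)

    def test_batches_pair_same_molecule(self, small_corpus, small_vocab, rng):
        """Every batch row decodes to a (source, target) pair describing the
        same molecule."""
        pairs = self._pairs(small_corpus, small_vocab, rng)
        batches = make_batches(pairs, 300, True, rng, small_vocab.pad_id)
        for b in batches[:3]:
            for row in range(b.source.shape[0]):
                src = small_vocab.decode(b.source[row])
                tgt = small_vocab.decode(b.target[row])
                assert canonicalize(src) == tgt


class TestChiralityEnrichment:
    def test_pure_chiral_corpus_unchanged(self, rng):
        recs = [MoleculeRecord("C[C@H](N)O", has_stereocenter=True)] * 50
        assert len(chirality_enriched_resample(recs, 0.5, rng)) == 50

    def test_zero_keep_prob_leaves_chiral_subset(self, rng):
        recs = ([MoleculeRecord("C[C@H](N)O", has_stereocenter=True)] * 5
                + [MoleculeRecord("CCO")] * 20)
        out = chirality_enriched_resample(recs, 0.0, rng)
        assert len(out) == 5
        assert all("@" in r.canonical_smiles for r in out)

    def test_retention_rate_within_binomial_interval(self):
        recs = [MoleculeRecord("CCO")] * 10_000
        out = chirality_enriched_resample(recs, 0.5,
                                          np.random.default_rng(3))
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.5)
        assert lo <= len(out) <= hi


def test_train_test_split_partitions(small_corpus, rng):
    train, test = train_test_split(small_corpus, 0.25, rng)
    assert len(test) == round(0.25 * len(small_corpus))
    assert len(train) + len(test) == len(small_corpus)
    overlap = {r.canonical_smiles for r in train} & \
        {r.canonical_smiles for r in test}
    assert not overlap
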