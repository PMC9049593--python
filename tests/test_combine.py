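"""Combined-corpus construction: normalization, stripping, re-splitting."""

import random
import re

import pytest

from chemner.combine import (
    NUM_TOKEN,
    build_combined_corpus,
    normalize_entity_string,
    replace_numeric_tokens,
    resplit_train_dev,
    strip_nonchemical_labels,
    unique_entity_stats,
)
from chemner.corpora import entity_token_spans
from chemner.synthcorpus import SynthConfig, generate_corpus

from conftest import make_seq, random_bio_tags


class TestNormalize:
    @pytest.mark.parametrize(
        "surface,expect",
        [
            ("TiO2", "tio2"),
            ("N, N-dimethyl formamide", "n,n-dimethylformamide"),
            ("  spaced\tout\nname ", "spacedoutname"),
        ],
    )
    def test_lowercase_and_whitespace_removal(self, surface, expect):
        assert normalize_entity_string(surface) == expect

    def test_idempotence_on_fuzzed_strings(self):
        rng = random.Random(2)
        alphabet = "aA zZ\t09-,."
        for _ in range(300):
            s = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 20)))
            once = normalize_entity_string(s)
            assert normalize_entity_string(once) == once


class TestUniqueEntityStats:
    def test_normalization_collapses_variants(self):
        assert unique_entity_stats({"TiO2", "tio2"}, {"TiO 2"}) == (1, 1, 1)

    def test_disjoint_sets(self):
        assert unique_entity_stats({"a"}, {"b"}) == (1, 1, 0)

    def test_on_synthetic_corpora(self):
        a = generate_corpus(SynthConfig(n_docs=30, seed=1))
        b = generate_corpus(SynthConfig(n_docs=30, seed=2))
        sa = [m.surface for d in a.documents for m in d.mentions]
        sb = [m.surface for d in b.documents for m in d.mentions]
        na, nb, common = unique_entity_stats(sa, sb)
        assert 0 < common <= min(na, nb)  # shared grammar => some overlap


class TestNumericReplacement:
    def test_pure_number_replaced(self):
        seq = make_seq(["grown", "at", "450", "K"], ["O", "O", "O", "O"])
        out = replace_numeric_tokens(seq)
        assert out.words() == ["grown", "at", NUM_TOKEN, "K"]
        assert out.tags == seq.tags and len(out.tokens) == len(seq.tokens)

    def test_alphanumeric_untouched(self):
        seq = make_seq(["TiO2", "4.5", "1,200", "4a"], ["B-CHEM", "O", "O", "O"])
        assert replace_numeric_tokens(seq).words() == ["TiO2", NUM_TOKEN, NUM_TOKEN, "4a"]

    def test_replacement_count_matches_regex_oracle(self):
        rng = random.Random(11)
        pat = re.compile(r"\d+(?:[.,]\d+)*")
        pool = ["450", "4.5", "1,2", "TiO2", "water", "a1", "7", ".", "-"]
        for _ in range(100):
            words = [rng.choice(pool) for _ in range(rng.randint(1, 12))]
            seq = make_seq(words, ["O"] * len(words))
            out = replace_numeric_tokens(seq)
            expect = sum(1 for w in words if pat.fullmatch(w))
            assert sum(w == NUM_TOKEN for w in out.words()) == expect


class TestLabelStripping:
    def test_nonchemical_tags_become_o(self):
        seq = make_seq(["GaN", "is", "blue"], ["B-MAT", "O", "B-PRO"])
        out = strip_nonchemical_labels(seq, chemical_classes=["MAT"])
        assert out.tags == ["B-MAT", "O", "O"]

    def test_all_chemical_is_identity(self):
        seq = make_seq(["GaN", "AlN"], ["B-MAT", "B-MAT"])
        assert strip_nonchemical_labels(seq, ["MAT"]).tags == seq.tags

    def test_unknown_class_inventory_raises(self):
        seq = make_seq(["x"], ["B-WEIRD"])
        with pytest.raises(ValueError, match="WEIRD"):
            strip_nonchemical_labels(seq, ["MAT"], known_classes=["PRO"])

    def test_entity_set_matches_filter_oracle_on_fuzzed_sequences(self):
        rng = random.Random(21)
        for _ in range(200):
            n = rng.randint(1, 15)
            tags = random_bio_tags(rng, n, classes=("MAT", "PRO", "APL"))
            seq = make_seq([f"w{i}" for i in range(n)], tags)
            out = strip_nonchemical_labels(seq, ["MAT"])
            expect = [s for s in entity_token_spans(tags) if s[2] == "MAT"]
            assert entity_token_spans(out.tags) == expect


class TestResplit:
    def test_90_10_on_100_docs(self):
        train, dev = resplit_train_dev(list(range(100)), ratio=0.9, seed=0)
        assert len(train) == 90 and len(dev) == 10
        assert sorted(train + dev) == list(range(100))

    def test_same_seed_same_split(self):
        docs = list(range(57))
        assert resplit_train_dev(docs, seed=5) == resplit_train_dev(docs, seed=5)
        assert resplit_train_dev(docs, seed=5) != resplit_train_dev(docs, seed=6)

    def test_invalid_ratio_and_too_few_docs(self):
        with pytest.raises(ValueError):
            resplit_train_dev(list(range(20)), ratio=1.5)
        with pytest.raises(ValueError):
            resplit_train_dev(list(range(5)))

    def test_dev_membership_frequency_over_reshuffles(self):
        """Monte-Carlo: each document lands in dev ~10% of the time (3 sigma)."""
        docs = list(range(30))
        n_trials = 1000
        counts = {d: 0 for d in docs}
        for seed in range(n_trials):
            _, dev = resplit_train_dev(docs, ratio=0.9, seed=seed)
            for d in dev:
                counts[d] += 1
        p = 0.1
        sigma = (n_trials * p * (1 - p)) ** 0.5
        for d, c in counts.items():
            assert abs(c - n_trials * p) < 3 * sigma + 1e-9, (d, c)


class TestBuildCombined:
    @pytest.fixture
    def sources(self):
        cd = generate_corpus(SynthConfig(n_docs=12, seed=3, fused_fraction=0.0))
        ms_corpus = generate_corpus(
            SynthConfig(n_docs=6, seed=4, label="MAT",
                        extra_classes=("PRO",), extra_class_rate=0.1,
                        fused_fraction=0.0))
        return cd.documents, ms_corpus.sequences

    def test_train_contains_both_provenances(self, sources):
        docs, ms = sources
        combined = build_combined_corpus(docs, ms, seed=0)
        provs = {s.provenance for s in combined.train}
        assert provs == {"chemdner", "matscholar"}

    def test_fixed_seed_is_deterministic(self, sources, tmp_path):
        from chemner.corpora import write_conll

        docs, ms = sources
        p1, p2 = tmp_path / "a.conll", tmp_path / "b.conll"
        write_conll(build_combined_corpus(docs, ms, seed=7).train, p1)
        write_conll(build_combined_corpus(docs, ms, seed=7).train, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_chemical_mentions_conserved(self, sources):
        """No chemical mention is lost or created by the pipeline."""
        docs, ms = sources
        n_chem_docs = sum(len(d.mentions) for d in docs)
        n_chem_ms = sum(
            sum(1 for s_ in entity_token_spans(s.tags) if s_[2] == "MAT") for s in ms)
        combined = build_combined_corpus(docs, ms, seed=1)
        total = sum(
            len(entity_token_spans(s.tags)) for s in combined.train + combined.dev)
        assert total == n_chem_docs + n_chem_ms

    def test_stripping_and_num_never_change_lengths_or_spans(self, sources):
        _, ms = sources
        for s in ms:
            stripped = strip_nonchemical_labels(s, ["MAT"])
            replaced = replace_numeric_tokens(stripped)
            assert len(replaced.tokens) == len(s.tokens)
            chem = [x for x in entity_token_spans(s.tags) if x[2] == "MAT"]
            assert entity_token_spans(replaced.tags) == chem

    def test_pipeline_is_a_permutation_of_sentences(self, sources):
        """Re-splitting and shuffling rearrange sentences; the multiset over
        train+dev is invariant across seeds."""
        docs, ms = sources
        c1 = build_combined_corpus(docs, ms, seed=2)
        c2 = build_combined_corpus(docs, ms, seed=9)
        key = lambda s: (tuple(s.words()), tuple(s.tags))
        assert sorted(map(key, c1.train + c1.dev)) == sorted(map(key, c2.train + c2.dev))
        assert [key(s) for s in c1.train] != [key(s) for s in c2.train]

    def test_manifest_counts(self, sources):
        docs, ms = sources
        c = build_combined_corpus(docs, ms, seed=0)
        assert c.manifest["n_train_sentences"] == len(c.train)
        assert c.manifest["provenance_counts"]["train"]["matscholar"] == len(ms)
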