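import numpy as np
import pandas as pd
import pytest

from phoskg.dataset import (
    ClassificationSample,
    InteractionSet,
    SpecificityTable,
    build_neg_km,
    build_neg_ks,
    generate_negatives,
    load_positives,
    read_samples,
    split_per_kinase,
    write_samples,
)


class TestInteractionSet:
    def test_orientation_independent(self):
        s = InteractionSet()
        s.add("A", "B")
        assert ("B", "A") in s
        assert ("A", "B") in s

    def test_no_self_pairs(self):
        s = InteractionSet()
        with pytest.raises(ValueError, match="self"):
            s.add("A", "A")

    def test_string_score_dialects(self):
        s = InteractionSet()
        s.add("A", "B", "string", 900)  # 0-999 scale -> 0.9
        s.add("C", "D", "string", 0.9)
        assert s.evidence_pairs(0.75) == {frozenset("AB"), frozenset("CD")}

    def test_string_threshold_discards(self):
        s = InteractionSet()
        s.add("A", "B", "string", 0.6)
        s.add("C", "D", "biogrid", 0.6)  # non-STRING always counts
        assert s.evidence_pairs(0.75) == {frozenset("CD")}


class TestLoadPositives:
    def test_confidence_threshold(self):
        df = pd.DataFrame(
            dict(kinase=["K1", "K2"], substrate=["S1", "S2"],
                 motif=["AAAASAAAA", "AAAATAAAA"], confidence=[0.5, 2.0])
        )
        out = load_positives([df], min_confidence=1.0)
        assert [p.kinase for p in out] == ["K2"]

    def test_rows_without_confidence_kept(self):
        df = pd.DataFrame(dict(kinase=["K1"], substrate=["S1"], motif=["AAAASAAAA"]))
        assert len(load_positives([df])) == 1

    def test_dedup(self):
        df = pd.DataFrame(
            dict(kinase=["K1", "K1"], substrate=["S1", "S1"], motif=["AAAASAAAA"] * 2)
        )
        assert len(load_positives([df])) == 1

    def test_motif_from_site_and_sequence(self):
        df = pd.DataFrame(dict(kinase=["K1"], substrate=["S1"], site=[5]))
        out = load_positives([df], sequences={"S1": "MTPKSPSTD"})
        assert out[0].motif == "MTPKSPSTD"

    def test_missing_sequence_lists_substrates(self):
        df = pd.DataFrame(dict(kinase=["K1"], substrate=["SUBX"], site=[5]))
        with pytest.raises(KeyError, match="SUBX"):
            load_positives([df], sequences={})

    def test_mixed_table_against_row_filter_oracle(self, rng):
        n = 200
        df = pd.DataFrame(
            dict(
                kinase=[f"K{rng.integers(0, 5)}" for _ in range(n)],
                substrate=[f"S{rng.integers(0, 10)}" for _ in range(n)],
                motif=[
                    "".join(rng.choice(list("ACDG"), 4))
                    + rng.choice(list("STY"))
                    + "".join(rng.choice(list("ACDG"), 4))
                    for _ in range(n)
                ],
                confidence=rng.uniform(0, 3, n).round(2),
            )
        )
        out = load_positives([df], min_confidence=1.0)
        survivors = df[df.confidence >= 1.0]
        expected = {
            (r.kinase, r.substrate, r.motif) for r in survivors.itertuples()
        }
        assert {(p.kinase, p.substrate, p.motif) for p in out} == expected
        assert all(p.label == 1 for p in out)


class TestNegKS:
    def test_complement(self):
        inter = InteractionSet()
        inter.add("K1", "S1", "biogrid", 1.0)
        out = build_neg_ks(["K1", "K2"], ["S1", "S2"], inter)
        assert out == {("K1", "S2"), ("K2", "S1"), ("K2", "S2")}

    def test_low_confidence_string_pair_is_noninteracting(self):
        inter = InteractionSet()
        inter.add("K1", "S1", "string", 0.6)
        out = build_neg_ks(["K1"], ["S1"], inter, string_threshold=0.75)
        assert out == {("K1", "S1")}

    def test_empty_lists_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            build_neg_ks([], ["S1"], InteractionSet())

    def test_random_against_set_algebra_oracle(self, rng):
        kinases = [f"K{i}" for i in range(8)]
        substrates = [f"S{i}" for i in range(12)]
        inter = InteractionSet()
        evidence = set()
        for _ in range(40):
            k = kinases[rng.integers(0, 8)]
            s = substrates[rng.integers(0, 12)]
            source = ["string", "biogrid", "bioplex"][rng.integers(0, 3)]
            conf = float(rng.uniform(0, 1))
            inter.add(k, s, source, conf)
            if source != "string" or conf >= 0.75:
                evidence.add(frozenset((k, s)))
        out = build_neg_ks(kinases, substrates, inter, 0.75)
        expected = {
            (k, s)
            for k in kinases
            for s in substrates
            if k != s and frozenset((k, s)) not in evidence
        }
        assert out == expected


class TestNegKM:
    def _tables(self):
        st = SpecificityTable("ST")
        st.add("KST", "AAAASAAAA", 150)
        st.add("KST", "CCCCSCCCC", 149)
        y = SpecificityTable("Y")
        y.add("KY", "AAAAYAAAA", 10.0)
        y.add("KY", "CCCCYCCCC", 10.1)
        return st, y

    def test_boundaries(self):
        st, y = self._tables()
        out = build_neg_km(st, y)
        assert ("KST", "AAAASAAAA") in out  # rank 150 inclusive
        assert ("KST", "CCCCSCCCC") not in out
        assert ("KY", "AAAAYAAAA") in out  # percentile 10.0 inclusive
        assert ("KY", "CCCCYCCCC") not in out

    def test_conflicting_class_error(self):
        st = SpecificityTable("ST")
        st.add("K", "AAAASAAAA", 1)
        y = SpecificityTable("Y")
        y.add("K", "AAAAYAAAA", 50)
        with pytest.raises(ValueError, match="both"):
            build_neg_km(st, y)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            SpecificityTable("ST").add("K", "AAAASAAAA", 0)
        with pytest.raises(ValueError, match="percentile"):
            SpecificityTable("Y").add("K", "AAAAYAAAA", 101)

    def test_random_tables_against_threshold_oracle(self, rng):
        st = SpecificityTable("ST")
        y = SpecificityTable("Y")
        expected = set()
        for i in range(100):
            k, m = f"KST{i % 7}", f"M{i}"
            rank = int(rng.integers(1, 400))
            st.add(k, m, rank)
            if rank >= 150:
                expected.add((k, m))
        for i in range(100):
            k, m = f"KY{i % 5}", f"N{i}"
            pct = float(rng.uniform(0, 100))
            y.add(k, m, pct)
            if pct <= 10:
                expected.add((k, m))
        assert build_neg_km(st, y) == expected


class TestGenerateNegatives:
    def _world(self):
        positives = [ClassificationSample("K1", "S1", "AAAASAAAA", 1)]
        registry = {("S1", "AAAASAAAA"), ("S1", "CCCCSCCCC"), ("S2", "AAAASAAAA")}
        neg_km = {("K9", "AAAASAAAA"), ("K1", "CCCCSCCCC")}
        neg_ks = {("K8", "S1"), ("K1", "S2")}
        return positives, neg_ks, neg_km, registry

    def test_all_four_methods_fire(self):
        positives, neg_ks, neg_km, registry = self._world()
        negs, skipped = generate_negatives(positives, neg_ks, neg_km, registry, seed=0)
        assert skipped == 0
        assert len(negs) == 4
        assert set(negs) == {
            ClassificationSample("K9", "S1", "AAAASAAAA", 0),  # method 1
            ClassificationSample("K8", "S1", "AAAASAAAA", 0),  # method 2
            ClassificationSample("K1", "S1", "CCCCSCCCC", 0),  # method 3
            ClassificationSample("K1", "S2", "AAAASAAAA", 0),  # method 4
        }

    def test_never_emits_a_positive(self):
        positives = [
            ClassificationSample("K1", "S1", "AAAASAAAA", 1),
            ClassificationSample("K9", "S1", "AAAASAAAA", 1),  # method-1 candidate
        ]
        registry = {("S1", "AAAASAAAA")}
        neg_km = {("K9", "AAAASAAAA")}
        neg_ks = set()
        negs, _ = generate_negatives(positives, neg_ks, neg_km, registry, seed=0)
        keys = {(n.kinase, n.substrate, n.motif) for n in negs}
        assert ("K9", "S1", "AAAASAAAA") not in keys

    def test_registry_validity_enforced(self):
        positives = [ClassificationSample("K1", "S1", "AAAASAAAA", 1)]
        with pytest.raises(ValueError, match="registry"):
            generate_negatives(positives, {("K2", "S1")}, set(), set(), seed=0)

    def test_deterministic_and_order_independent(self):
        rng = np.random.default_rng(9)
        positives = []
        registry = set()
        for i in range(20):
            m = "".join(rng.choice(list("ACDG"), 4)) + "S" + "".join(rng.choice(list("ACDG"), 4))
            s = f"S{i % 6}"
            registry.add((s, m))
            positives.append(ClassificationSample(f"K{i % 4}", s, m, 1))
        neg_km = {(f"K{i % 7}", m) for i, (s, m) in enumerate(sorted(registry))}
        neg_ks = {(f"K{i}", f"S{j}") for i in range(7) for j in range(6) if (i + j) % 3}
        a, _ = generate_negatives(positives, neg_ks, neg_km, registry, seed=5)
        b, _ = generate_negatives(list(reversed(positives)), neg_ks, neg_km, registry, seed=5)
        assert sorted(a) == sorted(b)

    def test_admissibility_against_exhaustive_oracle(self, rng):
        positives = []
        registry = set()
        for i in range(15):
            m = "".join(rng.choice(list("ACD"), 4)) + "S" + "".join(rng.choice(list("ACD"), 4))
            s = f"S{i % 5}"
            registry.add((s, m))
            positives.append(ClassificationSample(f"K{i % 3}", s, m, 1))
        neg_km = {(f"K{i % 6}", m) for i, (s, m) in enumerate(sorted(registry)) if i % 2}
        neg_ks = {(f"K{i}", f"S{j}") for i in range(6) for j in range(5) if (i * j) % 4 != 1}
        negs, _ = generate_negatives(positives, neg_ks, neg_km, registry, seed=1)

        pos_keys = {(p.kinase, p.substrate, p.motif) for p in positives}
        admissible = set()
        for k, s, m, _ in positives:
            admissible |= {(k2, s, m) for (k2, m2) in neg_km if m2 == m}  # 1
            admissible |= {(k2, s, m) for (k2, s2) in neg_ks if s2 == s}  # 2
            admissible |= {
                (k, s, m2) for (k2, m2) in neg_km if k2 == k and (s, m2) in registry
            }  # 3
            admissible |= {
                (k, s2, m) for (k2, s2) in neg_ks if k2 == k and (s2, m) in registry
            }  # 4
            # fallbacks
            admissible |= {
                (k, s2, m2)
                for (k2, m2) in neg_km
                if k2 == k
                for (s2, m3) in registry
                if m3 == m2
            }
            admissible |= {
                (k, s2, m2)
                for (k2, s2) in neg_ks
                if k2 == k
                for (s3, m2) in registry
                if s3 == s2
            }
        for n in negs:
            assert n.label == 0
            key = (n.kinase, n.substrate, n.motif)
            assert key in admissible
            assert key not in pos_keys
            assert (n.substrate, n.motif) in registry

    def test_at_most_four_per_positive_and_no_label_conflicts(self, small_world):
        from phoskg.pipeline import build_dataset

        bundle, stats = build_dataset(small_world, seed=3)
        assert stats["n_negatives"] <= 4 * stats["n_positives"]
        seen = {}
        for s in bundle.train + bundle.test2:
            key = (s.kinase, s.substrate, s.motif)
            assert seen.setdefault(key, s.label) == s.label

    def test_empty_pools_error(self):
        positives = [ClassificationSample("K1", "S1", "AAAASAAAA", 1)]
        with pytest.raises(ValueError, match="empty"):
            generate_negatives(positives, set(), set(), {("S1", "AAAASAAAA")}, seed=0)


class TestSplitPerKinase:
    def _samples(self, n_pos=10, n_neg=40, kinase="K1"):
        out = [
            ClassificationSample(kinase, f"S{i}", "AAAASAAAA", 1) for i in range(n_pos)
        ]
        out += [
            ClassificationSample(kinase, f"S{100 + i}", "AAAATAAAA", 0) for i in range(n_neg)
        ]
        return out

    def test_twenty_percent_per_class(self):
        bundle = split_per_kinase(self._samples(), 0.2, seed=0)
        pos2 = [s for s in bundle.test2 if s.label == 1]
        neg2 = [s for s in bundle.test2 if s.label == 0]
        assert len(pos2) == 2
        assert len(neg2) == 8

    def test_test1_balanced_for_every_seed(self):
        samples = self._samples(20, 70) + self._samples(12, 50, kinase="K2")
        for seed in range(5):
            bundle = split_per_kinase(samples, 0.2, seed=seed)
            pos1 = sum(1 for s in bundle.test1 if s.label == 1)
            neg1 = sum(1 for s in bundle.test1 if s.label == 0)
            assert pos1 == neg1 > 0

    def test_partition(self):
        samples = self._samples(15, 33)
        bundle = split_per_kinase(samples, 0.2, seed=1)
        assert sorted(bundle.train + bundle.test2) == sorted(samples)
        assert set(bundle.train).isdisjoint(bundle.test2)
        assert set(bundle.test1) <= set(bundle.test2)

    def test_single_sample_kinase_stays_in_train(self):
        samples = self._samples(4, 4) + [ClassificationSample("KX", "S1", "AAAASAAAA", 1)]
        with pytest.warns(UserWarning, match="KX"):
            bundle = split_per_kinase(samples, 0.2, seed=0)
        assert ClassificationSample("KX", "S1", "AAAASAAAA", 1) in bundle.train

    def test_determinism(self):
        samples = self._samples(11, 37)
        a = split_per_kinase(samples, 0.2, seed=7)
        b = split_per_kinase(samples, 0.2, seed=7)
        assert a.train == b.train and a.test1 == b.test1 and a.test2 == b.test2

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_per_kinase(self._samples(), 1.5, seed=0)


def test_samples_tsv_roundtrip(tmp_path, tiny_samples):
    path = tmp_path / "samples.tsv"
    write_samples(tiny_samples, path)
    assert read_samples(path) == tiny_samples
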