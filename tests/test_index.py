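"""Index construction: shortest-substring enumeration, L-mer counting,
sparsification and the bucket/trie lookup, all against brute-force oracles."""

import random

import numpy as np
import pytest

from duquant import (
    IndexFormatError,
    build_index,
    build_lookup,
    count_Lmers,
    db_from_sequences,
    deserialize_index,
    enumerate_shortest_substrings,
    reverse_complement,
    serialize_index,
    sparsify,
)
from duquant.index import UNIQUE, IndexedSubstring, count_Lmers as _cl

from conftest import (
    exhaustive_min_cover,
    oracle_Lmer_counts,
    oracle_shortest_substrings,
    random_db,
)


class TestEnumerate:
    def test_duplicate_genomes_have_no_unique_substrings(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(120))
        db = db_from_sequences([(1, "a", [seq]), (2, "b", [seq])])
        U, D = enumerate_shortest_substrings(db, 4, 10)
        assert U[1] == [] and U[2] == []
        assert D[1] and D[1] == D[2]
        assert all(s.genome_ids == (1, 2) for s in D[1])

    def test_single_genome_all_Lmin_unique_no_doubly(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(100))
        db = db_from_sequences([(1, "a", [seq])])
        Lmin = 6
        U, D = enumerate_shortest_substrings(db, Lmin, 12)
        assert D[1] == []
        assert U[1]
        assert all(len(s.seq) == Lmin for s in U[1])

    def test_no_substring_spans_ambiguous_base(self):
        db = db_from_sequences([(1, "a", ["ACGTTGCANGTTACCATGA"]), (2, "b", ["ACCATGGTTACAG"])])
        U, D = enumerate_shortest_substrings(db, 2, 8)
        for subs in (U[1], D[1], U[2], D[2]):
            for s in subs:
                assert "N" not in s.seq

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_small(self, seed):
        rng = random.Random(seed)
        db = random_db(rng, with_n=True)
        Lmin, Lmax = rng.choice([(2, 6), (3, 8), (4, 10)])
        U, D = enumerate_shortest_substrings(db, Lmin, Lmax)
        exp_u, exp_d, canon = oracle_shortest_substrings(db, Lmin, Lmax)
        assert {s.seq for subs in U.values() for s in subs} == exp_u
        assert {s.seq for subs in D.values() for s in subs} == exp_d
        for subs in list(U.values()) + list(D.values()):
            for s in subs:
                assert set(s.genome_ids) == canon[s.seq]

    def test_kind_partition_and_shortest_property(self, rng):
        db = random_db(rng, m=3, length_range=(150, 250))
        U, D = enumerate_shortest_substrings(db, 3, 9)
        useqs = {s.seq for subs in U.values() for s in subs}
        dseqs = {s.seq for subs in D.values() for s in subs}
        assert not useqs & dseqs
        for kept in (useqs, dseqs):
            for w in kept:
                for l in range(3, len(w)):
                    for i in range(len(w) - l + 1):
                        sub = min(w[i : i + l], reverse_complement(w[i : i + l]))
                        assert sub not in kept

    def test_snp_pair_unique_substrings_overlap_snp_locus(self, rng):
        base = "".join(rng.choice("ACGT") for _ in range(400))
        snp_pos = 200
        other = "ACGT".replace(base[snp_pos], "")[0]
        mutant = base[:snp_pos] + other + base[snp_pos + 1 :]
        db = db_from_sequences([(1, "wt", [base]), (2, "mut", [mutant])])
        U, D = enumerate_shortest_substrings(db, 4, 30)
        for gid in (1, 2):
            assert U[gid], "both strains must have unique substrings at the SNP"
            for s in U[gid]:
                for loc in s.loci:
                    assert loc.start <= snp_pos < loc.start + len(s.seq)
        # doubly-unique substrings tile loci away from the SNP too
        d_far = [
            s for s in D[1] for loc in s.loci
            if loc.genome_id == 1 and (loc.start + len(s.seq) <= snp_pos or loc.start > snp_pos)
        ]
        assert d_far


class TestCountLmers:
    def test_no_unique_substrings_means_q_zero(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(150))
        db = db_from_sequences([(1, "a", [seq]), (2, "b", [seq])])
        counts = count_Lmers(db, 4, 10, 20)
        nu, nd, nl = counts[1]
        assert nu == 0 and nd == nl > 0

    def test_single_genome_every_window_unique(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(140))
        db = db_from_sequences([(1, "a", [seq])])
        nu, nd, nl = count_Lmers(db, 4, 10, 20)[1]
        assert nu == nl == len(seq) - 20 + 1 and nd == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence(self, seed):
        rng = random.Random(100 + seed)
        db = random_db(rng, with_n=True)
        Lmin, Lmax = 3, 8
        L = rng.randint(Lmax, Lmax + 6)
        assert count_Lmers(db, Lmin, Lmax, L) == oracle_Lmer_counts(db, L)

    def test_L_below_Lmax_rejected(self, rng):
        db = random_db(rng, m=1)
        with pytest.raises(IndexFormatError, match="L >= Lmax"):
            count_Lmers(db, 4, 10, 8)


def _forward_intervals(rec, subs):
    out = {
        (loc.start, loc.start + len(s.seq))
        for s in subs
        for loc in s.loci
        if loc.genome_id == rec.genome_id
    }
    return sorted(out)


class TestSparsify:
    def test_single_substring_retained(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(60))
        db = db_from_sequences([(1, "a", [seq]), (2, "b", [seq[:30] + "T" + seq[31:]])])
        U, D = enumerate_shortest_substrings(db, 4, 12)
        if len(U[1]) == 1:
            Up = sparsify(U, db, 24)
            assert Up[1] == U[1]

    def test_two_substrings_one_window_keeps_rightmost(self):
        # genome g1 has two disjoint unique substrings close together
        g1 = "AAAAAAAACCAAAAAGGAAAAAAA"
        g2 = "AAAAAAAAAAAAAAAAAAAAAAAA"
        db = db_from_sequences([(1, "a", [g1]), (2, "b", [g2])])
        L = len(g1)
        U, D = enumerate_shortest_substrings(db, 2, 6)
        assert len(U[1]) >= 2
        Up = sparsify(U, db, L)
        assert len(Up[1]) == 1
        # the one kept must still cover every unique L-mer (here: the whole genome)
        counts = count_Lmers(db, 2, 6, L)
        assert counts[1][0] == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_minimum_cover_cardinality(self, seed):
        rng = random.Random(200 + seed)
        db = random_db(rng, m=3, length_range=(60, 120))
        Lmin, Lmax, L = 3, 8, 16
        U, D = enumerate_shortest_substrings(db, Lmin, Lmax)
        counts, masks = _cl(db, Lmin, Lmax, L, return_masks=True)
        Up = sparsify(U, db, L, window_masks={g: (masks[g][0], masks[g][1]) for g in masks})
        for rec in db:
            cands = U[rec.genome_id]
            ivs = _forward_intervals(rec, cands)
            if not (0 < len(ivs) <= 12) or len(ivs) != len(cands):
                continue  # exhaustive check only for single-occurrence instances
            ws, um, _dm = masks[rec.genome_id]
            need = [int(w) for w, f in zip(ws, um) if f]
            need = [w for w in need if any(w <= a and b <= w + L for a, b in ivs)]
            best = exhaustive_min_cover(need, ivs, L)
            assert len(Up[rec.genome_id]) == best


class TestLookup:
    def test_single_substring_path_structure(self):
        from duquant.index import bucket_key

        sub = IndexedSubstring(0, "ACGTACGT", UNIQUE, (1,))
        buckets = build_lookup([sub], 4)
        node = buckets[bucket_key("ACGT", 4)]
        for ch in "ACG":
            assert set(node) == {ch}
            node = node[ch]
        assert node["T"] == {"$": 0}

    def test_shared_prefix_one_bucket_two_leaves(self):
        from duquant.index import bucket_key

        a = IndexedSubstring(0, "ACGTAA", UNIQUE, (1,))
        b = IndexedSubstring(1, "ACGTCC", UNIQUE, (2,))
        buckets = build_lookup([a, b], 4)
        assert set(buckets) == {bucket_key("ACGT", 4)}
        node = buckets[bucket_key("ACGT", 4)]
        assert node["A"]["A"]["$"] == 0 and node["C"]["C"]["$"] == 1

    def test_substring_shorter_than_h_rejected(self):
        sub = IndexedSubstring(0, "ACG", UNIQUE, (1,))
        with pytest.raises(IndexFormatError, match="shorter"):
            build_lookup([sub], 4)

    def test_lookup_fails_on_last_character(self, rng):
        db = db_from_sequences(
            [(1, "a", ["".join(rng.choice("ACGT") for _ in range(200))])]
        )
        idx = build_index(db, Lmin=8, Lmax=16, L=32, h=8)
        sub = idx.substrings[0]
        probe = sub.seq[:-1] + ("A" if sub.seq[-1] != "A" else "C")
        assert idx.lookup(sub.seq) is sub
        assert idx.lookup(probe) is None

    def test_membership_fuzzing(self, rng):
        db = random_db(random.Random(77), m=4, length_range=(200, 300))
        idx = build_index(db, Lmin=5, Lmax=12, L=24, h=5)
        retained = {s.seq for s in idx.substrings}
        for s in idx.substrings:
            got = idx.lookup(s.seq)
            assert got is s
            assert idx.lookup(reverse_complement(s.seq)) is s
        misses = 0
        trials = 0
        while trials < 1000:
            l = rng.randint(5, 12)
            probe = "".join(rng.choice("ACGT") for _ in range(l))
            canon = min(probe, reverse_complement(probe))
            trials += 1
            if canon in retained:
                continue
            assert idx.lookup(probe) is None
            misses += 1
        assert misses > 900


class TestSerialization:
    def test_round_trip_identity_and_byte_stability(self, tmp_path, rng):
        db = random_db(random.Random(5), m=3, length_range=(150, 250))
        idx = build_index(db, Lmin=4, Lmax=10, L=20, h=4)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        serialize_index(idx, p1)
        idx2 = deserialize_index(p1)
        serialize_index(idx2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert [s.seq for s in idx2.substrings] == [s.seq for s in idx.substrings]
        assert [m.__dict__ for m in idx2.meta] == [m.__dict__ for m in idx.meta]
        assert (idx2.L, idx2.Lmin, idx2.Lmax, idx2.h) == (idx.L, idx.Lmin, idx.Lmax, idx.h)

    def test_empty_index_round_trips(self, tmp_path, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(40))
        db = db_from_sequences([(1, "a", [seq]), (2, "b", [seq])])
        # duplicate genomes, Lmin=Lmax small: only doubly substrings exist;
        # an index over a single duplicated genome pair may retain nothing
        idx = build_index(db, Lmin=4, Lmax=6, L=12, h=4)
        p = tmp_path / "i.json"
        serialize_index(idx, p)
        idx2 = deserialize_index(p)
        assert len(idx2.substrings) == len(idx.substrings)

    def test_truncated_file_raises(self, tmp_path, rng):
        db = random_db(random.Random(6), m=2)
        idx = build_index(db, Lmin=4, Lmax=10, L=20, h=4)
        p = tmp_path / "i.json"
        serialize_index(idx, p)
        data = p.read_bytes()
        p.write_bytes(data[: len(data) // 2])
        with pytest.raises(IndexFormatError, match="corrupt|truncated"):
            deserialize_index(p)

    def test_version_mismatch_refused(self, tmp_path):
        p = tmp_path / "i.json"
        p.write_text('{"format": "other-0", "params": {}}')
        with pytest.raises(IndexFormatError, match="unsupported format"):
            deserialize_index(p)
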