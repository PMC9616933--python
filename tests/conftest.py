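"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's suffix-array machinery: they
enumerate every substring of every length, count distinct-genome
occurrences by dictionary, and filter minimality by explicit containment
checks, so index-construction tests compare two fully independent routes.
"""

from __future__ import annotations

import itertools
import random

import pytest

from duquant import db_from_sequences, reverse_complement

ACGT = "ACGT"


def random_db(rng: random.Random, m=None, length_range=(80, 200), with_n=False,
              similar_prob=0.5, n_mut=(1, 5)):
    """A small random database; some genomes are point-mutated copies of the
    first so unique/doubly structure is non-trivial."""
    if m is None:
        m = rng.randint(1, 5)
    base = "".join(rng.choice(ACGT) for _ in range(rng.randint(*length_range)))
    genomes = []
    for g in range(m):
        if g > 0 and rng.random() < similar_prob:
            s = list(base)
            for _ in range(rng.randint(*n_mut)):
                s[rng.randrange(len(s))] = rng.choice(ACGT)
            seq = "".join(s)
        else:
            seq = "".join(rng.choice(ACGT) for _ in range(rng.randint(*length_range)))
        if with_n and rng.random() < 0.3:
            p = rng.randrange(len(seq))
            seq = seq[:p] + "N" + seq[p + 1 :]
        genomes.append((g + 1, f"g{g + 1}", [seq]))
    return db_from_sequences(genomes)


def substring_genome_sets(db, length):
    """genome-id sets of every strand-canonical substring of one length."""
    occ: dict[str, set[int]] = {}
    for rec in db:
        for blk in rec.text.split("#"):
            for i in range(len(blk) - length + 1):
                w = blk[i : i + length]
                if set(w) - set(ACGT):
                    continue
                occ.setdefault(min(w, reverse_complement(w)), set()).add(rec.genome_id)
    return occ


def oracle_shortest_substrings(db, Lmin, Lmax):
    """Brute-force shortest unique / doubly-unique substrings.

    Enumerates all substrings with length in [Lmin, Lmax], keeps those in
    exactly 1 (resp. 2) genomes, then drops any containing a shorter kept
    substring of the same kind.  Returns (unique set, doubly set,
    canonical substring -> genome set).
    """
    canon: dict[str, set[int]] = {}
    for l in range(Lmin, Lmax + 1):
        for w, gs in substring_genome_sets(db, l).items():
            canon.setdefault(w, set()).update(gs)
    kept_u = {w for w, gs in canon.items() if len(gs) == 1}
    kept_d = {w for w, gs in canon.items() if len(gs) == 2}

    def minimal(kept):
        out = set()
        for w in kept:
            contains = any(
                min(w[i : i + l], reverse_complement(w[i : i + l])) in kept
                for l in range(Lmin, len(w))
                for i in range(len(w) - l + 1)
            )
            if not contains:
                out.add(w)
        return out

    return minimal(kept_u), minimal(kept_d), canon


def oracle_Lmer_counts(db, L):
    """Brute-force per-genome (unique, doubly, total) L-mer counts."""
    occL = substring_genome_sets(db, L)
    out = {}
    for rec in db:
        nu = nd = nl = 0
        for c in rec.contigs:
            for i in range(len(c) - L + 1):
                w = c[i : i + L]
                if set(w) - set(ACGT):
                    continue
                nl += 1
                gs = occL[min(w, reverse_complement(w))]
                if len(gs) == 1:
                    nu += 1
                elif len(gs) == 2:
                    nd += 1
        out[rec.genome_id] = (nu, nd, nl)
    return out


def exhaustive_min_cover(need_windows, intervals, L):
    """Smallest number of intervals such that every window start in
    ``need_windows`` has an interval fully inside [w, w+L); None if
    infeasible."""
    need = sorted(need_windows)
    if not need:
        return 0
    for r in range(0, len(intervals) + 1):
        for comb in itertools.combinations(intervals, r):
            if all(any(w <= a and b <= w + L for a, b in comb) for w in need):
                return r
    return None


@pytest.fixture
def rng():
    return random.Random(20240917)
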