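"""Stage-1 query processing: read scanning, conflict-free assignment and the
presence (A1) and minimal-explanation (A2) queries.

Each read is scanned on both strands with a rolling 2-bit-packed h-mer
fingerprint; bucket hits are extended greedily through the suffix trie and
every accepting node passed reports a retained substring occurrence.  A read
is *conflict-free* when at least one genome is consistent with all of its
matched substrings (the intersection of their genome sets is non-empty);
only conflict-free reads contribute to the counters.

A1 returns the genomes with unique-substring evidence, ranked by aggregated
unique counters.  A2 returns a minimum-cardinality set of genomes explaining
all unique and doubly-unique evidence -- a hitting set over the active
genome pairs with unique-evidence genomes forced in -- solved as a binary
ILP (HiGHS), with deterministic lexicographic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .genomes import reverse_complement
from .index import SubstringIndex, encode

NO_MATCH = "no_match"
ASSIGNED_ONE = "assigned_one"
ASSIGNED_PAIR = "assigned_pair"
CONFLICT = "conflict"


@dataclass
class ReadMatch:
    """Resolution of one read against the index."""

    read_id: str
    matches: list[tuple[int, int, str]]  # (substring id, offset on scanned strand, strand)
    candidate_set: frozenset[int]
    status: str


@dataclass
class CountState:
    """Counters accumulated over a query.

    ``counts[sid]`` is the number of conflict-free reads containing the
    retained substring ``sid`` (once per read, however often it occurs in the
    read); ``pair_counts[(k, k')]`` the number of reads assignable to exactly
    the genome pair {k, k'}.
    """

    counts: dict[int, int] = field(default_factory=dict)
    pair_counts: dict[tuple[int, int], int] = field(default_factory=dict)
    n_reads: int = 0
    n_used: int = 0

    def genome_sums(self, index: SubstringIndex) -> dict[int, tuple[int, int]]:
        """Per-genome (sum of unique counters, sum of doubly counters)."""
        out = {}
        for m in index.meta:
            cu = sum(self.counts.get(s, 0) for s in m.u_sids)
            cd = sum(self.counts.get(s, 0) for s in m.d_sids)
            out[m.genome_id] = (cu, cd)
        return out


def scan_read(read: str, index: SubstringIndex) -> list[tuple[int, int, str]]:
    """All retained substrings occurring in the read or its reverse
    complement, as (substring id, offset on the scanned strand, strand).

    Rolling the packed h-mer across both strands gives candidate bucket
    hits; greedy trie extension reports every accepting node on the matched
    path.  Packing is exact (injective), so there are no fingerprint
    collisions to verify away.
    """
    h = index.h
    read = read.upper()
    out: set[tuple[int, int, str]] = set()
    if len(read) < h:
        return []
    for strand, seq in (("+", read), ("-", reverse_complement(read))):
        codes = encode(seq)
        n = len(codes)
        bad = np.concatenate(([0], np.cumsum(codes >= 4)))
        if h <= 31:
            win = np.lib.stride_tricks.sliding_window_view(
                codes.astype(np.int64), h
            )
            powers = 4 ** np.arange(h - 1, -1, -1, dtype=np.int64)
            keys = win @ powers
        else:
            keys = None
        for i in range(n - h + 1):
            if bad[i + h] - bad[i]:
                continue
            key = int(keys[i]) if keys is not None else seq[i : i + h]
            node = index.buckets.get(key)
            if node is None:
                continue
            j = i + h
            while True:
                sid = node.get("$")
                if sid is not None:
                    out.add((sid, i, strand))
                if j < n:
                    nxt = node.get(seq[j])
                    if nxt is not None:
                        node = nxt
                        j += 1
                        continue
                break
    return sorted(out)


def resolve_read(
    read_id: str, matches: list[tuple[int, int, str]], index: SubstringIndex
) -> ReadMatch:
    """Conflict-free resolution: intersect the genome sets of all matched
    substrings; one surviving genome assigns the read, two make a pair
    assignment, an empty intersection is a conflict and the read is
    discarded."""
    if not matches:
        return ReadMatch(read_id, [], frozenset(), NO_MATCH)
    cand: frozenset[int] | None = None
    for sid, _off, _strand in matches:
        gset = frozenset(index.substrings[sid].genome_ids)
        cand = gset if cand is None else cand & gset
    if not cand:
        return ReadMatch(read_id, matches, frozenset(), CONFLICT)
    status = ASSIGNED_ONE if len(cand) == 1 else (
        ASSIGNED_PAIR if len(cand) == 2 else CONFLICT
    )
    # |candidate_set| > 2 cannot occur: any match has at most 2 genomes
    return ReadMatch(read_id, matches, cand, status)


def accumulate(
    reads: Iterable[tuple[str, str]], index: SubstringIndex
) -> tuple[CountState, list[ReadMatch]]:
    """Scan and resolve every read, incrementing each matched substring's
    counter once per conflict-free read and the pair counter once per
    pair-assigned read.  Returns the counters and per-read resolutions."""
    state = CountState()
    resolutions = []
    for read_id, seq in reads:
        rm = resolve_read(read_id, scan_read(seq, index), index)
        resolutions.append(rm)
        state.n_reads += 1
        if rm.status in (ASSIGNED_ONE, ASSIGNED_PAIR):
            state.n_used += 1
            for sid in {m[0] for m in rm.matches}:
                state.counts[sid] = state.counts.get(sid, 0) + 1
            if rm.status == ASSIGNED_PAIR:
                pair = tuple(sorted(rm.candidate_set))
                state.pair_counts[pair] = state.pair_counts.get(pair, 0) + 1
    return state, resolutions


def query_A1(state: CountState, index: SubstringIndex) -> list[tuple[int, int]]:
    """Genomes with unique-substring evidence, as (genome_id, unique-counter
    sum), ranked by the sum descending (ties by genome_id)."""
    sums = state.genome_sums(index)
    hits = [(g, cu) for g, (cu, _cd) in sums.items() if cu > 0]
    return sorted(hits, key=lambda t: (-t[1], t[0]))


def query_A2(state: CountState, index: SubstringIndex) -> list[tuple[int, int]]:
    """Smallest genome set explaining all evidence, as (genome_id, total
    counter sum), ranked by the sum descending (ties by genome_id).

    Constraints: a genome with unique evidence is forced in; for every
    genome pair with a positive pair counter at least one member is chosen.
    Solved as a binary ILP with lexicographic tie-breaking: (1) minimum
    cardinality, (2) maximum total aggregated counters, (3) minimum total
    unique-L-mer count of the chosen genomes -- a genome carrying many
    unique markers of which none was observed is the less plausible member
    of an otherwise symmetric pair.
    """
    sums = state.genome_sums(index)
    gids = index.genome_ids
    gpos = {g: t for t, g in enumerate(gids)}
    m = len(gids)
    forced = [g for g in gids if sums[g][0] > 0]
    pairs = [p for p, c in sorted(state.pair_counts.items()) if c > 0]
    if not pairs and not forced:
        return []

    lb = np.zeros(m)
    for g in forced:
        lb[gpos[g]] = 1.0
    ub = np.ones(m)
    integrality = np.ones(m)

    rows, cols, vals = [], [], []
    for r, (k, kp) in enumerate(pairs):
        rows += [r, r]
        cols += [gpos[k], gpos[kp]]
        vals += [1.0, 1.0]
    A = csr_matrix((vals, (rows, cols)), shape=(len(pairs), m))
    cons = [LinearConstraint(A, lb=np.ones(len(pairs)), ub=np.inf)] if pairs else []

    def solve(c, extra_cons):
        res = milp(
            c=c,
            integrality=integrality,
            bounds=Bounds(lb, ub),
            constraints=cons + extra_cons,
        )
        if not res.success:
            raise RuntimeError(f"hitting-set ILP failed: {res.message}")
        return res

    ones = np.ones(m)
    res1 = solve(ones, [])
    card = float(np.round(res1.x.sum()))

    weights = np.array([float(sum(sums[g])) for g in gids])
    eq_card = LinearConstraint(ones, lb=card, ub=card)
    res2 = solve(-weights, [eq_card])
    wbest = float(weights @ np.round(res2.x))

    nuLs = np.array([float(index.meta_by_id[g].nuL) for g in gids])
    eq_w = LinearConstraint(weights, lb=wbest, ub=wbest)
    res3 = solve(nuLs, [eq_card, eq_w])

    chosen = [g for g, x in zip(gids, np.round(res3.x)) if x > 0.5]
    return sorted(
        ((g, sum(sums[g])) for g in chosen), key=lambda t: (-t[1], t[0])
    )
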