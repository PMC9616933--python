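"""Shortest unique / doubly-unique substring index.

The index of a genome database holds, for every genome, a sparsified set of
its *shortest unique substrings* (substrings occurring in no other genome,
containing no shorter such substring) and *shortest doubly-unique substrings*
(occurring in exactly one other genome), with lengths clipped to
[Lmin, Lmax].  Retained substrings are organized as h-mer hash buckets, each
holding a trie of suffix extensions, so a read can be scanned with a rolling
2-bit-packed fingerprint and greedy trie extension.

Construction strategy: a generalized suffix array over the concatenated
canonical texts (forward + reverse-complement strands of every genome, with
boundary sentinels), its LCP array, and two linear sweeps that compute, for
every text position, the longest prefix its suffix shares with any suffix of
each of the two nearest *other* genomes.  From those two match lengths the
minimal unique / doubly-unique substring starting at each position follows
directly; a containment prune then keeps only the shortest substrings.  A
quadratic brute-force enumeration serves as the independent oracle in the
test suite.

Distinct-genome semantics: an occurrence on either strand of genome j counts
as genome j, so a substring and its reverse complement are one biological
entity; substrings are stored strand-canonically (the lexicographically
smaller of the string and its reverse complement).
"""

from __future__ import annotations

import json
import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d

from .genomes import SEPARATOR, GenomeDB, GenomeRecord, reverse_complement

INDEX_FORMAT_VERSION = "duquant-index-1"

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_ENC = np.full(256, 4, dtype=np.int8)
for _b, _c in _BASE_CODE.items():
    _ENC[ord(_b)] = _c

UNIQUE = "unique"
DOUBLY = "doubly_unique"

DEFAULT_LMIN = 26
DEFAULT_LMAX = 50
DEFAULT_L = 100


class IndexFormatError(ValueError):
    """Raised for malformed index inputs or files."""


def encode(seq: str) -> np.ndarray:
    """2-bit base codes; anything outside A/C/G/T becomes the boundary code 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


# ---------------------------------------------------------------------------
# Suffix array + LCP
# ---------------------------------------------------------------------------

def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log n) lexsort rounds)."""
    n = len(codes)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = codes.astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r_s = rank[sa]
        k_s = key2[sa]
        changed = np.empty(n, dtype=bool)
        changed[0] = True
        changed[1:] = (r_s[1:] != r_s[:-1]) | (k_s[1:] != k_s[:-1])
        new_rank = np.cumsum(changed) - 1
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = new_rank
        if new_rank[-1] == n - 1:
            break
        k *= 2
    return sa


def lcp_array(codes: np.ndarray, sa: np.ndarray, run: np.ndarray) -> np.ndarray:
    """Kasai LCP, clamped so matches never extend across boundary characters.

    ``lcp[r]`` is the (clamped) longest common prefix of suffixes sa[r-1] and
    sa[r].  Boundary characters (code >= 4) never match valid sequence, and
    two equal-prefix suffixes reach their first boundary at the same offset,
    so clamping the plain Kasai values by the distance-to-boundary of the
    endpoints is exact.
    """
    n = len(codes)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    c = codes.tolist()
    sa_l = sa.tolist()
    rank_l = rank.tolist()
    h = 0
    for i in range(n):
        r = rank_l[i]
        if r == 0:
            h = 0
            continue
        j = sa_l[r - 1]
        while i + h < n and j + h < n and c[i + h] == c[j + h]:
            h += 1
        lcp[r] = h
        if h:
            h -= 1
    lcp = np.minimum(lcp, run[sa])
    lcp[1:] = np.minimum(lcp[1:], run[sa[:-1]])
    if n:
        lcp[0] = 0
    return lcp


def _sweep(lcp, sa_docs, forward: bool, K: int = 3):
    """One direction of the nearest-other-genome match-length computation.

    Walking the suffix array while keeping the running min of LCP values,
    maintain the K best (genome, match-length) pairs over *distinct* genomes
    seen so far.  Truncation to K=3 is lossless for the top-2 values among
    genomes other than the querying suffix's own: a dropped genome's running
    value can never later exceed the kept third's value.
    Returns (docs, vals) lists of up-to-K pairs indexed by suffix-array rank.
    """
    n = len(sa_docs)
    out: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    INF = n + 1
    sdocs: list[int] = []
    svals: list[int] = []
    docs_l = sa_docs.tolist()
    lcp_l = lcp.tolist()
    order = range(n) if forward else range(n - 1, -1, -1)
    first = True
    for r in order:
        if not first:
            mm = lcp_l[r] if forward else lcp_l[r + 1]
            for t in range(len(svals)):
                if svals[t] > mm:
                    svals[t] = mm
        first = False
        if sdocs:
            out[r] = list(zip(sdocs, svals))
        d = docs_l[r]
        if d >= 0:
            if d in sdocs:
                svals[sdocs.index(d)] = INF
            else:
                sdocs.append(d)
                svals.append(INF)
                if len(sdocs) > K:
                    t = svals.index(min(svals))
                    sdocs.pop(t)
                    svals.pop(t)
    return out


@dataclass
class DatabaseAnalysis:
    """Per-position match-length arrays for a genome database.

    For every position p of the concatenated canonical text: ``m1[p]`` is the
    longest prefix of the suffix at p shared with any suffix of the nearest
    *other* genome (``m1doc[p]``, a genome index); ``m2[p]`` the match length
    to the second-nearest distinct other genome; ``run[p]`` the distance to
    the next boundary character.
    """

    db: GenomeDB
    text: str
    codes: np.ndarray
    doc: np.ndarray
    run: np.ndarray
    m1: np.ndarray
    m1doc: np.ndarray
    m2: np.ndarray
    rec_offsets: list[int]


def analyze_database(db: GenomeDB) -> DatabaseAnalysis:
    parts = []
    rec_offsets = []
    pos = 0
    for rec in db:
        rec_offsets.append(pos)
        parts.append(rec.text)
        pos += len(rec.text) + 1
    text = SEPARATOR.join(parts) + SEPARATOR
    codes = encode(text)
    n = len(codes)
    doc = np.full(n, -1, dtype=np.int64)
    for gi, rec in enumerate(db):
        off = rec_offsets[gi]
        doc[off : off + len(rec.text)] = gi
    bpos = np.flatnonzero(codes >= 4)
    nxt = bpos[np.searchsorted(bpos, np.arange(n))]
    run = nxt - np.arange(n)

    sa = suffix_array(codes)
    lcp = lcp_array(codes, sa, run)
    sa_docs = doc[sa]
    fwd = _sweep(lcp, sa_docs, forward=True)
    bwd = _sweep(lcp, sa_docs, forward=False)

    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)

    m1 = np.zeros(n, dtype=np.int64)
    m1doc = np.full(n, -1, dtype=np.int64)
    m2 = np.zeros(n, dtype=np.int64)
    rank_l = rank.tolist()
    doc_l = doc.tolist()
    run_l = run.tolist()
    for p in range(n):
        if run_l[p] <= 0 or doc_l[p] < 0:
            continue
        r = rank_l[p]
        own = doc_l[p]
        best: dict[int, int] = {}
        for pairs in (fwd[r], bwd[r]):
            for d, v in pairs:
                if d == own or v <= 0:
                    continue
                if v > best.get(d, 0):
                    best[d] = v
        if not best:
            continue
        items = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
        m1[p] = items[0][1]
        m1doc[p] = items[0][0]
        if len(items) > 1:
            m2[p] = items[1][1]
    return DatabaseAnalysis(db, text, codes, doc, run, m1, m1doc, m2, rec_offsets)


# ---------------------------------------------------------------------------
# Minimal substring candidates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """One occurrence of an indexed substring: forward-strand start within
    the named contig (0-based), with the strand the occurrence lies on."""

    genome_id: int
    contig: int
    strand: str
    start: int


@dataclass
class IndexedSubstring:
    """One shortest unique or doubly-unique substring (strand-canonical)."""

    sid: int
    seq: str
    kind: str
    genome_ids: tuple[int, ...]
    loci: list[Locus] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)


def _candidate_positions(an: DatabaseAnalysis, Lmin: int, Lmax: int):
    """Per-position minimal candidates, Lmin-clipped, before containment
    pruning.  The minimal unique length at p is m1[p]+1 (one base past the
    longest other-genome match); the minimal doubly-unique length is m2[p]+1
    provided exactly one other genome still matches there (m1 > m2)."""
    run, m1, m2, m1doc, doc = an.run, an.m1, an.m2, an.m1doc, an.doc
    valid = (run >= 1) & (doc >= 0)

    lu = np.maximum(m1 + 1, Lmin)
    u_mask = valid & (lu <= Lmax) & (lu <= run)

    ld = np.maximum(m2 + 1, Lmin)
    d_mask = (
        valid
        & (m1doc >= 0)
        & (m1 > m2)
        & (ld <= Lmax)
        & (ld <= run)
        & (m1 >= ld)  # the partner still matches at the clipped length
    )
    return (
        (np.flatnonzero(u_mask), lu[u_mask]),
        (np.flatnonzero(d_mask), ld[d_mask], m1doc[d_mask]),
    )


def _prune_contained(n: int, ps: np.ndarray, ls: np.ndarray, Lmax: int) -> np.ndarray:
    """Drop candidates whose occurrence interval strictly contains another
    candidate interval of the same kind (the 'shortest' property).  String
    containment implies containment at every occurrence, so a positional
    check at each occurrence is exact."""
    if len(ps) == 0:
        return np.zeros(0, dtype=bool)
    BIG = np.int64(1 << 60)
    endarr = np.full(n + 1, BIG, dtype=np.int64)
    endarr[ps] = ps + ls
    size = Lmax if Lmax % 2 == 1 else Lmax + 1
    # q[i] = min(endarr[i : i + size]) covers starts strictly inside (p, p+Lmax]
    q = minimum_filter1d(endarr, size=size, origin=-(size // 2), mode="constant", cval=BIG)
    return ~(q[np.minimum(ps + 1, n)] <= ps + ls)


def _group_candidates(an: DatabaseAnalysis, ps, ls, kind: str, partners=None):
    """Group surviving positional candidates into strand-canonical
    IndexedSubstring objects keyed by sequence."""
    db = an.db
    text = an.text
    groups: dict[str, IndexedSubstring] = {}
    doc_l = an.doc
    for t in range(len(ps)):
        p = int(ps[t])
        l = int(ls[t])
        seq = text[p : p + l]
        canon = min(seq, reverse_complement(seq))
        gi = int(doc_l[p])
        rec = db.genomes[gi]
        if kind == UNIQUE:
            gids: tuple[int, ...] = (rec.genome_id,)
        else:
            gids = tuple(
                sorted((rec.genome_id, db.genomes[int(partners[t])].genome_id))
            )
        sub = groups.get(canon)
        if sub is None:
            sub = IndexedSubstring(sid=-1, seq=canon, kind=kind, genome_ids=gids)
            groups[canon] = sub
        elif sub.genome_ids != gids:
            raise IndexFormatError(
                f"inconsistent genome sets for substring {canon!r}: "
                f"{sub.genome_ids} vs {gids}"
            )
        local = p - an.rec_offsets[gi]
        contig, strand, start = rec.to_forward_coords(local, l)
        loc = Locus(rec.genome_id, contig, strand, start)
        if loc not in sub.loci:
            sub.loci.append(loc)
    for sub in groups.values():
        sub.loci.sort(key=lambda lc: (lc.genome_id, lc.contig, lc.start, lc.strand))
    return groups


def enumerate_shortest_substrings(
    db: GenomeDB, Lmin: int, Lmax: int
) -> tuple[dict[int, list[IndexedSubstring]], dict[int, list[IndexedSubstring]]]:
    """Compute per-genome sets (U_i, D_i) of shortest unique and shortest
    doubly-unique substrings with lengths in [Lmin, Lmax].

    A shortest substring shorter than Lmin is replaced by its minimal set of
    length-Lmin extensions; none longer than Lmax is reported.  Doubly-unique
    substrings appear in the lists of both member genomes (shared objects).
    """
    if not (1 <= Lmin <= Lmax):
        raise IndexFormatError(f"require 1 <= Lmin <= Lmax, got ({Lmin}, {Lmax})")
    an = analyze_database(db)
    return _enumerate_from_analysis(an, Lmin, Lmax)


def _enumerate_from_analysis(an: DatabaseAnalysis, Lmin: int, Lmax: int):
    (u_ps, u_ls), (d_ps, d_ls, d_partner) = _candidate_positions(an, Lmin, Lmax)
    n = len(an.codes)
    uk = _prune_contained(n, u_ps, u_ls, Lmax)
    dk = _prune_contained(n, d_ps, d_ls, Lmax)
    u_groups = _group_candidates(an, u_ps[uk], u_ls[uk], UNIQUE)
    d_groups = _group_candidates(an, d_ps[dk], d_ls[dk], DOUBLY, partners=d_partner[dk])
    U: dict[int, list[IndexedSubstring]] = {g.genome_id: [] for g in an.db}
    D: dict[int, list[IndexedSubstring]] = {g.genome_id: [] for g in an.db}
    for canon in sorted(u_groups):
        sub = u_groups[canon]
        U[sub.genome_ids[0]].append(sub)
    for canon in sorted(d_groups):
        sub = d_groups[canon]
        for gid in sub.genome_ids:
            D[gid].append(sub)
    return U, D


# ---------------------------------------------------------------------------
# L-mer counting
# ---------------------------------------------------------------------------

def _forward_blocks(rec: GenomeRecord, L: int):
    """Forward blocks large enough to hold an L-window, as (start, last
    window start) in canonical-text coordinates."""
    out = []
    for b in rec.blocks:
        if b.strand == "+" and b.end - b.start >= L:
            out.append((b.start, b.end - L))
    return out


def count_Lmers(
    db: GenomeDB, Lmin: int, Lmax: int, L: int, return_masks: bool = False
):
    """Per-genome counts of unique, doubly-unique and total L-mers.

    An L-mer is a forward-strand window of length L not crossing any contig
    boundary; it is a unique (doubly-unique) L-mer when the window string
    itself occurs in exactly one (two) distinct genome(s) of the database.
    Returns ``{genome_id: (nuL, ndL, nL)}``; with ``return_masks`` also
    ``{genome_id: (window_starts, unique_mask, doubly_mask)}`` over the
    genome's valid window starts (canonical-text coordinates of the record).
    """
    if L < Lmax:
        raise IndexFormatError(f"require L >= Lmax, got L={L}, Lmax={Lmax}")
    an = analyze_database(db)
    return _count_from_analysis(an, L, return_masks)


def _count_from_analysis(an: DatabaseAnalysis, L: int, return_masks: bool = False):
    counts: dict[int, tuple[int, int, int]] = {}
    masks: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for gi, rec in enumerate(an.db):
        off = an.rec_offsets[gi]
        spans = [
            np.arange(off + bs, off + wend + 1)
            for bs, wend in _forward_blocks(rec, L)
        ]
        if spans:
            w = np.concatenate(spans)
            w = w[an.run[w] >= L]
        else:
            w = np.empty(0, dtype=np.int64)
        uniq = an.m1[w] < L
        doub = (an.m1[w] >= L) & (an.m2[w] < L)
        counts[rec.genome_id] = (int(uniq.sum()), int(doub.sum()), int(len(w)))
        masks[rec.genome_id] = (w - off, uniq, doub)
    if return_masks:
        return counts, masks
    return counts


# ---------------------------------------------------------------------------
# Sparsification
# ---------------------------------------------------------------------------

def _forward_occurrences(rec: GenomeRecord, subs):
    """All occurrences of the given substrings on this genome, as
    (start, end, length, seq, sub) intervals on the record's canonical-text
    forward axis (reverse-strand occurrences project onto forward
    coordinates; Locus.start is already a forward-strand coordinate)."""
    fstart = {
        b.contig: b.start for b in rec.blocks if b.strand == "+"
    }
    occs = []
    for sub in subs:
        for loc in sub.loci:
            if loc.genome_id != rec.genome_id:
                continue
            s = fstart[loc.contig] + loc.start
            occs.append((s, s + len(sub.seq), len(sub.seq), sub.seq, sub))
    occs.sort(key=lambda o: (o[0], o[2], o[3]))
    return occs


def sparsify(
    substrings_by_genome: dict[int, list[IndexedSubstring]],
    db: GenomeDB,
    L: int,
    window_masks: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
) -> dict[int, list[IndexedSubstring]]:
    """Retain, per genome, a subset of shortest substrings such that every
    L-mer of the matching kind still contains at least one retained
    substring occurrence.

    Greedy left-to-right window sweep keeping the rightmost candidate inside
    each uncovered window (ties: shortest, then lexicographically smallest);
    optimal when every candidate occurs exactly once on the genome.
    ``window_masks`` maps genome_id to (window_starts, must_cover_mask) in
    the record's canonical-text coordinates (e.g. the unique- or
    doubly-L-mer masks from :func:`count_Lmers`); without it every valid
    window containing a candidate occurrence must be covered.  Windows with
    no candidate occurrence are uncoverable and skipped.
    """
    retained: dict[int, list[IndexedSubstring]] = {}
    for rec in db:
        gid = rec.genome_id
        occs = _forward_occurrences(rec, substrings_by_genome.get(gid, []))
        if not occs:
            retained[gid] = []
            continue
        starts = [o[0] for o in occs]

        if window_masks is not None and gid in window_masks:
            ws, mask = window_masks[gid]
            need = set(np.asarray(ws)[np.asarray(mask, dtype=bool)].tolist())
        else:
            need = None

        # windows containing >= 1 occurrence, per forward block
        cand_windows: set[int] = set()
        for bs, wend in _forward_blocks(rec, L):
            for s, e, _l, _q, _sub in occs:
                if s < bs or e > wend + L:
                    continue
                lo = max(e - L, bs)
                hi = min(s, wend)
                if lo <= hi:
                    cand_windows.update(range(lo, hi + 1))
        if need is not None:
            cand_windows &= need

        chosen: dict[int, IndexedSubstring] = {}
        cover_until = -1
        for w in sorted(cand_windows):
            if w <= cover_until:
                continue
            # best occurrence fully inside [w, w+L): max start, then
            # shortest, then lexicographically smallest sequence
            j = bisect_right(starts, w + L - 1) - 1
            jlo = bisect_left(starts, w)
            best = None
            while j >= jlo:
                s, e, l, q, sub = occs[j]
                if best is not None and s < best[0]:
                    break
                if e <= w + L:
                    if best is None or s > best[0] or (l, q) < (best[1], best[2]):
                        best = (s, l, q, sub)
                j -= 1
            if best is None:
                continue
            chosen[id(best[3])] = best[3]
            cover_until = best[0]
        retained[gid] = sorted(chosen.values(), key=lambda s: s.seq)
    return retained


# ---------------------------------------------------------------------------
# Lookup structure: h-mer buckets of suffix tries
# ---------------------------------------------------------------------------

def pack_hmer(seq: str) -> int:
    """Exact 2-bit packing of an A/C/G/T string into an integer key.

    Injective, so bucket lookups have no false positives; a rolling update
    (shift, mask, add) gives the Karp-Rabin style O(1) per-position scan.
    """
    key = 0
    for ch in seq:
        key = (key << 2) | _BASE_CODE[ch]
    return key


def bucket_key(seq: str, h: int):
    """Bucket key of an h-prefix: packed integer when it fits a machine word,
    else the string itself (both exact)."""
    return pack_hmer(seq[:h]) if h <= 31 else seq[:h]


def build_lookup(substrings: list["IndexedSubstring"], h: int) -> dict:
    """h-mer hash buckets, each a trie over the suffix extensions of the
    substrings sharing that h-prefix; accepting nodes carry the substring id.
    Tries are nested dicts; the reserved key "$" marks an accepting node.
    """
    buckets: dict = {}
    for sub in substrings:
        if len(sub.seq) < h:
            raise IndexFormatError(
                f"substring {sub.seq!r} shorter than bucket prefix h={h}"
            )
        key = bucket_key(sub.seq, h)
        node = buckets.setdefault(key, {})
        for ch in sub.seq[h:]:
            node = node.setdefault(ch, {})
        if "$" in node:
            raise IndexFormatError(f"duplicate indexed substring {sub.seq!r}")
        node["$"] = sub.sid
    return buckets


@dataclass
class GenomeIndexMeta:
    """Per-genome index statistics and retained-substring id lists.

    ``nu``/``nd`` are the sparsified counts |U'_i| / |D'_i|; ``nuL``/``ndL``
    the numbers of unique / doubly-unique L-mers; ``nL`` the total L-mers;
    ``q = nuL / nL`` the proportion of unique L-mers.
    """

    genome_id: int
    name: str
    genome_length: int
    nuL: int
    ndL: int
    nL: int
    u_sids: list[int] = field(default_factory=list)
    d_sids: list[int] = field(default_factory=list)

    @property
    def nu(self) -> int:
        return len(self.u_sids)

    @property
    def nd(self) -> int:
        return len(self.d_sids)

    @property
    def q(self) -> float:
        return self.nuL / self.nL if self.nL else 0.0


@dataclass
class SubstringIndex:
    """The queryable index: retained substrings, per-genome metadata and the
    h-mer bucket/trie lookup."""

    L: int
    Lmin: int
    Lmax: int
    h: int
    substrings: list[IndexedSubstring]
    meta: list[GenomeIndexMeta]
    buckets: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.meta_by_id = {m.genome_id: m for m in self.meta}

    @property
    def genome_ids(self) -> list[int]:
        return [m.genome_id for m in self.meta]

    def lookup(self, seq: str) -> IndexedSubstring | None:
        """Exact membership: the retained substring equal to ``seq`` (or its
        reverse complement -- strand is not identity), else None."""
        for s in (seq, reverse_complement(seq)):
            if len(s) < self.h:
                continue
            node = self.buckets.get(bucket_key(s, self.h))
            if node is None:
                continue
            ok = True
            for ch in s[self.h :]:
                node = node.get(ch)
                if node is None:
                    ok = False
                    break
            if ok and "$" in node:
                return self.substrings[node["$"]]
        return None


def build_index(
    db: GenomeDB,
    Lmin: int = DEFAULT_LMIN,
    Lmax: int = DEFAULT_LMAX,
    L: int = DEFAULT_L,
    h: int | None = None,
) -> SubstringIndex:
    """Full index construction: enumerate shortest unique and doubly-unique
    substrings, count L-mers, sparsify per genome against the L-mer masks,
    and assemble the bucket/trie lookup.  ``h`` defaults to Lmin."""
    if not (1 <= Lmin <= Lmax <= L):
        raise IndexFormatError(
            f"require 1 <= Lmin <= Lmax <= L, got ({Lmin}, {Lmax}, {L})"
        )
    h = Lmin if h is None else h
    if h > Lmin:
        raise IndexFormatError(f"h={h} exceeds the shortest retained length Lmin={Lmin}")
    for rec in db:
        if min(len(c) for c in rec.contigs) < Lmax:
            import warnings

            warnings.warn(
                f"genome {rec.genome_id}: a contig is shorter than Lmax={Lmax} "
                "and contributes no indexed substrings of that length",
                stacklevel=2,
            )
    an = analyze_database(db)
    U, D = _enumerate_from_analysis(an, Lmin, Lmax)
    counts, masks = _count_from_analysis(an, L, return_masks=True)
    u_masks = {g: (masks[g][0], masks[g][1]) for g in masks}
    d_masks = {g: (masks[g][0], masks[g][2]) for g in masks}
    Up = sparsify(U, db, L, window_masks=u_masks)
    Dp = sparsify(D, db, L, window_masks=d_masks)

    seen: dict[tuple[str, str], IndexedSubstring] = {}
    for per_genome in (Up, Dp):
        for subs in per_genome.values():
            for sub in subs:
                seen[(sub.kind, sub.seq)] = sub
    ordered = [seen[k] for k in sorted(seen)]
    for sid, sub in enumerate(ordered):
        sub.sid = sid

    meta = []
    for rec in db:
        nuL, ndL, nL = counts[rec.genome_id]
        meta.append(
            GenomeIndexMeta(
                genome_id=rec.genome_id,
                name=rec.name,
                genome_length=rec.genome_length,
                nuL=nuL,
                ndL=ndL,
                nL=nL,
                u_sids=[s.sid for s in Up[rec.genome_id]],
                d_sids=[s.sid for s in Dp[rec.genome_id]],
            )
        )
    buckets = build_lookup(ordered, h)
    return SubstringIndex(
        L=L, Lmin=Lmin, Lmax=Lmax, h=h, substrings=ordered, meta=meta, buckets=buckets
    )


# ---------------------------------------------------------------------------
# Serialization (versioned JSON text; byte-stable for identical input)
# ---------------------------------------------------------------------------

def serialize_index(index: SubstringIndex, path: str | os.PathLike) -> None:
    doc = {
        "format": INDEX_FORMAT_VERSION,
        "params": {"L": index.L, "Lmin": index.Lmin, "Lmax": index.Lmax, "h": index.h},
        "substrings": [
            {
                "seq": s.seq,
                "kind": s.kind,
                "genome_ids": list(s.genome_ids),
                "loci": [[l.genome_id, l.contig, l.strand, l.start] for l in s.loci],
            }
            for s in index.substrings
        ],
        "meta": [
            {
                "genome_id": m.genome_id,
                "name": m.name,
                "genome_length": m.genome_length,
                "nuL": m.nuL,
                "ndL": m.ndL,
                "nL": m.nL,
                "u_sids": m.u_sids,
                "d_sids": m.d_sids,
            }
            for m in index.meta
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def deserialize_index(path: str | os.PathLike) -> SubstringIndex:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise IndexFormatError(f"index file {path} is corrupt or truncated: {exc}")
    if not isinstance(doc, dict) or doc.get("format") != INDEX_FORMAT_VERSION:
        raise IndexFormatError(
            f"index file {path}: unsupported format "
            f"{doc.get('format') if isinstance(doc, dict) else type(doc)}, "
            f"expected {INDEX_FORMAT_VERSION}"
        )
    params = doc["params"]
    substrings = [
        IndexedSubstring(
            sid=sid,
            seq=d["seq"],
            kind=d["kind"],
            genome_ids=tuple(d["genome_ids"]),
            loci=[Locus(*l) for l in d["loci"]],
        )
        for sid, d in enumerate(doc["substrings"])
    ]
    meta = [
        GenomeIndexMeta(
            genome_id=d["genome_id"],
            name=d["name"],
            genome_length=d["genome_length"],
            nuL=d["nuL"],
            ndL=d["ndL"],
            nL=d["nL"],
            u_sids=list(d["u_sids"]),
            d_sids=list(d["d_sids"]),
        )
        for d in doc["meta"]
    ]
    buckets = build_lookup(substrings, params["h"])
    return SubstringIndex(
        L=params["L"],
        Lmin=params["Lmin"],
        Lmax=params["Lmax"],
        h=params["h"],
        substrings=substrings,
        meta=meta,
        buckets=buckets,
    )
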