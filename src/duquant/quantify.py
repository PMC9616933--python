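"""Stage-2 abundance estimation (the A3 query).

Joint genome selection and abundance estimation under the approximate
uniform-coverage model: a mixed-integer linear program chooses presence
indicators delta_i and coverage-scale abundances p_i so that the observed
per-substring read counters c are as close as possible (in total absolute
deviation, normalized per genome) to their expectations

    e(u_il) = (L - |u_il| + 1) * p_i * (1/L) * (1 - err)^|u_il|
    e(d_il) = (L - |d_il| + 1) * (p_i + p_j) * (1/L) * (1 - err)^|d_il|

for unique and doubly-unique substrings respectively: a substring of length
l fits in L - l + 1 of the L possible read windows per position, and
(1-err)^l is the chance it survives i.i.d. substitution errors.  Absolute
values are linearized with auxiliary variables gamma >= |c - e|.

Constraints: p_i <= delta_i * p_max; delta_i = 0 for genomes in the
alpha-filtered set M(Q); a (1 - epsilon) lower bound on the coverage of
selected genomes outside M(Q); and the read budget sum_i |s_i| p_i <= n L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .index import SubstringIndex
from .query import CountState

DEFAULT_ALPHA = 1e-4
DEFAULT_EPSILON = 0.3
DEFAULT_PMAX = 100.0
IDENTIFICATION_CUTOFF = 1e-4  # 0.01 % of total abundance


@dataclass
class QuantParams:
    """Parameters of the abundance ILP.

    ``err_hat`` is the estimated per-nucleotide substitution error rate of
    the reads (0 assumes error-free data); ``alpha`` scales the evidence
    threshold below which a genome is excluded from the solution space;
    ``epsilon`` slackens the coverage lower bound of selected genomes (the
    bound L*sum(c)/nuL overestimates coverage by the mean number of
    retained substrings per read window, so the default slack absorbs that
    overlap factor);
    ``p_max`` caps any single abundance to guard against contamination
    anomalies; ``n`` is the total number of reads in the query.
    """

    L: int
    n: int
    err_hat: float = 0.0
    p_max: float = DEFAULT_PMAX
    alpha: float = DEFAULT_ALPHA
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if not (self.p_max > 0):
            raise ValueError("p_max must be positive")
        for name in ("alpha", "epsilon", "err_hat"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1), got {v}")


@dataclass
class QuantResult:
    """Solution of the abundance ILP."""

    genome_ids: list[int]
    delta: dict[int, int]
    p: dict[int, float]
    rel_abundance: dict[int, float]
    objective: float
    filtered_set: set[int]
    solver_status: str

    def abundances(self) -> list[tuple[int, float]]:
        return sorted(self.rel_abundance.items(), key=lambda t: (-t[1], t[0]))


def expected_count(substr_len: int, p_total: float, params: QuantParams) -> float:
    """Expected number of reads covering a substring of the given length at
    combined abundance ``p_total`` (p_i for unique, p_i + p_j for
    doubly-unique substrings)."""
    if substr_len > params.L:
        raise ValueError(
            f"substring length {substr_len} exceeds read length {params.L}"
        )
    return (
        (params.L - substr_len + 1)
        * p_total
        * (1.0 / params.L)
        * (1.0 - params.err_hat) ** substr_len
    )


def compute_filtered_set(
    state: CountState, index: SubstringIndex, alpha: float = DEFAULT_ALPHA
) -> set[int]:
    """The filtered set M(Q): genomes excluded from the A3 solution space.

    A genome is excluded only when BOTH its unique-counter sum falls below
    alpha * nuL_i AND its doubly-counter sum falls below alpha * ndL_i.
    A genome with nuL_i = 0 has an unattainable strict bound (0 < 0 is
    false), so it is never excluded on the unique condition -- genomes with
    no unique L-mers must remain identifiable.
    """
    counts = {k: float(v) for k, v in state.counts.items()}
    return _filtered_from_counts(counts, index, alpha)


def _genome_sums(counts: dict[int, float], index: SubstringIndex):
    out = {}
    for m in index.meta:
        cu = sum(counts.get(s, 0.0) for s in m.u_sids)
        cd = sum(counts.get(s, 0.0) for s in m.d_sids)
        out[m.genome_id] = (cu, cd)
    return out


def _filtered_from_counts(
    counts: dict[int, float], index: SubstringIndex, alpha: float
) -> set[int]:
    sums = _genome_sums(counts, index)
    out = set()
    for m in index.meta:
        cu, cd = sums[m.genome_id]
        if cu < alpha * m.nuL and cd < alpha * m.ndL:
            out.add(m.genome_id)
    return out


def solve_A3(
    state: CountState,
    index: SubstringIndex,
    params: QuantParams,
    counts: dict[int, float] | None = None,
) -> QuantResult:
    """Solve the joint identification/abundance MILP.

    ``counts`` optionally overrides the integer counters of ``state`` with
    arbitrary (possibly fractional) per-substring values; the filtered set
    and coverage bounds then follow the overriding values.

    Objective terms of a genome with no retained substrings of a kind are
    dropped (empty-sum limit of the 1/nu_i normalization).  The coverage
    lower bound takes its min over defined arguments only; with neither
    defined it is dropped.  After solving, delta is reported as 1 exactly
    when p_i exceeds solver tolerance: presence means positive abundance.
    """
    if counts is None:
        counts = {k: float(v) for k, v in state.counts.items()}
    meta = index.meta
    gids = [m.genome_id for m in meta]
    m_genomes = len(gids)
    gpos = {g: t for t, g in enumerate(gids)}
    filtered = _filtered_from_counts(counts, index, params.alpha)
    sums = _genome_sums(counts, index)

    # variable layout: [delta (m) | p (m) | gamma (...)]
    entries = []  # (genome pos i, [genome pos list for e], coeff k, count c, weight)
    for mi in meta:
        i = gpos[mi.genome_id]
        nu, nd = mi.nu, mi.nd
        for sid in mi.u_sids:
            sub = index.substrings[sid]
            k = expected_count(len(sub.seq), 1.0, params)
            entries.append(([i], k, counts.get(sid, 0.0), 1.0 / nu))
        for sid in mi.d_sids:
            sub = index.substrings[sid]
            k = expected_count(len(sub.seq), 1.0, params)
            js = [gpos[g] for g in sub.genome_ids]
            entries.append((js, k, counts.get(sid, 0.0), 1.0 / nd))

    n_gamma = len(entries)
    n_var = 2 * m_genomes + n_gamma
    c_obj = np.zeros(n_var)
    for t, (_js, _k, _c, w) in enumerate(entries):
        c_obj[2 * m_genomes + t] = w

    lb = np.zeros(n_var)
    ub = np.full(n_var, np.inf)
    ub[:m_genomes] = 1.0
    ub[m_genomes : 2 * m_genomes] = params.p_max
    integrality = np.zeros(n_var)
    integrality[:m_genomes] = 1.0

    constraints = []
    rows, cols, vals, clo, cup = [], [], [], [], []
    r = 0

    def add_row(coefs, lo, hi):
        nonlocal r
        for c_, v_ in coefs:
            rows.append(r)
            cols.append(c_)
            vals.append(v_)
        clo.append(lo)
        cup.append(hi)
        r += 1

    # gamma >= |c - e|: gamma + e >= c and gamma - e >= -c
    for t, (js, k, c, _w) in enumerate(entries):
        g = 2 * m_genomes + t
        add_row([(g, 1.0)] + [(m_genomes + j, k) for j in js], c, np.inf)
        add_row([(g, 1.0)] + [(m_genomes + j, -k) for j in js], -c, np.inf)

    # p_i <= delta_i * p_max
    for i in range(m_genomes):
        add_row([(m_genomes + i, 1.0), (i, -params.p_max)], -np.inf, 0.0)

    # delta_i = 0 on the filtered set
    for g in filtered:
        ub[gpos[g]] = 0.0

    # coverage lower bound for genomes outside M(Q)
    for mi in meta:
        g = mi.genome_id
        if g in filtered:
            continue
        cu, cd = sums[g]
        terms = []
        if mi.nuL > 0:
            terms.append(params.L * cu / mi.nuL)
        if mi.ndL > 0:
            terms.append(params.L * cd / mi.ndL)
        if not terms:
            continue
        bound = min(terms) * (1.0 - params.epsilon)
        if bound <= 0:
            continue
        i = gpos[g]
        add_row([(m_genomes + i, 1.0), (i, -bound)], 0.0, np.inf)

    # read budget: sum |s_i| p_i <= n * L
    add_row(
        [(m_genomes + gpos[mi.genome_id], float(mi.genome_length)) for mi in meta],
        -np.inf,
        float(params.n) * params.L,
    )

    # genomes with no retained substrings are unquantifiable: pin to zero
    for mi in meta:
        if mi.nu == 0 and mi.nd == 0:
            ub[m_genomes + gpos[mi.genome_id]] = 0.0
            ub[gpos[mi.genome_id]] = 0.0

    A = csr_matrix((vals, (rows, cols)), shape=(r, n_var))
    constraints.append(LinearConstraint(A, lb=np.array(clo), ub=np.array(cup)))

    res = milp(
        c=c_obj,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        constraints=constraints,
        options={"mip_rel_gap": 1e-9},
    )
    if res.x is None:
        raise RuntimeError(f"A3 MILP infeasible or failed: {res.message}")

    p = {g: float(res.x[m_genomes + gpos[g]]) for g in gids}
    tol = 1e-9
    delta = {g: int(p[g] > tol) for g in gids}
    total = sum(v for g, v in p.items() if delta[g])
    rel = {
        g: (p[g] / total if delta[g] and total > 0 else 0.0) for g in gids
    }
    # recompute the objective from the model definition (not the solver's
    # value, which may include tolerance noise)
    obj = 0.0
    for js, k, c, w in entries:
        e = k * sum(res.x[m_genomes + j] for j in js)
        obj += w * abs(c - e)
    return QuantResult(
        genome_ids=list(gids),
        delta=delta,
        p=p,
        rel_abundance=rel,
        objective=obj,
        filtered_set=filtered,
        solver_status="optimal" if res.success else str(res.message),
    )


def identify(
    result: QuantResult, cutoff: float = IDENTIFICATION_CUTOFF
) -> list[tuple[int, float]]:
    """Genomes whose relative abundance reaches the identification cutoff
    (default 0.01 % of total abundance), ranked by abundance descending."""
    return [
        (g, a) for g, a in result.abundances() if a >= cutoff
    ]
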