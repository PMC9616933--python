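"""Sample-complexity guarantees for unique-substring identification and
quantification of error-free reads.

Setting: n error-free reads of length L are sampled independently, each from
a uniformly random position of a mixture of a genomes with abundances
p_1..p_a; q_i is the proportion of unique L-mers on genome i (windows whose
string occurs in no other database genome) and n_i^L its total L-mer count.
Reads land on genome i with probability p'_i ~ p_i * n_i^L (the
length-weighted, "unnormalized" abundance), and a read is attributed to
genome i exactly when it is one of i's unique L-mers, which happens with
probability p'_i * q_i.  Counting attributed reads c_i gives the estimator

    p_hat_i = (c_i / q_i) / n.

The module provides the sufficient read counts for identification and for an
L1 accuracy target, the achievable L1 bound at a given n, and a Monte-Carlo
harness that checks the guarantees empirically on synthetic databases using
the index module's unique-L-mer classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genomes import GenomeDB
from .index import count_Lmers


def _check(zeta: float, q_min: float, p_min: float | None = None) -> None:
    if not (0 < zeta < 1):
        raise ValueError(f"zeta must be in (0, 1), got {zeta}")
    if not (0 < q_min <= 1):
        raise ValueError(f"q_min must be in (0, 1], got {q_min}")
    if p_min is not None and not (0 < p_min <= 1):
        raise ValueError(f"p_min must be in (0, 1], got {p_min}")


def n_for_identification(a: int, p_min: float, q_min: float, zeta: float) -> int:
    """Minimal integer n such that, with probability >= 1 - zeta, every
    mixture genome receives at least one unique-L-mer read:
    n >= (2(a+1) + ln(1/zeta)) / (p_min * q_min)^2."""
    _check(zeta, q_min, p_min)
    return math.ceil((2 * (a + 1) + math.log(1 / zeta)) / (p_min * q_min) ** 2)


def n_for_l1(a: int, q_min: float, zeta: float, eps: float) -> int:
    """Minimal integer n such that, with probability >= 1 - zeta, the L1
    distance between the estimates and the length-weighted abundances is at
    most eps:  n >= (2(a+1) + ln(1/zeta)) / (eps * q_min)^2."""
    _check(zeta, q_min)
    if not (eps > 0):
        raise ValueError(f"eps must be positive, got {eps}")
    return math.ceil((2 * (a + 1) + math.log(1 / zeta)) / (eps * q_min) ** 2)


def l1_bound(n: int, a: int, q_min: float, zeta: float) -> float:
    """L1 distance achievable with probability >= 1 - zeta from n reads:
    sqrt(2 [ln(1/zeta) + (a+1)] / (n * q_min^2))."""
    _check(zeta, q_min)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return math.sqrt(2 * (math.log(1 / zeta) + (a + 1)) / (n * q_min**2))


def estimate_abundances_unique_only(
    counts: np.ndarray | list[float],
    q: np.ndarray | list[float],
    n: int,
) -> np.ndarray:
    """The unique-evidence plug-in estimator p_hat_i = (c_i / q_i) / n."""
    c = np.asarray(counts, dtype=float)
    qa = np.asarray(q, dtype=float)
    if np.any(qa <= 0):
        raise ValueError("all q_i must be positive")
    return (c / qa) / n


def unnormalized_abundances(
    p: np.ndarray | list[float], nL: np.ndarray | list[int]
) -> np.ndarray:
    """Length-weighted abundances p'_i = p_i n_i^L / sum_j p_j n_j^L: the
    probability that a uniformly sampled read originates from genome i."""
    pa = np.asarray(p, dtype=float)
    nLa = np.asarray(nL, dtype=float)
    w = pa * nLa
    return w / w.sum()


@dataclass
class TheoremReport:
    """Empirical success rates of the guarantees over seeded replicates."""

    reps: int
    n_ident: int
    n_l1: int
    q_min: float
    p_min: float
    identification_rate: float
    l1_rate: float


def validate_theorem(
    db: GenomeDB,
    abundances: np.ndarray | list[float],
    L: int,
    Lmin: int,
    Lmax: int,
    zeta: float,
    eps: float,
    reps: int,
    seed: int = 0,
) -> TheoremReport | None:
    """Monte-Carlo check of the guarantees on a concrete database.

    Per replicate, reads are sampled at the mandated n (genome drawn with
    probability p'_i, position uniform over L-windows) and attributed via
    the database's unique-L-mer classification from :func:`count_Lmers` --
    a read is counted for its genome exactly when its window contains a
    unique substring, which is what scanning an error-free read against the
    sparsified index yields.  Reports the fraction of replicates in which
    (i) every genome was detected at n = n_for_identification, and (ii) the
    estimator's L1 error was <= eps at n = n_for_l1.
    """
    if reps == 0:
        return None
    counts, masks = count_Lmers(db, Lmin, Lmax, L, return_masks=True)
    gids = [rec.genome_id for rec in db]
    q = np.array([counts[g][0] / counts[g][2] if counts[g][2] else 0.0 for g in gids])
    nL = np.array([counts[g][2] for g in gids], dtype=float)
    if np.any(q <= 0):
        bad = [g for g, qi in zip(gids, q) if qi <= 0]
        raise ValueError(
            f"genome(s) {bad} have no unique L-mers (q_i = 0); the unique-"
            "substring guarantees do not apply -- use the doubly-unique "
            "queries for such databases"
        )
    p = np.asarray(abundances, dtype=float)
    p = p / p.sum()
    pprime = unnormalized_abundances(p, nL)
    a = len(gids)
    q_min = float(q.min())
    p_min = float(p.min())
    n_ident = n_for_identification(a, p_min, q_min, zeta)
    n_l1v = n_for_l1(a, q_min, zeta, eps)

    uniq_frac = []  # per genome: bool array over valid windows
    for g in gids:
        _ws, um, _dm = masks[g]
        uniq_frac.append(um)

    rng = np.random.default_rng(seed)
    ident_ok = 0
    l1_ok = 0
    for _ in range(reps):
        # (i) identification at n_ident
        src = rng.multinomial(n_ident, pprime)
        detected = True
        for i in range(a):
            if src[i] == 0:
                detected = False
                break
            hits = uniq_frac[i][rng.integers(0, len(uniq_frac[i]), size=src[i])]
            if not hits.any():
                detected = False
                break
        ident_ok += detected

        # (ii) L1 accuracy at n_l1
        src = rng.multinomial(n_l1v, pprime)
        c = np.empty(a)
        for i in range(a):
            if src[i] == 0:
                c[i] = 0.0
                continue
            c[i] = uniq_frac[i][
                rng.integers(0, len(uniq_frac[i]), size=src[i])
            ].sum()
        p_hat = estimate_abundances_unique_only(c, q, n_l1v)
        l1_ok += float(np.abs(p_hat - pprime).sum()) <= eps

    return TheoremReport(
        reps=reps,
        n_ident=n_ident,
        n_l1=n_l1v,
        q_min=q_min,
        p_min=p_min,
        identification_rate=ident_ok / reps,
        l1_rate=l1_ok / reps,
    )
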