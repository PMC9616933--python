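"""Synthetic genome collections, read sampling and evaluation metrics.

The generator emulates the study conditions the rest of the package is
validated under: genome collections with controlled pairwise similarity
(independent genomes; pairs sharing a backbone fraction so the shared region
yields doubly-unique and the private regions unique substrings; near-clonal
pairs differing at a few SNPs), reads sampled uniformly over genome
positions under uniform or lognormal abundances, and i.i.d. per-base
substitution errors.  All randomness is driven by a single integer seed.

Abundance semantics: an abundance vector is interpreted on the coverage
scale -- the expected number of reads from a genome is proportional to
abundance x genome length (L-mer count), matching the coverage-scale p_i of
the abundance ILP.  ``read_share=True`` switches to read-share semantics
(reads proportional to abundance alone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import GenomeDB, db_from_sequences
from .query import ASSIGNED_ONE, ASSIGNED_PAIR, ReadMatch

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationSpec:
    """Design of one synthetic experiment.

    ``similarity_design`` is one of "independent", "shared_backbone" (pairs
    sharing ``shared_fraction`` of their sequence) or "snp_clone" (pairs
    identical except for ``n_snps`` substitutions).  ``n_pairs`` limits how
    many genome pairs follow the design; remaining genomes are independent.
    ``abundance_model`` is "uniform", "lognormal" (parameters
    ``lognormal_mu``/``lognormal_sigma``) or "explicit" (``abundances``).
    """

    m: int
    genome_length: int
    similarity_design: str = "independent"
    shared_fraction: float = 0.9
    n_snps: int = 1
    n_pairs: int | None = None
    abundance_model: str = "uniform"
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    abundances: list[float] | None = None
    n_reads: int = 10000
    L: int = 100
    err_rate: float = 0.0
    uneven: bool = False
    read_share: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.err_rate < 1):
            raise ValueError("err_rate must be in [0, 1)")
        if self.similarity_design == "shared_backbone" and not (
            0 < self.shared_fraction < 1
        ):
            raise ValueError("shared_fraction must be in (0, 1)")

    def abundance_vector(self, rng: np.random.Generator) -> np.ndarray:
        if self.abundance_model == "uniform":
            a = np.ones(self.m)
        elif self.abundance_model == "lognormal":
            a = rng.lognormal(self.lognormal_mu, self.lognormal_sigma, self.m)
        elif self.abundance_model == "explicit":
            if self.abundances is None or len(self.abundances) != self.m:
                raise ValueError("explicit abundance_model needs an abundances vector")
            a = np.asarray(self.abundances, dtype=float)
        else:
            raise ValueError(f"unknown abundance_model {self.abundance_model!r}")
        if np.any(a <= 0):
            raise ValueError("abundances must be strictly positive")
        return a / a.sum()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def make_genomes(spec: SimulationSpec) -> tuple[GenomeDB, dict]:
    """Generate a genome collection per the spec; deterministic per seed.

    Returns the database and a provenance dict mapping each genome_id to its
    design role ("independent" or ("pair", partner_id)).
    """
    rng = np.random.default_rng(spec.seed)
    seqs: list[str] = []
    provenance: dict[int, object] = {}
    n_pairs = spec.n_pairs
    if spec.similarity_design == "independent":
        n_pairs = 0
    elif n_pairs is None:
        n_pairs = spec.m // 2
    if 2 * n_pairs > spec.m:
        raise ValueError("n_pairs exceeds m // 2")

    gl = spec.genome_length
    for _ in range(n_pairs):
        if spec.similarity_design == "shared_backbone":
            shared = int(round(spec.shared_fraction * gl))
            backbone = _random_seq(rng, shared)
            a = _random_seq(rng, gl - shared) + backbone
            b = _random_seq(rng, gl - shared) + backbone
        elif spec.similarity_design == "snp_clone":
            a = _random_seq(rng, gl)
            arr = np.frombuffer(a.encode(), dtype=np.uint8).copy()
            pos = rng.choice(gl, size=min(spec.n_snps, gl), replace=False)
            for p in pos:
                cur = arr[p]
                choices = _BASES[_BASES != cur]
                arr[p] = rng.choice(choices)
            b = arr.tobytes().decode()
        else:
            raise ValueError(f"unknown similarity_design {spec.similarity_design!r}")
        seqs += [a, b]
    while len(seqs) < spec.m:
        seqs.append(_random_seq(rng, gl))

    named = [(i + 1, f"sim_{i + 1}", [s]) for i, s in enumerate(seqs)]
    db = db_from_sequences(named)
    for i in range(spec.m):
        gid = i + 1
        if i < 2 * n_pairs:
            partner = gid + 1 if i % 2 == 0 else gid - 1
            provenance[gid] = ("pair", partner)
        else:
            provenance[gid] = "independent"
    return db, provenance


def sample_reads(
    db: GenomeDB,
    abundances: np.ndarray | list[float],
    n: int,
    L: int,
    err_rate: float = 0.0,
    seed: int = 0,
    read_share: bool = False,
    uneven: bool = False,
) -> tuple[list[tuple[str, str]], list[int]]:
    """Sample n reads of length L; returns (reads, per-read true genome id).

    The source genome is drawn per read with probability proportional to
    abundance x number of valid L-windows (coverage semantics; plain
    abundance under ``read_share``); the start position is uniform over
    valid windows (or ramped 0.5x..1.5x along the genome when ``uneven``);
    the strand is uniform; each base is substituted by a uniformly chosen
    different base with probability ``err_rate``.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(abundances, dtype=float)
    if len(a) != db.m or np.any(a <= 0):
        raise ValueError("abundances must be positive, one per genome")
    windows = []
    for rec in db:
        ws = []
        for ci, c in enumerate(rec.contigs):
            if len(c) >= L:
                ws.extend((ci, s) for s in range(len(c) - L + 1))
        if not ws:
            raise ValueError(
                f"genome {rec.genome_id} has no contig of length >= L={L}"
            )
        windows.append(ws)
    weights = a * (1.0 if read_share else np.array([len(w) for w in windows]))
    probs = weights / weights.sum()
    src = rng.choice(db.m, size=n, p=probs)

    comp = {65: 84, 67: 71, 71: 67, 84: 65}
    comp_lut = np.arange(256, dtype=np.uint8)
    for k, v in comp.items():
        comp_lut[k] = v

    reads: list[tuple[str, str]] = []
    truth: list[int] = []
    for j in range(n):
        gi = int(src[j])
        rec = db.genomes[gi]
        ws = windows[gi]
        if uneven:
            ramp = 0.5 + np.linspace(0.0, 1.0, len(ws))
            wi = int(rng.choice(len(ws), p=ramp / ramp.sum()))
        else:
            wi = int(rng.integers(0, len(ws)))
        ci, s = ws[wi]
        arr = np.frombuffer(rec.contigs[ci][s : s + L].encode(), dtype=np.uint8).copy()
        if err_rate > 0:
            mask = rng.random(L) < err_rate
            if mask.any():
                cur = arr[mask]
                shift = rng.integers(1, 4, size=mask.sum())
                codes = np.searchsorted(_BASES, cur)  # _BASES is sorted
                arr[mask] = _BASES[(codes + shift) % 4]
        if rng.integers(0, 2):
            arr = comp_lut[arr][::-1]
        reads.append((f"read_{j}", arr.tobytes().decode()))
        truth.append(rec.genome_id)
    return reads, truth


@dataclass
class EvalReport:
    """The evaluation metrics: read-classification precision/recall,
    identification precision/recall at the 0.01 % abundance cutoff, and
    L1/L2 distances between true and predicted relative abundances."""

    classification_precision: float
    classification_recall: float
    identification_precision: float
    identification_recall: float
    l1_error: float
    l2_error: float

    def as_dict(self) -> dict[str, float]:
        return {
            "classification_precision": self.classification_precision,
            "classification_recall": self.classification_recall,
            "identification_precision": self.identification_precision,
            "identification_recall": self.identification_recall,
            "l1_error": self.l1_error,
            "l2_error": self.l2_error,
        }


def evaluate(
    resolutions: list[ReadMatch],
    truth: list[int],
    predicted_abundance: dict[int, float],
    true_abundance: dict[int, float],
    cutoff: float = 1e-4,
) -> EvalReport:
    """Compute the evaluation metrics.

    Classification counts a pair-assigned read as correct when the true
    source genome is either pair member.  Identification compares the
    genomes with predicted relative abundance >= cutoff against the truly
    present set.  L1/L2 are taken over the union of true and predicted
    genomes.
    """
    assigned = correct = 0
    for rm, t in zip(resolutions, truth):
        if rm.status in (ASSIGNED_ONE, ASSIGNED_PAIR):
            assigned += 1
            if t in rm.candidate_set:
                correct += 1
    n = len(truth)
    cls_p = correct / assigned if assigned else 0.0
    cls_r = correct / n if n else 0.0

    pred_set = {g for g, v in predicted_abundance.items() if v >= cutoff}
    true_set = {g for g, v in true_abundance.items() if v > 0}
    tp = len(pred_set & true_set)
    id_p = tp / len(pred_set) if pred_set else 0.0
    id_r = tp / len(true_set) if true_set else 0.0

    union = sorted(pred_set | true_set | set(true_abundance))
    diffs = np.array(
        [predicted_abundance.get(g, 0.0) - true_abundance.get(g, 0.0) for g in union]
    )
    return EvalReport(
        classification_precision=cls_p,
        classification_recall=cls_r,
        identification_precision=id_p,
        identification_recall=id_r,
        l1_error=float(np.abs(diffs).sum()),
        l2_error=float(np.sqrt((diffs**2).sum())),
    )
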