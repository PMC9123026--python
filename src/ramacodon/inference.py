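"""Two-sample permutation testing for codon dihedral distributions.

The question asked of every pair of synonymous codons (c, c'), separately
within each secondary-structure mode, is whether their underlying backbone
(phi, psi) distributions differ.  The test statistic is the L1 distance
between torus KDEs of the two samples; its null distribution is obtained by
permutation: pool the observations, re-split at |X| at random K times, and
recompute the statistic.  The p-value is (1 + eta) / (1 + K) with eta the
number of permutations whose statistic is at least the base value, so the
smallest attainable p is 1 / (1 + K).

Sample-size bias between rare and abundant codons is removed by estimating
every density in a synonymous group from the same number N of observations
(the rarest codon's count, capped at N_max), and abundant codons are
exploited through B bootstrap rounds: each round draws N observations with
replacement from each codon and runs a fresh K-permutation test.  The
aggregate p-value is (1 + sum_b eta_b) / (1 + B*K).

Self-comparisons (c, c) are run the same way — two independent bootstrap
resamples from the same pool — and serve as negative controls.  All
hypotheses of one secondary structure are corrected together with the
Benjamini-Hochberg procedure at FDR level q.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import DEFAULT_BANDWIDTH, DEFAULT_GRID_SIZE, _kernel_factors
from .config import RunConfig

__all__ = [
    "CodonSample",
    "PermutationResult",
    "PairTestResult",
    "FdrDecision",
    "permutation_test",
    "equalized_sample_size",
    "bootstrap_pair_test",
    "bh_procedure",
    "run_all_pairwise_tests",
    "normalize_distance_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class CodonSample:
    """Pooled (phi, psi) observations of one codon in one secondary structure."""

    codon: str
    secondary_structure: str
    observations: np.ndarray

    def __post_init__(self):
        self.observations = np.asarray(self.observations, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class PermutationResult:
    base_statistic: float
    eta: int
    K: int

    @property
    def p_value(self) -> float:
        return (1 + self.eta) / (1 + self.K)


@dataclass
class PairTestResult:
    codon_a: str
    codon_b: str
    secondary_structure: str
    per_bootstrap: list = field(default_factory=list)

    @property
    def B(self) -> int:
        return len(self.per_bootstrap)

    @property
    def K(self) -> int:
        return self.per_bootstrap[0].K

    @property
    def mean_distance(self) -> float:
        return float(np.mean([r.base_statistic for r in self.per_bootstrap]))

    @property
    def p_value(self) -> float:
        eta_total = sum(r.eta for r in self.per_bootstrap)
        return (1 + eta_total) / (1 + self.B * self.K)


@dataclass
class FdrDecision:
    q: float
    M: int
    alpha_M: float | None
    rejected: set


def _l1_stat_engine(X: np.ndarray, Y: np.ndarray, bandwidth: float, grid_size: int):
    """Closure evaluating the KDE-L1 statistic on index subsets of the pool.

    The per-axis kernel factors of the pooled observations are computed
    once; a KDE of any subset is then one matrix product of column slices,
    which makes the K permuted statistics cheap.
    """
    pool = np.vstack([X, Y])
    a, b = _kernel_factors(pool, bandwidth, grid_size)

    def stat(idx_x: np.ndarray, idx_y: np.ndarray) -> float:
        fx = a[:, idx_x] @ b[:, idx_x].T
        fy = a[:, idx_y] @ b[:, idx_y].T
        fx /= fx.sum()
        fy /= fy.sum()
        return float(np.abs(fx - fy).sum())

    return stat, len(X), len(pool)


def _permutation_test_rng(X, Y, K, rng, bandwidth, grid_size) -> PermutationResult:
    stat, n_x, n_pool = _l1_stat_engine(X, Y, bandwidth, grid_size)
    base = stat(np.arange(n_x), np.arange(n_x, n_pool))
    eta = 0
    for _ in range(K):
        perm = rng.permutation(n_pool)
        if base <= stat(perm[:n_x], perm[n_x:]):
            eta += 1
    return PermutationResult(base, eta, K)


def permutation_test(
    X,
    Y,
    K: int,
    seed,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> PermutationResult:
    """K-permutation two-sample test with the KDE-L1 statistic.

    ``seed`` may be an int or a numpy Generator/SeedSequence.  Returns the
    base statistic, the exceedance count eta = #{k : base <= permuted_k}
    and p = (1 + eta) / (1 + K).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.size == 0 or Y.size == 0:
        raise ValueError("permutation test requires non-empty samples")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    return _permutation_test_rng(X, Y, K, rng, bandwidth, grid_size)


def equalized_sample_size(counts, n_max: int = 200) -> int:
    """Common per-codon sample size for a synonymous group.

    N = min(N_max, min_c N_c): the rarest codon's count, capped at N_max.
    ``counts`` maps codon -> observation count; a zero count makes the whole
    group untestable and raises.
    """
    if not counts:
        raise ValueError("empty count map")
    values = list(counts.values()) if isinstance(counts, dict) else list(counts)
    if min(values) < 1:
        raise ValueError("a codon with zero observations is untestable")
    return int(min(n_max, min(values)))


def bootstrap_pair_test(
    sample_a: CodonSample,
    sample_b: CodonSample,
    N: int,
    B: int,
    K: int,
    seed,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> PairTestResult:
    """B bootstrap rounds of the K-permutation test at equalized size N.

    Each round draws N observations with replacement from each codon
    (independently, also when sample_a is sample_b) and runs one
    permutation test; the aggregate p-value is (1 + sum eta_b) / (1 + B*K).
    """
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("bootstrap test requires non-empty codon samples")
    if B < 1 or K < 1:
        raise ValueError("B and K must be >= 1")
    rng = np.random.default_rng(seed)
    result = PairTestResult(sample_a.codon, sample_b.codon,
                            sample_a.secondary_structure)
    for _ in range(B):
        xa = sample_a.observations[rng.integers(len(sample_a), size=N)]
        xb = sample_b.observations[rng.integers(len(sample_b), size=N)]
        result.per_bootstrap.append(
            _permutation_test_rng(xa, xb, K, rng, bandwidth, grid_size)
        )
    return result


def bh_procedure(p_values, q: float = 0.05, mode: str = "literal") -> FdrDecision:
    """Benjamini-Hochberg step-up FDR control over (test_id, p) pairs.

    With sorted p-values p(1) <= ... <= p(M), let
    i0 = max{i : p(i) <= q*i/M}.  In ``literal`` mode the adaptive
    threshold is alpha_M = p(i0) and tests with p strictly below alpha_M
    are rejected; ``textbook`` mode rejects all i <= i0.  If no index
    satisfies the condition nothing is rejected.
    """
    p_values = list(p_values)
    if not p_values:
        raise ValueError("empty p-value list")
    ids, ps = zip(*p_values)
    ps = np.asarray(ps, dtype=float)
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    M = len(ps)
    order = np.argsort(ps, kind="stable")
    sorted_p = ps[order]
    ranks = np.arange(1, M + 1)
    ok = sorted_p <= q * ranks / M
    if not np.any(ok):
        return FdrDecision(q, M, None, set())
    i0 = int(np.max(ranks[ok]))
    alpha_m = float(sorted_p[i0 - 1])
    if mode == "literal":
        rejected = {tid for tid, p in zip(ids, ps) if p < alpha_m}
    elif mode == "textbook":
        rejected = {ids[order[i]] for i in range(i0)}
    else:
        raise ValueError("mode must be 'literal' or 'textbook'")
    return FdrDecision(q, M, alpha_m, rejected)


def normalize_distance_matrix(raw) -> np.ndarray:
    """Scale a mean-distance matrix so every self-distance is exactly 1.

    d(c, c') / sqrt(d(c, c) * d(c', c')); scale-invariant, symmetric when
    the input is, and requires a strictly positive diagonal.
    """
    raw = np.asarray(raw, dtype=float)
    diag = np.diag(raw)
    if np.any(diag <= 0):
        raise ValueError("zero or negative self-distance on the diagonal")
    out = raw / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(out, 1.0)
    return out


def _pair_seed(master_seed: int, ss: str, codon_a: str, codon_b: str):
    """Deterministic child seed per (secondary structure, codon pair)."""
    key = [ord(ch) for ch in f"{ss}:{codon_a}:{codon_b}"]
    return np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF,
                                  spawn_key=tuple(key))


def run_all_pairwise_tests(samples, config: RunConfig, genetic_code=None):
    """All synonymous-pair and self-pair tests, with per-structure FDR.

    ``samples`` is an iterable of CodonSample.  Per secondary structure and
    amino acid, the equalized sample size N is computed, every unordered
    synonymous pair and every self-pair (control) is tested with the
    bootstrap-aggregated permutation test, and the pooled p-values of that
    structure are corrected with Benjamini-Hochberg at level ``config.q``.
    With the full standard code present this yields 61 self-tests plus 87
    synonymous-pair tests = 148 hypotheses per structure.

    Returns ``(table, decisions)``: a DataFrame with one row per test and a
    dict secondary_structure -> FdrDecision.  Amino-acid groups containing
    a codon with no observations in a structure are skipped with a warning.
    """
    from .genetics import GeneticCode

    code = genetic_code or GeneticCode()
    by_ss: dict[str, dict[str, CodonSample]] = {}
    for s in samples:
        by_ss.setdefault(s.secondary_structure, {})[s.codon] = s

    rows = []
    decisions: dict[str, FdrDecision] = {}
    for ss in sorted(by_ss):
        codon_map = by_ss[ss]
        results: list[PairTestResult] = []
        aa_of: dict[str, str] = {}
        self_distance: dict[str, float] = {}
        for aa, codons in sorted(code.synonymous_groups().items()):
            present = [c for c in codons if c in codon_map]
            if not present:
                continue
            if any(len(codon_map[c]) == 0 for c in present):
                logger.warning(
                    "skipping amino acid %s in structure %s: empty codon sample",
                    aa, ss,
                )
                continue
            N = equalized_sample_size({c: len(codon_map[c]) for c in present},
                                      config.n_max)
            pairs = [(c, c) for c in present]
            pairs += list(itertools.combinations(present, 2))
            for ca, cb in pairs:
                res = bootstrap_pair_test(
                    codon_map[ca], codon_map[cb], N,
                    config.b_test, config.k_perm,
                    _pair_seed(config.seed, ss, ca, cb),
                    config.bandwidth, config.grid_size,
                )
                res._N = N  # equalized size used, carried into the table
                results.append(res)
                aa_of[ca] = aa_of[cb] = aa
                if ca == cb:
                    self_distance[ca] = res.mean_distance
        if not results:
            continue
        decision = bh_procedure(
            [((r.codon_a, r.codon_b), r.p_value) for r in results],
            q=config.q, mode=config.bh_mode,
        )
        decisions[ss] = decision
        for r in results:
            d_aa = np.sqrt(self_distance[r.codon_a] * self_distance[r.codon_b])
            rows.append({
                "amino_acid": aa_of[r.codon_a],
                "codon_a": r.codon_a,
                "codon_b": r.codon_b,
                "secondary_structure": ss,
                "N": r._N,
                "B": r.B,
                "K": r.K,
                "mean_distance": r.mean_distance,
                "normalized_distance": r.mean_distance / d_aa if d_aa > 0
                else np.nan,
                "p_value": r.p_value,
                "rejected": (r.codon_a, r.codon_b) in decision.rejected,
            })
    return pd.DataFrame(rows), decisions
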