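"""Simulation experiments validating the delimitation machinery.

These are the package's own calibration studies: parameter recovery in the
favourable regime (well-separated species), loss of power when effective
population sizes dwarf species ages, and the structural nesting of the
model hierarchy.  They are exercised by the test suite and the results
reproduction script; problem sizes are arguments so callers choose their
compute budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gmyc
from .synthetic_data import recovery_fixture, simulate_msc_gene_tree, simulate_yule


@dataclass
class RecoveryResult:
    n_reps: int
    n_recovered: int          # single-threshold entity count == true S
    n_ci_covering: int        # 2-logL support set covers true S
    entity_counts: list[int]

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_reps

    @property
    def ci_coverage(self) -> float:
        return self.n_ci_covering / self.n_reps


def recovery_experiment(
    n_reps: int = 100,
    seed: int = 0,
    S: int = 10,
    samples_per_species: int = 4,
    depth_fraction: float = 0.075,
    n_starts: int = 4,
) -> RecoveryResult:
    """Single-threshold GMYC parameter recovery.

    Each replicate simulates a Yule species tree with within-species
    coalescent depths a small fraction of every divergence, fits all
    single-threshold models, and asks whether the best fit delimits
    exactly S entities and whether the 2 log-likelihood support set
    covers S.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(1, 2**31 - 1, size=n_reps)
    rec = ci = 0
    counts = []
    for s in seeds:
        _, gene, _ = recovery_fixture(
            S=S,
            samples_per_species=samples_per_species,
            depth_fraction=depth_fraction,
            seed=int(s),
        )
        _, fits = gmyc.candidate_single_threshold_fits(gene, n_starts=n_starts)
        best = max(fits, key=lambda f: f.logL)
        counts.append(best.entities)
        rec += best.entities == S
        lo, hi = gmyc.entity_confidence_interval(fits, delta=2.0)
        ci += lo <= S <= hi
    return RecoveryResult(n_reps, rec, ci, counts)


def power_collapse_experiment(
    n_reps: int = 100,
    seed: int = 0,
    S: int = 5,
    samples_per_species: int = 3,
    ne_factor: float = 10.0,
    alpha: float = 0.05,
    n_starts: int = 3,
) -> tuple[int, int]:
    """Fraction of significant single-vs-null LR tests when the coalescent
    scale dwarfs the species depths (massive incomplete lineage sorting).

    Returns (number significant at ``alpha``, n_reps).  With Ne far larger
    than the species tree age the mixed model is indistinguishable from a
    single coalescent, so the test should rarely reject.
    """
    rng = np.random.default_rng(seed)
    sig = 0
    for s in rng.integers(1, 2**31 - 1, size=n_reps):
        sp = simulate_yule(S, 1.0, seed=int(s))
        gene, _ = simulate_msc_gene_tree(
            sp, samples_per_species, Ne_time=ne_factor * sp.root_age,
            seed=int(s) + 1,
        )
        null = gmyc.fit_null(gene, n_starts=n_starts)
        single = gmyc.fit_single_threshold(gene, n_starts=n_starts)
        _, p = gmyc.lr_test(null.logL, single.logL)
        sig += p < alpha
    return sig, n_reps


def nesting_experiment(
    n_trees: int = 500,
    seed: int = 0,
    n_starts: int = 2,
    tol: float = 1e-9,
) -> int:
    """Count violations of logL(null) <= logL(single) <= logL(multiple)
    over random coalescent/Yule trees (should be zero: each search is
    seeded with the optimum of the model it nests)."""
    rng = np.random.default_rng(seed)
    violations = 0
    for s in rng.integers(1, 2**31 - 1, size=n_trees):
        s = int(s)
        if s % 2:
            tree = simulate_yule(int(5 + s % 6), 1.0, seed=s)
        else:
            sp = simulate_yule(3, 1.0, seed=s)
            tree, _ = simulate_msc_gene_tree(sp, 2, Ne_time=0.2, seed=s + 1)
        null = gmyc.fit_null(tree, n_starts=n_starts)
        single = max(
            gmyc.candidate_single_threshold_fits(tree, n_starts=n_starts)[1],
            key=lambda f: f.logL,
        )
        multiple = gmyc.fit_multiple_threshold(
            tree, seed=s, start=single, n_starts=n_starts
        )
        if null.logL > single.logL + tol or single.logL > multiple.logL + tol:
            violations += 1
    return violations
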