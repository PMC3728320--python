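"""Simulators with known truth: Yule species trees, multispecies-coalescent
gene trees, HKY+Gamma sequences, and alignment degradation.

The generator emulates the statistical structure the analysis assumes for a
recently diversified conifer group: S species arising under a Yule process,
a handful of haplotypes sampled per species that coalesce within species
(optionally with large effective sizes, so that lineage sorting is
incomplete), and low per-site diversity sequences with optional shared gap
events and terminal missing-data blocks.  Because truth (species tree,
species labels, S) is retained, every downstream module can be validated
without real data.

Time units are arbitrary "tree units"; all rates are per unit time.  The
delimitation model is time-unit invariant, so no absolute calibration is
simulated.  Gene trees are simulated without recombination, matching
uniparental plastid inheritance.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import msprime
import numpy as np
from scipy import stats as sp_stats
from scipy.linalg import expm

from .errors import InputError
from .io_formats import (
    Alignment,
    SpeciesMap,
    TreeNode,
    UltrametricTree,
    write_alignment,
    write_species_map,
    write_tree,
)

#: HKY equilibrium base frequencies emulating AT-rich plastid spacers/genes
#: (G+C ~ 0.37, as in hard-pine plastid markers).
PINE_FREQS = (0.315, 0.185, 0.185, 0.315)  # A, C, G, T


@dataclass
class SimParams:
    """Generator settings; defaults emulate the assumed study structure:
    S species under Yule branching, 2-14 haplotypes per species, ~1 kb
    sequences with per-site diversity in the low 1e-3 range."""

    S: int = 10
    birth_rate: float = 1.0
    samples_per_species: int | tuple[int, int] = (2, 14)
    Ne_time: float = 0.1
    mu: float = 0.002
    kappa: float = 2.0
    alpha: float | None = 1.0
    L: int = 1200
    indel_rate: float = 0.0
    missing_block_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise InputError("need at least 2 species")
        if self.L < 1:
            raise InputError("need at least 1 site")
        for name in ("birth_rate", "Ne_time", "mu", "kappa",
                     "indel_rate", "missing_block_prob"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Yule species tree
# ---------------------------------------------------------------------------

def simulate_yule(S: int, birth_rate: float = 1.0, seed: int = 0) -> UltrametricTree:
    """Yule tree conditioned on S tips.

    Forward simulation: with k lineages the waiting time to the next split
    is Exp(k * birth_rate); after the (S-1)th split one final Exp(S *
    birth_rate) interval separates the last split from the present (so for
    S = 2 the split age is Exp(2 * birth_rate) with mean 1/(2*birth_rate)).
    Tips are labelled sp1..spS.
    """
    if S < 2:
        raise InputError("need at least 2 species")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    active = [root]
    split_time: dict[int, float] = {}
    t = 0.0
    while len(active) < S:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        split_time[id(node)] = t
        for _ in range(2):
            active.append(node.add_child(TreeNode()))
    t_end = t + rng.exponential(1.0 / (S * birth_rate))
    for node in root.preorder():
        node.age = t_end - split_time[id(node)] if node.children else 0.0
    tree = UltrametricTree(root)
    for i, tip in enumerate(tree.tips(), 1):
        tip.label = f"sp{i}"
    return tree


# ---------------------------------------------------------------------------
# Multispecies coalescent gene tree (msprime)
# ---------------------------------------------------------------------------

def simulate_msc_gene_tree(
    species_tree: UltrametricTree,
    samples_per_species: int | tuple[int, int] = 2,
    Ne_time: float = 0.1,
    seed: int = 0,
) -> tuple[UltrametricTree, SpeciesMap]:
    """Simulate one non-recombining gene tree under the multispecies
    coalescent along ``species_tree``.

    Within every (ancestral) population a lineage pair coalesces at rate
    1/``Ne_time``; uncoalesced lineages enter the parent population at the
    species divergence age.  Haploid samples, so the mean within-population
    pairwise coalescence time is ``Ne_time``.  Tips are labelled
    ``<species>_<i>`` and returned with their SpeciesMap.
    """
    rng = np.random.default_rng(seed)
    species = species_tree.tip_labels()
    if isinstance(samples_per_species, int):
        counts = {sp: samples_per_species for sp in species}
    else:
        lo, hi = samples_per_species
        counts = {sp: int(rng.integers(lo, hi + 1)) for sp in species}
    ne = max(Ne_time, 1e-9)
    demography = msprime.Demography.from_species_tree(
        species_tree.newick(), initial_size=ne
    )
    ts = msprime.sim_ancestry(
        samples=counts,
        demography=demography,
        ploidy=1,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    t = ts.first()
    pop_name = {p.id: p.metadata["name"] for p in ts.populations()}
    tip_counter: dict[str, int] = {sp: 0 for sp in species}
    assignments: dict[str, str] = {}

    def rec(u: int) -> TreeNode:
        node = TreeNode(age=float(t.time(u)))
        kids = t.children(u)
        if not kids:
            sp = pop_name[ts.node(u).population]
            tip_counter[sp] += 1
            node.label = f"{sp}_{tip_counter[sp]}"
            node.age = 0.0
            assignments[node.label] = sp
        for v in kids:
            node.add_child(rec(v))
        return node

    gene_tree = UltrametricTree(rec(t.root))
    return gene_tree, SpeciesMap(assignments)


# ---------------------------------------------------------------------------
# HKY + Gamma sequence simulation
# ---------------------------------------------------------------------------

def _hky_rate_matrix(mu: float, kappa: float, freqs) -> np.ndarray:
    """HKY85 generator scaled to ``mu`` expected substitutions per site per
    unit time.  Base order A, C, G, T; transitions are A<->G and C<->T."""
    pi = np.asarray(freqs, dtype=float)
    if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-8 or (pi <= 0).any():
        raise InputError("freqs must be 4 positive values summing to 1")
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    if rate > 0:
        Q *= mu / rate
    return Q


def _gamma_category_rates(alpha: float | None, K: int = 4) -> np.ndarray:
    """Discrete-gamma site-rate categories (median method, mean 1)."""
    if alpha is None or not np.isfinite(alpha):
        return np.ones(1)
    qs = (2 * np.arange(K) + 1) / (2 * K)
    r = sp_stats.gamma.ppf(qs, a=alpha, scale=1.0 / alpha)
    return r / r.mean()


def simulate_sequences(
    tree: UltrametricTree,
    mu: float = 0.002,
    kappa: float = 2.0,
    alpha: float | None = 1.0,
    L: int = 1200,
    seed: int = 0,
    freqs=PINE_FREQS,
) -> Alignment:
    """Evolve sequences along ``tree`` under HKY with discrete-gamma
    site-rate heterogeneity (4 categories; ``alpha=None`` disables it).

    The root sequence is drawn from the equilibrium frequencies and each
    branch applies the transition matrix expm(Q * r_c * branch length) per
    rate category.  Deterministic given ``seed``.
    """
    if L < 1:
        raise InputError("need at least 1 site")
    rng = np.random.default_rng(seed)
    Q = _hky_rate_matrix(mu, kappa, freqs)
    cat_rates = _gamma_category_rates(alpha)
    site_cat = rng.integers(len(cat_rates), size=L)
    pi = np.asarray(freqs, dtype=float)
    root_seq = rng.choice(4, size=L, p=pi)
    seqs: dict[int, np.ndarray] = {id(tree.root): root_seq}
    rows: list[tuple[str, str]] = []
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for node in tree.root.preorder():
        if node.parent is not None:
            parent_seq = seqs[id(node.parent)]
            child_seq = parent_seq.copy()
            bl = node.edge_length
            if bl > 0 and mu > 0:
                for c, r in enumerate(cat_rates):
                    P = expm(Q * (r * bl))
                    P = np.clip(P, 0, None)
                    P /= P.sum(axis=1, keepdims=True)
                    for b in range(4):
                        sel = (site_cat == c) & (parent_seq == b)
                        n_sel = int(sel.sum())
                        if n_sel:
                            child_seq[sel] = rng.choice(4, size=n_sel, p=P[b])
            seqs[id(node)] = child_seq
        if node.is_leaf:
            rows.append(
                (node.label, alphabet[seqs[id(node)]].tobytes().decode())
            )
    return Alignment(rows)


# ---------------------------------------------------------------------------
# Degradation: shared indels and terminal missing blocks
# ---------------------------------------------------------------------------

def degrade(
    aln: Alignment,
    indel_rate: float = 0.0,
    missing_block_prob: float = 0.0,
    seed: int = 0,
    terminal_char: str = "N",
) -> tuple[Alignment, list[tuple[int, int, tuple[str, ...]]]]:
    """Insert shared internal gap events and per-row terminal missing
    blocks; returns the degraded alignment and the truth mask of inserted
    events as (start, end, member ids) in 1-based columns.

    Events get distinct non-adjacent spans away from the row ends
    (geometric lengths, mean 3), so each is recoverable exactly as one
    indel event.  Terminal blocks emulate partial reads and use ``N`` by
    default (missing data, not indels).
    """
    rng = np.random.default_rng(seed)
    L = aln.length
    n = aln.n
    seqs = {rid: list(seq) for rid, seq in aln.rows}
    ids = aln.ids
    truth: list[tuple[int, int, tuple[str, ...]]] = []

    n_events = int(rng.poisson(indel_rate * L)) if indel_rate > 0 else 0
    lo_col = max(2, int(0.15 * L))
    hi_col = min(L - 1, int(0.85 * L))
    occupied = np.zeros(L + 2, dtype=bool)
    for _ in range(n_events):
        for _try in range(200):
            length = int(rng.geometric(1.0 / 3.0))
            start = int(rng.integers(lo_col, max(hi_col - length, lo_col) + 1))
            end = start + length - 1
            if end > hi_col:
                continue
            if occupied[start - 1 : end + 2].any():  # keep events non-adjacent
                continue
            occupied[start - 1 : end + 2] = True
            n_members = 1 + int(rng.binomial(max(n - 1, 0), 0.4))
            members = tuple(
                sorted(rng.choice(ids, size=min(n_members, n), replace=False))
            )
            for rid in members:
                for c in range(start - 1, end):
                    seqs[rid][c] = "-"
            truth.append((start, end, members))
            break
    truth.sort()

    if missing_block_prob > 0:
        max_block = max(1, int(0.1 * L))
        for rid in ids:
            if rng.random() < missing_block_prob:
                blk = int(rng.integers(1, max_block + 1))
                if rng.random() < 0.5:
                    cols = range(blk)
                else:
                    cols = range(L - blk, L)
                for c in cols:
                    seqs[rid][c] = terminal_char
    rows = [(rid, "".join(seqs[rid])) for rid in ids]
    return Alignment(rows, list(aln.partitions)), truth


def recovery_fixture(
    S: int = 10,
    samples_per_species: int = 4,
    depth_fraction: float = 0.075,
    birth_rate: float = 1.0,
    seed: int = 0,
) -> tuple[UltrametricTree, UltrametricTree, SpeciesMap]:
    """Fixture in the delimitation-favourable regime: the expected
    within-species coalescent depth is ``depth_fraction`` of the shallowest
    species divergence, so every speciation event is separable from
    intraspecific coalescence.

    With n haploid samples per species E[T_MRCA] = 2 Ne (1 - 1/n), so
    Ne_time = depth_fraction * min_divergence / (2 (1 - 1/n)).  Returns
    (species tree, gene tree, species map).
    """
    rng = np.random.default_rng(seed)
    s1, s2 = (int(x) for x in rng.integers(1, 2**31 - 1, size=2))
    sp_tree = simulate_yule(S, birth_rate, seed=s1)
    min_split = min(n.age for n in sp_tree.internal_nodes())
    n = samples_per_species
    ne = depth_fraction * min_split / (2.0 * (1.0 - 1.0 / n))
    gene_tree, smap = simulate_msc_gene_tree(sp_tree, n, ne, seed=s2)
    return sp_tree, gene_tree, smap


# ---------------------------------------------------------------------------
# Fixture composition
# ---------------------------------------------------------------------------

@dataclass
class TruthBundle:
    params: SimParams
    species_tree: UltrametricTree
    gene_tree: UltrametricTree
    smap: SpeciesMap
    alignment: Alignment
    indel_truth: list = field(default_factory=list)

    @property
    def true_entities(self) -> int:
        return self.params.S


def make_fixture(params: SimParams, out_dir: str | None = None) -> TruthBundle:
    """Compose the three simulators into one fixture with known truth.

    Seeds for the stages are derived deterministically from ``params.seed``,
    so identical params give byte-identical outputs.  When ``out_dir`` is
    given, writes alignment.fasta, gene_tree.nwk, species_tree.nwk,
    species_map.tsv and truth.json.
    """
    rng = np.random.default_rng(params.seed)
    s1, s2, s3, s4 = (int(x) for x in rng.integers(1, 2**31 - 1, size=4))
    sp_tree = simulate_yule(params.S, params.birth_rate, seed=s1)
    gene_tree, smap = simulate_msc_gene_tree(
        sp_tree, params.samples_per_species, params.Ne_time, seed=s2
    )
    aln = simulate_sequences(
        gene_tree, params.mu, params.kappa, params.alpha, params.L, seed=s3
    )
    truth: list = []
    if params.indel_rate > 0 or params.missing_block_prob > 0:
        aln, truth = degrade(
            aln, params.indel_rate, params.missing_block_prob, seed=s4
        )
    bundle = TruthBundle(
        params=params,
        species_tree=sp_tree,
        gene_tree=gene_tree,
        smap=smap,
        alignment=aln,
        indel_truth=truth,
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_alignment(aln, os.path.join(out_dir, "alignment.fasta"))
        write_tree(gene_tree, os.path.join(out_dir, "gene_tree.nwk"))
        write_tree(sp_tree, os.path.join(out_dir, "species_tree.nwk"))
        write_species_map(smap, os.path.join(out_dir, "species_map.tsv"))
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(
                {
                    "params": {
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in vars(params).items()
                    },
                    "true_entities": bundle.true_entities,
                    "indel_events": [
                        {"start": s, "end": e, "members": list(m)}
                        for s, e, m in truth
                    ],
                },
                fh,
                indent=1,
                sort_keys=True,
            )
    return bundle
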