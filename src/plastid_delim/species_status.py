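"""Classify species on a gene tree as mono-, para- or polyphyletic.

For a species S on a rooted tree, monophyly is clade purity under the MRCA
of its tips.  For non-monophyletic species the classification rests on the
minimum number of *origins* of the binary character "is S" over all
most-parsimonious reconstructions: one origin = paraphyletic (S arises once
but excludes some descendants), two or more = polyphyletic ("biphyletic"
when exactly two).  The root carrying state S counts as one origin, which
makes the quantity well defined on any rooted topology.

Classification is purely topological: branch lengths are ignored and
identical haplotypes appear as separate tips unless collapsed beforehand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import pandas as pd

from .alignment_stats import HaplotypeTable
from .barcode_eval import species_sharing
from .errors import SpeciesMapError, TreeError
from .io_formats import SpeciesMap, TreeNode, UltrametricTree


@dataclass
class SpeciesStatus:
    species: str
    n_tips: int
    status: str  # monophyletic | paraphyletic | polyphyletic
    origins: int
    diagnosable: bool | None = None


def read_topology(path: str | None = None, data: str | None = None,
                  format: str = "newick") -> UltrametricTree:
    """Read a rooted topology for classification; branch lengths (and
    ultrametricity) are irrelevant here, so none are required."""
    src = {"data": data} if data is not None else {"path": path}
    dtree = dendropy.Tree.get(schema=format, preserve_underscores=True, **src)

    def rec(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(label=label)
        for child in dnode.child_nodes():
            node.add_child(rec(child))
        return node

    return UltrametricTree(rec(dtree.seed_node))


def min_state_origins(root: TreeNode, in_state: set[str]) -> int:
    """Minimum number of origins of the state "tip label in ``in_state``"
    over all most-parsimonious reconstructions (Fitch-style DP).

    An origin is an edge whose parent lacks the state and whose child has
    it, or the root itself having the state.
    """
    INF = math.inf
    f: dict[int, list[float]] = {}  # node -> [min changes | state 0, | state 1]
    g: dict[int, list[float]] = {}  # min origins among those reconstructions
    for node in root.postorder():
        if node.is_leaf:
            s = 1 if node.label in in_state else 0
            f[id(node)] = [0 if s == 0 else INF, 0 if s == 1 else INF]
            g[id(node)] = [0, 0]
            continue
        fv, gv = [0.0, 0.0], [0.0, 0.0]
        for s in (0, 1):
            for child in node.children:
                costs = [f[id(child)][sc] + (1 if sc != s else 0) for sc in (0, 1)]
                best = min(costs)
                orig = min(
                    g[id(child)][sc] + (1 if (s == 0 and sc == 1) else 0)
                    for sc in (0, 1)
                    if costs[sc] == best
                )
                fv[s] += best
                gv[s] += orig
        f[id(node)], g[id(node)] = fv, gv
    froot, groot = f[id(root)], g[id(root)]
    best = min(froot)
    return int(
        min(groot[s] + (1 if s == 1 else 0) for s in (0, 1) if froot[s] == best)
    )


def _mrca_is_pure(root: TreeNode, tip_set: set[str]) -> bool:
    """True iff the MRCA of ``tip_set`` subtends only ``tip_set`` tips."""
    below: dict[int, int] = {}
    size: dict[int, int] = {}
    target = len(tip_set)
    for node in root.postorder():
        if node.is_leaf:
            below[id(node)] = 1 if node.label in tip_set else 0
            size[id(node)] = 1
        else:
            below[id(node)] = sum(below[id(c)] for c in node.children)
            size[id(node)] = sum(size[id(c)] for c in node.children)
        if below[id(node)] == target:
            return size[id(node)] == target  # first node covering all = MRCA
    raise TreeError("tips not found in tree")


def classify_species(
    tree: UltrametricTree, smap: SpeciesMap
) -> list[SpeciesStatus]:
    """Per-species monophyly / paraphyly / polyphyly on a rooted tree.

    Outgroup tips are pruned first; every remaining tip needs a species
    assignment.  Singleton species are monophyletic by definition.
    """
    labels = tree.tip_labels()
    to_drop = {t for t in labels if t in smap.outgroup_ids}
    if to_drop:
        tree = tree.prune(to_drop)
        labels = tree.tip_labels()
    smap.validate_coverage(labels)
    by_species: dict[str, set[str]] = {}
    for t in labels:
        by_species.setdefault(smap.species_of(t), set()).add(t)

    out = []
    for sp in sorted(by_species):
        tips = by_species[sp]
        if len(tips) == 1 or _mrca_is_pure(tree.root, tips):
            out.append(SpeciesStatus(sp, len(tips), "monophyletic", 1))
            continue
        origins = min_state_origins(tree.root, tips)
        status = "paraphyletic" if origins == 1 else "polyphyletic"
        out.append(SpeciesStatus(sp, len(tips), status, origins))
    return out


def diagnosability(
    statuses: list[SpeciesStatus],
    haps: HaplotypeTable,
    smap: SpeciesMap,
    group_map: dict[str, str] | None = None,
) -> tuple[list[SpeciesStatus], pd.DataFrame]:
    """Fill each species' diagnosable flag (all haplotypes exclusive,
    regardless of topology) and build a per-group summary table:
    individuals/species, haplotypes, monophyletic count (%), diagnosable
    count (%), plus a TOTAL row."""
    sharing = species_sharing(haps, smap)
    for st in statuses:
        if st.species not in sharing:
            raise SpeciesMapError(
                f"species {st.species!r} absent from haplotype table scope"
            )
        st.diagnosable = not sharing[st.species]

    group_map = group_map or {st.species: "all" for st in statuses}
    hap_groups: dict[str, set[str]] = {}
    for hid, members in haps.classes:
        for m in members:
            if m in smap.outgroup_ids:
                continue
            hap_groups.setdefault(hid, set()).add(group_map[smap.species_of(m)])

    rows = []
    groups = sorted(set(group_map.values()))
    for grp in groups + ["TOTAL"]:
        sts = [
            st for st in statuses if grp == "TOTAL" or group_map[st.species] == grp
        ]
        n_ind = sum(st.n_tips for st in sts)
        n_sp = len(sts)
        n_hap = sum(
            1
            for hid, gs in hap_groups.items()
            if grp == "TOTAL" or grp in gs
        )
        mono = sum(1 for st in sts if st.status == "monophyletic")
        diag = sum(1 for st in sts if st.diagnosable)
        rows.append(
            {
                "group": grp,
                "individuals": n_ind,
                "species": n_sp,
                "haplotypes": n_hap,
                "monophyletic": mono,
                "monophyletic_pct": round(100 * mono / n_sp) if n_sp else 0,
                "diagnosable": diag,
                "diagnosable_pct": round(100 * diag / n_sp) if n_sp else 0,
            }
        )
    return statuses, pd.DataFrame(rows)
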