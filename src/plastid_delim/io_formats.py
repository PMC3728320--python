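"""Shared data model and readers/writers for alignments, trees and species maps.

The pipeline works on three containers:

``Alignment``
    Equal-length nucleotide rows with per-locus partition boundaries.
    Partitions are stored 1-based inclusive, matching the NEXUS ``charset``
    convention users edit; internal site arithmetic is 0-based half-open.

``SpeciesMap``
    The hypothesis of species delimitation: tip id -> species label, plus a
    set of outgroup ids that are excluded from ingroup statistics.

``UltrametricTree``
    A rooted tree whose node ages are measured back from the present
    (tips at age 0), e.g. a relaxed-clock chronogram.  This is the input to
    the GMYC machinery.

Parsing of the standard formats is delegated to Biopython (FASTA/NEXUS/
PHYLIP alignments) and DendroPy (newick/NEXUS trees); the containers here
are deliberately small and validated.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

import dendropy
from Bio import AlignIO
from Bio.Nexus import Nexus

from .errors import AlignmentError, SpeciesMapError, TreeError

UNAMBIGUOUS = frozenset("ACGT")
#: IUPAC one-letter codes accepted in alignments.  '?' is normalised to 'N'
#: on input; ambiguity codes are kept but treated as missing by statistics.
VALID_CHARS = frozenset("ACGTUN-RYSWKMBDHV")
MISSING = frozenset("N-RYSWKMBDHV")


@dataclass(frozen=True)
class Partition:
    """A named 1-based inclusive column range (NEXUS charset convention)."""

    name: str
    start: int
    end: int

    def as_slice(self) -> slice:
        """0-based half-open column slice."""
        return slice(self.start - 1, self.end)


@dataclass
class Alignment:
    """An ordered multiple sequence alignment with optional partitions."""

    rows: list[tuple[str, str]]
    partitions: list[Partition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no sequences")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        L = self.length
        for rid, seq in self.rows:
            for pos, ch in enumerate(seq):
                if ch not in VALID_CHARS:
                    raise AlignmentError(
                        f"unknown character {ch!r} in sequence {rid!r} "
                        f"at column {pos + 1}"
                    )
        seen: list[Partition] = []
        for p in self.partitions:
            if not (1 <= p.start <= p.end <= L):
                raise AlignmentError(
                    f"partition {p.name!r} range {p.start}-{p.end} outside "
                    f"alignment of length {L}"
                )
            for q in seen:
                if p.start <= q.end and q.start <= p.end:
                    raise AlignmentError(
                        f"partitions {p.name!r} and {q.name!r} overlap"
                    )
            seen.append(p)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n(self) -> int:
        return len(self.rows)

    def partition(self, name: str) -> Partition:
        for p in self.partitions:
            if p.name == name:
                return p
        raise KeyError(f"no partition named {name!r}")

    def region_slice(self, region: str | Partition | None) -> slice:
        """Resolve a region argument (partition name, Partition or None for
        the whole alignment) to a 0-based column slice."""
        if region is None:
            return slice(0, self.length)
        if isinstance(region, Partition):
            return region.as_slice()
        return self.partition(region).as_slice()

    def subset(
        self,
        ids: list[str] | None = None,
        region: str | Partition | None = None,
    ) -> "Alignment":
        """Row/column subset.  Column subsetting drops partition metadata."""
        sl = self.region_slice(region)
        keep = set(ids) if ids is not None else None
        rows = [
            (rid, seq[sl])
            for rid, seq in self.rows
            if keep is None or rid in keep
        ]
        if keep is not None and len(rows) < len(keep):
            missing = sorted(keep - {r for r, _ in rows})
            raise AlignmentError(f"ids not in alignment: {missing}")
        parts = self.partitions if region is None and ids is not None else []
        return Alignment(rows, list(parts))

    def drop_columns(self, columns_1based: list[tuple[int, int]]) -> "Alignment":
        """Remove 1-based inclusive column ranges (e.g. an exclusion mask for
        an inversion).  Partitions are dropped because coordinates shift."""
        mask = [True] * self.length
        for start, end in columns_1based:
            if not (1 <= start <= end <= self.length):
                raise AlignmentError(f"exclusion range {start}-{end} out of bounds")
            for c in range(start - 1, end):
                mask[c] = False
        rows = [
            (rid, "".join(ch for ch, m in zip(seq, mask) if m))
            for rid, seq in self.rows
        ]
        return Alignment(rows, [])


@dataclass
class SpeciesMap:
    """Tip id -> species label, with an explicit outgroup id set."""

    assignments: dict[str, str]
    outgroup_ids: set[str] = field(default_factory=set)

    def species_of(self, tip_id: str) -> str:
        try:
            return self.assignments[tip_id]
        except KeyError:
            raise SpeciesMapError(f"tip {tip_id!r} has no species assignment")

    def species(self, ingroup_only: bool = True) -> list[str]:
        """Sorted distinct species labels."""
        labels = {
            sp
            for tid, sp in self.assignments.items()
            if not (ingroup_only and tid in self.outgroup_ids)
        }
        return sorted(labels)

    def members(self, species: str, ingroup_only: bool = True) -> list[str]:
        return sorted(
            tid
            for tid, sp in self.assignments.items()
            if sp == species and not (ingroup_only and tid in self.outgroup_ids)
        )

    def validate_coverage(self, tip_ids: list[str]) -> None:
        missing = sorted(
            t
            for t in tip_ids
            if t not in self.assignments and t not in self.outgroup_ids
        )
        if missing:
            raise SpeciesMapError(
                f"{len(missing)} ids lack a species assignment: {missing}"
            )


class TreeNode:
    """Node of an ultrametric tree; ``age`` is time before present."""

    __slots__ = ("label", "age", "parent", "children")

    def __init__(self, label: str | None = None, age: float = 0.0):
        self.label = label
        self.age = age
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def edge_length(self) -> float:
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]


class UltrametricTree:
    """Rooted tree with tips at age 0 and internal node ages > 0."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- basic accessors -------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.root.leaves())

    @property
    def root_age(self) -> float:
        return self.root.age

    def tips(self) -> list[TreeNode]:
        return self.root.leaves()

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.preorder() if not n.is_leaf]

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def validate(self) -> None:
        tol = 1e-9 * max(self.root.age, 1.0)
        for node in self.root.preorder():
            for child in node.children:
                if child.age > node.age + tol:
                    raise TreeError(
                        f"child age {child.age} exceeds parent age {node.age}"
                    )
            if node.is_leaf and abs(node.age) > tol:
                raise TreeError(f"tip {node.label!r} not at age 0 ({node.age})")

    # -- manipulation ----------------------------------------------------
    def copy(self) -> "UltrametricTree":
        def rec(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.age)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return UltrametricTree(rec(self.root))

    def prune(self, drop_labels: set[str]) -> "UltrametricTree":
        """Remove the named tips, suppressing resulting unifurcations."""
        keep = [t for t in self.tip_labels() if t not in set(drop_labels)]
        if len(keep) < 2:
            raise TreeError("pruning would leave fewer than 2 tips")
        keepset = set(keep)

        def rec(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                if node.label in keepset:
                    return TreeNode(node.label, node.age)
                return None
            kids = [rec(c) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            new = TreeNode(node.label, node.age)
            for k in kids:
                new.add_child(k)
            return new

        root = rec(self.root)
        assert root is not None
        return UltrametricTree(root)

    def newick(self, precision: int = 12) -> str:
        """Canonical newick string (branch lengths from age differences)."""

        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                core = _quote_label(node.label or "")
            else:
                inner = ",".join(rec(c) for c in node.children)
                core = f"({inner})" + (
                    _quote_label(node.label) if node.label else ""
                )
            if node.parent is None:
                return core
            return f"{core}:{node.edge_length:.{precision}g}"

        return rec(self.root) + ";"


def _quote_label(label: str) -> str:
    if re.search(r"[\s(),:;\[\]']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Alignment I/O
# ---------------------------------------------------------------------------

def _normalise(seq: str) -> str:
    return seq.upper().replace("?", "N").replace("U", "T")


def read_alignment(path: str, format: str = "fasta") -> Alignment:
    """Read a FASTA / NEXUS / relaxed-PHYLIP alignment.

    Characters are upper-cased and ``?`` is normalised to ``N``.  NEXUS
    ``charset`` statements become partitions.  Ragged rows or unknown
    characters raise :class:`AlignmentError` with a position report.
    """
    fmt = format.lower()
    partitions: list[Partition] = []
    if fmt == "nexus":
        nex = Nexus.Nexus(path)
        rows = [(str(tid), _normalise(str(nex.matrix[tid]))) for tid in nex.taxlabels]
        for name, sites in nex.charsets.items():
            if not sites:
                continue
            start, end = min(sites) + 1, max(sites) + 1
            if sorted(sites) != list(range(start - 1, end)):
                raise AlignmentError(
                    f"charset {name!r} is not a contiguous range"
                )
            partitions.append(Partition(name, start, end))
    elif fmt in ("fasta", "phylip", "phylip-relaxed"):
        bio_fmt = "phylip-relaxed" if fmt.startswith("phylip") else "fasta"
        try:
            msa = AlignIO.read(path, bio_fmt)
        except ValueError as exc:
            raise AlignmentError(f"cannot parse {path}: {exc}") from exc
        rows = [(rec.id, _normalise(str(rec.seq))) for rec in msa]
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    # FASTA with ragged rows does not parse as an MSA; re-check via SeqIO
    if fmt == "fasta":
        from Bio import SeqIO

        raw = list(SeqIO.parse(path, "fasta"))
        if len({len(r.seq) for r in raw}) > 1:
            raise AlignmentError("sequences have unequal lengths")
    return Alignment(rows, partitions)


def write_alignment(aln: Alignment, path: str) -> None:
    """Canonical FASTA writer: one header + one sequence line per row."""
    with open(path, "w") as fh:
        for rid, seq in aln.rows:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Tree I/O
# ---------------------------------------------------------------------------

def tree_from_dendropy(dtree: "dendropy.Tree") -> TreeNode:
    def rec(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = TreeNode(label=label)
        for child in dnode.child_nodes():
            node.add_child(rec(child))
        return node

    root = rec(dtree.seed_node)

    # depths from branch lengths, then ages = max tip depth - depth
    depths: dict[int, float] = {}

    def set_depth(dnode, node, d):
        depths[id(node)] = d
        for dc, c in zip(dnode.child_nodes(), node.children):
            bl = dc.edge.length
            if bl is None:
                raise TreeError("tree has edges without branch lengths")
            set_depth(dc, c, d + bl)

    set_depth(dtree.seed_node, root, 0.0)
    max_depth = max(
        depths[id(n)] for n in root.preorder() if n.is_leaf
    )
    for n in root.preorder():
        n.age = max_depth - depths[id(n)]
    return root


def read_tree(
    path: str,
    format: str = "newick",
    *,
    data: str | None = None,
    tolerance: float | None = None,
    resolve_polytomies: bool = False,
    seed: int = 0,
) -> UltrametricTree:
    """Read a rooted ultrametric tree (chronogram) from newick or NEXUS.

    Parameters
    ----------
    tolerance:
        If ``None`` the tree must be ultrametric to within 1e-9 x root age.
        Otherwise tips whose ages deviate by at most ``tolerance`` x root age
        are clamped to 0; larger deviations still raise :class:`TreeError`.
    resolve_polytomies:
        Replace polytomies (including an unrooted basal trifurcation) by
        zero-length branches, in an order drawn from ``seed``.
    """
    fmt = format.lower()
    if fmt not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format {format!r}")
    src = {"data": data} if data is not None else {"path": path}
    dtree = dendropy.Tree.get(schema=fmt, preserve_underscores=True, **src)
    root = tree_from_dendropy(dtree)

    polytomies = [n for n in root.preorder() if len(n.children) > 2]
    if polytomies:
        if not resolve_polytomies:
            raise TreeError(
                f"tree contains {len(polytomies)} polytomies (it may be "
                "unrooted); pass resolve_polytomies=True to resolve them "
                "with zero-length branches"
            )
        rng = random.Random(seed)
        for node in polytomies:
            kids = list(node.children)
            rng.shuffle(kids)
            while len(kids) > 2:
                a = kids.pop()
                b = kids.pop()
                joint = TreeNode(age=node.age)
                joint.add_child(a)
                joint.add_child(b)
                kids.append(joint)
            node.children = []
            for k in kids:
                node.add_child(k)

    tree = UltrametricTree(root)
    tol = (tolerance if tolerance is not None else 1e-9) * max(tree.root_age, 1e-300)
    bad = [t for t in tree.tips() if abs(t.age) > tol]
    if bad:
        worst = max(abs(t.age) for t in bad)
        raise TreeError(
            f"tree is not ultrametric: {len(bad)} tips deviate from age 0 "
            f"(max deviation {worst:g}); tips at unequal ages"
        )
    for t in tree.tips():
        t.age = 0.0
    tree.validate()
    return tree


def write_tree(tree: UltrametricTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# Species map I/O
# ---------------------------------------------------------------------------

def read_species_map(path: str) -> SpeciesMap:
    """Read a 2-3 column TSV: tip id, species label, optional ``outgroup``."""
    assignments: dict[str, str] = {}
    outgroups: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SpeciesMapError(
                    f"{path}:{lineno}: expected at least 2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            tid, sp = fields[0].strip(), fields[1].strip()
            if tid in assignments:
                raise SpeciesMapError(f"{path}:{lineno}: duplicate tip id {tid!r}")
            assignments[tid] = sp
            if len(fields) >= 3 and fields[2].strip().lower() == "outgroup":
                outgroups.add(tid)
    if not assignments:
        raise SpeciesMapError(f"{path}: species map is empty")
    return SpeciesMap(assignments, outgroups)


def write_species_map(smap: SpeciesMap, path: str) -> None:
    with open(path, "w") as fh:
        for tid in sorted(smap.assignments):
            out = "\toutgroup" if tid in smap.outgroup_ids else ""
            fh.write(f"{tid}\t{smap.assignments[tid]}{out}\n")
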