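"""Per-marker alignment statistics: site classes, diversity, haplotypes, indels.

These reproduce the descriptive statistics a systematist computes per locus
and per taxonomic group before delimitation: counts of constant / variable /
parsimony-informative sites, nucleotide diversity pi, Watterson's theta,
G+C content, haplotype collapsing under a missing-data rule, and gap-event
(indel) detection with simple indel coding.

Conventions (all exposed as flags):

* Site classes default to the parsimony-software convention: gaps, ``N`` and
  IUPAC ambiguity codes are ignored at a site (``gap_policy="missing"``).
* Diversity defaults to DnaSP-style complete deletion: any column containing
  a gap or missing state in any row is dropped before computing S, pi and
  the effective length.
* Ambiguity codes count as missing everywhere (one consistent rule).
* Leading/trailing gap runs are missing data, not indel events.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError
from .io_formats import Alignment, Partition

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP = ord("-")


def _matrix(aln: Alignment, region) -> np.ndarray:
    sl = aln.region_slice(region)
    if sl.stop - sl.start <= 0:
        raise AlignmentError("empty region")
    return np.array(
        [np.frombuffer(seq[sl].encode(), dtype=np.uint8) for _, seq in aln.rows]
    )


def _unambiguous_mask(mat: np.ndarray) -> np.ndarray:
    return np.isin(mat, _BASES)


def _base_counts(mat: np.ndarray) -> np.ndarray:
    """4 x L matrix of A/C/G/T counts per column (missing ignored)."""
    return np.stack([(mat == b).sum(axis=0) for b in _BASES])


# ---------------------------------------------------------------------------
# Site classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteClassCounts:
    constant: int
    variable_uninformative: int
    parsimony_informative: int
    excluded: int

    @property
    def total(self) -> int:
        return (
            self.constant
            + self.variable_uninformative
            + self.parsimony_informative
            + self.excluded
        )

    @property
    def variable(self) -> int:
        return self.variable_uninformative + self.parsimony_informative


def site_classes(
    aln: Alignment,
    region: str | Partition | None = None,
    gap_policy: str = "missing",
) -> SiteClassCounts:
    """Classify every column of ``region`` as constant, variable but
    parsimony-uninformative, parsimony-informative, or excluded.

    A site is variable when at least two distinct unambiguous bases occur;
    parsimony-informative when at least two bases each occur in at least two
    sequences.  Under ``gap_policy="missing"`` non-ACGT states are simply
    ignored at each site; under ``"exclude_site"`` any column containing a
    gap or missing state in any row is counted as excluded.
    """
    if aln.n < 2:
        raise AlignmentError("site classification needs at least 2 sequences")
    mat = _matrix(aln, region)
    L = mat.shape[1]
    counts = _base_counts(mat)
    if gap_policy == "exclude_site":
        excluded_cols = ~_unambiguous_mask(mat).all(axis=0)
    elif gap_policy == "missing":
        excluded_cols = np.zeros(L, dtype=bool)
    else:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    distinct = (counts > 0).sum(axis=0)
    informative = ((counts >= 2).sum(axis=0) >= 2) & ~excluded_cols
    variable = (distinct >= 2) & ~excluded_cols
    n_inf = int(informative.sum())
    n_var_uninf = int((variable & ~informative).sum())
    n_excl = int(excluded_cols.sum())
    return SiteClassCounts(
        constant=L - n_inf - n_var_uninf - n_excl,
        variable_uninformative=n_var_uninf,
        parsimony_informative=n_inf,
        excluded=n_excl,
    )


# ---------------------------------------------------------------------------
# Diversity (pi, Watterson's theta)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityStats:
    S: int
    n: int
    L_eff: int
    a_n: float
    theta_w_site: float
    pi_site: float
    gc: float


def diversity(
    aln: Alignment,
    region: str | Partition | None = None,
    deletion: str = "complete",
) -> DiversityStats:
    """Segregating sites S, per-site Watterson's theta and per-site pi.

    ``deletion="complete"`` drops every column containing a gap/missing
    state in any row first (S, pi and ``L_eff`` all refer to the retained
    columns).  ``deletion="pairwise"`` computes each pair's difference
    proportion over the columns where both members are unambiguous and
    averages those proportions; S and ``L_eff`` then refer to columns with
    at least two unambiguous bases.
    """
    if aln.n < 2:
        raise AlignmentError("diversity needs at least 2 sequences")
    mat = _matrix(aln, region)
    n = mat.shape[0]
    unamb = _unambiguous_mask(mat)
    a_n = float(sum(1.0 / i for i in range(1, n)))
    npairs = n * (n - 1) / 2.0

    if deletion == "complete":
        keep = unamb.all(axis=0)
        L_eff = int(keep.sum())
        if L_eff == 0:
            raise AlignmentError("no analyzable sites after complete deletion")
        sub = mat[:, keep]
        counts = _base_counts(sub)
        S = int(((counts > 0).sum(axis=0) >= 2).sum())
        # per-column pairwise difference count: sum_b c_b (n - c_b) / 2
        diff_total = float((counts * (n - counts)).sum() / 2.0)
        pi_site = diff_total / npairs / L_eff
    elif deletion == "pairwise":
        col_n = unamb.sum(axis=0)
        keep = col_n >= 2
        L_eff = int(keep.sum())
        if L_eff == 0:
            raise AlignmentError("no analyzable sites under pairwise deletion")
        counts = _base_counts(mat[:, keep])
        S = int(((counts > 0).sum(axis=0) >= 2).sum())
        props = []
        for i in range(n):
            for j in range(i + 1, n):
                valid = unamb[i] & unamb[j]
                m = int(valid.sum())
                if m == 0:
                    raise AlignmentError(
                        f"sequence pair ({aln.ids[i]}, {aln.ids[j]}) shares "
                        "no unambiguous sites"
                    )
                d = int(((mat[i] != mat[j]) & valid).sum())
                props.append(d / m)
        pi_site = float(np.mean(props))
    else:
        raise ValueError(f"unknown deletion mode {deletion!r}")

    theta = S / (a_n * L_eff)
    return DiversityStats(
        S=S,
        n=n,
        L_eff=L_eff,
        a_n=a_n,
        theta_w_site=float(theta),
        pi_site=float(pi_site),
        gc=gc_content(aln, region),
    )


def gc_content(aln: Alignment, region: str | Partition | None = None) -> float:
    """(G+C)/(A+C+G+T) over all rows; gaps/missing/ambiguities excluded."""
    mat = _matrix(aln, region)
    counts = _base_counts(mat)
    total = counts.sum()
    if total == 0:
        raise AlignmentError("no unambiguous bases in region")
    gc = counts[1].sum() + counts[2].sum()  # C, G rows of _BASES order
    return float(gc / total)


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTable:
    """Partition of sequence ids into identity classes."""

    classes: list[tuple[str, list[str]]]
    policy: str

    @property
    def n_haplotypes(self) -> int:
        return len(self.classes)

    def class_of(self) -> dict[str, str]:
        return {m: hid for hid, members in self.classes for m in members}


def collapse_haplotypes(
    aln: Alignment,
    region: str | Partition | None = None,
    identity: str = "distance_zero",
) -> HaplotypeTable:
    """Group sequences into haplotype classes.

    ``identity="strict"`` is byte equality after normalisation.
    ``identity="distance_zero"`` merges two sequences whenever no column
    exists at which both carry differing unambiguous bases (the PAUP-style
    "pairwise distance zero" de-duplication with missing data), closed
    transitively by single linkage.
    """
    mat = _matrix(aln, region)
    ids = aln.ids
    n = len(ids)
    if identity == "strict":
        groups: dict[bytes, list[int]] = {}
        for i in range(n):
            groups.setdefault(mat[i].tobytes(), []).append(i)
        members = sorted(groups.values(), key=lambda g: g[0])
    elif identity == "distance_zero":
        unamb = _unambiguous_mask(mat)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if find(i) == find(j):
                    continue
                both = unamb[i] & unamb[j]
                if not ((mat[i] != mat[j]) & both).any():
                    parent[find(j)] = find(i)
        groups2: dict[int, list[int]] = {}
        for i in range(n):
            groups2.setdefault(find(i), []).append(i)
        members = sorted(groups2.values(), key=lambda g: g[0])
    else:
        raise ValueError(f"unknown identity rule {identity!r}")
    classes = [
        (f"H{k + 1}", [ids[i] for i in idx]) for k, idx in enumerate(members)
    ]
    return HaplotypeTable(classes=classes, policy=identity)


# ---------------------------------------------------------------------------
# Indels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelEvent:
    """A shared gap event: identical maximal gap run [start, end] (1-based,
    inclusive, whole-alignment coordinates) across its member rows."""

    start: int
    end: int
    members: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal '-' runs as 0-based half-open (start, end) pairs."""
    return [(m.start(), m.end()) for m in re.finditer(r"-+", seq)]


def detect_indels(
    aln: Alignment, region: str | Partition | None = None
) -> list[IndelEvent]:
    """Find shared internal gap events.

    Each maximal gap run per row is a candidate; candidates with identical
    (start, end) merge into one event.  Runs touching the region's ends are
    leading/trailing missing data, never indels.
    """
    sl = aln.region_slice(region)
    width = sl.stop - sl.start
    if width <= 0:
        raise AlignmentError("empty region")
    events: dict[tuple[int, int], list[str]] = {}
    for rid, seq in aln.rows:
        sub = seq[sl]
        for s, e in _gap_runs(sub):
            if s == 0 or e == width:
                continue  # touches a row end: missing data
            key = (sl.start + s + 1, sl.start + e)  # 1-based inclusive
            events.setdefault(key, []).append(rid)
    return [
        IndelEvent(start=k[0], end=k[1], members=tuple(v))
        for k, v in sorted(events.items())
    ]


@dataclass
class IndelCoding:
    """Simple indel coding: one binary character per gap event.

    ``matrix[tip_id]`` is a string over {'1','0','-'}, one position per
    event in ``events`` order: 1 = gapped exactly over the event span,
    0 = fully nucleotide over the span, '-' = inapplicable/missing (the
    row's gap strictly contains the event, partially overlaps it, or the
    span contains missing data).
    """

    events: list[IndelEvent]
    matrix: dict[str, str] = field(default_factory=dict)


def simple_indel_coding(
    aln: Alignment, region: str | Partition | None = None
) -> IndelCoding:
    """Code each detected gap event as a presence/absence character."""
    sl = aln.region_slice(region)
    events = detect_indels(aln, region)
    matrix: dict[str, str] = {}
    for rid, seq in aln.rows:
        sub = seq[sl]
        runs = {(sl.start + s + 1, sl.start + e) for s, e in _gap_runs(sub)}
        states = []
        for ev in events:
            span = seq[ev.start - 1 : ev.end]
            if (ev.start, ev.end) in runs:
                states.append("1")
            elif all(ch in "ACGT" for ch in span):
                states.append("0")
            else:
                states.append("-")
        matrix[rid] = "".join(states)
    return IndelCoding(events=events, matrix=matrix)
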