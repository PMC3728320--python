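"""DNA-barcode discrimination: which species have exclusive haplotypes?

A species is *discriminated* (diagnosable) by a marker when every haplotype
class containing one of its sequences contains only its sequences — i.e.
none of its haplotypes is shared with another species.  This is stricter
than owning one private haplotype and matches how diagnosability is tallied
in barcoding assessments of closely related species.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment_stats import HaplotypeTable
from .errors import AlignmentError, SpeciesMapError
from .io_formats import Alignment, Partition, SpeciesMap


@dataclass
class DiscriminationReport:
    marker: str
    n_haplotypes: int
    species_status: dict[str, str]  # species -> "diagnosable" | "shared"
    discriminated: int
    n_species: int

    @property
    def fraction(self) -> float:
        return self.discriminated / self.n_species


def species_sharing(
    haps: HaplotypeTable, smap: SpeciesMap
) -> dict[str, set[str]]:
    """For each ingroup species, the set of *other* species it shares at
    least one haplotype class with (empty set = diagnosable)."""
    sharing: dict[str, set[str]] = {sp: set() for sp in smap.species()}
    for _, members in haps.classes:
        ingroup = [m for m in members if m not in smap.outgroup_ids]
        sps = {smap.species_of(m) for m in ingroup}
        if len(sps) > 1:
            for sp in sps:
                sharing[sp].update(sps - {sp})
    return sharing


def marker_discrimination(
    haps: HaplotypeTable, smap: SpeciesMap, marker: str = ""
) -> DiscriminationReport:
    """Count the species whose haplotypes are all exclusive to them.

    Outgroup sequences are dropped from both the classes and the species
    denominator.  Every remaining sequence id must have an assignment.
    """
    for _, members in haps.classes:
        for m in members:
            if m not in smap.assignments and m not in smap.outgroup_ids:
                raise SpeciesMapError(f"sequence {m!r} has no species assignment")
    sharing = species_sharing(haps, smap)
    status = {
        sp: ("diagnosable" if not shared else "shared")
        for sp, shared in sharing.items()
    }
    n_ingroup_classes = sum(
        1
        for _, members in haps.classes
        if any(m not in smap.outgroup_ids for m in members)
    )
    discriminated = sum(1 for v in status.values() if v == "diagnosable")
    return DiscriminationReport(
        marker=marker,
        n_haplotypes=n_ingroup_classes,
        species_status=status,
        discriminated=discriminated,
        n_species=len(status),
    )


def concatenate(alns: list[Alignment], names: list[str] | None = None) -> Alignment:
    """Column-wise concatenation over an identical id set.

    Rows follow the first alignment's order; one partition is recorded per
    source (named by ``names`` or the source's index).
    """
    if not alns:
        raise AlignmentError("nothing to concatenate")
    base_ids = alns[0].ids
    base_set = set(base_ids)
    for k, a in enumerate(alns[1:], 2):
        other = set(a.ids)
        if other != base_set:
            diff = sorted(base_set.symmetric_difference(other))
            raise AlignmentError(
                f"alignment {k} id set differs from the first; "
                f"symmetric difference: {diff}"
            )
    names = names or [f"part{k + 1}" for k in range(len(alns))]
    seqs = {rid: [] for rid in base_ids}
    partitions = []
    offset = 0
    for name, a in zip(names, alns):
        lookup = dict(a.rows)
        for rid in base_ids:
            seqs[rid].append(lookup[rid])
        partitions.append(Partition(name, offset + 1, offset + a.length))
        offset += a.length
    rows = [(rid, "".join(seqs[rid])) for rid in base_ids]
    return Alignment(rows, partitions)


@dataclass
class GroupAssignmentReport:
    marker: str
    group_diagnostic: bool
    offending_classes: list[tuple[str, set[str]]]  # haplotype id -> groups spanned


def subsection_assignment(
    haps: HaplotypeTable,
    smap: SpeciesMap,
    group_map: dict[str, str],
    marker: str = "",
) -> GroupAssignmentReport:
    """Flag a marker group-diagnostic iff no haplotype class spans two
    higher-level groups (e.g. *Pinus* subsections).  ``group_map`` must
    cover every ingroup species."""
    for sp in smap.species():
        if sp not in group_map:
            raise SpeciesMapError(f"species {sp!r} missing from group map")
    offending = []
    for hid, members in haps.classes:
        groups = {
            group_map[smap.species_of(m)]
            for m in members
            if m not in smap.outgroup_ids
        }
        if len(groups) > 1:
            offending.append((hid, groups))
    return GroupAssignmentReport(
        marker=marker,
        group_diagnostic=not offending,
        offending_classes=offending,
    )
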