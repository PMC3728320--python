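"""End-to-end orchestration: stats -> barcode -> tree status -> GMYC.

A single plain-text config (YAML mapping) drives everything so that every
convention-sensitive choice (gap policy, deletion mode, haplotype identity,
LR test df, AICc cutoff, probability thresholds, seed) is auditable.  Every
report is regenerated from the inputs on each run; the config is embedded
verbatim in the run log.
"""

from __future__ import annotations

import json
import math
import os
import sys
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import __version__, alignment_stats, barcode_eval, gmyc, species_status
from .errors import InputError
from .io_formats import (
    Alignment,
    SpeciesMap,
    UltrametricTree,
    read_alignment,
    read_species_map,
    read_tree,
)

DEFAULTS: dict[str, Any] = {
    "gap_policy": "missing",
    "deletion": "complete",
    "haplotype_identity": "distance_zero",
    "df": 2,
    "aicc_cutoff": 7.0,
    "prob_thresholds": [0.95, 0.50],
    "seed": 1,
    "gmyc_starts": 10,
    "make_plots": False,
}


@dataclass
class RunConfig:
    """Validated run settings; unknown keys are rejected."""

    alignment: str
    species_map: str
    tree: str | None = None
    alignment_format: str = "fasta"
    tree_format: str = "newick"
    exclusion_mask: list[tuple[int, int]] = field(default_factory=list)
    group_map: dict[str, str] = field(default_factory=dict)
    gap_policy: str = DEFAULTS["gap_policy"]
    deletion: str = DEFAULTS["deletion"]
    haplotype_identity: str = DEFAULTS["haplotype_identity"]
    df: int = DEFAULTS["df"]
    aicc_cutoff: float = DEFAULTS["aicc_cutoff"]
    prob_thresholds: list[float] = field(
        default_factory=lambda: list(DEFAULTS["prob_thresholds"])
    )
    seed: int = DEFAULTS["seed"]
    gmyc_starts: int = DEFAULTS["gmyc_starts"]
    make_plots: bool = DEFAULTS["make_plots"]
    out_dir: str = "plastid_delim_out"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "exclusion_mask" in raw:
            raw["exclusion_mask"] = [tuple(r) for r in raw["exclusion_mask"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["exclusion_mask"] = [list(r) for r in self.exclusion_mask]
        return d


def _markers(aln: Alignment) -> list[tuple[str, Any]]:
    if aln.partitions:
        return [(p.name, p) for p in aln.partitions]
    return [("whole", None)]


def stats_report(
    aln: Alignment, smap: SpeciesMap, config: RunConfig
) -> pd.DataFrame:
    """Per-marker x per-group statistics table (groups = subsections from
    the config group map, plus the whole ingroup)."""
    ingroup_ids = [i for i in aln.ids if i not in smap.outgroup_ids]
    group_rows: list[tuple[str, list[str]]] = []
    if config.group_map:
        for grp in sorted(set(config.group_map.values())):
            ids = [
                i
                for i in ingroup_ids
                if config.group_map.get(smap.species_of(i)) == grp
            ]
            if len(ids) >= 2:
                group_rows.append((grp, ids))
    group_rows.append(("ingroup", ingroup_ids))

    records = []
    for marker, region in _markers(aln):
        for grp, ids in group_rows:
            sub = aln.subset(ids=ids, region=region)
            sc = alignment_stats.site_classes(sub, gap_policy=config.gap_policy)
            div = alignment_stats.diversity(sub, deletion=config.deletion)
            haps = alignment_stats.collapse_haplotypes(
                sub, identity=config.haplotype_identity
            )
            indels = alignment_stats.detect_indels(sub)
            records.append(
                {
                    "marker": marker,
                    "group": grp,
                    "n_sequences": sub.n,
                    "length": sub.length,
                    "gc": round(div.gc, 4),
                    "variable_uninformative": sc.variable_uninformative,
                    "parsimony_informative": sc.parsimony_informative,
                    "S": div.S,
                    "theta_w_site": round(div.theta_w_site, 6),
                    "pi_site": round(div.pi_site, 6),
                    "n_haplotypes": haps.n_haplotypes,
                    "n_indel_events": len(indels),
                }
            )
    return pd.DataFrame(records)


def barcode_report(
    aln: Alignment, smap: SpeciesMap, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species-discrimination tables: one row per (marker, species) with
    its status, and one summary row per marker (including the full
    concatenation and, if a group map is present, group diagnosability)."""
    summaries = []
    per_species = []
    markers = _markers(aln)
    for marker, region in [(m, r) for m, r in markers] + (
        [("concatenated", None)] if len(markers) > 1 else []
    ):
        haps = alignment_stats.collapse_haplotypes(
            aln.subset(region=region), identity=config.haplotype_identity
        )
        rep = barcode_eval.marker_discrimination(haps, smap, marker=marker)
        rec = {
            "marker": marker,
            "n_haplotypes": rep.n_haplotypes,
            "discriminated": rep.discriminated,
            "n_species": rep.n_species,
            "fraction": round(rep.fraction, 4),
        }
        if config.group_map:
            grp = barcode_eval.subsection_assignment(
                haps, smap, config.group_map, marker=marker
            )
            rec["group_diagnostic"] = grp.group_diagnostic
        summaries.append(rec)
        for sp, status in sorted(rep.species_status.items()):
            per_species.append(
                {"marker": marker, "species": sp, "status": status}
            )
    return pd.DataFrame(summaries), pd.DataFrame(per_species)


def gmyc_report(
    tree: UltrametricTree, smap: SpeciesMap, config: RunConfig
) -> dict:
    """Null / single / multiple threshold fits, LR tests, AICc averaging
    and probability-threshold entity counts, as one JSON-serialisable
    record."""
    drop = {t for t in tree.tip_labels() if t in smap.outgroup_ids}
    if drop:
        tree = tree.prune(drop)
    null, singles = gmyc.candidate_single_threshold_fits(
        tree, n_starts=config.gmyc_starts
    )
    best_single = max(singles, key=lambda f: f.logL)
    multiple = gmyc.fit_multiple_threshold(
        tree, seed=config.seed, start=best_single,
        n_starts=max(2, config.gmyc_starts // 2),
    )
    lr_single = gmyc.lr_test(null.logL, best_single.logL, df=config.df)
    lr_multiple = gmyc.lr_test(best_single.logL, multiple.logL, df=config.df)
    report: dict[str, Any] = {
        "null": null.summary(),
        "single": best_single.summary(),
        "multiple": multiple.summary(),
        "lr_single_vs_null": {"ratio": lr_single[0], "p": lr_single[1]},
        "lr_multiple_vs_single": {"ratio": lr_multiple[0], "p": lr_multiple[1]},
        "single_entity_ci_2logL": list(
            gmyc.entity_confidence_interval(singles)
        ),
        "ages_perturbed": gmyc.branching_intervals(tree).perturbed,
        "candidate_set": "null + all single-threshold models",
    }
    try:
        mm = gmyc.multimodel_average(
            [null] + singles, tree.tip_labels(), cutoff=config.aicc_cutoff
        )
        report["multimodel"] = {
            "cutoff": config.aicc_cutoff,
            "n_candidates": mm.n_candidates,
            "n_retained": len(mm.fits),
            "mean_clusters": mm.mean_clusters,
            "var_clusters": mm.var_clusters,
            "mean_entities": mm.mean_entities,
            "var_entities": mm.var_entities,
        }
        for thr in config.prob_thresholds:
            clusters, singletons = gmyc.entities_at_probability(mm, tree, thr)
            report["multimodel"][f"entities_at_p{thr:g}"] = (
                len(clusters) + len(singletons)
            )
    except gmyc.NumericalError as exc:
        report["multimodel"] = {"error": str(exc)}
    report["ltt"] = gmyc.ltt(tree)
    return report


def run_all(config: RunConfig) -> dict[str, str]:
    """Run every applicable stage; returns {stage: output path}.

    Stage order: stats, barcode, species status (needs a tree), GMYC
    (needs a tree).  Any stage error aborts with the stage name; outputs
    of completed stages are preserved.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    log_lines = [
        f"plastid-delim {__version__} (python {sys.version.split()[0]})",
        "config:",
        yaml.safe_dump(config.to_dict(), sort_keys=True).rstrip(),
    ]
    stage = "load"
    try:
        aln = read_alignment(config.alignment, config.alignment_format)
        if config.exclusion_mask:
            aln_masked = aln.drop_columns(list(config.exclusion_mask))
            log_lines.append(
                f"exclusion mask applied: {config.exclusion_mask} "
                "(whole-matrix statistics only; partitions keep original "
                "coordinates)"
            )
        else:
            aln_masked = aln
        smap = read_species_map(config.species_map)
        smap.validate_coverage(aln.ids)
        tree = None
        if config.tree:
            tree = read_tree(config.tree, config.tree_format)

        stage = "stats"
        stats = stats_report(aln, smap, config)
        path = os.path.join(config.out_dir, "stats.tsv")
        stats.to_csv(path, sep="\t", index=False)
        outputs["stats"] = path

        stage = "barcode"
        bar, bar_species = barcode_report(aln, smap, config)
        path = os.path.join(config.out_dir, "barcode.tsv")
        bar.to_csv(path, sep="\t", index=False)
        bar_species.to_csv(
            os.path.join(config.out_dir, "barcode_species.tsv"),
            sep="\t",
            index=False,
        )
        outputs["barcode"] = path

        if tree is not None:
            stage = "status"
            statuses = species_status.classify_species(tree, smap)
            haps = alignment_stats.collapse_haplotypes(
                aln_masked, identity=config.haplotype_identity
            )
            statuses, summary = species_status.diagnosability(
                statuses, haps, smap, config.group_map or None
            )
            path = os.path.join(config.out_dir, "species_status.tsv")
            pd.DataFrame([vars(s) for s in statuses]).to_csv(
                path, sep="\t", index=False
            )
            summary.to_csv(
                os.path.join(config.out_dir, "status_summary.tsv"),
                sep="\t",
                index=False,
            )
            outputs["status"] = path

            stage = "gmyc"
            report = gmyc_report(tree, smap, config)
            path = os.path.join(config.out_dir, "gmyc.json")
            with open(path, "w") as fh:
                json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
            outputs["gmyc"] = path
            ltt_path = os.path.join(config.out_dir, "ltt.tsv")
            pd.DataFrame(report["ltt"], columns=["age", "lineages"]).to_csv(
                ltt_path, sep="\t", index=False
            )
            outputs["ltt"] = ltt_path
            if config.make_plots:
                drop = {
                    t for t in tree.tip_labels() if t in smap.outgroup_ids
                }
                gmyc.ltt_plot(
                    tree.prune(drop) if drop else tree,
                    os.path.join(config.out_dir, "ltt.png"),
                )
        else:
            log_lines.append("no tree in config: status and GMYC stages skipped")
    except Exception:
        log_lines.append(f"ABORTED in stage: {stage}")
        _write_log(config, log_lines)
        raise InputError(f"pipeline failed in stage {stage!r}") from sys.exc_info()[1]

    log_lines.append(f"stages completed: {sorted(outputs)}")
    _write_log(config, log_lines)
    outputs["log"] = os.path.join(config.out_dir, "run.log")
    return outputs


def _write_log(config: RunConfig, lines: list[str]) -> None:
    with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else repr(obj)
    return obj
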