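"""End-to-end pipeline runs with versioned, reproducible report bundles.

Stages: qc -> haplotypes -> twopoint -> map -> genome-length -> synteny ->
stepping-stone; any prefix is selectable.  Every threshold, input path and
seed is echoed into the run report so a run can be reproduced from the
report alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .genome_length import Karyotype, SOLE_KARYOTYPE, estimate_genome_length
from .genotypes import apply_qc, read_genotypes
from .haplotypes import combine_contigs
from .linkage import GeneticMap, build_map, twopoint_table, FamilySet
from .stepping_stone import BridgeTable, bridge
from .synteny import (
    SyntenyScheme,
    assign_chromosomes,
    oxford_grid,
    read_hits_tabular,
    syntenic_regions,
)

STAGES = ("qc", "haplotypes", "twopoint", "map", "genomelen", "synteny", "bridge")


class StageDependencyError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run (defaults = the
    published analysis settings)."""

    genotypes: str | None = None
    hits: dict[str, str] = field(default_factory=dict)  # species -> path
    scheme: str | None = None
    bridge_table: str | None = None
    outdir: str = "solemap_run"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    max_missing_individual: float = 0.30
    max_missing_marker: float = 0.30
    min_recombinants: int = 1
    lod_group: float = 8.0
    lod_pool: float = 4.0
    lod_weak: float = 0.5
    majority: float = 0.5
    flips_window: int = 5
    e_max: float = 1e-10
    min_shared: int = 2
    min_support: int = 2
    haploid_n: int = SOLE_KARYOTYPE.haploid_n
    n_acrocentric: int = SOLE_KARYOTYPE.n_acrocentric
    max_gap_cm: float = SOLE_KARYOTYPE.max_gap_cm

    @property
    def karyotype(self) -> Karyotype:
        return Karyotype(self.haploid_n, self.n_acrocentric, self.max_gap_cm)


def _write_map(gmap: GeneticMap, path: Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("group\trank\tposition_cm\tmarker\tcontig\n")
        for g in gmap.groups:
            for rank, (m, pos) in enumerate(zip(g.marker_ids, g.positions), start=1):
                contig = gmap.contig_of.get(m) or "-"
                fh.write(f"{g.group_id}\t{rank}\t{pos:.3f}\t{m}\t{contig}\n")
        for m in gmap.unmapped:
            fh.write(f"-\t-\t-\t{m}\t{gmap.contig_of.get(m) or '-'}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stage prefix and write the report bundle.

    Returns a dict of in-memory artifacts keyed by stage name.  Identical
    config + inputs produce byte-identical outputs.
    """
    stages = list(config.stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    report: dict = {
        "solemap_version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "stages_run": [],
    }

    markers = families = None
    if any(s in stages for s in ("qc", "haplotypes", "twopoint", "map")):
        if config.genotypes is None:
            raise StageDependencyError("stage qc requires a genotype table path")
        markers, families = read_genotypes(config.genotypes)

    if "qc" in stages:
        markers, families, qc = apply_qc(
            markers, families,
            config.max_missing_individual, config.max_missing_marker,
        )
        artifacts["qc"] = qc
        with open(outdir / "qc_report.json", "wt", encoding="utf-8") as fh:
            json.dump(
                {
                    "excluded_individuals": qc.excluded_individuals,
                    "excluded_markers": qc.excluded_markers,
                    "informative": qc.informative,
                    "notes": qc.notes,
                },
                fh, indent=2, sort_keys=True,
            )
        report["stages_run"].append("qc")

    if "haplotypes" in stages:
        if markers is None:
            raise StageDependencyError("stage haplotypes requires qc genotypes")
        markers, families, comb_log = combine_contigs(
            markers, families, config.min_recombinants
        )
        artifacts["haplotypes"] = comb_log
        with open(outdir / "combination_log.tsv", "wt", encoding="utf-8") as fh:
            fh.write("contig\tn_snps\tstatus\tevidence_offspring\n")
            for rec in comb_log:
                fh.write(rec.as_row() + "\n")
        report["stages_run"].append("haplotypes")

    tp = None
    if "twopoint" in stages or "map" in stages:
        if markers is None:
            raise StageDependencyError("stage twopoint requires genotypes")
        fs = FamilySet(markers, families)
        tp = twopoint_table(markers, families, fs=fs)
        artifacts["twopoint"] = tp
        if "twopoint" in stages:
            with open(outdir / "twopoint.tsv", "wt", encoding="utf-8") as fh:
                fh.write("marker_a\tmarker_b\tr_hat\tlod\tn_informative\n")
                L = len(tp.ids)
                for i in range(L):
                    for j in range(i + 1, L):
                        if tp.n[i, j] > 0:
                            fh.write(
                                f"{tp.ids[i]}\t{tp.ids[j]}\t{tp.r[i, j]:.6f}\t"
                                f"{tp.lod[i, j]:.4f}\t{tp.n[i, j]}\n"
                            )
            report["stages_run"].append("twopoint")

    gmap = None
    if "map" in stages:
        gmap = build_map(
            markers, families,
            lod_group=config.lod_group, lod_pool=config.lod_pool,
            lod_weak=config.lod_weak, majority=config.majority,
            flips_window=config.flips_window, tp=tp,
        )
        artifacts["map"] = gmap
        _write_map(gmap, outdir / "map.tsv")
        report["stages_run"].append("map")
        report["map_stats"] = asdict(gmap.stats)

    if "genomelen" in stages:
        if gmap is None:
            raise StageDependencyError("stage genomelen requires the map stage")
        table = [(g.length_cm, g.n_markers) for g in gmap.groups]
        est = estimate_genome_length(table, config.karyotype, gmap.stats.d_av_cm)
        artifacts["genomelen"] = est
        with open(outdir / "genome_length.json", "wt", encoding="utf-8") as fh:
            json.dump(
                {**asdict(est), "d_av_cm": gmap.stats.d_av_cm,
                 "total_length_cm": gmap.stats.total_length_cm,
                 "n_groups": len(gmap.groups)},
                fh, indent=2, sort_keys=True,
            )
        report["stages_run"].append("genomelen")

    assignments = None
    if "synteny" in stages:
        if gmap is None:
            raise StageDependencyError("stage synteny requires the map stage")
        if not config.hits or config.scheme is None:
            raise StageDependencyError(
                "stage synteny requires hit tables and a scheme config"
            )
        hits = {
            sp: read_hits_tabular(path, sp, config.e_max)
            for sp, path in sorted(config.hits.items())
        }
        scheme = SyntenyScheme.from_yaml(config.scheme)
        grid = oxford_grid(gmap, hits)
        regions, region_summary = syntenic_regions(gmap, hits, config.min_shared)
        result = assign_chromosomes(grid, scheme, config.karyotype)
        artifacts["synteny"] = (grid, regions, result)
        grid.counts.to_csv(outdir / "oxford_grid.tsv", sep="\t")
        region_summary.to_csv(outdir / "syntenic_regions_summary.tsv",
                              sep="\t", index=False)
        with open(outdir / "assignments.tsv", "wt", encoding="utf-8") as fh:
            fh.write("putative_chromosome\tprimary_lg\tmerged_lgs\tlabels\t"
                     "fusion\thomologs\n")
            for a in result.assignments:
                homs = ";".join(
                    f"{sp}:{','.join(chroms)}"
                    for sp, chroms in sorted(a.homolog_chromosomes.items())
                )
                fh.write(
                    f"{a.putative_chromosome_id}\t{a.primary_lg}\t"
                    f"{','.join(a.merged_lgs) or '-'}\t"
                    f"{','.join(a.synteny_labels)}\t"
                    f"{'yes' if a.is_fusion else 'no'}\t{homs}\n"
                )
        assignments = result.assignments
        report["stages_run"].append("synteny")

    if "bridge" in stages:
        if assignments is None:
            raise StageDependencyError("stage bridge requires the synteny stage")
        if config.bridge_table is None:
            raise StageDependencyError("stage bridge requires a bridge table config")
        bt = BridgeTable.from_yaml(config.bridge_table)
        res = bridge(assignments, bt, config.min_support)
        artifacts["bridge"] = res
        with open(outdir / "bridge.tsv", "wt", encoding="utf-8") as fh:
            fh.write("putative_chromosome\tprimary_lg\thomologs\tsupport\tnote\n")
            for e in res.entries:
                supp = ";".join(f"{lg}:{v}" for lg, v in e.support.items())
                fh.write(
                    f"{e.putative_chromosome_id}\t{e.primary_lg}\t"
                    f"{','.join(e.homologs) or '-'}\t{supp or '-'}\t{e.note or '-'}\n"
                )
        report["stages_run"].append("bridge")

    with open(outdir / "run_report.json", "wt", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    artifacts["report"] = report
    return artifacts
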