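"""Comparative mapping: Oxford grids, conserved synteny and chromosome
assignment of linkage groups.

EST contigs underlying the mapped markers are aligned against the genomes of
sequenced model species; the resulting hit tables (BLAST tabular, outfmt 6)
are reduced to the best hit per (contig, species, chromosome).  Counting
distinct contigs per (linkage group, chromosome) yields an Oxford grid, from
which conserved syntenic regions (>=2 shared contigs, order-agnostic) are
read off.  Chromosomes of the model species are organised into synteny
groups: A-groups with one-to-one relationships across species and B-groups
involving inter-chromosomal rearrangements.  Each group label votes for the
linkage group that dominates its member chromosomes; the winners become
putative chromosomes, linkage groups winning two A-labels are flagged as
fusions, and leftover (surplus) linkage groups whose hits all fall inside a
single label are folded into that label's putative chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .genome_length import Karyotype
from .linkage import GeneticMap

__all__ = [
    "HomologyHit",
    "SyntenyScheme",
    "OxfordGrid",
    "SyntenicRegion",
    "ChromosomeAssignment",
    "AssignmentResult",
    "HitTableError",
    "read_hits_tabular",
    "oxford_grid",
    "syntenic_regions",
    "assign_chromosomes",
]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class HitTableError(ValueError):
    """Raised for malformed BLAST tabular input."""


@dataclass(frozen=True)
class HomologyHit:
    contig_id: str
    species: str
    chromosome: str
    subject_start: int  # 1-based inclusive, normalized start <= end
    subject_end: int
    strand: str         # '+' or '-'
    e_value: float
    bit_score: float


@dataclass
class SyntenyScheme:
    """A/B synteny-group labels -> member chromosome per species.

    A-labels map exactly one chromosome per listed species; B-(sub)labels may
    share chromosomes across sublabels (rearranged blocks).
    """

    labels: dict[str, dict[str, str]]

    def species(self) -> list[str]:
        out: list[str] = []
        for members in self.labels.values():
            for sp in members:
                if sp not in out:
                    out.append(sp)
        return sorted(out)

    def labels_of(self, species: str, chromosome: str) -> list[str]:
        return sorted(
            lab for lab, members in self.labels.items()
            if members.get(species) == chromosome
        )

    @classmethod
    def from_yaml(cls, path) -> "SyntenyScheme":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(labels={str(k): dict(v) for k, v in data["labels"].items()})

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump({"labels": self.labels}, fh, sort_keys=True)


def read_hits_tabular(path, species: str, e_max: float = 1e-10) -> list[HomologyHit]:
    """Read a 12-column BLAST tabular (outfmt 6) hit table for one species.

    Hits with e-value >= ``e_max`` are discarded (strict inequality retains);
    per (contig, chromosome) only the best hit is kept (highest bit score,
    then lowest e-value, then lowest subject start).  Minus-strand hits
    (sstart > send) are normalized, retaining the strand.
    """
    rows: list[HomologyHit] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitTableError(
                    f"line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                sstart, send = int(fields[8]), int(fields[9])
                evalue, bitscore = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise HitTableError(f"line {lineno}: {exc}") from exc
            if evalue >= e_max:
                continue
            strand = "+" if sstart <= send else "-"
            rows.append(
                HomologyHit(
                    contig_id=fields[0], species=species, chromosome=fields[1],
                    subject_start=min(sstart, send),
                    subject_end=max(sstart, send),
                    strand=strand, e_value=evalue, bit_score=bitscore,
                )
            )
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in rows:
        key = (h.contig_id, h.chromosome)
        cur = best.get(key)
        if cur is None or (-h.bit_score, h.e_value, h.subject_start) < \
                (-cur.bit_score, cur.e_value, cur.subject_start):
            best[key] = h
    return [best[k] for k in sorted(best)]


@dataclass
class OxfordGrid:
    """Distinct-contig counts per (linkage group, species chromosome).

    ``counts`` counts a contig once per chromosome it hits (multi-chromosome
    contigs are flagged as potential paralogs); ``best_counts`` counts only
    each contig's single best hit per species (highest bit score) and is the
    basis for surplus-group merging decisions, where weaker paralog hits
    would otherwise scatter the evidence.
    """

    counts: pd.DataFrame  # index: lg; columns: MultiIndex (species, chromosome)
    best_counts: pd.DataFrame = None
    #: contigs hitting >1 chromosome of one species (potential paralogs)
    paralog_flags: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def count(self, lg: str, species: str, chromosome: str) -> int:
        try:
            return int(self.counts.loc[lg, (species, chromosome)])
        except KeyError:
            return 0


def _contig_to_lg(gmap: GeneticMap) -> dict[str, str]:
    out: dict[str, str] = {}
    for g in gmap.groups:
        for m in g.marker_ids:
            contig = gmap.contig_of.get(m)
            if contig is not None:
                out[contig] = g.group_id
    return out


def oxford_grid(gmap: GeneticMap, hits_by_species: dict[str, list[HomologyHit]]) -> OxfordGrid:
    """Build the Oxford grid from per-species hit lists.

    Contigs are counted once per (lg, species, chromosome); a contig with
    retained hits on several chromosomes of one species is counted once per
    chromosome and flagged as a potential paralog.
    """
    lg_of = _contig_to_lg(gmap)
    cells: dict[tuple[str, str, str], set[str]] = {}
    best_cells: dict[tuple[str, str, str], set[str]] = {}
    per_contig: dict[tuple[str, str], set[str]] = {}
    best_hit: dict[tuple[str, str], HomologyHit] = {}
    for species, hits in hits_by_species.items():
        for h in hits:
            lg = lg_of.get(h.contig_id)
            if lg is None:
                continue
            cells.setdefault((lg, species, h.chromosome), set()).add(h.contig_id)
            per_contig.setdefault((species, h.contig_id), set()).add(h.chromosome)
            key = (species, h.contig_id)
            cur = best_hit.get(key)
            if cur is None or (-h.bit_score, h.e_value, h.chromosome) < \
                    (-cur.bit_score, cur.e_value, cur.chromosome):
                best_hit[key] = h
    for (species, contig), h in best_hit.items():
        best_cells.setdefault((lg_of[contig], species, h.chromosome), set()).add(contig)
    paralogs = {
        key: sorted(chroms)
        for key, chroms in per_contig.items() if len(chroms) > 1
    }

    def _frame(cell_map):
        if not cells:
            return pd.DataFrame(
                index=pd.Index([]),
                columns=pd.MultiIndex.from_tuples([], names=["species", "chromosome"]),
            )
        index = sorted({lg for lg, _, _ in cells})
        columns = pd.MultiIndex.from_tuples(
            sorted({(sp, ch) for _, sp, ch in cells}),
            names=["species", "chromosome"],
        )
        frame = pd.DataFrame(0, index=index, columns=columns)
        for (lg, sp, ch), contigs in cell_map.items():
            frame.loc[lg, (sp, ch)] = len(contigs)
        return frame

    return OxfordGrid(counts=_frame(cells), best_counts=_frame(best_cells),
                      paralog_flags=paralogs)


@dataclass(frozen=True)
class SyntenicRegion:
    lg: str
    species: str
    chromosome: str
    n_contigs: int
    span_bp: int


def syntenic_regions(
    gmap: GeneticMap,
    hits_by_species: dict[str, list[HomologyHit]],
    min_shared: int = 2,
) -> tuple[list[SyntenicRegion], pd.DataFrame]:
    """Conserved syntenic regions: >= ``min_shared`` distinct contigs of one
    linkage group on one chromosome, regardless of marker order.

    Returns the region list plus a per-species summary with region count,
    mean contigs per region and total subject-coordinate span (bp).
    """
    lg_of = _contig_to_lg(gmap)
    bucket: dict[tuple[str, str, str], list[HomologyHit]] = {}
    for species, hits in hits_by_species.items():
        for h in hits:
            lg = lg_of.get(h.contig_id)
            if lg is not None:
                bucket.setdefault((lg, species, h.chromosome), []).append(h)
    regions = []
    for (lg, sp, ch), hs in sorted(bucket.items()):
        contigs = {h.contig_id for h in hs}
        if len(contigs) < min_shared:
            continue
        span = max(h.subject_end for h in hs) - min(h.subject_start for h in hs) + 1
        regions.append(SyntenicRegion(lg, sp, ch, len(contigs), span))
    rows = []
    for sp in sorted(hits_by_species):
        rs = [r for r in regions if r.species == sp]
        rows.append({
            "species": sp,
            "n_regions": len(rs),
            "mean_contigs": (sum(r.n_contigs for r in rs) / len(rs)) if rs else 0.0,
            "total_span_bp": sum(r.span_bp for r in rs),
        })
    return regions, pd.DataFrame(rows)


@dataclass
class ChromosomeAssignment:
    putative_chromosome_id: str
    primary_lg: str
    merged_lgs: list[str]
    synteny_labels: list[str]
    homolog_chromosomes: dict[str, list[str]]  # species -> member chromosomes
    evidence_counts: dict[str, int]            # label -> supporting hit contigs
    is_fusion: bool = False


@dataclass
class AssignmentResult:
    assignments: list[ChromosomeAssignment]
    unplaced_lgs: list[str]
    conflicts: list[str]
    tie_log: list[str]


def assign_chromosomes(
    grid: OxfordGrid,
    scheme: SyntenyScheme,
    karyotype: Karyotype,
) -> AssignmentResult:
    """Assign linkage groups to putative chromosomes via the A/B scheme.

    Per species chromosome the max-count linkage group is marked; per scheme
    label the marked groups of its member chromosomes vote and the modal
    group becomes the label's primary LG.  Each primary LG defines one
    putative chromosome (two A-labels on one LG = fusion).  Surplus LGs are
    merged into a putative chromosome iff all their hits fall within that
    single label's chromosomes.  All ties break lexicographically and are
    logged.
    """
    if grid.counts.empty:
        raise ValueError("empty Oxford grid: nothing to assign")
    tie_log: list[str] = []
    conflicts: list[str] = []

    # (1) per species chromosome, the linkage group with the highest count
    marked: dict[tuple[str, str], str] = {}
    for col in grid.counts.columns:
        series = grid.counts[col]
        top = series.max()
        if top <= 0:
            continue
        winners = sorted(series.index[series == top])
        if len(winners) > 1:
            tie_log.append(
                f"chromosome {col[0]}:{col[1]}: tie between {winners}, "
                f"kept {winners[0]}"
            )
        marked[col] = winners[0]

    # (2) per label, modal marked group over its member chromosomes
    primary_of_label: dict[str, str] = {}
    label_votes: dict[str, dict[str, int]] = {}
    for label in sorted(scheme.labels):
        votes: dict[str, int] = {}
        for sp, ch in sorted(scheme.labels[label].items()):
            lg = marked.get((sp, ch))
            if lg is not None:
                votes[lg] = votes.get(lg, 0) + 1
        label_votes[label] = votes
        if not votes:
            continue
        top = max(votes.values())
        winners = sorted(lg for lg, v in votes.items() if v == top)
        if len(winners) > 1:
            tie_log.append(f"label {label}: tie between {winners}, kept {winners[0]}")
        primary_of_label[label] = winners[0]

    # (3) one putative chromosome per primary LG
    labels_of_lg: dict[str, list[str]] = {}
    for label, lg in primary_of_label.items():
        labels_of_lg.setdefault(lg, []).append(label)

    # hit support per LG per label (for surplus merging and evidence counts)
    chrom_label: dict[tuple[str, str], set[str]] = {}
    for label, members in scheme.labels.items():
        for sp, ch in members.items():
            chrom_label.setdefault((sp, ch), set()).add(label)

    support_counts = grid.best_counts if grid.best_counts is not None else grid.counts

    def lg_label_support(lg: str) -> dict[str, int]:
        support: dict[str, int] = {}
        unassigned = 0
        for col in support_counts.columns:
            cnt = int(support_counts.loc[lg, col]) if lg in support_counts.index else 0
            if cnt <= 0:
                continue
            labs = chrom_label.get(col)
            if not labs:
                unassigned += cnt
                continue
            for lab in labs:
                support[lab] = support.get(lab, 0) + cnt
        if unassigned:
            support["<unassigned>"] = unassigned
        return support

    assignments: list[ChromosomeAssignment] = []
    for k, lg in enumerate(sorted(labels_of_lg), start=1):
        labels = sorted(labels_of_lg[lg])
        homologs: dict[str, list[str]] = {}
        for label in labels:
            for sp, ch in scheme.labels[label].items():
                homologs.setdefault(sp, [])
                if ch not in homologs[sp]:
                    homologs[sp].append(ch)
        n_a = sum(1 for lab in labels if lab.startswith("A"))
        assignments.append(
            ChromosomeAssignment(
                putative_chromosome_id=f"PC{k}",
                primary_lg=lg,
                merged_lgs=[],
                synteny_labels=labels,
                homolog_chromosomes={sp: sorted(v) for sp, v in homologs.items()},
                evidence_counts={
                    lab: sum(label_votes.get(lab, {}).values()) for lab in labels
                },
                is_fusion=n_a >= 2,
            )
        )

    # (4) surplus LGs: merge iff every hit lies within a single label
    primary_lgs = set(labels_of_lg)
    by_label = {
        lab: a for a in assignments for lab in a.synteny_labels
    }
    unplaced: list[str] = []
    for lg in sorted(grid.counts.index):
        if lg in primary_lgs:
            continue
        support = lg_label_support(lg)
        labs = [lab for lab in support if lab != "<unassigned>"]
        if len(labs) == 1 and "<unassigned>" not in support and labs[0] in by_label:
            by_label[labs[0]].merged_lgs.append(lg)
        else:
            unplaced.append(lg)
            conflicts.append(
                f"surplus group {lg}: hits on labels {sorted(support)}; left unplaced"
            )
    for a in assignments:
        a.merged_lgs.sort()

    # (5) reconcile with the karyotype
    if len(assignments) > karyotype.haploid_n:
        conflicts.append(
            f"{len(assignments)} putative chromosomes exceed haploid "
            f"n={karyotype.haploid_n}"
        )
    return AssignmentResult(assignments, unplaced, conflicts, tie_log)
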