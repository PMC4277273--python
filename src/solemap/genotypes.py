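"""Genotype data model, I/O and quality control for full-sib mapping families.

The mapping design is two unrelated full-sib families (outbred parents, CP
cross).  Markers are biallelic SNPs annotated with the EST contig they were
discovered in, multi-allelic microsatellites, or contig haplotypes built
downstream.  QC follows the usual order for small family designs: individuals
with excessive missing data are dropped first, then markers are screened for
missingness, Mendelian consistency and informativeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "Marker",
    "HaplotypeMarker",
    "Family",
    "QCReport",
    "GenotypeFormatError",
    "read_genotypes",
    "write_genotypes",
    "filter_missingness",
    "check_mendelian",
    "flag_informative",
    "apply_qc",
    "MISSING",
]

#: sentinel used in genotype tables for a missing allele pair
MISSING = "-/-"

FORMAT_TAG = "#solemap-genotypes"
FORMAT_VERSION = "1"

SNP = "snp"
MICROSATELLITE = "microsatellite"
HAPLOTYPE = "haplotype"

# per-family segregation classes
UNINFORMATIVE = "uninformative"
TESTCROSS_SIRE = "testcross_sire"  # sire heterozygous, dam homozygous
TESTCROSS_DAM = "testcross_dam"
INTERCROSS = "intercross"          # both parents het with the same genotype
OUTBRED = "outbred"                # both parents het, different genotypes (e.g. ab x cd)


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype tables."""


@dataclass(frozen=True)
class Marker:
    """A mapped locus: SNP, microsatellite or combined contig haplotype."""

    id: str
    kind: str
    alleles: tuple[str, ...]
    contig_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (SNP, MICROSATELLITE, HAPLOTYPE):
            raise ValueError(f"marker {self.id}: unknown kind {self.kind!r}")
        if self.kind == SNP and len(self.alleles) != 2:
            raise ValueError(
                f"marker {self.id}: a SNP must have exactly 2 alleles, "
                f"got {len(self.alleles)}"
            )
        if len(self.alleles) < 2:
            raise ValueError(f"marker {self.id}: needs >=2 alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"marker {self.id}: duplicate alleles")
        if self.kind == SNP and self.contig_id is None:
            raise ValueError(f"marker {self.id}: every SNP must carry a contig_id")


@dataclass(frozen=True)
class HaplotypeMarker(Marker):
    """Multi-allelic marker formed by combining the SNPs of one contig."""

    member_snp_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.member_snp_ids) < 2:
            raise ValueError(f"marker {self.id}: haplotype needs >=2 member SNPs")


Genotype = tuple[str, str] | None


@dataclass
class Family:
    """One full-sib family: two parents and their offspring.

    Genotypes are unordered allele pairs keyed by marker id; ``None`` encodes
    a missing genotype and is never imputed.
    """

    family_id: str
    sire_id: str
    dam_id: str
    sire: dict[str, Genotype]
    dam: dict[str, Genotype]
    offspring: dict[str, dict[str, Genotype]]

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)

    def parent(self, which: str) -> dict[str, Genotype]:
        return self.sire if which == "sire" else self.dam

    def drop_markers(self, marker_ids: set[str]) -> "Family":
        keep = lambda g: {m: v for m, v in g.items() if m not in marker_ids}
        return Family(
            self.family_id, self.sire_id, self.dam_id,
            keep(self.sire), keep(self.dam),
            {o: keep(g) for o, g in self.offspring.items()},
        )


@dataclass
class QCReport:
    """Everything removed (and why) plus per-marker informativeness flags."""

    excluded_individuals: dict[str, float] = field(default_factory=dict)
    excluded_markers: dict[str, str] = field(default_factory=dict)  # id -> reason
    informative: dict[str, dict[str, str]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def merge(self, other: "QCReport") -> None:
        self.excluded_individuals.update(other.excluded_individuals)
        for m, reason in other.excluded_markers.items():
            self.excluded_markers.setdefault(m, reason)
        self.informative.update(other.informative)
        self.notes.extend(other.notes)


# ---------------------------------------------------------------------------
# I/O: delimited genotype table (see docs/methods.md for the layout)
# ---------------------------------------------------------------------------

def _parse_pair(cell: str, marker: Marker, individual: str, lineno: int) -> Genotype:
    if cell == MISSING:
        return None
    parts = cell.split("/")
    if len(parts) != 2:
        raise GenotypeFormatError(
            f"line {lineno}: malformed genotype {cell!r} for marker "
            f"{marker.id}, individual {individual}"
        )
    a, b = parts
    for allele in (a, b):
        if allele not in marker.alleles:
            raise GenotypeFormatError(
                f"line {lineno}: allele {allele!r} outside the declared alphabet "
                f"of marker {marker.id} for individual {individual}"
            )
    return (a, b)


def read_genotypes(path) -> tuple[list[Marker], list[Family]]:
    """Read a v1 solemap genotype table.

    Returns the declared marker list and one :class:`Family` per family block.
    Missing genotypes are preserved as ``None``.
    """
    markers: list[Marker] = []
    seen_ids: set[str] = set()
    rows: list[tuple[int, str, str, str, list[str]]] = []
    header: list[str] | None = None

    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(FORMAT_TAG):
                version = line.split("\t")[1] if "\t" in line else ""
                if version != FORMAT_VERSION:
                    raise GenotypeFormatError(
                        f"line {lineno}: unsupported format version {version!r}"
                    )
                continue
            if line.startswith("#marker"):
                fields = line.split("\t")
                if len(fields) != 5:
                    raise GenotypeFormatError(
                        f"line {lineno}: marker declaration needs 5 fields"
                    )
                _, mid, kind, contig, alleles = fields
                if mid in seen_ids:
                    raise GenotypeFormatError(f"line {lineno}: duplicate marker id {mid!r}")
                seen_ids.add(mid)
                try:
                    markers.append(
                        Marker(
                            id=mid, kind=kind,
                            alleles=tuple(alleles.split(",")),
                            contig_id=None if contig == "-" else contig,
                        )
                    )
                except ValueError as exc:
                    raise GenotypeFormatError(f"line {lineno}: {exc}") from exc
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields[:3] != ["family", "role", "individual"]:
                    raise GenotypeFormatError(
                        f"line {lineno}: expected header 'family role individual ...'"
                    )
                header = fields[3:]
                unknown = [m for m in header if m not in seen_ids]
                if unknown:
                    raise GenotypeFormatError(
                        f"line {lineno}: undeclared markers in header: {unknown[:3]}"
                    )
                continue
            if len(fields) != 3 + len(header):
                raise GenotypeFormatError(
                    f"line {lineno}: expected {3 + len(header)} columns, got {len(fields)}"
                )
            rows.append((lineno, fields[0], fields[1], fields[2], fields[3:]))

    if header is None:
        raise GenotypeFormatError("no genotype table header found")
    marker_by_id = {m.id: m for m in markers}
    order = [marker_by_id[m] for m in header]

    families: dict[str, Family] = {}
    for lineno, fam_id, role, ind, cells in rows:
        if role not in ("sire", "dam", "offspring"):
            raise GenotypeFormatError(f"line {lineno}: unknown role {role!r}")
        genos = {
            m.id: _parse_pair(cell, m, ind, lineno)
            for m, cell in zip(order, cells)
        }
        fam = families.setdefault(fam_id, Family(fam_id, "", "", {}, {}, {}))
        if role == "sire":
            fam.sire_id, fam.sire = ind, genos
        elif role == "dam":
            fam.dam_id, fam.dam = ind, genos
        else:
            fam.offspring[ind] = genos
    for fam in families.values():
        if not fam.sire_id or not fam.dam_id:
            raise GenotypeFormatError(
                f"family {fam.family_id}: missing sire and/or dam row"
            )
    return markers, list(families.values())


def write_genotypes(path, markers: list[Marker], families: list[Family]) -> None:
    """Write markers + families in the v1 table layout (round-trips exactly)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{FORMAT_TAG}\t{FORMAT_VERSION}\n")
        for m in markers:
            contig = m.contig_id if m.contig_id is not None else "-"
            fh.write(f"#marker\t{m.id}\t{m.kind}\t{contig}\t{','.join(m.alleles)}\n")
        ids = [m.id for m in markers]
        fh.write("family\trole\tindividual\t" + "\t".join(ids) + "\n")

        def cell(g: Genotype) -> str:
            return MISSING if g is None else f"{g[0]}/{g[1]}"

        for fam in families:
            fh.write(
                f"{fam.family_id}\tsire\t{fam.sire_id}\t"
                + "\t".join(cell(fam.sire.get(m)) for m in ids) + "\n"
            )
            fh.write(
                f"{fam.family_id}\tdam\t{fam.dam_id}\t"
                + "\t".join(cell(fam.dam.get(m)) for m in ids) + "\n"
            )
            for off, genos in fam.offspring.items():
                fh.write(
                    f"{fam.family_id}\toffspring\t{off}\t"
                    + "\t".join(cell(genos.get(m)) for m in ids) + "\n"
                )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def filter_missingness(
    families: list[Family],
    max_missing_individual: float = 0.30,
    max_missing_marker: float = 0.30,
) -> tuple[list[Family], QCReport]:
    """Drop offspring, then markers, with a missing fraction strictly above
    the thresholds.

    Offspring are screened first, against the full marker list; the marker
    missing fraction is then computed over the retained individuals (parents
    included), pooled across both families.  Parents are never removed, only
    flagged in the report notes.
    """
    if not (0 <= max_missing_individual <= 1 and 0 <= max_missing_marker <= 1):
        raise ValueError("missingness thresholds must lie in [0, 1]")
    report = QCReport()

    def frac_missing(genos: dict[str, Genotype]) -> float:
        if not genos:
            return 1.0
        return sum(1 for v in genos.values() if v is None) / len(genos)

    kept_families: list[Family] = []
    for fam in families:
        for pid, genos in ((fam.sire_id, fam.sire), (fam.dam_id, fam.dam)):
            f = frac_missing(genos)
            if f > max_missing_individual:
                report.notes.append(
                    f"parent {pid} (family {fam.family_id}) has missing fraction "
                    f"{f:.3f} > {max_missing_individual}; retained (parents are "
                    "required for the family)"
                )
        kept_off = {}
        for oid, genos in fam.offspring.items():
            f = frac_missing(genos)
            if f > max_missing_individual:
                report.excluded_individuals[oid] = f
            else:
                kept_off[oid] = genos
        kept_families.append(replace(fam, offspring=kept_off))

    # pooled marker missingness over retained individuals of both families
    marker_ids: list[str] = []
    seen = set()
    for fam in kept_families:
        for m in fam.sire:
            if m not in seen:
                seen.add(m)
                marker_ids.append(m)
    drop: set[str] = set()
    for m in marker_ids:
        n = miss = 0
        for fam in kept_families:
            for genos in (fam.sire, fam.dam, *fam.offspring.values()):
                if m in genos:
                    n += 1
                    miss += genos[m] is None
        if n == 0 or miss / n > max_missing_marker:
            drop.add(m)
            report.excluded_markers[m] = "missing"
    if drop:
        kept_families = [f.drop_markers(drop) for f in kept_families]
    if all(not f.offspring for f in kept_families):
        report.notes.append("no offspring retained after missingness filtering")
    return kept_families, report


def _transmission_set(sire: Genotype, dam: Genotype) -> set[tuple[str, str]]:
    """All offspring genotypes (as sorted pairs) producible by two parents."""
    assert sire is not None and dam is not None
    return {tuple(sorted((a, b))) for a in sire for b in dam}


def check_mendelian(families: list[Family], markers: list[Marker]) -> QCReport:
    """Flag markers with offspring genotypes impossible under the parents.

    A marker failing in either family is excluded globally.  Missing offspring
    genotypes never count as violations; a missing parent genotype means the
    marker cannot be checked in that family (noted in the report).
    """
    report = QCReport()
    for marker in markers:
        bad = False
        for fam in families:
            sire, dam = fam.sire.get(marker.id), fam.dam.get(marker.id)
            if marker.id not in fam.sire and marker.id not in fam.dam:
                continue
            if sire is None or dam is None:
                report.notes.append(
                    f"marker {marker.id}: parent genotype missing in family "
                    f"{fam.family_id}; Mendelian check skipped there"
                )
                continue
            allowed = _transmission_set(sire, dam)
            for oid, genos in fam.offspring.items():
                g = genos.get(marker.id)
                if g is not None and tuple(sorted(g)) not in allowed:
                    report.notes.append(
                        f"marker {marker.id}: offspring {oid} genotype "
                        f"{g[0]}/{g[1]} impossible from parents in family "
                        f"{fam.family_id}"
                    )
                    bad = True
        if bad:
            report.excluded_markers[marker.id] = "non_mendelian"
    return report


def segregation_class(sire: Genotype, dam: Genotype) -> str:
    """Per-family segregation class of a marker given its parents."""
    if sire is None or dam is None:
        return UNINFORMATIVE
    sire_het, dam_het = sire[0] != sire[1], dam[0] != dam[1]
    if not sire_het and not dam_het:
        return UNINFORMATIVE
    if sire_het and dam_het:
        return INTERCROSS if sorted(sire) == sorted(dam) else OUTBRED
    return TESTCROSS_SIRE if sire_het else TESTCROSS_DAM


def flag_informative(families: list[Family], markers: list[Marker]) -> QCReport:
    """Record the segregation class per (marker, family); a marker is retained
    iff at least one parent is heterozygous in at least one family."""
    report = QCReport()
    for marker in markers:
        classes = {}
        for fam in families:
            if marker.id not in fam.sire and marker.id not in fam.dam:
                continue
            classes[fam.family_id] = segregation_class(
                fam.sire.get(marker.id), fam.dam.get(marker.id)
            )
        report.informative[marker.id] = classes
        if all(c == UNINFORMATIVE for c in classes.values()) or not classes:
            report.excluded_markers[marker.id] = "uninformative"
    return report


def apply_qc(
    markers: list[Marker],
    families: list[Family],
    max_missing_individual: float = 0.30,
    max_missing_marker: float = 0.30,
) -> tuple[list[Marker], list[Family], QCReport]:
    """Full QC pass: individual missingness -> marker missingness ->
    Mendelian consistency -> informativeness.  Deterministic and idempotent."""
    families, report = filter_missingness(
        families, max_missing_individual, max_missing_marker
    )
    kept = [m for m in markers if m.id not in report.excluded_markers]

    mend = check_mendelian(families, kept)
    report.merge(mend)
    kept = [m for m in kept if m.id not in report.excluded_markers]

    info = flag_informative(families, kept)
    report.merge(info)
    kept = [m for m in kept if m.id not in report.excluded_markers]

    dropped = set(report.excluded_markers)
    families = [f.drop_markers(dropped) for f in families]
    return kept, families, report
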