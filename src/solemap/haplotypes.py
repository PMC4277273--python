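"""Combine the SNPs of one EST contig into a single multi-allelic marker.

SNPs discovered in the same contig sit within a few kb, so in a full-sib
family they should be co-inherited without exception.  Each contig is phased
per family by exhaustive enumeration over parental phase assignments (contigs
carry only a handful of SNPs, so the 2^(h-1) phase space per parent is tiny).
If some offspring cannot be explained by one paternal plus one maternal
haplotype under any phase pair, that is evidence of intra-contig
recombination (or a genotyping artefact) and the contig is left split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .genotypes import (
    HAPLOTYPE,
    Family,
    Genotype,
    HaplotypeMarker,
    Marker,
    segregation_class,
    UNINFORMATIVE,
)

__all__ = ["PhaseResult", "CombinationRecord", "phase_contig", "combine_contigs"]

HAP_SEP = "-"


@dataclass
class PhaseResult:
    """Outcome of phasing one contig in one family."""

    family_id: str
    snp_ids: tuple[str, ...]
    phased: bool
    sire_haplotypes: tuple[tuple[str, ...], tuple[str, ...]] | None = None
    dam_haplotypes: tuple[tuple[str, ...], tuple[str, ...]] | None = None
    #: offspring id -> unordered pair of haplotype labels (None = ambiguous)
    offspring_haplotypes: dict[str, tuple[str, str] | None] = field(default_factory=dict)
    #: offspring incompatible with every phase assignment (recombination evidence)
    recombinant_offspring: tuple[str, ...] = ()


def _parent_phases(genotypes: list[Genotype]):
    """Enumerate the distinct haplotype pairs of one parent over k loci.

    A missing parental genotype at a locus is treated as an unknown symbol
    ('?') on both haplotypes; heterozygous loci beyond the first contribute a
    factor 2 each (first het locus fixed to break the global swap symmetry).
    """
    het_loci = [i for i, g in enumerate(genotypes) if g is not None and g[0] != g[1]]
    free = het_loci[1:]
    for bits in product((0, 1), repeat=len(free)):
        flip = dict(zip(free, bits))
        h1, h2 = [], []
        for i, g in enumerate(genotypes):
            if g is None:
                h1.append("?")
                h2.append("?")
            elif flip.get(i, 0):
                h1.append(g[1])
                h2.append(g[0])
            else:
                h1.append(g[0])
                h2.append(g[1])
        yield tuple(h1), tuple(h2)


def _compatible(obs: list[Genotype], hs: tuple[str, ...], hd: tuple[str, ...]) -> bool:
    """Can offspring genotypes be produced by sire haplotype hs + dam hap hd?
    Missing offspring loci are wildcards; '?' parental alleles match anything."""
    for g, a, b in zip(obs, hs, hd):
        if g is None:
            continue
        x, y = g
        if a == "?" or b == "?":
            # one known parental allele must still be present in the genotype
            known = b if a == "?" else a
            if known != "?" and known not in (x, y):
                return False
            continue
        if tuple(sorted((a, b))) != tuple(sorted((x, y))):
            return False
    return True


def _hap_label(h: tuple[str, ...]) -> str:
    return HAP_SEP.join(h)


def phase_contig(snp_ids: list[str], family: Family) -> PhaseResult:
    """Phase one contig's SNPs in one family by exhaustive phase enumeration.

    Returns a fully phased assignment when every offspring is explained by one
    paternal plus one maternal haplotype without intra-contig crossover;
    otherwise reports the offending offspring (under the phase pair explaining
    the most offspring, ties resolved by enumeration order).
    """
    if len(snp_ids) < 2:
        raise ValueError("phase_contig needs >=2 SNPs on the contig")
    sire = [family.sire.get(m) for m in snp_ids]
    dam = [family.dam.get(m) for m in snp_ids]
    if all(g is None for g in sire) and all(g is None for g in dam):
        raise ValueError(
            f"contig {snp_ids}: all parental genotypes missing in family "
            f"{family.family_id}"
        )
    obs = {o: [g.get(m) for m in snp_ids] for o, g in family.offspring.items()}

    best = None  # (n_bad, sire_haps, dam_haps, per-offspring pair sets)
    for hs_pair in _parent_phases(sire):
        for hd_pair in _parent_phases(dam):
            assignments: dict[str, set[tuple[str, str]]] = {}
            bad = []
            for oid, genos in obs.items():
                pairs = {
                    tuple(sorted((_hap_label(hs), _hap_label(hd))))
                    for hs in hs_pair
                    for hd in hd_pair
                    if _compatible(genos, hs, hd)
                }
                if pairs:
                    assignments[oid] = pairs
                else:
                    bad.append(oid)
            if best is None or len(bad) < best[0]:
                best = (len(bad), hs_pair, hd_pair, assignments, tuple(bad))
            if best[0] == 0:
                break
        if best is not None and best[0] == 0:
            break

    n_bad, hs_pair, hd_pair, assignments, bad = best
    offspring_haps = {
        oid: (pairs.pop() if len(pairs) == 1 else None)
        for oid, pairs in ((o, set(p)) for o, p in assignments.items())
    }
    for oid in bad:
        offspring_haps[oid] = None
    return PhaseResult(
        family_id=family.family_id,
        snp_ids=tuple(snp_ids),
        phased=n_bad == 0,
        sire_haplotypes=hs_pair,
        dam_haplotypes=hd_pair,
        offspring_haplotypes=offspring_haps,
        recombinant_offspring=bad,
    )


@dataclass
class CombinationRecord:
    contig_id: str
    snp_ids: tuple[str, ...]
    combined: bool
    recombinant_offspring: tuple[str, ...] = ()

    def as_row(self) -> str:
        status = "combined" if self.combined else "split"
        ev = ",".join(self.recombinant_offspring) or "-"
        return f"{self.contig_id}\t{len(self.snp_ids)}\t{status}\t{ev}"


def combine_contigs(
    markers: list[Marker],
    families: list[Family],
    min_recombinants: int = 1,
) -> tuple[list[Marker], list[Family], list[CombinationRecord]]:
    """Replace each multi-SNP contig by one haplotype marker.

    Contigs with >= ``min_recombinants`` recombination-evidence offspring in
    any family keep their SNPs as separate markers and are logged as split.
    Single-SNP contigs, microsatellites and existing haplotypes pass through
    unchanged.  Marker ids of combined contigs are the contig id prefixed 'C',
    mirroring the published map's naming.
    """
    by_contig: dict[str, list[Marker]] = {}
    for m in markers:
        if m.kind == "snp" and m.contig_id is not None:
            by_contig.setdefault(m.contig_id, []).append(m)

    log: list[CombinationRecord] = []
    new_markers: list[Marker] = []
    removed: set[str] = set()
    # per family: new haplotype genotype columns to add
    new_cols: dict[str, dict[str, dict[str, Genotype]]] = {f.family_id: {} for f in families}

    fam_by_id = {f.family_id: f for f in families}
    for contig_id in sorted(c for c, ms in by_contig.items() if len(ms) >= 2):
        member = sorted(by_contig[contig_id], key=lambda m: m.id)
        snp_ids = [m.id for m in member]
        results = {fid: phase_contig(snp_ids, fam) for fid, fam in fam_by_id.items()}
        evidence = tuple(
            oid for r in results.values() for oid in r.recombinant_offspring
        )
        n_unambiguous = sum(
            len(r.recombinant_offspring) for r in results.values()
        )
        if n_unambiguous >= min_recombinants:
            log.append(CombinationRecord(contig_id, tuple(snp_ids), False, evidence))
            continue

        alleles: set[str] = set()
        col: dict[str, dict[str, Genotype]] = {}
        hap_id = "C" + contig_id
        for fid, r in results.items():
            fam = fam_by_id[fid]
            sire_g = tuple(_hap_label(h) for h in r.sire_haplotypes)
            dam_g = tuple(_hap_label(h) for h in r.dam_haplotypes)
            genos: dict[str, Genotype] = {fam.sire_id: sire_g, fam.dam_id: dam_g}
            alleles.update(sire_g)
            alleles.update(dam_g)
            for oid in fam.offspring:
                pair = r.offspring_haplotypes.get(oid)
                genos[oid] = pair
                if pair is not None:
                    alleles.update(pair)
            col[fid] = genos
        if len(alleles) < 2:
            # fully homozygous haplotype (should not happen for informative SNPs)
            log.append(CombinationRecord(contig_id, tuple(snp_ids), False, ()))
            continue
        new_markers.append(
            HaplotypeMarker(
                id=hap_id,
                kind=HAPLOTYPE,
                alleles=tuple(sorted(alleles)),
                contig_id=contig_id,
                member_snp_ids=tuple(snp_ids),
            )
        )
        new_cols_for_marker = col
        for fid, genos in new_cols_for_marker.items():
            new_cols[fid][hap_id] = genos
        removed.update(snp_ids)
        log.append(CombinationRecord(contig_id, tuple(snp_ids), True, ()))

    out_markers = [m for m in markers if m.id not in removed] + new_markers
    out_families: list[Family] = []
    for fam in families:
        fam2 = fam.drop_markers(removed)
        for hap_id, genos in new_cols[fam.family_id].items():
            fam2.sire[hap_id] = genos.get(fam2.sire_id)
            fam2.dam[hap_id] = genos.get(fam2.dam_id)
            for oid in fam2.offspring:
                fam2.offspring[oid][hap_id] = genos.get(oid)
        out_families.append(fam2)
    return out_markers, out_families, log
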