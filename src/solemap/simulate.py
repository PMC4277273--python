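"""Synthetic-data generator with exported ground truth.

Emulates the statistical structure of the study design end to end: a known
genome (chromosome lengths in cM, EST contigs carrying one or several SNPs,
a handful of microsatellites), two full-sib families whose meioses are drawn
with per-interval recombination probabilities given by the inverse Kosambi
function (crossovers are interference-free across intervals — a deliberate
simplification documented in the methods note), genotyping missingness and
error, and per-species homology hit tables with planted orthology, optional
lineage-specific fusions and paralog noise straddling the e-value threshold.

Every stochastic output is a pure function of (config, seed), and the
generator exports its ground truth (true positions, transmitted haplotypes,
ortholog assignments, synteny scheme, bridge table) so each downstream stage
has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import (
    Family,
    Marker,
    MICROSATELLITE,
    SNP,
)
from .linkage import GeneticMap, LinkageGroup, kosambi_inverse, map_stats
from .stepping_stone import BridgeTable
from .synteny import BLAST6_COLUMNS, SyntenyScheme

__all__ = [
    "SimConfig",
    "TrueGenome",
    "SimTruth",
    "simulate_genome",
    "simulate_families",
    "simulate_hits",
    "write_hits_tabular",
    "true_map_from_genome",
    "DEFAULT_DETECTABILITY",
]

#: observed fractions of map contigs with significant homology per species
DEFAULT_DETECTABILITY = {
    "stickleback": 0.47,
    "tilapia": 0.39,
    "medaka": 0.31,
    "pufferfish": 0.30,
}

_SPECIES_PREFIX = {
    "stickleback": "S",
    "tilapia": "T",
    "medaka": "M",
    "pufferfish": "P",
}


@dataclass
class SimConfig:
    """Study-scale defaults: two families of 46 and 35 offspring, 469 SNPs on
    291 single-SNP + 73 multi-SNP contigs, 10 microsatellites, 21
    chromosomes, <=3% missing genotypes."""

    seed: int
    n_chromosomes: int = 21
    chrom_length_range: tuple[float, float] = (60.0, 100.0)
    family_sizes: tuple[int, ...] = (46, 35)
    n_snps: int = 469
    n_single_snp_contigs: int = 291
    n_multi_snp_contigs: int = 73
    multi_snp_max: int = 4
    n_microsatellites: int = 10
    informative_fraction: float = 1.0
    #: P(both parents het), P(sire only), P(dam only) for an informative SNP
    seg_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)
    missing_rate: float = 0.03
    genotype_error_rate: float = 0.0
    intra_contig_span_cm: float = 0.0
    n_fusions: int = 0
    species: tuple[str, ...] = ("stickleback", "tilapia", "medaka", "pufferfish")
    detectability: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTABILITY)
    )
    paralog_noise_rate: float = 0.05
    true_evalue_exp: tuple[float, float] = (15.0, 60.0)
    noise_evalue_exp: tuple[float, float] = (8.0, 12.0)
    bp_per_cm: float = 5e5

    def __post_init__(self) -> None:
        for p in (self.informative_fraction, self.missing_rate,
                  self.genotype_error_rate, self.paralog_noise_rate,
                  *self.seg_probs, *self.detectability.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.n_fusions > self.n_chromosomes:
            raise ValueError("more planted fusions than chromosomes")
        min_snps = self.n_single_snp_contigs + 2 * self.n_multi_snp_contigs
        max_snps = self.n_single_snp_contigs + self.multi_snp_max * self.n_multi_snp_contigs
        if not min_snps <= self.n_snps <= max_snps:
            raise ValueError(
                f"n_snps={self.n_snps} incompatible with contig counts "
                f"(feasible range {min_snps}..{max_snps})"
            )


@dataclass(frozen=True)
class SimMarker:
    id: str
    kind: str
    contig_id: str | None
    chrom: int
    pos_cm: float


@dataclass
class TrueGenome:
    """Planted genome: chromosomes, markers, orthology blocks and schemes."""

    chrom_lengths: list[float]
    #: per chromosome, list of (ancestral unit, start_cM, end_cM) blocks
    blocks: list[list[tuple[int, float, float]]]
    markers: list[SimMarker]
    n_units: int
    species: tuple[str, ...]
    scheme: SyntenyScheme
    bridge_table: BridgeTable

    def unit_of(self, chrom: int, pos_cm: float) -> tuple[int, float]:
        """Ancestral unit and within-unit cM offset of a genome position."""
        for unit, start, end in self.blocks[chrom]:
            if start <= pos_cm <= end:
                return unit, pos_cm - start
        unit, start, end = self.blocks[chrom][-1]
        return unit, pos_cm - start

    def species_chromosome(self, species: str, unit: int) -> str:
        return f"{_SPECIES_PREFIX.get(species, species[0].upper())}{unit + 1}"

    def contig_positions(self) -> dict[str, tuple[int, float]]:
        out: dict[str, tuple[int, float]] = {}
        for m in self.markers:
            if m.contig_id is not None and m.contig_id not in out:
                out[m.contig_id] = (m.chrom, m.pos_cm)
        return out


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_genome(config: SimConfig) -> TrueGenome:
    """Draw chromosome lengths, place contigs/markers, plant fusions and
    derive the matching synteny scheme and stepping-stone bridge table."""
    rng = _rng(config, 0)
    C = config.n_chromosomes
    lengths = rng.uniform(*config.chrom_length_range, size=C)

    # ancestral units: fused chromosomes carry two, the rest one
    n_units = C + config.n_fusions
    blocks: list[list[tuple[int, float, float]]] = []
    unit = 0
    for c in range(C):
        if c < config.n_fusions:
            half = lengths[c] / 2.0
            blocks.append([(unit, 0.0, half), (unit + 1, half, lengths[c])])
            unit += 2
        else:
            blocks.append([(unit, 0.0, lengths[c])])
            unit += 1

    # contigs: single-SNP + multi-SNP; SNP totals allocated to match n_snps
    n_contigs = config.n_single_snp_contigs + config.n_multi_snp_contigs
    snps_per_contig = np.ones(n_contigs, dtype=int)
    multi = np.arange(config.n_single_snp_contigs, n_contigs)
    snps_per_contig[multi] = 2
    extra = config.n_snps - snps_per_contig.sum()
    while extra > 0:
        room = multi[snps_per_contig[multi] < config.multi_snp_max]
        pick = rng.choice(room, size=min(extra, len(room)), replace=False)
        snps_per_contig[pick] += 1
        extra = config.n_snps - snps_per_contig.sum()

    probs = lengths / lengths.sum()
    contig_chrom = rng.choice(C, size=n_contigs, p=probs)
    contig_pos = rng.uniform(0.0, lengths[contig_chrom])
    width = max(len(str(n_contigs)), 4)

    markers: list[SimMarker] = []
    snp_no = 0
    for k in range(n_contigs):
        cid = f"ctg{k + 1:0{width}d}"
        for s in range(snps_per_contig[k]):
            snp_no += 1
            offset = rng.uniform(0.0, config.intra_contig_span_cm) if s else 0.0
            pos = float(np.clip(contig_pos[k] + offset, 0.0, lengths[contig_chrom[k]]))
            markers.append(
                SimMarker(f"snp{snp_no:04d}", SNP, cid, int(contig_chrom[k]), pos)
            )
    ms_chrom = rng.choice(C, size=config.n_microsatellites, p=probs)
    ms_pos = rng.uniform(0.0, lengths[ms_chrom])
    for k in range(config.n_microsatellites):
        markers.append(
            SimMarker(f"ms{k + 1:02d}", MICROSATELLITE, None,
                      int(ms_chrom[k]), float(ms_pos[k]))
        )
    markers.sort(key=lambda m: (m.chrom, m.pos_cm, m.id))

    labels = {
        f"A{u + 1}": {
            sp: f"{_SPECIES_PREFIX.get(sp, sp[0].upper())}{u + 1}"
            for sp in config.species
        }
        for u in range(n_units)
    }
    scheme = SyntenyScheme(labels=labels)
    bridge = BridgeTable(
        relative_name="relative",
        mapping={
            f"RLG{u + 1}": {
                sp: [f"{_SPECIES_PREFIX.get(sp, sp[0].upper())}{u + 1}"]
                for sp in config.species
            }
            for u in range(n_units)
        },
    )
    return TrueGenome(
        chrom_lengths=[float(x) for x in lengths],
        blocks=blocks,
        markers=markers,
        n_units=n_units,
        species=tuple(config.species),
        scheme=scheme,
        bridge_table=bridge,
    )


@dataclass
class SimTruth:
    """Generator bookkeeping: everything a downstream oracle needs."""

    marker_ids: list[str]
    #: marker id -> (chromosome index, position cM)
    position: dict[str, tuple[int, float]]
    #: family id -> marker id -> segregation class string
    seg_class: dict[str, dict[str, str]]
    #: family id -> (2 parents, n_offspring, n_markers) transmitted haplotype
    hap_source: dict[str, np.ndarray]
    #: family id -> parent index -> marker id -> (allele_hap0, allele_hap1)
    phases: dict[str, list[dict[str, tuple[str, str]]]]


def simulate_families(
    genome: TrueGenome, config: SimConfig
) -> tuple[list[Marker], list[Family], SimTruth]:
    """Draw parental genotypes and full-sib meioses over the planted genome.

    Recombination between adjacent markers is an independent event with
    probability given by the inverse Kosambi transform of the cM gap; the
    transmitted haplotype index per (offspring, parent, marker) is recorded
    as ground truth before missingness and genotyping error are applied.
    """
    rng = _rng(config, 1)
    sim_markers = genome.markers
    M = len(sim_markers)

    markers: list[Marker] = []
    for sm in sim_markers:
        if sm.kind == SNP:
            markers.append(Marker(sm.id, SNP, ("A", "B"), sm.contig_id))
        else:
            markers.append(Marker(sm.id, MICROSATELLITE, ("a", "b", "c", "d")))

    # adjacent-interval recombination probabilities per chromosome walk
    r_gap = np.zeros(M)
    for i in range(1, M):
        a, b = sim_markers[i - 1], sim_markers[i]
        r_gap[i] = 0.5 if b.chrom != a.chrom else kosambi_inverse(b.pos_cm - a.pos_cm)

    families: list[Family] = []
    truth = SimTruth([m.id for m in markers],
                     {m.id: (m.chrom, m.pos_cm) for m in sim_markers},
                     {}, {}, {})
    for fi, n_off in enumerate(config.family_sizes, start=1):
        fam_id = f"F{fi}"
        # parent haplotypes: (2 parents, 2 haplotypes, M) allele strings
        haps = np.empty((2, 2, M), dtype=object)
        seg: dict[str, str] = {}
        for i, (sm, m) in enumerate(zip(sim_markers, markers)):
            if sm.kind == MICROSATELLITE:
                order = rng.permutation(4)
                al = [m.alleles[k] for k in order]
                haps[0, :, i] = al[:2]
                haps[1, :, i] = al[2:]
                seg[m.id] = "outbred"
            else:
                if rng.random() >= config.informative_fraction:
                    a = m.alleles[int(rng.integers(2))]
                    haps[:, :, i] = a
                    seg[m.id] = "uninformative"
                    continue
                u = rng.random()
                p_both, p_sire, _ = config.seg_probs
                if u < p_both:
                    kinds = ("het", "het")
                    seg[m.id] = "intercross"
                elif u < p_both + p_sire:
                    kinds = ("het", "hom")
                    seg[m.id] = "testcross_sire"
                else:
                    kinds = ("hom", "het")
                    seg[m.id] = "testcross_dam"
                for p, kind in enumerate(kinds):
                    if kind == "het":
                        order = rng.permutation(2)
                        haps[p, 0, i] = m.alleles[order[0]]
                        haps[p, 1, i] = m.alleles[order[1]]
                    else:
                        a = m.alleles[int(rng.integers(2))]
                        haps[p, :, i] = a
        truth.seg_class[fam_id] = seg
        truth.phases[fam_id] = [
            {markers[i].id: (haps[p, 0, i], haps[p, 1, i]) for i in range(M)}
            for p in (0, 1)
        ]

        # meioses: haplotype index walks with per-interval switch probability,
        # restarted independently on every chromosome
        source = np.zeros((2, n_off, M), dtype=np.int8)
        chrom_of = np.array([sm.chrom for sm in sim_markers])
        bounds = [0, *(np.nonzero(np.diff(chrom_of))[0] + 1), M]
        for p in (0, 1):
            for s, e in zip(bounds[:-1], bounds[1:]):
                start = rng.integers(0, 2, size=n_off)
                switch = rng.random((n_off, e - s)) < r_gap[s:e][None, :]
                switch[:, 0] = False
                walk = np.logical_xor.accumulate(switch, axis=1)
                source[p, :, s:e] = (start[:, None] + walk) % 2
        truth.hap_source[fam_id] = source

        sire_id, dam_id = f"{fam_id}_sire", f"{fam_id}_dam"
        sire = {markers[i].id: (haps[0, 0, i], haps[0, 1, i]) for i in range(M)}
        dam = {markers[i].id: (haps[1, 0, i], haps[1, 1, i]) for i in range(M)}
        offspring: dict[str, dict[str, tuple[str, str] | None]] = {}
        err = rng.random((n_off, M)) < config.genotype_error_rate
        err_allele = rng.integers(0, 4, size=(n_off, M))
        err_which = rng.integers(0, 2, size=(n_off, M))
        miss = rng.random((n_off, M)) < config.missing_rate
        for n in range(n_off):
            oid = f"{fam_id}_o{n + 1:02d}"
            genos: dict[str, tuple[str, str] | None] = {}
            for i, m in enumerate(markers):
                if miss[n, i]:
                    genos[m.id] = None
                    continue
                a = haps[0, source[0, n, i], i]
                b = haps[1, source[1, n, i], i]
                g = [a, b]
                if err[n, i]:
                    g[err_which[n, i]] = m.alleles[err_allele[n, i] % len(m.alleles)]
                genos[m.id] = (g[0], g[1])
            offspring[oid] = genos
        families.append(Family(fam_id, sire_id, dam_id, sire, dam, offspring))
    return markers, families, truth


@dataclass
class HitTruth:
    """Which hits are genuine orthologs and which are injected noise."""

    #: species -> contig -> true ortholog chromosome
    ortholog: dict[str, dict[str, str]]
    #: species -> list of (contig, chromosome, e_value) noise hits
    noise: dict[str, list[tuple[str, str, float]]]


def simulate_hits(
    genome: TrueGenome, config: SimConfig
) -> tuple[dict[str, pd.DataFrame], HitTruth]:
    """Per-species homology hit tables in BLAST outfmt-6 layout.

    Each contig gains its true ortholog hit with the configured per-species
    detectability (strong e-values), plus paralog noise on random
    chromosomes with e-values straddling the 1e-10 threshold and bit scores
    below any true hit.
    """
    rng = _rng(config, 2)
    positions = genome.contig_positions()
    tables: dict[str, pd.DataFrame] = {}
    truth = HitTruth({sp: {} for sp in genome.species},
                     {sp: [] for sp in genome.species})
    for sp in genome.species:
        det = config.detectability.get(sp, 1.0)
        rows = []
        for cid in sorted(positions):
            chrom_idx, pos_cm = positions[cid]
            unit, off_cm = genome.unit_of(chrom_idx, pos_cm)
            true_chrom = genome.species_chromosome(sp, unit)
            truth.ortholog[sp][cid] = true_chrom
            if rng.random() < det:
                length = int(rng.integers(400, 1500))
                sstart = int(off_cm * config.bp_per_cm) + 1
                send = sstart + length - 1
                if rng.random() < 0.5:
                    sstart, send = send, sstart
                evalue = 10.0 ** -rng.uniform(*config.true_evalue_exp)
                rows.append([
                    cid, true_chrom, round(rng.uniform(78, 96), 2), length,
                    int(rng.integers(0, 40)), int(rng.integers(0, 5)),
                    1, length, sstart, send, evalue,
                    round(rng.uniform(120, 400), 1),
                ])
            if rng.random() < config.paralog_noise_rate:
                unit_noise = int(rng.integers(0, genome.n_units))
                chrom_noise = genome.species_chromosome(sp, unit_noise)
                length = int(rng.integers(200, 600))
                sstart = int(rng.integers(1, 3_000_000))
                evalue = 10.0 ** -rng.uniform(*config.noise_evalue_exp)
                truth.noise[sp].append((cid, chrom_noise, evalue))
                rows.append([
                    cid, chrom_noise, round(rng.uniform(70, 85), 2), length,
                    int(rng.integers(10, 60)), int(rng.integers(0, 8)),
                    1, length, sstart, sstart + length - 1, evalue,
                    round(rng.uniform(40, 90), 1),
                ])
        tables[sp] = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
    return tables, truth


def write_hits_tabular(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", header=False, index=False)


def true_map_from_genome(
    genome: TrueGenome,
    splits: dict[int, float] | None = None,
    marker_subset: set[str] | None = None,
) -> GeneticMap:
    """The noiseless linkage map implied by the planted genome.

    ``splits`` optionally breaks a chromosome (by index) at a cM breakpoint
    into two linkage groups, emulating the surplus groups a sparse dataset
    produces.  Groups are numbered by decreasing length like a built map.
    """
    splits = splits or {}
    buckets: dict[tuple[int, int], list[SimMarker]] = {}
    for m in genome.markers:
        if marker_subset is not None and m.id not in marker_subset:
            continue
        part = 0
        if m.chrom in splits and m.pos_cm > splits[m.chrom]:
            part = 1
        buckets.setdefault((m.chrom, part), []).append(m)
    groups = []
    for key in sorted(buckets):
        ms = sorted(buckets[key], key=lambda m: (m.pos_cm, m.id))
        if len(ms) < 2:
            continue
        base = ms[0].pos_cm
        groups.append(
            LinkageGroup("", [m.id for m in ms],
                         np.array([m.pos_cm - base for m in ms]))
        )
    groups.sort(key=lambda g: (-g.length_cm, -g.n_markers, min(g.marker_ids)))
    for k, g in enumerate(groups, start=1):
        g.group_id = f"LG{k}"
    contig_of = {m.id: m.contig_id for m in genome.markers}
    placed = {m for g in groups for m in g.marker_ids}
    unmapped = sorted(
        m.id for m in genome.markers
        if m.id not in placed and (marker_subset is None or m.id in marker_subset)
    )
    return GeneticMap(groups, unmapped, map_stats(groups), contig_of)
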