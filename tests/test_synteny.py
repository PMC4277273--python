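"""BLAST-tabular parsing, Oxford grids, syntenic regions and chromosome
assignment."""

import numpy as np
import pandas as pd
import pytest

from solemap.genome_length import Karyotype
from solemap.synteny import (
    HitTableError,
    OxfordGrid,
    SyntenyScheme,
    assign_chromosomes,
    oxford_grid,
    read_hits_tabular,
    syntenic_regions,
)
from solemap.simulate import (
    SimConfig,
    simulate_genome,
    simulate_hits,
    true_map_from_genome,
    write_hits_tabular,
)


def _row(contig, chrom, evalue, bits, sstart=100, send=600):
    return "\t".join(map(str, [
        contig, chrom, 95.0, 500, 5, 0, 1, 500, sstart, send, evalue, bits,
    ]))


class TestReadHits:
    def test_filter_and_best_hit(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join([
            _row("c1", "S1", 1e-20, 200.0),
            _row("c1", "S1", 1e-12, 150.0),
            _row("c1", "S1", 1e-5, 90.0),
        ]) + "\n")
        hits = read_hits_tabular(path, "stickleback")
        assert len(hits) == 1
        assert hits[0].e_value == 1e-20 and hits[0].bit_score == 200.0

    def test_boundary_evalue_excluded(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_row("c1", "S1", 1e-10, 100.0) + "\n")
        assert read_hits_tabular(path, "s") == []

    def test_minus_strand_normalized(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_row("c1", "S1", 1e-20, 200.0, sstart=900, send=400) + "\n")
        (hit,) = read_hits_tabular(path, "s")
        assert (hit.subject_start, hit.subject_end, hit.strand) == (400, 900, "-")

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_row("c1", "S1", 1e-20, 200.0) + "\nc2\tS1\tbroken\n")
        with pytest.raises(HitTableError, match="line 2"):
            read_hits_tabular(path, "s")

    def test_simulated_retained_equals_truth(self, tmp_path):
        cfg = SimConfig(seed=9, n_chromosomes=4, n_snps=60,
                        n_single_snp_contigs=60, n_multi_snp_contigs=0,
                        n_microsatellites=0,
                        detectability={s: 0.6 for s in
                                       ("stickleback", "tilapia",
                                        "medaka", "pufferfish")})
        genome = simulate_genome(cfg)
        tables, truth = simulate_hits(genome, cfg)
        sp = "stickleback"
        path = tmp_path / "hits.tsv"
        write_hits_tabular(tables[sp], path)
        hits = read_hits_tabular(path, sp)
        got = {(h.contig_id, h.chromosome) for h in hits}
        true_hits = {
            (row.qseqid, row.sseqid)
            for row in tables[sp].itertuples()
            if row.evalue < 1e-10
        }
        assert got == true_hits
        # every injected noise hit at or above threshold was dropped
        weak = {(c, ch) for c, ch, e in truth.noise[sp] if e >= 1e-10}
        assert not (got & (weak - true_hits))


def _small_world(seed=13, n_fusions=0, noise=0.0, det=1.0, splits=None):
    cfg = SimConfig(
        seed=seed, n_chromosomes=6, n_snps=72, n_single_snp_contigs=72,
        n_multi_snp_contigs=0, n_microsatellites=0, n_fusions=n_fusions,
        paralog_noise_rate=noise,
        detectability={s: det for s in
                       ("stickleback", "tilapia", "medaka", "pufferfish")},
    )
    genome = simulate_genome(cfg)
    gmap = true_map_from_genome(genome, splits=splits)
    tables, truth = simulate_hits(genome, cfg)
    hits = {}
    for sp, table in tables.items():
        keep = table[table.evalue < 1e-10]
        hits[sp] = [
            h for h in _frame_to_hits(keep, sp)
        ]
    return cfg, genome, gmap, hits, truth


def _frame_to_hits(frame, species):
    import io
    from solemap.synteny import read_hits_tabular as _read
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", header=False, index=False)
    import tempfile, os
    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        fh.write(buf.getvalue())
        name = fh.name
    try:
        return _read(name, species)
    finally:
        os.unlink(name)


class TestOxfordGrid:
    def test_single_contig_count(self):
        from solemap.linkage import GeneticMap, LinkageGroup, MapStats
        from solemap.synteny import HomologyHit
        lg = LinkageGroup("LG1", ["m1"], np.array([0.0]))
        gmap = GeneticMap([lg], [], MapStats(0, 0, 0, 1, 1), {"m1": "c1"})
        hit = HomologyHit("c1", "medaka", "M5", 10, 20, "+", 1e-30, 200.0)
        grid = oxford_grid(gmap, {"medaka": [hit]})
        assert grid.count("LG1", "medaka", "M5") == 1

    def test_contig_distinct_counting(self):
        from solemap.linkage import GeneticMap, LinkageGroup, MapStats
        from solemap.synteny import HomologyHit
        lg = LinkageGroup("LG1", ["m1", "m2"], np.array([0.0, 1.0]))
        gmap = GeneticMap([lg], [], MapStats(1, 1, 1, 2, 1),
                          {"m1": "c1", "m2": "c1"})  # two SNPs, one contig
        hits = [HomologyHit("c1", "medaka", "M5", 10, 20, "+", 1e-30, 200.0)]
        grid = oxford_grid(gmap, {"medaka": hits})
        assert grid.count("LG1", "medaka", "M5") == 1

    def test_paralog_flagged_and_counted_per_chromosome(self):
        from solemap.linkage import GeneticMap, LinkageGroup, MapStats
        from solemap.synteny import HomologyHit
        lg = LinkageGroup("LG1", ["m1"], np.array([0.0]))
        gmap = GeneticMap([lg], [], MapStats(0, 0, 0, 1, 1), {"m1": "c1"})
        hits = [
            HomologyHit("c1", "medaka", "M5", 10, 20, "+", 1e-30, 200.0),
            HomologyHit("c1", "medaka", "M9", 10, 20, "+", 1e-15, 90.0),
        ]
        grid = oxford_grid(gmap, {"medaka": hits})
        assert grid.count("LG1", "medaka", "M5") == 1
        assert grid.count("LG1", "medaka", "M9") == 1
        assert grid.paralog_flags == {("medaka", "c1"): ["M5", "M9"]}
        # best-hit counting keeps only the strongest chromosome
        assert int(grid.best_counts.loc["LG1", ("medaka", "M9")]) == 0

    def test_simulated_argmax_recovers_homolog(self):
        cfg, genome, gmap, hits, truth = _small_world(seed=13)
        grid = oxford_grid(gmap, hits)
        lg_by_chrom = {}
        for gi, lg in enumerate(gmap.groups):
            chrom = genome.markers[0].chrom
        # true LG of each unit: the group holding that chromosome's markers
        marker_chrom = {m.id: m.chrom for m in genome.markers}
        for col in grid.counts.columns:
            sp, ch = col
            unit = int(ch[1:]) - 1
            best_lg = grid.counts[col].idxmax()
            chroms = {marker_chrom[m] for m in
                      next(g for g in gmap.groups
                           if g.group_id == best_lg).marker_ids}
            assert chroms == {unit}


class TestSyntenicRegions:
    def test_span_arithmetic(self):
        from solemap.linkage import GeneticMap, LinkageGroup, MapStats
        from solemap.synteny import HomologyHit
        lg = LinkageGroup("LG3", ["m1", "m2"], np.array([0.0, 1.0]))
        gmap = GeneticMap([lg], [], MapStats(1, 1, 1, 2, 1),
                          {"m1": "c1", "m2": "c2"})
        hits = [
            HomologyHit("c1", "tilapia", "T7", 100, 200, "+", 1e-30, 200.0),
            HomologyHit("c2", "tilapia", "T7", 900, 1000, "+", 1e-30, 200.0),
        ]
        regions, summary = syntenic_regions(gmap, {"tilapia": hits})
        assert len(regions) == 1
        assert regions[0].span_bp == 901
        assert summary.loc[0, "n_regions"] == 1

    def test_below_min_shared_no_region(self):
        from solemap.linkage import GeneticMap, LinkageGroup, MapStats
        from solemap.synteny import HomologyHit
        lg = LinkageGroup("LG3", ["m1"], np.array([0.0]))
        gmap = GeneticMap([lg], [], MapStats(0, 0, 0, 1, 1), {"m1": "c1"})
        hits = [HomologyHit("c1", "tilapia", "T7", 100, 200, "+", 1e-30, 200.0)]
        regions, _ = syntenic_regions(gmap, {"tilapia": hits})
        assert regions == []

    def test_rearrangement_free_one_region_per_pair(self):
        cfg, genome, gmap, hits, truth = _small_world(seed=21)
        regions, _ = syntenic_regions(gmap, hits)
        pairs = {(r.lg, r.species, r.chromosome) for r in regions}
        assert len(pairs) == len(regions)  # no duplicated (lg, chromosome)
        for r in regions:
            unit = int(r.chromosome[1:]) - 1
            marker_chrom = {m.id: m.chrom for m in genome.markers}
            lg_chroms = {marker_chrom[m] for m in
                         next(g for g in gmap.groups
                              if g.group_id == r.lg).marker_ids}
            assert lg_chroms == {unit}


class TestAssignment:
    def test_planted_fusion_flagged_and_surplus_merged(self):
        # chromosome 0 = fusion of units 0+1; chromosome 3 split into two LGs
        cfg, genome, gmap, hits, truth = _small_world(
            seed=33, n_fusions=1, noise=0.05,
            splits={3: 30.0},
        )
        grid = oxford_grid(gmap, hits)
        result = assign_chromosomes(grid, genome.scheme,
                                    Karyotype(haploid_n=6, n_acrocentric=0))
        fusions = [a for a in result.assignments if a.is_fusion]
        assert len(fusions) == 1
        assert sorted(fusions[0].synteny_labels) == ["A1", "A2"]
        # the split-off part of chromosome 3 merged back
        marker_chrom = {m.id: m.chrom for m in genome.markers}
        merged = {lg for a in result.assignments for lg in a.merged_lgs}
        assert len(merged) == 1
        (mlg,) = merged
        chroms = {marker_chrom[m] for m in
                  next(g for g in gmap.groups if g.group_id == mlg).marker_ids}
        assert chroms == {3}
        host = next(a for a in result.assignments if mlg in a.merged_lgs)
        host_chroms = {marker_chrom[m] for m in
                       next(g for g in gmap.groups
                            if g.group_id == host.primary_lg).marker_ids}
        assert host_chroms == {3}
        assert result.unplaced_lgs == []

    def test_conflicted_surplus_left_unplaced(self):
        counts = pd.DataFrame(
            [[5, 0, 0], [0, 5, 0], [2, 2, 0]],
            index=["LG1", "LG2", "LG3"],
            columns=pd.MultiIndex.from_tuples(
                [("s", "S1"), ("s", "S2"), ("s", "S3")],
                names=["species", "chromosome"],
            ),
        )
        grid = OxfordGrid(counts=counts, best_counts=counts)
        scheme = SyntenyScheme({"A1": {"s": "S1"}, "A2": {"s": "S2"}})
        result = assign_chromosomes(grid, scheme, Karyotype(6, 0))
        assert result.unplaced_lgs == ["LG3"]
        assert any("LG3" in c for c in result.conflicts)

    def test_empty_grid_errors(self):
        grid = OxfordGrid(
            counts=pd.DataFrame(
                index=pd.Index([]),
                columns=pd.MultiIndex.from_tuples([],
                                                  names=["species",
                                                         "chromosome"]),
            ),
            best_counts=None,
        )
        with pytest.raises(ValueError, match="empty"):
            assign_chromosomes(grid, SyntenyScheme({}), Karyotype(6, 0))


def test_scheme_yaml_roundtrip(tmp_path):
    scheme = SyntenyScheme({"A1": {"stickleback": "S1", "medaka": "M1"},
                            "B1a": {"stickleback": "S4"}})
    path = tmp_path / "scheme.yaml"
    scheme.to_yaml(path)
    again = SyntenyScheme.from_yaml(path)
    assert again.labels == scheme.labels
    assert again.labels_of("stickleback", "S4") == ["B1a"]
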