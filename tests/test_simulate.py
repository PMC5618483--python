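"""The synthetic-data generator: planted truth, determinism, error paths."""

import numpy as np
import pandas as pd
import pytest

from snrkfam.expression import ddct
from snrkfam.promoter import scan
from snrkfam.simulate import (REFERENCE_GENE, ConfigError, GenerationError,
                              GeneratorConfig, TruthTable, gen_expression,
                              gen_genome, gen_promoters, gen_qpcr,
                              write_fixture_set)
from snrkfam.structure import write_gff3


def _placements(rows):
    return pd.DataFrame(rows, columns=["gene", "group", "element", "pattern",
                                       "position", "strand"])


class TestConfig:
    def test_group_sizes_must_sum_to_family_size(self):
        with pytest.raises(ConfigError):
            gen_genome(GeneratorConfig(family_size=10, group_sizes=(6, 4, 8, 4)))

    def test_promoter_must_fit_longest_pattern(self, catalog):
        cfg = GeneratorConfig(promoter_length=8)
        with pytest.raises(ConfigError):
            cfg.validate(catalog)

    def test_family_size_zero_yields_empty_truth(self):
        cfg = GeneratorConfig(family_size=0, group_sizes=(0, 0, 0, 0),
                              decoy_near=0, decoy_unrelated=0)
        syn = gen_genome(cfg)
        assert syn.truth.planted_genes == []
        assert syn.models == []


class TestDeterminism:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = GeneratorConfig(seed=9, decoy_unrelated=1, decoy_near=1)
        outs = []
        for run in ("a", "b"):
            syn = gen_genome(cfg)
            d = tmp_path / run
            d.mkdir()
            write_gff3(syn.models, d / "genes.gff3")
            fasta = "".join(f">{c}\n{s}\n" for c, s in syn.genome.items())
            (d / "genome.fasta").write_text(fasta)
            outs.append(((d / "genes.gff3").read_bytes(),
                         (d / "genome.fasta").read_bytes()))
        assert outs[0] == outs[1]

    def test_different_seed_changes_sequence(self):
        a = gen_genome(GeneratorConfig(seed=1))
        b = gen_genome(GeneratorConfig(seed=2))
        assert a.genome != b.genome


class TestGenPromoters:
    def test_overlapping_placements_merge_base_consistently(self, catalog):
        rows = _placements([
            ("g", 2, "GARE-motif", "AAACAGA", 314, "+"),
            ("g", 2, "TCA-element", "CAGAAAAGGA", 317, "+"),
        ])
        windows, truth = gen_promoters(catalog, rows, seed=0)
        assert windows["g"][313:326] == "AAACAGAAAAGGA"
        assert len(truth.planted_elements) == 2
        assert truth.dropped_placements == []

    def test_planted_pattern_substring_arithmetic(self, catalog):
        rows = _placements([("g", 3, "ABRE", "CCTACGTGGC", 1349, "+")])
        windows, _ = gen_promoters(catalog, rows, seed=0)
        w = windows["g"]
        assert w[1348:1358] == "CCTACGTGGC"
        assert w[1350:1356] == "TACGTG"
        assert w[1351:1358] == "ACGTGGC"

    def test_minus_strand_plants_reverse_complement(self, catalog):
        rows = _placements([("g", 1, "CGTCA-motif", "CGTCA", 410, "-")])
        windows, _ = gen_promoters(catalog, rows, seed=0)
        assert windows["g"][409:414] == "TGACG"

    def test_conflicting_bases_raise_or_skip(self, catalog):
        rows = _placements([
            ("g", 1, "TGACG-motif", "TGACG", 834, "+"),
            ("g", 1, "TGA-element", "AACGAC", 836, "-"),
        ])
        with pytest.raises(GenerationError):
            gen_promoters(catalog, rows, seed=0, on_conflict="error")
        windows, truth = gen_promoters(catalog, rows, seed=0,
                                       on_conflict="skip")
        assert truth.dropped_placements == [("g", "TGA-element", "AACGAC",
                                             836, "-")]
        assert windows["g"][833:838] == "TGACG"

    def test_ambiguous_pattern_cannot_be_planted(self, catalog):
        rows = _placements([("g", 1, "amb", "ACGN", 100, "+")])
        with pytest.raises(GenerationError):
            gen_promoters(catalog, rows, seed=0)

    def test_out_of_window_placement_rejected(self, catalog):
        rows = _placements([("g", 1, "ERE", "ATTTCAAA", 1998, "+")])
        with pytest.raises(ConfigError):
            gen_promoters(catalog, rows, seed=0)

    def test_clean_background_has_zero_catalog_hits(self, catalog):
        windows, truth = gen_promoters(catalog, _placements([]),
                                       genes=["empty"], seed=3)
        assert truth.planted_elements == []
        assert scan(windows["empty"], catalog) == []

    def test_background_never_creates_hits_next_to_planted(self, catalog):
        rows = _placements([("g", 3, "ABRE", "TACGTG", 516, "+")])
        windows, _ = gen_promoters(catalog, rows, seed=5)
        hits = scan(windows["g"], catalog)
        assert [(h.element, h.index, h.strand) for h in hits] == \
            [("ABRE", 516, "+")]


class TestGenExpression:
    def test_block_correlation_exceeds_half_target(self):
        cfg = GeneratorConfig(seed=1)
        truth = TruthTable()
        truth.planted_genes = []  # gene list supplied via blocks below
        genes = [f"g{i}" for i in range(3)]
        from snrkfam.simulate import PlantedGene
        truth.planted_genes = [PlantedGene(g, 1, 9, ()) for g in genes]
        truth.expression_blocks = [(tuple(genes), 0.9)]
        counts, _, _ = gen_expression(cfg, truth, seed=1)
        r = np.corrcoef(counts.to_numpy().astype(float))
        iu = np.triu_indices(3, 1)
        assert (r[iu] > 0.5).all()

    def test_independent_genes_have_low_mean_abs_pcc(self):
        from snrkfam.simulate import PlantedGene
        cfg = GeneratorConfig(seed=0)
        genes = [f"g{i}" for i in range(10)]
        vals = []
        for seed in range(100):
            truth = TruthTable(planted_genes=[PlantedGene(g, 1, 9, ())
                                              for g in genes])
            counts, _, _ = gen_expression(cfg, truth, seed=seed)
            r = np.corrcoef(counts.to_numpy().astype(float))
            vals.append(np.abs(r[np.triu_indices(10, 1)]).mean())
        assert np.mean(vals) < 0.2

    def test_counts_are_nonnegative_integers(self, default_genome):
        counts, L, N = gen_expression(GeneratorConfig(seed=42),
                                      default_genome.truth)
        assert (counts.to_numpy() >= 0).all()
        assert counts.to_numpy().dtype.kind == "i"
        assert counts.shape == (22, 28)

    def test_single_tissue_rejected(self, default_genome):
        with pytest.raises(ConfigError):
            gen_expression(GeneratorConfig(tissue_count=1),
                           default_genome.truth)

    def test_correlation_target_must_be_open_interval(self, default_genome):
        truth = default_genome.truth
        bad = TruthTable(planted_genes=truth.planted_genes,
                         expression_blocks=[(("a", "b"), 1.0)])
        with pytest.raises(ConfigError):
            gen_expression(GeneratorConfig(), bad)


class TestGenQpcr:
    def _truth(self, effects):
        from snrkfam.simulate import PlantedGene
        genes = sorted({e[0] for e in effects} | {"flat"})
        return TruthTable(planted_genes=[PlantedGene(g, 1, 9, ())
                                         for g in genes],
                          qpcr_effects=effects)

    def test_noise_free_fold_change_recovered_exactly(self):
        cfg = GeneratorConfig(noise_sd_ct=0.0)
        truth = self._truth([("gA", "NaCl", 8.0, 4.0)])
        fc = ddct(gen_qpcr(cfg, truth, seed=0), REFERENCE_GENE)
        row = fc[(fc.gene == "gA") & (fc.treatment == "NaCl")
                 & (fc.time_h == 8.0)]
        assert row.fold_change.iloc[0] == pytest.approx(4.0)

    def test_large_fold_change_recovered_within_tolerance(self):
        cfg = GeneratorConfig(noise_sd_ct=0.1)
        truth = self._truth([("gA", "NaCl", 8.0, 18.0)])
        fc = ddct(gen_qpcr(cfg, truth, seed=3), REFERENCE_GENE)
        row = fc[(fc.gene == "gA") & (fc.treatment == "NaCl")
                 & (fc.time_h == 8.0)]
        assert 14.0 <= row.fold_change.iloc[0] <= 22.0

    def test_nonpositive_fold_change_rejected(self):
        truth = self._truth([("gA", "NaCl", 8.0, 0.0)])
        with pytest.raises(ConfigError):
            gen_qpcr(GeneratorConfig(), truth)

    def test_replicate_layout(self, default_genome):
        cfg = GeneratorConfig(seed=4)
        ct = gen_qpcr(cfg, default_genome.truth)
        layout = ct.groupby(["gene", "treatment", "time_h"]).size()
        assert (layout == cfg.replicate_count).all()
        assert set(ct.treatment) == {"control", "NaCl", "ABA", "rac-GR24"}
        assert (ct[ct.gene == REFERENCE_GENE].ct - 20.0).abs().max() < 1.5


def test_fixture_bundle_is_complete(tmp_path, default_genome):
    cfg = GeneratorConfig(seed=42)
    paths = write_fixture_set(default_genome, cfg, tmp_path)
    for key in ("genome", "gff3", "proteins", "promoters", "counts",
                "lengths", "totals", "ct", "truth_genes", "truth_elements",
                "ref_labels"):
        assert paths[key].exists() and paths[key].stat().st_size > 0
    truth_genes = pd.read_csv(paths["truth_genes"], sep="\t")
    assert len(truth_genes) == 22
    assert set(truth_genes.group) == {1, 2, 3, 4}
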