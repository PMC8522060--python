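import numpy as np
import pytest
from scipy.stats import chisquare

from glycomet.refdb import FamilyCode
from glycomet.simulate import (BACK_TABLE, EnvironmentSpec, GeneRecord,
                               GenomeModel, _mutate_protein, back_translate,
                               build_benchmark, fragment_gene,
                               sample_fragments, synth_genome,
                               synth_metagenome, synth_reference_db)
from glycomet.search import six_frame_translate


class TestFragmentation:
    @pytest.mark.parametrize("length, expected", [
        (350, 3), (300, 3), (99, 0), (0, 0), (100, 1),
    ])
    def test_window_count(self, length, expected):
        windows = fragment_gene("A" * length, read_len=100)
        assert len(windows) == expected
        assert all(len(w) == 100 for w in windows)

    def test_windows_tile_from_five_prime(self):
        cds = "".join(np.random.default_rng(0).choice(list("ACGT"), 350))
        windows = fragment_gene(cds, 100)
        assert windows == [cds[0:100], cds[100:200], cds[200:300]]

    def test_sampling_cardinality_and_fallback(self):
        windows = list("abcdefghij")
        assert len(sample_fragments(windows, k=3, seed=1)) == 3
        assert sample_fragments(["a", "b"], k=3, seed=1) == ["a", "b"]

    def test_sampling_deterministic(self):
        windows = list(range(10))
        assert sample_fragments(windows, 3, seed=5) == \
            sample_fragments(windows, 3, seed=5)

    def test_sampled_windows_distinct(self):
        got = sample_fragments(list(range(50)), k=3, seed=2)
        assert len(set(got)) == 3


class TestBenchmark:
    def test_counts_and_labels(self):
        fam = FamilyCode.parse("GH13")
        genome = GenomeModel("g", [
            GeneRecord("true1", "ATG" * 100, True, fam),   # 300 nt
            GeneRecord("false1", "C" * 100, False),        # 100 nt
        ])
        bench = build_benchmark(genome, seed=3)
        labels = [f.truth_label for f in bench.fragments]
        assert labels.count(True) == 3 and labels.count(False) == 1

    def test_all_genes_too_short(self):
        genome = GenomeModel("g", [GeneRecord("a", "ACGT" * 10, False)])
        bench = build_benchmark(genome, read_len=100, seed=0)
        assert bench.fragments == []

    def test_fixture_counts_match_brute_force(self):
        # 30 True + 70 False genes, 300 nt each -> 300 fragments, 90 True
        fam = FamilyCode.parse("GT2")
        rng = np.random.default_rng(4)
        genes = []
        for i in range(100):
            cds = "".join(rng.choice(list("ACGT"), 300))
            genes.append(GeneRecord(f"gene{i}", cds, i < 30,
                                    fam if i < 30 else None))
        genome = GenomeModel("g", genes)
        bench = build_benchmark(genome, read_len=100, k=3, seed=1)
        expected_true = sum(min(3, len(g.cds) // 100)
                            for g in genes if g.label)
        expected_total = sum(min(3, len(g.cds) // 100) for g in genes)
        assert len(bench.fragments) == expected_total == 300
        assert sum(f.truth_label for f in bench.fragments) \
            == expected_true == 90

    def test_fragment_labels_match_source_genes(self):
        fam = FamilyCode.parse("GH1")
        genes = [GeneRecord(f"g{i}", "ATGAAA" * 60, i % 2 == 0,
                            fam if i % 2 == 0 else None) for i in range(10)]
        bench = build_benchmark(GenomeModel("G", genes), seed=8)
        by_id = {g.gene_id: g for g in genes}
        for frag in bench.fragments:
            assert frag.truth_label == by_id[frag.source_gene].label

    def test_read_ids_encode_genome_gene_offset(self):
        genome = GenomeModel("gX", [GeneRecord(
            "gene0", "A" * 90 + "ATGGCC" + "A" * 204, False)])
        bench = build_benchmark(genome, seed=0)
        for frag in bench.fragments:
            gid, gene, offset = frag.read_id.split("|")
            assert gid == "gX" and gene == "gene0"
            cds = genome.genes[0].cds
            assert cds[int(offset):int(offset) + 100] == frag.dna


class TestBackTranslation:
    def test_roundtrip_through_translation(self):
        protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        cds = back_translate(protein)
        plus1 = next(f for f in six_frame_translate(cds, "r")
                     if f.frame == "+1")
        assert plus1.peptide == protein

    def test_table_covers_the_twenty_amino_acids(self):
        assert sorted(BACK_TABLE) == sorted("ACDEFGHIKLMNPQRSTVWY")


class TestSynthReferenceDB:
    def test_sizes_and_lengths(self):
        db = synth_reference_db(n_proteins=200, length_range=(150, 400),
                                seed=0)
        assert len(db) == 200
        assert all(150 <= len(p.sequence) <= 400 for p in db)

    def test_deterministic_per_seed(self):
        a = synth_reference_db(50, seed=9)
        b = synth_reference_db(50, seed=9)
        assert [(p.accession, p.sequence, p.families) for p in a] == \
            [(p.accession, p.sequence, p.families) for p in b]

    def test_family_assignment_uniform(self):
        pool = [f"GH{i}" for i in range(1, 11)]
        db = synth_reference_db(2000, family_pool=pool, seed=3)
        counts = {f: 0 for f in pool}
        for p in db:
            counts[str(p.families[0])] += 1
        stat, p_value = chisquare(list(counts.values()))
        assert p_value > 0.01


class TestSynthGenome:
    def test_composition(self, small_refdb):
        g = synth_genome(small_refdb, n_true=10, n_decoy_random=20,
                         n_decoy_homolog=5, seed=2)
        assert len(g.genes) == 35
        assert sum(gene.label for gene in g.genes) == 10
        for gene in g.genes:
            if gene.label:
                assert gene.family is not None

    def test_true_genes_are_exact_back_translations(self, small_refdb):
        g = synth_genome(small_refdb, n_true=5, n_decoy_random=0,
                         n_decoy_homolog=0, seed=1)
        ref_cds = {back_translate(p.sequence) for p in small_refdb}
        assert all(gene.cds in ref_cds for gene in g.genes)

    def test_too_many_true_genes_is_fatal(self, small_refdb):
        with pytest.raises(ValueError):
            synth_genome(small_refdb, n_true=len(small_refdb) + 1, seed=0)

    def test_mutation_hits_target_identity(self):
        rng = np.random.default_rng(6)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300))
        mutated = _mutate_protein(protein, 0.8, rng)
        identity = sum(a == b for a, b in zip(protein, mutated)) / 300
        assert abs(identity - 0.8) <= 0.02


class TestSynthMetagenome:
    SPEC = {
        "envA": EnvironmentSpec(["GH13", "GT2"], n_samples=4,
                                reads_per_sample=200,
                                background_fraction=0.2),
        "envB": EnvironmentSpec(["GT2"], n_samples=4, reads_per_sample=200,
                                background_fraction=0.2),
    }

    def _refdb(self):
        return synth_reference_db(30, family_pool=["GH13", "GT2", "PL1"],
                                  seed=21)

    def test_shapes(self):
        meta = synth_metagenome(self.SPEC, self._refdb(), seed=1)
        assert len(meta.reads) == 8
        assert len(meta.sample_table) == 8
        assert all(len(v) == 200 for v in meta.reads.values())

    def test_family_restricted_to_its_environment(self):
        meta = synth_metagenome(self.SPEC, self._refdb(), seed=1)
        env_of = dict(zip(meta.sample_table.sample_id,
                          meta.sample_table.environment))
        fams_by_env = {}
        for rid, sid, fam in meta.truth.itertuples(index=False):
            if fam:
                fams_by_env.setdefault(env_of[sid], set()).add(fam)
        assert fams_by_env["envA"] == {"GH13", "GT2"}
        assert fams_by_env["envB"] == {"GT2"}

    def test_background_fraction_binomial(self):
        spec = {"e": EnvironmentSpec(["GH13"], n_samples=1,
                                     reads_per_sample=1000,
                                     background_fraction=0.5)}
        meta = synth_metagenome(spec, self._refdb(), seed=13)
        n_bg = (meta.truth.family == "").sum()
        sd = np.sqrt(1000 * 0.5 * 0.5)
        assert abs(n_bg - 500) <= 4 * sd

    def test_bit_reproducible(self):
        a = synth_metagenome(self.SPEC, self._refdb(), seed=77)
        b = synth_metagenome(self.SPEC, self._refdb(), seed=77)
        assert a.reads == b.reads
        assert a.sample_table.equals(b.sample_table)

    def test_empty_spec_fatal(self):
        with pytest.raises(ValueError):
            synth_metagenome({}, self._refdb(), seed=0)
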