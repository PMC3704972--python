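import pytest

from cdpkfam import duplication as dup, synthetic_data as sd
from cdpkfam.errors import InputError
from cdpkfam.phylogeny import global_align, pairwise_stats
from cdpkfam.seqio import GeneModel, ProteinRecord


def _model(gene_id, chrom, start, length=300, strand="+"):
    return GeneModel(gene_id, f"{gene_id}_T01", chrom, strand,
                     exons=[(start, start + length)],
                     cds_segments=[(start, start + length)])


def _family_inputs(genome):
    primary = {}
    for m in genome.models:
        primary.setdefault(m.gene_id, m)
    fam_ids = set(genome.truth.family_member_ids)
    records = [r for r in genome.proteins if r.id in fam_ids]
    models = {r.id: primary[r.id] for r in records}
    return records, models, dup.GeneIndex(genome.models)


class TestCriteria:
    def test_identical_pair_on_different_chromosomes(self):
        seq = "MGNACSGA" + "ACDEFGHIKLMNPQRSTVWY" * 10
        records = [ProteinRecord("gA", seq), ProteinRecord("gB", seq)]
        models = {"gA": _model("gA", "chr1", 0), "gB": _model("gB", "chr2", 0)}
        events = dup.find_duplications(records, models)
        assert len(events) == 1
        e = events[0]
        assert (e.kind, e.coverage, e.identity) == ("segmental", 1.0, 1.0)

    def test_low_identity_pair_yields_no_event(self):
        # ~75% identity: every 4th residue differs
        base = list("ACDEFGHIKLMNPQRSTVWY" * 10)
        other = base.copy()
        for i in range(0, len(other), 4):
            other[i] = "W" if other[i] != "W" else "A"
        a, b = "".join(base), "".join(other)
        stats = pairwise_stats(global_align(a, b), len(a))
        assert stats.identity <= 0.80  # construction sanity
        records = [ProteinRecord("gA", a), ProteinRecord("gB", b)]
        models = {"gA": _model("gA", "chr1", 0), "gB": _model("gB", "chr2", 0)}
        assert dup.find_duplications(records, models) == []

    def test_missing_model_errors_with_gene_name(self):
        records = [ProteinRecord("gA", "ACDEF" * 20),
                   ProteinRecord("gB", "ACDEF" * 20)]
        with pytest.raises(InputError, match="gB"):
            dup.find_duplications(records, {"gA": _model("gA", "chr1", 0)})

    def test_invalid_threshold_rejected(self):
        with pytest.raises(InputError):
            dup.DuplicationCriteria(min_identity=1.5)


class TestClassification:
    def test_adjacent_same_chromosome_is_tandem(self):
        models = [_model("a", "chr1", 0), _model("b", "chr1", 1000)]
        idx = dup.GeneIndex(models)
        assert dup.classify_event(models[0], models[1], idx) == "tandem"

    def test_many_intervening_genes_is_segmental(self):
        models = [_model(f"g{i:02d}", "chr1", i * 1000) for i in range(42)]
        idx = dup.GeneIndex(models)
        assert dup.classify_event(models[0], models[41], idx) == "segmental"

    def test_different_chromosomes_is_segmental(self):
        a, b = _model("a", "chr1", 0), _model("b", "chr2", 0)
        idx = dup.GeneIndex([a, b])
        assert dup.classify_event(a, b, idx) == "segmental"


class TestChromosomeSummary:
    def test_counts_per_chromosome(self):
        models = [_model("a", "chr1", 0), _model("b", "chr1", 10_000),
                  _model("c", "chr1", 20_000), _model("d", "chr2", 0)]
        summary = dup.chromosome_summary(models)
        assert summary["chr1"]["count"] == 3
        assert summary["chr2"]["count"] == 1
        assert summary["chr1"]["clustered"]  # 3 genes within 5 Mb

    def test_empty_input(self):
        assert dup.chromosome_summary([]) == {}

    def test_synthetic_counts_match_ground_truth(self, small_genome):
        fam = set(small_genome.truth.family_member_ids)
        primary = {}
        for m in small_genome.models:
            if m.gene_id in fam:
                primary.setdefault(m.gene_id, m)
        summary = dup.chromosome_summary(list(primary.values()))
        assert sum(v["count"] for v in summary.values()) == len(fam)


class TestPlantedRecovery:
    def test_study_scale_genome_recovers_ten_segmental_four_tandem(
        self, study_genome
    ):
        records, models, index = _family_inputs(study_genome)
        events = dup.find_duplications(records, models, gene_index=index)
        found = {(e.gene_a, e.gene_b): e.kind for e in events}
        truth = {(d["gene_a"], d["gene_b"]): d["kind"]
                 for d in study_genome.truth.duplications}
        assert found == truth
        kinds = sorted(found.values())
        assert kinds.count("segmental") == 10
        assert kinds.count("tandem") == 4

    def test_low_identity_plants_rejected(self):
        genome = sd.generate_family_genome(sd.GeneratorConfig(
            seed=5,
            groups=(sd.GroupSpec("I", 6),),
            duplications=(sd.DuplicationSpec("segmental", 0.70),
                          sd.DuplicationSpec("tandem", 0.70)),
            n_chromosomes=4, n_background_genes=10,
        ))
        records, models, index = _family_inputs(genome)
        events = dup.find_duplications(records, models, gene_index=index)
        assert events == []

    def test_events_self_consistent(self, study_genome):
        """Stored coverage/identity re-verify against fresh alignments."""
        records, models, index = _family_inputs(study_genome)
        events = dup.find_duplications(records, models, gene_index=index)
        seqs = {r.id: r.sequence for r in records}
        for e in events:
            a, b = seqs[e.gene_a], seqs[e.gene_b]
            stats = pairwise_stats(global_align(a, b), max(len(a), len(b)))
            assert stats.coverage == pytest.approx(e.coverage)
            assert stats.identity == pytest.approx(e.identity)
            assert stats.coverage > 0.80 and stats.identity > 0.80

    def test_symmetric_under_input_order(self, small_genome):
        records, models, index = _family_inputs(small_genome)
        fwd = dup.find_duplications(records, models, gene_index=index)
        rev = dup.find_duplications(list(reversed(records)), models,
                                    gene_index=index)
        assert fwd == rev

    def test_raising_identity_threshold_monotone(self, small_genome):
        records, models, index = _family_inputs(small_genome)
        loose = dup.find_duplications(
            records, models, dup.DuplicationCriteria(min_identity=0.80),
            gene_index=index)
        strict = dup.find_duplications(
            records, models, dup.DuplicationCriteria(min_identity=0.95),
            gene_index=index)
        assert len(strict) <= len(loose)
        assert {(e.gene_a, e.gene_b) for e in strict} <= {
            (e.gene_a, e.gene_b) for e in loose
        }
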