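"""Synthetic-data generator: genes, evolution, lesions, genomes and reads."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relicscan import simulate as sim
from relicscan.formats import Interval, write_fasta, write_gtf
from relicscan.lesions import reconstruct_orf
from relicscan.reconstruct import STOP_CODONS, translate


class TestGeneBlueprint:
    def test_cds_must_be_codon_multiple(self):
        with pytest.raises(ValueError):
            sim.GeneBlueprint(n_exons=1, exon_lengths=(10,))

    def test_intron_minimum(self):
        with pytest.raises(ValueError):
            sim.GeneBlueprint(n_exons=2, exon_lengths=(6, 6), intron_lengths=(3,))

    def test_exon_count_mismatch(self):
        with pytest.raises(ValueError):
            sim.GeneBlueprint(n_exons=2, exon_lengths=(9,))


class TestMakeGene:
    def test_smallest_gene(self):
        bp = sim.GeneBlueprint(n_exons=1, exon_lengths=(9,), seed=0)
        model, locus = bp_gene = sim.make_gene(bp)
        assert len(locus) == 9
        assert locus.startswith("ATG")
        assert locus[6:9] in STOP_CODONS
        protein = translate(locus)
        assert len(protein) == 3 and protein[0] == "M" and protein[2] == "*"

    def test_two_exon_intron_dinucleotides(self):
        bp = sim.GeneBlueprint(
            n_exons=2, exon_lengths=(12, 9), intron_lengths=(20,), seed=2
        )
        model, locus = sim.make_gene(bp)
        intron = locus[12 : 12 + 20]
        assert intron.startswith("GT") and intron.endswith("AG")

    @given(st.data())
    @settings(max_examples=300, deadline=None)
    def test_random_blueprints_satisfy_invariants(self, data):
        n_exons = data.draw(st.integers(1, 5))
        n_codons = data.draw(st.integers(n_exons + 2, 60))
        # partition codons across exons (multiples of 3 per exon)
        cuts = sorted(
            data.draw(
                st.lists(
                    st.integers(1, n_codons - 1),
                    min_size=n_exons - 1,
                    max_size=n_exons - 1,
                    unique=True,
                )
            )
        )
        bounds = [0] + cuts + [n_codons]
        exon_lengths = tuple(3 * (b - a) for a, b in zip(bounds, bounds[1:]))
        intron_lengths = tuple(
            data.draw(st.integers(4, 60)) for _ in range(n_exons - 1)
        )
        seed = data.draw(st.integers(0, 10**6))
        bp = sim.GeneBlueprint(n_exons, exon_lengths, intron_lengths, seed)
        model, locus = sim.make_gene(bp)
        # GeneModel invariants
        assert [e.length for e in model.exons] == list(exon_lengths)
        cds = model.spliced_sequence({model.chrom: locus})
        assert cds.startswith("ATG")
        assert cds[-3:] in STOP_CODONS
        protein = translate(cds)
        assert "*" not in protein[:-1]
        for intron in model.introns():
            assert locus[intron.start : intron.start + 2] == "GT"
            assert locus[intron.end - 2 : intron.end] == "AG"

    def test_determinism(self):
        bp = sim.GeneBlueprint(n_exons=2, exon_lengths=(30, 30),
                               intron_lengths=(15,), seed=7)
        assert sim.make_gene(bp) == sim.make_gene(bp)


class TestEvolve:
    def test_zero_rates_identity(self, two_exon_gene):
        model, locus = two_exon_gene
        res = sim.evolve(locus, model, sim.EvolutionParams(sub_rate=0.0, seed=1))
        assert res.sequence == locus
        assert res.events == []

    def test_substitution_identity_oracle(self):
        """Mean per-site identity across replicates equals 1 - p within
        3 standard errors (each site flips independently with prob p)."""
        rng = np.random.default_rng(0)
        seq = sim.random_dna(rng, 3000)
        p = 0.1
        reps = 300
        identities = []
        for seed in range(reps):
            res = sim.evolve(
                seq, None, sim.EvolutionParams(sub_rate=p, seed=seed)
            )
            same = sum(a == b for a, b in zip(seq, res.sequence))
            identities.append(same / len(seq))
        mean = float(np.mean(identities))
        se = np.sqrt(p * (1 - p) / len(seq)) / np.sqrt(reps)
        assert abs(mean - (1 - p)) <= 3 * se

    def test_event_log_complete(self, two_exon_gene):
        model, locus = two_exon_gene
        res = sim.evolve(
            locus, model,
            sim.EvolutionParams(sub_rate=0.02, indel_rate=0.005, seed=3),
        )
        n_subs = sum(e.kind == "sub" for e in res.events)
        n_indels = sum(e.kind in ("ins", "del") for e in res.events)
        assert n_subs > 0
        # length change equals the net of logged indels
        net = sum(
            (e.length if e.kind == "ins" else -e.length)
            for e in res.events
            if e.kind in ("ins", "del")
        )
        assert len(res.sequence) - len(locus) == net

    def test_constrained_regime_keeps_orf(self, two_exon_gene):
        model, locus = two_exon_gene
        for seed in range(10):
            res = sim.evolve(
                locus, model,
                sim.EvolutionParams(
                    sub_rate=0.03, indel_rate=0.005, constrained=True, seed=seed
                ),
            )
            orf = reconstruct_orf({model.chrom: res.sequence}, res.model)
            assert orf.intact
            assert orf.cds.startswith("ATG")
            assert orf.premature_stop is None

    def test_constrained_requires_model(self):
        with pytest.raises(ValueError):
            sim.evolve("ACGT" * 10, None,
                       sim.EvolutionParams(sub_rate=0.1, constrained=True))

    def test_determinism(self, two_exon_gene):
        model, locus = two_exon_gene
        params = sim.EvolutionParams(sub_rate=0.05, indel_rate=0.01, seed=11)
        a = sim.evolve(locus, model, params)
        b = sim.evolve(locus, model, params)
        assert a.sequence == b.sequence and a.events == b.events


class TestImplantLesions:
    def test_deletion_recorded_as_frameshift(self, two_exon_gene):
        model, locus = two_exon_gene
        seq, truth, m2 = sim.implant_lesions(
            locus, model,
            [sim.LesionSpec(kind="frameshift", exon_index=1, op="del", length=1)],
            seed=0,
        )
        assert len(seq) == len(locus) - 1
        (lesion,) = truth
        assert lesion.kind == "frameshift" and lesion.exon_index == 1
        assert m2.exons[0].length == model.exons[0].length - 1

    def test_nonsense_creates_in_frame_stop(self, two_exon_gene):
        model, locus = two_exon_gene
        seq, truth, m2 = sim.implant_lesions(
            locus, model, [sim.LesionSpec(kind="nonsense")], seed=1
        )
        (lesion,) = truth
        codon = seq[lesion.interval.start : lesion.interval.end]
        assert codon in STOP_CODONS
        assert lesion.cds_offset % 3 == 0

    def test_overlapping_specs_rejected(self, two_exon_gene):
        model, locus = two_exon_gene
        with pytest.raises(sim.LesionPlacementError):
            sim.implant_lesions(
                locus, model,
                [
                    sim.LesionSpec(kind="frameshift", exon_index=1, offset=30),
                    sim.LesionSpec(kind="frameshift", exon_index=1, offset=31),
                ],
                seed=0,
            )

    def test_splice_lesions_break_dinucleotides(self, two_exon_gene):
        model, locus = two_exon_gene
        seq, truth, m2 = sim.implant_lesions(
            locus, model,
            [
                sim.LesionSpec(kind="splice_donor", exon_index=1),
                sim.LesionSpec(kind="splice_acceptor", exon_index=2),
            ],
            seed=2,
        )
        intron = m2.introns()[0]
        assert seq[intron.start : intron.start + 2] != "GT"
        assert seq[intron.end - 2 : intron.end] != "AG"

    def test_start_loss(self, two_exon_gene):
        model, locus = two_exon_gene
        seq, truth, m2 = sim.implant_lesions(
            locus, model, [sim.LesionSpec(kind="start_loss")], seed=3
        )
        assert seq[:3] != "ATG"
        assert truth[0].kind == "start_loss"

    def test_determinism(self, two_exon_gene):
        model, locus = two_exon_gene
        specs = [sim.LesionSpec(kind="frameshift"), sim.LesionSpec(kind="nonsense")]
        a = sim.implant_lesions(locus, model, specs, seed=9)
        b = sim.implant_lesions(locus, model, specs, seed=9)
        assert a[0] == b[0]
        assert [l.key() for l in a[1]] == [l.key() for l in b[1]]


class TestAssembleGenome:
    def _entries(self, seed=0):
        entries = []
        for i, mid in enumerate(["A", "B", "target", "C", "D"]):
            m, s = sim.make_marker_gene(mid, seed=seed + i)
            entries.append((mid, m, s))
        return entries

    def test_order_preserved(self):
        genome, models = sim.assemble_genome(self._entries(), seed=1)
        assert [m.gene_id for m in models] == ["A", "B", "target", "C", "D"]
        starts = [m.span.start for m in models]
        assert starts == sorted(starts)

    def test_sequence_content_matches_annotation(self):
        genome, models = sim.assemble_genome(self._entries(), seed=1)
        chrom_seq = genome[models[0].chrom]
        for model in models:
            cds = model.spliced_sequence(genome)
            assert cds.startswith("ATG")
            assert translate(cds)[-1] == "*"

    def test_deterministic_files(self, tmp_path):
        for run in ("x", "y"):
            genome, models = sim.assemble_genome(self._entries(), seed=5)
            write_fasta(genome, tmp_path / f"{run}.fa")
            write_gtf(models, tmp_path / f"{run}.gtf")
        assert (tmp_path / "x.fa").read_bytes() == (tmp_path / "y.fa").read_bytes()
        assert (tmp_path / "x.gtf").read_bytes() == (tmp_path / "y.gtf").read_bytes()


class TestSimulateReads:
    def test_all_noise_uniform_window_counts(self):
        """Binomial oracle: expected reads on a window of length L is
        n * (L + read_len - 1) / placeable, checked within 3 SD."""
        rng = np.random.default_rng(0)
        genome_len = 50_000
        genome = sim.SeqRecordSet({"c": sim.random_dna(rng, genome_len)})
        window = Interval("c", 20_000, 21_000)
        n_reads, read_len = 5000, 50
        hits = []
        for seed in range(30):
            params = sim.ReadSimParams(
                expression={}, noise_rate=1.0, read_length=read_len,
                n_reads=n_reads, seed=seed,
            )
            rs = sim.simulate_reads(genome, [], params)
            count = sum(
                1 for r in rs.reads if r.start < window.end and r.end > window.start
            )
            hits.append(count)
        placeable = genome_len - read_len + 1
        p = (window.length + read_len - 1) / placeable
        expected = n_reads * p
        sd = np.sqrt(n_reads * p * (1 - p) / len(hits))
        assert abs(np.mean(hits) - expected) <= 3 * sd

    def test_single_gene_reads_overlap_its_exons(self, two_exon_gene):
        model, locus = two_exon_gene
        genome, models = sim.assemble_genome(
            [("g", model, locus)], seed=0
        )
        params = sim.ReadSimParams(
            expression={"g": 1.0}, noise_rate=0.0, read_length=40,
            n_reads=500, seed=1,
        )
        rs = sim.simulate_reads(genome, models, params)
        exons = models[0].exons
        for read in rs.reads:
            assert any(read.overlaps(e) for e in exons)

    def test_silenced_gene_scaled_counts(self):
        """Silenced target with sparse noise: counts of the same magnitude
        as the near-zero exon counts the analysis expects (0-2 reads)."""
        rng = np.random.default_rng(1)
        entries = []
        for i, mid in enumerate(["m1", "m2"]):
            m, s = sim.make_marker_gene(mid, seed=10 + i)
            entries.append((mid, m, s))
        bp = sim.GeneBlueprint(2, (123, 120), (90,), seed=5)
        tmodel, tlocus = sim.make_gene(bp, gene_id="target")
        entries.insert(1, ("target", tmodel, tlocus))
        genome, models = sim.assemble_genome(
            entries, intergenic_mean=40_000, intergenic_min=20_000, seed=2
        )
        target = next(m for m in models if m.gene_id == "target")
        counts = []
        for seed in range(10):
            params = sim.ReadSimParams(
                expression={"m1": 1.0, "m2": 1.0, "target": 0.0},
                noise_rate=0.002, read_length=80, n_reads=100_000, seed=seed,
            )
            rs = sim.simulate_reads(genome, models, params)
            from relicscan.expression import count_reads

            counts.append(count_reads(rs, target))
        assert np.median(counts) <= 2
        assert max(counts) <= 5
        assert min(counts) >= 0

    def test_zero_weights_and_zero_noise_rejected(self):
        genome = sim.SeqRecordSet({"c": "ACGT" * 100})
        params = sim.ReadSimParams(
            expression={}, noise_rate=0.0, read_length=30, n_reads=10, seed=0
        )
        with pytest.raises(ValueError):
            sim.simulate_reads(genome, [], params)

    def test_library_total_equals_n_reads(self):
        rng = np.random.default_rng(2)
        genome = sim.SeqRecordSet({"c": sim.random_dna(rng, 2000)})
        params = sim.ReadSimParams(
            expression={}, noise_rate=1.0, read_length=50, n_reads=777, seed=0
        )
        rs = sim.simulate_reads(genome, [], params)
        assert rs.library_total == 777
        assert len(rs.reads) == 777

    def test_determinism(self):
        rng = np.random.default_rng(3)
        genome = sim.SeqRecordSet({"c": sim.random_dna(rng, 2000)})
        params = sim.ReadSimParams(
            expression={}, noise_rate=1.0, read_length=50, n_reads=100, seed=4
        )
        a = sim.simulate_reads(genome, [], params)
        b = sim.simulate_reads(genome, [], params)
        assert a.reads == b.reads


class TestConstrainedNeverInactivates:
    def test_cross_module_invariant(self, two_exon_gene, reference):
        """Constrained evolution never yields a sequence in which the
        classifier finds an inactivating lesion."""
        from relicscan.lesions import classify_lesions

        model, locus = two_exon_gene
        for seed in range(15):
            res = sim.evolve(
                locus, model,
                sim.EvolutionParams(
                    sub_rate=0.02, indel_rate=0.003, constrained=True, seed=seed
                ),
            )
            found = classify_lesions(
                reference, {model.chrom: res.sequence}, res.model
            )
            assert found == []
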