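import math

import numpy as np
import pytest

from mitocomp.genecontent import (
    SaturatedDistance,
    classify_gene,
    concatenate_genes,
    gene_content_matrix,
    intron_lengths,
    k2p,
    pairwise_gene_k2p,
)
from mitocomp.seqio import Genome, Interval, reverse_complement

from conftest import random_cds, random_seq


class TestK2P:
    def test_identical_sequences(self):
        r = k2p("ACGTACGT", "ACGTACGT")
        assert r.d == 0.0
        assert r.P == r.Q == 0.0

    def test_closed_form_p01_q005(self):
        # 1000 sites: 100 transitions, 50 transversions
        # d = -0.5*ln(0.75) - 0.25*ln(0.9) = 0.170183... (scalar oracle)
        a = list("A" * 1000)
        b = list("A" * 1000)
        for i in range(100):
            b[i] = "G"  # transition
        for i in range(100, 150):
            b[i] = "C"  # transversion
        r = k2p("".join(a), "".join(b))
        assert r.P == pytest.approx(0.1)
        assert r.Q == pytest.approx(0.05)
        oracle = -0.5 * math.log(1 - 2 * 0.1 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert r.d == pytest.approx(oracle, abs=1e-12)
        assert r.d == pytest.approx(0.1702, abs=5e-4)

    def test_pairwise_deletion(self):
        r = k2p("ACGT-N", "ACGTAC")
        assert r.sites_used == 4
        assert r.d == 0.0

    def test_saturation_raises(self):
        a = "A" * 100
        b = "G" * 100  # all transitions: 1 - 2P - Q = -1
        with pytest.raises(SaturatedDistance):
            k2p(a, b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            k2p("ACGT", "ACG")

    def test_symmetry(self):
        rng = np.random.default_rng(90)
        a = random_seq(rng, 500)
        b = "".join(
            c if rng.random() > 0.1 else str(rng.choice(list("ACGT")))
            for c in a
        )
        ra, rb = k2p(a, b), k2p(b, a)
        assert ra == rb

    def test_correction_inflates_raw_mismatch(self):
        rng = np.random.default_rng(91)
        a = random_seq(rng, 2000)
        b = list(a)
        idx = rng.choice(2000, 200, replace=False)
        for i in idx:
            b[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[i]]
        # add transversions at half the transition rate
        idx2 = rng.choice(2000, 100, replace=False)
        for i in idx2:
            b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
        r = k2p(a, "".join(b))
        raw = sum(1 for x, y in zip(a, b) if x != y) / 2000
        assert r.d >= raw


class TestClassifyGene:
    @pytest.fixture
    def ref(self):
        rng = np.random.default_rng(92)
        return random_cds(rng, 201)  # 603 bp

    @pytest.fixture
    def background(self):
        rng = np.random.default_rng(93)
        return random_seq(rng, 6000)

    def test_verbatim_insertion_intact(self, ref, background):
        g = Genome(id="g", sequence=background[:3000] + ref + background[3000:])
        model = classify_gene(g, "geneA", ref)
        assert model.status == "intact"
        assert model.coverage >= 0.99

    def test_frameshift_pseudogene(self, ref, background):
        mutated = ref[:300] + ref[301:]  # 1 bp deletion
        g = Genome(id="g", sequence=background[:3000] + mutated + background[3000:])
        assert classify_gene(g, "geneA", ref).status == "pseudogene"

    def test_internal_stop_pseudogene(self, ref, background):
        mutated = ref[:300] + "TAA" + ref[303:]
        g = Genome(id="g", sequence=background[:3000] + mutated + background[3000:])
        assert classify_gene(g, "geneA", ref).status == "pseudogene"

    def test_80bp_subsegment_absent(self, ref, background):
        g = Genome(id="g", sequence=background[:3000] + ref[100:180] + background[3000:])
        assert classify_gene(g, "geneA", ref).status == "absent"

    def test_150bp_subsegment_fragment(self, ref, background):
        g = Genome(id="g", sequence=background[:3000] + ref[100:250] + background[3000:])
        assert classify_gene(g, "geneA", ref).status == "fragment"

    def test_no_hit_absent(self, ref, background):
        assert classify_gene(Genome(id="g", sequence=background), "geneA", ref).status == "absent"

    def test_minus_strand_intact(self, ref, background):
        g = Genome(
            id="g", sequence=background[:3000] + reverse_complement(ref) + background[3000:]
        )
        model = classify_gene(g, "geneA", ref)
        assert model.status == "intact"
        assert model.strand == "-"

    def test_reference_not_codon_multiple_rejected(self, background):
        with pytest.raises(ValueError):
            classify_gene(Genome(id="g", sequence=background), "geneA", "ACGTA")


class TestIntronLengths:
    def test_two_exons_arithmetic(self, ):
        from mitocomp.genecontent import GeneModel

        model = GeneModel(
            gene_name="x",
            status="intact",
            exons=[Interval(100, 200), Interval(500, 600)],
            strand="+",
            coverage=1.0,
            identity=1.0,
        )
        assert intron_lengths(model) == [300]

    def test_planted_intron_growth(self):
        rng = np.random.default_rng(94)
        ref = random_cds(rng, 300)  # 900 bp
        bg = random_seq(rng, 8000)
        intron0 = random_seq(rng, 400)
        g1 = Genome(id="g1", sequence=bg[:4000] + ref[:450] + intron0 + ref[450:] + bg[4000:])
        m1 = classify_gene(g1, "x", ref)
        # insert an extra 2.9 kb into the intron
        insert = random_seq(rng, 2900)
        g2 = Genome(
            id="g2",
            sequence=bg[:4000] + ref[:450] + intron0[:200] + insert + intron0[200:] + ref[450:] + bg[4000:],
        )
        m2 = classify_gene(g2, "x", ref)
        assert intron_lengths(m2)[0] - intron_lengths(m1)[0] == 2900

    def test_single_exon_no_introns(self):
        rng = np.random.default_rng(95)
        ref = random_cds(rng, 150)
        bg = random_seq(rng, 4000)
        g = Genome(id="g", sequence=bg[:2000] + ref + bg[2000:])
        model = classify_gene(g, "x", ref)
        assert intron_lengths(model) == []

    def test_absent_gene_rejected(self):
        from mitocomp.genecontent import GeneModel

        model = GeneModel("x", "absent", [], "+", 0.0, 0.0)
        with pytest.raises(ValueError):
            intron_lengths(model)


class TestConcatenateGenes:
    def test_length_additivity(self):
        alns = {"g1": ("A" * 300, "A" * 300), "g2": ("C" * 600, "C" * 600)}
        concat = concatenate_genes(alns, ["g1", "g2"])
        assert len(concat.aligned_a) == 900
        assert concat.gene_boundaries == [("g1", 0, 300), ("g2", 300, 900)]

    def test_missing_gene_skipped_with_warning(self):
        alns = {"g1": ("ACGT", "ACGT")}
        with pytest.warns(UserWarning, match="g2"):
            concat = concatenate_genes(alns, ["g1", "g2"])
        assert len(concat.aligned_a) == 4

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            concatenate_genes({}, [])

    def test_k2p_recovery_on_simulated_genes(self):
        # genes evolved at total path length 0.05: K2P on the concatenation
        # should recover 0.05 within 3 binomial standard errors
        from mitocomp.simulate import SimulationConfig, default_gene_set, evolve

        cfg = SimulationConfig(
            tree="(A:0.025,B:0.025);",
            genome_len=20_000,
            gene_set=default_gene_set(10, 900),
            seed=96,
        )
        genomes, truth = evolve(cfg)
        seqs = {}
        for leaf in ("A", "B"):
            seqs[leaf] = {
                gene: genomes[leaf].subseq(iv.start, iv.end)
                for gene, iv in truth.gene_intervals[leaf].items()
            }
        gene_list = sorted(seqs["A"])
        result, concat = pairwise_gene_k2p(seqs["A"], seqs["B"], gene_list)
        n_sites = result.sites_used
        se = math.sqrt(0.05 * 0.95 / n_sites)
        assert result.d == pytest.approx(0.05, abs=3 * se)


class TestGeneContentMatrix:
    def test_statuses_filled_for_all_cells(self):
        rng = np.random.default_rng(97)
        refs = {"gA": random_cds(rng, 120), "gB": random_cds(rng, 150)}
        bg1 = random_seq(rng, 4000)
        bg2 = random_seq(rng, 4000)
        g1 = Genome(id="g1", sequence=bg1[:2000] + refs["gA"] + bg1[2000:])
        g2 = Genome(id="g2", sequence=bg2[:2000] + refs["gB"] + bg2[2000:])
        gcm = gene_content_matrix([g1, g2], refs)
        assert gcm.status["g1"]["gA"] == "intact"
        assert gcm.status["g1"]["gB"] == "absent"
        assert gcm.status["g2"]["gB"] == "intact"
        for g in gcm.genome_ids:
            for gene in gcm.gene_names:
                assert gcm.status[g][gene] in {"intact", "pseudogene", "fragment", "absent"}
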