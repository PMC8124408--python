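"""Flanking-context, orthology and collinearity-calling tests."""

import itertools

import numpy as np
import pytest

import oracles
from oryzalnc.iolib import Exon, GenomeLabel, TranscriptModel
from oryzalnc.synteny import (
    FlankContext,
    call_positional,
    contexts_for,
    flank_context,
    intersect_triples,
    ortholog_map,
    rbh_orthologs,
)
from oryzalnc.synthetic import mutate_stratified, shuffle_gene_positions

G = GenomeLabel("g")


def gene(tid, start, length=1000, chrom="chr1", biotype="coding"):
    return TranscriptModel(tid, tid, G,
                          [Exon(chrom, start, start + length - 1, "+")],
                          biotype)


class TestFlankContext:
    def test_mixed_sides(self):
        lnc = gene("lnc", 50_000, 500, biotype="lnc_candidate")
        genes = [gene(f"g{i}", pos) for i, pos in
                 enumerate([10_000, 30_000, 45_000, 55_000, 70_000, 90_000])]
        ctx = flank_context(lnc, genes)
        assert ctx.complete
        assert len(ctx.genes) == 5
        assert set(ctx.sides) == {"upstream", "downstream"}
        assert ctx.genes[0] in {"g2", "g3"}  # the two nearest

    def test_chromosome_start_skew(self):
        lnc = gene("lnc", 2_000, 500, biotype="lnc_candidate")
        genes = [gene("u1", 500, 100), gene("u2", 1_200, 100)] + [
            gene(f"d{i}", 4_000 + i * 2_000, 100) for i in range(10)
        ]
        ctx = flank_context(lnc, genes)
        assert ctx.complete
        assert ctx.sides.count("upstream") == 2
        assert ctx.sides.count("downstream") == 3

    def test_fewer_than_five_incomplete(self, caplog):
        lnc = gene("lnc", 5_000, 500, biotype="lnc_candidate")
        genes = [gene(f"g{i}", 10_000 * (i + 1)) for i in range(3)]
        with caplog.at_level("WARNING", logger="oryzalnc"):
            ctx = flank_context(lnc, genes)
        assert not ctx.complete
        assert contexts_for([lnc], genes) == {}

    def test_matches_distance_sort_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            genes = [gene(f"g{i}", int(rng.integers(1, 500_000)), 500)
                     for i in range(20)]
            lnc = gene("lnc", int(rng.integers(1, 500_000)), 400,
                       biotype="lnc_candidate")
            ctx = flank_context(lnc, genes)
            assert ctx.genes == oracles.nearest_genes_oracle(
                lnc.midpoint, genes)


class TestRbh:
    def test_identity_map(self):
        rng = np.random.default_rng(0)
        seqs = {f"g{i}": "".join(rng.choice(list("ACGT"), 300))
                for i in range(6)}
        pairs = rbh_orthologs(seqs, dict(seqs))
        assert ortholog_map(pairs) == {k: k for k in seqs}

    def test_planted_orthologs_recovered(self):
        rng = np.random.default_rng(1)
        ancestors = ["".join(rng.choice(list("ACGT"), 600)) for _ in range(8)]
        a = {f"a{i}": mutate_stratified(s, 97.5, rng)
             for i, s in enumerate(ancestors)}
        b = {f"b{i}": mutate_stratified(s, 97.5, rng)
             for i, s in enumerate(ancestors)}
        a["a_extra"] = "".join(rng.choice(list("ACGT"), 600))
        b["b_extra"] = "".join(rng.choice(list("ACGT"), 600))
        got = ortholog_map(rbh_orthologs(a, b))
        assert got == {f"a{i}": f"b{i}" for i in range(8)}

    def test_tied_best_hit_excluded(self, caplog):
        rng = np.random.default_rng(2)
        s = "".join(rng.choice(list("ACGT"), 300))
        a = {"a1": s}
        b = {"b1": s, "b2": s}  # two equally scoring partners
        with caplog.at_level("WARNING", logger="oryzalnc"):
            pairs = rbh_orthologs(a, b)
        assert pairs.empty
        assert "ambiguous" in caplog.text

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            rbh_orthologs({}, {"b": "ACGT"})


def _ctx(lid, genome, chrom, midpoint, genes):
    return FlankContext(lncrna_id=lid, genome=genome, chrom=chrom,
                        midpoint=midpoint, genes=list(genes),
                        sides=["upstream"] * len(genes),
                        distances=[0.0] * len(genes))


class TestCallBoundary:
    def make_world(self, n_ortho):
        """a1's context has 5 genes; n_ortho of them map into b1's context."""
        ctx_a = {"a1": _ctx("a1", "A", "chr1", 100.0,
                            [f"g{i}" for i in range(5)])}
        ctx_b = {"b1": _ctx("b1", "B", "chr1", 100_000.0,
                            [f"h{i}" for i in range(5)])}
        orthologs = {f"g{i}": f"h{i}" for i in range(n_ortho)}
        annotation_b = [gene(f"h{i}", 90_000 + i * 3_000) for i in range(5)]
        return ctx_a, ctx_b, orthologs, annotation_b

    @pytest.mark.parametrize("n_ortho,conserved", [
        (5, True), (4, True), (3, False), (0, False),
    ])
    def test_four_of_five_rule(self, n_ortho, conserved):
        ctx_a, ctx_b, orth, ann = self.make_world(n_ortho)
        calls = call_positional(ctx_a, ctx_b, orth, ann)
        if n_ortho == 0:
            assert calls == []
        else:
            assert calls[0].close_count == n_ortho
            assert calls[0].conserved is conserved

    def test_rank_window_rule(self):
        # the ortholog sits outside b's context but within the rank window
        ctx_a = {"a1": _ctx("a1", "A", "chr1", 100.0, ["g0"])}
        ctx_b = {"b1": _ctx("b1", "B", "chr1", 50_000.0, ["h0"])}
        ann = [gene(f"h{i}", (i + 1) * 10_000) for i in range(30)]
        # b1 sits at rank 4; h8 is 4 ranks away, h20 is 16 ranks away
        calls = call_positional(ctx_a, ctx_b, {"g0": "h8"}, ann,
                                window=10, min_close=1)
        assert calls and calls[0].conserved
        calls = call_positional(ctx_a, ctx_b, {"g0": "h20"}, ann,
                                window=10, min_close=1)
        assert calls == []

    def test_close_count_monotone_in_window(self):
        ctx_a, ctx_b, orth, ann = self.make_world(5)
        counts = []
        for w in (0, 2, 5, 10, 20):
            calls = call_positional(ctx_a, ctx_b, orth, ann, window=w,
                                    min_close=1)
            counts.append(calls[0].close_count if calls else 0)
        assert counts == sorted(counts)


class TestTriples:
    def c(self, a, b, close=5):
        from oryzalnc.synteny import PositionalCall
        return PositionalCall(a, b, close, close >= 4)

    def test_empty(self):
        assert intersect_triples([], [], []) == []

    def test_missing_third_leg(self):
        wa = [self.c("w1", "a1")]
        wb = [self.c("w1", "b1")]
        assert intersect_triples(wa, wb, []) == []

    def test_full_triangle(self):
        wa = [self.c("w1", "a1")]
        wb = [self.c("w1", "b1")]
        ab = [self.c("a1", "b1")]
        assert intersect_triples(wa, wb, ab) == [("w1", "a1", "b1")]

    def test_triple_count_bounded_by_pairwise(self):
        rng = np.random.default_rng(8)
        ws = [f"w{i}" for i in range(10)]
        As = [f"a{i}" for i in range(10)]
        Bs = [f"b{i}" for i in range(10)]
        wa = [self.c(rng.choice(ws), rng.choice(As)) for _ in range(15)]
        wb = [self.c(rng.choice(ws), rng.choice(Bs)) for _ in range(15)]
        ab = [self.c(rng.choice(As), rng.choice(Bs)) for _ in range(15)]
        triples = intersect_triples(wa, wb, ab)
        # every triple is backed by all three pairwise calls
        wa_set = {(c.lncrna_a, c.lncrna_b) for c in wa}
        wb_set = {(c.lncrna_a, c.lncrna_b) for c in wb}
        ab_set = {(c.lncrna_a, c.lncrna_b) for c in ab}
        for w, a, b in triples:
            assert (w, a) in wa_set and (w, b) in wb_set and (a, b) in ab_set


class TestPlantedRecovery:
    def run_calls(self, bundle, shuffle_genome=None, seed=0):
        genomes = list(bundle.config.genomes)
        orth = bundle.truth.orthologs
        annotations = {g: bundle.transcripts[g] for g in genomes}
        if shuffle_genome is not None:
            rng = np.random.default_rng(seed)
            annotations[shuffle_genome] = shuffle_gene_positions(
                annotations[shuffle_genome], rng)
        lncs = {g: [t for t in annotations[g] if t.biotype != "coding"]
                for g in genomes}
        ctx = {g: contexts_for(lncs[g], annotations[g]) for g in genomes}
        calls = {}
        for a, b in itertools.combinations(genomes, 2):
            sel = orth[(orth.genome_a == a) & (orth.genome_b == b)]
            calls[(a, b)] = call_positional(ctx[a], ctx[b],
                                            ortholog_map(sel),
                                            annotations[b])
        return calls

    def test_planted_blocks_called_exactly(self, trio_hom):
        genomes = list(trio_hom.config.genomes)
        calls = self.run_calls(trio_hom)
        tp = trio_hom.truth.positional
        real = tp[~tp.decoy]
        lnc_of = {(r.block_id, r.genome): r.lncrna_id
                  for r in real.itertuples()}
        for a, b in itertools.combinations(genomes, 2):
            expected = {
                (lnc_of[(bid, a)], lnc_of[(bid, b)])
                for bid, grp in real.groupby("block_id")
                if {a, b} <= set(grp.genome)
            }
            got = {(c.lncrna_a, c.lncrna_b) for c in calls[(a, b)]
                   if c.conserved}
            assert got == expected
        # the wild-indica planted count exceeds wild-japonica, and the
        # recovered counts preserve that order
        n_wa = sum(c.conserved for c in calls[(genomes[0], genomes[1])])
        n_wb = sum(c.conserved for c in calls[(genomes[0], genomes[2])])
        assert n_wb > n_wa

    def test_decoy_blocks_never_called(self, trio_hom):
        calls = self.run_calls(trio_hom)
        decoy_ids = set(trio_hom.truth.positional.query("decoy").lncrna_id)
        for pair_calls in calls.values():
            for c in pair_calls:
                if c.conserved:
                    assert c.lncrna_a not in decoy_ids
                    assert c.lncrna_b not in decoy_ids

    def test_triples_recovered_exactly(self, trio_hom):
        genomes = list(trio_hom.config.genomes)
        calls = self.run_calls(trio_hom)
        triples = intersect_triples(calls[(genomes[0], genomes[1])],
                                    calls[(genomes[0], genomes[2])],
                                    calls[(genomes[1], genomes[2])])
        tp = trio_hom.truth.positional
        expected = tp[(~tp.decoy)
                      & (tp.genomes.str.count(",") == 2)].block_id.nunique()
        assert len(triples) == expected == 8

    def test_shuffled_annotation_negative_control(self, trio_hom):
        genomes = list(trio_hom.config.genomes)
        calls = self.run_calls(trio_hom, shuffle_genome=genomes[1])
        affected = [(genomes[0], genomes[1]), (genomes[1], genomes[2])]
        for pair in affected:
            assert sum(c.conserved for c in calls[pair]) == 0
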