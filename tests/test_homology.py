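"""Aligner, conservation screen and family-construction tests."""

import numpy as np
import pytest

import oracles
from oryzalnc.homology import (
    AlignParams,
    HomologySegment,
    build_families,
    conserved_families,
    flag_multicopy,
    local_align,
    screen_homologs,
)

RNG = np.random.default_rng(1)
BASES = list("ACGT")


def rand_seq(n, rng=RNG):
    return "".join(rng.choice(BASES, n))


class TestLocalAlign:
    def test_identical_sequences(self):
        s = rand_seq(500)
        seg = local_align(s, s)
        assert seg.aligned_length == 500
        assert seg.identity_pct == 100.0

    def test_flanked_core_worked_example(self):
        # a 1187 nt core against the same core wrapped in 5 + 75 non-matching
        # bases recovers a 1187-column segment at 100% identity
        core = rand_seq(1187)
        longer = "N" * 5 + core + "N" * 75
        assert len(longer) == 1267
        seg = local_align(core, longer)
        assert seg.aligned_length == 1187
        assert seg.identity_pct == 100.0
        assert (seg.subject_start, seg.subject_end) == (6, 1192)
        params = AlignParams()
        assert seg.aligned_length > params.min_segment_length
        assert seg.identity_pct > params.min_identity

    def test_empty_sequence_returns_none(self):
        assert local_align("", "ACGT") is None
        assert local_align("ACGT", "") is None

    def test_all_n_returns_none(self):
        assert local_align("NNNNN", "NNNNN") is None

    def test_reverse_strand_hit(self):
        core = rand_seq(200)
        rc = core.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        subject = rand_seq(50) + rc + rand_seq(50)
        seg = local_align(core, subject)
        assert seg.strand == "-"
        assert seg.aligned_length == 200
        assert seg.identity_pct == 100.0
        # subject coordinates mapped back to the forward strand
        assert (seg.subject_start, seg.subject_end) == (51, 250)

    def test_matches_exhaustive_dp_oracle(self):
        rng = np.random.default_rng(77)
        alphabet = list("ACGTN")
        params = AlignParams(both_strands=False)
        for _ in range(150):
            a = "".join(rng.choice(alphabet, rng.integers(1, 31),
                                   p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            b = "".join(rng.choice(alphabet, rng.integers(1, 31),
                                   p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            seg = local_align(a, b, params)
            expected = oracles.sw_score(a, b)
            got = seg.score if seg else 0.0
            assert got == expected


class TestScreenThresholds:
    def segment(self, length, identities):
        return HomologySegment(aligned_length=length, identities=identities)

    def test_exactly_100_columns_rejected(self):
        # strict "> 100 nt": a perfect 100-column hit fails the screen
        a = rand_seq(100)
        b = "N" * 10 + a + "N" * 10
        seg = local_align(a, b)
        assert seg.aligned_length == 100
        assert seg.identity_pct == 100.0
        p = AlignParams()
        assert not (seg.aligned_length > p.min_segment_length)

    def test_exactly_90_percent_rejected_above_passes(self):
        core = list(rand_seq(150))
        other = core[:]
        for i in range(15):  # evenly spaced -> full window stays optimal
            pos = i * 10 + 5
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        seg = local_align("".join(core), "".join(other))
        assert seg.aligned_length == 150
        assert seg.identity_pct == pytest.approx(90.0)
        p = AlignParams()
        assert not (seg.identity_pct > p.min_identity)
        other[5] = core[5]  # 14 mismatches -> 90.67% -> passes
        seg2 = local_align("".join(core), "".join(other))
        assert seg2.identity_pct > p.min_identity
        assert seg2.aligned_length > p.min_segment_length

    def test_screen_symmetric_on_planted_trio(self, trio_hom):
        genomes = list(trio_hom.config.genomes)
        a, b = genomes[0], genomes[1]
        fam = trio_hom.truth.families
        ids_a = set(fam[(fam.genome == a)].transcript_id)
        ids_b = set(fam[(fam.genome == b)].transcript_id)
        seqs_a = {k: v for k, v in trio_hom.lnc_sequences(a).items()
                  if k in ids_a}
        seqs_b = {k: v for k, v in trio_hom.lnc_sequences(b).items()
                  if k in ids_b}
        fwd = screen_homologs(seqs_a, seqs_b, AlignParams(), a, b)
        rev = screen_homologs(seqs_b, seqs_a, AlignParams(), b, a)
        assert {(s.query_id, s.subject_id) for s in fwd} == \
               {(s.subject_id, s.query_id) for s in rev}

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            screen_homologs({}, {"a": "ACGT"})


class TestFamilies:
    def seg(self, qg, q, sg, s):
        return HomologySegment(query_id=q, query_genome=qg,
                               subject_id=s, subject_genome=sg,
                               aligned_length=150, identities=145)

    def test_pairwise_only_not_three_way(self):
        fams = build_families([self.seg("w", "a", "j", "b")], ["w", "j", "i"])
        assert len(fams) == 1
        assert not fams[0].is_three_way(["w", "j", "i"])
        assert conserved_families(fams, ["w", "j", "i"]) == []

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(21)
        genomes = ["w", "j", "i"]
        for _ in range(20):
            nodes = [(rng.choice(genomes), f"t{i}")
                     for i in range(rng.integers(5, 40))]
            edges = []
            for _ in range(rng.integers(1, 60)):
                u, v = rng.integers(0, len(nodes), 2)
                if u != v:
                    edges.append((tuple(nodes[u]), tuple(nodes[v])))
            if not edges:
                continue
            fams = build_families(
                [self.seg(u[0], u[1], v[0], v[1]) for u, v in edges], genomes)
            got = {
                frozenset((g, tid) for g, ids in f.members.items()
                          for tid in ids)
                for f in fams
            }
            assert got == oracles.union_find_components(edges)

    def test_multicopy_flagging(self):
        fams = build_families(
            [self.seg("w", f"w{i}", "j", "j0") for i in range(41)]
            + [self.seg("w", "w0", "i", f"i{k}") for k in range(3)]
            + [self.seg("w", "s1", "j", "s2"),
               self.seg("w", "s1", "i", "s3")],
            ["w", "j", "i"],
        )
        report = flag_multicopy(fams, threshold=5, wild="w")
        by_id = {r["family_id"]: r for r in report}
        flags = sorted((r["copies_w"], r["te_like"]) for r in report)
        assert flags == [(1, False), (41, True)]
        big = next(r for r in report if r["te_like"])
        assert big["contraction_ratio"] == pytest.approx(41 / 2)

    def test_threshold_sweep_monotone(self):
        fams = build_families(
            [self.seg("w", f"w{i}", "j", "j0") for i in range(7)], ["w", "j"])
        flagged = [
            sum(r["te_like"] for r in flag_multicopy(fams, threshold=k))
            for k in range(1, 12)
        ]
        assert flagged == sorted(flagged, reverse=True)


class TestPlantedRecovery:
    def test_families_and_decoys(self, trio_hom, hom_segments):
        genomes = list(trio_hom.config.genomes)
        truth = trio_hom.truth.families
        fams = build_families(hom_segments, genomes)
        # every planted family recovered as one component, exactly
        for fid, grp in truth[~truth.decoy].groupby("family_id"):
            members = set(grp.transcript_id)
            assert any(
                set(t for ids in f.members.values() for t in ids) == members
                for f in fams
            ), f"family {fid} not recovered exactly"
        # zero decoy members appear in any passing link
        decoy_ids = set(truth[truth.decoy].transcript_id)
        linked = {s.query_id for s in hom_segments} | \
                 {s.subject_id for s in hom_segments}
        assert not (decoy_ids & linked)

    def test_copy_profiles_exact(self, trio_hom, hom_segments):
        genomes = list(trio_hom.config.genomes)
        fams = conserved_families(build_families(hom_segments, genomes),
                                  genomes)
        profiles = sorted(
            tuple(f.copy_profile[g] for g in genomes) for f in fams
        )
        assert profiles == [(21, 1, 2), (41, 1, 3)]

    def test_planted_identity_within_band(self, trio_hom, hom_segments):
        # realized identity over the planted interval stays within 2 points
        # of the configured value (the screen's reported identity can only
        # sit higher, because local alignment trims mismatching ends)
        truth = trio_hom.truth.families
        real = truth[~truth.decoy].set_index("transcript_id")
        seqs = {}
        for g in trio_hom.config.genomes:
            seqs.update(trio_hom.lnc_sequences(g))

        def planted_segment(tid):
            row = real.loc[tid]
            return seqs[tid][int(row.segment_start) - 1: int(row.segment_end)]

        fam_segs = [s for s in hom_segments if ".FAM" in s.query_id]
        assert fam_segs
        for s in fam_segs[:40]:
            a, b = planted_segment(s.query_id), planted_segment(s.subject_id)
            ident = 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
            assert abs(ident - 96.0) <= 2.0
            assert s.identity_pct >= ident - 0.5
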