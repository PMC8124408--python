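"""Shared fixtures: synthetic trio bundles built once per session."""

from __future__ import annotations

import dataclasses
import itertools

import pytest

from oryzalnc.homology import AlignParams, screen_homologs
from oryzalnc.synthetic import TrioConfig, generate_trio


def homology_trio_config() -> TrioConfig:
    """The standard trio for conservation-recovery suites: default planted
    families/decoys/blocks over a 200-background-lncRNA genome each."""
    return dataclasses.replace(
        TrioConfig(seed=1),
        lnc_per_genome=(200, 200, 200),
        n_chromosomes=4,
        coding_per_chrom=25,
    )


@pytest.fixture(scope="session")
def trio_hom(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("trio_hom")
    return generate_trio(homology_trio_config(), outdir)


@pytest.fixture(scope="session")
def trio_default(tmp_path_factory):
    """Full-size trio (2000 lncRNAs per genome) for distribution and
    expression-direction checks."""
    outdir = tmp_path_factory.mktemp("trio_default")
    return generate_trio(TrioConfig(seed=1), outdir)


@pytest.fixture(scope="session")
def hom_segments(trio_hom):
    """All three pairwise homology screens of the standard trio (computed
    once; the screen is the expensive step of the conservation analysis)."""
    genomes = list(trio_hom.config.genomes)
    seqs = {g: trio_hom.lnc_sequences(g) for g in genomes}
    segments = []
    for a, b in itertools.combinations(genomes, 2):
        segments += screen_homologs(seqs[a], seqs[b], AlignParams(), a, b)
    return segments
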