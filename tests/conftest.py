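"""Shared fixtures: synthetic study-scale datasets built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import goldenpath as gp
from goldenpath import simulate as sim
from goldenpath.digest_links import digest_assembly, ingest_pairs

STUDY_SEED = 1


def build_assembly(bundle) -> gp.AssemblyObject:
    """Assembly object from a simulator bundle (digest + Q10 ingestion)."""
    fragments = digest_assembly(bundle["contig_sequences"])
    pairs = ingest_pairs(bundle["pairs"], mapq_min=10)
    return gp.new_assembly(
        bundle["truth"].contig_catalog(),
        fragments,
        pairs,
        bundle["alignments"],
        bundle["contig_sequences"],
    )


@pytest.fixture(scope="session")
def study_bundle():
    """Reference conditions: 2 x 20 Mb, 60 contigs, 5e5 pairs, 100-kb markers."""
    return sim.simulate_all(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_assembly(study_bundle):
    return build_assembly(study_bundle)


@pytest.fixture(scope="session")
def study_map(study_assembly):
    return gp.scaffold_assembly(study_assembly)


@pytest.fixture(scope="session")
def chimera_bundle():
    """Reference conditions plus three injected inter-chromosomal chimeras."""
    return sim.simulate_all(seed=STUDY_SEED, chimera_count=3)


@pytest.fixture(scope="session")
def chimera_assembly(chimera_bundle):
    return build_assembly(chimera_bundle)


@pytest.fixture(scope="session")
def small_bundle():
    """A light instance for unit tests: 2 x 2 Mb, 12 contigs, 5e4 pairs."""
    return sim.simulate_all(
        seed=7, chrom_lengths=2_000_000, n_contigs=12, n_pairs=50_000,
        marker_spacing=50_000,
    )


@pytest.fixture(scope="session")
def small_assembly(small_bundle):
    return build_assembly(small_bundle)


@pytest.fixture(scope="session")
def small_map(small_assembly):
    return gp.scaffold_assembly(small_assembly)


@pytest.fixture
def toy_assembly():
    """Two hand-built contigs with a handful of pairs and markers."""
    contigs = pd.DataFrame({"contig_id": ["A", "B"], "length": [1000, 2000]})
    fragments = pd.DataFrame(
        {
            "contig_id": ["A", "A", "B"],
            "start": [0, 400, 0],
            "end": [400, 1000, 2000],
            "index": [0, 1, 0],
        }
    )
    pairs = pd.DataFrame(
        {
            "contig1": ["A", "A", "B"],
            "pos1": [10, 900, 100],
            "mapq1": [60, 60, 60],
            "contig2": ["B", "A", "B"],
            "pos2": [50, 950, 1900],
            "mapq2": [60, 60, 60],
        }
    )
    alignments = pd.DataFrame(
        {
            "marker_id": ["m1", "m2"],
            "guide_chr": ["chr1", "chr1"],
            "guide_pos": [1000.0, 2500.0],
            "contig_id": ["A", "B"],
            "contig_pos": [500, 700],
            "aligned_len": [101, 101],
            "identity": [1.0, 1.0],
            "orientation": [1, 1],
        }
    )
    sequences = {
        "A": "".join(np.random.default_rng(3).choice(list("ACGT"), 1000)),
        "B": "".join(np.random.default_rng(4).choice(list("ACGT"), 2000)),
    }
    return gp.new_assembly(contigs, fragments, pairs, alignments, sequences)
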