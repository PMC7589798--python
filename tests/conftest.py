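"""Shared fixtures: synthetic bundles and small hand-built objects."""

from __future__ import annotations

import numpy as np
import pytest

from srna_transgen.io_formats import (
    FeatureSet,
    GenomicFeature,
    GenomicInterval,
)
from srna_transgen.synthetic_data import make_fixture


@pytest.fixture(scope="session")
def tiny_bundle():
    """One deterministic tiny simulation shared across the suite."""
    return make_fixture("tiny", seed=101)


@pytest.fixture(scope="session")
def tiny_dir(tmp_path_factory):
    """The tiny bundle written out as an on-disk input directory."""
    outdir = tmp_path_factory.mktemp("fixture")
    make_fixture("tiny", seed=101, outdir=outdir)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(20201013)


@pytest.fixture()
def small_annotation() -> FeatureSet:
    """A hand-built annotation with one gene/CDS, one TE and one tRNA."""
    gene = GenomicFeature(GenomicInterval("c1", 4000, 5000, "+"), "gene", "g1")
    cds = GenomicFeature(
        GenomicInterval("c1", 4100, 4900, "+"), "CDS", "g1.cds", {"Parent": "g1"}
    )
    te = GenomicFeature(GenomicInterval("c1", 8000, 9000), "TE", "te1")
    trna = GenomicFeature(
        GenomicInterval("c1", 1000, 1075, "+"),
        "tRNA",
        "t1",
        {
            "anticodon": "CAA",
            "amino_acid": "Leu",
            "anticodon_interval": GenomicInterval("c1", 1033, 1036, "+"),
        },
    )
    return FeatureSet([gene, cds, te, trna])
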