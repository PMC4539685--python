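"""Shared fixtures: a session-scoped default study run and small genomes."""

from __future__ import annotations

import numpy as np
import pytest

from mobilecodon.io_core import AnnotatedGenome, GeneFeature
from mobilecodon.pipeline import PipelineConfig, run_pipeline
from mobilecodon.synthetic import TruthSet


@pytest.fixture(scope="session")
def study(tmp_path_factory) -> dict:
    """One full default-conditions pipeline run shared by the whole suite.

    12 strains (5 pathogen-like + 7 others), 2000 host genes, three SGE
    families at 30-150 copies (divergence 0-4% plus 6% decoys), planted
    multi-copy tRNAs and node-specific LGT gene sets.
    """
    out = tmp_path_factory.mktemp("study")
    config = PipelineConfig(out_dir=str(out), seed=1)
    summary = run_pipeline(config)
    truth = TruthSet.from_json(out / "genomes" / "truth.json")
    return {"summary": summary, "out": out, "truth": truth, "config": config}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_genome() -> AnnotatedGenome:
    """60 bp genome with one plus-strand and one minus-strand CDS."""
    #               0         1         2         3         4         5
    #               0123456789012345678901234567890123456789012345678901234567890
    seq = "ATGAAATAAGGGGGGTTACATCATCCCCCCAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA"
    return AnnotatedGenome(
        strain_id="tiny",
        sequence=seq,
        features=[
            GeneFeature("plus1", 0, 9, "+", "host"),
            GeneFeature("minus1", 15, 24, "-", "host"),
        ],
    )
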