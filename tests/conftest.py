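"""Shared fixtures.

The expensive fixture is ``study``: one full desk-scale run of the pipeline
(synthetic genome, usage quantification, three-phase training of the
miniature probability and usage models, held-out evaluation).  It is
session-scoped and shared by every test that needs trained models.
"""

from __future__ import annotations

import numpy as np
import pytest

from spliceml import pipeline
from spliceml.datasets import load_annotation
from spliceml.model import ModelConfig, SpliceNet
from spliceml.synthetic import GrammarSpec, generate_genome

STUDY_SEED = 1
STUDY_GENES = 250


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """A small random network (context 24) for contract tests."""
    return ModelConfig(n_residual_blocks=2, channels=8, kernels=(5, 5),
                       dilations=(2, 4), skip_taps=(1,))


@pytest.fixture(scope="session")
def tiny_net(tiny_config) -> SpliceNet:
    return SpliceNet(tiny_config, seed=123)


@pytest.fixture(scope="session")
def tiny_genome(tmp_path_factory):
    """A 20-gene synthetic genome with files on disk."""
    out = tmp_path_factory.mktemp("tiny_genome")
    chroms, genes, truth = generate_genome(20, GrammarSpec(), seed=7,
                                           out_dir=out)
    return {"dir": out, "chroms": chroms, "genes": genes, "truth": truth,
            "fasta": out / "genome.fa", "gff": out / "genes.gff3"}


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The full desk-scale study: data, trained models and metrics."""
    out = tmp_path_factory.mktemp("study")
    results = pipeline.run_pipeline(out, seed=STUDY_SEED,
                                    n_genes=STUDY_GENES)
    results["out_dir"] = out
    return results


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
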