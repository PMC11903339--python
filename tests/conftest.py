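"""Shared fixtures: one small fully-processed synthetic screen.

The demo screen keeps every guide active and plants strong effects so
recovery-oriented tests exercise the pipeline rather than Cas9-failure
dilution; tests that study activity or dispersion build their own
configs.
"""

import warnings

import pytest

import opscreen as op


@pytest.fixture(scope="session")
def demo_config() -> op.ScreenConfig:
    return op.ScreenConfig(
        n_genes=200,
        n_nontargeting=80,
        n_plates=3,
        cells_per_guide_mean=60,
        frac_zero_tpm=0.50,
        frac_hit_genes=0.15,
        effect_size=2.0,
        guide_activity_prob=1.0,
        n_vatpase_like=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def demo_screen(demo_config) -> op.ScreenDataset:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return op.generate_screen(demo_config)


@pytest.fixture(scope="session")
def demo_annotations(demo_screen) -> op.AnnotationSet:
    return op.generate_annotations(demo_screen)


@pytest.fixture(scope="session")
def demo_processed(demo_screen) -> op.ProcessedScreen:
    return op.process_cells(demo_screen.cells)


@pytest.fixture(scope="session")
def demo_scores(demo_processed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return op.score_screen(demo_processed.guide)


@pytest.fixture(scope="session")
def demo_truth(demo_screen):
    return demo_screen.truth.genes.set_index("gene")
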