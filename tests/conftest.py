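"""Shared fixtures: synthetic experiments at two scales.

The full-scale experiment mirrors the emulated study design (470
metabolites, 7 isolates, n=3 media replicates); the small experiment keeps
unit tests fast.  Both are session-scoped and deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from exoniche.io import FeatureTable
from exoniche.pipeline import PipelineConfig, analyze_experiment
from exoniche.simulate import GeneratorConfig, RELEASE_MEDIUM, generate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """Full-scale synthetic experiment at the emulated study design."""
    return generate_experiment(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_experiment):
    table, meta, _ = default_experiment
    cfg = PipelineConfig(release_medium=RELEASE_MEDIUM, assign_formulas=False)
    return analyze_experiment(table, meta, cfg)


SMALL_CONFIG = dict(
    n_metabolites=120,
    fraction_abundant=80 / 120,
    n_isolates=5,
    used_fraction_range=(0.2, 0.4),
)


@pytest.fixture(scope="session")
def small_experiment():
    return generate_experiment(GeneratorConfig(seed=11, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_result(small_experiment):
    table, meta, _ = small_experiment
    cfg = PipelineConfig(release_medium=RELEASE_MEDIUM, assign_formulas=False)
    return analyze_experiment(table, meta, cfg)


def make_feature_table(rows, intensities, sample_ids=None):
    """Tiny ad-hoc FeatureTable: rows = {fid: (mz, rt, polarity)}."""
    feats = pd.DataFrame(
        [(mz, rt, pol) for mz, rt, pol in rows.values()],
        index=pd.Index(list(rows), name="feature_id"),
        columns=["mz", "rt", "polarity"],
    )
    inten = np.asarray(intensities, float)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(inten.shape[1])]
    return FeatureTable(feats, pd.DataFrame(inten, index=feats.index, columns=sample_ids))
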