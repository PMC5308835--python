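import numpy as np
import pandas as pd
import pytest

from coexnet import (
    ExpressionMatrix,
    FeatureAnnotation,
    ModuleGene,
    ScreenConfig,
    SynthSpec,
)
from coexnet.screen import CorrelationRecord, ScreenResult


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_matrix():
    """4 features x 6 samples, one missing cell, one constant feature."""
    data = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            [1.5, np.nan, 2.5, 3.0, 2.0, 4.0],
        ]
    )
    df = pd.DataFrame(
        data,
        index=["f_up", "f_down", "f_flat", "f_gap"],
        columns=[f"s{i}" for i in range(1, 7)],
    )
    return ExpressionMatrix(dataset_id="toy", values=df)


@pytest.fixture
def small_spec():
    """Tiny planted-module spec for fast integration tests."""
    beta = 2.0  # population r = 0.8 with unit noise
    module = [
        ModuleGene("GSK3B", beta, 1),
        ModuleGene("ELAVL1", beta, 1),
        ModuleGene("MOD01", beta, 1),
        ModuleGene("MOD02", beta, -1),
        ModuleGene("MOD03", beta, 1),
    ]
    return SynthSpec(
        module=module,
        seed_gene="GSK3B",
        hub_gene="ELAVL1",
        n_background_genes=120,
        n_samples_1=80,
        n_samples_2=60,
        background_edge_prob=0.0,
        rng_seed=7,
    )


def make_screen(dataset_id, seed_symbol, rows, r_threshold=0.55, min_pairs=10):
    """Build a ScreenResult from (feature_id, symbol, n, r) tuples."""
    config = ScreenConfig(seed=seed_symbol, r_threshold=r_threshold, min_pairs=min_pairs)
    records = []
    for fid, sym, n, r in rows:
        passes = abs(r) > r_threshold and n >= min_pairs
        records.append(
            CorrelationRecord(
                feature_id=fid,
                gene_symbol=sym,
                n_pairs=n,
                r=r,
                p_analytic=0.5,
                p_permutation=None,
                direction=int(np.sign(r)),
                passes=passes,
            )
        )
    passing = sorted(
        (rec for rec in records if rec.passes),
        key=lambda rec: (-abs(rec.r), rec.feature_id),
    )
    return ScreenResult(
        dataset_id=dataset_id,
        seed_feature_id=seed_symbol,
        config=config,
        records=records,
        passing_ids=[rec.feature_id for rec in passing],
    )


@pytest.fixture
def identity_annotation():
    def _make(ids):
        return FeatureAnnotation.identity(ids)

    return _make
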