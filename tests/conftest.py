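import numpy as np
import pandas as pd
import pytest

from proppr.datatypes import IntensityMatrix
from proppr.simulate import (
    HistologySimConfig,
    LesionSpec,
    ProteomicsSimConfig,
    simulate_histology,
    simulate_proteomics,
)


def make_matrix(values: dict, meta_rows: list[tuple]) -> IntensityMatrix:
    """Hand-build a tiny IntensityMatrix.

    ``values`` maps sample id -> list of quantities (NaN = missing);
    ``meta_rows`` is (sample_id, disease, case, condition).
    """
    df = pd.DataFrame(values)
    df.index = [f"P{i}" for i in range(len(df))]
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "disease", "case",
                                            "condition"]).set_index("sample_id")
    return IntensityMatrix(values=df, meta=meta)


@pytest.fixture
def two_disease_matrix() -> IntensityMatrix:
    """Small deterministic two-disease matrix, 2 pulldown + 2 control each."""
    rng = np.random.default_rng(7)
    samples = {}
    meta = []
    for d in ("AD", "CBD"):
        for c in (1, 2):
            for cond in ("pulldown", "control"):
                sid = f"{d}_case{c}_{cond}"
                samples[sid] = rng.lognormal(10, 1, 20)
                meta.append((sid, d, f"{d}_case{c}", cond))
    return make_matrix(samples, meta)


@pytest.fixture
def spiked_run():
    """One seeded spike-in run: log2fc=3, 6+6 samples per disease."""
    cfg = ProteomicsSimConfig(seed=11)
    return simulate_proteomics(cfg)


@pytest.fixture
def noiseless_scene():
    """Mixed blob/thread/corona scene without noise, with ground truth."""
    cfg = HistologySimConfig(
        lesions=[
            LesionSpec("blob", (100, 100), 15, 0.6),
            LesionSpec("blob", (300, 300), 20, 1.0),
            LesionSpec("blob", (430, 430), 12, 0.0),
            LesionSpec("thread", (250, 100), 40, 0.3),
            LesionSpec("corona", (400, 120), 25, 0.8),
        ],
        noise_sd=0.0, seed=21)
    return simulate_histology(cfg)
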