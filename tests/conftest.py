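import numpy as np
import pandas as pd
import pytest

from crossmir.preprocess import CtMatrix


def make_ct_matrix(values: np.ndarray, detected: np.ndarray | None = None,
                   tissue: list[str] | None = None) -> CtMatrix:
    """Small helper: wrap a numeric array into a CtMatrix with generic metadata."""
    values = np.asarray(values, dtype=float)
    n_mir, n_samp = values.shape
    mirnas = [f"mmu-miR-t{i}" for i in range(n_mir)]
    samples = [f"S{j}" for j in range(n_samp)]
    if detected is None:
        detected = np.isfinite(values)
    if tissue is None:
        tissue = ["tumor"] * (n_samp // 2) + ["adrenal"] * (n_samp - n_samp // 2)
    meta = pd.DataFrame(
        {"species": "mouse", "tissue_class": tissue, "genotype": "TH-MYCN",
         "study": "test"},
        index=pd.Index(samples, name="sample_id"),
    )
    return CtMatrix(
        values=pd.DataFrame(values, index=mirnas, columns=samples),
        detected=pd.DataFrame(np.asarray(detected, dtype=bool), index=mirnas,
                              columns=samples),
        samples=meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_ct():
    """4 miRNAs x 4 samples, all detected, no censoring."""
    vals = np.array([
        [20.0, 21.0, 24.0, 25.0],
        [30.0, 29.0, 26.0, 27.0],
        [25.0, 25.5, 25.0, 24.5],
        [33.0, 32.0, 34.0, 33.5],
    ])
    return make_ct_matrix(vals)
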