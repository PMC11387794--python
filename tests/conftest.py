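import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cocusig import CultureExperiment, ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples, linear scale."""
    data = pd.DataFrame(
        [[1.0, 2.0], [3.5, 0.0], [10.0, 7.25]],
        index=["GENEA", "GENEB", "GENEC"],
        columns=["S1", "S2"],
    )
    return ExpressionMatrix(data)


def make_experiment(
    co: dict[str, list[float]],
    mono: dict[str, list[float]],
    dataset_id: str = "D1",
    cell_type: str = "cancer",
    scale: str = "linear",
) -> CultureExperiment:
    """Build a CultureExperiment from per-gene replicate values."""
    genes = list(co)
    assert list(mono) == genes
    n_co = len(next(iter(co.values())))
    n_mono = len(next(iter(mono.values())))
    cols = [f"mono{i}" for i in range(n_mono)] + [f"co{i}" for i in range(n_co)]
    rows = [list(mono[g]) + list(co[g]) for g in genes]
    mat = ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=cols), scale=scale)
    conditions = pd.Series(["mono"] * n_mono + ["co"] * n_co, index=cols)
    return CultureExperiment(dataset_id, cell_type, mat, conditions)


@pytest.fixture
def marker_universe() -> list[str]:
    return [
        "CDH1", "EPCAM", "CD24", "KRT5", "KRT14",
        "COL1A1", "COL1A2", "DCN", "CD248", "PDGFRA", "PDGFRB",
    ] + [f"G{i:03d}" for i in range(60)]


@pytest.fixture
def mono_profiles(marker_universe):
    """Carcinoma-like and fibroblast-like linear profiles over one universe."""
    rng = np.random.default_rng(7)
    carcinoma = pd.Series(rng.uniform(1.0, 50.0, len(marker_universe)), index=marker_universe)
    fibroblast = pd.Series(rng.uniform(1.0, 50.0, len(marker_universe)), index=marker_universe)
    carcinoma[["CDH1", "EPCAM", "CD24", "KRT5", "KRT14"]] += 200.0
    fibroblast[["COL1A1", "COL1A2", "DCN", "CD248", "PDGFRA", "PDGFRB"]] += 200.0
    return carcinoma, fibroblast
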