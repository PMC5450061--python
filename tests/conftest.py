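import numpy as np
import pandas as pd
import pytest

from cellverdict import io, pipeline as pl
from cellverdict.simulate import SimulationConfig, simulate, write_bundle


def make_matrix(values, genes, cells, unit=io.COUNTS, **kw):
    """Small ExpressionMatrix builder for hand-made examples."""
    return io.ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=cells),
        unit=unit,
        **kw,
    )


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic biopsy: chr7 gain + chr10 loss clone, 10% immune."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, d)
    return d


@pytest.fixture(scope="session")
def pipeline_result(bundle_dir):
    cfg = pl.load_config(bundle_dir / "config.yaml")
    return pl.run_pipeline(cfg, seed=1)


@pytest.fixture(scope="session")
def biopsy_cpm(bundle):
    return io.to_cpm(bundle.biopsy)


@pytest.fixture(scope="session")
def control_cpm(bundle):
    return io.to_cpm(bundle.control)


@pytest.fixture(scope="session")
def truth(bundle):
    return bundle.truth_cells.set_index("cell_id")
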