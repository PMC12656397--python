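import numpy as np
import pandas as pd
import pytest

from pmfrisk import default_element_registry, ELEMENT_ORDER
from pmfrisk.core_data import from_arrays


@pytest.fixture(scope="session")
def registry():
    return default_element_registry()


@pytest.fixture()
def small_table(registry):
    """Three samples, hand-set concentrations, with one below-MDL Cr cell."""
    conc = np.array(
        [
            # Cd    Cr    Cu    Ni    Pb    Zn    As    Hg
            [0.13, 85.0, 26.0, 36.2, 26.8, 68.4, 7.6, 0.030],
            [0.35, 2.0, 10.0, 20.0, 30.0, 50.0, 5.0, 0.020],
            [0.05, 60.0, 22.0, 25.0, 20.0, 60.0, 2.0, 0.001],
        ]
    )
    return from_arrays(conc, registry, ph=np.array([6.58, 6.58, 7.8]))


@pytest.fixture()
def sample_csv(tmp_path, small_table):
    from pmfrisk import write_samples

    path = tmp_path / "samples.csv"
    write_samples(small_table, path)
    return path


def write_csv(tmp_path, rows, header=None, name="t.csv"):
    header = header or ["sample_id", *ELEMENT_ORDER, "pH"]
    lines = [",".join(header)]
    lines += [",".join(str(v) for v in row) for row in rows]
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path
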