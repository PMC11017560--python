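import numpy as np
import pytest

import dentbayes as db


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def region_panel():
    """Small fully-observed three-region panel."""
    y = np.array([[0, 1, 1], [1, 0, 0], [0, 0, 1], [0, 1, 0]], dtype=float)
    return db.DefectPanel(
        list(range(4)), y, np.ones_like(y, dtype=bool), "regions",
        ("cervical", "middle", "incisal"),
    )


@pytest.fixture
def write_csv(tmp_path):
    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def eh_spec():
    return db.scenario_preset("EH_s1")
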