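import numpy as np
import pytest

from cmfqsar import ActivityTable, DescriptorTable


@pytest.fixture
def tiny_tables():
    """4 compounds x 3 cell lines with one missing cell, 2 descriptors."""
    rng = np.random.default_rng(42)
    mask = np.ones((4, 3))
    mask[1, 2] = 0
    x = ActivityTable(
        ["c1", "c2", "c3", "c4"], ["t1", "t2", "t3"],
        np.abs(rng.standard_normal((4, 3))), mask,
    )
    y = DescriptorTable(
        ["c1", "c2", "c3", "c4"], ["f1", "f2"],
        rng.standard_normal((4, 2)),
    )
    return x, y


@pytest.fixture
def activity_csv(tmp_path):
    p = tmp_path / "act.csv"
    p.write_text(
        "compound,t1,t2\n"
        "c1,1.5,2.0\n"
        "c2,,0.5\n"
        "c3,3.25,NA\n"
    )
    return p


@pytest.fixture
def descriptor_csv(tmp_path):
    p = tmp_path / "desc.csv"
    rows = ["compound," + ",".join(f"F{j}" for j in range(28))]
    rng = np.random.default_rng(7)
    for i in range(4):
        rows.append(f"c{i}," + ",".join(str(v) for v in rng.integers(0, 5, 28)))
    p.write_text("\n".join(rows) + "\n")
    return p
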