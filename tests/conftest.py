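import numpy as np
import pandas as pd
import pytest

from kinedelta import SpotTable


@pytest.fixture
def six_row_csv(tmp_path):
    """Two kinetochores x three channels, known coordinates."""
    path = tmp_path / "spots.csv"
    path.write_text(
        "cell_id,sister_pair_id,kinetochore_id,channel,x_nm,y_nm,z_nm,intensity,background\n"
        "c1,sp1,kt1,488,0.0,0.0,0.0,100.0,20.0\n"
        "c1,sp1,kt1,568,3.0,4.0,0.0,60.0,20.0\n"
        "c1,sp1,kt1,647,1.0,1.0,1.0,80.0,20.0\n"
        "c1,sp1,kt2,488,10.0,0.0,0.0,120.0,20.0\n"
        "c1,sp1,kt2,568,13.0,4.0,0.0,55.0,20.0\n"
        "c1,sp1,kt2,647,11.0,1.0,1.0,90.0,20.0\n"
    )
    return path


def make_table(records):
    """Build a SpotTable from (cell, kt, channel, x, y, z) tuples."""
    df = pd.DataFrame(
        records, columns=["cell_id", "kinetochore_id", "channel", "x_nm", "y_nm", "z_nm"]
    )
    return SpotTable(data=df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
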