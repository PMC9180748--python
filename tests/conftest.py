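import numpy as np
import pandas as pd
import pytest

from lysoquant import QuantMatrix


@pytest.fixture
def tiny_quant():
    """3 proteins × 4 samples with known means and metadata."""
    intensities = pd.DataFrame(
        {
            "ctrl_1": [19.0, 100.0, 50.0],
            "ctrl_2": [21.0, 102.0, 50.0],
            "case_1": [29.0, 99.0, 50.0],
            "case_2": [31.0, 101.0, 50.0],
        },
        index=pd.Index(["P00001", "P00002", "P00003"], name="accession"),
    )
    group_of = {"ctrl_1": "control", "ctrl_2": "control",
                "case_1": "case", "case_2": "case"}
    meta = pd.DataFrame(
        {
            "gene_symbol": ["GENEA", "GENEB", "GENEC"],
            "unique_peptides": [5, 3, 2],
            "id_fdr": [0.001, 0.005, 0.002],
        },
        index=intensities.index,
    )
    return QuantMatrix(intensities, group_of), meta


def disk_mask(radius_px, pad=10):
    """Digitized filled disk for geometry oracles."""
    n = 2 * radius_px + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
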