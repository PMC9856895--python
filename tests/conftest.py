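import pandas as pd
import pytest


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """Six-gene count table with the three calibrating controls planted enriched."""
    df = pd.DataFrame(
        {
            "gene_id": ["orb2", "act5C", "tub56D", "g1", "g2", "g3"],
            "biotype": ["protein_coding"] * 5 + ["other"],
            "input": [100, 200, 150, 100, 100, 100],
            "ip": [400, 700, 500, 600, 100, 600],
            "mock_ip": [100, 200, 150, 100, 100, 100],
        }
    ).set_index("gene_id")
    return df
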