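import numpy as np
import pandas as pd
import pytest

from senescreen import synthetic_marker_panel


@pytest.fixture(scope="session")
def panel():
    """Small self-contained marker panel driving the generators."""
    return synthetic_marker_panel(n_sasp=20, n_ecm=20, n_consensus_extra=10)


def make_de_table(genes, log2fc, p_adj, direction=None):
    """Hand-build a minimal direction-called DE table."""
    df = pd.DataFrame(
        {
            "gene": list(genes),
            "log2fc": np.asarray(log2fc, dtype=float),
            "t_moderated": 0.0,
            "p": np.asarray(p_adj, dtype=float),
            "p_adj": np.asarray(p_adj, dtype=float),
        }
    )
    if direction is None:
        direction = np.where(
            (df["p_adj"] < 0.05) & (df["log2fc"] > 0.5),
            "up",
            np.where((df["p_adj"] < 0.05) & (df["log2fc"] < -0.5), "down", "none"),
        )
    df["direction"] = direction
    return df
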