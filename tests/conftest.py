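import numpy as np
import pandas as pd
import pytest

from glycomine.features import featurize_table
from glycomine.quant import SampleDesign


@pytest.fixture(scope="session")
def design() -> SampleDesign:
    return SampleDesign.default_tmt10()


def make_igp_frame(rows, channels=None, intensities=None):
    """Build a featurized IGP frame from (protein, site, peptide, code,
    oacetyl, call, log2fc) tuples for mining tests."""
    df = pd.DataFrame(
        rows, columns=["protein_id", "glycosite", "peptide", "glycan_code",
                       "oacetyl", "call", "log2fc"])
    df["fc"] = 2.0 ** df["log2fc"]
    df = featurize_table(df)
    if channels:
        rng = np.random.default_rng(0)
        for ch in channels:
            df[ch] = intensities if intensities is not None \
                else rng.uniform(1e5, 1e6, len(df))
    return df


@pytest.fixture()
def small_igps():
    """Nine unique IGPs across three proteins with mixed calls."""
    man5 = "N(N(H(H)(H(H)(H))))"
    sial = "N(N(H(H(N(H(A))))(H(N(H)))))"          # Core-I, sialyl-LacNAc + LacNAc
    bis_sole = "N(N(H(N)(H(N))(H(N))))"             # Core-III, 2x sole GlcNAc
    ldn = "N(F)(N(H(H(N(N)))(H(N(H)))))"            # Core-II, LacdiNAc + LacNAc
    lewis = "N(N(H(H(N(F)(H)))(H(N(H)))))"          # Core-I, Lewis x/a + LacNAc
    rows = [
        ("P1", 107, "AAANK", sial, False, "up", 1.4),
        ("P1", 107, "AAANK", bis_sole, False, "down", -1.2),
        ("P1", 197, "CCNRT", man5, False, "up", 0.9),
        ("P2", 50, "DDNVS", ldn, False, "up", 2.6),
        ("P2", 50, "DDNVS", sial, True, "up", 1.1),
        ("P2", 88, "EENWT", lewis, False, "ns", 0.1),
        ("P3", 12, "FFNGS", bis_sole, False, "down", -1.9),
        ("P3", 12, "FFNGS", man5, False, "ns", -0.2),
        ("P3", 300, "GGNHT", ldn, False, "ns", 0.3),
    ]
    df = make_igp_frame(rows)
    df["sequon"] = ["NKS", "NKS", "NRT", "NVS", "NVS", "NWT", "NGS", "NGS",
                    "NHT"]
    df["p"] = np.where(df["call"] == "ns", 0.5, 0.001)
    return df
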