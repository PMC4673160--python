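import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from opnsplice.deconvolution import ExpressionMatrix
from opnsplice.spp1 import SPP1_EXONS, SPP1_ISOFORMS, ST21_OBSERVED_EXONS, spp1_incidence
from opnsplice.transcript_model import build_incidence


@pytest.fixture(scope="session")
def spp1_M():
    return spp1_incidence()


@pytest.fixture
def noise_free_expression():
    """Noise-free exon signals for hand-picked linear abundances.

    Abundances: OPNa=4, OPNb=3, OPNc=2, OPN4=1, OPN5=0.5 in every sample, so
    total=10.5, exon-5 signal=7.5 (a+b+5), exon-4 signal=0.5 (5 only).
    """
    truth = pd.DataFrame(
        {"OPNa": [4.0] * 4, "OPNb": [3.0] * 4, "OPNc": [2.0] * 4, "OPN4": [1.0] * 4,
         "OPN5": [0.5] * 4},
        index=[f"S{i}" for i in range(4)],
    )
    M = spp1_incidence()
    values = {}
    probe_to_exon = {}
    for e in ST21_OBSERVED_EXONS:
        carriers = M.carriers(e)
        signal = truth[list(carriers)].sum(axis=1)
        pid = f"PS{e:02d}_1"
        values[pid] = np.log2(signal)
        probe_to_exon[pid] = e
    X = ExpressionMatrix(values=pd.DataFrame(values, index=truth.index), probe_to_exon=probe_to_exon)
    return truth, X
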