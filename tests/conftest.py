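import numpy as np
import pandas as pd
import pytest

from xenomet.xenofilter import DualSpeciesCounts


@pytest.fixture
def tiny_dual() -> DualSpeciesCounts:
    """2 human + 2 mouse genes, 1 xenograft + 1 control of each species.

    Control read counts are chosen for easy hand arithmetic: the
    mouse-only library has 1,000,000 reads on mouse genes and gives 10
    reads to human gene hg1.
    """
    genes = ["hg1", "hg2", "mg1", "mg2"]
    samples = ["x1", "hc1", "mc1"]
    counts = pd.DataFrame(
        {
            # xenograft: human tumor + mouse stroma
            "x1": [1000, 500, 600_000, 400_000],
            # human-only control: pure human reads
            "hc1": [800_000, 200_000, 0, 0],
            # mouse-only control: pure mouse reads + cross-mapping into hg1
            "mc1": [10, 0, 700_000, 300_000],
        },
        index=genes,
    )
    gene_info = pd.DataFrame(
        {"species": ["human", "human", "mouse", "mouse"], "length_bp": [1000] * 4},
        index=genes,
    )
    sample_info = pd.DataFrame(
        {"class": ["xenograft", "human_only", "mouse_only"]}, index=samples
    )
    return DualSpeciesCounts(counts, gene_info, sample_info)
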