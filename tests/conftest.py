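import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from chipms.track import ProbeTrack


def make_track(ratios, chrom="chr1", spacing=300, length=60, label="", history=None):
    """Evenly spaced single-chromosome track from a list of ratios."""
    ratios = list(ratios)
    starts = [1 + i * spacing for i in range(len(ratios))]
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": [s + length - 1 for s in starts],
            "ratio": [float(r) for r in ratios],
        }
    )
    return ProbeTrack(data=df, label=label, history=list(history or []))


@pytest.fixture
def small_genome():
    from chipms.genome import simulate_genome

    return simulate_genome(
        chromosomes=[("chr1", 120_000), ("chr2", 80_000)], n_genes=60, seed=42
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
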