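import numpy as np
import pandas as pd
import pytest

from tmtdiff import EffectSpec, SampleDesign, default_design
from tmtdiff.design import DESIGN_COLUMNS


@pytest.fixture(scope="session")
def design16() -> SampleDesign:
    """The 16-plex two-cell-line design used throughout."""
    return default_design()


@pytest.fixture()
def small_design() -> SampleDesign:
    """Two conditions x three replicates, reference first."""
    rows = []
    for i in range(3):
        rows.append((f"R{i+1}", f"c{i+1}", "iDUX4", "DMSO", 14, i + 1, True))
    for i in range(3):
        rows.append((f"T{i+1}", f"c{i+4}", "iDUX4", "dox", 14, i + 1, False))
    return SampleDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


@pytest.fixture()
def noise_free_spec() -> EffectSpec:
    """Deterministic generator settings: every stochastic term switched off."""
    return EffectSpec(
        n_proteins=40,
        n_phosphopeptides=60,
        noise_sd_log2=0.0,
        ionization_spread_sd_log2=0.0,
        loading_offsets_log2=np.zeros(16),
        seed=11,
    )


def write_design_tsv(design: SampleDesign, path) -> None:
    from tmtdiff import write_design

    write_design(design, path)
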