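import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from c1census import synthetic_data as syn


@pytest.fixture(scope="session")
def small_reference():
    """A compact reference set shared by search-heavy tests: 3 focal and 2
    decoy strains, 10 gene families of identical length, 1 paralog pair."""
    return syn.generate_reference_set(
        n_focal=3, n_decoy=2, genes_per_proteome=10, paralog_pairs=1,
        seed=11, gene_length_mean=80, gene_length_jitter=0)
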