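from pathlib import Path

import pytest

from cd4lag3 import synthetic_data as sd


@pytest.fixture(scope="session")
def canonical():
    """One deterministic fixture gene per class (seed 1, plus strand)."""
    out = {}
    for cls in sd.CLASSES:
        out[cls] = sd.generate_gene(cls, seed=1, gene_id=f"fx_{cls}", strand="+")
    return out


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory) -> Path:
    """A 100-gene, mutation-free cohort written to disk (seed 7)."""
    d = tmp_path_factory.mktemp("cohort")
    sd.generate_cohort(sd.SimParams(n_per_class=25, mutation_rate=0.0, seed=7), outdir=d)
    return d
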