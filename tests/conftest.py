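import numpy as np
import pandas as pd
import pytest

import tadscape as ts
from tadscape import compare as cmp


def call_study(design):
    """Run simulate -> balance -> insulation -> call for every sample."""
    per_sample, tracks, group_of = {}, {}, {}
    for sample, grp, rep in design.samples():
        group_of[sample] = grp
        tracks[sample] = {}
        calls = []
        for chrom in design.chrom_sizes:
            m = ts.simulate_contact_matrix(design, grp, rep, chrom)
            mb = ts.ice_balance(m)
            tr = ts.insulation_scores(mb)
            calls.append(ts.call_boundaries(tr, sample=sample, group=grp))
            tracks[sample][chrom] = tr.delta
        per_sample[sample] = pd.concat(calls, ignore_index=True)
    return cmp.BoundarySetCollection(per_sample=per_sample, group_of=group_of,
                                     bin_size=design.bin_size, tracks=tracks)


@pytest.fixture(scope="session")
def planted_design():
    """Default 2x20 Mb, 2v2 study with six planted case-specific boundaries."""
    return ts.make_design(seed=1)


@pytest.fixture(scope="session")
def planted_truth(planted_design):
    return ts.truth_set(planted_design)


@pytest.fixture(scope="session")
def planted_collection(planted_design):
    """Boundary calls for the planted study (shared across tests; ~5 s)."""
    return call_study(planted_design)


@pytest.fixture(scope="session")
def null_design():
    return ts.make_design(seed=1, planted=False)


@pytest.fixture(scope="session")
def null_collection(null_design):
    return call_study(null_design)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
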