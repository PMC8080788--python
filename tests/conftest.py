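import numpy as np
import pytest

from scmira import ExpressionMatrix, fold_changes, make_fixture, normalize_counts
from scmira.mirna_seeds import dedupe_motifs
from scmira.motif_probability import probability_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced planted-signal dataset shared by the unit tests."""
    return make_fixture(
        seed=11,
        n_genes=600,
        n_cells=60,
        n_active=30,
        n_targets=80,
        n_mirnas=20,
        delta=1.0,
        library_size=60_000,
    )


@pytest.fixture(scope="session")
def small_pipeline(small_bundle):
    """Fold changes, motif map and probability table for the shared dataset."""
    b = small_bundle
    motif_map = dedupe_motifs(b.mirnas)
    prob = probability_table(sorted(motif_map), b.utrs)
    em = normalize_counts(ExpressionMatrix(b.counts))
    fc = fold_changes(em)
    return {"bundle": b, "motif_map": motif_map, "prob": prob, "fc": fc}
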