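import numpy as np
import pytest

from duodecon.synthetic import SyntheticSpec, generate_reference


@pytest.fixture(scope="session")
def small_ref():
    """A well-separated reference: 3 types, 200 genes, 300 cells/type, fold-8
    markers.  Session-scoped; treat as read-only."""
    spec = SyntheticSpec(n_cell_types=3, n_genes=200, cells_per_type=300,
                         n_markers_per_type=10, marker_fold_change=8.0,
                         baseline_mean=2.0, seed=123)
    return generate_reference(spec)


@pytest.fixture(scope="session")
def two_condition_ref():
    """Two-condition reference with planted condition DEGs (fold 4)."""
    spec = SyntheticSpec(n_cell_types=3, n_genes=300, cells_per_type=200,
                         n_markers_per_type=12, marker_fold_change=8.0,
                         n_conditions=2, n_condition_degs=10,
                         condition_fold_change=4.0, seed=321)
    return generate_reference(spec)
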