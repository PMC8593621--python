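import warnings

import pytest

import scnetkit as sk
from scnetkit import preprocess_embed as pe


@pytest.fixture(scope="session")
def planted_run():
    """Default planted-marker experiment plus its DE table (seed 0)."""
    exp, cat, truth = sk.generate_experiment(sk.SyntheticSpec())
    table = sk.compute_diffexp(exp, cat)
    return exp, cat, truth, table


@pytest.fixture(scope="session")
def separated_run():
    """Small fixture with three well-separated groups for embeddings."""
    spec = sk.SyntheticSpec(
        n_groups=3, cells_per_group=20, n_genes=120, markers_per_group=30,
        marker_log2fc=3.0, seed=0,
    )
    exp, cat, truth = sk.generate_experiment(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prepped, _ = pe.preprocess(exp, pe.PreprocessConfig(min_genes_per_cell=10))
    return exp, cat, prepped


@pytest.fixture(scope="session")
def marker_network_inputs(planted_run):
    """Marker selection plus a planted interaction fixture."""
    _, _, truth, table = planted_run
    markers = sk.select_markers(table)
    edges, alias, planted = sk.generate_interactions(truth, seed=1)
    source = sk.InteractionTable(
        edges=edges, alias=dict(zip(alias["gene"], alias["protein"]))
    )
    return markers, source, planted
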