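import numpy as np
import pytest

from neurograph.dgcnn import DGCNNConfig
from neurograph.fc_network import MDD, NC, BinaryAdjacency, BrainGraph
from neurograph.synthetic_data import SyntheticCohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects, 12 ROIs, 3 sites — fast enough for every protocol."""
    spec = SyntheticCohortSpec(
        n_per_group=10, n_rois=12, T=80, n_blocks=3, effect_delta=0.3, site_count=3, seed=7
    )
    return generate_cohort(spec)


@pytest.fixture
def tiny_config():
    """Small architecture for fast unit tests (valid head for k >= 10)."""
    return DGCNNConfig(
        conv_channels=(4, 2),
        conv1_filters=3,
        conv2_filters=4,
        dense_width=8,
        dropout_rate=0.0,
        epochs=3,
        batch_size=8,
        seed=0,
    )


def random_graph(rng, n=10, d=None, label=MDD, edge_p=0.35, site_id="siteA", subject_id=""):
    """Random symmetric binary graph with continuous node features."""
    d = n if d is None else d
    upper = np.triu((rng.random((n, n)) < edge_p).astype(np.uint8), k=1)
    entries = upper + upper.T
    feats = rng.standard_normal((n, d))
    return BrainGraph(
        adjacency=BinaryAdjacency(entries=entries, threshold=0.3),
        node_features=feats,
        label=label,
        site_id=site_id,
        subject_id=subject_id,
    )


@pytest.fixture
def random_graphs(rng):
    """16 random graphs, half per class, across two sites."""
    graphs = []
    for i in range(16):
        graphs.append(
            random_graph(
                rng,
                n=10,
                label=MDD if i % 2 == 0 else NC,
                site_id=f"site{(i // 2) % 2}",
                subject_id=f"subj{i:02d}",
            )
        )
    return graphs
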