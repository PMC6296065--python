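import numpy as np
import pytest

from pasnet import data as data_mod
from pasnet.pathways import BiadjacencyMatrix, PathwayCollection, build_biadjacency
from pasnet.simulate import SimulationDesign, simulate_dataset
from pasnet.training import TrainConfig, fit


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def toy_gmt(tmp_path):
    """Three-pathway GMT file with a duplicated symbol on the first line."""
    path = tmp_path / "toy.gmt"
    path.write_text(
        "P1\tdesc\tG1\tG2\tG2\n"
        "P2\tanother\tG2\tG3\tG4\n"
        "P3\tthird\tG5\tG1\n"
    )
    return path


@pytest.fixture
def toy_adjacency():
    """Hand-enumerated 3 pathways × 6 genes incidence."""
    pathways = PathwayCollection(
        [
            ("P1", {"G1", "G2", "G3"}),
            ("P2", {"G3", "G4", "G5"}),
            ("P3", {"G1", "G5", "G6"}),
        ]
    )
    genes = ["G1", "G2", "G3", "G4", "G5", "G6"]
    return build_biadjacency(pathways, genes, min_pathway_size=2)


def small_design(**overrides) -> SimulationDesign:
    base = dict(
        n_samples=80,
        n_genes=60,
        n_pathways=5,
        genes_per_pathway=(12, 12),
        n_informative_pathways=2,
        effect_size=2.0,
        minority_fraction=0.25,
        seed=7,
    )
    base.update(overrides)
    return SimulationDesign(**base)


def load_sim(design: SimulationDesign):
    """Simulate and assemble (Z, y, A, truth) ready for fitting."""
    ds = simulate_dataset(design)
    labels, _ = data_mod.derive_labels(ds.clinical, design.cutoff_months)
    pc = PathwayCollection([(n, set(g)) for n, g in ds.memberships])
    A = build_biadjacency(pc, list(ds.expression.columns), min_pathway_size=10)
    expr, labels, _ = data_mod.align_samples(ds.expression, labels)
    return expr[A.gene_names].to_numpy(), labels.to_numpy(), A, ds.truth


@pytest.fixture(scope="session")
def trained_small():
    """One small trained model shared by interpretation/serialization tests."""
    X, y, A, truth = load_sim(small_design())
    Z, _ = data_mod.standardize_fold(X)
    cfg = TrainConfig(
        max_epochs=80, patience=10**9, hidden_size=8,
        learning_rate=1e-2, seed=7,
    )
    state, log = fit(Z, y, A, cfg)
    return {"state": state, "log": log, "Z": Z, "y": y, "A": A, "truth": truth}


def tiny_state(seed=0, m=4, n=2, h=2, K=2, density=0.7):
    """Random small NetworkState with a non-trivial biadjacency."""
    from pasnet.network import initialize

    rng = np.random.default_rng(seed)
    while True:
        A = (rng.random((n, m)) < density).astype(np.int8)
        if A.sum(axis=1).min() >= 1 and A.sum(axis=0).min() >= 1:
            break
    bam = BiadjacencyMatrix(
        A, [f"P{i}" for i in range(n)], [f"G{j}" for j in range(m)]
    )
    return initialize(bam, h, K, seed=seed + 1), bam
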