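import numpy as np
import pytest

from enantioselect.core_data import MoleculeRole, ReactionFeatureTable
from enantioselect.synthetic_data import SyntheticSpec, generate


def make_table(
    n: int = 20,
    seed: int = 0,
    n_nucleophile: int = 2,
    n_imine: int = 1,
    n_solvent: int = 1,
    n_catalyst: int = 0,
    target: np.ndarray | None = None,
    coef: np.ndarray | None = None,
    noise_std: float = 0.0,
) -> ReactionFeatureTable:
    """Small dense table with linear target y = X @ coef + noise."""
    rng = np.random.default_rng(seed)
    names, roles = [], {}
    for role, count, stem in (
        (MoleculeRole.NUCLEOPHILE, n_nucleophile, "nu"),
        (MoleculeRole.IMINE, n_imine, "im"),
        (MoleculeRole.SOLVENT, n_solvent, "sol"),
        (MoleculeRole.CATALYST, n_catalyst, "cat"),
    ):
        for i in range(count):
            name = f"{stem}{i + 1}"
            names.append(name)
            roles[name] = role
    d = len(names)
    X = rng.standard_normal((n, d))
    if target is None:
        if coef is None:
            coef = np.zeros(d)
            coef[0] = 1.0
        target = X @ coef + noise_std * rng.standard_normal(n)
    return ReactionFeatureTable(
        reaction_ids=[f"rx{i}" for i in range(n)],
        features=X,
        feature_names=names,
        feature_roles=roles,
        target=np.asarray(target, dtype=float),
    )


@pytest.fixture(scope="session")
def default_pair():
    """One default-condition synthetic (train, test) pair, shared read-only."""
    return generate(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def small_pair():
    """A reduced table for fast end-to-end checks."""
    return generate(SyntheticSpec(seed=7, n_train=120, n_test=20,
                                  cluster_count_per_role=6))
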