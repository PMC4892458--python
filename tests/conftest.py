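import numpy as np
import pytest

import phylosoc as ps


@pytest.fixture
def worked_tree():
    """The hand-checkable 3-tip ultrametric tree ((a:1,b:1):1,c:2)."""
    return ps.parse_newick("((a:1,b:1):1,c:2);")


@pytest.fixture
def yule_tree_50():
    return ps.simulate_yule_tree(50, seed=42)


@pytest.fixture
def small_dataset():
    recs = [
        ps.SpeciesRecord("sp1", "wasp", 1.0, 10.0).with_category(),
        ps.SpeciesRecord("sp2", "wasp", 3.0, 12.0).with_category(),
        ps.SpeciesRecord("sp3", "ant", 2.0, 100.0).with_category(),
        ps.SpeciesRecord("sp4", "bird", 2.5, 5.0).with_category(),
        ps.SpeciesRecord("sp5", "mammal", 1.0, 1.0).with_category(),
    ]
    return ps.Dataset(records=recs, provenance="test")


def pgls_inputs(n_tips: int, seed: int, slope: float = -0.4, **scenario_kw):
    """Simulated tree + log-log regression inputs (multi-breeder filter off)."""
    tree = ps.simulate_yule_tree(n_tips, seed=seed)
    sc = ps.SyntheticScenario(
        n_species=n_tips, slope=slope, seed=seed + 1,
        fraction_single_breeder=0.0, **scenario_kw,
    )
    ds = ps.simulate_sociality_dataset(tree, sc)
    m = ps.compute_metrics(ds)
    corr = ps.correlation_from_tree(tree).reorder(list(m["species_id"]))
    y = np.log(m["proportion_breeders"].to_numpy())
    x = np.log(m["N"].to_numpy())
    return tree, m, corr, y, x
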