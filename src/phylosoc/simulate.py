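"""Synthetic phylogenies and trait tables with the statistical structure
the comparative analysis assumes.

Two generating scenarios mirror the competing hypotheses about social
structure:

* ``discrete`` — selection maintains a taxon-specific proportional
  decline of breeders with group size: log P = alpha + beta * log N
  plus a phylogenetically heritable (Brownian) deviation and
  independent residual noise, with a subset of species fixed at exactly
  one breeder (monogyny / singular breeding);
* ``continuum`` — any ratio of breeders to non-breeders is possible:
  log P is drawn independently of group size.

Group sizes are log-normal with an optional Brownian (phylogenetically
correlated) component, clamped at a floor ``n_min``; generated records
always satisfy 1 <= B <= N and pass dataset validation.  Taxon presets
encode the group-size ranges and slopes characteristic of social
insects (colonies up to ~10^6 females, steep declines) versus
vertebrates (groups of ~2-30 females, shallow declines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import dendropy
import numpy as np

from .data import Dataset, SpeciesRecord
from .trees import is_ultrametric, tree_depth

__all__ = [
    "SyntheticScenario",
    "simulate_yule_tree",
    "simulate_brownian",
    "simulate_sociality_dataset",
    "insect_like",
    "vertebrate_like",
    "taxon_preset",
    "TAXON_PRESETS",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the trait-generating model.

    ``sigma2_phylo`` and ``sigma2_resid`` are the tip-level variances of
    the heritable and independent components of log P.  The group-size
    distribution is log-normal (natural-log mean/sd) with a fraction
    ``group_size_phylo_frac`` of its variance phylogenetically
    correlated, floored at ``n_min`` females.
    """

    scenario: str = "discrete"
    n_species: int = 150
    fraction_single_breeder: float = 0.3
    intercept: float = 0.0
    slope: float = -0.4
    sigma2_phylo: float = 0.1
    sigma2_resid: float = 0.15
    group_size_log_mean: float = math.log(50.0)
    group_size_log_sd: float = 1.5
    group_size_phylo_frac: float = 0.5
    n_min: float = 2.0
    continuum_log_mean: float = -1.0
    continuum_log_sd: float = 0.8
    integer_counts: bool = False
    taxon: str = "other"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("discrete", "continuum"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "discrete" and self.slope > 0:
            raise ValueError("discrete scenario requires a non-positive slope")
        if not 0 <= self.fraction_single_breeder <= 1:
            raise ValueError("fraction_single_breeder must lie in [0, 1]")
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")

    def replace(self, **kw) -> "SyntheticScenario":
        return replace(self, **kw)


#: taxon presets parameterised from published per-taxon slopes and the
#: group-size ranges visible in comparative compilations
TAXON_PRESETS: dict[str, SyntheticScenario] = {
    "wasp": SyntheticScenario(
        taxon="wasp", slope=-0.378, fraction_single_breeder=0.2,
        group_size_log_mean=math.log(40.0), group_size_log_sd=1.2, n_min=6.0,
    ),
    "ant": SyntheticScenario(
        taxon="ant", slope=-0.672, fraction_single_breeder=0.8,
        group_size_log_mean=math.log(500.0), group_size_log_sd=2.0, n_min=20.0,
    ),
    "bird": SyntheticScenario(
        taxon="bird", slope=-0.404, fraction_single_breeder=0.5,
        group_size_log_mean=math.log(4.5), group_size_log_sd=0.5, n_min=2.0,
        sigma2_resid=0.08,
    ),
    "mammal": SyntheticScenario(
        taxon="mammal", slope=-0.206, fraction_single_breeder=0.4,
        group_size_log_mean=math.log(6.0), group_size_log_sd=0.6, n_min=2.0,
        sigma2_resid=0.08,
    ),
}


def insect_like(**overrides) -> SyntheticScenario:
    """Insect-style scenario: wide colony-size range, steep decline."""
    base = SyntheticScenario(
        taxon="other", slope=-0.55, group_size_log_mean=math.log(200.0),
        group_size_log_sd=2.2, n_min=5.0, fraction_single_breeder=0.4,
    )
    return base.replace(**overrides)


def vertebrate_like(**overrides) -> SyntheticScenario:
    """Vertebrate-style scenario: small groups (~2-30 females), shallow decline."""
    base = SyntheticScenario(
        taxon="other", slope=-0.2, group_size_log_mean=math.log(8.0),
        group_size_log_sd=0.7, n_min=2.0, fraction_single_breeder=0.3,
        sigma2_resid=0.08,
    )
    return base.replace(**overrides)


def taxon_preset(name: str, **overrides) -> SyntheticScenario:
    return TAXON_PRESETS[name].replace(**overrides)


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree conditioned on ``n_tips``.

    Starting from two lineages at the root, each of k extant lineages
    splits at total rate k * birth_rate; after the last split the tree
    grows for one further exponential holding time, so the expected
    root-to-tip depth is sum_{k=2..n} 1/(k * birth_rate).  Tips are
    labelled t1..tn deterministically; the same seed gives an
    identical tree.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        active.append((root.new_child(), 0.0))
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.edge.length = t - born
        active.append((node.new_child(), t))
        active.append((node.new_child(), t))
        k += 1
    t += rng.exponential(1.0 / (k * birth_rate))
    for node, born in active:
        node.edge.length = t - born
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.require_taxon(label=f"t{i + 1}")
    tree.is_rooted = True
    return tree


def simulate_brownian(
    tree: dendropy.Tree, sigma2: float, root_value: float = 0.0, seed: int = 0
) -> dict[str, float]:
    """Brownian motion along an ultrametric tree.

    Tip values are jointly normal with variance sigma2 * depth and
    covariance sigma2 * (depth of the shared path), i.e. sigma2 * depth
    times the tree's Brownian correlation matrix.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    ok, dev = is_ultrametric(tree)
    if not ok:
        raise ValueError(f"tree is not ultrametric (relative deviation {dev:.3g})")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            edge = node.edge.length or 0.0
            step = rng.normal(0.0, math.sqrt(sigma2 * edge)) if sigma2 > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def _standardized_bm(tree: dendropy.Tree, seed: int) -> dict[str, float]:
    """Brownian tip values standardised to unit variance at the tips."""
    depth = tree_depth(tree)
    return simulate_brownian(tree, 1.0 / depth, 0.0, seed)


def simulate_sociality_dataset(
    tree: dendropy.Tree, sc: SyntheticScenario
) -> Dataset:
    """Generate a species trait table on the tips of ``tree``.

    Uses the first ``sc.n_species`` tips (tip order).  All records
    satisfy 1 <= B <= N with N >= n_min; a ``fraction_single_breeder``
    subset is set to exactly one breeder.  Deterministic given
    ``sc.seed``.
    """
    from .trees import tip_labels

    labels = tip_labels(tree)
    if len(labels) < sc.n_species:
        raise ValueError(
            f"tree has {len(labels)} tips but the scenario asks for {sc.n_species}"
        )
    labels = labels[: sc.n_species]
    rng = np.random.default_rng(sc.seed)
    seed_n, seed_p = (int(s) for s in rng.integers(2**31, size=2))

    bm_n = _standardized_bm(tree, seed_n)
    z = rng.standard_normal(sc.n_species)
    f = sc.group_size_phylo_frac
    log_n = sc.group_size_log_mean + sc.group_size_log_sd * (
        math.sqrt(f) * np.array([bm_n[l] for l in labels]) + math.sqrt(1.0 - f) * z
    )
    N = np.maximum(np.exp(log_n), sc.n_min)

    depth = tree_depth(tree)
    bm_p_map = (
        simulate_brownian(tree, sc.sigma2_phylo / depth, 0.0, seed_p)
        if sc.sigma2_phylo > 0
        else {l: 0.0 for l in labels}
    )
    bm_p = np.array([bm_p_map[l] for l in labels])
    noise = rng.normal(0.0, math.sqrt(sc.sigma2_resid), sc.n_species)

    if sc.scenario == "discrete":
        log_p = sc.intercept + sc.slope * np.log(N) + bm_p + noise
    else:
        # log P independent of N: phylogenetic + iid parts rescaled to
        # the configured spread around the configured mean
        raw = bm_p + noise
        sd = math.sqrt(sc.sigma2_phylo + sc.sigma2_resid)
        log_p = sc.continuum_log_mean + sc.continuum_log_sd * (
            raw / sd if sd > 0 else rng.standard_normal(sc.n_species)
        )

    P = np.minimum(np.exp(log_p), 1.0)
    B = np.clip(P * N, 1.0, N)
    if sc.integer_counts:
        B = np.clip(np.round(B), 1.0, np.floor(N))

    n_single = int(round(sc.fraction_single_breeder * sc.n_species))
    if n_single > 0:
        single_idx = rng.choice(sc.n_species, size=n_single, replace=False)
        B[single_idx] = 1.0

    if not np.all((B >= 1.0) & (B <= N)):
        raise RuntimeError("generator produced an out-of-range record")

    records = [
        SpeciesRecord(
            species_id=lab,
            taxon_group=sc.taxon,
            mean_breeding_females=float(b),
            mean_total_females=float(n),
        ).with_category()
        for lab, b, n in zip(labels, B, N)
    ]
    return Dataset(records=records, provenance=f"synthetic:{sc.scenario}:seed={sc.seed}")
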