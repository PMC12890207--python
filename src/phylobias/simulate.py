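"""Birth–death tree simulation, incomplete sampling, and trait evolution.

The generator provides ground truth for testing how naive estimators behave
under incomplete taxon sampling: a complete birth–death tree (extinct
lineages retained), the reconstructed extant-only tree, a subsampled tree
under either uniform-random or one-representative-per-clade sampling, and
Brownian-motion trait values at every node of the complete tree.

Simulation is an exact Gillespie walk started from a crown pair (two
lineages at the crown age), so the crown age of the complete tree equals
the simulation duration.  A stem age is recorded as the crown age plus an
Exponential(lambda) stem branch, since the log(n)/t rate estimator needs a
stem age.  All randomness flows from explicit integer seeds; the same seed
always reproduces the same output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phylogeny import (
    ULTRAMETRIC_TOL,
    IntervalGrid,
    Phylogeny,
    TreeError,
    parse_newick,
    prune_to_tips,
)

import dendropy


@dataclass(frozen=True)
class SimParams:
    """Birth–death parameters: rates per lineage per My, a stopping rule, a seed.

    Exactly one of ``t_max`` (simulate for a fixed duration) or ``n_target``
    (stop when the extant count first reaches a target) must be set.
    ``mu < lam`` is required only in ``n_target`` mode, where a subcritical
    process might never reach the target.
    """

    lam: float
    mu: float = 0.0
    t_max: float | None = None
    n_target: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("speciation rate lam must be > 0")
        if self.mu < 0:
            raise ValueError("extinction rate mu must be >= 0")
        if (self.t_max is None) == (self.n_target is None):
            raise ValueError("set exactly one of t_max / n_target")
        if self.t_max is not None and self.t_max <= 0:
            raise ValueError("t_max must be > 0")
        if self.n_target is not None:
            if self.n_target < 2:
                raise ValueError("n_target must be >= 2")
            if self.mu >= self.lam:
                raise ValueError("n_target mode requires mu < lam")


@dataclass(frozen=True)
class SamplingScheme:
    """Incomplete-sampling scheme applied to an ultrametric tree.

    ``uniform`` keeps ``max(1, round(f * n))`` tips chosen uniformly without
    replacement.  ``one_per_clade`` keeps one uniformly chosen tip from each
    maximal clade whose crown age is younger than ``cutoff_age``, mimicking
    one-species-per-genus sampling of genus-level trees.
    """

    kind: str
    f: float | None = None
    cutoff_age: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "one_per_clade"):
            raise ValueError(f"unknown sampling kind {self.kind!r}")
        if self.kind == "uniform":
            if self.f is None or not (0 < self.f <= 1):
                raise ValueError("uniform sampling requires f in (0, 1]")
        else:
            if self.cutoff_age is None or self.cutoff_age <= 0:
                raise ValueError("one_per_clade sampling requires cutoff_age > 0")


@dataclass(frozen=True)
class TraitModel:
    """Brownian-motion trait model with an optional cladogenetic jump.

    Along each branch the state diffuses with variance ``sigma2`` per My.
    If ``cladogenetic_jump_sd > 0``, an additional independent
    Normal(0, jump_sd^2) jump is added at the origin of every daughter
    branch of a branching event; with ``sigma2`` small and jumps large the
    model approaches purely cladogenetic change.  If ``log_scale`` is true,
    states are interpreted as log-traits and mapped through exp() when
    positive tip traits (e.g. Vcmax-like capacities) are required.
    """

    sigma2: float
    root_state: float = 0.0
    cladogenetic_jump_sd: float = 0.0
    seed: int = 0
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.cladogenetic_jump_sd < 0:
            raise ValueError("cladogenetic_jump_sd must be >= 0")


@dataclass
class SimulationRecord:
    """Complete ground truth for one simulated dataset.

    ``true_origin_age`` maps each extant tip to the age of its parent node
    in the fully sampled reconstructed tree — the truth against which naive
    origin ages from the subsampled tree are compared.  ``node_states``
    maps every node label of the complete tree to its simulated trait
    state; ``tip_traits`` restricts that to extant tips (exponentiated when
    the trait model is on log scale).
    """

    complete_tree: Phylogeny
    reconstructed_tree: Phylogeny
    sampled_tree: Phylogeny
    sampled_labels: tuple[str, ...]
    true_origin_age: dict[str, float]
    node_states: dict[str, float]
    tip_traits: dict[str, float]
    params: SimParams | None = None
    scheme: SamplingScheme | None = None
    trait_model: TraitModel | None = None


# ---------------------------------------------------------------------------
# Birth–death simulation


class _Lineage:
    __slots__ = ("birth", "end", "children", "label", "extinct")

    def __init__(self, birth: float):
        self.birth = birth
        self.end: float | None = None
        self.children: list["_Lineage"] = []
        self.label: str | None = None
        self.extinct = False


def simulate_birth_death(params: SimParams) -> Phylogeny | None:
    """Simulate a complete birth–death tree from a crown pair.

    Returns the complete tree including extinct lineages (hence generally
    non-ultrametric), with tips labelled ``t1..`` and internal nodes
    ``n1..``, and a stem age drawn as crown age + Exponential(lam).
    Returns ``None`` if the whole clade goes extinct before ``t_max``
    (the explicit extinct outcome).  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    lam, mu = params.lam, params.mu

    root = _Lineage(0.0)
    left, right = _Lineage(0.0), _Lineage(0.0)
    root.end = 0.0
    root.children = [left, right]
    alive = [left, right]
    t = 0.0

    while True:
        n = len(alive)
        if n == 0:
            return None  # the whole clade went extinct
        if params.n_target is not None and n >= params.n_target:
            # stay in the n-lineage state for an exponential dwell so the
            # newest tips get positive pendant branches
            t += rng.exponential(1.0 / (n * (lam + mu)))
            break
        total = n * (lam + mu)
        wait = rng.exponential(1.0 / total)
        if params.t_max is not None and t + wait >= params.t_max:
            t = params.t_max
            break
        t += wait
        idx = rng.integers(n)
        lineage = alive[idx]
        lineage.end = t
        if rng.random() < lam / (lam + mu):
            a, b = _Lineage(t), _Lineage(t)
            lineage.children = [a, b]
            alive[idx] = a
            alive.append(b)
        else:
            lineage.extinct = True
            alive.pop(idx)

    present = t
    for lineage in alive:
        lineage.end = present

    tree = _to_phylogeny(root, present)
    tree.stem_age = tree.crown_age + rng.exponential(1.0 / lam)
    return tree


def _to_phylogeny(root: _Lineage, present: float) -> Phylogeny:
    """Convert the forward-time lineage record into a Phylogeny."""
    tns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)
    counters = {"tip": 0, "node": 0}

    def build(lineage: _Lineage, node: dendropy.Node) -> None:
        if lineage.children:
            counters["node"] += 1
            node.label = f"n{counters['node']}"
            for child in lineage.children:
                cn = node.new_child(edge_length=child.end - child.birth)
                build(child, cn)
        else:
            counters["tip"] += 1
            node.taxon = tns.new_taxon(f"t{counters['tip']}")

    build(root, dtree.seed_node)
    return Phylogeny(dtree)


def reconstruct_extant(complete: Phylogeny) -> Phylogeny:
    """Prune extinct lineages, giving the ultrametric reconstructed tree."""
    ages = complete.tip_ages()
    extant = [lab for lab, a in ages.items() if a <= ULTRAMETRIC_TOL]
    if not extant:
        raise TreeError("no extant tips to reconstruct")
    return prune_to_tips(complete, extant)


# ---------------------------------------------------------------------------
# Incomplete sampling


def apply_sampling(
    tree: Phylogeny, scheme: SamplingScheme
) -> tuple[Phylogeny, tuple[str, ...]]:
    """Subsample tips of an ultrametric tree under the given scheme.

    Returns the pruned tree and the kept labels; retained node ages are
    unchanged (pruning suppresses unifurcations with summed branch
    lengths).  Deterministic given ``scheme.seed``.
    """
    rng = np.random.default_rng(scheme.seed)
    labels = sorted(tree.tip_labels)
    if scheme.kind == "uniform":
        n_keep = int(round(scheme.f * len(labels)))
        if n_keep < 1:
            warnings.warn("f*n rounds to 0; keeping 1 tip", stacklevel=2)
            n_keep = 1
        keep = tuple(sorted(rng.choice(labels, size=n_keep, replace=False)))
    else:
        ages = tree.ages()
        keep_list: list[str] = []

        def visit(node: dendropy.Node) -> None:
            if node.is_leaf() or ages[node] < scheme.cutoff_age:
                tips = sorted(
                    t.taxon.label for t in (node.leaf_iter() if not node.is_leaf() else [node])
                )
                keep_list.append(tips[rng.integers(len(tips))])
            else:
                for child in node.child_nodes():
                    visit(child)

        visit(tree.root)
        keep = tuple(sorted(keep_list))
    return prune_to_tips(tree, keep), keep


# ---------------------------------------------------------------------------
# Trait evolution


def simulate_traits(tree: Phylogeny, model: TraitModel) -> dict[str, float]:
    """Simulate Brownian-motion states at every node of ``tree``.

    Returns a map from node label to state.  Unlabelled internal nodes are
    labelled in place (``nd1..``) so states can be keyed and serialised.
    Each child state is its parent state plus Normal(0, sigma2 * branch
    length), plus an independent Normal(0, jump_sd^2) cladogenetic jump
    when the parent is a branching event and jumps are enabled.
    """
    rng = np.random.default_rng(model.seed)
    states: dict[dendropy.Node, float] = {tree.root: model.root_state}
    fresh = 0
    out: dict[str, float] = {}
    for node in tree.dtree.preorder_node_iter():
        if node is not tree.root:
            parent = states[node.parent_node]
            step = rng.normal(0.0, np.sqrt(model.sigma2 * node.edge.length))
            jump = 0.0
            if model.cladogenetic_jump_sd > 0 and len(node.parent_node.child_nodes()) >= 2:
                jump = rng.normal(0.0, model.cladogenetic_jump_sd)
            states[node] = parent + step + jump
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
        else:
            if not node.label:
                fresh += 1
                node.label = f"nd{fresh}"
            label = node.label
        out[label] = states[node]
    return out


def tip_traits_from_states(
    tree: Phylogeny, states: dict[str, float], log_scale: bool = False
) -> dict[str, float]:
    """Extract tip trait values from node states, exponentiating if log-scale."""
    out = {}
    for lab in tree.tip_labels:
        v = states[lab]
        out[lab] = float(np.exp(v)) if log_scale else float(v)
    return out


# ---------------------------------------------------------------------------
# End-to-end record


def simulate_record(
    params: SimParams,
    scheme: SamplingScheme,
    trait_model: TraitModel,
    require_min_tips: int = 2,
    max_tries: int = 1000,
) -> SimulationRecord:
    """Simulate a full dataset: complete, reconstructed, and sampled trees plus traits.

    Re-draws (advancing the seed deterministically) if the clade goes
    extinct or yields fewer than ``require_min_tips`` extant tips, so the
    record is always usable downstream; the effective seeds are recorded in
    the trees' provenance via ``params``.
    """
    for k in range(max_tries):
        p = SimParams(
            lam=params.lam, mu=params.mu, t_max=params.t_max,
            n_target=params.n_target, seed=params.seed + k * 7919,
        )
        complete = simulate_birth_death(p)
        if complete is None:
            continue
        tip_ages = complete.tip_ages()
        n_extant = sum(1 for a in tip_ages.values() if a <= ULTRAMETRIC_TOL)
        if n_extant >= require_min_tips:
            params = p
            break
    else:
        raise TreeError(f"no surviving clade with >= {require_min_tips} tips in {max_tries} tries")

    reconstructed = reconstruct_extant(complete)
    sampled, kept = apply_sampling(reconstructed, scheme)
    states = simulate_traits(complete, trait_model)
    traits = tip_traits_from_states(reconstructed, states, trait_model.log_scale)
    true_origin = reconstructed.parent_ages()
    return SimulationRecord(
        complete_tree=complete,
        reconstructed_tree=reconstructed,
        sampled_tree=sampled,
        sampled_labels=kept,
        true_origin_age=true_origin,
        node_states=states,
        tip_traits=traits,
        params=params,
        scheme=scheme,
        trait_model=trait_model,
    )


# ---------------------------------------------------------------------------
# Worked-example fixture: four species, two cherries


FIG2_NEWICK = "((A:2.5,B:2.5)AB:5.0,(C:2.5,D:2.5)CD:5.0)R;"


def make_fig2_fixture() -> SimulationRecord:
    """Four-taxon worked example: sisters A/B and C/D each split 2.5 Mya,
    their common ancestor 7.5 Mya.

    Tip traits are the placeholder values {A: 1, B: 2, C: 3, D: 4};
    internal-node states are synthetic placeholders (child means), present
    only so the record is structurally complete.  The sampled tree is the
    incomplete-sampling variant with D removed; the complete variant is the
    record's reconstructed tree.
    """
    tree = parse_newick(FIG2_NEWICK)
    traits = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
    states = dict(traits)
    states["AB"] = 1.5
    states["CD"] = 3.5
    states["R"] = 2.5
    sampled = prune_to_tips(tree, {"A", "B", "C"})
    return SimulationRecord(
        complete_tree=tree,
        reconstructed_tree=tree,
        sampled_tree=sampled,
        sampled_labels=("A", "B", "C"),
        true_origin_age={lab: 2.5 for lab in "ABCD"},
        node_states=states,
        tip_traits=traits,
    )
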