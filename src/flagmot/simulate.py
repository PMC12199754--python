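"""Synthetic-data generators: trees, traits evolved under known CTMC rates,
and genome-scale homology hit tables with ground truth.

Every generator is a pure function of its parameters and a mandatory seed,
and emits exactly the objects/formats the rest of the pipeline consumes.
Ground truth (true node states, true presence/absence, true motility labels)
is returned alongside, never embedded in the pipeline-facing outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import registry
from .ctmc import (
    FOUR_STATES,
    RateModel,
    _edge_P_eig,
    _two_state_P,
    build_rate_matrix,
    flatten_tree,
    stationary_distribution,
)


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_tips`` leaves labelled ``t1..tn``.

    Every extant lineage splits at rate ``birth_rate``; after the n-th lineage
    appears, all pendant edges are extended by a final Exp(n·birth_rate)
    waiting time, so the expected root-to-tip depth is
    :math:`\\sum_{k=2}^{n} 1/(k\\,\\lambda)`.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    now = 0.0
    birth: dict[int, float] = {}
    active = []
    for _ in range(2):
        child = root.new_child()
        birth[id(child)] = now
        active.append(child)
    while len(active) < n_tips:
        k = len(active)
        now += rng.exponential(1.0 / (k * birth_rate))
        parent = active.pop(int(rng.integers(k)))
        parent.edge.length = now - birth.pop(id(parent))
        for _ in range(2):
            child = parent.new_child()
            birth[id(child)] = now
            active.append(child)
    now += rng.exponential(1.0 / (len(active) * birth_rate))
    for i, node in enumerate(active, start=1):
        node.edge.length = now - birth.pop(id(node))
        node.taxon = taxa.new_taxon(f"t{i}")
    return tree


@dataclass
class TraitSimulation:
    """Tip states plus the hidden truth of a trait simulation."""

    tips: pd.DataFrame                 # columns: taxon, state
    node_states: np.ndarray            # state index per flattened-tree node
    root_state: int
    states: tuple[str, ...]
    tree_arrays: object = field(repr=False, default=None)

    def tip_dict(self) -> dict[str, str]:
        return dict(zip(self.tips["taxon"], self.tips["state"]))


def _simulate_states(arrays, P, k, root_state, rng) -> np.ndarray:
    states = np.empty(arrays.n_nodes, dtype=np.int64)
    states[arrays.root] = root_state
    for node in arrays.postorder[::-1]:
        par = arrays.parent[node]
        if par < 0:
            continue
        probs = P[node, states[par]]
        probs = np.clip(probs, 0, None)
        probs = probs / probs.sum()
        states[node] = rng.choice(k, p=probs)
    return states


def simulate_binary_trait(tree, q01: float, q10: float,
                          root_state: int | None = None,
                          seed: int = 0) -> TraitSimulation:
    """Evolve a binary trait tip-ward using exact 2-state transition kernels.

    ``root_state`` defaults to a draw from the stationary distribution
    q01/(q01+q10) for state 1.
    """
    if q01 < 0 or q10 < 0 or q01 + q10 <= 0:
        raise ValueError("rates must be non-negative with q01 + q10 > 0")
    rng = np.random.default_rng(seed)
    arrays = flatten_tree(tree) if isinstance(tree, dendropy.Tree) else tree
    if root_state is None:
        pi1 = q01 / (q01 + q10)
        root_state = int(rng.random() < pi1)
    P = _two_state_P(q01, q10, arrays.lengths)
    states = _simulate_states(arrays, P, 2, root_state, rng)
    tips = pd.DataFrame({
        "taxon": list(arrays.tip_index),
        "state": [str(states[i]) for i in arrays.tip_index.values()],
    })
    return TraitSimulation(tips=tips, node_states=states, root_state=root_state,
                           states=("0", "1"), tree_arrays=arrays)


def simulate_pair_traits(tree, model: RateModel,
                         root_state: str | None = None,
                         seed: int = 0) -> TraitSimulation:
    """Evolve a joint 4-state trait pair (states 00/01/10/11) under a
    dependent or independent model; double changes never occur within the
    embedded jump process because the generator forbids them."""
    if model.n_states != 4:
        raise ValueError("pair simulation needs a 4-state model")
    rng = np.random.default_rng(seed)
    arrays = flatten_tree(tree) if isinstance(tree, dendropy.Tree) else tree
    Q = build_rate_matrix(model)
    if root_state is None:
        pi = stationary_distribution(Q)
        root_idx = int(rng.choice(4, p=pi))
    else:
        root_idx = FOUR_STATES.index(root_state)
    P = _edge_P_eig(Q, arrays.lengths)
    row_sums = P.sum(axis=2, keepdims=True)
    P = P / row_sums
    states = _simulate_states(arrays, P, 4, root_idx, rng)
    tips = pd.DataFrame({
        "taxon": list(arrays.tip_index),
        "state": [FOUR_STATES[states[i]] for i in arrays.tip_index.values()],
    })
    return TraitSimulation(tips=tips, node_states=states, root_state=root_idx,
                           states=FOUR_STATES, tree_arrays=arrays)


def split_pair_traits(sim: TraitSimulation) -> tuple[dict, dict]:
    """Decompose a 4-state simulation into the two marginal binary traits."""
    tips = sim.tip_dict()
    return ({t: s[0] for t, s in tips.items()},
            {t: s[1] for t, s in tips.items()})


@dataclass
class HitTableSpec:
    """Conditions for the synthetic genome screen.

    The protein-count distribution is bimodal: non-motile genomes draw
    Poisson(``nonmotile_count_mean``) proteins from the non-filament classes,
    motile genomes draw round-Normal(``motile_count_mean``,
    ``motile_count_sd``) proteins and always carry flagellin (FliC), so every
    truth-motile genome has at least one filament protein and (by default)
    no truth-non-motile genome has any.
    """

    n_genomes: int = 1000
    motile_fraction: float = 0.5
    nonmotile_count_mean: float = 8.0
    motile_count_mean: float = 40.0
    motile_count_sd: float = 3.0
    filament_weight_nonmotile: float = 0.0
    decoy_mean_per_genome: float = 2.0

    def __post_init__(self):
        if not 0 <= self.motile_fraction <= 1:
            raise ValueError("motile_fraction must be in [0, 1]")
        if self.nonmotile_count_mean > 15 or self.motile_count_mean < 32:
            import warnings
            warnings.warn("count modes overlap the 15/32 thresholds; "
                          "classifier recovery will degrade", stacklevel=2)


@dataclass
class HitSimulation:
    hits: pd.DataFrame            # pipeline input (includes filter-violating decoys)
    truth_labels: pd.DataFrame    # genome_id, label, n_fp
    truth_matrix: pd.DataFrame    # genomes x 54 binary, the post-filter truth


def simulate_hit_tables(spec: HitTableSpec | None = None,
                        seed: int = 0) -> HitSimulation:
    """Generate a raw homology hit table plus its ground truth.

    Each truly present protein gets one hit that passes every filter
    (e-value ≤ 1e-10, length inside the registry range); decoy hits that
    violate the e-value or length filter are sprinkled on random proteins so
    that unfiltered binarization would over-call presence.
    """
    spec = spec or HitTableSpec()
    rng = np.random.default_rng(seed)
    specs = registry.default_query_specs()
    proteins = registry.default_protein_names()
    class_map = registry.default_class_map()
    filament = [p for p in proteins if class_map[p] == "filament"]
    non_filament = [p for p in proteins if class_map[p] != "filament"]

    rows, truth_rows = [], []
    matrix = pd.DataFrame(0, index=[f"g{i + 1}" for i in range(spec.n_genomes)],
                          columns=proteins, dtype=np.int8)
    for gi in range(spec.n_genomes):
        gid = f"g{gi + 1}"
        motile = rng.random() < spec.motile_fraction
        if motile:
            count = int(np.clip(round(rng.normal(spec.motile_count_mean,
                                                 spec.motile_count_sd)), 1, 54))
            present = ["FliC"]
            others = [p for p in proteins if p != "FliC"]
            extra = rng.choice(len(others), size=count - 1, replace=False)
            present += [others[i] for i in extra]
        else:
            pool = list(non_filament)
            if spec.filament_weight_nonmotile > 0:
                for p in filament:
                    if rng.random() < spec.filament_weight_nonmotile:
                        pool.append(p)
            count = int(min(rng.poisson(spec.nonmotile_count_mean), len(pool)))
            chosen = rng.choice(len(pool), size=count, replace=False)
            present = [pool[i] for i in chosen]
        for p in present:
            ps = specs[p]
            rows.append((gid, p, 10.0 ** (-rng.uniform(12, 60)),
                         int(rng.integers(ps.length_min, ps.length_max + 1)),
                         f"{gid}|{p}|ok"))
            matrix.loc[gid, p] = 1
        n_decoys = rng.poisson(spec.decoy_mean_per_genome)
        for d in range(n_decoys):
            p = proteins[rng.integers(len(proteins))]
            ps = specs[p]
            if rng.random() < 0.5:  # fails the e-value filter
                ev = 10.0 ** (-rng.uniform(2, 9.9))
                ln = int(rng.integers(ps.length_min, ps.length_max + 1))
            else:  # fails the length filter
                ev = 10.0 ** (-rng.uniform(12, 60))
                ln = int(ps.length_max + rng.integers(10, 200))
            rows.append((gid, p, ev, ln, f"{gid}|{p}|decoy{d}"))
        truth_rows.append((gid, "motile" if motile else "non-motile", len(present)))

    hits = pd.DataFrame(rows, columns=["genome_id", "query_protein", "e_value",
                                       "subject_length", "subject_id"])
    hits = hits.sample(frac=1.0, random_state=int(rng.integers(2 ** 31))).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=["genome_id", "label", "n_fp"])
    return HitSimulation(hits=hits, truth_labels=truth, truth_matrix=matrix)


def simulate_phenotype_labels(truth_labels: pd.DataFrame, flip_rate: float = 0.0,
                              seed: int = 0) -> pd.DataFrame:
    """Observed-phenotype table: the truth with independent label flips."""
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    flip = {"motile": "non-motile", "non-motile": "motile"}
    out = []
    for _, row in truth_labels.iterrows():
        label = row["label"]
        if label not in flip:
            continue
        if rng.random() < flip_rate:
            label = flip[label]
        out.append((row["genome_id"], label))
    return pd.DataFrame(out, columns=["taxon", "phenotype"])
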