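r"""Continuous-time Markov chains for discrete traits on rooted phylogenies.

The models are the standard Mk-family generators used for binary-trait
macroevolution:

* ``two_state_equal`` — one rate ``q`` for both directions,
  :math:`Q = \begin{pmatrix}-q & q\\ q & -q\end{pmatrix}`;
* ``two_state_free`` — asymmetric gain/loss rates ``q01`` (0→1) and
  ``q10`` (1→0);
* ``four_state_independent`` — two binary traits evolving independently;
  the joint generator is the Kronecker sum of the two 2-state generators;
* ``four_state_dependent`` — Pagel's correlated-evolution model over the
  paired states 00/01/10/11, with eight free transition rates and the two
  double-change transitions (00↔11, 01↔10) structurally forbidden.

Likelihoods are computed by Felsenstein's pruning algorithm with per-node
rescaling, so trees with thousands of tips do not underflow. The 2-state
transition probabilities use the closed form

.. math::
   P_{01}(t) = \frac{q_{01}}{q_{01}+q_{10}}\,(1 - e^{-(q_{01}+q_{10})t}),

and the 4-state ones an eigendecomposition of the generator (with a
scaling-and-squaring matrix exponential as fallback for ill-conditioned
eigensystems).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm, null_space

from ._pruning import loglik_2state, loglik_slots, loglik_slots4, prune_kernel

TWO_STATES = ("0", "1")
FOUR_STATES = ("00", "01", "10", "11")

#: free-parameter names per model kind, in canonical order
PARAM_NAMES = {
    "two_state_equal": ("q",),
    "two_state_free": ("q01", "q10"),
    "four_state_independent": ("qA01", "qA10", "qB01", "qB10"),
    "four_state_dependent": (
        "q00_01", "q00_10", "q01_00", "q01_11",
        "q10_00", "q10_11", "q11_01", "q11_10",
    ),
}


@dataclass(frozen=True)
class RateModel:
    """A CTMC rate model: a kind plus its named positive rates."""

    kind: str
    rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in PARAM_NAMES:
            raise ValueError(f"unknown model kind {self.kind!r}")
        names = PARAM_NAMES[self.kind]
        missing = set(names) - set(self.rates)
        if missing:
            raise ValueError(f"{self.kind}: missing rate(s) {sorted(missing)}")
        for name in names:
            if not self.rates[name] >= 0:
                raise ValueError(f"{self.kind}: rate {name} must be >= 0, "
                                 f"got {self.rates[name]}")

    @property
    def n_states(self) -> int:
        return 2 if self.kind.startswith("two") else 4

    @property
    def states(self) -> tuple[str, ...]:
        return TWO_STATES if self.n_states == 2 else FOUR_STATES

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.kind]

    def rate_vector(self) -> np.ndarray:
        return np.array([self.rates[n] for n in self.param_names])

    def with_rates(self, vector: Sequence[float]) -> "RateModel":
        return replace(self, rates=dict(zip(self.param_names, map(float, vector))))


def two_state_equal(q: float) -> RateModel:
    return RateModel("two_state_equal", {"q": q})


def two_state_free(q01: float, q10: float) -> RateModel:
    return RateModel("two_state_free", {"q01": q01, "q10": q10})


def four_state_independent(qA01, qA10, qB01, qB10) -> RateModel:
    return RateModel("four_state_independent",
                     {"qA01": qA01, "qA10": qA10, "qB01": qB01, "qB10": qB10})


def four_state_dependent(**rates: float) -> RateModel:
    return RateModel("four_state_dependent", dict(rates))


def dependent_from_independent(model: RateModel) -> RateModel:
    """Embed an independent pair model in the dependent parameterization."""
    r = model.rates
    return four_state_dependent(
        q00_01=r["qB01"], q00_10=r["qA01"], q01_00=r["qB10"], q01_11=r["qA01"],
        q10_00=r["qA10"], q10_11=r["qB01"], q11_01=r["qA10"], q11_10=r["qB10"],
    )


def build_rate_matrix(model: RateModel) -> np.ndarray:
    """Generator matrix Q for a model; rows sum to zero, structural zeros kept."""
    r = model.rates
    if model.kind == "two_state_equal":
        q = r["q"]
        Q = np.array([[-q, q], [q, -q]], dtype=float)
    elif model.kind == "two_state_free":
        Q = np.array([[-r["q01"], r["q01"]], [r["q10"], -r["q10"]]], dtype=float)
    elif model.kind == "four_state_independent":
        QA = np.array([[-r["qA01"], r["qA01"]], [r["qA10"], -r["qA10"]]])
        QB = np.array([[-r["qB01"], r["qB01"]], [r["qB10"], -r["qB10"]]])
        Q = np.kron(QA, np.eye(2)) + np.kron(np.eye(2), QB)
    elif model.kind == "four_state_dependent":
        # state order 00, 01, 10, 11; no simultaneous double changes
        Q = np.zeros((4, 4))
        idx = {"00": 0, "01": 1, "10": 2, "11": 3}
        for name, value in r.items():
            src, dst = name[1:].split("_")
            Q[idx[src], idx[dst]] = value
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
    else:  # pragma: no cover - guarded in RateModel
        raise ValueError(model.kind)
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); closed form for 2 states, expm otherwise. Requires t >= 0."""
    if t < 0:
        raise ValueError(f"negative time {t}")
    Q = np.asarray(Q, dtype=float)
    if Q.shape == (2, 2):
        return _two_state_P(Q[0, 1], Q[1, 0], np.array([t]))[0]
    return expm(Q * t)


def _two_state_P(q01: float, q10: float, lengths: np.ndarray) -> np.ndarray:
    """Closed-form 2-state transition matrices for a vector of durations."""
    n = lengths.shape[0]
    P = np.empty((n, 2, 2))
    s = q01 + q10
    if s <= 0:
        P[:] = np.eye(2)
        return P
    pi1 = q01 / s
    pi0 = q10 / s
    e = np.exp(-s * lengths)
    P[:, 0, 0] = pi0 + pi1 * e
    P[:, 0, 1] = pi1 * (1.0 - e)
    P[:, 1, 0] = pi0 * (1.0 - e)
    P[:, 1, 1] = pi1 + pi0 * e
    return P


def _edge_P_eig(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q t_e) for every edge via one eigendecomposition of Q."""
    k = Q.shape[0]
    w, V = np.linalg.eig(Q)
    use_eig = True
    try:
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) > 1e10:
            use_eig = False
    except np.linalg.LinAlgError:
        use_eig = False
    if use_eig:
        E = np.exp(np.multiply.outer(lengths, w))
        P = np.einsum("ij,nj,jk->nik", V, E, Vinv)
        P = np.ascontiguousarray(P.real)
    else:
        P = np.stack([expm(Q * t) for t in lengths])
    np.clip(P, 0.0, None, out=P)
    return P


@dataclass
class TreeArrays:
    """A rooted tree flattened to index arrays for fast likelihood passes."""

    postorder: np.ndarray        # node indices, root last
    parent: np.ndarray           # parent index per node, -1 at root
    lengths: np.ndarray          # length of the edge above each node (root: 0)
    root: int
    tip_index: dict[str, int]    # tip label -> node index
    n_nodes: int

    @property
    def n_tips(self) -> int:
        return len(self.tip_index)


def flatten_tree(tree: dendropy.Tree) -> TreeArrays:
    """Index a dendropy tree for array-based traversal."""
    nodes = list(tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    lengths = np.zeros(n)
    tip_index: dict[str, int] = {}
    for node in nodes:
        i = index[id(node)]
        if node.parent_node is not None:
            parent[i] = index[id(node.parent_node)]
            lengths[i] = node.edge.length if node.edge.length is not None else 0.0
        if node.is_leaf():
            if node.taxon is None:
                raise ValueError("tip without a label")
            tip_index[node.taxon.label] = i
    return TreeArrays(
        postorder=np.arange(n, dtype=np.int64),
        parent=parent,
        lengths=lengths,
        root=index[id(tree.seed_node)],
        tip_index=tip_index,
        n_nodes=n,
    )


def _as_arrays(tree) -> TreeArrays:
    return tree if isinstance(tree, TreeArrays) else flatten_tree(tree)


def _trait_mapping(traits) -> Mapping[str, str]:
    if isinstance(traits, pd.DataFrame):
        return dict(zip(traits["taxon"], traits["state"].astype(str)))
    return {str(k): str(v) for k, v in dict(traits).items()}


def tip_partials(arrays: TreeArrays, traits, states: Sequence[str],
                 missing: str = "-") -> np.ndarray:
    """Seed the per-node conditional likelihood table from observed tip states.

    Missing tips (state ``-``) contribute a partial likelihood of 1 in every
    state; internal nodes start at 1 by construction.
    """
    mapping = _trait_mapping(traits)
    k = len(states)
    state_idx = {s: i for i, s in enumerate(states)}
    partials = np.ones((arrays.n_nodes, k))
    for label, node in arrays.tip_index.items():
        if label not in mapping:
            raise ValueError(f"tip {label!r} absent from trait table "
                             f"(use {missing!r} to mark missing data)")
        state = mapping[label]
        if state == missing:
            continue
        if state not in state_idx:
            raise ValueError(f"tip {label!r}: state {state!r} not in {list(states)}")
        partials[node] = 0.0
        partials[node, state_idx[state]] = 1.0
    return partials


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    ns = null_space(Q.T)
    if ns.shape[1] == 0:
        raise ValueError("generator has no stationary distribution")
    pi = np.abs(ns[:, 0])
    return pi / pi.sum()


def resolve_root_prior(prior, Q: np.ndarray, root_partials=None) -> np.ndarray:
    """Root-state weighting: 'flat' (default), 'equilibrium', 'fitzjohn', or a vector."""
    k = Q.shape[0]
    if isinstance(prior, str):
        if prior == "flat":
            return np.full(k, 1.0 / k)
        if prior == "equilibrium":
            return stationary_distribution(Q)
        if prior == "fitzjohn":
            if root_partials is None:
                raise ValueError("fitzjohn weighting needs the root partials")
            total = root_partials.sum()
            if total <= 0:
                return np.full(k, 1.0 / k)
            return root_partials / total
        raise ValueError(f"unknown root prior {prior!r}")
    vec = np.asarray(prior, dtype=float)
    if vec.shape != (k,) or (vec < 0).any() or not np.isclose(vec.sum(), 1.0):
        raise ValueError("root prior vector must be non-negative and sum to 1")
    return vec


def edge_transition_matrices(model: RateModel, arrays: TreeArrays) -> np.ndarray:
    Q = build_rate_matrix(model)
    if model.n_states == 2:
        return _two_state_P(Q[0, 1], Q[1, 0], arrays.lengths)
    return _edge_P_eig(Q, arrays.lengths)


def pruning_log_likelihood(tree, traits, model: RateModel,
                           root_prior="flat") -> float:
    """Log-likelihood of tip states under a CTMC, by pruning with rescaling."""
    arrays = _as_arrays(tree)
    partials = tip_partials(arrays, traits, model.states)
    P = edge_transition_matrices(model, arrays)
    log_scale = prune_kernel(arrays.postorder, arrays.parent, P, partials,
                             arrays.root)
    if np.isnan(log_scale):
        return -np.inf
    Q = build_rate_matrix(model)
    prior = resolve_root_prior(root_prior, Q, partials[arrays.root])
    site = float(prior @ partials[arrays.root])
    if site <= 0:
        return -np.inf
    return log_scale + np.log(site)


def _finish(log_scale: float, prior: np.ndarray, root_partial: np.ndarray) -> float:
    if np.isnan(log_scale):
        return -np.inf
    site = float(prior @ root_partial)
    if site <= 0:
        return -np.inf
    return log_scale + np.log(site)


def _two_state_prior(root_prior, q01: float, q10: float,
                     root_partial: np.ndarray) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "flat":
            return np.array([0.5, 0.5])
        if root_prior == "equilibrium":
            s = q01 + q10
            return np.array([q10 / s, q01 / s]) if s > 0 else np.array([0.5, 0.5])
        if root_prior == "fitzjohn":
            total = root_partial.sum()
            return (root_partial / total if total > 0 else np.array([0.5, 0.5]))
        raise ValueError(f"unknown root prior {root_prior!r}")
    return resolve_root_prior(root_prior, np.zeros((2, 2)), root_partial)


def _real_eigensystem(Q: np.ndarray, tol: float = 1e-9):
    """Real modal decomposition Q = V B V⁻¹ with 2x2 blocks for conjugate
    eigenpairs; returns None when the eigensystem is unreliable."""
    k = Q.shape[0]
    try:
        w, Vc = np.linalg.eig(Q)
    except np.linalg.LinAlgError:
        return None
    scale = max(1.0, float(np.abs(w).max()))
    V = np.empty((k, k))
    a = np.empty(k)
    b = np.zeros(k)
    pair_first = np.zeros(k, dtype=np.bool_)
    j = 0
    while j < k:
        if abs(w[j].imag) <= tol * scale:
            V[:, j] = Vc[:, j].real
            a[j] = w[j].real
            j += 1
        else:
            if j + 1 >= k or abs(w[j + 1] - np.conj(w[j])) > 10 * tol * scale:
                return None
            wj, vj = (w[j], Vc[:, j]) if w[j].imag > 0 else (w[j + 1], Vc[:, j + 1])
            V[:, j] = vj.real
            V[:, j + 1] = vj.imag
            a[j] = a[j + 1] = wj.real
            b[j] = wj.imag
            pair_first[j] = True
            j += 2
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return None
    B = np.diag(a)
    for jj in range(k):
        if pair_first[jj]:
            B[jj, jj + 1] = b[jj]
            B[jj + 1, jj] = -b[jj]
    if np.abs(V @ B @ Vinv - Q).max() > 1e-8 * (1.0 + np.abs(Q).max()):
        return None
    return a, b, pair_first, V, Vinv


def make_loglik(tree, traits, kind: str, root_prior="flat"):
    """Bind tree+data once and return ``f(rate_vector) -> logL`` for samplers.

    The flattened tree and the tip indicator table are cached, and the pass
    runs in a compiled kernel: 2-state models use the closed-form transition
    probabilities inline; the independent pair model factorizes into its two
    2-state marginals (valid for flat/equilibrium root weightings); the
    dependent model diagonalizes its 4x4 generator once per call, with a
    dense matrix-exponential fallback when the eigensystem is unreliable.
    """
    arrays = _as_arrays(tree)
    template = RateModel(kind, dict.fromkeys(PARAM_NAMES[kind], 1.0))
    base = tip_partials(arrays, traits, template.states)
    tip_rows = list(arrays.tip_index.values())
    informative = bool((base[tip_rows] == 0).any())
    order, parent, lengths, root = (arrays.postorder, arrays.parent,
                                    arrays.lengths, arrays.root)

    factorizable = (kind == "four_state_independent"
                    and root_prior in ("flat", "equilibrium"))
    if kind in ("two_state_equal", "two_state_free"):
        work = np.empty_like(base)

        def loglik(vector: np.ndarray) -> float:
            if not informative:
                return 0.0
            q01, q10 = ((vector[0], vector[0]) if kind == "two_state_equal"
                        else (vector[0], vector[1]))
            e = np.exp(-(q01 + q10) * lengths)
            log_scale = loglik_2state(order, parent, e, base, work,
                                      root, q01, q10)
            prior = _two_state_prior(root_prior, q01, q10, work[root])
            return _finish(log_scale, prior, work[root])

    elif factorizable:
        # marginal indicator tables: joint state 2a+b -> per-trait indicators
        baseA = np.ones((arrays.n_nodes, 2))
        baseB = np.ones((arrays.n_nodes, 2))
        for i in tip_rows:
            if (base[i] == 1).all():
                continue
            joint = base[i].reshape(2, 2)
            baseA[i] = joint.max(axis=1)
            baseB[i] = joint.max(axis=0)
        workA = np.empty_like(baseA)
        workB = np.empty_like(baseB)

        def loglik(vector: np.ndarray) -> float:
            if not informative:
                return 0.0
            qA01, qA10, qB01, qB10 = vector
            eA = np.exp(-(qA01 + qA10) * lengths)
            eB = np.exp(-(qB01 + qB10) * lengths)
            lsA = loglik_2state(order, parent, eA, baseA, workA, root,
                                qA01, qA10)
            lsB = loglik_2state(order, parent, eB, baseB, workB, root,
                                qB01, qB10)
            llA = _finish(lsA, _two_state_prior(root_prior, qA01, qA10,
                                                workA[root]), workA[root])
            llB = _finish(lsB, _two_state_prior(root_prior, qB01, qB10,
                                                workB[root]), workB[root])
            return llA + llB

    else:
        work = np.empty_like(base)
        k = template.n_states
        zeros_sin = np.zeros((arrays.n_nodes, k))
        buf_cos = np.empty((arrays.n_nodes, k))
        buf_sin = np.empty((arrays.n_nodes, k))
        kernel = loglik_slots4 if k == 4 else loglik_slots

        def loglik(vector: np.ndarray) -> float:
            if not informative:
                return 0.0
            model = template.with_rates(vector)
            Q = build_rate_matrix(model)
            eigensystem = _real_eigensystem(Q)
            if eigensystem is not None:
                a, b, pair_first, V, Vinv = eigensystem
                np.multiply(lengths[:, None], a[None, :], out=buf_cos)
                np.exp(buf_cos, out=buf_cos)
                if pair_first.any():
                    np.multiply(lengths[:, None], b[None, :], out=buf_sin)
                    np.sin(buf_sin, out=buf_sin)
                    cos_bt = np.cos(np.multiply.outer(lengths, b))
                    np.multiply(buf_sin, buf_cos, out=buf_sin)
                    np.multiply(buf_cos, cos_bt, out=buf_cos)
                    expsin = buf_sin
                else:
                    expsin = zeros_sin
                log_scale = kernel(order, parent, base, work, root,
                                   buf_cos, expsin, pair_first, V, Vinv)
            else:
                partials = base.copy()
                P = np.stack([expm(Q * t) for t in lengths])
                log_scale = prune_kernel(order, parent, P, partials, root)
                work[:] = partials
            prior = resolve_root_prior(root_prior, Q, work[root])
            return _finish(log_scale, prior, work[root])

    loglik.arrays = arrays
    loglik.kind = kind
    loglik.n_params = len(PARAM_NAMES[kind])
    return loglik


def pair_trait_table(traitA, traitB) -> dict[str, str]:
    """Join two binary traits into the 00/01/10/11 coding (missing if either is)."""
    a = _trait_mapping(traitA)
    b = _trait_mapping(traitB)
    if set(a) != set(b):
        raise ValueError("trait tables cover different tip sets")
    joined = {}
    for taxon, sa in a.items():
        sb = b[taxon]
        joined[taxon] = "-" if "-" in (sa, sb) else sa + sb
    return joined


def independent_pair_log_likelihood(tree, traitA, traitB,
                                    ratesA: tuple[float, float],
                                    ratesB: tuple[float, float],
                                    root_prior="flat") -> float:
    """4-state independent-model log-likelihood of a trait pair.

    Equal, by construction, to the sum of the two separate 2-state
    log-likelihoods under a product root prior.
    """
    model = four_state_independent(ratesA[0], ratesA[1], ratesB[0], ratesB[1])
    return pruning_log_likelihood(tree, pair_trait_table(traitA, traitB),
                                  model, root_prior=root_prior)


def ancestral_marginals(tree, traits, model: RateModel,
                        root_prior="flat") -> np.ndarray:
    """Marginal posterior state probabilities for every node at fixed rates.

    Inside–outside (up–down) pass: the up pass is pruning; the outside pass
    propagates root-to-tip using sibling messages, so each node's marginal is
    proportional to inside × outside. Rows sum to 1.
    """
    arrays = _as_arrays(tree)
    k = model.n_states
    P = edge_transition_matrices(model, arrays)
    inside = tip_partials(arrays, traits, model.states)
    messages = np.ones((arrays.n_nodes, k))  # child->parent message per node

    children: list[list[int]] = [[] for _ in range(arrays.n_nodes)]
    for node in range(arrays.n_nodes):
        if arrays.parent[node] >= 0:
            children[arrays.parent[node]].append(node)

    for node in arrays.postorder:
        m = inside[node].max()
        if m > 0:
            inside[node] /= m
        if arrays.parent[node] >= 0:
            messages[node] = P[node] @ inside[node]
            inside[arrays.parent[node]] *= messages[node]

    Q = build_rate_matrix(model)
    prior = resolve_root_prior(root_prior, Q, inside[arrays.root])
    outside = np.zeros((arrays.n_nodes, k))
    outside[arrays.root] = prior
    for node in arrays.postorder[::-1]:
        for child in children[node]:
            sib = outside[node] * inside[node]
            with np.errstate(divide="ignore", invalid="ignore"):
                sib = np.where(messages[child] > 0, sib / messages[child], 0.0)
            outside[child] = P[child].T @ sib
            m = outside[child].max()
            if m > 0:
                outside[child] /= m

    marg = inside * outside
    totals = marg.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return marg / totals
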