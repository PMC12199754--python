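"""Bayesian inference of trait-evolution rates on phylogenies.

A Metropolis–Hastings sampler targets the posterior over CTMC rates under a
uniform(0, 100) prior per rate; marginal likelihoods come from stepping-stone
sampling along a prior-to-posterior power path; models are compared with
logBF = 2·(logML_complex − logML_simple), read as positive support above 2.
Ancestral states are marginal node posteriors averaged over retained rate
samples. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from . import ctmc
from .ctmc import PARAM_NAMES, RateModel, make_loglik, pair_trait_table


@dataclass
class MCMCSettings:
    """Chain-length and prior configuration.

    ``iterations`` is the total chain length including the ``burn_in``
    prefix; every ``thin``-th post-burn-in state is retained, giving
    floor((iterations - burn_in)/thin) samples. The per-rate prior is
    uniform over ``rate_prior``; the sliding-window proposal scale is
    auto-tuned during burn-in toward 20–40% acceptance, then frozen.
    """

    iterations: int = 5_000_000
    burn_in: int = 300_000
    thin: int = 5_000
    seed: int = 0
    proposal_scale: float | None = None
    rate_prior: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self):
        if not self.burn_in < self.iterations:
            raise ValueError("burn_in must be below iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        lo, hi = self.rate_prior
        if not 0 <= lo < hi:
            raise ValueError("rate_prior must be (lo, hi) with 0 <= lo < hi")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


#: chain lengths used for desk-scale analyses (the full-corpus defaults above
#: mirror a 5M-iteration production run)
REDUCED = MCMCSettings(iterations=50_000, burn_in=10_000, thin=40)


@dataclass
class MCMCChain:
    samples: np.ndarray          # (n_samples, n_rates)
    log_likelihoods: np.ndarray  # (n_samples,)
    acceptance_rate: float
    param_names: tuple[str, ...]
    settings: MCMCSettings

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.samples, columns=list(self.param_names))
        frame["logL"] = self.log_likelihoods
        return frame


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    return x


def _sample_chain(loglik: Callable, settings: MCMCSettings, rng,
                  power: float = 1.0, init: np.ndarray | None = None,
                  collect_all_loglik: bool = False):
    """Core MH loop over rate vectors; one coordinate updated per iteration."""
    k = loglik.n_params
    lo, hi = settings.rate_prior
    x = (np.asarray(init, dtype=float) if init is not None
         else rng.uniform(max(lo, 1e-3), min(hi, 2.0), size=k))
    cur = power * loglik(x)
    scale = np.full(k, settings.proposal_scale
                    if settings.proposal_scale is not None else (hi - lo) / 20)
    window_acc = np.zeros(k)
    window_n = np.zeros(k)
    n_acc = 0
    n_prop = 0
    samples = np.empty((settings.n_samples, k))
    logls = np.empty(settings.n_samples)
    all_logls = [] if collect_all_loglik else None
    kept = 0
    for it in range(settings.iterations):
        j = it % k
        prop = x.copy()
        prop[j] = _reflect(x[j] + (rng.random() - 0.5) * scale[j], lo, hi)
        cand = power * loglik(prop)
        accept = cand >= cur or rng.random() < np.exp(cand - cur)
        window_n[j] += 1
        if accept:
            x = prop
            cur = cand
            window_acc[j] += 1
        if it >= settings.burn_in:
            n_prop += 1
            n_acc += int(accept)
            if collect_all_loglik:
                all_logls.append(cur / power if power > 0 else loglik(x))
            if (it + 1 - settings.burn_in) % settings.thin == 0:
                samples[kept] = x
                logls[kept] = cur / power if power > 0 else loglik(x)
                kept += 1
        elif window_n[j] >= 50:
            rate = window_acc[j] / window_n[j]
            if rate > 0.4:
                scale[j] = min(scale[j] * 1.4, hi - lo)
            elif rate < 0.2:
                scale[j] /= 1.4
            window_acc[j] = window_n[j] = 0
    acc_rate = n_acc / max(n_prop, 1)
    return samples[:kept], logls[:kept], acc_rate, x, (np.asarray(all_logls)
                                                       if collect_all_loglik else None)


def run_mcmc(tree, traits, model: RateModel | str,
             settings: MCMCSettings | None = None,
             root_prior="flat") -> MCMCChain:
    """Posterior sampling of the rates of ``model`` given tip states.

    ``model`` may be a :class:`RateModel` (its rates are ignored — only the
    kind matters) or a kind string. Deterministic given ``settings.seed``.
    """
    settings = settings or MCMCSettings()
    kind = model.kind if isinstance(model, RateModel) else model
    loglik = make_loglik(tree, traits, kind, root_prior=root_prior)
    rng = np.random.default_rng(settings.seed)
    samples, logls, acc, _, _ = _sample_chain(loglik, settings, rng)
    if acc == 0:
        raise RuntimeError("zero MCMC acceptance after tuning; "
                           "proposal scale is pathological")
    return MCMCChain(samples=samples, log_likelihoods=logls,
                     acceptance_rate=acc, param_names=PARAM_NAMES[kind],
                     settings=settings)


@dataclass
class RatePosterior:
    """Posterior mean, credible interval, and ESS per rate."""

    summary: pd.DataFrame  # index: rate name; columns: mean, lower, upper, ess
    ci_level: float = 0.95

    def mean(self, name: str) -> float:
        return float(self.summary.loc[name, "mean"])


def summarize_rate_posterior(chain: MCMCChain, ci: float = 0.95) -> RatePosterior:
    if len(chain.samples) == 0:
        raise ValueError("empty chain")
    alpha = (1 - ci) / 2
    rows = {}
    for j, name in enumerate(chain.param_names):
        draws = chain.samples[:, j]
        if np.allclose(draws, draws[0]):
            ess = float(len(draws))
        else:
            ess = float(az.ess(az.convert_to_dataset(draws[None, :])).x)
        rows[name] = {
            "mean": float(draws.mean()),
            "lower": float(np.quantile(draws, alpha)),
            "upper": float(np.quantile(draws, 1 - alpha)),
            "ess": ess,
        }
    return RatePosterior(summary=pd.DataFrame(rows).T, ci_level=ci)


@dataclass
class MarginalLikelihood:
    log_ml: float
    n_stones: int
    iterations_per_stone: int
    betas: np.ndarray = field(repr=False)


def stepping_stone_schedule(n_stones: int, alpha: float = 0.4) -> np.ndarray:
    """Power schedule β_k = (k/K)^(1/α), the Beta(α, 1)-quantile spacing that
    concentrates stones near the prior where the integrand varies fastest."""
    return (np.arange(n_stones + 1) / n_stones) ** (1 / alpha)


def estimate_log_marginal_likelihood(tree, traits, model: RateModel | str,
                                     settings: MCMCSettings | None = None,
                                     n_stones: int = 32,
                                     alpha: float = 0.4,
                                     root_prior="flat") -> MarginalLikelihood:
    """Stepping-stone estimate of log ∫ L(θ) π(θ) dθ.

    Samples are drawn at each power β_k of the path prior→posterior (iid from
    the prior at β=0, warm-started MH chains above), and the marginal
    likelihood accumulates the log importance ratios
    log E_{β_k}[L^{β_{k+1}-β_k}]. With a uniform prior and no data the
    estimate is exactly 0.
    """
    settings = settings or MCMCSettings()
    kind = model.kind if isinstance(model, RateModel) else model
    loglik = make_loglik(tree, traits, kind, root_prior=root_prior)
    rng = np.random.default_rng(settings.seed)
    betas = stepping_stone_schedule(n_stones, alpha)
    per_stone = max((settings.iterations - settings.burn_in) // n_stones, 50)
    stone_burn = max(settings.burn_in // n_stones, 20)
    lo, hi = settings.rate_prior
    k = loglik.n_params

    log_ml = 0.0
    state = None
    for s in range(n_stones):
        beta = betas[s]
        if beta == 0.0:
            draws = rng.uniform(lo, hi, size=(per_stone, k))
            logls = np.array([loglik(v) for v in draws])
            state = draws[-1]
        else:
            stone_settings = replace(settings,
                                     iterations=stone_burn + per_stone,
                                     burn_in=stone_burn, thin=1)
            _, _, _, state, logls = _sample_chain(
                loglik, stone_settings, rng, power=beta, init=state,
                collect_all_loglik=True)
        delta = betas[s + 1] - beta
        finite = np.isfinite(logls)
        if not finite.any():
            raise RuntimeError(f"no finite likelihoods at stone {s}")
        # -inf log-likelihoods contribute zero weight
        log_ml += logsumexp(delta * logls[finite]) - np.log(len(logls))
    return MarginalLikelihood(log_ml=float(log_ml), n_stones=n_stones,
                              iterations_per_stone=per_stone, betas=betas)


@dataclass
class ModelComparison:
    """logBF = 2·(logML_complex − logML_simple); >2 reads as positive support."""

    log_ml_complex: float
    log_ml_simple: float

    @property
    def log_bf(self) -> float:
        return 2.0 * (self.log_ml_complex - self.log_ml_simple)

    @property
    def significant(self) -> bool:
        return self.log_bf > 2.0


def log_bayes_factor(ml_complex, ml_simple) -> ModelComparison:
    c = ml_complex.log_ml if isinstance(ml_complex, MarginalLikelihood) else float(ml_complex)
    s = ml_simple.log_ml if isinstance(ml_simple, MarginalLikelihood) else float(ml_simple)
    if not (np.isfinite(c) and np.isfinite(s)):
        raise ValueError("marginal likelihoods must be finite")
    return ModelComparison(log_ml_complex=c, log_ml_simple=s)


@dataclass
class AncestralReconstruction:
    """Marginal state posteriors per node, averaged over rate samples."""

    probabilities: pd.DataFrame  # index: node id; columns: states
    labels: pd.Series            # argmax state, 'tie' at exact 0.5
    root_id: int

    @property
    def root_probabilities(self) -> pd.Series:
        return self.probabilities.loc[self.root_id]


def reconstruct_ancestral_states(tree, traits, chain: MCMCChain,
                                 model: RateModel | str,
                                 nodes: Sequence[int] | None = None,
                                 root_prior="flat",
                                 max_samples: int = 100) -> AncestralReconstruction:
    """Average the fixed-rate marginal node posteriors over retained samples.

    ``nodes`` restricts the reported rows (flattened-tree node indices);
    the root row equals the model's root-state posterior.
    """
    kind = model.kind if isinstance(model, RateModel) else model
    arrays = ctmc._as_arrays(tree)
    template = RateModel(kind, dict.fromkeys(PARAM_NAMES[kind], 1.0))
    take = np.linspace(0, len(chain.samples) - 1,
                       min(max_samples, len(chain.samples))).astype(int)
    acc = np.zeros((arrays.n_nodes, template.n_states))
    for idx in np.unique(take):
        model_i = template.with_rates(chain.samples[idx])
        acc += ctmc.ancestral_marginals(arrays, traits, model_i,
                                        root_prior=root_prior)
    acc /= len(np.unique(take))
    probs = pd.DataFrame(acc, columns=list(template.states))
    if nodes is not None:
        unknown = set(nodes) - set(range(arrays.n_nodes))
        if unknown:
            raise KeyError(f"unknown node id(s): {sorted(unknown)}")
        probs = probs.loc[list(nodes)]
    top = probs.max(axis=1)
    tie = np.isclose(top, 1.0 / template.n_states, rtol=0.0, atol=1e-9)
    labels = probs.idxmax(axis=1).where(~tie, other="tie")
    return AncestralReconstruction(probabilities=probs, labels=labels,
                                   root_id=arrays.root)


def _is_constant(traits) -> bool:
    mapping = ctmc._trait_mapping(traits)
    observed = {v for v in mapping.values() if v != "-"}
    return len(observed) < 2


@dataclass
class AsymmetryResult:
    comparison: ModelComparison          # free vs equal rates
    posterior: RatePosterior             # free-model (q01, q10)
    chain: MCMCChain
    direction: str                       # 'loss-biased' | 'gain-biased'

    @property
    def log_bf(self) -> float:
        return self.comparison.log_bf


def test_rate_asymmetry(tree, trait, settings: MCMCSettings | None = None,
                        n_stones: int = 32, root_prior="flat") -> AsymmetryResult:
    """Equal- vs free-rates model choice for one binary trait.

    Stepping-stone logMLs for ``two_state_equal`` and ``two_state_free`` give
    logBF = 2·(logML_free − logML_equal); the free-model posterior classifies
    the direction (loss-biased when mean q10 > mean q01). Constant traits are
    rejected — the comparison is undefined for them.
    """
    if _is_constant(trait):
        raise ValueError("trait is constant across tips; logBF undefined")
    settings = settings or MCMCSettings()
    ml_equal = estimate_log_marginal_likelihood(
        tree, trait, "two_state_equal", settings, n_stones, root_prior=root_prior)
    ml_free = estimate_log_marginal_likelihood(
        tree, trait, "two_state_free",
        replace(settings, seed=settings.seed + 1), n_stones, root_prior=root_prior)
    chain = run_mcmc(tree, trait, "two_state_free",
                     replace(settings, seed=settings.seed + 2),
                     root_prior=root_prior)
    posterior = summarize_rate_posterior(chain)
    direction = ("loss-biased" if posterior.mean("q10") > posterior.mean("q01")
                 else "gain-biased")
    return AsymmetryResult(comparison=log_bayes_factor(ml_free, ml_equal),
                           posterior=posterior, chain=chain, direction=direction)


def test_correlated_evolution(tree, traitA, traitB,
                              settings: MCMCSettings | None = None,
                              n_stones: int = 32,
                              root_prior="flat") -> ModelComparison:
    """Pagel's dependent vs independent model for two binary traits.

    The traits are paired into the 4-state coding 00/01/10/11 and both
    models fit by stepping-stone; logBF = 2·(logML_dependent −
    logML_independent). Symmetric in the order of the traits up to the
    state relabelling, which both models' likelihoods are invariant to.
    """
    if _is_constant(traitA) or _is_constant(traitB):
        raise ValueError("correlation test needs both traits non-constant")
    settings = settings or MCMCSettings()
    joint = pair_trait_table(traitA, traitB)
    ml_indep = estimate_log_marginal_likelihood(
        tree, joint, "four_state_independent", settings, n_stones,
        root_prior=root_prior)
    ml_dep = estimate_log_marginal_likelihood(
        tree, joint, "four_state_dependent",
        replace(settings, seed=settings.seed + 1), n_stones,
        root_prior=root_prior)
    return log_bayes_factor(ml_dep, ml_indep)


def compare_rates_to_reference(rate_posteriors: pd.DataFrame,
                               reference_protein: str,
                               fold: float = 10.0) -> pd.DataFrame:
    """Per-protein gain/loss posterior means as fold changes vs a reference.

    ``rate_posteriors`` is indexed by protein with columns ``q01`` and
    ``q10`` (posterior means). Flags mark ratios ≥ ``fold`` or ≤ 1/``fold``.
    """
    if reference_protein not in rate_posteriors.index:
        raise KeyError(f"reference protein {reference_protein!r} missing")
    ref = rate_posteriors.loc[reference_protein]
    out = pd.DataFrame(index=rate_posteriors.index)
    out["gain_ratio"] = rate_posteriors["q01"] / ref["q01"]
    out["loss_ratio"] = rate_posteriors["q10"] / ref["q10"]
    out["gain_tenfold_up"] = out["gain_ratio"] >= fold
    out["gain_tenfold_down"] = out["gain_ratio"] <= 1.0 / fold
    out["loss_tenfold_up"] = out["loss_ratio"] >= fold
    out["loss_tenfold_down"] = out["loss_ratio"] <= 1.0 / fold
    return out


class CTMCRateEstimator(BaseEstimator):
    """Sklearn-style wrapper: posterior rate estimation for one trait.

    ``fit(tree, traits)`` runs the MH sampler and exposes ``chain_``,
    ``posterior_``, ``rates_`` (posterior means), and the root-state
    posterior ``root_probabilities_`` from ancestral reconstruction.
    """

    def __init__(self, kind: str = "two_state_free", iterations: int = 50_000,
                 burn_in: int = 10_000, thin: int = 40, seed: int = 0,
                 rate_prior: tuple[float, float] = (0.0, 100.0),
                 root_prior="flat"):
        self.kind = kind
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.rate_prior = rate_prior
        self.root_prior = root_prior

    def _settings(self) -> MCMCSettings:
        return MCMCSettings(iterations=self.iterations, burn_in=self.burn_in,
                            thin=self.thin, seed=self.seed,
                            rate_prior=tuple(self.rate_prior))

    def fit(self, tree, traits):
        self.chain_ = run_mcmc(tree, traits, self.kind, self._settings(),
                               root_prior=self.root_prior)
        self.posterior_ = summarize_rate_posterior(self.chain_)
        self.rates_ = {n: self.posterior_.mean(n)
                       for n in self.chain_.param_names}
        recon = reconstruct_ancestral_states(tree, traits, self.chain_,
                                             self.kind,
                                             root_prior=self.root_prior)
        self.ancestral_ = recon
        self.root_probabilities_ = recon.root_probabilities
        return self


class RateAsymmetryTest(BaseEstimator):
    """Sklearn-style wrapper around :func:`test_rate_asymmetry`."""

    def __init__(self, iterations: int = 50_000, burn_in: int = 10_000,
                 thin: int = 40, seed: int = 0, n_stones: int = 16,
                 root_prior="flat"):
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.n_stones = n_stones
        self.root_prior = root_prior

    def fit(self, tree, trait):
        settings = MCMCSettings(iterations=self.iterations,
                                burn_in=self.burn_in, thin=self.thin,
                                seed=self.seed)
        result = test_rate_asymmetry(tree, trait, settings, self.n_stones,
                                     root_prior=self.root_prior)
        self.result_ = result
        self.log_bf_ = result.log_bf
        self.significant_ = result.comparison.significant
        self.direction_ = result.direction
        self.rates_ = {n: result.posterior.mean(n) for n in ("q01", "q10")}
        return self


class CorrelatedEvolutionTest(BaseEstimator):
    """Sklearn-style wrapper around :func:`test_correlated_evolution`."""

    def __init__(self, iterations: int = 50_000, burn_in: int = 10_000,
                 thin: int = 40, seed: int = 0, n_stones: int = 16,
                 root_prior="flat"):
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.n_stones = n_stones
        self.root_prior = root_prior

    def fit(self, tree, traitA, traitB):
        settings = MCMCSettings(iterations=self.iterations,
                                burn_in=self.burn_in, thin=self.thin,
                                seed=self.seed)
        comparison = test_correlated_evolution(tree, traitA, traitB, settings,
                                               self.n_stones,
                                               root_prior=self.root_prior)
        self.comparison_ = comparison
        self.log_bf_ = comparison.log_bf
        self.significant_ = comparison.significant
        return self


def run_manifest(settings: MCMCSettings, extra: dict | None = None) -> str:
    """JSON manifest of sampler settings for byte-reproducible reruns."""
    payload = {
        "iterations": settings.iterations,
        "burn_in": settings.burn_in,
        "thin": settings.thin,
        "seed": settings.seed,
        "rate_prior": list(settings.rate_prior),
    }
    payload.update(extra or {})
    return json.dumps(payload, indent=2, sort_keys=True)
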