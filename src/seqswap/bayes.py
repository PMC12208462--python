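"""Bayesian estimation of second-position choice probabilities in context 2
and posterior strategy classification.

Model
-----
Counts of the objects chosen at the second ordinal position (immediately
after a correct A, on pre-criterion context-2 trials) are multinomial with
probability vector theta over {B, C, D, E, X} (optionally including A).
Each raw component carries an independent Beta(alpha, beta) prior on (0, 1);
the multinomial likelihood is evaluated at the normalized vector
theta / sum(theta). The prior breaks the likelihood's scale invariance, so
the posterior over the raw components is proper; all reported summaries are
computed from the normalized draws.

Sampling
--------
A Metropolis-Hastings random walk with Gaussian steps of fixed scale 0.05.
Components are updated one at a time in a systematic scan (one component
per iteration): a joint perturbation of all components at this step size
has a near-zero acceptance rate once counts reach a few hundred, freezing
the chains, whereas the component-wise walk keeps acceptance in a healthy
range (roughly 0.1-0.6) across count sizes of 100-10,000. Proposals
leaving (0, 1) are rejected. Chain 1 starts at the empirical-proportion
maximum-likelihood estimate (zero counts floored at 1e-3); the remaining
chains start overdispersed from the prior.

Strategy regions (posterior mass over the normalized draws):

* position coding (swapping): theta_D > theta_B and theta_D > theta_C
* serial inference:           theta_C > theta_B and theta_C > theta_D
* other:                      the remainder
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .types import SeqswapError, ValidationError

logger = logging.getLogger("seqswap")

DEFAULT_LABELS: tuple[str, ...] = ("B", "C", "D", "E", "X")
STRATEGIES = ("position_coding", "serial_inference", "other")

#: Acceptance-rate band considered healthy for the default settings.
ACCEPTANCE_BAND = (0.05, 0.8)


@dataclass
class MCMCConfig:
    alpha: float = 2.0
    beta: float = 5.0
    n_iter: int = 200_000
    burn_in: int = 100_000
    step: float = 0.05
    n_chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError("alpha and beta must be > 0")
        if self.n_iter <= 0:
            raise ValidationError("n_iter must be > 0")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValidationError("burn_in must satisfy 0 <= burn_in < "
                                  "n_iter")
        if self.step <= 0:
            raise ValidationError("step must be > 0")
        if self.n_chains < 2:
            raise ValidationError("need at least 2 chains for convergence "
                                  "diagnostics")


#: Reduced settings used when many per-session posteriors are needed; the
#: component-wise walk equilibrates on 50-1,000 event counts well within
#: these budgets.
SESSION_MCMC = MCMCConfig(n_iter=20_000, burn_in=10_000, n_chains=2)


@dataclass
class ThetaPosterior:
    labels: tuple[str, ...]
    draws: np.ndarray            # normalized draws, (chains, kept, K)
    counts: np.ndarray
    config: MCMCConfig
    acceptance: np.ndarray       # per chain
    means: np.ndarray = field(init=False)
    ci_low: np.ndarray = field(init=False)
    ci_high: np.ndarray = field(init=False)
    rhat: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pooled = self.draws.reshape(-1, self.draws.shape[2])
        self.means = pooled.mean(axis=0)
        self.ci_low = np.quantile(pooled, 0.025, axis=0)
        self.ci_high = np.quantile(pooled, 0.975, axis=0)
        self.rhat = np.array([gelman_rubin(self.draws[:, :, k])
                              for k in range(self.draws.shape[2])])

    def mean(self, label: str) -> float:
        return float(self.means[self.labels.index(label)])

    def component(self, label: str) -> np.ndarray:
        """Pooled normalized draws of one component."""
        return self.draws[:, :, self.labels.index(label)].reshape(-1)

    def ordering_matrix(self) -> np.ndarray:
        k = len(self.labels)
        out = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                if i != j:
                    out[i, j] = ordering_probability(self, self.labels[i],
                                                     self.labels[j])
        return out


@dataclass
class StrategyCall:
    label: str
    region_probabilities: dict[str, float]


def log_posterior(theta, counts, cfg: MCMCConfig) -> float:
    """Unnormalized log posterior of one raw component vector.

    Returns -inf when any component leaves (0, 1), which rejects the
    proposal in the Metropolis step.
    """
    theta = np.asarray(theta, float)
    counts = np.asarray(counts, float)
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(theta <= 0.0) or np.any(theta >= 1.0):
        return -math.inf
    p = theta / theta.sum()
    ll = float(np.sum(counts * np.log(p)))
    lp = float(np.sum((cfg.alpha - 1.0) * np.log(theta)
                      + (cfg.beta - 1.0) * np.log1p(-theta)))
    return ll + lp


def mh_sample(counts, cfg: MCMCConfig | None = None,
              labels: tuple[str, ...] | None = None) -> ThetaPosterior:
    """Run the Metropolis-Hastings sampler on a count vector."""
    if cfg is None:
        cfg = MCMCConfig()
    counts = np.asarray(counts, float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValidationError("counts must be a vector of length >= 2")
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    k = counts.size
    if labels is None:
        labels = (DEFAULT_LABELS if k == len(DEFAULT_LABELS)
                  else tuple(f"c{i}" for i in range(k)))
    if len(labels) != k:
        raise ValidationError("labels length must match counts length")

    rng = np.random.default_rng(cfg.seed)
    chains = cfg.n_chains
    theta = np.empty((chains, k))
    total = counts.sum()
    mle = counts / total if total > 0 else np.full(k, 1.0 / k)
    theta[0] = np.clip(mle, 1e-3, 1.0 - 1e-3)
    theta[1:] = rng.beta(cfg.alpha, cfg.beta, size=(chains - 1, k))
    theta[1:] = np.clip(theta[1:], 1e-6, 1.0 - 1e-6)

    alpha1 = cfg.alpha - 1.0
    beta1 = cfg.beta - 1.0

    def logpost(th: np.ndarray) -> np.ndarray:
        p = th / th.sum(axis=1, keepdims=True)
        ll = np.log(p) @ counts
        lp = (alpha1 * np.log(th) + beta1 * np.log1p(-th)).sum(axis=1)
        return ll + lp

    lp = logpost(theta)
    kept = cfg.n_iter - cfg.burn_in
    draws = np.empty((chains, kept, k))
    accepted = np.zeros(chains)
    steps = rng.normal(0.0, cfg.step, size=(cfg.n_iter, chains))
    logu = np.log(rng.random(size=(cfg.n_iter, chains)))
    for it in range(cfg.n_iter):
        comp = it % k
        proposal = theta.copy()
        proposal[:, comp] += steps[it]
        inside = (proposal[:, comp] > 0.0) & (proposal[:, comp] < 1.0)
        lp_prop = np.full(chains, -np.inf)
        if inside.any():
            lp_prop[inside] = logpost(proposal[inside])
        accept = logu[it] < lp_prop - lp
        theta[accept] = proposal[accept]
        lp[accept] = lp_prop[accept]
        accepted += accept
        if it >= cfg.burn_in:
            draws[:, it - cfg.burn_in] = theta
    acceptance = accepted / cfg.n_iter
    if np.any(acceptance < ACCEPTANCE_BAND[0]) or \
            np.any(acceptance > ACCEPTANCE_BAND[1]):
        logger.warning("MH acceptance rate outside %s: %s",
                       ACCEPTANCE_BAND, np.round(acceptance, 4).tolist())
    else:
        logger.info("MH acceptance rates: %s",
                    np.round(acceptance, 4).tolist())
    normalized = draws / draws.sum(axis=2, keepdims=True)
    return ThetaPosterior(labels=tuple(labels), draws=normalized,
                          counts=counts, config=cfg, acceptance=acceptance)


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential-scale-reduction statistic from parallel chains of one
    scalar quantity (rows are chains)."""
    x = np.asarray(chains, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise SeqswapError("gelman_rubin needs >= 2 chains (a 2-D array "
                           "with one chain per row)")
    m, n = x.shape
    if n < 10:
        raise SeqswapError("each chain needs >= 10 draws")
    within = x.var(axis=1, ddof=1).mean()
    between = n * x.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def running_mean(chain: np.ndarray) -> np.ndarray:
    """Cumulative mean of a single chain's draws."""
    x = np.asarray(chain, float)
    if x.size == 0:
        raise SeqswapError("empty chain")
    return np.cumsum(x) / np.arange(1, x.size + 1)


def stability_metric(trace: np.ndarray, tail_fraction: float = 0.1) -> float:
    """Maximum absolute change of a running-mean trace over its final
    stretch; small values indicate a stabilized estimate."""
    trace = np.asarray(trace, float)
    tail = trace[int(len(trace) * (1.0 - tail_fraction)):]
    if tail.size < 2:
        return 0.0
    return float(np.max(np.abs(np.diff(tail))))


def ordering_probability(posterior: ThetaPosterior, i: str, j: str) -> float:
    """Posterior probability that component i exceeds component j."""
    for lab in (i, j):
        if lab not in posterior.labels:
            raise SeqswapError(f"unknown label {lab!r}")
    return float(np.mean(posterior.component(i) > posterior.component(j)))


def classify_strategy(posterior: ThetaPosterior) -> StrategyCall:
    """Assign the dominant choice strategy from posterior ordering mass."""
    for lab in ("B", "C", "D"):
        if lab not in posterior.labels:
            raise SeqswapError("posterior must contain components B, C, D")
    d = posterior.component("D")
    b = posterior.component("B")
    c = posterior.component("C")
    p_position = float(np.mean((d > b) & (d > c)))
    p_serial = float(np.mean((c > b) & (c > d)))
    regions = {
        "position_coding": p_position,
        "serial_inference": p_serial,
        "other": max(0.0, 1.0 - p_position - p_serial),
    }
    best = max(regions.values())
    winners = [k for k, v in regions.items() if v == best]
    label = winners[0] if len(winners) == 1 else "other"
    return StrategyCall(label=label, region_probabilities=regions)


@dataclass
class AggregateResult:
    pooled: dict[str, ThetaPosterior]
    calls: dict[str, dict[str, StrategyCall]]   # group -> session -> call
    strategy_proportions: dict[str, dict[str, float]]
    excluded_sessions: list[str]


def aggregate_posteriors(session_counts: dict[str, np.ndarray],
                         cfg: MCMCConfig | None = None,
                         labels: tuple[str, ...] = DEFAULT_LABELS,
                         grouping: dict[str, str] | None = None,
                         min_events: int = 5,
                         session_cfg: MCMCConfig | None = None
                         ) -> AggregateResult:
    """Pooled posteriors per group plus per-session strategy calls.

    ``session_counts`` maps a session id to its count vector;
    ``grouping`` maps session ids to group names (default: one pooled
    group). Sessions with fewer than ``min_events`` conditioning events are
    excluded and logged. The pooled posterior uses ``cfg`` (study
    defaults); per-session classification uses ``session_cfg`` (reduced
    :data:`SESSION_MCMC` settings by default).
    """
    if cfg is None:
        cfg = MCMCConfig()
    if session_cfg is None:
        session_cfg = MCMCConfig(alpha=cfg.alpha, beta=cfg.beta,
                                 n_iter=SESSION_MCMC.n_iter,
                                 burn_in=SESSION_MCMC.burn_in,
                                 step=cfg.step,
                                 n_chains=SESSION_MCMC.n_chains,
                                 seed=cfg.seed)
    valid: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for sid in sorted(session_counts):
        counts = np.asarray(session_counts[sid], float)
        if counts.sum() < min_events:
            excluded.append(sid)
        else:
            valid[sid] = counts
    if excluded:
        logger.info("aggregate_posteriors: excluded %d session(s) below "
                    "%d events: %s", len(excluded), min_events, excluded)
    if not valid:
        raise SeqswapError("no sessions with enough conditioning events")

    groups: dict[str, list[str]] = {}
    for sid in valid:
        group = grouping.get(sid, "pooled") if grouping else "pooled"
        groups.setdefault(group, []).append(sid)

    pooled: dict[str, ThetaPosterior] = {}
    calls: dict[str, dict[str, StrategyCall]] = {}
    proportions: dict[str, dict[str, float]] = {}
    for group, sids in sorted(groups.items()):
        total = np.sum([valid[s] for s in sids], axis=0)
        pooled[group] = mh_sample(total, cfg, labels=labels)
        calls[group] = {}
        for offset, sid in enumerate(sids):
            scfg = MCMCConfig(alpha=session_cfg.alpha,
                              beta=session_cfg.beta,
                              n_iter=session_cfg.n_iter,
                              burn_in=session_cfg.burn_in,
                              step=session_cfg.step,
                              n_chains=session_cfg.n_chains,
                              seed=session_cfg.seed + offset)
            calls[group][sid] = classify_strategy(
                mh_sample(valid[sid], scfg, labels=labels))
        n = len(sids)
        proportions[group] = {
            s: sum(1 for c in calls[group].values() if c.label == s) / n
            for s in STRATEGIES}
    return AggregateResult(pooled=pooled, calls=calls,
                           strategy_proportions=proportions,
                           excluded_sessions=excluded)
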