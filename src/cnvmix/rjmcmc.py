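"""Reversible-jump MCMC sampler for the spatial copy-number mixture.

The model: observed log2-ratios y_1..y_n along a chromosome follow a
k-component normal mixture whose components correspond to integer
copy-number classes.  The mixture weights are spatially smoothed through k
independent Gaussian Markov random fields (one per active component) via a
tempered softmax, so neighboring SNPs prefer the same component.  The
number of active components k is itself unknown, with a truncated Poisson
prior, and the sampler jumps between dimensions with birth/death moves.

Components are permanently identified with copy-number classes: each class
owns a disjoint uniform interval for its mean, which removes the usual
mixture label-switching.  One sampler iteration executes, in order:

1. birth/death move on k (reversible jump),
2. sequential Metropolis-Hastings sweep over the field rows x_i.,
3. random-walk Metropolis-Hastings update of the smoothing parameter h,
4. Gibbs draw of the allocations z,
5. truncated-normal update of the means (with interval re-selection and the
   merge rule for interval collisions) and inverse-gamma update of the
   variances.

After burn-in the per-SNP weight rows are accumulated over iterations and
averaged; inactive classes contribute zero weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from ._kernels import pairwise_sq_diff, sweep_field, total_log_mixture
from .calling import ChainResult, call_copy_numbers
from .gmrf import NeighborGraph, build_neighbor_graph, sample_field, weights_from_field
from .signal_model import CopyNumberClass, default_classes

__all__ = [
    "PriorConfig",
    "MixtureState",
    "MoveStats",
    "log_prior_k",
    "birth_probability",
    "birth_move",
    "death_move",
    "update_field",
    "update_h",
    "update_allocations",
    "update_means_variances",
    "merge_components",
    "tune_sigma_h",
    "run_chain",
]


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters and fixed model settings.

    classes       copy-number classes (uniform mean supports); k_max = len
    poisson_mean  mean of the truncated Poisson prior on k
    ig_shape/ig_scale  inverse-gamma prior on the component variances;
                  defaults give prior mean 0.22/(2.1-1) = 0.2 with a vague
                  (barely finite) variance
    h_max         upper bound of the uniform prior on the smoothing h
    phi           softmax temperature of the weight transform
    nb            neighbor window half-width of the GMRF
    """

    classes: tuple[CopyNumberClass, ...] = field(
        default_factory=lambda: tuple(default_classes()))
    poisson_mean: float = 2.0
    ig_shape: float = 2.1
    ig_scale: float = 0.22
    h_max: float = 1_000_000.0
    phi: float = 0.01
    nb: int = 4

    def __post_init__(self) -> None:
        if len(self.classes) < 1:
            raise ValueError("need at least one copy-number class")
        if self.poisson_mean <= 0 or self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if self.h_max <= 0:
            raise ValueError("h_max must be positive")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.nb < 1:
            raise ValueError("neighbor window nb must be >= 1")

    @property
    def k_max(self) -> int:
        return len(self.classes)


@dataclass
class MixtureState:
    """Full sampler state.

    Arrays are indexed by class slot (0..k_max-1); ``active`` marks which
    slots currently host a component.  Field columns of inactive slots are
    kept at zero.  ``z`` holds per-SNP class-slot allocations.
    """

    active: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    x: np.ndarray
    z: np.ndarray
    h: float

    @property
    def k(self) -> int:
        return int(np.sum(self.active))

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def active_indices(self) -> np.ndarray:
        return np.flatnonzero(self.active)

    def copy(self) -> "MixtureState":
        return MixtureState(self.active.copy(), self.mu.copy(),
                            self.sigma2.copy(), self.x.copy(),
                            self.z.copy(), self.h)

    def check_invariants(self, cfg: PriorConfig) -> None:
        """Raise if the state violates the model's structural invariants
        (used by the test suite after full iterations)."""
        act = self.active_indices()
        if not 1 <= len(act) <= cfg.k_max:
            raise AssertionError("component count out of range")
        for c in act:
            cls = cfg.classes[c]
            if not cls.lower < self.mu[c] < cls.upper:
                raise AssertionError(f"mu[{c}]={self.mu[c]} outside its interval")
            if not self.sigma2[c] > 0:
                raise AssertionError("non-positive component variance")
        if not np.all(np.isin(self.z, act)):
            raise AssertionError("allocation to inactive component")
        if not (0 <= self.h <= cfg.h_max):
            raise AssertionError("h outside its prior support")


@dataclass
class MoveStats:
    """Per-move proposal/acceptance counters and the adaptive random-walk
    scale sigma_h for the smoothing-parameter update."""

    birth_proposed: int = 0
    birth_accepted: int = 0
    death_proposed: int = 0
    death_accepted: int = 0
    field_proposed: int = 0
    field_accepted: int = 0
    h_proposed: int = 0
    h_accepted: int = 0
    h_window_proposed: int = 0
    h_window_accepted: int = 0
    merges: int = 0
    sigma_h: float = 10.0

    def rate(self, move: str) -> float:
        prop = getattr(self, f"{move}_proposed")
        return getattr(self, f"{move}_accepted") / prop if prop else math.nan

    def as_dict(self) -> dict:
        return {
            "birth_rate": self.rate("birth"),
            "death_rate": self.rate("death"),
            "field_rate": self.rate("field"),
            "h_rate": self.rate("h"),
            "merges": self.merges,
            "sigma_h": self.sigma_h,
        }


# ---------------------------------------------------------------------------
# prior on k and move probabilities


def log_prior_k(k: int, cfg: PriorConfig) -> float:
    """Log pmf of the truncated Poisson prior on {1..k_max}."""
    kmax = cfg.k_max
    if not 1 <= k <= kmax:
        raise ValueError(f"k={k} outside 1..{kmax}")
    lam = cfg.poisson_mean
    logs = [j * math.log(lam) - math.lgamma(j + 1) for j in range(1, kmax + 1)]
    m = max(logs)
    log_norm = m + math.log(sum(math.exp(v - m) for v in logs))
    return k * math.log(lam) - math.lgamma(k + 1) - log_norm


def birth_probability(k: int, cfg: PriorConfig) -> float:
    """Probability of proposing a birth at the current k: 1 at k=1, 0 at
    k=k_max, 1/2 in between."""
    if not 1 <= k <= cfg.k_max:
        raise ValueError(f"k={k} outside 1..{cfg.k_max}")
    if k == 1:
        return 1.0
    if k == cfg.k_max:
        return 0.0
    return 0.5


def birth_log_acceptance_prior(k: int, cfg: PriorConfig) -> float:
    """Log of the prior/proposal factor of the birth acceptance ratio,
    (1-b_{k+1}) * 1/(k+1) * p(k+1)  /  ( b_k * 1/(k_max - k) * p(k) ).
    The parameter proposal densities cancel against the parameter priors
    and the identity augmentation has unit Jacobian."""
    bk = birth_probability(k, cfg)
    bk1 = birth_probability(k + 1, cfg)
    return (math.log1p(-bk1) - math.log(k + 1) + log_prior_k(k + 1, cfg)) \
        - (math.log(bk) - math.log(cfg.k_max - k) + log_prior_k(k, cfg))


def death_log_acceptance_prior(k: int, cfg: PriorConfig) -> float:
    """Log prior/proposal factor of the death acceptance ratio; the exact
    reverse of :func:`birth_log_acceptance_prior` at k-1."""
    bk = birth_probability(k, cfg)
    bkm = birth_probability(k - 1, cfg)
    return (math.log(bkm) - math.log(cfg.k_max - (k - 1)) + log_prior_k(k - 1, cfg)) \
        - (math.log1p(-bk) - math.log(k) + log_prior_k(k, cfg))


# ---------------------------------------------------------------------------
# dimension moves


def sample_sigma2_prior(cfg: PriorConfig, rng: np.random.Generator) -> float:
    """Inverse-gamma prior draw for a component variance."""
    return cfg.ig_scale / rng.gamma(cfg.ig_shape)


def _total_loglik(state: MixtureState, y: np.ndarray, cfg: PriorConfig,
                  act: np.ndarray) -> float:
    return total_log_mixture(state.x, act, y,
                             np.ascontiguousarray(state.mu[act]),
                             np.ascontiguousarray(state.sigma2[act]), cfg.phi)


def birth_log_acceptance(state: MixtureState, y: np.ndarray, cfg: PriorConfig,
                         j: int, mu_new: float, s2_new: float,
                         xcol: np.ndarray, data_on: bool = True) -> float:
    """Log acceptance probability for adding class slot ``j`` with the
    proposed (mu*, sigma*^2, x*)."""
    log_acc = birth_log_acceptance_prior(state.k, cfg)
    if data_on:
        act_old = state.active_indices()
        ll_old = _total_loglik(state, y, cfg, act_old)
        state.x[:, j] = xcol
        state.mu[j] = mu_new
        state.sigma2[j] = s2_new
        act_new = np.sort(np.append(act_old, j))
        ll_new = _total_loglik(state, y, cfg, act_new)
        state.x[:, j] = 0.0
        log_acc += ll_new - ll_old
    return log_acc


def death_log_acceptance(state: MixtureState, y: np.ndarray, cfg: PriorConfig,
                         j: int, data_on: bool = True) -> float:
    """Log acceptance probability for removing active class slot ``j``."""
    log_acc = death_log_acceptance_prior(state.k, cfg)
    if data_on:
        act_old = state.active_indices()
        act_new = act_old[act_old != j]
        log_acc += _total_loglik(state, y, cfg, act_new) \
            - _total_loglik(state, y, cfg, act_old)
    return log_acc


def birth_move(state: MixtureState, y: np.ndarray, cfg: PriorConfig,
               graph: NeighborGraph, rng: np.random.Generator,
               stats: MoveStats, data_on: bool = True) -> bool:
    """Propose adding one of the inactive classes; mu* from its uniform
    interval, sigma*^2 from the inverse-gamma prior, x* from the GMRF prior
    at the current h.  Returns whether the move was accepted."""
    if state.k >= cfg.k_max:
        return False
    inactive = np.flatnonzero(~state.active)
    j = int(inactive[rng.integers(inactive.size)])
    cls = cfg.classes[j]
    mu_new = float(rng.uniform(cls.lower, cls.upper))
    s2_new = sample_sigma2_prior(cfg, rng)
    xcol = sample_field(state.h, graph, rng)
    log_acc = birth_log_acceptance(state, y, cfg, j, mu_new, s2_new, xcol, data_on)
    stats.birth_proposed += 1
    if math.log(rng.uniform()) < log_acc:
        state.active[j] = True
        state.mu[j] = mu_new
        state.sigma2[j] = s2_new
        state.x[:, j] = xcol
        stats.birth_accepted += 1
        return True
    return False


def death_move(state: MixtureState, y: np.ndarray, cfg: PriorConfig,
               rng: np.random.Generator, stats: MoveStats,
               data_on: bool = True) -> bool:
    """Propose removing a uniformly chosen active component.  Allocations
    pointing at a removed component are refreshed at the next Gibbs sweep;
    the acceptance ratio uses the allocation-free mixture likelihood."""
    if state.k <= 1:
        return False
    act = state.active_indices()
    j = int(act[rng.integers(act.size)])
    log_acc = death_log_acceptance(state, y, cfg, j, data_on)
    stats.death_proposed += 1
    if math.log(rng.uniform()) < log_acc:
        state.active[j] = False
        state.x[:, j] = 0.0
        stats.death_accepted += 1
        return True
    return False


# ---------------------------------------------------------------------------
# field, smoothing parameter, allocations


def update_field(state: MixtureState, y: np.ndarray, cfg: PriorConfig,
                 graph: NeighborGraph, rng: np.random.Generator,
                 stats: MoveStats, data_on: bool = True) -> None:
    """Sequential MH sweep over SNP locations: at each i the active row is
    proposed jointly from the product of GMRF full conditionals and
    accepted with the ratio of mixture densities at y_i."""
    act = state.active_indices()
    n = state.n
    zdraws = rng.standard_normal((n, act.size))
    udraws = rng.uniform(size=n)
    acc = sweep_field(state.x, act, y,
                      np.ascontiguousarray(state.mu[act]),
                      np.ascontiguousarray(state.sigma2[act]),
                      state.h, cfg.phi, cfg.nb, zdraws, udraws, data_on)
    stats.field_proposed += n
    stats.field_accepted += int(acc)


def h_log_acceptance(h_old: float, h_new: float, k: int, pair_sq: float,
                     sigma_h: float, cfg: PriorConfig,
                     graph: NeighborGraph) -> float:
    """Log MH acceptance ratio for the smoothing-parameter random walk:
    the k-th power of the GMRF normalizing-constant ratio, the quadratic
    roughness term, and the truncated-normal proposal correction."""
    g = graph.laplacian_eigenvalues
    dlogc = 0.5 * k * float(np.sum(np.log1p(h_new * g) - np.log1p(h_old * g)))
    exponent = -0.5 * (h_new - h_old) * pair_sq
    num = ndtr((cfg.h_max - h_old) / sigma_h) - ndtr(-h_old / sigma_h)
    den = ndtr((cfg.h_max - h_new) / sigma_h) - ndtr(-h_new / sigma_h)
    return dlogc + exponent + math.log(num) - math.log(den)


def update_h(state: MixtureState, cfg: PriorConfig, graph: NeighborGraph,
             rng: np.random.Generator, stats: MoveStats) -> None:
    """Random-walk MH step on h with proposal TN(h, sigma_h^2) on
    [0, h_max] (inverse-CDF draw)."""
    s = stats.sigma_h
    m = state.h
    plo = ndtr(-m / s)
    phi_hi = ndtr((cfg.h_max - m) / s)
    u = rng.uniform()
    h_new = m + s * ndtri(plo + u * (phi_hi - plo))
    h_new = float(np.clip(h_new, 1e-12, cfg.h_max * (1 - 1e-15)))
    act = state.active_indices()
    pair_sq = pairwise_sq_diff(state.x, act, cfg.nb)
    log_acc = h_log_acceptance(m, h_new, act.size, pair_sq, s, cfg, graph)
    stats.h_proposed += 1
    stats.h_window_proposed += 1
    if math.log(rng.uniform()) < log_acc:
        state.h = h_new
        stats.h_accepted += 1
        stats.h_window_accepted += 1


def tune_sigma_h(stats: MoveStats) -> float:
    """Burn-in-only multiplicative adaptation of the h random-walk scale,
    targeting the 40-70% acceptance band; resets the adaptation window."""
    if stats.h_window_proposed:
        rate = stats.h_window_accepted / stats.h_window_proposed
        if rate > 0.70:
            stats.sigma_h *= 1.25
        elif rate < 0.40:
            stats.sigma_h *= 0.8
    stats.h_window_proposed = 0
    stats.h_window_accepted = 0
    return stats.sigma_h


def allocation_log_probs(state: MixtureState, y: np.ndarray, cfg: PriorConfig,
                         data_on: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized log allocation probabilities over the active classes:
    log w_ij + log N(y_i | mu_j, sigma_j^2).  Returns (active, n x k)."""
    act = state.active_indices()
    logits = state.x[:, act] / cfg.phi
    if data_on:
        s2 = state.sigma2[act]
        mu = state.mu[act]
        logits = logits - 0.5 * np.log(2.0 * np.pi * s2) \
            - (y[:, None] - mu) ** 2 / (2.0 * s2)
    return act, logits


def update_allocations(state: MixtureState, y: np.ndarray, cfg: PriorConfig,
                       rng: np.random.Generator, data_on: bool = True) -> None:
    """Gibbs draw of all n allocations (Gumbel-argmax in log space, so no
    normalization underflow is possible)."""
    act, logits = allocation_log_probs(state, y, cfg, data_on)
    g = rng.gumbel(size=logits.shape)
    state.z = act[np.argmax(logits + g, axis=1)]


# ---------------------------------------------------------------------------
# means, variances, merge rule


def interval_masses(mean: float, sd: float,
                    classes: Sequence[CopyNumberClass]) -> np.ndarray:
    """Posterior mass of N(mean, sd^2) on each class interval."""
    lo = np.array([c.lower for c in classes])
    hi = np.array([c.upper for c in classes])
    return ndtr((hi - mean) / sd) - ndtr((lo - mean) / sd)


def select_interval(mean: float, sd: float,
                    classes: Sequence[CopyNumberClass]) -> int:
    """Class whose interval carries the largest mass of the unconstrained
    full conditional; exact ties break toward the lowest class index.  If
    every mass underflows, the interval nearest the mean is chosen."""
    masses = interval_masses(mean, sd, classes)
    if masses.max() <= 0.0:
        dist = [abs(mean - min(max(mean, c.lower), c.upper)) for c in classes]
        return int(np.argmin(dist))
    return int(np.argmax(masses))


def sample_truncated_normal(mean: float, sd: float, lower: float, upper: float,
                            rng: np.random.Generator) -> float:
    """Inverse-CDF draw from N(mean, sd^2) truncated to (lower, upper)."""
    plo = ndtr((lower - mean) / sd)
    phi_hi = ndtr((upper - mean) / sd)
    eps = 1e-9 * (upper - lower)
    if phi_hi - plo < 1e-300:
        # Entire interval is in an extreme tail: collapse to nearest edge.
        return lower + eps if mean <= lower else upper - eps
    val = mean + sd * ndtri(plo + rng.uniform() * (phi_hi - plo))
    return float(np.clip(val, lower + eps, upper - eps))


def _find_interval(value: float, classes: Sequence[CopyNumberClass]) -> int:
    for idx, c in enumerate(classes):
        if c.contains(value):
            return idx
    dist = [abs(value - min(max(value, c.lower), c.upper)) for c in classes]
    return int(np.argmin(dist))


def merge_components(state: MixtureState, cfg: PriorConfig) -> int:
    """Combine components whose means were sampled into the same interval.

    Each active component is (re)assigned to the class interval containing
    its mean; components sharing an interval are merged, with mu, sigma and
    the field column replaced by allocation-count-weighted averages (equal
    weights if all merged components are empty).  Allocations are redirected
    to the merged component.  Returns the number of merge events.
    """
    classes = cfg.classes
    act = state.active_indices()
    groups: dict[int, list[int]] = {}
    for c in act:
        groups.setdefault(_find_interval(state.mu[c], classes), []).append(int(c))
    if all(len(srcs) == 1 and srcs[0] == t for t, srcs in groups.items()):
        return 0
    kmax = cfg.k_max
    counts = np.bincount(state.z, minlength=kmax).astype(float)
    new_active = np.zeros(kmax, dtype=bool)
    new_mu = np.zeros(kmax)
    new_sigma2 = np.ones(kmax)
    new_x = np.zeros_like(state.x)
    zmap = np.arange(kmax)
    merges = 0
    for t, srcs in groups.items():
        new_active[t] = True
        if len(srcs) == 1:
            s = srcs[0]
            new_mu[t] = state.mu[s]
            new_sigma2[t] = state.sigma2[s]
            new_x[:, t] = state.x[:, s]
            zmap[s] = t
        else:
            ns = counts[srcs]
            w = ns / ns.sum() if ns.sum() > 0 else np.full(len(srcs), 1.0 / len(srcs))
            new_mu[t] = float(state.mu[srcs] @ w)
            sigma = float(np.sqrt(state.sigma2[srcs]) @ w)
            new_sigma2[t] = sigma * sigma
            new_x[:, t] = state.x[:, srcs] @ w
            for s in srcs:
                zmap[s] = t
            merges += 1
    state.active = new_active
    state.mu = new_mu
    state.sigma2 = new_sigma2
    state.x = new_x
    state.z = zmap[state.z]
    return merges


def update_means_variances(state: MixtureState, y: np.ndarray, cfg: PriorConfig,
                           rng: np.random.Generator, stats: MoveStats,
                           data_on: bool = True) -> None:
    """Update all component means and variances.

    For each active component the unconstrained mean full conditional
    N(ybar_j, sigma_j^2/N_j) is evaluated on every class interval; the
    interval with the largest mass is selected and mu_j drawn truncated to
    it (possibly relocating or merging the component).  Variances then
    follow their inverse-gamma full conditionals, IG(N_j/2 + a, SS_j/2 + b),
    which reduce to the prior for empty components.
    """
    classes = cfg.classes
    act = state.active_indices()
    if not data_on:
        for c in act:
            state.mu[c] = rng.uniform(classes[c].lower, classes[c].upper)
            state.sigma2[c] = sample_sigma2_prior(cfg, rng)
        return
    kmax = cfg.k_max
    counts = np.bincount(state.z, minlength=kmax)
    sums = np.bincount(state.z, weights=y, minlength=kmax)
    for c in act:
        n_j = counts[c]
        if n_j == 0:
            state.mu[c] = rng.uniform(classes[c].lower, classes[c].upper)
        else:
            m = sums[c] / n_j
            sd = math.sqrt(state.sigma2[c] / n_j)
            t = select_interval(m, sd, classes)
            state.mu[c] = sample_truncated_normal(
                m, sd, classes[t].lower, classes[t].upper, rng)
    stats.merges += merge_components(state, cfg)
    act = state.active_indices()
    counts = np.bincount(state.z, minlength=kmax)
    resid = y - state.mu[state.z]
    ssq = np.bincount(state.z, weights=resid * resid, minlength=kmax)
    for c in act:
        shape = 0.5 * counts[c] + cfg.ig_shape
        scale = 0.5 * ssq[c] + cfg.ig_scale
        state.sigma2[c] = scale / rng.gamma(shape)


# ---------------------------------------------------------------------------
# chain driver


def _init_state(y: np.ndarray, cfg: PriorConfig, rng: np.random.Generator,
                init_h: float, data_on: bool) -> MixtureState:
    """Start from three active components spanning loss/normal/gain (CN 1,
    2, 3 when present), means at interval midpoints, flat fields, h at a
    mildly smoothing value."""
    kmax = cfg.k_max
    n = len(y)
    labels = [c.cn_label for c in cfg.classes]
    init = [labels.index(v) for v in (1, 2, 3) if v in labels]
    if not init:
        init = list(range(min(3, kmax)))
    active = np.zeros(kmax, dtype=bool)
    active[init] = True
    mu = np.zeros(kmax)
    sigma2 = np.ones(kmax)
    for c in init:
        mu[c] = cfg.classes[c].midpoint
        sigma2[c] = 0.04
    state = MixtureState(active=active, mu=mu, sigma2=sigma2,
                         x=np.zeros((n, kmax)), z=np.zeros(n, dtype=np.int64),
                         h=float(init_h))
    update_allocations(state, y, cfg, rng, data_on)
    return state


def _iterate(state: MixtureState, y: np.ndarray, cfg: PriorConfig,
             graph: NeighborGraph, rng: np.random.Generator,
             stats: MoveStats, data_on: bool = True) -> None:
    """One full sampler iteration in the implemented move order."""
    if rng.uniform() < birth_probability(state.k, cfg):
        birth_move(state, y, cfg, graph, rng, stats, data_on)
    else:
        death_move(state, y, cfg, rng, stats, data_on)
    update_field(state, y, cfg, graph, rng, stats, data_on)
    update_h(state, cfg, graph, rng, stats)
    update_allocations(state, y, cfg, rng, data_on)
    update_means_variances(state, y, cfg, rng, stats, data_on)


def run_chain(track, cfg: PriorConfig | None = None, n_burnin: int = 5000,
              n_samples: int = 5000, seed: int = 0, *,
              sigma_h0: float = 10.0, adapt_every: int = 100,
              init_h: float = 10.0, likelihood_off: bool = False) -> ChainResult:
    """Run the full sampler and return averaged per-SNP class probabilities
    and integer calls.

    ``track`` is a LogRatioTrack or a plain array of ordered log2-ratios.
    The random-walk scale for h adapts every ``adapt_every`` iterations
    during burn-in only, so the post-burn-in kernel is fixed.  With
    ``likelihood_off`` every data-dependent factor is replaced by a
    constant (prior-recovery mode for validation).
    """
    y = np.ascontiguousarray(getattr(track, "y", track), dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("need a 1-D track with at least 2 SNPs")
    if not np.all(np.isfinite(y)):
        raise ValueError("log2-ratios must be finite")
    if n_samples < 1 or n_burnin < 0:
        raise ValueError("need n_samples >= 1 and n_burnin >= 0")
    if cfg is None:
        cfg = PriorConfig()
    data_on = not likelihood_off
    n = len(y)
    graph = build_neighbor_graph(n, cfg.nb)
    rng = np.random.default_rng(seed)
    stats = MoveStats(sigma_h=float(sigma_h0))
    state = _init_state(y, cfg, rng, init_h, data_on)
    total = n_burnin + n_samples
    omega_acc = np.zeros((n, cfg.k_max))
    k_trace = np.empty(total, dtype=np.int8)
    h_trace = np.empty(total)
    for it in range(total):
        _iterate(state, y, cfg, graph, rng, stats, data_on)
        if it < n_burnin and adapt_every and (it + 1) % adapt_every == 0:
            tune_sigma_h(stats)
        k_trace[it] = state.k
        h_trace[it] = state.h
        if it >= n_burnin:
            act = state.active_indices()
            omega_acc[:, act] += weights_from_field(state.x[:, act], cfg.phi)
    omega_bar = omega_acc / n_samples
    calls = call_copy_numbers(omega_bar, cfg.classes)
    return ChainResult(omega_bar=omega_bar, calls=calls,
                       classes=list(cfg.classes), diagnostics=stats,
                       k_trace=k_trace, h_trace=h_trace)
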