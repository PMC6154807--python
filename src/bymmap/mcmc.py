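"""Besag-York-Mollié convolution model fitted by Metropolis-within-Gibbs.

Model
-----
Observed counts ``Y_i ~ Poisson(theta_i * E_i)`` with

    log(theta_i) = alpha + u_i + v_i

where ``alpha`` is the log baseline relative risk (improper flat prior),
``u`` is the spatially structured heterogeneity with an intrinsic Gaussian
autoregression (ICAR) prior on the neighbor graph, and ``v`` is unstructured
heterogeneity, iid N(0, 1/tau_v).  Both precisions carry Gamma(shape, rate)
hyperpriors, Gamma(0.5, 0.0005) by default — the long-standing convention of
the BUGS disease-mapping lineage.

Sampling
--------
The Poisson/log-normal full conditionals of alpha, u_i and v_i are
non-conjugate, so they are updated by random-walk Metropolis on the log-risk
scale; tau_u and tau_v have conjugate Gamma full conditionals and are drawn
by Gibbs.  u_i updates are performed in graph-coloring blocks: sites of one
color are mutually non-adjacent, so updating them simultaneously is exactly
the per-site update, just vectorized.  The ICAR prior is improper (flat
along per-component constants); identifiability is restored by recentring u
to mean zero after every sweep and absorbing the removed mean into alpha,
which leaves every theta_i unchanged.  Step sizes adapt toward ~44%
acceptance during burn-in only and are frozen afterward, preserving the
stationary target.

Islands (areas with no neighbors) have u_i pinned at 0: the ICAR conditional
is undefined for degree 0 and the intrinsic rank correction (n minus the
number of connected components) removes them from the precision's shape.
Their area-level variation is carried entirely by v_i.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .adjacency import AdjacencyGraph
from .areal_data import AreaTable, ValidationError

logger = logging.getLogger(__name__)

_EXP_MAX = 700.0  # beyond this, exp overflows float64; proposals are rejected
_ADAPT_WINDOW = 50  # sweeps between burn-in step-size adjustments
_ADAPT_TARGET = 0.44  # classic scalar random-walk acceptance target


@dataclass
class Priors:
    """Gamma(shape, rate) hyperpriors on the two precisions; alpha is flat."""

    a_u: float = 0.5
    b_u: float = 0.0005
    a_v: float = 0.5
    b_v: float = 0.0005

    def __post_init__(self) -> None:
        if min(self.a_u, self.b_u, self.a_v, self.b_v) <= 0:
            raise ValidationError("Gamma hyperprior shapes and rates must be > 0")


@dataclass
class MCMCConfig:
    """Run-length, proposal and update-toggle settings.

    ``seed`` is mandatory: every run is deterministic given it.  The
    ``update_*`` switches freeze individual blocks (used to reduce the model
    to closed-form oracles); frozen precisions stay at their ``init_tau_*``
    values.
    """

    seed: int
    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    step_alpha: float = 0.1
    step_u: float = 0.5
    step_v: float = 0.5
    adapt: bool = True
    init_tau_u: float = 1.0
    init_tau_v: float = 1.0
    update_u: bool = True
    update_v: bool = True
    update_tau_u: bool = True
    update_tau_v: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("an explicit seed is required")
        if self.n_iter <= 0 or self.burn_in < 0 or self.burn_in >= self.n_iter:
            raise ValidationError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if min(self.step_alpha, self.step_u, self.step_v) < 0:
            raise ValidationError("proposal step sizes must be >= 0")
        if min(self.init_tau_u, self.init_tau_v) <= 0:
            raise ValidationError("initial precisions must be > 0")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "MCMCConfig":
        """Parse a ``key = value`` text file (booleans: true/false)."""
        kwargs: dict[str, object] = {}
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValidationError(f"line {lineno}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in fields:
                    raise ValidationError(f"line {lineno}: unknown setting {key!r}")
                if key in ("seed", "n_iter", "burn_in", "thin"):
                    kwargs[key] = int(val)
                elif key.startswith(("update_", "adapt")):
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = float(val)
        kwargs.update(overrides)
        return cls(**kwargs)  # type: ignore[arg-type]


@dataclass
class ModelState:
    """The BYM parameter vector at one iteration: (alpha, u, v, tau_u, tau_v)."""

    alpha: float
    u: np.ndarray
    v: np.ndarray
    tau_u: float
    tau_v: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float).copy()
        self.v = np.asarray(self.v, dtype=float).copy()
        if self.u.shape != self.v.shape:
            raise ValidationError("u and v must have the same length")
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise ValidationError("precisions must be > 0")

    @property
    def theta(self) -> np.ndarray:
        return np.exp(self.alpha + self.u + self.v)

    def copy(self) -> "ModelState":
        return ModelState(self.alpha, self.u.copy(), self.v.copy(), self.tau_u, self.tau_v)


@dataclass
class ChainOutput:
    """Retained posterior draws and run diagnostics.

    Arrays are aligned: row t of ``theta`` corresponds to ``alpha[t]``,
    ``tau_u[t]``, ``tau_v[t]`` and ``deviance[t]``.  ``acceptance`` maps
    block name (u, v, alpha) to its post-burn-in acceptance rate.
    """

    area_ids: tuple[str, ...]
    alpha: np.ndarray
    tau_u: np.ndarray
    tau_v: np.ndarray
    theta: np.ndarray
    deviance: np.ndarray
    acceptance: dict[str, float]
    n_iter: int
    burn_in: int
    thin: int

    @property
    def n_draws(self) -> int:
        return len(self.alpha)

    def scalar_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alpha,
                "tau_u": self.tau_u,
                "tau_v": self.tau_v,
                "deviance": self.deviance,
            }
        )

    def write(self, path: str | Path, theta_path: str | Path | None = None,
              sep: str = ",") -> None:
        """One row per retained draw; optionally a wide file of theta draws."""
        self.scalar_frame().to_csv(path, sep=sep, index=False)
        if theta_path is not None:
            pd.DataFrame(self.theta, columns=list(self.area_ids)).to_csv(
                theta_path, sep=sep, index=False
            )


class DICResult(NamedTuple):
    dic: float
    p_d: float
    d_bar: float


def poisson_deviance(Y: np.ndarray, E: np.ndarray, theta: np.ndarray) -> float:
    """Poisson deviance -2 log L with the saturated-independent log(Y!) term.

    D = -2 * sum_i [ Y_i log(mu_i) - mu_i - log(Y_i!) ], mu_i = theta_i E_i.
    Includes the data-only log-factorial term, so only DIC *differences*
    between models on the same data are meaningful.
    """
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(E <= 0) or np.any(theta <= 0):
        raise ValidationError("poisson_deviance requires E > 0 and theta > 0")
    mu = theta * E
    if not np.all(np.isfinite(mu)):
        raise ValidationError("non-finite Poisson mean")
    # xlogy-style guard: Y=0 contributes no Y*log(mu) term
    ll = np.where(Y > 0, Y * np.log(mu), 0.0) - mu - gammaln(Y + 1.0)
    return float(-2.0 * ll.sum())


def icar_logpdf(u: np.ndarray, tau_u: float, graph: AdjacencyGraph) -> float:
    """Unnormalized log density of the intrinsic autoregression.

    ((n - c)/2) log(tau_u) - (tau_u/2) * sum_edges (u_i - u_j)^2, with c the
    number of connected components (the rank of the intrinsic precision is
    n - c).  Invariant under adding a constant to u within one component.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (graph.n,):
        raise ValidationError("u length does not match the graph")
    ei, ej = graph.edge_arrays()
    ss = float(np.sum((u[ei] - u[ej]) ** 2))
    rank = graph.n - graph.n_components
    return 0.5 * rank * math.log(tau_u) - 0.5 * tau_u * ss


def u_full_conditional_prior(
    i: int, u: np.ndarray, tau_u: float, graph: AdjacencyGraph
) -> tuple[float, float]:
    """Gaussian prior part of the target for u_i: (mean, precision).

    mean = average of the neighbors' u, precision = tau_u * m_i.  Undefined
    for an isolated area (m_i = 0): callers must pin island u at 0 instead.
    """
    m = int(graph.degrees[i])
    if m == 0:
        raise ValidationError(
            f"area {graph.area_ids[i]!r} has no neighbors; the ICAR conditional "
            "is undefined — island u is pinned at 0"
        )
    u = np.asarray(u, dtype=float)
    mean = float(np.mean([u[j] for j in graph.neighbors[i]]))
    return mean, tau_u * m


def gibbs_tau_u(
    u: np.ndarray,
    graph: AdjacencyGraph,
    priors: Priors,
    rng: np.random.Generator,
) -> float:
    """Conjugate draw of the ICAR precision.

    tau_u | u ~ Gamma(a_u + (n - c)/2, b_u + (1/2) sum_edges (u_i - u_j)^2)
    in shape-rate form.
    """
    u = np.asarray(u, dtype=float)
    ei, ej = graph.edge_arrays()
    ss = float(np.sum((u[ei] - u[ej]) ** 2))
    shape = priors.a_u + 0.5 * (graph.n - graph.n_components)
    rate = priors.b_u + 0.5 * ss
    return float(rng.gamma(shape, 1.0 / rate))


def gibbs_tau_v(
    v: np.ndarray, priors: Priors, rng: np.random.Generator
) -> float:
    """Conjugate draw: tau_v | v ~ Gamma(a_v + n/2, b_v + (1/2) sum v_i^2)."""
    v = np.asarray(v, dtype=float)
    shape = priors.a_v + 0.5 * v.size
    rate = priors.b_v + 0.5 * float(np.sum(v * v))
    return float(rng.gamma(shape, 1.0 / rate))


def _color_classes(graph: AdjacencyGraph, free: np.ndarray) -> list[np.ndarray]:
    """Partition the non-island vertices into mutually non-adjacent blocks."""
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in np.flatnonzero(free))
    g.add_edges_from(graph.edges)
    coloring = nx.greedy_color(g, strategy="largest_first")
    classes: dict[int, list[int]] = {}
    for node, color in coloring.items():
        if free[node]:
            classes.setdefault(color, []).append(node)
    return [np.array(sorted(v), dtype=int) for _, v in sorted(classes.items())]


class BYMSampler:
    """Precomputed structures plus the one-sweep kernel.

    Holds the data vectors, the per-color sub-rows of the adjacency matrix
    (for vectorized neighbor sums) and mutable per-site step sizes.  One
    :meth:`sweep` performs, in order: u updates (per color block), v update,
    alpha update, sum-to-zero recentring of u with the mean absorbed into
    alpha, then Gibbs draws of the precisions.
    """

    def __init__(
        self,
        areas: AreaTable,
        graph: AdjacencyGraph,
        priors: Priors | None = None,
        config: MCMCConfig | None = None,
    ):
        if config is None:
            raise ValidationError("an MCMCConfig (with seed) is required")
        if areas.E is None or np.any(areas.E <= 0):
            raise ValidationError("model fitting requires E > 0 for every area")
        if tuple(areas.area_ids) != tuple(graph.area_ids):
            raise ValidationError("AreaTable and AdjacencyGraph area ids differ")
        self.priors = priors if priors is not None else Priors()
        self.config = config
        self.Y = areas.Y.astype(float)
        self.E = areas.E.astype(float)
        self.sum_Y = float(self.Y.sum())
        self.graph = graph
        self.n = graph.n
        self.W = graph.to_sparse()
        self.degrees = graph.degrees.astype(float)
        self.island = graph.degrees == 0
        self.free = ~self.island
        self.colors = _color_classes(graph, self.free)
        self.W_rows = [self.W[idx] for idx in self.colors]
        ei, ej = graph.edge_arrays()
        self._ei, self._ej = ei, ej
        # per-site step sizes (mutated only by burn-in adaptation)
        self.step_u = np.full(self.n, config.step_u, dtype=float)
        self.step_v = np.full(self.n, config.step_v, dtype=float)
        self.step_alpha = float(config.step_alpha)

    def initial_state(self) -> ModelState:
        alpha0 = math.log(self.sum_Y / float(self.E.sum())) if self.sum_Y > 0 else 0.0
        return ModelState(
            alpha0,
            np.zeros(self.n),
            np.zeros(self.n),
            self.config.init_tau_u,
            self.config.init_tau_v,
        )

    def sweep(self, state: ModelState, rng: np.random.Generator) -> dict[str, tuple[np.ndarray | int, ...]]:
        """One full Metropolis-within-Gibbs sweep, in place.

        Returns per-block (accepted, proposed) counts; for u and v these are
        per-site arrays so burn-in adaptation can tune sites individually.
        """
        cfg = self.config
        acc_u = np.zeros(self.n)
        prop_u = np.zeros(self.n)
        acc_v = np.zeros(self.n)
        prop_v = np.zeros(self.n)
        acc_a = 0
        prop_a = 0

        if cfg.update_u and self.free.any():
            ev = self.E * np.exp(np.clip(state.alpha + state.v, None, _EXP_MAX))
            for idx, W_rows in zip(self.colors, self.W_rows):
                cur = state.u[idx]
                prop = cur + self.step_u[idx] * rng.standard_normal(idx.size)
                s = W_rows @ state.u  # neighbor sums; same-color sites not adjacent
                m = self.degrees[idx]
                arg = np.clip(prop, None, _EXP_MAX)
                d_lik = self.Y[idx] * (prop - cur) - ev[idx] * (np.exp(arg) - np.exp(cur))
                d_prior = -0.5 * state.tau_u * (
                    m * (prop**2 - cur**2) - 2.0 * s * (prop - cur)
                )
                delta = d_lik + d_prior
                ok = np.isfinite(delta) & (state.alpha + prop + state.v[idx] < _EXP_MAX)
                accept = ok & (np.log(rng.random(idx.size)) < delta)
                state.u[idx] = np.where(accept, prop, cur)
                acc_u[idx] = accept
                prop_u[idx] = 1.0

        if cfg.update_v:
            eu = self.E * np.exp(np.clip(state.alpha + state.u, None, _EXP_MAX))
            cur = state.v
            prop = cur + self.step_v * rng.standard_normal(self.n)
            arg = np.clip(prop, None, _EXP_MAX)
            delta = (
                self.Y * (prop - cur)
                - eu * (np.exp(arg) - np.exp(cur))
                - 0.5 * state.tau_v * (prop**2 - cur**2)
            )
            ok = np.isfinite(delta) & (state.alpha + state.u + prop < _EXP_MAX)
            accept = ok & (np.log(rng.random(self.n)) < delta)
            state.v = np.where(accept, prop, cur)
            acc_v = accept.astype(float)
            prop_v = np.ones(self.n)

        # alpha: flat prior, full Poisson likelihood
        cur_a = state.alpha
        prop_a_val = cur_a + self.step_alpha * rng.standard_normal()
        t = self.E * np.exp(np.clip(state.u + state.v, None, _EXP_MAX))
        if prop_a_val + np.max(state.u + state.v, initial=0.0) < _EXP_MAX:
            delta_a = self.sum_Y * (prop_a_val - cur_a) - float(t.sum()) * (
                math.exp(prop_a_val) - math.exp(cur_a)
            )
            if math.isfinite(delta_a) and math.log(rng.random()) < delta_a:
                state.alpha = prop_a_val
                acc_a = 1
        prop_a = 1

        # identifiability: recentre u, alpha absorbs the mean (theta invariant).
        # Skipped when islands exist: their u is pinned at 0 so an alpha shift
        # would not be likelihood-invariant, and the posterior is proper anyway.
        if cfg.update_u and self.free.any() and not self.island.any():
            ubar = float(state.u.mean())
            state.u -= ubar
            state.alpha += ubar

        if cfg.update_tau_u:
            du = state.u[self._ei] - state.u[self._ej]
            shape = self.priors.a_u + 0.5 * (self.n - self.graph.n_components)
            rate = self.priors.b_u + 0.5 * float(du @ du)
            state.tau_u = float(rng.gamma(shape, 1.0 / rate))
        if cfg.update_tau_v:
            state.tau_v = gibbs_tau_v(state.v, self.priors, rng)

        return {
            "u": (acc_u, prop_u),
            "v": (acc_v, prop_v),
            "alpha": (acc_a, prop_a),
        }

    def adapt_steps(self, window: dict[str, np.ndarray | float]) -> None:
        """Nudge step sizes toward the acceptance target (burn-in only)."""
        rate_u = window["acc_u"] / np.maximum(window["prop_u"], 1.0)
        rate_v = window["acc_v"] / np.maximum(window["prop_v"], 1.0)
        self.step_u *= np.exp(np.clip(rate_u - _ADAPT_TARGET, -0.5, 0.5))
        self.step_v *= np.exp(np.clip(rate_v - _ADAPT_TARGET, -0.5, 0.5))
        if window["prop_a"] > 0:
            rate_a = window["acc_a"] / window["prop_a"]
            self.step_alpha *= math.exp(
                max(-0.5, min(0.5, rate_a - _ADAPT_TARGET))
            )


def mh_sweep(
    state: ModelState,
    areas: AreaTable,
    graph: AdjacencyGraph,
    priors: Priors,
    config: MCMCConfig,
    rng: np.random.Generator,
) -> ModelState:
    """One full sweep as a pure function: returns the new state.

    Convenience wrapper that builds the sampler afresh; :func:`run_mcmc`
    reuses one sampler for the whole chain.
    """
    sampler = BYMSampler(areas, graph, priors, config)
    new = state.copy()
    sampler.sweep(new, rng)
    return new


def run_mcmc(
    areas: AreaTable,
    graph: AdjacencyGraph,
    config: MCMCConfig,
    priors: Priors | None = None,
) -> ChainOutput:
    """Fit the BYM model; deterministic given ``config.seed``.

    Initial state: alpha = log(sum Y / sum E), u = v = 0, precisions at
    their ``init_tau_*`` values.  Burn-in draws are discarded, the rest
    thinned; the per-draw Poisson deviance is stored for DIC.
    """
    sampler = BYMSampler(areas, graph, priors, config)
    rng = np.random.default_rng(config.seed)
    state = sampler.initial_state()

    n_keep = (config.n_iter - config.burn_in) // config.thin
    alpha = np.empty(n_keep)
    tau_u_draws = np.empty(n_keep)
    tau_v_draws = np.empty(n_keep)
    theta = np.empty((n_keep, sampler.n))
    deviance = np.empty(n_keep)

    window = _fresh_window(sampler.n)
    post = _fresh_window(sampler.n)
    kept = 0
    for t in range(1, config.n_iter + 1):
        counts = sampler.sweep(state, rng)
        _accumulate(window, counts)
        in_burn = t <= config.burn_in
        if in_burn and config.adapt and t % _ADAPT_WINDOW == 0:
            sampler.adapt_steps(window)
            window = _fresh_window(sampler.n)
        if not in_burn:
            _accumulate(post, counts)
            if (t - config.burn_in) % config.thin == 0:
                th = state.theta
                d = poisson_deviance(sampler.Y, sampler.E, th)
                if not math.isfinite(d):
                    raise RuntimeError(
                        f"non-finite deviance at iteration {t}: alpha={state.alpha}, "
                        f"tau_u={state.tau_u}, tau_v={state.tau_v}"
                    )
                alpha[kept] = state.alpha
                tau_u_draws[kept] = state.tau_u
                tau_v_draws[kept] = state.tau_v
                theta[kept] = th
                deviance[kept] = d
                kept += 1
        if t % 1000 == 0:
            logger.info(
                "sweep %d/%d: acceptance u=%.2f v=%.2f alpha=%.2f",
                t, config.n_iter,
                float(np.sum(window["acc_u"]) / max(np.sum(window["prop_u"]), 1.0)),
                float(np.sum(window["acc_v"]) / max(np.sum(window["prop_v"]), 1.0)),
                window["acc_a"] / max(window["prop_a"], 1.0),
            )

    acceptance = {
        "u": float(np.sum(post["acc_u"]) / max(np.sum(post["prop_u"]), 1.0)),
        "v": float(np.sum(post["acc_v"]) / max(np.sum(post["prop_v"]), 1.0)),
        "alpha": float(post["acc_a"] / max(post["prop_a"], 1.0)),
    }
    return ChainOutput(
        area_ids=tuple(areas.area_ids),
        alpha=alpha,
        tau_u=tau_u_draws,
        tau_v=tau_v_draws,
        theta=theta,
        deviance=deviance,
        acceptance=acceptance,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        thin=config.thin,
    )


def _fresh_window(n: int) -> dict[str, np.ndarray | float]:
    return {
        "acc_u": np.zeros(n), "prop_u": np.zeros(n),
        "acc_v": np.zeros(n), "prop_v": np.zeros(n),
        "acc_a": 0.0, "prop_a": 0.0,
    }


def _accumulate(window: dict, counts: dict) -> None:
    window["acc_u"] += counts["u"][0]
    window["prop_u"] += counts["u"][1]
    window["acc_v"] += counts["v"][0]
    window["prop_v"] += counts["v"][1]
    window["acc_a"] += counts["alpha"][0]
    window["prop_a"] += counts["alpha"][1]


def dic(chain: ChainOutput, areas: AreaTable) -> DICResult:
    """Deviance information criterion from retained draws.

    Dbar = mean per-draw deviance; Dhat = deviance at the posterior-mean
    relative risks; pD = Dbar - Dhat; DIC = Dbar + pD.
    """
    if chain.n_draws < 2:
        raise ValidationError("DIC needs at least 2 retained draws")
    if areas.E is None:
        raise ValidationError("AreaTable has no expected counts")
    d_bar = float(chain.deviance.mean())
    theta_bar = chain.theta.mean(axis=0)
    d_hat = poisson_deviance(areas.Y, areas.E, theta_bar)
    p_d = d_bar - d_hat
    return DICResult(dic=d_bar + p_d, p_d=p_d, d_bar=d_bar)
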