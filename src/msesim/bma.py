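"""Bayesian model averaging over decomposable loglinear models (LLM-BMA).

Every chordal (decomposable) graph on the K lists defines a graphical
loglinear model whose hyper-Dirichlet prior on cell probabilities yields
a closed-form marginal likelihood: a product of Dirichlet-multinomial
normalizers over clique margins divided by the same over separator
margins.  The table is completed with an unknown count ``n0`` in the
unobservable all-zero cell; for each model the marginal likelihood is
evaluated on an integer grid of ``n0``, combined with a prior on
``N = n + n0``, and the model-specific posteriors are averaged with
weights proportional to each model's integrated evidence (uniform prior
over models).

The per-cell hyperparameter of the full table is ``delta`` (default
``2**-K``); margin cells inherit the sum of their cells' deltas, so each
clique or separator margin is a symmetric Dirichlet whose total
concentration is ``delta * 2**K`` regardless of margin size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import gammaln

from msesim.synthetic import FrequencyTable, all_histories

__all__ = [
    "DecomposableModel",
    "PosteriorGrid",
    "enumerate_decomposable",
    "log_marginal",
    "bma_posterior",
]


@dataclass(frozen=True)
class DecomposableModel:
    """A chordal graph on the K lists with its junction-forest factorization."""

    K: int
    edges: frozenset  # frozenset of frozenset({i, j}) with 0-based list indices
    cliques: tuple  # tuple of frozensets
    separators: tuple  # tuple of frozensets, with multiplicity; empties dropped

    def __repr__(self) -> str:
        e = sorted(tuple(sorted(x)) for x in self.edges)
        return f"DecomposableModel(K={self.K}, edges={e})"


def _junction_forest(g: nx.Graph) -> tuple[tuple, tuple]:
    """Maximal cliques and separators of a chordal graph.

    The separators are the clique intersections along a maximum-weight
    spanning forest of the clique graph (weight = intersection size);
    for chordal graphs any such forest satisfies the running-intersection
    property.  Empty separators (between connected components) contribute
    nothing to the marginal likelihood and are dropped.
    """
    cliques = [frozenset(c) for c in nx.find_cliques(g)]
    if len(cliques) <= 1:
        return tuple(cliques), ()
    cg = nx.Graph()
    cg.add_nodes_from(range(len(cliques)))
    for i, j in itertools.combinations(range(len(cliques)), 2):
        w = len(cliques[i] & cliques[j])
        if w > 0:
            cg.add_edge(i, j, weight=w)
    seps = []
    for i, j, _ in nx.maximum_spanning_edges(cg, data=True):
        seps.append(cliques[i] & cliques[j])
    # components of the clique graph correspond to components of g; edges
    # between components have empty separators and are omitted entirely.
    return tuple(cliques), tuple(seps)


def enumerate_decomposable(K: int) -> list[DecomposableModel]:
    """All decomposable (chordal) graphical models on K labeled lists.

    Deterministic order: graphs sorted by edge count, then by sorted edge
    list.  Counts for K = 1..5 are 1, 2, 8, 61, 822.
    """
    if not 1 <= K <= 5:
        raise ValueError("K must be between 1 and 5")
    pairs = list(itertools.combinations(range(K), 2))
    models = []
    for mask in range(2 ** len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        g = nx.Graph()
        g.add_nodes_from(range(K))
        g.add_edges_from(edges)
        if not nx.is_chordal(g):
            continue
        cliques, seps = _junction_forest(g)
        models.append(
            DecomposableModel(
                K=K,
                edges=frozenset(frozenset(e) for e in edges),
                cliques=cliques,
                separators=seps,
            )
        )
    models.sort(key=lambda m: (len(m.edges), sorted(tuple(sorted(e)) for e in m.edges)))
    return models


def _margin_counts(table_array: np.ndarray, K: int, subset: frozenset) -> np.ndarray:
    """Observed-cell margin over ``subset``: counts of the 2**|A| margin
    cells, margin cell 0 collecting observed histories absent from every
    list in the subset (the all-zero full-table cell projects there too,
    but is excluded here and handled via n0)."""
    H = all_histories(K)
    idx = sorted(subset)
    weights = 1 << np.arange(len(idx) - 1, -1, -1)
    codes = H[:, idx] @ weights
    return np.bincount(codes, weights=table_array, minlength=2 ** len(idx)).astype(float)


def _subset_terms(
    table_array: np.ndarray, K: int, subset: frozenset, delta: float
) -> tuple[float, float, float]:
    """For one margin subset A: (const, delta_zero, z) where
    const = sum over nonzero margin cells of lgamma(d + count) - lgamma(d),
    delta_zero = the Dirichlet parameter of the margin's all-zero cell,
    z = observed count in that cell (n0 is added by the caller)."""
    m = _margin_counts(table_array, K, subset)
    d = delta * 2 ** (K - len(subset))
    const = float(np.sum(gammaln(d + m[1:]) - gammaln(d)))
    return const, d, float(m[0])


def log_marginal(
    model: DecomposableModel, table: FrequencyTable, n0: int, delta: float | None = None
) -> float:
    """Log marginal likelihood of the completed table under one model.

    The completed table places ``n0`` individuals in the all-zero cell.
    Includes the multinomial coefficient of the completed table, so that
    summing exp(log_marginal) over all tables with a fixed total gives 1.
    """
    if n0 < 0:
        raise ValueError("n0 must be nonnegative")
    if delta is None:
        delta = 2.0 ** -model.K
    return float(
        _log_marginal_grid(model, table, np.array([n0]), delta)[0]
    )


class _GridWorkspace:
    """Shared per-table quantities for evaluating many models on one n0 grid.

    Only 2**K - 1 distinct margin subsets exist, so the n0-dependent
    log-Gamma vector of each subset is computed once and reused across
    the hundreds of models that share it."""

    def __init__(self, table: FrequencyTable, n0: np.ndarray, delta: float):
        self.table = table
        self.n0 = n0
        self.delta = delta
        self.K = table.K
        self.arr = table.array.astype(float)
        N = table.n_observed + n0
        s = delta * 2**self.K  # total concentration of every margin
        self.base = gammaln(N + 1) - gammaln(n0 + 1) - float(np.sum(gammaln(self.arr + 1)))
        self.norm = gammaln(s) - gammaln(s + N)  # shared margin normalizer
        self._subset: dict[frozenset, np.ndarray] = {}

    def subset_term(self, subset: frozenset) -> np.ndarray:
        if subset not in self._subset:
            const, d0, z = _subset_terms(self.arr, self.K, subset, self.delta)
            self._subset[subset] = self.norm + const + gammaln(d0 + z + self.n0) - gammaln(d0)
        return self._subset[subset]

    def model_logw(self, model: DecomposableModel) -> np.ndarray:
        out = self.base.copy()
        for c in model.cliques:
            out += self.subset_term(c)
        for sp in model.separators:
            out -= self.subset_term(sp)
        return out


def _log_marginal_grid(
    model: DecomposableModel,
    table: FrequencyTable,
    n0: np.ndarray,
    delta: float,
    _ws: _GridWorkspace | None = None,
) -> np.ndarray:
    """Vectorized log marginal over a grid of n0 values."""
    if _ws is None:
        _ws = _GridWorkspace(table, np.asarray(n0), delta)
    return _ws.model_logw(model)


@dataclass
class PosteriorGrid:
    """Model-averaged posterior over the unobserved count n0."""

    n_observed: int
    n0_values: np.ndarray
    log_weights_by_model: np.ndarray = field(repr=False)  # (models, grid)
    model_posteriors: np.ndarray
    averaged_posterior: np.ndarray
    models: list[DecomposableModel] = field(repr=False, default=None)

    def quantile(self, q: float) -> int:
        """Smallest N = n + n0 whose cumulative averaged posterior >= q."""
        cdf = np.cumsum(self.averaged_posterior)
        i = int(np.searchsorted(cdf, q))
        return self.n_observed + int(self.n0_values[min(i, len(self.n0_values) - 1)])

    @property
    def median_N(self) -> int:
        return self.quantile(0.5)

    def interval(self, level: float = 0.95) -> tuple[int, int]:
        half = (1 - level) / 2
        return self.quantile(half), self.quantile(1 - half)

    def to_csv(self, path) -> None:
        """Write the averaged posterior as CSV (columns n0, probability)."""
        import pandas as pd

        pd.DataFrame(
            {"n0": self.n0_values, "probability": self.averaged_posterior}
        ).to_csv(path, index=False)


def bma_posterior(
    table: FrequencyTable,
    n0_max: int,
    delta: float | None = None,
    prior: str = "reciprocal",
    models: list[DecomposableModel] | None = None,
) -> PosteriorGrid:
    """Model-averaged posterior of the unobserved count.

    Per model, posterior over n0 is proportional to prior(n + n0) times the
    hyper-Dirichlet marginal; the model posterior is proportional to the
    grid-summed evidence under a uniform prior over models; the averaged
    posterior is the model-posterior-weighted mixture.  ``prior`` is
    ``"reciprocal"`` (p(N) ∝ 1/N, the conventional vague choice) or
    ``"uniform"``.
    """
    K = table.K
    if not 3 <= K <= 5:
        raise ValueError("model averaging supports 3 to 5 lists")
    if n0_max < 0:
        raise ValueError("n0_max must be nonnegative")
    if delta is None:
        delta = 2.0**-K
    if models is None:
        models = enumerate_decomposable(K)
    n = table.n_observed
    n0 = np.arange(n0_max + 1)
    if prior == "reciprocal":
        log_prior = -np.log(n + n0) if n > 0 else -np.log1p(n0)
    elif prior == "uniform":
        log_prior = np.zeros_like(n0, dtype=float)
    else:
        raise ValueError(f"unknown prior {prior!r}")

    ws = _GridWorkspace(table, n0, delta)
    logw = np.empty((len(models), len(n0)))
    for i, m in enumerate(models):
        logw[i] = ws.model_logw(m) + log_prior
    shift = logw.max()
    if not np.isfinite(shift):
        raise RuntimeError("all models degenerate: no finite evidence")
    w = np.exp(logw - shift)  # joint (model, n0) weights up to a constant
    evidence = w.sum(axis=1)
    model_post = evidence / evidence.sum()
    averaged = w.sum(axis=0)
    averaged /= averaged.sum()
    return PosteriorGrid(
        n_observed=n,
        n0_values=n0,
        log_weights_by_model=logw,
        model_posteriors=model_post,
        averaged_posterior=averaged,
        models=models,
    )
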