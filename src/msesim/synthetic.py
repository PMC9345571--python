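"""Beta-Bernoulli encounter-history simulation for closed populations.

A population of ``N`` individuals can be recorded on each of ``K`` lists
(sampling occasions, service rosters).  The encounter indicator of
individual ``j`` on list ``k`` is Bernoulli(p_jk), with p_jk built from
Beta-distributed effects according to one of six classical inhomogeneity
patterns:

``Mh``
    heterogeneity — one Beta draw per individual, constant across lists;
``Mt``
    temporal — one Beta draw per list, shared by all individuals;
``Mb``
    behavioral — constant probability until first capture, multiplied by
    ``behavior_multiplier`` afterwards;
``Mth``, ``Mbh``, ``Mtbh``
    combinations of the above.

Individuals never captured on any list are unobservable and are removed
before estimation; the ``2**K - 1`` observable capture histories are
summarised in a :class:`FrequencyTable`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.special import betaln

__all__ = [
    "PATTERNS",
    "BetaShape",
    "GeneratorSpec",
    "EncounterMatrix",
    "FrequencyTable",
    "shapes_from_mean_cv",
    "expected_first_encounter",
    "expected_observed_fraction",
    "simulate_sample",
    "collapse_frequencies",
    "all_histories",
    "sample_seed",
]

#: The six data-generating patterns, in canonical order.
PATTERNS = ("Mh", "Mt", "Mb", "Mth", "Mbh", "Mtbh")


@dataclass(frozen=True)
class BetaShape:
    """Shape parameters of a Beta distribution for encounter probabilities."""

    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        if not (self.beta1 > 0 and self.beta2 > 0):
            raise ValueError("Beta shape parameters must be positive")

    @property
    def mean(self) -> float:
        return self.beta1 / (self.beta1 + self.beta2)

    @property
    def sd(self) -> float:
        a, b = self.beta1, self.beta2
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))

    @property
    def cv(self) -> float:
        return self.sd / self.mean


def shapes_from_mean_cv(mean_p: float, cv: float) -> BetaShape:
    """Solve Beta shape parameters from a mean and coefficient of variation.

    Uses the closed form ``s = (1 - m) / (m * cv**2) - 1``, ``beta1 = m * s``,
    ``beta2 = (1 - m) * s``, valid whenever ``m * (1 + cv**2) < 1``.

    Raises
    ------
    ValueError
        If no Beta distribution has the requested moments.
    """
    if not 0 < mean_p < 1:
        raise ValueError(f"mean_p must lie in (0, 1), got {mean_p}")
    if cv <= 0:
        raise ValueError(f"cv must be positive, got {cv}")
    if mean_p * (1 + cv**2) >= 1:
        raise ValueError(
            f"no Beta distribution has mean {mean_p} and cv {cv}: "
            "need mean_p * (1 + cv**2) < 1"
        )
    s = (1 - mean_p) / (mean_p * cv**2) - 1
    return BetaShape(mean_p * s, (1 - mean_p) * s)


def expected_first_encounter(shape: BetaShape, k: int) -> float:
    """Expected fraction of the population first encountered on list ``k``.

    With a per-individual probability ``p`` constant over lists, the chance
    of a first encounter on list ``k`` is ``p * (1 - p)**(k - 1)``; its
    expectation under ``p ~ Beta(beta1, beta2)`` is
    ``B(beta1 + 1, beta2 + k - 1) / B(beta1, beta2)``, evaluated in
    log-Gamma space.  At ``k = 1`` this is the Beta mean.
    """
    if k < 1:
        raise ValueError("list index k must be >= 1")
    a, b = shape.beta1, shape.beta2
    return float(np.exp(betaln(a + 1, b + k - 1) - betaln(a, b)))


def expected_observed_fraction(shape: BetaShape, K: int) -> float:
    """Expected fraction of the population observed at least once in K lists."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return float(sum(expected_first_encounter(shape, k) for k in range(1, K + 1)))


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one simulated sampling scenario.

    ``cv = 0`` denotes a degenerate (point-mass) probability distribution,
    giving homogeneous encounter probabilities equal to ``mean_p``.
    """

    pattern: str
    N: int
    mean_p: float
    cv: float = 0.85
    K: int = 5
    behavior_multiplier: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}")
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        if not 2 <= self.K <= 5:
            raise ValueError("K must be between 2 and 5")
        if not 0 < self.mean_p < 1:
            raise ValueError("mean_p must lie in (0, 1)")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if self.cv > 0 and self.mean_p * (1 + self.cv**2) >= 1:
            raise ValueError("no Beta distribution matches (mean_p, cv)")
        if not 0 <= self.behavior_multiplier <= 1:
            raise ValueError("behavior_multiplier must lie in [0, 1]")

    @property
    def shape(self) -> BetaShape | None:
        """The Beta shape implied by (mean_p, cv), or None when degenerate."""
        if self.cv == 0:
            return None
        return shapes_from_mean_cv(self.mean_p, self.cv)

    @property
    def heterogeneous(self) -> bool:
        return "h" in self.pattern

    @property
    def temporal(self) -> bool:
        return "t" in self.pattern

    @property
    def behavioral(self) -> bool:
        return "b" in self.pattern


@dataclass
class EncounterMatrix:
    """Observed binary capture histories (all-zero rows already removed)."""

    histories: np.ndarray  # (n_observed, K) of 0/1
    true_N: int
    spec: GeneratorSpec | None = None

    def __post_init__(self) -> None:
        self.histories = np.asarray(self.histories, dtype=np.int8)
        if self.histories.ndim != 2:
            raise ValueError("histories must be a 2-D binary matrix")
        if self.histories.size and not np.isin(self.histories, (0, 1)).all():
            raise ValueError("histories must contain only 0/1")
        if self.histories.size and (self.histories.sum(axis=1) == 0).any():
            raise ValueError("all-zero capture histories are unobservable")
        if self.n_observed > self.true_N:
            raise ValueError("cannot observe more individuals than the population holds")

    @property
    def n_observed(self) -> int:
        return self.histories.shape[0]

    @property
    def K(self) -> int:
        return self.histories.shape[1]

    # -- serialization ----------------------------------------------------
    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write histories as CSV (columns list_1..list_K) + JSON metadata."""
        path = Path(path)
        cols = [f"list_{k + 1}" for k in range(self.K)]
        pd.DataFrame(self.histories, columns=cols).to_csv(path, index=False)
        meta = {"true_N": self.true_N}
        if self.spec is not None:
            meta["spec"] = asdict(self.spec)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "EncounterMatrix":
        path = Path(path)
        hist = pd.read_csv(path).to_numpy(dtype=np.int8)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".meta.json")
        meta = json.loads(sidecar.read_text())
        spec = GeneratorSpec(**meta["spec"]) if "spec" in meta else None
        return cls(hist, true_N=meta["true_N"], spec=spec)


def all_histories(K: int) -> np.ndarray:
    """The 2**K - 1 observable histories, ordered by binary code.

    Row ``i`` (``i = 0..2**K - 2``) is the binary expansion of ``i + 1``
    with list 1 as the most significant bit; e.g. for K=5 the history
    ``10110`` sits at index ``0b10110 - 1 = 21``.
    """
    codes = np.arange(1, 2**K)
    return (codes[:, None] >> np.arange(K - 1, -1, -1)[None, :]) & 1


def _history_codes(histories: np.ndarray) -> np.ndarray:
    K = histories.shape[1]
    weights = 1 << np.arange(K - 1, -1, -1)
    return histories @ weights


class FrequencyTable:
    """Counts of the 2**K - 1 observable capture histories."""

    def __init__(self, K: int, counts: Mapping[tuple, int] | np.ndarray):
        if not 2 <= K <= 5:
            raise ValueError("K must be between 2 and 5")
        self.K = K
        if isinstance(counts, Mapping):
            arr = np.zeros(2**K - 1, dtype=np.int64)
            for hist, cnt in counts.items():
                hist = tuple(int(h) for h in hist)
                if len(hist) != K or not all(h in (0, 1) for h in hist):
                    raise ValueError(f"invalid history {hist} for K={K}")
                code = int("".join(map(str, hist)), 2)
                if code == 0:
                    raise ValueError("the all-zero history is unobservable")
                if cnt < 0:
                    raise ValueError("counts must be nonnegative")
                arr[code - 1] = cnt
        else:
            arr = np.asarray(counts, dtype=np.int64)
            if arr.shape != (2**K - 1,):
                raise ValueError(f"counts array must have length {2**K - 1}")
            if (arr < 0).any():
                raise ValueError("counts must be nonnegative")
        self.array = arr

    @property
    def n_observed(self) -> int:
        return int(self.array.sum())

    @property
    def counts(self) -> dict[tuple, int]:
        """Mapping over all 2**K - 1 observable histories (zeros included)."""
        hists = all_histories(self.K)
        return {tuple(int(v) for v in row): int(c) for row, c in zip(hists, self.array)}

    def __getitem__(self, hist) -> int:
        code = int("".join(str(int(h)) for h in hist), 2)
        if not 1 <= code <= 2**self.K - 1:
            raise KeyError(hist)
        return int(self.array[code - 1])

    def __iter__(self) -> Iterator[tuple]:
        return iter(self.counts)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrequencyTable)
            and self.K == other.K
            and np.array_equal(self.array, other.array)
        )

    def __repr__(self) -> str:
        return f"FrequencyTable(K={self.K}, n={self.n_observed})"

    # -- serialization ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        hists = all_histories(self.K)
        df = pd.DataFrame(
            {
                "history": ["".join(map(str, row)) for row in hists],
                "count": self.array,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrequencyTable":
        df = pd.read_csv(path, dtype={"history": str, "count": np.int64})
        K = len(df["history"].iloc[0])
        return cls(K, {tuple(map(int, h)): c for h, c in zip(df["history"], df["count"])})


def _beta_draws(rng: np.random.Generator, spec: GeneratorSpec, size) -> np.ndarray:
    """Draws from the configured probability distribution (Beta or point mass)."""
    if spec.cv == 0:
        return np.full(size, spec.mean_p)
    shape = spec.shape
    return rng.beta(shape.beta1, shape.beta2, size=size)


def simulate_sample(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> EncounterMatrix:
    """Simulate one sample of encounter histories under ``spec.pattern``.

    Lists are simulated sequentially so behavioral effects (probability
    multiplied by ``behavior_multiplier`` after the first capture) apply
    to all lists following an individual's first encounter.  Unobservable
    all-zero histories are removed.  Deterministic given ``spec.seed``
    (or a caller-supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    N, K = spec.N, spec.K

    # Per-individual and per-list multiplicative effects.
    if spec.heterogeneous:
        base = _beta_draws(rng, spec, N)  # individual effect
    else:
        base = np.full(N, spec.mean_p)
    if spec.temporal:
        list_p = _beta_draws(rng, spec, K)
        # scale so the marginal mean of the individual effect is preserved
        list_factor = list_p / spec.mean_p if spec.heterogeneous else None
    else:
        list_p = None
        list_factor = None

    histories = np.empty((N, K), dtype=np.int8)
    captured = np.zeros(N, dtype=bool)
    for k in range(K):
        if spec.temporal and spec.heterogeneous:
            p = np.clip(base * list_factor[k], 0.0, 1.0)
        elif spec.temporal:
            p = np.full(N, list_p[k])
        else:
            p = base.copy()
        if spec.behavioral:
            p = np.where(captured, p * spec.behavior_multiplier, p)
        histories[:, k] = rng.random(N) < p
        captured |= histories[:, k].astype(bool)

    observed = histories[histories.sum(axis=1) > 0]
    return EncounterMatrix(observed, true_N=N, spec=spec)


def collapse_frequencies(matrix: EncounterMatrix, K_use: int) -> FrequencyTable:
    """Tabulate the first ``K_use`` lists of a matrix into a frequency table.

    Individuals whose truncated history is all-zero (seen only on later
    lists) are dropped, mirroring an analysis that never consulted those
    lists.
    """
    if not 2 <= K_use <= matrix.K:
        raise ValueError(f"K_use must be in [2, {matrix.K}], got {K_use}")
    sub = matrix.histories[:, :K_use]
    sub = sub[sub.sum(axis=1) > 0]
    codes = _history_codes(sub)
    arr = np.bincount(codes, minlength=2**K_use)[1:]
    return FrequencyTable(K_use, arr)


def sample_seed(master_seed: int, replicate: int, pattern: str, mean_p: float, N: int) -> int:
    """Deterministic per-sample seed derived from the study master seed.

    Any single study cell is re-runnable in isolation; derived seeds stay
    below 2**31.
    """
    ss = np.random.SeedSequence(
        (master_seed, replicate, PATTERNS.index(pattern), int(round(mean_p * 10_000)), N)
    )
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))
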