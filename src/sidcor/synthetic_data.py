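"""Seeded synthetic feature matrices with known dependence structure.

Every scenario emulates the shape of a small metabolomics matrix (tens of
samples x tens-hundreds of features) with a planted pairwise or graphical
dependence, so that detection and structure-recovery behaviour can be
tested without any external data.  The generator makes no attempt to mimic
real intensity distributions (log-normal abundances, batch effects); it
provides clean mathematical dependence structures plus optional injected
defects (missing cells, constant columns) for the error paths.

All randomness comes from ``numpy.random.default_rng`` (PCG64), so a seed
fully and portably determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_validate import RawTable, SidcorError

RELATIONSHIPS = ("independent", "linear", "quadratic", "sinusoidal",
                 "circular", "gaussian_chain", "hub")

#: Adjacent correlation used by the gaussian_chain and hub scenarios.
CHAIN_RHO = 0.7


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one synthetic matrix; the seed determines it."""

    n_samples: int
    n_features: int
    relationship: str
    noise_sd: float = 0.1
    seed: int = 0
    missing_cells: int = 0
    constant_features: int = 0

    def __post_init__(self) -> None:
        if self.relationship not in RELATIONSHIPS:
            raise SidcorError(
                f"unknown relationship {self.relationship!r}; "
                f"choose from {RELATIONSHIPS}")
        if self.n_samples < 3 or self.n_features < 2:
            raise SidcorError("need n_samples >= 3 and n_features >= 2")
        if self.noise_sd < 0:
            raise SidcorError("noise_sd must be >= 0")
        if self.missing_cells < 0 or self.constant_features < 0:
            raise SidcorError("defect counts must be >= 0")
        if self.missing_cells > self.n_samples * self.n_features:
            raise SidcorError("more missing cells requested than table cells")
        if self.constant_features > self.n_features:
            raise SidcorError("more constant features requested than features")


@dataclass(frozen=True)
class GroundTruth:
    """True dependence structure of a scenario, for recovery assertions."""

    edges: frozenset[tuple[str, str]]
    feature_names: tuple[str, ...]
    params: dict = field(default_factory=dict)


def _chain_covariance(m: int, rho: float = CHAIN_RHO) -> np.ndarray:
    """Markov-chain covariance: unit variances, cov(X_i, X_j) = rho^|i-j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _hub_covariance(m: int, rho: float = CHAIN_RHO) -> np.ndarray:
    """Hub covariance: feature 0 drives all leaves with correlation rho;
    leaves correlate at rho² through the hub only."""
    cov = np.full((m, m), rho * rho)
    cov[0, :] = rho
    cov[:, 0] = rho
    np.fill_diagonal(cov, 1.0)
    return cov


def _pair_scenario(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """First two columns carry the named relationship; the rest are noise."""
    n = spec.n_samples
    eps = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
    if spec.relationship == "linear":
        x = rng.normal(size=n)
        y = x + eps
    elif spec.relationship == "quadratic":
        # Deterministic grid symmetric about 0 so that the odd moments vanish
        # and Pearson(x, x²) is numerically zero in the noiseless case.
        x = np.linspace(-1.0, 1.0, n)
        y = x * x + eps
    elif spec.relationship == "sinusoidal":
        x = np.linspace(0.0, 1.0, n)
        y = np.sin(2.0 * math.pi * x) + eps
    elif spec.relationship == "circular":
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
        x = np.cos(theta) + (rng.normal(0.0, spec.noise_sd, size=n)
                             if spec.noise_sd > 0 else 0.0)
        y = np.sin(theta) + eps
    else:  # independent
        x = rng.normal(size=n)
        y = rng.normal(size=n)
    cols = [x, np.asarray(y, dtype=float) + np.zeros(n)]
    for _ in range(spec.n_features - 2):
        cols.append(rng.normal(size=n))
    return np.column_stack(cols)


def _feature_names(spec: ScenarioSpec) -> tuple[str, ...]:
    m = spec.n_features
    if spec.relationship == "hub":
        return ("Z",) + tuple(f"X{i}" for i in range(1, m))
    if spec.relationship == "gaussian_chain":
        return tuple(f"X{i}" for i in range(1, m + 1))
    base = ["X", "Y"]
    base += [f"N{i}" for i in range(1, m - 1)]
    return tuple(base)


def generate(spec: ScenarioSpec) -> RawTable:
    """Realize a scenario as a RawTable; defects are injected last.

    Defect positions are drawn from the same seeded stream, after the data,
    so the clean part of two tables differing only in defect counts is
    identical.  Constant columns are overwritten (value 7.0) starting from
    the last feature; missing cells are sampled without replacement over the
    remaining (non-constant) columns.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.relationship in ("gaussian_chain", "hub"):
        cov = (_chain_covariance(spec.n_features)
               if spec.relationship == "gaussian_chain"
               else _hub_covariance(spec.n_features))
        values = rng.multivariate_normal(
            np.zeros(spec.n_features), cov, size=spec.n_samples,
            method="cholesky")
    else:
        values = _pair_scenario(spec, rng)
    values = np.asarray(values, dtype=float)

    n, m = values.shape
    const_cols = list(range(m - spec.constant_features, m))
    for j in const_cols:
        values[:, j] = 7.0
    if spec.missing_cells:
        live_cols = [j for j in range(m) if j not in const_cols]
        cells = [(i, j) for j in live_cols for i in range(n)]
        if spec.missing_cells > len(cells):
            raise SidcorError(
                "cannot place that many missing cells outside constant columns")
        pick = rng.choice(len(cells), size=spec.missing_cells, replace=False)
        for k in np.sort(pick):
            i, j = cells[int(k)]
            values[i, j] = np.nan

    sample_ids = tuple(f"S{i + 1}" for i in range(n))
    return RawTable(sample_ids, _feature_names(spec), values)


def ground_truth(spec: ScenarioSpec) -> GroundTruth:
    """True edge set and generating parameters of a scenario."""
    names = _feature_names(spec)
    if spec.relationship == "gaussian_chain":
        edges = {(names[i], names[i + 1]) for i in range(spec.n_features - 1)}
        params = {"adjacent_correlation": CHAIN_RHO,
                  "covariance": _chain_covariance(spec.n_features)}
    elif spec.relationship == "hub":
        edges = {(names[0], names[i]) for i in range(1, spec.n_features)}
        params = {"hub_correlation": CHAIN_RHO,
                  "covariance": _hub_covariance(spec.n_features)}
    elif spec.relationship == "independent":
        edges = set()
        params = {}
    else:
        edges = {(names[0], names[1])}
        params = {"relationship": spec.relationship, "noise_sd": spec.noise_sd}
    return GroundTruth(edges=frozenset(edges), feature_names=names,
                       params=params)
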