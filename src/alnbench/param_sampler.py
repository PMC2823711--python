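"""Empirical parameter distributions, per-data-set parameter draws, and
EM fitting of mixture weights over binned score densities.

The sampled-parameter mode replaces single fixed parameter values with
independent draws — one per parameter type — from distributions of values
observed genome-wide.  Branch lengths are drawn as one joint vector (a single
fragment's phylogeny) to preserve inter-branch correlation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .evolver import EvolutionParams, IndelLengthModel
from .phylo import adjust_branch_lengths

__all__ = [
    "EmpiricalDistribution",
    "ParameterDraw",
    "MixtureFit",
    "load_distribution",
    "sample_parameters",
    "histogram_density",
    "fit_mixture_weights",
]

#: Registry labels understood by :func:`sample_parameters`.
KNOWN_LABELS = (
    "branch_lengths",     # vector: replaces the template tree's branch lengths
    "sub_indel_ratio",    # scalar rho
    "ins_del_ratio",      # scalar r
    "alpha",              # scalar conserved-block coverage
    "indel_model",        # 3-vector (weight, q1, q2)
)


@dataclass(frozen=True)
class EmpiricalDistribution:
    """A sampleable collection of observed values (scalars or vectors)."""

    label: str
    observations: np.ndarray          # shape (n,) or (n, d)
    weights: np.ndarray | None = None
    names: tuple[str, ...] | None = None   # vector component names (optional)

    def __post_init__(self):
        obs = np.asarray(self.observations, dtype=float)
        object.__setattr__(self, "observations", obs)
        if obs.size == 0:
            raise ValueError(f"{self.label}: no observations")
        if obs.ndim not in (1, 2):
            raise ValueError(f"{self.label}: observations must be 1- or 2-dimensional")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(obs),) or (w <= 0).any():
                raise ValueError(f"{self.label}: weights must be positive, one per row")
            object.__setattr__(self, "weights", w / w.sum())

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def is_vector(self) -> bool:
        return self.observations.ndim == 2

    @property
    def dimension(self) -> int:
        return self.observations.shape[1] if self.is_vector else 1

    def sample(self, rng: np.random.Generator):
        idx = int(rng.choice(len(self.observations), p=self.weights))
        value = self.observations[idx]
        return value.copy() if self.is_vector else float(value)

    def mean(self):
        if self.weights is None:
            return self.observations.mean(axis=0)
        return np.average(self.observations, axis=0, weights=self.weights)


def load_distribution(path, kind: str = "scalar", label: str | None = None) -> EmpiricalDistribution:
    """Load a TSV of observations: one per line, vector components tab-separated.

    Vector files may begin with a header row naming components (branches in
    tree-traversal order); any row whose first field is non-numeric is treated
    as the header.
    """
    if kind not in ("scalar", "vector"):
        raise ValueError("kind must be 'scalar' or 'vector'")
    label = label or str(path)
    rows: list[list[float]] = []
    names: tuple[str, ...] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not rows and names is None:
                try:
                    float(fields[0])
                except ValueError:
                    names = tuple(fields)
                    continue
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric field on row {lineno}: {exc}") from None
            if kind == "scalar" and len(values) != 1:
                raise ValueError(f"{path}: expected 1 value on row {lineno}, got {len(values)}")
            if rows and len(values) != len(rows[0]):
                raise ValueError(
                    f"{path}: ragged row {lineno} ({len(values)} fields, expected {len(rows[0])})"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no observations")
    if names is not None and len(names) != len(rows[0]):
        raise ValueError(f"{path}: header names {len(names)} columns, rows have {len(rows[0])}")
    obs = np.asarray(rows, dtype=float)
    if kind == "scalar":
        obs = obs[:, 0]
    return EmpiricalDistribution(label, obs, names=names)


@dataclass(frozen=True)
class ParameterDraw:
    """One complete draw: label -> sampled value, plus the seed that made it."""

    values: dict
    seed: int | None = None


def sample_parameters(
    registry: dict[str, EmpiricalDistribution],
    template: EvolutionParams,
    rng: np.random.Generator,
    seed: int | None = None,
) -> tuple[EvolutionParams, ParameterDraw]:
    """Draw each registered parameter independently and build concrete params.

    A registered branch-length vector replaces the template tree's branch
    lengths jointly (tree-traversal order), after which the tree is rescaled
    to neutral rates via ``adjust_branch_lengths(alpha, beta)``.  Unregistered
    parameters keep their template values.  The tree embedded in the template
    is expected to carry *overall* (block-averaged) branch lengths whenever a
    branch-length distribution is registered.
    """
    unknown = set(registry) - set(KNOWN_LABELS)
    if unknown:
        raise ValueError(f"unknown distribution labels: {sorted(unknown)}")

    drawn: dict = {}
    for lbl in KNOWN_LABELS:
        if lbl in registry:
            drawn[lbl] = registry[lbl].sample(rng)

    alpha = float(drawn.get("alpha", template.alpha))
    updates: dict = {"alpha": alpha, "seed": seed if seed is not None else template.seed}
    if "sub_indel_ratio" in drawn:
        updates["sub_indel_ratio"] = float(drawn["sub_indel_ratio"])
    if "ins_del_ratio" in drawn:
        updates["ins_del_ratio"] = float(drawn["ins_del_ratio"])
    if "indel_model" in drawn:
        w, q1, q2 = (float(v) for v in np.atleast_1d(drawn["indel_model"]))
        updates["indel_model"] = IndelLengthModel(w, q1, q2)

    tree = template.tree.copy()
    if "branch_lengths" in drawn:
        vector = np.atleast_1d(drawn["branch_lengths"])
        n_branches = len(tree.branches())
        if vector.shape != (n_branches,):
            raise ValueError(
                f"branch-length vector has {vector.size} entries, tree has {n_branches} branches"
            )
        tree.set_branch_lengths(vector)
        tree = adjust_branch_lengths(tree, alpha, template.beta)
    updates["tree"] = tree

    params = dataclasses.replace(template, **updates)
    return params, ParameterDraw(drawn, seed=seed)


# ---------------------------------------------------------------------------
# EM over mixture weights (component densities fixed)

@dataclass
class MixtureFit:
    n_components: int
    weights: np.ndarray
    log_likelihood: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def histogram_density(
    scores,
    n_bins: int = 100,
    value_range: tuple[float, float] = (0.0, 100.0),
    pseudocount: float = 1e-6,
) -> np.ndarray:
    """Binned density of scores over a fixed range, with per-bin pseudocount."""
    scores = np.asarray(scores, dtype=float)
    if ((scores < value_range[0]) | (scores > value_range[1])).any():
        raise ValueError(f"scores outside {value_range}")
    counts, _ = np.histogram(scores, bins=n_bins, range=value_range)
    density = counts.astype(float) + pseudocount
    return density / density.sum()


def _bin_indices(observations, n_bins: int, value_range: tuple[float, float]) -> np.ndarray:
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise ValueError("no observations")
    lo, hi = value_range
    if ((obs < lo) | (obs > hi)).any():
        raise ValueError(f"observations outside {value_range}")
    idx = np.floor((obs - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def fit_mixture_weights(
    component_histograms,
    observations,
    max_iter: int = 1000,
    tol: float = 1e-8,
    value_range: tuple[float, float] = (0.0, 100.0),
    initial_weights=None,
) -> MixtureFit:
    """Maximum-likelihood mixture weights by EM, component densities held fixed.

    ``component_histograms`` is a (K, B) array of normalized bin densities over
    identical edges spanning ``value_range``; observations are binned and the
    E-step computes responsibilities proportional to ``w_k * f_k(bin(x))``,
    the M-step sets each weight to the mean responsibility.
    """
    f = np.asarray(component_histograms, dtype=float)
    if f.ndim == 1:
        f = f[None, :]
    if f.ndim != 2 or f.shape[0] < 1:
        raise ValueError("component_histograms must be a (K, B) array")
    if (f < 0).any():
        raise ValueError("negative density in component histograms")
    row_sums = f.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("each component histogram must be normalized")

    K, B = f.shape
    bins = _bin_indices(observations, B, value_range)
    fx = f[:, bins]                       # (K, n) component densities at each obs
    if (fx.sum(axis=0) <= 0).any():
        raise ValueError(
            "an observation falls in a bin where every component has zero mass; "
            "use a larger pseudocount when building the histograms"
        )

    if initial_weights is None:
        w = np.full(K, 1.0 / K)
    else:
        w = np.asarray(initial_weights, dtype=float)
        if w.shape != (K,) or (w < 0).any() or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("initial_weights must be K non-negative values summing to 1")

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mix = w @ fx                      # (n,)
        ll = float(np.log(mix).sum())
        trace.append(ll)
        resp = (w[:, None] * fx) / mix    # (K, n)
        w = resp.mean(axis=1)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
    mix = w @ fx
    trace.append(float(np.log(mix).sum()))
    return MixtureFit(K, w, trace, n_iter=n_iter, converged=converged)


def write_mixture_report(path, fit: MixtureFit) -> None:
    """TSV report: weights, then the log-likelihood trace."""
    with open(path, "w") as fh:
        fh.write("component\tweight\n")
        for k, w in enumerate(fit.weights):
            fh.write(f"{k}\t{w:.10g}\n")
        fh.write("iteration\tlog_likelihood\n")
        for i, ll in enumerate(fit.log_likelihood):
            fh.write(f"{i}\t{ll:.10g}\n")
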