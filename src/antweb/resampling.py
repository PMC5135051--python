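"""Null models and Monte-Carlo significance machinery.

All significance statements in the pipeline condition on the observed
margins: the Patefield algorithm draws uniform-conditional random integer
matrices with exactly the observed row and column totals (the classic
r2dtable null), so every null network preserves species' total interaction
frequencies while shuffling who interacts with whom.

P-values use the add-one Monte-Carlo convention p = (1 + x) / (N + 1), so
they are never exactly zero; two-sided tests are the doubled smaller tail,
capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateNullError, UndefinedMetricError, ValidationError
from .metrics import MetricValue
from .modularity import AnnealingConfig, best_of, quanbimo_fit
from .network_model import LayerMatrix

__all__ = [
    "MetricReport",
    "LayerComparison",
    "QSignificance",
    "patefield_sample",
    "null_matrices",
    "metric_significance",
    "standardized_Q",
    "layer_difference_test",
]

MetricFn = Callable[[LayerMatrix], "MetricValue | float"]


@dataclass(frozen=True)
class MetricReport:
    """An observed metric with its margin-conditional null distribution."""

    metric: MetricValue
    null_values: np.ndarray
    p_value: float
    n_null: int
    n_missing: int
    seed: int
    sidedness: str

    def null_summary(self) -> dict[str, float]:
        q = np.quantile(self.null_values, [0.025, 0.5, 0.975])
        return {
            "mean": float(self.null_values.mean()),
            "sd": float(self.null_values.std(ddof=1)) if self.n_null > 1 else 0.0,
            "q025": float(q[0]),
            "median": float(q[1]),
            "q975": float(q[2]),
        }


@dataclass(frozen=True)
class LayerComparison:
    """Monte-Carlo comparison of one metric between two resource layers."""

    metric_name: str
    layer_a: str
    layer_b: str
    value_a: float
    value_b: float
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


@dataclass(frozen=True)
class QSignificance:
    """Observed modularity standardized against margin-preserving nulls.

    ``z`` counts how many null standard deviations the observed optimum Q
    sits above the null mean; values >= 2 are flagged significant.
    """

    q_obs: float
    null_mean: float
    null_sd: float
    z: float
    n_null: int
    seed: int

    @property
    def significant(self) -> bool:
        return self.z >= 2.0


# -- Patefield null ---------------------------------------------------------


def patefield_sample(
    margins_r: Sequence[int],
    margins_c: Sequence[int],
    seed: "int | np.random.Generator" = 0,
    size: Optional[int] = None,
) -> np.ndarray:
    """Draw random integer matrices with fixed margins (Patefield 1981).

    Sampling is uniform over the multiple-hypergeometric (independence-
    conditional) distribution, delegated to ``scipy.stats.random_table``
    with the Patefield method.  Returns one matrix, or a stack of ``size``
    matrices when requested.
    """
    r = np.asarray(margins_r, dtype=np.int64)
    c = np.asarray(margins_c, dtype=np.int64)
    if r.sum() != c.sum() or r.sum() <= 0:
        raise ValidationError(
            f"margin sums must match and be positive (got {r.sum()} vs {c.sum()})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if r.size == 1 or c.size == 1:
        # a single row or column is forced by the margins
        forced = np.broadcast_to(c, (r.size, c.size)) if r.size == 1 else r[:, None]
        out = np.repeat(forced[None, :, :], size if size is not None else 1, axis=0)
        out = out.astype(np.int64)
    else:
        dist = stats.random_table(r, c)
        out = dist.rvs(size if size is not None else 1, method="patefield", random_state=rng)
        out = np.asarray(out, dtype=np.int64)
        if out.ndim == 2:  # scipy squeezes size=1
            out = out[None, :, :]
    return out if size is not None else out[0]


def null_matrices(A: LayerMatrix, n: int, rng: np.random.Generator) -> list[LayerMatrix]:
    """``n`` Patefield randomizations of a layer, keeping the species labels.

    Margins are preserved, so no species is ever dropped from a null draw.
    """
    draws = patefield_sample(A.row_margins, A.col_margins, seed=rng, size=n)
    return [
        LayerMatrix(A.resource, A.plants, A.ants, d, A.provenance) for d in draws
    ]


# -- significance -----------------------------------------------------------


def _metric_value(metric_fn: MetricFn, A: LayerMatrix) -> float:
    v = metric_fn(A)
    return float(v.value) if isinstance(v, MetricValue) else float(v)


def _mc_p(observed: float, nulls: np.ndarray, sidedness: str) -> float:
    n = nulls.size
    tol = 1e-9 * max(1.0, abs(observed))
    p_ge = (1 + int(np.sum(nulls >= observed - tol))) / (n + 1)
    p_le = (1 + int(np.sum(nulls <= observed + tol))) / (n + 1)
    if sidedness == "greater":
        return p_ge
    if sidedness == "less":
        return p_le
    if sidedness == "two-sided":
        return min(1.0, 2.0 * min(p_ge, p_le))
    raise ValueError(f"unknown sidedness {sidedness!r}")


def metric_significance(
    A: LayerMatrix,
    metric_fn: MetricFn,
    n_null: int = 999,
    sidedness: str = "greater",
    seed: int = 0,
) -> MetricReport:
    """Observed metric vs. its Patefield null distribution.

    Null draws on which the metric is undefined are recorded as missing and
    excluded from the p-value denominator.
    """
    observed = metric_fn(A)
    obs_value = observed if isinstance(observed, MetricValue) else MetricValue(
        getattr(metric_fn, "__name__", "metric"), float(observed), A.shape
    )
    rng = np.random.default_rng(seed)
    nulls = []
    n_missing = 0
    for null_layer in null_matrices(A, n_null, rng):
        try:
            nulls.append(_metric_value(metric_fn, null_layer))
        except UndefinedMetricError:
            n_missing += 1
    null_arr = np.array(nulls, dtype=float)
    if null_arr.size == 0:
        raise DegenerateNullError("metric undefined on every null draw")
    p = _mc_p(float(obs_value.value), null_arr, sidedness)
    return MetricReport(
        metric=obs_value,
        null_values=null_arr,
        p_value=p,
        n_null=int(null_arr.size),
        n_missing=n_missing,
        seed=int(seed),
        sidedness=sidedness,
    )


def standardized_Q(
    A: LayerMatrix,
    n_null: int = 1000,
    config: Optional[AnnealingConfig] = None,
    seed: int = 0,
    n_iter_obs: int = 20,
) -> QSignificance:
    """Standardized modularity: (Q_obs - mean Q_null) / sd Q_null.

    The observed Q is the best of ``n_iter_obs`` annealing restarts; each
    Patefield null matrix gets one annealing fit (its own deterministic
    seed).  A null distribution with zero spread raises
    :class:`DegenerateNullError`.
    """
    rng = np.random.default_rng(seed)
    obs = best_of(A, n_iter=n_iter_obs, config=config, seed=int(rng.integers(2**31 - 1)))
    fit_seeds = rng.integers(1, 2**31 - 1, size=n_null)
    q_null = np.empty(n_null)
    for k, null_layer in enumerate(null_matrices(A, n_null, rng)):
        q_null[k] = quanbimo_fit(null_layer, config=config, seed=int(fit_seeds[k])).Q
    sd = float(q_null.std(ddof=1))
    if sd < 1e-12:
        raise DegenerateNullError("null modularity distribution has zero variance")
    z = (obs.Q - float(q_null.mean())) / sd
    return QSignificance(
        q_obs=obs.Q,
        null_mean=float(q_null.mean()),
        null_sd=sd,
        z=float(z),
        n_null=n_null,
        seed=int(seed),
    )


def layer_difference_test(
    A: LayerMatrix,
    B: LayerMatrix,
    metric_fn: MetricFn,
    n: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    metric_name: Optional[str] = None,
) -> LayerComparison:
    """Monte-Carlo test of a metric difference between two layers.

    The observed difference m(A) - m(B) is compared two-sided against
    differences computed on independent Patefield randomizations of each
    layer — the null keeps every species' interaction total in both layers
    and asks whether the structural difference exceeds what margin effects
    alone produce.
    """
    value_a = _metric_value(metric_fn, A)
    value_b = _metric_value(metric_fn, B)
    observed = value_a - value_b
    rng = np.random.default_rng(seed)
    nulls_a = null_matrices(A, n, rng)
    nulls_b = null_matrices(B, n, rng)
    diffs = []
    for na, nb in zip(nulls_a, nulls_b):
        try:
            diffs.append(_metric_value(metric_fn, na) - _metric_value(metric_fn, nb))
        except UndefinedMetricError:
            continue
    null_diffs = np.array(diffs, dtype=float)
    if null_diffs.size == 0:
        raise DegenerateNullError("metric undefined on every null pair")
    p = _mc_p(observed, null_diffs, "two-sided")
    name = metric_name or getattr(metric_fn, "__name__", "metric")
    return LayerComparison(
        metric_name=name,
        layer_a=A.resource,
        layer_b=B.resource,
        value_a=value_a,
        value_b=value_b,
        observed_diff=observed,
        null_diffs=null_diffs,
        p_value=p,
        alpha=alpha,
    )
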