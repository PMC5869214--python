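"""Randomization inference for the habitat-validation comparison.

Tests whether counties with historical occurrence records contain more
predicted suitable habitat than chance would produce: the observed F from a
linear model of percent-suitable on the binary presence indicator (equal to
the two-group one-way ANOVA F) is compared against a null distribution built
by permuting the presence labels. Proportions are analysed untransformed --
they contain a high frequency of zeroes, which a logit transform cannot
handle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = ["PermutationResult", "ols_f_statistic", "permutation_f_test"]

_EQ_TOL = 1e-10  # absolute slack when comparing permuted F to the observed F


@dataclass
class PermutationResult:
    """Outcome of a permutation F-test.

    ``f_null`` holds one F per permutation (all distinct label arrangements
    when ``exhaustive``). ``p_value`` is the proportion of null statistics
    satisfying the comparison rule against ``f_observed``. ``degenerate``
    flags a response with zero variance, for which F is defined as 0.
    """

    f_observed: float
    n_iterations: int
    f_null: np.ndarray
    p_value: float
    seed: int | None
    exhaustive: bool
    comparison: str
    degenerate: bool = False


def _check_inputs(response: np.ndarray, labels: np.ndarray) -> None:
    if response.shape != labels.shape or response.ndim != 1:
        raise ValueError("response and labels must be 1-D and equal length")
    if response.size < 3:
        raise ValueError("need at least 3 observations")
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be binary (0/1)")
    if uniq.size < 2:
        raise ValueError("labels are constant; both groups must be present")


def _f_from_group_sums(
    sum1: np.ndarray, n1: int, total: float, sst: float, n: int
) -> np.ndarray:
    """Two-group ANOVA F from the label-1 group sum(s); vectorised."""
    n0 = n - n1
    sum0 = total - sum1
    ssb = sum1**2 / n1 + sum0**2 / n0 - total**2 / n
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ssw > 0, ssb / (ssw / (n - 2)), np.inf)
    return np.where(ssb <= 0, 0.0, f)


def ols_f_statistic(response, labels) -> float:
    """Overall regression F for ``response ~ labels`` on the raw scale.

    With a single binary predictor this equals the one-way ANOVA F between
    the two label groups, on (1, n-2) degrees of freedom. A zero-variance
    response returns 0 (degenerate).
    """
    y = np.asarray(response, dtype=float)
    g = np.asarray(labels, dtype=float)
    _check_inputs(y, g)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    n1 = int(g.sum())
    f = _f_from_group_sums(
        np.array([float(y[g == 1].sum())]), n1, float(y.sum()), sst, y.size
    )
    return float(f[0])


def permutation_f_test(
    response,
    labels,
    n_iterations: int = 10_000,
    seed: int | None = None,
    comparison: str = "greater_equal",
    bootstrap_labels: bool = False,
    force_monte_carlo: bool = False,
) -> PermutationResult:
    """Permutation test of the F statistic under randomised presence labels.

    The null is built by permuting the labels without replacement, which
    preserves the number of presence counties (the design margin); with
    ``bootstrap_labels`` the labels are instead resampled with replacement,
    as a sensitivity analysis. When the number of distinct label
    arrangements is at most ``n_iterations`` the null is enumerated
    exhaustively instead of sampled.

    ``comparison`` is ``"greater_equal"`` (default: permuted F >= observed
    counts toward p) or ``"greater"`` (strictly greater). The two differ
    only through ties at the observed value.
    """
    y = np.asarray(response, dtype=float)
    g = np.asarray(labels, dtype=int)
    _check_inputs(y, g.astype(float))
    if comparison not in {"greater", "greater_equal"}:
        raise ValueError(f"unknown comparison rule {comparison!r}")

    n = y.size
    n1 = int(g.sum())
    total = float(y.sum())
    sst = float(((y - y.mean()) ** 2).sum())
    degenerate = sst == 0.0
    f_obs = ols_f_statistic(y, g)

    rng = np.random.default_rng(seed)
    n_arrangements = math.comb(n, n1)
    exhaustive = (
        not bootstrap_labels
        and not force_monte_carlo
        and n_arrangements <= n_iterations
    )
    if degenerate:
        f_null = np.zeros(n_arrangements if exhaustive else n_iterations)
    elif exhaustive:
        sums1 = np.array(
            [y[list(idx)].sum() for idx in combinations(range(n), n1)]
        )
        f_null = _f_from_group_sums(sums1, n1, total, sst, n)
    elif bootstrap_labels:
        f_null = np.empty(n_iterations)
        for i in range(n_iterations):
            while True:  # redraw until both labels present
                gb = rng.integers(0, 2, size=n)
                k = int(gb.sum())
                if 0 < k < n:
                    break
            f_null[i] = _f_from_group_sums(
                np.array([float(y[gb == 1].sum())]), k, total, sst, n
            )[0]
    else:
        # permute without replacement: draw n1 indices per iteration
        order = np.argsort(rng.random((n_iterations, n)), axis=1)[:, :n1]
        sums1 = y[order].sum(axis=1)
        f_null = _f_from_group_sums(sums1, n1, total, sst, n)

    if comparison == "greater_equal":
        hits = f_null >= f_obs - _EQ_TOL
    else:
        hits = f_null > f_obs + _EQ_TOL
    p = float(hits.mean())
    return PermutationResult(
        f_observed=f_obs,
        n_iterations=len(f_null),
        f_null=f_null,
        p_value=p,
        seed=seed,
        exhaustive=exhaustive,
        comparison=comparison,
        degenerate=degenerate,
    )
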