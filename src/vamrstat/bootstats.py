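"""Pooled-bootstrap median-difference testing with FDR control.

The behavioral endpoints are heterogeneous, bounded and mostly
non-Gaussian, so group comparisons use a model-free two-sample bootstrap
on the absolute difference of group medians:

* observed statistic ``T_obs = |median(A) - median(B)|``;
* the null is enforced by pooling the two groups; each of ``B``
  resamples draws ``N = n_A + n_B`` values with replacement from the
  pool, assigns the first ``n_A`` to a pseudo-A and the remaining
  ``n_B`` to a pseudo-B (honoring the original group sizes), and
  recomputes the statistic;
* the two-sided p-value is the proportion of resample statistics that
  meet or exceed the observed one, floored at ``1/B`` so reported
  p-values are strictly positive.

An alternative location-shift bootstrap (resampling each group from
itself and centering the resampled difference at the observed one) is
available via ``null="separate"``.  Benjamini-Hochberg (default) or
Hochberg step-up adjustment is applied within a declared test family.
Percentile bootstrap confidence intervals for medians use a separate,
smaller resample count.  All resampling is seeded: per-test generators
are derived deterministically from the master seed and the
(endpoint, comparison) labels so serial and parallel execution agree.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .endpoints import ENDPOINT_NAMES

_ADJUST_METHODS = {"bh": "fdr_bh", "hochberg": "simes-hochberg"}


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling parameters for tests and confidence intervals."""

    b_test: int = 10_000
    b_ci: int = 1_000
    ci_level: float = 0.95
    seed: int = 0
    adjust_method: str = "bh"
    null: str = "pooled"  # pooled | separate
    add_one: bool = False  # (count+1)/(B+1) estimator variant

    def __post_init__(self) -> None:
        if self.b_test < 1 or self.b_ci < 1:
            raise ValueError("resample counts must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.adjust_method not in _ADJUST_METHODS:
            raise ValueError(f"adjust_method must be one of {sorted(_ADJUST_METHODS)}")
        if self.null not in ("pooled", "separate"):
            raise ValueError("null must be 'pooled' or 'separate'")


@dataclass(frozen=True)
class TestResult:
    """One comparison's statistic, p-values and resampling provenance."""

    endpoint: str
    comparison: str
    n_a: int
    n_b: int
    observed_stat: float
    p_raw: float
    p_adj: float = float("nan")
    b: int = 0
    seed: int = 0


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-test generator derived from seed and string keys."""
    digest = zlib.crc32("|".join(str(k) for k in keys).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), digest]))


def _clean(values, label: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError(f"group {label!r} has fewer than 2 non-missing values")
    # canonical order: resampling treats a group as a multiset, so permuting
    # values within a group must not change the seeded result
    return np.sort(v)


def bootstrap_median_test(
    group_a,
    group_b,
    config: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
    endpoint: str = "",
    comparison: str = "",
) -> TestResult:
    """Two-sided pooled-bootstrap test on |median(A) - median(B)|.

    Missing values must be removed upstream; NaNs here are dropped with
    the same <2-values guard.  Deterministic given the config seed (or an
    explicitly supplied generator).
    """
    cfg = config or BootstrapConfig()
    a = _clean(group_a, "A")
    b = _clean(group_b, "B")
    if rng is None:
        rng = substream(cfg.seed, endpoint, comparison)
    t_obs = abs(float(np.median(a)) - float(np.median(b)))

    n_a, n_b = a.size, b.size
    if cfg.null == "pooled":
        pooled = np.concatenate([a, b])
        idx = rng.integers(0, n_a + n_b, size=(cfg.b_test, n_a + n_b))
        samples = pooled[idx]
        t_star = np.abs(
            np.median(samples[:, :n_a], axis=1) - np.median(samples[:, n_a:], axis=1)
        )
    else:  # location-shift bootstrap, centered at the observed difference
        diff_obs = float(np.median(a)) - float(np.median(b))
        ia = rng.integers(0, n_a, size=(cfg.b_test, n_a))
        ib = rng.integers(0, n_b, size=(cfg.b_test, n_b))
        diff_star = np.median(a[ia], axis=1) - np.median(b[ib], axis=1)
        t_star = np.abs(diff_star - diff_obs)

    count = int(np.count_nonzero(t_star >= t_obs))
    if cfg.add_one:
        p = (count + 1) / (cfg.b_test + 1)
    else:
        p = max(count, 1) / cfg.b_test  # floor at 1/B: p stays in (0, 1]
    return TestResult(
        endpoint=endpoint,
        comparison=comparison,
        n_a=n_a,
        n_b=n_b,
        observed_stat=t_obs,
        p_raw=float(p),
        b=cfg.b_test,
        seed=cfg.seed,
    )


def adjust_pvalues(p_values, method: str = "bh") -> np.ndarray:
    """Step-up multiplicity adjustment (BH false-discovery-rate control or
    Hochberg family-wise control), order-stable and clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=_ADJUST_METHODS[method])[1]


def bootstrap_median_ci(
    values, config: BootstrapConfig | None = None, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the median.

    Draws ``b_ci`` resamples with replacement (one ``(b_ci, n)`` index
    block, rows used in order) and returns the lower/upper percentiles
    of the resample medians at the configured level.
    """
    cfg = config or BootstrapConfig()
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least 2 non-missing values for a median CI")
    v = np.sort(v)  # canonical order, as in the test resampler
    if rng is None:
        rng = substream(cfg.seed, "median_ci")
    idx = rng.integers(0, v.size, size=(cfg.b_ci, v.size))
    medians = np.median(v[idx], axis=1)
    tail = 100 * (1 - cfg.ci_level) / 2
    lower, upper = np.percentile(medians, [tail, 100 - tail])
    return float(lower), float(upper)


def run_endpoint_tests(
    endpoint_table: pd.DataFrame,
    control_label: str,
    config: BootstrapConfig | None = None,
    group_col: str = "group",
    endpoints=ENDPOINT_NAMES,
) -> pd.DataFrame:
    """Test every endpoint in every non-control group against the control.

    One test per (endpoint x group) pair; all tests from the run form a
    single adjustment family (the most conservative plate-level
    reading).  Missing endpoint values are dropped per test with the
    retained group sizes recorded in the result table.
    """
    cfg = config or BootstrapConfig()
    if group_col not in endpoint_table.columns:
        raise ValueError(f"endpoint table has no {group_col!r} column")
    groups = endpoint_table[group_col]
    if control_label not in set(groups):
        raise ValueError(f"control group {control_label!r} not present in the table")
    others = [g for g in pd.unique(groups) if g != control_label]

    rows = []
    for endpoint in endpoints:
        control = endpoint_table.loc[groups == control_label, endpoint].to_numpy(dtype=float)
        for g in others:
            treated = endpoint_table.loc[groups == g, endpoint].to_numpy(dtype=float)
            res = bootstrap_median_test(
                control, treated, cfg, endpoint=endpoint, comparison=str(g)
            )
            rows.append(res)

    result = pd.DataFrame(
        {
            "endpoint": [r.endpoint for r in rows],
            "comparison": [r.comparison for r in rows],
            "n_control": [r.n_a for r in rows],
            "n_treatment": [r.n_b for r in rows],
            "observed_stat": [r.observed_stat for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "b": [r.b for r in rows],
            "seed": [r.seed for r in rows],
        }
    )
    result["p_adj"] = adjust_pvalues(result["p_raw"].to_numpy(), cfg.adjust_method)
    return result


def bin_median_ci_series(
    activity: np.ndarray, config: BootstrapConfig | None = None, bins=None
) -> pd.DataFrame:
    """Per-1-s-bin median with percentile bootstrap CI across wells.

    ``activity`` is (n_wells, n_seconds); ``bins`` optionally restricts
    the computation to a subset of second indices.  Intended for
    median +/- CI line plots of group traces.
    """
    cfg = config or BootstrapConfig()
    activity = np.asarray(activity, dtype=float)
    if bins is None:
        bins = np.arange(activity.shape[1])
    bins = np.asarray(bins, dtype=int)
    rng = substream(cfg.seed, "bin_ci")
    n = activity.shape[0]
    idx = rng.integers(0, n, size=(cfg.b_ci, n))
    tail = 100 * (1 - cfg.ci_level) / 2
    out = np.empty((bins.size, 3))
    for j, t in enumerate(bins):
        col = activity[:, t]
        med = np.median(col[idx], axis=1)
        out[j] = (np.median(col), *np.percentile(med, [tail, 100 - tail]))
    return pd.DataFrame(
        {"time_s": bins, "median": out[:, 0], "lower": out[:, 1], "upper": out[:, 2]}
    )
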