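"""Systematic Monte Carlo resampling of the grid offset.

Replicates the whole estimation over a K x K jittered regular subgrid of
offsets inside the fundamental box.  The subgrid needs a single pair of
uniform random numbers: offset ``(i, j)`` sits at ``((U1+i-1)*Delta,
(U2+j-1)*Delta)`` with ``Delta = T/K``.  The replicates give the empirical
distribution of the size estimate, its empirical variance (denominator K^2),
and the mean behaviour of both variance predictors as squared coefficients
of error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import count_points
from .estimation import (
    InsufficientSampleError,
    estimate_n,
    split_stripes,
    var_cavalieri,
    var_independence,
)
from .geometry import GridSpec, PointPattern

__all__ = [
    "McReplicate",
    "McResult",
    "systematic_offsets",
    "run_sweep",
    "quadrat_content_distribution",
]


def systematic_offsets(
    k_side: int, seed: int, spec: GridSpec | None = None
) -> list[tuple[float, float]]:
    """K^2 offsets on a jittered regular subgrid of the fundamental box.

    Returned as unit-box fractions; multiply by T for pixel positions.  All
    K^2 replications derive from one pair of uniform random numbers.
    """
    if k_side < 1:
        raise ValueError(f"k_side must be >= 1, got {k_side}")
    rng = np.random.default_rng(seed)
    u1, u2 = rng.random(2)
    k = k_side
    return [
        (float((u1 + i) / k), float((u2 + j) / k))
        for i in range(k)
        for j in range(k)
    ]


@dataclass(frozen=True)
class McReplicate:
    """One offset replication of the full estimation."""

    index: int
    u1: float
    u2: float
    q: int
    n_hat: float
    var_ind: float
    var_cav: float


@dataclass
class McResult:
    """Replicated estimates plus empirical and predicted error summaries.

    ``ce2_*`` values are squared coefficients of error: variances divided by
    the squared true size when it is known, else by the squared empirical
    mean (``normalized_by`` records which).
    """

    replicates: list[McReplicate]
    k_side: int
    spec: dict
    true_n: int | None
    empirical_mean: float
    empirical_var: float
    ce2_emp: float
    ce2_ind_mean: float
    ce2_cav_mean: float
    quantiles_cav: tuple[float, float]
    normalized_by: str

    def replicates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [r.index for r in self.replicates],
                "u_x": [r.u1 for r in self.replicates],
                "u_y": [r.u2 for r in self.replicates],
                "Q_k": [r.q for r in self.replicates],
                "n_hat_k": [r.n_hat for r in self.replicates],
                "var_ind_k": [r.var_ind for r in self.replicates],
                "var_cav_k": [r.var_cav for r in self.replicates],
            }
        )

    def replicates_to_csv(self, path: str | Path) -> None:
        self.replicates_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "k_side": self.k_side,
            "n_replicates": len(self.replicates),
            "spec": self.spec,
            "true_n": self.true_n,
            "empirical_mean": self.empirical_mean,
            "empirical_var": self.empirical_var,
            "ce2_emp": self.ce2_emp,
            "ce2_ind_mean": self.ce2_ind_mean,
            "ce2_cav_mean": self.ce2_cav_mean,
            "quantiles_cav": list(self.quantiles_cav),
            "normalized_by": self.normalized_by,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def run_sweep(
    pattern: PointPattern, spec: GridSpec, k_side: int, seed: int
) -> McResult:
    """Replicate counting and estimation over the systematic offset sweep."""
    if pattern.n == 0:
        raise ValueError("cannot sweep an empty pattern")
    offsets = systematic_offsets(k_side, seed, spec)
    reps: list[McReplicate] = []
    for k, (u1, u2) in enumerate(offsets, start=1):
        spec_k = replace(spec, offset=(u1, u2))
        sample = count_points(pattern, spec_k)
        q = sample.total_q
        n_hat = estimate_n(sample)
        try:
            v_ind = var_independence(sample)
        except InsufficientSampleError:
            v_ind = float("nan")
        try:
            # clamping on individual replicates is routine, not reportable
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                v_cav = var_cavalieri(split_stripes(sample)).total
        except InsufficientSampleError:
            v_cav = float("nan")
        reps.append(McReplicate(k, u1, u2, q, float(n_hat), v_ind, v_cav))

    qs = np.array([r.q for r in reps], dtype=float)
    n_hats = np.array([r.n_hat for r in reps])
    v_inds = np.array([r.var_ind for r in reps])
    v_cavs = np.array([r.var_cav for r in reps])

    emp_mean = float(spec.inflation * qs.mean())
    emp_var = float(np.mean((n_hats - emp_mean) ** 2))  # K^-2 denominator
    if pattern.true_n:
        denom = float(pattern.true_n) ** 2
        normalized_by = "true_n"
    else:
        denom = emp_mean**2
        normalized_by = "empirical_mean"
    with np.errstate(invalid="ignore"):
        ce2_ind = float(np.nanmean(v_inds) / denom)
        ce2_cav = float(np.nanmean(v_cavs) / denom)
        qlo, qhi = np.nanquantile(v_cavs / denom, [0.025, 0.975])
    return McResult(
        replicates=reps,
        k_side=k_side,
        spec=spec.to_dict(),
        true_n=pattern.true_n,
        empirical_mean=emp_mean,
        empirical_var=emp_var,
        ce2_emp=emp_var / denom,
        ce2_ind_mean=ce2_ind,
        ce2_cav_mean=ce2_cav,
        quantiles_cav=(float(qlo), float(qhi)),
        normalized_by=normalized_by,
    )


def quadrat_content_distribution(
    pattern: PointPattern, spec: GridSpec, k_side: int, seed: int
) -> dict[int, float]:
    """Pooled relative frequencies of nonzero per-quadrat counts.

    Pools the nonempty quadrat contents over all K^2 systematic offsets and
    normalizes to probabilities.
    """
    if pattern.n == 0:
        raise ValueError("cannot sweep an empty pattern")
    pooled: dict[int, int] = {}
    for u1, u2 in systematic_offsets(k_side, seed, spec):
        sample = count_points(pattern, replace(spec, offset=(u1, u2)))
        for c in sample.counts.values():
            if c > 0:
                pooled[c] = pooled.get(c, 0) + 1
    total = sum(pooled.values())
    return {c: pooled[c] / total for c in sorted(pooled)}
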