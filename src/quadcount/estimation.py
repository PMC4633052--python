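"""Population-size estimation and its two error-variance predictors.

From a quadrat sample with total count Q and sampling design (t, T), the
size estimate is ``(T/t)**2 * Q``, which is design-unbiased for any fixed
population pattern.  Its error variance is predicted two ways:

* ``var_independence`` — the naive predictor that treats the nonempty
  quadrat counts as independent draws;
* ``var_cavalieri`` — the transitive (Cavalieri stripes) predictor, which
  models the serial correlation of the stripe totals and adds a
  within-stripe term obtained by splitting each stripe's quadrats into odd
  and even numbered ones.

The Cavalieri predictor decomposes as ``between + within`` with

    between = (1/6) * (1-tau)^2 / (tau^4 * (2-tau)) * [3*(C0 - nu) - 4*C1 + C2]
    within  = nu / tau^4
    nu      = (1-tau)^2 / (3 - 2*tau) * sum_i (Q_oi - Q_ei)^2

where ``tau = t/T``, ``C_k = sum_j Q_j Q_{j+k}`` over the stripe totals, and
``Q_oi``/``Q_ei`` are odd/even-position quadrat totals within stripe ``i``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .counting import QuadratSample
from .geometry import GridSpec

__all__ = [
    "InsufficientSampleError",
    "TooFewStripesError",
    "StripeSummary",
    "CavalieriVariance",
    "EstimateReport",
    "estimate_n",
    "var_independence",
    "split_stripes",
    "splitting_nu",
    "var_cavalieri",
    "coefficient_of_error",
    "report_from_sample",
    "report_from_stripes",
    "read_stripe_table",
]


class InsufficientSampleError(ValueError):
    """Raised when a sample is too small for the requested estimator."""


class TooFewStripesError(InsufficientSampleError):
    """Raised when fewer than three stripes carry the sample."""


def estimate_n(sample: QuadratSample) -> float:
    """Design-unbiased size estimate ``(T/t)**2 * Q``."""
    return sample.spec.inflation * sample.total_q


def _var_independence_core(nonempty_counts: np.ndarray, side_ratio: float) -> float:
    n = len(nonempty_counts)
    if n < 2:
        raise InsufficientSampleError(
            f"independence variance needs >= 2 nonempty quadrats, got {n}"
        )
    s2 = float(np.var(nonempty_counts, ddof=1))
    return side_ratio**4 * n * s2


def var_independence(sample: QuadratSample) -> float:
    """Naive variance predictor ``(T/t)**4 * n * s2``.

    ``n`` is the number of nonempty quadrats and ``s2`` the sample variance
    (denominator ``n - 1``) of their counts.
    """
    return _var_independence_core(
        sample.nonempty_counts(), sample.spec.T / sample.spec.t
    )


@dataclass(frozen=True)
class StripeSummary:
    """Per-stripe count vectors, ordered bottom-to-top within each stripe.

    Stripes run from the first to the last one holding any particle;
    interior all-zero stripes are kept (their totals are 0).  Odd/even
    labels follow the within-stripe position, starting at 1 at the bottom.
    """

    counts: tuple[tuple[int, ...], ...]
    tau: float

    def __post_init__(self) -> None:
        if not (0.0 < self.tau <= 1.0):
            raise ValueError(f"tau must lie in (0, 1], got {self.tau}")
        for stripe in self.counts:
            for c in stripe:
                if c < 0:
                    raise ValueError("quadrat counts must be nonnegative")

    @classmethod
    def from_table(
        cls, stripes: Sequence[Sequence[int]], tau: float
    ) -> "StripeSummary":
        return cls(
            counts=tuple(tuple(int(c) for c in s) for s in stripes),
            tau=float(tau),
        )

    @property
    def n(self) -> int:
        """Number of stripes."""
        return len(self.counts)

    @cached_property
    def q_i(self) -> np.ndarray:
        """Stripe totals."""
        return np.array([sum(s) for s in self.counts], dtype=float)

    @cached_property
    def q_oi(self) -> np.ndarray:
        """Odd-position totals per stripe (positions 1, 3, 5, ...)."""
        return np.array([sum(s[0::2]) for s in self.counts], dtype=float)

    @cached_property
    def q_ei(self) -> np.ndarray:
        """Even-position totals per stripe (positions 2, 4, 6, ...)."""
        return np.array([sum(s[1::2]) for s in self.counts], dtype=float)

    @property
    def total_q(self) -> int:
        return int(self.q_i.sum())

    @property
    def split_sum_sq(self) -> float:
        """``sum_i (Q_oi - Q_ei)**2`` — the splitting statistic."""
        return float(np.sum((self.q_oi - self.q_ei) ** 2))

    def nonempty_counts(self) -> np.ndarray:
        return np.array(
            [c for stripe in self.counts for c in stripe if c > 0], dtype=float
        )

    def reversed_stripes(self) -> "StripeSummary":
        return StripeSummary(counts=self.counts[::-1], tau=self.tau)


def split_stripes(sample: QuadratSample) -> StripeSummary:
    """Group a quadrat sample into per-stripe bottom-to-top count vectors.

    Stripe enumeration is trimmed to the first..last stripe with any
    particle; within-stripe positions are those of the quadrats enumerated
    against the observation window, so the odd/even labelling matches a
    manual count sheet.
    """
    if not sample.counts:
        raise InsufficientSampleError("cannot split an empty sample into stripes")
    by_stripe: dict[int, dict[int, int]] = {}
    for addr, c in sample.counts.items():
        by_stripe.setdefault(addr.stripe_index, {})[addr.within_index] = c
    occupied = [s for s, d in by_stripe.items() if any(v > 0 for v in d.values())]
    if not occupied:
        raise InsufficientSampleError("sample holds no particles")
    s_lo, s_hi = min(occupied), max(occupied)
    stripes: list[tuple[int, ...]] = []
    for s in range(s_lo, s_hi + 1):
        col = by_stripe.get(s, {})
        depth = max(col, default=0)
        stripes.append(tuple(col.get(p, 0) for p in range(1, depth + 1)))
    return StripeSummary(counts=tuple(stripes), tau=sample.spec.tau)


def splitting_nu(summary: StripeSummary) -> float:
    """Within-stripe variance term of the splitting estimator."""
    tau = summary.tau
    return (1.0 - tau) ** 2 / (3.0 - 2.0 * tau) * summary.split_sum_sq


class CavalieriVariance(NamedTuple):
    total: float
    between: float
    within: float


def var_cavalieri(summary: StripeSummary) -> CavalieriVariance:
    """Transitive variance predictor, split into between/within-stripe terms.

    The between term can go negative on adversarial count sequences; it is
    then clamped to zero with a warning, so that the returned variance is
    always nonnegative.
    """
    n = summary.n
    if n <= 2:
        raise TooFewStripesError(f"need more than 2 stripes, got {n}")
    tau = summary.tau
    q = summary.q_i
    c0, c1, c2 = (float(q[: n - k] @ q[k:]) for k in (0, 1, 2))
    nu = splitting_nu(summary)
    bracket = 3.0 * (c0 - nu) - 4.0 * c1 + c2
    if bracket < 0.0:
        warnings.warn(
            "between-stripes variance bracket is negative; clamping to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        bracket = 0.0
    between = (1.0 - tau) ** 2 / (6.0 * tau**4 * (2.0 - tau)) * bracket
    within = nu / tau**4
    return CavalieriVariance(between + within, between, within)


def coefficient_of_error(variance: float, n_hat: float) -> float:
    """Percent coefficient of error (relative standard error)."""
    if n_hat <= 0:
        raise ValueError("coefficient of error is undefined for a zero estimate")
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    return 100.0 * math.sqrt(variance) / n_hat


@dataclass
class EstimateReport:
    """Full estimation output: size estimate, variances and error rates."""

    n_hat: float
    n_hat_rounded: int
    var_ind: float
    var_cav: float
    var_cav_between: float
    var_cav_within: float
    ce_ind_pct: float
    ce_cav_pct: float
    q_total: int
    n_nonempty: int
    n_stripes: int
    nu: float
    spec: dict
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        return {
            "n_hat": clean(self.n_hat),
            "n_hat_rounded": self.n_hat_rounded,
            "var_ind": clean(self.var_ind),
            "var_cav": clean(self.var_cav),
            "var_cav_between": clean(self.var_cav_between),
            "var_cav_within": clean(self.var_cav_within),
            "ce_ind_pct": clean(self.ce_ind_pct),
            "ce_cav_pct": clean(self.ce_cav_pct),
            "q_total": self.q_total,
            "n_nonempty": self.n_nonempty,
            "n_stripes": self.n_stripes,
            "nu": clean(self.nu),
            "spec": self.spec,
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        def fmt(v, digits=3):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return "n/a"
            return f"{v:.{digits}f}"

        lines = [
            "population size estimate",
            f"  quadrats counted (nonempty): {self.n_nonempty}",
            f"  stripes:                     {self.n_stripes}",
            f"  total count Q:               {self.q_total}",
            f"  N-hat:                       {fmt(self.n_hat, 2)}"
            f"  (rounded {self.n_hat_rounded})",
            "error prediction",
            f"  var (independence):          {fmt(self.var_ind)}",
            f"  ce  (independence):          {fmt(self.ce_ind_pct, 2)} %",
            f"  var (Cavalieri/splitting):   {fmt(self.var_cav)}"
            f"  = {fmt(self.var_cav_between)} between"
            f" + {fmt(self.var_cav_within)} within",
            f"  ce  (Cavalieri/splitting):   {fmt(self.ce_cav_pct, 2)} %",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _build_report(
    q_total: int,
    nonempty: np.ndarray,
    summary: StripeSummary | None,
    spec: GridSpec,
) -> EstimateReport:
    notes: list[str] = []
    n_hat = spec.inflation * q_total
    if q_total == 0:
        notes.append("empty sample: Q = 0, the size estimate is zero")

    var_ind = float("nan")
    ce_ind = float("nan")
    try:
        var_ind = _var_independence_core(nonempty, spec.T / spec.t)
        if n_hat > 0:
            ce_ind = coefficient_of_error(var_ind, n_hat)
    except InsufficientSampleError as exc:
        notes.append(str(exc))

    var_cav = between = within = nu = float("nan")
    ce_cav = float("nan")
    n_stripes = summary.n if summary is not None else 0
    if summary is not None:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                cav = var_cavalieri(summary)
            for w in caught:
                notes.append(str(w.message))
            var_cav, between, within = cav
            nu = splitting_nu(summary)
            if n_hat > 0:
                ce_cav = coefficient_of_error(var_cav, n_hat)
        except InsufficientSampleError as exc:
            notes.append(str(exc))
    return EstimateReport(
        n_hat=float(n_hat),
        n_hat_rounded=_round_half_up(n_hat),
        var_ind=var_ind,
        var_cav=var_cav,
        var_cav_between=between,
        var_cav_within=within,
        ce_ind_pct=ce_ind,
        ce_cav_pct=ce_cav,
        q_total=int(q_total),
        n_nonempty=int(len(nonempty)),
        n_stripes=n_stripes,
        nu=nu,
        spec=spec.to_dict(),
        warnings=tuple(notes),
    )


def report_from_sample(sample: QuadratSample) -> EstimateReport:
    """Estimate and error-predict from a geometric quadrat sample."""
    summary = None
    if sample.total_q > 0:
        summary = split_stripes(sample)
    return _build_report(
        sample.total_q, sample.nonempty_counts(), summary, sample.spec
    )


def report_from_stripes(
    summary: StripeSummary, t: float, T: float, theta_deg: float = 0.0
) -> EstimateReport:
    """Estimate and error-predict from a manually entered stripe table."""
    spec = GridSpec(t=t, T=T, theta_deg=theta_deg)
    if abs(spec.tau - summary.tau) > 1e-9:
        raise ValueError(
            f"stripe table tau={summary.tau} does not match t/T={spec.tau}"
        )
    return _build_report(
        summary.total_q, summary.nonempty_counts(), summary, spec
    )


def read_stripe_table(path: str | Path) -> list[list[int]]:
    """Read a manual count sheet: columns are stripes, rows are positions.

    Row 1 of each column is the bottom-most quadrat of that stripe.  Stripes
    may differ in length; leave cells blank below a stripe's last quadrat.
    Zeros must be written explicitly — a blank means "no quadrat here".
    """
    df = pd.read_csv(path)
    stripes: list[list[int]] = []
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="raise")
        vals = vals.dropna()
        stripes.append([int(v) for v in vals])
    return stripes
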