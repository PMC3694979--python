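"""Fractional-polynomial transforms for continuous covariates.

Implements the canonical single-variable fractional polynomial (FP) family
with powers drawn from {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (power 0 denoting the
natural log, and repeated powers adding a log-multiplied column), together
with the closed test sequence used to pick between FP2, FP1, a plain linear
term, or omission of the variable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from ._errors import DegenerateOutcomeError, ValidationError
from ._util import as_binary

CANONICAL_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FPTransform:
    """A fitted fractional-polynomial preprocessing recipe for one variable.

    ``shift`` and ``scale`` are frozen at selection time so that scoring new
    data applies byte-identical preprocessing.
    """

    variable: str
    powers: tuple[float, ...]
    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if len(self.powers) not in (1, 2):
            raise ValidationError("degree must be 1 or 2", field="powers")
        for p in self.powers:
            if p not in CANONICAL_POWERS:
                raise ValidationError(
                    f"power {p} not in canonical set {CANONICAL_POWERS}",
                    field="powers",
                )
        if tuple(sorted(self.powers)) != tuple(self.powers):
            raise ValidationError("powers must be stored sorted", field="powers")
        if self.shift < 0:
            raise ValidationError("shift must be nonnegative", field="shift")
        if self.scale <= 0:
            raise ValidationError("scale must be positive", field="scale")

    @property
    def degree(self) -> int:
        return len(self.powers)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "powers": list(self.powers),
            "shift": self.shift,
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FPTransform":
        return cls(
            variable=d["variable"],
            powers=tuple(d["powers"]),
            shift=d["shift"],
            scale=d["scale"],
        )


def _power_col(z: np.ndarray, p: float) -> np.ndarray:
    if p == 0.0:
        return np.log(z)
    return z ** p


def fp_apply(x, transform: FPTransform) -> np.ndarray:
    """Apply a fractional-polynomial transform; returns an (n, degree) matrix.

    Power 0 means the natural log; a repeated FP2 power (p, p) produces the
    columns z^p and z^p * ln(z).
    """
    x = np.asarray(x, dtype=float)
    z = (x + transform.shift) / transform.scale
    bad = np.nonzero(~(z > 0))[0]
    if bad.size:
        raise ValidationError(
            f"nonpositive value after shift/scale at index {bad[0]} "
            f"(x={x[bad[0]]!r})",
            field=transform.variable,
        )
    ps = transform.powers
    if len(ps) == 1:
        return _power_col(z, ps[0])[:, None]
    p1, p2 = ps
    c1 = _power_col(z, p1)
    if p1 == p2:
        c2 = c1 * np.log(z)
    else:
        c2 = _power_col(z, p2)
    return np.column_stack([c1, c2])


def choose_shift_scale(x: np.ndarray) -> tuple[float, float]:
    """Standard preprocessing rule: shift to positivity, scale to order one.

    Shift is 0 when min(x) > 0; otherwise -min(x) plus a data-derived offset
    (5% of the interquartile range, floored by the smallest spacing between
    distinct values) so that negative powers and logs stay bounded at the
    low end. Scale is the power of 10 nearest to the median shifted value.
    """
    x = np.asarray(x, dtype=float)
    xmin = np.min(x)
    if xmin > 0:
        shift = 0.0
    else:
        diffs = np.diff(np.unique(x))
        eps = float(diffs.min()) if diffs.size else 1.0
        q25, q75 = np.quantile(x, [0.25, 0.75])
        spread = float(q75 - q25) or float(np.max(x) - xmin) or 1.0
        shift = float(-xmin + max(eps, 0.05 * spread))
    z = x + shift
    med = float(np.median(z))
    scale = float(10.0 ** np.round(np.log10(med))) if med > 0 else 1.0
    return shift, scale


@dataclass
class FPSelectResult:
    """Rich output of the closed-test selection (deviances retained)."""

    decision: str  # "omit" | "linear" | "fp"
    transform: FPTransform | None
    dev_null: float
    dev_linear: float
    dev_fp1: float
    dev_fp2: float | None
    best_fp1_powers: tuple[float, ...] = (1.0,)
    best_fp2_powers: tuple[float, ...] | None = None
    shift: float = 0.0
    scale: float = 1.0
    p_overall: float = field(default=1.0)

    @property
    def entry_deviance(self) -> float:
        """Deviance of the selected form (dev_null when omitted)."""
        if self.decision == "omit":
            return self.dev_null
        if self.decision == "linear":
            return self.dev_linear
        if self.transform.degree == 1:
            return self.dev_fp1
        return self.dev_fp2


def _deviance(y: np.ndarray, cols: np.ndarray | None, adjustment) -> float:
    parts = [np.ones((len(y), 1))]
    if adjustment is not None:
        parts.append(np.asarray(adjustment, dtype=float).reshape(len(y), -1))
    if cols is not None:
        parts.append(cols)
    X = np.column_stack(parts)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100,
                                                              tol=1e-10)
    return float(res.deviance)


def fp_select_detail(
    x,
    y,
    adjustment=None,
    alpha: float = 0.05,
    variable: str = "x",
    max_degree: int = 2,
) -> FPSelectResult:
    """Closed-test FP selection, returning all intermediate deviances.

    Test sequence (chi-square on deviance differences, level ``alpha``):
    best FP2 vs null (4 df) -> omit if NS; vs linear (3 df) -> linear if NS;
    vs best FP1 (2 df) -> FP1 if NS; else FP2. With ``max_degree=1`` the
    sequence degenerates to FP1 vs null (2 df) then vs linear (1 df).
    """
    from scipy.stats import chi2

    x = np.asarray(x, dtype=float)
    y = as_binary(y)
    if len(x) != len(y):
        raise ValidationError("x and y must be row-aligned", field="x")
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise DegenerateOutcomeError("outcome vector is constant")
    n_adj = 0 if adjustment is None else np.asarray(adjustment).reshape(len(y), -1).shape[1]
    max_params = 1 + n_adj + 2 * max_degree
    if min(n_events, len(y) - n_events) < max_params:
        raise ValidationError(
            f"fewer events ({n_events}) than parameters ({max_params})",
            field="y",
        )

    shift, scale = choose_shift_scale(x)

    def dev_for(powers: tuple[float, ...]) -> float:
        t = FPTransform(variable=variable, powers=powers, shift=shift, scale=scale)
        return _deviance(y, fp_apply(x, t), adjustment)

    dev_null = _deviance(y, None, adjustment)
    dev_linear = dev_for((1.0,))

    # Exhaustive search; iterate in lexicographic order and only accept a
    # strictly better deviance, so ties break toward smaller power tuples.
    best1_p, best1_dev = (1.0,), dev_linear
    for p in CANONICAL_POWERS:
        d = dev_for((p,)) if p != 1.0 else dev_linear
        if d < best1_dev - 1e-9:
            best1_p, best1_dev = (p,), d

    best2_p, best2_dev = None, np.inf
    if max_degree >= 2:
        for p1, p2 in itertools.combinations_with_replacement(CANONICAL_POWERS, 2):
            d = dev_for((p1, p2))
            if d < best2_dev - 1e-9:
                best2_p, best2_dev = (p1, p2), d

    def lr_p(dev_lo: float, dev_hi: float, df: int) -> float:
        return float(chi2.sf(max(dev_hi - dev_lo, 0.0), df))

    if max_degree >= 2:
        p_overall = lr_p(best2_dev, dev_null, 4)
        if p_overall >= alpha:
            decision, transform = "omit", None
        elif lr_p(best2_dev, dev_linear, 3) >= alpha:
            decision, transform = "linear", None
        elif lr_p(best2_dev, best1_dev, 2) >= alpha:
            decision = "fp"
            transform = FPTransform(variable, best1_p, shift, scale)
        else:
            decision = "fp"
            transform = FPTransform(variable, best2_p, shift, scale)
    else:
        p_overall = lr_p(best1_dev, dev_null, 2)
        if p_overall >= alpha:
            decision, transform = "omit", None
        elif lr_p(best1_dev, dev_linear, 1) >= alpha:
            decision, transform = "linear", None
        else:
            decision = "fp"
            transform = FPTransform(variable, best1_p, shift, scale)

    return FPSelectResult(
        decision=decision,
        transform=transform,
        dev_null=dev_null,
        dev_linear=dev_linear,
        dev_fp1=best1_dev,
        dev_fp2=None if max_degree < 2 else best2_dev,
        best_fp1_powers=best1_p,
        best_fp2_powers=best2_p,
        shift=shift,
        scale=scale,
        p_overall=p_overall,
    )


def fp_select(x, y, adjustment=None, alpha: float = 0.05, variable: str = "x"):
    """Select the functional form for one continuous covariate.

    Returns an :class:`FPTransform`, the string ``"linear"``, or the string
    ``"omit"`` per the closed test.
    """
    res = fp_select_detail(x, y, adjustment=adjustment, alpha=alpha, variable=variable)
    if res.decision == "fp":
        return res.transform
    return res.decision
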