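"""Model terms: mapping covariate columns to design-matrix blocks.

A fitted model stores a list of terms; each term knows how to turn a cohort
DataFrame into its block of design columns, so a serialized model is
self-contained for prediction on new data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .fracpoly import FPTransform, fp_apply


@dataclass(frozen=True)
class BinaryTerm:
    """Single 0/1 indicator for a boolean covariate."""

    name: str
    kind = "binary"

    def columns(self, df: pd.DataFrame) -> np.ndarray:
        return np.asarray(df[self.name], dtype=float)[:, None]

    def labels(self) -> list[str]:
        return [self.name]

    def to_dict(self) -> dict:
        return {"kind": "binary", "name": self.name}


@dataclass(frozen=True)
class CategoricalTerm:
    """Indicator block for a categorical covariate; first level is reference.

    Enters and leaves models as a whole block (multi-df tests).
    """

    name: str
    levels: tuple
    kind = "categorical"

    @property
    def reference(self):
        return self.levels[0]

    def columns(self, df: pd.DataFrame) -> np.ndarray:
        vals = df[self.name]
        known = set(self.levels)
        bad = vals[~vals.isin(list(known))]
        if len(bad):
            raise ValidationError(
                f"unknown level {bad.iloc[0]!r} for covariate {self.name!r}",
                field=self.name,
            )
        return np.column_stack(
            [(vals == lev).to_numpy(dtype=float) for lev in self.levels[1:]]
        )

    def labels(self) -> list[str]:
        return [f"{self.name}[{lev}]" for lev in self.levels[1:]]

    def to_dict(self) -> dict:
        return {"kind": "categorical", "name": self.name, "levels": list(self.levels)}


@dataclass(frozen=True)
class ContinuousTerm:
    """Continuous covariate, optionally through a fractional-polynomial
    transform (``transform is None`` means a plain linear column)."""

    name: str
    transform: FPTransform | None = None
    kind = "continuous"

    def columns(self, df: pd.DataFrame) -> np.ndarray:
        x = np.asarray(df[self.name], dtype=float)
        if self.transform is None:
            return x[:, None]
        return fp_apply(x, self.transform)

    def labels(self) -> list[str]:
        if self.transform is None:
            return [self.name]
        return [f"{self.name}^({p})" for p in self.transform.powers]

    def contribution(self, x: float, coefs: np.ndarray) -> float:
        """Linear-predictor contribution of a single value under ``coefs``."""
        if self.transform is None:
            return float(coefs[0] * x)
        row = fp_apply(np.array([x], dtype=float), self.transform)[0]
        return float(np.dot(np.asarray(coefs, dtype=float), row))

    def to_dict(self) -> dict:
        return {
            "kind": "continuous",
            "name": self.name,
            "transform": None if self.transform is None else self.transform.to_dict(),
        }


@dataclass(frozen=True)
class InteractionTerm:
    """Elementwise products of two terms' column blocks."""

    left: object
    right: object
    kind = "interaction"

    @property
    def name(self) -> str:
        return f"{self.left.name}:{self.right.name}"

    def columns(self, df: pd.DataFrame) -> np.ndarray:
        a = self.left.columns(df)
        b = self.right.columns(df)
        cols = [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])]
        return np.column_stack(cols)

    def labels(self) -> list[str]:
        return [
            f"{la}:{lb}" for la in self.left.labels() for lb in self.right.labels()
        ]

    def to_dict(self) -> dict:
        return {
            "kind": "interaction",
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


def term_from_dict(d: dict):
    kind = d["kind"]
    if kind == "binary":
        return BinaryTerm(d["name"])
    if kind == "categorical":
        return CategoricalTerm(d["name"], tuple(d["levels"]))
    if kind == "continuous":
        t = d.get("transform")
        return ContinuousTerm(d["name"], None if t is None else FPTransform.from_dict(t))
    if kind == "interaction":
        return InteractionTerm(term_from_dict(d["left"]), term_from_dict(d["right"]))
    raise ValidationError(f"unknown term kind {kind!r}", field="kind")


def build_design(df: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    """Stack term blocks into a design matrix (no intercept column)."""
    if not terms:
        return np.empty((len(df), 0)), []
    blocks, labels = [], []
    for t in terms:
        blocks.append(t.columns(df))
        labels.extend(t.labels())
    return np.column_stack(blocks), labels
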