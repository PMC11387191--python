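"""Model specifications and one-hot design matrices with interactions.

The readthrough models are logistic regressions over categorical sequence
features. A :class:`ModelSpec` names the terms of a model; each term is a
group of factor interactions (e.g. the ``down_123`` term contains the
three downstream-nucleotide main effects, their three pairwise
interactions and the three-way interaction). Grouping columns by named
term is what makes term-level ablation and the position scan possible.

Encoding is one-hot with reference-level drop per factor; interaction
columns are products of indicator columns, so a three-factor full
factorial over 4-level factors yields 4^3 - 1 = 63 columns. Reference
levels sort alphabetically except that the "absent" level ``-`` is never
the reference (A is the reference for nucleotide factors, UAA for the
stop type). Factor levels are frozen at fit time: a level unseen during
fitting raises an error when building a training design and is mapped to
the reference (with a logged warning) when building a prediction design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations, product

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Term:
    """A named group of factor interactions.

    ``factors`` is a tuple of factor-name tuples; each inner tuple is one
    interaction (a single name is a main effect).
    """

    name: str
    factors: tuple[tuple[str, ...], ...]

    def crossed_with(self, factor: str, name: str) -> "Term":
        return Term(name, tuple((factor, *f) for f in self.factors))


def factorial_term(name: str, columns: tuple[str, ...]) -> Term:
    """Full-factorial term: all main effects and interactions."""
    tuples = []
    for k in range(1, len(columns) + 1):
        tuples.extend(combinations(columns, k))
    return Term(name, tuple(tuples))


def main_term(name: str, column: str | None = None) -> Term:
    return Term(name, ((column or name,),))


DOWN_123 = ("down_1", "down_2", "down_3")
UP_123 = ("up_1", "up_2", "up_3")

FORMULA_KINDS = (
    "drug_f4",
    "drug_f5_extended",
    "pan_f6",
    "simplified_no_stopdown",
)


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the readthrough regression."""

    formula_kind: str
    terms: tuple[Term, ...]
    max_down_position: int = 3

    @classmethod
    def drug_f4(cls) -> "ModelSpec":
        """Single-drug model: stop type, down/up 1-3 nt full factorials
        and the stop-type x downstream interaction."""
        down = factorial_term("down_123", DOWN_123)
        up = factorial_term("up_123", UP_123)
        stop = main_term("stop_type")
        stop_down = down.crossed_with("stop_type", "stop_down")
        return cls("drug_f4", (stop, down, up, stop_down))

    @classmethod
    def simplified_no_stopdown(cls) -> "ModelSpec":
        """f4 without the stop x downstream interaction, used when
        comparing coefficients across drugs."""
        base = cls.drug_f4()
        return cls(
            "simplified_no_stopdown",
            tuple(t for t in base.terms if t.name != "stop_down"),
        )

    @classmethod
    def drug_f5(cls, max_down_position: int = 8) -> "ModelSpec":
        """f4 extended with downstream positions +4..+k as main effects."""
        if not 3 <= max_down_position <= 8:
            raise ValueError("max_down_position must be in 3..8")
        base = cls.drug_f4()
        extra = tuple(
            main_term(f"down_{k}") for k in range(4, max_down_position + 1)
        )
        return cls(
            "drug_f5_extended", base.terms + extra, max_down_position
        )

    @classmethod
    def pan_f6(cls) -> "ModelSpec":
        """Pan-drug model: every f4 term plus a drug main effect and the
        drug x term interaction for each f4 term."""
        base = cls.drug_f4()
        terms = list(base.terms) + [main_term("drug")]
        terms += [
            t.crossed_with("drug", f"drug_x_{t.name}") for t in base.terms
        ]
        return cls("pan_f6", tuple(terms))

    def drop_term(self, name: str) -> "ModelSpec":
        if name not in self.term_names:
            raise KeyError(f"no term named {name!r}")
        return replace(
            self, terms=tuple(t for t in self.terms if t.name != name)
        )

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    @property
    def factor_columns(self) -> tuple[str, ...]:
        cols: list[str] = []
        for term in self.terms:
            for tup in term.factors:
                for col in tup:
                    if col not in cols:
                        cols.append(col)
        return tuple(cols)


def _reference_sort_key(level: str):
    # "absent" sorts last so it can never become the reference level
    return (level == "-", level)


class DesignBuilder:
    """Fits factor levels on training data, then builds design matrices."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.levels_: dict[str, list[str]] | None = None
        self.columns_: list[str] | None = None
        self.term_columns_: dict[str, list[str]] | None = None

    # -- fitting -----------------------------------------------------------
    def fit(self, features: pd.DataFrame) -> "DesignBuilder":
        levels = {}
        for col in self.spec.factor_columns:
            if col not in features.columns:
                raise KeyError(f"feature column {col!r} missing")
            observed = features[col].astype(str).unique().tolist()
            levels[col] = sorted(set(observed), key=_reference_sort_key)
            if len(levels[col]) < 2:
                logger.warning(
                    "factor %s has a single level %r; its columns are empty",
                    col,
                    levels[col][0],
                )
        if "drug" in levels and len(levels["drug"]) < 2:
            raise ValueError("pan-drug spec requires >= 2 drug levels")
        self.levels_ = levels
        self._build_column_index()
        return self

    def _build_column_index(self) -> None:
        columns = ["Intercept"]
        term_columns: dict[str, list[str]] = {}
        for term in self.spec.terms:
            names = []
            for tup in term.factors:
                for combo in product(
                    *[self.levels_[f][1:] for f in tup]
                ):
                    names.append(
                        ":".join(
                            f"{f}[{l}]" for f, l in zip(tup, combo)
                        )
                    )
            term_columns[term.name] = names
            columns.extend(names)
        self.columns_ = columns
        self.term_columns_ = term_columns

    # -- transforming ------------------------------------------------------
    def transform(
        self, features: pd.DataFrame, allow_unseen: bool = False
    ) -> pd.DataFrame:
        """Build the design matrix (with intercept) for ``features``.

        ``allow_unseen=True`` is the prediction-time policy: levels not
        seen at fit time are mapped to the reference level with a logged
        warning. At fit time they raise.
        """
        if self.levels_ is None:
            raise RuntimeError("builder not fitted")
        n = len(features)
        # per-factor one-hot (reference dropped), as {factor: (n, L-1)}
        onehot: dict[str, np.ndarray] = {}
        for col, levels in self.levels_.items():
            values = features[col].astype(str).to_numpy()
            index = {lvl: i for i, lvl in enumerate(levels)}
            codes = np.array([index.get(v, -1) for v in values])
            unseen = codes < 0
            if unseen.any():
                bad = sorted(set(values[unseen]))
                if not allow_unseen:
                    raise ValueError(
                        f"factor {col!r}: unseen level(s) {bad} at fit time"
                    )
                logger.warning(
                    "factor %s: unseen level(s) %s mapped to reference %r",
                    col,
                    bad,
                    levels[0],
                )
                codes[unseen] = 0
            mat = np.zeros((n, len(levels) - 1))
            nonref = codes > 0
            mat[np.nonzero(nonref)[0], codes[nonref] - 1] = 1.0
            onehot[col] = mat
        blocks = [np.ones((n, 1))]
        for term in self.spec.terms:
            for tup in term.factors:
                mats = [onehot[f] for f in tup]
                block = mats[0]
                for m in mats[1:]:
                    # pairwise level products, flattened in product() order
                    block = (block[:, :, None] * m[:, None, :]).reshape(
                        n, -1
                    )
                blocks.append(block)
        X = np.hstack(blocks)
        return pd.DataFrame(X, index=features.index, columns=self.columns_)

    def fit_transform(self, features: pd.DataFrame) -> pd.DataFrame:
        return self.fit(features).transform(features)

    def term_of_column(self, column: str) -> str:
        if column == "Intercept":
            return "Intercept"
        for name, cols in self.term_columns_.items():
            if column in cols:
                return name
        raise KeyError(column)


def build_design_matrix(
    features: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, DesignBuilder]:
    """Convenience wrapper: fit a builder and return (X, builder)."""
    builder = DesignBuilder(spec)
    X = builder.fit_transform(features)
    return X, builder
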