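"""Model-role declarations and dummy-coded design matrices.

Every estimation stage consumes the same explicit design construction: a
column is either numeric (used as-is) or categorical (expanded into
indicator columns against a declared reference level). No formula engine is
involved, so reference categories and column naming are fully deterministic
and shared between the simulator, the probit stage, the count stage and the
linear-IV diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ModelRoles", "DesignInfo", "build_design", "dummy_name"]


class DesignError(ValueError):
    """Raised when a design matrix cannot be built as declared."""


def dummy_name(column: str, level) -> str:
    return f"{column}[{level}]"


@dataclass
class DesignInfo:
    """Bookkeeping for a built design matrix.

    Attributes
    ----------
    matrix:
        DataFrame of float64 columns, first column ``const`` when an
        intercept was requested.
    term_columns:
        Mapping source column -> list of design-column names it produced
        (a single-element list for numeric columns).
    categorical_levels:
        Mapping categorical source column -> ordered list of all levels,
        reference first.
    """

    matrix: pd.DataFrame
    term_columns: dict[str, list[str]] = field(default_factory=dict)
    categorical_levels: dict[str, list] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class ModelRoles:
    """Declares which columns play which role in the two-equation model.

    ``excluded_instruments`` are the columns entering only the selection
    equation (the WASH availability dummies); ``exogenous`` are the controls
    entering both equations.  Categorical columns are expanded against the
    base level in ``reference_levels``.
    """

    outcome: str
    endogenous: str
    excluded_instruments: list[str]
    exogenous: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.excluded_instruments:
            raise DesignError("at least one excluded instrument is required")
        overlap = {self.endogenous} & (
            set(self.excluded_instruments) | set(self.exogenous)
        )
        if overlap:
            raise DesignError(
                f"endogenous column {self.endogenous!r} also declared "
                "as instrument or exogenous control"
            )
        both = set(self.excluded_instruments) & set(self.exogenous)
        if both:
            raise DesignError(f"columns in both roles: {sorted(both)}")

    def selection_columns(self) -> list[str]:
        """Covariates of the selection (first-stage) equation: W + X1."""
        return list(self.excluded_instruments) + list(self.exogenous)

    def outcome_columns(self) -> list[str]:
        """Exogenous covariates of the outcome equation (X1 only)."""
        return list(self.exogenous)


def _is_categorical(series: pd.Series, declared_ref: bool) -> bool:
    if declared_ref:
        return True
    return not pd.api.types.is_numeric_dtype(series) or isinstance(
        series.dtype, pd.CategoricalDtype
    )


def build_design(
    table: pd.DataFrame,
    columns: list[str],
    reference_levels: dict[str, str] | None = None,
    *,
    add_intercept: bool = True,
    require_full_rank: bool = False,
) -> DesignInfo:
    """Build a float design matrix from ``table``.

    Parameters
    ----------
    columns:
        Source columns in the order they should appear.
    reference_levels:
        Base level per categorical column; a column listed here is always
        treated as categorical.  Categoricals absent from the mapping use
        their first-sorted level as base.
    require_full_rank:
        When True, raise :class:`DesignError` naming collinear columns if
        the matrix is rank-deficient.
    """
    reference_levels = reference_levels or {}
    pieces: dict[str, np.ndarray] = {}
    term_columns: dict[str, list[str]] = {}
    categorical_levels: dict[str, list] = {}

    if add_intercept:
        pieces["const"] = np.ones(len(table))

    for col in columns:
        if col not in table.columns:
            raise DesignError(f"column {col!r} not found in table")
        series = table[col]
        if _is_categorical(series, col in reference_levels):
            observed = pd.unique(series.dropna())
            levels = sorted(observed, key=str)
            ref = reference_levels.get(col, levels[0] if levels else None)
            if ref not in levels:
                if ref is None or not levels:
                    raise DesignError(f"column {col!r} has no observed levels")
                # reference level may be legitimately absent from a subsample
                levels = [ref] + levels
            ordered = [ref] + [lv for lv in levels if lv != ref]
            categorical_levels[col] = ordered
            names = []
            for lv in ordered[1:]:
                name = dummy_name(col, lv)
                pieces[name] = (series == lv).to_numpy(dtype=float)
                names.append(name)
            term_columns[col] = names
        else:
            if series.isna().any():
                raise DesignError(f"numeric column {col!r} contains missing values")
            pieces[col] = series.to_numpy(dtype=float)
            term_columns[col] = [col]

    matrix = pd.DataFrame(pieces, index=table.index)
    if require_full_rank and matrix.shape[1] > 0:
        rank = np.linalg.matrix_rank(matrix.to_numpy())
        if rank < matrix.shape[1]:
            culprits = _collinear_columns(matrix.to_numpy(), matrix.columns)
            raise DesignError(f"design matrix is rank deficient; check {culprits}")
    return DesignInfo(matrix=matrix, term_columns=term_columns,
                      categorical_levels=categorical_levels)


def _collinear_columns(x: np.ndarray, names) -> list[str]:
    """Greedy scan naming columns that add no rank."""
    bad = []
    kept: list[int] = []
    for j in range(x.shape[1]):
        cand = kept + [j]
        if np.linalg.matrix_rank(x[:, cand]) < len(cand):
            bad.append(str(names[j]))
        else:
            kept.append(j)
    return bad


def check_unseen_levels(design_info: DesignInfo, table: pd.DataFrame) -> None:
    """Raise if ``table`` carries a categorical level the design never saw."""
    for col, levels in design_info.categorical_levels.items():
        extra = set(pd.unique(table[col].dropna())) - set(levels)
        if extra:
            raise DesignError(f"unseen level(s) {sorted(map(str, extra))} in {col!r}")
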