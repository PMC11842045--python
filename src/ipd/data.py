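"""Data ingestion: stacked / separate tables -> a validated StackedDataset.

The canonical in-memory container orders labeled rows first, then
unlabeled rows, preserving the original order within each block.  True
outcomes supplied on unlabeled rows (possible in simulations) are
retained but ignored by every estimator except the oracle benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import UsageError, ValidationError
from .formula import IPDFormula

logger = logging.getLogger(__name__)

_LABELED_TOKENS = {"1", "true", "labeled", "labelled"}
_UNLABELED_TOKENS = {"0", "false", "unlabeled", "unlabelled"}
# rows used only upstream (to train the prediction model) are dropped
_EXCLUDED_TOKENS = {"training", "train"}


@dataclass
class StackedDataset:
    """Labeled + unlabeled observations sharing predictions and features.

    ``outcome`` is NaN on unlabeled rows unless the source table carried
    true outcomes there (simulation oracle use only).  Labeled rows come
    first: indices ``[:n_labeled]`` are labeled, ``[n_labeled:]`` are not.
    """

    outcome: np.ndarray
    prediction: np.ndarray
    features: np.ndarray          # (n_labeled + n_unlabeled, n_features)
    feature_names: tuple[str, ...]
    n_labeled: int
    n_unlabeled: int

    def __post_init__(self):
        n = self.n_labeled + self.n_unlabeled
        if self.outcome.shape != (n,) or self.prediction.shape != (n,):
            raise ValidationError("outcome/prediction length mismatch with counts")
        if self.features.shape[0] != n:
            raise ValidationError("feature row count mismatch")
        if self.n_labeled < 1:
            raise ValidationError("at least one labeled observation is required")
        if not np.all(np.isfinite(self.prediction)):
            raise ValidationError("predictions must be finite on all rows")
        if not np.all(np.isfinite(self.outcome[: self.n_labeled])):
            raise ValidationError("outcome must be finite on every labeled row")

    # -- convenience accessors -------------------------------------------
    @property
    def set_indicator(self) -> np.ndarray:
        """1 on labeled rows, 0 on unlabeled rows."""
        ind = np.zeros(self.n_labeled + self.n_unlabeled, dtype=int)
        ind[: self.n_labeled] = 1
        return ind

    @property
    def y_labeled(self) -> np.ndarray:
        return self.outcome[: self.n_labeled]

    @property
    def f_labeled(self) -> np.ndarray:
        return self.prediction[: self.n_labeled]

    @property
    def f_unlabeled(self) -> np.ndarray:
        return self.prediction[self.n_labeled:]

    @property
    def y_unlabeled(self) -> np.ndarray:
        """True outcomes on unlabeled rows; NaN when genuinely unobserved."""
        return self.outcome[self.n_labeled:]

    def has_unlabeled_truth(self) -> bool:
        return self.n_unlabeled > 0 and bool(
            np.all(np.isfinite(self.outcome[self.n_labeled:]))
        )


@dataclass(frozen=True)
class DesignMatrix:
    values: np.ndarray
    column_names: tuple[str, ...]


def _classify_set_value(value) -> str:
    """Map a raw set-label value to 'labeled'/'unlabeled'/'excluded'."""
    if isinstance(value, (bool, np.bool_)):
        return "labeled" if value else "unlabeled"
    token = str(value).strip().lower()
    if token in {"1.0", "0.0"}:
        token = token[0]
    if token in _LABELED_TOKENS:
        return "labeled"
    if token in _UNLABELED_TOKENS:
        return "unlabeled"
    if token in _EXCLUDED_TOKENS:
        return "excluded"
    raise ValidationError(
        f"unrecognised set-label value {value!r}: expected 1/0, true/false, "
        "labeled/unlabeled (training rows are dropped automatically)"
    )


def _require_columns(table: pd.DataFrame, names, which: str) -> None:
    missing = [n for n in names if n not in table.columns]
    if missing:
        raise ValidationError(f"column(s) {missing} not found in {which} table")


def _numeric_block(table: pd.DataFrame, formula: IPDFormula, which: str,
                   require_outcome: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (outcome, prediction, features) arrays with NA policy applied."""
    cols = [formula.prediction_name, *formula.feature_names]
    _require_columns(table, cols, which)
    block = table[cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    if not np.all(np.isfinite(block)):
        bad = [c for c, ok in zip(
            cols, np.all(np.isfinite(block), axis=0)) if not ok]
        raise ValidationError(
            f"missing or non-numeric values in column(s) {bad} of the {which} "
            "table; rows are never silently dropped or imputed"
        )
    if formula.outcome_name in table.columns:
        y = pd.to_numeric(table[formula.outcome_name], errors="coerce").to_numpy(float)
    else:
        if require_outcome:
            raise ValidationError(
                f"outcome column {formula.outcome_name!r} not found in {which} table"
            )
        y = np.full(len(table), np.nan)
    if require_outcome and not np.all(np.isfinite(y)):
        raise ValidationError(
            f"missing outcome value(s) on labeled rows of the {which} table"
        )
    f = block[:, 0]
    X = block[:, 1:]
    return y, f, X


def assemble(
    data: pd.DataFrame,
    formula: IPDFormula,
    unlabeled_data: pd.DataFrame | None = None,
    label: str | None = None,
) -> StackedDataset:
    """Build a :class:`StackedDataset` from user tables.

    Exactly one of ``label`` (stacked mode: ``data`` holds all rows plus a
    set-indicator column) or ``unlabeled_data`` (separate mode: ``data``
    is the labeled table) must be given.  Columns not referenced by the
    formula or the label column are dropped.  In stacked mode rows whose
    set label marks the upstream training split are excluded with a
    logged count.
    """
    if (label is None) == (unlabeled_data is None):
        raise UsageError(
            "supply exactly one of 'label' (stacked mode) or "
            "'unlabeled_data' (separate mode)"
        )

    if label is not None:
        _require_columns(data, [label], "stacked")
        kinds = data[label].map(_classify_set_value)
        n_dropped = int((kinds == "excluded").sum())
        if n_dropped:
            logger.info("dropping %d training-split row(s) before assembly", n_dropped)
        labeled_tab = data.loc[kinds == "labeled"]
        unlabeled_tab = data.loc[kinds == "unlabeled"]
    else:
        labeled_tab = data
        unlabeled_tab = unlabeled_data

    if len(labeled_tab) == 0:
        raise ValidationError("no labeled rows after assembly")

    y_l, f_l, X_l = _numeric_block(labeled_tab, formula, "labeled", True)
    if len(unlabeled_tab) > 0:
        y_u, f_u, X_u = _numeric_block(unlabeled_tab, formula, "unlabeled", False)
    else:
        p = len(formula.feature_names)
        y_u, f_u, X_u = np.empty(0), np.empty(0), np.empty((0, p))

    return StackedDataset(
        outcome=np.concatenate([y_l, y_u]),
        prediction=np.concatenate([f_l, f_u]),
        features=np.vstack([X_l, X_u]),
        feature_names=formula.feature_names,
        n_labeled=len(labeled_tab),
        n_unlabeled=len(unlabeled_tab),
    )


def build_design(ds: StackedDataset, formula: IPDFormula,
                 subset: str = "all") -> DesignMatrix:
    """Design matrix for a subset of rows: intercept column first, then
    features in formula order."""
    if subset == "labeled":
        X = ds.features[: ds.n_labeled]
    elif subset == "unlabeled":
        X = ds.features[ds.n_labeled:]
    elif subset == "all":
        X = ds.features
    else:
        raise UsageError(f"subset must be labeled/unlabeled/all, got {subset!r}")
    if X.shape[0] == 0:
        raise ValidationError(f"subset {subset!r} contains no rows")
    missing = [n for n in formula.feature_names if n not in ds.feature_names]
    if missing:
        raise ValidationError(f"feature(s) {missing} not present in the dataset")
    idx = [ds.feature_names.index(n) for n in formula.feature_names]
    X = X[:, idx]
    names = list(formula.feature_names)
    if formula.intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["(Intercept)", *names]
    return DesignMatrix(values=X, column_names=tuple(names))


def read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV with a header row; delimiter inferred from the
    extension (.tsv/.tab -> tab) unless given explicitly."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=delimiter)
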