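"""Model-formula parsing for inference on predicted data.

A formula names the observed outcome, its machine prediction, and the
features of interest, in the form::

    Y - f ~ X1 + X2 + X3

The left-hand side is always ``<outcome> - <prediction>``.  The
right-hand side is a ``+``-separated list of numeric feature columns, or
the literal ``1`` for an intercept-only model (mean and quantile
estimands).  ``=`` is accepted in place of ``~`` and the unicode minus
sign is normalised, so formulas copied from typeset text parse as-is.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._exceptions import FormulaError

_IDENT = re.compile(r"^[A-Za-z_.][A-Za-z0-9_.]*$")

# unicode minus / dashes occasionally produced by typesetting
_DASHES = {"−": "-", "–": "-", "—": "-"}


@dataclass(frozen=True)
class IPDFormula:
    """Parsed ``Y - f ~ X...`` specification.

    Attributes
    ----------
    outcome_name : str
        Column holding the observed outcome (missing on unlabeled rows).
    prediction_name : str
        Column holding the machine-generated prediction, present on all rows.
    feature_names : tuple of str
        Ordered features; empty for intercept-only (mean/quantile) models.
    intercept : bool
        Whether design matrices carry a leading column of ones.
    """

    outcome_name: str
    prediction_name: str
    feature_names: tuple[str, ...] = ()
    intercept: bool = True

    def __post_init__(self):
        if self.outcome_name == self.prediction_name:
            raise FormulaError(
                f"outcome and prediction must differ (both {self.outcome_name!r})"
            )
        names = (self.outcome_name, self.prediction_name, *self.feature_names)
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise FormulaError(f"duplicate name(s) in formula: {sorted(dupes)}")

    def render(self) -> str:
        rhs = " + ".join(self.feature_names) if self.feature_names else "1"
        return f"{self.outcome_name} - {self.prediction_name} ~ {rhs}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.render()


def _check_ident(token: str, context: str) -> str:
    if not _IDENT.match(token):
        raise FormulaError(f"invalid name {token!r} in {context}")
    return token


def parse_formula(spec: str) -> IPDFormula:
    """Parse a formula string into an :class:`IPDFormula`.

    Parameters
    ----------
    spec : str
        A string of the form ``"Y - f ~ X1 + X2"``.  ``=`` may replace
        ``~``; ``"Y - f ~ 1"`` requests an intercept-only model.

    Raises
    ------
    FormulaError
        If the left-hand side is not exactly ``<name> - <name>``, a name
        is not a valid identifier, or a feature is duplicated.
    """
    if not isinstance(spec, str):
        raise FormulaError(f"formula must be a string, got {type(spec).__name__}")
    s = spec
    for bad, good in _DASHES.items():
        s = s.replace(bad, good)

    # split into LHS / RHS on '~' (preferred) or a single '=' separator
    if "~" in s:
        lhs, _, rhs = s.partition("~")
    elif "=" in s:
        lhs, _, rhs = s.partition("=")
    else:
        raise FormulaError(
            f"formula {spec!r} has no '~' (or '=') separating outcome from features"
        )
    if "~" in rhs or "=" in rhs:
        raise FormulaError(f"formula {spec!r} has more than one separator")

    lhs_parts = [p.strip() for p in lhs.split("-")]
    if len(lhs_parts) != 2 or not all(lhs_parts):
        raise FormulaError(
            f"left-hand side {lhs.strip()!r} must be '<outcome> - <prediction>' "
            "(exactly two names joined by '-')"
        )
    outcome = _check_ident(lhs_parts[0], "left-hand side")
    prediction = _check_ident(lhs_parts[1], "left-hand side")

    rhs_parts = [p.strip() for p in rhs.split("+")]
    if any(not p for p in rhs_parts):
        raise FormulaError(f"empty term in right-hand side {rhs.strip()!r}")
    if rhs_parts == ["1"]:
        features: tuple[str, ...] = ()
    else:
        features = tuple(_check_ident(p, "right-hand side") for p in rhs_parts)

    return IPDFormula(outcome, prediction, features)
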