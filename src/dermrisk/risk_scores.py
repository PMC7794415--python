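"""Composite risk scores: family history, grouped scores, DRS and DRSA.

Every score is a weighted sum of factor responses, the weights being the
fitted coefficients of the per-cancer 32-factor binomial GLM.  The DRS
uses all factors; the DRSA drops the age polynomial block while keeping
the same weights for everything else, which makes it (approximately) age
independent.  Scores deliberately omit the model intercept: they are only
ever used through ranks, percentile bins, and z-scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_build import FactorMatrix, RiskModel

#: canonical grouped-score names, in reporting order
SCORE_GROUPS = ("Demographic", "Family", "Mole", "Susceptibility",
                "Exposure", "Miscellaneous", "PRS")


def family_history_score(father, mother, any_sibling, any_child):
    """Simple 0-3 family-history score.

    One point each for an affected father, mother, at least one sibling,
    and at least one child (any skin-cancer type); the rare raw values 3
    and 4 are collapsed into a single top category 3.  Inputs must be
    binary and complete — missing indicators are an error here and must be
    handled by the upstream imputation policy, never silently zeroed.
    """
    arrs = [np.asarray(a, dtype=float) for a in
            (father, mother, any_sibling, any_child)]
    for a in arrs:
        if np.isnan(a).any():
            raise ValueError("family-history indicators contain missing "
                             "values; impute upstream first")
        if not np.isin(a, (0.0, 1.0)).all():
            raise ValueError("family-history indicators must be binary")
    raw = sum(arrs)
    return np.minimum(raw, 3.0)


def compute_score(design: FactorMatrix, model: RiskModel,
                  include: Sequence[str]) -> np.ndarray:
    """Weighted factor-response sum over ``include`` (no intercept).

    ``include`` must be a subset of the model's factors; an empty subset
    yields all-zero scores.
    """
    include = list(include)
    unknown = [f for f in include if f not in model.factor_columns]
    if unknown:
        raise KeyError(f"factors not in model: {unknown}")
    if not include:
        return np.zeros(len(design.X))
    cols = []
    for f in include:
        cols.extend(model.factor_columns[f])
    return design.X[cols].to_numpy(dtype=float) @ \
        model.coef[cols].to_numpy()


@dataclass
class ScoreSet:
    """Per-participant scores for one cancer: DRS, DRSA, PRS, groups."""

    cancer: str
    scores: pd.DataFrame          # columns: DRS, DRSA, PRS?, group scores
    standardization: dict         # score name -> (mean, sd) if z-scored

    def to_long(self) -> pd.DataFrame:
        recs = []
        for name in self.scores.columns:
            for pid, val in self.scores[name].items():
                recs.append({"participant": pid, "cancer": self.cancer,
                             "score_name": name, "value": val})
        return pd.DataFrame(recs)


def compute_score_set(design: FactorMatrix, model: RiskModel,
                      age_factor: str = "age") -> ScoreSet:
    """All composite scores for one fitted cancer model.

    Grouped scores follow the factor -> group labels carried on the
    model; DRS sums every factor, DRSA everything except the age block
    (sex and ancestry stay in).  When the groups partition the factors,
    the grouped scores plus the age block sum to the DRS exactly.
    """
    factors = list(model.factor_columns)
    scores = {}
    scores["DRS"] = compute_score(design, model, factors)
    drsa_factors = [f for f in factors if f != age_factor]
    scores["DRSA"] = compute_score(design, model, drsa_factors)
    for grp in SCORE_GROUPS:
        members = [f for f in factors
                   if model.groups.get(f) == grp and f != age_factor]
        if members:
            scores[grp] = compute_score(design, model, members)
    return ScoreSet(cancer=model.cancer,
                    scores=pd.DataFrame(scores, index=design.X.index),
                    standardization={})


def standardize(score, reference=None):
    """Z-scale ``score`` against ``reference`` (default: itself).

    Returns ``(z, mean, sd)``; the reference defaults to the training-set
    scores so validation scores share the training scale.  A zero-variance
    reference is an error.
    """
    score = np.asarray(score, dtype=float)
    ref = score if reference is None else np.asarray(reference, dtype=float)
    mean = float(ref.mean())
    sd = float(ref.std())
    if sd == 0:
        raise ValueError("reference score has zero variance")
    return (score - mean) / sd, mean, sd


def validate_group_map(groups: dict,
                       expected_sizes: Optional[dict] = None) -> None:
    """Check each factor maps to a known group, optionally with the
    expected per-group factor counts (e.g. Mole 4, Susceptibility 8,
    Exposure 8, Miscellaneous 7)."""
    known = set(SCORE_GROUPS) | {"Age"}
    bad = {f: g for f, g in groups.items() if g not in known}
    if bad:
        raise ValueError(f"factors with unknown groups: {bad}")
    if expected_sizes:
        counts = pd.Series(list(groups.values())).value_counts()
        for grp, size in expected_sizes.items():
            if counts.get(grp, 0) != size:
                raise ValueError(
                    f"group {grp!r} has {counts.get(grp, 0)} factors, "
                    f"expected {size}")
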