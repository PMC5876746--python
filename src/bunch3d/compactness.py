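"""Candidate bunch-compactness factors and their rank correlation with
visual OIV 204 classes.

OIV 204 scores bunch compactness on five classes (1 = very loose … 9 = very
dense).  Quantitative factors are arithmetic combinations of the exported
bunch traits; because the exact published factor formulas are not fixed,
factors live in a configurable registry of named expressions over the trait
fields.  The shipped defaults are plausible interpretations (volume per
projected extent, volume per length, packing ratios), not authoritative
definitions — replace them via a plain-text config when the true formulas
are known.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .traits import BunchTraits

__all__ = ["FactorDefinition", "FactorEvaluationError", "DEFAULT_FACTORS",
           "evaluate_factor", "spearman_rank_correlation",
           "load_factor_config", "correlate_factors"]

_TRAIT_FIELDS = ("n_berries", "mean_diameter", "mean_volume", "total_volume",
                 "convex_hull_volume", "width", "length")
_TOKEN_RE = re.compile(r"[A-Za-z_][A-Za-z_0-9]*")


class FactorEvaluationError(ValueError):
    """A factor expression could not be evaluated on the given traits."""


@dataclass(frozen=True)
class FactorDefinition:
    """A named arithmetic expression over the BunchTraits field names."""

    name: str
    expression: str
    description: str = ""

    def __post_init__(self) -> None:
        for tok in _TOKEN_RE.findall(self.expression):
            if tok not in _TRAIT_FIELDS:
                raise ValueError(
                    f"factor {self.name!r}: unknown name {tok!r}; allowed: {_TRAIT_FIELDS}")


# Interpretation defaults, not authoritative formulas (see module docstring).
# Factor A (a published external definition) is intentionally absent: supply
# it through the config file if needed.
DEFAULT_FACTORS = [
    FactorDefinition("B", "total_volume / (length * width)",
                     "berry volume per projected bunch extent [mL/mm^2]"),
    FactorDefinition("C", "total_volume / length",
                     "berry volume per bunch length [mL/mm]"),
    FactorDefinition("D", "total_volume / convex_hull_volume",
                     "fill fraction of the convex hull [-]"),
    FactorDefinition("E", "convex_hull_volume / (length * width)",
                     "hull volume per projected bunch extent [mL/mm^2]"),
]


def evaluate_factor(definition: FactorDefinition, traits: BunchTraits) -> float:
    """Evaluate a factor expression on one bunch's traits.

    Raises :class:`FactorEvaluationError` naming the factor when a
    denominator is zero or the result is non-finite.
    """
    env = {f: float(getattr(traits, f)) for f in _TRAIT_FIELDS}
    try:
        value = eval(definition.expression, {"__builtins__": {}}, env)  # noqa: S307
    except ZeroDivisionError:
        raise FactorEvaluationError(
            f"factor {definition.name!r}: division by zero on these traits") from None
    except Exception as exc:
        raise FactorEvaluationError(f"factor {definition.name!r}: {exc}") from exc
    value = float(value)
    if not np.isfinite(value):
        raise FactorEvaluationError(f"factor {definition.name!r}: non-finite value")
    return value


def spearman_rank_correlation(values, classes) -> float:
    """Spearman's rho between factor values and ordinal classes.

    Ties are handled by average ranks (essential: OIV classes take only
    five levels).  Raises ``ValueError`` for constant inputs, where the
    correlation is undefined.
    """
    values = np.asarray(values, dtype=np.float64)
    classes = np.asarray(classes, dtype=np.float64)
    if values.shape != classes.shape or values.ndim != 1:
        raise ValueError("values and classes must be equal-length 1-D sequences")
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(values) == 0 or np.ptp(classes) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    rho = stats.spearmanr(values, classes).statistic
    return float(rho)


def load_factor_config(path) -> list[FactorDefinition]:
    """Read ``name = expression`` lines (# comments allowed) into definitions."""
    factors = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'name = expression'")
        name, expr = (s.strip() for s in line.split("=", 1))
        factors.append(FactorDefinition(name, expr))
    return factors


def correlate_factors(traits_table: pd.DataFrame, ratings: pd.DataFrame,
                      factors: list[FactorDefinition] | None = None) -> pd.DataFrame:
    """Per-factor Spearman rho against OIV 204 ratings.

    ``traits_table`` holds one row per scan with the trait columns and a
    ``scan_id`` column; ``ratings`` holds ``scan_id`` and ``oiv204_class``
    (values in {1, 3, 5, 7, 9}).  Returns a DataFrame (factor, rho, n) over
    the scans present in both tables.
    """
    if factors is None:
        factors = DEFAULT_FACTORS
    bad = set(ratings["oiv204_class"]) - {1, 3, 5, 7, 9}
    if bad:
        raise ValueError(f"invalid OIV 204 classes: {sorted(bad)} (allowed: 1,3,5,7,9)")
    merged = traits_table.merge(ratings, on="scan_id", how="inner")
    rename = {"mean_diameter_mm": "mean_diameter", "mean_volume_mL": "mean_volume",
              "total_volume_mL": "total_volume", "convex_hull_mL": "convex_hull_volume",
              "width_mm": "width", "length_mm": "length"}
    merged = merged.rename(columns=rename)
    rows = []
    for factor in factors:
        vals = [evaluate_factor(factor, BunchTraits(
            n_berries=int(r.n_berries), mean_diameter=r.mean_diameter,
            mean_volume=r.mean_volume, total_volume=r.total_volume,
            convex_hull_volume=r.convex_hull_volume, width=r.width, length=r.length))
            for r in merged.itertuples()]
        rho = spearman_rank_correlation(vals, merged["oiv204_class"].to_numpy())
        rows.append({"factor": factor.name, "rho": rho, "n": len(vals)})
    return pd.DataFrame(rows)
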