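"""Parent-offspring regression estimates of narrow-sense heritability.

Midparent regression: each offspring's trait is regressed on its family's
parental midpoint (mean of dam and sire traits); the OLS slope is h2.
Single-parent regression (maternal designs): offspring trait on dam trait;
h2 is twice the slope, because one parent transmits half the additive
variation.  Estimates outside [0, 1] are reported raw with a warning
rather than silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RegressionResult",
    "RegressionError",
    "midparent_regression",
    "single_parent_regression",
]


class RegressionError(ValueError):
    pass


@dataclass
class RegressionResult:
    mode: str  # "midparent" | "single_parent"
    slope: float
    intercept: float
    se_slope: float
    n: int
    h2: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "slope": self.slope,
            "se_slope": self.se_slope,
            "intercept": self.intercept,
            "n": self.n,
            "h2": self.h2,
            "warnings": self.warnings,
        }


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if np.var(x) == 0:
        raise RegressionError("zero variance in the predictor (parental) trait values")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.stderr)


def _flag_range(h2: float, warnings_out: list[str]) -> None:
    if not 0.0 <= h2 <= 1.0:
        warnings_out.append(
            f"h2 estimate {h2:.4g} outside [0, 1]; raw value retained"
        )


def midparent_regression(
    offspring: Sequence[tuple[str, float]],
    parent_traits: Mapping[str, tuple[float, float]],
    family_means: bool = False,
) -> RegressionResult:
    """OLS of offspring trait on family midparent trait; h2 = slope.

    ``offspring`` holds (family_id, trait) records, one per offspring
    individual; ``parent_traits`` maps family_id to (dam, sire) trait
    values.  With ``family_means=True`` offspring are first averaged per
    family (one regression point per family).
    """
    families = sorted({fam for fam, _ in offspring})
    if len(families) < 3:
        raise RegressionError("need at least 3 families")
    missing = [f for f in families if f not in parent_traits]
    if missing:
        raise RegressionError(f"families without parental traits: {missing}")
    midparent = {f: 0.5 * (parent_traits[f][0] + parent_traits[f][1]) for f in families}
    if family_means:
        x = np.array([midparent[f] for f in families])
        y = np.array(
            [np.mean([t for fam, t in offspring if fam == f]) for f in families]
        )
    else:
        x = np.array([midparent[fam] for fam, _ in offspring])
        y = np.array([t for _, t in offspring])
    slope, intercept, se = _ols(x, y)
    h2 = slope
    warn: list[str] = []
    _flag_range(h2, warn)
    return RegressionResult("midparent", slope, intercept, se, len(x), h2, warn)


def single_parent_regression(
    offspring: Sequence[tuple[str, float]],
    dam_traits: Mapping[str, float],
) -> RegressionResult:
    """OLS of offspring trait on dam trait; h2 = 2 x slope."""
    dams = sorted({dam for dam, _ in offspring})
    if len(dams) < 3:
        raise RegressionError("need at least 3 dams")
    missing = [d for d in dams if d not in dam_traits]
    if missing:
        raise RegressionError(f"dams without trait values: {missing}")
    x = np.array([dam_traits[dam] for dam, _ in offspring])
    y = np.array([t for _, t in offspring])
    slope, intercept, se = _ols(x, y)
    h2 = 2.0 * slope
    warn: list[str] = []
    _flag_range(h2, warn)
    return RegressionResult("single_parent", slope, intercept, se, len(x), h2, warn)
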