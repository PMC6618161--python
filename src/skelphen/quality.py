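"""Bone-quality scoring against a wild-type reference regression.

Each biomechanical parameter is regressed on bone mineral content (BMC) in
a reference cohort; a mutant group's quality score for that parameter is
the gap between its observed group mean and the value predicted at its
group-mean BMC, expressed in units of the reference residual SD.  Scores
beyond +/-2 SD are flagged as outside the reference band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from skelphen.synthetic import BIOMECH_PARAMETERS

__all__ = [
    "ParamFit",
    "ReferenceModel",
    "QualityScore",
    "fit_reference",
    "quality_score",
    "per_specimen_scores",
    "quality_report",
    "regression_band",
]

OUTLIER_SD = 2.0


@dataclass(frozen=True)
class ParamFit:
    """OLS fit of one biomechanical parameter on BMC."""

    parameter: str
    slope: float
    intercept: float
    residual_sd: float  # sd of OLS residuals with n-2 denominator
    n: int
    p_value: float  # two-sided t-test on the slope
    degenerate: bool = False  # exact fit: residual_sd == 0, p-value unreliable

    def predict(self, bmc) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(bmc, dtype=float)


@dataclass(frozen=True)
class ReferenceModel:
    fits: Mapping[str, ParamFit]
    n: int
    sex: Optional[str] = None

    def to_json(self, path: Optional[Path] = None) -> str:
        payload = {
            "n": self.n,
            "sex": self.sex,
            "fits": {
                name: {
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "residual_sd": f.residual_sd,
                    "n": f.n,
                    "p_value": f.p_value,
                    "degenerate": f.degenerate,
                }
                for name, f in self.fits.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ReferenceModel":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and Path(source).exists()):
            source = Path(source).read_text()
        payload = json.loads(source)
        fits = {
            name: ParamFit(parameter=name, **f) for name, f in payload["fits"].items()
        }
        return cls(fits=fits, n=payload["n"], sex=payload.get("sex"))


@dataclass(frozen=True)
class QualityScore:
    parameter: str
    observed_mean: float
    predicted: float
    score: float  # (observed - predicted) / residual_sd
    flagged: bool  # |score| > 2
    group_mean_bmc: float
    n: int

    def __post_init__(self) -> None:
        if self.flagged != (abs(self.score) > OUTLIER_SD):
            raise ValueError("flag inconsistent with score")


def _check_cohort(cohort: pd.DataFrame, parameters: Sequence[str]) -> None:
    if "bmc" not in cohort.columns:
        raise ValueError("cohort must have a 'bmc' column")
    missing = [p for p in parameters if p not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing parameter columns: {missing}")
    cols = ["bmc", *parameters]
    if cohort[cols].isna().any().any() or not np.isfinite(cohort[cols].to_numpy()).all():
        raise ValueError("cohort contains missing or non-finite values")


def fit_reference(
    cohort: pd.DataFrame,
    parameters: Sequence[str] = BIOMECH_PARAMETERS,
    allow_mixed_sex: bool = False,
) -> ReferenceModel:
    """Fit per-parameter OLS regressions of parameter on BMC.

    The reference is sex-matched: a cohort with more than one sex is
    refused unless ``allow_mixed_sex`` is set.  The residual SD uses the
    n-2 denominator; an exact fit (residual_sd == 0) is flagged degenerate
    because the slope p-value is then meaningless.
    """
    _check_cohort(cohort, parameters)
    n = len(cohort)
    if n < 3:
        raise ValueError(f"regression needs >= 3 specimens, got {n}")
    sex: Optional[str] = None
    if "sex" in cohort.columns:
        sexes = set(cohort["sex"].astype(str))
        if len(sexes) > 1 and not allow_mixed_sex:
            raise ValueError(
                f"cohort mixes sexes {sorted(sexes)}; the reference is sex-matched "
                "(pass allow_mixed_sex=True to override)"
            )
        sex = sexes.pop() if len(sexes) == 1 else "mixed"
    bmc = cohort["bmc"].to_numpy(dtype=float)
    if np.var(bmc) == 0:
        raise ValueError("BMC variance is zero: regression undefined")

    fits = {}
    for name in parameters:
        y = cohort[name].to_numpy(dtype=float)
        res = sps.linregress(bmc, y)
        residuals = y - (res.intercept + res.slope * bmc)
        residual_sd = float(np.sqrt(np.sum(residuals**2) / (n - 2)))
        degenerate = residual_sd == 0.0
        fits[name] = ParamFit(
            parameter=name,
            slope=float(res.slope),
            intercept=float(res.intercept),
            residual_sd=residual_sd,
            n=n,
            p_value=float(res.pvalue) if not degenerate else float("nan"),
            degenerate=degenerate,
        )
    return ReferenceModel(fits=fits, n=n, sex=sex)


def quality_score(model: ReferenceModel, group: pd.DataFrame) -> dict[str, QualityScore]:
    """Score a group against the reference model, one score per parameter.

    The score compares the observed group mean with the regression
    prediction at the group-mean BMC, in residual-SD units; |score| > 2
    is flagged as outside the reference band.
    """
    parameters = list(model.fits)
    _check_cohort(group, parameters)
    if len(group) == 0:
        raise ValueError("group is empty")
    mean_bmc = float(group["bmc"].mean())
    out = {}
    for name, fit in model.fits.items():
        if fit.residual_sd == 0:
            raise ValueError(f"residual_sd is 0 for {name!r}: score undefined")
        observed = float(group[name].mean())
        predicted = float(fit.predict(mean_bmc))
        score = (observed - predicted) / fit.residual_sd
        out[name] = QualityScore(
            parameter=name,
            observed_mean=observed,
            predicted=predicted,
            score=score,
            flagged=abs(score) > OUTLIER_SD,
            group_mean_bmc=mean_bmc,
            n=len(group),
        )
    return out


def per_specimen_scores(model: ReferenceModel, group: pd.DataFrame) -> pd.DataFrame:
    """Diagnostic per-specimen residual-SD scores (one column per parameter)."""
    parameters = list(model.fits)
    _check_cohort(group, parameters)
    out = pd.DataFrame(index=group.index)
    if "specimen_id" in group.columns:
        out["specimen_id"] = group["specimen_id"]
    for name, fit in model.fits.items():
        if fit.residual_sd == 0:
            raise ValueError(f"residual_sd is 0 for {name!r}: score undefined")
        out[name] = (
            group[name].to_numpy(dtype=float) - fit.predict(group["bmc"])
        ) / fit.residual_sd
    return out


def quality_report(
    model: ReferenceModel, groups: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-group, per-parameter score table, ordered as the groups mapping."""
    rows = []
    for group_name, table in groups.items():
        scores = quality_score(model, table)
        for name, s in scores.items():
            rows.append(
                {
                    "group": group_name,
                    "parameter": name,
                    "n": s.n,
                    "group_mean_bmc": s.group_mean_bmc,
                    "observed_mean": s.observed_mean,
                    "predicted": s.predicted,
                    "score_sd": s.score,
                    "outside_2sd": s.flagged,
                }
            )
    columns = [
        "group", "parameter", "n", "group_mean_bmc",
        "observed_mean", "predicted", "score_sd", "outside_2sd",
    ]
    return pd.DataFrame(rows, columns=columns)


def regression_band(
    model: ReferenceModel, parameter: str, bmc_grid: Sequence[float]
) -> pd.DataFrame:
    """Regression line and constant +/-2 residual-SD band for plotting."""
    fit = model.fits[parameter]
    grid = np.asarray(bmc_grid, dtype=float)
    line = fit.predict(grid)
    return pd.DataFrame(
        {
            "bmc": grid,
            "line": line,
            "band_lo": line - OUTLIER_SD * fit.residual_sd,
            "band_hi": line + OUTLIER_SD * fit.residual_sd,
        }
    )
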