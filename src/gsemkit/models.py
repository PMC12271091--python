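"""Prebuilt latent-factor models for the impulsivity / substance-use /
anorexia analysis, and the replication workflow that fits them to a
supplied (S, V) pair.

Default trait labels:

====================  =======================================
label                 trait
====================  =======================================
NU / PU               UPPS-P negative / positive urgency
PREMED                UPPS-P (lack of) premeditation
ATT / MOTOR / NONPLAN BIS attentional / motor / non-planning
PERSEV                lack of perseverance
SS                    sensation seeking
DD                    delay discounting (higher = steeper)
PAU / CUD / OUD / TUD substance-use-disorder traits
AN                    anorexia nervosa
====================  =======================================

Latent factors: CI (common impulsivity over the six UPPS-P/BIS
indicators), URG (urgency-specific, over NU and PU, fixed to be
uncorrelated with CI), SUDF (single factor over the four SUD traits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fit import fit_dwls, fit_indices, standardize_solution
from .ldsc import SVMatrices
from .model import ModelSpec, parse_model

__all__ = ["PaperModelConfig", "correlated_factors_model", "regression_model",
           "replicate", "REFERENCE_RESULTS"]

#: published point estimates the replication report compares against
REFERENCE_RESULTS = {
    "correlated": {
        "chisq": 1035.32,
        "cfi": 0.940,
        "srmr": 0.074,
        "AN~~DD": -0.19,
        "AN~~PERSEV": -0.15,
        "AN~~SUDF": 0.07,
        "AN~~CI": -0.07,
        "AN~~URG": 0.14,
        "AN~~SS": -0.07,
    },
    "regression": {
        "AN~DD": -0.32,
        "AN~PERSEV": -0.25,
        "AN~CI": 0.14,
        "AN~URG": 0.01,
        "AN~SS": -0.14,
    },
}


@dataclass
class PaperModelConfig:
    """Indicator/outcome layout of the two study models."""

    common_impulsivity_indicators: list[str] = field(
        default_factory=lambda: ["NU", "PU", "PREMED", "ATT", "MOTOR", "NONPLAN"])
    urgency_indicators: list[str] = field(default_factory=lambda: ["NU", "PU"])
    sud_indicators: list[str] = field(
        default_factory=lambda: ["PAU", "CUD", "OUD", "TUD"])
    singles: list[str] = field(default_factory=lambda: ["DD", "SS", "PERSEV"])
    outcome: str = "AN"
    common_factor: str = "CI"
    urgency_factor: str = "URG"
    sud_factor: str = "SUDF"

    def __post_init__(self) -> None:
        if not set(self.urgency_indicators) <= set(self.common_impulsivity_indicators):
            raise ValueError("urgency indicators must be a subset of the "
                             "common-impulsivity indicators")
        indicators = (self.common_impulsivity_indicators + self.sud_indicators
                      + self.singles)
        if self.outcome in indicators:
            raise ValueError(f"outcome {self.outcome!r} may not also be an indicator")

    @property
    def entities(self) -> list[str]:
        """Factors and single indicators that covary freely (minus the one
        fixed-zero pair)."""
        return ([self.common_factor, self.urgency_factor, self.sud_factor]
                + self.singles)

    @property
    def observed(self) -> list[str]:
        return (self.common_impulsivity_indicators + self.sud_indicators
                + self.singles + [self.outcome])

    def check_traits(self, available: list[str]) -> None:
        missing = [t for t in self.observed if t not in available]
        if missing:
            raise ValueError(f"indicator(s) absent from available traits: {missing}")


def _measurement_lines(config: PaperModelConfig) -> list[str]:
    # A two-indicator orthogonal factor is only identified with its
    # loadings constrained equal (shared label), so the urgency loadings
    # share one parameter; the implied chi-square df (60 for the default
    # 14-trait layout) matches the published test statistic's p-value.
    urg = " + ".join(f"u_load*{v}" for v in config.urgency_indicators)
    return [
        f"{config.common_factor} =~ " + " + ".join(config.common_impulsivity_indicators),
        f"{config.urgency_factor} =~ {urg}",
        f"{config.sud_factor} =~ " + " + ".join(config.sud_indicators),
        f"{config.urgency_factor} ~~ 0*{config.common_factor}",
    ]


def correlated_factors_model(config: PaperModelConfig | None = None,
                             include_outcome: bool = True) -> ModelSpec:
    """Correlated-factor model: CI / orthogonal URG / SUDF factors plus the
    single indicators and the outcome, all freely inter-correlated except
    the single fixed-zero CI-URG covariance."""
    config = config or PaperModelConfig()
    lines = _measurement_lines(config)
    entities = config.entities + ([config.outcome] if include_outcome else [])
    for j, b in enumerate(entities):
        for a_ent in entities[j + 1:]:
            if {a_ent, b} == {config.common_factor, config.urgency_factor}:
                continue  # already fixed at 0
            lines.append(f"{a_ent} ~~ {b}")
    return parse_model("\n".join(lines))


def regression_model(config: PaperModelConfig | None = None) -> ModelSpec:
    """As the correlated-factor model, but the outcome is regressed on the
    two impulsivity factors, the SUD factor and the single indicators; its
    residual variance stays free."""
    config = config or PaperModelConfig()
    lines = _measurement_lines(config)
    predictors = config.entities
    for j, b in enumerate(predictors):
        for a_ent in predictors[j + 1:]:
            if {a_ent, b} == {config.common_factor, config.urgency_factor}:
                continue
            lines.append(f"{a_ent} ~~ {b}")
    lines.append(f"{config.outcome} ~ " + " + ".join(predictors))
    return parse_model("\n".join(lines))


def replicate(
    sv: SVMatrices,
    config: PaperModelConfig | None = None,
    rename: dict[str, str] | None = None,
    chisq_kind: str = "mean_corrected",
    seed: int = 0,
) -> dict:
    """Fit both study models to (S, V) and report standardized estimates,
    fit indices, and a side-by-side comparison with the published values.

    ``rename`` maps the trait labels used in ``sv`` onto the canonical
    labels of ``config``.
    """
    config = config or PaperModelConfig()
    if rename:
        sv = SVMatrices([rename.get(t, t) for t in sv.traits], sv.S, sv.V,
                        sv.smoothed, sv.n_blocks, sv.intercepts)
    config.check_traits(sv.traits)
    sv = sv.smooth()

    report: dict = {"traits": list(sv.traits), "models": {}}
    specs = {
        "correlated": correlated_factors_model(config),
        "regression": regression_model(config),
    }
    for name, spec in specs.items():
        res = fit_dwls(sv, spec, chisq_kind=chisq_kind, seed=seed)
        idx = fit_indices(res, sv, spec)
        std = standardize_solution(res, spec)
        entry = {
            "converged": res.converged,
            "chisq": res.chisq,
            "df": res.df,
            "chisq_p": res.chisq_p,
            "cfi": idx.cfi,
            "srmr": idx.srmr,
            "aic": idx.aic,
            "good_fit": idx.cfi > 0.95 and idx.srmr < 0.08,
            "acceptable_fit": idx.cfi >= 0.90 and idx.srmr < 0.08,
            "estimates_standardized": std.estimates,
            "se_standardized": std.se,
            "pvalues": std.pvalues,
            "reference_comparison": _compare(name, res, idx, std),
        }
        report["models"][name] = entry

    dd_cov = report["models"]["correlated"]["estimates_standardized"].get(
        f"{config.outcome}~~DD")
    report["outcome_dd_negative"] = bool(dd_cov is not None and dd_cov < 0)
    return report


def _compare(model_name: str, res, idx, std) -> list[dict]:
    ref = REFERENCE_RESULTS.get(model_name, {})
    fitted = {"chisq": res.chisq, "cfi": idx.cfi, "srmr": idx.srmr}
    rows = []
    for key, ref_val in ref.items():
        if key in fitted:
            val = fitted[key]
        else:
            val = std.estimates.get(key, std.estimates.get(_swap(key)))
        if val is None:
            continue
        rows.append({"quantity": key, "reference": ref_val,
                     "fitted": float(val),
                     "abs_diff": float(abs(val - ref_val))})
    return rows


def _swap(key: str) -> str:
    if "~~" in key:
        a, b = key.split("~~")
        return f"{b}~~{a}"
    return key
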