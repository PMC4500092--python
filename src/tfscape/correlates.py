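"""Regression of structural summary features against binding energy.

Features (e.g. interface hydrogen-bond counts or 4.5 Å contact-pair
counts, averaged over simulation replicates) are regressed on mean
ΔG_dissociation either globally over all 128 complexes or separately
within each protein's 16 REs.  Each regression is classified positive
(slope > 0, p < α), negative (slope < 0, p < α) or NS.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import linregress

from .genotype_space import enumerate_re_genotypes
from .pathways import as_landscape

__all__ = ["CorrelationResult", "regress_feature"]


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    group: str  # "global" or a protein label
    slope: float
    intercept: float
    p_value: float
    r2: float
    classification: str  # "positive" | "negative" | "NS"
    zero_variance: bool
    n: int


def _classify(slope: float, p: float, alpha: float) -> str:
    if p < alpha:
        return "positive" if slope > 0 else "negative"
    return "NS"


def regress_feature(
    features: pd.DataFrame,
    landscape,
    grouping: str = "global",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[CorrelationResult]:
    """OLS of ΔG on each feature, globally or per protein genotype.

    ``features`` needs columns protein, re, feature, mean (sem/n are
    carried for display only; the fit is unweighted).  With
    ``bonferroni=True`` the α threshold is divided by the number of
    groups tested per feature.
    """
    values = as_landscape(landscape)
    dg = {(g.protein.label, g.re.label): v for g, v in values.items()}
    results: list[CorrelationResult] = []
    for name, sub in features.groupby("feature"):
        missing = [
            (p, r)
            for p, r in zip(sub["protein"], sub["re"])
            if (p, r) not in dg
        ]
        if missing:
            raise ValueError(f"feature rows without landscape cells: {missing[:5]}")
        if grouping == "global":
            groups = [("global", sub)]
        elif grouping == "per_protein":
            groups = list(sub.groupby("protein"))
            n_res = len(enumerate_re_genotypes())
            for label, block in groups:
                if len(block) < n_res:
                    raise ValueError(
                        f"per-protein regression for {label!r} needs all "
                        f"{n_res} REs, got {len(block)}"
                    )
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        thresh = alpha / len(groups) if bonferroni else alpha
        for label, block in groups:
            x = block["mean"].to_numpy(dtype=float)
            y = [dg[(p, r)] for p, r in zip(block["protein"], block["re"])]
            if x.std() == 0:
                results.append(
                    CorrelationResult(
                        feature=str(name), group=str(label),
                        slope=0.0, intercept=float(pd.Series(y).mean()),
                        p_value=1.0, r2=0.0, classification="NS",
                        zero_variance=True, n=len(block),
                    )
                )
                continue
            fit = linregress(x, y)
            results.append(
                CorrelationResult(
                    feature=str(name), group=str(label),
                    slope=float(fit.slope), intercept=float(fit.intercept),
                    p_value=float(fit.pvalue), r2=float(fit.rvalue**2),
                    classification=_classify(fit.slope, fit.pvalue, thresh),
                    zero_variance=False, n=len(block),
                )
            )
    return results


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
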