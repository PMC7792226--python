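"""Allele-substitution effects on breeding values and their economic value.

Per trait, the mutant allele's effect is the slope of an ordinary least
squares regression of estimated breeding values on the expected allele
dosage (y = a + b x + e), restricted to records whose EBV reliability is at
least the filter threshold.  P-values are two-sided from the t distribution
with n - 2 df.  Significance across the trait family uses a Bonferroni
correction fixed at eleven tests by convention (overridable).  Significant
effects aggregate into a monetary index as the signed sum of effect times
euro weight per trait unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import landrace


@dataclass
class EffectEstimate:
    trait: str
    n: int
    b: float
    se: float
    p: float
    significant: bool | None = None


def regress_ebv_on_dosage(ebvs: pd.DataFrame, dosages: dict,
                          min_reliability: float = 0.40) -> EffectEstimate:
    """OLS of one trait's EBVs on expected dosage.

    ``ebvs`` holds one trait (columns id, trait, ebv, reliability);
    ``dosages`` maps sow id -> expected dosage.  Records below
    ``min_reliability`` (inclusive filter: >= is kept) or without a dosage
    are dropped.
    """
    traits = ebvs["trait"].unique()
    if len(traits) != 1:
        raise ValueError("regress_ebv_on_dosage expects a single trait")
    df = ebvs[ebvs["reliability"] >= min_reliability]
    x = np.array([dosages.get(str(i), np.nan) for i in df["id"]])
    ok = np.isfinite(x)
    x, y = x[ok], df["ebv"].to_numpy(dtype=float)[ok]
    if len(y) < 3:
        raise ValueError("need at least three sows after filtering")
    if len(np.unique(x)) < 2:
        raise ValueError("all dosages identical: no contrast to regress on")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    b = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    if se == 0.0:                      # exact fit: P degenerates to 0 (or 1)
        p = 1.0 if b == 0.0 else 0.0
    return EffectEstimate(trait=str(traits[0]), n=int(len(y)), b=b, se=se,
                          p=p)


def multi_trait_effects(ebvs: pd.DataFrame, dosages: dict,
                        alpha: float = 0.05,
                        n_tests: int = landrace.N_TRAIT_TESTS,
                        min_reliability: float = 0.40) -> list:
    """Per-trait regressions with a fixed-family Bonferroni flag.

    The corrected level is alpha / n_tests with n_tests defaulting to the
    conventional eleven-trait family regardless of how many traits are
    supplied; an effect is significant iff P <= that level.
    """
    if ebvs.empty:
        raise ValueError("empty breeding-value table")
    level = alpha / n_tests
    out = []
    for trait, sub in ebvs.groupby("trait", sort=False):
        est = regress_ebv_on_dosage(sub, dosages, min_reliability)
        est.significant = est.p <= level
        out.append(est)
    return out


def economic_index(estimates, weights: dict | None = None,
                   only_significant: bool = True) -> float:
    """Monetary value of the allele: sum of effect x euro weight.

    Traits without a weight contribute nothing; a weighted trait must have
    an estimate.  With ``only_significant`` (default) only effects whose
    significance flag is set enter the sum.  The raw signed product is used
    for every weighted trait; rounding to cents happens only at
    presentation.
    """
    weights = landrace.ECONOMIC_WEIGHTS if weights is None else weights
    by_trait = {e.trait: e for e in estimates}
    missing = [t for t in weights if t not in by_trait]
    if missing:
        raise ValueError(f"weights given for traits without an estimate: "
                         f"{missing}")
    total = 0.0
    for trait, w in weights.items():
        e = by_trait[trait]
        if only_significant and not e.significant:
            continue
        total += e.b * w
    return total


def effects_frame(estimates) -> pd.DataFrame:
    """Result table mirroring the conventional report layout."""
    return pd.DataFrame([{
        "trait": e.trait, "n": e.n, "effect": e.b, "se": e.se,
        "p": e.p, "significant": e.significant,
    } for e in estimates])


def read_ebvs(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    need = {"id", "trait", "ebv", "reliability"}
    if not need.issubset(df.columns):
        raise ValueError(f"EBV table must have columns {sorted(need)}")
    if ((df["reliability"] < 0) | (df["reliability"] > 1)).any():
        raise ValueError("reliability must lie in [0, 1]")
    return df
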