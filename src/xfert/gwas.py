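"""Mixed-linear-model case-control association scan.

The association model per candidate SNP is

    y = a + b x + g + e,      g ~ N(0, G sigma2_g),   e ~ N(0, I sigma2_e),

with y the 0/1 case status, x the alt-allele count (0/1/2), and G the
genomic relationship matrix (GRM) built from all QC-passing SNPs.  Variance
components are estimated once by REML on the null model (no marker term) and
reused for every marker; each marker is then tested by generalized least
squares under V = sigma2_g G + sigma2_e I with a 1-df Wald chi-square.

Computation routes through a single symmetric eigendecomposition of G:
rotating y, the intercept and the genotype matrix into the eigenbasis turns
every GLS solve into a diagonally weighted least squares, so the whole scan
is two dense matrix products plus O(n) work per marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geno_qc import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: median of the 1-df chi-square distribution
CHI2_MEDIAN = 0.4549364


@dataclass
class Grm:
    """Genomic relationship matrix with a cached eigendecomposition."""

    values: np.ndarray
    sample_ids: list
    n_markers_used: int
    n_skipped_monomorphic: int
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (clipped at 0) and eigenvectors of the GRM."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.values)
            self._eig = (np.clip(vals, 0.0, None), vecs)
        return self._eig


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    loglik: float

    @property
    def ratio(self) -> float:
        """sigma2_g / sigma2_e (the REML search parameter)."""
        return self.sigma2_g / self.sigma2_e if self.sigma2_e > 0 else np.inf

    @property
    def heritability(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


@dataclass
class AssocRecord:
    marker_id: str
    chrom: str
    pos: int
    b: float
    se: float
    chi2: float
    p: float
    undefined: bool = False


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    count: int


@dataclass
class RegionSummary:
    regions: dict                    # chrom -> Region
    primary: str | None              # chromosome with the largest cluster
    scattered: list                  # significant AssocRecords off-primary


@dataclass
class GwasSummary:
    lambda_: float
    threshold: float
    significant: list
    regions: RegionSummary


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def compute_grm(gm: GenotypeMatrix, dtype=np.float64) -> Grm:
    """VanRaden-style GRM: mean over markers of (x_j-2p)(x_k-2p)/(2p(1-p)).

    Allele frequency p is the observed mean code / 2; missing codes are
    mean-imputed (their standardized value is 0).  Monomorphic markers carry
    no relationship information and are skipped with a logged count.
    """
    if gm.n_samples < 2:
        raise ValueError("GRM needs at least two samples")
    X = gm.codes.astype(dtype)
    miss = gm.codes == MISSING
    X[miss] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_skip = int((~poly).sum())
    if not poly.any():
        raise ValueError("no polymorphic markers for the GRM")
    if n_skip:
        logger.info("GRM: skipped %d monomorphic markers", n_skip)
    X = X[:, poly]
    p = p[poly]
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    Z[np.isnan(Z)] = 0.0
    G = (Z @ Z.T) / Z.shape[1]
    return Grm(values=np.asarray(G, dtype=np.float64),
               sample_ids=list(gm.samples),
               n_markers_used=int(poly.sum()),
               n_skipped_monomorphic=n_skip)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def reml_fit(y: np.ndarray, grm: Grm, tol: float = 1e-8,
             max_ratio: float = 1e8) -> VarianceComponents:
    """Restricted maximum likelihood for y = a + g + e.

    The restricted likelihood is profiled down to a one-dimensional search
    over the variance ratio gamma = sigma2_g / sigma2_e after one
    eigendecomposition of G; the bounded scalar optimizer converges to
    ``tol`` on gamma (via the transform h = gamma / (1 + gamma)).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != grm.n:
        raise ValueError("phenotype length does not match GRM order")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype: variance components undefined")
    d, U = grm.eig()
    ty = U.T @ y
    tx = U.T @ np.ones(len(y))
    n = len(y)

    def neg_restricted_ll(h: float) -> float:
        gamma = h / (1.0 - h) if h < 1.0 else max_ratio
        w = 1.0 / (gamma * d + 1.0)
        sxx = float(w @ (tx * tx))
        a = float(w @ (tx * ty)) / sxx
        r = ty - a * tx
        rss = float(w @ (r * r))
        sigma2_e = rss / (n - 1)
        return 0.5 * (np.log(gamma * d + 1.0).sum()
                      + (n - 1) * np.log(sigma2_e)
                      + np.log(sxx) + (n - 1))

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, max_ratio / (1.0 + max_ratio)),
        method="bounded", options={"xatol": tol / 10.0})
    if not res.success:
        raise RuntimeError("REML did not converge")
    h = float(res.x)
    if neg_restricted_ll(0.0) <= res.fun:      # boundary check
        h = 0.0
    gamma = h / (1.0 - h)
    w = 1.0 / (gamma * d + 1.0)
    sxx = float(w @ (tx * tx))
    a = float(w @ (tx * ty)) / sxx
    r = ty - a * tx
    sigma2_e = float(w @ (r * r)) / (n - 1)
    return VarianceComponents(sigma2_g=gamma * sigma2_e, sigma2_e=sigma2_e,
                              loglik=-neg_restricted_ll(h))


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def mlma_scan(gm: GenotypeMatrix, y: np.ndarray, grm: Grm,
              vc: VarianceComponents) -> list:
    """Per-marker GLS of y on (1, x) under V = sigma2_g G + sigma2_e I.

    The null-model variance components are reused for every marker
    (single-fit strategy).  Missing genotypes are mean-imputed per marker
    for the scan only.  Markers monomorphic in the analysed samples yield a
    record flagged ``undefined`` rather than an error.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != gm.n_samples or grm.n != gm.n_samples:
        raise ValueError("y, genotypes and GRM must agree in sample count")
    d, U = grm.eig()
    w = 1.0 / (vc.sigma2_g * d + vc.sigma2_e)

    X = gm.codes.astype(float)
    miss = gm.codes == MISSING
    if miss.any():
        X[miss] = np.nan
        mu = np.nanmean(X, axis=0)
        X[miss] = np.broadcast_to(mu, X.shape)[miss]
    mono = np.ptp(X, axis=0) == 0

    ty = U.T @ y
    t1 = U.T @ np.ones(len(y))
    tX = U.T @ X

    a11 = float(w @ (t1 * t1))
    b1 = float(w @ (t1 * ty))
    a12 = (w * t1) @ tX
    a22 = w @ (tX * tX)
    b2 = (w * ty) @ tX
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a11 * b2 - a12 * b1) / det
        se = np.sqrt(a11 / det)
        chi2 = (beta / se) ** 2
    pvals = stats.chi2.sf(chi2, df=1)
    pvals = np.maximum(pvals, np.finfo(float).tiny)   # keep P in (0, 1]

    records = []
    for j in range(gm.n_markers):
        und = bool(mono[j]) or not np.isfinite(chi2[j])
        records.append(AssocRecord(
            marker_id=str(gm.panel.ids[j]),
            chrom=str(gm.panel.chrom[j]),
            pos=int(gm.panel.pos[j]),
            b=float(beta[j]) if not und else np.nan,
            se=float(se[j]) if not und else np.nan,
            chi2=float(chi2[j]) if not und else np.nan,
            p=float(pvals[j]) if not und else np.nan,
            undefined=und,
        ))
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# thresholds, inflation, regions
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests


def inflation_factor(pvalues, method: str = "regression") -> float:
    """Genomic inflation factor lambda from a vector of p-values.

    ``median``: median observed 1-df chi-square over its null median
    (0.4549364).  ``regression``: through-the-origin slope of ordered
    observed chi-squares on the corresponding null quantiles (the default of
    the estlambda-style estimator).
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 2:
        raise ValueError("need at least two p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    obs = stats.chi2.isf(p, df=1)
    if method == "median":
        return float(np.median(obs) / CHI2_MEDIAN)
    if method == "regression":
        m = len(obs)
        exp = stats.chi2.isf((np.arange(1, m + 1) - 0.5) / m, df=1)
        obs_sorted = np.sort(obs)[::-1]
        return float((exp @ obs_sorted) / (exp @ exp))
    raise ValueError(f"unknown lambda method {method!r}")


def significant_region(records, threshold: float) -> RegionSummary:
    """Per-chromosome span of significant markers.

    Every chromosome with at least one significant marker gets the inclusive
    interval [min pos, max pos] and a count (a single marker gives a
    degenerate width-0 interval).  The chromosome with the largest cluster
    is the primary region; significant markers elsewhere are reported as
    scattered.
    """
    sig = [r for r in records
           if not r.undefined and np.isfinite(r.p) and r.p < threshold]
    regions: dict[str, Region] = {}
    for r in sig:
        reg = regions.get(r.chrom)
        if reg is None:
            regions[r.chrom] = Region(r.chrom, r.pos, r.pos, 1)
        else:
            reg.start = min(reg.start, r.pos)
            reg.end = max(reg.end, r.pos)
            reg.count += 1
    primary = max(regions, key=lambda c: regions[c].count) if regions else None
    scattered = [r for r in sig if r.chrom != primary]
    return RegionSummary(regions=regions, primary=primary,
                         scattered=scattered)


def summarize(records, alpha: float = 0.05,
              lambda_method: str = "regression") -> GwasSummary:
    """Threshold, inflation factor and significant-region summary of a scan."""
    defined = [r for r in records if not r.undefined]
    m = len(defined)
    thr = bonferroni_threshold(alpha, m) if m else np.nan
    lam = inflation_factor([r.p for r in defined], method=lambda_method) \
        if m >= 2 else np.nan
    sig = [r for r in defined if r.p < thr]
    return GwasSummary(lambda_=lam, threshold=thr, significant=sig,
                       regions=significant_region(records, thr))


def qq_band(m: int, level: float = 0.95,
            simultaneous: bool = False) -> pd.DataFrame:
    """Null concentration band for a QQ plot of m p-values.

    Order statistic i of m uniform p-values follows Beta(i, m - i + 1);
    the band is the pointwise (1 - level) two-sided quantile envelope, or a
    Bonferroni-adjusted simultaneous envelope when ``simultaneous``.
    """
    i = np.arange(1, m + 1)
    a = 1.0 - level
    if simultaneous:
        a = a / m
    return pd.DataFrame({
        "expected": i / (m + 1.0),
        "lower": stats.beta.ppf(a / 2.0, i, m - i + 1),
        "upper": stats.beta.ppf(1.0 - a / 2.0, i, m - i + 1),
    })
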