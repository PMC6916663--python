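"""Genetic parameters derived from fitted variance components.

Per-site heritabilities and variance ratios use the phenotypic variance

    sigma_p^2 = sigma_a^2 + sigma_d^2 + sigma_i^2 + sigma_e^2

*excluding* the post-block variance, while the per-site variance
*proportions* (percent columns of a variance-component report) divide by
the site total *including* the block variance.  The two conventions are
deliberate: block effects are an experimental-design nuisance removed
from heritable signal, but they are part of the raw variance budget a
trial report accounts for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

EPISTATIC = ("epi_aa", "epi_ad", "epi_dd")


@dataclass
class SiteVariances:
    """Per-site variance components; the minimal genpar input.

    Any converged :class:`~metgblup.reml.FitResult` provides one via
    :func:`site_variances`; tests and reports may build one directly
    from published component tables.
    """

    block: float
    additive: float
    residual: float
    dominance: float = 0.0
    epi_aa: float = 0.0
    epi_ad: float = 0.0
    epi_dd: float = 0.0

    @property
    def epistatic(self) -> float:
        return self.epi_aa + self.epi_ad + self.epi_dd

    @property
    def genetic(self) -> float:
        return self.additive + self.dominance + self.epistatic

    @property
    def phenotypic(self) -> float:
        """sigma_p^2: genetic + residual (block variance excluded)."""
        return self.genetic + self.residual

    @property
    def total_with_block(self) -> float:
        return self.block + self.genetic + self.residual


def site_variances(fit, site: str) -> SiteVariances:
    """Extract per-site components from a fit (or pass through)."""
    if isinstance(fit, SiteVariances):
        return fit
    return SiteVariances(
        block=fit.site_variance("block", site),
        additive=fit.site_variance("additive", site),
        dominance=fit.site_variance("dominance", site),
        epi_aa=fit.site_variance("epi_aa", site),
        epi_ad=fit.site_variance("epi_ad", site),
        epi_dd=fit.site_variance("epi_dd", site),
        residual=fit.site_variance("residual", site),
    )


@dataclass
class HeritabilityReport:
    site: str
    h2: float
    H2: float
    d2: float
    i2: float
    phenotypic_variance: float
    includes_epistasis: bool


def heritability(fit, site: str = "") -> HeritabilityReport:
    """Narrow/broad-sense heritability and dominance/epistatic ratios.

    h2 = sigma_a^2 / sigma_p^2, d2 = sigma_d^2 / sigma_p^2,
    i2 = sigma_i^2 / sigma_p^2, H2 = sigma_g^2 / sigma_p^2.  For models
    without epistatic terms H2 = (sigma_a^2 + sigma_d^2) / sigma_p^2.
    """
    v = site_variances(fit, site)
    vp = v.phenotypic
    if vp <= 0:
        raise ValueError("non-positive phenotypic variance")
    return HeritabilityReport(
        site=site,
        h2=v.additive / vp,
        H2=v.genetic / vp,
        d2=v.dominance / vp,
        i2=v.epistatic / vp,
        phenotypic_variance=vp,
        includes_epistasis=v.epistatic > 0,
    )


def variance_proportions(fit, site: str = "") -> dict[str, float]:
    """Percent of the site total (block included) for each component."""
    v = site_variances(fit, site)
    tot = v.total_with_block
    if tot <= 0:
        raise ValueError("zero total variance at site")
    out = {
        "block": v.block,
        "additive": v.additive,
        "dominance": v.dominance,
        "epi_aa": v.epi_aa,
        "epi_ad": v.epi_ad,
        "epi_dd": v.epi_dd,
        "residual": v.residual,
    }
    return {k: 100.0 * x / tot for k, x in out.items()}


def _component_value(fit, component: str, site: str) -> float:
    if component in ("h2", "H2", "d2", "i2"):
        return getattr(heritability(fit, site), component)
    return getattr(site_variances(fit, site), component)


def model_ratio(fit_x, fit_y, component: str = "additive", site: str = "") -> float:
    """One model's component (or ratio) as a percentage of another's.

    ``component`` is a variance component name ('additive', 'dominance',
    ...) or a heritability ratio ('h2', 'H2', 'd2', 'i2').  Both
    arguments may be fits or :class:`SiteVariances`.
    """
    num = _component_value(fit_x, component, site)
    den = _component_value(fit_y, component, site)
    if den == 0:
        raise ZeroDivisionError("zero denominator in model ratio")
    return 100.0 * num / den


def percent_change(new: float, old: float) -> float:
    """Relative change 100 * (new - old) / old."""
    if old == 0:
        raise ZeroDivisionError("zero baseline in percent change")
    return 100.0 * (new - old) / old


def fitted_line_r2(fit, site: str) -> float:
    """R^2 of the fitted-line plot: corr(predicted, observed)^2 at a site.

    Predictions are fixed effects + block BLUP + total genetic BLUP for
    each record.
    """
    rec = fit.records
    sub = rec[rec["site"] == site]
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 observations at site {site!r}")
    yhat = (sub["fixed_hat"] + sub["block_hat"] + sub["genetic_hat"]).to_numpy()
    y = sub["y"].to_numpy()
    if np.std(yhat) < 1e-12 * max(1.0, np.std(y)):
        warnings.warn("predictions have no variance at this site; R^2 set to 0")
        return 0.0
    r, _ = pearsonr(yhat, y)
    return float(r**2)


def heritability_table(fit) -> pd.DataFrame:
    """Per-site summary of ratios for reporting (2-decimal rounding)."""
    rows = []
    for s in fit.sites:
        h = heritability(fit, s)
        rows.append(
            {
                "site": s,
                "h2": round(h.h2, 2),
                "H2": round(h.H2, 2),
                "d2": round(h.d2, 2),
                "i2": round(h.i2, 2),
            }
        )
    return pd.DataFrame(rows)
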