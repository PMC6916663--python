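"""Cross-validated predictive ability for single-trial and MET models.

Validation individuals' phenotypes are masked, the model is refit on the
remaining records, and predictions for the masked individuals are formed
from one of three bases:

* ``M``  — main (across-site) genetic effect only;
* ``A``  — M plus the site-specific interaction effect, i.e. the full
  site additive value;
* ``AD`` — A plus the dominance BLUP.

Predictive ability (PA) is the Pearson correlation between the
predictions and the validation phenotypes adjusted by the *training*
fit's fixed-effect and block-effect estimates, so no validation
information enters the adjustment (a constant offset does not change a
correlation, but block adjustments do).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .covstruct import DECOMPOSABLE
from .reml import FitResult, ModelSpec, REMLOptions, fit_reml

SCENARIOS = ("ST-within", "ST-across", "MET-within")


@dataclass
class CVPlan:
    """Folding and scenario description for one cross-validation run."""

    scenario: str = "MET-within"
    validation_site: str = ""
    training_sites: tuple[str, ...] = ()
    k: int = 10
    reps: int = 10
    seed: int = 0
    bases: tuple[str, ...] = ("M", "A", "AD")
    family_intact: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        for b in self.bases:
            if b not in ("M", "A", "AD"):
                raise ValueError(f"unknown prediction basis {b!r}")


@dataclass
class CVReport:
    plan: CVPlan
    summary: pd.DataFrame  # basis, mean PA, SE over replications
    folds: pd.DataFrame  # rep, fold, basis, n, pa

    def pa(self, basis: str) -> float:
        return float(self.summary.set_index("basis").loc[basis, "pa"])

    def se(self, basis: str) -> float:
        return float(self.summary.set_index("basis").loc[basis, "se"])


def predictive_ability(predicted, observed_adjusted) -> float:
    """Pearson correlation between predictions and adjusted phenotypes."""
    x = np.asarray(predicted, float)
    y = np.asarray(observed_adjusted, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("predictive ability needs >= 3 paired values")
    if np.std(x) < 1e-14 or np.std(y) < 1e-14:
        raise ValueError("zero variance in predictions or phenotypes")
    return float(pearsonr(x, y)[0])


def _pa_or_zero(pred, adj) -> float:
    """PA, with constant predictions scored 0 (no ranking information)."""
    if np.std(np.asarray(pred, float)) < 1e-14:
        warnings.warn(
            "constant predictions (variance component at zero); PA recorded as 0"
        )
        return 0.0
    return predictive_ability(pred, adj)


def predict_basis(fit: FitResult, ids, site: str, basis: str) -> np.ndarray:
    """Predicted genetic values for ``ids`` at ``site`` from a fitted model.

    When the model never saw ``site`` (across-site prediction from a
    single-trial fit), the training site's genetic values are carried
    over unchanged.
    """
    col_site = site if site in fit.sites else fit.sites[0]
    col = f"site:{col_site}"
    if basis == "M":
        if "m" not in fit.blups:
            raise ValueError(
                "basis 'M' requires a main+interaction additive structure "
                f"(one of {DECOMPOSABLE})"
            )
        pred = fit.blups["m"].loc[ids, "m"].to_numpy()
    elif basis == "A":
        pred = fit.blups["additive"].loc[ids, col].to_numpy()
    elif basis == "AD":
        pred = fit.blups["additive"].loc[ids, col].to_numpy()
        if "dominance" in fit.blups:
            pred = pred + fit.blups["dominance"].loc[ids, col].to_numpy()
        else:
            raise ValueError("basis 'AD' requires a dominance effect in the model")
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return pred


def _block_effect_map(fit: FitResult) -> dict[tuple[str, str], float]:
    rec = fit.records
    return {
        (s, b): float(v)
        for (s, b), v in rec.groupby(["site", "block"])["block_hat"].first().items()
    }


def adjusted_validation_phenotypes(fit: FitResult, val_records: pd.DataFrame, trait: str):
    """y - (training) fixed-effect value - (training) block BLUP."""
    site = val_records["site"].astype(str)
    mu = fit.fixed["intercept"]
    fixed = np.full(len(val_records), mu)
    for j, s in enumerate(fit.sites[1:]):
        fixed += np.where(site == s, fit.fixed.get(f"site:{s}", 0.0), 0.0)
    bmap = _block_effect_map(fit)
    block = np.array(
        [bmap.get((s, str(b)), 0.0) for s, b in zip(site, val_records["block"])]
    )
    return val_records[trait].to_numpy(float) - fixed - block


def _make_folds(ids, k, rng, families=None):
    """Random partition of ids into k folds (family-intact if given)."""
    ids = np.asarray(ids)
    if families is None:
        perm = rng.permutation(len(ids))
        return [ids[perm[i::k]] for i in range(k)]
    fam = pd.Series(families).reindex(ids)
    groups = [g.index.to_numpy() for _, g in fam.groupby(fam)]
    rng.shuffle(groups)
    folds = [[] for _ in range(k)]
    sizes = np.zeros(k, int)
    for g in groups:  # greedy balancing keeps families intact
        j = int(sizes.argmin())
        folds[j].extend(g)
        sizes[j] += len(g)
    return [np.asarray(f) for f in folds]


def run_cv(
    data: pd.DataFrame,
    spec: ModelSpec,
    kernels,
    plan: CVPlan,
    trait: str | None = None,
    families: dict[str, str] | None = None,
    options: REMLOptions | None = None,
) -> CVReport:
    """Run one cross-validation scenario and report PA per basis."""
    if trait is None:
        trait = [c for c in data.columns if c not in ("id", "site", "block")][0]
    data = data.loc[data[trait].notna()].copy()
    data["site"] = data["site"].astype(str)
    opts = options or REMLOptions(compute_seps=False)
    val_site = plan.validation_site or sorted(data["site"].unique())[0]
    train_sites = list(plan.training_sites) or sorted(data["site"].unique())
    if val_site not in data["site"].values:
        raise ValueError(f"validation site {val_site!r} not present in data")

    rows = []
    if plan.scenario == "ST-across":
        # one deterministic evaluation: full training site vs full other site
        train = data[data["site"].isin([s for s in train_sites if s != val_site])]
        if train.empty:
            raise ValueError("ST-across needs a training site different from validation")
        fit = fit_reml(train, spec, kernels, trait=trait, options=opts)
        val = data[data["site"] == val_site]
        adj = adjusted_validation_phenotypes(fit, val, trait)
        for basis in plan.bases:
            pred = predict_basis(fit, val["id"].tolist(), val_site, basis)
            rows.append(
                {"rep": 0, "fold": 0, "basis": basis, "n": len(val),
                 "pa": _pa_or_zero(pred, adj)}
            )
    else:
        if plan.scenario == "ST-within":
            pool = data[data["site"] == val_site]
        else:  # MET-within
            pool = data[data["site"].isin(train_sites)]
        val_ids = pool.loc[pool["site"] == val_site, "id"].unique()
        # warm-start fold refits from the all-data estimates (same model,
        # 90% shared records: the optimum moves little between folds)
        base_fit = fit_reml(pool, spec, kernels, trait=trait, options=opts)
        warm = base_fit.varcomps
        ss = np.random.SeedSequence([plan.seed & 0x7FFFFFFF])
        for rep, child in enumerate(ss.spawn(plan.reps)):
            rng = np.random.default_rng(child)
            folds = _make_folds(
                val_ids, plan.k, rng, families if plan.family_intact else None
            )
            pooled: dict[str, list] = {b: [] for b in plan.bases}
            pooled_obs: list = []
            for fold_no, fold_ids in enumerate(folds):
                val_mask = pool["id"].isin(fold_ids) & (pool["site"] == val_site)
                val = pool[val_mask]
                if len(val) < 2:
                    warnings.warn(f"fold {fold_no} has < 2 validation records; skipped")
                    continue
                fit = fit_reml(
                    pool[~val_mask], spec, kernels, trait=trait, options=opts,
                    start=warm,
                )
                adj = adjusted_validation_phenotypes(fit, val, trait)
                pooled_obs.append(adj)
                for basis in plan.bases:
                    pred = predict_basis(fit, val["id"].tolist(), val_site, basis)
                    pooled[basis].append(pred)
                    rows.append(
                        {"rep": rep, "fold": fold_no, "basis": basis, "n": len(val),
                         "pa": _pa_or_zero(pred, adj)}
                    )
            # site-level PA per replication: every individual validated once
            obs = np.concatenate(pooled_obs)
            for basis in plan.bases:
                rows.append(
                    {"rep": rep, "fold": -1, "basis": basis, "n": len(obs),
                     "pa": _pa_or_zero(np.concatenate(pooled[basis]), obs)}
                )

    folds_df = pd.DataFrame(rows)
    site_level = folds_df[folds_df["fold"] == -1] if (folds_df["fold"] == -1).any() else folds_df
    summary_rows = []
    for basis, grp in site_level.groupby("basis", sort=False):
        rep_means = grp.groupby("rep")["pa"].mean()
        se = float(rep_means.std(ddof=1) / np.sqrt(len(rep_means))) if len(rep_means) > 1 else 0.0
        summary_rows.append({"basis": basis, "pa": float(rep_means.mean()), "se": se})
    order = {b: i for i, b in enumerate(plan.bases)}
    summary = pd.DataFrame(summary_rows).sort_values(
        "basis", key=lambda s: s.map(order)
    ).reset_index(drop=True)
    return CVReport(plan=plan, summary=summary, folds=folds_df)


def accuracy_from_pa(pa: float, h2: float) -> float:
    """Prediction accuracy: PA divided by the square root of h^2."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    return pa / np.sqrt(h2)


def spearman_bv(fitX: FitResult, fitY: FitResult, site: str | None = None) -> float:
    """Spearman rank correlation of additive BLUPs from two fits.

    With ``site`` given, compares that site's breeding values; otherwise
    the per-individual mean across sites.  Ties get average ranks.
    """
    ax, ay = fitX.blups["additive"], fitY.blups["additive"]
    common = [i for i in ax.index if i in set(ay.index)]
    if len(common) < 3:
        raise ValueError("Spearman correlation needs >= 3 shared individuals")
    if site is not None:
        x = ax.loc[common, f"site:{site}"]
        y = ay.loc[common, f"site:{site}"]
    else:
        x = ax.loc[common].mean(axis=1)
        y = ay.loc[common].mean(axis=1)
    return float(spearmanr(x, y).statistic)
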