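"""REML fitting of multi-environment individual-tree mixed models.

The observation model is

    y = X beta (+ f i) + W b + sum_g Z_g u_g + eps

with a grand mean and site contrasts in ``beta``, an optional genomic
inbreeding covariate ``f`` (coefficient ``i`` = inbreeding depression per
unit inbreeding), random post-block-within-site effects ``b`` with
per-site variances, one or more genetic effects ``u_g`` (additive,
dominance, first-order epistatic) distributed ``N(0, Sigma_g (x) K_g)``
where ``Sigma_g`` is an across-site covariance structure and ``K_g`` a
relationship matrix, and heterogeneous per-site residuals.

Variance components are estimated by maximizing the restricted
log-likelihood

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y + (n - p) log(2 pi) ]

directly with a bounded quasi-Newton optimizer (L-BFGS-B) using the
analytic score  d logL / d theta_i = -1/2 [ tr(P dV_i) - y'P dV_i P y ].
Variances are kept non-negative by box bounds, so null components
converge to the zero boundary.  Approximate standard errors come from
the inverse average-information matrix at the optimum.

BLUPs of all random effects are recovered from the converged estimates
as  u_hat = Cov(u, y) P y,  and prediction error variances (SEP^2) as
diag(Var(u) - Cov(u, y) P Cov(u, y)').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, lapack
from scipy.optimize import minimize

from .covstruct import DECOMPOSABLE, VarStruct, canonical_name, n_params as struct_n_params, to_sitecov
from .relmat import InbreedingVector, RelationshipMatrix

_LOG2PI = np.log(2.0 * np.pi)

#: epistatic effect names in model order and the kernel kinds they use
EPISTATIC_EFFECTS = (("epi_aa", ("Gaa",)), ("epi_ad", ("Gad",)), ("epi_dd", ("Gdd",)))


class REMLError(RuntimeError):
    pass


class ConvergenceError(REMLError):
    def __init__(self, message: str, trajectory: list[float] | None = None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclass
class ModelSpec:
    """Which genetic effects enter the model and their site structures.

    ``source`` selects pedigree (A/D) or genomic (Ga/Gd) kernels.
    Epistasis is available only with genomic kernels (full-sib progeny
    trials without clonal replication cannot separate epistasis under a
    pedigree model) and is always fitted with the IDEN structure.
    """

    source: str = "genomic"
    additive: str = "CS"
    dominance: str | None = None
    epistasis: bool = False
    include_f: bool = False

    def __post_init__(self) -> None:
        if self.source not in ("pedigree", "genomic"):
            raise ValueError("source must be 'pedigree' or 'genomic'")
        self.additive = canonical_name(self.additive)
        if self.dominance is not None:
            self.dominance = canonical_name(self.dominance)
        if self.epistasis and self.source != "genomic":
            raise ValueError("epistatic effects require genomic kernels")

    @property
    def name(self) -> str:
        base = "GBLUP" if self.source == "genomic" else "ABLUP"
        suff = "A" + ("D" if self.dominance else "") + ("E" if self.epistasis else "")
        return f"{base}-{suff}"

    def effect_structures(self, n_sites: int) -> dict[str, VarStruct]:
        out = {"additive": VarStruct(self.additive, n_sites)}
        if self.dominance:
            out["dominance"] = VarStruct(self.dominance, n_sites)
        if self.epistasis:
            for eff, _ in EPISTATIC_EFFECTS:
                out[eff] = VarStruct("IDEN", n_sites)
        return out

    def kernel_kind(self, effect: str) -> str:
        gen = self.source == "genomic"
        table = {
            "additive": "Ga" if gen else "A",
            "dominance": "Gd" if gen else "D",
            "epi_aa": "Gaa",
            "epi_ad": "Gad",
            "epi_dd": "Gdd",
        }
        return table[effect]


@dataclass
class REMLOptions:
    max_iter: int = 200
    ftol: float = 1e-10
    gtol: float = 1e-6
    jitter: float = 1e-8
    compute_seps: bool = True
    verbose: bool = False


def count_params(spec: ModelSpec, n_sites: int = 2) -> int:
    """Number of variance parameters: structures + per-site block + residual."""
    p = sum(struct_n_params(s) for s in spec.effect_structures(n_sites).values())
    return p + 2 * n_sites


def aic(logL: float, n_params: int) -> float:
    """Akaike information criterion, -2 logL + 2 p."""
    return -2.0 * logL + 2.0 * n_params


# ---------------------------------------------------------------------------
# variance model terms


class _LinearTerm:
    """V(theta) = sum_i theta_i * mats_i with theta_i >= 0."""

    def __init__(self, labels, mats, bounds=None):
        self.labels = list(labels)
        self.mats = mats
        self.n_par = len(mats)
        self.bounds = bounds or [(0.0, None)] * self.n_par

    def V(self, theta):
        out = theta[0] * self.mats[0]
        for t, M in zip(theta[1:], self.mats[1:]):
            out += t * M
        return out

    def dV(self, theta):
        return self.mats


class _USTerm:
    """Unstructured site covariance via its Cholesky factor L (PSD by design)."""

    def __init__(self, effect, pair_mats, n_sites):
        self.n_sites = n_sites
        self.tril = [(s, t) for s in range(n_sites) for t in range(s + 1)]
        self.labels = [f"{effect}:L{s+1}{t+1}" for s, t in self.tril]
        self.pair_mats = pair_mats  # dict[(s,t)] -> masked kernel, s <= t
        self.n_par = len(self.tril)
        self.bounds = [(0.0, None) if s == t else (None, None) for s, t in self.tril]

    def _L(self, theta):
        L = np.zeros((self.n_sites, self.n_sites))
        for val, (s, t) in zip(theta, self.tril):
            L[s, t] = val
        return L

    def _from_sigma(self, Sigma):
        n = Sigma.shape[0]
        out = None
        for s in range(n):
            for t in range(s + 1):
                M = self.pair_mats[(t, s)]
                contrib = Sigma[s, t] * (M if s == t else (M + M.T))
                out = contrib if out is None else out + contrib
        return out

    def V(self, theta):
        L = self._L(theta)
        return self._from_sigma(L @ L.T)

    def dV(self, theta):
        L = self._L(theta)
        out = []
        for s, t in self.tril:
            E = np.zeros_like(L)
            E[s, t] = 1.0
            dS = E @ L.T + L @ E.T
            out.append(self._from_sigma(dS))
        return out


def _genetic_term(effect: str, struct: VarStruct, Kfull: np.ndarray, site_codes: np.ndarray):
    """Record-level covariance term for a genetic effect under a structure."""
    S = struct.n_sites
    same = site_codes[:, None] == site_codes[None, :]
    name = struct.name
    if name == "IDEN":
        return _LinearTerm([f"{effect}:sigma2"], [Kfull * same])
    if name == "DIAG":
        mats = [Kfull * np.outer(site_codes == s, site_codes == s) for s in range(S)]
        return _LinearTerm([f"{effect}:sigma2_s{s+1}" for s in range(S)], mats)
    if name == "CS":
        return _LinearTerm([f"{effect}:var_m", f"{effect}:var_me"], [Kfull, Kfull * same])
    if name in ("CS_DIAG", "FAMK"):
        mats = [Kfull] + [
            Kfull * np.outer(site_codes == s, site_codes == s) for s in range(S)
        ]
        labels = [f"{effect}:var_m"] + [f"{effect}:psi_s{s+1}" for s in range(S)]
        return _LinearTerm(labels, mats)
    # US
    pair_mats = {
        (s, t): Kfull * np.outer(site_codes == s, site_codes == t)
        for s in range(S)
        for t in range(s, S)
    }
    return _USTerm(effect, pair_mats, S)


def _natural_struct(effect: str, struct: VarStruct, theta: np.ndarray) -> VarStruct:
    """Map internal REML parameters back to the structure's natural ones."""
    S = struct.n_sites
    name = struct.name
    if name == "CS":
        m, me = theta
        params = [m + me, m]
    elif name == "CS_DIAG":
        params = np.concatenate([[theta[0]], theta[0] + theta[1:]])
    elif name in ("IDEN", "DIAG", "FAMK", "US"):
        params = theta
    return VarStruct(name, S, k=struct.k, params=np.asarray(params, float))


# ---------------------------------------------------------------------------
# likelihood


def _reml_pieces(V, X, y, jitter):
    n, p = X.shape
    Vj = V.copy()
    Vj[np.diag_indices_from(Vj)] += jitter
    try:
        c = cho_factor(Vj, lower=True)
    except np.linalg.LinAlgError as exc:
        raise REMLError("covariance matrix not positive definite") from exc
    logdetV = 2.0 * np.sum(np.log(np.diag(c[0])))
    ViX = cho_solve(c, X)
    Viy = cho_solve(c, y)
    XtViX = X.T @ ViX
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise REMLError("singular fixed-effects design (X'V^-1X not PD)")
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    Py = Viy - ViX @ beta
    yPy = float(y @ Py)
    logL = -0.5 * (logdetV + logdetXtViX + yPy + (n - p) * _LOG2PI)
    return logL, c, ViX, XtViX, beta, Py


def _negloglik_and_grad(theta, terms, slices, X, y, jitter):
    V = None
    for term, sl in zip(terms, slices):
        contrib = term.V(theta[sl])
        V = contrib if V is None else V + contrib
    logL, c, ViX, XtViX, beta, Py = _reml_pieces(V, X, y, jitter)
    Vinv_tri, info = lapack.dpotri(c[0], lower=True)
    if info != 0:
        raise REMLError("inversion from Cholesky factor failed")
    Vinv = np.tril(Vinv_tri) + np.tril(Vinv_tri, -1).T
    P = Vinv - ViX @ np.linalg.solve(XtViX, ViX.T)
    grad = np.empty_like(theta)
    for term, sl in zip(terms, slices):
        for k, dV in enumerate(term.dV(theta[sl])):
            tr = float(np.sum(P * dV))
            quad = float(Py @ (dV @ Py))
            grad[sl.start + k] = -0.5 * (tr - quad)
    return -logL, -grad, P, Py, beta, XtViX


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Converged REML fit: estimates, BLUPs, likelihood and precision."""

    spec: ModelSpec
    trait: str
    sites: list[str]
    varcomps: dict[str, float]
    varcomp_se: dict[str, float]
    fixed: dict[str, float]
    fixed_se: dict[str, float]
    structures: dict[str, VarStruct]
    block_vars: dict[str, float]
    residual_vars: dict[str, float]
    blups: dict[str, pd.DataFrame]
    seps: pd.DataFrame | None
    logL: float
    aic: float
    n_params: int
    converged: bool
    iterations: int
    records: pd.DataFrame = field(repr=False, default=None)

    def site_variance(self, component: str, site: str) -> float:
        """Variance of one component at one site.

        ``component`` is 'block', 'additive', 'dominance', 'epi_aa',
        'epi_ad', 'epi_dd' or 'residual'.  Genetic components are the
        diagonal entry of the structure's site covariance.
        """
        s = self._site_index(site)
        if component == "block":
            return self.block_vars[self.sites[s]]
        if component == "residual":
            return self.residual_vars[self.sites[s]]
        if component not in self.structures:
            return 0.0
        return float(to_sitecov(self.structures[component]).values[s, s])

    def _site_index(self, site: str) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise KeyError(f"site {site!r} not among fitted sites {self.sites}")

    def additive_sitecov(self) -> np.ndarray:
        return to_sitecov(self.structures["additive"]).values

    @property
    def genetic_effects(self) -> list[str]:
        return list(self.structures)


def seps(fit: FitResult) -> pd.DataFrame:
    """Per-individual, per-site standard errors of predicted breeding values."""
    if not fit.converged:
        raise REMLError("SEPs requested before convergence")
    if fit.seps is None:
        raise REMLError("fit was run with compute_seps=False")
    return fit.seps


# ---------------------------------------------------------------------------
# main entry


def _design_matrices(records, sites, f_map):
    n = len(records)
    S = len(sites)
    cols = ["intercept"] + [f"site:{s}" for s in sites[1:]]
    X = np.ones((n, 1 + (S - 1) + (1 if f_map is not None else 0)))
    for j, s in enumerate(sites[1:], start=1):
        X[:, j] = (records["site"] == s).to_numpy(float)
    if f_map is not None:
        fv = records["id"].map(f_map)
        if fv.isna().any():
            missing = records.loc[fv.isna(), "id"].unique()[:5]
            raise ValueError(f"inbreeding coefficient missing for ids {list(missing)}")
        fv = fv.to_numpy(float)
        if np.ptp(fv) < 1e-12:
            raise ValueError(
                "inbreeding covariate is constant across individuals "
                "(confounded with the intercept)"
            )
        X[:, -1] = fv
        cols.append("f")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise REMLError("singular fixed-effects design")
    return X, cols


def _validate_inputs(records, spec, kernels, n_sites):
    for site, cnt in records["site"].value_counts().items():
        if cnt < 2:
            raise ValueError(f"site {site!r} has fewer than 2 observations")
    needed = [spec.kernel_kind(e) for e in spec.effect_structures(n_sites)]
    for kind in needed:
        if kind not in kernels:
            raise ValueError(f"kernel {kind!r} required by the model but not supplied")
    return needed


def fit_reml(
    data: pd.DataFrame,
    spec: ModelSpec,
    kernels: dict[str, RelationshipMatrix],
    trait: str | None = None,
    f: InbreedingVector | None = None,
    options: REMLOptions | None = None,
    start: dict[str, float] | None = None,
) -> FitResult:
    """Fit the mixed model by REML and return estimates and BLUPs.

    ``data`` needs columns id, site, block and the trait; rows with a
    missing trait value are dropped.  ``kernels`` maps kernel kinds
    (A, D, Ga, Gd, Gaa, Gad, Gdd) to relationship matrices over a common
    id set covering every phenotyped individual.  ``start`` optionally
    warm-starts the optimizer from a previous fit's ``varcomps`` (labels
    must match); components default to an equal split of the phenotypic
    variance.
    """
    opts = options or REMLOptions()
    if trait is None:
        extras = [c for c in data.columns if c not in ("id", "site", "block")]
        if not extras:
            raise ValueError("no trait column found")
        trait = extras[0]
    records = data.loc[data[trait].notna(), ["id", "site", "block", trait]].copy()
    records = records.reset_index(drop=True)
    sites = sorted(records["site"].astype(str).unique())
    records["site"] = records["site"].astype(str)
    n_sites = len(sites)
    needed = _validate_inputs(records, spec, kernels, n_sites)

    kid = kernels[needed[0]].ids
    for kind in needed[1:]:
        if kernels[kind].ids != kid:
            raise ValueError("all kernels must share the same ids and order")
    pos = {v: i for i, v in enumerate(kid)}
    missing = [i for i in records["id"] if i not in pos]
    if missing:
        raise ValueError(f"phenotyped ids absent from kernels: {sorted(set(missing))[:5]}")
    idx = records["id"].map(pos).to_numpy()
    site_codes = records["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()

    y_raw = records[trait].to_numpy(float)
    yscale = float(y_raw.std()) or 1.0
    y = y_raw / yscale

    f_map = None
    if spec.include_f:
        if f is None:
            raise ValueError("spec.include_f requires an InbreedingVector")
        f_map = dict(zip(f.ids, f.f))
    X, fixed_cols = _design_matrices(records, sites, f_map)

    # --- variance model terms ------------------------------------------------
    terms: list = []
    effect_structs = spec.effect_structures(n_sites)
    block_key = records["site"] + "\x00" + records["block"].astype(str)
    same_block = (block_key.to_numpy()[:, None] == block_key.to_numpy()[None, :])
    block_mats = [
        same_block * np.outer(site_codes == s, site_codes == s) * 1.0
        for s in range(n_sites)
    ]
    terms.append(
        _LinearTerm([f"block:sigma2_s{s+1}" for s in range(n_sites)], block_mats)
    )
    for eff, struct in effect_structs.items():
        K = kernels[spec.kernel_kind(eff)]
        try:
            np.linalg.cholesky(K.values + opts.jitter * 10 * np.eye(K.n))
        except np.linalg.LinAlgError:
            raise REMLError(f"kernel {K.kind} not positive semi-definite after jitter")
        Kfull = K.values[np.ix_(idx, idx)]
        terms.append(_genetic_term(eff, struct, Kfull, site_codes))
    resid_mats = [np.diag((site_codes == s) * 1.0) for s in range(n_sites)]
    terms.append(
        _LinearTerm([f"residual:sigma2_s{s+1}" for s in range(n_sites)], resid_mats)
    )

    slices, labels, bounds = [], [], []
    off = 0
    for term in terms:
        slices.append(slice(off, off + term.n_par))
        labels.extend(term.labels)
        bounds.extend(term.bounds)
        off += term.n_par

    # --- starting values: phenotypic variance split equally over components --
    vp_site = np.array([y[site_codes == s].var() for s in range(n_sites)])
    vp = float(vp_site.mean())
    n_slots = len(terms)  # block + each genetic effect + residual
    theta0 = np.empty(off)
    for term, sl in zip(terms, slices):
        share = vp / n_slots
        if isinstance(term, _USTerm):
            L0 = np.linalg.cholesky(share * np.eye(n_sites))
            theta0[sl] = L0[np.tril_indices(n_sites)]
        elif term.labels[0].endswith("var_m"):
            theta0[sl] = share / term.n_par
        else:
            theta0[sl] = share
    if start:
        scale2 = yscale**2
        for term, sl in zip(terms, slices):
            div = yscale if isinstance(term, _USTerm) else scale2
            for k, lbl in enumerate(term.labels):
                if lbl in start:
                    theta0[sl.start + k] = start[lbl] / div
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    theta0 = np.maximum(theta0, np.where(np.isfinite(lo), lo, theta0))

    trajectory: list[float] = []

    def objective(theta):
        nll, grad, *_ = _negloglik_and_grad(theta, terms, slices, X, y, opts.jitter)
        trajectory.append(-nll)
        return nll, grad

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": opts.max_iter, "ftol": opts.ftol, "gtol": opts.gtol},
    )
    converged = bool(res.success) or res.status == 0
    if not converged and "ITERATIONS" in str(res.message).upper():
        raise ConvergenceError(
            f"REML did not converge within {opts.max_iter} iterations", trajectory
        )
    theta = res.x

    nll, _, P, Py, beta, XtViX = _negloglik_and_grad(
        theta, terms, slices, X, y, opts.jitter
    )
    logL = -nll - 0.5 * (len(y) - X.shape[1]) * np.log(yscale**2)
    # logL reported on the original trait scale (Jacobian of y -> y/s)

    # --- standard errors from average information ----------------------------
    dVs = []
    for term, sl in zip(terms, slices):
        dVs.extend(term.dV(theta[sl]))
    U = np.column_stack([dV @ Py for dV in dVs])
    PU = P @ U
    AI = 0.5 * (U.T @ PU)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            se_theta = np.sqrt(np.clip(np.diag(np.linalg.pinv(AI)), 0, None))
        except np.linalg.LinAlgError:
            se_theta = np.full_like(theta, np.nan)

    scale2 = yscale**2
    varcomps = {lbl: float(v * scale2) for lbl, v in zip(labels, theta)}
    varcomp_se = {lbl: float(s * scale2) for lbl, s in zip(labels, se_theta)}
    # US parameters are Cholesky entries: scale linearly
    for term, sl in zip(terms, slices):
        if isinstance(term, _USTerm):
            for k, lbl in enumerate(term.labels):
                varcomps[lbl] = float(theta[sl][k] * yscale)
                varcomp_se[lbl] = float(se_theta[sl][k] * yscale)

    beta_cov = np.linalg.inv(XtViX)
    fixed = {c: float(b * yscale) for c, b in zip(fixed_cols, beta)}
    fixed_se = {
        c: float(np.sqrt(max(beta_cov[j, j], 0.0)) * yscale)
        for j, c in enumerate(fixed_cols)
    }

    structures: dict[str, VarStruct] = {}
    genetic_terms: dict[str, tuple] = {}
    for (eff, struct), term, sl in zip(
        effect_structs.items(), terms[1:-1], slices[1:-1]
    ):
        th = theta[sl] * (yscale if isinstance(term, _USTerm) else scale2)
        structures[eff] = _natural_struct(eff, struct, th)
        genetic_terms[eff] = (term, theta[sl])

    block_vars = {
        s: varcomps[f"block:sigma2_s{i+1}"] for i, s in enumerate(sites)
    }
    residual_vars = {
        s: varcomps[f"residual:sigma2_s{i+1}"] for i, s in enumerate(sites)
    }

    # --- BLUPs and per-record decomposition ----------------------------------
    blups, seps_df, rec_parts = _extract_random_effects(
        spec, effect_structs, structures, kernels, kid, idx, site_codes, sites,
        terms, slices, theta, Py, P, yscale, opts,
    )
    records_out = records.rename(columns={trait: "y"})
    records_out["fixed_hat"] = X @ beta * yscale
    records_out["block_hat"] = rec_parts["block"]
    records_out["genetic_hat"] = rec_parts["genetic"]

    p_var = count_params(spec, n_sites)
    return FitResult(
        spec=spec,
        trait=trait,
        sites=sites,
        varcomps=varcomps,
        varcomp_se=varcomp_se,
        fixed=fixed,
        fixed_se=fixed_se,
        structures=structures,
        block_vars=block_vars,
        residual_vars=residual_vars,
        blups=blups,
        seps=seps_df,
        logL=float(logL),
        aic=aic(float(logL), p_var),
        n_params=p_var,
        converged=converged,
        iterations=int(res.nit),
        records=records_out,
    )


def _extract_random_effects(
    spec, effect_structs, structures, kernels, kid, idx, site_codes, sites,
    terms, slices, theta, Py, P, yscale, opts,
):
    """BLUPs for every kernel id, additive SEPs, per-record fitted parts."""
    n_sites = len(sites)
    blups: dict[str, pd.DataFrame] = {}
    seps_df = None
    genetic_rec = np.zeros(len(Py))
    block_term, block_sl = terms[0], slices[0]
    block_rec = block_term.V(theta[block_sl]) @ Py * yscale

    for (eff, struct0), term, sl in zip(
        effect_structs.items(), terms[1:-1], slices[1:-1]
    ):
        K = kernels[spec.kernel_kind(eff)]
        C_all = K.values[:, idx]  # cov(u_i, y_r) / variance, all ids x records
        th = theta[sl]
        genetic_rec += term.V(th) @ Py
        Sigma = to_sitecov(structures[eff]).values / yscale**2
        masks = [(site_codes == s) for s in range(n_sites)]
        decomposable = struct0.name in DECOMPOSABLE
        a_site = np.empty((K.n, n_sites))
        C_site = []
        for s in range(n_sites):
            Cs = np.zeros_like(C_all)
            for t in range(n_sites):
                if Sigma[s, t] != 0.0:
                    Cs[:, masks[t]] += Sigma[s, t] * C_all[:, masks[t]]
            C_site.append(Cs)
            a_site[:, s] = Cs @ Py * yscale
        cols = [f"site:{s}" for s in sites]
        blups[eff] = pd.DataFrame(a_site, index=kid, columns=cols)
        if decomposable and eff == "additive":
            var_m = th[0]
            m_hat = var_m * (C_all @ Py) * yscale
            blups["m"] = pd.DataFrame({"m": m_hat}, index=kid)
            me = a_site - m_hat[:, None]
            blups["me"] = pd.DataFrame(me, index=kid, columns=cols)
        if eff == "additive" and opts.compute_seps:
            sep = np.empty((K.n, n_sites))
            diagK = np.diag(K.values)
            for s in range(n_sites):
                Cs = C_site[s]
                pev = Sigma[s, s] * diagK - ((Cs @ P) * Cs).sum(axis=1)
                sep[:, s] = np.sqrt(np.clip(pev, 0.0, None)) * yscale
            seps_df = pd.DataFrame(sep, index=kid, columns=cols)

    return blups, seps_df, {"block": block_rec, "genetic": genetic_rec * yscale}


def build_kernels(spec: ModelSpec, pedigree=None, genotypes=None) -> dict:
    """All relationship matrices a model spec needs, keyed by kind."""
    from . import relmat as rm

    out: dict[str, RelationshipMatrix] = {}
    if spec.source == "pedigree":
        if pedigree is None:
            raise ValueError("pedigree-based model needs a pedigree")
        A = rm.build_pedigree_A(pedigree)
        out["A"] = A
        if spec.dominance:
            out["D"] = rm.build_pedigree_D(pedigree, A)
    else:
        if genotypes is None:
            raise ValueError("genomic model needs genotypes")
        Ga = rm.build_Ga(genotypes)
        out["Ga"] = Ga
        if spec.dominance or spec.epistasis:
            out["Gd"] = rm.build_Gd(genotypes)
        if spec.epistasis:
            out["Gaa"] = rm.build_epistatic(Ga, Ga, "Gaa")
            out["Gad"] = rm.build_epistatic(Ga, out["Gd"], "Gad")
            out["Gdd"] = rm.build_epistatic(out["Gd"], out["Gd"], "Gdd")
    return out


def test_inbreeding_depression(
    data: pd.DataFrame,
    spec: ModelSpec,
    f: InbreedingVector,
    kernels: dict[str, RelationshipMatrix],
    trait: str | None = None,
    alpha: float = 0.05,
    options: REMLOptions | None = None,
) -> tuple[float, float, bool]:
    """Wald test of the inbreeding-depression covariate.

    Refits the model with the genomic inbreeding coefficient as a fixed
    covariate and returns ``(estimate, standard error, significant)``.
    Callers typically drop the covariate when it is not significant.
    """
    if spec.source != "genomic":
        raise ValueError("inbreeding-depression test uses genomic models")
    from dataclasses import replace
    from scipy.stats import norm

    spec_f = replace(spec, include_f=True)
    fit = fit_reml(data, spec_f, kernels, trait=trait, f=f, options=options)
    est, se = fit.fixed["f"], fit.fixed_se["f"]
    z = est / se if se > 0 else np.inf
    significant = bool(abs(z) > norm.ppf(1.0 - alpha / 2.0))
    return est, se, significant
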