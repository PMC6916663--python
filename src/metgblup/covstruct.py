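"""Across-site variance-covariance structures for multi-environment models.

A genetic effect observed at ``n`` sites has an ``n x n`` site covariance
matrix.  Six parameterizations are supported:

========  ==============  ===========================================
name      parameters      site covariance
========  ==============  ===========================================
IDEN      1               sigma^2 I (no across-site covariance)
DIAG      n               diag(sigma_s^2)
CS        2               sigma^2 on diagonal, common cov off-diagonal
CS_DIAG   1 + n           common cov, heterogeneous diagonal
US        n(n+1)/2        unstructured (Cholesky parameterized)
FAMK      1 + (k+1) n     factor-analytic with a main term; k = 0 here
========  ==============  ===========================================

With two sites, FAMK(k=0) and CS_DIAG describe the same family of
matrices: diagonal ``sigma_m^2 + psi_s``, off-diagonal ``sigma_m^2``.
CS, CS_DIAG and FAMK admit the main + interaction decomposition
``a = m + me`` with ``var(a)_s = var(m) + var(me)_s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NAMES = ("IDEN", "DIAG", "CS", "CS_DIAG", "US", "FAMK")

#: structures that admit the a = m + me decomposition
DECOMPOSABLE = ("CS", "CS_DIAG", "FAMK")

_ALIASES = {"CS+DIAG": "CS_DIAG", "FA0": "FAMK", "FA(0)": "FAMK", "FAMK0": "FAMK"}


def canonical_name(name: str) -> str:
    name = name.strip().upper()
    name = _ALIASES.get(name, name)
    if name not in NAMES:
        raise ValueError(f"unknown variance structure {name!r}; expected one of {NAMES}")
    return name


@dataclass
class VarStruct:
    """A named across-site structure with its parameter vector.

    Parameter order:
      IDEN:    (sigma2,)
      DIAG:    (sigma2_1, ..., sigma2_n)
      CS:      (sigma2, cov)                 with 0 <= cov <= sigma2
      CS_DIAG: (cov, sigma2_1, ..., sigma2_n)
      US:      lower-triangular Cholesky factor, row by row
      FAMK:    (sigma2_m, psi_1, ..., psi_n)  (k = 0 only)
    """

    name: str
    n_sites: int
    k: int = 0
    params: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.name = canonical_name(self.name)
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.name == "FAMK" and self.k != 0:
            raise NotImplementedError(
                "FAMK implemented only with k = 0 (main term + specific variances)"
            )
        if self.params is not None:
            self.params = np.asarray(self.params, dtype=float)
            if self.params.shape != (n_params(self),):
                raise ValueError(
                    f"{self.name} with {self.n_sites} sites needs "
                    f"{n_params(self)} parameters, got {self.params.shape}"
                )


@dataclass
class SiteCov:
    """Symmetric PSD matrix of genetic (co)variances across sites."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T):
            raise ValueError("site covariance must be symmetric")
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("site covariance must be positive semi-definite")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]


def n_params(struct: VarStruct) -> int:
    """Number of free parameters of a structure (FAMK: 1 + (k+1) n)."""
    n = struct.n_sites
    return {
        "IDEN": 1,
        "DIAG": n,
        "CS": 2,
        "CS_DIAG": 1 + n,
        "US": n * (n + 1) // 2,
        "FAMK": 1 + (struct.k + 1) * n,
    }[struct.name]


def _require_params(struct: VarStruct) -> np.ndarray:
    if struct.params is None:
        raise ValueError("structure has no parameters set")
    return struct.params


def to_sitecov(struct: VarStruct) -> SiteCov:
    """Materialize the implied n_sites x n_sites covariance matrix."""
    p = _require_params(struct)
    n = struct.n_sites
    name = struct.name
    if name == "IDEN":
        if p[0] < 0:
            raise ValueError("variance must be non-negative")
        V = p[0] * np.eye(n)
    elif name == "DIAG":
        if (p < 0).any():
            raise ValueError("variances must be non-negative")
        V = np.diag(p)
    elif name == "CS":
        sigma2, cov = p
        if not (0.0 <= cov <= sigma2):
            raise ValueError("CS requires 0 <= covariance <= variance")
        V = np.full((n, n), cov)
        np.fill_diagonal(V, sigma2)
    elif name == "CS_DIAG":
        cov, sig = p[0], p[1:]
        if cov < 0 or (sig < cov).any():
            raise ValueError("CS_DIAG requires 0 <= covariance <= each variance")
        V = np.full((n, n), cov)
        np.fill_diagonal(V, sig)
    elif name == "FAMK":
        sm, psi = p[0], p[1:]
        if sm < 0 or (psi < 0).any():
            raise ValueError("FAMK requires non-negative main and specific variances")
        V = np.full((n, n), sm)
        np.fill_diagonal(V, sm + psi)
    elif name == "US":
        L = np.zeros((n, n))
        L[np.tril_indices(n)] = p
        V = L @ L.T
    return SiteCov(V)


def decompose_main_plus_interaction(struct: VarStruct) -> tuple[float, np.ndarray]:
    """Split var(a) into var(m) + per-site var(me).

    CS:      var(m) = covariance, var(me) = sigma2 - covariance at each site.
    CS_DIAG: var(m) = covariance, var(me)_s = sigma2_s - covariance.
    FAMK:    var(m) = sigma2_m,   var(me)_s = psi_s.
    """
    if struct.name not in DECOMPOSABLE:
        raise ValueError(
            f"main + interaction decomposition undefined for {struct.name}; "
            f"requires one of {DECOMPOSABLE}"
        )
    p = _require_params(struct)
    n = struct.n_sites
    if struct.name == "CS":
        sigma2, cov = p
        return float(cov), np.full(n, sigma2 - cov)
    if struct.name == "CS_DIAG":
        return float(p[0]), p[1:] - p[0]
    return float(p[0]), p[1:].copy()  # FAMK


def fit_params_from_sitecov(struct_name: str, cov: SiteCov, k: int = 0) -> VarStruct:
    """Least-squares recovery of structure parameters from a site covariance.

    Inverse of :func:`to_sitecov` whenever the matrix lies in the
    structure's family.
    """
    name = canonical_name(struct_name)
    V = cov.values
    n = cov.n_sites
    off = V[~np.eye(n, dtype=bool)]
    if name == "IDEN":
        params = [np.diag(V).mean()]
    elif name == "DIAG":
        params = np.diag(V)
    elif name == "CS":
        params = [np.diag(V).mean(), off.mean() if off.size else 0.0]
    elif name == "CS_DIAG":
        c = off.mean() if off.size else 0.0
        params = np.concatenate([[c], np.diag(V)])
    elif name == "FAMK":
        c = off.mean() if off.size else 0.0
        params = np.concatenate([[c], np.diag(V) - c])
    else:  # US
        params = np.linalg.cholesky(V + 1e-12 * np.eye(n))[np.tril_indices(n)]
    return VarStruct(name, n, k=k, params=np.asarray(params, dtype=float))
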