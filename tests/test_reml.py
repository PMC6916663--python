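"""REML engine: likelihood oracle, BLUP identities, SEPs, AIC bookkeeping.

The direct-likelihood oracle assembles the marginal covariance V record
by record from the fitted site-covariance matrices and evaluates the
restricted log-likelihood with plain numpy inverses/determinants —
independently of the engine's Cholesky path.
"""

import numpy as np
import pandas as pd
import pytest

from metgblup.covstruct import to_sitecov
from metgblup.relmat import InbreedingVector, Pedigree, genomic_inbreeding
from metgblup.reml import (
    ModelSpec,
    REMLOptions,
    aic,
    build_kernels,
    count_params,
    fit_reml,
    seps,
    test_inbreeding_depression as wald_inbreeding,
)
from metgblup.simulate import cs_config, simulate

wald_inbreeding.__test__ = False  # helper import, not a test

# ---------------------------------------------------------------------------
# direct restricted-likelihood oracle


def oracle_logL(fit, data, kernels, trait):
    rec = data.loc[data[trait].notna()].reset_index(drop=True)
    rec["site"] = rec["site"].astype(str)
    sites = sorted(rec["site"].unique())
    n = len(rec)
    V = np.zeros((n, n))
    for eff, struct in fit.structures.items():
        K = kernels[fit.spec.kernel_kind(eff)]
        Sigma = to_sitecov(struct).values
        pos = {v: i for i, v in enumerate(K.ids)}
        for r1 in range(n):
            for r2 in range(n):
                s1 = sites.index(rec.loc[r1, "site"])
                s2 = sites.index(rec.loc[r2, "site"])
                V[r1, r2] += (
                    Sigma[s1, s2] * K.values[pos[rec.loc[r1, "id"]], pos[rec.loc[r2, "id"]]]
                )
    for r1 in range(n):
        for r2 in range(n):
            if (
                rec.loc[r1, "site"] == rec.loc[r2, "site"]
                and rec.loc[r1, "block"] == rec.loc[r2, "block"]
            ):
                V[r1, r2] += fit.block_vars[rec.loc[r1, "site"]]
        V[r1, r1] += fit.residual_vars[rec.loc[r1, "site"]]
    X = np.ones((n, len(sites)))
    for j, s in enumerate(sites[1:], start=1):
        X[:, j] = (rec["site"] == s).to_numpy(float)
    y = rec[trait].to_numpy(float)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    p = X.shape[1]
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + r @ Vi @ r
        + (n - p) * np.log(2 * np.pi)
    )


def tiny_dataset(seed=0, n_families=4, progeny=3, sites=2, snps=80, **cfg_kw):
    b = simulate(
        cs_config(
            seed=seed,
            n_parents=2 * n_families,
            n_families=n_families,
            progeny_per_family=progeny,
            n_snps=snps,
            blocks_per_site=2,
            n_sites=sites,
            **cfg_kw,
        )
    )
    return b


SPEC_DRAWS = [
    ModelSpec(source="genomic", additive="IDEN"),
    ModelSpec(source="genomic", additive="DIAG", dominance="IDEN"),
    ModelSpec(source="genomic", additive="CS", dominance="IDEN"),
    ModelSpec(source="genomic", additive="FAMK"),
    ModelSpec(source="genomic", additive="US"),
    ModelSpec(source="pedigree", additive="CS", dominance="IDEN"),
    ModelSpec(source="genomic", additive="CS", dominance="IDEN", epistasis=True),
]


class TestLikelihood:
    @pytest.mark.parametrize("i,spec", list(enumerate(SPEC_DRAWS)))
    def test_engine_matches_direct_oracle(self, i, spec):
        """Engine logL equals the dense restricted likelihood at the optimum."""
        b = tiny_dataset(seed=20 + i)
        kernels = build_kernels(spec, pedigree=b.pedigree, genotypes=b.genotypes)
        fit = fit_reml(b.phenotypes, spec, kernels, options=REMLOptions(jitter=1e-12))
        assert fit.converged
        direct = oracle_logL(fit, b.phenotypes, kernels, fit.trait)
        assert fit.logL == pytest.approx(direct, abs=1e-6)

    def test_single_site_iden_tiny(self):
        """n = 12 single-site additive-only instance against the oracle."""
        rng = np.random.default_rng(1)
        ped = Pedigree(
            [("P1", "0", "0"), ("P2", "0", "0"), ("P3", "0", "0"), ("P4", "0", "0")]
            + [(f"O{i}", "P1", "P2") for i in range(1, 5)]
            + [(f"Q{i}", "P3", "P4") for i in range(1, 5)]
        )
        data = pd.DataFrame(
            {
                "id": ped.ids,
                "site": "S1",
                "block": ["B1", "B2"] * 6,
                "y": rng.normal(10.0, 2.0, size=12),
            }
        )
        spec = ModelSpec(source="pedigree", additive="IDEN")
        kernels = build_kernels(spec, pedigree=ped)
        fit = fit_reml(data, spec, kernels, options=REMLOptions(jitter=1e-12))
        direct = oracle_logL(fit, data, kernels, "y")
        assert fit.logL == pytest.approx(direct, abs=1e-6)

    def test_zero_signal_hits_boundary(self):
        """Pure site-mean + noise data drives genetic variances to (near) zero.

        Variance estimates are non-negative, so under the null they sit
        at or just above the boundary; the genetic share of the total
        must be small on average.
        """
        shares = []
        for seed in (3, 4, 5):
            b = tiny_dataset(
                seed=seed,
                n_families=48,
                progeny=8,
                snps=400,
                additive_var=(0.0, 0.0),
                dominance_var=(0.0, 0.0),
                block_var=(0.0, 0.0),
                residual_var=(1.0, 1.0),
            )
            spec = ModelSpec(source="genomic", additive="CS", dominance="IDEN")
            kernels = build_kernels(spec, genotypes=b.genotypes)
            fit = fit_reml(b.phenotypes, spec, kernels)
            genetic = (
                fit.varcomps["additive:var_m"]
                + fit.varcomps["additive:var_me"]
                + fit.varcomps["dominance:sigma2"]
            )
            resid = np.mean(list(fit.residual_vars.values()))
            shares.append(genetic / (genetic + resid))
        assert np.mean(shares) < 0.15

    def test_aic_bookkeeping(self):
        assert aic(-6870.21, 8) == pytest.approx(13756.42)
        assert aic(0.0, 0) == 0.0
        assert aic(1184.63, 7) == pytest.approx(-2355.26)

    @pytest.mark.parametrize(
        "spec,n_sites,expected",
        [
            # FAMK additive + IDEN dominance + 2 blocks + 2 residuals
            (ModelSpec(source="genomic", additive="FAMK", dominance="IDEN"), 2, 8),
            # CS additive only
            (ModelSpec(source="pedigree", additive="CS"), 2, 6),
            # CS + IDEN dominance + 3 IDEN epistatic terms
            (
                ModelSpec(
                    source="genomic", additive="CS", dominance="IDEN", epistasis=True
                ),
                2,
                10,
            ),
        ],
    )
    def test_variance_parameter_counts(self, spec, n_sites, expected):
        assert count_params(spec, n_sites) == expected


class TestBlupIdentities:
    def _single_site_fit(self):
        b = tiny_dataset(seed=9, n_families=14, progeny=6, sites=1,
                         site_effects=(0.0,), block_var=(400.0,),
                         additive_var=(2000.0,), dominance_var=(0.0,),
                         residual_var=(1000.0,))
        spec = ModelSpec(source="pedigree", additive="IDEN")
        kernels = build_kernels(spec, pedigree=b.pedigree)
        fit = fit_reml(
            b.phenotypes, spec, kernels, options=REMLOptions(jitter=1e-12)
        )
        return b, kernels, fit

    def test_mixed_model_equations_residual(self):
        """BLUPs and GLS fixed effects satisfy the MME at the estimates."""
        b, kernels, fit = self._single_site_fit()
        rec = fit.records
        A = kernels["A"]
        n_ind = A.n
        pos = {v: i for i, v in enumerate(A.ids)}
        Z = np.zeros((len(rec), n_ind))
        for r, rid in enumerate(rec["id"]):
            Z[r, pos[rid]] = 1.0
        blocks = sorted(rec["block"].unique())
        W = np.zeros((len(rec), len(blocks)))
        for r, blk in enumerate(rec["block"]):
            W[r, blocks.index(blk)] = 1.0
        X = np.ones((len(rec), 1))
        y = rec["y"].to_numpy()
        s2e = fit.residual_vars[fit.sites[0]]
        s2a = fit.varcomps["additive:sigma2"]
        s2b = fit.varcomps["block:sigma2_s1"]
        a_hat = fit.blups["additive"][f"site:{fit.sites[0]}"].to_numpy()
        b_hat = np.array(
            [rec.loc[rec["block"] == blk, "block_hat"].iloc[0] for blk in blocks]
        )
        beta = np.array([fit.fixed["intercept"]])
        Ainv = np.linalg.inv(A.values)
        # Henderson's equations, scaled by the residual variance
        lhs_rows = [
            X.T @ X @ beta + X.T @ W @ b_hat + X.T @ Z @ a_hat - X.T @ y,
            W.T @ X @ beta
            + (W.T @ W + s2e / s2b * np.eye(len(blocks))) @ b_hat
            + W.T @ Z @ a_hat
            - W.T @ y,
            Z.T @ X @ beta
            + Z.T @ W @ b_hat
            + (Z.T @ Z + s2e / s2a * Ainv) @ a_hat
            - Z.T @ y,
        ]
        scale = np.linalg.norm(np.concatenate([r.ravel() for r in [X.T @ y, W.T @ y, Z.T @ y]]))
        for r in lhs_rows:
            assert np.linalg.norm(r) < 1e-8 * scale

    def test_sep_matches_mme_inverse(self):
        """Additive SEPs equal the a-block of the inverted MME coefficients."""
        b, kernels, fit = self._single_site_fit()
        rec = fit.records
        A = kernels["A"]
        pos = {v: i for i, v in enumerate(A.ids)}
        Z = np.zeros((len(rec), A.n))
        for r, rid in enumerate(rec["id"]):
            Z[r, pos[rid]] = 1.0
        blocks = sorted(rec["block"].unique())
        W = np.zeros((len(rec), len(blocks)))
        for r, blk in enumerate(rec["block"]):
            W[r, blocks.index(blk)] = 1.0
        X = np.ones((len(rec), 1))
        s2e = fit.residual_vars[fit.sites[0]]
        s2a = fit.varcomps["additive:sigma2"]
        s2b = fit.varcomps["block:sigma2_s1"]
        U = np.hstack([X, W, Z])
        nb, na = len(blocks), A.n
        Ginv = np.zeros((1 + nb + na, 1 + nb + na))
        Ginv[1 : 1 + nb, 1 : 1 + nb] = s2e / s2b * np.eye(nb)
        Ginv[1 + nb :, 1 + nb :] = s2e / s2a * np.linalg.inv(A.values)
        C = U.T @ U + Ginv
        pev = s2e * np.diag(np.linalg.inv(C))[1 + nb :]
        expected = np.sqrt(pev)
        got = seps(fit)[f"site:{fit.sites[0]}"].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_sep_no_information_limit(self):
        """An unrelated, unphenotyped founder's SEP is the additive SD."""
        b, kernels, fit = self._single_site_fit()
        ped2 = Pedigree(b.pedigree.records + [("LONER", "0", "0")])
        spec = ModelSpec(source="pedigree", additive="IDEN")
        k2 = build_kernels(spec, pedigree=ped2)
        fit2 = fit_reml(b.phenotypes, spec, k2)
        sd_a = np.sqrt(fit2.varcomps["additive:sigma2"])
        got = seps(fit2).loc["LONER"].iloc[0]
        assert got == pytest.approx(sd_a, rel=1e-6)

    def test_sep_shrinks_with_duplicated_records(self):
        b, kernels, fit = self._single_site_fit()
        target = fit.records["id"].iloc[0]
        dup = pd.concat(
            [b.phenotypes, b.phenotypes[b.phenotypes["id"] == target]],
            ignore_index=True,
        )
        spec = ModelSpec(source="pedigree", additive="IDEN")
        fit2 = fit_reml(dup, spec, kernels, start=fit.varcomps)
        col = f"site:{fit.sites[0]}"
        assert seps(fit2).loc[target, col] < seps(fit).loc[target, col]


class TestModelSpecInvariants:
    def test_epistasis_requires_genomic(self):
        with pytest.raises(ValueError, match="genomic"):
            ModelSpec(source="pedigree", additive="CS", dominance="IDEN",
                      epistasis=True)

    def test_missing_kernel_detected(self):
        b = tiny_dataset(seed=5)
        spec = ModelSpec(source="genomic", additive="CS", dominance="IDEN")
        kernels = build_kernels(
            ModelSpec(source="genomic", additive="CS"), genotypes=b.genotypes
        )
        with pytest.raises(ValueError, match="Gd"):
            fit_reml(b.phenotypes, spec, kernels)

    def test_site_relabeling_permutes_estimates(self):
        b = tiny_dataset(seed=6, n_families=8, progeny=4)
        spec = ModelSpec(source="genomic", additive="DIAG")
        kernels = build_kernels(spec, genotypes=b.genotypes)
        fit1 = fit_reml(b.phenotypes, spec, kernels)
        swapped = b.phenotypes.assign(
            site=b.phenotypes["site"].map({"S1": "T2", "S2": "T1"})
        )
        fit2 = fit_reml(swapped, spec, kernels)
        assert fit2.site_variance("additive", "T1") == pytest.approx(
            fit1.site_variance("additive", "S2"), rel=1e-3, abs=1.0
        )
        assert fit2.residual_vars["T2"] == pytest.approx(
            fit1.residual_vars["S1"], rel=1e-3
        )


class TestPedigreeGenomicAgreement:
    def test_dense_markers_recover_pedigree_expectation(self):
        """With very many markers the genomic additive estimate approaches
        the pedigree-based one on the same families."""
        b = simulate(
            cs_config(seed=44, n_parents=30, n_families=30,
                      progeny_per_family=6, n_snps=50000,
                      dominance_var=(0.0, 0.0))
        )
        spec_g = ModelSpec(source="genomic", additive="CS")
        spec_p = ModelSpec(source="pedigree", additive="CS")
        fg = fit_reml(b.phenotypes, spec_g,
                      build_kernels(spec_g, genotypes=b.genotypes))
        fp = fit_reml(b.phenotypes, spec_p,
                      build_kernels(spec_p, pedigree=b.pedigree))
        ag = fg.site_variance("additive", "S1")
        ap = fp.site_variance("additive", "S1")
        assert abs(ag - ap) / ap < 0.15


class TestInbreedingDepression:
    def test_constant_f_rejected(self):
        b = tiny_dataset(seed=7)
        spec = ModelSpec(source="genomic", additive="CS")
        kernels = build_kernels(spec, genotypes=b.genotypes)
        f = InbreedingVector(b.genotypes.ids, np.full(len(b.genotypes.ids), 0.3))
        with pytest.raises(ValueError, match="constant"):
            wald_inbreeding(b.phenotypes, spec, f, kernels)

    def test_type_I_error_controlled(self):
        """Null simulations reject at roughly the nominal 5% level."""
        rejections = 0
        n_sims = 60
        for s in range(n_sims):
            b = tiny_dataset(seed=1000 + s, n_families=10, progeny=5)
            spec = ModelSpec(source="genomic", additive="CS")
            kernels = build_kernels(spec, genotypes=b.genotypes)
            f = genomic_inbreeding(b.genotypes)
            _, _, sig = wald_inbreeding(b.phenotypes, spec, f, kernels)
            rejections += sig
        # 3*sqrt(0.05*0.95/60) ~ 0.084 Monte-Carlo margin
        assert rejections / n_sims <= 0.05 + 0.085

    def test_power_against_strong_depression(self):
        """Strong inbreeding depression is detected reliably.

        In a non-inbred diallel the homozygosity proportion varies only
        by its binomial sampling spread, so "strong" is calibrated as a
        phenotypic shift of 2 residual SD per f-standard-deviation.
        """
        detected = 0
        n_sims = 8
        for s in range(n_sims):
            cfg = cs_config(seed=2000 + s)
            probe = simulate(cfg)
            sd_f = genomic_inbreeding(probe.genotypes).f.std()
            strength = -2.0 * np.sqrt(3000.0) / sd_f
            b = simulate(cfg, inbreeding_depression=strength)
            spec = ModelSpec(source="genomic", additive="CS")
            kernels = build_kernels(spec, genotypes=b.genotypes)
            f = genomic_inbreeding(b.genotypes)
            est, se, sig = wald_inbreeding(b.phenotypes, spec, f, kernels)
            detected += sig and est < 0
        assert detected >= 7
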