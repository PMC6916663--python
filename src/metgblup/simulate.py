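"""Synthetic multi-site progeny-trial generator.

Emulates a two-site control-pollinated progeny test: a partial diallel
of 55 parents producing 128 full-sib families, SNP genotypes segregating
through the pedigree by Mendelian gene dropping (independent loci, no
linkage map), and phenotypes built from marker effects so that additive,
dominance and marker-by-environment signal arise mechanistically:

* per-SNP additive effects are drawn per site from a correlated normal
  (across-site correlation ``r_additive`` < 1 creates M x E) and scaled
  so that the additive kernel variance equals the configured per-site
  sigma_a^2 (effect variance sigma_a^2 / sum 2 p q);
* dominance deviations likewise on the dominance design with scale
  sigma_d^2 / sum (2 p q)^2;
* optional pairwise-product epistatic terms rescaled to the configured
  additive-by-additive / dominance-by-dominance variances;
* per-site post-block effects, heterogeneous residuals, and an optional
  inbreeding-depression term on the genomic homozygosity proportion.

Each individual is planted at exactly one site (families split across
sites), so across-site genetic correlation is induced through shared
marker effects, as in a real paired-trial design.  Default variance
components follow the tree-height magnitudes of the study design this
package targets; ``cs_config`` gives a symmetric compound-symmetry
preset used for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .relmat import GenotypeMatrix, Pedigree, genomic_inbreeding
from .relmat import additive_design, dominance_design


@dataclass
class SimConfig:
    """Study-design and variance-component settings for one simulation."""

    n_parents: int = 55
    n_families: int = 128
    progeny_per_family: int = 5
    n_sites: int = 2
    blocks_per_site: int = 44
    n_snps: int = 2000
    freq_range: tuple[float, float] = (0.05, 0.95)
    trait: str = "height"
    mean: float = 400.0
    site_effects: tuple[float, ...] = (0.0, -30.0)
    block_var: tuple[float, ...] = (703.0, 1919.0)
    additive_var: tuple[float, ...] = (778.0, 1859.0)
    r_additive: float = 0.385
    dominance_var: tuple[float, ...] = (1224.0, 1224.0)
    r_dominance: float = 1.0
    epi_aa_var: float = 0.0
    epi_dd_var: float = 0.0
    residual_var: tuple[float, ...] = (4053.0, 7524.0)
    inbreeding_depression: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families > self.n_parents * (self.n_parents - 1) // 2:
            raise ValueError(
                f"{self.n_families} families infeasible from "
                f"{self.n_parents} parents (distinct pairs exhausted)"
            )
        for name in ("block_var", "additive_var", "dominance_var", "residual_var"):
            v = np.asarray(getattr(self, name))
            if (v < 0).any():
                raise ValueError(f"{name} must be non-negative")
            if v.shape != (self.n_sites,):
                raise ValueError(f"{name} needs one value per site")
        for r in (self.r_additive, self.r_dominance):
            if not 0.0 <= r <= 1.0:
                raise ValueError("across-site effect correlations must lie in [0, 1]")


def cs_config(**overrides) -> SimConfig:
    """Symmetric compound-symmetry preset (equal site variances)."""
    base = dict(
        block_var=(500.0, 500.0),
        additive_var=(1000.0, 1000.0),
        r_additive=0.6,
        dominance_var=(600.0, 600.0),
        r_dominance=1.0,
        residual_var=(3000.0, 3000.0),
        site_effects=(0.0, 0.0),
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery and prediction tests."""

    breeding_values: pd.DataFrame  # individuals x sites
    dominance_values: pd.DataFrame
    epistatic_values: pd.DataFrame | None
    marker_additive: np.ndarray  # SNPs x sites
    marker_dominance: np.ndarray
    realized: dict[str, float]


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, stream]))


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Partial diallel: distinct parent pairs, every parent used at least once."""
    rng = _rng(cfg, 0)
    parents = [f"P{i+1:02d}" for i in range(cfg.n_parents)]
    order = list(rng.permutation(cfg.n_parents))
    pairs: list[tuple[int, int]] = []
    used = set()
    # chain through a permutation so each parent enters >= 1 cross
    for a, b in zip(order, order[1:] + order[:1]):
        if len(pairs) == cfg.n_families:
            break
        key = (min(a, b), max(a, b))
        if key not in used:
            used.add(key)
            pairs.append(key)
    while len(pairs) < cfg.n_families:
        a, b = rng.choice(cfg.n_parents, size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key not in used:
            used.add(key)
            pairs.append(key)
    records = [(p, "0", "0") for p in parents]
    for fam, (a, b) in enumerate(pairs, start=1):
        for j in range(cfg.progeny_per_family):
            records.append((f"F{fam:03d}_{j+1}", parents[a], parents[b]))
    return Pedigree(records)


def families(ped: Pedigree) -> dict[str, str]:
    """Full-sib family label (sire x dam) for each non-founder."""
    return {
        rid: f"{s}x{d}"
        for rid, s, d in ped.records
        if s not in ("0", "") and d not in ("0", "")
    }


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Founder HW draws + Mendelian gene dropping of independent loci."""
    rng = _rng(cfg, 1)
    m = cfg.n_snps
    p = rng.uniform(*cfg.freq_range, size=m)
    pos = {v: i for i, v in enumerate(ped.ids)}
    codes = np.zeros((len(ped), m), dtype=np.int8)
    for i, (rid, sire, dam) in enumerate(ped.records):
        if sire in ("0", "") or dam in ("0", ""):
            codes[i] = rng.binomial(2, p)
        else:
            cs = codes[pos[sire]]
            cd = codes[pos[dam]]
            codes[i] = (rng.random(m) < cs / 2.0).astype(np.int8) + (
                rng.random(m) < cd / 2.0
            ).astype(np.int8)
    geno = GenotypeMatrix(ped.ids, codes).drop_monomorphic()
    return geno


def _correlated_effects(rng, m, site_sd, r):
    """Per-site effect vectors with common-factor correlation r (>= 0)."""
    S = len(site_sd)
    common = rng.standard_normal(m)
    out = np.empty((m, S))
    for s in range(S):
        specific = rng.standard_normal(m)
        out[:, s] = site_sd[s] * (np.sqrt(r) * common + np.sqrt(1.0 - r) * specific)
    return out


def _epistatic_values(rng, M, target_var, n_pairs, progeny_idx):
    m = M.shape[1]
    j = rng.integers(0, m, size=n_pairs)
    k = rng.integers(0, m, size=n_pairs)
    keep = j != k
    j, k = j[keep], k[keep]
    prod = M[:, j] * M[:, k]
    gamma = rng.standard_normal(len(j))
    vals = prod @ gamma
    sd = vals[progeny_idx].std()
    if sd > 0:
        vals *= np.sqrt(target_var) / sd
    return vals


def simulate_phenotypes(
    ped: Pedigree, geno: GenotypeMatrix, cfg: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotype table (progeny only) plus the generating ground truth."""
    if geno.ids != ped.ids:
        raise ValueError("genotypes do not cover the pedigree (id mismatch)")
    rng = _rng(cfg, 2)
    S = cfg.n_sites
    fam = families(ped)
    progeny = list(fam)
    pos = {v: i for i, v in enumerate(geno.ids)}
    progeny_idx = np.array([pos[i] for i in progeny])

    Z = additive_design(geno)
    W = dominance_design(geno)
    pq = 2.0 * geno.freqs * (1.0 - geno.freqs)
    denom_a = float(pq.sum())
    denom_d = float((pq**2).sum())

    alpha = _correlated_effects(
        rng, geno.m, np.sqrt(np.asarray(cfg.additive_var) / denom_a), cfg.r_additive
    )
    delta = _correlated_effects(
        rng, geno.m, np.sqrt(np.asarray(cfg.dominance_var) / denom_d), cfg.r_dominance
    )
    tbv = Z @ alpha  # all individuals x sites
    tdv = W @ delta

    epi = None
    epi_total = np.zeros(len(geno.ids))
    if cfg.epi_aa_var > 0 or cfg.epi_dd_var > 0:
        cols = {}
        if cfg.epi_aa_var > 0:
            cols["aa"] = _epistatic_values(
                rng, Z, cfg.epi_aa_var, min(4 * geno.m, 5000), progeny_idx
            )
        if cfg.epi_dd_var > 0:
            cols["dd"] = _epistatic_values(
                rng, W, cfg.epi_dd_var, min(4 * geno.m, 5000), progeny_idx
            )
        epi = pd.DataFrame(cols, index=geno.ids)
        epi_total = epi.sum(axis=1).to_numpy()

    # family halves alternate sites so every family appears at both sites
    site_of = {}
    for f_label in sorted(set(fam.values())):
        members = [i for i in progeny if fam[i] == f_label]
        half = (len(members) + 1) // 2
        order = rng.permutation(len(members))
        for r, midx in enumerate(order):
            site_of[members[midx]] = 0 if r < half else 1 if S > 1 else 0

    block_eff = [
        rng.normal(0.0, np.sqrt(cfg.block_var[s]), size=cfg.blocks_per_site)
        for s in range(S)
    ]
    f_inbr = genomic_inbreeding(geno)
    f_map = dict(zip(f_inbr.ids, f_inbr.f))

    rows = []
    for i in progeny:
        s = site_of[i]
        b = int(rng.integers(cfg.blocks_per_site))
        gi = pos[i]
        y = (
            cfg.mean
            + cfg.site_effects[s]
            + block_eff[s][b]
            + tbv[gi, s]
            + tdv[gi, s]
            + epi_total[gi]
            + cfg.inbreeding_depression * f_map[i]
            + rng.normal(0.0, np.sqrt(cfg.residual_var[s]))
        )
        rows.append(
            {"id": i, "site": f"S{s+1}", "block": f"S{s+1}_B{b+1:02d}", cfg.trait: y}
        )
    pheno = pd.DataFrame(rows)

    site_arr = np.array([site_of[i] for i in progeny])
    realized = {}
    for s in range(S):
        own = progeny_idx[site_arr == s]
        realized[f"additive_var_s{s+1}"] = float(tbv[own, s].var())
        realized[f"dominance_var_s{s+1}"] = float(tdv[own, s].var())
    if S > 1:
        realized["additive_cov_12"] = float(np.cov(tbv[progeny_idx, 0], tbv[progeny_idx, 1])[0, 1])

    truth = SimTruth(
        breeding_values=pd.DataFrame(
            tbv, index=geno.ids, columns=[f"site:S{s+1}" for s in range(S)]
        ),
        dominance_values=pd.DataFrame(
            tdv, index=geno.ids, columns=[f"site:S{s+1}" for s in range(S)]
        ),
        epistatic_values=epi,
        marker_additive=alpha,
        marker_dominance=delta,
        realized=realized,
    )
    return pheno, truth


@dataclass
class SimBundle:
    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: SimTruth
    families: dict[str, str]


def simulate(cfg: SimConfig | None = None, **overrides) -> SimBundle:
    """One-call generation of pedigree, genotypes, phenotypes and truth."""
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    pheno, truth = simulate_phenotypes(ped, geno, cfg)
    return SimBundle(cfg, ped, geno, pheno, truth, families(ped))
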