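"""Pedigree-based and genomic-based relationship matrices.

Builds the additive (A) and dominance (D) numerator relationship matrices
from a pedigree, the genomic additive (Ga, VanRaden) and dominance
(Gd, Vitezica-style) matrices from SNP genotypes, first-order epistatic
kernels as trace-normalized Hadamard products, and the genomic inbreeding
coefficient (proportion of homozygous SNPs per individual).

Conventions
-----------
Genotype codes count copies of the reference allele A: 0 = aa, 1 = Aa,
2 = AA.  ``p_i`` is the frequency of A at SNP i and ``q_i = 1 - p_i``.
All matrices carry an explicit id vector; operations that combine
matrices require identical id order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

UNKNOWN = "0"

#: kinds produced by Hadamard products of base kernels
_EPISTATIC_KINDS = {
    ("A", "A"): "Paa",
    ("A", "D"): "Pad",
    ("D", "D"): "Pdd",
    ("Ga", "Ga"): "Gaa",
    ("Ga", "Gd"): "Gad",
    ("Gd", "Gd"): "Gdd",
}


class PedigreeError(ValueError):
    """Raised for structural problems in a pedigree (cycles, bad parents)."""


@dataclass
class Pedigree:
    """Ordered pedigree records ``(id, sire, dam)``.

    Unknown parents are the string ``"0"`` (or empty).  Records are
    topologically sorted (parents before offspring) on construction, so
    callers may supply them in any order.
    """

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate individual id(s): {dup}")
        self.records = self._toposort(self.records)

    @staticmethod
    def _toposort(records):
        known = {r[0] for r in records}
        for rid, sire, dam in records:
            for par in (sire, dam):
                if par not in (UNKNOWN, "") and par not in known:
                    raise PedigreeError(
                        f"unknown parent label {par!r} for individual {rid!r}"
                    )
        pending = {r[0]: r for r in records}
        placed: dict[str, tuple[str, str, str]] = {}
        order: list[tuple[str, str, str]] = []
        # Kahn-style sweep; stagnation means a cycle.
        while pending:
            progressed = False
            for rid in list(pending):
                _, sire, dam = pending[rid]
                if all(p in (UNKNOWN, "") or p in placed for p in (sire, dam)):
                    rec = pending.pop(rid)
                    placed[rid] = rec
                    order.append(rec)
                    progressed = True
            if not progressed:
                bad = sorted(pending)[0]
                raise PedigreeError(f"cycle in pedigree involving {bad!r}")
        return order

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def parents(self, rid: str) -> tuple[str, str]:
        for r, s, d in self.records:
            if r == rid:
                return s, d
        raise KeyError(rid)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GenotypeMatrix:
    """Individuals x SNP codes in {0,1,2} with per-SNP allele frequencies.

    ``freqs`` defaults to the frequencies observed in ``codes``; founder
    or base-population frequencies may be supplied instead.
    """

    ids: list[str]
    codes: np.ndarray
    freqs: np.ndarray | None = None
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x SNPs)")
        if len(self.ids) != self.codes.shape[0]:
            raise ValueError("ids length does not match codes rows")
        if not np.isin(self.codes, (0, 1, 2)).all():
            raise ValueError("genotype codes must be in {0, 1, 2}")
        if self.freqs is None:
            self.freqs = self.codes.mean(axis=0) / 2.0
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (self.codes.shape[1],):
            raise ValueError("freqs length does not match number of SNPs")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j}" for j in range(self.codes.shape[1])]

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    def drop_monomorphic(self) -> "GenotypeMatrix":
        keep = (self.freqs > 0) & (self.freqs < 1)
        return GenotypeMatrix(
            self.ids,
            self.codes[:, keep],
            self.freqs[keep],
            [s for s, k in zip(self.snp_ids, keep) if k],
        )


@dataclass
class RelationshipMatrix:
    ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be n x n with n = len(ids)")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> np.ndarray:
        """Rows/columns for ``ids`` (cross-relationships preserved)."""
        pos = {v: i for i, v in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return self.values[np.ix_(idx, idx)]


@dataclass
class InbreedingVector:
    ids: list[str]
    f: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (len(self.ids),):
            raise ValueError("f length does not match ids")
        if (self.f < 0).any() or (self.f > 1).any():
            raise ValueError("inbreeding coefficients must lie in [0, 1]")


def build_pedigree_A(ped: Pedigree) -> RelationshipMatrix:
    """Additive numerator relationship matrix by the tabular method.

    ``A_ii = 1 + A_gh / 2`` with g, h the parents of i (founders: 1);
    ``A_ij = (A_jg + A_jh) / 2``.
    """
    ids = ped.ids
    pos = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, (rid, sire, dam) in enumerate(ped.records):
        s = pos.get(sire, -1) if sire not in (UNKNOWN, "") else -1
        d = pos.get(dam, -1) if dam not in (UNKNOWN, "") else -1
        A[i, i] = 1.0 + (A[s, d] / 2.0 if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            a = (A[j, s] if s >= 0 else 0.0) + (A[j, d] if d >= 0 else 0.0)
            A[i, j] = A[j, i] = a / 2.0
    return RelationshipMatrix(ids, A, "A")


def build_pedigree_D(ped: Pedigree, A: RelationshipMatrix) -> RelationshipMatrix:
    """Dominance relationship matrix from parental additive relationships.

    ``D_ii = 1``; ``D_ij = (A_gk A_hl + A_gl A_hk) / 4`` where g, h are the
    parents of i and k, l the parents of j.  Individuals with any unknown
    parent contribute zero off-diagonals.
    """
    if A.ids != ped.ids:
        raise ValueError("A matrix ids do not match pedigree ids")
    pos = {v: i for i, v in enumerate(ped.ids)}
    n = len(ped.ids)

    def _par(lbl):
        return pos[lbl] if lbl not in (UNKNOWN, "") else -1

    parents = [(_par(s), _par(d)) for _, s, d in ped.records]
    D = np.eye(n)
    Av = A.values
    for i in range(n):
        g, h = parents[i]
        if g < 0 or h < 0:
            continue
        for j in range(i):
            k, l = parents[j]
            if k < 0 or l < 0:
                continue
            D[i, j] = D[j, i] = (Av[g, k] * Av[h, l] + Av[g, l] * Av[h, k]) / 4.0
    return RelationshipMatrix(ped.ids, D, "D")


def _check_polymorphic(geno: GenotypeMatrix) -> None:
    mono = np.flatnonzero((geno.freqs <= 0) | (geno.freqs >= 1))
    if mono.size:
        names = [geno.snp_ids[j] for j in mono[:5]]
        raise ValueError(
            f"{mono.size} monomorphic SNP(s) present (e.g. {names}); "
            "filter them first (GenotypeMatrix.drop_monomorphic)"
        )


def additive_design(geno: GenotypeMatrix) -> np.ndarray:
    """Centered additive marker design Z: {aa: -2p, Aa: q-p, AA: 2q}."""
    p = geno.freqs
    return geno.codes - 2.0 * p


def dominance_design(geno: GenotypeMatrix) -> np.ndarray:
    """Dominance marker design W: {aa: -2p^2, Aa: 2pq, AA: -2q^2}."""
    p = geno.freqs
    q = 1.0 - p
    W = np.empty(geno.codes.shape)
    c = geno.codes
    W[:] = np.where(c == 0, -2.0 * p**2, np.where(c == 1, 2.0 * p * q, -2.0 * q**2))
    return W


def build_Ga(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic additive relationship matrix Ga = ZZ' / sum(2 p q)."""
    _check_polymorphic(geno)
    Z = additive_design(geno)
    denom = float(np.sum(2.0 * geno.freqs * (1.0 - geno.freqs)))
    return RelationshipMatrix(geno.ids, (Z @ Z.T) / denom, "Ga")


def build_Gd(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic dominance relationship matrix Gd = WW' / sum((2 p q)^2)."""
    _check_polymorphic(geno)
    W = dominance_design(geno)
    pq2 = (2.0 * geno.freqs * (1.0 - geno.freqs)) ** 2
    return RelationshipMatrix(geno.ids, (W @ W.T) / float(pq2.sum()), "Gd")


def build_epistatic(
    K1: RelationshipMatrix, K2: RelationshipMatrix, kind: str | None = None
) -> RelationshipMatrix:
    """First-order epistatic kernel: Hadamard product, trace-normalized to n.

    ``K = (K1 # K2) / (tr(K1 # K2) / n)`` so that ``tr(K) = n`` exactly.
    """
    if K1.ids != K2.ids:
        raise ValueError("epistatic inputs must share ids in identical order")
    expected = _EPISTATIC_KINDS.get((K1.kind, K2.kind)) or _EPISTATIC_KINDS.get(
        (K2.kind, K1.kind)
    )
    if kind is None:
        kind = expected
    if expected is not None and kind != expected:
        raise ValueError(f"kind {kind!r} inconsistent with inputs {K1.kind}#{K2.kind}")
    if kind is None:
        raise ValueError(f"no epistatic kind defined for {K1.kind}#{K2.kind}")
    H = K1.values * K2.values
    tr = np.trace(H)
    if tr <= 0:
        raise ValueError("Hadamard product has non-positive trace")
    return RelationshipMatrix(K1.ids, H / (tr / K1.n), kind)


def genomic_inbreeding(geno: GenotypeMatrix) -> InbreedingVector:
    """Genomic inbreeding: proportion of homozygous SNPs per individual."""
    hom = (geno.codes != 1).sum(axis=1)
    return InbreedingVector(geno.ids, hom / geno.m)
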