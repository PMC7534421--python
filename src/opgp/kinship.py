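"""Relationship matrices for pedigree + marker analyses.

Builds the five covariance structures used by the BLUP models:

* ``A``   pedigree numerator relationship matrix (tabular method),
* ``G``   VanRaden additive genomic relationship matrix,
* ``D``   dominance genomic relationship matrix (Vitezica coding),
* ``H``   single-step blend of A and the rescaled G (Legarra-type blocks),
* ``HD``  single-step blend of the pedigree dominance matrix and D.

For an open-pollinated pedigree with unknown sires the pedigree dominance
matrix is the identity (half-sibs have pedigree dominance relationship 0),
so ``HD`` reduces to the same block formula with identity off the
genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .data import UNKNOWN, GenotypeMatrix, PedigreeTable

KINDS = {"A", "AD", "G", "GD", "Ga", "D", "H", "HD"}


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix over an ordered set of individuals."""

    kind: str
    ids: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with ids")
        if len(set(self.ids)) != n:
            raise ValueError("ids must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError(f"{self.kind} matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"id {err.args[0]!r} not in {self.kind} matrix") from err

    def submatrix(self, ids, kind: str | None = None) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(kind or self.kind,
                                  np.asarray(ids, dtype=object),
                                  self.values[np.ix_(idx, idx)], dict(self.meta))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class ScalingFactors:
    """Linear map Ga = beta*G + alpha matching G to the A22 moments."""

    beta: float
    alpha: float


def build_A(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Unknown parents are treated as unrelated non-inbred founders; the
    pedigree is processed in the (already validated) topological order.
    """
    ids = ped.ids
    pos = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    dams = ped.table["dam_id"].to_numpy()
    sires = ped.table["sire_id"].to_numpy()
    for i in range(n):
        di = pos[dams[i]] if dams[i] != UNKNOWN else -1
        si = pos[sires[i]] if sires[i] != UNKNOWN else -1
        row = np.zeros(i)
        if di >= 0:
            row += a[di, :i]
        if si >= 0:
            row += a[si, :i]
        a[i, :i] = 0.5 * row
        a[:i, i] = a[i, :i]
        f = 0.5 * a[di, si] if (di >= 0 and si >= 0) else 0.0
        a[i, i] = 1.0 + f
    return RelationshipMatrix("A", ids, a)


def inbreeding(mat: RelationshipMatrix) -> pd.Series:
    """Inbreeding coefficients F_i = diag_i - 1 (valid for A- or H-type matrices)."""
    return pd.Series(np.diag(mat.values) - 1.0, index=mat.ids, name="F")


def pedigree_dominance(ped: PedigreeTable) -> RelationshipMatrix:
    """Pedigree dominance matrix for OP data: identity.

    With unrecorded sires, maternal half-sibs have pedigree dominance
    relationship 0, so no non-trivial pedigree dominance structure exists.
    """
    return RelationshipMatrix("AD", ped.ids, np.eye(ped.n))


def _additive_coding(g: GenotypeMatrix) -> tuple[np.ndarray, float]:
    p = g.allele_freq
    w = g.codes - 2.0 * p  # {2-2p, 1-2p, -2p}; imputed/missing entries -> 0
    w[np.isnan(g.codes)] = 0.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    return w, denom


def _dominance_coding(g: GenotypeMatrix) -> tuple[np.ndarray, float]:
    p = g.allele_freq
    codes = g.codes
    w = np.zeros_like(codes)
    het = np.isclose(codes, 1.0)
    hom0 = np.isclose(codes, 0.0)
    hom2 = np.isclose(codes, 2.0)
    pq = np.broadcast_to(p * (1 - p), codes.shape)
    w[het] = 2.0 * pq[het]
    w[hom0] = np.broadcast_to(-2.0 * p**2, codes.shape)[hom0]
    w[hom2] = np.broadcast_to(-2.0 * (1 - p) ** 2, codes.shape)[hom2]
    # missing or mean-imputed fractional codes carry the coding's zero mean
    denom = 4.0 * np.sum((p * (1.0 - p)) ** 2)
    return w, denom


def build_G(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden additive GRM: G = Wa Wa' / (2 * sum p_j (1-p_j))."""
    w, denom = _additive_coding(g)
    if denom <= 0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    return RelationshipMatrix("G", g.individual_ids, (w @ w.T) / denom)


def build_D(g: GenotypeMatrix) -> RelationshipMatrix:
    """Dominance GRM: D = Wd Wd' / (4 * sum (p_j (1-p_j))^2)."""
    w, denom = _dominance_coding(g)
    if denom <= 0:
        raise ValueError("all markers monomorphic: dominance denominator is zero")
    return RelationshipMatrix("D", g.individual_ids, (w @ w.T) / denom)


def fit_scaling(G: RelationshipMatrix, A22: RelationshipMatrix
                ) -> tuple[ScalingFactors, RelationshipMatrix]:
    """Match G to the A22 scale: solve Avg.diag(G) b + a = Avg.diag(A22) and
    Avg.offdiag(G) b + a = Avg.offdiag(A22); return (factors, Ga = b*G + a)."""
    if G.n != A22.n or not np.array_equal(G.ids, A22.ids):
        raise ValueError("G and A22 must cover the same ids in the same order")
    n = G.n

    def moments(m):
        d = np.trace(m) / n
        off = (m.sum() - np.trace(m)) / (n * (n - 1)) if n > 1 else 0.0
        return d, off

    gd, go = moments(G.values)
    ad, ao = moments(A22.values)
    coef = np.array([[gd, 1.0], [go, 1.0]])
    if abs(np.linalg.det(coef)) < 1e-12:
        raise ValueError("Avg.diag(G) equals Avg.offdiag(G): scaling system singular")
    beta, alpha = np.linalg.solve(coef, np.array([ad, ao]))
    ga = RelationshipMatrix("Ga", G.ids, beta * G.values + alpha,
                            {"beta": float(beta), "alpha": float(alpha)})
    return ScalingFactors(float(beta), float(alpha)), ga


def _blend(kind: str, full: RelationshipMatrix, geno: RelationshipMatrix,
           genotyped_ids, w: float = 0.05, ridge: float = 1e-8) -> RelationshipMatrix:
    genotyped_ids = np.asarray(genotyped_ids, dtype=object)
    gset = set(genotyped_ids)
    if not gset <= set(full.ids):
        raise ValueError("genotyped ids must be a subset of the pedigree matrix ids")
    if set(geno.ids) != gset:
        raise ValueError("genomic matrix must cover exactly the genotyped ids")
    # group 1 = pedigree-only, group 2 = genotyped (standard ssGBLUP subscripts)
    ids1 = np.array([i for i in full.ids if i not in gset], dtype=object)
    order = np.concatenate([ids1, genotyped_ids])
    A = full.submatrix(order).values
    n1 = len(ids1)
    A11, A12, A22 = A[:n1, :n1], A[:n1, n1:], A[n1:, n1:]
    Gg = geno.submatrix(genotyped_ids).values
    Gw = (1.0 - w) * Gg + w * A22
    conditioning = []
    try:
        cho = linalg.cho_factor(A22)
    except linalg.LinAlgError:
        conditioning.append(f"A22 ridge {ridge}")
        cho = linalg.cho_factor(A22 + ridge * np.eye(len(A22)))
    H = np.empty_like(A)
    if n1:
        A22inv_A21 = linalg.cho_solve(cho, A12.T)          # A22^-1 A21
        H12 = A22inv_A21.T @ Gw                            # A12 A22^-1 Gw
        H11 = A11 - A12 @ A22inv_A21 + A22inv_A21.T @ Gw @ A22inv_A21
        H[:n1, :n1] = H11
        H[:n1, n1:] = H12
        H[n1:, :n1] = H12.T
    H[n1:, n1:] = Gw
    meta = {"w": w, "n_pedigree_only": n1, "n_genotyped": len(genotyped_ids)}
    if conditioning:
        meta["conditioning"] = conditioning
    return RelationshipMatrix(kind, order, 0.5 * (H + H.T), meta)


def blend_H(A: RelationshipMatrix, Ga: RelationshipMatrix, genotyped_ids,
            w: float = 0.05, ridge: float = 1e-8) -> RelationshipMatrix:
    """Single-step combined additive matrix H from A and the rescaled GRM.

    Blocks: H11 = A11 - A12 A22^-1 A21 + A12 A22^-1 Gw A22^-1 A21,
    H12 = A12 A22^-1 Gw, H22 = Gw, where Gw = (1-w) Ga + w A22 guards
    invertibility of the genotyped block.
    """
    return _blend("H", A, Ga, genotyped_ids, w=w, ridge=ridge)


def blend_HD(AD: RelationshipMatrix, GD: RelationshipMatrix, genotyped_ids,
             w: float = 0.05, ridge: float = 1e-8) -> RelationshipMatrix:
    """Single-step combined dominance matrix (same blocks with AD, GD)."""
    return _blend("HD", AD, GD, genotyped_ids, w=w, ridge=ridge)


def summarize_relationships(mat: RelationshipMatrix, subset_ids=None,
                            threshold: float = 0.10, inbred_tol: float = 0.05) -> dict:
    """Off-diagonal pair fractions above/below a threshold plus inbred flags."""
    sub = mat if subset_ids is None else mat.submatrix(subset_ids)
    v = sub.values
    n = sub.n
    iu = np.triu_indices(n, k=1)
    off = v[iu]
    n_pairs = len(off)
    frac_above = float((off > threshold).mean()) if n_pairs else 0.0
    frac_below = float((off < threshold).mean()) if n_pairs else 0.0
    inbred = [str(i) for i, d in zip(sub.ids, np.diag(v)) if d > 1.0 + inbred_tol]
    return {"frac_above": frac_above, "frac_below": frac_below,
            "inbred_ids": inbred, "threshold": threshold, "n_pairs": n_pairs}


def min_eigenvalue(mat: RelationshipMatrix) -> float:
    return float(linalg.eigvalsh(mat.values)[0])


def write_matrix(mat: RelationshipMatrix, path, fmt: str = "dense") -> None:
    if fmt == "dense":
        mat.to_dataframe().to_csv(path, index_label="individual_id")
    elif fmt == "long":
        iu = np.triu_indices(mat.n)
        pd.DataFrame({"id1": mat.ids[iu[0]], "id2": mat.ids[iu[1]],
                      "value": mat.values[iu]}).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path, kind: str) -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return RelationshipMatrix(kind, df.index.to_numpy(dtype=object),
                              df.to_numpy(dtype=float))
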