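"""Pedigree, genomic and hybrid relationship matrices.

Implements the four kinship-scale matrices used in one-step blending of
pedigree and genomic information:

* ``A`` — numerator (pedigree) relationship matrix, tabular method with
  inbreeding;
* ``A22`` — its principal submatrix on the genotyped animals;
* ``G`` — genomic relationship matrix, VanRaden method 1:
  ``G = ZZ' / (2 * sum_j p_j (1 - p_j))`` with ``Z = M - 2p``;
* ``G_a = G * beta + alpha`` — G rescaled so its diagonal and off-diagonal
  averages match those of A22 (scale-compatibility adjustment);
* ``H`` — the hybrid matrix propagating genomic information to
  non-genotyped animals through pedigree regression:

  ``H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A12'``,
  ``H12 = A12 A22^-1 G``, ``H22 = G``.

``build_H`` evaluates the block formula directly; no inverse of G is
required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .popsim import Pedigree

__all__ = [
    "RelationshipMatrix",
    "GAdjustment",
    "build_A",
    "extract_A22",
    "build_G",
    "adjust_G",
    "build_H",
    "stabilize_G",
]


class DegenerateSNPError(ValueError):
    """A SNP with allele frequency 0 or 1 reached G construction."""


class SingularAdjustmentError(ValueError):
    """The 2x2 moment-matching system for (beta, alpha) is singular."""


class StructuralError(ValueError):
    """Matrix construction failed for structural/numerical reasons."""


@dataclass
class RelationshipMatrix:
    """Symmetric kinship-scale matrix with an explicit animal-ID index."""

    animal_ids: list[str]
    values: np.ndarray
    kind: str  # A | A22 | G | G_adjusted | H

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match animal_ids")
        if n and np.abs(self.values - self.values.T).max() > 1e-9:
            raise ValueError(f"{self.kind} matrix is not symmetric")

    def __len__(self) -> int:
        return len(self.animal_ids)

    def index_of(self, ids: list[str]) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([pos[a] for a in ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"animal {e.args[0]} not in {self.kind} matrix") from None

    def submatrix(self, ids: list[str], kind: str | None = None) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)], kind or self.kind)


@dataclass
class GAdjustment:
    """Solution of the moment-matching adjustment G_a = G*beta + alpha."""

    beta: float
    alpha: float
    avg_diag_G: float
    avg_offdiag_G: float
    avg_diag_A22: float
    avg_offdiag_A22: float


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    For animal i with parents s, d (processed in pedigree order):
    ``a_ii = 1 + 0.5 * a_sd`` (the inbreeding term; 0 if either parent is
    unknown) and ``a_ij = 0.5 * (a_js + a_jd)`` for every earlier animal j,
    unknown parents contributing 0.
    """
    ped.validate()
    n = len(ped)
    sire, dam = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ped.ids, A, "A")


def extract_A22(A: RelationshipMatrix, ped: Pedigree) -> RelationshipMatrix:
    """Principal submatrix of A on the genotyped animals, in genotype order."""
    ids = ped.genotyped_ids
    if not ids:
        raise ValueError("no genotyped animals: A22 is empty")
    return A.submatrix(ids, kind="A22")


def build_G(
    animal_ids: list[str] | None = None,
    counts: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    *,
    geno=None,
) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1.

    Accepts either a :class:`~onestepblend.popsim.GenotypeMatrix` via
    ``geno=`` or explicit (animal_ids, counts, freqs).  Allele counts are
    centered by twice the allele frequency and the cross-product is scaled
    by ``2 * sum_j p_j (1 - p_j)``.
    """
    if geno is not None:
        animal_ids, counts, freqs = geno.animal_ids, geno.counts, geno.freqs
    if animal_ids is None or counts is None or freqs is None:
        raise ValueError("provide geno= or (animal_ids, counts, freqs)")
    counts = np.asarray(counts, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        raise DegenerateSNPError(
            "allele frequencies at 0 or 1 present; filter monomorphic SNPs first"
        )
    Z = counts - 2.0 * freqs
    denom = 2.0 * float(np.sum(freqs * (1.0 - freqs)))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(list(animal_ids), G, "G")


def adjust_G(
    G: RelationshipMatrix, A22: RelationshipMatrix
) -> tuple[RelationshipMatrix, GAdjustment]:
    """Rescale G so its moments match A22: solve for (beta, alpha) in

    ``Avg(diag(G)) * beta + alpha = Avg(diag(A22))``
    ``Avg(offdiag(G)) * beta + alpha = Avg(offdiag(A22))``

    and return ``G_a = G * beta + alpha`` (alpha added to every element)
    together with the :class:`GAdjustment` record.
    """
    if G.animal_ids != A22.animal_ids:
        raise ValueError("G and A22 must index the same animals in the same order")
    n = len(G)
    if n < 2:
        raise SingularAdjustmentError("need at least 2 animals for off-diagonal moments")
    off = ~np.eye(n, dtype=bool)
    dG = float(np.mean(np.diag(G.values)))
    oG = float(np.mean(G.values[off]))
    dA = float(np.mean(np.diag(A22.values)))
    oA = float(np.mean(A22.values[off]))
    M = np.array([[dG, 1.0], [oG, 1.0]])
    if abs(dG - oG) < 1e-12:
        raise SingularAdjustmentError(
            "Avg(diag(G)) == Avg(offdiag(G)): moment system is singular"
        )
    beta, alpha = np.linalg.solve(M, np.array([dA, oA]))
    Ga = RelationshipMatrix(list(G.animal_ids), G.values * beta + alpha, "G_adjusted")
    return Ga, GAdjustment(float(beta), float(alpha), dG, oG, dA, oA)


def stabilize_G(
    G: RelationshipMatrix, A22: RelationshipMatrix, weight: float = 0.95
) -> RelationshipMatrix:
    """Optional conditioning step ``G* = w*G + (1-w)*A22`` for
    ill-conditioned G.  Not applied anywhere by default."""
    if G.animal_ids != A22.animal_ids:
        raise ValueError("G and A22 must index the same animals in the same order")
    return RelationshipMatrix(
        list(G.animal_ids), weight * G.values + (1.0 - weight) * A22.values, G.kind
    )


def build_H(
    A: RelationshipMatrix, G: RelationshipMatrix, ped: Pedigree
) -> RelationshipMatrix:
    """Hybrid relationship matrix blending pedigree and genomic information.

    G must index (a reordering of) the genotyped subset of A's animals.
    The result is returned in pedigree order; its restriction to genotyped
    animals equals G exactly.
    """
    ped.validate()
    if A.animal_ids != ped.ids:
        raise ValueError("A must be indexed by the pedigree animals in pedigree order")
    geno_ids = ped.genotyped_ids
    nongeno_ids = [a for a in ped.ids if a not in set(geno_ids)]
    if set(G.animal_ids) != set(geno_ids):
        raise ValueError("G must cover exactly the genotyped animals")

    gidx = A.index_of(geno_ids)
    nidx = A.index_of(nongeno_ids)
    Av = A.values
    A11 = Av[np.ix_(nidx, nidx)]
    A12 = Av[np.ix_(nidx, gidx)]
    A22 = Av[np.ix_(gidx, gidx)]
    Gv = G.submatrix(geno_ids).values

    try:
        c, low = linalg.cho_factor(A22)
    except linalg.LinAlgError as e:
        cond = np.linalg.cond(A22)
        raise StructuralError(
            f"A22 is numerically singular (condition number {cond:.3e})"
        ) from e
    # T = A12 * A22^-1, computed via the Cholesky factor of A22
    T = linalg.cho_solve((c, low), A12.T).T
    H11 = A11 + T @ (Gv - A22) @ T.T
    H12 = T @ Gv
    H22 = Gv

    n = len(ped)
    H = np.zeros((n, n))
    H[np.ix_(nidx, nidx)] = H11
    H[np.ix_(nidx, gidx)] = H12
    H[np.ix_(gidx, nidx)] = H12.T
    H[np.ix_(gidx, gidx)] = H22
    H = 0.5 * (H + H.T)
    return RelationshipMatrix(ped.ids, H, "H")
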