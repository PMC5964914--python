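"""Relationship matrices: pedigree A, additive genomic G, dominance D.

* ``build_nrm`` — numerator relationship matrix by the tabular (recursive)
  method; founders unrelated and non-inbred.
* ``build_grm`` — VanRaden method-1 additive GRM: ``G = WW' / c`` with
  ``W = M - 2p`` (column-centred dosages) and ``c = 2 * sum_j p_j (1 - p_j)``.
* ``build_drm`` — classical (GCTA-compatible) dominance relationship matrix:
  per-marker codes ``0 -> -2p^2``, ``1 -> 2p(1-p)``, ``2 -> -2(1-p)^2`` and
  ``D = HH' / sum_j (2 p_j (1 - p_j))^2``.

Both genomic matrices are invariant to marker order and to swapping the
ref/alt labels of any marker.  Allele frequencies default to those observed
in the supplied genotypes; external frequencies may be passed instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import MISSING, GenotypeMatrix, HornpredError, Pedigree

logger = logging.getLogger(__name__)

DEFAULT_RIDGE = 1e-6


@dataclass
class RelationshipMatrix:
    """A labelled symmetric covariance-structure matrix among animals."""

    kind: str  # pedigree_A | genomic_G | dominance_D
    labels: np.ndarray
    values: np.ndarray
    scale_c: float | None = None  # genomic scale constant
    freqs: np.ndarray | None = None  # allele frequencies used

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in relationship matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, ids: Sequence[str]) -> np.ndarray:
        lut = {a: i for i, a in enumerate(self.labels)}
        try:
            return np.array([lut[a] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"animal {exc.args[0]!r} not in relationship matrix") from None

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = self.index(ids)
        return RelationshipMatrix(
            kind=self.kind,
            labels=np.asarray(list(ids), dtype=object),
            values=self.values[np.ix_(idx, idx)],
            scale_c=self.scale_c,
            freqs=self.freqs,
        )

    def block(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        return self.values[np.ix_(self.index(rows), self.index(cols))]

    def with_ridge(self, ridge: float = DEFAULT_RIDGE) -> np.ndarray:
        """Values with a small diagonal ridge (added before any inversion)."""
        return self.values + ridge * np.eye(self.n)


# ---------------------------------------------------------------------------
# Pedigree NRM
# ---------------------------------------------------------------------------


def build_nrm(pedigree: Pedigree, ids: Sequence[str] | None = None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Animals are processed in an order where parents precede offspring:
    ``a_ij = 0.5 (a_sj + a_dj)`` for j already tabulated and
    ``a_ii = 1 + 0.5 a_sd``.  Unknown parents contribute 0.  ``ids``
    optionally restricts the returned matrix (the recursion always runs over
    the full pedigree).
    """
    order = pedigree.topological_order()
    n = len(order)
    pos = {a: i for i, a in enumerate(order)}
    sire = dict(zip(pedigree.table["animal"], pedigree.table["sire"]))
    dam = dict(zip(pedigree.table["animal"], pedigree.table["dam"]))
    s_idx = np.full(n, -1, dtype=np.int64)
    d_idx = np.full(n, -1, dtype=np.int64)
    for a, i in pos.items():
        s, d = sire.get(a), dam.get(a)
        if s is not None and s in pos:
            s_idx[i] = pos[s]
        if d is not None and d in pos:
            d_idx[i] = pos[d]

    A = np.zeros((n, n))
    for i in range(n):
        s, d = s_idx[i], d_idx[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)

    if ids is None:
        ids = pedigree.table["animal"].tolist()
    take = np.array([pos[a] for a in ids], dtype=np.int64)
    return RelationshipMatrix(
        kind="pedigree_A",
        labels=np.asarray(list(ids), dtype=object),
        values=A[np.ix_(take, take)],
    )


# ---------------------------------------------------------------------------
# Genomic matrices
# ---------------------------------------------------------------------------


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """ALT-allele frequency per marker, missing calls excluded pairwise."""
    obs = geno.dosage != MISSING
    nobs = obs.sum(axis=0)
    if (nobs == 0).any():
        bad = geno.marker_ids[nobs == 0][0]
        raise HornpredError(f"marker {bad} has no non-missing calls")
    return np.where(obs, geno.dosage, 0).sum(axis=0) / (2.0 * nobs)


def _prepare(geno: GenotypeMatrix, frequencies: np.ndarray | None, impute_mean: bool):
    p = allele_frequencies(geno) if frequencies is None else np.asarray(frequencies, float)
    if p.shape != (geno.n_markers,):
        raise ValueError("frequencies length does not match marker count")
    poly = (p > 0) & (p < 1)
    if not poly.all():
        logger.info("excluding %d monomorphic markers from genomic matrix", int((~poly).sum()))
    M = geno.dosage_float(impute_mean=impute_mean)[:, poly]
    return M, p[poly]


def build_grm(
    geno: GenotypeMatrix,
    frequencies: np.ndarray | None = None,
    impute_mean: bool = False,
) -> RelationshipMatrix:
    """VanRaden method-1 additive genomic relationship matrix."""
    M, p = _prepare(geno, frequencies, impute_mean)
    c = float(2.0 * np.sum(p * (1.0 - p)))
    if c == 0.0:
        raise HornpredError("all markers monomorphic; GRM scale constant is zero")
    W = M - 2.0 * p
    G = (W @ W.T) / c
    return RelationshipMatrix(
        kind="genomic_G", labels=geno.animal_ids.copy(), values=G, scale_c=c, freqs=p
    )


def dominance_codes(M: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Classical-parameterisation dominance coding per marker.

    Genotype 0 -> -2p^2, 1 -> 2p(1-p), 2 -> -2(1-p)^2.  ``M`` must contain
    only values in {0, 1, 2} (mean-imputed values are rounded to the nearest
    genotype class for coding).
    """
    Mr = np.rint(M).astype(np.int64)
    H = np.empty_like(M, dtype=np.float64)
    code0 = -2.0 * p**2
    code1 = 2.0 * p * (1.0 - p)
    code2 = -2.0 * (1.0 - p) ** 2
    H[:] = np.where(Mr == 0, code0, np.where(Mr == 1, code1, code2))
    return H


def build_drm(
    geno: GenotypeMatrix,
    frequencies: np.ndarray | None = None,
    impute_mean: bool = False,
) -> RelationshipMatrix:
    """Classical (GCTA-compatible) dominance relationship matrix."""
    M, p = _prepare(geno, frequencies, impute_mean)
    denom = float(np.sum((2.0 * p * (1.0 - p)) ** 2))
    if denom == 0.0:
        raise HornpredError("all markers monomorphic; DRM scale constant is zero")
    H = dominance_codes(M, p)
    D = (H @ H.T) / denom
    return RelationshipMatrix(
        kind="dominance_D", labels=geno.animal_ids.copy(), values=D, scale_c=denom, freqs=p
    )


# ---------------------------------------------------------------------------
# Text serialisation (GCTA-GRM-like)
# ---------------------------------------------------------------------------


def write_relationship(mat: RelationshipMatrix, prefix: str | Path) -> None:
    """Write ids (``.grm.id``) and lower triangle (``.grm.txt``) text files.

    Each triangle row is ``i j n_markers value`` with 1-based indices,
    mirroring GCTA's plain-text GRM layout.
    """
    prefix = Path(prefix)
    with open(prefix.with_suffix(".grm.id"), "w") as fh:
        for a in mat.labels:
            fh.write(f"{a}\t{a}\n")
    nm = len(mat.freqs) if mat.freqs is not None else 0
    with open(prefix.with_suffix(".grm.txt"), "w") as fh:
        fh.write(f"# kind={mat.kind} scale_c={mat.scale_c if mat.scale_c is not None else 'NA'}\n")
        for i in range(mat.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{nm}\t{mat.values[i, j]:.10g}\n")


def read_relationship(prefix: str | Path) -> RelationshipMatrix:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(prefix.with_suffix(".grm.id"))]
    n = len(ids)
    values = np.zeros((n, n))
    kind, scale_c = "genomic_G", None
    with open(prefix.with_suffix(".grm.txt")) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "kind":
                        kind = v
                    elif k == "scale_c" and v != "NA":
                        scale_c = float(v)
                continue
            i, j, _, val = line.split()
            values[int(i) - 1, int(j) - 1] = float(val)
            values[int(j) - 1, int(i) - 1] = float(val)
    return RelationshipMatrix(
        kind=kind, labels=np.asarray(ids, dtype=object), values=values, scale_c=scale_c
    )
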