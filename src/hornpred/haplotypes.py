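"""Multi-marker haplotype alleles from phased genotypes.

Haplotype alleles over a set of k markers (typically the 3/5/10 most
significant SNPs of a scan) are read directly off the phased haplotype
matrices; each animal contributes two alleles, so per-animal copy counts are
0/1/2 and sum to 2.  Rare alleles (population frequency below a threshold,
default 2%) are pooled into a single residual class before the copy-count
matrix is used as a random-effect design with one shared variance component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, HornpredError

RESIDUAL = "residual"


@dataclass
class HaplotypeSet:
    """Distinct haplotype alleles at k markers with per-animal copy counts."""

    marker_ids: tuple[str, ...]
    animal_ids: np.ndarray
    alleles: tuple[str, ...]  # bit-strings of length k (plus optional residual)
    frequencies: np.ndarray  # per allele, sums to 1
    copies: np.ndarray  # (n_animals, n_alleles), rows sum to 2
    pooled: bool = False
    pooled_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.copies = np.asarray(self.copies, dtype=np.int64)
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if not (self.copies.sum(axis=1) == 2).all():
            raise ValueError("per-animal haplotype copies must sum to 2")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"allele": self.alleles, "frequency": self.frequencies}
        )


def build_haplotypes(geno: GenotypeMatrix, marker_ids: Sequence[str]) -> HaplotypeSet:
    """Form haplotype alleles at the listed markers from phased genotypes.

    Requires phase: each animal's two haplotypes are read off ``hap1``/``hap2``
    as bit-strings in map order of the listed markers.
    """
    if not geno.phased:
        raise HornpredError(
            "haplotype construction requires phased genotypes; supply phased "
            "data (the simulator always emits phase)"
        )
    cols = np.array([geno.marker_index(m) for m in marker_ids])
    order = np.argsort(geno.pos_bp[cols], kind="mergesort")
    cols = cols[order]
    used = tuple(str(m) for m in geno.marker_ids[cols])

    h1 = geno.hap1[:, cols]
    h2 = geno.hap2[:, cols]
    s1 = ["".join(map(str, row)) for row in h1]
    s2 = ["".join(map(str, row)) for row in h2]
    all_alleles = pd.Series(s1 + s2)
    freq = all_alleles.value_counts(normalize=True)
    # order: frequency descending, then lexicographic for determinism
    alleles = tuple(sorted(freq.index, key=lambda a: (-freq[a], a)))
    idx = {a: j for j, a in enumerate(alleles)}
    n = geno.n_animals
    copies = np.zeros((n, len(alleles)), dtype=np.int64)
    for i in range(n):
        copies[i, idx[s1[i]]] += 1
        copies[i, idx[s2[i]]] += 1
    return HaplotypeSet(
        marker_ids=used,
        animal_ids=geno.animal_ids.copy(),
        alleles=alleles,
        frequencies=np.array([freq[a] for a in alleles]),
        copies=copies,
    )


def pool_rare_haplotypes(hset: HaplotypeSet, freq_threshold: float = 0.02) -> HaplotypeSet:
    """Merge alleles with frequency below the threshold into one residual class.

    The threshold applies to allele (haplotype-copy) frequency.  Idempotent:
    an existing residual class is never re-pooled.  Raises if no allele
    reaches the threshold (nothing left to contrast).
    """
    if not (0.0 < freq_threshold < 0.5):
        raise ValueError("freq_threshold must be in (0, 0.5)")
    keep = [
        j
        for j, (a, f) in enumerate(zip(hset.alleles, hset.frequencies))
        if f >= freq_threshold or a == RESIDUAL
    ]
    rare = [j for j in range(hset.n_alleles) if j not in keep]
    if not rare:
        return hset
    if not any(hset.alleles[j] != RESIDUAL for j in keep):
        raise HornpredError(
            "all haplotype alleles are below the pooling threshold; nothing to contrast"
        )
    members = tuple(hset.alleles[j] for j in rare) + hset.pooled_members
    res_freq = float(hset.frequencies[rare].sum())
    res_copies = hset.copies[:, rare].sum(axis=1)
    alleles, freqs, cols = [], [], []
    had_residual = False
    for j in keep:
        if hset.alleles[j] == RESIDUAL:
            had_residual = True
            alleles.append(RESIDUAL)
            freqs.append(float(hset.frequencies[j]) + res_freq)
            cols.append(hset.copies[:, j] + res_copies)
        else:
            alleles.append(hset.alleles[j])
            freqs.append(float(hset.frequencies[j]))
            cols.append(hset.copies[:, j])
    if not had_residual:
        alleles.append(RESIDUAL)
        freqs.append(res_freq)
        cols.append(res_copies)
    return HaplotypeSet(
        marker_ids=hset.marker_ids,
        animal_ids=hset.animal_ids,
        alleles=tuple(alleles),
        frequencies=np.array(freqs),
        copies=np.column_stack(cols),
        pooled=True,
        pooled_members=members,
    )


def haplotype_design(hset: HaplotypeSet) -> tuple[np.ndarray, tuple[str, ...]]:
    """Copy-count design matrix (animals x haplotype classes) for fitting.

    All classes share one variance component when used as a random term.
    A single-class set is rejected: its constant column (rows always sum to
    2) is confounded with the intercept.
    """
    if hset.n_alleles < 2:
        raise HornpredError(
            "haplotype design has a single class; the constant copy-count "
            "column is confounded with the intercept"
        )
    return hset.copies.astype(np.float64), tuple(hset.alleles)


def select_window_markers(
    geno: GenotypeMatrix, chrom: str, center_bp: int, halfwidth_bp: int
) -> list[str]:
    """Marker ids within +/- halfwidth of a position (closed interval)."""
    sub = geno.region(chrom, center_bp - halfwidth_bp, center_bp + halfwidth_bp)
    return [str(m) for m in sub.marker_ids]


def write_haplotypes_tsv(hset: HaplotypeSet, path) -> None:
    df = hset.to_frame()
    df["class_id"] = range(len(df))
    df.to_csv(path, sep="\t", index=False)
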