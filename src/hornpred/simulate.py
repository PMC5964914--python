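"""Synthetic populations with the structure the horn-phenotype analyses assume.

The generator emulates a Merino-style half-sib study population: ~180 sires
each with 1–51 offspring, dams with ~1.5 offspring on average, two sex labels
(female / wether), a chromosome-10-like segment carrying a causal biallelic
insertion locus at 29,456,047 bp with tag SNPs in strong LD, optional
independent background chromosomes for genome-wide relationship matrices, a
polygenic liability component, and sex x genotype penetrance over the four
horn-score classes.

Founder linkage disequilibrium comes from a mosaic copying model: each founder
haplotype carries a latent ancestral lineage that is retained or switched
between adjacent markers, and marker alleles are emitted from the lineage by
maximal coupling so that configured marginal frequencies are respected.  The
per-interval retention is calibrated so that realized r^2 between the causal
locus and its designated tag markers hits the configured targets.  This is
deliberately simpler than coalescent simulation: it gives direct control of
tag-causal LD, which is all the prediction methods need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, Pedigree, PhenotypeTable, HornpredError

# ---------------------------------------------------------------------------
# Penetrance
# ---------------------------------------------------------------------------

#: Default per sex x causal-genotype probabilities over
#: (polled, knobs+scurs, horned), expressed as observed class fractions in a
#: large Merino dataset.  Genotype 2 counts the polled-associated allele.
_DEF = {
    ("female", 0): (174 / 1232, None, 81 / 1230),
    ("female", 1): (811 / 1053, None, 6 / 1052),
    ("female", 2): (138 / 163, None, 1 / 166),
    ("wether", 0): (29 / 704, None, 472 / 700),
    ("wether", 1): (385 / 725, None, 9 / 728),
    ("wether", 2): (97 / 124, None, 0 / 125),
}


@dataclass(frozen=True)
class PenetranceModel:
    """P(horn-score class | sex, causal genotype).

    ``probs[(sex, genotype)]`` is a probability vector over the three
    analysis classes ``(polled, knobs_scurs, horned)``; knobs and scurs are
    always pooled in the analyses and are split 50/50 when individual scores
    are drawn.
    """

    probs: dict[tuple[str, int], tuple[float, float, float]]

    def __post_init__(self) -> None:
        for key, p in self.probs.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"penetrance for {key} must have 3 classes")
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"penetrance for {key} outside [0, 1]: {p}")
            if abs(arr.sum() - 1.0) > 1e-12:
                raise ValueError(f"penetrance for {key} sums to {arr.sum()}, not 1")

    @classmethod
    def default(cls) -> "PenetranceModel":
        probs = {}
        for key, (p_pol, _, p_horn) in _DEF.items():
            probs[key] = (p_pol, 1.0 - p_pol - p_horn, p_horn)
        return cls(probs)

    @classmethod
    def uniform(cls, vec: tuple[float, float, float]) -> "PenetranceModel":
        """Same class probabilities for every sex and genotype."""
        return cls({(s, g): vec for s in ("female", "wether") for g in (0, 1, 2)})

    @classmethod
    def additive(
        cls, p_case_by_genotype: tuple[float, float, float], case_class: str = "horned"
    ) -> "PenetranceModel":
        """Sex-independent penetrance with P(case | g) given per genotype.

        The non-case mass is split evenly between the two remaining classes;
        useful for generating purely additive traits.
        """
        idx = {"polled": 0, "knobs_scurs": 1, "horned": 2}[case_class]
        probs = {}
        for s in ("female", "wether"):
            for g in (0, 1, 2):
                q = float(p_case_by_genotype[g])
                vec = [(1 - q) / 2] * 3
                vec[idx] = q
                probs[(s, g)] = tuple(vec)
        return cls(probs)

    def p_class(self, sex: np.ndarray, genotype: np.ndarray) -> np.ndarray:
        """(n, 3) array of class probabilities for the given sex/genotype."""
        out = np.empty((len(sex), 3), dtype=float)
        for key, p in self.probs.items():
            mask = (sex == key[0]) & (genotype == key[1])
            out[mask] = p
        return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TagSpec:
    """A designated tag marker with a target r^2 to the causal locus."""

    marker_id: str
    pos_bp: int
    target_r2: float
    freq: float | None = None  # default: causal frequency


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the study generator; defaults are the study conditions.

    ``seed`` is mandatory for :func:`simulate_study`; every sub-operation is
    reproducible from it.
    """

    seed: int | None = None
    # pedigree
    n_sires: int = 182
    offspring_range: tuple[int, int] = (1, 51)
    mean_offspring_per_dam: float = 1.5
    female_prop: float = 2448 / 4001
    n_flocks: int = 8
    birth_years: tuple[int, int] = (2007, 2011)
    # causal locus and core (chromosome-10-like) segment
    core_chrom: str = "10"
    causal_pos: int = 29_456_047
    causal_id: str = "insertion_29456047"
    causal_freq: float = 0.295
    tags: tuple[TagSpec, ...] = (
        TagSpec("snp10_29458450", 29_458_450, 0.985),
        TagSpec("snp10_29512572", 29_512_572, 0.985),
    )
    n_core_markers: int = 41
    core_span: tuple[int, int] = (29_156_047, 29_756_047)
    core_freq_range: tuple[float, float] = (0.10, 0.50)
    background_retention: float = 0.90
    switch_rate: float | None = None  # overrides calibration when set
    # background genome (independent loci, for genome-wide matrices)
    n_background_markers: int = 120
    n_background_chroms: int = 5
    background_chrom_len: int = 100_000_000
    # transmission and genetic architecture
    recomb_rate: float = 1e-8  # Morgan per bp
    sigma2_a: float = 0.2  # polygenic variance on the liability (logit) scale
    penetrance: PenetranceModel = field(default_factory=PenetranceModel.default)

    def __post_init__(self) -> None:
        if self.sigma2_a < 0:
            raise ValueError("sigma2_a must be >= 0")
        if not (0 < self.causal_freq < 1):
            raise ValueError("causal_freq must be in (0, 1)")
        for t in self.tags:
            if not (0 <= t.target_r2 <= 1):
                raise ValueError(f"tag {t.marker_id}: target r2 must be in [0, 1]")
        if self.offspring_range[0] < 1 or self.offspring_range[1] < self.offspring_range[0]:
            raise ValueError("invalid offspring_range")
        if not (1.0 <= self.mean_offspring_per_dam <= 2.0):
            raise ValueError("mean_offspring_per_dam must be in [1, 2]")


# ---------------------------------------------------------------------------
# Founder haplotypes (mosaic copying model)
# ---------------------------------------------------------------------------


@dataclass
class FounderPool:
    """A pool of phased founder haplotypes with marker metadata."""

    marker_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    freqs: np.ndarray
    haplotypes: np.ndarray  # (n_hap, n_markers) int8
    causal_index: int

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


def hill_robertson_r2max(p: float, q: float) -> float:
    """Upper bound on r^2 between two biallelic loci with frequencies p, q.

    For positively coupled alleles the bound is
    ``min(pq', p'q) / max(pq', p'q)`` ... expressed here in the standard form
    p(1-q)/(q(1-p)) for p <= q (symmetric in the loci).
    """
    p, q = min(p, 1 - p), min(q, 1 - q)  # fold to minor frequencies
    lo, hi = sorted((p, q))
    return (lo * (1 - hi)) / (hi * (1 - lo))


def _core_marker_map(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Positions, ids, freqs for the core segment, causal index included."""
    lo, hi = config.core_span
    base = np.linspace(lo, hi, config.n_core_markers).astype(np.int64)
    special = {config.causal_pos: (config.causal_id, config.causal_freq)}
    for t in config.tags:
        special[t.pos_bp] = (t.marker_id, t.freq if t.freq is not None else config.causal_freq)
    # drop evenly spaced positions that collide with special ones
    base = np.array([p for p in base if p not in special], dtype=np.int64)
    pos = np.sort(np.concatenate([base, np.array(sorted(special), dtype=np.int64)]))
    ids = np.empty(len(pos), dtype=object)
    freqs = np.empty(len(pos), dtype=float)
    for j, p in enumerate(pos):
        if int(p) in special:
            ids[j], freqs[j] = special[int(p)]
        else:
            ids[j] = f"snp{config.core_chrom}_{p}"
            freqs[j] = np.nan  # drawn later
    causal_index = int(np.flatnonzero(pos == config.causal_pos)[0])
    return pos, ids, freqs, causal_index


def _interval_retentions(config: SimConfig, pos: np.ndarray, causal_index: int) -> np.ndarray:
    """Per-interval lineage retention calibrated to the tag r^2 targets.

    The lineage correlation between the causal locus and a marker k intervals
    away is the product of the interval retentions on the path, so each tag's
    target fixes the product over its path; segments between consecutive tags
    get the ratio, spread evenly over their intervals.
    """
    n_int = len(pos) - 1
    if config.switch_rate is not None:
        rho = max(0.0, 1.0 - 2.0 * config.switch_rate)
        return np.full(n_int, rho)
    rho = np.full(n_int, config.background_retention)
    pos_to_idx = {int(p): j for j, p in enumerate(pos)}
    for side in (-1, +1):
        tags = [t for t in config.tags
                if (pos_to_idx[t.pos_bp] - causal_index) * side > 0]
        tags.sort(key=lambda t: abs(pos_to_idx[t.pos_bp] - causal_index))
        prev_idx, prev_corr = causal_index, 1.0
        for t in tags:
            p_tag = t.freq if t.freq is not None else config.causal_freq
            bound = hill_robertson_r2max(config.causal_freq, p_tag)
            if t.target_r2 > bound + 1e-12:
                raise HornpredError(
                    f"tag {t.marker_id}: target r2 {t.target_r2} exceeds the "
                    f"Hill-Robertson bound r2max={bound:.4f} implied by allele "
                    f"frequencies {config.causal_freq} and {p_tag}"
                )
            idx = pos_to_idx[t.pos_bp]
            need = math.sqrt(t.target_r2 / bound)  # lineage corr required
            if need > prev_corr + 1e-12:
                raise HornpredError(
                    f"tag {t.marker_id}: target r2 {t.target_r2} not reachable "
                    f"beyond an inner tag with a lower target"
                )
            seg = sorted((prev_idx, idx))
            k = seg[1] - seg[0]
            rho[seg[0]:seg[1]] = (need / prev_corr) ** (1.0 / k)
            prev_idx, prev_corr = idx, need
    return rho


def simulate_founder_haplotypes(
    config: SimConfig, seed: int | np.random.Generator, n_haplotypes: int = 2000
) -> FounderPool:
    """Generate a pool of phased founder haplotypes.

    Core-segment markers are generated by the lineage mosaic described in the
    module docstring; background markers are independent draws at their
    configured frequencies (no background LD).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos, ids, freqs, c_idx = _core_marker_map(config)
    m_core = len(pos)
    if m_core < 2:
        raise ValueError("need at least 2 core markers")
    lo, hi = config.core_freq_range
    draw = rng.uniform(lo, hi, size=m_core)
    freqs = np.where(np.isnan(freqs), draw, freqs)

    rho = _interval_retentions(config, pos, c_idx)
    pi = config.causal_freq

    # latent lineage chain, outward from the causal locus
    L = np.empty((n_haplotypes, m_core), dtype=np.int8)
    L[:, c_idx] = (rng.random(n_haplotypes) < pi).astype(np.int8)
    for j in range(c_idx + 1, m_core):
        r = rho[j - 1]
        u = rng.random(n_haplotypes)
        prev = L[:, j - 1]
        L[:, j] = np.where(prev == 1, u < pi + r * (1 - pi), u < pi * (1 - r)).astype(np.int8)
    for j in range(c_idx - 1, -1, -1):
        r = rho[j]
        u = rng.random(n_haplotypes)
        prev = L[:, j + 1]
        L[:, j] = np.where(prev == 1, u < pi + r * (1 - pi), u < pi * (1 - r)).astype(np.int8)

    # emit alleles from the lineage by maximal coupling (keeps marginals)
    H_core = np.empty_like(L)
    for j in range(m_core):
        p_j = freqs[j]
        if abs(p_j - pi) < 1e-9:
            H_core[:, j] = L[:, j]
        elif p_j > pi:
            extra = (p_j - pi) / (1 - pi)
            H_core[:, j] = np.where(
                L[:, j] == 1, 1, (rng.random(n_haplotypes) < extra)
            ).astype(np.int8)
        else:
            keep = p_j / pi
            H_core[:, j] = np.where(
                L[:, j] == 1, (rng.random(n_haplotypes) < keep), 0
            ).astype(np.int8)

    # background chromosomes: independent loci
    bg_ids, bg_chrom, bg_pos, bg_freqs, bg_cols = [], [], [], [], []
    if config.n_background_markers > 0:
        per = int(np.ceil(config.n_background_markers / config.n_background_chroms))
        count = 0
        for c in range(1, config.n_background_chroms + 1):
            chrom_label = str(c if str(c) != config.core_chrom else config.n_background_chroms + 1)
            k = min(per, config.n_background_markers - count)
            if k <= 0:
                break
            positions = np.linspace(1_000_000, config.background_chrom_len, k).astype(np.int64)
            for p in positions:
                bg_ids.append(f"snp{chrom_label}_{p}")
                bg_chrom.append(chrom_label)
                bg_pos.append(int(p))
            f = rng.uniform(lo, hi, size=k)
            bg_freqs.extend(f.tolist())
            bg_cols.append((rng.random((n_haplotypes, k)) < f).astype(np.int8))
            count += k

    marker_ids = np.concatenate([ids, np.array(bg_ids, dtype=object)]) if bg_ids else ids
    chrom = np.concatenate(
        [np.full(m_core, config.core_chrom, dtype=object), np.array(bg_chrom, dtype=object)]
    ) if bg_ids else np.full(m_core, config.core_chrom, dtype=object)
    pos_all = np.concatenate([pos, np.array(bg_pos, dtype=np.int64)]) if bg_ids else pos
    freqs_all = np.concatenate([freqs, np.array(bg_freqs)]) if bg_ids else freqs
    H = np.hstack([H_core] + bg_cols) if bg_cols else H_core

    # canonical ordering: background chroms sorted, then core; stable by (chrom, pos)
    order = np.lexsort((pos_all, np.array([_chrom_sort_key(c) for c in chrom])))
    return FounderPool(
        marker_ids=marker_ids[order],
        chrom=chrom[order],
        pos_bp=pos_all[order],
        freqs=freqs_all[order],
        haplotypes=H[:, order],
        causal_index=int(np.flatnonzero(marker_ids[order] == config.causal_id)[0]),
    )


def _chrom_sort_key(c: str) -> int:
    try:
        return int(c)
    except ValueError:
        return 10_000 + hash(c) % 1000


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimConfig, seed: int | np.random.Generator) -> Pedigree:
    """Half-sib pedigree: each sire mated to several dams, dams reused so the
    mean number of offspring per dam matches the configured value."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = config.offspring_range
    fam_sizes = rng.integers(lo, hi + 1, size=config.n_sires)
    q_second = config.mean_offspring_per_dam - 1.0  # P(a dam has a 2nd offspring)

    rows = []
    sire_ids = [f"S{k + 1:04d}" for k in range(config.n_sires)]
    for s in sire_ids:
        rows.append((s, None, None, "wether", None, None))
    dam_counter = 0
    animal_counter = 0
    yr_lo, yr_hi = config.birth_years
    offspring_rows = []
    for s, size in zip(sire_ids, fam_sizes):
        remaining = int(size)
        while remaining > 0:
            dam_counter += 1
            d = f"D{dam_counter:05d}"
            rows.append((d, None, None, "female", None, None))
            litter = 2 if (remaining >= 2 and rng.random() < q_second) else 1
            for _ in range(litter):
                animal_counter += 1
                a = f"A{animal_counter:05d}"
                sex = "female" if rng.random() < config.female_prop else "wether"
                flock = f"F{int(rng.integers(1, config.n_flocks + 1))}"
                year = int(rng.integers(yr_lo, yr_hi + 1))
                offspring_rows.append((a, s, d, sex, flock, year))
            remaining -= litter
    rows.extend(offspring_rows)
    table = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "flock", "year"])
    return Pedigree(table)


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------


def gene_drop(
    pedigree: Pedigree,
    pool: FounderPool,
    recomb_rate: float,
    seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Drop founder haplotypes through the pedigree with recombination.

    Founders receive haplotype pairs from the pool (without replacement when
    the pool is large enough); each non-founder inherits one recombinant
    gamete per parent, with crossovers from a Poisson process along physical
    positions (``recomb_rate`` in Morgan/bp) within each chromosome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = list(pedigree.table["animal"])
    sire = dict(zip(pedigree.table["animal"], pedigree.table["sire"]))
    dam = dict(zip(pedigree.table["animal"], pedigree.table["dam"]))
    known = set(ids)
    founders = set(pedigree.founders())
    for a in ids:
        s, d = sire[a], dam[a]
        if a not in founders and ((s is None or s not in known) != (d is None or d not in known)):
            raise HornpredError(f"animal {a}: exactly one parent genotyped/known — cannot gene-drop")

    m = len(pool.marker_ids)
    n = len(ids)
    # chromosome blocks (markers are sorted by chrom, pos)
    chroms, starts = np.unique(pool.chrom, return_index=True)
    order = np.argsort(starts)
    blocks = []
    bounds = sorted(starts)
    for b, st in enumerate(bounds):
        en = bounds[b + 1] if b + 1 < len(bounds) else m
        span = int(pool.pos_bp[en - 1] - pool.pos_bp[st]) if en - st > 1 else 0
        blocks.append((st, en, float(span)))

    hap = np.zeros((n, 2, m), dtype=np.int8)
    index = {a: i for i, a in enumerate(ids)}

    n_founders = len(founders)
    if pool.n_haplotypes >= 2 * n_founders:
        picks = rng.choice(pool.n_haplotypes, size=2 * n_founders, replace=False)
    else:
        picks = rng.integers(0, pool.n_haplotypes, size=2 * n_founders)
    for k, a in enumerate(sorted(founders, key=index.__getitem__)):
        hap[index[a], 0] = pool.haplotypes[picks[2 * k]]
        hap[index[a], 1] = pool.haplotypes[picks[2 * k + 1]]

    def gamete(parent_row: np.ndarray) -> np.ndarray:
        out = np.empty(m, dtype=np.int8)
        for st, en, span in blocks:
            start = int(rng.integers(0, 2))
            k = int(rng.poisson(recomb_rate * span)) if span > 0 and recomb_rate > 0 else 0
            if k == 0:
                out[st:en] = parent_row[start, st:en]
                continue
            cx = np.sort(rng.uniform(pool.pos_bp[st], pool.pos_bp[en - 1], size=k))
            seg = np.searchsorted(cx, pool.pos_bp[st:en], side="right")
            which = (start + seg) % 2
            idx = np.arange(st, en)
            out[st:en] = parent_row[which, idx]
        return out

    for a in pedigree.topological_order():
        if a in founders or a not in index:
            continue
        i = index[a]
        hap[i, 0] = gamete(hap[index[sire[a]]])
        hap[i, 1] = gamete(hap[index[dam[a]]])

    dosage = (hap[:, 0, :] + hap[:, 1, :]).astype(np.int16)
    alleles = np.array([("A", "T")] * m, dtype=object)
    return GenotypeMatrix(
        animal_ids=np.array(ids, dtype=object),
        marker_ids=pool.marker_ids.copy(),
        chrom=pool.chrom.copy(),
        pos_bp=pool.pos_bp.copy(),
        alleles=alleles,
        dosage=dosage,
        phased=True,
        hap1=hap[:, 0, :],
        hap2=hap[:, 1, :],
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_polygenic_values(
    pedigree: Pedigree, sigma2_a: float, seed: int | np.random.Generator
) -> dict[str, float]:
    """Additive polygenic values by pedigree recursion.

    Founders draw N(0, sigma2_a); non-founders get the mid-parent value plus a
    Mendelian-sampling deviate N(0, sigma2_a/2) (parents assumed non-inbred,
    which holds for the generator's two-generation pedigrees).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sire = dict(zip(pedigree.table["animal"], pedigree.table["sire"]))
    dam = dict(zip(pedigree.table["animal"], pedigree.table["dam"]))
    founders = set(pedigree.founders())
    u: dict[str, float] = {}
    sd_f = math.sqrt(sigma2_a)
    sd_m = math.sqrt(sigma2_a / 2.0)
    for a in pedigree.topological_order():
        if a in founders:
            u[a] = rng.normal(0.0, sd_f) if sigma2_a > 0 else 0.0
        else:
            mid = 0.5 * (u[sire[a]] + u[dam[a]])
            u[a] = mid + (rng.normal(0.0, sd_m) if sigma2_a > 0 else 0.0)
    return u


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def assign_phenotypes(
    causal_genotype: np.ndarray,
    sex: np.ndarray,
    polygenic: np.ndarray,
    penetrance: PenetranceModel,
    seed: int | np.random.Generator,
    animal_ids: Sequence[str] | None = None,
) -> PhenotypeTable:
    """Draw horn scores from sex x genotype penetrance with a polygenic shift.

    The polygenic value shifts the horned-class probability on the logit
    scale; the remaining mass is reallocated to polled and knobs/scurs in
    their original proportion.  Classes with probability exactly 0 or 1 are
    left untouched (the shift cannot create the phenotype from nothing).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sex = np.asarray(sex, dtype=object)
    g = np.asarray(causal_genotype, dtype=int)
    u = np.asarray(polygenic, dtype=float)
    n = len(g)
    base = penetrance.p_class(sex, g)  # (n, 3): polled, ks, horned
    p_horn = base[:, 2].copy()
    interior = (p_horn > 0) & (p_horn < 1)
    p_horn[interior] = _expit(_logit(p_horn[interior]) + u[interior])
    rest = 1.0 - p_horn
    base_rest = base[:, 0] + base[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_polled = np.where(base_rest > 0, base[:, 0] / base_rest, 0.5)
    p_polled = rest * frac_polled

    u1 = rng.random(n)
    u2 = rng.random(n)
    u3 = rng.random(n)
    horned = u1 < p_horn
    polled = ~horned & (u2 * rest < p_polled)
    ks = ~horned & ~polled
    score = np.empty(n, dtype=object)
    score[horned] = "horned"
    score[polled] = "polled"
    score[ks] = np.where(u3[ks] < 0.5, "knobs", "scurs")

    if animal_ids is None:
        animal_ids = [f"A{i + 1:05d}" for i in range(n)]
    return PhenotypeTable(pd.DataFrame({"animal": list(animal_ids), "horn_score": score}))


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """A complete simulated study: genotypes, pedigree, phenotypes, truth."""

    config: SimConfig
    genotypes: GenotypeMatrix  # phased, all pedigree animals, causal included
    pedigree: Pedigree
    phenotypes: PhenotypeTable  # offspring generation only
    true_polygenic: dict[str, float]
    causal_id: str

    @property
    def study_animals(self) -> np.ndarray:
        """Phenotyped animals (the offspring generation)."""
        return self.phenotypes.animal_ids

    def causal_genotype(self, animal_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.study_animals if animal_ids is None else animal_ids
        j = self.genotypes.marker_index(self.causal_id)
        return self.genotypes.dosage[self.genotypes.animal_index(list(ids)), j].astype(int)


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a full study: pedigree, founder LD, gene drop, phenotypes.

    Fully deterministic given ``config.seed``.
    """
    if config.seed is None:
        raise ValueError("SimConfig.seed is mandatory for simulate_study")
    ss = np.random.SeedSequence(config.seed)
    r_ped, r_pool, r_drop, r_poly, r_phen = [np.random.default_rng(s) for s in ss.spawn(5)]

    pedigree = simulate_pedigree(config, r_ped)
    n_founders = len(pedigree.founders())
    pool = simulate_founder_haplotypes(config, r_pool, n_haplotypes=2 * n_founders)
    geno = gene_drop(pedigree, pool, config.recomb_rate, r_drop)
    upoly = simulate_polygenic_values(pedigree, config.sigma2_a, r_poly)

    founders = set(pedigree.founders())
    offspring = [a for a in pedigree.table["animal"] if a not in founders]
    j = geno.marker_index(config.causal_id)
    rows = geno.animal_index(offspring)
    g = geno.dosage[rows, j].astype(int)
    sex = pedigree.sex_of(offspring)
    u = np.array([upoly[a] for a in offspring])
    phen = assign_phenotypes(g, sex, u, config.penetrance, r_phen, animal_ids=offspring)

    return SyntheticStudy(
        config=config,
        genotypes=geno,
        pedigree=pedigree,
        phenotypes=phen,
        true_polygenic=upoly,
        causal_id=config.causal_id,
    )
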