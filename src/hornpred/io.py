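"""Core data containers and file I/O.

Holds the three primary containers of the package — :class:`GenotypeMatrix`,
:class:`Pedigree` and :class:`PhenotypeTable` — together with readers/writers
for VCF and PLINK-style text, derivation of the two binary horn traits
(polled/non-polled and horned/non-horned) from the four-class horn score, and
per-marker quality control (call rate, Hardy–Weinberg chi-square, minor allele
frequency).

Conventions
-----------
* Dosages count copies of the ALT allele as written in the source file
  (0/1/2, ``-1`` for missing).  Analysis code re-orients per marker where an
  orientation matters, so file orientation never changes results.
* Base-pair coordinates are 1-based; region filters are closed intervals.
* Horn-score labels are case-insensitive with canonical vocabulary
  ``{"polled", "knobs", "scurs", "horned"}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

HORN_SCORES = ("polled", "knobs", "scurs", "horned")
SEX_LABELS = ("female", "wether")

NON_AUTOSOMAL = {"x", "y", "mt", "xy", "chrx", "chry", "chrm", "chrmt"}


class HornpredError(RuntimeError):
    """Base error for user-facing failures."""


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Animals x biallelic markers, dosage coded, optionally phased.

    Attributes
    ----------
    animal_ids, marker_ids
        Ordered unique identifiers.
    chrom, pos_bp, alleles
        Per-marker chromosome label, 1-based position and ``(ref, alt)`` pair.
    dosage
        ``(n_animals, n_markers)`` int16 array of ALT-allele counts with
        ``-1`` marking missing calls.
    phased
        If true, ``hap1 + hap2 == dosage`` at every non-missing cell.
    """

    animal_ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    alleles: np.ndarray  # (m, 2) of str
    dosage: np.ndarray
    phased: bool = False
    hap1: np.ndarray | None = None
    hap2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object).reshape(-1, 2)
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.validate()

    # -- basic introspection ------------------------------------------------

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker_id: str) -> int:
        idx = np.flatnonzero(self.marker_ids == marker_id)
        if idx.size == 0:
            raise KeyError(f"unknown marker id {marker_id!r}")
        return int(idx[0])

    def animal_index(self, animal_ids: Sequence[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([lookup[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown animal id {exc.args[0]!r}") from None

    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.animal_ids) or m != len(self.marker_ids):
            raise ValueError("dosage shape does not match id vectors")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        if len(set(self.animal_ids)) != n:
            raise ValueError("duplicate animal ids")
        ok = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(f"invalid dosage {self.dosage[tuple(bad)]} at {tuple(bad)}")
        for c in np.unique(self.chrom):
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        if self.phased:
            if self.hap1 is None or self.hap2 is None:
                raise ValueError("phased matrix requires hap1 and hap2")
            self.hap1 = np.asarray(self.hap1, dtype=np.int8)
            self.hap2 = np.asarray(self.hap2, dtype=np.int8)
            obs = self.dosage != MISSING
            if not np.array_equal(
                (self.hap1 + self.hap2)[obs], self.dosage[obs].astype(np.int8)
            ):
                raise ValueError("hap1 + hap2 != dosage at a non-missing cell")

    # -- subsetting ---------------------------------------------------------

    def subset(
        self,
        animals: Sequence[str] | np.ndarray | None = None,
        markers: Sequence[str] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given animal and/or marker ids."""
        ai = (
            np.arange(self.n_animals)
            if animals is None
            else self.animal_index(list(animals))
        )
        if markers is None:
            mi = np.arange(self.n_markers)
        else:
            mi = np.array([self.marker_index(m) for m in markers], dtype=np.int64)
            mi = np.sort(mi)
        return GenotypeMatrix(
            animal_ids=self.animal_ids[ai],
            marker_ids=self.marker_ids[mi],
            chrom=self.chrom[mi],
            pos_bp=self.pos_bp[mi],
            alleles=self.alleles[mi],
            dosage=self.dosage[np.ix_(ai, mi)],
            phased=self.phased,
            hap1=None if self.hap1 is None else self.hap1[np.ix_(ai, mi)],
            hap2=None if self.hap2 is None else self.hap2[np.ix_(ai, mi)],
        )

    def region(self, chrom: str, start_bp: int, end_bp: int) -> "GenotypeMatrix":
        """Markers on ``chrom`` with ``start_bp <= pos <= end_bp`` (closed)."""
        keep = (self.chrom == chrom) & (self.pos_bp >= start_bp) & (self.pos_bp <= end_bp)
        return self.subset(markers=self.marker_ids[keep])

    # -- numeric views ------------------------------------------------------

    def dosage_float(self, impute_mean: bool = False) -> np.ndarray:
        """Dosages as float64, optionally mean-imputing missing cells.

        Mean imputation is an explicit, logged step: model fitting requires
        complete data while QC and allele frequencies exclude missing calls
        pairwise.
        """
        x = self.dosage.astype(np.float64)
        miss = self.dosage == MISSING
        if miss.any():
            if not impute_mean:
                raise HornpredError(
                    f"{int(miss.sum())} missing dosages present; "
                    "pass impute_mean=True for model fitting"
                )
            col_mean = np.where(miss, np.nan, x).astype(np.float64)
            with np.errstate(invalid="ignore"):
                mu = np.nanmean(col_mean, axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)
            x[miss] = np.broadcast_to(mu, x.shape)[miss]
            logger.info("mean-imputed %d missing dosage cells", int(miss.sum()))
        return x


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Animal/sire/dam/sex records; parents may be founders (null parent).

    The underlying table has columns ``animal, sire, dam, sex, flock, year``
    with ``sire``/``dam`` as ``None`` for founders.  Construction checks that
    the pedigree is acyclic and that sex labels come from the two-level
    vocabulary (``female``/``wether``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal", "sire", "dam", "sex"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["animal"] = t["animal"].astype(str)
        for col in ("sire", "dam"):
            t[col] = t[col].where(t[col].notna(), None)
            t[col] = t[col].map(lambda v: None if v in (None, "", "0", 0) else str(v))
        t["sex"] = t["sex"].astype(str).str.lower()
        bad_sex = sorted(set(t["sex"]) - set(SEX_LABELS))
        if bad_sex:
            raise HornpredError(
                f"unknown sex label(s) {bad_sex}; allowed labels are {list(SEX_LABELS)}"
            )
        if t["animal"].duplicated().any():
            dup = t.loc[t["animal"].duplicated(), "animal"].iloc[0]
            raise ValueError(f"duplicate animal id {dup!r} in pedigree")
        self.table = t.reset_index(drop=True)
        # add implicit founder rows for parents that have no record of their own
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        ids = set(self.table["animal"])
        parents = {
            a: tuple(p for p in (s, d) if p is not None and p in ids)
            for a, s, d in zip(self.table["animal"], self.table["sire"], self.table["dam"])
        }
        state: dict[str, int] = {}
        stack_trace: list[str] = []

        def visit(a: str) -> None:
            state[a] = 1
            stack_trace.append(a)
            for p in parents.get(a, ()):
                st = state.get(p, 0)
                if st == 1:
                    cycle = stack_trace[stack_trace.index(p):] + [p]
                    raise HornpredError(
                        "cyclic pedigree: " + " -> ".join(cycle)
                    )
                if st == 0:
                    visit(p)
            stack_trace.pop()
            state[a] = 2

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, len(parents) * 2 + 100))
        try:
            for a in parents:
                if state.get(a, 0) == 0:
                    visit(a)
        finally:
            sys.setrecursionlimit(old)

    # -- views --------------------------------------------------------------

    @property
    def animal_ids(self) -> np.ndarray:
        return self.table["animal"].to_numpy(dtype=object)

    def founders(self) -> np.ndarray:
        """Animals with neither parent recorded in the pedigree."""
        ids = set(self.table["animal"])
        is_f = [
            (s is None or s not in ids) and (d is None or d not in ids)
            for s, d in zip(self.table["sire"], self.table["dam"])
        ]
        return self.table.loc[is_f, "animal"].to_numpy(dtype=object)

    def topological_order(self) -> list[str]:
        """Animal ids ordered so every parent precedes its offspring."""
        ids = set(self.table["animal"])
        parents = {
            a: [p for p in (s, d) if p is not None and p in ids]
            for a, s, d in zip(self.table["animal"], self.table["sire"], self.table["dam"])
        }
        order: list[str] = []
        seen: set[str] = set()

        # iterative DFS post-order; acyclicity already checked
        for root in self.table["animal"]:
            if root in seen:
                continue
            stack: list[tuple[str, bool]] = [(root, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    order.append(node)
                    continue
                if node in seen:
                    continue
                seen.add(node)
                stack.append((node, True))
                for p in parents[node]:
                    if p not in seen:
                        stack.append((p, False))
        return order

    def sex_of(self, animal_ids: Sequence[str]) -> np.ndarray:
        lut = dict(zip(self.table["animal"], self.table["sex"]))
        return np.array([lut[a] for a in animal_ids], dtype=object)

    def offspring_by_sire(self, phenotyped: Iterable[str] | None = None) -> dict[str, list[str]]:
        keep = set(phenotyped) if phenotyped is not None else None
        fam: dict[str, list[str]] = {}
        for a, s in zip(self.table["animal"], self.table["sire"]):
            if s is None:
                continue
            if keep is not None and a not in keep:
                continue
            fam.setdefault(s, []).append(a)
        return fam


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def derive_binary_traits(horn_score: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Derive the two binary traits from the four-class horn score.

    Polled/non-polled (``pnp``): polled = 0, everything else (knobs, scurs,
    horned) = 1.  Horned/non-horned (``hnh``): horned = 1, everything else = 0.
    Hence ``hnh <= pnp`` elementwise.
    """
    scores = np.array([str(s).strip().lower() for s in horn_score], dtype=object)
    bad = sorted(set(scores) - set(HORN_SCORES))
    if bad:
        raise HornpredError(
            f"unknown horn score(s) {bad}; allowed classes are {list(HORN_SCORES)}"
        )
    pnp = (scores != "polled").astype(np.int8)
    hnh = (scores == "horned").astype(np.int8)
    return pnp, hnh


@dataclass
class PhenotypeTable:
    """Per-animal horn score with the two derived binary traits."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal", "horn_score"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["animal"] = t["animal"].astype(str)
        t["horn_score"] = [str(s).strip().lower() for s in t["horn_score"]]
        pnp, hnh = derive_binary_traits(t["horn_score"])
        t["pnp"] = pnp
        t["hnh"] = hnh
        self.table = t.reset_index(drop=True)

    @property
    def animal_ids(self) -> np.ndarray:
        return self.table["animal"].to_numpy(dtype=object)

    def trait(self, name: str, animal_ids: Sequence[str] | None = None) -> np.ndarray:
        if name not in ("pnp", "hnh"):
            raise KeyError(f"unknown trait {name!r}; use 'pnp' or 'hnh'")
        t = self.table.set_index("animal")[name]
        if animal_ids is None:
            return t.to_numpy(dtype=np.float64)
        return t.loc[list(animal_ids)].to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from VCF or a PLINK-style ``.ped``/``.map`` text pair.

    For ``format="plink_text"`` pass the file prefix (without extension).
    Phase is captured from VCF ``|`` separators; the matrix is flagged phased
    only if every genotype in the file is phased.
    """
    if format == "vcf":
        return _read_vcf(Path(path))
    if format == "plink_text":
        return _read_plink(Path(path))
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    marker_ids, chrom, pos, alleles = [], [], [], []
    dos_cols, h1_cols, h2_cols = [], [], []
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1:
            raise HornpredError(
                f"multi-allelic record {var.ID or var.CHROM + ':' + str(var.POS)} "
                "is not supported; split or drop it first"
            )
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        alleles.append((var.REF, var.ALT[0]))
        gt = np.asarray(var.genotypes)  # (n, 3): a1, a2, phased
        a1, a2, ph = gt[:, 0], gt[:, 1], gt[:, 2].astype(bool)
        miss = (a1 < 0) | (a2 < 0)
        d = np.where(miss, MISSING, a1 + a2)
        dos_cols.append(d.astype(np.int16))
        h1_cols.append(np.where(miss, 0, a1).astype(np.int8))
        h2_cols.append(np.where(miss, 0, a2).astype(np.int8))
        if not ph.all():
            all_phased = False
    if not marker_ids:
        raise HornpredError(f"no variant records in {path}")
    dosage = np.column_stack(dos_cols)
    return GenotypeMatrix(
        animal_ids=samples,
        marker_ids=np.array(marker_ids, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        alleles=np.array(alleles, dtype=object),
        dosage=dosage,
        phased=all_phased,
        hap1=np.column_stack(h1_cols) if all_phased else None,
        hap2=np.column_stack(h2_cols) if all_phased else None,
    )


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT fields (``|`` separators if phased)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hornpred\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(geno.chrom):  # preserve order, unique
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.animal_ids))
            + "\n"
        )
        sep = "|" if geno.phased else "/"
        for j in range(geno.n_markers):
            ref, alt = geno.alleles[j]
            if geno.phased:
                g1, g2 = geno.hap1[:, j], geno.hap2[:, j]
            else:
                d = geno.dosage[:, j]
                g1 = np.where(d == 2, 1, 0)
                g2 = np.where(d >= 1, 1, 0)
            cells = [
                "./." if geno.dosage[i, j] == MISSING else f"{g1[i]}{sep}{g2[i]}"
                for i in range(geno.n_animals)
            ]
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos_bp[j]}\t{geno.marker_ids[j]}\t"
                f"{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(cells) + "\n"
            )


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write PLINK-style ``.ped``/``.map`` plus a ``.ref`` alt-allele file.

    The ``.ref`` file (marker, ref, alt) pins the counted allele so a
    round trip reproduces dosages exactly; without it a reader must guess
    orientation.
    """
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(geno.n_markers):
            fh.write(f"{geno.chrom[j]}\t{geno.marker_ids[j]}\t0\t{geno.pos_bp[j]}\n")
    with open(prefix.with_suffix(".ref"), "w") as fh:
        for j in range(geno.n_markers):
            ref, alt = geno.alleles[j]
            fh.write(f"{geno.marker_ids[j]}\t{ref}\t{alt}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(geno.n_animals):
            row = [str(geno.animal_ids[i]), str(geno.animal_ids[i]), "0", "0", "0", "-9"]
            for j in range(geno.n_markers):
                d = geno.dosage[i, j]
                ref, alt = geno.alleles[j]
                if d == MISSING:
                    row += ["0", "0"]
                elif geno.phased:
                    row += [alt if geno.hap1[i, j] else ref, alt if geno.hap2[i, j] else ref]
                else:
                    row += [alt] * d + [ref] * (2 - d)
            fh.write(" ".join(row) + "\n")


def _read_plink(prefix: Path) -> GenotypeMatrix:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    ref_path = prefix.with_suffix(".ref")
    for p in (map_path, ped_path):
        if not p.exists():
            raise FileNotFoundError(p)
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "pos"], dtype=str)
    marker_ids = mp["id"].to_numpy(dtype=object)
    chrom = mp["chrom"].to_numpy(dtype=object)
    pos = mp["pos"].astype(np.int64).to_numpy()
    m = len(marker_ids)

    alt_lut: dict[str, tuple[str, str]] = {}
    if ref_path.exists():
        rf = pd.read_csv(ref_path, sep="\t", header=None, names=["id", "ref", "alt"], dtype=str)
        alt_lut = {r.id: (r.ref, r.alt) for r in rf.itertuples()}

    animals, rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise HornpredError(
                    f"{ped_path} line {ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            animals.append(parts[1])
            rows.append(parts[6:])
    allele_pairs = np.array(rows, dtype=object).reshape(len(animals), m, 2)

    dosage = np.zeros((len(animals), m), dtype=np.int16)
    alleles = []
    for j in range(m):
        col = allele_pairs[:, j, :]
        obs = col[col != "0"]
        uniq = sorted(set(obs))
        if len(uniq) > 2:
            raise HornpredError(f"marker {marker_ids[j]} has >2 alleles in {ped_path}")
        if marker_ids[j] in alt_lut:
            ref, alt = alt_lut[marker_ids[j]]
        else:
            # fall back: minor allele counted as alt (logged — orientation guess)
            if len(uniq) == 2:
                counts = {a: int((obs == a).sum()) for a in uniq}
                alt = min(uniq, key=lambda a: (counts[a], a))
                ref = uniq[0] if uniq[1] == alt else uniq[1]
            else:
                ref = uniq[0] if uniq else "A"
                alt = "B"
            logger.info("marker %s: no .ref file, counting minor allele %s", marker_ids[j], alt)
        alleles.append((ref, alt))
        miss = (col[:, 0] == "0") | (col[:, 1] == "0")
        d = (col[:, 0] == alt).astype(np.int16) + (col[:, 1] == alt).astype(np.int16)
        dosage[:, j] = np.where(miss, MISSING, d)
    return GenotypeMatrix(
        animal_ids=np.array(animals, dtype=object),
        marker_ids=marker_ids,
        chrom=chrom,
        pos_bp=pos,
        alleles=np.array(alleles, dtype=object),
        dosage=dosage,
        phased=False,
    )


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a delimited pedigree table (animal,sire,dam,sex[,flock,year])."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return Pedigree(df)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    out = ped.table.copy()
    out.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a delimited phenotype table with columns ``animal, horn_score``."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return PhenotypeTable(df[[c for c in df.columns if c in ("animal", "horn_score")]])


def write_phenotypes(phe: PhenotypeTable, path: str | Path) -> None:
    phe.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Per-marker QC metrics with pass/fail flags and firing rules."""

    table: pd.DataFrame  # marker_id, call_rate, maf, hwe_chi2, rules, passed

    @property
    def n_failed(self) -> int:
        return int((~self.table["passed"]).sum())

    def failures_by_rule(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rules in self.table.loc[~self.table["passed"], "rules"]:
            for r in rules.split(","):
                if r:
                    counts[r] = counts.get(r, 0) + 1
        return counts

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def hwe_chisq(dosage_col: np.ndarray) -> float:
    """Genotype-count chi-square (1 df) against Hardy–Weinberg proportions.

    Expected proportions use the observed allele frequency; missing calls are
    excluded.  Monomorphic markers return 0.
    """
    d = dosage_col[dosage_col != MISSING]
    n = d.size
    if n == 0:
        return float("nan")
    n0 = float((d == 0).sum())
    n1 = float((d == 1).sum())
    n2 = float((d == 2).sum())
    p = (2 * n2 + n1) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n0, n1, n2])
    return float(((obs - exp) ** 2 / exp).sum())


def qc_filter(
    geno: GenotypeMatrix,
    call_rate_min: float = 0.90,
    hwe_chi2_max: float = 600.0,
    maf_min: float = 0.01,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers on call rate, HWE chi-square, MAF and autosomal status.

    Mirrors standard SNP-chip QC: a marker is removed if its call rate is
    below ``call_rate_min``, its HWE genotype-count chi-square exceeds
    ``hwe_chi2_max``, its minor allele frequency is below ``maf_min``, or it
    is not autosomal.  Every removal is reported with the firing rule(s).
    """
    if not (0 < call_rate_min <= 1):
        raise ValueError("call_rate_min must be in (0, 1]")
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if hwe_chi2_max <= 0:
        raise ValueError("hwe_chi2_max must be positive")

    n = geno.n_animals
    obs = geno.dosage != MISSING
    call_rate = obs.sum(axis=0) / n
    with np.errstate(invalid="ignore"):
        dsum = np.where(obs, geno.dosage, 0).sum(axis=0)
        nobs = obs.sum(axis=0)
        p = np.where(nobs > 0, dsum / np.maximum(2 * nobs, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    hwe = np.array([hwe_chisq(geno.dosage[:, j]) for j in range(geno.n_markers)])
    autosomal = np.array(
        [str(c).lower() not in NON_AUTOSOMAL for c in geno.chrom], dtype=bool
    )

    rules_per_marker: list[str] = []
    passed = np.ones(geno.n_markers, dtype=bool)
    for j in range(geno.n_markers):
        fired = []
        if call_rate[j] < call_rate_min:
            fired.append("call_rate")
        if np.isfinite(hwe[j]) and hwe[j] > hwe_chi2_max:
            fired.append("hwe")
        if not np.isfinite(maf[j]) or maf[j] < maf_min:
            fired.append("maf")
        if not autosomal[j]:
            fired.append("non_autosomal")
        rules_per_marker.append(",".join(fired))
        passed[j] = not fired

    report = QCReport(
        pd.DataFrame(
            {
                "marker_id": geno.marker_ids,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_chi2": hwe,
                "rules": rules_per_marker,
                "passed": passed,
            }
        )
    )
    if not passed.any():
        raise HornpredError("no markers pass QC; check thresholds and input data")
    kept = geno.subset(markers=geno.marker_ids[passed])
    logger.info(
        "QC removed %d of %d markers (%s)",
        report.n_failed,
        geno.n_markers,
        report.failures_by_rule(),
    )
    return kept, report
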