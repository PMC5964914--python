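"""Prediction strategies and validation designs for the binary horn traits.

Predictors
----------
* :func:`predict_marker_model` — a single SNP (or the causal insertion
  genotype) under its best mode-of-inheritance model, or a pooled-haplotype
  copy-count design, optionally joint with a polygenic term (pedigree A or
  genomic G).
* :func:`gblup_predict` — GBLUP with an additive G and optionally a dominance
  D relationship matrix; validation genetic values come either from the
  covariance blocks directly or by back-solving per-marker effects and
  applying them to validation genotypes (the two routes are algebraically
  identical and both are implemented).

Validation designs
------------------
Fivefold cross-validation repeated five times; within-family splits (half of
each big half-sib family trains, the other half tests); across-family splits
(half of the families train, the rest test).  Families are half-sib groups of
sires with more than a minimum number of offspring (default 13).  Accuracy is
the Pearson correlation between predicted phenotype and the observed binary
trait, reported per sex with the mean and standard error over folds.

Training fits never see validation phenotypes; deleting test-animal
phenotypes from the input leaves every prediction bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import HornpredError, Pedigree
from .kinship import DEFAULT_RIDGE, RelationshipMatrix
from .mixedmodel import MixedModelSpec, RandomTerm, fit_variance_components
from .inheritance import _STRUCTURE, MODEL_IDS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class PredictionResult:
    """Predicted phenotypes for validation animals with their components."""

    animal_ids: np.ndarray
    predicted: np.ndarray
    components: dict[str, np.ndarray]
    model_tag: str = ""

    def __post_init__(self) -> None:
        total = sum(self.components.values(), np.zeros(len(self.animal_ids)))
        if not np.allclose(total, self.predicted, atol=1e-8):
            raise ValueError("predicted is not the sum of its declared components")


@dataclass
class ValidationReport:
    """Per-fold, per-sex accuracies with means and standard errors."""

    scheme: str
    folds: pd.DataFrame  # repeat, fold, sex, accuracy, n
    model_tag: str = ""

    def summary(self) -> pd.DataFrame:
        """Mean accuracy and SE = sd/sqrt(#contributing folds) per sex."""
        rows = []
        for sx, grp in self.folds.groupby("sex", sort=False):
            acc = grp["accuracy"].dropna()
            if len(acc) < len(grp):
                logger.warning(
                    "%s: %d fold cells undefined for sex=%s (constant trait)",
                    self.scheme, len(grp) - len(acc), sx,
                )
            rows.append(
                (sx, acc.mean(), acc.std(ddof=1) / np.sqrt(len(acc)) if len(acc) > 1 else np.nan,
                 len(acc))
            )
        return pd.DataFrame(rows, columns=["sex", "mean_accuracy", "se", "n_folds"])


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------


def accuracy(
    predicted: np.ndarray,
    observed: np.ndarray,
    sex: np.ndarray | None = None,
) -> dict[str, float]:
    """Pearson correlation of prediction with the observed binary trait.

    Returned per sex (plus ``"pooled"``).  Cells with fewer than 3 pairs or
    zero variance in either vector are NaN (undefined, flagged by a log
    warning), never silently 0.
    """
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed lengths differ")

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) < 3 or np.var(a) == 0 or np.var(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    out = {"pooled": _corr(pred, obs)}
    if sex is not None:
        s = np.asarray(sex, dtype=object)
        for sx in pd.unique(s):
            m = s == sx
            out[str(sx)] = _corr(pred[m], obs[m])
    return out


# ---------------------------------------------------------------------------
# Marker-based prediction
# ---------------------------------------------------------------------------


@dataclass
class MarkerModelSpec:
    """What the marker part of a prediction model fits.

    ``kind='single'`` / ``'insertion'``: a 0/1/2 genotype under mode-of-
    inheritance ``model_id``; ``kind='haplotype'``: a pooled copy-count
    design with one shared variance.  All arrays are aligned to the caller's
    animal order.
    """

    kind: str  # single | insertion | haplotype
    marker_id: str = ""
    model_id: int = 1
    dosage: np.ndarray | None = None
    hap_design: np.ndarray | None = None
    genotyping_error: float = 0.0  # for insertion: per-animal flip rate
    error_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("single", "insertion", "haplotype"):
            raise ValueError(f"unknown marker-model kind {self.kind!r}")
        if self.kind in ("single", "insertion"):
            if self.dosage is None:
                raise ValueError("single/insertion spec requires dosage")
            if self.model_id not in MODEL_IDS:
                raise ValueError(f"model_id must be in {MODEL_IDS}")
        else:
            if self.hap_design is None:
                raise ValueError("haplotype spec requires hap_design")

    def effective_dosage(self) -> np.ndarray:
        """Dosage with optional symmetric genotyping error applied.

        Emulates imputation error of the causal insertion: each animal's
        genotype is replaced, with probability ``genotyping_error``, by a
        draw from the observed genotype distribution.
        """
        d = np.asarray(self.dosage, float)
        if self.genotyping_error <= 0:
            return d
        rng = np.random.default_rng(self.error_seed)
        flip = rng.random(len(d)) < self.genotyping_error
        pool = rng.choice(d, size=len(d), replace=True)
        return np.where(flip, pool, d)


def _marker_columns(spec: MarkerModelSpec, sex: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Named random-effect covariate columns for the marker part."""
    if spec.kind == "haplotype":
        H = np.asarray(spec.hap_design, float)
        return [("haplotype", H)]
    lam = spec.effective_dosage()
    is_w = (np.asarray(sex, dtype=object) == "wether").astype(float)
    is_f = 1.0 - is_w
    delta = (np.rint(lam) == 1).astype(float)
    pooled_a, pooled_d, sex_a, sex_d = _STRUCTURE[spec.model_id]
    cols: list[tuple[str, np.ndarray]] = []
    if pooled_a:
        cols.append(("alpha", lam))
    if sex_a:
        cols.append(("alpha_female", lam * is_f))
        cols.append(("alpha_wether", lam * is_w))
    if pooled_d:
        cols.append(("delta", delta))
    if sex_d:
        cols.append(("delta_female", delta * is_f))
        cols.append(("delta_wether", delta * is_w))
    return cols


def _polygenic_blup_validation(
    K: RelationshipMatrix,
    train_ids: Sequence[str],
    valid_ids: Sequence[str],
    u_train: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
) -> np.ndarray:
    """BLUP of validation genetic values from their covariance with training.

    ``u_val = K_vt (K_tt + ridge I)^-1 u_train`` — the conditional mean of the
    validation effects given the training BLUPs.  Validation animals with no
    covariance to training get exactly 0.
    """
    known = set(K.labels)
    missing = [a for a in list(train_ids) + list(valid_ids) if a not in known]
    if missing:
        raise HornpredError(
            f"animals absent from the {K.kind} covariance structure: {missing[:5]}"
        )
    K_tt = K.block(train_ids, train_ids) + ridge * np.eye(len(train_ids))
    K_vt = K.block(valid_ids, train_ids)
    return K_vt @ np.linalg.solve(K_tt, u_train)


def predict_marker_model(
    spec: MarkerModelSpec,
    trait: np.ndarray,
    sex: np.ndarray,
    animal_ids: Sequence[str],
    train_ids: Sequence[str],
    valid_ids: Sequence[str],
    polygenic: RelationshipMatrix | None = None,
    method: str = "REML",
) -> PredictionResult:
    """Fit a marker/haplotype model on training animals and predict validation.

    The prediction is intercept + fixed sex effect + marker (or haplotype)
    random-effect solutions applied to the validation designs + (when a
    relationship matrix is supplied) the polygenic BLUP of validation animals
    from their covariance with training animals.
    """
    ids = np.asarray(list(animal_ids), dtype=object)
    lut = {a: i for i, a in enumerate(ids)}
    tr = np.array([lut[a] for a in train_ids], dtype=np.int64)
    va = np.array([lut[a] for a in valid_ids], dtype=np.int64)

    y = np.asarray(trait, float)
    sex = np.asarray(sex, dtype=object)
    cols = _marker_columns(spec, sex)

    is_w = (sex == "wether").astype(float)
    X = np.column_stack([np.ones(len(ids)), is_w])
    terms: list[RandomTerm] = []
    if polygenic is not None:
        K_tt = polygenic.block(train_ids, train_ids)
        terms.append(RandomTerm("polygenic", Z=None, K=K_tt))
    for name, Z in cols:
        terms.append(RandomTerm(name, Z=np.asarray(Z, float)[tr]))

    mspec = MixedModelSpec(
        y=y[tr], X=X[tr], fixed_names=["intercept", "sex_wether"], random_terms=terms
    )
    fit = fit_variance_components(mspec, method=method)

    components: dict[str, np.ndarray] = {}
    components["fixed"] = X[va] @ fit.beta
    marker_total = np.zeros(len(va))
    for name, Z in cols:
        Zv = np.asarray(Z, float)[va]
        if Zv.ndim == 1:
            Zv = Zv[:, None]
        u = np.atleast_1d(fit.blups[name])
        marker_total += Zv @ u
    components["marker"] = marker_total
    if polygenic is not None:
        components["polygenic"] = _polygenic_blup_validation(
            polygenic, list(train_ids), list(valid_ids), fit.blups["polygenic"]
        )
    predicted = sum(components.values(), np.zeros(len(va)))
    tag = f"{spec.kind}:{spec.marker_id or 'hap'}" + (
        f"+{polygenic.kind}" if polygenic is not None else ""
    )
    return PredictionResult(
        animal_ids=np.asarray(list(valid_ids), dtype=object),
        predicted=predicted,
        components=components,
        model_tag=tag,
    )


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------


def backsolve_marker_effects(
    gebv: np.ndarray,
    W: np.ndarray,
    G: RelationshipMatrix,
    ridge: float = DEFAULT_RIDGE,
) -> np.ndarray:
    """Back-solve per-marker effects from individual-level genomic values.

    ``alpha_hat = (1/c) W' (G + ridge I)^-1 gebv`` where W is the centred
    coding matrix and c the scale constant of the GRM built from the same W.
    The reconstruction ``W alpha_hat`` reproduces gebv up to the ridge.
    """
    W = np.asarray(W, float)
    g = np.asarray(gebv, float)
    if G.scale_c is None:
        raise HornpredError("relationship matrix has no scale constant; not genomic")
    if W.shape[0] != G.n or len(g) != G.n:
        raise HornpredError("W/GEBV dimensions do not match the relationship matrix")
    Ginv_g = np.linalg.solve(G.with_ridge(ridge), g)
    return (W.T @ Ginv_g) / G.scale_c


def genomic_codings(geno, frequencies: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Centred additive (W) and dominance (H) codings matching the G/D builds.

    Monomorphic markers are excluded exactly as in the relationship-matrix
    construction, so ``W W' / c_a`` reproduces G and ``H H' / c_d`` reproduces
    D built from the same genotypes and frequencies.
    """
    from .kinship import allele_frequencies, dominance_codes

    p = allele_frequencies(geno) if frequencies is None else np.asarray(frequencies, float)
    poly = (p > 0) & (p < 1)
    M = geno.dosage_float(impute_mean=True)[:, poly]
    p = p[poly]
    W = M - 2.0 * p
    H = dominance_codes(M, p)
    return {
        "W": W,
        "H": H,
        "c_a": float(2.0 * np.sum(p * (1.0 - p))),
        "c_d": float(np.sum((2.0 * p * (1.0 - p)) ** 2)),
    }


def gblup_predict(
    trait: np.ndarray,
    sex: np.ndarray,
    animal_ids: Sequence[str],
    train_ids: Sequence[str],
    valid_ids: Sequence[str],
    G: RelationshipMatrix,
    D: RelationshipMatrix | None = None,
    route: str = "covariance",
    codings: dict[str, np.ndarray] | None = None,
    method: str = "REML",
    ridge: float = DEFAULT_RIDGE,
) -> PredictionResult:
    """GBLUP prediction with additive G and optional dominance D.

    Variance components are estimated on the training subset.  When marker
    codings are supplied (``codings={'W': ..., 'H': ...}`` row-aligned to
    ``animal_ids``, see :func:`genomic_codings`) the fit exploits the low
    rank of G = WW'/c: the genetic terms enter as scaled marker designs,
    which is exact and far cheaper than factorising the n x n covariance.
    Validation genetic values come from:

    * ``route='covariance'`` — the covariance blocks,
      ``g_val = G_vt (G_tt + ridge I)^-1 g_train`` (same for dominance);
    * ``route='backsolve'`` — per-marker additive (and dominance) effects
      back-solved from the training values and applied to validation codings.

    Both routes are algebraically identical when G (and D) were built from
    the same codings.
    """
    if route not in ("covariance", "backsolve"):
        raise ValueError("route must be 'covariance' or 'backsolve'")
    if route == "backsolve" and (codings is None or "W" not in codings):
        raise HornpredError("backsolve route requires codings={'W': ...}")
    if D is not None and route == "backsolve" and "H" not in codings:
        raise HornpredError("backsolve with dominance requires codings={'H': ...}")
    ids = np.asarray(list(animal_ids), dtype=object)
    lut = {a: i for i, a in enumerate(ids)}
    tr = np.array([lut[a] for a in train_ids], dtype=np.int64)
    va = np.array([lut[a] for a in valid_ids], dtype=np.int64)
    y = np.asarray(trait, float)
    sex = np.asarray(sex, dtype=object)
    is_w = (sex == "wether").astype(float)
    X = np.column_stack([np.ones(len(ids)), is_w])

    lowrank = codings is not None and "W" in codings and (D is None or "H" in codings)
    terms: list[RandomTerm] = []
    if lowrank:
        if G.scale_c is None:
            raise HornpredError("G has no scale constant; rebuild from genotypes")
        terms.append(RandomTerm("additive", Z=np.asarray(codings["W"], float)[tr]
                                / np.sqrt(G.scale_c)))
        if D is not None:
            terms.append(RandomTerm("dominance", Z=np.asarray(codings["H"], float)[tr]
                                    / np.sqrt(D.scale_c)))
    else:
        G_tt = G.subset(list(train_ids))
        try:
            np.linalg.cholesky(G_tt.with_ridge(ridge))
        except np.linalg.LinAlgError as exc:
            raise HornpredError("singular training block in G") from exc
        terms.append(RandomTerm("additive", Z=None, K=G_tt.with_ridge(ridge)))
        if D is not None:
            terms.append(RandomTerm("dominance", Z=None,
                                    K=D.subset(list(train_ids)).with_ridge(ridge)))
    mspec = MixedModelSpec(
        y=y[tr], X=X[tr], fixed_names=["intercept", "sex_wether"], random_terms=terms
    )
    fit = fit_variance_components(mspec, method=method)

    components: dict[str, np.ndarray] = {"fixed": X[va] @ fit.beta}

    def _training_values(name: str) -> np.ndarray:
        # individual-level genetic values of the training animals
        return fit.contributions[name] if lowrank else fit.blups[name]

    def _project(K: RelationshipMatrix, u_train: np.ndarray, coding_key: str) -> np.ndarray:
        if route == "covariance":
            return _polygenic_blup_validation(K, list(train_ids), list(valid_ids),
                                              u_train, ridge=ridge)
        C = np.asarray(codings[coding_key], float)
        eff = backsolve_marker_effects(u_train, C[tr], K.subset(list(train_ids)), ridge=ridge)
        return C[va] @ eff

    components["additive"] = _project(G, _training_values("additive"), "W")
    if D is not None:
        components["dominance"] = _project(D, _training_values("dominance"), "H")

    predicted = sum(components.values(), np.zeros(len(va)))
    tag = "gblup" + ("+D" if D is not None else "") + f":{route}"
    return PredictionResult(
        animal_ids=np.asarray(list(valid_ids), dtype=object),
        predicted=predicted,
        components=components,
        model_tag=tag,
    )


# ---------------------------------------------------------------------------
# Validation designs
# ---------------------------------------------------------------------------

Predictor = Callable[[list[str], list[str]], np.ndarray]
"""A fitted-on-train predictor: (train_ids, valid_ids) -> predictions."""


def kfold_cv(
    trait: np.ndarray,
    sex: np.ndarray,
    animal_ids: Sequence[str],
    predictor: Predictor,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    scheme_name: str = "cv5x5",
    model_tag: str = "",
) -> ValidationReport:
    """Repeated k-fold cross-validation with per-sex Pearson accuracy.

    Animal-level random partitions (fold sizes differ by at most one); the
    mean and SE pool all ``k x repeats`` folds.
    """
    from sklearn.model_selection import KFold

    if k < 2:
        raise ValueError("k must be >= 2")
    ids = np.asarray(list(animal_ids), dtype=object)
    y = np.asarray(trait, float)
    s = np.asarray(sex, dtype=object)
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(repeats)):
        rs = int(child.generate_state(1)[0] % (2**31))
        kf = KFold(n_splits=k, shuffle=True, random_state=rs)
        for fold, (tr, va) in enumerate(kf.split(ids)):
            pred = predictor(list(ids[tr]), list(ids[va]))
            acc = accuracy(pred, y[va], s[va])
            for sx in pd.unique(s):
                rows.append((rep, fold, str(sx), acc.get(str(sx), np.nan), int((s[va] == sx).sum())))
    return ValidationReport(
        scheme=scheme_name,
        folds=pd.DataFrame(rows, columns=["repeat", "fold", "sex", "accuracy", "n"]),
        model_tag=model_tag,
    )


def family_split(
    pedigree: Pedigree,
    phenotyped_ids: Sequence[str],
    mode: str = "within",
    min_offspring: int = 13,
    n_folds: int = 5,
    seed: int = 0,
) -> list[tuple[list[str], list[str]]]:
    """Train/test splits over big half-sib families.

    Eligible animals are offspring of sires with **more than**
    ``min_offspring`` phenotyped offspring.  ``mode='within'``: roughly half
    of each family trains and the rest tests (every eligible sire appears on
    both sides; odd counts resolve toward training).  ``mode='across'``:
    roughly half of the families train as whole units, so no sire appears on
    both sides.  ``n_folds`` independent randomised splits are returned.
    """
    if mode not in ("within", "across"):
        raise ValueError("mode must be 'within' or 'across'")
    fams = pedigree.offspring_by_sire(phenotyped=phenotyped_ids)
    eligible = {s: kids for s, kids in fams.items() if len(kids) > min_offspring}
    if not eligible:
        raise HornpredError(
            f"no sires with more than {min_offspring} phenotyped offspring"
        )
    rng = np.random.default_rng(seed)
    splits: list[tuple[list[str], list[str]]] = []
    sires = sorted(eligible)
    for _ in range(n_folds):
        train: list[str] = []
        test: list[str] = []
        if mode == "within":
            for s in sires:
                kids = list(eligible[s])
                rng.shuffle(kids)
                half = (len(kids) + 1) // 2  # odd counts toward training
                train += kids[:half]
                test += kids[half:]
        else:
            order = list(sires)
            rng.shuffle(order)
            half = (len(order) + 1) // 2
            for s in order[:half]:
                train += eligible[s]
            for s in order[half:]:
                test += eligible[s]
        splits.append((train, test))
    return splits


def family_validation(
    trait: np.ndarray,
    sex: np.ndarray,
    animal_ids: Sequence[str],
    predictor: Predictor,
    splits: Sequence[tuple[list[str], list[str]]],
    scheme_name: str,
    model_tag: str = "",
) -> ValidationReport:
    """Run a predictor over precomputed family splits and score per sex."""
    ids = np.asarray(list(animal_ids), dtype=object)
    lut = {a: i for i, a in enumerate(ids)}
    y = np.asarray(trait, float)
    s = np.asarray(sex, dtype=object)
    rows = []
    for fold, (train, test) in enumerate(splits):
        pred = predictor(list(train), list(test))
        idx = np.array([lut[a] for a in test], dtype=np.int64)
        acc = accuracy(pred, y[idx], s[idx])
        for sx in pd.unique(s):
            rows.append((0, fold, str(sx), acc.get(str(sx), np.nan), int((s[idx] == sx).sum())))
    return ValidationReport(
        scheme=scheme_name,
        folds=pd.DataFrame(rows, columns=["repeat", "fold", "sex", "accuracy", "n"]),
        model_tag=model_tag,
    )
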