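"""Mode-of-inheritance models for a single marker with sex interactions.

Five nested specifications of the marker effect on a binary horn trait, all
fitted as random effects alongside an optional polygenic term:

1. additive (allele-substitution effect alpha)
2. additive + dominance (alpha + heterozygosity effect delta)
3. sex-dependent additive (alpha per sex)
4. additive + sex-dependent dominance (alpha + delta per sex)
5. sex-dependent additive + sex-dependent dominance

Sex enters the fixed part as a main effect in every model (hierarchy
principle: interactions without the main effect would confound sex with the
marker term).  Sex-dependent effects are separate random effects per sex,
each with its own variance.  Models are compared by AIC on ML likelihoods;
incomplete penetrance is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HornpredError
from .kinship import RelationshipMatrix
from .mixedmodel import (
    KinshipEigen,
    MixedModelFit,
    MixedModelSpec,
    RandomTerm,
    fit_variance_components,
)

MODEL_IDS = (1, 2, 3, 4, 5)

#: marker terms per model: (pooled_alpha, pooled_delta, sex_alpha, sex_delta)
_STRUCTURE = {
    1: (True, False, False, False),
    2: (True, True, False, False),
    3: (False, False, True, False),
    4: (True, False, False, True),
    5: (False, False, True, True),
}


@dataclass
class MOIModelFit:
    """A fitted mode-of-inheritance model."""

    model_id: int
    trait: str
    marker_id: str
    fit: MixedModelFit

    @property
    def aic(self) -> float:
        return self.fit.aic


def build_moi_design(
    model_id: int,
    trait: np.ndarray,
    dosage: np.ndarray,
    sex: np.ndarray,
    kinship: RelationshipMatrix | KinshipEigen | np.ndarray | None = None,
    polygenic_name: str = "polygenic",
) -> MixedModelSpec:
    """Assemble the mixed-model spec for one mode-of-inheritance model.

    ``dosage`` is the 0/1/2 marker genotype (Lambda); the heterozygosity
    indicator Delta is 1 for dosage 1.  ``sex`` holds 'female'/'wether'
    labels.  ``kinship`` (aligned to the same animals) adds the polygenic
    random term; ``None`` fits marker terms only.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"model_id must be one of {MODEL_IDS}")
    y = np.asarray(trait, dtype=np.float64)
    lam = np.asarray(dosage, dtype=np.float64)
    if not np.isin(lam, (0.0, 1.0, 2.0)).all():
        raise HornpredError("marker genotypes must be complete 0/1/2 for MOI fitting")
    sex = np.asarray(sex, dtype=object)
    is_w = (sex == "wether").astype(np.float64)
    is_f = (sex == "female").astype(np.float64)
    delta = (lam == 1.0).astype(np.float64)

    X = np.column_stack([np.ones_like(y), is_w])
    fixed_names = ["intercept", "sex_wether"]

    terms: list[RandomTerm] = []
    if kinship is not None:
        K = kinship
        if isinstance(K, RelationshipMatrix):
            K = K.values
        terms.append(RandomTerm(polygenic_name, Z=None, K=K))

    pooled_a, pooled_d, sex_a, sex_d = _STRUCTURE[model_id]
    if pooled_a:
        terms.append(RandomTerm("alpha", Z=lam))
    if sex_a:
        terms.append(RandomTerm("alpha_female", Z=lam * is_f))
        terms.append(RandomTerm("alpha_wether", Z=lam * is_w))
    if pooled_d:
        terms.append(RandomTerm("delta", Z=delta))
    if sex_d:
        for label, ind in (("female", is_f), ("wether", is_w)):
            if not np.any(delta * ind):
                raise HornpredError(
                    f"model {model_id}: no heterozygotes among {label}s — "
                    "the per-sex dominance cell is empty"
                )
        terms.append(RandomTerm("delta_female", Z=delta * is_f))
        terms.append(RandomTerm("delta_wether", Z=delta * is_w))
    return MixedModelSpec(y=y, X=X, fixed_names=fixed_names, random_terms=terms)


def fit_moi(
    model_id: int,
    trait: np.ndarray,
    dosage: np.ndarray,
    sex: np.ndarray,
    kinship: RelationshipMatrix | KinshipEigen | np.ndarray | None = None,
    trait_name: str = "",
    marker_id: str = "",
) -> MOIModelFit:
    """Fit one mode-of-inheritance model by ML (AIC-comparable)."""
    spec = build_moi_design(model_id, trait, dosage, sex, kinship)
    fit = fit_variance_components(spec, method="ML")
    return MOIModelFit(model_id=model_id, trait=trait_name, marker_id=marker_id, fit=fit)


def select_mode_of_inheritance(
    trait: np.ndarray,
    dosage: np.ndarray,
    sex: np.ndarray,
    kinship: RelationshipMatrix | KinshipEigen | np.ndarray | None = None,
    trait_name: str = "",
    marker_id: str = "",
) -> tuple[pd.DataFrame, MOIModelFit | None]:
    """Fit models 1–5 and rank them by AIC.

    Returns the five-row AIC table (``delta_aic`` is improvement over model
    1, positive = better) and the best fit.  A model that fails to fit is
    annotated in the table and skipped for selection; ties in AIC go to the
    lower model id.
    """
    fits: dict[int, MOIModelFit] = {}
    errors: dict[int, str] = {}
    for mid in MODEL_IDS:
        try:
            fits[mid] = fit_moi(mid, trait, dosage, sex, kinship,
                                trait_name=trait_name, marker_id=marker_id)
        except HornpredError as exc:
            errors[mid] = str(exc)
    if 1 not in fits:
        raise HornpredError(f"null model failed to fit: {errors.get(1, 'unknown error')}")
    aic_null = fits[1].aic
    rows = []
    best_id, best_aic = None, np.inf
    for mid in MODEL_IDS:
        if mid in fits:
            aic = fits[mid].aic
            rows.append((mid, aic, aic_null - aic, fits[mid].fit.n_params, ""))
            if aic < best_aic - 1e-12:  # strict improvement; ties keep lower id
                best_id, best_aic = mid, aic
        else:
            rows.append((mid, np.nan, np.nan, np.nan, errors[mid]))
    table = pd.DataFrame(rows, columns=["model", "aic", "delta_aic", "n_params", "note"])
    table["best"] = table["model"] == best_id
    return table, fits.get(best_id)


# ---------------------------------------------------------------------------
# Degree of dominance
# ---------------------------------------------------------------------------


@dataclass
class DominanceSummary:
    """Genotype-class means and the degree of dominance d/a per sex."""

    table: pd.DataFrame  # sex, m0, m1, m2, a, d, degree, flipped, available


def dominance_from_means(m0: float, m1: float, m2: float) -> tuple[float, float, float, bool]:
    """(a, d, d/a, flipped) from the three genotype-class means.

    Orientation: genotype labels are flipped (0 <-> 2) when ``m2 < m0`` so
    the additive scale ``a = (m2 - m0) / 2`` is non-negative; the dominance
    deviation ``d = m1 - (m0 + m2)/2`` is orientation-invariant.  ``|d/a| = 1``
    is complete dominance, 0 pure additivity.
    """
    flipped = m2 < m0
    if flipped:
        m0, m2 = m2, m0
    a = (m2 - m0) / 2.0
    d = m1 - (m0 + m2) / 2.0
    degree = d / a if a > 0 else np.nan
    return a, d, degree, flipped


def degree_of_dominance(
    genotype: np.ndarray,
    trait: np.ndarray,
    sex: np.ndarray,
) -> DominanceSummary:
    """Per-sex genotype-class means of the binary trait and d/a.

    A sex with an empty genotype class is reported unavailable rather than
    extrapolated.
    """
    g = np.asarray(genotype, dtype=int)
    y = np.asarray(trait, dtype=float)
    s = np.asarray(sex, dtype=object)
    rows = []
    for sx in pd.unique(s):
        means = []
        ok = True
        for cls in (0, 1, 2):
            m = (s == sx) & (g == cls)
            if not m.any():
                ok = False
                means.append(np.nan)
            else:
                means.append(float(y[m].mean()))
        if ok:
            a, d, degree, flipped = dominance_from_means(*means)
        else:
            a = d = degree = np.nan
            flipped = False
        rows.append((sx, *means, a, d, degree, flipped, ok))
    return DominanceSummary(
        pd.DataFrame(
            rows,
            columns=["sex", "m0", "m1", "m2", "a", "d", "degree", "flipped", "available"],
        )
    )
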