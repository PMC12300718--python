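"""Frozen published models and the sequential classify-then-quantify screen.

The full-dataset models are published as printed linear equations with
rounded coefficients; this module freezes them verbatim:

Classification (121 training compounds)::

    Class A score = -47 + 37*GATS3e + 79*ATSC6p + 10*GATS8m + 39*MIC2 + ln(0.61)
    Class I score = -38 + 30*GATS3e + 73*ATSC6p + 8.1*GATS8m + 32*MIC2 + ln(0.39)

Regression (63 training compounds)::

    Log RP = -2.7 + 1.6*piPC5 - 3.3*GGI9 - 11*AATSC0e

A compound is assigned to the higher-scoring class (exact ties go to A, the
precautionary choice); posteriors are the softmax of the two scores.  The
prior terms use the natural log, the canonical LDA form.  These frozen
equations are deliberately distinct from any model refit by
:mod:`ttrqsar.model_build`: they are the published models, applied as
printed.  ``Log RP >= -1.26`` marks a strong hTTR binder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import softmax

from .applicability import (
    ADVerdict,
    ClassificationAD,
    RegressionAD,
    assess_classification,
    assess_regression,
)
from .chem_io import CompoundRecord
from .descriptors import compute_model_descriptors

logger = logging.getLogger("ttrqsar")

MODEL_VERSION = "full-dataset-1.0"

LDA_DESCRIPTORS = ("GATS3e", "ATSC6p", "GATS8m", "MIC2")
MLR_DESCRIPTORS = ("piPC5", "GGI9", "AATSC0e")

STRONG_BINDER_THRESHOLD = -1.26  # Log RP at or above which a binder is "strong"


@dataclass(frozen=True)
class FrozenLDA:
    """The published classification equations, coefficients as printed."""

    descriptor_names: tuple[str, ...] = LDA_DESCRIPTORS
    classes: tuple[str, str] = ("A", "I")
    intercepts: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType({"A": -47.0, "I": -38.0})
    )
    weights: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: MappingProxyType(
            {"A": (37.0, 79.0, 10.0, 39.0), "I": (30.0, 73.0, 8.1, 32.0)}
        )
    )
    priors: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType({"A": 0.61, "I": 0.39})
    )
    version: str = MODEL_VERSION

    def _vector(self, descriptors) -> np.ndarray:
        if isinstance(descriptors, Mapping):
            missing = [d for d in self.descriptor_names if d not in descriptors]
            if missing:
                raise ValueError(f"missing descriptors: {missing}")
            descriptors = [descriptors[d] for d in self.descriptor_names]
        x = np.asarray(descriptors, dtype=float)
        if x.shape[-1] != len(self.descriptor_names) or not np.all(np.isfinite(x)):
            raise ValueError("need four finite descriptor values")
        return np.atleast_2d(x)

    def scores(self, descriptors) -> np.ndarray:
        x = self._vector(descriptors)
        return np.column_stack(
            [
                self.intercepts[c]
                + x @ np.asarray(self.weights[c])
                + np.log(self.priors[c])
                for c in self.classes
            ]
        )

    def posterior(self, descriptors) -> np.ndarray:
        return softmax(self.scores(descriptors), axis=1)

    def classify(self, descriptors) -> tuple[str, np.ndarray, np.ndarray]:
        """(class, scores, posteriors) for one compound; ties go to A."""
        s = self.scores(descriptors)[0]
        post = softmax(s)
        cls = "A" if s[0] >= s[1] else "I"
        return cls, s, post


@dataclass(frozen=True)
class FrozenMLR:
    """The published Log RP regression equation, coefficients as printed."""

    descriptor_names: tuple[str, ...] = MLR_DESCRIPTORS
    intercept: float = -2.7
    weights: tuple[float, ...] = (1.6, -3.3, -11.0)
    coefficient_se: tuple[float, ...] = (1.3, 0.26, 0.79, 2.7)  # intercept first
    strong_threshold: float = STRONG_BINDER_THRESHOLD
    version: str = MODEL_VERSION

    def _vector(self, descriptors) -> np.ndarray:
        if isinstance(descriptors, Mapping):
            missing = [d for d in self.descriptor_names if d not in descriptors]
            if missing:
                raise ValueError(f"missing descriptors: {missing}")
            descriptors = [descriptors[d] for d in self.descriptor_names]
        x = np.asarray(descriptors, dtype=float)
        if x.shape[-1] != len(self.descriptor_names) or not np.all(np.isfinite(x)):
            raise ValueError("need three finite descriptor values")
        return np.atleast_2d(x)

    def predict(self, descriptors) -> np.ndarray:
        return self.intercept + self._vector(descriptors) @ np.asarray(self.weights)


FROZEN_LDA = FrozenLDA()
FROZEN_MLR = FrozenMLR()


def frozen_classify(descriptors) -> tuple[str, np.ndarray, np.ndarray]:
    """Apply the printed classification equations; see :class:`FrozenLDA`."""
    return FROZEN_LDA.classify(descriptors)


def frozen_predict_logrp(descriptors) -> float:
    """Apply the printed Log RP equation; see :class:`FrozenMLR`."""
    return float(FROZEN_MLR.predict(descriptors)[0])


# ---------------------------------------------------------------------------
# Sequential screening


@dataclass
class ScreeningResult:
    id: str
    smiles: str
    descriptors: Optional[dict[str, float]]
    activity_class: Optional[str] = None
    posterior_a: Optional[float] = None
    classification_verdict: Optional[ADVerdict] = None
    log_rp: Optional[float] = None
    regression_verdict: Optional[ADVerdict] = None
    strong_binder: Optional[bool] = None
    tier: str = "unreliable"
    error: Optional[str] = None


def sequential_screen(
    compounds: Sequence,
    lda_ad: ClassificationAD,
    mlr_ad: RegressionAD,
    strong_threshold: float = STRONG_BINDER_THRESHOLD,
    lda: FrozenLDA = FROZEN_LDA,
    mlr: FrozenMLR = FROZEN_MLR,
) -> tuple[list[ScreeningResult], dict]:
    """Classify every compound, then quantify the reliable actives.

    Each compound (SMILES string or :class:`CompoundRecord`) is classified
    with the frozen LDA equations; predictions outside the classification AD
    or with a maximum posterior below the band edge are tiered
    ``unreliable``.  Reliable class-I compounds are tiered
    ``weak/not active``.  Reliable class-A compounds get a Log RP prediction
    from the frozen MLR equation; if the regression verdict is reliable the
    tier is ``active-strong`` when Log RP >= ``strong_threshold`` (inclusive)
    and ``active-moderate`` otherwise, else ``unreliable``.  Per-compound
    failures are recorded and never abort the batch.
    """
    results: list[ScreeningResult] = []
    for i, comp in enumerate(compounds, 1):
        if isinstance(comp, CompoundRecord):
            cid, smiles = comp.id, comp.smiles
        else:
            cid, smiles = f"mol{i}", str(comp)
        try:
            desc = compute_model_descriptors(smiles)
        except Exception as exc:  # noqa: BLE001 - robustness contract
            logger.warning("screening failure for %s: %s", cid, exc)
            results.append(ScreeningResult(cid, smiles, None, error=str(exc), tier="failed"))
            continue
        res = ScreeningResult(cid, smiles, desc)
        x_lda = np.array([desc[d] for d in lda.descriptor_names])
        cls, _, post = lda.classify(x_lda)
        res.activity_class = cls
        res.posterior_a = float(post[0])
        res.classification_verdict = assess_classification(x_lda, lda, lda_ad)
        if res.classification_verdict.overall != "reliable":
            res.tier = "unreliable"
        elif cls == "I":
            res.tier = "weak/not active"
        else:
            x_mlr = np.array([desc[d] for d in mlr.descriptor_names])
            res.log_rp = float(mlr.predict(x_mlr)[0])
            res.regression_verdict = assess_regression(x_mlr, mlr, mlr_ad)
            if res.regression_verdict.overall != "reliable":
                res.tier = "unreliable"
            else:
                res.strong_binder = res.log_rp >= strong_threshold
                res.tier = "active-strong" if res.strong_binder else "active-moderate"
        results.append(res)
    return results, screening_summary(results)


def screening_summary(results: Sequence[ScreeningResult]) -> dict:
    """Per-category counts and percentages in the shape of a coverage table."""
    n = len(results)
    failed = sum(r.tier == "failed" for r in results)
    screened = n - failed
    tiers = {}
    for t in ("weak/not active", "active-moderate", "active-strong", "unreliable"):
        tiers[t] = sum(r.tier == t for r in results)
    classified_reliable = sum(
        r.classification_verdict is not None and r.classification_verdict.overall == "reliable"
        for r in results
    )
    active = sum(r.activity_class == "A" for r in results if r.tier not in ("failed",))
    strong = tiers["active-strong"]
    return {
        "n_input": n,
        "n_failed": failed,
        "n_screened": screened,
        "tiers": tiers,
        "n_inside_classification_ad": classified_reliable,
        "pct_reliable_classification": 100.0 * classified_reliable / screened if screened else 0.0,
        "n_active": active,
        "pct_active": 100.0 * active / screened if screened else 0.0,
        "n_strong_binders": strong,
        "pct_strong_of_active": 100.0 * strong / active if active else 0.0,
        "n_log_rp_positive": sum(r.log_rp is not None and r.log_rp > 0 for r in results),
    }
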