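"""Seedable synthetic data: descriptor matrices with known structure, and
random fluoroalkyl SMILES for exercising the descriptor engine.

Random numbers come from numpy's PCG64 (``np.random.default_rng``); for a
fixed seed every generator is bit-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

RNG_ALGORITHM = "numpy.random.PCG64"


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset; same spec -> identical dataset.

    ``separation`` is the Mahalanobis distance between class means
    (classification); ``beta``/``noise_sd`` define the linear response
    (regression).  Defaults mirror the modelled dataset geometry: 74 active
    vs 49 inactive compounds for classification, and a 43-compound,
    3-descriptor training design with R^2 around 0.8 for regression.
    """

    n_per_class: tuple[int, int] = (74, 49)
    n: int = 43
    n_descriptors: int = 4
    separation: float = 3.0
    beta: tuple[float, ...] = (1.6, -3.3, -11.0)
    noise_sd: Optional[float] = None
    target_r2: float = 0.8
    seed: int = 0


def gen_classification_dataset(
    spec: Optional[SyntheticSpec] = None, **overrides
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two multivariate-normal descriptor clouds with shared unit covariance.

    Class means differ by ``separation`` along the first descriptor axis, so
    the Mahalanobis separation equals ``separation`` and the Bayes accuracy
    (equal priors) is Phi(separation / 2).  Returns (descriptor frame,
    class labels array of 'A'/'I').
    """
    spec = _with_overrides(spec, overrides)
    rng = np.random.default_rng(spec.seed)
    n_a, n_i = spec.n_per_class
    p = spec.n_descriptors
    mean_a = np.zeros(p)
    mean_i = np.zeros(p)
    mean_a[0] = spec.separation / 2.0
    mean_i[0] = -spec.separation / 2.0
    xa = rng.standard_normal((n_a, p)) + mean_a
    xi = rng.standard_normal((n_i, p)) + mean_i
    x = np.vstack([xa, xi])
    y = np.array(["A"] * n_a + ["I"] * n_i)
    cols = [f"D{j+1}" for j in range(p)]
    ids = [f"syn{i+1}" for i in range(n_a + n_i)]
    return pd.DataFrame(x, columns=cols, index=pd.Index(ids, name="id")), y


def gen_regression_dataset(
    spec: Optional[SyntheticSpec] = None, **overrides
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, float]:
    """Linear response y = X beta + eps, eps ~ N(0, sigma^2).

    If ``noise_sd`` is not given it is chosen from ``target_r2`` via the
    population identity R^2 = Var(X beta) / (Var(X beta) + sigma^2) with
    X ~ N(0, I): sigma = ||beta|| * sqrt((1 - R^2) / R^2).  Returns
    (descriptor frame, y, beta, sigma).
    """
    spec = _with_overrides(spec, overrides)
    rng = np.random.default_rng(spec.seed)
    beta = np.asarray(spec.beta, dtype=float)
    p = beta.size
    sigma = (
        spec.noise_sd
        if spec.noise_sd is not None
        else float(np.linalg.norm(beta)) * np.sqrt((1 - spec.target_r2) / spec.target_r2)
    )
    x = rng.standard_normal((spec.n, p))
    y = x @ beta + rng.normal(0.0, sigma, size=spec.n)
    cols = [f"D{j+1}" for j in range(p)]
    ids = [f"syn{i+1}" for i in range(spec.n)]
    return pd.DataFrame(x, columns=cols, index=pd.Index(ids, name="id")), y, beta, sigma


def _with_overrides(spec: Optional[SyntheticSpec], overrides: dict) -> SyntheticSpec:
    spec = spec or SyntheticSpec()
    if overrides:
        fields = {**spec.__dict__, **overrides}
        spec = SyntheticSpec(**fields)
    return spec


# ---------------------------------------------------------------------------
# Fluoroalkyl SMILES

#: Head-group SMILES fragments appended to a CF3-(CF2)k- backbone.  These
#: emulate the chemotypes of the modelled PFAS: perfluoroalkyl carboxylic and
#: sulfonic acids, fluorotelomer alcohols, ether acids and amides.
HEAD_GROUPS: dict[str, str] = {
    "carboxylic_acid": "C(=O)O",
    "sulfonic_acid": "S(=O)(=O)O",
    "telomer_alcohol": "CCO",
    "ether_acid": "OC(F)(F)C(=O)O",
    "amide": "C(=O)N",
    "sulfonamide": "S(=O)(=O)N",
}


def fluoroalkyl_smiles(chain_length: int, head: str) -> str:
    """SMILES of CF3-(CF2)_{chain_length}-<head>."""
    if chain_length < 0:
        raise ValueError("chain_length must be >= 0")
    if head not in HEAD_GROUPS:
        raise ValueError(f"unknown head group {head!r}")
    return "FC(F)(F)" + "C(F)(F)" * chain_length + HEAD_GROUPS[head]


def gen_fluoroalkyl_smiles(
    n: int,
    chain_range: tuple[int, int] = (3, 12),
    head_groups: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> list[str]:
    """``n`` distinct, curation-passing fluoroalkyl SMILES.

    Chain lengths (number of CF2 units after the terminal CF3) are sampled
    uniformly from ``chain_range``; combinations are drawn without
    replacement so the batch contains no duplicates.
    """
    heads = list(head_groups) if head_groups else list(HEAD_GROUPS)
    lo, hi = chain_range
    combos = [(k, h) for k in range(lo, hi + 1) for h in heads]
    if n > len(combos):
        raise ValueError(
            f"requested {n} unique molecules but only {len(combos)} chain/head combinations"
        )
    rng = np.random.default_rng(seed)
    picks = rng.permutation(len(combos))[:n]
    return [fluoroalkyl_smiles(*combos[i]) for i in picks]
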