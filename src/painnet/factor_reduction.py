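"""Correlation-matrix PCA with Promax rotation and cross-group scoring.

The reduction stage condenses the 21 behavioural/clinical measures into a
small number of oblique components: sampling adequacy is checked with the
Kaiser-Meyer-Olkin statistic, components are retained by the eigenvalue > 1
rule (the scree elbow is reported for inspection but never auto-applied),
retained components are varimax pre-rotated and then Promax-transformed
(power target, kappa = 4 by default), and measures are assigned to the
component on which their pattern loading passes |0.5|.

Scoring uses regression-method weights (R^-1 times the structure matrix)
together with the fitting sample's means and SDs, so subjects of another
group can be scored with the weights fitted on the first - the device used
to project the small hip arm through the knee-arm solution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import AnalysisConfig

logger = logging.getLogger("painnet")


class SingularCorrelationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Sampling adequacy
# ---------------------------------------------------------------------------

def kmo(correlation_matrix) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy: overall and per measure.

    Compares squared correlations with squared anti-image partial
    correlations obtained from the inverse correlation matrix; values near 1
    indicate that measures share enough variance for factoring.
    """
    R = np.asarray(correlation_matrix, float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise SingularCorrelationError(
            "correlation matrix is singular; remove collinear measures or add a ridge"
        ) from err
    if np.linalg.cond(R) > 1e12:
        raise SingularCorrelationError(
            "correlation matrix is numerically singular; remove collinear "
            "measures or add a ridge")
    d = 1.0 / np.sqrt(np.diag(Rinv))
    partial = -Rinv * np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R ** 2)[off]
    q2 = (partial ** 2)[off]
    overall = r2.sum() / (r2.sum() + q2.sum())
    r2_row = np.where(off, R ** 2, 0.0).sum(axis=1)
    q2_row = np.where(off, partial ** 2, 0.0).sum(axis=1)
    per_measure = r2_row / (r2_row + q2_row)
    return float(overall), per_measure


# ---------------------------------------------------------------------------
# Retention
# ---------------------------------------------------------------------------

def retain_components(eigenvalues, cut: float = 1.0) -> int:
    """Number of eigenvalues strictly above ``cut`` (Kaiser rule)."""
    ev = np.asarray(eigenvalues, float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue vector")
    return int(np.sum(ev > cut))


def scree_elbow(eigenvalues) -> int:
    """1-based index of the largest drop in the scree - reported, never applied."""
    ev = np.sort(np.asarray(eigenvalues, float))[::-1]
    if ev.size < 2:
        return 1
    drops = ev[:-1] - ev[1:]
    return int(np.argmax(drops) + 1)


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------

def varimax(loadings, normalize: bool = True, tol: float = 1e-14,
            max_iter: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (SVD algorithm, Kaiser row normalization).

    Returns (rotated, rotation_matrix) with rotated = loadings @ rotation.
    """
    A = np.asarray(loadings, float).copy()
    p, k = A.shape
    if k < 2:
        return A.copy(), np.eye(k)
    if normalize:
        h = np.sqrt(np.sum(A ** 2, axis=1))
        h[h == 0] = 1.0
        A = A / h[:, None]
    T = np.eye(k)
    for _ in range(max_iter):
        L = A @ T
        G = A.T @ (L ** 3 - L @ np.diag(np.sum(L ** 2, axis=0)) / p)
        U, s, Vt = np.linalg.svd(G)
        T_new = U @ Vt
        delta = np.abs(T_new - T).max()
        T = T_new
        if delta < tol:
            break
    L = A @ T
    if normalize:
        L = L * h[:, None]
    return L, T


def promax(unrotated_loadings, kappa: float = 4.0,
           normalize: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Promax oblique rotation: varimax followed by a power-target transform.

    Returns ``(pattern, phi, rotation)`` where ``pattern = unrotated @
    rotation`` and ``phi`` is the factor correlation matrix (symmetric, unit
    diagonal).  Columns are sign-fixed so the largest-|loading| entry of each
    is positive and ordered by explained variance (sum of squared pattern
    loadings, descending).  A single component passes through unrotated, with
    a warning.
    """
    A = np.asarray(unrotated_loadings, float)
    p, k = A.shape
    if k < 2:
        warnings.warn("promax with a single component is the identity rotation")
        return A.copy(), np.ones((1, 1)), np.eye(1)
    V, T_vm = varimax(A, normalize=normalize)
    # Hendrickson-White power target: raise varimax loadings to kappa,
    # preserving the sign, then least-squares map the varimax solution onto it
    target = np.sign(V) * np.abs(V) ** kappa
    U = np.linalg.solve(V.T @ V, V.T @ target)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    rotation = T_vm @ U
    pattern = A @ rotation
    phi = np.linalg.inv(rotation.T @ rotation)
    # sign fix: dominant entry of each column positive
    signs = np.sign(pattern[np.argmax(np.abs(pattern), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    rotation = rotation * signs
    phi = phi * np.outer(signs, signs)
    # order columns by explained variance
    order = np.argsort(-np.sum(pattern ** 2, axis=0), kind="stable")
    pattern = pattern[:, order]
    rotation = rotation[:, order]
    phi = phi[np.ix_(order, order)]
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 1.0)
    return pattern, phi, rotation


# ---------------------------------------------------------------------------
# Model fit and scoring
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    measure_ids: list[str]
    eigenvalues: np.ndarray                  # descending, sum = n measures
    variance_explained: np.ndarray           # percent, per component
    loadings_unrotated: np.ndarray           # p x k
    pattern: np.ndarray                      # p x k, Promax pattern matrix
    phi: np.ndarray                          # k x k factor correlations
    weights: np.ndarray                      # p x k regression scoring weights
    means: np.ndarray                        # fitting sample means
    sds: np.ndarray                          # fitting sample SDs (ddof=1)
    kmo_overall: float
    kmo_per_measure: np.ndarray
    retained_k: int
    component_labels: list[str]
    loading_threshold: float
    membership: dict = field(default_factory=dict)   # measure -> label
    multi_loading: list = field(default_factory=list)
    scree_elbow_at: int = 1
    n: int = 0

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FactorModel":
        arrays = ("eigenvalues", "variance_explained", "loadings_unrotated",
                  "pattern", "phi", "weights", "means", "sds", "kmo_per_measure")
        kw = dict(d)
        for a in arrays:
            kw[a] = np.asarray(kw[a], float)
        return cls(**kw)


def fit_factor_model(harmonized: pd.DataFrame,
                     config: AnalysisConfig | None = None,
                     community_labels: dict | None = None) -> FactorModel:
    """PCA -> eigenvalue>1 retention -> Promax -> thresholded membership.

    ``harmonized`` is a complete subjects x measures matrix (pain intensity
    outcomes excluded upstream: they are what the components later model).
    If ``community_labels`` maps measures to domain names, components are
    labelled by the majority community of their member measures; otherwise
    they are labelled C1..Ck.
    """
    config = config or AnalysisConfig()
    X = harmonized.to_numpy(float)
    n, p = X.shape
    if p < 3:
        raise ValueError("need at least 3 measures")
    if n <= p:
        warnings.warn(f"n={n} subjects <= p={p} measures; solution will be unstable")
    measure_ids = list(harmonized.columns)
    sds = X.std(axis=0, ddof=1)
    zero = sds == 0
    if zero.any():
        bad = [m for m, z in zip(measure_ids, zero) if z]
        raise ValueError(f"zero-variance measures: {bad}")
    means = X.mean(axis=0)
    R = np.corrcoef(X, rowvar=False)
    kmo_overall, kmo_per = kmo(R)
    if kmo_overall < 0.5:
        warnings.warn(f"overall KMO {kmo_overall:.3f} < 0.5: sampling adequacy poor")
        logger.warning("KMO overall %.3f below 0.5", kmo_overall)

    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = retain_components(evals, config.eigenvalue_cut)
    k = max(k, 1)
    loadings = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))

    if k >= 2:
        pattern, phi, rotation = promax(loadings, kappa=config.promax_kappa)
    else:
        pattern, phi, rotation = loadings.copy(), np.ones((1, 1)), np.eye(1)

    structure = pattern @ phi
    weights = np.linalg.solve(R, structure)

    membership: dict[str, str] = {}
    multi = []
    thr = config.loading_threshold
    labels = [f"C{j + 1}" for j in range(k)]
    for i, m in enumerate(measure_ids):
        hits = np.where(np.abs(pattern[i]) >= thr)[0]
        if hits.size == 0:
            membership[m] = "unassigned"
            continue
        if hits.size > 1:
            multi.append(m)
        best = hits[np.argmax(np.abs(pattern[i, hits]))]
        membership[m] = labels[best]

    if community_labels:
        labels = _label_components(labels, membership, community_labels)
        membership = {m: labels[int(c[1:]) - 1] if c != "unassigned" else c
                      for m, c in membership.items()}

    model = FactorModel(
        measure_ids=measure_ids,
        eigenvalues=evals,
        variance_explained=100.0 * evals / p,
        loadings_unrotated=loadings,
        pattern=pattern,
        phi=phi,
        weights=weights,
        means=means,
        sds=sds,
        kmo_overall=kmo_overall,
        kmo_per_measure=kmo_per,
        retained_k=k,
        component_labels=labels,
        loading_threshold=thr,
        membership=membership,
        multi_loading=multi,
        scree_elbow_at=scree_elbow(evals),
        n=n,
    )
    logger.info("factor model: k=%d, KMO=%.3f, variance %.1f%%",
                k, kmo_overall, model.variance_explained[:k].sum())
    return model


def _label_components(generic: list[str], membership: dict, communities: dict) -> list[str]:
    """Name each component after the majority community of its members."""
    out = []
    used: set[str] = set()
    for j, g in enumerate(generic):
        members = [m for m, c in membership.items() if c == g]
        counts: dict[str, int] = {}
        for m in members:
            com = communities.get(m, "unassigned")
            counts[com] = counts.get(com, 0) + 1
        name = max(counts, key=counts.get) if counts else g
        if name in used:
            name = f"{name} ({g})"
        used.add(name)
        out.append(name)
    return out


def score_subjects(model: FactorModel, harmonized: pd.DataFrame) -> pd.DataFrame:
    """Component scores: standardized measures times regression weights.

    Standardization always uses the *fitting* sample's means and SDs, so a
    different group (e.g. the hip arm) is projected through the knee-arm
    solution exactly as fitted.
    """
    missing = [m for m in model.measure_ids if m not in harmonized.columns]
    if missing:
        raise ValueError(f"matrix lacks model measures: {missing}")
    X = harmonized[model.measure_ids].to_numpy(float)
    Z = (X - model.means) / model.sds
    scores = Z @ model.weights
    return pd.DataFrame(scores, index=harmonized.index,
                        columns=model.component_labels[: scores.shape[1]])
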