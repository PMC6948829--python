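"""Synthetic cohorts with the latent-factor structure the analysis assumes.

The generator emulates a two-arm (knee / hip osteoarthritis) longitudinal
cohort observed at baseline and 3 and 6 months after total joint replacement:

* 21 behavioural/clinical measures driven by 5 latent factors (affect, pain
  catastrophizing, pain quality, health, physical performance), each measure
  loading 0.75 (in absolute value) on its own factor and 0 elsewhere, the
  six-minute-walk test loading negatively;
* 4 pain intensity outcomes on a 0-10 scale whose group x visit means and SDs
  default to the published cohort values, the post-surgical mean being
  baseline x a per-scale *retention* fraction;
* a surgery effect that rewires the inter-measure correlation structure
  (convex mixing of factor scores with fresh draws plus a rotation of the
  loading rows toward random directions), stronger in the hip arm, together
  with an optional *structure attenuation* that shrinks communalities and
  emulates the fracturing of the shared behavioural structure with strong
  pain relief;
* month-6 factor scores strongly correlated with month-3 (stability of the
  post-surgical state);
* item-level missingness, completely at random.

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_model import (
    GROUPS,
    VISITS,
    CohortTable,
    MeasureRegistry,
    default_registry,
)
from .preprocess import inverse_rescale_measure

# Published group x visit means and SDs of the four pain outcome scales
# (0-10 presentation).  Order: BPI-PS, NRS, KOOS-Pain (joint pain), SF36-BP.
PAIN_SCALES = ("BPI-PS", "NRS", "KOOS-Pain", "SF36-BP")

PAIN_MEANS = {
    "KOA": {
        "baseline": {"BPI-PS": 4.79, "NRS": 6.53, "KOOS-Pain": 6.49, "SF36-BP": 7.04},
        "m3": {"BPI-PS": 1.69, "NRS": 1.89, "KOOS-Pain": 2.45, "SF36-BP": 3.39},
        "m6": {"BPI-PS": 1.70, "NRS": 2.01, "KOOS-Pain": 2.19, "SF36-BP": 2.98},
    },
    "HOA": {
        "baseline": {"BPI-PS": 4.38, "NRS": 6.09, "KOOS-Pain": 5.86, "SF36-BP": 6.49},
        "m3": {"BPI-PS": 0.54, "NRS": 0.55, "KOOS-Pain": 0.79, "SF36-BP": 1.95},
        "m6": {"BPI-PS": 0.63, "NRS": 0.73, "KOOS-Pain": 0.80, "SF36-BP": 1.98},
    },
}

PAIN_SDS = {
    "KOA": {
        "baseline": {"BPI-PS": 1.50, "NRS": 1.67, "KOOS-Pain": 1.49, "SF36-BP": 1.82},
        "m3": {"BPI-PS": 1.48, "NRS": 2.03, "KOOS-Pain": 1.96, "SF36-BP": 2.25},
        "m6": {"BPI-PS": 1.53, "NRS": 1.90, "KOOS-Pain": 2.17, "SF36-BP": 2.26},
    },
    "HOA": {
        "baseline": {"BPI-PS": 1.52, "NRS": 1.66, "KOOS-Pain": 1.63, "SF36-BP": 1.55},
        "m3": {"BPI-PS": 1.05, "NRS": 1.06, "KOOS-Pain": 0.88, "SF36-BP": 1.71},
        "m6": {"BPI-PS": 0.76, "NRS": 0.93, "KOOS-Pain": 0.77, "SF36-BP": 1.87},
    },
}


def default_retention() -> dict:
    """Post/pre mean ratios implied by the published pain means."""
    out: dict = {}
    for g in GROUPS:
        out[g] = {}
        for s in PAIN_SCALES:
            base = PAIN_MEANS[g]["baseline"][s]
            out[g][s] = {v: PAIN_MEANS[g][v][s] / base for v in ("m3", "m6")}
    return out


def default_loading_matrix(registry: MeasureRegistry | None = None,
                           loading: float = 0.75) -> tuple[np.ndarray, list[str], list[str]]:
    """21 x 5 loading matrix: |loading| on the own-community factor, 0 elsewhere.

    Returns (matrix, measure_ids, factor_labels); the 6MWT row is negative
    (walking further is the *good* direction of physical performance).
    """
    registry = registry or default_registry()
    measures = registry.network_ids
    factors = []
    for m in measures:
        c = registry[m].community
        if c not in factors:
            factors.append(c)
    L = np.zeros((len(measures), len(factors)))
    for i, m in enumerate(measures):
        j = factors.index(registry[m].community)
        sign = -1.0 if m == "6MWT" else 1.0
        L[i, j] = sign * loading
    return L, measures, factors


@dataclass
class SyntheticSpec:
    """Study-conditions dial-board for :func:`generate_cohort`."""

    n_koa: int = 84
    n_hoa: int = 22
    factor_loading_matrix: np.ndarray | None = None        # 21 x 5
    uniqueness: np.ndarray | None = None                   # per measure
    pain_baseline_means: Mapping = field(default_factory=lambda: PAIN_MEANS)
    pain_sds: Mapping = field(default_factory=lambda: PAIN_SDS)
    surgery_pain_retention: Mapping = field(default_factory=default_retention)
    rewire_strength: Mapping[str, float] = field(
        default_factory=lambda: {"KOA": 0.2, "HOA": 0.5})
    structure_attenuation: Mapping[str, float] = field(
        default_factory=lambda: {"KOA": 0.0, "HOA": 0.7})
    pain_factor_loading: float = 0.6        # baseline pain ~ pain-quality factor
    pain_factor_loading_post: float = 0.45  # weaker post-surgical coupling
    visit_persistence: float = 0.9          # corr(factor m6, factor m3)
    measure_mean_0_10: float = 5.0
    measure_sd_0_10: float = 1.5
    missing_rate: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.factor_loading_matrix is None:
            self.factor_loading_matrix, self._measures, self._factors = \
                default_loading_matrix()
        else:
            self.factor_loading_matrix = np.asarray(self.factor_loading_matrix, float)
            reg = default_registry()
            self._measures = reg.network_ids[: self.factor_loading_matrix.shape[0]]
            self._factors = [f"F{k + 1}" for k in range(self.factor_loading_matrix.shape[1])]
        if not np.all(np.isfinite(self.factor_loading_matrix)):
            raise ValueError("loadings must be finite")
        if self.uniqueness is None:
            self.uniqueness = 1.0 - np.sum(self.factor_loading_matrix ** 2, axis=1)
        self.uniqueness = np.asarray(self.uniqueness, float)
        if self.uniqueness.shape[0] != self.factor_loading_matrix.shape[0]:
            raise ValueError("uniqueness length must match number of measures")
        if np.any(self.uniqueness <= 0):
            raise ValueError("uniqueness must be positive")
        for g in GROUPS:
            s = self.rewire_strength[g]
            if not 0 <= s <= 1:
                raise ValueError("rewire_strength must lie in [0, 1]")
            if not 0 <= self.structure_attenuation[g] < 1:
                raise ValueError("structure_attenuation must lie in [0, 1)")
        if not 0 <= self.missing_rate < 0.3:
            raise ValueError("missing_rate must lie in [0, 0.3)")

    @classmethod
    def from_yaml(cls, path, section: str = "synthetic") -> "SyntheticSpec":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**(doc.get(section) or {}))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    factor_scores: dict            # (group, visit) -> n x 5 array
    factor_labels: list[str]
    measure_ids: list[str]
    communities: dict[str, str]    # planted measure -> factor label
    loadings: dict                 # (group, visit) -> 21 x 5 effective loadings
    uniqueness: dict               # (group, visit) -> per-measure uniqueness
    planted_pain_coefficients: dict
    correlation_matrices: dict     # (group, visit) -> implied population corr
    clip_fraction: float
    subject_ids: dict              # group -> list


def sample_measure_matrix(loadings: np.ndarray, uniqueness: np.ndarray,
                          n: int, seed) -> np.ndarray:
    """Draw n subjects from the linear factor model L f + e.

    The implied population correlation of measures i, j is
    (L L^T)_ij / sqrt((sum_k L_ik^2 + u_i)(sum_k L_jk^2 + u_j)).
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    loadings = np.asarray(loadings, float)
    uniqueness = np.asarray(uniqueness, float)
    if np.any(uniqueness <= 0):
        raise ValueError("uniqueness must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p, k = loadings.shape
    f = rng.standard_normal((n, k))
    e = rng.standard_normal((n, p)) * np.sqrt(uniqueness)
    return f @ loadings.T + e


def implied_correlation(loadings: np.ndarray, uniqueness: np.ndarray) -> np.ndarray:
    """Population correlation matrix of the linear factor model."""
    loadings = np.asarray(loadings, float)
    cov = loadings @ loadings.T + np.diag(np.asarray(uniqueness, float))
    d = 1.0 / np.sqrt(np.diag(cov))
    return cov * np.outer(d, d)


def _perturb_loadings(L: np.ndarray, strength: float, attenuation: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rotate each loading row toward a random direction, then attenuate.

    Row norms are preserved by the rotation (so the rewiring dial changes
    *which* correlations exist, not the communalities); attenuation then
    shrinks the row norms, moving shared variance into uniqueness.
    """
    norms = np.linalg.norm(L, axis=1, keepdims=True)
    if strength > 0:
        Z = rng.standard_normal(L.shape)
        Z *= norms / np.linalg.norm(Z, axis=1, keepdims=True)
        M = (1 - strength) * L + strength * Z
        M *= norms / np.linalg.norm(M, axis=1, keepdims=True)
    else:
        M = L.copy()
    M = M * (1.0 - attenuation)
    u = 1.0 - np.sum(M ** 2, axis=1)
    return M, u


def _mix_scores(F: np.ndarray, weight: float, rng: np.random.Generator) -> np.ndarray:
    """Convex mix with fresh standard-normal scores, renormalized to unit SD."""
    if weight <= 0:
        return F.copy()
    G = rng.standard_normal(F.shape)
    return ((1 - weight) * F + weight * G) / np.sqrt((1 - weight) ** 2 + weight ** 2)


def _clip_adjusted_location(target_mean: float, sd: float,
                            lo: float = 0.0, hi: float = 10.0) -> float:
    """Location mu such that E[clip(N(mu, sd), lo, hi)] = target_mean."""

    def clipped_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return (mu
                + sd * (stats.norm.pdf(a) - stats.norm.pdf(b))
                + (lo - mu) * stats.norm.cdf(a)
                + (hi - mu) * stats.norm.sf(b)) - target_mean

    return optimize.brentq(clipped_mean, lo - 10 * sd, hi + 10 * sd, xtol=1e-10)


def generate_cohort(spec: SyntheticSpec | None = None,
                    registry: MeasureRegistry | None = None
                    ) -> tuple[CohortTable, GroundTruth]:
    """Generate a full two-arm, three-visit cohort plus its ground truth."""
    spec = spec or SyntheticSpec()
    registry = registry or default_registry()
    rng = np.random.default_rng(spec.rng_seed)
    measures = spec._measures
    factors = spec._factors
    L0 = spec.factor_loading_matrix
    u0 = spec.uniqueness
    pq_idx = factors.index("Pain Quality") if "Pain Quality" in factors else 2

    blocks: list[pd.DataFrame] = []
    gt_scores: dict = {}
    gt_load: dict = {}
    gt_uniq: dict = {}
    gt_corr: dict = {}
    subject_ids: dict = {}
    clip_hits = 0
    clip_total = 0

    for group, n in (("KOA", spec.n_koa), ("HOA", spec.n_hoa)):
        sids = [f"{group}{i + 1:03d}" for i in range(n)]
        subject_ids[group] = sids
        s = spec.rewire_strength[group]
        att = spec.structure_attenuation[group]

        F = {"baseline": rng.standard_normal((n, len(factors)))}
        F["m3"] = _mix_scores(F["baseline"], s, rng)
        rho = spec.visit_persistence
        F["m6"] = rho * F["m3"] + np.sqrt(1 - rho ** 2) * rng.standard_normal(F["m3"].shape)

        L_post, u_post = _perturb_loadings(L0, s, att, rng)
        Ls = {"baseline": (L0, u0), "m3": (L_post, u_post), "m6": (L_post, u_post)}

        for visit in VISITS:
            Lv, uv = Ls[visit]
            gt_scores[(group, visit)] = F[visit]
            gt_load[(group, visit)] = Lv
            gt_uniq[(group, visit)] = uv
            gt_corr[(group, visit)] = implied_correlation(Lv, uv)

            X = F[visit] @ Lv.T + rng.standard_normal((n, len(measures))) * np.sqrt(uv)
            H = spec.measure_mean_0_10 + spec.measure_sd_0_10 * X
            clip_hits += int(np.sum((H < 0) | (H > 10)))
            clip_total += H.size
            H = np.clip(H, 0.0, 10.0)

            wide = {m: inverse_rescale_measure(H[:, j], registry[m])
                    for j, m in enumerate(measures)}

            # pain outcomes: coupled to the pain-quality factor of this visit
            lam = (spec.pain_factor_loading if visit == "baseline"
                   else spec.pain_factor_loading_post)
            for scale in PAIN_SCALES:
                base_mean = spec.pain_baseline_means[group]["baseline"][scale]
                if visit == "baseline":
                    target = base_mean
                else:
                    target = base_mean * spec.surgery_pain_retention[group][scale][visit]
                sd = spec.pain_sds[group][visit][scale]
                mu = _clip_adjusted_location(target, sd)
                z = lam * F[visit][:, pq_idx] + np.sqrt(1 - lam ** 2) * \
                    rng.standard_normal(n)
                h = np.clip(mu + sd * z, 0.0, 10.0)
                wide[scale] = inverse_rescale_measure(h, registry[scale])

            block = pd.DataFrame(wide, index=sids)
            block.index.name = "subject_id"
            long = block.reset_index().melt(
                id_vars="subject_id", var_name="measure_id", value_name="value")
            long.insert(1, "group", group)
            long.insert(2, "visit", visit)
            long["missing_flag"] = False
            blocks.append(long)

    data = pd.concat(blocks, ignore_index=True)
    if spec.missing_rate > 0:
        mask = rng.random(len(data)) < spec.missing_rate
        data.loc[mask, "value"] = np.nan
        data.loc[mask, "missing_flag"] = True

    covariates = _covariates(subject_ids, rng)
    cohort = CohortTable(data=data, covariates=covariates, registry=registry)
    truth = GroundTruth(
        factor_scores=gt_scores,
        factor_labels=factors,
        measure_ids=measures,
        communities={m: registry[m].community for m in measures},
        loadings=gt_load,
        uniqueness=gt_uniq,
        planted_pain_coefficients={
            "pain_factor_loading": spec.pain_factor_loading,
            "pain_factor_loading_post": spec.pain_factor_loading_post,
            "pain_factor": "Pain Quality",
        },
        correlation_matrices=gt_corr,
        clip_fraction=clip_hits / max(clip_total, 1),
        subject_ids=subject_ids,
    )
    return cohort, truth


def _covariates(subject_ids: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics drawn independently of outcomes (typical arthroplasty cohort)."""
    recs = []
    for group, sids in subject_ids.items():
        n = len(sids)
        age = np.clip(rng.normal(66, 8, n), 40, 85)
        gender = (rng.random(n) < 0.65).astype(int)          # 1 = female
        education = rng.choice([0, 1, 2], size=n, p=[0.3, 0.45, 0.25])
        bmi = np.clip(rng.normal(29, 4.5, n), 18, 45)
        pain_dur = np.clip(rng.lognormal(np.log(48), 0.6, n), 3, 360)
        kl = rng.choice([2, 3, 4], size=n, p=[0.25, 0.45, 0.30])
        for i, sid in enumerate(sids):
            recs.append({"subject_id": sid, "age": age[i], "gender": gender[i],
                         "education": education[i], "bmi": bmi[i],
                         "pain_duration": pain_dur[i], "kl_grade": kl[i]})
    return pd.DataFrame(recs).set_index("subject_id")
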