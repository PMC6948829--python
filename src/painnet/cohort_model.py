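"""Core domain types shared by every analysis stage.

The pipeline's universal input is a *long-format* cohort table: one row per
(subject, visit, measure) with the subject's osteoarthritis group (knee ``KOA``
or hip ``HOA``).  A :class:`MeasureRegistry` carries the metadata needed to
interpret each measure: the instrument it comes from, its native score range,
whether a higher score means worse pain/function, and the behavioural
community (latent dimension) it belongs to.

The default registry enumerates the 19 questionnaire subscales and 2
physical-performance scores used as network nodes, plus the four pain
intensity outcome scales (NRS, BPI severity, KOOS/HOOS pain, SF-36 bodily
pain) that the outcome models target.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("painnet")

VISITS = ("baseline", "m3", "m6")
GROUPS = ("KOA", "HOA")

HIGHER_IS_WORSE = "higher_is_worse"
HIGHER_IS_BETTER = "higher_is_better"


class CohortValidationError(ValueError):
    """Raised when an input table violates the cohort contract."""


# ---------------------------------------------------------------------------
# Measure registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasureEntry:
    measure_id: str
    instrument: str
    subscale: str
    native_min: float
    native_max: float
    orientation: str
    community: str = "unassigned"
    is_pain_outcome: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in (HIGHER_IS_WORSE, HIGHER_IS_BETTER):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if not self.native_min < self.native_max:
            raise ValueError(
                f"{self.measure_id}: native_min must be < native_max "
                f"({self.native_min} vs {self.native_max})"
            )


class MeasureRegistry:
    """Metadata lookup for every measure the pipeline may encounter."""

    def __init__(self, entries: Iterable[MeasureEntry]):
        self.entries: list[MeasureEntry] = list(entries)
        ids = [e.measure_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate measure_ids in registry: {dupes}")
        n_out = sum(e.is_pain_outcome for e in self.entries)
        if n_out != 4:
            raise ValueError(f"registry must flag exactly 4 pain outcomes, got {n_out}")
        self._by_id = {e.measure_id: e for e in self.entries}

    def __contains__(self, measure_id: str) -> bool:
        return measure_id in self._by_id

    def __getitem__(self, measure_id: str) -> MeasureEntry:
        return self._by_id[measure_id]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def measure_ids(self) -> list[str]:
        return [e.measure_id for e in self.entries]

    @property
    def network_ids(self) -> list[str]:
        """The non-outcome measures: the nodes of the correlation networks."""
        return [e.measure_id for e in self.entries if not e.is_pain_outcome]

    @property
    def pain_outcome_ids(self) -> list[str]:
        return [e.measure_id for e in self.entries if e.is_pain_outcome]

    @property
    def communities(self) -> dict[str, str]:
        return {e.measure_id: e.community for e in self.entries}


AFFECT = "Affect"
CATASTROPHIZING = "Pain Catastrophizing"
PAIN_QUALITY = "Pain Quality"
HEALTH = "Health"
PHYS_PERF = "Physical Performance"


def default_registry() -> MeasureRegistry:
    """The 21 network measures plus the 4 pain intensity outcomes.

    Community assignments follow the five behavioural dimensions used
    throughout the pipeline (affect, pain catastrophizing, pain quality,
    health, physical performance).  Native ranges follow the standard scoring
    of each instrument; where an instrument exists in several versions the
    range is a documented, overridable default.
    """
    W, B = HIGHER_IS_WORSE, HIGHER_IS_BETTER
    e = MeasureEntry
    entries = [
        # Affect: hospital anxiety / depression
        e("HADS-A", "HADS", "Anxiety", 0, 21, W, AFFECT),
        e("HADS-D", "HADS", "Depression", 0, 21, W, AFFECT),
        # Pain catastrophizing: rumination / magnification / helplessness
        e("PCS-R", "PCS", "Rumination", 0, 16, W, CATASTROPHIZING),
        e("PCS-M", "PCS", "Magnification", 0, 12, W, CATASTROPHIZING),
        e("PCS-H", "PCS", "Helplessness", 0, 24, W, CATASTROPHIZING),
        # Pain quality: McGill affective/sensory, neuropathic screen, joint
        # symptom / function subscales
        e("MPQ-A", "MPQ", "Affective", 0, 12, W, PAIN_QUALITY),
        e("MPQ-S", "MPQ", "Sensory", 0, 33, W, PAIN_QUALITY),
        e("DN4", "DN4", "Total", 0, 10, W, PAIN_QUALITY),
        e("KOOS-S", "KOOS", "Symptoms", 0, 100, B, PAIN_QUALITY),
        e("KOOS-SR", "KOOS", "Sport/Recreation", 0, 100, B, PAIN_QUALITY),
        e("KOOS-QOL", "KOOS", "Quality of Life", 0, 100, B, PAIN_QUALITY),
        e("KOOS-ADL", "KOOS", "Activities of Daily Living", 0, 100, B, PAIN_QUALITY),
        # Health: SF-36 profile
        e("SF36-PF", "SF-36", "Physical Functioning", 0, 100, B, HEALTH),
        e("SF36-PH", "SF-36", "Role Physical", 0, 100, B, HEALTH),
        e("SF36-EP", "SF-36", "Role Emotional", 0, 100, B, HEALTH),
        e("SF36-EF", "SF-36", "Energy/Fatigue", 0, 100, B, HEALTH),
        e("SF36-E", "SF-36", "Emotional Well-being", 0, 100, B, HEALTH),
        e("SF36-SF", "SF-36", "Social Functioning", 0, 100, B, HEALTH),
        e("SF36-GH", "SF-36", "General Health", 0, 100, B, HEALTH),
        # Physical performance
        e("TUG", "TUG", "Timed Up and Go (s)", 0, 60, W, PHYS_PERF),
        e("6MWT", "6MWT", "Six-minute walk (m)", 0, 800, B, PHYS_PERF),
        # Pain intensity outcomes (modelled, not network nodes)
        e("NRS", "NRS", "Pain intensity", 0, 10, W, is_pain_outcome=True),
        e("BPI-PS", "BPI", "Pain Severity", 0, 10, W, is_pain_outcome=True),
        e("KOOS-Pain", "KOOS/HOOS", "Pain", 0, 100, B, is_pain_outcome=True),
        e("SF36-BP", "SF-36", "Bodily Pain", 0, 100, B, is_pain_outcome=True),
    ]
    return MeasureRegistry(entries)


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Scalar constants of the analysis, with the study's defaults."""

    binarize_fraction: float = 0.25
    louvain_reps: int = 100
    permutation_reps: int = 10_000
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    loading_threshold: float = 0.5
    eigenvalue_cut: float = 1.0
    missing_threshold: float = 0.30
    outlier_sd: float = 3.0
    outlier_cap: int = 3
    promax_kappa: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.binarize_fraction < 1:
            raise ValueError("binarize_fraction must lie in (0, 1)")
        if self.louvain_reps < 1 or self.permutation_reps < 1:
            raise ValueError("repetition counts must be >= 1")
        for name in ("alpha_enter", "alpha_remove", "loading_threshold",
                     "eigenvalue_cut", "missing_threshold", "outlier_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, section: str = "analysis") -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**(doc.get(section) or {}))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


COVARIATE_COLUMNS = ("age", "gender", "education", "bmi", "pain_duration", "kl_grade")


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Long-format subject x visit x measure table plus per-subject covariates.

    ``data`` columns: subject_id, group, visit, measure_id, value, missing_flag.
    ``covariates`` is indexed by subject_id (may be empty).
    """

    data: pd.DataFrame
    covariates: pd.DataFrame
    registry: MeasureRegistry

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        required = {"subject_id", "group", "visit", "measure_id", "value", "missing_flag"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise CohortValidationError(f"missing columns: {sorted(missing_cols)}")
        bad_visit = set(df["visit"].unique()) - set(VISITS)
        if bad_visit:
            raise CohortValidationError(f"unknown visit labels: {sorted(bad_visit)}")
        bad_group = set(df["group"].unique()) - set(GROUPS)
        if bad_group:
            raise CohortValidationError(f"unknown group labels: {sorted(bad_group)}")
        unknown = sorted(set(df["measure_id"].unique()) - set(self.registry.measure_ids))
        if unknown:
            raise CohortValidationError(f"measure_ids absent from registry: {unknown}")
        dup = df.duplicated(subset=["subject_id", "visit", "measure_id"])
        if dup.any():
            rows = df.loc[dup, ["subject_id", "visit", "measure_id"]].head(5)
            raise CohortValidationError(
                f"duplicate (subject, visit, measure) records, e.g.\n{rows.to_string(index=False)}"
            )
        ngroups = df.groupby("subject_id")["group"].nunique()
        incon = ngroups[ngroups > 1]
        if len(incon):
            raise CohortValidationError(
                f"group label not constant within subjects: {list(incon.index[:5])}"
            )

    @property
    def subjects(self) -> list:
        return sorted(self.data["subject_id"].unique())

    def group_of(self) -> pd.Series:
        return self.data.groupby("subject_id")["group"].first()

    def wide(self, visit: str, measure_ids: Sequence[str] | None = None,
             group: str | None = None) -> pd.DataFrame:
        """Subjects x measures matrix of native values for one visit.

        Missing cells are NaN.  Row/column order is deterministic (sorted
        subjects, registry measure order) so downstream results never depend
        on input row order.
        """
        df = self.data[self.data["visit"] == visit]
        if group is not None:
            df = df[df["group"] == group]
        mat = df.pivot(index="subject_id", columns="measure_id", values="value")
        cols = measure_ids if measure_ids is not None else [
            m for m in self.registry.measure_ids if m in mat.columns
        ]
        mat = mat.reindex(columns=cols).sort_index()
        return mat


def load_cohort(path: str | Path, registry: MeasureRegistry) -> CohortTable:
    """Read a long-format cohort CSV and validate it against the registry.

    Unparseable numeric cells (e.g. ``NA``) are kept as missing-flag records,
    never silently dropped.  Optional covariate columns
    (age/gender/education/bmi/pain_duration/kl_grade) are collected per
    subject from the first row in which they appear.
    """
    raw = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    for col in ("subject_id", "group", "visit", "measure_id"):
        if col not in raw.columns:
            raise CohortValidationError(f"input file lacks required column {col!r}")
    values = pd.to_numeric(raw["value"], errors="coerce")
    data = pd.DataFrame({
        "subject_id": raw["subject_id"],
        "group": raw["group"].astype(str),
        "visit": raw["visit"].astype(str),
        "measure_id": raw["measure_id"].astype(str),
        "value": values,
        "missing_flag": values.isna(),
    })
    cov_cols = [c for c in COVARIATE_COLUMNS if c in raw.columns]
    if cov_cols:
        covariates = (
            raw[["subject_id", *cov_cols]]
            .dropna(subset=cov_cols, how="all")
            .groupby("subject_id")
            .first()
        )
        covariates = covariates.apply(pd.to_numeric, errors="coerce")
    else:
        covariates = pd.DataFrame(index=pd.Index(sorted(data["subject_id"].unique()),
                                                 name="subject_id"))
    return CohortTable(data=data, covariates=covariates, registry=registry)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort back to the canonical long CSV (covariates inlined)."""
    df = cohort.data.copy()
    df["value"] = df["value"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    if len(cohort.covariates.columns):
        df = df.merge(cohort.covariates, left_on="subject_id", right_index=True, how="left")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _jsonable(obj.to_dict())
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {"index": list(obj.index), "columns": list(obj.columns),
                "values": obj.to_numpy().tolist()}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results, path: str | Path) -> None:
    """Serialize a stage output.

    JSON is used for models, metrics and permutation results; floats keep
    full ``repr`` precision so a round trip reproduces every number exactly.
    ``BinaryNetwork`` objects additionally support GraphML (``.graphml``) and
    two-column edge lists (``.edges`` / ``.tsv``).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if hasattr(results, "graph") and suffix in (".graphml", ".edges", ".tsv"):
        import networkx as nx

        if suffix == ".graphml":
            nx.write_graphml(results.graph, path)
        else:
            with open(path, "w") as fh:
                for u, v in sorted(map(tuple, map(sorted, results.graph.edges()))):
                    fh.write(f"{u}\t{v}\n")
        return
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=1)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Run log
# ---------------------------------------------------------------------------

def start_run_log(path: str | Path, config: AnalysisConfig) -> logging.Logger:
    """Attach a timestamped file handler recording the config hash and seed."""
    handler = logging.FileHandler(path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("run start t=%s config_hash=%s rng_seed=%d",
                time.strftime("%Y-%m-%dT%H:%M:%S"), config.config_hash(), config.rng_seed)
    return logger
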