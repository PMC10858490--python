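"""Cohort filtering and similarity-vector patient representation.

Each patient carries a set D of distinct phenotype terms.  Against an ordered
feature space P (the distinct terms of the dataset), the patient is encoded
as a vector V with ``V[i] = max_{d in D} sim(p_i, d)``: under the binary
similarity this is the presence/absence indicator, under a semantic
similarity each feature records how close the patient's nearest phenotype is.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ontology import OntologyGraph
from .similarity import SimilarityModel, similarity_matrix

logger = logging.getLogger(__name__)

LABELS = ("case", "control", "unknown")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    phenotypes: frozenset[str]
    label: str = "unknown"
    censor_date: dt.date | None = None
    phenotype_dates: Mapping[str, dt.date] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class Cohort:
    """A list of patients with unique ids plus filtering provenance."""

    patients: tuple[PatientRecord, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def labels(self) -> np.ndarray:
        """1 for case, 0 for control/unknown."""
        return np.array([1 if p.label == "case" else 0 for p in self.patients])

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def n_by_label(self) -> dict[str, int]:
        out = {lab: 0 for lab in LABELS}
        for p in self.patients:
            out[p.label] += 1
        return out

    def with_note(self, note: str) -> "Cohort":
        return replace(self, provenance=self.provenance + (note,))


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered list of distinct terms P, lexicographically sorted.

    ``fit_scope`` records whether P was built from the full dataset (the
    default: the feature vocabulary is not label information, and the study
    defines P over all patients) or from the training split only.
    """

    terms: tuple[str, ...]
    fit_scope: str = "full_dataset"

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in feature space")
        if list(self.terms) != sorted(self.terms):
            raise ValueError("feature space terms must be lexicographically sorted")

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_cohort(cls, cohort: Cohort, fit_scope: str = "full_dataset") -> "FeatureSpace":
        terms: set[str] = set()
        for p in cohort:
            terms |= p.phenotypes
        return cls(terms=tuple(sorted(terms)), fit_scope=fit_scope)


@dataclass(frozen=True)
class PatientVector:
    patient_id: str
    values: np.ndarray


def resolve_terms(cohort: Cohort, graph: OntologyGraph) -> Cohort:
    """Drop phenotype terms the ontology does not contain, with a warning."""
    out = []
    dropped = 0
    for p in cohort:
        keep = frozenset(t for t in p.phenotypes if t in graph)
        dropped += len(p.phenotypes) - len(keep)
        out.append(replace(p, phenotypes=keep))
    if dropped:
        logger.warning("dropped %d unresolvable term assignments", dropped)
    return Cohort(tuple(out), cohort.provenance + (f"resolve_terms: dropped {dropped} assignments",))


def censor_phenotypes(record: PatientRecord, censor_date: dt.date | None = None) -> PatientRecord:
    """Remove phenotypes dated on/after the censor date (e.g. a transplant).

    With a censor date set, undated phenotypes are also removed - only
    phenotypes known to precede the event are kept.  Without one the record
    is returned unchanged.
    """
    date = censor_date if censor_date is not None else record.censor_date
    if date is None:
        return record
    kept = frozenset(
        t for t in record.phenotypes
        if t in record.phenotype_dates and record.phenotype_dates[t] < date
    )
    removed = len(record.phenotypes) - len(kept)
    if removed:
        logger.info("patient %s: censored %d phenotypes", record.patient_id, removed)
    return replace(record, phenotypes=kept, censor_date=date)


def censor_cohort(cohort: Cohort) -> Cohort:
    out = tuple(censor_phenotypes(p) for p in cohort)
    return Cohort(out, cohort.provenance + ("censor_phenotypes applied",))


def filter_min_terms(cohort: Cohort, k: int = 4) -> Cohort:
    """Keep patients with at least ``k`` distinct phenotype terms."""
    if k < 1:
        raise ValueError("k must be >= 1")
    kept = tuple(p for p in cohort if len(p.phenotypes) >= k)
    removed = len(cohort) - len(kept)
    if not kept:
        raise ValueError("no patients remain after the minimum-term filter")
    return Cohort(
        kept,
        cohort.provenance + (f"filter_min_terms(k={k}): removed {removed}, kept {len(kept)}",),
    )


def vectorize(
    cohort: Cohort,
    feature_space: FeatureSpace,
    model: SimilarityModel,
    sim_matrix: np.ndarray | None = None,
) -> list[PatientVector]:
    """Encode each patient as ``V[i] = max_{d in D} sim(p_i, d)``.

    The pairwise similarity matrix over the feature space is precomputed
    once (or passed in) and each patient's vector is a column-wise max over
    the columns of their phenotype terms.  Patient terms outside the feature
    space are ignored in the max (they carry no feature to score against).
    """
    if sim_matrix is None:
        sim_matrix = similarity_matrix(model, feature_space.terms)
    index = {t: i for i, t in enumerate(feature_space.terms)}
    vectors = []
    for p in cohort:
        if not p.phenotypes:
            raise ValueError(
                f"patient {p.patient_id} has an empty phenotype set; filter the cohort first"
            )
        cols = [index[t] for t in p.phenotypes if t in index]
        if not cols:
            values = np.zeros(len(feature_space))
        else:
            values = sim_matrix[:, cols].max(axis=1)
        vectors.append(PatientVector(patient_id=p.patient_id, values=values))
    return vectors


def vector_matrix(vectors: Sequence[PatientVector]) -> np.ndarray:
    """Stack patient vectors into an (n_patients, n_features) array."""
    return np.stack([v.values for v in vectors])
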