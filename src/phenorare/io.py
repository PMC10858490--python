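"""File readers/writers and the end-to-end run orchestration.

Formats: OBO or child-parent edge tables for the ontology; long-format TSV
``patient_id<TAB>term_id[<TAB>date]`` for phenotype assignments plus a
``patient_id<TAB>label`` table; word2vec text format for term embeddings;
JSON for metrics; TSV for per-repetition metrics and ranked patient lists.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import representation
from .evaluation import EvaluationReport, RankedList
from .ontology import OntologyGraph, load_ontology
from .pipeline import PipelineConfig, run_protocol
from .representation import Cohort, FeatureSpace, PatientRecord
from .similarity import EmbeddingTable, SimilarityModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    ontology_path: str
    patients_path: str
    labels_path: str
    output_dir: str
    embeddings_path: str | None = None
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    specificity: float = 0.90
    k_percents: tuple[float, ...] = (1.0, 10.0)
    min_terms: int = 4
    apply_censoring: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pipe = PipelineConfig(**raw.pop("pipeline", {}))
        if "k_percents" in raw:
            raw["k_percents"] = tuple(raw["k_percents"])
        return cls(pipeline=pipe, **raw)


def _parse_date(text: str, lineno: int) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: bad ISO-8601 date {text!r}") from exc


def read_patients(
    patients_path: str | Path,
    labels_path: str | Path | None = None,
    censor_dates_path: str | Path | None = None,
) -> Cohort:
    """Assemble a cohort from long-format phenotype and label tables.

    Duplicate (patient, term) rows collapse to one; patients missing from
    the label table are marked ``unknown``.  An optional third table
    ``patient_id<TAB>date`` supplies per-patient censor dates.
    """
    phenotypes: dict[str, set[str]] = {}
    dates: dict[str, dict[str, dt.date]] = {}
    n_rows = 0
    with open(patients_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"line {lineno}: expected 2 or 3 tab-separated columns, got {len(parts)}"
                )
            pid, term = parts[0], parts[1]
            if not pid or not term:
                raise ValueError(f"line {lineno}: empty patient or term id")
            phenotypes.setdefault(pid, set()).add(term)
            if len(parts) == 3 and parts[2]:
                dates.setdefault(pid, {})[term] = _parse_date(parts[2], lineno)
            n_rows += 1
    if not phenotypes:
        raise ValueError(f"no phenotype rows in {patients_path}")
    logger.info("read %d assignment rows for %d patients", n_rows, len(phenotypes))

    labels: dict[str, str] = {}
    if labels_path is not None:
        table = pd.read_csv(
            labels_path, sep="\t", comment="#", header=None,
            names=["patient_id", "label"], dtype=str,
        )
        bad = set(table["label"]) - set(representation.LABELS)
        if bad:
            raise ValueError(f"unknown label strings: {sorted(bad)}")
        labels = dict(zip(table["patient_id"], table["label"]))

    censor: dict[str, dt.date] = {}
    if censor_dates_path is not None:
        table = pd.read_csv(
            censor_dates_path, sep="\t", comment="#", header=None,
            names=["patient_id", "date"], dtype=str,
        )
        censor = {
            pid: dt.date.fromisoformat(d) for pid, d in zip(table["patient_id"], table["date"])
        }

    records = tuple(
        PatientRecord(
            patient_id=pid,
            phenotypes=frozenset(terms),
            label=labels.get(pid, "unknown"),
            censor_date=censor.get(pid),
            phenotype_dates=dates.get(pid, {}),
        )
        for pid, terms in sorted(phenotypes.items())
    )
    return Cohort(records, provenance=(f"read {len(records)} patients from {patients_path}",))


def write_patients(cohort: Cohort, patients_path: str | Path, labels_path: str | Path) -> None:
    with open(patients_path, "w") as fh:
        fh.write("# patient_id\tterm_id\n")
        for p in cohort:
            for term in sorted(p.phenotypes):
                fh.write(f"{p.patient_id}\t{term}\n")
    with open(labels_path, "w") as fh:
        fh.write("# patient_id\tlabel\n")
        for p in cohort:
            fh.write(f"{p.patient_id}\t{p.label}\n")


def read_embeddings(path: str | Path) -> EmbeddingTable:
    """word2vec text format: header ``n d`` then ``term v1 ... vd`` lines."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("expected word2vec text header: '<n_terms> <dim>'")
        n, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, 2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != dim + 1:
                raise ValueError(f"line {lineno}: expected {dim} values")
            vectors[parts[0]] = np.array([float(v) for v in parts[1:]])
    if len(vectors) != n:
        logger.warning("header said %d terms, read %d", n, len(vectors))
    return EmbeddingTable(vectors=vectors, dim=dim)


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(table.vectors)} {table.dim}\n")
        for term in sorted(table.vectors):
            vals = " ".join(f"{v:.6g}" for v in table.vectors[term])
            fh.write(f"{term} {vals}\n")


def write_edge_table(graph: OntologyGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# child\tparent\n")
        for child, parent in sorted(graph.edges):
            fh.write(f"{child}\t{parent}\n")


def build_model(
    method: str,
    graph: OntologyGraph,
    embeddings: EmbeddingTable | None = None,
) -> SimilarityModel:
    from .ontology import information_content

    if method == "embedding_cosine":
        if embeddings is None:
            raise ValueError("similarity stage: method 'embedding_cosine' needs an embedding table")
        return SimilarityModel(method=method, graph=graph, embeddings=embeddings)
    if method in ("lin", "restricted_lin"):
        return SimilarityModel(method=method, graph=graph, stats=information_content(graph))
    return SimilarityModel(method=method, graph=graph)


def prepare_cohort(cohort: Cohort, graph: OntologyGraph, *,
                   min_terms: int = 4, apply_censoring: bool = True) -> Cohort:
    """Inclusion pipeline: resolve terms, censor dated phenotypes, min-count filter."""
    cohort = representation.resolve_terms(cohort, graph)
    if apply_censoring:
        cohort = representation.censor_cohort(cohort)
    return representation.filter_min_terms(cohort, k=min_terms)


def run_pipeline(config: RunConfig) -> EvaluationReport:
    """End-to-end run: load, filter, vectorize, train/evaluate, write artifacts.

    Writes ``metrics.json``, ``per_repetition.tsv`` and ``ranking.tsv`` into
    the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = load_ontology(config.ontology_path)
    cohort = read_patients(config.patients_path, config.labels_path)
    cohort = prepare_cohort(
        cohort, graph, min_terms=config.min_terms, apply_censoring=config.apply_censoring
    )
    counts = cohort.n_by_label()
    if counts["case"] < 2 or counts["control"] < 2:
        raise ValueError(
            f"cohort stage: need >=2 cases and >=2 controls, got {counts}"
        )
    embeddings = (
        read_embeddings(config.embeddings_path) if config.embeddings_path else None
    )
    model = build_model(config.pipeline.similarity_method, graph, embeddings)
    feature_space = FeatureSpace.from_cohort(cohort)
    vectors = representation.vectorize(cohort, feature_space, model)
    x = representation.vector_matrix(vectors)
    report, mean_scores = run_protocol(
        cohort, x, config.pipeline,
        specificity=config.specificity, k_percents=config.k_percents,
    )

    with open(out / "metrics.json", "w") as fh:
        json.dump(
            {"aggregate": report.aggregate, "config": report.config},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    pd.DataFrame([
        {k: v for k, v in rep.items() if not isinstance(v, dict)}
        for rep in report.per_repetition
    ]).to_csv(out / "per_repetition.tsv", sep="\t", index=False)
    ranked = RankedList.from_scores(mean_scores)
    with open(out / "ranking.tsv", "w") as fh:
        fh.write("patient_id\tscore\trank\n")
        for rank, (pid, s) in enumerate(zip(ranked.patient_ids, ranked.scores), 1):
            fh.write(f"{pid}\t{s:.6f}\t{rank}\n")
    logger.info("wrote metrics.json, per_repetition.tsv, ranking.tsv to %s", out)
    return report
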