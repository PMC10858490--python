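"""Synthetic ontologies, cohorts and embeddings for end-to-end testing.

The generator emulates the structure of a hospital-scale case-detection
study: a DAG-shaped phenotype vocabulary, a handful of rare cases against
thousands of controls drawn from an overlapping background region, cases
enriched for a set of signature terms expressed at variable granularity
(a case may carry a signature term or any of its descendants, the way
clinical coding records a more or less specific concept), and right-skewed
per-patient phenotype counts.

Per-class phenotype counts follow a lognormal whose parameters are solved
from a target median and interquartile range; the defaults reproduce the
study cohort's counts (cases: median 18, IQR 10.3-35.8; controls: median
10, IQR 6-18) and its 30 / 7,231 class imbalance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .ontology import OntologyGraph
from .representation import Cohort, PatientRecord
from .similarity import EmbeddingTable

_Z75 = 0.6744897501960817  # standard normal upper quartile


@dataclass(frozen=True)
class SimulationConfig:
    # ontology shape (a scaled-down stand-in for a phenotype ontology)
    n_terms: int = 200
    branching: int = 3                  # mean children per internal term
    max_depth: int | None = None
    extra_parent_prob: float = 0.1      # multiple-inheritance rate
    # cohort
    n_cases: int = 30
    n_controls: int = 7231
    n_signature_terms: int = 5
    case_carriage: float = 0.8          # per-signature-term carriage probability
    control_carriage: float = 0.05
    signature_terms: tuple[str, ...] | None = None
    background_root: str | None = None  # None -> all non-root terms
    # per-class distinct-phenotype-count targets (median, (q1, q3))
    case_count_median: float = 18.0
    case_count_iqr: tuple[float, float] = (10.3, 35.8)
    control_count_median: float = 10.0
    control_count_iqr: tuple[float, float] = (6.0, 18.0)
    # embeddings
    embedding_dim: int = 50
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 3:
            raise ValueError("need at least 3 terms")
        if self.n_cases < 1:
            raise ValueError("need at least 1 case")
        for p in (self.case_carriage, self.control_carriage, self.extra_parent_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


def lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given median and IQR."""
    q1, q3 = iqr
    if not (0 < q1 < q3):
        raise ValueError("need 0 < q1 < q3")
    return math.log(median), math.log(q3 / q1) / (2.0 * _Z75)


def simulate_ontology(config: SimulationConfig, seed: int | None = None) -> OntologyGraph:
    """Random DAG grown level by level.

    Each non-root term gets one parent drawn from the previous level, plus,
    with ``extra_parent_prob``, a second distinct parent drawn from any
    earlier term — earlier-only parents guarantee acyclicity.
    """
    rng = np.random.default_rng(config.master_seed if seed is None else seed)
    n = config.n_terms
    names = [f"T{i:0{max(4, len(str(n)))}d}" for i in range(n)]
    g = nx.DiGraph()
    g.add_node(names[0])
    levels: list[list[str]] = [[names[0]]]
    created = [names[0]]
    i = 1
    depth = 0
    while i < n:
        depth += 1
        if config.max_depth is not None and depth >= config.max_depth:
            size = n - i
        else:
            size = min(n - i, max(1, len(levels[-1]) * config.branching))
        level = []
        for _ in range(size):
            term = names[i]
            parent = levels[-1][rng.integers(len(levels[-1]))]
            g.add_edge(term, parent)
            eligible = [t for t in created if t != parent]
            if eligible and rng.random() < config.extra_parent_prob:
                extra = eligible[rng.integers(len(eligible))]
                g.add_edge(term, extra)
            level.append(term)
            created.append(term)
            i += 1
        levels.append(level)
    return OntologyGraph(graph=g, root=names[0])


def choose_signature_terms(
    graph: OntologyGraph, n_signature: int, rng: np.random.Generator,
    min_descendants: int = 3, max_descendants: int | None = None,
) -> tuple[str, ...]:
    """Internal, non-root terms with a moderate-sized descendant family.

    Signature concepts model specific disease-phenotype families, so terms
    subsuming more than ~10% of the ontology (top-level categories) are
    excluded along with near-leaves.
    """
    if max_descendants is None:
        max_descendants = max(min_descendants, len(graph) // 10)
    sizes = {
        t: len(graph.descendants(t, reflexive=True))
        for t in graph.terms if t != graph.root
    }
    candidates: list[str] = []
    # relax the size cap when a small ontology offers too few mid-sized terms
    while len(candidates) < n_signature and max_descendants < len(graph):
        candidates = sorted(
            t for t, n in sizes.items() if min_descendants <= n <= max_descendants
        )
        if len(candidates) < n_signature:
            max_descendants *= 2
    if len(candidates) < n_signature:
        raise ValueError(
            f"ontology has only {len(candidates)} terms with >= {min_descendants} "
            f"descendants; cannot pick {n_signature} signature terms"
        )
    idx = rng.choice(len(candidates), size=n_signature, replace=False)
    return tuple(candidates[i] for i in sorted(idx))


def _draw_counts(
    rng: np.random.Generator, n: int, median: float, iqr: tuple[float, float],
    max_count: int,
) -> np.ndarray:
    mu, sigma = lognormal_params(median, iqr)
    counts = np.rint(rng.lognormal(mu, sigma, size=n)).astype(int)
    return np.clip(counts, 1, max_count)


def simulate_cohort(
    graph: OntologyGraph, config: SimulationConfig, seed: int | None = None
) -> Cohort:
    """Imbalanced case/control cohort over a phenotype ontology.

    Cases and controls each carry every signature term — expressed as a
    uniformly chosen reflexive descendant — with their class's carriage
    probability, then draw background terms to reach a lognormal distinct
    count.  Both classes share the background region, so separation comes
    only from the signature enrichment.
    """
    rng = np.random.default_rng(config.master_seed if seed is None else seed)
    if config.signature_terms is not None:
        signature = config.signature_terms
        unknown = [t for t in signature if t not in graph]
        if unknown:
            raise ValueError(f"signature terms not in ontology: {unknown}")
    else:
        signature = choose_signature_terms(graph, config.n_signature_terms, rng)
    sig_descendants = {
        s: sorted(graph.descendants(s, reflexive=True)) for s in signature
    }
    if config.background_root is not None:
        background = sorted(graph.descendants(config.background_root, reflexive=True))
    else:
        # Default background excludes the signature subtrees so that the
        # per-class carriage probabilities are the only channel through
        # which signature-branch terms enter a patient record.
        sig_all = set().union(*sig_descendants.values())
        background = sorted(graph.terms - {graph.root} - sig_all)
    if not background:
        raise ValueError("empty background region")

    def make_patients(n: int, carriage: float, median: float,
                      iqr: tuple[float, float], prefix: str) -> list[PatientRecord]:
        counts = _draw_counts(rng, n, median, iqr, len(background))
        label = "case" if prefix == "case" else "control"
        width = len(str(n))
        patients = []
        for i in range(n):
            terms: set[str] = set()
            for s in signature:
                if rng.random() < carriage:
                    dec = sig_descendants[s]
                    terms.add(dec[rng.integers(len(dec))])
            target = max(int(counts[i]), len(terms))
            pool = [t for t in background if t not in terms]
            need = min(target - len(terms), len(pool))
            if need > 0:
                picks = rng.choice(len(pool), size=need, replace=False)
                terms.update(pool[j] for j in picks)
            patients.append(
                PatientRecord(
                    patient_id=f"{prefix}_{i:0{width}d}",
                    phenotypes=frozenset(terms),
                    label=label,
                )
            )
        return patients

    cases = make_patients(
        config.n_cases, config.case_carriage,
        config.case_count_median, config.case_count_iqr, "case",
    )
    controls = make_patients(
        config.n_controls, config.control_carriage,
        config.control_count_median, config.control_count_iqr, "ctrl",
    )
    return Cohort(
        tuple(cases + controls),
        provenance=(
            f"simulated: {config.n_cases} cases / {config.n_controls} controls, "
            f"signature={list(signature)}",
        ),
    )


def simulate_embeddings(
    graph: OntologyGraph, dim: int = 50, seed: int = 0, step_sd: float = 0.5
) -> EmbeddingTable:
    """Random-walk embeddings: child = mean of parents + Gaussian step.

    Cosine similarity then decays with graph distance, mimicking how trained
    term embeddings place ontologically close concepts close in space.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    vectors: dict[str, np.ndarray] = {}
    # edges point child -> parent, so reversed topological order is root-first
    for term in reversed(list(nx.topological_sort(graph.graph))):
        parents = sorted(graph.parents(term))
        if not parents:
            base = rng.standard_normal(dim)
        else:
            base = np.mean([vectors[p] for p in parents], axis=0)
        vec = base + step_sd * rng.standard_normal(dim) if parents else base
        vectors[term] = vec
    return EmbeddingTable(vectors=vectors, dim=dim)
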