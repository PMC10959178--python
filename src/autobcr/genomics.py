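"""Variant pathogenicity filtering, consensus-cluster assignment, and Hans
cell-of-origin calls.

Variant filtering retains a record only if its gene and consequence are
whitelisted and at least one predictor flags it damaging (SIFT deleterious,
PolyPhen possibly/probably damaging, or clinical significance likely
pathogenic/pathogenic); anything annotated benign in ClinVar is always
discarded, regardless of the other predictors.

Cluster assignment is a naive-Bayes calculation over binary locus states:
posterior(c) is proportional to prior(c) times the product over observed
loci of the cluster-conditional aberration frequency (or its complement for
wild-type loci), computed in log space.  Frequencies are epsilon-smoothed so
a single discordant locus cannot zero out a cluster.  An assignment is
confident ("assigned") only when the top posterior strictly exceeds 0.9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "VariantRecord",
    "ClusterModel",
    "ClusterAssignment",
    "filter_variants",
    "assign_consensus_cluster",
    "confidence_call",
    "hans_coo",
]


def _norm_label(label: str | None) -> str | None:
    if label is None:
        return None
    s = str(label).strip().lower().replace(" ", "_")
    return s or None


DAMAGING_SIFT = {"deleterious"}
DAMAGING_POLYPHEN = {"possibly_damaging", "probably_damaging"}
PATHOGENIC_CLINSIG = {"likely_pathogenic", "pathogenic"}
BENIGN_CLINSIG = {"benign", "likely_benign"}


@dataclass(frozen=True)
class VariantRecord:
    gene: str
    consequence: str
    sift_label: str | None = None
    polyphen_label: str | None = None
    clinical_significance: str | None = None
    case_id: str = ""

    def __post_init__(self) -> None:
        if not self.consequence:
            raise ValueError("consequence must be non-empty")


def _is_retained(
    rec: VariantRecord, genes: frozenset[str], consequences: frozenset[str]
) -> bool:
    clin = _norm_label(rec.clinical_significance)
    if clin in BENIGN_CLINSIG:
        return False  # benign annotation dominates every other predictor
    if rec.gene not in genes or _norm_label(rec.consequence) not in consequences:
        return False
    sift = _norm_label(rec.sift_label)
    poly = _norm_label(rec.polyphen_label)
    return (
        (sift in DAMAGING_SIFT)
        or (poly in DAMAGING_POLYPHEN)
        or (clin in PATHOGENIC_CLINSIG)
    )


def filter_variants(
    records: Iterable[VariantRecord],
    gene_whitelist: Sequence[str],
    consequence_whitelist: Sequence[str],
) -> list[VariantRecord]:
    """Apply the pathogenicity filter; idempotent and order-preserving."""
    if not gene_whitelist or not consequence_whitelist:
        raise ValueError("gene and consequence whitelists must be non-empty")
    genes = frozenset(gene_whitelist)
    consequences = frozenset(_norm_label(c) for c in consequence_whitelist)
    return [r for r in records if _is_retained(r, genes, consequences)]


# ---------------------------------------------------------------------------
# Consensus-cluster naive Bayes
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """Priors and locus-conditional aberration frequencies.

    ``frequencies[l, c]`` is the probability that locus ``l`` is aberrant in
    a case of cluster ``c`` (raw, unsmoothed; smoothing with ``epsilon`` is
    applied at classification time).  Priors default to uniform.
    """

    clusters: tuple[str, ...]
    loci: tuple[str, ...]
    frequencies: np.ndarray  # shape (n_loci, n_clusters)
    priors: np.ndarray | None = None
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        self.clusters = tuple(self.clusters)
        self.loci = tuple(self.loci)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (len(self.loci), len(self.clusters)):
            raise ValueError(
                f"frequencies shape {self.frequencies.shape} must be "
                f"(n_loci={len(self.loci)}, n_clusters={len(self.clusters)})"
            )
        if np.any(self.frequencies < 0) or np.any(self.frequencies > 1):
            raise ValueError("conditional frequencies must be in [0, 1]")
        if self.priors is None:
            self.priors = np.full(len(self.clusters), 1.0 / len(self.clusters))
        else:
            self.priors = np.asarray(self.priors, dtype=float)
            if len(self.priors) != len(self.clusters):
                raise ValueError("priors length must equal the number of clusters")
            if np.any(self.priors < 0) or not np.isclose(self.priors.sum(), 1.0):
                raise ValueError("priors must be non-negative and sum to 1")
        if not (0 < self.epsilon < 0.5):
            raise ValueError(f"epsilon must be in (0, 0.5), got {self.epsilon}")

    def smoothed_frequencies(self) -> np.ndarray:
        """Frequencies clipped into [epsilon, 1 - epsilon]."""
        return np.clip(self.frequencies, self.epsilon, 1.0 - self.epsilon)

    # -- JSON round trip (the user-supplied model file format) ------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "clusters": list(self.clusters),
                    "loci": list(self.loci),
                    "frequencies": self.frequencies.tolist(),
                    "priors": self.priors.tolist(),
                    "epsilon": self.epsilon,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        return cls(
            clusters=tuple(d["clusters"]),
            loci=tuple(d["loci"]),
            frequencies=np.asarray(d["frequencies"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float) if d.get("priors") else None,
            epsilon=d.get("epsilon", 0.01),
        )


@dataclass
class ClusterAssignment:
    posteriors: dict[str, float]
    cluster: str
    confidence: str | None = None  # "assigned" | "unclassified"
    uninformative: bool = False  # no observed loci: posteriors are the priors
    ambiguous: bool = False  # argmax tied, broken by cluster order

    @property
    def max_posterior(self) -> float:
        return self.posteriors[self.cluster]


def assign_consensus_cluster(
    aberration_vector: Mapping[str, int | bool | None], model: ClusterModel
) -> ClusterAssignment:
    """Posterior cluster probabilities for one case's binary locus states.

    ``aberration_vector`` maps locus name to 1/True (aberrant) or 0/False
    (wild-type); ``None``/NaN values are treated as unobserved and skipped,
    as are model loci absent from the vector.  A locus name not in the model
    is an error.
    """
    known = set(model.loci)
    unknown = [l for l in aberration_vector if l not in known]
    if unknown:
        raise ValueError(f"locus not in model: {sorted(unknown)}")
    p = model.smoothed_frequencies()
    log_post = np.log(model.priors)
    n_observed = 0
    for li, locus in enumerate(model.loci):
        state = aberration_vector.get(locus)
        if state is None or (isinstance(state, float) and np.isnan(state)):
            continue
        n_observed += 1
        if state:
            log_post = log_post + np.log(p[li])
        else:
            log_post = log_post + np.log1p(-p[li])
    log_post = log_post - logsumexp(log_post)
    post = np.exp(log_post)
    post = post / post.sum()
    best = int(np.argmax(post))
    ambiguous = bool(np.sum(np.isclose(post, post[best], rtol=0, atol=1e-12)) > 1)
    return ClusterAssignment(
        posteriors={c: float(v) for c, v in zip(model.clusters, post)},
        cluster=model.clusters[best],
        uninformative=(n_observed == 0),
        ambiguous=ambiguous,
    )


def confidence_call(assignment: ClusterAssignment, threshold: float = 0.9) -> str:
    """"assigned" iff the top posterior strictly exceeds the threshold."""
    call = "assigned" if assignment.max_posterior > threshold else "unclassified"
    assignment.confidence = call
    return call


# ---------------------------------------------------------------------------
# Hans immunohistochemistry algorithm
# ---------------------------------------------------------------------------


def hans_coo(cd10: bool | None, bcl6: bool | None, mum1: bool | None) -> str:
    """Cell-of-origin by the CD10/BCL6/MUM1 decision tree.

    CD10+ -> GCB; CD10- BCL6- -> non_GCB; CD10- BCL6+ MUM1+ -> non_GCB;
    CD10- BCL6+ MUM1- -> GCB.  All three marker calls are required.
    """
    markers = {"cd10": cd10, "bcl6": bcl6, "mum1": mum1}
    missing = [k for k, v in markers.items() if v is None]
    if missing:
        raise ValueError(f"missing marker call(s): {missing}")
    if cd10:
        return "GCB"
    if not bcl6:
        return "non_GCB"
    return "non_GCB" if mum1 else "GCB"
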