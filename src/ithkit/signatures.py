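"""SBS-96 catalogue construction and simplex-constrained exposure fitting.

Exposures are estimated by minimising the squared error between the
frequency-normalised catalogue and a convex combination of signature
columns, i.e. a quadratic programme over the probability simplex. Cohort
signature selection keeps signatures reaching at least 10% in at least one
sample; per-population refitting iteratively removes signatures below 5%
and reassigns their mutations to the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .io_formats import (
    CHANNELS96,
    MutationRecord,
    ReferenceGenome,
    SignatureMatrix,
    annotate_contexts,
)

logger = logging.getLogger(__name__)

#: Cohort signature set retained at the 10% screen (without platinum).
DEFAULT_COHORT_SIGNATURES = (
    "SBS1",
    "SBS2",
    "SBS3",
    "SBS5",
    "SBS8",
    "SBS13",
    "SBS17a",
    "SBS17b",
    "SBS18",
    "SBS20",
    "SBS26",
    "SBS36",
    "SBS39",
    "SBS40",
    "SBS44",
    "SBS93",
)

#: Platinum-therapy signatures added for pre-/post-treatment analyses.
PLATINUM_SIGNATURES = ("SBS31", "SBS35")

#: Signature groupings used for reporting and presence dichotomisation.
DEFAULT_GROUPS: dict[str, frozenset[str]] = {
    "APOBEC": frozenset({"SBS2", "SBS13"}),
    "MMR/MSI": frozenset({"SBS20", "SBS26", "SBS44"}),
}


@dataclass
class CatalogVector:
    """SBS-96 channel counts for one mutation population."""

    counts: np.ndarray  # shape (96,), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError(f"catalog must have 96 channels, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("catalog counts must be non-negative")

    @property
    def n_mutations(self) -> int:
        return int(round(self.counts.sum()))

    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("cannot normalise an all-zero catalogue")
        return self.counts / total


@dataclass
class ExposureVector:
    """Non-negative per-signature weights on the probability simplex."""

    names: list[str]
    weights: np.ndarray
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.names) != self.weights.shape[0]:
            raise ValueError("names and weights lengths differ")
        if np.any(self.weights < -1e-12):
            raise ValueError("exposure weights must be non-negative")
        self.weights = np.clip(self.weights, 0.0, None)
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"exposure weights must sum to 1, got {total}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.weights)))

    def weight(self, name: str) -> float:
        """Weight of one signature, 0.0 when it is not in the vector."""
        try:
            return float(self.weights[self.names.index(name)])
        except ValueError:
            return 0.0


def build_catalog(
    records: Iterable[MutationRecord], genome: ReferenceGenome | None = None
) -> CatalogVector:
    """Count SNVs per SBS-96 channel.

    Records lacking a channel annotation are annotated on the fly when a
    genome is supplied; records whose window leaves the contig are dropped
    with a logged count.
    """
    records = list(records)
    if genome is not None:
        missing = [r for r in records if r.channel is None]
        have = [r for r in records if r.channel is not None]
        records = have + annotate_contexts(missing, genome)
    counts = np.zeros(96)
    n_unresolved = 0
    for rec in records:
        if rec.channel is None:
            n_unresolved += 1
            continue
        counts[rec.channel] += 1
    if n_unresolved:
        logger.info("build_catalog: %d records had no resolvable context", n_unresolved)
    return CatalogVector(counts)


def fit_exposures(catalog: CatalogVector, matrix: SignatureMatrix) -> ExposureVector:
    """Quadratic-programming exposure estimate on the probability simplex.

    Minimises ``|| P w - c ||^2`` where ``c`` is the frequency-normalised
    catalogue and ``P`` the signature matrix, subject to ``w >= 0`` and
    ``sum(w) = 1``. Deterministic for a given input.
    """
    if catalog.counts.sum() == 0:
        raise ValueError("cannot fit exposures to a zero catalogue")
    S = matrix.n_signatures
    if S == 1:
        return ExposureVector(list(matrix.names), np.array([1.0]))
    c = catalog.frequencies()
    P = matrix.probs
    PtP = P.T @ P
    Ptc = P.T @ c

    def objective(w: np.ndarray) -> float:
        return float(w @ PtP @ w - 2.0 * Ptc @ w + c @ c)

    def gradient(w: np.ndarray) -> np.ndarray:
        return 2.0 * (PtP @ w - Ptc)

    w0 = np.full(S, 1.0 / S)
    res = optimize.minimize(
        objective,
        w0,
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * S,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    return ExposureVector(list(matrix.names), w)


def select_cohort_signatures(
    per_sample_exposures: Mapping[str, ExposureVector], min_prop: float = 0.10
) -> set[str]:
    """Signatures reaching ``min_prop`` weight in at least one sample."""
    if not per_sample_exposures:
        raise ValueError("no per-sample exposures supplied")
    kept: set[str] = set()
    for exp in per_sample_exposures.values():
        for name, w in zip(exp.names, exp.weights):
            if w >= min_prop:
                kept.add(name)
    return kept


def refit_with_pruning(
    catalog: CatalogVector,
    matrix_subset: SignatureMatrix,
    min_prop: float = 0.05,
    single_pass: bool = False,
) -> ExposureVector:
    """Fit exposures, dropping sub-threshold signatures and refitting.

    Iterates fit-then-prune to a fixed point (at most S rounds), so every
    retained signature ends at weight >= ``min_prop`` — except that the
    largest-weight signature is never dropped, so at least one signature
    always survives. ``single_pass=True`` stops after one prune-and-refit.
    """
    matrix = matrix_subset
    exposure = fit_exposures(catalog, matrix)
    for _ in range(matrix_subset.n_signatures):
        keep = exposure.weights >= min_prop
        if not keep.any():
            keep[int(np.argmax(exposure.weights))] = True
        if keep.all():
            break
        names = [n for n, k in zip(matrix.names, keep) if k]
        matrix = matrix.subset(names)
        exposure = fit_exposures(catalog, matrix)
        if single_pass:
            break
    return exposure


def group_exposures(
    exposure: ExposureVector, groups: Mapping[str, frozenset[str]] = None
) -> dict[str, float]:
    """Sum member weights per group; ungrouped signatures pass through.

    Groups with no member present report weight 0, so the output keys are
    stable across populations. Total weight is conserved.
    """
    if groups is None:
        groups = DEFAULT_GROUPS
    member_of: dict[str, str] = {}
    for gname, members in groups.items():
        for m in members:
            if m in member_of:
                raise ValueError(f"signature {m} belongs to several groups")
            member_of[m] = gname
    out: dict[str, float] = {g: 0.0 for g in groups}
    for name, w in zip(exposure.names, exposure.weights):
        target = member_of.get(name, name)
        out[target] = out.get(target, 0.0) + float(w)
    return out


def signature_presence(
    exposure: ExposureVector, group: str | frozenset[str]
) -> bool:
    """Whether a signature (or group of signatures) survived pruning.

    A group is present when any member carries positive weight after the
    5% prune-and-refit; the pruning threshold itself is the dichotomisation
    cutoff.
    """
    members = DEFAULT_GROUPS.get(group, {group}) if isinstance(group, str) else group
    return any(exposure.weight(m) > 0.0 for m in members)


@dataclass
class PopulationProfile:
    """Refitted exposure vector for one mutation population."""

    population: str
    exposure: ExposureVector
    n_mutations: int
    low_confidence: bool = False
    grouped: dict[str, float] = field(default_factory=dict)


def population_signature_profile(
    records: Iterable[MutationRecord],
    matrix: SignatureMatrix,
    cohort_signatures: Sequence[str] = DEFAULT_COHORT_SIGNATURES,
    include_platinum: bool = False,
    genome: ReferenceGenome | None = None,
    min_prop: float = 0.05,
    min_mutations: int = 50,
    population: str = "",
) -> PopulationProfile:
    """Catalogue + prune-refit pipeline for one mutation population.

    The candidate set is the cohort signature set, augmented with the
    platinum signatures SBS31/SBS35 for pre-/post-treatment analyses.
    Populations smaller than ``min_mutations`` are still fitted but
    flagged low-confidence.
    """
    names = [n for n in cohort_signatures if n in matrix.names]
    if include_platinum:
        names += [n for n in PLATINUM_SIGNATURES if n in matrix.names and n not in names]
    if not names:
        raise ValueError("no requested signatures found in the matrix")
    catalog = build_catalog(records, genome)
    exposure = refit_with_pruning(catalog, matrix.subset(names), min_prop=min_prop)
    low_conf = catalog.n_mutations < min_mutations
    exposure.low_confidence = low_conf
    return PopulationProfile(
        population=population,
        exposure=exposure,
        n_mutations=catalog.n_mutations,
        low_confidence=low_conf,
        grouped=group_exposures(exposure),
    )
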