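"""Classification of mutations into shared/private and unique-pre/-post populations.

A mutation found in both treatment-naive biopsies of a tumour is *shared*;
one found in only a single biopsy is *private*. When post-treatment samples
are added, *shared* means present in every available sample, *unique pre*
means present in at least one treatment-naive sample and no post-treatment
sample, and *unique post* the converse. Mutations present in some but not
all samples across both timepoints do not fit any of those labels and are
reported under the explicit residual class ``partial``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import MutationKey, MutationRecord

SPATIAL_LABELS = ("shared", "private")
TEMPORAL_LABELS = ("shared", "unique_pre", "unique_post", "partial")


@dataclass(frozen=True)
class PopulationLabel:
    """Population assignment of one mutation key plus its carrier samples."""

    label: str
    carrier_samples: frozenset[str]


@dataclass
class PopulationSummary:
    """Per-tumour counts and proportions of shared and private mutations."""

    tumour_id: str
    n_total: int
    n_shared: int
    n_private_per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def n_private(self) -> int:
        return sum(self.n_private_per_sample.values())

    @property
    def prop_shared(self) -> float:
        return self.n_shared / self.n_total if self.n_total else 0.0

    @property
    def prop_private(self) -> float:
        return self.n_private / self.n_total if self.n_total else 0.0


def index_by_key(
    records: Iterable[MutationRecord],
) -> dict[MutationKey, set[str]]:
    """Map each mutation key to the set of samples in which it was called.

    All records must belong to one tumour; mixing tumours raises.
    """
    index: dict[MutationKey, set[str]] = {}
    tumour_ids = set()
    for rec in records:
        tumour_ids.add(rec.tumour_id)
        if len(tumour_ids) > 1:
            raise ValueError(f"records span multiple tumours: {sorted(tumour_ids)}")
        index.setdefault(rec.key, set()).add(rec.sample_id)
    return index


def classify_spatial(
    index: Mapping[MutationKey, set[str]],
    sample_pre_1: str,
    sample_pre_2: str,
) -> dict[MutationKey, PopulationLabel]:
    """Label keys as shared (both treatment-naive samples) or private (one).

    The classification only inspects the two named pre-treatment samples;
    a key carried by neither raises (it does not belong in this analysis).
    """
    if sample_pre_1 == sample_pre_2:
        raise ValueError("the two pre-treatment samples must differ")
    labels: dict[MutationKey, PopulationLabel] = {}
    pair = {sample_pre_1, sample_pre_2}
    for key, carriers in index.items():
        hit = carriers & pair
        if not hit:
            raise ValueError(
                f"key {key} carried by neither {sample_pre_1} nor {sample_pre_2}"
            )
        label = "shared" if len(hit) == 2 else "private"
        labels[key] = PopulationLabel(label, frozenset(hit))
    return labels


def classify_temporal(
    index: Mapping[MutationKey, set[str]],
    pre_samples: Sequence[str],
    post_samples: Sequence[str],
) -> dict[MutationKey, PopulationLabel]:
    """Label keys by presence across pre- and post-treatment samples.

    shared: called in all samples; unique_pre: called in >=1 pre-treatment
    and no post-treatment sample; unique_post: the converse; partial:
    everything else (present in some but not all samples spanning both
    timepoints).
    """
    if not pre_samples or not post_samples:
        raise ValueError("need at least one pre- and one post-treatment sample")
    pre, post = set(pre_samples), set(post_samples)
    if pre & post:
        raise ValueError(f"samples listed at both timepoints: {sorted(pre & post)}")
    everything = pre | post
    labels: dict[MutationKey, PopulationLabel] = {}
    for key, carriers in index.items():
        hit = carriers & everything
        if not hit:
            raise ValueError(f"key {key} carried by no listed sample")
        if hit == everything:
            label = "shared"
        elif not (hit & post):
            label = "unique_pre"
        elif not (hit & pre):
            label = "unique_post"
        else:
            label = "partial"
        labels[key] = PopulationLabel(label, frozenset(hit))
    return labels


def population_proportions(
    labels: Mapping[MutationKey, PopulationLabel], tumour_id: str = ""
) -> PopulationSummary:
    """Summarise shared/private counts over distinct mutation keys.

    Private counts are broken down by carrier sample (each private key has
    exactly one carrier among the analysed pair).
    """
    if not labels:
        raise ValueError("empty label map")
    n_shared = 0
    private_per_sample: dict[str, int] = {}
    for lab in labels.values():
        if lab.label == "shared":
            n_shared += 1
        elif lab.label == "private":
            (carrier,) = lab.carrier_samples
            private_per_sample[carrier] = private_per_sample.get(carrier, 0) + 1
    return PopulationSummary(
        tumour_id=tumour_id,
        n_total=len(labels),
        n_shared=n_shared,
        n_private_per_sample=private_per_sample,
    )


def records_in_population(
    records: Iterable[MutationRecord],
    labels: Mapping[MutationKey, PopulationLabel],
    label: str,
) -> list[MutationRecord]:
    """Records whose key carries the given population label, one per key.

    Where a key was called in several samples, the record from the
    lexicographically first carrier sample represents it, so population
    catalogues count each distinct mutation once.
    """
    chosen: dict[MutationKey, MutationRecord] = {}
    for rec in records:
        lab = labels.get(rec.key)
        if lab is None or lab.label != label:
            continue
        prev = chosen.get(rec.key)
        if prev is None or rec.sample_id < prev.sample_id:
            chosen[rec.key] = rec
    return list(chosen.values())
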