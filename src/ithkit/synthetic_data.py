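"""Seeded synthetic cohorts with the structure the analysis assumes.

Generates a fixture genome, a COSMIC-style *synthetic* signature matrix,
multi-region (and optionally multi-timepoint) tumours with planted clone
trees, per-clone signature mixtures, binomial read counts, treatment-
induced C>A-in-CpC mutations, neoantigen affinities and survival times
linked to signature presence — everything the pipeline consumes, plus a
truth record for assertions.

The default parameters mirror the study conditions the pipeline targets:
two treatment-naive biopsies per tumour, 1-9 clones pre-treatment with
1-3 additional post-only clones, ~63% shared mutations, 60x depth,
purity 0.38-0.94 and disease-specific survival censored at 60 months.
Mutation counts per clone are scaled to desk size (hundreds per clone
rather than thousands).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    BASES,
    CHANNELS96,
    ClinicalRecord,
    MutationKey,
    MutationRecord,
    ReferenceGenome,
    SignatureMatrix,
    Timepoint,
    reverse_complement,
    sbs96_channel,
)
from .neoantigen import NeoantigenRecord

# ---------------------------------------------------------------------------
# Synthetic signature matrix

DEFAULT_SIGNATURE_NAMES = (
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
    "SBS31",
    "SBS35",
    "SBS36",
    "SBS39",
    "SBS40",
    "SBS44",
    "SBS93",
)

#: Channel families that anchor the better-characterised signatures:
#: (substitution, 5' flank or None, 3' flank or None).
_SIGNATURE_ANCHORS: dict[str, list[tuple[str, str | None, str | None]]] = {
    "SBS1": [("C>T", None, "G")],  # deamination at CpG
    "SBS2": [("C>T", "T", None)],  # APOBEC at TpC
    "SBS13": [("C>G", "T", None)],  # APOBEC at TpC
    "SBS17a": [("T>A", "C", "T")],  # CTT context
    "SBS17b": [("T>G", "C", "T")],  # CTT context
    "SBS18": [("C>A", None, None)],  # ROS-type C>A
    "SBS31": [("C>A", "C", None), ("C>T", "C", None)],  # platinum, CpC
    "SBS35": [("C>A", "C", None)],  # platinum, CpC
    "SBS36": [("C>A", None, None)],
}


def _channel_mask(sub: str, five: str | None, three: str | None) -> np.ndarray:
    mask = np.zeros(96, dtype=bool)
    for i, label in enumerate(CHANNELS96):
        if label[2:5] != sub:
            continue
        if five is not None and label[0] != five:
            continue
        if three is not None and label[6] != three:
            continue
        mask[i] = True
    return mask


def synthetic_signature_matrix(
    names: Sequence[str] = DEFAULT_SIGNATURE_NAMES, seed: int = 96
) -> SignatureMatrix:
    """Deterministic COSMIC-*style* synthetic SBS-96 signature matrix.

    These are synthetic stand-ins, not the published COSMIC profiles:
    each signature is a sparse random channel distribution (seeded from
    its name, so any subset of names yields the same columns), with the
    well-known biological concentrations imposed where they matter for
    the analysis — platinum signatures on C>A at CpC, APOBEC on C>T/C>G
    at TpC, SBS17a/b on the CTT context, SBS1 on CpG deamination. Use
    :func:`ithkit.io_formats.read_signature_matrix` to supply a real
    COSMIC matrix instead.
    """
    cols = []
    for name in names:
        digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        base = rng.dirichlet(np.full(96, 0.15))
        anchors = _SIGNATURE_ANCHORS.get(name)
        if anchors:
            col = 0.2 * base
            share = 0.8 / len(anchors)
            for sub, five, three in anchors:
                mask = _channel_mask(sub, five, three)
                inner = rng.dirichlet(np.full(int(mask.sum()), 1.0))
                add = np.zeros(96)
                add[mask] = inner * share
                col = col + add
        else:
            col = base
        cols.append(col / col.sum())
    return SignatureMatrix(CHANNELS96, list(names), np.column_stack(cols))


# ---------------------------------------------------------------------------
# Fixture genome and context index


def make_fixture_genome(
    length: int,
    seed: int,
    path: str | Path,
    cpc_freq: float | None = None,
) -> Path:
    """Write a reproducible random single-contig FASTA.

    Bases are drawn i.i.d.; ``cpc_freq`` sets the target CpC dinucleotide
    frequency by solving for the cytosine probability (freq(CC) = p_C^2
    under independence), with C and G kept symmetric. Same seed, same
    bytes.
    """
    if cpc_freq is None:
        probs = np.array([0.25, 0.25, 0.25, 0.25])
    else:
        if not 0 < cpc_freq < 0.25:
            raise ValueError("cpc_freq must lie in (0, 0.25)")
        p_c = float(np.sqrt(cpc_freq))
        p_other = (1.0 - 2.0 * p_c) / 2.0
        probs = np.array([p_other, p_c, p_c, p_other])  # A, C, G, T
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(BASES)[rng.choice(4, size=length, p=probs)])
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(">contig1\n")
        for i in range(0, length, 80):
            fh.write(seq[i : i + 80] + "\n")
    return path


class ContextIndex:
    """Positions of every SBS-96-compatible site in a genome.

    For each of the 32 pyrimidine-centric trinucleotide contexts, stores
    the 1-based positions (per contig) whose forward-strand context
    matches directly (pyrimidine reference) or after reverse complement
    (purine reference). Sampling a channel then means sampling a site
    from its context class and orienting ref/alt to the forward strand.
    """

    def __init__(self, genome: ReferenceGenome, contigs: Sequence[str] | None = None):
        self.genome = genome
        self.sites: dict[str, list[tuple[str, int, bool]]] = {}
        contigs = list(contigs) if contigs else list(genome._fasta.keys())
        for contig in contigs:
            seq = genome.sequence(contig)
            for i in range(1, len(seq) - 1):
                tri = seq[i - 1 : i + 2]
                if any(b not in BASES for b in tri):
                    continue
                centre = tri[1]
                if centre in ("C", "T"):
                    self.sites.setdefault(tri, []).append((contig, i + 1, False))
                else:
                    self.sites.setdefault(reverse_complement(tri), []).append(
                        (contig, i + 1, True)
                    )

    def sample_channel_site(
        self, channel: int, rng: np.random.Generator, used: set[tuple[str, int]]
    ) -> tuple[str, int, str, str, str]:
        """Draw an unused site for a channel; returns (chrom, pos, ref, alt, ctx).

        ref/alt/context are on the forward reference strand. Raises when
        the genome has no unused context-matching site left.
        """
        label = CHANNELS96[channel]
        tri = label[0] + label[2] + label[6]
        ref, alt = label[2], label[4]
        pool = self.sites.get(tri, [])
        if not pool:
            raise ValueError(f"genome has no site matching context {tri}")
        site = None
        for _ in range(50):  # fast path: rejection sampling
            cand = pool[int(rng.integers(len(pool)))]
            if (cand[0], cand[1]) not in used:
                site = cand
                break
        if site is None:  # crowded pool: sample among the unused sites
            free = [s for s in pool if (s[0], s[1]) not in used]
            if not free:
                raise ValueError(f"exhausted unused sites for context {tri}")
            site = free[int(rng.integers(len(free)))]
        contig, pos, flipped = site
        used.add((contig, pos))
        if flipped:
            fwd_ctx = self.genome.fetch(contig, pos - 1, pos + 1)
            return contig, pos, reverse_complement(ref), reverse_complement(alt), fwd_ctx
        return contig, pos, ref, alt, tri


def sample_mutations_from_signature(
    mixture: np.ndarray,
    n: int,
    index: ContextIndex,
    rng: np.random.Generator,
    used: set[tuple[str, int]] | None = None,
) -> list[tuple[str, int, str, str, str, int]]:
    """Draw ``n`` SNV sites whose channels follow a 96-channel mixture.

    Returns (chrom, pos, ref, alt, context, channel) tuples with no
    duplicate positions (``used`` carries exclusions across calls).
    """
    mixture = np.asarray(mixture, dtype=float)
    if mixture.shape != (96,):
        raise ValueError("mixture must be a 96-vector")
    mixture = mixture / mixture.sum()
    if used is None:
        used = set()
    channels = rng.choice(96, size=n, p=mixture)
    out = []
    for ch in channels:
        chrom, pos, ref, alt, ctx = index.sample_channel_site(int(ch), rng, used)
        out.append((chrom, pos, ref, alt, ctx, int(ch)))
    return out


def mixture_from_names(
    matrix: SignatureMatrix, weights: Mapping[str, float]
) -> np.ndarray:
    """Convex combination of signature columns as a 96-channel vector."""
    w = np.zeros(matrix.n_signatures)
    for name, weight in weights.items():
        w[matrix.names.index(name)] = weight
    if w.sum() <= 0:
        raise ValueError("mixture weights sum to zero")
    return matrix.probs @ (w / w.sum())


# ---------------------------------------------------------------------------
# Simulation configuration and cohort assembly

#: Baseline (founder / early) signature mixture over the synthetic set.
SHARED_MIXTURE = {"SBS17a": 0.25, "SBS17b": 0.15, "SBS5": 0.30, "SBS1": 0.15, "SBS18": 0.15}
#: Baseline subclonal mixture before any planted process.
PRIVATE_MIXTURE = {"SBS5": 0.35, "SBS1": 0.15, "SBS17a": 0.10, "SBS18": 0.20, "SBS8": 0.20}
#: APOBEC component planted into private clones of flagged tumours.
APOBEC_ADDON = {"SBS2": 0.20, "SBS13": 0.20}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator."""

    n_tumours: int = 29
    samples_per_tumour_pre: int = 2
    include_post: bool = False
    post_tumour_fraction: float = 1.0  # share of tumours that get post samples
    n_post_samples: int = 2
    clones_per_tumour: tuple[int, int] = (1, 9)
    post_extra_clones: tuple[int, int] = (1, 3)
    mutations_per_clone: tuple[int, int] = (150, 500)
    shared_fraction: float = 0.63
    subclone_both_prob: float = 0.25
    apobec_private_prob: float = 0.5
    platinum_fraction_post: float = 0.3
    depth_mean: float = 60.0
    purity_range: tuple[float, float] = (0.38, 0.94)
    hr_signature_present: float = 4.0
    baseline_median_months: float = 35.0
    censor_month: float = 60.0
    genome_length: int = 800_000
    min_clone_separation: float = 0.15
    min_clone_prevalence: float = 0.15
    min_alt_calls: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.clones_per_tumour, self.mutations_per_clone):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty and start at >= 1")
        for frac in (self.shared_fraction, self.platinum_fraction_post, self.apobec_private_prob):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SimulatedTumour:
    """One synthetic tumour: called records, full pileup, and the truth."""

    tumour_id: str
    sample_timepoints: dict[str, str]
    purity: dict[str, float]
    records: list[MutationRecord]
    pileup: pd.DataFrame
    truth: dict


@dataclass
class SimulatedCohort:
    config: SimConfig
    genome_path: Path
    genome: ReferenceGenome
    signature_matrix: SignatureMatrix
    tumours: list[SimulatedTumour]
    clinical: list[ClinicalRecord]
    affinities: list[NeoantigenRecord]
    truth: dict = field(default_factory=dict)


def _plant_prevalences(
    K: int,
    parents: list[int | None],
    n_samples: int,
    rng: np.random.Generator,
    present: np.ndarray,
    min_sep: float,
    floor: float = 0.15,
) -> np.ndarray:
    """Per-sample clone prevalences obeying the tree sum rule.

    The founder sits at prevalence 1 in every sample; each present child
    receives at least ``floor`` (the detectability floor) plus a random
    share of its parent's unallocated mass, so children never sum past
    their parent. Resamples until clone prevalence vectors are pairwise
    separated by ``min_sep`` in Chebyshev distance (best of 300 tries
    kept when the geometry cannot reach it).
    """
    children: dict[int, list[int]] = {k: [] for k in range(K)}
    for k, p in enumerate(parents):
        if p is not None:
            children[p].append(k)

    best = None
    best_sep = -1.0
    for _ in range(300):
        prev = np.zeros((K, n_samples))
        for s in range(n_samples):
            prev[0, s] = 1.0 if present[0, s] else 0.0
            stack = [0]
            while stack:
                node = stack.pop()
                avail = prev[node, s]
                kids = [k for k in children[node] if present[k, s]]
                stack.extend(children[node])
                if not kids or avail <= 0:
                    continue
                need = len(kids) * floor
                if avail >= need:
                    extra = rng.dirichlet(np.full(len(kids) + 1, 1.0))
                    cuts = floor + extra[:-1] * (avail - need)
                else:  # starved branch: split what is left evenly
                    cuts = np.full(len(kids), avail / len(kids))
                for kid, mass in zip(kids, cuts):
                    prev[kid, s] = mass
        if K == 1:
            return prev
        sep = min(
            np.max(np.abs(prev[i] - prev[j]))
            for i in range(K)
            for j in range(i + 1, K)
        )
        if sep > best_sep:
            best_sep, best = sep, prev
        if sep >= min_sep:
            return prev
    return best


def _merge_indistinct_clones(
    prev: np.ndarray,
    present: np.ndarray,
    parents: list[int | None],
    K_pre: int,
    min_sep: float,
) -> tuple[np.ndarray, np.ndarray, list[int | None], int, int]:
    """Merge clone pairs closer than ``min_sep`` in Chebyshev distance.

    When the prevalence geometry cannot realise the requested separation,
    the closest pair collapses into its higher-prevalence member (children
    reattach there) until every remaining pair is separated. The returned
    truth therefore only contains clones that are distinguishable in
    principle.
    """
    while prev.shape[0] > 1:
        K = prev.shape[0]
        dist = np.max(np.abs(prev[:, None, :] - prev[None, :, :]), axis=2)
        dist[np.tril_indices(K)] = np.inf
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i, j] >= min_sep:
            break
        keep, drop = (i, j) if prev[i].mean() >= prev[j].mean() else (j, i)
        if drop == 0:  # never absorb the founder
            keep, drop = drop, keep
        parents = [keep if p == drop else p for p in parents]
        parents = [p if p is None or p < drop else p - 1 for p in parents]
        del parents[drop]
        mask = np.arange(K) != drop
        prev, present = prev[mask], present[mask]
        if drop < K_pre:
            K_pre -= 1
    return prev, present, parents, prev.shape[0], K_pre


def plant_clone_structure(
    config: SimConfig,
    tumour_id: str,
    index: ContextIndex,
    matrix: SignatureMatrix,
    rng: np.random.Generator,
    apobec_private: bool,
    include_post: bool | None = None,
) -> SimulatedTumour:
    """Simulate one tumour: clone tree, prevalences, mutations, read counts.

    Pre-treatment clones follow ``clones_per_tumour``; the founder is
    present in every sample, subclones are present in both pre samples
    with the probability implied by ``shared_fraction`` and otherwise in
    exactly one. With post samples, extra post-only clones carry a
    platinum signature component of weight ``platinum_fraction_post``.
    Read counts are binomial at Poisson(depth) with VAF mapped from
    prevalence through purity on diploid copy number; a mutation is
    "called" in a sample when the clone is present there and at least
    ``min_alt_calls`` alt reads were drawn.
    """
    include_post = config.include_post if include_post is None else include_post
    K_pre = int(rng.integers(config.clones_per_tumour[0], config.clones_per_tumour[1] + 1))
    n_pre = config.samples_per_tumour_pre
    n_post = config.n_post_samples if include_post else 0
    K_post = (
        int(rng.integers(config.post_extra_clones[0], config.post_extra_clones[1] + 1))
        if include_post
        else 0
    )
    K = K_pre + K_post
    samples = [f"{tumour_id}_T{i + 1}" for i in range(n_pre)] + [
        f"{tumour_id}_P{i + 1}" for i in range(n_post)
    ]
    timepoints = {s: ("pre" if s.split("_")[-1].startswith("T") else "post") for s in samples}
    S = len(samples)
    purity = {
        s: float(rng.uniform(*config.purity_range)) for s in samples
    }

    parents: list[int | None] = [None]
    for k in range(1, K):
        if k >= K_pre:  # post-only clones hang off the founder
            parents.append(0)
        else:
            parents.append(int(rng.integers(k)))

    # presence: founder everywhere; pre subclones are mostly region-specific
    p_both = config.subclone_both_prob if K_pre > 1 else 1.0
    present = np.zeros((K, S), dtype=bool)
    present[0, :] = True
    pre_idx = list(range(n_pre))
    post_idx = list(range(n_pre, S))
    for k in range(1, K_pre):
        if rng.random() < p_both:
            present[k, pre_idx] = True
        else:
            present[k, int(rng.integers(n_pre))] = True
        if include_post and rng.random() < 0.5:  # surviving clones persist post
            present[k, post_idx] = True
        # presence must be monotone along the tree for the sum rule to hold
        present[k] &= present[parents[k]]
    for k in range(K_pre, K):
        present[k, post_idx] = True

    prev = _plant_prevalences(
        K,
        parents,
        S,
        rng,
        present,
        config.min_clone_separation,
        floor=config.min_clone_prevalence,
    )
    # planted clones must be identifiable: two clones whose prevalence
    # vectors differ by less than the separation floor in every sample are
    # one clone by any operational definition, so merge them in the truth
    prev, present, parents, K, K_pre = _merge_indistinct_clones(
        prev, present, parents, K_pre, config.min_clone_separation
    )

    # per-clone signature mixtures
    clone_mixtures: list[dict[str, float]] = []
    apobec_planted = False
    for k in range(K):
        if k >= K_pre:
            f = config.platinum_fraction_post
            mix = {n: w * (1 - f) for n, w in PRIVATE_MIXTURE.items()}
            mix["SBS35"] = f
        elif k == 0:
            mix = dict(SHARED_MIXTURE)
        else:
            mix = dict(PRIVATE_MIXTURE)
            if apobec_private and not present[k].all():
                mix = {n: w * 0.6 for n, w in mix.items()}
                mix.update(APOBEC_ADDON)
                apobec_planted = True
        clone_mixtures.append(mix)

    # mutation load: subclone sizes are uniform in the configured range;
    # the founder carries the clonal mass needed to land the cohort's
    # shared-mutation fraction at its target, as clonal mutations dominate
    # real tumours
    lo, hi = config.mutations_per_clone
    n_per_clone = [0] + [int(rng.integers(lo, hi + 1)) for _ in range(1, K)]
    n_sub_pre = sum(n_per_clone[1:K_pre])
    sf = config.shared_fraction
    if K_pre > 1 and sf < 1.0:
        founder = int(round(n_sub_pre * max(sf - p_both, 0.0) / (1.0 - sf)))
        n_per_clone[0] = max(founder, lo)
    else:
        n_per_clone[0] = int(rng.integers(lo, hi + 1)) * 2

    used: set[tuple[str, int]] = set()
    records: list[MutationRecord] = []
    pileup_rows = []
    assignment: dict[str, int] = {}
    for k in range(K):
        mixture = mixture_from_names(matrix, clone_mixtures[k])
        sites = sample_mutations_from_signature(mixture, n_per_clone[k], index, rng, used)
        for chrom, pos, ref, alt, ctx, channel in sites:
            key = MutationKey(chrom, pos, ref, alt)
            assignment[f"{chrom}:{pos}:{ref}:{alt}"] = k
            for j, s in enumerate(samples):
                depth = int(rng.poisson(config.depth_mean))
                vaf = prev[k, j] * purity[s] / 2.0
                alt_count = int(rng.binomial(depth, min(vaf, 1.0))) if depth else 0
                pileup_rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "ref_allele": ref,
                        "alt_allele": alt,
                        "sample_id": s,
                        "alt_count": alt_count,
                        "depth": depth,
                    }
                )
                if present[k, j] and alt_count >= config.min_alt_calls:
                    records.append(
                        MutationRecord(
                            tumour_id=tumour_id,
                            sample_id=s,
                            timepoint=Timepoint(timepoints[s]),
                            region_label=s.split("_")[-1],
                            chrom=chrom,
                            pos=pos,
                            ref_allele=ref,
                            alt_allele=alt,
                            alt_count=alt_count,
                            depth=max(depth, alt_count),
                            trinucleotide_context=ctx,
                            channel=sbs96_channel(ref, alt, ctx),
                            cn_total=2,
                            cn_major=1,
                        )
                    )

    shared_truth = sum(
        n for k, n in enumerate(n_per_clone[:K_pre]) if present[k, pre_idx].all()
    ) / max(sum(n_per_clone[:K_pre]), 1)
    truth = {
        "K": K,
        "K_pre": K_pre,
        "parents": parents,
        "prevalence": prev.tolist(),
        "present": present.tolist(),
        "samples": samples,
        "clone_mixtures": clone_mixtures,
        "n_per_clone": n_per_clone,
        "assignment": assignment,
        "apobec_private": bool(apobec_planted),
        "platinum_clones": list(range(K_pre, K)),
        "shared_fraction": float(shared_truth),
    }
    return SimulatedTumour(
        tumour_id=tumour_id,
        sample_timepoints=timepoints,
        purity=purity,
        records=records,
        pileup=pd.DataFrame(pileup_rows),
        truth=truth,
    )


def plant_platinum(
    records_post: list[MutationRecord],
    fraction: float,
    index: ContextIndex,
    rng: np.random.Generator,
    cpc_bias: float = 0.85,
) -> list[MutationRecord]:
    """Augment a post-treatment record list with platinum-style mutations.

    Adds C>A mutations, a ``cpc_bias`` share of them at CpC-context
    cytosines, until the additions make up ``fraction`` of the result.
    ``fraction=0`` returns the input unchanged.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0.0 or not records_post:
        return list(records_post)
    template = records_post[0]
    n_new = int(round(len(records_post) * fraction / (1.0 - fraction)))
    used = {(r.chrom, r.pos) for r in records_post}
    cpc_channels = [i for i, l in enumerate(CHANNELS96) if l[2:5] == "C>A" and l[0] == "C"]
    other_channels = [i for i, l in enumerate(CHANNELS96) if l[2:5] == "C>A" and l[0] != "C"]
    out = list(records_post)
    for _ in range(n_new):
        pool = cpc_channels if rng.random() < cpc_bias else other_channels
        channel = int(pool[int(rng.integers(len(pool)))])
        chrom, pos, ref, alt, ctx = index.sample_channel_site(channel, rng, used)
        depth = max(int(rng.poisson(60)), 1)
        alt_count = max(int(rng.binomial(depth, 0.3)), 1)
        out.append(
            MutationRecord(
                tumour_id=template.tumour_id,
                sample_id=template.sample_id,
                timepoint=template.timepoint,
                region_label=template.region_label,
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                alt_count=alt_count,
                depth=depth,
                trinucleotide_context=ctx,
                channel=sbs96_channel(ref, alt, ctx),
            )
        )
    return out


def simulate_survival(
    presence_flags: Sequence[bool],
    hr: float,
    rng: np.random.Generator,
    baseline_median_months: float = 35.0,
    censor_month: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards survival times with censoring.

    Signature-present patients have their hazard multiplied by ``hr``;
    everyone is administratively censored at ``censor_month``. Returns
    (times, events).
    """
    flags = np.asarray(presence_flags, dtype=bool)
    h0 = np.log(2.0) / baseline_median_months
    hazard = h0 * np.where(flags, hr, 1.0)
    raw = rng.exponential(1.0 / hazard)
    events = (raw <= censor_month).astype(int)
    times = np.minimum(raw, censor_month)
    return times, events


def simulate_affinities(
    records: Sequence[MutationRecord],
    rng: np.random.Generator,
    fraction: float = 0.15,
) -> list[NeoantigenRecord]:
    """Synthetic neoantigen affinity table for a subset of mutations.

    Mutant IC50 values are log-normal around ~200 nM; wild-type values
    are the mutant value scaled by a log-normal factor, so DAI spans
    negative to strongly positive values as real NetMHCpan output does.
    """
    keys = sorted({r.key for r in records})
    n = int(round(len(keys) * fraction))
    chosen = [keys[i] for i in rng.choice(len(keys), size=n, replace=False)] if n else []
    out = []
    for key in chosen:
        ic50_mt = float(np.exp(rng.normal(np.log(200.0), 1.0)))
        ic50_wt = float(ic50_mt * np.exp(rng.normal(0.4, 0.9)))
        out.append(
            NeoantigenRecord(
                key=key,
                hla_allele="HLA-A*02:01",
                peptide_mt="",
                peptide_wt="",
                ic50_mt=max(ic50_mt, 1.0),
                ic50_wt=max(ic50_wt, 1.0),
            )
        )
    return out


def simulate_cohort(config: SimConfig, workdir: str | Path) -> SimulatedCohort:
    """Generate a full synthetic cohort under one seed.

    Writes the fixture genome under ``workdir`` and returns in-memory
    tumours, clinical records, affinities and the truth dictionary. Two
    runs with the same config are identical.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome_path = make_fixture_genome(
        config.genome_length, seed=config.seed + 7, path=workdir / "genome.fa"
    )
    genome = ReferenceGenome(genome_path)
    index = ContextIndex(genome)
    matrix = synthetic_signature_matrix()

    tumours: list[SimulatedTumour] = []
    flags: list[bool] = []
    n_post_tumours = int(round(config.n_tumours * config.post_tumour_fraction))
    for t in range(config.n_tumours):
        tumour_id = f"SIM_{t + 1:04d}"
        apobec = bool(rng.random() < config.apobec_private_prob)
        tumour = plant_clone_structure(
            config,
            tumour_id,
            index,
            matrix,
            rng,
            apobec,
            include_post=config.include_post and t < n_post_tumours,
        )
        # the effective truth flag: APOBEC actually planted in >=1 private
        # clone (tumours without private clones cannot carry the process)
        flags.append(bool(tumour.truth["apobec_private"]))
        tumours.append(tumour)

    times, events = simulate_survival(
        flags,
        config.hr_signature_present,
        rng,
        baseline_median_months=config.baseline_median_months,
        censor_month=config.censor_month,
    )
    clinical = []
    for tum, t_i, e_i in zip(tumours, times, events):
        clinical.append(
            ClinicalRecord(
                patient_id=tum.tumour_id,
                age_years=float(rng.integers(38, 72)),
                stage_ctnm=int(rng.choice([1, 2, 3, 4], p=[0.034, 0.207, 0.725, 0.034])),
                treatment_arm=str(rng.choice(["CF", "DCF", "DCF_RT"], p=[0.5, 0.3, 0.2])),
                dss_months=float(t_i),
                event=int(e_i),
            )
        )

    affinities: list[NeoantigenRecord] = []
    for tum in tumours:
        affinities.extend(simulate_affinities(tum.records, rng))

    truth = {
        "apobec_private_flags": flags,
        "tumours": {t.tumour_id: t.truth for t in tumours},
    }
    return SimulatedCohort(
        config=config,
        genome_path=genome_path,
        genome=genome,
        signature_matrix=matrix,
        tumours=tumours,
        clinical=clinical,
        affinities=affinities,
        truth=truth,
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort in the formats the readers consume.

    Emits a cohort MAF, pileup/purity/sample-metadata/clinical/affinity
    TSVs, the signature matrix, and a truth JSON; the fixture genome is
    already on disk next to them.
    """
    from .io_formats import write_signature_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_dest = outdir / "genome.fa"
    if genome_dest.resolve() != Path(cohort.genome_path).resolve():
        genome_dest.write_bytes(Path(cohort.genome_path).read_bytes())
    paths: dict[str, Path] = {"genome": genome_dest}

    maf_rows = []
    pileups = []
    meta_rows = []
    purity_rows = []
    for tum in cohort.tumours:
        for r in tum.records:
            maf_rows.append(
                {
                    "Chromosome": r.chrom,
                    "Start_Position": r.pos,
                    "Reference_Allele": r.ref_allele,
                    "Tumor_Seq_Allele2": r.alt_allele,
                    "t_alt_count": r.alt_count,
                    "t_depth": r.depth,
                    "Tumor_Sample_Barcode": r.sample_id,
                }
            )
        pileups.append(tum.pileup)
        for s, tp in tum.sample_timepoints.items():
            meta_rows.append(
                {
                    "sample_id": s,
                    "tumour_id": tum.tumour_id,
                    "timepoint": tp,
                    "region_label": s.split("_")[-1],
                }
            )
            purity_rows.append({"sample_id": s, "purity": tum.purity[s]})

    paths["maf"] = outdir / "mutations.maf"
    pd.DataFrame(maf_rows).to_csv(paths["maf"], sep="\t", index=False)
    paths["pileup"] = outdir / "pileup.tsv"
    pd.concat(pileups, ignore_index=True).to_csv(paths["pileup"], sep="\t", index=False)
    paths["samples"] = outdir / "samples.tsv"
    pd.DataFrame(meta_rows).to_csv(paths["samples"], sep="\t", index=False)
    paths["purity"] = outdir / "purity.tsv"
    pd.DataFrame(purity_rows).to_csv(paths["purity"], sep="\t", index=False)

    paths["clinical"] = outdir / "clinical.tsv"
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "age_years": c.age_years,
                "stage_ctnm": c.stage_ctnm,
                "treatment_arm": c.treatment_arm,
                "dss_months": c.dss_months,
                "event": c.event,
            }
            for c in cohort.clinical
        ]
    ).to_csv(paths["clinical"], sep="\t", index=False)

    paths["affinity"] = outdir / "affinity.tsv"
    pd.DataFrame(
        [
            {
                "chrom": a.key.chrom,
                "pos": a.key.pos,
                "ref_allele": a.key.ref_allele,
                "alt_allele": a.key.alt_allele,
                "hla_allele": a.hla_allele,
                "peptide_mt": a.peptide_mt,
                "peptide_wt": a.peptide_wt,
                "ic50_mt": a.ic50_mt,
                "ic50_wt": a.ic50_wt,
            }
            for a in cohort.affinities
        ]
    ).to_csv(paths["affinity"], sep="\t", index=False)

    paths["signatures"] = outdir / "signatures.tsv"
    write_signature_matrix(cohort.signature_matrix, paths["signatures"])

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"config": asdict(cohort.config), **cohort.truth}, fh, indent=1, default=str
        )
    return paths
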