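"""End-to-end orchestration of the analysis stages.

Three entry points mirror the study design: :func:`run_spatial` compares
the two treatment-naive biopsies of each tumour (shared/private
populations, signature profiles, presence dichotomisation, survival
association); :func:`run_temporal` compares pre- against post-treatment
samples (unique-pre/unique-post profiles with the platinum signatures,
platinum enrichment odds ratios, paired tests); :func:`run_clonal`
decomposes each tumour into clones and joins per-clone signatures,
platinum scores and neoantigen DAI summaries. :func:`run_all` chains the
three and writes TSV outputs plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clones import (
    CloneModel,
    build_count_matrix,
    clone_mutations,
    cluster_mutations,
    infer_tree,
    prune_clones,
    timepoint_prevalence,
    clone_table,
)
from .io_formats import (
    ClinicalRecord,
    MutationRecord,
    ReferenceGenome,
    SampleInfo,
    SignatureMatrix,
    Timepoint,
    read_affinity_table,
    read_clinical_table,
    read_mutation_table,
    read_signature_matrix,
)
from .neoantigen import NeoantigenRecord, dai_by_population, filter_binders
from .platinum import PlatinumResult, platinum_enrichment
from .populations import (
    classify_spatial,
    classify_temporal,
    index_by_key,
    population_proportions,
    records_in_population,
)
from .signatures import (
    DEFAULT_COHORT_SIGNATURES,
    PLATINUM_SIGNATURES,
    PopulationProfile,
    build_catalog,
    fit_exposures,
    population_signature_profile,
    select_cohort_signatures,
    signature_presence,
)
from .survival_stats import (
    SurvivalFit,
    cox_adjusted,
    fdr_adjust,
    km_logrank,
    paired_t,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All numeric thresholds and knobs of the pipeline in one place."""

    cohort_sig_min: float = 0.10  # per-sample weight to enter the cohort set
    population_prune: float = 0.05  # per-population prune-and-refit threshold
    clone_min_fraction: float = 0.01  # clones below this share are excluded
    max_clusters: int = 40
    restarts: int = 100
    platinum_window: int = 41
    ic50_threshold: float = 500.0  # nM, inclusive binder cutoff
    censor_month: float = 60.0
    min_population_mutations: int = 50  # below this, profiles are flagged
    tree_tol: float = 0.05
    neighbor_side: str = "5p"  # CpC convention for the platinum statistic
    single_pass_prune: bool = False
    cohort_signatures: tuple[str, ...] | None = None  # None = select at 10%
    spatial_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cohort_sig_min", "population_prune", "clone_min_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.platinum_window % 2 == 0:
            raise ValueError("platinum_window must be odd")


@dataclass
class TumourData:
    """All inputs of one tumour: called records, purity, pileup, timepoints."""

    tumour_id: str
    records: list[MutationRecord]
    sample_timepoints: dict[str, str]
    purity: dict[str, float]
    pileup: pd.DataFrame | None = None

    @property
    def pre_samples(self) -> list[str]:
        return sorted(s for s, tp in self.sample_timepoints.items() if tp == "pre")

    @property
    def post_samples(self) -> list[str]:
        return sorted(s for s, tp in self.sample_timepoints.items() if tp == "post")


@dataclass
class CohortData:
    """A cohort ready for analysis, in memory."""

    tumours: dict[str, TumourData]
    genome: ReferenceGenome
    signature_matrix: SignatureMatrix
    clinical: list[ClinicalRecord]
    affinities: list[NeoantigenRecord] = field(default_factory=list)

    def clinical_by_id(self) -> dict[str, ClinicalRecord]:
        return {c.patient_id: c for c in self.clinical}


def cohort_from_simulation(sim) -> CohortData:
    """Adapt a :class:`~ithkit.synthetic_data.SimulatedCohort` for analysis."""
    tumours = {
        t.tumour_id: TumourData(
            tumour_id=t.tumour_id,
            records=t.records,
            sample_timepoints=dict(t.sample_timepoints),
            purity=dict(t.purity),
            pileup=t.pileup,
        )
        for t in sim.tumours
    }
    return CohortData(
        tumours=tumours,
        genome=sim.genome,
        signature_matrix=sim.signature_matrix,
        clinical=sim.clinical,
        affinities=sim.affinities,
    )


def load_cohort(directory: str | Path, censor_month: float = 60.0) -> CohortData:
    """Load a cohort directory (the layout ``write_cohort`` emits).

    Expects genome.fa, mutations.maf, samples.tsv, purity.tsv,
    clinical.tsv, signatures.tsv and optionally pileup.tsv and
    affinity.tsv.
    """
    directory = Path(directory)
    samples = pd.read_csv(directory / "samples.tsv", sep="\t")
    metadata = {
        str(r.sample_id): SampleInfo(
            tumour_id=str(r.tumour_id),
            timepoint=Timepoint(str(r.timepoint)),
            region_label=str(r.region_label),
        )
        for r in samples.itertuples(index=False)
    }
    records = read_mutation_table(directory / "mutations.maf", "maf", metadata)
    purity_df = pd.read_csv(directory / "purity.tsv", sep="\t")
    purity = {str(r.sample_id): float(r.purity) for r in purity_df.itertuples(index=False)}
    pileup_path = directory / "pileup.tsv"
    pileup = pd.read_csv(pileup_path, sep="\t") if pileup_path.exists() else None

    tumours: dict[str, TumourData] = {}
    for sample_id, info in metadata.items():
        td = tumours.setdefault(
            info.tumour_id,
            TumourData(info.tumour_id, [], {}, {}, None),
        )
        td.sample_timepoints[sample_id] = info.timepoint.value
        td.purity[sample_id] = purity.get(sample_id, 1.0)
    for rec in records:
        tumours[rec.tumour_id].records.append(rec)
    if pileup is not None:
        sample_tumour = {s: i.tumour_id for s, i in metadata.items()}
        pileup["_tumour"] = pileup["sample_id"].map(sample_tumour)
        for tid, sub in pileup.groupby("_tumour"):
            tumours[tid].pileup = sub.drop(columns="_tumour")

    affinity_path = directory / "affinity.tsv"
    return CohortData(
        tumours=tumours,
        genome=ReferenceGenome(directory / "genome.fa"),
        signature_matrix=read_signature_matrix(directory / "signatures.tsv"),
        clinical=read_clinical_table(directory / "clinical.tsv", censor_month),
        affinities=(
            read_affinity_table(affinity_path) if affinity_path.exists() else []
        ),
    )


# ---------------------------------------------------------------------------
# Shared helpers


def _spatial_pair(tumour: TumourData, config: PipelineConfig) -> tuple[str, str]:
    """The two treatment-naive samples entering the spatial analysis.

    Tumours with more than two pre-treatment biopsies must name their
    pair in ``config.spatial_pairs`` (the study picked the two closest in
    cellularity); with exactly two the choice is forced.
    """
    if tumour.tumour_id in config.spatial_pairs:
        return config.spatial_pairs[tumour.tumour_id]
    pre = tumour.pre_samples
    if len(pre) < 2:
        raise ValueError(f"{tumour.tumour_id} has fewer than two pre-treatment samples")
    if len(pre) > 2:
        raise ValueError(
            f"{tumour.tumour_id} has {len(pre)} pre-treatment samples; "
            "name the analysis pair in config.spatial_pairs"
        )
    return pre[0], pre[1]


def resolve_cohort_signatures(
    cohort: CohortData, config: PipelineConfig
) -> list[str]:
    """The signature set used for population refits.

    When the config does not pin a set, exposures are fitted per sample
    over all of that sample's mutations against the full candidate
    matrix and signatures reaching the 10% screen in at least one sample
    are retained (platinum signatures are handled separately and never
    enter the base set here).
    """
    if config.cohort_signatures is not None:
        return [n for n in config.cohort_signatures if n in cohort.signature_matrix.names]
    per_sample = {}
    for tumour in cohort.tumours.values():
        by_sample: dict[str, list[MutationRecord]] = {}
        for r in tumour.records:
            by_sample.setdefault(r.sample_id, []).append(r)
        for sample_id, recs in by_sample.items():
            catalog = build_catalog(recs, cohort.genome)
            if catalog.n_mutations == 0:
                continue
            per_sample[sample_id] = fit_exposures(catalog, cohort.signature_matrix)
    selected = select_cohort_signatures(per_sample, config.cohort_sig_min)
    selected -= set(PLATINUM_SIGNATURES)
    ordered = [n for n in cohort.signature_matrix.names if n in selected]
    logger.info("cohort signature set (10%% screen): %s", ordered)
    return ordered


def _profile(
    records: Sequence[MutationRecord],
    cohort: CohortData,
    cohort_sigs: Sequence[str],
    config: PipelineConfig,
    include_platinum: bool,
    population: str,
) -> PopulationProfile | None:
    if not records:
        return None
    return population_signature_profile(
        records,
        cohort.signature_matrix,
        cohort_signatures=cohort_sigs,
        include_platinum=include_platinum,
        genome=cohort.genome,
        min_prop=config.population_prune,
        min_mutations=config.min_population_mutations,
        population=population,
    )


def _profiles_frame(profiles: Mapping[tuple[str, str], PopulationProfile]) -> pd.DataFrame:
    rows = []
    for (tumour_id, population), prof in profiles.items():
        if prof is None:
            continue
        for name, w in zip(prof.exposure.names, prof.exposure.weights):
            rows.append(
                {
                    "tumour_id": tumour_id,
                    "population": population,
                    "signature": name,
                    "weight": float(w),
                    "n_mutations": prof.n_mutations,
                    "low_confidence": prof.low_confidence,
                }
            )
    return pd.DataFrame(rows)


def _survival_for_flags(
    cohort: CohortData, flags: Mapping[str, bool]
) -> tuple[SurvivalFit | None, SurvivalFit | None]:
    """Log-rank and stage-adjusted Cox for a per-patient presence flag."""
    clin = cohort.clinical_by_id()
    rows = [
        (clin[pid].dss_months, clin[pid].event, int(f), clin[pid].stage_ctnm)
        for pid, f in flags.items()
        if pid in clin
    ]
    if not rows:
        return None, None
    times, events, flag, stage = map(np.asarray, zip(*rows))
    if len(set(flag)) < 2:
        fit = SurvivalFit(flagged=True, flag_reason="presence flag is constant")
        return fit, fit
    km = km_logrank(times, events, flag)
    cox = cox_adjusted(times, events, flag, stage)
    return km, cox


# ---------------------------------------------------------------------------
# Spatial analysis (two treatment-naive biopsies per tumour)


@dataclass
class SpatialResult:
    summary: pd.DataFrame  # per-tumour shared/private counts and proportions
    profiles: pd.DataFrame  # long per-population exposures
    presence: pd.DataFrame  # per tumour x group presence in shared/private
    shared_vs_private_t: tuple[float, float]
    presence_survival: dict[str, tuple[SurvivalFit | None, SurvivalFit | None]]
    labels: dict[str, dict] = field(default_factory=dict)
    cohort_signatures: list[str] = field(default_factory=list)


def run_spatial(
    cohort: CohortData,
    config: PipelineConfig,
    presence_groups: Sequence[str] = ("APOBEC", "SBS3"),
) -> SpatialResult:
    """Shared/private population analysis of the treatment-naive biopsies."""
    cohort_sigs = resolve_cohort_signatures(cohort, config)
    summaries = []
    profiles: dict[tuple[str, str], PopulationProfile] = {}
    labels_by_tumour: dict[str, dict] = {}
    presence_rows = []
    for tumour_id in sorted(cohort.tumours):
        tumour = cohort.tumours[tumour_id]
        s1, s2 = _spatial_pair(tumour, config)
        pre_records = [r for r in tumour.records if r.sample_id in (s1, s2)]
        if not pre_records:
            continue
        index = index_by_key(pre_records)
        labels = classify_spatial(index, s1, s2)
        labels_by_tumour[tumour_id] = labels
        summary = population_proportions(labels, tumour_id)
        summaries.append(
            {
                "tumour_id": tumour_id,
                "n_total": summary.n_total,
                "n_shared": summary.n_shared,
                "n_private": summary.n_private,
                "prop_shared": summary.prop_shared,
                "prop_private": summary.prop_private,
                "sample_1": s1,
                "sample_2": s2,
                "n_private_sample_1": summary.n_private_per_sample.get(s1, 0),
                "n_private_sample_2": summary.n_private_per_sample.get(s2, 0),
            }
        )
        row: dict = {"tumour_id": tumour_id}
        for pop in ("shared", "private"):
            prof = _profile(
                records_in_population(pre_records, labels, pop),
                cohort,
                cohort_sigs,
                config,
                include_platinum=False,
                population=pop,
            )
            profiles[(tumour_id, pop)] = prof
            for group in presence_groups:
                row[f"{group}_{pop}"] = (
                    signature_presence(prof.exposure, group) if prof else False
                )
        presence_rows.append(row)

    summary_df = pd.DataFrame(summaries)
    t_stat, t_p = paired_t(
        summary_df["prop_shared"].to_numpy(), summary_df["prop_private"].to_numpy()
    )
    presence_df = pd.DataFrame(presence_rows)
    presence_survival = {}
    for group in presence_groups:
        flags = {
            r["tumour_id"]: bool(r[f"{group}_private"]) for r in presence_rows
        }
        presence_survival[group] = _survival_for_flags(cohort, flags)
    return SpatialResult(
        summary=summary_df,
        profiles=_profiles_frame(profiles),
        presence=presence_df,
        shared_vs_private_t=(t_stat, t_p),
        presence_survival=presence_survival,
        labels=labels_by_tumour,
        cohort_signatures=list(cohort_sigs),
    )


# ---------------------------------------------------------------------------
# Temporal analysis (pre vs post treatment)


@dataclass
class TemporalResult:
    counts: pd.DataFrame  # per tumour: shared / unique_pre / unique_post sizes
    profiles: pd.DataFrame  # exposures incl. SBS31/35
    platinum: pd.DataFrame  # per tumour x population odds ratios
    platinum_paired_t: tuple[float, float] | None
    labels: dict[str, dict] = field(default_factory=dict)


def run_temporal(cohort: CohortData, config: PipelineConfig) -> TemporalResult:
    """Unique-pre / unique-post analysis with the platinum signatures.

    Tumours without post-treatment samples are skipped with a log
    message. The platinum enrichment odds ratio is computed on the
    unique-pre and unique-post populations of each tumour and compared
    by a paired t-test.
    """
    cohort_sigs = resolve_cohort_signatures(cohort, config)
    counts_rows, platinum_rows = [], []
    profiles: dict[tuple[str, str], PopulationProfile] = {}
    labels_by_tumour: dict[str, dict] = {}
    or_pre, or_post = [], []
    for tumour_id in sorted(cohort.tumours):
        tumour = cohort.tumours[tumour_id]
        if not tumour.post_samples:
            logger.info("run_temporal: %s has no post-treatment samples; skipped", tumour_id)
            continue
        index = index_by_key(tumour.records)
        labels = classify_temporal(index, tumour.pre_samples, tumour.post_samples)
        labels_by_tumour[tumour_id] = labels
        pops = {
            pop: records_in_population(tumour.records, labels, pop)
            for pop in ("shared", "unique_pre", "unique_post")
        }
        counts_rows.append(
            {
                "tumour_id": tumour_id,
                **{f"n_{pop}": len(recs) for pop, recs in pops.items()},
                "n_partial": sum(1 for l in labels.values() if l.label == "partial"),
            }
        )
        pair: dict[str, PlatinumResult] = {}
        for pop in ("unique_pre", "unique_post"):
            profiles[(tumour_id, pop)] = _profile(
                pops[pop], cohort, cohort_sigs, config,
                include_platinum=True, population=pop,
            )
            result = platinum_enrichment(
                pops[pop],
                cohort.genome,
                window=config.platinum_window,
                neighbor_side=config.neighbor_side,
            )
            pair[pop] = result
            platinum_rows.append(
                {
                    "tumour_id": tumour_id,
                    "population": pop,
                    "odds_ratio": result.odds_ratio,
                    "n_eligible": result.n_eligible,
                    "mut_cpc": int(result.table[0, 0]),
                    "mut_non_cpc": int(result.table[0, 1]),
                    "bg_cpc": int(result.table[1, 0]),
                    "bg_non_cpc": int(result.table[1, 1]),
                    "flagged_undefined": result.flagged_undefined,
                    "haldane": result.haldane,
                }
            )
        if (
            pair["unique_pre"].odds_ratio is not None
            and pair["unique_post"].odds_ratio is not None
        ):
            or_pre.append(pair["unique_pre"].odds_ratio)
            or_post.append(pair["unique_post"].odds_ratio)

    paired = paired_t(or_post, or_pre) if len(or_pre) >= 2 else None
    return TemporalResult(
        counts=pd.DataFrame(counts_rows),
        profiles=_profiles_frame(profiles),
        platinum=pd.DataFrame(platinum_rows),
        platinum_paired_t=paired,
        labels=labels_by_tumour,
    )


# ---------------------------------------------------------------------------
# Clonal analysis


@dataclass
class ClonalResult:
    clones: pd.DataFrame  # clone x sample prevalences, fractions, parents
    assignments: pd.DataFrame  # mutation key -> clone
    fishplot: pd.DataFrame  # clone x timepoint averaged prevalences
    profiles: pd.DataFrame  # per-clone signature exposures
    platinum: pd.DataFrame  # per-clone platinum odds ratios
    dai: pd.DataFrame  # per-clone DAI summaries
    models: dict[str, CloneModel] = field(default_factory=dict)


def run_clonal(cohort: CohortData, config: PipelineConfig) -> ClonalResult:
    """Clonal decomposition and per-clone signature/platinum/DAI joins."""
    cohort_sigs = resolve_cohort_signatures(cohort, config)
    binders = filter_binders(cohort.affinities, config.ic50_threshold)
    clone_rows, assign_rows, fish_rows = [], [], []
    profiles: dict[tuple[str, str], PopulationProfile] = {}
    platinum_rows, dai_frames = [], []
    models: dict[str, CloneModel] = {}
    for tumour_id in sorted(cohort.tumours):
        tumour = cohort.tumours[tumour_id]
        matrix = build_count_matrix(
            tumour.records, tumour.pileup, purity=tumour.purity
        )
        model = cluster_mutations(
            matrix,
            max_clusters=config.max_clusters,
            restarts=config.restarts,
            seed=config.seed,
        )
        model = prune_clones(model, config.clone_min_fraction)
        infer_tree(model, tol=config.tree_tol)
        models[tumour_id] = model

        df = clone_table(model)
        df.insert(0, "tumour_id", tumour_id)
        clone_rows.append(df)
        for key, cid in model.assignment.items():
            assign_rows.append(
                {
                    "tumour_id": tumour_id,
                    "chrom": key.chrom,
                    "pos": key.pos,
                    "ref_allele": key.ref_allele,
                    "alt_allele": key.alt_allele,
                    "clone": model.clone_name(cid),
                }
            )
        fish = timepoint_prevalence(model, tumour.sample_timepoints).reset_index()
        fish.insert(0, "tumour_id", tumour_id)
        fish_rows.append(fish)

        by_key = {}
        for r in tumour.records:
            by_key.setdefault(r.key, r)
        include_platinum = bool(tumour.post_samples)
        clone_keys = clone_mutations(model)
        group_of = {}
        for cid, keys in clone_keys.items():
            name = model.clone_name(cid)
            recs = [by_key[k] for k in keys if k in by_key]
            for k in keys:
                group_of[k] = name
            profiles[(tumour_id, name)] = _profile(
                recs, cohort, cohort_sigs, config,
                include_platinum=include_platinum, population=name,
            )
            result = platinum_enrichment(
                recs,
                cohort.genome,
                window=config.platinum_window,
                neighbor_side=config.neighbor_side,
            )
            platinum_rows.append(
                {
                    "tumour_id": tumour_id,
                    "clone": name,
                    "odds_ratio": result.odds_ratio,
                    "n_eligible": result.n_eligible,
                    "flagged_undefined": result.flagged_undefined,
                }
            )
        dai = dai_by_population(binders, group_of)
        if not dai.empty:
            dai.insert(0, "tumour_id", tumour_id)
            dai_frames.append(dai)

    return ClonalResult(
        clones=pd.concat(clone_rows, ignore_index=True),
        assignments=pd.DataFrame(assign_rows),
        fishplot=pd.concat(fish_rows, ignore_index=True),
        profiles=_profiles_frame(profiles),
        platinum=pd.DataFrame(platinum_rows),
        dai=(
            pd.concat(dai_frames, ignore_index=True)
            if dai_frames
            else pd.DataFrame(columns=["tumour_id", "group", "n", "median_dai"])
        ),
        models=models,
    )


# ---------------------------------------------------------------------------
# run-all and output writing


def run_all(
    cohort: CohortData,
    config: PipelineConfig,
    outdir: str | Path | None = None,
) -> dict:
    """Run spatial, temporal and clonal analyses; optionally write outputs."""
    spatial = run_spatial(cohort, config)
    has_post = any(t.post_samples for t in cohort.tumours.values())
    temporal = run_temporal(cohort, config) if has_post else None
    clonal = run_clonal(cohort, config)
    results = {"spatial": spatial, "temporal": temporal, "clonal": clonal}
    if outdir is not None:
        write_results(results, config, Path(outdir))
    return results


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_results(results: dict, config: PipelineConfig, outdir: Path) -> None:
    """Write analysis tables as TSV plus a reproducibility manifest."""
    outdir.mkdir(parents=True, exist_ok=True)
    spatial: SpatialResult = results["spatial"]
    spatial.summary.to_csv(outdir / "population_summary.tsv", sep="\t", index=False)
    spatial.profiles.to_csv(outdir / "spatial_profiles.tsv", sep="\t", index=False)
    spatial.presence.to_csv(outdir / "presence.tsv", sep="\t", index=False)
    temporal: TemporalResult | None = results.get("temporal")
    if temporal is not None:
        temporal.counts.to_csv(outdir / "temporal_counts.tsv", sep="\t", index=False)
        temporal.profiles.to_csv(outdir / "temporal_profiles.tsv", sep="\t", index=False)
        temporal.platinum.to_csv(outdir / "platinum.tsv", sep="\t", index=False)
    clonal: ClonalResult = results["clonal"]
    clonal.clones.to_csv(outdir / "clones.tsv", sep="\t", index=False)
    clonal.assignments.to_csv(outdir / "clone_assignments.tsv", sep="\t", index=False)
    clonal.fishplot.to_csv(outdir / "fishplot.tsv", sep="\t", index=False)
    clonal.profiles.to_csv(outdir / "clone_profiles.tsv", sep="\t", index=False)
    clonal.platinum.to_csv(outdir / "clone_platinum.tsv", sep="\t", index=False)
    clonal.dai.to_csv(outdir / "clone_dai.tsv", sep="\t", index=False)

    survival_summary = {}
    for group, (km, cox) in spatial.presence_survival.items():
        survival_summary[group] = {
            "logrank_stat": None if km is None else km.logrank_stat,
            "logrank_p": None if km is None else km.logrank_p,
            "cox_hr": None if cox is None else cox.cox_hr,
            "cox_p": None if cox is None else cox.cox_p,
            "flagged": bool(km is not None and km.flagged),
        }
    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "shared_vs_private_paired_t": list(spatial.shared_vs_private_t),
        "platinum_paired_t": (
            list(temporal.platinum_paired_t)
            if temporal is not None and temporal.platinum_paired_t is not None
            else None
        ),
        "presence_survival": survival_summary,
        "counts": {
            "tumours": int(spatial.summary.shape[0]),
            "mutations": int(spatial.summary["n_total"].sum()),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
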