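"""Readers, writers and the internal mutation data model.

Normalises somatic SNV tables (MAF, VCF, internal TSV) into
:class:`MutationRecord` lists, extracts trinucleotide context from an
indexed FASTA, maps substitutions onto the pyrimidine-centric SBS-96
channel set, and reads COSMIC-format signature matrices, clinical tables
and neoantigen affinity tables.

Coordinates are 1-based and fully closed throughout. Only single-base
substitutions enter the pipeline; indels and multi-allelic rows are
counted and dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The six pyrimidine-centric substitution classes in COSMIC order.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical SBS-96 channel labels, COSMIC ordering: substitution-major,
#: then 5' flank, then 3' flank (A[C>A]A, A[C>A]C, ..., T[T>G]T).
CHANNELS96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS96)}


class Timepoint(str, Enum):
    """Sampling timepoint relative to neoadjuvant therapy."""

    PRE = "pre"
    POST = "post"


class MutationKey(NamedTuple):
    """Sample-independent identity of a somatic SNV."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-base substitution observed in one sample."""

    tumour_id: str
    sample_id: str
    timepoint: Timepoint
    region_label: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    alt_count: int
    depth: int
    trinucleotide_context: str | None = None  # reference strand, length 3
    channel: int | None = None  # SBS-96 index, 0..95
    cn_total: int | None = None
    cn_major: int | None = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based, got {self.pos}")
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}] "
                f"at {self.chrom}:{self.pos}"
            )
        ctx = self.trinucleotide_context
        if ctx is not None and ctx[1] != self.ref_allele:
            raise ValueError(
                f"context centre {ctx[1]!r} does not match ref {self.ref_allele!r}"
            )

    @property
    def key(self) -> MutationKey:
        return MutationKey(self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def with_context(self, context: str) -> "MutationRecord":
        """Return a copy annotated with reference context and SBS-96 channel."""
        return replace(
            self,
            trinucleotide_context=context,
            channel=sbs96_channel(self.ref_allele, self.alt_allele, context),
        )


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical covariates and disease-specific survival.

    Survival is censored at ``censor_month`` (60 by default) at read time,
    so downstream survival code never sees uncensored times.
    """

    patient_id: str
    age_years: float | None
    stage_ctnm: int  # ordinal: IB=1, IIB=2, III=3, IVA=4
    treatment_arm: str  # CF, DCF, DCF_RT, other
    dss_months: float
    event: int  # 1 = death from disease
    stage_yptnm: int | None = None
    tumour_length_pre_cm: float | None = None
    tumour_size_post_cm: float | None = None
    regression_pct: float | None = None

    def __post_init__(self) -> None:
        if self.dss_months < 0:
            raise ValueError(f"negative survival time for {self.patient_id}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event}")


@dataclass
class SignatureMatrix:
    """A 96 x S matrix of per-channel substitution probabilities."""

    channels: tuple[str, ...]
    names: list[str]
    probs: np.ndarray  # shape (96, S), columns sum to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (96, len(self.names)):
            raise ValueError(
                f"probs shape {self.probs.shape} != (96, {len(self.names)})"
            )
        if tuple(self.channels) != CHANNELS96:
            raise ValueError("channels must be the canonical SBS-96 label set")
        if np.any(self.probs < 0):
            raise ValueError("signature probabilities must be non-negative")
        sums = self.probs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"signature columns must sum to 1, got {sums}")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def subset(self, names: Sequence[str]) -> "SignatureMatrix":
        """Column subset in the given order; unknown names raise KeyError."""
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(self.channels, list(names), self.probs[:, idx])


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def sbs96_channel(ref: str, alt: str, context: str) -> int:
    """Map a substitution in trinucleotide context to its SBS-96 channel.

    Purine-reference mutations are reverse-complemented onto the
    pyrimidine-centric channel set, so the 192 strand-specific inputs map
    two-to-one onto 96 channels.
    """
    if len(context) != 3:
        raise ValueError(f"context must be length 3, got {context!r}")
    for b in (ref, alt, *context):
        if b not in BASES:
            raise ValueError(f"ambiguous or invalid base {b!r}")
    if context[1] != ref:
        raise ValueError(f"context centre {context[1]!r} != ref {ref!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in ("A", "G"):  # purine: flip to the pyrimidine strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context = reverse_complement(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return _CHANNEL_INDEX[label]


def channel_label(index: int) -> str:
    return CHANNELS96[index]


class ReferenceGenome:
    """Thin wrapper over an indexed FASTA with chr-prefix normalisation."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        self._contigs = set(self._fasta.keys())

    def normalise_chrom(self, chrom: str) -> str:
        """Strip/add a ``chr`` prefix to match the genome's contig names."""
        if chrom in self._contigs:
            return chrom
        alt = chrom[3:] if chrom.startswith("chr") else f"chr{chrom}"
        if alt in self._contigs:
            return alt
        raise KeyError(f"contig {chrom!r} not found in {self.path.name}")

    def contig_length(self, chrom: str) -> int:
        return len(self._fasta[self.normalise_chrom(chrom)])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based, fully-closed slice of the reference strand, uppercase."""
        chrom = self.normalise_chrom(chrom)
        if start < 1 or end > len(self._fasta[chrom]):
            raise ValueError(
                f"window {chrom}:{start}-{end} exceeds contig bounds "
                f"(length {len(self._fasta[chrom])})"
            )
        return str(self._fasta[chrom][start - 1 : end])

    def sequence(self, chrom: str) -> str:
        return str(self._fasta[self.normalise_chrom(chrom)][:])


def fetch_context(genome: ReferenceGenome, chrom: str, pos: int, flank: int) -> str:
    """Reference-strand sequence of length ``2*flank + 1`` centred on ``pos``.

    Raises ``ValueError`` when the window leaves the contig; the caller
    decides whether to drop the mutation.
    """
    return genome.fetch(chrom, pos - flank, pos + flank)


def annotate_contexts(
    records: Iterable[MutationRecord], genome: ReferenceGenome
) -> list[MutationRecord]:
    """Attach trinucleotide context and SBS-96 channel to each record.

    Records whose context window leaves the contig, or whose stated ref
    allele disagrees with the genome, are dropped with a logged count.
    """
    out: list[MutationRecord] = []
    n_out_of_range = 0
    n_ref_mismatch = 0
    for rec in records:
        try:
            ctx = fetch_context(genome, rec.chrom, rec.pos, 1)
        except (ValueError, KeyError):
            n_out_of_range += 1
            continue
        if ctx[1] != rec.ref_allele:
            n_ref_mismatch += 1
            continue
        out.append(rec.with_context(ctx))
    if n_out_of_range or n_ref_mismatch:
        logger.info(
            "annotate_contexts: dropped %d out-of-range and %d ref-mismatch records",
            n_out_of_range,
            n_ref_mismatch,
        )
    return out


# ---------------------------------------------------------------------------
# Mutation table readers

_MAF_REQUIRED = (
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "t_alt_count",
    "t_depth",
    "Tumor_Sample_Barcode",
)

#: Fixed column order of the internal canonical TSV.
INTERNAL_COLUMNS = (
    "tumour_id",
    "sample_id",
    "timepoint",
    "region_label",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "alt_count",
    "depth",
    "trinucleotide_context",
    "channel",
    "cn_total",
    "cn_major",
)


@dataclass
class SampleInfo:
    """Maps a sample barcode to its tumour, timepoint and region."""

    tumour_id: str
    timepoint: Timepoint
    region_label: str = ""


@dataclass
class ReadReport:
    """Row accounting for a mutation-table read."""

    n_records: int = 0
    n_skipped_indel: int = 0
    n_skipped_multiallelic: int = 0
    skipped_rows: list[int] = field(default_factory=list)


def _is_snv(ref: str, alt: str) -> bool:
    return (
        len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES and ref != alt
    )


def _lookup_sample(
    sample_metadata: Mapping[str, SampleInfo], sample_id: str
) -> SampleInfo:
    try:
        return sample_metadata[sample_id]
    except KeyError:
        raise KeyError(f"unknown sample id {sample_id!r} in mutation table") from None


def read_mutation_table(
    path: str | Path,
    format: str,
    sample_metadata: Mapping[str, SampleInfo],
    report: ReadReport | None = None,
) -> list[MutationRecord]:
    """Read a somatic mutation table into :class:`MutationRecord` objects.

    ``format`` is one of ``maf``, ``vcf`` or ``tsv`` (the internal canonical
    TSV). Indels and multi-allelic rows are skipped and counted in
    ``report``. Coordinates are returned 1-based regardless of dialect.
    """
    if format == "maf":
        return _read_maf(path, sample_metadata, report)
    if format == "vcf":
        return _read_vcf(path, sample_metadata, report)
    if format == "tsv":
        return read_internal_tsv(path)
    raise ValueError(f"unknown mutation table format {format!r}")


def _read_maf(
    path: str | Path,
    sample_metadata: Mapping[str, SampleInfo],
    report: ReadReport | None,
) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in _MAF_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"MAF is missing mandatory column {col!r}")
    report = report if report is not None else ReadReport()
    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        ref = str(getattr(row, "Reference_Allele"))
        alt = str(getattr(row, "Tumor_Seq_Allele2"))
        if "," in alt:
            report.n_skipped_multiallelic += 1
            report.skipped_rows.append(i)
            continue
        if not _is_snv(ref, alt):
            report.n_skipped_indel += 1
            report.skipped_rows.append(i)
            continue
        sample_id = str(getattr(row, "Tumor_Sample_Barcode"))
        info = _lookup_sample(sample_metadata, sample_id)
        records.append(
            MutationRecord(
                tumour_id=info.tumour_id,
                sample_id=sample_id,
                timepoint=info.timepoint,
                region_label=info.region_label,
                chrom=str(getattr(row, "Chromosome")),
                pos=int(getattr(row, "Start_Position")),
                ref_allele=ref,
                alt_allele=alt,
                alt_count=int(float(getattr(row, "t_alt_count"))),
                depth=int(float(getattr(row, "t_depth"))),
            )
        )
    report.n_records = len(records)
    if report.n_skipped_indel or report.n_skipped_multiallelic:
        logger.info(
            "read_mutation_table(%s): kept %d SNVs, skipped %d indel/MNV and %d multi-allelic rows",
            path,
            report.n_records,
            report.n_skipped_indel,
            report.n_skipped_multiallelic,
        )
    return records


def _read_vcf(
    path: str | Path,
    sample_metadata: Mapping[str, SampleInfo],
    report: ReadReport | None,
) -> list[MutationRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if not vcf_samples:
        raise ValueError(f"VCF {path} carries no sample columns")
    # tumour column: the single sample present in the metadata map
    tumour_cols = [s for s in vcf_samples if s in sample_metadata]
    if not tumour_cols:
        raise KeyError(
            f"unknown sample id(s) {vcf_samples!r}: none found in sample metadata"
        )
    sample_id = tumour_cols[0]
    s_idx = vcf_samples.index(sample_id)
    info = _lookup_sample(sample_metadata, sample_id)

    report = report if report is not None else ReadReport()
    records: list[MutationRecord] = []
    for i, variant in enumerate(vcf):
        alts = variant.ALT
        if len(alts) != 1:
            report.n_skipped_multiallelic += 1
            report.skipped_rows.append(i)
            continue
        ref, alt = variant.REF, alts[0]
        if not _is_snv(ref, alt):
            report.n_skipped_indel += 1
            report.skipped_rows.append(i)
            continue
        ad = variant.format("AD")
        if ad is not None:
            alt_count = int(ad[s_idx][1])
            depth = int(ad[s_idx].sum())
        else:
            depths = variant.format("DP")
            depth = int(depths[s_idx][0]) if depths is not None else 0
            alt_count = 0
        records.append(
            MutationRecord(
                tumour_id=info.tumour_id,
                sample_id=sample_id,
                timepoint=info.timepoint,
                region_label=info.region_label,
                chrom=variant.CHROM,
                pos=variant.POS,  # cyvcf2 POS is already 1-based
                ref_allele=ref,
                alt_allele=alt,
                alt_count=alt_count,
                depth=max(depth, alt_count),
            )
        )
    report.n_records = len(records)
    return records


def write_internal_tsv(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write records to the internal canonical TSV with fixed column order."""
    rows = []
    for r in records:
        rows.append(
            {
                "tumour_id": r.tumour_id,
                "sample_id": r.sample_id,
                "timepoint": r.timepoint.value,
                "region_label": r.region_label,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref_allele": r.ref_allele,
                "alt_allele": r.alt_allele,
                "alt_count": r.alt_count,
                "depth": r.depth,
                "trinucleotide_context": r.trinucleotide_context or "",
                "channel": "" if r.channel is None else r.channel,
                "cn_total": "" if r.cn_total is None else r.cn_total,
                "cn_major": "" if r.cn_major is None else r.cn_major,
            }
        )
    df = pd.DataFrame(rows, columns=list(INTERNAL_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_internal_tsv(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(INTERNAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"internal TSV is missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MutationRecord(
                tumour_id=row.tumour_id,
                sample_id=row.sample_id,
                timepoint=Timepoint(row.timepoint),
                region_label=row.region_label,
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=row.ref_allele,
                alt_allele=row.alt_allele,
                alt_count=int(row.alt_count),
                depth=int(row.depth),
                trinucleotide_context=row.trinucleotide_context or None,
                channel=int(row.channel) if row.channel != "" else None,
                cn_total=int(row.cn_total) if row.cn_total != "" else None,
                cn_major=int(row.cn_major) if row.cn_major != "" else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Signature matrix

def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a COSMIC-format tab-separated SBS-96 signature matrix.

    The first column holds channel labels (``A[C>A]A`` style); every other
    column is one signature. Rows may appear in any order and are
    canonicalised; columns within 1e-3 of unit sum are renormalised, and
    anything further off raises.
    """
    df = pd.read_csv(path, sep="\t")
    chan_col = df.columns[0]
    labels = df[chan_col].astype(str).tolist()
    unknown = [l for l in labels if l not in _CHANNEL_INDEX]
    if unknown:
        raise ValueError(f"unrecognised channel labels: {unknown[:5]}")
    if len(set(labels)) != 96 or len(labels) != 96:
        missing = set(CHANNELS96) - set(labels)
        raise ValueError(f"signature matrix must list all 96 channels; missing {sorted(missing)[:5]}")
    order = np.argsort([_CHANNEL_INDEX[l] for l in labels])
    names = [str(c) for c in df.columns[1:]]
    if not names:
        raise ValueError("signature matrix has no signature columns")
    probs = df.iloc[:, 1:].to_numpy(dtype=float)[order]
    sums = probs.sum(axis=0)
    bad = np.abs(sums - 1.0) > 1e-3
    if np.any(bad):
        raise ValueError(
            f"signature column(s) {[n for n, b in zip(names, bad) if b]} sum to "
            f"{sums[bad]}, more than 1e-3 from 1"
        )
    probs = probs / sums
    return SignatureMatrix(CHANNELS96, names, probs)


def write_signature_matrix(matrix: SignatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.probs, columns=matrix.names)
    df.insert(0, "Type", list(matrix.channels))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical and affinity tables

_STAGE_ORDINALS = {"IB": 1, "IIB": 2, "III": 3, "IVA": 4}


def stage_to_ordinal(stage: str | int | float) -> int:
    """Encode cTNM stage as an ordinal (IB=1, IIB=2, III=3, IVA=4)."""
    if isinstance(stage, (int, np.integer)):
        return int(stage)
    if isinstance(stage, float) and stage == int(stage):
        return int(stage)
    s = str(stage).strip()
    if s in _STAGE_ORDINALS:
        return _STAGE_ORDINALS[s]
    if s.isdigit():
        return int(s)
    raise ValueError(f"unrecognised cTNM stage {stage!r}")


def read_clinical_table(
    path: str | Path, censor_month: float = 60.0
) -> list[ClinicalRecord]:
    """Read the per-patient clinical TSV, censoring DSS at ``censor_month``.

    Times beyond the censoring horizon are truncated and their event flag
    suppressed, so downstream survival code never sees uncensored times.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "stage_ctnm", "treatment_arm", "dss_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table is missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        dss = float(row.dss_months)
        if dss < 0:
            raise ValueError(f"negative survival time for {row.patient_id}")
        event = int(row.event)
        if dss > censor_month:
            dss, event = censor_month, 0

        def _opt(name: str) -> float | None:
            val = getattr(row, name, None)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                return None
            return float(val)

        records.append(
            ClinicalRecord(
                patient_id=str(row.patient_id),
                age_years=_opt("age_years"),
                stage_ctnm=stage_to_ordinal(row.stage_ctnm),
                treatment_arm=str(row.treatment_arm),
                dss_months=dss,
                event=event,
                stage_yptnm=(
                    int(v) if (v := _opt("stage_yptnm")) is not None else None
                ),
                tumour_length_pre_cm=_opt("tumour_length_pre_cm"),
                tumour_size_post_cm=_opt("tumour_size_post_cm"),
                regression_pct=_opt("regression_pct"),
            )
        )
    return records


def read_affinity_table(path: str | Path):
    """Read the neoantigen affinity TSV into NeoantigenRecord objects.

    Expected columns: chrom, pos, ref_allele, alt_allele, hla_allele,
    peptide_mt, peptide_wt, ic50_mt, ic50_wt.
    """
    from .neoantigen import NeoantigenRecord

    df = pd.read_csv(path, sep="\t")
    required = {
        "chrom",
        "pos",
        "ref_allele",
        "alt_allele",
        "hla_allele",
        "ic50_mt",
        "ic50_wt",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"affinity table is missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            NeoantigenRecord(
                key=MutationKey(
                    str(row.chrom), int(row.pos), str(row.ref_allele), str(row.alt_allele)
                ),
                hla_allele=str(row.hla_allele),
                peptide_mt=str(getattr(row, "peptide_mt", "")),
                peptide_wt=str(getattr(row, "peptide_wt", "")),
                ic50_mt=float(row.ic50_mt),
                ic50_wt=float(row.ic50_wt),
            )
        )
    return records
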