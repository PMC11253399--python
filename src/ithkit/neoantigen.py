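"""Putative-neoantigen filtering and the differential agretopicity index.

Predicted epitopes with mutant-peptide binding affinity IC50 <= 500 nM are
considered putative neoantigens. The differential agretopicity index (DAI)
is the wild-type IC50 minus the mutant IC50: positive values mean the
mutant peptide binds MHC more strongly than its wild-type counterpart and
is therefore more likely to be immunogenic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MutationKey

IC50_BINDER_THRESHOLD_NM = 500.0


@dataclass(frozen=True)
class NeoantigenRecord:
    """One predicted (peptide, HLA allele) pair for one mutation."""

    key: MutationKey
    hla_allele: str
    peptide_mt: str
    peptide_wt: str
    ic50_mt: float  # nM
    ic50_wt: float  # nM
    dai: float | None = None

    def __post_init__(self) -> None:
        if self.ic50_mt <= 0 or self.ic50_wt <= 0:
            raise ValueError("IC50 values must be positive")
        if self.peptide_mt and self.peptide_wt and len(self.peptide_mt) != len(self.peptide_wt):
            raise ValueError("mutant and wild-type peptides must be equal length")


def filter_binders(
    records: Iterable[NeoantigenRecord],
    threshold: float = IC50_BINDER_THRESHOLD_NM,
) -> list[NeoantigenRecord]:
    """Keep records whose mutant IC50 is at or below the binder threshold.

    The boundary is inclusive (exactly 500 nM is retained). Idempotent.
    """
    return [r for r in records if r.ic50_mt <= threshold]


def compute_dai(record: NeoantigenRecord) -> float:
    """DAI = wild-type IC50 minus mutant IC50, in nM."""
    return record.ic50_wt - record.ic50_mt


def annotate_dai(records: Iterable[NeoantigenRecord]) -> list[NeoantigenRecord]:
    return [replace(r, dai=compute_dai(r)) for r in records]


def best_binder_per_mutation(
    records: Iterable[NeoantigenRecord],
) -> list[NeoantigenRecord]:
    """One record per mutation: the strongest mutant binder (lowest IC50)."""
    best: dict[MutationKey, NeoantigenRecord] = {}
    for r in records:
        cur = best.get(r.key)
        if cur is None or r.ic50_mt < cur.ic50_mt:
            best[r.key] = r
    return list(best.values())


def dai_by_population(
    records: Iterable[NeoantigenRecord],
    group_of: Mapping[MutationKey, str | int],
    per_mutation_best: bool = False,
) -> pd.DataFrame:
    """Median and quartiles of DAI per mutation population or clone.

    ``group_of`` maps mutation keys to a population label or clone id;
    records whose key has no group are dropped. By default every
    (peptide, HLA) record counts; ``per_mutation_best=True`` first reduces
    to the strongest binder per mutation. Groups with no records are
    absent from the output.
    """
    records = list(records)
    if per_mutation_best:
        records = best_binder_per_mutation(records)
    rows = []
    for r in records:
        group = group_of.get(r.key)
        if group is None:
            continue
        rows.append({"group": group, "dai": compute_dai(r)})
    if not rows:
        return pd.DataFrame(columns=["group", "n", "median_dai", "q1_dai", "q3_dai"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("group")["dai"]
        .agg(
            n="size",
            median_dai="median",
            q1_dai=lambda x: float(np.percentile(x, 25)),
            q3_dai=lambda x: float(np.percentile(x, 75)),
        )
        .reset_index()
    )
    return out
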