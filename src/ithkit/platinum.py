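"""Platinum-signature enrichment odds ratio.

Platinum chemotherapy leaves C>A substitutions at CpC dinucleotides. The
enrichment statistic compares, among a population's C>A (or G>T,
reverse-complemented) mutations, the odds that the mutated cytosine sits
in a CpC context against the background odds that a reference cytosine in
the surrounding 41-base windows sits in a CpC context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io_formats import MutationRecord, ReferenceGenome, reverse_complement


@dataclass
class PlatinumResult:
    """2x2 enrichment table and odds ratio for one mutation population.

    ``table`` rows: (mutated CpC, mutated non-CpC), (background CpC,
    background non-CpC). ``haldane`` marks the +0.5 zero-cell correction;
    ``flagged_undefined`` marks populations with no eligible mutation.
    """

    odds_ratio: float | None
    table: np.ndarray  # shape (2, 2) counts
    n_eligible: int
    flagged_undefined: bool = False
    haldane: bool = False


def _is_cpc(window: str, centre: int, neighbor_side: str) -> bool:
    """Whether the C at ``centre`` of a C-strand-oriented window is CpC."""
    if neighbor_side == "5p":
        return centre >= 1 and window[centre - 1] == "C"
    return centre + 1 < len(window) and window[centre + 1] == "C"


def platinum_enrichment(
    records: Iterable[MutationRecord],
    genome: ReferenceGenome,
    window: int = 41,
    neighbor_side: str = "5p",
) -> PlatinumResult:
    """Compute the platinum enrichment odds ratio on one mutation population.

    Eligible mutations are C>A on the reference strand and G>T mutations
    reverse-complemented onto the C strand. For each eligible mutation a
    ``window``-base region centred on the mutated cytosine is read; the
    numerator odds are mutated-CpC : mutated-non-CpC and the background
    odds count every reference C in those windows (G positions counted as
    C on the reverse strand), with multiplicity across overlapping
    windows. Any zero cell triggers a Haldane +0.5 correction on all four
    cells, flagged in the result.

    ``neighbor_side`` selects which neighbour of the mutated C defines the
    CpC dinucleotide: ``"5p"`` (default, the CC read 5'->3' ending at the
    mutated base) or ``"3p"``.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if neighbor_side not in ("5p", "3p"):
        raise ValueError(f"neighbor_side must be '5p' or '3p', got {neighbor_side!r}")
    flank = window // 2

    mut_cpc = mut_non = bg_cpc = bg_non = 0
    n_eligible = 0
    for rec in records:
        if (rec.ref_allele, rec.alt_allele) == ("C", "A"):
            strand = "+"
        elif (rec.ref_allele, rec.alt_allele) == ("G", "T"):
            strand = "-"
        else:
            continue
        try:
            seq = genome.fetch(rec.chrom, rec.pos - flank, rec.pos + flank)
        except (ValueError, KeyError):
            continue  # window leaves the contig; drop from the statistic
        n_eligible += 1
        oriented = seq if strand == "+" else reverse_complement(seq)
        # after orientation the mutated base is a C at the window centre
        if _is_cpc(oriented, flank, neighbor_side):
            mut_cpc += 1
        else:
            mut_non += 1
        # background: every reference C in the window (on either strand,
        # G counted as C of the reverse strand), skipping edge positions
        # whose defining neighbour falls outside the window
        for i in range(1, window - 1):
            if seq[i] == "C":
                if _is_cpc(seq, i, neighbor_side):
                    bg_cpc += 1
                else:
                    bg_non += 1
            elif seq[i] == "G":
                # reverse strand C; its 5' neighbour is the forward 3' base
                flipped = "5p" if neighbor_side == "3p" else "3p"
                if (seq[i + 1] if flipped == "3p" else seq[i - 1]) == "G":
                    bg_cpc += 1
                else:
                    bg_non += 1

    table = np.array([[mut_cpc, mut_non], [bg_cpc, bg_non]], dtype=float)
    if n_eligible == 0:
        return PlatinumResult(None, table, 0, flagged_undefined=True)
    haldane = bool((table == 0).any())
    t = table + 0.5 if haldane else table
    odds_ratio = float((t[0, 0] / t[0, 1]) / (t[1, 0] / t[1, 1]))
    return PlatinumResult(
        odds_ratio=odds_ratio,
        table=table.astype(int),
        n_eligible=n_eligible,
        haldane=haldane,
    )
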