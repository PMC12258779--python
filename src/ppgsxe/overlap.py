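"""GWIS locus pruning and "explained" annotation of significant pathways.

Genome-wide significant interaction hits are pruned into loci by greedy
distance pruning (take the smallest-p variant as a lead, drop every
significant variant within the radius on the same chromosome, repeat;
default +/- 500 kb).  A significant pathway is "explained" when at least one
lead variant lies within the window (default 100 kb) of the transcription
start site of any of the pathway's genes — TSS is ``start`` for + strand
genes and ``end`` for - strand genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .io import PathwayCollection

log = logging.getLogger(__name__)

__all__ = ["LocusSet", "ExplainOverlap", "prune_loci", "annotate_explained",
           "unexplained_fraction"]


@dataclass
class LocusSet:
    """Lead variants after distance pruning, sorted by p_int ascending."""

    leads: pd.DataFrame  # variant_id, chrom, pos, p_int
    radius_bp: int

    def __len__(self) -> int:
        return len(self.leads)


@dataclass
class ExplainOverlap:
    """Per significant pathway: explained flag and implicated (lead, gene) pairs."""

    explained: dict = field(default_factory=dict)     # pathway -> bool
    implicated: dict = field(default_factory=dict)    # pathway -> [(lead_id, gene_id)]
    window_bp: int = 100_000

    def n_significant(self) -> int:
        return len(self.explained)

    def n_unexplained(self) -> int:
        return sum(not v for v in self.explained.values())


def prune_loci(gwis_stats: pd.DataFrame, threshold: float = 5e-8,
               radius_bp: int = 500_000) -> LocusSet:
    if "p_int" not in gwis_stats.columns:
        raise ValueError("summary statistics lack a p_int column")
    p = gwis_stats["p_int"].to_numpy(dtype=float)
    sig = gwis_stats.loc[np.nan_to_num(p, nan=1.0) < threshold,
                         ["variant_id", "chrom", "pos", "p_int"]]
    sig = sig.sort_values(["p_int", "chrom", "pos"], kind="stable").reset_index(drop=True)
    chrom = sig["chrom"].to_numpy()
    pos = sig["pos"].to_numpy()
    alive = np.ones(len(sig), dtype=bool)
    lead_rows = []
    for i in range(len(sig)):
        if not alive[i]:
            continue
        lead_rows.append(i)
        alive &= ~((chrom == chrom[i]) & (np.abs(pos - pos[i]) <= radius_bp))
    leads = sig.iloc[lead_rows].reset_index(drop=True)
    return LocusSet(leads=leads, radius_bp=radius_bp)


def annotate_explained(significant_pathways: list[str], loci: LocusSet,
                       genes: pd.DataFrame, pathways: PathwayCollection,
                       window_bp: int = 100_000) -> ExplainOverlap:
    """Flag each significant pathway as explained by a nearby GWIS lead.

    Pathway gene IDs absent from the gene table are skipped with a log note.
    Window is symmetric around the TSS, bounds inclusive.
    """
    tss = np.where(genes["strand"].to_numpy() == "+",
                   genes["start"].to_numpy(), genes["end"].to_numpy())
    tss_of = dict(zip(genes["gene_id"], tss))
    chrom_of = dict(zip(genes["gene_id"], genes["chrom"]))

    out = ExplainOverlap(window_bp=window_bp)
    lead_id = loci.leads["variant_id"].to_numpy() if len(loci) else np.array([])
    lead_chrom = loci.leads["chrom"].to_numpy() if len(loci) else np.array([])
    lead_pos = loci.leads["pos"].to_numpy() if len(loci) else np.array([])
    for pwy in significant_pathways:
        if pwy not in pathways:
            raise KeyError(f"pathway {pwy!r} not in the collection")
        pairs: list[tuple[str, str]] = []
        for g in pathways.genes[pwy]:
            if g not in tss_of:
                log.debug("pathway %s: gene %s absent from gene table; skipped", pwy, g)
                continue
            near = (lead_chrom == chrom_of[g]) & (np.abs(lead_pos - tss_of[g]) <= window_bp)
            pairs.extend((lid, g) for lid in lead_id[near])
        out.explained[pwy] = bool(pairs)
        out.implicated[pwy] = pairs
    return out


def unexplained_fraction(overlap: ExplainOverlap) -> tuple[int, float, int]:
    """(count unexplained, exact fraction, percent rounded half-up).

    Undefined for zero significant pathways.
    """
    n_sig = overlap.n_significant()
    if n_sig == 0:
        raise ValueError("unexplained fraction is undefined with zero significant pathways")
    n_un = overlap.n_unexplained()
    frac = n_un / n_sig
    pct = int((Decimal(100 * n_un) / Decimal(n_sig))
              .quantize(Decimal(1), rounding=ROUND_HALF_UP))
    return n_un, frac, pct
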