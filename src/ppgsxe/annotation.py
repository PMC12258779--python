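"""Variant-to-gene and gene-to-pathway assignment.

A variant is assigned to a gene when its position falls inside the gene's
window: the gene interval extended by ``upstream_bp`` beyond the 5' end and
``downstream_bp`` beyond the 3' end (strand-aware; defaults 2 kb upstream,
1 kb downstream).  Bounds are inclusive, coordinates 1-based.  A pathway's
variant set is the union of its member genes' variants; gene IDs absent from
the gene table are logged and skipped, never fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .io import PathwayCollection

log = logging.getLogger(__name__)

__all__ = ["VariantGeneMap", "map_variants_to_genes", "build_pathway_variant_sets"]


@dataclass
class VariantGeneMap:
    """variant_id -> set of gene_ids, with the windows that produced it."""

    mapping: dict = field(default_factory=dict)
    upstream_bp: int = 2000
    downstream_bp: int = 1000

    def genes_for(self, variant_id: str) -> frozenset:
        return self.mapping.get(variant_id, frozenset())

    def gene_to_variants(self) -> dict[str, set]:
        inv: dict[str, set] = {}
        for v, gs in self.mapping.items():
            for g in gs:
                inv.setdefault(g, set()).add(v)
        return inv


def gene_windows(genes: pd.DataFrame, upstream_bp: int, downstream_bp: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Window [lo, hi] per gene row, strand-aware.

    + strand: [start - upstream, end + downstream]
    - strand: [start - downstream, end + upstream]
    """
    start = genes["start"].to_numpy()
    end = genes["end"].to_numpy()
    plus = (genes["strand"] == "+").to_numpy()
    lo = np.where(plus, start - upstream_bp, start - downstream_bp)
    hi = np.where(plus, end + downstream_bp, end + upstream_bp)
    return lo, hi


def map_variants_to_genes(variants: pd.DataFrame, genes: pd.DataFrame,
                          upstream_bp: int = 2000, downstream_bp: int = 1000
                          ) -> VariantGeneMap:
    if upstream_bp < 0 or downstream_bp < 0:
        raise ConfigurationError("window parameters must be non-negative")
    lo, hi = gene_windows(genes, upstream_bp, downstream_bp)
    gene_ids = genes["gene_id"].to_numpy()
    gene_chrom = genes["chrom"].to_numpy()

    mapping: dict[str, frozenset] = {}
    vpos = variants["pos"].to_numpy()
    vids = variants["variant_id"].to_numpy()
    vchrom = variants["chrom"].to_numpy()
    for chrom in pd.unique(vchrom):
        gmask = gene_chrom == chrom
        if not gmask.any():
            continue
        glo, ghi, gid = lo[gmask], hi[gmask], gene_ids[gmask]
        vmask = vchrom == chrom
        pos = vpos[vmask]
        # inclusive window containment, all pairs on this chromosome
        inside = (pos[:, None] >= glo[None, :]) & (pos[:, None] <= ghi[None, :])
        for i, vid in enumerate(vids[vmask]):
            hit = inside[i]
            if hit.any():
                mapping[vid] = frozenset(gid[hit])
    return VariantGeneMap(mapping=mapping, upstream_bp=upstream_bp,
                          downstream_bp=downstream_bp)


def build_pathway_variant_sets(vg_map: VariantGeneMap,
                               pathways: PathwayCollection) -> dict[str, frozenset]:
    """Pathway name -> union of member genes' mapped variants.

    Pathway genes with no mapped variants contribute nothing; pathways that
    end up empty are flagged in the log.
    """
    inv = vg_map.gene_to_variants()
    known_genes = set(inv)
    out: dict[str, frozenset] = {}
    for name in pathways.names:
        members = pathways.genes[name]
        absent = [g for g in members if g not in known_genes]
        if absent:
            log.debug("pathway %s: %d gene ID(s) without mapped variants: %s",
                      name, len(absent), ", ".join(absent[:5]))
        vs: set = set()
        for g in members:
            vs |= inv.get(g, set())
        if not vs:
            log.warning("pathway %s maps to zero variants", name)
        out[name] = frozenset(vs)
    return out
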