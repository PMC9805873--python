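"""Proximity of off-target sites to transcription start sites.

The published analysis considers a potential off-target binding site
"proximal" to a gene when it lies within 500 bp of one of the gene's TSSs.
Distance is measured from the TSS point to the nearest base of the site
interval (0 when the TSS falls inside it) and the boundary is inclusive.
TSS strand is carried but plays no role in the distance.
"""

from __future__ import annotations

import logging

import numpy as np

from .offtarget import _interval_tss_distance
from .types import OffTargetSite, ProximalHit, TSSRecord

logger = logging.getLogger(__name__)


def _tss_by_chrom(tss: list[TSSRecord]) -> dict[str, tuple[np.ndarray, list[TSSRecord]]]:
    groups: dict[str, list[TSSRecord]] = {}
    for rec in tss:
        groups.setdefault(rec.chromosome, []).append(rec)
    out = {}
    for chrom, recs in groups.items():
        recs.sort(key=lambda r: r.position)
        out[chrom] = (np.array([r.position for r in recs]), recs)
    return out


def annotate_proximal(
    sites: list[OffTargetSite],
    tss: list[TSSRecord],
    window: int = 500,
    include_on_target: bool = False,
) -> list[ProximalHit]:
    """One hit per (gene, site) pair with TSS-to-site distance <= ``window``.

    On-target-flagged sites are excluded by default so the distinct-gene set
    of the hits is exactly the "genes proximal to potential off-target
    binding sites".  A gene with several TSSs is proximal if any qualifies
    (one hit per qualifying TSS's gene-site pair is collapsed to the minimum
    distance).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    index = _tss_by_chrom(tss)
    missing_chroms: set[str] = set()
    best: dict[tuple[str, tuple], ProximalHit] = {}
    for site in sites:
        if site.is_on_target and not include_on_target:
            continue
        if site.chromosome not in index:
            if site.chromosome not in missing_chroms:
                missing_chroms.add(site.chromosome)
                logger.warning(
                    "site chromosome %r absent from TSS table; no hits possible",
                    site.chromosome,
                )
            continue
        positions, recs = index[site.chromosome]
        lo = int(np.searchsorted(positions, site.start - window, side="left"))
        hi = int(np.searchsorted(positions, site.end - 1 + window, side="right"))
        for rec in recs[lo:hi]:
            d = _interval_tss_distance(site.start, site.end, rec.position)
            if d <= window:
                key = (rec.gene, site.key())
                prev = best.get(key)
                if prev is None or d < prev.distance:
                    best[key] = ProximalHit(
                        gene=rec.gene, guide_id=site.guide_id,
                        site=site, distance=d,
                    )
    return sorted(
        best.values(),
        key=lambda h: (h.site.chromosome, h.site.start, h.site.strand,
                       h.guide_id, h.gene),
    )


def proximal_genes(hits: list[ProximalHit]) -> set[str]:
    """Distinct genes proximal to potential off-target binding sites."""
    return {h.gene for h in hits}


def neighborhood_genes(
    target_site: OffTargetSite,
    tss: list[TSSRecord],
    half_window: int = 1_000_000,
    exclude_gene: str | None = None,
) -> list[str]:
    """Genes with any TSS within +/- ``half_window`` of the site midpoint
    (inclusive), excluding the intended target gene itself.

    The default window matches the 1 Mb up/downstream region used to assess
    spreading of repression to neighbouring genes.
    """
    mid = target_site.midpoint
    genes = {
        rec.gene
        for rec in tss
        if rec.chromosome == target_site.chromosome
        and abs(rec.position - mid) <= half_window
        and rec.gene != exclude_gene
    }
    return sorted(genes)
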