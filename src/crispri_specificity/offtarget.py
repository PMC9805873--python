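"""Flaw-budget enumeration of candidate guide-RNA binding sites.

A site is reported where the 3-mer immediately 3' of the protospacer matches
the PAM pattern exactly, and the Hamming mismatches ("flaws") between spacer
and genomic protospacer — partitioned into the PAM-proximal seed region and
the non-seed remainder — satisfy all three caps of the
:class:`~crispri_specificity.types.FlawBudget`.  Both strands are scanned;
an overlapping site on the opposite strand is a distinct record.  A genomic
``N`` always counts as a mismatch and never satisfies a PAM position.

:func:`enumerate_sites` is the production scanner (vectorised sliding-window
comparison); :func:`brute_force_sites` is the deliberately literal
position-by-position oracle used in tests and ``--verify-oracle`` mode.
"""

from __future__ import annotations

import numpy as np

from . import _seq
from .types import FlawBudget, Genome, OffTargetSite, Spacer

#: window (bp) around the declared intended TSS within which a site is
#: flagged on-target and excluded from "potential off-target" counts
ON_TARGET_WINDOW = 500


def _check_args(spacer: Spacer, budget: FlawBudget, pam: str) -> str:
    pam = _seq.validate_pattern(pam)
    if budget.seed_length > len(spacer):
        raise ValueError(
            f"seed_length {budget.seed_length} exceeds spacer length {len(spacer)}"
        )
    return pam


def _interval_tss_distance(start: int, end: int, pos: int) -> int:
    """Distance from a point to a 0-based half-open interval (0 if inside)."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - (end - 1)
    return 0


def _flag_on_target(site: OffTargetSite, spacer: Spacer) -> OffTargetSite:
    if spacer.intended_tss is None:
        return site
    chrom, pos = spacer.intended_tss
    if site.chromosome != chrom:
        return site
    d = _interval_tss_distance(site.start, site.end, pos)
    if d <= ON_TARGET_WINDOW:
        return OffTargetSite(**{**site.__dict__, "is_on_target": True})
    return site


def sort_sites(sites: list[OffTargetSite]) -> list[OffTargetSite]:
    """Deterministic output order: (chromosome, start, strand, guide_id)."""
    return sorted(sites, key=lambda s: (s.chromosome, s.start, s.strand, s.guide_id))


def enumerate_sites(
    genome: Genome,
    spacer: Spacer,
    budget: FlawBudget = FlawBudget(),
    pam: str = "NGG",
) -> list[OffTargetSite]:
    """Enumerate all genomic sites matching ``spacer`` under ``budget``.

    Returns one :class:`OffTargetSite` per (chromosome, start, strand),
    sorted deterministically.  Chromosomes shorter than spacer + PAM simply
    yield no sites.
    """
    pam = _check_args(spacer, budget, pam)
    L, seed = len(spacer), budget.seed_length
    plen = len(pam)
    sp = _seq.encode(spacer.sequence)
    rc_sp = _seq.revcomp_codes(sp)
    pam_tab = _seq.pattern_tables(pam)
    rc_pam_tab = _seq.pattern_tables(_seq.revcomp_pattern(pam))

    out: list[OffTargetSite] = []
    for chrom, seq in genome.items():
        g = _seq.encode(seq)
        n = len(g)
        if n < L + plen:
            continue
        win = np.lib.stride_tricks.sliding_window_view(g, L)

        # forward strand: protospacer [i, i+L), PAM at [i+L, i+L+plen)
        fw = win[: n - L - plen + 1]
        mm = fw != sp
        seed_mm = mm[:, L - seed:].sum(axis=1) if seed else np.zeros(len(fw), int)
        non_mm = mm[:, : L - seed].sum(axis=1)
        ok = (
            (seed_mm <= budget.max_seed_flaws)
            & (non_mm <= budget.max_nonseed_flaws)
            & (seed_mm + non_mm <= budget.max_total_flaws)
        )
        for j in range(plen):
            ok &= pam_tab[j][g[L + j : n - plen + 1 + j]]
        for i in np.flatnonzero(ok):
            site = OffTargetSite(
                chromosome=chrom, start=int(i), strand="+",
                guide_id=spacer.guide_id, end=int(i) + L,
                seed_flaws=int(seed_mm[i]), nonseed_flaws=int(non_mm[i]),
                total_flaws=int(seed_mm[i] + non_mm[i]),
                pam_sequence=seq[i + L : i + L + plen],
            )
            out.append(_flag_on_target(site, spacer))

        # reverse strand: protospacer occupies forward [s, s+L), PAM at
        # [s-plen, s); window-vs-revcomp(spacer) mismatch at offset k maps to
        # spacer position L-1-k, so the seed is the first `seed` offsets
        rv = win[plen:]
        mm = rv != rc_sp
        seed_mm = mm[:, :seed].sum(axis=1) if seed else np.zeros(len(rv), int)
        non_mm = mm[:, seed:].sum(axis=1)
        ok = (
            (seed_mm <= budget.max_seed_flaws)
            & (non_mm <= budget.max_nonseed_flaws)
            & (seed_mm + non_mm <= budget.max_total_flaws)
        )
        for j in range(plen):
            ok &= rc_pam_tab[j][g[j : j + n - L - plen + 1]]
        for k in np.flatnonzero(ok):
            s = int(k) + plen
            site = OffTargetSite(
                chromosome=chrom, start=s, strand="-",
                guide_id=spacer.guide_id, end=s + L,
                seed_flaws=int(seed_mm[k]), nonseed_flaws=int(non_mm[k]),
                total_flaws=int(seed_mm[k] + non_mm[k]),
                pam_sequence=_seq.revcomp(seq[s - plen : s]),
            )
            out.append(_flag_on_target(site, spacer))

    return sort_sites(out)


MAX_BRUTE_FORCE_GENOME = 10**6


def brute_force_sites(
    genome: Genome,
    spacer: Spacer,
    budget: FlawBudget = FlawBudget(),
    pam: str = "NGG",
) -> list[OffTargetSite]:
    """Literal position-by-position oracle; identical contract to
    :func:`enumerate_sites`.  Refuses genomes over 1 Mb."""
    pam = _check_args(spacer, budget, pam)
    if genome.total_length > MAX_BRUTE_FORCE_GENOME:
        raise ValueError(
            f"genome of {genome.total_length} bp exceeds brute-force guard "
            f"of {MAX_BRUTE_FORCE_GENOME} bp"
        )
    L, seed, plen = len(spacer), budget.seed_length, len(pam)
    sp = spacer.sequence

    out: list[OffTargetSite] = []
    for chrom, seq in genome.items():
        n = len(seq)
        for start in range(0, n - L + 1):
            for strand in "+-":
                if strand == "+":
                    if start + L + plen > n:
                        continue
                    proto = seq[start : start + L]
                    pam_seq = seq[start + L : start + L + plen]
                else:
                    if start < plen:
                        continue
                    proto = _seq.revcomp(seq[start : start + L])
                    pam_seq = _seq.revcomp(seq[start - plen : start])
                if not _seq.iupac_match(pam_seq, pam):
                    continue
                seed_mm = non_mm = 0
                for j, (a, b) in enumerate(zip(sp, proto)):
                    if a != b or b == "N":
                        if j >= L - seed:
                            seed_mm += 1
                        else:
                            non_mm += 1
                if (
                    seed_mm <= budget.max_seed_flaws
                    and non_mm <= budget.max_nonseed_flaws
                    and seed_mm + non_mm <= budget.max_total_flaws
                ):
                    site = OffTargetSite(
                        chromosome=chrom, start=start, strand=strand,
                        guide_id=spacer.guide_id, end=start + L,
                        seed_flaws=seed_mm, nonseed_flaws=non_mm,
                        total_flaws=seed_mm + non_mm, pam_sequence=pam_seq,
                    )
                    out.append(_flag_on_target(site, spacer))
    return sort_sites(out)


def pool_sites(site_lists: list[list[OffTargetSite]]) -> list[OffTargetSite]:
    """Union of sites across the guides of a pool.

    De-duplicates on (guide_id, chromosome, start, strand): a locus hit by
    two pool members keeps one record per guide.
    """
    seen: dict[tuple, OffTargetSite] = {}
    for sites in site_lists:
        for s in sites:
            seen.setdefault(s.key(), s)
    return sort_sites(list(seen.values()))


def shared_loci(sites: list[OffTargetSite]) -> set[tuple[str, int, str]]:
    """Loci (chrom, start, strand) matched by more than one guide in a pool."""
    counts: dict[tuple[str, int, str], set[str]] = {}
    for s in sites:
        counts.setdefault((s.chromosome, s.start, s.strand), set()).add(s.guide_id)
    return {k for k, guides in counts.items() if len(guides) > 1}
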