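"""Integration of differential-expression results with off-target proximity.

The DE test itself (DESeq-style) is an *input*: this module consumes its
table, calls significant genes under the |log2FC| > 1.5, p < 0.05 rule
(adjusted p by default), cross-references them with the genes proximal to
potential off-target binding sites, partitions the candidates using the
target-matched siRNA orthogonal control, runs the 1 Mb neighbourhood
spreading check, and computes the global log2(TPM+1) Pearson correlation.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import DERecord, SpecificityReport, Thresholds

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "log2fc", "pvalue", "padj"]


def as_de_frame(table) -> pd.DataFrame:
    """Normalise a DE table (DataFrame or iterable of DERecord) to a frame."""
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in table])
    missing = [c for c in ("gene", "log2fc", "pvalue") if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if "padj" not in df.columns:
        df["padj"] = np.nan
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].unique()[:5]
        raise ValueError(f"duplicate genes in DE table, e.g. {list(dups)}")
    return df


def call_significant(table, th: Thresholds = Thresholds()) -> set[str]:
    """Genes with |log2fc| > th.min_abs_log2fc and p < th.alpha (both strict).

    Uses the adjusted p-value when ``th.use_adjusted``; if every adjusted
    p-value is missing, falls back to the raw p-value with a warning.
    Records with non-finite log2fc are skipped with a warning.
    """
    df = as_de_frame(table)
    if df.empty:
        raise ValueError("DE table is empty")
    finite = np.isfinite(df["log2fc"])
    if not finite.all():
        logger.warning(
            "skipping %d DE records with non-finite log2fc", (~finite).sum()
        )
        df = df[finite]
    pcol = "padj" if th.use_adjusted else "pvalue"
    if th.use_adjusted and df["padj"].isna().all():
        logger.warning(
            "all adjusted p-values missing; falling back to raw p-values"
        )
        pcol = "pvalue"
    sig = (df["log2fc"].abs() > th.min_abs_log2fc) & (df[pcol] < th.alpha)
    return set(df.loc[sig.fillna(False), "gene"])


def cross_reference(significant: set[str], proximal: set[str]) -> set[str]:
    """Candidate off-target-driven genes: significant AND proximal."""
    return set(significant) & set(proximal)


def attribute_orthogonal(
    candidates: set[str], sirna_significant: set[str]
) -> tuple[set[str], set[str]]:
    """Partition candidates using the target-matched siRNA control.

    A candidate also significant under the orthogonal siRNA knockdown is
    attributed to the on-target pathway (the published table's bolded genes);
    the remainder stay possible off-target effects.  Returns
    ``(pathway_attributed, possible_offtarget)``, a disjoint partition.
    """
    candidates = set(candidates)
    pathway = candidates & set(sirna_significant)
    return pathway, candidates - pathway


def spreading_check(significant: set[str], neighborhood: Iterable[str]) -> list[str]:
    """Significant genes within the on-target neighbourhood (+/- 1 Mb).

    An empty result is the "no spreading to neighbouring genes" outcome.
    """
    return sorted(set(neighborhood) & set(significant))


def specificity_correlation(
    treated_tpm: Mapping[str, float],
    control_tpm: Mapping[str, float],
    exclude: set[str] = frozenset(),
) -> float:
    """Pearson r of log2(TPM+1) across shared genes, excluding ``exclude``.

    The intended target gene is conventionally excluded so the statistic
    reflects global (off-target) agreement.  Returns NaN with a warning if
    either vector has zero variance.
    """
    treated = pd.Series(treated_tpm, dtype=float)
    control = pd.Series(control_tpm, dtype=float)
    shared = treated.index.intersection(control.index).difference(list(exclude))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared genes after exclusion, have {len(shared)}"
        )
    x = np.log2(treated[shared].to_numpy() + 1.0)
    y = np.log2(control[shared].to_numpy() + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance in a TPM vector; correlation undefined")
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def build_report(
    comparison: str,
    de_table,
    sirna_table=None,
    proximal: set[str] = frozenset(),
    neighborhood: Iterable[str] = (),
    thresholds: Thresholds = Thresholds(),
    treated_tpm: Mapping[str, float] | None = None,
    control_tpm: Mapping[str, float] | None = None,
    target_gene: str | None = None,
) -> SpecificityReport:
    """Assemble one comparison's specificity summary.

    ``proximal`` is the distinct-gene set from the TSS-proximity annotation;
    ``neighborhood`` the gene list within +/- 1 Mb of the on-target site.
    Proximal genes absent from the DE table are noted and kept (they simply
    cannot be significant).
    """
    significant = call_significant(de_table, thresholds)
    universe = set(as_de_frame(de_table)["gene"])
    stray = set(proximal) - universe
    if stray:
        logger.warning(
            "%d proximal genes absent from DE table (e.g. %s)",
            len(stray), sorted(stray)[:5],
        )
    candidates = cross_reference(significant, proximal)
    if sirna_table is not None:
        sirna_sig = call_significant(sirna_table, thresholds)
    else:
        sirna_sig = set()
    pathway, offtarget = attribute_orthogonal(candidates, sirna_sig)

    r = math.nan
    if treated_tpm is not None and control_tpm is not None:
        exclude = {target_gene} if target_gene else set()
        r = specificity_correlation(treated_tpm, control_tpm, exclude)

    return SpecificityReport(
        comparison=comparison,
        n_significant=len(significant),
        n_proximal_genes=len(set(proximal)),
        candidates=sorted(candidates),
        pathway_attributed=sorted(pathway),
        possible_offtarget=sorted(offtarget),
        neighborhood_flagged=spreading_check(significant, neighborhood),
        pearson_r=r,
    )
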