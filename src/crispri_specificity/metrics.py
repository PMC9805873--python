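"""Readout arithmetic: ΔΔCq relative expression and control-normalised values.

relative_expression implements the double-delta quantification-cycle method:

    ΔΔCq = (Cq_target,sample − Cq_housekeeping,sample)
         − (Cq_target,NTC   − Cq_housekeeping,NTC)
    relative expression = 2^(−ΔΔCq)

with a housekeeping gene (e.g. GAPDH or ACTB) and a non-targeting control
(NTC) as the baseline.  Technical replicates are averaged on the Cq scale
before the formula.
"""

from __future__ import annotations

import math

import pandas as pd


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


def delta_delta_cq(
    cq_target_sample: float,
    cq_hk_sample: float,
    cq_target_ntc: float,
    cq_hk_ntc: float,
) -> float:
    _require_finite(
        cq_target_sample=cq_target_sample, cq_hk_sample=cq_hk_sample,
        cq_target_ntc=cq_target_ntc, cq_hk_ntc=cq_hk_ntc,
    )
    return (cq_target_sample - cq_hk_sample) - (cq_target_ntc - cq_hk_ntc)


def relative_expression(
    cq_target_sample: float,
    cq_hk_sample: float,
    cq_target_ntc: float,
    cq_hk_ntc: float,
) -> float:
    """2^−ΔΔCq relative expression of the target versus the NTC baseline."""
    return 2.0 ** -delta_delta_cq(
        cq_target_sample, cq_hk_sample, cq_target_ntc, cq_hk_ntc
    )


def normalized_readout(value: float, control_value: float) -> float:
    """Readout (fluorescence, percent-positive, ...) over its control."""
    _require_finite(value=value, control_value=control_value)
    if control_value <= 0:
        raise ValueError(f"control_value must be > 0, got {control_value}")
    return value / control_value


def percent_knockdown(value: float, control_value: float) -> float:
    """Convenience: 1 − normalised value, as a fraction (repression depth)."""
    return 1.0 - normalized_readout(value, control_value)


def mean_cq(cq_table: pd.DataFrame, sample: str, gene: str) -> float:
    """Average technical-replicate Cq values (Cq scale) for one sample/gene.

    ``cq_table`` needs columns ``sample``, ``gene``, ``cq``.
    """
    sel = cq_table[(cq_table["sample"] == sample) & (cq_table["gene"] == gene)]
    if sel.empty:
        raise ValueError(f"no Cq records for sample={sample!r} gene={gene!r}")
    m = float(sel["cq"].mean())
    if not math.isfinite(m):
        raise ValueError(f"non-finite Cq for sample={sample!r} gene={gene!r}")
    return m


def relative_expression_table(
    cq_table: pd.DataFrame,
    target_gene: str,
    housekeeping_gene: str,
    ntc_sample: str,
) -> pd.DataFrame:
    """Per-sample 2^−ΔΔCq for every non-NTC sample in a long Cq table."""
    samples = [s for s in cq_table["sample"].unique() if s != ntc_sample]
    cq_t_ntc = mean_cq(cq_table, ntc_sample, target_gene)
    cq_h_ntc = mean_cq(cq_table, ntc_sample, housekeeping_gene)
    rows = []
    for s in samples:
        rel = relative_expression(
            mean_cq(cq_table, s, target_gene),
            mean_cq(cq_table, s, housekeeping_gene),
            cq_t_ntc, cq_h_ntc,
        )
        rows.append({"sample": s, "gene": target_gene,
                     "relative_expression": rel,
                     "percent_repression": 100.0 * (1.0 - rel)})
    return pd.DataFrame(rows)
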