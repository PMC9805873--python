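"""Domain records shared across the pipeline.

A CRISPRi guide is described by its :class:`Spacer` (the ~20-nt sequence that
base-pairs with the genomic protospacer).  Genomic matches found under a
seed/non-seed mismatch budget are :class:`OffTargetSite` records; annotation
and reporting build on :class:`TSSRecord`, :class:`DERecord` and the
Table-style :class:`SpecificityReport`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

from ._seq import CODE


@dataclass(frozen=True)
class Spacer:
    """A guide's protospacer-matching sequence and intended target.

    ``sequence`` must be unambiguous DNA over {A,C,G,T}, 18-25 nt (20 nt is
    the SpCas9 standard).  ``intended_tss`` is an optional ``(chromosome,
    position)`` used to flag on-target sites.
    """

    guide_id: str
    sequence: str
    intended_gene: str = ""
    intended_tss: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("spacer sequence is empty")
        bad = sorted({c for c in seq if c not in "ACGT"})
        if bad:
            raise ValueError(
                f"spacer {self.guide_id!r}: ambiguous/invalid bases {bad}; "
                "spacers must be unambiguous A/C/G/T"
            )
        if not 18 <= len(seq) <= 25:
            raise ValueError(
                f"spacer {self.guide_id!r}: length {len(seq)} outside 18-25"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FlawBudget:
    """Mismatch caps for the off-target scan.

    ``seed_length`` bases adjacent to the PAM form the seed region; the caps
    on seed, non-seed and total flaws are independent (the total is not
    required to equal the sum of the regional caps).
    """

    max_seed_flaws: int = 2
    max_nonseed_flaws: int = 2
    max_total_flaws: int = 4
    seed_length: int = 12

    def __post_init__(self) -> None:
        for name in ("max_seed_flaws", "max_nonseed_flaws",
                     "max_total_flaws", "seed_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True, order=True)
class OffTargetSite:
    """One genomic site matched under the flaw budget.

    ``start``/``end`` is the 0-based half-open interval of the protospacer on
    the forward genome coordinate system; the PAM (not included in the
    interval) lies 3' of the protospacer on ``strand``.
    """

    chromosome: str
    start: int
    strand: str
    guide_id: str
    end: int = 0
    seed_flaws: int = 0
    nonseed_flaws: int = 0
    total_flaws: int = 0
    pam_sequence: str = ""
    is_on_target: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.total_flaws != self.seed_flaws + self.nonseed_flaws:
            raise ValueError("total_flaws must equal seed_flaws + nonseed_flaws")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def key(self) -> tuple[str, int, str, str]:
        """De-duplication key: one record per (chrom, start, strand, guide)."""
        return (self.chromosome, self.start, self.strand, self.guide_id)


class Genome(Mapping[str, str]):
    """Named chromosomes mapped to nucleotide strings over {A,C,G,T,N}."""

    def __init__(self, chromosomes: Mapping[str, str]):
        self._chroms: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            seq = seq.upper()
            bad = sorted({c for c in seq if c not in CODE})
            if bad:
                raise ValueError(f"chromosome {name!r}: invalid bases {bad}")
            self._chroms[name] = seq

    def __getitem__(self, name: str) -> str:
        return self._chroms[name]

    def __iter__(self):
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._chroms.values())


@dataclass(frozen=True)
class TSSRecord:
    """One transcription start site (0-based point coordinate)."""

    gene: str
    chromosome: str
    position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("TSS position must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class ProximalHit:
    """A (gene, off-target site) pair with TSS-to-site distance <= window."""

    gene: str
    guide_id: str
    site: OffTargetSite
    distance: int


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression result (test itself is an input)."""

    gene: str
    log2fc: float
    pvalue: float
    padj: Optional[float] = None
    tpm_treated: Optional[float] = None
    tpm_control: Optional[float] = None


@dataclass(frozen=True)
class Thresholds:
    """Significance thresholds: |log2FC| > min_abs_log2fc and p < alpha.

    Both inequalities are strict.  ``use_adjusted`` selects BH-adjusted
    p-values (the default) versus raw p-values.
    """

    min_abs_log2fc: float = 1.5
    alpha: float = 0.05
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SpecificityReport:
    """One comparison's specificity summary (counts plus attributed genes).

    ``candidates`` are genes both significantly differentially expressed and
    proximal to a potential off-target binding site; ``pathway_attributed``
    are the candidates also significant under the target-matched siRNA
    (attributable to on-target knockdown), ``possible_offtarget`` the rest.
    """

    comparison: str
    n_significant: int = 0
    n_proximal_genes: int = 0
    candidates: list[str] = field(default_factory=list)
    pathway_attributed: list[str] = field(default_factory=list)
    possible_offtarget: list[str] = field(default_factory=list)
    neighborhood_flagged: list[str] = field(default_factory=list)
    pearson_r: float = math.nan

    def __post_init__(self) -> None:
        cand = set(self.candidates)
        attr, off = set(self.pathway_attributed), set(self.possible_offtarget)
        if attr & off:
            raise ValueError("pathway_attributed and possible_offtarget overlap")
        if attr | off != cand:
            raise ValueError("attribution does not partition the candidates")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def tsv_row(self) -> dict:
        """Flat row in the shape of the published summary table."""
        return {
            "comparison": self.comparison,
            "n_significant": self.n_significant,
            "n_proximal_genes": self.n_proximal_genes,
            "n_candidates": len(self.candidates),
            "candidates": ",".join(self.candidates),
            "pathway_attributed": ",".join(self.pathway_attributed),
            "possible_offtarget": ",".join(self.possible_offtarget),
            "neighborhood_flagged": ",".join(self.neighborhood_flagged),
            "pearson_r": self.pearson_r,
        }
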