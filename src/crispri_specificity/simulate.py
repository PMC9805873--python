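"""Synthetic fixtures with planted ground truth.

Everything the pipeline consumes can be generated here deterministically:
a pseudo-random genome with protospacer sites planted at known coordinates,
strands and seed/non-seed flaw partitions; a TSS table with genes placed at
known distances from the planted sites; DESeq-style differential-expression
tables with a planted on-target signal, pathway co-regulation shared with a
matched siRNA table, and off-target-proximal signals among a null
background; and :func:`make_study`, which bundles all of it into one
analysis-ready synthetic study.

Null DE genes carry uniform p-values and Normal(0, noise) log2 fold changes
directly — the DE test itself is out of scope, so its output distribution
is emulated, not recomputed from counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import _seq
from .offtarget import brute_force_sites
from .types import FlawBudget, Genome, Spacer, Thresholds, TSSRecord


class PlantingError(ValueError):
    """Planting could not satisfy its spec (overlap, bounds, collisions)."""


def make_genome(length: int, gc_fraction: float = 0.41, rng_seed: int = 0) -> Genome:
    """Single-chromosome pseudo-random genome; same seed, same sequence.

    The default GC fraction approximates the human genome average.
    """
    if not 0 <= gc_fraction <= 1:
        raise ValueError(f"gc_fraction must be in [0,1], got {gc_fraction}")
    if length < 1:
        raise ValueError("length must be >= 1")
    seq = _random_sequence(length, gc_fraction, np.random.default_rng(rng_seed))
    return Genome({"chr1": seq})


def _random_sequence(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    return "".join(
        rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
    )


@dataclass(frozen=True)
class PlantSpec:
    """One protospacer site to plant: where, which strand, which flaws.

    ``position`` is the 0-based forward-coordinate start of the protospacer;
    the concrete PAM 3-mer goes 3' of it on ``strand``.  Flaw positions are
    drawn inside the designated region (seed = PAM-proximal) and each flawed
    base is substituted with a random different base.
    """

    spacer: str
    chromosome: str
    position: int
    strand: str
    seed_flaws: int = 0
    nonseed_flaws: int = 0
    pam: str = "TGG"

    def footprint(self) -> tuple[int, int]:
        """Forward-coordinate interval occupied by protospacer + PAM."""
        L, p = len(self.spacer), len(self.pam)
        if self.strand == "+":
            return self.position, self.position + L + p
        return self.position - p, self.position + L


def plant_sites(
    genome: Genome,
    specs: list[PlantSpec],
    rng_seed: int = 0,
    seed_length: int = 12,
    budget: FlawBudget = FlawBudget(),
    pam_pattern: str = "NGG",
) -> tuple[Genome, pd.DataFrame]:
    """Edit ``genome`` so each planted locus matches its spec exactly.

    Returns the edited genome and a truth table (one row per planted site
    with its flaw partition and an ``in_budget`` flag under ``budget``).
    After editing, the whole genome is re-scanned with the brute-force
    oracle for every distinct spacer; an accidental extra in-budget site
    raises :class:`PlantingError` (callers regenerate with a fresh seed,
    see :func:`make_planted_genome`).
    """
    rng = np.random.default_rng(rng_seed)
    chroms = {name: list(seq) for name, seq in genome.items()}

    # bounds + overlap validation up front
    taken: dict[str, list[tuple[int, int]]] = {}
    for spec in specs:
        L = len(spec.spacer)
        n_seed = min(seed_length, L)
        if spec.seed_flaws > n_seed or spec.nonseed_flaws > L - n_seed:
            raise PlantingError(
                f"flaw counts ({spec.seed_flaws},{spec.nonseed_flaws}) not "
                f"achievable with spacer length {L} and seed {n_seed}"
            )
        if spec.strand not in "+-":
            raise PlantingError(f"bad strand {spec.strand!r}")
        lo, hi = spec.footprint()
        if spec.chromosome not in chroms:
            raise PlantingError(f"unknown chromosome {spec.chromosome!r}")
        if lo < 0 or hi > len(chroms[spec.chromosome]):
            raise PlantingError(
                f"planted interval [{lo},{hi}) outside {spec.chromosome}"
            )
        for a, b in taken.setdefault(spec.chromosome, []):
            if lo < b and a < hi:
                raise PlantingError(f"overlapping plant specs at [{lo},{hi})")
        taken[spec.chromosome].append((lo, hi))

    rows = []
    for spec in specs:
        L = len(spec.spacer)
        n_seed = min(seed_length, L)
        proto = list(spec.spacer)

        def _pick(region: np.ndarray, k: int) -> np.ndarray:
            if k == 0:
                return np.array([], dtype=int)
            return rng.choice(region, k, replace=False)

        seed_pos = _pick(np.arange(L - n_seed, L), spec.seed_flaws)
        non_pos = _pick(np.arange(0, L - n_seed), spec.nonseed_flaws)
        for j in np.concatenate([seed_pos, non_pos]).astype(int):
            proto[j] = rng.choice([b for b in "ACGT" if b != spec.spacer[j]])
        proto_s = "".join(proto)
        chrom = chroms[spec.chromosome]
        if spec.strand == "+":
            chrom[spec.position : spec.position + L] = proto_s
            chrom[spec.position + L : spec.position + L + len(spec.pam)] = spec.pam
        else:
            chrom[spec.position : spec.position + L] = _seq.revcomp(proto_s)
            chrom[spec.position - len(spec.pam) : spec.position] = _seq.revcomp(spec.pam)
        rows.append({
            "spacer": spec.spacer, "chromosome": spec.chromosome,
            "start": spec.position, "end": spec.position + L,
            "strand": spec.strand, "seed_flaws": spec.seed_flaws,
            "nonseed_flaws": spec.nonseed_flaws,
            "total_flaws": spec.seed_flaws + spec.nonseed_flaws,
            "pam": spec.pam,
            "in_budget": (
                spec.seed_flaws <= budget.max_seed_flaws
                and spec.nonseed_flaws <= budget.max_nonseed_flaws
                and spec.seed_flaws + spec.nonseed_flaws <= budget.max_total_flaws
            ),
        })
    truth = pd.DataFrame(rows)
    edited = Genome({name: "".join(c) for name, c in chroms.items()})

    # post-check: oracle scan must find the planted in-budget sites and
    # nothing else within budget
    bf_budget = FlawBudget(
        budget.max_seed_flaws, budget.max_nonseed_flaws,
        budget.max_total_flaws, seed_length,
    )
    for sp_seq in truth["spacer"].unique():
        sp = Spacer(guide_id="plant-check", sequence=sp_seq)
        found = {
            (s.chromosome, s.start, s.strand)
            for s in brute_force_sites(edited, sp, bf_budget, pam_pattern)
        }
        want = truth[truth["spacer"] == sp_seq]
        planted = {
            (r.chromosome, r.start, r.strand)
            for r in want.itertuples() if r.in_budget
        }
        if not planted <= found:
            raise PlantingError("planted in-budget site not recovered by oracle")
        extras = found - planted
        if extras:
            raise PlantingError(
                f"accidental in-budget site(s) created: {sorted(extras)[:3]}"
            )
    return edited, truth


def make_planted_genome(
    chrom_lengths: dict[str, int],
    specs: list[PlantSpec],
    rng_seed: int = 0,
    gc_fraction: float = 0.41,
    seed_length: int = 12,
    budget: FlawBudget = FlawBudget(),
    pam_pattern: str = "NGG",
    max_attempts: int = 10,
) -> tuple[Genome, pd.DataFrame]:
    """Generate a background genome and plant ``specs``, retrying with an
    incremented derived seed if the background happens to contain an
    accidental in-budget site."""
    for attempt in range(max_attempts):
        seed = rng_seed + attempt
        rng = np.random.default_rng(seed)
        genome = Genome({
            name: _random_sequence(n, gc_fraction, rng)
            for name, n in chrom_lengths.items()
        })
        try:
            return plant_sites(genome, specs, rng_seed=seed,
                               seed_length=seed_length, budget=budget,
                               pam_pattern=pam_pattern)
        except PlantingError as err:
            if "accidental" not in str(err):
                raise
    raise PlantingError(f"no collision-free genome in {max_attempts} attempts")


def make_tss_table(
    placements: list[tuple[str, str, int, str]],
    genome: Genome | None = None,
) -> list[TSSRecord]:
    """TSS records from (gene, chromosome, position, strand) placements,
    bounds-checked against ``genome`` when given."""
    records = []
    for gene, chrom, pos, strand in placements:
        if genome is not None:
            if chrom not in genome:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if not 0 <= pos < len(genome[chrom]):
                raise ValueError(f"TSS for {gene} at {pos} outside {chrom}")
        records.append(TSSRecord(gene=gene, chromosome=chrom,
                                 position=pos, strand=strand))
    return records


@dataclass(frozen=True)
class DEPlantSpec:
    """Statistical structure to plant into a DE-table pair.

    ``pathway_genes`` get effects in both the CRISPRi and the siRNA table
    (on-target pathway co-regulation); ``offtarget_genes`` only in the
    CRISPRi table.  Null genes get log2FC ~ Normal(0, ``noise_sd``) and
    uniform p-values; adjusted p-values are Benjamini-Hochberg.
    ``target_gene=None`` plants nothing at all (a pure null table pair).
    """

    n_genes: int = 1000
    target_gene: str | None = "TARGET01"
    target_log2fc: float = -5.0
    pathway_genes: frozenset[str] = frozenset()
    offtarget_genes: frozenset[str] = frozenset()
    noise_sd: float = 0.2
    rng_seed: int = 0
    planted_abs_log2fc: tuple[float, float] = (2.0, 3.0)
    planted_pvalue: float = 1e-8

    def __post_init__(self) -> None:
        target = {self.target_gene} if self.target_gene else set()
        sets = [target, set(self.pathway_genes), set(self.offtarget_genes)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("planted gene sets must be disjoint")
        n_named = len(target) + len(self.pathway_genes) + len(self.offtarget_genes)
        if n_named > self.n_genes:
            raise ValueError("more planted genes than the gene universe")
        if self.target_gene is not None and abs(self.target_log2fc) <= 1.5:
            raise ValueError("planted target |log2fc| must exceed 1.5")


def _gene_universe(spec: DEPlantSpec) -> list[str]:
    named = [*([spec.target_gene] if spec.target_gene else []),
             *sorted(spec.pathway_genes), *sorted(spec.offtarget_genes)]
    n_null = spec.n_genes - len(named)
    return named + [f"G{i:04d}" for i in range(1, n_null + 1)]


def _null_table(genes: list[str], spec: DEPlantSpec,
                rng: np.random.Generator) -> pd.DataFrame:
    n = len(genes)
    df = pd.DataFrame({
        "gene": genes,
        "log2fc": rng.normal(0.0, spec.noise_sd, n),
        "pvalue": rng.uniform(0.0, 1.0, n),
    })
    # baseline expression for the TPM columns (log-normal, like bulk RNA-seq)
    df["tpm_control"] = rng.lognormal(mean=3.0, sigma=1.5, size=n)
    return df


def _plant(df: pd.DataFrame, genes: set[str], spec: DEPlantSpec,
           rng: np.random.Generator, fixed_lfc: dict[str, float] | None = None
           ) -> None:
    lo, hi = spec.planted_abs_log2fc
    for g in sorted(genes):
        if fixed_lfc and g in fixed_lfc:
            lfc = fixed_lfc[g]
        else:
            lfc = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        df.loc[df["gene"] == g, ["log2fc", "pvalue"]] = [lfc, spec.planted_pvalue]


def _finalise(df: pd.DataFrame) -> pd.DataFrame:
    df["padj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    df["tpm_treated"] = df["tpm_control"] * np.power(2.0, df["log2fc"])
    return df[["gene", "log2fc", "pvalue", "padj", "tpm_treated", "tpm_control"]]


def make_de_tables(spec: DEPlantSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(CRISPRi table, target-matched siRNA table) with planted structure.

    The on-target and pathway signals appear in both tables (pathway effects
    share sign and magnitude — they are knockdown consequences, not noise);
    the off-target-proximal signals appear only in the CRISPRi table.
    """
    genes = _gene_universe(spec)
    rng = np.random.default_rng(spec.rng_seed)

    crispri = _null_table(genes, spec, rng)
    sirna = _null_table(genes, spec, rng)

    # shared pathway effects: one draw, used in both tables
    lo, hi = spec.planted_abs_log2fc
    pathway_lfc = {
        g: float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
        for g in sorted(spec.pathway_genes)
    }
    if spec.target_gene is not None:
        _plant(crispri, {spec.target_gene}, spec, rng,
               {spec.target_gene: spec.target_log2fc})
        _plant(sirna, {spec.target_gene}, spec, rng,
               {spec.target_gene: 0.8 * spec.target_log2fc})
    _plant(crispri, set(spec.pathway_genes), spec, rng, pathway_lfc)
    _plant(sirna, set(spec.pathway_genes), spec, rng, pathway_lfc)
    _plant(crispri, set(spec.offtarget_genes), spec, rng)

    return _finalise(crispri), _finalise(sirna)


# --------------------------------------------------------------------------
# the standard synthetic study


@dataclass
class Study:
    """One analysis-ready synthetic study with its planted truth."""

    genome: Genome
    spacer: Spacer
    tss: list[TSSRecord]
    crispri_de: pd.DataFrame
    sirna_de: pd.DataFrame
    site_truth: pd.DataFrame
    truth: dict
    budget: FlawBudget = field(default_factory=FlawBudget)
    window: int = 500
    thresholds: Thresholds = field(default_factory=Thresholds)


#: flaw partitions planted on the off-target chromosome of the standard
#: study: the full in-budget grid plus three over-budget decoys
STUDY_PARTITIONS = [(0, 0), (0, 1), (1, 0), (1, 1), (0, 2), (2, 0),
                    (2, 1), (1, 2), (2, 2)]
STUDY_DECOYS = [(3, 0), (0, 3), (3, 2)]


def make_study(
    rng_seed: int = 0,
    chr1_length: int = 4000,
    chr2_length: int = 16000,
    n_genes: int = 1000,
    n_pathway: int = 2,
    n_offtarget: int = 1,
    tss_offset: int = 150,
) -> Study:
    """The standard synthetic study.

    chr1 carries the on-target site (exact protospacer match, intended TSS
    ``tss_offset`` bp away) and a handful of null neighbourhood genes; chr2
    carries twelve planted sites — the nine-partition in-budget grid and
    three over-budget decoys — with the pathway and off-target gene TSSs
    placed within 500 bp of distinct in-budget sites, plus non-proximal
    decoy genes and the 500/501 bp boundary pair.  DE tables plant the
    on-target signal and pathway co-regulation (shared with the siRNA
    table) and the off-target-proximal signals among ~``n_genes`` nulls.
    """
    rng = np.random.default_rng(rng_seed)
    spacer_seq = "".join(rng.choice(list("ACGT"), size=20))
    L = 20
    on_target_start = chr1_length // 2

    specs = [PlantSpec(spacer_seq, "chr1", on_target_start, "+", 0, 0)]
    partitions = STUDY_PARTITIONS + STUDY_DECOYS
    spacing = (chr2_length - 400) // len(partitions)
    chr2_starts = [200 + k * spacing for k in range(len(partitions))]
    for k, ((sf, nf), start) in enumerate(zip(partitions, chr2_starts)):
        specs.append(PlantSpec(spacer_seq, "chr2", start,
                               "+" if k % 2 == 0 else "-", sf, nf))

    genome, site_truth = make_planted_genome(
        {"chr1": chr1_length, "chr2": chr2_length}, specs,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )

    target_gene = "TARGET01"
    pathway = [f"PATH{i}" for i in range(1, n_pathway + 1)]
    offtarget = [f"OFFT{i}" for i in range(1, n_offtarget + 1)]
    spacer = Spacer(
        guide_id="sg1", sequence=spacer_seq, intended_gene=target_gene,
        intended_tss=("chr1", on_target_start + tss_offset),
    )

    # TSSs: planted proximal genes sit `tss_offset` bp 3' of distinct
    # in-budget chr2 sites; decoys sit well outside the 500 bp window;
    # G0001/G0002 probe the inclusive boundary (500 in, 501 out)
    in_budget_idx = [k for k, p in enumerate(partitions) if p not in STUDY_DECOYS]
    placements = [(target_gene, "chr1", on_target_start + tss_offset, "+")]
    proximal_sites = in_budget_idx[1 : 1 + len(pathway) + len(offtarget)]
    for gene, k in zip(pathway + offtarget, proximal_sites):
        placements.append((gene, "chr2", chr2_starts[k] + L - 1 + tss_offset, "+"))
    boundary_site = chr2_starts[in_budget_idx[-1]]
    placements.append(("G0001", "chr2", boundary_site + L - 1 + 500, "+"))
    placements.append(("G0002", "chr2", boundary_site + L - 1 + 501, "-"))
    # non-proximal decoys and chr1 neighbourhood nulls
    placements.append(("G0003", "chr2", chr2_starts[in_budget_idx[0]] + 700, "+"))
    for i, dist in enumerate((600, 1500), start=4):
        placements.append((f"G{i:04d}", "chr1", on_target_start + dist, "+"))
    tss = make_tss_table(placements, genome)

    de_spec = DEPlantSpec(
        n_genes=n_genes, target_gene=target_gene,
        pathway_genes=frozenset(pathway), offtarget_genes=frozenset(offtarget),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
    crispri_de, sirna_de = make_de_tables(de_spec)

    truth = {
        "target_gene": target_gene,
        "pathway_attributed": sorted(pathway),
        "possible_offtarget": sorted(offtarget),
        "proximal_genes": sorted(pathway + offtarget + ["G0001"]),
        "neighborhood_flagged": [],
        "n_planted_in_budget": int(site_truth["in_budget"].sum()),
        "n_planted_decoys": int((~site_truth["in_budget"]).sum()),
    }
    return Study(genome=genome, spacer=spacer, tss=tss,
                 crispri_de=crispri_de, sirna_de=sirna_de,
                 site_truth=site_truth, truth=truth)


def write_fixtures(study: Study, out_dir: str | Path) -> None:
    """Write a study to disk as plain-text fixtures."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_genome_fasta(study.genome, out / "genome.fa")
    _io.write_tss_bed(study.tss, out / "tss.bed")
    _io.write_spacers([study.spacer], out / "guides.tsv")
    study.crispri_de.to_csv(out / "de.tsv", sep="\t", index=False)
    study.sirna_de.to_csv(out / "sirna_de.tsv", sep="\t", index=False)
    study.site_truth.to_csv(out / "site_truth.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(study.truth, indent=2))
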