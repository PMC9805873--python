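"""Plain-text readers and writers for the pipeline's tabular formats.

Genomes travel as FASTA (Biopython), sites and DE results as
tab-separated tables, TSS annotations as BED6 (name = gene) or a
four-column TSV, in keeping with the rest of the genomics toolchain.
Coordinates are 0-based half-open on disk (BED convention).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import Genome, OffTargetSite, ProximalHit, Spacer, TSSRecord

SITE_COLUMNS = ["guide_id", "chrom", "start", "end", "strand", "seed_flaws",
                "nonseed_flaws", "total_flaws", "pam", "is_on_target"]


def read_genome_fasta(path: str | Path) -> Genome:
    records = SeqIO.parse(str(path), "fasta")
    return Genome({rec.id: str(rec.seq) for rec in records})


def write_genome_fasta(genome: Genome, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_spacers(path: str | Path) -> list[Spacer]:
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str})
    spacers = []
    for row in df.itertuples():
        tss = None
        chrom = getattr(row, "intended_chrom", None)
        pos = getattr(row, "intended_tss_pos", None)
        if isinstance(chrom, str) and pd.notna(pos):
            tss = (chrom, int(pos))
        gene = getattr(row, "intended_gene", "")
        spacers.append(Spacer(
            guide_id=row.guide_id, sequence=row.sequence,
            intended_gene="" if pd.isna(gene) else str(gene),
            intended_tss=tss,
        ))
    return spacers


def write_spacers(spacers: list[Spacer], path: str | Path) -> None:
    rows = []
    for sp in spacers:
        chrom, pos = sp.intended_tss if sp.intended_tss else ("", "")
        rows.append({"guide_id": sp.guide_id, "sequence": sp.sequence,
                     "intended_gene": sp.intended_gene,
                     "intended_chrom": chrom, "intended_tss_pos": pos})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def sites_to_frame(sites: list[OffTargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"guide_id": s.guide_id, "chrom": s.chromosome, "start": s.start,
          "end": s.end, "strand": s.strand, "seed_flaws": s.seed_flaws,
          "nonseed_flaws": s.nonseed_flaws, "total_flaws": s.total_flaws,
          "pam": s.pam_sequence, "is_on_target": s.is_on_target}
         for s in sites],
        columns=SITE_COLUMNS,
    )


def write_sites_tsv(sites: list[OffTargetSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[OffTargetSite]:
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "chrom": str})
    return [
        OffTargetSite(
            chromosome=r.chrom, start=int(r.start), strand=r.strand,
            guide_id=r.guide_id, end=int(r.end),
            seed_flaws=int(r.seed_flaws), nonseed_flaws=int(r.nonseed_flaws),
            total_flaws=int(r.total_flaws), pam_sequence=str(r.pam),
            is_on_target=bool(r.is_on_target),
        )
        for r in df.itertuples()
    ]


def write_sites_bed(sites: list[OffTargetSite], path: str | Path) -> None:
    """BED6: name = guide id, score = total flaws."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chromosome}\t{s.start}\t{s.end}\t{s.guide_id}"
                     f"\t{s.total_flaws}\t{s.strand}\n")


def read_tss(path: str | Path) -> list[TSSRecord]:
    """TSS table from BED6 (name = gene; TSS = interval start) or a
    headered TSV with columns gene, chrom, pos, strand."""
    first = Path(path).read_text().splitlines()[0].split("\t")
    if first[:2] == ["gene", "chrom"]:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return [TSSRecord(r.gene, r.chrom, int(r.pos), r.strand)
                for r in df.itertuples()]
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return [TSSRecord(r.name, str(r.chrom), int(r.start), r.strand)
            for r in df.itertuples()]


def write_tss_bed(tss: list[TSSRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in tss:
            fh.write(f"{r.chromosome}\t{r.position}\t{r.position + 1}"
                     f"\t{r.gene}\t0\t{r.strand}\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table {path} missing columns {sorted(missing)}")
    return df


def hits_to_frame(hits: list[ProximalHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": h.gene, "guide_id": h.guide_id, "chrom": h.site.chromosome,
          "site_start": h.site.start, "site_end": h.site.end,
          "strand": h.site.strand, "distance": h.distance}
         for h in hits],
        columns=["gene", "guide_id", "chrom", "site_start", "site_end",
                 "strand", "distance"],
    )


def read_cq_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "gene", "cq"} - set(df.columns)
    if missing:
        raise ValueError(f"Cq table {path} missing columns {sorted(missing)}")
    return df
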