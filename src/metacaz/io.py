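"""Readers and writers for the pipeline's on-disk table dialects.

Formats handled here: 12-column tabular alignment reports plus a taxon
column (gene hits), HMMER domtblout-style domain tables and a simplified
6-column TSV equivalent, EC-evidence TSVs, contig tables, peptide-model
TSVs and protein FASTA.  Lines starting with ``#`` are treated as
comments everywhere.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cazyme import DomainHit, ECEvidence, PeptideHit, PeptideModel
from .errors import DataError
from .taxonomy import GeneHit, contig_of_gene

HIT_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "staxid",
)


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, stripped


# -- gene hits (alignment dialect + taxon column) ----------------------------------------


def read_gene_hits(path: str | Path) -> list[GeneHit]:
    """Read a 13-column tab-separated hit table (12 alignment fields + taxon id)."""
    hits = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 13:
            raise DataError(f"{path}:{lineno}: expected 13 columns, got {len(fields)}")
        try:
            hits.append(
                GeneHit(
                    gene_id=fields[0],
                    contig_id=contig_of_gene(fields[0]),
                    subject_taxon=fields[12],
                    evalue=float(fields[10]),
                    percent_identity=float(fields[2]),
                    bit_score=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_gene_hits(hits: Iterable[GeneHit], path: str | Path, rng=None) -> None:
    """Write hits in the 13-column dialect (placeholder alignment coordinates)."""
    with open(path, "w") as fh:
        for h in hits:
            aln_len = 100
            fh.write(
                "\t".join(
                    [
                        h.gene_id, f"subj_{h.subject_taxon}", f"{h.percent_identity:.1f}",
                        str(aln_len), "0", "0", "1", str(aln_len), "1", str(aln_len),
                        f"{h.evalue:.3g}", f"{h.bit_score:.1f}", h.subject_taxon,
                    ]
                )
                + "\n"
            )


# -- domain hits -------------------------------------------------------------------------


def read_domain_tsv(path: str | Path) -> list[DomainHit]:
    """Read the simplified 6-column domain table (gene, family, start, end, plen, evalue)."""
    hits = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 6:
            raise DataError(f"{path}:{lineno}: expected 6 columns, got {len(f)}")
        try:
            hits.append(
                DomainHit(
                    gene_id=f[0], family=f[1], align_start=int(f[2]), align_end=int(f[3]),
                    profile_length=int(f[4]), evalue=float(f[5]),
                )
            )
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domain_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tfamily\talign_start\talign_end\tprofile_length\tevalue\n")
        for h in hits:
            fh.write(
                f"{h.gene_id}\t{h.family}\t{h.align_start}\t{h.align_end}"
                f"\t{h.profile_length}\t{h.evalue:.3g}\n"
            )


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Read a HMMER per-domain table (hmmscan layout, whitespace-delimited).

    Target = profile (a trailing ``.hmm`` suffix is stripped to give the
    family label), query = gene, column 3 = profile length, column 13 =
    independent per-domain E-value, columns 18-19 = alignment coordinates
    on the protein.
    """
    hits = []
    for lineno, line in _data_lines(path):
        f = line.split()
        if len(f) < 22:
            raise DataError(f"{path}:{lineno}: expected >=22 domtblout columns")
        family = f[0].removesuffix(".hmm")
        try:
            hits.append(
                DomainHit(
                    gene_id=f[3], family=family, profile_length=int(f[2]),
                    evalue=float(f[12]), align_start=int(f[17]), align_end=int(f[18]),
                )
            )
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write domain hits in the hmmscan per-domain layout (placeholder scores)."""
    with open(path, "w") as fh:
        fh.write("# target name accession tlen query name accession qlen ...\n")
        for h in hits:
            f = [
                f"{h.family}.hmm", "-", str(h.profile_length), h.gene_id, "-", "500",
                f"{h.evalue:.3g}", "100.0", "0.1", "1", "1",
                f"{h.evalue:.3g}", f"{h.evalue:.3g}", "100.0", "0.1",
                "1", str(h.profile_length),
                str(h.align_start), str(h.align_end),
                str(h.align_start), str(h.align_end), "0.95", "-",
            ]
            fh.write(" ".join(f) + "\n")


# -- peptide hits & models ---------------------------------------------------------------


def read_peptide_hits(path: str | Path) -> list[PeptideHit]:
    hits = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 4:
            raise DataError(f"{path}:{lineno}: expected 4 columns")
        hits.append(
            PeptideHit(gene_id=f[0], family=f[1], n_matched=int(f[2]), score=float(f[3]))
        )
    return hits


def write_peptide_hits(hits: Iterable[PeptideHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tfamily\tn_matched\tscore\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.family}\t{h.n_matched}\t{h.score:g}\n")


def read_peptide_models(path: str | Path) -> list[PeptideModel]:
    rows: dict[str, dict[str, int]] = {}
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 3:
            raise DataError(f"{path}:{lineno}: expected 3 columns")
        rows.setdefault(f[0], {})[f[1]] = int(f[2])
    return [
        PeptideModel(family=fam, k=len(next(iter(peps))), peptides=peps)
        for fam, peps in sorted(rows.items())
    ]


def write_peptide_models(models: Iterable[PeptideModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# family\tpeptide\tcount\n")
        for m in models:
            for pep, count in sorted(m.peptides.items()):
                fh.write(f"{m.family}\t{pep}\t{count}\n")


# -- EC evidence -------------------------------------------------------------------------


def read_ec_evidence(path: str | Path) -> list[ECEvidence]:
    records = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 3:
            raise DataError(f"{path}:{lineno}: expected 3 columns")
        try:
            records.append(ECEvidence(gene_id=f[0], channel=f[1], ec=f[2]))
        except DataError as exc:
            raise DataError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_ec_evidence(records: Iterable[ECEvidence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tchannel\tec\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.channel}\t{r.ec}\n")


# -- contig tables & profiles ------------------------------------------------------------


def read_contig_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"contig_id", "length_bp", "mapped_reads"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: contig table must carry columns {sorted(required)}")
    return df


def write_contig_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_profile_tsv(
    frame: pd.DataFrame | pd.Series, path: str | Path, provenance: str | None = None
) -> None:
    """Write a profile table with an optional leading provenance comment line."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        frame.to_csv(fh, sep="\t")


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


# -- FASTA -------------------------------------------------------------------------------


def read_proteins(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_proteins(proteins: dict[str, str] | Sequence[tuple[str, str]], path: str | Path) -> None:
    items = proteins.items() if isinstance(proteins, dict) else proteins
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(records, str(path), "fasta")
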