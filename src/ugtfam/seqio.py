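"""Domain types and readers/writers for the standard formats the pipeline touches.

All genomic coordinates are 0-based half-open internally.  GFF3 (1-based
inclusive) and BED (0-based half-open) are converted at the boundary, so the
rest of the package never sees a dialect-specific coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET_X = AA_ALPHABET | {"X"}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; ``species`` is an optional provenance tag."""

    id: str
    sequence: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET_X
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class GeneLocus:
    """Genomic span of a gene (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")


@dataclass
class GeneModel:
    """Coding-exon structure of one gene on a chromosome.

    ``exons`` are (start, end) intervals in genomic coordinates, ordered in
    transcription order (descending genomic coordinate on the minus strand).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    protein_id: str | None = None
    length_flag_ok: bool = True  # False when CDS length is not divisible by 3

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon ({s},{e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def locus(self) -> GeneLocus:
        start = min(s for s, _ in self.exons)
        end = max(e for _, e in self.exons)
        return GeneLocus(self.gene_id, self.chrom, start, end)

    def check_protein_length(self, protein_len: int) -> bool:
        """Exon total consistent with the linked protein.

        Accepts both annotation layouts: CDS covering exactly the coding
        residues, or CDS including a trailing stop codon (3 bp extra).
        """
        total = self.coding_length
        return total in (protein_len * 3, protein_len * 3 + 3)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[ProteinRecord]:
    """Read protein (or CDS) records; uppercases; rejects duplicate ids."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        species = None
        if "species=" in rec.description:
            species = rec.description.split("species=")[1].split()[0]
        records.append(ProteinRecord(rec.id, seq, species))
    return records


def read_cds_fasta(path) -> dict[str, str]:
    """Nucleotide FASTA as an id -> sequence mapping (uppercased)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate record id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records, path) -> None:
    """Write records in input order; bit-stable for fixed input order."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, ProteinRecord):
                desc = f" species={rec.species}" if rec.species else ""
                fh.write(f">{rec.id}{desc}\n")
                seq = rec.sequence
            else:  # (id, seq) pair
                fh.write(f">{rec[0]}\n")
                seq = rec[1]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models

def read_gff3_gene_models(path) -> list[GeneModel]:
    """Group CDS features per mRNA into GeneModels.

    GFF3 1-based inclusive coordinates become 0-based half-open.  Minus-strand
    exons are re-ordered 5'->3' of the transcript.  A model whose coding
    length is not divisible by 3 is kept but flagged (``length_flag_ok``).
    """
    mrna_parent: dict[str, str] = {}
    mrna_strand: dict[str, str] = {}
    mrna_chrom: dict[str, str] = {}
    cds_by_mrna: dict[str, list[tuple[int, int]]] = {}
    mrna_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            attr = _parse_attrs(attrs)
            if ftype == "mRNA":
                mid = attr.get("ID")
                if mid is None:
                    raise ParseError(f"{path}:{lineno}: mRNA without ID")
                mrna_parent[mid] = attr.get("Parent", mid)
                mrna_strand[mid] = strand
                mrna_chrom[mid] = chrom
                mrna_order.append(mid)
            elif ftype == "CDS":
                parent = attr.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}:{lineno}: CDS without Parent")
                # GFF3 1-based inclusive -> 0-based half-open
                cds_by_mrna.setdefault(parent, []).append((start_i - 1, end_i))

    models: list[GeneModel] = []
    for mid in mrna_order:
        exons = cds_by_mrna.get(mid)
        if not exons:
            continue
        strand = mrna_strand[mid]
        exons = sorted(exons)
        if strand == "-":
            exons = exons[::-1]
        gene_id = mrna_parent[mid]
        model = GeneModel(
            gene_id=gene_id,
            chrom=mrna_chrom[mid],
            strand=strand,
            exons=exons,
            protein_id=mid,
            length_flag_ok=True,
        )
        if model.coding_length % 3 != 0:
            model.length_flag_ok = False
        models.append(model)
    orphans = set(cds_by_mrna) - set(mrna_order)
    if orphans:
        raise ParseError(f"{path}: CDS with missing parent mRNA: {sorted(orphans)}")
    return models


def _parse_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def write_gff3_gene_models(models: list[GeneModel], path) -> None:
    """Emit gene/mRNA/CDS features, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            loc = m.locus
            fh.write(
                f"{m.chrom}\tugtfam\tgene\t{loc.start + 1}\t{loc.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            mid = m.protein_id or f"{m.gene_id}.1"
            fh.write(
                f"{m.chrom}\tugtfam\tmRNA\t{loc.start + 1}\t{loc.end}\t.\t"
                f"{m.strand}\t.\tID={mid};Parent={m.gene_id}\n"
            )
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.chrom}\tugtfam\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={mid}.cds;Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# BED loci

def read_bed_loci(path) -> list[GeneLocus]:
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(f"{path}:{lineno}: BED needs chrom,start,end,name")
            loci.append(GeneLocus(cols[3], cols[0], int(cols[1]), int(cols[2])))
    return loci


def write_bed_loci(loci: list[GeneLocus], path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.gene_id}\n")


# ---------------------------------------------------------------------------
# Expression matrices

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a sample -> condition map.

    ``unit`` is one of 'counts', 'tpm', 'intensity'.  TPM matrices satisfy
    column sums of 1e6 (within floating tolerance).
    """

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    condition_map: dict[str, str]
    unit: str = "counts"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.condition_map)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if self.unit == "tpm":
            sums = self.values.sum(axis=0).to_numpy(dtype=float)
            if not np.allclose(sums, 1e6, rtol=1e-6):
                raise ValueError("TPM columns must each sum to 1e6")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_map[s] == condition]

    def condition_means(self, condition: str) -> pd.Series:
        cols = self.samples_for(condition)
        if not cols:
            raise ValueError(f"no samples for condition {condition!r}")
        return self.values[cols].mean(axis=1)


def read_expression_tsv(values_path, condition_path, unit: str = "counts") -> ExpressionMatrix:
    """Matrix TSV (first column gene id) plus a two-column sample/condition TSV."""
    df = pd.read_csv(values_path, sep="\t", index_col=0)
    cond = pd.read_csv(condition_path, sep="\t", index_col=0).iloc[:, 0].to_dict()
    return ExpressionMatrix(df.astype(float), {str(k): str(v) for k, v in cond.items()}, unit)


def write_expression_tsv(m: ExpressionMatrix, values_path, condition_path=None) -> None:
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(values_path, sep="\t", float_format="%.6g")
    if condition_path is not None:
        with open(condition_path, "w") as fh:
            fh.write("sample_id\tcondition\n")
            for s in m.sample_ids:
                fh.write(f"{s}\t{m.condition_map[s]}\n")


def compute_tpm(counts: ExpressionMatrix, lengths: dict[str, int]) -> ExpressionMatrix:
    """Length- and depth-normalize raw counts to TPM.

    Per sample: rate_g = count_g / length_g; TPM_g = rate_g / sum(rate) * 1e6.
    Gene length is the summed CDS length in bp.
    """
    if counts.unit != "counts":
        raise ValueError("compute_tpm expects a counts matrix")
    lens = pd.Series({g: lengths[g] for g in counts.gene_ids}, dtype=float)
    if (lens <= 0).any():
        raise ValueError("all gene lengths must be > 0")
    rates = counts.values.div(lens, axis=0)
    totals = rates.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero total rate in column(s): {bad}")
    tpm = rates.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm, dict(counts.condition_map), unit="tpm")


# ---------------------------------------------------------------------------
# Reference anchors

GROUP_LABELS = tuple("ABCDEFGHIJKLMNOP")


@dataclass
class ReferenceAnchorSet:
    """Reference proteins with their phylogenetic group labels (A-P)."""

    records: list[ProteinRecord]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        for aid, grp in self.group_of.items():
            if grp not in GROUP_LABELS:
                raise ValueError(f"group label {grp!r} not in A..P")
            if aid not in ids:
                raise ValueError(f"anchor {aid!r} has no sequence record")
        unlabeled = ids - set(self.group_of)
        if unlabeled:
            raise ValueError(f"anchors without group label: {sorted(unlabeled)}")


def read_anchor_set(fasta_path, map_path) -> ReferenceAnchorSet:
    records = read_fasta(fasta_path)
    mapping = pd.read_csv(map_path, sep="\t", index_col=0).iloc[:, 0].to_dict()
    return ReferenceAnchorSet(records, {str(k): str(v) for k, v in mapping.items()})


def write_anchor_map(group_of: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("anchor_id\tgroup\n")
        for aid in sorted(group_of):
            fh.write(f"{aid}\t{group_of[aid]}\n")
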