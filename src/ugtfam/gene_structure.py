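"""Intron architecture: counts, sizes, phases; projection of intron positions
onto protein-alignment columns; conserved insertion-event calling.

Intron phase is the number of coding nucleotides 5' of the intron modulo 3
(phase 0 = between codons).  ``protein_pos`` is the 0-based index of the codon
containing the first coding base after the intron; for a phase-0 intron that
is the codon immediately following the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

from .phylo import GAP_CHARS, Alignment
from .seqio import GeneModel


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    index: int  # 1-based ordinal in transcript order
    length_bp: int
    phase: int  # 0, 1, 2
    protein_pos: int  # codon index interrupted / immediately following


def extract_introns(model: GeneModel) -> list[IntronRecord]:
    """Introns between consecutive coding exons, in transcript order.

    Phase comes from the cumulative coding length upstream of each junction;
    intron length is the genomic gap between the flanking exons.
    """
    records: list[IntronRecord] = []
    cumulative = 0
    for idx, ((s1, e1), (s2, e2)) in enumerate(zip(model.exons, model.exons[1:]), start=1):
        cumulative += e1 - s1
        if model.strand == "+":
            length = s2 - e1
        else:
            length = s1 - e2
        if length < 1:
            raise ValueError(f"{model.gene_id}: non-positive intron between exons {idx},{idx + 1}")
        records.append(
            IntronRecord(
                gene_id=model.gene_id,
                index=idx,
                length_bp=length,
                phase=cumulative % 3,
                protein_pos=cumulative // 3,
            )
        )
    return records


@dataclass(frozen=True)
class IntronMark:
    """An intron projected into alignment space."""

    gene_id: str
    column: int  # 0-based alignment column
    phase: int


def map_introns_to_alignment(
    introns: dict[str, list[IntronRecord]], aln: Alignment
) -> list[IntronMark]:
    """Convert each intron's protein position to an alignment column by
    walking the gene's gapped row and skipping gap columns."""
    row_of = dict(zip(aln.ids, aln.rows))
    marks: list[IntronMark] = []
    for gene_id in sorted(introns):
        if gene_id not in row_of:
            raise KeyError(f"gene {gene_id!r} absent from alignment")
        row = row_of[gene_id]
        residue_cols = [i for i, ch in enumerate(row) if ch not in GAP_CHARS]
        for intron in introns[gene_id]:
            if intron.protein_pos >= len(residue_cols):
                raise ValueError(
                    f"{gene_id}: intron protein_pos {intron.protein_pos} beyond "
                    f"row of {len(residue_cols)} residues"
                )
            marks.append(
                IntronMark(gene_id, residue_cols[intron.protein_pos], intron.phase)
            )
    return marks


@dataclass
class InsertionEvent:
    event_id: str  # "I-1", "I-2", ... in column order
    column: int  # membership-weighted median column
    phase: int
    member_genes: list[str]


def call_insertion_events(
    marks: list[IntronMark], column_tolerance: int = 0
) -> list[InsertionEvent]:
    """Cluster intron marks into shared insertion events.

    Marks with identical phase whose columns lie within ``column_tolerance``
    of the previous mark (single linkage along the column axis) form one
    event.  Events are serially numbered I-1, I-2, ... left to right; each is
    reported at the median column of its member marks.  Independent of gene
    input order.
    """
    events: list[InsertionEvent] = []
    by_phase: dict[int, list[IntronMark]] = {}
    for mark in marks:
        by_phase.setdefault(mark.phase, []).append(mark)
    clusters: list[list[IntronMark]] = []
    for phase in sorted(by_phase):
        ms = sorted(by_phase[phase], key=lambda m: (m.column, m.gene_id))
        group = [ms[0]]
        for m in ms[1:]:
            if m.column - group[-1].column <= column_tolerance:
                group.append(m)
            else:
                clusters.append(group)
                group = [m]
        clusters.append(group)
    # serial numbering by representative column, left to right
    def median_column(group: list[IntronMark]) -> int:
        cols = sorted(m.column for m in group)
        return cols[(len(cols) - 1) // 2]

    clusters.sort(key=lambda g: (median_column(g), g[0].phase))
    for i, group in enumerate(clusters, start=1):
        events.append(
            InsertionEvent(
                event_id=f"I-{i}",
                column=median_column(group),
                phase=group[0].phase,
                member_genes=sorted(m.gene_id for m in group),
            )
        )
    return events


def structure_summary(models: list[GeneModel]) -> dict:
    """Family-level intron architecture summary.

    Returns intron-count histogram (keys 0..3 and '4+'), phase histogram,
    and the min/max intron length.
    """
    count_hist: dict[str, int] = {"0": 0, "1": 0, "2": 0, "3": 0, "4+": 0}
    phase_hist = {0: 0, 1: 0, 2: 0}
    lengths: list[int] = []
    for model in models:
        introns = extract_introns(model)
        n = len(introns)
        key = str(n) if n < 4 else "4+"
        count_hist[key] += 1
        for intron in introns:
            phase_hist[intron.phase] += 1
            lengths.append(intron.length_bp)
    return {
        "intron_count_hist": count_hist,
        "phase_hist": phase_hist,
        "min_intron_bp": min(lengths) if lengths else None,
        "max_intron_bp": max(lengths) if lengths else None,
        "n_genes": len(models),
        "n_introns": sum(phase_hist.values()),
    }


def write_introns_tsv(
    introns: dict[str, list[IntronRecord]],
    path,
    marks: list[IntronMark] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tindex\tlength_bp\tphase\tprotein_pos\tcolumn\n")
        for gene_id in sorted(introns):
            gene_marks = sorted(
                (m for m in (marks or []) if m.gene_id == gene_id),
                key=lambda m: m.column,
            )
            for i, rec in enumerate(introns[gene_id]):
                col = str(gene_marks[i].column) if i < len(gene_marks) else ""
                fh.write(
                    f"{rec.gene_id}\t{rec.index}\t{rec.length_bp}\t{rec.phase}\t"
                    f"{rec.protein_pos}\t{col}\n"
                )


def write_events_tsv(events: list[InsertionEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tcolumn\tphase\tn_members\tmembers\n")
        for e in events:
            fh.write(
                f"{e.event_id}\t{e.column}\t{e.phase}\t{len(e.member_genes)}\t"
                f"{','.join(e.member_genes)}\n"
            )
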