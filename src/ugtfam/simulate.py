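"""Synthetic-data generation with recorded ground truth.

Every pipeline stage can be exercised without external downloads: the
generators emit proteomes with planted PSPG motifs, sequence families evolved
down a known tree with one labeled reference anchor per group, duplicated
coding-sequence pairs diverged to target synonymous distances under a strict
clock, gene models with planned intron phases and shared insertion columns,
and two-condition count matrices with planted regulation labels.

The default scenario mirrors the shape of a plant UGT family study at desk
scale: 16 phylogenetic groups (A-P), chromosomal clusters of 2-15 members,
an intron-count plan of 83:92:12:1:3 genes with 0-4 introns, and an
expression plan in which 152 of 200 genes pass the 1-TPM retention filter and
42 are up- and 42 down-regulated under stress.  All randomness flows through
``numpy.random.default_rng([seed, stage])`` so that (config, seed) determines
every output byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import duplication as dup
from . import motif as motif_mod
from .gene_structure import extract_introns
from .phylo import Alignment, write_alignment_fasta
from .seqio import (
    ExpressionMatrix,
    GeneLocus,
    GeneModel,
    ProteinRecord,
    ReferenceAnchorSet,
    write_anchor_map,
    write_bed_loci,
    write_expression_tsv,
    write_fasta,
    write_gff3_gene_models,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: codons whose third position is 4-fold degenerate and whose first/second
#: position changes are always nonsynonymous; mutating third positions of
#: these gives exactly one synonymous site per codon under NG86.
FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "TC")
GROUPS16 = tuple("ABCDEFGHIJKLMNOP")


@dataclass
class ScenarioConfig:
    """Knobs of the default synthetic study.

    Counts and rates are chosen to mirror the structure of a UGT-family
    analysis at desk scale; see the methods note for the reasoning.
    """

    # proteome / motif scan
    n_genes: int = 200
    motif_rate: float = 0.955  # fraction of proteins carrying a planted PSPG box
    protein_len_range: tuple[int, int] = (420, 520)

    # family tree / groups
    n_groups: int = 16
    n_queries: int = 50
    alignment_length: int = 300
    between_group_branch: float = 0.30  # expected substitutions/site
    within_group_branch: float = 0.02

    # duplication / dating
    ks_targets: tuple[float, ...] = (0.1, 0.5, 1.0)
    n_codons: int = 300
    pairs_per_target: int = 5
    cluster_sizes: tuple[int, ...] = tuple(range(2, 16))  # 2..15 per chromosome
    cluster_spacing: int = 100_000  # bp between clustered starts (< window)
    cluster_window: int = 200_000
    gene_span: int = 2_000

    # gene structure
    intron_count_plan: tuple[tuple[int, int], ...] = ((0, 83), (1, 92), (2, 12), (3, 1), (4, 3))
    shared_event_residue: int = 160
    shared_event_phase: int = 1
    shared_event_members: int = 35
    minor_event_residue: int = 300
    minor_event_phase: int = 0
    minor_event_members: int = 3
    struct_protein_len: int = 450
    intron_len_range: tuple[int, int] = (80, 2_000)

    # expression
    n_retained: int = 152
    n_up: int = 42
    n_down: int = 42
    n_replicates: int = 3
    baseline_tpm_range: tuple[float, float] = (20.0, 300.0)
    regulated_fold: float = 4.0
    violator_tpm: float = 0.02
    nb_dispersion: float = 0.01
    depth_scale: float = 0.02  # reads per (relative TPM unit * bp); sets depth
    cds_len_range: tuple[int, int] = (900, 1_800)

    def validate(self) -> None:
        if not 0 <= self.motif_rate <= 1:
            raise ValueError("motif_rate must be in [0,1]")
        if self.n_groups < 1 or self.n_groups > 16:
            raise ValueError("n_groups must be in 1..16")
        if self.n_retained > self.n_genes:
            raise ValueError("n_retained exceeds n_genes")
        if self.n_up + self.n_down > self.n_retained:
            raise ValueError("regulated genes exceed retained genes")
        if self.cluster_spacing <= 0 or self.cluster_window <= 0:
            raise ValueError("spacings must be > 0")


# ---------------------------------------------------------------------------
# helpers

def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stage)])


def sample_pattern_instance(pattern: motif_mod.PrositePattern, rng: np.random.Generator) -> str:
    """One string drawn uniformly from the pattern's language."""
    out = []
    for elem in pattern.elements:
        count = int(rng.integers(elem.min_repeat, elem.max_repeat + 1))
        pool = AA20 if elem.residues is None else "".join(sorted(elem.residues))
        out.extend(pool[int(rng.integers(len(pool)))] for _ in range(count))
    return "".join(out)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


# ---------------------------------------------------------------------------
# proteome with planted motifs

def generate_proteome(
    cfg: ScenarioConfig, seed: int
) -> tuple[list[ProteinRecord], dict]:
    """Random proteins, a fraction carrying one planted PSPG instance.

    Instances sit at a C-terminal-biased offset; negatives are verified
    motif-free by the scanner itself (re-sampled on the astronomically rare
    accidental hit), so the recorded truth is exact.
    """
    rng = _rng(seed, 1)
    pattern = motif_mod.parse_pattern(motif_mod.PSPG_PATTERN)
    n_pos = int(round(cfg.motif_rate * cfg.n_genes))
    records: list[ProteinRecord] = []
    planted: dict[str, list[tuple[int, int]]] = {}
    lo, hi = cfg.protein_len_range
    for i in range(cfg.n_genes):
        gid = f"UGTsim{i + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        if i < n_pos:
            while True:
                seq = _random_protein(rng, length)
                inst = sample_pattern_instance(pattern, rng)
                tail = int(rng.integers(5, 31))
                start = max(0, length - len(inst) - tail)
                seq = seq[:start] + inst + seq[start + len(inst) :]
                hits = motif_mod.scan(pattern, sequence=seq, protein_id=gid)
                box = max(hits, key=lambda m: m.start) if hits else None
                if box and box.start == start and box.end == start + len(inst):
                    planted[gid] = [(start, start + len(inst))]
                    break
        else:
            while True:
                seq = _random_protein(rng, length)
                if not motif_mod.scan(pattern, sequence=seq, protein_id=gid):
                    break
        records.append(ProteinRecord(gid, seq))
    truth = {"planted_motifs": {g: [list(s) for s in spans] for g, spans in planted.items()}}
    return records, truth


# ---------------------------------------------------------------------------
# family tree with anchored groups

def _random_binary_topology(labels: list[str], rng: np.random.Generator):
    """Random rooted binary tree as nested tuples over ``labels``."""
    nodes: list = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


def _evolve(seq: str, branch: float, rng: np.random.Generator) -> str:
    """Per-site substitution with probability 1-exp(-branch); replacement is a
    uniform draw from the other 19 residues."""
    p = 1.0 - np.exp(-branch)
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hits:
        alt = AA20.replace(out[i], "")
        out[i] = alt[int(rng.integers(len(alt)))]
    return "".join(out)


def generate_family_tree(
    cfg: ScenarioConfig, seed: int
) -> tuple[Alignment, ReferenceAnchorSet, dict]:
    """Sequences evolved down a known two-level tree.

    The deep level is a random binary topology over the groups (long
    branches); inside each group sits one labeled anchor plus that group's
    queries (short branches).  Queries are dealt round-robin so every group
    has at least one.  The alignment is emitted gap-free.
    """
    rng = _rng(seed, 2)
    groups = list(GROUPS16[: cfg.n_groups])
    group_topo = _random_binary_topology(groups, rng)
    root_seq = _random_protein(rng, cfg.alignment_length)

    queries_of: dict[str, list[str]] = {g: [] for g in groups}
    species_of: dict[str, str] = {}
    for q in range(cfg.n_queries):
        g = groups[q % len(groups)]
        qid = f"Q{q + 1:03d}"
        queries_of[g].append(qid)
        species_of[qid] = "target"

    ids: list[str] = []
    rows: list[str] = []
    group_of: dict[str, str] = {}

    def walk(node, seq: str) -> None:
        if isinstance(node, tuple):
            for child in node:
                walk(child, _evolve(seq, cfg.between_group_branch, rng))
            return
        # a group tip: evolve the anchor and the group's queries from the
        # group ancestor along short within-group branches
        g = node
        anchor_id = f"ANCHOR_{g}"
        members = [anchor_id] + queries_of[g]
        for mid in members:
            tip = _evolve(seq, cfg.within_group_branch, rng)
            ids.append(mid)
            rows.append(tip)
        group_of[anchor_id] = g
        species_of[anchor_id] = "reference"
        for qid in queries_of[g]:
            group_of[qid] = g

    walk(group_topo, root_seq)
    aln = Alignment(ids, rows)

    def groups_in(node) -> list[str]:
        if isinstance(node, tuple):
            return [g for child in node for g in groups_in(child)]
        return [node]

    def members_of(gs: list[str]) -> list[str]:
        out = []
        for g in gs:
            out.append(f"ANCHOR_{g}")
            out.extend(queries_of[g])
        return sorted(out)

    # the two deepest splits of the true tree: the root bipartition and the
    # bipartition under the root's larger child
    deep_splits = []
    if isinstance(group_topo, tuple):
        left, right = group_topo
        deep_splits.append(members_of(groups_in(left)))
        bigger = left if len(groups_in(left)) >= len(groups_in(right)) else right
        if isinstance(bigger, tuple):
            deep_splits.append(members_of(groups_in(bigger[0])))
    anchor_records = [
        ProteinRecord(i, r) for i, r in zip(ids, rows) if i.startswith("ANCHOR_")
    ]
    anchors = ReferenceAnchorSet(
        anchor_records, {r.id: group_of[r.id] for r in anchor_records}
    )
    truth = {
        "group_of": {i: group_of[i] for i in ids},
        "species_of": species_of,
        "group_topology": repr(group_topo),
        "queries": sorted(q for g in groups for q in queries_of[g]),
        "deep_splits": deep_splits,
    }
    return aln, anchors, truth


# ---------------------------------------------------------------------------
# duplicated CDS pairs and chromosomal layout

def _random_fourfold_cds(rng: np.random.Generator, n_codons: int) -> str:
    prefixes = [FOURFOLD_PREFIXES[i] for i in rng.integers(0, len(FOURFOLD_PREFIXES), n_codons)]
    thirds = ["ACGT"[i] for i in rng.integers(0, 4, n_codons)]
    return "".join(p + t for p, t in zip(prefixes, thirds))


def ks_to_proportion(ks: float) -> float:
    """Invert the Jukes–Cantor correction: expected proportion of synonymous
    differences that realizes a target Ks."""
    return 0.75 * (1.0 - np.exp(-4.0 * ks / 3.0))


def generate_duplicates(cfg: ScenarioConfig, seed: int) -> dict:
    """Duplicate CDS pairs at target Ks values plus a clustered gene layout.

    Each pair starts as a shared ancestral CDS built from 4-fold degenerate
    codons (exactly one synonymous site per codon); one copy receives
    synonymous third-position changes in distinct codons until the realized
    proportion of synonymous differences matches the Jukes–Cantor inversion
    of the target Ks, so the planted divergence is tracked exactly and the
    expected Ka is 0.  Loci are laid out as one cluster per configured size
    (starts ``cluster_spacing`` apart, within the window) plus two distant
    singletons per chromosome; pair members sit on different chromosomes
    (segmental) except the first pair, which is placed adjacently (tandem).
    """
    rng = _rng(seed, 3)
    cds: dict[str, str] = {}
    pair_rows = []
    for t_idx, ks_target in enumerate(cfg.ks_targets):
        p = ks_to_proportion(ks_target)
        n_mut = int(round(p * cfg.n_codons))
        for rep in range(cfg.pairs_per_target):
            a_id = f"DUPA_t{t_idx}_r{rep}"
            b_id = f"DUPB_t{t_idx}_r{rep}"
            anc = _random_fourfold_cds(rng, cfg.n_codons)
            b = list(anc)
            codon_idx = rng.choice(cfg.n_codons, size=n_mut, replace=False)
            for c in codon_idx:
                pos = 3 * c + 2
                alt = "ACGT".replace(b[pos], "")
                b[pos] = alt[int(rng.integers(3))]
            cds[a_id] = anc
            cds[b_id] = "".join(b)
            expected_ks = dup.jukes_cantor(n_mut / cfg.n_codons)
            pair_rows.append(
                {
                    "gene_a": a_id,
                    "gene_b": b_id,
                    "ks_target": ks_target,
                    "n_synonymous_changes": n_mut,
                    "expected_ks_estimate": expected_ks,
                    "expected_age_mya": dup.date_duplication(expected_ks)
                    if expected_ks is not None
                    else None,
                }
            )

    # chromosomal layout: one cluster per size on its own chromosome
    loci: list[GeneLocus] = []
    true_clusters: list[list[str]] = []
    gene_no = 0
    for c_idx, size in enumerate(cfg.cluster_sizes):
        chrom = f"chr{c_idx + 1:02d}"
        members = []
        base = 1_000_000
        for k in range(size):
            gene_no += 1
            gid = f"LOC{gene_no:04d}"
            start = base + k * cfg.cluster_spacing
            loci.append(GeneLocus(gid, chrom, start, start + cfg.gene_span))
            members.append(gid)
        true_clusters.append(members)
        for far in range(2):  # distant singletons that must not join
            gene_no += 1
            gid = f"LOC{gene_no:04d}"
            start = 10_000_000 + far * 5_000_000
            loci.append(GeneLocus(gid, chrom, start, start + cfg.gene_span))

    # place duplicate pairs: first pair tandem (adjacent), rest segmental
    pair_loci: list[GeneLocus] = []
    for i, row in enumerate(pair_rows):
        if i == 0:
            chrom = "chrP1"
            pair_loci.append(GeneLocus(row["gene_a"], chrom, 500_000, 500_000 + cfg.gene_span))
            pair_loci.append(GeneLocus(row["gene_b"], chrom, 550_000, 550_000 + cfg.gene_span))
            row["true_dup_type"] = "tandem"
        else:
            pair_loci.append(
                GeneLocus(row["gene_a"], f"chrPa{i}", 500_000, 500_000 + cfg.gene_span)
            )
            pair_loci.append(
                GeneLocus(row["gene_b"], f"chrPb{i}", 500_000, 500_000 + cfg.gene_span)
            )
            row["true_dup_type"] = "segmental"

    return {
        "cds": cds,
        "loci": loci,
        "pair_loci": pair_loci,
        "pairs": pair_rows,
        "true_clusters": true_clusters,
    }


# ---------------------------------------------------------------------------
# gene models with planned introns

def generate_gene_models(cfg: ScenarioConfig, seed: int) -> tuple[list[GeneModel], dict]:
    """Gene models realizing the configured intron plan.

    All structure genes share one protein length, so the implied protein
    alignment is gap-free and alignment column equals residue index.  The
    conserved insertion event is planted at ``shared_event_residue`` with
    ``shared_event_phase`` in the first ``shared_event_members``
    intron-containing genes; a minor event is planted likewise.  Remaining
    intron positions are drawn at random residues/phases away from the event
    columns.  Phases are realized through the coding offset 3*residue+phase,
    and the generator re-derives every intron with the extraction code to
    guarantee plan consistency.
    """
    rng = _rng(seed, 4)
    plan: list[int] = []
    for n_introns, n_genes in cfg.intron_count_plan:
        plan.extend([n_introns] * n_genes)
    prot_len = cfg.struct_protein_len
    coding_len = 3 * prot_len

    shared_offset = 3 * cfg.shared_event_residue + cfg.shared_event_phase
    minor_offset = 3 * cfg.minor_event_residue + cfg.minor_event_phase
    if not (0 < shared_offset < coding_len and 0 < minor_offset < coding_len):
        raise ValueError("event residues fall outside the protein")

    # deal the shared events to the first intron-containing genes
    intron_gene_indices = [i for i, n in enumerate(plan) if n > 0]
    shared_members = intron_gene_indices[: cfg.shared_event_members]
    minor_members = intron_gene_indices[
        cfg.shared_event_members : cfg.shared_event_members + cfg.minor_event_members
    ]

    models: list[GeneModel] = []
    true_introns: dict[str, list[tuple[int, int]]] = {}
    lo, hi = cfg.intron_len_range
    for i, n_introns in enumerate(plan):
        gid = f"STR{i + 1:04d}"
        offsets: set[int] = set()
        if i in shared_members:
            offsets.add(shared_offset)
        if i in minor_members:
            offsets.add(minor_offset)
        while len(offsets) < n_introns:
            cand = int(rng.integers(3, coding_len - 3))
            # keep random introns off the planted event columns
            if cand // 3 in (cfg.shared_event_residue, cfg.minor_event_residue):
                continue
            offsets.add(cand)
        cut_points = sorted(offsets)
        strand = "+" if i % 2 == 0 else "-"
        chrom = f"chrS{(i % 10) + 1:02d}"
        intron_lengths = [int(rng.integers(lo, hi + 1)) for _ in cut_points]
        exon_coding = np.diff([0, *cut_points, coding_len])
        # genomic layout
        gstart = 10_000 + (i // 10) * 50_000
        exons: list[tuple[int, int]] = []
        pos = gstart
        for exon_len, intron_len in zip(exon_coding, [*intron_lengths, 0]):
            exons.append((pos, pos + int(exon_len)))
            pos += int(exon_len) + int(intron_len)
        if strand == "-":
            # mirror the layout so transcript order is descending genomic
            span_end = pos
            exons = [
                (gstart + (span_end - e), gstart + (span_end - s)) for s, e in exons
            ]
        model = GeneModel(gid, chrom, strand, exons, protein_id=f"{gid}.1")
        models.append(model)
        true_introns[gid] = [(off // 3, off % 3) for off in cut_points]
        # plan-consistency check via the extraction code itself
        got = [(r.protein_pos, r.phase) for r in extract_introns(model)]
        if got != true_introns[gid]:
            raise AssertionError(f"{gid}: generator produced inconsistent phases")

    truth = {
        "true_introns": {g: [list(t) for t in v] for g, v in true_introns.items()},
        "shared_event": {
            "residue": cfg.shared_event_residue,
            "phase": cfg.shared_event_phase,
            "members": [f"STR{i + 1:04d}" for i in shared_members],
        },
        "minor_event": {
            "residue": cfg.minor_event_residue,
            "phase": cfg.minor_event_phase,
            "members": [f"STR{i + 1:04d}" for i in minor_members],
        },
        "intron_count_plan": [list(t) for t in cfg.intron_count_plan],
    }
    return models, truth


def structure_alignment(cfg: ScenarioConfig, models: list[GeneModel], seed: int) -> Alignment:
    """Gap-free protein alignment for the structure genes (column = residue)."""
    rng = _rng(seed, 5)
    rows = [_random_protein(rng, cfg.struct_protein_len) for _ in models]
    return Alignment([m.gene_id for m in models], rows)


# ---------------------------------------------------------------------------
# expression counts

def generate_expression(
    cfg: ScenarioConfig, seed: int
) -> tuple[ExpressionMatrix, dict[str, int], dict]:
    """Two-condition negative-binomial count matrix with planted regulation.

    Genes are planned in relative-abundance space and converted to per-sample
    count means through each gene's CDS length, so the pipeline's own TPM
    computation recovers the plan.  TPM is compositional, so regulated genes
    are planned in up/down couples with mirrored abundances (up: x -> fold*x;
    down: fold*x -> x): the total abundance of each condition matches and the
    realized fold changes stay at ``regulated_fold`` instead of drifting with
    the normalization.  Retention violators are essentially silent
    (``violator_tpm`` relative units), as unexpressed genes are in real data.
    Counts are negative binomial with dispersion ``nb_dispersion``.
    """
    rng = _rng(seed, 6)
    n = cfg.n_genes
    genes = [f"EXP{i + 1:04d}" for i in range(n)]
    lengths = {
        g: int(rng.integers(cfg.cds_len_range[0] // 3, cfg.cds_len_range[1] // 3 + 1)) * 3
        for g in genes
    }

    labels: dict[str, str] = {}
    retained = genes[: cfg.n_retained]
    violators = genes[cfg.n_retained :]
    up = retained[: cfg.n_up]
    down = retained[cfg.n_up : cfg.n_up + cfg.n_down]
    for g in retained:
        labels[g] = "up" if g in set(up) else ("down" if g in set(down) else "unchanged")

    lo, hi = cfg.baseline_tpm_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    tpm_control = np.array(base)
    tpm_stress = np.array(base)
    idx = {g: i for i, g in enumerate(genes)}
    fold = cfg.regulated_fold
    for k, g in enumerate(up):
        x = base[idx[g]]
        tpm_control[idx[g]] = x
        tpm_stress[idx[g]] = fold * x
        if k < len(down):  # mirrored couple keeps condition totals equal
            h = down[k]
            tpm_control[idx[h]] = fold * x
            tpm_stress[idx[h]] = x
    for k, h in enumerate(down[len(up):], start=len(up)):
        tpm_control[idx[h]] = fold * base[idx[h]]
        tpm_stress[idx[h]] = base[idx[h]]
    for k, g in enumerate(violators):
        # a violator is silent (zero reads) in at least one condition: with a
        # few hundred genes sharing the TPM million, even one stray read puts
        # a gene far above the 1-TPM floor, exactly as in shallow libraries
        if k % 3 == 0:
            tpm_control[idx[g]] = tpm_stress[idx[g]] = 0.0
        elif k % 3 == 1:
            tpm_control[idx[g]] = 0.0
            tpm_stress[idx[g]] = cfg.violator_tpm + base[idx[g]]
        else:
            tpm_control[idx[g]] = cfg.violator_tpm + base[idx[g]]
            tpm_stress[idx[g]] = 0.0

    len_arr = np.array([lengths[g] for g in genes], dtype=float)
    scale = cfg.depth_scale
    disp = cfg.nb_dispersion
    samples: dict[str, np.ndarray] = {}
    cond_map: dict[str, str] = {}
    for cond, tpm_plan in (("control", tpm_control), ("drought", tpm_stress)):
        mu = tpm_plan * len_arr * scale
        for r in range(cfg.n_replicates):
            sample = f"{cond}_{r + 1}"
            # NB via gamma-Poisson mixture: var = mu + disp*mu^2
            lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
            counts = rng.poisson(lam)
            samples[sample] = counts
            cond_map[sample] = cond

    values = pd.DataFrame(samples, index=genes).astype(float)
    matrix = ExpressionMatrix(values, cond_map, unit="counts")
    truth = {
        "regulation": labels,
        "retained": retained,
        "violators": violators,
        "planned_tpm_control": {g: float(tpm_control[idx[g]]) for g in genes},
        "planned_tpm_stress": {g: float(tpm_stress[idx[g]]) for g in genes},
    }
    return matrix, lengths, truth


# ---------------------------------------------------------------------------
# full scenario

def generate_scenario(cfg: ScenarioConfig, seed: int, outdir) -> dict:
    """Write every stage's inputs plus truth.json into ``outdir``.

    Returns the truth dictionary.  Bit-identical for fixed (config, seed).
    """
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    proteins, motif_truth = generate_proteome(cfg, seed)
    write_fasta(proteins, out / "proteome.faa")

    aln, anchors, tree_truth = generate_family_tree(cfg, seed)
    write_alignment_fasta(aln, out / "alignment.faa")
    write_fasta(anchors.records, out / "anchors.faa")
    write_anchor_map(anchors.group_of, out / "anchors.tsv")
    with open(out / "species.tsv", "w") as fh:
        fh.write("id\tspecies\n")
        for tid in sorted(tree_truth["species_of"]):
            fh.write(f"{tid}\t{tree_truth['species_of'][tid]}\n")

    dup_truth = generate_duplicates(cfg, seed)
    write_fasta(sorted(dup_truth["cds"].items()), out / "cds.fna")
    write_bed_loci(dup_truth["loci"] + dup_truth["pair_loci"], out / "loci.bed")
    with open(out / "pairs_in.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for row in dup_truth["pairs"]:
            fh.write(f"{row['gene_a']}\t{row['gene_b']}\n")

    models, struct_truth = generate_gene_models(cfg, seed)
    write_gff3_gene_models(models, out / "gene_models.gff3")
    write_alignment_fasta(structure_alignment(cfg, models, seed), out / "struct_alignment.faa")

    matrix, lengths, expr_truth = generate_expression(cfg, seed)
    write_expression_tsv(matrix, out / "expression_counts.tsv", out / "conditions.tsv")
    with open(out / "gene_lengths.tsv", "w") as fh:
        fh.write("gene_id\tlength_bp\n")
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{lengths[g]}\n")
    # group labels for the expression genes (down-plan mirrors group structure)
    expr_groups = {
        g: GROUPS16[i % cfg.n_groups] for i, g in enumerate(matrix.gene_ids)
    }
    with open(out / "expression_groups.tsv", "w") as fh:
        fh.write("gene_id\tgroup\n")
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{expr_groups[g]}\n")

    truth = {
        "config": asdict(cfg),
        "seed": seed,
        **motif_truth,
        "tree": tree_truth,
        "duplication": {
            "pairs": dup_truth["pairs"],
            "true_clusters": dup_truth["true_clusters"],
        },
        "structure": struct_truth,
        "expression": {
            "regulation": expr_truth["regulation"],
            "retained": expr_truth["retained"],
            "violators": expr_truth["violators"],
        },
        "expression_groups": expr_groups,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
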