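"""Chromosomal clustering, tandem/segmental classification, Nei–Gojobori
Ka/Ks estimation, and molecular-clock duplication dating.

A gene cluster is two or more family members whose consecutive start
coordinates on one chromosome are each less than a window (default 200 kb)
apart.  Duplication ages come from synonymous divergence under a strict
clock, T = Ks / (2 lambda), with lambda the per-year synonymous substitution
rate (default 9.1e-9 for Populus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import pandas as pd

from .seqio import GeneLocus

NUCLEOTIDES = "ACGT"

_CODON_TABLE = {}
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AMINO[16 * _i + 4 * _j + _k]


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon.

    At each position, the fraction of the three possible single-base changes
    that preserve the amino acid; changes creating a stop count as
    nonsynonymous.  Total sites per codon is 3.
    """
    aa = _CODON_TABLE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} in coding sequence")
    s = 0.0
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if _CODON_TABLE[mutated] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous substitution counts between two codons,
    averaged over all mutational pathways (orders of the differing sites).

    Pathways passing through a stop codon are excluded; if every pathway hits
    a stop, all pathways are averaged (a step is synonymous iff the
    translation is unchanged).
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def path_steps(order):
        cur = codon_a
        steps = []
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            cur = nxt
        return steps

    all_paths = [path_steps(order) for order in permutations(diff)]
    valid = [
        steps
        for steps in all_paths
        if all(_CODON_TABLE[b] != "*" for _, b in steps[:-1])
    ]
    paths = valid if valid else all_paths
    sd = nd = 0.0
    for steps in paths:
        for a, b in steps:
            if _CODON_TABLE[a] == _CODON_TABLE[b]:
                sd += 1.0
            else:
                nd += 1.0
    return sd / len(paths), nd / len(paths)


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # +0.0 avoids -0.0


@dataclass(frozen=True)
class KaKsResult:
    ka: float | None  # None when saturated
    ks: float | None
    sd: float  # synonymous differences
    nd: float
    s_sites: float
    n_sites: float
    n_codons: int  # codon pairs actually compared

    @property
    def saturated(self) -> bool:
        return self.ka is None or self.ks is None


def nei_gojobori_ks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction.

    Sequences must be equal-length, in-frame codon alignments.  Codon pairs
    containing a gap or ambiguous base are dropped before counting.  Site
    counts are averaged over the two sequences; multi-hit codons use
    pathway-averaged substitution counting.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("coding sequences differ in length")
    if len(cds_a) % 3 != 0:
        raise ValueError("coding length not divisible by 3")
    valid = set(NUCLEOTIDES)
    sa = sb = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if set(ca) - valid or set(cb) - valid:
            continue  # gapped or ambiguous codon pair dropped
        sa += synonymous_sites(ca)
        sb += synonymous_sites(cb)
        d_s, d_n = _pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons")
    s_sites = (sa + sb) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return KaKsResult(
        ka=jukes_cantor(pn),
        ks=jukes_cantor(ps),
        sd=sd,
        nd=nd,
        s_sites=s_sites,
        n_sites=n_sites,
        n_codons=n_codons,
    )


# ---------------------------------------------------------------------------
# Clock dating

@dataclass(frozen=True)
class ClockParams:
    """Strict molecular clock: substitutions per synonymous site per year."""

    lambda_rate: float = 9.1e-9

    def __post_init__(self) -> None:
        if self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be > 0")


def date_duplication(ks: float | None, clock: ClockParams = ClockParams()) -> float | None:
    """Age of a duplication in million years: T = Ks / (2 lambda)."""
    if ks is None:
        return None
    if ks < 0:
        raise ValueError("ks must be >= 0")
    return ks / (2.0 * clock.lambda_rate) / 1e6


# ---------------------------------------------------------------------------
# Clusters and pair classification

@dataclass
class GeneCluster:
    chrom: str
    member_ids: list[str]  # sorted by start coordinate
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a cluster needs at least 2 members")


def detect_clusters(
    loci: list[GeneLocus], window: int = 200_000, min_size: int = 2
) -> list[GeneCluster]:
    """Single-linkage chaining of family members along each chromosome.

    Consecutive (by start) members whose start-to-start gap is strictly less
    than ``window`` join one chain; chains of at least ``min_size`` members
    are emitted as clusters, ordered by (chrom, span start).
    """
    clusters: list[GeneCluster] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda l: (l.start, l.gene_id))
        chain: list[GeneLocus] = [members[0]]
        for locus in members[1:]:
            if locus.start - chain[-1].start < window:
                chain.append(locus)
            else:
                if len(chain) >= min_size:
                    clusters.append(_as_cluster(chrom, chain))
                chain = [locus]
        if len(chain) >= min_size:
            clusters.append(_as_cluster(chrom, chain))
    return clusters


def _as_cluster(chrom: str, chain: list[GeneLocus]) -> GeneCluster:
    return GeneCluster(
        chrom=chrom,
        member_ids=[l.gene_id for l in chain],
        span=(min(l.start for l in chain), max(l.end for l in chain)),
    )


def classify_pair(
    a: GeneLocus,
    b: GeneLocus,
    clusters: list[GeneCluster],
    intervening_loci: list[GeneLocus] | None = None,
) -> str:
    """Tandem vs segmental call for a duplicated pair.

    Tandem requires co-membership in one cluster and either adjacency within
    the cluster or, when a list of non-family gene loci is supplied, the
    absence of any such gene between the two members.  Everything else is a
    segmental candidate.
    """
    if a.chrom == b.chrom:
        for cluster in clusters:
            if cluster.chrom != a.chrom:
                continue
            ids = cluster.member_ids
            if a.gene_id in ids and b.gene_id in ids:
                if intervening_loci is not None:
                    lo = min(a.end, b.end)
                    hi = max(a.start, b.start)
                    blocked = any(
                        g.chrom == a.chrom and g.start >= lo and g.end <= hi
                        for g in intervening_loci
                    )
                    return "segmental" if blocked else "tandem"
                ia, ib = ids.index(a.gene_id), ids.index(b.gene_id)
                return "tandem" if abs(ia - ib) == 1 else "segmental"
    return "segmental"


# ---------------------------------------------------------------------------
# Duplication pairs and per-group summary

@dataclass
class DuplicationPair:
    gene_a: str
    gene_b: str
    dup_type: str  # tandem | segmental
    ka: float | None
    ks: float | None
    time_mya: float | None
    flags: tuple[str, ...] = ()


def build_pair(
    gene_a: str,
    gene_b: str,
    cds_a: str,
    cds_b: str,
    dup_type: str,
    clock: ClockParams = ClockParams(),
    ks_ceiling: float = 3.0,
) -> DuplicationPair:
    """Estimate Ka/Ks for a pair and date it under the clock.

    Identical pairs get the flag "recent" (ks = 0, age 0).  Pairs whose Ks
    exceeds ``ks_ceiling`` are flagged "ks_ceiling" and left undated, a guard
    against saturation artifacts; Jukes–Cantor-saturated pairs are flagged
    "saturated".
    """
    res = nei_gojobori_ks(cds_a, cds_b)
    flags: list[str] = []
    ks, ka = res.ks, res.ka
    if res.sd == 0 and res.nd == 0:
        flags.append("recent")
    if res.saturated:
        flags.append("saturated")
    time_mya = None
    if ks is not None:
        if ks > ks_ceiling:
            flags.append("ks_ceiling")
        else:
            time_mya = date_duplication(ks, clock)
    return DuplicationPair(gene_a, gene_b, dup_type, ka, ks, time_mya, tuple(flags))


def mean_ks_by_block(
    pairs: list[DuplicationPair], block_of: dict[tuple[str, str], str]
) -> dict[str, float]:
    """Mean Ks per duplicated block, for block-level dating when block
    assignments are available (default analysis is per-pair)."""
    acc: dict[str, list[float]] = {}
    for p in pairs:
        if p.ks is None:
            continue
        block = block_of.get((p.gene_a, p.gene_b)) or block_of.get((p.gene_b, p.gene_a))
        if block is not None:
            acc.setdefault(block, []).append(p.ks)
    return {b: sum(v) / len(v) for b, v in sorted(acc.items())}


def pair_table(
    pairs: list[DuplicationPair], group_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-group summary: pair counts by type and dated-age range.

    A pair belongs to a group when both genes share it; otherwise "mixed".
    Without group calls every pair lands in a single "all" row.
    """
    rows = []
    for p in pairs:
        if group_of is None:
            grp = "all"
        else:
            ga = group_of.get(p.gene_a, "unassigned")
            gb = group_of.get(p.gene_b, "unassigned")
            grp = ga if ga == gb else "mixed"
        rows.append(
            {
                "group": grp,
                "tandem": p.dup_type == "tandem",
                "segmental": p.dup_type == "segmental",
                "time_mya": p.time_mya,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["group", "n_pairs", "n_tandem", "n_segmental", "t_min_mya", "t_max_mya"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("group")
        .agg(
            n_pairs=("group", "size"),
            n_tandem=("tandem", "sum"),
            n_segmental=("segmental", "sum"),
            t_min_mya=("time_mya", "min"),
            t_max_mya=("time_mya", "max"),
        )
        .reset_index()
        .sort_values("group")
        .reset_index(drop=True)
    )
    return out


def write_pairs_tsv(pairs: list[DuplicationPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tdup_type\tka\tks\ttime_mya\tflags\n")
        for p in sorted(pairs, key=lambda p: (p.gene_a, p.gene_b)):
            ka = "" if p.ka is None else f"{p.ka:.6g}"
            ks = "" if p.ks is None else f"{p.ks:.6g}"
            t = "" if p.time_mya is None else f"{p.time_mya:.6g}"
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.dup_type}\t{ka}\t{ks}\t{t}\t"
                f"{','.join(p.flags)}\n"
            )


def write_clusters_tsv(clusters: list[GeneCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_members\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.span[0]}\t{c.span[1]}\t{len(c.member_ids)}\t"
                f"{','.join(c.member_ids)}\n"
            )
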