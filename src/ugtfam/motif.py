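"""PROSITE-dialect fuzzy motif compilation and proteome scanning.

The family-defining instrument is the ~44-residue plant secondary product
glycosyltransferase (PSPG) consensus pattern found near the C terminus of
family-1 UDP-glycosyltransferases.  The pattern ships verbatim as
``PSPG_PATTERN``; any pattern in the same dialect can be compiled and scanned.

Match policy (deterministic and oracle-checkable): leftmost start, shortest
match per start, then non-overlapping continuation after each reported match.
Variable-width wildcards are resolved greedily-minimal, which also fixes the
per-element spans.  An all-overlapping enumeration is available via
``scan(..., overlapping=True)``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import AA_ALPHABET, ProteinRecord

#: Consensus pattern of the PSPG box, as published for the family scan.
PSPG_PATTERN = (
    "[FW]-x(2)-[QL]-x(2)-[LIVMYA]-[LIMV]-x(4,6)-[LVGAC]-[LVFYAHM]-[LIVMF]-"
    "[STAGCM]-[HNQ]-[STAGC]-G-x(2)-[STAG]-x(3)-[STAGL]-[LIVMFA]-x(4,5)-"
    "[PQR]-[LIVMTA]-x(3)-[PA]-x(2,3)-[DES]-[QEHNR]"
)


class PatternError(ValueError):
    """Raised for a malformed PROSITE-dialect pattern string."""


@dataclass(frozen=True)
class PatternElement:
    """One pattern element: a residue set (None = wildcard) with a repeat range."""

    residues: frozenset | None  # None means wildcard 'x'
    min_repeat: int
    max_repeat: int


@dataclass(frozen=True)
class PrositePattern:
    elements: tuple[PatternElement, ...]

    @property
    def span_min(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def span_max(self) -> int:
        return sum(e.max_repeat for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    protein_id: str
    start: int
    end: int
    matched_seq: str
    element_spans: tuple[tuple[int, int], ...]  # relative to the match start


def parse_pattern(text: str) -> PrositePattern:
    """Compile a dash-separated PROSITE-dialect pattern.

    Elements are ``[CLASS]``, a single residue letter, or ``x``; each may take
    an optional ``(n)`` or ``(m,n)`` repeat suffix.
    """
    elements: list[PatternElement] = []
    for raw in text.strip().split("-"):
        token = raw.strip()
        if not token:
            raise PatternError(f"empty element in pattern {text!r}")
        lo, hi = 1, 1
        if "(" in token:
            if not token.endswith(")"):
                raise PatternError(f"unbalanced parentheses in {token!r}")
            token, rep = token[:-1].split("(", 1)
            parts = rep.split(",")
            try:
                nums = [int(p) for p in parts]
            except ValueError as exc:
                raise PatternError(f"bad repeat count in {raw!r}") from exc
            if len(nums) == 1:
                lo = hi = nums[0]
            elif len(nums) == 2:
                lo, hi = nums
            else:
                raise PatternError(f"bad repeat spec in {raw!r}")
            if lo < 0 or lo > hi:
                raise PatternError(f"invalid repeat range ({lo},{hi}) in {raw!r}")
        if token == "x":
            residues = None
        elif token.startswith("["):
            if not token.endswith("]"):
                raise PatternError(f"unbalanced brackets in {raw!r}")
            body = token[1:-1]
            if not body:
                raise PatternError(f"empty residue class in {raw!r}")
            bad = set(body) - AA_ALPHABET
            if bad:
                raise PatternError(f"unknown residue letters {sorted(bad)} in {raw!r}")
            residues = frozenset(body)
        elif len(token) == 1 and token in AA_ALPHABET:
            residues = frozenset(token)
        else:
            raise PatternError(f"unrecognized element {raw!r}")
        elements.append(PatternElement(residues, lo, hi))
    if not elements:
        raise PatternError("pattern has no elements")
    return PrositePattern(tuple(elements))


def pattern_to_regex(pattern: PrositePattern, lazy: bool = True) -> str:
    """Mechanical translation to a regular expression.

    With ``lazy=True`` the variable repeats are non-greedy, which makes
    ``re.finditer`` reproduce the scanner's leftmost/shortest/non-overlapping
    policy exactly.  Residue classes list their explicit letters only, so the
    ambiguity code X is matched by wildcards but never by a class.
    """
    parts = []
    for e in pattern.elements:
        atom = "[A-Z]" if e.residues is None else "[" + "".join(sorted(e.residues)) + "]"
        if e.min_repeat == e.max_repeat:
            rep = "" if e.min_repeat == 1 else f"{{{e.min_repeat}}}"
        else:
            rep = f"{{{e.min_repeat},{e.max_repeat}}}" + ("?" if lazy else "")
        parts.append(atom + rep)
    return "".join(parts)


def _match_here(pattern: PrositePattern, seq: str, pos: int):
    """Greedy-minimal backtracking match starting at ``pos``.

    Returns (end, element_spans) of the shortest viable assignment, or None.
    Wildcards prefer their minimum width; on failure the most recent
    variable-width element is widened (standard backtracking), which yields
    the lexicographically smallest repeat vector and hence the shortest match.
    """
    n_elem = len(pattern.elements)
    n = len(seq)

    def consume(elem: PatternElement, at: int, count: int) -> bool:
        if at + count > n:
            return False
        if elem.residues is None:
            return True
        return all(seq[at + k] in elem.residues for k in range(count))

    # iterative backtracking over repeat choices
    choices: list[int] = []  # repeat count chosen per element
    starts: list[int] = []  # absolute start of each element
    i, at = 0, pos
    while True:
        if i == n_elem:
            spans = tuple(
                (starts[k] - pos, starts[k] - pos + choices[k]) for k in range(n_elem)
            )
            return at, spans
        elem = pattern.elements[i]
        count = elem.min_repeat
        placed = False
        while count <= elem.max_repeat:
            if consume(elem, at, count):
                choices.append(count)
                starts.append(at)
                at += count
                i += 1
                placed = True
                break
            count += 1
        if placed:
            continue
        # backtrack: widen the most recent element that still has slack
        while choices:
            i -= 1
            elem = pattern.elements[i]
            at = starts.pop()
            count = choices.pop() + 1
            while count <= elem.max_repeat:
                if consume(elem, at, count):
                    break
                count += 1
            if count <= elem.max_repeat:
                choices.append(count)
                starts.append(at)
                at += count
                i += 1
                break
        else:
            return None
        continue


def scan(
    pattern: PrositePattern,
    protein: ProteinRecord | None = None,
    *,
    sequence: str | None = None,
    protein_id: str = "",
    overlapping: bool = False,
) -> list[MotifMatch]:
    """All matches of ``pattern`` in one protein under the stated policy.

    Default policy: leftmost start, shortest match at that start, continue
    scanning after the match end.  ``overlapping=True`` instead reports the
    shortest match at every start position.
    """
    if protein is not None:
        seq, pid = protein.sequence, protein.id
    else:
        seq, pid = (sequence or ""), protein_id
    matches: list[MotifMatch] = []
    pos = 0
    n = len(seq)
    while pos <= n - pattern.span_min:
        hit = _match_here(pattern, seq, pos)
        if hit is None:
            pos += 1
            continue
        end, rel_spans = hit
        spans = tuple((pos + s, pos + e) for s, e in rel_spans)
        matches.append(MotifMatch(pid, pos, end, seq[pos:end], spans))
        pos = pos + 1 if (overlapping or end == pos) else end
    return matches


def classify_family(
    proteins: list[ProteinRecord], pattern: PrositePattern
) -> tuple[list[str], dict[str, MotifMatch]]:
    """Family membership = at least one pattern match.

    When a protein carries several matches the most C-terminal one is reported
    as its PSPG box, reflecting the motif's C-terminal location in the family.
    """
    members: list[str] = []
    boxes: dict[str, MotifMatch] = {}
    for prot in proteins:
        hits = scan(pattern, prot)
        if hits:
            members.append(prot.id)
            boxes[prot.id] = max(hits, key=lambda m: m.start)
    return members, boxes


@dataclass
class MotifProfile:
    """Position x residue counts over fixed-width matches, plus conserved sites."""

    counts: dict[int, dict[str, int]]  # 0-based position -> residue -> count
    conserved_positions: list[tuple[int, str, float]]  # (1-based pos, residue, freq)
    n_matches: int
    n_excluded: int  # matches dropped for having non-modal width


def profile_motif(matches: list[MotifMatch], threshold: float = 0.95) -> MotifProfile:
    """Residue frequency profile of the motif across matches.

    Matches are normalized to the modal match width; other widths are excluded
    (their count is reported).  ``conserved_positions`` lists positions whose
    modal residue reaches ``threshold`` of the contributing matches, 1-based
    as motif positions are conventionally numbered.
    """
    if not matches:
        raise ValueError("profile_motif requires at least one match")
    widths = [m.end - m.start for m in matches]
    modal_width = max(sorted(set(widths)), key=widths.count)
    kept = [m for m in matches if m.end - m.start == modal_width]
    counts: dict[int, dict[str, int]] = {i: {} for i in range(modal_width)}
    for m in kept:
        for i, res in enumerate(m.matched_seq):
            counts[i][res] = counts[i].get(res, 0) + 1
    conserved = []
    for i in range(modal_width):
        res, cnt = max(sorted(counts[i].items()), key=lambda kv: kv[1])
        freq = cnt / len(kept)
        if freq >= threshold:
            conserved.append((i + 1, res, freq))
    return MotifProfile(counts, conserved, len(kept), len(matches) - len(kept))


def write_matches_tsv(boxes: dict[str, MotifMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tmatched_seq\n")
        for pid in sorted(boxes):
            m = boxes[pid]
            fh.write(f"{pid}\t{m.start}\t{m.end}\t{m.matched_seq}\n")
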