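"""Progenitor-guided classification of variable amplicon sites.

Given the tetraploid consensus observations of a variety panel and the two
diploid progenitor observations for the same locus, this module

1. infers which locus copies survive in the tetraploid (copy composition)
   by enumerating candidate copy sets and scoring how well their IUPAC
   superposition predicts the observed consensus, and
2. classifies every variable alignment column as a homologous SNP
   (segregates among varieties on one subgenome copy), an HSV (fixed
   difference between retained A and B copies), or a PSV (difference between
   retained paralogs of one genome), flagging SNPs that sit on HSV columns.

A global aligner with ambiguity-aware matching is provided for real inputs
with indels; the substitution-only simulator produces positionally aligned
sequences, so the classifier itself works on reference coordinates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .ampliconobs import (
    AmpliconObservation,
    iupac_decompose,
    iupac_superpose,
)

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: strand-collapsed variant class labels, keyed by unordered base pair
_COLLAPSED = {
    frozenset("CT"): "C/T(G/A)",
    frozenset("GA"): "C/T(G/A)",
    frozenset("AC"): "A/C(T/G)",
    frozenset("TG"): "A/C(T/G)",
    frozenset("AT"): "A/T(T/A)",
    frozenset("CG"): "C/G(G/C)",
}

COLLAPSED_CLASSES = ("C/T(G/A)", "A/C(T/G)", "A/T(T/A)", "C/G(G/C)")

HYPOTHESES = ("AB", "A_only", "B_only", "A_paralogs", "B_paralogs", "AB_paralogs")


def collapse_variant_class(allele_a: str, allele_b: str) -> str:
    """Map an unordered pair of distinct canonical bases onto one of the four
    strand-collapsed variant classes."""
    pair = frozenset((allele_a.upper(), allele_b.upper()))
    if len(pair) != 2:
        raise ValueError("alleles must be distinct")
    try:
        return _COLLAPSED[pair]
    except KeyError:
        raise ValueError(f"not a canonical base pair: {allele_a}/{allele_b}") from None


# ---------------------------------------------------------------------------
# global alignment (ambiguity-aware Needleman-Wunsch with affine gaps)


@dataclass(frozen=True)
class AlignParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -4.0  # charged once per gap, plus gap_extend per base
    gap_extend: float = -1.0


@dataclass(frozen=True)
class Alignment:
    query_id: str
    ref_id: str
    aligned_query: str
    aligned_ref: str
    score: float
    identity: float

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.aligned_query, self.aligned_ref))


def _letters_match(a: str, b: str) -> bool:
    return bool(iupac_decompose(a) & iupac_decompose(b))


def align_global(
    a: str,
    b: str,
    params: AlignParams = AlignParams(),
    query_id: str = "query",
    ref_id: str = "ref",
) -> Alignment:
    """Optimal global alignment of two IUPAC sequences (Gotoh affine gaps).

    Two letters match when their decomposed base sets intersect. A gap of
    length k costs ``gap_open + k * gap_extend``. Traceback ties prefer
    diagonal, then up (gap in ``b``), then left (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    neg = float("-inf")
    go, ge = params.gap_open, params.gap_extend

    # M: a[i] aligned to b[j]; X: gap in b (consume a); Y: gap in a (consume b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    ptrM = [[""] * (m + 1) for _ in range(n + 1)]
    ptrX = [[""] * (m + 1) for _ in range(n + 1)]
    ptrY = [[""] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + ge * i
        ptrX[i][0] = "M" if i == 1 else "X"
    for j in range(1, m + 1):
        Y[0][j] = go + ge * j
        ptrY[0][j] = "M" if j == 1 else "Y"
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = params.match if _letters_match(a[i - 1], b[j - 1]) else params.mismatch
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            best = max(prev)
            M[i][j] = best + s
            ptrM[i][j] = "MXY"[prev.index(best)]  # prefer M, then X, then Y
            open_x, extend_x = M[i - 1][j] + go + ge, X[i - 1][j] + ge
            X[i][j] = max(open_x, extend_x)
            ptrX[i][j] = "M" if open_x >= extend_x else "X"
            open_y, extend_y = M[i][j - 1] + go + ge, Y[i][j - 1] + ge
            Y[i][j] = max(open_y, extend_y)
            ptrY[i][j] = "M" if open_y >= extend_y else "Y"

    # traceback with fixed tie preference: M (diagonal), X (up), Y (left)
    aligned_a: list[str] = []
    aligned_b: list[str] = []
    i, j = n, m
    final = max(M[n][m], X[n][m], Y[n][m])
    state = "M" if M[n][m] == final else ("X" if X[n][m] == final else "Y")
    while i > 0 or j > 0:
        if state == "M":
            aligned_a.append(a[i - 1])
            aligned_b.append(b[j - 1])
            state = ptrM[i][j]
            i, j = i - 1, j - 1
        elif state == "X":
            aligned_a.append(a[i - 1])
            aligned_b.append("-")
            state = ptrX[i][j]
            i -= 1
        else:
            aligned_a.append("-")
            aligned_b.append(b[j - 1])
            state = ptrY[i][j]
            j -= 1
    aligned_a.reverse()
    aligned_b.reverse()
    matches = sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x != "-" and y != "-" and _letters_match(x, y)
    )
    identity = matches / len(aligned_a)
    return Alignment(
        query_id=query_id,
        ref_id=ref_id,
        aligned_query="".join(aligned_a),
        aligned_ref="".join(aligned_b),
        score=final,
        identity=identity,
    )


# ---------------------------------------------------------------------------
# copy composition


@dataclass(frozen=True)
class CopyComposition:
    """Which copies of a locus the tetraploid is inferred to retain."""

    locus_id: str
    hypothesis: str  # one of HYPOTHESES
    mismatch_count: int
    explained: bool
    copy_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")


def _position_explained(
    observed: frozenset[str], groups: list[tuple[frozenset[str], int]]
) -> tuple[bool, bool]:
    """Whether some per-copy base choice makes the superposition equal the
    observed base set, and whether the explanation depends on that choice.

    Each group is (progenitor base set S, copies taken). Taking both copies of
    a heterozygous progenitor contributes S exactly; taking one contributes a
    single (unknown) base of S. The second flag is True when the position is
    explained but some alternative choice would fail — such positions make a
    hypothesis less specific than one that predicts the column outright.
    """
    fixed: set[str] = set()
    alternatives: list[frozenset[str]] = []
    for s, k in groups:
        if len(s) == 1 or k >= len(s):
            fixed |= s
        else:  # one copy of a heterozygous pair: one base of s, unknown
            alternatives.append(s)
    if not alternatives:
        return fixed == observed, False
    outcomes = [
        fixed | set(choice) == observed
        for choice in itertools.product(*alternatives)
    ]
    explained = any(outcomes)
    return explained, explained and not all(outcomes)


# hypothesis -> (copies taken from A, copies taken from B)
_HYPOTHESIS_TAKES: dict[str, list[tuple[int, int]]] = {
    "AB": [(1, 1)],
    "A_only": [(1, 0)],
    "B_only": [(0, 1)],
    "A_paralogs": [(2, 0)],
    "B_paralogs": [(0, 2)],
    "AB_paralogs": [(2, 1), (1, 2), (2, 2)],
}


def infer_copy_composition(
    tetra: AmpliconObservation,
    prog_a: AmpliconObservation,
    prog_b: AmpliconObservation,
) -> CopyComposition:
    """Infer the retained copy set of a locus from one tetraploid observation.

    Candidate copy sets (bounded at four copies) are scored by the number of
    positions where no choice of per-copy bases reproduces the observed
    consensus; paralog candidates exist only when the corresponding progenitor
    is heterozygous. Equal-mismatch hypotheses are ranked by specificity
    (fewer positions whose explanation depends on an arbitrary base choice for
    a single retained copy of a heterozygous progenitor), then by the
    precedence AB > A_only > B_only > A_paralogs > B_paralogs > AB_paralogs.
    """
    if not (len(tetra) == len(prog_a) == len(prog_b)):
        raise ValueError("observations have incompatible lengths")
    a_het = prog_a.is_heterozygous
    b_het = prog_b.is_heterozygous

    candidates: list[tuple[str, tuple[int, int]]] = []
    for hyp in HYPOTHESES:
        for ka, kb in _HYPOTHESIS_TAKES[hyp]:
            if ka == 2 and not a_het:
                continue
            if kb == 2 and not b_het:
                continue
            if hyp == "AB_paralogs" and not (
                (ka == 2 and a_het) or (kb == 2 and b_het)
            ):
                continue
            candidates.append((hyp, (ka, kb)))

    best: tuple[int, int, int] | None = None  # (mismatch, choice-dependence, precedence)
    best_hyp = "AB"
    best_take = (1, 1)
    for hyp, (ka, kb) in candidates:
        mismatches = 0
        choice_dependent = 0
        for p in range(len(tetra)):
            groups = []
            if ka:
                groups.append((prog_a.base_set(p), ka))
            if kb:
                groups.append((prog_b.base_set(p), kb))
            explained, by_choice = _position_explained(tetra.base_set(p), groups)
            if not explained:
                mismatches += 1
            elif by_choice:
                choice_dependent += 1
        key = (mismatches, choice_dependent, HYPOTHESES.index(hyp))
        if best is None or key < best:
            best = key
            best_hyp, best_take = hyp, (ka, kb)

    ka, kb = best_take
    labels = tuple(
        [f"A{i + 1}" for i in range(ka)] + [f"B{i + 1}" for i in range(kb)]
    )
    assert best is not None
    return CopyComposition(
        locus_id=tetra.locus_id,
        hypothesis=best_hyp,
        mismatch_count=best[0],
        explained=best[0] == 0,
        copy_labels=labels,
    )


# ---------------------------------------------------------------------------
# variant sites


@dataclass(frozen=True)
class VariantSite:
    """A classified variable alignment column (1-based reference position)."""

    locus_id: str
    position: int
    category: str  # SNP | HSV | PSV | unresolved
    subgenome: str | None  # A | B | between | within-A | within-B | None
    alleles: tuple[str, str] | None
    collapsed_class: str | None = None
    hsv_coincident: bool = False
    n_varieties_minor: int | None = None
    calls: Mapping[str, str] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.category == "HSV" and self.subgenome != "between":
            raise ValueError("HSV sites must have subgenome 'between'")
        if self.category == "PSV" and self.subgenome not in ("within-A", "within-B"):
            raise ValueError("PSV sites must be within-A or within-B")


def detect_psv(
    prog: AmpliconObservation, genome: str = "A"
) -> list[VariantSite]:
    """One PSV per ambiguity position of a (paralog-bearing) progenitor.

    Positions decomposing to more than two bases are flagged complex and
    excluded with a warning.
    """
    if genome not in ("A", "B"):
        raise ValueError("genome must be 'A' or 'B'")
    sites = []
    for pos in prog.ambiguity_positions:
        bases = sorted(prog.base_set(pos))
        if len(bases) > 2:
            logger.warning(
                "locus %s position %d decomposes to %d bases; excluded as complex",
                prog.locus_id,
                pos + 1,
                len(bases),
            )
            continue
        sites.append(
            VariantSite(
                locus_id=prog.locus_id,
                position=pos + 1,
                category="PSV",
                subgenome=f"within-{genome}",
                alleles=(bases[0], bases[1]),
                collapsed_class=collapse_variant_class(bases[0], bases[1]),
            )
        )
    return sites


def _resolve_copy_bases(
    composition: CopyComposition,
    prog_a: AmpliconObservation,
    prog_b: AmpliconObservation,
    panel: Mapping[str, AmpliconObservation],
    position: int,
) -> list[tuple[str, str, str]] | None:
    """Per-copy (label, genome, base) assignment at one position.

    A single retained copy of a heterozygous progenitor has an unknown phase;
    its base is resolved as the choice consistent with the modal variety
    letter, or None when no choice fits.
    """
    letters = [obs.sequence[position] for obs in panel.values()]
    modal = max(set(letters), key=letters.count)
    modal_set = iupac_decompose(modal)

    takes = {"A": 0, "B": 0}
    for lab in composition.copy_labels:
        takes[lab[0]] += 1
    fixed: list[tuple[str, str, str]] = []
    free: list[tuple[str, frozenset[str]]] = []  # (genome, candidate bases)
    for genome, prog in (("A", prog_a), ("B", prog_b)):
        k = takes[genome]
        if k == 0:
            continue
        s = prog.base_set(position)
        if len(s) > 2:
            return None
        if len(s) == 1:
            for i in range(k):
                fixed.append((f"{genome}{i + 1}", genome, next(iter(s))))
        elif k >= 2:
            for i, base in enumerate(sorted(s)):
                fixed.append((f"{genome}{i + 1}", genome, base))
        else:
            free.append((genome, s))

    if not free:
        return fixed
    fixed_bases = {b for _, _, b in fixed}
    for choice in itertools.product(*(sorted(s) for _, s in free)):
        if fixed_bases | set(choice) == modal_set:
            return fixed + [
                (f"{genome}1", genome, base)
                for (genome, _), base in zip(free, choice)
            ]
    # modal letter may carry a segregating allele; fall back to any choice
    # compatible with (subset of) the modal set
    for choice in itertools.product(*(sorted(s) for _, s in free)):
        if set(choice) <= modal_set:
            return fixed + [
                (f"{genome}1", genome, base)
                for (genome, _), base in zip(free, choice)
            ]
    return None


def _try_snp(
    copies: list[tuple[str, str, str]],
    variety_letters: Mapping[str, str],
) -> list[tuple[str, dict[str, str], tuple[str, str]]]:
    """All single-varying-copy explanations of a segregating column.

    Returns a list of (genome, per-variety allele calls, allele pair); empty
    when no copy can explain the variation alone.
    """
    results = []
    for idx, (label, genome, ref_base) in enumerate(copies):
        others = frozenset(b for i, (_, _, b) in enumerate(copies) if i != idx)
        calls: dict[str, str] = {}
        ok = True
        for variety, letter in variety_letters.items():
            observed = iupac_decompose(letter)
            if not others <= observed:
                ok = False
                break
            extra = observed - others
            if len(extra) == 1:
                allele = next(iter(extra))
                if observed != others | {allele}:
                    ok = False
                    break
            elif len(extra) == 0:
                # the varying copy's base hides inside the fixed set
                if observed != others:
                    ok = False
                    break
                if ref_base in others:
                    allele = ref_base
                elif len(others) == 1:
                    allele = next(iter(others))
                else:
                    ok = False
                    break
            else:
                ok = False
                break
            calls[variety] = allele
        if not ok:
            continue
        alleles = sorted(set(calls.values()))
        if len(alleles) == 2:
            results.append((genome, calls, (alleles[0], alleles[1])))
    return results


def classify_sites(
    panel: Mapping[str, AmpliconObservation],
    prog_a: AmpliconObservation,
    prog_b: AmpliconObservation,
    composition: CopyComposition,
) -> list[VariantSite]:
    """Classify every variable column of a locus across the variety panel.

    Requires an explained copy composition and at least two varieties. Each
    variable column yields exactly one site record: HSV (fixed A-vs-B
    difference shown by every variety), PSV (retained within-genome paralog
    difference), SNP (segregates among varieties, attributable to one copy;
    ``hsv_coincident`` set when the column is also an HSV column), or an
    ``unresolved`` record.
    """
    if not composition.explained:
        raise ValueError(
            f"copy composition for locus {composition.locus_id} is unexplained "
            f"({composition.mismatch_count} mismatches); refusing to classify"
        )
    if len(panel) < 2:
        raise ValueError("need at least two varieties to classify sites")
    lengths = {len(obs) for obs in panel.values()} | {len(prog_a), len(prog_b)}
    if len(lengths) != 1:
        raise ValueError("length-incompatible observations")
    length = lengths.pop()

    sites: list[VariantSite] = []
    for p in range(length):
        copies = _resolve_copy_bases(composition, prog_a, prog_b, panel, p)
        variety_letters = {v: obs.sequence[p] for v, obs in panel.items()}
        distinct = set(variety_letters.values())

        if copies is None:
            if len(distinct) > 1 or any(
                len(iupac_decompose(let)) > 1 for let in distinct
            ):
                sites.append(
                    VariantSite(
                        locus_id=composition.locus_id,
                        position=p + 1,
                        category="unresolved",
                        subgenome=None,
                        alleles=None,
                        note="complex or unphaseable column",
                    )
                )
            continue

        expected = frozenset(b for _, _, b in copies)
        expected_letter = iupac_superpose(expected)
        a_bases = {b for _, g, b in copies if g == "A"}
        b_bases = {b for _, g, b in copies if g == "B"}
        is_hsv_column = bool(a_bases and b_bases and a_bases != b_bases)

        if len(distinct) == 1 and distinct == {expected_letter}:
            if len(expected) == 1:
                continue  # invariant column
            if len(expected) > 2:
                sites.append(
                    VariantSite(
                        locus_id=composition.locus_id,
                        position=p + 1,
                        category="unresolved",
                        subgenome=None,
                        alleles=None,
                        note="more than two superposed bases",
                    )
                )
                continue
            x, y = sorted(expected)
            paralog_genome = None
            for genome, bases in (("A", a_bases), ("B", b_bases)):
                if len(bases) == 2:
                    paralog_genome = genome
            if paralog_genome is not None:
                sites.append(
                    VariantSite(
                        locus_id=composition.locus_id,
                        position=p + 1,
                        category="PSV",
                        subgenome=f"within-{paralog_genome}",
                        alleles=(x, y),
                        collapsed_class=collapse_variant_class(x, y),
                    )
                )
            elif is_hsv_column:
                sites.append(
                    VariantSite(
                        locus_id=composition.locus_id,
                        position=p + 1,
                        category="HSV",
                        subgenome="between",
                        alleles=(x, y),
                        collapsed_class=collapse_variant_class(x, y),
                    )
                )
            else:  # unreachable for well-formed input
                sites.append(
                    VariantSite(
                        locus_id=composition.locus_id,
                        position=p + 1,
                        category="unresolved",
                        subgenome=None,
                        alleles=None,
                        note="ambiguity not explained by copy structure",
                    )
                )
            continue

        if len(distinct) == 1:
            # uniform panel that disagrees with the composition prediction
            sites.append(
                VariantSite(
                    locus_id=composition.locus_id,
                    position=p + 1,
                    category="unresolved",
                    subgenome=None,
                    alleles=None,
                    note="fixed difference vs inferred composition",
                )
            )
            continue

        explanations = _try_snp(copies, variety_letters)
        if not explanations:
            sites.append(
                VariantSite(
                    locus_id=composition.locus_id,
                    position=p + 1,
                    category="unresolved",
                    subgenome=None,
                    alleles=None,
                    note="segregating column not attributable to one copy",
                )
            )
            continue
        genomes = {g for g, _, _ in explanations}
        genome, calls, alleles = explanations[0]
        subgenome = genome if len(genomes) == 1 else None
        counts = {a: sum(1 for c in calls.values() if c == a) for a in alleles}
        minor = min(counts.values())
        sites.append(
            VariantSite(
                locus_id=composition.locus_id,
                position=p + 1,
                category="SNP",
                subgenome=subgenome,
                alleles=alleles,
                collapsed_class=collapse_variant_class(*alleles),
                hsv_coincident=is_hsv_column,
                n_varieties_minor=minor,
                calls=calls,
            )
        )
    return sites


def sites_to_table(sites: Sequence[VariantSite]) -> pd.DataFrame:
    """Variant sites as an exportable table."""
    rows = []
    for s in sites:
        rows.append(
            {
                "locus": s.locus_id,
                "pos_1based": s.position,
                "category": s.category,
                "subgenome": s.subgenome if s.subgenome else "",
                "alleles": "/".join(s.alleles) if s.alleles else "",
                "collapsed_class": s.collapsed_class or "",
                "hsv_coincident": s.hsv_coincident,
                "n_varieties_minor": (
                    s.n_varieties_minor if s.n_varieties_minor is not None else ""
                ),
                "note": s.note,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus",
            "pos_1based",
            "category",
            "subgenome",
            "alleles",
            "collapsed_class",
            "hsv_coincident",
            "n_varieties_minor",
            "note",
        ],
    )
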