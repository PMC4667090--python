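"""Synthetic amplicon panels with known ground truth.

Generates two diploid progenitor genomes (A and B) locus by locus, derives a
tetraploid variety panel from them (with optional subgenome sequence
elimination, paralog pairs, and segregating SNPs), and simulates a
recombinant-inbred-line population. Every planted variable position is
recorded as a :class:`TrueVariant`, so downstream classification can be
scored against exact truth.

Coordinates are 0-based internally and 1-based in written reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")

SNP = "SNP"
HSV = "HSV"
PSV = "PSV"


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the progenitor/tetraploid panel simulation.

    Rates are per-bp planting probabilities; elimination probabilities are
    per-copy loss probabilities after polyploidisation, with multi-copy loci
    at least as likely to lose copies as single-copy loci.
    """

    n_loci: int
    locus_length_bp: int = 600
    hsv_rate: float = 1.0 / 50.0
    psv_dup_prob: float = 0.1
    psv_rate: float = 1.0 / 50.0
    snp_rate: float = 1.0 / 1500.0
    elimination_prob_single: float = 0.05
    elimination_prob_multi: float = 0.15
    n_varieties: int = 96
    minor_allele_freq_range: tuple[float, float] = (0.05, 0.5)
    hsv_coincident_fraction: float = 0.0
    gss_fraction: float = 0.5
    sequencing_fail_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if self.locus_length_bp <= 0:
            raise ValueError("locus_length_bp must be positive")
        for name in (
            "hsv_rate",
            "psv_dup_prob",
            "psv_rate",
            "snp_rate",
            "elimination_prob_single",
            "elimination_prob_multi",
            "hsv_coincident_fraction",
            "gss_fraction",
            "sequencing_fail_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.elimination_prob_multi < self.elimination_prob_single:
            raise ValueError(
                "elimination_prob_multi must be >= elimination_prob_single"
            )
        lo, hi = self.minor_allele_freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("minor_allele_freq_range must lie in (0, 0.5]")
        if self.n_varieties <= 0:
            raise ValueError("n_varieties must be positive")


@dataclass(frozen=True)
class RILConfig:
    """Parameters of the recombinant-inbred-line simulation."""

    n_lines: int = 142
    n_markers: int = 10
    selfing_generations: int = 6
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines <= 0:
            raise ValueError("n_lines must be positive")
        if self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# truth records


@dataclass(frozen=True)
class TrueVariant:
    """Ground truth for one planted variable position."""

    locus_id: str
    position: int  # 0-based
    category: str  # SNP | HSV | PSV
    subgenome: str  # A | B | between | within-A | within-B
    alleles: tuple[str, str]
    panel_counts: dict[str, int] | None = None
    hsv_coincident: bool = False

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a == b or {a, b} - set(BASES):
            raise ValueError(f"alleles must be two distinct canonical bases: {self.alleles}")
        if self.category == SNP:
            if self.panel_counts is None:
                raise ValueError("SNP truth requires panel_counts")


@dataclass
class LocusModel:
    """True copy structure of one locus across both progenitor genomes."""

    locus_id: str
    source_class: str  # EST | GSS
    a_copies: list[str]
    b_copies: list[str]
    retained_in_tetraploid: list[str] = field(default_factory=list)
    truth_sites: list[TrueVariant] = field(default_factory=list)
    sequenceable: bool = True

    @property
    def copy_labels(self) -> list[str]:
        labels = [f"A{i + 1}" for i in range(len(self.a_copies))]
        labels += [f"B{i + 1}" for i in range(len(self.b_copies))]
        return labels

    def copy_sequence(self, label: str) -> str:
        copies = self.a_copies if label[0] == "A" else self.b_copies
        return copies[int(label[1:]) - 1]

    @property
    def is_multi_copy(self) -> bool:
        return len(self.a_copies) + len(self.b_copies) > 2


@dataclass
class PanelTruth:
    """A simulated tetraploid panel: loci with retained copies, per-variety
    copy sequences, and the completed ground-truth variant list."""

    loci: list[LocusModel]
    variety_ids: list[str]
    # (locus_id, variety_id) -> {copy_label: sequence}
    sequences: dict[tuple[str, str], dict[str, str]]

    def variety_copies(self, locus_id: str, variety_id: str) -> dict[str, str]:
        return self.sequences[(locus_id, variety_id)]

    def observable_sites(self, locus: LocusModel) -> list[TrueVariant]:
        """Truth sites visible in the tetraploid given the retained copies.

        HSVs need at least one copy from each genome, PSVs need both paralogs
        of their genome; SNPs are planted on retained copies, hence always
        visible.
        """
        retained = set(locus.retained_in_tetraploid)
        has_a = any(lab.startswith("A") for lab in retained)
        has_b = any(lab.startswith("B") for lab in retained)
        out = []
        for site in locus.truth_sites:
            if site.category == HSV:
                if has_a and has_b:
                    out.append(site)
            elif site.category == PSV:
                genome = site.subgenome[-1]  # within-A -> A
                if {f"{genome}1", f"{genome}2"} <= retained:
                    out.append(site)
            else:
                out.append(site)
        return out


# ---------------------------------------------------------------------------
# generators


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    others = [b for b in BASES if b != base]
    return others[rng.integers(len(others))]


def simulate_progenitors(cfg: SimConfig) -> list[LocusModel]:
    """Generate diploid progenitor loci with planted HSVs and paralog PSVs.

    Per locus an ancestral sequence is drawn uniformly; A/B copies diverge at
    positions sampled at ``hsv_rate``; each genome independently gains a
    paralog pair (probability ``psv_dup_prob``) diverged at ``psv_rate``.
    Planted positions are disjoint within a locus so that every variable
    column maps to exactly one truth record. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    length = cfg.locus_length_bp
    loci: list[LocusModel] = []
    for i in range(cfg.n_loci):
        locus_id = f"L{i + 1:04d}"
        source = "GSS" if rng.random() < cfg.gss_fraction else "EST"
        ancestral = _random_sequence(rng, length)

        n_hsv = rng.binomial(length, cfg.hsv_rate)
        dup_a = rng.random() < cfg.psv_dup_prob
        dup_b = rng.random() < cfg.psv_dup_prob
        n_psv_a = rng.binomial(length, cfg.psv_rate) if dup_a else 0
        n_psv_b = rng.binomial(length, cfg.psv_rate) if dup_b else 0
        n_total = min(n_hsv + n_psv_a + n_psv_b, length)
        positions = rng.choice(length, size=n_total, replace=False)
        hsv_pos = positions[:n_hsv]
        psv_a_pos = positions[n_hsv : n_hsv + n_psv_a]
        psv_b_pos = positions[n_hsv + n_psv_a :]

        seq_a = list(ancestral)
        seq_b = list(ancestral)
        truth: list[TrueVariant] = []
        for pos in sorted(hsv_pos):
            derived = _mutate_base(rng, ancestral[pos])
            if rng.random() < 0.5:
                seq_a[pos] = derived
            else:
                seq_b[pos] = derived
            truth.append(
                TrueVariant(
                    locus_id, int(pos), HSV, "between", (seq_a[pos], seq_b[pos])
                )
            )

        a_copies = ["".join(seq_a)]
        b_copies = ["".join(seq_b)]
        for genome, base_seq, psv_pos, copies in (
            ("A", seq_a, psv_a_pos, a_copies),
            ("B", seq_b, psv_b_pos, b_copies),
        ):
            if genome == "A" and not dup_a:
                continue
            if genome == "B" and not dup_b:
                continue
            paralog = list(base_seq)
            for pos in sorted(psv_pos):
                paralog[pos] = _mutate_base(rng, base_seq[pos])
                truth.append(
                    TrueVariant(
                        locus_id, int(pos), PSV, f"within-{genome}",
                        (base_seq[pos], paralog[pos]),
                    )
                )
            copies.append("".join(paralog))

        loci.append(
            LocusModel(
                locus_id=locus_id,
                source_class=source,
                a_copies=a_copies,
                b_copies=b_copies,
                truth_sites=sorted(truth, key=lambda t: t.position),
                sequenceable=bool(rng.random() >= cfg.sequencing_fail_prob),
            )
        )
    return loci


def simulate_tetraploid_panel(
    loci: Sequence[LocusModel], cfg: SimConfig
) -> PanelTruth:
    """Derive a tetraploid variety panel from progenitor loci.

    Each copy is dropped independently with the class-appropriate elimination
    probability (loci carrying a paralog pair use ``elimination_prob_multi``);
    at least one copy is always retained. SNPs are planted on retained copies
    at ``snp_rate``; minor-allele variety counts are drawn from
    ``minor_allele_freq_range``. A fraction ``hsv_coincident_fraction`` of
    SNPs is planted at retained HSV columns and flagged ``hsv_coincident``.
    """
    if not loci:
        raise ValueError("empty locus list")
    rng = np.random.default_rng([cfg.seed, 1])
    length = cfg.locus_length_bp
    variety_ids = [f"V{i + 1:03d}" for i in range(cfg.n_varieties)]
    sequences: dict[tuple[str, str], dict[str, str]] = {}
    out_loci: list[LocusModel] = []

    for locus in loci:
        locus = dataclasses.replace(
            locus,
            a_copies=list(locus.a_copies),
            b_copies=list(locus.b_copies),
            truth_sites=list(locus.truth_sites),
        )
        labels = locus.copy_labels
        p_drop = (
            cfg.elimination_prob_multi
            if locus.is_multi_copy
            else cfg.elimination_prob_single
        )
        dropped = rng.random(len(labels)) < p_drop
        retained = [lab for lab, d in zip(labels, dropped) if not d]
        if not retained:
            retained = [labels[rng.integers(len(labels))]]
        locus.retained_in_tetraploid = retained

        taken = {t.position for t in locus.truth_sites}
        free = np.array(sorted(set(range(length)) - taken), dtype=int)
        retained_hsv = [
            t
            for t in locus.truth_sites
            if t.category == HSV
            and any(lab.startswith("A") for lab in retained)
            and any(lab.startswith("B") for lab in retained)
        ]

        n_snp = rng.binomial(length, cfg.snp_rate)
        snp_records: list[tuple[int, str, str, str, set[str], bool]] = []
        used_hsv: set[int] = set()
        for _ in range(n_snp):
            coincident = (
                bool(retained_hsv)
                and rng.random() < cfg.hsv_coincident_fraction
            )
            if coincident:
                candidates = [
                    t for t in retained_hsv if t.position not in used_hsv
                ]
                if not candidates:
                    coincident = False
            if coincident:
                site = candidates[rng.integers(len(candidates))]
                pos = site.position
                used_hsv.add(pos)
            else:
                if free.size == 0:
                    break
                idx = rng.integers(free.size)
                pos = int(free[idx])
                free = np.delete(free, idx)
            copy_label = retained[rng.integers(len(retained))]
            major = locus.copy_sequence(copy_label)[pos]
            minor = _mutate_base(rng, major)
            lo, hi = cfg.minor_allele_freq_range
            maf = rng.uniform(lo, hi)
            n_minor = max(1, int(round(maf * cfg.n_varieties)))
            # keep the minor allele strictly in the minority so the panel
            # modal letter always reflects the major allele
            n_minor = min(n_minor, max(1, (cfg.n_varieties - 1) // 2))
            carriers = set(
                rng.choice(cfg.n_varieties, size=n_minor, replace=False).tolist()
            )
            snp_records.append((pos, copy_label, major, minor, carriers, coincident))
            locus.truth_sites.append(
                TrueVariant(
                    locus.locus_id,
                    pos,
                    SNP,
                    copy_label[0],
                    (major, minor),
                    panel_counts={
                        major: cfg.n_varieties - n_minor,
                        minor: n_minor,
                    },
                    hsv_coincident=coincident,
                )
            )
        locus.truth_sites.sort(key=lambda t: (t.position, t.category))

        base_copies = {lab: locus.copy_sequence(lab) for lab in retained}
        for v_idx, variety in enumerate(variety_ids):
            copies = dict(base_copies)
            for pos, copy_label, _major, minor, carriers, _c in snp_records:
                if v_idx in carriers:
                    seq = copies[copy_label]
                    copies[copy_label] = seq[:pos] + minor + seq[pos + 1 :]
            sequences[(locus.locus_id, variety)] = copies
        out_loci.append(locus)

    return PanelTruth(loci=out_loci, variety_ids=variety_ids, sequences=sequences)


def simulate_ril(
    parent_calls_1: Sequence[str],
    parent_calls_2: Sequence[str],
    cfg: RILConfig,
) -> pd.DataFrame:
    """Simulate an unlinked-marker RIL genotype matrix (markers x lines).

    Calls are ``a`` (parent-1 allele), ``b`` (parent-2 allele), ``h``
    (residual heterozygote, expected fraction ``(1/2)**selfing_generations``)
    or ``NA`` (missing at ``missing_rate``). Markers at which the parents do
    not differ are monomorphic in the offspring.
    """
    if len(parent_calls_1) != len(parent_calls_2):
        raise ValueError("parent call vectors must have equal length")
    p1 = np.asarray(parent_calls_1, dtype=object)
    p2 = np.asarray(parent_calls_2, dtype=object)
    segregating = p1 != p2
    if not segregating.any():
        raise ValueError("parents are identical at every marker; nothing segregates")
    rng = np.random.default_rng(cfg.seed)
    n_markers = len(p1)
    het_prob = 0.5**cfg.selfing_generations
    calls = np.empty((n_markers, cfg.n_lines), dtype=object)
    for m in range(n_markers):
        if not segregating[m]:
            calls[m, :] = "a"
            continue
        u = rng.random(cfg.n_lines)
        het = u < het_prob
        from_p2 = rng.random(cfg.n_lines) < 0.5
        calls[m, :] = np.where(het, "h", np.where(from_p2, "b", "a"))
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = "NA"
    markers = [f"M{m + 1:03d}" for m in range(n_markers)]
    lines = [f"RIL{i + 1:03d}" for i in range(cfg.n_lines)]
    return pd.DataFrame(calls, index=markers, columns=lines)


# ---------------------------------------------------------------------------
# writers


def write_panel_fasta(panel: PanelTruth, path: Path | str) -> None:
    """Multi-FASTA of every variety's retained copies: id = locus|variety|copy."""
    path = Path(path)
    with path.open("w") as fh:
        for locus in panel.loci:
            for variety in panel.variety_ids:
                for label, seq in panel.variety_copies(
                    locus.locus_id, variety
                ).items():
                    fh.write(f">{locus.locus_id}|{variety}|{label}\n{seq}\n")


def write_progenitor_fasta(loci: Sequence[LocusModel], path: Path | str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for locus in loci:
            for label in locus.copy_labels:
                genotype = "progA" if label[0] == "A" else "progB"
                fh.write(
                    f">{locus.locus_id}|{genotype}|{label}\n"
                    f"{locus.copy_sequence(label)}\n"
                )


def truth_to_table(loci: Sequence[LocusModel]) -> pd.DataFrame:
    """Truth sites as a table with 1-based positions."""
    rows = []
    for locus in loci:
        for t in locus.truth_sites:
            counts = (
                ",".join(f"{a}:{n}" for a, n in sorted(t.panel_counts.items()))
                if t.panel_counts
                else ""
            )
            rows.append(
                {
                    "locus": t.locus_id,
                    "pos_1based": t.position + 1,
                    "category": t.category,
                    "subgenome": t.subgenome,
                    "alleles": "/".join(t.alleles),
                    "counts": counts,
                    "hsv_coincident": t.hsv_coincident,
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
            "counts",
            "hsv_coincident",
        ],
    )


def write_manifest(path: Path | str, **entries: object) -> None:
    Path(path).write_text(json.dumps(entries, indent=2, default=str) + "\n")
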