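"""Marker panel statistics.

Polymorphism information content (PIC), variant densities, strand-collapsed
variant-class spectra, pairwise LD r-squared for multi-SNP fragments, and
1:1 segregation chi-square tests for RIL populations.

Denominator convention
----------------------
Allele frequencies default to ``count / panel_size`` (the full genotyping
panel, normally 96), NOT ``count / n_typed``. Markers with failed calls thus
have allele frequencies summing below 1, which deflates their PIC relative to
the typed-only convention. This is the convention that reproduces the bundled
published marker table; pass ``denominator="typed"`` for the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import COLLAPSED_CLASSES, VariantSite


@dataclass(frozen=True)
class MarkerPanel:
    """Per-variety categorical calls for one biallelic marker."""

    marker_id: str
    calls: tuple[str | None, ...]  # allele symbol or None (missing)
    panel_size: int = 96

    def __post_init__(self) -> None:
        if len(self.calls) != self.panel_size:
            raise ValueError("calls length must equal panel_size")

    @property
    def allele_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.calls:
            if c is not None:
                counts[c] = counts.get(c, 0) + 1
        return counts

    @property
    def n_missing(self) -> int:
        return sum(1 for c in self.calls if c is None)


@dataclass(frozen=True)
class MarkerStats:
    marker_id: str
    k: int
    frequencies: tuple[float, ...]
    pic: float
    pic_rounded: float

    def __post_init__(self) -> None:
        # the 1 - 1/k upper bound only binds when the frequencies sum to 1
        # (no missing calls under the panel-denominator convention)
        if not 0.0 <= self.pic <= 1.0:
            raise ValueError(f"PIC {self.pic} outside [0, 1]")


@dataclass(frozen=True)
class LDResult:
    marker_pair: tuple[str, str]
    r2: float
    n_complete: int
    defined: bool = True


@dataclass(frozen=True)
class SegregationTest:
    marker_id: str
    observed: tuple[int, int]
    chi2: float
    df: int
    p: float
    distorted: bool


def pic(
    counts: Sequence[int],
    panel_size: int,
    marker_id: str = "",
    denominator: str = "panel",
) -> MarkerStats:
    """PIC = 1 - sum(p_i^2) from per-allele variety counts.

    ``denominator="panel"`` divides by the panel size (missing varieties
    shrink the frequency sum below 1 — see module docstring);
    ``denominator="typed"`` divides by the number of genotyped varieties.
    """
    if panel_size <= 0:
        raise ValueError("panel_size must be positive")
    counts = list(counts)
    if any(c < 0 for c in counts):
        raise ValueError("negative allele count")
    total = sum(counts)
    if total == 0:
        raise ValueError("no genotyped varieties (all counts zero)")
    if total > panel_size:
        raise ValueError(f"allele counts sum to {total} > panel_size {panel_size}")
    if denominator == "panel":
        denom = panel_size
    elif denominator == "typed":
        if total == 0:
            raise ValueError("no typed varieties")
        denom = total
    else:
        raise ValueError("denominator must be 'panel' or 'typed'")
    freqs = tuple(c / denom for c in counts)
    value = 1.0 - sum(f * f for f in freqs)
    return MarkerStats(
        marker_id=marker_id,
        k=len(counts),
        frequencies=freqs,
        pic=value,
        pic_rounded=round(value, 3),
    )


def pic_from_panel(panel: MarkerPanel, denominator: str = "panel") -> MarkerStats:
    counts = [n for _, n in sorted(panel.allele_counts.items())]
    return pic(counts, panel.panel_size, panel.marker_id, denominator)


def summarize_markers(
    table: pd.DataFrame,
    panel_size: int = 96,
    group_column: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker PIC report plus per-group min/max/mean summary.

    ``table`` needs columns ``marker``, ``count1``, ``count2`` and the group
    column (e.g. EST vs GSS).
    """
    if table.empty:
        raise ValueError("empty marker table")
    report = table.copy()
    values = [
        pic((int(r.count1), int(r.count2)), panel_size, str(r.marker)).pic
        for r in table.itertuples()
    ]
    report["pic"] = np.round(values, 3)
    report["pic_unrounded"] = values
    grouped = report.groupby(group_column)["pic_unrounded"]
    summary = pd.DataFrame(
        {
            "n_markers": grouped.size(),
            "min_pic": grouped.min().round(3),
            "max_pic": grouped.max().round(3),
            "mean_pic": grouped.mean().round(3),
        }
    )
    return report, summary


def variant_density(n_variants: int, total_bp: int) -> float:
    """Base pairs per variant (the "one variant every N bp" figure)."""
    if n_variants < 0 or total_bp <= 0:
        raise ValueError("need total_bp > 0 and n_variants >= 0")
    if n_variants == 0:
        raise ZeroDivisionError("no variants: density undefined, report 'no variants'")
    return total_bp / n_variants


def class_spectrum(sites: Sequence[VariantSite]) -> pd.DataFrame:
    """Counts and proportions of sites over the four strand-collapsed classes."""
    if not sites:
        raise ValueError("no sites given")
    counts = {cls: 0 for cls in COLLAPSED_CLASSES}
    for s in sites:
        if s.collapsed_class is None:
            raise ValueError(f"site at {s.locus_id}:{s.position} has no collapsed class")
        counts[s.collapsed_class] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "count": list(counts.values()),
            "proportion": [c / total for c in counts.values()],
        },
        index=pd.Index(counts.keys(), name="collapsed_class"),
    )


def _encode_biallelic(calls: Sequence[str | None]) -> np.ndarray:
    alleles = sorted({c for c in calls if c is not None})
    if len(alleles) > 2:
        raise ValueError(f"marker is not biallelic: alleles {alleles}")
    code = {a: float(i) for i, a in enumerate(alleles)}
    return np.array(
        [code[c] if c is not None else np.nan for c in calls], dtype=float
    )


def ld_r2(
    calls_x: Sequence[str | None],
    calls_y: Sequence[str | None],
    marker_x: str = "x",
    marker_y: str = "y",
) -> LDResult:
    """Squared Pearson correlation of 0/1-coded calls over pairwise-complete
    varieties. Symmetric and invariant to allele relabeling; flagged undefined
    when either marker is monomorphic among complete pairs."""
    if len(calls_x) != len(calls_y):
        raise ValueError("call vectors must have equal length")
    x = _encode_biallelic(calls_x)
    y = _encode_biallelic(calls_y)
    complete = ~(np.isnan(x) | np.isnan(y))
    n = int(complete.sum())
    if n < 2:
        raise ValueError("need at least two pairwise-complete varieties")
    xc, yc = x[complete], y[complete]
    if np.all(xc == xc[0]) or np.all(yc == yc[0]):
        return LDResult((marker_x, marker_y), float("nan"), n, defined=False)
    r = np.corrcoef(xc, yc)[0, 1]
    return LDResult((marker_x, marker_y), float(r * r), n, defined=True)


def marker_selection(
    fragment: Sequence[tuple[int, str, Sequence[str | None]]],
    tol: float = 1e-9,
) -> list[str]:
    """Reduce a multi-SNP fragment to one marker per full-LD class.

    ``fragment`` is a list of (position, marker_id, calls). SNPs whose
    pairwise r-squared equals 1 are redundant for genotyping; the first by
    position within each r2=1 equivalence class is kept.
    """
    if not fragment:
        raise ValueError("fragment contains no SNPs")
    ordered = sorted(fragment, key=lambda t: t[0])
    selected: list[tuple[str, Sequence[str | None]]] = []
    kept_ids: list[str] = []
    for _pos, marker_id, calls in ordered:
        redundant = False
        for _kept_id, kept_calls in selected:
            result = ld_r2(kept_calls, calls)
            if result.defined and result.r2 >= 1.0 - tol:
                redundant = True
                break
        if not redundant:
            selected.append((marker_id, calls))
            kept_ids.append(marker_id)
    return kept_ids


def chi_square_1to1(
    counts: tuple[int, int], alpha: float = 0.05, marker_id: str = ""
) -> SegregationTest:
    """Goodness-of-fit test of a 1:1 segregation ratio (df = 1)."""
    o1, o2 = counts
    total = o1 + o2
    if total <= 0:
        raise ValueError("zero total count")
    expected = total / 2.0
    chi2 = (o1 - expected) ** 2 / expected + (o2 - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationTest(
        marker_id=marker_id,
        observed=(o1, o2),
        chi2=float(chi2),
        df=1,
        p=p,
        distorted=p < alpha,
    )


def load_reference_marker_table() -> pd.DataFrame:
    """Bundled allele-count table for a published 96-variety peanut SNP panel
    (33 biallelic HRM markers, EST- and GSS-derived)."""
    with resources.files("tetrasnp.data").joinpath(
        "peanut_marker_counts.tsv"
    ).open() as fh:
        table = pd.read_csv(fh, sep="\t")
    table["group"] = table["marker"].str.split("-").str[0]
    return table
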