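"""Simplified high-resolution-melting (HRM) genotyping engine.

Melting is modeled as a two-state transition per duplex species: fluorescence
is a weighted sum of logistic sigmoids centered at each species' melting
temperature on the instrument grid (72.0-90.0 degC, 0.1 degC steps, 181
points). A heterozygous sample re-anneals into two homoduplexes and two
heteroduplexes; heteroduplex Tm is lowered by a per-mismatch penalty, which
creates the early-melting shoulder that separates genotype clusters after
curve normalization and difference plotting.

The signal model (logistic transition, width 0.8 degC, 4.0 degC/mismatch
penalty, equal re-annealing weights) is a deliberate simplification chosen so
that a single SNP stays resolvable on the 0.1 degC grid even under heavy
per-point noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import uniform_filter1d
from scipy.spatial.distance import pdist

GRID_START = 72.0
GRID_STOP = 90.0
GRID_POINTS = 181

#: the melt protocol grid: 72.0-90.0 degC inclusive, 0.1 degC steps
TEMP_GRID = np.round(np.linspace(GRID_START, GRID_STOP, GRID_POINTS), 1)

DEFAULT_WIDTH = 0.8  # degC, logistic transition width
# degC Tm drop per heteroduplex mismatch; 4.0 keeps the heterozygote cluster
# separable from homozygotes even at per-point noise of 10% of curve range
DEFAULT_MISMATCH_PENALTY = 4.0
DEFAULT_SALT_OFFSET = 12.0  # degC, brings typical short amplicons onto the grid
DEFAULT_PRE_WINDOW = (72.5, 75.5)
DEFAULT_POST_WINDOW = (87.0, 90.0)
DEFAULT_CLUSTER_THRESHOLD = 24.0  # normalized-% units, complete linkage cut


@dataclass(frozen=True)
class MeltCurve:
    sample_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence grids differ in length")


@dataclass(frozen=True)
class DuplexSpecies:
    seq_a: str
    seq_b: str
    weight: float
    tm: float
    transition_width: float = DEFAULT_WIDTH


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    cluster_id: int
    reference_distance: float


def predict_tm(seq: str, salt_offset: float = DEFAULT_SALT_OFFSET) -> float:
    """Melting temperature from GC content and length:
    Tm = 81.5 + 0.41*GC% - 675/length - salt_offset.

    Requires >= 20 canonical bases; IUPAC ambiguity letters are rejected
    (expand per-allele amplicons first).
    """
    seq = seq.upper()
    if len(seq) < 20:
        raise ValueError("amplicon too short for Tm prediction (< 20 bp)")
    invalid = set(seq) - set("ACGT")
    if invalid:
        raise ValueError(
            f"ambiguity letters not allowed in Tm prediction: {sorted(invalid)}"
        )
    gc_percent = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
    return 81.5 + 0.41 * gc_percent - 675.0 / len(seq) - salt_offset


def sample_duplexes(
    alleles: tuple[str, str],
    amplicons: Mapping[str, str],
    mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
    width: float = DEFAULT_WIDTH,
    salt_offset: float = DEFAULT_SALT_OFFSET,
) -> list[DuplexSpecies]:
    """Duplex species formed by a sample's allele pair after re-annealing.

    Homozygotes form a single homoduplex (weight 1). Heterozygotes form two
    homoduplexes and two heteroduplexes (weight 1/4 each); heteroduplex Tm is
    the homoduplex mean minus ``mismatch_penalty`` per mismatched base.
    """
    a1, a2 = alleles
    if a1 not in amplicons or a2 not in amplicons:
        raise ValueError("no amplicon sequence for one of the alleles")
    if a1 == a2:
        seq = amplicons[a1]
        return [DuplexSpecies(seq, seq, 1.0, predict_tm(seq, salt_offset), width)]
    seq1, seq2 = amplicons[a1], amplicons[a2]
    if len(seq1) != len(seq2):
        raise ValueError("allele amplicons must have equal length")
    tm1 = predict_tm(seq1, salt_offset)
    tm2 = predict_tm(seq2, salt_offset)
    n_mismatch = sum(1 for x, y in zip(seq1, seq2) if x != y)
    het_tm = 0.5 * (tm1 + tm2) - mismatch_penalty * n_mismatch
    return [
        DuplexSpecies(seq1, seq1, 0.25, tm1, width),
        DuplexSpecies(seq2, seq2, 0.25, tm2, width),
        DuplexSpecies(seq1, seq2, 0.25, het_tm, width),
        DuplexSpecies(seq2, seq1, 0.25, het_tm, width),
    ]


def simulate_melt_curve(
    species: Sequence[DuplexSpecies],
    noise_sd: float = 0.0,
    seed: int | None = None,
    sample_id: str = "",
    grid: np.ndarray = TEMP_GRID,
) -> MeltCurve:
    """F(T) = sum_d w_d * logistic((tm_d - T)/width_d) + Gaussian noise.

    Noiseless curves are monotone non-increasing in temperature; each species
    contributes a sigmoid with midpoint F = w/2 at T = tm.
    """
    if not species:
        raise ValueError("empty species list")
    weights = sum(s.weight for s in species)
    if abs(weights - 1.0) > 1e-6:
        raise ValueError(f"species weights must sum to 1, got {weights}")
    signal = np.zeros_like(grid, dtype=float)
    for s in species:
        signal += s.weight / (1.0 + np.exp((grid - s.tm) / s.transition_width))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=grid.shape)
    return MeltCurve(sample_id=sample_id, temperatures=grid, fluorescence=signal)


def _window_baseline(
    curve: MeltCurve, window: tuple[float, float]
) -> np.ndarray:
    lo, hi = window
    mask = (curve.temperatures >= lo - 1e-9) & (curve.temperatures <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"window {window} selects fewer than 2 grid points")
    coeffs = np.polyfit(curve.temperatures[mask], curve.fluorescence[mask], 1)
    # evaluate the fitted line inside the window and hold it constant beyond
    # the window edges: extrapolating a line fitted on a 2 degC window across
    # the whole grid amplifies per-point noise by more than an order of
    # magnitude, which would swamp the genotype signal
    t = np.clip(curve.temperatures, lo, hi)
    return np.polyval(coeffs, t)


def _window_mean(curve: MeltCurve, window: tuple[float, float]) -> float:
    lo, hi = window
    mask = (curve.temperatures >= lo - 1e-9) & (curve.temperatures <= hi + 1e-9)
    return float(np.mean(curve.fluorescence[mask]))


def normalize_and_difference(
    curves: Sequence[MeltCurve],
    reference: str,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Two-window baseline normalization (100% -> 0%) and difference plot.

    Linear baselines are fitted on the pre- and post-melt windows; each curve
    is rescaled to percent-melted units and the reference sample's normalized
    curve is subtracted. Returns (normalized, difference) keyed by sample id;
    the reference maps to the zero curve.
    """
    if pre_window[1] >= post_window[0]:
        raise ValueError("pre and post windows must not overlap")
    normalized: dict[str, np.ndarray] = {}
    for curve in curves:
        upper = _window_baseline(curve, pre_window)
        lower = _window_baseline(curve, post_window)
        span = upper - lower
        if np.min(span) < 1e-9:
            # noisy window fits can make the extrapolated lines cross; fall
            # back to flat baselines at the window means
            upper = np.full_like(span, _window_mean(curve, pre_window))
            lower = np.full_like(span, _window_mean(curve, post_window))
            span = upper - lower
            if np.min(span) < 1e-9:
                raise ValueError(
                    f"degenerate normalization windows for sample {curve.sample_id}"
                )
        normalized[curve.sample_id] = (
            100.0 * (curve.fluorescence - lower) / span
        )
    if reference not in normalized:
        raise KeyError(f"reference sample {reference!r} not among curves")
    ref = normalized[reference]
    difference = {sid: norm - ref for sid, norm in normalized.items()}
    return normalized, difference


def cluster_genotypes(
    difference: Mapping[str, np.ndarray],
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    smooth_points: int = 31,
    grid: np.ndarray = TEMP_GRID,
    region: tuple[float, float] = (DEFAULT_PRE_WINDOW[1], DEFAULT_POST_WINDOW[0]),
) -> list[GenotypeCall]:
    """Agglomerative (complete-linkage) clustering of difference curves.

    Distance is the max-abs difference between curves after smoothing
    (``smooth_points`` grid points ~ 2 degC) and restriction to the melt
    ``region`` between the normalization windows, where the genotype signal
    lives (the pinned plateaus carry only amplified noise). Clusters are the
    cut at ``threshold``; labels are ordered by cluster size descending
    (0 = largest), ties broken by first sample appearance.
    """
    samples = list(difference)
    if len(samples) < 2:
        raise ValueError("need at least two samples to cluster")
    matrix = np.vstack([difference[s] for s in samples])
    if smooth_points > 1:
        matrix = uniform_filter1d(matrix, size=smooth_points, axis=1, mode="nearest")
    if region is not None:
        mask = (grid >= region[0]) & (grid <= region[1])
        if mask.sum() >= 2:
            matrix = matrix[:, mask]
    condensed = pdist(matrix, metric="chebyshev")
    tree = linkage(condensed, method="complete")
    raw_labels = fcluster(tree, t=threshold, criterion="distance")

    order: dict[int, tuple[int, int]] = {}
    for raw in np.unique(raw_labels):
        members = np.nonzero(raw_labels == raw)[0]
        order[int(raw)] = (-len(members), int(members[0]))
    relabel = {
        raw: new for new, raw in enumerate(sorted(order, key=order.__getitem__))
    }
    return [
        GenotypeCall(
            sample_id=s,
            cluster_id=relabel[int(raw_labels[i])],
            reference_distance=float(np.max(np.abs(matrix[i]))),
        )
        for i, s in enumerate(samples)
    ]


def hrm_qc_filter(
    traces: Mapping[str, np.ndarray],
    cycles: np.ndarray,
    window: float = 5.0,
    threshold_frac: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Exclude samples with significantly early or late amplification.

    The crossing cycle is where a trace first reaches ``threshold_frac`` of
    its own plateau (linear interpolation); samples whose crossing cycle
    deviates from the panel median by more than ``window`` cycles are excluded
    and should be treated as missing calls downstream. Returns
    (retained, excluded) sample id lists.
    """
    crossing: dict[str, float] = {}
    for sample, signal in traces.items():
        level = threshold_frac * np.max(signal)
        above = np.nonzero(signal >= level)[0]
        if above.size == 0:
            crossing[sample] = float("inf")
            continue
        i = int(above[0])
        if i == 0:
            crossing[sample] = float(cycles[0])
        else:
            frac = (level - signal[i - 1]) / (signal[i] - signal[i - 1])
            crossing[sample] = float(cycles[i - 1] + frac * (cycles[i] - cycles[i - 1]))
    finite = [c for c in crossing.values() if np.isfinite(c)]
    median = float(np.median(finite)) if finite else float("inf")
    retained, excluded = [], []
    for sample in traces:
        if abs(crossing[sample] - median) <= window:
            retained.append(sample)
        else:
            excluded.append(sample)
    return retained, excluded


def curves_to_long_frame(curves: Sequence[MeltCurve]):
    """Long-format (sample, temperature, fluorescence) table for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample": np.repeat(
                [c.sample_id for c in curves], [len(c.temperatures) for c in curves]
            ),
            "temperature": np.concatenate([c.temperatures for c in curves]),
            "fluorescence": np.concatenate([c.fluorescence for c in curves]),
        }
    )
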