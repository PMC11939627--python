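"""Distribution-level adhesion statistics.

At the optimal phase t*, the normalized motion-disparity values inside the
pericoronary ROI are binned into an equal-width histogram on [0, 1]. Two
shape statistics summarize it:

* peak ratio ``PR = Hmax / Halpha`` — the maximum bin count over the count of
  the bin sitting at the alpha-percent position of the bin axis (default
  25%). Sharply decaying distributions (restricted motion, adhesion) give
  large PR; broad mid-peaked distributions (free sliding) give small PR.
* distribution width index ``DWI = Nnonzero / Ntotal`` — the fraction of
  occupied bins; concentrated distributions give low DWI.

A two-sample Kolmogorov-Smirnov matrix across the nine phases validates the
temporal structure of the disparity distributions, and an exact Mann-Whitney
U test compares metric values between patient groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .errors import EmptyHistogramError, InsufficientSamplesError
from .io import EXPECTED_PHASES


@dataclass
class DisparityHistogram:
    """Equal-width histogram of normalized disparity values on [0, 1]."""

    edges: np.ndarray
    counts: np.ndarray
    alpha_percent: float
    h_max: int = field(init=False)
    h_alpha: int = field(init=False)
    n_nonzero: int = field(init=False)
    n_total: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.edges = np.asarray(self.edges, dtype=float)
        self.n_total = len(self.counts)
        self.h_max = int(self.counts.max())
        self.h_alpha = int(self.counts[self.alpha_bin_index])
        self.n_nonzero = int(np.count_nonzero(self.counts))

    @property
    def alpha_bin_index(self) -> int:
        """Index of the bin at the alpha-percent position of the bin axis
        (the bin covering normalized value alpha/100)."""
        return min(int(np.floor(self.alpha_percent / 100.0 * self.n_total)), self.n_total - 1)

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


@dataclass
class KSMatrix:
    """Pairwise two-sample KS statistics between per-phase distributions."""

    d: np.ndarray
    phase_labels: tuple[int, ...] = EXPECTED_PHASES


@dataclass
class AdhesionReport:
    """Final per-case analysis result."""

    pr: float
    dwi: float
    t_star: int
    t_star_phase_percent: int
    classification: str
    m_t: list[float]
    d_max_mm: float
    h_alpha_raw: int
    n_roi_points: int
    group_p: float | None = None
    config: dict | None = None


def build_histogram(
    normalized_samples: np.ndarray,
    n_bins: int = 100,
    alpha_percent: float = 25.0,
) -> DisparityHistogram:
    """Bin normalized disparity values into ``n_bins`` equal-width bins on
    [0, 1] (last bin right-inclusive, so the value 1.0 is counted)."""
    samples = np.asarray(normalized_samples, dtype=float).ravel()
    if samples.size == 0:
        raise EmptyHistogramError("no samples to bin")
    if samples.min() < 0 or samples.max() > 1:
        raise ValueError("normalized samples must lie in [0, 1]")
    counts, edges = np.histogram(samples, bins=n_bins, range=(0.0, 1.0))
    return DisparityHistogram(edges=edges, counts=counts, alpha_percent=alpha_percent)


def peak_ratio(h: DisparityHistogram) -> float:
    """PR = Hmax / Halpha, with an empty alpha bin guarded as a count of 1
    (sharply decayed histograms would otherwise divide by zero)."""
    return float(h.h_max) / float(max(h.h_alpha, 1))


def distribution_width_index(h: DisparityHistogram) -> float:
    """DWI = Nnonzero / Ntotal, the fraction of occupied bins."""
    return float(h.n_nonzero) / float(h.n_total)


def ks_matrix(per_phase_samples: list[np.ndarray]) -> KSMatrix:
    """Two-sample KS statistic between every pair of phase distributions.

    Only the statistic (sup distance between the empirical CDFs) is kept;
    the matrix is symmetric with a zero diagonal.
    """
    samples = [np.asarray(s, dtype=float).ravel() for s in per_phase_samples]
    for k, s in enumerate(samples):
        if s.size == 0:
            raise InsufficientSamplesError(f"phase index {k} has no samples")
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = stats.ks_2samp(samples[i], samples[j]).statistic
    labels = EXPECTED_PHASES if n == len(EXPECTED_PHASES) else tuple(range(n))
    return KSMatrix(d=d, phase_labels=labels)


def ks_statistic_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Independent brute-force sup |F_x - F_y| over the pooled sample points."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pooled = np.concatenate([x, y])
    fx = np.searchsorted(x, pooled, side="right") / len(x)
    fy = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.abs(fx - fy).max())


def classify(pr: float, dwi: float, config: AnalysisConfig | None = None) -> str:
    """Threshold rule: adhesion when PR is high and DWI low; non-adhesion
    when PR is moderate and DWI high; indeterminate otherwise."""
    config = config or AnalysisConfig()
    if not (np.isfinite(pr) and np.isfinite(dwi)):
        raise ValueError("PR and DWI must be finite")
    if pr > config.pr_adhesion_threshold and dwi < config.dwi_adhesion_threshold:
        return "adhesion"
    if pr < config.pr_nonadhesion_threshold and dwi > config.dwi_nonadhesion_threshold:
        return "non-adhesion"
    return "indeterminate"


def group_test(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney U p-value between two patient groups.

    For the degenerate all-tied input the p-value is 1 (with a warning);
    with ties present the normal approximation with tie correction is used,
    otherwise the exact null distribution.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 cases")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("degenerate all-tied groups; p = 1", stacklevel=2)
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "asymptotic" if has_ties else "exact"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
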