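"""Separate the pooled micro/homology length distribution into TMEJ and SSA
components.

The separation point ("baseline") is the global minimum of a local-linear
(lowess, tricube weights) smooth of the histogram inside a fixed search
range; the two sides are then fitted with independent box-constrained
Poisson components and their overlap across the baseline quantified with
exact Poisson CDF arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import RunConfig, DEFAULT_CONFIG

log = logging.getLogger(__name__)


@dataclass
class MechanismSummary:
    histogram: np.ndarray
    baseline: int
    lambda_tmej: float | None
    lambda_ssa: float | None
    weight_tmej: float
    weight_ssa: float
    overlap_tmej_over_baseline: float
    overlap_ssa_under_baseline: float
    chrom_density: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "histogram": self.histogram.tolist(),
            "baseline": self.baseline,
            "lambda_tmej": self.lambda_tmej,
            "lambda_ssa": self.lambda_ssa,
            "weight_tmej": self.weight_tmej,
            "weight_ssa": self.weight_ssa,
            "overlap_tmej_over_baseline": self.overlap_tmej_over_baseline,
            "overlap_ssa_under_baseline": self.overlap_ssa_under_baseline,
            "chrom_density": {
                c: {m: v.tolist() for m, v in d.items()}
                for c, d in self.chrom_density.items()
            },
        }


def histogram_from_lengths(lengths) -> np.ndarray:
    """Counts per 1-bp length bin (index = length in bp)."""
    lengths = np.asarray(list(lengths), dtype=int)
    if lengths.size == 0:
        return np.zeros(1, dtype=np.int64)
    return np.bincount(lengths)


def find_baseline(histogram: np.ndarray, span: float | None = None,
                  search_range: tuple[int, int] | None = None) -> int:
    """Length at the global minimum of the lowess-smoothed histogram inside
    ``search_range``.

    Requires mass on both sides of 20 bp; without an interior minimum the
    conventional 29-bp fallback is returned with a warning.  The result is
    invariant under uniform scaling of the histogram (no robustifying
    iterations are used, so the smoother is linear in the counts).
    """
    cfg = DEFAULT_CONFIG
    if span is None:
        span = cfg.lowess_span
    if search_range is None:
        search_range = cfg.baseline_range
    hist = np.asarray(histogram, dtype=float)
    if hist.sum() <= 0:
        raise ValueError("all-zero histogram")
    lo, hi = search_range
    below = hist[:min(len(hist), 21)].sum()
    above = hist[21:].sum() if len(hist) > 21 else 0.0
    if below == 0 or above == 0:
        log.warning("histogram lacks mass on both sides of 20 bp; "
                    "falling back to baseline 29")
        return 29
    xs = np.arange(lo, hi + 1, dtype=float)
    ys = np.array([hist[int(x)] if int(x) < len(hist) else 0.0 for x in xs])
    smoothed = lowess(ys, xs, frac=span, it=0, return_sorted=False)
    # the separation point is the dip *between* the two modes: find the
    # upper-component mode first, then the minimum left of it
    upper_from = int(round(0.3 * (hi - lo)))  # skip the lower-component lobe
    upper = smoothed[upper_from:]
    if upper.size == 0 or upper.max() <= 0:
        log.warning("no upper component in smoothed histogram in [%d,%d]; "
                    "falling back to baseline 29", lo, hi)
        return 29
    peak2 = upper_from + int(np.argmax(upper))
    imin = int(np.argmin(smoothed[:peak2 + 1]))
    if imin == 0 or imin == peak2:
        log.warning("no interior minimum of smoothed histogram in [%d,%d]; "
                    "falling back to baseline 29", lo, hi)
        return 29
    return int(xs[imin])


def _fit_side(k: np.ndarray, c: np.ndarray, box: tuple[float, float]
              ) -> tuple[float, float] | None:
    """Weighted least-squares fit of w * Poisson(lam).pmf(k) to counts c.

    Weights are Poisson-variance weights with a floor of 1.  Returns
    (lam, w) or None when the side carries no mass.
    """
    total = c.sum()
    if total <= 0:
        return None
    mean = float((k * c).sum() / total)
    lam0 = float(np.clip(mean, box[0], box[1]))
    mass0 = stats.poisson.pmf(k, lam0).sum()
    w0 = float(total / max(mass0, 1e-12))
    sd = np.sqrt(np.maximum(c, 1.0))

    def resid(params):
        lam, w = params
        return (w * stats.poisson.pmf(k, lam) - c) / sd

    sol = optimize.least_squares(
        resid, x0=[lam0, w0],
        bounds=([box[0], 0.0], [box[1], np.inf]),
    )
    lam, w = float(sol.x[0]), float(sol.x[1])
    return lam, w


def fit_dual_poisson(histogram: np.ndarray, baseline: int,
                     cfg: RunConfig = DEFAULT_CONFIG) -> MechanismSummary:
    """Fit independent Poisson components to the two sides of the baseline.

    lambda boxes are [5, 20] (TMEJ) and [37, 50] (SSA) by default; the
    overlap fractions are exact tail masses of the fitted components across
    the baseline.
    """
    hist = np.asarray(histogram, dtype=float)
    k = np.arange(len(hist))
    left_mask = k <= baseline
    right_mask = ~left_mask

    left = _fit_side(k[left_mask], hist[left_mask], cfg.lambda_tmej_box)
    right = _fit_side(k[right_mask], hist[right_mask], cfg.lambda_ssa_box)

    lam1, w1 = left if left is not None else (None, 0.0)
    lam2, w2 = right if right is not None else (None, 0.0)

    overlap1 = float(stats.poisson.sf(baseline, lam1)) if lam1 is not None else 0.0
    overlap2 = float(stats.poisson.cdf(baseline, lam2)) if lam2 is not None else 0.0

    return MechanismSummary(
        histogram=np.asarray(histogram),
        baseline=baseline,
        lambda_tmej=lam1, lambda_ssa=lam2,
        weight_tmej=w1, weight_ssa=w2,
        overlap_tmej_over_baseline=overlap1,
        overlap_ssa_under_baseline=overlap2,
    )


def chromosome_density(annots: list, genome, window: int | None = None,
                       cfg: RunConfig = DEFAULT_CONFIG) -> dict:
    """Per-mechanism variant counts in fixed windows along each chromosome.

    Returns {chrom: {mechanism: counts array}}; totals conserve the number
    of annotations.
    """
    if window is None:
        window = cfg.density_window
    lengths = genome.lengths
    density: dict[str, dict[str, np.ndarray]] = {}
    for ann in annots:
        v = ann.variant
        chrom = v.ref_chrom
        if chrom not in lengths:
            continue
        nwin = max(1, -(-lengths[chrom] // window))
        per = density.setdefault(chrom, {})
        arr = per.get(ann.mechanism)
        if arr is None:
            arr = np.zeros(nwin, dtype=np.int64)
            per[ann.mechanism] = arr
        i = min(nwin - 1, v.ref_start // window)
        arr[i] += 1
    return density
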