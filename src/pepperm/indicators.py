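"""Peptide-spectrum match indicators.

Re-implementations of the indicator families reported by the three classic
open-source search engines, each with a declared direction:

* counting / X! Tandem style: number of matched ions, convolution score
  (matched-intensity dot product), hyperscore (convolution scaled by the
  factorials of the matched b- and y-ion counts);
* SEQUEST/Crux style: Sp preliminary score, fast XCorr (background-subtracted
  cross-correlation on an m/z grid) and deltaCn;
* OMSSA style: Poisson mean lambda of random fragment matches, its tail
  probability, and the E-value (tail probability x effective database size).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, factorial, inf, isnan, lgamma, log

import numpy as np
from scipy import stats

from .mass_model import TheoreticalSpectrum
from .spectra import ExperimentalSpectrum

INDICATOR_NAMES = (
    "n_matched",
    "convolution",
    "hyperscore",
    "sp",
    "xcorr",
    "delta_cn",
    "lambda",
    "poisson_p",
    "e_value",
)

#: direction of improvement for each indicator
INDICATOR_DIRECTIONS: dict[str, str] = {
    "n_matched": "higher",
    "convolution": "higher",
    "hyperscore": "higher",
    "sp": "higher",
    "xcorr": "higher",
    # deltaCn_i = (xcorr_1 - xcorr_i)/xcorr_1: 0 for the best candidate and
    # growing for worse ones, so smaller is better and its permutation
    # p-values coincide with XCorr's.
    "delta_cn": "lower",
    "lambda": "lower",
    "poisson_p": "lower",
    "e_value": "lower",
}


@dataclass(frozen=True)
class MatchIndicators:
    n_matched: int
    convolution: float
    hyperscore: float
    sp: float
    xcorr: float
    delta_cn: float  # NaN when undefined (best XCorr <= 0)
    lam: float
    poisson_p: float
    e_value: float

    def as_tuple(self) -> tuple:
        return (
            self.n_matched,
            self.convolution,
            self.hyperscore,
            self.sp,
            self.xcorr,
            self.delta_cn,
            self.lam,
            self.poisson_p,
            self.e_value,
        )


# ---------------------------------------------------------------------------
# Ion matching
# ---------------------------------------------------------------------------

def greedy_match(
    theo_mz: np.ndarray, exp_mz: np.ndarray, frag_tol: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one assignment of theoretical ions to experimental peaks.

    Pairs within +-frag_tol are assigned nearest-|dm/z| first; ties at equal
    distance are broken toward the lower experimental m/z.  Each ion and each
    peak participates in at most one pair.  Returns (theo_index, exp_index)
    pairs.  ``exp_mz`` must be sorted.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    lo = np.searchsorted(exp_mz, theo_mz - frag_tol, side="left")
    hi = np.searchsorted(exp_mz, theo_mz + frag_tol, side="right")
    pairs = [
        (abs(theo_mz[t] - exp_mz[e]), exp_mz[e], t, e)
        for t in range(theo_mz.size)
        for e in range(lo[t], hi[t])
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_e: set[int] = set()
    out = []
    for _, _, t, e in pairs:
        if t in used_t or e in used_e:
            continue
        used_t.add(t)
        used_e.add(e)
        out.append((t, e))
    return out


def match_ions(
    exp: ExperimentalSpectrum, theo: TheoreticalSpectrum, frag_tol: float = 0.3
):
    """Matched-ion count and matched (FragmentIon, peak index) pairs."""
    theo_mz = theo.mz_array
    pairs = greedy_match(theo_mz, exp.mz, frag_tol)
    return len(pairs), [(theo.ions[t], e) for t, e in pairs]


def convolution_score(matched_intensities) -> float:
    """Dot product of matched intensities with unit theoretical intensities:
    the sum of the matched experimental peak intensities."""
    return float(np.sum(matched_intensities))


def hyperscore(n_b: int, n_y: int, convolution: float) -> float:
    """n_b! x n_y! x convolution, computed in log space; ``inf`` when the
    natural-scale value exceeds the float range."""
    if n_b < 0 or n_y < 0:
        raise ValueError("matched ion counts must be non-negative")
    if convolution < 0:
        raise ValueError("convolution score must be non-negative")
    if convolution == 0:
        return 0.0
    log_h = lgamma(n_b + 1) + lgamma(n_y + 1) + log(convolution)
    if log_h >= 709.0:
        return inf
    fact = factorial(n_b) * factorial(n_y)
    if fact < 10**308:  # exact integer factorial product stays in float range
        return float(fact) * convolution
    return exp(log_h)


def count_consecutive(series: np.ndarray, index: np.ndarray, loss: np.ndarray, charge: np.ndarray) -> int:
    """Number of adjacent-index pairs among matched ions within one
    (series, loss, charge) ladder."""
    seen = {(int(s), int(i), str(l), int(z)) for s, i, l, z in zip(series, index, loss, charge)}
    return sum(1 for (s, i, l, z) in seen if (s, i + 1, l, z) in seen)


def sp_score(
    matched_intensities, n_matched: int, n_theoretical: int, n_consecutive: int
) -> float:
    """SEQUEST preliminary score: matched-intensity sum scaled by the matched
    fraction, with a 0.075-per-step ion-series continuity bonus."""
    if n_theoretical < 1:
        raise ValueError("n_theoretical must be >= 1")
    total = float(np.sum(matched_intensities))
    return total * (n_matched / n_theoretical) * (1.0 + 0.075 * n_consecutive)


# ---------------------------------------------------------------------------
# Poisson family (OMSSA style)
# ---------------------------------------------------------------------------

def poisson_lambda(
    n_theoretical_mz: int,
    n_peaks_considered: int,
    frag_tol: float,
    mz_range: float,
) -> float:
    """Expected random fragment matches under a uniform peak background."""
    if mz_range <= 0:
        raise ValueError("degenerate spectrum: non-positive m/z range")
    lam = n_theoretical_mz * n_peaks_considered * (2.0 * frag_tol) / mz_range
    return max(lam, 1e-12)


def poisson_pvalue(n_matched: int, lam: float) -> float:
    """P(X >= n_matched) for X ~ Poisson(lam)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if n_matched <= 0:
        return 1.0
    return float(stats.poisson.sf(n_matched - 1, lam))


def omssa_evalue(poisson_p: float, effective_db_size: int) -> float:
    """Expected number of matches at least this good: p x effective database
    size (the number of candidates scored for the spectrum)."""
    if effective_db_size < 1:
        raise ValueError("effective_db_size must be >= 1")
    return poisson_p * effective_db_size


# ---------------------------------------------------------------------------
# XCorr family (Crux/SEQUEST fast form)
# ---------------------------------------------------------------------------

XCORR_OFFSET = 75  # background window half-width, in bins
XCORR_WINDOWS = 10
XCORR_NORM = 50.0


def xcorr_background(
    exp: ExperimentalSpectrum, bin_width: float = 0.3
) -> np.ndarray:
    """Preprocessed, background-subtracted experimental vector y'.

    Intensities are square-rooted, the m/z axis is divided into 10 equal
    windows each normalized to a maximum of 50, and the mean of the vector
    shifted over offsets +-75 bins (offset 0 excluded) is subtracted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    bins = np.floor(exp.mz / bin_width).astype(int)
    n_bins = int(bins.max()) + XCORR_OFFSET + 1
    y = np.zeros(n_bins)
    np.maximum.at(y, bins, np.sqrt(exp.intensity))

    edges = np.linspace(0, bins.max() + 1, XCORR_WINDOWS + 1).astype(int)
    for a, b in zip(edges[:-1], edges[1:]):
        top = y[a:b].max() if b > a else 0.0
        if top > 0:
            y[a:b] *= XCORR_NORM / top

    # mean over offsets tau in [-75, 75], tau != 0
    padded = np.concatenate([np.zeros(XCORR_OFFSET), y, np.zeros(XCORR_OFFSET)])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    i = np.arange(n_bins)
    window_sum = csum[i + 2 * XCORR_OFFSET + 1] - csum[i]
    background = (window_sum - y) / (2 * XCORR_OFFSET)
    return y - background


def xcorr_from_background(theo_mz: np.ndarray, yprime: np.ndarray, bin_width: float = 0.3) -> float:
    """Dot product of the unit theoretical vector with y', scaled by 1e-4."""
    bins = np.unique(np.floor(theo_mz / bin_width).astype(int))
    bins = bins[(bins >= 0) & (bins < yprime.size)]
    return float(yprime[bins].sum()) / 1e4


def xcorr(
    exp: ExperimentalSpectrum, theo: TheoreticalSpectrum, bin_width: float = 0.3
) -> float:
    return xcorr_from_background(theo.mz_array, xcorr_background(exp, bin_width), bin_width)


def delta_cn(xcorr_scores) -> np.ndarray:
    """deltaCn_i = (xcorr_1 - xcorr_i) / xcorr_1 against the best score;
    NaN everywhere when the best score is not positive."""
    x = np.asarray(xcorr_scores, dtype=float)
    if x.size == 0:
        return x
    best = float(np.max(x))
    if best <= 0:
        return np.full(x.shape, np.nan)
    return (best - x) / best


# ---------------------------------------------------------------------------
# Prefilter
# ---------------------------------------------------------------------------

def top_peak_prefilter(
    exp: ExperimentalSpectrum,
    theo_mz: np.ndarray,
    top_n: int = 8,
    frag_tol: float = 0.3,
) -> bool:
    """True iff at least one theoretical ion lies within frag_tol of one of
    the top_n most intense experimental peaks."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    order = np.argsort(-exp.intensity, kind="stable")[:top_n]
    top_mz = np.sort(exp.mz[order])
    idx = np.searchsorted(top_mz, theo_mz)
    near_lo = (idx > 0) & (theo_mz - top_mz[np.maximum(idx - 1, 0)] <= frag_tol)
    near_hi = (idx < top_mz.size) & (
        top_mz[np.minimum(idx, top_mz.size - 1)] - theo_mz <= frag_tol
    )
    return bool(np.any(near_lo | near_hi))


def round_sig(a, sig: int = 6):
    """Round to ``sig`` significant digits (element-wise).

    Used for homeometric equality: absolute decimal rounding would collapse
    indicators spanning many orders of magnitude (Poisson tails, E-values)
    to zero, so equality is defined on significant digits instead.
    """
    a = np.asarray(a, dtype=float)
    out = a.copy()
    nz = np.isfinite(a) & (a != 0)
    exp = np.floor(np.log10(np.abs(a[nz])))
    out[nz] = np.round(a[nz] / 10**exp, sig - 1) * 10**exp
    return out if out.ndim else float(out)


def compare(value: float, reference: float, direction: str) -> bool:
    """Is ``value`` equal-or-better than ``reference`` for this direction?
    Missing values (NaN) are never better."""
    if isnan(value):
        return isnan(reference)
    if isnan(reference):
        return True
    return value >= reference if direction == "higher" else value <= reference
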