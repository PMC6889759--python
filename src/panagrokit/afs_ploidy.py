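"""Variant-frequency spectra and ploidy classification.

RNA-seq (or genomic) reads mapped to coding sequences yield, at each
heterozygous site, an alternative-allele read fraction. The shape of the
distribution of these fractions is diagnostic of ploidy: a diploid
heterozygote shows a mode at 1/2, a triploid carrying the variant on one
of three homeologous copies shows a mode at 1/3 (2/3 when two copies carry
it), and a homozygous genome shows only a flat, error-driven background.
Spectra are folded (f -> min(f, 1-f)) by default so that the 1/3 and 2/3
triploid modes coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .core_io import VariantSite

#: folded-frequency windows in which a smoothed spectral peak is read as a
#: ploidy signature: 1/3 for triploid heterozygosity, 1/2 for diploid.
DEFAULT_WINDOWS: Mapping[str, tuple[float, float]] = {
    "triploid": (0.28, 0.40),
    "diploid_heterozygous": (0.44, 0.50),
}

DEFAULT_BIN_WIDTH = 0.02
DEFAULT_TRIM = (0.05, 0.95)
DEFAULT_MIN_DEPTH = 20
DEFAULT_MIN_VARIANTS = 200
DEFAULT_FLATNESS_THRESHOLD = 1.5
SMOOTH_WINDOW_BINS = 5

#: exact small-sample KS p-values are enumerated up to this pooled size
KS_EXACT_MAX_N = 12


@dataclass(frozen=True)
class FrequencySpectrum:
    """Binned distribution of variant frequencies.

    Bins are half-open ``[a, b)`` except the last, which is closed; when
    folded the support is (0, 0.5].
    """

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    n_variants: int
    folded: bool

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if sum(self.counts) != self.n_variants:
            raise ValueError("counts must sum to n_variants")
        edges = np.asarray(self.bin_edges)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        widths = np.diff(edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must have equal width")

    @property
    def bin_centers(self) -> np.ndarray:
        edges = np.asarray(self.bin_edges)
        return (edges[:-1] + edges[1:]) / 2.0

    def modal_bin_center(self, smooth: bool = True) -> float:
        """Center of the modal bin, optionally after moving-average smoothing."""
        counts = np.asarray(self.counts, dtype=float)
        if smooth:
            counts = uniform_filter1d(counts, SMOOTH_WINDOW_BINS, mode="nearest")
        return float(self.bin_centers[int(np.argmax(counts))])


@dataclass(frozen=True)
class PloidyCall:
    call: str  # homozygous_flat | diploid_heterozygous | triploid | ambiguous
    peak_location: float | None
    peak_prominence: float
    n_variants_used: int


@dataclass(frozen=True)
class KsResult:
    D: float
    p_value: float
    n1: int
    n2: int


def variant_frequencies(
    sites: Sequence[VariantSite],
    min_depth: int = DEFAULT_MIN_DEPTH,
    trim: tuple[float, float] = DEFAULT_TRIM,
) -> list[float]:
    """Per-site alternative-allele fractions, depth-filtered and trimmed.

    Sites with total depth below ``min_depth`` are dropped; fractions are
    kept only inside the open interval ``(trim[0], trim[1])``, removing the
    fixed-allele spikes at 0 and 1 that carry no heterozygosity signal.
    Input order is preserved.
    """
    lo, hi = trim
    out: list[float] = []
    for site in sites:
        if site.depth < min_depth:
            continue
        f = site.alt_fraction
        if lo < f < hi:
            out.append(f)
    return out


def fold(freqs: Sequence[float]) -> list[float]:
    """Fold frequencies onto (0, 0.5]: f -> min(f, 1 - f)."""
    return [min(f, 1.0 - f) for f in freqs]


def build_spectrum(
    freqs: Sequence[float],
    bin_width: float = DEFAULT_BIN_WIDTH,
    folded: bool = True,
) -> FrequencySpectrum:
    """Histogram variant frequencies into equal-width bins.

    Folding maps each frequency to ``min(f, 1-f)`` before binning, merging
    the 1/3 and 2/3 triploid modes into a single peak.
    """
    if not 0 < bin_width <= 0.1:
        raise ValueError(f"bin_width must lie in (0, 0.1], got {bin_width}")
    values = np.asarray(fold(freqs) if folded else freqs, dtype=float)
    upper = 0.5 if folded else 1.0
    n_bins = int(round(upper / bin_width))
    edges = np.linspace(0.0, upper, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return FrequencySpectrum(
        bin_edges=tuple(edges.tolist()),
        counts=tuple(int(c) for c in counts),
        n_variants=len(values),
        folded=folded,
    )


def classify_ploidy(
    spectrum: FrequencySpectrum,
    windows: Mapping[str, tuple[float, float]] = DEFAULT_WINDOWS,
    flatness_threshold: float = DEFAULT_FLATNESS_THRESHOLD,
    min_variants: int = DEFAULT_MIN_VARIANTS,
) -> PloidyCall:
    """Call ploidy from the peak structure of a folded spectrum.

    Counts are smoothed with a 5-bin moving average; peak prominence is the
    ratio of the smoothed maximum to the smoothed median. A spectrum with
    too few variants is ``ambiguous``; one with prominence below
    ``flatness_threshold`` is ``homozygous_flat``; otherwise the location
    of the smoothed mode decides: inside the triploid window it is a 1/3
    signature, inside the diploid window a 1/2 signature, elsewhere
    ``ambiguous``.
    """
    if not spectrum.folded:
        raise ValueError("classify_ploidy requires a folded spectrum")
    counts = np.asarray(spectrum.counts, dtype=float)
    smoothed = uniform_filter1d(counts, SMOOTH_WINDOW_BINS, mode="nearest")
    med = float(np.median(smoothed))
    peak = float(np.max(smoothed))
    prominence = peak / med if med > 0 else (np.inf if peak > 0 else 1.0)

    if spectrum.n_variants < min_variants:
        return PloidyCall("ambiguous", None, prominence, spectrum.n_variants)
    if prominence < flatness_threshold:
        return PloidyCall("homozygous_flat", None, prominence, spectrum.n_variants)

    peak_location = float(spectrum.bin_centers[int(np.argmax(smoothed))])
    for call, (lo, hi) in windows.items():
        if lo <= peak_location <= hi:
            return PloidyCall(call, peak_location, prominence, spectrum.n_variants)
    return PloidyCall("ambiguous", peak_location, prominence, spectrum.n_variants)


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_A - ECDF_B| over the pooled sample points."""
    pooled = np.concatenate([a, b])
    pooled.sort(kind="mergesort")
    cdf_a = np.searchsorted(np.sort(a), pooled, side="right") / len(a)
    cdf_b = np.searchsorted(np.sort(b), pooled, side="right") / len(b)
    return float(np.max(np.abs(cdf_a - cdf_b)))


def ks_two_sample(
    freqs_a: Sequence[float], freqs_b: Sequence[float]
) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test between frequency samples.

    D is the supremum ECDF distance. For pooled sizes up to
    ``KS_EXACT_MAX_N`` the p-value is the exact permutation tail: the
    fraction of all C(n1+n2, n1) label assignments of the pooled values
    whose D is at least the observed one. Larger samples use the
    asymptotic Kolmogorov distribution at effective size
    ``ne = n1*n2/(n1+n2)``.
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    d_obs = _ks_statistic(a, b)

    if n1 + n2 <= KS_EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        total = 0
        extreme = 0
        idx = range(n1 + n2)
        for labels_a in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(labels_a)] = True
            d = _ks_statistic(pooled[mask], pooled[~mask])
            total += 1
            if d >= d_obs - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        ne = n1 * n2 / (n1 + n2)
        p = float(stats.kstwobign.sf(d_obs * sqrt(ne)))
    return KsResult(D=d_obs, p_value=min(max(p, 0.0), 1.0), n1=n1, n2=n2)
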