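"""Circular-dichroism analysis: conformation calls and melting temperatures.

Intramolecular G-quadruplex topologies leave characteristic CD fingerprints:

* parallel — maximum ~265 nm, minimum ~240 nm
* antiparallel 2+2 chair — maximum ~290 nm, minimum ~265 nm
* antiparallel 2+2 basket — maxima ~250 and ~290 nm, minima ~235 and ~265 nm
* 3+1 hybrid (parallel/antiparallel) — maxima ~265 and ~290 nm,
  minima ~240 and ~275 nm

Conformation calling matches observed spectral extrema against these
signatures; mixed populations are resolved by a non-negative least-squares
decomposition onto signature-derived band shapes (see
:func:`classify_conformation`).

Melting temperatures are extracted from single-wavelength temperature ramps
by fitting a third-order polynomial and taking the root of its second
derivative: for aT^3 + bT^2 + cT + d the inflection is Tm = -b/(3a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal

__all__ = [
    "CDSpectrum",
    "SpectralSignature",
    "ConformationCall",
    "MeltingCurve",
    "MeltResult",
    "DEFAULT_SIGNATURES",
    "DEFAULT_BAND_WIDTH_NM",
    "signature_basis_curve",
    "average_and_subtract",
    "find_extrema",
    "classify_conformation",
    "pick_melt_wavelength",
    "fit_cubic_tm",
    "delta_tm",
    "check_refold",
    "DegenerateFitError",
    "TmOutOfRangeError",
]

#: Gaussian band width (sigma, nm) used to turn a signature into a model curve.
DEFAULT_BAND_WIDTH_NM = 12.0


@dataclass(frozen=True)
class CDSpectrum:
    """Ellipticity (mdeg) on an ascending wavelength grid (nm)."""

    wavelengths: np.ndarray
    ellipticity: np.ndarray
    name: str = ""
    cation: str = "K"
    temperature: float = 23.0

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        el = np.asarray(self.ellipticity, dtype=float)
        if wl.shape != el.shape or wl.ndim != 1:
            raise ValueError("wavelengths and ellipticity must be 1-D and equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "ellipticity", el)


@dataclass(frozen=True)
class SpectralSignature:
    """CD extrema signature of one quadruplex topology."""

    label: str
    maxima: tuple[float, ...]
    minima: tuple[float, ...]
    tolerance: float = 8.0

    def __post_init__(self):
        for m in self.maxima:
            for n in self.minima:
                if abs(m - n) <= self.tolerance:
                    raise ValueError(
                        f"{self.label}: maximum {m} and minimum {n} nm are not "
                        f"disjoint within the {self.tolerance} nm tolerance"
                    )

    @property
    def n_required(self) -> int:
        return len(self.maxima) + len(self.minima)


DEFAULT_SIGNATURES: tuple[SpectralSignature, ...] = (
    SpectralSignature("parallel", maxima=(265.0,), minima=(240.0,)),
    SpectralSignature("antiparallel_chair", maxima=(290.0,), minima=(265.0,)),
    SpectralSignature("antiparallel_basket", maxima=(250.0, 290.0), minima=(235.0, 265.0)),
    SpectralSignature("hybrid_3plus1", maxima=(265.0, 290.0), minima=(240.0, 275.0)),
)


def signature_basis_curve(
    sig: SpectralSignature,
    wavelengths: np.ndarray,
    band_width: float = DEFAULT_BAND_WIDTH_NM,
) -> np.ndarray:
    """Model spectrum for a signature: unit-amplitude Gaussian bands,
    positive at each maximum and negative at each minimum."""
    wl = np.asarray(wavelengths, dtype=float)
    y = np.zeros_like(wl)
    for c in sig.maxima:
        y += np.exp(-((wl - c) ** 2) / (2.0 * band_width**2))
    for c in sig.minima:
        y -= np.exp(-((wl - c) ** 2) / (2.0 * band_width**2))
    return y


@dataclass(frozen=True)
class ConformationCall:
    """Result of conformation calling on one spectrum.

    ``scores`` are extrema-match fractions per signature; ``weights`` are the
    normalized non-negative decomposition weights (empty when the
    decomposition did not explain the spectrum).  ``unclassifiable`` is set
    when no extremum at all was detected.
    """

    called: frozenset[str]
    scores: dict[str, float]
    weights: dict[str, float] = field(default_factory=dict)
    unclassifiable: bool = False

    @property
    def mixture_flag(self) -> bool:
        return len(self.called) > 1


class DegenerateFitError(ValueError):
    """Cubic fit has no usable curvature (leading coefficient ~ 0)."""


class TmOutOfRangeError(ValueError):
    """Inflection of the fitted cubic falls outside the fitted window."""

    def __init__(self, tm: float, lo: float, hi: float):
        super().__init__(f"inflection {tm:.2f} degC outside fitted window [{lo}, {hi}]")
        self.tm = tm


# ---------------------------------------------------------------------------
# spectrum processing


def average_and_subtract(
    sample_scans: Sequence[CDSpectrum], buffer_scans: Sequence[CDSpectrum]
) -> CDSpectrum:
    """Mean of repeated sample scans minus mean of buffer scans."""
    if not sample_scans:
        raise ValueError("need at least one sample scan")
    grid = sample_scans[0].wavelengths
    for s in list(sample_scans) + list(buffer_scans):
        if s.wavelengths.shape != grid.shape or not np.allclose(s.wavelengths, grid):
            raise ValueError("all scans must share one wavelength grid")
    sample_mean = np.mean([s.ellipticity for s in sample_scans], axis=0)
    if buffer_scans:
        sample_mean = sample_mean - np.mean([b.ellipticity for b in buffer_scans], axis=0)
    first = sample_scans[0]
    return CDSpectrum(grid.copy(), sample_mean, name=first.name, cation=first.cation,
                      temperature=first.temperature)


def _smooth(y: np.ndarray, window_pts: int) -> np.ndarray:
    if window_pts <= 1:
        return y
    kernel = np.ones(window_pts) / window_pts
    # reflect-pad so the ends are not biased toward zero
    pad = window_pts // 2
    ypad = np.concatenate([y[pad:0:-1], y, y[-2 : -pad - 2 : -1]])
    return np.convolve(ypad, kernel, mode="valid")[: y.size]


def find_extrema(
    spectrum: CDSpectrum,
    smooth_window: float = 0.0,
    min_prominence: Optional[float] = None,
) -> list[tuple[float, float, str]]:
    """Local extrema of the (optionally smoothed) spectrum.

    ``smooth_window`` is a moving-average width in nm (0 = no smoothing, the
    default; repeated scans are averaged upstream).  ``min_prominence``
    defaults to 5% of the spectrum's maximum absolute ellipticity.  Returns
    (wavelength, ellipticity, 'max'|'min') sorted by wavelength.
    """
    wl, y = spectrum.wavelengths, spectrum.ellipticity
    if wl.size < 3:
        return []
    pitch = float(np.median(np.diff(wl)))
    window_pts = max(1, int(round(smooth_window / pitch)))
    if window_pts > wl.size:
        raise ValueError("smoothing window larger than the wavelength grid")
    ys = _smooth(y, window_pts)
    if min_prominence is None:
        min_prominence = 0.05 * float(np.max(np.abs(ys))) if np.any(ys) else 0.0
    out = []
    for arr, kind in ((ys, "max"), (-ys, "min")):
        idx, _ = signal.find_peaks(arr, prominence=min_prominence)
        out.extend((float(wl[i]), float(ys[i]), kind) for i in idx)
    return sorted(out)


# ---------------------------------------------------------------------------
# conformation calling


def _match_signature(
    sig: SpectralSignature, extrema: list[tuple[float, float, str]]
) -> tuple[float, frozenset[tuple[float, str]]]:
    """Extrema-match score and the set of observed extrema that matched."""
    matched: set[tuple[float, str]] = set()
    n_hit = 0
    for required, kind in [(m, "max") for m in sig.maxima] + [(m, "min") for m in sig.minima]:
        candidates = [
            (abs(w - required), w)
            for (w, _e, k) in extrema
            if k == kind and abs(w - required) <= sig.tolerance
        ]
        if candidates:
            n_hit += 1
            matched.add((min(candidates)[1], kind))
    return n_hit / sig.n_required, frozenset(matched)


def classify_conformation(
    spectrum: CDSpectrum,
    signatures: Sequence[SpectralSignature] = DEFAULT_SIGNATURES,
    threshold: float = 0.75,
    smooth_window: float = 9.0,
    mixture_weight_threshold: float = 0.25,
    max_decomposition_residual: float = 0.3,
    band_width: float = DEFAULT_BAND_WIDTH_NM,
) -> ConformationCall:
    """Call the quadruplex conformation(s) present in a spectrum.

    Two complementary rules are combined:

    1. *Extrema matching* — each signature is scored by the fraction of its
       required maxima/minima matched by an observed extremum of the correct
       kind within the signature tolerance; signatures scoring >= ``threshold``
       pass.  A passing signature whose matched extrema are a subset of a more
       specific passing signature's is pruned (a pure 3+1 hybrid spectrum
       contains the parallel fingerprint as a subset and must not be called a
       mixture).
    2. *Band decomposition* — the spectrum is decomposed by non-negative least
       squares onto the signatures' Gaussian-band model curves.  When the
       reconstruction explains the spectrum (relative residual <=
       ``max_decomposition_residual``), the decomposition arbitrates: the
       call is every component holding >= ``mixture_weight_threshold`` of the
       total weight.  This resolves mixtures whose components mask each
       other's extrema (in a parallel + antiparallel-chair mixture the
       parallel 265-nm maximum and the chair 265-nm minimum cancel, so
       neither component can reach the extrema-score threshold on its own)
       and discards signatures that only pass the extrema score via spurious
       noise peaks.  When the decomposition cannot explain the spectrum the
       extrema-based call stands alone.

    The default 9-nm moving average applied before peak picking emulates the
    noise suppression of averaging repeated instrument scans.

    Returns an unclassifiable call (empty set) when no extremum is detected.
    """
    extrema = find_extrema(spectrum, smooth_window=smooth_window)
    scores: dict[str, float] = {}
    matched_sets: dict[str, frozenset] = {}
    for sig in signatures:
        scores[sig.label], matched_sets[sig.label] = _match_signature(sig, extrema)
    if not extrema:
        return ConformationCall(frozenset(), scores, unclassifiable=True)

    by_label = {s.label: s for s in signatures}
    passing = {lab for lab, sc in scores.items() if sc >= threshold}
    # specificity pruning
    pruned = set(passing)
    for a in passing:
        for b in passing:
            if a == b:
                continue
            if (
                matched_sets[a] <= matched_sets[b]
                and by_label[b].n_required > by_label[a].n_required
            ):
                pruned.discard(a)
                break
    called = set(pruned)

    # non-negative decomposition for mixture resolution
    basis = np.column_stack(
        [signature_basis_curve(s, spectrum.wavelengths, band_width) for s in signatures]
    )
    w, rnorm = optimize.nnls(basis, spectrum.ellipticity)
    weights: dict[str, float] = {}
    ynorm = float(np.linalg.norm(spectrum.ellipticity))
    total = float(w.sum())
    if ynorm > 0 and total > 0 and rnorm / ynorm <= max_decomposition_residual:
        weights = {s.label: float(wi / total) for s, wi in zip(signatures, w)}
        weight_called = {lab for lab, frac in weights.items() if frac >= mixture_weight_threshold}
        if weight_called:
            called = weight_called

    return ConformationCall(frozenset(called), scores, weights)


def pick_melt_wavelength(spectrum: CDSpectrum, override: Optional[float] = None) -> float:
    """Wavelength of maximum ellipticity, unless overridden (mixed-population
    samples are melted at a conformation-specific wavelength instead)."""
    if override is not None:
        return float(override)
    if spectrum.wavelengths.size == 0:
        raise ValueError("empty spectrum")
    return float(spectrum.wavelengths[int(np.argmax(spectrum.ellipticity))])


# ---------------------------------------------------------------------------
# melting curves


@dataclass(frozen=True)
class MeltingCurve:
    """Single-wavelength ellipticity vs temperature ramp."""

    temperatures: np.ndarray
    ellipticity: np.ndarray
    wavelength: float
    direction: str = "melt"  # 'melt' (ascending) or 'anneal' (descending)

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        y = np.asarray(self.ellipticity, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("temperatures and ellipticity must be 1-D and equal length")
        if self.direction not in ("melt", "anneal"):
            raise ValueError(f"direction must be 'melt' or 'anneal', got {self.direction!r}")
        d = np.diff(t)
        if t.size >= 2:
            if self.direction == "melt" and not np.all(d > 0):
                raise ValueError("melt curve temperatures must increase")
            if self.direction == "anneal" and not np.all(d < 0):
                raise ValueError("anneal curve temperatures must decrease")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "ellipticity", y)


@dataclass(frozen=True)
class MeltResult:
    """Cubic-fit melting temperature: tm = -b/(3a) for aT^3+bT^2+cT+d."""

    tm: float
    coefficients: tuple[float, float, float, float]
    wavelength: float
    direction: str
    window: tuple[float, float]


def fit_cubic_tm(
    curve: MeltingCurve,
    window: Optional[tuple[float, float]] = None,
    auto_window: bool = False,
    auto_half_width: float = 15.0,
    rel_curvature_tol: float = 1e-8,
) -> MeltResult:
    """Melting temperature by the cubic second-derivative-root procedure.

    A third-order polynomial is least-squares fitted to ellipticity vs
    temperature over ``window`` (default: the full recorded ramp); Tm is the
    root of its second derivative, -b/(3a).  With ``auto_window`` the fit is
    restricted to +/- ``auto_half_width`` degC around the steepest-slope
    temperature, which reduces asymmetry bias on sigmoidal transitions.
    """
    t, y = curve.temperatures, curve.ellipticity
    order = np.argsort(t)
    t, y = t[order], y[order]

    if auto_window and window is None:
        dy = np.gradient(y, t)
        t_star = float(t[int(np.argmax(np.abs(dy)))])
        window = (t_star - auto_half_width, t_star + auto_half_width)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
    lo, hi = (float(t.min()), float(t.max())) if t.size else (math.nan, math.nan)

    if t.size < 8 or (hi - lo) < 20.0:
        raise ValueError(
            f"need >= 8 points spanning >= 20 degC inside the fit window, "
            f"got {t.size} points over {hi - lo:.1f} degC"
        )

    a, b, c, d = np.polyfit(t, y, 3)
    # curvature scale of the cubic term relative to the data amplitude
    scale = max(float(np.max(np.abs(y))), np.finfo(float).tiny)
    if abs(a) * ((hi - lo) / 2.0) ** 3 < rel_curvature_tol * scale:
        raise DegenerateFitError(
            f"cubic leading coefficient {a:.3e} carries no curvature at the "
            f"data scale; melting transition not identifiable"
        )
    tm = -b / (3.0 * a)
    if not lo <= tm <= hi:
        raise TmOutOfRangeError(tm, lo, hi)
    return MeltResult(
        tm=float(tm),
        coefficients=(float(a), float(b), float(c), float(d)),
        wavelength=curve.wavelength,
        direction=curve.direction,
        window=(lo, hi),
    )


def delta_tm(sample: MeltResult, reference: MeltResult) -> float:
    """Melting-temperature shift of a sample relative to the reference
    construct (sample minus reference), degC."""
    if sample.direction != reference.direction:
        raise ValueError("cannot compare melt and anneal results")
    return sample.tm - reference.tm


def check_refold(
    pre_melt: CDSpectrum,
    post_melt: CDSpectrum,
    window: tuple[float, float] = (230.0, 320.0),
) -> float:
    """Similarity of the pre-melt and post-melt/reanneal spectra.

    Product-moment (Pearson) similarity of the two ellipticity vectors over
    the structured 230-320 nm region; 1.0 = identical shape, values below
    ~0.9 indicate the original conformation did not reform.
    """
    if pre_melt.wavelengths.shape != post_melt.wavelengths.shape or not np.allclose(
        pre_melt.wavelengths, post_melt.wavelengths
    ):
        raise ValueError("spectra must share one wavelength grid")
    mask = (pre_melt.wavelengths >= window[0]) & (pre_melt.wavelengths <= window[1])
    a = pre_melt.ellipticity[mask]
    b = post_melt.ellipticity[mask]
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance spectrum: similarity undefined")
    return float(np.dot(a, b) / (na * nb))
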