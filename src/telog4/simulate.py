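"""Synthetic data generators for every assay in the pipeline.

All generators are deterministic given (seed, parameters).  They emulate the
statistical structure the analysis modules assume:

* CD spectra — weighted sums of the four conformation basis curves
  (Gaussian bands at the signature extrema) plus white noise;
* melting/annealing curves — two-state sigmoids (logistic folded fraction)
  or exact cubics with a prescribed inflection;
* smFRET trajectories — per-molecule behavioral types (static folded,
  two-state Markov dynamic, unfolded) with Gaussian emission noise,
  reconstructed into donor/acceptor intensity pairs that the efficiency
  formula inverts exactly;
* cleavage time courses — saturating first-order kinetics rendered as
  cleaved/uncleaved band intensities.

Defaults encode the study conditions: folded emission mean 0.67 (the
constructs' common histogram peak), unfolded mean 0.4, 100 ms frames, 3-min
trace records and 2-s histogram movies, and the canonical construct's
trace-type fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cd import (
    CDSpectrum,
    DEFAULT_BAND_WIDTH_NM,
    DEFAULT_SIGNATURES,
    MeltingCurve,
    signature_basis_curve,
)
from .cleavage import CleavageMeasurement, CleavageTimecourse
from .fret import FretTrace

__all__ = [
    "SyntheticConfig",
    "gen_cd_spectrum",
    "gen_melting_curve",
    "gen_fret_traces",
    "gen_cleavage_timecourse",
    "WAVELENGTH_GRID_NM",
    "TEMPERATURE_GRID_C",
]

WAVELENGTH_GRID_NM = np.arange(220.0, 341.0, 1.0)
TEMPERATURE_GRID_C = np.arange(25.0, 96.0, 1.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for the synthetic generators.

    Emission means are FRET-efficiency units; switch rates are per second
    (folded->unfolded, unfolded->folded); type_fractions order is
    (static_folded, dynamic, unfolded) and must sum to 1.
    """

    seed: int = 0
    # CD
    cd_noise_sd: float = 0.0  # mdeg
    band_width: float = DEFAULT_BAND_WIDTH_NM  # nm
    # melting
    melt_width: float = 3.0  # degC logistic steepness
    theta_folded: float = 1.0  # mdeg at full folding
    theta_unfolded: float = 0.0
    # smFRET
    fret_frame_interval: float = 0.1  # s
    fret_duration: float = 180.0  # s (3-min trace records; 2.0 for movies)
    folded_mean: float = 0.67
    unfolded_mean: float = 0.4
    emission_noise_sd: float = 0.05
    switch_rates: tuple[float, float] = (0.2, 0.3)  # per second
    type_fractions: tuple[float, float, float] = (0.743, 0.178, 0.079)
    # cleavage
    cleavage_rate: float = 0.004  # per minute
    cleavage_plateau: float = 0.6  # fraction
    burst_fraction: float = 0.0  # fraction
    cleavage_noise_sd: float = 0.02  # fraction
    intensity_scale: float = 1000.0  # arbitrary units

    def __post_init__(self):
        f = self.type_fractions
        if len(f) != 3 or any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"type_fractions must be 3 nonnegative values summing to 1, got {f}")
        if self.fret_frame_interval <= 0:
            raise ValueError("fret_frame_interval must be positive")
        for name in ("cd_noise_sd", "emission_noise_sd", "cleavage_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if any(k < 0 for k in self.switch_rates):
            raise ValueError("switch rates must be nonnegative")
        for name in ("cleavage_plateau", "burst_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _signature_by_label(label: str):
    for sig in DEFAULT_SIGNATURES:
        if sig.label == label:
            return sig
    raise KeyError(f"unknown conformation {label!r}")


def gen_cd_spectrum(
    weights: dict[str, float],
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> CDSpectrum:
    """CD spectrum of a (possibly mixed) conformation population.

    ``weights`` maps conformation labels to nonnegative population weights;
    the spectrum is the weighted sum of the four basis curves on the
    220-340 nm grid plus zero-mean Gaussian noise of SD ``cd_noise_sd``.
    """
    if not weights or all(w == 0 for w in weights.values()):
        raise ValueError("need at least one positive conformation weight")
    if any(w < 0 for w in weights.values()):
        raise ValueError("conformation weights must be nonnegative")
    rng = config.rng() if rng is None else rng
    wl = WAVELENGTH_GRID_NM.copy()
    y = np.zeros_like(wl)
    for label, w in weights.items():
        y += w * signature_basis_curve(_signature_by_label(label), wl, config.band_width)
    if config.cd_noise_sd > 0:
        y = y + rng.normal(0.0, config.cd_noise_sd, size=wl.size)
    name = "+".join(sorted(lab for lab, w in weights.items() if w > 0))
    return CDSpectrum(wl, y, name=name)


def gen_melting_curve(
    tm: float,
    config: SyntheticConfig,
    direction: str = "melt",
    model: str = "sigmoid",
    wavelength: float = 265.0,
    rng: Optional[np.random.Generator] = None,
) -> MeltingCurve:
    """Single-wavelength melting or annealing ramp with midpoint ``tm``.

    sigmoid model: two-state folded fraction f(T) = 1/(1+exp((T-tm)/width)),
    ellipticity = theta_U + (theta_F - theta_U) f(T) + noise, sampled 25-95 degC
    at 1 degC; the anneal direction reverses the temperature order only.

    cubic model: an exact third-order polynomial (nonzero leading term) whose
    inflection point equals ``tm``; noise-free by construction, for validating
    the second-derivative-root extraction.
    """
    if config.melt_width <= 0:
        raise ValueError("melt_width must be positive")
    rng = config.rng() if rng is None else rng
    t = TEMPERATURE_GRID_C.copy()
    if model == "sigmoid":
        if not 25.0 <= tm <= 95.0:
            raise ValueError("sigmoid tm must lie within the 25-95 degC ramp")
        f = 1.0 / (1.0 + np.exp((t - tm) / config.melt_width))
        y = config.theta_unfolded + (config.theta_folded - config.theta_unfolded) * f
        if config.cd_noise_sd > 0:
            y = y + rng.normal(0.0, config.cd_noise_sd, size=t.size)
    elif model == "cubic":
        # y = a (T - tm)^3 + c (T - tm) + d  => inflection exactly at tm
        a, c, d = -2e-4, -0.02, 0.5
        y = a * (t - tm) ** 3 + c * (t - tm) + d
    else:
        raise ValueError(f"unknown melting model {model!r}")
    if direction == "anneal":
        t, y = t[::-1], y[::-1]
    return MeltingCurve(t, y, wavelength=wavelength, direction=direction)


def gen_fret_traces(
    n: int,
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[FretTrace], list[str]]:
    """Simulate ``n`` molecules with ground-truth behavioral labels.

    Each molecule draws its type from ``type_fractions``.  Static molecules
    emit ``folded_mean`` each frame, unfolded ``unfolded_mean``; dynamic
    molecules follow a two-state discrete-time Markov chain with per-frame
    switch probabilities 1 - exp(-k dt), started from the chain's stationary
    distribution.  Gaussian emission noise is added per frame, then
    intensities are reconstructed as acceptor = scale*E, donor = scale*(1-E)
    so that the efficiency formula inverts them exactly.
    """
    if n < 1:
        raise ValueError("need at least one molecule")
    rng = config.rng() if rng is None else rng
    dt = config.fret_frame_interval
    n_frames = int(round(config.fret_duration / dt))
    if n_frames < 1:
        raise ValueError("fret_duration shorter than one frame")

    types = rng.choice(3, size=n, p=np.asarray(config.type_fractions))
    labels = [("static_folded", "dynamic", "unfolded")[t] for t in types]

    k_fu, k_uf = config.switch_rates
    p_fu = 1.0 - np.exp(-k_fu * dt)  # folded -> unfolded per frame
    p_uf = 1.0 - np.exp(-k_uf * dt)
    p_folded_stat = k_uf / (k_fu + k_uf) if (k_fu + k_uf) > 0 else 1.0

    # state matrix: 1 = folded for every molecule/frame
    folded = np.ones((n, n_frames), dtype=bool)
    folded[types == 2] = False
    dyn = np.flatnonzero(types == 1)
    if dyn.size:
        state = rng.random(dyn.size) < p_folded_stat
        flips = rng.random((dyn.size, n_frames))
        for j in range(n_frames):
            folded[dyn, j] = state
            p_switch = np.where(state, p_fu, p_uf)
            state = state ^ (flips[:, j] < p_switch)

    e_true = np.where(folded, config.folded_mean, config.unfolded_mean)
    e_noisy = e_true + rng.normal(0.0, config.emission_noise_sd, size=e_true.shape)
    acceptor = config.intensity_scale * e_noisy
    donor = config.intensity_scale * (1.0 - e_noisy)

    traces = [
        FretTrace(
            molecule_id=f"mol{i:05d}",
            frame_interval=dt,
            donor=donor[i],
            acceptor=acceptor[i],
        )
        for i in range(n)
    ]
    return traces, labels


def gen_cleavage_timecourse(
    config: SyntheticConfig,
    timepoints: Sequence[float] = (1.0, 5.0, 15.0, 30.0, 60.0, 120.0),
    replicates: int = 3,
    construct: str = "synthetic",
    cation: str = "K",
    rng: Optional[np.random.Generator] = None,
) -> list[CleavageTimecourse]:
    """Saturating cleavage time courses rendered as band-intensity pairs.

    True cleaved fraction F(t) = burst + (plateau - burst)(1 - exp(-rate t)),
    clipped to [0, 1]; Gaussian noise on the fraction is truncated so both
    band intensities stay nonnegative.
    """
    tp = np.asarray(timepoints, dtype=float)
    if tp.size == 0 or np.any(tp <= 0) or np.any(np.diff(tp) <= 0):
        raise ValueError("timepoints must be positive and strictly increasing")
    rng = config.rng() if rng is None else rng
    f_true = np.clip(
        config.burst_fraction
        + (config.cleavage_plateau - config.burst_fraction) * (1.0 - np.exp(-config.cleavage_rate * tp)),
        0.0,
        1.0,
    )
    out = []
    for rep in range(replicates):
        noise = rng.normal(0.0, config.cleavage_noise_sd, size=tp.size) if config.cleavage_noise_sd > 0 else np.zeros(tp.size)
        f_obs = np.clip(f_true + noise, 0.0, 1.0)
        measurements = tuple(
            CleavageMeasurement(
                time=float(t),
                intensity_cleaved=config.intensity_scale * f,
                intensity_uncleaved=config.intensity_scale * (1.0 - f),
            )
            for t, f in zip(tp, f_obs)
        )
        out.append(
            CleavageTimecourse(construct=construct, cation=cation, replicate=rep + 1,
                               measurements=measurements)
        )
    return out
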