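"""Synthetic strain-screening datasets with known ground truth.

Emulates the three experimental setups the analysis pipeline consumes:

* a growth screening (scattered-light curves every few minutes plus
  endpoint metabolite samples) across strains and lignocellulosic
  hydrolysate media with condition-dependent lag, rate and no-growth
  outcomes;
* a biosensor screening in which eight fluorescence channels follow
  phase-dependent trends and are emitted as raw / blank / parental /
  reference rows, so the normalisation stage can be closed-loop tested;
* a single-cell microscopy screening in which per-cell fluorescence is
  drawn from one- or two-component mixtures with known weights,
  component CVs and paired-channel correlation.

Everything is parameterised by :class:`StrainSpec` and
:class:`MediumSpec`; the generator returns both the measurement table and
a :class:`SyntheticGroundTruth` holding the true rates, levels and
mixture labels, so recovery can be asserted exactly. A fixed seed gives
bit-identical output.

The growth model is deliberately simple: flat at the inoculum level for
the lag, then logistic growth at the medium-penalised rate towards a
carrying capacity. The inhibitor penalty is a single scalar per medium
(``inhibitor_load``, a weighted sum of the inhibitory compounds in the
composition) acting exponentially on the rate — enough structure to
produce the lag/rate/no-growth phenomenology without a kinetic model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import COLUMNS, MeasurementTable

__all__ = [
    "MediumSpec",
    "StrainSpec",
    "ChannelProfile",
    "MixtureSpec",
    "SyntheticGroundTruth",
    "TEMPLATE_COMPOSITIONS",
    "INHIBITOR_WEIGHTS",
    "PAIRED_CHANNELS",
    "default_media",
    "default_strains",
    "generate_screening_dataset",
    "generate_biosensor_dataset",
    "generate_single_cell_dataset",
    "load_spec_file",
]

#: Relative inhibitory potency per g/L used to reduce a medium's
#: composition to one scalar load. Aldehydes (furfural, HMF) are far more
#: growth-inhibiting per gram than the weak acids.
INHIBITOR_WEIGHTS = {
    "formic_acid": 0.15,
    "acetic_acid": 0.10,
    "levulinic_acid": 0.10,
    "furfural": 1.0,
    "hydroxymethylfurfural": 0.7,
}

#: Undiluted (100%-strength) compositions of seven lignocellulosic
#: hydrolysates, g/L, usable as template media for the generator.
TEMPLATE_COMPOSITIONS: dict[str, tuple[bool, dict[str, float]]] = {
    # name: (woody?, composition)
    "WSH": (False, {"glucose": 82.3, "galactose": 1.3, "arabinose": 3.1, "xylose": 38.1,
                    "formic_acid": 0.2, "acetic_acid": 5.0, "levulinic_acid": 2.1,
                    "furfural": 3.2}),
    "SBH": (False, {"glucose": 95.6, "galactose": 0.7, "arabinose": 2.0, "xylose": 47.1,
                    "acetic_acid": 4.7, "furfural": 1.1}),
    "CSH": (False, {"glucose": 62.5, "galactose": 1.3, "arabinose": 1.9, "xylose": 26.3,
                    "acetic_acid": 2.5, "furfural": 2.7, "hydroxymethylfurfural": 0.4}),
    "OHH": (False, {"glucose": 37.0, "galactose": 2.6, "arabinose": 5.3, "xylose": 87.7,
                    "formic_acid": 3.1, "acetic_acid": 5.1, "furfural": 3.4}),
    "BiH": (True, {"glucose": 124.4, "mannose": 3.2, "galactose": 1.7, "arabinose": 1.1,
                   "xylose": 63.8, "formic_acid": 1.5, "acetic_acid": 13.4,
                   "furfural": 0.6}),
    "HGSH": (True, {"glucose": 84.9, "mannose": 31.6, "galactose": 6.2, "arabinose": 4.0,
                    "xylose": 15.0, "formic_acid": 1.4, "acetic_acid": 7.8,
                    "levulinic_acid": 3.6, "furfural": 0.4, "hydroxymethylfurfural": 0.9}),
    "SLRH": (True, {"glucose": 26.7, "mannose": 21.6, "galactose": 9.4, "arabinose": 4.3,
                    "xylose": 16.5, "formic_acid": 0.1, "acetic_acid": 2.7,
                    "levulinic_acid": 0.7, "furfural": 0.5, "hydroxymethylfurfural": 0.7}),
}

#: Dual-readout sensor pairings: component identity and correlation are
#: shared within a pair when drawing single-cell values.
PAIRED_CHANNELS = {"glycolytic_flux": "OxSR", "ribosome": "UPR"}

_SUGARS = ("glucose", "mannose", "galactose", "xylose", "arabinose")
_HEXOSES = ("glucose", "mannose", "galactose")


@dataclass
class MediumSpec:
    """A (possibly diluted) growth medium."""

    name: str
    woody: bool = False
    dilution_fraction: float = 1.0
    composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.dilution_fraction <= 1):
            raise ValueError("dilution_fraction must be in (0, 1]")

    @property
    def diluted_composition(self) -> dict[str, float]:
        """Composition at working strength: 100%-strength values x dilution."""
        return {k: v * self.dilution_fraction for k, v in self.composition.items()}

    @property
    def inhibitor_load(self) -> float:
        """Scalar inhibitory burden (unitless), weighted over compounds."""
        diluted = self.diluted_composition
        return sum(INHIBITOR_WEIGHTS.get(k, 0.0) * c for k, c in diluted.items())


@dataclass
class ChannelProfile:
    """Phase-dependent true ratio of one biosensor channel.

    The true (noise-free) ratio sits at ``lag_level`` during lag, shifts
    smoothly to ``exp_level`` around the end of lag, and is observed with
    multiplicative log-normal noise of coefficient of variation
    ``noise_cv``.
    """

    lag_level: float = 1.0
    exp_level: float = 1.0
    noise_cv: float = 0.02


@dataclass
class MixtureSpec:
    """Single-cell mixture for one channel: 1 or more log-normal components.

    ``rel_means`` are component means relative to the channel's bulk
    level; ``correlation`` is the within-component log-scale correlation
    with the paired channel.
    """

    weights: tuple[float, ...] = (1.0,)
    rel_means: tuple[float, ...] = (1.0,)
    cvs: tuple[float, ...] = (0.05,)
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not (len(self.weights) == len(self.rel_means) == len(self.cvs)):
            raise ValueError("weights, rel_means and cvs must have equal length")
        if any(cv < 0 for cv in self.cvs):
            raise ValueError("component CVs must be >= 0")


def _default_profiles() -> dict[str, ChannelProfile]:
    # Lag-vs-exponential contrasts mirror the usual physiology: pyruvate
    # metabolism up in exponential phase, ethanol consumption repressed by
    # abundant glucose, pH/ATP flat.
    return {
        "pHi": ChannelProfile(1.0, 1.0),
        "ATP": ChannelProfile(1.2, 1.2),
        "glycolytic_flux": ChannelProfile(1.0, 0.9),
        "OxSR": ChannelProfile(0.8, 1.0),
        "UPR": ChannelProfile(0.7, 0.9),
        "ribosome": ChannelProfile(1.0, 1.3),
        "pyruvate": ChannelProfile(0.8, 1.6),
        "ethanol_consumption": ChannelProfile(1.5, 0.6),
    }


@dataclass
class StrainSpec:
    """Generator parameters for one strain."""

    name: str
    mu_base: float = 0.40          # 1/h, rate in unstressed medium
    lag_base: float = 3.0          # h, lag in unstressed medium
    inhibitor_sensitivity: float = 0.2   # rate penalty per unit load
    yield_ethanol_base: float = 0.42     # g/g hexose
    yield_glycerol_base: float = 0.06
    yield_cell_mass_base: float = 0.10
    biosensor_profile: dict[str, ChannelProfile] = field(default_factory=_default_profiles)
    heterogeneity: dict[str, MixtureSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mu_base <= 0:
            raise ValueError("mu_base must be > 0")
        if self.inhibitor_sensitivity < 0:
            raise ValueError("inhibitor_sensitivity must be >= 0")

    def true_mu(self, medium: MediumSpec) -> float:
        return self.mu_base * float(np.exp(-self.inhibitor_sensitivity * medium.inhibitor_load))

    def true_lag(self, medium: MediumSpec, lag_load_factor: float = 0.6) -> float:
        return self.lag_base * (1.0 + lag_load_factor * medium.inhibitor_load)


@dataclass
class SyntheticGroundTruth:
    """True parameters behind a generated dataset, for recovery tests."""

    growth: pd.DataFrame = field(default_factory=pd.DataFrame)
    biosensor: pd.DataFrame = field(default_factory=pd.DataFrame)
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    params: dict = field(default_factory=dict)

    def to_csv(self, directory) -> list[str]:
        """Write each non-empty truth table to <directory>/truth_<name>.csv."""
        import os
        written = []
        for name in ("growth", "biosensor", "cells"):
            df = getattr(self, name)
            if not df.empty:
                path = os.path.join(directory, f"truth_{name}.csv")
                df.to_csv(path, index=False)
                written.append(path)
        return written


def default_media(dilution_fraction: float = 0.5) -> list[MediumSpec]:
    """The control medium plus seven template hydrolysates at one dilution."""
    media = [MediumSpec("Delft", woody=False, dilution_fraction=1.0,
                        composition={"glucose": 20.0})]
    for name, (woody, comp) in TEMPLATE_COMPOSITIONS.items():
        media.append(MediumSpec(f"{name}{int(round(dilution_fraction * 100))}",
                                woody=woody, dilution_fraction=dilution_fraction,
                                composition=dict(comp)))
    return media


def default_strains() -> list[StrainSpec]:
    """Three archetypes: a lab strain, a robust industrial strain, and a
    heterogeneous industrial strain with a two-component glycolytic-flux /
    oxidative-stress subpopulation structure."""
    lab = StrainSpec("LAB-1", mu_base=0.42, lag_base=3.0, inhibitor_sensitivity=0.35,
                     yield_ethanol_base=0.40, yield_glycerol_base=0.06)
    robust = StrainSpec("IND-R", mu_base=0.38, lag_base=2.5, inhibitor_sensitivity=0.12,
                        yield_ethanol_base=0.44, yield_glycerol_base=0.05)
    hetero = StrainSpec(
        "IND-H", mu_base=0.40, lag_base=4.0, inhibitor_sensitivity=0.22,
        yield_ethanol_base=0.42, yield_glycerol_base=0.07,
        heterogeneity={
            "glycolytic_flux": MixtureSpec(weights=(0.5, 0.5), rel_means=(0.7, 1.4),
                                           cvs=(0.08, 0.08), correlation=0.6),
            "OxSR": MixtureSpec(weights=(0.5, 0.5), rel_means=(0.7, 1.4),
                                cvs=(0.08, 0.08), correlation=0.6),
        },
    )
    return [lab, robust, hetero]


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _rows_to_table(rows: list[dict], metadata: dict[str, str]) -> MeasurementTable:
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["replicate"] = df["replicate"].astype("int64")
    return MeasurementTable(df, metadata)


# ---------------------------------------------------------------------------
# Growth screening
# ---------------------------------------------------------------------------

def _logistic_curve(t: np.ndarray, lag: float, mu: float, x0: float, cap: float) -> np.ndarray:
    """Flat at x0 until ``lag``, then logistic growth at rate ``mu`` to ``cap``."""
    x = np.full_like(t, x0, dtype=float)
    growing = t > lag
    e = np.exp(mu * (t[growing] - lag))
    x[growing] = cap * x0 * e / (cap + x0 * (e - 1.0))
    return x


def generate_screening_dataset(
    strains: list[StrainSpec] | None = None,
    media: list[MediumSpec] | None = None,
    replicates: int = 3,
    duration_h: float = 48.0,
    sampling_min: float = 10.0,
    seed: int = 0,
    noise_cv: float = 0.02,
    inoculum: float = 0.02,
    carrying_capacity: float = 100.0,
    mu_threshold: float = 0.05,
) -> tuple[MeasurementTable, SyntheticGroundTruth]:
    """Simulate a growth screening: scattered-light curves + endpoint samples.

    Each (strain, medium) pair has a true rate ``mu_base * exp(-sensitivity
    * inhibitor_load)`` and a load-lengthened lag; pairs whose true rate
    falls below ``mu_threshold`` produce flat noisy curves and consume no
    sugar. Endpoint concentration rows (``conc:<analyte>`` at t=0 and
    t=duration) are exactly consistent with the true yields, so the yield
    stage recovers them to noise precision.
    """
    strains = default_strains() if strains is None else strains
    media = default_media() if media is None else media
    if not strains or not media or replicates < 1:
        raise ValueError("need at least 1 strain, 1 medium and 1 replicate")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, sampling_min / 60.0)

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for strain in strains:
        for medium in media:
            mu = strain.true_mu(medium)
            grew = mu >= mu_threshold
            lag = strain.true_lag(medium) if grew else duration_h
            comp0 = medium.diluted_composition
            hexose_available = sum(comp0.get(h, 0.0) for h in _HEXOSES)
            consumed = 0.97 * hexose_available if grew else 0.0
            truth_rows.append({
                "system": strain.name, "condition": medium.name,
                "true_mu": mu if grew else 0.0, "true_lag_h": lag, "grew": grew,
                "yield_ethanol": strain.yield_ethanol_base if grew else 0.0,
                "yield_glycerol": strain.yield_glycerol_base if grew else 0.0,
                "yield_cell_mass": strain.yield_cell_mass_base if grew else 0.0,
                "hexose_consumed_g_L": consumed,
                "inhibitor_load": medium.inhibitor_load,
            })
            for rep in range(1, replicates + 1):
                if grew:
                    x = _logistic_curve(t, lag, mu, inoculum, carrying_capacity)
                else:
                    x = np.full_like(t, inoculum)
                obs = x * _lognormal_factor(rng, noise_cv, t.size)
                rows.extend(
                    {"system": strain.name, "condition": medium.name, "replicate": rep,
                     "time_h": ti, "cell_id": None, "function_name": "scattered_light",
                     "value": vi}
                    for ti, vi in zip(t, obs)
                )
                # endpoint samples, exactly consistent with true yields
                end_conc = dict(comp0)
                if grew and hexose_available > 0:
                    frac = consumed / hexose_available
                    for h in _HEXOSES:
                        if h in end_conc:
                            end_conc[h] = end_conc[h] * (1.0 - frac)
                end_conc["ethanol"] = strain.yield_ethanol_base * consumed
                end_conc["glycerol"] = strain.yield_glycerol_base * consumed
                end_conc["cell_dry_weight"] = strain.yield_cell_mass_base * consumed
                meas_noise = _lognormal_factor(rng, noise_cv, len(end_conc) + len(comp0))
                items = list(comp0.items()) + list(end_conc.items())
                for i, (analyte, conc) in enumerate(items):
                    at_t0 = i < len(comp0)
                    rows.append({
                        "system": strain.name, "condition": medium.name, "replicate": rep,
                        "time_h": 0.0 if at_t0 else duration_h, "cell_id": None,
                        "function_name": f"conc:{analyte}",
                        "value": conc * meas_noise[i],
                    })

    table = _rows_to_table(rows, {
        "generator": "screening", "seed": str(seed), "duration_h": str(duration_h),
        "sampling_min": str(sampling_min), "noise_cv": str(noise_cv),
    })
    truth = SyntheticGroundTruth(
        growth=pd.DataFrame(truth_rows),
        params={"seed": seed, "noise_cv": noise_cv, "mu_threshold": mu_threshold,
                "inoculum": inoculum, "carrying_capacity": carrying_capacity},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Biosensor screening
# ---------------------------------------------------------------------------

#: How hydrolysate origin shifts stress channels: woody media (rich in
#: weak acids) raise the unfolded-protein response, non-woody media (rich
#: in aldehydes) raise the oxidative-stress response, most strongly in
#: exponential phase.
_WOODY_UPR_BOOST = 1.5
_NONWOODY_OXSR_BOOST = 1.5
_LAG_BOOST = 1.2

_BLANK_LEVEL = 15.0
_PARENTAL_LEVEL = 10.0
_REFERENCE_LEVEL = 100.0


def _condition_adjusted(profile: ChannelProfile, channel: str, medium: MediumSpec) -> ChannelProfile:
    lag_level, exp_level = profile.lag_level, profile.exp_level
    stressed = medium.inhibitor_load > 0
    if stressed and medium.woody and channel == "UPR":
        lag_level, exp_level = lag_level * _LAG_BOOST, exp_level * _WOODY_UPR_BOOST
    if stressed and not medium.woody and channel == "OxSR":
        lag_level, exp_level = lag_level * _LAG_BOOST, exp_level * _NONWOODY_OXSR_BOOST
    return ChannelProfile(lag_level, exp_level, profile.noise_cv)


def _true_ratio(t: np.ndarray, profile: ChannelProfile, t_mid: float,
                tau_h: float = 1.0) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-(t - t_mid) / tau_h))
    return profile.lag_level + (profile.exp_level - profile.lag_level) * s


def generate_biosensor_dataset(
    strains: list[StrainSpec] | None = None,
    media: list[MediumSpec] | None = None,
    replicates: int = 3,
    duration_h: float = 36.0,
    sampling_min: float = 10.0,
    seed: int = 0,
    noise_cv: float | None = None,
    channels: tuple[str, ...] | None = None,
) -> tuple[MeasurementTable, SyntheticGroundTruth]:
    """Simulate the multi-channel biosensor screening.

    Each channel's true ratio moves smoothly from its lag level to its
    exponential level around the strain's lag end. Raw, blank, parental
    and reference rows are emitted (``biosensor_raw:<ch>`` etc.) such
    that background subtraction and reference normalisation reconstruct
    the true ratio exactly in the zero-noise limit and in expectation
    otherwise. ``noise_cv`` overrides every channel profile's CV when given.
    """
    strains = default_strains() if strains is None else strains
    media = default_media(0.6) if media is None else media
    if not strains or not media or replicates < 1:
        raise ValueError("need at least 1 strain, 1 medium and 1 replicate")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, sampling_min / 60.0)

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for strain in strains:
        use_channels = channels if channels is not None else tuple(strain.biosensor_profile)
        for medium in media:
            t_mid = min(strain.true_lag(medium), duration_h)
            for channel in use_channels:
                profile = _condition_adjusted(strain.biosensor_profile[channel],
                                              channel, medium)
                cv = profile.noise_cv if noise_cv is None else noise_cv
                ratio = _true_ratio(t, profile, t_mid)
                truth_rows.append({
                    "system": strain.name, "condition": medium.name, "channel": channel,
                    "lag_level": profile.lag_level, "exp_level": profile.exp_level,
                    "t_mid_h": t_mid, "true_mean": float(ratio.mean()),
                    "woody": medium.woody,
                })
                for rep in range(1, replicates + 1):
                    signal = ratio * _REFERENCE_LEVEL * _lognormal_factor(rng, cv, t.size)
                    raw = signal + _BLANK_LEVEL + _PARENTAL_LEVEL
                    ref = _REFERENCE_LEVEL * _lognormal_factor(rng, cv, t.size)
                    for fn, series in (
                        (f"biosensor_raw:{channel}", raw),
                        (f"biosensor_blank:{channel}", np.full(t.size, _BLANK_LEVEL)),
                        (f"biosensor_parental:{channel}", np.full(t.size, _PARENTAL_LEVEL)),
                        (f"biosensor_ref:{channel}", ref),
                    ):
                        rows.extend(
                            {"system": strain.name, "condition": medium.name,
                             "replicate": rep, "time_h": ti, "cell_id": None,
                             "function_name": fn, "value": vi}
                            for ti, vi in zip(t, series)
                        )

    table = _rows_to_table(rows, {
        "generator": "biosensor", "seed": str(seed), "duration_h": str(duration_h),
        "sampling_min": str(sampling_min),
    })
    truth = SyntheticGroundTruth(
        biosensor=pd.DataFrame(truth_rows),
        params={"seed": seed, "blank": _BLANK_LEVEL, "parental": _PARENTAL_LEVEL,
                "reference": _REFERENCE_LEVEL},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Single-cell screening
# ---------------------------------------------------------------------------

def generate_single_cell_dataset(
    strains: list[StrainSpec] | None = None,
    media: list[MediumSpec] | None = None,
    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0),
    cells_per_sample: int = 50,
    seed: int = 0,
    channels: tuple[str, ...] = ("glycolytic_flux", "OxSR", "ribosome", "UPR"),
) -> tuple[MeasurementTable, SyntheticGroundTruth]:
    """Simulate per-cell biosensor snapshots with mixture-structured heterogeneity.

    For each (strain, medium, timepoint) sample, ``cells_per_sample``
    cells are drawn. Channels carrying a :class:`MixtureSpec` in the
    strain's ``heterogeneity`` map are drawn as log-normal mixtures;
    paired channels share the component draw and correlate within a
    component, so two subpopulations show up as two clouds in a
    scatter of the pair. Ground truth records every cell's component.
    """
    strains = default_strains() if strains is None else strains
    media = default_media(0.5) if media is None else media
    if cells_per_sample < 1:
        raise ValueError("cells_per_sample must be >= 1")
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    cell_rows: list[dict] = []
    # channels drawn jointly: leaders draw the component, partners follow
    leaders = [c for c in channels if c in PAIRED_CHANNELS and PAIRED_CHANNELS[c] in channels]
    solo = [c for c in channels
            if c not in leaders and c not in {PAIRED_CHANNELS[l] for l in leaders}]

    for strain in strains:
        for medium in media:
            for t in timepoints:
                t_mid = strain.true_lag(medium)
                for i in range(1, cells_per_sample + 1):
                    cell = f"c{i:04d}"
                    drawn: dict[str, float] = {}
                    component_label = 0
                    for leader in leaders:
                        partner = PAIRED_CHANNELS[leader]
                        mix = strain.heterogeneity.get(leader, MixtureSpec())
                        mix_p = strain.heterogeneity.get(partner, mix)
                        k = int(rng.choice(len(mix.weights), p=mix.weights))
                        component_label = max(component_label, k)
                        base_l = _true_ratio(np.array([t]), _condition_adjusted(
                            strain.biosensor_profile[leader], leader, medium), t_mid)[0]
                        base_p = _true_ratio(np.array([t]), _condition_adjusted(
                            strain.biosensor_profile[partner], partner, medium), t_mid)[0]
                        kp = min(k, len(mix_p.rel_means) - 1)
                        mean_l = base_l * mix.rel_means[k]
                        mean_p = base_p * mix_p.rel_means[kp]
                        sig_l = float(np.sqrt(np.log1p(mix.cvs[k] ** 2)))
                        sig_p = float(np.sqrt(np.log1p(mix_p.cvs[kp] ** 2)))
                        rho = mix.correlation
                        cov = np.array([[sig_l ** 2, rho * sig_l * sig_p],
                                        [rho * sig_l * sig_p, sig_p ** 2]])
                        z = rng.multivariate_normal([0.0, 0.0], cov)
                        drawn[leader] = mean_l * float(np.exp(z[0] - 0.5 * sig_l ** 2))
                        drawn[partner] = mean_p * float(np.exp(z[1] - 0.5 * sig_p ** 2))
                    for channel in solo:
                        mix = strain.heterogeneity.get(channel, MixtureSpec())
                        k = int(rng.choice(len(mix.weights), p=mix.weights))
                        component_label = max(component_label, k)
                        base = _true_ratio(np.array([t]), _condition_adjusted(
                            strain.biosensor_profile[channel], channel, medium), t_mid)[0]
                        sig = float(np.sqrt(np.log1p(mix.cvs[k] ** 2)))
                        drawn[channel] = (base * mix.rel_means[k]
                                          * float(rng.lognormal(-0.5 * sig * sig, sig)))
                    for channel, value in drawn.items():
                        rows.append({
                            "system": strain.name, "condition": medium.name,
                            "replicate": 1, "time_h": t, "cell_id": cell,
                            "function_name": f"biosensor:{channel}", "value": value,
                        })
                    cell_rows.append({
                        "system": strain.name, "condition": medium.name, "time_h": t,
                        "cell_id": cell, "component": component_label,
                    })

    table = _rows_to_table(rows, {
        "generator": "single_cell", "seed": str(seed),
        "cells_per_sample": str(cells_per_sample),
    })
    truth = SyntheticGroundTruth(
        cells=pd.DataFrame(cell_rows),
        params={"seed": seed, "cells_per_sample": cells_per_sample,
                "heterogeneity": {s.name: {ch: vars(m) for ch, m in s.heterogeneity.items()}
                                  for s in strains}},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Spec files
# ---------------------------------------------------------------------------

def load_spec_file(path) -> tuple[list[StrainSpec], list[MediumSpec], dict]:
    """Load generator specs from YAML or JSON.

    Layout: top-level ``strains`` and ``media`` lists mirroring the
    dataclass fields, plus an optional ``settings`` map passed through to
    the generator call. Omitted fields take the dataclass defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    strains = []
    for s in doc.get("strains", []):
        s = dict(s)
        profile = {ch: ChannelProfile(**p) for ch, p in s.pop("biosensor_profile", {}).items()}
        het = {ch: MixtureSpec(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in m.items()})
               for ch, m in s.pop("heterogeneity", {}).items()}
        spec = StrainSpec(**s)
        if profile:
            spec.biosensor_profile.update(profile)
        spec.heterogeneity = het
        strains.append(spec)
    media = [MediumSpec(**m) for m in doc.get("media", [])]
    return strains, media, doc.get("settings", {})
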