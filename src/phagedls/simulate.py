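"""Synthetic DLS spectra of decaying phage preparations.

The generator embodies the structure-function picture that motivates
DLS-based quality control: an intact phage preparation scatters as a single
quasi-lognormal peak near the virion's hydrodynamic diameter; as the
preparation decays, intensity moves into sub-virion fragments and, mostly,
into large aggregates (hundreds of nm to several um), and the lytic titer
falls.  A latent damage parameter lambda in [0, 1] couples the two:

* spectral mixture weights: intact (1 - lambda), aggregate lambda * a_frac,
  fragment lambda * (1 - a_frac);
* true titer loss: titer_slope * lambda, plus Gaussian plaque-assay noise.

Because the mixture interpolates linearly between the intact and fully
damaged spectra, the noise-free AUC-delta against baseline is *exactly*
linear in lambda -- the regime in which the linear titer-loss calibration
is exact.  Replicate measurement error is emulated as multiplicative
per-bin intensity jitter followed by renormalization.

The module also provides deterministic canonical fixtures (intact vs
sonicated preparations, an aged archival phage, a predicted fresh
baseline) so the whole pipeline is testable without instrument data.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .calibration import PairedObservation
from .spectra import (
    DLSSpectrum,
    NORMALIZED_AREA,
    SampleRecord,
    SizeGrid,
    average_replicates,
    default_grid,
    normalize,
)
from .aucdelta import auc_delta

__all__ = [
    "SpeciesComponent",
    "DecayConfig",
    "DecayDataset",
    "SimulatedSample",
    "mixture_spectrum",
    "damage_weights",
    "simulate_decay",
    "paired_observations",
    "canonical_fixture",
    "CANONICAL_FIXTURES",
    "config_from_dict",
]


@dataclasses.dataclass(frozen=True)
class SpeciesComponent:
    """One particle species: a lognormal intensity peak.

    ``mode_nm`` is the peak diameter; ``gsd`` the geometric standard
    deviation (>1; the peak is Gaussian in log10-diameter with SD
    log10(gsd)); ``weight`` its fraction of total spectral area.
    """

    mode_nm: float
    gsd: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.mode_nm <= 0:
            raise ValueError("mode_nm must be > 0")
        if self.gsd <= 1:
            raise ValueError("gsd must be > 1")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("weight must lie in [0, 1]")


def _component_spectrum(comp: SpeciesComponent, grid: SizeGrid) -> np.ndarray:
    """Area-100 spectrum of a single species on ``grid`` (renormalized
    within the grid, so mixture weights are exact area fractions)."""
    log_c = np.log10(grid.centers)
    dens = stats.norm.pdf(log_c, loc=np.log10(comp.mode_nm), scale=np.log10(comp.gsd))
    intensity = dens * grid.log_widths
    total = intensity.sum()
    if total <= 0:
        raise ValueError(f"component at {comp.mode_nm} nm has no mass on the grid")
    return intensity * (NORMALIZED_AREA / total)


def mixture_spectrum(
    components: Sequence[SpeciesComponent],
    grid: SizeGrid | None = None,
    label: str = "",
) -> DLSSpectrum:
    """Normalized spectrum of a weighted mixture of lognormal species.

    Weights must sum to 1 (within 1e-9) and every mode must lie inside the
    grid span.  Each component is normalized to area 100 within the grid
    before mixing, so ``weight`` is exactly the component's share of area.
    """
    if grid is None:
        grid = default_grid()
    comps = list(components)
    if not comps:
        raise ValueError("mixture needs at least one component")
    wsum = sum(c.weight for c in comps)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"component weights must sum to 1, got {wsum}")
    lo, hi = grid.span_nm
    for c in comps:
        if not (lo <= c.mode_nm <= hi):
            raise ValueError(f"component mode {c.mode_nm} nm outside grid span")
    intensity = np.zeros(grid.n_bins)
    for c in comps:
        if c.weight > 0:
            intensity += c.weight * _component_spectrum(c, grid)
    return DLSSpectrum(grid=grid, intensity=intensity, label=label, is_normalized=True)


#: Default species, emulating an intact preparation near 100 nm that decays
#: into 90 nm fragments and broad aggregates centered at 2 um (the observed
#: aggregate range runs ~500-8,000 nm).
_DEFAULT_INTACT = SpeciesComponent(mode_nm=100.0, gsd=1.25, weight=1.0)
_DEFAULT_FRAGMENT = SpeciesComponent(mode_nm=90.0, gsd=1.25, weight=1.0)
_DEFAULT_AGGREGATE = SpeciesComponent(mode_nm=2000.0, gsd=2.0, weight=1.0)


@dataclasses.dataclass(frozen=True)
class DecayConfig:
    """Parameters of the synthetic decay experiment.

    Defaults emulate the study conditions: stocks near 10^9 PFU/mL, three
    DLS replicates per sample, plaque-assay noise ~0.3 log10, decay driven
    mostly by aggregation (a_frac = 0.8), and a titer loss of 6 log10 at
    full damage.
    """

    intact: SpeciesComponent = _DEFAULT_INTACT
    fragment: SpeciesComponent = _DEFAULT_FRAGMENT
    aggregate: SpeciesComponent = _DEFAULT_AGGREGATE
    #: fraction of damaged intensity going to aggregates (rest to fragments)
    a_frac: float = 0.8
    #: fixed damage level for all samples; None -> uniform draw per sample
    damage: float | None = None
    #: log10 titer loss at full damage (lambda = 1)
    titer_slope: float = 6.0
    #: SD of multiplicative per-bin replicate intensity jitter (log scale)
    noise_sd_intensity: float = 0.05
    #: SD of plaque-assay noise on the log10 titer loss
    noise_sd_titer: float = 0.3
    baseline_titer_log10: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.damage is not None and not (0.0 <= self.damage <= 1.0):
            raise ValueError("damage must lie in [0, 1]")
        if not (0.0 <= self.a_frac <= 1.0):
            raise ValueError("a_frac must lie in [0, 1]")
        if self.noise_sd_intensity < 0 or self.noise_sd_titer < 0:
            raise ValueError("noise SDs must be >= 0")


def damage_weights(config: DecayConfig, lam: float) -> list[SpeciesComponent]:
    """Mixture components at damage level ``lam``."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("damage must lie in [0, 1]")
    return [
        dataclasses.replace(config.intact, weight=1.0 - lam),
        dataclasses.replace(config.aggregate, weight=lam * config.a_frac),
        dataclasses.replace(config.fragment, weight=lam * (1.0 - config.a_frac)),
    ]


def _jitter(
    spectrum: DLSSpectrum, sd: float, rng: np.random.Generator, label: str
) -> DLSSpectrum:
    if sd <= 0:
        return dataclasses.replace(normalize(spectrum), label=label)
    noisy = spectrum.intensity * rng.lognormal(mean=0.0, sigma=sd, size=spectrum.intensity.size)
    return normalize(DLSSpectrum(grid=spectrum.grid, intensity=noisy, label=label))


@dataclasses.dataclass(frozen=True)
class SimulatedSample:
    """A simulated sample with its latent ground truth."""

    record: SampleRecord
    damage: float
    titer_loss_log10: float


@dataclasses.dataclass(frozen=True)
class DecayDataset:
    config: DecayConfig
    grid: SizeGrid
    baseline: SampleRecord
    samples: list[SimulatedSample]


def simulate_decay(
    config: DecayConfig,
    n_samples: int,
    n_replicates: int = 3,
    damage_schedule: Sequence[float] | None = None,
    phage_id: str = "simphage",
    grid: SizeGrid | None = None,
) -> DecayDataset:
    """Generate a baseline and ``n_samples`` decayed samples with titers.

    Damage levels come from ``damage_schedule`` if given, else from
    ``config.damage`` (fixed), else uniform draws on [0, 1].  All
    randomness derives from ``config.seed``; identical inputs give
    bit-identical outputs.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(config.seed)
    if damage_schedule is not None:
        lams = np.asarray(list(damage_schedule), dtype=float)
        if lams.size != n_samples:
            raise ValueError("damage_schedule length must equal n_samples")
    elif config.damage is not None:
        lams = np.full(n_samples, config.damage)
    else:
        lams = rng.uniform(0.0, 1.0, size=n_samples)

    def replicates(mean_spec: DLSSpectrum, tag: str) -> list[DLSSpectrum]:
        return [
            _jitter(mean_spec, config.noise_sd_intensity, rng, f"{tag}_r{j + 1}")
            for j in range(n_replicates)
        ]

    base_spec = mixture_spectrum(damage_weights(config, 0.0), grid, label="baseline")
    baseline = SampleRecord(
        phage_id=phage_id,
        condition="baseline",
        timepoint=0.0,
        replicates=replicates(base_spec, "baseline"),
        titer_log10=config.baseline_titer_log10,
    )

    samples = []
    for i, lam in enumerate(lams):
        tag = f"sample_{i + 1:03d}"
        spec = mixture_spectrum(damage_weights(config, float(lam)), grid, label=tag)
        noise = rng.normal(0.0, config.noise_sd_titer) if config.noise_sd_titer > 0 else 0.0
        loss = config.titer_slope * float(lam) + noise
        samples.append(
            SimulatedSample(
                record=SampleRecord(
                    phage_id=phage_id,
                    condition="decayed",
                    timepoint=float(i + 1),
                    replicates=replicates(spec, tag),
                    titer_log10=config.baseline_titer_log10 - loss,
                ),
                damage=float(lam),
                titer_loss_log10=loss,
            )
        )
    return DecayDataset(config=config, grid=grid, baseline=baseline, samples=samples)


def paired_observations(dataset: DecayDataset) -> list[PairedObservation]:
    """AUC-delta vs averaged baseline, paired with each sample's titer loss."""
    base_mean = average_replicates(dataset.baseline.replicates, grid=dataset.grid)
    pairs = []
    for s in dataset.samples:
        mean = average_replicates(s.record.replicates, grid=dataset.grid)
        pairs.append(
            PairedObservation(
                auc_delta=auc_delta(mean, base_mean).value,
                titer_loss_log10=s.titer_loss_log10,
                phage_id=s.record.phage_id,
                condition=s.record.condition,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Canonical fixtures
#
# Deterministic spectra emulating well-characterized preparations: a fresh
# ~100 nm virion peak; the same preparation sonicated into 90 nm fragments
# plus 500-8,000 nm aggregates; clinical-trial phages with virion peaks at
# 120/150 nm (implementation constants); a 50-year archival phage whose
# surviving peak sits at 200 nm; and a predicted fresh baseline at 60 nm.
# Peak widths are implementation constants (gsd 1.25 virions, 2.0 aggregates).
# ---------------------------------------------------------------------------

CANONICAL_FIXTURES: Mapping[str, tuple[SpeciesComponent, ...]] = {
    "LPS5_intact": (SpeciesComponent(100.0, 1.25, 1.0),),
    "LPS5_sonicated": (
        SpeciesComponent(90.0, 1.25, 0.3),
        SpeciesComponent(2000.0, 2.0, 0.7),
    ),
    "TIVP_H6": (SpeciesComponent(120.0, 1.25, 1.0),),
    "OMKO1": (SpeciesComponent(150.0, 1.25, 1.0),),
    "T6_aged": (SpeciesComponent(200.0, 1.25, 1.0),),
    "T3_predicted_baseline": (SpeciesComponent(60.0, 1.25, 1.0),),
}


def canonical_fixture(name: str, n_replicates: int = 3) -> SampleRecord:
    """Deterministic canonical sample (identical replicates, no noise)."""
    try:
        components = CANONICAL_FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(CANONICAL_FIXTURES)}"
        ) from None
    grid = default_grid()
    spec = mixture_spectrum(components, grid, label=name)
    return SampleRecord(
        phage_id=name,
        condition="fixture",
        replicates=[spec.with_label(f"{name}_r{j + 1}") for j in range(n_replicates)],
    )


# ---------------------------------------------------------------------------
# Config parsing (for the CLI's simulate command)
# ---------------------------------------------------------------------------

_COMPONENT_KEYS = {"mode_nm", "gsd"}
_TOP_KEYS = {
    "n_samples",
    "n_replicates",
    "seed",
    "damage",
    "damage_schedule",
    "a_frac",
    "titer_slope",
    "noise_sd_intensity",
    "noise_sd_titer",
    "baseline_titer_log10",
    "phage_id",
    "intact",
    "fragment",
    "aggregate",
}


def _parse_component(name: str, d: Mapping, default: SpeciesComponent) -> SpeciesComponent:
    unknown = set(d) - _COMPONENT_KEYS
    if unknown:
        raise ValueError(f"unknown key {sorted(unknown)[0]!r} in component {name!r}")
    return SpeciesComponent(
        mode_nm=float(d.get("mode_nm", default.mode_nm)),
        gsd=float(d.get("gsd", default.gsd)),
        weight=1.0,
    )


def config_from_dict(d: Mapping) -> tuple[DecayConfig, dict]:
    """Build a DecayConfig plus run options (n_samples, ...) from a mapping.

    Unknown keys raise, naming the offending key.
    """
    unknown = set(d) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key {sorted(unknown)[0]!r}")
    config = DecayConfig(
        intact=_parse_component("intact", d.get("intact", {}), _DEFAULT_INTACT),
        fragment=_parse_component("fragment", d.get("fragment", {}), _DEFAULT_FRAGMENT),
        aggregate=_parse_component("aggregate", d.get("aggregate", {}), _DEFAULT_AGGREGATE),
        a_frac=float(d.get("a_frac", 0.8)),
        damage=None if d.get("damage") is None else float(d["damage"]),
        titer_slope=float(d.get("titer_slope", 6.0)),
        noise_sd_intensity=float(d.get("noise_sd_intensity", 0.05)),
        noise_sd_titer=float(d.get("noise_sd_titer", 0.3)),
        baseline_titer_log10=float(d.get("baseline_titer_log10", 9.0)),
        seed=int(d.get("seed", 0)),
    )
    options = {
        "n_samples": int(d.get("n_samples", 30)),
        "n_replicates": int(d.get("n_replicates", 3)),
        "damage_schedule": d.get("damage_schedule"),
        "phage_id": str(d.get("phage_id", "simphage")),
    }
    return config, options
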