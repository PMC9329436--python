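"""Seeded synthetic data with the statistical structure the screen assumes.

Event-level wells are drawn from two-component lognormal mixtures per
channel: a baseline population and a stressed population shifted in
log-intensity, with the stressed fraction following a Hill curve in
concentration.  This emulates the dose-dependent subpopulation shifts the
flow screen measures without modelling dye biophysics.  The module also
generates labelled training libraries (analytically, or through the full
event-level pipeline) and quadruplicate 4PL viability plates with
multiplicative noise, so every pipeline stage is testable end to end.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import LABEL_NO, LABEL_YES, TrainingExample
from .flow import DEFAULT_PANEL, ChannelPanel, EventMatrix
from .plates import (ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_TEST, DoseSeries,
                     PlateMap, build_dose_series)
from .qf import PhenotypeVector, QFCurve, feature_names, phenotype_vector

#: baseline log-intensity medians (natural log, instrument units): scatter
#: channels sit well above the fluorescence channels, as on a real cytometer
_DEFAULT_BASELINE_LOGMU = {"FSC": 10.8, "SSC": 10.2}
_FLUOR_BASELINE_LOGMU = 5.7  # ≈ ln(300); arcsinh cofactor 150 is mid-scale


def hill_fraction(concentration: float, ec50: float, hill: float) -> float:
    """Fractional occupancy Hill curve in [0, 1); 0 at zero concentration."""
    if concentration <= 0:
        return 0.0
    r = (concentration / ec50) ** hill
    return r / (1.0 + r)


@dataclass(frozen=True)
class ChannelEffect:
    """Dose-dependent stress response of one detection channel."""

    ec50: float                    # µM
    max_shift: float               # log-intensity shift of the stressed mode
    max_stressed_fraction: float   # asymptotic stressed subpopulation
    hill: float = 1.5

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if not 0.0 <= self.max_stressed_fraction <= 1.0:
            raise ValueError("max_stressed_fraction must lie in [0, 1]")

    @property
    def qf_amplitude(self) -> float:
        """Asymptotic QF-distance amplitude used by the analytic shortcut."""
        return self.max_stressed_fraction * abs(self.max_shift)


@dataclass(frozen=True)
class StressProfile:
    compound_id: str
    effects: dict[str, ChannelEffect] = field(default_factory=dict)
    label: str | None = None


def null_profile(compound_id: str = "vehicle") -> StressProfile:
    return StressProfile(compound_id=compound_id)


def positive_control_profile(panel: ChannelPanel = DEFAULT_PANEL,
                             compound_id: str = "positive-control") -> StressProfile:
    """A strong broad stressor, as the mix-specific positive controls are
    chosen to give optimal response across their dye subset."""
    effects = {ch: ChannelEffect(ec50=1.0, max_shift=1.5,
                                 max_stressed_fraction=0.9)
               for ch in panel.names}
    return StressProfile(compound_id=compound_id, effects=effects,
                         label=LABEL_YES)


def endpoint_stressor(channels: list[str], compound_id: str = "stressor", *,
                      ec50: float = 1.0, max_shift: float = 2.0,
                      max_stressed_fraction: float = 0.9,
                      hill: float = 1.5) -> StressProfile:
    """A stressor acting only on the given channels (endpoint-specific)."""
    effects = {ch: ChannelEffect(ec50=ec50, max_shift=max_shift,
                                 max_stressed_fraction=max_stressed_fraction,
                                 hill=hill)
               for ch in channels}
    return StressProfile(compound_id=compound_id, effects=effects,
                         label=LABEL_YES)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screen.

    Defaults mirror the physical assay: 10,000 events per well (the
    autosampler aspiration target), 5% CV multiplicative viability noise,
    quadruplicate viability plates, and a 10-step 3× series topping at
    100 µM.
    """

    seed: int
    n_events_per_well: int = 10_000
    event_sigma: float = 0.5        # lognormal shape of each component
    viability_cv: float = 0.05
    qf_noise_sd: float = 0.03       # analytic-shortcut curve noise
    baseline_logmu: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_events_per_well < 1:
            raise ValueError("n_events_per_well must be positive")

    def logmu(self, channel: str) -> float:
        if channel in self.baseline_logmu:
            return self.baseline_logmu[channel]
        return _DEFAULT_BASELINE_LOGMU.get(channel, _FLUOR_BASELINE_LOGMU)


def simulate_well_events(profile: StressProfile, concentration: float,
                         config: SimulationConfig, *,
                         panel: ChannelPanel = DEFAULT_PANEL,
                         well: str = "sim",
                         rng: np.random.Generator | None = None) -> EventMatrix:
    """Draw one well's 12-channel event matrix from the mixture model.

    Per channel the stressed fraction is
    ``max_stressed_fraction × Hill(concentration; ec50, hill)``; stressed
    events are shifted by ``max_shift`` in log-intensity.  Deterministic
    for a given (profile, concentration, config.seed).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_events_per_well
    cols = []
    for ch in panel.names:
        mu = config.logmu(ch)
        eff = profile.effects.get(ch)
        frac = (eff.max_stressed_fraction
                * hill_fraction(concentration, eff.ec50, eff.hill)
                if eff is not None else 0.0)
        n_stressed = rng.binomial(n, frac)
        z = rng.standard_normal(n)
        shift = np.zeros(n)
        if n_stressed:
            shift[:n_stressed] = eff.max_shift
        vals = np.exp(mu + shift + config.event_sigma * z)
        cols.append(rng.permutation(vals))
    return EventMatrix(well=well, channels=list(panel.names),
                       values=np.column_stack(cols))


def simulate_screen(profiles: list[StressProfile], platemap: PlateMap,
                    config: SimulationConfig, *,
                    panel: ChannelPanel = DEFAULT_PANEL,
                    positive_profile: StressProfile | None = None,
                    positive_concentration: float = 100.0) -> dict[str, EventMatrix]:
    """Simulate every non-blank well of a plate; returns address → events.

    Test wells use their mapped compound and concentration, negative
    controls are baseline draws, positive controls use a designated strong
    stressor at ``positive_concentration``.
    """
    by_id = {p.compound_id: p for p in profiles}
    missing = set(platemap.compounds) - set(by_id)
    if missing:
        raise ValueError(f"no stress profile for compounds {sorted(missing)}")
    pos = positive_profile or positive_control_profile(panel)
    master = np.random.default_rng(config.seed)
    out: dict[str, EventMatrix] = {}
    for addr in sorted(platemap.wells, key=lambda a: (a[0], int(a[1:]))):
        spec = platemap.wells[addr]
        child = np.random.default_rng(master.integers(2**31))
        if spec.role == ROLE_TEST:
            out[addr] = simulate_well_events(
                by_id[spec.compound_id], spec.concentration, config,
                panel=panel, well=addr, rng=child)
        elif spec.role == ROLE_NEGATIVE:
            out[addr] = simulate_well_events(null_profile(), 0.0, config,
                                             panel=panel, well=addr, rng=child)
        elif spec.role == ROLE_POSITIVE:
            out[addr] = simulate_well_events(pos, positive_concentration,
                                             config, panel=panel, well=addr,
                                             rng=child)
    return out


# ---- training library ---------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Class-separation prior for the two-class training library.

    "yes"-class compounds stress several channels with large amplitudes;
    "no"-class compounds are near-null.  Amplitudes are QF-curve
    amplitudes (see :attr:`ChannelEffect.qf_amplitude`).
    """

    amp_yes: tuple[float, float] = (1.0, 2.5)
    amp_no: tuple[float, float] = (0.0, 0.2)
    n_channels_yes: tuple[int, int] = (3, 8)
    n_channels_no: tuple[int, int] = (0, 2)
    ec50_range_um: tuple[float, float] = (0.05, 20.0)
    hill: float = 1.5


def _draw_profile(compound_id: str, label: str, spec: EffectSpec,
                  rng: np.random.Generator,
                  panel: ChannelPanel) -> StressProfile:
    if label == LABEL_YES:
        lo, hi = spec.n_channels_yes
        amp_lo, amp_hi = spec.amp_yes
    else:
        lo, hi = spec.n_channels_no
        amp_lo, amp_hi = spec.amp_no
    k = int(rng.integers(lo, hi + 1))
    channels = rng.choice(panel.names, size=k, replace=False) if k else []
    effects = {}
    for ch in channels:
        amp = rng.uniform(amp_lo, amp_hi)
        ec50 = float(np.exp(rng.uniform(*np.log(spec.ec50_range_um))))
        # realise the amplitude as a strongly shifted partial subpopulation
        frac = float(np.clip(rng.uniform(0.5, 0.95), 0, 1))
        effects[str(ch)] = ChannelEffect(ec50=ec50, max_shift=amp / frac,
                                         max_stressed_fraction=frac,
                                         hill=spec.hill)
    return StressProfile(compound_id=compound_id, effects=effects, label=label)


def analytic_phenotype(profile: StressProfile, config: SimulationConfig,
                       series: DoseSeries, *,
                       panel: ChannelPanel = DEFAULT_PANEL,
                       rng: np.random.Generator | None = None) -> PhenotypeVector:
    """Fast analytic shortcut: synthesise each channel's QF dose-response
    curve directly (amplitude × Hill plus folded-Gaussian noise) and run it
    through the real curve-reduction code, skipping event sampling.

    Flagged shortcut: it shares the curve-level statistics of the
    event-level pipeline but not its event-sampling variance.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    concs = tuple(sorted(series.concentrations))
    curves = []
    for ch in panel.names:
        eff = profile.effects.get(ch)
        base = np.abs(rng.normal(0.0, config.qf_noise_sd, len(concs)))
        if eff is not None:
            signal = np.array([eff.qf_amplitude
                               * hill_fraction(c, eff.ec50, eff.hill)
                               for c in concs])
            d = signal + base
        else:
            d = base
        curves.append(QFCurve(compound_id=profile.compound_id, channel=ch,
                              concentrations=concs, distances=tuple(d)))
    return phenotype_vector(curves, panel)


def simulate_training_library(n_yes: int, n_no: int,
                              effect: EffectSpec | None = None,
                              config: SimulationConfig | None = None, *,
                              panel: ChannelPanel = DEFAULT_PANEL,
                              series: DoseSeries | None = None,
                              pipeline: bool = False) -> list[TrainingExample]:
    """A labelled two-class compound library of phenotype vectors.

    With ``pipeline=False`` (default) phenotypes come from the analytic
    shortcut; ``pipeline=True`` runs full event-level simulation through
    the QF reduction (slow; meant for small n).
    """
    if n_yes < 2 or n_no < 2:
        raise ValueError("need at least 2 compounds per class")
    effect = effect or EffectSpec()
    config = config or SimulationConfig(seed=0)
    series = series or build_dose_series(100.0, 10, 3.0)
    rng = np.random.default_rng(config.seed)

    labels = [LABEL_YES] * n_yes + [LABEL_NO] * n_no
    examples = []
    for i, label in enumerate(labels):
        cid = f"{'Y' if label == LABEL_YES else 'N'}{i:04d}"
        profile = _draw_profile(cid, label, effect, rng, panel)
        if pipeline:
            phen = _pipeline_phenotype(profile, config, series, panel, rng)
        else:
            phen = analytic_phenotype(profile, config, series, panel=panel,
                                      rng=rng)
        examples.append(TrainingExample(compound_id=cid, phenotype=phen,
                                        label=label))
    return examples


def _pipeline_phenotype(profile, config, series, panel, rng):
    from .qf import gaussian_kernel, qf_dose_curve

    kernel = gaussian_kernel(64)
    negs = [simulate_well_events(null_profile(), 0.0, config, panel=panel,
                                 well=f"neg{i}",
                                 rng=np.random.default_rng(rng.integers(2**31)))
            for i in range(4)]
    grouped = {c: [simulate_well_events(
        profile, c, config, panel=panel, well=f"t{c:g}r{r}",
        rng=np.random.default_rng(rng.integers(2**31))) for r in (1, 2)]
        for c in series.concentrations}
    curves = [qf_dose_curve(grouped, negs, ch, kernel,
                            compound_id=profile.compound_id, panel=panel)
              for ch in panel.names]
    return phenotype_vector(curves, panel)


# ---- viability plates ----------------------------------------------------

@dataclass(frozen=True)
class ViabilityTruth:
    """Ground-truth 4PL parameters (inhibition convention, hill > 0)."""

    ic50: float
    hill: float = 1.0
    top: float = 1.0
    bottom: float = 0.0

    def response(self, c: float) -> float:
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (c / self.ic50) ** self.hill)


def simulate_viability_plate(truths: dict[tuple[str, str], ViabilityTruth],
                             series: DoseSeries, n_reps: int = 4,
                             config: SimulationConfig | None = None) -> pd.DataFrame:
    """Quadruplicate viability responses with multiplicative noise.

    Returns tidy rows (well, compound_id, cell_line, concentration_uM,
    response); responses are 4PL(c) × (1 + CV·ε) with ε standard normal.
    """
    config = config or SimulationConfig(seed=0)
    rng = np.random.default_rng(config.seed)
    rows = []
    widx = 0
    for (compound, line), truth in truths.items():
        for c in series.concentrations:
            for rep in range(n_reps):
                eps = rng.standard_normal()
                rows.append({
                    "well": f"W{widx:04d}", "compound_id": compound,
                    "cell_line": line, "concentration_uM": c,
                    "replicate": rep + 1,
                    "response": truth.response(c) * (1.0 + config.viability_cv * eps),
                })
                widx += 1
    return pd.DataFrame(rows)
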