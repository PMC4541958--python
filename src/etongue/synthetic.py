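"""Synthetic cyclic-voltammogram generator.

Real multi-electrode rice-solution measurements are not publicly deposited,
so this module generates datasets with the statistical structure the analysis
pipeline assumes:

* each working electrode (Pt, Ag, Au, Pd) has a characteristic waveform built
  as a small capacitive baseline (proportional to the triangle-wave potential)
  plus a fixed set of Gaussian "landmark" bumps — the peaks and troughs a
  chemist would circle on the current-time chart.  Pt, Au and Pd carry 5
  designed landmarks each and Ag carries 3;
* the four rice varieties differ by class-specific perturbations of the bump
  amplitudes, scaled by ``between_class_separation``;
* dilution shrinks every class waveform toward the grand-mean waveform by a
  per-dilution attenuation factor, so class differences (not the signal
  itself) fade with dilution while measurement noise stays constant;
* each commercial sample carries a random constant current offset per channel
  (bottling/batch effect) and each replicate measurement adds i.i.d. Gaussian
  noise.

Waveforms are treated purely as patterns: no redox kinetics are modelled.
The generator is fully deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    CHANNELS,
    CODE_TO_LABEL,
    DEFAULT_RECORD_LENGTH,
    ExcitationProgram,
    LabeledDataset,
    SampleRecord,
    Voltammogram,
)

#: Designed landmark bumps per channel: (center index, relative amplitude,
#: width in samples).  Signs alternate along the sweep so every interior
#: extremum of the noise-free waveform is a designed landmark; the dominant
#: positive bump of each channel sits at/near the +2 V triangle apex
#: (index 2000 at the reference settings) and the deepest negative bump near
#: a −2 V end of the sweep.
BASE_BUMPS: dict[str, tuple[tuple[int, float, float], ...]] = {
    "Pt": (
        (350, -0.90, 150.0),
        (1300, 0.55, 140.0),
        (1700, -0.40, 110.0),
        (2000, 1.00, 130.0),
        (3000, -0.65, 160.0),
    ),
    "Ag": (
        (600, -0.75, 170.0),
        (2000, 1.00, 150.0),
        (3400, -0.55, 150.0),
    ),
    "Au": (
        (500, -0.80, 150.0),
        (1250, 0.50, 130.0),
        (1750, -0.45, 110.0),
        (2050, 1.00, 130.0),
        (3200, -0.60, 160.0),
    ),
    "Pd": (
        (400, -0.85, 150.0),
        (1950, 1.00, 140.0),
        (2600, -0.50, 130.0),
        (3100, 0.40, 120.0),
        (3700, -0.70, 110.0),
    ),
}

#: Per-class relative amplitude perturbations (one entry per bump, in [-1, 1]).
#: Multiplied by ``between_class_separation`` to set how strongly varieties
#: differ.  Values are an arbitrary fixed design, chosen once so that no two
#: classes share a pattern on any channel.
_CLASS_DELTAS: dict[int, dict[str, tuple[float, ...]]] = {
    1: {
        "Pt": (1.0, -0.5, 0.3, -0.8, 0.6),
        "Ag": (0.7, -0.6, 0.4),
        "Au": (-0.9, 0.5, -0.2, 0.8, -0.4),
        "Pd": (0.5, 0.9, -0.7, 0.2, -0.6),
    },
    2: {
        "Pt": (-0.8, 0.9, -0.4, 0.5, -0.3),
        "Ag": (-0.5, 0.8, -0.7),
        "Au": (0.6, -0.7, 0.9, -0.3, 0.2),
        "Pd": (-0.4, -0.8, 0.6, -0.9, 0.7),
    },
    3: {
        "Pt": (0.4, 0.6, -0.9, -0.2, 0.8),
        "Ag": (0.9, 0.3, -0.8),
        "Au": (-0.3, -0.9, 0.6, 0.4, -0.7),
        "Pd": (0.8, -0.3, -0.5, 0.7, 0.4),
    },
    4: {
        "Pt": (-0.6, -0.7, 0.8, 0.4, -0.9),
        "Ag": (-0.8, -0.4, 0.9),
        "Au": (0.7, 0.8, -0.5, -0.6, 0.3),
        "Pd": (-0.7, 0.4, 0.9, -0.3, -0.8),
    },
}


@dataclass(frozen=True)
class ChannelWave:
    """Waveform recipe for one electrode: landmark bumps over a baseline."""

    bumps: tuple[tuple[int, float, float], ...]  # (center, amplitude A, sigma)
    baseline_slope: float  # amperes per volt of excitation potential


@dataclass(frozen=True)
class ClassTemplate:
    """Per-channel waveform recipes for one rice variety."""

    channels: dict[str, ChannelWave]

    def __post_init__(self) -> None:
        expected = {"Pt": 5, "Ag": 3, "Au": 5, "Pd": 5}
        for ch, n in expected.items():
            if ch not in self.channels:
                raise ValueError(f"template missing channel {ch}")
            if len(self.channels[ch].bumps) != n:
                raise ValueError(f"channel {ch} must carry {n} designed landmarks")


def make_excitation(
    program: ExcitationProgram, n_points: int = DEFAULT_RECORD_LENGTH
) -> np.ndarray:
    """Sample the triangle-wave excitation potential.

    Emits ``n_points`` samples (default 3986, the reference acquisition
    length).  The cycle repeats periodically if ``n_points`` exceeds one
    cycle, matching an instrument that sweeps until stopped; at the reference
    settings one cycle spans 4000 samples so the emitted record is a
    truncated single cycle.
    """
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    rate = program.scan_rate
    d1 = abs(program.high_potential - program.initial_potential) / rate
    d2 = abs(program.high_potential - program.low_potential) / rate
    d3 = abs(program.final_potential - program.low_potential) / rate
    period = d1 + d2 + d3
    if period <= 0:
        raise ValueError("degenerate excitation program: zero sweep span")
    t = np.arange(n_points) / program.sampling_rate
    tau = np.mod(t, period)
    E = np.empty(n_points)
    up = tau < d1
    down = (~up) & (tau < d1 + d2)
    back = ~(up | down)
    E[up] = program.initial_potential + rate * tau[up]
    E[down] = program.high_potential - rate * (tau[down] - d1)
    E[back] = program.low_potential + rate * (tau[back] - d1 - d2)
    return E


def default_templates(
    separation: float, base_amplitude: float
) -> dict[int, ClassTemplate]:
    """Build the four variety templates from the shipped bump geometry."""
    templates = {}
    for code in (1, 2, 3, 4):
        channels = {}
        for ch in CHANNELS:
            bumps = tuple(
                (c, base_amplitude * a * (1.0 + separation * d), s)
                for (c, a, s), d in zip(BASE_BUMPS[ch], _CLASS_DELTAS[code][ch])
            )
            # small capacitive line following the potential trace
            channels[ch] = ChannelWave(bumps=bumps, baseline_slope=0.05 * base_amplitude)
        templates[code] = ClassTemplate(channels=channels)
    return templates


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study design.

    Defaults reproduce the reference design: 4 varieties x 4 samples x 5
    replicates = 80 records of 4 x 3986 points, at dilutions 0/5/10/100.
    Current magnitudes are of order tens of microamperes; they are pattern
    scales, not claims about real rice solutions.
    """

    between_class_separation: float = 0.35
    base_amplitude: float = 2.0e-5  # amperes; dominant bump height
    noise_sd: float = 8.0e-7  # amperes, i.i.d. per sample point
    drift_ratio: float = 1.0  # baseline-drift sd as a multiple of noise_sd
    sample_offset_sd: float = 4.0e-7  # amperes, constant per sample & channel
    dilution_attenuation: dict[int, float] = field(
        default_factory=lambda: {0: 1.0, 5: 0.22, 10: 0.07, 100: 0.04}
    )
    amplitude_gain: float = 1.0  # global multiplier (crushed pretreatment > 1)
    seed: int = 1234
    replicates: int = 5
    samples_per_class: int = 4
    n_points: int = DEFAULT_RECORD_LENGTH
    excitation: ExcitationProgram = field(default_factory=ExcitationProgram)
    class_templates: dict[int, ClassTemplate] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.sample_offset_sd < 0 or self.drift_ratio < 0:
            raise ValueError("noise scales must be non-negative")
        if self.amplitude_gain <= 0:
            raise ValueError("amplitude_gain must be positive")
        dils = sorted(self.dilution_attenuation)
        factors = [self.dilution_attenuation[d] for d in dils]
        if any(not (0 < fct <= 1) for fct in factors):
            raise ValueError("attenuation factors must lie in (0, 1]")
        if any(a < b for a, b in zip(factors, factors[1:])):
            raise ValueError("attenuation must be non-increasing in dilution")
        if self.class_templates is None:
            self.class_templates = default_templates(
                self.between_class_separation, self.base_amplitude
            )


def render_template(
    template: ClassTemplate, potential: np.ndarray
) -> dict[str, np.ndarray]:
    """Render a noise-free class template onto a sampled potential trace."""
    n = potential.size
    idx = np.arange(n)
    waves = {}
    for ch in CHANNELS:
        cw = template.channels[ch]
        w = cw.baseline_slope * potential.copy()
        for center, amp, sigma in cw.bumps:
            if not (0 < center < n - 1):
                raise ValueError(f"landmark at {center} outside record of length {n}")
            w = w + amp * np.exp(-0.5 * ((idx - center) / sigma) ** 2)
        waves[ch] = w
    return waves


def class_waveforms(
    config: GeneratorConfig, dilution: int
) -> dict[int, dict[str, np.ndarray]]:
    """Noise-free per-class waveforms after dilution attenuation and gain.

    Dilution shrinks each class waveform toward the grand mean:
    ``w_c -> mean + a(dilution) * (w_c - mean)``, leaving the common signal
    shape intact while class contrasts fade.
    """
    if dilution not in config.dilution_attenuation:
        raise KeyError(
            f"unknown dilution {dilution}; configured: "
            f"{sorted(config.dilution_attenuation)}"
        )
    atten = config.dilution_attenuation[dilution]
    potential = make_excitation(config.excitation, config.n_points)
    rendered = {
        code: render_template(tpl, potential)
        for code, tpl in config.class_templates.items()
    }
    grand = {
        ch: np.mean([rendered[c][ch] for c in rendered], axis=0) for ch in CHANNELS
    }
    out = {}
    for code, waves in rendered.items():
        out[code] = {
            ch: config.amplitude_gain * (grand[ch] + atten * (waves[ch] - grand[ch]))
            for ch in CHANNELS
        }
    return out


def generate_dataset(config: GeneratorConfig, dilution: int) -> LabeledDataset:
    """Generate the full labelled design at one dilution level.

    Record order: class codes 1..4, within each class the commercial samples,
    within each sample the replicates.  The seed (together with the dilution)
    fully determines the output.
    """
    waves = class_waveforms(config, dilution)
    # sample-to-sample chemistry dilutes along with the class contrast;
    # replicate noise is instrumental and does not
    offset_sd = config.sample_offset_sd * config.dilution_attenuation[dilution]
    rng = np.random.default_rng([config.seed, dilution])
    records = []
    for code in sorted(waves):
        for s in range(config.samples_per_class):
            sample_id = (code - 1) * config.samples_per_class + s + 1
            offsets = {ch: rng.normal(0.0, offset_sd) for ch in CHANNELS}
            drift_sd = config.drift_ratio * config.noise_sd
            ramp = np.linspace(-0.5, 0.5, config.n_points)
            for rep in range(1, config.replicates + 1):
                currents = {}
                for ch in CHANNELS:
                    # slow electrode-polarization drift per replicate: a
                    # random level + slope, on top of white sampling noise
                    c0, c1 = rng.normal(0.0, drift_sd, 2)
                    currents[ch] = (
                        waves[code][ch]
                        + offsets[ch]
                        + c0
                        + c1 * ramp
                        + rng.normal(0.0, config.noise_sd, config.n_points)
                    )
                records.append(
                    SampleRecord(
                        voltammogram=Voltammogram(
                            currents=currents, excitation=config.excitation
                        ),
                        class_label=CODE_TO_LABEL[code],
                        dilution=dilution,
                        replicate=rep,
                        sample_id=sample_id,
                    )
                )
    return LabeledDataset(records=records)


def expected_separability(config: GeneratorConfig, dilution: int) -> float:
    """Signal-to-noise summary: mean between-class waveform distance / noise.

    Distances are Euclidean over the concatenated noise-free channel
    waveforms after attenuation and gain.  Diverges to ``inf`` as
    ``noise_sd`` tends to zero; strictly decreasing in dilution whenever the
    attenuation map is.
    """
    waves = class_waveforms(config, dilution)
    codes = sorted(waves)
    concat = {
        c: np.concatenate([waves[c][ch] for ch in CHANNELS]) for c in codes
    }
    dists = [
        np.linalg.norm(concat[a] - concat[b])
        for i, a in enumerate(codes)
        for b in codes[i + 1 :]
    ]
    mean_dist = float(np.mean(dists))
    if config.noise_sd == 0:
        return float("inf")
    return mean_dist / config.noise_sd


def designed_landmarks(
    config: GeneratorConfig, class_code: int, dilution: int = 0
) -> dict[str, list[tuple[int, float]]]:
    """Ground-truth landmark positions/values of a noise-free class waveform.

    For each designed bump, the true landmark is the local extremum of the
    rendered (attenuated, gained) waveform nearest the bump centre — the
    baseline tilts apexes by a few samples, so positions are located
    numerically rather than read off the bump centres.
    """
    waves = class_waveforms(config, dilution)[class_code]
    out = {}
    for ch in CHANNELS:
        w = waves[ch]
        marks = []
        for center, amp, sigma in config.class_templates[class_code].channels[ch].bumps:
            lo = max(0, center - int(2 * sigma))
            hi = min(w.size, center + int(2 * sigma))
            seg = w[lo:hi] if amp > 0 else -w[lo:hi]
            idx = lo + int(np.argmax(seg))
            marks.append((idx, float(w[idx])))
        out[ch] = sorted(marks)
    return out
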