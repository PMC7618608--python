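"""Synthetic element sequences with known rhythmic structure (or none).

The generator emulates the statistical shape of natural warble recordings —
bouts of heavily dispersed size separated by silences, heavy-tailed
(lognormal) inter-onset intervals, per-individual and per-class strata —
and can plant integer-ratio rhythmic patterns:

* *null* sequences draw every IOI i.i.d. within its stratum, which makes
  the order exchangeable by construction: the permutation test should
  reject at its nominal rate on this output;
* *patterned* sequences repeat a relative-IOI grammar (``[1]`` isochrony,
  ``[1, 2]`` a 1:2 alternation, ...) scaled by a per-bout base interval and
  multiplied by lognormal jitter of a given coefficient of variation.

The per-bout base interval is itself lognormal: rhythm under the stratified
permutation null is an *ordering* property, and it is the tempo
heterogeneity across bouts that makes a planted within-bout pattern
detectable (shuffling mixes IOIs of different tempi, spreading the permuted
ratio distribution while the observed one stays on the grammar's ratios).

A companion audio synthesizer places tone bursts at annotated intervals
over Gaussian background noise, providing ground-truth material for the
segmentation front-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError, ValidationError
from .sequence_model import AnnotationSet, ElementRecord

__all__ = [
    "RhythmPattern",
    "SyntheticSpec",
    "BUDGERIGAR_CLASS_WEIGHTS",
    "generate_null_dataset",
    "generate_patterned_dataset",
    "generate_synthetic_audio",
]

#: Average warble element-class frequencies (percent) across recorded birds,
#: used for realistic stratum sparsity in budgerigar-like simulations.
BUDGERIGAR_CLASS_WEIGHTS: dict[str, float] = {
    "alarm": 2.30,
    "click": 10.60,
    "complex_phrase": 40.40,
    "long_harmonic": 1.99,
    "noisy": 6.17,
    "short_harmonic": 27.6,
    "unknown": 11.0,
}


@dataclass(frozen=True)
class RhythmPattern:
    """A repeating relative-IOI grammar planted into bouts.

    ``relative_iois=(1,)`` is isochrony; ``(1, 2)`` alternates short-long
    (ratios 2/3 and 1/3 under zero jitter).  With ``mixture_weight`` w < 1,
    a fraction 1 - w of bouts are generated as null bouts instead.
    """

    relative_iois: tuple[float, ...] = (1.0,)
    mixture_weight: float = 1.0

    def __post_init__(self):
        if not self.relative_iois or min(self.relative_iois) <= 0:
            raise ConfigError("pattern relative IOIs must be positive")
        if not 0 < self.mixture_weight <= 1:
            raise ConfigError("mixture_weight must lie in (0, 1]")

    @classmethod
    def isochronous(cls, mixture_weight: float = 1.0) -> "RhythmPattern":
        return cls((1.0,), mixture_weight)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters of the synthetic generator.

    Defaults mirror the descriptive statistics of natural warble material:
    bout sizes with mean ~8.9 elements and a long tail (negative binomial,
    minimum 1), lognormal IOIs with a ~120 ms median, inter-bout silences of
    500 ms, and elements whose durations are clipped so that intra-bout gaps
    stay below the 250 ms bout-splitting threshold.
    """

    individuals: int = 1
    #: class label -> sampling weight (need not be normalized)
    classes: dict = field(
        default_factory=lambda: {"A": 1.0, "B": 1.0, "C": 1.0})
    bout_count: int = 200
    #: (mean, dispersion); dispersion None/0 -> every bout has round(mean)
    #: elements, otherwise 1 + NegBinom with the given shape parameter
    elements_per_bout: tuple[float, Optional[float]] = (8.9, 0.6)
    #: (family, params); families: lognormal {median, sigma},
    #: gamma {shape, mean}, uniform {low, high}
    ioi_distribution: tuple[str, dict] = (
        "lognormal", None)  # None -> {"median": 0.12, "sigma": 0.6}
    pattern: Optional[RhythmPattern] = None
    jitter_cv: float = 0.03
    #: per-bout base interval for patterned bouts
    base_interval: tuple[str, dict] = ("lognormal", None)
    element_duration: tuple[str, dict] = ("lognormal", None)
    #: intra-bout gaps are clipped below this (must stay under the bout
    #: silence threshold used downstream)
    intra_bout_max_gap: float = 0.2
    silence_between_bouts: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        if self.jitter_cv < 0:
            raise ConfigError("jitter_cv must be >= 0")
        if self.elements_per_bout[0] < 1:
            raise ConfigError("mean elements per bout must be >= 1")
        if self.individuals < 1 or self.bout_count < 1:
            raise ConfigError("need at least one individual and one bout")
        if self.intra_bout_max_gap <= 0 or \
                self.silence_between_bouts <= self.intra_bout_max_gap:
            raise ConfigError(
                "need 0 < intra_bout_max_gap < silence_between_bouts")


_DEFAULTS = {
    "ioi": {"median": 0.12, "sigma": 0.6},
    "base": {"median": 0.10, "sigma": 0.5},
    "duration": {"median": 0.06, "sigma": 0.5},
}


def _sampler(family: str, params: dict | None, fallback: dict):
    params = dict(fallback if params is None else params)
    if family == "lognormal":
        mu, sigma = math.log(params["median"]), params["sigma"]
        return lambda rng, size: rng.lognormal(mu, sigma, size)
    if family == "gamma":
        shape = params["shape"]
        scale = params["mean"] / shape
        return lambda rng, size: rng.gamma(shape, scale, size)
    if family == "uniform":
        low, high = params["low"], params["high"]
        if not 0 < low < high:
            raise ConfigError("uniform IOI family needs 0 < low < high")
        return lambda rng, size: rng.uniform(low, high, size)
    raise ConfigError(f"unknown distribution family {family!r}")


def _bout_sizes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    mean, dispersion = spec.elements_per_bout
    if not dispersion:
        return np.full(spec.bout_count, int(round(mean)), dtype=int)
    extra_mean = mean - 1.0
    r = float(dispersion)
    p = r / (r + extra_mean)
    return 1 + rng.negative_binomial(r, p, size=spec.bout_count)


def _jitter(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multiplicative jitter with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def _assemble(spec: SyntheticSpec, rng: np.random.Generator,
              patterned: bool) -> AnnotationSet:
    labels = list(spec.classes)
    weights = np.array([spec.classes[c] for c in labels], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ConfigError("class weights must be non-negative, not all zero")
    weights = weights / weights.sum()
    ioi_draw = _sampler(spec.ioi_distribution[0], spec.ioi_distribution[1],
                        _DEFAULTS["ioi"])
    base_draw = _sampler(spec.base_interval[0], spec.base_interval[1],
                         _DEFAULTS["base"])
    dur_draw = _sampler(spec.element_duration[0], spec.element_duration[1],
                        _DEFAULTS["duration"])

    records: list[ElementRecord] = []
    for ind_i in range(spec.individuals):
        individual = f"ind{ind_i:02d}"
        recording = f"sim-{individual}"
        sizes = _bout_sizes(spec, rng)
        t = 0.0
        for n in sizes:
            n = int(n)
            if patterned and rng.random() < spec.pattern.mixture_weight:
                grammar = np.array(spec.pattern.relative_iois, dtype=float)
                reps = int(np.ceil((n - 1) / grammar.size))
                rel = np.tile(grammar, max(reps, 1))[:max(n - 1, 0)]
                base = base_draw(rng, 1)[0]
                iois = base * rel * _jitter(rng, spec.jitter_cv,
                                            max(n - 1, 0))
            else:
                iois = ioi_draw(rng, max(n - 1, 0))
            classes = rng.choice(len(labels), size=n, p=weights)
            onsets = t + np.concatenate([[0.0], np.cumsum(iois)])
            durations = dur_draw(rng, n)
            for k in range(n):
                if k < n - 1:
                    ioi = iois[k]
                    gap = ioi - durations[k]
                    if gap <= 1e-4 * ioi:
                        durations[k] = 0.8 * ioi
                    elif gap > spec.intra_bout_max_gap:
                        durations[k] = ioi - spec.intra_bout_max_gap
                records.append(ElementRecord(
                    recording=recording, individual=individual,
                    onset=float(onsets[k]),
                    offset=float(onsets[k] + durations[k]),
                    element_class=labels[int(classes[k])]))
            t = records[-1].offset + spec.silence_between_bouts
    return AnnotationSet(records, provenance={"source": "synthetic",
                                              "seed": spec.rng_seed})


def generate_null_dataset(spec: SyntheticSpec) -> AnnotationSet:
    """Sequences whose IOI order is random by construction.

    Per bout, IOIs are drawn i.i.d. from the configured distribution, so the
    values are exchangeable within any stratum labeling — the exact setting
    of the permutation test's null hypothesis.
    """
    if spec.pattern is not None:
        raise ConfigError("generate_null_dataset requires pattern=None")
    rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed))
    return _assemble(spec, rng, patterned=False)


def generate_patterned_dataset(spec: SyntheticSpec) -> AnnotationSet:
    """Sequences with a planted relative-IOI grammar (see RhythmPattern)."""
    if spec.pattern is None:
        raise ConfigError("generate_patterned_dataset requires a pattern")
    rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed))
    return _assemble(spec, rng, patterned=True)


def generate_synthetic_audio(annotations: AnnotationSet, rate: float,
                             snr_db: float | None = 20.0,
                             tone_freq: float = 2500.0,
                             seed: int | np.random.Generator = 0,
                             pad: float = 0.1) -> np.ndarray:
    """Tone bursts at the annotated intervals over Gaussian noise.

    Bursts are unit-amplitude sinusoids with 1 ms cosine on/off ramps; the
    noise level realizes the requested burst-RMS-to-noise-RMS ratio in dB
    (``snr_db=None`` disables the noise).  The input annotations are the
    ground-truth element boundaries of the returned signal.
    """
    if len(annotations.recordings) > 1:
        raise ValidationError("audio synthesis expects a single recording")
    for a, b in zip(annotations, annotations.records[1:]):
        if b.onset < a.offset:
            raise ValidationError("overlapping element intervals")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    total = (annotations.records[-1].offset + pad) if len(annotations) \
        else pad
    n = int(round(total * rate))
    x = np.zeros(n)
    ramp = max(int(round(0.001 * rate)), 1)
    for rec in annotations:
        i0 = int(round(rec.onset * rate))
        m = int(round(rec.duration * rate))
        if m <= 0:
            continue
        tt = np.arange(m) / rate
        burst = np.sin(2 * np.pi * tone_freq * tt)
        edge = min(ramp, m // 2)
        if edge > 0:
            win = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
            burst[:edge] *= win
            burst[m - edge:] *= win[::-1]
        x[i0:i0 + m] += burst[:max(0, min(m, n - i0))]
    if snr_db is not None and np.isfinite(snr_db):
        burst_rms = 1.0 / math.sqrt(2.0)
        sigma = burst_rms / (10.0 ** (snr_db / 20.0))
        x = x + rng.normal(0.0, sigma, n)
    return x
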