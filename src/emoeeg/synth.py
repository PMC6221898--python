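"""Synthetic EEG cohort generator.

Emulates a film-viewing affect study: each subject watches four emotion-
eliciting clips (amusement, tenderness, anger, fear), each preceded by an
eyes-open resting baseline, while multichannel EEG is recorded; after each
clip the subject fills in 9-point SAM ratings (arousal, valence, liking,
familiarity, dominance) and a four-word differential-emotions scale.

Signals are built per frequency band by inverse-FFT spectrum shaping:
flat magnitude inside the band, independent uniform random phases, scaled
to a target band variance.  A sinusoid-equivalent parameterization is
used throughout: a band with "amplitude" a carries variance a²/2.  Group-
level emotion effects are planted as multiplicative amplitude factors on
named channel groups (right-frontal sites, midline sites), so the planted
ground truth of every downstream feature is known in closed form.

Between-subject heterogeneity is a multiplicative log-normal factor:
absolute EEG power is strictly positive and right-skewed, so a log-scale
spread is the natural stand-in.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .layout import DEFAULT_LAYOUT, MIDLINE_SITES, ChannelLayout

#: Analysis bands, Hz, half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

CONDITIONS = ("amusement", "tenderness", "anger", "fear")

SAM_DIMENSIONS = ("arousal", "valence", "liking", "familiarity", "dominance")

#: Per-condition (mean, sd) of each 9-point rating dimension.  ``target``
#: is the differential-emotions score of the clip's own emotion; scores
#: for the three non-target emotions default to a low floor.
RATING_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "amusement": {
        "arousal": (5.94, 2.12), "valence": (5.91, 2.37), "liking": (5.14, 2.47),
        "familiarity": (2.24, 2.27), "dominance": (5.78, 2.23), "target": (6.84, 2.09),
    },
    "tenderness": {
        "arousal": (5.39, 1.52), "valence": (5.30, 1.74), "liking": (5.38, 1.99),
        "familiarity": (2.73, 2.42), "dominance": (6.51, 1.97), "target": (7.22, 1.64),
    },
    "anger": {
        "arousal": (7.46, 1.50), "valence": (1.09, 0.29), "liking": (1.49, 1.12),
        "familiarity": (2.95, 2.77), "dominance": (4.03, 2.40), "target": (7.70, 1.53),
    },
    "fear": {
        "arousal": (7.30, 1.81), "valence": (1.24, 0.44), "liking": (2.11, 1.70),
        "familiarity": (1.24, 0.76), "dominance": (3.68, 2.42), "target": (6.65, 2.36),
    },
}

NONTARGET_DES = (2.0, 1.0)

#: Channel groups addressable by effect multipliers.
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "right_frontal": ("FP2", "F4"),
    "midline": MIDLINE_SITES,
}

#: Directions of the planted group effects: tenderness exceeds amusement
#: in right-frontal theta/alpha and midline alpha/beta; fear exceeds
#: anger in right-frontal and midline theta.  The magnitude (1.3) is a
#: free generator parameter, not an empirical claim.
DEFAULT_EFFECTS: dict[tuple[str, str, str], float] = {
    ("tenderness", "right_frontal", "theta"): 1.3,
    ("tenderness", "right_frontal", "alpha"): 1.3,
    ("tenderness", "midline", "alpha"): 1.3,
    ("tenderness", "midline", "beta"): 1.3,
    ("fear", "right_frontal", "theta"): 1.3,
    ("fear", "midline", "theta"): 1.3,
}

#: Film segment lengths, seconds, matching the four clips' run times.
DEFAULT_FILM_DURATIONS: dict[str, float] = {
    "amusement": 67.0, "tenderness": 99.0, "anger": 73.0, "fear": 92.0,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study-level configuration of the synthetic cohort."""

    n_subjects: int = 33
    fs: float = 500.0
    film_duration_s: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FILM_DURATIONS))
    baseline_duration_s: float = 40.0
    bands: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    base_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"theta": 5.0, "alpha": 7.0, "beta": 3.0})
    effect_multipliers: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    channel_groups: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS))
    subject_sd: float = 0.2
    noise_floor: float = 1.0
    rating_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {c: dict(v) for c, v in RATING_DEFAULTS.items()})
    force_hit: bool = True
    band_guard_hz: float = 1.0
    conditions: tuple[str, ...] = CONDITIONS
    layout: ChannelLayout = DEFAULT_LAYOUT
    baseline_per_film: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.layout.names:
            raise ValueError("layout must not be empty")
        top = max(hi for _, hi in self.bands.values())
        if self.fs <= 2 * top:
            raise ValueError(f"fs={self.fs} below Nyquist of top band edge {top} Hz")
        edges = sorted(self.bands.values())
        for (lo, hi) in edges:
            if not (1.0 <= lo < hi <= 35.0):
                raise ValueError(f"band [{lo}, {hi}) must lie within [1, 35] Hz")
        for (_, hi1), (lo2, _) in zip(edges, edges[1:]):
            if lo2 < hi1:
                raise ValueError("bands must not overlap")
        for key, m in self.effect_multipliers.items():
            if m <= 0:
                raise ValueError(f"effect multiplier for {key} must be positive")
        durations = [self.baseline_duration_s] + [
            self.film_duration(c) for c in self.conditions]
        if min(durations) < 2.0:
            raise ValueError("segment durations must be >= 2 s (one analysis window)")

    def film_duration(self, condition: str) -> float:
        if isinstance(self.film_duration_s, Mapping):
            return float(self.film_duration_s[condition])
        return float(self.film_duration_s)

    def amplitude(self, electrode: str, band: str, condition: str,
                  segment_kind: str, subject_factor: float) -> float:
        """Planted band amplitude at one electrode (variance = amp²/2)."""
        amp = float(self.base_amplitude[band]) * subject_factor
        if segment_kind == "film":
            for (cond, group, b), mult in self.effect_multipliers.items():
                if cond == condition and b == band and \
                        electrode in self.channel_groups.get(group, ()):
                    amp *= mult
        return amp


@dataclass
class RawRecording:
    """One subject × segment multichannel time series, µV."""

    subject_id: str
    segment_kind: str          # "baseline_eyes_open" | "film"
    condition: str             # emotion label, or "none"
    samples: np.ndarray        # (n_channels, n_samples)
    fs: float
    layout: ChannelLayout

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != self.layout.n_channels:
            raise ValueError("samples must be (n_channels, n_samples) matching layout")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.layout.index(name)]


def band_limited_noise(n_channels: int, n_samples: int, fs: float,
                       lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian-like noise via spectrum shaping.

    Flat magnitude on rFFT bins with lo <= f < hi, i.i.d. uniform phases
    per channel; each channel rescaled to sample variance exactly 1.
    Returns zeros if the band contains no resolvable bin.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    # DC and (for even n) Nyquist bins must stay real; exclude them.
    mask[0] = False
    if n_samples % 2 == 0:
        mask[-1] = False
    n_bins = int(mask.sum())
    if n_bins == 0:
        return np.zeros((n_channels, n_samples))
    spectrum = np.zeros((n_channels, freqs.size), dtype=complex)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, n_bins))
    spectrum[:, mask] = np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n_samples, axis=1)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def synthesize_recording(config: SynthConfig, subject_id: str, subject_factor: float,
                         condition: str, segment_kind: str, duration_s: float,
                         rng: np.random.Generator) -> RawRecording:
    """Render one segment: per-band shaped noise plus a broadband floor.

    Each channel is the sum over bands of a band-limited component scaled
    to the planted band variance amp²/2, plus white noise of standard
    deviation ``noise_floor``.  The planted variances are exact sample
    variances, not just expectations.
    """
    if duration_s < 2.0:
        raise ValueError("duration must be >= 2 s")
    top = max(hi for _, hi in config.bands.values())
    if config.fs <= 2 * top:
        raise ValueError("sampling rate below Nyquist of top band")
    layout = config.layout
    n_samples = int(round(duration_s * config.fs))
    x = np.zeros((layout.n_channels, n_samples))
    for band, (lo, hi) in config.bands.items():
        amps = np.array([
            config.amplitude(e, band, condition, segment_kind, subject_factor)
            for e in layout.names
        ])
        if not np.any(amps):
            continue
        # Keep planted energy one analysis-resolution width clear of the
        # band edges: a 2-s Hann taper smears ±1 Hz, so edge energy would
        # otherwise bleed into neighboring bands and break the planted-
        # variance calibration.
        guard = min(config.band_guard_hz, (hi - lo) / 4.0)
        component = band_limited_noise(layout.n_channels, n_samples, config.fs,
                                       lo + guard, hi - guard, rng)
        x += component * (amps / np.sqrt(2.0))[:, None]
    if config.noise_floor > 0:
        x += config.noise_floor * rng.standard_normal(x.shape)
    return RawRecording(subject_id=subject_id, segment_kind=segment_kind,
                        condition=condition, samples=x, fs=config.fs, layout=layout)


def generate_ratings(config: SynthConfig, condition: str,
                     rng: np.random.Generator) -> dict[str, int]:
    """Draw one subject's 9-point ratings for one film.

    Each dimension is a rounded, clipped Gaussian.  With hit forcing
    enabled (the default) the target differential-emotions score is held
    at least one point above every non-target score, mirroring films
    validated at a 100% hit rate.
    """
    params = config.rating_params[condition]

    def draw(mean: float, sd: float) -> int:
        return int(np.clip(np.round(rng.normal(mean, sd)), 1, 9))

    record = {dim: draw(*params[dim]) for dim in SAM_DIMENSIONS}
    target = draw(*params["target"])
    des = {f"des_{emo}": draw(*NONTARGET_DES) for emo in CONDITIONS if emo != condition}
    if config.force_hit:
        target = max(target, 2)
        des = {k: min(v, target - 1) for k, v in des.items()}
    des[f"des_{condition}"] = target
    record.update({k: des[k] for k in (f"des_{e}" for e in CONDITIONS)})
    return record


def generate_subject(config: SynthConfig, subject_index: int,
                     seed_seq: np.random.SeedSequence
                     ) -> tuple[list[RawRecording], list[dict]]:
    """All segments and rating rows for one subject (streaming unit)."""
    rng = np.random.default_rng(seed_seq)
    subject_id = f"S{subject_index + 1:02d}"
    factor = float(np.exp(rng.normal(0.0, config.subject_sd)))
    recordings: list[RawRecording] = []
    if not config.baseline_per_film:
        recordings.append(synthesize_recording(
            config, subject_id, factor, "none", "baseline_eyes_open",
            config.baseline_duration_s, rng))
    rating_rows = []
    for condition in config.conditions:
        if config.baseline_per_film:
            recordings.append(synthesize_recording(
                config, subject_id, factor, condition, "baseline_eyes_open",
                config.baseline_duration_s, rng))
        recordings.append(synthesize_recording(
            config, subject_id, factor, condition, "film",
            config.film_duration(condition), rng))
        row = {"subject": subject_id, "condition": condition}
        row.update(generate_ratings(config, condition, rng))
        rating_rows.append(row)
    return recordings, rating_rows


def generate_cohort(config: SynthConfig) -> tuple[list[RawRecording], pd.DataFrame]:
    """Generate the full cohort: recordings plus a ratings table.

    Deterministic given ``config.seed``: per-subject RNG streams are
    spawned from a single seed sequence, so cohorts are bit-identical
    across runs and subjects are independent.
    """
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    recordings: list[RawRecording] = []
    rating_rows: list[dict] = []
    for i, seq in enumerate(seqs):
        recs, rows = generate_subject(config, i, seq)
        recordings.extend(recs)
        rating_rows.extend(rows)
    ratings = pd.DataFrame(rating_rows)
    return recordings, ratings


# ---------------------------------------------------------------------------
# On-disk interchange: JSON manifest + per-segment float32 arrays + CSV.

def save_cohort(recordings: list[RawRecording], ratings: pd.DataFrame,
                outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    segments = []
    for rec in recordings:
        tag = f"{rec.subject_id}_{rec.segment_kind}_{rec.condition}"
        fname = f"{tag}.npy"
        data = rec.samples.astype(np.float32)
        np.save(outdir / fname, data)
        segments.append({
            "subject_id": rec.subject_id,
            "segment_kind": rec.segment_kind,
            "condition": rec.condition,
            "fs": rec.fs,
            "file": fname,
            "shape": list(data.shape),
            "sha256": hashlib.sha256(data.tobytes()).hexdigest(),
        })
    layout = recordings[0].layout
    manifest = {
        "format": "emoeeg-cohort-v1",
        "layout": {
            "names": list(layout.names),
            "scalp": sorted(layout.scalp),
            "midline": sorted(layout.midline),
            "pairs": [list(p) for p in layout.pairs],
            "reference": sorted(layout.reference),
            "eog": sorted(layout.eog),
        },
        "segments": segments,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    ratings.to_csv(outdir / "ratings.csv", index=False)
    return outdir


def load_cohort(indir: str | Path) -> tuple[list[RawRecording], pd.DataFrame]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    lay = manifest["layout"]
    layout = ChannelLayout(
        names=tuple(lay["names"]),
        scalp=frozenset(lay["scalp"]),
        midline=frozenset(lay["midline"]),
        pairs=tuple(tuple(p) for p in lay["pairs"]),
        reference=frozenset(lay.get("reference", [])),
        eog=frozenset(lay.get("eog", [])),
    )
    recordings = []
    for seg in manifest["segments"]:
        samples = np.load(indir / seg["file"]).astype(float)
        recordings.append(RawRecording(
            subject_id=seg["subject_id"], segment_kind=seg["segment_kind"],
            condition=seg["condition"], samples=samples, fs=seg["fs"],
            layout=layout))
    ratings = pd.read_csv(indir / "ratings.csv")
    return recordings, ratings
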