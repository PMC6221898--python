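"""Preprocessing and baseline-normalized band-power estimation.

The chain: zero-phase 1–35 Hz band-pass → optional mastoid re-reference →
segmentation into 2-s Hann windows with 50% overlap → amplitude-threshold
artifact rejection → per-epoch Hann periodograms averaged over epochs →
integrated band power per electrode → division by the across-electrode
mean baseline power of the same subject and band.

Normalization: for subject/condition C, electrode e and band f,

    norm(e, f) = P_C(e, f) / [ (1/N) Σ_{e'∈scalp} P_B(e', f) ]

where P_B is the power of the eyes-open baseline preceding the film and
N is the scalp-set size.  The denominator is a per-subject, per-band
scalar, so the spatial topography of the condition is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.signal

from .layout import ChannelLayout
from .synth import BANDS, RawRecording

BAND_COLUMNS = ["subject", "condition", "electrode", "band", "absolute", "normalized"]


@dataclass
class EpochSet:
    """Windowed view of one recording after segmentation/rejection."""

    subject_id: str
    condition: str
    segment_kind: str
    epochs: np.ndarray            # (n_epochs, n_channels, n_samples)
    fs: float
    layout: ChannelLayout
    kept_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if not 0.0 <= self.kept_fraction <= 1.0:
            raise ValueError("kept_fraction must lie in [0, 1]")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class BandPowerTable:
    """Per subject × condition × electrode × band power table.

    ``data`` is long-format with columns subject, condition, electrode,
    band, absolute (µV²) and normalized (dimensionless).  ``baseline``
    holds the per-subject baseline powers that fed the normalization;
    ``n_norm`` is N, the number of scalp electrodes in the baseline
    average.
    """

    data: pd.DataFrame
    baseline: pd.DataFrame
    n_norm: int

    def __post_init__(self) -> None:
        missing = set(BAND_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"band-power table missing columns {sorted(missing)}")
        if (self.data["absolute"] < 0).any() or (self.data["normalized"] < 0).any():
            raise ValueError("band powers must be non-negative")

    def pivot(self, value: str = "normalized") -> pd.DataFrame:
        """Wide view: rows (subject, condition), columns (band, electrode)."""
        return self.data.pivot_table(index=["subject", "condition"],
                                     columns=["band", "electrode"],
                                     values=value, sort=False)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, baseline_path=None, n_norm: int = 0) -> "BandPowerTable":
        data = pd.read_csv(path)
        baseline = (pd.read_csv(baseline_path) if baseline_path is not None
                    else pd.DataFrame(columns=["subject", "condition", "electrode",
                                               "band", "power"]))
        return cls(data=data, baseline=baseline, n_norm=n_norm)


def bandpass_filter(rec: RawRecording, lo: float = 1.0, hi: float = 35.0,
                    order: int = 5) -> RawRecording:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    nyq = rec.fs / 2.0
    if not 0.0 < lo < hi < nyq:
        raise ValueError(f"invalid band [{lo}, {hi}] for fs={rec.fs}")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs,
                              output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def rereference(rec: RawRecording, reference_labels: Iterable[str] | None = None
                ) -> RawRecording:
    """Subtract the mean of the reference channels from every channel.

    Synthetic cohorts usually carry no mastoid channels; in that case the
    recording passes through unchanged with a warning.
    """
    labels = tuple(reference_labels if reference_labels is not None
                   else rec.layout.reference)
    present = [l for l in labels if l in rec.layout.names]
    if not present:
        warnings.warn("no reference channels present; re-referencing skipped",
                      stacklevel=2)
        return rec
    ref = rec.samples[rec.layout.indices(present)].mean(axis=0)
    return replace(rec, samples=rec.samples - ref)


def segment_epochs(rec: RawRecording, epoch_len_s: float = 2.0,
                   overlap_frac: float = 0.5) -> EpochSet:
    """Slice a recording into fixed windows; a trailing partial window is dropped."""
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap fraction must lie in [0, 1)")
    win = int(round(epoch_len_s * rec.fs))
    n = rec.samples.shape[1]
    if win > n:
        raise ValueError(f"epoch length {epoch_len_s}s exceeds record "
                         f"duration {n / rec.fs:.1f}s")
    hop = int(round(win * (1.0 - overlap_frac)))
    if hop < 1:
        raise ValueError("overlap too large: hop would be < 1 sample")
    starts = range(0, n - win + 1, hop)
    epochs = np.stack([rec.samples[:, s:s + win] for s in starts])
    return EpochSet(subject_id=rec.subject_id, condition=rec.condition,
                    segment_kind=rec.segment_kind, epochs=epochs, fs=rec.fs,
                    layout=rec.layout, kept_fraction=1.0)


def reject_artifacts(es: EpochSet, amp_threshold_uv: float = 100.0) -> EpochSet:
    """Drop every epoch containing any sample exceeding ±threshold µV."""
    if amp_threshold_uv <= 0:
        raise ValueError("amplitude threshold must be positive")
    keep = np.abs(es.epochs).max(axis=(1, 2)) <= amp_threshold_uv
    if not keep.any():
        raise ValueError(
            f"all epochs rejected for subject {es.subject_id}, "
            f"condition {es.condition} at threshold {amp_threshold_uv} µV")
    kept = es.kept_fraction * keep.mean()
    return replace(es, epochs=es.epochs[keep], kept_fraction=float(kept))


def band_power(es: EpochSet, bands: Mapping[str, tuple[float, float]] = BANDS
               ) -> pd.DataFrame:
    """Absolute band power per electrode (µV²), averaged across epochs.

    Each epoch gets a Hann-tapered periodogram (window-power compensated,
    density scaling); the PSD is averaged over epochs and integrated over
    each half-open band [lo, hi).  Integrated power satisfies Parseval:
    a pure in-band sinusoid of amplitude a yields ≈ a²/2.
    """
    if es.n_epochs < 1:
        raise ValueError("need at least one epoch")
    freqs, psd = scipy.signal.periodogram(es.epochs, fs=es.fs, window="hann",
                                          scaling="density", axis=2)
    mean_psd = psd.mean(axis=0)              # (n_channels, n_freqs)
    resolution = freqs[1] - freqs[0]
    out = {}
    for band, (lo, hi) in bands.items():
        if hi > es.fs / 2:
            raise ValueError(f"band [{lo}, {hi}) not resolvable at fs={es.fs}")
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            raise ValueError(f"band [{lo}, {hi}) narrower than the spectral "
                             f"resolution {resolution:.3f} Hz")
        out[band] = mean_psd[:, mask].mean(axis=1) * (hi - lo)
    return pd.DataFrame(out, index=list(es.layout.names))


def baseline_normalize(powers: pd.DataFrame, baseline_powers: pd.DataFrame,
                       scalp_set: Iterable[str]) -> pd.DataFrame:
    """Divide condition powers by the scalp-average baseline power per band."""
    scalp = list(scalp_set)
    if not scalp:
        raise ValueError("scalp set must be non-empty")
    denom = baseline_powers.loc[scalp].mean(axis=0)
    if (denom <= 0).any():
        bad = denom[denom <= 0].index.tolist()
        raise ValueError(f"non-positive baseline average for band(s) {bad}")
    return powers / denom


def preprocess_recording(rec: RawRecording, *, filter_band=(1.0, 35.0),
                         epoch_len_s: float = 2.0, overlap_frac: float = 0.5,
                         amp_threshold_uv: float = 100.0,
                         apply_filter: bool = True,
                         reference_labels: Iterable[str] | None = None
                         ) -> EpochSet:
    """Full per-segment chain: filter → re-reference → segment → reject."""
    if apply_filter:
        rec = bandpass_filter(rec, *filter_band)
    if reference_labels is not None or rec.layout.reference:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = rereference(rec, reference_labels)
    es = segment_epochs(rec, epoch_len_s, overlap_frac)
    return reject_artifacts(es, amp_threshold_uv)


def process_cohort(recordings: Iterable[RawRecording], *,
                   bands: Mapping[str, tuple[float, float]] = BANDS,
                   filter_band=(1.0, 35.0), epoch_len_s: float = 2.0,
                   overlap_frac: float = 0.5, amp_threshold_uv: float = 100.0,
                   apply_filter: bool = True) -> BandPowerTable:
    """Estimate the baseline-normalized band-power table for a cohort.

    Film segments are normalized against the eyes-open baseline recorded
    for the same subject and condition; with a shared baseline
    (condition "none") that one baseline serves all four films.
    """
    abs_rows: list[dict] = []
    base_rows: list[dict] = []
    baselines: dict[tuple[str, str], pd.DataFrame] = {}
    films: list[tuple[str, str, pd.DataFrame, ChannelLayout]] = []
    layout = None
    for rec in recordings:
        layout = rec.layout
        es = preprocess_recording(rec, filter_band=filter_band,
                                  epoch_len_s=epoch_len_s,
                                  overlap_frac=overlap_frac,
                                  amp_threshold_uv=amp_threshold_uv,
                                  apply_filter=apply_filter)
        powers = band_power(es, bands)
        if rec.segment_kind == "film":
            films.append((rec.subject_id, rec.condition, powers, layout))
        else:
            baselines[(rec.subject_id, rec.condition)] = powers
            for e in powers.index:
                for b in powers.columns:
                    base_rows.append({"subject": rec.subject_id,
                                      "condition": rec.condition,
                                      "electrode": e, "band": b,
                                      "power": powers.loc[e, b]})
    if layout is None:
        raise ValueError("no recordings supplied")
    for subject, condition, powers, lay in films:
        base = baselines.get((subject, condition), baselines.get((subject, "none")))
        if base is None:
            raise ValueError(f"no baseline available for subject {subject}, "
                             f"condition {condition}")
        norm = baseline_normalize(powers, base, lay.scalp)
        for e in powers.index:
            for b in powers.columns:
                abs_rows.append({"subject": subject, "condition": condition,
                                 "electrode": e, "band": b,
                                 "absolute": powers.loc[e, b],
                                 "normalized": norm.loc[e, b]})
    data = pd.DataFrame(abs_rows, columns=BAND_COLUMNS)
    baseline = pd.DataFrame(
        base_rows, columns=["subject", "condition", "electrode", "band", "power"])
    return BandPowerTable(data=data, baseline=baseline, n_norm=len(layout.scalp))
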