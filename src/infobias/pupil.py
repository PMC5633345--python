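"""Pupillometry preprocessing: raw 500 Hz traces to binned difference series.

The chain is order-exact: linear blink interpolation -> zero-phase low-pass
Butterworth (3.75 Hz cut-off, order 3) -> session-wide z-transform ->
outcome-locked epoching (1 s baseline, 6 s post-outcome) with per-epoch
baseline correction -> trial exclusions (>50% interpolated outcome window;
first 10 trials per block) -> obtained-minus-unobtained difference timeseries
per block and valence -> 1 s bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "CleanTrace",
    "PupilEpochs",
    "BinnedDifference",
    "interpolate_blinks",
    "lowpass_filter",
    "z_transform",
    "clean_trace",
    "extract_epochs",
    "apply_exclusions",
    "difference_timeseries",
    "exclude_participant",
    "preprocess_session",
]

DEFAULT_FS = 500.0
DEFAULT_CUTOFF = 3.75
FILTER_ORDER = 3
BASELINE_S = 1.0
POST_S = 6.0
INTERP_THRESHOLD = 0.5
FIRST_TRIALS_EXCLUDED = 10
PARTICIPANT_EXCLUSION_FRACTION = 0.99
N_BINS = 6


@dataclass
class CleanTrace:
    """Interpolated, filtered, z-transformed session trace."""

    signal: np.ndarray
    interpolated: np.ndarray  # bool per sample
    fs: float = DEFAULT_FS

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.signal.size) / self.fs


@dataclass
class PupilEpochs:
    """Baseline-corrected outcome-locked epochs, two per trial (win/loss).

    ``data`` holds one 6 s post-outcome vector per epoch; ``meta`` aligns
    row-wise with columns ``block, trial, valence, obtained,
    fraction_interpolated, included, reason``.
    """

    data: np.ndarray  # (n_epochs, n_post_samples)
    meta: pd.DataFrame
    fs: float = DEFAULT_FS

    @property
    def n_epochs(self) -> int:
        return len(self.meta)

    def excluded_fraction(self) -> float:
        return float(1.0 - self.meta["included"].mean())


@dataclass
class BinnedDifference:
    """Per block x valence obtained-minus-unobtained response, 1 s bins."""

    bins: pd.DataFrame  # block, valence, bin (1..6), difference
    mean6s: pd.DataFrame  # block, valence, mean6s
    missing: list  # (block, valence) cells with an empty side


def interpolate_blinks(
    pupil: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate invalid runs; edges take the nearest valid value.

    Returns the gap-filled trace and a boolean flag per filled sample.
    """
    pupil = np.asarray(pupil, dtype=float)
    valid = np.asarray(valid).astype(bool)
    if valid.sum() < 2:
        raise ValueError("need at least two valid samples to interpolate")
    idx = np.arange(pupil.size)
    filled = pupil.copy()
    # np.interp holds the boundary values flat outside the valid range,
    # which implements nearest-valid fill for leading/trailing gaps.
    filled[~valid] = np.interp(idx[~valid], idx[valid], pupil[valid])
    return filled, ~valid


def lowpass_filter(
    trace: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    fs: float = DEFAULT_FS,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (applied forward-backward)."""
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, fs/2)")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    return filtfilt(b, a, np.asarray(trace, dtype=float))


def z_transform(trace: np.ndarray) -> np.ndarray:
    """Session-wide z-score with the population (n) standard deviation."""
    trace = np.asarray(trace, dtype=float)
    sd = trace.std(ddof=0)
    if sd == 0:
        raise ValueError("trace has zero variance; cannot z-transform")
    return (trace - trace.mean()) / sd


def clean_trace(
    pupil: np.ndarray, valid: np.ndarray, fs: float = DEFAULT_FS,
    cutoff: float = DEFAULT_CUTOFF,
) -> CleanTrace:
    """Interpolate, filter and z-transform a raw session trace."""
    filled, flags = interpolate_blinks(pupil, valid)
    filtered = lowpass_filter(filled, cutoff=cutoff, fs=fs)
    return CleanTrace(signal=z_transform(filtered), interpolated=flags, fs=fs)


def extract_epochs(
    clean: CleanTrace,
    markers: pd.DataFrame,
    baseline_s: float = BASELINE_S,
    post_s: float = POST_S,
) -> PupilEpochs:
    """Outcome-locked, baseline-corrected epochs for both valences.

    Each trial contributes one win and one loss epoch sharing the trial's
    outcome-onset sample; they differ in the obtained/not-obtained label.
    Each epoch covers ``post_s`` seconds after onset minus the mean of the
    ``baseline_s`` seconds before onset; the interpolated fraction is
    computed over the post-outcome window.  Epochs whose window leaves the
    trace are kept as NaN rows flagged excluded with reason ``edge``.
    """
    fs = clean.fs
    n_base = int(round(baseline_s * fs))
    n_post = int(round(post_s * fs))
    rows = []
    data = np.full((2 * len(markers), n_post), np.nan)
    for i, m in enumerate(markers.itertuples(index=False)):
        s = int(m.event_sample)
        ok = s - n_base >= 0 and s + n_post <= clean.signal.size
        if ok:
            baseline = clean.signal[s - n_base : s].mean()
            seg = clean.signal[s : s + n_post] - baseline
            frac = float(clean.interpolated[s : s + n_post].mean())
        else:
            seg = None
            frac = np.nan
        for j, (valence, obtained) in enumerate(
            (("win", m.win_obtained), ("loss", m.loss_obtained))
        ):
            row_idx = 2 * i + j
            if ok:
                data[row_idx] = seg
            rows.append(
                {
                    "block": m.block,
                    "trial": m.trial,
                    "valence": valence,
                    "obtained": bool(obtained),
                    "fraction_interpolated": frac,
                    "included": ok,
                    "reason": "" if ok else "edge",
                }
            )
    return PupilEpochs(data=data, meta=pd.DataFrame(rows), fs=fs)


def apply_exclusions(
    epochs: PupilEpochs,
    interp_threshold: float = INTERP_THRESHOLD,
    first_trials: int = FIRST_TRIALS_EXCLUDED,
) -> PupilEpochs:
    """Drop >50%-interpolated epochs and the first trials of each block.

    The interpolation rule is strict (exactly 50% interpolated is retained);
    the adaptation rule drops trials 1..``first_trials`` per block.  Reasons
    are recorded; already-excluded epochs keep their original reason.
    """
    meta = epochs.meta.copy()
    interp = meta["fraction_interpolated"] > interp_threshold
    adapt = meta["trial"] <= first_trials
    newly = meta["included"] & (interp | adapt)
    meta.loc[newly & interp, "reason"] = "interpolation"
    meta.loc[newly & adapt & ~interp, "reason"] = "adaptation"
    meta.loc[newly, "included"] = False
    return PupilEpochs(data=epochs.data, meta=meta, fs=epochs.fs)


def difference_timeseries(
    epochs: PupilEpochs, n_bins: int = N_BINS
) -> BinnedDifference:
    """Obtained-minus-unobtained mean response per block and valence.

    The full-resolution difference vector is averaged within ``n_bins``
    consecutive equal-length bins (1 s bins for the 6 s window); the overall
    window mean is returned alongside for between-subject correlations.
    Cells with no included epoch on either side are reported missing.
    """
    meta = epochs.meta
    bins_rows = []
    mean_rows = []
    missing = []
    n_samples = epochs.data.shape[1]
    edges = np.linspace(0, n_samples, n_bins + 1).astype(int)
    for (block, valence), grp in meta.groupby(["block", "valence"], sort=True):
        inc = grp[grp["included"]]
        got = inc[inc["obtained"]].index.to_numpy()
        not_got = inc[~inc["obtained"]].index.to_numpy()
        if got.size == 0 or not_got.size == 0:
            missing.append((block, valence))
            diff = np.full(n_samples, np.nan)
        else:
            diff = epochs.data[got].mean(axis=0) - epochs.data[not_got].mean(
                axis=0
            )
        binned = [
            diff[edges[k] : edges[k + 1]].mean() for k in range(n_bins)
        ]
        for k, v in enumerate(binned, start=1):
            bins_rows.append(
                {"block": block, "valence": valence, "bin": k, "difference": v}
            )
        mean_rows.append(
            {"block": block, "valence": valence, "mean6s": diff.mean()}
        )
    return BinnedDifference(
        bins=pd.DataFrame(bins_rows),
        mean6s=pd.DataFrame(mean_rows),
        missing=missing,
    )


def exclude_participant(
    epochs: PupilEpochs, threshold: float = PARTICIPANT_EXCLUSION_FRACTION
) -> bool:
    """True when the excluded-trial fraction exceeds the threshold (99%)."""
    return epochs.excluded_fraction() > threshold


def preprocess_session(
    trace: pd.DataFrame,
    markers: pd.DataFrame,
    fs: float = DEFAULT_FS,
    cutoff: float = DEFAULT_CUTOFF,
) -> dict:
    """Full chain for one session's trace + marker tables.

    Returns ``clean`` (CleanTrace), ``epochs`` (after exclusions), ``binned``
    (BinnedDifference) and the participant-level ``excluded`` decision.
    """
    clean = clean_trace(
        trace["pupil"].to_numpy(), trace["valid"].to_numpy(), fs=fs,
        cutoff=cutoff,
    )
    epochs = apply_exclusions(extract_epochs(clean, markers))
    return {
        "clean": clean,
        "epochs": epochs,
        "binned": difference_timeseries(epochs),
        "excluded": exclude_participant(epochs),
    }
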