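"""Signal chain: filtering, ICA-KL denoising, bipolar referencing, epoching.

Order of operations for a 2 kHz session: downsample to 500 Hz → 60 Hz FIR
notch → 1 Hz high-pass → ICA denoising (global across all contacts, then per
electrode) → 250 Hz low-pass → bipolar re-referencing → epoching with
pre-event baseline correction.

The ICA denoising criterion targets *distal* noise: a source that loads
near-uniformly over contacts (volume conduction, line/ground artifacts)
rather than focally. For each independent component, the distribution of
absolute mixing weights over the K channels is compared with the uniform
distribution via the Kullback-Leibler divergence D(w ‖ 1/K); components
below a divergence threshold (near-uniform loading) are removed. D is 0 for
an exactly uniform loading and ln K for a one-hot loading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import FastICA

DEFAULT_KL_GLOBAL = 0.2
DEFAULT_KL_PER_ELECTRODE = 0.05
EPOCH_TMIN = -0.2
EPOCH_TMAX = 0.5


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _fir_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR along the last axis with delay compensation."""
    n = data.shape[-1]
    pad = taps.size // 2
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = signal.fftconvolve(padded, taps[np.newaxis, :], mode="same", axes=-1)
    return out[..., pad : pad + n]


def downsample(data: np.ndarray, sfreq: float, target: float = 500.0) -> np.ndarray:
    factor = sfreq / target
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"sampling rate {sfreq} not an integer multiple of {target}")
    return signal.resample_poly(data.astype(float), up=1, down=int(round(factor)), axis=-1)


def notch_filter(
    data: np.ndarray, sfreq: float, freq: float = 60.0, width: float = 4.0, numtaps: int = 801
) -> np.ndarray:
    taps = signal.firwin(
        numtaps, [freq - width, freq + width], fs=sfreq, pass_zero="bandstop"
    )
    return _fir_zero_phase(data, taps)


def highpass(data: np.ndarray, sfreq: float, cutoff: float = 1.0, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, cutoff, btype="highpass", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def lowpass(data: np.ndarray, sfreq: float, cutoff: float = 250.0, order: int = 4) -> np.ndarray:
    if cutoff >= sfreq / 2:
        return data  # already band-limited by the sampling theorem
    sos = signal.butter(order, cutoff, btype="lowpass", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def apply_filters(
    raw: np.ndarray,
    sfreq: float = 2000.0,
    target_sfreq: float = 500.0,
    notch: float = 60.0,
    hp: float = 1.0,
    lp: float = 250.0,
) -> np.ndarray:
    """Full filter chain (without the ICA stage): 2 kHz in, 500 Hz out."""
    if sfreq != 2000.0:
        raise ValueError(f"expected 2000 Hz input, got {sfreq}")
    x = downsample(raw, sfreq, target_sfreq)
    x = notch_filter(x, target_sfreq, notch)
    x = highpass(x, target_sfreq, hp)
    return lowpass(x, target_sfreq, lp)


# ---------------------------------------------------------------------------
# ICA with the KL-uniformity criterion
# ---------------------------------------------------------------------------

def kl_uniformity(weights: np.ndarray) -> float:
    """D(w ‖ uniform) in nats for a vector of absolute channel weights."""
    w = np.abs(np.asarray(weights, dtype=float))
    if w.size < 2:
        raise ValueError("need weights over at least 2 channels")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero weight vector")
    w = w / total
    k = w.size
    nz = w > 0
    return float(np.sum(w[nz] * np.log(w[nz] * k)))


@dataclass
class IcaDecomposition:
    mixing: np.ndarray  # channels x components
    sources: np.ndarray  # components x samples
    weight_distributions: np.ndarray  # components x channels, rows sum to 1
    dkl_per_component: np.ndarray


@dataclass
class RemovalRecord:
    component: int
    dkl: float
    variance_explained: float


def fit_ica(
    data: np.ndarray, seed: int = 0, max_iter: int = 300, max_fit_samples: int = 40000
) -> IcaDecomposition:
    """Seeded linear ICA over channels; components = channel count (or rank).

    The unmixing matrix is estimated on an evenly strided temporal subsample
    (up to ``max_fit_samples``) and then applied to the full series; with
    hundreds of thousands of samples the spatial decomposition is already
    stable on the subsample.
    """
    n_ch, n_samp = data.shape
    n_comp = min(n_ch, int(np.linalg.matrix_rank(data @ data.T)))
    ica = FastICA(
        n_components=n_comp, random_state=seed, max_iter=max_iter, tol=1e-4,
        whiten="unit-variance",
    )
    stride = max(1, n_samp // max_fit_samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FastICA convergence chatter on noise data
        ica.fit(data[:, ::stride].T)
        sources = ica.transform(data.T).T
    mixing = ica.mixing_  # channels x components
    absw = np.abs(mixing.T)
    dist = absw / absw.sum(axis=1, keepdims=True)
    dkl = np.array([kl_uniformity(row) for row in dist])
    return IcaDecomposition(mixing, sources, dist, dkl)


def ica_kl_denoise(
    data: np.ndarray,
    stage: str = "GLOBAL",
    threshold: float | None = None,
    seed: int = 0,
    electrode_ids: list | None = None,
) -> tuple[np.ndarray, list[RemovalRecord]]:
    """Remove near-uniformly loading ICA components below the D_kl threshold.

    GLOBAL runs one decomposition over all channels; PER_ELECTRODE runs one
    per electrode group (requires ``electrode_ids``, one per channel).
    """
    if stage not in ("GLOBAL", "PER_ELECTRODE"):
        raise ValueError(f"unknown stage {stage!r}")
    if threshold is None:
        threshold = DEFAULT_KL_GLOBAL if stage == "GLOBAL" else DEFAULT_KL_PER_ELECTRODE
    if stage == "PER_ELECTRODE":
        if electrode_ids is None:
            raise ValueError("PER_ELECTRODE stage requires electrode_ids")
        electrode_ids = list(electrode_ids)
        cleaned = data.astype(float).copy()
        removed: list[RemovalRecord] = []
        for eid in dict.fromkeys(electrode_ids):
            idx = [i for i, e in enumerate(electrode_ids) if e == eid]
            if len(idx) < 2:
                continue
            sub, rec = ica_kl_denoise(data[idx], "GLOBAL", threshold, seed)
            cleaned[idx] = sub
            removed.extend(rec)
        return cleaned, removed

    dec = fit_ica(data, seed=seed)
    total_var = float(np.var(data))
    removed = []
    drop = []
    for k in range(dec.dkl_per_component.size):
        if dec.dkl_per_component[k] < threshold:
            comp = np.outer(dec.mixing[:, k], dec.sources[k])
            removed.append(
                RemovalRecord(
                    component=k,
                    dkl=float(dec.dkl_per_component[k]),
                    variance_explained=float(np.var(comp) / total_var) if total_var else 0.0,
                )
            )
            drop.append(k)
    if not drop:
        return data.astype(float).copy(), removed
    cleaned = data - dec.mixing[:, drop] @ dec.sources[drop]
    return cleaned, removed


# ---------------------------------------------------------------------------
# Bipolar referencing
# ---------------------------------------------------------------------------

def bipolar_rereference(
    data: np.ndarray, channels: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Difference adjacent same-electrode contacts; drop white-white pairs.

    ``channels`` rows describe ``data`` rows in order, with columns
    electrode_id, contact_index, roi_label, x, y, z, tissue.
    """
    out_rows = []
    out_sig = []
    for eid, grp in channels.groupby("electrode_id", sort=False):
        grp = grp.sort_values("contact_index")
        if len(grp) < 2:
            warnings.warn(f"electrode {eid} has a single contact; no bipolar pairs")
            continue
        idx = grp.index.to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            ca, cb = channels.loc[a], channels.loc[b]
            if ca["tissue"] == "WHITE" and cb["tissue"] == "WHITE":
                continue
            out_sig.append(data[channels.index.get_loc(a)] - data[channels.index.get_loc(b)])
            out_rows.append(
                {
                    "name": f"{eid}:{ca['contact_index']}-{cb['contact_index']}",
                    "electrode_id": eid,
                    "roi_label": ca["roi_label"],
                    "x": (ca["x"] + cb["x"]) / 2,
                    "y": (ca["y"] + cb["y"]) / 2,
                    "z": (ca["z"] + cb["z"]) / 2,
                }
            )
    if not out_sig:
        return np.empty((0, data.shape[1])), pd.DataFrame(out_rows)
    return np.vstack(out_sig), pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

@dataclass
class EpochTensor:
    """Epochs x channels x timepoints with a time axis relative to onset."""

    data: np.ndarray
    times: np.ndarray  # seconds, EPOCH_TMIN..EPOCH_TMAX at 2 ms steps
    event_types: np.ndarray  # per-epoch label
    trial_index: np.ndarray  # per-epoch trial number
    channels: pd.DataFrame

    @property
    def decoding_mask(self) -> np.ndarray:
        """Timepoints used for decoding: 0..0.5 s inclusive (251 points)."""
        return self.times >= -1e-12

    def decoding_times(self) -> np.ndarray:
        return self.times[self.decoding_mask]

    def select_event(self, event_type: str) -> "EpochTensor":
        m = self.event_types == event_type
        return EpochTensor(
            self.data[m], self.times, self.event_types[m], self.trial_index[m], self.channels
        )


def epoch(
    data: np.ndarray,
    sfreq: float,
    events: pd.DataFrame,
    channels: pd.DataFrame,
    downsample_factor: float = 4.0,
    tmin: float = EPOCH_TMIN,
    tmax: float = EPOCH_TMAX,
) -> EpochTensor:
    """Cut baseline-corrected epochs around each event onset.

    ``events.onset_sample`` is on the original (2 kHz) grid; ``data`` is at
    ``sfreq`` (500 Hz) after downsampling by ``downsample_factor``. Each
    epoch spans tmin..tmax inclusive; the mean over [tmin, 0) per channel is
    subtracted. Events too close to the recording edge are dropped with a
    warning.
    """
    step = 1.0 / sfreq
    n_pre = int(round(-tmin * sfreq))
    n_post = int(round(tmax * sfreq))
    times = np.arange(-n_pre, n_post + 1) * step
    epochs, labels, trials = [], [], []
    n_samples = data.shape[1]
    for _, row in events.iterrows():
        center = int(round(row["onset_sample"] / downsample_factor))
        lo, hi = center - n_pre, center + n_post + 1
        if lo < 0 or hi > n_samples:
            warnings.warn(
                f"event {row['event_type']} (trial {row['trial']}) too close to edge; dropped"
            )
            continue
        seg = data[:, lo:hi].astype(float)
        seg = seg - seg[:, :n_pre].mean(axis=1, keepdims=True)
        epochs.append(seg)
        labels.append(row["event_type"])
        trials.append(int(row["trial"]))
    return EpochTensor(
        data=np.stack(epochs) if epochs else np.empty((0, data.shape[0], times.size)),
        times=times,
        event_types=np.asarray(labels, dtype=object),
        trial_index=np.asarray(trials, dtype=int),
        channels=channels,
    )


def preprocess_session(
    recording,
    kl_global: float = DEFAULT_KL_GLOBAL,
    kl_electrode: float = DEFAULT_KL_PER_ELECTRODE,
    seed: int = 0,
    run_ica: bool = True,
) -> EpochTensor:
    """Full chain for one SessionRecording: filters → ICA → bipolar → epochs."""
    import dataclasses as _dc

    channels = pd.DataFrame([_dc.asdict(c) for c in recording.contacts])
    x = downsample(recording.raw, recording.sfreq)
    sfreq = 500.0
    x = notch_filter(x, sfreq)
    x = highpass(x, sfreq)
    if run_ica:
        x, _ = ica_kl_denoise(x, "GLOBAL", kl_global, seed=seed)
        x, _ = ica_kl_denoise(
            x, "PER_ELECTRODE", kl_electrode, seed=seed,
            electrode_ids=channels["electrode_id"].tolist(),
        )
    x = lowpass(x, sfreq)
    bip, bip_channels = bipolar_rereference(x, channels)
    return epoch(bip, sfreq, recording.events, bip_channels,
                 downsample_factor=recording.sfreq / sfreq)
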