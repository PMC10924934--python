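"""Synthetic iEEG-like cohorts with planted, ground-truth encodings.

Real recordings for this task are intracranial potentials from epilepsy
patients; this module emulates their statistical structure well enough to
exercise every downstream stage — filtering, ICA denoising, bipolar
referencing, epoching, residualization, pseudo-population decoding and
cluster inference — with a known answer key:

* behavior: i.i.d. trials of the card game with ~91.5% report accuracy and
  no win-stay/lose-shift or key stickiness (matching the task's design,
  where each trial is independent);
* contacts: depth-electrode layouts per subject with ROI labels, template
  y-coordinates and a gray/white tissue flag;
* raw signal at 2 kHz: per-contact AR(1) noise, a few shared near-uniformly
  loading noise components (the kind the KL-uniformity ICA criterion is
  built to flag), 60 Hz line noise, and event-locked encodings — a smooth
  raised-cosine bump at a chosen latency, scaled by the z-scored model
  variable and projected onto a differential spatial pattern across the
  ROI's contacts so bipolar referencing preserves it.

The encoding patterns are drawn once per (encoding, subject) and stored in
:class:`GroundTruth`, so parameter-recovery tests can compare recovered
clusters against the planted (ROI, variable, latency) triples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from . import task_model
from .task_model import Trial, TrialVariables, simulate_trials

EVENTS = ("GUESS", "CARD1_ON", "CARD1_OFF", "CARD2_ON", "REPORT")

# template anteroposterior coordinates (mm) used for ROI placement
ROI_Y = {
    "AngularGyrus": -56.0,
    "SupramarginalGyrus": -45.0,
    "Hippocampus": -17.0,
    "PosteriorInsula": -8.0,
    "Amygdala": -3.0,
    "Putamen": 0.0,
    "CingulateGyrus": -10.0,
    "AnteriorInsula": 10.0,
    "vmPFC": 15.0,
    "OFC": 23.0,
    "FrontalPole": 51.0,
}

# fixed event offsets (s) after the guess response, per the trial structure:
# guess shown 1.0 s, fixation 1.5 s, card1 2.0 s, ISI 1.5 s, card2 2.0 s
_CARD1_ON = 2.5
_CARD1_OFF = 4.5
_CARD2_ON = 6.0
_REPORT_PROMPT = 8.0


@dataclass(frozen=True)
class ContactSpec:
    subject_id: str
    electrode_id: str
    contact_index: int
    roi_label: str
    x: float
    y: float
    z: float
    tissue: str  # "GRAY" | "WHITE"


@dataclass(frozen=True)
class EncodingSpec:
    """A planted linear encoding of one model variable.

    ``amplitude`` is in units of signal s.d. per s.d. of the (z-scored)
    variable, so it reads as an SNR against the unit-variance contact noise.
    ``variable`` may also be one of the unique-variance variants
    ``RePE_unique`` (RePE orthogonalized to OUT) or ``RiPE_unique``
    (RiPE_card2 orthogonalized to O.Risk), used to plant codes that are
    genuinely independent of the companion observed variable.
    """

    variable: str
    roi_label: str
    event: str
    latency_center: float
    kernel_width: float = 0.12
    amplitude: float = 1.5
    contact_fraction: float = 1.0
    # encodings sharing (roi_label, pattern_group) reuse one spatial pattern
    # (a shared neural code); encodings sharing (roi_label, disjoint_group)
    # get mutually exclusive contact subsets (independent codes)
    pattern_group: str | None = None
    disjoint_group: str | None = None

    def __post_init__(self) -> None:
        if self.event not in EVENTS:
            raise ValueError(f"unknown event {self.event!r}")
        if not 0.0 <= self.latency_center <= 0.5:
            raise ValueError("latency_center must lie in [0, 0.5] s")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class NoiseConfig:
    ar_coef: float = 0.95
    noise_sd: float = 1.0
    n_shared: int = 2
    shared_sd: float = 1.0
    shared_loading_jitter: float = 0.08
    line_amplitude: float = 0.5
    line_freq: float = 60.0


@dataclass
class SessionRecording:
    subject_id: str
    session_id: int
    sfreq: float
    contacts: list[ContactSpec]
    trials: list[tuple[Trial, TrialVariables]]
    events: pd.DataFrame  # onset_sample, event_type, trial
    raw: np.ndarray | None = None  # channels x samples, float32


@dataclass
class GroundTruth:
    """Answer key serialized alongside every generated cohort."""

    seed: int
    encodings: list[EncodingSpec]
    noise: NoiseConfig
    # (encoding index, subject_id) -> {"contacts": [...], "pattern": [...]}
    patterns: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "encodings": [dataclasses.asdict(e) for e in self.encodings],
            "noise": dataclasses.asdict(self.noise),
            "patterns": {
                f"{i}|{s}": {"contacts": v["contacts"], "pattern": list(v["pattern"])}
                for (i, s), v in self.patterns.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        gt = cls(
            seed=d["seed"],
            encodings=[EncodingSpec(**e) for e in d["encodings"]],
            noise=NoiseConfig(**d["noise"]),
        )
        for key, v in d["patterns"].items():
            i, s = key.split("|", 1)
            gt.patterns[(int(i), s)] = {
                "contacts": v["contacts"],
                "pattern": np.asarray(v["pattern"]),
            }
        return gt


@dataclass
class CohortConfig:
    """Study-shaped defaults: 10 subjects, 16 sessions, 1440 trials."""

    n_subjects: int = 10
    # six subjects completed two sessions, four completed one
    sessions_per_subject: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 1, 1, 1, 1)
    trials_per_session: int = 90
    roi_contacts: dict = field(
        default_factory=lambda: {"vmPFC": 6, "OFC": 8, "AnteriorInsula": 6, "AngularGyrus": 6}
    )
    contact_count_jitter: int = 2  # subjects differ by up to this many contacts per ROI
    report_accuracy: float = 0.915
    sfreq: float = 2000.0
    encodings: list[EncodingSpec] = field(default_factory=list)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if not self.roi_contacts:
            raise ValueError("roi_contacts must name at least one ROI")
        if len(self.sessions_per_subject) != self.n_subjects:
            raise ValueError("sessions_per_subject length must equal n_subjects")
        if not 0.0 < self.report_accuracy <= 1.0:
            raise ValueError("report_accuracy must lie in (0, 1]")


def generate_behavior(
    n_trials: int, rng: np.random.Generator, report_accuracy: float = 0.915
) -> list[tuple[Trial, TrialVariables]]:
    """Draw i.i.d. guesses and trials; reports match truth with given accuracy.

    Guesses carry no outcome dependence (no win-stay/lose-shift) and no
    stickiness by construction.
    """
    if not 0.0 < report_accuracy <= 1.0:
        raise ValueError("report_accuracy must lie in (0, 1]")
    return simulate_trials(n_trials, rng, None, report_accuracy)


def _variable_values(trials: list[tuple[Trial, TrialVariables]], name: str) -> np.ndarray:
    frame = task_model.trials_to_frame(trials)
    simple = {
        "EV": "ev",
        "OUT": "outcome",
        "RePE": "repe",
        "ERisk_card2": "erisk_card2",
        "RiPE_card2": "ripe_card2",
        "ORisk": "orisk",
    }
    if name in simple:
        return frame[simple[name]].to_numpy(dtype=float)
    if name == "RePE_unique":
        return _orth(frame["repe"].to_numpy(float), frame["outcome"].to_numpy(float))
    if name == "RiPE_unique":
        return _orth(frame["ripe_card2"].to_numpy(float), frame["orisk"].to_numpy(float))
    raise ValueError(f"unknown encoding variable {name!r}")


def _orth(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.column_stack([np.ones_like(b), b])
    return a - d @ np.linalg.lstsq(d, a, rcond=None)[0]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _ar1(
    rng: np.random.Generator, phi: float, sd: float, shape, heavy_tails: bool = True
) -> np.ndarray:
    """AR(1) noise; Laplace innovations by default.

    Field potentials carry transient, heavy-tailed structure; keeping the
    innovations non-Gaussian also makes the ICA denoising stage well-posed
    (iid Gaussian channels leave the decomposition rotation-ambiguous, so
    arbitrary near-uniform directions would be removed, smearing focal
    sources across contacts).
    """
    if heavy_tails:
        white = rng.laplace(scale=1.0 / np.sqrt(2.0), size=shape)
    else:
        white = rng.standard_normal(shape)
    out = signal.lfilter([1.0], [1.0, -phi], white, axis=-1)
    return out * (sd * np.sqrt(1.0 - phi**2))


def _raised_cosine(times: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth compact bump: support [center − width/2, center + width/2], peak 1."""
    arg = (times - center) / width
    k = 0.5 * (1.0 + np.cos(2.0 * np.pi * arg))
    k[np.abs(arg) > 0.5] = 0.0
    return k


def _make_contacts(
    config: CohortConfig, subject_id: str, rng: np.random.Generator, subject_index: int
) -> list[ContactSpec]:
    contacts: list[ContactSpec] = []
    for roi_i, (roi, base_n) in enumerate(sorted(config.roi_contacts.items())):
        n = int(base_n + rng.integers(0, config.contact_count_jitter + 1))
        electrode = f"{subject_id}-{roi}"
        y0 = ROI_Y.get(roi, 0.0)
        # the deepest pair of the first electrode sits in white matter on
        # alternating subjects, exercising the white-white exclusion rule
        white_tail = roi_i == 0 and subject_index % 2 == 0
        for k in range(n):
            tissue = "WHITE" if (white_tail and k >= n - 2) else "GRAY"
            contacts.append(
                ContactSpec(
                    subject_id=subject_id,
                    electrode_id=electrode,
                    contact_index=k,
                    roi_label=roi,
                    x=float(40.0 - 3.0 * k + rng.normal(0, 1)),
                    y=float(y0 + rng.normal(0, 2)),
                    z=float(rng.normal(0, 5)),
                    tissue=tissue,
                )
            )
    return contacts


def _make_events(
    n_trials: int, sfreq: float, rng: np.random.Generator
) -> tuple[pd.DataFrame, int]:
    rows = []
    t = 2.0  # lead-in padding
    for trial in range(n_trials):
        guess = t + rng.uniform(0.6, 1.4)
        report = guess + _REPORT_PROMPT + rng.uniform(0.4, 1.2)
        onsets = {
            "GUESS": guess,
            "CARD1_ON": guess + _CARD1_ON,
            "CARD1_OFF": guess + _CARD1_OFF,
            "CARD2_ON": guess + _CARD2_ON,
            "REPORT": report,
        }
        for ev in EVENTS:
            rows.append(
                {
                    "onset_sample": int(round(onsets[ev] * sfreq)),
                    "event_type": ev,
                    "trial": trial,
                }
            )
        t = report + 0.8
    n_samples = int(round((t + 2.0) * sfreq))
    return pd.DataFrame(rows), n_samples


def synthesize_raw(
    session: SessionRecording,
    encodings: list[EncodingSpec],
    noise_config: NoiseConfig,
    rng: np.random.Generator,
    patterns: dict | None = None,
    n_samples: int | None = None,
) -> np.ndarray:
    """Render the continuous multichannel signal for one session.

    ``patterns`` maps (encoding index, subject_id) to the contact subset and
    spatial pattern; when absent, patterns are drawn from ``rng`` (and are
    then session-specific — cohort generation always passes shared ones).
    """
    contacts = session.contacts
    n_ch = len(contacts)
    if n_samples is None:
        n_samples = int(session.events["onset_sample"].max() + 2.0 * session.sfreq)
    raw = _ar1(rng, noise_config.ar_coef, noise_config.noise_sd, (n_ch, n_samples))

    # shared components: near-uniform |loading| across contacts
    for _ in range(noise_config.n_shared):
        source = _ar1(rng, noise_config.ar_coef, noise_config.shared_sd, n_samples)
        loadings = 1.0 + noise_config.shared_loading_jitter * rng.standard_normal(n_ch)
        raw += loadings[:, None] * source[None, :]

    if noise_config.line_amplitude > 0:
        tt = np.arange(n_samples) / session.sfreq
        phase = rng.uniform(0, 2 * np.pi)
        amps = noise_config.line_amplitude * (1.0 + 0.1 * rng.standard_normal(n_ch))
        raw += amps[:, None] * np.sin(2 * np.pi * noise_config.line_freq * tt + phase)[None, :]

    kernel_t = np.arange(0, 0.5 + 1e-9, 1.0 / session.sfreq)
    events = session.events
    for enc_i, enc in enumerate(encodings):
        roi_idx = [i for i, c in enumerate(contacts) if c.roi_label == enc.roi_label]
        if not roi_idx:
            raise ValueError(f"encoding names ROI {enc.roi_label!r} with zero contacts")
        key = (enc_i, session.subject_id)
        if patterns is not None and key in patterns:
            sel_names = patterns[key]["contacts"]
            name_of = {f"{c.electrode_id}:{c.contact_index}": i for i, c in enumerate(contacts)}
            sel = [name_of[s] for s in sel_names]
            pattern = np.asarray(patterns[key]["pattern"], dtype=float)
        else:
            n_sel = max(2, int(round(enc.contact_fraction * len(roi_idx))))
            sel = roi_idx[:n_sel]
            pattern = rng.standard_normal(len(sel))
        values = _zscore(_variable_values(session.trials, enc.variable))
        kern = _raised_cosine(kernel_t, enc.latency_center, enc.kernel_width)
        ev_rows = events[events["event_type"] == enc.event]
        for _, row in ev_rows.iterrows():
            v = values[int(row["trial"])]
            start = int(row["onset_sample"])
            stop = min(start + kern.size, n_samples)
            seg = kern[: stop - start] * (enc.amplitude * v)
            raw[np.asarray(sel), start:stop] += pattern[:, None] * seg[None, :]
    return raw.astype(np.float32)


def _draw_patterns(
    config: CohortConfig,
    contacts_by_subject: dict[str, list[ContactSpec]],
    rng: np.random.Generator,
) -> dict:
    """One contact subset + spatial pattern per (encoding, subject)."""
    patterns: dict = {}
    shared: dict = {}  # (roi, pattern_group, subject) -> drawn pattern
    used: dict = {}  # (roi, disjoint_group, subject) -> set of contact names
    for enc_i, enc in enumerate(config.encodings):
        for subject_id, contacts in contacts_by_subject.items():
            roi = [c for c in contacts if c.roi_label == enc.roi_label]
            if not roi:
                raise ValueError(f"encoding names ROI {enc.roi_label!r} with zero contacts")
            share_key = (enc.roi_label, enc.pattern_group, subject_id)
            if enc.pattern_group is not None and share_key in shared:
                patterns[(enc_i, subject_id)] = shared[share_key]
                continue
            n_sel = max(2, int(round(enc.contact_fraction * len(roi))))
            if enc.disjoint_group is not None:
                # contiguous blocks separated by one unused contact, so no
                # bipolar pair straddles two independent codes
                excl_key = (enc.roi_label, enc.disjoint_group, subject_id)
                start = used.setdefault(excl_key, 0)
                if start + n_sel > len(roi):
                    raise ValueError(
                        f"not enough free contacts in {enc.roi_label!r} for disjoint encodings"
                    )
                chosen = roi[start : start + n_sel]
                used[excl_key] = start + n_sel + 1
            else:
                chosen = roi if n_sel >= len(roi) else [
                    roi[j] for j in rng.choice(len(roi), n_sel, replace=False)
                ]
            pattern = rng.standard_normal(len(chosen))
            small = np.abs(pattern) < 0.5  # keep every selected contact informative
            pattern[small] = 0.5 * np.sign(pattern[small] + 1e-12)
            entry = {
                "contacts": [f"{c.electrode_id}:{c.contact_index}" for c in chosen],
                "pattern": pattern,
            }
            patterns[(enc_i, subject_id)] = entry
            if enc.pattern_group is not None:
                shared[share_key] = entry
    return patterns


def generate_cohort(
    config: CohortConfig, seed: int, include_raw: bool = True
) -> tuple[list[SessionRecording], GroundTruth]:
    """Generate the full cohort deterministically from (config, seed)."""
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(config.n_subjects)
    layout_rng = np.random.default_rng(root.spawn(1)[0])

    contacts_by_subject: dict[str, list[ContactSpec]] = {}
    for si in range(config.n_subjects):
        sid = f"sub-{si:02d}"
        contacts_by_subject[sid] = _make_contacts(config, sid, layout_rng, si)

    patterns = _draw_patterns(config, contacts_by_subject, layout_rng)
    ground_truth = GroundTruth(
        seed=seed, encodings=list(config.encodings), noise=config.noise, patterns=patterns
    )

    sessions: list[SessionRecording] = []
    for si in range(config.n_subjects):
        sid = f"sub-{si:02d}"
        sub_rng = np.random.default_rng(subject_seeds[si])
        for sess in range(config.sessions_per_subject[si]):
            trials = generate_behavior(
                config.trials_per_session, sub_rng, config.report_accuracy
            )
            events, n_samples = _make_events(
                config.trials_per_session, config.sfreq, sub_rng
            )
            rec = SessionRecording(
                subject_id=sid,
                session_id=sess,
                sfreq=config.sfreq,
                contacts=contacts_by_subject[sid],
                trials=trials,
                events=events,
            )
            if include_raw:
                rec.raw = synthesize_raw(
                    rec, config.encodings, config.noise, sub_rng, patterns, n_samples
                )
            sessions.append(rec)
    return sessions, ground_truth


def generate_null_dataset(
    n_subjects: int,
    n_contacts: int,
    n_trials: int,
    n_timepoints: int,
    seed: int,
    ar_coef: float = 0.9,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Signal-free epoch tensors plus task labels, for error-rate studies.

    Returns ``{subject_id: (epochs x contacts x timepoints noise, outcome
    vector)}`` where the noise carries no information about the outcomes —
    the ground truth for any decoder is chance.
    """
    root = np.random.SeedSequence(seed)
    per_sub = max(1, n_contacts // n_subjects)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for si, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        X = _ar1(rng, ar_coef, 1.0, (n_trials, per_sub, n_timepoints))
        trials = simulate_trials(n_trials, rng)
        y = np.array([t.outcome for t, _ in trials], dtype=float)
        out[f"sub-{si:02d}"] = (X, y)
    return out


# ---------------------------------------------------------------------------
# Disk round trip: HDF5 raw + BIDS-iEEG-flavoured TSV sidecars + JSON truth.
# ---------------------------------------------------------------------------

def _session_dir(directory: Path, rec: SessionRecording) -> Path:
    return Path(directory) / f"{rec.subject_id}_ses-{rec.session_id:02d}"


def write_cohort(
    sessions: list[SessionRecording], ground_truth: GroundTruth, directory
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    try:
        (directory / "ground_truth.json").write_text(ground_truth.to_json())
        for rec in sessions:
            d = _session_dir(directory, rec)
            d.mkdir(exist_ok=True)
            if rec.raw is not None:
                with h5py.File(d / "raw.h5", "w") as f:
                    ds = f.create_dataset("raw", data=rec.raw)
                    ds.attrs["sfreq"] = rec.sfreq
            pd.DataFrame([dataclasses.asdict(c) for c in rec.contacts]).to_csv(
                d / "channels.tsv", sep="\t", index=False
            )
            rec.events.to_csv(d / "events.tsv", sep="\t", index=False)
            task_model.trials_to_tsv(rec.trials, d / "trials.tsv")
    except OSError as err:
        raise OSError(f"failed writing cohort under {directory}: {err}") from err


def read_cohort(directory) -> tuple[list[SessionRecording], GroundTruth]:
    directory = Path(directory)
    try:
        gt = GroundTruth.from_json((directory / "ground_truth.json").read_text())
        sessions = []
        for d in sorted(p for p in directory.iterdir() if p.is_dir()):
            sub, ses = d.name.split("_ses-")
            channels = pd.read_csv(d / "channels.tsv", sep="\t")
            contacts = [
                ContactSpec(
                    subject_id=r["subject_id"],
                    electrode_id=r["electrode_id"],
                    contact_index=int(r["contact_index"]),
                    roi_label=r["roi_label"],
                    x=float(r["x"]),
                    y=float(r["y"]),
                    z=float(r["z"]),
                    tissue=r["tissue"],
                )
                for _, r in channels.iterrows()
            ]
            rec = SessionRecording(
                subject_id=sub,
                session_id=int(ses),
                sfreq=2000.0,
                contacts=contacts,
                trials=task_model.trials_from_tsv(d / "trials.tsv"),
                events=pd.read_csv(d / "events.tsv", sep="\t"),
            )
            raw_path = d / "raw.h5"
            if raw_path.exists():
                with h5py.File(raw_path, "r") as f:
                    rec.raw = f["raw"][...]
                    rec.sfreq = float(f["raw"].attrs["sfreq"])
            sessions.append(rec)
        return sessions, gt
    except OSError as err:
        raise OSError(f"failed reading cohort under {directory}: {err}") from err
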