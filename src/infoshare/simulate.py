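"""Synthetic two-group resting-state EEG cohorts with known ground truth.

The generator emulates the study design the analysis pipeline targets: a
small patient group (default n = 13) against a larger matched control group
(default n = 25), each subject contributing band-limited (8–20 Hz) epoched
EEG on a montage with seven scalp ROIs, plus a 19-variable
neuropsychological score table with group mean shifts.

Signal model, per subject and channel::

    x_c(t) = pink_c(t) + osc_c(t) + sum_p  g_p * tanh(s_p(t - lag_side))

* ``pink_c`` — 1/f background noise, independent per channel.
* ``osc_c`` — band-limited (default 8–20 Hz) noise, independent per channel.
* ``s_p`` — one shared band-limited source per unordered ROI pair *p*;
  channels of the first ROI receive it lagged by ``coupling_lag_ms`` relative
  to channels of the second, and it passes through a tanh nonlinearity.
  This is exactly the kind of lagged, nonlinear dependence the weighted
  symbolic mutual information is designed to detect, while the lag keeps it
  from being nulled by the identical/mirrored-symbol weighting.

The mixing weight ``g_p`` is ``base_coupling`` (times a per-subject
log-normal jitter that creates realistic between-subject variance) for every
ROI pair; for pairs listed in ``altered_links`` it is additionally reduced by
``coupling_drop`` in patients only.  ``coupling_drop = 0`` therefore yields
an exact null cohort: the patient and control generative laws coincide.

The default ``coupling_drop`` was calibrated (see ``docs/methods.md``) so
that the subject-level wSMI difference on an altered ROI pair has a Cohen's
d of about one at the default design — the effect-size regime the targeted
study reports (d 0.98–1.11).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import Montage, ROI_IDS, build_montage, roi_pairs

__all__ = [
    "NpvVariable",
    "CohortDesign",
    "EpochedEEG",
    "Cohort",
    "default_npv_spec",
    "simulate_subject_eeg",
    "simulate_cohort",
    "ground_truth",
]

PATIENT = "patient"
CONTROL = "control"


@dataclass(frozen=True)
class NpvVariable:
    """Group-wise truncated-normal law of one neuropsychological score."""

    control_mean: float
    control_sd: float
    patient_mean: float
    patient_sd: float
    lo: float
    hi: float

    def params(self, group: str) -> tuple[float, float]:
        if group == PATIENT:
            return self.patient_mean, self.patient_sd
        return self.control_mean, self.control_sd

    def law(self, group: str):
        """Frozen truncated-normal law for ``group`` (requires sd > 0)."""
        mu, sd = self.params(group)
        if sd == 0:
            raise ValueError("degenerate variable has no continuous law")
        a, b = (self.lo - mu) / sd, (self.hi - mu) / sd
        return sps.truncnorm(a, b, loc=mu, scale=sd)


def default_npv_spec() -> dict[str, NpvVariable]:
    """Nineteen scores: three test batteries plus their subscores.

    Global scores follow published bvFTD-vs-control summary statistics;
    subscore laws are plausible inventions on the tests' actual score
    ranges, shifted in the patient group in the same direction as the
    parent test.
    """
    rows = {
        #                         ctrl_m  ctrl_sd  pat_m  pat_sd   lo   hi
        "ace_total":              (92.17,   6.84, 70.77,  10.66,   0, 100),
        "ace_attention":          (17.3,    0.9,  14.5,    2.4,    0,  18),
        "ace_memory":             (22.5,    2.5,  16.0,    4.5,    0,  26),
        "ace_fluency":            (10.5,    2.0,   7.0,    2.5,    0,  14),
        "ace_language":           (24.0,    1.8,  21.0,    3.0,    0,  26),
        "ace_visuospatial":       (14.5,    1.4,  12.0,    2.4,    0,  16),
        "ifs_total":              (24.94,   2.25, 15.65,   4.39,   0,  30),
        "ifs_motor_programming":  (2.5,     0.6,   1.7,    0.9,    0,   3),
        "ifs_conflicting_instr":  (2.6,     0.5,   1.9,    0.9,    0,   3),
        "ifs_go_no_go":           (2.4,     0.7,   1.4,    1.0,    0,   3),
        "ifs_backward_digits":    (4.2,     1.0,   3.0,    1.2,    0,   6),
        "ifs_verbal_wm":          (1.5,     0.5,   1.0,    0.6,    0,   2),
        "ifs_spatial_wm":         (3.0,     0.8,   2.0,    1.0,    0,   4),
        "ifs_abstraction":        (2.2,     0.7,   1.2,    0.9,    0,   3),
        "ifs_verbal_inhibition":  (4.8,     1.1,   3.0,    1.6,    0,   6),
        "ravlt_immediate":        (42.89,  10.07, 24.23,   8.87,   0,  75),
        "ravlt_delayed":          (7.28,    3.32,  3.69,   2.81,   0,  15),
        "ravlt_recognition":      (12.5,    2.0,   9.5,    3.0,    0,  15),
        "verbal_fluency":         (17.0,    4.5,  11.0,    4.5,    0,  40),
    }
    return {name: NpvVariable(*vals) for name, vals in rows.items()}


# Calibrated so subject-level wSMI on an altered ROI pair differs between
# groups with Cohen's d ~= 1 at the default design (see docs/methods.md).
DEFAULT_COUPLING_DROP = 0.25


@dataclass(frozen=True)
class CohortDesign:
    """Full description of a synthetic two-group cohort."""

    n_patients: int = 13
    n_controls: int = 25
    montage_layout: str = "standard1020"
    epochs_per_subject: int = 60
    epoch_len_s: float = 2.0
    fs: float = 256.0
    band: tuple[float, float] = (8.0, 20.0)
    base_coupling: float = 1.5
    altered_links: tuple[tuple[str, str], ...] = (
        ("R1", "R3"), ("R1", "R4"), ("R1", "R5"), ("R1", "R6"),
        ("R2", "R3"), ("R2", "R4"), ("R2", "R5"), ("R2", "R6"),
    )
    coupling_drop: float = DEFAULT_COUPLING_DROP
    coupling_jitter: float = 0.2  # sd of log-normal subject-level jitter
    coupling_lag_ms: float = 16.0
    npv_spec: dict[str, NpvVariable] = field(default_factory=default_npv_spec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if self.epochs_per_subject <= 0 or self.epoch_len_s <= 0:
            raise ValueError("epoch counts and lengths must be positive")
        if not 0.0 <= self.coupling_drop <= 1.0:
            raise ValueError("coupling_drop must be in [0, 1]")
        lo, hi = self.band
        if not (0.0 < lo < hi < self.fs / 2.0):
            raise ValueError("band must satisfy 0 < low < high < fs/2")
        for link in self.altered_links:
            if not (len(link) == 2 and set(link) <= set(ROI_IDS)):
                raise ValueError(f"bad altered link {link!r}")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_len_s * self.fs))

    @property
    def lag_samples(self) -> int:
        return max(1, int(round(self.coupling_lag_ms * self.fs / 1000.0)))

    def altered_set(self) -> set[frozenset[str]]:
        return {frozenset(link) for link in self.altered_links}

    def with_(self, **kwargs) -> "CohortDesign":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EpochedEEG:
    """One subject's epoched EEG: channels x epochs x samples, in µV."""

    subject_id: str
    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("data must be (channels, epochs, samples)")
        if not np.all(np.isfinite(d)):
            raise ValueError("EEG data must be finite")
        object.__setattr__(self, "data", d)


@dataclass
class Cohort:
    """Subjects, their EEG (or connectivity), scores, and the montage."""

    subjects: list[tuple[str, str]]  # (subject_id, group)
    eeg: dict[str, EpochedEEG]
    npv: pd.DataFrame  # index: subject_id
    montage: Montage
    design: CohortDesign | None = None
    connectivity: dict[str, np.ndarray] | None = None

    @property
    def subject_ids(self) -> list[str]:
        return [s for s, _ in self.subjects]

    @property
    def groups(self) -> pd.Series:
        return pd.Series(dict(self.subjects), name="group")

    def ids_of(self, group: str) -> list[str]:
        return [s for s, g in self.subjects if g == group]


def _band_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fs: float,
    band: tuple[float, float] | None,
    pink: bool = False,
) -> np.ndarray:
    """Unit-variance noise shaped in the frequency domain.

    ``band`` restricts support to [low, high] Hz; ``pink=True`` applies a
    1/f amplitude profile instead.
    """
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    if pink:
        gain = np.zeros_like(freqs)
        gain[1:] = freqs[1:] ** -0.5
    else:
        lo, hi = band  # type: ignore[misc]
        gain = ((freqs >= lo) & (freqs <= hi)).astype(float)
    x = np.fft.irfft(spec * gain, n=shape[-1], axis=-1)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_subject_eeg(
    design: CohortDesign,
    group: str,
    subject_seed: int,
    subject_id: str = "S00",
    montage: Montage | None = None,
) -> EpochedEEG:
    """Simulate one subject's epoched EEG under the cohort design.

    Bit-reproducible for a given ``(design, group, subject_seed)``; with
    ``coupling_drop == 0`` the draw is identical for both groups.
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"unknown group {group!r}")
    m = montage or build_montage(design.montage_layout)
    rng = np.random.default_rng(subject_seed)
    n_ch = m.n_channels
    n_ep = design.epochs_per_subject
    n_s = design.samples_per_epoch
    lag = design.lag_samples

    x = _band_noise(rng, (n_ch, n_ep, n_s), design.fs, None, pink=True)
    x += _band_noise(rng, (n_ch, n_ep, n_s), design.fs, design.band)

    roi_members = {roi: [m.index(c) for c in m.roi_channels(roi)] for roi in ROI_IDS}
    altered = design.altered_set()
    for ra, rb in roi_pairs():
        u = _band_noise(rng, (n_ep, n_s + lag), design.fs, design.band)
        jitter = float(np.exp(design.coupling_jitter * rng.standard_normal()))
        g_full = design.base_coupling * jitter
        g = g_full
        if group == PATIENT and frozenset((ra, rb)) in altered:
            g *= 1.0 - design.coupling_drop
        shared_a = np.tanh(u[:, lag:])
        shared_b = np.tanh(u[:, :n_s])
        shared_a = shared_a / shared_a.std()
        shared_b = shared_b / shared_b.std()
        members = roi_members[ra] + roi_members[rb]
        x[roi_members[ra]] += g * shared_a
        x[roi_members[rb]] += g * shared_b
        if frozenset((ra, rb)) in altered:
            # replace the variance removed from the shared source with
            # channel-independent band noise, so patient channels keep the
            # same power and spectrum and unaltered couplings are untouched;
            # the noise is drawn for both groups to keep the RNG stream (and
            # hence the coupling_drop = 0 null cohort) group-identical
            comp = np.sqrt(max(g_full**2 - g**2, 0.0))
            extra = _band_noise(
                rng, (len(members), n_ep, n_s), design.fs, design.band
            )
            x[members] += comp * extra

    return EpochedEEG(subject_id=subject_id, data=10.0 * x, fs=design.fs)


def _simulate_npv(
    design: CohortDesign, subjects: list[tuple[str, str]], rng: np.random.Generator
) -> pd.DataFrame:
    groups = np.array([g for _, g in subjects])
    cols = {}
    for name, var in design.npv_spec.items():
        vals = np.empty(len(subjects))
        for group in (PATIENT, CONTROL):
            idx = np.flatnonzero(groups == group)
            if idx.size == 0:
                continue
            mu, sd = var.params(group)
            if sd == 0:
                vals[idx] = mu
            else:
                vals[idx] = var.law(group).rvs(size=idx.size, random_state=rng)
        cols[name] = vals
    npv = pd.DataFrame(cols, index=[s for s, _ in subjects])
    npv.index.name = "subject"
    return npv


def simulate_cohort(design: CohortDesign) -> Cohort:
    """Draw a full cohort: EEG per subject plus the score table."""
    m = build_montage(design.montage_layout)
    subjects = [(f"P{i + 1:02d}", PATIENT) for i in range(design.n_patients)]
    subjects += [(f"C{i + 1:02d}", CONTROL) for i in range(design.n_controls)]
    master = np.random.default_rng(design.seed)
    subject_seeds = master.integers(0, 2**31, size=len(subjects))
    eeg = {
        sid: simulate_subject_eeg(design, grp, int(seed), sid, montage=m)
        for (sid, grp), seed in zip(subjects, subject_seeds)
    }
    npv = _simulate_npv(design, subjects, master)
    return Cohort(subjects=subjects, eeg=eeg, npv=npv, montage=m, design=design)


def ground_truth(design: CohortDesign) -> list[tuple[str, str, str]]:
    """The injected hypoconnectivity links, deduplicated and ordered."""
    seen: set[frozenset[str]] = set()
    out: list[tuple[str, str, str]] = []
    for link in design.altered_links:
        key = frozenset(link)
        if key in seen:
            continue
        seen.add(key)
        a, b = sorted(key)
        out.append((a, b, "patient<control"))
    return out
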