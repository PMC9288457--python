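"""Generic blood-pressure dataset generator.

Simulates longitudinal BP cohorts with controllable *inter*personal
variability (spread of subject baselines) and *intra*personal variability
(within-subject fluctuation), the two quantities the relative-performance
score is built on.  Three built-in families mimic common study settings:

* ``lab``      — a 30-minute resting laboratory session: tight baselines,
                 little within-subject noise, no circadian excursion;
* ``normal24`` — a 24-hour ambulatory profile with a normally distributed
                 circadian rhythm (nocturnal dip around 03:00);
* ``hard24``   — a 24-hour profile of a heterogeneous cohort: wide
                 baselines, strong rhythm, noisy measurements.

Short-period pressure oscillations (Traube-Hering-Mayer waves, ~10 s) are
far below the sampling density of 50 readings per day and are therefore
absorbed into the white within-subject noise term.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import BPDataset

__all__ = ["SyntheticProfile", "builtin_profiles", "generate_dataset", "sd_sweep"]

#: Minute of day where the circadian minimum (nocturnal dip) is placed.
DIP_MINUTE = 180.0  # 03:00


@dataclass(frozen=True)
class SyntheticProfile:
    """Generator parameters for one generic dataset family.

    All pressures in mmHg, times in minutes, heart rate in beats/min.
    ``inter_sd`` is the SD of subject baselines, ``intra_sd`` the SD of
    within-subject measurement noise; the circadian amplitude is drawn per
    subject from a normal distribution truncated at zero.  Diastolic values
    reuse the systolic variability parameters scaled by ``dbp_scale``.
    ``sex_ratio`` is the fraction of female subjects.
    """

    name: str
    n_subjects: int = 10_000
    per_subject: int = 50
    duration: float = 1440.0
    population_mean_sbp: float = 120.0
    population_mean_dbp: float = 75.0
    inter_sd: float = 12.0
    intra_sd: float = 7.0
    circadian_amplitude_mean: float = 10.0
    circadian_amplitude_sd: float = 3.0
    circadian_phase_sd: float = 60.0
    hr_mean: float = 75.0
    hr_sd: float = 8.0
    hr_noise_sd: float = 3.0
    hr_bp_coupling: float = 0.2
    age_range: tuple = (18.0, 80.0)
    sex_ratio: float = 0.5
    dbp_scale: float = 0.6

    def __post_init__(self) -> None:
        for name in (
            "inter_sd",
            "intra_sd",
            "circadian_amplitude_mean",
            "circadian_amplitude_sd",
            "circadian_phase_sd",
            "hr_sd",
            "hr_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.per_subject < 3:
            raise ValueError("per_subject must be >= 3")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be a fraction in [0, 1]")

    @property
    def total_sd(self) -> float:
        """Approximate marginal SD of the systolic channel.

        Baseline, noise and circadian components are independent; a cosine
        with random amplitude A sampled at uniform phase contributes
        variance E[A^2]/2.
        """
        amp_msq = self.circadian_amplitude_mean**2 + self.circadian_amplitude_sd**2
        return float(np.sqrt(self.inter_sd**2 + self.intra_sd**2 + amp_msq / 2.0))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticProfile":
        data = dict(data)
        if "age_range" in data:
            data["age_range"] = tuple(data["age_range"])
        return cls(**data)


def builtin_profiles() -> dict[str, SyntheticProfile]:
    """The three generic dataset families, 10,000 subjects x 50 readings.

    Variability is strictly ordered lab < normal24 < hard24 in both the
    inter- and intrapersonal SDs.
    """
    return {
        "lab": SyntheticProfile(
            name="lab",
            duration=30.0,
            inter_sd=8.0,
            intra_sd=3.0,
            circadian_amplitude_mean=0.0,
            circadian_amplitude_sd=0.0,
        ),
        "normal24": SyntheticProfile(
            name="normal24",
            duration=1440.0,
            inter_sd=12.0,
            intra_sd=7.0,
            circadian_amplitude_mean=10.0,
            circadian_amplitude_sd=10.0 / 3.0,
        ),
        "hard24": SyntheticProfile(
            name="hard24",
            duration=1440.0,
            inter_sd=18.0,
            intra_sd=12.0,
            circadian_amplitude_mean=15.0,
            circadian_amplitude_sd=5.0,
        ),
    }


def generate_dataset(profile: SyntheticProfile, seed: int = 0) -> BPDataset:
    """Simulate one cohort under ``profile``; bit-identical given the seed.

    Per subject: a normal baseline, a truncated-normal circadian amplitude
    with normally jittered phase, measurement times uniform over the
    profile duration (sorted), and white within-subject noise.  Diastolic
    values get independently drawn components scaled by ``dbp_scale`` and
    are constrained strictly below systolic.  Heart rate couples linearly
    to the BP excursion around the subject baseline.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))
    ns, k = profile.n_subjects, profile.per_subject

    base_sbp = rng.normal(profile.population_mean_sbp, profile.inter_sd, ns)
    base_dbp = rng.normal(profile.population_mean_dbp, profile.inter_sd * profile.dbp_scale, ns)
    amp_sbp = np.clip(
        rng.normal(profile.circadian_amplitude_mean, profile.circadian_amplitude_sd, ns), 0, None
    )
    amp_dbp = amp_sbp * profile.dbp_scale
    phase = rng.normal(0.0, profile.circadian_phase_sd, ns)
    base_hr = rng.normal(profile.hr_mean, profile.hr_sd, ns)
    age = rng.uniform(profile.age_range[0], profile.age_range[1], ns)
    is_female = rng.random(ns) < profile.sex_ratio

    times = np.sort(rng.uniform(0.0, profile.duration, size=(ns, k)), axis=1)
    circ = -np.cos(2 * np.pi * (times - phase[:, None] - DIP_MINUTE) / 1440.0)
    sbp = (
        base_sbp[:, None]
        + amp_sbp[:, None] * circ
        + rng.normal(0.0, profile.intra_sd, size=(ns, k))
    )
    dbp = (
        base_dbp[:, None]
        + amp_dbp[:, None] * circ
        + rng.normal(0.0, profile.intra_sd * profile.dbp_scale, size=(ns, k))
    )
    dbp = np.minimum(dbp, sbp - 1.0)
    hr = (
        base_hr[:, None]
        + profile.hr_bp_coupling * (sbp - base_sbp[:, None])
        + rng.normal(0.0, profile.hr_noise_sd, size=(ns, k))
    )

    width = max(5, len(str(ns)))
    subjects = np.array([f"S{i:0{width}d}" for i in range(ns)])
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat(subjects, k),
            "time": times.ravel(),
            "sbp": sbp.ravel(),
            "dbp": dbp.ravel(),
            "heart_rate": hr.ravel(),
            "age": np.repeat(np.round(age, 1), k),
            "sex": np.repeat(np.where(is_female, "female", "male"), k),
        }
    )
    return BPDataset(frame)


def sd_sweep(
    base: SyntheticProfile,
    sd_values,
    n_per_dataset: int = 50_000,
    seed: int = 0,
) -> list[BPDataset]:
    """Datasets with increasing total BP standard deviation.

    Each target SD rescales the base profile's inter-, intra- and circadian
    SDs by a common factor, so the inter/intra proportion is fixed along
    the sweep.  One dataset of ``n_per_dataset`` rows per SD value; each
    dataset gets its own seed stream derived from ``seed``.
    """
    sd_values = [float(s) for s in sd_values]
    if any(s <= 0 for s in sd_values) or sorted(sd_values) != sd_values:
        raise ValueError("sd_values must be positive and increasing")
    n_subjects = max(1, n_per_dataset // base.per_subject)
    datasets = []
    for i, target in enumerate(sd_values):
        scale = target / base.total_sd
        profile = dataclasses.replace(
            base,
            name=f"{base.name}_sd{target:g}",
            n_subjects=n_subjects,
            inter_sd=base.inter_sd * scale,
            intra_sd=base.intra_sd * scale,
            circadian_amplitude_mean=base.circadian_amplitude_mean * scale,
            circadian_amplitude_sd=base.circadian_amplitude_sd * scale,
        )
        child = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2**31))
        datasets.append(generate_dataset(profile, seed=child))
    return datasets
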