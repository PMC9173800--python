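"""Synthetic twin cohort: genotypes, covariates, kinship, per-subject
cellular gains and full recording sessions.

The cohort emulates an adult twin-registry sample genotyped at one
biallelic risk locus: monozygotic (MZ) co-twins share their genotype,
dizygotic (DZ) co-twins are generated by explicit parental transmission
(so allele sharing is exactly Mendelian), and singleton founders follow
Hardy–Weinberg proportions.  The risk allele acts multiplicatively on the
OFF-bipolar gain only (by default), so cone-driven amplitudes carry a dose
effect while rod-driven amplitudes do not.

Between-subject gain variability is lognormal with an additive-genetic
style shared component (correlation 1 within MZ pairs, 0.5 within DZ
pairs) matching the kinship covariance assumed by the association model,
plus an independent individual component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ergtwin.defaults import DEFAULT_GAINS
from ergtwin.forward_model import (
    CellularGains,
    StimulusSpec,
    Trace,
    add_noise,
    synthesize_flash_response,
    synthesize_flicker_response,
)

__all__ = [
    "SubjectRecord",
    "CohortSpec",
    "Session",
    "make_families",
    "draw_genotypes",
    "assign_gains",
    "assign_cohort_gains",
    "build_kinship",
    "simulate_cohort",
    "simulate_session",
]

#: Gain fields that vary between subjects (lognormal deviations).
VARIABLE_GAIN_FIELDS = (
    "rod_pr_max",
    "cone_pr_max",
    "on_bipolar_gain",
    "off_bipolar_gain",
    "op_gain",
)

#: Risk-allele frequency implied by a 37/101/48 genotype-group split:
#: (101 + 2*48) / (2*186).
DEFAULT_RISK_ALLELE_FREQUENCY = (101 + 2 * 48) / (2 * 186)


@dataclass
class SubjectRecord:
    subject_id: str
    family_id: str
    zygosity: str  # MZ, DZ or singleton
    age: float
    sex: str  # F or M
    dosage: int
    gains: Optional[CellularGains] = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ", "singleton"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.dosage not in (0, 1, 2):
            raise ValueError("dosage must be 0, 1 or 2")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be F or M")


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of the synthetic study population.

    Defaults emulate the analyzed cohort: 93 same-sex twin pairs
    (~186 subjects), 95% female, ages ~ Normal(64.2, 9.7) truncated to
    [18, 95], risk-allele frequency matching a 37/101/48 genotype split.
    The per-allele OFF-gain effect of -0.17 is calibrated so that, given
    the OFF share (~0.45) of the modelled cone-driven a-wave, group means
    of the brightest-flash cone a-wave fall from ≈56 µV (dosage 0) to
    ≈47.5 µV (dosage 2).
    """

    n_pairs: int = 93
    fraction_mz: float = 0.5
    n_singletons: int = 0
    risk_allele_frequency: float = DEFAULT_RISK_ALLELE_FREQUENCY
    age_mean: float = 64.2
    age_sd: float = 9.7
    age_range: Tuple[float, float] = (18.0, 95.0)
    female_fraction: float = 0.95
    off_effect_per_allele: float = -0.17
    other_effects: Dict[str, float] = field(default_factory=dict)
    gain_sd_genetic: float = 0.16      # lognormal log-sd, shared (kinship-correlated)
    gain_sd_individual: float = 0.12   # lognormal log-sd, independent
    inter_eye_sd: float = 0.03
    noise_sd: float = 5.0
    drift_sd: float = 2.0
    sweeps_per_stimulus: int = 4
    artifact_rate: float = 0.02
    rod_suppression: float = 1.0
    cone_desensitization: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("fraction_mz", "risk_allele_frequency", "female_fraction",
                     "artifact_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_pairs < 0 or self.n_singletons < 0:
            raise ValueError("cohort sizes must be >= 0")
        for eff in (self.off_effect_per_allele, *self.other_effects.values()):
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")
            if 1.0 + 2.0 * eff < 0.0:
                raise ValueError("per-allele effect would drive a gain negative")
        for name in ("gain_sd_genetic", "gain_sd_individual", "inter_eye_sd",
                     "noise_sd", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sweeps_per_stimulus < 1:
            raise ValueError("sweeps_per_stimulus must be >= 1")

    def rng(self, rng: Optional[np.random.Generator] = None) -> np.random.Generator:
        if rng is not None:
            return rng
        if self.seed is None:
            raise ValueError("CohortSpec.seed is mandatory when no generator is supplied")
        return np.random.default_rng(self.seed)


@dataclass
class Session:
    """One subject's recording session: raw sweeps plus the generator log."""

    subject_id: str
    sweeps: List[Trace]
    log: Dict


def make_families(spec: CohortSpec) -> List[Tuple[str, str, int]]:
    """Deterministic family layout: (family_id, zygosity, n_members)."""
    n_mz = int(round(spec.n_pairs * spec.fraction_mz))
    fams = []
    for i in range(spec.n_pairs):
        zyg = "MZ" if i < n_mz else "DZ"
        fams.append((f"F{i:03d}", zyg, 2))
    for j in range(spec.n_singletons):
        fams.append((f"F{spec.n_pairs + j:03d}", "singleton", 1))
    return fams


def _transmit(parent_dosage: int, rng: np.random.Generator) -> int:
    """One allele transmitted by a parent with the given risk-allele count."""
    return int(rng.random() < parent_dosage / 2.0)


def draw_genotypes(
    spec: CohortSpec, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Risk-allele dosages (0/1/2) per subject, in family order.

    Founders (parents of twin pairs, and singletons) are Hardy–Weinberg at
    the risk-allele frequency; MZ co-twins copy one transmitted genotype;
    DZ co-twins receive two independent transmissions from the same
    parents, so their allele sharing is exactly Mendelian.
    """
    rng = spec.rng(rng)
    p = spec.risk_allele_frequency
    dosages: List[int] = []
    for _, zyg, n in make_families(spec):
        if zyg == "singleton":
            dosages.append(int(rng.binomial(2, p)))
            continue
        mother = int(rng.binomial(2, p))
        father = int(rng.binomial(2, p))
        child1 = _transmit(mother, rng) + _transmit(father, rng)
        if zyg == "MZ":
            child2 = child1
        else:
            child2 = _transmit(mother, rng) + _transmit(father, rng)
        dosages.extend([child1, child2])
    return np.asarray(dosages, dtype=int)


def _gain_multipliers(
    dosage: int,
    spec: CohortSpec,
    genetic_dev: Dict[str, float],
    individual_dev: Dict[str, float],
) -> Dict[str, float]:
    mult = {}
    for name in VARIABLE_GAIN_FIELDS:
        m = float(np.exp(genetic_dev[name] + individual_dev[name]))
        if name == "off_bipolar_gain":
            m *= 1.0 + dosage * spec.off_effect_per_allele
        if name in spec.other_effects:
            m *= 1.0 + dosage * spec.other_effects[name]
        mult[name] = m
    return mult


def assign_gains(
    dosage: int,
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
    base: CellularGains = DEFAULT_GAINS,
    genetic_dev: Optional[Dict[str, float]] = None,
) -> CellularGains:
    """Draw one subject's gains: lognormal deviations around the base,
    with the per-allele multiplicative dosage effect on the OFF-bipolar
    gain (and on any other configured fields).

    ``genetic_dev`` supplies the shared log-deviations when gains are
    drawn family-wise (see :func:`assign_cohort_gains`); when omitted they
    are drawn independently here.
    """
    rng = spec.rng(rng)
    if genetic_dev is None:
        genetic_dev = {
            f: rng.normal(0.0, spec.gain_sd_genetic) for f in VARIABLE_GAIN_FIELDS
        }
    individual_dev = {
        f: rng.normal(0.0, spec.gain_sd_individual) for f in VARIABLE_GAIN_FIELDS
    }
    mult = _gain_multipliers(dosage, spec, genetic_dev, individual_dev)
    return base.replace(**{f: getattr(base, f) * mult[f] for f in VARIABLE_GAIN_FIELDS})


def assign_cohort_gains(
    subjects: Sequence[SubjectRecord],
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
    base: CellularGains = DEFAULT_GAINS,
) -> List[CellularGains]:
    """Gains for a whole cohort with kinship-consistent shared deviations:
    genetic log-deviations correlate 1 within MZ pairs and 0.5 within DZ
    pairs, matching the relatedness matrix used by the association model."""
    rng = spec.rng(rng)
    out: List[Optional[CellularGains]] = [None] * len(subjects)
    by_family: Dict[str, List[int]] = {}
    for i, s in enumerate(subjects):
        by_family.setdefault(s.family_id, []).append(i)
    sg = spec.gain_sd_genetic
    for fam_id in sorted(by_family):
        idx = by_family[fam_id]
        zyg = subjects[idx[0]].zygosity
        devs: List[Dict[str, float]] = [dict() for _ in idx]
        for fname in VARIABLE_GAIN_FIELDS:
            if zyg == "MZ" and len(idx) == 2:
                a = rng.normal(0.0, sg)
                vals = [a, a]
            elif zyg == "DZ" and len(idx) == 2:
                z1, z2 = rng.normal(0.0, 1.0, 2)
                vals = [sg * z1, sg * (0.5 * z1 + np.sqrt(0.75) * z2)]
            else:
                vals = [rng.normal(0.0, sg) for _ in idx]
            for d, v in zip(devs, vals):
                d[fname] = v
        for pos, i in enumerate(idx):
            out[i] = assign_gains(
                subjects[i].dosage, spec, rng, base=base, genetic_dev=devs[pos]
            )
    return list(out)  # type: ignore[arg-type]


def build_kinship(subjects: Sequence[SubjectRecord]) -> np.ndarray:
    """Expected additive relatedness matrix: diagonal 1, MZ pairs 1,
    DZ pairs 0.5, unrelated 0.  Order follows ``subjects``."""
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated subject id")
    n = len(subjects)
    K = np.eye(n)
    by_family: Dict[str, List[int]] = {}
    for i, s in enumerate(subjects):
        by_family.setdefault(s.family_id, []).append(i)
    for idx in by_family.values():
        if len(idx) < 2:
            continue
        zyg = subjects[idx[0]].zygosity
        r = 1.0 if zyg == "MZ" else 0.5
        for a in idx:
            for b in idx:
                if a != b:
                    K[a, b] = r
    return K


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def simulate_cohort(
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
    base: CellularGains = DEFAULT_GAINS,
) -> List[SubjectRecord]:
    """Full cohort draw: structure, genotypes, covariates and gains.

    Twins share family id, age and sex.  Returns subjects in kinship
    order (the order used by :func:`build_kinship`).
    """
    rng = spec.rng(rng)
    dosages = draw_genotypes(spec, rng)
    subjects: List[SubjectRecord] = []
    k = 0
    for fam_id, zyg, n in make_families(spec):
        age = _truncated_normal(spec.age_mean, spec.age_sd, *spec.age_range, rng=rng)
        sex = "F" if rng.random() < spec.female_fraction else "M"
        for _ in range(n):
            subjects.append(
                SubjectRecord(
                    subject_id=f"S{k:04d}",
                    family_id=fam_id,
                    zygosity=zyg,
                    age=round(age, 1),
                    sex=sex,
                    dosage=int(dosages[k]),
                )
            )
            k += 1
    gains = assign_cohort_gains(subjects, spec, rng, base=base)
    for s, g in zip(subjects, gains):
        s.gains = g
    return subjects


def cohort_table(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "family_id": [s.family_id for s in subjects],
            "zygosity": [s.zygosity for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "dosage": [s.dosage for s in subjects],
        }
    )
    return df.set_index("subject_id")


def _artifact_transient(times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A large gaussian-bump transient, exceeding the rejection cap."""
    center = rng.uniform(10.0, min(200.0, times[-1]))
    width = rng.uniform(2.0, 6.0)
    amp = (1500.0 + rng.exponential(1500.0)) * rng.choice([-1.0, 1.0])
    return amp * np.exp(-0.5 * ((times - center) / width) ** 2)


def simulate_session(
    subject: SubjectRecord,
    protocol: Sequence[StimulusSpec],
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
) -> Session:
    """Per-subject recording session: both eyes, ``spec.sweeps_per_stimulus``
    noisy sweeps per stimulus, occasional injected artifact sweeps.

    Eyes share the subject's gains up to a small lognormal inter-eye
    deviation.  Injected artifacts are recorded in sweep metadata and in
    the session log, so downstream rejection can be audited.
    """
    if not protocol:
        raise ValueError("protocol must be non-empty")
    if subject.gains is None:
        raise ValueError("subject has no gains assigned")
    rng = spec.rng(rng)
    sweeps: List[Trace] = []
    injected: List[Dict] = []
    for eye in ("R", "L"):
        eye_mult = float(np.exp(rng.normal(0.0, spec.inter_eye_sd)))
        g = subject.gains.replace(
            **{f: getattr(subject.gains, f) * eye_mult for f in VARIABLE_GAIN_FIELDS}
        )
        for stim in protocol:
            if stim.mode == "flicker_30hz":
                clean = synthesize_flicker_response(
                    stim, g,
                    rod_suppression=spec.rod_suppression,
                    cone_desensitization=spec.cone_desensitization,
                )
            else:
                clean = synthesize_flash_response(
                    stim, g,
                    rod_suppression=spec.rod_suppression,
                    cone_desensitization=spec.cone_desensitization,
                ).trace
            for j in range(spec.sweeps_per_stimulus):
                sw = add_noise(clean, spec.noise_sd, spec.drift_sd, rng=rng)
                is_artifact = bool(rng.random() < spec.artifact_rate)
                if is_artifact:
                    sw = sw.copy(volts=sw.volts + _artifact_transient(sw.times, rng))
                    injected.append({"stimulus": stim.label, "eye": eye, "sweep": j})
                sw.meta.update(
                    subject_id=subject.subject_id,
                    eye=eye,
                    sweep=j,
                    stimulus=stim.label,
                    flash_strength=stim.flash_strength,
                    background=stim.background_kind,
                    mode=stim.mode,
                    artifact=is_artifact,
                )
                sweeps.append(sw)
    return Session(
        subject_id=subject.subject_id,
        sweeps=sweeps,
        log={"n_sweeps": len(sweeps), "injected_artifacts": injected},
    )
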