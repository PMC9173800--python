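"""End-to-end study orchestration: simulate → process → associate → report.

A run is a pure function of its configuration (including the master seed):
per-stage random streams are spawned deterministically from the seed, and
every output table carries a provenance header with the config hash, seed
and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from ergtwin import io as ergio
from ergtwin.association import association_scan, summarize_by_group
from ergtwin.cohort import (
    CohortSpec,
    SubjectRecord,
    build_kinship,
    cohort_table,
    simulate_cohort,
    simulate_session,
)
from ergtwin.defaults import DEFAULT_GAINS
from ergtwin.forward_model import (
    CellularGains,
    StimulusSpec,
    synthesize_flash_response,
    synthesize_flicker_response,
)
from ergtwin.processing import (
    CONE_PARAMETERS,
    ROD_PARAMETERS,
    TABLE1_PARAMETERS,
    ArtifactCriteria,
    extract_features,
    features_to_frame,
)
from ergtwin.protocols import protocol_by_label, standard_protocol

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "noiseless_features",
    "lesion_comparison",
    "subject_features",
    "cohort_features",
]


@dataclass(frozen=True)
class StudyConfig:
    """Fully serializable description of one study run."""

    seed: int
    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(seed=0))
    protocol: Optional[List[str]] = None  # stimulus labels; None = full set
    artifact_abs_cap: float = 1000.0
    artifact_k: float = 5.0
    alpha: float = 0.05
    method: str = "reml"
    dosage_coding: str = "additive"
    bh_correction: bool = False
    lesion_demo: bool = True
    make_plots: bool = False

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["cohort"]["age_range"] = list(d["cohort"]["age_range"])
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "StudyConfig":
        d = dict(d)
        c = dict(d.pop("cohort", {}))
        if "age_range" in c:
            c["age_range"] = tuple(c["age_range"])
        return cls(cohort=CohortSpec(**c), **d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def stimuli(self) -> List[StimulusSpec]:
        if self.protocol is None:
            return standard_protocol()
        by_label = protocol_by_label()
        return [by_label[label] for label in self.protocol]

    def criteria(self) -> ArtifactCriteria:
        return ArtifactCriteria(abs_cap=self.artifact_abs_cap, k=self.artifact_k)


@dataclass
class StudyReport:
    cohort: pd.DataFrame
    kinship: np.ndarray
    features: pd.DataFrame
    summary_standard: pd.DataFrame
    summary_rod_cone: pd.DataFrame
    association: pd.DataFrame
    lesions: Dict[str, pd.DataFrame]
    rejection_log: List[Dict]
    provenance: Dict[str, str]


def _session_streams(seed: int, n_subjects: int):
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + n_subjects)
    return np.random.default_rng(children[0]), [
        np.random.default_rng(c) for c in children[1:]
    ]


def subject_features(
    subject: SubjectRecord,
    protocol: Sequence[StimulusSpec],
    spec: CohortSpec,
    rng: np.random.Generator,
    criteria: ArtifactCriteria = ArtifactCriteria(),
):
    """Simulate one session and measure its features (the per-subject
    pipeline used by ``run_study``)."""
    session = simulate_session(subject, protocol, spec, rng)
    feats, logs = extract_features(session.sweeps, criteria)
    return feats, logs, session


def cohort_features(
    subjects: Sequence[SubjectRecord],
    protocol: Sequence[StimulusSpec],
    spec: CohortSpec,
    rngs: Sequence[np.random.Generator],
    criteria: ArtifactCriteria = ArtifactCriteria(),
) -> pd.DataFrame:
    """Features for every subject (no files written)."""
    rows = {}
    for subject, rng in zip(subjects, rngs):
        feats, _, _ = subject_features(subject, protocol, spec, rng, criteria)
        rows[subject.subject_id] = feats
    return features_to_frame(rows)


def noiseless_features(
    gains: CellularGains,
    lesion: str = "none",
    protocol: Optional[Sequence[StimulusSpec]] = None,
    *,
    rod_suppression: float = 1.0,
    cone_desensitization: float = 1.0,
) -> Dict[str, float]:
    """Features of a noiseless single-eye recording through the full
    processing chain (baseline, measurement windows, rod isolation)."""
    if protocol is None:
        protocol = standard_protocol()
    sweeps = []
    for stim in protocol:
        if stim.mode == "flicker_30hz":
            tr = synthesize_flicker_response(
                stim, gains, lesion,
                rod_suppression=rod_suppression,
                cone_desensitization=cone_desensitization,
            )
        else:
            tr = synthesize_flash_response(
                stim, gains, lesion,
                rod_suppression=rod_suppression,
                cone_desensitization=cone_desensitization,
            ).trace
        tr.meta.update(
            stimulus=stim.label,
            eye="R",
            sweep=0,
            flash_strength=stim.flash_strength,
            background=stim.background_kind,
            mode=stim.mode,
        )
        sweeps.append(tr)
    feats, _ = extract_features(sweeps)
    return feats


def lesion_comparison(
    protocol: Optional[Sequence[StimulusSpec]] = None,
    gains: CellularGains = DEFAULT_GAINS,
    lesion: str = "crao",
) -> pd.DataFrame:
    """Noiseless lesioned/healthy amplitude ratios per measured parameter,
    computed through the full processing chain (including rod isolation).

    Emulates within-patient comparisons: a CRAO eye versus the healthy
    fellow eye, or a cCSNB patient versus a healthy control with the same
    underlying gains.
    """
    healthy = noiseless_features(gains, "none", protocol)
    lesioned = noiseless_features(gains, lesion, protocol)
    rows = []
    for param in healthy:
        h = healthy[param]
        l = lesioned.get(param, np.nan)
        rows.append(
            {
                "parameter": param,
                "healthy_uV": h,
                "lesioned_uV": l,
                "ratio": (l / h) if h > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_study(
    config: StudyConfig,
    out_dir: Optional[Path] = None,
    write_sessions: bool = False,
) -> StudyReport:
    """Execute the whole pipeline; deterministic given ``config.seed``.

    When ``out_dir`` is set, all report tables are written there with
    provenance headers; a stage failure leaves a ``FAILED`` marker naming
    the stage.
    """
    provenance = {
        "config_hash": config.config_hash(),
        "seed": str(config.seed),
        "ergtwin_version": _version(),
    }
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    stage = "simulate"
    try:
        spec = dataclasses.replace(config.cohort, seed=None)
        cohort_rng, session_rngs = _session_streams(
            config.seed, 2 * config.cohort.n_pairs + config.cohort.n_singletons
        )
        subjects = simulate_cohort(spec, rng=cohort_rng)
        cohort_df = cohort_table(subjects)
        K = build_kinship(subjects)
        protocol = config.stimuli()

        rejection_log: List[Dict] = []
        rows = {}
        stage = "process"
        for subject, rng in zip(subjects, session_rngs):
            feats, logs, session = subject_features(
                subject, protocol, spec, rng, config.criteria()
            )
            rows[subject.subject_id] = feats
            for log in logs:
                log["subject_id"] = subject.subject_id
                rejection_log.append(log)
            if write_sessions and out is not None:
                ergio.write_session(session, out / "sessions")
        features = features_to_frame(rows)

        stage = "associate"
        params = [
            p
            for p in (*TABLE1_PARAMETERS, *CONE_PARAMETERS, *ROD_PARAMETERS)
            if p in features.columns
        ]
        association = association_scan(
            features,
            cohort_df,
            K,
            params,
            alpha=config.alpha,
            method=config.method,
            dosage_coding=config.dosage_coding,
            bh_correction=config.bh_correction,
        )
        dosages = cohort_df["dosage"]
        summary_standard = summarize_by_group(
            features[[p for p in TABLE1_PARAMETERS if p in features.columns]], dosages
        )
        summary_rod_cone = summarize_by_group(
            features[
                [p for p in (*CONE_PARAMETERS, *ROD_PARAMETERS) if p in features.columns]
            ],
            dosages,
        )

        stage = "lesion-demo"
        lesions: Dict[str, pd.DataFrame] = {}
        if config.lesion_demo:
            for lesion in ("crao", "ccsnb"):
                lesions[lesion] = lesion_comparison(lesion=lesion)

        stage = "report"
        if out is not None:
            ergio.write_table(cohort_df, out / "cohort.csv", provenance)
            ergio.write_kinship(
                K, list(cohort_df.index), out / "kinship.csv", provenance
            )
            ergio.write_table(features, out / "features.csv", provenance)
            ergio.write_table(
                summary_standard, out / "summary_standard.csv", provenance, index=False
            )
            ergio.write_table(
                summary_rod_cone, out / "summary_rod_cone.csv", provenance, index=False
            )
            ergio.write_table(
                association, out / "association.csv", provenance, index=False
            )
            for lesion, table in lesions.items():
                ergio.write_table(
                    table, out / f"lesion_{lesion}.csv", provenance, index=False
                )
            ergio.write_jsonl(rejection_log, out / "rejection_log.jsonl")
            if config.make_plots:
                plot_dosage_group_traces(subjects, "LA 3", out / "la3_by_dosage.png")
    except Exception as exc:
        if out is not None:
            (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"study failed in stage {stage!r}: {exc}") from exc

    return StudyReport(
        cohort=cohort_df,
        kinship=K,
        features=features,
        summary_standard=summary_standard,
        summary_rod_cone=summary_rod_cone,
        association=association,
        lesions=lesions,
        rejection_log=rejection_log,
        provenance=provenance,
    )


def plot_dosage_group_traces(
    subjects: Sequence[SubjectRecord],
    stimulus_label: str,
    out_png: Path,
) -> Path:
    """Advisory plot: noiseless group-average responses per dosage group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stim = protocol_by_label()[stimulus_label]
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {0: "k", 1: "tab:blue", 2: "tab:red"}
    for dosage in (0, 1, 2):
        group = [s for s in subjects if s.dosage == dosage and s.gains is not None]
        if not group:
            continue
        traces = [
            synthesize_flash_response(stim, s.gains).trace.volts for s in group
        ]
        t = synthesize_flash_response(stim, group[0].gains).trace.times
        ax.plot(
            t, np.mean(traces, axis=0), color=colors[dosage],
            label=f"dosage {dosage} (n={len(group)})",
        )
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("voltage (µV)")
    ax.set_title(f"{stimulus_label}: group-average noiseless response")
    ax.legend(frameon=False)
    fig.tight_layout()
    out_png = Path(out_png)
    out_png.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return out_png


def _version() -> str:
    from ergtwin import __version__

    return __version__
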