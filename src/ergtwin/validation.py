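"""Self-validation experiments for the pipeline.

Each function runs one end-to-end check of the package under its default
study conditions — subtraction-identity closure, mixed-model/oracle
agreement, type-I calibration, effect recovery, the cone/rod association
dissociation, lesion waveform ratios, generator calibration and run
determinism — and returns plain numbers.  The test suite asserts on these
numbers; the acceptance script reports them.

Problem sizes are chosen so that each experiment completes in seconds to
a few minutes while leaving Monte Carlo error well below the effects
being measured; where a reduced stimulus set suffices (the xenon
rod/cone-separation flashes), the full protocol is not simulated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ergtwin.association import (
    _kinship_eig,
    build_design,
    fit_lmm,
    gls_oracle,
)
from ergtwin.cohort import (
    CohortSpec,
    SubjectRecord,
    assign_gains,
    build_kinship,
    cohort_table,
    draw_genotypes,
    simulate_cohort,
)
from ergtwin.defaults import CALIBRATION_TARGETS, DEFAULT_GAINS
from ergtwin.forward_model import synthesize_flash_response
from ergtwin.processing import measure_b_wave
from ergtwin.protocols import protocol_by_label, xenon_pairs
from ergtwin.study import (
    StudyConfig,
    _session_streams,
    cohort_features,
    noiseless_features,
    run_study,
    subject_features,
)

__all__ = [
    "subtraction_identity_error",
    "lmm_oracle_comparison",
    "ols_reduction",
    "type1_calibration",
    "parameter_recovery",
    "dissociation_power",
    "lesion_ratios",
    "calibration_check",
    "determinism_check",
]


def _seed32(seed: int, offset: int = 0) -> int:
    return int(np.random.SeedSequence([seed, offset]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# waveform checks
# ---------------------------------------------------------------------------

def subtraction_identity_error(gains=DEFAULT_GAINS) -> float:
    """Max |dark - blue - rod components| (µV) over all xenon strengths.

    In idealized mode (complete rod suppression, cones unaffected by the
    blue background) the rod-isolation subtraction must recover the
    generator's rod component sub-traces sample for sample.
    """
    worst = 0.0
    for _, dark, blue in xenon_pairs():
        rd = synthesize_flash_response(dark, gains)
        rb = synthesize_flash_response(blue, gains)
        rod_truth = rd.components["rod_pr"].volts + rd.components["rod_on_bipolar"].volts
        err = np.abs(rd.trace.volts - rb.trace.volts - rod_truth).max()
        worst = max(worst, float(err))
    return worst


def lesion_ratios(gains=DEFAULT_GAINS) -> Dict[str, float]:
    """Noiseless lesioned/healthy amplitude ratios of the key parameters.

    CRAO (inner retina lost, photoreceptors intact): the rod-isolated
    a-wave is untouched while the cone-driven a-wave loses its
    postreceptoral (OFF) fraction.  cCSNB (ON-bipolar loss): the
    blue-background bright-flash b-wave collapses while the standard
    light-adapted flash keeps a clear (OFF-driven) b-wave.
    """
    by_label = protocol_by_label()
    healthy = noiseless_features(gains, "none")
    crao = noiseless_features(gains, "crao")
    ccsnb = noiseless_features(gains, "ccsnb")
    h67 = synthesize_flash_response(by_label["X67-blue"], gains).trace
    c67 = synthesize_flash_response(by_label["X67-blue"], gains, "ccsnb").trace
    return {
        "crao_rod67_a_ratio": crao["rod 67 a"] / healthy["rod 67 a"],
        "crao_cone67_a_ratio": crao["cone 67 a"] / healthy["cone 67 a"],
        "ccsnb_blue67_b_ratio": measure_b_wave(c67)[0] / measure_b_wave(h67)[0],
        "ccsnb_la3_b_ratio": ccsnb["LA 3 b"] / healthy["LA 3 b"],
    }


def calibration_check(gains=DEFAULT_GAINS) -> Dict[str, float]:
    """Noiseless baseline-subject amplitudes for the calibration targets."""
    feats = noiseless_features(gains)
    return {name: feats[name] for name in CALIBRATION_TARGETS}


# ---------------------------------------------------------------------------
# mixed-model checks
# ---------------------------------------------------------------------------

def _simulate_twin_outcome(
    K: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = K.shape[0]
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    u = L @ rng.normal(0.0, np.sqrt(sigma_g2), n) if sigma_g2 > 0 else 0.0
    return X @ beta + u + rng.normal(0.0, np.sqrt(sigma_e2), n)


def lmm_oracle_comparison(n_datasets: int = 20, seed: int = 0) -> Dict[str, float]:
    """Max relative differences between the spectral fit and the dense
    oracle in β, se and λ̂ over simulated twin datasets (n = 40–60)."""
    worst = {"beta": 0.0, "se": 0.0, "lambda": 0.0}
    for i in range(n_datasets):
        n_pairs = 20 + i % 11
        spec = CohortSpec(n_pairs=n_pairs, seed=None)
        subs = simulate_cohort(spec, rng=np.random.default_rng(_seed32(seed, i)))
        K = build_kinship(subs)
        X, names = build_design(cohort_table(subs))
        rng = np.random.default_rng(_seed32(seed, 1000 + i))
        beta = np.zeros(X.shape[1])
        beta[0], beta[names.index("dosage")] = 10.0, 0.5
        y = _simulate_twin_outcome(K, X, beta, 1.0, 1.0, rng)
        f1 = fit_lmm(y, X, K, names=names)
        f2 = gls_oracle(y, X, K, names=names)
        worst["beta"] = max(
            worst["beta"],
            float(np.max(np.abs(f1.beta - f2.beta) / np.maximum(np.abs(f2.beta), 1e-12))),
        )
        worst["se"] = max(worst["se"], float(np.max(np.abs(f1.se - f2.se) / f2.se)))
        worst["lambda"] = max(
            worst["lambda"], abs(f1.lam - f2.lam) / max(f2.lam, 1e-12)
        )
    return worst


def ols_reduction(n_subjects: int = 200, seed: int = 0) -> Dict[str, float]:
    """Null-relatedness reduction: with data simulated at σg² = 0 in an
    unrelated cohort (kinship = identity), the REML fit must reproduce the
    OLS closed form and park λ̂ at the grid lower bound.

    Also reports the median λ̂ on twin-structured σg² = 0 data, where the
    boundary estimate is reached only in distribution.
    """
    spec = CohortSpec(n_pairs=0, n_singletons=n_subjects, seed=None)
    subs = simulate_cohort(spec, rng=np.random.default_rng(_seed32(seed, 0)))
    K = build_kinship(subs)
    X, names = build_design(cohort_table(subs))
    rng = np.random.default_rng(_seed32(seed, 1))
    beta = np.zeros(X.shape[1])
    beta[0], beta[names.index("dosage")] = 10.0, 0.3
    y = _simulate_twin_outcome(K, X, beta, 0.0, 1.0, rng)
    fit = fit_lmm(y, X, K, names=names)
    b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    rel = float(np.max(np.abs(fit.beta - b_ols) / np.maximum(np.abs(b_ols), 1e-12)))

    twin_lams = []
    for i in range(10):
        tspec = CohortSpec(n_pairs=30, seed=None)
        tsubs = simulate_cohort(tspec, rng=np.random.default_rng(_seed32(seed, 100 + i)))
        tK = build_kinship(tsubs)
        tX, tnames = build_design(cohort_table(tsubs))
        trng = np.random.default_rng(_seed32(seed, 200 + i))
        ty = _simulate_twin_outcome(tK, tX, np.zeros(tX.shape[1]), 0.0, 1.0, trng)
        twin_lams.append(fit_lmm(ty, tX, tK, names=tnames).lam)
    return {
        "max_rel_diff": rel,
        "lambda_hat": fit.lam,
        "twin_lambda_median": float(np.median(twin_lams)),
    }


def type1_calibration(
    n_reps: int = 2000,
    n_pairs: int = 93,
    sigma_g2: float = 1.0,
    sigma_e2: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> Dict[str, float]:
    """Wald rejection rates under the null (zero dosage effect) on
    twin-structured data, for the kinship LMM and for naive OLS.

    The LMM should hold its nominal level; OLS, which ignores the family
    correlation of both outcome and genotype, should exceed it.
    """
    spec = CohortSpec(n_pairs=n_pairs, seed=None)
    subs = simulate_cohort(spec, rng=np.random.default_rng(_seed32(seed, 0)))
    K = build_kinship(subs)
    df = cohort_table(subs)
    eig = _kinship_eig(K)
    n = len(subs)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    rng = np.random.default_rng(_seed32(seed, 1))
    rej_lmm = rej_ols = 0
    for _ in range(n_reps):
        df2 = df.copy()
        df2["dosage"] = draw_genotypes(spec, rng)
        X, names = build_design(df2)
        y = L @ rng.normal(0.0, np.sqrt(sigma_g2), n) + rng.normal(
            0.0, np.sqrt(sigma_e2), n
        )
        fit = fit_lmm(y, X, eig=eig, names=names)
        rej_lmm += fit.p_wald < alpha
        # naive OLS Wald test on the same data
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ b
        s2 = float(r @ r) / (n - X.shape[1])
        cov = s2 * np.linalg.inv(X.T @ X)
        j = names.index("dosage")
        t = b[j] / np.sqrt(cov[j, j])
        rej_ols += 2.0 * stats.t.sf(abs(t), n - X.shape[1]) < alpha
    return {
        "lmm_rate": rej_lmm / n_reps,
        "ols_rate": rej_ols / n_reps,
        "n_reps": n_reps,
        "mc_sd": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
    }


# ---------------------------------------------------------------------------
# cohort-level effect checks (full trace pipeline)
# ---------------------------------------------------------------------------

def _xenon_protocol(strengths: Sequence[float]):
    by_label = protocol_by_label()
    out = []
    for s in strengths:
        tag = f"{s:g}"
        out.extend([by_label[f"X{tag}-dark"], by_label[f"X{tag}-blue"]])
    return out


def _recovery_spec() -> CohortSpec:
    # default study conditions, two sweeps per stimulus (replicate budget)
    return CohortSpec(seed=None, sweeps_per_stimulus=2)


def _truth_slope(
    spec: CohortSpec, parameter: str, n_per_dosage: int, seed: int
) -> Tuple[float, List[float]]:
    """Population slope of E[phenotype | dosage] under Hardy–Weinberg
    weights, from a large per-dosage Monte Carlo through the same
    session/measurement pipeline."""
    protocol = _xenon_protocol([67.0])
    rng = np.random.default_rng(_seed32(seed, 51))
    means, sems = [], []
    for d in (0, 1, 2):
        vals = []
        for i in range(n_per_dosage):
            s = SubjectRecord(
                f"T{d}_{i}", f"TF{d}_{i}", "singleton", spec.age_mean, "F", d
            )
            s.gains = assign_gains(d, spec, rng)
            feats, _, _ = subject_features(s, protocol, spec, rng)
            vals.append(feats[parameter])
        means.append(float(np.mean(vals)))
        sems.append(float(np.std(vals, ddof=1) / np.sqrt(n_per_dosage)))
    p = spec.risk_allele_frequency
    w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    d = np.array([0.0, 1.0, 2.0])
    m = np.array(means)
    dbar = float(w @ d)
    coef = w * (d - dbar) / float((w * (d - dbar) ** 2).sum())
    slope = float(coef @ (m - float(w @ m)))
    slope_sem = float(np.sqrt(((coef * np.array(sems)) ** 2).sum()))
    return slope, means, slope_sem


def parameter_recovery(
    n_cohorts: int = 200,
    n_truth: int = 1500,
    parameter: str = "cone 67 a",
    seed: int = 0,
) -> Dict[str, float]:
    """Bias and 95% CI coverage of the dosage effect on the cone-driven
    a-wave across replicate default cohorts (full trace pipeline)."""
    spec = _recovery_spec()
    truth, group_means, truth_sem = _truth_slope(spec, parameter, n_truth, seed)
    protocol = _xenon_protocol([67.0])
    betas, ses, dfs = [], [], []
    for b in range(n_cohorts):
        crng, srngs = _session_streams(_seed32(seed, 10_000 + b), 2 * spec.n_pairs)
        subs = simulate_cohort(spec, rng=crng)
        feats = cohort_features(subs, protocol, spec, srngs)
        X, names = build_design(cohort_table(subs))
        fit = fit_lmm(
            feats[parameter].to_numpy(), X, build_kinship(subs), names=names
        )
        j = names.index("dosage")
        betas.append(fit.beta[j])
        ses.append(fit.se[j])
        dfs.append(fit.df)
    betas, ses = np.array(betas), np.array(ses)
    tcrit = stats.t.ppf(0.975, np.array(dfs))
    coverage = float(
        np.mean((betas - tcrit * ses <= truth) & (truth <= betas + tcrit * ses))
    )
    sem = float(betas.std(ddof=1) / np.sqrt(n_cohorts))
    return {
        "mean_beta": float(betas.mean()),
        "sem": sem,
        "truth": truth,
        "truth_sem": truth_sem,
        "bias": float(betas.mean() - truth),
        "bias_tol": float(3.0 * np.hypot(sem, truth_sem)),
        "coverage": coverage,
        "group_means": group_means,
        "n_cohorts": n_cohorts,
    }


def dissociation_power(
    n_cohorts: int = 100,
    strengths: Sequence[float] = (13.0, 67.0),
    alpha: float = 0.05,
    seed: int = 0,
) -> Dict[str, float]:
    """Power to flag cone-driven a-waves versus the rejection rate on
    rod-isolated a-waves, with the dosage effect placed on the OFF-bipolar
    gain only (the emergent rod/cone dissociation)."""
    spec = _recovery_spec()
    protocol = _xenon_protocol(strengths)
    cone_params = [f"cone {s:g} a" for s in strengths]
    rod_params = [f"rod {s:g} a" for s in strengths]
    cone_hits = {p: 0 for p in cone_params}
    rod_hits = 0
    for b in range(n_cohorts):
        crng, srngs = _session_streams(_seed32(seed, 20_000 + b), 2 * spec.n_pairs)
        subs = simulate_cohort(spec, rng=crng)
        feats = cohort_features(subs, protocol, spec, srngs)
        df = cohort_table(subs)
        K = build_kinship(subs)
        eig = _kinship_eig(K)
        X, names = build_design(df)
        for p in cone_params + rod_params:
            fit = fit_lmm(feats[p].to_numpy(), X, eig=eig, names=names)
            if fit.p_wald < alpha:
                if p in cone_hits:
                    cone_hits[p] += 1
                else:
                    rod_hits += 1
    out = {f"power_{p}": cone_hits[p] / n_cohorts for p in cone_params}
    out["cone_power"] = cone_hits[cone_params[-1]] / n_cohorts
    out["rod_rate"] = rod_hits / (n_cohorts * len(rod_params))
    out["n_cohorts"] = n_cohorts
    return out


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def determinism_check(seed: int, workdir: Path, config: Optional[StudyConfig] = None) -> Dict[str, float]:
    """Run the whole study twice with one seed and compare output bytes."""
    import hashlib

    if config is None:
        config = StudyConfig(seed=seed)
    else:
        config = dataclasses.replace(config, seed=seed)
    workdir = Path(workdir)
    digests = []
    for run in ("run1", "run2"):
        out = workdir / run
        run_study(config, out_dir=out)
        h = hashlib.sha256()
        for path in sorted(out.glob("*.csv")):
            h.update(path.name.encode())
            h.update(path.read_bytes())
        digests.append(h.hexdigest())
    return {"identical": float(digests[0] == digests[1]), "digest": digests[0]}
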