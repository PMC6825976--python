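"""Synthetic input generator with planted ground truth.

Every pipeline stage is exercised against cohorts drawn from a
linear-Gaussian regulon model: each transcription factor (TF) has a latent
activity per sample, its targets follow ``sign * a * activity + noise``, and
background genes are independent standard normals.  Under this model the
behaviour of every downstream statistic has a closed form or a cheap
simulation oracle:

* the TF-target Pearson correlation is ``sign / sqrt(1 + sigma^2 / a^2)``,
* a disease shift ``delta`` on a TF's activity moves each target's expected
  log fold change by ``sign * a * delta``,
* a hazard coefficient ``beta`` on the latent activity yields a Cox model
  that is exactly proportional-hazards in the activity,
* a "reverter" drug profile is ``-c * signature + noise`` whose correlation
  with the disease signature is ``-c / sqrt(c^2 + 1)``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ExpressionMatrix

__all__ = [
    "SimParams",
    "GroundTruth",
    "PlantedTarget",
    "generate_reference_cohort",
    "generate_case_control",
    "generate_survival_cohort",
    "generate_drug_reference",
    "benchmark_params",
]

#: Coefficients of the synthetic clinical covariates used by survival cohorts.
STAGE_LEVELS = ("I", "II", "III")
STAGE_COEF = {"I": 0.0, "II": 0.4, "III": 0.8}
AGE_COEF = 0.02  # per year of age
AGE_MEAN, AGE_SD = 65.0, 8.0


@dataclass(frozen=True)
class PlantedTarget:
    """A single planted TF->target edge with its mode and coupling."""

    gene: str
    sign: int  # +1 or -1
    coupling: float  # a > 0


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic study bundle."""

    planted_regulons: dict[str, list[PlantedTarget]]
    disease_mrs: dict[str, int] = field(default_factory=dict)  # tf -> +-1 shift direction
    survival_mrs: dict[str, float] = field(default_factory=dict)  # tf -> hazard beta
    reverter_drugs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        tfs = set(self.planted_regulons)
        if not set(self.disease_mrs) <= tfs:
            raise ValueError("disease MRs must be a subset of planted TFs")
        if not set(self.survival_mrs) <= tfs:
            raise ValueError("survival MRs must be a subset of planted TFs")
        for tf, targets in self.planted_regulons.items():
            for t in targets:
                if t.coupling <= 0:
                    raise ValueError(f"coupling must be positive ({tf}->{t.gene})")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.planted_regulons)

    def target_signs(self, tf: str) -> dict[str, int]:
        return {t.gene: t.sign for t in self.planted_regulons[tf]}


@dataclass
class SimParams:
    """Tunable knobs of the generator; defaults are the benchmark conditions."""

    n_tfs: int = 50
    targets_per_tf: int = 20
    n_background_genes: int = 1000
    n_samples: int = 300  # reference-cohort size
    n_cases: int = 40  # per case-control study
    n_controls: int = 40
    n_studies: int = 13
    noise_sd: float = 0.5  # sigma on each planted target
    coupling: float = 1.0  # a
    disease_shift: float = 2.0  # delta on disease-MR activity
    frac_negative: float = 0.3  # fraction of negative-mode targets
    n_disease_mrs: int = 10
    n_survival_mrs: int = 3
    hazard_beta: float = 0.7
    baseline_hazard: float = 0.1  # lambda0, events per time unit
    censoring_rate: float = 0.3
    n_survival_samples: int = 300
    n_drugs: int = 100
    n_reverters: int = 3
    reverter_strength: float = 2.0  # c
    seed: int = 20190910

    def __post_init__(self) -> None:
        counts = (
            self.n_tfs, self.targets_per_tf, self.n_background_genes,
            self.n_samples, self.n_cases, self.n_controls, self.n_studies,
            self.n_survival_samples, self.n_drugs,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.frac_negative <= 1.0:
            raise ValueError("frac_negative must lie in [0, 1]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


def benchmark_params(preset: str = "network", seed: int = 20190910) -> SimParams:
    """Named study conditions.

    ``network``
        50 TFs x 20 targets + 1000 background genes, n=300: the
        network-recovery benchmark.
    ``mra``
        55 targets per TF so every planted regulon clears the size->50
        consensus filter; used by the MR/survival/CMap benchmarks.
    """
    if preset == "network":
        return SimParams(seed=seed)
    if preset == "mra":
        return SimParams(targets_per_tf=55, seed=seed)
    raise ValueError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# reference cohort


def _plant_truth(p: SimParams, rng: np.random.Generator) -> GroundTruth:
    regulons: dict[str, list[PlantedTarget]] = {}
    for i in range(p.n_tfs):
        tf = f"TF{i:03d}"
        targets = []
        for j in range(p.targets_per_tf):
            sign = -1 if rng.random() < p.frac_negative else 1
            targets.append(PlantedTarget(f"T{i:03d}_{j:03d}", sign, p.coupling))
        regulons[tf] = targets
    tfs = list(regulons)
    disease = rng.choice(tfs, size=min(p.n_disease_mrs, p.n_tfs), replace=False)
    disease_mrs = {tf: (1 if rng.random() < 0.5 else -1) for tf in sorted(disease)}
    survival = rng.choice(sorted(disease), size=min(p.n_survival_mrs, len(disease)),
                          replace=False)
    survival_mrs = {tf: p.hazard_beta for tf in sorted(survival)}
    return GroundTruth(regulons, disease_mrs, survival_mrs)


def _expression_from_activity(
    p: SimParams,
    truth: GroundTruth,
    activity: dict[str, np.ndarray],
    n: int,
    rng: np.random.Generator,
    sample_prefix: str,
) -> ExpressionMatrix:
    """Assemble a gene-by-sample matrix given per-TF latent activities."""
    genes: list[str] = []
    rows: list[np.ndarray] = []
    for tf, targets in truth.planted_regulons.items():
        act = activity[tf]
        genes.append(tf)
        rows.append(act)  # observed TF expression tracks its activity
        for t in targets:
            genes.append(t.gene)
            rows.append(t.sign * t.coupling * act + rng.normal(0.0, p.noise_sd, n))
    for b in range(p.n_background_genes):
        genes.append(f"BG{b:04d}")
    rows.append(rng.normal(0.0, 1.0, (p.n_background_genes, n)))
    values = np.vstack([np.atleast_2d(r) for r in rows])
    samples = [f"{sample_prefix}{i:04d}" for i in range(n)]
    return ExpressionMatrix(genes, samples, values)


def generate_reference_cohort(
    p: SimParams, truth: GroundTruth | None = None, cohort_id: str = "REF1"
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Healthy-tissue cohort used to infer the reference network.

    TF activity is iid standard normal per sample, targets follow the
    linear-Gaussian coupling, and background genes are independent noise.
    Pass an existing ``truth`` to draw a second cohort from the same planted
    network (dual reference networks share their ground truth).
    """
    total = p.n_tfs * (1 + p.targets_per_tf) + p.n_background_genes
    if total > 5000:
        warnings.warn(f"{total} genes exceeds the desk-scale guard (~5000)",
                      stacklevel=2)
    rng = np.random.default_rng([p.seed, _cohort_stream(cohort_id)])
    if truth is None:
        truth = _plant_truth(p, np.random.default_rng([p.seed, 0]))
    activity = {tf: rng.normal(0.0, 1.0, p.n_samples) for tf in truth.tf_ids}
    expr = _expression_from_activity(p, truth, activity, p.n_samples, rng,
                                     f"{cohort_id}_S")
    return expr, truth


def _cohort_stream(cohort_id: str) -> int:
    # Stable stream index per cohort label, independent of call order.
    return int.from_bytes(cohort_id.encode()[:8].ljust(8, b"\0"), "big") % (2**31)


# ---------------------------------------------------------------------------
# case-control studies


def generate_case_control(
    p: SimParams, truth: GroundTruth
) -> list[ExpressionMatrix]:
    """One labelled tumour/normal matrix per study.

    Controls follow the reference model.  In cases, each disease MR's
    activity is drawn ``Normal(+-delta, 1)`` so its targets shift by
    ``sign * a * (+-delta)`` in expectation; everything else is redrawn
    independently per study.
    """
    if p.disease_shift == 0 and truth.disease_mrs:
        warnings.warn("disease_shift is 0: planted disease MRs are undetectable",
                      stacklevel=2)
    studies = []
    for s in range(p.n_studies):
        rng = np.random.default_rng([p.seed, 1000 + s])
        n = p.n_controls + p.n_cases
        activity = {}
        for tf in truth.tf_ids:
            act = rng.normal(0.0, 1.0, n)
            if tf in truth.disease_mrs:
                act[p.n_controls:] += truth.disease_mrs[tf] * p.disease_shift
            activity[tf] = act
        expr = _expression_from_activity(p, truth, activity, n, rng,
                                         f"CC{s:02d}_S")
        expr.sample_groups = ["normal"] * p.n_controls + ["tumor"] * p.n_cases
        studies.append(expr)
    return studies


# ---------------------------------------------------------------------------
# survival cohorts


def generate_survival_cohort(
    p: SimParams, truth: GroundTruth, study_index: int = 0
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression plus clinical table whose hazard depends on planted activity.

    Event times are exponential with rate
    ``lambda0 * exp(beta*z + stage + age)`` where ``z`` is the latent
    activity of each survival MR; censoring is an independent exponential
    whose rate is tuned so the expected censored fraction equals
    ``censoring_rate``.  Two synthetic covariates (categorical ``stage``,
    real ``age``) carry known coefficients.
    """
    if p.censoring_rate >= 0.95:
        raise ValueError("censoring_rate >= 0.95 yields an uninformative cohort")
    rng = np.random.default_rng([p.seed, 2000 + study_index])
    n = p.n_survival_samples
    activity = {tf: rng.normal(0.0, 1.0, n) for tf in truth.tf_ids}
    expr = _expression_from_activity(p, truth, activity, n, rng,
                                     f"SV{study_index:02d}_S")

    stage = rng.choice(STAGE_LEVELS, size=n, p=[0.5, 0.3, 0.2])
    age = rng.normal(AGE_MEAN, AGE_SD, n)
    log_hr = np.zeros(n)
    for tf, beta in truth.survival_mrs.items():
        log_hr += beta * activity[tf]
    log_hr += np.vectorize(STAGE_COEF.get)(stage) + AGE_COEF * (age - AGE_MEAN)
    rate = p.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / rate)

    if p.censoring_rate > 0:
        lam_c = _censoring_rate_for(rate, p.censoring_rate)
        cens_time = rng.exponential(1.0 / lam_c, n)
    else:
        cens_time = np.full(n, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    clinical = pd.DataFrame({
        "sample_id": expr.sample_ids,
        "time": time,
        "event": event,
        "stage": stage,
        "age": age,
    })
    return expr, clinical


def _censoring_rate_for(event_rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving an expected censored fraction.

    For exponential event rate ``r`` and censoring rate ``c`` the censoring
    probability is ``c / (c + r)``; solve the cohort average for ``c``.
    """
    def frac(c: float) -> float:
        return float(np.mean(c / (c + event_rates))) - target

    hi = 10.0 * float(np.max(event_rates))
    while frac(hi) < 0:
        hi *= 10.0
    return brentq(frac, 1e-12, hi)


# ---------------------------------------------------------------------------
# drug-perturbation reference


def generate_drug_reference(
    p: SimParams, disease_signature: pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Drug-by-gene perturbation statistics with planted reverters.

    Non-reverters are iid standard normal per gene; each reverter is
    ``-c * signature + Normal(0, 1)`` so it anti-correlates with the disease
    signature (population r = ``-c / sqrt(c^2 + 1)`` for a unit-variance
    signature).
    """
    if p.n_reverters >= p.n_drugs:
        raise ValueError("n_reverters must be smaller than n_drugs")
    rng = np.random.default_rng([p.seed, 3000])
    genes = list(disease_signature.index)
    sig = disease_signature.to_numpy(dtype=float)
    drugs = [f"DRUG{i:03d}" for i in range(p.n_drugs)]
    reverters = sorted(rng.choice(drugs, size=p.n_reverters, replace=False))
    mat = rng.normal(0.0, 1.0, (p.n_drugs, len(genes)))
    for d in reverters:
        i = drugs.index(d)
        mat[i] = -p.reverter_strength * sig + rng.normal(0.0, 1.0, len(genes))
    ref = pd.DataFrame(mat, index=pd.Index(drugs, name="drug"), columns=genes)
    return ref, list(reverters)


# ---------------------------------------------------------------------------
# on-disk benchmark bundle


def write_bundle(p: SimParams, outdir, n_reference: int = 2,
                 n_survival_studies: int = 2):
    """Write a complete input bundle (expression, labels, clinical, drugs,
    truth JSON) plus a ready-to-run pipeline config under ``outdir``.

    Returns the PipelineConfig.  The disease signature used to plant
    reverters is the expected log fold change of every gene under the
    generator model (sign * a * delta for disease-MR targets, 0 elsewhere).
    """
    import json
    from pathlib import Path

    from .config import CohortSpec, PipelineConfig, SurvivalSpec
    from .io import write_clinical, write_expression

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ref_specs = []
    truth = None
    for i in range(n_reference):
        expr, truth = generate_reference_cohort(p, truth, cohort_id=f"REF{i+1}")
        path = outdir / f"reference_{i+1}.tsv"
        write_expression(expr, path)
        ref_specs.append(CohortSpec(id=f"TN{i+1}", expression=str(path)))

    tf_path = outdir / "tfs.txt"
    tf_path.write_text("\n".join(truth.tf_ids) + "\n")

    cc_specs = []
    for s, expr in enumerate(generate_case_control(p, truth)):
        epath = outdir / f"cc_{s:02d}.tsv"
        lpath = outdir / f"cc_{s:02d}_labels.tsv"
        write_expression(expr, epath)
        pd.DataFrame({"sample_id": expr.sample_ids,
                      "group": expr.sample_groups}).to_csv(
            lpath, sep="\t", index=False)
        cc_specs.append(CohortSpec(id=f"CC{s:02d}", expression=str(epath),
                                   labels=str(lpath)))

    sv_specs = []
    for s in range(n_survival_studies):
        expr, clin = generate_survival_cohort(p, truth, study_index=s)
        epath = outdir / f"sv_{s:02d}.tsv"
        cpath = outdir / f"sv_{s:02d}_clinical.tsv"
        write_expression(expr, epath)
        write_clinical(clin, cpath)
        sv_specs.append(SurvivalSpec(id=f"SV{s:02d}", expression=str(epath),
                                     clinical=str(cpath)))

    signature = expected_signature(p, truth)
    drug_ref, reverters = generate_drug_reference(p, signature)
    truth.reverter_drugs = reverters
    drug_path = outdir / "drug_reference.tsv"
    drug_ref.to_csv(drug_path, sep="\t")

    with open(outdir / "truth.json", "w") as fh:
        json.dump({
            "planted_regulons": {
                tf: [[t.gene, t.sign, t.coupling] for t in targets]
                for tf, targets in truth.planted_regulons.items()},
            "disease_mrs": truth.disease_mrs,
            "survival_mrs": truth.survival_mrs,
            "reverter_drugs": truth.reverter_drugs,
        }, fh, indent=2, sort_keys=True)

    config = PipelineConfig(
        reference_cohorts=ref_specs, case_control=cc_specs, tfs=str(tf_path),
        outdir=str(outdir / "results"), survival=sv_specs,
        drug_reference=str(drug_path), seed=p.seed,
    )
    config.to_yaml(outdir / "config.yaml")
    return config


def expected_signature(p: SimParams, truth: GroundTruth) -> pd.Series:
    """Population case-control log fold change of every generated gene."""
    sig = {}
    for tf, targets in truth.planted_regulons.items():
        shift = truth.disease_mrs.get(tf, 0) * p.disease_shift
        sig[tf] = float(shift)
        for t in targets:
            sig[t.gene] = float(t.sign * t.coupling * shift)
    for b in range(p.n_background_genes):
        sig[f"BG{b:04d}"] = 0.0
    return pd.Series(sig)
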