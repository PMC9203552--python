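"""Synthetic cohort generation with planted ground truth.

Every downstream stage of the pipeline is exercised on cohorts produced
here: subjects carry FC panels for two scan sessions, clinical metrics,
demographic covariates, genotypes with twin relatedness, and split
labels (train / validation / replication) with matched case fractions.

The generative model is a latent-severity construction.  Each subject
has one latent liability per biotype, i.i.d. standard normal; a causal
SNP adds ``causal_beta`` per minor allele to the causal biotype's
liability.  Within each split the subjects with the largest maximal
liability become cases (at ``am_fraction``), each labelled with the
arg-max biotype; that subject's own-biotype liability is its severity.
Signal FC features (a disjoint index set per biotype, with alternating
effect signs so the biotypes have genuinely distinct signatures) and the
clinical metrics are noisy monotone functions of severity, which
produces the Spearman structure the screening stage looks for without
committing to marginals real data never pins down.  FC noise lives on
the Fisher-z scale and is mapped back through tanh so correlations stay
in (-1, 1); scan 2 adds independent z-scale noise to scan 1.

Genotypes are drawn allele-wise at per-SNP minor allele frequencies
(hence in Hardy-Weinberg equilibrium); monozygotic twins duplicate
genotypes and dizygotic twins are produced by gene dropping from
simulated parents, giving expected GRM entries near 1 and 0.5.

Default sizes are scaled down from the motivating study design for
desk-scale runs; study-scale sizes are one config away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from biotypeflow.motion import MotionTrace, TimeSeriesPanel, n_fc_features
from biotypeflow.screening import ALCOHOL_METRICS, ASR_SCORES

FREQUENCY_METRICS = ("12Frq", "12Frq5plus", "HvyFrq", "HvyFrq5plus")
POPULATIONS = ("EA", "AA", "OTHER")
POPULATION_WEIGHTS = (0.74, 0.14, 0.12)


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the generator; identical configs give identical cohorts."""

    n_train: int = 300
    n_validation: int = 74
    n_replication: int = 74
    am_fraction: float = 0.33
    n_roi: int = 268
    n_biotypes: int = 3
    n_signal_fc: int = 30          # signal features per biotype (disjoint sets)
    effect_size: float = 1.0       # standardized z-scale mean shift per signal feature
    n_snps: int = 500
    causal_maf: float = 0.3
    causal_beta: float = 0.5       # liability units per minor allele
    mz_pairs: int = 10
    dz_pairs: int = 10
    fc_noise_sd: float = 0.3       # subject-level z-scale noise
    scan2_noise_sd: float = 0.15   # extra z-scale noise on the second scan
    severity_slope: float = 0.3    # severity modulation of the signal shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roi < 3:
            raise ValueError("n_roi must be at least 3")
        if not 0.0 < self.am_fraction < 1.0:
            raise ValueError("am_fraction must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not 0.05 <= self.causal_maf <= 0.5:
            raise ValueError("causal_maf must lie in [0.05, 0.5]")
        if self.n_signal_fc * self.n_biotypes > n_fc_features(self.n_roi):
            raise ValueError(
                "n_signal_fc x n_biotypes exceeds the FC panel width "
                f"{n_fc_features(self.n_roi)}"
            )
        needed = 2 * (self.mz_pairs + self.dz_pairs)
        if needed > self.n_subjects:
            raise ValueError("more twin-pair members than subjects")

    @property
    def n_subjects(self) -> int:
        return self.n_train + self.n_validation + self.n_replication

    @property
    def n_fc(self) -> int:
        return n_fc_features(self.n_roi)


@dataclass
class GroundTruth:
    """Planted structure for parameter-recovery tests.

    ``biotype_label`` is 0 for controls and 1..B for cases;
    ``biotype_liability`` holds every subject's latent liability per
    biotype (severity of case subjects is their own-biotype entry).
    """

    biotype_label: np.ndarray
    biotype_liability: np.ndarray
    signal_fc_indices: dict[int, np.ndarray]
    causal_snp_index: int
    causal_biotype: int
    kinship_pairs: list[tuple[int, int, str]]
    effect_signs: dict[int, float] = field(default_factory=dict)


@dataclass
class Cohort:
    """Everything the pipeline consumes, plus the ground truth."""

    subjects: pd.DataFrame
    fc_scan1: np.ndarray
    fc_scan2: np.ndarray
    genotypes: "object"  # GenotypePanel; typed loosely to avoid a cycle
    truth: GroundTruth
    config: CohortConfig

    def split_mask(self, split: str) -> np.ndarray:
        return (self.subjects["split"] == split).to_numpy()

    def am_mask(self) -> np.ndarray:
        return (self.subjects["group"] == "AM").to_numpy()


def _draw_genotypes(cfg: CohortConfig, rng: np.random.Generator):
    """HWE allele-wise genotypes with MZ duplication and DZ gene dropping."""
    from biotypeflow.genetics import GenotypePanel

    n, m = cfg.n_subjects, cfg.n_snps
    mafs = rng.uniform(0.05, 0.5, size=m)
    causal_idx = int(rng.integers(m))
    mafs[causal_idx] = cfg.causal_maf

    # twin pairs occupy the first 2*(mz+dz) subject slots, then are shuffled
    order = rng.permutation(n)
    pairs: list[tuple[int, int, str]] = []
    cursor = 0
    for _ in range(cfg.mz_pairs):
        pairs.append((int(order[cursor]), int(order[cursor + 1]), "MZ"))
        cursor += 2
    for _ in range(cfg.dz_pairs):
        pairs.append((int(order[cursor]), int(order[cursor + 1]), "DZ"))
        cursor += 2

    alleles = (rng.random((n, m)) < mafs) * 1 + (rng.random((n, m)) < mafs) * 1
    dosages = alleles.astype(float)
    for a, b, kind in pairs:
        if kind == "MZ":
            dosages[b] = dosages[a]
        else:  # gene dropping: both children sample one allele per parent
            mother = np.column_stack(
                [(rng.random(m) < mafs) * 1, (rng.random(m) < mafs) * 1]
            )
            father = np.column_stack(
                [(rng.random(m) < mafs) * 1, (rng.random(m) < mafs) * 1]
            )
            for child in (a, b):
                mi = rng.integers(0, 2, size=m)
                fi = rng.integers(0, 2, size=m)
                dosages[child] = mother[np.arange(m), mi] + father[np.arange(m), fi]

    chrom = np.where(np.arange(m) < m // 2, "1", "2")
    pos = np.concatenate(
        [np.arange(1, m // 2 + 1) * 1000, np.arange(1, m - m // 2 + 1) * 1000]
    )
    populations = rng.choice(POPULATIONS, size=n, p=POPULATION_WEIGHTS)
    panel = GenotypePanel(
        dosages=dosages,
        snp_ids=np.array([f"rs{900000 + j}" for j in range(m)]),
        chrom=chrom,
        pos=pos,
        populations=populations,
        subject_ids=np.array([f"S{i:05d}" for i in range(n)]),
    )
    return panel, causal_idx, pairs


def _assign_cases(
    cfg: CohortConfig, split: np.ndarray, liability: np.ndarray
) -> np.ndarray:
    """Per split, the subjects with the largest max-liability become cases."""
    label = np.zeros(len(split), dtype=int)
    top = liability.max(axis=1)
    for s in ("train", "validation", "replication"):
        idx = np.flatnonzero(split == s)
        n_am = int(round(cfg.am_fraction * len(idx)))
        chosen = idx[np.argsort(top[idx])[::-1][:n_am]]
        label[chosen] = liability[chosen].argmax(axis=1) + 1
    return label


def _severity(label: np.ndarray, liability: np.ndarray, b: int) -> np.ndarray:
    """Standardized own-biotype liability of biotype-b cases."""
    members = label == b
    sev = liability[members, b - 1]
    if sev.std() > 0:
        sev = (sev - sev.mean()) / sev.std()
    else:
        sev = sev - sev.mean()
    return sev


def _clinical_metrics(
    cfg: CohortConfig,
    label: np.ndarray,
    liability: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Alcohol-use severities (0-5 scale) and ASR-like psychiatric scores.

    Frequency-of-drinking metrics order biotype 3 > biotype 1 > biotype
    2 among cases; the antisocial score is elevated in biotype 2 —
    mirroring the moderate / mild / comorbid pattern the biotypes are
    meant to emulate.  All metrics of a case are monotone in the
    subject's severity.
    """
    n = len(label)
    am = label > 0
    data: dict[str, np.ndarray] = {}
    sev = np.zeros(n)
    for b in range(1, cfg.n_biotypes + 1):
        sev[label == b] = _severity(label, liability, b)

    freq_offsets = {1: 0.5, 2: 0.0, 3: 1.0}  # biotype3 > biotype1 > biotype2
    for name in ALCOHOL_METRICS:
        base = rng.uniform(1.0, 1.6)
        vals = base + 0.35 * rng.standard_normal(n)
        boost = np.where(am, 1.0, 0.0).astype(float)
        if name in FREQUENCY_METRICS:
            for b in range(1, min(cfg.n_biotypes, 3) + 1):
                boost[label == b] += freq_offsets.get(b, 0.0)
        vals = vals + boost + 0.6 * sev
        data[name] = np.clip(vals, 0.0, 5.0)

    for name in ASR_SCORES:
        vals = 48.0 + 8.0 * rng.standard_normal(n) + np.where(am, 1.0, 0.0)
        if name == "Antisocial" and cfg.n_biotypes >= 2:
            vals = vals + np.where(label == 2, 6.0, 0.0)
        vals = vals + 2.0 * sev
        data[name] = vals
    return pd.DataFrame(data)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one complete cohort; bit-identical under the same config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    split = np.array(
        ["train"] * cfg.n_train
        + ["validation"] * cfg.n_validation
        + ["replication"] * cfg.n_replication
    )
    split = split[rng.permutation(n)]

    genotypes, causal_idx, pairs = _draw_genotypes(cfg, rng)

    liability = rng.standard_normal((n, cfg.n_biotypes))
    causal_biotype = int(rng.integers(1, cfg.n_biotypes + 1))
    # centred dosage: the SNP perturbs liability without inflating the
    # causal biotype's prevalence in the arg-max case assignment
    dosage = genotypes.dosages[:, causal_idx]
    liability[:, causal_biotype - 1] += cfg.causal_beta * (dosage - dosage.mean())

    label = _assign_cases(cfg, split, liability)

    # disjoint signal feature sets, alternating effect signs per biotype
    all_signal = rng.choice(cfg.n_fc, size=cfg.n_signal_fc * cfg.n_biotypes, replace=False)
    signal_idx = {
        b: np.sort(all_signal[(b - 1) * cfg.n_signal_fc : b * cfg.n_signal_fc])
        for b in range(1, cfg.n_biotypes + 1)
    }
    signs = {b: 1.0 if b % 2 else -1.0 for b in range(1, cfg.n_biotypes + 1)}

    feature_means = rng.normal(0.0, 0.25, size=cfg.n_fc)
    z1 = feature_means[None, :] + cfg.fc_noise_sd * rng.standard_normal((n, cfg.n_fc))
    for b in range(1, cfg.n_biotypes + 1):
        members = label == b
        if members.sum() == 0:
            continue
        sev = _severity(label, liability, b)
        shift = cfg.effect_size * cfg.fc_noise_sd * (1.0 + cfg.severity_slope * sev)
        z1[np.ix_(members, signal_idx[b])] += signs[b] * shift[:, None]
    z2 = z1 + cfg.scan2_noise_sd * rng.standard_normal((n, cfg.n_fc))
    fc_scan1 = np.tanh(z1)
    fc_scan2 = np.tanh(z2)

    metrics = _clinical_metrics(cfg, label, liability, rng)
    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "split": split,
            "group": np.where(label > 0, "AM", "control"),
            "age": rng.integers(22, 37, size=n),
            "sex": rng.integers(0, 2, size=n),
            "race": genotypes.populations,
            "censored_frames": rng.poisson(100.0, size=n),
        }
    )
    subjects = pd.concat([subjects, metrics], axis=1)

    truth = GroundTruth(
        biotype_label=label,
        biotype_liability=liability,
        signal_fc_indices=signal_idx,
        causal_snp_index=causal_idx,
        causal_biotype=causal_biotype,
        kinship_pairs=pairs,
        effect_signs=signs,
    )
    return Cohort(
        subjects=subjects,
        fc_scan1=fc_scan1,
        fc_scan2=fc_scan2,
        genotypes=genotypes,
        truth=truth,
        config=cfg,
    )


def generate_motion_and_bold(
    n_frames: int,
    outlier_times: list[int] | np.ndarray = (),
    tr: float = 0.72,
    n_units: int = 20,
    seed: int = 0,
    motion_step_mm: float = 0.3,
    bold_step: float = 150.0,
) -> tuple[MotionTrace, TimeSeriesPanel]:
    """Smooth motion and BOLD series with planted outlier frames.

    The baseline trace keeps per-frame FD well below the 0.2 mm
    threshold; at each requested outlier time a persistent translation
    step of ``motion_step_mm`` raises FD above threshold at exactly that
    frame, and a matching persistent intensity step in every unit spikes
    DVARS there too.
    """
    outlier_times = np.asarray(outlier_times, dtype=int)
    if len(outlier_times) and (
        outlier_times.min() < 0 or outlier_times.max() >= n_frames
    ):
        raise ValueError("outlier times must lie within [0, n_frames)")
    rng = np.random.default_rng(seed)
    # per-frame parameter increments small enough that baseline FD < 0.05 mm
    trans = np.cumsum(rng.uniform(-0.01, 0.01, size=(n_frames, 3)), axis=0)
    rots = np.cumsum(rng.uniform(-1e-4, 1e-4, size=(n_frames, 3)), axis=0)
    sign = 1.0
    for t in outlier_times:
        trans[t:, 0] += sign * motion_step_mm
        sign = -sign
    trace = MotionTrace(
        dx=trans[:, 0], dy=trans[:, 1], dz=trans[:, 2],
        alpha=rots[:, 0], beta=rots[:, 1], gamma=rots[:, 2], tr=tr,
    )

    time = np.arange(n_frames) * tr
    freqs = rng.uniform(0.01, 0.07, size=n_units)
    phases = rng.uniform(0, 2 * np.pi, size=n_units)
    bold = 10.0 * np.sin(2 * np.pi * time[:, None] * freqs + phases)
    bold += 5.0 * rng.standard_normal((n_frames, n_units))
    sign = 1.0
    for t in outlier_times:
        bold[t:, :] += sign * bold_step
        sign = -sign
    return trace, TimeSeriesPanel(data=bold, tr=tr)
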