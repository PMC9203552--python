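"""Quantitative-trait genetic association with relatedness correction.

The classifier's biotype membership scores (and the overall case score)
are treated as quantitative traits.  SNPs pass quality control (call
rate >= 0.95, exact Hardy-Weinberg p >= 1e-7, minor allele frequency
>= 0.05 in every population), relatedness is captured by a genetic
relationship matrix (GRM) from standardized genome-wide dosages, and
each SNP is tested with the linear mixed model

    y = W a + x b + u + e,   u ~ N(0, sg^2 K),  e ~ N(0, se^2 I),

where W holds the age/sex/race covariates and K is the GRM.  The
variance ratio lambda = sg^2/se^2 is profiled by REML through a single
eigendecomposition of K that is reused across SNPs; significance is the
Wald chi-square test of b.  Because a plain Bonferroni correction
overcounts tests among SNPs in linkage disequilibrium, the effective
number of independent tests m counts one SNP per LD block plus every
SNP outside a block, and the significance threshold is alpha/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# genotype container
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Subjects x SNPs minor-allele dosages with SNP and subject metadata.

    ``dosages`` is float with values in {0, 1, 2} or NaN for missing.
    ``populations`` labels each subject's population for per-population
    MAF filtering.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    populations: np.ndarray
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos)
        self.populations = np.asarray(self.populations)
        n, m = self.dosages.shape
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos) == m):
            raise ValueError("SNP metadata length does not match dosage columns")
        if len(self.populations) != n:
            raise ValueError("population labels must match subject rows")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(
            dosages=self.dosages[:, mask],
            snp_ids=self.snp_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            populations=self.populations,
            subject_ids=self.subject_ids,
        )

    def subset_subjects(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(
            dosages=self.dosages[mask],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            populations=self.populations[mask],
            subject_ids=None if self.subject_ids is None else self.subject_ids[mask],
        )


# ---------------------------------------------------------------------------
# QC primitives
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(
    n_het: int, n_hom_rare: int, n_hom_common: int, midp: bool = False
) -> float:
    """Exact Hardy-Weinberg test p-value by heterozygote enumeration.

    Conditional on allele counts, enumerates every possible heterozygote
    count and accumulates probabilities no larger than the observed
    configuration's (two-sided exact test).  ``midp=True`` counts the
    observed configuration at half weight — the mid-p variant whose null
    distribution is closer to uniform, appropriate for calibration
    checks; QC filtering uses the conservative exact p.
    """
    if min(n_het, n_hom_rare, n_hom_common) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * n_hom_rare + n_het
    if rare > n:  # ensure 'rare' really is the minor allele
        rare = 2 * n - rare
    # heterozygote count shares the parity of the rare-allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    # unnormalized log-probabilities of each heterozygote count
    from scipy.special import gammaln

    hom_r = (rare - het_values) // 2
    hom_c = n - het_values - hom_r
    logp = (
        het_values * np.log(2.0)
        - gammaln(hom_r + 1)
        - gammaln(het_values + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    # the heterozygote count is invariant under allele relabelling
    p_obs = probs[het_values == n_het]
    if len(p_obs) == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    at_most = probs <= p_obs[0] * (1 + 1e-12)
    if midp:
        strictly_below = probs < p_obs[0] * (1 - 1e-12)
        return float(min(1.0, probs[strictly_below].sum()
                         + 0.5 * probs[at_most & ~strictly_below].sum()))
    return float(min(1.0, probs[at_most].sum()))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(het, hom-minor, hom-major) counts of one SNP, ignoring missing."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 1).sum()), int((d == 2).sum()), int((d == 0).sum())


def maf(dosages: np.ndarray, population_mask: np.ndarray | None = None) -> float:
    """Folded minor allele frequency (<= 0.5) over non-missing subjects."""
    d = np.asarray(dosages, dtype=float)
    if population_mask is not None:
        d = d[np.asarray(population_mask, dtype=bool)]
    d = d[~np.isnan(d)]
    if len(d) == 0:
        return float("nan")
    freq = d.sum() / (2.0 * len(d))
    return float(min(freq, 1.0 - freq))


def snp_qc(
    panel: GenotypePanel,
    call_rate_min: float = 0.95,
    hwe_min: float = 1e-7,
    maf_min: float = 0.05,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Apply the three QC rules; return the retained panel and per-SNP flags.

    A SNP is retained iff call rate >= ``call_rate_min``, exact HWE p
    (pooled across the tested sample) >= ``hwe_min``, and MAF >=
    ``maf_min`` in *every* population present.  Flags record which rule
    failed; the rules commute, so application order is irrelevant.
    """
    d = panel.dosages
    n = panel.n_subjects
    call_rate = 1.0 - np.isnan(d).mean(axis=0)
    pass_call = call_rate >= call_rate_min

    hwe_p = np.empty(panel.n_snps)
    for j in range(panel.n_snps):
        het, hom_r, hom_c = genotype_counts(d[:, j])
        hwe_p[j] = hwe_exact_pvalue(het, hom_r, hom_c)
    pass_hwe = hwe_p >= hwe_min

    pops = np.unique(panel.populations)
    pop_mafs = {
        pop: np.array([maf(d[:, j], panel.populations == pop) for j in range(panel.n_snps)])
        for pop in pops
    }
    pass_maf = np.ones(panel.n_snps, dtype=bool)
    for pop in pops:
        pass_maf &= pop_mafs[pop] >= maf_min

    retained = pass_call & pass_hwe & pass_maf
    flags = pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "pass_call_rate": pass_call,
            "pass_hwe": pass_hwe,
            "pass_maf": pass_maf,
            "retained": retained,
            **{f"maf_{pop}": pop_mafs[pop] for pop in pops},
        }
    )
    if not retained.any():
        raise ValueError(
            "all SNPs removed by QC "
            f"(call-rate fails: {int((~pass_call).sum())}, "
            f"HWE fails: {int((~pass_hwe).sum())}, MAF fails: {int((~pass_maf).sum())})"
        )
    return panel.subset_snps(retained), flags


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def _impute_standardize(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages and standardize by sqrt(2 p (1-p))."""
    d = np.array(dosages, dtype=float)
    means = np.nanmean(d, axis=0)
    nan_mask = np.isnan(d)
    d[nan_mask] = np.take(means, np.nonzero(nan_mask)[1])
    p = means / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic SNP(s) skipped in standardization",
            stacklevel=3,
        )
    z = (d[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    return z


def compute_grm(panel: GenotypePanel) -> np.ndarray:
    """Genetic relationship matrix K = Z Z' / m from standardized dosages."""
    if panel.n_snps < 50:
        warnings.warn(
            f"GRM from only {panel.n_snps} SNPs; relatedness estimates are noisy",
            stacklevel=2,
        )
    z = _impute_standardize(panel.dosages)
    if z.shape[1] == 0:
        raise ValueError("no polymorphic SNPs available for the GRM")
    return z @ z.T / z.shape[1]


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

def build_covariates(
    age: np.ndarray, sex: np.ndarray, race: np.ndarray | None = None
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) of age, sex and race indicators.

    Race is coded as indicator columns against the first (reference)
    population in sorted order.
    """
    cols = [np.ones(len(age)), np.asarray(age, dtype=float), np.asarray(sex, dtype=float)]
    names = ["intercept", "age", "sex"]
    if race is not None:
        race = np.asarray(race)
        levels = sorted(np.unique(race).tolist())
        for lev in levels[1:]:
            cols.append((race == lev).astype(float))
            names.append(f"race_{lev}")
    w = np.column_stack(cols)
    _check_full_rank(w, names)
    return w, names


def _check_full_rank(w: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(w)
    if rank < w.shape[1]:
        # localize offending columns by incremental rank growth
        bad = []
        r = 0
        for j in range(w.shape[1]):
            rj = np.linalg.matrix_rank(w[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"singular covariate matrix; collinear columns: {bad}")


class LinearMixedModel:
    """REML LMM with one eigendecomposition of K shared across SNPs.

    Rotating the model by the eigenvectors of K diagonalizes the
    covariance to se^2 (lambda s_i + 1), turning each profile-likelihood
    evaluation into a weighted least squares.  ``lambda`` is profiled on
    a log grid and polished by Brent per SNP.
    """

    LOG_GRID = np.linspace(-5.0, 5.0, 41)

    def __init__(self, covariates: np.ndarray, grm: np.ndarray) -> None:
        w = np.asarray(covariates, dtype=float)
        k = np.asarray(grm, dtype=float)
        if w.ndim != 2:
            raise ValueError("covariates must be a 2-D design matrix")
        if k.shape != (w.shape[0], w.shape[0]):
            raise ValueError("GRM shape does not match the number of subjects")
        if not np.allclose(k, k.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        self.n = w.shape[0]
        eigval, eigvec = np.linalg.eigh(k)
        self.s = np.clip(eigval, 0.0, None)  # PSD jitter: clamp tiny negatives
        self.u = eigvec
        self.w_rot = self.u.T @ w
        self.n_cov = w.shape[1]

    def _reml_neg_loglik(self, log_lam: float, x_rot: np.ndarray, y_rot: np.ndarray) -> float:
        lam = 10.0**log_lam
        v = lam * self.s + 1.0
        d = 1.0 / v
        xw = x_rot * d[:, None]
        xtx = x_rot.T @ xw
        try:
            beta = np.linalg.solve(xtx, xw.T @ y_rot)
        except np.linalg.LinAlgError:
            return np.inf
        resid = y_rot - x_rot @ beta
        rss = float(resid @ (d * resid))
        if rss <= 0:
            return np.inf
        nc = self.n - x_rot.shape[1]
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
        return 0.5 * (np.log(v).sum() + logdet_xtx + nc * np.log(rss))

    def _profile_lambda(self, x_rot: np.ndarray, y_rot: np.ndarray) -> float:
        grid_vals = [self._reml_neg_loglik(g, x_rot, y_rot) for g in self.LOG_GRID]
        i = int(np.argmin(grid_vals))
        lo = self.LOG_GRID[max(i - 1, 0)]
        hi = self.LOG_GRID[min(i + 1, len(self.LOG_GRID) - 1)]
        if lo == hi:
            return 10.0 ** self.LOG_GRID[i]
        res = optimize.minimize_scalar(
            self._reml_neg_loglik, bounds=(lo, hi), args=(x_rot, y_rot), method="bounded"
        )
        best = res.x if res.fun < grid_vals[i] else self.LOG_GRID[i]
        return 10.0**best

    def fit_snp(self, trait: np.ndarray, dosage: np.ndarray) -> tuple[float, float, float]:
        """(beta, se, Wald p) for one SNP; missing dosages mean-imputed."""
        y = np.asarray(trait, dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("trait contains non-finite values")
        if self.n < self.n_cov + 2:
            raise ValueError("too few subjects for the covariate count")
        x = np.array(dosage, dtype=float)
        miss = np.isnan(x)
        if miss.any():
            x[miss] = np.nanmean(x)
        y_rot = self.u.T @ y
        x_rot = np.column_stack([self.w_rot, self.u.T @ x])
        lam = self._profile_lambda(x_rot, y_rot)
        v = lam * self.s + 1.0
        d = 1.0 / v
        xw = x_rot * d[:, None]
        xtx = x_rot.T @ xw
        xtx_inv = np.linalg.inv(xtx)
        beta_all = xtx_inv @ (xw.T @ y_rot)
        resid = y_rot - x_rot @ beta_all
        sigma2 = float(resid @ (d * resid)) / (self.n - x_rot.shape[1])
        beta = float(beta_all[-1])
        se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        p = float(stats.chi2.sf((beta / se) ** 2, df=1))
        return beta, se, p


def lmm_wald(
    trait: np.ndarray,
    snp_dosage: np.ndarray,
    covariates: np.ndarray,
    grm: np.ndarray,
) -> tuple[float, float, float]:
    """One-SNP convenience wrapper around :class:`LinearMixedModel`."""
    return LinearMixedModel(covariates, grm).fit_snp(trait, snp_dosage)


def association_scan(
    trait: np.ndarray,
    panel: GenotypePanel,
    covariates: np.ndarray,
    grm: np.ndarray,
) -> pd.DataFrame:
    """LMM Wald test of every SNP in the panel against one trait."""
    model = LinearMixedModel(covariates, grm)
    rows = []
    for j in range(panel.n_snps):
        beta, se, p = model.fit_snp(trait, panel.dosages[:, j])
        rows.append((panel.snp_ids[j], panel.chrom[j], panel.pos[j], beta, se, p))
    out = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "beta", "se", "p"])
    for pop in np.unique(panel.populations):
        out[f"maf_{pop}"] = [
            maf(panel.dosages[:, j], panel.populations == pop) for j in range(panel.n_snps)
        ]
    return out


# ---------------------------------------------------------------------------
# LD blocks and multiplicity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDBlockSet:
    """Disjoint within-chromosome SNP-index blocks; singletons included.

    ``n_independent`` counts one test per block plus one per singleton —
    the effective multiplicity m for Bonferroni correction.
    """

    blocks: tuple[tuple[int, int], ...]  # half-open [start, stop) index ranges
    n_snps: int = field(default=0)

    @property
    def n_independent(self) -> int:
        return len(self.blocks)


def ld_blocks(
    panel: GenotypePanel, r2_threshold: float = 0.5, window: int = 50
) -> LDBlockSet:
    """Greedy deterministic LD blocking within chromosomes.

    Walking SNPs in panel order, a SNP joins the current block while its
    squared correlation with the block's seed SNP is at least
    ``r2_threshold`` and it lies within ``window`` SNPs of the seed;
    otherwise it seeds a new block.  Blocks never span chromosomes.
    """
    d = panel.dosages
    means = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), means[None, :], d)
    blocks: list[tuple[int, int]] = []
    seed_idx = 0
    for j in range(1, panel.n_snps + 1):
        new_block = j == panel.n_snps
        if not new_block:
            same_chrom = panel.chrom[j] == panel.chrom[seed_idx]
            in_window = (j - seed_idx) <= window
            if same_chrom and in_window:
                a, b = filled[:, seed_idx], filled[:, j]
                if a.std() == 0 or b.std() == 0:
                    r2 = 1.0 if a.std() == b.std() == 0 else 0.0
                else:
                    r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
                new_block = r2 < r2_threshold
            else:
                new_block = True
        if new_block:
            blocks.append((seed_idx, j))
            seed_idx = j
    return LDBlockSet(blocks=tuple(blocks), n_snps=panel.n_snps)


def ld_adjusted_bonferroni(
    pvals: np.ndarray, blockset: LDBlockSet, alpha: float = 0.05
) -> np.ndarray:
    """Boolean significance at the LD-adjusted threshold alpha / m."""
    m = blockset.n_independent
    if m < 1:
        raise ValueError("block set is empty")
    return np.asarray(pvals, dtype=float) < alpha / m
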