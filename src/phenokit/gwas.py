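"""Mixed-model association scan with filtering, kinship, thresholds and clumping.

The chain mirrors a resequencing-panel GWAS on an inbred crop:

1. SNP filtering on minor allele frequency and minor-allele carrier count;
2. kinship as the pairwise identity-genotype proportion over an evenly
   spaced SNP subset;
3. a spectrally transformed linear mixed model (single eigendecomposition
   of the kinship, variance-ratio optimisation on the null, per-SNP
   likelihood-ratio tests against chi-square with 1 df);
4. Bonferroni-style thresholds 1/N (suggestive) and 0.05/N (significant)
   from a block-eigenvalue effective number of independent markers N;
5. greedy LD clumping of passing SNPs at an r-squared cutoff, with an
   optional peak-support filter.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "AssociationResult",
    "ThresholdPair",
    "ClumpedLocus",
    "maf_filter",
    "kinship_identity_proportion",
    "phenotype_preprocess",
    "lmm_scan",
    "ols_scan",
    "genomic_inflation",
    "effective_marker_number",
    "significance_thresholds",
    "ld_r2",
    "clump_loci",
    "peak_filter",
]


@dataclasses.dataclass
class GenotypeMatrix:
    """Accession-by-SNP dosage matrix with positional metadata.

    ``dosages`` is float64 with values in {0, 1, 2} and NaN for missing.
    Positions are 1-based and strictly increasing within a chromosome.
    """

    dosages: np.ndarray
    chrom: np.ndarray  # per-SNP chromosome label (str)
    pos: np.ndarray  # per-SNP 1-based position (int64)
    accessions: list[str]
    snp_ids: list[str] | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be n_accessions x m_snps")
        n, m = self.dosages.shape
        if not (len(self.chrom) == len(self.pos) == m):
            raise ValueError("SNP metadata length mismatch")
        if len(self.accessions) != n:
            raise ValueError("accession id length mismatch")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.snp_ids is None:
            self.snp_ids = [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            accessions=list(self.accessions),
            snp_ids=[self.snp_ids[i] for i in idx] if self.snp_ids else None,
            ref=self.ref[idx] if self.ref is not None else None,
            alt=self.alt[idx] if self.alt is not None else None,
        )


@dataclasses.dataclass
class KinshipMatrix:
    """Identity-proportion relatedness, raw and PSD-repaired."""

    values: np.ndarray  # PSD-repaired, diagonal renormalised to 1
    raw: np.ndarray
    n_snps_used: int
    repaired: bool


@dataclasses.dataclass
class AssociationResult:
    chrom: np.ndarray
    pos: np.ndarray
    snp_ids: list[str]
    beta: np.ndarray
    lr_stat: np.ndarray
    p_value: np.ndarray
    sigma_g2: float
    sigma_e2: float
    delta: float
    null_loglik: float


@dataclasses.dataclass(frozen=True)
class ThresholdPair:
    suggestive: float
    significant: float
    effective_n: float


@dataclasses.dataclass
class ClumpedLocus:
    lead_index: int
    lead_chrom: str
    lead_pos: int
    lead_p: float
    member_indices: list[int]
    span: tuple[int, int]


# ---------------------------------------------------------------------------
# Filtering and preprocessing
# ---------------------------------------------------------------------------

def maf_filter(
    G: GenotypeMatrix, maf_min: float = 0.05, mac_accessions_min: int = 6
) -> GenotypeMatrix:
    """Keep SNPs with MAF >= ``maf_min`` and minor-allele carriers >= ``mac_accessions_min``.

    MAF is computed over non-missing calls; a carrier is an accession with
    at least one copy of the minor allele.
    """
    D = G.dosages
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alt_freq = np.nanmean(D, axis=0) / 2.0
    alt_freq = np.where(np.isnan(alt_freq), 0.0, alt_freq)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    minor_is_alt = alt_freq <= 0.5
    carries_alt = (D > 0) & ~np.isnan(D)
    carries_ref = (D < 2) & ~np.isnan(D)
    carriers = np.where(minor_is_alt, carries_alt.sum(axis=0), carries_ref.sum(axis=0))
    keep = (maf >= maf_min) & (carriers >= mac_accessions_min)
    if not keep.any():
        warnings.warn("all SNPs removed by MAF/MAC filter", RuntimeWarning)
    return G.take_snps(np.flatnonzero(keep))


def phenotype_preprocess(
    values: np.ndarray, ids: Sequence[str] | None = None, z_max: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass outlier removal at mean +/- ``z_max`` standard deviations.

    Returns a boolean keep-mask over the input and the list of dropped
    positions.  Missing (NaN) values are dropped as well.  With zero SD the
    vector is returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 10:
        raise ValueError("need at least 10 non-missing phenotype values")
    mu = values[finite].mean()
    sd = values[finite].std(ddof=0)
    if sd == 0:
        keep = finite
    else:
        keep = finite & (np.abs(values - mu) <= z_max * sd)
    dropped = np.flatnonzero(~keep & finite)
    return keep, dropped


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def evenly_spaced_subset(m: int, subset_size: int, seed: int = 0) -> np.ndarray:
    """Indices of ~``subset_size`` evenly spaced SNPs with a seeded phase."""
    subset_size = min(subset_size, m)
    if subset_size == m:
        return np.arange(m)
    step = m / subset_size
    phase = np.random.default_rng(seed).uniform(0, step)
    idx = np.unique(np.minimum((phase + step * np.arange(subset_size)).astype(int), m - 1))
    return idx


def kinship_identity_proportion(
    G: GenotypeMatrix, subset_size: int | None = None, seed: int = 0
) -> KinshipMatrix:
    """Pairwise fraction of subset SNPs with identical non-missing calls.

    The raw matrix may be indefinite; the usable matrix is eigenvalue-
    clipped at zero and its diagonal renormalised to 1.
    """
    idx = evenly_spaced_subset(G.m, subset_size or G.m, seed)
    D = G.dosages[:, idx]
    n = D.shape[0]
    obs = ~np.isnan(D)
    same = np.zeros((n, n))
    for code in (0.0, 1.0, 2.0):
        A = ((D == code) & obs).astype(np.float64)
        same += A @ A.T
    co_obs = obs.astype(np.float64) @ obs.astype(np.float64).T
    if np.any(co_obs == 0):
        raise ValueError("a pair of accessions shares no non-missing SNP")
    raw = same / co_obs
    raw = (raw + raw.T) / 2.0
    np.fill_diagonal(raw, 1.0)

    eigval, eigvec = np.linalg.eigh(raw)
    repaired = bool(eigval.min() < -1e-10)
    if repaired:
        warnings.warn("kinship not PSD; clipping negative eigenvalues", RuntimeWarning)
    K = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
    d = np.sqrt(np.clip(np.diag(K), 1e-12, None))
    K = K / np.outer(d, d)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(values=K, raw=raw, n_snps_used=len(idx), repaired=repaired)


# ---------------------------------------------------------------------------
# Spectral linear mixed model
# ---------------------------------------------------------------------------

def _profiled_loglik(
    delta: float, s: np.ndarray, Uty: np.ndarray, UtX: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """ML log-likelihood profiled over beta and sigma_g2 at fixed delta.

    Model: y ~ N(X beta, sigma_g2 (K + delta I)); after rotation the
    weights are 1/(s_i + delta).
    """
    n = len(s)
    w = 1.0 / (s + delta)
    Xw = UtX * w[:, None]
    XtWX = UtX.T @ Xw
    XtWy = Xw.T @ Uty
    beta = np.linalg.solve(XtWX, XtWy)
    r = Uty - UtX @ beta
    sigma_g2 = float((r * r * w).sum() / n)
    ll = -0.5 * (
        n * math.log(2 * math.pi)
        + n * math.log(sigma_g2)
        + np.log(s + delta).sum()
        + n
    )
    return float(ll), beta, sigma_g2


def _optimize_delta(
    s: np.ndarray, Uty: np.ndarray, UtX: np.ndarray, grid_points: int = 100
) -> tuple[float, float, np.ndarray, float]:
    """Grid over log10 delta in [-5, 5] plus bounded local refinement."""
    grid = np.logspace(-5, 5, grid_points)
    lls = np.array([_profiled_loglik(d, s, Uty, UtX)[0] for d in grid])
    i = int(np.argmax(lls))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(
        lambda ld: -_profiled_loglik(10.0**ld, s, Uty, UtX)[0],
        bounds=(math.log10(lo), math.log10(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(10.0**res.x)
    ll, beta, sigma_g2 = _profiled_loglik(delta, s, Uty, UtX)
    return delta, ll, beta, sigma_g2


def lmm_scan(
    G: GenotypeMatrix,
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    mode: Literal["null_delta", "per_snp_delta"] = "null_delta",
) -> AssociationResult:
    """Per-SNP likelihood-ratio tests under ``y = mu + x beta + g + e``.

    ``g ~ N(0, sigma_g2 K)``, ``e ~ N(0, sigma_e2 I)``.  The kinship is
    eigendecomposed once; the variance ratio ``delta = sigma_e2 / sigma_g2``
    is maximised on the null model and, in the default mode, held fixed for
    every SNP (re-optimised per SNP in ``per_snp_delta`` mode).  P-values
    come from ``2 (ll_alt - ll_null)`` against chi-square(1).

    Missing dosages are mean-imputed in the tested design column;
    monomorphic SNPs get NaN statistics.
    """
    y = np.asarray(y, dtype=float)
    n = G.n
    if len(y) != n:
        raise ValueError("phenotype length does not match accession count")
    if n < 30:
        raise ValueError("need at least 30 accessions")
    Kmat = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    eigval, U = np.linalg.eigh(Kmat)
    if eigval.min() < -1e-8:
        warnings.warn("kinship not PSD; clipping for the scan", RuntimeWarning)
    s = np.clip(eigval, 0.0, None)

    Uty = U.T @ y
    ones = np.ones((n, 1))
    Ut1 = U.T @ ones
    delta0, ll_null, _, sigma_g2 = _optimize_delta(s, Uty, Ut1)
    sigma_e2 = sigma_g2 * delta0

    D = G.dosages.copy()
    col_mean = np.nanmean(np.where(np.isnan(D), np.nan, D), axis=0)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    mono = np.nanstd(D, axis=0) == 0

    UtG = U.T @ D
    m = G.m
    beta_out = np.full(m, np.nan)
    lr_out = np.full(m, np.nan)
    p_out = np.full(m, np.nan)

    if mode == "null_delta":
        w = 1.0 / (s + delta0)
        a11 = float((Ut1[:, 0] ** 2 * w).sum())
        a1y = float((Ut1[:, 0] * Uty * w).sum())
        yy = float((Uty**2 * w).sum())
        a1g = (Ut1[:, 0][:, None] * UtG * w[:, None]).sum(axis=0)
        agg = (UtG**2 * w[:, None]).sum(axis=0)
        agy = (UtG * Uty[:, None] * w[:, None]).sum(axis=0)
        det = a11 * agg - a1g**2
        ok = ~mono & (det > 1e-12 * np.maximum(a11 * agg, 1e-300))
        # 2x2 weighted normal equations, vectorised across SNPs
        beta_snp = np.where(ok, (a11 * agy - a1g * a1y) / np.where(ok, det, 1.0), np.nan)
        beta_mu = np.where(ok, (a1y - a1g * beta_snp) / a11, np.nan)
        rss_alt = yy - 2 * beta_mu * a1y - 2 * beta_snp * agy + beta_mu**2 * a11 \
            + 2 * beta_mu * beta_snp * a1g + beta_snp**2 * agg
        rss_alt = np.clip(rss_alt, 1e-300, None)
        rss_null = yy - a1y**2 / a11
        const = -0.5 * (n * math.log(2 * math.pi) + np.log(s + delta0).sum() + n)
        ll_alt = const - 0.5 * n * np.log(rss_alt / n)
        ll_null_fixed = const - 0.5 * n * math.log(rss_null / n)
        lr = 2.0 * (ll_alt - ll_null_fixed)
        lr = np.clip(lr, 0.0, None)
        beta_out[ok] = beta_snp[ok]
        lr_out[ok] = lr[ok]
        p_out[ok] = stats.chi2.sf(lr[ok], df=1)
    elif mode == "per_snp_delta":
        for j in range(m):
            if mono[j]:
                continue
            UtX = np.column_stack([Ut1[:, 0], UtG[:, j]])
            _, ll_alt_j, beta_j, _ = _optimize_delta(s, Uty, UtX)
            lr = max(0.0, 2.0 * (ll_alt_j - ll_null))
            beta_out[j] = beta_j[1]
            lr_out[j] = lr
            p_out[j] = stats.chi2.sf(lr, df=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    p_out = np.where(np.isnan(p_out), np.nan, np.clip(p_out, np.nextafter(0, 1), 1.0))
    return AssociationResult(
        chrom=G.chrom.copy(),
        pos=G.pos.copy(),
        snp_ids=list(G.snp_ids or []),
        beta=beta_out,
        lr_stat=lr_out,
        p_value=p_out,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta0,
        null_loglik=ll_null,
    )


def ols_scan(G: GenotypeMatrix, y: np.ndarray) -> AssociationResult:
    """Naive per-SNP regression without any relatedness correction.

    Likelihood-ratio test of ``y ~ 1 + x`` against ``y ~ 1`` under i.i.d.
    Gaussian errors — the uncorrected baseline a mixed model is compared
    against.
    """
    identity = KinshipMatrix(
        values=np.eye(G.n), raw=np.eye(G.n), n_snps_used=0, repaired=False
    )
    return lmm_scan(G, y, identity, mode="null_delta")


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median observed chi2(1) over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    chi2_obs = stats.chi2.isf(p, df=1)
    return float(np.median(chi2_obs) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# Effective marker number and thresholds
# ---------------------------------------------------------------------------

def effective_marker_number(
    G: GenotypeMatrix, block_size: int = 200
) -> float:
    """Block-eigenvalue effective number of independent markers.

    Within each chromosome, SNPs are cut into consecutive blocks of at most
    ``block_size``; for each block the eigenvalues of the SNP Pearson
    correlation matrix contribute ``I(lambda >= 1) + (lambda - floor(lambda))``
    each, and N is the sum over blocks.  Constant SNP columns are excluded.
    """
    if G.m < 2:
        raise ValueError("need at least 2 SNPs")
    D = G.dosages
    col_mean = np.nanmean(D, axis=0)
    Dimp = np.where(np.isnan(D), col_mean[None, :], D)
    sd = Dimp.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("constant SNP columns excluded from N", RuntimeWarning)
    total = 0.0
    for c in np.unique(G.chrom):
        cols = np.flatnonzero((G.chrom == c) & (sd > 0))
        for start in range(0, len(cols), block_size):
            block = Dimp[:, cols[start : start + block_size]]
            if block.shape[1] == 0:
                continue
            corr = np.corrcoef(block, rowvar=False)
            corr = np.atleast_2d(corr)
            lam = np.linalg.eigvalsh(corr)
            # round to absorb float error at integer eigenvalues, where the
            # floor-fraction rule is discontinuous (k identical SNPs -> k)
            lam = np.round(np.clip(lam, 0.0, None), 9)
            total += float(((lam >= 1.0).astype(float) + (lam - np.floor(lam))).sum())
    return total


def significance_thresholds(effective_n: float, alpha: float = 0.05) -> ThresholdPair:
    """Suggestive ``1/N`` and significant ``alpha/N`` genome-wide thresholds."""
    if effective_n < 1:
        raise ValueError("effective_n must be >= 1")
    suggestive = 1.0 / effective_n
    # computed from the suggestive value so significant == alpha * suggestive
    # holds exactly in floating point
    return ThresholdPair(
        suggestive=suggestive,
        significant=alpha * suggestive,
        effective_n=effective_n,
    )


# ---------------------------------------------------------------------------
# LD and clumping
# ---------------------------------------------------------------------------

def ld_r2(x: np.ndarray, z: np.ndarray) -> float:
    """Haplotype-frequency LD r² between two SNPs of an inbred panel.

    Homozygous diploid calls are treated as observed haplotypes; pairs with
    a missing or heterozygous call at either SNP are excluded.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = np.isin(x, (0.0, 2.0)) & np.isin(z, (0.0, 2.0))
    a = x[ok] / 2.0
    b = z[ok] / 2.0
    if a.size == 0:
        raise ValueError("no usable haplotypes")
    pA = a.mean()
    pB = b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic SNP after exclusions")
    pAB = (a * b).mean()
    d = pAB - pA * pB
    return float(d * d / (pA * (1 - pA) * pB * (1 - pB)))


def clump_loci(
    results: AssociationResult,
    G: GenotypeMatrix,
    p_threshold: float,
    r2_threshold: float = 0.25,
    window_kb: int = 250,
) -> list[ClumpedLocus]:
    """Greedy LD clumping of SNPs passing ``p_threshold``.

    Repeatedly take the unassigned passing SNP with the smallest p-value as
    a lead; absorb every unassigned passing SNP on the same chromosome
    within ``window_kb`` of the lead with r² > ``r2_threshold``.  Loci are
    returned sorted by lead p-value.
    """
    p = results.p_value
    passing = np.flatnonzero(np.isfinite(p) & (p <= p_threshold))
    window = window_kb * 1000
    unassigned = set(int(i) for i in passing)
    loci: list[ClumpedLocus] = []
    order = passing[np.argsort(p[passing], kind="stable")]
    for lead in order:
        lead = int(lead)
        if lead not in unassigned:
            continue
        unassigned.discard(lead)
        members = [lead]
        near = [
            j
            for j in sorted(unassigned)
            if G.chrom[j] == G.chrom[lead]
            and abs(int(G.pos[j]) - int(G.pos[lead])) <= window
        ]
        for j in near:
            try:
                r2 = ld_r2(G.dosages[:, lead], G.dosages[:, j])
            except ValueError:
                continue
            if r2 > r2_threshold:
                members.append(j)
                unassigned.discard(j)
        span = (int(G.pos[members[0]]), int(G.pos[members[0]]))
        if len(members) > 1:
            ps = [int(G.pos[j]) for j in members]
            span = (min(ps), max(ps))
        loci.append(
            ClumpedLocus(
                lead_index=lead,
                lead_chrom=str(G.chrom[lead]),
                lead_pos=int(G.pos[lead]),
                lead_p=float(p[lead]),
                member_indices=sorted(members),
                span=span,
            )
        )
    loci.sort(key=lambda locus: locus.lead_p)
    return loci


def peak_filter(
    loci: Sequence[ClumpedLocus],
    results: AssociationResult,
    G: GenotypeMatrix,
    p_threshold: float,
    min_support: int = 2,
    support_p: float | None = None,
    window_kb: int = 250,
) -> list[ClumpedLocus]:
    """Keep loci whose lead is supported by nearby sub-threshold signals.

    A locus survives when at least ``min_support`` other SNPs within the
    lead's window have p below ``support_p`` (default: 100x the clumping
    threshold ``p_threshold``).
    """
    out = []
    window = window_kb * 1000
    p = results.p_value
    cutoff = support_p if support_p is not None else 100.0 * p_threshold
    for locus in loci:
        near = np.flatnonzero(
            (results.chrom == locus.lead_chrom)
            & (np.abs(results.pos - locus.lead_pos) <= window)
            & np.isfinite(p)
        )
        support = int(((p[near] < cutoff)).sum()) - 1  # exclude the lead itself
        if support >= min_support:
            out.append(locus)
    return out
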