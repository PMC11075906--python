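"""Genome-scan engine over 8-founder haplotype dosages.

The mapping model follows the standard multiparent-population practice: a
linear mixed model per trait with a genetic relatedness (kinship) matrix
built from founder dosages, computed with the leave-one-chromosome-out
(LOCO) convention so markers on the scanned chromosome do not contaminate
the polygenic term. Per chromosome, the null (covariates-only) heritability
is estimated once by REML through the kinship eigendecomposition, the data
are rotated into the eigenbasis and weighted, and each marker adds the 8
founder dosage columns to a weighted least-squares fit. Evidence is the LOD
score

    LOD = (n / 2) * log10(RSS0 / RSS1)

in the rotated space. Haplotype effects at a locus are estimated as BLUPs
(founder effects treated as i.i.d. random with a REML-estimated variance),
significance is assessed by permutation (phenotype and covariate rows
shuffled jointly against the genotypes), and a shared permutation null
drives the experiment-wide genome-wide FDR across traits. Variant
association collapses the 8 founder dosages through a strain-distribution
pattern (SDP) into a single allele dosage for a 1-df test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .simulate import FOUNDER_STRAINS, GenoProbs, MarkerMap, N_FOUNDERS

# ---------------------------------------------------------------------------
# kinship


@dataclass
class KinshipMatrices:
    """Overall kinship and, optionally, one LOCO matrix per chromosome."""

    overall: np.ndarray
    loco: dict = field(default_factory=dict)
    individual_ids: list = field(default_factory=list)

    def for_chromosome(self, chromosome):
        """The kinship used when scanning a chromosome (LOCO if available)."""
        return self.loco.get(chromosome, self.overall)


def calc_kinship(genoprobs: GenoProbs, loco: bool = False) -> KinshipMatrices:
    """Genetic relatedness from founder dosages.

    K_ij = (1/M) sum_m sum_f q_imf q_jmf with q = dosage / 2 (haplotype
    probabilities), averaged over the included markers. With ``loco`` a
    per-chromosome matrix excludes that chromosome's markers.
    """
    if genoprobs.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    q = genoprobs.dosage / 2.0  # (n, 8, M)
    n, _, M = q.shape
    flat = q.reshape(n, -1)
    overall = (flat @ flat.T) / M
    loco_mats = {}
    if loco:
        chroms = genoprobs.marker_map.chromosomes
        if len(chroms) < 2:
            raise ValueError("LOCO requires at least 2 chromosomes")
        for chrom in chroms:
            idx = genoprobs.marker_map.chrom_index(chrom)
            sub = q[:, :, idx].reshape(n, -1)
            m_out = M - idx.size
            loco_mats[chrom] = (overall * M - sub @ sub.T) / m_out
    return KinshipMatrices(overall, loco_mats, list(genoprobs.individual_ids))


# ---------------------------------------------------------------------------
# heritability / null mixed model


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    loglik: float
    trait: str = ""


def _design_matrix(covariates, n: int) -> np.ndarray:
    """Intercept plus dummy-coded covariates (strings become indicators)."""
    cols = [np.ones(n)]
    if covariates is not None:
        df = pd.DataFrame(covariates)
        dummies = pd.get_dummies(df, drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _neg2_reml_rotated(h2, ys, Xs, lam):
    """-2 REML loglik (up to constant) for V = h2 K + (1 - h2) I, in the
    kinship eigenbasis (ys = U'y, Xs = U'X, lam = eigenvalues)."""
    n, p = Xs.shape
    w = h2 * lam + (1.0 - h2)
    w = np.maximum(w, 1e-12)
    sw = np.sqrt(w)
    Xw = Xs / sw[:, None]
    yw = ys / sw
    beta, rss, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rss.size == 0:
        rss_val = float(np.sum((yw - Xw @ beta) ** 2))
    else:
        rss_val = float(rss[0])
    sigma2 = rss_val / (n - p)
    sign, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
    return (n - p) * np.log(sigma2) + float(np.sum(np.log(w))) + logdet_xx


def estimate_heritability(
    pheno, K: np.ndarray, covariates=None, trait: str = ""
) -> HeritabilityEstimate:
    """REML narrow-sense heritability on [0, 1] via a single kinship
    eigendecomposition and a 1-D bounded optimization."""
    y = np.asarray(pheno, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype")
    if np.ptp(y) == 0.0:
        raise ValueError("constant phenotype")
    n = y.size
    X = _design_matrix(covariates, n)
    lam, U = np.linalg.eigh(K)
    ys, Xs = U.T @ y, U.T @ X
    res = minimize_scalar(
        _neg2_reml_rotated,
        bounds=(0.0, 1.0),
        method="bounded",
        args=(ys, Xs, lam),
        options={"xatol": 1e-8},
    )
    # check the boundaries explicitly; 'bounded' never lands exactly on them
    h2, val = float(res.x), float(res.fun)
    for edge in (0.0, 1.0 - 1e-9):
        v = _neg2_reml_rotated(edge, ys, Xs, lam)
        if v < val:
            h2, val = edge, v
    return HeritabilityEstimate(h2, -0.5 * val, trait)


# ---------------------------------------------------------------------------
# scanning core


def _rss_given_design(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sums of squares of each column of Y on X (min-norm LS)."""
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.sum(resid * resid, axis=0)


def _marker_rss_batched(G: np.ndarray, Y: np.ndarray, X0: np.ndarray) -> np.ndarray:
    """RSS of each trait on [X0, founder dosages] at every marker.

    G is (n, 8, M); Y is (n, T); X0 is (n, p). Uses batched normal
    equations with a pseudoinverse, so collinear dosage columns (and the
    intercept/dosage sum dependency) are handled by the minimum-norm
    solution. Returns (M, T).
    """
    n, _, M = G.shape
    p = X0.shape[1]
    X0X0 = X0.T @ X0  # (p, p)
    X0G = np.einsum("np,nfm->mpf", X0, G, optimize=True)  # (M, p, 8)
    GG = np.einsum("nfm,ngm->mfg", G, G, optimize=True)  # (M, 8, 8)
    X0Y = X0.T @ Y  # (p, T)
    GY = np.einsum("nfm,nt->mft", G, Y, optimize=True)  # (M, 8, T)

    k = p + N_FOUNDERS
    S = np.empty((M, k, k))
    S[:, :p, :p] = X0X0
    S[:, :p, p:] = X0G
    S[:, p:, :p] = np.transpose(X0G, (0, 2, 1))
    S[:, p:, p:] = GG
    rhs = np.concatenate([np.broadcast_to(X0Y, (M, p, Y.shape[1])), GY], axis=1)
    Sinv = np.linalg.pinv(S, hermitian=True)
    beta = Sinv @ rhs  # (M, k, T)
    yy = np.sum(Y * Y, axis=0)  # (T,)
    rss = yy[None, :] - np.sum(beta * rhs, axis=1)
    return np.maximum(rss, 1e-300)


def _lod_from_rss(rss0: np.ndarray, rss1: np.ndarray, n: int) -> np.ndarray:
    lod = (n / 2.0) * np.log10(rss0[None, :] / rss1)
    return np.maximum(lod, 0.0)


def marker_lod(dosage_at_locus, pheno, covariates=None) -> float:
    """LOD of the additive 8-allele fit at a single locus (no kinship).

    ``dosage_at_locus`` is (individuals, 8); the null model is the
    covariates-only (or intercept-only) regression.
    """
    G = np.asarray(dosage_at_locus, dtype=float)
    y = np.asarray(pheno, dtype=float)
    n = y.size
    X0 = _design_matrix(covariates, n)
    rss0 = _rss_given_design(X0, y[:, None])[0]
    rss1 = _rss_given_design(np.column_stack([X0, G]), y[:, None])[0]
    return float(max(0.0, (n / 2.0) * np.log10(rss0 / max(rss1, 1e-300))))


@dataclass
class ScanResult:
    """Per-marker LOD profile per trait, plus the null-model heritabilities."""

    lod: pd.DataFrame  # index marker_id, one column per trait
    marker_map: MarkerMap
    null_h2: dict = field(default_factory=dict)  # (trait, chromosome) -> h2

    @property
    def traits(self) -> list:
        return list(self.lod.columns)

    def max_lod(self, trait=None) -> float:
        col = self.lod[trait] if trait is not None else self.lod
        return float(np.asarray(col).max())


def _as_trait_frame(pheno) -> pd.DataFrame:
    if isinstance(pheno, pd.DataFrame):
        return pheno
    if isinstance(pheno, pd.Series):
        return pheno.to_frame(pheno.name or "trait")
    arr = np.asarray(pheno, dtype=float)
    if arr.ndim == 1:
        return pd.DataFrame({"trait": arr})
    return pd.DataFrame(arr, columns=[f"trait{j}" for j in range(arr.shape[1])])


def genome_scan(
    genoprobs: GenoProbs,
    pheno,
    covariates=None,
    kinship: KinshipMatrices = None,
) -> ScanResult:
    """Additive 8-allele genome scan.

    Per trait and chromosome (when a kinship is supplied) the null
    heritability is REML-estimated once under the covariates-only model with
    that chromosome's LOCO kinship, the phenotype, covariates and dosages
    are rotated into the kinship eigenbasis and weighted, and every marker
    is tested by weighted least squares. Without kinship the scan reduces to
    plain least squares. Individuals with a missing phenotype are dropped
    for that trait.
    """
    Y = _as_trait_frame(pheno)
    mm = genoprobs.marker_map
    n_all = genoprobs.n_individuals
    if len(Y) != n_all:
        raise ValueError("phenotype rows must align with genoprobs individuals")
    X_all = _design_matrix(covariates, n_all)
    lod = pd.DataFrame(
        np.zeros((mm.n_markers, Y.shape[1])),
        index=mm.df["marker_id"].to_numpy(),
        columns=Y.columns,
    )
    null_h2 = {}

    complete = np.all(np.isfinite(Y.to_numpy()), axis=1)
    if kinship is None and complete.all():
        # fast path: one batched pass over all traits
        Ymat = Y.to_numpy(dtype=float)
        rss0 = _rss_given_design(X_all, Ymat)
        rss1 = _marker_rss_batched(genoprobs.dosage, Ymat, X_all)
        lod.iloc[:, :] = _lod_from_rss(rss0, rss1, n_all)
        return ScanResult(lod, mm, null_h2)

    eig_cache = {}
    for trait in Y.columns:
        y_full = Y[trait].to_numpy(dtype=float)
        keep = np.isfinite(y_full)
        y = y_full[keep]
        X = X_all[keep]
        n = int(keep.sum())
        for chrom in mm.chromosomes:
            idx = mm.chrom_index(chrom)
            G = genoprobs.dosage[np.ix_(keep, range(N_FOUNDERS), idx)]
            if kinship is not None:
                Kc = kinship.for_chromosome(chrom)[np.ix_(keep, keep)]
                key = (chrom, keep.tobytes())
                if key not in eig_cache:
                    eig_cache[key] = np.linalg.eigh(Kc)
                lam, U = eig_cache[key]
                ys, Xs = U.T @ y, U.T @ X
                res = minimize_scalar(
                    _neg2_reml_rotated,
                    bounds=(0.0, 1.0),
                    method="bounded",
                    args=(ys, Xs, lam),
                    options={"xatol": 1e-6},
                )
                h2 = float(res.x)
                if _neg2_reml_rotated(0.0, ys, Xs, lam) < float(res.fun):
                    h2 = 0.0
                null_h2[(trait, chrom)] = h2
                w = np.maximum(h2 * lam + (1.0 - h2), 1e-12)
                sw = np.sqrt(w)[:, None]
                yt = (ys / sw.ravel())[:, None]
                Xt = Xs / sw
                Gt = np.einsum("ij,jfm->ifm", U.T, G, optimize=True) / sw[:, :, None]
            else:
                yt, Xt, Gt = y[:, None], X, G
            rss0 = _rss_given_design(Xt, yt)
            rss1 = _marker_rss_batched(Gt, yt, Xt)
            lod.loc[mm.df["marker_id"].iloc[idx].to_numpy(), trait] = _lod_from_rss(
                rss0, rss1, n
            ).ravel()
    return ScanResult(lod, mm, null_h2)


# ---------------------------------------------------------------------------
# haplotype effects


@dataclass
class HaplotypeEffectVector:
    """Centered BLUP-shrunk effects of the 8 founder haplotypes at a locus."""

    effects: np.ndarray
    marker_id: str
    trait: str = ""
    founder_order: tuple = FOUNDER_STRAINS
    tau: float = np.nan  # ratio var(founder effect) / var(residual)
    zero_variance: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(self.effects, index=list(self.founder_order))


def _neg2_reml_tau(log_tau, y, X, G):
    tau = np.exp(log_tau)
    n, p = X.shape
    V = np.eye(n) + tau * (G @ G.T)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    ypy = float(r @ np.linalg.solve(V, r))
    sigma2 = ypy / (n - p)
    sign, logdet_xx = np.linalg.slogdet(XtViX)
    return (n - p) * np.log(sigma2) + logdet_V + logdet_xx


def _blup_solve(y, X, G, tau):
    """Founder BLUPs from Henderson's equations at a fixed variance ratio."""
    p = X.shape[1]
    k = p + G.shape[1]
    C = np.empty((k, k))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ G
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = G.T @ G
    if np.isfinite(tau):
        C[p:, p:] += np.eye(G.shape[1]) / tau
    rhs = np.concatenate([X.T @ y, G.T @ y])
    sol = np.linalg.pinv(C) @ rhs
    return sol[p:]


def haplotype_blup_effects(
    genoprobs: GenoProbs,
    marker_id: str,
    pheno,
    covariates=None,
    kinship: KinshipMatrices = None,
    trait: str = "",
    tau: float = None,
) -> HaplotypeEffectVector:
    """Founder haplotype effects at a locus, shrunk as BLUPs.

    The founder effects are treated as i.i.d. random with variance ratio
    ``tau`` (relative to the residual) estimated by REML unless supplied.
    With a kinship the data are first rotated/weighted exactly as in
    :func:`genome_scan` using the locus chromosome's LOCO matrix. Effects
    are returned centered; a REML estimate collapsing to zero variance
    yields the all-zero vector with a flag.
    """
    mm = genoprobs.marker_map
    m = mm.marker_index(marker_id)
    chrom = mm.df["chromosome"].iloc[m]
    y = np.asarray(pheno, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    X = _design_matrix(covariates, genoprobs.n_individuals)[keep]
    G = genoprobs.dosage[keep, :, m]
    if kinship is not None:
        Kc = kinship.for_chromosome(chrom)[np.ix_(keep, keep)]
        lam, U = np.linalg.eigh(Kc)
        ys, Xs = U.T @ y, U.T @ X
        res = minimize_scalar(
            _neg2_reml_rotated,
            bounds=(0.0, 1.0),
            method="bounded",
            args=(ys, Xs, lam),
            options={"xatol": 1e-6},
        )
        h2 = float(res.x)
        w = np.maximum(h2 * lam + (1.0 - h2), 1e-12)
        sw = np.sqrt(w)
        y = ys / sw
        X = Xs / sw[:, None]
        G = (U.T @ G) / sw[:, None]

    if tau is None:
        res = minimize_scalar(
            _neg2_reml_tau,
            bounds=(np.log(1e-8), np.log(1e8)),
            method="bounded",
            args=(y, X, G),
            options={"xatol": 1e-6},
        )
        tau_hat = float(np.exp(res.x))
        # compare against the no-effect boundary
        if _neg2_reml_tau(np.log(1e-12), y, X, G) <= float(res.fun) + 1e-9:
            return HaplotypeEffectVector(
                np.zeros(N_FOUNDERS), marker_id, trait, FOUNDER_STRAINS, 0.0, True
            )
        tau = tau_hat
    u = _blup_solve(y, X, G, tau)
    u = u - u.mean()
    return HaplotypeEffectVector(u, marker_id, trait, FOUNDER_STRAINS, float(tau), False)


# ---------------------------------------------------------------------------
# peaks


@dataclass(frozen=True)
class QtlPeak:
    trait: str
    chromosome: object
    marker_id: str
    position_bp: int
    lod: float
    ci_lo_bp: int
    ci_hi_bp: int


def find_peaks(
    scan: ScanResult,
    threshold: float = 7.5,
    drop: float = 1.5,
    genome_wide_max: bool = False,
) -> pd.DataFrame:
    """Call QTL peaks above a LOD threshold.

    At most one peak per chromosome per trait (the maximum; the first marker
    wins exact ties). The support interval spans the outermost markers on
    the chromosome with LOD >= peak - drop. With ``genome_wide_max`` only
    each trait's single best peak is kept.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mm = scan.marker_map
    peaks = []
    for trait in scan.traits:
        lods = scan.lod[trait].to_numpy()
        trait_peaks = []
        for chrom in mm.chromosomes:
            idx = mm.chrom_index(chrom)
            sub = lods[idx]
            j = int(np.argmax(sub))
            peak_lod = float(sub[j])
            if peak_lod < threshold:
                continue
            in_ci = np.flatnonzero(sub >= peak_lod - drop)
            bp = mm.df["position_bp"].iloc[idx].to_numpy()
            trait_peaks.append(
                QtlPeak(
                    trait,
                    chrom,
                    mm.df["marker_id"].iloc[idx[j]],
                    int(bp[j]),
                    peak_lod,
                    int(bp[in_ci[0]]),
                    int(bp[in_ci[-1]]),
                )
            )
        if genome_wide_max and trait_peaks:
            trait_peaks = [max(trait_peaks, key=lambda pk: pk.lod)]
        peaks.extend(trait_peaks)
    return pd.DataFrame(
        [vars(pk) for pk in peaks],
        columns=["trait", "chromosome", "marker_id", "position_bp", "lod", "ci_lo_bp", "ci_hi_bp"],
    )


# ---------------------------------------------------------------------------
# permutations and FDR


@dataclass
class NullDistribution:
    """Genome-wide maximum LODs under permutation."""

    max_lods: np.ndarray
    seed: int
    n_perm: int

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.max_lods, q))


def permutation_null(
    genoprobs: GenoProbs,
    pheno,
    covariates=None,
    kinship: KinshipMatrices = None,
    n_perm: int = 100,
    seed: int = 0,
) -> NullDistribution:
    """Permutation null of the genome-wide maximum LOD.

    Phenotype rows and their covariates are shuffled jointly against the
    genotypes (the kinship structure is deliberately ignored under the
    null), the scan repeated, and the genome-wide maximum recorded.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(pheno, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("permutations require a complete phenotype")
    rng = np.random.default_rng(seed)
    if covariates is None and kinship is None:
        # intercept-only, no kinship: all permuted scans share one design,
        # so the whole null batches into a single pass
        n = y.size
        Y = np.empty((n, n_perm))
        for b in range(n_perm):
            Y[:, b] = y[rng.permutation(n)]
        X0 = np.ones((n, 1))
        rss0 = _rss_given_design(X0, Y)
        rss1 = _marker_rss_batched(genoprobs.dosage, Y, X0)
        maxima = _lod_from_rss(rss0, rss1, n).max(axis=0)
        return NullDistribution(maxima, seed, n_perm)
    cov = pd.DataFrame(covariates) if covariates is not None else None
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(y.size)
        cov_b = cov.iloc[perm].reset_index(drop=True) if cov is not None else None
        scan = genome_scan(genoprobs, pd.Series(y[perm], name="perm"), cov_b, kinship)
        maxima[b] = scan.max_lod()
    return NullDistribution(maxima, seed, n_perm)


def fdr_threshold(null: NullDistribution, observed_max_lods, q: float = 0.10):
    """Shared-null genome-wide FDR threshold across traits.

    The threshold is the smallest observed maximum LOD t with
    m * tail_null(t) / #{observed >= t} <= q, where tail_null is the
    empirical exceedance probability of the shared permutation null and m
    the number of traits. Returns (threshold, boolean discovery flags);
    threshold is +inf when no t qualifies.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    nulls = np.sort(np.asarray(null.max_lods, dtype=float))
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    obs = np.asarray(observed_max_lods, dtype=float)
    m = obs.size
    threshold = np.inf
    for t in np.sort(np.unique(obs)):
        tail = float(np.mean(nulls >= t))
        n_disc = int(np.sum(obs >= t))
        if n_disc > 0 and (m * tail) / n_disc <= q:
            threshold = float(t)
            break
    return threshold, obs >= threshold


# ---------------------------------------------------------------------------
# SDP-collapsed variant association


def _parse_sdp(sdp) -> np.ndarray:
    s = str(sdp)
    if len(s) != N_FOUNDERS or set(s) - {"0", "1"}:
        raise ValueError(f"SDP must be an 8-char 0/1 string, got {sdp!r}")
    return np.array([ch == "1" for ch in s])


def snp_association(
    genoprobs: GenoProbs,
    variants: pd.DataFrame,
    pheno,
    covariates=None,
    kinship: KinshipMatrices = None,
) -> pd.DataFrame:
    """1-df association tests of variants via SDP-collapsed founder dosages.

    Each variant's allele dosage is the sum of founder dosages over the
    founders carrying the alternate allele (taken from the nearest marker to
    the variant position on its chromosome). Monomorphic SDPs (all 0 or all
    1) get LOD 0 and a flag. Returns the variant table with ``lod`` and
    ``monomorphic`` columns.
    """
    mm = genoprobs.marker_map
    y = np.asarray(pheno, dtype=float)
    keep = np.isfinite(y)
    y_k = y[keep]
    n = int(keep.sum())
    X_all = _design_matrix(covariates, genoprobs.n_individuals)[keep]

    # per-chromosome rotation, as in the genome scan
    transforms = {}
    for chrom in variants["chromosome"].unique():
        if kinship is None:
            transforms[chrom] = (y_k, X_all, None, None)
            continue
        Kc = kinship.for_chromosome(chrom)[np.ix_(keep, keep)]
        lam, U = np.linalg.eigh(Kc)
        ys, Xs = U.T @ y_k, U.T @ X_all
        res = minimize_scalar(
            _neg2_reml_rotated,
            bounds=(0.0, 1.0),
            method="bounded",
            args=(ys, Xs, lam),
            options={"xatol": 1e-6},
        )
        h2 = float(res.x)
        sw = np.sqrt(np.maximum(h2 * lam + (1.0 - h2), 1e-12))
        transforms[chrom] = (ys / sw, Xs / sw[:, None], U, sw)

    lods = np.zeros(len(variants))
    mono = np.zeros(len(variants), dtype=bool)
    for i, row in enumerate(variants.itertuples(index=False)):
        mask = _parse_sdp(row.sdp)
        if mask.all() or not mask.any():
            mono[i] = True
            continue
        chrom = row.chromosome
        idx = mm.chrom_index(chrom)
        if idx.size == 0:
            raise ValueError(f"variant chromosome {chrom!r} not in marker map")
        bp = mm.df["position_bp"].iloc[idx].to_numpy()
        nearest = idx[int(np.argmin(np.abs(bp - row.position_bp)))]
        v = genoprobs.dosage[keep][:, mask, nearest].sum(axis=1)
        yt, Xt, U, sw = transforms[chrom]
        if U is not None:
            v = (U.T @ v) / sw
        rss0 = _rss_given_design(Xt, yt[:, None])[0]
        rss1 = _rss_given_design(np.column_stack([Xt, v]), yt[:, None])[0]
        lods[i] = max(0.0, (n / 2.0) * np.log10(rss0 / max(rss1, 1e-300)))
    out = variants.copy()
    out["lod"] = lods
    out["monomorphic"] = mono
    return out
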