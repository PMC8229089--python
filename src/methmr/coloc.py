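"""Single-variant colocalization (SMR statistic) and the HEIDI heterogeneity
test distinguishing one shared causal variant from linkage of distinct
variants.

The SMR statistic at the top QTL SNP combines the QTL and GWAS z-scores,

    T = z1^2 z2^2 / (z1^2 + z2^2),        p = upper tail of chi^2(1),

and the ratio estimate is ``b_smr = b_gwas / b_qtl`` with delta-method
standard error ``|b_smr| * sqrt(1/z1^2 + 1/z2^2)``.

HEIDI compares the ratio estimate at each eligible cis SNP with the top-SNP
ratio; under a single shared causal variant all ratios agree and the
standardized differences follow a zero-mean Gaussian whose correlation is
induced by LD, so the sum of squares is a weighted sum of independent
chi^2(1) variables (weights = eigenvalues of that correlation matrix),
evaluated by Imhof's method with a Satterthwaite fallback.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .sumstats import LDPanel, QtlTable, SummaryStatSet, harmonize, ld_matrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# weighted chi-square mixture
# ---------------------------------------------------------------------------

def weighted_chi2_sf(q: float, weights: np.ndarray, tol: float = 1e-9) -> float:
    """Upper-tail probability of ``sum_k w_k X_k`` with ``X_k ~ chi^2(1)`` iid.

    Imhof (1961) numerical inversion; falls back to a Satterthwaite
    scaled-chi-square approximation if the integration misbehaves.
    """
    w = np.asarray([x for x in np.atleast_1d(weights) if x > 1e-12], dtype=float)
    if w.size == 0:
        return 1.0
    if q <= 0:
        return 1.0
    if w.size == 1:
        return float(stats.chi2.sf(q / w[0], df=1))

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(w * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((w * u) ** 2)))
        return math.sin(theta) / (u * rho)

    import warnings as _warnings
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", integrate.IntegrationWarning)
            val, err = integrate.quad(integrand, 0.0, np.inf, limit=500,
                                      epsabs=tol, epsrel=tol)
        p = 0.5 + val / math.pi
        # far in the tail the oscillatory integral loses all precision;
        # the moment-matched tail approximation is more trustworthy there
        if err > 1e-4 or not np.isfinite(p) or p < 1e-10:
            raise RuntimeError("imhof integration unreliable")
    except (Exception, integrate.IntegrationWarning):
        p = _satterthwaite_sf(q, w)
    return float(min(max(p, 1e-300), 1.0))


def _satterthwaite_sf(q: float, w: np.ndarray) -> float:
    s1, s2 = w.sum(), (w ** 2).sum()
    scale = s2 / s1
    df = s1 ** 2 / s2
    return float(stats.chi2.sf(q / scale, df=df))


def weighted_chi2_sf_mc(q: float, weights: np.ndarray, n_draws: int = 100_000,
                        rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo evaluation of the same tail probability (test oracle)."""
    rng = np.random.default_rng(0) if rng is None else rng
    w = np.asarray(weights, dtype=float)
    draws = (w[None, :] * rng.standard_normal((n_draws, w.size)) ** 2).sum(axis=1)
    return float((draws > q).mean())


# ---------------------------------------------------------------------------
# SMR
# ---------------------------------------------------------------------------

@dataclass
class SmrStats:
    top_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    z_qtl: float
    z_gwas: float


class ProbeSkipped(Exception):
    """Raised when a probe cannot be tested; carries the reason."""


def smr_test(qtl: QtlTable, gwas: SummaryStatSet,
             p_eligibility: float = 5e-8) -> SmrStats:
    """SMR colocalization test at the probe's top QTL SNP.

    Inputs must already be harmonized to a common allele orientation.
    """
    shared = [s for s in qtl.sset.snp_ids if s in gwas]
    if not shared:
        raise ProbeSkipped(f"probe {qtl.probe_id}: no SNPs shared with GWAS")
    z_q = qtl.sset.zscores().loc[shared]
    top = (z_q ** 2).idxmax()
    if float(qtl.sset.df.loc[top, "pvalue"]) >= p_eligibility:
        raise ProbeSkipped(
            f"probe {qtl.probe_id}: top QTL SNP {top} below eligibility "
            f"(p >= {p_eligibility:g})")
    b_q, se_q = (float(qtl.sset.df.loc[top, c]) for c in ("beta", "se"))
    b_g, se_g = (float(gwas.df.loc[top, c]) for c in ("beta", "se"))
    z1, z2 = b_q / se_q, b_g / se_g
    z1sq, z2sq = z1 * z1, z2 * z2
    if z2sq == 0.0:  # includes underflow of a denormal z2
        t_smr, se_term = 0.0, float("inf")
    else:
        t_smr = (z1sq * z2sq) / (z1sq + z2sq)
        se_term = math.sqrt(1.0 / z1sq + 1.0 / z2sq)
    p_smr = float(stats.chi2.sf(t_smr, df=1))
    b_smr = b_g / b_q
    se_smr = abs(b_smr) * se_term
    return SmrStats(top_snp=top, b_smr=b_smr, se_smr=se_smr,
                    p_smr=max(p_smr, 1e-300), z_qtl=z1, z_gwas=z2)


# ---------------------------------------------------------------------------
# HEIDI
# ---------------------------------------------------------------------------

@dataclass
class HeidiParams:
    p_inclusion: float = 1.57e-3   # QTL z^2 > 10
    r2_min: float = 0.05
    r2_max: float = 0.9
    max_snps: int = 20
    min_snps: int = 3
    ridge: float = 1e-8


@dataclass
class HeidiStats:
    p_heidi: float      # NaN when undefined
    n_snps: int
    defined: bool
    note: str = ""


def heidi_test(qtl: QtlTable, gwas: SummaryStatSet, panel: LDPanel,
               top_snp: str, params: HeidiParams | None = None) -> HeidiStats:
    """Heterogeneity test of ratio estimates across cis SNPs in LD with the
    top SNP; null = one shared causal variant."""
    params = params or HeidiParams()
    d = qtl.sset.df
    shared = [s for s in d.index if s in gwas and s in panel and s != top_snp]
    if top_snp not in panel:
        return HeidiStats(float("nan"), 0, False, "top SNP absent from panel")
    cand = [s for s in shared if float(d.loc[s, "pvalue"]) < params.p_inclusion]
    if cand:
        r_top = ld_matrix(panel, [top_snp] + cand)[0, 1:]
        r2 = r_top ** 2
        cand = [s for s, v in zip(cand, r2)
                if params.r2_min <= v <= params.r2_max]
    if len(cand) < params.min_snps:
        return HeidiStats(float("nan"), len(cand), False,
                          f"only {len(cand)} eligible SNPs")
    z2 = (d.loc[cand, "beta"] / d.loc[cand, "se"]) ** 2
    cand = z2.sort_values(ascending=False).index[:params.max_snps].tolist()

    snps = [top_snp] + cand
    R = ld_matrix(panel, snps)
    bx = d.loc[snps, "beta"].to_numpy()
    sx = d.loc[snps, "se"].to_numpy()
    by = gwas.df.loc[snps, "beta"].to_numpy()
    sy = gwas.df.loc[snps, "se"].to_numpy()
    bxy = by / bx

    # delta-method covariance of the ratio estimates
    C = R * (np.outer(sy, sy) + np.outer(bxy, bxy) * np.outer(sx, sx)) \
        / np.outer(bx, bx)
    dvec = bxy[1:] - bxy[0]
    covd = C[1:, 1:] - C[1:, :1] - C[:1, 1:] + C[0, 0]
    sd = np.sqrt(np.diag(covd))
    u = dvec / sd
    q = float(u @ u)
    corr = covd / np.outer(sd, sd)
    lam = np.linalg.eigvalsh(corr)
    if lam.min() < -1e-6:
        logger.info("heidi: correlation matrix not PSD for probe %s; "
                    "ridge-regularizing by %.1e", qtl.probe_id, params.ridge)
        corr = corr + params.ridge * np.eye(len(u))
        lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    p = weighted_chi2_sf(q, lam)
    return HeidiStats(p_heidi=p, n_snps=len(cand), defined=True)


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

@dataclass
class ColocThresholds:
    p_smr: float = 5e-8
    p_heidi_keep: float = 0.05
    p_eligibility: float = 5e-8
    heidi: HeidiParams = field(default_factory=HeidiParams)


@dataclass
class ColocResult:
    probe_id: str
    probe_chr: str
    probe_pos: int
    top_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    p_heidi: float      # NaN when undefined
    n_heidi_snps: int
    passed: bool
    note: str = ""

    REPORT_COLUMNS = ["probe_id", "probe_chr", "probe_pos", "top_snp",
                      "b_smr", "se_smr", "p_smr", "p_heidi", "n_heidi_snps",
                      "passed", "note"]


def coloc_passed(p_smr: float, p_heidi: float,
                 thresholds: ColocThresholds) -> bool:
    """An undefined HEIDI p-value (NaN) never passes the probe."""
    return bool(p_smr < thresholds.p_smr
                and np.isfinite(p_heidi)
                and p_heidi > thresholds.p_heidi_keep)


def coloc_scan(qtls: list[QtlTable], gwas: SummaryStatSet, panel: LDPanel,
               thresholds: ColocThresholds | None = None,
               harmonized: bool = False) -> list[ColocResult]:
    """One :class:`ColocResult` per probe, ordered by probe id."""
    thresholds = thresholds or ColocThresholds()
    results = []
    for qtl in sorted(qtls, key=lambda t: t.probe_id):
        try:
            if harmonized:
                hq, hg = qtl, gwas
            else:
                hq_s, hg = harmonize(qtl.sset, gwas, panel)
                hq = QtlTable(qtl.probe_id, qtl.probe_chrom, qtl.probe_pos, hq_s)
            smr = smr_test(hq, hg, p_eligibility=thresholds.p_eligibility)
        except (ProbeSkipped, Exception) as exc:
            if not isinstance(exc, ProbeSkipped):
                logger.warning("coloc: probe %s failed: %s", qtl.probe_id, exc)
            results.append(ColocResult(
                probe_id=qtl.probe_id, probe_chr=qtl.probe_chrom,
                probe_pos=qtl.probe_pos, top_snp="NA", b_smr=float("nan"),
                se_smr=float("nan"), p_smr=float("nan"),
                p_heidi=float("nan"), n_heidi_snps=0, passed=False,
                note=str(exc)))
            continue
        heidi = heidi_test(hq, hg, panel, smr.top_snp, thresholds.heidi)
        results.append(ColocResult(
            probe_id=qtl.probe_id, probe_chr=qtl.probe_chrom,
            probe_pos=qtl.probe_pos, top_snp=smr.top_snp, b_smr=smr.b_smr,
            se_smr=smr.se_smr, p_smr=smr.p_smr, p_heidi=heidi.p_heidi,
            n_heidi_snps=heidi.n_snps,
            passed=coloc_passed(smr.p_smr, heidi.p_heidi, thresholds),
            note=heidi.note))
    return results
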