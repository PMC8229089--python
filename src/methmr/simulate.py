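"""Two-sample synthetic cohorts with known causal ground truth.

Generates genotypes for three mutually independent samples (exposure cohort,
outcome cohort, LD reference panel) from a common population with
block-decaying LD, simulates methylation / expression / phenotype values under
one of five causal scenarios, and emits per-SNP summary statistics exactly as
a two-sample design requires: molecular QTLs from the exposure cohort, trait
GWAS from the outcome cohort.

Scenarios
---------
``causal``      SNPs -> M; E = th_me*M + e; Y = th_ey*E + th_my*M + background.
``pleiotropy``  SNPs -> M; the strongest of them also affects Y directly
                (single shared variant; no M -> Y path).
``linkage``     one SNP -> M only, a second SNP in LD with it -> Y only.
``reverse``     Y has a genetic basis; M = th_ym * Y + e.
``null``        M has a genetic basis; Y is background only.

Every scenario additionally plants ``n_background_snps`` SNPs with direct
effects on Y in linkage equilibrium with the molecular signal ("local
polygenic background"); these keep the reverse-direction MR testable.

LD model: per-haplotype latent Gaussian AR(1) with correlation
``rho^|i - j|`` between SNP latents, thresholded at the MAF quantile; the two
haplotypes are summed to a dosage in {0, 1, 2}, marginally Binomial(2, maf).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (LDPanel, QtlTable, RareVariantTable, SummaryStatSet,
                       write_ld_panel)

logger = logging.getLogger(__name__)

SCENARIOS = ("causal", "pleiotropy", "linkage", "reverse", "null")

_SNP_SPACING_BP = 500
_ALLELES = ("A", "G")  # non-ambiguous pair; harmonization keeps everything


class ConfigError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Generator settings for one locus under one causal scenario.

    Effect sizes are specified as fractions of trait variance explained and
    converted internally to per-allele betas; path coefficients
    (``theta_me``, ``theta_ey``, ``theta_my``, ``theta_ym``) act on
    variance-one trait scales, so the true total methylation->phenotype
    effect is ``theta_me * theta_ey + theta_my``.
    """

    scenario: str = "causal"
    n_exposure_cohort: int = 20_000
    n_outcome_cohort: int = 20_000
    n_panel: int = 503
    n_snps_per_locus: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay_rho: float = 0.9
    theta_mx: float = 0.6          # total M variance explained by causal SNPs
    n_causal_snps: int = 3
    theta_me: float = 0.5          # M -> E path
    theta_ey: float = 0.3          # E -> Y path
    theta_my: float = 0.0          # direct M -> Y path
    theta_ym: float = 0.0          # reverse Y -> M path (reverse scenario)
    h2_y_direct: float = 0.05      # variance of Y from the locus direct-Y SNP
    h2_background: float = 0.012   # variance of Y per background SNP
    n_background_snps: int = 3
    n_decoy_genes: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if min(self.n_exposure_cohort, self.n_outcome_cohort) < 100:
            raise ConfigError("cohort sizes must be >= 100")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if self.scenario == "reverse":
            if self.theta_my != 0:
                raise ConfigError(
                    "reverse scenario is incompatible with a nonzero direct "
                    "M->Y effect (theta_my)")
            if self.theta_ym == 0:
                raise ConfigError("reverse scenario requires theta_ym != 0")
        elif self.theta_ym != 0:
            raise ConfigError("theta_ym is only meaningful under scenario='reverse'")

    @property
    def true_b_xy(self) -> float:
        if self.scenario == "causal":
            return self.theta_me * self.theta_ey + self.theta_my
        return 0.0

    @classmethod
    def preset(cls, scenario: str, **overrides) -> "ScenarioConfig":
        """Scenario defaults sized so planted effects clear the pipeline's
        genome-wide thresholds at the default cohort sizes."""
        base: dict = {"scenario": scenario}
        if scenario == "causal":
            base |= dict(theta_mx=0.6, theta_me=0.5, theta_ey=0.3)
        elif scenario == "pleiotropy":
            base |= dict(theta_mx=0.6, theta_me=0.0, theta_ey=0.0,
                         h2_y_direct=0.012)
        elif scenario == "linkage":
            base |= dict(theta_mx=0.3, n_causal_snps=1, theta_me=0.0,
                         theta_ey=0.0, h2_y_direct=0.05)
        elif scenario == "reverse":
            base |= dict(theta_mx=0.0, n_causal_snps=0, theta_me=0.0,
                         theta_ey=0.0, h2_y_direct=0.4, theta_ym=0.3)
        elif scenario == "null":
            base |= dict(theta_mx=0.6, theta_me=0.0, theta_ey=0.0)
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class Genotypes:
    """Dosage matrices for the three independent samples plus SNP metadata."""

    snps: pd.DataFrame  # snp_id, chrom, pos, a1, a2, maf
    X_exposure: np.ndarray
    X_outcome: np.ndarray
    X_panel: np.ndarray

    def expected_var(self) -> np.ndarray:
        maf = self.snps["maf"].to_numpy()
        return 2.0 * maf * (1.0 - maf)


def _ar1_dosages(n: int, mafs: np.ndarray, rho: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Sum of two latent-AR(1)-thresholded haplotypes; Binomial(2, maf) marginally."""
    m = len(mafs)
    thr = stats.norm.isf(mafs).astype(np.float32)
    X = np.zeros((n, m), dtype=np.float32)
    rho32 = np.float32(rho)
    c = np.float32(math.sqrt(1.0 - rho * rho))
    for _hap in range(2):
        z = rng.standard_normal(n, dtype=np.float32)
        X[:, 0] += z > thr[0]
        for j in range(1, m):
            z = rho32 * z + c * rng.standard_normal(n, dtype=np.float32)
            X[:, j] += z > thr[j]
    return X


def _fix_monomorphic(X: np.ndarray, mafs: np.ndarray,
                     rng: np.random.Generator, label: str) -> None:
    for _ in range(10):
        mono = np.flatnonzero(X.std(axis=0) == 0)
        if not mono.size:
            return
        logger.info("simulate: resampling %d degenerate SNP column(s) in %s",
                    mono.size, label)
        for j in mono:
            X[:, j] = rng.binomial(2, mafs[j], size=X.shape[0]).astype(np.float32)
    raise RuntimeError("could not resample degenerate SNP columns")


def simulate_genotypes(config: ScenarioConfig,
                       rng: np.random.Generator | None = None,
                       locus_tag: str = "0", chrom: str = "1",
                       base_pos: int = 1_000_000) -> Genotypes:
    """Draw exposure-cohort, outcome-cohort and panel dosages independently."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.n_snps_per_locus
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    snps = pd.DataFrame({
        "snp_id": [f"rs{locus_tag}_{j}" for j in range(m)],
        "chrom": chrom,
        "pos": base_pos + _SNP_SPACING_BP * np.arange(m),
        "a1": _ALLELES[0], "a2": _ALLELES[1],
        "maf": mafs,
    })
    out = {}
    for name, n in [("exposure", config.n_exposure_cohort),
                    ("outcome", config.n_outcome_cohort),
                    ("panel", config.n_panel)]:
        X = _ar1_dosages(n, mafs, config.ld_decay_rho, rng)
        _fix_monomorphic(X, mafs, rng, name)
        out[name] = X
    return Genotypes(snps=snps, X_exposure=out["exposure"],
                     X_outcome=out["outcome"], X_panel=out["panel"])


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

@dataclass
class LocusTruth:
    probe_id: str
    scenario: str
    true_b_xy: float
    theta_me: float
    theta_ey: float
    mediator_gene: str
    causal_snps: list[str]
    y_snps: list[str]

    REPORT_COLUMNS = ["probe_id", "scenario", "true_b_xy", "theta_me",
                      "theta_ey", "mediator_gene", "causal_snps", "y_snps"]


@dataclass
class Traits:
    """Per-individual trait values for both cohorts plus planted effects."""

    M_exposure: np.ndarray
    E_exposure: list[np.ndarray]   # mediator first, then decoy genes
    Y_exposure: np.ndarray
    M_outcome: np.ndarray
    Y_outcome: np.ndarray
    causal_idx: np.ndarray
    y_direct_idx: np.ndarray
    background_idx: np.ndarray
    beta_m: np.ndarray             # per-allele SNP -> M effects (causal_idx)
    beta_y: np.ndarray             # per-allele SNP -> Y direct effects (y_direct_idx)


def _spread_indices(m: int, k: int, lo_frac: float, hi_frac: float) -> np.ndarray:
    if k == 0:
        return np.array([], dtype=int)
    if k == 1:
        fr = np.array([lo_frac])
    else:
        fr = lo_frac + (hi_frac - lo_frac) * np.arange(k) / (k - 1)
    return np.unique(np.clip(np.round(fr * m).astype(int), 0, m - 1))


def _vexp_to_beta(h2: np.ndarray, var_g: np.ndarray) -> np.ndarray:
    return np.sqrt(np.asarray(h2) / np.asarray(var_g))


def locus_layout(config: ScenarioConfig) -> dict[str, np.ndarray]:
    """Deterministic placement of planted SNPs within the locus."""
    m = config.n_snps_per_locus
    causal = _spread_indices(m, config.n_causal_snps, 0.10, 0.55)
    background = _spread_indices(m, config.n_background_snps, 0.75, 0.95)
    if config.scenario == "linkage":
        a = int(round(0.40 * m))
        lag = max(1, int(round(math.log(0.55) / math.log(max(config.ld_decay_rho, 0.01)))))
        causal = np.array([a])
        y_direct = np.array([min(a + lag, m - 1)])
    elif config.scenario == "pleiotropy":
        y_direct = causal[:1]
    elif config.scenario == "reverse":
        causal = np.array([], dtype=int)
        y_direct = np.array([int(round(0.40 * m))])
    else:
        y_direct = np.array([], dtype=int)
    return {"causal": causal, "y_direct": y_direct, "background": background}


def simulate_traits(geno: Genotypes, config: ScenarioConfig,
                    rng: np.random.Generator | None = None) -> Traits:
    """Simulate methylation, expression and phenotype in both cohorts."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    layout = locus_layout(config)
    cidx, yidx, bgidx = layout["causal"], layout["y_direct"], layout["background"]
    var_g = geno.expected_var()

    # per-allele effects, shared across cohorts
    k = len(cidx)
    if k:
        w = np.arange(k, 0, -1, dtype=float)
        w /= w.sum()
        beta_m = _vexp_to_beta(config.theta_mx * w, var_g[cidx])
        beta_m *= rng.choice([-1.0, 1.0], size=k)
    else:
        beta_m = np.array([])
    beta_bg = _vexp_to_beta(np.full(len(bgidx), config.h2_background), var_g[bgidx]) \
        * rng.choice([-1.0, 1.0], size=len(bgidx))
    if config.scenario in ("pleiotropy", "linkage", "reverse"):
        beta_yd = _vexp_to_beta([config.h2_y_direct], var_g[yidx]) \
            * rng.choice([-1.0, 1.0], size=1)
    else:
        beta_yd = np.array([])

    h2bg = config.h2_background * len(bgidx)

    def build(X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
        n = X.shape[0]
        Xd = X.astype(np.float64, copy=False)
        g_m = Xd[:, cidx] @ beta_m if k else np.zeros(n)
        g_bg = Xd[:, bgidx] @ beta_bg if len(bgidx) else np.zeros(n)
        g_yd = Xd[:, yidx] @ beta_yd if len(beta_yd) else np.zeros(n)
        noise = lambda s: s * rng.standard_normal(n)  # noqa: E731

        if config.scenario == "reverse":
            sy = math.sqrt(max(1.0 - config.h2_y_direct - h2bg, 0.02))
            Y = g_yd + g_bg + noise(sy)
            M = config.theta_ym * Y + noise(math.sqrt(max(1.0 - config.theta_ym ** 2, 0.02)))
            E = [noise(1.0) for _ in range(1 + config.n_decoy_genes)]
            return M, E, Y

        M = g_m + noise(math.sqrt(max(1.0 - config.theta_mx, 0.02)))
        E_med = config.theta_me * M + noise(
            math.sqrt(max(1.0 - config.theta_me ** 2, 0.02)))
        E = [E_med] + [noise(1.0) for _ in range(config.n_decoy_genes)]
        struct = (config.theta_ey ** 2 + config.theta_my ** 2
                  + 2 * config.theta_ey * config.theta_my * config.theta_me
                  + config.h2_y_direct * bool(len(beta_yd)) + h2bg)
        sy = math.sqrt(max(1.0 - struct, 0.02))
        Y = (config.theta_ey * E_med + config.theta_my * M + g_yd + g_bg
             + noise(sy))
        return M, E, Y

    M_exp, E_exp, Y_exp = build(geno.X_exposure)
    M_out, _, Y_out = build(geno.X_outcome)
    return Traits(M_exposure=M_exp, E_exposure=E_exp, Y_exposure=Y_exp,
                  M_outcome=M_out, Y_outcome=Y_out,
                  causal_idx=cidx, y_direct_idx=yidx, background_idx=bgidx,
                  beta_m=beta_m, beta_y=beta_yd)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def association_scan(y: np.ndarray, X: np.ndarray,
                     snps: pd.DataFrame, trait_id: str) -> SummaryStatSet:
    """Per-SNP simple linear regression of ``y`` on each dosage column."""
    n = X.shape[0]
    Xd = X.astype(np.float64, copy=False)
    yc = y - y.mean()
    Xc = Xd - Xd.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    beta = (Xc.T @ yc) / sxx
    sse = np.maximum((yc @ yc) - beta ** 2 * sxx, 0.0)
    se = np.sqrt(sse / (n - 2) / sxx)
    z = beta / se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)
    df = pd.DataFrame({
        "snp_id": snps["snp_id"].to_numpy(),
        "chrom": snps["chrom"].to_numpy(),
        "pos": snps["pos"].to_numpy(),
        "effect_allele": snps["a1"].to_numpy(),
        "other_allele": snps["a2"].to_numpy(),
        "eaf": Xd.mean(axis=0) / 2.0,
        "beta": beta, "se": se, "pvalue": p,
        "n": float(n),
    })
    return SummaryStatSet(trait_id, df)


@dataclass
class LocusData:
    """In-memory view of one simulated locus, ready for analysis."""

    mqtl: QtlTable
    eqtls: list[QtlTable]
    gwas: SummaryStatSet
    panel: LDPanel
    truth: LocusTruth
    genotypes: Genotypes | None = None
    traits: Traits | None = None


def _panel_from_genotypes(geno: Genotypes) -> LDPanel:
    snp_index = list(zip(geno.snps["snp_id"], geno.snps["a1"], geno.snps["a2"]))
    return LDPanel(snp_index=snp_index,
                   dosages=geno.X_panel.astype(np.float64))


def simulate_locus(config: ScenarioConfig, locus_tag: str = "0",
                   chrom: str = "1", base_pos: int = 1_000_000,
                   with_expression: bool = True,
                   keep_raw: bool = False,
                   rng: np.random.Generator | None = None) -> LocusData:
    """Simulate one locus end to end and return analysis-ready objects."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    geno = simulate_genotypes(config, rng, locus_tag=locus_tag, chrom=chrom,
                              base_pos=base_pos)
    traits = simulate_traits(geno, config, rng)
    m = config.n_snps_per_locus
    probe_id = f"cg{locus_tag}"
    probe_pos = int(base_pos + _SNP_SPACING_BP * (m // 2))

    mqtl_set = association_scan(traits.M_exposure, geno.X_exposure, geno.snps,
                                probe_id)
    mqtl = QtlTable(probe_id, chrom, probe_pos, mqtl_set)
    eqtls: list[QtlTable] = []
    if with_expression:
        for g, E in enumerate(traits.E_exposure):
            gene_id = f"G{locus_tag}M" if g == 0 else f"G{locus_tag}D{g}"
            eset = association_scan(E, geno.X_exposure, geno.snps, gene_id)
            eqtls.append(QtlTable(gene_id, chrom, probe_pos + 1000, eset))
    gwas = association_scan(traits.Y_outcome, geno.X_outcome, geno.snps, "trait")

    snp_ids = geno.snps["snp_id"]
    truth = LocusTruth(
        probe_id=probe_id, scenario=config.scenario,
        true_b_xy=config.true_b_xy,
        theta_me=config.theta_me if config.scenario == "causal" else 0.0,
        theta_ey=config.theta_ey if config.scenario == "causal" else 0.0,
        mediator_gene=f"G{locus_tag}M" if with_expression else "NA",
        causal_snps=snp_ids.iloc[traits.causal_idx].tolist(),
        y_snps=snp_ids.iloc[np.concatenate(
            [traits.y_direct_idx, traits.background_idx]).astype(int)].tolist(),
    )
    return LocusData(mqtl=mqtl, eqtls=eqtls, gwas=gwas,
                     panel=_panel_from_genotypes(geno), truth=truth,
                     genotypes=geno if keep_raw else None,
                     traits=traits if keep_raw else None)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _ma_frame(sset: SummaryStatSet, with_pos: bool = False) -> pd.DataFrame:
    d = sset.df
    out = pd.DataFrame({
        "SNP": d["snp_id"], "A1": d["effect_allele"], "A2": d["other_allele"],
        "freq": d["eaf"], "b": d["beta"], "se": d["se"], "p": d["pvalue"],
        "N": d["n"],
    })
    if with_pos:
        out.insert(1, "Chr", d["chrom"])
        out.insert(2, "Pos", d["pos"].astype(int))
    return out


def _qtl_frame(tables: list[QtlTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        d = t.sset.df
        rows.append(pd.DataFrame({
            "Probe": t.probe_id, "ProbeChr": t.probe_chrom,
            "ProbePos": t.probe_pos,
            "SNP": d["snp_id"], "Chr": d["chrom"], "Pos": d["pos"].astype(int),
            "A1": d["effect_allele"], "A2": d["other_allele"],
            "freq": d["eaf"], "b": d["beta"], "se": d["se"], "p": d["pvalue"],
            "N": d["n"],
        }))
    return pd.concat(rows, ignore_index=True)


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def emit_sumstats(traits: Traits, geno: Genotypes, config: ScenarioConfig,
                  out_dir, locus_tag: str = "0") -> dict[str, Path]:
    """Write single-locus .ma / QTL / panel / truth files to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = config.n_snps_per_locus
    probe_id = f"cg{locus_tag}"
    probe_pos = int(geno.snps["pos"].iloc[m // 2])
    mqtl = QtlTable(probe_id, str(geno.snps["chrom"].iloc[0]), probe_pos,
                    association_scan(traits.M_exposure, geno.X_exposure,
                                     geno.snps, probe_id))
    eqtls = []
    for g, E in enumerate(traits.E_exposure):
        gene_id = f"G{locus_tag}M" if g == 0 else f"G{locus_tag}D{g}"
        eqtls.append(QtlTable(gene_id, str(geno.snps["chrom"].iloc[0]),
                              probe_pos + 1000,
                              association_scan(E, geno.X_exposure, geno.snps,
                                               gene_id)))
    gwas = association_scan(traits.Y_outcome, geno.X_outcome, geno.snps, "trait")

    paths = {
        "gwas": out / "gwas.ma",
        "mqtl": out / "mqtl.tsv",
        "eqtl": out / "eqtl.tsv",
        "panel": out / "panel.tsv",
        "truth": out / "truth.tsv",
    }
    _write_tsv(_ma_frame(gwas), paths["gwas"])
    _write_tsv(_qtl_frame([mqtl]), paths["mqtl"])
    _write_tsv(_qtl_frame(eqtls), paths["eqtl"])
    write_ld_panel(_panel_from_genotypes(geno), paths["panel"])
    snp_ids = geno.snps["snp_id"]
    truth = LocusTruth(
        probe_id=probe_id, scenario=config.scenario,
        true_b_xy=config.true_b_xy,
        theta_me=config.theta_me if config.scenario == "causal" else 0.0,
        theta_ey=config.theta_ey if config.scenario == "causal" else 0.0,
        mediator_gene=f"G{locus_tag}M",
        causal_snps=snp_ids.iloc[traits.causal_idx].tolist(),
        y_snps=snp_ids.iloc[np.concatenate(
            [traits.y_direct_idx, traits.background_idx]).astype(int)].tolist(),
    )
    from .sumstats import write_report
    write_report([truth], paths["truth"], kind=LocusTruth)
    return paths


# ---------------------------------------------------------------------------
# multi-probe fixture
# ---------------------------------------------------------------------------

@dataclass
class FixtureConfig:
    """A mixed bag of probes: planted causal loci plus confounding decoys."""

    n_causal: int = 3
    n_pleiotropy: int = 3
    n_linkage: int = 3
    n_reverse: int = 3
    n_null: int = 38
    n_exposure_cohort: int = 20_000
    n_outcome_cohort: int = 20_000
    n_panel: int = 503
    n_snps_per_locus: int = 200
    n_decoy_genes: int = 2
    seed: int = 0
    overrides: dict = field(default_factory=dict)  # scenario -> kwargs

    def scenario_sequence(self) -> list[str]:
        seq = (["causal"] * self.n_causal + ["pleiotropy"] * self.n_pleiotropy
               + ["linkage"] * self.n_linkage + ["reverse"] * self.n_reverse
               + ["null"] * self.n_null)
        return seq

    def locus_config(self, scenario: str) -> ScenarioConfig:
        kw = dict(
            n_exposure_cohort=self.n_exposure_cohort,
            n_outcome_cohort=self.n_outcome_cohort,
            n_panel=self.n_panel,
            n_snps_per_locus=self.n_snps_per_locus,
            n_decoy_genes=self.n_decoy_genes if scenario == "causal" else 0,
            seed=self.seed,
        )
        kw.update(self.overrides.get(scenario, {}))
        return ScenarioConfig.preset(scenario, **kw)


def simulate_fixture(fcfg: FixtureConfig, out_dir=None,
                     with_expression: bool = True) -> dict:
    """Simulate every locus of the fixture; optionally write the file set.

    Returns a dict with ``loci`` (list of :class:`LocusData`), ``truth``
    (DataFrame) and, when ``out_dir`` is given, ``paths``.
    """
    rng = np.random.default_rng(fcfg.seed)
    loci: list[LocusData] = []
    for i, scenario in enumerate(fcfg.scenario_sequence()):
        cfg = fcfg.locus_config(scenario)
        locus = simulate_locus(
            cfg, locus_tag=f"{i:05d}", chrom="1",
            base_pos=1_000_000 + i * 10_000_000,
            with_expression=with_expression and scenario == "causal",
            rng=rng)
        loci.append(locus)
    truth_df = pd.DataFrame([{
        "probe_id": l.truth.probe_id, "scenario": l.truth.scenario,
        "true_b_xy": l.truth.true_b_xy, "theta_me": l.truth.theta_me,
        "theta_ey": l.truth.theta_ey, "mediator_gene": l.truth.mediator_gene,
        "causal_snps": ",".join(l.truth.causal_snps) or "NA",
        "y_snps": ",".join(l.truth.y_snps) or "NA",
    } for l in loci])

    result = {"loci": loci, "truth": truth_df}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gwas": out / "gwas.ma", "mqtl": out / "mqtl.tsv",
            "eqtl": out / "eqtl.tsv", "panel": out / "panel.tsv",
            "truth": out / "truth.tsv", "rare": out / "rare_variants.tsv",
        }
        _write_tsv(pd.concat([_ma_frame(l.gwas) for l in loci],
                             ignore_index=True), paths["gwas"])
        _write_tsv(_qtl_frame([l.mqtl for l in loci]), paths["mqtl"])
        etabs = [t for l in loci for t in l.eqtls]
        if etabs:
            _write_tsv(_qtl_frame(etabs), paths["eqtl"])
        # panel: horizontally concatenate per-locus dosages
        snp_index = [s for l in loci for s in l.panel.snp_index]
        dosages = np.hstack([l.panel.dosages for l in loci])
        write_ld_panel(LDPanel(snp_index=snp_index, dosages=dosages),
                       paths["panel"])
        _write_tsv(truth_df, paths["truth"])
        _write_tsv(_rare_variant_frame(loci), paths["rare"])
        result["paths"] = paths
    return result


def _rare_variant_frame(loci: list[LocusData]) -> pd.DataFrame:
    """Plant rare variants near causal-probe mQTLs plus unmatched decoys."""
    rows = []
    v = 0
    for l in loci:
        if l.truth.scenario != "causal" or not l.truth.causal_snps:
            continue
        top = l.truth.causal_snps[0]
        pos = int(l.mqtl.sset.df.loc[top, "pos"])
        chrom = l.mqtl.probe_chrom
        rows.append(("rv%d" % v, chrom, pos, "C", "T", "obesity")); v += 1
        rows.append(("rv%d" % v, chrom, pos + 600, "G", "A", "obesity")); v += 1
    rows.append(("rv%d" % v, "99", 12_345, "A", "G", "obesity"))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref",
                                       "alt", "condition"])
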