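"""LD-aware multi-SNP Mendelian randomization by generalized least squares.

Instrument construction follows three criteria: exposure-significant SNPs
(``p < p_instrument``), pairwise linkage equilibrium enforced by greedy
p-ordered pruning (``r^2 < r2_prune``), and removal of pleiotropic outliers
(per-SNP heterogeneity ``p < p_outlier`` against a provisional fit, single
iteration).

The causal effect is the GLS combination of per-SNP ratio estimates
``b_i = b_zy_i / b_zx_i`` with delta-method variances

    v_i = (se_zy_i^2 + b_i^2 se_zx_i^2) / b_zx_i^2

and LD-induced covariances

    cov(b_i, b_j) = r_ij (se_zy_i se_zy_j + b_i b_j se_zx_i se_zx_j)
                    / (b_zx_i b_zx_j),

giving ``b_xy = (1' V^-1 b) / (1' V^-1 1)`` and
``se_xy = (1' V^-1 1)^{-1/2}``; p-values are two-sided normal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDPanel, SummaryStatSet, ld_matrix

logger = logging.getLogger(__name__)


@dataclass
class MrParams:
    p_instrument: float = 5e-8
    r2_prune: float = 0.05
    p_outlier: float = 0.01
    min_outlier_snps: int = 3
    p_forward: float = 5e-8
    p_reverse: float = 0.05
    ridge: float = 1e-10


@dataclass
class Instrument:
    """Harmonized exposure/outcome effects for independent significant SNPs."""

    exposure_id: str
    outcome_id: str
    snps: pd.DataFrame  # snp_id, b_zx, se_zx, b_zy, se_zy (ordered)
    ld: np.ndarray      # r over those SNPs, same order
    provenance: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(self, keep: np.ndarray) -> "Instrument":
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return Instrument(
            exposure_id=self.exposure_id, outcome_id=self.outcome_id,
            snps=self.snps.iloc[idx].reset_index(drop=True),
            ld=self.ld[np.ix_(idx, idx)],
            provenance=dict(self.provenance), flags=list(self.flags))


@dataclass
class NoInstrument:
    """Typed 'no instrument' outcome: the pair is reported, not crashed."""

    exposure_id: str
    outcome_id: str
    reason: str
    provenance: dict = field(default_factory=dict)


@dataclass
class MRResult:
    exposure_id: str
    outcome_id: str
    direction: str          # forward | reverse
    b_xy: float
    se_xy: float
    p_xy: float
    n_snps_used: int
    removed_snps: list = field(default_factory=list)  # (snp_id, outlier p)
    flags: list = field(default_factory=list)

    REPORT_COLUMNS = ["exposure_id", "outcome_id", "direction", "n_snps_used",
                      "b_xy", "se_xy", "p_xy", "removed_snps", "flags"]


@dataclass
class MrDecision:
    exposure_id: str
    outcome_id: str
    retained: bool
    reason: str
    forward_p: float
    reverse_p: float

    REPORT_COLUMNS = ["exposure_id", "outcome_id", "retained", "reason",
                      "forward_p", "reverse_p"]


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

def select_instrument(exposure: SummaryStatSet, outcome: SummaryStatSet,
                      panel: LDPanel, params: MrParams | None = None):
    """Exposure-significant SNPs pruned to pairwise linkage equilibrium.

    Greedy rule: sort ascending by exposure p (ties by snp id), accept a SNP
    iff its ``r^2`` with every already-accepted SNP is below ``r2_prune``.
    Inputs must be harmonized. Returns :class:`Instrument` or
    :class:`NoInstrument`.
    """
    params = params or MrParams()
    d = exposure.df
    cand = d[(d["pvalue"] < params.p_instrument)
             & d["snp_id"].isin(outcome.df.index)
             & d["snp_id"].map(lambda s: s in panel)]
    prov = {"candidates": len(cand), "removed_significance":
            len(d) - len(cand), "removed_ld": 0, "removed_pleiotropy": 0}
    if cand.empty:
        return NoInstrument(exposure.trait_id, outcome.trait_id,
                            "no exposure-significant SNPs", prov)
    # ascending p, but ranked on z^2 so ties from p-value underflow at the
    # float boundary cannot scramble the order
    cand = cand.reset_index(drop=True)
    cand["_z2"] = (cand["beta"] / cand["se"]) ** 2
    order = (cand.sort_values(["_z2", "snp_id"], ascending=[False, True],
                              kind="mergesort")["snp_id"].tolist())
    R = ld_matrix(panel, order)
    kept_idx: list[int] = []
    for i in range(len(order)):
        if all(R[i, j] ** 2 < params.r2_prune for j in kept_idx):
            kept_idx.append(i)
    prov["removed_ld"] = len(order) - len(kept_idx)
    kept = [order[i] for i in kept_idx]
    snps = pd.DataFrame({
        "snp_id": kept,
        "b_zx": d.loc[kept, "beta"].to_numpy(),
        "se_zx": d.loc[kept, "se"].to_numpy(),
        "b_zy": outcome.df.loc[kept, "beta"].to_numpy(),
        "se_zy": outcome.df.loc[kept, "se"].to_numpy(),
    })
    return Instrument(exposure_id=exposure.trait_id,
                      outcome_id=outcome.trait_id, snps=snps,
                      ld=R[np.ix_(kept_idx, kept_idx)], provenance=prov)


# ---------------------------------------------------------------------------
# GLS estimation
# ---------------------------------------------------------------------------

def _ratio_cov(instr: Instrument) -> tuple[np.ndarray, np.ndarray]:
    s = instr.snps
    bx = s["b_zx"].to_numpy()
    sx = s["se_zx"].to_numpy()
    by = s["b_zy"].to_numpy()
    sy = s["se_zy"].to_numpy()
    b = by / bx
    V = instr.ld * (np.outer(sy, sy) + np.outer(b, b) * np.outer(sx, sx)) \
        / np.outer(bx, bx)
    return b, V


def _gls_weights(V: np.ndarray, ridge: float) -> np.ndarray:
    ones = np.ones(V.shape[0])
    try:
        Vi1 = np.linalg.solve(V, ones)
    except np.linalg.LinAlgError:
        eps = ridge * float(np.mean(np.diag(V)))
        logger.info("gls_mr: singular covariance; adding ridge %.3e", eps)
        Vi1 = np.linalg.solve(V + eps * np.eye(V.shape[0]), ones)
    return Vi1


def gls_mr(instr: Instrument, direction: str = "forward",
           params: MrParams | None = None) -> MRResult:
    """GLS slope over per-SNP ratio estimates; Wald ratio when n = 1."""
    params = params or MrParams()
    if instr.n_snps < 1:
        raise ValueError("gls_mr requires at least one SNP")
    b, V = _ratio_cov(instr)
    if instr.n_snps == 1:
        b_xy = float(b[0])
        se_xy = float(math.sqrt(V[0, 0]))
    else:
        Vi1 = _gls_weights(V, params.ridge)
        denom = float(Vi1 @ np.ones_like(Vi1))
        b_xy = float(Vi1 @ b) / denom
        se_xy = 1.0 / math.sqrt(denom)
    z = b_xy / se_xy
    p = max(float(2.0 * stats.norm.sf(abs(z))), 1e-300)
    return MRResult(exposure_id=instr.exposure_id,
                    outcome_id=instr.outcome_id, direction=direction,
                    b_xy=b_xy, se_xy=se_xy, p_xy=p, n_snps_used=instr.n_snps,
                    removed_snps=[], flags=list(instr.flags))


def remove_pleiotropic(instr: Instrument, p_outlier: float = 0.01,
                       params: MrParams | None = None):
    """Single-iteration outlier removal against a provisional GLS fit.

    Returns ``(instrument, removed)`` where ``removed`` is a list of
    ``(snp_id, outlier_p)``. Below ``min_outlier_snps`` SNPs the instrument
    passes through unchanged with a flag.
    """
    params = params or MrParams()
    if instr.n_snps < params.min_outlier_snps:
        out = instr.subset(np.arange(instr.n_snps))
        out.flags.append("outlier test skipped (too few SNPs)")
        return out, []
    b, V = _ratio_cov(instr)
    Vi1 = _gls_weights(V, params.ridge)
    denom = float(Vi1 @ np.ones_like(Vi1))
    b_fit = float(Vi1 @ b) / denom
    w = Vi1 / denom                      # b_fit = w' b
    var_fit = 1.0 / denom
    cov_bi_fit = V @ w                   # cov(b_i, b_fit)
    var_d = np.diag(V) + var_fit - 2.0 * cov_bi_fit
    var_d = np.maximum(var_d, 1e-30)
    chi = (b - b_fit) ** 2 / var_d
    p_out = stats.chi2.sf(chi, df=1)
    drop = p_out < p_outlier
    removed = [(sid, float(pv)) for sid, pv in
               zip(instr.snps["snp_id"], p_out) if pv < p_outlier]
    if drop.all():
        return NoInstrument(instr.exposure_id, instr.outcome_id,
                            "all SNPs removed as pleiotropic outliers",
                            dict(instr.provenance)), removed
    out = instr.subset(~drop)
    out.provenance["removed_pleiotropy"] = int(drop.sum())
    return out, removed


def _run_mr(exposure: SummaryStatSet, outcome: SummaryStatSet,
            panel: LDPanel, params: MrParams | None, direction: str):
    params = params or MrParams()
    instr = select_instrument(exposure, outcome, panel, params)
    if isinstance(instr, NoInstrument):
        return instr
    instr, removed = remove_pleiotropic(instr, params.p_outlier, params)
    if isinstance(instr, NoInstrument):
        return instr
    res = gls_mr(instr, direction=direction, params=params)
    res.removed_snps = removed
    return res


def forward_mr(exposure: SummaryStatSet, outcome: SummaryStatSet,
               panel: LDPanel, params: MrParams | None = None):
    """Full forward analysis: selection, outlier removal, GLS."""
    return _run_mr(exposure, outcome, panel, params, "forward")


def reverse_mr(exposure: SummaryStatSet, outcome: SummaryStatSet,
               panel: LDPanel, params: MrParams | None = None):
    """Same machinery with exposure and outcome roles swapped: the outcome
    trait provides the instrument and the molecular trait is the outcome."""
    return _run_mr(outcome, exposure, panel, params, "reverse")


def bidirectional_filter(forward, reverse, params: MrParams | None = None,
                         ) -> MrDecision:
    """Retain a pair iff forward p < p_forward and reverse p >= p_reverse.

    A reverse analysis with no instrument provides no evidence of reverse
    causation and does not exclude the pair.
    """
    params = params or MrParams()
    if isinstance(forward, NoInstrument):
        return MrDecision(forward.exposure_id, forward.outcome_id, False,
                          "no forward instrument", float("nan"), float("nan"))
    rev_p = float("nan")
    if isinstance(reverse, MRResult):
        rev_p = reverse.p_xy
    if forward.p_xy >= params.p_forward:
        reason = "below forward threshold"
        retained = False
    elif isinstance(reverse, MRResult) and reverse.p_xy < params.p_reverse:
        reason = "reverse causation"
        retained = False
    else:
        retained = True
        reason = "ok" if isinstance(reverse, MRResult) else "ok (no reverse instrument)"
    return MrDecision(forward.exposure_id, forward.outcome_id, retained,
                      reason, forward.p_xy, rev_p)
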