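"""Expression mediation chains and rare-variant to mQTL positional matching.

The mediation logic is sign-level: the methylation -> expression and
expression -> phenotype MR effects imply a chain sign ``sign(b_me * b_ey)``
which is compared with the sign of the direct methylation -> phenotype MR
effect; consistency is only defined when both chain links pass their
significance thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .mr import MrParams, MRResult, NoInstrument, forward_mr
from .sumstats import (LDPanel, QtlTable, RareVariantTable, SummaryStatSet,
                       harmonize)

logger = logging.getLogger(__name__)


@dataclass
class MediationParams:
    p_chain_me: float = 5e-8       # methylation -> expression link
    alpha_ey: float = 0.05         # expression -> phenotype, divided by n genes
    mr: MrParams = field(default_factory=MrParams)


@dataclass
class MediationResult:
    probe_id: str
    gene_id: str
    b_me: float
    se_me: float
    p_me: float
    b_ey: float
    se_ey: float
    p_ey: float
    b_my_direct: float
    p_my_direct: float
    implied_sign: int          # sign(b_me * b_ey); 0 when indeterminate
    consistent: bool | None    # None = indeterminate
    is_mediator: bool
    note: str = ""

    REPORT_COLUMNS = ["probe_id", "gene_id", "b_me", "se_me", "p_me",
                      "b_ey", "se_ey", "p_ey", "b_my_direct", "p_my_direct",
                      "implied_sign", "consistent", "is_mediator", "note"]


@dataclass
class RareOverlapResult:
    variant_id: str
    chrom: str
    pos: int
    probe_id: str
    match_type: str            # exact_position | within_window
    window_bp: int
    mqtl_snp_ids: list = field(default_factory=list)

    REPORT_COLUMNS = ["variant_id", "chrom", "pos", "probe_id", "match_type",
                      "window_bp", "mqtl_snp_ids"]


def _link_mr(exposure: SummaryStatSet, outcome: SummaryStatSet,
             panel: LDPanel, params: MrParams):
    try:
        harm_e, harm_o = harmonize(exposure, outcome, panel)
    except Exception as exc:
        return NoInstrument(exposure.trait_id, outcome.trait_id, str(exc))
    return forward_mr(harm_e, harm_o, panel, params)


def mediation_chain(probe_qtl: QtlTable, gene_eqtl: QtlTable,
                    gwas: SummaryStatSet, panel: LDPanel,
                    params: MediationParams | None = None,
                    n_genes: int = 1) -> MediationResult:
    """Run the three MR analyses of one mediation chain and assess sign
    consistency.

    Links: exposure = methylation / outcome = expression; exposure =
    expression / outcome = phenotype; plus the direct methylation ->
    phenotype MR.
    """
    params = params or MediationParams()
    me = _link_mr(probe_qtl.sset, gene_eqtl.sset, panel, params.mr)
    ey = _link_mr(gene_eqtl.sset, gwas, panel, params.mr)
    my = _link_mr(probe_qtl.sset, gwas, panel, params.mr)

    def unpack(res):
        if isinstance(res, MRResult):
            return res.b_xy, res.se_xy, res.p_xy, ""
        return float("nan"), float("nan"), float("nan"), res.reason

    b_me, se_me, p_me, note_me = unpack(me)
    b_ey, se_ey, p_ey, note_ey = unpack(ey)
    b_my, _, p_my, note_my = unpack(my)

    alpha_ey = params.alpha_ey / max(n_genes, 1)
    me_sig = np.isfinite(p_me) and p_me < params.p_chain_me
    ey_sig = np.isfinite(p_ey) and p_ey < alpha_ey
    is_mediator = bool(me_sig and ey_sig)

    if is_mediator:
        implied = int(math.copysign(1, b_me * b_ey)) if b_me * b_ey != 0 else 0
        consistent = (int(math.copysign(1, b_my)) == implied
                      if np.isfinite(b_my) and b_my != 0 else None)
    else:
        implied, consistent = 0, None

    notes = "; ".join(x for x in
                      [f"m->e: {note_me}" if note_me else "",
                       f"e->y: {note_ey}" if note_ey else "",
                       f"m->y: {note_my}" if note_my else ""] if x)
    return MediationResult(
        probe_id=probe_qtl.probe_id, gene_id=gene_eqtl.probe_id,
        b_me=b_me, se_me=se_me, p_me=p_me,
        b_ey=b_ey, se_ey=se_ey, p_ey=p_ey,
        b_my_direct=b_my, p_my_direct=p_my,
        implied_sign=implied, consistent=consistent,
        is_mediator=is_mediator, note=notes)


def scan_mediators(probe_qtl: QtlTable, eqtls: list[QtlTable],
                   gwas: SummaryStatSet, panel: LDPanel,
                   params: MediationParams | None = None,
                   ) -> list[MediationResult]:
    """One :class:`MediationResult` per candidate gene in the region."""
    params = params or MediationParams()
    return [mediation_chain(probe_qtl, eqtl, gwas, panel, params,
                            n_genes=len(eqtls))
            for eqtl in sorted(eqtls, key=lambda t: t.probe_id)]


def rare_variant_overlap(rares: RareVariantTable, qtls: list[QtlTable],
                         window_bp: int = 1000,
                         mqtl_p_threshold: float | None = 5e-8,
                         ) -> list[RareOverlapResult]:
    """Match variant positions against mQTL SNP positions per probe.

    A variant matches a probe if its position equals an mQTL SNP position
    (``exact_position``) or lies within ``window_bp`` of any mQTL SNP for the
    probe (``within_window``). Only SNPs with QTL
    ``p < mqtl_p_threshold`` count as mQTLs (pass ``None`` to use every SNP
    in the table). Exact matches are reported first; matches are monotone
    non-decreasing in ``window_bp``.
    """
    results: list[RareOverlapResult] = []
    for qtl in sorted(qtls, key=lambda t: t.probe_id):
        d = qtl.sset.df
        if mqtl_p_threshold is not None:
            d = d[d["pvalue"] < mqtl_p_threshold]
        if d.empty:
            continue
        pos = d["pos"].to_numpy()
        for _, row in rares.df.iterrows():
            if str(row["chrom"]) != str(qtl.probe_chrom):
                continue
            dist = np.abs(pos - int(row["pos"]))
            exact = dist == 0
            near = dist <= window_bp
            if exact.any():
                results.append(RareOverlapResult(
                    variant_id=row["variant_id"], chrom=str(row["chrom"]),
                    pos=int(row["pos"]), probe_id=qtl.probe_id,
                    match_type="exact_position", window_bp=window_bp,
                    mqtl_snp_ids=d["snp_id"][exact].tolist()))
            elif near.any():
                results.append(RareOverlapResult(
                    variant_id=row["variant_id"], chrom=str(row["chrom"]),
                    pos=int(row["pos"]), probe_id=qtl.probe_id,
                    match_type="within_window", window_bp=window_bp,
                    mqtl_snp_ids=d["snp_id"][near].tolist()))
    results.sort(key=lambda r: (r.match_type != "exact_position",
                                r.variant_id, r.probe_id))
    return results
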