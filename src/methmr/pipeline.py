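"""Discovery/replication orchestration: colocalization scan -> forward MR ->
reverse-causation filter -> mediation -> rare-variant overlap.

Statistics for every stage are computed for every probe; pass/fail
classification is a pure function of the stored statistics and the decision
thresholds, so tightening a threshold can only shrink the passed set and the
cascade can be re-classified without recomputation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import coloc as _coloc
from . import mediation as _mediation
from . import mr as _mr
from .mr import Instrument, MrParams, MRResult, NoInstrument
from .sumstats import (LDPanel, QtlTable, SummaryStatSet, harmonize,
                       read_ld_panel, read_rare_variants, read_sumstats,
                       write_report)

logger = logging.getLogger(__name__)

FINAL_STATUSES = ("passed", "failed_coloc", "failed_heidi",
                  "failed_forward_mr", "failed_reverse", "no_instrument")


@dataclass
class PipelineConfig:
    mqtl: str = ""
    gwas: str = ""
    panel: str = ""
    eqtl: str | None = None
    variants: str | None = None
    replication_mqtl: str | None = None
    replication_gwas: str | None = None
    replication_panel: str | None = None
    p_smr: float = 5e-8
    p_heidi_keep: float = 0.05
    p_instrument: float = 5e-8
    r2_prune: float = 0.05
    p_outlier: float = 0.01
    p_forward: float = 5e-8
    p_reverse: float = 0.05
    cis_window_bp: int = 1_000_000
    rare_window_bp: int = 1000
    seed: int = 0
    out_dir: str = "methmr_out"

    def __post_init__(self):
        for name in ("p_smr", "p_heidi_keep", "p_instrument", "p_outlier",
                     "p_forward", "p_reverse"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if not (0 < self.r2_prune < 1):
            raise ValueError("r2_prune must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def mr_params(self) -> MrParams:
        return MrParams(p_instrument=self.p_instrument,
                        r2_prune=self.r2_prune, p_outlier=self.p_outlier,
                        p_forward=self.p_forward, p_reverse=self.p_reverse)

    def coloc_thresholds(self) -> _coloc.ColocThresholds:
        return _coloc.ColocThresholds(p_smr=self.p_smr,
                                      p_heidi_keep=self.p_heidi_keep,
                                      p_eligibility=self.p_instrument)


@dataclass
class DiscoveryRecord:
    probe_id: str
    probe_chr: str
    probe_pos: int
    top_snp: str
    b_smr: float
    p_smr: float
    p_heidi: float
    n_heidi_snps: int
    forward_b: float
    forward_se: float
    forward_p: float
    forward_n_snps: int
    reverse_p: float
    no_instrument_reason: str
    final_status: str
    replication_status: str = "not_run"     # replicated | failed | untestable
    replication_b: float = float("nan")
    replication_p: float = float("nan")

    REPORT_COLUMNS = ["probe_id", "probe_chr", "probe_pos", "top_snp",
                      "b_smr", "p_smr", "p_heidi", "n_heidi_snps",
                      "forward_b", "forward_se", "forward_p",
                      "forward_n_snps", "reverse_p", "no_instrument_reason",
                      "final_status", "replication_status", "replication_b",
                      "replication_p"]


def classify_record(rec: DiscoveryRecord, p_smr: float, p_heidi_keep: float,
                    p_forward: float, p_reverse: float) -> str:
    """Pure threshold cascade on precomputed statistics (paper stage order)."""
    if not np.isfinite(rec.p_smr) or rec.p_smr >= p_smr:
        return "failed_coloc"
    if not np.isfinite(rec.p_heidi) or rec.p_heidi <= p_heidi_keep:
        return "failed_heidi"
    if rec.no_instrument_reason:
        return "no_instrument"
    if not np.isfinite(rec.forward_p) or rec.forward_p >= p_forward:
        return "failed_forward_mr"
    if np.isfinite(rec.reverse_p) and rec.reverse_p < p_reverse:
        return "failed_reverse"
    return "passed"


def _probe_record(qtl: QtlTable, gwas: SummaryStatSet, panel: LDPanel,
                  config: PipelineConfig) -> DiscoveryRecord:
    rec = DiscoveryRecord(
        probe_id=qtl.probe_id, probe_chr=qtl.probe_chrom,
        probe_pos=qtl.probe_pos, top_snp="NA", b_smr=float("nan"),
        p_smr=float("nan"), p_heidi=float("nan"), n_heidi_snps=0,
        forward_b=float("nan"), forward_se=float("nan"),
        forward_p=float("nan"), forward_n_snps=0, reverse_p=float("nan"),
        no_instrument_reason="", final_status="failed_coloc")
    mr_params = config.mr_params()
    try:
        hq, hg = harmonize(qtl.sset, gwas, panel)
    except Exception as exc:
        logger.warning("probe %s: harmonization failed: %s", qtl.probe_id, exc)
        rec.no_instrument_reason = str(exc)
        rec.final_status = "no_instrument"
        return rec
    hqt = QtlTable(qtl.probe_id, qtl.probe_chrom, qtl.probe_pos, hq)

    # colocalization statistics
    try:
        smr = _coloc.smr_test(hqt, hg, p_eligibility=config.p_instrument)
        rec.top_snp, rec.b_smr, rec.p_smr = smr.top_snp, smr.b_smr, smr.p_smr
        heidi = _coloc.heidi_test(hqt, hg, panel, smr.top_snp,
                                  config.coloc_thresholds().heidi)
        rec.p_heidi, rec.n_heidi_snps = heidi.p_heidi, heidi.n_snps
    except _coloc.ProbeSkipped as exc:
        logger.info("probe %s: %s", qtl.probe_id, exc)

    # forward and reverse MR statistics (computed unconditionally)
    fwd = _mr.forward_mr(hq, hg, panel, mr_params)
    if isinstance(fwd, NoInstrument):
        rec.no_instrument_reason = fwd.reason
    else:
        rec.forward_b, rec.forward_se = fwd.b_xy, fwd.se_xy
        rec.forward_p, rec.forward_n_snps = fwd.p_xy, fwd.n_snps_used
    rev = _mr.reverse_mr(hq, hg, panel, mr_params)
    if isinstance(rev, MRResult):
        rec.reverse_p = rev.p_xy

    rec.final_status = classify_record(rec, config.p_smr, config.p_heidi_keep,
                                       config.p_forward, config.p_reverse)
    return rec


def _genes_near(probe: QtlTable, eqtls: list[QtlTable],
                window_bp: int) -> list[QtlTable]:
    return [g for g in eqtls
            if g.probe_chrom == probe.probe_chrom
            and abs(g.probe_pos - probe.probe_pos) <= window_bp]


def run_discovery(config: PipelineConfig,
                  write_outputs: bool = True) -> list[DiscoveryRecord]:
    """Execute the discovery cascade over every probe in the mQTL file.

    Writes ``discovery.tsv`` (always), ``mediation.tsv`` (when an eQTL file
    is configured) and ``rare_overlap.tsv`` (when a variant table is
    configured) to ``config.out_dir``. Deterministic given config and seed.
    """
    for attr in ("mqtl", "gwas", "panel"):
        p = getattr(config, attr)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"config.{attr}: missing input file {p!r}")
    for attr in ("eqtl", "variants"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config.{attr}: missing input file {p!r}")

    qtls = read_sumstats(config.mqtl, format="qtl",
                         cis_window_bp=config.cis_window_bp)
    gwas = read_sumstats(config.gwas, format="ma", trait_id="trait")
    panel = read_ld_panel(config.panel)
    eqtls = (read_sumstats(config.eqtl, format="qtl",
                           cis_window_bp=config.cis_window_bp)
             if config.eqtl else [])
    rares = read_rare_variants(config.variants) if config.variants else None

    records = [_probe_record(q, gwas, panel, config)
               for q in sorted(qtls, key=lambda t: t.probe_id)]
    for rec in records:
        logger.info("discovery: probe=%s status=%s p_smr=%.3g p_heidi=%.3g "
                    "forward_p=%.3g reverse_p=%.3g", rec.probe_id,
                    rec.final_status, rec.p_smr, rec.p_heidi, rec.forward_p,
                    rec.reverse_p)

    mediations: list[_mediation.MediationResult] = []
    overlaps: list[_mediation.RareOverlapResult] = []
    passed_ids = {r.probe_id for r in records if r.final_status == "passed"}
    passed_qtls = [q for q in qtls if q.probe_id in passed_ids]
    if eqtls:
        med_params = _mediation.MediationParams(mr=config.mr_params())
        for q in sorted(passed_qtls, key=lambda t: t.probe_id):
            genes = _genes_near(q, eqtls, config.cis_window_bp)
            mediations.extend(_mediation.scan_mediators(
                q, genes, gwas, panel, med_params))
    if rares is not None:
        overlaps = _mediation.rare_variant_overlap(
            rares, passed_qtls, window_bp=config.rare_window_bp)

    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(records, out / "discovery.tsv", kind=DiscoveryRecord)
        if eqtls:
            write_report(mediations, out / "mediation.tsv",
                         kind=_mediation.MediationResult)
        if rares is not None:
            write_report(overlaps, out / "rare_overlap.tsv",
                         kind=_mediation.RareOverlapResult)
    return records


def run_replication(records: list[DiscoveryRecord], config: PipelineConfig,
                    write_outputs: bool = True) -> list[DiscoveryRecord]:
    """Repeat forward MR on replication files for discovery-passed probes.

    A probe replicates iff the replication effect has the same sign as the
    discovery effect and ``p < 0.05 / n_passed``. Probes absent from the
    replication data are ``untestable``.
    """
    for attr in ("replication_mqtl", "replication_gwas", "replication_panel"):
        p = getattr(config, attr)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"config.{attr}: missing input file {p!r}")
    qtls = {q.probe_id: q for q in read_sumstats(
        config.replication_mqtl, format="qtl",
        cis_window_bp=config.cis_window_bp)}
    gwas = read_sumstats(config.replication_gwas, format="ma",
                         trait_id="trait")
    panel = read_ld_panel(config.replication_panel)
    passed = [r for r in records if r.final_status == "passed"]
    alpha = 0.05 / max(len(passed), 1)
    mr_params = config.mr_params()
    for rec in passed:
        q = qtls.get(rec.probe_id)
        if q is None:
            rec.replication_status = "untestable"
            continue
        try:
            hq, hg = harmonize(q.sset, gwas, panel)
            res = _mr.forward_mr(hq, hg, panel, mr_params)
        except Exception as exc:
            logger.warning("replication: probe %s failed: %s",
                           rec.probe_id, exc)
            rec.replication_status = "untestable"
            continue
        if isinstance(res, NoInstrument):
            rec.replication_status = "untestable"
            continue
        rec.replication_b, rec.replication_p = res.b_xy, res.p_xy
        same_sign = np.sign(res.b_xy) == np.sign(rec.forward_b)
        rec.replication_status = ("replicated" if same_sign
                                  and res.p_xy < alpha else "failed")
    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(records, out / "replication.tsv", kind=DiscoveryRecord)
    return records


def plot_mr(instr: Instrument, result: MRResult, path) -> None:
    """Effect-vs-effect scatter with SE bars and the origin-anchored fit line."""
    if isinstance(instr, NoInstrument) or instr.n_snps < 1:
        raise ValueError("cannot plot an empty instrument")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = instr.snps
    fig, ax = plt.subplots(figsize=(4.5, 4.0))
    ax.errorbar(s["b_zx"], s["b_zy"], xerr=s["se_zx"], yerr=s["se_zy"],
                fmt="o", ms=4, color="#30598c", ecolor="#9db8d6", lw=1,
                capsize=2)
    xmax = 1.1 * float(np.abs(s["b_zx"]).max())
    xs = np.array([-xmax, xmax])
    ax.plot(xs, result.b_xy * xs, "--", color="#b03a3a", lw=1.2)
    ax.axhline(0, color="0.85", lw=0.8, zorder=0)
    ax.axvline(0, color="0.85", lw=0.8, zorder=0)
    ax.set_xlabel(f"SNP effect on {instr.exposure_id}")
    ax.set_ylabel(f"SNP effect on {instr.outcome_id}")
    ax.set_title(f"b_xy = {result.b_xy:.3g} (p = {result.p_xy:.2g})",
                 fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
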