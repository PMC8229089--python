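"""Reading, validation, harmonization and LD computation for summary statistics.

File dialects (all plain text, whitespace- or tab-delimited, mandatory header):

* ``.ma`` summary statistics: columns ``SNP A1 A2 freq b se p N`` (optional
  extra ``Chr Pos`` columns are honoured when present).
* QTL tables: columns ``Probe ProbeChr ProbePos SNP Chr Pos A1 A2 freq b se p N``;
  one file may hold several probes, rows are grouped by probe identifier.
* LD panel: first column ``IID`` (individual id), subsequent column headers
  ``snpid:A1:A2`` and cells holding effect-allele dosage counts in [0, 2].
* Rare-variant table: columns ``variant_id chrom pos ref alt condition``.

Coordinates are 1-based inclusive. Missing effect-allele frequency may be
encoded as ``NA`` or ``.``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
QTL_COLUMNS = ["Probe", "ProbeChr", "ProbePos", "SNP", "Chr", "Pos"] + MA_COLUMNS[1:]
RARE_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "condition"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: internal column names used by :class:`SummaryStatSet` dataframes
_SS_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
               "eaf", "beta", "se", "pvalue", "n"]


class SumStatsError(ValueError):
    """Malformed summary-statistics input."""


class MonomorphicSNPError(ValueError):
    """A requested SNP has zero dosage variance in the LD panel."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """A single per-SNP association record."""

    snp_id: str
    chrom: str | None
    pos: int | None
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float


class SummaryStatSet:
    """Per-SNP association records for one trait or molecular probe.

    Backed by a :class:`pandas.DataFrame` with columns ``snp_id, chrom, pos,
    effect_allele, other_allele, eaf, beta, se, pvalue, n`` indexed by
    ``snp_id`` (unique).
    """

    def __init__(self, trait_id: str, df: pd.DataFrame):
        if df["snp_id"].duplicated().any():
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
            raise SumStatsError(
                f"duplicate snp_id in set '{trait_id}': {dups[:5]}")
        self.trait_id = trait_id
        self.df = df.reset_index(drop=True).set_index("snp_id", drop=False)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.df.index

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def record(self, snp_id: str) -> SummaryStatRecord:
        row = self.df.loc[snp_id]
        return SummaryStatRecord(
            snp_id=row["snp_id"],
            chrom=None if pd.isna(row["chrom"]) else str(row["chrom"]),
            pos=None if pd.isna(row["pos"]) else int(row["pos"]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pvalue=float(row["pvalue"]),
            n=float(row["n"]),
        )

    @property
    def records(self) -> list[SummaryStatRecord]:
        return [self.record(s) for s in self.df.index]

    def subset(self, snp_ids: Sequence[str]) -> "SummaryStatSet":
        return SummaryStatSet(self.trait_id, self.df.loc[list(snp_ids)].copy())

    def zscores(self) -> pd.Series:
        return self.df["beta"] / self.df["se"]


@dataclass
class QtlTable:
    """cis-QTL summary statistics for one probe/gene."""

    probe_id: str
    probe_chrom: str
    probe_pos: int
    sset: SummaryStatSet

    def __post_init__(self):
        if self.sset.trait_id != self.probe_id:
            self.sset.trait_id = self.probe_id

    def validate_cis(self, window_bp: int = 1_000_000) -> None:
        pos = self.sset.df["pos"]
        if pos.isna().any():
            raise SumStatsError(
                f"probe {self.probe_id}: QTL records lack positions")
        off = (pos - self.probe_pos).abs()
        bad = off[off > window_bp]
        if len(bad):
            raise SumStatsError(
                f"probe {self.probe_id}: {len(bad)} records outside the "
                f"±{window_bp} bp cis window (first: {bad.index[0]})")


@dataclass
class LDPanel:
    """Reference genotype dosages used to estimate allelic correlation.

    ``snp_index`` gives, per column, ``(snp_id, effect_allele, other_allele)``;
    dosages count copies of the effect allele.
    """

    snp_index: list[tuple[str, str, str]]
    dosages: np.ndarray  # (n_individuals, n_snps), values in [0, 2]
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_index):
            raise ValueError("dosage matrix does not match snp_index")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosage values must lie in [0, 2]")
        self._col = {s[0]: j for j, s in enumerate(self.snp_index)}
        if not self.individual_ids:
            self.individual_ids = [f"I{i}" for i in range(self.dosages.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._col

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self._col[snp_id]]

    def alleles(self, snp_id: str) -> tuple[str, str]:
        _, a1, a2 = self.snp_index[self._col[snp_id]]
        return a1, a2

    def eaf(self, snp_id: str) -> float:
        return float(self.column(snp_id).mean() / 2.0)


@dataclass
class RareVariantTable:
    """Positions of (typically rare) variants to be matched against mQTLs."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in RARE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumStatsError(f"rare-variant table missing columns {missing}")
        if (self.df["pos"] < 1).any():
            raise SumStatsError("rare-variant positions must be >= 1")

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")


def _validate_numeric(df: pd.DataFrame, colmap: dict[str, str], path) -> list[str]:
    """Coerce numeric columns in-place; return per-row error strings.

    Line numbers are 1-based file lines (header is line 1).
    """
    errors: list[str] = []
    for src, kind in colmap.items():
        coerced = pd.to_numeric(df[src].replace({"NA": np.nan, ".": np.nan}),
                                errors="coerce")
        bad = coerced.isna() & df[src].notna() & ~df[src].isin(["NA", "."])
        for i in df.index[bad]:
            errors.append(f"{path}:line {i + 2}: non-numeric {src}={df.loc[i, src]!r}")
        df[src] = coerced
    return errors


def _check_record_invariants(df: pd.DataFrame, path,
                             check_p_consistency: bool,
                             p_rel_tol: float = 0.20) -> list[str]:
    errors: list[str] = []

    def err(mask, msg):
        for i in df.index[mask]:
            errors.append(f"{path}:line {i + 2}: {msg(df.loc[i])}")

    err(~(df["se"] > 0), lambda r: f"se must be > 0 (snp {r['snp_id']}, se={r['se']})")
    eaf_bad = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    err(eaf_bad, lambda r: f"eaf outside [0,1] (snp {r['snp_id']})")
    err(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)),
        lambda r: f"p-value outside (0,1] (snp {r['snp_id']})")
    err(~(df["n"] >= 2), lambda r: f"sample size < 2 (snp {r['snp_id']})")
    err(df["effect_allele"] == df["other_allele"],
        lambda r: f"identical alleles (snp {r['snp_id']})")

    if check_p_consistency:
        # compare on the z scale: a rounded printed p like 3e-10 should still
        # pass, while a grossly inconsistent (b, se, p) triple should not
        ok = (df["se"] > 0) & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
        z_obs = (df["beta"].abs() / df["se"])[ok]
        z_p = pd.Series(stats.norm.isf(df.loc[ok, "pvalue"] / 2.0), index=z_obs.index)
        # skip near z = 0 (relative comparison meaningless) and where p is at
        # the float underflow boundary (z implied by p saturates ~37)
        check = (z_obs > 1.0) & (df.loc[ok, "pvalue"] > 1e-290)
        rel = (z_p - z_obs).abs() / z_obs
        bad = check & (rel > p_rel_tol)
        for i in bad.index[bad]:
            errors.append(
                f"{path}:line {i + 2}: p-value inconsistent with |beta/se| "
                f"(snp {df.loc[i, 'snp_id']}: |z|={z_obs[i]:.3g}, "
                f"z implied by p={z_p[i]:.3g})")
    return errors


def _to_internal(df: pd.DataFrame, has_pos: bool) -> pd.DataFrame:
    out = pd.DataFrame({
        "snp_id": df["SNP"].astype(str),
        "chrom": df["Chr"].astype(str) if has_pos else pd.Series([None] * len(df)),
        "pos": pd.to_numeric(df["Pos"], errors="coerce") if has_pos
               else pd.Series([np.nan] * len(df)),
        "effect_allele": df["A1"].astype(str).str.upper(),
        "other_allele": df["A2"].astype(str).str.upper(),
        "eaf": df["freq"], "beta": df["b"], "se": df["se"],
        "pvalue": df["p"], "n": df["N"],
    })
    return out


def read_sumstats(path, format: str = "ma", trait_id: str | None = None,
                  validate: bool = True, check_p_consistency: bool = True,
                  cis_window_bp: int = 1_000_000):
    """Read summary statistics.

    Parameters
    ----------
    path:
        text file in ``.ma`` or QTL dialect (gzip transparent via pandas).
    format:
        ``"ma"`` returns one :class:`SummaryStatSet`; ``"qtl"`` returns a
        list of :class:`QtlTable`, one per probe, ordered by probe id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _read_table(path)

    if format == "ma":
        missing = [c for c in MA_COLUMNS if c not in raw.columns]
        if missing:
            raise SumStatsError(f"{path}: missing column(s) {missing} "
                                f"(expected header {' '.join(MA_COLUMNS)})")
        has_pos = "Chr" in raw.columns and "Pos" in raw.columns
        errors = _validate_numeric(raw, {c: "f" for c in ["freq", "b", "se", "p", "N"]}, path)
        df = _to_internal(raw, has_pos)
        if validate:
            errors += _check_record_invariants(df, path, check_p_consistency)
        if errors:
            raise SumStatsError("invalid rows:\n" + "\n".join(errors))
        return SummaryStatSet(trait_id or path.stem, df)

    if format == "qtl":
        missing = [c for c in QTL_COLUMNS if c not in raw.columns]
        if missing:
            raise SumStatsError(f"{path}: missing column(s) {missing} "
                                f"(expected header {' '.join(QTL_COLUMNS)})")
        errors = _validate_numeric(
            raw, {c: "f" for c in ["freq", "b", "se", "p", "N", "ProbePos", "Pos"]}, path)
        if errors:
            raise SumStatsError("invalid rows:\n" + "\n".join(errors))
        tables: list[QtlTable] = []
        for probe_id, grp in raw.groupby("Probe", sort=True):
            df = _to_internal(grp.reset_index(drop=False).rename(
                columns={"index": "_line"}), has_pos=True)
            df.index = grp.index  # keep file line numbers for error messages
            if validate:
                errs = _check_record_invariants(df, path, check_p_consistency)
                if errs:
                    raise SumStatsError("invalid rows:\n" + "\n".join(errs))
            tab = QtlTable(
                probe_id=str(probe_id),
                probe_chrom=str(grp["ProbeChr"].iloc[0]),
                probe_pos=int(float(grp["ProbePos"].iloc[0])),
                sset=SummaryStatSet(str(probe_id), df.reset_index(drop=True)),
            )
            if validate:
                tab.validate_cis(cis_window_bp)
            tables.append(tab)
        return tables

    raise ValueError(f"unknown format {format!r} (expected 'ma' or 'qtl')")


def read_ld_panel(path) -> LDPanel:
    """Read a dosage TSV (first column individual id, headers ``snp:A1:A2``)."""
    df = pd.read_csv(path, sep=r"\s+")
    iids = df.iloc[:, 0].astype(str).tolist()
    snp_index = []
    for col in df.columns[1:]:
        parts = str(col).split(":")
        if len(parts) == 3:
            snp_index.append((parts[0], parts[1].upper(), parts[2].upper()))
        else:
            snp_index.append((str(col), "N", "N"))  # alleles unknown
    dosages = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return LDPanel(snp_index=snp_index, dosages=dosages, individual_ids=iids)


def write_ld_panel(panel: LDPanel, path) -> None:
    cols = [f"{s}:{a1}:{a2}" for s, a1, a2 in panel.snp_index]
    df = pd.DataFrame(panel.dosages, columns=cols)
    df.insert(0, "IID", panel.individual_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_rare_variants(path) -> RareVariantTable:
    df = _read_table(path)
    missing = [c for c in RARE_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsError(f"{path}: missing column(s) {missing}")
    df = df.copy()
    df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
    return RareVariantTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    comp = a1.map(_COMPLEMENT)
    return comp == a2


def _align_to_panel(sset: SummaryStatSet, panel: LDPanel, snp_ids: list[str],
                    ambiguous_policy: str, freq_margin: float) -> pd.DataFrame:
    """Return the subset of ``sset`` aligned to the panel's allele orientation.

    Rows that cannot be aligned are dropped (and logged).
    """
    df = sset.df.loc[snp_ids].copy()
    pa = pd.DataFrame(
        [(s,) + panel.alleles(s) for s in snp_ids],
        columns=["snp_id", "pA1", "pA2"]).set_index("snp_id")
    df = df.join(pa)

    same = (df["effect_allele"] == df["pA1"]) & (df["other_allele"] == df["pA2"])
    swapped = (df["effect_allele"] == df["pA2"]) & (df["other_allele"] == df["pA1"])
    ambiguous = _is_ambiguous(df["effect_allele"], df["other_allele"])

    keep = same | swapped
    mismatched = ~keep
    if mismatched.any():
        for s in df.index[mismatched][:20]:
            logger.warning("harmonize: allele mismatch for %s in set %s "
                           "(%s/%s vs panel %s/%s) -- dropped", s,
                           sset.trait_id, df.loc[s, "effect_allele"],
                           df.loc[s, "other_allele"], df.loc[s, "pA1"],
                           df.loc[s, "pA2"])

    if ambiguous_policy == "drop":
        drop_amb = ambiguous & keep
        if drop_amb.any():
            logger.info("harmonize: dropping %d strand-ambiguous SNPs from %s",
                        int(drop_amb.sum()), sset.trait_id)
        keep &= ~ambiguous
    elif ambiguous_policy == "freq":
        # allele labels are unreliable for A/T and C/G SNPs; orient by
        # comparing minor-allele side with the panel frequency
        panel_eaf = pd.Series({s: panel.eaf(s) for s in df.index})
        informative = (df["eaf"].notna()
                       & ((df["eaf"] - 0.5).abs() > freq_margin)
                       & ((panel_eaf - 0.5).abs() > freq_margin))
        keep &= ~ambiguous | informative
        freq_flip = ambiguous & informative & \
            ((df["eaf"] - 0.5) * (panel_eaf - 0.5) < 0)
        swapped = (swapped & ~ambiguous) | freq_flip
        same = keep & ~swapped
    else:
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")

    df = df[keep]
    flip = swapped[keep]
    df.loc[flip, "beta"] = -df.loc[flip, "beta"]
    df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
    df.loc[flip, ["effect_allele", "other_allele"]] = \
        df.loc[flip, ["pA1", "pA2"]].to_numpy()
    return df.drop(columns=["pA1", "pA2"])


def harmonize(a: SummaryStatSet, b: SummaryStatSet, panel: LDPanel,
              ambiguous_policy: str = "drop", freq_margin: float = 0.08,
              ) -> tuple[SummaryStatSet, SummaryStatSet]:
    """Intersect two sets and align both to the panel's allele orientation.

    For SNPs whose A1/A2 are swapped relative to the panel the effect sign is
    flipped and ``eaf`` replaced by ``1 - eaf``. Strand-ambiguous SNPs (A/T,
    C/G) are dropped by default, or oriented by allele frequency under
    ``ambiguous_policy="freq"`` (requires ``|eaf - 0.5| > freq_margin`` in
    both the record and the panel). Allele mismatches are dropped with a log
    entry. Idempotent.
    """
    common = [s for s in a.snp_ids if s in b and s in panel]
    if not common:
        raise SumStatsError(
            f"harmonize: no shared SNPs between {a.trait_id} and {b.trait_id} "
            f"(after restricting to the LD panel)")
    da = _align_to_panel(a, panel, common, ambiguous_policy, freq_margin)
    db = _align_to_panel(b, panel, common, ambiguous_policy, freq_margin)
    final = [s for s in common if s in da.index and s in db.index]
    if not final:
        raise SumStatsError(
            f"harmonize: empty intersection between {a.trait_id} and "
            f"{b.trait_id} after allele alignment")
    return (SummaryStatSet(a.trait_id, da.loc[final].reset_index(drop=True)),
            SummaryStatSet(b.trait_id, db.loc[final].reset_index(drop=True)))


def harmonize_qtl(qtl: QtlTable, gwas: SummaryStatSet, panel: LDPanel,
                  **kw) -> tuple[QtlTable, SummaryStatSet]:
    qs, gs = harmonize(qtl.sset, gwas, panel, **kw)
    return QtlTable(qtl.probe_id, qtl.probe_chrom, qtl.probe_pos, qs), gs


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_matrix(panel: LDPanel, snps: Sequence[str],
              shrinkage: float = 0.0) -> np.ndarray:
    """Pairwise allelic correlation ``r`` between the requested SNPs.

    ``r[i, j]`` is the Pearson correlation of effect-allele dosage columns;
    the diagonal is exactly 1. Optional ``shrinkage`` moves the matrix toward
    the identity, ``(1 - s) R + s I``, guaranteeing positive definiteness for
    ``s > 0``.
    """
    missing = [s for s in snps if s not in panel]
    if missing:
        raise KeyError(f"SNPs absent from LD panel: {missing[:5]}")
    if panel.n_individuals < 30:
        warnings.warn(
            f"LD panel has only {panel.n_individuals} individuals; "
            "correlation estimates will be noisy", stacklevel=2)
    X = np.column_stack([panel.column(s) for s in snps])
    sd = X.std(axis=0)
    mono = np.flatnonzero(sd == 0)
    if mono.size:
        raise MonomorphicSNPError(
            f"monomorphic SNP(s) in panel: {[snps[i] for i in mono[:5]]}")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    if shrinkage:
        R = (1.0 - shrinkage) * R + shrinkage * np.eye(len(snps))
    np.fill_diagonal(R, 1.0)
    return R


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _result_columns(kind) -> list[str]:
    cols = getattr(kind, "REPORT_COLUMNS", None)
    if cols is not None:
        return list(cols)
    return [f.name for f in dataclasses.fields(kind)]


def _cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.10g}"
    if isinstance(value, (list, tuple)):
        return ",".join(str(v) for v in value) if value else "NA"
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    return str(value)


def write_report(results: Iterable, path, kind=None) -> None:
    """Write a deterministic TSV report for a homogeneous result collection.

    ``kind`` (a result dataclass) is required when ``results`` is empty so a
    header-only file can still be produced. Floats are written with 10
    significant digits and round-trip through :func:`read_report`.
    """
    results = list(results)
    if kind is None:
        if not results:
            raise ValueError("empty result list: pass kind= to emit a header")
        kind = type(results[0])
    cols = _result_columns(kind)
    lines = ["\t".join(cols)]
    for r in results:
        row = r if isinstance(r, dict) else dataclasses.asdict(r)
        lines.append("\t".join(_cell(row.get(c)) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_report(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
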