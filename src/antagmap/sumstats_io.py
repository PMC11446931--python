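"""Reading, validation, and allele harmonization of GWAS summary statistics.

Summary statistics arrive as one whitespace- or tab-delimited table per
image-derived phenotype (IDP), with a header and a configurable column
mapping. Effects for cortical IDPs are regression betas in phenotype units;
subcortical-volume tables report Z-scores and may lack a standard error.

Harmonization aligns each record's signed effect to a target SNP's risk
allele: if the record's effect allele already is the risk allele the record
is unchanged, if the *other* allele is the risk allele the alleles are
swapped and the effect sign negated. Strand-ambiguous pairs (A/T, C/G)
cannot be resolved without allele-frequency data, which these curated target
sets do not carry; the default policy warns and accepts them as-is.

A target SNP absent from a given table may be substituted by a pre-annotated
LD proxy when its r² exceeds the admissibility threshold (default 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from antagmap.errors import (
    AlleleMismatchError,
    ConfigError,
    InputError,
    StrandAmbiguityError,
)

#: disorder codes of the eight-disorder cross-disorder meta-analysis
DISORDER_CODES = frozenset({"ADHD", "ANO", "ASD", "BIP", "MDD", "OCD", "SCZ", "TS"})

#: missing-value tokens accepted in sumstats tables (dialects vary)
NA_TOKENS = ["NA", "NaN", "nan", ".", ""]

#: complement map used to detect strand-ambiguous allele pairs
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SumstatsRecord:
    """One SNP's association with one IDP, as read from a summary table."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    effect: float
    pvalue: float
    se: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self):
        if not (0.0 < self.pvalue <= 1.0):
            raise InputError(f"{self.snp_id}: p-value {self.pvalue} outside (0, 1]")
        if self.effect_allele == self.other_allele:
            raise InputError(f"{self.snp_id}: effect and other allele identical")
        if self.pos < 1:
            raise InputError(f"{self.snp_id}: position {self.pos} < 1 (1-based)")


@dataclass(frozen=True)
class IdpDescriptor:
    """An image-derived phenotype: an atlas region plus a measure type."""

    idp_id: str
    region: str
    measure: str  # SA | CT | VOL
    source: str

    def __post_init__(self):
        if self.measure not in {"SA", "CT", "VOL"}:
            raise ConfigError(f"{self.idp_id}: measure must be SA/CT/VOL, got {self.measure!r}")


@dataclass(frozen=True)
class TargetSnp:
    """An antagonistic target SNP with its risk/protective annotation."""

    snp_id: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    disorder_risk: str
    disorder_protective: str
    proxy_id: Optional[str] = None
    proxy_r2: Optional[float] = None

    def __post_init__(self):
        if self.proxy_r2 is not None and not (0.0 <= self.proxy_r2 <= 1.0):
            raise InputError(f"{self.snp_id}: proxy r² {self.proxy_r2} outside [0, 1]")
        for code in (self.disorder_risk, self.disorder_protective):
            if code not in DISORDER_CODES:
                raise InputError(f"{self.snp_id}: unknown disorder code {code!r}")


@dataclass
class ReadResult:
    """Records retained by :func:`read_sumstats` plus drop bookkeeping."""

    records: list
    n_dropped: int


@dataclass(frozen=True)
class ProxyResolution:
    """Outcome of proxy substitution for one target SNP."""

    target_id: str
    used_id: Optional[str]
    r2: Optional[float]
    status: str  # direct | proxy | unresolvable


DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "effect": "EFFECT",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

_MANDATORY = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "effect", "pvalue")


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True for allele pairs indistinguishable from their reverse complement."""
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def read_sumstats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    idp: Optional[IdpDescriptor] = None,
) -> ReadResult:
    """Read one summary-statistics table into validated records.

    Rows with missing or non-finite p-value or effect are dropped and
    counted. Duplicated rsIDs keep the first occurrence with a warning (the
    resolution of multi-allelic duplicates in source GWAS is not published).

    Parameters
    ----------
    path:
        Whitespace- or tab-delimited text file, optionally gzipped.
    column_map:
        Mapping from record fields to column names; merged over the default
        (``SNP, CHR, BP, EA, OA, EFFECT, SE, P, N``).
    idp:
        Optional descriptor, carried through for provenance only.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep=r"\s+", na_values=NA_TOKENS, keep_default_na=True)
    if df.empty:
        raise InputError(f"{path}: empty summary-statistics table")

    for field in _MANDATORY:
        if cmap[field] not in df.columns:
            raise ConfigError(f"{path}: mapped column {cmap[field]!r} (field {field!r}) not present")

    has_se = cmap["se"] in df.columns
    has_n = cmap["n"] in df.columns

    p = pd.to_numeric(df[cmap["pvalue"]], errors="coerce")
    eff = pd.to_numeric(df[cmap["effect"]], errors="coerce")
    keep = np.isfinite(p) & np.isfinite(eff)
    n_dropped = int((~keep).sum())
    df = df.loc[keep]

    dup = df[cmap["snp_id"]].duplicated()
    if dup.any():
        warnings.warn(
            f"{path}: {int(dup.sum())} duplicated rsID rows; keeping first occurrence",
            stacklevel=2,
        )
        df = df.loc[~dup]

    records = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        records.append(
            SumstatsRecord(
                snp_id=str(row[cmap["snp_id"]]),
                chrom=str(row[cmap["chrom"]]),
                pos=int(row[cmap["pos"]]),
                effect_allele=str(row[cmap["effect_allele"]]).upper(),
                other_allele=str(row[cmap["other_allele"]]).upper(),
                effect=float(row[cmap["effect"]]),
                pvalue=float(row[cmap["pvalue"]]),
                se=float(row[cmap["se"]]) if has_se and np.isfinite(_f(row[cmap["se"]])) else None,
                n=float(row[cmap["n"]]) if has_n and np.isfinite(_f(row[cmap["n"]])) else None,
            )
        )
    return ReadResult(records=records, n_dropped=n_dropped)


def _f(x) -> float:
    try:
        return float(x)
    except (TypeError, ValueError):
        return float("nan")


def harmonize_to_target(
    record: SumstatsRecord,
    target: TargetSnp,
    ambiguity_policy: str = "warn",
) -> SumstatsRecord:
    """Align a record's signed effect to the target's risk allele.

    If the record's effect allele equals the risk allele the record is
    returned unchanged; if its other allele does, alleles are swapped and the
    effect negated. |effect| and the p-value are never altered.

    ``ambiguity_policy`` is ``"warn"`` (default: accept strand-ambiguous A/T
    and C/G pairs with a warning) or ``"exclude"`` (raise
    :class:`StrandAmbiguityError`).
    """
    if record.snp_id not in (target.snp_id, target.proxy_id):
        raise InputError(
            f"record {record.snp_id} is neither target {target.snp_id} nor its proxy"
        )
    if is_strand_ambiguous(record.effect_allele, record.other_allele):
        if ambiguity_policy == "exclude":
            raise StrandAmbiguityError(
                f"{record.snp_id}: strand-ambiguous pair "
                f"{record.effect_allele}/{record.other_allele}"
            )
        warnings.warn(
            f"{record.snp_id}: strand-ambiguous pair "
            f"{record.effect_allele}/{record.other_allele}; accepted as-is",
            stacklevel=2,
        )

    risk = target.risk_allele.upper()
    if record.effect_allele == risk:
        return record
    if record.other_allele == risk:
        return replace(
            record,
            effect_allele=record.other_allele,
            other_allele=record.effect_allele,
            effect=-record.effect,
        )
    raise AlleleMismatchError(
        (record.effect_allele, record.other_allele), risk, snp_id=record.snp_id
    )


def proxy_substitute(
    targets: Iterable[TargetSnp],
    available_ids: set,
    min_r2: float = 0.8,
) -> list:
    """Resolve which rsID to use per target given the SNPs a table contains.

    A target present in ``available_ids`` is used directly; an absent target
    with a pre-annotated proxy of r² ≥ ``min_r2`` that is itself present is
    looked up under the proxy id; anything else is reported unresolvable
    (a state, not an error).
    """
    out = []
    for t in targets:
        if t.snp_id in available_ids:
            out.append(ProxyResolution(t.snp_id, t.snp_id, None, "direct"))
        elif (
            t.proxy_id is not None
            and t.proxy_r2 is not None
            and t.proxy_r2 >= min_r2
            and t.proxy_id in available_ids
        ):
            out.append(ProxyResolution(t.snp_id, t.proxy_id, t.proxy_r2, "proxy"))
        else:
            out.append(ProxyResolution(t.snp_id, None, t.proxy_r2, "unresolvable"))
    return out


def write_sumstats(records: Sequence[SumstatsRecord], path) -> None:
    """Write records back to the on-disk dialect (tab-delimited, default columns)."""
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "BP": [r.pos for r in records],
            "EA": [r.effect_allele for r in records],
            "OA": [r.other_allele for r in records],
            "EFFECT": [r.effect for r in records],
            "SE": [r.se if r.se is not None else np.nan for r in records],
            "P": [r.pvalue for r in records],
            "N": [r.n if r.n is not None else np.nan for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_target_snps(path) -> list:
    """Read the target-SNP table (TSV mirroring the published annotation).

    Columns: rsID, CHR, BP, EA, OA, Risk, Prot, proxy, proxy_r2 (the last two
    optional/blank).
    """
    df = pd.read_csv(path, sep="\t", na_values=NA_TOKENS, keep_default_na=True)
    required = {"rsID", "CHR", "BP", "EA", "OA", "Risk", "Prot"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing target-SNP columns {sorted(missing)}")
    targets = []
    for row in df.itertuples(index=False):
        proxy = getattr(row, "proxy", None)
        proxy_r2 = getattr(row, "proxy_r2", None)
        targets.append(
            TargetSnp(
                snp_id=str(row.rsID),
                chrom=str(row.CHR),
                pos=int(row.BP),
                risk_allele=str(row.EA).upper(),
                other_allele=str(row.OA).upper(),
                disorder_risk=str(row.Risk),
                disorder_protective=str(row.Prot),
                proxy_id=None if pd.isna(proxy) else str(proxy),
                proxy_r2=None if pd.isna(proxy_r2) else float(proxy_r2),
            )
        )
    return targets


def read_idp_catalog(path) -> list:
    """Read the IDP catalog TSV (idp_id, region, measure, source)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("idp_id", "region", "measure", "source"):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing IDP-catalog column {col!r}")
    if df["idp_id"].duplicated().any():
        raise InputError(f"{path}: duplicated idp_id in catalog")
    return [
        IdpDescriptor(str(r.idp_id), str(r.region), str(r.measure), str(r.source))
        for r in df.itertuples(index=False)
    ]
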