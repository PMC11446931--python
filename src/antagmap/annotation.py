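"""eQTL and trait-association filters for pre-extracted annotation tables.

eQTL records (SNP, gene, HGNC locus type, tissue, normalized effect size,
nominal p) pass when p is below a Bonferroni threshold alpha / (n_snps ×
n_tissues); pseudogene targets are removed first, identified by a
case-insensitive "pseudogene" substring in the HGNC locus type (HGNC uses
several pseudogene subtypes). The Bonferroni denominator is an explicit,
required parameter — it reflects how many SNPs and tissues were actually
queried and is never inferred from the table.

Trait records (SNP, trait label, p) pass a genome-wide threshold (default
5e-8) and must not match any of the eight cross-disorder neuropsychiatric
disorders, via a case-insensitive substring synonym table.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from antagmap.errors import ConfigError, InputError

#: threshold the published analysis quoted after rounding (Bonferroni for
#: 8 SNPs x 16 brain tissues is exactly 0.05/128 = 3.90625e-4)
PAPER_COMPAT_EQTL_THRESHOLD = 4.0e-4

GENOME_WIDE_P = 5.0e-8

#: label synonyms for the eight disorders, matched as lowercase substrings
DISORDER_SYNONYMS: Mapping[str, Sequence[str]] = {
    "ADHD": ("adhd", "attention deficit", "hyperactivity disorder"),
    "ANO": ("anorexia",),
    "ASD": ("autism", "asperger", "asd"),
    "BIP": ("bipolar",),
    "MDD": ("major depress", "depressive disorder", "mdd", "depression"),
    "OCD": ("obsessive-compulsive", "obsessive compulsive", "ocd"),
    "SCZ": ("schizophrenia", "scz"),
    "TS": ("tourette",),
}

_EQTL_COLUMNS = ("snp_id", "gene", "locus_type", "tissue", "nes", "p")
_TRAIT_COLUMNS = ("snp_id", "trait", "p")


def bonferroni_threshold(n_snps: int, n_tissues: int, alpha: float = 0.05) -> float:
    """Exact Bonferroni per-test threshold alpha / (n_snps * n_tissues)."""
    if n_snps < 1 or n_tissues < 1:
        raise InputError("n_snps and n_tissues must be >= 1")
    return alpha / (n_snps * n_tissues)


def is_pseudogene(locus_type: str) -> bool:
    return "pseudogene" in str(locus_type).lower()


def eqtl_filter(
    records: pd.DataFrame,
    n_snps: int,
    n_tissues: int,
    alpha: float = 0.05,
    paper_compat: bool = False,
) -> pd.DataFrame:
    """Retain Bonferroni-significant eQTL records, pseudogenes excluded first.

    ``paper_compat=True`` uses the published rounded threshold 4.0e-4
    instead of the exact alpha / (n_snps · n_tissues); the rounded value
    admits p-values the exact correction would reject.
    """
    _require(records, _EQTL_COLUMNS, "eQTL")
    threshold = (
        PAPER_COMPAT_EQTL_THRESHOLD
        if paper_compat
        else bonferroni_threshold(n_snps, n_tissues, alpha)
    )
    kept = records.loc[~records["locus_type"].map(is_pseudogene)]
    return kept.loc[kept["p"] < threshold].reset_index(drop=True)


def trait_filter(
    records: pd.DataFrame,
    threshold: float = GENOME_WIDE_P,
    excluded_traits: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Retain genome-wide-significant trait records not naming a disorder.

    ``excluded_traits`` maps disorder codes to label synonyms; the default
    covers the eight cross-disorder diagnoses and may be extended.
    """
    _require(records, _TRAIT_COLUMNS, "trait")
    synonyms = DISORDER_SYNONYMS if excluded_traits is None else excluded_traits
    markers = [s.lower() for group in synonyms.values() for s in group]

    labels = records["trait"].astype(str).str.lower()
    is_disorder = pd.Series(False, index=records.index)
    for marker in markers:
        is_disorder |= labels.str.contains(marker, regex=False)
    return records.loc[(records["p"] < threshold) & ~is_disorder].reset_index(drop=True)


def read_eqtl(path) -> pd.DataFrame:
    """Read an eQTL TSV with the EqtlRecord schema."""
    df = pd.read_csv(path, sep="\t")
    _require(df, _EQTL_COLUMNS, str(path))
    _check_p(df)
    return df


def read_traits(path) -> pd.DataFrame:
    """Read a trait-association TSV with the TraitRecord schema."""
    df = pd.read_csv(path, sep="\t")
    _require(df, _TRAIT_COLUMNS, str(path))
    _check_p(df)
    return df


def _require(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise ConfigError(f"{what}: missing columns {sorted(missing)}")


def _check_p(df: pd.DataFrame) -> None:
    p = pd.to_numeric(df["p"], errors="coerce")
    if not ((p > 0) & (p <= 1)).all():
        raise InputError("p column contains values outside (0, 1]")
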