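"""Target-SNP × IDP association grid with grid-wide Benjamini–Hochberg FDR.

The scan looks every target SNP up in the summary-statistics table of every
image-derived phenotype (IDP), harmonizes each hit to the target's risk
allele, and controls the false discovery rate across the *whole grid* of
tests with the classical BH step-up procedure,

    p_adj(i) = min_{j : p(j) >= p(i)} min(1, m * p(j) / rank(j)),

where m is the number of tests in the grid. Cells beyond the supplied
p-values (e.g. grid positions with no lookup result, under the
count-missing-as-tests convention) are treated as p = 1, which leaves the
adjusted values of the supplied p-values unchanged apart from the larger m.

BH is implemented in-house because the padded-m convention (m larger than
the number of supplied p-values) is not expressible through the standard
multiple-testing helpers; those serve as an independent cross-check when
m equals the count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from antagmap.errors import AlleleMismatchError, InputError, StrandAmbiguityError
from antagmap.sumstats_io import (
    IdpDescriptor,
    SumstatsRecord,
    TargetSnp,
    harmonize_to_target,
)


def bh_adjust(pvalues: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Parameters
    ----------
    pvalues:
        Raw p-values, each in (0, 1].
    m:
        Total number of tests; must be at least ``len(pvalues)``. Tests
        beyond the supplied list are implicitly p = 1. Default: the count.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise InputError("p-values must be finite and in (0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise InputError(f"m = {m} smaller than number of p-values ({k})")

    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    # implicit padded p = 1 entries occupy ranks k+1..m with value m*1/rank >= 1,
    # so min(..., 1) covers them
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


@dataclass
class AssociationGrid:
    """The harmonized target-SNP × IDP grid with grid-wide FDR."""

    entries: pd.DataFrame  # target_snp, used_snp, idp_id, region, measure, effect, p[, p_fdr, significant]
    missing: list  # (snp_id, idp_id, reason)
    m: int
    alpha: float = 0.05

    def adjust(self, m: Optional[int] = None, alpha: Optional[float] = None) -> "AssociationGrid":
        """Compute p_FDR and the significance flag in place; returns self."""
        if m is not None:
            self.m = int(m)
        if alpha is not None:
            self.alpha = float(alpha)
        if self.m < len(self.entries):
            raise InputError(f"m = {self.m} smaller than number of grid entries")
        self.entries["p_fdr"] = bh_adjust(self.entries["p"].to_numpy(), m=self.m)
        self.entries["significant"] = self.entries["p_fdr"] < self.alpha
        return self


LookupFn = Callable[[str, IdpDescriptor], Optional[SumstatsRecord]]


def build_grid(
    targets: Iterable[TargetSnp],
    idps: Iterable[IdpDescriptor],
    catalogs: Mapping[str, Mapping[str, SumstatsRecord]] | LookupFn,
    min_proxy_r2: float = 0.8,
    ambiguity_policy: str = "warn",
    count_missing_as_tests: bool = False,
) -> AssociationGrid:
    """Assemble the harmonized association grid (p_FDR left unset).

    ``catalogs`` maps ``idp_id`` to a dict of ``snp_id -> SumstatsRecord``
    (what a per-IDP sumstats table reduces to after indexing), or is a
    callable ``(snp_id, idp) -> record or None``. Per (target, IDP) cell the
    target id is looked up first; if absent and the target carries an
    admissible proxy (r² ≥ ``min_proxy_r2``) the proxy id is tried. Cells
    with no result, or with irreconcilable alleles, are recorded in
    ``missing`` with a reason.

    ``m`` defaults to the number of successful (non-missing) cells;
    ``count_missing_as_tests=True`` sets m to the full attempted grid size.
    """
    targets = list(targets)
    idps = list(idps)
    if not targets or not idps:
        raise InputError("need at least one target SNP and one IDP")

    if callable(catalogs):
        lookup = catalogs
    else:
        def lookup(snp_id, idp, _c=catalogs):
            return _c.get(idp.idp_id, {}).get(snp_id)

    rows = []
    missing = []
    for t in targets:
        for idp in idps:
            rec = lookup(t.snp_id, idp)
            used = t.snp_id
            if rec is None and t.proxy_id is not None and (t.proxy_r2 or 0.0) >= min_proxy_r2:
                rec = lookup(t.proxy_id, idp)
                used = t.proxy_id
            if rec is None:
                missing.append((t.snp_id, idp.idp_id, "not-found"))
                continue
            try:
                h = harmonize_to_target(rec, t, ambiguity_policy=ambiguity_policy)
            except AlleleMismatchError:
                missing.append((t.snp_id, idp.idp_id, "allele-mismatch"))
                continue
            except StrandAmbiguityError:
                missing.append((t.snp_id, idp.idp_id, "strand-ambiguous"))
                continue
            rows.append(
                {
                    "target_snp": t.snp_id,
                    "used_snp": used,
                    "idp_id": idp.idp_id,
                    "region": idp.region,
                    "measure": idp.measure,
                    "effect": h.effect,
                    "p": h.pvalue,
                }
            )
    entries = pd.DataFrame(
        rows, columns=["target_snp", "used_snp", "idp_id", "region", "measure", "effect", "p"]
    )
    m = len(targets) * len(idps) if count_missing_as_tests else len(entries)
    return AssociationGrid(entries=entries, missing=missing, m=m)


def significant_table(
    grid: AssociationGrid,
    alpha: Optional[float] = None,
    targets: Optional[Iterable[TargetSnp]] = None,
) -> pd.DataFrame:
    """Report rows with p_FDR < alpha, grouped by SNP and sorted by p within SNP.

    When ``targets`` is given, the published annotation columns (CHR, BP,
    EA/OA, risk/protective disorders) are joined in.
    """
    if "p_fdr" not in grid.entries.columns:
        raise InputError("grid has no p_fdr column; call grid.adjust() first")
    alpha = grid.alpha if alpha is None else alpha
    sig = grid.entries[grid.entries["p_fdr"] < alpha].copy()
    sig = sig.sort_values(["target_snp", "p"], kind="stable").reset_index(drop=True)
    if targets is not None:
        meta = pd.DataFrame(
            [
                {
                    "target_snp": t.snp_id,
                    "CHR": t.chrom,
                    "BP": t.pos,
                    "EA": t.risk_allele,
                    "OA": t.other_allele,
                    "risk": t.disorder_risk,
                    "protective": t.disorder_protective,
                }
                for t in targets
            ]
        )
        sig = sig.merge(meta, on="target_snp", how="left")
        sig = sig[
            [
                "target_snp", "used_snp", "CHR", "BP", "EA", "OA", "risk", "protective",
                "idp_id", "region", "measure", "p", "p_fdr", "effect", "significant",
            ]
        ]
    return sig


def format_pvalue(p: float, sig_figs: int = 3) -> str:
    """Render a p-value at the report precision (default 3 significant figures)."""
    return f"{p:.{sig_figs - 1}e}"


def write_report(table: pd.DataFrame, path, sig_figs: int = 3) -> None:
    """Write the significant-association table as TSV with rounded p columns."""
    out = table.copy()
    for col in ("p", "p_fdr"):
        if col in out.columns:
            out[col] = out[col].map(lambda x: format_pvalue(x, sig_figs))
    out.to_csv(path, sep="\t", index=False)
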