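"""Effect-direction triangulation among SNP→IDP, SNP→disorder, and patient data.

For each antagonistic SNP, one allele raises risk for one disorder and
protects against another. If the allele's effect on a brain measure mediates
those opposite risks, the direction of its IDP effect should agree with the
case-vs-control alteration seen in patients: the risk disorder's patients
should be shifted in the direction the risk allele pushes, and the protected
disorder's patients in the direction the *other* allele pushes.

The classification compares, per disorder, the published case-control
Cohen's d (negative = lower in patients) against the IDP effect sign of that
disorder's own risk allele (s for the risk disorder, −s for the protective
disorder, where s is the harmonized risk-allele effect sign). This symmetric
form makes the call invariant to which allele the record was harmonized to.

Calls:

* ``opposed_idp`` — both disorders show significant case-control effects of
  opposite sign (the sought-after antagonistic signature).
* ``consistent_mediation`` — every disorder with a significant case-control
  effect agrees with its risk-allele direction.
* ``inconsistent`` — some significant case-control effect disagrees.
* ``indeterminate`` — no significant case-control effect, or no data (e.g.
  disorders without a large-scale case-control imaging study).

Case-control tables come per hemisphere while the SNP grid uses
hemisphere-averaged IDPs; :func:`hemisphere_merge` reconciles the two
(default policy: both hemispheres significant with agreeing sign).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from antagmap.errors import ConfigError, InputError
from antagmap.sumstats_io import TargetSnp

#: disorders with no large-scale case-control imaging study at analysis time
NO_CASE_CONTROL_DATA = frozenset({"ANO", "TS"})

#: default disorder-specific subphenotype markers excluded at ingestion
DEFAULT_SUBPHENOTYPE_MARKERS = (
    "recurrent",
    "first episode",
    "early onset",
    "late onset",
    "subtype",
    "type i",
    "type ii",
    "medicat",
    "psychotic",
)


@dataclass(frozen=True)
class CaseControlEffect:
    """Published case-vs-control effect for one (disorder, region, measure)."""

    disorder: str
    region: str
    measure: str  # SA | CT | VOL
    hemisphere: str  # left | right | both
    d: float  # Cohen's d, negative = lower in cases
    p_adjusted: float

    def __post_init__(self):
        if self.hemisphere not in {"left", "right", "both"}:
            raise InputError(f"hemisphere must be left/right/both, got {self.hemisphere!r}")
        if not (0.0 < self.p_adjusted <= 1.0):
            raise InputError(f"p_adjusted {self.p_adjusted} outside (0, 1]")


@dataclass(frozen=True)
class EffectTriplet:
    """Sign triangulation for one (SNP, IDP, disorder-pair) combination."""

    snp_id: str
    risk_allele: str
    disorder_risk: str
    disorder_protective: str
    idp_id: str
    sign_snp_idp: str  # "+" | "-"
    sign_case_control: Mapping[str, str]  # disorder -> "+" | "-" | "ns"
    call: str  # consistent_mediation | inconsistent | opposed_idp | indeterminate
    reason: Optional[str] = None


def read_case_control(
    path,
    exclude_subphenotypes: Sequence[str] = DEFAULT_SUBPHENOTYPE_MARKERS,
) -> pd.DataFrame:
    """Read a case-control effect TSV (disorder, region, measure, hemisphere, d, p_adjusted).

    Rows whose optional ``subphenotype`` column matches any exclusion marker
    (case-insensitive substring) are dropped, so only the main diagnosis
    contrasts remain.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"disorder", "region", "measure", "hemisphere", "d", "p_adjusted"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing case-control columns {sorted(missing)}")
    if "subphenotype" in df.columns and exclude_subphenotypes:
        sub = df["subphenotype"].fillna("").str.lower()
        drop = np.zeros(len(df), dtype=bool)
        for marker in exclude_subphenotypes:
            drop |= sub.str.contains(marker.lower(), regex=False)
        df = df.loc[~drop]
    return df.reset_index(drop=True)


def hemisphere_merge(
    left: Optional[CaseControlEffect],
    right: Optional[CaseControlEffect],
    policy: str = "both-required",
    alpha: float = 0.05,
) -> CaseControlEffect:
    """Merge per-hemisphere effects into one hemisphere-averaged record.

    ``both-required`` (default): significant only if both hemispheres are
    significant with the same sign; d is the mean of the two. A sign
    disagreement between two significant hemispheres is flagged
    non-significant (p set to 1). ``either``: significant if either
    hemisphere is; sign and p from the more significant one; d the mean of
    whatever is present.
    """
    if left is None and right is None:
        raise InputError("hemisphere_merge needs at least one hemisphere")
    present = [e for e in (left, right) if e is not None]
    for a in present:
        for b in present:
            if (a.disorder, a.region, a.measure) != (b.disorder, b.region, b.measure):
                raise InputError("hemisphere_merge inputs differ in disorder/region/measure")
    proto = present[0]
    d_mean = float(np.mean([e.d for e in present]))

    if policy == "both-required":
        if left is None or right is None:
            return replace(proto, hemisphere="both", d=d_mean, p_adjusted=1.0)
        both_sig = left.p_adjusted < alpha and right.p_adjusted < alpha
        same_sign = np.sign(left.d) == np.sign(right.d)
        if both_sig and same_sign:
            p = max(left.p_adjusted, right.p_adjusted)
        else:
            p = 1.0  # includes the flagged sign-disagreement case
        return replace(proto, hemisphere="both", d=d_mean, p_adjusted=p)
    if policy == "either":
        best = min(present, key=lambda e: e.p_adjusted)
        return replace(proto, hemisphere="both", d=d_mean if len(present) > 1 else best.d,
                       p_adjusted=best.p_adjusted)
    raise ConfigError(f"unknown hemisphere policy {policy!r}")


def _sign(x: float) -> str:
    return "+" if x > 0 else "-"


def classify_triplet(
    snp_effect: float,
    target: TargetSnp,
    case_control: Mapping[str, Optional[CaseControlEffect]],
    idp_id: str = "",
    alpha: float = 0.05,
) -> EffectTriplet:
    """Classify the direction relationship for one (SNP, IDP, disorder-pair).

    ``snp_effect`` is the harmonized risk-allele effect on the IDP;
    ``case_control`` maps each of the two disorders to its (hemisphere-
    merged) effect, or None when no matching region/measure entry exists.
    """
    s = _sign(snp_effect)
    # per-disorder expected sign under mediation: the disorder's own risk
    # allele is the harmonized allele for the risk disorder and the other
    # allele for the protective disorder
    expected = {target.disorder_risk: s, target.disorder_protective: "-" if s == "+" else "+"}

    signs = {}
    missing = []
    for disorder in (target.disorder_risk, target.disorder_protective):
        eff = case_control.get(disorder)
        if eff is None:
            signs[disorder] = "ns"
            missing.append(disorder)
        elif eff.p_adjusted < alpha:
            signs[disorder] = _sign(eff.d)
        else:
            signs[disorder] = "ns"

    sig = {d: sg for d, sg in signs.items() if sg != "ns"}
    reason = None
    if not sig:
        call = "indeterminate"
        if set(missing) & NO_CASE_CONTROL_DATA:
            reason = "no-case-control-data"
        elif missing:
            reason = "missing-data"
        else:
            reason = "non-significant"
    elif len(sig) == 2 and len(set(sig.values())) == 2:
        call = "opposed_idp"
    elif all(sg == expected[d] for d, sg in sig.items()):
        call = "consistent_mediation"
    else:
        call = "inconsistent"

    return EffectTriplet(
        snp_id=target.snp_id,
        risk_allele=target.risk_allele,
        disorder_risk=target.disorder_risk,
        disorder_protective=target.disorder_protective,
        idp_id=idp_id,
        sign_snp_idp=s,
        sign_case_control=signs,
        call=call,
        reason=reason,
    )


def lookup_case_control(
    table: pd.DataFrame,
    disorder: str,
    region: str,
    measure: str,
    policy: str = "both-required",
    alpha: float = 0.05,
) -> Optional[CaseControlEffect]:
    """Fetch and hemisphere-merge the case-control effect for one cell."""
    sel = table[
        (table["disorder"] == disorder)
        & (table["region"].str.lower() == region.lower())
        & (table["measure"] == measure)
    ]
    if sel.empty:
        return None
    by_hemi = {}
    for row in sel.itertuples(index=False):
        by_hemi[row.hemisphere] = CaseControlEffect(
            disorder=row.disorder, region=row.region, measure=row.measure,
            hemisphere=row.hemisphere, d=float(row.d), p_adjusted=float(row.p_adjusted),
        )
    if "both" in by_hemi and len(by_hemi) == 1:
        return by_hemi["both"]
    return hemisphere_merge(by_hemi.get("left"), by_hemi.get("right"), policy=policy, alpha=alpha)


def triangulate(
    significant: pd.DataFrame,
    targets: Iterable[TargetSnp],
    case_control: pd.DataFrame,
    policy: str = "both-required",
    alpha: float = 0.05,
) -> list:
    """Classify every significant grid entry against the case-control table."""
    by_id = {t.snp_id: t for t in targets}
    out = []
    for row in significant.itertuples(index=False):
        t = by_id.get(row.target_snp)
        if t is None:
            continue
        cc = {
            d: lookup_case_control(case_control, d, row.region, row.measure, policy, alpha)
            for d in (t.disorder_risk, t.disorder_protective)
        }
        out.append(classify_triplet(row.effect, t, cc, idp_id=row.idp_id, alpha=alpha))
    return out


def find_opposed_idps(
    significant: pd.DataFrame,
    case_control: pd.DataFrame,
    disorder_pairs: Iterable[Tuple[str, str]],
    policy: str = "both-required",
    alpha: float = 0.05,
) -> list:
    """IDPs with significant, oppositely-signed patient alterations in a pair.

    Scans every significantly associated IDP against every disorder pair of
    the antagonistic set; an empty result is a valid, reportable outcome.
    Output pairs are stored sorted, so the result is symmetric in the pair.
    """
    pairs = {tuple(sorted(p)) for p in disorder_pairs}
    seen = set()
    out = []
    for row in significant.itertuples(index=False):
        for d1, d2 in sorted(pairs):
            key = (row.idp_id, d1, d2)
            if key in seen:
                continue
            e1 = lookup_case_control(case_control, d1, row.region, row.measure, policy, alpha)
            e2 = lookup_case_control(case_control, d2, row.region, row.measure, policy, alpha)
            if e1 is None or e2 is None:
                continue
            if (
                e1.p_adjusted < alpha
                and e2.p_adjusted < alpha
                and np.sign(e1.d) != np.sign(e2.d)
            ):
                seen.add(key)
                out.append((row.idp_id, (d1, d2)))
    return out
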