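"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's data sources:

* :func:`gen_sumstats` — per-IDP GWAS summary tables with planted
  standardized effects. Effects are simulated on the effect/SE scale
  (z-scores): the per-IDP standard error is 1/sqrt(n) with sample sizes
  matching the source GWAS magnitudes (tens of thousands), the observed z
  is Normal(planted, 1) with optional block-equicorrelation across IDPs,
  and p is the two-sided normal tail. Raw-beta scaling is a presentation
  transform; all downstream logic consumes p and sign.
* :func:`gen_case_control_table` — ENIGMA-style case-control effect tables
  with exactly the specified Cohen's d / adjusted-p structure, emitted per
  hemisphere with optional jitter.
* :func:`gen_imaging_cohort` — a desk-scale 3D cohort: spatially smoothed
  Gaussian noise fields standardized to unit voxel SD, covariate
  contributions, and a planted dosage effect (in noise-SD units) inside a
  chosen voxel region.

Every generator is a pure function of its scenario plus seed, and returns a
truth record sufficient for bias/error computations downstream.

:func:`table1_fixture` reproduces the published significant-association
table: the 27 printed (SNP, IDP, raw p, effect) cells embedded in the full
11 × 79 grid (the remaining 842 cells at p = 1), with m = 869, enabling
end-to-end reproduction of the printed FDR-adjusted column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from antagmap.errors import InputError
from antagmap.fdr_scan import AssociationGrid
from antagmap.sumstats_io import IdpDescriptor, TargetSnp
from antagmap.vbm import ImagingCohort

# ---------------------------------------------------------------------------
# catalogs

#: the 34 cortical parcellation regions (hemisphere-averaged)
DK_REGIONS = (
    "bankssts", "caudal anterior cingulate", "caudal middle frontal", "cuneus",
    "entorhinal", "frontal pole", "fusiform", "inferior parietal",
    "inferior temporal", "insula", "isthmus cingulate", "lateral occipital",
    "lateral orbitofrontal", "lingual", "medial orbitofrontal", "middle temporal",
    "paracentral", "parahippocampal", "pars opercularis", "pars orbitalis",
    "pars triangularis", "pericalcarine", "postcentral", "posterior cingulate",
    "precentral", "precuneus", "rostral anterior cingulate",
    "rostral middle frontal", "superior frontal", "superior parietal",
    "superior temporal", "supramarginal", "temporal pole", "transverse temporal",
)

SUBCORTICAL_REGIONS = (
    "amygdala", "nucleus accumbens", "brainstem", "caudate",
    "globus pallidus", "hippocampus", "putamen", "thalamus",
)


def _slug(region: str) -> str:
    return region.replace(" ", "_")


def default_idp_catalog() -> list:
    """The 79-column IDP catalog of the association scan.

    34 regional SA + 34 regional CT + total SA + mean CT (one cortical GWAS
    source), 8 subcortical volumes (subcortical GWAS), and hippocampal
    volume from its own dedicated GWAS — hippocampus therefore contributes
    two columns, which is what makes the grid 11 × 79 = 869 tests.
    """
    idps = []
    for region in DK_REGIONS:
        idps.append(IdpDescriptor(f"SA_{_slug(region)}", region, "SA", "cortical_gwas"))
    for region in DK_REGIONS:
        idps.append(IdpDescriptor(f"CT_{_slug(region)}", region, "CT", "cortical_gwas"))
    idps.append(IdpDescriptor("SA_total", "total surface area", "SA", "cortical_gwas"))
    idps.append(IdpDescriptor("CT_mean", "average thickness", "CT", "cortical_gwas"))
    for region in SUBCORTICAL_REGIONS:
        idps.append(IdpDescriptor(f"VOL_{_slug(region)}", region, "VOL", "subcortical_gwas"))
    idps.append(
        IdpDescriptor("VOL_hippocampus_dedicated", "hippocampus", "VOL", "hippocampal_gwas")
    )
    return idps


# ---------------------------------------------------------------------------
# summary-statistics generator

@dataclass
class SumstatsScenario:
    """Scenario for planted-effect GWAS summary statistics."""

    n_snps: int = 100
    n_idps: int = 20
    planted_effects: Mapping[Tuple[int, int], float] = field(default_factory=dict)
    n: float = 30000.0  # per-IDP GWAS sample size, drives the SE scale
    correlation: float = 0.0  # equicorrelation of z across IDPs within a block
    block_size: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise InputError("sample size n must be >= 2")
        for (i, j) in self.planted_effects:
            if not (0 <= i < self.n_snps and 0 <= j < self.n_idps):
                raise InputError(f"planted effect key ({i}, {j}) outside grid")
        if not (0.0 <= self.correlation < 1.0):
            raise InputError("correlation must be in [0, 1)")


@dataclass
class SumstatsTruth:
    snp_ids: list
    idps: list
    planted: Dict[Tuple[str, str], float]
    z: np.ndarray  # realized z-scores, (n_snps, n_idps)


_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


def gen_sumstats(scenario: SumstatsScenario) -> Tuple[Dict[str, pd.DataFrame], SumstatsTruth]:
    """Generate one summary table per IDP plus the planted-truth record."""
    rng = np.random.default_rng(scenario.seed)
    ns, ni = scenario.n_snps, scenario.n_idps

    mean = np.zeros((ns, ni))
    for (i, j), z in scenario.planted_effects.items():
        mean[i, j] = z

    rho = scenario.correlation
    eps = rng.standard_normal((ns, ni))
    if rho > 0:
        n_blocks = -(-ni // scenario.block_size)
        shared = rng.standard_normal((ns, n_blocks))
        block_of = np.arange(ni) // scenario.block_size
        eps = np.sqrt(1 - rho) * eps + np.sqrt(rho) * shared[:, block_of]
    z = mean + eps

    se = 1.0 / np.sqrt(scenario.n)
    effects = z * se
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    snp_ids = [f"rs{1000001 + i}" for i in range(ns)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=ns)
    ea = [_ALLELE_PAIRS[k][0] for k in pair_idx]
    oa = [_ALLELE_PAIRS[k][1] for k in pair_idx]
    positions = 10_000 + 1_000 * np.arange(ns)

    idp_ids = [f"IDP_{j:03d}" for j in range(ni)]
    tables = {}
    for j, idp in enumerate(idp_ids):
        tables[idp] = pd.DataFrame(
            {
                "SNP": snp_ids,
                "CHR": "1",
                "BP": positions,
                "EA": ea,
                "OA": oa,
                "EFFECT": effects[:, j],
                "SE": se,
                "P": pvals[:, j],
                "N": scenario.n,
            }
        )
    planted = {
        (snp_ids[i], idp_ids[j]): v for (i, j), v in scenario.planted_effects.items()
    }
    return tables, SumstatsTruth(snp_ids=snp_ids, idps=idp_ids, planted=planted, z=z)


def sumstats_p_matrix(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-IDP tables into one SNP × IDP p-value matrix."""
    cols = {idp: df.set_index("SNP")["P"] for idp, df in tables.items()}
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# case-control generator

def gen_case_control_table(
    spec: Iterable[Mapping],
    hemisphere_jitter: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit an ENIGMA-style case-control table from explicit row specs.

    Each spec entry gives disorder, region, measure, d, p_adjusted; a row is
    emitted for both hemispheres, with optional Gaussian jitter of d between
    hemispheres. Per-hemisphere overrides (``d_left``/``d_right``,
    ``p_left``/``p_right``) take precedence.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for entry in spec:
        for hemi in ("left", "right"):
            d = entry.get(f"d_{hemi}", entry.get("d"))
            p = entry.get(f"p_{hemi}", entry.get("p_adjusted"))
            if d is None or p is None:
                raise InputError(f"case-control spec entry incomplete: {entry}")
            if hemisphere_jitter > 0:
                d = d + rng.normal(0.0, hemisphere_jitter)
            rows.append(
                {
                    "disorder": entry["disorder"],
                    "region": entry["region"],
                    "measure": entry["measure"],
                    "hemisphere": hemi,
                    "d": float(d),
                    "p_adjusted": float(p),
                    "source": entry.get("source", "synthetic"),
                }
            )
    return pd.DataFrame(
        rows, columns=["disorder", "region", "measure", "hemisphere", "d", "p_adjusted", "source"]
    )


def paper_case_control_fixture() -> pd.DataFrame:
    """Case-control table mirroring the published patient-alteration pattern.

    All significant entries are decreases in patients (SA reductions in SCZ,
    CT reductions in BIP/MDD/SCZ), so no IDP carries oppositely-signed
    significant alterations in any disorder pair — the published outcome.
    The superior temporal SA row carries the published SCZ values
    (d_left = −0.196, p_left = 9.2e-9; d_right = −0.195, p_right = 9.3e-7).
    """
    spec = [
        {"disorder": "SCZ", "region": "superior temporal", "measure": "SA",
         "d_left": -0.196, "p_left": 9.2e-9, "d_right": -0.195, "p_right": 9.3e-7},
        {"disorder": "SCZ", "region": "transverse temporal", "measure": "SA",
         "d": -0.12, "p_adjusted": 1.0e-4},
        {"disorder": "SCZ", "region": "insula", "measure": "SA",
         "d": -0.10, "p_adjusted": 2.0e-3},
        {"disorder": "SCZ", "region": "posterior cingulate", "measure": "CT",
         "d": -0.14, "p_adjusted": 5.0e-4},
        {"disorder": "BIP", "region": "posterior cingulate", "measure": "CT",
         "d": -0.09, "p_adjusted": 4.0e-2},
        {"disorder": "MDD", "region": "rostral anterior cingulate", "measure": "CT",
         "d": -0.08, "p_adjusted": 3.0e-2},
        {"disorder": "MDD", "region": "caudal anterior cingulate", "measure": "CT",
         "d": -0.05, "p_adjusted": 0.40},
        {"disorder": "ASD", "region": "superior temporal", "measure": "SA",
         "d": 0.02, "p_adjusted": 0.80},
        {"disorder": "ASD", "region": "transverse temporal", "measure": "SA",
         "d": 0.01, "p_adjusted": 0.90},
    ]
    return gen_case_control_table(spec)


# ---------------------------------------------------------------------------
# imaging generator

@dataclass
class ImagingScenario:
    """Scenario for a desk-scale voxel-wise cohort with a planted dosage effect."""

    shape: Tuple[int, int, int] = (16, 16, 16)
    n_subjects: int = 40
    effect_voxels: Tuple[Tuple[int, int, int], ...] = ()
    effect_size: float = 0.0  # in units of (unit) noise SD per dosage allele
    fwhm_vox: float = 2.0
    dosage_af: float = 0.3
    snp_id: str = "rs1"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.dosage_af < 1.0):
            raise InputError("allele frequency must be in (0, 1)")
        for v in self.effect_voxels:
            if any(not (0 <= c < s) for c, s in zip(v, self.shape)):
                raise InputError(f"effect voxel {v} outside grid {self.shape}")


def cube_region(center: Tuple[int, int, int], half: int = 1) -> Tuple[Tuple[int, int, int], ...]:
    """Convenience: the (2*half+1)³ cube of voxel indices around a center."""
    cx, cy, cz = center
    return tuple(
        (x, y, z)
        for x in range(cx - half, cx + half + 1)
        for y in range(cy - half, cy + half + 1)
        for z in range(cz - half, cz + half + 1)
    )


def gen_imaging_cohort(scenario: ImagingScenario) -> Tuple[ImagingCohort, dict]:
    """Smoothed-noise volumes + covariate effects + planted dosage effect.

    Noise fields are Gaussian-smoothed (FWHM in voxels) and rescaled to unit
    voxel SD, so ``effect_size`` is literally in noise-SD units. Covariates
    (age, sex, diagnosis, intracranial volume, scanner, three ancestry
    components) contribute small global offsets, giving the GLM genuine
    nuisance structure to remove.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_subjects
    shape = scenario.shape

    dosage = rng.binomial(2, scenario.dosage_af, size=n).astype(float)
    age = rng.normal(35.4, 13.1, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    diagnosis = (rng.random(n) < 0.47).astype(float)
    tiv = rng.normal(1500.0, 120.0, size=n)
    scanner = rng.choice(["bodycoil", "headcoil"], size=n)
    ancestry = rng.normal(0.0, 1.0, size=(n, 3))

    sigma = scenario.fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    noise = np.empty((n, *shape))
    for i in range(n):
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
        noise[i] = f / f.std()

    # global covariate contributions (arbitrary consistent units)
    base = (
        0.01 * (age - 35.4)
        + 0.10 * sex
        - 0.05 * diagnosis
        + 0.002 * (tiv - 1500.0)
        + 0.08 * (scanner == "bodycoil")
        + ancestry @ np.array([0.05, -0.03, 0.02])
    )
    volumes = noise + base[:, None, None, None]

    if scenario.effect_voxels and scenario.effect_size != 0.0:
        idx = tuple(np.array(scenario.effect_voxels).T)
        volumes[(slice(None),) + idx] += scenario.effect_size * dosage[:, None]

    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "diagnosis": diagnosis,
            "tiv": tiv,
            "scanner": scanner,
            "anc1": ancestry[:, 0],
            "anc2": ancestry[:, 1],
            "anc3": ancestry[:, 2],
        }
    )
    cohort = ImagingCohort(
        volumes=volumes,
        mask=np.ones(shape, dtype=bool),
        covariates=covariates,
        dosage=pd.DataFrame({scenario.snp_id: dosage}),
        affine=np.diag([2.0, 2.0, 2.0, 1.0]),  # 2 mm isotropic, origin at index 0
    )
    truth = {
        "beta": scenario.effect_size,
        "effect_voxels": tuple(scenario.effect_voxels),
        "dosage": dosage,
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# published-table fixture

# the 8 significantly associated target SNPs with their published annotation
_REAL_TARGETS = (
    ("rs2388334", "6", 98591622, "A", "G", "TS", "ASD", None, None),
    ("rs301805", "1", 8481016, "T", "G", "MDD", "SCZ", None, None),
    ("rs75595651", "4", 123133540, "T", "C", "BIP", "MDD", "rs77087420", 1.0),
    ("rs1933802", "6", 105365891, "A", "G", "SCZ", "MDD", "rs314280", 1.0),
    ("rs6748341", "2", 225377574, "C", "G", "SCZ", "ANO", None, None),
    ("rs3806843", "5", 140212538, "T", "C", "SCZ", "MDD", None, None),
    ("rs9329221", "8", 10240202, "T", "G", "SCZ", "ASD", None, None),
    ("rs2921036", "8", 8363897, "T", "C", "ASD", "SCZ", None, None),
)

# placeholders for the three targets with no significant association; their
# rsIDs are synthetic (the real identifiers live in the source study's
# supplement) and they contribute only p = 1 filler cells to the grid
_SYNTHETIC_TARGETS = (
    ("rs900000001", "3", 50000001, "A", "C", "ADHD", "MDD", None, None),
    ("rs900000002", "7", 60000002, "A", "C", "OCD", "BIP", None, None),
    ("rs900000003", "11", 70000003, "A", "C", "ASD", "ADHD", None, None),
)

# the 27 published significant cells: (snp_id, idp_id, raw p, effect)
TABLE1_CELLS = (
    ("rs2388334", "SA_transverse_temporal", 2.16e-05, 1.643),
    ("rs2388334", "SA_bankssts", 2.89e-05, -3.548),
    ("rs2388334", "SA_insula", 6.04e-04, 4.445),
    ("rs2388334", "SA_inferior_parietal", 1.50e-03, -10.312),
    ("rs301805", "SA_caudal_anterior_cingulate", 7.09e-04, -2.571),
    ("rs301805", "SA_insula", 1.00e-03, 4.277),
    ("rs301805", "CT_posterior_cingulate", 1.05e-03, 0.003),
    ("rs75595651", "CT_rostral_anterior_cingulate", 2.87e-05, 0.013),
    ("rs75595651", "SA_frontal_pole", 7.88e-05, 2.018),
    ("rs75595651", "CT_caudal_anterior_cingulate", 2.16e-04, 0.013),
    ("rs1933802", "SA_pericalcarine", 5.39e-05, -6.217),
    ("rs1933802", "SA_lingual", 4.68e-04, -8.131),
    ("rs1933802", "VOL_caudate", 1.39e-03, 3.197),
    ("rs6748341", "SA_pars_opercularis", 7.55e-05, 5.788),
    ("rs3806843", "VOL_putamen", 1.64e-05, -4.310),
    ("rs3806843", "VOL_caudate", 2.10e-05, -4.254),
    ("rs3806843", "VOL_nucleus_accumbens", 3.10e-04, -3.607),
    ("rs9329221", "SA_superior_temporal", 7.93e-12, -12.496),
    ("rs9329221", "SA_transverse_temporal", 1.33e-05, -1.707),
    ("rs9329221", "SA_isthmus_cingulate", 2.04e-04, 3.264),
    ("rs9329221", "CT_supramarginal", 3.84e-04, 0.002),
    ("rs9329221", "SA_lateral_orbitofrontal", 3.87e-04, 5.045),
    ("rs9329221", "SA_posterior_cingulate", 8.46e-04, -2.924),
    ("rs2921036", "SA_superior_temporal", 1.11e-08, 10.374),
    ("rs2921036", "SA_transverse_temporal", 3.46e-05, 1.615),
    ("rs2921036", "SA_lateral_orbitofrontal", 1.20e-04, -5.439),
    ("rs2921036", "VOL_brainstem", 2.28e-04, 3.685),
)


@dataclass
class Table1Fixture:
    """The published association grid: 27 real cells + 842 filler cells, m = 869."""

    targets: list
    idps: list
    grid: AssociationGrid


def table1_targets() -> list:
    """The eleven target SNPs (eight published + three synthetic placeholders)."""
    return [
        TargetSnp(snp_id=s, chrom=c, pos=b, risk_allele=ea, other_allele=oa,
                  disorder_risk=r, disorder_protective=p, proxy_id=px, proxy_r2=pr2)
        for (s, c, b, ea, oa, r, p, px, pr2) in _REAL_TARGETS + _SYNTHETIC_TARGETS
    ]


def table1_fixture() -> Table1Fixture:
    """The 11 × 79 grid carrying the 27 published cells, ready for BH at m = 869."""
    targets = table1_targets()
    idps = default_idp_catalog()
    assert len(targets) * len(idps) == 869

    cell = {(s, i): (p, e) for (s, i, p, e) in TABLE1_CELLS}
    region_of = {i.idp_id: i.region for i in idps}
    measure_of = {i.idp_id: i.measure for i in idps}
    rows = []
    for t in targets:
        used = t.proxy_id if t.snp_id == "rs1933802" else t.snp_id
        for idp in idps:
            p, e = cell.get((t.snp_id, idp.idp_id), (1.0, 0.0))
            rows.append(
                {
                    "target_snp": t.snp_id,
                    "used_snp": used,
                    "idp_id": idp.idp_id,
                    "region": region_of[idp.idp_id],
                    "measure": measure_of[idp.idp_id],
                    "effect": e,
                    "p": p,
                }
            )
    entries = pd.DataFrame(rows)
    grid = AssociationGrid(entries=entries, missing=[], m=869)
    return Table1Fixture(targets=targets, idps=idps, grid=grid)
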