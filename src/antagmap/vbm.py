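"""Voxel-wise GLM of gray-matter volume on allele dosage, with permutation FWE.

Per masked voxel, gray-matter volume is regressed on allele dosage plus
covariates (ordinary least squares; categorical covariates dummy-coded), and
the dosage coefficient's t-statistic forms the map. Suprathreshold voxels
(one-sided p below the cluster-forming threshold, default 0.001, in the
requested direction) are grouped into connected components (default
18-connectivity) and components above the extent threshold (default k > 10,
i.e. k ≥ 11) are reported with their peak statistic.

Peak-level family-wise error is controlled by permutation maxT: gray-matter
volume and dosage are both residualized on the nuisance covariates
(Frisch–Waugh–Lovell, so the reduced-model t equals the full-model dosage t
exactly), the dosage residuals are permuted, and the null distribution of
the global maximum |t| over the mask yields

    p_FWE(peak) = (1 + #{max|t|_perm >= |t_peak|}) / (1 + n_perm).

This is an exact-level permutation analogue of the peak-level correction;
parametric random-field theory is deliberately not implemented, so published
RFT p_FWE values are not comparable quantities.

Peaks are reported in world (mm) coordinates through the image affine and
can be annotated against any integer label volume with a lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.linalg import qr as _qr

from antagmap.errors import ConfigError, InputError

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ImagingCohort:
    """Per-subject 3D volumes with a shared grid, mask, covariates, and dosage."""

    volumes: np.ndarray  # (n_subjects, X, Y, Z)
    mask: np.ndarray  # (X, Y, Z) bool
    covariates: pd.DataFrame  # n_subjects rows
    dosage: pd.DataFrame  # n_subjects rows, one column per SNP, values in [0, 2]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        n = self.volumes.shape[0]
        if self.volumes.shape[1:] != self.mask.shape:
            raise InputError("volumes and mask disagree in grid shape")
        if len(self.covariates) != n or len(self.dosage) != n:
            raise InputError("covariate/dosage row count does not match number of volumes")
        if self.affine.shape != (4, 4):
            raise InputError("affine must be 4x4")
        masked = self.volumes[:, self.mask]
        if not np.all(np.isfinite(masked)):
            raise InputError("mask covers non-finite voxels in some subject")

    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]


@dataclass
class GlmResult:
    """Voxel-wise t-map for the dosage coefficient plus fit metadata."""

    t: np.ndarray  # (X, Y, Z), NaN outside the mask
    beta: np.ndarray  # dosage coefficient, NaN outside the mask
    df: int
    mask: np.ndarray
    affine: np.ndarray
    design_columns: List[str]


@dataclass
class ClusterResult:
    """One suprathreshold cluster with its peak statistics."""

    cluster_id: int
    k: int
    peak_index: Tuple[int, int, int]
    peak_mni: Tuple[float, float, float]
    peak_t: float
    peak_p_uncorrected: float
    direction: str  # positive | negative
    peak_p_fwe: Optional[float] = None
    label: str = "unlabeled"
    out_of_field: bool = False


def build_design(cohort: ImagingCohort, snp: str) -> Tuple[np.ndarray, List[str]]:
    """Assemble intercept + dosage + covariates, dummy-coding categoricals.

    Raises a rank-deficiency error naming the collinear columns.
    """
    if snp not in cohort.dosage.columns:
        raise ConfigError(f"dosage column {snp!r} not present")
    if cohort.covariates.shape[1]:
        cov = pd.get_dummies(cohort.covariates, drop_first=True, dtype=float)
    else:
        cov = cohort.covariates.copy()
    X = pd.concat(
        [
            pd.Series(1.0, index=cov.index, name="intercept"),
            cohort.dosage[snp].astype(float).rename(f"dosage[{snp}]"),
            cov,
        ],
        axis=1,
    )
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    if Xm.shape[0] < Xm.shape[1] + 2:
        raise InputError(
            f"need at least {Xm.shape[1] + 2} subjects for {Xm.shape[1]} design columns"
        )
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        _, _, piv = _qr(Xm, mode="economic", pivoting=True)
        collinear = sorted(names[j] for j in piv[rank:])
        raise InputError(f"design matrix is rank-deficient; collinear columns: {collinear}")
    return Xm, names


def fit_voxelwise_glm(cohort: ImagingCohort, snp: str) -> GlmResult:
    """OLS per masked voxel; t-statistic of the dosage coefficient."""
    if not cohort.mask.any():
        raise InputError("mask is empty")
    X, names = build_design(cohort, snp)
    Y = cohort.volumes[:, cohort.mask]  # (n, V)
    n, p = X.shape
    df = n - p  # full column rank established by build_design

    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ Y)  # (p, V)
    resid = Y - X @ coef
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    j = 1  # dosage column position
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef[j] / se, 0.0)

    t_map = np.full(cohort.mask.shape, np.nan)
    b_map = np.full(cohort.mask.shape, np.nan)
    t_map[cohort.mask] = tvals
    b_map[cohort.mask] = coef[j]
    return GlmResult(t=t_map, beta=b_map, df=df, mask=cohort.mask,
                     affine=cohort.affine, design_columns=names)


def voxel_to_world(index, affine: np.ndarray) -> Tuple[float, float, float]:
    """Map a 0-based grid index to world (mm) coordinates through the affine."""
    v = np.asarray(affine, dtype=float) @ np.array([*index, 1.0])
    return tuple(float(c) for c in v[:3])


def threshold_clusters(
    result: GlmResult,
    direction: str = "positive",
    p_cluster_forming: float = 0.001,
    k_min: int = 11,
    connectivity: int = 18,
) -> List[ClusterResult]:
    """Suprathreshold connected components with extent filter and peak stats.

    ``k_min`` is the minimum retained size: the default 11 encodes the
    strict extent rule k > 10. An empty list is a valid result.
    """
    if direction not in {"positive", "negative"}:
        raise ConfigError("direction must be 'positive' or 'negative'")
    if connectivity not in _STRUCTURES:
        raise ConfigError("connectivity must be one of 6, 18, 26")
    t_thresh = stats.t.isf(p_cluster_forming, result.df)
    signed = result.t if direction == "positive" else -result.t
    supra = np.zeros(result.mask.shape, dtype=bool)
    supra[result.mask] = signed[result.mask] > t_thresh

    labels, n_comp = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    clusters: List[ClusterResult] = []
    for cid in range(1, n_comp + 1):
        idx = np.argwhere(labels == cid)
        k = len(idx)
        if k < k_min:
            continue
        vals = signed[tuple(idx.T)]
        peak = idx[int(np.argmax(vals))]
        peak_signed = float(result.t[tuple(peak)])
        clusters.append(
            ClusterResult(
                cluster_id=len(clusters) + 1,
                k=k,
                peak_index=tuple(int(i) for i in peak),
                peak_mni=voxel_to_world(peak, result.affine),
                peak_t=peak_signed,
                peak_p_uncorrected=float(stats.t.sf(abs(peak_signed), result.df)),
                direction=direction,
            )
        )
    clusters.sort(key=lambda c: -c.k)
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = i
    return clusters


def _residualize(cohort: ImagingCohort, snp: str):
    """Frisch–Waugh–Lovell reduction: residualize dosage and GMV on nuisance."""
    X, names = build_design(cohort, snp)
    x = X[:, 1]
    Z = np.delete(X, 1, axis=1)
    Y = cohort.volumes[:, cohort.mask]
    Qz, _ = np.linalg.qr(Z)
    x_res = x - Qz @ (Qz.T @ x)
    Y_res = Y - Qz @ (Qz.T @ Y)
    df = X.shape[0] - X.shape[1]
    return x_res, Y_res, df, Qz


def _fwl_tmap(x_res: np.ndarray, Y_res: np.ndarray, df: int) -> np.ndarray:
    """Vectorized dosage-coefficient t over voxels from residualized data."""
    xx = float(x_res @ x_res)
    if xx <= 0:
        raise InputError("dosage is collinear with the nuisance covariates")
    b = (x_res @ Y_res) / xx
    yy = np.einsum("ij,ij->j", Y_res, Y_res)
    rss = np.maximum(yy - b * b * xx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / np.sqrt(rss / (df * xx))
    return np.where(np.isfinite(t), t, 0.0)


def max_t_null(
    cohort: ImagingCohort,
    snp: str,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Permutation null of the global max |t| over the mask (Freedman–Lane maxT).

    Outcome residuals from the nuisance-only model are permuted and then
    re-residualized on the nuisance, so each permuted statistic has the same
    scale as the observed one; permuting the dosage residuals instead would
    leave part of the permuted vector inside the nuisance span and deflate
    the null maxima.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    x_res, Y_res, df, Qz = _residualize(cohort, snp)
    xx = float(x_res @ x_res)
    if xx <= 0:
        raise InputError("dosage is collinear with the nuisance covariates")
    yy = np.einsum("ij,ij->j", Y_res, Y_res)
    rng = np.random.default_rng(seed)
    n = len(x_res)
    out = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(n)
        Yp = Y_res[perm]
        # x_res is orthogonal to the nuisance, so re-residualizing Yp only
        # changes the residual sum of squares, not the numerator
        b = (x_res @ Yp) / xx
        W = Qz.T @ Yp
        yyp = yy - np.einsum("ij,ij->j", W, W)
        rss = np.maximum(yyp - b * b * xx, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / np.sqrt(rss / (df * xx))
        out[r] = np.max(np.abs(np.where(np.isfinite(t), t, 0.0)))
    return out


def permutation_peak_fwe(
    cohort: ImagingCohort,
    snp: str,
    clusters: Sequence[ClusterResult],
    n_perm: int,
    seed: int,
) -> List[ClusterResult]:
    """Attach permutation peak-level FWE p-values to clusters (in place)."""
    max_null = max_t_null(cohort, snp, n_perm, seed)
    for c in clusters:
        c.peak_p_fwe = float((1 + np.sum(max_null >= abs(c.peak_t))) / (1 + n_perm))
    return list(clusters)


def label_peak(
    peak_mni: Sequence[float],
    label_volume: np.ndarray,
    label_affine: np.ndarray,
    lookup: Mapping[int, str],
) -> Tuple[str, bool]:
    """Annotate a world coordinate against an integer label volume.

    Returns (label, out_of_field). Label 0 and coordinates outside the grid
    map to "unlabeled"; the latter additionally sets the out-of-field flag.
    """
    inv = np.linalg.inv(np.asarray(label_affine, dtype=float))
    voxel = inv @ np.array([*peak_mni, 1.0])
    idx = np.rint(voxel[:3]).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(label_volume.shape)):
        return "unlabeled", True
    value = int(label_volume[tuple(idx)])
    if value == 0:
        return "unlabeled", False
    return lookup.get(value, "unlabeled"), False


def annotate_clusters(
    clusters: Sequence[ClusterResult],
    label_volume: np.ndarray,
    label_affine: np.ndarray,
    lookup: Mapping[int, str],
) -> List[ClusterResult]:
    for c in clusters:
        c.label, c.out_of_field = label_peak(c.peak_mni, label_volume, label_affine, lookup)
    return list(clusters)


def clusters_to_frame(clusters: Sequence[ClusterResult]) -> pd.DataFrame:
    """Tabulate clusters for reporting (world coordinates in mm)."""
    columns = [
        "cluster_id", "k", "x", "y", "z", "peak_t",
        "p_uncorrected", "p_fwe", "direction", "label",
    ]
    if not clusters:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "k": c.k,
                "x": c.peak_mni[0],
                "y": c.peak_mni[1],
                "z": c.peak_mni[2],
                "peak_t": c.peak_t,
                "p_uncorrected": c.peak_p_uncorrected,
                "p_fwe": c.peak_p_fwe,
                "direction": c.direction,
                "label": c.label,
            }
            for c in clusters
        ]
    )


def load_cohort(
    image_paths: Sequence[str] | str,
    mask_path: str,
    covariates_path: str,
    dosage_columns: Sequence[str],
) -> ImagingCohort:
    """Load a cohort from NIfTI volumes (3D per subject or one 4D stack).

    The covariates TSV must contain the dosage columns; remaining columns
    are treated as covariates.
    """
    import nibabel as nib

    if isinstance(image_paths, str):
        img = nib.load(image_paths)
        data = np.asarray(img.get_fdata())
        if data.ndim != 4:
            raise InputError("single image path must be a 4D stack")
        volumes = np.moveaxis(data, -1, 0)
        affine = img.affine
    else:
        imgs = [nib.load(p) for p in image_paths]
        affine = imgs[0].affine
        for im in imgs[1:]:
            if im.shape != imgs[0].shape or not np.allclose(im.affine, affine):
                raise InputError("subject images disagree in shape or affine")
        volumes = np.stack([np.asarray(im.get_fdata()) for im in imgs])

    mask_img = nib.load(mask_path)
    if mask_img.shape != volumes.shape[1:]:
        raise InputError("mask shape does not match image grid")
    mask = np.asarray(mask_img.get_fdata()) > 0.5

    table = pd.read_csv(covariates_path, sep="\t")
    missing = set(dosage_columns) - set(table.columns)
    if missing:
        raise ConfigError(f"dosage columns missing from covariate table: {sorted(missing)}")
    dosage = table[list(dosage_columns)].astype(float)
    cov = table.drop(columns=list(dosage_columns))
    return ImagingCohort(volumes=volumes, mask=mask, covariates=cov, dosage=dosage, affine=affine)


def read_label_lookup(path) -> Dict[int, str]:
    """Read a (value, label) TSV lookup table for an atlas label volume."""
    df = pd.read_csv(path, sep="\t")
    if not {"value", "label"} <= set(df.columns):
        raise ConfigError(f"{path}: label lookup needs 'value' and 'label' columns")
    return {int(r.value): str(r.label) for r in df.itertuples(index=False)}
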