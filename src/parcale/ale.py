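"""Activation-likelihood estimation over reported foci.

Each focus is modeled as an isotropic 3-D Gaussian whose width reflects the
spatial uncertainty of the reported peak; the dominant determinant is the
study's sample size N, combined in quadrature with a fixed between-template
term:

    sigma_total^2 = sigma_template^2 + sigma_subject^2 / N
    FWHM = 2 * sqrt(2 ln 2) * sigma_total

Per experiment, the modeled-activation (MA) map is the voxel-wise maximum of
its focus kernels (non-additive, so several nearby peaks from one experiment
cannot inflate apparent convergence).  The ALE statistic is the probabilistic
union across experiments, ALE(v) = 1 - prod_i (1 - MA_i(v)): the probability
that at least one experiment's true activation lies at v.  Significance is
assessed against a permutation null that relocates every experiment's foci
uniformly within the analysis mask, pooling null ALE values for voxel-wise p
and recording per-iteration maximum cluster extents for cluster-level FWE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .coords import Experiment, Focus, Space, StudySet

__all__ = [
    "GridSpec",
    "KernelModel",
    "MapKind",
    "ScalarMap",
    "NullModel",
    "ThresholdSpec",
    "NullTables",
    "FWHM_TO_SIGMA",
    "kernel_fwhm",
    "gaussian_kernel_map",
    "modeled_activation_map",
    "ale_union",
    "build_null",
    "voxel_p_map",
    "experiment_contribution",
    "make_mni_grid",
]

# FWHM = 2*sqrt(2 ln 2) * sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class GridSpec:
    """The voxel lattice an analysis lives on.

    ``affine`` maps voxel indices to mm; only axis-aligned (diagonal) affines
    are supported, which covers every standard MNI-aligned grid.  ``mask``
    bounds the analysis domain (e.g. gray matter).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    voxel_size: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        lin = self.affine[:3, :3]
        if not np.allclose(lin, np.diag(np.diag(lin))):
            raise ValueError("only axis-aligned (diagonal) grid affines are supported")
        if self.mask.shape != self.shape:
            raise ValueError(f"mask shape {self.mask.shape} != grid shape {self.shape}")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """mm coordinate of each voxel center along each axis."""
        d = np.diag(self.affine[:3, :3])
        t = self.affine[:3, 3]
        return tuple(d[a] * np.arange(self.shape[a]) + t[a] for a in range(3))  # type: ignore[return-value]

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        arr = np.asarray(ijk, dtype=float)
        single = arr.ndim == 1
        out = np.atleast_2d(arr) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if single else out

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        out = xyz @ inv[:3, :3].T + inv[:3, 3]
        return out

    def mask_voxel_centers(self) -> np.ndarray:
        """(n_inmask, 3) mm coordinates of all in-mask voxel centers."""
        ijk = np.argwhere(self.mask)
        return np.asarray(self.voxel_to_mm(ijk))

    @property
    def n_inmask(self) -> int:
        return int(self.mask.sum())

    def same_geometry(self, other: "GridSpec") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


def make_mni_grid(voxel_size: float = 4.0, mask: str = "ellipsoid") -> GridSpec:
    """An MNI-aligned isotropic grid spanning roughly the adult brain bounding box.

    The default mask is an ellipsoid of semi-axes (70, 85, 75) mm centered at
    (0, -18, 10) mm — a coarse brain envelope adequate for simulation work;
    real analyses should pass their own gray-matter mask.
    """
    # bounding box in mm, generous around MNI152
    lo = np.array([-90.0, -126.0, -72.0])
    hi = np.array([90.0, 90.0, 108.0])
    shape = tuple(int(np.floor((hi[a] - lo[a]) / voxel_size)) + 1 for a in range(3))
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = lo
    if mask == "ellipsoid":
        center = np.array([0.0, -18.0, 10.0])
        semi = np.array([70.0, 85.0, 75.0])
        ax = [lo[a] + voxel_size * np.arange(shape[a]) for a in range(3)]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        m = (
            ((xx - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((zz - center[2]) / semi[2]) ** 2
        ) <= 1.0
    elif mask == "full":
        m = np.ones(shape, dtype=bool)
    else:
        raise ValueError(f"unknown mask preset {mask!r}")
    return GridSpec(shape=shape, affine=affine, voxel_size=voxel_size, mask=m)


# The ALE lineage estimated localization uncertainty as mean Euclidean
# displacements of 5.7 mm (between templates) and 11.6 mm (between subjects)
# and converts displacement to Gaussian FWHM by sqrt(8 ln 2) / (2 sqrt(2/pi)).
_ED_TO_FWHM = math.sqrt(8.0 * math.log(2.0)) / (2.0 * math.sqrt(2.0 / math.pi))
DEFAULT_FWHM_TEMPLATE = 5.7 * _ED_TO_FWHM  # ~8.41 mm
DEFAULT_FWHM_SUBJECT = 11.6 * _ED_TO_FWHM  # ~17.12 mm


@dataclass(frozen=True)
class KernelModel:
    """Two-component spatial-uncertainty model for the focus kernel.

    ``fwhm_template`` captures between-template (normalization) uncertainty;
    ``fwhm_subject`` captures between-subject uncertainty and shrinks with
    sample size as sigma_subject/sqrt(N).  Defaults are the standard ALE
    lineage values — empirical mean displacements of 5.7 and 11.6 mm
    expressed as Gaussian FWHMs (8.41 and 17.12 mm); a 15-subject study gets
    a ~9.5 mm kernel.
    """

    fwhm_template: float = DEFAULT_FWHM_TEMPLATE
    fwhm_subject: float = DEFAULT_FWHM_SUBJECT

    def __post_init__(self) -> None:
        if self.fwhm_template <= 0 and self.fwhm_subject <= 0:
            raise ValueError("at least one FWHM component must be positive")
        if self.fwhm_template < 0 or self.fwhm_subject < 0:
            raise ValueError("FWHM components must be non-negative")


def kernel_fwhm(n_subjects: int, k: KernelModel = KernelModel()) -> float:
    """Kernel FWHM (mm) for a study of N subjects.

    Strictly decreasing in N whenever the subject term is nonzero, tending to
    ``fwhm_template`` as N grows.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    s_t = k.fwhm_template * FWHM_TO_SIGMA
    s_s = k.fwhm_subject * FWHM_TO_SIGMA
    sigma = math.sqrt(s_t**2 + s_s**2 / n_subjects)
    return sigma / FWHM_TO_SIGMA


class MapKind(str, Enum):
    MA = "MA"
    ALE = "ALE"
    P = "P"


@dataclass
class ScalarMap:
    """One scalar per voxel on a grid; zero outside the mask."""

    grid: GridSpec
    values: np.ndarray
    kind: MapKind
    source_id: str | None = None  # experiment id for MA maps

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid shape")

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float64), self.grid.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


# per-axis relative weight below which kernel tails are dropped; the mass
# discarded is < 1e-9 of the kernel, far inside the 1e-6 normalization check
_KERNEL_TAIL_REL = 1e-12


def _axis_kernels(
    focus_mm: np.ndarray, grid: GridSpec, sigma: float
) -> list[tuple[int, np.ndarray]] | None:
    """Per-axis discretized Gaussian factors, normalized to unit full-axis sum.

    Returns ``None`` when the kernel carries no mass on the lattice (focus far
    outside the grid).  Each factor is (start_index, weights) restricted to
    where the weights are non-negligible; because the factors are normalized
    over the *full* axis, the separable product sums to 1 over the full
    (unmasked) lattice up to the discarded tails.
    """
    out: list[tuple[int, np.ndarray]] = []
    for a, coords in enumerate(grid.axis_coords()):
        w = np.exp(-0.5 * ((coords - focus_mm[a]) / sigma) ** 2)
        tot = w.sum()
        if tot <= 0:
            return None
        w = w / tot
        keep = np.nonzero(w > _KERNEL_TAIL_REL * w.max())[0]
        out.append((int(keep[0]), w[keep[0] : keep[-1] + 1]))
    return out


def gaussian_kernel_map(
    focus: Focus, grid: GridSpec, fwhm: float, out: np.ndarray | None = None
) -> np.ndarray:
    """Dense lattice discretization of the focus kernel, summing to 1 unmasked.

    With ``out`` given, writes the kernel into it via element-wise maximum
    (the MA combination rule) and returns ``out``.
    """
    sigma = fwhm * FWHM_TO_SIGMA
    if sigma <= 0:
        raise ValueError("kernel FWHM must be positive")
    if out is None:
        out = np.zeros(grid.shape, dtype=float)
    factors = _axis_kernels(focus.as_array(), grid, sigma)
    if factors is None:
        return out
    (i0, wx), (j0, wy), (k0, wz) = factors
    block = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
    sl = (
        slice(i0, i0 + wx.size),
        slice(j0, j0 + wy.size),
        slice(k0, k0 + wz.size),
    )
    np.maximum(out[sl], block, out=out[sl])
    return out


def modeled_activation_map(
    e: Experiment,
    g: GridSpec,
    k: KernelModel = KernelModel(),
    *,
    warn: bool = True,
) -> ScalarMap:
    """Per-experiment MA map: voxel-wise max over the experiment's focus kernels."""
    if e.space != Space.MNI:
        raise ValueError(f"experiment {e.id!r} must be in MNI space (got {e.space})")
    if not e.foci:
        raise ValueError(f"experiment {e.id!r} has no foci")
    fwhm = kernel_fwhm(e.n_subjects, k)
    vals = np.zeros(g.shape, dtype=float)
    axes = g.axis_coords()
    lo = np.array([min(c[0], c[-1]) for c in axes])
    hi = np.array([max(c[0], c[-1]) for c in axes])
    for f in e.foci:
        p = f.as_array()
        if np.any(p < lo - 3 * fwhm) or np.any(p > hi + 3 * fwhm):
            if warn:
                import warnings

                warnings.warn(
                    f"experiment {e.id!r}: focus at {tuple(p)} lies more than "
                    f"3*FWHM outside the grid; skipped",
                    stacklevel=2,
                )
            continue
        gaussian_kernel_map(f, g, fwhm, out=vals)
    vals[~g.mask] = 0.0
    return ScalarMap(grid=g, values=vals, kind=MapKind.MA, source_id=e.id)


def _sorted_ma(mas: list[ScalarMap]) -> list[ScalarMap]:
    # sorting by source id makes the log-space reduction bit-identical under
    # any input ordering; unnamed maps keep their relative positions at the end
    keyed = sorted(
        enumerate(mas),
        key=lambda t: (t[1].source_id is None, t[1].source_id or "", t[0]),
    )
    return [m for _, m in keyed]


def ale_union(mas: list[ScalarMap]) -> ScalarMap:
    """Probabilistic union of MA maps: ALE(v) = 1 - prod_i (1 - MA_i(v)).

    Accumulated in log space over maps sorted by source id, so the result is
    bit-identical regardless of the order the maps are supplied in.
    """
    if not mas:
        raise ValueError("ale_union requires at least one MA map")
    g = mas[0].grid
    for m in mas[1:]:
        if not g.same_geometry(m.grid):
            raise ValueError("MA maps live on different grids")
    log_comp = np.zeros(g.shape, dtype=float)
    for m in _sorted_ma(mas):
        log_comp += np.log1p(-np.clip(m.values, 0.0, 1.0 - 1e-300))
    vals = -np.expm1(log_comp)
    vals[~g.mask] = 0.0
    return ScalarMap(grid=g, values=vals, kind=MapKind.ALE)


def _studyset_ale(
    foci_mm: list[np.ndarray],
    fwhms: list[float],
    g: GridSpec,
    exp_ids: list[str],
) -> np.ndarray:
    """ALE values from raw per-experiment foci arrays (fast inner loop)."""
    log_comp = np.zeros(g.shape, dtype=float)
    order = sorted(range(len(exp_ids)), key=lambda i: exp_ids[i])
    for i in order:
        ma = np.zeros(g.shape, dtype=float)
        sigma = fwhms[i] * FWHM_TO_SIGMA
        for p in foci_mm[i]:
            factors = _axis_kernels(p, g, sigma)
            if factors is None:
                continue
            (i0, wx), (j0, wy), (k0, wz) = factors
            block = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
            sl = (
                slice(i0, i0 + wx.size),
                slice(j0, j0 + wy.size),
                slice(k0, k0 + wz.size),
            )
            np.maximum(ma[sl], block, out=ma[sl])
        ma[~g.mask] = 0.0
        log_comp += np.log1p(-np.clip(ma, 0.0, 1.0 - 1e-300))
    vals = -np.expm1(log_comp)
    vals[~g.mask] = 0.0
    return vals


class NullMethod(str, Enum):
    PERMUTATION = "permutation"
    HISTOGRAM = "histogram"


@dataclass(frozen=True)
class NullModel:
    """Configuration of the empirical null for ALE significance."""

    method: NullMethod = NullMethod.PERMUTATION
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class ThresholdSpec:
    """Voxel-forming and cluster-level thresholds."""

    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not (0.0 < self.voxel_p < 1.0):
            raise ValueError("voxel_p must be in (0, 1)")
        if not (0.0 < self.cluster_alpha < 1.0):
            raise ValueError("cluster_alpha must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")


def connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


@dataclass
class NullTables:
    """Empirical null distributions from foci permutation.

    ``voxel_null`` pools the null ALE values over all in-mask voxels and all
    iterations (sorted ascending).  ``cluster_extent_null`` holds, per
    iteration, the maximum supra-threshold cluster size in voxels after
    voxel-level thresholding at ``ale_crit`` (the pooled-null ALE value whose
    exceedance probability is the voxel-forming p).  ``max_ale_null`` holds
    each iteration's maximum in-mask ALE value (the max-statistic null).
    """

    voxel_null: np.ndarray
    cluster_extent_null: list[int]
    ale_crit: float
    seed: int
    n_permutations: int
    method: NullMethod = NullMethod.PERMUTATION
    max_ale_null: np.ndarray | None = None

    def save(self, prefix: str | Path) -> None:
        import json

        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".voxel_null.tsv"), self.voxel_null, fmt="%.10g")
        np.savetxt(
            prefix.with_suffix(".cluster_null.tsv"),
            np.asarray(self.cluster_extent_null, dtype=int),
            fmt="%d",
        )
        meta = {
            "seed": self.seed,
            "n_permutations": self.n_permutations,
            "method": self.method.value,
            "ale_crit": self.ale_crit,
        }
        prefix.with_suffix(".null.json").write_text(json.dumps(meta, indent=2) + "\n")


def _null_critical_value(voxel_null_sorted: np.ndarray, voxel_p: float) -> float:
    """Smallest ALE value whose corrected exceedance p is below ``voxel_p``.

    Uses the (r+1)/(n+1) estimator: p(a) = (#null >= a + 1)/(n + 1).
    """
    n = voxel_null_sorted.size
    # need (#null >= a) + 1 < voxel_p * (n + 1)  =>  #null >= a <= k_max
    k_max = math.ceil(voxel_p * (n + 1)) - 2  # largest admissible count >= a
    if k_max < 0:
        return math.inf  # voxel_p unreachable at this permutation count
    # a must exceed the (k_max+1)-th largest null value
    idx = n - (k_max + 1)
    return float(np.nextafter(voxel_null_sorted[idx], math.inf))


def build_null(
    s: StudySet,
    g: GridSpec,
    k: KernelModel,
    nm: NullModel,
    t: ThresholdSpec,
) -> NullTables:
    """Permutation null: relocate every experiment's foci uniformly in the mask.

    Focus counts and sample sizes (hence kernel widths) are preserved; only
    locations are randomized, realizing the hypothesis of no spatial
    association between the reported foci.
    """
    if nm.method != NullMethod.PERMUTATION:
        raise NotImplementedError("only the permutation null is implemented")
    centers = g.mask_voxel_centers()
    n_foci = [len(e.foci) for e in s.experiments]
    if centers.shape[0] < max(n_foci, default=1):
        raise ValueError("mask too small for the requested number of foci")
    fwhms = [kernel_fwhm(e.n_subjects, k) for e in s.experiments]
    ids = [e.id for e in s.experiments]
    rng = np.random.default_rng(nm.seed)
    mask_flat = g.mask.ravel()
    n_inmask = g.n_inmask

    null_vals = np.empty((nm.n_permutations, n_inmask), dtype=np.float32)
    for it in range(nm.n_permutations):
        foci_mm = [
            centers[rng.integers(0, centers.shape[0], size=nf)] for nf in n_foci
        ]
        vals = _studyset_ale(foci_mm, fwhms, g, ids)
        null_vals[it] = vals.ravel()[mask_flat]

    pooled = np.sort(null_vals.reshape(-1).astype(float))
    ale_crit = _null_critical_value(pooled, t.voxel_p)

    struct = connectivity_structure(t.connectivity)
    extents: list[int] = []
    supra = np.zeros(g.shape, dtype=bool)
    for it in range(nm.n_permutations):
        supra[:] = False
        supra.ravel()[mask_flat] = null_vals[it] >= ale_crit
        if supra.any():
            labels, n_lab = ndimage.label(supra, structure=struct)
            sizes = np.bincount(labels.ravel())[1:]
            extents.append(int(sizes.max()))
        else:
            extents.append(0)

    return NullTables(
        voxel_null=pooled,
        cluster_extent_null=extents,
        ale_crit=ale_crit,
        seed=nm.seed,
        n_permutations=nm.n_permutations,
        max_ale_null=null_vals.max(axis=1).astype(float),
    )


def voxel_p_map(ale: ScalarMap, null: NullTables) -> ScalarMap:
    """Voxel-wise permutation p: share of pooled null ALE values >= observed.

    Uses the (r+1)/(n+1) small-sample correction, so p never reaches zero at
    finite permutation counts.  Outside the mask the map is zero (by the
    zero-outside-mask convention for all grids); mask before thresholding.
    """
    if null.voxel_null.size == 0:
        raise ValueError("voxel null table is empty")
    n = null.voxel_null.size
    flat = ale.values.ravel()
    # count of null values >= observed, via searchsorted on the ascending pool
    ge = n - np.searchsorted(null.voxel_null, flat, side="left")
    p = (ge + 1.0) / (n + 1.0)
    p = p.reshape(ale.grid.shape)
    p[~ale.grid.mask] = 0.0
    return ScalarMap(grid=ale.grid, values=p, kind=MapKind.P)


def supra_threshold(ale: ScalarMap, null: NullTables, t: ThresholdSpec) -> np.ndarray:
    """Boolean volume of in-mask voxels passing the voxel-forming threshold."""
    p = voxel_p_map(ale, null)
    return (p.values < t.voxel_p) & ale.grid.mask & (p.values > 0)


def experiment_contribution(
    cluster_voxels: np.ndarray | list[tuple[int, int, int]],
    s: StudySet,
    mas: list[ScalarMap],
) -> dict[str, float]:
    """Leave-one-out contribution of each experiment to a cluster's summed ALE.

    contribution_i = (sum_ALE - sum_ALE_without_i) / sum_ALE over the cluster.
    The maximum over experiments bounds how much a single study dominates the
    pooled result; a well-powered meta-analysis keeps it at or below 50%.
    """
    if len(mas) != len(s.experiments):
        raise ValueError("need one MA map per experiment")
    by_id = {m.source_id: m for m in mas}
    if set(by_id) != {e.id for e in s.experiments}:
        raise ValueError("MA map source ids do not match experiment ids")
    vox = np.asarray(list(cluster_voxels) if not isinstance(cluster_voxels, np.ndarray) else cluster_voxels)
    if vox.ndim != 2 or vox.shape[1] != 3:
        raise ValueError("cluster voxels must be an (n, 3) index array")
    g = mas[0].grid
    if np.any(vox < 0) or np.any(vox >= np.array(g.shape)):
        raise ValueError("cluster voxels outside the grid")
    idx = tuple(vox.T)

    ids = sorted(by_id)
    log_comp = np.zeros(vox.shape[0], dtype=float)
    per_exp = {}
    for i in ids:
        li = np.log1p(-np.clip(by_id[i].values[idx], 0.0, 1.0 - 1e-300))
        per_exp[i] = li
        log_comp += li
    ale_full = -np.expm1(log_comp)
    total = ale_full.sum()
    if total <= 0:
        raise ValueError("cluster has zero summed ALE")
    contrib: dict[str, float] = {}
    for i in ids:
        ale_wo = -np.expm1(log_comp - per_exp[i])
        contrib[i] = float((total - ale_wo.sum()) / total)
    return contrib
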