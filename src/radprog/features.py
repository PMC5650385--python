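"""The 970-feature radiomics catalog: first-order, shape, GLCM and GLRLM
features over the 13 image variants of each of two MRI sequences.

Per sequence the catalog is: 11 shape features (mask only) + 19 first-order
features (original image) + (24 GLCM + 11 GLRLM) x 13 variants = 485; two
sequences give 970 per patient.  Texture matrices are accumulated over the 13
unique 3-D directions at distance 1 and merged before normalization, giving a
single GLCM / GLRLM per variant.

Feature keys follow ``{sequence}_{variant}_{family}_{name}``, e.g.
``T2w_3_GLCM_homogeneity1`` (sequence T2w, variant 3 = LoG sigma 1.5).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes, mesh_surface_area

from .imaging import (
    DEFAULT_LOG_SIGMAS,
    DiscretizedROI,
    ImageVolume,
    ROIMask,
    build_variant_set,
    discretize,
)

__all__ = [
    "DIRECTIONS_3D_13",
    "GLCM",
    "GLRLM",
    "FeatureCatalog",
    "NormalizationStats",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "firstorder_features",
    "shape_features",
    "extract_all",
    "extract_selected",
    "zscore_normalize",
    "volume_correlation_audit",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "FIRSTORDER_FEATURE_NAMES",
    "SHAPE_FEATURE_NAMES",
    "VOLUME_CORRELATION_CATEGORIES",
]

#: The 13 unique 3-D neighbor directions (offsets up to sign).
DIRECTIONS_3D_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation", "cluster_prominence", "cluster_shade", "cluster_tendency",
    "contrast", "correlation", "difference_average", "difference_entropy",
    "difference_variance", "dissimilarity", "energy", "entropy",
    "homogeneity1", "homogeneity2", "idmn", "idn", "imc1", "imc2",
    "inverse_variance", "maximum_probability", "sum_average", "sum_entropy",
    "sum_variance", "variance",
)

GLRLM_FEATURE_NAMES: tuple[str, ...] = (
    "sre", "lre", "gln", "rln", "rp",
    "lglre", "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle",
)

FIRSTORDER_FEATURE_NAMES: tuple[str, ...] = (
    "mean", "median", "min", "max", "range", "variance", "std",
    "skewness", "kurtosis", "energy", "entropy", "uniformity", "rms",
    "mad", "p10", "p90", "iqr", "robust_mad", "total_energy",
)

SHAPE_FEATURE_NAMES: tuple[str, ...] = (
    "volume_mm3", "surface_area_mm2", "surface_volume_ratio", "sphericity",
    "compactness1", "compactness2", "spherical_disproportion",
    "max_3d_diameter_mm", "major_axis_mm", "minor_axis_mm", "least_axis_mm",
)


@dataclass
class GLCM:
    """Symmetric, normalized gray-level co-occurrence matrix."""

    p: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.n_levels, self.n_levels):
            raise ValueError("GLCM must be n_levels x n_levels")
        total = self.p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"GLCM must sum to 1, got {total}")


@dataclass
class GLRLM:
    """Merged gray-level run-length matrix (levels x run lengths).

    ``r[i, j]`` counts maximal runs of level ``i+1`` with length ``j+1``,
    summed over the scan directions; ``n_runs`` is the total run count and
    ``n_voxels``/``n_directions`` support run-percentage normalization.
    """

    r: np.ndarray
    n_levels: int
    n_voxels: int
    n_directions: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if (self.r < 0).any():
            raise ValueError("run counts must be non-negative")

    @property
    def n_runs(self) -> float:
        return float(self.r.sum())


def compute_glcm(
    d: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D_13,
    distance: int = 1,
) -> GLCM:
    """Co-occurrence counts of in-mask level pairs at the given distance,
    accumulated over all directions, symmetrized, and normalized to sum 1."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if not directions:
        raise ValueError("directions must be non-empty")
    levels = d.levels
    ng = d.n_bins
    counts = np.zeros((ng, ng), dtype=float)
    shape = levels.shape
    for dx, dy, dz in directions:
        off = (dx * distance, dy * distance, dz * distance)
        src = tuple(
            slice(max(0, -o), min(n, n - o)) for o, n in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), min(n, n + o)) for o, n in zip(off, shape)
        )
        a = levels[src].ravel()
        b = levels[dst].ravel()
        valid = (a > 0) & (b > 0)
        if valid.any():
            flat = (a[valid] - 1) * ng + (b[valid] - 1)
            counts += np.bincount(flat, minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-mask voxel pairs at this distance")
    return GLCM(counts / total, ng)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(m: GLCM) -> dict[str, float]:
    """The 24-feature GLCM set (Haralick and descendants).

    Degenerate marginals (sigma_x or sigma_y = 0, or zero marginal entropy)
    yield correlation = 1 and imc1 = imc2 = 0 by convention.
    """
    ng = m.n_levels
    p = m.p
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))
    diff = np.abs(ii - jj)

    # p_{x-y}(k), k = 0..ng-1 and p_{x+y}(k), k = 2..2ng
    k_minus = np.arange(ng, dtype=float)
    p_minus = np.array([p[diff == k].sum() for k in range(ng)])
    k_plus = np.arange(2, 2 * ng + 1, dtype=float)
    p_plus = np.array([p[(ii + jj) == k].sum() for k in k_plus])

    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii - mu_x) * (jj - mu_y) * p).sum() / (sd_x * sd_y))
    else:
        correlation = 1.0

    hxy = _entropy2(p.ravel())
    hx = _entropy2(px)
    hy = _entropy2(py)
    outer = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = _entropy2(outer.ravel())
    denom = max(hx, hy)
    imc1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if denom > 0 else 0.0

    da = float((k_minus * p_minus).sum())
    sa = float((k_plus * p_plus).sum())
    off_diag = diff > 0

    return {
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_prominence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "cluster_shade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "cluster_tendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": correlation,
        "difference_average": da,
        "difference_entropy": _entropy2(p_minus),
        "difference_variance": float(((k_minus - da) ** 2 * p_minus).sum()),
        "dissimilarity": float((diff * p).sum()),
        "energy": float((p * p).sum()),
        "entropy": hxy,
        "homogeneity1": float((p / (1.0 + diff)).sum()),
        "homogeneity2": float((p / (1.0 + diff**2)).sum()),
        "idmn": float((p / (1.0 + (diff / ng) ** 2)).sum()),
        "idn": float((p / (1.0 + diff / ng)).sum()),
        "imc1": imc1,
        "imc2": imc2,
        "inverse_variance": float((p[off_diag] / diff[off_diag] ** 2).sum()),
        "maximum_probability": float(p.max()),
        "sum_average": sa,
        "sum_entropy": _entropy2(p_plus),
        "sum_variance": float(((k_plus - sa) ** 2 * p_plus).sum()),
        "variance": float(((ii - mu_x) ** 2 * p).sum()),
    }


def compute_glrlm(
    d: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D_13,
) -> GLRLM:
    """Maximal runs of equal gray level along each direction, within the mask,
    with run matrices summed over directions.

    Out-of-mask voxels (level 0) break runs.  Runs are enumerated by sorting
    voxels by scan line and position along the line, which is equivalent to
    walking every line in each direction.
    """
    if not directions:
        raise ValueError("directions must be non-empty")
    levels = d.levels
    ng = d.n_bins
    shape = levels.shape
    coords = np.indices(shape).reshape(3, -1)
    flat_levels = levels.ravel()
    max_len = int(np.ceil(np.sqrt(sum((n - 1) ** 2 for n in shape)))) + 1
    counts = np.zeros((ng, max_len), dtype=float)

    for dvec in directions:
        dvec_arr = np.asarray(dvec)
        # position along the line: the coordinate of the first axis with a
        # non-zero step (its step is +1 for every direction in the set)
        axis = int(np.nonzero(dvec_arr)[0][0])
        t = coords[axis]
        line_id = coords - np.outer(dvec_arr, t)
        order = np.lexsort((t, line_id[2], line_id[1], line_id[0]))
        lv = flat_levels[order]
        lid = line_id[:, order]
        same_line = np.all(lid[:, 1:] == lid[:, :-1], axis=0)
        new_run = np.empty(lv.size, dtype=bool)
        new_run[0] = True
        new_run[1:] = ~same_line | (lv[1:] != lv[:-1])
        starts = np.flatnonzero(new_run)
        lengths = np.diff(np.append(starts, lv.size))
        run_levels = lv[starts]
        keep = run_levels > 0
        np.add.at(counts, (run_levels[keep] - 1, lengths[keep] - 1), 1.0)

    used = np.flatnonzero(counts.sum(axis=0))
    rmax = int(used[-1]) + 1 if used.size else 1
    return GLRLM(counts[:, :rmax], ng, d.n_voxels, len(directions))


def glrlm_features(m: GLRLM) -> dict[str, float]:
    """The 11-feature GLRLM set (run emphases, nonuniformities, run %)."""
    nr = m.n_runs
    if nr == 0:
        raise ValueError("GLRLM has no runs")
    r = m.r
    i = np.arange(1, r.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, r.shape[1] + 1, dtype=float)[None, :]
    return {
        "sre": float((r / j**2).sum() / nr),
        "lre": float((r * j**2).sum() / nr),
        "gln": float((r.sum(axis=1) ** 2).sum() / nr),
        "rln": float((r.sum(axis=0) ** 2).sum() / nr),
        "rp": float(nr / (m.n_voxels * m.n_directions)),
        "lglre": float((r / i**2).sum() / nr),
        "hglre": float((r * i**2).sum() / nr),
        "srlgle": float((r / (i**2 * j**2)).sum() / nr),
        "srhgle": float((r * i**2 / j**2).sum() / nr),
        "lrlgle": float((r * j**2 / i**2).sum() / nr),
        "lrhgle": float((r * i**2 * j**2).sum() / nr),
    }


def firstorder_features(
    image: ImageVolume, mask: ROIMask, n_bins: int = 32
) -> dict[str, float]:
    """Intensity-histogram statistics over in-mask voxels.

    Entropy and uniformity use an equal-width ``n_bins`` histogram of the
    in-mask range (base-2 entropy); skewness and kurtosis (Pearson, not
    excess) are defined as 0 for a constant region.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    v = image.values[mask.values]
    if v.max() > v.min():
        var = float(np.var(v))
        skew = float(sps.skew(v))
        kurt = float(sps.kurtosis(v, fisher=False))
    else:  # constant region: central moments vanish by definition
        var = 0.0
        skew = 0.0
        kurt = 0.0
    hist, _ = np.histogram(v, bins=n_bins)
    pk = hist / hist.sum()
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    energy = float((v**2).sum())
    return {
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "variance": var,
        "std": float(np.sqrt(var)),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": energy,
        "entropy": _entropy2(pk),
        "uniformity": float((pk**2).sum()),
        "rms": float(np.sqrt((v**2).mean())),
        "mad": float(np.abs(v - v.mean()).mean()),
        "p10": float(p10),
        "p90": float(p90),
        "iqr": float(p75 - p25),
        "robust_mad": float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "total_energy": float(np.prod(image.spacing_mm)) * energy,
    }


def _max_diameter(points_mm: np.ndarray) -> float:
    if len(points_mm) < 2:
        return 0.0
    if len(points_mm) > 500:
        try:
            points_mm = points_mm[ConvexHull(points_mm).vertices]
        except QhullError:
            pass  # degenerate (coplanar) clouds fall back to all points
    d2 = ((points_mm[:, None, :] - points_mm[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: ROIMask, spacing_mm: tuple[float, float, float] | None = None) -> dict[str, float]:
    """Volume and 3-D shape descriptors of the tumor mask.

    Volume is voxel count x voxel volume; surface area comes from a
    marching-cubes mesh of the (zero-padded) mask; axis lengths are
    4 sqrt(lambda) of the physical-coordinate covariance eigenvalues.
    Single-voxel masks have zero diameter and axis lengths.
    """
    spacing = tuple(float(s) for s in (spacing_mm or mask.spacing_mm))
    n = mask.n_voxels
    volume = n * float(np.prod(spacing))
    padded = np.pad(mask.values.astype(np.uint8), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(mesh_surface_area(verts, faces))
    coords = np.argwhere(mask.values) * np.asarray(spacing)
    if n > 1:
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(coords.T, bias=True)))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
        major, minor, least = (4.0 * np.sqrt(e) for e in eigvals)
    else:
        major = minor = least = 0.0
    sphere_r = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = (np.pi ** (1.0 / 3.0)) * (6.0 * volume) ** (2.0 / 3.0) / area
    return {
        "volume_mm3": volume,
        "surface_area_mm2": area,
        "surface_volume_ratio": area / volume,
        "sphericity": float(sphericity),
        "compactness1": float(volume / (np.sqrt(np.pi) * area**1.5)),
        "compactness2": float(36.0 * np.pi * volume**2 / area**3),
        "spherical_disproportion": float(area / (4.0 * np.pi * sphere_r**2)),
        "max_3d_diameter_mm": _max_diameter(coords),
        "major_axis_mm": float(major),
        "minor_axis_mm": float(minor),
        "least_axis_mm": float(least),
    }


@dataclass(frozen=True)
class FeatureCatalog:
    """Deterministic ordered definition of every feature key.

    Entries are ``(sequence, variant_index, family, name)`` tuples; the string
    key is ``{sequence}_{variant}_{family}_{name}``.  With the default two
    sequences and 13 variants the catalog has exactly 970 entries (485 per
    sequence): 11 shape + 19 first-order on the original variant, plus
    24 GLCM + 11 GLRLM on each of the 13 variants.
    """

    sequences: tuple[str, ...] = ("T2w", "CET1w")
    n_variants: int = 13
    entries: tuple[tuple[str, int, str, str], ...] = field(init=False)

    def __post_init__(self) -> None:
        entries: list[tuple[str, int, str, str]] = []
        for seq in self.sequences:
            for name in SHAPE_FEATURE_NAMES:
                entries.append((seq, 1, "shape", name))
            for name in FIRSTORDER_FEATURE_NAMES:
                entries.append((seq, 1, "firstorder", name))
            for variant in range(1, self.n_variants + 1):
                for name in GLCM_FEATURE_NAMES:
                    entries.append((seq, variant, "GLCM", name))
                for name in GLRLM_FEATURE_NAMES:
                    entries.append((seq, variant, "GLRLM", name))
        per_seq = len(entries) // len(self.sequences)
        expected = (
            len(SHAPE_FEATURE_NAMES)
            + len(FIRSTORDER_FEATURE_NAMES)
            + self.n_variants * (len(GLCM_FEATURE_NAMES) + len(GLRLM_FEATURE_NAMES))
        )
        assert per_seq == expected, "catalog arithmetic broken"
        if self.n_variants == 13:
            assert per_seq == 485, per_seq
        object.__setattr__(self, "entries", tuple(entries))
        assert len(set(self.keys)) == len(entries), "duplicate catalog keys"

    @property
    def keys(self) -> list[str]:
        return [f"{s}_{v}_{fam}_{name}" for s, v, fam, name in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def checksum(self) -> str:
        return hashlib.sha256("\n".join(self.keys).encode()).hexdigest()

    def parse_key(self, key: str) -> tuple[str, int, str, str]:
        seq, variant, family, name = key.split("_", 3)
        entry = (seq, int(variant), family, name)
        if entry not in self.entries:
            raise KeyError(f"unknown catalog key: {key}")
        return entry

    def to_json(self) -> list[str]:
        return self.keys


def _variant_images(
    volume: ImageVolume,
    needed: set[int],
    log_sigmas: tuple[float, ...],
    wavelet: str,
) -> dict[int, ImageVolume]:
    variants = build_variant_set(volume, log_sigmas=log_sigmas, wavelet=wavelet)
    return {v.variant_index: v.image for v in variants if v.variant_index in needed}


def extract_all(
    volumes: dict[str, ImageVolume],
    mask: ROIMask,
    catalog: FeatureCatalog | None = None,
    n_bins: int = 32,
    log_sigmas: tuple[float, ...] = DEFAULT_LOG_SIGMAS,
    wavelet: str = "coif1",
) -> pd.Series:
    """Compute the full feature vector for one patient, ordered by catalog.

    ``volumes`` maps sequence label to its image; both catalog sequences must
    be present and aligned with the mask.
    """
    catalog = catalog or FeatureCatalog()
    missing = [s for s in catalog.sequences if s not in volumes]
    if missing:
        raise ValueError(f"missing sequence(s): {', '.join(missing)}")
    values: dict[str, float] = {}
    for seq in catalog.sequences:
        vol = volumes[seq]
        if vol.shape != mask.shape:
            raise ValueError(f"sequence {seq} not aligned with mask")
        shape_vals = shape_features(mask, vol.spacing_mm)
        fo_vals = firstorder_features(vol, mask, n_bins=n_bins)
        texture: dict[int, tuple[dict[str, float], dict[str, float]]] = {}
        for var in build_variant_set(vol, log_sigmas=log_sigmas, wavelet=wavelet):
            d = discretize(var.image, mask, n_bins=n_bins)
            texture[var.variant_index] = (
                glcm_features(compute_glcm(d)),
                glrlm_features(compute_glrlm(d)),
            )
        for s, variant, family, name in catalog.entries:
            if s != seq:
                continue
            key = f"{s}_{variant}_{family}_{name}"
            if family == "shape":
                values[key] = shape_vals[name]
            elif family == "firstorder":
                values[key] = fo_vals[name]
            elif family == "GLCM":
                values[key] = texture[variant][0][name]
            else:
                values[key] = texture[variant][1][name]
    out = pd.Series(values, dtype=float).reindex(catalog.keys)
    if out.isna().any():
        raise RuntimeError("catalog entries left uncomputed")
    return out


def extract_selected(
    volumes: dict[str, ImageVolume],
    mask: ROIMask,
    keys: list[str],
    catalog: FeatureCatalog | None = None,
    n_bins: int = 32,
    log_sigmas: tuple[float, ...] = DEFAULT_LOG_SIGMAS,
    wavelet: str = "coif1",
) -> pd.Series:
    """Compute only the requested catalog keys (used for planted signals)."""
    catalog = catalog or FeatureCatalog()
    entries = [catalog.parse_key(k) for k in keys]
    needed: dict[str, set[int]] = {}
    for seq, variant, family, _ in entries:
        if family in ("GLCM", "GLRLM"):
            needed.setdefault(seq, set()).add(variant)
    cache: dict[tuple[str, int], tuple[dict[str, float], dict[str, float]]] = {}
    for seq, variants in needed.items():
        if seq not in volumes:
            raise ValueError(f"missing sequence: {seq}")
        for variant, img in _variant_images(volumes[seq], variants, log_sigmas, wavelet).items():
            d = discretize(img, mask, n_bins=n_bins)
            cache[(seq, variant)] = (
                glcm_features(compute_glcm(d)),
                glrlm_features(compute_glrlm(d)),
            )
    values: dict[str, float] = {}
    for key, (seq, variant, family, name) in zip(keys, entries):
        if family == "shape":
            values[key] = shape_features(mask, volumes[seq].spacing_mm)[name]
        elif family == "firstorder":
            values[key] = firstorder_features(volumes[seq], mask, n_bins=n_bins)[name]
        elif family == "GLCM":
            values[key] = cache[(seq, variant)][0][name]
        else:
            values[key] = cache[(seq, variant)][1][name]
    return pd.Series(values, dtype=float)


@dataclass
class NormalizationStats:
    """Per-feature discovery-set mean/sd (population convention, ddof=0).

    Features with zero variance are flagged in ``zero_variance`` — they are
    centered and left at 0 in the transformed table, and must be excluded
    from model selection rather than silently dropped.
    """

    mean: pd.Series
    std: pd.Series
    zero_variance: list[str]


def zscore_normalize(
    table: pd.DataFrame, stats: NormalizationStats | None = None
) -> tuple[pd.DataFrame, NormalizationStats]:
    """Z-score transform each feature column (mean 0, sd 1).

    With ``stats=None`` the statistics are estimated on the input table (the
    discovery set) and applied; otherwise the frozen statistics are applied
    unchanged (the validation set).
    """
    if stats is None:
        if len(table) < 2:
            raise ValueError("need >= 2 rows to estimate normalization statistics")
        mean = table.mean(axis=0)
        std = table.std(axis=0, ddof=0)
        zero = std.index[std == 0].tolist()
        stats = NormalizationStats(mean, std, zero)
    safe_std = stats.std.replace(0.0, 1.0)
    out = (table - stats.mean) / safe_std
    return out, stats


#: |rho| breakpoints and labels for the feature-volume correlation audit.
VOLUME_CORRELATION_CATEGORIES: tuple[tuple[float, str], ...] = (
    (0.255, "little if any"),
    (0.495, "low"),
    (0.695, "moderate"),
    (0.895, "high"),
    (1.001, "very high"),
)


def _correlation_category(rho: float) -> str:
    a = abs(rho)
    for upper, label in VOLUME_CORRELATION_CATEGORIES:
        if a < upper:
            return label
    return VOLUME_CORRELATION_CATEGORIES[-1][1]


def volume_correlation_audit(
    table: pd.DataFrame,
    volumes: np.ndarray | pd.Series,
    catalog: FeatureCatalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of every feature with tumor volume.

    Returns a per-feature frame (feature, rho, category, constant flag) and a
    per-sequence count of features in each strength category.  Category
    breakpoints: <0.26 little-if-any, 0.26-0.49 low, 0.50-0.69 moderate,
    0.70-0.89 high, >=0.90 very high, applied to |rho|.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 patients for a correlation audit")
    catalog = catalog or FeatureCatalog()
    vol = np.asarray(volumes, dtype=float)
    rows = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rho, constant = float("nan"), True
        else:
            rho = float(sps.spearmanr(x, vol).statistic)
            constant = False
        category = "little if any" if constant or not np.isfinite(rho) else _correlation_category(rho)
        rows.append({"feature": col, "rho": rho, "category": category, "constant": constant})
    per_feature = pd.DataFrame(rows)
    per_feature["sequence"] = [c.split("_", 1)[0] for c in table.columns]
    order = [label for _, label in VOLUME_CORRELATION_CATEGORIES]
    counts = (
        per_feature.groupby(["sequence", "category"]).size().unstack(fill_value=0)
        .reindex(columns=order, fill_value=0)
    )
    return per_feature, counts
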