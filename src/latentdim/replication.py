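"""Cross-cohort replicability: loading averaging, Pearson and spin tests.

Behavioural loading profiles from two cohorts are compared with Pearson's
correlation.  Surface-based brain loading maps (cortical thickness,
surface area) are spatially autocorrelated, so their similarity is
evaluated with a spin test: the spherical representation of one map is
randomly rotated (the right hemisphere receiving the mirror image of the
left hemisphere's rotation, preserving hemispheric symmetry), parcels are
reassigned by nearest centroid, and the null distribution of correlations
between rotated and fixed maps yields the p-value.  Volumetric maps (grey
matter volume, subcortex, cerebellum) are never spin-tested.

The exceedance rule is two-sided on the magnitude (|r_null| >= |r_obs|) by
default, so significant negative similarities are detected; the literal
one-sided "null higher than observed" rule is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import special_ortho_group

from .framework import DimensionResult
from .rcca import LoadingSet
from .synthetic import ParcelAtlas

__all__ = [
    "AveragedLoadings",
    "SurfaceMap",
    "MapComparison",
    "average_loadings",
    "spin_rotation",
    "spin_test",
    "naive_permutation_test",
    "compare_dimensions",
    "compare_cohorts",
]

#: mean |loading| below which a variable is considered weakly associated
UNSTABLE_LOADING_THRESHOLD = 0.2


@dataclass
class AveragedLoadings:
    """Per-variable mean and SD of loadings over splits, with a stability
    flag: a variable is 'unstable' when its mean |loading| is below 0.2 and
    its one-SD band crosses zero."""

    mean: pd.Series
    sd: pd.Series
    unstable: pd.Series


def average_loadings(loading_sets: list[LoadingSet]) -> dict[str, AveragedLoadings]:
    """Average sign-aligned per-split loadings; keyed 'brain'/'behaviour'."""
    if not loading_sets:
        raise ValueError("need at least one LoadingSet")
    out = {}
    for side in ("brain", "behaviour"):
        series = [getattr(l, side) for l in loading_sets]
        idx = series[0].index
        for s in series[1:]:
            if not s.index.equals(idx):
                raise ValueError(f"mismatched {side} variable sets across splits")
        mat = pd.concat(series, axis=1)
        mean = mat.mean(axis=1)
        sd = mat.std(axis=1, ddof=1) if mat.shape[1] > 1 else mat.std(axis=1) * 0.0
        unstable = (mean.abs() < UNSTABLE_LOADING_THRESHOLD) & (mean.abs() < sd)
        out[side] = AveragedLoadings(mean=mean, sd=sd, unstable=unstable)
    return out


@dataclass
class SurfaceMap:
    """Per-parcel values on the surface parcels of one block."""

    values: pd.Series  # indexed by parcel_id

    def aligned(self, other: "SurfaceMap") -> tuple[np.ndarray, np.ndarray]:
        if not self.values.index.equals(other.values.index):
            raise ValueError("maps are defined on different parcel sets")
        return self.values.to_numpy(float), other.values.to_numpy(float)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"parcel_id": self.values.index,
                           "value": self.values.to_numpy(float)})
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "SurfaceMap":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if not {"parcel_id", "value"} <= set(df.columns):
            raise ValueError("surface map TSV needs parcel_id and value columns")
        return cls(values=pd.Series(df["value"].to_numpy(float),
                                    index=df["parcel_id"]))


@dataclass
class MapComparison:
    label: str
    r: float
    p: float
    p_corrected: float
    n_rotations: int
    method: str  # "pearson" or "spin"


def _surface_frame(atlas: ParcelAtlas, parcel_ids: pd.Index) -> pd.DataFrame:
    t = atlas.table.set_index("parcel_id")
    missing = [p for p in parcel_ids if p not in t.index]
    if missing:
        raise ValueError(f"parcels missing from atlas: {missing[:5]}")
    t = t.loc[parcel_ids]
    if t["subcortical"].any() or t[["x", "y", "z"]].isna().any().any():
        raise ValueError("spin test requires surface parcels with centroids")
    return t


_MIRROR = np.diag([-1.0, 1.0, 1.0])


def _spin_perm_from_rotation(
    cents: np.ndarray, hemi: np.ndarray, rot: np.ndarray
) -> np.ndarray:
    perm = np.empty(len(cents), dtype=int)
    for h, R in (("L", rot), ("R", _MIRROR @ rot @ _MIRROR)):
        sel = np.flatnonzero(hemi == h)
        if sel.size == 0:
            continue
        rotated = cents[sel] @ R.T
        # nearest original centroid by cosine similarity (argmax returns
        # the lowest index on ties)
        nearest = np.argmax(rotated @ cents[sel].T, axis=1)
        perm[sel] = sel[nearest]
    return perm


def spin_rotation(
    atlas: ParcelAtlas,
    parcel_ids: pd.Index,
    rng: np.random.Generator,
) -> np.ndarray:
    """One hemisphere-symmetric spin: an index map ``perm`` such that the
    rotated map is ``values[perm]``.

    A uniform random 3-D rotation is applied to left-hemisphere centroids
    and its mirror image to the right hemisphere; each rotated centroid is
    assigned the parcel whose original centroid is nearest on the sphere
    (ties broken toward the lowest parcel index; duplicates allowed).
    """
    t = _surface_frame(atlas, parcel_ids)
    rot = special_ortho_group.rvs(3, random_state=rng)
    return _spin_perm_from_rotation(
        t[["x", "y", "z"]].to_numpy(float), t["hemisphere"].to_numpy(), rot
    )


def _exceedance_p(
    r_obs: float, r_null: np.ndarray, n: int, sided: str
) -> float:
    if sided == "two_sided_magnitude":
        count = int(np.sum(np.abs(r_null) >= np.abs(r_obs)))
    elif sided == "greater":
        count = int(np.sum(r_null > r_obs))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return min(1.0, max(count, 1) / n)


def spin_test(
    map_a: SurfaceMap,
    map_b: SurfaceMap,
    atlas: ParcelAtlas,
    n_rotations: int = 1000,
    seed: int = 0,
    sided: str = "two_sided_magnitude",
    bonferroni: int = 1,
    label: str = "",
) -> MapComparison:
    """Spatial-null comparison of two surface maps.

    ``map_a`` is rotated; ``map_b`` (e.g. a reference gradient map) stays
    fixed.  The p-value is the exceedance fraction of the null
    correlations, floored at 1/n_rotations.
    """
    a, b = map_a.aligned(map_b)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant map: correlation undefined")
    r_obs = float(stats.pearsonr(a, b)[0])
    t = _surface_frame(atlas, map_a.values.index)
    cents = t[["x", "y", "z"]].to_numpy(float)
    hemi = t["hemisphere"].to_numpy()
    rng = np.random.default_rng(seed)
    rots = special_ortho_group.rvs(3, size=n_rotations, random_state=rng)
    bc = b - b.mean()
    bn = np.linalg.norm(bc)
    r_null = np.empty(n_rotations)
    for i in range(n_rotations):
        ai = a[_spin_perm_from_rotation(cents, hemi, rots[i])]
        ac = ai - ai.mean()
        an = np.linalg.norm(ac)
        r_null[i] = (ac @ bc) / (an * bn) if an > 0 else 0.0
    p = _exceedance_p(r_obs, r_null, n_rotations, sided)
    return MapComparison(
        label=label, r=r_obs, p=p, p_corrected=min(1.0, bonferroni * p),
        n_rotations=n_rotations, method="spin",
    )


def naive_permutation_test(
    map_a: SurfaceMap,
    map_b: SurfaceMap,
    n_permutations: int = 1000,
    seed: int = 0,
    sided: str = "two_sided_magnitude",
) -> MapComparison:
    """Spatially unaware control: free shuffling of parcels.  On smooth
    maps this is anti-conservative; provided for calibration contrasts."""
    a, b = map_a.aligned(map_b)
    r_obs = float(stats.pearsonr(a, b)[0])
    rng = np.random.default_rng(seed)
    r_null = np.array([
        stats.pearsonr(rng.permutation(a), b)[0] for _ in range(n_permutations)
    ])
    p = _exceedance_p(r_obs, r_null, n_permutations, sided)
    return MapComparison(
        label="naive", r=r_obs, p=p, p_corrected=p,
        n_rotations=n_permutations, method="naive",
    )


def _loading_surface_map(
    result: DimensionResult, atlas: ParcelAtlas, block: str
) -> SurfaceMap:
    surf = atlas.surface(block)["parcel_id"]
    vals = result.loadings_mean.brain.reindex(surf)
    return SurfaceMap(values=vals)


def compare_dimensions(
    result_a: DimensionResult,
    result_b: DimensionResult,
    atlas: ParcelAtlas,
    n_rotations: int = 1000,
    seed: int = 0,
    bonferroni: int = 1,
    sided: str = "two_sided_magnitude",
) -> list[MapComparison]:
    """Compare one dimension pair: behaviour by Pearson (analytic p), CT
    and SA surface maps by spin test.  GMV is excluded (volumetric)."""
    la = result_a.loadings_mean.behaviour
    lb = result_b.loadings_mean.behaviour
    if not la.index.equals(lb.index):
        diff = set(la.index) ^ set(lb.index)
        raise ValueError(f"behavioural variable mismatch: {sorted(diff)[:6]}")
    r, p = stats.pearsonr(la.to_numpy(float), lb.to_numpy(float))
    comps = [MapComparison(
        label=f"behaviour:a{result_a.dimension}-b{result_b.dimension}",
        r=float(r), p=float(p), p_corrected=min(1.0, bonferroni * float(p)),
        n_rotations=0, method="pearson",
    )]
    blocks = [b for b in ("CT", "SA") if (atlas.table["block"] == b).any()]
    for block in blocks:
        comps.append(spin_test(
            _loading_surface_map(result_a, atlas, block),
            _loading_surface_map(result_b, atlas, block),
            atlas, n_rotations=n_rotations, seed=seed, sided=sided,
            bonferroni=bonferroni,
            label=f"{block}:a{result_a.dimension}-b{result_b.dimension}",
        ))
    return comps


def compare_cohorts(
    results_a: list[DimensionResult],
    results_b: list[DimensionResult],
    atlas: ParcelAtlas,
    n_rotations: int = 1000,
    seed: int = 0,
    sided: str = "two_sided_magnitude",
) -> list[MapComparison]:
    """All dimension pairs across two cohorts; the Bonferroni factor is the
    full family size n_dims_a * n_dims_b * 3 loading families (behaviour,
    CT, SA)."""
    factor = len(results_a) * len(results_b) * 3
    comps = []
    for i, ra in enumerate(results_a):
        for j, rb in enumerate(results_b):
            comps.extend(compare_dimensions(
                ra, rb, atlas, n_rotations=n_rotations,
                seed=seed + 1000 * i + j, bonferroni=factor, sided=sided,
            ))
    return comps
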