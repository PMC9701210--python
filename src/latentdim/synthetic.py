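"""Synthetic cohorts with planted latent brain-behaviour structure.

Generates two row-aligned data views — a multi-block brain-structure view
(grey matter volume, cortical thickness, surface area parcels) and a
behavioural view — that share a configurable number of planted latent
dimensions, together with the nuisance structure the analysis pipeline is
designed to handle:

* linear age and gender effects on every feature,
* per-participant global-size scaling of brain features (TIV, mean cortical
  thickness and total surface area analogues),
* family blocks containing MZ/DZ twin pairs, non-twin siblings and
  singletons, with a configurable additive-genetic share of the latent
  variates (MZ co-twins share the genetic component fully, DZ co-twins and
  full siblings share half),
* spatially smooth brain loading patterns sampled from an exponential
  kernel on each hemisphere's unit sphere, so spatial null models face
  realistic autocorrelation.

All ground truth (patterns, latent variates, the generating spec) is kept
on the returned :class:`Cohort`, which makes every downstream stage
testable without any external data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import special_ortho_group

__all__ = [
    "FamilyBlock",
    "ConfoundEffects",
    "PlantedDimension",
    "CohortSpec",
    "ParcelAtlas",
    "Cohort",
    "GroundTruth",
    "substream",
    "generate_cohort",
    "generate_sphere_parcellation",
    "generate_twin_sample",
    "default_family_blocks",
]

BRAIN_BLOCKS = ("GMV", "CT", "SA")
SIZE_COLUMN = {"GMV": "tiv", "CT": "mean_ct", "SA": "total_sa"}

#: fraction of twin pairs that are monozygotic (292:323, a realistic
#: young-adult twin-cohort ratio)
MZ_FRACTION = 292 / (292 + 323)


def substream(seed: int, *key) -> np.random.Generator:
    """Derive an independent random stream from one master seed.

    String key parts are hashed with crc32 so every stage of the pipeline
    draws from its own deterministic substream of the master seed.
    """
    parts = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=parts))


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------


@dataclass
class FamilyBlock:
    """One family: ``n_members`` individuals, at most one twin pair."""

    n_members: int
    twin_type: str | None = None  # None, "MZ" or "DZ"

    def __post_init__(self):
        if self.n_members < 1:
            raise ValueError("family must have at least one member")
        if self.twin_type not in (None, "MZ", "DZ"):
            raise ValueError(f"unknown twin type {self.twin_type!r}")
        if self.twin_type is not None and self.n_members < 2:
            raise ValueError("a family with a twin pair needs >= 2 members")


@dataclass
class ConfoundEffects:
    """Scales of the per-feature linear age and gender coefficients.

    Coefficients are drawn as N(0, scale^2) per feature.  Units: feature
    units per year (age) and per gender code step (gender).
    """

    age_scale: float = 0.05
    gender_scale: float = 0.3

    @classmethod
    def zero(cls) -> "ConfoundEffects":
        return cls(age_scale=0.0, gender_scale=0.0)


@dataclass
class PlantedDimension:
    """Ground truth for one latent dimension.

    ``rho`` is the correlation between the brain-side and behaviour-side
    latent variates.  Loading patterns are unit-norm; if omitted they are
    sampled at generation time (spatially smooth on the sphere for surface
    parcels, i.i.d. Gaussian for behaviour and subcortical parcels).
    """

    rho: float
    brain_loading_pattern: np.ndarray | None = None
    behaviour_loading_pattern: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("planted canonical correlation must be in [0, 1]")


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_participants: int
    family_blocks: list[FamilyBlock]
    n_behaviour: int
    brain_blocks: list[tuple[str, int]]
    planted_dimensions: list[PlantedDimension] = field(default_factory=list)
    confound_effects: ConfoundEffects = field(default_factory=ConfoundEffects)
    global_size_noise: float = 0.1
    h2_target: float = 0.5
    seed: int = 0
    age_range: tuple[float, float] = (22.0, 37.0)
    n_sites: int = 1
    signal_strength: float = 5.0
    noise_sd: float = 1.0
    smoothness: float = 0.5
    subcortical_counts: dict[str, int] | None = None

    def __post_init__(self):
        if self.n_participants < 1 or self.n_behaviour < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must be in [0, 1]")
        total = sum(f.n_members for f in self.family_blocks)
        if total != self.n_participants:
            raise ValueError(
                f"family blocks cover {total} members, expected {self.n_participants}"
            )
        for name, n in self.brain_blocks:
            if name not in BRAIN_BLOCKS:
                raise ValueError(f"unknown brain block {name!r}")
            if n < 1:
                raise ValueError("parcel counts must be positive")
            if self._n_surface(name, n) % 2:
                raise ValueError(
                    f"block {name}: surface parcel count must be even "
                    "(mirror-symmetric hemispheres)"
                )
        for d in self.planted_dimensions:
            if d.rho >= 1.0 and self.noise_sd > 0:
                raise ValueError(
                    "infeasible spec: rho = 1 cannot be realised with a "
                    "nonzero noise floor"
                )

    def _n_surface(self, name: str, n: int) -> int:
        sub = (self.subcortical_counts or {}).get(name)
        if sub is None:
            # GMV defaults to the study layout: up to 200 cortical parcels,
            # the remainder subcortical/cerebellar; CT and SA are all-surface
            sub = max(0, n - 200) if name == "GMV" else 0
        return n - sub


def default_family_blocks(
    n_participants: int, kind: str = "twins", seed: int = 0
) -> list[FamilyBlock]:
    """Family structures mirroring the two cohort styles.

    ``"twins"``: families of 3-6 members, each with one MZ or DZ twin pair
    (young-adult cohort style).  ``"singletons"``: all unrelated (aging
    cohort style).
    """
    if kind == "singletons":
        return [FamilyBlock(1) for _ in range(n_participants)]
    if kind != "twins":
        raise ValueError(f"unknown family structure kind {kind!r}")
    rng = substream(seed, "families")
    blocks: list[FamilyBlock] = []
    left = n_participants
    while left > 0:
        size = int(rng.integers(3, 7))
        if left - size < 3:
            size = left
        if size >= 2:
            tt = "MZ" if rng.random() < MZ_FRACTION else "DZ"
            blocks.append(FamilyBlock(size, tt))
        else:
            blocks.append(FamilyBlock(1))
        left -= size
    return blocks


# ---------------------------------------------------------------------------
# parcel atlas on the sphere
# ---------------------------------------------------------------------------


@dataclass
class ParcelAtlas:
    """Parcel table: id, feature block, hemisphere, spherical centroid.

    Surface parcels carry unit-norm centroids on their hemisphere's sphere;
    the right hemisphere mirrors the left through the x = 0 plane.
    Subcortical/cerebellar parcels have no centroid.
    """

    table: pd.DataFrame  # parcel_id, block, hemisphere, x, y, z, subcortical

    def surface(self, block: str | None = None) -> pd.DataFrame:
        t = self.table[~self.table["subcortical"]]
        if block is not None:
            t = t[t["block"] == block]
        return t

    def centroids(self, block: str, hemisphere: str) -> np.ndarray:
        t = self.surface(block)
        return t.loc[t["hemisphere"] == hemisphere, ["x", "y", "z"]].to_numpy()


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform lattice of n points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def generate_sphere_parcellation(
    n_parcels_per_hemisphere: int, seed: int = 0, block: str = "CT"
) -> ParcelAtlas:
    """Mirror-symmetric parcel centroids, near-uniform on each hemisphere.

    Each hemisphere is its own unit sphere (as in surface registration);
    right-hemisphere centroids are the mirror image (x -> -x) of the left.
    A Fibonacci lattice keeps the implied parcel cells near-equal in area;
    a seeded random rotation decouples the lattice from the coordinate axes.
    """
    n = n_parcels_per_hemisphere
    if n < 4:
        raise ValueError("need at least 4 parcels per hemisphere")
    rng = substream(seed, "sphere", block)
    rot = special_ortho_group.rvs(3, random_state=rng)
    left = _fibonacci_sphere(n) @ rot.T
    right = left * np.array([-1.0, 1.0, 1.0])
    rows = []
    for hemi, pts in (("L", left), ("R", right)):
        for k, (x, y, z) in enumerate(pts):
            rows.append(
                {
                    "parcel_id": f"{block}_{hemi}_{k:03d}",
                    "block": block,
                    "hemisphere": hemi,
                    "x": x,
                    "y": y,
                    "z": z,
                    "subcortical": False,
                }
            )
    return ParcelAtlas(pd.DataFrame(rows))


def _smooth_sphere_sample(
    centroids: np.ndarray, length_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a spatially smooth field at centroids: exponential kernel in
    great-circle distance, exp(-d / length_scale)."""
    g = np.clip(centroids @ centroids.T, -1.0, 1.0)
    cov = np.exp(-np.arccos(g) / length_scale)
    cov[np.diag_indices_from(cov)] += 1e-8
    return np.linalg.cholesky(cov) @ rng.standard_normal(len(centroids))


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    spec: CohortSpec
    brain_patterns: np.ndarray  # (p, k) unit-norm columns
    behaviour_patterns: np.ndarray  # (q, k)
    latents_brain: np.ndarray  # (n, k)
    latents_behaviour: np.ndarray  # (n, k)


@dataclass
class Cohort:
    """Two aligned data views plus metadata, family structure and truth."""

    ids: np.ndarray
    metadata: pd.DataFrame  # id, age, gender, site, family_id, pair_id, zygosity
    X: np.ndarray
    x_names: list[str]
    x_blocks: np.ndarray  # block name per brain column
    Y: np.ndarray
    y_names: list[str]
    size_totals: pd.DataFrame  # id, tiv, mean_ct, total_sa
    atlas: ParcelAtlas
    truth: GroundTruth | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        if not (len(self.ids) == self.X.shape[0] == self.Y.shape[0]
                == len(self.metadata) == len(self.size_totals)):
            raise ValueError("views and metadata are not row-aligned")
        if np.isnan(self.X).any() or np.isnan(self.Y).any():
            raise ValueError("cohort contains missing values")


# ---------------------------------------------------------------------------
# family-structured additive-genetic draws
# ---------------------------------------------------------------------------


def _genetic_draw(meta: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal vector with Cov = 2*Phi: MZ co-twins correlate 1,
    other members of a family 0.5, across families 0.

    a_i = sqrt(1/2) * c_family + sqrt(1/2) * m_i, where MZ co-twins share
    their m component.
    """
    n = len(meta)
    a = np.empty(n)
    for _, idx in meta.groupby("family_id", sort=False).indices.items():
        c = rng.standard_normal()
        sub = meta.iloc[idx]
        m = rng.standard_normal(len(idx))
        mz = (sub["zygosity"] == "MZ").to_numpy()
        if mz.any():
            shared = rng.standard_normal()
            m[mz] = shared
        a[idx] = np.sqrt(0.5) * c + np.sqrt(0.5) * m
    return a


def _correlated_pair(
    base: np.ndarray, other: np.ndarray, rho: float
) -> np.ndarray:
    """Mix two equal-variance draws to correlate `rho` with `base`."""
    return rho * base + np.sqrt(max(0.0, 1.0 - rho**2)) * other


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _build_metadata(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    pid = 0
    for fi, fam in enumerate(spec.family_blocks):
        fam_id = f"fam{fi:04d}"
        for mi in range(fam.n_members):
            is_twin = fam.twin_type is not None and mi < 2
            rows.append(
                {
                    "id": f"sub{pid:05d}",
                    "family_id": fam_id,
                    "pair_id": f"{fam_id}_tw" if is_twin else "",
                    "zygosity": fam.twin_type if is_twin else "NT",
                }
            )
            pid += 1
    meta = pd.DataFrame(rows)
    lo, hi = spec.age_range
    meta["age"] = rng.uniform(lo, hi, len(meta))
    meta["gender"] = rng.integers(0, 2, len(meta))
    meta["site"] = [f"site{int(s)}" for s in rng.integers(0, spec.n_sites, len(meta))]
    return meta[["id", "age", "gender", "site", "family_id", "pair_id", "zygosity"]]


def _build_atlas(spec: CohortSpec) -> tuple[ParcelAtlas, list[str], np.ndarray]:
    frames, names, blocks = [], [], []
    for name, n in spec.brain_blocks:
        n_surf = spec._n_surface(name, n)
        if n_surf:
            at = generate_sphere_parcellation(n_surf // 2, seed=spec.seed, block=name)
            frames.append(at.table)
            names.extend(at.table["parcel_id"])
            blocks.extend([name] * n_surf)
        for k in range(n - n_surf):
            frames.append(
                pd.DataFrame(
                    [{
                        "parcel_id": f"{name}_SC_{k:03d}", "block": name,
                        "hemisphere": "none", "x": np.nan, "y": np.nan,
                        "z": np.nan, "subcortical": True,
                    }]
                )
            )
            names.append(f"{name}_SC_{k:03d}")
            blocks.append(name)
    atlas = ParcelAtlas(pd.concat(frames, ignore_index=True))
    return atlas, names, np.asarray(blocks)


def _brain_patterns(
    spec: CohortSpec, atlas: ParcelAtlas, names: list[str], k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample k unit-norm, mutually orthogonal brain loading patterns;
    smooth on the sphere for surface parcels, i.i.d. for subcortical."""
    p = len(names)
    pats = np.empty((p, k))
    table = atlas.table.set_index("parcel_id")
    for d in range(k):
        vec = np.empty(p)
        name_arr = np.asarray(names)
        for block in dict.fromkeys(table["block"]):
            for hemi in ("L", "R"):
                sel = (table["block"] == block) & (table["hemisphere"] == hemi)
                pids = table.index[sel]
                if len(pids) == 0:
                    continue
                cents = table.loc[pids, ["x", "y", "z"]].to_numpy()
                vals = _smooth_sphere_sample(cents, spec.smoothness, rng)
                vec[np.isin(name_arr, pids)] = vals
            sub_sel = (table["block"] == block) & table["subcortical"]
            pids = table.index[sub_sel]
            if len(pids):
                vec[np.isin(name_arr, pids)] = rng.standard_normal(len(pids))
        pats[:, d] = vec
    q, _ = np.linalg.qr(pats)
    # QR orthonormalises while keeping the first column's direction
    return q * np.sign(np.sum(q * pats, axis=0))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort with the requested planted structure.

    The latent variate pair of each planted dimension is drawn with the
    requested cross-view correlation; family members share an
    additive-genetic component scaled so the latent-score heritability is
    ``h2_target`` (MZ fully shared, DZ/siblings half).  Observed features
    are ``signal_strength * latent x loading pattern`` plus linear
    age/gender effects plus i.i.d. Gaussian noise; brain features are then
    multiplied by the participant's global size factor.
    """
    meta = _build_metadata(spec, substream(spec.seed, "metadata"))
    atlas, x_names, x_blocks = _build_atlas(spec)
    n, p, q = spec.n_participants, len(x_names), spec.n_behaviour
    k = len(spec.planted_dimensions)

    lat_rng = substream(spec.seed, "latents")
    h2 = spec.h2_target
    zb = np.zeros((n, k))
    zy = np.zeros((n, k))
    for d, dim in enumerate(spec.planted_dimensions):
        a_b = _genetic_draw(meta, lat_rng)
        a_y = _correlated_pair(a_b, _genetic_draw(meta, lat_rng), dim.rho)
        e_b = lat_rng.standard_normal(n)
        e_y = _correlated_pair(e_b, lat_rng.standard_normal(n), dim.rho)
        zb[:, d] = np.sqrt(h2) * a_b + np.sqrt(1 - h2) * e_b
        zy[:, d] = np.sqrt(h2) * a_y + np.sqrt(1 - h2) * e_y

    pat_rng = substream(spec.seed, "patterns")
    if k:
        P_b = _brain_patterns(spec, atlas, x_names, k, pat_rng)
        P_y = np.linalg.qr(pat_rng.standard_normal((q, k)))[0] if q > 1 else np.ones((1, k))
        for d, dim in enumerate(spec.planted_dimensions):
            if dim.brain_loading_pattern is not None:
                v = np.asarray(dim.brain_loading_pattern, dtype=float)
                P_b[:, d] = v / np.linalg.norm(v)
            if dim.behaviour_loading_pattern is not None:
                v = np.asarray(dim.behaviour_loading_pattern, dtype=float)
                P_y[:, d] = v / np.linalg.norm(v)
    else:
        P_b = np.zeros((p, 0))
        P_y = np.zeros((q, 0))

    noise_rng = substream(spec.seed, "noise")
    s = np.full(k, spec.signal_strength)
    X = (zb * s) @ P_b.T + spec.noise_sd * noise_rng.standard_normal((n, p))
    Y = (zy * s) @ P_y.T + spec.noise_sd * noise_rng.standard_normal((n, q))

    conf_rng = substream(spec.seed, "confounds")
    ce = spec.confound_effects
    age = meta["age"].to_numpy()
    gender = meta["gender"].to_numpy().astype(float)
    X += np.outer(age, conf_rng.normal(0, ce.age_scale, p) if ce.age_scale else np.zeros(p))
    Y += np.outer(age, conf_rng.normal(0, ce.age_scale, q) if ce.age_scale else np.zeros(q))
    X += np.outer(gender, conf_rng.normal(0, ce.gender_scale, p) if ce.gender_scale else np.zeros(p))
    Y += np.outer(gender, conf_rng.normal(0, ce.gender_scale, q) if ce.gender_scale else np.zeros(q))

    size_rng = substream(spec.seed, "size")
    cv = spec.global_size_noise
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        totals = {
            col: np.exp(size_rng.normal(-sigma**2 / 2, sigma, n))
            for col in ("tiv", "mean_ct", "total_sa")
        }
    else:
        totals = {col: np.ones(n) for col in ("tiv", "mean_ct", "total_sa")}
    size_totals = pd.DataFrame({"id": meta["id"], **totals})
    for block in dict.fromkeys(x_blocks):
        cols = x_blocks == block
        X[:, cols] *= totals[SIZE_COLUMN[block]][:, None]

    y_names = [f"behav_{j:02d}" for j in range(q)]
    cohort = Cohort(
        ids=meta["id"].to_numpy(),
        metadata=meta,
        X=X, x_names=list(x_names), x_blocks=x_blocks,
        Y=Y, y_names=y_names,
        size_totals=size_totals,
        atlas=atlas,
        truth=GroundTruth(
            spec=spec, brain_patterns=P_b, behaviour_patterns=P_y,
            latents_brain=zb, latents_behaviour=zy,
        ),
    )
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# twin samples for the variance-decomposition module
# ---------------------------------------------------------------------------


def generate_twin_sample(
    n_mz_pairs: int,
    n_dz_pairs: int,
    n_singletons: int,
    h2_true: float | tuple[float, float],
    seed: int = 0,
    rho_g: float = 0.0,
    rho_e: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Twin-design phenotypes: MVN with covariance 2*Phi*sigma2_A + I*sigma2_E.

    With a scalar ``h2_true`` one phenotype is returned (shape (n,)); with a
    pair ``(h2_x, h2_y)`` two phenotypes (shape (n, 2)) whose additive
    genetic components correlate ``rho_g`` and environmental components
    ``rho_e``.  Total variance is 1 per trait, so sigma2_A = h2.
    """
    h2s = (h2_true,) if np.isscalar(h2_true) else tuple(h2_true)
    for h in h2s:
        if not 0.0 <= h <= 1.0:
            raise ValueError("h2_true must be in [0, 1]")
    rows = []
    fam = 0
    for zyg, count in (("MZ", n_mz_pairs), ("DZ", n_dz_pairs)):
        for _ in range(count):
            fid = f"fam{fam:05d}"
            rows.append({"id": f"sub{2*fam:05d}", "family_id": fid,
                         "pair_id": f"{fid}_tw", "zygosity": zyg})
            rows.append({"id": f"sub{2*fam+1:05d}", "family_id": fid,
                         "pair_id": f"{fid}_tw", "zygosity": zyg})
            fam += 1
    base = 2 * fam
    for s in range(n_singletons):
        rows.append({"id": f"sub{base+s:05d}", "family_id": f"fam{fam+s:05d}",
                     "pair_id": "", "zygosity": "NT"})
    ped = pd.DataFrame(rows)

    rng = substream(seed, "twin_sample")
    a1 = _genetic_draw(ped, rng)
    e1 = rng.standard_normal(len(ped))
    if len(h2s) == 1:
        pheno = np.sqrt(h2s[0]) * a1 + np.sqrt(1 - h2s[0]) * e1
        return pheno, ped
    a2 = _correlated_pair(a1, _genetic_draw(ped, rng), rho_g)
    e2 = _correlated_pair(e1, rng.standard_normal(len(ped)), rho_e)
    x = np.sqrt(h2s[0]) * a1 + np.sqrt(1 - h2s[0]) * e1
    y = np.sqrt(h2s[1]) * a2 + np.sqrt(1 - h2s[1]) * e2
    return np.column_stack([x, y]), ped
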