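"""Multiple-holdout machine-learning framework around the RCCA core.

The data are divided by *outer* splits into an optimisation set (80%) and a
holdout set (20%), and each optimisation set by *inner* splits into
training (80%) and testing (20%) sets, always at the family level so that
no family ever straddles a split.  Hyperparameters (the regularisation
pair ``c_x, c_y``) are selected on the inner splits by a joint
correlation-and-stability criterion, the selected model is refitted on the
full optimisation set, and the holdout set is projected onto its weights
to measure out-of-sample generalisation.  Statistical evaluation of each
latent dimension uses family-restricted permutations (see
:mod:`latentdim.permutation`); once a dimension is accepted its variance
is removed by projection deflation within each outer split, using the
optimisation-set model, before the next dimension is sought.

Preprocessing (participant-wise brain-size normalisation, then OLS
residualisation of age/gender/site effects) is estimated on the
optimisation set of each outer split and applied unchanged to the holdout
set, so no holdout row ever influences the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rcca import (
    DegenerateDataError,
    LoadingSet,
    RccaModel,
    compute_loadings,
    fit_rcca,
    make_deflator,
    project,
)
from .synthetic import SIZE_COLUMN, Cohort, substream

__all__ = [
    "SplitScheme",
    "PreprocessState",
    "HyperparameterGridResult",
    "DimensionResult",
    "RunConfig",
    "make_split_scheme",
    "fit_preprocess",
    "apply_preprocess",
    "normalise_brain",
    "grid_search",
    "run_framework",
]

DEFAULT_GRID_VALUES = (0.0, 0.3, 0.6, 0.9, 0.99, 1.0)


@dataclass
class RunConfig:
    """Run configuration; defaults mirror the study's stated settings."""

    n_outer: int = 5
    n_inner: int = 5
    holdout_fraction: float = 0.2
    test_fraction: float = 0.2
    grid_x: tuple[float, ...] = DEFAULT_GRID_VALUES
    grid_y: tuple[float, ...] = DEFAULT_GRID_VALUES
    n_permutations: int = 1000
    alpha: float = 0.05
    max_dimensions: int = 3
    seed: int = 0
    confounds: tuple[str, ...] = ("age", "gender")
    normalise_brain_size: bool = True
    #: per-behaviour-variable sign multipliers (e.g. flip reaction times)
    sign_map: dict[str, float] = field(default_factory=dict)
    #: "floor": p = max(count, 1)/n_perm; "add_one": p = (count+1)/(n_perm+1)
    p_estimator: str = "floor"
    #: strict ("greater") vs non-strict ("geq") exceedance counting
    tie_rule: str = "greater"

    @property
    def grid(self) -> list[tuple[float, float]]:
        return [(cx, cy) for cx in self.grid_x for cy in self.grid_y]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["grid_x"] = list(self.grid_x)
        d["grid_y"] = list(self.grid_y)
        d["confounds"] = list(self.confounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("grid_x", "grid_y", "confounds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# family-aware nested splits
# ---------------------------------------------------------------------------


@dataclass
class SplitScheme:
    """Nested outer (optimisation/holdout) and inner (train/test) splits.

    All index arrays are positional row indices into the cohort; within
    each split the two sets partition the participants and no family
    appears on both sides.
    """

    outer: list[tuple[np.ndarray, np.ndarray]]  # (optimisation, holdout)
    inner: list[list[tuple[np.ndarray, np.ndarray]]]  # per outer: (train, test)
    seed: int


def _family_split(
    families: list[np.ndarray], frac_right: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Assign whole families to the right-hand set, hitting the target
    participant fraction as closely as family sizes allow."""
    n = sum(len(f) for f in families)
    target = int(round(frac_right * n))
    biggest = max(len(f) for f in families)
    if biggest > target:
        raise ValueError(
            f"a family of {biggest} members exceeds the target set size "
            f"{target}; increase the fraction or the sample size"
        )
    order = rng.permutation(len(families))
    chosen = np.zeros(len(families), dtype=bool)
    count = 0
    for fi in order:
        size = len(families[fi])
        if count >= target:
            break
        if count + size - target > target - count:
            continue  # including overshoots more than excluding undershoots
        chosen[fi] = True
        count += size
    right = (
        np.sort(np.concatenate([f for f, c in zip(families, chosen) if c]))
        if chosen.any() else np.array([], dtype=int)
    )
    left = np.sort(np.concatenate([f for f, c in zip(families, chosen) if not c]))
    return left, right


def make_split_scheme(
    metadata: pd.DataFrame,
    n_outer: int = 5,
    n_inner: int = 5,
    holdout_fraction: float = 0.2,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitScheme:
    """Random family-level nested splits, deterministic given the seed."""
    if "family_id" not in metadata.columns:
        raise ValueError("metadata must carry a family_id column")
    fam_groups = [
        np.asarray(idx) for idx in
        metadata.groupby("family_id", sort=False).indices.values()
    ]
    outer, inner = [], []
    for o in range(n_outer):
        rng = substream(seed, "outer_split", o)
        opt, hold = _family_split(fam_groups, holdout_fraction, rng)
        outer.append((opt, hold))
        opt_set = set(opt.tolist())
        # family-level assignment keeps families whole: a family is either
        # entirely inside the optimisation set or entirely outside it
        opt_fams = [f for f in fam_groups if int(f[0]) in opt_set]
        splits_o = []
        for i in range(n_inner):
            rng_i = substream(seed, "inner_split", o, i)
            splits_o.append(_family_split(opt_fams, test_fraction, rng_i))
        inner.append(splits_o)
    return SplitScheme(outer=outer, inner=inner, seed=seed)


# ---------------------------------------------------------------------------
# preprocessing: brain-size normalisation, confound residualisation
# ---------------------------------------------------------------------------


def normalise_brain(
    X: np.ndarray, size_totals: pd.DataFrame, x_blocks: np.ndarray
) -> np.ndarray:
    """Divide each participant's features by the block-appropriate global
    size total (GMV by the TIV analogue, CT by mean CT, SA by total SA)."""
    X = np.array(X, dtype=float)
    for block in dict.fromkeys(x_blocks):
        col = SIZE_COLUMN[block]
        totals = size_totals[col].to_numpy(dtype=float)
        if (totals <= 0).any():
            bad = np.flatnonzero(totals <= 0)[:5].tolist()
            raise ValueError(f"nonpositive {col} totals at rows {bad}")
        X[:, x_blocks == block] /= totals[:, None]
    return X


@dataclass
class PreprocessState:
    """OLS confound-regression coefficients estimated on a training set."""

    confounds: tuple[str, ...]
    coef: np.ndarray  # (1 + n_confounds + extra dummies, n_features)
    columns: list[str]  # design column names (after dummy expansion)
    fitted_on: np.ndarray  # positional indices


def _confound_design(
    metadata: pd.DataFrame, confounds: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(len(metadata))], ["intercept"]
    for c in confounds:
        if c == "site":
            dummies = pd.get_dummies(metadata["site"], prefix="site", drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(name)
        else:
            if c not in metadata.columns:
                raise ValueError(f"confound {c!r} missing from metadata")
            cols.append(metadata[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def fit_preprocess(
    features: np.ndarray,
    metadata: pd.DataFrame,
    confounds: tuple[str, ...] = ("age", "gender"),
    fitted_on: np.ndarray | None = None,
) -> PreprocessState:
    """Estimate per-feature confound regressions on a training slice."""
    W, names = _confound_design(metadata, confounds)
    rank = np.linalg.matrix_rank(W)
    if rank < W.shape[1]:
        # name the collinear columns via the QR diagonal
        r = np.abs(np.diag(np.linalg.qr(W, mode="r")))
        bad = [names[j] for j in np.flatnonzero(r < 1e-10 * r.max())]
        raise ValueError(f"confound design is rank-deficient; collinear: {bad}")
    coef, *_ = np.linalg.lstsq(W, np.asarray(features, dtype=float), rcond=None)
    if fitted_on is None:
        fitted_on = np.arange(len(metadata))
    return PreprocessState(
        confounds=confounds, coef=coef, columns=names, fitted_on=fitted_on
    )


def apply_preprocess(
    state: PreprocessState, features: np.ndarray, metadata: pd.DataFrame
) -> np.ndarray:
    """Residualise any slice with coefficients from the training slice."""
    W, names = _confound_design(metadata, state.confounds)
    if names != state.columns:
        raise ValueError(
            f"confound design mismatch: fitted on {state.columns}, got {names}"
        )
    return np.asarray(features, dtype=float) - W @ state.coef


# ---------------------------------------------------------------------------
# hyperparameter grid search: correlation + stability
# ---------------------------------------------------------------------------


@dataclass
class HyperparameterGridResult:
    grid: list[tuple[float, float]]
    mean_test_corr: np.ndarray
    mean_stability: np.ndarray
    selected: tuple[float, float]


def _weight_similarity(models: list[RccaModel]) -> float:
    """Mean pairwise Pearson similarity of weights across inner-split
    models, sign-aligned to the first model by the concatenated-weight dot
    product; u and v similarities are averaged."""
    ok = [m for m in models if m is not None]
    if len(ok) < 2:
        return np.nan
    ref = np.concatenate([ok[0].u, ok[0].v])
    us, vs = [], []
    for m in ok:
        w = np.concatenate([m.u, m.v])
        s = 1.0 if w @ ref >= 0 else -1.0
        us.append(s * m.u)
        vs.append(s * m.v)
    sims = []
    for vecs in (us, vs):
        M = np.array(vecs)
        M = M - M.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(M, axis=1)
        if (norms <= 0).any():
            return np.nan
        C = (M @ M.T) / np.outer(norms, norms)
        iu = np.triu_indices(len(vecs), k=1)
        sims.append(C[iu].mean())
    return float(np.mean(sims))


def select_cell(
    grid: list[tuple[float, float]],
    mean_corr: np.ndarray,
    mean_stability: np.ndarray,
) -> tuple[float, float]:
    """Joint selection: best average of the correlation rank and the
    stability rank; ties broken toward larger c_x + c_y (more regularised),
    then larger c_x."""
    from scipy.stats import rankdata

    mean_corr = np.asarray(mean_corr, dtype=float)
    mean_stability = np.asarray(mean_stability, dtype=float)
    if not np.isfinite(mean_stability).any():
        mean_stability = np.zeros_like(mean_corr)  # single inner split
    valid = np.isfinite(mean_corr) & np.isfinite(mean_stability)
    if not valid.any():
        raise DegenerateDataError("all grid cells degenerate")
    corr_rank = rankdata(np.where(valid, -mean_corr, np.inf))
    stab_rank = rankdata(np.where(valid, -mean_stability, np.inf))
    avg = np.where(valid, (corr_rank + stab_rank) / 2.0, np.inf)
    best = avg.min()
    tied = [grid[i] for i in np.flatnonzero(avg == best)]
    return max(tied, key=lambda c: (c[0] + c[1], c[0]))


def grid_search(
    X_opt: np.ndarray,
    Y_opt: np.ndarray,
    inner_splits: list[tuple[np.ndarray, np.ndarray]],
    grid: list[tuple[float, float]],
) -> HyperparameterGridResult:
    """Evaluate every (c_x, c_y) cell over the inner splits.

    Index arrays in ``inner_splits`` are positional into ``X_opt``/``Y_opt``.
    """
    if len(inner_splits) < 1:
        raise ValueError("need at least one inner split")
    # with a single inner split stability is undefined (NaN) and selection
    # falls back to the test-correlation ranking alone
    n_cells = len(grid)
    corr = np.full((n_cells, len(inner_splits)), np.nan)
    models: list[list[RccaModel | None]] = [[] for _ in range(n_cells)]
    for k, (tr, te) in enumerate(inner_splits):
        for ci, (cx, cy) in enumerate(grid):
            try:
                m = fit_rcca(X_opt[tr], Y_opt[tr], cx, cy)
                corr[ci, k] = project(m, X_opt[te], Y_opt[te]).corr()
                models[ci].append(m)
            except DegenerateDataError:
                models[ci].append(None)
    mean_corr = np.nanmean(corr, axis=1)
    mean_stab = np.array([_weight_similarity(ms) for ms in models])
    selected = select_cell(grid, mean_corr, mean_stab)
    return HyperparameterGridResult(
        grid=grid, mean_test_corr=mean_corr, mean_stability=mean_stab,
        selected=selected,
    )


# ---------------------------------------------------------------------------
# full framework
# ---------------------------------------------------------------------------


@dataclass
class DimensionResult:
    """Everything the pipeline reports for one latent dimension."""

    dimension: int
    per_split: pd.DataFrame  # split, c_x, c_y, holdout_corr, p, p_corrected
    models: list[RccaModel]
    loadings_mean: LoadingSet
    loadings_sd: LoadingSet
    per_split_loadings: list[LoadingSet]
    scores: pd.DataFrame  # id, brain/behaviour averaged + holdout-only
    omnibus: bool | None  # None when permutation testing was disabled
    null_corrs: list[np.ndarray] | None = None


def _apply_sign_map(Y: np.ndarray, y_names: list[str], sign_map: dict) -> np.ndarray:
    if not sign_map:
        return Y
    Y = np.array(Y, dtype=float)
    for name, s in sign_map.items():
        if name not in y_names:
            raise ValueError(f"sign map names unknown variable {name!r}")
        Y[:, y_names.index(name)] *= float(s)
    return Y


def _align_to_reference(loads: LoadingSet, ref: LoadingSet) -> float:
    """Sign with which a split's model agrees with the reference split."""
    a = np.concatenate([loads.brain.to_numpy(), loads.behaviour.to_numpy()])
    b = np.concatenate([ref.brain.to_numpy(), ref.behaviour.to_numpy()])
    ok = np.isfinite(a) & np.isfinite(b)
    return 1.0 if float(a[ok] @ b[ok]) >= 0 else -1.0


def run_framework(cohort: Cohort, config: RunConfig) -> list[DimensionResult]:
    """Run the full multiple-holdout pipeline on one cohort.

    Per dimension and outer split: preprocess, grid-search on the inner
    splits, refit on the full optimisation set with the selected
    hyperparameters, project the holdout set, then (if enabled) run the
    family-restricted permutation test.  Deflation is applied within each
    split using the optimisation-set model.  Stops after the first
    dimension whose omnibus hypothesis is not rejected.
    """
    from .permutation import (
        blocks_from_metadata, omnibus_decision, permutation_null,
        permutation_pvalue,
    )

    cohort.validate()
    scheme = make_split_scheme(
        cohort.metadata, config.n_outer, config.n_inner,
        config.holdout_fraction, config.test_fraction, seed=config.seed,
    )
    X_all = cohort.X
    if config.normalise_brain_size:
        X_all = normalise_brain(X_all, cohort.size_totals, cohort.x_blocks)
    Y_all = _apply_sign_map(cohort.Y, cohort.y_names, config.sign_map)

    # per outer split: residualise with optimisation-set coefficients;
    # base_* stay undeflated (for loadings), work_* are deflated in place
    base_X, base_Y, work_X, work_Y = [], [], [], []
    for opt, hold in scheme.outer:
        st_x = fit_preprocess(X_all[opt], cohort.metadata.iloc[opt],
                              config.confounds, fitted_on=opt)
        st_y = fit_preprocess(Y_all[opt], cohort.metadata.iloc[opt],
                              config.confounds, fitted_on=opt)
        base_X.append(apply_preprocess(st_x, X_all, cohort.metadata))
        base_Y.append(apply_preprocess(st_y, Y_all, cohort.metadata))
        work_X.append(base_X[-1])
        work_Y.append(base_Y[-1])

    results: list[DimensionResult] = []
    for dim in range(1, config.max_dimensions + 1):
        rows, models, null_all, split_loads = [], [], [], []
        scores_brain = np.full((cohort.n, config.n_outer), np.nan)
        scores_behav = np.full((cohort.n, config.n_outer), np.nan)
        hold_brain = np.full((cohort.n, config.n_outer), np.nan)
        hold_behav = np.full((cohort.n, config.n_outer), np.nan)

        for o, (opt, hold) in enumerate(scheme.outer):
            Xs, Ys = work_X[o], work_Y[o]
            # inner indices are absolute; map into the optimisation slice
            pos = {int(i): k for k, i in enumerate(opt)}
            inner = [
                (np.array([pos[int(i)] for i in tr]),
                 np.array([pos[int(i)] for i in te]))
                for tr, te in scheme.inner[o]
            ]
            gres = grid_search(Xs[opt], Ys[opt], inner, config.grid)
            cx, cy = gres.selected
            model = fit_rcca(Xs[opt], Ys[opt], cx, cy)
            models.append(model)
            hold_scores = project(model, Xs[hold], Ys[hold])
            r_hold = hold_scores.corr()

            # loadings: undeflated preprocessed variables vs this split's
            # optimisation-set scores
            opt_scores = project(model, Xs[opt], Ys[opt])
            split_loads.append(compute_loadings(
                base_X[o][opt], base_Y[o][opt],
                opt_scores, cohort.x_names, cohort.y_names,
            ))

            all_scores = project(model, Xs, Ys)
            scores_brain[:, o] = all_scores.brain
            scores_behav[:, o] = all_scores.behaviour
            hold_brain[hold, o] = hold_scores.brain
            hold_behav[hold, o] = hold_scores.behaviour

            p = p_corr = np.nan
            if config.n_permutations > 0:
                blocks_opt = blocks_from_metadata(cohort.metadata.iloc[opt])
                blocks_hold = blocks_from_metadata(cohort.metadata.iloc[hold])
                rng = substream(config.seed, "permutation", dim, o)
                nulls = permutation_null(
                    Xs[opt], Ys[opt], Xs[hold], Ys[hold],
                    blocks_opt, blocks_hold, cx, cy,
                    config.n_permutations, rng,
                )
                null_all.append(nulls)
                p, p_corr = permutation_pvalue(
                    r_hold, nulls, n_comparisons=config.n_outer,
                    estimator=config.p_estimator, tie_rule=config.tie_rule,
                )
            rows.append({"split": o, "c_x": cx, "c_y": cy,
                         "holdout_corr": r_hold, "p": p, "p_corrected": p_corr})

        # sign-align splits to the first before averaging loadings/scores
        signs = np.array([
            _align_to_reference(l, split_loads[0]) for l in split_loads
        ])
        aligned = []
        for s, l in zip(signs, split_loads):
            aligned.append(LoadingSet(brain=l.brain * s, behaviour=l.behaviour * s))
        brain_mat = pd.concat([l.brain for l in aligned], axis=1)
        behav_mat = pd.concat([l.behaviour for l in aligned], axis=1)
        loads_mean = LoadingSet(brain_mat.mean(axis=1), behav_mat.mean(axis=1))
        loads_sd = LoadingSet(brain_mat.std(axis=1, ddof=1),
                              behav_mat.std(axis=1, ddof=1))

        scores_brain *= signs
        scores_behav *= signs
        hold_brain *= signs
        hold_behav *= signs

        def _standardise(v: np.ndarray) -> np.ndarray:
            sd = np.nanstd(v, ddof=1)
            return (v - np.nanmean(v)) / sd if sd > 0 else v

        import warnings

        with warnings.catch_warnings():
            # participants never drawn into a holdout set stay NaN
            warnings.simplefilter("ignore", category=RuntimeWarning)
            scores = pd.DataFrame({
                "id": cohort.ids,
                "brain_score": _standardise(np.nanmean(scores_brain, axis=1)),
                "behaviour_score": _standardise(np.nanmean(scores_behav, axis=1)),
                "brain_score_holdout": _standardise(np.nanmean(hold_brain, axis=1)),
                "behaviour_score_holdout": _standardise(np.nanmean(hold_behav, axis=1)),
            })

        per_split = pd.DataFrame(rows)
        omnibus = None
        if config.n_permutations > 0:
            omnibus = omnibus_decision(
                per_split["p_corrected"].to_numpy(), config.alpha
            )
        results.append(DimensionResult(
            dimension=dim, per_split=per_split, models=models,
            loadings_mean=loads_mean, loadings_sd=loads_sd,
            per_split_loadings=aligned, scores=scores, omnibus=omnibus,
            null_corrs=null_all or None,
        ))
        if omnibus is False:
            break
        if dim < config.max_dimensions:
            for o, (opt, hold) in enumerate(scheme.outer):
                defl = make_deflator(work_X[o][opt], work_Y[o][opt], models[o])
                work_X[o], work_Y[o] = defl.apply(work_X[o], work_Y[o])
    return results
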