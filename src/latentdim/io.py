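"""Tabular readers/writers, configuration and run manifests.

All interchange is plain text: features, metadata and parcel tables as TSV,
configuration as YAML, ground truth / model weights / manifests as JSON.
These files are the pipeline's input and output contracts; the writers and
readers round-trip losslessly (floats are serialised at full precision).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .framework import DimensionResult, RunConfig
from .rcca import LoadingSet, RccaModel
from .synthetic import (
    Cohort,
    CohortSpec,
    ConfoundEffects,
    FamilyBlock,
    GroundTruth,
    ParcelAtlas,
    PlantedDimension,
)

__all__ = [
    "write_cohort",
    "load_cohort",
    "write_results",
    "load_results",
    "load_config",
    "write_manifest",
    "CohortValidationError",
]

_FLOAT_FMT = "%.17g"

META_COLUMNS = ["id", "age", "gender", "site", "family_id", "pair_id", "zygosity"]
SIZE_COLUMNS = ["tiv", "mean_ct", "total_sa"]


class CohortValidationError(ValueError):
    """Raised with an itemised report when cohort files are inconsistent."""


# ---------------------------------------------------------------------------
# cohort round trip
# ---------------------------------------------------------------------------


def _spec_to_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["family_blocks"] = [
        {"n_members": f.n_members, "twin_type": f.twin_type}
        for f in spec.family_blocks
    ]
    d["planted_dimensions"] = [
        {
            "rho": p.rho,
            "brain_loading_pattern": None
            if p.brain_loading_pattern is None
            else np.asarray(p.brain_loading_pattern).tolist(),
            "behaviour_loading_pattern": None
            if p.behaviour_loading_pattern is None
            else np.asarray(p.behaviour_loading_pattern).tolist(),
        }
        for p in spec.planted_dimensions
    ]
    return d


def _spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    d["family_blocks"] = [FamilyBlock(**f) for f in d["family_blocks"]]
    d["planted_dimensions"] = [
        PlantedDimension(
            rho=p["rho"],
            brain_loading_pattern=None
            if p["brain_loading_pattern"] is None
            else np.asarray(p["brain_loading_pattern"]),
            behaviour_loading_pattern=None
            if p["behaviour_loading_pattern"] is None
            else np.asarray(p["behaviour_loading_pattern"]),
        )
        for p in d["planted_dimensions"]
    ]
    d["confound_effects"] = ConfoundEffects(**d["confound_effects"])
    d["age_range"] = tuple(d["age_range"])
    d["brain_blocks"] = [tuple(b) for b in d["brain_blocks"]]
    return CohortSpec(**d)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort to its four-file TSV/JSON contract."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats = pd.DataFrame(
        np.hstack([cohort.X, cohort.Y]),
        columns=list(cohort.x_names) + list(cohort.y_names),
    )
    feats.insert(0, "id", cohort.ids)
    feats.to_csv(out / "features.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = cohort.metadata.merge(cohort.size_totals, on="id")
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    cohort.atlas.table.to_csv(
        out / "parcels.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    if cohort.truth is not None:
        truth = {
            "spec": _spec_to_dict(cohort.truth.spec),
            "brain_patterns": cohort.truth.brain_patterns.tolist(),
            "behaviour_patterns": cohort.truth.behaviour_patterns.tolist(),
            "latents_brain": cohort.truth.latents_brain.tolist(),
            "latents_behaviour": cohort.truth.latents_behaviour.tolist(),
        }
        (out / "truth.json").write_text(json.dumps(truth))
    return out


def _validate_table(df: pd.DataFrame, name: str, required: list[str]) -> list[str]:
    problems = []
    for col in required:
        if col not in df.columns:
            problems.append(f"{name}: missing column {col!r}")
    return problems


def load_cohort(cohort_dir: str | Path) -> Cohort:
    """Load and validate a cohort written by :func:`write_cohort`.

    Incomplete cases are rejected outright: any NaN cell, id mismatch or
    missing column produces a :class:`CohortValidationError` whose message
    itemises every problem found.
    """
    d = Path(cohort_dir)
    problems: list[str] = []
    try:
        feats = pd.read_csv(d / "features.tsv", sep="\t",
                            float_precision="round_trip")
        meta = pd.read_csv(d / "metadata.tsv", sep="\t", keep_default_na=False,
                           na_values=[""], dtype={"pair_id": str},
                           float_precision="round_trip")
        parcels = pd.read_csv(d / "parcels.tsv", sep="\t")
    except FileNotFoundError as e:
        raise CohortValidationError(f"missing cohort file: {e.filename}") from e

    problems += _validate_table(feats, "features", ["id"])
    problems += _validate_table(meta, "metadata", META_COLUMNS + SIZE_COLUMNS)
    problems += _validate_table(
        parcels, "parcels", ["parcel_id", "block", "hemisphere", "x", "y", "z",
                             "subcortical"]
    )
    if problems:
        raise CohortValidationError("; ".join(problems))

    meta["pair_id"] = meta["pair_id"].fillna("")
    fid = set(feats["id"])
    mid = set(meta["id"])
    if fid != mid:
        only_f = sorted(fid - mid)[:5]
        only_m = sorted(mid - fid)[:5]
        if only_f:
            problems.append(f"ids only in features: {only_f}")
        if only_m:
            problems.append(f"ids only in metadata: {only_m}")
    value_cols = [c for c in feats.columns if c != "id"]
    nan_mask = feats[value_cols].isna()
    if nan_mask.to_numpy().any():
        for col in value_cols:
            for row in feats.index[nan_mask[col]][:3]:
                problems.append(
                    f"NaN in features at id={feats.loc[row, 'id']}, column={col}"
                )
    for col in ["age", "gender"] + SIZE_COLUMNS:
        if col in meta.columns and meta[col].isna().any():
            bad = meta.loc[meta[col].isna(), "id"].tolist()[:3]
            problems.append(f"NaN in metadata column {col} for ids {bad}")
    if problems:
        raise CohortValidationError("; ".join(problems))

    parcel_ids = list(parcels["parcel_id"])
    x_names = [c for c in value_cols if c in set(parcel_ids)]
    y_names = [c for c in value_cols if c not in set(parcel_ids)]
    block_of = dict(zip(parcels["parcel_id"], parcels["block"]))

    truth = None
    tp = d / "truth.json"
    if tp.exists():
        t = json.loads(tp.read_text())
        truth = GroundTruth(
            spec=_spec_from_dict(t["spec"]),
            brain_patterns=np.asarray(t["brain_patterns"]),
            behaviour_patterns=np.asarray(t["behaviour_patterns"]),
            latents_brain=np.asarray(t["latents_brain"]),
            latents_behaviour=np.asarray(t["latents_behaviour"]),
        )

    cohort = Cohort(
        ids=meta["id"].to_numpy(),
        metadata=meta[META_COLUMNS],
        X=feats.set_index("id").loc[meta["id"], x_names].to_numpy(float),
        x_names=x_names,
        x_blocks=np.asarray([block_of[c] for c in x_names]),
        Y=feats.set_index("id").loc[meta["id"], y_names].to_numpy(float),
        y_names=y_names,
        size_totals=meta[["id"] + SIZE_COLUMNS],
        atlas=ParcelAtlas(parcels),
        truth=truth,
    )
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_results(results: list[DimensionResult], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = []
    for res in results:
        k = res.dimension
        res.per_split.to_csv(out / f"dimension_{k}_splits.tsv", sep="\t",
                             index=False, float_format=_FLOAT_FMT)
        loads = pd.DataFrame({
            "variable": list(res.loadings_mean.brain.index)
            + list(res.loadings_mean.behaviour.index),
            "view": ["brain"] * len(res.loadings_mean.brain)
            + ["behaviour"] * len(res.loadings_mean.behaviour),
            "loading_mean": np.concatenate([
                res.loadings_mean.brain.to_numpy(),
                res.loadings_mean.behaviour.to_numpy(),
            ]),
            "loading_sd": np.concatenate([
                res.loadings_sd.brain.to_numpy(),
                res.loadings_sd.behaviour.to_numpy(),
            ]),
        })
        loads.to_csv(out / f"dimension_{k}_loadings.tsv", sep="\t",
                     index=False, float_format=_FLOAT_FMT)
        res.scores.to_csv(out / f"dimension_{k}_scores.tsv", sep="\t",
                          index=False, float_format=_FLOAT_FMT)
        (out / f"dimension_{k}_models.json").write_text(
            json.dumps([m.to_dict() for m in res.models])
        )
        if res.null_corrs is not None:
            pd.DataFrame({f"split{i}": n for i, n in enumerate(res.null_corrs)}
                         ).to_csv(out / f"dimension_{k}_nulls.tsv", sep="\t",
                                  index=False, float_format=_FLOAT_FMT)
        summary.append({"dimension": k, "omnibus": res.omnibus})
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return out


def load_results(results_dir: str | Path) -> list[DimensionResult]:
    """Reload results for downstream comparison; model weights included,
    per-split loadings and null distributions are not reconstructed."""
    d = Path(results_dir)
    summary = json.loads((d / "summary.json").read_text())
    results = []
    for entry in summary:
        k = entry["dimension"]
        per_split = pd.read_csv(d / f"dimension_{k}_splits.tsv", sep="\t")
        loads = pd.read_csv(d / f"dimension_{k}_loadings.tsv", sep="\t")
        brain = loads[loads["view"] == "brain"].set_index("variable")
        behav = loads[loads["view"] == "behaviour"].set_index("variable")
        models = [
            RccaModel.from_dict(m)
            for m in json.loads((d / f"dimension_{k}_models.json").read_text())
        ]
        results.append(DimensionResult(
            dimension=k,
            per_split=per_split,
            models=models,
            loadings_mean=LoadingSet(brain["loading_mean"], behav["loading_mean"]),
            loadings_sd=LoadingSet(brain["loading_sd"], behav["loading_sd"]),
            per_split_loadings=[],
            scores=pd.read_csv(d / f"dimension_{k}_scores.tsv", sep="\t"),
            omnibus=entry["omnibus"],
        ))
    return results


# ---------------------------------------------------------------------------
# configuration and manifest
# ---------------------------------------------------------------------------


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path, config: RunConfig, inputs: list[str | Path]
) -> Path:
    """Run manifest: config snapshot, seed, input digests, timestamp.

    Together with the package version this is sufficient to reproduce a
    run bitwise (all randomness derives from the config seed).
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "master_seed": config.seed,
        "version": __version__,
        "inputs": {str(p): _digest(Path(p)) for p in inputs if Path(p).is_file()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
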