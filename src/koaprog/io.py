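"""File formats and serialization tying the pipeline stages together.

All interchange formats are plain text: comma-separated UTF-8 CSV with a
mandatory header for tables, JSON for models, event sets, configurations,
and run manifests.  Stages are 0-based everywhere.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .events import BiomarkerDef, Event, EventSequence, EventSet
from .inference import SequencePosterior, SubtypeProgressionModel
from .simulate import SyntheticCohort

FORMAT_VERSION = 1


class SchemaError(ValueError):
    """A file does not match the expected schema."""


# ---------------------------------------------------------------------------
# Tables


def read_cohort_csv(path, biomarkers: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a subjects x columns CSV; optionally require biomarker columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.shape[0] == 0:
        raise SchemaError(f"{path}: no data rows")
    if biomarkers is not None:
        missing = [b for b in biomarkers if b not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        for col in biomarkers:
            try:
                df[col] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError) as exc:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:3]
                raise SchemaError(
                    f"{path}: non-numeric value in column {col!r} "
                    f"(row(s) {list(bad)})"
                ) from exc
    return df


def read_biomarker_defs(path) -> list[BiomarkerDef]:
    """Read biomarker definitions from CSV (columns: name, direction[, candidate_events]).

    ``candidate_events`` is a semicolon-separated threshold list, defaulting
    to 1;2;3;5.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    for col in ("name", "direction"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    defs = []
    for i, row in df.iterrows():
        try:
            direction = int(row["direction"])
        except (ValueError, TypeError):
            raise SchemaError(
                f"{path}: row {i}: unknown direction value {row['direction']!r}"
            ) from None
        kwargs = {}
        if "candidate_events" in df.columns and not pd.isna(row["candidate_events"]):
            try:
                kwargs["candidate_events"] = tuple(
                    float(z) for z in str(row["candidate_events"]).split(";")
                )
            except ValueError:
                raise SchemaError(
                    f"{path}: row {i}: bad candidate_events "
                    f"{row['candidate_events']!r}"
                ) from None
        try:
            defs.append(BiomarkerDef(name=str(row["name"]), direction=direction, **kwargs))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    if not defs:
        raise SchemaError(f"{path}: no biomarker definitions")
    return defs


def write_biomarker_defs(defs: Sequence[BiomarkerDef], path) -> None:
    pd.DataFrame(
        {
            "name": [d.name for d in defs],
            "direction": [d.direction for d in defs],
            "candidate_events": [
                ";".join(str(z) for z in d.candidate_events) for d in defs
            ],
        }
    ).to_csv(path, index=False)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write a synthetic cohort: cohort.csv, controls.csv, config.json.

    The cohort CSV has one row per subject: biomarker columns, demographic
    columns, severity grade, and the ground-truth subtype and stage.
    """
    from .simulate import generate_control_group

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = cohort.raw_values.copy()
    for col in cohort.demographics.columns:
        table[col] = cohort.demographics[col].to_numpy()
    table["grade"] = cohort.severity_grade
    table["truth_subtype"] = cohort.truth_subtype
    table["truth_stage"] = cohort.truth_stage
    cohort_path = out / "cohort.csv"
    table.to_csv(cohort_path, index=False)

    controls = generate_control_group(cohort.config)
    controls_path = out / "controls.csv"
    controls.to_csv(controls_path, index=False)

    cfg = cohort.config
    config_path = out / "config.json"
    config_path.write_text(
        json.dumps(
            {
                "format_version": FORMAT_VERSION,
                "seed": cfg.seed,
                "n_subjects": cfg.n_subjects,
                "n_controls": cfg.n_controls,
                "noise_sd": cfg.noise_sd,
                "severity_thresholds": list(cfg.severity_thresholds),
                "grade_flip_prob": cfg.grade_flip_prob,
                "fractions": cfg.fractions().tolist(),
                "truth_orders": [list(s.sequence.order) for s in cfg.subtypes],
                "event_set": _event_set_dict(cfg.event_set),
            },
            indent=2,
        )
    )
    if cfg.biomarker_defs:
        write_biomarker_defs(cfg.biomarker_defs, out / "biomarker_defs.csv")
    return {"cohort": cohort_path, "controls": controls_path, "config": config_path}


# ---------------------------------------------------------------------------
# Event sets and models


def _event_set_dict(es: EventSet) -> dict:
    return {
        "events": [[e.biomarker, e.z] for e in es.events],
        "max_z": dict(es.max_z),
    }


def _event_set_from_dict(d: dict) -> EventSet:
    return EventSet(
        events=tuple(Event(str(b), float(z)) for b, z in d["events"]),
        max_z={str(k): float(v) for k, v in d["max_z"].items()},
    )


def write_event_set(es: EventSet, path) -> None:
    Path(path).write_text(
        json.dumps({"format_version": FORMAT_VERSION, **_event_set_dict(es)}, indent=2)
    )


def read_event_set(path) -> EventSet:
    d = _load_json(path)
    return _event_set_from_dict(d)


def write_model_json(
    model: SubtypeProgressionModel,
    path,
    posterior: SequencePosterior | None = None,
) -> None:
    """Serialize a fitted model (and optionally its sequence posterior).

    The positional-variance matrices, when present, are additionally
    exported as CSV heatmap tables next to the model file (one per subtype,
    rows = events, columns = positions; rows sum to 1).
    """
    model._check_fitted()
    path = Path(path)
    doc = {
        "format_version": FORMAT_VERSION,
        "event_set": _event_set_dict(model._es()),
        "n_subtypes": len(model.sequences_),
        "sequences": [list(s.order) for s in model.sequences_],
        "fractions": np.asarray(model.fractions_).tolist(),
        "sigma": np.asarray(model.sigma).tolist(),
        "loglik": float(model.loglik_),
        "params": {
            k: v
            for k, v in model.get_params().items()
            if k not in ("event_set",) and _jsonable(v)
        },
    }
    if posterior is not None:
        doc["acceptance_rate"] = [float(r) for r in posterior.acceptance_rate]
        es = model._es()
        labels = [f"{e.biomarker}:z{e.z:g}" for e in es.events]
        for t, pvd in enumerate(posterior.positional_variance):
            pvd_path = path.with_name(path.stem + f".pvd{t}.csv")
            pd.DataFrame(
                pvd, index=labels, columns=[f"pos{p}" for p in range(1, es.S + 1)]
            ).to_csv(pvd_path, index_label="event")
    path.write_text(json.dumps(doc, indent=2))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _load_json(path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc


def read_model_json(path) -> SubtypeProgressionModel:
    """Rebuild a fitted model from :func:`write_model_json` output."""
    d = _load_json(path)
    version = d.get("format_version")
    if version != FORMAT_VERSION:
        raise SchemaError(
            f"{path}: format version {version!r} does not match {FORMAT_VERSION}"
        )
    es = _event_set_from_dict(d["event_set"])
    sigma = d["sigma"]
    sigma = float(sigma) if np.isscalar(sigma) else np.asarray(sigma, dtype=float)
    model = SubtypeProgressionModel(
        event_set=es, n_subtypes=int(d["n_subtypes"]), sigma=sigma
    )
    for k, v in d.get("params", {}).items():
        if k in model.get_params() and k not in ("event_set", "n_subtypes", "sigma"):
            setattr(model, k, v)
    model.sequences_ = [
        EventSequence(order=tuple(int(i) for i in o), event_set=es)
        for o in d["sequences"]
    ]
    model.fractions_ = np.asarray(d["fractions"], dtype=float)
    model.loglik_ = float(d["loglik"])
    model.converged_ = True
    model.em_traces_ = {}
    model.n_features_in_ = es.n_biomarkers
    return model


# ---------------------------------------------------------------------------
# Run manifests


def write_manifest(out_dir, config: dict, inputs: Sequence[str | Path] = ()) -> Path:
    """Write a run manifest: configuration plus content hashes of inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for p in inputs:
        p = Path(p)
        hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = out / "manifest.json"
    manifest.write_text(
        json.dumps(
            {"format_version": FORMAT_VERSION, "config": config, "input_sha256": hashes},
            indent=2,
            default=str,
        )
    )
    return manifest
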