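"""JSON serialization of stage outputs, plus document validation models."""

from __future__ import annotations

import json
import math
from typing import Iterable, Mapping

from pydantic import BaseModel, Field

from .bayes import CorrelationResult, SequentialResult
from .design import (EXPOSURE_MS, FIXATION_MS, LineEnsemble, N_GRID_COLS,
                     N_GRID_ROWS, TASKS)
from .screening import ExclusionReport


def _clean(x):
    if isinstance(x, float) and not math.isfinite(x):
        return None
    return x


def design_to_json(designs: Mapping[str, list[LineEnsemble]],
                   provenance: dict) -> str:
    doc = {
        "provenance": provenance,
        "display": {"exposure_ms": EXPOSURE_MS, "fixation_ms": FIXATION_MS,
                    "grid_rows": N_GRID_ROWS, "grid_cols": N_GRID_COLS},
        "tasks": {},
    }
    for task, ensembles in designs.items():
        trials = []
        for i, ens in enumerate(ensembles):
            trials.append({
                "trial_index": i,
                "spec": {
                    "task": ens.spec.task,
                    "mean_length": ens.spec.mean_length,
                    "sd_length": ens.spec.sd_length,
                    "mean_orientation": ens.spec.mean_orientation,
                    "sd_orientation": ens.spec.sd_orientation,
                    "repetition": ens.spec.repetition,
                },
                "lengths": list(ens.lengths),
                "orientations": list(ens.orientations),
                "layout": {"version": ens.layout.version,
                           "cells": [list(c) for c in ens.layout.cells]},
            })
        doc["tasks"][task] = trials
    return json.dumps(doc, indent=1)


def reports_to_json(reports: Iterable[ExclusionReport], alphas: Mapping[str, float],
                    provenance: dict) -> str:
    doc = {
        "provenance": provenance,
        "reliability": {t: _clean(alphas[t]) for t in TASKS},
        "observers": [
            {
                "observer_id": r.observer_id,
                "above_chance_length": r.above_chance_length,
                "above_chance_orientation": r.above_chance_orientation,
                "person_fit_length": _clean(r.person_fit_length),
                "person_fit_orientation": _clean(r.person_fit_orientation),
                "included": r.included,
                "reason": r.reason,
            }
            for r in reports
        ],
    }
    return json.dumps(doc, indent=1)


def result_to_json(result: CorrelationResult, seq: SequentialResult | None,
                   alphas: Mapping[str, float], provenance: dict,
                   seq_note: str = "") -> str:
    doc = {
        "provenance": provenance,
        "correlation": {
            "r": _clean(result.r),
            "n": result.n,
            "bf_plus0": _clean(result.bf_plus0),
            "ci_low": _clean(result.ci_low),
            "ci_high": _clean(result.ci_high),
            "jeffreys_label": result.jeffreys_label,
            "r_disattenuated": _clean(result.r_disattenuated),
            "shared_variance": _clean(result.shared_variance),
            "degenerate": result.degenerate,
            "note": result.note,
        },
        "reliability": {t: _clean(alphas[t]) for t in TASKS},
        "sequential": None if seq is None else {
            "n_start": seq.n_start,
            "threshold_high": seq.threshold_high,
            "threshold_low": seq.threshold_low,
            "bf_trajectory": [_clean(b) for b in seq.bf_trajectory],
            "n_stop": seq.n_stop,
            "decision": seq.decision,
        },
        "sequential_note": seq_note,
    }
    return json.dumps(doc, indent=1)


# -- validation models for third-party design documents ----------------------

class SpecModel(BaseModel):
    task: str
    mean_length: float
    sd_length: float
    mean_orientation: float
    sd_orientation: float
    repetition: int = Field(ge=1, le=2)


class TrialModel(BaseModel):
    trial_index: int = Field(ge=0)
    spec: SpecModel
    lengths: list[float] = Field(min_length=12, max_length=12)
    orientations: list[float] = Field(min_length=12, max_length=12)
    layout: dict


class DesignDocument(BaseModel):
    provenance: dict
    display: dict
    tasks: dict[str, list[TrialModel]]


def validate_design_document(text: str) -> DesignDocument:
    """Validate a design.json payload (raises pydantic.ValidationError)."""
    return DesignDocument.model_validate_json(text)
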