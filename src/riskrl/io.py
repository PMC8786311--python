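"""Validated tabular readers and writers for the pipeline's artifacts.

Everything is plain CSV with declared schemas: per-subject trial tables,
memory tables, fit results, learning traces, and recovery matrices. The
trial-table reader validates machine labels and choice consistency and
reports offending row numbers; a column-mapping option accommodates
externally produced tables with different headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, models, sessions, task
from .memory import MemoryRecord
from .synth import SubjectData

__all__ = [
    "write_machines_json",
    "read_machines_json",
    "write_trial_table",
    "read_trial_table",
    "write_memory_table",
    "read_memory_table",
    "write_fit_results",
    "write_trace",
    "write_truth",
    "write_json_sidecar",
]

TRIAL_COLUMNS = [
    "subject_id", "trial", "block", "trial_type", "machine_left",
    "machine_right", "chosen", "outcome_points", "missed", "image_id",
]

MEMORY_COLUMNS = [
    "subject_id", "image_id", "truly_old", "response", "said_old", "correct",
    "trial", "agency", "pe", "pe_mag", "pe_valence", "machine_type",
    "mem_trial_number",
]


def write_machines_json(machines: list[task.MachineSpec], path: str | Path) -> None:
    """Serialize a machine set, for non-canonical task variants."""
    payload = [
        {"machine_id": m.machine_id, "outcomes": list(m.outcomes),
         "probabilities": list(m.probabilities)}
        for m in machines
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_machines_json(path: str | Path) -> list[task.MachineSpec]:
    payload = json.loads(Path(path).read_text())
    out = []
    for i, entry in enumerate(payload):
        extra = set(entry) - {"machine_id", "outcomes", "probabilities"}
        if extra:
            raise ValueError(f"machine entry {i}: unknown keys {sorted(extra)}")
        out.append(
            task.MachineSpec(
                entry["machine_id"], tuple(entry["outcomes"]), tuple(entry["probabilities"])
            )
        )
    return out


def _float_fmt(x) -> str:
    # fixed formatting so outputs are byte-identical across runs
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.10g}"


def write_trial_table(subjects: list[SubjectData], path: str | Path) -> None:
    """One row per trial per subject, in task order."""
    rows = []
    for subj in subjects:
        for spec, rec in zip(subj.session.sequence, subj.session.records):
            if spec.trial_type == "forced":
                left = spec.offered[0] if spec.forced_position == "left" else ""
                right = spec.offered[0] if spec.forced_position == "right" else ""
            else:
                left, right = spec.offered
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "trial": spec.index,
                    "block": spec.block,
                    "trial_type": spec.trial_type,
                    "machine_left": left,
                    "machine_right": right,
                    "chosen": "" if rec.missed else rec.chosen,
                    "outcome_points": "" if rec.missed else rec.outcome_points,
                    "missed": int(rec.missed),
                    "image_id": rec.image_id or "",
                }
            )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_trial_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> dict[int, sessions.Session]:
    """Read and validate a trial table; returns sessions keyed by subject.

    Raises descriptive errors naming the offending CSV row (1-based, header
    excluded) for unknown machines or choices of unoffered machines.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        frame = frame.rename(columns=column_map)
    missing_cols = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ValueError(f"trial table missing columns: {sorted(missing_cols)}")
    known = set(sessions.MACHINE_INDEX)
    out: dict[int, sessions.Session] = {}
    for subject_id, group in frame.groupby(frame["subject_id"].astype(int), sort=True):
        specs, records = [], []
        for row_idx, row in group.iterrows():
            rownum = row_idx + 1
            trial_type = row["trial_type"]
            left, right = row["machine_left"], row["machine_right"]
            offered = tuple(m for m in (left, right) if m)
            for m in offered:
                if m not in known:
                    raise ValueError(f"row {rownum}: unknown machine {m!r}")
            forced_position = None
            if trial_type == "forced":
                if len(offered) != 1:
                    raise ValueError(f"row {rownum}: forced trial must offer one machine")
                forced_position = "left" if left else "right"
            elif len(offered) != 2 or offered[0] == offered[1]:
                raise ValueError(f"row {rownum}: free trial must offer two distinct machines")
            specs.append(
                task.TrialSpec(int(row["trial"]), int(row["block"]), trial_type, offered, forced_position)
            )
            missed = bool(int(row["missed"]))
            if missed:
                records.append(task.ChoiceRecord(int(row["trial"]), None, None, missed=True))
                continue
            chosen = row["chosen"]
            if chosen not in offered:
                raise ValueError(
                    f"row {rownum}: chosen machine {chosen!r} was not offered {offered}"
                )
            records.append(
                task.ChoiceRecord(
                    int(row["trial"]),
                    chosen,
                    int(row["outcome_points"]),
                    image_id=row["image_id"] or None,
                )
            )
        seq = task.TrialSequence(tuple(specs), seed=-1)  # seed unknown for ingested data
        out[int(subject_id)] = sessions.Session(seq, tuple(records))
    return out


def write_memory_table(subjects: list[SubjectData], path: str | Path) -> None:
    rows = []
    for subj in subjects:
        for rec in subj.memory_records:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "image_id": rec.image_id,
                    "truly_old": int(rec.truly_old),
                    "response": rec.response,
                    "said_old": int(rec.said_old),
                    "correct": int(rec.correct),
                    "trial": "" if rec.trial is None else rec.trial,
                    "agency": rec.agency or "",
                    "pe": _float_fmt(rec.pe),
                    "pe_mag": _float_fmt(rec.pe_magnitude),
                    "pe_valence": "" if rec.pe_valence is None else rec.pe_valence,
                    "machine_type": rec.machine_type or "",
                    "mem_trial_number": rec.mem_trial_number,
                }
            )
    pd.DataFrame(rows, columns=MEMORY_COLUMNS).to_csv(path, index=False)


def read_memory_table(path: str | Path) -> dict[int, list[MemoryRecord]]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(MEMORY_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ValueError(f"memory table missing columns: {sorted(missing_cols)}")
    out: dict[int, list[MemoryRecord]] = {}
    for _, row in frame.iterrows():
        rec = MemoryRecord(
            subject_id=int(row["subject_id"]),
            image_id=row["image_id"],
            truly_old=bool(int(row["truly_old"])),
            response=int(row["response"]),
            mem_trial_number=int(row["mem_trial_number"]),
            trial=int(row["trial"]) if row["trial"] else None,
            agency=row["agency"] or None,
            pe=float(row["pe"]) if row["pe"] else None,
            machine_type=row["machine_type"] or None,
        )
        out.setdefault(rec.subject_id, []).append(rec)
    return out


FIT_COLUMNS = [
    "subject_id", "model", "alpha", "alpha_pos", "alpha_neg",
    "alpha_pos_forced", "alpha_neg_forced", "beta", "rho",
    "nlp", "loglik", "k", "n", "bic", "ai", "converged",
]


def write_fit_results(fits: dict[int, inference.FitResult], path: str | Path) -> None:
    """Per-subject fit export; FourLR free-trial rates fill the alpha_pos /
    alpha_neg columns and its forced-trial rates the *_forced columns."""
    rows = []
    for subject_id, fit in sorted(fits.items()):
        p = fit.map_params
        rows.append(
            {
                "subject_id": subject_id,
                "model": fit.model_name,
                "alpha": _float_fmt(p.alpha),
                "alpha_pos": _float_fmt(p.alpha_pos if p.alpha_pos is not None else p.alpha_pos_free),
                "alpha_neg": _float_fmt(p.alpha_neg if p.alpha_neg is not None else p.alpha_neg_free),
                "alpha_pos_forced": _float_fmt(p.alpha_pos_forced),
                "alpha_neg_forced": _float_fmt(p.alpha_neg_forced),
                "beta": _float_fmt(p.beta),
                "rho": _float_fmt(p.rho),
                "nlp": _float_fmt(fit.neg_log_posterior),
                "loglik": _float_fmt(fit.log_likelihood_at_map),
                "k": models.N_PARAMS[fit.model_name],
                "n": fit.n_modeled_choices,
                "bic": _float_fmt(fit.bic),
                "ai": _float_fmt(fit.asymmetry_index),
                "converged": int(fit.converged),
            }
        )
    pd.DataFrame(rows, columns=FIT_COLUMNS).to_csv(path, index=False)


def write_trace(subject_id: int, trace: models.LearningTrace, path: str | Path) -> None:
    rows = [
        {
            "subject_id": subject_id,
            "trial": s.trial,
            "agency": s.agency,
            "chosen": s.chosen,
            "q_pre": _float_fmt(s.q_pre),
            "pe": _float_fmt(s.delta),
            "valence": s.valence,
            "q_post": _float_fmt(s.q_post),
        }
        for s in trace
    ]
    pd.DataFrame(
        rows, columns=["subject_id", "trial", "agency", "chosen", "q_pre", "pe", "valence", "q_post"]
    ).to_csv(path, index=False)


def write_truth(subjects: list[SubjectData], path: str | Path) -> None:
    """Generating parameters of a synthetic cohort, for recovery tests."""
    rows = []
    for subj in subjects:
        p = subj.true_params
        rows.append(
            {
                "subject_id": subj.subject_id,
                "age": _float_fmt(subj.age),
                "alpha_pos": _float_fmt(p.alpha_pos if p else None),
                "alpha_neg": _float_fmt(p.alpha_neg if p else None),
                "beta": _float_fmt(p.beta if p else None),
                "true_ai": _float_fmt(subj.true_ai),
                "fa_rate": _float_fmt(subj.fa_rate),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json_sidecar(payload: dict, path: str | Path) -> None:
    """Run metadata (seeds, sizes, versions) next to a data artifact."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
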