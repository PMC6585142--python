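"""Tabular serialisation for profiles, plans, records and labeled calls.

CSV bodies are deterministic functions of their inputs; an optional
provenance header line (``# neocds ...``) is written above the header row
and skipped on read (``comment='#'``).
"""

from __future__ import annotations

import json
from datetime import datetime
from typing import Iterable, Optional, Sequence

import pandas as pd

from neocds import __version__ as _version
from neocds.classify import CONDITIONS, ConditionProfile, TriResult
from neocds.evaluate import LabeledAssessment
from neocds.forms import AssessmentRecord
from neocds.manage import COUNSELING_ITEMS, ManagementPlan

__all__ = [
    "write_frame",
    "profiles_to_frame",
    "profiles_from_frame",
    "read_profiles_csv",
    "write_profiles_csv",
    "plans_to_frame",
    "write_plans_csv",
    "records_to_frame",
    "records_from_frame",
    "read_records_csv",
    "write_records_csv",
    "labeled_to_frame",
    "labeled_from_frame",
    "read_labeled_csv",
    "write_labeled_csv",
]


def provenance_line(seed=None, config_hash: Optional[str] = None) -> str:
    parts = [f"# neocds v{_version}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash:
        parts.append(f"config={config_hash}")
    return " ".join(parts)


def write_frame(df: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(seed, config_hash) + "\n")
        df.to_csv(fh, index=False)


# --- condition profiles

def profiles_to_frame(profiles: Iterable[ConditionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"infant_id": p.infant_id}
        for c in CONDITIONS:
            row[c] = p[c].value
        row["preterm"] = p.preterm.value
        row["any_danger_sign"] = int(p.any_danger_sign)
        row["eligible"] = int(p.eligible)
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame) -> list[ConditionProfile]:
    out = []
    for row in df.to_dict(orient="records"):
        out.append(
            ConditionProfile(
                infant_id=str(row.get("infant_id", "")),
                conditions={c: TriResult(row[c]) for c in CONDITIONS},
                preterm=TriResult(row.get("preterm", "na")),
                any_danger_sign=bool(int(row.get("any_danger_sign", 0))),
                eligible=bool(int(row.get("eligible", 1))),
            )
        )
    return out


def write_profiles_csv(profiles, path, **prov) -> None:
    write_frame(profiles_to_frame(profiles), path, **prov)


def read_profiles_csv(path) -> list[ConditionProfile]:
    return profiles_from_frame(pd.read_csv(path, comment="#"))


# --- management plans

def plans_to_frame(plans: Iterable[ManagementPlan]) -> pd.DataFrame:
    rows = []
    for p in plans:
        row = {
            "infant_id": p.infant_id,
            "refer": int(p.refer),
            "referral_reasons": ";".join(p.referral_reasons),
            "follow_up_date": p.follow_up_date.isoformat() if p.follow_up_date else "",
        }
        for item in COUNSELING_ITEMS:
            row[item] = int(item in p.counseling)
        rows.append(row)
    return pd.DataFrame(rows)


def write_plans_csv(plans, path, **prov) -> None:
    write_frame(plans_to_frame(plans), path, **prov)


# --- assessment records (answers as a JSON column)

def records_to_frame(records: Iterable[AssessmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "method": r.method,
                "chw_id": r.chw_id,
                "infant_id": r.infant_id,
                "start_time": r.start_time.isoformat() if r.start_time else "",
                "end_time": r.end_time.isoformat() if r.end_time else "",
                "recommendations": " | ".join(r.recommendations),
                "answers": json.dumps(r.answers, default=str, sort_keys=True),
            }
        )
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[AssessmentRecord]:
    out = []
    for row in df.to_dict(orient="records"):
        recs = str(row.get("recommendations") or "")
        out.append(
            AssessmentRecord(
                method=row["method"],
                chw_id=str(row["chw_id"]),
                infant_id=str(row["infant_id"]),
                answers=json.loads(row["answers"]) if row.get("answers") else {},
                recommendations=[s for s in recs.split(" | ") if s],
                start_time=datetime.fromisoformat(row["start_time"]) if row.get("start_time") else None,
                end_time=datetime.fromisoformat(row["end_time"]) if row.get("end_time") else None,
            )
        )
    return out


def write_records_csv(records, path, **prov) -> None:
    write_frame(records_to_frame(records), path, **prov)


def read_records_csv(path) -> list[AssessmentRecord]:
    return records_from_frame(pd.read_csv(path, comment="#", keep_default_na=False))


# --- labeled per-condition calls

def labeled_to_frame(labeled: Iterable[LabeledAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chw_id": r.chw_id,
                "infant_id": r.infant_id,
                "method": r.method,
                "condition": r.condition,
                "assessor_call": r.assessor_call.value,
                "gold_call": int(r.gold_call),
                "correct": int(r.correct),
            }
            for r in labeled
        ]
    )


def labeled_from_frame(df: pd.DataFrame) -> list[LabeledAssessment]:
    return [
        LabeledAssessment(
            chw_id=str(r["chw_id"]),
            infant_id=str(r["infant_id"]),
            method=r["method"],
            condition=r["condition"],
            assessor_call=TriResult(r["assessor_call"]),
            gold_call=bool(int(r["gold_call"])),
        )
        for r in df.to_dict(orient="records")
    ]


def write_labeled_csv(labeled, path, **prov) -> None:
    write_frame(labeled_to_frame(labeled), path, **prov)


def read_labeled_csv(path) -> list[LabeledAssessment]:
    return labeled_from_frame(pd.read_csv(path, comment="#"))
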