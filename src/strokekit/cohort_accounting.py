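"""Cohort bookkeeping: chronological splits, exclusions, class ratios.

A :class:`CohortManifest` records one row per screened patient —
identifier, acquisition date, labels, and an optional exclusion flag with
its reason. ``chronological_split`` reproduces the development/test
protocol (earliest 80% of patients by acquisition date form the
development set); ``summarize`` tallies class counts, percentages, and
exclusion rates. Percentages are rounded half-up to 1 decimal place.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

__all__ = ["ManifestRow", "CohortManifest", "chronological_split",
           "summarize", "round_half_up", "read_manifest", "write_manifest",
           "write_summary"]

MANIFEST_COLUMNS = ("patient_id", "acquisition_date", "size_label",
                    "territory_label", "excluded", "exclusion_reason")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the printed-table convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ManifestRow:
    patient_id: str
    acquisition_date: date
    size_label: str = ""
    territory_label: str = ""
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.excluded and not self.exclusion_reason:
            raise ValueError(
                f"excluded patient {self.patient_id!r} has no exclusion reason")


@dataclass
class CohortManifest:
    """Screened-cohort roster; one row per patient, unique ids."""

    rows: list[ManifestRow] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.patient_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")

    @property
    def included(self) -> list[ManifestRow]:
        return [r for r in self.rows if not r.excluded]

    @property
    def excluded_rows(self) -> list[ManifestRow]:
        return [r for r in self.rows if r.excluded]


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"unparseable acquisition date: {value!r}") from exc


def chronological_split(manifest: CohortManifest, dev_fraction: float = 0.8
                        ) -> tuple[list[str], list[str]]:
    """Split included patients by acquisition date.

    The earliest ``ceil(N * dev_fraction)`` patients form the development
    set; the remainder are the test set. Ties in date are broken by
    patient id, so the split is deterministic.
    """
    if not 0.0 < dev_fraction < 1.0:
        raise ValueError("dev_fraction must lie in (0, 1)")
    rows = manifest.included
    ordered = sorted(rows, key=lambda r: (r.acquisition_date, r.patient_id))
    n = len(ordered)
    n_dev = math.ceil(n * dev_fraction)
    dev = [r.patient_id for r in ordered[:n_dev]]
    test = [r.patient_id for r in ordered[n_dev:]]
    return dev, test


def _ratio_table(labels: list[str]) -> list[dict]:
    total = len(labels)
    out = []
    for lab in sorted(set(labels)):
        n = labels.count(lab)
        out.append({"label": lab, "count": n,
                    "percent": round_half_up(100.0 * n / total)})
    return out


def summarize(manifest: CohortManifest,
              split: tuple[list[str], list[str]] | None = None) -> dict:
    """Class counts/percentages and exclusion tallies.

    Returns a dict with ``screened``, ``excluded`` (count, percent of
    screened, per-reason tallies), ``included``, per-label ratio tables,
    and — when ``split`` is given — the same tables per split. An empty
    manifest yields zero counts and empty tables.
    """
    screened = len(manifest.rows)
    excl = manifest.excluded_rows
    incl = manifest.included
    reasons: dict[str, int] = {}
    for r in excl:
        reasons[r.exclusion_reason] = reasons.get(r.exclusion_reason, 0) + 1
    summary = {
        "screened": screened,
        "excluded": {
            "count": len(excl),
            "percent_of_screened": (round_half_up(100.0 * len(excl) / screened)
                                    if screened else 0.0),
            "by_reason": reasons,
        },
        "included": len(incl),
        "size": _ratio_table([r.size_label for r in incl if r.size_label]),
        "territory": _ratio_table(
            [r.territory_label for r in incl if r.territory_label]),
    }
    if split is not None:
        dev_ids, test_ids = split
        by_id = {r.patient_id: r for r in incl}
        for name, ids in (("development", dev_ids), ("test", test_ids)):
            rows = [by_id[i] for i in ids if i in by_id]
            summary[name] = {
                "count": len(rows),
                "size": _ratio_table([r.size_label for r in rows
                                      if r.size_label]),
                "territory": _ratio_table([r.territory_label for r in rows
                                           if r.territory_label]),
            }
    return summary


# ---------------------------------------------------------------------------
# I/O: manifest as TSV; summary as TSV + JSON
# ---------------------------------------------------------------------------

def write_manifest(manifest: CohortManifest, path) -> None:
    frame = pd.DataFrame(
        [{"patient_id": r.patient_id,
          "acquisition_date": r.acquisition_date.isoformat(),
          "size_label": r.size_label,
          "territory_label": r.territory_label,
          "excluded": int(r.excluded),
          "exclusion_reason": r.exclusion_reason} for r in manifest.rows],
        columns=list(MANIFEST_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    rows = [ManifestRow(patient_id=rec.patient_id,
                        acquisition_date=_parse_date(rec.acquisition_date),
                        size_label=rec.size_label,
                        territory_label=rec.territory_label,
                        excluded=bool(int(rec.excluded or 0)),
                        exclusion_reason=rec.exclusion_reason)
            for rec in frame.itertuples()]
    return CohortManifest(rows)


def write_summary(summary: dict, tsv_path, json_path) -> None:
    """Flatten the summary into a long-format TSV and a JSON document."""
    records = [
        {"section": "cohort", "label": "screened",
         "count": summary["screened"], "percent": ""},
        {"section": "cohort", "label": "excluded",
         "count": summary["excluded"]["count"],
         "percent": summary["excluded"]["percent_of_screened"]},
        {"section": "cohort", "label": "included",
         "count": summary["included"], "percent": ""},
    ]
    for reason, n in sorted(summary["excluded"]["by_reason"].items()):
        records.append({"section": "exclusion_reason", "label": reason,
                        "count": n, "percent": ""})
    for section in ("size", "territory"):
        for row in summary[section]:
            records.append({"section": section, "label": row["label"],
                            "count": row["count"], "percent": row["percent"]})
    for split_name in ("development", "test"):
        if split_name in summary:
            block = summary[split_name]
            records.append({"section": split_name, "label": "count",
                            "count": block["count"], "percent": ""})
            for section in ("size", "territory"):
                for row in block[section]:
                    records.append({"section": f"{split_name}.{section}",
                                    "label": row["label"],
                                    "count": row["count"],
                                    "percent": row["percent"]})
    pd.DataFrame(records).to_csv(tsv_path, sep="\t", index=False)
    Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")
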