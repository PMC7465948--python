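"""Per-compound aggregation of match factors and study-level totals.

Each compound's identifications across replicate analyses are collapsed
into an average match factor (AMF) and average reverse match factor (ARMF),
both rounded half-up to integers, plus the number of positive hits. Study
totals average the per-compound AMF/ARMF over all compounds with at least
one hit; the ARMF-AMF difference is computed on the unrounded means and
rounded only at the end (rounding the two totals first can shift the
difference by one unit).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "Hit",
    "CompoundReport",
    "StudySummary",
    "aggregate_compound",
    "summarize_study",
    "export_report",
    "load_reference_table",
    "reference_reports",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Hit:
    analysis_id: str
    mf: int
    rmf: int


@dataclass
class CompoundReport:
    compound: str
    hits: list  # list[Hit]
    expected_rt: float | None = None

    @property
    def n_positive(self) -> int:
        return len(self.hits)

    @property
    def amf(self) -> int | None:
        if not self.hits:
            return None
        return _round_half_up(sum(h.mf for h in self.hits) / len(self.hits))

    @property
    def armf(self) -> int | None:
        if not self.hits:
            return None
        return _round_half_up(sum(h.rmf for h in self.hits) / len(self.hits))


@dataclass
class StudySummary:
    total_amf: int
    total_armf: int
    armf_amf_difference: int
    min_amf: int
    n_compounds: int
    share_amf_above_threshold: float
    threshold: int = 800


def aggregate_compound(compound: str, hits, expected_rt: float | None = None
                       ) -> CompoundReport:
    """Collapse one compound's hits across analyses into a report row."""
    hits = [h if isinstance(h, Hit) else Hit(*h) for h in hits]
    return CompoundReport(compound=compound, hits=hits, expected_rt=expected_rt)


def summarize_study(reports, threshold: int = 800) -> StudySummary:
    """Study-level totals over all compounds with at least one hit.

    The ARMF-AMF difference is taken on the unrounded means of the
    per-compound integers and rounded last.
    """
    identified = [r for r in reports if r.n_positive >= 1]
    if not identified:
        raise ValueError("no identifiable compounds: every report has zero hits")
    amfs = [r.amf for r in identified]
    armfs = [r.armf for r in identified]
    mean_amf = sum(amfs) / len(amfs)
    mean_armf = sum(armfs) / len(armfs)
    return StudySummary(
        total_amf=_round_half_up(mean_amf),
        total_armf=_round_half_up(mean_armf),
        armf_amf_difference=_round_half_up(mean_armf - mean_amf),
        min_amf=min(amfs),
        n_compounds=len(identified),
        share_amf_above_threshold=sum(a > threshold for a in amfs) / len(amfs),
        threshold=threshold,
    )


def export_report(reports, summary: StudySummary | None, path,
                  fmt: str = "csv") -> None:
    """Write the compound table (and summary) as CSV or XLSX.

    Columns: No, Compound, RT [min], AMF, ARMF, Hits. The summary goes to a
    second sheet (XLSX) or trailing comment-style rows (CSV).
    """
    rows = [
        {
            "No": i + 1,
            "Compound": r.compound,
            "RT [min]": r.expected_rt,
            "AMF": r.amf,
            "ARMF": r.armf,
            "Hits": r.n_positive,
        }
        for i, r in enumerate(reports)
    ]
    frame = pd.DataFrame(
        rows, columns=["No", "Compound", "RT [min]", "AMF", "ARMF", "Hits"]
    )
    summary_rows = []
    if summary is not None:
        summary_rows = [
            ("total_amf", summary.total_amf),
            ("total_armf", summary.total_armf),
            ("armf_amf_difference", summary.armf_amf_difference),
            ("min_amf", summary.min_amf),
            ("n_compounds", summary.n_compounds),
            (f"share_amf_above_{summary.threshold}",
             summary.share_amf_above_threshold),
        ]
    if fmt == "csv":
        frame.to_csv(path, index=False)
        if summary_rows:
            with open(path, "a", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow([])
                writer.writerow(["summary_statistic", "value"])
                writer.writerows(summary_rows)
    elif fmt == "xlsx":
        with pd.ExcelWriter(path) as writer:
            frame.to_excel(writer, sheet_name="compounds", index=False)
            if summary_rows:
                pd.DataFrame(summary_rows,
                             columns=["summary_statistic", "value"]).to_excel(
                    writer, sheet_name="summary", index=False
                )
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'xlsx'")


def load_reference_table():
    """Load the bundled published AMF/ARMF reference table.

    Returns a DataFrame with per-compound AMF, ARMF and hit counts for a
    40-compound standard mixture and pooled real-sample analyses, used as an
    aggregation fixture: its column means reproduce the published study
    totals.
    """
    ref = resources.files("chromdecon.data") / "reference_match_factors.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def reference_reports(table: pd.DataFrame, which: str = "std") -> list:
    """Reference rows as single-hit CompoundReports carrying AMF/ARMF.

    Each published row already is an average over replicates; representing
    it as one hit with mf = AMF and rmf = ARMF makes summarize_study's
    per-compound means coincide with the published per-compound values.
    """
    if which not in ("std", "real"):
        raise ValueError("which must be 'std' or 'real'")
    reports = []
    for _, row in table.iterrows():
        if which == "std":
            n_hits = int(row["std_n"])
        else:
            n_hits = int(row["s1_n"]) + int(row["s2_n"]) + int(row["s3_n"])
        hits = (
            [Hit("pooled", int(row[f"{which}_amf"]), int(row[f"{which}_armf"]))]
            if n_hits >= 1
            else []
        )
        reports.append(
            CompoundReport(
                compound=str(row["compound"]),
                hits=hits,
                expected_rt=float(row["rt_min"]),
            )
        )
    return reports
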