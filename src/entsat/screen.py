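"""Batch saturation screening of per-locus alignments.

Each locus passes through two empirical filters before the test runs: a
minimum number of parsimony-informative sites (default 30) and a cap on the
largest nucleotide frequency (default 0.5, evaluated on the informative-site
composition the test itself uses). Loci failing a filter — or failing to
parse — are reported as ``not_testable`` with a reason rather than silently
excluded, so the report always has one row per input locus.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .align import base_frequencies, informative_mask, read_alignment
from .entropy import INFORMATIVE_SITES, run_saturation_test
from .errors import EntsatError

__all__ = ["LocusReport", "screen_loci", "write_report", "read_report"]

REPORT_COLUMNS = [
    "locus_id",
    "n_taxa",
    "n_sites",
    "n_informative",
    "max_base_freq",
    "t_obs_inf",
    "t_crit",
    "decision",
    "not_testable_reason",
    "expected_fpr",
    "expected_tpr",
]


@dataclass
class LocusReport:
    """Screening outcome for one locus."""

    locus_id: str
    n_taxa: int | None = None
    n_sites: int | None = None
    n_informative: int | None = None
    max_base_freq: float | None = None
    t_obs_inf: float | None = None
    t_crit: float | None = None
    decision: str = "not_testable"
    not_testable_reason: str = ""
    expected_fpr: float | None = None
    expected_tpr: float | None = None


def screen_locus(
    path: str,
    crit,
    min_informative: int = 30,
    max_freq: float = 0.5,
    format: str = "auto",
) -> LocusReport:
    """Apply the empirical filters, then the informative-sites test."""
    locus_id = os.path.splitext(os.path.basename(str(path)))[0]
    report = LocusReport(locus_id=locus_id)
    try:
        aln = read_alignment(str(path), format=format)
    except (EntsatError, OSError) as exc:
        report.not_testable_reason = f"unreadable: {type(exc).__name__}: {exc}"
        return report
    report.n_taxa = aln.n_taxa
    report.n_sites = aln.n_sites
    mask = informative_mask(aln)
    report.n_informative = int(mask.sum())
    if report.n_informative < min_informative:
        report.not_testable_reason = (
            f"min_informative: {report.n_informative} < {min_informative}"
        )
        return report
    comp = base_frequencies(aln, mask=mask)
    report.max_base_freq = float(np.max(comp.p))
    if report.max_base_freq > max_freq:
        report.not_testable_reason = (
            f"max_freq: {report.max_base_freq:.3f} > {max_freq}"
        )
        return report
    try:
        result = run_saturation_test(aln, mode=INFORMATIVE_SITES, crit=crit)
    except EntsatError as exc:
        report.not_testable_reason = f"test: {type(exc).__name__}: {exc}"
        return report
    report.t_obs_inf = result.t_obs
    report.t_crit = result.t_crit
    report.decision = result.decision or "not_testable"
    report.expected_fpr = result.expected_fpr
    report.expected_tpr = result.expected_tpr
    return report


def screen_loci(
    paths,
    crit,
    min_informative: int = 30,
    max_freq: float = 0.5,
    format: str = "auto",
) -> list[LocusReport]:
    """Screen a batch of alignment files; one report per input, input order.

    A corrupt or unreadable file yields a ``not_testable`` row and never
    aborts the batch.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("no alignment files given")
    return [
        screen_locus(p, crit, min_informative, max_freq, format) for p in paths
    ]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def report_lines(reports: list[LocusReport]) -> list[str]:
    """TSV lines (header first) for a list of locus reports."""
    if not reports:
        raise ValueError("empty report list")
    lines = ["\t".join(REPORT_COLUMNS)]
    for rep in reports:
        lines.append("\t".join(_fmt(getattr(rep, col)) for col in REPORT_COLUMNS))
    return lines


def write_report(reports: list[LocusReport], path: str) -> None:
    """Write a TSV report, one row per locus, fixed column order."""
    with open(path, "w") as fh:
        fh.write("\n".join(report_lines(reports)) + "\n")


def read_report(path: str) -> list[LocusReport]:
    """Parse a report written by :func:`write_report`."""
    reports = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != REPORT_COLUMNS:
            raise ValueError("unrecognized report header")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(REPORT_COLUMNS, vals))
            reports.append(
                LocusReport(
                    locus_id=row["locus_id"],
                    n_taxa=int(row["n_taxa"]) if row["n_taxa"] else None,
                    n_sites=int(row["n_sites"]) if row["n_sites"] else None,
                    n_informative=(
                        int(row["n_informative"]) if row["n_informative"] else None
                    ),
                    max_base_freq=(
                        float(row["max_base_freq"]) if row["max_base_freq"] else None
                    ),
                    t_obs_inf=float(row["t_obs_inf"]) if row["t_obs_inf"] else None,
                    t_crit=float(row["t_crit"]) if row["t_crit"] else None,
                    decision=row["decision"],
                    not_testable_reason=row["not_testable_reason"],
                    expected_fpr=(
                        float(row["expected_fpr"]) if row["expected_fpr"] else None
                    ),
                    expected_tpr=(
                        float(row["expected_tpr"]) if row["expected_tpr"] else None
                    ),
                )
            )
    return reports
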