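"""Plain-text results report: writer and parser.

The exported ``*.txt`` report is the tool's interchange format for further
statistical work: a tab-separated row block (``#  Filename  Ratio (%)  CS``)
followed by a fixed footer of cohort statistics.  Numbers are rounded to
two decimals with halves away from zero, and trailing zeros (and a bare
decimal point) are trimmed, so ``18.5``, ``21.2`` and ``12.71`` coexist.
The parser reads the same dialect back, turning ``n/a`` fields into
``None``, and round-trips bit-exactly.
"""

from __future__ import annotations

import re

from .cohort_stats import CohortReport, round_half_away
from .errors import ReportFormatError

HEADER = "#\tFilename\tRatio (%)\tCS"

_FOOTER_LABELS = (
    "CS threshold",
    "Total number of pictures",
    "Number of pictures with CS",
    "Mean picture ratio",
    "Mean picture with CS ratio",
    "Mean picture without CS ratio",
    "SD picture ratio",
    "SD picture with CS ratio",
    "SD picture without CS ratio",
    "Frequency distribution of the whole picture set",
    "Frequency distribution of the CS picture set",
    "Frequency distribution of the non-CS picture set",
)


def format_number(value: float | None) -> str:
    """Two-decimal rounding (half away from zero), trailing zeros trimmed.

    ``None`` renders as ``n/a``.
    """
    if value is None:
        return "n/a"
    text = f"{round_half_away(value, 2):.2f}"
    return text.rstrip("0").rstrip(".")


def _format_freq(pair: tuple[int, int] | None) -> str:
    if pair is None:
        return "n/a"
    return f"{pair[0]}/{pair[1]}"


def format_report(report: CohortReport) -> list[str]:
    """Render a report as its list of text lines."""
    lines = [HEADER]
    for index, filename, ratio, flag in report.rows:
        lines.append(
            f"{index}\t{filename}\t{format_number(ratio)}\t{flag}"
        )
    lines += [
        f"CS threshold = {format_number(report.threshold_percent)}%",
        f"Total number of pictures = {report.n_total}",
        (
            f"Number of pictures with CS = {report.n_cs} "
            f"({format_number(report.cs_percent)}%)"
        ),
        f"Mean picture ratio = {format_number(report.mean_all)}",
        f"Mean picture with CS ratio = {format_number(report.mean_cs)}",
        f"Mean picture without CS ratio = {format_number(report.mean_non_cs)}",
        f"SD picture ratio = {format_number(report.sd_all)}",
        f"SD picture with CS ratio = {format_number(report.sd_cs)}",
        f"SD picture without CS ratio = {format_number(report.sd_non_cs)}",
        (
            "Frequency distribution of the whole picture set = "
            f"{_format_freq(report.freq_all)}"
        ),
        (
            "Frequency distribution of the CS picture set = "
            f"{_format_freq(report.freq_cs)}"
        ),
        (
            "Frequency distribution of the non-CS picture set = "
            f"{_format_freq(report.freq_non_cs)}"
        ),
    ]
    return lines


def write_report(report: CohortReport, path) -> list[str]:
    """Write the report to ``path`` (UTF-8, LF) and return its lines."""
    lines = format_report(report)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return lines


def _parse_number(text: str, lineno: int) -> float | None:
    if text == "n/a":
        return None
    try:
        return float(text)
    except ValueError:
        raise ReportFormatError(
            f"line {lineno}: expected a number or 'n/a', got {text!r}"
        ) from None


def _parse_freq(text: str, lineno: int) -> tuple[int, int] | None:
    if text == "n/a":
        return None
    m = re.fullmatch(r"(\d+)/(\d+)", text)
    if not m:
        raise ReportFormatError(
            f"line {lineno}: expected 'm/n' or 'n/a', got {text!r}"
        )
    return int(m.group(1)), int(m.group(2))


def parse_report(path) -> CohortReport:
    """Read a report file back into a :class:`CohortReport`.

    Raises
    ------
    ReportFormatError
        On a malformed header, row, or footer line (with its line number).
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != HEADER:
        raise ReportFormatError(
            f"line 1: expected header {HEADER!r}, got "
            f"{lines[0]!r}" if lines else "empty report file"
        )

    rows: list[tuple[int, str, float, bool]] = []
    i = 1
    while i < len(lines) and not lines[i].startswith("CS threshold"):
        parts = lines[i].split("\t")
        if len(parts) != 4:
            raise ReportFormatError(
                f"line {i + 1}: expected 4 tab-separated fields, "
                f"got {len(parts)}"
            )
        idx_s, filename, ratio_s, flag_s = parts
        if flag_s not in ("True", "False"):
            raise ReportFormatError(
                f"line {i + 1}: CS flag must be 'True' or 'False', "
                f"got {flag_s!r}"
            )
        try:
            idx = int(idx_s)
            ratio = float(ratio_s)
        except ValueError:
            raise ReportFormatError(
                f"line {i + 1}: malformed row {lines[i]!r}"
            ) from None
        rows.append((idx, filename, ratio, flag_s == "True"))
        i += 1

    footer: dict[str, str] = {}
    for label in _FOOTER_LABELS:
        if i >= len(lines):
            raise ReportFormatError(
                f"line {i + 1}: missing footer line {label!r}"
            )
        prefix = label + " = "
        if not lines[i].startswith(prefix):
            raise ReportFormatError(
                f"line {i + 1}: expected footer line starting "
                f"{prefix!r}, got {lines[i]!r}"
            )
        footer[label] = (lines[i][len(prefix):], i + 1)
        i += 1

    thr_s, thr_ln = footer["CS threshold"]
    if not thr_s.endswith("%"):
        raise ReportFormatError(
            f"line {thr_ln}: CS threshold must end with '%', got {thr_s!r}"
        )
    threshold = _parse_number(thr_s[:-1], thr_ln)

    ntot_s, ntot_ln = footer["Total number of pictures"]
    try:
        n_total = int(ntot_s)
    except ValueError:
        raise ReportFormatError(
            f"line {ntot_ln}: expected an integer, got {ntot_s!r}"
        ) from None

    ncs_s, ncs_ln = footer["Number of pictures with CS"]
    m = re.fullmatch(r"(\d+) \(([\d.]+)%\)", ncs_s)
    if not m:
        raise ReportFormatError(
            f"line {ncs_ln}: expected 'k (p%)', got {ncs_s!r}"
        )
    n_cs, cs_percent = int(m.group(1)), float(m.group(2))

    def num(label: str) -> float | None:
        return _parse_number(*footer[label])

    def freq(label: str) -> tuple[int, int] | None:
        return _parse_freq(*footer[label])

    return CohortReport(
        rows=rows,
        threshold_percent=threshold,
        n_total=n_total,
        n_cs=n_cs,
        cs_percent=cs_percent,
        mean_all=num("Mean picture ratio"),
        mean_cs=num("Mean picture with CS ratio"),
        mean_non_cs=num("Mean picture without CS ratio"),
        sd_all=num("SD picture ratio"),
        sd_cs=num("SD picture with CS ratio"),
        sd_non_cs=num("SD picture without CS ratio"),
        freq_all=freq("Frequency distribution of the whole picture set"),
        freq_cs=freq("Frequency distribution of the CS picture set"),
        freq_non_cs=freq("Frequency distribution of the non-CS picture set"),
    )
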