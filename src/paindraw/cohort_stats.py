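"""Cohort-level statistics and central-sensitization classification.

Widespread pain — a large fraction of the body map painted — is a
recognized sign of central sensitization (CS).  The user chooses a
pain-extent threshold (in percent of body area); every drawing whose ratio
exceeds it is flagged CS.  The cohort summary mirrors the exported report
footer: group sizes, means and sample standard deviations of the ratios
over the whole set and the CS / non-CS subsets, and the per-pixel overlap
summaries from the frequency maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import EmptyCohortError
from .drawing_analysis import AnalysisResult


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round with halves away from zero (13.725 -> 13.73), unlike banker's
    rounding.  Used for every number the report prints."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortReport:
    """Everything the exported results file contains.

    ``rows`` holds ``(index, filename, ratio_percent, cs_flag)`` per image,
    in input order.  Subgroup means are ``None`` when the subgroup is
    empty, subgroup SDs when it has fewer than two members; the writer
    prints those as ``n/a``.  ``freq_*`` are ``(max_count, subset_size)``
    pairs from the frequency maps, or ``None`` when no maps were built.
    """

    rows: list[tuple[int, str, float, bool]]
    threshold_percent: float
    n_total: int
    n_cs: int
    cs_percent: float
    mean_all: float | None
    mean_cs: float | None
    mean_non_cs: float | None
    sd_all: float | None
    sd_cs: float | None
    sd_non_cs: float | None
    freq_all: tuple[int, int] | None = None
    freq_cs: tuple[int, int] | None = None
    freq_non_cs: tuple[int, int] | None = None


def classify_cs(
    ratio_percent: float, threshold_percent: float, inclusive: bool = False
) -> bool:
    """True iff the pain extent is over the CS threshold.

    The comparison is strict by default (a ratio exactly at the threshold
    is not flagged); set ``inclusive`` to flag ratios >= the threshold.
    """
    if inclusive:
        return ratio_percent >= threshold_percent
    return ratio_percent > threshold_percent


def cs_percentage(n_cs: int, n_total: int) -> float:
    """Share of CS-flagged images, as a percent rounded to 2 decimals."""
    if n_total == 0:
        raise EmptyCohortError("cannot compute a CS percentage of 0 images")
    if not 0 <= n_cs <= n_total:
        raise ValueError(f"n_cs={n_cs} out of range for n_total={n_total}")
    return round_half_away(100.0 * n_cs / n_total, 2)


def _mean(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def _sd(values: list[float]) -> float | None:
    # sample SD (n-1); undefined below two observations
    return float(np.std(values, ddof=1)) if len(values) >= 2 else None


def summarize(
    results: list[AnalysisResult],
    threshold_percent: float,
    freq_maps=None,
    inclusive: bool = False,
) -> CohortReport:
    """Build the cohort report from per-image results.

    ``freq_maps``, when given, is a triple of
    :class:`~paindraw.frequency_map.FrequencyMap` for the whole set and the
    CS / non-CS subsets; their ``(max_count, subset_size)`` summaries land
    in the report footer.  Statistics are computed on full-precision
    ratios; rounding is an export concern.
    """
    if not results:
        raise EmptyCohortError("cannot summarize an empty cohort")
    from .frequency_map import freq_summary  # local import avoids a cycle

    rows = []
    for i, res in enumerate(results, start=1):
        flag = classify_cs(res.ratio_percent, threshold_percent, inclusive)
        rows.append((i, res.filename, res.ratio_percent, flag))

    all_ratios = [r for _, _, r, _ in rows]
    cs_ratios = [r for _, _, r, f in rows if f]
    non_cs_ratios = [r for _, _, r, f in rows if not f]
    n_total = len(rows)
    n_cs = len(cs_ratios)

    freq_all = freq_cs = freq_non_cs = None
    if freq_maps is not None:
        fm_all, fm_cs, fm_non_cs = freq_maps
        freq_all = freq_summary(fm_all, n_total) if fm_all is not None else None
        freq_cs = freq_summary(fm_cs, n_cs) if fm_cs is not None else None
        freq_non_cs = (
            freq_summary(fm_non_cs, n_total - n_cs)
            if fm_non_cs is not None else None
        )

    return CohortReport(
        rows=rows,
        threshold_percent=threshold_percent,
        n_total=n_total,
        n_cs=n_cs,
        cs_percent=cs_percentage(n_cs, n_total),
        mean_all=_mean(all_ratios),
        mean_cs=_mean(cs_ratios),
        mean_non_cs=_mean(non_cs_ratios),
        sd_all=_sd(all_ratios),
        sd_cs=_sd(cs_ratios),
        sd_non_cs=_sd(non_cs_ratios),
        freq_all=freq_all,
        freq_cs=freq_cs,
        freq_non_cs=freq_non_cs,
    )
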