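"""Cross-method concordance: contingency tables and agreement percentages.

Compares category calls from two scoring methods (e.g. a reference manual
score against an automated classifier) case by case.  Overall concordance is
the percentage of cases on the diagonal of the cross-tabulation; per-class
concordance is computed on reference strata.  Cases rejected by either
method (missing category) are excluded with an explicit count, matching how
validation series drop unanalyzable specimens.

For equivocal analyses the ratio scale is binned as
``<1.8 | >=1.8 - <2.0 | 2.0 - 2.2 | >2.2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import InvalidInputError, Thresholds

__all__ = ["ConcordanceReport", "concordance", "bin_ratio", "RATIO_BINS"]

RATIO_BINS = ("<1.8", ">=1.8 - <2.0", "2.0 - 2.2", ">2.2")


@dataclass
class ConcordanceReport:
    """Cross-tabulation of reference vs test category calls."""

    table: pd.DataFrame
    overall_pct: float
    per_class_pct: dict[str, float]
    n: int
    n_excluded: int = 0

    def summary(self) -> str:
        lines = [
            f"cases compared: {self.n}"
            + (f" (excluded: {self.n_excluded})" if self.n_excluded else ""),
            f"overall concordance: {self.overall_pct:.1f}%",
        ]
        for cls, pct in self.per_class_pct.items():
            n_cls = int(self.table.loc[cls].sum())
            lines.append(f"  {cls}: {pct:.1f}% (n={n_cls})")
        lines.append("")
        lines.append(self.table.to_string())
        return "\n".join(lines)


def concordance(
    reference: list[str | None], test: list[str | None]
) -> ConcordanceReport:
    """Agreement between paired category calls.

    ``None`` entries (rejected/unanalyzable cases in either list) are
    excluded from the comparison and reported in ``n_excluded``.
    Percentages are rounded to one decimal in the summary but kept exact in
    the report fields.
    """
    if len(reference) != len(test):
        raise InvalidInputError("reference and test lists must have equal length")
    pairs = [(r, t) for r, t in zip(reference, test) if r is not None and t is not None]
    n_excluded = len(reference) - len(pairs)
    if not pairs:
        raise InvalidInputError("no comparable cases (all empty or excluded)")
    ref = [p[0] for p in pairs]
    tst = [p[1] for p in pairs]
    cats = sorted(set(ref) | set(tst))
    table = pd.crosstab(
        pd.Categorical(ref, categories=cats),
        pd.Categorical(tst, categories=cats),
        dropna=False,
    )
    table.index.name = "reference"
    table.columns.name = "test"
    n = len(pairs)
    matches = sum(r == t for r, t in pairs)
    per_class = {}
    for cls in cats:
        n_cls = sum(r == cls for r in ref)
        if n_cls:
            per_class[cls] = 100.0 * sum(r == t == cls for r, t in pairs) / n_cls
    return ConcordanceReport(
        table=table,
        overall_pct=100.0 * matches / n,
        per_class_pct=per_class,
        n=n,
        n_excluded=n_excluded,
    )


def bin_ratio(ratio: float, thresholds: Thresholds = Thresholds()) -> str:
    """Assign a HER2/CEP17 ratio to its reporting bin.

    The four bins partition [0, inf): below the nonamplified cut-off, the
    lower equivocal half-band, the eligibility band (2.0–2.2 inclusive), and
    above the amplified cut-off.
    """
    ratio = float(ratio)
    if not (ratio >= 0 and ratio == ratio and ratio != float("inf")):
        raise InvalidInputError(f"ratio must be finite and >= 0, got {ratio!r}")
    if ratio < thresholds.nonamp_below:
        return RATIO_BINS[0]
    if ratio < thresholds.eligibility_at:
        return RATIO_BINS[1]
    if ratio <= thresholds.amp_above:
        return RATIO_BINS[2]
    return RATIO_BINS[3]
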