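"""Relative quantification of qRT-PCR data by the 2^-dCt method.

For single-embryo expression measurements, each embryo contributes
replicate Ct values (typically triplicates) for a target gene and a
housekeeping reference (default eef1a1l1). The per-embryo dCt is the
mean target Ct minus the mean housekeeping Ct, and the relative
expression level is 2^-dCt — a ratio to the reference gene. Group
comparison is a two-tailed t-test, by default on the dCt scale (where
the normality assumption is usually more reasonable than on the
exponentiated level scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, summarize, welch_t, pooled_t_from_summaries, levene

__all__ = [
    "CtRecord",
    "RelativeExpression",
    "DEFAULT_HOUSEKEEPING",
    "delta_ct",
    "relative_level",
    "delta_ct_table",
    "compare_groups",
]

DEFAULT_HOUSEKEEPING = "eef1a1l1"

# Replicate spread above this many cycles is suspicious (pipetting error);
# warn, never drop — no outlier handling by default.
REPLICATE_SPREAD_WARN = 0.5


@dataclass(frozen=True)
class CtRecord:
    """Replicate Ct values of one gene in one embryo."""

    embryo_id: str
    gene: str
    cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.cts:
            raise ValueError("need at least one Ct replicate")
        if any(ct <= 0 for ct in self.cts):
            raise ValueError("Ct values must be positive")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.cts))

    @property
    def spread(self) -> float:
        return max(self.cts) - min(self.cts)


@dataclass(frozen=True)
class RelativeExpression:
    """Per-embryo dCt and 2^-dCt level."""

    embryo_id: str
    delta_ct: float

    @property
    def level(self) -> float:
        return 2.0 ** (-self.delta_ct)


def delta_ct(target: CtRecord, housekeeping: CtRecord) -> float:
    """dCt = mean(target Ct) - mean(housekeeping Ct) for one embryo."""
    if target.embryo_id != housekeeping.embryo_id:
        raise ValueError(
            f"records belong to different embryos: "
            f"{target.embryo_id!r} vs {housekeeping.embryo_id!r}"
        )
    return target.mean_ct - housekeeping.mean_ct


def relative_level(dct: float) -> float:
    """Expression relative to the housekeeping gene: 2^-dCt."""
    return 2.0 ** (-dct)


def delta_ct_table(
    ct_frame: pd.DataFrame,
    target_gene: str,
    housekeeping_gene: str = DEFAULT_HOUSEKEEPING,
) -> pd.DataFrame:
    """Per-embryo dCt and relative level from a long Ct table.

    ``ct_frame`` columns: embryo_id, gene, then one or more replicate
    columns named ct1, ct2, ... Embryos missing either gene are dropped.
    Extra columns (e.g. a group label) are carried through.
    """
    ct_cols = [c for c in ct_frame.columns if c.startswith("ct")]
    if not ct_cols:
        raise ValueError("no replicate columns (ct1, ct2, ...) found")
    rows = []
    for embryo_id, sub in ct_frame.groupby("embryo_id", sort=False):
        genes = dict(zip(sub["gene"], sub.index))
        if target_gene not in genes or housekeeping_gene not in genes:
            continue
        t_row = sub.loc[genes[target_gene]]
        h_row = sub.loc[genes[housekeeping_gene]]
        rec_t = CtRecord(
            str(embryo_id), target_gene,
            tuple(float(t_row[c]) for c in ct_cols if pd.notna(t_row[c])),
        )
        rec_h = CtRecord(
            str(embryo_id), housekeeping_gene,
            tuple(float(h_row[c]) for c in ct_cols if pd.notna(h_row[c])),
        )
        dct = delta_ct(rec_t, rec_h)
        row = {
            "embryo_id": str(embryo_id),
            "delta_ct": dct,
            "rel_level": relative_level(dct),
        }
        for extra in ct_frame.columns:
            if extra not in ("embryo_id", "gene", *ct_cols):
                row[extra] = t_row[extra]
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    group_a: Iterable[float],
    group_b: Iterable[float],
    on_scale: str = "delta_ct",
    welch: bool = False,
    labels: tuple[str, str] = ("A", "B"),
) -> dict:
    """Two-tailed t-test between two groups of per-embryo dCt values.

    The test runs on the chosen scale (default dCt; pass
    ``on_scale='level'`` to exponentiate first). The fold change and
    percent change of B relative to A are reported on the 2^-dCt scale
    under both conventions — from group-mean dCts and from per-embryo mean
    levels — because the two differ whenever levels are skewed and
    published percentages rarely say which was used.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if on_scale not in ("delta_ct", "level"):
        raise ValueError("on_scale must be 'delta_ct' or 'level'")
    xa, xb = (a, b) if on_scale == "delta_ct" else (2.0**-a, 2.0**-b)
    sa, sb = summarize(xa, labels[0]), summarize(xb, labels[1])
    test = welch_t(sa, sb) if welch else pooled_t_from_summaries(sa, sb)

    # Convention 1: ratio of levels implied by the group-mean dCts.
    ratio_mean_dct = 2.0 ** (-(b.mean() - a.mean()))
    # Convention 2: ratio of per-embryo mean levels.
    ratio_mean_level = float((2.0**-b).mean() / (2.0**-a).mean())
    return {
        "test": test,
        "levene": levene([xa, xb]),
        "fold_change_group_mean_dct": ratio_mean_dct,
        "percent_change_group_mean_dct": 100.0 * (ratio_mean_dct - 1.0),
        "fold_change_mean_levels": ratio_mean_level,
        "percent_change_mean_levels": 100.0 * (ratio_mean_level - 1.0),
    }
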