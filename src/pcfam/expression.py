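"""Relative expression by 2^-ddCt, anthocyanin units, ANOVA + Tukey letters.

Replicates are averaged on the Ct scale before ddCt by default (a
``per_replicate`` option computes per-replicate folds with mean +- SE to
mirror error bars). The calibrator sample's fold change is exactly 1 by
construction. One-way ANOVA and Tukey HSD (Tukey-Kramer for unbalanced
designs) come from scipy, with a greedy compact letter display assigned
from the largest group mean downward.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnthocyaninSample",
    "delta_delta_ct",
    "anthocyanin_units",
    "anthocyanin_table",
    "anova_tukey",
]

_CT_COLUMNS = ["gene_id", "sample_id", "replicate", "ct_target", "ct_reference"]


def _validate_ct(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s) {missing}")
    bad = records[
        (records.ct_target <= 0)
        | (records.ct_target >= 45)
        | (records.ct_reference <= 0)
        | (records.ct_reference >= 45)
    ]
    if len(bad):
        raise ValueError("Ct values must lie in (0, 45)")
    return records


def delta_delta_ct(
    records: pd.DataFrame, calibrator: str, per_replicate: bool = False
) -> pd.DataFrame:
    """2^-ddCt fold-change table, genes as rows and samples as columns.

    dCt = mean(ct_target) - mean(ct_reference) per (gene, sample);
    ddCt = dCt_sample - dCt_calibrator; fold = 2^-ddCt. With
    ``per_replicate`` the result is long-form with per-replicate folds and
    mean +- SE per (gene, sample).
    """
    records = _validate_ct(records)
    dct = (
        records.groupby(["gene_id", "sample_id"])
        .apply(
            lambda g: g.ct_target.mean() - g.ct_reference.mean(),
            include_groups=False,
        )
        .rename("dct")
        .reset_index()
    )
    cal = dct[dct.sample_id == calibrator].set_index("gene_id").dct
    missing = set(dct.gene_id) - set(cal.index)
    if missing:
        raise ValueError(
            f"calibrator {calibrator!r} missing for gene(s): {sorted(missing)}"
        )
    if not per_replicate:
        dct["fold"] = 2.0 ** -(dct.dct - dct.gene_id.map(cal))
        wide = dct.pivot(index="gene_id", columns="sample_id", values="fold")
        wide[calibrator] = 1.0  # exact by convention
        return wide

    # per-replicate folds against the replicate-averaged calibrator dCt
    rec = records.copy()
    rec["dct_rep"] = rec.ct_target - rec.ct_reference
    rec["fold"] = 2.0 ** -(rec.dct_rep - rec.gene_id.map(cal))
    out = (
        rec.groupby(["gene_id", "sample_id"])
        .fold.agg(["mean", "sem", list])
        .rename(columns={"list": "replicate_folds"})
        .reset_index()
    )
    return out


@dataclass
class AnthocyaninSample:
    sample_id: str
    od530: float
    od600: float
    mass: float  # grams fresh weight

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"{self.sample_id}: mass must be positive")
        if self.od530 < 0 or self.od600 < 0:
            raise ValueError(f"{self.sample_id}: absorbances must be >= 0")


def anthocyanin_units(s: AnthocyaninSample) -> tuple[float, bool]:
    """U = (OD530 - OD600) / gFW; a negative U is returned but flagged
    (blank-subtraction artifact)."""
    u = (s.od530 - s.od600) / s.mass
    return u, u < 0


def anthocyanin_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Batch U computation from columns sample_id, od530, od600, mass_g."""
    rows = []
    for _, r in samples.iterrows():
        s = AnthocyaninSample(str(r.sample_id), r.od530, r.od600, r.mass_g)
        u, flagged = anthocyanin_units(s)
        rows.append({"sample_id": s.sample_id, "anthocyanin_u": u, "negative_flag": flagged})
    return pd.DataFrame(rows)


def _compact_letters(
    groups: list[str],
    means: dict[str, float],
    significant: set[frozenset[str]],
) -> dict[str, str]:
    """Greedy compact letter display from the largest mean downward.

    Guarantees: groups sharing a letter are never significantly different;
    every non-significant pair shares at least one letter.
    """
    ordered = sorted(groups, key=lambda g: -means[g])
    letter_sets: list[set[str]] = []
    for g in ordered:
        placed = False
        for ls in letter_sets:
            if all(frozenset((g, other)) not in significant for other in ls):
                ls.add(g)
                placed = True
        if not placed:
            new = {g}
            # absorb earlier groups compatible with the new class
            for other in ordered:
                if other == g:
                    continue
                if all(frozenset((other, m)) not in significant for m in new):
                    new.add(other)
            letter_sets.append(new)
    # completeness sweep: any non-significant pair must share a letter
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if frozenset((a, b)) in significant:
                continue
            if not any(a in ls and b in ls for ls in letter_sets):
                new = {a, b}
                for other in ordered:
                    if other in new:
                        continue
                    if all(frozenset((other, m)) not in significant for m in new):
                        new.add(other)
                letter_sets.append(new)
    labels = {g: "" for g in groups}
    for letter, ls in zip(string.ascii_lowercase, letter_sets):
        for g in ordered:
            if g in ls:
                labels[g] += letter
    return labels


def anova_tukey(
    values: dict[str, list[float]], alpha: float = 0.05
) -> tuple[float, float, dict[str, str]]:
    """One-way ANOVA plus Tukey HSD compact letter display.

    ``values`` maps group name to replicate measurements. Returns
    (F statistic, p-value, per-group letters); groups sharing a letter are
    not significantly different at ``alpha``.
    """
    names = list(values)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(values[g], dtype=float) for g in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("need at least 2 replicates per group")
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0:
        raise ValueError("zero within-group variance: ANOVA undefined")
    f_stat, p_value = stats.f_oneway(*arrays)

    tk = stats.tukey_hsd(*arrays)
    significant: set[frozenset[str]] = set()
    for i, j in combinations(range(len(names)), 2):
        if tk.pvalue[i, j] < alpha:
            significant.add(frozenset((names[i], names[j])))
    means = {g: float(np.mean(values[g])) for g in names}
    letters = _compact_letters(names, means, significant)
    return float(f_stat), float(p_value), letters
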