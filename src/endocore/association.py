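"""Compound statistics and microbe-metabolite association.

Group comparisons follow the usual phytochemistry workflow: Shapiro-Wilk
on the one-way ANOVA residuals, a natural-log transform when normality is
rejected at 0.05, then ANOVA with Tukey HSD pairwise letters.  The
association matrix is per-(taxon, compound) Spearman rho on per-sample
relative abundance versus content, starred at raw p < 0.05 (*) and
p < 0.01 (**) without multiplicity correction (BH optional).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, CompoundTable, SampleMetadata, relative_abundance

EXACT_PERM_MAX_N = 9  # exact permutation p up to 9 samples, t approximation beyond


@dataclass
class GroupComparison:
    """Per-compound ANOVA summary with Tukey compact-letter display."""

    means: pd.DataFrame        # group x compound means
    sems: pd.DataFrame         # group x compound standard errors
    anova: pd.DataFrame        # compound x (F, p, transform_applied)
    letters: pd.DataFrame      # group x compound Tukey letters


def _tukey_letters(groups: list[str], not_different: set[frozenset]) -> dict[str, str]:
    """Compact letter display via the insert-absorb algorithm: groups that
    are not significantly different share at least one letter."""
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if frozenset((a, b)) in not_different:
            continue
        new_sets: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend(({x for x in s if x != b}, {x for x in s if x != a}))
            else:
                new_sets.append(s)
        # absorb subsets
        letter_sets = [
            s for s in new_sets
            if not any(s < t for t in new_sets)
        ]
        deduped = []
        for s in letter_sets:
            if s not in deduped:
                deduped.append(s)
        letter_sets = deduped
    letter_sets.sort(key=lambda s: sorted(groups.index(g) for g in s))
    out = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", letter_sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def compare_groups(
    compounds: CompoundTable, metadata: SampleMetadata, alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA + Tukey HSD per compound, ln-transforming when the
    Shapiro-Wilk test rejects residual normality at ``alpha``."""
    groups = metadata.groups_for(compounds.sample_ids)
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")

    means, sems, anova_rows, letter_rows = {}, {}, {}, {}
    for compound in compounds.compound_ids:
        values = compounds.values[compound]
        samples = [values[groups.index[groups == g]].to_numpy() for g in labels]
        resid = np.concatenate([s - s.mean() for s in samples])
        transform = "none"
        if resid.std() > 0 and stats.shapiro(resid).pvalue < alpha:
            if (values <= 0).any():
                raise ValueError(
                    f"{compound}: non-positive values; ln transform impossible "
                    "(add an offset before comparison)"
                )
            samples = [np.log(s) for s in samples]
            transform = "ln"
        if all(s.std() == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            f_stat, p_val = 0.0, 1.0
            nd = {frozenset(p) for p in itertools.combinations(labels, 2)}
        else:
            f_stat, p_val = stats.f_oneway(*samples)
            hsd = stats.tukey_hsd(*samples)
            nd = {
                frozenset((labels[i], labels[j]))
                for i, j in itertools.combinations(range(len(labels)), 2)
                if hsd.pvalue[i, j] >= alpha
            }
        means[compound] = {g: s.mean() for g, s in zip(labels, (compounds.values[compound][groups.index[groups == g]].to_numpy() for g in labels))}
        sems[compound] = {
            g: compounds.values[compound][groups.index[groups == g]].sem()
            for g in labels
        }
        anova_rows[compound] = {"F": float(f_stat), "p": float(p_val), "transform_applied": transform}
        letter_rows[compound] = _tukey_letters(labels, nd)

    return GroupComparison(
        means=pd.DataFrame(means).loc[labels],
        sems=pd.DataFrame(sems).loc[labels],
        anova=pd.DataFrame.from_dict(anova_rows, orient="index"),
        letters=pd.DataFrame(letter_rows).loc[labels],
    )


def fold_change(
    compounds: CompoundTable,
    metadata: SampleMetadata,
    compound: str,
    group_a: str,
    group_b: str,
) -> tuple[float, float]:
    """Ratio of group means mean(a)/mean(b); returns (full precision,
    rounded to 1 d.p.).  NaN when the denominator mean is zero."""
    groups = metadata.groups_for(compounds.sample_ids)
    for g in (group_a, group_b):
        if g not in set(groups):
            raise ValueError(f"group {g!r} not present")
    values = compounds.values[compound]
    num = values[groups.index[groups == group_a]].mean()
    den = values[groups.index[groups == group_b]].mean()
    if den == 0:
        return float("nan"), float("nan")
    ratio = float(num / den)
    return ratio, round(ratio, 1)


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho with two-sided p: exact permutation p over all label
    permutations when n <= 9, t approximation otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERM_MAX_N:
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        perm_c = perms - ry.mean()
        denom = math.sqrt((rx_c**2).sum() * ((ry - ry.mean()) ** 2).sum())
        rhos = perm_c @ rx_c / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def _star(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def core_compound_spearman(
    table: AbundanceTable,
    compounds: CompoundTable,
    core_taxa: list[str],
    fdr: bool = False,
) -> pd.DataFrame:
    """Association matrix: rows core taxa, columns compounds, cells
    (rho, p, star).  Returned long-form with columns taxon, compound,
    rho, p, star (plus p_adjusted under ``fdr``)."""
    unmatched = sorted(
        set(table.sample_ids).symmetric_difference(compounds.sample_ids)
    )
    if unmatched:
        raise ValueError(f"sample ids do not match between tables: {unmatched}")
    if len(table.sample_ids) < 4:
        raise ValueError("association needs at least 4 samples")
    missing = [t for t in core_taxa if t not in table.taxon_ids]
    if missing:
        raise ValueError(f"core taxa absent from abundance table: {missing}")
    rel = relative_abundance(table)
    comp_vals = compounds.values.loc[table.sample_ids]
    rows = []
    for taxon in core_taxa:
        for compound in compounds.compound_ids:
            rho, p = spearman_with_p(rel[taxon], comp_vals[compound])
            rows.append({"taxon": taxon, "compound": compound, "rho": rho, "p": p})
    frame = pd.DataFrame(rows)
    if fdr:
        ok = frame["p"].notna()
        frame["p_adjusted"] = np.nan
        frame.loc[ok, "p_adjusted"] = stats.false_discovery_control(
            frame.loc[ok, "p"], method="bh"
        )
        frame["star"] = frame["p_adjusted"].map(_star)
    else:
        frame["star"] = frame["p"].map(_star)
    return frame


def association_pivot(frame: pd.DataFrame, value: str = "rho") -> pd.DataFrame:
    """Wide taxon x compound view of one column of the association frame."""
    return frame.pivot(index="taxon", columns="compound", values=value)
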