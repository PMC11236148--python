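"""Alpha diversity (Shannon-Wiener, Margalef), the C/P bioindication
quotient, and group comparisons.

Natural logarithms throughout. Group-level indices are means of per-sample
values (the convention behind "average Margalef richness index"); a pooled
mode recomputes the index on summed counts instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, TaxonomyTable, ValidationError

__all__ = [
    "shannon",
    "margalef",
    "alpha_table",
    "group_alpha",
    "cp_quotient",
    "compare_groups",
]

#: Classes whose species counts form the C/P denominator ("polyhymenophorans",
#: typically k-selected inhabitants of stable soils).
POLYHYMENOPHORA = ("Spirotrichea", "Heterotrichea", "Armophorea")
COLPODEA = "Colpodea"


def shannon(counts) -> float:
    """Shannon-Wiener diversity H = -sum (n_i/N) ln(n_i/N), in nats.

    Zero counts contribute nothing; an all-zero vector is an error.
    """
    n = np.asarray(counts, dtype=float)
    if (n < 0).any():
        raise ValidationError("negative counts")
    n = n[n > 0]
    if n.size == 0:
        raise ValidationError("shannon undefined for an all-zero vector")
    p = n / n.sum()
    return float(-(p * np.log(p)).sum())


def margalef(S: int, N: float) -> float:
    """Margalef richness D = (S-1)/ln N; D(S=1) = 0 by convention."""
    if S < 1:
        raise ValidationError("margalef needs at least one species")
    if N < 1:
        raise ValidationError("margalef needs at least one individual")
    if S == 1:
        return 0.0
    if N == 1:
        raise ValidationError(f"{S} species cannot fit in 1 individual")
    return float((S - 1) / np.log(N))


def alpha_table(ab: AbundanceTable) -> pd.DataFrame:
    """Per-sample H (nats), Margalef D, observed species S and total N."""
    rows = {}
    for sample in ab.samples:
        vec = ab.counts.loc[sample].to_numpy(dtype=float)
        S = int((vec > 0).sum())
        N = float(vec.sum())
        rows[sample] = {
            "H": shannon(vec),
            "D": margalef(S, N),
            "S": S,
            "N": N,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def group_alpha(ab: AbundanceTable, group_by: str, pooled: bool = False) -> pd.DataFrame:
    """Group-level alpha diversity.

    Default: mean of per-sample H and D within each group. ``pooled=True``
    instead sums counts over the group's samples and recomputes the indices
    on the pooled community.
    """
    labels = ab.groups(group_by)
    if pooled:
        rows = {}
        for g, idx in labels.groupby(labels).groups.items():
            vec = ab.counts.loc[idx].sum(axis=0).to_numpy(dtype=float)
            S, N = int((vec > 0).sum()), float(vec.sum())
            rows[g] = {"H": shannon(vec), "D": margalef(S, N), "S": S, "N": N}
        return pd.DataFrame.from_dict(rows, orient="index")
    per_sample = alpha_table(ab)
    return per_sample.groupby(labels).mean()


def cp_quotient(
    ab: AbundanceTable,
    tax: TaxonomyTable,
    scope: dict[str, str] | None = None,
    basis: str = "richness",
) -> dict:
    """C/P quotient: Colpodea over Spirotrichea + Heterotrichea + Armophorea.

    Colpodeans are r-selected colonisers of harsh soils; the polyhymenophoran
    classes are k-selected residents of stable ones, so a quotient <= 1 marks
    a relatively benign soil habitat ("good"), > 1 a disturbed one ("poor").

    ``basis='richness'`` (default) counts species present; ``'abundance'``
    sums individuals. ``scope`` filters samples by metadata, e.g.
    ``{'ecosystem': 'grassland'}``.
    """
    if basis not in ("richness", "abundance"):
        raise ValidationError(f"unknown basis {basis!r}")
    sub = ab
    label = "all"
    if scope:
        mask = pd.Series(True, index=ab.counts.index)
        for col, val in scope.items():
            mask &= ab.groups(col) == val
        if not mask.any():
            raise ValidationError(f"scope {scope} matches no samples")
        sub = ab.subset(mask[mask].index)
        label = "&".join(str(v) for v in scope.values())
    totals = sub.counts.sum(axis=0)
    present = totals[totals > 0]
    classes = tax.rank_of(list(present.index), "class")
    if basis == "richness":
        c_val = int((classes == COLPODEA).sum())
        p_val = int(classes.isin(POLYHYMENOPHORA).sum())
    else:
        c_val = float(present[classes == COLPODEA].sum())
        p_val = float(present[classes.isin(POLYHYMENOPHORA)].sum())
    result = {
        "scope": label,
        "colpodea": c_val,
        "polyhymenophora": p_val,
        "quotient": None,
        "verdict": None,
        "defined": p_val > 0,
    }
    if p_val > 0:
        q = c_val / p_val
        result["quotient"] = q
        result["verdict"] = "good" if q <= 1 else "poor"
    return result


def compare_groups(
    values,
    groups,
    method: str = "permutation",
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Omnibus + pairwise comparison of a per-sample statistic across groups.

    ``method='anova'``: one-way ANOVA with Tukey HSD pairwise.
    ``method='permutation'`` (default, recommended at small n): the F
    statistic's null distribution is built from ``n_perm`` label shuffles;
    pairwise p-values come from two-sample permutation of |mean difference|.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValidationError(f"groups with < 2 samples: {small}")

    def f_stat(vals, grp):
        gm = vals.mean()
        ss_between = sum(
            len(v := vals[grp == g]) * (v.mean() - gm) ** 2 for g in labels
        )
        ss_within = sum(((vals[grp == g] - vals[grp == g].mean()) ** 2).sum() for g in labels)
        dfb, dfw = len(labels) - 1, len(vals) - len(labels)
        if ss_within == 0:
            return 0.0 if ss_between == 0 else np.inf
        return (ss_between / dfb) / (ss_within / dfw)

    if method == "anova":
        F, p = stats.f_oneway(*[values[groups == g] for g in labels])
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tukey = pairwise_tukeyhsd(values, groups)
        frame = pd.DataFrame(
            data=tukey._results_table.data[1:], columns=tukey._results_table.data[0]
        )
        pairwise = {
            (str(r["group1"]), str(r["group2"])): float(r["p-adj"])
            for _, r in frame.iterrows()
        }
        return {"method": "anova", "statistic": float(F), "p": float(p), "pairwise": pairwise}

    if method != "permutation":
        raise ValidationError(f"unknown method {method!r}")
    if n_perm < 99:
        raise ValidationError("need >= 99 permutations")
    rng = np.random.default_rng(seed)
    obs = f_stat(values, groups)
    hits = 0
    for _ in range(n_perm):
        hits += f_stat(values, rng.permutation(groups)) >= obs
    p = (1 + hits) / (1 + n_perm)
    pairwise = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            va, vb = values[groups == a], values[groups == b]
            d_obs = abs(va.mean() - vb.mean())
            pool = np.concatenate([va, vb])
            hits_ab = 0
            for _ in range(n_perm):
                rng.shuffle(pool)
                hits_ab += abs(pool[: len(va)].mean() - pool[len(va) :].mean()) >= d_obs
            pairwise[(str(a), str(b))] = (1 + hits_ab) / (1 + n_perm)
    return {"method": "permutation", "statistic": float(obs), "p": float(p), "pairwise": pairwise}
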