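"""Relative qRT-PCR quantification (2^−ΔΔCt) and its statistical battery.

Each well measures a threshold cycle Ct; lower Ct means more template.
Expression of a target assay is normalised within each sample against a
reference assay (e.g. GAPDH for genes, a small nucleolar RNA for miRNAs):
ΔCt = Ct(target) − Ct(reference).  Treated samples are then compared to
the mean control ΔCt, ΔΔCt = ΔCt(treated) − mean ΔCt(control), and the
fold change is 2^−ΔΔCt.  Replicate fold changes are aggregated by the
geometric mean, since fold changes live on a log scale.

Group differences are assessed on the ΔCt scale with a classical one-way
fixed-effects ANOVA and Tukey's HSD post hoc test; normality is screened
with a one-sample Kolmogorov–Smirnov test against a normal with the sample
mean and SD (the plain, non-Lilliefors-corrected variant, so the p-value
is conservative when parameters are estimated).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("treated", "control")


@dataclass
class CtTable:
    """Replicate Ct measurements plus the reference-assay map.

    ``data`` holds one row per well: sample_id, group (treated/control),
    assay, ct.  ``reference_map`` names the normaliser assay for each
    target assay.
    """

    data: pd.DataFrame
    reference_map: Dict[str, str]

    def __post_init__(self) -> None:
        required = ["sample_id", "group", "assay", "ct"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns {missing}")
        bad_groups = set(self.data["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels {sorted(bad_groups)}; expected {GROUPS}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        dup = self.data.duplicated(subset=["sample_id", "assay"])
        if dup.any():
            pairs = self.data.loc[dup, ["sample_id", "assay"]].to_records(index=False)
            raise ValueError(f"duplicate (sample, assay) measurements: {list(pairs)[:5]}")

    def reference_for(self, assay: str) -> str:
        try:
            return self.reference_map[assay]
        except KeyError:
            raise ValueError(f"no reference assay configured for {assay!r}") from None


@dataclass
class DDCtResult:
    """Relative-expression output for one assay."""

    assay: str
    mean_fold_change: float
    fold_changes: List[float]  # per treated replicate
    control_fold_changes: List[float]  # control replicates vs their own mean
    p_anova: float
    p_tukey: Dict[Tuple[str, str], float]
    normality_p: float
    significant: bool
    threshold: float = 0.05
    fdr: float = field(default=float("nan"))


def delta_delta_ct(ct: CtTable, assay: str, threshold: float = 0.05) -> DDCtResult:
    """2^−ΔΔCt relative expression of ``assay`` in treated vs control.

    Requires at least two replicates per group for both the target and its
    reference assay; a sample missing the reference measurement is an
    error naming that sample.
    """
    reference = ct.reference_for(assay)
    df = ct.data
    target = df[df["assay"] == assay].set_index("sample_id")
    ref = df[df["assay"] == reference].set_index("sample_id")
    if target.empty:
        raise ValueError(f"no measurements for assay {assay!r}")
    missing_ref = sorted(set(target.index) - set(ref.index))
    if missing_ref:
        raise ValueError(
            f"missing reference ({reference}) measurement for sample(s): {missing_ref}"
        )

    dct = (target["ct"] - ref.loc[target.index, "ct"]).rename("dct")
    groups = target["group"]
    dct_by_group = {g: dct[groups == g].to_numpy() for g in GROUPS}
    for g, vals in dct_by_group.items():
        if len(vals) < 2:
            raise ValueError(f"need >=2 {g} replicates for {assay!r}, got {len(vals)}")

    control_mean = float(np.mean(dct_by_group["control"]))
    fold = (2.0 ** -(dct_by_group["treated"] - control_mean)).tolist()
    control_fold = (2.0 ** -(dct_by_group["control"] - control_mean)).tolist()
    mean_fold = float(np.exp(np.mean(np.log(fold))))

    p_anova, p_tukey = anova_tukey({g: v.tolist() for g, v in dct_by_group.items()})
    residuals = np.concatenate([v - v.mean() for v in dct_by_group.values()])
    try:
        normality_p = ks_normality(residuals.tolist())
    except ValueError:  # zero-variance residuals (noise-free synthetic input)
        normality_p = float("nan")

    return DDCtResult(
        assay=assay,
        mean_fold_change=mean_fold,
        fold_changes=fold,
        control_fold_changes=control_fold,
        p_anova=p_anova,
        p_tukey=p_tukey,
        normality_p=normality_p,
        significant=p_anova < threshold,
        threshold=threshold,
    )


def ddct_all(ct: CtTable, threshold: float = 0.05, fdr_adjust: bool = False) -> List[DDCtResult]:
    """Run :func:`delta_delta_ct` for every assay with a configured reference.

    With ``fdr_adjust`` the ANOVA p-values across assays are BH-adjusted
    and significance is called on the adjusted values (the default mirrors
    unadjusted per-assay testing).
    """
    from .enrichment import bh_fdr

    assays = [a for a in ct.reference_map if (ct.data["assay"] == a).any()]
    results = [delta_delta_ct(ct, a, threshold=threshold) for a in assays]
    if fdr_adjust and results:
        fdrs = bh_fdr([r.p_anova for r in results])
        for r, q in zip(results, fdrs):
            r.fdr = q
            r.significant = q < threshold
    return results


def ks_normality(values: Sequence[float]) -> float:
    """One-sample KS test against N(sample mean, sample SD); asymptotic p.

    The statistic is the exact sup-distance between the empirical CDF and
    the fitted normal CDF.  Parameters are estimated from the data (no
    Lilliefors correction), matching common statistics-package defaults.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError(f"KS normality test needs n >= 3, got {n}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("KS normality test undefined for zero-variance data")
    cdf = stats.norm.cdf(x, loc=float(np.mean(x)), scale=sd)
    upper = np.max(np.arange(1, n + 1) / n - cdf)
    lower = np.max(cdf - np.arange(0, n) / n)
    d = max(upper, lower)
    return float(stats.kstwobign.sf(d * math.sqrt(n)))


def anova_tukey(
    groups: Dict[str, Sequence[float]],
) -> Tuple[float, Dict[Tuple[str, str], float]]:
    """Classical one-way ANOVA plus Tukey HSD over all group pairs.

    Returns the ANOVA p-value and a map (label_a, label_b) → Tukey p,
    with labels in sorted order within each pair.  If every observation
    is identical the ANOVA p is 1 by convention; if groups differ but the
    within-group variance is zero the p-values are 0.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs n >= 2, got {arr.size}")

    all_vals = np.concatenate([arrays[g] for g in labels])
    n_total = all_vals.size
    k = len(labels)
    grand = all_vals.mean()
    ss_between = sum(arr.size * (arr.mean() - grand) ** 2 for arr in arrays.values())
    ss_within = sum(((arr - arr.mean()) ** 2).sum() for arr in arrays.values())
    df_between = k - 1
    df_within = n_total - k

    pairs = list(itertools.combinations(labels, 2))
    if ss_within == 0 and ss_between == 0:
        return 1.0, {pair: 1.0 for pair in pairs}
    if ss_within == 0:
        tukey = {
            (a, b): (1.0 if arrays[a].mean() == arrays[b].mean() else 0.0) for a, b in pairs
        }
        return 0.0, tukey

    ms_within = ss_within / df_within
    f_stat = (ss_between / df_between) / ms_within
    p_anova = float(stats.f.sf(f_stat, df_between, df_within))

    if k == 2:
        # with two groups the studentized range is sqrt(2)|t|, so the Tukey
        # p-value coincides with the ANOVA p-value
        return p_anova, {pairs[0]: p_anova}
    tukey = {}
    for a, b in pairs:
        xa, xb = arrays[a], arrays[b]
        se = math.sqrt(ms_within / 2.0 * (1.0 / xa.size + 1.0 / xb.size))
        q = abs(xa.mean() - xb.mean()) / se
        tukey[(a, b)] = float(stats.studentized_range.sf(q, k, df_within))
    return p_anova, tukey
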