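"""Relative-expression (2^−ΔΔCT) quantification and the associated
statistics for qPCR and germination experiments.

The quantification follows the comparative-CT convention: technical
replicates of the cycle threshold are averaged first; ΔCT is target minus
reference gene within each (group, biological replicate); ΔΔCT subtracts
the calibrator group's mean ΔCT; the expression ratio is 2^−ΔΔCT and the
amplification efficiency is fixed at 2 (no efficiency-corrected variant).
Group testing runs one-way ANOVA on log2 ratios with Bonferroni
(pooled-MSE pairwise t tests) or Dunnett (many-to-one, equicorrelated
multivariate-t) post hoc procedures.  Germination proportions are
variance-stabilised with the angular (arcsine-square-root) transform
before the same ANOVA machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ALPHA_LEVELS = (0.05, 0.01)


@dataclass(frozen=True)
class PosthocResult:
    contrast: tuple[str, str]
    statistic: float
    p_value: float

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_value < 0.01


@dataclass(frozen=True)
class RelativeExpression:
    """Per-replicate ΔΔCT quantities and per-group summaries."""

    per_replicate: pd.DataFrame   # group, bio_rep, dct, ddct, ratio, log2_ratio
    per_group: pd.DataFrame       # group, mean_log2_ratio, se_log2_ratio, n
    target_gene: str
    reference_gene: str
    calibrator_group: str


def ddct(table: pd.DataFrame, target_gene: str, reference_gene: str,
         calibrator_group: str) -> RelativeExpression:
    """2^−ΔΔCT relative quantification with reference-gene normalisation.

    ``table`` is long-format with columns (gene, group, bio_rep, tech_rep,
    ct).  Technical replicates are averaged first.  A missing reference
    measurement in any (group, bio_rep) cell is an error naming the cell.
    """
    for gene, label in ((target_gene, "target"), (reference_gene, "reference")):
        if gene not in set(table["gene"]):
            raise ValueError(f"{label} gene {gene!r} absent from table")
    tech_mean = (table.groupby(["gene", "group", "bio_rep"], sort=True)["ct"]
                 .mean().reset_index())
    target = tech_mean[tech_mean["gene"] == target_gene]
    ref = tech_mean[tech_mean["gene"] == reference_gene]
    merged = target.merge(ref, on=["group", "bio_rep"], how="left",
                          suffixes=("_target", "_ref"))
    missing = merged[merged["ct_ref"].isna()]
    if not missing.empty:
        cells = [f"({r.group}, bio_rep={r.bio_rep})" for r in missing.itertuples()]
        raise ValueError(f"reference gene {reference_gene!r} missing in "
                         f"{', '.join(cells)}")
    merged["dct"] = merged["ct_target"] - merged["ct_ref"]
    cal = merged[merged["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} absent for "
                         f"target {target_gene!r}")
    cal_mean = cal["dct"].mean()
    merged["ddct"] = merged["dct"] - cal_mean
    merged["ratio"] = 2.0 ** (-merged["ddct"])
    merged["log2_ratio"] = -merged["ddct"]
    per_rep = merged[["group", "bio_rep", "dct", "ddct", "ratio", "log2_ratio"]]
    grp = per_rep.groupby("group", sort=True)["log2_ratio"]
    per_group = pd.DataFrame({
        "mean_log2_ratio": grp.mean(),
        "se_log2_ratio": grp.sem(),
        "n": grp.size(),
    }).reset_index()
    return RelativeExpression(per_rep.reset_index(drop=True), per_group,
                              target_gene, reference_gene, calibrator_group)


def log2_transform(ratios) -> np.ndarray:
    """Elementwise log2 of expression ratios (ratio 1 → 0)."""
    ratios = np.asarray(ratios, dtype=float)
    if (ratios <= 0).any():
        raise ValueError("ratios must be positive for log2 transform")
    return np.log2(ratios)


def angular_transform(p) -> np.ndarray | float:
    """Arcsine-square-root transform of proportions in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def one_way_anova(values, groups) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value over labelled values."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("ANOVA requires at least 2 values per group")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def anova_posthoc(values, groups, method: str = "bonferroni",
                  control_group: str | None = None,
                  seed: int | None = 0) -> list[PosthocResult]:
    """Post hoc contrasts after one-way ANOVA.

    ``bonferroni``: all pairwise t tests on the pooled mean-square error
    (df = N − k), raw p multiplied by the number of contrasts and capped
    at 1.  ``dunnett``: many-to-one comparisons against ``control_group``
    using the equicorrelated multivariate-t distribution.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    samples = {g: values[groups == g] for g in labels}
    if len(labels) < 2:
        raise ValueError("post hoc tests require at least 2 groups")
    if any(len(s) < 2 for s in samples.values()):
        raise ValueError("post hoc tests require at least 2 values per group")

    if method == "bonferroni":
        n_total = sum(len(s) for s in samples.values())
        k = len(labels)
        df = n_total - k
        mse = sum(((s - s.mean()) ** 2).sum() for s in samples.values()) / df
        contrasts = list(combinations(labels, 2))
        out = []
        for a, b in contrasts:
            sa, sb = samples[a], samples[b]
            se = np.sqrt(mse * (1 / len(sa) + 1 / len(sb)))
            t = (sa.mean() - sb.mean()) / se
            raw = 2.0 * stats.t.sf(abs(t), df)
            out.append(PosthocResult((a, b), float(t),
                                     min(1.0, raw * len(contrasts))))
        return out

    if method == "dunnett":
        if control_group is None or control_group not in samples:
            raise ValueError("dunnett requires a control_group present in the data")
        treatments = [g for g in labels if g != control_group]
        # seeded: the multivariate-t CDF is evaluated by randomised
        # quadrature, so p-values are only reproducible with a fixed rng
        res = stats.dunnett(*[samples[g] for g in treatments],
                            control=samples[control_group], rng=seed)
        return [
            PosthocResult((g, control_group), float(res.statistic[i]),
                          float(res.pvalue[i]))
            for i, g in enumerate(treatments)
        ]

    raise ValueError(f"unknown post hoc method {method!r}")


def recovery_bias(planted: dict[str, float], simulate, estimate,
                  n_sims: int = 50, seed: int | None = None) -> dict[str, float]:
    """Estimate per-group recovery bias of an estimator over replicate
    simulations.

    ``simulate(seed)`` draws one dataset; ``estimate(dataset)`` returns a
    mapping group → recovered value.  Bias is the mean recovery error per
    group across ``n_sims`` independent draws — a single draw measures
    noise, not bias.
    """
    rng = np.random.default_rng(seed)
    sums = {g: 0.0 for g in planted}
    for _ in range(n_sims):
        est = estimate(simulate(int(rng.integers(2**31))))
        for g in planted:
            sums[g] += est[g] - planted[g]
    return {g: s / n_sims for g, s in sums.items()}


def germination_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Germination proportions with their angular transform, one row per
    (genotype, condition, replicate)."""
    out = table.copy()
    out["rate"] = out["germinated"] / out["total"]
    out["angular"] = angular_transform(out["rate"].to_numpy())
    return out


def germination_test(table: pd.DataFrame, condition: str,
                     control_genotype: str,
                     method: str = "dunnett") -> list[PosthocResult]:
    """ANOVA + post hoc on angular-transformed germination rates within
    one condition, comparing genotypes (Dunnett: vs the control)."""
    sub = germination_rates(table[table["condition"] == condition])
    if sub.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    return anova_posthoc(sub["angular"].to_numpy(), sub["genotype"].to_numpy(),
                         method=method, control_group=control_genotype)
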