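"""qPCR standard curves, relative quantification and group statistics.

Relative copy number uses the comparative 2^-ddCt method against a
single-copy reference gene; relative expression uses the
efficiency-corrected (1+E)^-ddCt form with the lowest-expression
(highest normalized Ct) sample as calibrator. Amplification efficiency
comes from a dilution-series standard curve: with slope y of mean Ct on
log10 concentration, E = (10^(-1/y) - 1) * 100 so that a slope of
-3.3219 (= -1/log10(2)) gives 100 % efficiency and a per-cycle fold of
exactly 2. Normalizer stability is the geNorm M value, and group
comparisons use one-way ANOVA gated Fisher's LSD.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "group", "target", "replicate", "ct"]

COPY_NUMBER_METHOD = "copy_number_2ddct"
EXPRESSION_METHOD = "expression_eff_ddct"


def validate_ct_table(table: pd.DataFrame, need_conc: bool = False) -> pd.DataFrame:
    missing = {"sample", "target", "ct"} - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    if need_conc and "log10_conc" not in table.columns:
        raise ValueError("dilution series needs a log10_conc column")
    return table


@dataclass
class StandardCurve:
    """Linear fit of mean Ct on log10(template concentration)."""

    slope: float  # cycles per log10 concentration
    intercept: float
    r_squared: float
    efficiency_percent: float
    fold: float  # per-cycle amplification factor = 1 + E/100

    @property
    def efficiency(self) -> float:
        """Efficiency as a fraction (for the (1+E)^-ddCt formula)."""
        return self.efficiency_percent / 100.0


@dataclass
class RelativeQuantity:
    sample_id: str
    target_id: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    method: str
    calibrator_id: str


@dataclass
class StabilityResult:
    gene_id: str
    M: float


def efficiency_from_slope(y: float) -> tuple[float, float]:
    """(E percent, per-cycle fold) from a standard-curve slope.

    E = (10^(-1/y) - 1) * 100; the fold is 1 + E/100, equal to 2 at the
    ideal slope -1/log10(2) = -3.3219.
    """
    if y >= 0:
        raise ValueError("standard-curve slope must be negative")
    e_percent = (10.0 ** (-1.0 / y) - 1.0) * 100.0
    return e_percent, 1.0 + e_percent / 100.0


def fit_standard_curve(dilution_table: pd.DataFrame) -> StandardCurve:
    """OLS of mean Ct per dilution point on log10 concentration."""
    table = validate_ct_table(dilution_table, need_conc=True)
    means = table.groupby("log10_conc", as_index=False)["ct"].mean()
    if len(means) < 3:
        raise ValueError("need at least three distinct concentrations")
    if means["log10_conc"].nunique() < 2 or means["log10_conc"].std() == 0:
        raise ValueError("zero variance in concentration")
    fit = stats.linregress(means["log10_conc"], means["ct"])
    e_percent, fold = efficiency_from_slope(fit.slope)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency_percent=float(e_percent),
        fold=float(fold),
    )


def _mean_ct(table: pd.DataFrame, sample: str, target: str) -> float:
    sub = table[(table["sample"] == sample) & (table["target"] == target)]
    if sub.empty:
        raise ValueError(f"no Ct values for sample {sample!r}, target {target!r}")
    return float(sub["ct"].mean())


def copy_number_rq(
    table: pd.DataFrame,
    target: str,
    reference_gene: str,
    test_sample: str,
    calibrator_sample: str,
) -> RelativeQuantity:
    """Relative copy number by the comparative 2^-ddCt method.

    dCt = mean Ct(target) - mean Ct(single-copy reference) per sample;
    ddCt compares the test sample with the calibrator genome.
    """
    table = validate_ct_table(table)
    d_test = _mean_ct(table, test_sample, target) - _mean_ct(
        table, test_sample, reference_gene
    )
    d_cal = _mean_ct(table, calibrator_sample, target) - _mean_ct(
        table, calibrator_sample, reference_gene
    )
    ddct = d_test - d_cal
    return RelativeQuantity(
        sample_id=test_sample,
        target_id=target,
        delta_ct=d_test,
        delta_delta_ct=ddct,
        rq=2.0 ** (-ddct),
        method=COPY_NUMBER_METHOD,
        calibrator_id=calibrator_sample,
    )


def expression_rq(
    table: pd.DataFrame,
    target: str,
    normalizer: str,
    efficiency: float,
    calibrator: Optional[str] = None,
    min_efficiency: float = 0.90,
) -> list[RelativeQuantity]:
    """Efficiency-corrected relative expression per sample.

    rq = (1 + E)^-ddCt with ddCt = dCt(sample) - dCt(calibrator) and
    dCt = mean Ct(target) - mean Ct(normalizer). The calibrator defaults
    to the sample with the highest normalized Ct (lowest expression) and
    gets rq = 1 exactly. Reactions below ``min_efficiency`` are refused,
    mirroring the quality filter applied to per-primer efficiencies.
    """
    table = validate_ct_table(table)
    if not 0.0 < efficiency <= 1.1:
        raise ValueError("efficiency must lie in (0, 1.1]")
    if efficiency < min_efficiency:
        raise ValueError(
            f"efficiency {efficiency:.2f} below the {min_efficiency:.2f} threshold"
        )
    samples = list(dict.fromkeys(table["sample"]))
    dct = {s: _mean_ct(table, s, target) - _mean_ct(table, s, normalizer) for s in samples}
    if calibrator is None:
        calibrator = max(dct, key=lambda s: dct[s])
    elif calibrator not in dct:
        raise ValueError(f"calibrator {calibrator!r} not in table")
    out = []
    for s in samples:
        ddct = dct[s] - dct[calibrator]
        rq = 1.0 if s == calibrator else (1.0 + efficiency) ** (-ddct)
        out.append(
            RelativeQuantity(
                sample_id=s,
                target_id=target,
                delta_ct=dct[s],
                delta_delta_ct=ddct,
                rq=rq,
                method=EXPRESSION_METHOD,
                calibrator_id=calibrator,
            )
        )
    return out


def genorm_m(expression: pd.DataFrame) -> list[StabilityResult]:
    """geNorm stability M per candidate normalizer gene.

    ``expression`` is genes x samples with positive relative quantities.
    M_j is the mean over all other genes k of the standard deviation
    across samples of log2(x_j / x_k); perfectly proportional genes give
    M = 0, and values below 0.15 mark a normalizer that needs no
    companion gene.
    """
    if expression.shape[0] < 2 or expression.shape[1] < 2:
        raise ValueError("need at least two genes and two samples")
    values = expression.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("expression values must be > 0")
    logs = np.log2(values)
    results = []
    for j, gene in enumerate(expression.index):
        sds = [
            float(np.std(logs[j] - logs[k], ddof=1))
            for k in range(len(expression.index))
            if k != j
        ]
        results.append(StabilityResult(gene_id=gene, M=float(np.mean(sds))))
    return results


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    t: float
    p: float
    significant: bool


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    mse: float
    significant: bool
    degenerate: bool
    comparisons: list[PairwiseComparison] = field(default_factory=list)
    letters: dict[str, str] = field(default_factory=dict)


def anova_lsd(groups: dict[str, Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Fisher's LSD post-hoc comparisons.

    Pairwise LSD t-tests (pooled within-group MSE, N - k df) run only
    when the ANOVA is significant at ``alpha``; groups sharing a letter
    in ``letters`` are not significantly different.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("need at least two replicates per group")
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    mse = ssw / df_w

    degenerate = ssw == 0.0
    if degenerate:
        if ssb == 0.0:
            # every observation identical: nothing to separate
            return AnovaResult(
                F=0.0, p=1.0, df_between=df_b, df_within=df_w, mse=0.0,
                significant=False, degenerate=True,
                letters={g: "a" for g in names},
            )
        f_stat, p_val = math.inf, 0.0
    else:
        f_stat = (ssb / df_b) / mse
        p_val = float(stats.f.sf(f_stat, df_b, df_w))

    significant = p_val < alpha
    comparisons: list[PairwiseComparison] = []
    if significant:
        for ga, gb in itertools.combinations(names, 2):
            a, b = np.asarray(groups[ga], float), np.asarray(groups[gb], float)
            diff = a.mean() - b.mean()
            if mse > 0:
                se = math.sqrt(mse * (1 / len(a) + 1 / len(b)))
                t_stat = diff / se
                p_pair = float(2 * stats.t.sf(abs(t_stat), df_w))
            else:
                t_stat = math.inf if diff != 0 else 0.0
                p_pair = 0.0 if diff != 0 else 1.0
            comparisons.append(
                PairwiseComparison(
                    group_a=ga, group_b=gb, mean_diff=diff,
                    t=t_stat, p=p_pair, significant=p_pair < alpha,
                )
            )
    letters = _letter_groups(names, groups, comparisons, significant)
    return AnovaResult(
        F=float(f_stat), p=p_val, df_between=df_b, df_within=df_w, mse=float(mse),
        significant=significant, degenerate=degenerate,
        comparisons=comparisons, letters=letters,
    )


def _letter_groups(
    names: list[str],
    groups: dict[str, Sequence[float]],
    comparisons: list[PairwiseComparison],
    significant: bool,
) -> dict[str, str]:
    """Greedy compact letter display: non-different groups share a letter."""
    if not significant:
        return {g: "a" for g in names}
    differ = {
        frozenset((c.group_a, c.group_b)) for c in comparisons if c.significant
    }
    order = sorted(names, key=lambda g: -np.mean(np.asarray(groups[g], float)))
    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in differ for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # drop letter sets wholly contained in another
    keep = [
        s
        for i, s in enumerate(letter_sets)
        if not any(i != j and s < t for j, t in enumerate(letter_sets))
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in names}
    for letter, s in zip(alphabet, keep):
        for g in order:
            if g in s:
                out[g] += letter
    return out
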