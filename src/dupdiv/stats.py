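"""Mantel permutation tests, matrix regression, class summaries, weighted LM.

Within a gene class, association between two distance matrices (expression vs
genetic, expression vs omega) is tested by the Mantel procedure: Pearson
correlation over the unmasked off-diagonal pairs, with the null distribution
built by jointly permuting the row/column labels of the second matrix (the
mask travels with the labels, so undefined pairs are excluded pairwise).
Tests are one-sided (upper) by default because the hypotheses concern
positive association; two-sided is available.  For 7 or fewer labels all
permutations are enumerated and the p-value is exact; otherwise Monte-Carlo
sampling uses the (1+b)/(1+m) convention.

Between classes, per-class mean distances are compared by least squares
weighted by the class sample size (number of usable pairs), with the p-value
from the t statistic of the slope on n-2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import statsmodels.api as sm

from .distmatrix import DistanceMatrix
from .errors import (
    DegeneratePredictorError,
    IdError,
    InsufficientDataError,
)

EXACT_MAX_LABELS = 7


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_value: float
    n_labels: int
    n_pairs: int
    n_permutations: int
    tail: str
    method: str  # "exact" | "monte-carlo"
    seed: int | None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float | None
    weights: str
    n_points: int


@dataclass(frozen=True)
class ClassSummary:
    name: str
    kind: str  # distance kind: genetic | expression | omega
    mean: float
    sd: float | None
    n: int


def _aligned_pair(d1: DistanceMatrix, d2: DistanceMatrix):
    if set(d1.labels) != set(d2.labels):
        raise IdError("distance matrices do not share the same label set")
    d2 = d2.reorder(d1.labels)
    return d1, d2


def _perm_indices(n, n_perm, seed):
    """Permutations of range(n): exhaustive for small n, seeded samples else."""
    if n <= EXACT_MAX_LABELS:
        return np.array(list(iter_permutations(range(n)))), "exact"
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)]), "monte-carlo"


def _masked_pearson(x, y, use):
    xs, ys = x[use], y[use]
    if len(xs) < 3:
        return np.nan
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    den = np.sqrt((xs**2).sum() * (ys**2).sum())
    if den == 0:
        return np.nan
    return float((xs * ys).sum() / den)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "upper",
) -> MantelResult:
    """Mantel test of association between two labeled distance matrices.

    ``d1`` is held fixed; labels of ``d2`` are permuted (with its mask).
    """
    if tail not in ("upper", "two"):
        raise ValueError("tail must be 'upper' or 'two'")
    d1, d2 = _aligned_pair(d1, d2)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    m1 = d1.mask[iu]
    use_obs = ~m1 & ~d2.mask[iu]
    n_pairs = int(use_obs.sum())
    if n_pairs < 3:
        raise InsufficientDataError(
            f"Mantel test needs >= 3 usable pairs, got {n_pairs}"
        )
    r_obs = _masked_pearson(v1, d2.values[iu], use_obs)
    if math.isnan(r_obs):
        raise InsufficientDataError("zero variance among usable pairs")

    perms, method = _perm_indices(n, n_perm, seed)
    i_idx, j_idx = iu
    pv = d2.values[perms[:, i_idx], perms[:, j_idx]]  # (n_perm, n_pairs_total)
    pm = d2.mask[perms[:, i_idx], perms[:, j_idx]]
    better = 0
    total = 0
    for row_v, row_m in zip(pv, pm):
        use = ~m1 & ~row_m
        r = _masked_pearson(v1, row_v, use)
        if math.isnan(r):
            continue
        total += 1
        if tail == "upper":
            hit = r >= r_obs - 1e-12
        else:
            hit = abs(r) >= abs(r_obs) - 1e-12
        if hit:
            better += 1
    if method == "exact":
        p = better / total
    else:
        p = (1 + better) / (1 + total)
    return MantelResult(
        statistic=r_obs,
        p_value=p,
        n_labels=n,
        n_pairs=n_pairs,
        n_permutations=total,
        tail=tail,
        method=method,
        seed=None if method == "exact" else seed,
    )


def matrix_regression(
    dy: DistanceMatrix,
    dx: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "upper",
) -> RegressionResult:
    """OLS of vectorized dy on vectorized dx over usable pairs, with a
    label-permutation p-value for the slope (dy's labels are permuted)."""
    dy, dx = _aligned_pair(dy, dx)
    n = dy.n
    iu = np.triu_indices(n, k=1)
    use = ~dy.mask[iu] & ~dx.mask[iu]
    if int(use.sum()) < 3:
        raise InsufficientDataError("matrix regression needs >= 3 usable pairs")
    x = dx.values[iu]
    y = dy.values[iu]

    def fit(yv, uv):
        xs, ys = x[uv], yv[uv]
        if np.ptp(xs) == 0:
            raise DegeneratePredictorError("predictor matrix has zero variance")
        beta, alpha = np.polyfit(xs, ys, 1)
        resid = ys - (alpha + beta * xs)
        tot = ((ys - ys.mean()) ** 2).sum()
        r2 = 1.0 - (resid**2).sum() / tot if tot > 0 else 1.0
        return float(beta), float(alpha), float(r2)

    beta, alpha, r2 = fit(y, use)

    perms, method = _perm_indices(n, n_perm, seed)
    i_idx, j_idx = iu
    better = total = 0
    for p_row in perms:
        yv = dy.values[p_row[i_idx], p_row[j_idx]]
        mv = dy.mask[p_row[i_idx], p_row[j_idx]]
        uv = ~mv & ~dx.mask[iu]
        if int(uv.sum()) < 3 or np.ptp(x[uv]) == 0:
            continue
        b, _, _ = fit(yv, uv)
        total += 1
        if tail == "upper":
            hit = b >= beta - 1e-12
        else:
            hit = abs(b) >= abs(beta) - 1e-12
        if hit:
            better += 1
    p = better / total if method == "exact" else (1 + better) / (1 + total)
    return RegressionResult(
        slope=beta,
        intercept=alpha,
        r_squared=r2,
        p_value=p,
        weights="none (per-pair OLS, permutation p)",
        n_points=int(use.sum()),
    )


def class_summary(matrices: dict[str, dict[str, DistanceMatrix]]):
    """Per-class mean/sd/n over unmasked off-diagonal pairs for each kind.

    ``matrices`` maps class name -> {kind: DistanceMatrix}.  Classes with a
    kind having zero usable pairs are skipped for that kind, with a warning
    record returned alongside the summaries.
    """
    summaries: list[ClassSummary] = []
    warnings: list[str] = []
    for name, kinds in matrices.items():
        for kind, dm in kinds.items():
            vals, msk = dm.condensed(with_mask=True)
            usable = vals[~msk]
            if usable.size == 0:
                warnings.append(f"class {name!r}: no usable {kind} pairs, skipped")
                continue
            sd = float(np.std(usable, ddof=1)) if usable.size >= 2 else None
            summaries.append(
                ClassSummary(name, kind, float(usable.mean()), sd, int(usable.size))
            )
    return summaries, warnings


def weighted_lm(x, y, w) -> RegressionResult:
    """Weighted least squares of y on x; p from the slope's t statistic.

    With all weights equal this reduces exactly to OLS.  A p-value needs at
    least 3 points (n-2 > 0 degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("weighted LM needs >= 2 points")
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("zero variance in x")
    model = sm.WLS(y, sm.add_constant(x), weights=w)
    res = model.fit()
    intercept, slope = res.params
    p = float(res.pvalues[1]) if len(x) >= 3 else None
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(res.rsquared),
        p_value=p,
        weights="class sample sizes",
        n_points=len(x),
    )


@dataclass
class DivergenceReport:
    within: dict[str, dict] = field(default_factory=dict)
    summaries: list[ClassSummary] = field(default_factory=list)
    between: dict[str, RegressionResult | str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)


def run_divergence_suite(
    classes: dict[str, dict[str, DistanceMatrix]],
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "upper",
) -> DivergenceReport:
    """Run the full within-/between-class divergence analysis.

    ``classes`` maps class name -> dict with keys ``genetic``, ``expression``
    and optionally ``omega``.  Per class: Mantel(expression, genetic),
    Mantel(expression, omega), matrix_regression(omega, genetic).  Between
    classes: weighted LM of class mean expression distance on mean genetic
    distance and on mean omega, weighted by the class pair counts.
    """
    report = DivergenceReport()
    report.seeds["base"] = seed
    for k, (name, kinds) in enumerate(sorted(classes.items())):
        cls_seed = seed + 1000 * (k + 1)
        entry: dict = {"seed": cls_seed}
        try:
            entry["mantel_expression_genetic"] = mantel(
                kinds["expression"], kinds["genetic"], n_perm, cls_seed, tail
            )
        except Exception as exc:
            entry["mantel_expression_genetic"] = f"failed: {exc}"
        if "omega" in kinds:
            try:
                entry["mantel_expression_omega"] = mantel(
                    kinds["expression"], kinds["omega"], n_perm, cls_seed + 1, tail
                )
            except Exception as exc:
                entry["mantel_expression_omega"] = f"failed: {exc}"
            try:
                entry["regression_omega_genetic"] = matrix_regression(
                    kinds["omega"], kinds["genetic"], n_perm, cls_seed + 2, tail
                )
            except Exception as exc:
                entry["regression_omega_genetic"] = f"failed: {exc}"
        report.within[name] = entry

    summaries, warnings = class_summary(classes)
    report.summaries = summaries
    report.warnings = warnings

    by_kind: dict[str, dict[str, ClassSummary]] = {}
    for s in summaries:
        by_kind.setdefault(s.kind, {})[s.name] = s
    for yk, xk, label in (
        ("expression", "genetic", "wls_expression_vs_genetic"),
        ("expression", "omega", "wls_expression_vs_omega"),
    ):
        names = sorted(
            set(by_kind.get(yk, {})) & set(by_kind.get(xk, {}))
        )
        if len(names) < 3:
            report.between[label] = (
                f"skipped: needs >= 3 classes with both kinds, have {len(names)}"
            )
            continue
        xs = [by_kind[xk][n].mean for n in names]
        ys = [by_kind[yk][n].mean for n in names]
        ws = [min(by_kind[xk][n].n, by_kind[yk][n].n) for n in names]
        try:
            report.between[label] = weighted_lm(xs, ys, ws)
        except Exception as exc:
            report.between[label] = f"failed: {exc}"
    return report
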