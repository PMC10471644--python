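"""One-way permutational ANOVA with variance-component effect sizes.

Partitioning follows Anderson's distance-based formulation: with pairwise
distances d_ij among N observations,

    SS_total  = (1/N) Σ_{i<j} d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j ∈ g} d²_ij
    SS_between = SS_total − SS_within

and pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a)).  For univariate data
under Euclidean distance this partition coincides exactly with classical
one-way ANOVA, so the permutation test here is a distribution-free version of
the familiar F test; the mass fractions analysed are log(x+1) transformed
first.

The permutation p-value counts random group relabelings with pseudo-F at
least the observed one, including the observed labelling itself:
``(count + 1) / (n_perm + 1)``.  The Monte-Carlo p-value ``p_mc`` uses the
classical F reference distribution with (a−1, N−a) degrees of freedom (exact
for the univariate Euclidean case).

Effect sizes come from components of variation for unbalanced one-way
designs: with n0 = (N − Σ n_g²/N)/(a−1),

    σ²_within  = MS_within
    σ²_between = max(0, (MS_between − MS_within)/n0)
    effect size = σ²_between / (σ²_between + σ²_within)
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PermanovaResult",
    "log1_transform",
    "one_way_permanova",
    "variance_components",
]


@dataclass(frozen=True)
class PermanovaResult:
    """Outcome of a one-way permutational ANOVA."""

    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    p_perm: float | None = None
    p_mc: float | None = None
    n0: float | None = None
    var_between: float | None = None
    var_within: float | None = None
    effect_size: float | None = None

    @property
    def df_total(self) -> int:
        return self.df_between + self.df_within

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within

    @property
    def pseudo_f(self) -> float:
        return self.ms_between / self.ms_within

    @classmethod
    def from_anova_table(
        cls,
        ss_between: float,
        ss_within: float,
        df_between: int,
        df_within: int,
        group_sizes: Sequence[int] | None = None,
    ) -> "PermanovaResult":
        """Build a result from published sums of squares and degrees of freedom.

        Used to check pseudo-F/MS arithmetic against printed ANOVA tables; when
        ``group_sizes`` is given the variance components are filled in too.
        """
        result = cls(
            df_between=int(df_between),
            df_within=int(df_within),
            ss_between=float(ss_between),
            ss_within=float(ss_within),
            p_mc=float(stats.f.sf(
                (ss_between / df_between) / (ss_within / df_within),
                df_between,
                df_within,
            )),
        )
        if group_sizes is not None:
            vb, vw, n0, eff = variance_components(
                result.ms_between, result.ms_within, group_sizes
            )
            result = replace(
                result, n0=n0, var_between=vb, var_within=vw, effect_size=eff
            )
        return result


def log1_transform(values) -> np.ndarray:
    """Natural log of (x + 1); rejects negative input."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log(x + 1) transform requires non-negative values")
    return np.log1p(arr)


def _group_indices(groups: Sequence) -> tuple[np.ndarray, np.ndarray]:
    labels, idx = np.unique(np.asarray(groups), return_inverse=True)
    return labels, idx


def _univariate_ss(y: np.ndarray, idx: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Classical one-way sums of squares (equals the Euclidean-distance partition)."""
    n = y.size
    totals = np.bincount(idx, weights=y, minlength=n_groups)
    sizes = np.bincount(idx, minlength=n_groups)
    ss_total = float(np.sum(y * y) - y.sum() ** 2 / n)
    ss_between = float(np.sum(totals**2 / sizes) - y.sum() ** 2 / n)
    return ss_between, ss_total - ss_between


def _distance_ss(d2: np.ndarray, idx: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Anderson's partition from a squared-distance matrix."""
    n = d2.shape[0]
    ss_total = float(d2.sum() / (2 * n))
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(idx == g)
        ss_within += d2[np.ix_(members, members)].sum() / (2 * members.size)
    return ss_total - ss_within, ss_within


def one_way_permanova(
    values,
    groups: Sequence,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA of ``values`` (1-D, or 2-D row-per-observation) on
    group labels, under Euclidean distance.

    Returns the full result including permutation and Monte-Carlo p-values and
    components-of-variation effect size.  ``n_perm=0`` skips the permutation
    test (``p_perm`` is then ``None``).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("values must be 1-D or 2-D (observations in rows)")
    n = arr.shape[0]
    labels, idx = _group_indices(groups)
    a = labels.size
    if len(groups) != n:
        raise ValueError("values and groups must have equal length")
    if a < 2:
        raise ValueError("need at least 2 groups")
    if n <= a:
        raise ValueError("need more observations than groups")
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")

    sizes = np.bincount(idx, minlength=a)
    univariate = arr.shape[1] == 1

    if univariate:
        y = arr[:, 0]
        ss_b, ss_w = _univariate_ss(y, idx, a)
    else:
        diff = arr[:, None, :] - arr[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        ss_b, ss_w = _distance_ss(d2, idx, a)

    df_b, df_w = a - 1, n - a
    f_obs = (ss_b / df_b) / (ss_w / df_w)

    p_perm: float | None = None
    if n_perm >= 1:
        rng = np.random.default_rng(seed)
        if univariate:
            # Relabeling is equivalent to permuting observations against the
            # fixed group structure; vectorised over all permutations.
            perms = rng.permuted(np.broadcast_to(y, (n_perm, n)).copy(), axis=1)
            onehot = np.zeros((n, a))
            onehot[np.arange(n), idx] = 1.0
            totals = perms @ onehot  # (n_perm, a)
            grand = y.sum()
            ss_total = ss_b + ss_w
            ss_b_perm = (totals**2 / sizes).sum(axis=1) - grand**2 / n
            ss_w_perm = ss_total - ss_b_perm
            f_perm = (ss_b_perm / df_b) / (ss_w_perm / df_w)
        else:
            f_perm = np.empty(n_perm)
            for k in range(n_perm):
                perm_idx = rng.permutation(idx)
                sb, sw = _distance_ss(d2, perm_idx, a)
                f_perm[k] = (sb / df_b) / (sw / df_w)
        p_perm = float((np.sum(f_perm >= f_obs) + 1) / (n_perm + 1))

    p_mc = float(stats.f.sf(f_obs, df_b, df_w))
    vb, vw, n0, eff = variance_components(ss_b / df_b, ss_w / df_w, sizes)
    return PermanovaResult(
        df_between=df_b,
        df_within=df_w,
        ss_between=ss_b,
        ss_within=ss_w,
        p_perm=p_perm,
        p_mc=p_mc,
        n0=n0,
        var_between=vb,
        var_within=vw,
        effect_size=eff,
    )


def variance_components(
    ms_between: float, ms_within: float, group_sizes: Sequence[int]
) -> tuple[float, float, float, float]:
    """Components of variation for an unbalanced one-way design.

    Returns ``(var_between, var_within, n0, effect_size)`` with the between
    component floored at zero before forming the effect-size ratio.
    """
    sizes = np.asarray(group_sizes, dtype=float)
    if np.any(sizes < 1):
        raise ValueError("every group needs at least one observation")
    n = sizes.sum()
    a = sizes.size
    if n <= a:
        raise ValueError("variance components undefined when N <= number of groups")
    n0 = (n - np.sum(sizes**2) / n) / (a - 1)
    var_within = float(ms_within)
    var_between = max(0.0, (ms_between - ms_within) / n0)
    effect = var_between / (var_between + var_within)
    return var_between, var_within, float(n0), float(effect)
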