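"""Statistical-significance feature screening.

Every feature column is tested for a class effect with a per-feature
univariate test — Student's pooled-variance two-sample t-test for two
classes, the one-way fixed-effects ANOVA F-test for three or more — and
kept when its two-sided p-value falls below the significance level
(default alpha = 0.05, strict inequality).  No multiple-testing
correction is applied by default, mirroring the raw per-feature screen
of the reference analysis; a Benjamini-Hochberg variant is available as
a clearly-marked extension.

Degenerate columns (zero variance in every group) get p = 1 when the
group means agree and p = 0 when they differ, so constant features are
never selected by numerical accident.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import FeatureMatrix, ValidationError

__all__ = ["SelectionResult", "pvalue_ttest", "pvalue_anova", "select_features"]


@dataclass
class SelectionResult:
    """Per-feature p-values and the significance mask at level alpha."""

    p_values: np.ndarray
    mask: np.ndarray
    test_used: str              # "ttest" or "anova"
    alpha: float
    names: tuple[str, ...] = ()

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    @property
    def selected_names(self) -> tuple[str, ...]:
        if not self.names:
            return ()
        return tuple(n for n, m in zip(self.names, self.mask) if m)


def _degenerate_p(groups: list[np.ndarray]) -> float:
    means = [float(np.mean(g)) for g in groups]
    return 1.0 if np.ptp(means) == 0.0 else 0.0


def pvalue_ttest(a: np.ndarray, b: np.ndarray, variant: str = "pooled") -> float:
    """Two-sided two-sample t-test p-value (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("t-test needs >= 2 observations per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return _degenerate_p([a, b])
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    p = float(res.pvalue)
    return p if np.isfinite(p) else _degenerate_p([a, b])


def pvalue_anova(groups: list[np.ndarray]) -> float:
    """One-way fixed-effects ANOVA F-test p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValidationError("ANOVA needs >= 2 observations per group")
    if all(np.var(g) == 0.0 for g in groups):
        return _degenerate_p(groups)
    res = stats.f_oneway(*groups)
    p = float(res.pvalue)
    return p if np.isfinite(p) else _degenerate_p(groups)


def _columnwise_pvalues(
    X: np.ndarray, groups_idx: list[np.ndarray], variant: str
) -> np.ndarray:
    """Vectorised per-column tests with degenerate-column conventions."""
    group_data = [X[idx] for idx in groups_idx]
    if len(group_data) == 2:
        res = stats.ttest_ind(
            group_data[0], group_data[1], axis=0, equal_var=(variant == "pooled")
        )
        p = np.asarray(res.pvalue, dtype=float)
    else:
        res = stats.f_oneway(*group_data, axis=0)
        p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if np.any(bad):
        for j in np.flatnonzero(bad):
            cols = [g[:, j] for g in group_data]
            if all(np.var(c) == 0.0 for c in cols):
                p[j] = _degenerate_p(cols)
            else:
                p[j] = 1.0  # numerically indeterminate: treat as no evidence
    return p


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


def select_features(
    fm: FeatureMatrix,
    alpha: float = 0.05,
    variant: str = "pooled",
    correction: str | None = None,
) -> SelectionResult:
    """Screen every feature column at level alpha.

    Two classes use the t-test, three or more the one-way ANOVA.  With
    ``correction="bh"`` the mask is applied to Benjamini-Hochberg-adjusted
    p-values (the reported p_values stay raw).
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    classes = fm.class_names
    if len(classes) < 2:
        raise ValidationError("selection needs >= 2 classes")
    labels = np.asarray(fm.labels)
    groups_idx = [np.flatnonzero(labels == c) for c in classes]
    for c, idx in zip(classes, groups_idx):
        if idx.size < 2:
            raise ValidationError(f"class {c!r} has fewer than 2 segments")
    p = _columnwise_pvalues(fm.values, groups_idx, variant)
    if correction == "bh":
        mask = _bh_adjust(p) < alpha
    elif correction is None:
        mask = p < alpha
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    test_used = "ttest" if len(classes) == 2 else "anova"
    return SelectionResult(p, mask, test_used, alpha, names=fm.names)
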