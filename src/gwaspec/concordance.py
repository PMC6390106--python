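"""Cross-disease sharing diagnostics: signed-logP concordance and conditional QQ.

Two views of how much genetic architecture two diseases share:

* the Pearson correlation of per-variant signed scores ±(−log10 P), signed by
  whether the minor allele increases risk in each disease, on an LD-pruned
  set of variants;
* conditional quantile-quantile plots — one disease's P values restricted to
  variants passing successively tighter association thresholds in the other —
  summarised per threshold by the median-based genomic inflation factor
  lambda = median(chi2_observed) / median(chi2_null), with
  chi2 = [Phi^-1(p/2)]^2.  Shared architecture shows as lambda growing while
  the conditioning threshold tightens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

log = logging.getLogger(__name__)

#: standard conditioning-threshold ladder, loosest first
DEFAULT_THRESHOLDS = (0.05, 0.01, 0.005, 0.001, 5e-4, 1e-4)

# median of chi-square(1): the null expectation of the median observed chi2
_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def signed_logp_concordance(harm: pd.DataFrame) -> tuple[float, float]:
    """Correlation of signed −log10 P scores between the two diseases.

    The sign of each disease's score is positive when the minor allele
    increases that disease's risk.  "Minor" is decided once, from disease A's
    effect-allele frequency (eaf_a <= 0.5 means the effect allele is the
    minor allele), so both scores refer to the same allele.

    Returns (Pearson r, two-sided P).  Requires at least 10 variants.
    """
    if len(harm) < 10:
        raise DataError("signed_logp_concordance: need at least 10 variants")
    minor_is_effect = (harm["eaf_a"] <= 0.5).to_numpy()
    flip = np.where(minor_is_effect, 1.0, -1.0)
    score_a = flip * np.sign(harm["beta_a"].to_numpy()) * (-np.log10(harm["p_a"].to_numpy()))
    score_b = flip * np.sign(harm["beta_b"].to_numpy()) * (-np.log10(harm["p_b"].to_numpy()))
    r, p = stats.pearsonr(score_a, score_b)
    return float(r), float(p)


def genomic_lambda(p_values: np.ndarray) -> float:
    """Median-based genomic inflation factor of a set of P values."""
    p = np.asarray(p_values, dtype=float)
    chi2 = stats.norm.isf(p / 2.0) ** 2
    return float(np.median(chi2) / _CHI2_MEDIAN)


@dataclass
class QQStratum:
    """One conditioning threshold's slice of a conditional QQ analysis."""

    threshold: float
    n: int
    observed: np.ndarray  # sorted observed -log10 P, ascending
    expected: np.ndarray  # -log10(i/(n+1)), ascending
    lam: float


@dataclass
class ConditionalQQResult:
    """Conditional QQ strata for one direction (condition on X, test Y)."""

    condition_on: str
    test: str
    strata: list[QQStratum]

    def lambdas(self) -> dict[float, float]:
        return {s.threshold: s.lam for s in self.strata}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            for e, o in zip(s.expected, s.observed):
                rows.append((self.condition_on, self.test, s.threshold,
                             s.n, e, o, s.lam))
        return pd.DataFrame(rows, columns=[
            "condition_on", "test", "threshold", "n", "expected", "observed",
            "lambda"])


def _qq_stratum(p_target: np.ndarray, threshold: float) -> QQStratum:
    n = len(p_target)
    observed = np.sort(-np.log10(p_target))
    expected = np.sort(-np.log10(np.arange(1, n + 1) / (n + 1)))
    return QQStratum(threshold=threshold, n=n, observed=observed,
                     expected=expected, lam=genomic_lambda(p_target))


def conditional_qq(harm: pd.DataFrame,
                   thresholds=DEFAULT_THRESHOLDS,
                   ) -> dict[str, ConditionalQQResult]:
    """Conditional QQ data for both directions on a pruned harmonised table.

    For each threshold t, the subset is the variants whose conditioning-
    disease P is below t; the target disease's P values in that subset give
    the observed quantiles, uniform order statistics −log10(i/(n+1)) the
    expected ones, and a median-based lambda the one-number summary.  Empty
    subsets are skipped with a log message.

    Returns ``{"A_on_B": ..., "B_on_A": ...}`` where ``A_on_B`` tests
    disease A's P values conditioned on disease B.
    """
    results = {}
    for cond, target, name in (("b", "a", "A_on_B"), ("a", "b", "B_on_A")):
        p_cond = harm[f"p_{cond}"].to_numpy()
        p_target = harm[f"p_{target}"].to_numpy()
        strata = []
        for t in thresholds:
            sel = p_cond < t
            if not sel.any():
                log.info("conditional_qq: empty subset at threshold %g "
                         "(condition on %s); skipped", t, cond.upper())
                continue
            strata.append(_qq_stratum(p_target[sel], t))
        results[name] = ConditionalQQResult(
            condition_on=cond.upper(), test=target.upper(), strata=strata)
    return results


def qq_lambda_table(results: dict[str, ConditionalQQResult]) -> pd.DataFrame:
    rows = [(r.condition_on, r.test, s.threshold, s.n, s.lam)
            for r in results.values() for s in r.strata]
    return pd.DataFrame(rows, columns=["condition_on", "test", "threshold",
                                       "n", "lambda"])


def plot_conditional_qq(results: dict[str, ConditionalQQResult], path) -> None:
    """Render the conditional QQ strata to a figure file (thin plotting layer)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results), figsize=(5 * len(results), 4.5))
    axes = np.atleast_1d(axes)
    for ax, (name, res) in zip(axes, results.items()):
        top = 0.0
        for s in res.strata:
            ax.plot(s.expected, s.observed, marker=".", ms=2, lw=1,
                    label=f"P<{s.threshold:g} (λ={s.lam:.2f})")
            top = max(top, s.expected.max(), s.observed.max())
        ax.plot([0, top], [0, top], color="red", lw=1)
        ax.set_xlabel("expected −log10 P")
        ax.set_ylabel(f"observed −log10 P ({res.test})")
        ax.set_title(f"{res.test} conditioned on {res.condition_on}")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
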