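"""Differential-expression screen: normalization, a conditioned
negative-binomial test, FDR adjustment, and the two-comparison candidate
screen with its elimination cascade.

The screen asks two questions of every gene: (A) is it differentially
expressed between wild type and the regulator-null mutant in stationary
phase, and (B) is it also differentially expressed between stationary-phase
and young wild-type cultures (i.e. co-regulated with antibiotic
production)?  Genes passing (A) at the fold-change/q-value thresholds are
candidates; candidates flat in (B) are eliminated as not
production-dependent.

The testing machinery is a deliberately simple re-implementation of the
classic count-based exact-test workflow: median-of-ratios size factors, a
method-of-moments dispersion estimate floored by a 1/mean trend, and a
test that conditions on the total count of the two conditions and sums the
probabilities of outcomes at least as extreme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountTable

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "nb_conditioned_test",
    "bh_adjust",
    "de_test",
    "candidate_screen",
    "DEResult",
]

STATUS_KNOWN = "known_target"
STATUS_REGULATOR = "soxR"
STATUS_NOVEL = "novel_candidate"
STATUS_ELIMINATED = "eliminated_not_act_dependent"


@dataclass
class DEResult:
    """Per-gene DE summary for one comparison.

    ``table`` columns: mean_num, mean_den, fc, p, q.  ``fc`` is the ratio
    of mean normalized counts, numerator condition first (``orientation``
    records which condition is the numerator).
    """

    table: pd.DataFrame
    orientation: tuple[str, str]  # (numerator condition, denominator condition)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, ``s_j = median_i k_ij / (prod_v k_iv)**(1/m)`` over
    genes whose geometric mean across samples is positive.
    """
    k = table.counts.to_numpy(dtype=float)
    positive = (k > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample; cannot normalize")
    logk = np.log(k[positive])
    log_geomean = logk.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logk - log_geomean, axis=0))
    return pd.Series(s, index=table.samples, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(
    table: CountTable,
    sf: pd.Series,
    design: dict[str, str] | None = None,
    pool_all: bool = False,
) -> pd.Series:
    """Per-gene NB dispersion phi (variance = mu + phi * mu**2).

    Method-of-moments on normalized counts within replicate groups:
    ``phi_hat_i = max(0, (v_i - m_i) / m_i**2)`` with ``v_i`` the pooled
    within-group variance and ``m_i`` the overall mean; a mean-dispersion
    trend ``phi(m) = a1/m + a0`` is fit by least squares and the final
    estimate is the conservative ``max(phi_hat_i, phi(m_i))``.

    When any contrasted condition has a single sample (or ``pool_all``),
    the two conditions are pooled into one group for estimation — a
    "blind" estimate that is conservative because real signal inflates the
    apparent variance.
    """
    design = design or table.conditions
    z = table.counts.to_numpy(dtype=float) / sf.loc[table.samples].to_numpy()
    groups: list[list[int]] = []
    conds = sorted(set(design[s] for s in table.samples))
    for c in conds:
        groups.append([i for i, s in enumerate(table.samples) if design[s] == c])
    if pool_all or any(len(g) < 2 for g in groups):
        if not pool_all:
            warnings.warn(
                "a condition has no replicates: pooling both conditions for a "
                "blind (conservative) dispersion estimate",
                stacklevel=2,
            )
        groups = [list(range(len(table.samples)))]
    if sum(len(g) for g in groups) < 2:
        raise ValueError("dispersion estimation needs at least two samples")

    m = z.mean(axis=1)
    if not (m > 0).any():
        raise ValueError("all genes have zero counts")
    # pooled within-group variance
    ss = np.zeros(z.shape[0])
    dof = 0
    for g in groups:
        if len(g) < 2:
            continue
        sub = z[:, g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += len(g) - 1
    v = ss / max(dof, 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_hat = np.where(m > 0, np.maximum(0.0, (v - m) / m**2), 0.0)

    # least-squares fit of phi(m) = a1/m + a0 over genes with positive mean
    ok = m > 0
    X = np.column_stack([1.0 / m[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, phi_hat[ok], rcond=None)
    a1, a0 = coef
    with np.errstate(divide="ignore"):
        trend = np.where(m > 0, np.maximum(0.0, a1 / np.where(m > 0, m, 1.0) + a0), 0.0)
    phi = np.maximum(phi_hat, trend)
    return pd.Series(phi, index=table.genes, name="dispersion")


# ---------------------------------------------------------------------------
# conditioned NB test
# ---------------------------------------------------------------------------

def _condition_sum_params(
    counts: np.ndarray, sf: np.ndarray, mu_hat: float, phi: float
) -> tuple[float, float]:
    """Moment-matched mean and variance of a condition's count sum."""
    mean = mu_hat * sf.sum()
    var = (mu_hat * sf + phi * (mu_hat * sf) ** 2).sum()
    return mean, var


def _sum_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log pmf of a count sum: NB moment-matched, Poisson when var <= mean."""
    if var <= mean * (1 + 1e-12):
        return stats.poisson.logpmf(k, mean)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def nb_conditioned_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    phi: float,
) -> float:
    """Two-sided test of equal means, conditioning on the total count.

    With ``K_A`` and ``K_B`` the condition count sums modeled as NB
    (moment-matched means/variances under the pooled mean estimate), the
    p-value is::

        p = sum_{a+b=k_S, P(a)P(b) <= P(k_A)P(k_B)} P(a)P(b)
            / sum_{a+b=k_S} P(a)P(b)

    which reduces to the conditional binomial (exact Poisson) test at
    ``phi = 0``.  Exhaustive over the k_S + 1 splits, so exact.
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    for c in (counts_a, counts_b):
        if not np.allclose(c, np.round(c)) or (c < 0).any():
            raise ValueError("counts must be non-negative integers")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    sf_a = np.asarray(sf_a, dtype=float)
    sf_b = np.asarray(sf_b, dtype=float)

    k_a = int(counts_a.sum())
    k_b = int(counts_b.sum())
    k_s = k_a + k_b
    if k_s == 0:
        return 1.0
    mu_hat = k_s / (sf_a.sum() + sf_b.sum())
    mean_a, var_a = _condition_sum_params(counts_a, sf_a, mu_hat, phi)
    mean_b, var_b = _condition_sum_params(counts_b, sf_b, mu_hat, phi)

    a = np.arange(k_s + 1)
    logp = _sum_logpmf(a, mean_a, var_a) + _sum_logpmf(k_s - a, mean_b, var_b)
    log_obs = logp[k_a]
    logp_max = logp.max()
    w = np.exp(logp - logp_max)
    # include all splits no more probable than the observed one (tiny
    # tolerance guards against log-pmf rounding at exactly-tied splits)
    include = logp <= log_obs + 1e-9
    p = w[include].sum() / w.sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)``, clipped at 1, mapped back to
    the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# whole-table test
# ---------------------------------------------------------------------------

def de_test(
    table: CountTable,
    condition_num: str,
    condition_den: str,
    phi: pd.Series | None = None,
) -> DEResult:
    """Run the conditioned NB test for every gene on one contrast.

    Fold change is the ratio of mean normalized counts
    (``condition_num`` / ``condition_den``); when either mean is zero,
    0.5 is added to both means before forming the ratio.
    """
    sf = size_factors(table)
    samples_num = table.samples_of(condition_num)
    samples_den = table.samples_of(condition_den)
    if not samples_num or not samples_den:
        raise ValueError(f"no samples for contrast {condition_num} vs {condition_den}")
    if phi is None:
        phi = estimate_dispersion(table, sf)

    k = table.counts
    z = k / sf
    mean_num = z[samples_num].mean(axis=1)
    mean_den = z[samples_den].mean(axis=1)
    zero = (mean_num == 0) | (mean_den == 0)
    fc = (mean_num + 0.5 * zero) / (mean_den + 0.5 * zero)

    sf_num = sf.loc[samples_num].to_numpy()
    sf_den = sf.loc[samples_den].to_numpy()
    pvals = np.empty(len(table.genes))
    kn = k[samples_num].to_numpy()
    kd = k[samples_den].to_numpy()
    for i, gene in enumerate(table.genes):
        pvals[i] = nb_conditioned_test(kn[i], kd[i], sf_num, sf_den, float(phi.loc[gene]))
    q = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "mean_num": mean_num,
            "mean_den": mean_den,
            "fc": fc,
            "p": pvals,
            "q": q,
        },
        index=table.genes,
    )
    return DEResult(table=out, orientation=(condition_num, condition_den))


# ---------------------------------------------------------------------------
# candidate screen
# ---------------------------------------------------------------------------

def candidate_screen(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    known_targets: list[str],
    regulator_id: str,
    tau_fc: float = 4.0,
    tau_q: float = 0.5,
    tau_act: float = 1.0,
) -> pd.DataFrame:
    """Two-criteria candidate screen with the elimination cascade.

    ``de_a`` / ``de_b`` are indexed by gene with columns ``fc`` and ``q``
    (comparison A: wild type vs regulator-null, stationary phase;
    comparison B: wild-type stationary phase vs early growth).  A gene
    passes the screen iff ``fc_a >= tau_fc`` and ``q_a <= tau_q``.
    Passing genes partition into known targets, the regulator itself, and
    novel candidates; a novel candidate is eliminated as not
    production-dependent iff ``fc_b <= tau_act``.

    Returns a table sorted by descending ``fc_a`` (ties: gene id) with a
    ``status`` column.
    """
    universe_a = set(de_a.index)
    universe_b = set(de_b.index)
    if universe_a != universe_b:
        raise ValueError(
            "comparisons cover different gene universes; "
            f"only in A: {sorted(universe_a - universe_b)}; "
            f"only in B: {sorted(universe_b - universe_a)}"
        )
    known = set(known_targets)
    rows = []
    for gene in de_a.index:
        fc_a, q_a = float(de_a.loc[gene, "fc"]), float(de_a.loc[gene, "q"])
        fc_b, q_b = float(de_b.loc[gene, "fc"]), float(de_b.loc[gene, "q"])
        if not (fc_a >= tau_fc and q_a <= tau_q):
            continue
        if gene == regulator_id:
            status = STATUS_REGULATOR
        elif gene in known:
            status = STATUS_KNOWN
        elif fc_b <= tau_act:
            status = STATUS_ELIMINATED
        else:
            status = STATUS_NOVEL
        rows.append(
            {"gene": gene, "status": status, "fc_a": fc_a, "q_a": q_a, "fc_b": fc_b, "q_b": q_b}
        )
    out = pd.DataFrame(rows, columns=["gene", "status", "fc_a", "q_a", "fc_b", "q_b"])
    if not out.empty:
        out = out.sort_values(["fc_a", "gene"], ascending=[False, True], kind="stable")
        out = out.reset_index(drop=True)
    return out
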