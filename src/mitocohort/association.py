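"""Cohort-level association statistics.

Implements the case-control and symptom association layer: Fisher exact
tests per haplogroup with exact-conditional confidence intervals, an
overall haplogroup-distribution test (exact enumeration or Monte Carlo
over tables with fixed margins), Benjamini–Hochberg FDR, missingness/
minor-allele-frequency site filtering, covariate-adjusted single-marker
regressions (linear for quantitative phenotypes, logistic for binary),
marker × phenotype scans with per-phenotype FDR families, the
Kolmogorov–Smirnov comparison of per-individual pathogenicity burdens,
and generic stratified re-analysis.

Conventions
-----------
* Odds ratio: the sample cross-product ratio ``a·d / b·c`` (undefined
  and reported as ``None`` when a zero cell makes it degenerate); the
  conditional maximum-likelihood estimate is computed alongside.
* Two-sided Fisher p: probability-mass ordering — the sum of
  probabilities of all tables with fixed margins no more likely than
  the observed one.
* 95% CI: inversion of the noncentral hypergeometric likelihood
  (exact conditional, alpha/2 per tail).
* BH: standard step-up — sort p ascending, scale by m/rank, enforce the
  running minimum from the largest rank down, cap at 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .errors import DegenerateFitError, InputContractError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a = exposed cases, b = exposed controls, c/d their unexposed counterparts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputContractError("contingency cells must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise InputContractError("empty contingency table")


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float | None
    p: float
    ci_low: float | None
    ci_high: float | None
    cmle_odds_ratio: float


@dataclass(frozen=True)
class OverallTestResult:
    p: float
    method: str          # "exact" | "monte-carlo"
    mc_se: float | None  # standard error of the Monte Carlo estimate


@dataclass
class AssociationResult:
    test_id: str
    model: str            # "linear" | "logistic"
    effect: float         # coefficient (linear) or odds ratio (logistic)
    ci_low: float
    ci_high: float
    p: float
    n: int
    q: float | None = None


def _nchg(t: ContingencyTable2x2):
    n = t.a + t.b + t.c + t.d
    return n, t.a + t.b, t.a + t.c  # total, exposed margin, case margin


def fisher_2x2(t: ContingencyTable2x2, alpha: float = 0.05) -> FisherResult:
    """Fisher exact test with sample OR, exact-conditional CI and CMLE."""
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    if t.a * t.d == 0 or t.b * t.c == 0:
        odds_ratio = None
        ci_low = ci_high = None
    else:
        odds_ratio = (t.a * t.d) / (t.b * t.c)
        ci_low, ci_high = _exact_ci(t, alpha)
    return FisherResult(
        odds_ratio=odds_ratio,
        p=float(p),
        ci_low=ci_low,
        ci_high=ci_high,
        cmle_odds_ratio=_cmle(t),
    )


def _support(t: ContingencyTable2x2) -> tuple[int, int]:
    n, K, N = _nchg(t)
    return max(0, K + N - n), min(K, N)


def _nchg_weights(t: ContingencyTable2x2, log_psi: float):
    """Support and normalized log-probabilities of the noncentral
    hypergeometric distribution of cell ``a`` given the margins.

    Computed in log space over the (small) support, which stays stable
    at extreme odds where generic distribution machinery overflows.
    """
    n, K, N = _nchg(t)
    lo_sup, hi_sup = _support(t)
    k = np.arange(lo_sup, hi_sup + 1)
    logw = (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(n - K + 1) - gammaln(N - k + 1) - gammaln(n - K - N + k + 1)
        + k * log_psi
    )
    logw -= logsumexp(logw)
    return k, logw


def _exact_ci(t: ContingencyTable2x2, alpha: float) -> tuple[float, float]:
    lo_sup, hi_sup = _support(t)
    a = t.a

    def sf(log_psi: float) -> float:  # P(X >= a | psi)
        k, logw = _nchg_weights(t, log_psi)
        return float(np.exp(logsumexp(logw[k >= a])))

    def cdf(log_psi: float) -> float:  # P(X <= a | psi)
        k, logw = _nchg_weights(t, log_psi)
        return float(np.exp(logsumexp(logw[k <= a])))

    if a == lo_sup:
        lower = 0.0
    else:
        lower = float(np.exp(optimize.brentq(
            lambda lg: sf(lg) - alpha / 2, -40.0, 40.0, xtol=1e-12)))
    if a == hi_sup:
        upper = float("inf")
    else:
        upper = float(np.exp(optimize.brentq(
            lambda lg: cdf(lg) - alpha / 2, -40.0, 40.0, xtol=1e-12)))
    return lower, upper


def _cmle(t: ContingencyTable2x2) -> float:
    lo_sup, hi_sup = _support(t)
    if t.a == lo_sup:
        return 0.0
    if t.a == hi_sup:
        return float("inf")

    def mean_minus_a(log_psi: float) -> float:
        k, logw = _nchg_weights(t, log_psi)
        return float(np.sum(k * np.exp(logw))) - t.a

    return float(np.exp(optimize.brentq(mean_minus_a, -40.0, 40.0, xtol=1e-12)))


def _log_table_prob(col1, row_margins, n, c1) -> float:
    # P(table | fixed margins) for an r x 2 table, column-1 entries col1
    col1 = np.asarray(col1)
    row_margins = np.asarray(row_margins)
    return float(
        gammaln(row_margins + 1).sum()
        - gammaln(col1 + 1).sum()
        - gammaln(row_margins - col1 + 1).sum()
        + gammaln(c1 + 1)
        + gammaln(n - c1 + 1)
        - gammaln(n + 1)
    )


def _enumerate_rx2(row_margins, c1):
    """Yield all column-1 fill vectors of r x 2 tables with fixed margins."""
    r = len(row_margins)
    tail = [0] * (r + 1)
    for i in range(r - 1, -1, -1):
        tail[i] = tail[i + 1] + row_margins[i]

    def rec(i, remaining, prefix):
        if i == r:
            if remaining == 0:
                yield tuple(prefix)
            return
        lo = max(0, remaining - tail[i + 1])
        hi = min(row_margins[i], remaining)
        for v in range(lo, hi + 1):
            yield from rec(i + 1, remaining - v, prefix + [v])

    yield from rec(0, c1, [])


def overall_distribution_test(
    counts,
    exact_limit: int = 60,
    n_mc: int = 100_000,
    seed: int = 0,
) -> OverallTestResult:
    """Exact test of homogeneity for an r x 2 count table.

    Enumerates all tables with the observed margins when the total is
    at most ``exact_limit`` (probability-mass ordering, as in the 2x2
    case); otherwise estimates the p-value by Monte Carlo over
    ``n_mc`` tables drawn from the fixed-margin null (Patefield's
    algorithm), reporting the binomial standard error.
    """
    table = np.asarray(counts, dtype=np.int64)
    if table.ndim != 2 or table.shape[1] != 2:
        raise InputContractError("counts must be an r x 2 table")
    if table.shape[0] < 2:
        raise InputContractError("need at least two haplogroup rows")
    if (table < 0).any():
        raise InputContractError("negative counts")
    row_margins = table.sum(axis=1)
    keep = row_margins > 0
    table = table[keep]
    row_margins = row_margins[keep]
    n = int(table.sum())
    c1 = int(table[:, 0].sum())
    obs_logp = _log_table_prob(table[:, 0], row_margins, n, c1)
    tol = 1e-9 * abs(obs_logp) + 1e-12
    if n <= exact_limit:
        total = 0.0
        for col1 in _enumerate_rx2(row_margins.tolist(), c1):
            lp = _log_table_prob(col1, row_margins, n, c1)
            if lp <= obs_logp + tol:
                total += np.exp(lp)
        return OverallTestResult(p=min(float(total), 1.0), method="exact", mc_se=None)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row_margins, [c1, n - c1])
    draws = sampler.rvs(n_mc, method="patefield", random_state=rng)
    col1 = draws[..., 0]
    lgm = gammaln(row_margins + 1).sum() + gammaln(c1 + 1) + gammaln(n - c1 + 1) - gammaln(n + 1)
    lps = lgm - gammaln(col1 + 1).sum(axis=-1) - gammaln(
        row_margins[None, :] - col1 + 1
    ).sum(axis=-1)
    p = float(np.mean(lps <= obs_logp + tol))
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return OverallTestResult(p=p, method="monte-carlo", mc_se=se)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg q-values, returned in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputContractError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def genotype_matrix(profiles, reference, sites=None) -> pd.DataFrame:
    """Individuals × sites allele matrix from consensus profiles.

    Sites are variant tokens like ``"1234G"``; by default the union of
    all variants observed across the cohort. Entries: 1 if the
    individual's consensus carries the alternate allele, 0 if it was
    called as something else, NaN if the position is missing.
    """
    from .consensus import MISSING, extract_variants
    from .genome import format_variant_token, parse_variant_token

    profiles = list(profiles)
    if sites is None:
        tokens = sorted(
            {
                format_variant_token(pos, allele)
                for p in profiles
                for pos, allele in extract_variants(p, reference).variants
            },
            key=lambda t: parse_variant_token(t),
        )
    else:
        tokens = list(sites)
    parsed = [parse_variant_token(t) for t in tokens]
    data = np.empty((len(profiles), len(tokens)))
    for i, prof in enumerate(profiles):
        for j, (pos, alt) in enumerate(parsed):
            code = prof.alleles[pos - 1]
            if code == MISSING:
                data[i, j] = np.nan
            else:
                data[i, j] = 1.0 if prof.allele_at(pos) == alt else 0.0
    frame = pd.DataFrame(
        data, index=[p.individual_id for p in profiles], columns=tokens
    )
    frame.index.name = "individual_id"
    return frame


def site_statistics(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-site missingness fraction and minor-allele frequency.

    ``genotypes`` is an individuals × sites frame with entries 1
    (alternate), 0 (reference) and NaN (missing).
    """
    missingness = genotypes.isna().mean()
    alt_freq = genotypes.mean(skipna=True)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    return pd.DataFrame({"missingness": missingness, "maf": maf})


def filter_sites(
    genotypes: pd.DataFrame,
    max_missing: float = 0.10,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Drop sites above the missingness cap or below the MAF floor."""
    stats_ = site_statistics(genotypes)
    keep = (stats_["missingness"] <= max_missing) & (stats_["maf"] >= min_maf)
    return genotypes.loc[:, keep[keep].index]


def _prepare_design(alleles, phenotype, covariates):
    data = pd.DataFrame({"allele": alleles, "phenotype": phenotype})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reindex(data.index)
        data = pd.concat([data, cov], axis=1)
    data = data.dropna()
    y = data["phenotype"].astype(float)
    X = data.drop(columns=["phenotype"]).astype(float)
    # drop covariate columns made constant by subsetting (keeps design full rank)
    constant = [c for c in X.columns if c != "allele" and X[c].nunique() <= 1]
    X = X.drop(columns=constant)
    X = sm.add_constant(X, has_constant="add")
    return y, X


def single_marker_test(
    alleles,
    phenotype,
    covariates=None,
    test_id: str = "",
    min_n: int = 10,
) -> AssociationResult:
    """Covariate-adjusted association of one site with one phenotype.

    Quantitative phenotypes (> 2 distinct values) are fit by ordinary
    least squares; binary phenotypes by maximum-likelihood logistic
    regression, with the effect reported as an odds ratio. The p-value
    is the Wald test on the allele coefficient. Individuals missing the
    allele, the phenotype or any covariate are dropped.
    """
    y, X = _prepare_design(alleles, phenotype, covariates)
    n = len(y)
    if n < min_n:
        raise DegenerateFitError(f"{test_id}: only {n} complete observations")
    if y.nunique() <= 1:
        raise DegenerateFitError(f"{test_id}: phenotype is constant")
    if X["allele"].nunique() <= 1:
        raise DegenerateFitError(f"{test_id}: allele column is constant")
    binary = y.nunique() == 2
    if binary:
        y = (y == y.max()).astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception as exc:
            raise DegenerateFitError(f"{test_id}: logistic fit failed ({exc})") from exc
        if not fit.mle_retvals.get("converged", False):
            raise DegenerateFitError(f"{test_id}: logistic fit did not converge")
        if abs(fit.params["allele"]) > 15:
            raise DegenerateFitError(f"{test_id}: separation in logistic fit")
        beta = float(fit.params["allele"])
        lo, hi = fit.conf_int().loc["allele"]
        return AssociationResult(
            test_id=test_id,
            model="logistic",
            effect=float(np.exp(beta)),
            ci_low=float(np.exp(lo)),
            ci_high=float(np.exp(hi)),
            p=float(fit.pvalues["allele"]),
            n=n,
        )
    fit = sm.OLS(y, X).fit()
    lo, hi = fit.conf_int().loc["allele"]
    return AssociationResult(
        test_id=test_id,
        model="linear",
        effect=float(fit.params["allele"]),
        ci_low=float(lo),
        ci_high=float(hi),
        p=float(fit.pvalues["allele"]),
        n=n,
    )


def marker_phenotype_scan(
    markers: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Test every marker against every phenotype with per-phenotype FDR.

    One regression per (marker, phenotype) pair; BH is applied within
    each phenotype across the markers (the FDR family is the marker
    set, never the phenotype set — related symptoms are not corrected
    against each other). Degenerate fits are skipped and logged.
    Returns a tidy frame with columns marker, phenotype, model, effect,
    CI bounds, n, p, q, significant.
    """
    if markers.shape[1] < 1:
        raise InputContractError("no marker columns to test")
    rows = []
    for phen in phenotypes.columns:
        fam: list[dict] = []
        for marker in markers.columns:
            try:
                res = single_marker_test(
                    markers[marker],
                    phenotypes[phen],
                    covariates,
                    test_id=f"{marker}~{phen}",
                )
            except DegenerateFitError as exc:
                logger.warning("skipped %s ~ %s: %s", marker, phen, exc)
                continue
            fam.append(
                {
                    "marker": marker,
                    "phenotype": phen,
                    "model": res.model,
                    "effect": res.effect,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n": res.n,
                    "p": res.p,
                }
            )
        if fam:
            qs = bh_adjust([r["p"] for r in fam])
            for r, q in zip(fam, qs):
                r["q"] = float(q)
                r["significant"] = bool(q <= fdr)
            rows.extend(fam)
    return pd.DataFrame(
        rows,
        columns=[
            "marker", "phenotype", "model", "effect", "ci_low", "ci_high",
            "n", "p", "q", "significant",
        ],
    )


def haplogroup_symptom_scan(
    indicators: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Haplogroup-indicator × symptom scan (per-phenotype FDR over clades)."""
    return marker_phenotype_scan(indicators, phenotypes, covariates, fdr=fdr)


def pathogenicity_burden_test(scores_a, scores_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov comparison of per-individual mean scores.

    Returns ``(statistic, two-sided asymptotic p)``.
    """
    a = np.asarray([s for s in scores_a if s is not None], dtype=float)
    b = np.asarray([s for s in scores_b if s is not None], dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputContractError("both score groups must be nonempty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def stratified_run(strata, analysis, min_size: int = 10) -> dict:
    """Re-run an analysis independently within each stratum.

    ``strata`` maps individual ids to stratum labels (a pandas Series);
    ``analysis`` is a callable receiving the index of one stratum's
    individuals and returning that stratum's result table. Filters
    inside ``analysis`` are therefore recomputed within-stratum. Strata
    smaller than ``min_size`` are skipped with a log entry; if every
    stratum is too small an error is raised.
    """
    strata = pd.Series(strata)
    results: dict = {}
    for level, idx in strata.groupby(strata).groups.items():
        if len(idx) < min_size:
            logger.warning(
                "stratum %r skipped: %d individuals < %d", level, len(idx), min_size
            )
            continue
        results[level] = analysis(list(idx))
    if not results:
        raise InputContractError("all strata below the minimum size")
    return results
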