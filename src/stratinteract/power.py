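"""Analytic and Monte-Carlo power for the stratified interaction screens.

A :class:`Scenario` fixes the true per-stratum additive effects (in SD
units of the inverse-normal-transformed trait), the allele frequency and
the per-stratum sample sizes; the sampling SE of each stratum estimate for
a unit-variance trait is ``1 / sqrt(2 maf (1-maf) n)``.  All screen
statistics are deterministic functions of the four independent stratum
estimates, so two-way power is available in closed form (a shifted normal,
or a bivariate-normal rectangle when the a-priori filter on the overall
association is active) and arbitrary unions of screens are evaluated by
Monte Carlo over the joint sampling distribution.

Effect sizes may equivalently be stated as explained variance:
``R^2 = 2 maf (1-maf) b^2`` for a unit-variance phenotype.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .sumstats import STRATA

#: default significance levels: filtered screens test far fewer markers
DEFAULT_ALPHA_FILTERED = 1e-5
DEFAULT_ALPHA_UNFILTERED = 5e-8


def expected_se(maf: float, n: float) -> float:
    """Sampling SE of an additive per-allele effect on a unit-variance trait."""
    if not 0.0 < maf < 1.0:
        raise ValueError(f"maf must be in (0, 1), got {maf}")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def beta_from_r2(r2: float, maf: float) -> float:
    """|b| explaining the fraction ``r2`` of a unit-variance phenotype."""
    return float(np.sqrt(r2 / (2.0 * maf * (1.0 - maf))))


def r2_from_beta(beta: float, maf: float) -> float:
    return float(2.0 * maf * (1.0 - maf) * beta**2)


@dataclasses.dataclass
class Scenario:
    """A four-stratum true-effect configuration.

    ``betas`` and ``n`` follow the stratum order
    ``(M_le50, M_gt50, F_le50, F_gt50)``.
    """

    betas: tuple[float, float, float, float]
    maf: float = 0.5
    n: tuple[float, float, float, float] = (75_000,) * 4
    name: str = ""
    description: str = ""

    @classmethod
    def equal_strata(cls, betas, total_n: float = 300_000, maf: float = 0.5,
                     name: str = "", description: str = "") -> "Scenario":
        return cls(betas=tuple(float(b) for b in betas), maf=maf,
                   n=(total_n / 4.0,) * 4, name=name, description=description)

    @property
    def ses(self) -> np.ndarray:
        return np.array([expected_se(self.maf, ni) for ni in self.n])

    @property
    def total_n(self) -> float:
        return float(sum(self.n))

    def scaled_to(self, total_n: float) -> "Scenario":
        """Same shape with all strata rescaled to a new total sample size."""
        factor = total_n / self.total_n
        return dataclasses.replace(self, n=tuple(ni * factor for ni in self.n))

    def beta_dict(self) -> dict[str, float]:
        return dict(zip(STRATA, self.betas))


# --- linear contrasts over the four stratum estimates -----------------------

def _ivw_weights(ses: np.ndarray, members: tuple[int, ...]) -> np.ndarray:
    """Coefficient vector of the IVW pool of a stratum subset."""
    c = np.zeros(4)
    w = 1.0 / ses[list(members)] ** 2
    c[list(members)] = w / w.sum()
    return c

# stratum index order: 0 M_le50, 1 M_gt50, 2 F_le50, 3 F_gt50
_LE50, _GT50 = (0, 2), (1, 3)
_MEN, _WOMEN = (0, 1), (2, 3)


def _contrast_and_denominator(test: str, ses: np.ndarray, r: float):
    """Contrast coefficients c (statistic numerator c.b_hat) and the test's
    denominator, as printed in the screen definitions."""
    if test == "agediff":
        c = _ivw_weights(ses, _LE50) - _ivw_weights(ses, _GT50)
        se_a = 1.0 / np.sqrt(np.sum(1.0 / ses[list(_LE50)] ** 2))
        se_b = 1.0 / np.sqrt(np.sum(1.0 / ses[list(_GT50)] ** 2))
        den = np.sqrt(se_a**2 + se_b**2 - 2.0 * r * se_a * se_b)
    elif test == "sexdiff":
        c = _ivw_weights(ses, _MEN) - _ivw_weights(ses, _WOMEN)
        se_a = 1.0 / np.sqrt(np.sum(1.0 / ses[list(_MEN)] ** 2))
        se_b = 1.0 / np.sqrt(np.sum(1.0 / ses[list(_WOMEN)] ** 2))
        den = np.sqrt(se_a**2 + se_b**2 - 2.0 * r * se_a * se_b)
    elif test == "agesexdiff":
        c = np.array([1.0, -1.0, -1.0, 1.0])  # (Ml - Fl) - (Mg - Fg)
        den = np.sqrt(np.sum(ses**2))
    elif test == "overall":
        c = _ivw_weights(ses, (0, 1, 2, 3))
        den = 1.0 / np.sqrt(np.sum(1.0 / ses**2))
    else:
        raise ValueError(f"unknown test {test!r}")
    return c, float(den)


def _statistic_moments(scenario: Scenario, test: str, r: float):
    """Mean and SD of the screen's Z statistic under the scenario."""
    ses = scenario.ses
    b = np.asarray(scenario.betas)
    c, den = _contrast_and_denominator(test, ses, r)
    mu = float(c @ b) / den
    sd = float(np.sqrt(np.sum((c * ses) ** 2))) / den
    return mu, sd


def _both_tails_prob(mu, sd, rho, c1, c2) -> float:
    """P(|Z1| > c1 and |Z2| > c2) for bivariate normal (Z1, Z2)."""
    total = 0.0
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            m = np.array([s1 * mu[0], s2 * mu[1]])
            cov = np.array([[sd[0] ** 2, s1 * s2 * rho * sd[0] * sd[1]],
                            [s1 * s2 * rho * sd[0] * sd[1], sd[1] ** 2]])
            # P(s1 Z1 > c1, s2 Z2 > c2) = F(-c1, -c2) under negated means
            total += stats.multivariate_normal.cdf(
                [-c1, -c2], mean=-m, cov=cov, allow_singular=True)
    return float(min(max(total, 0.0), 1.0))


def screen_power(scenario: Scenario, test: str, alpha: float,
                 prefilter: float | None = None, r: float = 0.0) -> float:
    """Analytic power of one screen under a scenario.

    Without the a-priori filter this is the two-sided normal (or, for the
    joint test, noncentral chi-square) tail beyond the alpha quantile,
    shifted by the statistic's noncentrality.  With the filter it is the
    bivariate-normal probability that the overall Z exceeds the filter
    quantile *and* the difference Z exceeds the alpha quantile, with their
    correlation derived from the IVW weights (the strata being independent).

    ``r`` is the between-group effect correlation used in the difference
    denominators; for a single planted scenario the default 0 applies.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if test == "joint":
        ses = scenario.ses
        ncp = float(np.sum((np.asarray(scenario.betas) / ses) ** 2))
        crit = stats.chi2.isf(alpha, df=4)
        power = float(stats.ncx2.sf(crit, df=4, nc=ncp))
        if prefilter is not None:
            raise NotImplementedError("prefilter is defined for difference tests")
        return power

    z_alpha = stats.norm.isf(alpha / 2.0)
    mu_d, sd_d = _statistic_moments(scenario, test, r)
    if prefilter is None:
        return float(stats.norm.sf((z_alpha - mu_d) / sd_d)
                     + stats.norm.cdf((-z_alpha - mu_d) / sd_d))

    ses = scenario.ses
    b = np.asarray(scenario.betas)
    c_d, den_d = _contrast_and_denominator(test, ses, r)
    c_o, den_o = _contrast_and_denominator("overall", ses, 0.0)
    mu = np.array([(c_o @ b) / den_o, (c_d @ b) / den_d])
    var = np.array([np.sum((c_o * ses) ** 2) / den_o**2,
                    np.sum((c_d * ses) ** 2) / den_d**2])
    cov = float(np.sum(c_o * c_d * ses**2) / (den_o * den_d))
    sd = np.sqrt(var)
    rho = cov / (sd[0] * sd[1]) if sd[0] * sd[1] > 0 else 0.0
    z_filter = stats.norm.isf(prefilter / 2.0)
    return _both_tails_prob(mu, sd, rho, z_filter, z_alpha)


def simulate_stratum_estimates(scenario: Scenario, n_replicates: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Draw stratum effect estimates from their sampling distribution;
    shape (n_replicates, 4)."""
    ses = scenario.ses
    return rng.normal(np.asarray(scenario.betas), ses,
                      size=(n_replicates, 4))


def _mc_rejections(est: np.ndarray, scenario: Scenario, test: str,
                   alpha: float, prefilter: float | None, r: float) -> np.ndarray:
    ses = scenario.ses
    if test == "joint":
        chi2 = np.sum((est / ses) ** 2, axis=1)
        reject = chi2 > stats.chi2.isf(alpha, df=4)
    else:
        c, den = _contrast_and_denominator(test, ses, r)
        z = est @ c / den
        reject = np.abs(z) > stats.norm.isf(alpha / 2.0)
    if prefilter is not None:
        c_o, den_o = _contrast_and_denominator("overall", ses, 0.0)
        z_o = est @ c_o / den_o
        reject &= np.abs(z_o) > stats.norm.isf(prefilter / 2.0)
    return reject


def mc_power(scenario: Scenario, test: str, alpha: float,
             prefilter: float | None = None, r: float = 0.0,
             n_replicates: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo power of one screen (independent check on the analytic
    form, and the only route for the joint-with-filter combination)."""
    rng = np.random.default_rng(seed)
    est = simulate_stratum_estimates(scenario, n_replicates, rng)
    return float(_mc_rejections(est, scenario, test, alpha, prefilter, r).mean())


def union_power(scenario: Scenario, screens: list[dict],
                n_replicates: int = 100_000, seed: int = 0) -> float:
    """Probability that at least one screen rejects.

    Each screen is a dict with keys ``test``, ``alpha`` and optionally
    ``prefilter`` and ``r``.  All screens are evaluated on the same drawn
    stratum estimates, respecting their full dependence.
    """
    if not screens:
        raise ValueError("need at least one screen")
    rng = np.random.default_rng(seed)
    est = simulate_stratum_estimates(scenario, n_replicates, rng)
    any_reject = np.zeros(n_replicates, dtype=bool)
    for spec in screens:
        any_reject |= _mc_rejections(
            est, scenario, spec["test"], spec["alpha"],
            spec.get("prefilter"), spec.get("r", 0.0))
    return float(any_reject.mean())


def required_n(scenario: Scenario, test: str, alpha: float,
               target_power: float = 0.8, prefilter: float | None = None,
               r: float = 0.0, resolution: int = 1_000,
               max_total_n: float = 20_000_000) -> float:
    """Smallest total sample size reaching the target power.

    The scenario shape (relative stratum sizes and effects) is held fixed
    and all strata scale together; bisection to ``resolution`` persons.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")

    def power_at(total):
        return screen_power(scenario.scaled_to(total), test, alpha,
                            prefilter=prefilter, r=r)

    lo, hi = float(resolution), float(max_total_n)
    if power_at(hi) < target_power:
        raise ValueError(
            f"target power {target_power} unreachable below total n {hi:.0f} "
            f"(power there: {power_at(hi):.4f})")
    while hi - lo > resolution:
        mid = (lo + hi) / 2.0
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return float(np.ceil(hi / resolution) * resolution)


def power_grid(base: Scenario, b_m_le50_values, b_f_gt50_values,
               screens: list[dict], n_replicates: int = 10_000,
               seed: int = 0) -> np.ndarray:
    """Union-power heat grid varying the men-younger and women-older effects.

    Axis convention follows the standard heat-plot construction: the
    women-younger effect is held at ``base.betas`` and the men-older effect
    at its base value while ``b_M_le50`` (rows) and ``b_F_gt50`` (columns)
    sweep their grids.  Returns a matrix of union powers.
    """
    rows = np.asarray(b_m_le50_values, dtype=float)
    cols = np.asarray(b_f_gt50_values, dtype=float)
    out = np.empty((rows.size, cols.size))
    for i, bm in enumerate(rows):
        for j, bf in enumerate(cols):
            betas = (float(bm), base.betas[1], base.betas[2], float(bf))
            scen = dataclasses.replace(base, betas=betas)
            out[i, j] = union_power(scen, screens, n_replicates=n_replicates,
                                    seed=seed + 104_729 * i + 1_299_709 * j)
    return out
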