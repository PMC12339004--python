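"""Selection inference from allele-frequency trajectories and associations.

Three analyses live here:

* logistic-trajectory fits: binomial GLM of allele counts on calendar
  year (logit link), giving a per-allele selection coefficient s (the
  per-year logit slope) and a joint coefficient s-tilde from a pooled fit
  with allele-specific intercepts and one shared slope, each with Wald Z
  and two-sided p;
* the recurrent-mutation worked example: Theta = k-bar per generation
  and the effective population size it implies under Theta = c * Ne * mu
  (c = 3 for a haplodiploid mating pair);
* population-level association between resistance survival and mutation
  frequency metrics (OLS R-squared), plus Hudson-style FST on resistance
  allele frequencies with a Mantel isolation-by-distance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from skbio import DistanceMatrix
from skbio.stats.distance import mantel

__all__ = [
    "SelectionFit",
    "RecurrentMutationEstimate",
    "AssociationResult",
    "fit_selection",
    "recurrent_mutation_estimate",
    "survival_association",
    "resistance_fst_ibd",
    "hudson_fst",
]


# ---------------------------------------------------------------------------
# trajectory fits


@dataclass
class SelectionFit:
    """Per-allele and joint selection-coefficient estimates (per year)."""

    per_allele: pd.DataFrame
    joint: pd.Series | None
    gens_per_year: int = 20

    @property
    def s_tilde(self) -> float:
        return float(self.joint["s"]) if self.joint is not None else float("nan")


def _binomial_counts(freq, n_chrom):
    successes = np.rint(np.asarray(freq, dtype=float) * np.asarray(n_chrom, dtype=float))
    failures = np.asarray(n_chrom, dtype=float) - successes
    return np.column_stack([successes, failures])


def _glm_slope(endog, exog_year, extra=None):
    x = exog_year[:, None] if extra is None else np.column_stack([extra, exog_year])
    if extra is None:
        x = sm.add_constant(x)
    res = sm.GLM(endog, x, family=sm.families.Binomial()).fit(maxiter=200)
    return res


def fit_selection(
    trajectories: pd.DataFrame,
    joint: bool = True,
    gens_per_year: int = 20,
) -> SelectionFit:
    """Estimate selection coefficients from allele-frequency time series.

    ``trajectories`` is long format with columns ``allele``,
    ``population``, ``year``, ``freq``, ``n_chromosomes``.  Counts are
    reconstructed from frequency times chromosomes sampled and modelled
    as binomial with a logit link, so populations with more sampled
    chromosomes carry proportionally more weight.  Alleles observed in
    fewer than two distinct years are reported as non-estimable; alleles
    at frequency 0 or 1 at every time point are flagged as separated.
    The slope is reported per year with the per-generation conversion
    alongside.
    """
    req = {"allele", "population", "year", "freq", "n_chromosomes"}
    if not req.issubset(trajectories.columns):
        raise ValueError(f"trajectories must have columns {sorted(req)}")
    df = trajectories.copy()
    year0 = float(df["year"].min())
    rows = []
    for allele, grp in df.groupby("allele", sort=True):
        record = dict(allele=allele, s=np.nan, se=np.nan, z=np.nan, p=np.nan,
                      s_per_generation=np.nan, status="ok")
        if grp["year"].nunique() < 2:
            record["status"] = "non-estimable"
            rows.append(record)
            continue
        if ((grp["freq"] <= 0) | (grp["freq"] >= 1)).all():
            record["status"] = "separated"
            rows.append(record)
            continue
        endog = _binomial_counts(grp["freq"], grp["n_chromosomes"])
        res = _glm_slope(endog, (grp["year"] - year0).to_numpy(dtype=float))
        record.update(
            s=float(res.params[1]), se=float(res.bse[1]),
            z=float(res.tvalues[1]), p=float(res.pvalues[1]),
            s_per_generation=float(res.params[1]) / gens_per_year,
        )
        rows.append(record)
    per_allele = pd.DataFrame(rows)

    joint_row = None
    if joint:
        usable = df[df.groupby("allele")["year"].transform("nunique") >= 2]
        if len(usable):
            endog = _binomial_counts(usable["freq"], usable["n_chromosomes"])
            dummies = pd.get_dummies(usable["allele"], dtype=float).to_numpy()
            res = _glm_slope(endog, (usable["year"] - year0).to_numpy(dtype=float),
                             extra=dummies)
            joint_row = pd.Series(dict(
                s=float(res.params[-1]), se=float(res.bse[-1]),
                z=float(res.tvalues[-1]), p=float(res.pvalues[-1]),
                s_per_generation=float(res.params[-1]) / gens_per_year,
                n_alleles=int(dummies.shape[1]),
            ))
    return SelectionFit(per_allele=per_allele, joint=joint_row,
                        gens_per_year=gens_per_year)


# ---------------------------------------------------------------------------
# recurrent-mutation worked example


@dataclass(frozen=True)
class RecurrentMutationEstimate:
    """Theta and implied Ne from the mean distinct mutations per population."""

    k_bar: float
    years_elapsed: float
    gens_per_year: float
    mu: float
    c: float
    theta: float
    ne_implied: float


def recurrent_mutation_estimate(
    k_bar: float,
    years_elapsed: float,
    gens_per_year: float,
    mu: float,
    c: float = 3.0,
) -> RecurrentMutationEstimate:
    """Per-generation recurrent-mutation rate Theta and the Ne it implies.

    Theta = k_bar / (years_elapsed * gens_per_year) distinct resistance
    mutations per population per generation, and Ne = Theta / (c * mu):
    the effective size needed for recurrent de-novo origin at per-bp rate
    ``mu`` with ``c`` genome copies per mating pair (3 under
    haplodiploidy).  k_bar = 0 gives Theta = Ne = 0.
    """
    if years_elapsed <= 0 or gens_per_year <= 0 or mu <= 0 or c <= 0:
        raise ValueError("years_elapsed, gens_per_year, mu and c must be positive")
    if k_bar < 0:
        raise ValueError("k_bar must be non-negative")
    theta = k_bar / (years_elapsed * gens_per_year)
    ne = theta / (c * mu)
    return RecurrentMutationEstimate(
        k_bar=k_bar, years_elapsed=years_elapsed, gens_per_year=gens_per_year,
        mu=mu, c=c, theta=theta, ne_implied=ne,
    )


# ---------------------------------------------------------------------------
# survival associations


@dataclass
class AssociationResult:
    """One univariate survival-vs-frequency regression."""

    metric: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    status: str = "ok"


def survival_association(
    pop_table: pd.DataFrame,
    metrics: tuple[str, ...] = ("predominant", "any_carrier", "homozygous"),
    mutation_columns: list[str] | None = None,
) -> tuple[list[AssociationResult], pd.DataFrame | None]:
    """OLS associations between survival and mutation-frequency metrics.

    ``pop_table`` has one row per population with a ``survival`` column
    (proportion surviving the discriminating dose), one column per metric
    in ``metrics``, and optionally per-mutation frequency columns for the
    multivariate fit.  Univariate R-squared equals the squared Pearson
    correlation; a constant predictor is flagged rather than fitted.
    """
    if "survival" not in pop_table.columns:
        raise ValueError("pop_table must have a 'survival' column")
    if len(pop_table) < 3:
        raise ValueError("at least 3 populations are required")
    y = pop_table["survival"].to_numpy(dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("survival must lie in [0, 1]")
    results = []
    for metric in metrics:
        x = pop_table[metric].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            results.append(AssociationResult(metric, np.nan, np.nan, np.nan, np.nan,
                                             len(x), status="constant-predictor"))
            continue
        res = sm.OLS(y, sm.add_constant(x)).fit()
        results.append(AssociationResult(
            metric=metric, slope=float(res.params[1]), intercept=float(res.params[0]),
            r_squared=float(res.rsquared), p_value=float(res.pvalues[1]), n=len(x),
        ))
    multi = None
    if mutation_columns:
        X = sm.add_constant(pop_table[list(mutation_columns)].to_numpy(dtype=float))
        res = sm.OLS(y, X).fit()
        multi = pd.DataFrame(dict(
            term=["intercept", *mutation_columns],
            coef=res.params, se=res.bse, t=res.tvalues, p=res.pvalues,
        ))
        multi.attrs["r_squared"] = float(res.rsquared)
    return results, multi


# ---------------------------------------------------------------------------
# isolation by distance


def hudson_fst(p1, p2) -> float:
    """Hudson-style FST from allele frequencies in two populations.

    1 - mean within-population heterozygosity / between-population
    heterozygosity, aggregated over alleles as a ratio of sums.
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    hw = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    if hb.sum() == 0:
        return 0.0
    return float(1.0 - hw.sum() / hb.sum())


def _haversine_matrix(lat, lon) -> np.ndarray:
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def resistance_fst_ibd(
    freqs: pd.DataFrame,
    coords: pd.DataFrame,
    permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Mantel test of isolation by distance on resistance-allele FST.

    ``freqs`` is indexed by population with one column per resistance
    allele; ``coords`` is indexed by population with ``lat``/``lon`` in
    degrees.  Pairwise Hudson FST (clamped at 0 for the distance matrix)
    is compared against great-circle distances with a one-sided
    (positive-association) Mantel permutation test.
    """
    pops = list(freqs.index)
    if len(pops) < 4:
        raise ValueError("at least 4 populations are required for a Mantel test")
    coords = coords.loc[pops]
    if coords[["lat", "lon"]].drop_duplicates().shape[0] < 2:
        raise ValueError("all populations share one coordinate; distances are degenerate")
    n = len(pops)
    f = np.zeros((n, n))
    vals = freqs.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            f[i, j] = f[j, i] = max(0.0, hudson_fst(vals[i], vals[j]))
    dists = _haversine_matrix(coords["lat"], coords["lon"])
    if seed is not None:
        np.random.seed(seed)  # skbio's mantel permutes via the global state
    r, p, n_used = mantel(
        DistanceMatrix(f, ids=pops),
        DistanceMatrix(dists, ids=pops),
        method="pearson",
        permutations=permutations,
        alternative="greater",
    )
    return dict(mantel_r=float(r), p_value=float(p), n=int(n_used),
                permutations=permutations, fst=f, distance_km=dists)
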