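"""Log-scale metabolic rate modelling and group comparisons.

Resting metabolic rate (RMR) and body mass are log10-transformed; per
species, seven candidate fixed-effect structures (built from thermal
treatment, log mass, sex and the treatment x mass interaction) are fit as
Gaussian linear mixed models with a per-individual random intercept and
compared by AICc.  A cross-species fixed-effects model yields mass-adjusted
marginal means and pairwise contrasts, and rank-based tests (Kruskal-Wallis
with Dunn post hoc) compare raw distributions.

Estimation notes
----------------
* All mixed models use the maximum-likelihood (not REML) objective so AICc
  is comparable across fixed-effect structures.
* AICc counts k = number of fixed coefficients + 2 variance components
  (random intercept and residual), and uses the number of *individuals*
  (independent grouping units) as the sample size n of the small-sample
  correction, consistent with the TPC module where the reported AICc sample
  sizes are individual counts.  ``aicc_n="observations"`` switches to raw
  observation count.
* Conditional R^2 = (fixed + random variance) / (fixed + random + residual).
* Coefficient tests are Wald z tests (reported as such; no Satterthwaite
  degrees of freedom).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ComputationError, ValidationError
from .respirometry import RMRRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelFitResult",
    "MarginalComparison",
    "RankTestResult",
    "log10_prepare",
    "candidate_set",
    "aicc_from_loglik",
    "fit_mixed",
    "fit_candidates",
    "species_adjusted_comparison",
    "rank_group_tests",
]

VALID_TERMS = ("treatment", "log_mass", "sex", "treatment:log_mass")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effect structure (random intercept always present)."""

    name: str
    fixed_terms: tuple[str, ...]

    def __post_init__(self):
        for t in self.fixed_terms:
            if t not in VALID_TERMS:
                raise ValidationError(f"unknown model term {t!r}")
        if "treatment:log_mass" in self.fixed_terms:
            if not {"treatment", "log_mass"} <= set(self.fixed_terms):
                raise ValidationError(
                    "interaction requires both main effects in the model"
                )

    def formula(self, response: str = "log_rmr", reference: int = 15) -> str:
        parts = []
        for t in self.fixed_terms:
            if t == "treatment":
                parts.append(f"C(treatment, Treatment(reference={reference}))")
            elif t == "treatment:log_mass":
                parts.append(
                    f"C(treatment, Treatment(reference={reference})):log_mass"
                )
            else:
                parts.append(t)
        rhs = " + ".join(parts) if parts else "1"
        return f"{response} ~ {rhs}"


@dataclass(frozen=True)
class ModelFitResult:
    """One fitted candidate with coefficients and selection diagnostics."""

    spec: ModelSpec
    coefficients: pd.DataFrame = field(repr=False)  # term, estimate, se, z, p
    aicc: float
    conditional_r2: float
    re_var: float
    resid_var: float
    n_obs: int
    n_individuals: int
    converged: bool


@dataclass(frozen=True)
class MarginalComparison:
    """Mass-adjusted marginal means per group and their pairwise contrasts."""

    groups: tuple[str, ...]
    adjusted_means: pd.Series = field(repr=False)
    contrasts: pd.DataFrame = field(repr=False)  # g1, g2, estimate, t, p
    reference_log_mass: float
    interaction_retained: bool


@dataclass(frozen=True)
class RankTestResult:
    """Kruskal-Wallis H (tie corrected) with Dunn post hoc comparisons."""

    h: float
    p: float
    posthoc: pd.DataFrame = field(repr=False)  # g1, g2, z, p_unadj, p_adj


# ---------------------------------------------------------------------------
# Data preparation and candidates
# ---------------------------------------------------------------------------


def log10_prepare(records: Iterable[RMRRecord] | pd.DataFrame) -> pd.DataFrame:
    """Build the modelling table with log10(RMR) and log10(mass) columns.

    Rows with non-positive RMR or mass cannot be log-transformed and are
    dropped with a logged count.  Raises if nothing survives.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "individual_id": r.individual_id,
                    "species": r.species,
                    "treatment": int(round(r.treatment_temp)),
                    "sex": r.sex,
                    "body_mass": r.body_mass,
                    "vco2": r.vco2,
                }
                for r in records
            ]
        )
    if df.empty:
        raise ValidationError("no RMR records to prepare")
    df["treatment"] = df["treatment"].round().astype(int)
    keep = (df["vco2"] > 0) & (df["body_mass"] > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("log10_prepare: dropped %d non-positive row(s)", n_dropped)
    df = df.loc[keep].copy()
    if df.empty:
        raise ValidationError("all rows dropped: no positive RMR/mass values")
    df["log_rmr"] = np.log10(df["vco2"])
    df["log_mass"] = np.log10(df["body_mass"])
    df.attrs["n_dropped"] = n_dropped
    return df


def candidate_set() -> list[ModelSpec]:
    """The seven candidate fixed-effect structures.

    {T; M; S; T+M; T+S; T+M+S; T+M+TxM}, each with the individual random
    intercept.
    """
    return [
        ModelSpec("T", ("treatment",)),
        ModelSpec("M", ("log_mass",)),
        ModelSpec("S", ("sex",)),
        ModelSpec("T+M", ("treatment", "log_mass")),
        ModelSpec("T+S", ("treatment", "sex")),
        ModelSpec("T+M+S", ("treatment", "log_mass", "sex")),
        ModelSpec("T+M+TxM", ("treatment", "log_mass", "treatment:log_mass")),
    ]


# ---------------------------------------------------------------------------
# Mixed-model fitting
# ---------------------------------------------------------------------------


def aicc_from_loglik(llf: float, n: int, k: int) -> float:
    """AICc from a maximized log-likelihood: -2llf + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ComputationError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_mixed(
    table: pd.DataFrame,
    spec: ModelSpec,
    reference: int = 15,
    aicc_n: str = "individuals",
) -> ModelFitResult:
    """Fit one candidate by Gaussian MixedLM with ML and a random intercept."""
    if aicc_n not in ("individuals", "observations"):
        raise ValidationError(f"bad aicc_n {aicc_n!r}")
    formula = spec.formula(reference=reference)
    model = smf.mixedlm(formula, table, groups=table["individual_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=False)
        except Exception:
            result = model.fit(reml=False, method="powell")
    converged = bool(getattr(result, "converged", True))

    fe = result.fe_params
    coef = pd.DataFrame(
        {
            "term": fe.index,
            "estimate": fe.values,
            "se": result.bse_fe.values,
            "z": result.tvalues[fe.index].values,
            "p": result.pvalues[fe.index].values,
        }
    )
    re_var = float(np.asarray(result.cov_re)[0, 0])
    resid_var = float(result.scale)
    fitted_fixed = np.dot(result.model.exog, fe.values)
    var_f = float(np.var(fitted_fixed))
    total = var_f + re_var + resid_var
    cond_r2 = (var_f + re_var) / total if total > 0 else float("nan")

    n_obs = int(table.shape[0])
    n_individuals = int(table["individual_id"].nunique())
    n_eff = n_individuals if aicc_n == "individuals" else n_obs
    k = len(fe) + 2  # fixed coefficients + random-intercept and residual var
    return ModelFitResult(
        spec=spec,
        coefficients=coef,
        aicc=aicc_from_loglik(float(result.llf), n_eff, k),
        conditional_r2=float(cond_r2),
        re_var=re_var,
        resid_var=resid_var,
        n_obs=n_obs,
        n_individuals=n_individuals,
        converged=converged,
    )


def fit_candidates(
    table: pd.DataFrame,
    specs: Sequence[ModelSpec] | None = None,
    reference: int = 15,
) -> tuple[list[ModelFitResult], ModelFitResult]:
    """Fit all candidate specs and select the lowest-AICc converged fit.

    Non-converged (or outright failing) fits are reported in the list but
    excluded from selection, with a warning.
    """
    if table["treatment"].nunique() < 2:
        raise ValidationError("need >= 2 treatment levels for candidate fitting")
    if not (table.groupby("individual_id").size() >= 2).any():
        raise ValidationError("need repeated measures for a random intercept")
    specs = list(specs) if specs is not None else candidate_set()
    results: list[ModelFitResult] = []
    for spec in specs:
        try:
            results.append(fit_mixed(table, spec, reference=reference))
        except Exception as exc:  # keep going; record nothing for this spec
            logger.warning("spec %s failed: %s", spec.name, exc)
    eligible = [r for r in results if r.converged and np.isfinite(r.aicc)]
    if not eligible:
        raise ComputationError("no candidate model converged")
    if len(eligible) < len(results):
        warnings.warn(
            f"{len(results) - len(eligible)} candidate(s) excluded from "
            "selection (non-convergence)", stacklevel=2)
    best = min(eligible, key=lambda r: (r.aicc, len(r.spec.fixed_terms)))
    return results, best


# ---------------------------------------------------------------------------
# Cross-species comparison
# ---------------------------------------------------------------------------


def species_adjusted_comparison(
    table: pd.DataFrame,
    alpha: float = 0.05,
    interaction: str = "auto",
) -> MarginalComparison:
    """Mass-adjusted marginal means and contrasts across species.

    Fits the fixed-effects model ``log_rmr ~ species + log_mass``; the
    species x mass interaction is tested first and retained only if
    significant at ``alpha`` (``interaction="auto"``; force with
    ``"always"``/``"never"``).  Adjusted means evaluate the fit at the grand
    mean of log mass; contrasts are unadjusted pairwise t tests.
    """
    if interaction not in ("auto", "always", "never"):
        raise ValidationError(f"bad interaction policy {interaction!r}")
    species = sorted(table["species"].unique())
    if len(species) < 2:
        raise ValidationError("species comparison needs >= 2 species")

    base = smf.ols("log_rmr ~ C(species) + log_mass", table).fit()
    retained = False
    if interaction != "never":
        full = smf.ols("log_rmr ~ C(species) * log_mass", table).fit()
        ftest = sm.stats.anova_lm(base, full)
        p_int = float(ftest["Pr(>F)"].iloc[1])
        retained = interaction == "always" or p_int < alpha
    result = full if retained else base

    grand = float(table["log_mass"].mean())
    new = pd.DataFrame({"species": species, "log_mass": grand})
    pred = result.get_prediction(new)
    means = pd.Series(pred.predicted_mean, index=species, name="adjusted_mean")

    # contrast rows in model design space for pairwise differences
    design = result.model.data.design_info
    from patsy import dmatrix

    X = np.asarray(dmatrix(design, new, return_type="matrix"))
    rows = []
    for i, j in itertools.combinations(range(len(species)), 2):
        contrast = X[i] - X[j]
        tt = result.t_test(contrast)
        rows.append(
            {
                "group1": species[i],
                "group2": species[j],
                "estimate": float(np.squeeze(tt.effect)),
                "t": float(np.squeeze(tt.tvalue)),
                "p": float(np.squeeze(tt.pvalue)),
            }
        )
    return MarginalComparison(
        groups=tuple(species),
        adjusted_means=means,
        contrasts=pd.DataFrame(rows),
        reference_log_mass=grand,
        interaction_retained=retained,
    )


# ---------------------------------------------------------------------------
# Rank-based tests
# ---------------------------------------------------------------------------


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def rank_group_tests(groups: Mapping[str, Sequence[float]]) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H plus Dunn z post hoc (Holm adjusted).

    Degenerate all-tied data yields H = 0, p = 1 and unit post-hoc p-values.
    """
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValidationError("need >= 2 groups with >= 2 values each")

    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        posthoc = pd.DataFrame(
            [
                {"group1": a, "group2": b, "z": 0.0, "p_unadj": 1.0, "p_adj": 1.0}
                for a, b in itertools.combinations(names, 2)
            ]
        )
        return RankTestResult(h=0.0, p=1.0, posthoc=posthoc)

    h, p = sps.kruskal(*samples)

    # Dunn post hoc on pooled mid-ranks with tie correction
    ranks = sps.rankdata(pooled)
    sizes = np.array([s.size for s in samples])
    edges = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = {
        g: ranks[edges[i]: edges[i + 1]].mean() for i, g in enumerate(names)
    }
    n_total = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_un = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z, "p_unadj": p_un})
    posthoc = pd.DataFrame(rows)
    posthoc["p_adj"] = _holm(posthoc["p_unadj"].to_numpy())
    return RankTestResult(h=float(h), p=float(p), posthoc=posthoc)
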