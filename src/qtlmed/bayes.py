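"""Bayesian model selection over causal DAGs for X-M-Y triplets.

For a genetic variant X (dosage encoded -1/0/1), a candidate mediator
phenotype M and an outcome phenotype Y, twelve directed-acyclic-graph
configurations are scored: every combination of the X->M edge (absent /
present), the mediation edge (absent / M->Y / Y->M), and the direct
X->Y edge (absent / present). Each configuration factorizes the joint
likelihood into two conjugate Bayesian linear regressions — the
M-equation and the Y-equation, each with its own covariates — whose
marginal likelihoods are available in closed form (multivariate-t after
integrating the Gaussian coefficients and the scaled-inverse-chi-square
residual variance). Posterior model probabilities combine these joint
evidences with a uniform prior over the allowed model set.

Effect-size hyperparameters phi^2 are expressed on the odds-of-PVE
scale (odds = pve / (1 - pve)): the prior variance of an effect
coefficient is phi^2 * sigma^2 / Var(column), so phi^2 = 1 places half
of the phenotype variance on the edge a priori. M and Y are centered
and variance-standardized before evaluation so that this scale is
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from qtlmed._ols import add_intercept

# Edge configuration: (x_to_m present, mediation edge in {none, m_to_y, y_to_m},
# x_to_y present). Labels are bijective with configurations.
CAUSAL_MODELS: dict[str, tuple[bool, str, bool]] = {
    "no-effects": (False, "none", False),
    "x->m only": (True, "none", False),
    "m->y only": (False, "m_to_y", False),
    "x->y only": (False, "none", True),
    "complete mediation": (True, "m_to_y", False),
    "co-local/independence": (True, "none", True),
    "y-with-m no-x->m": (False, "m_to_y", True),
    "partial mediation": (True, "m_to_y", True),
    "y->m only": (False, "y_to_m", False),
    "complete reactive": (False, "y_to_m", True),
    "x->m + y->m": (True, "y_to_m", False),
    "partial reactive": (True, "y_to_m", True),
}

REACTIVE_MODELS = ("y->m only", "complete reactive", "x->m + y->m", "partial reactive")
FORWARD_CALL = ("complete mediation", "partial mediation")
REACTIVE_CALL = ("complete reactive", "partial reactive")
INDEPENDENCE_MODEL = "co-local/independence"


@dataclass
class MediationPriors:
    """Hyperparameters of the conjugate mediation model.

    phi2: prior effect sizes (odds-of-PVE scale) for the X->M edge, the
    mediation edge (M->Y or Y->M), and the direct X->Y edge.
    kappa / lambda_scale: degrees of freedom and scale of the
    scaled-inverse-chi-square residual-variance prior.
    tau: prior variances (relative to sigma^2) for the intercept and
    for each covariate coefficient.
    model_prior_mode: "complete" excludes the four reactive-edge models
    a priori; "reactive" allows all twelve.
    """

    phi2: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kappa: float = 0.001
    lambda_scale: float = 0.001
    tau: tuple[float, float] = (1000.0, 1000.0)
    model_prior_mode: str = "complete"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (*self.phi2, self.kappa, self.lambda_scale, *self.tau)):
            raise ValueError("all prior hyperparameters must be positive")
        if self.model_prior_mode not in ("complete", "reactive"):
            raise ValueError("model_prior_mode must be 'complete' or 'reactive'")

    def allowed_models(self) -> list[str]:
        if self.model_prior_mode == "complete":
            return [m for m in CAUSAL_MODELS if m not in REACTIVE_MODELS]
        return list(CAUSAL_MODELS)


@dataclass
class ModelPosterior:
    """Posterior over the twelve causal configurations for one triplet."""

    log_marginal: dict[str, float]
    posterior: dict[str, float]
    classification: str
    posterior_forward_sum: float
    posterior_reactive_sum: float
    triplet_id: str = ""
    log_evidence: float = field(default=float("nan"))


def marginal_log_likelihood(
    response: np.ndarray,
    design: np.ndarray,
    prior_variances: np.ndarray,
    kappa: float,
    lambda_scale: float,
) -> float:
    """Closed-form log marginal likelihood of a conjugate linear model.

    response ~ N(design @ b, sigma^2 I), b ~ N(0, sigma^2 V) with
    V = diag(prior_variances), sigma^2 ~ scaled-inv-chi-square(kappa,
    lambda_scale). Integrating b and sigma^2 gives a multivariate-t_kappa
    density with scale lambda_scale * (I + design V design').
    """
    y = np.asarray(response, dtype=float)
    w = np.asarray(design, dtype=float)
    v = np.asarray(prior_variances, dtype=float)
    n, k = w.shape
    if v.shape != (k,):
        raise ValueError("one prior variance per design column required")
    if np.any(v <= 0):
        raise ValueError("prior variances must be positive")
    # |I + W V W'| = |V| |V^-1 + W'W|; quadratic form via the same inverse
    a = np.diag(1.0 / v) + w.T @ w
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        raise np.linalg.LinAlgError("penalized Gram matrix not positive definite")
    logdet_k = float(np.sum(np.log(v)) + logdet_a)
    wty = w.T @ y
    quad = float(y @ y - wty @ np.linalg.solve(a, wty))
    return float(
        gammaln((kappa + n) / 2.0)
        - gammaln(kappa / 2.0)
        - 0.5 * n * np.log(kappa * np.pi)
        - 0.5 * n * np.log(lambda_scale)
        - 0.5 * logdet_k
        - 0.5 * (kappa + n) * np.log1p(quad / (kappa * lambda_scale))
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("constant phenotype cannot be standardized")
    return (v - v.mean()) / sd


def _equation_loglik(
    response: np.ndarray,
    covariates: np.ndarray | None,
    effects: list[tuple[np.ndarray, float]],
    priors: MediationPriors,
) -> float:
    """Marginal likelihood of one structural equation.

    effects: (column, phi2) pairs; each effect coefficient has prior
    variance phi2 * sigma^2 / Var(column) so phi2 stays on the
    odds-of-PVE scale regardless of the column's empirical scale.
    """
    n = response.shape[0]
    base = add_intercept(covariates, n)
    variances = [priors.tau[0]] + [priors.tau[1]] * (base.shape[1] - 1)
    cols = [base]
    for col, phi2 in effects:
        var = float(np.var(col))
        if var == 0:
            var = 1.0  # constant effect column carries no information
        cols.append(np.asarray(col, dtype=float)[:, None])
        variances.append(phi2 / var)
    design = np.hstack(cols)
    return marginal_log_likelihood(
        response, design, np.asarray(variances), priors.kappa, priors.lambda_scale
    )


def joint_log_likelihood(
    model: str,
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates_m: np.ndarray | None,
    covariates_y: np.ndarray | None,
    priors: MediationPriors,
) -> float:
    """log p(m, y | x, theta): M-equation + Y-equation evidences.

    Forward-type factorization p(m|parents) p(y|parents) when the
    mediation edge is M->Y or absent; reactive factorization
    p(y|parents) p(m|parents) when it is Y->M.
    """
    x_to_m, med, x_to_y = CAUSAL_MODELS[model]
    phi_xm, phi_med, phi_xy = priors.phi2
    m_effects: list[tuple[np.ndarray, float]] = []
    y_effects: list[tuple[np.ndarray, float]] = []
    if x_to_m:
        m_effects.append((x, phi_xm))
    if x_to_y:
        y_effects.append((x, phi_xy))
    if med == "m_to_y":
        y_effects.append((m, phi_med))
    elif med == "y_to_m":
        m_effects.append((y, phi_med))
    return _equation_loglik(m, covariates_m, m_effects, priors) + _equation_loglik(
        y, covariates_y, y_effects, priors
    )


def posterior_over_models(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates_m: np.ndarray | None = None,
    covariates_y: np.ndarray | None = None,
    priors: MediationPriors | None = None,
    triplet_id: str = "",
    literal_reactive_call: bool = False,
) -> ModelPosterior:
    """Posterior model probabilities and causal classification.

    x is the variant dosage encoded -1/0/1 (dosage 0/1/2 inputs are
    re-encoded automatically); m and y are centered and standardized
    internally. Classification: "forward" when the complete + partial
    mediation posteriors sum above 0.5 (strict); "reactive" when the
    complete + partial reactive posteriors do; otherwise "independence"
    when the co-local model is the argmax, else "other".

    ``literal_reactive_call=True`` sums complete reactive + partial
    mediation for the reactive call instead of the two reactive models.
    """
    priors = priors or MediationPriors()
    x = np.asarray(x, dtype=float)
    if x.min() >= 0 and x.max() > 1:  # 0/1/2 dosage -> -1/0/1
        x = x - 1.0
    n = x.shape[0]
    n_cov = 0
    for cov in (covariates_m, covariates_y):
        if cov is not None:
            c = np.atleast_2d(np.asarray(cov))
            n_cov = max(n_cov, c.shape[1] if c.shape[0] == n else c.shape[0])
    if n < n_cov + 3:
        raise ValueError(f"n={n} too small for {n_cov} covariates plus the triplet effects")
    m_std = _standardize(m)
    y_std = _standardize(y)

    allowed = priors.allowed_models()
    log_marg = {
        model: joint_log_likelihood(model, x, m_std, y_std, covariates_m, covariates_y, priors)
        for model in allowed
    }
    vals = np.array([log_marg[mod] for mod in allowed])
    log_prior = -np.log(len(allowed))  # uniform over the allowed set
    log_evidence = float(logsumexp(vals + log_prior))
    post_vals = np.exp(vals - logsumexp(vals))
    posterior = {mod: 0.0 for mod in CAUSAL_MODELS}
    posterior.update(dict(zip(allowed, post_vals)))

    forward_sum = sum(posterior[mod] for mod in FORWARD_CALL)
    if literal_reactive_call:
        reactive_sum = posterior["complete reactive"] + posterior["partial mediation"]
    else:
        reactive_sum = sum(posterior[mod] for mod in REACTIVE_CALL)
    if forward_sum > 0.5:
        classification = "forward"
    elif reactive_sum > 0.5:
        classification = "reactive"
    elif max(posterior, key=posterior.get) == INDEPENDENCE_MODEL:
        classification = "independence"
    else:
        classification = "other"
    full_log_marg = {mod: log_marg.get(mod, -np.inf) for mod in CAUSAL_MODELS}
    return ModelPosterior(
        log_marginal=full_log_marg,
        posterior=posterior,
        classification=classification,
        posterior_forward_sum=forward_sum,
        posterior_reactive_sum=sum(posterior[mod] for mod in REACTIVE_CALL),
        triplet_id=triplet_id,
        log_evidence=log_evidence,
    )


def mediation_scan(
    x: np.ndarray,
    y: np.ndarray,
    candidates: "pd.DataFrame",
    candidate_positions: dict[str, int] | None = None,
    covariates_m: np.ndarray | None = None,
    covariates_y: np.ndarray | None = None,
    priors: MediationPriors | None = None,
) -> "pd.DataFrame":
    """Score every candidate mediator in a window as M for fixed X, Y.

    candidates: samples x candidate-features table (e.g. all peaks
    within 1 Mb of the outcome gene's TSS). Returns one row per
    candidate with the forward/reactive posterior sums and the
    classification, sorted by genomic position when positions are given.
    """
    import pandas as pd

    rows = []
    for cand in candidates.columns:
        post = posterior_over_models(
            x, candidates[cand].to_numpy(dtype=float), y,
            covariates_m, covariates_y, priors, triplet_id=str(cand),
        )
        rows.append(
            {
                "candidate_id": cand,
                "position": (candidate_positions or {}).get(cand, -1),
                "posterior_forward_sum": post.posterior_forward_sum,
                "posterior_reactive_sum": post.posterior_reactive_sum,
                "classification": post.classification,
                **{f"p_{k}": v for k, v in post.posterior.items()},
            }
        )
    table = pd.DataFrame(rows)
    if candidate_positions:
        table = table.sort_values("position", kind="stable").reset_index(drop=True)
    return table


def select_phi2(
    triplets: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    grid: list[tuple[float, float, float]],
    covariates_m: np.ndarray | None = None,
    covariates_y: np.ndarray | None = None,
    base_priors: MediationPriors | None = None,
) -> "pd.DataFrame":
    """Empirical-Bayes grid search over phi^2 hyperparameters.

    For each grid point, sums over triplets the log of the
    prior-weighted total evidence; returns the full table with the
    maximizer(s) flagged.
    """
    import pandas as pd

    if not triplets or not grid:
        raise ValueError("need a non-empty triplet collection and grid")
    base = base_priors or MediationPriors()
    rows = []
    for phi2 in grid:
        priors = MediationPriors(
            phi2=tuple(phi2), kappa=base.kappa, lambda_scale=base.lambda_scale,
            tau=base.tau, model_prior_mode=base.model_prior_mode,
        )
        total = 0.0
        for x, m, y in triplets:
            post = posterior_over_models(x, m, y, covariates_m, covariates_y, priors)
            total += post.log_evidence
        rows.append({"phi2_xm": phi2[0], "phi2_med": phi2[1], "phi2_xy": phi2[2],
                     "sum_log_evidence": total})
    table = pd.DataFrame(rows)
    table["is_argmax"] = np.isclose(table["sum_log_evidence"],
                                    table["sum_log_evidence"].max())
    return table
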