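"""Paleotemperature-dependent birth-death diversification models.

Speciation and extinction rates are deterministic functions of a
paleotemperature curve T(t) (t in Ma before present): constant, linear in
T (clamped at zero), or exponential in T. The likelihood of an ultrametric
chronogram under such a model is computed by propagating the
extinction-probability function E(t) of the reconstructed process from the
present toward the root:

    E'(t) = mu(t) - (lambda(t) + mu(t)) E(t) + lambda(t) E(t)^2,
    E(0)  = 1 - f,

with f the sampling fraction. The per-branch likelihood flow D(t) obeys
D'(t) = -(lambda + mu) D + 2 lambda E D, which is linear in D, so branch
factors are exp of the integral I(t) = int_0^t (lambda + mu - 2 lambda E);
both E and I are obtained from one adaptive ODE solve with dense output.
The crown-conditioned log-likelihood for a tree with n tips is

    logL = n log f - sum_edges [I(t_parent) - I(t_child)]
           + sum_internal (n_children - 1) log lambda(t_node)
           - 2 log(1 - E(t_crown)),

which for binary trees carries n-1 speciation factors including the root.
Model selection is by AICc over a configurable registry; by default seven
models spanning constant/linear/exponential speciation with no, constant,
or exponential extinction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .paleo import PaleoCurve
from .trees import Chronogram

logger = logging.getLogger(__name__)

__all__ = [
    "RateFunctionSpec",
    "ModelFit",
    "env_rate_function",
    "bd_loglik",
    "fit_env_bd",
    "model_select",
    "DEFAULT_MODELS",
    "fit_all_models",
    "aicc",
]

_FORMS_LAMBDA = ("constant", "linear", "exponential")
_FORMS_MU = ("none", "constant", "linear", "exponential")


class LikelihoodError(ArithmeticError):
    """Numerical failure while evaluating the birth-death likelihood."""


@dataclass(frozen=True)
class RateFunctionSpec:
    """Parameterization of lambda(t), mu(t) through the temperature curve.

    lambda(t) = lambda0                       (constant)
              = max(0, lambda0 + alpha*T(t))  (linear)
              = lambda0 * exp(alpha*T(t))     (exponential)
    and analogously for mu; mu_form 'none' means mu identically 0.
    ``sampling_fraction`` f is the probability an extant species is sampled
    in the tree; it is fixed, never estimated.
    """

    lambda_form: str = "constant"
    mu_form: str = "none"
    lambda0: float = 0.1
    alpha_lambda: float = 0.0
    mu0: float = 0.0
    alpha_mu: float = 0.0
    sampling_fraction: float = 1.0

    def __post_init__(self):
        if self.lambda_form not in _FORMS_LAMBDA:
            raise ValueError(f"bad lambda_form {self.lambda_form!r}")
        if self.mu_form not in _FORMS_MU:
            raise ValueError(f"bad mu_form {self.mu_form!r}")
        if not (0 < self.sampling_fraction <= 1):
            raise ValueError("sampling_fraction must be in (0, 1]")

    @property
    def free_parameters(self) -> list[str]:
        names = ["lambda0"]
        if self.lambda_form != "constant":
            names.append("alpha_lambda")
        if self.mu_form != "none":
            names.append("mu0")
        if self.mu_form in ("linear", "exponential"):
            names.append("alpha_mu")
        return names

    @property
    def k(self) -> int:
        return len(self.free_parameters)


def _one_rate(form: str, r0: float, alpha: float, paleo: PaleoCurve | None):
    if form in ("constant", "none"):
        val = 0.0 if form == "none" else float(r0)

        def rate(t, _v=val):
            return _v * np.ones_like(np.asarray(t, dtype=float))

        return rate
    if paleo is None:
        raise ValueError(f"{form!r} rate form requires a paleotemperature curve")
    if form == "linear":

        def rate(t):
            return np.maximum(0.0, r0 + alpha * paleo.at(t))

        return rate
    # exponential
    def rate(t):
        out = r0 * np.exp(alpha * paleo.at(t))
        if not np.all(np.isfinite(out)):
            raise LikelihoodError("exponential rate overflowed")
        return out

    return rate


def env_rate_function(spec: RateFunctionSpec, paleo: PaleoCurve | None):
    """Build vectorized callables (lambda(t), mu(t)) from a spec."""
    lam = _one_rate(spec.lambda_form, spec.lambda0, spec.alpha_lambda, paleo)
    mu = _one_rate(spec.mu_form, spec.mu0, spec.alpha_mu, paleo)
    return lam, mu


def bd_loglik(
    chrono: Chronogram,
    spec: RateFunctionSpec,
    paleo: PaleoCurve | None = None,
    conditioning: str = "crown",
    include_root_speciation: bool = True,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> float:
    """Log-likelihood of an ultrametric chronogram under the model.

    ``conditioning='crown'`` (default) conditions on the survival of both
    crown lineages, dividing by (1 - E(t_crown))^2; ``'none'`` drops that
    term. ``include_root_speciation`` toggles the lambda factor at the
    crown node (on by default, matching the crown convention above).
    """
    lam, mu = env_rate_function(spec, paleo)
    t_c = chrono.crown_age
    f = spec.sampling_fraction
    probe = np.linspace(0, t_c, 64)
    lam_probe, mu_probe = lam(probe), mu(probe)
    if float(np.max(lam_probe)) <= 0:
        raise LikelihoodError("speciation rate is identically zero on [0, t_c]")
    if float(np.max(lam_probe + mu_probe)) > 1e3:
        # per-Ma rates this large are unphysical and make the ODE needlessly
        # stiff; treat as an unevaluable parameter point
        raise LikelihoodError("total event rate exceeds 1e3/Ma on [0, t_c]")

    def rhs(t, y):
        e = y[0]
        l, m = float(lam(t)), float(mu(t))
        return [m - (l + m) * e + l * e * e, l + m - 2.0 * l * e]

    def extinct(t, y):  # E -> 1 means survival to the present is impossible
        return (1.0 - y[0]) - 1e-12

    extinct.terminal = True

    sol = solve_ivp(
        rhs,
        (0.0, t_c),
        [1.0 - f, 0.0],
        dense_output=True,
        rtol=rtol,
        atol=atol,
        method="LSODA",
        events=extinct,
    )
    if sol.status == 1:  # terminated by the event
        raise LikelihoodError("lineage survival probability vanished before t_c")
    if not sol.success:
        raise LikelihoodError(f"ODE integration failed: {sol.message}")

    tol = 1e-8
    if np.any(sol.y[0] < -tol) or np.any(sol.y[0] > 1 + tol):
        raise LikelihoodError("extinction probability E(t) left [0, 1]")

    def e_of(t):
        return sol.sol(t)[0]

    def i_of(t):
        return sol.sol(t)[1]

    n = chrono.n_tips
    loglik = n * np.log(f)
    # branch flow factors: -(I(parent) - I(child)) per edge, vectorized
    child_ages, parent_ages = [], []
    node_lambda_ages, node_mult = [], []
    for nd in chrono.tree.preorder_node_iter():
        if nd.parent_node is not None:
            child_ages.append(nd.age_ma)
            parent_ages.append(nd.parent_node.age_ma)
        if not nd.is_leaf():
            k_children = sum(1 for _ in nd.child_node_iter())
            mult = k_children - 1
            if nd.parent_node is None and not include_root_speciation:
                mult -= 1
            if mult > 0:
                node_lambda_ages.append(nd.age_ma)
                node_mult.append(mult)
    child_ages = np.asarray(child_ages)
    parent_ages = np.asarray(parent_ages)
    loglik -= float(np.sum(i_of(parent_ages) - i_of(child_ages)))
    if node_lambda_ages:
        lam_vals = lam(np.asarray(node_lambda_ages))
        if np.any(lam_vals <= 0):
            raise LikelihoodError("speciation rate is zero at a branching time")
        loglik += float(np.sum(np.asarray(node_mult) * np.log(lam_vals)))
    if conditioning == "crown":
        e_c = float(e_of(t_c))
        if e_c >= 1.0:
            raise LikelihoodError("survival probability vanished at the crown")
        loglik -= 2.0 * np.log1p(-e_c)
    elif conditioning != "none":
        raise ValueError(f"unknown conditioning {conditioning!r}")
    return float(loglik)


# ---- fitting -------------------------------------------------------------


@dataclass
class ModelFit:
    """A fitted diversification model and its selection statistics."""

    name: str
    spec: RateFunctionSpec
    params: dict[str, float]
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    n_starts_ok: int = 0

    def to_row(self) -> dict:
        row = {
            "model": self.name,
            "logL": self.loglik,
            "k": self.k,
            "n": self.n,
            "AICc": self.aicc,
            "converged": self.converged,
        }
        row.update(self.params)
        return row


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for k={k}, n={n} (n - k - 1 <= 0)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ModelTemplate:
    name: str
    lambda_form: str
    mu_form: str


#: Default registry of seven temperature-dependent birth-death models:
#: constant/linear/exponential speciation crossed with no, constant, or
#: exponential extinction. Reconstructed registry; configurable.
DEFAULT_MODELS: tuple[ModelTemplate, ...] = (
    ModelTemplate("lambda_const", "constant", "none"),
    ModelTemplate("lambda_const_mu_const", "constant", "constant"),
    ModelTemplate("lambda_linT", "linear", "none"),
    ModelTemplate("lambda_expT", "exponential", "none"),
    ModelTemplate("lambda_linT_mu_const", "linear", "constant"),
    ModelTemplate("lambda_expT_mu_const", "exponential", "constant"),
    ModelTemplate("lambda_expT_mu_expT", "exponential", "exponential"),
)

#: Default box constraints for the optimizer. The temperature-dependence
#: window of +/- 0.3 per deg C (an e-folding of the rate every 3.3 deg C)
#: already brackets any biologically plausible response; leaving alpha
#: unbounded lets the optimizer climb the classic high-turnover ridge of
#: time-varying birth-death models, where lambda(t) and mu(t) explode
#: jointly into the past — such fits are artifacts of the model family's
#: non-identifiability, not signal.
_BOUNDS = {
    "lambda0": (1e-8, 5.0),
    "mu0": (0.0, 5.0),
    "alpha_lambda": (-0.3, 0.3),
    "alpha_mu": (-0.3, 0.3),
}


def fit_env_bd(
    chrono: Chronogram,
    template: ModelTemplate | RateFunctionSpec,
    paleo: PaleoCurve | None = None,
    sampling_fraction: float = 1.0,
    starts: int = 3,
    seed: int = 0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    bounds: dict | None = None,
) -> ModelFit:
    """Maximum-likelihood fit of one model by bounded quasi-Newton search.

    Multi-start: the first start is a moment heuristic (pure-birth rate
    (n-1)/total branch length, alpha = 0, mu0 a tenth of lambda0); further
    starts jitter it with the seeded generator. lambda0, mu0 >= 0 enforced
    by bounds. The ODE tolerances are relaxed relative to ``bd_loglik``'s
    reporting defaults for speed during the search; the returned logL is
    re-evaluated at the tight tolerances.
    """
    if isinstance(template, ModelTemplate):
        base = RateFunctionSpec(
            lambda_form=template.lambda_form,
            mu_form=template.mu_form,
            sampling_fraction=sampling_fraction,
        )
        name = template.name
    else:
        base = replace(template, sampling_fraction=sampling_fraction)
        name = f"{base.lambda_form}-{base.mu_form}"
    free = base.free_parameters
    n_tips = chrono.n_tips
    lam_hat = max((n_tips - 1) / chrono.total_branch_length(), 1e-4)
    # for exponential forms lambda0 multiplies exp(alpha*T); at alpha=0 the
    # heuristic is the same
    start0 = {"lambda0": lam_hat, "alpha_lambda": 0.0, "mu0": lam_hat / 10, "alpha_mu": 0.0}
    rng = np.random.default_rng(seed)

    def unpack(x):
        return replace(base, **dict(zip(free, x)))

    _PENALTY = 1e10  # finite so numerical gradients stay usable

    def nll(x):
        try:
            val = -bd_loglik(chrono, unpack(x), paleo, rtol=rtol, atol=atol)
        except (LikelihoodError, FloatingPointError, OverflowError):
            return _PENALTY
        return val if np.isfinite(val) else _PENALTY

    bound_map = dict(_BOUNDS)
    if bounds:
        bound_map.update(bounds)
    bounds = [bound_map[p] for p in free]
    best = None
    n_ok = 0
    for s in range(starts):
        x0 = np.array([start0[p] for p in free])
        if s > 0:
            jitter = rng.uniform(0.5, 2.0, size=len(free))
            x0 = x0 * jitter
            for i, p in enumerate(free):
                if p.startswith("alpha"):
                    x0[i] = rng.uniform(-0.2, 0.2)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        if nll(x0) >= _PENALTY:
            continue
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds, options={"maxfun": 400}
        )
        if np.isfinite(res.fun) and res.fun < _PENALTY:
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise LikelihoodError(
            f"all {starts} starts failed for model {name!r} "
            f"(likelihood not evaluable anywhere tried)"
        )
    spec_hat = unpack(best.x)
    loglik = bd_loglik(chrono, spec_hat, paleo)  # tight tolerances
    n = n_tips - 1  # number of branching times
    # an optimum pinned to a box edge is not an interior ML solution
    on_edge = any(
        np.isclose(v, b[0]) or np.isclose(v, b[1])
        for v, b, p in zip(best.x, bounds, free)
        if not (p == "mu0" and np.isclose(v, 0.0))  # mu0 = 0 is a valid edge
    )
    return ModelFit(
        name=name,
        spec=spec_hat,
        params=dict(zip(free, (float(v) for v in best.x))),
        loglik=float(loglik),
        k=len(free),
        n=n,
        aicc=aicc(loglik, len(free), n),
        converged=bool(best.success) and not on_edge,
        n_starts_ok=n_ok,
    )


def model_select(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank fits by AICc (ascending); adds delta-AICc and a best flag."""
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits disagree on n (branching times): {sorted(ns)}")
    rows = [f.to_row() for f in fits]
    df = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    df["delta_AICc"] = df["AICc"] - df["AICc"].iloc[0]
    df["best"] = df["delta_AICc"] == 0.0
    return df


def fit_all_models(
    chrono: Chronogram,
    paleo: PaleoCurve | None,
    sampling_fraction: float = 1.0,
    models: tuple[ModelTemplate, ...] = DEFAULT_MODELS,
    starts: int = 3,
    seed: int = 0,
) -> tuple[list[ModelFit], pd.DataFrame]:
    """Fit the model registry and return (fits, AICc ranking table)."""
    fits = []
    for i, tmpl in enumerate(models):
        fits.append(
            fit_env_bd(
                chrono,
                tmpl,
                paleo,
                sampling_fraction=sampling_fraction,
                starts=starts,
                seed=seed + 1000 * i,
            )
        )
    return fits, model_select(fits)
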