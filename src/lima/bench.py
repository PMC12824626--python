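"""Simulation-study driver: replicate scenarios, fit estimators, score them.

For each replicate the driver generates a ground-truth model and summary
statistics, applies IVW mediator selection (re-simulating if the selected
set is empty), fits the requested estimators, and computes the per-replicate
mediation proportion with a normal-approximation 95% CI. Per scenario it
reports, per method:

* relative bias (percent of true MP) of the group-regression MP estimate,
* coverage: share of per-replicate CIs containing the true MP,
* power (MP > 0) or type-I error (MP = 0): share of CIs excluding zero,
* the variance of the per-replicate MP estimates,
* the non-convergence count (excluded from the group aggregation).

Replicate r draws its RNG from child r of a SeedSequence keyed by the
scenario seed, so results are reproducible and independent of batching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, field

import numpy as np
import pandas as pd

from .data import Scenario
from .ilima import ILiMA
from .lima_ml import LiMA
from .mediation import Z95, lrt_variances, mp_group, mp_single
from .mr import SingularDesignError, TwoStepMR
from .synth import simulate_replicate, simulate_selected_replicate

METHODS = ("mr_mvmr", "lima", "ilima")
_ALIASES = {"mr": "mr_mvmr", "mvmr": "mr_mvmr", "mr_mvmr": "mr_mvmr",
            "lima": "lima", "ilima": "ilima"}


def default_scenario(**overrides) -> Scenario:
    """The standard simulation conditions (see :class:`Scenario` defaults)."""
    return Scenario(**overrides)


def null_scenario(**overrides) -> Scenario:
    """No-mediation conditions: MP = 0, a single null mediator.

    The mediator carries no mediation (gamma = 0) though it may affect the
    outcome. IVW selection still runs (at Bonferroni 0.05/k = 0.05 for
    k = 1), with re-simulation when nothing passes — the winner's curse this
    induces on the selected gamma_hat is precisely what inflates the type-I
    error of estimators that read the indirect effect off gamma_hat.
    """
    params = dict(mp=0.0, k=1, p_k=1.0)
    params.update(overrides)
    return Scenario(**params)


def _fit_one(method: str, data):
    """Fit one estimator; returns (alpha, theta, var_alpha, var_theta, converged)."""
    if method == "mr_mvmr":
        est = TwoStepMR().fit(data)
        return est.alpha_, est.theta_, est.var_alpha_, est.var_theta_, True
    if method == "lima":
        est = LiMA().fit(data)
    elif method == "ilima":
        est = ILiMA().fit(data)
    else:
        raise ValueError(f"unknown method {method!r}")
    ll_ao = est.profile_loglik_ao(data)
    var_a, _, var_t, _, _ = lrt_variances(est.alpha_, est.omega_, ll_ao)
    return est.alpha_, est.theta_, var_a, var_t, est.converged_


@dataclass
class ScenarioMetrics:
    """Per-method performance metrics of one scenario."""

    scenario: Scenario
    methods: tuple
    metrics: dict            # method -> {metric -> (value, ci_lo, ci_hi)}
    estimates: pd.DataFrame  # one row per replicate x method
    n_resimulations: int = 0
    extras: dict = field(default_factory=dict)

    def value(self, method: str, metric: str) -> float:
        return self.metrics[_ALIASES[method]][metric][0]

    def to_long_frame(self, label: str = "scenario") -> pd.DataFrame:
        rows = []
        for method, mm in self.metrics.items():
            for metric, (value, lo, hi) in mm.items():
                rows.append({"scenario": label, "method": method,
                             "metric": metric, "value": value,
                             "ci_lo": lo, "ci_hi": hi})
        return pd.DataFrame(rows)


def _binomial_ci(p: float, n: int) -> tuple[float, float]:
    if n == 0 or not np.isfinite(p):
        return (math.nan, math.nan)
    half = Z95 * math.sqrt(max(p * (1 - p), 0.0) / n)
    return (p - half, p + half)


def run_scenario(scenario: Scenario, methods=METHODS, n_reps: int | None = None,
                 keep_all_mediators: bool = False) -> ScenarioMetrics:
    """Run ``n_reps`` replicates of a scenario through the chosen estimators.

    ``keep_all_mediators`` bypasses IVW selection (the oracle setting).
    """
    methods = tuple(_ALIASES[m] for m in methods)
    n_reps = scenario.n_reps if n_reps is None else n_reps
    children = np.random.SeedSequence(scenario.seed).spawn(n_reps)
    records = []
    n_resim_total = 0
    bypass = keep_all_mediators or scenario.selection_threshold >= 1.0
    for r in range(n_reps):
        rng = np.random.default_rng(children[r])
        if bypass:
            truth, arch, data = simulate_replicate(scenario, rng)
            n_selected, n_resim = data.k, 0
        else:
            truth, arch, data, idx, n_resim = simulate_selected_replicate(scenario, rng)
            n_selected = data.k
        n_resim_total += n_resim
        for method in methods:
            try:
                alpha, theta, var_a, var_t, conv = _fit_one(method, data)
            except (SingularDesignError, np.linalg.LinAlgError):
                records.append({"rep": r, "method": method, "converged": False,
                                "alpha": math.nan, "theta": math.nan,
                                "var_alpha": math.nan, "var_theta": math.nan,
                                "mp": math.nan, "var_mp": math.nan,
                                "n_selected": n_selected, "n_resim": n_resim,
                                "true_theta": truth.theta})
                continue
            mp = mp_single(alpha, theta, var_a, var_t, method=method)
            records.append({"rep": r, "method": method, "converged": bool(conv),
                            "alpha": alpha, "theta": theta,
                            "var_alpha": var_a, "var_theta": var_t,
                            "mp": mp.mp_hat, "var_mp": mp.var_mp,
                            "n_selected": n_selected, "n_resim": n_resim,
                            "true_theta": truth.theta})
    est = pd.DataFrame.from_records(records)
    metrics = {m: _score_method(est[est["method"] == m], scenario) for m in methods}
    return ScenarioMetrics(scenario=scenario, methods=methods, metrics=metrics,
                           estimates=est, n_resimulations=n_resim_total)


def _score_method(df: pd.DataFrame, scenario: Scenario) -> dict:
    mp_true = scenario.mp
    conv = df[df["converged"]]
    n_conv = len(conv)
    out = {}
    out["n_nonconverged"] = (float(len(df) - n_conv), math.nan, math.nan)
    if n_conv >= 2:
        grp = mp_group(conv["alpha"].to_numpy(), conv["theta"].to_numpy(),
                       n_excluded=len(df) - n_conv)
        out["mp_group"] = (grp.mp_hat, *grp.ci)
        if mp_true > 0:
            rb = 100.0 * (mp_true - grp.mp_hat) / mp_true
            half = 100.0 * Z95 * grp.se / mp_true
            out["relative_bias_pct"] = (rb, rb - half, rb + half)
    half_mp = Z95 * np.sqrt(conv["var_mp"].to_numpy())
    lo = conv["mp"].to_numpy() - half_mp
    hi = conv["mp"].to_numpy() + half_mp
    covered = (lo <= mp_true) & (mp_true <= hi)
    excl0 = (lo > 0) | (hi < 0)
    if n_conv:
        cov = 100.0 * float(np.mean(covered))
        out["coverage_pct"] = (cov, *(100 * c for c in _binomial_ci(cov / 100, n_conv)))
        rate = 100.0 * float(np.mean(excl0))
        key = "power_pct" if mp_true > 0 else "t1e_pct"
        out[key] = (rate, *(100 * c for c in _binomial_ci(rate / 100, n_conv)))
        finite = conv["mp"].to_numpy()
        finite = finite[np.isfinite(finite)]
        out["var_mp_hat"] = (float(np.var(finite, ddof=1)) if finite.size > 1 else math.nan,
                             math.nan, math.nan)
    return out


def sweep(parameter_name: str, values, base: Scenario, methods=METHODS,
          n_reps: int | None = None) -> list[ScenarioMetrics]:
    """One :func:`run_scenario` per value of a Scenario field."""
    valid = {f.name for f in fields(Scenario)}
    if parameter_name not in valid:
        raise ValueError(
            f"unknown Scenario parameter {parameter_name!r}; valid names: "
            f"{sorted(valid)}")
    return [run_scenario(base.with_(**{parameter_name: v}), methods=methods,
                         n_reps=n_reps) for v in values]


def sweep_long_frame(parameter_name: str, results) -> pd.DataFrame:
    """Tidy long-format table over a sweep, one row per metric value."""
    frames = []
    for res in results:
        label = f"{parameter_name}={getattr(res.scenario, parameter_name)}"
        frames.append(res.to_long_frame(label=label))
    return pd.concat(frames, ignore_index=True)
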