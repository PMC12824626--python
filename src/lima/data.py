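"""Core containers for the mediation framework.

All traits (exposure X, mediators M_1..M_k, outcome Y) are assumed standardized
to zero mean and unit variance, so the sampling variance of a marginal genetic
effect estimate is approximately the reciprocal of the study sample size.

The five summary-statistic blocks are

* ``beta_hat``  (m,)    instrument effects on the exposure,
* ``C_hat``     (m, k)  exposure-instrument effects on the mediators,
* ``B_hat``     (l, k)  mediator-instrument effects on the mediators,
* ``c_hat``     (m,)    exposure-instrument effects on the outcome,
* ``b_hat``     (l,)    mediator-instrument effects on the outcome,

and they are the sole input of every estimator in this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class InvalidParameterError(ValueError):
    """A simulation or model parameter is outside its admissible domain."""


class DegenerateModelError(ValueError):
    """The requested ground-truth model is internally inconsistent."""


@dataclass
class Scenario:
    """Full parameter set of one simulation scenario.

    Defaults are the standard study conditions used throughout: complex-trait
    exposure and outcome (n = 300,000), molecular mediators (n = 10,000),
    expected total effect E(theta) = 0.15 with mediation proportion 0.15,
    exposure heritability 0.35, k = 10 mediators all carrying mediation
    (p_k = 1), outcome variance explained by mediators 0.05, uncorrelated
    mediation effects, independent mediators, no pleiotropy, 300 replicates.
    """

    n_X: int = 300_000
    n_M: int = 10_000
    n_Y: int = 300_000
    m: int = 100
    k: int = 10
    p_k: float = 1.0
    selection_pval: float | None = None  # None -> Bonferroni 0.05/k
    expected_theta: float = 0.15
    mp: float = 0.15
    h2_X: float = 0.35
    sigma2_YM: float = 0.05
    rho_gd: float = 0.0
    sigma_strategy: str = "identity"
    sigma2_C: float = 0.0
    sigma2_c: float = 0.0
    sigma2_b: float = 0.0
    # alpha ~ Uniform((1-spread)E(theta), (1+spread)E(theta)) when mp == 0
    alpha_null_spread: float = 0.5
    # mean of the zero-truncated geometric for per-mediator instrument counts
    mean_instruments: float = 3.0
    n_reps: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.n_X, self.n_M, self.n_Y) <= 0:
            raise InvalidParameterError("sample sizes must be positive")
        if self.m < 1 or self.k < 1:
            raise InvalidParameterError("m and k must be >= 1")
        if not 0 <= self.p_k <= 1:
            raise InvalidParameterError("p_k must lie in [0, 1]")
        if not 0 <= self.mp <= 1:
            raise InvalidParameterError("mp must lie in [0, 1]")
        if not 0 < self.h2_X < 1:
            raise InvalidParameterError("h2_X must lie in (0, 1)")
        if self.sigma2_YM <= 0:
            raise InvalidParameterError("sigma2_YM must be positive")
        if not abs(self.rho_gd) < 1:
            raise InvalidParameterError("|rho_gd| must be < 1")
        if min(self.sigma2_C, self.sigma2_c, self.sigma2_b) < 0:
            raise InvalidParameterError("pleiotropy variances must be >= 0")
        if self.sigma_strategy not in ("identity", "random_vectors", "empirical_matrix"):
            raise InvalidParameterError(f"unknown sigma_strategy {self.sigma_strategy!r}")
        if self.selection_pval is not None and not 0 < self.selection_pval <= 1:
            raise InvalidParameterError("selection_pval must lie in (0, 1]")
        if self.mp > 0 and round(self.p_k * self.k) < 1 and self.p_k * self.k < 0.5:
            # k_s is floored at 1 when mp > 0, so this is a soft constraint
            pass

    @property
    def k_s(self) -> int:
        """Number of mediators carrying non-zero mediation effects."""
        ks = int(round(self.p_k * self.k))
        if self.mp > 0:
            ks = max(ks, 1)
        return ks

    @property
    def selection_threshold(self) -> float:
        return self.selection_pval if self.selection_pval is not None else 0.05 / self.k

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def with_(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


@dataclass
class TrueEffects:
    """Ground-truth causal parameters of one mediation model.

    theta = alpha + gamma'delta by construction; when mp > 0 the mediation
    proportion satisfies mp = 1 - alpha/theta exactly.
    """

    alpha: float
    gamma: np.ndarray
    delta: np.ndarray
    mp: float

    @property
    def omega(self) -> float:
        return float(self.gamma @ self.delta)

    @property
    def theta(self) -> float:
        return self.alpha + self.omega

    def validate(self, atol: float = 1e-10) -> None:
        if self.gamma.shape != self.delta.shape:
            raise DegenerateModelError("gamma and delta must have equal length")
        if self.mp > 0 and self.theta != 0:
            if abs((1 - self.alpha / self.theta) - self.mp) > 1e-8:
                raise DegenerateModelError("mp inconsistent with alpha and theta")


@dataclass
class GeneticArchitecture:
    """True instrument effects and mediator phenotypic correlation.

    ``B`` is block-sparse: mediator j's instruments occupy the contiguous row
    block recorded in ``owner`` (owner[i] = index of the mediator instrumenting
    row i), and B is zero outside those blocks.
    """

    beta: np.ndarray            # (m,)
    B: np.ndarray               # (l, k)
    h2_M: np.ndarray            # (k,)
    l_per_mediator: np.ndarray  # (k,) integer
    Sigma: np.ndarray           # (k, k)
    chol: np.ndarray            # lower Cholesky factor of Sigma
    owner: np.ndarray           # (l,) integer block labels

    @property
    def m(self) -> int:
        return self.beta.shape[0]

    @property
    def k(self) -> int:
        return self.B.shape[1]

    @property
    def l(self) -> int:
        return self.B.shape[0]


@dataclass
class SummaryData:
    """The five noisy summary-statistic blocks plus their variance model."""

    beta_hat: np.ndarray  # (m,)
    C_hat: np.ndarray     # (m, k)
    B_hat: np.ndarray     # (l, k)
    c_hat: np.ndarray     # (m,)
    b_hat: np.ndarray     # (l,)
    n_X: float
    n_M: float
    n_Y: float
    sigma2_C: float = 0.0
    sigma2_c: float = 0.0
    sigma2_b: float = 0.0
    var_c: np.ndarray | None = None  # per-element Var(c_hat_i); default 1/n_Y + sigma2_c
    var_b: np.ndarray | None = None  # per-element Var(b_hat_i); default 1/n_Y + sigma2_b
    owner: np.ndarray | None = None  # mediator index owning each B_hat row

    def __post_init__(self) -> None:
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        self.C_hat = np.atleast_2d(np.asarray(self.C_hat, dtype=float))
        self.B_hat = np.atleast_2d(np.asarray(self.B_hat, dtype=float))
        self.c_hat = np.asarray(self.c_hat, dtype=float)
        self.b_hat = np.asarray(self.b_hat, dtype=float)
        if self.var_c is None:
            self.var_c = np.full(self.m, 1.0 / self.n_Y + self.sigma2_c)
        else:
            self.var_c = np.asarray(self.var_c, dtype=float)
        if self.var_b is None:
            self.var_b = np.full(self.l, 1.0 / self.n_Y + self.sigma2_b)
        else:
            self.var_b = np.asarray(self.var_b, dtype=float)
        self.validate()

    @property
    def m(self) -> int:
        return self.beta_hat.shape[0]

    @property
    def k(self) -> int:
        return self.C_hat.shape[1]

    @property
    def l(self) -> int:
        return self.B_hat.shape[0]

    @property
    def var_C_element(self) -> float:
        """Variance of one C_hat element under unit-diagonal Sigma."""
        return 1.0 / self.n_M + self.sigma2_C

    def validate(self) -> None:
        m, k, l = self.m, self.k, self.l
        if self.C_hat.shape != (m, k):
            raise InvalidParameterError(f"C_hat must be ({m}, {k}), got {self.C_hat.shape}")
        if self.B_hat.shape[1] != k:
            raise InvalidParameterError("B_hat column count must equal k")
        if self.c_hat.shape != (m,) or self.b_hat.shape != (l,):
            raise InvalidParameterError("c_hat/b_hat lengths inconsistent")
        if self.var_c.shape != (m,) or self.var_b.shape != (l,):
            raise InvalidParameterError("var_c/var_b lengths inconsistent")
        if np.any(self.var_c <= 0) or np.any(self.var_b <= 0):
            raise InvalidParameterError("all variance entries must be > 0")
        if self.owner is not None and len(self.owner) != l:
            raise InvalidParameterError("owner must label every B_hat row")

    def subset(self, mediator_idx) -> "SummaryData":
        """Restrict to a subset of mediators (and their own instruments)."""
        idx = np.asarray(sorted(mediator_idx), dtype=int)
        if self.owner is not None:
            rows = np.isin(self.owner, idx)
        else:  # fall back to structural non-zeros
            rows = np.any(self.B_hat[:, idx] != 0, axis=1)
        new_owner = None
        if self.owner is not None:
            remap = {int(j): r for r, j in enumerate(idx)}
            new_owner = np.array([remap[int(j)] for j in self.owner[rows]], dtype=int)
        return SummaryData(
            beta_hat=self.beta_hat,
            C_hat=self.C_hat[:, idx],
            B_hat=self.B_hat[np.ix_(rows, idx)],
            c_hat=self.c_hat,
            b_hat=self.b_hat[rows],
            n_X=self.n_X, n_M=self.n_M, n_Y=self.n_Y,
            sigma2_C=self.sigma2_C, sigma2_c=self.sigma2_c, sigma2_b=self.sigma2_b,
            var_c=self.var_c, var_b=self.var_b[rows],
            owner=new_owner,
        )

    # ---- tab-separated serialization ------------------------------------

    def to_dir(self, path: str | Path, meta: dict | None = None) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        g_ids = [f"G{i + 1}" for i in range(self.m)]
        f_ids = [f"F{i + 1}" for i in range(self.l)]
        med = [f"M{j + 1}" for j in range(self.k)]
        pd.DataFrame({"instrument": g_ids, "beta_hat": self.beta_hat}).to_csv(
            path / "exposure.tsv", sep="\t", index=False)
        pd.DataFrame(self.C_hat, columns=med).assign(instrument=g_ids)[
            ["instrument", *med]].to_csv(path / "mediators_C.tsv", sep="\t", index=False)
        pd.DataFrame(self.B_hat, columns=med).assign(instrument=f_ids)[
            ["instrument", *med]].to_csv(path / "mediators_B.tsv", sep="\t", index=False)
        pd.DataFrame({"instrument": g_ids, "c_hat": self.c_hat, "var_c": self.var_c}).to_csv(
            path / "outcome_c.tsv", sep="\t", index=False)
        pd.DataFrame({"instrument": f_ids, "b_hat": self.b_hat, "var_b": self.var_b}).to_csv(
            path / "outcome_b.tsv", sep="\t", index=False)
        info = {
            "n_X": self.n_X, "n_M": self.n_M, "n_Y": self.n_Y,
            "sigma2_C": self.sigma2_C, "sigma2_c": self.sigma2_c, "sigma2_b": self.sigma2_b,
            "owner": None if self.owner is None else [int(j) for j in self.owner],
        }
        if meta:
            info["meta"] = meta
        (path / "meta.json").write_text(json.dumps(info, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> "SummaryData":
        path = Path(path)
        info = json.loads((path / "meta.json").read_text())
        exp = pd.read_csv(path / "exposure.tsv", sep="\t")
        C = pd.read_csv(path / "mediators_C.tsv", sep="\t").drop(columns="instrument")
        B = pd.read_csv(path / "mediators_B.tsv", sep="\t").drop(columns="instrument")
        oc = pd.read_csv(path / "outcome_c.tsv", sep="\t")
        ob = pd.read_csv(path / "outcome_b.tsv", sep="\t")
        owner = info.get("owner")
        return cls(
            beta_hat=exp["beta_hat"].to_numpy(),
            C_hat=C.to_numpy(), B_hat=B.to_numpy(),
            c_hat=oc["c_hat"].to_numpy(), b_hat=ob["b_hat"].to_numpy(),
            n_X=info["n_X"], n_M=info["n_M"], n_Y=info["n_Y"],
            sigma2_C=info["sigma2_C"], sigma2_c=info["sigma2_c"], sigma2_b=info["sigma2_b"],
            var_c=oc["var_c"].to_numpy(), var_b=ob["var_b"].to_numpy(),
            owner=None if owner is None else np.asarray(owner, dtype=int),
        )


@dataclass
class FitResult:
    """Output of one mediation estimator on one dataset."""

    method: str
    alpha: float
    omega: float
    gamma: np.ndarray | None = None
    delta: np.ndarray | None = None
    var_alpha: float = np.nan
    var_omega: float = np.nan
    var_theta: float = np.nan
    sigma2_g: float | None = None
    sigma2_d: float | None = None
    sigma_gd: float | None = None
    converged: bool = True
    loglik: float = np.nan
    n_mediators: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def theta(self) -> float:
        return self.alpha + self.omega

    def to_json(self) -> str:
        d = {
            "method": self.method, "alpha": self.alpha, "omega": self.omega,
            "theta": self.theta, "var_alpha": self.var_alpha,
            "var_omega": self.var_omega, "var_theta": self.var_theta,
            "converged": bool(self.converged), "loglik": self.loglik,
            "n_mediators": self.n_mediators,
        }
        if self.gamma is not None:
            d["gamma"] = list(map(float, np.atleast_1d(self.gamma)))
        if self.delta is not None:
            d["delta"] = list(map(float, np.atleast_1d(self.delta)))
        for name in ("sigma2_g", "sigma2_d", "sigma_gd"):
            v = getattr(self, name)
            if v is not None:
                d[name] = float(v)
        return json.dumps(d)
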