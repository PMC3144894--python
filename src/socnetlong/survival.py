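"""Barker joint live-recapture / dead-recovery / live-resight survival model.

The Barker model extends Cormack-Jolly-Seber by using, besides live
recaptures at trapping occasions, resightings made between occasions
and recoveries of dead animals.  Seven parameter families govern the
process between occasions i and i+1:

=====  ==============================================================
S      probability an animal alive at i is alive at i+1
p      probability an animal alive and at risk of capture at i is captured
r      probability an animal dying in (i, i+1) is found and reported
R      probability an animal alive at i+1 is resighted in (i, i+1)
R'     probability an animal dying in (i, i+1) is resighted before death
F      probability an animal at risk of capture at i is at risk at i+1
F'     probability an animal not at risk at i is at risk at i+1
=====  ==============================================================

The likelihood is computed per animal by a forward recursion over the
hidden states {alive at risk, alive off risk, dead}, which is
algebraically equivalent to Barker's multinomial formulation and easy
to verify against exhaustive path enumeration.  Model structures
(constant / time / group / two age classes, additively combined) act
on the logit scale; model selection uses QAICc with a user-supplied
overdispersion coefficient c-hat, AIC weights, model averaging with
unconditional standard errors, and likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from .errors import ConfigError, ConsistencyError, DegenerateInputError, RecordError

__all__ = [
    "EVENT_NONE",
    "EVENT_RESIGHT",
    "EVENT_DEAD",
    "EVENT_RESIGHT_DEAD",
    "PARAM_NAMES",
    "EncounterHistory",
    "ModelSpec",
    "FittedModel",
    "history_likelihood",
    "fit_model",
    "model_table",
    "model_average",
    "likelihood_ratio_test",
    "qaicc",
    "read_encounters",
    "write_encounters",
    "to_mark_ld",
]

EVENT_NONE = 0
EVENT_RESIGHT = 1          # resighted alive during the interval
EVENT_DEAD = 2             # found dead (band/collar recovered)
EVENT_RESIGHT_DEAD = 3     # resighted alive, then recovered dead, same interval

PARAM_NAMES = ("S", "p", "r", "R", "Rp", "F", "Fp")
_STRUCTURE_TOKENS = ("constant", "time", "group", "age")


@dataclass
class EncounterHistory:
    """One animal's capture occasions and between-occasion events."""

    id: str
    captures: np.ndarray          # shape (T,), 0/1
    events: np.ndarray            # shape (T-1,), event codes
    group: str = "all"
    age_class: str = "adult"      # age class at first capture: "pup" or "adult"
    cohort: int | None = None

    def __post_init__(self):
        self.captures = np.asarray(self.captures, dtype=np.int8)
        self.events = np.asarray(self.events, dtype=np.int8)
        T = len(self.captures)
        if len(self.events) != T - 1:
            raise RecordError(f"{self.id}: need T-1 interval events for T={T} occasions")
        if not np.any(self.captures == 1):
            raise RecordError(f"{self.id}: history has no capture")
        if np.any((self.captures != 0) & (self.captures != 1)):
            raise RecordError(f"{self.id}: capture flags must be 0/1")
        if np.any((self.events < 0) | (self.events > 3)):
            raise RecordError(f"{self.id}: unknown interval event code")
        f = self.first
        if np.any(self.captures[:f]) or np.any(self.events[:f]):
            raise RecordError(f"{self.id}: events precede first capture")
        dead = np.nonzero((self.events == EVENT_DEAD) | (self.events == EVENT_RESIGHT_DEAD))[0]
        if dead.size:
            d = dead[0]
            if dead.size > 1 or np.any(self.events[d + 1:]) or np.any(self.captures[d + 1:]):
                raise RecordError(f"{self.id}: events recorded after dead recovery")
        if self.age_class not in ("pup", "adult"):
            raise RecordError(f"{self.id}: age_class must be 'pup' or 'adult'")

    @property
    def first(self) -> int:
        return int(np.argmax(self.captures == 1))

    @property
    def n_occasions(self) -> int:
        return len(self.captures)


def _param_arrays(
    params: Mapping[str, float | np.ndarray],
    n_intervals: int,
) -> dict[str, np.ndarray]:
    """Broadcast scalar/per-interval parameters to length-n_intervals arrays."""
    out = {}
    for name in PARAM_NAMES:
        if name not in params:
            raise ConfigError(f"missing parameter {name!r}")
        length = n_intervals + 1 if name == "p" else n_intervals
        arr = np.broadcast_to(np.asarray(params[name], dtype=float), (length,)).copy()
        if np.any((arr < 0) | (arr > 1)):
            raise ConfigError(f"parameter {name!r} outside [0, 1]")
        out[name] = arr
    return out


def history_likelihood(
    history: EncounterHistory,
    params: Mapping[str, float | np.ndarray],
) -> float:
    """Exact probability of one observed encounter history.

    Forward pass from first capture over the hidden states
    {alive at risk, alive off risk, dead}: per interval, survival (S),
    then the resight/recovery emission (R for survivors; R' then r for
    deaths), the fidelity transition (F / F'), and the capture emission
    at the next occasion (p for at-risk animals; off-risk animals
    cannot be captured).
    """
    T = history.n_occasions
    P = _param_arrays(params, T - 1)
    ar, ao, dd = 1.0, 0.0, 0.0  # conditioned on release at first capture
    for i in range(history.first, T - 1):
        e = int(history.events[i])
        y = int(history.captures[i + 1])
        S, R, Rp, r = P["S"][i], P["R"][i], P["Rp"][i], P["r"][i]
        F, Fp, p = P["F"][i], P["Fp"][i], P["p"][i + 1]
        if e == EVENT_NONE:
            em_s, em_d = 1.0 - R, (1.0 - Rp) * (1.0 - r)
        elif e == EVENT_RESIGHT:
            em_s, em_d = R, Rp * (1.0 - r)
        elif e == EVENT_DEAD:
            em_s, em_d = 0.0, (1.0 - Rp) * r
        else:  # EVENT_RESIGHT_DEAD
            em_s, em_d = 0.0, Rp * r
        dd_next = (dd * (1.0 if e == EVENT_NONE else 0.0)
                   + (ar + ao) * (1.0 - S) * em_d)
        a_s = ar * S * em_s
        o_s = ao * S * em_s
        ar2 = a_s * F + o_s * Fp
        ao2 = a_s * (1.0 - F) + o_s * (1.0 - Fp)
        if y == 1:
            ar, ao, dd = ar2 * p, 0.0, 0.0  # a dead animal cannot be captured
        else:
            ar, ao, dd = ar2 * (1.0 - p), ao2, dd_next
    return float(ar + ao + dd)


# ---------------------------------------------------------------------------
# vectorized likelihood over an animal x occasion grid (used for fitting)
# ---------------------------------------------------------------------------


def _stack_histories(histories: Sequence[EncounterHistory]):
    if not histories:
        raise DegenerateInputError("no encounter histories")
    T = histories[0].n_occasions
    if any(h.n_occasions != T for h in histories):
        raise ConsistencyError("all histories must span the same occasions")
    captures = np.stack([h.captures for h in histories]).astype(np.int8)
    events = np.stack([h.events for h in histories]).astype(np.int8)
    first = np.array([h.first for h in histories], dtype=np.int64)
    groups = np.array([h.group for h in histories])
    ages = np.array([h.age_class for h in histories])
    return captures, events, first, groups, ages


def _forward_loglik(captures, events, first, P) -> float:
    """Sum of log history probabilities; P maps names to (n, T[-1]) arrays."""
    n, T = captures.shape
    ar = np.zeros(n)
    ao = np.zeros(n)
    dd = np.zeros(n)
    done = np.ones(n)  # finished likelihood for late releases handled at end
    for i in range(T - 1):
        entering = first == i
        ar[entering] = 1.0
        active = first <= i
        e = events[:, i]
        y = captures[:, i + 1]
        S, R, Rp, r = P["S"][:, i], P["R"][:, i], P["Rp"][:, i], P["r"][:, i]
        F, Fp, p = P["F"][:, i], P["Fp"][:, i], P["p"][:, i + 1]

        em_s = np.select([e == EVENT_NONE, e == EVENT_RESIGHT], [1.0 - R, R], 0.0)
        em_d = np.select(
            [e == EVENT_NONE, e == EVENT_RESIGHT, e == EVENT_DEAD],
            [(1.0 - Rp) * (1.0 - r), Rp * (1.0 - r), (1.0 - Rp) * r],
            Rp * r,
        )
        dd_next = (dd * (e == EVENT_NONE) + (ar + ao) * (1.0 - S) * em_d) * (y == 0)
        a_s = ar * S * em_s
        o_s = ao * S * em_s
        ar2 = a_s * F + o_s * Fp
        ao2 = a_s * (1.0 - F) + o_s * (1.0 - Fp)
        ar_new = ar2 * np.where(y == 1, p, 1.0 - p)
        ao_new = ao2 * (y == 0)
        ar = np.where(active, ar_new, ar)
        ao = np.where(active, ao_new, ao)
        dd = np.where(active, dd_next, dd)
    lik = ar + ao + dd
    lik[first == T - 1] = 1.0  # released at the terminal occasion
    return float(np.sum(np.log(np.clip(lik, 1e-300, None))))


# ---------------------------------------------------------------------------
# model structures and fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Per-parameter logit-scale structures.

    Each of S, p, r, R, Rp, F, Fp takes a structure string: "constant",
    "time", "group", "age" (two classes: first year after release as a
    pup vs. older), or additive combinations like "group+time".  A
    float instead of a string fixes the parameter at that value.
    """

    S: str | float = "constant"
    p: str | float = "constant"
    r: str | float = "constant"
    R: str | float = "constant"
    Rp: str | float = "constant"
    F: str | float = "constant"
    Fp: str | float = "constant"

    def structure(self, name: str) -> str | float:
        return getattr(self, name)

    def tokens(self, name: str) -> list[str]:
        s = self.structure(name)
        if isinstance(s, (int, float)):
            return []
        toks = [t.strip() for t in s.split("+") if t.strip()]
        for t in toks:
            if t not in _STRUCTURE_TOKENS:
                raise ConfigError(f"unknown structure token {t!r} for {name}")
        return toks or ["constant"]

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True when every parameter's structure is a sub-structure of other's."""
        for name in PARAM_NAMES:
            a, b = self.structure(name), other.structure(name)
            if isinstance(a, (int, float)) or isinstance(b, (int, float)):
                if a != b:
                    return False
                continue
            ta = set(self.tokens(name)) - {"constant"}
            tb = set(other.tokens(name)) - {"constant"}
            if not ta <= tb:
                return False
        return True


def _young_mask(first: np.ndarray, ages: np.ndarray, T: int, occasions: bool):
    """(n, T-1) or (n, T) indicator: animal in its first year after pup release."""
    n = len(first)
    m = T if occasions else T - 1
    out = np.zeros((n, m))
    pup = ages == "pup"
    idx = np.arange(m)[None, :]
    offset = 1 if occasions else 0
    out[pup] = (idx == (first[pup, None] + offset)).astype(float)
    return out


def _build_design(spec, name, first, groups, ages, T):
    """Design tensor X of shape (n, m, k) for one parameter on the logit scale."""
    n = len(first)
    m = T if name == "p" else T - 1
    cols = [np.ones((n, m))]
    labels = [f"{name}:(Intercept)"]
    for token in spec.tokens(name):
        if token == "constant":
            continue
        if token == "time":
            for t in range(1, m):
                col = np.zeros((n, m))
                col[:, t] = 1.0
                cols.append(col)
                labels.append(f"{name}:time[{t}]")
        elif token == "group":
            levels = sorted(set(groups.tolist()))
            for lev in levels[1:]:
                col = np.tile((groups == lev).astype(float)[:, None], (1, m))
                cols.append(col)
                labels.append(f"{name}:group[{lev}]")
        elif token == "age":
            cols.append(_young_mask(first, ages, T, occasions=(name == "p")))
            labels.append(f"{name}:age[young]")
    return np.stack(cols, axis=2), labels


@dataclass
class FittedModel:
    spec: ModelSpec
    coefficients: np.ndarray
    coef_labels: list[str]
    slices: dict
    loglik: float
    K: int
    n_eff: int
    c_hat: float
    qaicc: float
    vcov: np.ndarray | None
    converged: bool
    boundary: bool
    data_key: tuple
    _designs: dict = field(repr=False, default_factory=dict)
    _fixed: dict = field(repr=False, default_factory=dict)

    def coef(self, name: str) -> np.ndarray:
        return self.coefficients[self.slices[name]]

    def real_estimate(self, name: str, **covariates) -> tuple[float, float]:
        """Probability-scale estimate and delta-method SE for one stratum.

        Covariates select the stratum: ``time`` (interval or occasion
        index), ``group`` (label), ``young`` (bool).  The SE is
        inflated by sqrt(c-hat).
        """
        if name in self._fixed:
            return float(self._fixed[name]), 0.0
        labels = [l for l in self.coef_labels if l.startswith(f"{name}:")]
        x = np.zeros(len(labels))
        for j, lab in enumerate(labels):
            key = lab.split(":", 1)[1]
            if key == "(Intercept)":
                x[j] = 1.0
            elif key.startswith("time["):
                x[j] = 1.0 if int(key[5:-1]) == covariates.get("time", 0) else 0.0
            elif key.startswith("group["):
                x[j] = 1.0 if key[6:-1] == str(covariates.get("group", "")) else 0.0
            elif key == "age[young]":
                x[j] = 1.0 if covariates.get("young", False) else 0.0
        beta = self.coef(name)
        eta = float(x @ beta)
        est = 1.0 / (1.0 + np.exp(-eta))
        if self.vcov is None:
            return est, float("nan")
        sl = self.slices[name]
        v = self.vcov[sl.start:sl.stop, sl.start:sl.stop]
        var_eta = float(x @ v @ x)
        se = est * (1.0 - est) * np.sqrt(max(var_eta, 0.0) * self.c_hat)
        return est, se


def qaicc(loglik: float, K: int, n_eff: int, c_hat: float = 1.0) -> float:
    """Small-sample, overdispersion-corrected AIC:
    -2 lnL / c-hat + 2K + 2K(K+1)/(n_eff - K - 1)."""
    if n_eff <= K + 1:
        raise DegenerateInputError("effective sample size too small for QAICc")
    return -2.0 * loglik / c_hat + 2.0 * K + 2.0 * K * (K + 1) / (n_eff - K - 1)


def fit_model(
    histories: Sequence[EncounterHistory],
    spec: ModelSpec,
    c_hat: float = 1.0,
    n_starts: int = 1,
    seed: int = 0,
    compute_vcov: bool = True,
    gtol: float = 1e-8,
) -> FittedModel:
    """Maximize the joint Barker likelihood under a model structure.

    Coefficients live on the logit scale; optimization is L-BFGS-B with
    optional jittered multi-start.  The effective sample size for QAICc
    is the number of released animals.  Non-convergence and boundary
    estimates (|logit| > 10) are flagged on the result, never silent.
    """
    if c_hat <= 0:
        raise ConfigError("c_hat must be positive")
    captures, events, first, groups, ages = _stack_histories(histories)
    n, T = captures.shape

    designs: dict[str, np.ndarray] = {}
    fixed: dict[str, float] = {}
    slices: dict[str, slice] = {}
    labels: list[str] = []
    k = 0
    for name in PARAM_NAMES:
        struct = spec.structure(name)
        if isinstance(struct, (int, float)):
            if not 0.0 <= float(struct) <= 1.0:
                raise ConfigError(f"fixed value for {name} outside [0, 1]")
            fixed[name] = float(struct)
            slices[name] = slice(k, k)
            continue
        X, labs = _build_design(spec, name, first, groups, ages, T)
        designs[name] = X
        slices[name] = slice(k, k + X.shape[2])
        labels.extend(labs)
        k += X.shape[2]

    def params_from(theta: np.ndarray) -> dict[str, np.ndarray]:
        P = {}
        for name in PARAM_NAMES:
            if name in fixed:
                m = T if name == "p" else T - 1
                P[name] = np.full((n, m), fixed[name])
            else:
                eta = designs[name] @ theta[slices[name]]
                P[name] = 1.0 / (1.0 + np.exp(-eta))
        return P

    def nll(theta: np.ndarray) -> float:
        return -_forward_loglik(captures, events, first, params_from(theta))

    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        x0 = np.zeros(k) if s == 0 else rng.normal(scale=0.5, size=k)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            options={"maxiter": 2000, "gtol": gtol, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    loglik = -float(best.fun)
    boundary = bool(np.any(np.abs(theta) > 10.0))

    vcov = None
    if compute_vcov and k > 0:
        try:
            H = numdiff.approx_hess(theta, nll)
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = None

    return FittedModel(
        spec=spec,
        coefficients=theta,
        coef_labels=labels,
        slices=slices,
        loglik=loglik,
        K=k,
        n_eff=n,
        c_hat=c_hat,
        qaicc=qaicc(loglik, k, n, c_hat),
        vcov=vcov,
        converged=bool(best.success),
        boundary=boundary,
        data_key=(n, T, int(captures.sum()), int(events.sum())),
        _designs=designs,
        _fixed=fixed,
    )


def model_table(fits: Sequence[FittedModel]) -> pd.DataFrame:
    """Rank a candidate set by QAICc with deltas and normalized weights."""
    if not fits:
        raise ConfigError("empty model set")
    key = fits[0].data_key
    c = fits[0].c_hat
    if any(f.data_key != key or f.c_hat != c for f in fits):
        raise ConsistencyError("model table requires identical data and c-hat")
    q = np.array([f.qaicc for f in fits])
    delta = q - q.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    frame = pd.DataFrame(
        {
            "model": [repr(f.spec) for f in fits],
            "loglik": [f.loglik for f in fits],
            "K": [f.K for f in fits],
            "qaicc": q,
            "delta_qaicc": delta,
            "weight": w,
            "converged": [f.converged for f in fits],
        }
    )
    return frame.sort_values("qaicc").reset_index(drop=True)


def model_average(
    fits: Sequence[FittedModel],
    parameter: str,
    **covariates,
) -> tuple[float, float]:
    """QAICc-weight-averaged probability estimate with unconditional SE.

    The unconditional variance combines each model's sampling variance
    with the between-model spread of the estimates.
    """
    table = model_table(fits)
    order = np.argsort([f.qaicc for f in fits], kind="stable")
    weights = np.asarray(table["weight"])  # sorted ascending by qaicc
    ests, ses = [], []
    for idx in order:
        f = fits[idx]
        if parameter not in PARAM_NAMES:
            raise ConfigError(f"unknown parameter {parameter!r}")
        est, se = f.real_estimate(parameter, **covariates)
        if np.isnan(est):
            raise ConfigError(f"parameter {parameter!r} not estimable in model {f.spec!r}")
        ests.append(est)
        ses.append(se)
    ests = np.asarray(ests)
    ses = np.asarray(ses)
    avg = float(np.sum(weights * ests))
    var_u = float(np.sum(weights * (ses ** 2 + (ests - avg) ** 2)))
    return avg, float(np.sqrt(var_u))


def likelihood_ratio_test(
    nested: FittedModel,
    full: FittedModel,
) -> tuple[float, int, float]:
    """Chi-square LRT of a nested model against the full model."""
    if nested.data_key != full.data_key:
        raise ConsistencyError("LRT requires both fits on the same data")
    if not nested.spec.is_nested_in(full.spec) or nested.K >= full.K:
        raise ConsistencyError("first model is not nested in the second")
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    df = full.K - nested.K
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_encounters(path: str | Path) -> list[EncounterHistory]:
    """Read the encounter CSV: id, group, age_class, cap_1..cap_T, int_1..int_{T-1}."""
    frame = pd.read_csv(path)
    cap_cols = sorted(
        (c for c in frame.columns if c.startswith("cap_")), key=lambda c: int(c[4:])
    )
    int_cols = sorted(
        (c for c in frame.columns if c.startswith("int_")), key=lambda c: int(c[4:])
    )
    if not cap_cols or len(int_cols) != len(cap_cols) - 1:
        raise ConfigError("need cap_1..cap_T and int_1..int_{T-1} columns")
    out = []
    for _, row in frame.iterrows():
        out.append(
            EncounterHistory(
                id=str(row["id"]),
                captures=np.array([int(row[c]) for c in cap_cols]),
                events=np.array([int(row[c]) for c in int_cols]),
                group=str(row.get("group", "all")),
                age_class=str(row.get("age_class", "adult")),
            )
        )
    return out


def write_encounters(histories: Sequence[EncounterHistory], path: str | Path) -> None:
    rows = []
    for h in histories:
        row = {"id": h.id, "group": h.group, "age_class": h.age_class}
        row.update({f"cap_{i + 1}": int(v) for i, v in enumerate(h.captures)})
        row.update({f"int_{i + 1}": int(v) for i, v in enumerate(h.events)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def to_mark_ld(history: EncounterHistory) -> str:
    """Best-effort MARK-style LDLD string (capture, then interval code)."""
    out = []
    for i, cap in enumerate(history.captures):
        out.append(str(int(cap)))
        if i < len(history.events):
            e = int(history.events[i])
            out.append({EVENT_NONE: "0", EVENT_RESIGHT: "2",
                        EVENT_DEAD: "1", EVENT_RESIGHT_DEAD: "1"}[e])
    return "".join(out)
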