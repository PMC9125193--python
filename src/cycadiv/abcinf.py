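"""Approximate Bayesian computation: reference tables, rejection, model
choice, goodness of fit and regression-adjusted posteriors.

The workflow mirrors standard rejection ABC for demographic model
choice: draw parameters from priors, simulate a SNP dataset per draw,
summarize it, keep the ``k`` simulations closest to the observed
statistics (Euclidean distance on MAD-standardized statistics,
Epanechnikov weights), and read model posterior probabilities off the
retained weight shares.  Bayes factors are weighted-acceptance-odds
ratios against the equal-prior composite of the other models.  Parameter
posteriors under the selected model are summarized from the retained
draws, optionally after local-linear or neural-network regression
adjustment of log-parameters on the retained statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cycadiv import coalsim, sumstats
from cycadiv.coalsim import MODELS, DemographicParams, SimConfig
from cycadiv.sumstats import ABC_STAT_NAMES, SumStatVector

__all__ = [
    "PriorSet",
    "default_priors",
    "sample_priors",
    "SimTable",
    "build_reference_table",
    "prune_correlated",
    "rejection",
    "ModelSelectionResult",
    "model_posterior",
    "GofResult",
    "goodness_of_fit",
    "PosteriorSummary",
    "adjust_parameters",
    "weighted_interval",
]

TIME_ORDER = ("t1", "t2", "t3")  # sampled pastmost-first to honour t1<=t2<=t3


@dataclass
class Prior:
    kind: str  # 'uniform' | 'loguniform'
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ValueError(f"bad prior bounds ({self.lo}, {self.hi})")
        if self.kind not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "loguniform" and self.lo <= 0:
            raise ValueError("loguniform prior needs lo > 0")

    def draw(self, rng: np.random.Generator, n: int, hi: np.ndarray | float | None = None) -> np.ndarray:
        hi_arr = np.broadcast_to(np.asarray(self.hi if hi is None else hi, float), (n,))
        if self.kind == "uniform":
            return rng.uniform(self.lo, hi_arr)
        return np.exp(rng.uniform(np.log(self.lo), np.log(hi_arr)))


@dataclass
class PriorSet:
    """Independent priors per demographic parameter, with the ordering
    constraint t1 <= t2 <= t3 enforced by conditional sampling
    (t3 first, then t2 ~ prior truncated at t3, then t1 at t2)."""

    priors: dict[str, Prior]

    def __post_init__(self) -> None:
        missing = set(coalsim.PARAM_NAMES) - set(self.priors)
        if missing:
            raise ValueError(f"priors missing for {sorted(missing)}")


def default_priors() -> PriorSet:
    """Reconstructed default priors, chosen to be consistent with the
    posterior 95% intervals the models should be able to reach
    (``reconstructed: true`` in config exports)."""
    return PriorSet(priors={
        "N_CR2": Prior("uniform", 100.0, 1e4),
        "N_CT2": Prior("uniform", 100.0, 5e3),
        "N_anc_REL": Prior("uniform", 0.5, 10.0),
        "N_CR_REL": Prior("uniform", 0.5, 10.0),
        "N_CT_REL": Prior("uniform", 0.5, 10.0),
        "t1": Prior("uniform", 10.0, 3e5),
        "t2": Prior("uniform", 10.0, 3e5),
        "t3": Prior("uniform", 10.0, 3e5),
        "m_CT1": Prior("loguniform", 1e-8, 1.0),
        "m_CR1": Prior("loguniform", 1e-8, 1.0),
        "m_CT2": Prior("loguniform", 1e-8, 1.0),
        "m_CR2": Prior("loguniform", 1e-8, 1.0),
        "mu": Prior("uniform", 1e-8, 2e-7),
    })


def sample_priors(ps: PriorSet, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` parameter vectors honouring t1 <= t2 <= t3."""
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    draws["t3"] = ps.priors["t3"].draw(rng, n)
    draws["t2"] = ps.priors["t2"].draw(rng, n, hi=draws["t3"])
    draws["t1"] = ps.priors["t1"].draw(rng, n, hi=draws["t2"])
    for name in coalsim.PARAM_NAMES:
        if name in TIME_ORDER:
            continue
        draws[name] = ps.priors[name].draw(rng, n)
    return pd.DataFrame(draws)[coalsim.PARAM_NAMES]


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass
class SimTable:
    """ABC reference table: one row per simulation."""

    table: pd.DataFrame          # columns: model + params + statistics
    stat_names: list[str]
    param_names: list[str]
    meta: dict = field(default_factory=dict)

    def stats(self, names: list[str] | None = None) -> np.ndarray:
        return self.table[names or self.stat_names].to_numpy(float)

    def params(self) -> np.ndarray:
        return self.table[self.param_names].to_numpy(float)

    def restrict(self, model: str) -> "SimTable":
        sub = self.table[self.table["model"] == model].reset_index(drop=True)
        return SimTable(sub, list(self.stat_names), list(self.param_names), dict(self.meta))

    def save(self, tsv_path, meta_path=None) -> None:
        self.table.to_csv(tsv_path, sep="\t", index=False)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(
                    {"stat_names": self.stat_names,
                     "param_names": self.param_names,
                     **self.meta},
                    fh, indent=2, default=str,
                )

    @classmethod
    def load(cls, tsv_path, meta_path) -> "SimTable":
        table = pd.read_csv(tsv_path, sep="\t")
        with open(meta_path) as fh:
            meta = json.load(fh)
        return cls(table, meta.pop("stat_names"), meta.pop("param_names"), meta)


def build_reference_table(
    models: list[str],
    ps: PriorSet,
    cfg: SimConfig,
    n_per_model: int,
    seed: int,
    progress: bool = False,
) -> SimTable:
    """Simulate ``n_per_model`` draws per model and summarize each.

    Deterministic given ``seed``; a draw whose simulation fails is
    dropped, logged and replaced by a fresh draw.
    """
    rows = []
    root = np.random.SeedSequence(seed)
    model_seeds = root.generate_state(2 * len(models)).astype(np.int64)
    for mi, label in enumerate(models):
        draw_seed = int(model_seeds[2 * mi] % (2**31))
        sim_seed0 = int(model_seeds[2 * mi + 1] % (2**31))
        draws = sample_priors(ps, n_per_model, draw_seed)
        got = 0
        attempt = 0
        while got < n_per_model:
            rec = draws.iloc[attempt]
            try:
                p = DemographicParams(**rec.to_dict())
                sim_cfg = SimConfig(
                    n_CR=cfg.n_CR, n_CT=cfg.n_CT, n_loci=cfg.n_loci,
                    locus_len=cfg.locus_len,
                    seed=(sim_seed0 + attempt) % (2**31),
                    generation_years=cfg.generation_years,
                )
                gm = coalsim.simulate_dataset(p, label, sim_cfg)
                sv = sumstats.summarize(gm, extra=False)
            except Exception as exc:  # replacement draw
                warnings.warn(f"simulation failed for model {label}: {exc}", stacklevel=2)
                attempt += 1
                draws = pd.concat(
                    [draws, sample_priors(ps, 1, (draw_seed + attempt) % (2**31))],
                    ignore_index=True,
                )
                continue
            rows.append({"model": label, **rec.to_dict(),
                         **dict(zip(ABC_STAT_NAMES, sv.abc_values()))})
            got += 1
            attempt += 1
            if progress and got % 500 == 0:
                print(f"  {label}: {got}/{n_per_model}", flush=True)
    table = pd.DataFrame(rows)
    return SimTable(
        table=table,
        stat_names=list(ABC_STAT_NAMES),
        param_names=list(coalsim.PARAM_NAMES),
        meta={"seed": seed, "n_per_model": n_per_model, "models": list(models),
              "sim_config": vars(cfg)},
    )


def prune_correlated(table: SimTable, r_max: float = 0.95) -> list[str]:
    """Greedy scan in declared statistic order; drop any statistic whose
    |Pearson r| with an already-retained one reaches ``r_max``.
    Constant columns are dropped first (their correlation is undefined)."""
    X = table.stats()
    names = table.stat_names
    keep: list[str] = []
    keep_idx: list[int] = []
    for j, name in enumerate(names):
        col = X[:, j]
        if np.std(col) == 0:
            continue
        ok = True
        for i in keep_idx:
            r = np.corrcoef(col, X[:, i])[0, 1]
            if abs(r) >= r_max:
                ok = False
                break
        if ok:
            keep.append(name)
            keep_idx.append(j)
    return keep


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------

def _mad(x: np.ndarray) -> np.ndarray:
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    return np.where(mad > 0, mad, 1.0)


@dataclass
class Rejection:
    """Result of the rejection step: retained row indices (into the full
    table), distances and Epanechnikov weights."""

    index: np.ndarray
    distance: np.ndarray
    weight: np.ndarray
    stat_names: list[str]
    scale: np.ndarray
    obs_std: np.ndarray | None = None


def rejection(obs: SumStatVector | np.ndarray, table: SimTable, k: int = 1000,
              stat_names: list[str] | None = None) -> Rejection:
    """Keep the ``k`` rows closest to ``obs`` across all models jointly.

    Statistics are standardized by the median absolute deviation over
    the whole table; distance is Euclidean; weights are Epanechnikov
    ``w_i = 1 - (d_i / d_(k))^2`` (the k-th distance gets weight 0, an
    exact match weight 1).
    """
    names = stat_names or table.stat_names
    X = table.stats(names)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds table size {X.shape[0]}")
    v = obs.abc_values(names) if isinstance(obs, SumStatVector) else np.asarray(obs, float)
    scale = _mad(X)
    d = np.sqrt((((X - v) / scale) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    dk = d[order[-1]]
    if dk == 0:
        w = np.ones(k)
    else:
        w = 1.0 - (d[order] / dk) ** 2
    return Rejection(index=order, distance=d[order], weight=w,
                     stat_names=list(names), scale=scale, obs_std=v / scale)


@dataclass
class ModelSelectionResult:
    posterior: dict[str, float]
    bayes_factor: dict[str, float]
    retained_index: np.ndarray

    @property
    def best(self) -> str:
        return max(self.posterior, key=self.posterior.get)


def model_posterior(table: SimTable, rej: Rejection) -> ModelSelectionResult:
    """Model posterior probability = share of retained Epanechnikov
    weight; Bayes factor of M = posterior odds of M over the composite
    of the other models divided by the equal prior odds,
    ``BF_M = (G-1) P(M) / (1 - P(M))``."""
    models = list(dict.fromkeys(table.table["model"]))
    labels = table.table["model"].to_numpy()[rej.index]
    total = rej.weight.sum()
    post = {}
    for m in models:
        post[m] = float(rej.weight[labels == m].sum() / total) if total > 0 else 0.0
    G = len(models)
    bf = {}
    for m in models:
        pm = post[m]
        if pm == 0.0:
            warnings.warn(f"model {m} has zero retained weight", stacklevel=2)
            bf[m] = 0.0
        elif pm == 1.0:
            bf[m] = float("inf")
        else:
            bf[m] = float((G - 1) * pm / (1.0 - pm))
    s = sum(post.values())
    if s > 0:
        post = {m: v / s for m, v in post.items()}
    return ModelSelectionResult(posterior=post, bayes_factor=bf,
                                retained_index=rej.index)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class GofResult:
    p_value: float
    observed: float
    null: np.ndarray


def goodness_of_fit(
    obs: SumStatVector | np.ndarray,
    table: SimTable,
    k: int = 50,
    n_null: int = 1000,
    seed: int = 0,
    stat_names: list[str] | None = None,
) -> GofResult:
    """Mean-nearest-distance GOF test against one model's simulations.

    The observed statistic is the mean distance of ``obs`` to its ``k``
    nearest table rows; the null distribution repeats this for ``n_null``
    rows treated in turn as pseudo-observations (leave-one-out);
    ``p`` = fraction of null distances >= observed.
    """
    names = stat_names or table.stat_names
    X = table.stats(names)
    n = X.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the table")
    if n_null > n:
        warnings.warn(f"n_null={n_null} capped at table size {n}", stacklevel=2)
        n_null = n
    v = obs.abc_values(names) if isinstance(obs, SumStatVector) else np.asarray(obs, float)
    scale = _mad(X)
    Z = X / scale
    d = np.sqrt(((Z - v / scale) ** 2).sum(axis=1))
    observed = float(np.sort(d)[:k].mean())
    rng = np.random.default_rng(seed)
    pick = rng.choice(n, size=n_null, replace=False)
    null = np.empty(n_null)
    for i, row in enumerate(pick):
        dd = np.sqrt(((Z - Z[row]) ** 2).sum(axis=1))
        dd[row] = np.inf  # leave-one-out
        null[i] = np.sort(dd)[:k].mean()
    p = float((null >= observed).mean())
    return GofResult(p_value=p, observed=observed, null=null)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def weighted_interval(sample: np.ndarray, weights: np.ndarray, level: float = 0.95):
    """(lower, median, upper) quantiles of the weighted empirical
    distribution by cumulative-weight interpolation.

    Sorted values sit at cumulative positions ``(c_i - w_i/2) / W``;
    quantiles interpolate linearly between them (equal weights on
    {10,20,30,40} give a median of 25).
    """
    sample = np.asarray(sample, float)
    weights = np.asarray(weights, float)
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("weights must be non-negative and not all zero")
    keep = weights > 0
    sample, weights = sample[keep], weights[keep]
    order = np.argsort(sample, kind="stable")
    x = sample[order]
    w = weights[order]
    if x.size == 1:
        return float(x[0]), float(x[0]), float(x[0])
    W = w.sum()
    cum = np.cumsum(w)
    pos = (cum - 0.5 * w) / W
    alpha = (1.0 - level) / 2.0
    qs = np.interp([alpha, 0.5, 1.0 - alpha], pos, x)
    return float(qs[0]), float(qs[1]), float(qs[2])


def weighted_mean(sample: np.ndarray, weights: np.ndarray) -> float:
    return float(np.average(sample, weights=weights))


@dataclass
class PosteriorSummary:
    """Per-parameter weighted mean, median and 95% interval, plus the
    adjusted posterior sample itself."""

    summary: pd.DataFrame       # index: parameter; columns: mean, median, lo, hi
    sample: pd.DataFrame        # adjusted draws (natural scale)
    weights: np.ndarray
    method: str

    def to_dict(self) -> dict:
        return {
            p: {
                "weighted_mean": float(self.summary.loc[p, "mean"]),
                "weighted_median": float(self.summary.loc[p, "median"]),
                "weighted_95_interval": [
                    float(self.summary.loc[p, "lo"]),
                    float(self.summary.loc[p, "hi"]),
                ],
            }
            for p in self.summary.index
        }


def _summaries(sample: np.ndarray, weights: np.ndarray, names: list[str], method: str) -> PosteriorSummary:
    rows = []
    for j, _ in enumerate(names):
        lo, med, hi = weighted_interval(sample[:, j], weights)
        rows.append({"mean": weighted_mean(sample[:, j], weights),
                     "median": med, "lo": lo, "hi": hi})
    return PosteriorSummary(
        summary=pd.DataFrame(rows, index=names),
        sample=pd.DataFrame(sample, columns=names),
        weights=weights,
        method=method,
    )


def adjust_parameters(
    table: SimTable,
    rej: Rejection,
    method: str = "loclinear",
    log_params: bool = True,
    param_names: list[str] | None = None,
    seed: int = 0,
) -> PosteriorSummary:
    """Posterior summaries from the retained draws.

    ``method='rejection'`` summarizes the raw retained draws;
    ``'loclinear'`` fits a weighted linear regression of (log)
    parameters on the retained standardized statistics and corrects each
    draw by the regression shift at the observation (Beaumont-style);
    ``'neuralnet'`` replaces the linear fit by single-hidden-layer
    perceptrons (15 hidden units, 50 restarts averaged).  Parameters are
    log-transformed by default and summaries are back-transformed.
    """
    if len(rej.index) < 50 and method != "rejection":
        raise ValueError("need >= 50 retained rows for regression adjustment")
    pnames = param_names or table.param_names
    theta = table.table.iloc[rej.index][pnames].to_numpy(float)
    if log_params:
        if np.any(theta <= 0):
            raise ValueError("log transform requires positive parameters")
        theta = np.log(theta)
    w = rej.weight.copy()
    if w.sum() == 0:
        w = np.ones_like(w)

    if method == "rejection":
        adj = theta
    else:
        if rej.obs_std is None:
            raise ValueError("rejection output lacks the observed vector")
        X = table.stats(rej.stat_names)[rej.index] / rej.scale
        Xc = X - rej.obs_std
        if method == "loclinear":
            adj = _loclinear_adjust(theta, Xc, w)
        elif method == "neuralnet":
            adj = _neuralnet_adjust(theta, Xc, w, seed=seed)
        else:
            raise ValueError(f"unknown method {method!r}")

    if log_params:
        adj = np.exp(adj)
    return _summaries(adj, w, pnames, method)


def _loclinear_adjust(theta: np.ndarray, Xc: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Beaumont local-linear correction: theta* = theta - B (x - x_obs)."""
    A = np.hstack([np.ones((Xc.shape[0], 1)), Xc])
    Wsq = np.sqrt(w)[:, None]
    try:
        coef, *_ = np.linalg.lstsq(A * Wsq, theta * Wsq, rcond=None)
    except np.linalg.LinAlgError:
        warnings.warn("singular design in loclinear; falling back to rejection",
                      stacklevel=2)
        return theta
    fitted = A @ coef
    intercept_at_obs = coef[0]  # Xc is centred at the observation
    return theta - fitted + intercept_at_obs


def _neuralnet_adjust(theta: np.ndarray, Xc: np.ndarray, w: np.ndarray, seed: int,
                      hidden: int = 15, restarts: int = 50) -> np.ndarray:
    """Nonlinear correction via averaged single-hidden-layer networks."""
    from sklearn.neural_network import MLPRegressor

    rng = np.random.default_rng(seed)
    pred = np.zeros_like(theta)
    pred_obs = np.zeros(theta.shape[1])
    n_ok = 0
    for _ in range(restarts):
        net = MLPRegressor(
            hidden_layer_sizes=(hidden,),
            max_iter=500,
            random_state=int(rng.integers(2**31)),
            tol=1e-4,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net.fit(Xc, theta)
        pred += net.predict(Xc).reshape(theta.shape)
        pred_obs += net.predict(np.zeros((1, Xc.shape[1]))).reshape(-1)
        n_ok += 1
    pred /= n_ok
    pred_obs /= n_ok
    return theta - pred + pred_obs
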