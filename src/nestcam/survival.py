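"""Clutch-survival analysis: fate coding, Cox models, collinearity pruning,
candidate-suite enumeration, AICc ranking and model averaging.

Predation is the terminal event; every other fate (hatched, abandoned,
flooded, destroyed by humans, unhatched) is censored at the last check at
which the clutch still contained eggs and was attended.  Models are Cox
proportional-hazards fits (partial likelihood, Efron tie handling, via
lifelines) ranked by the small-sample Akaike criterion

    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)

with n the number of nests.  Relative support is summarized by AICc
differences (delta_i) and Akaike weights; parameter estimates of the
models with delta_i <= 2 are averaged (conditional averaging with
renormalized weights, unconditional variance) and reported as hazard
ratios with 95% confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

logger = logging.getLogger(__name__)

SPECIES_TERM = "Species"
#: Species is coded as an indicator for tern (plover is the reference level).
SPECIES_REFERENCE = "plover"

#: Fate vocabulary of the nest-check logs.
TERMINAL_STATES = {"empty", "hatched", "abandoned", "flooded", "human", "unhatched"}
_FATE_LABELS = {
    "empty": "predation",
    "hatched": "hatched",
    "abandoned": "abandonment",
    "flooded": "flooding",
    "human": "human",
    "unhatched": "unhatched",
}


class FateCodingError(ValueError):
    """Contradictory visit sequence (e.g. eggs reappear after loss)."""


def code_fates(visits: pd.DataFrame) -> pd.DataFrame:
    """Code raw nest-check logs into survival records.

    ``visits`` is long-format with columns nest_id, species, day, state;
    states are ``intact`` (eggs present, parents attending) or one of the
    terminal states.  Predation (state ``empty`` with no other cause)
    is an event at the day of detection; all other outcomes are censored
    — hatching at the hatch check, the remaining fates at the last
    attended observation.
    """
    required = {"nest_id", "species", "day", "state"}
    if not required.issubset(visits.columns):
        raise ValueError(f"visit table needs columns {sorted(required)}")
    rows = []
    for nest_id, grp in visits.groupby("nest_id", sort=False):
        grp = grp.sort_values("day")
        states = grp["state"].tolist()
        days = grp["day"].tolist()
        if len(grp) < 1:
            raise ValueError(f"nest {nest_id} has no visits")
        term_idx = [i for i, s in enumerate(states) if s in TERMINAL_STATES]
        if term_idx:
            first_term = term_idx[0]
            if any(s == "intact" for s in states[first_term + 1 :]):
                raise FateCodingError(f"nest {nest_id}: eggs reappear after loss")
            state = states[first_term]
            if state == "empty":
                exit_day, event = days[first_term], True
            elif state == "hatched":
                exit_day, event = days[first_term], False
            else:
                attended = [d for d, s in zip(days, states) if s == "intact"]
                if not attended:
                    raise FateCodingError(f"nest {nest_id}: never observed attended")
                exit_day, event = attended[-1], False
            fate = _FATE_LABELS[state]
        else:
            exit_day, event, fate = days[-1], False, "hatched"
            logger.warning("nest %s has no terminal observation; censored at last visit", nest_id)
        rows.append(
            {
                "nest_id": nest_id,
                "species": grp["species"].iloc[0],
                "entry_day": 0,
                "exit_day": exit_day,
                "event": event,
                "fate_label": fate,
            }
        )
    out = pd.DataFrame(rows)
    if (out["exit_day"] <= out["entry_day"]).any():
        bad = out.loc[out["exit_day"] <= out["entry_day"], "nest_id"].tolist()
        raise FateCodingError(f"non-positive observation span for nests {bad}")
    return out


# ---------------------------------------------------------------------------
# collinearity pruning


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1/(1-R^2) from regressing the
    column on all others (with intercept).  Perfect collinearity yields inf."""
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    X = design.to_numpy(dtype=float)
    n = X.shape[0]
    vifs = {}
    for j, col in enumerate(design.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


def _univariate_cox_z(records: pd.DataFrame, column: str) -> float:
    """|Wald z| of a single-covariate Cox fit (drop-ordering statistic)."""
    try:
        res = cox_fit(records, ModelSpec(terms=(column,)))
    except Exception as exc:  # constant or otherwise unusable column
        logger.warning("univariate Cox fit failed for %s (%s); treating effect as 0", column, exc)
        return 0.0
    se = res.ses[column]
    return abs(res.coefs[column] / se) if se > 0 else np.inf


def vif_prune(
    records: pd.DataFrame,
    columns: list[str],
    threshold: float = 5.0,
) -> tuple[list[str], list[dict]]:
    """Iteratively drop collinear covariates.

    While any VIF exceeds ``threshold``, drop — among the offending
    columns — the one with the smallest effect on survival (smallest
    absolute Wald z of its univariate Cox fit), then recompute.  Returns
    (retained columns, drop log).
    """
    retained = list(columns)
    log: list[dict] = []
    while len(retained) >= 2:
        vifs = compute_vif(records[retained])
        offending = vifs[vifs > threshold]
        if offending.empty:
            break
        zs = {c: _univariate_cox_z(records, c) for c in offending.index}
        drop = min(zs, key=zs.get)
        log.append({"dropped": drop, "vif": float(vifs[drop]), "abs_z": zs[drop]})
        logger.info("VIF pruning: dropped %s (VIF=%.2f, |z|=%.3f)", drop, vifs[drop], zs[drop])
        retained.remove(drop)
    return retained, log


# ---------------------------------------------------------------------------
# model suite


@dataclass(frozen=True)
class ModelSpec:
    """One candidate Cox model: an ordered tuple of terms.

    Terms are ``Species``, metric names, or ``Species:metric``
    interactions (an interaction implies both main effects).
    """

    terms: tuple

    def __post_init__(self) -> None:
        for t in self.terms:
            if ":" in t:
                _, metric = t.split(":", 1)
                if SPECIES_TERM not in self.terms or metric not in self.terms:
                    raise ValueError(f"interaction {t} requires both main effects")

    @property
    def includes_species(self) -> bool:
        return SPECIES_TERM in self.terms

    @property
    def name(self) -> str:
        inter = [t for t in self.terms if ":" in t]
        if len(inter) == 1 and len(self.terms) == 3:
            return f"{SPECIES_TERM} * {inter[0].split(':', 1)[1]}"
        return " + ".join(t for t in self.terms if ":" not in t) + (
            " + " + " + ".join(inter) if inter else ""
        )

    @property
    def key(self) -> frozenset:
        return frozenset(self.terms)


def enumerate_models(metrics: list[str], significant_set: list[str] | None = None) -> list[ModelSpec]:
    """Build the candidate suite.

    {Species-only} plus, per metric, {metric; Species+metric;
    Species*metric}; plus {Species + all significantly species-different
    metrics}; plus the two most complex models {all metrics} and
    {Species + all metrics}.  Duplicates are collapsed.  With the five
    pruned predictors and a two-metric significant set this yields the
    19-model suite.
    """
    if len(set(metrics)) != len(metrics):
        raise ValueError("metrics must be distinct")
    significant_set = list(significant_set or [])
    unknown = set(significant_set) - set(metrics)
    if unknown:
        raise ValueError(f"significant_set not among metrics: {sorted(unknown)}")
    specs: list[ModelSpec] = [ModelSpec(terms=(SPECIES_TERM,))]
    for m in metrics:
        specs.append(ModelSpec(terms=(m,)))
        specs.append(ModelSpec(terms=(SPECIES_TERM, m)))
        specs.append(ModelSpec(terms=(SPECIES_TERM, m, f"{SPECIES_TERM}:{m}")))
    if significant_set:
        specs.append(ModelSpec(terms=(SPECIES_TERM, *significant_set)))
    if metrics:
        specs.append(ModelSpec(terms=tuple(metrics)))
        specs.append(ModelSpec(terms=(SPECIES_TERM, *metrics)))
    seen = set()
    unique = []
    for s in specs:
        if s.key not in seen:
            seen.add(s.key)
            unique.append(s)
    return unique


# ---------------------------------------------------------------------------
# fitting and ranking


@dataclass
class CoxResult:
    spec: ModelSpec
    coefs: pd.Series
    ses: pd.Series
    loglik: float
    k: int
    converged: bool = True


def _design_matrix(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = {}
    species_ind = (records["species"] != SPECIES_REFERENCE).astype(float)
    for t in spec.terms:
        if t == SPECIES_TERM:
            cols[t] = species_ind
        elif ":" in t:
            metric = t.split(":", 1)[1]
            cols[t] = species_ind * records[metric].astype(float)
        else:
            cols[t] = records[t].astype(float)
    return pd.DataFrame(cols, index=records.index)


def cox_fit(records: pd.DataFrame, spec: ModelSpec) -> CoxResult:
    """Maximize the Cox partial likelihood (Efron ties) for one model.

    ``records`` needs species, exit_day, event and the metric columns the
    spec references; rows with missing covariates are dropped.  Raises on
    a dataset with no events or a rank-deficient design.
    """
    X = _design_matrix(records, spec)
    df = X.copy()
    df["exit_day"] = records["exit_day"].astype(float)
    df["event"] = records["event"].astype(bool)
    if "entry_day" in records.columns and (records["entry_day"] > 0).any():
        df["entry_day"] = records["entry_day"].astype(float)
        entry_col = "entry_day"
    else:
        entry_col = None
    df = df.dropna()
    if not df["event"].any():
        raise ValueError("no terminal events; Cox model undefined")
    design = df[list(X.columns)]
    if np.linalg.matrix_rank(design.to_numpy(dtype=float) - design.to_numpy(dtype=float).mean(0)) < design.shape[1]:
        raise ValueError("design matrix is rank deficient (constant or collinear covariates)")
    cph = CoxPHFitter()
    kwargs = {"duration_col": "exit_day", "event_col": "event"}
    if entry_col:
        kwargs["entry_col"] = entry_col
    cph.fit(df, **kwargs)
    return CoxResult(
        spec=spec,
        coefs=cph.params_.copy(),
        ses=cph.standard_errors_.copy(),
        loglik=float(cph.log_likelihood_),
        k=len(cph.params_),
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (needs n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(deltas) -> np.ndarray:
    """Akaike weights from AICc differences: exp(-d/2) renormalized."""
    d = np.asarray(deltas, dtype=float)
    w = np.exp(-d / 2.0)
    return w / w.sum()


def rank_and_weight(rows: list[tuple], n: int) -> pd.DataFrame:
    """Rank (name, loglik, k) rows by AICc with deltas and Akaike weights."""
    if not rows:
        raise ValueError("need at least one model")
    out = pd.DataFrame(rows, columns=["model", "loglik", "k"])
    out["aicc"] = [aicc(ll, k, n) for ll, k in zip(out["loglik"], out["k"])]
    out["delta"] = out["aicc"] - out["aicc"].min()
    out["weight"] = akaike_weights(out["delta"])
    return out.sort_values("aicc", kind="mergesort").reset_index(drop=True)


def fit_model_suite(records: pd.DataFrame, specs: list[ModelSpec], n: int | None = None):
    """Fit every candidate model and rank the suite.

    Returns (ranking DataFrame with model/k/loglik/aicc/delta/weight,
    dict name -> CoxResult).  Models that fail to fit are logged and
    excluded from the ranking.
    """
    n = len(records) if n is None else n
    fits: dict[str, CoxResult] = {}
    rows = []
    for spec in specs:
        try:
            res = cox_fit(records, spec)
        except Exception as exc:
            logger.warning("model %s failed to fit: %s", spec.name, exc)
            continue
        fits[spec.name] = res
        rows.append((spec.name, res.loglik, res.k))
    ranking = rank_and_weight(rows, n)
    return ranking, fits


def model_average(
    ranking: pd.DataFrame,
    fits: dict,
    delta_max: float = 2.0,
    z: float = 1.96,
) -> pd.DataFrame:
    """Average coefficients over the well-supported models (delta <= delta_max).

    Conditional (subset) averaging: per term, weights are renormalized
    over the supported models containing that term; the unconditional
    variance  sum_i w_i (SE_i^2 + (b_i - b_bar)^2)  inflates the standard
    error by between-model spread.  Reported as HR = exp(b_bar) with
    exp(b_bar +/- z*SE) confidence limits.
    """
    top = ranking[ranking["delta"] <= delta_max]
    if top.empty:
        raise ValueError("no models within the supported set")
    terms: dict[str, list[tuple[float, float, float]]] = {}
    for _, row in top.iterrows():
        res = fits[row["model"]]
        for term in res.coefs.index:
            terms.setdefault(term, []).append((row["weight"], res.coefs[term], res.ses[term]))
    out = []
    for term, entries in terms.items():
        w = np.array([e[0] for e in entries])
        b = np.array([e[1] for e in entries])
        se = np.array([e[2] for e in entries])
        w = w / w.sum()
        b_bar = float(np.sum(w * b))
        var = float(np.sum(w * (se**2 + (b - b_bar) ** 2)))
        se_bar = np.sqrt(var)
        out.append(
            {
                "term": term,
                "coef": b_bar,
                "se": se_bar,
                "hr": float(np.exp(b_bar)),
                "hr_lower": float(np.exp(b_bar - z * se_bar)),
                "hr_upper": float(np.exp(b_bar + z * se_bar)),
                "n_models": len(entries),
            }
        )
    return pd.DataFrame(out)


def km_curve(records: pd.DataFrame, group_col: str = "species") -> pd.DataFrame:
    """Product-limit survival per group with censoring marks.

    Returns a long-format table (group, time, survival, at_risk) suitable
    for CSV export or step plotting.
    """
    if records.empty:
        raise ValueError("need at least one record")
    frames = []
    for g, grp in records.groupby(group_col):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["exit_day"], grp["event"], label=str(g))
        sf = kmf.survival_function_
        ev = kmf.event_table
        df = pd.DataFrame(
            {
                "group": str(g),
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": ev["at_risk"].reindex(sf.index).to_numpy(dtype=float),
                "censored": ev["censored"].reindex(sf.index).to_numpy(dtype=float),
            }
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def plot_km(curves: pd.DataFrame, path=None):
    """Step plot of km_curve output (audit figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for g, grp in curves.groupby("group"):
        ax.step(grp["time"], grp["survival"], where="post", label=g)
    ax.set_xlabel("days since clutch completion")
    ax.set_ylabel("clutch survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
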