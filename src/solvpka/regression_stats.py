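"""Robust linear scaling relations, error statistics, cross-validation, and
the Kamlet–Taft solvatochromic regression.

Raw pKa values computed with an implicit solvation model deviate from the
experimental scale by an approximately linear map. A linear free-energy
scaling relation (LFESR) ``pKa(exp) ≈ slope·pKa(calc) + intercept`` is
fitted by least absolute deviation (LAD): the L1 criterion bounds the
influence of gross outliers in the experimental data, which are never
removed. Relations may be universal, per solvent class (protic/aprotic),
per solvent, or per functional group.

The LAD solver is iteratively reweighted least squares with ε-regularized
weights, followed by an exact polish that exploits the fact that an L1
optimum of a p-parameter linear model interpolates p sample points.

Cross-validation follows a repeated k-fold scheme (k = 5 folds × 3 runs by
default): each run re-fits the relation on every (k−1)-fold training set,
and the dispersion (sd, variance) of the per-fold slopes and intercepts
measures the fit's stability. The run with the highest dispersion is the
one flagged for discussion — a worst-case reading. Runs are only considered
routinely applicable for n ≥ 14 points; smaller sets proceed with a
prominent warning.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ProtonEnergies, normalize_name

__all__ = [
    "ScalingRelation",
    "FitReport",
    "CVRun",
    "CVReport",
    "KamletTaftModel",
    "lad_fit",
    "apply_scaling",
    "invert_scaling",
    "error_stats",
    "repeated_kfold_cv",
    "fit_relation_registry",
    "relation_for",
    "registry_to_json",
    "registry_from_json",
    "kamlet_taft_table",
    "kamlet_taft_fit",
    "MIN_POINTS_RULE",
]

logger = logging.getLogger(__name__)

#: routine-applicability rule for cross-validation
MIN_POINTS_RULE = 14


@dataclass(frozen=True)
class ScalingRelation:
    """A linear map from computed to experimental pKa with a scope label.

    Scope vocabulary: ``universal``, ``protic``, ``aprotic``,
    ``group:<label>``, ``solvent:<name>``. A relation with unset slope
    (``None``) is a placeholder and unusable until fitted or configured.
    """

    slope: float | None
    intercept: float | None
    scope: str = "universal"
    provenance: str = "fitted"  # fitted | configured | unfit
    n: int | None = None

    @property
    def usable(self) -> bool:
        return (
            self.slope is not None
            and self.intercept is not None
            and math.isfinite(self.slope)
            and math.isfinite(self.intercept)
            and self.slope != 0.0
        )


@dataclass(frozen=True)
class FitReport:
    """Residual summary of a fitted relation (MAE and sample σ in pKa units)."""

    slope: float | None
    intercept: float | None
    mae: float
    sigma: float
    n: int


@dataclass(frozen=True)
class CVRun:
    slopes: tuple[float, ...]
    intercepts: tuple[float, ...]
    sd_slope: float
    var_slope: float
    sd_intercept: float
    var_intercept: float
    heldout_mae: tuple[float, ...] = ()


@dataclass(frozen=True)
class CVReport:
    """Per-run fold dispersion of a repeated k-fold cross-validation.

    ``selected_run`` indexes the run with the highest combined standard
    deviation (sd_slope + sd_intercept); ties resolve to the lowest index.
    """

    k: int
    runs: int
    n: int
    seed: int
    run_results: tuple[CVRun, ...] = field(default_factory=tuple)
    selected_run: int = 0

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "runs": self.runs,
            "n": self.n,
            "seed": self.seed,
            "selected_run": self.selected_run,
            "run_results": [
                {
                    "slopes": list(r.slopes),
                    "intercepts": list(r.intercepts),
                    "sd_slope": r.sd_slope,
                    "var_slope": r.var_slope,
                    "sd_intercept": r.sd_intercept,
                    "var_intercept": r.var_intercept,
                    "heldout_mae": list(r.heldout_mae),
                }
                for r in self.run_results
            ],
        }


# --------------------------------------------------------------------------
# LAD solver
# --------------------------------------------------------------------------

def _l1_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    return float(np.abs(y - X @ beta).sum())


def _lad_irls(
    X: np.ndarray,
    y: np.ndarray,
    eps: float = 1e-8,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> np.ndarray:
    """Iteratively reweighted least squares for min Σ|y − Xβ|."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(max_iter):
        r = y - X @ beta
        sw = np.sqrt(1.0 / np.maximum(np.abs(r), eps))
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def _lad_polish(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, max_candidates: int = 60
) -> np.ndarray:
    """Exact refinement: try interpolating lines through p-point subsets.

    An L1 optimum of a p-parameter linear fit passes through at least p
    sample points, so for moderate n enumerating subsets of the
    lowest-residual points recovers the exact minimizer (and returns exact
    data-derived coefficients for mostly-collinear inputs). Deterministic:
    subsets are scanned in a fixed order and only strict improvements are
    taken.
    """
    n, p = X.shape
    resid0 = np.abs(y - X @ beta)
    order = np.argsort(resid0, kind="stable")
    limit = min(n, max_candidates if p == 2 else 24)
    idx = np.sort(order[:limit])
    irls_obj = _l1_objective(X, y, beta)
    scale = 1.0 + abs(irls_obj)
    best_cand: np.ndarray | None = None
    best_cand_obj = math.inf
    for subset in itertools.combinations(idx, p):
        rows = list(subset)
        try:
            cand = np.linalg.solve(X[rows], y[rows])
        except np.linalg.LinAlgError:
            continue
        obj = _l1_objective(X, y, cand)
        # strict improvement within a deterministic scan order breaks ties
        if obj < best_cand_obj - 1e-15 * scale:
            best_cand, best_cand_obj = cand, obj
    # adopt the interpolating optimum whenever it matches or beats IRLS: it
    # carries exact data-derived coefficients (exact on collinear inputs)
    if best_cand is not None and best_cand_obj <= irls_obj + 1e-9 * scale:
        return best_cand
    return np.asarray(beta, dtype=float)


def _lad_solve(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n, p = X.shape
    if n == p:
        return np.linalg.solve(X, y)
    beta = _lad_irls(X, y)
    return _lad_polish(X, y, beta)


def lad_fit(x, y) -> tuple[ScalingRelation, FitReport]:
    """Least-absolute-deviation straight-line fit y ≈ slope·x + intercept.

    Minimizes Σ|yᵢ − slope·xᵢ − intercept| (robust to gross outliers, which
    are down-weighted by the L1 criterion rather than removed). Requires
    n ≥ 2 and non-degenerate x. Residual MAE and sample standard deviation
    accompany the relation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 points for a line fit, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate fit: all x values are identical")
    X = np.column_stack([x, np.ones(n)])
    slope, intercept = _lad_solve(X, y)
    resid = y - (slope * x + intercept)
    mae = float(np.mean(np.abs(resid)))
    sigma = float(np.std(resid, ddof=1)) if n > 1 else 0.0
    relation = ScalingRelation(
        slope=float(slope), intercept=float(intercept), provenance="fitted", n=n
    )
    report = FitReport(
        slope=float(slope), intercept=float(intercept), mae=mae, sigma=sigma, n=n
    )
    return relation, report


def apply_scaling(pka_raw, relation: ScalingRelation):
    """Map a raw computed pKa onto the experimental scale.

    Refuses placeholder (unset/unfit) relations rather than silently
    passing values through.
    """
    if not relation.usable:
        raise ValueError(
            f"scaling relation '{relation.scope}' is not usable "
            f"(provenance={relation.provenance}, slope={relation.slope}); "
            "fit or configure it first"
        )
    return relation.slope * pka_raw + relation.intercept


def invert_scaling(pka_scaled, relation: ScalingRelation):
    """Inverse map: recover the raw computed pKa from a scaled value."""
    if not relation.usable:
        raise ValueError(f"scaling relation '{relation.scope}' is not usable")
    return (pka_scaled - relation.intercept) / relation.slope


def error_stats(pred, exp) -> FitReport:
    """MAE and sample σ of the residuals pred − exp (pKa units)."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape:
        raise ValueError(
            f"length mismatch: {pred.shape} predictions vs {exp.shape} observations"
        )
    if pred.size == 0:
        raise ValueError("need at least one residual")
    resid = pred - exp
    sigma = float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0
    return FitReport(
        slope=None,
        intercept=None,
        mae=float(np.mean(np.abs(resid))),
        sigma=sigma,
        n=resid.size,
    )


# --------------------------------------------------------------------------
# repeated k-fold cross-validation
# --------------------------------------------------------------------------

def repeated_kfold_cv(
    x, y, k: int = 5, runs: int = 3, seed: int = 0
) -> CVReport:
    """Repeated k-fold cross-validation of the LAD scaling relation.

    Each run shuffles the data with its own seed (seed, seed+1, ...),
    splits it into k folds of near-equal size (differing by at most one
    point), fits the relation on every training set of k−1 folds and
    evaluates the held-out fold's MAE. Reported per run: the k slopes and
    intercepts, their sample sd and variance (var = sd² exactly), and the
    held-out errors. The run with the largest sd_slope + sd_intercept is
    flagged as ``selected_run`` for worst-case discussion.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < k:
        raise ValueError(f"cannot split n={n} points into k={k} folds")
    if n < MIN_POINTS_RULE:
        warnings.warn(
            f"data set has n={n} < {MIN_POINTS_RULE} points; the "
            f"cross-validation applicability rule (n >= {MIN_POINTS_RULE}) is "
            "not met and fold statistics may be unstable",
            UserWarning,
            stacklevel=2,
        )
    run_results = []
    for r in range(runs):
        rng = np.random.default_rng(seed + r)
        folds = np.array_split(rng.permutation(n), k)
        slopes, intercepts, maes = [], [], []
        for i in range(k):
            test_idx = folds[i]
            train_idx = np.concatenate([folds[j] for j in range(k) if j != i])
            relation, _ = lad_fit(x[train_idx], y[train_idx])
            slopes.append(relation.slope)
            intercepts.append(relation.intercept)
            heldout = error_stats(
                apply_scaling(x[test_idx], relation), y[test_idx]
            )
            maes.append(heldout.mae)
        sd_slope = float(np.std(slopes, ddof=1))
        sd_intercept = float(np.std(intercepts, ddof=1))
        run_results.append(
            CVRun(
                slopes=tuple(slopes),
                intercepts=tuple(intercepts),
                sd_slope=sd_slope,
                var_slope=sd_slope**2,
                sd_intercept=sd_intercept,
                var_intercept=sd_intercept**2,
                heldout_mae=tuple(maes),
            )
        )
    ranking = [rr.sd_slope + rr.sd_intercept for rr in run_results]
    selected = int(np.argmax(ranking))  # first maximum -> lowest index on ties
    return CVReport(
        k=k,
        runs=runs,
        n=n,
        seed=seed,
        run_results=tuple(run_results),
        selected_run=selected,
    )


# --------------------------------------------------------------------------
# relation registry
# --------------------------------------------------------------------------

_GROUPINGS = ("universal", "per-solvent", "per-class", "per-group")


def fit_relation_registry(
    table: pd.DataFrame,
    grouping: str = "universal",
    min_n: int = 2,
) -> dict[str, ScalingRelation]:
    """Fit one LAD relation per group of a computed-vs-experimental join.

    ``table`` needs columns ``pka_raw`` and ``pka_exp``; grouping columns
    (``solvent``, ``solvent_class``, ``group_label``) are required by the
    respective grouping mode. Groups with fewer than ``min_n`` points are
    reported as unfit placeholders rather than fitted.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"unknown grouping '{grouping}'; expected one of {_GROUPINGS}")
    if table is None or len(table) == 0:
        raise ValueError("empty join: no computed/experimental pairs to fit")
    for column in ("pka_raw", "pka_exp"):
        if column not in table.columns:
            raise ValueError(f"join table lacks required column '{column}'")

    def scope_of(key) -> str:
        if grouping == "universal":
            return "universal"
        if grouping == "per-solvent":
            return f"solvent:{key}"
        if grouping == "per-class":
            return str(key)
        return f"group:{key}"

    if grouping == "universal":
        groups = [("universal", table)]
    else:
        column = {
            "per-solvent": "solvent",
            "per-class": "solvent_class",
            "per-group": "group_label",
        }[grouping]
        if column not in table.columns:
            raise ValueError(
                f"grouping '{grouping}' needs column '{column}' in the join table"
            )
        groups = [(key, sub) for key, sub in table.groupby(column, sort=True)]

    registry: dict[str, ScalingRelation] = {}
    for key, sub in groups:
        scope = scope_of(key) if grouping != "universal" else "universal"
        if len(sub) < min_n or np.ptp(sub["pka_raw"].to_numpy(float)) == 0.0:
            logger.warning(
                "group '%s' has n=%d (< %d usable points); reported unfit",
                scope,
                len(sub),
                min_n,
            )
            registry[scope] = ScalingRelation(
                slope=None, intercept=None, scope=scope, provenance="unfit", n=len(sub)
            )
            continue
        relation, _ = lad_fit(
            sub["pka_raw"].to_numpy(float), sub["pka_exp"].to_numpy(float)
        )
        registry[scope] = ScalingRelation(
            slope=relation.slope,
            intercept=relation.intercept,
            scope=scope,
            provenance="fitted",
            n=len(sub),
        )
    return registry


def relation_for(
    registry: dict[str, ScalingRelation],
    solvent: str | None = None,
    solvent_class: str | None = None,
    group_label: str | None = None,
) -> ScalingRelation | None:
    """Most specific usable relation: solvent > group > class > universal."""
    candidates = []
    if solvent is not None:
        candidates.append(f"solvent:{solvent}")
    if group_label is not None:
        candidates.append(f"group:{group_label}")
    if solvent_class is not None:
        candidates.append(solvent_class)
    candidates.append("universal")
    lowered = {normalize_name(k): v for k, v in registry.items()}
    for name in candidates:
        relation = lowered.get(normalize_name(name))
        if relation is not None and relation.usable:
            return relation
    return None


def registry_to_json(registry: dict[str, ScalingRelation]) -> str:
    payload = {
        scope: {
            "slope": rel.slope,
            "intercept": rel.intercept,
            "provenance": rel.provenance,
            "n": rel.n,
        }
        for scope, rel in registry.items()
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def registry_from_json(text: str) -> dict[str, ScalingRelation]:
    payload = json.loads(text)
    return {
        scope: ScalingRelation(
            slope=entry.get("slope"),
            intercept=entry.get("intercept"),
            scope=scope,
            provenance=entry.get("provenance", "configured"),
            n=entry.get("n"),
        )
        for scope, entry in payload.items()
    }


# --------------------------------------------------------------------------
# Kamlet–Taft solvatochromic regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KamletTaftModel:
    """Multilinear solvent-property model for the proton solvation energy.

    ΔG_solv(H+) ≈ c0 + c_pi·π* + c_alpha·α + c_beta·β, with π* the solvent
    polarizability and α/β the hydrogen-bond donation/acceptance abilities.
    Coefficients in eV (per unit solvatochromic parameter); the solvent
    molar volume term is neglected.
    """

    c0: float
    c_pi: float
    c_alpha: float
    c_beta: float

    def predict(self, pi_star: float, alpha: float, beta: float) -> float:
        return (
            self.c0
            + self.c_pi * np.asarray(pi_star)
            + self.c_alpha * np.asarray(alpha)
            + self.c_beta * np.asarray(beta)
        )


def kamlet_taft_table(
    solvents, protons
) -> pd.DataFrame:
    """Join solvent entries with proton energetics into a fit-ready frame.

    ``solvents`` is an iterable of :class:`SolventEntry`; ``protons`` maps
    solvent names to :class:`ProtonEnergies` (or bare ΔG_solv floats).
    Solvents lacking complete (π*, α, β) or a proton energy are dropped
    with a logged notice.
    """
    if hasattr(protons, "items"):
        proton_map = {normalize_name(k): v for k, v in protons.items()}
    else:
        proton_map = {normalize_name(p.solvent): p for p in protons}
    rows = []
    for entry in solvents:
        proton = proton_map.get(normalize_name(entry.name))
        if proton is None or not entry.has_kamlet_taft():
            logger.info(
                "solvent '%s' skipped in Kamlet-Taft table (incomplete data)",
                entry.name,
            )
            continue
        dg = proton.dg_solv if isinstance(proton, ProtonEnergies) else float(proton)
        rows.append(
            {
                "solvent": entry.name,
                "pi_star": entry.pi_star,
                "alpha": entry.alpha,
                "beta": entry.beta,
                "dg_solv": dg,
            }
        )
    return pd.DataFrame(rows)


def kamlet_taft_fit(table: pd.DataFrame) -> tuple[KamletTaftModel, FitReport]:
    """LAD multilinear fit of ΔG_solv(H+) on (π*, α, β).

    Requires at least 4 solvents with complete parameters; a design in
    which any solvatochromic parameter does not vary (or that is otherwise
    rank deficient) is rejected, naming the deficient parameter.
    """
    for column in ("pi_star", "alpha", "beta", "dg_solv"):
        if column not in table.columns:
            raise ValueError(f"Kamlet-Taft table lacks column '{column}'")
    clean = table.dropna(subset=["pi_star", "alpha", "beta", "dg_solv"])
    n = len(clean)
    if n < 4:
        raise ValueError(
            f"need at least 4 solvents with complete (pi*, alpha, beta), got {n}"
        )
    X = np.column_stack(
        [
            np.ones(n),
            clean["pi_star"].to_numpy(float),
            clean["alpha"].to_numpy(float),
            clean["beta"].to_numpy(float),
        ]
    )
    y = clean["dg_solv"].to_numpy(float)
    for j, name in ((1, "pi_star"), (2, "alpha"), (3, "beta")):
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(
                f"rank-deficient design: parameter '{name}' is constant across "
                "the provided solvents"
            )
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError(
            "rank-deficient design: the (pi*, alpha, beta) columns are linearly "
            "dependent"
        )
    beta = _lad_solve(X, y)
    resid = y - X @ beta
    model = KamletTaftModel(
        c0=float(beta[0]), c_pi=float(beta[1]), c_alpha=float(beta[2]),
        c_beta=float(beta[3]),
    )
    report = FitReport(
        slope=None,
        intercept=None,
        mae=float(np.mean(np.abs(resid))),
        sigma=float(np.std(resid, ddof=1)) if n > 1 else 0.0,
        n=n,
    )
    return model, report
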