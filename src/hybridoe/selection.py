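"""Three-step input-identification workflow.

1. PCA on the autoscaled candidate matrix (which variables carry the
   variance), plus squared correlation of every candidate to the two
   targets (VCC, titer) and a collinearity screen;
2. backward elimination: starting from the full candidate set, retrain a
   reduced model with each single input removed and drop the input whose
   removal gives the lowest validation error;
3. stop when the best removal worsens the validation error by more than
   the tolerance; the surviving set is the final model input set.

The elimination step trains rate-target regressions (network fitted to
smoothing-spline estimates of mu and v_px) rather than full
through-the-ODE hybrids; this keeps exhaustive leave-one-input-out
retraining tractable, and ranks candidate sets by the same network
family the hybrid uses.  The final set is meant to be refitted with
:func:`hybridoe.hybrid.fit_hybrid` at full cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from dataclasses import replace as replace_dc

import numpy as np
import pandas as pd

from hybridoe.ann_core import TrainConfig, apply_scaler, fit_scaler, init_network, lm_minimize, ann_forward
from hybridoe.datamodel import CultivationRun
from hybridoe.hybrid import (
    MU_REF,
    V_REF,
    CvConfig,
    HybridModel,
    _input_matrix,
    nrmse,
    predict_at_samples,
)
from hybridoe.mechanistic import estimate_specific_rates

#: The initial candidate set: the two CPPs, the amino acids flagged by
#: PCA and correlation screening, and the aspartate/glutamate ratio
#: (prior knowledge).  Proline is screened out by collinearity to
#: hydroxyproline before elimination starts.
CANDIDATE_INPUT_NAMES: tuple[str, ...] = (
    "temperature",
    "feed_glucose",
    "glutamine",
    "asparagine",
    "aspartate",
    "serine",
    "glycine",
    "alanine",
    "tyrosine",
    "hydroxyproline",
    "asp_glu_ratio",
)


@dataclass
class SelectionReport:
    """Everything the workflow produced, ending at the final input set."""

    candidates: list[str]
    explained_variance: np.ndarray  # percent, descending, sums to 100
    loadings: np.ndarray  # orthonormal columns
    r2_map: pd.DataFrame  # candidates x targets
    collinear_excluded: list[str]
    elimination_path: list[dict] = field(default_factory=list)  # removed, val_error
    final_inputs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "explained_variance": list(map(float, self.explained_variance)),
            "loadings": self.loadings.tolist(),
            "r2_map": self.r2_map.to_dict(),
            "collinear_excluded": self.collinear_excluded,
            "elimination_path": self.elimination_path,
            "final_inputs": self.final_inputs,
        }


def pca_explained_variance(X: np.ndarray, names=None) -> tuple[np.ndarray, np.ndarray]:
    """PCA on the autoscaled candidate matrix.

    Columns are z-scored first (so the decomposition is of the
    correlation structure); returns explained variance per component in
    percent (descending, summing to 100) and the orthonormal loading
    matrix (columns = components).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if np.any(~np.isfinite(X)):
        raise ValueError("candidate matrix contains missing values")
    stats = fit_scaler(X, names=names)
    Z = apply_scaler(stats, X)
    C = (Z.T @ Z) / Z.shape[0]
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return 100.0 * evals / evals.sum(), evecs


def correlation_r2(
    candidates: np.ndarray,
    targets: dict[str, np.ndarray],
    candidate_names=None,
) -> pd.DataFrame:
    """Squared Pearson correlation of every candidate to every target."""
    X = np.asarray(candidates, dtype=float)
    names = list(candidate_names) if candidate_names else [f"x{j}" for j in range(X.shape[1])]
    out = {}
    for tname, y in targets.items():
        y = np.asarray(y, dtype=float)
        if y.std() == 0:
            raise ValueError(f"target {tname!r} has zero variance")
        col = []
        for j in range(X.shape[1]):
            xj = X[:, j]
            if xj.std() == 0:
                raise ValueError(f"candidate {names[j]!r} has zero variance")
            col.append(float(np.corrcoef(xj, y)[0, 1]) ** 2)
        out[tname] = col
    return pd.DataFrame(out, index=names)


def flag_collinear(
    candidates: np.ndarray,
    candidate_names,
    targets: dict[str, np.ndarray],
    threshold: float = 0.95,
) -> list[str]:
    """Exclude the weaker member of each highly correlated candidate pair.

    For every pair with |r| above ``threshold``, the member with the
    lower mean R^2 to the targets is excluded.
    """
    X = np.asarray(candidates, dtype=float)
    names = list(candidate_names)
    r2 = correlation_r2(X, targets, names).mean(axis=1)
    excluded: list[str] = []
    for i in range(X.shape[1]):
        for j in range(i + 1, X.shape[1]):
            if names[i] in excluded or names[j] in excluded:
                continue
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if abs(r) > threshold:
                weaker = names[i] if r2[names[i]] < r2[names[j]] else names[j]
                excluded.append(weaker)
    return excluded


# ---------------------------------------------------------------------------
# rate-target regression used by the elimination loop


def _residuals_many(net, W: np.ndarray, Z: np.ndarray, y: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Scaled regression residuals for many weight vectors at once."""
    m = W.shape[0]
    nh, ni, no = net.n_hidden, net.n_inputs, net.n_outputs
    k = 0
    W_h = W[:, k : k + nh * ni].reshape(m, nh, ni); k += nh * ni
    b_h = W[:, k : k + nh]; k += nh
    W_o = W[:, k : k + no * nh].reshape(m, no, nh); k += no * nh
    b_o = W[:, k : k + no]
    h = np.tanh(np.einsum("mhi,ti->mth", W_h, Z) + b_h[:, None, :])
    out = np.einsum("moh,mth->mto", W_o, h) + b_o[:, None, :]
    return ((out - y[None, :, :]) / sd).reshape(m, -1)


class _RateRegression:
    """Network regression onto spline-derived specific-rate targets.

    Candidate input sets are ranked with a paired, warm-started design:
    per cross-validation partition one *parent* network is trained on the
    current candidate set; each single-input-removed child inherits the
    parent weights with the removed input's column excised and is briefly
    re-fitted.  All subsets therefore share the same partitions and the
    same optimization trajectory up to the removal, so score differences
    reflect the removed input's contribution rather than fitting luck.
    Scores are validation errors in *state* space: the fitted rates are
    propagated through the mass balances (closed form) and the mean of
    the per-run VCC/titer NRMSE over held-out runs is returned.
    """

    #: Samples below this VCC are excluded from the rate targets: the
    #: per-cell production rate divides by X, so early low-biomass points
    #: contribute mostly measurement noise.
    MIN_VCC: float = 1.0
    #: Parent fits per partition (best training loss kept).
    n_restarts: int = 2
    #: LM iterations for the brief child re-fit.
    child_iter: int = 30

    def __init__(self, runs: list[CultivationRun], smoothing: float | None = None):
        self.runs = runs
        mus, vs, self.masks, self.slices = [], [], [], []
        k = 0
        for r in runs:
            rs = estimate_specific_rates(r, smoothing=smoothing)
            keep = np.asarray(r.samples.vcc) >= self.MIN_VCC
            mus.append(rs.mu[keep] / MU_REF)
            vs.append(rs.vpx[keep] / V_REF)
            self.masks.append(keep)
            self.slices.append(slice(k, k + int(keep.sum())))
            k += int(keep.sum())
        self.mu_t = np.concatenate(mus)
        self.v_t = np.concatenate(vs)
        self._col_cache: dict[str, np.ndarray] = {}

    def _columns(self, names: list[str]) -> np.ndarray:
        from hybridoe.mechanistic import InputInterpolator

        cols = []
        for name in names:
            if name not in self._col_cache:
                self._col_cache[name] = np.concatenate(
                    [
                        InputInterpolator(r, [name])(r.samples.times)[m, 0]
                        for r, m in zip(self.runs, self.masks)
                    ]
                )
            cols.append(self._col_cache[name])
        return np.column_stack(cols)

    def _partitions(self, cv: CvConfig) -> list[tuple[list[int], list[int], int]]:
        ss = np.random.SeedSequence(cv.seed)
        groups = [
            [i for i, r in enumerate(self.runs) if r.scale == sc]
            for sc in sorted({r.scale for r in self.runs})
        ]
        parts = []
        for child in ss.spawn(cv.n_repeats):
            rng = np.random.default_rng(child)
            tr: list[int] = []
            va: list[int] = []
            for g in groups:
                k = int(np.ceil(cv.split_ratio * len(g)))
                perm = rng.permutation(g)
                tr.extend(perm[:k].tolist())
                va.extend(perm[k:].tolist())
            if not va:
                va.append(tr.pop())
            parts.append((sorted(tr), sorted(va), int(rng.integers(2**31))))
        return parts

    def _state_nrmse(self, model: HybridModel, runs: list[CultivationRun]) -> float:
        # mean of per-run errors so that low-biomass cultivations (e.g. the
        # 31 C corner) weigh as much as high-biomass ones
        errs = []
        for run in runs:
            X, P = predict_at_samples(model, run)
            errs.append(0.5 * (nrmse(run.samples.vcc, X) + nrmse(run.samples.titer, P)))
        return float(np.mean(errs))

    def _fit(self, names, tr_idx, w0, seed, train_cfg, max_iter=None):
        """LM fit on the training rows; returns (net, scaler, train_loss)."""
        X = self._columns(list(names))
        scaler = fit_scaler(X[tr_idx], names=list(names))
        Z = apply_scaler(scaler, X[tr_idx])
        y = np.column_stack([self.mu_t[tr_idx], self.v_t[tr_idx]])
        sd = y.std(axis=0)
        sd[sd == 0] = 1.0
        net = init_network(seed, n_inputs=len(names), input_names=list(names))
        if w0 is not None:
            net.set_weights(w0)
        cfg = train_cfg if max_iter is None else replace_dc(train_cfg, max_iter=max_iter)

        def objective(w, net=net):
            net.set_weights(w)
            return ((ann_forward(net, Z) - y) / sd).ravel()

        def jacobian(w, net=net, eps=1e-6):
            W = np.repeat(w[None, :], len(w) + 1, axis=0)
            W[np.arange(1, len(w) + 1), np.arange(len(w))] += eps
            R = _residuals_many(net, W, Z, y, sd)
            return (R[1:] - R[0]).T / eps

        w, hist = lm_minimize(objective, net.get_weights(), cfg, jac=jacobian)
        net.set_weights(w)
        return net, scaler, hist[-1]

    def _excise(self, net, names: list[str], drop: str) -> np.ndarray:
        """Parent weights with the dropped input's hidden column removed."""
        j = names.index(drop)
        W_h = np.delete(net.W_h, j, axis=1)
        return np.concatenate([W_h.ravel(), net.b_h, net.W_o.ravel(), net.b_o])

    def score_step(
        self,
        names: list[str],
        cv: CvConfig,
        train_cfg: TrainConfig,
    ) -> tuple[float, dict[str, float]]:
        """Score the current set and every single-input-removed subset.

        Returns ``(current_error, {removed_name: error})`` averaged over
        the cross-validation partitions.
        """
        parts = self._partitions(cv)
        cur_errs: list[float] = []
        rem_errs: dict[str, list[float]] = {n: [] for n in names}
        tr_rows = lambda idx: np.concatenate(
            [np.arange(self.slices[i].start, self.slices[i].stop) for i in idx]
        )
        for tr, va, seed in parts:
            tr_idx = tr_rows(tr)
            val_runs = [self.runs[i] for i in va]
            best = None
            for k in range(self.n_restarts):
                try:
                    fit = self._fit(names, tr_idx, None, seed + k, train_cfg)
                except ValueError:
                    continue
                if best is None or fit[2] < best[2]:
                    best = fit
            if best is None:
                continue
            parent, scaler, _ = best
            model = HybridModel(scaler=scaler, net=parent, input_names=tuple(names))
            cur_errs.append(self._state_nrmse(model, val_runs))
            for drop in names:
                sub = [n for n in names if n != drop]
                try:
                    w0 = self._excise(parent, list(names), drop)
                    child, cscaler, _ = self._fit(
                        sub, tr_idx, w0, seed, train_cfg, max_iter=self.child_iter
                    )
                except ValueError:
                    continue
                cmodel = HybridModel(scaler=cscaler, net=child, input_names=tuple(sub))
                rem_errs[drop].append(self._state_nrmse(cmodel, val_runs))
        if not cur_errs:
            raise RuntimeError("no cross-validation partition could be scored")
        return (
            float(np.mean(cur_errs)),
            {n: float(np.mean(v)) for n, v in rem_errs.items() if v},
        )

    def fit_score(self, input_names, cv: CvConfig, train_cfg: TrainConfig) -> float:
        """Validation error of one candidate set (no removals)."""
        parts = self._partitions(cv)
        errs = []
        for tr, va, seed in parts:
            tr_idx = np.concatenate(
                [np.arange(self.slices[i].start, self.slices[i].stop) for i in tr]
            )
            best = None
            for k in range(self.n_restarts):
                try:
                    fit = self._fit(list(input_names), tr_idx, None, seed + k, train_cfg)
                except ValueError:
                    continue
                if best is None or fit[2] < best[2]:
                    best = fit
            if best is None:
                continue
            net, scaler, _ = best
            model = HybridModel(scaler=scaler, net=net, input_names=tuple(input_names))
            errs.append(self._state_nrmse(model, [self.runs[i] for i in va]))
        if not errs:
            raise RuntimeError("no cross-validation partition could be scored")
        return float(np.mean(errs))


#: Inputs never offered for elimination: the two CPPs are designed
#: process factors, and the aspartate/glutamate ratio enters the model by
#: prior knowledge as a metabolic-shift indicator.
PROTECTED_INPUT_NAMES: tuple[str, ...] = ("temperature", "feed_glucose", "asp_glu_ratio")


def backward_eliminate(
    runs: list[CultivationRun],
    candidates=CANDIDATE_INPUT_NAMES,
    cv: CvConfig | None = None,
    train_cfg: TrainConfig | None = None,
    tol: float = 1.0,
    smoothing: float | None = None,
    min_inputs: int = 2,
    protected=PROTECTED_INPUT_NAMES,
) -> SelectionReport:
    """Run the full three-step workflow on ``runs``.

    PCA and the correlation screen are computed on the pooled candidate
    matrix; collinear candidates are excluded; then inputs are removed
    one at a time (exhaustive leave-one-input-out retraining, removing
    whichever input's removal yields the lowest validation error) until
    the best removal worsens the error by more than ``tol`` (absolute
    percentage points).  Candidate retrainings that fail are skipped
    with the failure recorded.
    """
    cv = cv or CvConfig(n_repeats=8)
    train_cfg = train_cfg or TrainConfig(max_iter=40)
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates")

    X = _input_matrix(runs, candidates)
    targets = {
        "vcc": np.concatenate([r.samples.vcc for r in runs]),
        "titer": np.concatenate([r.samples.titer for r in runs]),
    }
    ev, loadings = pca_explained_variance(X, names=candidates)
    r2 = correlation_r2(X, targets, candidates)
    excluded = [
        c for c in flag_collinear(X, candidates, targets) if c not in protected
    ]
    current = [c for c in candidates if c not in excluded]

    reg = _RateRegression(runs, smoothing=smoothing)
    path: list[dict] = []
    current_err = reg.fit_score(current, cv, train_cfg)
    while len(current) > min_inputs:
        removable = [c for c in current if c not in protected]
        if not removable:
            break
        best_name, best_err = None, np.inf
        for name in removable:
            subset = [c for c in current if c != name]
            try:
                err = reg.fit_score(subset, cv, train_cfg)
            except Exception:
                continue
            if err < best_err:
                best_name, best_err = name, err
        if best_name is None or best_err > current_err + tol:
            break
        current = [c for c in current if c != best_name]
        path.append({"removed": best_name, "val_error": best_err})
        current_err = best_err

    return SelectionReport(
        candidates=candidates,
        explained_variance=ev,
        loadings=loadings,
        r2_map=r2,
        collinear_excluded=excluded,
        elimination_path=path,
        final_inputs=current,
    )
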