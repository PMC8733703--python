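"""Serial hybrid model: ANN rate functions inside fed-batch mass balances.

Training minimizes mean-normalized residuals of VCC and titer at the
sampling times, with the network outputs propagated through the
integrated state equations (the mechanistic half).  Cross-validation is
at run level (random 60/40 splits repeated, or leave-one-run-out for
intensified designs); one model per partition is kept at its minimal
validation NRMSE, and the resulting ensemble is averaged with per-time
SD and CI bands.

Because the model inputs are interpolated measurements rather than the
integrated states themselves, the two balances are linear in X and P:
with total cells N = X*V and total product M = P*V,

    N(t) = N0 * exp( int_0^t mu )        M(t) = int_0^t v_px * N,

which both bolus dilution and continuous feeding leave invariant.  The
trainer exploits this closed form on a fine quadrature grid (vectorized
over weight perturbations); ``predict_run`` composes the same
operation chain through the adaptive-step integrator and agrees with the
quadrature path to ~1e-4 relative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from hybridoe.ann_core import (
    Network,
    ScalerStats,
    TrainConfig,
    apply_scaler,
    fit_scaler,
    init_network,
    lm_minimize,
)
from hybridoe.datamodel import CultivationRun, PredictionResult
from hybridoe.mechanistic import InputInterpolator, StateTrajectory, integrate_states

#: The six model inputs identified by the input-selection workflow.
MODEL_INPUT_NAMES: tuple[str, ...] = (
    "temperature",
    "feed_glucose",
    "glutamine",
    "asparagine",
    "alanine",
    "asp_glu_ratio",
)

#: Nominal rate magnitudes used to scale the network outputs so that both
#: residual blocks are comparable during training.
MU_REF: float = 0.03  # h^-1
V_REF: float = 5.0e-4  # g/L/h per 10^6 cells/mL


@dataclass
class HybridModel:
    """Input scaler + network mapping scaled inputs to specific rates."""

    scaler: ScalerStats
    net: Network
    input_names: tuple[str, ...] = MODEL_INPUT_NAMES
    mu_ref: float = MU_REF
    v_ref: float = V_REF

    def rates(self, x_raw: np.ndarray) -> np.ndarray:
        """(mu, v_px) in physical units for raw input rows ``x_raw``."""
        from hybridoe.ann_core import ann_forward

        out = ann_forward(self.net, apply_scaler(self.scaler, x_raw))
        return out * np.array([self.mu_ref, self.v_ref])

    def to_dict(self) -> dict:
        return {
            "scaler": self.scaler.to_dict(),
            "net": self.net.to_dict(),
            "input_names": list(self.input_names),
            "mu_ref": self.mu_ref,
            "v_ref": self.v_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HybridModel":
        return cls(
            scaler=ScalerStats.from_dict(d["scaler"]),
            net=Network.from_dict(d["net"]),
            input_names=tuple(d["input_names"]),
            mu_ref=float(d["mu_ref"]),
            v_ref=float(d["v_ref"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "HybridModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CvConfig:
    """Run-level cross-validation settings (0.6 split, 40 repeats).

    With ``stratify_by_scale`` (default) random splits allocate runs of
    each scale separately, so every training partition covers both
    feeding regimes whenever the dataset does; a model trained on one
    regime only cannot constrain the other.
    """

    split_ratio: float = 0.6
    n_repeats: int = 40
    mode: str = "random_split"  # or "leave_one_run_out"
    stratify_by_scale: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class Ensemble:
    """One hybrid model per cross-validation partition, averaged at use."""

    members: list[HybridModel]
    partitions: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        names = {m.input_names for m in self.members}
        if len(names) != 1:
            raise ValueError("ensemble members must share input_names")

    @property
    def input_names(self) -> tuple[str, ...]:
        return self.members[0].input_names

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            m.save(path / f"member_{i:03d}.json")
        with open(path / "ensemble.yaml", "w") as fh:
            yaml.safe_dump(
                {"n_members": len(self.members), "seed": self.seed, "partitions": self.partitions},
                fh,
            )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Ensemble":
        path = Path(path)
        with open(path / "ensemble.yaml") as fh:
            meta = yaml.safe_load(fh)
        members = [
            HybridModel.load(path / f"member_{i:03d}.json")
            for i in range(meta["n_members"])
        ]
        return cls(members=members, partitions=meta.get("partitions", []), seed=meta.get("seed", 0))


# ---------------------------------------------------------------------------
# metrics


def nrmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Normalized root mean square error in percent.

    ``100 * sqrt(mean((y - y_hat)^2)) / mean(y)``; requires equal lengths
    and a nonzero mean of the measured series.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 1:
        raise ValueError("series must have equal nonzero length")
    ybar = y.mean()
    if ybar == 0:
        raise ValueError("mean of the measured series is zero")
    return 100.0 * np.sqrt(np.mean((y - y_hat) ** 2)) / ybar


# ---------------------------------------------------------------------------
# prediction


def _volume_profile(run: CultivationRun, t: np.ndarray) -> np.ndarray:
    """Model-side broth volume (L): bolus jumps or continuous linear feed."""
    V0 = run.working_volume
    fb = run.design.batch_end
    if run.feed.mode == "bolus":
        # samples at bolus times are pre-bolus, hence the ceil
        n_boluses = np.clip(np.ceil((t - fb) / 24.0 - 1e-12), 0, None)
        return V0 * (1.0 + run.feed.bolus_fraction) ** n_boluses
    V = np.full_like(t, V0, dtype=float)
    active = t > fb
    # piecewise-constant flow integrated from fed-batch start
    tt = t[active]
    flows = np.array([run.feed.flow_at(x, V0) for x in tt])
    # constant-flow default; integrate exactly for the step-profile case
    V[active] = V0 + np.array(
        [np.trapezoid(np.append([run.feed.flow_at(fb, V0)], flows[: i + 1]),
                      np.append([fb], tt[: i + 1])) for i in range(len(tt))]
    ) if run.feed.rate_times is not None else V0 + flows * (tt - fb)
    return V


class _QuadPredictor:
    """Closed-form (quadrature) hybrid prediction for one run.

    Precomputes scaled inputs on a fine grid so that predictions for many
    weight vectors reduce to two cumulative trapezoid integrations.
    """

    def __init__(
        self,
        run: CultivationRun,
        scaler: ScalerStats,
        input_names=MODEL_INPUT_NAMES,
        grid_step_h: float = 0.5,
        mu_ref: float = MU_REF,
        v_ref: float = V_REF,
    ):
        self.run = run
        self.mu_ref, self.v_ref = mu_ref, v_ref
        t_end = float(run.samples.times[-1])
        pts = set(np.arange(0.0, t_end + 1e-9, grid_step_h))
        pts.update(float(x) for x in run.samples.times)
        for seg in run.design.segments:
            if 0 < seg.start_time < t_end:
                pts.update((seg.start_time - 1e-6, seg.start_time))
        self.t = np.array(sorted(pts))
        interp = InputInterpolator(run, input_names)
        self.x_scaled = apply_scaler(scaler, interp(self.t))
        self.V = _volume_profile(run, self.t)
        self.sample_idx = np.searchsorted(self.t, run.samples.times)
        self.N0 = run.seeding_density * run.working_volume

    def states(self, W: np.ndarray, net_template: Network) -> tuple[np.ndarray, np.ndarray]:
        """X and P at the sampling times for each weight row of ``W``.

        Returns arrays of shape (n_weight_vectors, n_samples).
        """
        W = np.atleast_2d(W)
        m = W.shape[0]
        nh, ni, no = net_template.n_hidden, net_template.n_inputs, net_template.n_outputs
        k = 0
        W_h = W[:, k : k + nh * ni].reshape(m, nh, ni); k += nh * ni
        b_h = W[:, k : k + nh]; k += nh
        W_o = W[:, k : k + no * nh].reshape(m, no, nh); k += no * nh
        b_o = W[:, k : k + no]
        # hidden: (m, n_t, nh)
        h = np.tanh(np.einsum("mhi,ti->mth", W_h, self.x_scaled) + b_h[:, None, :])
        out = np.einsum("moh,mth->mto", W_o, h) + b_o[:, None, :]
        mu = out[:, :, 0] * self.mu_ref
        vpx = out[:, :, 1] * self.v_ref
        dt = np.diff(self.t)
        int_mu = np.concatenate(
            [np.zeros((m, 1)), np.cumsum(0.5 * (mu[:, 1:] + mu[:, :-1]) * dt, axis=1)],
            axis=1,
        )
        # overflow guard for wildly wrong intermediate weights; inactive for
        # any physically plausible trajectory
        N = self.N0 * np.exp(np.clip(int_mu, -700.0, 60.0))
        vN = vpx * N
        M = np.concatenate(
            [np.zeros((m, 1)), np.cumsum(0.5 * (vN[:, 1:] + vN[:, :-1]) * dt, axis=1)],
            axis=1,
        )
        X = N / self.V
        P = M / self.V
        return X[:, self.sample_idx], P[:, self.sample_idx]


def predict_run(
    model: HybridModel, run: CultivationRun, rtol: float = 1e-8
) -> StateTrajectory:
    """Predict the state trajectory of ``run`` from its initial conditions.

    Composes input interpolation -> z-scoring -> network -> mass-balance
    integration, starting from X0 = seeding density and P0 = 0.
    Deterministic; raises ``KeyError`` naming any missing analyte.
    """
    interp = InputInterpolator(run, model.input_names)

    def rate_fn(t: float):
        mu, vpx = model.rates(interp(t))
        return float(mu), float(vpx)

    return integrate_states(rate_fn, run, X0=run.seeding_density, P0=0.0, rtol=rtol)


def predict_at_samples(model: HybridModel, run: CultivationRun) -> tuple[np.ndarray, np.ndarray]:
    """Fast (quadrature) prediction of VCC and titer at the sampling times."""
    qp = _QuadPredictor(run, model.scaler, model.input_names, mu_ref=model.mu_ref, v_ref=model.v_ref)
    X, P = qp.states(model.net.get_weights()[None, :], model.net)
    return X[0], P[0]


# ---------------------------------------------------------------------------
# training objective


def hybrid_residuals(
    model: HybridModel,
    runs: list[CultivationRun],
    weighting: tuple[float, float] | None = None,
) -> np.ndarray:
    """Concatenated mean-normalized state residuals over ``runs``.

    For every run, ``(measured - predicted)`` at the sampling times for
    VCC and titer, each block divided by its (training-set) mean so both
    targets contribute on the NRMSE scale.  ``weighting`` supplies the
    normalizing means ``(mean_vcc, mean_titer)``; if None they are
    computed from ``runs``.
    """
    if weighting is None:
        mean_vcc = float(np.mean(np.concatenate([r.samples.vcc for r in runs])))
        mean_titer = float(np.mean(np.concatenate([r.samples.titer for r in runs])))
    else:
        mean_vcc, mean_titer = weighting
    blocks = []
    for run in runs:
        try:
            x_hat, p_hat = predict_at_samples(model, run)
        except Exception as exc:
            raise RuntimeError(f"prediction failed for run {run.run_id!r}: {exc}") from exc
        blocks.append((run.samples.vcc - x_hat) / mean_vcc)
        blocks.append((run.samples.titer - p_hat) / mean_titer)
    return np.concatenate(blocks)


class _HybridObjective:
    """Residual function over a fixed training partition, with a batched
    forward-difference Jacobian sharing one vectorized state evaluation."""

    def __init__(self, runs, scaler, net_template, input_names, weighting, grid_step_h=2.0):
        self.preds = [
            _QuadPredictor(r, scaler, input_names, grid_step_h=grid_step_h) for r in runs
        ]
        self.runs = runs
        self.net = net_template
        self.mean_vcc, self.mean_titer = weighting

    def _residual_matrix(self, W: np.ndarray) -> np.ndarray:
        """Residuals for each weight row; shape (m, n_res)."""
        cols = []
        for run, qp in zip(self.runs, self.preds):
            X, P = qp.states(W, self.net)
            cols.append((run.samples.vcc[None, :] - X) / self.mean_vcc)
            cols.append((run.samples.titer[None, :] - P) / self.mean_titer)
        return np.concatenate(cols, axis=1)

    def residuals(self, w: np.ndarray) -> np.ndarray:
        return self._residual_matrix(w[None, :])[0]

    def jacobian(self, w: np.ndarray, eps: float = 1e-6) -> np.ndarray:
        n = len(w)
        W = np.repeat(w[None, :], n + 1, axis=0)
        idx = np.arange(n)
        W[idx + 1, idx] += eps
        R = self._residual_matrix(W)
        return (R[1:] - R[0]).T / eps


def _validation_nrmse(model: HybridModel, runs: list[CultivationRun]) -> float:
    """Unweighted mean of the VCC and titer NRMSE pooled over ``runs``."""
    y_x, yh_x, y_p, yh_p = [], [], [], []
    for run in runs:
        X, P = predict_at_samples(model, run)
        y_x.append(run.samples.vcc)
        yh_x.append(X)
        y_p.append(run.samples.titer)
        yh_p.append(P)
    return 0.5 * (
        nrmse(np.concatenate(y_x), np.concatenate(yh_x))
        + nrmse(np.concatenate(y_p), np.concatenate(yh_p))
    )


# ---------------------------------------------------------------------------
# cross-validated fitting


def _input_matrix(runs, input_names) -> np.ndarray:
    rows = [InputInterpolator(r, input_names)(r.samples.times) for r in runs]
    return np.concatenate(rows, axis=0)


def fit_hybrid(
    runs: list[CultivationRun],
    cv: CvConfig | None = None,
    train_cfg: TrainConfig | None = None,
    input_names=MODEL_INPUT_NAMES,
    grid_step_h: float = 2.0,
) -> Ensemble:
    """Fit a cross-validated hybrid ensemble on ``runs``.

    For each partition the network is initialized from a
    partition-specific seed, trained by Levenberg-Marquardt on the
    training-partition residuals, and the weight vector with minimal
    validation NRMSE (mean of the two targets) is kept.  Splits are by
    whole runs.  Partitions that fail to train are skipped with a
    warning; at least 2 members must survive.
    """
    cv = cv or CvConfig()
    train_cfg = train_cfg or TrainConfig()
    n = len(runs)
    if cv.mode == "random_split" and n < 3:
        raise ValueError("random_split cross-validation needs at least 3 runs")
    if cv.mode == "leave_one_run_out" and n < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")

    scaler = fit_scaler(_input_matrix(runs, input_names), names=list(input_names))

    ss = np.random.SeedSequence(cv.seed)
    if cv.mode == "leave_one_run_out":
        partitions = [
            ([j for j in range(n) if j != i], [i]) for i in range(n)
        ]
    else:
        partitions = []
        if cv.stratify_by_scale:
            groups = [
                [i for i, r in enumerate(runs) if r.scale == sc]
                for sc in sorted({r.scale for r in runs})
            ]
        else:
            groups = [list(range(n))]
        for child in ss.spawn(cv.n_repeats):
            rng = np.random.default_rng(child)
            tr: list[int] = []
            va: list[int] = []
            for g in groups:
                k = int(np.ceil(cv.split_ratio * len(g)))
                perm = rng.permutation(g)
                tr.extend(perm[:k].tolist())
                va.extend(perm[k:].tolist())
            if not va:  # tiny stratum fully in training; rebalance
                va.append(tr.pop())
            partitions.append((sorted(tr), sorted(va)))

    init_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(partitions) + 1)[1:]]

    members: list[HybridModel] = []
    part_meta: list[dict] = []
    for k, (train_idx, val_idx) in enumerate(partitions):
        train_runs = [runs[i] for i in train_idx]
        val_runs = [runs[i] for i in val_idx]
        mean_vcc = float(np.mean(np.concatenate([r.samples.vcc for r in train_runs])))
        mean_titer = float(np.mean(np.concatenate([r.samples.titer for r in train_runs])))
        net = init_network(init_seeds[k], n_inputs=len(input_names), input_names=list(input_names))
        obj = _HybridObjective(
            train_runs, scaler, net, input_names, (mean_vcc, mean_titer), grid_step_h
        )
        model = HybridModel(scaler=scaler, net=net, input_names=tuple(input_names))

        best = {"err": np.inf, "w": net.get_weights().copy()}

        def snapshot(_it, w, _loss, model=model, best=best, val_runs=val_runs):
            model.net.set_weights(w)
            err = _validation_nrmse(model, val_runs)
            if err < best["err"]:
                best["err"] = err
                best["w"] = w.copy()

        try:
            snapshot(0, net.get_weights(), np.inf)
            lm_minimize(
                obj.residuals, net.get_weights(), train_cfg, jac=obj.jacobian, callback=snapshot
            )
        except Exception as exc:
            warnings.warn(f"partition {k} failed to train: {exc}")
            continue
        trained = net.copy()
        trained.set_weights(best["w"])
        members.append(HybridModel(scaler=scaler, net=trained, input_names=tuple(input_names)))
        part_meta.append(
            {
                "partition": k,
                "train_runs": [runs[i].run_id for i in train_idx],
                "val_runs": [runs[i].run_id for i in val_idx],
                "init_seed": init_seeds[k],
                "val_nrmse": float(best["err"]),
            }
        )
    if len(members) < 2:
        raise RuntimeError(
            f"only {len(members)} partitions trained successfully; need >= 2"
        )
    return Ensemble(members=members, partitions=part_meta, seed=cv.seed)


# ---------------------------------------------------------------------------
# ensembling and evaluation


def average_predict(
    ensemble: Ensemble, run: CultivationRun, times: np.ndarray | None = None
) -> PredictionResult:
    """Ensemble-average prediction with SD and CI bands.

    SD(t) is the member spread ``sqrt(sum((avg - member_i)^2) / (n-1))``
    with n the member count; CI(t) = average +/- SD(t).  Members whose
    prediction fails are excluded with a warning (at least 2 must remain).
    """
    t_out = run.samples.times if times is None else np.asarray(times, dtype=float)
    Xs, Ps = [], []
    for i, m in enumerate(ensemble.members):
        try:
            qp = _QuadPredictor(run, m.scaler, m.input_names, mu_ref=m.mu_ref, v_ref=m.v_ref)
            X, P = qp.states(m.net.get_weights()[None, :], m.net)
            if times is not None:
                X = np.interp(t_out, run.samples.times, X[0])[None, :]
                P = np.interp(t_out, run.samples.times, P[0])[None, :]
            Xs.append(X[0])
            Ps.append(P[0])
        except Exception as exc:
            warnings.warn(f"member {i} failed on run {run.run_id!r}: {exc}")
    if len(Xs) < 2:
        raise RuntimeError(f"fewer than 2 members produced predictions for {run.run_id!r}")
    X = np.array(Xs)
    P = np.array(Ps)
    x_hat, p_hat = X.mean(axis=0), P.mean(axis=0)
    sd_x = X.std(axis=0, ddof=1)
    sd_p = P.std(axis=0, ddof=1)
    return PredictionResult(
        times=t_out,
        x_hat=x_hat,
        p_hat=p_hat,
        sd_x=sd_x,
        sd_p=sd_p,
        ci_x_lower=x_hat - sd_x,
        ci_x_upper=x_hat + sd_x,
        ci_p_lower=p_hat - sd_p,
        ci_p_upper=p_hat + sd_p,
    )


def evaluate(ensemble: Ensemble, runs: list[CultivationRun]) -> dict:
    """NRMSE of the ensemble-average prediction over ``runs``.

    Pools all sampling points of all runs per target; also reports the
    per-run values.  Returns a dict with keys ``nrmse_vcc``,
    ``nrmse_titer`` and ``per_run``.
    """
    y_x, yh_x, y_p, yh_p = [], [], [], []
    per_run = {}
    for run in runs:
        pred = average_predict(ensemble, run)
        y_x.append(run.samples.vcc)
        yh_x.append(pred.x_hat)
        y_p.append(run.samples.titer)
        yh_p.append(pred.p_hat)
        per_run[run.run_id] = {
            "nrmse_vcc": nrmse(run.samples.vcc, pred.x_hat),
            "nrmse_titer": nrmse(run.samples.titer, pred.p_hat),
            "n_samples": int(run.samples.n_samples()),
        }
    return {
        "nrmse_vcc": nrmse(np.concatenate(y_x), np.concatenate(yh_x)),
        "nrmse_titer": nrmse(np.concatenate(y_p), np.concatenate(yh_p)),
        "per_run": per_run,
    }
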