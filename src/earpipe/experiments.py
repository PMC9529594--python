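"""Reproducible study-level experiments on fully synthetic sessions.

These helpers bundle the generator and the detection pipeline into the
experiment designs used for validation: a train-on-two/test-on-one held-out
evaluation, a label-permutation null for the held-out F1, and an EMG-gain
sweep that probes how detection quality scales with clench burst amplitude.
All randomness derives from explicit seeds.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import EvalReport
from .model import BruxismModel, ModelConfig, SmoteConfig, SplitPlan, evaluate
from .synthdata import NoiseConfig, ProtocolConfig, default_emg_gains, generate_study


def make_study(
    trials_per_activity: int,
    seeds: list[int],
    bruxism_scale: float = 3.0,
    gain_seed: int = 0,
):
    """Generate a 3-session study at the default noise conditions.

    ``bruxism_scale`` scales the summed clench-row EMG gain relative to the
    median non-clench activity (3.0 is the default study condition;
    values closer to 1 make the detection problem harder).
    """
    cfg = ProtocolConfig(trials_per_activity=trials_per_activity)
    gains = default_emg_gains(cfg, rng_seed=gain_seed, bruxism_scale=bruxism_scale)
    noise = dataclasses.replace(NoiseConfig(), emg_gain_matrix=gains, rng_seed=gain_seed)
    return generate_study(cfg, noise, seeds), cfg


def heldout_evaluation(
    trials_per_activity: int,
    session_seeds: list[int],
    rng_seed: int = 0,
    bruxism_scale: float = 3.0,
    run_cv: bool = True,
    n_estimators: int = 100,
):
    """Train on sessions 1–2, evaluate on the held-out session 3."""
    study, _ = make_study(trials_per_activity, session_seeds, bruxism_scale, gain_seed=rng_seed)
    plan = SplitPlan(train_sessions=["S1", "S2"], test_session="S3", rng_seed=rng_seed)
    grid = {"n_estimators": [50, 100, 200]} if run_cv else None
    model = BruxismModel.from_study(
        study,
        plan,
        smote_cfg=SmoteConfig(rng_seed=rng_seed),
        model_cfg=ModelConfig(n_estimators=n_estimators, grid=grid, rng_seed=rng_seed),
    )
    return model.fit(run_cv=run_cv)


def permutation_null_f1(
    y_test: np.ndarray, y_pred: np.ndarray, n_reps: int = 200, seed: int = 0
) -> np.ndarray:
    """F1 scores of the prediction against label-permuted test sets."""
    rng = np.random.default_rng(seed)
    return np.array(
        [evaluate(rng.permutation(y_test), y_pred).f1 for _ in range(n_reps)]
    )


def gain_sweep(
    scales: tuple[float, ...] = (1.2, 2.0, 3.2),
    n_seeds: int = 5,
    trials_per_activity: int = 2,
    base_seed: int = 0,
    n_estimators: int = 50,
) -> dict[float, list[float]]:
    """Held-out F1 per EMG gain scale over several seeded study replicates.

    Detection quality should not degrade as the clench bursts get stronger;
    the sweep returns per-scale F1 lists whose medians are expected to be
    non-decreasing in the scale.
    """
    out: dict[float, list[float]] = {}
    for scale in scales:
        f1s = []
        for rep in range(n_seeds):
            offset = base_seed + 101 * rep
            res = heldout_evaluation(
                trials_per_activity,
                session_seeds=[offset + 1, offset + 2, offset + 3],
                rng_seed=offset,
                bruxism_scale=scale,
                run_cv=False,
                n_estimators=n_estimators,
            )
            f1s.append(res.report.f1)
        out[scale] = f1s
    return out


def leakage_canary(
    trials_per_activity: int = 2, session_seeds: list[int] | None = None, rng_seed: int = 0
) -> float:
    """Max |Δ| of training-side scaler parameters when the test set is poisoned.

    Injects an extreme outlier row into the held-out session's features and
    refits; any nonzero delta in the training-fitted standardization
    parameters would indicate information leaking across the split.
    """
    from .model import session_features

    session_seeds = session_seeds or [11, 22, 33]
    study, _ = make_study(trials_per_activity, session_seeds, gain_seed=rng_seed)
    feats = {rec.session_id: session_features(rec, anns) for rec, anns in study}
    plan = SplitPlan(train_sessions=["S1", "S2"], test_session="S3", rng_seed=rng_seed)
    cfg = ModelConfig(n_estimators=30, grid=None, rng_seed=rng_seed)

    clean = BruxismModel(feats, plan, model_cfg=cfg).fit(run_cv=False)
    poisoned_feats = dict(feats)
    fm = feats["S3"]
    values = fm.values.copy()
    values[0] = 1e9
    poisoned_feats["S3"] = dataclasses.replace(fm, values=values)
    poisoned = BruxismModel(poisoned_feats, plan, model_cfg=cfg).fit(run_cv=False)

    d_mean = np.max(np.abs(clean.scaler[0] - poisoned.scaler[0]))
    d_sd = np.max(np.abs(clean.scaler[1] - poisoned.scaler[1]))
    return float(max(d_mean, d_sd))
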