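"""Hyperparameter optimization harness for the augmented CNN workflow.

Per trial, an architecture (layer count, per-layer filter count and width,
FC units, dropout, L2 factor) and the local subset size n_lsa are sampled
from the declared ranges.  The trial first trains once on the full training
groups to obtain the intermediate objective sum(R^2_train); median pruning
then aborts unpromising trials *before* the expensive cross-validation: once
``activation_after`` trials have completed, a trial is pruned when its
intermediate value falls below the median of all previously reported
intermediate values.  Surviving trials run the leave-one-group-out CV and
report sum(R^2_CV) as the objective.

The first 100 trials use seeded uniform random sampling; the protocol then
switches to a model-based (TPE) phase.  No TPE backend ships with this
package, so the TPE phase delegates to the same seeded random sampler (a
warning is emitted when sampler='tpe' is requested).  Study state is
append-only JSON lines and can be resumed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .augment import LSAConfig, augment_dataset
from .cnn import (CNNArchitecture, TrainingConfig, build_cnn,
                  cross_validate_cnn, train_cnn)
from .dataset import SpectralDataset
from .metrics import compute_metrics

__all__ = ["SearchSpace", "TrialRecord", "median_prune_decision",
           "run_hpo_study", "select_and_retrain", "params_to_arch"]


@dataclass
class SearchSpace:
    """Sampling ranges (inclusive) for the architecture and n_lsa.

    ``width_cap`` bounds the first layer's filter width (usually the number
    of wavelengths); the admissible cap halves with each additional layer
    because of the interposed pooling steps.  ``l2_range`` is sampled
    log-uniformly.
    """

    n_conv_layers: tuple[int, int] = (1, 3)
    n_filters: tuple[int, int] = (1, 10)
    width_cap: int = 61
    fc_units: tuple[int, int] = (5, 100)
    dropout_rate: tuple[float, float] = (0.0, 0.3)
    l2_range: tuple[float, float] = (1e-9, 1e-3)
    n_lsa: tuple[int, int] = (5, 15)

    def __post_init__(self) -> None:
        for lo, hi in (self.n_conv_layers, self.n_filters, self.fc_units,
                       self.dropout_rate, self.l2_range, self.n_lsa):
            if lo > hi:
                raise ValueError("range low exceeds high")
        if not 1 <= self.n_conv_layers[0] <= self.n_conv_layers[1] <= 3:
            raise ValueError("n_conv_layers must lie within [1, 3]")
        if self.width_cap < 3:
            raise ValueError("width_cap must be >= 3")
        if self.l2_range[0] <= 0:
            raise ValueError("l2_range must be positive (log-uniform)")

    def layer_width_caps(self) -> list[int]:
        """Maximum odd filter width per layer (halving with pooling)."""
        caps = []
        cap = self.width_cap
        for _ in range(self.n_conv_layers[1]):
            odd_cap = cap if cap % 2 == 1 else cap - 1
            caps.append(max(odd_cap, 3))
            cap //= 2
        return caps

    def sample(self, rng: np.random.Generator) -> dict:
        """One uniform draw of all (conditional) parameters."""
        n_layers = int(rng.integers(self.n_conv_layers[0],
                                    self.n_conv_layers[1] + 1))
        caps = self.layer_width_caps()
        filters, widths = [], []
        for i in range(n_layers):
            filters.append(int(rng.integers(self.n_filters[0],
                                            self.n_filters[1] + 1)))
            odd_choices = np.arange(3, caps[i] + 1, 2)
            widths.append(int(rng.choice(odd_choices)))
        lo, hi = self.l2_range
        return {
            "n_conv_layers": n_layers,
            "n_filters": filters,
            "filter_widths": widths,
            "fc_units": int(rng.integers(self.fc_units[0],
                                         self.fc_units[1] + 1)),
            "dropout_rate": float(rng.uniform(*self.dropout_rate)),
            "l2_factor": float(math.exp(rng.uniform(math.log(lo),
                                                    math.log(hi)))),
            "n_lsa": int(rng.integers(self.n_lsa[0], self.n_lsa[1] + 1)),
        }


def params_to_arch(params: dict) -> CNNArchitecture:
    """Build the architecture described by a sampled parameter dict."""
    return CNNArchitecture(
        n_filters=list(params["n_filters"]),
        filter_widths=list(params["filter_widths"]),
        fc_units=params["fc_units"],
        dropout_rate=params["dropout_rate"],
        l2_factor=params["l2_factor"],
    )


@dataclass
class TrialRecord:
    """One HPO trial: sampled parameters, intermediate and final objectives."""

    trial_id: int
    params: dict
    sum_r2_train: float | None = None
    sum_r2_cv: float | None = None
    status: str = "completed"        # completed | pruned | failed
    error: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, line: str) -> "TrialRecord":
        return cls(**json.loads(line))


def median_prune_decision(trial_train_value: float,
                          history: list[float] | np.ndarray,
                          trial_index: int,
                          activation_after: int = 100) -> str:
    """'keep' or 'prune' by the median rule.

    Before ``activation_after`` trials have completed the decision is always
    'keep'; afterwards the trial is pruned iff its intermediate objective is
    strictly lower than the median of all previously reported values.
    """
    if trial_index < 0:
        raise ValueError("trial_index must be >= 0")
    if trial_index < activation_after or len(history) == 0:
        return "keep"
    med = float(np.median(np.asarray(history, dtype=float)))
    return "prune" if trial_train_value < med else "keep"


def _train_once_sum_r2(ds: SpectralDataset, arch: CNNArchitecture,
                       lsa_cfg: LSAConfig, train_cfg: TrainingConfig) -> float:
    """Single training run on all training groups -> sum(R^2_train)."""
    aug = augment_dataset(ds, lsa_cfg)
    model = build_cnn(arch, ds.n_wavelengths, ds.n_components,
                      seed=train_cfg.seed)
    train_cnn(model, aug.X_star, aug.Y_star, ds.X, ds.Y, train_cfg)
    r2 = compute_metrics(ds.Y, model.predict(ds.X)).r2
    return float(np.sum(r2))


def run_hpo_study(ds: SpectralDataset, space: SearchSpace,
                  n_trials: int = 500, sampler: str = "random",
                  seed: int = 0,
                  lsa_base: LSAConfig | None = None,
                  train_cfg: TrainingConfig | None = None,
                  activation_after: int = 100,
                  switch_after: int = 100,
                  record_path: str | None = None,
                  resume: list[TrialRecord] | None = None
                  ) -> list[TrialRecord]:
    """Run (or resume) an HPO study; returns the full trial record list.

    ``sampler`` is 'random' or 'tpe'; the TPE phase (after ``switch_after``
    completed trials) delegates to the seeded random sampler since no TPE
    backend is bundled.  Records are appended incrementally to
    ``record_path`` (JSON lines) when given.  Trial-level failures are
    recorded with status 'failed' and the study continues.
    """
    if sampler not in ("random", "tpe"):
        raise ValueError("sampler must be 'random' or 'tpe'")
    if sampler == "tpe":
        warnings.warn("no TPE backend available; the TPE phase uses the "
                      "seeded random sampler", stacklevel=2)
    lsa_base = lsa_base or LSAConfig()
    train_cfg = train_cfg or TrainingConfig()
    records: list[TrialRecord] = list(resume) if resume else []
    start = len(records)
    train_history = [r.sum_r2_train for r in records
                     if r.sum_r2_train is not None]
    completed = sum(r.status == "completed" for r in records)

    fh = open(record_path, "a") if record_path else None
    try:
        for t in range(start, n_trials):
            rng = np.random.default_rng(np.random.SeedSequence((seed, t)))
            params = space.sample(rng)
            rec = TrialRecord(trial_id=t, params=params)
            try:
                arch = params_to_arch(params)
                lsa_cfg = replace(lsa_base, n_lsa=params["n_lsa"],
                                  seed=lsa_base.seed + t)
                tcfg = replace(train_cfg, seed=train_cfg.seed + t)
                rec.sum_r2_train = _train_once_sum_r2(ds, arch, lsa_cfg, tcfg)
                decision = median_prune_decision(
                    rec.sum_r2_train, train_history, completed,
                    activation_after)
                train_history.append(rec.sum_r2_train)
                if decision == "prune":
                    rec.status = "pruned"
                    rec.sum_r2_cv = None
                else:
                    cv = cross_validate_cnn(ds, arch, lsa_cfg, tcfg)
                    rec.sum_r2_cv = cv["sum_r2_cv"]
                    rec.status = "completed"
                    completed += 1
            except Exception as exc:        # noqa: BLE001 - study continues
                rec.status = "failed"
                rec.error = str(exc)
            records.append(rec)
            if fh:
                fh.write(rec.to_json() + "\n")
                fh.flush()
    finally:
        if fh:
            fh.close()
    return records


def select_and_retrain(records: list[TrialRecord], ds: SpectralDataset,
                       top_k: int = 5, repeats: int = 10,
                       lsa_base: LSAConfig | None = None,
                       train_cfg: TrainingConfig | None = None,
                       test_ds: SpectralDataset | None = None,
                       retrain_patience: int = 10) -> dict:
    """Rank trials, retrain the best configuration with elevated patience.

    Returns the top-k table (for inspection), the chosen parameters, the
    retrained model ensemble and per-repeat train/test metrics (NRMSE and
    R^2 per component).
    """
    done = [r for r in records if r.status == "completed"
            and r.sum_r2_cv is not None]
    if len(done) < top_k:
        raise ValueError(f"need at least top_k={top_k} completed trials, "
                         f"have {len(done)}")
    ranked = sorted(done, key=lambda r: -r.sum_r2_cv)
    top = ranked[:top_k]
    best = top[0]
    arch = params_to_arch(best.params)
    lsa_base = lsa_base or LSAConfig()
    train_cfg = train_cfg or TrainingConfig()

    models, metrics_rows = [], []
    for rep in range(repeats):
        lsa_cfg = replace(lsa_base, n_lsa=best.params["n_lsa"],
                          seed=lsa_base.seed + 5000 + rep)
        tcfg = replace(train_cfg, patience=retrain_patience,
                       seed=train_cfg.seed + 5000 + rep)
        aug = augment_dataset(ds, lsa_cfg)
        model = build_cnn(arch, ds.n_wavelengths, ds.n_components,
                          seed=tcfg.seed)
        train_cnn(model, aug.X_star, aug.Y_star, ds.X, ds.Y, tcfg)
        models.append(model)
        row = {"repeat": rep}
        m_train = compute_metrics(ds.Y, model.predict(ds.X))
        row["train_nrmse"] = m_train.nrmse.tolist()
        row["train_r2"] = m_train.r2.tolist()
        if test_ds is not None:
            m_test = compute_metrics(test_ds.Y, model.predict(test_ds.X))
            row["test_nrmse"] = m_test.nrmse.tolist()
            row["test_r2"] = m_test.r2.tolist()
        metrics_rows.append(row)
    return {
        "top_table": [dataclasses.asdict(r) for r in top],
        "best_params": best.params,
        "models": models,
        "metrics": metrics_rows,
    }
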