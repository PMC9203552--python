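"""Case-control classification with and without biotype knowledge.

Two artificial neural networks share one architectural template over
the vectorized FC matrix:

* the **baseline** model maps FC straight to a single case-vs-control
  probability;
* the **biotype-aware** model first distinguishes each retained biotype
  from controls with its own subnetwork, then combines the per-biotype
  membership scores in a learned nonnegative weighted sum into the
  overall case score.  Its objective is the sum of per-biotype
  cross-entropies (each over that biotype's cases plus all controls)
  plus ``lam`` times the overall case-vs-control cross-entropy of the
  combined score, so the combination weights and every subnetwork are
  trained jointly.

Each subnetwork uses a grouped per-ROI extractor: every FC feature
belongs to exactly two ROIs, and each ROI's row of R-1 pairwise
correlations is compressed by a small per-ROI linear map before one
dense hidden layer.  The parameter count is thereby sublinear in
p x hidden-width, which keeps the model trainable at p = 35,778 with a
few hundred subjects.

The networks are plain numpy with explicit backpropagation and Adam,
full-batch, deterministic under a seed.  Per-biotype membership scores
double as quantitative traits for the genetic association stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

OMITTED = -1  # biotype label of omitted-cluster cases (case loss only)

_EPS = 1e-7


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, with ties counted 1/2.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC is undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def gscore(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return float(np.sqrt(sensitivity * specificity))


@dataclass(frozen=True)
class DecisionThreshold:
    """Probability cutoff chosen on the validation split."""

    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def gscore(self) -> float:
        return gscore(self.sensitivity, self.specificity)


def _sens_spec(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> tuple[float, float]:
    pred = scores >= cutoff
    pos = labels.astype(bool)
    sens = float(pred[pos].mean())
    spec = float((~pred[~pos]).mean())
    return sens, spec


def choose_threshold(val_scores: np.ndarray, val_labels: np.ndarray) -> DecisionThreshold:
    """Pick the cutoff minimizing |specificity - sensitivity| on validation.

    Candidates are midpoints between adjacent sorted unique scores (plus
    one candidate below the minimum and one above the maximum).  Ties on
    the objective prefer higher specificity, then the lower cutoff.
    """
    scores = np.asarray(val_scores, dtype=float)
    labels = np.asarray(val_labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold selection needs both classes in validation")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best: DecisionThreshold | None = None
    best_key: tuple[float, float, float] | None = None
    for c in candidates:
        sens, spec = _sens_spec(scores, labels, c)
        key = (abs(spec - sens), -spec, c)
        if best_key is None or key < best_key:
            best_key = key
            best = DecisionThreshold(cutoff=float(c), sensitivity=sens, specificity=spec)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# network primitives
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _roi_pair_index(n_roi: int) -> np.ndarray:
    """(R, R-1) matrix: row r lists the FC indices of pairs involving ROI r."""
    p = n_roi * (n_roi - 1) // 2
    iu, ju = np.triu_indices(n_roi, k=1)
    idx: list[list[int]] = [[] for _ in range(n_roi)]
    for f in range(p):
        idx[iu[f]].append(f)
        idx[ju[f]].append(f)
    return np.asarray(idx, dtype=int)


def _infer_n_roi(p: int) -> int:
    r = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
    if r * (r - 1) // 2 != p:
        raise ValueError(f"feature count {p} is not R(R-1)/2 for any integer R")
    return r


@dataclass
class TrainConfig:
    """Hyperparameters of both network modes (recorded in provenance)."""

    roi_code: int = 2          # per-ROI code width of the grouped extractor
    hidden: int = 16           # dense hidden width per subnetwork
    lam: float = 1.0           # weight of the overall case loss (aware mode)
    detach_combined: bool = True  # combined loss trains the combination
    # weights only; per-biotype supervision alone shapes each subnetwork
    lr: float = 0.01
    epochs: int = 300
    weight_decay: float = 1e-4
    val_check_every: int = 10  # early-stopping cadence on validation AUC
    patience: int = 10         # checks without improvement before stopping

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _init_params(
    rng: np.random.Generator, n_roi: int, n_heads: int, cfg: TrainConfig, aware: bool
) -> dict[str, np.ndarray]:
    """One grouped extractor + hidden layer + logistic output per head."""
    c, h, b = cfg.roi_code, cfg.hidden, n_heads
    k = n_roi - 1
    params = {
        "Wg": rng.normal(0, 1.0 / np.sqrt(k), size=(b, n_roi, k, c)),
        "bg": np.zeros((b, n_roi, c)),
        "W2": rng.normal(0, 1.0 / np.sqrt(n_roi * c), size=(b, n_roi * c, h)),
        "b2": np.zeros((b, h)),
        "w3": rng.normal(0, 1.0 / np.sqrt(h), size=(b, h)),
        "b3": np.zeros(b),
    }
    if aware:
        params["a"] = np.zeros(b)  # softplus(0) -> equal combination weights
    return params


def _forward(params: dict, x: np.ndarray, pair_index: np.ndarray, aware: bool) -> dict:
    xg = x[:, pair_index]                                          # (n, R, R-1)
    h1 = np.tanh(np.einsum("nrk,brkc->bnrc", xg, params["Wg"]) + params["bg"][:, None])
    f1 = h1.reshape(h1.shape[0], h1.shape[1], -1)                  # (B, n, R*c)
    h2 = np.tanh(np.einsum("bnf,bfh->bnh", f1, params["W2"]) + params["b2"][:, None])
    logits = np.einsum("bnh,bh->bn", h2, params["w3"]) + params["b3"][:, None]
    s = _sigmoid(logits).T                                         # (n, B)
    out = {"xg": xg, "h1": h1, "f1": f1, "h2": h2, "s": s}
    if aware:
        w = _softplus(params["a"])
        wn = w / w.sum()
        out["wn"] = wn
        out["combined"] = s @ wn
    else:
        out["combined"] = s[:, 0]
    return out


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    prob = np.clip(prob, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def _bce_grad_prob(prob: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d/d prob of the elementwise binary cross-entropy."""
    prob = np.clip(prob, _EPS, 1.0 - _EPS)
    return (prob - y) / (prob * (1.0 - prob))


def _loss_and_grads(
    params: dict,
    x: np.ndarray,
    pair_index: np.ndarray,
    y_am: np.ndarray,
    head_y: np.ndarray,
    head_mask: np.ndarray,
    cfg: TrainConfig,
    aware: bool,
) -> tuple[float, dict[str, np.ndarray]]:
    """Joint objective and its analytic gradients.

    ``head_y``/``head_mask`` are (n, B): per-head targets and the
    subjects entering that head's cross-entropy (that biotype's cases
    plus all controls; for the baseline, everyone against the case
    label).
    """
    n, n_heads = x.shape[0], head_y.shape[1]
    fwd = _forward(params, x, pair_index, aware)
    s = fwd["s"]

    loss = 0.0
    d_logits = np.zeros_like(s)  # (n, B)
    for j in range(n_heads):
        m = head_mask[:, j]
        loss += _bce(s[m, j], head_y[m, j])
        d_logits[m, j] += (s[m, j] - head_y[m, j]) / m.sum()

    if aware:
        comb = np.clip(fwd["combined"], _EPS, 1.0 - _EPS)
        wn = fwd["wn"]
        loss += cfg.lam * _bce(comb, y_am)
        d_comb = cfg.lam * _bce_grad_prob(comb, y_am) / n
        if not cfg.detach_combined:
            d_logits += d_comb[:, None] * wn[None, :] * s * (1.0 - s)
        w = _softplus(params["a"])
        d_wn = d_comb @ s
        d_w = (d_wn - d_wn @ wn) / w.sum()
        d_a = d_w * _sigmoid(params["a"])

    h1, f1, h2, xg = fwd["h1"], fwd["f1"], fwd["h2"], fwd["xg"]
    dl = d_logits.T                                                # (B, n)
    grads = {
        "w3": np.einsum("bn,bnh->bh", dl, h2) + cfg.weight_decay * params["w3"],
        "b3": dl.sum(axis=1),
    }
    d_h2 = dl[:, :, None] * params["w3"][:, None, :] * (1.0 - h2**2)
    grads["W2"] = (
        np.einsum("bnf,bnh->bfh", f1, d_h2) + cfg.weight_decay * params["W2"]
    )
    grads["b2"] = d_h2.sum(axis=1)
    d_f1 = np.einsum("bnh,bfh->bnf", d_h2, params["W2"])
    d_h1 = d_f1.reshape(h1.shape) * (1.0 - h1**2)
    grads["Wg"] = (
        np.einsum("nrk,bnrc->brkc", xg, d_h1) + cfg.weight_decay * params["Wg"]
    )
    grads["bg"] = d_h1.sum(axis=1)
    if aware:
        grads["a"] = d_a
    # weight decay is a regularizer on the weights, not part of the
    # reported loss; biases and combination weights are not decayed
    return loss, grads


@dataclass
class ClassifierModel:
    """Trained network: per-head grouped extractors + score combination."""

    mode: str                      # "baseline" | "biotype_aware"
    n_roi: int
    n_biotypes: int
    params: dict[str, np.ndarray]
    config: TrainConfig
    seed: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._pair_index = _roi_pair_index(self.n_roi)

    def predict(self, fc: np.ndarray) -> dict[str, np.ndarray]:
        """Per-biotype membership scores and the combined case score."""
        fwd = _forward(
            self.params, np.asarray(fc, dtype=float), self._pair_index,
            self.mode == "biotype_aware",
        )
        return {"biotype_scores": fwd["s"], "combined": fwd["combined"]}

    def predict_combined(self, fc: np.ndarray) -> np.ndarray:
        return self.predict(fc)["combined"]

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.params)
        manifest = {
            "mode": self.mode,
            "n_roi": self.n_roi,
            "n_biotypes": self.n_biotypes,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "provenance": self.provenance,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ClassifierModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        with np.load(directory / "params.npz") as npz:
            params = {k: npz[k] for k in npz.files}
        return cls(
            mode=manifest["mode"],
            n_roi=manifest["n_roi"],
            n_biotypes=manifest["n_biotypes"],
            params=params,
            config=TrainConfig(**manifest["config"]),
            seed=manifest["seed"],
            provenance=manifest["provenance"],
        )


def _train(
    mode: str,
    x_train: np.ndarray,
    y_am: np.ndarray,
    biotype_labels: np.ndarray | None,
    x_val: np.ndarray,
    y_val: np.ndarray,
    seed: int,
    cfg: TrainConfig,
) -> ClassifierModel:
    x_train = np.asarray(x_train, dtype=float)
    y_am = np.asarray(y_am, dtype=float)
    n, p = x_train.shape
    n_roi = _infer_n_roi(p)
    aware = mode == "biotype_aware"

    if aware:
        assert biotype_labels is not None
        blabs = np.asarray(biotype_labels, dtype=int)
        biotypes = np.unique(blabs[blabs > 0])
        # underpowered biotypes fall back to the overall case loss only
        keep = []
        for b in biotypes:
            if (blabs == b).sum() < 5:
                warnings.warn(
                    f"biotype {b} has <5 training subjects; merged into case-only loss",
                    stacklevel=3,
                )
                blabs = np.where(blabs == b, OMITTED, blabs)
            else:
                keep.append(b)
        biotypes = np.asarray(keep, dtype=int)
        if len(biotypes) == 0:
            raise ValueError("no biotype has enough training subjects")
        n_heads = len(biotypes)
        controls = y_am == 0
        head_y = np.zeros((n, n_heads))
        head_mask = np.zeros((n, n_heads), dtype=bool)
        for j, b in enumerate(biotypes):
            members = blabs == b
            head_y[:, j] = members.astype(float)
            head_mask[:, j] = members | controls
    else:
        n_heads = 1
        biotypes = np.asarray([], dtype=int)
        head_y = y_am[:, None]
        head_mask = np.ones((n, 1), dtype=bool)

    rng = np.random.default_rng(seed)
    params = _init_params(rng, n_roi, n_heads, cfg, aware)
    model = ClassifierModel(
        mode=mode, n_roi=n_roi, n_biotypes=n_heads, params=params, config=cfg,
        seed=seed, provenance={"biotype_ids": biotypes.tolist(), "n_train": n},
    )
    pair_index = model._pair_index

    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0

    best_auc = -np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    stall = 0

    for epoch in range(cfg.epochs):
        _, grads = _loss_and_grads(
            params, x_train, pair_index, y_am, head_y, head_mask, cfg, aware
        )
        step += 1
        for k in params:
            adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
            adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
            mhat = adam_m[k] / (1 - beta1**step)
            vhat = adam_v[k] / (1 - beta2**step)
            params[k] -= cfg.lr * mhat / (np.sqrt(vhat) + adam_eps)

        if (epoch + 1) % cfg.val_check_every == 0:
            val_auc = auc(model.predict_combined(x_val), y_val)
            if val_auc > best_auc + 1e-6:
                best_auc = val_auc
                best_params = {k: v.copy() for k, v in params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break

    model.params = best_params
    model.provenance["best_val_auc"] = float(best_auc)
    return model


def train_baseline(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    seed: int = 0,
    config: TrainConfig | None = None,
) -> ClassifierModel:
    """Train the direct case-vs-control network (no biotype knowledge)."""
    y_train = np.asarray(y_train).astype(int)
    if len(np.unique(y_train)) < 2 or len(np.unique(np.asarray(y_val).astype(int))) < 2:
        raise ValueError("both classes must be present in train and validation")
    return _train(
        "baseline", x_train, y_train.astype(float), None,
        np.asarray(x_val, dtype=float), np.asarray(y_val).astype(int),
        seed, config or TrainConfig(),
    )


def train_biotype_aware(
    x_train: np.ndarray,
    y_train: np.ndarray,
    biotype_labels: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    seed: int = 0,
    config: TrainConfig | None = None,
) -> ClassifierModel:
    """Train the biotype-aware network with the joint objective.

    ``biotype_labels`` holds 0 for controls, 1..B for retained-biotype
    cases and :data:`OMITTED` for omitted-cluster cases, which enter the
    overall case loss but no biotype head.
    """
    y_train = np.asarray(y_train).astype(int)
    if len(np.unique(y_train)) < 2 or len(np.unique(np.asarray(y_val).astype(int))) < 2:
        raise ValueError("both classes must be present in train and validation")
    return _train(
        "biotype_aware", x_train, y_train.astype(float), biotype_labels,
        np.asarray(x_val, dtype=float), np.asarray(y_val).astype(int),
        seed, config or TrainConfig(),
    )
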