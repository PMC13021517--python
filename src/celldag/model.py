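"""Linear and MLP cell-type classifiers with a seeded mini-batch trainer.

The interface follows the model/results convention of statistical
modelling packages: :class:`CellTypeClassifier` is built from data (an
expression matrix, ontology-indexed labels and the :class:`~celldag.ontology.Ontology`
defining the label space) and ``fit()`` returns a
:class:`ClassifierResults` carrying the fitted parameters, the training
history and prediction/evaluation methods.

The flat-CE and HCE variants of a model share identical architecture,
initialisation and batch order for the same seed; the loss term is the
only difference between them.  Training is mini-batch gradient descent
with Adam by default (plain SGD behind ``optimizer="sgd"``), with
gradients from :func:`celldag.hierarchy_loss.loss_and_grad`.  Adam is the
default because the stabilised logarithm ``log(s + eps)`` flattens the
loss once a class's adjusted score falls well below ``eps``; plain SGD
can stall on that plateau, while Adam's per-parameter rescaling escapes
it.  Everything is deterministic given ``(seed, data, config)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from celldag.hierarchy_loss import (
    DEFAULT_EPSILON,
    ClassWeights,
    compute_class_weights,
    loss_and_grad,
    softmax,
)
from celldag.ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = ["CellTypeClassifier", "ClassifierResults"]


def _as_dense(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense(), dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class CellTypeClassifier:
    """A softmax classifier over an ontology-structured label space.

    Parameters
    ----------
    X
        Cells x genes expression matrix (normalized; dense or sparse).
    labels
        Per-cell class indices into the ontology's node order, or term-ID
        strings (mapped through the ontology).
    ontology
        The label space; its size fixes the output dimension and its
        reachability matrix drives the HCE loss.
    architecture
        ``"linear"`` (no hidden layer) or ``"mlp"``.
    hidden_dims
        Hidden-layer widths for the MLP; must be empty/None for linear.
        Default for the MLP is a single hidden layer of width 64, ReLU.
    seed
        Governs weight initialisation and batch shuffling jointly.
    """

    def __init__(
        self,
        X,
        labels,
        ontology: Ontology,
        architecture: str = "linear",
        hidden_dims: tuple[int, ...] | None = None,
        seed: int = 0,
    ):
        if architecture not in ("linear", "mlp"):
            raise ValueError(f"unknown architecture {architecture!r}")
        if architecture == "linear":
            if hidden_dims:
                raise ValueError("hidden_dims must be empty for a linear model")
            hidden_dims = ()
        else:
            hidden_dims = tuple(hidden_dims) if hidden_dims else (64,)
            if not all(h > 0 for h in hidden_dims):
                raise ValueError("hidden_dims must be positive")

        self.X = _as_dense(X)
        self.ontology = ontology
        if len(np.atleast_1d(labels)) and isinstance(np.atleast_1d(labels)[0], str):
            labels = ontology.indices(labels)
        self.labels = np.asarray(labels, dtype=np.int64)
        if self.labels.shape[0] != self.X.shape[0]:
            raise ValueError("one label per cell is required")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(ontology)
        ):
            raise ValueError("label indices out of ontology range")

        self.architecture = architecture
        self.hidden_dims = hidden_dims
        self.input_dim = self.X.shape[1]
        self.output_dim = len(ontology)
        self.seed = seed

    # ------------------------------------------------------------------
    # parameters and forward/backward passes
    # ------------------------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        dims = (self.input_dim, *self.hidden_dims, self.output_dim)
        params: dict[str, np.ndarray] = {}
        for layer, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:])):
            scale = np.sqrt(2.0 / fan_in)
            params[f"W{layer}"] = rng.normal(0.0, scale, size=(fan_in, fan_out))
            params[f"b{layer}"] = np.zeros(fan_out)
        return params

    def _forward(
        self, params: dict[str, np.ndarray], X: np.ndarray
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return logits and the per-layer activations (for backprop)."""
        n_layers = len(self.hidden_dims) + 1
        activations = [X]
        h = X
        for layer in range(n_layers - 1):
            h = np.maximum(h @ params[f"W{layer}"] + params[f"b{layer}"], 0.0)
            activations.append(h)
        logits = h @ params[f"W{n_layers - 1}"] + params[f"b{n_layers - 1}"]
        return logits, activations

    def _backward(
        self,
        params: dict[str, np.ndarray],
        activations: list[np.ndarray],
        grad_logits: np.ndarray,
    ) -> dict[str, np.ndarray]:
        n_layers = len(self.hidden_dims) + 1
        grads: dict[str, np.ndarray] = {}
        delta = grad_logits
        for layer in range(n_layers - 1, -1, -1):
            a = activations[layer]
            grads[f"W{layer}"] = a.T @ delta
            grads[f"b{layer}"] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ params[f"W{layer}"].T) * (a > 0)
        return grads

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------
    def fit(
        self,
        loss: str = "hce",
        epochs: int = 60,
        batch_size: int = 64,
        learning_rate: float = 0.005,
        optimizer: str = "adam",
        weighted: bool = True,
        epsilon: float = DEFAULT_EPSILON,
        validation: tuple | None = None,
        patience: int | None = None,
    ) -> "ClassifierResults":
        """Minimise the configured loss by mini-batch gradient descent.

        Parameters
        ----------
        loss
            ``"ce"`` (flat weighted cross-entropy) or ``"hce"``
            (hierarchical, via the ontology's reachability matrix).
        validation, patience
            Optional ``(X_val, labels_val)`` pair; when given together
            with ``patience``, training stops after ``patience`` epochs
            without improvement in validation macro F1 (descendant-aware)
            and the best parameters are restored.

        Class weights are computed from the training labels only.
        """
        if loss not in ("ce", "hce"):
            raise ValueError(f"unknown loss {loss!r}")
        if min(epochs, batch_size) <= 0 or learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        reachability = (
            self.ontology.reachability().astype(np.float64) if loss == "hce" else None
        )
        weights: ClassWeights | None = (
            compute_class_weights(self.labels, self.output_dim) if weighted else None
        )

        rng = np.random.default_rng(self.seed)
        params = self._init_params(rng)
        adam_state = (
            {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in params.items()}
            if optimizer == "adam"
            else None
        )
        if optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {optimizer!r}")

        n = self.X.shape[0]
        history: list[dict] = []
        best_val, best_params, stall = -np.inf, None, 0
        step = 0
        for epoch in range(1, epochs + 1):
            order = rng.permutation(n)
            epoch_loss, epoch_weight = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits, activations = self._forward(params, self.X[idx])
                batch_loss, grad_logits = loss_and_grad(
                    logits, self.labels[idx], weights, reachability, epsilon
                )
                if not np.isfinite(batch_loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {batch_loss!r}; "
                        "lower the learning rate"
                    )
                grads = self._backward(params, activations, grad_logits)
                step += 1
                for key in params:
                    g = grads[key]
                    if adam_state is None:
                        params[key] -= learning_rate * g
                    else:  # Adam, beta=(0.9, 0.999)
                        m, v = adam_state[key]
                        m[:] = 0.9 * m + 0.1 * g
                        v[:] = 0.999 * v + 0.001 * g * g
                        m_hat = m / (1 - 0.9**step)
                        v_hat = v / (1 - 0.999**step)
                        params[key] -= learning_rate * m_hat / (np.sqrt(v_hat) + 1e-8)
                epoch_loss += batch_loss * len(idx)
                epoch_weight += len(idx)

            record = {"epoch": epoch, "train_loss": epoch_loss / epoch_weight}
            if validation is not None:
                record["val_macro_f1"] = self._validation_f1(params, validation)
                if patience is not None:
                    if record["val_macro_f1"] > best_val + 1e-12:
                        best_val = record["val_macro_f1"]
                        best_params = {k: v.copy() for k, v in params.items()}
                        stall = 0
                    else:
                        stall += 1
            history.append(record)
            if patience is not None and stall >= patience:
                break
        if best_params is not None:
            params = best_params

        config = {
            "loss": loss,
            "epochs": epochs,
            "batch_size": batch_size,
            "learning_rate": learning_rate,
            "optimizer": optimizer,
            "weighted": weighted,
            "epsilon": epsilon,
            "seed": self.seed,
            "architecture": self.architecture,
            "hidden_dims": list(self.hidden_dims),
        }
        return ClassifierResults(
            model=self,
            params=params,
            history=pd.DataFrame(history),
            class_weights=weights,
            config=config,
        )

    def _validation_f1(self, params, validation) -> float:
        from celldag.evaluation import evaluation_report

        x_val, y_val = validation
        logits, _ = self._forward(params, _as_dense(x_val))
        preds = np.argmax(logits, axis=1)
        y_val = np.asarray(y_val, dtype=np.int64)
        report = evaluation_report(preds, y_val, self.ontology.reachability())
        return report.macro_f1


@dataclass
class ClassifierResults:
    """A fitted classifier: parameters, history, prediction and persistence."""

    model: CellTypeClassifier
    params: dict[str, np.ndarray]
    history: pd.DataFrame
    class_weights: ClassWeights | None
    config: dict

    @property
    def config_hash(self) -> str:
        return _config_hash(self.config)

    # ------------------------------------------------------------------
    # prediction
    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Per-cell raw class distribution p (rows sum to one)."""
        X = _as_dense(X)
        if X.shape[1] != self.model.input_dim:
            raise ValueError(
                f"expected {self.model.input_dim} genes, got {X.shape[1]}"
            )
        logits, _ = self.model._forward(self.params, X)
        return softmax(logits)

    def predict_label(self, X, use_adjusted: bool = False) -> np.ndarray:
        """Per-cell class index: argmax of p (ties -> lowest index).

        ``use_adjusted=True`` argmaxes the hierarchy-adjusted scores
        ``s = R p`` instead of the raw distribution; the default scores
        raw predictions.
        """
        p = self.predict_proba(X)
        if use_adjusted:
            from celldag.hierarchy_loss import adjust_scores

            p = adjust_scores(p, self.model.ontology.reachability())
        return np.argmax(p, axis=1)

    predict = predict_label

    def evaluate(self, X, labels, include: str = "present"):
        """Descendant-aware evaluation report on a labelled set."""
        from celldag.evaluation import evaluation_report

        if len(np.atleast_1d(labels)) and isinstance(np.atleast_1d(labels)[0], str):
            labels = self.model.ontology.indices(labels)
        preds = self.predict_label(X)
        return evaluation_report(
            preds,
            np.asarray(labels, dtype=np.int64),
            self.model.ontology.reachability(),
            include=include,
            class_names=self.model.ontology.node_ids,
        )

    # ------------------------------------------------------------------
    # reporting and persistence
    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fit, statsmodels-style."""
        m = self.model
        n_params = sum(v.size for v in self.params.values())
        lines = [
            "Cell-type classifier results",
            "=" * 44,
            f"architecture:    {m.architecture}"
            + (f" hidden={m.hidden_dims}" if m.hidden_dims else ""),
            f"loss:            {self.config['loss']}",
            f"classes:         {m.output_dim}",
            f"genes:           {m.input_dim}",
            f"training cells:  {m.X.shape[0]}",
            f"parameters:      {n_params}",
            f"epochs run:      {len(self.history)}",
            f"final train loss:{self.history['train_loss'].iloc[-1]: .6f}",
        ]
        if "val_macro_f1" in self.history:
            lines.append(
                f"best val macroF1:{self.history['val_macro_f1'].max(): .4f}"
            )
        lines.append(f"config hash:     {self.config_hash}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Write a self-describing JSON checkpoint.

        The checkpoint records the architecture spec, the fitted weights,
        the ontology node ordering (so class alignment can be verified at
        load/evaluation time) and the training-config hash.
        """
        payload = {
            "format": "celldag-checkpoint-v1",
            "config": self.config,
            "config_hash": self.config_hash,
            "node_ids": list(self.model.ontology.node_ids),
            "input_dim": self.model.input_dim,
            "params": {k: v.tolist() for k, v in self.params.items()},
            "history": self.history.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path, ontology: Ontology) -> "ClassifierResults":
        """Load a checkpoint; the ontology must match the stored node order."""
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "celldag-checkpoint-v1":
            raise ValueError(f"{path} is not a celldag checkpoint")
        stored = tuple(payload["node_ids"])
        if stored != ontology.node_ids:
            raise ValueError(
                "ontology node ordering does not match checkpoint; refusing to "
                "evaluate with misaligned classes"
            )
        config = payload["config"]
        model = CellTypeClassifier(
            X=np.zeros((0, payload["input_dim"])),
            labels=np.zeros(0, dtype=np.int64),
            ontology=ontology,
            architecture=config["architecture"],
            hidden_dims=tuple(config["hidden_dims"]) or None,
            seed=config["seed"],
        )
        params = {k: np.asarray(v, dtype=np.float64) for k, v in payload["params"].items()}
        return cls(
            model=model,
            params=params,
            history=pd.DataFrame(payload["history"]),
            class_weights=None,
            config=config,
        )
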