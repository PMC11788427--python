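"""Scikit-learn style estimator around the transformer TIS scorer.

:class:`TISTransformer` follows the sklearn estimator contract
(``get_params``/``set_params``, ``fit``/``predict_proba``, fitted attributes
with a trailing underscore) so it composes with sklearn model-selection
utilities. ``X`` is a sequence of per-transcript count matrices (or dense
``(L, 21)`` count arrays) rather than a rectangular feature matrix — the
natural sample unit here is a transcript of arbitrary length.

Two objectives share the encoder trunk:

* ``objective="supervised"`` — per-position binary cross-entropy against
  TIS labels, with a positive-class weight countering the extreme class
  imbalance (roughly one positive per coding transcript versus thousands
  of negatives).
* ``objective="masked_pretrain"`` — a seeded random fraction of positions
  per transcript is masked (inputs replaced by a learned mask token, or
  zeroed) and the model predicts read presence per read length at the
  masked positions only, under a 21-wide binary cross-entropy head.

Early stopping tracks validation loss with a configurable patience and the
best-validation weights are restored after fitting.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import average_precision_score

from .encoder import ModelConfig, TISNet, normalize_counts
from .ingest import N_READ_LENGTHS, ReadCountMatrix
from .nn import Adam, Tensor


def _as_inputs(x) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, ReadCountMatrix):
        return normalize_counts(x)
    dense = np.asarray(x, dtype=np.float64)
    if dense.ndim != 2 or dense.shape[1] != N_READ_LENGTHS:
        raise ValueError("dense inputs must be (length, 21) count arrays")
    return normalize_counts(ReadCountMatrix.from_dense("_", dense.astype(np.int64)))


def make_pretrain_labels(
    matrix: ReadCountMatrix | np.ndarray, read_presence_threshold: int = 1
) -> np.ndarray:
    """Per-position, per-read-length binary read-presence labels (L, 21)."""
    dense = matrix.to_dense() if isinstance(matrix, ReadCountMatrix) else np.asarray(matrix)
    return (dense >= read_presence_threshold).astype(np.float64)


class TISTransformer(BaseEstimator):
    """Per-position TIS (or read-presence) classifier over count profiles.

    Parameters mirror :class:`~riboscope.encoder.ModelConfig` plus the
    optimization settings. ``pos_weight="balanced"`` sets the positive-class
    weight to the train-set negative/positive ratio; a float fixes it.
    ``init_state`` warm-starts the encoder trunk from a previously fitted
    model's weights (the output head is re-initialized when the objective's
    head differs), which is how fine-tuning from a pretrained checkpoint is
    expressed. ``monitor`` selects the early-stopping/checkpoint criterion:
    ``"loss"`` (validation loss, the default) or ``"pr_auc"`` (validation
    average precision; useful under heavy positive weighting, which makes
    the weighted loss a noisy model selector).
    """

    def __init__(
        self,
        h: int = 32,
        n_layers: int = 4,
        n_heads: int = 4,
        attention_kind: str = "exact",
        dropout: float = 0.1,
        max_transcript_length: int = 8192,
        chunk_overlap: Optional[int] = None,
        ff_mult: int = 2,
        n_random_features: int = 64,
        positional: str = "relative",
        relative_window: int = 48,
        conv_stem_kernel: int = 13,
        weight_decay: float = 0.0,
        learning_rate: float = 1e-3,
        batch_size: int = 8,
        max_epochs: int = 40,
        patience: int = 3,
        objective: str = "supervised",
        mask_fraction: float = 0.15,
        mask_style: str = "token",
        read_presence_threshold: int = 1,
        pos_weight: str | float = "balanced",
        monitor: str = "loss",
        seed: int = 0,
        init_state: Optional[dict] = None,
    ):
        self.h = h
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.attention_kind = attention_kind
        self.dropout = dropout
        self.max_transcript_length = max_transcript_length
        self.chunk_overlap = chunk_overlap
        self.ff_mult = ff_mult
        self.n_random_features = n_random_features
        self.positional = positional
        self.relative_window = relative_window
        self.conv_stem_kernel = conv_stem_kernel
        self.weight_decay = weight_decay
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.objective = objective
        self.mask_fraction = mask_fraction
        self.mask_style = mask_style
        self.read_presence_threshold = read_presence_threshold
        self.pos_weight = pos_weight
        self.monitor = monitor
        self.seed = seed
        self.init_state = init_state

    # ------------------------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            h=self.h,
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            attention_kind=self.attention_kind,
            dropout=self.dropout,
            max_transcript_length=self.max_transcript_length,
            chunk_overlap=self.chunk_overlap,
            ff_mult=self.ff_mult,
            n_random_features=self.n_random_features,
            positional=self.positional,
            relative_window=self.relative_window,
            conv_stem_kernel=self.conv_stem_kernel,
            seed=self.seed,
        )

    def _validate(self, X, y) -> tuple[list, Optional[list]]:
        if self.objective not in ("supervised", "masked_pretrain"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if not 0.0 < self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        inputs = [_as_inputs(x) for x in X]
        labels = None
        if self.objective == "supervised":
            if y is None:
                raise ValueError("supervised objective requires per-position labels y")
            labels = [np.asarray(yy, dtype=np.float64) for yy in y]
            for (c, _l), yy in zip(inputs, labels):
                if yy.shape != c.shape:
                    raise ValueError("label length mismatch with transcript length")
        else:
            labels = [
                make_pretrain_labels(x, self.read_presence_threshold) for x in X
            ]
        return inputs, labels

    # ------------------------------------------------------------------

    def fit(
        self,
        X: Sequence,
        y: Optional[Sequence[np.ndarray]] = None,
        X_val: Optional[Sequence] = None,
        y_val: Optional[Sequence[np.ndarray]] = None,
        ids: Optional[Sequence[str]] = None,
    ) -> "TISTransformer":
        inputs, labels = self._validate(X, y)
        if not inputs:
            raise ValueError("empty training set")
        head = "tis" if self.objective == "supervised" else "pretrain"
        if self.objective == "supervised":
            n_pos = sum(float(yy.sum()) for yy in labels)
            n_tot = sum(yy.size for yy in labels)
            if n_pos == 0:
                raise ValueError("no positive labels in training set")
            self.pos_weight_ = (
                (n_tot - n_pos) / n_pos if self.pos_weight == "balanced" else float(self.pos_weight)
            )
        else:
            self.pos_weight_ = 1.0

        net = TISNet(self._model_config())
        if self.init_state is not None:
            own = net.state()
            merged = dict(own)
            for k, v in self.init_state.items():
                if k in own and own[k].shape == np.asarray(v).shape:
                    merged[k] = np.asarray(v, dtype=np.float64)
            net.load_state(merged)
        params = net.named_parameters()
        opt = Adam(params, lr=self.learning_rate, weight_decay=self.weight_decay)

        val = None
        if X_val is not None:
            if self.objective == "supervised":
                if y_val is None:
                    raise ValueError("X_val given without y_val")
                val = ([_as_inputs(x) for x in X_val], [np.asarray(v, float) for v in y_val])
            else:
                val = (
                    [_as_inputs(x) for x in X_val],
                    [make_pretrain_labels(x, self.read_presence_threshold) for x in X_val],
                )

        order_rng = np.random.default_rng([self.seed, 101])
        dropout_rng = np.random.default_rng([self.seed, 202]) if self.dropout > 0 else None
        self.history_ = []
        best_loss = np.inf
        best_state = net.state()
        best_epoch = 0
        n = len(inputs)
        lengths = np.array([len(ci) for ci, _ in inputs])
        for epoch in range(1, self.max_epochs + 1):
            idx = self._bucketed_order(order_rng, lengths)
            epoch_loss = 0.0
            epoch_weight = 0.0
            for start in range(0, n, self.batch_size):
                batch = idx[start : start + self.batch_size]
                loss, w = self._step(net, opt, [inputs[i] for i in batch],
                                     [labels[i] for i in batch], head, epoch,
                                     int(batch[0]), dropout_rng)
                epoch_loss += loss * w
                epoch_weight += w
            row = {"epoch": epoch, "train_loss": epoch_loss / max(epoch_weight, 1e-12)}
            if val is not None:
                row.update(self._eval_epoch(net, val[0], val[1], head, epoch))
                if self.monitor == "pr_auc" and "val_pr_auc" in row:
                    monitored = -row["val_pr_auc"]
                else:
                    monitored = row["val_loss"]
            else:
                monitored = row["train_loss"]
            self.history_.append(row)
            if monitored < best_loss - 1e-6:
                best_loss = monitored
                best_state = net.state()
                best_epoch = epoch
            elif epoch - best_epoch >= self.patience:
                break
        net.load_state(best_state)
        self.net_ = net
        self.state_ = best_state
        self.best_val_loss_ = float(best_loss)
        self.best_epoch_ = best_epoch
        self.n_epochs_ = len(self.history_)
        self.train_ids_ = list(ids) if ids is not None else None
        return self

    # ------------------------------------------------------------------

    def _bucketed_order(self, rng: np.random.Generator, lengths: np.ndarray) -> np.ndarray:
        """Shuffled order, locally sorted by length to limit padding waste."""
        idx = rng.permutation(len(lengths))
        pool = max(4 * self.batch_size, self.batch_size)
        out = []
        for start in range(0, len(idx), pool):
            chunk = idx[start : start + pool]
            out.append(chunk[np.argsort(lengths[chunk], kind="stable")])
        return np.concatenate(out) if out else idx

    def _masked_positions(self, L: int, epoch: int, item: int) -> np.ndarray:
        rng = np.random.default_rng([self.seed, 303, epoch, item])
        k = int(round(self.mask_fraction * L))
        masked = np.zeros(L, dtype=bool)
        if k:
            masked[rng.choice(L, size=k, replace=False)] = True
        return masked

    def _pad_batch(self, batch_inputs, batch_labels, head, epoch, base_item, masking):
        Ls = [len(c) for c, _ in batch_inputs]
        Lmax = max(Ls)
        B = len(batch_inputs)
        c = np.zeros((B, Lmax))
        l = np.zeros((B, Lmax, N_READ_LENGTHS))
        valid = np.zeros((B, Lmax), dtype=bool)
        if head == "tis":
            y = np.zeros((B, Lmax))
            w = np.zeros((B, Lmax))
        else:
            y = np.zeros((B, Lmax, N_READ_LENGTHS))
            w = np.zeros((B, Lmax, 1))
        masked = np.zeros((B, Lmax), dtype=bool) if masking else None
        for i, ((ci, li), yi) in enumerate(zip(batch_inputs, batch_labels)):
            L = Ls[i]
            c[i, :L] = ci
            l[i, :L] = li
            valid[i, :L] = True
            if head == "tis":
                y[i, :L] = yi
                w[i, :L] = np.where(yi > 0, self.pos_weight_, 1.0)
            else:
                y[i, :L] = yi
                m = self._masked_positions(L, epoch, base_item + i)
                if not m.any():  # nothing to predict on very short transcripts
                    continue
                masked[i, :L] = m
                w[i, :L, 0] = m.astype(float)
        if head != "tis":
            w = np.broadcast_to(w, y.shape).copy()
        return c, l, valid, y, w, masked

    def _loss_tensor(self, net: TISNet, c, l, valid, y, w, masked, head, dropout_rng):
        logits = net.forward(
            c, l, valid=valid, head=head, masked=masked,
            mask_style=self.mask_style, dropout_rng=dropout_rng,
        )
        yt = Tensor(y)
        wt = Tensor(w * (valid if head == "tis" else valid[..., None]))
        per = yt * (-logits).softplus() + (1.0 - yt) * logits.softplus()
        total_w = float(wt.data.sum())
        if total_w == 0:
            return None, 0.0
        return (per * wt).sum() / total_w, total_w

    def _step(self, net, opt, batch_inputs, batch_labels, head, epoch, base_item, dropout_rng):
        masking = head == "pretrain"
        c, l, valid, y, w, masked = self._pad_batch(
            batch_inputs, batch_labels, head, epoch, base_item, masking
        )
        loss, total_w = self._loss_tensor(net, c, l, valid, y, w, masked, head, dropout_rng)
        if loss is None:
            return 0.0, 0.0
        opt.zero_grad()
        loss.backward()
        opt.step()
        return loss.item(), total_w

    def _eval_epoch(self, net, inputs, labels, head, epoch) -> dict:
        """Validation loss (and, for the TIS head, average precision) from a
        single batched forward pass per chunk."""
        from .nn import no_grad

        total, weight = 0.0, 0.0
        masking = head == "pretrain"
        all_logits, all_y = [], []
        order = np.argsort([len(ci) for ci, _ in inputs], kind="stable")
        for start in range(0, len(order), self.batch_size):
            sel = order[start : start + self.batch_size]
            bi = [inputs[i] for i in sel]
            bl = [labels[i] for i in sel]
            c, l, valid, y, w, masked = self._pad_batch(bi, bl, head, epoch, 10_000 + start, masking)
            with no_grad():
                logits = net.forward(c, l, valid=valid, head=head, masked=masked,
                                     mask_style=self.mask_style)
                loss, tw = self._bce_from_logits(logits, y, w, valid, head)
            if loss is not None:
                total += loss * tw
                weight += tw
            if head == "tis":
                all_logits.append(logits.data[valid])
                all_y.append(y[valid])
        out = {"val_loss": total / max(weight, 1e-12)}
        if head == "tis":
            yv = np.concatenate(all_y)
            if yv.sum() > 0:
                sv = 1.0 / (1.0 + np.exp(-np.concatenate(all_logits)))
                out["val_pr_auc"] = float(average_precision_score(yv, sv))
        return out

    def _bce_from_logits(self, logits, y, w, valid, head):
        wt = w * (valid if head == "tis" else valid[..., None])
        total_w = float(wt.sum())
        if total_w == 0:
            return None, 0.0
        z = logits.data
        per = y * (np.maximum(-z, 0) + np.log1p(np.exp(-np.abs(z)))) + (1 - y) * (
            np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))
        )
        return float((per * wt).sum() / total_w), total_w

    def _batched_scores(self, net: TISNet, inputs) -> list[np.ndarray]:
        """Per-transcript TIS probabilities, batched with padding."""
        from .nn import no_grad

        order = np.argsort([len(ci) for ci, _ in inputs], kind="stable")
        out: list[Optional[np.ndarray]] = [None] * len(inputs)
        for start in range(0, len(order), self.batch_size):
            sel = order[start : start + self.batch_size]
            Ls = [len(inputs[i][0]) for i in sel]
            Lmax = max(Ls)
            c = np.zeros((len(sel), Lmax))
            l = np.zeros((len(sel), Lmax, N_READ_LENGTHS))
            valid = np.zeros((len(sel), Lmax), dtype=bool)
            for j, i in enumerate(sel):
                ci, li = inputs[i]
                c[j, : Ls[j]] = ci
                l[j, : Ls[j]] = li
                valid[j, : Ls[j]] = True
            with no_grad():
                logits = net.forward(c, l, valid=valid).data
            for j, i in enumerate(sel):
                out[i] = 1.0 / (1.0 + np.exp(-logits[j, : Ls[j]].astype(np.float64)))
        return out  # type: ignore[return-value]

    # ------------------------------------------------------------------

    def predict_proba(self, X: Sequence) -> list[np.ndarray]:
        """Per-transcript arrays of per-position TIS probabilities."""
        self._check_fitted()
        max_len = self.net_.cfg.max_transcript_length
        inputs = []
        overlong: dict[int, np.ndarray] = {}
        for i, x in enumerate(X):
            if isinstance(x, ReadCountMatrix) and x.length > max_len:
                overlong[i] = self.net_.score_positions(x)  # chunked path
                inputs.append((np.zeros(1), np.zeros((1, N_READ_LENGTHS))))
            else:
                inputs.append(_as_inputs(x))
        scores = self._batched_scores(self.net_, inputs)
        for i, s in overlong.items():
            scores[i] = s
        return scores

    def predict(self, X: Sequence, threshold: float = 0.5) -> list[np.ndarray]:
        return [(p > threshold).astype(int) for p in self.predict_proba(X)]

    def score(self, X: Sequence, y: Sequence[np.ndarray]) -> float:
        """Pooled average-precision (PR AUC) over all positions."""
        scores = np.concatenate(self.predict_proba(X))
        labels = np.concatenate([np.asarray(v) for v in y])
        return float(average_precision_score(labels, scores))

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
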