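"""Sequence encoder: per-position embeddings of RPF counts and a transformer.

Each transcript position is embedded from two features only — the
max-normalized total read count ``c`` at that position and the read-length
fraction vector ``l`` over lengths 20-40 — as

    e_c = e * tanh(phi(c))        (phi: two affine layers, nonlinearity between)
    e_l = sum_i E[i] * l[i]       (E: one learned row per read length)

and the position embedding is ``e_c + e_l``. Read-free positions carry
``l = 0`` so ``e_l`` is the zero vector there. No nucleotide sequence
enters the model. A stack of self-attention blocks (exact, or
kernel-approximated for long inputs) maps the embedded transcript to one
logit per position; logistic squashing yields a TIS probability per
nucleotide.

Positional information is configurable: the default is a learned relative
position bias added to the attention logits (clipped at
``relative_window`` nt), which makes the scorer translation-invariant —
the TIS signature (sharp onset of dense, 3-periodic coverage) is a local
relative pattern, not an absolute-coordinate one. Learned absolute
positional encodings are available as ``positional="absolute"`` (required
for the kernel-approximate attention path, which cannot carry an additive
bias), and ``"none"`` disables positional information for ablation.

The length-fraction vector has 21 entries, one per read length 20-40
inclusive; this matrix has exactly 21 rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .ingest import N_READ_LENGTHS, ReadCountMatrix
from .nn import Tensor, no_grad
from .nn.autodiff import Parameter
from .nn.layers import Dense, LayerNorm, LocalConv, Module, TransformerBlock

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    h: int = 32
    n_layers: int = 4
    n_heads: int = 4
    attention_kind: str = "exact"  # or "kernel-approximate"
    dropout: float = 0.1
    max_transcript_length: int = 8192
    chunk_overlap: Optional[int] = None  # None -> overlong transcripts error
    ff_mult: int = 2
    n_random_features: int = 64
    positional: str = "relative"  # "relative", "absolute" or "none"
    relative_window: int = 48
    conv_stem_kernel: int = 13  # 0 disables the local convolutional stem
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h % self.n_heads:
            raise ValueError("h must be divisible by n_heads")
        if self.attention_kind not in ("exact", "kernel-approximate"):
            raise ValueError(f"unknown attention_kind {self.attention_kind!r}")
        if self.positional not in ("relative", "absolute", "none"):
            raise ValueError(f"unknown positional mode {self.positional!r}")
        if self.conv_stem_kernel and self.conv_stem_kernel % 2 == 0:
            raise ValueError("conv_stem_kernel must be odd (same padding)")
        if self.positional == "relative" and self.attention_kind != "exact":
            raise ValueError(
                "relative position bias requires exact attention; use "
                "positional='absolute' (or 'none') with kernel-approximate attention"
            )


@dataclass
class PositionScores:
    transcript_id: str
    scores: np.ndarray  # one probability per transcript position

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


def normalize_counts(matrix: ReadCountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-position model inputs (c, l) from a count matrix.

    ``c[pos]`` is the total count at ``pos`` divided by the transcript-wide
    maximum (all zeros for a read-free transcript); ``l[pos]`` holds the
    per-read-length fractions at ``pos`` (zero vector at read-free positions).
    """
    dense = matrix.to_dense().astype(np.float64)
    raw = dense.sum(axis=1)
    peak = raw.max() if raw.size else 0.0
    c = raw / peak if peak > 0 else np.zeros_like(raw)
    l = np.zeros_like(dense)
    nz = raw > 0
    l[nz] = dense[nz] / raw[nz, None]
    return c, l


class InputEmbedding(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        h = cfg.h
        self.e = Parameter(rng.normal(0.0, 1.0, size=h))
        self.phi1 = Dense(1, h, rng)
        self.phi2 = Dense(h, h, rng)
        self.E = Parameter(rng.normal(0.0, 0.5, size=(N_READ_LENGTHS, h)))
        self.mask_token = Parameter(rng.normal(0.0, 0.5, size=h))
        if cfg.positional == "absolute":
            self.pos = Parameter(
                rng.normal(0.0, 0.02, size=(cfg.max_transcript_length, h))
            )
        self._positional = cfg.positional == "absolute"

    def phi(self, c: Tensor) -> Tensor:
        return self.phi2(self.phi1(c).gelu())

    def __call__(
        self,
        c: np.ndarray,  # (B, L)
        l: np.ndarray,  # (B, L, 21)
        masked: Optional[np.ndarray] = None,  # (B, L) bool
        mask_style: str = "token",
    ) -> Tensor:
        e_c = self.e * self.phi(Tensor(c[..., None])).tanh()
        e_l = Tensor(l) @ self.E
        x = e_c + e_l
        if masked is not None and masked.any():
            keep = Tensor((~masked)[..., None].astype(float))
            x = x * keep
            if mask_style == "token":
                x = x + self.mask_token * Tensor(masked[..., None].astype(float))
        if self._positional:
            L = c.shape[1]
            x = x + self.pos[:L]
        return x


def embed_position(c: float, l: np.ndarray, embedding: InputEmbedding) -> np.ndarray:
    """Embed a single position; validates the length-fraction vector."""
    l = np.asarray(l, dtype=float)
    if l.shape != (N_READ_LENGTHS,):
        raise ValueError(f"l must have {N_READ_LENGTHS} entries")
    if (l < 0).any():
        raise ValueError("l has negative entries")
    s = l.sum()
    if not (abs(s) <= 1e-6 or abs(s - 1.0) <= 1e-6):
        raise ValueError(f"sum(l) must be 0 or 1, got {s}")
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c must be in [0,1], got {c}")
    was_positional = embedding._positional
    embedding._positional = False
    try:
        with no_grad():
            out = embedding(np.array([[c]]), l[None, None, :])
    finally:
        embedding._positional = was_positional
    return out.data[0, 0]


class TISNet(Module):
    """Transformer over embedded count profiles with two output heads.

    The 1-wide head scores TIS presence per position; the 21-wide head
    predicts read presence per read length for the masked self-supervised
    objective. Both heads share the encoder trunk.
    """

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.emb = InputEmbedding(cfg, rng)
        self.stem = LocalConv(cfg.h, cfg.h, cfg.conv_stem_kernel, rng) if cfg.conv_stem_kernel else None
        rel = cfg.relative_window if cfg.positional == "relative" else 0
        self.blocks = [
            TransformerBlock(
                cfg.h,
                cfg.n_heads,
                rng,
                attention_kind=cfg.attention_kind,
                ff_mult=cfg.ff_mult,
                n_features=cfg.n_random_features,
                relative_window=rel,
            )
            for _ in range(cfg.n_layers)
        ]
        self.ln_f = LayerNorm(cfg.h)
        self.head_tis = Dense(cfg.h, 1, rng)
        self.head_pretrain = Dense(cfg.h, N_READ_LENGTHS, rng)

    def forward(
        self,
        c: np.ndarray,
        l: np.ndarray,
        valid: Optional[np.ndarray] = None,
        head: str = "tis",
        masked: Optional[np.ndarray] = None,
        mask_style: str = "token",
        dropout_rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Logits: (B, L) for the TIS head, (B, L, 21) for the pretrain head."""
        B, L = c.shape
        if L > self.cfg.max_transcript_length:
            raise ValueError(
                f"input length {L} exceeds max_transcript_length "
                f"{self.cfg.max_transcript_length}; configure chunk_overlap to chunk"
            )
        if valid is None:
            valid = np.ones((B, L), dtype=bool)
        x = self.emb(c, l, masked=masked, mask_style=mask_style)
        if not valid.all():
            # zero padded positions so batched and unbatched scoring agree
            x = x * Tensor(valid[..., None].astype(x.data.dtype))
        if self.stem is not None:
            x = x + self.stem(x).gelu()
        p = self.cfg.dropout if dropout_rng is not None else 0.0
        for blk in self.blocks:
            x = blk(x, valid, dropout=p, rng=dropout_rng)
        x = self.ln_f(x)
        if head == "tis":
            return self.head_tis(x).reshape(B, L)
        if head == "pretrain":
            return self.head_pretrain(x)
        raise ValueError(f"unknown head {head!r}")

    def score_positions(self, matrix: ReadCountMatrix) -> np.ndarray:
        """TIS probabilities for one transcript, chunking overlong inputs."""
        c, l = normalize_counts(matrix)
        L = len(c)
        max_len = self.cfg.max_transcript_length
        with no_grad():
            if L <= max_len:
                logits = self.forward(c[None], l[None]).data[0]
            else:
                if self.cfg.chunk_overlap is None:
                    raise ValueError(
                        f"{matrix.transcript_id}: length {L} exceeds "
                        f"max_transcript_length {max_len} and chunking is not configured"
                    )
                logits = self._chunked_logits(c, l, max_len, self.cfg.chunk_overlap)
        return 1.0 / (1.0 + np.exp(-logits))

    def _chunked_logits(
        self, c: np.ndarray, l: np.ndarray, window: int, overlap: int
    ) -> np.ndarray:
        if not 0 < overlap < window:
            raise ValueError("chunk_overlap must be in (0, max_transcript_length)")
        L = len(c)
        logits = np.zeros(L)
        step = window - overlap
        start = 0
        while start < L:
            end = min(start + window, L)
            piece = self.forward(c[None, start:end], l[None, start:end]).data[0]
            keep_from = 0 if start == 0 else overlap // 2
            logits[start + keep_from : end] = piece[keep_from:]
            if end == L:
                break
            start += step
        return logits


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(path: str | Path, net: TISNet, extra: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["version"] = CHECKPOINT_VERSION
        fh.attrs["config"] = json.dumps(asdict(net.cfg))
        if extra:
            fh.attrs["extra"] = json.dumps(extra)
        g = fh.create_group("weights")
        for name, arr in net.state().items():
            g.create_dataset(name, data=arr)
    Path(str(path) + ".json").write_text(
        json.dumps({"version": CHECKPOINT_VERSION, "config": asdict(net.cfg)}, indent=2)
    )


def load_checkpoint(path: str | Path) -> tuple[TISNet, dict]:
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs["version"])
        if version != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {version} incompatible with {CHECKPOINT_VERSION}"
            )
        cfg = ModelConfig(**json.loads(fh.attrs["config"]))
        state = {name: ds[()] for name, ds in fh["weights"].items()}
        extra = json.loads(fh.attrs["extra"]) if "extra" in fh.attrs else {}
    net = TISNet(cfg)
    net.load_state(state)
    return net, extra
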