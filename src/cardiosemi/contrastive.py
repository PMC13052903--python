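"""Contrastive consistency over encoder embeddings.

A batch of images and their augmented views are pushed through the encoder;
the embedding of an image and of its augmented view form a positive pair,
while the other images in the batch act as negatives.  The loss is a
modified NT-Xent on cosine similarities of ℓ2-normalised embeddings:

    ℓ(h_i, h_i^aug) = −log[ exp(sim(h_i, h_i^aug)/τ)
                            / Σ_{t≠i} exp(sim(h_i, h_t)/τ) ]

where the denominator runs over the B−1 *other original* embeddings only —
it excludes the positive pair, so the loss can be negative.  The batch loss
averages both directions over the batch:
L_con = (1/2B) Σ_k [ℓ(h_k, h_k^aug) + ℓ(h_k^aug, h_k)].  A
``simclr_denominator`` switch replaces the denominator by the standard
NT-Xent one (all 2B−1 other embeddings including the positive), which is
guaranteed non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = ["EmbeddingBatch", "pool_embedding", "pairwise_nt_xent", "nt_xent_t"]

DEFAULT_TEMPERATURE = 0.1


@dataclass(frozen=True)
class EmbeddingBatch:
    """Paired original/augmented embeddings, each (B, d) with B ≥ 2."""

    original: np.ndarray
    augmented: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        orig = np.asarray(self.original, dtype=float)
        aug = np.asarray(self.augmented, dtype=float)
        if orig.shape != aug.shape or orig.ndim != 2:
            raise ValueError(
                f"original/augmented must both be (B, d), got {orig.shape} and {aug.shape}")
        if orig.shape[0] < 2:
            raise ValueError("contrastive batch needs B >= 2 (at least one negative)")
        if not (np.all(np.isfinite(orig)) and np.all(np.isfinite(aug))):
            raise ValueError("embeddings must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature τ must be > 0")
        object.__setattr__(self, "original", orig)
        object.__setattr__(self, "augmented", aug)


def pool_embedding(feature_field) -> np.ndarray:
    """Collapse a (h', w', d) feature field to a d-vector by global spatial
    averaging."""
    f = np.asarray(feature_field, dtype=float)
    if f.ndim != 3 or f.size == 0:
        raise ValueError(f"expected nonempty (h', w', d) field, got shape {f.shape}")
    return f.mean(axis=(0, 1))


def _l2_normalize_t(x: Tensor) -> Tensor:
    norm = ((x * x).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    return x / norm


def nt_xent_t(original: Tensor, augmented: Tensor, temperature: float,
              simclr_denominator: bool = False) -> Tensor:
    """Differentiable NT-Xent consistency loss on (B, d) embedding Tensors."""
    b = original.shape[0]
    if b < 2:
        raise ValueError("contrastive batch needs B >= 2")
    hn = _l2_normalize_t(original)
    an = _l2_normalize_t(augmented)
    inv_t = 1.0 / temperature
    pos = (hn * an).sum(axis=1) * inv_t  # (B,) sim(h_i, h_i^aug)/τ, both directions

    dtype = original.dtype
    if simclr_denominator:
        # standard NT-Xent: anchors are all 2B embeddings, denominator over
        # the 2B-1 others (positive included)
        all_emb = _cat_rows(hn, an)
        sims = (all_emb @ all_emb.transpose(1, 0)) * inv_t  # (2B, 2B)
        mask = (1.0 - np.eye(2 * b)).astype(dtype)
        den = ((sims.exp() * Tensor(mask)).sum(axis=1)).log()  # (2B,)
        num = _cat_rows_1d(pos, pos)
        return ((den - num).sum()) / float(2 * b)

    off_diag = (1.0 - np.eye(b)).astype(dtype)
    # anchors = originals: negatives are the other originals
    s_orig = (hn @ hn.transpose(1, 0)) * inv_t
    den_orig = ((s_orig.exp() * Tensor(off_diag)).sum(axis=1)).log()
    # anchors = augmented views: denominator again over the other originals
    s_aug = (an @ hn.transpose(1, 0)) * inv_t
    den_aug = ((s_aug.exp() * Tensor(off_diag)).sum(axis=1)).log()
    total = (den_orig - pos).sum() + (den_aug - pos).sum()
    return total / float(2 * b)


def _cat_rows(a: Tensor, b: Tensor) -> Tensor:
    from .autodiff import concatenate
    return concatenate([a, b], axis=0)


_cat_rows_1d = _cat_rows


def pairwise_nt_xent(batch: EmbeddingBatch, simclr_denominator: bool = False) -> float:
    """NT-Xent consistency loss of an :class:`EmbeddingBatch` (NumPy in,
    float out)."""
    return float(
        nt_xent_t(Tensor(batch.original), Tensor(batch.augmented),
                  batch.temperature, simclr_denominator)
    )
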