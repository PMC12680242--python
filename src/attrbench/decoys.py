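"""Permutation decoy genotypes for the precision benchmark.

Decoys are built on the fly by permuting sample indices within each chunk of
SNP columns. One row permutation is drawn per (split, chunk) and shared by
every SNP column in the chunk, which preserves per-SNP genotype multisets
(and within-chunk structure) while destroying genotype-phenotype
correspondence. The permutation is a pure function of
(decoy_seed + split_offset + chunk_idx), so decoys are reproducible across
epochs yet independent across splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["DecoyConfig", "permute_chunk", "expand_features"]

SPLITS = ("train", "validation", "test")


@dataclass(frozen=True)
class DecoyConfig:
    decoy_seed: int = 0
    # large co-prime offsets so (seed + offset + chunk_idx) never collides
    # across splits for any realistic chunk count
    split_offsets: dict = field(
        default_factory=lambda: {"train": 0, "validation": 1_000_003, "test": 2_000_003}
    )
    chunk_size: int = 10_000

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ConfigurationError("chunk_size must be >= 1")
        offs = list(self.split_offsets.values())
        if len(set(offs)) != len(offs):
            raise ConfigurationError("split offsets must be pairwise distinct")

    def permutation(self, n_rows: int, split: str, chunk_idx: int) -> np.ndarray:
        """Deterministic row permutation for one (split, chunk)."""
        if split not in self.split_offsets:
            raise ConfigurationError(f"unknown split {split!r}")
        key = self.decoy_seed + self.split_offsets[split] + chunk_idx
        # counter-based generator: stable seed -> permutation mapping
        rng = np.random.Generator(np.random.Philox(key=key))
        return rng.permutation(n_rows)


def permute_chunk(
    chunk: np.ndarray,
    split: str,
    chunk_idx: int,
    cfg: DecoyConfig,
) -> np.ndarray:
    """Apply the (split, chunk)-specific row permutation to a genotype chunk."""
    perm = cfg.permutation(chunk.shape[0], split, chunk_idx)
    return chunk[perm]


def expand_features(
    G: np.ndarray,
    cfg: DecoyConfig,
    split: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate [real | decoy] along features, returning labels.

    Returns ``(expanded, is_decoy)`` where ``expanded`` has twice as many
    columns as ``G`` and ``is_decoy`` is a boolean vector over the expanded
    feature axis (False for the leading real block).
    """
    n, m = G.shape
    if m == 0:
        return G.copy(), np.zeros(0, dtype=bool)
    decoy = np.empty_like(G)
    for chunk_idx, start in enumerate(range(0, m, cfg.chunk_size)):
        stop = min(start + cfg.chunk_size, m)
        decoy[:, start:stop] = permute_chunk(G[:, start:stop], split, chunk_idx, cfg)
    expanded = np.concatenate([G, decoy], axis=1)
    is_decoy = np.concatenate([np.zeros(m, dtype=bool), np.ones(m, dtype=bool)])
    return expanded, is_decoy
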