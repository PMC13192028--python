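"""The per-cell, per-position, per-base, per-strand mtDNA read-count tensor.

This is the raw substrate every heteroplasmy statistic is computed from.  Only
positions that actually carry data are stored (mgatk-style output is sparse in
the same sense); within stored positions the array is dense:
``counts[cell, position, base, strand]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import BASES, MT_GENOME_LENGTH

PLUS, MINUS = 0, 1


@dataclass
class BaseCountTensor:
    """Read counts per (cell, mtDNA position, base, strand).

    Parameters
    ----------
    barcodes
        Cell barcodes, unique, length N.
    positions
        Sorted unique 1-based mtDNA positions actually stored, length P.
    ref_bases
        Reference base per stored position, length P.
    counts
        ``int64`` array of shape (N, P, 4, 2); base axis ordered A,C,G,T,
        strand axis ordered (+, -).
    """

    barcodes: list[str]
    positions: np.ndarray
    ref_bases: np.ndarray
    counts: np.ndarray
    _pos_index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_bases = np.asarray(self.ref_bases, dtype="<U1")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n, p = len(self.barcodes), len(self.positions)
        if len(set(self.barcodes)) != n:
            raise ValueError("duplicated cell barcodes")
        if self.counts.shape != (n, p, 4, 2):
            raise ValueError(
                f"counts shape {self.counts.shape} != {(n, p, 4, 2)}"
            )
        if p and (self.positions.min() < 1 or self.positions.max() > MT_GENOME_LENGTH):
            raise ValueError("positions outside mtDNA genome")
        if p and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be sorted and unique")
        if self.ref_bases.shape != (p,):
            raise ValueError("ref_bases length mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")
        self._pos_index = {int(pos): i for i, pos in enumerate(self.positions)}

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def position_index(self, pos: int) -> int:
        try:
            return self._pos_index[int(pos)]
        except KeyError:
            raise KeyError(f"position {pos} not stored in tensor") from None

    def ref_base(self, pos: int) -> str:
        return str(self.ref_bases[self.position_index(pos)])

    def coverage(self) -> np.ndarray:
        """Total coverage per (cell, stored position): sum over bases and strands."""
        return self.counts.sum(axis=(2, 3))

    def allele_counts(self, pos: int, base: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell (+, -) strand read counts for ``base`` at ``pos``."""
        pi = self.position_index(pos)
        bi = BASES.index(base)
        return self.counts[:, pi, bi, PLUS], self.counts[:, pi, bi, MINUS]

    def mean_coverage_per_cell(self) -> np.ndarray:
        """Mean coverage per cell over stored positions (mtDNA sequencing depth proxy)."""
        if self.n_positions == 0:
            return np.zeros(self.n_cells)
        return self.coverage().mean(axis=1)

    def subset_cells(self, barcodes: list[str]) -> "BaseCountTensor":
        index = {b: i for i, b in enumerate(self.barcodes)}
        rows = [index[b] for b in barcodes]
        return BaseCountTensor(
            barcodes=list(barcodes),
            positions=self.positions.copy(),
            ref_bases=self.ref_bases.copy(),
            counts=self.counts[rows].copy(),
        )

    @classmethod
    def concat(cls, tensors: list["BaseCountTensor"]) -> "BaseCountTensor":
        """Pool cells from several tensors sharing the same stored positions.

        Used to compute variant filter statistics across a donor's
        longitudinal samples.  Barcodes must be globally unique.
        """
        if not tensors:
            raise ValueError("no tensors to concatenate")
        first = tensors[0]
        for t in tensors[1:]:
            if not np.array_equal(t.positions, first.positions):
                raise ValueError("tensors store different position sets")
            if not np.array_equal(t.ref_bases, first.ref_bases):
                raise ValueError("tensors disagree on reference bases")
        return cls(
            barcodes=[b for t in tensors for b in t.barcodes],
            positions=first.positions.copy(),
            ref_bases=first.ref_bases.copy(),
            counts=np.concatenate([t.counts for t in tensors], axis=0),
        )
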