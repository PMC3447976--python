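"""In-memory containers for count and fraction tables.

The canonical orientation everywhere in this package is samples x
components: row ``s`` holds one sample (one sequencing library, one
community draw), column ``d`` holds one component (OTU, gene, taxon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CountTable", "FractionTable"]

_ROW_SUM_TOL = 1e-12


def _check_ids(ids: list[str], what: str, expected: int) -> list[str]:
    ids = [str(i) for i in ids]
    if len(ids) != expected:
        raise ValueError(f"{what}: expected {expected} ids, got {len(ids)}")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what}: {dupes}")
    return ids


@dataclass
class CountTable:
    """Nonnegative integer counts, samples x components.

    Parameters
    ----------
    counts
        ``(S, D)`` array of nonnegative integers.
    sample_ids, component_ids
        Unique identifiers matching the matrix dimensions.
    taxonomy
        Optional map from component id to a lineage string.
    """

    counts: np.ndarray
    sample_ids: list[str]
    component_ids: list[str]
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(counts, rounded):
                bad = np.argwhere(counts != rounded)[0]
                raise ValueError(
                    f"non-integer count at sample index {bad[0]}, "
                    f"component index {bad[1]}"
                )
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample index {bad[0]}, component index {bad[1]}"
            )
        self.counts = counts.astype(np.int64, copy=False)
        self.sample_ids = _check_ids(self.sample_ids, "sample_ids", counts.shape[0])
        self.component_ids = _check_ids(
            self.component_ids, "component_ids", counts.shape[1]
        )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_components(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class FractionTable:
    """Strictly positive fractions, samples x components; rows sum to 1."""

    fractions: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    component_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 2:
            raise ValueError("fractions must be a 2-D matrix")
        if (f <= 0).any():
            raise ValueError("fractions must be strictly positive (log-transformable)")
        sums = f.sum(axis=1)
        if np.abs(sums - 1.0).max() > _ROW_SUM_TOL * max(1, f.shape[1]):
            worst = int(np.abs(sums - 1.0).argmax())
            raise ValueError(
                f"row {worst} sums to {sums[worst]!r}, not 1 within tolerance"
            )
        self.fractions = f
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(f.shape[0])]
        if not self.component_ids:
            self.component_ids = [f"c{i}" for i in range(f.shape[1])]
        self.sample_ids = _check_ids(self.sample_ids, "sample_ids", f.shape[0])
        self.component_ids = _check_ids(
            self.component_ids, "component_ids", f.shape[1]
        )

    @property
    def n_samples(self) -> int:
        return self.fractions.shape[0]

    @property
    def n_components(self) -> int:
        return self.fractions.shape[1]
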