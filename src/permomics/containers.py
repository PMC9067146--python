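"""Core in-memory containers shared across pipeline stages.

An :class:`OmicsMatrix` is a feature-by-sample table of abundances plus a
sample-metadata frame and a layer tag recording what scale the values are on:

``fpkm``
    non-negative transcript abundances (fragments per kilobase per million);
``lognorm``
    log2(FPKM + 1), usually quantile-normalized;
``protein``
    normalized log-scale protein reporter abundances (may be negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("fpkm", "lognorm", "protein")


class PermomicsError(Exception):
    """Base class for errors raised by this package."""


class InvalidDesignError(PermomicsError):
    """A synthetic-data design violates its constraints."""


class LayerMismatchError(PermomicsError):
    """An operation was applied to a matrix with the wrong layer tag."""


class SchemaError(PermomicsError):
    """A file or table does not conform to the expected schema."""


@dataclass
class OmicsMatrix:
    """Feature-by-sample abundance matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, one column per sample id.
    metadata
        DataFrame indexed by sample id with grouping columns
        (e.g. ``cell_type``, ``condition``, ``replicate`` or ``group``).
    layer
        One of ``fpkm``, ``lognorm``, ``protein``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise LayerMismatchError(
                f"unknown layer {self.layer!r}; expected one of {LAYERS}"
            )
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate feature ids in matrix")
        if self.values.columns.has_duplicates:
            raise SchemaError("duplicate sample ids in matrix")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise SchemaError(f"samples missing from metadata: {sorted(missing)}")
        if self.layer == "fpkm":
            vals = self.values.to_numpy()
            if vals.size and np.nanmin(vals) < 0:
                raise SchemaError("fpkm layer requires non-negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_layer(self, *layers: str) -> None:
        if self.layer not in layers:
            raise LayerMismatchError(
                f"operation requires layer in {layers}, got {self.layer!r}"
            )

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata matches every ``column=value`` condition."""
        mask = pd.Series(True, index=self.metadata.index)
        for col, val in conditions.items():
            mask &= self.metadata[col] == val
        ids = list(self.metadata.index[mask])
        return [s for s in self.sample_ids if s in set(ids)]

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        return OmicsMatrix(
            values=self.values[sample_ids].copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
            layer=self.layer,
        )

    def copy_with(self, values: pd.DataFrame, layer: str | None = None) -> "OmicsMatrix":
        return OmicsMatrix(
            values=values,
            metadata=self.metadata.copy(),
            layer=layer if layer is not None else self.layer,
        )


@dataclass
class GeneSet:
    """One annotation term: id, human name, ontology level, level-1 module, members."""

    term_id: str
    name: str
    level: int
    module: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise SchemaError(f"term {self.term_id} has no members")
        self.members = frozenset(self.members)


@dataclass
class GeneSetCollection:
    """Mapping of term id -> :class:`GeneSet`, GMT-backed.

    The GMT description field encodes ``level|module`` so that round-trips
    preserve the level-1 grouping used for network modules.
    """

    terms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, term in self.terms.items():
            if tid != term.term_id:
                raise SchemaError(f"key {tid} does not match term id {term.term_id}")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.terms[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def add(self, term: GeneSet) -> None:
        if term.term_id in self.terms:
            raise SchemaError(f"duplicate term id {term.term_id}")
        self.terms[term.term_id] = term

    def restricted_to(self, universe) -> "GeneSetCollection":
        """Intersect every member set with ``universe``; drop emptied terms."""
        universe = frozenset(universe)
        out = GeneSetCollection()
        for term in self:
            kept = term.members & universe
            if kept:
                out.add(GeneSet(term.term_id, term.name, term.level, term.module, kept))
        return out

    def modules(self) -> list[str]:
        return sorted({t.module for t in self})
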