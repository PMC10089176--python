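"""Tip-to-area assignments: the observed geographic data G.

Each sampled pathogen contributes a single observation — the discrete area
(city, state, country, ...) in which it was sampled.  ``GeographicData``
holds the ordered list of ``k`` area labels and the map from tip label to
area index; the ordering fixes the indexing of the rate matrix Q, so it is
deterministic (lexicographic unless the user supplies an explicit list).
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from .tree import Tree

__all__ = ["GeographicData", "read_tip_areas"]


@dataclass(frozen=True)
class GeographicData:
    """Observed areas at the tips of a companion tree.

    ``areas`` is the ordered area-label tuple (length k >= 2); ``tip_area``
    maps tip label -> area index in ``[0, k)``.
    """

    areas: tuple[str, ...]
    tip_area: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("area labels must be unique")
        if len(self.areas) < 2:
            raise ValueError("need at least k = 2 areas")
        k = len(self.areas)
        for taxon, a in self.tip_area.items():
            if not 0 <= a < k:
                raise ValueError(f"area index {a} for tip {taxon!r} out of range")

    @property
    def k(self) -> int:
        return len(self.areas)

    def tip_state_vector(self, tree: Tree) -> np.ndarray:
        """Per-node observed state (-1 for internal nodes), aligned to node ids."""
        states = np.full(tree.n_nodes, -1, dtype=np.int64)
        for node, label in tree.tip_labels.items():
            if label not in self.tip_area:
                raise ValueError(f"tree tip {label!r} has no area assignment")
            states[node] = self.tip_area[label]
        return states

    def area_counts(self) -> np.ndarray:
        counts = np.zeros(self.k, dtype=np.int64)
        for a in self.tip_area.values():
            counts[a] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, self.areas[a]) for t, a in sorted(self.tip_area.items())]
        return pd.DataFrame(rows, columns=["taxon", "area"])


def read_tip_areas(
    table: str,
    tree: Tree,
    *,
    areas: list[str] | None = None,
    sep: str | None = None,
    on_extra_taxa: str = "error",
) -> GeographicData:
    """Read a two-column (taxon, area) delimited table against a tree.

    ``k`` is the number of distinct observed areas unless ``areas`` declares
    an explicit ordered list, which may include unsampled areas — the area
    count changes the route prior, so it is never inflated silently.
    ``on_extra_taxa`` is ``"error"`` or ``"ignore"`` for table rows whose
    taxon is absent from the tree.
    """
    if sep is None:
        sep = "\t" if "\t" in table.splitlines()[0] else ","
    df = pd.read_csv(StringIO(table), sep=sep, dtype=str, skipinitialspace=True)
    if df.shape[1] < 2:
        raise ValueError("tip-area table needs two columns: taxon, area")
    df.columns = [c.strip().lower() for c in df.columns]
    taxon_col, area_col = df.columns[:2]
    mapping = dict(zip(df[taxon_col].str.strip(), df[area_col].str.strip()))

    tree_tips = set(tree.tip_labels.values())
    extra = set(mapping) - tree_tips
    if extra:
        if on_extra_taxa == "error":
            raise ValueError(f"taxa in table absent from tree: {sorted(extra)}")
        for t in extra:
            del mapping[t]
    missing = tree_tips - set(mapping)
    if missing:
        raise ValueError(f"tree tips missing from table: {sorted(missing)}")

    observed = sorted(set(mapping.values()))
    if areas is None:
        area_list = observed
    else:
        area_list = list(areas)
        undeclared = set(observed) - set(area_list)
        if undeclared:
            raise ValueError(f"areas observed but not declared: {sorted(undeclared)}")
    index = {a: i for i, a in enumerate(area_list)}
    return GeographicData(
        areas=tuple(area_list),
        tip_area={t: index[a] for t, a in mapping.items()},
    )
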