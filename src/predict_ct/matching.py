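"""Cell-type matching across species or tissues by marker-gene overlap.

Marker genes of a cell type are the genes with preferential-expression
Z >= 2 (inclusive). Markers of one side may be translated through an
ortholog map (many-to-many resolved by union of images). Each pair of cell
types is compared by the Jaccard index of the marker sets, and a pair is
called matching when its Jaccard is >= 0.05 and lies in the top decile of
all pairwise values of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

DEFAULT_MARKER_Z = 2.0
DEFAULT_JACCARD_MIN = 0.05
DEFAULT_PERCENTILE_CUT = 0.90

MATCH_COLUMNS = ["cell_type_a", "cell_type_b", "jaccard", "percentile_rank", "matched"]


@dataclass(frozen=True)
class OrthologMap:
    """Gene pairs (species A <-> species B); may be many-to-many."""

    pairs: frozenset  # of (gene_a, gene_b)

    def __post_init__(self):
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair in ortholog map: {a!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologMap":
        return cls(frozenset(tuple(p) for p in pairs))

    @classmethod
    def from_tsv(cls, path: str) -> "OrthologMap":
        t = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_pairs(zip(t["gene_a"], t["gene_b"]))

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(sorted(self.pairs), columns=["gene_a", "gene_b"]).to_csv(
            path, sep="\t", index=False)

    def forward(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
        return out

    def reverse(self) -> "OrthologMap":
        return OrthologMap(frozenset((b, a) for a, b in self.pairs))


def marker_genes(z, threshold: float = DEFAULT_MARKER_Z) -> dict[str, set[str]]:
    """Markers per cell type: genes with Z >= threshold (inclusive).

    ``z`` is a :class:`~predict_ct.expr.PreferentialExpression`. Empty marker
    sets are allowed.
    """
    arr = z.z.to_numpy()
    genes = z.genes.to_numpy()
    return {ct: set(genes[arr[:, j] >= threshold])
            for j, ct in enumerate(z.cell_types)}


def map_orthologs(markers: set[str], orthologs: OrthologMap) -> tuple[set[str], int]:
    """Translate a marker set through the ortholog map (union of images).

    Returns the mapped set and the number of markers without any ortholog.
    """
    if not orthologs.pairs:
        raise ValueError("empty ortholog map")
    fwd = orthologs.forward()
    image: set[str] = set()
    unmapped = 0
    for g in markers:
        if g in fwd:
            image |= fwd[g]
        else:
            unmapped += 1
    return image, unmapped


def jaccard_index(a: set, b: set) -> float:
    """|a n b| / |a u b|; two empty sets give 0 by convention."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def call_matches(markers_a: Mapping[str, set[str]],
                 markers_b: Mapping[str, set[str]],
                 jaccard_min: float = DEFAULT_JACCARD_MIN,
                 percentile_cut: float = DEFAULT_PERCENTILE_CUT,
                 orthologs: Optional[OrthologMap] = None) -> pd.DataFrame:
    """Jaccard similarity of every AxB cell-type pair plus match calls.

    ``percentile_rank`` of a pair is the fraction of all pairwise Jaccard
    values (of this comparison) that are <= its value; a pair matches when
    jaccard >= ``jaccard_min`` and percentile_rank >= ``percentile_cut``
    (both inclusive), i.e. membership in the top decile at defaults.

    If ``orthologs`` is given, side-A markers are translated into B's gene
    space before comparison.
    """
    if not markers_a or not markers_b:
        raise ValueError("both sides need at least one cell type")
    if orthologs is not None:
        markers_a = {ct: map_orthologs(m, orthologs)[0]
                     for ct, m in markers_a.items()}
    cts_a = sorted(markers_a)
    cts_b = sorted(markers_b)
    rows = [(ca, cb, jaccard_index(markers_a[ca], markers_b[cb]))
            for ca in cts_a for cb in cts_b]
    table = pd.DataFrame(rows, columns=["cell_type_a", "cell_type_b", "jaccard"])
    vals = table["jaccard"].to_numpy()
    order = np.sort(vals)
    table["percentile_rank"] = np.searchsorted(order, vals, side="right") / len(vals)
    table["matched"] = ((table["jaccard"] >= jaccard_min)
                        & (table["percentile_rank"] >= percentile_cut))
    return table


def rematch_excluding_genes(markers_a: Mapping[str, set[str]],
                            markers_b: Mapping[str, set[str]],
                            exclusion: set[str],
                            jaccard_min: float = DEFAULT_JACCARD_MIN,
                            percentile_cut: float = DEFAULT_PERCENTILE_CUT,
                            orthologs: Optional[OrthologMap] = None,
                            exclusion_b: Optional[set[str]] = None,
                            ) -> tuple[pd.DataFrame, float]:
    """Robustness check: repeat matching after removing ``exclusion`` genes
    (e.g. disease genes) from the marker sets.

    Returns the re-run MatchTable and the concordance fraction
    |matched_before n matched_after| / |matched_before| (1.0 when nothing was
    matched before).
    """
    if exclusion_b is None:
        exclusion_b = exclusion
    before = call_matches(markers_a, markers_b, jaccard_min, percentile_cut,
                          orthologs=orthologs)
    ex_a = {ct: m - exclusion for ct, m in markers_a.items()}
    ex_b = {ct: m - exclusion_b for ct, m in markers_b.items()}
    after = call_matches(ex_a, ex_b, jaccard_min, percentile_cut,
                         orthologs=orthologs)
    key = ["cell_type_a", "cell_type_b"]
    m_before = set(map(tuple, before.loc[before["matched"], key].itertuples(index=False)))
    m_after = set(map(tuple, after.loc[after["matched"], key].itertuples(index=False)))
    concordance = (len(m_before & m_after) / len(m_before)) if m_before else 1.0
    return after, concordance
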